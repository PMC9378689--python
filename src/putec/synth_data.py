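"""Synthetic fixtures with known ground truth.

Every pipeline stage has a generator here that emits both a fixture and
the ground truth it was built from, so round-trip tests never depend on
external downloads:

* two-module pseudo-C-alpha models with a known swivel rotation applied
  about a bridge-helix-parallel axis (plus optional coordinate noise);
* idealized A-form duplexes, RNA-DNA hybrid scaffolds and minor-groove
  triples built from the idealized base templates;
* gel-lane datasets with known anti-pausing activities and
  multiplicative log-normal noise;
* charge-state peak series from a known neutral mass (see
  :mod:`putec.masscalc`).

All generators are pure functions of their arguments and seed.  Helical
geometry uses fiber A-form twist/rise; the helix is idealized (zero
base-pair inclination, axis through the C1'-C1' midpoints), which keeps
the generated ground truth exact for axis and kink measurements.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import _bases, _chemistry
from .structure_io import Atom, DomainSet, SelectionExpr, StructureModel, write_structure
from .assay_stats import LaneQuant

__all__ = [
    "SwivelFixture",
    "DuplexFixture",
    "GelFixture",
    "make_two_module_model",
    "make_duplex",
    "make_gel_dataset",
    "write_fixture",
]

A_FORM_TWIST = 32.7  # degrees per base pair
A_FORM_RISE = 2.81  # Angstrom per base pair

COMPLEMENT = {"A": "U", "U": "A", "G": "C", "C": "G"}
DNA_NAME = {"A": "DA", "C": "DC", "G": "DG", "U": "DT", "T": "DT"}

#: crude ribose/phosphate offsets from C1' in the local base frame
#: (x toward C1' from the glycosidic N, z the base normal); idealized
#: plumbing so fixtures exercise full-residue I/O, not refined geometry
SUGAR_OFFSETS = {
    "O4'": (0.65, 1.25, 0.30),
    "C2'": (1.00, -0.90, 0.80),
    "O2'": (0.60, -2.20, 0.60),
    "C3'": (2.40, -0.60, 1.00),
    "O3'": (3.20, -1.60, 0.50),
    "C4'": (2.10, 0.90, 0.90),
    "C5'": (2.90, 2.00, 0.40),
    "O5'": (2.60, 3.00, 1.30),
    "P": (3.30, 4.30, 1.10),
    "OP1": (4.70, 4.30, 1.00),
    "OP2": (2.70, 5.30, 2.00),
}


def _rotation_about(axis: np.ndarray, angle_deg: float) -> np.ndarray:
    axis = np.asarray(axis, float)
    n = np.linalg.norm(axis)
    if n < 1e-12:
        raise ValueError("degenerate (zero) rotation axis")
    axis = axis / n
    th = math.radians(angle_deg)
    k = np.array([[0, -axis[2], axis[1]],
                  [axis[2], 0, -axis[0]],
                  [-axis[1], axis[0], 0]])
    return np.eye(3) + math.sin(th) * k + (1 - math.cos(th)) * (k @ k)


# ---------------------------------------------------------------------------
# swivel fixture


@dataclass(frozen=True)
class SwivelFixture:
    reference: StructureModel
    target: StructureModel
    true_angle: float
    true_axis: np.ndarray
    axis_point: np.ndarray
    noise_sigma: float
    seed: int
    marked_tip_displacement: float
    marked_tip: tuple
    domain_set: DomainSet


def make_two_module_model(n_core: int = 300, n_swivel: int = 300,
                          angle: float = 2.5,
                          axis: np.ndarray | None = None,
                          noise_sigma: float = 0.0,
                          seed: int = 0) -> SwivelFixture:
    """Reference/target pair of pseudo-C-alpha models with a known swivel.

    The reference holds a ``core`` cloud (chain C), a ``swivel`` cloud
    (chain S) and a straight bridge-helix marker line (chain H, included
    in the core module).  The target applies the requested rotation to
    the swivel cloud about an axis through the bridge-helix line (the
    axis direction defaults to the bridge-helix direction), then adds
    i.i.d. Gaussian coordinate noise.
    """
    if n_core < 50 or n_swivel < 50:
        raise ValueError("n_core and n_swivel must be >= 50")
    if not 0.0 <= angle <= 20.0:
        raise ValueError("swivel angle must be in [0, 20] degrees")
    rng = np.random.default_rng(seed)

    bh_dir = np.array([1.0, 0.15, 0.1])
    bh_dir /= np.linalg.norm(bh_dir)
    if axis is None:
        rot_axis = bh_dir.copy()
    else:
        rot_axis = np.asarray(axis, float)
        n = np.linalg.norm(rot_axis)
        if n < 1e-12:
            raise ValueError("degenerate (zero) swivel axis")
        rot_axis = rot_axis / n
    axis_point = np.zeros(3)

    core_xyz = rng.uniform([-50, -50, -30], [50, 50, 30], size=(n_core, 3))
    swivel_xyz = rng.uniform([-40, 25, -30], [40, 85, 30], size=(n_swivel, 3))
    t_vals = np.linspace(-17.0, 17.0, 31)
    bh_xyz = axis_point + t_vals[:, None] * bh_dir[None, :]

    def atoms_of(chain: str, xyz: np.ndarray, start_serial: int) -> list[Atom]:
        return [Atom(serial=start_serial + i, name="CA", element="C",
                     residue_name="GLY", chain_id=chain, residue_number=i + 1,
                     insertion_code="", position=xyz[i])
                for i in range(len(xyz))]

    ref_atoms = (atoms_of("C", core_xyz, 1)
                 + atoms_of("H", bh_xyz, n_core + 1)
                 + atoms_of("S", swivel_xyz, n_core + 32))
    reference = StructureModel("synthetic-reference", ref_atoms)

    rot = _rotation_about(rot_axis, angle)
    swivel_rot = (swivel_xyz - axis_point) @ rot.T + axis_point
    disp = np.linalg.norm(swivel_rot - swivel_xyz, axis=1)
    tip_idx = int(np.argmax(disp))
    tip_displacement = float(disp[tip_idx])

    tgt_core = core_xyz + rng.normal(0.0, noise_sigma, core_xyz.shape) \
        if noise_sigma > 0 else core_xyz
    tgt_bh = bh_xyz + rng.normal(0.0, noise_sigma, bh_xyz.shape) \
        if noise_sigma > 0 else bh_xyz
    tgt_swivel = swivel_rot + rng.normal(0.0, noise_sigma, swivel_rot.shape) \
        if noise_sigma > 0 else swivel_rot
    tgt_atoms = (atoms_of("C", tgt_core, 1)
                 + atoms_of("H", tgt_bh, n_core + 1)
                 + atoms_of("S", tgt_swivel, n_core + 32))
    target = StructureModel("synthetic-target", tgt_atoms)

    # five contiguous blocks of the swivel chain stand in for the five
    # swivel-module members
    bounds = np.linspace(1, n_swivel + 1, 6).astype(int)
    members = {}
    for name, lo, hi in zip(("clamp", "shelf", "jaw", "si3", "betaprime_cterm"),
                            bounds[:-1], bounds[1:] - 1):
        members[name] = [SelectionExpr(chain_id="S", residue_ranges=((int(lo), int(hi)),))]
    domains = DomainSet(name="synthetic-two-module", domains={
        "core": [SelectionExpr(chain_id="C"), SelectionExpr(chain_id="H")],
        "bridge_helix": [SelectionExpr(chain_id="H")],
        **members,
    })

    return SwivelFixture(
        reference=reference, target=target, true_angle=float(angle),
        true_axis=rot_axis, axis_point=axis_point, noise_sigma=float(noise_sigma),
        seed=int(seed), marked_tip_displacement=tip_displacement,
        marked_tip=("S", tip_idx + 1, "", "CA"), domain_set=domains,
    )


# ---------------------------------------------------------------------------
# duplex / hybrid / triplex fixture


@dataclass(frozen=True)
class DuplexFixture:
    model: StructureModel
    n_pairs: int
    form: str
    bend_angle: float
    third_strand: bool
    sequence: str
    pair_list: tuple[tuple[tuple, tuple], ...]  # ground-truth (strand1, strand2) keys
    triple_residues: tuple[tuple, ...] = ()
    i_plus_1_template: int | None = None


def _residue_atoms_from_template(base_coords: dict[str, np.ndarray],
                                 code: str, rna: bool) -> dict[str, np.ndarray]:
    """Full heavy-atom nucleotide: template base + crude sugar/phosphate."""
    gn = _bases.GLYCOSIDIC_N[code]
    origin = base_coords[gn]
    x = base_coords["C1'"] - origin
    x = x / np.linalg.norm(x)
    ring = [nm for nm in _bases.RING_ATOMS[code] if nm in base_coords]
    pts = np.array([base_coords[nm] for nm in ring])
    _, _, vt = np.linalg.svd(pts - pts.mean(axis=0))
    z = vt[2]
    z = z - (z @ x) * x
    z = z / np.linalg.norm(z)
    y = np.cross(z, x)
    frame = np.column_stack([x, y, z])
    out = dict(base_coords)
    c1 = base_coords["C1'"]
    for nm, off in SUGAR_OFFSETS.items():
        if nm == "O2'" and not rna:
            continue
        out[nm] = c1 + frame @ np.asarray(off, float)
    return out


def _place(coords: dict[str, np.ndarray], rot: np.ndarray,
           trans: np.ndarray) -> dict[str, np.ndarray]:
    return {nm: rot @ p + trans for nm, p in coords.items()}


def make_duplex(sequence: str | int = 10, form: str = "A_RNA",
                bend_angle: float = 0.0, third_strand: bool = False,
                template_overhang_5: int = 0,
                partial_occupancy_3prime: bool = False) -> DuplexFixture:
    """Idealized duplex (or hybrid scaffold) with ground-truth pairs.

    ``sequence`` is the strand-1 (RNA) sequence 5'->3', or a length for
    a default alternating sequence.  ``form`` is ``A_RNA`` (both strands
    RNA, chains R and S) or ``hybrid_RNA_DNA`` (RNA chain R vs template
    DNA chain T).  An optional mid-helix bend and an optional
    minor-groove third strand (chain Q, one U per purine of strand 1)
    are supported.  For hybrid scaffolds, ``template_overhang_5`` adds
    unpaired template nucleotides past the RNA 3' end (the substrate
    i+1 site and downstream), and ``partial_occupancy_3prime`` models
    the RNA 3' residue at half occupancy (a mixed translocation
    population).
    """
    if isinstance(sequence, int):
        if sequence < 4:
            raise ValueError("duplex length must be >= 4")
        sequence = ("GAUC" * ((sequence + 3) // 4))[:sequence]
    sequence = sequence.upper().replace("T", "U")
    if len(sequence) < 4:
        raise ValueError("duplex length must be >= 4")
    if any(ch not in COMPLEMENT for ch in sequence):
        raise ValueError(f"invalid RNA sequence {sequence!r}")
    if not 0.0 <= bend_angle <= 60.0:
        raise ValueError("bend angle must be in [0, 60] degrees")
    if form not in ("A_RNA", "hybrid_RNA_DNA"):
        raise ValueError(f"unknown duplex form {form!r}")

    hybrid = form == "hybrid_RNA_DNA"
    chain2 = "T" if hybrid else "S"
    n = len(sequence)

    res_coords: list[tuple[str, int, str, bool, dict]] = []  # chain, resnum, resname, rna, atoms
    pair_list = []
    triple_residues = []

    def pair_template_for(b1: str):
        b2 = COMPLEMENT[b1]
        if b1 in ("A", "G"):
            a, b = _bases.wc_pair_template(b1, b2)
            return a, b
        a, b = _bases.wc_pair_template(b2, b1)
        return b, a

    for k, b1 in enumerate(sequence):
        c1_tpl, c2_tpl = pair_template_for(b1)
        b2 = COMPLEMENT[b1]
        # centre the pair on the C1'-C1' midpoint so the helix axis runs
        # through the pair centres (idealized zero-displacement helix)
        mid = 0.5 * (c1_tpl["C1'"] + c2_tpl["C1'"])
        rot = _rotation_about(np.array([0.0, 0.0, 1.0]), A_FORM_TWIST * k)
        trans = np.array([0.0, 0.0, A_FORM_RISE * k])
        nt1 = _residue_atoms_from_template(
            {nm: p - mid for nm, p in c1_tpl.items()}, b1, rna=True)
        nt2 = _residue_atoms_from_template(
            {nm: p - mid for nm, p in c2_tpl.items()}, b2, rna=not hybrid)
        nt1 = _place(nt1, rot, trans)
        nt2 = _place(nt2, rot, trans)
        res1 = (("R", k + 1, b1, True, nt1))
        # strand 2 is antiparallel: residue numbering runs the other way
        name2 = DNA_NAME[b2] if hybrid else b2
        res2 = ((chain2, n - k + template_overhang_5, name2, not hybrid, nt2))
        res_coords.append(res1)
        res_coords.append(res2)
        pair_list.append((("R", k + 1, ""), (chain2, n - k + template_overhang_5, "")))

        if third_strand and b1 in ("A", "G"):
            third = _third_strand_base(c1_tpl, b1)
            if third is not None:
                third = {nm: p - mid for nm, p in third.items()}
                nt3 = _residue_atoms_from_template(third, "G", rna=True)
                nt3 = _place(nt3, rot, trans)
                res_coords.append(("Q", k + 1, "G", True, nt3))
                triple_residues.append(("Q", k + 1, ""))

    # template overhang past the RNA 3' terminus (i+1 site and downstream)
    i_plus_1 = None
    if hybrid and template_overhang_5 > 0:
        for j in range(template_overhang_5):
            k_ext = n + j
            rot = _rotation_about(np.array([0.0, 0.0, 1.0]), A_FORM_TWIST * k_ext)
            trans = np.array([0.0, 0.0, A_FORM_RISE * k_ext])
            # an unpaired template adenine continuing the strand-2 helix track
            c1_tpl, c2_tpl = pair_template_for("U")
            mid = 0.5 * (c1_tpl["C1'"] + c2_tpl["C1'"])
            nt2 = _residue_atoms_from_template(
                {nm: p - mid for nm, p in c2_tpl.items()}, "A", rna=False)
            nt2 = _place(nt2, rot, trans)
            res_coords.append((chain2, template_overhang_5 - j, "DA", False, nt2))
        i_plus_1 = template_overhang_5

    # optional mid-helix bend: rotate the top half about an in-plane axis
    if bend_angle > 0:
        z_split = A_FORM_RISE * (n / 2.0 - 0.5)
        bend_rot = _rotation_about(np.array([0.0, 1.0, 0.0]), bend_angle)
        pivot = np.array([0.0, 0.0, z_split])
        bent = []
        for chain, resnum, resname, rna, atoms in res_coords:
            ctr_z = float(np.mean([p[2] for p in atoms.values()]))
            if ctr_z > z_split:
                atoms = {nm: bend_rot @ (p - pivot) + pivot for nm, p in atoms.items()}
            bent.append((chain, resnum, resname, rna, atoms))
        res_coords = bent

    atoms: list[Atom] = []
    serial = 0
    res_coords.sort(key=lambda r: (r[0], r[1]))
    for chain, resnum, resname, rna, amap in res_coords:
        occ = 1.0
        if partial_occupancy_3prime and chain == "R" and resnum == n:
            occ = 0.5
        for nm in sorted(amap):
            serial += 1
            atoms.append(Atom(
                serial=serial, name=nm, element=nm[0], residue_name=resname,
                chain_id=chain, residue_number=resnum, insertion_code="",
                position=amap[nm], occupancy=occ))
    model = StructureModel(f"synthetic-{form}-{n}bp", atoms)
    return DuplexFixture(
        model=model, n_pairs=n, form=form, bend_angle=float(bend_angle),
        third_strand=third_strand, sequence=sequence,
        pair_list=tuple(pair_list), triple_residues=tuple(triple_residues),
        i_plus_1_template=i_plus_1,
    )


def _third_strand_base(purine_coords: dict[str, np.ndarray],
                       code: str) -> dict[str, np.ndarray] | None:
    """Place a minor-groove G donating its N2 to a purine's N3 acceptor.

    A purine third base is required: only a purine's glycosidic carbon
    sits far enough from its minor-groove edge for the third-strand
    C1'-C1' distance to reach the canonical pairing window.
    """
    ctr = np.mean([purine_coords[nm] for nm in ("N1", "C2", "N3", "C4", "C5", "C6")],
                  axis=0)
    if "N3" not in purine_coords:
        return None
    acc = purine_coords["N3"]
    d = acc - ctr
    d = d / np.linalg.norm(d)
    target = acc + d * _bases.HBOND_TARGET

    tpl = _bases.base_template("G")
    best = None
    for mirror in (False, True):
        t = {nm: (p * np.array([1.0, -1.0, 1.0]) if mirror else p)
             for nm, p in tpl.items()}
        tctr = np.mean([t[nm] for nm in ("N1", "C2", "N3", "C4", "C5", "C6")], axis=0)
        r2 = t["N2"] - tctr
        r2 = r2 / np.linalg.norm(r2)
        # rotate about z so the G N2 radial points back at the acceptor
        ang = math.atan2(-d[1], -d[0]) - math.atan2(r2[1], r2[0])
        rot = _rotation_about(np.array([0.0, 0.0, 1.0]), math.degrees(ang))
        placed0 = {nm: rot @ p for nm, p in t.items()}
        placed0 = {nm: p + (target - placed0["N2"]) for nm, p in placed0.items()}
        # swing the base about its N2 contact (hbond preserved) so the
        # third-strand C1' falls in the canonical C1'-C1' window
        for phi in np.arange(-120.0, 121.0, 2.0):
            swing = _rotation_about(np.array([0.0, 0.0, 1.0]), float(phi))
            placed = {nm: swing @ (p - target) + target
                      for nm, p in placed0.items()}
            c1c1 = float(np.linalg.norm(placed["C1'"] - purine_coords["C1'"]))
            min_d = min(float(np.linalg.norm(p - q))
                        for nm, p in placed.items()
                        for nm2, q in purine_coords.items()
                        if not (nm == "N2" and nm2 == "N3"))
            ok_window = 7.5 <= c1c1 <= 11.5
            key = (not ok_window, min_d < 2.5, abs(c1c1 - 8.0))
            if best is None or key < best[0]:
                best = (key, placed)
    return best[1]


# ---------------------------------------------------------------------------
# gel fixture


@dataclass(frozen=True)
class GelFixture:
    lanes: tuple[LaneQuant, ...]
    true_activities: dict[str, float]
    p_wt: float
    p_putminus: float
    noise_cv: float
    seed: int


def make_gel_dataset(true_activities: dict[str, float],
                     p_wt: float = 0.05, p_putminus: float = 0.60,
                     n_replicates: int = 3, noise_cv: float = 0.05,
                     seed: int = 0,
                     n_c_paused: int = 24, n_c_runoff: int = 30) -> GelFixture:
    """Gel lanes realising known anti-pausing activities.

    Each lane's paused fraction is inverted from the activity formula,
    converted to paused/run-off molar amounts, scaled by the transcript
    cytosine counts (the label enters via cytosines), and perturbed with
    multiplicative log-normal noise of the requested CV.  Labels ``WT``
    and ``put-`` (activities 1 and 0) are always included as anchors.
    """
    if p_wt == p_putminus:
        raise ValueError("P_WT and P_put- must differ")
    if not 0.0 <= noise_cv <= 0.5:
        raise ValueError("noise_cv must be in [0, 0.5]")
    acts = dict(true_activities)
    acts.setdefault("WT", 1.0)
    acts.setdefault("put-", 0.0)
    for label, a in acts.items():
        if not -0.2 <= a <= 1.2:
            raise ValueError(f"{label}: activity {a} outside the plausible [-0.2, 1.2]")
    rng = np.random.default_rng(seed)
    sigma = math.sqrt(math.log(1.0 + noise_cv ** 2)) if noise_cv > 0 else 0.0

    lanes = []
    total_molar = 1000.0
    for rep in range(1, n_replicates + 1):
        for label in sorted(acts):
            p_x = p_wt + (1.0 - acts[label]) * (p_putminus - p_wt)
            paused_molar = p_x * total_molar
            runoff_molar = (1.0 - p_x) * total_molar
            noise_p = math.exp(rng.normal(-0.5 * sigma ** 2, sigma)) if sigma else 1.0
            noise_r = math.exp(rng.normal(-0.5 * sigma ** 2, sigma)) if sigma else 1.0
            lanes.append(LaneQuant(
                label=label,
                paused_intensity=paused_molar * n_c_paused * noise_p,
                runoff_intensity=runoff_molar * n_c_runoff * noise_r,
                n_c_paused=n_c_paused, n_c_runoff=n_c_runoff,
                replicate_id=rep, time_min=0.5,
            ))
    return GelFixture(lanes=tuple(lanes), true_activities=acts,
                      p_wt=p_wt, p_putminus=p_putminus,
                      noise_cv=float(noise_cv), seed=int(seed))


# ---------------------------------------------------------------------------
# fixture export


def write_fixture(fixture, out_dir: str | Path) -> dict[str, Path]:
    """Write a fixture as standard files plus a ground-truth JSON sidecar."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}
    if isinstance(fixture, SwivelFixture):
        paths["reference"] = out / "reference.pdb"
        paths["target"] = out / "target.pdb"
        write_structure(fixture.reference, paths["reference"])
        write_structure(fixture.target, paths["target"])
        truth = {
            "true_angle": fixture.true_angle,
            "true_axis": fixture.true_axis.tolist(),
            "noise_sigma": fixture.noise_sigma,
            "seed": fixture.seed,
            "marked_tip": list(fixture.marked_tip),
            "marked_tip_displacement": fixture.marked_tip_displacement,
        }
    elif isinstance(fixture, DuplexFixture):
        paths["model"] = out / "duplex.pdb"
        write_structure(fixture.model, paths["model"])
        truth = {
            "n_pairs": fixture.n_pairs,
            "form": fixture.form,
            "bend_angle": fixture.bend_angle,
            "sequence": fixture.sequence,
            "pairs": [[list(a), list(b)] for a, b in fixture.pair_list],
            "triple_residues": [list(t) for t in fixture.triple_residues],
            "i_plus_1_template": fixture.i_plus_1_template,
        }
    elif isinstance(fixture, GelFixture):
        import pandas as pd
        paths["lanes"] = out / "lanes.csv"
        pd.DataFrame([{
            "label": ln.label, "replicate": ln.replicate_id,
            "paused_intensity": ln.paused_intensity,
            "runoff_intensity": ln.runoff_intensity,
            "n_c_paused": ln.n_c_paused, "n_c_runoff": ln.n_c_runoff,
            "time_min": ln.time_min,
        } for ln in fixture.lanes]).to_csv(paths["lanes"], index=False)
        truth = {
            "true_activities": fixture.true_activities,
            "p_wt": fixture.p_wt, "p_putminus": fixture.p_putminus,
            "noise_cv": fixture.noise_cv, "seed": fixture.seed,
        }
    else:
        raise TypeError(f"unknown fixture type {type(fixture).__name__}")
    paths["ground_truth"] = out / "ground_truth.json"
    paths["ground_truth"].write_text(json.dumps(truth, indent=2))
    return paths
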