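"""Solvent-accessible surface area, buried interfaces, and polar contacts.

The buried surface area (BSA) between two selections follows the PISA
convention: half the total solvent-accessible surface area lost upon
complex formation, BSA = (SASA(A) + SASA(B) - SASA(A+B)) / 2.  SASA is
computed by Shrake-Rupley sphere sampling with a deterministic
golden-spiral point set, so results are bit-stable across runs.

Polar contacts are typed as hydrogen bonds, salt bridges, or cation-pi
interactions using heavy-atom geometric criteria (the deposited models
have no hydrogens, so all contacts are "potential" in the
crystallographer's sense).  Salt bridges take priority over hydrogen
bonds for the same atom pair.

Also provides in-silico base substitution: replacing a base with an
idealized template superposed on the glycosidic anchor atoms, used to
recount hydrogen bonds a substituted base could make with a binding
pocket.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
from scipy.spatial import cKDTree

from . import _bases, _chemistry
from .structure_io import Atom, SelectionError, StructureModel, select_atoms

__all__ = [
    "SASAResult",
    "InterfaceReport",
    "Contact",
    "shrake_rupley_sasa",
    "buried_surface_area",
    "detect_polar_contacts",
    "mutate_base",
    "load_radii",
    "golden_spiral_points",
]

HBOND_CUTOFF = 3.5  # donor-acceptor heavy atom distance, Angstrom
HBOND_MIN_ANGLE = 90.0  # donor-acceptor-antecedent, degrees
SALT_BRIDGE_CUTOFF = 4.0
CATION_PI_CUTOFF = 6.0
CATION_PI_MAX_ANGLE = 30.0  # centroid->N vector vs ring normal
INTERFACE_RESIDUE_MIN_BSA = 0.1  # Angstrom^2

_RADII_PATH = Path(__file__).parent / "data" / "vdw_radii.json"


def load_radii(path: str | Path = _RADII_PATH) -> tuple[str, dict[str, float], float]:
    data = json.loads(Path(path).read_text())
    return data["name"], {k.upper(): float(v) for k, v in data["radii"].items()}, \
        float(data.get("default", 1.7))


@dataclass(frozen=True)
class SASAResult:
    per_atom_area: dict[tuple, float]
    total: float
    probe_radius: float
    n_sphere_points: int
    radii_set_name: str


@dataclass(frozen=True)
class InterfaceReport:
    bsa: float
    partner_a: object
    partner_b: object
    interface_residues_a: dict[tuple, float]
    interface_residues_b: dict[tuple, float]
    fraction_residues_a: float
    fraction_residues_b: float
    radii_set_name: str

    def to_dict(self) -> dict:
        return {
            "bsa": self.bsa,
            "fraction_residues_a": self.fraction_residues_a,
            "fraction_residues_b": self.fraction_residues_b,
            "n_interface_residues_a": len(self.interface_residues_a),
            "n_interface_residues_b": len(self.interface_residues_b),
            "radii_set_name": self.radii_set_name,
        }


@dataclass(frozen=True)
class Contact:
    kind: str  # hbond | salt_bridge | cation_pi
    atom_a: tuple
    atom_b: tuple
    distance: float
    angle: float | None
    residue_a: tuple
    residue_b: tuple

    def sort_key(self):
        return (self.kind, self.residue_a, self.residue_b,
                self.atom_a, self.atom_b, round(self.distance, 6))


def golden_spiral_points(n: int) -> np.ndarray:
    """Deterministic, nearly uniform unit-sphere point set (Fibonacci spiral)."""
    if n < 1:
        raise ValueError("need at least one sphere point")
    k = np.arange(n, dtype=float)
    z = 1.0 - (2.0 * k + 1.0) / n
    phi = k * math.pi * (3.0 - math.sqrt(5.0))
    r = np.sqrt(np.clip(1.0 - z * z, 0.0, None))
    return np.column_stack([r * np.cos(phi), r * np.sin(phi), z])


def _atom_list(model_or_atoms) -> list[Atom]:
    if isinstance(model_or_atoms, StructureModel):
        return list(model_or_atoms.atoms)
    return list(model_or_atoms)


def shrake_rupley_sasa(model_or_atoms, probe_radius: float = 1.4,
                       n_points: int = 960,
                       radii: dict[str, float] | None = None,
                       radii_name: str | None = None) -> SASAResult:
    """Per-atom solvent-accessible surface area by sphere sampling.

    Each atom's extended sphere (vdW radius + probe) is sampled with a
    deterministic golden-spiral point set; a point is accessible when it
    lies outside every neighbouring extended sphere.
    """
    atoms = _atom_list(model_or_atoms)
    if not atoms:
        raise ValueError("SASA of an empty atom set is undefined")
    if radii is None:
        radii_name, radii, default_r = load_radii()
    else:
        radii = {k.upper(): float(v) for k, v in radii.items()}
        radii_name = radii_name or "user-supplied"
        default_r = None
    if default_r is None:
        missing = sorted({a.element.upper() for a in atoms
                          if a.element.upper() not in radii})
        if missing:
            raise ValueError(f"no van der Waals radius for element(s): {missing}")

    coords = np.array([a.position for a in atoms])
    rad = np.array([radii.get(a.element.upper(),
                              default_r if default_r is not None else math.nan)
                    for a in atoms])
    ext = rad + probe_radius
    sphere = golden_spiral_points(n_points)

    tree = cKDTree(coords)
    max_ext = float(ext.max())
    per_atom: dict[tuple, float] = {}
    total = 0.0
    for i, atom in enumerate(atoms):
        pts = coords[i] + ext[i] * sphere
        neighbours = [j for j in tree.query_ball_point(coords[i], ext[i] + max_ext)
                      if j != i]
        if neighbours:
            nb_xyz = coords[neighbours]
            nb_ext = ext[neighbours]
            d2 = np.sum((pts[:, None, :] - nb_xyz[None, :, :]) ** 2, axis=2)
            buried = np.any(d2 < (nb_ext ** 2)[None, :], axis=1)
            n_acc = int(np.count_nonzero(~buried))
        else:
            n_acc = n_points
        area = (n_acc / n_points) * 4.0 * math.pi * ext[i] ** 2
        per_atom[atom.atom_key] = area
        total += area
    return SASAResult(per_atom_area=per_atom, total=total,
                      probe_radius=probe_radius, n_sphere_points=n_points,
                      radii_set_name=radii_name or "bondi-1964-extended")


def _per_residue(atoms: list[Atom], areas: dict[tuple, float]) -> dict[tuple, float]:
    out: dict[tuple, float] = {}
    for a in atoms:
        out[a.residue_key] = out.get(a.residue_key, 0.0) + areas.get(a.atom_key, 0.0)
    return out


def buried_surface_area(model: StructureModel, a, b,
                        probe_radius: float = 1.4, n_points: int = 960,
                        radii: dict[str, float] | None = None) -> InterfaceReport:
    """Buried surface area between two disjoint selections (PISA convention)."""
    atoms_a = select_atoms(model, a)
    atoms_b = select_atoms(model, b)
    keys_a = {x.atom_key for x in atoms_a}
    overlap = [x for x in atoms_b if x.atom_key in keys_a]
    if overlap:
        raise SelectionError(
            f"partner selections overlap at {overlap[0].atom_key} (A and B must be disjoint)"
        )
    kw = dict(probe_radius=probe_radius, n_points=n_points, radii=radii)
    sasa_a = shrake_rupley_sasa(atoms_a, **kw)
    sasa_b = shrake_rupley_sasa(atoms_b, **kw)
    sasa_ab = shrake_rupley_sasa(atoms_a + atoms_b, **kw)
    bsa = (sasa_a.total + sasa_b.total - sasa_ab.total) / 2.0

    res_a_alone = _per_residue(atoms_a, sasa_a.per_atom_area)
    res_b_alone = _per_residue(atoms_b, sasa_b.per_atom_area)
    res_a_cplx = _per_residue(atoms_a, sasa_ab.per_atom_area)
    res_b_cplx = _per_residue(atoms_b, sasa_ab.per_atom_area)
    iface_a = {k: v - res_a_cplx.get(k, 0.0) for k, v in res_a_alone.items()
               if v - res_a_cplx.get(k, 0.0) > INTERFACE_RESIDUE_MIN_BSA}
    iface_b = {k: v - res_b_cplx.get(k, 0.0) for k, v in res_b_alone.items()
               if v - res_b_cplx.get(k, 0.0) > INTERFACE_RESIDUE_MIN_BSA}
    n_res_a = len({x.residue_key for x in atoms_a})
    n_res_b = len({x.residue_key for x in atoms_b})
    return InterfaceReport(
        bsa=float(bsa), partner_a=a, partner_b=b,
        interface_residues_a=iface_a, interface_residues_b=iface_b,
        fraction_residues_a=len(iface_a) / n_res_a,
        fraction_residues_b=len(iface_b) / n_res_b,
        radii_set_name=sasa_a.radii_set_name,
    )


# ---------------------------------------------------------------------------
# polar contacts


def _residue_atoms(atoms: list[Atom]) -> dict[tuple, dict[str, Atom]]:
    out: dict[tuple, dict[str, Atom]] = {}
    for a in atoms:
        out.setdefault(a.residue_key, {})[a.name] = a
    return out


def _hbond_angle_ok(donor: Atom, acceptor: Atom, antecedent: Atom | None) -> tuple[bool, float | None]:
    if antecedent is None:
        return True, None
    v1 = donor.position - acceptor.position
    v2 = antecedent.position - acceptor.position
    denom = np.linalg.norm(v1) * np.linalg.norm(v2)
    if denom == 0:
        return True, None
    ang = math.degrees(math.acos(min(1.0, max(-1.0, float(v1 @ v2) / denom))))
    return ang >= HBOND_MIN_ANGLE, ang


def _ring_geometry(res_atoms: dict[str, Atom], ring: tuple[str, ...]):
    pts = [res_atoms[nm].position for nm in ring if nm in res_atoms]
    if len(pts) < 3:
        return None
    pts = np.array(pts)
    centroid = pts.mean(axis=0)
    _, _, vt = np.linalg.svd(pts - centroid)
    return centroid, vt[2] / np.linalg.norm(vt[2])


def _directional_hbonds(donor_res: tuple, donor_atoms_map: dict[str, Atom],
                        acc_res: tuple, acc_atoms_map: dict[str, Atom],
                        cutoff: float) -> list[tuple[Atom, Atom, float, float | None]]:
    d_name = next(iter(donor_atoms_map.values())).residue_name
    a_name = next(iter(acc_atoms_map.values())).residue_name
    donors = _chemistry.donor_atoms(d_name)
    acceptors = _chemistry.acceptor_atoms(a_name)
    hits = []
    for dn in donors:
        if dn not in donor_atoms_map:
            continue
        datom = donor_atoms_map[dn]
        for an, ante in acceptors.items():
            if an not in acc_atoms_map:
                continue
            aatom = acc_atoms_map[an]
            dist = float(np.linalg.norm(datom.position - aatom.position))
            if dist > cutoff:
                continue
            ok, ang = _hbond_angle_ok(datom, aatom, acc_atoms_map.get(ante))
            if ok:
                hits.append((datom, aatom, dist, ang))
    return hits


def detect_polar_contacts(model: StructureModel, a, b,
                          hbond_cutoff: float = HBOND_CUTOFF,
                          salt_bridge_cutoff: float = SALT_BRIDGE_CUTOFF,
                          cation_pi_cutoff: float = CATION_PI_CUTOFF,
                          cation_pi_max_angle: float = CATION_PI_MAX_ANGLE
                          ) -> list[Contact]:
    """Typed polar contacts between two disjoint selections.

    Returns hydrogen bonds (donor-acceptor <= cutoff with the antecedent
    angle criterion), salt bridges (charged-group nitrogen to phosphate
    or carboxylate oxygen), and cation-pi contacts (charged nitrogen to
    aromatic/base ring centroid, near the ring normal).  A pair that
    qualifies as both salt bridge and hydrogen bond is reported once, as
    a salt bridge.
    """
    atoms_a = select_atoms(model, a)
    atoms_b = select_atoms(model, b)
    keys_a = {x.atom_key for x in atoms_a}
    if any(x.atom_key in keys_a for x in atoms_b):
        raise SelectionError("contact partners must be disjoint selections")
    res_a = _residue_atoms(atoms_a)
    res_b = _residue_atoms(atoms_b)

    contacts: dict[tuple, Contact] = {}

    def note(c: Contact):
        key = (c.atom_a, c.atom_b)
        prev = contacts.get(key)
        if prev is None or (prev.kind == "hbond" and c.kind == "salt_bridge"):
            contacts[key] = c

    # hydrogen bonds, both donor directions
    for ra, amap in res_a.items():
        for rb, bmap in res_b.items():
            for datom, aatom, dist, ang in _directional_hbonds(ra, amap, rb, bmap, hbond_cutoff):
                note(Contact("hbond", datom.atom_key, aatom.atom_key, dist, ang,
                             datom.residue_key, aatom.residue_key))
            for datom, aatom, dist, ang in _directional_hbonds(rb, bmap, ra, amap, hbond_cutoff):
                note(Contact("hbond", aatom.atom_key, datom.atom_key, dist, ang,
                             aatom.residue_key, datom.residue_key))

    # salt bridges
    def cations(res_map):
        for rk, amap in res_map.items():
            rn = next(iter(amap.values())).residue_name.upper()
            for nm in _chemistry.CATION_ATOMS.get(rn, ()):  # charged N (and Arg CZ)
                if nm in amap and amap[nm].element.upper() == "N":
                    yield amap[nm]

    def anions(res_map):
        for rk, amap in res_map.items():
            rn = next(iter(amap.values())).residue_name.upper()
            for nm in _chemistry.ANION_ATOMS_PROTEIN.get(rn, ()):
                if nm in amap:
                    yield amap[nm]
            if _chemistry.base_code(rn) is not None:
                for nm in _chemistry.PHOSPHATE_OXYGENS:
                    if nm in amap:
                        yield amap[nm]

    for side_cat, side_ani, flip in ((res_a, res_b, False), (res_b, res_a, True)):
        for nat in cations(side_cat):
            for oat in anions(side_ani):
                dist = float(np.linalg.norm(nat.position - oat.position))
                if dist <= salt_bridge_cutoff:
                    at_a, at_b = (oat, nat) if flip else (nat, oat)
                    note(Contact("salt_bridge", at_a.atom_key, at_b.atom_key, dist,
                                 None, at_a.residue_key, at_b.residue_key))

    # cation-pi
    def rings(res_map):
        for rk, amap in res_map.items():
            rn = next(iter(amap.values())).residue_name
            for ring in _chemistry.ring_definitions(rn):
                geo = _ring_geometry(amap, ring)
                if geo is not None:
                    yield rk, next(iter(amap.values())), geo

    for side_cat, side_ring, flip in ((res_a, res_b, False), (res_b, res_a, True)):
        for nat in cations(side_cat):
            for rk, any_atom, (centroid, normal) in rings(side_ring):
                v = nat.position - centroid
                dist = float(np.linalg.norm(v))
                if dist > cation_pi_cutoff or dist == 0:
                    continue
                cosang = abs(float(v @ normal)) / dist
                ang = math.degrees(math.acos(min(1.0, cosang)))
                if ang <= cation_pi_max_angle:
                    ring_key = (rk[0], rk[1], rk[2], "ring_centroid")
                    at_a, at_b = (ring_key, nat.atom_key) if flip else (nat.atom_key, ring_key)
                    ra_, rb_ = (rk, nat.residue_key) if flip else (nat.residue_key, rk)
                    note(Contact("cation_pi", at_a, at_b, dist, ang, ra_, rb_))

    return sorted(contacts.values(), key=Contact.sort_key)


# ---------------------------------------------------------------------------
# in-silico base substitution


def mutate_base(model: StructureModel, residue: tuple, new_base: str) -> StructureModel:
    """Replace an RNA base with an idealized template of another base.

    ``residue`` is (chain_id, residue_number) or (chain_id,
    residue_number, insertion_code).  The backbone and ribose are left
    untouched; the base heavy atoms are rebuilt from the idealized
    template placed on the glycosidic anchor frame (N1/C1' for
    pyrimidines, N9/C1' for purines, plus the ring plane).  The sign of
    the template plane normal is chosen to best reproduce the original
    base orientation.
    """
    new_base = new_base.upper()
    if new_base not in ("A", "C", "G", "U"):
        raise ValueError(f"new_base must be one of A/C/G/U, got {new_base!r}")
    chain_id, resnum = residue[0], residue[1]
    ins = residue[2] if len(residue) > 2 else ""
    target = [a for a in model.atoms
              if a.chain_id == chain_id and a.residue_number == resnum
              and a.insertion_code == ins]
    if not target:
        raise SelectionError(f"residue {residue} not found in model {model.id!r}")
    old_code = _chemistry.base_code(target[0].residue_name)
    if old_code is None or target[0].residue_name.upper() not in _chemistry.RNA_RESIDUES:
        raise SelectionError(f"residue {residue} is not an RNA base")
    res_map = {a.name: a for a in target}

    # glycosidic anchor triads: purine (N9, C4, C8) <-> pyrimidine (N1, C2, C6)
    def anchors(code: str) -> tuple[str, str, str]:
        return ("N9", "C4", "C8") if code in ("A", "G") else ("N1", "C2", "C6")

    old_anchor = anchors(old_code)
    missing = [nm for nm in old_anchor if nm not in res_map]
    if "C1'" not in res_map:
        missing.append("C1'")
    if missing:
        raise SelectionError(
            f"residue {residue}: missing anchor atom(s) {missing} for base substitution"
        )
    tpl = _bases.base_template(new_base)
    new_anchor = anchors(new_base)

    src = np.array([tpl[nm] for nm in new_anchor])
    dst = np.array([res_map[nm].position for nm in old_anchor])
    sc, dc = src.mean(axis=0), dst.mean(axis=0)
    h = (src - sc).T @ (dst - dc)
    u, _, vt = np.linalg.svd(h)
    rot = vt.T @ u.T
    if np.linalg.det(rot) < 0:
        vt[-1] *= -1
        rot = vt.T @ u.T
    placed = {nm: rot @ (pos - sc) + dc
              for nm, pos in tpl.items() if nm != "C1'"}

    old_base_names = set(_bases.RING_ATOMS[old_code]) | set(
        nm for nm in res_map
        if nm in ("N1", "C2", "N3", "C4", "C5", "C6", "N7", "C8", "N9",
                  "O2", "O4", "O6", "N2", "N4", "N6", "C7")
    )

    kept = [a for a in model.atoms if not (
        a.chain_id == chain_id and a.residue_number == resnum
        and a.insertion_code == ins and a.name in old_base_names)]
    tmpl_atom = target[0]
    new_atoms = []
    for nm, pos in placed.items():
        new_atoms.append(Atom(
            serial=0, name=nm, element=nm[0], residue_name=new_base,
            chain_id=chain_id, residue_number=resnum, insertion_code=ins,
            position=pos, occupancy=tmpl_atom.occupancy, is_hetero=False))

    # rebuild the atom list: rebuilt base atoms follow the residue's
    # remaining (sugar/phosphate) atoms
    res_key = (chain_id, resnum, ins)
    final: list[Atom] = []
    serial = 0
    inserted = False
    for i, a in enumerate(kept):
        if a.residue_key == res_key:
            a = replace(a, residue_name=new_base)
        serial += 1
        final.append(replace(a, serial=serial))
        if not inserted and a.residue_key == res_key:
            is_last_of_res = (i + 1 == len(kept)) or kept[i + 1].residue_key != res_key
            if is_last_of_res:
                for na in sorted(new_atoms, key=lambda x: x.name):
                    serial += 1
                    final.append(replace(na, serial=serial))
                inserted = True
    if not inserted:  # residue consisted of base atoms only
        for na in sorted(new_atoms, key=lambda x: x.name):
            serial += 1
            final.append(replace(na, serial=serial))
    return StructureModel(model.id, final)


def count_pocket_hbonds(model: StructureModel, residue: tuple, pocket) -> int:
    """Number of hydrogen bonds between one residue and a pocket selection."""
    chain_id, resnum = residue[0], residue[1]
    ins = residue[2] if len(residue) > 2 else ""
    from .structure_io import SelectionExpr
    res_sel = SelectionExpr(chain_id=chain_id, residue_ranges=((resnum, resnum),))
    contacts = detect_polar_contacts(model, res_sel, pocket)
    return sum(1 for c in contacts if c.kind == "hbond")
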