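"""Base-pair detection and classification, hybrid metrics, kink angles.

Base pairs are detected geometrically: two nucleotides pair when their
C1'-C1' distance falls in a canonical window, their base planes are
roughly coplanar, and at least one inter-base hydrogen bond links their
edges.  Detected pairs are classified against a small catalog of
Saenger hydrogen-bonding patterns: the canonical Watson-Crick classes
(XIX for G:C, XX for A:U), the G:U wobble (XXVIII), and the two A:G
families the putRNA uses (VIII and the sheared XI).  A residue may pair
twice — the second partner is flagged as a triplex extra, which is how
the minor-groove RNA triple in the put stem is represented.

The RNA-DNA hybrid of an elongation complex is measured as the
contiguous run of RNA:template-DNA Watson-Crick pairs ending at the RNA
3' terminus; the translocation register is called from the occupancy of
the substrate (i+1) template position.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from . import _chemistry
from .structure_io import Atom, SelectionError, StructureModel

__all__ = [
    "BasePair",
    "HybridReport",
    "HelixSegment",
    "detect_base_pairs",
    "assign_saenger_class",
    "hybrid_length",
    "kink_angle",
]

C1_C1_WINDOW = (7.5, 11.5)  # Angstrom
MAX_PLANE_ANGLE = 35.0  # degrees
MAX_VERTICAL_SHEAR = 2.0  # Angstrom, stagger of base centroids along the normal
HBOND_CUTOFF = 3.5  # heavy-atom donor-acceptor
MAX_PARTNERS = 2  # triplex allowance


@dataclass(frozen=True)
class BasePair:
    residue_i: tuple
    residue_j: tuple
    base_i: str
    base_j: str
    n_hbonds: int
    c1_c1_distance: float
    coplanarity_angle: float
    hbond_atoms: tuple[tuple[str, str], ...]
    is_watson_crick: bool
    saenger_class: str = "unassigned"
    is_triplex_extra: bool = False

    def key(self) -> tuple:
        return tuple(sorted((self.residue_i, self.residue_j)))


@dataclass(frozen=True)
class HybridReport:
    n_template_bases: int
    n_rna_bases: int
    register: str  # pre_translocated | post_translocated | ambiguous
    pairs: tuple[tuple[tuple, tuple], ...]  # (template residue, RNA residue)


@dataclass(frozen=True)
class HelixSegment:
    residues: tuple
    axis_point: np.ndarray
    axis_direction: np.ndarray
    fit_rmsd: float


# --- Saenger catalog --------------------------------------------------------
# each entry: (base of first strand, base of second) -> required hydrogen
# bond atom pairs.  A pair classifies into the class whose full pattern
# its observed hydrogen bonds contain (for the 3-bond XIX, two of three
# suffice provided the central N1-N3 bond is present).

SAENGER_CATALOG: dict[str, tuple[tuple[str, str], tuple[tuple[str, str], ...]]] = {
    # canonical Watson-Crick
    "XIX": (("G", "C"), (("N1", "N3"), ("O6", "N4"), ("N2", "O2"))),
    "XX": (("A", "U"), (("N1", "N3"), ("N6", "O4"))),
    # G:U wobble
    "XXVIII": (("G", "U"), (("O6", "N3"), ("N1", "O2"))),
    # A:G imino
    "VIII": (("A", "G"), (("N6", "O6"), ("N1", "N1"))),
    # G:A sheared
    "XI": (("A", "G"), (("N6", "N3"), ("N7", "N2"))),
}

WC_COMPLEMENT = {("A", "U"), ("U", "A"), ("A", "T"), ("T", "A"),
                 ("G", "C"), ("C", "G")}


def _nucleic_residues(model: StructureModel, chains=None) -> list[dict]:
    """Per-residue records: key, base code, atom map, C1', plane normal."""
    wanted = None
    if chains is not None:
        wanted = {chains} if isinstance(chains, str) else set(chains)
    records = []
    for chain_id, residues in model.chains.items():
        if wanted is not None and chain_id not in wanted:
            continue
        for res in residues:
            code = _chemistry.base_code(res[0].residue_name)
            if code is None:
                continue
            amap = {a.name: a for a in res}
            if "C1'" not in amap:
                continue
            ring = _chemistry.ring_definitions(res[0].residue_name)[0]
            pts = [amap[nm].position for nm in ring if nm in amap]
            if len(pts) < 3:
                continue
            pts = np.array(pts)
            ctr = pts.mean(axis=0)
            _, _, vt = np.linalg.svd(pts - ctr)
            records.append({
                "key": res[0].residue_key,
                "code": code,
                "atoms": amap,
                "c1": amap["C1'"].position,
                "centroid": ctr,
                "normal": vt[2] / np.linalg.norm(vt[2]),
                "occupancy": float(np.mean([a.occupancy for a in res])),
            })
    if not records:
        raise SelectionError("no nucleic-acid residues with base atoms in selection")
    return records


def _interbase_hbonds(ri: dict, rj: dict, cutoff: float) -> list[tuple[str, str, float]]:
    """Heavy-atom hydrogen bonds between two base edges (donor_i/acc_j or vice versa)."""
    out = []
    di = _chemistry.BASE_DONORS.get(ri["code"], set())
    ai = _chemistry.BASE_ACCEPTORS.get(ri["code"], {})
    dj = _chemistry.BASE_DONORS.get(rj["code"], set())
    aj = _chemistry.BASE_ACCEPTORS.get(rj["code"], {})
    for dn in di:
        if dn not in ri["atoms"]:
            continue
        for an in aj:
            if an not in rj["atoms"]:
                continue
            d = float(np.linalg.norm(ri["atoms"][dn].position - rj["atoms"][an].position))
            if d <= cutoff:
                out.append((dn, an, d))
    for dn in dj:
        if dn not in rj["atoms"]:
            continue
        for an in ai:
            if an not in ri["atoms"]:
                continue
            d = float(np.linalg.norm(rj["atoms"][dn].position - ri["atoms"][an].position))
            if d <= cutoff:
                out.append((an, dn, d))  # always (atom of i, atom of j)
    # deduplicate same atom pair found in both directions (e.g. N1-N1)
    best: dict[tuple[str, str], float] = {}
    for x, y, d in out:
        if (x, y) not in best or d < best[(x, y)]:
            best[(x, y)] = d
    return [(x, y, d) for (x, y), d in sorted(best.items())]


def _plane_angle(n1: np.ndarray, n2: np.ndarray) -> float:
    c = abs(float(n1 @ n2))
    return math.degrees(math.acos(min(1.0, c)))


def _match_saenger(code_i: str, code_j: str,
                   hbonds: tuple[tuple[str, str], ...]) -> str:
    """Match observed hydrogen-bond atom pairs against the catalog."""
    norm = lambda c: "U" if c == "T" else c
    ci, cj = norm(code_i), norm(code_j)
    observed_fwd = set(hbonds)
    observed_rev = {(y, x) for x, y in hbonds}
    matches = []
    for cls, ((b1, b2), pattern) in SAENGER_CATALOG.items():
        pat = set(pattern)
        for (ca, cb, obs) in ((ci, cj, observed_fwd), (cj, ci, observed_rev)):
            if (ca, cb) != (b1, b2):
                continue
            if cls == "XIX":
                ok = ("N1", "N3") in obs and len(obs & pat) >= 2
            else:
                ok = pat <= obs
            if ok:
                matches.append(cls)
    matches = sorted(set(matches))
    if len(matches) == 1:
        return matches[0]
    if len(matches) > 1:
        return "unassigned"  # ambiguous pattern
    return "other"


def assign_saenger_class(pair: BasePair, model: StructureModel | None = None) -> str:
    """Saenger class of a detected pair from its hydrogen-bond pattern.

    Covers XIX/XX (canonical), XXVIII (wobble), VIII and XI (A:G
    families); anything else is ``other``; patterns matching several
    classes are ``unassigned``.
    """
    return _match_saenger(pair.base_i, pair.base_j, pair.hbond_atoms)


def detect_base_pairs(model: StructureModel, chains=None,
                      c1_window: tuple[float, float] = C1_C1_WINDOW,
                      max_plane_angle: float = MAX_PLANE_ANGLE,
                      hbond_cutoff: float = HBOND_CUTOFF,
                      max_vertical_shear: float = MAX_VERTICAL_SHEAR) -> list[BasePair]:
    """Detect base pairs among the nucleic residues of selected chains.

    Candidates must be coplanar in the strong sense: small angle between
    base planes AND small stagger of the base centroids along the mean
    normal (which rejects stacked neighbours).  Greedy selection by
    descending hydrogen-bond count then ascending C1'-C1' distance; each
    residue may appear in at most two pairs, the second flagged
    ``is_triplex_extra``.
    """
    residues = _nucleic_residues(model, chains)
    candidates = []
    for i in range(len(residues)):
        for j in range(i + 1, len(residues)):
            ri, rj = residues[i], residues[j]
            d = float(np.linalg.norm(ri["c1"] - rj["c1"]))
            if not (c1_window[0] <= d <= c1_window[1]):
                continue
            ang = _plane_angle(ri["normal"], rj["normal"])
            if ang > max_plane_angle:
                continue
            n_mean = ri["normal"] + (rj["normal"] if float(ri["normal"] @ rj["normal"]) >= 0
                                     else -rj["normal"])
            n_mean = n_mean / np.linalg.norm(n_mean)
            shear = abs(float((rj["centroid"] - ri["centroid"]) @ n_mean))
            if shear > max_vertical_shear:
                continue
            hbonds = _interbase_hbonds(ri, rj, hbond_cutoff)
            if not hbonds:
                continue
            candidates.append((ri, rj, d, ang, hbonds))

    candidates.sort(key=lambda c: (-len(c[4]), c[2], c[0]["key"], c[1]["key"]))
    partner_count: dict[tuple, int] = {}
    pairs: list[BasePair] = []
    for ri, rj, d, ang, hbonds in candidates:
        ki, kj = ri["key"], rj["key"]
        if partner_count.get(ki, 0) >= MAX_PARTNERS or partner_count.get(kj, 0) >= MAX_PARTNERS:
            continue
        extra = partner_count.get(ki, 0) > 0 or partner_count.get(kj, 0) > 0
        hb_atoms = tuple((x, y) for x, y, _ in hbonds)
        wc = ((ri["code"], rj["code"]) in WC_COMPLEMENT and len(hbonds) >= 2
              and _match_saenger(ri["code"], rj["code"], hb_atoms) in ("XIX", "XX"))
        pair = BasePair(
            residue_i=ki, residue_j=kj, base_i=ri["code"], base_j=rj["code"],
            n_hbonds=len(hbonds), c1_c1_distance=d, coplanarity_angle=ang,
            hbond_atoms=hb_atoms, is_watson_crick=wc,
            is_triplex_extra=extra,
        )
        pair = BasePair(**{**pair.__dict__, "saenger_class": assign_saenger_class(pair)})
        pairs.append(pair)
        partner_count[ki] = partner_count.get(ki, 0) + 1
        partner_count[kj] = partner_count.get(kj, 0) + 1
    pairs.sort(key=lambda p: (p.residue_i, p.residue_j))
    return pairs


# ---------------------------------------------------------------------------
# RNA-DNA hybrid


def hybrid_length(model: StructureModel, rna_chain: str, template_dna_chain: str,
                  i_plus_1_template: int | None = None) -> HybridReport:
    """Length and register of the RNA-DNA hybrid in an elongation complex.

    The hybrid is the contiguous run of inter-chain Watson-Crick pairs
    ending at the RNA 3' terminus.  The register is called from the
    substrate (i+1) template position — the template residue adjacent to
    the hybrid on the template 5' side (toward the downstream duplex):
    if it is absent the complex is pre-translocated (the RNA 3' base
    still occupies i+1); if present and unpaired, post-translocated; if
    the RNA 3' residue is modeled at partial occupancy (a mixed
    population), ambiguous.  ``i_plus_1_template`` overrides the
    inferred substrate-site residue number.
    """
    pairs = detect_base_pairs(model, chains=[rna_chain, template_dna_chain])
    inter = [p for p in pairs
             if {p.residue_i[0], p.residue_j[0]} == {rna_chain, template_dna_chain}
             and p.is_watson_crick]
    if not inter:
        raise SelectionError(
            f"no RNA:template base pairs between chains {rna_chain!r} "
            f"and {template_dna_chain!r}"
        )

    def split(p: BasePair) -> tuple[tuple, tuple]:
        if p.residue_i[0] == rna_chain:
            return p.residue_i, p.residue_j
        return p.residue_j, p.residue_i

    by_rna = {}
    for p in inter:
        rna_key, tmpl_key = split(p)
        by_rna[rna_key] = tmpl_key

    rna_residues = [r[0].residue_key for r in model.chains[rna_chain]]
    rna_3prime = rna_residues[-1]

    # walk upstream from the RNA 3' terminus while pairs stay contiguous
    run: list[tuple[tuple, tuple]] = []
    idx = len(rna_residues) - 1
    # allow an unpaired 3' residue only if nothing at all pairs (strict: run
    # must end at the terminus)
    if rna_3prime not in by_rna:
        raise SelectionError("RNA 3' terminal residue is not base-paired to the template")
    prev_tmpl = None
    while idx >= 0:
        rk = rna_residues[idx]
        if rk not in by_rna:
            break
        tk = by_rna[rk]
        if prev_tmpl is not None and abs(tk[1] - prev_tmpl[1]) != 1:
            break
        run.append((tk, rk))
        prev_tmpl = tk
        idx -= 1
    run.reverse()

    # register: the i+1 site is the template position one step past the
    # 3'-end pair, continuing the hybrid's template numbering direction
    tmpl_at_3p = run[-1][0]
    if len(run) >= 2:
        step = tmpl_at_3p[1] - run[-2][0][1]
    else:
        step = -1
    i1_num = i_plus_1_template if i_plus_1_template is not None \
        else tmpl_at_3p[1] + step
    template_nums = {r[0].residue_key[1] for r in model.chains[template_dna_chain]}

    rna_3p_occ = float(np.mean([a.occupancy for a in model.chains[rna_chain][-1]]))
    if rna_3p_occ < 0.99:
        register = "ambiguous"
    elif i_plus_1_template is not None and tmpl_at_3p[1] == i_plus_1_template:
        register = "pre_translocated"
    elif i1_num in template_nums:
        register = "post_translocated"
    else:
        register = "pre_translocated"

    return HybridReport(
        n_template_bases=len(run),
        n_rna_bases=len(run),
        register=register,
        pairs=tuple(run),
    )


# ---------------------------------------------------------------------------
# helix kink


def _segment_axis(model: StructureModel, chains, residue_ranges) -> HelixSegment:
    """Least-squares axis through C1' midpoints of consecutive pairs."""
    sel_keys = set()
    for chain_id, lo, hi in residue_ranges:
        for r in range(lo, hi + 1):
            sel_keys.add((chain_id, r))
    pairs = detect_base_pairs(model, chains=chains)
    seg_pairs = [p for p in pairs
                 if (p.residue_i[0], p.residue_i[1]) in sel_keys
                 or (p.residue_j[0], p.residue_j[1]) in sel_keys]
    if len(seg_pairs) < 3:
        raise SelectionError(
            f"helix segment needs >= 3 base pairs, found {len(seg_pairs)}"
        )
    mids = []
    res_map = {r[0].residue_key: {a.name: a for a in r} for r in model.residues()}
    seg_pairs.sort(key=lambda p: min(p.residue_i[1], p.residue_j[1]))
    for p in seg_pairs:
        c1i = res_map[p.residue_i]["C1'"].position
        c1j = res_map[p.residue_j]["C1'"].position
        mids.append(0.5 * (c1i + c1j))
    mids = np.array(mids)
    ctr = mids.mean(axis=0)
    _, s, vt = np.linalg.svd(mids - ctr)
    axis = vt[0]
    if float(axis @ (mids[-1] - mids[0])) < 0:
        axis = -axis
    proj = (mids - ctr) @ axis
    resid = mids - ctr - np.outer(proj, axis)
    rmsd = float(np.sqrt(np.mean(np.sum(resid ** 2, axis=1))))
    return HelixSegment(
        residues=tuple(p.key() for p in seg_pairs),
        axis_point=ctr, axis_direction=axis, fit_rmsd=rmsd,
    )


def kink_angle(model: StructureModel, segment1, segment2, chains=None) -> float:
    """Angle (degrees, in [0, 90]) between two helical segments' axes.

    Each segment is a list of (chain_id, start, end) residue ranges that
    must cover at least three base pairs.
    """
    seg_a = _segment_axis(model, chains, segment1)
    seg_b = _segment_axis(model, chains, segment2)
    c = abs(float(seg_a.axis_direction @ seg_b.axis_direction))
    return math.degrees(math.acos(min(1.0, c)))
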