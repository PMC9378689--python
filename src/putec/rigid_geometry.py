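"""Superposition, RMSD, and swivel-angle measurements.

The swivel angle of an elongation complex (EC) relative to a reference
EC is measured in two stages: (1) the target is superposed onto the
reference using the core module; (2) the residual rigid transform that
maps the core-aligned target's swivel module (clamp, shelf, jaw, SI3 and
the beta' C-terminal region) onto the reference's is extracted, and its
rotation angle is the swivel angle.  The rotation axis is compared with
the bridge-helix axis, since swiveling is a rotation about an axis
roughly parallel to the bridge helix.

Least-squares superposition (Kabsch) is delegated to
scipy.spatial.transform.Rotation.align_vectors, which excludes
reflections.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.transform import Rotation

from .structure_io import (
    Atom,
    SelectionExpr,
    SelectionError,
    StructureModel,
    DomainSet,
    select_atoms,
)

__all__ = [
    "RigidTransform",
    "SuperpositionResult",
    "SwivelReport",
    "GeometryError",
    "kabsch_superpose",
    "rotation_angle",
    "rotation_axis",
    "swivel_angle",
    "atom_displacement",
    "pairwise_distance",
    "fit_line_axis",
]

#: below this rotation angle (degrees) the axis is considered undefined
AXIS_UNDEFINED_TOL_DEG = 1e-6

PROTEIN_BACKBONE = frozenset({"N", "CA", "C", "O"})


class GeometryError(ValueError):
    """Raised for degenerate geometry or pairing failures."""


@dataclass(frozen=True)
class RigidTransform:
    """Proper rigid motion x -> R x + t."""

    rotation: np.ndarray
    translation: np.ndarray

    def __post_init__(self):
        rot = np.asarray(self.rotation, float)
        tr = np.asarray(self.translation, float)
        if rot.shape != (3, 3) or tr.shape != (3,):
            raise GeometryError("rotation must be 3x3 and translation a 3-vector")
        if not np.allclose(rot @ rot.T, np.eye(3), atol=1e-9):
            raise GeometryError("rotation matrix is not orthonormal")
        if not math.isclose(float(np.linalg.det(rot)), 1.0, abs_tol=1e-9):
            raise GeometryError("rotation matrix determinant is not +1 (reflection?)")
        object.__setattr__(self, "rotation", rot)
        object.__setattr__(self, "translation", tr)

    def apply(self, coords: np.ndarray) -> np.ndarray:
        return np.asarray(coords, float) @ self.rotation.T + self.translation

    def compose(self, other: "RigidTransform") -> "RigidTransform":
        """self o other (apply ``other`` first)."""
        return RigidTransform(self.rotation @ other.rotation,
                              self.rotation @ other.translation + self.translation)

    @classmethod
    def identity(cls) -> "RigidTransform":
        return cls(np.eye(3), np.zeros(3))


@dataclass(frozen=True)
class SuperpositionResult:
    transform: RigidTransform
    rmsd: float
    n_atoms: int
    atom_pairing: tuple[tuple, ...] = ()


@dataclass(frozen=True)
class SwivelReport:
    angle_deg: float
    axis: np.ndarray | None
    axis_point: np.ndarray | None
    screw_translation: float
    bridge_helix_axis_angle: float | None
    per_domain_rmsd: dict[str, float] = field(default_factory=dict)
    n_core_atoms: int = 0
    n_swivel_atoms: int = 0
    n_dropped_residues: int = 0

    def to_dict(self) -> dict:
        return {
            "angle_deg": self.angle_deg,
            "axis": None if self.axis is None else [float(x) for x in self.axis],
            "axis_point": None if self.axis_point is None
            else [float(x) for x in self.axis_point],
            "screw_translation": self.screw_translation,
            "bridge_helix_axis_angle": self.bridge_helix_axis_angle,
            "per_domain_rmsd": {k: float(v) for k, v in self.per_domain_rmsd.items()},
            "n_core_atoms": self.n_core_atoms,
            "n_swivel_atoms": self.n_swivel_atoms,
            "n_dropped_residues": self.n_dropped_residues,
        }


def _coords(atoms) -> np.ndarray:
    if isinstance(atoms, np.ndarray):
        return np.asarray(atoms, float)
    atoms = list(atoms)
    if atoms and isinstance(atoms[0], Atom):
        return np.array([a.position for a in atoms], float)
    return np.asarray(atoms, float)


def _pair_by_identity(mobile: list[Atom], reference: list[Atom],
                      strict: bool = True) -> tuple[list[Atom], list[Atom]]:
    ref_map = {a.atom_key: a for a in reference}
    mob_map = {a.atom_key: a for a in mobile}
    if strict:
        for a in mobile:
            if a.atom_key not in ref_map:
                raise GeometryError(
                    f"identity pairing failed: mobile atom {a.atom_key} "
                    f"has no counterpart in reference"
                )
        for a in reference:
            if a.atom_key not in mob_map:
                raise GeometryError(
                    f"identity pairing failed: reference atom {a.atom_key} "
                    f"has no counterpart in mobile"
                )
    shared = [k for k in mob_map if k in ref_map]
    shared.sort()
    return [mob_map[k] for k in shared], [ref_map[k] for k in shared]


def _check_not_degenerate(pts: np.ndarray, what: str) -> None:
    if len(pts) < 3:
        raise GeometryError(f"{what}: need >= 3 paired atoms, got {len(pts)}")
    centered = pts - pts.mean(axis=0)
    if np.linalg.matrix_rank(centered, tol=1e-8) < 2:
        raise GeometryError(f"{what}: points are collinear or coincident")


def kabsch_superpose(mobile, reference, pairing: str = "by_order") -> SuperpositionResult:
    """Least-squares rigid superposition of mobile onto reference.

    ``pairing`` is ``"by_order"`` (equal-length lists paired positionally)
    or ``"by_identity"`` (Atom lists matched on (chain, residue,
    insertion code, atom name); unmatched atoms are an error).
    Reflections are excluded; the returned RMSD is the minimized value.
    """
    if pairing == "by_identity":
        mobile, reference = _pair_by_identity(list(mobile), list(reference), strict=True)
    elif pairing != "by_order":
        raise GeometryError(f"unknown pairing mode {pairing!r}")
    mob = _coords(list(mobile))
    ref = _coords(list(reference))
    if len(mob) != len(ref):
        raise GeometryError(f"atom count mismatch: {len(mob)} mobile vs {len(ref)} reference")
    _check_not_degenerate(mob, "superposition (mobile)")
    _check_not_degenerate(ref, "superposition (reference)")
    mc, rc = mob.mean(axis=0), ref.mean(axis=0)
    rot, rssd = Rotation.align_vectors(ref - rc, mob - mc)
    rmat = rot.as_matrix()
    t = rc - rmat @ mc
    rmsd = float(rssd / math.sqrt(len(mob)))
    pairing_rec = ()
    mob_list, ref_list = list(mobile), list(reference)
    if mob_list and isinstance(mob_list[0], Atom) \
            and ref_list and isinstance(ref_list[0], Atom):
        pairing_rec = tuple((m.atom_key, r.atom_key) for m, r in zip(mob_list, ref_list))
    return SuperpositionResult(
        transform=RigidTransform(rmat, t),
        rmsd=rmsd,
        n_atoms=len(mob),
        atom_pairing=pairing_rec,
    )


def _validate_rotation(r: np.ndarray) -> np.ndarray:
    r = np.asarray(r, float)
    if r.shape != (3, 3) or not np.allclose(r @ r.T, np.eye(3), atol=1e-8) \
            or not math.isclose(float(np.linalg.det(r)), 1.0, abs_tol=1e-8):
        raise GeometryError("input is not a proper rotation matrix")
    return r


def rotation_angle(r: np.ndarray) -> float:
    """Rotation angle in degrees, in [0, 180]: arccos((trace - 1) / 2)."""
    r = _validate_rotation(r)
    c = (float(np.trace(r)) - 1.0) / 2.0
    return math.degrees(math.acos(min(1.0, max(-1.0, c))))


def rotation_axis(r: np.ndarray,
                  reference_direction: np.ndarray | None = None
                  ) -> tuple[np.ndarray, float]:
    """Unit rotation axis and angle (degrees) of a rotation matrix.

    The axis sign is chosen to give a positive dot product with
    ``reference_direction`` when supplied (the angle reported stays
    positive; the convention only fixes which of the two antiparallel
    axis representatives is returned).
    """
    r = _validate_rotation(r)
    rotvec = Rotation.from_matrix(r).as_rotvec()
    angle = float(np.linalg.norm(rotvec))
    if math.degrees(angle) <= AXIS_UNDEFINED_TOL_DEG:
        raise GeometryError("rotation angle ~ 0; axis undefined")
    axis = rotvec / angle
    if reference_direction is not None:
        ref = np.asarray(reference_direction, float)
        ref = ref / np.linalg.norm(ref)
        if float(axis @ ref) < 0:
            axis = -axis
    return axis, math.degrees(angle)


def fit_line_axis(coords: np.ndarray, orient_from_ends: bool = True) -> np.ndarray:
    """Unit direction of the least-squares line through a point set.

    Oriented from the first point toward the last (e.g. helix N-terminal
    to C-terminal end) when ``orient_from_ends``.
    """
    pts = _coords(coords)
    if len(pts) < 2:
        raise GeometryError("need >= 2 points to fit an axis")
    centered = pts - pts.mean(axis=0)
    _, _, vt = np.linalg.svd(centered, full_matrices=False)
    axis = vt[0]
    if orient_from_ends and float(axis @ (pts[-1] - pts[0])) < 0:
        axis = -axis
    return axis / np.linalg.norm(axis)


def _screw_decomposition(transform: RigidTransform,
                         axis: np.ndarray) -> tuple[np.ndarray, float]:
    """Point on the screw axis and the translation along it."""
    r, t = transform.rotation, transform.translation
    screw_t = float(t @ axis)
    t_perp = t - screw_t * axis
    # (I - R) p = t_perp, solved in the plane normal to the axis
    p, *_ = np.linalg.lstsq(np.eye(3) - r, t_perp, rcond=None)
    return p, screw_t


def _atom_subset_names(atom_subset: str) -> frozenset[str]:
    if atom_subset == "CA":
        return frozenset({"CA"})
    if atom_subset == "all_backbone":
        return PROTEIN_BACKBONE
    raise GeometryError(f"unknown atom subset {atom_subset!r}")


def swivel_angle(reference: StructureModel, target: StructureModel,
                 domains: DomainSet, atom_subset: str = "CA",
                 min_atoms: int = 50) -> SwivelReport:
    """Two-stage swivel measurement between two elongation complexes.

    Stage 1 aligns the target onto the reference via the core module;
    stage 2 superposes the core-aligned target's swivel module onto the
    reference's and reports the residual rotation angle/axis.  Residues
    modeled in only one structure are dropped symmetrically.  Also
    reports per-domain C-alpha RMSDs after core alignment.
    """
    names = _atom_subset_names(atom_subset)

    def domain_pairs(domain: str) -> tuple[list[Atom], list[Atom], int]:
        ref_atoms = domains.resolve(reference, domain, atom_names=names)
        tgt_atoms = domains.resolve(target, domain, atom_names=names)
        t_paired, r_paired = _pair_by_identity(tgt_atoms, ref_atoms, strict=False)
        dropped = (len({a.residue_key for a in ref_atoms} ^
                       {a.residue_key for a in tgt_atoms}))
        return t_paired, r_paired, dropped

    core_t, core_r, core_dropped = domain_pairs("core")
    if len(core_t) < min_atoms:
        raise GeometryError(
            f"only {len(core_t)} shared core {atom_subset} atoms (need >= {min_atoms})"
        )
    stage1 = kabsch_superpose(core_t, core_r, pairing="by_order")
    aligned = target.transformed(stage1.transform.rotation, stage1.transform.translation)

    members = domains.swivel_members()
    swivel_t: list[Atom] = []
    swivel_r: list[Atom] = []
    dropped = core_dropped
    for dom in members:
        ref_atoms = domains.resolve(reference, dom, atom_names=names)
        tgt_atoms = domains.resolve(aligned, dom, atom_names=names)
        t_p, r_p = _pair_by_identity(tgt_atoms, ref_atoms, strict=False)
        dropped += len({a.residue_key for a in ref_atoms} ^ {a.residue_key for a in tgt_atoms})
        swivel_t.extend(t_p)
        swivel_r.extend(r_p)
    if len(swivel_t) < min_atoms:
        raise GeometryError(
            f"only {len(swivel_t)} shared swivel-module {atom_subset} atoms "
            f"(need >= {min_atoms})"
        )
    stage2 = kabsch_superpose(swivel_t, swivel_r, pairing="by_order")
    angle = rotation_angle(stage2.transform.rotation)

    bh_axis = None
    if "bridge_helix" in domains:
        try:
            bh_atoms = domains.resolve(reference, "bridge_helix", atom_names=frozenset({"CA"}))
            bh_axis = fit_line_axis(_coords(bh_atoms))
        except SelectionError:
            bh_axis = None

    axis = axis_point = None
    screw_t = 0.0
    bh_angle = None
    if angle > AXIS_UNDEFINED_TOL_DEG:
        axis, _ = rotation_axis(stage2.transform.rotation, reference_direction=bh_axis)
        axis_point, screw_t = _screw_decomposition(stage2.transform, axis)
        if bh_axis is not None:
            cosang = abs(float(axis @ bh_axis))
            bh_angle = math.degrees(math.acos(min(1.0, cosang)))

    per_domain: dict[str, float] = {}
    for dom in ["core"] + members:
        ref_atoms = domains.resolve(reference, dom, atom_names=names)
        tgt_atoms = domains.resolve(aligned, dom, atom_names=names)
        t_p, r_p = _pair_by_identity(tgt_atoms, ref_atoms, strict=False)
        if t_p:
            diff = _coords(t_p) - _coords(r_p)
            per_domain[dom] = float(np.sqrt(np.mean(np.sum(diff ** 2, axis=1))))

    return SwivelReport(
        angle_deg=angle,
        axis=axis,
        axis_point=axis_point,
        screw_translation=screw_t,
        bridge_helix_axis_angle=bh_angle,
        per_domain_rmsd=per_domain,
        n_core_atoms=len(core_t),
        n_swivel_atoms=len(swivel_t),
        n_dropped_residues=dropped,
    )


def _single_atom(model: StructureModel, expr) -> Atom:
    atoms = select_atoms(model, expr)
    if len(atoms) != 1:
        raise SelectionError(
            f"probe selection resolves to {len(atoms)} atoms in {model.id!r}, need exactly 1"
        )
    return atoms[0]


def atom_displacement(reference: StructureModel, target: StructureModel,
                      align_on, probe) -> float:
    """Distance a probe atom moves between two structures, after alignment.

    The target is superposed onto the reference using ``align_on``
    (shared atoms, identity pairing); the Euclidean distance between the
    probe atom in the reference and the transformed target probe is
    returned (e.g. the ~15 A beta-SI2 tip displacement between swiveled
    and non-swiveled complexes).
    """
    ref_atoms = select_atoms(reference, align_on)
    tgt_atoms = select_atoms(target, align_on)
    t_p, r_p = _pair_by_identity(tgt_atoms, ref_atoms, strict=False)
    sup = kabsch_superpose(t_p, r_p, pairing="by_order")
    probe_ref = _single_atom(reference, probe)
    probe_tgt = _single_atom(target, probe)
    moved = sup.transform.apply(probe_tgt.position[None, :])[0]
    return float(np.linalg.norm(moved - probe_ref.position))


def pairwise_distance(model: StructureModel, a, b) -> float:
    """Euclidean distance between two single-atom selections."""
    atom_a = _single_atom(model, a)
    atom_b = _single_atom(model, b)
    return float(np.linalg.norm(atom_a.position - atom_b.position))
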