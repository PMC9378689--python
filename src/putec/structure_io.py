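"""Atomic-coordinate I/O, atom selection, and domain definitions.

File parsing and writing delegate to biotite (fixed-width PDB v3.3 and
mmCIF); this module owns the in-memory model, altloc resolution, the
selection language, and the named-domain configuration used by the
rigid-body comparisons.

Residue numbering follows author numbering (with insertion codes)
throughout, because that is the convention used to name functional
residues of the elongation complex (e.g. beta E1006, beta' D256).
Deposited cryo-EM models carry no hydrogens, so all downstream
hydrogen-bond logic is heavy-atom based.
"""

from __future__ import annotations

import tomllib
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import biotite.structure as bst
from biotite.structure.io import pdb as bio_pdb
from biotite.structure.io import pdbx as bio_pdbx

__all__ = [
    "Atom",
    "StructureModel",
    "SelectionExpr",
    "DomainSet",
    "StructureError",
    "SelectionError",
    "DomainConfigError",
    "read_structure",
    "write_structure",
    "select_atoms",
    "load_domain_config",
    "default_domain_config_path",
    "SWIVEL_MODULE_DOMAINS",
]

#: the five rigid-body members of the swivel module
SWIVEL_MODULE_DOMAINS = ("clamp", "shelf", "jaw", "si3", "betaprime_cterm")

WATER_NAMES = {"HOH", "WAT", "DOD", "H2O"}
METAL_ELEMENTS = {"ZN", "MG", "NA", "K", "CA", "MN", "FE", "CU", "NI", "CO", "CD"}


class StructureError(ValueError):
    """Raised for unreadable or empty coordinate files."""


class SelectionError(ValueError):
    """Raised when a selection is invalid or resolves to zero atoms."""


class DomainConfigError(ValueError):
    """Raised for invalid domain definition files."""


@dataclass(frozen=True)
class Atom:
    serial: int
    name: str
    element: str
    residue_name: str
    chain_id: str
    residue_number: int
    insertion_code: str
    position: np.ndarray
    occupancy: float = 1.0
    altloc: str = ""
    is_hetero: bool = False

    def __post_init__(self):
        pos = np.asarray(self.position, dtype=float)
        if pos.shape != (3,) or not np.all(np.isfinite(pos)):
            raise ValueError(f"atom {self.name}: position must be a finite 3-vector")
        object.__setattr__(self, "position", pos)
        if not self.element:
            raise ValueError(f"atom {self.name}: empty element symbol")
        if not 0.0 <= self.occupancy <= 1.0:
            raise ValueError(f"atom {self.name}: occupancy {self.occupancy} outside [0, 1]")

    @property
    def residue_key(self) -> tuple[str, int, str]:
        return (self.chain_id, self.residue_number, self.insertion_code)

    @property
    def atom_key(self) -> tuple[str, int, str, str]:
        return (self.chain_id, self.residue_number, self.insertion_code, self.name)


class StructureModel:
    """An atomic model: ordered chains of residues of atoms, plus metal ions.

    Atoms are stored in file order; chains and residues are views.  After
    construction each (chain, residue, atom name) key holds exactly one
    atom (altlocs resolved upstream).
    """

    def __init__(self, id: str, atoms: list[Atom]):
        if not atoms:
            raise StructureError(f"model {id!r} contains no atoms")
        self.id = id
        self.atoms = list(atoms)
        seen: set[tuple] = set()
        for a in self.atoms:
            key = a.atom_key + (a.altloc,)
            if key in seen:
                raise StructureError(f"duplicate atom {key} in model {id!r}")
            seen.add(key)
        self._coord = np.array([a.position for a in self.atoms])
        self._index = {a.atom_key: i for i, a in enumerate(self.atoms)}

    @property
    def coord(self) -> np.ndarray:
        return self._coord

    @property
    def chains(self) -> dict[str, list[list[Atom]]]:
        """Ordered chains, each an ordered list of residues (atom lists)."""
        out: dict[str, list[list[Atom]]] = {}
        last_key = None
        for a in self.atoms:
            res_list = out.setdefault(a.chain_id, [])
            if a.residue_key != last_key:
                res_list.append([])
                last_key = a.residue_key
            res_list[-1].append(a)
        return out

    @property
    def ions(self) -> list[Atom]:
        return [a for a in self.atoms
                if a.is_hetero and a.element.upper() in METAL_ELEMENTS]

    def residues(self, chain_id: str | None = None) -> list[list[Atom]]:
        ch = self.chains
        if chain_id is not None:
            if chain_id not in ch:
                raise SelectionError(f"chain {chain_id!r} absent from model {self.id!r}")
            return ch[chain_id]
        return [r for c in ch.values() for r in c]

    def get_atom(self, chain_id: str, residue_number: int, name: str,
                 insertion_code: str = "") -> Atom:
        try:
            return self.atoms[self._index[(chain_id, residue_number, insertion_code, name)]]
        except KeyError:
            raise SelectionError(
                f"atom {chain_id}/{residue_number}{insertion_code}/{name} "
                f"not found in model {self.id!r}"
            ) from None

    def transformed(self, rotation: np.ndarray, translation: np.ndarray) -> "StructureModel":
        """New model with every position mapped through x -> R x + t."""
        rot = np.asarray(rotation, float)
        tr = np.asarray(translation, float)
        atoms = [replace(a, position=rot @ a.position + tr) for a in self.atoms]
        return StructureModel(self.id, atoms)

    def __len__(self) -> int:
        return len(self.atoms)

    def __repr__(self) -> str:
        return (f"StructureModel({self.id!r}, {len(self.atoms)} atoms, "
                f"{len(self.chains)} chains, {len(self.ions)} metal ions)")


@dataclass(frozen=True)
class SelectionExpr:
    """Selection over chain / residue ranges / atom names / element.

    ``residue_ranges`` are inclusive [start, end] pairs in author
    numbering; ``None`` fields do not filter.  Also parseable from the
    string form ``"chain:start-end[:atom1,atom2]"``.
    """

    chain_id: str | None = None
    residue_ranges: tuple[tuple[int, int], ...] | None = None
    atom_names: frozenset[str] | None = None
    element: str | None = None

    def __post_init__(self):
        if self.residue_ranges is not None:
            rr = tuple(tuple(int(x) for x in r) for r in self.residue_ranges)
            if not rr:
                raise SelectionError("residue_ranges must be non-empty when given")
            for start, end in rr:
                if start > end:
                    raise SelectionError(f"invalid residue range [{start}, {end}]")
            object.__setattr__(self, "residue_ranges", rr)
        if self.atom_names is not None:
            object.__setattr__(self, "atom_names", frozenset(self.atom_names))

    @classmethod
    def parse(cls, text: str) -> "SelectionExpr":
        """Parse ``"chain:start-end[:atomnames]"`` (ranges comma-separated)."""
        parts = text.split(":")
        if not parts or not parts[0]:
            raise SelectionError(f"cannot parse selection {text!r}")
        chain = parts[0]
        ranges = None
        names = None
        if len(parts) > 1 and parts[1]:
            ranges = []
            for chunk in parts[1].split(","):
                if "-" in chunk.lstrip("-")[0:] and chunk.count("-") >= 1:
                    lo, _, hi = chunk.partition("-")
                    ranges.append((int(lo), int(hi)))
                else:
                    ranges.append((int(chunk), int(chunk)))
            ranges = tuple(ranges)
        if len(parts) > 2 and parts[2]:
            names = frozenset(parts[2].split(","))
        return cls(chain_id=chain, residue_ranges=ranges, atom_names=names)

    def matches(self, atom: Atom) -> bool:
        if self.chain_id is not None and atom.chain_id != self.chain_id:
            return False
        if self.residue_ranges is not None:
            if not any(lo <= atom.residue_number <= hi for lo, hi in self.residue_ranges):
                return False
        if self.atom_names is not None and atom.name not in self.atom_names:
            return False
        if self.element is not None and atom.element.upper() != self.element.upper():
            return False
        return True


def select_atoms(model: StructureModel,
                 expr: SelectionExpr | list[SelectionExpr] | str) -> list[Atom]:
    """Atoms matched by the expression(s), in (chain, residue, name) order.

    Overlapping ranges have set semantics (no duplicates).  Resolving to
    zero atoms is an explicit error, never a silent empty list.
    """
    if isinstance(expr, str):
        expr = SelectionExpr.parse(expr)
    exprs = expr if isinstance(expr, (list, tuple)) else [expr]
    hits = [a for a in model.atoms if any(e.matches(a) for e in exprs)]
    if not hits:
        raise SelectionError(f"selection {exprs!r} matches no atoms in model {model.id!r}")
    hits.sort(key=lambda a: (a.chain_id, a.residue_number, a.insertion_code, a.name))
    return hits


# ---------------------------------------------------------------------------
# file I/O


def _resolve_altlocs(order: list[tuple], table: dict) -> list[Atom]:
    atoms = []
    for key in order:
        variants = table[key]
        # keep highest occupancy; tie -> first altloc alphabetically
        variants.sort(key=lambda a: (-a.occupancy, a.altloc))
        atoms.append(replace(variants[0], altloc=""))
    return atoms


def _from_atom_array(label: str, arr, keep_waters: bool) -> StructureModel:
    if arr.array_length() == 0:
        raise StructureError(f"{label}: empty model")
    occ = arr.get_annotation("occupancy") if "occupancy" in arr.get_annotation_categories() \
        else np.ones(arr.array_length())
    alt = arr.get_annotation("altloc_id") if "altloc_id" in arr.get_annotation_categories() \
        else np.array([""] * arr.array_length())
    table: dict[tuple, list[Atom]] = {}
    order: list[tuple] = []
    serial = 0
    for i in range(arr.array_length()):
        res_name = str(arr.res_name[i])
        if not keep_waters and res_name in WATER_NAMES:
            continue
        serial += 1
        altloc = str(alt[i]).strip().replace(".", "")
        atom = Atom(
            serial=serial,
            name=str(arr.atom_name[i]),
            element=str(arr.element[i]) or "X",
            residue_name=res_name,
            chain_id=str(arr.chain_id[i]),
            residue_number=int(arr.res_id[i]),
            insertion_code=str(arr.ins_code[i]).strip(),
            position=np.array(arr.coord[i], dtype=float),
            occupancy=float(min(max(occ[i], 0.0), 1.0)),
            altloc=altloc,
            is_hetero=bool(arr.hetero[i]),
        )
        key = atom.atom_key
        if key not in table:
            table[key] = []
            order.append(key)
        table[key].append(atom)
    if not order:
        raise StructureError(f"{label}: empty model after filtering")
    atoms = _resolve_altlocs(order, table)
    return StructureModel(label, atoms)


def _detect_format(path: Path) -> str:
    suffix = path.suffix.lower()
    if suffix in (".pdb", ".ent"):
        return "pdb"
    if suffix in (".cif", ".mmcif", ".pdbx"):
        return "mmcif"
    head = path.read_text(errors="replace")[:4000]
    if head.lstrip().startswith("data_") or "_atom_site." in head:
        return "mmcif"
    return "pdb"


def read_structure(path: str | Path, format: str = "auto",
                   keep_waters: bool = False, id: str | None = None) -> StructureModel:
    """Read a PDB or mmCIF file into a :class:`StructureModel`.

    Altlocs are resolved to a single conformer per atom (highest
    occupancy, ties broken alphabetically).  Metal ions are retained and
    flagged; waters are discarded unless ``keep_waters``.
    """
    path = Path(path)
    if not path.exists():
        raise StructureError(f"no such file: {path}")
    fmt = _detect_format(path) if format == "auto" else format
    label = id or path.stem
    try:
        if fmt == "pdb":
            f = bio_pdb.PDBFile.read(str(path))
            arr = f.get_structure(model=1, altloc="all", extra_fields=["occupancy"])
        elif fmt == "mmcif":
            f = bio_pdbx.CIFFile.read(str(path))
            arr = bio_pdbx.get_structure(f, model=1, altloc="all", extra_fields=["occupancy"])
        else:
            raise StructureError(f"unknown format {fmt!r}")
    except StructureError:
        raise
    except Exception as exc:  # parse failure: name the offender
        raise StructureError(f"cannot parse {path} as {fmt}: {exc}") from exc
    return _from_atom_array(label, arr, keep_waters)


def write_structure(model: StructureModel, path: str | Path, format: str = "auto") -> None:
    """Write a model as fixed-width PDB or mmCIF."""
    path = Path(path)
    fmt = format
    if fmt == "auto":
        fmt = "mmcif" if path.suffix.lower() in (".cif", ".mmcif") else "pdb"
    n = len(model.atoms)
    arr = bst.AtomArray(n)
    arr.coord = np.array([a.position for a in model.atoms], dtype=np.float32)
    arr.set_annotation("chain_id", np.array([a.chain_id for a in model.atoms]))
    arr.set_annotation("res_id", np.array([a.residue_number for a in model.atoms]))
    arr.set_annotation("ins_code", np.array([a.insertion_code for a in model.atoms]))
    arr.set_annotation("res_name", np.array([a.residue_name for a in model.atoms]))
    arr.set_annotation("atom_name", np.array([a.name for a in model.atoms]))
    arr.set_annotation("element", np.array([a.element for a in model.atoms]))
    arr.set_annotation("hetero", np.array([a.is_hetero for a in model.atoms]))
    arr.set_annotation("occupancy", np.array([a.occupancy for a in model.atoms]))
    if fmt == "pdb":
        f = bio_pdb.PDBFile()
        f.set_structure(arr)
        f.write(str(path))
    elif fmt == "mmcif":
        f = bio_pdbx.CIFFile()
        bio_pdbx.set_structure(f, arr, data_block=model.id or "model")
        f.write(str(path))
    else:
        raise StructureError(f"unknown format {fmt!r}")


# ---------------------------------------------------------------------------
# domain definitions


@dataclass(frozen=True)
class DomainSet:
    """Named residue-range selections (core module, swivel module, markers).

    The five swivel-module members must be pairwise disjoint at the
    residue level; every selection must resolve to >= 3 atoms on a
    target structure (checked by :meth:`resolve`).
    """

    name: str
    domains: dict[str, list[SelectionExpr]] = field(default_factory=dict)

    def __post_init__(self):
        members = [d for d in SWIVEL_MODULE_DOMAINS if d in self.domains]
        occupied: dict[tuple[str, int], str] = {}
        for dom in members:
            for expr in self.domains[dom]:
                if expr.residue_ranges is None:
                    continue
                for lo, hi in expr.residue_ranges:
                    for r in range(lo, hi + 1):
                        key = (expr.chain_id or "*", r)
                        if key in occupied and occupied[key] != dom:
                            raise DomainConfigError(
                                f"swivel-module domains {occupied[key]!r} and {dom!r} "
                                f"overlap at chain {key[0]} residue {r}"
                            )
                        occupied[key] = dom

    def __contains__(self, name: str) -> bool:
        return name in self.domains

    def resolve(self, model: StructureModel, domain: str,
                atom_names: frozenset[str] | None = None) -> list[Atom]:
        """Atoms of a named domain on a model, optionally restricted by name."""
        if domain not in self.domains:
            raise DomainConfigError(f"domain {domain!r} not defined in set {self.name!r}")
        exprs = self.domains[domain]
        missing = [e.chain_id for e in exprs
                   if e.chain_id is not None and e.chain_id not in model.chains]
        if missing:
            raise SelectionError(
                f"domain {domain!r} names chain(s) {sorted(set(missing))} "
                f"absent from model {model.id!r}"
            )
        if atom_names is not None:
            exprs = [replace(e, atom_names=frozenset(atom_names)) for e in exprs]
        atoms = select_atoms(model, exprs)
        if len(atoms) < 3:
            raise SelectionError(
                f"domain {domain!r} resolves to only {len(atoms)} atoms "
                f"on model {model.id!r} (need >= 3)"
            )
        return atoms

    def swivel_members(self) -> list[str]:
        return [d for d in SWIVEL_MODULE_DOMAINS if d in self.domains]


MANDATORY_DOMAINS = ("core",) + SWIVEL_MODULE_DOMAINS


def load_domain_config(path: str | Path) -> DomainSet:
    """Load a TOML domain definition file.

    Expected layout::

        name = "some label"
        [domain.clamp]
        D = [[1, 342], [1318, 1344]]

    where keys under each ``[domain.<name>]`` table are chain IDs and the
    values are lists of inclusive author-numbering residue ranges.  The
    config must declare ``core`` and all five swivel-module members.
    """
    path = Path(path)
    try:
        cfg = tomllib.loads(path.read_text())
    except (OSError, tomllib.TOMLDecodeError) as exc:
        raise DomainConfigError(f"cannot read domain config {path}: {exc}") from exc
    name = cfg.get("name", path.stem)
    raw = cfg.get("domain", {})
    if not isinstance(raw, dict):
        raise DomainConfigError(f"{path}: [domain.<name>] tables missing")
    domains: dict[str, list[SelectionExpr]] = {}
    for dom, chains in raw.items():
        if not isinstance(chains, dict) or not chains:
            raise DomainConfigError(f"{path}: domain {dom!r} has no chain entries")
        exprs = []
        for chain_id, ranges in chains.items():
            try:
                rr = tuple((int(lo), int(hi)) for lo, hi in ranges)
            except (TypeError, ValueError) as exc:
                raise DomainConfigError(
                    f"{path}: domain {dom!r} chain {chain_id!r}: "
                    f"ranges must be [[start, end], ...]"
                ) from exc
            exprs.append(SelectionExpr(chain_id=chain_id, residue_ranges=rr))
        domains[dom.lower()] = exprs
    missing = [d for d in MANDATORY_DOMAINS if d not in domains]
    if missing:
        raise DomainConfigError(f"{path}: missing mandatory domain(s) {missing}")
    return DomainSet(name=name, domains=domains)


def default_domain_config_path() -> Path:
    """Path of the curated default E. coli RNAP domain definition file."""
    return Path(__file__).parent / "data" / "ecoli_rnap_domains.toml"
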