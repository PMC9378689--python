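"""End-to-end structure comparison: swivel, interfaces, base pairs, hybrid.

`run_compare` ties the geometric stages together the way the published
elongation-complex comparisons are laid out: one reference structure
(the non-paused EC), several targets, a shared domain definition, and
optional per-target interface / base-pair / hybrid analyses.  The
report is a plain serialisable mapping with a provenance block (input
hashes, parameter values, package version), so re-running on identical
inputs yields an identical report.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

from . import __version__
from .structure_io import (
    DomainSet,
    StructureModel,
    load_domain_config,
    default_domain_config_path,
    read_structure,
)
from .rigid_geometry import swivel_angle, atom_displacement, pairwise_distance
from .interface_contacts import buried_surface_area
from .na_annotate import detect_base_pairs, hybrid_length

__all__ = ["RunConfig", "ComparisonReport", "run_compare"]


@dataclass(frozen=True)
class RunConfig:
    """Configuration of one comparison run.

    ``displacements`` entries are (name, align_on, probe) selection
    strings; ``distances`` entries are (name, a, b); ``interfaces``
    entries are (name, selection_a, selection_b); ``basepair_chains``
    and ``hybrid_chains`` switch on the nucleic-acid analyses.
    """

    reference: str | Path | StructureModel
    targets: tuple = ()
    domain_config: str | Path | DomainSet | None = None
    atom_subset: str = "CA"
    displacements: tuple = ()
    distances: tuple = ()
    interfaces: tuple = ()
    basepair_chains: tuple = ()
    hybrid_chains: tuple | None = None  # (rna_chain, template_chain)
    sasa_n_points: int = 960
    probe_radius: float = 1.4
    seed: int = 0

    def parameters(self) -> dict:
        return {
            "atom_subset": self.atom_subset,
            "sasa_n_points": self.sasa_n_points,
            "probe_radius": self.probe_radius,
            "seed": self.seed,
        }


@dataclass
class ComparisonReport:
    reference_id: str
    per_target: dict[str, dict] = field(default_factory=dict)
    provenance: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "reference": self.reference_id,
            "targets": self.per_target,
            "provenance": self.provenance,
        }

    def to_json(self, path: str | Path | None = None, **kwargs) -> str:
        text = json.dumps(self.to_dict(), indent=2, sort_keys=True, **kwargs)
        if path is not None:
            Path(path).write_text(text)
        return text


def _load(obj, label=None) -> StructureModel:
    if isinstance(obj, StructureModel):
        return obj
    return read_structure(obj, id=label)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def run_compare(config: RunConfig) -> ComparisonReport:
    """Run every configured analysis of each target against the reference."""
    reference = _load(config.reference)
    if config.domain_config is None:
        domains = load_domain_config(default_domain_config_path())
    elif isinstance(config.domain_config, DomainSet):
        domains = config.domain_config
    else:
        domains = load_domain_config(config.domain_config)

    provenance: dict = {
        "package_version": __version__,
        "parameters": config.parameters(),
        "domain_set": domains.name,
        "inputs": {},
    }
    for obj in (config.reference, *config.targets):
        if not isinstance(obj, StructureModel):
            p = Path(obj)
            provenance["inputs"][p.name] = _sha256(p)

    report = ComparisonReport(reference_id=reference.id, provenance=provenance)
    for tgt in config.targets:
        target = _load(tgt)
        entry: dict = {}
        sw = swivel_angle(reference, target, domains, atom_subset=config.atom_subset)
        entry["swivel"] = sw.to_dict()
        for name, align_on, probe in config.displacements:
            entry.setdefault("displacements", {})[name] = atom_displacement(
                reference, target, align_on, probe)
        for name, sel_a, sel_b in config.distances:
            entry.setdefault("distances", {})[name] = pairwise_distance(
                target, sel_a, sel_b)
        for name, sel_a, sel_b in config.interfaces:
            iface = buried_surface_area(
                target, sel_a, sel_b,
                probe_radius=config.probe_radius, n_points=config.sasa_n_points)
            entry.setdefault("interfaces", {})[name] = iface.to_dict()
        if config.basepair_chains:
            pairs = detect_base_pairs(target, chains=list(config.basepair_chains))
            entry["base_pairs"] = {
                "n_watson_crick": sum(1 for p in pairs
                                      if p.is_watson_crick and not p.is_triplex_extra),
                "n_non_canonical": sum(1 for p in pairs
                                       if not p.is_watson_crick and not p.is_triplex_extra),
                "n_triplex_extra": sum(1 for p in pairs if p.is_triplex_extra),
            }
        if config.hybrid_chains is not None:
            rna_chain, tmpl_chain = config.hybrid_chains
            hyb = hybrid_length(target, rna_chain, tmpl_chain)
            entry["hybrid"] = {
                "n_template_bases": hyb.n_template_bases,
                "register": hyb.register,
            }
        report.per_target[target.id] = entry
    return report
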