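"""Transcription-assay quantification and alignment conservation scores.

A radiolabeled in vitro transcription assay yields, per lane, the band
intensities of the paused and the run-off transcript.  Because the
transcripts are body-labelled with alpha-32P CTP, intensities scale
with cytosine content; the paused fraction therefore uses
cytosine-calibrated (molar) intensities:

    P = (I_paused / nC_paused) / (I_paused / nC_paused + I_runoff / nC_runoff)

The relative anti-pausing activity of a put mutant places its paused
fraction on the linear scale anchored by wild type (activity 1) and the
inactive put- construct (activity 0):

    activity(x) = 1 - (P_x - P_WT) / (P_put- - P_WT)

Mutants are classed as inactivating (mean activity < 0.2), inert
(> 0.9), or other.  Conservation scores are per-reference-column
identity counts over a multiple sequence alignment of put sequences.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from Bio import AlignIO

__all__ = [
    "LaneQuant",
    "ActivityResult",
    "ConservationProfile",
    "paused_fraction",
    "relative_anti_pausing",
    "classify_mutants",
    "conservation_profile",
    "read_lane_table",
    "activities_from_lanes",
]

INACTIVATING_BELOW = 0.2
INERT_ABOVE = 0.9


@dataclass(frozen=True)
class LaneQuant:
    label: str
    paused_intensity: float
    runoff_intensity: float
    n_c_paused: int
    n_c_runoff: int
    replicate_id: int = 1
    time_min: float | None = None

    def __post_init__(self):
        for fname in ("paused_intensity", "runoff_intensity"):
            v = getattr(self, fname)
            if not math.isfinite(v) or v < 0:
                raise ValueError(f"{self.label}: {fname} must be finite and >= 0, got {v}")
        if self.n_c_paused < 1 or self.n_c_runoff < 1:
            raise ValueError(f"{self.label}: cytosine counts must be >= 1")


@dataclass(frozen=True)
class ActivityResult:
    label: str
    replicate_activities: tuple[float, ...]
    mean_activity: float
    sem: float | None
    activity_class: str  # inactivating | inert | other

    def to_dict(self) -> dict:
        return {
            "label": self.label,
            "mean_activity": self.mean_activity,
            "sem": self.sem,
            "class": self.activity_class,
            "n": len(self.replicate_activities),
        }


def paused_fraction(lane: LaneQuant) -> float:
    """Cytosine-calibrated paused fraction of one lane, in [0, 1]."""
    cal_p = lane.paused_intensity / lane.n_c_paused
    cal_r = lane.runoff_intensity / lane.n_c_runoff
    if cal_p + cal_r == 0:
        raise ValueError(f"{lane.label}: both calibrated intensities are zero")
    return cal_p / (cal_p + cal_r)


def relative_anti_pausing(p_x: float, p_wt: float, p_putminus: float) -> float:
    """1 - (P_x - P_WT) / (P_put- - P_WT); WT maps to 1 and put- to 0.

    Values slightly outside [0, 1] are legitimate (noise can push a lane
    past either anchor) and are returned unclipped.
    """
    if p_putminus == p_wt:
        raise ValueError("P_put- equals P_WT: the activity scale is undefined")
    return 1.0 - (p_x - p_wt) / (p_putminus - p_wt)


def _classify(mean: float) -> str:
    if mean < INACTIVATING_BELOW:
        return "inactivating"
    if mean > INERT_ABOVE:
        return "inert"
    return "other"


def classify_mutants(activities: dict[str, list[float]]) -> list[ActivityResult]:
    """Mean, SEM (sd / sqrt(n)), and class per label over replicates.

    A single replicate yields an undefined SEM (None) but still a class.
    """
    out = []
    for label in sorted(activities):
        vals = [float(v) for v in activities[label]]
        if not vals:
            raise ValueError(f"{label}: no replicate activities")
        mean = float(np.mean(vals))
        sem = float(np.std(vals, ddof=1) / math.sqrt(len(vals))) if len(vals) >= 2 else None
        out.append(ActivityResult(
            label=label, replicate_activities=tuple(vals),
            mean_activity=mean, sem=sem, activity_class=_classify(mean),
        ))
    return out


def read_lane_table(path: str | Path) -> list[LaneQuant]:
    """Read a lane-quantification CSV.

    Columns: label, replicate, paused_intensity, runoff_intensity,
    n_c_paused, n_c_runoff[, time_min].  Intensities are assumed
    background-corrected.
    """
    df = pd.read_csv(path)
    required = {"label", "replicate", "paused_intensity", "runoff_intensity",
                "n_c_paused", "n_c_runoff"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing column(s) {sorted(missing)}")
    lanes = []
    for _, row in df.iterrows():
        lanes.append(LaneQuant(
            label=str(row["label"]),
            paused_intensity=float(row["paused_intensity"]),
            runoff_intensity=float(row["runoff_intensity"]),
            n_c_paused=int(row["n_c_paused"]),
            n_c_runoff=int(row["n_c_runoff"]),
            replicate_id=int(row["replicate"]),
            time_min=float(row["time_min"]) if "time_min" in df.columns else None,
        ))
    return lanes


def activities_from_lanes(lanes: list[LaneQuant], wt_label: str = "WT",
                          putminus_label: str = "put-") -> list[ActivityResult]:
    """End-to-end: lanes -> paused fractions -> activities -> classes.

    The anchors P_WT and P_put- are taken per replicate, so a replicate
    is quantified against its own gel's anchor lanes.
    """
    by_replicate: dict[int, dict[str, float]] = {}
    for lane in lanes:
        by_replicate.setdefault(lane.replicate_id, {})[lane.label] = paused_fraction(lane)
    activities: dict[str, list[float]] = {}
    for rep, fractions in sorted(by_replicate.items()):
        if wt_label not in fractions or putminus_label not in fractions:
            raise ValueError(
                f"replicate {rep}: anchor lanes {wt_label!r}/{putminus_label!r} required"
            )
        p_wt = fractions[wt_label]
        p_pm = fractions[putminus_label]
        for label, p_x in fractions.items():
            activities.setdefault(label, []).append(
                relative_anti_pausing(p_x, p_wt, p_pm))
    return classify_mutants(activities)


# ---------------------------------------------------------------------------
# conservation


@dataclass(frozen=True)
class ConservationProfile:
    reference_id: str
    n_sequences: int
    scores: tuple[int, ...]  # one per ungapped reference position
    column_map: dict[int, int] = field(default_factory=dict)  # alignment col -> ref pos (1-based)

    def score_at(self, ref_position: int) -> int:
        """Score at a 1-based ungapped reference position."""
        return self.scores[ref_position - 1]


_ALIGN_FORMATS = {".fasta": "fasta", ".fa": "fasta", ".afa": "fasta",
                  ".aln": "clustal", ".clustal": "clustal",
                  ".sto": "stockholm", ".stockholm": "stockholm"}


def _read_alignment(source, fmt: str | None):
    if hasattr(source, "read"):
        return AlignIO.read(source, fmt or "fasta")
    path = Path(source)
    if fmt is None:
        fmt = _ALIGN_FORMATS.get(path.suffix.lower())
    if fmt is not None:
        return AlignIO.read(str(path), fmt)
    for candidate in ("fasta", "clustal", "stockholm"):
        try:
            return AlignIO.read(str(path), candidate)
        except Exception:
            continue
    raise ValueError(f"cannot read {path} as aligned FASTA, Clustal, or Stockholm")


def conservation_profile(alignment, reference_id: str,
                         fmt: str | None = None) -> ConservationProfile:
    """Per-reference-position identity counts over an alignment.

    ``alignment`` is a file path, file handle, or a Biopython
    MultipleSeqAlignment.  For each non-gap column of the reference
    sequence, the score is the number of sequences (reference included)
    whose character matches the reference's, case-insensitively; gaps
    never match.  T and U are treated as the same nucleotide.
    """
    if isinstance(alignment, (str, Path)) or hasattr(alignment, "read"):
        aln = _read_alignment(alignment, fmt)
    else:
        aln = alignment
    ref = None
    for rec in aln:
        if rec.id == reference_id:
            ref = rec
            break
    if ref is None:
        raise ValueError(f"reference {reference_id!r} not present in the alignment")

    def canon(ch: str) -> str:
        ch = ch.upper()
        return "U" if ch == "T" else ch

    scores: list[int] = []
    column_map: dict[int, int] = {}
    pos = 0
    for col in range(aln.get_alignment_length()):
        r = str(ref.seq[col])
        if r in "-.":
            continue
        pos += 1
        column_map[col] = pos
        rc = canon(r)
        score = sum(1 for rec in aln
                    if str(rec.seq[col]) not in "-." and canon(str(rec.seq[col])) == rc)
        scores.append(score)
    return ConservationProfile(
        reference_id=reference_id, n_sequences=len(aln),
        scores=tuple(scores), column_map=column_map,
    )
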