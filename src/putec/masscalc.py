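"""RNA transcript masses and charge-series deconvolution.

Native mass spectrometry of the transcripts extracted from a
reconstituted elongation complex validates which RNA species were
synthesised: the expected neutral mass of an n-mer is compared with the
mass recovered from its positive-mode charge-state peak series.

Masses are built from an elemental-composition table: each internal
nucleotide contributes its nucleoside-monophosphate residue (NMP minus
water), one water is added for the chain termini, and the 5' end
chemistry adds or removes phosphate groups (in-vitro transcripts
initiated with NTPs carry a 5'-triphosphate).  Average masses are the
default, appropriate for electrospray of large RNA; monoisotopic masses
are available.

Deconvolution here is a deliberately simple charge-series consistency
search (not a Bayesian deconvolution): consecutive peaks are assumed to
carry consecutive charges, and the base-peak charge minimising the
spread of implied neutral masses wins.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

__all__ = [
    "RnaSpecies",
    "PeakSeries",
    "DeconvolutionResult",
    "rna_mass",
    "residue_mass",
    "simulate_charge_series",
    "deconvolve_charge_series",
    "PROTON_MASS",
]

PROTON_MASS = 1.00728  # Da

#: atomic masses, Da
ATOMIC_MASS = {
    "average": {"H": 1.00794, "C": 12.0107, "N": 14.0067, "O": 15.9994, "P": 30.973762},
    "monoisotopic": {"H": 1.0078250319, "C": 12.0, "N": 14.0030740052,
                     "O": 15.9949146221, "P": 30.97376151},
}

#: elemental composition of the internal NMP residue (nucleoside
#: monophosphate minus one water), per base
RESIDUE_FORMULA = {
    "A": {"C": 10, "H": 12, "N": 5, "O": 6, "P": 1},
    "C": {"C": 9, "H": 12, "N": 3, "O": 7, "P": 1},
    "G": {"C": 10, "H": 12, "N": 5, "O": 7, "P": 1},
    "U": {"C": 9, "H": 11, "N": 2, "O": 8, "P": 1},
}

WATER = {"H": 2, "O": 1}
HPO3 = {"H": 1, "P": 1, "O": 3}  # one condensed phosphate unit

FIVE_PRIME_CHOICES = ("triphosphate", "monophosphate", "hydroxyl")


def _formula_mass(formula: dict[str, int], mode: str) -> float:
    table = ATOMIC_MASS[mode]
    return sum(table[el] * n for el, n in formula.items())


@dataclass(frozen=True)
class RnaSpecies:
    sequence: str
    five_prime: str = "triphosphate"
    three_prime: str = "hydroxyl"
    mass_mode: str = "average"

    def __post_init__(self):
        if not self.sequence:
            raise ValueError("sequence must be non-empty")
        seq = self.sequence.upper().replace("T", "U")
        for i, ch in enumerate(seq):
            if ch not in RESIDUE_FORMULA:
                raise ValueError(f"invalid RNA character {ch!r} at position {i + 1}")
        object.__setattr__(self, "sequence", seq)
        if self.five_prime not in FIVE_PRIME_CHOICES:
            raise ValueError(f"five_prime must be one of {FIVE_PRIME_CHOICES}")
        if self.three_prime != "hydroxyl":
            raise ValueError("only a 3'-hydroxyl terminus is supported")
        if self.mass_mode not in ATOMIC_MASS:
            raise ValueError("mass_mode must be 'average' or 'monoisotopic'")


def residue_mass(base: str, mode: str = "average") -> float:
    """Mass of one internal NMP residue (nucleotide minus water), Da."""
    return _formula_mass(RESIDUE_FORMULA[base.upper().replace("T", "U")], mode)


def rna_mass(species: RnaSpecies) -> float:
    """Neutral mass of an RNA species, Da.

    Sum of residue masses + one water + 5'-terminal adjustment
    (monophosphate is the residue default; triphosphate adds two HPO3
    units; hydroxyl removes one).
    """
    mode = species.mass_mode
    total = sum(residue_mass(b, mode) for b in species.sequence)
    total += _formula_mass(WATER, mode)
    if species.five_prime == "triphosphate":
        total += 2 * _formula_mass(HPO3, mode)
    elif species.five_prime == "hydroxyl":
        total -= _formula_mass(HPO3, mode)
    return total


# ---------------------------------------------------------------------------
# charge series


@dataclass(frozen=True)
class PeakSeries:
    peaks: tuple[tuple[float, float], ...]  # (m/z, intensity), sorted by m/z

    def __post_init__(self):
        pk = tuple((float(mz), float(it)) for mz, it in self.peaks)
        if any(mz <= 0 for mz, _ in pk):
            raise ValueError("all m/z values must be positive")
        if any(it < 0 for _, it in pk):
            raise ValueError("intensities must be >= 0")
        object.__setattr__(self, "peaks", tuple(sorted(pk)))

    @property
    def mz(self) -> np.ndarray:
        return np.array([p[0] for p in self.peaks])

    @property
    def intensity(self) -> np.ndarray:
        return np.array([p[1] for p in self.peaks])


@dataclass(frozen=True)
class DeconvolutionResult:
    neutral_mass: float
    charge_assignments: tuple[tuple[int, int], ...]  # (peak index, z)
    residual: float  # max |assigned mass - consensus|


def simulate_charge_series(mass: float, z_range: tuple[int, int],
                           proton_mass: float = PROTON_MASS) -> PeakSeries:
    """Positive-mode peak series of a neutral mass: m/z = (M + z mp) / z."""
    z_min, z_max = int(z_range[0]), int(z_range[1])
    if z_min < 1 or z_max < z_min:
        raise ValueError(f"invalid charge range [{z_min}, {z_max}]")
    if mass <= 0:
        raise ValueError("mass must be positive")
    peaks = tuple(((mass + z * proton_mass) / z, 1.0)
                  for z in range(z_min, z_max + 1))
    return PeakSeries(peaks=peaks)


def deconvolve_charge_series(peaks: PeakSeries, z_search: tuple[int, int] = (1, 50),
                             tolerance: float = 5.0,
                             proton_mass: float = PROTON_MASS) -> DeconvolutionResult:
    """Recover the neutral mass behind a charge-state peak series.

    Assumes the sorted peaks carry consecutive charges (z decreasing as
    m/z increases).  Every candidate charge of the highest-m/z peak in
    ``z_search`` is tried; the candidate minimising the spread of
    implied neutral masses wins.  The consensus mass is the
    intensity-weighted mean; an assignment whose spread exceeds
    ``tolerance`` (Da) is rejected.
    """
    mz = peaks.mz
    weights = peaks.intensity
    n = len(mz)
    if n < 2:
        raise ValueError("need at least two peaks for a charge-series deconvolution")
    if not np.any(weights > 0):
        weights = np.ones(n)
    z_min, z_max = int(z_search[0]), int(z_search[1])
    best = None
    for z_top in range(max(1, z_min), z_max + 1):
        # highest m/z peak carries the lowest charge z_top; charges increase
        # toward lower m/z
        charges = np.array([z_top + (n - 1 - i) for i in range(n)])
        masses = mz * charges - charges * proton_mass
        consensus = float(np.average(masses, weights=weights))
        residual = float(np.max(np.abs(masses - consensus)))
        if best is None or residual < best[0]:
            best = (residual, consensus, charges)
    residual, consensus, charges = best
    if residual > tolerance:
        raise ValueError(
            f"no charge assignment within tolerance {tolerance} Da "
            f"(best residual {residual:.3f} Da)"
        )
    return DeconvolutionResult(
        neutral_mass=consensus,
        charge_assignments=tuple((i, int(z)) for i, z in enumerate(charges)),
        residual=residual,
    )


def mass_from_peak(mz: float, z: int, proton_mass: float = PROTON_MASS) -> float:
    """Neutral mass from a single peak with known charge."""
    if z < 1:
        raise ValueError("charge must be >= 1")
    return mz * z - z * proton_mass
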