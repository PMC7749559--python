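"""From raw isotopomer and plasma measurements to fraction-new protein.

The observable is the mass isotopomer distribution (M0..M3) of protein-bound
alanine from a GC-MS run, plus the animal's plasma body-water deuterium
enrichment.  Three steps produce the kinetic input f:

1. natural-abundance correction: molar excess enrichment E of the alanine
   pool relative to the unlabelled baseline (MIDA);
2. true precursor enrichment p from body water, scaled by the effective
   number of exchangeable C-H positions on alanine (n ~ 3.7);
3. f = E / p, the fraction of the protein pool synthesized during labelling.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional, Union

import numpy as np

from . import mida

__all__ = [
    "IsotopomerDistribution",
    "PrecursorEnrichment",
    "FractionNew",
    "correct_natural_abundance",
    "precursor_enrichment",
    "fraction_new",
    "DEFAULT_N_SITES",
]

#: Effective number of deuterium-accessible C-H positions on alanine during
#: de novo synthesis.  Literature-standard value; configurable everywhere.
DEFAULT_N_SITES = 3.7

# Measurement-noise tolerance for the f clamping rule: values within this
# margin outside [0, 1] are clamped with a warning, beyond it the sample is
# flagged invalid.
_CLAMP_MARGIN = 0.02


@dataclass(frozen=True)
class IsotopomerDistribution:
    """Fractional abundances M0..Mk of the alanine derivative for one sample."""

    fractions: np.ndarray

    def __post_init__(self) -> None:
        arr = np.asarray(self.fractions, dtype=float)
        object.__setattr__(self, "fractions", arr)
        if arr.ndim != 1 or len(arr) < 2:
            raise ValueError("need a 1-D distribution over >= 2 mass shifts")
        if np.any(arr < 0):
            raise ValueError("isotopomer fractions must be non-negative")
        if abs(arr.sum() - 1.0) > 1e-9:
            raise ValueError(f"isotopomer fractions must sum to 1, got {arr.sum():.6g}")

    @property
    def k(self) -> int:
        """Maximum mass shift tracked."""
        return len(self.fractions) - 1


@dataclass(frozen=True)
class PrecursorEnrichment:
    """True precursor enrichment p derived from plasma body water."""

    body_water: float
    n_sites: float
    p: float
    mode: str = "linear"

    def __post_init__(self) -> None:
        if not 0.0 <= self.p <= 1.0:
            raise ValueError("precursor enrichment must be in [0, 1]")
        if (self.p == 0.0) != (self.body_water == 0.0):
            raise ValueError("p = 0 iff body water enrichment = 0")


@dataclass(frozen=True)
class FractionNew:
    f: float
    animal_id: str = ""
    fraction_id: str = ""
    valid: bool = True
    clamped: bool = False


def correct_natural_abundance(
    raw: Union[IsotopomerDistribution, np.ndarray],
    natural_dist: Optional[np.ndarray] = None,
    mode: str = "m1_excess",
) -> float:
    """Excess molar enrichment E of a measured distribution over baseline.

    ``mode='m1_excess'`` (default) converts the excess M1 abundance with the
    MIDA linear coefficient; ``mode='matrix'`` projects onto the full
    labelling-shift basis (least squares over all tracked bins).  Negative
    excess beyond tolerance is clamped to zero with a warning.
    """
    if isinstance(raw, IsotopomerDistribution):
        raw = raw.fractions
    if natural_dist is None:
        natural_dist = mida.natural_isotopomer_distribution()
    return mida.excess_from_distribution(raw, natural_dist, mode=mode)


def precursor_enrichment(
    body_water: float, n_sites: float = DEFAULT_N_SITES, mode: str = "linear"
) -> PrecursorEnrichment:
    """True precursor enrichment p from plasma body-water enrichment.

    Linear mode: p = n_sites * body_water (valid for body water <~ 0.05).
    Binomial mode (integer n_sites): p = 1 - (1 - body_water)^n, the exact
    probability that a new alanine carries at least one deuterium.
    """
    if not 0.0 <= body_water < 0.5:
        raise ValueError(f"body-water enrichment must be in [0, 0.5), got {body_water}")
    if n_sites <= 0:
        raise ValueError("n_sites must be positive")
    if mode == "linear":
        p = n_sites * body_water
    elif mode == "binomial":
        if not float(n_sites).is_integer():
            raise ValueError("binomial mode requires integer n_sites")
        p = 1.0 - (1.0 - body_water) ** int(n_sites)
    else:
        raise ValueError(f"unknown precursor mode {mode!r}")
    if p > 1.0:
        raise ValueError(f"implied precursor enrichment {p:.4g} > 1 is nonphysical")
    return PrecursorEnrichment(body_water=body_water, n_sites=n_sites, p=p, mode=mode)


def fraction_new(
    excess: float,
    precursor: Union[PrecursorEnrichment, float],
    animal_id: str = "",
    fraction_id: str = "",
) -> FractionNew:
    """Fraction-new protein f = E / p with the measurement-noise clamping rule.

    f slightly outside [0, 1] (within 0.02) is clamped to the boundary with a
    warning; further out the sample is flagged invalid (f = NaN) rather than
    silently truncated.
    """
    p = precursor.p if isinstance(precursor, PrecursorEnrichment) else float(precursor)
    if p <= 0:
        raise ValueError("no label delivered: precursor enrichment must be > 0")
    f = excess / p
    valid, clamped = True, False
    if f < 0.0 or f > 1.0:
        if -_CLAMP_MARGIN < f < 0.0:
            warnings.warn(f"f = {f:.4g} clamped to 0 ({animal_id}/{fraction_id})", stacklevel=2)
            f, clamped = 0.0, True
        elif 1.0 < f < 1.0 + _CLAMP_MARGIN:
            warnings.warn(f"f = {f:.4g} clamped to 1 ({animal_id}/{fraction_id})", stacklevel=2)
            f, clamped = 1.0, True
        else:
            warnings.warn(
                f"f = {f:.4g} outside tolerance; sample flagged invalid "
                f"({animal_id}/{fraction_id})",
                stacklevel=2,
            )
            f, valid = float("nan"), False
    return FractionNew(f=f, animal_id=animal_id, fraction_id=fraction_id, valid=valid, clamped=clamped)
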