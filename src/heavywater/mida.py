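"""Mass isotopomer distribution analysis (MIDA) primitives.

Shared by the synthetic generator (forward labelling of an isotopomer
distribution) and the enrichment module (inversion back to molar excess).
Distributions are fractional abundances over mass shifts M0..Mk (k = 3 by
default, matching a GC-MS selected-ion window for the alanine derivative).

The labelling model is linear in the molar excess enrichment E: a fraction E
of molecules carries one extra mass unit, so the observed distribution is the
natural baseline plus E times a one-unit shift operator.  The top bin of the
tracked window absorbs shifts that would leave it, so the distribution sum is
conserved exactly and the map is exactly invertible at zero noise.  An exact
binomial model at integer deuterium-site count is provided for cross-checks.
"""

from __future__ import annotations

import re
import warnings

import numpy as np

__all__ = [
    "ISOTOPE_ABUNDANCES",
    "natural_isotopomer_distribution",
    "label_shift_basis",
    "apply_excess_enrichment",
    "excess_from_distribution",
    "binomial_label_distribution",
]

# Terrestrial heavy-isotope abundances per element: list of (mass shift,
# probability) for one atom.  Fluorine is monoisotopic.
ISOTOPE_ABUNDANCES: dict[str, list[tuple[int, float]]] = {
    "C": [(0, 0.9893), (1, 0.0107)],
    "H": [(0, 0.999885), (1, 0.000115)],
    "N": [(0, 0.99636), (1, 0.00364)],
    "O": [(0, 0.99757), (1, 0.00038), (2, 0.00205)],
    "F": [(0, 1.0)],
    "S": [(0, 0.9499), (1, 0.0075), (2, 0.0425)],
}

# Pentafluorobenzyl-N,N-di(pentafluorobenzyl) alanine derivative: alanine
# C3H7NO2 with three hydrogens replaced by CH2-C6F5 groups.
DEFAULT_FORMULA = "C24H10F15NO2"

_FORMULA_RE = re.compile(r"([A-Z][a-z]?)(\d*)")


def _parse_formula(formula: str) -> dict[str, int]:
    counts: dict[str, int] = {}
    pos = 0
    for m in _FORMULA_RE.finditer(formula):
        if not m.group(0):
            continue
        if m.start() != pos:
            raise ValueError(f"cannot parse formula {formula!r}")
        pos = m.end()
        counts[m.group(1)] = counts.get(m.group(1), 0) + int(m.group(2) or 1)
    if pos != len(formula):
        raise ValueError(f"cannot parse formula {formula!r}")
    return counts


def natural_isotopomer_distribution(formula: str = DEFAULT_FORMULA, k: int = 3) -> np.ndarray:
    """Natural-abundance M0..Mk distribution for a molecular formula.

    Convolves single-atom isotope distributions; the result is truncated to
    the first ``k + 1`` mass shifts and renormalised (the discarded tail is
    far below measurement noise for small molecules).
    """
    dist = np.array([1.0])
    for element, n_atoms in _parse_formula(formula).items():
        try:
            shifts = ISOTOPE_ABUNDANCES[element]
        except KeyError:
            raise ValueError(f"no isotope data for element {element!r}") from None
        atom = np.zeros(max(s for s, _ in shifts) + 1)
        for shift, prob in shifts:
            atom[shift] = prob
        for _ in range(n_atoms):
            dist = np.convolve(dist, atom)
    out = dist[: k + 1].copy()
    if len(out) < k + 1:
        out = np.pad(out, (0, k + 1 - len(out)))
    return out / out.sum()


def label_shift_basis(natural_dist: np.ndarray) -> np.ndarray:
    """Direction in which the distribution moves per unit molar excess.

    One-mass-unit shift applied to all bins except the last, which absorbs
    the outflow so the basis sums to zero.
    """
    nat = np.asarray(natural_dist, dtype=float)
    basis = np.zeros_like(nat)
    basis[:-1] -= nat[:-1]
    basis[1:] += nat[:-1]
    return basis


def _check_distribution(dist: np.ndarray, name: str, tol: float = 1e-9) -> np.ndarray:
    dist = np.asarray(dist, dtype=float)
    if dist.ndim != 1 or len(dist) < 2:
        raise ValueError(f"{name} must be a 1-D distribution over >= 2 mass shifts")
    if np.any(dist < 0):
        raise ValueError(f"{name} has negative fractions")
    if abs(dist.sum() - 1.0) > tol:
        raise ValueError(f"{name} does not sum to 1 (sum = {dist.sum():.6g})")
    return dist


def apply_excess_enrichment(natural_dist: np.ndarray, excess: float) -> np.ndarray:
    """Forward labelling map: baseline plus ``excess`` along the shift basis."""
    nat = _check_distribution(natural_dist, "natural_dist")
    if not 0.0 <= excess <= 1.0:
        raise ValueError(f"excess enrichment must be in [0, 1], got {excess}")
    return nat + excess * label_shift_basis(nat)


def excess_from_distribution(
    observed: np.ndarray,
    natural_dist: np.ndarray,
    mode: str = "m1_excess",
    clamp_tol: float = 1e-6,
) -> float:
    """Invert the labelling map: molar excess enrichment from an observed
    distribution relative to the natural baseline.

    ``m1_excess`` uses only the M1 bin (excess M1 divided by the MIDA linear
    coefficient ``nat0 - nat1``); ``matrix`` projects the full residual onto
    the shift basis (least squares), which averages measurement noise over
    all tracked bins.  Both are exact inverses of
    :func:`apply_excess_enrichment` at zero noise.
    """
    obs = _check_distribution(observed, "observed")
    nat = _check_distribution(natural_dist, "natural_dist")
    if obs.shape != nat.shape:
        raise ValueError("observed and natural distributions differ in length")
    basis = label_shift_basis(nat)
    if mode == "m1_excess":
        coeff = basis[1]
        if coeff <= 0:
            raise ValueError("degenerate natural distribution: M1 coefficient <= 0")
        excess = (obs[1] - nat[1]) / coeff
    elif mode == "matrix":
        excess = float(basis @ (obs - nat) / (basis @ basis))
    else:
        raise ValueError(f"unknown correction mode {mode!r}")
    if excess < 0:
        if excess < -clamp_tol:
            warnings.warn(
                f"observed distribution less enriched than baseline "
                f"(excess = {excess:.3g}); clamped to 0",
                stacklevel=2,
            )
        excess = 0.0
    return float(excess)


def binomial_label_distribution(
    natural_dist: np.ndarray,
    fraction_new: float,
    n_sites: int,
    body_water: float,
) -> np.ndarray:
    """Exact labelling model at an integer deuterium-site count.

    New molecules carry deuterium at each of ``n_sites`` exchangeable
    positions independently with probability ``body_water``; the observed
    distribution is a mixture of old (baseline) and new (baseline convolved
    with the binomial label pattern) molecules, truncated to the tracked
    window with the top bin absorbing the tail.
    """
    nat = _check_distribution(natural_dist, "natural_dist")
    if not float(n_sites).is_integer() or n_sites < 1:
        raise ValueError("binomial mode requires integer n_sites >= 1")
    n_sites = int(n_sites)
    if not 0.0 <= body_water < 0.5:
        raise ValueError("body_water must be in [0, 0.5)")
    if not 0.0 <= fraction_new <= 1.0:
        raise ValueError("fraction_new must be in [0, 1]")
    from scipy.stats import binom

    label = binom.pmf(np.arange(n_sites + 1), n_sites, body_water)
    labelled = np.convolve(nat, label)
    out = labelled[: len(nat)].copy()
    out[-1] += labelled[len(nat):].sum()  # window truncation: top bin absorbs
    return (1.0 - fraction_new) * nat + fraction_new * out
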