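"""Deterministic supporting assay computations.

Relative qPCR quantification (2^-ddCt), permeabilized-fibre respirometry
normalisation (antimycin-A background subtraction per mg wet weight), fibre
cross-sectional-area frequency binning, and tumour-free muscle-mass
normalisation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

__all__ = [
    "CtPanel",
    "RespTrace",
    "CsaBins",
    "ddct",
    "normalize_ocr",
    "bin_fiber_csa",
    "normalize_mass",
    "DEFAULT_CSA_EDGES",
]


@dataclass(frozen=True)
class CtPanel:
    """qPCR Ct values: one row per animal, one column per gene, plus the
    group label of each animal and the calibrator group."""

    ct: pd.DataFrame                 # index: animal_id, columns: genes
    groups: pd.Series                # animal_id -> group label
    reference_gene: str = "18s"
    calibrator_group: str = "WT-saline"

    def __post_init__(self) -> None:
        if self.reference_gene not in self.ct.columns:
            raise ValueError(f"reference gene {self.reference_gene!r} missing from panel")
        if (self.ct.to_numpy() <= 0).any():
            raise ValueError("Ct values must be positive")
        if not self.groups.index.equals(self.ct.index):
            raise ValueError("groups must be indexed by the same animals as ct")
        if not (self.groups == self.calibrator_group).any():
            raise ValueError(f"calibrator group {self.calibrator_group!r} is empty")


def ddct(panel: CtPanel) -> pd.DataFrame:
    """Relative expression 2^-ddCt per gene per animal.

    dCt = Ct_gene - Ct_reference per animal; ddCt is dCt centred on the
    calibrator-group mean dCt, so the calibrator group's geometric-mean
    relative quantity is 1 for every gene.  Animals with a missing reference
    Ct are excluded with a warning.
    """
    ct = panel.ct
    ok = ct[panel.reference_gene].notna()
    if not ok.all():
        dropped = list(ct.index[~ok])
        warnings.warn(f"animals missing reference gene Ct excluded: {dropped}", stacklevel=2)
        ct = ct[ok]
    dct = ct.drop(columns=[panel.reference_gene]).sub(ct[panel.reference_gene], axis=0)
    calib = dct[panel.groups.loc[dct.index] == panel.calibrator_group]
    dddct = dct - calib.mean(axis=0)
    return 2.0 ** (-dddct)


@dataclass(frozen=True)
class RespTrace:
    """Raw oxygen fluxes of one permeabilized fibre bundle by titration state."""

    fluxes: dict[str, float]     # state label -> raw O2 flux
    bundle_wet_weight: float     # mg

    def __post_init__(self) -> None:
        if self.bundle_wet_weight <= 0:
            raise ValueError("bundle wet weight must be positive")
        if "antimycinA" not in self.fluxes:
            raise ValueError("antimycinA state required for background correction")


def normalize_ocr(trace: RespTrace, subtract_tmpd: bool = True) -> dict[str, float]:
    """Background-corrected oxygen consumption per mg wet weight.

    Subtracts the antimycin-A (non-mitochondrial) flux from every state and
    divides by bundle wet weight.  The complex-IV (TMPD) state is subtracted
    by default; ``subtract_tmpd=False`` leaves it uncorrected (ascorbate/TMPD
    autoxidation is not modelled).  Negative corrected fluxes are clamped to
    zero with a warning.
    """
    background = trace.fluxes["antimycinA"]
    out: dict[str, float] = {}
    for state, flux in trace.fluxes.items():
        corrected = flux - background
        if state == "TMPD" and not subtract_tmpd:
            corrected = flux
        if corrected < 0:
            warnings.warn(
                f"negative corrected flux in state {state!r} ({corrected:.4g}); clamped to 0",
                stacklevel=2,
            )
            corrected = 0.0
        out[state] = corrected / trace.bundle_wet_weight
    return out


#: (sub-threshold | small | average | large) boundaries in um^2; small is
#: closed on both ends, the middle bin is its complement up to the large cut.
DEFAULT_CSA_EDGES = (200.0, 1200.0, 2400.0)


@dataclass(frozen=True)
class CsaBins:
    counts: dict[str, int]
    frequencies: dict[str, float]       # over in-range fibres (>= lower edge)
    n_sub_threshold: int
    edges: tuple[float, float, float] = DEFAULT_CSA_EDGES


def bin_fiber_csa(areas, edges: tuple[float, float, float] = DEFAULT_CSA_EDGES) -> CsaBins:
    """Frequency distribution of fibre cross-sectional areas.

    small = [lo, mid], average = (mid, hi], large = (hi, inf); fibres below
    the lower edge are reported separately as sub-threshold.  An empty input
    yields zero counts, not an error.
    """
    areas = np.asarray(list(areas), dtype=float)
    if np.any(areas < 0):
        raise ValueError("areas must be non-negative")
    lo, mid, hi = edges
    if not lo < mid < hi:
        raise ValueError("bin edges must be strictly increasing")
    sub = int(np.sum(areas < lo))
    small = int(np.sum((areas >= lo) & (areas <= mid)))
    average = int(np.sum((areas > mid) & (areas <= hi)))
    large = int(np.sum(areas > hi))
    counts = {"small": small, "average": average, "large": large}
    total = small + average + large
    freqs = {k: (v / total if total else 0.0) for k, v in counts.items()}
    return CsaBins(counts=counts, frequencies=freqs, n_sub_threshold=sub, edges=edges)


def normalize_mass(muscle_mass: float, body_weight: float, tumour_weight: float = 0.0) -> float:
    """Muscle mass per gram of tumour-free body weight (mg/g)."""
    if muscle_mass < 0:
        raise ValueError("muscle mass must be non-negative")
    if tumour_weight < 0:
        raise ValueError("tumour weight must be non-negative")
    if body_weight <= tumour_weight:
        raise ValueError("body weight must exceed tumour weight")
    return muscle_mass / (body_weight - tumour_weight)
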