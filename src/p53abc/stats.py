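"""Descriptive analysis of single-cell intensity samples and qPCR data.

Gamma fits summarise the shape of per-cell fluorescence distributions (for
a gamma distribution CV = 1/sqrt(shape), the "fractional width"); the
comparative-CT (2^-ddCT) method converts qPCR cycle thresholds into
relative mRNA levels.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence, Tuple

import numpy as np
from scipy import stats as sps

from .model import PopulationSample

__all__ = ["GammaFit", "CtRecord", "fit_gamma", "cv_ratio",
           "exclude_outliers", "relative_mrna", "fold_change"]


@dataclass(frozen=True)
class GammaFit:
    """Gamma(shape k, scale theta) fit of an intensity sample."""

    shape: float
    scale: float
    n: int

    def __post_init__(self):
        if self.shape <= 0 or self.scale <= 0:
            raise ValueError("gamma shape and scale must be > 0")

    @property
    def cv(self) -> float:
        """Coefficient of variation, 1/sqrt(k)."""
        return 1.0 / np.sqrt(self.shape)

    @property
    def mean(self) -> float:
        """Fitted population mean k * theta."""
        return self.shape * self.scale


def fit_gamma(sample: PopulationSample) -> GammaFit:
    """Maximum-likelihood gamma fit with the location pinned at zero.

    Falls back to the method of moments if the MLE does not converge.
    """
    x = sample.protein
    if x.size < 10:
        raise ValueError("gamma fit requires at least 10 cells")
    if np.any(x <= 0):
        raise ValueError("gamma fit requires strictly positive intensities")
    try:
        k, loc, theta = sps.gamma.fit(x, floc=0)
        if not (np.isfinite(k) and np.isfinite(theta) and k > 0 and theta > 0):
            raise RuntimeError
    except Exception:
        m, v = x.mean(), x.var(ddof=1)
        k, theta = m * m / v, v / m
    return GammaFit(shape=float(k), scale=float(theta), n=x.size)


def cv_ratio(fit_reference: GammaFit, fit_regulated: GammaFit) -> float:
    """Fold-difference in fractional width, CV_regulated / CV_reference."""
    return fit_regulated.cv / fit_reference.cv


def exclude_outliers(sample: PopulationSample,
                     iqr_multiplier: float = 1.5
                     ) -> Tuple[PopulationSample, int]:
    """Drop cells above the upper Tukey fence Q3 + multiplier * IQR."""
    x = sample.protein
    if x.size < 10:
        raise ValueError("outlier filtering requires at least 10 cells")
    q1, q3 = np.percentile(x, [25, 75])
    fence = q3 + iqr_multiplier * (q3 - q1)
    keep = x <= fence
    mrna = sample.mrna[keep] if sample.mrna is not None else None
    return PopulationSample(protein=x[keep], mrna=mrna), int((~keep).sum())


@dataclass(frozen=True)
class CtRecord:
    """qPCR cycle thresholds for one cDNA sample (target vs housekeeping)."""

    sample: str
    ct_target: float
    ct_housekeeping: float

    def __post_init__(self):
        for v in (self.ct_target, self.ct_housekeeping):
            if not (np.isfinite(v) and v > 0):
                raise ValueError("C_T values must be positive and finite")

    @property
    def delta_ct(self) -> float:
        return self.ct_target - self.ct_housekeeping


def relative_mrna(records: Sequence[CtRecord],
                  reference: Optional[str] = None) -> dict:
    """Comparative-CT relative mRNA levels, 2^-(dCT - dCT_ref).

    ``reference`` names the normalising sample (defaults to the first
    record, conventionally the first reference-line replicate); its
    relative level is exactly 1.
    """
    if not records:
        raise ValueError("no C_T records supplied")
    if reference is None:
        reference = records[0].sample
    ref = [r for r in records if r.sample == reference]
    if not ref:
        raise ValueError(f"reference sample {reference!r} not found")
    d_ref = ref[0].delta_ct
    return {r.sample: float(2.0 ** -(r.delta_ct - d_ref)) for r in records}


def fold_change(mean_reference: float, mean_regulated: float) -> float:
    """Ratio of population means, regulated over reference."""
    if mean_reference <= 0:
        raise ValueError("reference mean must be > 0")
    return mean_regulated / mean_reference
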