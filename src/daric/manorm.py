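"""MA-style normalization of PIS tracks between two Hi-C samples.

Systematic differences between Hi-C experiments (restriction enzyme,
cell-cycle composition, depth) rescale the PIS. Borrowing from ChIP-seq
MA normalization, we assume most of the genome does not change
compartmentalization: per bin, M = PIS_ref − PIS_other and
A = (PIS_ref + PIS_other)/2; background bins are those whose M lies
between the 15th and 85th percentile of finite M values; a robust linear
model M ≈ slope·A + intercept fitted on the background (Huber-weighted
IRLS) is extrapolated genome-wide and subtracted, leaving only the
biological differences in the normalized M.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import statsmodels.api as sm

from .genome import PISTrack, SignalTrack

__all__ = [
    "NormalizationModel",
    "compute_ma",
    "fit_background_model",
    "apply_normalization",
    "normalize_pair",
    "normalize_panel",
]

logger = logging.getLogger(__name__)

MIN_FINITE_PAIRS = 50


@dataclass
class NormalizationModel:
    """Robust linear scaling relation fitted on background bins."""

    slope: float
    intercept: float
    background_bins: np.ndarray = field(repr=False)  # global bin indices
    reference_id: str = ""
    lo_pct: float = 15.0
    hi_pct: float = 85.0

    def to_dict(self) -> dict:
        return {
            "slope": self.slope,
            "intercept": self.intercept,
            "reference_id": self.reference_id,
            "lo_pct": self.lo_pct,
            "hi_pct": self.hi_pct,
            "n_background_bins": int(len(self.background_bins)),
        }


def compute_ma(pis_ref: PISTrack, pis_other: PISTrack) -> tuple[SignalTrack, SignalTrack]:
    """Per-bin M = ref − other and A = (ref + other)/2; NaN propagates."""
    pis_ref._require_same_genome(pis_other)
    m = SignalTrack(pis_ref.genome, pis_ref.values - pis_other.values)
    a = SignalTrack(pis_ref.genome, (pis_ref.values + pis_other.values) / 2.0)
    return m, a


def _huber_fit(a: np.ndarray, m: np.ndarray) -> tuple[float, float]:
    """Huber-weighted IRLS line fit m ≈ slope·a + intercept; deterministic."""
    if np.ptp(a) < 1e-12:  # degenerate abscissa: no scale information
        logger.warning("degenerate A values (zero variance); fitting slope 0")
        return 0.0, float(np.median(m))
    X = sm.add_constant(a)
    ols = sm.OLS(m, X).fit()
    resid = m - X @ ols.params
    mad = np.median(np.abs(resid - np.median(resid)))
    if mad < 1e-12:
        # already an exact linear relation; the robust scale would be 0
        return float(ols.params[1]), float(ols.params[0])
    rlm = sm.RLM(m, X, M=sm.robust.norms.HuberT(t=1.345))
    res = rlm.fit(maxiter=50, tol=1e-8)
    return float(res.params[1]), float(res.params[0])


def fit_background_model(
    m: SignalTrack,
    a: SignalTrack,
    lo_pct: float = 15.0,
    hi_pct: float = 85.0,
    reference_id: str = "",
) -> NormalizationModel:
    """Fit the robust background scaling model on mid-percentile bins.

    Background bins are those whose signed M value lies between the
    ``lo_pct`` and ``hi_pct`` percentiles of all finite M values, i.e.
    the bins presumed not to change compartmentalization.
    """
    m._require_same_genome(a)
    finite = np.isfinite(m.values) & np.isfinite(a.values)
    if finite.sum() < MIN_FINITE_PAIRS:
        raise ValueError(
            f"insufficient data: {int(finite.sum())} finite (M, A) pairs "
            f"(need >= {MIN_FINITE_PAIRS})"
        )
    lo, hi = np.percentile(m.values[finite], [lo_pct, hi_pct])
    bg = finite & (m.values >= lo) & (m.values <= hi)
    slope, intercept = _huber_fit(a.values[bg], m.values[bg])
    return NormalizationModel(
        slope=slope,
        intercept=intercept,
        background_bins=np.flatnonzero(bg),
        reference_id=reference_id,
        lo_pct=lo_pct,
        hi_pct=hi_pct,
    )


def apply_normalization(
    model: NormalizationModel,
    pis_ref: PISTrack,
    pis_other: PISTrack,
    sign: int = 1,
) -> PISTrack:
    """Re-express the other sample's PIS on the reference scale.

    The fitted line is subtracted from M genome-wide
    (M_norm = M − (slope·A + intercept)) and the normalized track is
    reconstructed as ``ref − M_norm`` (``sign=-1`` flips to
    ``ref + M_norm`` for callers who define M with the opposite
    orientation).
    """
    m, a = compute_ma(pis_ref, pis_other)
    m_norm = m.values - (model.slope * a.values + model.intercept)
    normalized = pis_ref.values - sign * m_norm
    out = pis_other.copy_with(normalized)
    return out


def normalize_pair(
    pis_ref: PISTrack,
    pis_other: PISTrack,
    lo_pct: float = 15.0,
    hi_pct: float = 85.0,
) -> tuple[PISTrack, NormalizationModel]:
    """Fit the background model and apply it in one step."""
    m, a = compute_ma(pis_ref, pis_other)
    model = fit_background_model(m, a, lo_pct, hi_pct, reference_id=pis_ref.sample)
    return apply_normalization(model, pis_ref, pis_other), model


def normalize_panel(
    reference: PISTrack,
    others: list[PISTrack],
    lo_pct: float = 15.0,
    hi_pct: float = 85.0,
) -> tuple[list[PISTrack], list[NormalizationModel]]:
    """Normalize each track independently against one shared reference."""
    tracks, models = [], []
    for other in others:
        t, mod = normalize_pair(reference, other, lo_pct, hi_pct)
        tracks.append(t)
        models.append(mod)
    return tracks, models
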