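"""Preferential Interaction Score (PIS) computation and smoothing.

For each genomic bin the PIS is the log2 ratio of its mean O/E contact
with A-compartment bins to its mean O/E contact with B-compartment bins
on the same chromosome:

    PIS_i = log2( mean_{j in A} OE[i, j] / mean_{j in B} OE[i, j] )

computed over valid matrix entries only. A positive score means the bin
preferentially interacts with the active compartment. Gap bins and bins
whose class means are undefined or non-positive are NaN.
"""

from __future__ import annotations

import logging
import warnings

import numpy as np
from scipy.ndimage import gaussian_filter1d

from .genome import A, B, BinnedGenome, CompartmentTrack, OEMatrix, PISTrack, SignalTrack

__all__ = ["compute_pis", "compute_pis_genome", "smooth_pis", "residual"]

logger = logging.getLogger(__name__)

#: minimum A and B bins a chromosome needs before its PIS is computed;
#: class means over fewer bins are too unstable to be meaningful.
MIN_CLASS_BINS = 10


def _class_means(oe: OEMatrix, class_mask: np.ndarray, exclude_diag: bool,
                 exclude_flank: int) -> np.ndarray:
    """Mean valid O/E of every row against the bins in ``class_mask``."""
    use = oe.valid & class_mask[np.newaxis, :]
    if exclude_diag:
        np.fill_diagonal(use, False)
    for k in range(1, exclude_flank + 1):
        n = oe.n
        idx = np.arange(n - k)
        use[idx, idx + k] = False
        use[idx + k, idx] = False
    counts = use.sum(axis=1)
    sums = np.where(use, oe.values, 0.0).sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        return np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)


def compute_pis(
    oe: OEMatrix,
    comps: CompartmentTrack,
    genome: BinnedGenome | None = None,
    *,
    min_class_bins: int = MIN_CLASS_BINS,
    exclude_diag: bool = True,
    exclude_flank: int = 0,
    sample: str = "",
) -> PISTrack:
    """Compute the PIS for one chromosome's O/E matrix.

    Returns a genome-length track whose values are filled on ``oe.chrom``
    and NaN elsewhere. A chromosome with fewer than ``min_class_bins``
    A or B bins is skipped with a warning (all-NaN track).

    ``exclude_diag`` drops each bin's own diagonal entry from its class
    means (the O/E diagonal is ~1 by construction and dilutes the
    signal); ``exclude_flank`` additionally drops the +/-k nearest
    off-diagonals.
    """
    genome = genome or comps.genome
    if not genome.same_binning(comps.genome):
        raise ValueError("compartment track on a different genome/binning")
    sl = genome.chrom_slice(oe.chrom)
    if oe.n != sl.stop - sl.start:
        raise ValueError(
            f"O/E matrix size {oe.n} != bin count of {oe.chrom} ({sl.stop - sl.start})"
        )
    values = np.full(genome.n_bins, np.nan)
    labels = comps.labels[sl]
    gap = genome.gap_mask[sl]
    a_mask = (labels == A) & ~gap
    b_mask = (labels == B) & ~gap
    if a_mask.sum() < min_class_bins or b_mask.sum() < min_class_bins:
        logger.warning(
            "chromosome %s skipped: %d A / %d B bins (< %d required)",
            oe.chrom, a_mask.sum(), b_mask.sum(), min_class_bins,
        )
        return PISTrack(genome, values, sample=sample)

    mean_a = _class_means(oe, a_mask, exclude_diag, exclude_flank)
    mean_b = _class_means(oe, b_mask, exclude_diag, exclude_flank)
    with np.errstate(invalid="ignore", divide="ignore"):
        pis = np.where((mean_a > 0) & (mean_b > 0), np.log2(mean_a / mean_b), np.nan)
    pis[gap] = np.nan
    values[sl] = pis
    return PISTrack(genome, values, sample=sample)


def compute_pis_genome(
    oes: dict[str, OEMatrix] | list[OEMatrix],
    comps: CompartmentTrack,
    genome: BinnedGenome | None = None,
    **kwargs,
) -> PISTrack:
    """Compute PIS for several chromosomes and merge into one track."""
    genome = genome or comps.genome
    if isinstance(oes, dict):
        oes = list(oes.values())
    track = PISTrack(genome, np.full(genome.n_bins, np.nan),
                     sample=kwargs.get("sample", ""))
    for oe in oes:
        part = compute_pis(oe, comps, genome, **kwargs)
        sl = genome.chrom_slice(oe.chrom)
        track.values[sl] = part.values[sl]
    return track


def smooth_pis(track: PISTrack, sigma_bins: float = 3.0) -> PISTrack:
    """NaN-aware 1-D Gaussian smoothing of a PIS track, per chromosome.

    Uses normalized convolution: the kernel is renormalized over finite
    neighbours so NaN bins contribute nothing and stay NaN; reflecting
    boundaries; smoothing never crosses a chromosome boundary.
    """
    if sigma_bins <= 0:
        raise ValueError(f"sigma_bins must be positive, got {sigma_bins}")
    if getattr(track, "smoothed", False):
        warnings.warn("smoothing an already-smoothed track", stacklevel=2)
    out = np.full_like(track.values, np.nan)
    for chrom in track.genome.chrom_names:
        sl = track.genome.chrom_slice(chrom)
        vals = track.values[sl]
        finite = np.isfinite(vals)
        if not finite.any():
            continue
        filled = np.where(finite, vals, 0.0)
        num = gaussian_filter1d(filled, sigma_bins, mode="reflect")
        den = gaussian_filter1d(finite.astype(float), sigma_bins, mode="reflect")
        with np.errstate(invalid="ignore", divide="ignore"):
            sm = num / den
        sm[~finite] = np.nan
        out[sl] = sm
    result = track.copy_with(out)
    result.smoothed = True
    return result


def residual(pis1: PISTrack, pis2: PISTrack) -> SignalTrack:
    """Residual PIS (ΔPIS) track: ``pis1 − pis2``; NaN where either is NaN."""
    pis1._require_same_genome(pis2)
    return SignalTrack(pis1.genome, pis1.values - pis2.values)
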