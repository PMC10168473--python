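"""Replicate-based empirical significance of PIS differences.

With two biological replicates per condition, the difference of the
replicate means,

    ΔPIS = (C1R1 + C1R2)/2 − (C2R1 + C2R2)/2,

is tested against an empirical null built from within-condition
replicate variation: with d1 = C1R1 − C1R2 and d2 = C2R1 − C2R2 per
bin, the vector φ collects (±d1 ± d2)/2 over all four sign
combinations at every finite bin (length 4N, mean exactly 0 by
symmetry). φ is approximated by a Gaussian N(0, σ) and each bin gets a
one-sided p-value in the direction of its observed ΔPIS, reported as a
significance score −log10(p) capped at 20. Strong+/Strong− domains
whose mean score exceeds 2 are deemed significant.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from itertools import product

import numpy as np
from scipy import stats

from .genome import PISTrack, SignalTrack
from .segmentation import DomainSegmentation

__all__ = [
    "NullDistribution",
    "SignificanceTrack",
    "delta_pis",
    "build_null",
    "significance_track",
    "filter_domains",
    "obs_exp_enrichment",
]

SCORE_CAP = 20.0  # p-values more extreme than 1e-20 are clamped


class SignificanceTrack(SignalTrack):
    """Per-bin −log10(p) significance score, in [0, 20]."""


@dataclass
class NullDistribution:
    """Empirical null of ΔPIS built from replicate pseudo-differences."""

    phi: np.ndarray = field(repr=False)
    sigma: float = 0.0
    mu: float = 0.0  # fixed at 0 by the symmetric construction

    def __post_init__(self):
        if self.sigma == 0.0 and len(self.phi):
            self.sigma = float(np.std(self.phi, ddof=1))


def _mean_tracks(tracks: list[PISTrack]) -> np.ndarray:
    return np.mean(np.vstack([t.values for t in tracks]), axis=0)


def _check_genomes(tracks):
    first = tracks[0]
    for t in tracks[1:]:
        first._require_same_genome(t)


def delta_pis(c1_reps: list[PISTrack], c2_reps: list[PISTrack]) -> SignalTrack:
    """ΔPIS: difference of per-condition replicate means; NaN propagates.

    The design assumes two replicates per condition; other counts are
    accepted with a warning using the generalized mean.
    """
    _check_genomes(c1_reps + c2_reps)
    if len(c1_reps) != 2 or len(c2_reps) != 2:
        warnings.warn(
            f"designed for 2 replicates per condition, got "
            f"{len(c1_reps)} and {len(c2_reps)}; using the mean of each set",
            stacklevel=2,
        )
    return SignalTrack(c1_reps[0].genome, _mean_tracks(c1_reps) - _mean_tracks(c2_reps))


def build_null(c1_reps: list[PISTrack], c2_reps: list[PISTrack]) -> NullDistribution:
    """Assemble φ from all sign orderings of within-condition differences.

    With 2+2 replicates each finite bin contributes the four values
    {(d1+d2)/2, (−d1+d2)/2, (d1−d2)/2, (−d1−d2)/2}; with k replicates
    per condition the within-condition contrast generalizes to the
    difference of the first-half and second-half means (warned, as this
    extends the 2-replicate design).
    """
    _check_genomes(c1_reps + c2_reps)
    contrasts = []
    for reps in (c1_reps, c2_reps):
        if len(reps) == 2:
            contrasts.append(reps[0].values - reps[1].values)
        else:
            warnings.warn(
                "null construction generalized beyond 2 replicates per condition",
                stacklevel=2,
            )
            if len(reps) < 2:
                raise ValueError("need >= 2 replicates per condition to build a null")
            half = len(reps) // 2
            contrasts.append(
                _mean_tracks(reps[:half]) - _mean_tracks(reps[half:])
            )
    d = np.vstack(contrasts)
    finite = np.all(np.isfinite(d), axis=0)
    d = d[:, finite]
    phi = np.concatenate(
        [(np.asarray(signs) @ d) / 2.0 for signs in product((1, -1), repeat=d.shape[0])]
    )
    if len(phi) == 0 or np.allclose(phi, 0.0):
        raise ValueError(
            "replicates are identical (sigma = 0): the empirical null is "
            "degenerate and significance cannot be assessed"
        )
    return NullDistribution(phi=phi)


def significance_track(delta: SignalTrack, null: NullDistribution) -> SignificanceTrack:
    """One-sided p-value of each bin's ΔPIS under the Gaussian null.

    The tested tail follows the sign of the observed ΔPIS, i.e.
    p = P(Z > |ΔPIS|/σ); the score is min(−log10 p, 20).
    """
    if null.sigma <= 0:
        raise ValueError("degenerate null (sigma <= 0)")
    with np.errstate(invalid="ignore"):
        p = stats.norm.sf(np.abs(delta.values), loc=null.mu, scale=null.sigma)
        score = np.minimum(-np.log10(np.maximum(p, 1e-300)), SCORE_CAP)
    score[~np.isfinite(delta.values)] = np.nan
    return SignificanceTrack(delta.genome, score)


def filter_domains(
    seg: DomainSegmentation,
    scores: SignificanceTrack,
    threshold: float = 2.0,
) -> DomainSegmentation:
    """Flag Strong+/Strong− domains whose mean score exceeds the threshold.

    Every domain gets its mean significance score recorded; only Strong
    domains are eligible for the significant flag (the state gate
    precedes the score gate), and Weak domains pass through unflagged.
    """
    offsets = seg.genome.chrom_offsets
    out = DomainSegmentation(seg.genome, [], seg.emissions)
    for d in seg.domains:
        vals = scores.values[offsets[d.chrom] + d.start_bin: offsets[d.chrom] + d.end_bin]
        finite = vals[np.isfinite(vals)]
        mean_score = float(finite.mean()) if len(finite) else float("nan")
        significant = d.state in ("Strong+", "Strong-") and mean_score > threshold
        out.domains.append(replace(d, mean_score=mean_score, significant=significant))
    return out


def obs_exp_enrichment(
    domain_counts: dict[str, float],
    gene_density: dict[str, float],
    total_features: float,
    cap: float = 20.0,
) -> dict[str, dict[str, float]]:
    """Observed/expected enrichment of features across domain classes.

    The expected count in class i is ``total_features × density_i``
    where density_i is the fraction of all features' parent elements
    (e.g. all genes) residing in that class. Returns per-class observed,
    expected, fold and log2 fold. A zero expectation with nonzero
    observation yields a capped log2 fold with a warning.
    """
    if any(c < 0 for c in domain_counts.values()):
        raise ValueError("counts must be non-negative")
    dens_sum = sum(gene_density.values())
    if dens_sum > 1 + 1e-9:
        raise ValueError(f"densities sum to {dens_sum:.4f} > 1")
    out: dict[str, dict[str, float]] = {}
    for cls, obs in domain_counts.items():
        exp = total_features * gene_density.get(cls, 0.0)
        if exp == 0:
            if obs > 0:
                warnings.warn(
                    f"class {cls!r}: zero expectation with {obs} observed; "
                    f"log2 fold capped at {cap}",
                    stacklevel=2,
                )
                fold, log2fold = float("inf"), cap
            else:
                fold, log2fold = float("nan"), float("nan")
        else:
            fold = obs / exp
            log2fold = float(np.log2(fold)) if fold > 0 else -cap
            log2fold = float(np.clip(log2fold, -cap, cap))
        out[cls] = {"observed": float(obs), "expected": float(exp),
                    "fold": float(fold), "log2_fold": float(log2fold)}
    return out
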