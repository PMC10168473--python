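"""Desk-scale validation experiments on synthetic data.

Each function builds its inputs with the synthetic generator, runs the
relevant pipeline stages, and returns the measured quantities. They
back both the validation test suite and ``scripts/acceptance.py``, and
are small enough to run on one CPU in seconds to a couple of minutes.
"""

from __future__ import annotations

import numpy as np

from .genome import A, B, UNDEFINED, BinnedGenome, OEMatrix, SignalTrack
from .manorm import normalize_pair, normalize_panel
from .pis import compute_pis, compute_pis_genome, smooth_pis
from .segmentation import decode, fit_hmm, label_variability_states, variability_profile
from .significance import build_null, delta_pis, filter_domains, significance_track
from .synthetic import (
    SyntheticTruth,
    default_genome,
    default_truth,
    generate_differential_pair,
    generate_plaid_oe,
    generate_replicates,
    random_truth,
    shifted_profile,
    truth_compartments,
)

__all__ = [
    "pis_oracle_check",
    "normalization_recovery",
    "planted_domain_recovery",
    "null_calibration",
    "score_semantics",
    "variability_labeling",
]


def _brute_force_pis(values, valid, labels, gap):
    """Independent nested-loop PIS: enumerate every (i, j) pair."""
    n = len(labels)
    out = np.full(n, np.nan)
    for i in range(n):
        if gap[i]:
            continue
        sums = {A: 0.0, B: 0.0}
        counts = {A: 0, B: 0}
        for j in range(n):
            if j == i or gap[j] or labels[j] == UNDEFINED or not valid[i][j]:
                continue
            sums[labels[j]] += values[i][j]
            counts[labels[j]] += 1
        if counts[A] and counts[B]:
            ma, mb = sums[A] / counts[A], sums[B] / counts[B]
            if ma > 0 and mb > 0:
                out[i] = np.log2(ma / mb)
    return out


def pis_oracle_check(n_bins: int = 200, seed: int = 7) -> dict:
    """Max deviation of the vectorized PIS from the pairwise-mean oracle."""
    rng = np.random.default_rng(seed)
    gap = rng.random(n_bins) < 0.05
    genome = BinnedGenome(("c",), (n_bins * 50_000,), 50_000, gap_mask=gap)
    e = rng.uniform(0.3, 1.0, n_bins) * rng.choice([-1, 1], n_bins)
    vals = np.exp(0.8 * np.outer(e, e)) * rng.lognormal(0, 0.3, (n_bins, n_bins))
    vals = (vals + vals.T) / 2
    valid = rng.random((n_bins, n_bins)) > 0.05
    valid &= valid.T
    valid[gap, :] = False
    valid[:, gap] = False
    labels = np.where(e > 0, A, B).astype(np.int8)
    labels[rng.random(n_bins) < 0.05] = UNDEFINED
    oe = OEMatrix("c", np.where(valid, vals, 0.0), valid)
    comps_labels = labels.copy()
    from .genome import CompartmentTrack

    comps = CompartmentTrack(genome, comps_labels)
    got = compute_pis(oe, comps, min_class_bins=1).values
    want = _brute_force_pis(oe.values, oe.valid, comps.labels, genome.gap_mask)
    both = np.isfinite(got) & np.isfinite(want)
    same_nan = np.array_equal(np.isfinite(got), np.isfinite(want))
    dev = float(np.max(np.abs(got[both] - want[both]))) if both.any() else np.inf
    return {"max_abs_dev": dev if same_nan else np.inf, "n": n_bins}


def normalization_recovery(seed: int = 7, n_bins_per_chrom: int = 1000,
                           planted_frac: float = 0.10, shift: float = 1.2) -> dict:
    """Restore a linearly distorted PIS copy; planted bins keep their effect.

    The distorted track is ``1.15 x + 0.4`` plus ``shift`` on a random
    ``planted_frac`` of bins. Reports the maximum absolute residual on
    background bins and the fraction of the planted effect retained.
    """
    genome = default_genome(2, n_bins_per_chrom, gap_fraction=0.01, seed=seed)
    truth = random_truth(genome, seed=seed, noise_sd=0.05)
    oes = generate_plaid_oe(truth, genome)
    comps = truth_compartments(genome, truth.eigen_profile)
    ref = smooth_pis(compute_pis_genome(oes, comps, genome, sample="ref"))

    rng = np.random.default_rng(seed + 1)
    n = genome.n_bins
    planted = rng.choice(n, int(planted_frac * n), replace=False)
    distorted = 1.15 * ref.values + 0.4
    distorted[planted] += shift
    other = ref.copy_with(distorted)
    other.sample = "distorted"

    normalized, _ = normalize_pair(ref, other)
    resid = normalized.values - ref.values
    background = np.setdiff1d(np.arange(n), planted)
    bg = resid[background]
    retained = resid[planted] / shift
    return {
        "background_resid_max": float(np.nanmax(np.abs(bg))),
        "effect_retention": float(np.nanmean(retained)),
        "n": n,
    }


def _strong_domain_metrics(genome, truth, seg):
    labels = seg.bin_labels()
    offsets = genome.chrom_offsets
    hits = total = 0
    boundary_errs = []
    for pd in truth.planted_domains:
        if abs(pd.shift) < 1.0:
            continue
        want = "Strong+" if pd.shift > 0 else "Strong-"
        lo = offsets[pd.chrom] + pd.start_bin
        hi = offsets[pd.chrom] + pd.end_bin
        span = labels[lo:hi]
        total += len(span)
        hits += int(np.sum(span == want))
        cen = (lo + hi) // 2
        if labels[cen] != want:
            boundary_errs.append(np.inf)
            continue
        a = cen
        while a - 1 >= offsets[pd.chrom] and labels[a - 1] == want:
            a -= 1
        b = cen
        chrom_end = offsets[pd.chrom] + genome.n_bins_chrom(pd.chrom)
        while b + 1 < chrom_end and labels[b + 1] == want:
            b += 1
        boundary_errs.append(max(abs(a - lo), abs(b + 1 - hi)))
    return hits / total, float(np.max(boundary_errs)), total


def planted_domain_recovery(seed: int = 7, n_chroms: int = 4,
                            bins_per_chrom: int = 2000,
                            noise_sd: float = 0.1) -> dict:
    """Full pipeline on the differential pair with planted ±1.5/±0.3 shifts.

    Measures the fraction of planted strong-shift bins decoded into the
    correct extreme state and the worst boundary placement error (bins).
    """
    genome = default_genome(n_chroms, bins_per_chrom, seed=seed)
    truth = default_truth(genome, seed=seed, noise_sd=noise_sd)
    oes1, oes2, _ = generate_differential_pair(truth, genome)
    c1 = truth_compartments(genome, truth.eigen_profile)
    c2 = truth_compartments(genome, shifted_profile(truth, genome))
    p1 = smooth_pis(compute_pis_genome(oes1, c1, genome, sample="c1"))
    p2 = smooth_pis(compute_pis_genome(oes2, c2, genome, sample="c2"))
    p2n, _ = normalize_pair(p1, p2)
    delta = SignalTrack(genome, p2n.values - p1.values)
    model = fit_hmm(delta, n_states=4, seed=13)
    seg = decode(model, delta)
    accuracy, boundary_max, n_strong = _strong_domain_metrics(genome, truth, seg)
    return {
        "strong_bin_accuracy": accuracy,
        "boundary_err_max_bins": boundary_max,
        "n": n_strong,
    }


def null_calibration(seed: int = 7, n_chroms: int = 4,
                     bins_per_chrom: int = 2000, noise_sd: float = 0.1) -> dict:
    """Two conditions rendered from identical truth with replicate noise.

    Reports the fraction of bins scored > 2 (one-sided p < 0.01 in the
    observed direction, so ~2% expected), the absolute mean of the
    pseudo-difference vector phi, and the ratio of |phi| to 4N.
    """
    genome = default_genome(n_chroms, bins_per_chrom, seed=seed)
    truth = random_truth(genome, seed=seed, noise_sd=noise_sd)
    clean = SyntheticTruth(truth.eigen_profile, noise_sd=0.0, seed=seed)
    base = generate_plaid_oe(clean, genome)
    comps = truth_compartments(genome, truth.eigen_profile)
    ss = np.random.SeedSequence(seed)
    rep_seeds = [int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(4)]
    tracks = []
    for i, rs in enumerate(rep_seeds):
        oes = {
            c: generate_replicates(base[c], 1, noise_sd, seed=rs + j)[0]
            for j, c in enumerate(genome.chrom_names)
        }
        tracks.append(
            smooth_pis(compute_pis_genome(oes, comps, genome, sample=f"rep{i}")))
    normalized, _ = normalize_panel(tracks[0], tracks[1:])
    panel = [tracks[0]] + normalized
    c1_reps, c2_reps = panel[:2], panel[2:]
    delta = delta_pis(c1_reps, c2_reps)
    null = build_null(c1_reps, c2_reps)
    scores = significance_track(delta, null)
    finite = np.isfinite(scores.values)
    n_finite = int(np.sum(np.all(np.isfinite(
        np.vstack([t.values for t in panel])), axis=0)))
    return {
        "false_positive_rate": float(np.mean(scores.values[finite] > 2)),
        "phi_mean_abs": float(abs(np.mean(null.phi))),
        "phi_len_over_4n": len(null.phi) / (4 * n_finite),
        "n": int(finite.sum()),
    }


def score_semantics(seed: int = 7) -> dict:
    """Cap and threshold behavior measured through the scoring stage.

    A track with extreme, moderate and null differences is scored
    against a unit null and filtered with the domain-state gate.
    """
    from .segmentation import Domain, DomainSegmentation
    from .significance import NullDistribution

    genome = BinnedGenome(("c",), (12 * 50_000,), 50_000)
    null = NullDistribution(phi=np.array([]), sigma=0.05)
    delta = np.array([5.0, 5.0, 5.0,      # p << 1e-20 -> score capped at 20
                      0.05, 0.05, 0.05,   # strong state, score below 2
                      0.25, 0.25, 0.25,   # weak state despite a high score
                      0.0, 0.0, 0.0])
    scores = significance_track(SignalTrack(genome, delta), null)
    seg = DomainSegmentation(genome, [
        Domain("c", 0, 3, "Strong+", mean_residual=5.0),
        Domain("c", 3, 6, "Strong+", mean_residual=0.05),
        Domain("c", 6, 9, "Weak+", mean_residual=0.25),
        Domain("c", 9, 12, "Weak-", mean_residual=0.0),
    ])
    filtered = filter_domains(seg, scores, threshold=2.0)
    flags = [d.significant for d in filtered.domains]
    return {
        "score_max": float(np.nanmax(scores.values)),
        "n_significant": int(sum(flags)),
        "weak_or_subthreshold_flagged": int(sum(flags[1:])),
        "n": len(delta),
    }


def variability_labeling(seed: int = 11, n_samples: int = 19,
                         n_chroms: int = 2, bins_per_chrom: int = 600) -> dict:
    """Recover the five planted variability classes across a sample panel."""
    from .synthetic import generate_variability_panel

    genome = default_genome(n_chroms, bins_per_chrom, seed=seed)
    panels, profiles, labels = generate_variability_panel(
        genome, n_samples=n_samples, seed=seed)
    tracks = []
    for i, (oes, prof) in enumerate(zip(panels, profiles)):
        comps = truth_compartments(genome, prof)
        tracks.append(
            smooth_pis(compute_pis_genome(oes, comps, genome, sample=f"s{i}")))
    normalized, _ = normalize_panel(tracks[0], tracks[1:])
    panel = [tracks[0]] + normalized
    profile = variability_profile(panel, min_samples=3)
    model = fit_hmm(profile, n_states=5, seed=13)
    seg = label_variability_states(decode(model, profile))
    pred = seg.bin_labels()
    mask = np.array([p is not None and t is not None
                     for p, t in zip(pred, labels)])
    accuracy = float(np.mean(pred[mask] == labels[mask]))
    return {"label_accuracy": accuracy, "n": int(mask.sum())}
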