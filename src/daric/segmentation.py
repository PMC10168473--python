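"""HMM segmentation of residual-PIS tracks into differential domains.

Differential mode: a Gaussian HMM with (by default) four states is
fitted to one or more residual PIS tracks and decoded by Viterbi; the
states, ordered by emission mean, are Strong− / Weak− / Weak+ / Strong+,
mirroring the four classes of the conventional A/B compartment switching
analysis (BB, BA, AB, AA). Supplying several residual tracks trains one
unified model so domain calls from different comparisons share state
definitions.

Variability mode: per-bin mean and standard deviation of normalized PIS
across a panel of samples form 2-D observations for a five-state HMM;
the states are labeled conA / conB (constitutive compartment, low
variability), varA / varB (clear compartment preference, moderate
variability) and variable (frequent switching, highest variability).

NaN runs split observation sequences: no state path ever bridges a gap,
and chromosomes are separate sequences.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from hmmlearn.hmm import GaussianHMM

from .genome import BinnedGenome, SignalTrack

__all__ = [
    "HMMSpec",
    "Domain",
    "DomainSegmentation",
    "VariabilityProfile",
    "fit_hmm",
    "decode",
    "variability_profile",
    "label_variability_states",
    "FOUR_STATE_LABELS",
    "VARIABILITY_LABELS",
]

logger = logging.getLogger(__name__)

FOUR_STATE_LABELS = ("Strong-", "Weak-", "Weak+", "Strong+")
VARIABILITY_LABELS = ("conA", "conB", "varA", "varB", "variable")

#: finite observations required per state before EM is attempted
MIN_OBS_PER_STATE = 10


@dataclass
class HMMSpec:
    """A fitted Gaussian HMM (diagonal covariance)."""

    n_states: int
    means: np.ndarray  # (n_states, n_dims)
    covars: np.ndarray  # (n_states, n_dims) diagonal variances
    transmat: np.ndarray
    startprob: np.ndarray
    seed: int = 13
    max_iter: int = 100
    tol: float = 1e-4
    converged: bool = True

    def __post_init__(self):
        self.means = np.atleast_2d(np.asarray(self.means, dtype=float))
        self.covars = np.atleast_2d(np.asarray(self.covars, dtype=float))
        self.transmat = np.asarray(self.transmat, dtype=float)
        self.startprob = np.asarray(self.startprob, dtype=float)
        if not np.allclose(self.transmat.sum(axis=1), 1.0, atol=1e-9):
            raise ValueError("transition rows must sum to 1")
        if not np.isclose(self.startprob.sum(), 1.0, atol=1e-9):
            raise ValueError("start probabilities must sum to 1")
        if np.any(self.covars <= 0):
            raise ValueError("emission variances must be positive")

    @property
    def n_dims(self) -> int:
        return self.means.shape[1]

    def to_hmmlearn(self) -> GaussianHMM:
        model = GaussianHMM(
            n_components=self.n_states,
            covariance_type="diag",
            init_params="",
            params="stmc",
            random_state=self.seed,
        )
        model.n_features = self.n_dims
        model.startprob_ = self.startprob.copy()
        model.transmat_ = self.transmat.copy()
        model.means_ = self.means.copy()
        model.covars_ = self.covars.copy()
        return model

    def to_dict(self) -> dict:
        return {
            "n_states": self.n_states,
            "means": self.means.tolist(),
            "covars": self.covars.tolist(),
            "transmat": self.transmat.tolist(),
            "startprob": self.startprob.tolist(),
            "seed": self.seed,
            "converged": self.converged,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "HMMSpec":
        return cls(
            n_states=d["n_states"],
            means=np.array(d["means"]),
            covars=np.array(d["covars"]),
            transmat=np.array(d["transmat"]),
            startprob=np.array(d["startprob"]),
            seed=d.get("seed", 13),
            converged=d.get("converged", True),
        )


@dataclass
class Domain:
    """A run of consecutive same-state bins on one chromosome.

    ``start_bin``/``end_bin`` are local bin indices, half-open.
    """

    chrom: str
    start_bin: int
    end_bin: int
    state: str
    mean_residual: float = float("nan")
    mean_score: float = float("nan")
    significant: bool = False

    @property
    def n_bins(self) -> int:
        return self.end_bin - self.start_bin


@dataclass
class DomainSegmentation:
    """Ordered, non-overlapping labeled domains covering finite-signal bins."""

    genome: BinnedGenome
    domains: list[Domain] = field(default_factory=list)
    #: per-label (mean vector, variance vector) of the decoding model
    emissions: dict[str, tuple[np.ndarray, np.ndarray]] | None = None

    def __len__(self) -> int:
        return len(self.domains)

    def __iter__(self):
        return iter(self.domains)

    def bin_labels(self) -> np.ndarray:
        """Global per-bin state label (object array, None where unsegmented)."""
        out = np.full(self.genome.n_bins, None, dtype=object)
        offsets = self.genome.chrom_offsets
        for d in self.domains:
            out[offsets[d.chrom] + d.start_bin: offsets[d.chrom] + d.end_bin] = d.state
        return out

    def relabel(self, mapping: dict[str, str]) -> "DomainSegmentation":
        domains = [
            Domain(d.chrom, d.start_bin, d.end_bin, mapping.get(d.state, d.state),
                   d.mean_residual, d.mean_score, d.significant)
            for d in self.domains
        ]
        emissions = None
        if self.emissions is not None:
            emissions = {mapping.get(k, k): v for k, v in self.emissions.items()}
        return DomainSegmentation(self.genome, domains, emissions)


class VariabilityProfile:
    """Per-bin mean and standard deviation of PIS across a sample panel."""

    def __init__(self, genome: BinnedGenome, mean: np.ndarray, sd: np.ndarray,
                 n_samples: int = 0):
        mean = np.asarray(mean, dtype=float)
        sd = np.asarray(sd, dtype=float)
        if mean.shape != (genome.n_bins,) or sd.shape != (genome.n_bins,):
            raise ValueError("profile length != genome bin count")
        self.genome = genome
        self.mean = mean
        self.sd = sd
        self.n_samples = n_samples

    @property
    def obs(self) -> np.ndarray:
        """(n_bins, 2) observation matrix: columns (mean, sd)."""
        return np.column_stack([self.mean, self.sd])


# ---------------------------------------------------------------------------
# observation-sequence plumbing


def _observations(track) -> np.ndarray:
    """(n_bins, d) observation matrix of a track-like object."""
    if isinstance(track, VariabilityProfile):
        return track.obs
    if isinstance(track, SignalTrack):
        return track.values[:, np.newaxis]
    raise TypeError(f"cannot extract observations from {type(track).__name__}")


def _sequences(track):
    """Split a track into per-chromosome, NaN-free observation sequences.

    Yields ``(chrom, start_local_bin, X)`` with X of shape (len, d).
    """
    obs = _observations(track)
    genome = track.genome
    for chrom in genome.chrom_names:
        sl = genome.chrom_slice(chrom)
        x = obs[sl]
        finite = np.all(np.isfinite(x), axis=1)
        if not finite.any():
            continue
        edges = np.flatnonzero(np.diff(finite.astype(int)))
        starts = [0] if finite[0] else []
        starts += [e + 1 for e in edges if finite[e + 1]]
        ends = [e + 1 for e in edges if finite[e]]
        ends += [len(finite)] if finite[-1] else []
        for s, e in zip(starts, ends):
            yield chrom, s, x[s:e]


def _pool(tracks):
    seqs = []
    for t in tracks:
        seqs.extend(_sequences(t))
    if not seqs:
        raise ValueError("no finite observations in the supplied tracks")
    X = np.concatenate([x for _, _, x in seqs], axis=0)
    lengths = [len(x) for _, _, x in seqs]
    return seqs, X, lengths


# ---------------------------------------------------------------------------
# fitting and decoding


def fit_hmm(
    tracks,
    n_states: int = 4,
    seed: int = 13,
    max_iter: int = 100,
    tol: float = 1e-4,
    self_prior: float = 0.9,
) -> HMMSpec:
    """Fit one Gaussian HMM by EM over all sequences of all supplied tracks.

    Initialization is deterministic: state k's mean starts at the
    (k+0.5)/n_states quantile of the pooled observations (per
    dimension), except that the two extreme states are anchored at the
    0.5th/99.5th percentiles; variances start at the pooled variance
    over the state count, with a geometric narrow-to-broad ladder across
    interior states; transitions are uniform with a ``self_prior``
    self-transition and start probabilities uniform. Several
    tracks (e.g. residuals of neighboring time points) train a single
    unified model so all comparisons share state definitions.
    """
    if isinstance(tracks, (SignalTrack, VariabilityProfile)):
        tracks = [tracks]
    _, X, lengths = _pool(tracks)
    n_obs, d = X.shape
    if n_obs < n_states * MIN_OBS_PER_STATE:
        raise ValueError(
            f"insufficient data: {n_obs} finite observations for {n_states} states "
            f"(need >= {n_states * MIN_OBS_PER_STATE})"
        )

    pooled_sd = X.std(axis=0)
    if np.all(pooled_sd < 1e-10):
        warnings.warn(
            "observations have (near-)zero variance; EM is degenerate, "
            "returning a single effective state",
            stacklevel=2,
        )
        means = np.tile(X.mean(axis=0), (n_states, 1))
        covars = np.full((n_states, d), 1e-6)
        # sticky transitions so ties in the (identical) emissions never
        # fragment the Viterbi path
        off = (1.0 - self_prior) / (n_states - 1) if n_states > 1 else 0.0
        transmat = np.full((n_states, n_states), off)
        np.fill_diagonal(transmat, self_prior)
        startprob = np.full(n_states, 1.0 / n_states)
        return HMMSpec(n_states, means, covars, transmat, startprob, seed=seed,
                       max_iter=max_iter, tol=tol, converged=True)

    v = np.maximum(X.var(axis=0), 1e-6)
    if d == 1:
        # States are ordered along the single observation axis. Extreme
        # states are anchored at the extreme quantiles: differential bins
        # can be a small genome fraction, and bulk quantiles alone would
        # start every state inside the null peak (a local EM optimum).
        # Interior states start at interior quantiles with a geometric
        # variance ladder (narrow -> broad) so EM can allocate them to a
        # sharp null peak and to broad mild drifts without a symmetric
        # trap.
        qs = (np.arange(n_states) + 0.5) / n_states
        means = np.quantile(X, qs, axis=0)
        means[0] = np.quantile(X, 0.005, axis=0)
        means[-1] = np.quantile(X, 0.995, axis=0)
        covars = np.tile(v / n_states, (n_states, 1))
        if n_states > 2:
            scales = np.geomspace(1.0 / (4 * n_states), 1.0, n_states - 2)
            for j, s in enumerate(scales, start=1):
                covars[j] = np.maximum(v * s, 1e-6)
    else:
        # no natural state ordering in >= 2 dimensions; seed the means
        # with k-means cluster centers and per-cluster variances
        from sklearn.cluster import KMeans

        km = KMeans(n_clusters=n_states, random_state=seed, n_init=10).fit(X)
        means = km.cluster_centers_
        covars = np.empty((n_states, d))
        for k in range(n_states):
            members = X[km.labels_ == k]
            covars[k] = np.maximum(
                members.var(axis=0) if len(members) > 1 else v, 1e-6)
    off = (1.0 - self_prior) / (n_states - 1) if n_states > 1 else 0.0
    transmat = np.full((n_states, n_states), off)
    np.fill_diagonal(transmat, self_prior)
    startprob = np.full(n_states, 1.0 / n_states)

    model = GaussianHMM(
        n_components=n_states,
        covariance_type="diag",
        n_iter=max_iter,
        tol=tol,
        init_params="",
        params="stmc",
        random_state=seed,
        min_covar=1e-6,
    )
    model.startprob_ = startprob
    model.transmat_ = transmat
    model.means_ = means
    model.covars_ = covars
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # hmmlearn warns on short sequences
        model.fit(X, lengths)
    converged = bool(model.monitor_.converged)
    if not converged:
        logger.warning("EM did not converge in %d iterations; returning best model",
                       max_iter)
    diag_covars = np.array([np.diag(c) for c in model.covars_])
    return HMMSpec(
        n_states=n_states,
        means=model.means_,
        covars=np.maximum(diag_covars, 1e-12),
        transmat=model.transmat_,
        startprob=np.maximum(model.startprob_, 0) / model.startprob_.sum(),
        seed=seed,
        max_iter=max_iter,
        tol=tol,
        converged=converged,
    )


def _state_labels(spec: HMMSpec) -> list[str]:
    """Label states by ascending first-dimension emission mean.

    1-D four-state mode gets the canonical Strong−/Weak−/Weak+/Strong+
    names; other state counts get Strong− for the lowest mean, Strong+
    for the highest and Mid_k in between. Ties break by state index.
    """
    order = np.argsort(spec.means[:, 0], kind="stable")
    n = spec.n_states
    if n == 4 and spec.n_dims == 1:
        names = list(FOUR_STATE_LABELS)
    elif n == 1:
        names = ["Strong+"]
    else:
        names = ["Strong-"] + [f"Mid{k}" for k in range(1, n - 1)] + ["Strong+"]
    labels = [""] * n
    for rank, state in enumerate(order):
        labels[state] = names[rank]
    return labels


def decode(spec: HMMSpec, track) -> DomainSegmentation:
    """Viterbi-decode a track and merge same-state runs into domains.

    States are relabeled by ascending emission mean; per-domain mean
    residual (first observation dimension) is recorded. Sequences are
    decoded independently, so a NaN gap never joins two domains.
    """
    obs_dim = _observations(track).shape[1]
    if obs_dim != spec.n_dims:
        raise ValueError(
            f"track has {obs_dim}-D observations but model expects {spec.n_dims}-D"
        )
    model = spec.to_hmmlearn()
    labels = _state_labels(spec)
    domains: list[Domain] = []
    for chrom, start, x in _sequences(track):
        path = model.predict(x)
        run_start = 0
        for i in range(1, len(path) + 1):
            if i == len(path) or path[i] != path[run_start]:
                domains.append(
                    Domain(
                        chrom=chrom,
                        start_bin=start + run_start,
                        end_bin=start + i,
                        state=labels[path[run_start]],
                        mean_residual=float(x[run_start:i, 0].mean()),
                    )
                )
                run_start = i
    emissions = {
        labels[k]: (spec.means[k].copy(), spec.covars[k].copy())
        for k in range(spec.n_states)
    }
    return DomainSegmentation(genome=track.genome, domains=domains, emissions=emissions)


def variability_profile(tracks: list, min_samples: int = 3) -> VariabilityProfile:
    """Per-bin sample mean and sd (ddof=1) of PIS across a panel of tracks.

    Bins with fewer than ``min_samples`` finite values are NaN.
    """
    if len(tracks) < 2:
        raise ValueError("variability profile needs at least 2 tracks")
    genome = tracks[0].genome
    for t in tracks[1:]:
        tracks[0]._require_same_genome(t)
    stack = np.vstack([t.values for t in tracks])
    finite = np.isfinite(stack)
    count = finite.sum(axis=0)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        mean = np.nanmean(stack, axis=0)
        sd = np.nanstd(stack, axis=0, ddof=1)
    ok = count >= max(min_samples, 2)
    mean[~ok] = np.nan
    sd[~ok] = np.nan
    return VariabilityProfile(genome, mean, sd, n_samples=len(tracks))


def label_variability_states(seg: DomainSegmentation) -> DomainSegmentation:
    """Map a five-state (mean, sd) segmentation onto variability classes.

    The two lowest-sd states become conA/conB by the sign of their mean
    PIS; of the remaining three, the highest-sd state is "variable" and
    the other two are varA/varB by mean sign. If a sign tie makes the
    A/B assignment ambiguous, labeling falls back to mean ordering with
    a warning (higher mean → A).
    """
    if seg.emissions is None or len(seg.emissions) != 5:
        raise ValueError("expected a segmentation from a 5-state model with emissions")
    items = list(seg.emissions.items())
    if any(mean.shape[0] != 2 for _, (mean, _) in items):
        raise ValueError("variability labeling needs 2-D (mean, sd) emissions")
    # order states by emitted sd (dimension 1 of the mean vector)
    by_sd = sorted(items, key=lambda kv: kv[1][0][1])
    low, rest = by_sd[:2], by_sd[2:]
    variable = max(rest, key=lambda kv: kv[1][0][1])
    mid = [kv for kv in rest if kv[0] != variable[0]]

    mapping: dict[str, str] = {variable[0]: "variable"}
    for pair, (a_lab, b_lab) in ((low, ("conA", "conB")), (mid, ("varA", "varB"))):
        signs = [np.sign(kv[1][0][0]) for kv in pair]
        if signs[0] == signs[1]:
            warnings.warn(
                "mean-sign tie in variability labeling; falling back to mean ordering",
                stacklevel=2,
            )
        hi, lo = sorted(pair, key=lambda kv: -kv[1][0][0])
        mapping[hi[0]] = a_lab
        mapping[lo[0]] = b_lab
    return seg.relabel(mapping)
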