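"""Synthetic Hi-C O/E data with known compartment structure.

The generator emulates the plaid (checkerboard) pattern of O/E contact
matrices that compartmentalization produces: each bin carries a latent
compartment strength e_i in [-1, 1] (positive = A-like), and

    OE[i, j] = exp(s * e_i * e_j) * noise,

with plaid strength s and mean-one multiplicative lognormal noise.
Same-sign bin pairs contact more than expected, opposite-sign pairs
less, which is exactly the signal the Preferential Interaction Score
reads out. Differential conditions are produced by shifting the latent
profile inside planted domains (not by editing PIS directly), so
pipeline recovery tests are genuinely end-to-end; replicates add
independent noise around the same expectation.

What this emulates — and what it does not: the latent profile is blocky
at the scale of real compartment domains and the plaid coupling is
homogeneous; real data additionally carry distance-dependent residual
structure, TADs, loops and coverage artifacts, which are out of scope
here (inputs to the pipeline are already O/E-normalized).
"""

from __future__ import annotations

import json
import math
import os
from dataclasses import dataclass, field

import numpy as np

from .genome import A, B, UNDEFINED, BinnedGenome, CompartmentTrack, OEMatrix

__all__ = [
    "PlantedDomain",
    "SyntheticTruth",
    "random_truth",
    "default_truth",
    "plant_domains",
    "shifted_profile",
    "generate_plaid_oe",
    "generate_differential_pair",
    "generate_replicates",
    "truth_compartments",
    "generate_variability_panel",
    "default_genome",
    "write_fixture",
]

PLAID_STRENGTH = 0.8


@dataclass(frozen=True)
class PlantedDomain:
    """A planted quantitative compartmentalization shift.

    ``shift`` is the target residual-PIS magnitude (log2 units) with its
    sign giving the direction (positive = increased A-affinity in the
    second condition). Bin coordinates are local to ``chrom``, half-open.
    """

    chrom: str
    start_bin: int
    end_bin: int
    shift: float


@dataclass
class SyntheticTruth:
    """Ground truth behind a synthetic dataset."""

    eigen_profile: np.ndarray  # global per-bin compartment strength, NaN on gaps
    planted_domains: list[PlantedDomain] = field(default_factory=list)
    noise_sd: float = 0.1
    seed: int = 7
    plaid_strength: float = PLAID_STRENGTH

    def __post_init__(self):
        e = np.asarray(self.eigen_profile, dtype=float)
        if np.nanmax(np.abs(e)) > 1 + 1e-9:
            raise ValueError("|eigen profile| must be <= 1")
        self.eigen_profile = e
        spans: dict[str, list[tuple[int, int]]] = {}
        for d in self.planted_domains:
            for s, e_ in spans.get(d.chrom, []):
                if d.start_bin < e_ and s < d.end_bin:
                    raise ValueError("planted domains overlap")
            spans.setdefault(d.chrom, []).append((d.start_bin, d.end_bin))


def default_genome(
    n_chroms: int = 4,
    bins_per_chrom: int = 2000,
    bin_size: int = 50_000,
    gap_fraction: float = 0.02,
    seed: int = 7,
) -> BinnedGenome:
    """A toy genome of equal-length chromosomes with a few random gap runs."""
    names = tuple(f"chr{i + 1}" for i in range(n_chroms))
    lengths = tuple(bins_per_chrom * bin_size for _ in names)
    genome = BinnedGenome(names, lengths, bin_size)
    if gap_fraction <= 0:
        return genome
    rng = np.random.default_rng(seed)
    mask = np.zeros(genome.n_bins, dtype=bool)
    n_gap = int(gap_fraction * genome.n_bins)
    offsets = genome.chrom_offsets
    placed = 0
    while placed < n_gap:
        chrom = names[rng.integers(len(names))]
        n = genome.n_bins_chrom(chrom)
        run = int(rng.integers(2, 8))
        start = int(rng.integers(0, max(1, n - run)))
        sl = slice(offsets[chrom] + start, offsets[chrom] + start + run)
        placed += int((~mask[sl]).sum())
        mask[sl] = True
    return BinnedGenome(names, lengths, bin_size, gap_mask=mask)


def random_truth(
    genome: BinnedGenome,
    seed: int = 7,
    block_bins: tuple[int, int] = (10, 40),
    magnitude: tuple[float, float] = (0.5, 1.0),
    noise_sd: float = 0.1,
    plaid_strength: float = PLAID_STRENGTH,
) -> SyntheticTruth:
    """Blocky alternating compartment profile with random block sizes.

    Blocks alternate sign (A-like / B-like) with magnitudes drawn
    uniformly, giving every chromosome both compartments; gap bins are
    NaN.
    """
    rng = np.random.default_rng(seed)
    e = np.full(genome.n_bins, np.nan)
    offsets = genome.chrom_offsets
    for chrom in genome.chrom_names:
        n = genome.n_bins_chrom(chrom)
        pos = 0
        sign = 1 if rng.random() < 0.5 else -1
        while pos < n:
            ln = int(rng.integers(block_bins[0], block_bins[1] + 1))
            mag = rng.uniform(*magnitude)
            e[offsets[chrom] + pos: offsets[chrom] + min(pos + ln, n)] = sign * mag
            sign = -sign
            pos += ln
    e[genome.gap_mask] = np.nan
    return SyntheticTruth(e, noise_sd=noise_sd, seed=seed,
                          plaid_strength=plaid_strength)


def plant_domains(
    truth: SyntheticTruth,
    genome: BinnedGenome,
    shifts: tuple[float, ...] = (1.5, -1.5, 0.3, -0.3),
    n_per_shift: int = 4,
    domain_bins: tuple[int, int] = (20, 45),
    seed: int | None = None,
    min_gap: int = 10,
) -> SyntheticTruth:
    """Plant non-overlapping shift domains, direction-aware.

    A positive (A-ward) shift is planted on a stretch whose base profile
    is B-like and vice versa, so the shifted profile stays within
    [-1, 1] without clipping away the effect. Domains keep at least
    ``min_gap`` unshifted bins between them so each planted boundary is
    unambiguous.
    """
    rng = np.random.default_rng(truth.seed if seed is None else seed)
    offsets = genome.chrom_offsets
    taken = np.zeros(genome.n_bins, dtype=bool)
    domains: list[PlantedDomain] = []
    for shift in shifts:
        placed = 0
        attempts = 0
        while placed < n_per_shift and attempts < 2000:
            attempts += 1
            chrom = genome.chrom_names[int(rng.integers(len(genome.chrom_names)))]
            n = genome.n_bins_chrom(chrom)
            ln = int(rng.integers(domain_bins[0], domain_bins[1] + 1))
            start = int(rng.integers(0, max(1, n - ln)))
            sl = slice(offsets[chrom] + start, offsets[chrom] + start + ln)
            base = truth.eigen_profile[sl]
            if taken[sl].any() or not np.isfinite(base).all():
                continue
            # direction-aware placement: the full latent shift must fit
            # inside [-1, 1] at every bin, else the effect would clip
            delta = shift / _pis_scale(truth, genome, chrom)
            if np.any(np.abs(base + delta) > 1.0):
                continue
            margin_lo = offsets[chrom] + max(0, start - min_gap)
            margin_hi = offsets[chrom] + min(n, start + ln + min_gap)
            taken[margin_lo:margin_hi] = True
            domains.append(PlantedDomain(chrom, start, start + ln, shift))
            placed += 1
        if placed < n_per_shift:
            raise RuntimeError(f"could not place {n_per_shift} domains of shift {shift}")
    return SyntheticTruth(
        truth.eigen_profile, domains, truth.noise_sd, truth.seed, truth.plaid_strength
    )


def default_truth(
    genome: BinnedGenome,
    seed: int = 7,
    noise_sd: float = 0.1,
    shifts: tuple[float, ...] = (1.5, -1.5, 0.3, -0.3),
) -> SyntheticTruth:
    """Random truth with planted domains scaled to the genome size.

    Domain count and length shrink with the genome so small test
    fixtures still place all shift levels; on the default 4 x 2000-bin
    genome this plants 16 domains (~7% of bins differential).
    """
    truth = random_truth(genome, seed=seed, noise_sd=noise_sd)
    n = genome.n_bins
    lo = max(6, n // 400)
    hi = max(10, n // 180)
    n_per_shift = max(1, n // 2000)
    return plant_domains(truth, genome, shifts=shifts, n_per_shift=n_per_shift,
                         domain_bins=(lo, hi))


def _pis_scale(truth: SyntheticTruth, genome: BinnedGenome, chrom: str) -> float:
    """log2-PIS change per unit eigen shift on one chromosome.

    First-order plaid relation: PIS_i ≈ s·e_i·(ē_A − ē_B)/ln 2, so a
    latent shift δ moves the PIS by s·δ·(ē_A − ē_B)/ln 2.
    """
    e = truth.eigen_profile[genome.chrom_slice(chrom)]
    ea = e[np.isfinite(e) & (e > 0)].mean()
    eb = e[np.isfinite(e) & (e < 0)].mean()
    return truth.plaid_strength * (ea - eb) / math.log(2)


def shifted_profile(truth: SyntheticTruth, genome: BinnedGenome) -> np.ndarray:
    """Second-condition eigen profile: base plus planted latent shifts."""
    e = truth.eigen_profile.copy()
    offsets = genome.chrom_offsets
    for d in truth.planted_domains:
        delta = d.shift / _pis_scale(truth, genome, d.chrom)
        sl = slice(offsets[d.chrom] + d.start_bin, offsets[d.chrom] + d.end_bin)
        e[sl] = np.clip(e[sl] + delta, -1.0, 1.0)
    return e


def _render_chrom(
    e_chrom: np.ndarray,
    plaid_strength: float,
    noise_sd: float,
    rng: np.random.Generator,
    chrom: str,
) -> OEMatrix:
    finite = np.isfinite(e_chrom)
    e = np.where(finite, e_chrom, 0.0)
    values = np.exp(plaid_strength * np.outer(e, e))
    if noise_sd > 0:
        z = rng.standard_normal(values.shape)
        z = np.triu(z) + np.triu(z, 1).T  # symmetric noise field
        values = values * np.exp(noise_sd * z - noise_sd**2 / 2.0)
    valid = np.outer(finite, finite)
    values[~valid] = 0.0
    return OEMatrix(chrom=chrom, values=values, valid=valid)


def generate_plaid_oe(
    truth: SyntheticTruth,
    genome: BinnedGenome,
    chroms: list[str] | None = None,
    profile: np.ndarray | None = None,
    rng: np.random.Generator | None = None,
) -> dict[str, OEMatrix]:
    """Render the latent profile into per-chromosome O/E matrices."""
    if rng is None:
        rng = np.random.default_rng(truth.seed)
    e = truth.eigen_profile if profile is None else profile
    out = {}
    for chrom in chroms or genome.chrom_names:
        out[chrom] = _render_chrom(
            e[genome.chrom_slice(chrom)], truth.plaid_strength, truth.noise_sd,
            rng, chrom,
        )
    return out


def generate_differential_pair(
    truth: SyntheticTruth,
    genome: BinnedGenome,
) -> tuple[dict[str, OEMatrix], dict[str, OEMatrix], SyntheticTruth]:
    """Render both conditions with independent noise.

    Condition 2's latent profile equals condition 1's except inside the
    planted domains. Returns (condition-1 matrices, condition-2
    matrices, truth).
    """
    ss = np.random.SeedSequence(truth.seed)
    rng1, rng2 = (np.random.default_rng(s) for s in ss.spawn(2))
    oes1 = generate_plaid_oe(truth, genome, rng=rng1)
    oes2 = generate_plaid_oe(truth, genome, profile=shifted_profile(truth, genome),
                             rng=rng2)
    return oes1, oes2, truth


def generate_replicates(
    oe: OEMatrix, k: int, noise_sd: float, seed: int
) -> list[OEMatrix]:
    """k copies of a matrix under independent mean-one lognormal noise."""
    rng = np.random.default_rng(seed)
    reps = []
    for _ in range(k):
        if noise_sd > 0:
            z = rng.standard_normal(oe.values.shape)
            z = np.triu(z) + np.triu(z, 1).T
            values = oe.values * np.exp(noise_sd * z - noise_sd**2 / 2.0)
        else:
            values = oe.values.copy()
        values[~oe.valid] = 0.0
        reps.append(OEMatrix(oe.chrom, values, oe.valid.copy()))
    return reps


def truth_compartments(
    genome: BinnedGenome, profile: np.ndarray
) -> CompartmentTrack:
    """Compartment labels from the sign of a latent profile."""
    labels = np.full(genome.n_bins, UNDEFINED, dtype=np.int8)
    finite = np.isfinite(profile)
    labels[finite & (profile > 0)] = A
    labels[finite & (profile < 0)] = B
    return CompartmentTrack(genome, labels, eigen=np.where(finite, profile, np.nan))


# ---------------------------------------------------------------------------
# variability panel

VARIABILITY_CLASS_PARAMS = {
    # class: (mean latent strength, across-sample latent sd)
    "conA": (0.85, 0.03),
    "conB": (-0.85, 0.03),
    "varA": (0.50, 0.18),
    "varB": (-0.50, 0.18),
    "variable": (0.0, 0.65),
}


def generate_variability_panel(
    genome: BinnedGenome,
    n_samples: int = 19,
    seed: int = 7,
    block_bins: tuple[int, int] = (15, 35),
    noise_sd: float = 0.1,
    plaid_strength: float = PLAID_STRENGTH,
):
    """A panel of samples whose compartment variability is planted per block.

    Each block of bins is assigned one of five classes — conA/conB
    (constitutive, tiny across-sample variation), varA/varB (clear
    preference, moderate variation) or variable (sign-switching, large
    variation) — and each sample draws its latent strength from the
    class distribution. Returns ``(per-sample O/E dicts, per-sample
    latent profiles, per-bin class labels)``.
    """
    rng = np.random.default_rng(seed)
    classes = list(VARIABILITY_CLASS_PARAMS)
    labels = np.full(genome.n_bins, None, dtype=object)
    blocks: list[tuple[int, int, str]] = []  # global-bin spans
    offsets = genome.chrom_offsets
    for chrom in genome.chrom_names:
        n = genome.n_bins_chrom(chrom)
        pos = 0
        while pos < n:
            ln = int(rng.integers(block_bins[0], block_bins[1] + 1))
            cls = classes[int(rng.integers(len(classes)))]
            lo = offsets[chrom] + pos
            hi = offsets[chrom] + min(pos + ln, n)
            labels[lo:hi] = cls
            blocks.append((lo, hi, cls))
            pos += ln
    labels[genome.gap_mask] = None

    profiles, panels = [], []
    for _ in range(n_samples):
        e = np.full(genome.n_bins, np.nan)
        # across-sample variation acts coherently per block (a cell
        # type's compartment strength drifts domain-wise, not bin-wise),
        # with small per-bin texture on top
        for lo, hi, cls in blocks:
            mu, sd = VARIABILITY_CLASS_PARAMS[cls]
            level = mu + sd * rng.standard_normal()
            e[lo:hi] = np.clip(level + 0.02 * rng.standard_normal(hi - lo), -1.0, 1.0)
        e[genome.gap_mask] = np.nan
        truth = SyntheticTruth(e, noise_sd=noise_sd, seed=seed,
                               plaid_strength=plaid_strength)
        panels.append(generate_plaid_oe(truth, genome, rng=rng))
        profiles.append(e)
    return panels, profiles, labels


# ---------------------------------------------------------------------------
# fixture writing (used by the `daric simulate` subcommand)


def write_fixture(outdir: str, truth: SyntheticTruth, genome: BinnedGenome,
                  n_replicates: int = 2) -> dict:
    """Write dump-text O/E (two conditions x replicates), compartment
    bedGraph, gap BED and truth JSON.

    Replicates are independent noisy renders around each condition's
    noise-free expectation, so the files feed the whole pipeline
    including the replicate-based significance stage.
    """
    from . import io as dio

    os.makedirs(outdir, exist_ok=True)
    clean = SyntheticTruth(truth.eigen_profile, truth.planted_domains, 0.0,
                           truth.seed, truth.plaid_strength)
    base1, base2, _ = generate_differential_pair(clean, genome)
    paths: dict[str, object] = {}
    for cond, oes in (("c1", base1), ("c2", base2)):
        for r in range(n_replicates):
            tag = f"{cond}r{r + 1}"
            paths[tag] = {}
            for ci, (chrom, oe) in enumerate(oes.items()):
                rep = generate_replicates(
                    oe, 1, truth.noise_sd,
                    seed=truth.seed + 1000 * (cond == "c2") + 100 * r + ci,
                )[0]
                p = os.path.join(outdir, f"{tag}_{chrom}.oe.txt")
                dio.write_oe_dump(rep, p, genome)
                paths[tag][chrom] = p  # type: ignore[index]

    comp_path = os.path.join(outdir, "compartments.bedGraph")
    comps = truth_compartments(genome, truth.eigen_profile)
    with open(comp_path, "w") as fh:
        for chrom in genome.chrom_names:
            sl = genome.chrom_slice(chrom)
            for i, v in enumerate(comps.eigen[sl]):
                if np.isfinite(v) and v != 0:
                    fh.write(f"{chrom}\t{genome.bin_start(chrom, i)}\t"
                             f"{genome.bin_end(chrom, i)}\t{v:.6g}\n")
    paths["compartments"] = comp_path

    gap_path = os.path.join(outdir, "gaps.bed")
    with open(gap_path, "w") as fh:
        for chrom in genome.chrom_names:
            sl = genome.chrom_slice(chrom)
            mask = genome.gap_mask[sl]
            i = 0
            while i < len(mask):
                if mask[i]:
                    j = i
                    while j < len(mask) and mask[j]:
                        j += 1
                    fh.write(f"{chrom}\t{genome.bin_start(chrom, i)}\t"
                             f"{genome.bin_end(chrom, j - 1)}\n")
                    i = j
                else:
                    i += 1
    paths["gaps"] = gap_path

    truth_path = os.path.join(outdir, "truth.json")
    with open(truth_path, "w") as fh:
        json.dump(
            {
                "seed": truth.seed,
                "noise_sd": truth.noise_sd,
                "plaid_strength": truth.plaid_strength,
                "chrom_names": list(genome.chrom_names),
                "chrom_lengths": list(genome.chrom_lengths),
                "bin_size": genome.bin_size,
                "planted_domains": [
                    {"chrom": d.chrom, "start_bin": d.start_bin,
                     "end_bin": d.end_bin, "shift": d.shift}
                    for d in truth.planted_domains
                ],
            },
            fh, indent=1,
        )
    paths["truth"] = truth_path
    return paths
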