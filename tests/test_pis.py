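"""PIS computation against a brute-force oracle, smoothing, residuals."""

import logging

import numpy as np
import pytest

from daric.genome import (
    A,
    B,
    UNDEFINED,
    BinnedGenome,
    CompartmentTrack,
    OEMatrix,
    PISTrack,
    SignalTrack,
)
from daric.pis import compute_pis, compute_pis_genome, residual, smooth_pis

from conftest import plaid_matrix


def brute_force_pis(values, valid, labels, gap, exclude_diag=True):
    """Nested-loop reference: enumerate every (i, j) pair explicitly."""
    n = len(labels)
    out = np.full(n, np.nan)
    for i in range(n):
        if gap[i]:
            continue
        sums = {A: 0.0, B: 0.0}
        counts = {A: 0, B: 0}
        for j in range(n):
            if j == i and exclude_diag:
                continue
            if gap[j] or labels[j] == UNDEFINED or not valid[i][j]:
                continue
            sums[labels[j]] += values[i][j]
            counts[labels[j]] += 1
        if counts[A] and counts[B]:
            ma, mb = sums[A] / counts[A], sums[B] / counts[B]
            if ma > 0 and mb > 0:
                out[i] = np.log2(ma / mb)
    return out


class TestComputePIS:
    def test_closed_form_log2_ratio(self, genome1):
        # probe bin 0 sees mean O/E 2.0 against A bins and 0.5 against B bins
        n = 25
        vals = np.ones((n, n))
        labels = np.array([UNDEFINED] + [A] * 12 + [B] * 12, dtype=np.int8)
        vals[0, labels == A] = 2.0
        vals[0, labels == B] = 0.5
        vals = np.triu(vals) + np.triu(vals, 1).T
        oe = OEMatrix("chr1", vals, np.ones((n, n), bool))
        track = compute_pis(oe, CompartmentTrack(genome1, labels))
        assert track.values[0] == pytest.approx(2.0)

    def test_equal_class_means_give_zero(self, genome1):
        n = 25
        labels = np.array([UNDEFINED] + [A] * 12 + [B] * 12, dtype=np.int8)
        oe = OEMatrix("chr1", np.ones((n, n)), np.ones((n, n), bool))
        track = compute_pis(oe, CompartmentTrack(genome1, labels))
        assert track.values[0] == pytest.approx(0.0)

    @pytest.mark.parametrize("exclude_diag", [True, False])
    def test_matches_brute_force_oracle_on_random_plaid(self, rng, exclude_diag):
        n = 12
        genome = BinnedGenome(("c",), (n * 50_000,), 50_000,
                              gap_mask=np.array([False] * 10 + [True, False]))
        e = np.where(np.arange(n) % 2 == 0, 0.8, -0.8) * rng.uniform(0.5, 1, n)
        vals, valid = plaid_matrix(e)
        vals *= rng.lognormal(0, 0.2, (n, n))
        vals = (vals + vals.T) / 2
        valid &= rng.random((n, n)) > 0.1
        valid &= valid.T
        labels = np.where(e > 0, A, B).astype(np.int8)
        labels[5] = UNDEFINED
        oe = OEMatrix("c", np.where(valid, vals, 0.0), valid)
        comps = CompartmentTrack(genome, labels)
        got = compute_pis(oe, comps, min_class_bins=1,
                          exclude_diag=exclude_diag).values
        want = brute_force_pis(oe.values, oe.valid, comps.labels,
                               genome.gap_mask, exclude_diag)
        assert np.allclose(got, want, atol=1e-12, equal_nan=True)

    def test_gap_bins_are_nan(self, rng):
        n = 24
        genome = BinnedGenome(("c",), (n * 50_000,), 50_000)
        genome = genome.with_gaps_from_intervals([("c", 100_000, 200_000)])
        e = np.tile([0.9, -0.9], n // 2)
        vals, valid = plaid_matrix(e)
        oe = OEMatrix("c", vals, valid)
        oe.valid[genome.gap_mask, :] = False
        oe.valid[:, genome.gap_mask] = False
        labels = np.where(e > 0, A, B).astype(np.int8)
        track = compute_pis(oe, CompartmentTrack(genome, labels))
        assert np.isnan(track.values[2:4]).all()
        assert np.isfinite(np.delete(track.values, [2, 3])).all()

    def test_too_few_class_bins_skips_chromosome(self, genome1, caplog):
        n = 25
        labels = np.array([A] * 24 + [B], dtype=np.int8)  # 1 B bin < 10
        oe = OEMatrix("chr1", np.ones((n, n)), np.ones((n, n), bool))
        with caplog.at_level(logging.WARNING):
            track = compute_pis(oe, CompartmentTrack(genome1, labels))
        assert np.isnan(track.values).all()
        assert "skipped" in caplog.text

    def test_multi_chromosome_merge(self, genome2, rng):
        labels = np.tile([A, B], genome2.n_bins // 2).astype(np.int8)
        comps = CompartmentTrack(genome2, labels)
        oes = []
        for chrom in genome2.chrom_names:
            n = genome2.n_bins_chrom(chrom)
            m = rng.uniform(0.5, 2, (n, n))
            m = (m + m.T) / 2
            oes.append(OEMatrix(chrom, m, np.ones((n, n), bool)))
        track = compute_pis_genome(oes, comps, min_class_bins=5)
        assert np.isfinite(track.values).all()


class TestSmoothing:
    def test_constant_track_is_preserved(self, genome2):
        t = PISTrack(genome2, np.full(genome2.n_bins, 1.7))
        s = smooth_pis(t, sigma_bins=2.5)
        assert np.allclose(s.values, 1.7)

    def test_unit_impulse_mass_is_conserved(self):
        g = BinnedGenome(("c",), (41 * 50_000,), 50_000)
        v = np.zeros(41)
        v[20] = 1.0
        s = smooth_pis(PISTrack(g, v), sigma_bins=1.0)
        assert s.values.sum() == pytest.approx(1.0, abs=1e-9)

    def test_nan_aware_matches_weighted_average_oracle(self, rng):
        from scipy.stats import norm

        g = BinnedGenome(("c",), (15 * 50_000,), 50_000)
        v = rng.standard_normal(15)
        v[6] = np.nan
        s = smooth_pis(PISTrack(g, v), sigma_bins=2.0)
        assert np.isnan(s.values[6])
        # explicit per-bin oracle with a reflected, truncated kernel
        pad = 8  # truncate=4 * sigma=2
        idx = np.arange(-pad, 15 + pad)
        # scipy 'reflect' boundary: (d c b a | a b c d | d c b a)
        reflected = np.where(idx < 0, -idx - 1, idx)
        reflected = np.where(reflected > 14, 29 - reflected, reflected)
        ext = v[reflected]
        for i in [0, 5, 7, 14]:
            w = norm.pdf(np.arange(-pad, pad + 1), scale=2.0)
            window = ext[i: i + 2 * pad + 1]
            ok = np.isfinite(window)
            want = np.sum(w[ok] * window[ok]) / np.sum(w[ok])
            assert s.values[i] == pytest.approx(want, rel=1e-3)

    def test_smoothing_stops_at_chromosome_boundary(self, genome2):
        v = np.zeros(genome2.n_bins)
        sl_b = genome2.chrom_slice("chrB")
        v[sl_b.start] = 1.0  # impulse at chrB's first bin
        s = smooth_pis(PISTrack(genome2, v), sigma_bins=2.0)
        assert np.allclose(s.values[genome2.chrom_slice("chrA")], 0.0)

    @pytest.mark.parametrize("sigma", [0.0, -1.0])
    def test_nonpositive_sigma_rejected(self, genome2, sigma):
        t = PISTrack(genome2, np.zeros(genome2.n_bins))
        with pytest.raises(ValueError, match="sigma"):
            smooth_pis(t, sigma)

    def test_double_smoothing_warns(self, genome2):
        t = smooth_pis(PISTrack(genome2, np.zeros(genome2.n_bins)), 1.0)
        with pytest.warns(UserWarning, match="already-smoothed"):
            smooth_pis(t, 1.0)


class TestResidual:
    def test_elementwise_difference(self, genome2):
        n = genome2.n_bins
        a = PISTrack(genome2, np.full(n, 1.0))
        b = PISTrack(genome2, np.full(n, 0.5))
        a.values[:2] = [1.0, 2.0]
        b.values[:2] = [0.5, 2.0]
        r = residual(a, b)
        assert r.values[0] == pytest.approx(0.5)
        assert r.values[1] == pytest.approx(0.0)

    def test_self_residual_is_zero_and_nan_propagates(self, genome2, rng):
        v = rng.standard_normal(genome2.n_bins)
        v[3] = np.nan
        t = PISTrack(genome2, v)
        r = residual(t, t)
        assert np.all(r.values[np.isfinite(v)] == 0)
        assert np.isnan(r.values[3])

    def test_genome_mismatch_raises(self, genome1, genome2):
        a = PISTrack(genome1, np.zeros(genome1.n_bins))
        b = PISTrack(genome2, np.zeros(genome2.n_bins))
        with pytest.raises(ValueError, match="genome"):
            residual(a, b)


class TestPlaidConcordance:
    def test_sign_matches_planted_compartments_and_tracks_eigen(self, rng):
        n = 120
        genome = BinnedGenome(("c",), (n * 50_000,), 50_000)
        blocks = rng.uniform(0.4, 1.0, n // 10) * np.where(
            np.arange(n // 10) % 2 == 0, 1, -1)
        e = np.repeat(blocks, 10)
        vals, valid = plaid_matrix(e)
        oe = OEMatrix("c", vals, valid)
        comps = CompartmentTrack(genome, np.where(e > 0, A, B).astype(np.int8))
        pis = compute_pis(oe, comps).values
        assert np.mean(np.sign(pis) == np.sign(e)) > 0.99
        r = np.corrcoef(pis, e)[0, 1]
        assert r > 0.95
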