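"""Windowed statistics, empirical FDR, segmentation and de novo detection."""

import numpy as np
import pytest
from scipy.stats import norm

from footprintkit.cleavage_bias import BiasModel
from footprintkit.dispersion import DispersionModel
from footprintkit.footprint_detect import (
    Z_CAP,
    DetectParams,
    detect_sample,
    empirical_fdr,
    segment_footprints,
    windowed_stat,
)
from footprintkit.tracks_io import CleavageProfile, GenomeSequence, GenomicInterval


def stouffer_oracle(p, tested, widths):
    """Brute-force min-over-widths Stouffer statistic."""
    z = [norm.ppf(pi) if t else Z_CAP for pi, t in zip(p, tested)]
    z = [min(zi, Z_CAP) for zi in z]
    out = []
    for i in range(len(p)):
        best = np.inf
        for w in widths:
            half = w // 2
            total = 0.0
            for j in range(i - half, i + half + 1):
                total += z[j] if 0 <= j < len(z) else Z_CAP
            best = min(best, total / np.sqrt(w))
        out.append(best)
    return np.array(out)


def fdr_oracle(obs, nulls):
    """Direct-counting empirical FDR with step-up monotonisation."""
    obs = np.asarray(obs, dtype=float)
    pooled = np.concatenate([np.asarray(n, dtype=float) for n in nulls])
    r = len(nulls)
    uniq = np.unique(obs)
    raw = []
    for t in uniq:
        n_null = (pooled <= t).sum() / r
        n_obs = (obs <= t).sum()
        raw.append(min(1.0, n_null / max(1, n_obs)))
    mono = [min(raw[j] for j in range(i, len(raw))) for i in range(len(raw))]
    lookup = dict(zip(uniq, mono))
    return np.array([lookup[t] for t in obs])


class TestWindowedStat:
    def test_neutral_pvalues_give_zero_statistic(self):
        p = np.array([0.5, 0.5, 0.5])
        stat = windowed_stat(p, np.ones(3, bool), widths=(3,))
        assert stat[1] == pytest.approx(0.0, abs=1e-12)

    def test_hand_stouffer_value(self):
        p = np.array([0.1, 0.1, 0.1])
        stat = windowed_stat(p, np.ones(3, bool), widths=(3,))
        assert stat[1] == pytest.approx(3 * norm.ppf(0.1) / np.sqrt(3), rel=1e-6)
        assert stat[1] == pytest.approx(-2.2198, abs=2e-4)

    def test_width_one_is_probit_identity(self, rng):
        p = rng.uniform(0.01, 0.99, 30)
        stat = windowed_stat(p, np.ones(30, bool), widths=(1,))
        np.testing.assert_allclose(stat, norm.ppf(p), rtol=1e-12)

    def test_even_width_rejected(self):
        with pytest.raises(ValueError):
            windowed_stat(np.array([0.5]), np.array([True]), widths=(4,))

    def test_untested_positions_capped(self):
        p = np.array([0.5, 0.5, 0.5])
        stat = windowed_stat(p, np.array([True, False, True]), widths=(1,))
        assert stat[1] == pytest.approx(Z_CAP)

    def test_matches_bruteforce_oracle(self, rng):
        p = rng.uniform(1e-4, 1.0, 60)
        tested = rng.random(60) > 0.2
        widths = (3, 5, 9)
        got = windowed_stat(p, tested, widths)
        np.testing.assert_allclose(got, stouffer_oracle(p, tested, widths), rtol=1e-10)


class TestEmpiricalFdr:
    def test_self_null_gives_fdr_one_everywhere(self, rng):
        obs = rng.normal(size=50)
        fdr = empirical_fdr(obs, [obs.copy()])
        assert np.allclose(fdr, 1.0)

    def test_direct_counting_example(self):
        obs = np.array([-5.0, -1.0, 0.0])
        fdr = empirical_fdr(obs, [np.array([-0.5, 0.0, 0.2])])
        assert fdr[0] == 0.0
        assert fdr[2] == pytest.approx(2 / 3)

    def test_positive_observations_near_one(self, rng):
        obs = rng.uniform(1.0, 2.0, 200)
        nulls = [rng.normal(size=200) for _ in range(5)]
        assert empirical_fdr(obs, nulls).min() >= 0.5

    def test_matches_bruteforce_oracle(self, rng):
        obs = rng.normal(size=80)
        nulls = [rng.normal(size=80) for _ in range(4)]
        np.testing.assert_allclose(
            empirical_fdr(obs, nulls), fdr_oracle(obs, nulls), rtol=1e-12
        )

    def test_monotone_in_statistic(self, rng):
        obs = rng.normal(size=300)
        nulls = [rng.normal(size=300) for _ in range(3)]
        fdr = empirical_fdr(obs, nulls)
        order = np.argsort(obs)
        assert np.all(np.diff(fdr[order]) >= 0)

    def test_requires_a_null_replicate(self):
        with pytest.raises(ValueError):
            empirical_fdr(np.array([0.0]), [])


class TestSegmentFootprints:
    IV = GenomicInterval("c", 0, 5)

    def test_single_run(self):
        fdr = np.array([1, 0.005, 0.005, 0.005, 1.0])
        calls = segment_footprints(fdr, self.IV, threshold=0.01, merge_gap=0, min_width=3)
        assert len(calls) == 1
        assert (calls[0].interval.start, calls[0].interval.end) == (1, 4)
        assert calls[0].width == 3
        assert calls[0].best_fdr == pytest.approx(0.005)

    def test_all_failing_gives_empty(self):
        assert segment_footprints(np.ones(5), self.IV) == []

    def test_gap_merging(self):
        fdr = np.array([0.001] * 3 + [1.0] * 2 + [0.001] * 3)
        iv = GenomicInterval("c", 0, 8)
        merged = segment_footprints(fdr, iv, merge_gap=3, min_width=3)
        assert len(merged) == 1
        assert (merged[0].interval.start, merged[0].interval.end) == (0, 8)
        split = segment_footprints(fdr, iv, merge_gap=1, min_width=3)
        assert len(split) == 2

    def test_min_width_filter(self):
        fdr = np.array([0.001, 0.001, 1.0, 1.0, 1.0])
        assert segment_footprints(fdr, self.IV, min_width=3) == []

    def test_score_from_best_fdr(self):
        fdr = np.full(8, 1e-3)
        calls = segment_footprints(fdr, GenomicInterval("c", 0, 8), min_width=3)
        assert calls[0].score == 30


def _simulate_interval(rng, n, rate, r, footprints=()):
    lam = np.full(n, rate)
    for lo, hi, delta in footprints:
        lam[lo:hi] *= delta
    plus = rng.poisson(rng.gamma(r / 2, (lam / 2) / (r / 2)))
    minus = rng.poisson(rng.gamma(r / 2, (lam / 2) / (r / 2)))
    return CleavageProfile(GenomicInterval("c", 0, n), plus, minus)


@pytest.fixture(scope="module")
def detect_setup():
    rng = np.random.default_rng(99)
    seq = "".join(rng.choice(list("ACGT"), 400))
    return (
        GenomeSequence({"c": seq}),
        BiasModel.uniform(),
        DispersionModel.from_trend(r=8.0, fit_range=(0.0, 60.0)),
    )


class TestDetectSample:
    def test_planted_footprint_recovered_with_tight_boundaries(self, detect_setup):
        genome, bias, model = detect_setup
        planted = GenomicInterval("c", 200, 215)
        edge_errors = []
        for seed in range(5):
            rng = np.random.default_rng(seed)
            prof = _simulate_interval(rng, 400, 20.0, 8.0, [(200, 215, 0.2)])
            res = detect_sample([prof], genome, bias, model, DetectParams(), seed=seed + 1000)
            over = [c for c in res.calls if c.interval.overlaps(planted)]
            assert len(over) == 1
            edge_errors.append(abs(over[0].interval.start - planted.start))
            edge_errors.append(abs(over[0].interval.end - planted.end))
        assert np.mean(edge_errors) <= 3.0

    def test_null_interval_rarely_yields_calls(self, detect_setup):
        genome, bias, model = detect_setup
        n_with_calls = 0
        for seed in range(100):
            rng = np.random.default_rng(10_000 + seed)
            prof = _simulate_interval(rng, 300, 20.0, 8.0)
            res = detect_sample(
                [prof], genome, bias, model, DetectParams(), seed=seed
            )
            n_with_calls += bool(res.calls)
        assert n_with_calls <= 5  # 0 calls in >= 95% of null seeds

    def test_zero_depth_interval_all_untested_no_calls(self, detect_setup):
        genome, bias, model = detect_setup
        prof = CleavageProfile(
            GenomicInterval("c", 0, 300), np.zeros(300, int), np.zeros(300, int)
        )
        res = detect_sample([prof], genome, bias, model, DetectParams(), seed=0)
        assert res.calls == []
        assert not res.stats[0].tested.any()

    def test_deterministic_given_seed(self, detect_setup):
        genome, bias, model = detect_setup
        rng = np.random.default_rng(7)
        prof = _simulate_interval(rng, 400, 20.0, 8.0, [(150, 170, 0.25)])
        r1 = detect_sample([prof], genome, bias, model, DetectParams(), seed=5)
        r2 = detect_sample([prof], genome, bias, model, DetectParams(), seed=5)
        np.testing.assert_array_equal(r1.fdr_tracks[0].fdr, r2.fdr_tracks[0].fdr)
        assert [c.interval for c in r1.calls] == [c.interval for c in r2.calls]

    def test_sensitivity_increases_with_depth(self, detect_setup):
        # deeper sequencing detects more of a fixed weak-footprint truth
        genome, bias, model = detect_setup
        footprints = [(60 + 80 * i, 72 + 80 * i, 0.55) for i in range(4)]
        hits = {}
        for depth in (5.0, 40.0):
            found = 0
            for seed in range(10):
                rng = np.random.default_rng(500 + seed)
                prof = _simulate_interval(rng, 400, depth, 8.0, footprints)
                res = detect_sample(
                    [prof], genome, bias, model, DetectParams(), seed=seed
                )
                for lo, hi, _ in footprints:
                    iv = GenomicInterval("c", lo, hi)
                    found += any(c.interval.overlaps(iv) for c in res.calls)
            hits[depth] = found
        assert hits[40.0] > hits[5.0]
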