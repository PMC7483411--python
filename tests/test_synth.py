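import numpy as np
import pytest

from hrvc.dfa import dfa
from hrvc.mse import mse_curve
from hrvc.preprocess import filter_nn
from hrvc.synth import (RRProfile, CohortSpec, spectral_noise, synth_rr_series,
                        insert_artifacts, simulate_cohort, generate_cohort)
from hrvc.timedomain import time_domain_metrics


class TestSpectralNoise:
    def test_unit_moments(self, rng):
        y = spectral_noise(8192, 1.0, rng)
        assert y.mean() == pytest.approx(0.0, abs=1e-12)
        assert y.std(ddof=1) == pytest.approx(1.0, abs=1e-12)

    @pytest.mark.parametrize("beta", [0.0, 1.0, 1.5])
    def test_periodogram_slope_recovers_beta(self, beta):
        slopes = []
        for seed in range(5):
            y = spectral_noise(16384, beta, np.random.default_rng(seed))
            f = np.fft.rfftfreq(len(y))[1:]
            p = np.abs(np.fft.rfft(y))[1:] ** 2
            # average the periodogram in log-spaced bins before fitting
            bins = np.logspace(np.log10(f[0]), np.log10(f[-1]), 30)
            idx = np.digitize(f, bins)
            fm = [f[idx == i].mean() for i in range(1, 30) if (idx == i).any()]
            pm = [p[idx == i].mean() for i in range(1, 30) if (idx == i).any()]
            slopes.append(np.polyfit(np.log10(fm), np.log10(pm), 1)[0])
        assert np.mean(slopes) == pytest.approx(-beta, abs=0.15)


class TestSynthRRSeries:
    def test_deterministic_given_seed(self):
        p = RRProfile(n_beats=2000, seed=42, ectopic_rate=0.05)
        a, b = synth_rr_series(p), synth_rr_series(p)
        np.testing.assert_array_equal(a.intervals, b.intervals)
        assert list(a.labels) == list(b.labels)

    def test_mean_and_sd_hit_targets_within_2pct(self):
        p = RRProfile(n_beats=12000, mean_rr=800, sd_rr=40, beta=1.0, seed=7)
        rr = synth_rr_series(p)
        assert rr.intervals.mean() == pytest.approx(800, rel=0.02)
        assert rr.intervals.std(ddof=1) == pytest.approx(40, rel=0.02)

    def test_zero_sd_gives_constant_series(self):
        rr = synth_rr_series(RRProfile(n_beats=500, mean_rr=750, sd_rr=0))
        np.testing.assert_allclose(rr.intervals, 750.0)

    def test_heavy_clipping_warns(self):
        with pytest.warns(UserWarning, match="clipped"):
            synth_rr_series(RRProfile(n_beats=2000, mean_rr=400, sd_rr=200,
                                      beta=0.0, seed=1))

    def test_white_noise_profile_dfa_exponents(self):
        # alpha1 (boxes 4-11) carries the known small-box upward bias for
        # white noise (exact expectation 0.617); alpha2 is near 0.5
        a1, a2 = [], []
        for seed in range(5):
            rr = synth_rr_series(RRProfile(n_beats=10000, mean_rr=800,
                                           sd_rr=30, beta=0.0, seed=seed))
            d = dfa(rr.intervals)
            a1.append(d.alpha1)
            a2.append(d.alpha2)
        assert np.mean(a1) == pytest.approx(0.617, abs=0.05)
        assert np.mean(a2) == pytest.approx(0.5, abs=0.06)

    def test_pink_profile_mse_flatter_than_white(self):
        def drop(beta):
            rr = synth_rr_series(RRProfile(n_beats=8000, mean_rr=800,
                                           sd_rr=30, beta=beta, seed=3))
            e = mse_curve(rr.intervals).entropies
            return abs(e[19] - e[0])
        assert drop(1.0) < drop(0.0)


class TestInsertArtifacts:
    def test_rate_zero_is_identity(self):
        rr = synth_rr_series(RRProfile(n_beats=1000, seed=1))
        assert insert_artifacts(rr, 0.0, seed=5) is rr

    def test_ectopic_count_near_binomial_expectation(self):
        rr = synth_rr_series(RRProfile(n_beats=10000, mean_rr=800, sd_rr=20,
                                       beta=1.0, seed=2))
        out = insert_artifacts(rr, 0.05, seed=9)
        n_ect = sum(lb == "ectopic" for lb in out.labels)
        # ~Binomial(9999, 0.025) couplet starts, two beats each
        assert abs(n_ect - 500) < 5 * np.sqrt(10000 * 0.05)

    def test_filter_recovers_clean_sdrr_within_5pct(self):
        clean = synth_rr_series(RRProfile(n_beats=10000, mean_rr=800,
                                          sd_rr=35, beta=1.0, seed=4))
        dirty = insert_artifacts(clean, 0.05, seed=11)
        sd_clean = time_domain_metrics(filter_nn(clean)).sdrr
        sd_dirty = time_domain_metrics(filter_nn(dirty)).sdrr
        assert sd_dirty == pytest.approx(sd_clean, rel=0.05)

    def test_beat_count_preserved(self):
        rr = synth_rr_series(RRProfile(n_beats=3000, seed=1))
        assert len(insert_artifacts(rr, 0.1, seed=2)) == 3000


class TestCohort:
    def test_simulate_cohort_shapes_and_groups(self):
        cov, recs = simulate_cohort(CohortSpec(n_hf=4, n_control=5, seed=3,
                                               duration_h=0.5))
        assert len(cov) == 9 == len(recs)
        assert (cov["group"] == "HF").sum() == 4
        assert set(cov.columns) >= {"subject_id", "group", "rr_file", "age",
                                    "male", "creatinine"}
        assert cov["male"].isin([0, 1]).all()
        assert (cov["creatinine"] >= 0.4).all()

    def test_null_spec_uses_control_profile_for_both_groups(self):
        sep, _ = simulate_cohort(CohortSpec(n_hf=2, n_control=2, seed=3,
                                            duration_h=0.5))
        null_cov, null_recs = simulate_cohort(
            CohortSpec(n_hf=2, n_control=2, seed=3, duration_h=0.5, null=True))
        ctl_cov, ctl_recs = simulate_cohort(
            CohortSpec(n_hf=2, n_control=2, seed=3, duration_h=0.5))
        # same seed path: the HF subjects of the null cohort are drawn from
        # the control distribution, so they differ from the separated spec
        assert null_cov.loc[0, "group"] == "HF"
        hf_null = null_recs["HF001"].intervals
        hf_sep = ctl_recs["HF001"].intervals
        assert not np.array_equal(hf_null, hf_sep)

    def test_generate_cohort_is_byte_identical(self, tmp_path):
        spec = CohortSpec(n_hf=2, n_control=2, seed=17, duration_h=0.3)
        d1, d2 = tmp_path / "a", tmp_path / "b"
        generate_cohort(spec, d1)
        generate_cohort(spec, d2)
        for p1 in sorted(d1.rglob("*")):
            if p1.is_file():
                p2 = d2 / p1.relative_to(d1)
                assert p1.read_bytes() == p2.read_bytes()

    def test_rr_files_round_trip_labels(self, tmp_path):
        from hrvc.preprocess import read_rr_file
        spec = CohortSpec(n_hf=2, n_control=2, seed=8, duration_h=0.3)
        man = generate_cohort(spec, tmp_path)
        _, recs = simulate_cohort(spec)
        rr = read_rr_file(tmp_path / "rr" / "HF001.csv")
        assert list(rr.labels) == list(recs["HF001"].labels)
        np.testing.assert_allclose(rr.intervals, recs["HF001"].intervals,
                                   atol=5e-4)


def test_profile_validation():
    with pytest.raises(ValueError):
        RRProfile(n_beats=100)
    with pytest.raises(ValueError):
        RRProfile(ectopic_rate=0.5)
    with pytest.raises(ValueError):
        CohortSpec(n_hf=1)
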