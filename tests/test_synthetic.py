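"""Cluster point process, feature-level synthesis, and raw iEEG synthesis."""

import numpy as np
import pytest
from scipy import stats

from pibcast.core_io import RunConfig, SeizureCatalog
from pibcast.features import extract_features
from pibcast.synthetic_data import (SimParams, simulate_pib_features,
                                    simulate_raw_ieeg, simulate_seizure_times)


class TestSeizureTimes:
    def test_zero_rate_empty(self):
        cat = simulate_seizure_times(SimParams(lead_rate=0.0, seed=0))
        assert len(cat) == 0

    def test_expected_total_count(self):
        """E[total] ~ lead_rate * duration * mean cluster size (brute-force
        expectation over 200 realizations; truncation biases slightly low)."""
        days, rate, m = 60.0, 0.3, 3.0
        p = SimParams(duration_s=days * 86400.0, lead_rate=rate,
                      cluster_size_mean=m)
        counts = [len(simulate_seizure_times(p, np.random.default_rng(s)))
                  for s in range(200)]
        expected = rate * days * m
        se = np.std(counts, ddof=1) / np.sqrt(len(counts))
        assert abs(np.mean(counts) - expected) < 4 * se + 0.05 * expected

    def test_regime_matches_long_record_cohort_member(self):
        """~5 clusters of mean size 5.4 over 197 days centers near 27 events."""
        p = SimParams(duration_s=197 * 86400.0, lead_rate=5 / 197.0,
                      cluster_size_mean=5.4)
        counts = [len(simulate_seizure_times(p, np.random.default_rng(s)))
                  for s in range(200)]
        assert abs(np.mean(counts) - 27.0) < 3.0

    def test_events_sorted_disjoint_within_record(self):
        p = SimParams(duration_s=20 * 86400.0, lead_rate=1.0,
                      cluster_size_mean=4.0, seed=3)
        cat = simulate_seizure_times(p)
        assert np.all(np.diff(cat.onsets) > 0)
        assert np.all(cat.onsets[1:] >= cat.offsets[:-1])
        assert cat.offsets[-1] <= p.duration_s

    def test_seed_determinism(self):
        p = SimParams(seed=42)
        a = simulate_seizure_times(p)
        b = simulate_seizure_times(p)
        np.testing.assert_array_equal(a.onsets, b.onsets)


def _mid_catalog(duration_s, n=4):
    onsets = np.linspace(0.2, 0.8, n) * duration_s
    return SeizureCatalog(onsets, onsets + 60.0)


class TestPibFeatures:
    def test_null_effect_distributions_match(self):
        """With effect=1, pre-ictal and inter-ictal features are identically
        distributed: a two-sample test rejects at alpha=0.01 in few seeds."""
        from pibcast.labeling_cv import label_blocks
        rejections = 0
        for seed in range(20):
            p = SimParams(duration_s=4 * 86400.0, seed=seed)
            cat = _mid_catalog(p.duration_s)
            fm = simulate_pib_features(int(p.duration_s // 60), cat, p)
            label_blocks(fm, cat)
            x = np.log10(fm.X[fm.labels == 1, 2])
            y = np.log10(fm.X[fm.labels == 0, 2])
            if stats.ks_2samp(x, y).pvalue < 0.01:
                rejections += 1
        assert rejections <= 2

    def test_effect_shifts_log_mean(self):
        from pibcast.labeling_cv import label_blocks
        p = SimParams(duration_s=6 * 86400.0, effect={"ch1_alpha": 4.0}, seed=1)
        cat = _mid_catalog(p.duration_s, n=6)
        fm = simulate_pib_features(int(p.duration_s // 60), cat, p)
        label_blocks(fm, cat)
        col = fm.feature_names.index("ch1_alpha")
        pre = np.log10(fm.X[fm.labels == 1, col])
        inter = np.log10(fm.X[fm.labels == 0, col])
        shift = pre.mean() - inter.mean()
        ci = 3 * p.log10_pib_sd / np.sqrt(len(pre))
        assert abs(shift - np.log10(4.0)) < ci
        # untouched feature shows no shift
        other = fm.feature_names.index("ch2_beta")
        assert abs(np.log10(fm.X[fm.labels == 1, other]).mean()
                   - np.log10(fm.X[fm.labels == 0, other]).mean()) < ci

    def test_linear_ramp_grows_toward_onset(self):
        p = SimParams(duration_s=2 * 86400.0, effect={"ch1_alpha": 10.0},
                      ramp="linear", log10_pib_sd=0.01, seed=2)
        cat = _mid_catalog(p.duration_s, n=1)
        fm = simulate_pib_features(int(p.duration_s // 60), cat, p)
        col = fm.feature_names.index("ch1_alpha")
        on = cat.onsets[0]
        win = (fm.block_start_s >= on - p.preictal_len_s) & (fm.block_start_s < on)
        vals = np.log10(fm.X[win, col])
        # early window < late window, by about the full shift
        assert vals[-5:].mean() - vals[:5].mean() > 0.8 * np.log10(10.0)

    def test_zero_blocks_empty(self):
        fm = simulate_pib_features(0, _mid_catalog(86400.0), SimParams())
        assert fm.X.shape[0] == 0

    def test_unknown_effect_feature_rejected(self):
        p = SimParams(effect={"ch9_alpha": 2.0}, n_channels=2)
        with pytest.raises(ValueError, match="unknown feature"):
            simulate_pib_features(100, _mid_catalog(86400.0), p)

    def test_gap_fraction_block_level(self):
        p = SimParams(duration_s=4 * 86400.0, gap_fraction=0.2, seed=5)
        fm = simulate_pib_features(int(p.duration_s // 60), _mid_catalog(p.duration_s), p)
        frac = 1.0 - fm.valid.mean()
        assert frac == pytest.approx(0.2, abs=0.01)
        assert np.isnan(fm.X[~fm.valid]).all()

    def test_seed_determinism(self):
        p = SimParams(duration_s=86400.0, seed=9)
        cat = _mid_catalog(p.duration_s)
        a = simulate_pib_features(1440, cat, p)
        b = simulate_pib_features(1440, cat, p)
        np.testing.assert_array_equal(a.X, b.X)


class TestRawIEEG:
    def test_gap_fraction_counted(self):
        p = SimParams(duration_s=1200.0, n_channels=2, gap_fraction=0.2,
                      gap_mean_len_s=30.0, seed=1)
        rec = simulate_raw_ieeg(SeizureCatalog(np.array([]), np.array([])), p)
        assert 1.0 - rec.valid_mask.mean() == pytest.approx(0.2, abs=0.01)

    def test_memory_budget_enforced(self):
        p = SimParams(duration_s=90 * 86400.0, n_channels=16)
        with pytest.raises(ValueError, match="simulate_pib_features"):
            simulate_raw_ieeg(SeizureCatalog(np.array([]), np.array([])), p)

    def test_white_noise_pib_proportional_to_bandwidth(self):
        p = SimParams(duration_s=600.0, n_channels=4, alpha_slope=0.0,
                      oscillations=[], seed=2)
        rec = simulate_raw_ieeg(SeizureCatalog(np.array([]), np.array([])), p)
        fm = extract_features(rec, RunConfig())
        share = fm.X.reshape(-1, 6)
        share = (share / share.sum(axis=1, keepdims=True)).mean(axis=0)
        from pibcast.features import DEFAULT_BANDS
        widths = np.array([b.hi_hz - b.lo_hz for b in DEFAULT_BANDS]) / 179.9
        np.testing.assert_allclose(share, widths, rtol=0.1)

    def test_preictal_alpha_power_ratio(self):
        """effect=4 on ch1_alpha: extracted alpha PIB in pre-ictal blocks
        rises by the configured gain, attenuated by the average reference.
        For 4 iid channels the referenced ch1 signal is (3/4)x1 - rest/4,
        so the predicted pre/inter power ratio is (9*4+3)/(9+3) = 3.25."""
        from pibcast.labeling_cv import label_blocks
        p = SimParams(duration_s=4 * 3600.0, n_channels=4, seed=3,
                      effect={"ch1_alpha": 4.0}, oscillations=[(10.0, 2.0, 3.0)])
        on = np.array([3.5 * 3600.0])
        cat = SeizureCatalog(on, on + 60.0)
        rec = simulate_raw_ieeg(cat, p)
        fm = extract_features(rec, RunConfig())
        label_blocks(fm, cat, p.preictal_len_s)
        col = fm.feature_names.index("ch1_alpha")
        ratio = (fm.X[fm.labels == 1, col].mean()
                 / fm.X[fm.labels == 0, col].mean())
        assert ratio == pytest.approx(39 / 12, rel=0.2)

    def test_seed_determinism(self):
        p = SimParams(duration_s=300.0, n_channels=2, seed=11)
        cat = SeizureCatalog(np.array([]), np.array([]))
        a = simulate_raw_ieeg(cat, p)
        b = simulate_raw_ieeg(cat, p)
        np.testing.assert_array_equal(a.samples, b.samples)
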