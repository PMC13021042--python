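"""Signed offsets, bias statistics, ambivalent-probe analysis, precision, power."""

import numpy as np
import pandas as pd
import pytest
from statsmodels.stats.power import TTestPower

from wmbias import analysis as a
from wmbias import simulate as s
from wmbias.exceptions import InsufficientDataError, InvalidParameterError


class TestSignedOffsets:
    @pytest.mark.parametrize(
        "response, s_m, s_p, expected",
        [(10, 0, 40, 10), (10, 0, -40, -10), (0, 0, 40, 0), (350, 0, 40, -10)],
    )
    def test_sign_is_toward_probe(self, response, s_m, s_p, expected):
        assert a.signed_offset_exp1(response, s_m, s_p) == pytest.approx(expected)

    def test_reference_flip_negates(self):
        v1 = a.signed_offset_exp2(12, 0, 40)
        v2 = a.signed_offset_exp2(12, 0, -40)
        assert v1 == -v2

    def test_degenerate_probe_randomizes_sign_keeping_magnitude(self, rng):
        with pytest.warns(UserWarning):
            vals = a.signed_offset_exp1(
                np.full(500, 10.0), np.zeros(500), np.zeros(500), rng=rng
            )
        assert np.all(np.abs(vals) == 10.0)
        assert 0.4 < np.mean(vals > 0) < 0.6

    def test_baseline_signing_preserves_magnitudes(self):
        rng = np.random.default_rng(2)
        offs = np.array([3.0, -7.0, 12.0, 0.5])
        signed = a.assign_baseline_signs(offs, rng)
        assert np.array_equal(np.abs(signed), np.abs(offs))
        rng2 = np.random.default_rng(2)
        assert np.array_equal(signed, a.assign_baseline_signs(offs, rng2))


class TestHighConfidenceFilter:
    def _table(self):
        return pd.DataFrame(
            {
                "participant_id": [0, 0, 0, 1, 1, 1],
                "condition": ["x", "x", "y", "x", "y", "y"],
                "confidence": [1, 2, 1, 1, 3, 1],
                "offset": [1.0] * 6,
            }
        )

    def test_keeps_only_high_confidence(self):
        kept, retention = a.filter_high_confidence(self._table())
        assert (kept["confidence"] == 1).all()
        assert len(kept) == 4
        row = retention[
            (retention["participant_id"] == 0) & (retention["condition"] == "x")
        ].iloc[0]
        assert row["fraction"] == pytest.approx(0.5)

    def test_all_high_confidence_is_identity(self):
        t = self._table().assign(confidence=1)
        kept, retention = a.filter_high_confidence(t)
        assert len(kept) == len(t)
        assert (retention["fraction"] == 1.0).all()

    def test_empty_cells_flagged(self):
        t = self._table().assign(confidence=2)
        with pytest.warns(UserWarning):
            kept, _ = a.filter_high_confidence(t)
        assert len(kept) == 0


class TestBiasMagnitude:
    def test_constant_offsets(self):
        t = pd.DataFrame(
            {
                "participant_id": np.repeat(np.arange(3), 4),
                "condition": "c",
                "offset": 5.0,
            }
        )
        out = a.bias_magnitude(t)
        row = out.group.iloc[0]
        assert row["mean"] == pytest.approx(5.0)
        assert row["sd"] == pytest.approx(0.0)

    def test_antisymmetric_offsets_cancel(self):
        t = pd.DataFrame(
            {
                "participant_id": np.repeat(np.arange(4), 2),
                "condition": "c",
                "offset": [3, -3, 8, -8, 1, -1, 4, -4],
            }
        )
        assert a.bias_magnitude(t).group.iloc[0]["mean"] == pytest.approx(0.0)

    def test_statistics_match_brute_force(self, rng):
        means = rng.normal(4, 2, size=12)
        t = pd.DataFrame(
            {"participant_id": np.arange(12), "condition": "c", "offset": means}
        )
        row = a.bias_magnitude(t).group.iloc[0]
        assert row["cohens_d"] == pytest.approx(means.mean() / means.std(ddof=1))
        assert row["t"] == pytest.approx(
            means.mean() / (means.std(ddof=1) / np.sqrt(12))
        )
        assert row["df"] == 11

    def test_single_participant_rejected(self):
        t = pd.DataFrame({"participant_id": [0], "condition": "c", "offset": [1.0]})
        with pytest.raises(InsufficientDataError):
            a.bias_magnitude(t)

    def test_paired_contrast_on_construction(self):
        t = pd.DataFrame(
            {
                "participant_id": list(range(5)) * 2,
                "condition": ["a"] * 5 + ["b"] * 5,
                "offset": [6, 7, 8, 9, 10] + [1, 2, 3, 4, 5],
            }
        )
        res = a.paired_contrast(a.bias_magnitude(t), "a", "b")
        assert res["mean"] == pytest.approx(5.0)
        assert res["sd"] == pytest.approx(0.0)


class TestAmbivalentAnalysis:
    def test_constructed_difference(self):
        rows = []
        for pid in range(3):
            for bin_center in (20, 40, 60):
                for judgment, off in (("similar", 8.0), ("dissimilar", 2.0)):
                    rows.append(
                        {
                            "participant_id": pid,
                            "probe_distance": bin_center,
                            "judgment": judgment,
                            "offset": off,
                        }
                    )
        res = a.ambivalent_probe_analysis(pd.DataFrame(rows))
        assert np.allclose(res.per_participant["difference"], 6.0)
        assert res.excluded == []

    def test_participant_without_shared_bins_excluded(self):
        rows = [
            {"participant_id": 0, "probe_distance": 20, "judgment": "similar", "offset": 5},
            {"participant_id": 0, "probe_distance": 90, "judgment": "dissimilar", "offset": 1},
        ]
        with pytest.warns(UserWarning):
            res = a.ambivalent_probe_analysis(pd.DataFrame(rows))
        assert res.excluded == [0]
        assert len(res.per_participant) == 0

    def test_joint_observer_shows_positive_difference(self):
        table = s.generate_dataset(s.exp1_design(), [s.ObserverSpec()] * 4, seed=11)
        off = a.compute_offsets(table, seed=1)
        hc, _ = a.filter_high_confidence(off)
        res = a.ambivalent_probe_analysis(hc[hc["condition"] == "comparison"])
        assert res.per_participant["difference"].mean() > 0


class TestDistanceBins:
    def test_endpoints_and_partition(self):
        assert a.discretize_probe_distance([16.0])[0] == 1
        assert a.discretize_probe_distance([105.0])[0] == 18
        d = np.linspace(16, 105, 500)
        bins = a.discretize_probe_distance(d)
        assert bins.min() == 1 and bins.max() == 18
        assert len(bins) == 500
        # equal-width bins: counts roughly uniform for uniform input
        counts = np.bincount(bins)[1:]
        assert counts.max() - counts.min() <= 3

    def test_out_of_range_rejected(self):
        with pytest.raises(InvalidParameterError):
            a.discretize_probe_distance([10.0])


class TestPrecisionEstimate:
    def test_recovers_generating_concentration(self):
        rng = np.random.default_rng(8)
        offs = np.rad2deg(rng.vonmises(0.0, 12.0, size=10_000))
        est = a.estimate_precision(offs)
        assert est.kappa == pytest.approx(12.0, rel=0.05)

    def test_sign_flip_invariance(self, rng):
        offs = np.rad2deg(rng.vonmises(0.0, 6.0, size=500))
        assert a.estimate_precision(offs).kappa == pytest.approx(
            a.estimate_precision(-offs).kappa
        )

    def test_degenerate_offsets_capped(self):
        est = a.estimate_precision(np.zeros(100))
        assert est.capped and est.kappa == a.KAPPA_CAP

    def test_wider_spread_gives_smaller_kappa(self, rng):
        tight = np.rad2deg(rng.vonmises(0.0, 20.0, size=2000))
        wide = np.rad2deg(rng.vonmises(0.0, 2.0, size=2000))
        assert a.estimate_precision(wide).kappa < a.estimate_precision(tight).kappa


class TestPrecisionBiasCorrelation:
    def test_perfect_anticorrelation(self):
        x = np.arange(10.0)
        res = a.precision_bias_correlation(x, -x)
        assert res.r == pytest.approx(-1.0)
        assert res.df == 8

    def test_outlier_exclusion_reported_both_ways(self, rng):
        x = rng.normal(10, 1, 40)
        y = -x + rng.normal(0, 0.3, 40)
        x[0] = 60.0  # gross outlier in precision
        res = a.precision_bias_correlation(x, y, ids=np.arange(40))
        assert 0 in res.excluded_ids
        assert res.df == 37 and res.df_all == 38
        assert res.r < 0 and res.r_all != res.r

    def test_too_few_pairs_rejected(self):
        with pytest.raises(InsufficientDataError):
            a.precision_bias_correlation([1, 2, 3], [3, 2, 1])


class TestDistributions:
    def test_offset_distribution_normalized_and_centered(self, rng):
        offs = np.rad2deg(rng.vonmises(np.deg2rad(10), 8.0, size=5000))
        dist = a.offset_distribution(offs)
        assert dist["proportion"].sum() == pytest.approx(1.0)
        peak = dist.loc[dist["proportion"].idxmax(), "offset"]
        assert abs(peak - 10) < 10

    def test_within_subject_sem_ignores_participant_offsets(self, rng):
        wide = pd.DataFrame(rng.normal(0, 1, size=(20, 3)), columns=list("abc"))
        shifted = wide.add(rng.normal(0, 5, size=20), axis=0)
        assert np.allclose(
            a.within_subject_sem(wide), a.within_subject_sem(shifted), atol=1e-12
        )


class TestPowerCalculators:
    @pytest.mark.parametrize(
        "d, power, expected", [(0.8, 0.8, 15), (0.73, 0.9, 22), (0.5, 0.8, 34)]
    )
    def test_one_sample_t_matches_reference_implementation(self, d, power, expected):
        n = a.required_n_one_sample_t(d, power=power)
        assert n == expected
        # independent check against statsmodels' noncentral-t power
        ref = TTestPower()
        assert ref.power(effect_size=d, nobs=n, alpha=0.05) >= power
        assert ref.power(effect_size=d, nobs=n - 1, alpha=0.05) < power

    @pytest.mark.parametrize("rho, power, expected", [(0.32, 0.9, 99), (0.5, 0.8, 30)])
    def test_correlation_minimum_is_tight(self, rho, power, expected):
        n = a.required_n_correlation(rho, power=power)
        assert n == expected
        # boundary property: n meets the target, n-1 does not
        from scipy import stats

        z = abs(np.arctanh(rho))
        crit = stats.norm.ppf(0.975)
        assert stats.norm.cdf(z * np.sqrt(n - 3) - crit) >= power
        assert stats.norm.cdf(z * np.sqrt(n - 4) - crit) < power

    def test_invalid_requests_rejected(self):
        with pytest.raises(InvalidParameterError):
            a.required_n_one_sample_t(-0.5)
        with pytest.raises(InvalidParameterError):
            a.required_n_correlation(1.5)
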