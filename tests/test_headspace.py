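"""Air-contamination correction and anchor-ratio properties."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

import rumengas as rg
from rumengas.headspace import DegenerateSampleError, _cyclic_trapezoid_mean


def _sample(co2, ch4, n2o, n2=0.0, o2=0.0, time=1.0, day=1):
    return pd.DataFrame([{
        "cow_id": "cow1", "period": 1, "day": day, "time_rel_feeding": time,
        "co2": co2, "ch4": ch4, "n2o": n2o, "n2": n2, "o2": o2,
    }])


def _truth_frame(triplets, times=None):
    rows = []
    for i, (co2, ch4, n2o) in enumerate(triplets):
        rows.append({"cow_id": "cow1", "period": 1, "day": 1,
                     "time_rel_feeding": float(i if times is None else times[i]),
                     "co2": co2, "ch4": ch4, "n2o": n2o})
    return rg.CORRECTED_HEADSPACE.validate(pd.DataFrame(rows))


class TestCorrection:
    def test_hand_worked_contaminated_sample(self):
        out = rg.correct_air_contamination(_sample(60.0, 15.0, 0.006, 20.0, 4.994))
        # divide by the three-gas sum 75.006 and scale to 100
        assert out.loc[0, "co2"] == pytest.approx(60.0 / 75.006 * 100, rel=1e-9)
        assert out.loc[0, "ch4"] == pytest.approx(15.0 / 75.006 * 100, rel=1e-9)
        assert out.loc[0, "n2o"] == pytest.approx(0.00800, abs=5e-6)

    def test_clean_sample_unchanged(self):
        out = rg.correct_air_contamination(_sample(79.5, 20.495, 0.005))
        np.testing.assert_allclose(out[["co2", "ch4", "n2o"]].iloc[0],
                                   [79.5, 20.495, 0.005], rtol=1e-12)

    def test_output_sums_to_100(self, study):
        out = rg.correct_air_contamination(study["headspace"])
        np.testing.assert_allclose(out[["co2", "ch4", "n2o"]].sum(axis=1),
                                   100.0, atol=1e-9)

    def test_idempotent(self, study):
        once = rg.correct_air_contamination(study["headspace"])
        twice = rg.correct_air_contamination(once)
        pd.testing.assert_frame_equal(once, twice)

    @given(
        co2=st.floats(30, 90), ch4=st.floats(5, 30),
        n2o=st.floats(1e-4, 0.05), f=st.floats(0, 0.9),
    )
    def test_dilution_invariance(self, co2, ch4, n2o, f):
        """Correcting a diluted sample equals correcting the undiluted one."""
        total = co2 + ch4 + n2o
        truth = _truth_frame([(co2 / total * 100, ch4 / total * 100,
                               n2o / total * 100)])
        air = {"co2": 0.0, "ch4": 0.0, "n2o": 0.0, "n2": 79.05, "o2": 20.95}
        diluted = rg.dilute_with_air(truth, f, air=air)
        a = rg.correct_air_contamination(diluted)
        b = rg.correct_air_contamination(rg.dilute_with_air(truth, 0.0, air=air))
        np.testing.assert_allclose(a[["co2", "ch4", "n2o"]].to_numpy(),
                                   b[["co2", "ch4", "n2o"]].to_numpy(), atol=1e-9)

    def test_atmospheric_co2_bias_is_small(self):
        # with real air (0.04 vol% CO2) the invariance is approximate;
        # the bias stays below 0.1% of the rumen CO2 proportion at f = 0.5
        truth = _truth_frame([(79.5, 20.49, 0.01)])
        diluted = rg.dilute_with_air(truth, 0.5)
        out = rg.correct_air_contamination(diluted)
        assert abs(out.loc[0, "co2"] - 79.5) / 79.5 < 1e-3

    def test_negative_fraction_rejected(self):
        with pytest.raises(ValueError, match="negative"):
            rg.correct_air_contamination(_sample(-1.0, 20.0, 0.005))

    def test_degenerate_sample_rejected(self):
        with pytest.raises(DegenerateSampleError):
            rg.correct_air_contamination(_sample(0.0, 0.0, 0.0, 79.0, 21.0))


class TestAnchorRatio:
    def test_single_sample_hand_value(self):
        corrected = _truth_frame([(81.292, 18.7, 0.008)])
        for method in ("per-sample-mean", "ratio-of-means", "time-weighted"):
            ar = rg.anchor_ratio(corrected, method=method)
            assert ar.ratio == pytest.approx(0.008 / 18.7, rel=1e-12)
        assert ar.ratio == pytest.approx(4.278e-4, rel=1e-3)

    def test_constant_samples_all_methods_agree(self):
        corrected = _truth_frame([(80.0, 19.99, 0.01)] * 5)
        ratios = {m: rg.anchor_ratio(corrected, method=m).ratio
                  for m in ("per-sample-mean", "ratio-of-means", "time-weighted")}
        assert len({round(r, 15) for r in ratios.values()}) == 1

    def test_equal_spacing_per_sample_mean(self):
        # two samples with ratios 2e-4 and 6e-4 -> arithmetic mean 4e-4
        corrected = _truth_frame(
            [(80.0 - 0.004, 20.0, 20.0 * 2e-4), (80.0 - 0.012, 20.0, 20.0 * 6e-4)],
            times=[0.0, 12.0])
        ar = rg.anchor_ratio(corrected, method="per-sample-mean")
        assert ar.ratio == pytest.approx(4e-4, rel=1e-12)
        # equal cyclic spacing: the time-weighted mean agrees
        tw = rg.anchor_ratio(corrected, method="time-weighted")
        assert tw.ratio == pytest.approx(4e-4, rel=1e-12)

    @given(st.lists(st.tuples(st.floats(5, 30), st.floats(1e-4, 0.05)),
                    min_size=2, max_size=10))
    def test_ratio_within_per_sample_bounds(self, pairs):
        triplets = [(100 - ch4 - n2o, ch4, n2o) for ch4, n2o in pairs]
        corrected = _truth_frame(triplets, times=np.linspace(0, 20, len(pairs)))
        per_sample = corrected["n2o"] / corrected["ch4"]
        lo, hi = per_sample.min(), per_sample.max()
        for m in ("per-sample-mean", "ratio-of-means", "time-weighted"):
            r = rg.anchor_ratio(corrected, method=m).ratio
            assert lo - 1e-12 <= r <= hi + 1e-12

    def test_zero_ch4_is_degenerate(self):
        corrected = _truth_frame([(99.99, 0.0, 0.01)])
        with pytest.raises(DegenerateSampleError):
            rg.anchor_ratio(corrected)

    def test_front_loaded_schedule_weighting(self):
        # high ratio only in the densely sampled post-feeding window: the
        # unweighted mean overstates the time-weighted daily average
        times = list(rg.HEADSPACE_TIMES)
        triplets = []
        for t in times:
            ratio = 6e-4 if t < 4 else 2e-4
            triplets.append((100 - 20 - 20 * ratio, 20.0, 20.0 * ratio))
        corrected = _truth_frame(triplets, times=times)
        tw = rg.anchor_ratio(corrected, method="time-weighted").ratio
        psm = rg.anchor_ratio(corrected, method="per-sample-mean").ratio
        assert tw < psm

    def test_cyclic_trapezoid_constant_is_exact(self):
        t = np.array(rg.HEADSPACE_TIMES)
        assert _cyclic_trapezoid_mean(t, np.full(t.size, 3.3)) == pytest.approx(3.3)

    def test_multiple_cows_rejected(self, study):
        corrected = rg.correct_air_contamination(study["headspace"])
        with pytest.raises(ValueError, match="single cow"):
            rg.anchor_ratio(corrected)

    def test_ratios_table_covers_all_cow_periods(self, study):
        corrected = rg.correct_air_contamination(study["headspace"])
        tbl = rg.anchor_ratios(corrected)
        assert len(tbl) == 8  # 4 cows x 2 periods
        assert (tbl["n_samples"] == 32).all()


class TestDiurnalProfile:
    def test_constant_input_flat_profile_zero_se(self):
        triplets = [(80.0, 19.99, 0.01)] * 4
        corrected = pd.concat([
            _truth_frame(triplets, times=[0, 6, 12, 18]).assign(cow_id=c)
            for c in ("cow1", "cow2")
        ])
        prof = rg.diurnal_profile(corrected, "ch4")
        assert prof["mean"].nunique() == 1
        np.testing.assert_allclose(prof["se"], 0.0, atol=1e-12)

    def test_balanced_profile_equals_simple_means(self, study, small_params):
        corrected = rg.correct_air_contamination(study["headspace"])
        trt = study["summaries"][["cow_id", "period", "treatment"]]
        prof = rg.diurnal_profile(corrected, "ch4", treatments=trt)
        merged = corrected.merge(trt, on=["cow_id", "period"])
        simple = merged.groupby(["treatment", "time_rel_feeding"])["ch4"].mean()
        for _, r in prof.iterrows():
            assert r["mean"] == pytest.approx(
                simple.loc[(r["treatment"], r["time_rel_feeding"])], rel=1e-12)

    def test_peak_at_first_post_feeding_point(self, noise_free_params, config):
        raw = rg.generate_headspace(noise_free_params, config)
        corrected = rg.correct_air_contamination(raw)
        prof = rg.diurnal_profile(corrected, "ch4")
        assert prof.loc[prof["mean"].idxmax(), "time_rel_feeding"] == pytest.approx(
            min(rg.HEADSPACE_TIMES))

    def test_log_profile_backtransform(self, study):
        corrected = rg.correct_air_contamination(study["headspace"])
        prof = rg.diurnal_profile(corrected, "n2o", transform="log")
        np.testing.assert_allclose(prof["backtransformed_mean"],
                                   np.exp(prof["mean"]), rtol=1e-12)
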