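"""Per-condition aggregation, control normalization and the 5% MIC rule."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

import crystalscreen as cs
from crystalscreen.quantification import NormalizationError


def _crystal_rows(experiment="E1", compound="IP6", conc=0.0, well="w1",
                  areas_by_class=None, n_fields=1):
    rows = []
    for cls, areas in (areas_by_class or {}).items():
        for i, area in enumerate(areas):
            rows.append({
                "experiment_id": experiment, "compound": compound,
                "concentration_nm": conc, "well_id": well,
                "field_index": 1 + i % n_fields, "area": area, "label": cls,
            })
    return rows


def _series(concs, totals, coms=None):
    return pd.DataFrame({
        "concentration_nm": concs,
        "mean_normalized_total": totals,
        "mean_normalized_com": coms if coms is not None else totals,
    })


class TestQuantifyWells:
    def test_simple_sum_and_count(self):
        crystals = pd.DataFrame(_crystal_rows(areas_by_class={0: [50.0] * 3}))
        wells = cs.quantify_wells(crystals)
        assert wells["total_area_COM"].iloc[0] == 150.0
        assert wells["count_COM"].iloc[0] == 3

    def test_noise_excluded_from_crystal_total(self):
        crystals = pd.DataFrame(_crystal_rows(areas_by_class={3: [10.0, 20.0]}))
        wells = cs.quantify_wells(crystals)
        assert wells["total_area_crystal"].iloc[0] == 0.0
        assert wells["total_area_noise"].iloc[0] == 30.0

    def test_crystal_total_is_sum_of_three_classes(self):
        rng = np.random.default_rng(0)
        crystals = pd.DataFrame(_crystal_rows(areas_by_class={
            c: list(rng.uniform(1, 50, 10)) for c in range(4)}))
        wells = cs.quantify_wells(crystals)
        row = wells.iloc[0]
        assert row["total_area_crystal"] == (
            row["total_area_COM"] + row["total_area_COD"] + row["total_area_nd"])

    def test_unlabeled_segment_rejected(self):
        crystals = pd.DataFrame(_crystal_rows(areas_by_class={0: [1.0]}))
        crystals.loc[0, "label"] = np.nan
        with pytest.raises(ValueError, match="unlabeled"):
            cs.quantify_wells(crystals)


class TestNormalizeToControl:
    def _wells(self, control_total=100.0, sample_total=5.0):
        rows = []
        for conc, total in [(0.0, control_total), (1000.0, sample_total)]:
            rows.append({
                "experiment_id": "E1", "compound": "IP6", "concentration_nm": conc,
                "total_area_COM": total * 0.6, "total_area_COD": total * 0.3,
                "total_area_nd": total * 0.1, "total_area_noise": 1.0,
                "total_area_crystal": total, "n_fields": 10,
            })
        return pd.DataFrame(rows)

    def test_control_normalizes_to_100(self):
        out = cs.normalize_to_control(self._wells())
        assert out.loc[out["concentration_nm"] == 0, "normalized_total"].iloc[0] == 100.0

    def test_sample_fraction_of_control(self):
        out = cs.normalize_to_control(self._wells(100.0, 5.0))
        assert out.loc[out["concentration_nm"] > 0, "normalized_total"].iloc[0] == 5.0

    def test_scale_invariance_within_experiment(self):
        a = cs.normalize_to_control(self._wells(100.0, 20.0))
        wells_scaled = self._wells(100.0, 20.0)
        cols = [c for c in wells_scaled.columns if c.startswith("total_area")]
        wells_scaled[cols] *= 7.3
        b = cs.normalize_to_control(wells_scaled)
        pd.testing.assert_series_equal(a["normalized_total"], b["normalized_total"])

    def test_two_experiments_with_equal_ratios_normalize_identically(self):
        w1 = self._wells(100.0, 5.0)
        w2 = self._wells(400.0, 20.0)
        w2["experiment_id"] = "E2"
        out = cs.normalize_to_control(pd.concat([w1, w2], ignore_index=True))
        by_exp = out.pivot(index="concentration_nm", columns="experiment_id",
                           values="normalized_total")
        np.testing.assert_allclose(by_exp["E1"], by_exp["E2"])

    def test_missing_control_raises(self):
        wells = self._wells()
        wells = wells[wells["concentration_nm"] > 0]
        with pytest.raises(NormalizationError, match="control"):
            cs.normalize_to_control(wells)

    def test_zero_control_raises(self):
        wells = self._wells(control_total=0.0)
        with pytest.raises(NormalizationError, match="zero"):
            cs.normalize_to_control(wells)


class TestMIC:
    def test_threshold_crossing_on_grid(self):
        series = _series([100, 300, 1000, 3000], [80.0, 30.0, 4.0, 1.0])
        assert cs.min_inhibitory_concentration(series) == 1000.0

    def test_never_inhibited_returns_sentinel(self):
        series = _series([100, 300, 3000], [80.0, 30.0, 10.0])
        assert cs.min_inhibitory_concentration(series) is None

    def test_exactly_five_percent_is_not_inhibition(self):
        series = _series([100, 300], [5.0, 5.0])
        assert cs.min_inhibitory_concentration(series) is None

    def test_empty_series_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            cs.min_inhibitory_concentration(_series([], []))

    def test_unsorted_series_rejected(self):
        with pytest.raises(ValueError, match="ascending"):
            cs.min_inhibitory_concentration(_series([300, 100], [1.0, 1.0]))

    @settings(derandomize=True, max_examples=50)
    @given(st.lists(st.floats(0.0, 200.0), min_size=1, max_size=8),
           st.integers(0, 7))
    def test_lowering_any_mean_never_raises_the_mic(self, means, idx):
        """Pointwise improvement of inhibition cannot worsen the MIC."""
        concs = [10.0 * 3**i for i in range(len(means))]
        before = cs.min_inhibitory_concentration(_series(concs, means))
        lowered = list(means)
        lowered[idx % len(means)] *= 0.5
        after = cs.min_inhibitory_concentration(_series(concs, lowered))
        if before is not None:
            assert after is not None and after <= before

    def test_sentinel_rendering_matches_reporting_convention(self):
        res = cs.InhibitionResult(
            compound="x", concentrations_nm=(1e5,), mean_normalized_total=(50.0,),
            mean_normalized_com=(50.0,), mic_complete_nm=None, mic_com_nm=4e4)
        assert res.render_mic("complete") == ">100 µM"
        assert res.render_mic("com") == "40 µM"


class TestDoseResponse:
    def _normalized(self):
        rows = []
        for exp, scale in [("E1", 1.0), ("E2", 1.1)]:
            for conc, total, com in [(0.0, 100.0, 60.0), (100.0, 80.0, 40.0),
                                     (300.0, 30.0, 3.0), (1000.0, 4.0, 0.5)]:
                rows.append({
                    "experiment_id": exp, "compound": "control" if conc == 0 else "IP6",
                    "concentration_nm": conc,
                    "normalized_total": total * scale, "normalized_COM": com * scale,
                    "total_area_COM": com * scale, "total_area_crystal": total * scale,
                })
        return pd.DataFrame(rows)

    def test_mic_com_not_above_mic_complete(self):
        res = cs.dose_response(self._normalized())[0]
        assert res.mic_com_nm is not None
        assert res.mic_complete_nm is not None
        assert res.mic_complete_nm >= res.mic_com_nm

    def test_complete_mic_uses_mean_across_experiments(self):
        res = cs.dose_response(self._normalized())[0]
        assert res.mic_complete_nm == 1000.0
        assert res.mic_com_nm == 300.0


class TestSizeDistribution:
    def test_equal_areas_have_zero_iqr(self):
        crystals = pd.DataFrame(_crystal_rows(areas_by_class={0: [25.0] * 8}))
        dist = cs.com_size_distribution(crystals)
        assert dist["q75"].iloc[0] - dist["q25"].iloc[0] == 0.0

    def test_pooled_count_matches_com_count(self):
        crystals = pd.DataFrame(
            _crystal_rows(areas_by_class={0: [10.0] * 7, 1: [99.0] * 3}))
        dist = cs.com_size_distribution(crystals)
        assert dist["n"].iloc[0] == 7

    def test_median_area_decreases_with_dose_on_shrinking_series(self):
        """A COM-size-scaling dose series shows shrinking median COM area."""
        rng = np.random.default_rng(0)
        rows = []
        for conc, scale in [(0.0, 1.0), (300.0, 0.8), (1000.0, 0.55)]:
            areas = 40.0 * scale**2 * rng.lognormal(0, 0.15, 120)
            rows += _crystal_rows(conc=conc, areas_by_class={0: list(areas)})
        dist = cs.com_size_distribution(pd.DataFrame(rows)).sort_values(
            "concentration_nm")
        medians = dist["median"].tolist()
        assert medians[0] > medians[1] > medians[2]
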