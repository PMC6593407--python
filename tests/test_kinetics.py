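"""Translocation events, population fractions and CFU arithmetic."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from sporeloc import (
    KineticsConfig,
    cfp_only_fraction,
    counts_from_onsets,
    efficiency_of_transport,
    events_from_timelapse,
    per_cell_translocation_time,
    population_fractions,
    simulate_timelapse,
    sporulation_efficiency,
    translocation_time_distribution,
)
from sporeloc.detect import OnsetCall
from sporeloc.kinetics import CFP_ONLY_EXCLUDED, COMPLETE, YFP_ONLY_CENSORED


def call(cell_id, channel, t):
    if t is None:
        return OnsetCall(cell_id, channel, None, None)
    return OnsetCall(cell_id, channel, int(t // 2), float(t))


class TestPerCellEvents:
    def test_complete_pair_subtracts(self):
        e = per_cell_translocation_time(call(0, "YFP", 10.0), call(0, "CFP", 21.0))
        assert e.classification == COMPLETE
        assert e.delta_t == pytest.approx(11.0)

    def test_missing_cfp_is_censored(self):
        e = per_cell_translocation_time(call(0, "YFP", 10.0), call(0, "CFP", None))
        assert e.classification == YFP_ONLY_CENSORED and e.delta_t is None

    def test_cfp_without_yfp_is_excluded(self):
        e = per_cell_translocation_time(call(0, "YFP", None), call(0, "CFP", 8.0))
        assert e.classification == CFP_ONLY_EXCLUDED

    def test_cfp_before_yfp_is_excluded(self):
        e = per_cell_translocation_time(call(0, "YFP", 10.0), call(0, "CFP", 6.0))
        assert e.classification == CFP_ONLY_EXCLUDED

    def test_both_censored_drops_the_cell(self):
        assert per_cell_translocation_time(call(0, "YFP", None), call(0, "CFP", None)) is None


class TestDistribution:
    def _events(self, deltas):
        return [
            per_cell_translocation_time(call(i, "YFP", 10.0), call(i, "CFP", 10.0 + d))
            for i, d in enumerate(deltas)
        ]

    def test_mean_of_three(self):
        s = translocation_time_distribution(self._events([9.0, 11.0, 13.0]))
        assert s.mean_min == pytest.approx(11.0) and s.n == 3

    def test_single_event_single_full_bin(self):
        s = translocation_time_distribution(self._events([19.0]), bin_width=2.0)
        assert s.mean_min == pytest.approx(19.0)
        assert s.fractions.max() == pytest.approx(1.0)
        assert s.fractions.sum() == pytest.approx(1.0)

    def test_no_complete_events_is_an_error(self):
        events = [per_cell_translocation_time(call(0, "YFP", 5.0), call(0, "CFP", None))]
        with pytest.raises(ValueError):
            translocation_time_distribution(events)

    def test_recovers_simulated_25min_mean(self):
        k = KineticsConfig(translocation_time=("normal", 25.0, 5.0))
        sim = simulate_timelapse(100, k, seed=6)
        s = translocation_time_distribution(
            [e for e in events_from_timelapse(sim) if e is not None]
        )
        assert abs(s.mean_min - 25.0) < 1.96 * 5.0 / np.sqrt(100) + k.frame_interval


class TestPopulationFractions:
    def test_single_field_ratio(self):
        counts = pd.DataFrame(
            [{"timepoint": 225, "field_id": 0, "n_yfp_pos": 100, "n_cfp_and_yfp": 50}]
        )
        out = population_fractions(counts)
        assert out["fraction_mean"].iloc[0] == pytest.approx(0.5)

    def test_sd_across_two_fields(self):
        counts = pd.DataFrame(
            [
                {"timepoint": 225, "field_id": 0, "n_yfp_pos": 10, "n_cfp_and_yfp": 4},
                {"timepoint": 225, "field_id": 1, "n_yfp_pos": 10, "n_cfp_and_yfp": 6},
            ]
        )
        out = population_fractions(counts)
        assert out["fraction_mean"].iloc[0] == pytest.approx(0.5)
        assert out["fraction_sd"].iloc[0] == pytest.approx(np.sqrt(0.02), abs=1e-6)

    def test_zero_yfp_field_excluded(self):
        counts = pd.DataFrame(
            [
                {"timepoint": 60, "field_id": 0, "n_yfp_pos": 0, "n_cfp_and_yfp": 0},
                {"timepoint": 60, "field_id": 1, "n_yfp_pos": 10, "n_cfp_and_yfp": 5},
            ]
        )
        out = population_fractions(counts)
        assert out["n_fields"].iloc[0] == 1

    def test_all_fields_zero_is_an_error(self):
        counts = pd.DataFrame(
            [{"timepoint": 60, "field_id": 0, "n_yfp_pos": 0, "n_cfp_and_yfp": 0}]
        )
        with pytest.raises(ValueError):
            population_fractions(counts)

    @settings(derandomize=True, max_examples=20)
    @given(st.integers(min_value=2, max_value=50))
    def test_fractions_invariant_under_scaling_counts(self, scale):
        base = pd.DataFrame(
            [
                {"timepoint": 225, "field_id": 0, "n_yfp_pos": 10, "n_cfp_and_yfp": 3},
                {"timepoint": 225, "field_id": 1, "n_yfp_pos": 20, "n_cfp_and_yfp": 11},
            ]
        )
        scaled = base.copy()
        scaled[["n_yfp_pos", "n_cfp_and_yfp"]] *= scale
        a, b = population_fractions(base), population_fractions(scaled)
        assert a["fraction_mean"].iloc[0] == pytest.approx(b["fraction_mean"].iloc[0])
        assert a["fraction_sd"].iloc[0] == pytest.approx(b["fraction_sd"].iloc[0])


class TestEfficiency:
    def test_ratio(self):
        r = efficiency_of_transport(0.45, 0.90)
        assert r.efficiency == pytest.approx(0.5)

    def test_identity(self):
        assert efficiency_of_transport(0.8, 0.8).efficiency == pytest.approx(1.0)

    def test_zero_wildtype_fraction_is_an_error(self):
        with pytest.raises(ValueError):
            efficiency_of_transport(0.5, 0.0)

    def test_fold_change_of_deficit(self):
        # 32% deficit vs a 5% reference deficit ~ 6.4-fold
        r = efficiency_of_transport(0.68, 1.0, reference_deficit=0.05)
        assert r.fold_change == pytest.approx(6.4)


class TestCfpOnly:
    def test_one_in_ten(self):
        assert cfp_only_fraction(1, 9) == pytest.approx(0.10)

    def test_none(self):
        assert cfp_only_fraction(0, 25) == 0.0

    def test_no_cfp_positive_is_an_error(self):
        with pytest.raises(ValueError):
            cfp_only_fraction(0, 0)

    def test_recovers_simulated_miscapture_probability(self):
        k = KineticsConfig(yfp_miss_prob=0.10, septation_time=("uniform", 20.0, 80.0))
        sim = simulate_timelapse(500, k, seed=30)
        events = [e for e in events_from_timelapse(sim) if e is not None]
        counts = counts_from_onsets(events, timepoints=[240.0], n_fields=1)
        row = counts.iloc[0]
        frac = cfp_only_fraction(int(row["n_cfp_only"]), int(row["n_cfp_and_yfp"]))
        ci = 1.96 * np.sqrt(0.1 * 0.9 / 500)
        assert abs(frac - 0.10) < ci + 0.01


class TestSporulationEfficiency:
    def _table(self, rows):
        return pd.DataFrame(rows, columns=["condition", "stage", "dilution", "colonies"])

    def test_fig_formula_arithmetic(self):
        cfu = self._table(
            [
                ("wild_type", "resuspension", 10, 100),  # 1000 CFU
                ("mutant", "post_heat_kill", 10, 30),  # 300 spores
            ]
        )
        r = sporulation_efficiency(cfu, "mutant")
        assert r.efficiency == pytest.approx(0.30)

    def test_zero_spores_gives_zero_efficiency(self):
        cfu = self._table(
            [
                ("wild_type", "resuspension", 10, 100),
                ("mutant", "post_heat_kill", 1, 0),
                ("mutant", "post_heat_kill", 10, 0),
            ]
        )
        assert sporulation_efficiency(cfu, "mutant").efficiency == 0.0

    def test_mean_and_sd_across_dilutions(self):
        cfu = self._table(
            [
                ("wild_type", "resuspension", 10, 100),
                ("mutant", "post_heat_kill", 1, 280),  # 28%
                ("mutant", "post_heat_kill", 10, 32),  # 32%
            ]
        )
        r = sporulation_efficiency(cfu, "mutant")
        assert r.efficiency == pytest.approx(0.30)
        assert r.sd == pytest.approx(np.std([0.28, 0.32], ddof=1), abs=1e-9)

    def test_no_countable_dilution_is_an_error(self):
        cfu = self._table(
            [
                ("wild_type", "resuspension", 10, 100),
                ("mutant", "post_heat_kill", 1, 5000),
            ]
        )
        with pytest.raises(ValueError):
            sporulation_efficiency(cfu, "mutant")


class TestOrderingAcrossMotorSpeeds:
    def test_slower_motors_never_increase_the_fraction(self):
        # stochastically larger translocation times -> lower CFP+/YFP+
        # fraction at every fixed timepoint (wild type > slow > slower)
        timepoints = np.arange(60.0, 200.0, 20.0)
        fractions = {}
        for label, mean_dt in (("wt", 11.0), ("slow", 19.0), ("slower", 25.0)):
            k = KineticsConfig(
                translocation_time=("normal", mean_dt, 3.0),
                septation_time=("normal", 60.0, 15.0),
            )
            sim = simulate_timelapse(300, k, seed=77)  # shared seed: common septation
            events = [e for e in events_from_timelapse(sim) if e is not None]
            counts = counts_from_onsets(events, timepoints, n_fields=3)
            out = population_fractions(counts).set_index("timepoint")
            fractions[label] = out["fraction_mean"]
        for t in timepoints:
            assert fractions["wt"][t] >= fractions["slow"][t] >= fractions["slower"][t]
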