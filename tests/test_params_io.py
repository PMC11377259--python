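"""Parameter derivation: probabilities from counts, derived utilities,
PSA distribution construction, and configuration validation."""
import math

import numpy as np
import pytest
import scipy.stats

from ceatree import evaluate_base_case
from ceatree.params_io import (
    ConfigError,
    CostEntry,
    ResponderCounts,
    UtilityEntry,
    build_distribution,
    conditional_probability,
    mbs_utility,
    model_config_from_dict,
    probabilities_table,
    residual_probability,
    utilities_table,
    export_tables,
)


class TestConditionalProbability:
    @pytest.mark.parametrize(
        "successes, failures, expected",
        [
            (132, 534, 0.1982),  # treatment pain freedom at 2 h
            (0, 50, 0.0),
            (7, 65, 0.0972),  # placebo pain freedom within 15 min
        ],
    )
    def test_matches_responder_proportion(self, successes, failures, expected):
        p = conditional_probability(ResponderCounts(successes, failures))
        assert round(p, 4) == expected

    def test_zero_total_names_the_endpoint(self):
        with pytest.raises(ConfigError, match="pf_2h"):
            ResponderCounts(0, 0, label="arms.treatment.pf_2h")

    def test_negative_counts_rejected(self):
        with pytest.raises(ConfigError):
            ResponderCounts(-1, 10)


class TestResidualProbability:
    def test_treatment_pf_residual_matches_count_complement(self):
        bins = [5 / 132, 2 / 132, 15 / 132, 23 / 132, 37 / 132]
        assert residual_probability(bins) == pytest.approx(50 / 132, abs=1e-12)

    def test_comparator_fmbs_residual_matches_count_complement(self):
        bins = [75 / 241, 25 / 241, 34 / 241, 33 / 241, 47 / 241]
        assert residual_probability(bins) == pytest.approx(27 / 241, abs=1e-12)

    def test_printed_values_residuals(self):
        # complements of the printed 4-d.p. conditional bins
        assert residual_probability([0.0379, 0.0152, 0.1136, 0.1742, 0.2803]) == (
            pytest.approx(0.3788, abs=1e-12)
        )
        assert residual_probability([0.3112, 0.1037, 0.1411, 0.1369, 0.1950]) == (
            pytest.approx(0.1121, abs=1e-12)
        )

    def test_empty_list_is_full_mass(self):
        assert residual_probability([]) == 1.0

    def test_excess_mass_rejected(self):
        with pytest.raises(ConfigError, match="sum"):
            residual_probability([0.7, 0.6])


class TestMbsUtility:
    @pytest.mark.parametrize(
        "pf, expected", [(0.7573, 0.658851), (0.0, 0.0), (0.5040, 0.438480)]
    )
    def test_factor_applied(self, pf, expected):
        assert mbs_utility(pf, 0.87) == pytest.approx(expected, abs=1e-12)

    @pytest.mark.parametrize("pf, factor", [(1.2, 0.87), (-0.1, 0.87), (0.5, 0.0), (0.5, 1.5)])
    def test_out_of_range_rejected(self, pf, factor):
        with pytest.raises(ConfigError):
            mbs_utility(pf, factor)


class TestBuildDistribution:
    def test_counts_become_beta_with_printed_shapes(self):
        d = build_distribution(ResponderCounts(132, 534))
        assert (d.family, d.a, d.b) == ("beta", 132.0, 534.0)
        assert d.mean() == pytest.approx(132 / 666, abs=1e-12)

    def test_zero_sd_cost_is_point_mass(self):
        d = build_distribution(CostEntry(219.0, 219.0, 219.0, 0.0))
        assert d.family == "point" and d.mean() == 219.0

    def test_utility_moment_match_reproduces_mean_and_sd(self):
        entry = UtilityEntry(0.44, 0.374, 0.502, 0.2477)
        d = build_distribution(entry)
        assert d.family == "beta"
        mean, var = scipy.stats.beta.stats(d.a, d.b, moments="mv")
        assert mean == pytest.approx(0.44, abs=1e-12)
        assert math.sqrt(var) == pytest.approx(0.2477, abs=1e-9)

    def test_cost_moment_match_reproduces_mean_and_sd(self):
        d = build_distribution(CostEntry(219.0, 175.2, 262.8, 22.24))
        assert d.family == "gamma"
        mean, var = scipy.stats.gamma.stats(d.a, scale=d.b, moments="mv")
        assert mean == pytest.approx(219.0, abs=1e-9)
        assert math.sqrt(var) == pytest.approx(22.24, abs=1e-9)

    def test_sampling_mean_matches_base_value(self):
        # empirical round trip at 10^5 draws, three Monte Carlo SEs
        rng = np.random.default_rng(0)
        entry = UtilityEntry(0.44, 0.374, 0.502, 0.2477)
        draws = build_distribution(entry).sample(rng, size=100_000)
        se = draws.std() / math.sqrt(draws.size)
        assert abs(draws.mean() - 0.44) < 3 * se

    def test_infeasible_moment_match_falls_back_to_point(self, caplog):
        # sd^2 >= base(1-base): no beta has these moments
        entry = UtilityEntry(0.5, 0.4, 0.6, 0.6)
        with caplog.at_level("WARNING"):
            d = build_distribution(entry)
        assert d.family == "point" and d.a == 0.5
        assert "infeasible" in caplog.text


class TestModelConfigLoading:
    def test_principal_states_partition_to_one(self, base_config):
        for spec in (base_config.treatment_spec(), base_config.comparator_spec()):
            assert spec.p_pf + spec.p_fmbs + spec.p_ti == pytest.approx(1.0, abs=1e-9)

    def test_conditional_bins_sum_to_one(self, base_config):
        for spec in (base_config.treatment_spec(), base_config.comparator_spec()):
            for branches in (spec.pf_branches, spec.fmbs_branches):
                assert math.fsum(b.probability for b in branches) == pytest.approx(
                    1.0, abs=1e-9
                )

    def test_fmbs_utilities_derived_from_pf(self, base_config):
        for spec in (base_config.treatment_spec(), base_config.comparator_spec()):
            pf_u = {b.time_min: b.utility for b in spec.pf_branches}
            for b in spec.fmbs_branches:
                assert b.utility == pytest.approx(0.87 * pf_u[b.time_min], abs=1e-12)

    def test_treatment_pf_probability_matches_table(self, base_config):
        assert round(base_config.treatment_spec().p_pf, 4) == 0.1982

    def test_bin_sum_violation_names_key(self, raw_config):
        raw_config["arms"]["treatment"]["pain_freedom_bins"][15] = {
            "probability": 0.95
        }
        for t in (30, 45, 60, 90):
            raw_config["arms"]["treatment"]["pain_freedom_bins"][t] = {
                "probability": 0.1
            }
        with pytest.raises(ConfigError, match="sum"):
            model_config_from_dict(raw_config)

    def test_negative_cost_rejected(self, raw_config):
        raw_config["arms"]["treatment"]["dose_cost"]["base"] = -5.0
        with pytest.raises(ConfigError, match="dose_cost"):
            model_config_from_dict(raw_config)

    def test_missing_field_names_key(self, raw_config):
        del raw_config["arms"]["treatment"]["fmbs_2h"]
        with pytest.raises(ConfigError, match="fmbs_2h"):
            model_config_from_dict(raw_config)

    def test_probability_direct_config_is_equivalent(self, raw_config, base_config):
        """Giving probabilities instead of counts must not change deterministic
        results."""
        for arm in raw_config["arms"].values():
            for key in ("pain_freedom_2h", "fmbs_2h"):
                c = arm[key]
                arm[key] = {
                    "probability": c["successes"] / (c["successes"] + c["failures"])
                }
            for bins in (arm["pain_freedom_bins"], arm["fmbs_bins"]):
                for t, c in bins.items():
                    bins[t] = {
                        "probability": c["successes"] / (c["successes"] + c["failures"])
                    }
        direct = model_config_from_dict(raw_config)
        a = evaluate_base_case(direct)
        b = evaluate_base_case(base_config)
        assert a.treatment.effect == pytest.approx(b.treatment.effect, abs=1e-15)
        assert a.comparator.effect == pytest.approx(b.comparator.effect, abs=1e-15)
        assert a.incremental.icer == pytest.approx(b.incremental.icer, rel=1e-12)


class TestTabularExport:
    def test_probabilities_table_mirrors_input_layout(self, base_config):
        tab = probabilities_table(base_config).set_index("input_variable")
        row = tab.loc["pain_freedom_2h"]
        assert round(row.treatment_base, 4) == 0.1982
        assert (row.treatment_alpha, row.treatment_beta) == (132, 534)
        assert round(row.comparator_base, 4) == 0.1068

    def test_utilities_table_round_trips_printed_values(self, base_config):
        tab = utilities_table(base_config).set_index("health_state")
        assert tab.loc["pain_freedom_15min", "base"] == 0.7573
        assert tab.loc["sustained_pain_2h", "sd"] == 0.2477

    def test_export_writes_three_csvs(self, base_config, tmp_path):
        paths = export_tables(base_config, tmp_path)
        assert sorted(paths) == ["costs", "probabilities", "utilities"]
        for p in paths.values():
            assert p.exists() and p.stat().st_size > 0
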