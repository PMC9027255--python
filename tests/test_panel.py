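"""OR-rule panels: positivity, the continuous combination score, rate
tables, AFP-negative rescue and the exhaustive full-coverage search."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest

from seropanel.cohort import (
    CohortDesign,
    Stage,
    default_profiles,
    generate_serum_cohort,
    validation_design,
)
from seropanel.model import MarkerDiagnostics, PanelDiagnostics
from seropanel.panel import (
    PanelRule,
    combined_score,
    combined_score_frame,
    panel_positive,
    panel_positive_frame,
    positive_rate_table,
    rescue_analysis,
    search_full_coverage,
)
from seropanel.roc import MarkerCutoff, empirical_roc

AFP20 = MarkerCutoff("AFP", 20.0)
HMMR08 = MarkerCutoff("HMMR", 0.8)
PAIR = PanelRule((AFP20, HMMR08))


class TestPanelRule:
    def test_duplicate_members_rejected(self):
        with pytest.raises(ValueError):
            PanelRule((AFP20, MarkerCutoff("AFP", 10.0)))

    def test_size_limits(self):
        with pytest.raises(ValueError):
            PanelRule(())

    def test_or_rule_any_member(self):
        assert panel_positive({"AFP": 25.0, "HMMR": 0.5}, PAIR)

    def test_all_below_negative(self):
        assert not panel_positive({"AFP": 10.0, "HMMR": 0.4}, PAIR)

    def test_and_rule(self):
        rule = PanelRule((AFP20, HMMR08), logic="and")
        assert not panel_positive({"AFP": 25.0, "HMMR": 0.5}, rule)
        assert panel_positive({"AFP": 25.0, "HMMR": 0.9}, rule)

    def test_missing_member_rejected(self):
        with pytest.raises(ValueError, match="HMMR"):
            panel_positive({"AFP": 25.0}, PAIR)
        with pytest.raises(ValueError, match="HMMR"):
            panel_positive({"AFP": 25.0, "HMMR": math.nan}, PAIR)

    def test_single_member_equivalence(self, serum_cohort):
        rule = PanelRule((HMMR08,))
        single = panel_positive_frame(serum_cohort, rule)
        direct = serum_cohort["HMMR"] > 0.8
        assert (single == direct).all()


class TestCombinedScore:
    def test_boundary_score_zero(self):
        assert combined_score({"AFP": 20.0, "HMMR": 0.8}, PAIR) == pytest.approx(0.0)

    def test_sign_agrees_with_positivity(self, serum_cohort):
        scores = combined_score_frame(serum_cohort, PAIR)
        pos = panel_positive_frame(serum_cohort, PAIR)
        assert ((scores > 0) == pos).all()

    def test_monotone_in_member_values(self, rng):
        for _ in range(100):
            subject = {"AFP": rng.lognormal(2, 1), "HMMR": rng.lognormal(0, 1)}
            base = combined_score(subject, PAIR)
            doubled = dict(subject, AFP=2 * subject["AFP"])
            assert combined_score(doubled, PAIR) >= base - 1e-12

    def test_zero_value_floored(self):
        score = combined_score({"AFP": 0.0, "HMMR": 0.0}, PAIR)
        assert math.isfinite(score) and score < 0

    def test_single_member_auc_equals_marker_auc(self, serum_cohort):
        # the score is a strictly increasing transform of the raw value
        rule = PanelRule((HMMR08,))
        scores = combined_score_frame(serum_cohort, rule)
        hcc = serum_cohort["stage"].isin(["eHCC", "aHCC"])
        auc_score = empirical_roc(scores[hcc], scores[~hcc]).auc
        auc_raw = empirical_roc(serum_cohort.loc[hcc, "HMMR"],
                                serum_cohort.loc[~hcc, "HMMR"]).auc
        assert auc_score == pytest.approx(auc_raw, abs=1e-12)


class TestRateTable:
    def test_rates_and_denominators(self, serum_cohort):
        table = positive_rate_table(serum_cohort, [HMMR08, PAIR])
        nl_hmmr = table[(table["group"] == "NL") & (table["rule"] == "HMMR")].iloc[0]
        assert nl_hmmr["n"] == 49
        assert nl_hmmr["rate_pct"] == pytest.approx(
            100 * nl_hmmr["n_positive"] / nl_hmmr["n"])

    def test_or_dominance_per_stage(self, serum_cohort):
        table = positive_rate_table(serum_cohort, [HMMR08, AFP20, PAIR])
        for stage in ("NL", "CH", "LC", "eHCC", "aHCC"):
            sub = table[table["group"] == stage].set_index("rule")["rate_pct"]
            assert sub["AFP-HMMR"] >= max(sub["HMMR"], sub["AFP"]) - 1e-9

    def test_calibrated_nl_afp_rate(self):
        # the stage-refined profile pins AFP positivity in normal liver at 2%
        profiles = default_profiles(stage_refined_afp=True)
        design = CohortDesign({Stage.NL: 10_000}, profiles=profiles)
        cohort = generate_serum_cohort(design, seed=21)
        table = positive_rate_table(cohort, [AFP20])
        rate = table.iloc[0]["rate_pct"] / 100
        assert rate == pytest.approx(0.02, abs=3 * np.sqrt(0.02 * 0.98 / 10_000))


class TestRescue:
    def cases(self, seed=13, n=4000):
        design = CohortDesign({Stage.EHCC: n // 2, Stage.AHCC: n // 2},
                              profiles=default_profiles())
        return generate_serum_cohort(design, seed=seed)

    def test_strata_partition_cases(self):
        cases = self.cases()
        res = rescue_analysis(cases, AFP20, [HMMR08])
        assert res.n_reference_negative + res.n_reference_positive == len(cases)

    def test_marker_identical_to_reference_never_rescues(self):
        cases = self.cases()
        res = rescue_analysis(cases, AFP20, [AFP20])
        assert res.rates_in_negative["AFP"] == 0.0
        assert res.rates_in_positive["AFP"] == 100.0

    def test_independent_marker_rescue_matches_marginal(self):
        # markers are generated independently, so positivity among
        # AFP-negative cases equals the marginal sensitivity
        cases = self.cases()
        res = rescue_analysis(cases, AFP20, [HMMR08])
        marginal = 100 * (cases["HMMR"] > 0.8).mean()
        assert res.rates_in_negative["HMMR"] == pytest.approx(marginal, abs=3.0)

    def test_all_reference_positive_flags_empty_stratum(self):
        cases = pd.DataFrame({
            "stage": ["eHCC"] * 3, "AFP": [30.0, 40.0, 50.0], "HMMR": [1.0, 0.5, 2.0],
        })
        res = rescue_analysis(cases, AFP20, [HMMR08])
        assert res.n_reference_negative == 0
        assert math.isnan(res.rates_in_negative["HMMR"])
        assert any("negative stratum empty" in f for f in res.flags)


def brute_force_full_coverage(cases, candidates, k):
    winners = []
    for combo in itertools.combinations(sorted(candidates, key=lambda c: c.marker), k):
        if all(any(row[c.marker] > c.cutoff for c in combo)
               for _, row in cases.iterrows()):
            winners.append(tuple(c.marker for c in combo))
    return winners


class TestFullCoverageSearch:
    CANDIDATES = [AFP20, HMMR08, MarkerCutoff("NXPH4", 7.5), MarkerCutoff("PITX1", 2.5)]

    def test_constructed_cover_found(self):
        cases = pd.DataFrame({
            "AFP": [25.0, 1.0], "HMMR": [0.1, 0.9],
            "NXPH4": [1.0, 1.0], "PITX1": [1.0, 1.0],
        })
        winners = search_full_coverage(cases, self.CANDIDATES, 2)
        names = [w.marker_names for w in winners]
        assert ("AFP", "HMMR") in names
        assert ("NXPH4", "PITX1") not in names

    def test_k_equals_candidate_count(self):
        cases = pd.DataFrame({"AFP": [25.0], "HMMR": [0.9], "NXPH4": [8.0]})
        winners = search_full_coverage(cases, self.CANDIDATES[:3], 3)
        assert len(winners) <= 1

    def test_missing_measurement_rejected(self):
        cases = pd.DataFrame({"AFP": [25.0, math.nan], "HMMR": [0.9, 1.0],
                              "NXPH4": [1.0, 1.0], "PITX1": [1.0, 1.0]})
        with pytest.raises(ValueError):
            search_full_coverage(cases, self.CANDIDATES, 2)

    @pytest.mark.parametrize("k", [2, 3])
    def test_agrees_with_brute_force(self, k, rng):
        for _ in range(25):
            n = int(rng.integers(3, 30))
            cases = pd.DataFrame({
                c.marker: rng.lognormal(np.log(c.cutoff), 1.2, n)
                for c in self.CANDIDATES
            })
            winners = [w.marker_names for w in
                       search_full_coverage(cases, self.CANDIDATES, k)]
            assert winners == brute_force_full_coverage(cases, self.CANDIDATES, k)


class TestPanelModel:
    def test_or_dominance_sensitivity_specificity(self, serum_cohort):
        rule = PanelRule((AFP20, HMMR08, MarkerCutoff("NXPH4", 7.5)))
        panel = PanelDiagnostics(serum_cohort, rule).fit()
        members = [MarkerDiagnostics.from_dataframe(serum_cohort, m).fit(cutoff=c)
                   for m, c in [("AFP", 20.0), ("HMMR", 0.8), ("NXPH4", 7.5)]]
        assert panel.metrics.sensitivity >= max(m.metrics.sensitivity for m in members) - 1e-9
        assert panel.metrics.specificity <= min(m.metrics.specificity for m in members) + 1e-9

    def test_adding_member_never_reduces_coverage(self, serum_cohort):
        small = PanelRule((AFP20, HMMR08))
        large = PanelRule((AFP20, HMMR08, MarkerCutoff("PITX1", 2.5)))
        cases = serum_cohort[serum_cohort["stage"].isin(["eHCC", "aHCC"])]
        assert panel_positive_frame(cases, large).sum() >= panel_positive_frame(cases, small).sum()

    def test_summary_mentions_panel(self, serum_cohort):
        res = PanelDiagnostics(serum_cohort, PAIR).fit()
        text = res.summary()
        assert "AFP-HMMR" in text and "AUC" in text
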