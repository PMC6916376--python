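"""Cohort and event simulators, and the deterministic reference cohort."""

import numpy as np
import pytest

from monotriage import (
    CohortSimParams,
    CombinedRule,
    Diagnosis,
    EventSimParams,
    ValidationError,
    combined_rule,
    default_gateset,
    paper_fixture,
    simulate_cohort,
    simulate_events,
    simulate_rule_table,
    tabulate,
    who_eligible,
)
from monotriage.scores import ScoreConfig, cmo_positive, detect_bulbous, dysplasia_positive, monoscore_positive


class TestPaperFixture:
    def test_class_mixture(self, fixture_cohort):
        by_dx = fixture_cohort.n_by_diagnosis()
        assert by_dx[Diagnosis.NONCLONAL] == 136 and by_dx[Diagnosis.CMML] == 60

    def test_trigger_marginal(self, fixture_cohort):
        assert sum(r.triggers.any_trigger for r in fixture_cohort) == 72

    def test_trigger_arm_joint_cells(self, fixture_cohort, cfg):
        # the sixteen printed joint counts of the trigger arm
        cells = {}
        for r in fixture_cohort:
            if not r.triggers.any_trigger:
                continue
            key = (
                r.consensus_dx.value,
                monoscore_positive(r.monoscore, cfg),
                dysplasia_positive(r.dysplasia, cfg),
                cmo_positive(r.subsets, cfg),
            )
            cells[key] = cells.get(key, 0) + 1
        expected = {
            ("NONCLONAL", False, True, True): 1,
            ("NONCLONAL", False, False, False): 9,
            ("NONCLONAL", False, False, True): 3,
            ("NONCLONAL", True, True, False): 5,
            ("NONCLONAL", True, False, False): 15,
            ("NONCLONAL", True, False, True): 2,
            ("CMML", False, True, False): 1,
            ("CMML", True, True, False): 1,
            ("CMML", True, True, True): 33,
            ("CMML", True, False, True): 2,
        }
        assert cells == expected

    def test_no_trigger_arm_counts(self, fixture_cohort, cfg):
        arm = [r for r in fixture_cohort if not r.triggers.any_trigger]
        assert len(arm) == 124
        ms_neg = [r for r in arm if not monoscore_positive(r.monoscore, cfg)]
        assert len(ms_neg) == 57
        assert sum(r.consensus_dx is Diagnosis.CMML for r in ms_neg) == 1
        ms_pos_cmml = [r for r in arm if monoscore_positive(r.monoscore, cfg)
                       and r.consensus_dx is Diagnosis.CMML]
        assert len(ms_pos_cmml) == 22
        assert sum(cmo_positive(r.subsets, cfg) for r in ms_pos_cmml) == 20
        bulbous = [r for r in ms_pos_cmml if r.subsets.bulbous]
        assert len(bulbous) == 2 and all(r.followup_cmo_confirmed for r in bulbous)
        # morphology marks 17/23 CMML and 11/101 nonclonal in this arm
        assert sum(dysplasia_positive(r.dysplasia, cfg) for r in arm
                   if r.consensus_dx is Diagnosis.CMML) == 17
        assert sum(dysplasia_positive(r.dysplasia, cfg) for r in arm
                   if r.consensus_dx is Diagnosis.NONCLONAL) == 11

    @pytest.mark.parametrize("rule, row_pos, row_neg", [
        (CombinedRule.MS_OR_DYS, (60, 73), (0, 63)),
        (CombinedRule.MS_OR_CMO, (59, 79), (1, 57)),
        (CombinedRule.DYS_OR_CMO, (60, 37), (0, 99)),
    ])
    def test_combined_rule_row_totals(self, fixture_cohort, rule, row_pos, row_neg):
        table, _ = tabulate(fixture_cohort, lambda r: combined_rule(r, rule))
        assert (table.tp, table.fp) == row_pos and (table.fn, table.tn) == row_neg

    def test_workflow_node_sizes(self, fixture_cohort, cfg):
        # node occupancies of the applied decision tree
        trig = [r for r in fixture_cohort if r.triggers.any_trigger]
        dys_pos = [r for r in trig if dysplasia_positive(r.dysplasia, cfg)]
        dys_neg = [r for r in trig if not dysplasia_positive(r.dysplasia, cfg)]
        assert (len(dys_pos), len(dys_neg)) == (41, 31)
        ms_neg = [r for r in dys_neg if not monoscore_positive(r.monoscore, cfg)]
        assert (len(ms_neg), len(dys_neg) - len(ms_neg)) == (12, 19)
        no_trig = [r for r in fixture_cohort if not r.triggers.any_trigger]
        ms_pos = [r for r in no_trig if monoscore_positive(r.monoscore, cfg)]
        assert (len(no_trig) - len(ms_pos), len(ms_pos)) == (57, 67)

    def test_every_record_valid_and_eligible(self, fixture_cohort, cfg):
        for r in fixture_cohort:
            assert who_eligible(r.cbc)
            r.triggers.check_consistent(r.cbc)
            assert r.subsets.bulbous == detect_bulbous(r.subsets, cfg)

    def test_deterministic(self, fixture_cohort):
        again = paper_fixture()
        assert again.records == fixture_cohort.records


class TestSimulateCohort:
    def test_same_seed_identical(self):
        a = simulate_cohort(seed=5)
        b = simulate_cohort(seed=5)
        assert a.records == b.records

    def test_zero_prevalence_all_nonclonal(self):
        co = simulate_cohort(CohortSimParams(n_total=50, cmml_prevalence=0.0, seed=1))
        assert all(r.consensus_dx is Diagnosis.NONCLONAL for r in co)

    def test_records_satisfy_invariants(self):
        co = simulate_cohort(seed=2)
        for r in co:
            assert who_eligible(r.cbc)
            r.triggers.check_consistent(r.cbc)
            assert 0.0 <= r.monoscore <= 1.0

    def test_trigger_prevalence_matches_configuration(self):
        params = CohortSimParams(n_total=10_000, seed=7)
        co = simulate_cohort(params)
        cmml = [r for r in co if r.consensus_dx is Diagnosis.CMML]
        prev = np.mean([r.triggers.any_trigger for r in cmml])
        assert abs(prev - params.p_trigger["CMML"]) < 0.02

    def test_monoscore_medians_match_study_population(self):
        co = simulate_cohort(CohortSimParams(n_total=10_000, seed=11))
        ms = {"CMML": [], "NONCLONAL": []}
        for r in co:
            if r.consensus_dx.value in ms:
                ms[r.consensus_dx.value].append(r.monoscore)
        assert abs(np.median(ms["NONCLONAL"]) - 0.15) < 0.1
        assert abs(np.median(ms["CMML"]) - 0.98) < 0.1

    def test_bulbous_cmml_records_get_followup_confirmation(self):
        co = simulate_cohort(CohortSimParams(n_total=2000, cmml_prevalence=0.5,
                                             bulbous_prob_cmml=0.3, seed=3))
        bulbous_cmml = [r for r in co if r.consensus_dx is Diagnosis.CMML
                        and r.subsets.bulbous]
        assert bulbous_cmml and all(r.followup_cmo_confirmed for r in bulbous_cmml)

    def test_invalid_params_rejected_before_sampling(self):
        with pytest.raises(ValidationError):
            simulate_cohort(CohortSimParams(cmml_prevalence=1.5))


class TestSimulateEvents:
    def test_same_seed_identical(self):
        a = simulate_events(seed=9)
        b = simulate_events(seed=9)
        assert np.array_equal(a.cd14, b.cd14) and np.array_equal(a.cd16, b.cd16)

    def test_single_component_lands_in_its_gate(self):
        ev = simulate_events(EventSimParams(fractions=(100.0, 0.0, 0.0),
                                            n_events=5000, seed=1))
        gate = default_gateset().cmo
        inside = gate.contains(ev.cd14, ev.cd16).mean()
        assert inside >= 0.99

    def test_invalid_fractions_rejected(self):
        with pytest.raises(ValidationError):
            simulate_events(EventSimParams(fractions=(50.0, 10.0, 10.0)))


class TestRuleTable:
    def test_deterministic_and_noiseless(self):
        a = simulate_rule_table(200, seed=6)
        b = simulate_rule_table(200, seed=6)
        assert a.equals(b)
        rule = np.where(
            a["any_trigger"].astype(bool),
            a["dysplasia_pos"].astype(bool)
            | (a["monoscore_pos"].astype(bool) & a["cmo_pos"].astype(bool)),
            a["monoscore_pos"].astype(bool) & a["cmo_pos"].astype(bool),
        )
        assert (a["consensus_dx"] == np.where(rule, "CMML", "NONCLONAL")).all()
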