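"""Gate semantics, calibration and ranking."""

import numpy as np
import pandas as pd
import pytest

from bpascreen import (
    SimConfig,
    apply_gate,
    calibrate,
    default_candidate_gate,
    gen_reference_panel,
    nucleophilicity_rank,
    rank_candidates,
)
from bpascreen.errors import ScoringError
from bpascreen.screening import GateThresholds

PASSING = {
    "compound_id": "ok",
    "herg_pic50": 5.0,
    "neg_logs": 6.0,
    "cns_mpo": 3.5,
    "bbb_score": 4.2,
    "mpa": 50.0,
}


class TestGate:
    def test_all_inside_bounds_passes(self):
        assert apply_gate(PASSING, default_candidate_gate()).verdict

    @pytest.mark.parametrize(
        "key,value,criterion",
        [
            ("herg_pic50", 5.8, "herg"),
            ("neg_logs", 8.0, "neg_logs"),
            ("cns_mpo", 2.5, "cns_mpo"),
            ("bbb_score", 5.6, "bbb_score"),
            ("mpa", 65.0, "mpa"),
        ],
    )
    def test_single_violation_fails_only_that_criterion(self, key, value, criterion):
        record = {**PASSING, key: value}
        result = apply_gate(record, default_candidate_gate())
        assert not result.verdict
        failed = [c for c, (_, _, ok) in result.per_criterion.items() if not ok]
        assert failed == [criterion]

    def test_boundary_values_fail_strict_criteria(self):
        record = {**PASSING, "herg_pic50": 5.5, "neg_logs": 7.5, "cns_mpo": 3.0}
        result = apply_gate(record, default_candidate_gate())
        failed = {c for c, (_, _, ok) in result.per_criterion.items() if not ok}
        assert failed == {"herg", "neg_logs", "cns_mpo"}

    def test_bbb_band_is_closed_interval(self):
        for edge in (4.0, 5.0):
            assert apply_gate({**PASSING, "bbb_score": edge}, default_candidate_gate()).verdict

    def test_missing_value_skipped_and_listed(self):
        record = dict(PASSING)
        record.pop("mpa")
        result = apply_gate(record, default_candidate_gate())
        assert result.verdict
        assert "mpa" in result.missing
        assert "mpa" not in result.per_criterion

    def test_direct_evaluation_of_lead_like_record(self):
        record = {
            "compound_id": "lead",
            "herg_pic50": 5.0,
            "neg_logs": 6.8,
            "cns_mpo": 3.71,
            "bbb_score": 4.5,
            "mpa": 55.0,
        }
        assert apply_gate(record, default_candidate_gate()).verdict

    def test_monotone_improvement_never_flips_pass_to_fail(self):
        rng = np.random.default_rng(3)
        gate = default_candidate_gate()
        improvements = {
            "herg_pic50": -0.5,
            "neg_logs": -1.0,
            "cns_mpo": +0.5,
            "mpa": -5.0,
        }
        for _ in range(200):
            record = {
                "compound_id": "r",
                "herg_pic50": rng.uniform(3, 7),
                "neg_logs": rng.uniform(4, 9),
                "cns_mpo": rng.uniform(2, 5),
                "bbb_score": rng.uniform(3.5, 5.5),
                "mpa": rng.uniform(40, 80),
            }
            before = apply_gate(record, gate).verdict
            if not before:
                continue
            for key, delta in improvements.items():
                assert apply_gate({**record, key: record[key] + delta}, gate).verdict

    def test_invalid_thresholds(self):
        with pytest.raises(ScoringError):
            GateThresholds(bbb_min=5.0, bbb_max=4.0)


class TestCalibration:
    def test_degenerate_panel_thresholds_equal_scores(self):
        row = {"herg_pic50": 5.0, "neg_logs": 6.0, "cns_mpo": 3.5, "bbb_score": 4.2}
        panel = pd.DataFrame([{**row, "acceptable": True}, {**row, "acceptable": True}])
        th = calibrate(panel)
        assert th.herg_max == pytest.approx(5.0)
        assert th.cns_mpo_min == pytest.approx(3.5)
        assert (th.bbb_min, th.bbb_max) == (pytest.approx(4.2), pytest.approx(4.2))

    def test_two_drug_min_under_range_policy(self):
        panel = pd.DataFrame(
            [
                {"cns_mpo": 3.2, "acceptable": True},
                {"cns_mpo": 4.1, "acceptable": True},
            ]
        )
        assert calibrate(panel).cns_mpo_min == pytest.approx(3.2)

    def test_empty_acceptable_subset_errors(self):
        panel = pd.DataFrame([{"cns_mpo": 3.0, "acceptable": False}] * 3)
        with pytest.raises(ScoringError, match="acceptable"):
            calibrate(panel)

    def test_synthetic_panel_recovers_generating_box(self):
        panel = gen_reference_panel(SimConfig(seed=20230420))
        th = calibrate(panel)
        acc = panel[panel["acceptable"]]
        # thresholds track the acceptable subset's observed range, which lies
        # inside the generating box (hERG <= 5.5, -logS box, MPO/BBB bands)
        assert acc["herg_pic50"].max() <= th.herg_max <= 5.5 + 1e-9
        assert 3.0 - 1e-9 <= th.cns_mpo_min <= acc["cns_mpo"].min()
        assert th.bbb_min <= acc["bbb_score"].min()
        assert th.bbb_max >= acc["bbb_score"].max()

    def test_closure_every_acceptable_member_passes(self):
        panel = gen_reference_panel(SimConfig(seed=99))
        th = calibrate(panel)
        for rec in panel[panel["acceptable"]].to_dict(orient="records"):
            rec["compound_id"] = rec["drug"]
            assert apply_gate(rec, th).verdict, rec["drug"]


class TestRanking:
    def _results(self, records):
        gate = default_candidate_gate()
        return [apply_gate(r, gate) for r in records], {r["compound_id"]: r for r in records}

    def test_higher_mpo_listed_first(self):
        a = {**PASSING, "compound_id": "a", "cns_mpo": 4.0}
        b = {**PASSING, "compound_id": "b", "cns_mpo": 3.5}
        results, scores = self._results([b, a])
        ranked = rank_candidates(results, scores)
        assert list(ranked["compound_id"][:2]) == ["a", "b"]

    def test_all_failing_gives_empty_pass_list(self):
        bad = {**PASSING, "compound_id": "x", "herg_pic50": 6.5}
        results, scores = self._results([bad])
        ranked = rank_candidates(results, scores)
        assert (ranked["verdict"] == "fail").all()

    def test_full_tie_breaks_by_id(self):
        a = {**PASSING, "compound_id": "a"}
        b = {**PASSING, "compound_id": "b"}
        results, scores = self._results([b, a])
        ranked = rank_candidates(results, scores)
        assert list(ranked["compound_id"]) == ["a", "b"]


class TestNucleophilicity:
    def test_higher_homo_more_nucleophilic(self):
        ranked = nucleophilicity_rank([("aminopyridine", -8.6), ("aniline", -8.0)])
        assert ranked[0][0] == "aniline"

    def test_single_entry(self):
        assert nucleophilicity_rank([("only", -7.0)]) == [("only", -7.0)]

    def test_ties_keep_input_order(self):
        ranked = nucleophilicity_rank([("b", -8.0), ("a", -8.0)])
        assert [n for n, _ in ranked] == ["b", "a"]
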