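import dataclasses
import itertools

import pytest

from mipscan import (
    EvalReport,
    PipelineConfig,
    PredictionRecord,
    SweepGrid,
    evaluate,
    run_pipeline,
    sweep,
)
from mipscan.simulate import GroundTruth


def _pred(pid):
    return PredictionRecord(
        mip_id=pid, mip_length=100, target_tf_ids=("tf1",),
        target_tf_lengths=(400,), mip_domains=(), provenance="tier1",
    )


def _truth(n_mips=10, n_decoys=10):
    labels = {f"m{i}": "true_mip_tier1" for i in range(n_mips)}
    labels.update({f"d{i}": "decoy_random" for i in range(n_decoys)})
    expected = {pid: frozenset({"tf1"}) for pid in labels}
    return GroundTruth(labels=labels, expected_targets=expected)


class TestEvaluate:
    def test_perfect_recovery(self):
        truth = _truth()
        report = evaluate([_pred(f"m{i}") for i in range(10)], truth)
        assert (report.recall, report.precision) == (1.0, 1.0)
        assert report.target_accuracy == 1.0

    def test_half_recovered_half_decoys(self):
        truth = _truth()
        preds = [_pred(f"m{i}") for i in range(5)] + [_pred(f"d{i}") for i in range(5)]
        report = evaluate(preds, truth)
        assert (report.recall, report.precision) == (0.5, 0.5)
        assert report.per_class_counts == {"true_mip_tier1": 5, "decoy_random": 5}

    def test_zero_predictions_precision_undefined_not_zero(self):
        report = evaluate([], _truth())
        assert report.recall == 0.0
        assert report.precision is None
        assert report.target_accuracy is None

    def test_unknown_prediction_id_is_error(self):
        with pytest.raises(ValueError, match="mystery"):
            evaluate([_pred("mystery")], _truth())

    def test_invariant_to_prediction_order(self):
        truth = _truth()
        preds = [_pred(f"m{i}") for i in range(5)] + [_pred("d0")]
        assert evaluate(preds, truth) == evaluate(list(reversed(preds)), truth)

    def test_wrong_targets_lower_target_accuracy_not_precision(self):
        truth = _truth(n_mips=2, n_decoys=0)
        wrong = dataclasses.replace(_pred("m0"), target_tf_ids=("other",),
                                    target_tf_lengths=(300,))
        report = evaluate([wrong, _pred("m1")], truth)
        assert report.precision == 1.0
        assert report.target_accuracy == 0.5


class TestSweepGrid:
    def test_must_be_sorted_and_non_empty(self):
        with pytest.raises(ValueError):
            SweepGrid(tier1_cutoffs=(), tier2_cutoffs=(0.5,), reverse_cutoffs=(0.1,))
        with pytest.raises(ValueError):
            SweepGrid(
                tier1_cutoffs=(1e-4, 1e-7),
                tier2_cutoffs=(0.5,),
                reverse_cutoffs=(0.1,),
            )


DEFAULT_GRID = SweepGrid(
    tier1_cutoffs=(1e-12, 1e-7, 1e-3),
    tier2_cutoffs=(1e-3, 0.5, 1.0),
    reverse_cutoffs=(1e-4, 0.1, 1.0),
)


@pytest.fixture(scope="module")
def sweep_result(default_fixture):
    return sweep(default_fixture, DEFAULT_GRID)


class TestSweep:
    def test_single_point_matches_direct_pipeline_run(self, default_fixture):
        fx = default_fixture
        grid = SweepGrid(
            tier1_cutoffs=(1e-7,), tier2_cutoffs=(0.5,), reverse_cutoffs=(0.1,)
        )
        table, selected = sweep(fx, grid)
        assert len(table) == 1
        preds = run_pipeline(
            fx.proteome, fx.tfs, fx.unwanted,
            cfg=PipelineConfig(), domain_library=fx.library,
        )
        row = table.iloc[0]
        assert row["n_predictions"] == len(preds)
        assert row["recall"] == 1.0

    def test_recall_non_decreasing_along_each_axis(self, sweep_result):
        table, _ = sweep_result
        axes = ["e1", "e2", "e3"]
        for axis in axes:
            others = [a for a in axes if a != axis]
            for _, group in table.groupby(others):
                ordered = group.sort_values(axis)["recall"].tolist()
                assert ordered == sorted(ordered), axis

    def test_loosest_corner_recalls_all_planted(self, sweep_result):
        table, _ = sweep_result
        corner = table[
            (table["e1"] == 1e-3) & (table["e2"] == 1.0) & (table["e3"] == 1.0)
        ]
        assert corner["recall"].iloc[0] == 1.0

    def test_selected_row_is_most_stringent_at_max_recall(self, sweep_result):
        table, selected = sweep_result
        best = table["recall"].max()
        assert selected["recall"] == best
        achievers = table[table["recall"] == best]
        expected = achievers.sort_values(["e1", "e2", "e3"]).iloc[0]
        assert (selected["e1"], selected["e2"], selected["e3"]) == (
            expected["e1"], expected["e2"], expected["e3"],
        )

    def test_rethreshold_shortcut_equals_naive_full_runs(self, default_fixture):
        fx = default_fixture
        grid = SweepGrid(
            tier1_cutoffs=(1e-12, 1e-7),
            tier2_cutoffs=(0.5,),
            reverse_cutoffs=(1e-4, 0.1),
        )
        table, _ = sweep(fx, grid)
        for e1, e2, e3 in itertools.product(
            grid.tier1_cutoffs, grid.tier2_cutoffs, grid.reverse_cutoffs
        ):
            cfg = PipelineConfig(tier1_cutoff=e1, tier2_cutoff=e2, reverse_cutoff=e3)
            preds = run_pipeline(
                fx.proteome, fx.tfs, fx.unwanted, cfg=cfg, domain_library=fx.library
            )
            row = table[
                (table["e1"] == e1) & (table["e2"] == e2) & (table["e3"] == e3)
            ].iloc[0]
            assert row["n_predictions"] == len(preds)
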