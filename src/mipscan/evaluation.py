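"""Scoring predictions against ground truth and E-value threshold sweeps.

``evaluate`` computes recall (planted miPs recovered / planted), precision
(outputs labeled as true miPs / all outputs), per-class output counts, and
target accuracy (recovered miPs whose reported targets intersect the
expected target set).  Precision counts any true-miP-labeled output as
correct even if its reported targets are wrong — physical-interaction-based
precision is known to be an underestimate, so target correctness is
reported separately.

``sweep`` reruns the pipeline over a cutoff grid.  Searches are executed
once at the loosest cutoffs of each axis and re-thresholded per grid point
(hit sets are monotone in the cutoff, so this is exact), making the sweep
a filtering pass rather than repeated alignment.  The selected row follows
the recall-driven rule: among rows achieving maximal recall, the most
stringent cutoffs, ties broken lexicographically by (e1, e2, e3).
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Optional, Sequence

import pandas as pd

from .homology import (
    BuiltinSearchBackend,
    PrecomputedSearchBackend,
    ScoringScheme,
    SearchBackend,
)
from .io_formats import PredictionRecord
from .pipeline import PipelineConfig, partition_by_length, run_pipeline
from .simulate import TRUE_CLASSES, Fixture, GroundTruth


@dataclass(frozen=True)
class EvalReport:
    """Prediction quality on one labeled fixture.

    ``precision`` and ``target_accuracy`` are ``None`` when their
    denominators are empty (no predictions / no recovered miPs) rather
    than being forced to 0.
    """

    recall: float
    precision: Optional[float]
    target_accuracy: Optional[float]
    per_class_counts: dict[str, int]
    n_planted: int
    n_recovered: int
    n_predictions: int


def evaluate(
    predictions: Sequence[PredictionRecord], truth: GroundTruth
) -> EvalReport:
    """Score a prediction set against ground-truth labels.

    A planted miP counts as recovered iff its id appears among the
    predictions.  Prediction ids absent from the truth labels are a hard
    error.
    """
    unknown = sorted(
        {p.mip_id for p in predictions} - set(truth.labels)
    )
    if unknown:
        raise ValueError(f"predictions with unknown ids: {unknown}")

    predicted_ids = {p.mip_id for p in predictions}
    planted = truth.planted_mips()
    recovered = [pid for pid in planted if pid in predicted_ids]

    per_class: dict[str, int] = {}
    for p in predictions:
        cls = truth.labels[p.mip_id]
        per_class[cls] = per_class.get(cls, 0) + 1

    n_true_out = sum(
        1 for p in predictions if truth.labels[p.mip_id] in TRUE_CLASSES
    )
    precision = n_true_out / len(predictions) if predictions else None

    by_id = {p.mip_id: p for p in predictions}
    if recovered:
        good = sum(
            1
            for pid in recovered
            if set(by_id[pid].target_tf_ids) & truth.expected_targets.get(pid, frozenset())
        )
        target_accuracy: Optional[float] = good / len(recovered)
    else:
        target_accuracy = None

    recall = len(recovered) / len(planted) if planted else 0.0
    return EvalReport(
        recall=recall,
        precision=precision,
        target_accuracy=target_accuracy,
        per_class_counts=per_class,
        n_planted=len(planted),
        n_recovered=len(recovered),
        n_predictions=len(predictions),
    )


@dataclass(frozen=True)
class SweepGrid:
    """Ordered E-value cutoff lists for the three searches."""

    tier1_cutoffs: tuple[float, ...]
    tier2_cutoffs: tuple[float, ...]
    reverse_cutoffs: tuple[float, ...]

    def __post_init__(self) -> None:
        for name in ("tier1_cutoffs", "tier2_cutoffs", "reverse_cutoffs"):
            values = getattr(self, name)
            if not values:
                raise ValueError(f"{name} must be non-empty")
            if list(values) != sorted(values):
                raise ValueError(f"{name} must be sorted ascending")


SWEEP_COLUMNS = ["e1", "e2", "e3", "recall", "precision", "n_predictions"]


def sweep(
    fixture: Fixture,
    grid: SweepGrid,
    base_cfg: PipelineConfig | None = None,
    scheme: ScoringScheme | None = None,
) -> tuple[pd.DataFrame, dict]:
    """Run the pipeline over a cutoff grid; return (table, selected row).

    The table has one row per (e1, e2, e3) grid point, sorted by the
    cutoffs; ``selected`` is the recall-maximizing, most stringent row.
    Precision is NaN where no predictions were made.
    """
    base_cfg = base_cfg or PipelineConfig()
    builtin = BuiltinSearchBackend(scheme)

    e1_max = grid.tier1_cutoffs[-1]
    e2_max = max(grid.tier2_cutoffs[-1], e1_max)
    e3_max = grid.reverse_cutoffs[-1]

    # One search per stage at the loosest cutoff; tighter grid points are
    # pure re-thresholding through the precomputed backend.
    big = partition_by_length(fixture.proteome, base_cfg.max_mip_length)
    small = partition_by_length(fixture.proteome, base_cfg.small_protein_length)
    tier1_hits = (
        builtin.search_stage(fixture.tfs, big, e1_max, "tier1")
        if len(big)
        else []
    )
    tier2_hits = (
        builtin.search_stage(fixture.tfs, small, e2_max, "tier2")
        if len(small)
        else []
    )
    tf_ids = set(fixture.tfs.ids())
    forward_subjects = [
        sid
        for sid in dict.fromkeys(h.subject_id for h in tier2_hits)
        if sid not in tf_ids
    ]
    reverse_hits = (
        builtin.search_stage(
            fixture.proteome.subset(forward_subjects),
            fixture.tfs,
            e3_max,
            "reverse",
        )
        if forward_subjects
        else []
    )
    known = set(fixture.proteome.ids()) | tf_ids
    backend = PrecomputedSearchBackend(
        tier1_hits, tier2_hits, reverse_hits, known
    )

    rows = []
    for e1 in grid.tier1_cutoffs:
        for e2 in grid.tier2_cutoffs:
            for e3 in grid.reverse_cutoffs:
                cfg = replace(
                    base_cfg,
                    tier1_cutoff=e1,
                    tier2_cutoff=max(e2, e1),
                    reverse_cutoff=e3,
                )
                preds = run_pipeline(
                    fixture.proteome,
                    fixture.tfs,
                    fixture.unwanted,
                    cfg=cfg,
                    search_backend=backend,
                    domain_library=fixture.library,
                )
                report = evaluate(preds, fixture.truth)
                rows.append(
                    {
                        "e1": e1,
                        "e2": e2,
                        "e3": e3,
                        "recall": report.recall,
                        "precision": report.precision,
                        "n_predictions": report.n_predictions,
                    }
                )
    table = pd.DataFrame(rows, columns=SWEEP_COLUMNS).sort_values(
        ["e1", "e2", "e3"], kind="mergesort", ignore_index=True
    )
    best_recall = table["recall"].max()
    candidates = table[table["recall"] == best_recall].sort_values(
        ["e1", "e2", "e3"], kind="mergesort"
    )
    selected = candidates.iloc[0].to_dict()
    return table, selected
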