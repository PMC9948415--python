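"""Generation-stratified analysis and cross-generation ranking aggregation.

The full pipeline (train/test split, forest fitting, permutation-importance
ranking, top-x selection) is re-run independently within each 10-year birth
cohort. Age adjustment of the outcome is performed once on the pooled
population before stratification (per-stratum adjustment is available via a
flag). Across generations, each exposure's results are aggregated into the
number of generations in which it was selected as a top-ranked predictor
and its average rank over those generations.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .model import (
    ImportanceRanking,
    PredictionMetrics,
    RFParams,
    TuningGrid,
    default_grid,
    evaluate,
    fit_rf,
    null_metrics,
    permutation_importance,
    split_train_test,
    tune_rf,
)
from .selection import SelectionCurve, refit_topx, selection_curve


@dataclass
class AnalysisResult:
    """End-to-end result of one (sub)population's pipeline run."""

    label: str
    n: int
    tuned_params: RFParams
    tuning_table: pd.DataFrame | None
    metrics_final: PredictionMetrics
    metrics_null: PredictionMetrics
    ranking: ImportanceRanking
    curve: SelectionCurve
    chosen_x: int
    top_features: list[str]
    topx_metrics: Mapping[str, PredictionMetrics]
    skipped: bool = False


@dataclass
class GenerationResult(AnalysisResult):
    pass


def run_analysis(
    X: pd.DataFrame,
    y: np.ndarray | pd.Series,
    label: str = "total",
    params: RFParams | None = None,
    grid: TuningGrid | None = None,
    tune: bool = False,
    train_fraction: float = 0.8,
    cv_folds: int = 5,
    n_repeats: int = 5,
    selection_x_values: list[int] | None = None,
    selection_tolerance: float = 0.01,
    seed: int = 0,
) -> AnalysisResult:
    """Run split -> (optional tuning) -> fit -> null comparison -> importance
    -> top-x selection on one population.

    When ``tune`` is False and ``params`` is None, the defaults
    ``mtry = p/3, ntree = 500, nodesize = 5`` are used directly.
    """
    y = np.asarray(y, dtype=float)
    X_tr, X_te, y_tr, y_te = split_train_test(X, y, train_fraction=train_fraction, seed=seed)
    tuning_table = None
    if tune:
        g = grid if grid is not None else default_grid(X.shape[1], seed=seed)
        g.cv_folds = cv_folds
        params, tuning_table = tune_rf(X_tr, y_tr, g)
    elif params is None:
        params = RFParams(mtry=max(1, X.shape[1] // 3), ntree=500, nodesize=5)

    model = fit_rf(X_tr, y_tr, params, seed=seed)
    metrics_final = evaluate(model, X_te, y_te)
    metrics_null = null_metrics(y_tr, y_te)
    ranking = permutation_importance(model, X_te, y_te, n_repeats=n_repeats, seed=seed)
    curve = selection_curve(
        X_tr, y_tr, ranking, params,
        x_values=selection_x_values, cv_folds=cv_folds, seed=seed,
        tolerance=selection_tolerance,
    )
    top = ranking.top(curve.chosen_x)
    topx = refit_topx(X_tr, X_te, y_tr, y_te, top, params, seed=seed)
    return AnalysisResult(
        label=label, n=len(X), tuned_params=params, tuning_table=tuning_table,
        metrics_final=metrics_final, metrics_null=metrics_null, ranking=ranking,
        curve=curve, chosen_x=curve.chosen_x, top_features=top, topx_metrics=topx,
    )


def stratum_seed(master_seed: int, label: str) -> int:
    """Deterministic per-stratum sub-seed below 2**31."""
    return (int(master_seed) * 1000003 + zlib.crc32(label.encode())) % (2**31 - 1)


def run_stratified(
    X: pd.DataFrame,
    y: np.ndarray | pd.Series,
    generation_labels: Sequence[str],
    min_stratum_size: int = 100,
    seed: int = 0,
    **analysis_kwargs,
) -> list[GenerationResult]:
    """Run the full pipeline independently within each generation stratum.

    ``generation_labels`` assigns each row of ``X`` to exactly one
    generation. Strata smaller than ``min_stratum_size`` are flagged
    ``skipped`` and carry no model results. Each stratum draws its own seed
    from the master seed and its label, so results are independent of the
    processing order.
    """
    labels = pd.Series(list(generation_labels), index=X.index)
    if labels.isna().any():
        raise ValueError("every participant must carry a generation label")
    y = pd.Series(np.asarray(y, dtype=float), index=X.index)
    results: list[GenerationResult] = []
    for label in labels.drop_duplicates():
        mask = (labels == label).to_numpy()
        n = int(mask.sum())
        if n < min_stratum_size:
            import warnings

            warnings.warn(f"generation {label!r} has only {n} participants; skipped")
            results.append(
                GenerationResult(
                    label=str(label), n=n, tuned_params=RFParams(mtry=1),
                    tuning_table=None, metrics_final=None, metrics_null=None,
                    ranking=None, curve=None, chosen_x=0, top_features=[],
                    topx_metrics={}, skipped=True,
                )
            )
            continue
        res = run_analysis(
            X[mask], y[mask].to_numpy(), label=str(label),
            seed=stratum_seed(seed, str(label)), **analysis_kwargs,
        )
        results.append(GenerationResult(**res.__dict__))
    return results


def average_ranking(ranks_by_generation: Sequence[int | None]) -> tuple[int, float | None]:
    """Aggregate one exposure's per-generation ranks.

    Returns ``(times_selected, average_rank_if_selected)`` where the
    average divides the sum of the present ranks by the number of
    generations in which the exposure was selected; an exposure never
    selected yields ``(0, None)``.
    """
    present = [r for r in ranks_by_generation if r is not None and np.isfinite(r)]
    if not present:
        return 0, None
    return len(present), float(sum(present)) / len(present)


def cross_generation_table(results: Sequence[GenerationResult]) -> pd.DataFrame:
    """One row per exposure ever selected as a top-ranked predictor.

    Columns: per-generation rank where selected, ``times_selected`` and
    ``average_ranking``; ordered by descending times_selected, then
    ascending average ranking, then exposure name.
    """
    active = [r for r in results if not r.skipped]
    if not active:
        raise ValueError("no usable generation results")
    per_gen: dict[str, dict[str, int]] = {}
    for r in active:
        for rank, feat in enumerate(r.top_features, start=1):
            per_gen.setdefault(feat, {})[r.label] = rank
    rows = []
    for feat, ranks in per_gen.items():
        times, avg = average_ranking([ranks.get(r.label) for r in active])
        rows.append(
            {
                "exposure": feat,
                **{f"rank_{r.label}": ranks.get(r.label, np.nan) for r in active},
                "times_selected": times,
                "average_ranking": avg,
            }
        )
    table = pd.DataFrame(rows).sort_values(
        ["times_selected", "average_ranking", "exposure"],
        ascending=[False, True, True],
        kind="mergesort",
    )
    return table.reset_index(drop=True)
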