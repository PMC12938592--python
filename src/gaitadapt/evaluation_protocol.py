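"""Leave-one-subject-out evaluation and the reported metrics.

Each fold trains the estimator on all subjects but one, predicts the
held-out subject's full chronological window sequence and scores it
against that subject's metabolic ground-truth adaptation labels:

* band accuracy — percent of windows whose estimate falls within +/-10
  percentage points of the reference (boundary inclusive);
* MAE (percentage points), Pearson r, and R^2 = 1 - SSE/SST;
* Day-1 vs Day-6 paired t-tests on metabolic cost and on each
  variability indicator, plus per-indicator percent reductions.

Pooled numbers are means +/- sd over folds, each fold weighted equally.
"""

from __future__ import annotations

import logging
from dataclasses import replace

import numpy as np
from scipy import stats

from .adaptation_estimator import (
    EstimatorConfig,
    SubjectSequence,
    predict_stream,
    train,
)
from .types import EvaluationReport, FoldResult

__all__ = [
    "loso_folds",
    "band_accuracy",
    "regression_metrics",
    "paired_ttest",
    "run_loso",
]

log = logging.getLogger(__name__)

BAND_PP = 10.0  # +/- percentage points counted as an accurate estimate


def loso_folds(subject_ids: list[str]) -> list[tuple[list[str], str]]:
    """One (train_ids, test_id) fold per subject."""
    if len(subject_ids) < 2:
        raise ValueError("leave-one-subject-out needs at least 2 subjects")
    if len(set(subject_ids)) != len(subject_ids):
        raise ValueError("duplicate subject ids")
    return [
        ([s for s in subject_ids if s != test], test) for test in subject_ids
    ]


def band_accuracy(pred, ref, band: float = BAND_PP) -> float:
    """Percent of estimates with |pred - ref| <= band (inclusive)."""
    pred = np.asarray(pred, dtype=float)
    ref = np.asarray(ref, dtype=float)
    if pred.shape != ref.shape or pred.size == 0:
        raise ValueError("pred and ref must be equal-length, non-empty")
    # small absolute slack keeps the boundary inclusive under float round-off
    return 100.0 * float(np.mean(np.abs(pred - ref) <= band + 1e-9))


def regression_metrics(pred, ref) -> tuple[float, float, float]:
    """(MAE, Pearson r, R^2) of predictions against the reference.

    R^2 = 1 - SSE/SST and may be negative; r is NaN (flagged via log)
    when the reference is constant.
    """
    pred = np.asarray(pred, dtype=float)
    ref = np.asarray(ref, dtype=float)
    if pred.shape != ref.shape:
        raise ValueError("length mismatch")
    if pred.size < 3:
        raise ValueError("need at least 3 points")
    mae = float(np.mean(np.abs(pred - ref)))
    sst = float(np.sum((ref - ref.mean()) ** 2))
    if sst == 0.0:
        log.warning("constant reference: r undefined")
        return mae, float("nan"), float("nan")
    r = float(stats.pearsonr(pred, ref).statistic)
    r2 = 1.0 - float(np.sum((pred - ref) ** 2)) / sst
    return mae, r, r2


def paired_ttest(day1, day6) -> tuple[float, float, int]:
    """Two-sided paired t-test on per-subject (day1 - day6) differences."""
    day1 = np.asarray(day1, dtype=float)
    day6 = np.asarray(day6, dtype=float)
    if day1.shape != day6.shape or day1.size < 2:
        raise ValueError("need equal-length paired samples, n >= 2")
    if np.ptp(day1 - day6) == 0.0 and np.all(day1 == day6):
        return 0.0, 1.0, int(day1.size)
    res = stats.ttest_rel(day1, day6)
    t, p = float(res.statistic), float(res.pvalue)
    if not np.isfinite(t):
        log.warning("degenerate paired t-test (zero-variance differences)")
    return t, p, int(day1.size)


def _score_fold(
    test: SubjectSequence, pred: np.ndarray, note: str = ""
) -> FoldResult:
    mae, r, r2 = regression_metrics(pred, test.labels)
    return FoldResult(
        test_subject=test.subject_id,
        band_accuracy=band_accuracy(pred, test.labels),
        mae=mae,
        pearson_r=r,
        r2=r2,
        n_windows=int(test.labels.size),
        note=note,
    )


def run_loso(
    sequences: list[SubjectSequence],
    config: EstimatorConfig | None = None,
    predictor: str = "lstm",
) -> EvaluationReport:
    """Cross-validated evaluation over per-subject sequences.

    ``predictor`` selects the model under test: ``"lstm"`` trains the
    recurrent estimator per fold (scaler fitted on training subjects
    only); ``"oracle"`` replays the reference labels (upper bound for
    harness checks); ``"constant50"`` always answers 50%.  A fold whose
    training fails is flagged in its result and the report is still
    produced.
    """
    config = config or EstimatorConfig()
    by_id = {s.subject_id: s for s in sequences}
    report = EvaluationReport()
    for train_ids, test_id in loso_folds(list(by_id)):
        test = by_id[test_id]
        try:
            if predictor == "oracle":
                pred = test.labels.copy()
            elif predictor == "constant50":
                pred = np.full_like(test.labels, 50.0)
            elif predictor == "lstm":
                # scaler and any virtual training subjects are derived
                # inside train() from the training fold only
                fitted = train([by_id[s] for s in train_ids], config=config)
                pred = predict_stream(fitted, test.features)
            else:
                raise ValueError(f"unknown predictor {predictor!r}")
            report.per_fold.append(_score_fold(test, pred))
        except (FloatingPointError, RuntimeError) as exc:  # fold failure
            log.error("fold %s failed: %s", test_id, exc)
            report.per_fold.append(
                FoldResult(
                    test_subject=test_id,
                    band_accuracy=float("nan"),
                    mae=float("nan"),
                    pearson_r=float("nan"),
                    r2=float("nan"),
                    n_windows=int(test.labels.size),
                    converged=False,
                    note=str(exc),
                )
            )
    ok = [f for f in report.per_fold if f.converged]
    for metric in ("band_accuracy", "mae", "pearson_r", "r2"):
        vals = np.array([getattr(f, metric) for f in ok], dtype=float)
        report.pooled[metric] = (
            (float(np.mean(vals)), float(np.std(vals, ddof=1) if vals.size > 1 else 0.0))
            if vals.size
            else (float("nan"), float("nan"))
        )
    return report


def multi_seed_loso(
    sequences: list[SubjectSequence],
    config: EstimatorConfig,
    seeds: list[int],
) -> list[EvaluationReport]:
    """Repeat the LOSO evaluation with different training seeds."""
    return [
        run_loso(sequences, config=replace(config, seed=int(s)), predictor="lstm")
        for s in seeds
    ]
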