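"""Model validation: repeated k-fold cross-validation and metrics.

The protocol is 50 repetitions of fivefold cross-validation. Each repetition
draws a fresh random partition into k folds; the model is fitted on every
combination of k-1 folds and scored on the held-out fold; the repetition's
value for each metric is the mean over its k folds. The overall estimate is
the mean over repetition values with a 95% confidence interval computed by
the normal approximation (mean +/- 1.96 * sd / sqrt(repetitions)); a
percentile bootstrap across repetition values is available as an option.

Metrics: RMSE for PROM predictions, Harrell's concordance index and a
fixed-time Brier score for survival risk. A pair is usable for concordance
when the member with the earlier time had the event; tied risk scores count
0.5.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import UndefinedMetricError, ValidationError

__all__ = [
    "CVResult",
    "kfold_partition",
    "repeated_cv",
    "prom_rmse",
    "concordance_index",
    "brier_score",
]


@dataclass(frozen=True)
class CVResult:
    """Cross-validated estimate of one metric."""

    metric_name: str
    per_repetition_values: tuple[float, ...]
    overall_mean: float
    ci_low: float
    ci_high: float
    ci_method: str = "normal"
    n_failed_repetitions: int = 0

    def to_dict(self) -> dict:
        return {
            "metric": self.metric_name,
            "overall_mean": self.overall_mean,
            "ci_low": self.ci_low,
            "ci_high": self.ci_high,
            "ci_method": self.ci_method,
            "repetitions": len(self.per_repetition_values),
            "failed_repetitions": self.n_failed_repetitions,
            "per_repetition_values": list(self.per_repetition_values),
        }


def kfold_partition(n: int, k: int, seed) -> list[np.ndarray]:
    """Random partition of range(n) into k folds of near-equal size.

    Fold sizes differ by at most one; the partition is disjoint, exhaustive,
    and reproducible under the seed (which may be an int or a Generator).
    """
    if k < 2:
        raise ValidationError(f"k must be >= 2, got {k}")
    if n < k:
        raise ValidationError(f"need at least k={k} records, got n={n}")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    perm = rng.permutation(n)
    return [np.sort(fold) for fold in np.array_split(perm, k)]


def _take(data, idx: np.ndarray):
    if isinstance(data, pd.DataFrame):
        return data.iloc[idx]
    if hasattr(data, "subset"):
        return data.subset(idx)
    if isinstance(data, np.ndarray):
        return data[idx]
    return [data[i] for i in idx]


def _length(data) -> int:
    if isinstance(data, (pd.DataFrame, np.ndarray, list, tuple)):
        return len(data)
    if hasattr(data, "n"):
        return int(data.n)
    return len(data)


def repeated_cv(
    data,
    fit_fn,
    metric_fns: dict,
    repetitions: int = 50,
    k: int = 5,
    seed: int = 0,
    ci_method: str = "normal",
    bootstrap_samples: int = 2000,
) -> dict[str, CVResult]:
    """Repeated k-fold cross-validation of ``fit_fn`` under ``metric_fns``.

    ``fit_fn(train)`` returns a fitted model; each ``metric_fns[name](model,
    test)`` returns a scalar. ``data`` may be a DataFrame, an object with a
    ``subset(indices)`` method (e.g. SurvivalDataset), an array, or a list.

    A repetition in which any fold fit or metric raises is recorded as failed
    and excluded from the averages; if more than 20% of repetitions fail the
    run aborts.
    """
    n = _length(data)
    rng = np.random.default_rng(seed)
    per_rep: dict[str, list[float]] = {name: [] for name in metric_fns}
    n_failed = 0
    for _ in range(repetitions):
        folds = kfold_partition(n, k, rng)
        fold_vals: dict[str, list[float]] = {name: [] for name in metric_fns}
        try:
            for test_idx in folds:
                train_idx = np.setdiff1d(np.arange(n), test_idx)
                model = fit_fn(_take(data, train_idx))
                test = _take(data, test_idx)
                for name, fn in metric_fns.items():
                    fold_vals[name].append(float(fn(model, test)))
        except Exception:
            n_failed += 1
            if n_failed > 0.2 * repetitions:
                raise ValidationError(
                    f"more than 20% of repetitions failed "
                    f"({n_failed}/{repetitions}); aborting"
                )
            continue
        for name in metric_fns:
            per_rep[name].append(float(np.mean(fold_vals[name])))

    results = {}
    for name, values in per_rep.items():
        if not values:
            raise ValidationError(f"no successful repetitions for metric {name!r}")
        arr = np.asarray(values)
        mean = float(arr.mean())
        if ci_method == "normal":
            half = 1.96 * float(arr.std(ddof=1)) / np.sqrt(arr.size) if arr.size > 1 else 0.0
            lo, hi = mean - half, mean + half
        elif ci_method == "bootstrap":
            boot = rng.choice(arr, size=(bootstrap_samples, arr.size), replace=True)
            means = boot.mean(axis=1)
            lo, hi = (float(np.percentile(means, 2.5)),
                      float(np.percentile(means, 97.5)))
        else:
            raise ValidationError(f"unknown ci_method {ci_method!r}")
        results[name] = CVResult(
            metric_name=name,
            per_repetition_values=tuple(values),
            overall_mean=mean,
            ci_low=lo,
            ci_high=hi,
            ci_method=ci_method,
            n_failed_repetitions=n_failed,
        )
    return results


def prom_rmse(predictions, truths) -> float:
    """Root mean squared error of (raw) PROM predictions."""
    p = np.asarray(predictions, dtype=float)
    t = np.asarray(truths, dtype=float)
    if p.size != t.size or p.size == 0:
        raise ValidationError("predictions and truths must be non-empty and aligned")
    return float(np.sqrt(np.mean((p - t) ** 2)))


def concordance_index(risk_scores, times, events) -> float:
    """Harrell's concordance index (higher score = higher risk).

    A pair (i, j) is usable when t_i < t_j and subject i had the event; it is
    concordant when score_i > score_j, and tied scores contribute 0.5.
    """
    s = np.asarray(risk_scores, dtype=float)
    t = np.asarray(times, dtype=float)
    d = np.asarray(events, dtype=int)
    if not (s.size == t.size == d.size):
        raise ValidationError("risk_scores, times, events must align")
    # vectorised pairwise comparison; fine up to a few thousand rows
    earlier = (t[:, None] < t[None, :]) & (d[:, None] == 1)
    n_usable = int(earlier.sum())
    if n_usable == 0:
        raise UndefinedMetricError("no usable pairs for concordance")
    conc = (s[:, None] > s[None, :]) & earlier
    ties = (s[:, None] == s[None, :]) & earlier
    return float((conc.sum() + 0.5 * ties.sum()) / n_usable)


def brier_score(predicted_risk, outcomes) -> float:
    """Fixed-time Brier score: mean squared error of predicted event risk.

    ``outcomes`` are 0/1 event statuses already resolved at the horizon
    (records censored before the horizon must be excluded upstream).
    """
    p = np.asarray(predicted_risk, dtype=float)
    o = np.asarray(outcomes, dtype=float)
    if p.size != o.size or p.size == 0:
        raise ValidationError("predicted_risk and outcomes must be non-empty and aligned")
    if np.any((p < 0) | (p > 1)):
        raise ValidationError("predicted risks must lie in [0, 1]")
    return float(np.mean((p - o) ** 2))
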