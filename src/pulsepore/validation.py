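"""Robustness checks for PLS models of PEF response data.

Three protocols, all seed-reproducible:

* repeated random train/test splits (default 500 repeats at a 2:1 ratio),
  summarising the distribution of training and held-out R²;
* leave-one-out cross-validated Q² = 1 − PRESS/SStot, refitting the
  scaling and the model on the remaining rows in every fold;
* the Y-scrambling (response permutation) test: the model is refit on
  shuffled responses and its R²/Q² are recorded against the correlation
  between the shuffled and original response, to show that performance
  collapses as the shuffled response decorrelates — i.e. that the real
  model is not a chance correlation.

Randomness policy: each caller supplies one integer seed; per-repeat
sub-streams are derived from (seed, repeat index) so results do not
depend on execution order.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .pls import (
    SampleTable,
    autoscale,
    fit_pls,
    predict,
    r2_score_corr,
    r2_score_ss,
)

__all__ = [
    "SplitResult",
    "PermutationRecord",
    "repeated_split_validation",
    "loo_q2",
    "y_permutation_test",
]

logger = logging.getLogger(__name__)


@dataclass
class SplitResult:
    """Statistics of one random train/test split."""

    repeat_index: int
    train_ids: list[str]
    test_ids: list[str]
    r2_train: float
    r2_test_corr: float
    r2_test_ss: float


@dataclass
class PermutationRecord:
    """One Y-scrambling refit.

    ``y_correlation`` is the Pearson correlation between the permuted and
    original responses; record 0 is always the identity permutation.
    """

    perm_index: int
    y_correlation: float
    r2: float
    q2: float


def _fit_eval(train: SampleTable, test: SampleTable, n_components: int):
    Xs, ys, scaler = autoscale(train)
    model = fit_pls(Xs, ys, n_components, scaler=scaler)
    r2_train = r2_score_ss(train.response(), predict(model, train))
    pred_test = predict(model, test)
    return (
        r2_train,
        r2_score_corr(test.response(), pred_test),
        r2_score_ss(test.response(), pred_test),
    )


def repeated_split_validation(
    table: SampleTable,
    n_repeats: int = 500,
    train_fraction: float = 2.0 / 3.0,
    seed: int = 0,
    n_components: int = 1,
) -> tuple[list[SplitResult], dict]:
    """Fit the PLS pipeline on many random train/test partitions.

    Each repeat draws a uniform random partition without replacement with
    ``round(n * train_fraction)`` training rows (8:4 for the 12-sample
    reference table).  Splits whose training response has zero variance
    are recorded as failed and excluded, with a logged count.

    Returns the per-repeat results and a summary dict with the mean and
    sd of each statistic plus the failure count.
    """
    if n_repeats < 1:
        raise ValueError("n_repeats must be >= 1")
    n = len(table)
    n_train = int(round(n * train_fraction))
    n_test = n - n_train
    if n_train < 2 or n_test < 2:
        raise ValueError(
            f"degenerate split sizes: {n_train} train / {n_test} test from {n} rows"
        )
    # partitions are drawn over sorted ids so results do not depend on the
    # row order of the input table
    ids = np.sort(np.asarray(table.sample_ids))
    results: list[SplitResult] = []
    n_failed = 0
    for i in range(n_repeats):
        rng = np.random.default_rng([seed, i])
        perm = rng.permutation(n)
        train_ids = sorted(ids[perm[:n_train]].tolist())
        test_ids = sorted(ids[perm[n_train:]].tolist())
        train = table.select_ids(train_ids)
        test = table.select_ids(test_ids)
        try:
            r2_train, r2_corr, r2_ss = _fit_eval(train, test, n_components)
        except ValueError:
            n_failed += 1
            continue
        results.append(
            SplitResult(
                repeat_index=i, train_ids=train_ids, test_ids=test_ids,
                r2_train=r2_train, r2_test_corr=r2_corr, r2_test_ss=r2_ss,
            )
        )
    if n_failed:
        logger.warning("%d of %d splits failed (zero-variance partition)", n_failed, n_repeats)
    summary = {"n_repeats": n_repeats, "n_failed": n_failed}
    for key in ("r2_train", "r2_test_corr", "r2_test_ss"):
        vals = np.array([getattr(r, key) for r in results])
        summary[f"mean_{key}"] = float(vals.mean())
        summary[f"sd_{key}"] = float(vals.std(ddof=1))
    return results, summary


def loo_q2(table: SampleTable, n_components: int = 1) -> float:
    """Leave-one-out cross-validated R² (Q²) of the PLS pipeline.

    Q² = 1 − PRESS/SStot, where PRESS accumulates the squared prediction
    error of each row under a model refit — autoscaling included — on the
    other rows, and SStot is about the full-table mean.  Q² of a real
    signal approaches R²; Q² of pure noise is negative because PRESS
    exceeds SStot.
    """
    n = len(table)
    if n < 3:
        raise ValueError("leave-one-out requires at least 3 rows")
    y = table.response()
    press = 0.0
    for i in range(n):
        keep = [j for j in range(n) if j != i]
        train = SampleTable(table.df.iloc[keep].reset_index(drop=True))
        Xs, ys, scaler = autoscale(train)
        model = fit_pls(Xs, ys, n_components, scaler=scaler)
        pred = predict(model, table.df.iloc[[i]])
        press += float((y[i] - pred[0]) ** 2)
    sstot = float(((y - y.mean()) ** 2).sum())
    if sstot == 0.0:
        raise ValueError("zero response variance")
    return 1.0 - press / sstot


def y_permutation_test(
    table: SampleTable,
    n_perm: int = 500,
    seed: int = 0,
    n_components: int = 1,
) -> tuple[list[PermutationRecord], dict]:
    """Y-scrambling test: refit on permuted responses, track collapse.

    Record 0 is the identity permutation (the unpermuted model); records
    1..n_perm each refit the full pipeline on a seeded random permutation
    of the response column.  The trend summary reports the Spearman rank
    correlation between |y_correlation| and R² across records — positive
    when model quality genuinely tracks the response (the hallmark of a
    non-chance model).
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    # canonical row order so the drawn permutations do not depend on how
    # the caller ordered the table
    table = SampleTable(
        table.df.sort_values("sample_id").reset_index(drop=True)
    )
    y0 = table.response()
    records: list[PermutationRecord] = []
    n_failed = 0
    for k in range(n_perm + 1):
        if k == 0:
            y_perm = y0.copy()
        else:
            rng = np.random.default_rng([seed, k])
            y_perm = y0[rng.permutation(len(y0))]
        perm_table = table.with_response(y_perm)
        try:
            Xs, ys, scaler = autoscale(perm_table)
            model = fit_pls(Xs, ys, n_components, scaler=scaler)
            r2 = r2_score_ss(y_perm, predict(model, perm_table))
            q2 = loo_q2(perm_table, n_components=n_components)
        except ValueError:
            n_failed += 1
            continue
        ycorr = float(np.corrcoef(y_perm, y0)[0, 1])
        records.append(PermutationRecord(perm_index=k, y_correlation=ycorr, r2=r2, q2=q2))
    if n_failed:
        logger.warning("%d permutation refits failed", n_failed)
    abs_corr = [abs(r.y_correlation) for r in records]
    rho_r2, _ = stats.spearmanr(abs_corr, [r.r2 for r in records])
    rho_q2, _ = stats.spearmanr(abs_corr, [r.q2 for r in records])
    summary = {
        "n_perm": n_perm,
        "n_failed": n_failed,
        "spearman_abs_ycorr_vs_r2": float(rho_r2),
        "spearman_abs_ycorr_vs_q2": float(rho_q2),
        "r2_unpermuted": records[0].r2 if records else float("nan"),
        "q2_unpermuted": records[0].q2 if records else float("nan"),
    }
    return records, summary
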