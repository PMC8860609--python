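"""Greedy forward-selected linear regression of per-window SSU density.

One model per footprint length: windows are split 60/20/20 into train, test
and validation sets, independently 20 times.  Selection proposes, at each
step, the feature whose ordinary-least-squares refit most raises the
Spearman correlation between predictions and observed density on the
training set, and accepts it only while the test-set correlation keeps
improving by more than 0.001; the final model is scored on the validation
set.  Feature attribution uses partial Spearman correlation (rank-transform
everything, project out the controls, correlate the residuals).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

IMPROVE_TOL = 1e-3


@dataclass
class SplitPlan:
    replicate: int
    train: np.ndarray
    test: np.ndarray
    validation: np.ndarray
    seed: int = 0

    @property
    def n(self) -> int:
        return len(self.train) + len(self.test) + len(self.validation)


@dataclass
class GreedyModel:
    features: list[str]
    coef: np.ndarray
    intercept: float
    train_trace: list[float]
    test_trace: list[float]
    validation_rho: float = np.nan
    validation_p: float = np.nan
    replicate: int = 0
    length_class: int | None = None
    flagged: bool = False

    def predict(self, X: pd.DataFrame) -> np.ndarray:
        if not self.features:
            return np.full(len(X), self.intercept)
        return X[self.features].to_numpy() @ self.coef + self.intercept


def make_splits(
    n_windows: int,
    seed: int,
    n_replicates: int = 20,
    fractions: tuple[float, float, float] = (0.6, 0.2, 0.2),
) -> list[SplitPlan]:
    """20 independent random train/test/validation partitions of the windows."""
    if n_windows < 10:
        raise ValueError("need at least 10 windows to split 60/20/20")
    if not np.isclose(sum(fractions), 1.0):
        raise ValueError("fractions must sum to 1")
    rng = np.random.default_rng(seed)
    n_train = int(round(fractions[0] * n_windows))
    n_test = int(round(fractions[1] * n_windows))
    plans = []
    for rep in range(1, n_replicates + 1):
        perm = rng.permutation(n_windows)
        plans.append(
            SplitPlan(
                replicate=rep,
                train=np.sort(perm[:n_train]),
                test=np.sort(perm[n_train : n_train + n_test]),
                validation=np.sort(perm[n_train + n_test :]),
                seed=seed,
            )
        )
    return plans


def _spearman(a: np.ndarray, b: np.ndarray) -> float:
    if np.std(a) == 0 or np.std(b) == 0:
        return np.nan
    return float(stats.spearmanr(a, b).statistic)


def _ols(X: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, float]:
    A = np.column_stack([X, np.ones(len(X))])
    beta, *_ = np.linalg.lstsq(A, y, rcond=None)
    return beta[:-1], float(beta[-1])


def greedy_fit(
    features: pd.DataFrame,
    target: np.ndarray,
    plan: SplitPlan,
    improve_tol: float = IMPROVE_TOL,
    select_on: str = "train",
    stop_on: str = "test",
    length_class: int | None = None,
) -> GreedyModel:
    """Forward feature selection with an OLS refit and Spearman objective.

    At each step the candidate maximizing the Spearman correlation on the
    ``select_on`` split is proposed; it is accepted only when the refit
    model's correlation on the ``stop_on`` split improves on the previous
    accepted step by more than ``improve_tol``.  The default (propose on
    train, stop on test) keeps candidate ranking independent of the test set
    while letting the stop rule do what it exists for - halting before the
    model starts fitting training noise; a pure in-sample stop would accept
    noise features indefinitely at desk-scale n because every added OLS
    feature raises the in-sample correlation.  Candidate ties break by
    column order.  An all-constant target yields an empty, flagged model.
    """
    if select_on not in ("train", "test") or stop_on not in ("train", "test"):
        raise ValueError("select_on and stop_on must be 'train' or 'test'")
    y = np.asarray(target, dtype=float)
    Xall = features.to_numpy(dtype=float)
    cols = list(features.columns)
    tr, te = plan.train, plan.test
    sel_idx = tr if select_on == "train" else te
    stop_idx = tr if stop_on == "train" else te

    if np.std(y[tr]) == 0:
        logger.warning("all-constant training target; empty model")
        return GreedyModel([], np.array([]), float(np.mean(y[tr])), [], [],
                           replicate=plan.replicate, length_class=length_class,
                           flagged=True)

    selected: list[int] = []
    train_trace: list[float] = []
    test_trace: list[float] = []
    current = 0.0
    remaining = list(range(len(cols)))
    while remaining:
        best_rho, best_j = -np.inf, None
        for j in remaining:
            idx = selected + [j]
            coef, b0 = _ols(Xall[np.ix_(tr, idx)], y[tr])
            pred = Xall[np.ix_(sel_idx, idx)] @ coef + b0
            rho = _spearman(pred, y[sel_idx])
            if np.isnan(rho):
                continue
            if rho > best_rho:
                best_rho, best_j = rho, j
        if best_j is None:
            break
        idx = selected + [best_j]
        coef, b0 = _ols(Xall[np.ix_(tr, idx)], y[tr])
        stop_rho = _spearman(Xall[np.ix_(stop_idx, idx)] @ coef + b0, y[stop_idx])
        if not np.isfinite(stop_rho) or stop_rho <= current + improve_tol:
            break
        selected.append(best_j)
        remaining.remove(best_j)
        current = stop_rho
        train_trace.append(_spearman(Xall[np.ix_(tr, selected)] @ coef + b0, y[tr]))
        test_trace.append(_spearman(Xall[np.ix_(te, selected)] @ coef + b0, y[te]))

    if selected:
        coef, b0 = _ols(Xall[np.ix_(tr, selected)], y[tr])
    else:
        coef, b0 = np.array([]), float(np.mean(y[tr]))
    model = GreedyModel(
        features=[cols[j] for j in selected],
        coef=coef,
        intercept=b0,
        train_trace=train_trace,
        test_trace=test_trace,
        replicate=plan.replicate,
        length_class=length_class,
    )
    rho, p = evaluate(model, features, y, plan.validation)
    model.validation_rho, model.validation_p = rho, p
    return model


def evaluate(
    model: GreedyModel, features: pd.DataFrame, target: np.ndarray, subset: np.ndarray
) -> tuple[float, float]:
    """Spearman rho (average ranks for ties) and its t-approximation p-value."""
    subset = np.asarray(subset)
    if len(subset) < 3:
        return np.nan, np.nan
    pred = model.predict(features.iloc[subset])
    obs = np.asarray(target, dtype=float)[subset]
    if np.std(pred) == 0 or np.std(obs) == 0:
        return np.nan, np.nan
    res = stats.spearmanr(pred, obs)
    return float(res.statistic), float(res.pvalue)


def partial_spearman(
    x: np.ndarray, y: np.ndarray, controls: np.ndarray | None = None
) -> tuple[float, float]:
    """Rank-based partial correlation of x and y given control covariates.

    All variables are rank-transformed (average ranks); x and y are
    residualized on the controls (plus intercept) by least squares; the
    partial coefficient is the Pearson correlation of the residuals, with a
    t-approximation p-value on n - k - 2 degrees of freedom.  Constant or
    rank-deficient control columns are dropped with a log message.
    """
    x = stats.rankdata(np.asarray(x, dtype=float))
    y = stats.rankdata(np.asarray(y, dtype=float))
    n = len(x)
    if controls is None or (hasattr(controls, "size") and controls.size == 0):
        k = 0
        rx, ry = x - x.mean(), y - y.mean()
    else:
        C = np.atleast_2d(np.asarray(controls, dtype=float))
        if C.shape[0] != n:
            C = C.T
        C = np.apply_along_axis(stats.rankdata, 0, C)
        keep = C.std(axis=0) > 0
        if not keep.all():
            logger.info("dropping %d constant control columns", (~keep).sum())
            C = C[:, keep]
        A = np.column_stack([C, np.ones(n)])
        k = np.linalg.matrix_rank(A) - 1
        rx = x - A @ np.linalg.lstsq(A, x, rcond=None)[0]
        ry = y - A @ np.linalg.lstsq(A, y, rcond=None)[0]
    # a residual that is zero to numerical precision means the variable is
    # fully explained by the controls: the partial correlation is 0
    if rx.std() <= 1e-10 * x.std() or ry.std() <= 1e-10 * y.std():
        return 0.0, 1.0
    r = float(np.corrcoef(rx, ry)[0, 1])
    df = n - k - 2
    if df <= 0:
        return r, np.nan
    r_ = min(max(r, -0.999999999), 0.999999999)
    tstat = r_ * np.sqrt(df / (1 - r_**2))
    p = 2 * stats.t.sf(abs(tstat), df)
    return r, float(p)


def folding_only_fit(
    folding_features: pd.DataFrame,
    target: np.ndarray,
    plan: SplitPlan,
    main_plan: SplitPlan | None = None,
    other_features: pd.DataFrame | None = None,
    mrna_levels: np.ndarray | None = None,
    improve_tol: float = IMPROVE_TOL,
) -> tuple[GreedyModel, tuple[float, float]]:
    """Folding-energy-only predictor evaluated against the main run's split.

    Trains a greedy model restricted to the folding columns on the same
    split plan as the main predictor (a differing ``main_plan`` is a hard
    error - the comparison is only fair on identical validation windows) and
    reports the partial Spearman correlation between its validation-set
    predictions and the observed density, controlling for the non-folding
    features and mRNA levels.
    """
    if main_plan is not None:
        same = (
            np.array_equal(plan.train, main_plan.train)
            and np.array_equal(plan.test, main_plan.test)
            and np.array_equal(plan.validation, main_plan.validation)
        )
        if not same:
            raise ValueError("folding-only fit must reuse the main run's split indices")
    model = greedy_fit(folding_features, target, plan, improve_tol=improve_tol)
    val = plan.validation
    pred = model.predict(folding_features.iloc[val])
    obs = np.asarray(target, dtype=float)[val]
    blocks = []
    if other_features is not None:
        blocks.append(other_features.iloc[val].to_numpy(dtype=float))
    if mrna_levels is not None:
        blocks.append(np.asarray(mrna_levels, dtype=float)[val][:, None])
    controls = np.hstack(blocks) if blocks else None
    return model, partial_spearman(pred, obs, controls)


@dataclass
class RegressionReport:
    """Per-length replicate correlations plus selection-frequency tables."""

    validation: pd.DataFrame          # columns: length, replicate, rho, p
    frequency: pd.DataFrame           # index feature, columns length, values 0..20
    partial: pd.DataFrame | None = None

    @property
    def median_rho(self) -> pd.Series:
        return self.validation.groupby("length")["rho"].median()


def run_regression(
    features: pd.DataFrame,
    targets_by_length: dict[int, np.ndarray],
    seed: int,
    n_replicates: int = 20,
    improve_tol: float = IMPROVE_TOL,
) -> tuple[RegressionReport, dict[int, list[GreedyModel]]]:
    """Fit the per-length greedy models over all split replicates."""
    n = len(features)
    plans = make_splits(n, seed, n_replicates=n_replicates)
    rows, models = [], {}
    freq = pd.DataFrame(0, index=features.columns,
                        columns=sorted(targets_by_length))
    for length, target in sorted(targets_by_length.items()):
        models[length] = []
        for plan in plans:
            m = greedy_fit(features, target, plan, improve_tol=improve_tol,
                           length_class=length)
            models[length].append(m)
            rows.append({"length": length, "replicate": plan.replicate,
                         "rho": m.validation_rho, "p": m.validation_p,
                         "n_features": len(m.features)})
            for f in m.features:
                freq.loc[f, length] += 1
    return RegressionReport(pd.DataFrame(rows), freq), models
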