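"""Model objects for CIMP-status prediction from gene expression.

Three estimators share one sparse-logistic machinery:

* :class:`LassoLogisticModel` — one tissue, L1-penalized logistic regression.
* :class:`CombinedLassoModel` — samples pooled across tissues, one shared
  coefficient vector, per-tissue unpenalized intercepts.
* :class:`GroupLassoModel` — one coefficient vector per tissue, with a
  group-lasso penalty on each gene's cross-tissue coefficient block, so the
  *set* of predictive genes is shared while the coefficients may differ.

Each ``fit(lam)`` returns a :class:`SparseLogisticResults`.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import _solver
from .._labels import to_binary

POSITIVE = "positive"


@dataclass
class PredictionTask:
    """Standardized expression features aligned with CIMP labels."""

    X: pd.DataFrame  # samples × genes, standardized within tissue
    y: pd.Series  # 1 = CIMP-positive, 0 = CIMP-negative
    tissue: str = ""

    def __post_init__(self):
        if not self.X.index.equals(self.y.index):
            raise ValueError("features must be row-aligned with labels")
        if self.y.nunique() < 2:
            warnings.warn(f"task {self.tissue!r} contains a single class")

    @property
    def genes(self) -> pd.Index:
        return self.X.columns

    @property
    def y_sign(self) -> np.ndarray:
        return np.where(self.y.to_numpy() > 0, 1.0, -1.0)


def prepare_features(
    expression: pd.DataFrame, labels: pd.Series, tissue: str = ""
) -> PredictionTask:
    """Build a prediction task from an RPKM matrix (genes × samples) and a
    CIMP call.

    Sample ids are intersected; expression is transformed by log2(RPKM + 1)
    and each gene standardized to zero mean / unit variance within the
    tissue.  Constant genes are dropped.
    """
    common = expression.columns.intersection(labels.index)
    if len(common) == 0:
        raise ValueError("no overlap between expression samples and CIMP call")
    y = to_binary(labels.loc[common]).astype(int)
    if (y == 1).sum() < 2 or (y == 0).sum() < 2:
        warnings.warn(
            f"tissue {tissue!r} has < 2 samples in one CIMP class; "
            "downstream CV will exclude it"
        )
    logx = np.log2(expression[common].astype(float) + 1.0).T  # samples × genes
    sd = logx.std(axis=0, ddof=0)
    keep = sd > 0
    if (~keep).any():
        logx = logx.loc[:, keep]
        sd = sd[keep]
    X = (logx - logx.mean(axis=0)) / sd
    return PredictionTask(X=X, y=y, tissue=tissue)


def majority_baseline(labels) -> float:
    """Accuracy of the majority-class ('random') predictor."""
    s = pd.Series(labels)
    if s.empty:
        raise ValueError("need at least one label")
    return float(s.value_counts(normalize=True).iloc[0])


@dataclass
class SparseLogisticResults:
    """Fitted sparse logistic model: coefficients, intercepts, selection."""

    method: str
    coef: pd.DataFrame  # genes × tissues (single column for lasso/combined)
    intercepts: pd.Series  # per tissue
    lam: float
    objective: float
    n_iter: int
    converged: bool

    @property
    def selected_genes(self) -> list[str]:
        norms = np.linalg.norm(self.coef.to_numpy(), axis=1)
        return list(self.coef.index[norms > _solver.SELECT_TOL])

    def decision_function(self, X: pd.DataFrame, tissue: str | None = None) -> pd.Series:
        col = tissue if tissue in self.coef.columns else self.coef.columns[0]
        icol = tissue if tissue in self.intercepts.index else self.intercepts.index[0]
        w = self.coef[col].reindex(X.columns).fillna(0.0).to_numpy()
        return pd.Series(X.to_numpy() @ w + self.intercepts[icol], index=X.index)

    def predict(self, X: pd.DataFrame, tissue: str | None = None) -> pd.Series:
        return (self.decision_function(X, tissue) > 0).astype(int)

    def summary(self) -> str:
        sel = self.selected_genes
        lines = [
            f"{self.method} logistic fit — lam={self.lam:.4g}, "
            f"objective={self.objective:.6g}, iterations={self.n_iter}, "
            f"converged={self.converged}",
            f"selected genes: {len(sel)} / {len(self.coef)}",
        ]
        show = self.coef.loc[sel].head(10)
        if not show.empty:
            lines.append(show.round(4).to_string())
        return "\n".join(lines)


class LassoLogisticModel:
    """L1-penalized logistic regression for one tissue."""

    def __init__(self, task: PredictionTask, max_iter: int = 5000, tol: float = 1e-7):
        self.task = task
        self.max_iter = max_iter
        self.tol = tol

    @property
    def lambda_max(self) -> float:
        X = self.task.X.to_numpy()
        n = X.shape[0]
        return _solver.lasso_lambda_max(
            X, self.task.y_sign, np.full(n, 1.0 / n), np.ones((n, 1))
        )

    def fit(self, lam: float) -> SparseLogisticResults:
        return self.fit_path([lam])[0]

    def fit_path(self, lams) -> list[SparseLogisticResults]:
        X = self.task.X.to_numpy()
        fits = _solver.fit_lasso_path(
            X, self.task.y_sign, lams, max_iter=self.max_iter, tol=self.tol
        )
        tissue = self.task.tissue or "all"
        return [
            SparseLogisticResults(
                method="lasso",
                coef=pd.DataFrame({tissue: w}, index=self.task.genes),
                intercepts=pd.Series({tissue: c[0]}),
                lam=float(lam),
                objective=info.objective,
                n_iter=info.n_iter,
                converged=info.converged,
            )
            for lam, (w, c, info) in zip(lams, fits)
        ]


class CombinedLassoModel:
    """One lasso over all tissues pooled, per-tissue unpenalized intercepts."""

    def __init__(self, tasks: list[PredictionTask], max_iter: int = 5000, tol: float = 1e-7):
        genes = tasks[0].genes
        for t in tasks[1:]:
            if not t.genes.equals(genes):
                raise ValueError("tasks must share the same gene universe")
        self.tasks = tasks
        self.genes = genes
        self.max_iter = max_iter
        self.tol = tol
        self._X = np.vstack([t.X.to_numpy() for t in tasks])
        self._y = np.concatenate([t.y_sign for t in tasks])
        n = len(self._y)
        self._U = np.zeros((n, len(tasks)))
        start = 0
        for j, t in enumerate(tasks):
            self._U[start:start + len(t.y), j] = 1.0
            start += len(t.y)

    @property
    def tissues(self) -> list[str]:
        return [t.tissue or f"task{i}" for i, t in enumerate(self.tasks)]

    @property
    def lambda_max(self) -> float:
        n = len(self._y)
        return _solver.lasso_lambda_max(self._X, self._y, np.full(n, 1.0 / n), self._U)

    def fit(self, lam: float) -> SparseLogisticResults:
        return self.fit_path([lam])[0]

    def fit_path(self, lams) -> list[SparseLogisticResults]:
        fits = _solver.fit_lasso_path(
            self._X, self._y, lams, U=self._U, max_iter=self.max_iter, tol=self.tol
        )
        out = []
        for lam, (w, c, info) in zip(lams, fits):
            coef = pd.DataFrame({ts: w for ts in self.tissues}, index=self.genes)
            out.append(
                SparseLogisticResults(
                    method="combined_lasso",
                    coef=coef,
                    intercepts=pd.Series(c, index=self.tissues),
                    lam=float(lam),
                    objective=info.objective,
                    n_iter=info.n_iter,
                    converged=info.converged,
                )
            )
        return out


class GroupLassoModel:
    """Multi-task group-lasso logistic regression across tissues.

    Each gene's coefficients across the T tissues form one group penalized
    by lam·sqrt(T)·||·||_2; per-tissue losses are averaged with weight 1/n_t
    and per-tissue intercepts are unpenalized.
    """

    def __init__(self, tasks: list[PredictionTask], max_iter: int = 5000, tol: float = 1e-7):
        genes = tasks[0].genes
        for t in tasks[1:]:
            if not t.genes.equals(genes):
                raise ValueError("tasks must share the same gene universe")
        self.tasks = tasks
        self.genes = genes
        self.max_iter = max_iter
        self.tol = tol

    @property
    def tissues(self) -> list[str]:
        return [t.tissue or f"task{i}" for i, t in enumerate(self.tasks)]

    @property
    def lambda_max(self) -> float:
        Xs = [t.X.to_numpy() for t in self.tasks]
        ys = [t.y_sign for t in self.tasks]
        T = len(self.tasks)
        weights = [np.full(len(y), 1.0 / (T * len(y))) for y in ys]
        return _solver.group_lambda_max(Xs, ys, weights)

    def fit(self, lam: float) -> SparseLogisticResults:
        return self.fit_path([lam])[0]

    def fit_path(self, lams) -> list[SparseLogisticResults]:
        Xs = [t.X.to_numpy() for t in self.tasks]
        ys = [t.y_sign for t in self.tasks]
        fits = _solver.fit_group_lasso_path(
            Xs, ys, lams, max_iter=self.max_iter, tol=self.tol
        )
        out = []
        for lam, (W, b, info) in zip(lams, fits):
            out.append(
                SparseLogisticResults(
                    method="group_lasso",
                    coef=pd.DataFrame(W, index=self.genes, columns=self.tissues),
                    intercepts=pd.Series(b, index=self.tissues),
                    lam=float(lam),
                    objective=info.objective,
                    n_iter=info.n_iter,
                    converged=info.converged,
                )
            )
        return out


def fit_lasso_logistic(task: PredictionTask, lam: float) -> SparseLogisticResults:
    """Functional wrapper: single-tissue lasso logistic fit."""
    return LassoLogisticModel(task).fit(lam)


def fit_combined_lasso(tasks: list[PredictionTask], lam: float) -> SparseLogisticResults:
    """Functional wrapper: pooled lasso with per-tissue intercepts."""
    return CombinedLassoModel(tasks).fit(lam)


def fit_group_lasso_logistic(tasks: list[PredictionTask], lam: float) -> SparseLogisticResults:
    """Functional wrapper: multi-task group-lasso logistic fit."""
    return GroupLassoModel(tasks).fit(lam)
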