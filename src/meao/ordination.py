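"""PCA of feature tables and the PC1-versus-age regression.

``FeaturePCA`` follows the model/results idiom: construct from a complete
feature table (well- or plate-level), call :meth:`FeaturePCA.fit`, and work
with the returned :class:`PcaResult` (scores, loadings, explained-variance
fractions, scree, plots).  Features are centred and, by default, scaled to
unit variance before the eigendecomposition.  Component signs are fixed so
that each component's loading sum is non-negative, which makes the output
deterministic and, for developmental data whose features all rise with age,
orients PC1 so that it increases with maturity.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from sklearn.decomposition import PCA as _SkPCA

from meao.features import FEATURE_NAMES

__all__ = ["FeaturePCA", "PcaResult", "run_pca", "scree", "regress_pc1_on_age"]


@dataclass(frozen=True)
class PcaResult:
    """Fitted PCA: row scores, feature loadings and explained-variance fractions.

    ``scores`` is (n_rows × n_components) with columns ``PC1`` …;
    ``loadings`` is (n_features × n_components); ``explained`` are fractions
    summing to 1 over all components, in decreasing order.
    """

    scores: pd.DataFrame
    loadings: pd.DataFrame
    explained: np.ndarray
    standardized: bool
    dropped_features: tuple[str, ...] = ()

    @property
    def n_components(self) -> int:
        return len(self.explained)

    def scree(self) -> np.ndarray:
        """Cumulative percent of variance explained, ending at 100."""
        return np.cumsum(self.explained) * 100.0

    def summary(self) -> str:
        lines = ["Principal components analysis",
                 f"  rows: {len(self.scores)}   features: {len(self.loadings)}"
                 f"   standardized: {self.standardized}"]
        if self.dropped_features:
            lines.append(f"  dropped constant features: {', '.join(self.dropped_features)}")
        cum = self.scree()
        lines.append("  dim   % var   cum %")
        for i, (e, c) in enumerate(zip(self.explained, cum), start=1):
            lines.append(f"  PC{i:<3d} {100 * e:6.1f}  {c:6.1f}")
        return "\n".join(lines)

    def plot_scores(self, color_by=None, ax=None):
        """Scatter of rows on (PC1, PC2), optionally coloured by a label series."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        x, y = self.scores.iloc[:, 0], self.scores.iloc[:, 1]
        if color_by is None:
            ax.scatter(x, y, s=12)
        else:
            color_by = np.asarray(color_by)
            for lab in np.unique(color_by):
                m = color_by == lab
                ax.scatter(x[m], y[m], s=12, label=str(lab))
            ax.legend(title="group")
        ax.set_xlabel(f"PC1 ({100 * self.explained[0]:.0f}%)")
        ax.set_ylabel(f"PC2 ({100 * self.explained[1]:.0f}%)")
        return ax

    def plot_scree(self, ax=None):
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        dims = np.arange(1, self.n_components + 1)
        ax.plot(dims, self.scree(), marker="o")
        ax.set_xlabel("number of PC dimensions")
        ax.set_ylabel("cumulative % variance explained")
        ax.set_ylim(0, 105)
        return ax


class FeaturePCA:
    """PCA model over a complete feature table.

    Parameters
    ----------
    table:
        DataFrame whose feature columns (default: the 12 canonical features,
        else every numeric column present) contain no missing values.
    standardize:
        Scale each feature to unit variance after centring (default).  With
        standardisation, constant features are dropped with a warning.
    """

    def __init__(self, table: pd.DataFrame, features: list[str] | None = None,
                 standardize: bool = True):
        if features is None:
            features = [c for c in FEATURE_NAMES if c in table.columns]
            if not features:
                features = list(table.select_dtypes("number").columns)
        if len(table) < 2:
            raise ValueError("PCA needs at least two rows")
        X = table[features]
        if X.isna().any().any():
            raise ValueError("feature table contains missing values; prepare it first")
        self.table = table
        self.features = list(features)
        self.standardize = standardize

    def fit(self) -> PcaResult:
        X = self.table[self.features].to_numpy(dtype=float)
        features = list(self.features)
        dropped: tuple[str, ...] = ()
        sd = X.std(axis=0, ddof=1)
        if self.standardize:
            constant = sd == 0
            if constant.any():
                dropped = tuple(f for f, c in zip(features, constant) if c)
                warnings.warn(f"dropping constant feature(s) under standardization: {dropped}",
                              stacklevel=2)
                keep = ~constant
                X, sd = X[:, keep], sd[keep]
                features = [f for f, k in zip(features, keep) if k]
            X = (X - X.mean(axis=0)) / sd
        else:
            X = X - X.mean(axis=0)

        model = _SkPCA(n_components=min(X.shape))
        scores = model.fit_transform(X)
        loadings = model.components_.T  # features × components
        # deterministic orientation: loading sum of every component ≥ 0
        signs = np.where(loadings.sum(axis=0) < 0, -1.0, 1.0)
        loadings = loadings * signs
        scores = scores * signs
        explained = model.explained_variance_ratio_

        cols = [f"PC{i + 1}" for i in range(scores.shape[1])]
        return PcaResult(
            scores=pd.DataFrame(scores, index=self.table.index, columns=cols),
            loadings=pd.DataFrame(loadings, index=features, columns=cols),
            explained=np.asarray(explained),
            standardized=self.standardize,
            dropped_features=dropped,
        )


def run_pca(table: pd.DataFrame, standardize: bool = True,
            features: list[str] | None = None) -> PcaResult:
    """Functional wrapper: ``FeaturePCA(table, features, standardize).fit()``."""
    return FeaturePCA(table, features=features, standardize=standardize).fit()


def scree(result: PcaResult) -> np.ndarray:
    """Cumulative explained-variance percentages of a fitted PCA."""
    return result.scree()


def regress_pc1_on_age(result: PcaResult, ages) -> tuple[float, float]:
    """OLS of the PC1 score on numeric age; returns (slope, two-sided p-value)."""
    ages = np.asarray(ages, dtype=float)
    if len(ages) != len(result.scores):
        raise ValueError("need one age per row of the score matrix")
    if np.all(ages == ages[0]):
        raise ValueError("age is constant; slope undefined")
    fit = sm.OLS(result.scores.iloc[:, 0].to_numpy(), sm.add_constant(ages)).fit()
    return float(fit.params[1]), float(fit.pvalues[1])
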