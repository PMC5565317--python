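"""Brain-behavior linkage: PCA composite score and edge regression.

Two face-recognition measures (famous-faces questionnaire and Cambridge
Face Memory Test, both percent correct) are z-scored and factorized by
PCA; the first principal component serves as a single composite
face-recognition score (for two standardized measures its variance
explained is exactly (1 + |r|) / 2).  The composite is then regressed by
ordinary least squares on group membership (control = 0, CP = 1) and the
connectivity value of a selected edge, testing whether the edge carries
behavioral information beyond the group label.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

__all__ = [
    "CompositeResult",
    "RegressionResult",
    "composite_score",
    "measure_correlation",
    "edge_behavior_regression",
]


@dataclass
class CompositeResult:
    """First-principal-component composite of two standardized measures."""

    scores: np.ndarray          # zero-mean PC1 scores, one per subject
    variance_explained: float   # proportion, lambda_1 / 2
    loadings: np.ndarray        # PC1 loadings on (measure1, measure2)


def composite_score(measure1, measure2) -> CompositeResult:
    """PCA composite of two behavioral measures.

    Both measures are z-scored; PCA is an eigendecomposition of their 2x2
    correlation matrix.  The PC1 sign is fixed so the score correlates
    positively with both inputs (with the first measure if the two are
    negatively correlated, in which case no common-positive sign exists).
    """
    m1 = np.asarray(measure1, dtype=float)
    m2 = np.asarray(measure2, dtype=float)
    if m1.shape != m2.shape or m1.ndim != 1:
        raise ValueError("measures must be equal-length vectors")
    if m1.size < 3:
        raise ValueError("need at least 3 subjects")
    if m1.std() == 0 or m2.std() == 0:
        raise ValueError("zero-variance measure")
    z = np.column_stack(
        [(m1 - m1.mean()) / m1.std(ddof=1), (m2 - m2.mean()) / m2.std(ddof=1)]
    )
    corr = np.corrcoef(z.T)
    evals, evecs = np.linalg.eigh(corr)
    v1 = evecs[:, np.argmax(evals)]
    if v1[0] < 0 or (v1[0] == 0 and v1[1] < 0):
        v1 = -v1
    scores = z @ v1
    return CompositeResult(
        scores=scores,
        variance_explained=float(evals.max() / evals.sum()),
        loadings=v1,
    )


def measure_correlation(measure1, measure2) -> tuple[float, int, float]:
    """Pearson correlation between two measures: returns (r, df, p)."""
    m1 = np.asarray(measure1, dtype=float)
    m2 = np.asarray(measure2, dtype=float)
    if m1.size < 3:
        raise ValueError("need at least 3 paired observations")
    if m1.std() == 0 or m2.std() == 0:
        raise ValueError("zero-variance measure")
    r, p = stats.pearsonr(m1, m2)
    return float(r), m1.size - 2, float(p)


@dataclass
class RegressionResult:
    """OLS fit of the composite on intercept + group + edge value."""

    params: dict[str, float]
    bse: dict[str, float]
    tvalues: dict[str, float]
    pvalues: dict[str, float]
    r_squared: float
    r_squared_adj: float
    f_statistic: float
    f_pvalue: float
    df_model: int
    df_resid: int

    def to_frame(self) -> pd.DataFrame:
        names = list(self.params)
        return pd.DataFrame(
            {
                "beta": [self.params[k] for k in names],
                "se": [self.bse[k] for k in names],
                "t": [self.tvalues[k] for k in names],
                "p": [self.pvalues[k] for k in names],
            },
            index=names,
        )


def edge_behavior_regression(
    composite, group_codes, edge_values
) -> RegressionResult:
    """OLS of the behavioral composite on group membership and an edge value."""
    y = np.asarray(composite, dtype=float)
    g = np.asarray(group_codes, dtype=float)
    e = np.asarray(edge_values, dtype=float)
    if not (y.shape == g.shape == e.shape) or y.ndim != 1:
        raise ValueError("composite, group codes and edge values must align")
    if y.size < 4:
        raise ValueError("need at least 4 subjects for 3 parameters")
    X = sm.add_constant(
        pd.DataFrame({"group": g, "edge": e}), has_constant="add"
    )
    if np.linalg.cond(X.to_numpy()) > 1e10:
        raise ValueError("predictors are (near-)collinear")
    fit = sm.OLS(y, X).fit()
    names = {"const": "intercept", "group": "group", "edge": "edge"}
    return RegressionResult(
        params={names[k]: float(v) for k, v in fit.params.items()},
        bse={names[k]: float(v) for k, v in fit.bse.items()},
        tvalues={names[k]: float(v) for k, v in fit.tvalues.items()},
        pvalues={names[k]: float(v) for k, v in fit.pvalues.items()},
        r_squared=float(fit.rsquared),
        r_squared_adj=float(fit.rsquared_adj),
        f_statistic=float(fit.fvalue),
        f_pvalue=float(fit.f_pvalue),
        df_model=int(fit.df_model),
        df_resid=int(fit.df_resid),
    )
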