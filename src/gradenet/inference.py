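"""Progress regression, sequential (Type I) ANOVA and correlation utilities.

The headline model regresses a student's one-year academic progress y on
four predictors measured at the first timepoint: their own ranking g and
the three tier environment scores,

    y = b0 + b_g g + b_xa x_acq + b_xf x_friend + b_xb x_best + e.

The accompanying ANOVA decomposes the total sum of squares sequentially:
each term's SS is the drop in residual sum of squares when that term is
added after all preceding terms, in a fixed order, each on 1 degree of
freedom; F-ratios use the full model's error mean square.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .ranking import EnvironmentScores, RankingTable, scores_frame

#: Default predictor order of the sequential decomposition.
TERMS = ("g", "x_acquaintance", "x_friend", "x_best_friend")

# Singular values below this fraction of the largest flag rank deficiency.
_RANK_TOL = 1e-10


class CollinearityError(ValueError):
    """Design matrix is numerically rank-deficient."""


@dataclass
class RegressionFit:
    """Ordinary-least-squares fit of the four-predictor progress model."""

    beta0: float
    beta_g: float
    beta_xa: float
    beta_xf: float
    beta_xb: float
    residuals: pd.Series
    rss: float
    n: int

    @property
    def coefficients(self) -> dict[str, float]:
        return {
            "intercept": self.beta0,
            "g": self.beta_g,
            "x_acquaintance": self.beta_xa,
            "x_friend": self.beta_xf,
            "x_best_friend": self.beta_xb,
        }

    def equation(self) -> str:
        """The fitted model as a human-readable string, 6 significant digits."""
        parts = [f"{self.beta0:.6g}"]
        for name, b in list(self.coefficients.items())[1:]:
            sign = "+" if b >= 0 else "-"
            parts.append(f" {sign} {abs(b):.6g}*{name}")
        return "y = " + "".join(parts)


@dataclass
class AnovaRow:
    term: str
    df: int
    ss: float
    ms: float
    f: float
    p: float


@dataclass
class SequentialAnovaTable:
    """Sequential (Type I) ANOVA: one 1-DF row per term plus error and total."""

    rows: list[AnovaRow]
    error_df: int
    error_ss: float
    error_ms: float
    total_df: int
    total_ss: float

    def to_frame(self) -> pd.DataFrame:
        recs = [
            {"term": r.term, "DF": r.df, "SS": r.ss, "MS": r.ms, "F": r.f, "p": r.p}
            for r in self.rows
        ]
        recs.append(
            {
                "term": "Error",
                "DF": self.error_df,
                "SS": self.error_ss,
                "MS": self.error_ms,
                "F": np.nan,
                "p": np.nan,
            }
        )
        recs.append(
            {
                "term": "Total",
                "DF": self.total_df,
                "SS": self.total_ss,
                "MS": np.nan,
                "F": np.nan,
                "p": np.nan,
            }
        )
        return pd.DataFrame.from_records(recs).set_index("term")


@dataclass
class CorrelationResult:
    r: float
    n: int


def significance_stars(p: float) -> str:
    """Report annotation: '***' for p < 0.001, '*' for p < 0.05."""
    if p < 0.001:
        return "***"
    if p < 0.05:
        return "*"
    return ""


def _as_frame(scores, g: RankingTable | None) -> pd.DataFrame:
    if isinstance(scores, EnvironmentScores):
        if g is None:
            raise ValueError("a RankingTable is required alongside EnvironmentScores")
        return scores_frame(scores, g)
    return scores


def _design(df: pd.DataFrame, terms: Sequence[str]) -> tuple[np.ndarray, np.ndarray]:
    missing = [t for t in terms if t not in df.columns]
    if missing:
        raise ValueError(f"missing predictor columns: {missing}")
    sub = df[list(terms) + ["y"]].dropna()
    x = np.column_stack([np.ones(len(sub))] + [sub[t].to_numpy(float) for t in terms])
    return x, sub["y"].to_numpy(float)


def _ols(x: np.ndarray, yv: np.ndarray, names: Sequence[str]) -> tuple[np.ndarray, float]:
    """Least squares via SVD with an explicit rank check."""
    u_, sv, vt = np.linalg.svd(x, full_matrices=False)
    if sv[-1] < _RANK_TOL * sv[0]:
        null_vec = vt[-1]
        cols = ["intercept", *names]
        involved = [c for c, w in zip(cols, null_vec) if abs(w) > 1e-8]
        raise CollinearityError(f"design matrix is rank-deficient; collinear columns: {involved}")
    beta = vt.T @ ((u_.T @ yv) / sv)
    resid = yv - x @ beta
    return beta, float(resid @ resid)


def fit_progress_model(
    scores, g: RankingTable | None = None, terms: Sequence[str] = TERMS
) -> RegressionFit:
    """Fit the progress model by ordinary least squares.

    ``scores`` is either an :class:`EnvironmentScores` (with ``g`` the
    t0 ranking table) or a ready-made data frame with the predictor
    columns and ``y``.
    """
    df = _as_frame(scores, g)
    x, yv = _design(df, terms)
    n = len(yv)
    if n < len(terms) + 2:
        raise ValueError(f"need at least {len(terms) + 2} rows, got {n}")
    beta, rss = _ols(x, yv, terms)
    resid = pd.Series(yv - x @ beta, index=df[list(terms) + ["y"]].dropna().index)
    full = dict(zip(terms, beta[1:]))
    return RegressionFit(
        beta0=float(beta[0]),
        beta_g=float(full.get("g", np.nan)),
        beta_xa=float(full.get("x_acquaintance", np.nan)),
        beta_xf=float(full.get("x_friend", np.nan)),
        beta_xb=float(full.get("x_best_friend", np.nan)),
        residuals=resid,
        rss=rss,
        n=n,
    )


def sequential_anova(
    scores, g: RankingTable | None = None, term_order: Sequence[str] = TERMS
) -> SequentialAnovaTable:
    """Sequential ANOVA of the progress model in ``term_order``.

    SS of the k-th term is RSS(intercept + first k-1 terms) minus
    RSS(intercept + first k terms); F uses the full model's error mean
    square with (1, n - 1 - #terms) degrees of freedom.
    """
    df = _as_frame(scores, g)
    x_full, yv = _design(df, term_order)
    n = len(yv)
    k = len(term_order)
    if n < k + 2:
        raise ValueError(f"need at least {k + 2} rows, got {n}")
    total_ss = float(np.sum((yv - yv.mean()) ** 2))
    rss_prev = total_ss  # intercept-only model
    term_ss: list[float] = []
    for j in range(1, k + 1):
        _, rss_j = _ols(x_full[:, : j + 1], yv, term_order[:j])
        term_ss.append(rss_prev - rss_j)
        rss_prev = rss_j
    error_ss = rss_prev
    error_df = n - 1 - k
    if error_df <= 0:
        raise ValueError("no residual degrees of freedom")
    error_ms = error_ss / error_df
    rows = []
    for term, ss in zip(term_order, term_ss):
        ms = ss / 1.0
        if error_ms > 0:
            f = ms / error_ms
            p = float(stats.f.sf(f, 1, error_df))
        else:  # zero residual variance: the F ratio is undefined
            f = float("nan")
            p = float("nan")
        rows.append(AnovaRow(term=term, df=1, ss=ss, ms=ms, f=f, p=p))
    return SequentialAnovaTable(
        rows=rows,
        error_df=error_df,
        error_ss=error_ss,
        error_ms=error_ms,
        total_df=n - 1,
        total_ss=total_ss,
    )


def pearson_r(a: Sequence[float], b: Sequence[float]) -> CorrelationResult:
    """Pearson product-moment correlation of two equal-length series."""
    av = np.asarray(a, dtype=float)
    bv = np.asarray(b, dtype=float)
    if av.shape != bv.shape or av.ndim != 1:
        raise ValueError("series must be one-dimensional and of equal length")
    if len(av) < 3:
        raise ValueError("need at least 3 pairs")
    if np.ptp(av) == 0 or np.ptp(bv) == 0:
        raise ValueError("correlation undefined for a constant series")
    r = stats.pearsonr(av, bv).statistic
    return CorrelationResult(r=float(r), n=len(av))
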