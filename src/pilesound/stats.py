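"""Permutational ANOVA and companion statistics for mortality data.

PERMANOVA partitions the total sum of squared Euclidean distances among
observations into sequential (entry-order) components for a list of design
terms, exactly as a distance-based linear model: with Euclidean distance on
an untransformed univariate response the term sums of squares and the
pseudo-F statistic coincide with classical sequential (type-I) ANOVA.

Significance comes from unrestricted permutation of the observations:

    pseudo-F_j = (SS_j / df_j) / (SS_residual / df_residual)
    p_perm     = (#{F* >= F} + 1) / (n_perm + 1)

When the design admits few distinct permutations, the permutation
distribution is too coarse and a Monte-Carlo style p-value is preferred:
here a Pearson type III curve is moment-matched (mean, variance, skewness)
to the permuted pseudo-F values and its upper tail evaluated at the
observed statistic.  Both p-values are always reported.
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as _sps

__all__ = [
    "TermResult",
    "PermanovaResult",
    "permanova",
    "spearman_rho",
    "linreg_r2",
    "cumulative_mortality",
    "immediate_mortality_response",
    "delayed_mortality_response",
]


# ---------------------------------------------------------------------------
# PERMANOVA
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TermResult:
    name: str
    df: int
    ss: float
    pseudo_f: float
    p_perm: float
    p_mc: float


@dataclass
class PermanovaResult:
    terms: list[TermResult]
    residual_df: int
    residual_ss: float
    total_ss: float
    n_perm: int
    seed: int | None

    def term(self, name: str) -> TermResult:
        for t in self.terms:
            if t.name == name:
                return t
        raise KeyError(name)

    def to_dict(self) -> dict:
        return {
            "terms": [vars(t) for t in self.terms],
            "residual_df": self.residual_df,
            "residual_ss": self.residual_ss,
            "total_ss": self.total_ss,
            "n_perm": self.n_perm,
            "seed": self.seed,
        }


def _term_columns(factors: pd.DataFrame, term: str) -> np.ndarray:
    """Indicator (one-hot) columns for a main effect or `a:b` interaction."""
    parts = term.split(":")
    for p in parts:
        if p not in factors.columns:
            raise KeyError(f"unknown factor {p!r} in term {term!r}")
        if factors[p].nunique() < 2:
            raise ValueError(f"factor {p!r} has a single level")
    cells = factors[parts[0]].astype(str)
    for p in parts[1:]:
        cells = cells + "\x1f" + factors[p].astype(str)
    return pd.get_dummies(cells, dtype=float).to_numpy()


def _sequential_projectors(
    factors: pd.DataFrame, order: Sequence[str]
) -> tuple[list[np.ndarray], list[int], np.ndarray, np.ndarray]:
    """Projection-difference matrices and dfs for sequential decomposition.

    Returns per-term projectors ``P_j = H_j - H_{j-1}``, their dfs, the
    residual projector ``I - H_K`` and the centering projector ``I - H_0``.
    """
    n = len(factors)
    ones = np.ones((n, 1))
    X = ones
    H_prev = ones @ ones.T / n
    rank_prev = 1
    projectors, dfs = [], []
    for term in order:
        X = np.hstack([X, _term_columns(factors, term)])
        # pinv-based hat matrix; designs here are small
        H = X @ np.linalg.pinv(X)
        rank = int(np.linalg.matrix_rank(X))
        projectors.append(H - H_prev)
        dfs.append(rank - rank_prev)
        H_prev, rank_prev = H, rank
    resid = np.eye(n) - H_prev
    center = np.eye(n) - ones @ ones.T / n
    return projectors, dfs, resid, center


def _quadratic_forms(Yp: np.ndarray, M: np.ndarray) -> np.ndarray:
    """sum over response columns of y' M y, for each permutation row-block."""
    # Yp: (m, n, q); M: (n, n)
    return np.einsum("mnq,nk,mkq->m", Yp, M, Yp)


def _n_distinct_permutations(factors: pd.DataFrame, order: Sequence[str]) -> float:
    """Distinct permutations of observations w.r.t. the full design cells."""
    parts = sorted({p for t in order for p in t.split(":")})
    cells = factors[parts].astype(str).agg("\x1f".join, axis=1)
    counts = cells.value_counts().to_numpy()
    n = int(counts.sum())
    log_count = math.lgamma(n + 1) - sum(math.lgamma(int(c) + 1) for c in counts)
    return math.exp(log_count) if log_count < 700 else math.inf


def permanova(
    response: np.ndarray | pd.Series,
    factors: pd.DataFrame,
    order: Sequence[str],
    n_perm: int = 9999,
    seed: int | None = None,
    exact: bool = False,
) -> PermanovaResult:
    """Euclidean-distance PERMANOVA with sequential sums of squares.

    Parameters
    ----------
    response:
        Numeric vector (or n x q matrix) of untransformed observations.
    factors:
        One categorical column per design factor, one row per observation.
    order:
        Term entry order, e.g. ``["treatment", "age", "treatment:age"]``;
        the decomposition is sequential, so order matters for unbalanced
        designs.
    n_perm:
        Number of random unrestricted permutations of the observations.
    seed:
        Seed for the permutation stream (required when ``n_perm > 0``).
    exact:
        Enumerate all n! permutations instead of sampling (n <= 8 only).
    """
    Y = np.asarray(response, dtype=np.float64)
    if Y.ndim == 1:
        Y = Y[:, None]
    n = Y.shape[0]
    if len(factors) != n:
        raise ValueError("response and factors must have equal length")
    if not order:
        raise ValueError("order must list at least one term")

    projectors, dfs, resid_proj, center = _sequential_projectors(factors, order)
    resid_df = n - 1 - sum(dfs)
    if resid_df <= 0:
        raise ValueError("saturated design: no residual degrees of freedom")

    n_distinct = _n_distinct_permutations(factors, order)
    if n_distinct < 20:
        warnings.warn(
            f"only {n_distinct:.0f} distinct permutations; the permutation "
            "p-value is coarse — prefer the Monte-Carlo p-value",
            stacklevel=2,
        )

    if exact:
        if n > 8:
            raise ValueError("exact enumeration limited to n <= 8 observations")
        perms = np.array(list(itertools.permutations(range(n))))
    elif n_perm > 0:
        rng = np.random.default_rng(seed)
        perms = np.vstack([rng.permutation(n) for _ in range(n_perm)])
    else:
        perms = np.empty((0, n), dtype=int)
    # observed ordering first, permutations after
    all_idx = np.vstack([np.arange(n)[None, :], perms]) if perms.size else np.arange(n)[None, :]
    Yp = Y[all_idx]  # (m, n, q)

    ss_res_all = _quadratic_forms(Yp, resid_proj)
    total_ss = float(_quadratic_forms(Y[None], center)[0])
    # constant response: every partition is exactly zero, F undefined -> p = 1
    if total_ss <= 1e-12 * n * max(1.0, float(np.mean(Y**2))):
        return PermanovaResult(
            terms=[TermResult(t, df, 0.0, 0.0, 1.0, 1.0)
                   for t, df in zip(order, dfs)],
            residual_df=resid_df,
            residual_ss=0.0,
            total_ss=0.0,
            n_perm=int(perms.shape[0]),
            seed=seed,
        )

    terms: list[TermResult] = []
    eps = np.finfo(float).tiny
    for term, P, df in zip(order, projectors, dfs):
        ss_all = _quadratic_forms(Yp, P)
        with np.errstate(divide="ignore", invalid="ignore"):
            f_all = (ss_all / df) / np.maximum(ss_res_all / resid_df, eps)
        f_obs = float(f_all[0])
        f_perm = f_all[1:]
        if f_perm.size:
            if exact:
                p_perm = float(np.mean(f_perm >= f_obs - 1e-12))
            else:
                p_perm = float((np.sum(f_perm >= f_obs - 1e-12) + 1) / (f_perm.size + 1))
            p_mc = _pearson3_tail(f_perm, f_obs)
        else:
            p_perm = math.nan
            p_mc = math.nan
        terms.append(
            TermResult(term, df, float(ss_all[0]), f_obs, p_perm, p_mc)
        )

    return PermanovaResult(
        terms=terms,
        residual_df=resid_df,
        residual_ss=float(ss_res_all[0]),
        total_ss=total_ss,
        n_perm=int(perms.shape[0]),
        seed=seed,
    )


def _pearson3_tail(f_perm: np.ndarray, f_obs: float) -> float:
    """Upper-tail probability of a Pearson type III curve moment-matched to
    the permuted statistics (a continuous stand-in for the discrete
    permutation distribution when distinct permutations are few)."""
    mu = float(np.mean(f_perm))
    sd = float(np.std(f_perm, ddof=1)) if f_perm.size > 1 else 0.0
    if not math.isfinite(sd) or sd <= 0:
        return 1.0 if f_obs <= mu else 0.0
    skew = float(_sps.skew(f_perm, bias=False))
    if not math.isfinite(skew):
        skew = 0.0
    return float(_sps.pearson3.sf(f_obs, skew, loc=mu, scale=sd))


# ---------------------------------------------------------------------------
# rank correlation and regression
# ---------------------------------------------------------------------------

def _ranks_average_ties(x: np.ndarray) -> np.ndarray:
    """Ranks 1..n with tied values assigned the average of their positions."""
    x = np.asarray(x, dtype=np.float64)
    order = np.argsort(x, kind="stable")
    ranks = np.empty(x.size)
    sx = x[order]
    i = 0
    while i < x.size:
        j = i
        while j + 1 < x.size and sx[j + 1] == sx[i]:
            j += 1
        ranks[order[i : j + 1]] = 0.5 * (i + j) + 1.0
        i = j + 1
    return ranks


def _pearson(x: np.ndarray, y: np.ndarray) -> float:
    xc = x - x.mean()
    yc = y - y.mean()
    denom = math.sqrt(float(xc @ xc) * float(yc @ yc))
    if denom == 0.0:
        return math.nan
    return float(xc @ yc) / denom


def spearman_rho(x: Sequence[float], y: Sequence[float]) -> float:
    """Spearman rank correlation: Pearson correlation of average-tie ranks.

    Constant input has undefined rank correlation; NaN is returned with a
    warning.
    """
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    if x.shape != y.shape or x.size < 3:
        raise ValueError("need equal-length sequences of at least 3 values")
    rho = _pearson(_ranks_average_ties(x), _ranks_average_ties(y))
    if math.isnan(rho):
        warnings.warn("constant input: Spearman correlation undefined", stacklevel=2)
    return rho


def linreg_r2(x: Sequence[float], y: Sequence[float]) -> float:
    """Ordinary-least-squares R^2 of y on x (squared Pearson correlation)."""
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    if x.shape != y.shape or x.size < 3:
        raise ValueError("need equal-length sequences of at least 3 values")
    if np.all(x == x[0]):
        raise ValueError("x is constant: regression undefined")
    r = _pearson(x, y)
    return 0.0 if math.isnan(r) else r * r


# ---------------------------------------------------------------------------
# mortality table summaries and model responses
# ---------------------------------------------------------------------------

_VIAL_KEY = ["trip", "experiment", "treatment", "age_dph", "vial"]


def _check_table(t: pd.DataFrame) -> None:
    required = set(_VIAL_KEY + ["day", "n_alive", "n_dead"])
    missing = required - set(t.columns)
    if missing:
        raise ValueError(f"mortality table missing columns: {sorted(missing)}")
    if (t["n_alive"] < 0).any() or (t["n_dead"] < 0).any():
        raise ValueError("counts must be non-negative")
    for key, g in t.groupby(_VIAL_KEY):
        days = np.sort(g["day"].to_numpy())
        expected = np.arange(days.min(), days.max() + 1)
        if not np.array_equal(days, expected):
            raise ValueError(f"vial {key} has missing days (explicit gaps required)")
        dead = g.sort_values("day")["n_dead"].to_numpy()
        if np.any(np.diff(dead) < 0):
            raise ValueError(f"vial {key} has decreasing cumulative deaths")


def cumulative_mortality(
    t: pd.DataFrame, by: Sequence[str] = ("experiment", "treatment")
) -> pd.DataFrame:
    """Percent cumulative mortality by day per group.

    Initial fish count per vial is ``n_alive + n_dead`` (constant over
    days); group mortality is total cumulative deaths over the group's
    initial count, in percent.  The result is non-decreasing along days.
    """
    _check_table(t)
    t = t.copy()
    t["n_initial"] = t["n_alive"] + t["n_dead"]
    out = (
        t.groupby([*by, "day"])[["n_dead", "n_initial"]]
        .sum()
        .reset_index()
    )
    out["mortality_pct"] = 100.0 * out["n_dead"] / out["n_initial"]
    return out[[*by, "day", "mortality_pct"]]


def immediate_mortality_response(
    t: pd.DataFrame,
) -> tuple[np.ndarray, pd.DataFrame]:
    """Per-vial proportion dead at the day-0 (immediate) check.

    Returns the response vector and the matching factor frame with
    ``treatment`` and ``age`` columns, ready for a two-factor PERMANOVA.
    """
    _check_table(t)
    d0 = t[t["day"] == 0]
    if d0.empty:
        raise ValueError("table has no day-0 rows")
    y = (d0["n_dead"] / (d0["n_alive"] + d0["n_dead"])).to_numpy(dtype=float)
    factors = d0[["treatment", "age_dph"]].rename(columns={"age_dph": "age"})
    return y, factors.reset_index(drop=True).astype(str)


def delayed_mortality_response(
    t: pd.DataFrame,
) -> tuple[np.ndarray, pd.DataFrame]:
    """Per-vial, per-day cumulative mortality proportion over the follow-up.

    Days 1..max are used (day 0 is the immediate assessment).  Factors are
    ``treatment``, ``age`` and ``day``, matching a three-factor design with
    days after exposure as the third term.
    """
    _check_table(t)
    dd = t[t["day"] > 0]
    if dd.empty:
        raise ValueError("table has no follow-up days")
    y = (dd["n_dead"] / (dd["n_alive"] + dd["n_dead"])).to_numpy(dtype=float)
    factors = dd[["treatment", "age_dph", "day"]].rename(
        columns={"age_dph": "age"}
    )
    return y, factors.reset_index(drop=True).astype(str)
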