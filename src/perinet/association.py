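"""Unadjusted odds ratios and multivariate logistic regression.

Unadjusted ORs come from 2x2 contingency counts with Woolf (log-OR) 95%
intervals and Wald p-values, matching how univariate logistic regression
reports a binary contrast.  The multivariate model for inter-region
transport is fitted by iteratively reweighted least squares (IRLS) with Wald
intervals; complete separation is detected and flagged rather than silently
reported.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

Z975 = 1.959963984540054


@dataclass(frozen=True)
class TwoByTwo:
    """Exposure x outcome cell counts.

    ``a``: exposed with outcome, ``b``: exposed without, ``c``: reference
    level with outcome, ``d``: reference without.
    """

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        for name in "abcd":
            v = getattr(self, name)
            if v < 0 or v != int(v):
                raise ValueError(f"cell {name} must be a nonnegative integer")


@dataclass(frozen=True)
class ORResult:
    or_: float
    ci_low: float
    ci_high: float
    p_value: float
    method: str = "woolf"
    degenerate: bool = False


def odds_ratio(t: TwoByTwo) -> ORResult:
    """Odds ratio ad/(bc) with Woolf confidence interval.

    Zero cells are reported literally (OR of 0 or inf with a (0, inf)
    interval and a degenerate flag); no Haldane-Anscombe correction is
    applied by default.  The p-value is the Wald test on the log odds ratio,
    which coincides with the univariate logistic Wald test for a 2x2 table.
    """
    a, b, c, d = t.a, t.b, t.c, t.d
    if a == b == c == d == 0:
        raise ValueError("all-zero 2x2 table")
    if b == 0 or c == 0:
        or_ = math.inf if (a > 0 and d > 0) else math.nan
        return ORResult(or_, 0.0, math.inf, math.nan, degenerate=True)
    if a == 0 or d == 0:
        return ORResult(0.0, 0.0, math.inf, math.nan, degenerate=True)
    or_ = (a * d) / (b * c)
    se = math.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
    log_or = math.log(or_)
    p = 2.0 * stats.norm.sf(abs(log_or) / se)
    return ORResult(
        or_=or_,
        ci_low=math.exp(log_or - Z975 * se),
        ci_high=math.exp(log_or + Z975 * se),
        p_value=float(p),
    )


def univariate_or_table(
    records: pd.DataFrame,
    covariate: str,
    reference_level: str,
    outcome: str = "transported",
) -> pd.DataFrame:
    """One OR per non-reference covariate level against the reference.

    Each level (including Unknown) is contrasted with the reference in its
    own collapsed 2x2 table.  A constant covariate yields an empty table
    with a warning; an absent reference level raises.
    """
    values = records[covariate].astype("string").fillna("Unknown")
    y = records[outcome].astype(bool)
    tab = pd.crosstab(values, y)
    for col in (True, False):
        if col not in tab.columns:
            tab[col] = 0
    if reference_level not in tab.index:
        raise ValueError(
            f"reference level {reference_level!r} absent from {covariate!r}"
        )
    levels = [lvl for lvl in tab.index if lvl != reference_level]
    if not levels:
        warnings.warn(f"covariate {covariate!r} is constant; nothing to contrast",
                      stacklevel=2)
        return pd.DataFrame(
            columns=["covariate", "level", "ref", "n0", "n1", "or", "ci_low",
                     "ci_high", "p_value", "degenerate"]
        )
    c = int(tab.loc[reference_level, True])
    d = int(tab.loc[reference_level, False])
    rows = []
    for lvl in levels:
        a = int(tab.loc[lvl, True])
        b = int(tab.loc[lvl, False])
        res = odds_ratio(TwoByTwo(a, b, c, d))
        rows.append(
            {
                "covariate": covariate,
                "level": lvl,
                "ref": reference_level,
                "n0": b,
                "n1": a,
                "or": res.or_,
                "ci_low": res.ci_low,
                "ci_high": res.ci_high,
                "p_value": res.p_value,
                "degenerate": res.degenerate,
            }
        )
    return pd.DataFrame(rows)


def label_inter_region(
    records: pd.DataFrame, facilities: pd.DataFrame
) -> pd.DataFrame:
    """Append inter_region and same_system flags to transport records.

    ``inter_region`` is True when origin and destination facilities lie in
    different designated regions; ``same_system`` when they share a health
    system.  Both endpoints must be rostered (records are expected to have
    passed the network-eligibility filter).
    """
    fac = facilities.set_index("facility_id")
    out = records.copy()
    for col in ("origin_facility", "destination_facility"):
        missing = set(out[col].dropna()) - set(fac.index)
        if missing:
            raise KeyError(f"{col} IDs absent from roster: {sorted(missing)[:5]}")
    origin_dpr = out["origin_facility"].map(fac["dpr"])
    dest_dpr = out["destination_facility"].map(fac["dpr"])
    out["inter_region"] = (origin_dpr != dest_dpr).astype(bool)
    out["same_system"] = (
        out["origin_facility"].map(fac["system"])
        == out["destination_facility"].map(fac["system"])
    ).astype(bool)
    return out


@dataclass(frozen=True)
class LogisticFit:
    """IRLS maximum-likelihood logistic fit with Wald inference."""

    coefficients: dict[str, float]
    standard_errors: dict[str, float]
    or_table: pd.DataFrame
    converged: bool
    n_iterations: int
    log_likelihood: float
    separation: bool = False
    terms: tuple[str, ...] = field(default=())


def build_design(
    records: pd.DataFrame,
    model_spec: Sequence[tuple[str, str]],
) -> tuple[np.ndarray, list[str]]:
    """Dummy-coded design matrix (with intercept) for an ordered model spec.

    ``model_spec`` is a list of (covariate, reference_level) pairs; each
    non-reference level (Unknown included, never dropped silently) becomes a
    term named ``covariate[level]``.
    """
    columns = [np.ones(len(records))]
    names = ["intercept"]
    for covariate, reference in model_spec:
        values = records[covariate].astype("string").fillna("Unknown")
        levels = sorted(values.unique(), key=str)
        if reference not in levels:
            raise ValueError(
                f"reference level {reference!r} absent from {covariate!r}"
            )
        for lvl in levels:
            if lvl == reference:
                continue
            columns.append((values == lvl).to_numpy(float))
            names.append(f"{covariate}[{lvl}]")
    X = np.column_stack(columns)
    return X, names


def _safe_exp(x: float) -> float:
    try:
        return math.exp(x)
    except OverflowError:
        return math.inf


def _aliased_columns(X: np.ndarray, names: list[str]) -> list[str]:
    _, r = np.linalg.qr(X)
    diag = np.abs(np.diag(r))
    tol = diag.max() * max(X.shape) * np.finfo(float).eps
    return [names[i] for i in np.flatnonzero(diag < tol)]


def fit_logistic(
    records: pd.DataFrame,
    model_spec: Sequence[tuple[str, str]],
    outcome: str,
    tol: float = 1e-8,
    max_iter: int = 50,
) -> LogisticFit:
    """Maximum-likelihood logistic regression by IRLS.

    Convergence when the maximum absolute score component falls below
    ``tol`` (or after ``max_iter`` Newton steps).  Diverging coefficients
    (|beta| > 12 on the log-odds scale) are flagged as separation.  A
    rank-deficient design raises, naming the aliased terms.
    """
    y = records[outcome].astype(bool).to_numpy(float)
    X, names = build_design(records, model_spec)
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError(
            f"rank-deficient design; aliased terms: {_aliased_columns(X, names)}"
        )
    beta = np.zeros(X.shape[1])
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        eta = X @ beta
        p = 1.0 / (1.0 + np.exp(-np.clip(eta, -35, 35)))
        score = X.T @ (y - p)
        if np.max(np.abs(score)) < tol:
            converged = True
            break
        w = np.clip(p * (1.0 - p), 1e-10, None)
        hessian = (X * w[:, None]).T @ X
        beta = beta + np.linalg.solve(hessian, score)
    eta = X @ beta
    p = 1.0 / (1.0 + np.exp(-np.clip(eta, -35, 35)))
    w = np.clip(p * (1.0 - p), 1e-10, None)
    cov = np.linalg.inv((X * w[:, None]).T @ X)
    se = np.sqrt(np.diag(cov))
    loglik = float(np.sum(y * np.log(np.clip(p, 1e-300, None))
                          + (1 - y) * np.log(np.clip(1 - p, 1e-300, None))))
    separation = bool(np.any(np.abs(beta) > 12.0))
    if separation:
        logger.warning(
            "possible complete separation: diverging coefficients %s",
            [n for n, b in zip(names, beta) if abs(b) > 12.0],
        )
    rows = []
    for name, b, s in zip(names, beta, se):
        if name == "intercept":
            continue
        z = b / s if s > 0 else math.nan
        rows.append(
            {
                "term": name,
                "or": _safe_exp(b),
                "ci_low": _safe_exp(b - Z975 * s),
                "ci_high": _safe_exp(b + Z975 * s),
                "p_value": float(2.0 * stats.norm.sf(abs(z))),
            }
        )
    return LogisticFit(
        coefficients=dict(zip(names, map(float, beta))),
        standard_errors=dict(zip(names, map(float, se))),
        or_table=pd.DataFrame(rows),
        converged=converged and not separation,
        n_iterations=it,
        log_likelihood=loglik,
        separation=separation,
        terms=tuple(names),
    )


def collapse_sparse_levels(
    records: pd.DataFrame,
    covariate: str,
    min_count: int = 20,
    other_label: str = "Other",
    keep: Sequence[str] = (),
) -> pd.DataFrame:
    """Collapse covariate levels with fewer than ``min_count`` observations
    into a pooled level, as is common when sparse categories destabilize a
    multivariate fit."""
    out = records.copy()
    counts = out[covariate].value_counts()
    sparse = [
        lvl for lvl, n in counts.items() if n < min_count and lvl not in set(keep)
    ]
    if sparse:
        out[covariate] = out[covariate].replace(dict.fromkeys(sparse, other_label))
    return out
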