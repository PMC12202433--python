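"""Scoring and data cleaning: raw records to the 31 model indicators.

Pipeline order mirrors the study workflow: partial-credit scoring of span
trials and composite scoring of the item pool, 3-SD within-group
winsorization of outliers, Little's MCAR test on the incomplete matrix,
then deterministic EM (conditional-mean) imputation of missing cells.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .specs import (
    BOTH_ITEMS,
    CW_ITEMS,
    NEITHER_COMPOSITE,
    NEITHER_ITEMS,
    PA_ITEMS,
)

__all__ = [
    "CleaningReport",
    "partial_credit_scores",
    "winsorize_outliers",
    "em_mvnorm",
    "em_impute",
    "little_mcar_test",
    "score_composites",
    "default_classification",
    "preprocess_pipeline",
]


@dataclass
class CleaningReport:
    """What the cleaning steps touched."""

    outlier_cells: dict = field(default_factory=dict)   # group -> count
    outlier_fraction: dict = field(default_factory=dict)
    missing_cells: int = 0
    missing_fraction: float = 0.0
    mcar_chi2: float = np.nan
    mcar_df: int = 0
    mcar_p: float = np.nan
    em_iterations: int = 0


def partial_credit_scores(trials: pd.DataFrame) -> pd.DataFrame:
    """Partial-credit unit scores: mean stimuli-correct across the six trials
    of each task x set size, one column per indicator, one row per subject.

    Expects long records with columns subject, task, set_size, trial,
    n_correct.  A subject missing any of the six trials for a condition gets
    a missing indicator (never zero).
    """
    req = {"subject", "task", "set_size", "trial", "n_correct"}
    missing = req - set(trials.columns)
    if missing:
        raise ValueError(f"trial records lack columns {sorted(missing)}")
    bad = trials["n_correct"] > trials["set_size"]
    if bad.any() or (trials["n_correct"] < 0).any():
        raise ValueError("stimuli-correct outside [0, set size]")
    g = trials.groupby(["subject", "task", "set_size"])["n_correct"]
    agg = g.agg(["mean", "count"])
    agg.loc[agg["count"] != 6, "mean"] = np.nan
    wide = agg["mean"].unstack(["task", "set_size"])
    wide.columns = [f"{task}_ss{ss}" for task, ss in wide.columns]
    order = sorted(wide.columns, key=lambda c: (not c.startswith("phono"), c))
    return wide[order]


def winsorize_outliers(
    indicators: pd.DataFrame,
    group_labels: pd.Series | Sequence | None = None,
    z: float = 3.0,
    columns: Sequence[str] | None = None,
) -> tuple[pd.DataFrame, CleaningReport]:
    """Correct univariate outliers to the next most extreme in-group value.

    Within each group and variable, values more than ``z`` group SDs from
    the group mean (mean/SD computed on all observed values, candidate
    included) are replaced by the most extreme value in that group's column
    that is not itself flagged — the maximum non-outlier for high outliers,
    the minimum for low ones.  Single pass; missing cells are ignored.
    """
    out = indicators.copy()
    if columns is None:
        columns = [
            c for c in indicators.columns
            if np.issubdtype(indicators[c].dtype, np.number)
        ]
    if group_labels is None:
        group_labels = pd.Series(["all"] * len(indicators), index=indicators.index)
    else:
        group_labels = pd.Series(np.asarray(group_labels), index=indicators.index)
    report = CleaningReport()
    for gname, idx in group_labels.groupby(group_labels).groups.items():
        count = 0
        cells = 0
        for c in columns:
            col = out.loc[idx, c].astype(float)
            obs = col.dropna()
            cells += len(obs)
            if len(obs) < 2:
                continue
            m, sd = obs.mean(), obs.std(ddof=1)
            if sd == 0:
                continue
            zscores = (obs - m) / sd
            flagged = zscores.abs() > z
            if not flagged.any():
                continue
            if flagged.all():
                raise ValueError(
                    f"every value of {c!r} in group {gname!r} is flagged"
                )
            keep = obs[~flagged]
            hi, lo = keep.max(), keep.min()
            repl = obs.where(~flagged, np.where(obs > m, hi, lo))
            out.loc[obs.index, c] = repl
            count += int(flagged.sum())
        report.outlier_cells[gname] = count
        report.outlier_fraction[gname] = count / cells if cells else 0.0
    return out, report


def em_mvnorm(
    X: np.ndarray, tol: float = 1e-6, max_iter: int = 500
) -> tuple[np.ndarray, np.ndarray, int, list[float]]:
    """ML mean and covariance of a multivariate normal with missing data.

    Standard EM: the E-step replaces missing blocks with their conditional
    moments given observed cells; the M-step re-estimates (mu, Sigma).
    Converges when the largest parameter change drops below ``tol``.
    Returns (mu, Sigma, n_iterations, observed-data log-likelihood trace).
    """
    X = np.asarray(X, dtype=float)
    n, p = X.shape
    obs = ~np.isnan(X)
    if np.any(obs.sum(axis=0) < 2):
        j = int(np.argmin(obs.sum(axis=0)))
        raise ValueError(f"variable {j} observed fewer than 2 times")
    mu = np.nanmean(X, axis=0)
    Xc = np.where(obs, X, mu)
    Sigma = np.cov(Xc, rowvar=False, ddof=0) + 1e-6 * np.eye(p)

    patterns: dict[bytes, np.ndarray] = {}
    for i in range(n):
        patterns.setdefault(obs[i].tobytes(), []).append(i)
    patterns = {k: np.asarray(v) for k, v in patterns.items()}

    loglik_trace: list[float] = []
    it = 0
    for it in range(1, max_iter + 1):
        T1 = np.zeros(p)
        T2 = np.zeros((p, p))
        ll = 0.0
        for key, rows in patterns.items():
            o = np.frombuffer(key, dtype=bool)
            mi = ~o
            Xo = X[np.ix_(rows, np.where(o)[0])]
            k = len(rows)
            Soo = Sigma[np.ix_(o, o)]
            try:
                Soo_inv = np.linalg.inv(Soo)
            except np.linalg.LinAlgError as e:
                raise ValueError(
                    f"singular observed-block covariance for pattern {o.astype(int)}"
                ) from e
            dev = Xo - mu[o]
            sign, ld = np.linalg.slogdet(Soo)
            ll += -0.5 * k * (o.sum() * np.log(2 * np.pi) + ld)
            ll += -0.5 * float(np.sum((dev @ Soo_inv) * dev))
            Xfull = np.tile(mu, (k, 1))
            Xfull[:, o] = Xo
            if mi.any():
                B = Sigma[np.ix_(mi, o)] @ Soo_inv
                Xfull[:, mi] = mu[mi] + dev @ B.T
                Cmm = Sigma[np.ix_(mi, mi)] - B @ Sigma[np.ix_(o, mi)]
            T1 += Xfull.sum(axis=0)
            T2 += Xfull.T @ Xfull
            if mi.any():
                T2[np.ix_(mi, mi)] += k * Cmm
        mu_new = T1 / n
        Sigma_new = T2 / n - np.outer(mu_new, mu_new)
        delta = max(
            np.abs(mu_new - mu).max(), np.abs(Sigma_new - Sigma).max()
        )
        mu, Sigma = mu_new, (Sigma_new + Sigma_new.T) / 2
        loglik_trace.append(ll)
        if delta < tol:
            break
    else:
        raise RuntimeError(
            f"EM did not converge in {max_iter} iterations; "
            f"log-likelihood trace tail: {loglik_trace[-5:]}"
        )
    return mu, Sigma, it, loglik_trace


def em_impute(
    indicators: pd.DataFrame | np.ndarray,
    tol: float = 1e-6,
    max_iter: int = 500,
) -> tuple[pd.DataFrame | np.ndarray, dict]:
    """Deterministic single imputation: missing cells get their conditional
    expectation under the EM-converged multivariate-normal parameters.

    Observed cells are untouched (bit-identical).  No residual noise is
    added; repeated calls give identical output.
    """
    df = isinstance(indicators, pd.DataFrame)
    X = indicators.to_numpy(dtype=float) if df else np.asarray(indicators, dtype=float)
    if not np.isnan(X).any():
        info = {"iterations": 1, "imputed_cells": 0, "loglik": []}
        return (indicators.copy() if df else X.copy()), info
    mu, Sigma, it, ll = em_mvnorm(X, tol=tol, max_iter=max_iter)
    out = X.copy()
    obs = ~np.isnan(X)
    for i in range(X.shape[0]):
        o = obs[i]
        if o.all():
            continue
        mi = ~o
        Soo_inv = np.linalg.inv(Sigma[np.ix_(o, o)])
        out[i, mi] = mu[mi] + Sigma[np.ix_(mi, o)] @ Soo_inv @ (X[i, o] - mu[o])
    info = {
        "iterations": it,
        "imputed_cells": int((~obs).sum()),
        "loglik": ll,
        "mu": mu,
        "Sigma": Sigma,
    }
    if df:
        return pd.DataFrame(out, columns=indicators.columns, index=indicators.index), info
    return out, info


def little_mcar_test(
    indicators: pd.DataFrame | np.ndarray,
) -> tuple[float, int, float]:
    """Little's (1988) test that data are missing completely at random.

    chi2 = sum_j n_j (ybar_obs,j - mu_j)' Sigma_j^-1 (ybar_obs,j - mu_j)
    over missingness patterns j, with mu/Sigma the EM estimates restricted
    to each pattern's observed variables; df = sum_j p_j - p.  Complete data
    (a single pattern) give chi2 = 0, df = 0, p = 1 with a warning.
    """
    X = (
        indicators.to_numpy(dtype=float)
        if isinstance(indicators, pd.DataFrame)
        else np.asarray(indicators, dtype=float)
    )
    n, p = X.shape
    obs = ~np.isnan(X)
    keys = {}
    for i in range(n):
        keys.setdefault(obs[i].tobytes(), []).append(i)
    if len(keys) < 2:
        warnings.warn("no missing data: Little's test is undefined; returning p=1")
        return 0.0, 0, 1.0
    mu, Sigma, _, _ = em_mvnorm(X)
    chi2 = 0.0
    df = -p
    for key, rows in keys.items():
        o = np.frombuffer(key, dtype=bool)
        if not o.any():
            continue
        rows = np.asarray(rows)
        ybar = X[np.ix_(rows, np.where(o)[0])].mean(axis=0)
        dev = ybar - mu[o]
        Soo = Sigma[np.ix_(o, o)]
        try:
            sol = np.linalg.solve(Soo, dev)
        except np.linalg.LinAlgError as e:
            raise ValueError(
                f"singular covariance for pattern {o.astype(int)}"
            ) from e
        chi2 += len(rows) * float(dev @ sol)
        df += int(o.sum())
    pval = float(stats.chi2.sf(chi2, df)) if df > 0 else 1.0
    return float(chi2), int(df), pval


def default_classification() -> dict[str, str]:
    """The consensus item classification: 11 worry, 11 arousal, 1 both,
    17 neither."""
    cls = {}
    for i in CW_ITEMS:
        cls[f"item{i:02d}"] = "cognitive_worry"
    for i in PA_ITEMS:
        cls[f"item{i:02d}"] = "physiological_arousal"
    for i in BOTH_ITEMS:
        cls[f"item{i:02d}"] = "both"
    for i in NEITHER_ITEMS:
        cls[f"item{i:02d}"] = "neither_unclear"
    return cls


def score_composites(
    items: pd.DataFrame,
    classification: Mapping[str, str] | None = None,
) -> pd.DataFrame:
    """Build the 23 anxiety model indicators from the 40-item matrix.

    The 22 worry/arousal items pass through unchanged; the 17 "neither"
    items are summed into the reference composite; "both" items are dropped
    from modeling.  A composite with any missing constituent is flagged
    missing (imputation happens later, on the indicator table).
    """
    classification = dict(classification or default_classification())
    missing_items = set(classification) - set(items.columns)
    if missing_items:
        raise ValueError(f"items table lacks columns {sorted(missing_items)}")
    unclassified = [c for c in items.columns if c not in classification]
    if unclassified:
        raise ValueError(f"items without classification: {unclassified}")
    by_cat: dict[str, list[str]] = {}
    for item, cat in classification.items():
        by_cat.setdefault(cat, []).append(item)
    n_cw = len(by_cat.get("cognitive_worry", []))
    n_pa = len(by_cat.get("physiological_arousal", []))
    n_ne = len(by_cat.get("neither_unclear", []))
    if (n_cw, n_pa, n_ne) != (11, 11, 17):
        raise ValueError(
            f"classification counts (CW={n_cw}, PA={n_pa}, Neither={n_ne}) do not "
            "match the required 11/11/17 structure"
        )
    keep = sorted(by_cat["cognitive_worry"] + by_cat["physiological_arousal"])
    out = items[keep].copy()
    neither = items[sorted(by_cat["neither_unclear"])]
    comp = neither.sum(axis=1, min_count=len(neither.columns))
    out[NEITHER_COMPOSITE] = comp
    return out


def preprocess_pipeline(
    items: pd.DataFrame,
    trials: pd.DataFrame,
    covariates: pd.DataFrame,
    group: pd.Series,
    classification: Mapping[str, str] | None = None,
    z: float = 3.0,
) -> tuple[pd.DataFrame, CleaningReport]:
    """Score -> winsorize -> MCAR test -> EM impute; returns the completed
    indicator table (indicators + covariates + group) and a cleaning report."""
    wm = partial_credit_scores(trials)
    anx = score_composites(items, classification)
    ind = wm.join(anx, how="outer")
    ind, report = winsorize_outliers(ind, group_labels=group.loc[ind.index], z=z)
    n_missing = int(ind.isna().sum().sum())
    report.missing_cells = n_missing
    report.missing_fraction = n_missing / ind.size
    if n_missing:
        report.mcar_chi2, report.mcar_df, report.mcar_p = little_mcar_test(ind)
        ind, info = em_impute(ind)
        report.em_iterations = info["iterations"]
    out = ind.join(covariates).join(group.rename("group"))
    return out, report
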