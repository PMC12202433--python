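"""Model-fit and bifactor reliability/dimensionality indices.

Fit: chi-square, CFI, TLI, RMSEA with a 90% CI from inverting the
noncentral chi-square CDF, and SRMR.  Reliability/dimensionality: the
omega family (total, hierarchical, subscale, hierarchical-subscale),
explained common variance (ECV), percentage of uncontaminated correlations
(PUC, a purely structural quantity), and construct replicability (H).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import optimize, stats

from .engine import FitResult
from .specs import BifactorSpec

__all__ = [
    "FitIndices",
    "fit_indices",
    "relative_fit",
    "delta_chi2",
    "omega_indices",
    "ecv",
    "puc",
    "construct_h",
    "cohens_d",
    "reliability_report",
]


@dataclass
class FitIndices:
    chi2: float
    df: int
    pvalue: float
    cfi: float
    tli: float
    rmsea: float
    rmsea_ci: tuple[float, float]
    srmr: float

    def to_row(self) -> dict:
        lo, hi = self.rmsea_ci
        return {
            "chi2": round(self.chi2, 2), "df": self.df,
            "p": round(self.pvalue, 4), "CFI": round(self.cfi, 3),
            "TLI": round(self.tli, 3), "RMSEA": round(self.rmsea, 3),
            "RMSEA 90% CI": f"({lo:.3f}-{hi:.3f})", "SRMR": round(self.srmr, 3),
        }


def _rmsea_ci(chi2: float, df: int, N: int, G: int, level: float = 0.90):
    """Invert the noncentral chi-square CDF in the noncentrality parameter."""
    lo_q, hi_q = (1 + level) / 2, (1 - level) / 2  # .95 and .05

    def bound(target: float) -> float:
        # largest lambda with cdf(chi2; df, lambda) >= target is the solution
        f = lambda lam: stats.ncx2.cdf(chi2, df, lam) - target
        if f(0) < 0:
            return 0.0
        hi = max(chi2, 1.0)
        while f(hi) > 0:
            hi *= 2
            if hi > 1e8:
                break
        return float(optimize.brentq(f, 0, hi, xtol=1e-10))

    lam_lo, lam_hi = bound(lo_q), bound(hi_q)
    scale = np.sqrt(G)
    return (
        scale * np.sqrt(lam_lo / (df * N)),
        scale * np.sqrt(lam_hi / (df * N)),
    )


def relative_fit(
    chi2_m: float, df_m: int, chi2_b: float, df_b: int, N: int, G: int = 1
) -> dict:
    """CFI, TLI and RMSEA (with 90% CI) from model and baseline chi-squares.

    CFI = 1 - max(chi2_m - df_m, 0)/max(chi2_b - df_b, chi2_m - df_m, 0);
    TLI = (chi2_b/df_b - chi2_m/df_m)/(chi2_b/df_b - 1);
    RMSEA = sqrt(G) * sqrt(max(chi2_m - df_m, 0)/(df_m N)), CI by inverting
    the noncentral chi-square CDF in the noncentrality parameter.
    """
    num = max(chi2_m - df_m, 0.0)
    den = max(chi2_b - df_b, chi2_m - df_m, 0.0)
    cfi = 1.0 - (num / den if den > 0 else 0.0)
    if df_m <= 0:
        tli, rmsea, ci = 1.0, 0.0, (0.0, 0.0)
    else:
        rb = chi2_b / df_b
        tli = (rb - chi2_m / df_m) / (rb - 1.0) if rb > 1 else 1.0
        rmsea = float(np.sqrt(G) * np.sqrt(max(chi2_m - df_m, 0.0) / (df_m * N)))
        ci = _rmsea_ci(chi2_m, df_m, N, G)
    return {"cfi": float(np.clip(cfi, 0, 1)), "tli": float(tli),
            "rmsea": rmsea, "rmsea_ci": ci}


def fit_indices(model: FitResult, baseline: FitResult) -> FitIndices:
    """CFI/TLI/RMSEA(+90% CI)/SRMR for a fitted model against its
    independence baseline (same data, same groups).

    SRMR = sqrt(mean squared correlation-metric residual over the unique
    indicator-covariance cells), averaged across groups.
    """
    if (
        model.group_names != baseline.group_names
        or model.n != baseline.n
        or model.structure.indicators != baseline.structure.indicators
    ):
        raise ValueError("baseline was fitted to different data/groups")
    cm, dm = model.chi2, model.df
    cb, db = baseline.chi2, baseline.df
    G = len(model.group_names)
    N = model.n_total
    rel = relative_fit(cm, dm, cb, db, N, G)
    # SRMR over the indicator block, correlation metric, diagonal included
    p = model.structure.p
    tot = 0.0
    cnt = 0
    for g, gd in enumerate(model.data):
        Sig, _ = model.implied(g)
        Sig = Sig[:p, :p]
        S = gd.S[:p, :p]
        d = np.sqrt(np.diag(S))
        resid = (S - Sig) / np.outer(d, d)
        iu = np.triu_indices(p)
        tot += float(np.sum(resid[iu] ** 2))
        cnt += len(iu[0])
    srmr = float(np.sqrt(tot / cnt))
    return FitIndices(
        chi2=cm, df=dm, pvalue=model.pvalue, cfi=rel["cfi"],
        tli=rel["tli"], rmsea=rel["rmsea"], rmsea_ci=rel["rmsea_ci"],
        srmr=srmr,
    )


def delta_chi2(
    restricted: FitResult, unrestricted: FitResult, tol: float = 1e-6
) -> tuple[float, int, float]:
    """Likelihood-ratio (chi-square difference) test of nested models.

    Small negative differences (within optimizer tolerance) are clipped to
    zero; larger ones indicate the restricted optimum was not reached and
    raise, so the caller can refit from better start values.
    """
    d = restricted.chi2 - unrestricted.chi2
    ddf = restricted.df - unrestricted.df
    if ddf < 0:
        raise ValueError("restricted model has fewer df than unrestricted")
    if d < 0:
        if d > -max(tol * max(1.0, unrestricted.chi2), 1e-4):
            d = 0.0
        else:
            raise ValueError(
                f"negative chi-square difference ({d:.4g}): restricted fit "
                "did not reach its optimum; refit from the unrestricted solution"
            )
    p = float(stats.chi2.sf(d, ddf)) if ddf > 0 else 1.0
    return float(d), int(ddf), p


def _check_standardized(lam_std: np.ndarray, theta_std: np.ndarray, tol=1e-3):
    comm = (lam_std**2).sum(axis=1) + theta_std
    if np.any(np.abs(comm - 1.0) > tol) or np.any(np.abs(lam_std) > 1 + tol):
        raise ValueError(
            "loadings/residuals are not a standardized solution "
            "(squared loadings + residual must equal 1 per indicator)"
        )


def omega_indices(
    spec: BifactorSpec, lam_std: np.ndarray, theta_std: np.ndarray,
    check: bool = True,
) -> dict:
    """Model-based reliability for a standardized bifactor solution.

    omega_total = [(sum lam_g)^2 + sum_s (sum lam_s)^2] / [same + sum theta];
    omega_h keeps only the general-factor term in the numerator.  Subscale
    versions restrict every sum to one specific factor's own indicators,
    with omega_hs crediting only the specific factor.
    """
    st = spec.structure()
    lam_std = np.asarray(lam_std, dtype=float)
    theta_std = np.asarray(theta_std, dtype=float)
    if check:
        _check_standardized(lam_std, theta_std)
    g = st.factor_index(spec.general)
    sum_g = lam_std[:, g].sum()
    denom = sum_g**2 + theta_std.sum()
    spec_terms = {}
    for fac in spec.specifics:
        f = st.factor_index(fac)
        spec_terms[fac] = lam_std[:, f].sum() ** 2
    denom += sum(spec_terms.values())
    omega_total = (sum_g**2 + sum(spec_terms.values())) / denom
    omega_h = sum_g**2 / denom
    out = {"omega_total": float(omega_total), "omega_h": float(omega_h),
           "omega_s": {}, "omega_hs": {}}
    for fac, members in spec.specifics.items():
        f = st.factor_index(fac)
        rows = [st.indicators.index(i) for i in members]
        sg = lam_std[rows, g].sum()
        ss = lam_std[rows, f].sum()
        th = theta_std[rows].sum()
        sub_denom = sg**2 + ss**2 + th
        out["omega_s"][fac] = float((sg**2 + ss**2) / sub_denom)
        out["omega_hs"][fac] = float(ss**2 / sub_denom)
    return out


def ecv(spec: BifactorSpec, lam_std: np.ndarray) -> dict[str, float]:
    """Explained common variance per factor: each factor's share of the
    total squared standardized loadings.  Entries sum to one."""
    st = spec.structure()
    lam_std = np.asarray(lam_std, dtype=float)
    ssq = (lam_std**2).sum(axis=0)
    total = ssq.sum()
    if total <= 0:
        raise ValueError("all loadings are zero; ECV undefined")
    return {fac: float(ssq[st.factor_index(fac)] / total) for fac in spec.factor_names}


def puc(spec: BifactorSpec) -> float:
    """Percentage of uncontaminated correlations: the fraction of indicator
    pairs whose model-implied correlation involves only the general factor.

    PUC = [C - sum_s C_s] / C with C = p(p-1)/2 and C_s = p_s(p_s-1)/2
    within each specific factor.  Purely structural — no estimates needed.
    """
    p = spec.n_indicators
    if p < 2:
        raise ValueError("need at least 2 indicators")
    C = p * (p - 1) / 2
    within = sum(len(m) * (len(m) - 1) / 2 for m in spec.specifics.values())
    return float((C - within) / C)


def construct_h(loadings: np.ndarray) -> float:
    """Construct replicability H = [sum l^2/(1-l^2)] / [1 + sum l^2/(1-l^2)]
    over one factor's standardized loadings."""
    lam = np.asarray(loadings, dtype=float)
    if np.any(np.abs(lam) >= 1):
        raise ValueError("standardized loadings must satisfy |l| < 1")
    s = float(np.sum(lam**2 / (1 - lam**2)))
    return s / (1 + s)


def cohens_d(
    m1: float, sd1: float, n1: int, m2: float, sd2: float, n2: int
) -> float:
    """Cohen's d with the pooled SD: (m2 - m1) / s_p, where
    s_p^2 = [(n1-1) sd1^2 + (n2-1) sd2^2] / (n1 + n2 - 2)."""
    sp = np.sqrt(((n1 - 1) * sd1**2 + (n2 - 1) * sd2**2) / (n1 + n2 - 2))
    return float((m2 - m1) / sp)


def reliability_report(fit: FitResult, group: int = 0) -> dict:
    """Omega family, ECV, PUC, and per-factor H for a fitted bifactor model."""
    spec = fit.spec
    if spec is None:
        raise ValueError("fit does not carry a BifactorSpec")
    st = spec.structure()
    p = st.p
    lam_std = fit.std[group]["lambda"][:p, : st.m]
    th_std = fit.std[group]["theta"][:p]
    # with MIMIC covariates the factors acquire small covariate-induced
    # correlations, so the orthogonal variance decomposition is approximate
    exact = fit.structure.q == 0
    out = {
        "omega": omega_indices(spec, lam_std, th_std, check=exact),
        "ecv": ecv(spec, lam_std),
        "puc": puc(spec),
        "H": {},
    }
    for fac in spec.factor_names:
        f = st.factor_index(fac)
        lams = lam_std[st.loading_free[:, f], f]
        out["H"][fac] = construct_h(lams)
    return out
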