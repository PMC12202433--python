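"""Normal-theory maximum-likelihood estimation of bifactor SEMs.

The estimator minimizes the ML discrepancy

    F(theta) = ln|Sigma| + tr(S Sigma^-1) - ln|S| - P   [+ mean term]

over the free parameters of a :class:`~bifactorlab.specs.ModelStructure`:
free loadings, log residual variances, cross-construct factor covariances,
factor-on-covariate regressions, and (optionally) intercepts and latent
means.  Factor (disturbance) variances are fixed to one and within-construct
factor covariances to zero, which identifies the reference-facet bifactor
models estimated here.

Covariates enter MIMIC-style: latent factors are regressed on observed
exogenous covariates whose own moments are fixed at their sample values
("fixed-x"), so the covariate block of the implied moments is saturated and
contributes nothing to the discrepancy.

Optimization defaults to Fisher scoring (Newton-type steps under the
expected information with Levenberg damping and a backtracking line
search) with analytic gradients and deterministic start values, falling
back to a quasi-Newton (L-BFGS-B) polish when scoring stalls; a plain
L-BFGS-B route is selectable.  A fit is therefore a pure function of
(data, structure, options).  Standard errors come from the inverse
expected information.  chi-square is N * F_min by default (normal
likelihood scaling; N-1 Wishart scaling is switchable).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import linalg, optimize, stats

from .specs import BifactorSpec, ModelStructure

__all__ = [
    "FitResult",
    "GroupData",
    "fit_ml",
    "fit_multigroup",
    "fit_baseline",
    "implied_moments",
    "latent_mean_compare",
]

_TIE_CATEGORIES = ("loadings", "intercepts", "residuals", "phi", "gamma")


# --------------------------------------------------------------------------
# data containers
# --------------------------------------------------------------------------


@dataclass
class GroupData:
    """Sample moments of one group: indicators first, covariates last."""

    S: np.ndarray
    mean: np.ndarray
    n: int
    p: int
    q: int

    @property
    def P(self) -> int:
        return self.p + self.q

    @property
    def Sxx(self) -> np.ndarray:
        return self.S[self.p :, self.p :]

    @property
    def xbar(self) -> np.ndarray:
        return self.mean[self.p :]


def _as_group_data(data, structure: ModelStructure) -> GroupData:
    if isinstance(data, GroupData):
        return data
    cols = list(structure.indicators) + list(structure.covariates)
    if isinstance(data, pd.DataFrame):
        missing = [c for c in cols if c not in data.columns]
        if missing:
            raise ValueError(f"data is missing columns {missing}")
        X = data[cols].to_numpy(dtype=float)
    else:
        X = np.asarray(data, dtype=float)
        if X.shape[1] != len(cols):
            raise ValueError(
                f"expected {len(cols)} columns (indicators + covariates), got {X.shape[1]}"
            )
    if np.isnan(X).any():
        raise ValueError("data contain missing values; impute before fitting")
    n = X.shape[0]
    if n <= len(cols):
        raise ValueError(f"need n > {len(cols)} observations, got {n}")
    mean = X.mean(axis=0)
    S = np.cov(X, rowvar=False, ddof=0)  # ML covariance
    return GroupData(S=S, mean=mean, n=n, p=structure.p, q=structure.q)


def moments_group_data(
    S: np.ndarray, n: int, structure: ModelStructure, means: np.ndarray | None = None
) -> GroupData:
    """Wrap a covariance matrix (and optional means) for fitting."""
    S = np.asarray(S, dtype=float)
    P = structure.p + structure.q
    if S.shape != (P, P):
        raise ValueError(f"S must be {P}x{P}")
    mean = np.zeros(P) if means is None else np.asarray(means, dtype=float)
    return GroupData(S=S, mean=mean, n=int(n), p=structure.p, q=structure.q)


# --------------------------------------------------------------------------
# parameter bookkeeping
# --------------------------------------------------------------------------


class _ParamMap:
    """Maps a flat free-parameter vector onto per-group model matrices.

    Tied categories share one global index across groups; untied categories
    get a per-group copy.  Fixed cells never appear in the vector.
    """

    def __init__(
        self,
        structure: ModelStructure,
        group_names: Sequence[str],
        ties: Sequence[str],
        meanstructure: bool,
        free_latent_means: bool,
        identification: str = "variance",
    ):
        bad = set(ties) - set(_TIE_CATEGORIES)
        if bad:
            raise ValueError(f"unknown tie categories {sorted(bad)}")
        if identification not in ("variance", "marker"):
            raise ValueError("identification must be 'variance' or 'marker'")
        self.structure = structure
        self.groups = list(group_names)
        self.G = len(self.groups)
        self.meanstructure = meanstructure
        self.free_latent_means = free_latent_means
        self.identification = identification
        self.names: list[str] = []

        st = structure
        # marker identification: one loading per factor fixed to 1 (a
        # reference indicator when the factor has one), factor variance free
        self.marker_rows: dict[int, int] = {}
        if identification == "marker":
            for f in range(st.m):
                rows = np.nonzero(st.loading_free[:, f])[0]
                if rows.size == 0:
                    raise ValueError(f"factor {st.factors[f]!r} has no indicators")
                exclusive = [i for i in rows if st.loading_free[i].sum() == 1]
                self.marker_rows[f] = int(exclusive[0] if exclusive else rows[0])
        cells = np.argwhere(st.loading_free)
        if self.marker_rows:
            keep = [
                k for k, (i, f) in enumerate(cells)
                if self.marker_rows.get(f) != i
            ]
            cells = cells[keep]
        self.lam_cells = cells
        self.psi_cells = st.free_phi_pairs
        self.psi_diag = (
            list(range(st.m)) if identification == "marker" else []
        )
        self.gam_cells = [(f, c) for f in range(st.m) for c in range(st.q)]

        def add(name: str) -> int:
            self.names.append(name)
            return len(self.names) - 1

        def alloc(cells, namer, tied: bool) -> list[np.ndarray]:
            if tied:
                base = [add(namer(c)) for c in cells]
                return [np.asarray(base, dtype=int)] * self.G
            out = []
            for g, gname in enumerate(self.groups):
                suff = "" if self.G == 1 else f"|{gname}"
                out.append(np.asarray([add(namer(c) + suff) for c in cells], dtype=int))
            return out

        ind, fac, cov = st.indicators, st.factors, st.covariates
        self.lam_idx = alloc(
            self.lam_cells, lambda c: f"lam[{ind[c[0]]}~{fac[c[1]]}]", "loadings" in ties
        )
        self.th_idx = alloc(
            range(st.p), lambda i: f"theta[{ind[i]}]", "residuals" in ties
        )
        self.psi_idx = alloc(
            self.psi_cells, lambda c: f"psi[{fac[c[0]]},{fac[c[1]]}]", "phi" in ties
        )
        self.psi_diag_idx = alloc(
            self.psi_diag, lambda f: f"psi[{fac[f]},{fac[f]}]", "phi" in ties
        )
        self.gam_idx = alloc(
            self.gam_cells, lambda c: f"gam[{fac[c[0]]}~{cov[c[1]]}]", "gamma" in ties
        )
        if meanstructure:
            self.nu_idx = alloc(
                range(st.p), lambda i: f"nu[{ind[i]}]", "intercepts" in ties
            )
            if free_latent_means:
                self.alpha_idx = [None] + [
                    np.asarray(
                        [add(f"alpha[{fac[f]}]|{g}") for f in range(st.m)], dtype=int
                    )
                    for g in self.groups[1:]
                ]
            else:
                self.alpha_idx = [None] * self.G
        else:
            self.nu_idx = [None] * self.G
            self.alpha_idx = [None] * self.G

    @property
    def n_free(self) -> int:
        return len(self.names)

    def unpack(self, theta: np.ndarray, g: int):
        st = self.structure
        Lam = np.zeros((st.p, st.m))
        if len(self.lam_cells):
            Lam[self.lam_cells[:, 0], self.lam_cells[:, 1]] = theta[self.lam_idx[g]]
        for f, i in self.marker_rows.items():
            Lam[i, f] = 1.0
        th = np.exp(theta[self.th_idx[g]])
        Psi = np.eye(st.m)
        for k, f in enumerate(self.psi_diag):
            Psi[f, f] = theta[self.psi_diag_idx[g][k]]
        for k, (a, b) in enumerate(self.psi_cells):
            Psi[a, b] = Psi[b, a] = theta[self.psi_idx[g][k]]
        Gam = np.zeros((st.m, st.q))
        if st.q:
            for k, (f, c) in enumerate(self.gam_cells):
                Gam[f, c] = theta[self.gam_idx[g][k]]
        nu = theta[self.nu_idx[g]] if self.nu_idx[g] is not None else None
        alpha = np.zeros(st.m)
        if self.alpha_idx[g] is not None:
            alpha = theta[self.alpha_idx[g]]
        return Lam, th, Psi, Gam, nu, alpha

    def start_vector(self, groups: Sequence[GroupData]) -> np.ndarray:
        """Deterministic start: loadings .5 (general) / .3 (specific) on the
        standardized scale, residual variances half the sample variance."""
        st = self.structure
        theta = np.zeros(self.n_free)
        # average indicator scale across groups sharing a tied parameter
        sd = np.mean([np.sqrt(np.diag(g.S)[: st.p]) for g in groups], axis=0)
        var = sd**2
        # which factor is "general" per construct: the one with most loadings
        n_load = st.loading_free.sum(axis=0)
        general_like = np.zeros(st.m, dtype=bool)
        for constr in set(st.factor_construct):
            cols = [k for k in range(st.m) if st.factor_construct[k] == constr]
            general_like[cols[int(np.argmax(n_load[cols]))]] = True
        for g in range(self.G):
            if self.identification == "marker":
                for k, (i, f) in enumerate(self.lam_cells):
                    theta[self.lam_idx[g][k]] = sd[i] / sd[self.marker_rows[f]]
                for k, f in enumerate(self.psi_diag):
                    scale = (0.5 if general_like[f] else 0.3) * sd[self.marker_rows[f]]
                    theta[self.psi_diag_idx[g][k]] = scale**2
            else:
                for k, (i, f) in enumerate(self.lam_cells):
                    theta[self.lam_idx[g][k]] = (
                        0.5 if general_like[f] else 0.3
                    ) * sd[i]
            theta[self.th_idx[g]] = np.log(0.5 * var)
            if self.nu_idx[g] is not None:
                theta[self.nu_idx[g]] = groups[g].mean[: st.p]
        # psi, gamma, alpha start at zero
        return theta


# --------------------------------------------------------------------------
# implied moments and discrepancy
# --------------------------------------------------------------------------


def implied_moments(
    Lam: np.ndarray,
    Phi: np.ndarray,
    theta_diag: np.ndarray,
    Gam: np.ndarray | None = None,
    Sxx: np.ndarray | None = None,
    nu: np.ndarray | None = None,
    alpha: np.ndarray | None = None,
    xbar: np.ndarray | None = None,
):
    """Model-implied covariance (and mean) of indicators [and covariates].

    Sigma_yy = Lam Phi* Lam' + diag(theta), with Phi* = Phi + Gam Sxx Gam'
    when covariates are present; the covariate block is fixed at Sxx.
    """
    Lam = np.atleast_2d(np.asarray(Lam, dtype=float))
    Phi = np.atleast_2d(np.asarray(Phi, dtype=float))
    theta_diag = np.asarray(theta_diag, dtype=float)
    p, m = Lam.shape
    if Phi.shape != (m, m):
        raise ValueError("Phi dimension mismatch")
    if theta_diag.shape != (p,):
        raise ValueError("theta dimension mismatch")
    if Gam is None or Gam.size == 0:
        Sig = Lam @ Phi @ Lam.T + np.diag(theta_diag)
        Sig = (Sig + Sig.T) / 2
        mu = None
        if nu is not None:
            mu = nu + Lam @ (alpha if alpha is not None else np.zeros(m))
        return Sig, mu
    Gam = np.asarray(Gam, dtype=float)
    q = Gam.shape[1]
    Phi_star = Phi + Gam @ Sxx @ Gam.T
    Sig = np.empty((p + q, p + q))
    Sig[:p, :p] = Lam @ Phi_star @ Lam.T + np.diag(theta_diag)
    Sig[:p, p:] = Lam @ Gam @ Sxx
    Sig[p:, :p] = Sig[:p, p:].T
    Sig[p:, p:] = Sxx
    Sig = (Sig + Sig.T) / 2
    mu = None
    if nu is not None:
        a = alpha if alpha is not None else np.zeros(m)
        xb = xbar if xbar is not None else np.zeros(q)
        mu = np.concatenate([nu + Lam @ (a + Gam @ xb), xb])
    return Sig, mu


_BIG = 1e12


def _group_objective(theta, pm: _ParamMap, g: int, data: GroupData, logdetS: float):
    """F_ML and its gradient (into global coordinates) for one group."""
    st = pm.structure
    p, m, q = st.p, st.m, st.q
    Lam, th, Psi, Gam, nu, alpha = pm.unpack(theta, g)
    P = p + q
    # augmented loading W and factor-block covariance C
    if q:
        W = np.zeros((P, m + q))
        W[:p, :m] = Lam
        W[:p, m:] = Lam @ Gam
        W[p:, m:] = np.eye(q)
        C = np.zeros((m + q, m + q))
        C[:m, :m] = Psi
        C[m:, m:] = data.Sxx
    else:
        W, C = Lam, Psi
    Sig = W @ C @ W.T
    Sig[np.diag_indices(p)[0], np.diag_indices(p)[1]] += th
    Sig = (Sig + Sig.T) / 2
    try:
        cf = linalg.cho_factor(Sig, check_finite=False)
    except linalg.LinAlgError:
        return _BIG, np.zeros(pm.n_free)
    logdet = 2.0 * np.sum(np.log(np.diag(cf[0])))
    Siginv = linalg.cho_solve(cf, np.eye(P), check_finite=False)
    F = logdet - logdetS + float(np.sum(Siginv * data.S)) - P
    G = Siginv - Siginv @ data.S @ Siginv
    d = None
    if nu is not None:
        mu_y = nu + Lam @ (alpha + (Gam @ data.xbar if q else 0.0))
        mu = np.concatenate([mu_y, data.xbar]) if q else mu_y
        d = data.mean - mu
        Sid = Siginv @ d
        F += float(d @ Sid)
        G -= np.outer(Sid, Sid)
    if not np.isfinite(F):
        return _BIG, np.zeros(pm.n_free)

    grad = np.zeros(pm.n_free)
    T = 2.0 * G @ W @ C  # dF/dW
    gLam = T[:p, :m] + (T[:p, m:] @ Gam.T if q else 0.0)
    B = W.T @ G @ W
    if d is not None:
        dFdmu = -2.0 * Sid
        eta_mean = alpha + (Gam @ data.xbar if q else 0.0)
        gLam = gLam + np.outer(dFdmu[:p], eta_mean)
        np.add.at(grad, pm.nu_idx[g], dFdmu[:p])
        if pm.alpha_idx[g] is not None:
            np.add.at(grad, pm.alpha_idx[g], Lam.T @ dFdmu[:p])
    if len(pm.lam_cells):
        np.add.at(grad, pm.lam_idx[g], gLam[pm.lam_cells[:, 0], pm.lam_cells[:, 1]])
    np.add.at(grad, pm.th_idx[g], np.diag(G)[:p] * th)
    if pm.psi_diag:
        np.add.at(grad, pm.psi_diag_idx[g], np.diag(B)[pm.psi_diag])
    if pm.psi_cells:
        a = np.asarray([c[0] for c in pm.psi_cells])
        b = np.asarray([c[1] for c in pm.psi_cells])
        np.add.at(grad, pm.psi_idx[g], 2.0 * B[a, b])
    if q:
        gGam = Lam.T @ T[:p, m:]
        if d is not None:
            gGam = gGam + np.outer(Lam.T @ dFdmu[:p], data.xbar)
        np.add.at(
            grad,
            pm.gam_idx[g],
            gGam[[c[0] for c in pm.gam_cells], [c[1] for c in pm.gam_cells]],
        )
    return F, grad


# --------------------------------------------------------------------------
# fit result
# --------------------------------------------------------------------------


@dataclass
class FitResult:
    """Fitted model: estimates, uncertainty, and fit statistics."""

    structure: ModelStructure
    group_names: list[str]
    n: list[int]
    params: list[dict]          # per group: lambda, theta, psi, gamma, nu, alpha
    std: list[dict]             # per group: lambda, theta (standardized), psi
    theta_hat: np.ndarray       # flat free-parameter vector
    param_names: list[str]
    se: np.ndarray
    F_min: float
    chi2: float
    df: int
    converged: bool
    admissible: bool
    n_iter: int
    meanstructure: bool
    chi2_scale: str
    data: list[GroupData]
    message: str = ""
    spec: BifactorSpec | None = None

    @property
    def pvalue(self) -> float:
        if self.df <= 0:
            return 1.0
        return float(stats.chi2.sf(self.chi2, self.df))

    @property
    def n_total(self) -> int:
        return int(sum(self.n))

    @property
    def n_free(self) -> int:
        return len(self.param_names)

    def param(self, name: str) -> float:
        return float(self.theta_hat[self.param_names.index(name)])

    def se_of(self, name: str) -> float:
        return float(self.se[self.param_names.index(name)])

    def implied(self, group: int = 0):
        """Model-implied (Sigma, mu) for one group."""
        pp = self.params[group]
        gd = self.data[group]
        return implied_moments(
            pp["lambda"], pp["psi"], pp["theta"],
            Gam=pp["gamma"] if self.structure.q else None,
            Sxx=gd.Sxx if self.structure.q else None,
            nu=pp["nu"], alpha=pp["alpha"] if pp["nu"] is not None else None,
            xbar=gd.xbar if self.structure.q else None,
        )

    def wald_table(self) -> pd.DataFrame:
        """Estimate, SE, z and two-sided p for every free parameter."""
        with np.errstate(divide="ignore", invalid="ignore"):
            z = np.where(self.se > 0, self.theta_hat / self.se, np.nan)
        est = self.theta_hat.copy()
        # residual variances are optimized on the log scale; report variance
        for k, name in enumerate(self.param_names):
            if name.startswith("theta["):
                est[k] = np.exp(est[k])
                z[k] = np.nan  # Wald on log-variance is not of interest here
        p = 2 * stats.norm.sf(np.abs(z))
        return pd.DataFrame(
            {"estimate": est, "se": self.se, "z": z, "p": p}, index=self.param_names
        )

    def loading_table(self, group: int = 0) -> pd.DataFrame:
        """Loadings with SEs, Wald tests and standardized values."""
        st = self.structure
        wt = self.wald_table()
        rows = []
        lam_std = self.std[group]["lambda"]
        for i, ind in enumerate(st.indicators):
            for f, fac in enumerate(st.factors):
                if not st.loading_free[i, f]:
                    continue
                name = f"lam[{ind}~{fac}]"
                key = name if name in wt.index else f"{name}|{self.group_names[group]}"
                if key not in wt.index:  # fixed marker loading
                    rows.append(
                        {"indicator": ind, "factor": fac, "estimate": 1.0,
                         "se": np.nan, "z": np.nan, "p": np.nan,
                         "std": lam_std[i, f]}
                    )
                    continue
                r = wt.loc[key]
                rows.append(
                    {
                        "indicator": ind, "factor": fac,
                        "estimate": r["estimate"], "se": r["se"],
                        "z": r["z"], "p": r["p"], "std": lam_std[i, f],
                    }
                )
        return pd.DataFrame(rows)

    def factor_correlations(self, group: int = 0) -> pd.DataFrame:
        """Cross-construct disturbance correlations with Wald tests."""
        st = self.structure
        wt = self.wald_table()
        rows = []
        for a, b in st.free_phi_pairs:
            name = f"psi[{st.factors[a]},{st.factors[b]}]"
            key = name if name in wt.index else f"{name}|{self.group_names[group]}"
            r = wt.loc[key]
            rows.append(
                {
                    "factor_1": st.factors[a], "factor_2": st.factors[b],
                    "r": r["estimate"], "se": r["se"], "z": r["z"], "p": r["p"],
                }
            )
        return pd.DataFrame(rows)

    def to_dict(self) -> dict:
        """JSON-serializable summary of the fitted model."""
        return {
            "indicators": list(self.structure.indicators),
            "factors": list(self.structure.factors),
            "groups": list(self.group_names),
            "n": [int(v) for v in self.n],
            "estimates": dict(zip(self.param_names, map(float, self.theta_hat))),
            "se": dict(zip(self.param_names, map(float, self.se))),
            "chi2": float(self.chi2),
            "df": int(self.df),
            "pvalue": float(self.pvalue),
            "converged": bool(self.converged),
            "admissible": bool(self.admissible),
        }


# --------------------------------------------------------------------------
# fitting
# --------------------------------------------------------------------------


def _resolve_structure(spec, covariates) -> tuple[ModelStructure, BifactorSpec | None]:
    if isinstance(spec, ModelStructure):
        return spec, None
    if isinstance(spec, BifactorSpec):
        return spec.structure(covariates=covariates), spec
    raise TypeError("spec must be a BifactorSpec or ModelStructure")


def _expected_information(theta, pm: _ParamMap, groups, n_eff):
    st = pm.structure
    p, m, q = st.p, st.m, st.q
    n_par = pm.n_free
    info = np.zeros((n_par, n_par))
    for g, data in enumerate(groups):
        Lam, th, Psi, Gam, nu, alpha = pm.unpack(theta, g)
        P = p + q
        if q:
            W = np.zeros((P, m + q))
            W[:p, :m] = Lam
            W[:p, m:] = Lam @ Gam
            W[p:, m:] = np.eye(q)
            C = np.zeros((m + q, m + q))
            C[:m, :m] = Psi
            C[m:, m:] = data.Sxx
        else:
            W, C = Lam, Psi
        Sig, _ = implied_moments(
            Lam, Psi, th,
            Gam=Gam if q else None, Sxx=data.Sxx if q else None,
        )
        Siginv = linalg.inv(Sig)
        WC = W @ C
        # collect (global index, dSigma, dmu) for parameters active in g
        idx: list[int] = []
        Ds: list[np.ndarray] = []
        dmus: list[np.ndarray] = []
        zero_mu = np.zeros(P)
        eta_mean = (
            alpha + (Gam @ data.xbar if q else 0.0) if nu is not None else None
        )
        for k, (i, f) in enumerate(pm.lam_cells):
            v = np.zeros(m + q) if q else np.zeros(m)
            v[f] = 1.0
            if q:
                v[m:] = Gam[f, :]
            a = W @ (C @ v)
            D = np.zeros((P, P))
            D[i, :] += a
            D[:, i] += a
            idx.append(pm.lam_idx[g][k])
            Ds.append(D)
            if nu is not None:
                dmu = np.zeros(P)
                dmu[i] = eta_mean[f]
                dmus.append(dmu)
            else:
                dmus.append(zero_mu)
        for i in range(p):
            D = np.zeros((P, P))
            D[i, i] = th[i]  # log-scale chain rule
            idx.append(pm.th_idx[g][i])
            Ds.append(D)
            dmus.append(zero_mu)
        for k, f in enumerate(pm.psi_diag):
            idx.append(pm.psi_diag_idx[g][k])
            Ds.append(np.outer(W[:, f], W[:, f]))
            dmus.append(zero_mu)
        for k, (a_, b_) in enumerate(pm.psi_cells):
            D = np.outer(W[:, a_], W[:, b_])
            D = D + D.T
            idx.append(pm.psi_idx[g][k])
            Ds.append(D)
            dmus.append(zero_mu)
        if q:
            for k, (f, c) in enumerate(pm.gam_cells):
                u = np.zeros(P)
                u[:p] = Lam[:, f]
                b_vec = WC[:, m + c]
                D = np.outer(u, b_vec)
                D = D + D.T
                idx.append(pm.gam_idx[g][k])
                Ds.append(D)
                if nu is not None:
                    dmu = np.zeros(P)
                    dmu[:p] = Lam[:, f] * data.xbar[c]
                    dmus.append(dmu)
                else:
                    dmus.append(zero_mu)
        if nu is not None:
            for i in range(p):
                idx.append(pm.nu_idx[g][i])
                Ds.append(np.zeros((P, P)))
                dmu = np.zeros(P)
                dmu[i] = 1.0
                dmus.append(dmu)
            if pm.alpha_idx[g] is not None:
                for f in range(m):
                    idx.append(pm.alpha_idx[g][f])
                    Ds.append(np.zeros((P, P)))
                    dmu = np.zeros(P)
                    dmu[:p] = Lam[:, f]
                    dmus.append(dmu)
        Dstack = np.stack(Ds)  # (t, P, P)
        A = np.einsum("ab,tbc->tac", Siginv, Dstack)
        t = len(idx)
        Ig = 0.5 * n_eff[g] * np.einsum("tab,uba->tu", A, A)
        if nu is not None:
            M = np.stack(dmus)
            Ig += n_eff[g] * (M @ Siginv @ M.T)
        ii = np.asarray(idx)
        info[np.ix_(ii, ii)] += Ig
    return info


def _finish_fit(
    res, pm: _ParamMap, groups, n_eff, structure, spec, meanstructure,
    chi2_scale, tol, compute_se,
) -> FitResult:
    theta = res.x
    grad_norm = float(np.max(np.abs(res.jac))) if res.jac is not None else np.inf
    converged = bool(res.success) or grad_norm < 50 * tol
    params, std = [], []
    admissible = True
    for g, data in enumerate(groups):
        Lam, th, Psi, Gam, nu, alpha = pm.unpack(theta, g)
        Phi_star = Psi + (Gam @ data.Sxx @ Gam.T if structure.q else 0.0)
        Sig_yy = Lam @ Phi_star @ Lam.T + np.diag(th)
        sd_y = np.sqrt(np.diag(Sig_yy))
        fac_sd = np.sqrt(np.clip(np.diag(Phi_star), 0, None))
        Lam_std = Lam * fac_sd[None, :] / sd_y[:, None]
        th_std = th / sd_y**2
        params.append(
            {"lambda": Lam, "theta": th, "psi": Psi, "gamma": Gam,
             "nu": nu, "alpha": alpha}
        )
        std.append({"lambda": Lam_std, "theta": th_std, "psi": Psi.copy()})
        if th_std.min() <= 1e-6:
            admissible = False
        if pm.psi_cells or pm.psi_diag:
            eig = np.linalg.eigvalsh((Psi + Psi.T) / 2)
            if eig.min() <= 1e-8:
                admissible = False

    F_min = float(res.fun)
    chi2 = float(sum(n_eff) * F_min)
    # degrees of freedom: moments minus free parameters minus the saturated
    # fixed-x covariate block per group
    P = structure.p + structure.q
    mom = 0
    fixed_x = 0
    for _ in groups:
        mom += P * (P + 1) // 2 + (P if meanstructure else 0)
        fixed_x += structure.q * (structure.q + 1) // 2 + (
            structure.q if meanstructure else 0
        )
    df = mom - pm.n_free - fixed_x

    se = np.full(pm.n_free, np.nan)
    if compute_se and pm.n_free:
        info = _expected_information(theta, pm, groups, n_eff)
        eig = np.linalg.eigvalsh((info + info.T) / 2)
        if eig.min() <= 0 or eig.min() / eig.max() < 1e-12:
            # standard errors not computable: empirically underidentified
            # solution (e.g. a collapsed specific factor)
            admissible = False
            cov = linalg.pinvh(info)
            se = np.sqrt(np.clip(np.diag(cov), 0, None))
        else:
            se = np.sqrt(np.diag(linalg.inv(info)))

    return FitResult(
        structure=structure,
        group_names=list(pm.groups),
        n=[g.n for g in groups],
        params=params,
        std=std,
        theta_hat=theta,
        param_names=list(pm.names),
        se=se,
        F_min=F_min,
        chi2=chi2,
        df=df,
        converged=converged,
        admissible=admissible,
        n_iter=int(res.nit),
        meanstructure=meanstructure,
        chi2_scale=chi2_scale,
        data=list(groups),
        message=str(res.message),
        spec=spec,
    )


class _ScoringResult:
    def __init__(self, x, fun, jac, nit, success, message):
        self.x, self.fun, self.jac = x, fun, jac
        self.nit, self.success, self.message = nit, success, message


def _minimize(pm, groups, n_eff, start, tol, max_iter, method="fisher"):
    w = np.asarray(n_eff, dtype=float)
    w = w / w.sum()
    logdetS = []
    for data in groups:
        sign, ld = np.linalg.slogdet(data.S)
        if sign <= 0:
            raise ValueError("sample covariance matrix is not positive definite")
        logdetS.append(ld)

    def objective(theta):
        F = 0.0
        grad = np.zeros(pm.n_free)
        for g in range(len(groups)):
            Fg, gg = _group_objective(theta, pm, g, groups[g], logdetS[g])
            F += w[g] * Fg
            grad += w[g] * gg
        return F, grad

    if method == "lbfgs":
        return optimize.minimize(
            objective,
            start,
            jac=True,
            method="L-BFGS-B",
            options={"maxiter": max_iter, "maxfun": 10 * max_iter,
                     "gtol": tol, "ftol": 1e-14},
        )
    if method != "fisher":
        raise ValueError(f"unknown optimizer {method!r}")
    res = _fisher_scoring(
        objective, pm, groups, n_eff, start, tol, min(300, max_iter)
    )
    if not res.success:
        # scoring can crawl near a flat ridge (e.g. a vanishing specific
        # factor); polish with a quasi-Newton pass from where it stopped
        polish = optimize.minimize(
            objective,
            res.x,
            jac=True,
            method="L-BFGS-B",
            options={"maxiter": max_iter, "maxfun": 10 * max_iter,
                     "gtol": tol, "ftol": 1e-14},
        )
        if polish.fun <= res.fun:
            return polish
    return res


def _fisher_scoring(objective, pm, groups, n_eff, start, tol, max_iter):
    """Fisher scoring: Newton-type steps with the expected information,
    Levenberg damping and step-halving line search.

    Monotone descent from the deterministic start values, so the fit
    converges to the stationary point in the start basin — the estimation
    convention of standard SEM software (sign-indeterminate factors keep
    the orientation of their start values unless the data monotonically
    pull them across zero).
    """
    n_tot = float(sum(n_eff))
    x = np.asarray(start, dtype=float).copy()
    F, g = objective(x)
    it = 0
    message = "maximum iterations reached"
    success = False
    for it in range(1, max_iter + 1):
        if np.max(np.abs(g)) < tol:
            success = True
            message = "gradient norm below tolerance"
            break
        info = _expected_information(x, pm, groups, n_eff)
        H = (2.0 / n_tot) * info
        ridge = 0.0
        step = None
        step_cap = 2.0 + 0.5 * float(np.abs(x).max())
        for _ in range(60):
            try:
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore", linalg.LinAlgWarning)
                    Hd = H + ridge * np.eye(len(x))
                    step = linalg.solve(Hd, -g, assume_a="pos")
            except linalg.LinAlgError:
                step = None
            # accept a damped step that descends and is not absurdly long
            if step is not None and step @ g < 0 and np.abs(step).max() <= step_cap:
                break
            ridge = max(1e-8, 4.0 * ridge) if ridge else 1e-8
        if step is None or step @ g >= 0:
            step = -g  # gradient fallback
        # Armijo backtracking
        t = 1.0
        accepted = False
        for _ in range(60):
            Fn, gn = objective(x + t * step)
            if Fn < F + 1e-4 * t * (g @ step):
                x = x + t * step
                F, g = Fn, gn
                accepted = True
                break
            t *= 0.5
        if not accepted:
            message = "line search failed to improve the discrepancy"
            success = np.max(np.abs(g)) < 50 * tol
            break
    else:
        it = max_iter
    if np.max(np.abs(g)) < tol:
        success = True
        message = "gradient norm below tolerance"
    return _ScoringResult(x, F, g, it, success, message)


def fit_ml(
    data,
    spec,
    *,
    covariates: Sequence[str] = (),
    meanstructure: bool = False,
    chi2_scale: str = "N",
    tol: float = 1e-7,
    max_iter: int = 3000,
    start: np.ndarray | None = None,
    compute_se: bool = True,
    method: str = "fisher",
    identification: str = "variance",
) -> FitResult:
    """Fit a single-group bifactor model by normal-theory ML.

    ``data`` may be a DataFrame/array of raw scores (indicator columns then
    covariate columns) or a :class:`GroupData` of sample moments.
    ``identification`` picks the scale convention: ``"variance"`` fixes all
    factor variances to 1 with every loading free; ``"marker"`` fixes one
    loading per factor to 1 (a reference indicator when available) and
    frees the factor variance.  Both describe the same model; standardized
    results agree at a proper solution.
    """
    structure, bspec = _resolve_structure(spec, covariates)
    gd = _as_group_data(data, structure)
    pm = _ParamMap(structure, ["all"], (), meanstructure, False,
                   identification=identification)
    n_eff = [gd.n if chi2_scale == "N" else gd.n - 1]
    x0 = pm.start_vector([gd]) if start is None else np.asarray(start, dtype=float)
    res = _minimize(pm, [gd], n_eff, x0, tol, max_iter, method)
    return _finish_fit(
        res, pm, [gd], n_eff, structure, bspec, meanstructure,
        chi2_scale, tol, compute_se,
    )


def fit_multigroup(
    datasets: Mapping[str, object],
    spec,
    *,
    ties: Sequence[str] = (),
    covariates: Sequence[str] = (),
    meanstructure: bool = False,
    free_latent_means: bool | None = None,
    chi2_scale: str = "N",
    tol: float = 1e-7,
    max_iter: int = 4000,
    start: np.ndarray | None = None,
    compute_se: bool = True,
    method: str = "fisher",
    identification: str = "variance",
) -> FitResult:
    """Fit the same model in several groups with optional equality ties.

    ``ties`` is a subset of ``{"loadings", "intercepts", "residuals", "phi",
    "gamma"}``; tied categories share parameters across groups (metric =
    loadings, scalar = loadings + intercepts).  When intercepts are tied and
    a mean structure is present, latent means are freed in all groups but
    the first (the reference group anchors them at zero).
    """
    if len(datasets) < 2:
        raise ValueError("need at least two groups")
    structure, bspec = _resolve_structure(spec, covariates)
    names = list(datasets.keys())
    groups = [_as_group_data(datasets[k], structure) for k in names]
    if free_latent_means is None:
        free_latent_means = meanstructure and "intercepts" in ties
    if free_latent_means and not meanstructure:
        raise ValueError("free_latent_means requires meanstructure=True")
    pm = _ParamMap(structure, names, tuple(ties), meanstructure, free_latent_means,
                   identification=identification)
    n_eff = [g.n if chi2_scale == "N" else g.n - 1 for g in groups]
    x0 = pm.start_vector(groups) if start is None else np.asarray(start, dtype=float)
    res = _minimize(pm, groups, n_eff, x0, tol, max_iter, method)
    return _finish_fit(
        res, pm, groups, n_eff, structure, bspec, meanstructure,
        chi2_scale, tol, compute_se,
    )


def fit_baseline(
    data,
    spec,
    *,
    covariates: Sequence[str] = (),
    meanstructure: bool = False,
    chi2_scale: str = "N",
) -> FitResult:
    """Independence (null) model: free indicator variances, zero covariances.

    With covariates the exogenous block stays saturated, mirroring the
    fixed-x convention of the target models.  Closed form — no optimization.
    """
    structure, bspec = _resolve_structure(spec, covariates)
    if isinstance(data, Mapping):
        names = list(data.keys())
        groups = [_as_group_data(data[k], structure) for k in names]
    else:
        names = ["all"]
        groups = [_as_group_data(data, structure)]
    p, q = structure.p, structure.q
    P = p + q
    chi2 = 0.0
    F_tot = 0.0
    params, std = [], []
    n_eff_tot = 0
    for gd in groups:
        Syy_diag = np.diag(gd.S)[:p]
        _, logdetS = np.linalg.slogdet(gd.S)
        F = float(np.sum(np.log(Syy_diag))) - logdetS
        if q:
            _, ldx = np.linalg.slogdet(gd.Sxx)
            F += ldx
        n_eff = gd.n if chi2_scale == "N" else gd.n - 1
        n_eff_tot += n_eff
        chi2 += n_eff * F
        F_tot += F
        params.append(
            {"lambda": np.zeros((p, 0)), "theta": Syy_diag.copy(),
             "psi": np.zeros((0, 0)), "gamma": np.zeros((0, q)),
             "nu": gd.mean[:p].copy() if meanstructure else None,
             "alpha": np.zeros(0)}
        )
        std.append({"lambda": np.zeros((p, 0)), "theta": np.ones(p),
                    "psi": np.zeros((0, 0))})
    mom = len(groups) * (P * (P + 1) // 2 + (P if meanstructure else 0))
    fixed_x = len(groups) * (q * (q + 1) // 2 + (q if meanstructure else 0))
    free = len(groups) * (p + (p if meanstructure else 0))
    df = mom - free - fixed_x
    null_struct = ModelStructure(
        indicators=structure.indicators,
        factors=(),
        factor_construct=(),
        loading_free=np.zeros((p, 0), dtype=bool),
        phi_free=np.zeros((0, 0), dtype=bool),
        covariates=structure.covariates,
    )
    return FitResult(
        structure=null_struct,
        group_names=names,
        n=[g.n for g in groups],
        params=params,
        std=std,
        theta_hat=np.zeros(0),
        param_names=[],
        se=np.zeros(0),
        F_min=F_tot,
        chi2=float(chi2),
        df=df,
        converged=True,
        admissible=True,
        n_iter=0,
        meanstructure=meanstructure,
        chi2_scale=chi2_scale,
        data=list(groups),
        spec=bspec,
    )


def latent_mean_compare(fit: FitResult) -> pd.DataFrame:
    """Standardized latent mean differences between groups under scalar invariance.

    Requires a multigroup fit with free latent means (scalar model).  For
    each factor, d is the latent mean difference between the reference group
    (mean fixed at zero) and each other group, divided by the model-implied
    pooled latent SD; positive d means the comparison group scores *lower*
    (reads as "worse" for ability factors).  The p-value is the Wald test of
    the mean difference.
    """
    if len(fit.group_names) < 2:
        raise ValueError("latent mean comparison requires a multigroup fit")
    has_alpha = any(name.startswith("alpha[") for name in fit.param_names)
    if not (fit.meanstructure and has_alpha):
        raise ValueError(
            "latent means are not free in this fit; refit with meanstructure=True "
            "and ties including 'intercepts' (scalar invariance)"
        )
    st = fit.structure
    rows = []
    ref = fit.group_names[0]
    n = np.asarray(fit.n, dtype=float)
    for g, gname in enumerate(fit.group_names[1:], start=1):
        pp_ref, pp_g = fit.params[0], fit.params[g]
        for f, fac in enumerate(st.factors):
            name = f"alpha[{fac}]|{gname}"
            alpha = fit.param(name)
            se = fit.se_of(name)
            # pooled model-implied latent SD across the two groups
            sds = []
            for gg, pp in ((0, pp_ref), (g, pp_g)):
                Phi_star = pp["psi"] + (
                    pp["gamma"] @ fit.data[gg].Sxx @ pp["gamma"].T
                    if st.q else 0.0
                )
                sds.append(Phi_star[f, f])
            pooled_sd = float(
                np.sqrt(((n[0] - 1) * sds[0] + (n[g] - 1) * sds[1]) / (n[0] + n[g] - 2))
            )
            d = -alpha / pooled_sd
            z = alpha / se if se > 0 else np.nan
            rows.append(
                {"factor": fac, "group": gname, "reference": ref,
                 "latent_mean_diff": alpha, "se": se,
                 "d": d, "z": z, "p": 2 * stats.norm.sf(abs(z))}
            )
    return pd.DataFrame(rows)
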