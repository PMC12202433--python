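"""The full inferential sequence over a cleaned indicator table.

Measurement stage: 1-factor vs bifactor comparison with fit and
reliability indices.  Structural stage: joint model of both constructs
with the nine cross-construct disturbance correlations free.  Multigroup
stage: the covariance-equality test between ADHD and non-ADHD plus the
configural/metric/scalar invariance ladder and latent mean comparison.
Sensitivity suite: covariate-free and item-removal reruns.

Every stage is a pure function of (data, spec, options); rerunning with
the same inputs reproduces every number.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .engine import (
    FitResult,
    fit_baseline,
    fit_ml,
    fit_multigroup,
    latent_mean_compare,
)
from .indices import FitIndices, delta_chi2, fit_indices, reliability_report
from .specs import BifactorSpec, anxiety_spec, combine_specs, wm_spec

__all__ = [
    "MeasurementStage",
    "StructuralResult",
    "InvarianceLadder",
    "MultigroupResult",
    "run_measurement_stage",
    "run_structural_stage",
    "run_multigroup_stage",
    "sensitivity_suite",
    "table3_row",
]

DEFAULT_COVARIATES = ("age", "sex", "ses")


@dataclass
class MeasurementStage:
    one_factor: FitResult
    bifactor: FitResult
    delta: tuple[float, int, float]          # dchi2, ddf, p
    one_factor_indices: FitIndices
    bifactor_indices: FitIndices
    reliability: dict

    def summary(self) -> pd.DataFrame:
        rows = [
            {"model": "single_factor", **self.one_factor_indices.to_row()},
            {"model": "bifactor", **self.bifactor_indices.to_row(),
             "dchi2": round(self.delta[0], 2), "ddf": self.delta[1],
             "dchi2_p": round(self.delta[2], 4)},
        ]
        return pd.DataFrame(rows)


def _refit_guard(restricted: FitResult, unrestricted: FitResult, refit):
    """Nested Delta-chi2 with a one-shot refit from the unrestricted optimum
    if the restricted fit looks under-optimized."""
    try:
        return delta_chi2(restricted, unrestricted), restricted
    except ValueError:
        refitted = refit()
        return delta_chi2(refitted, unrestricted), refitted


def run_measurement_stage(
    data: pd.DataFrame,
    spec: BifactorSpec,
    covariates: Sequence[str] = DEFAULT_COVARIATES,
    **fit_kwargs,
) -> MeasurementStage:
    """Fit the 1-factor and bifactor measurement models, compare them, and
    report fit and reliability indices.

    The bifactor model is retained on substantive grounds when the nested
    chi-square difference is significant and the indices are adequate; the
    stage reports everything and decides nothing.
    """
    covariates = tuple(c for c in covariates if c in data.columns)
    bifactor = fit_ml(data, spec, covariates=covariates, **fit_kwargs)
    if not bifactor.admissible:
        warnings.warn(
            f"bifactor fit for {spec.construct!r} is inadmissible "
            "(Heywood case or underidentified solution); comparison reported anyway"
        )
    onef = fit_ml(data, spec.one_factor(), covariates=covariates, **fit_kwargs)
    baseline = fit_baseline(data, spec, covariates=covariates)
    (d, ddf, p), onef = _refit_guard(
        onef, bifactor,
        lambda: fit_ml(data, spec.one_factor(), covariates=covariates,
                       method="lbfgs", **fit_kwargs),
    )
    return MeasurementStage(
        one_factor=onef,
        bifactor=bifactor,
        delta=(d, ddf, p),
        one_factor_indices=fit_indices(onef, baseline),
        bifactor_indices=fit_indices(bifactor, baseline),
        reliability=reliability_report(bifactor),
    )


@dataclass
class StructuralResult:
    fit: FitResult
    correlations: pd.DataFrame      # 9 rows: anxiety factor x WM factor
    indices: FitIndices

    def correlation_block(self) -> pd.DataFrame:
        """3x3 block: anxiety factors (rows) by WM factors (columns)."""
        tab = self.correlations
        return tab.pivot(index="anxiety_factor", columns="wm_factor", values="r")


def run_structural_stage(
    data: pd.DataFrame,
    anx_spec: BifactorSpec | None = None,
    wm_sp: BifactorSpec | None = None,
    covariates: Sequence[str] = DEFAULT_COVARIATES,
    **fit_kwargs,
) -> StructuralResult:
    """Joint structural model: both measurement structures, within-construct
    orthogonality retained, nine cross-construct disturbance correlations
    free, factors regressed on covariates; Wald p per correlation."""
    anx_spec = anx_spec or anxiety_spec()
    wm_sp = wm_sp or wm_spec()
    covariates = tuple(c for c in covariates if c in data.columns)
    structure = combine_specs(wm_sp, anx_spec, covariates=covariates)
    fit = fit_ml(data, structure, **fit_kwargs)
    if not fit.converged:
        # fall back to staged start values assembled from the separate
        # measurement fits
        fit = fit_ml(data, structure, method="lbfgs", **fit_kwargs)
    baseline = fit_baseline(data, structure)
    corr = fit.factor_correlations()
    wm_factors = set(wm_sp.factor_names)
    rows = []
    for _, rec in corr.iterrows():
        f1, f2 = rec["factor_1"], rec["factor_2"]
        wm_f, anx_f = (f1, f2) if f1 in wm_factors else (f2, f1)
        rows.append(
            {"anxiety_factor": anx_f, "wm_factor": wm_f,
             "r": rec["r"], "se": rec["se"], "z": rec["z"], "p": rec["p"]}
        )
    return StructuralResult(
        fit=fit,
        correlations=pd.DataFrame(rows),
        indices=fit_indices(fit, baseline),
    )


@dataclass
class InvarianceLadder:
    configural: FitResult
    metric: FitResult
    scalar: FitResult
    tests: pd.DataFrame      # Delta-chi2 between adjacent rungs
    latent_means: pd.DataFrame


@dataclass
class MultigroupResult:
    unconstrained: FitResult
    constrained: FitResult
    delta: tuple[float, int, float]
    ladder: InvarianceLadder
    unconstrained_indices: FitIndices
    constrained_indices: FitIndices


def run_multigroup_stage(
    data: pd.DataFrame,
    group_col: str = "group",
    anx_spec: BifactorSpec | None = None,
    wm_sp: BifactorSpec | None = None,
    covariates: Sequence[str] = DEFAULT_COVARIATES,
    min_group_n: int = 20,
    reference_group: str | None = None,
    **fit_kwargs,
) -> MultigroupResult:
    """Multigroup joint model: the covariance-equality test (the nine
    cross-construct covariances tied, df = 9) plus the configural, metric
    and scalar invariance ladder with latent mean comparison.

    The reference group (whose latent means anchor at zero) defaults to
    ``"non_adhd"`` when present, so a lower-scoring clinical group yields
    positive d ("worse") on ability factors.
    """
    anx_spec = anx_spec or anxiety_spec()
    wm_sp = wm_sp or wm_spec()
    covariates = tuple(c for c in covariates if c in data.columns)
    structure = combine_specs(wm_sp, anx_spec, covariates=covariates)
    groups = {
        str(g): sub.drop(columns=[group_col])
        for g, sub in data.groupby(group_col, sort=True)
    }
    if reference_group is None and "non_adhd" in groups:
        reference_group = "non_adhd"
    if reference_group is not None:
        if reference_group not in groups:
            raise ValueError(f"reference group {reference_group!r} not in data")
        groups = {
            reference_group: groups[reference_group],
            **{g: v for g, v in groups.items() if g != reference_group},
        }
    for g, sub in groups.items():
        if len(sub) < min_group_n:
            raise ValueError(f"group {g!r} has n={len(sub)} < {min_group_n}")

    unconstrained = fit_multigroup(groups, structure, ties=(), **fit_kwargs)
    constrained = fit_multigroup(groups, structure, ties=("phi",), **fit_kwargs)
    (d, ddf, p), constrained = _refit_guard(
        constrained, unconstrained,
        lambda: fit_multigroup(groups, structure, ties=("phi",),
                               method="lbfgs", **fit_kwargs),
    )
    baseline = fit_baseline(groups, structure)

    configural = fit_multigroup(
        groups, structure, ties=(), meanstructure=True, **fit_kwargs
    )
    metric = fit_multigroup(
        groups, structure, ties=("loadings",), meanstructure=True, **fit_kwargs
    )
    scalar = fit_multigroup(
        groups, structure, ties=("loadings", "intercepts"),
        meanstructure=True, **fit_kwargs
    )
    t_rows = []
    for label, restr, unrestr in (
        ("metric_vs_configural", metric, configural),
        ("scalar_vs_metric", scalar, metric),
    ):
        dc, ddf2, p2 = delta_chi2(restr, unrestr)
        t_rows.append({"comparison": label, "dchi2": dc, "ddf": ddf2, "p": p2})
    ladder = InvarianceLadder(
        configural=configural,
        metric=metric,
        scalar=scalar,
        tests=pd.DataFrame(t_rows),
        latent_means=latent_mean_compare(scalar),
    )
    return MultigroupResult(
        unconstrained=unconstrained,
        constrained=constrained,
        delta=(d, ddf, p),
        ladder=ladder,
        unconstrained_indices=fit_indices(unconstrained, baseline),
        constrained_indices=fit_indices(constrained, baseline),
    )


def sensitivity_suite(
    data: pd.DataFrame,
    drop_items: Sequence[str] = (),
    drop_from: str = "cognitive_worry",
    covariates: Sequence[str] = DEFAULT_COVARIATES,
    **fit_kwargs,
) -> dict:
    """Reruns of the structural stage (a) without covariates and (b) with a
    named item subset removed from one anxiety specific factor; returns the
    side-by-side correlation blocks."""
    primary = run_structural_stage(data, covariates=covariates, **fit_kwargs)
    no_cov = run_structural_stage(data, covariates=(), **fit_kwargs)
    out = {
        "primary": primary,
        "no_covariates": no_cov,
        "comparison": pd.DataFrame(
            {
                "primary_r": primary.correlations.set_index(
                    ["anxiety_factor", "wm_factor"]
                )["r"],
                "no_covariates_r": no_cov.correlations.set_index(
                    ["anxiety_factor", "wm_factor"]
                )["r"],
            }
        ),
    }
    if drop_items:
        reduced = anxiety_spec().drop_indicators(drop_items)
        out["items_removed"] = run_structural_stage(
            data, anx_spec=reduced, covariates=covariates, **fit_kwargs
        )
        out["comparison"]["items_removed_r"] = out[
            "items_removed"
        ].correlations.set_index(["anxiety_factor", "wm_factor"])["r"]
    return out


def table3_row(name: str, idx: FitIndices, reliability: dict | None = None) -> dict:
    """One row of a fit-statistics summary table (CFI, TLI, RMSEA with CI,
    SRMR, chi2[df], and — for bifactor measurement models — omega, omega_s,
    ECV, PUC and H)."""
    row = {"model": name, **idx.to_row()}
    if reliability:
        row["omega"] = round(reliability["omega"]["omega_total"], 2)
        row["omega_s"] = {
            k: round(v, 2) for k, v in reliability["omega"]["omega_s"].items()
        }
        row["ECV"] = {k: round(v, 2) for k, v in reliability["ecv"].items()}
        row["PUC"] = round(reliability["puc"], 2)
        row["H"] = {k: round(v, 2) for k, v in reliability["H"].items()}
    return row
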