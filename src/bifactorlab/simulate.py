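"""Synthetic study data with the statistical structure the analyses assume.

The generator draws orthogonal-within-construct latent factors from a
population bifactor model (standardized general loadings .60; specific
loadings .40 for the short-term-memory factors and .30 for the anxiety
factors), adds group latent-mean shifts and optional MIMIC covariate
effects, and emits continuous indicators.  Downstream realism layers turn
those into what a study would actually record: 4-point Likert item
responses, trial-level span records (six trials per task x set size),
MCAR missingness, and injected outliers.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .specs import (
    BifactorSpec,
    ModelStructure,
    NEITHER_COMPOSITE,
    NEITHER_ITEMS,
    anxiety_spec,
    combine_specs,
    wm_spec,
)

__all__ = [
    "PopulationModel",
    "SyntheticDataset",
    "build_population_model",
    "wm_population",
    "anxiety_population",
    "joint_population",
    "simulate_latents_and_indicators",
    "simulate_covariates",
    "discretize_to_likert",
    "emit_wm_trials",
    "inject_missing_and_outliers",
    "simulate_ratings",
    "simulate_study",
    "DEFAULT_GROUP_MEANS",
    "WM_INDICATOR_SCALE",
]

#: Default latent mean offsets (standardized units) of the non-ADHD group
#: relative to the ADHD group, mirroring the magnitude of reported latent
#: group differences: large central-executive gap, moderate short-term
#: memory gaps, no anxiety differences.
DEFAULT_GROUP_MEANS: dict[str, dict[str, float]] = {
    "adhd": {},
    "non_adhd": {
        "central_executive": 1.0,
        "phonological_stm": 0.7,
        "visuospatial_stm": 0.66,
    },
}

#: Raw-score location/scale used to map standardized span indicators onto
#: the stimuli-correct-per-trial metric (pooled across groups, consistent
#: with the printed descriptives of the two span tasks).
WM_INDICATOR_SCALE: dict[str, tuple[float, float]] = {
    "phonological_ss3": (2.71, 0.40),
    "phonological_ss4": (3.39, 0.58),
    "phonological_ss5": (3.85, 0.87),
    "phonological_ss6": (3.49, 1.22),
    "visuospatial_ss3": (2.12, 0.63),
    "visuospatial_ss4": (2.62, 0.89),
    "visuospatial_ss5": (2.73, 1.07),
    "visuospatial_ss6": (2.56, 1.17),
}

_DEFAULT_SPECIFIC = {"working_memory": 0.40, "anxiety": 0.30}


@dataclass(frozen=True)
class PopulationModel:
    """True parameter values used by the simulator and the power engines.

    Loadings are standardized, factors have unit variance, and residual
    variances are 1 - lambda_g^2 - lambda_s^2, so indicators are
    standardized in the population.
    """

    structure: ModelStructure
    loadings: np.ndarray          # p x m, zeros where the structure fixes zero
    factor_corr: np.ndarray       # m x m correlation matrix
    group_latent_means: Mapping[str, Mapping[str, float]] = field(
        default_factory=dict
    )
    covariate_effects: np.ndarray | None = None   # m x q
    covariates: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        lam = np.asarray(self.loadings, dtype=float)
        st = self.structure
        if lam.shape != (st.p, st.m):
            raise ValueError("loading matrix shape does not match structure")
        if np.any(lam[~st.loading_free] != 0):
            raise ValueError("nonzero loading in a structurally fixed cell")
        comm = (lam**2).sum(axis=1)
        if np.any(comm >= 1.0):
            bad = st.indicators[int(np.argmax(comm))]
            raise ValueError(
                f"indicator {bad!r} has communality {comm.max():.3f} >= 1 "
                "(negative population residual variance)"
            )
        phi = np.asarray(self.factor_corr, dtype=float)
        if phi.shape != (st.m, st.m):
            raise ValueError("factor_corr shape does not match structure")
        if not np.allclose(phi, phi.T) or not np.allclose(np.diag(phi), 1.0):
            raise ValueError("factor_corr must be symmetric with unit diagonal")
        fixed_zero = ~st.phi_free & ~np.eye(st.m, dtype=bool)
        if np.any(phi[fixed_zero] != 0):
            raise ValueError("within-construct factor correlations must be 0")
        if np.linalg.eigvalsh(phi).min() <= 0:
            raise ValueError("factor correlation matrix is not positive definite")
        if np.linalg.eigvalsh(self.implied_corr()).min() <= 0:
            raise ValueError("implied indicator correlation matrix is not PD")

    @property
    def residual_variances(self) -> np.ndarray:
        return 1.0 - (np.asarray(self.loadings) ** 2).sum(axis=1)

    def implied_corr(self) -> np.ndarray:
        lam = np.asarray(self.loadings, dtype=float)
        sig = lam @ self.factor_corr @ lam.T
        np.fill_diagonal(sig, 1.0)
        return sig

    def latent_mean_vector(self, group: str) -> np.ndarray:
        mu = np.zeros(self.structure.m)
        offsets = self.group_latent_means.get(group, {})
        unknown = set(offsets) - set(self.structure.factors)
        if unknown:
            raise ValueError(f"unknown factors in group means: {sorted(unknown)}")
        for fac, val in offsets.items():
            mu[self.structure.factor_index(fac)] = val
        return mu


def build_population_model(
    spec: BifactorSpec | Sequence[BifactorSpec],
    *,
    lambda_general: float | Mapping[str, float] = 0.60,
    lambda_specific: float | Mapping[str, float] | None = None,
    factor_corr: Mapping[tuple[str, str], float] | None = None,
    group_latent_means: Mapping[str, Mapping[str, float]] | None = None,
    covariate_effects: np.ndarray | None = None,
    covariates: Sequence[str] = (),
) -> PopulationModel:
    """Assemble a population bifactor model from one or more construct specs.

    ``lambda_general`` / ``lambda_specific`` may be scalars or per-indicator
    mappings; unlisted specific loadings default to .40 for working memory
    and .30 for anxiety.  ``factor_corr`` gives cross-construct correlations
    by factor-name pair; within-construct correlations are fixed at zero.
    """
    specs = [spec] if isinstance(spec, BifactorSpec) else list(spec)
    st = combine_specs(*specs, covariates=covariates)
    lam = np.zeros((st.p, st.m))
    for s in specs:
        g = st.factor_index(s.general)
        for ind in s.indicators:
            i = st.indicators.index(ind)
            lg = (
                lambda_general.get(ind, 0.60)
                if isinstance(lambda_general, Mapping)
                else lambda_general
            )
            if not -1 < lg < 1:
                raise ValueError(f"general loading {lg} outside (-1, 1)")
            lam[i, g] = lg
        for fac, members in s.specifics.items():
            fcol = st.factor_index(fac)
            default_s = _DEFAULT_SPECIFIC.get(s.construct, 0.40)
            for ind in members:
                i = st.indicators.index(ind)
                ls = (
                    lambda_specific.get(ind, default_s)
                    if isinstance(lambda_specific, Mapping)
                    else (default_s if lambda_specific is None else lambda_specific)
                )
                if not -1 < ls < 1:
                    raise ValueError(f"specific loading {ls} outside (-1, 1)")
                lam[i, fcol] = ls
    phi = np.eye(st.m)
    for (a, b), r in (factor_corr or {}).items():
        ia, ib = st.factor_index(a), st.factor_index(b)
        if not st.phi_free[ia, ib]:
            raise ValueError(f"correlation {a!r}~{b!r} is fixed at 0 (same construct)")
        if not -1 < r < 1:
            raise ValueError("factor correlations must lie in (-1, 1)")
        phi[ia, ib] = phi[ib, ia] = r
    gam = None
    if covariates:
        gam = (
            np.zeros((st.m, st.q))
            if covariate_effects is None
            else np.asarray(covariate_effects, dtype=float)
        )
        if gam.shape != (st.m, st.q):
            raise ValueError("covariate_effects must be m x q")
    return PopulationModel(
        structure=st,
        loadings=lam,
        factor_corr=phi,
        group_latent_means=dict(group_latent_means or {}),
        covariate_effects=gam,
        covariates=tuple(covariates),
    )


def aggregate_reference_loading(item_loading: float = 0.60, k: int = 17) -> float:
    """Standardized general-factor loading of a unit-weight sum of ``k``
    standardized items that each load ``item_loading`` on the general factor
    alone: k*l / sqrt(k + k(k-1) l^2).  For 17 items at .60 this is ~.95 —
    an aggregate reference facet anchors the general factor far more
    strongly than any single item."""
    l = float(item_loading)
    return k * l / float(np.sqrt(k + k * (k - 1) * l**2))


def wm_population(**kwargs) -> PopulationModel:
    """Hypothesized working-memory population: lambda_g=.60, lambda_s=.40."""
    return build_population_model(wm_spec(), **kwargs)


def anxiety_population(
    lambda_general: float | Mapping[str, float] = 0.60,
    composite_loading: float | None = None,
    **kwargs,
) -> PopulationModel:
    """Hypothesized anxiety population: item loadings lambda_g=.60 and
    lambda_s=.30; the reference composite, being a 17-item aggregate, gets
    the loading implied by the item-level hypothesis (~.95) unless
    overridden via ``composite_loading`` or a ``lambda_general`` mapping."""
    if not isinstance(lambda_general, Mapping):
        if composite_loading is None:
            composite_loading = aggregate_reference_loading(lambda_general)
        lg: Mapping[str, float] | float = {
            **{i: lambda_general for i in anxiety_spec().indicators},
            NEITHER_COMPOSITE: composite_loading,
        }
    else:
        lg = lambda_general
    return build_population_model(anxiety_spec(), lambda_general=lg, **kwargs)


def joint_population(
    r_general: float = 0.30,
    factor_corr: Mapping[tuple[str, str], float] | None = None,
    composite_loading: float | None = None,
    lambda_general: float | Mapping[str, float] = 0.60,
    **kwargs,
) -> PopulationModel:
    """Joint 31-indicator population with a cross-construct general-general
    correlation ``r_general``; other cross correlations default to zero."""
    fc = {("central_executive", "common_anxiety"): r_general}
    fc.update(factor_corr or {})
    if not isinstance(lambda_general, Mapping):
        if composite_loading is None:
            composite_loading = aggregate_reference_loading(lambda_general)
        lambda_general = {NEITHER_COMPOSITE: composite_loading}
    return build_population_model(
        [wm_spec(), anxiety_spec()], factor_corr=fc,
        lambda_general=lambda_general, **kwargs,
    )


@dataclass
class SyntheticDataset:
    """One simulated study: indicator table plus optional realism layers."""

    indicators: pd.DataFrame          # continuous indicators + covariates + group
    latents: pd.DataFrame             # true per-subject factor scores
    population: PopulationModel
    seed: int
    anxiety_items: pd.DataFrame | None = None   # 40-item integer responses
    wm_trials: pd.DataFrame | None = None       # long trial records
    changes: dict = field(default_factory=dict)  # injected missing/outlier cells

    @property
    def n(self) -> int:
        return len(self.indicators)


def simulate_covariates(n: int, rng: np.random.Generator) -> pd.DataFrame:
    """Age ~ U(8.1, 13.5) years, sex ~ Bernoulli(.5), Hollingshead SES ~
    N(47, 11) truncated to [11, 66]."""
    age = rng.uniform(8.1, 13.5, n)
    sex = rng.integers(0, 2, n).astype(float)
    a, b = (11 - 47) / 11, (66 - 47) / 11
    ses = stats.truncnorm.rvs(a, b, loc=47, scale=11, size=n, random_state=rng)
    return pd.DataFrame({"age": age, "sex": sex, "ses": ses})


def simulate_latents_and_indicators(
    pop: PopulationModel,
    n: int,
    seed: int,
    group_mix: Mapping[str, float] | None = None,
) -> SyntheticDataset:
    """Draw latent factors and continuous indicators from a population model.

    Factors are multivariate normal with unit variances, within-construct
    orthogonality and the population's cross-construct correlations; each
    group's latent means are shifted by its configured offsets.  Indicators
    are Lambda f + Gamma-mediated covariate effects + normal residual.
    Identical (pop, n, seed, group_mix) reproduce the dataset bit for bit.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    st = pop.structure
    if group_mix is None:
        group_mix = {"all": 1.0} if not pop.group_latent_means else {
            g: 1.0 / len(pop.group_latent_means) for g in pop.group_latent_means
        }
    gnames = list(group_mix)
    probs = np.asarray([group_mix[g] for g in gnames], dtype=float)
    if probs.sum() <= 0:
        raise ValueError("group_mix proportions must sum to a positive value")
    probs = probs / probs.sum()
    group = rng.choice(len(gnames), size=n, p=probs)
    group_labels = np.asarray(gnames, dtype=object)[group]

    L = np.linalg.cholesky(pop.factor_corr)
    eta = rng.standard_normal((n, st.m)) @ L.T
    for gi, gname in enumerate(gnames):
        mask = group == gi
        eta[mask] += pop.latent_mean_vector(gname)

    cov_df = None
    if pop.covariates:
        cov_df = simulate_covariates(n, rng)[list(pop.covariates)]
        xc = cov_df.to_numpy() - cov_df.to_numpy().mean(axis=0)
        eta = eta + xc @ pop.covariate_effects.T

    eps = rng.standard_normal((n, st.p)) * np.sqrt(pop.residual_variances)
    Y = eta @ pop.loadings.T + eps
    ind = pd.DataFrame(Y, columns=list(st.indicators))
    if cov_df is not None:
        ind = pd.concat([ind, cov_df], axis=1)
    ind["group"] = group_labels
    latents = pd.DataFrame(eta, columns=list(st.factors))
    return SyntheticDataset(
        indicators=ind, latents=latents, population=pop, seed=seed
    )


def discretize_to_likert(
    continuous: np.ndarray | pd.DataFrame,
    thresholds: Sequence[float] | np.ndarray,
) -> np.ndarray | pd.DataFrame:
    """Bin continuous item values into ordinal categories 0..K.

    ``thresholds`` is either one strictly increasing cut-point vector shared
    by all items or a per-item (n_items x K) array.  A value in
    (t_{k-1}, t_k] maps to category k-? — concretely, category = number of
    thresholds strictly below-or-equal, so value 0.0 with cuts (-.5, .5, 1.5)
    falls in category 1.
    """
    arr = continuous.to_numpy() if isinstance(continuous, pd.DataFrame) else np.asarray(continuous)
    arr = np.atleast_2d(arr)
    th = np.asarray(thresholds, dtype=float)
    if th.ndim == 1:
        th = np.tile(th, (arr.shape[1], 1))
    if th.shape[0] != arr.shape[1]:
        raise ValueError("need one threshold vector per item")
    if np.any(np.diff(th, axis=1) <= 0):
        raise ValueError("thresholds must be strictly increasing")
    out = np.zeros_like(arr, dtype=int)
    for j in range(arr.shape[1]):
        out[:, j] = np.searchsorted(th[j], arr[:, j], side="left")
    if isinstance(continuous, pd.DataFrame):
        return pd.DataFrame(out, columns=continuous.columns, index=continuous.index)
    return out


def emit_wm_trials(
    indicator_scores: pd.DataFrame, seed: int = 0
) -> pd.DataFrame:
    """Expand per-subject span scores into six-trial records.

    Each of the 8 task x set-size indicators is a mean of six stimuli-correct
    counts, so attainable means lie on the grid of multiples of 1/6.  The
    target score is rounded to that grid and decomposed into six integer
    trials in [0, set size]; rescoring the trials recovers the target to
    within half a grid step (1/12).  Trial order is shuffled with ``seed``.
    """
    rng = np.random.default_rng(seed)
    rows = []
    for subj, row in indicator_scores.iterrows():
        for col in indicator_scores.columns:
            task, ss = col.rsplit("_ss", 1)
            s = int(ss)
            target = float(row[col])
            if not 0 <= target <= s:
                raise ValueError(
                    f"target {target} outside [0, {s}] for {col!r} (subject {subj})"
                )
            total = int(round(target * 6))
            base, rem = divmod(total, 6)
            trials = np.full(6, base, dtype=int)
            trials[:rem] += 1
            rng.shuffle(trials)
            for t, nc in enumerate(trials, start=1):
                rows.append(
                    {"subject": subj, "task": task, "set_size": s,
                     "trial": t, "n_correct": int(nc)}
                )
    return pd.DataFrame(rows)


def inject_missing_and_outliers(
    data: pd.DataFrame,
    missing_rate: float = 0.0,
    outlier_count: int = 0,
    seed: int = 0,
    *,
    columns: Sequence[str] | None = None,
    group_col: str = "group",
    outlier_sd: float = 5.0,
) -> tuple[pd.DataFrame, dict]:
    """Blank cells completely at random and inflate cells into outliers.

    Returns the perturbed copy plus a record of which cells were blanked or
    inflated, so cleaning steps can be verified against ground truth.
    Outliers are placed at group mean + ``outlier_sd`` group SDs (> 3 by
    construction, so the 3-SD screen must flag them).
    """
    if not 0 <= missing_rate < 1:
        raise ValueError("missing_rate must be in [0, 1)")
    if outlier_sd <= 3:
        raise ValueError("outlier_sd must exceed the 3-SD screening threshold")
    rng = np.random.default_rng(seed)
    out = data.copy()
    if columns is None:
        columns = [
            c for c in data.columns
            if c != group_col and np.issubdtype(data[c].dtype, np.number)
        ]
    cells = [(i, c) for c in columns for i in range(len(data))]
    if outlier_count > len(cells):
        raise ValueError("outlier_count exceeds available cells")
    changes: dict = {"missing": [], "outliers": []}
    groups = (
        data[group_col] if group_col in data.columns
        else pd.Series(["all"] * len(data), index=data.index)
    )
    if outlier_count:
        picked = rng.choice(len(cells), size=outlier_count, replace=False)
        for k in picked:
            i, c = cells[k]
            if np.issubdtype(out[c].dtype, np.integer):
                out[c] = out[c].astype(float)
            g = groups.iloc[i]
            col_g = data.loc[groups == g, c]
            val = float(col_g.mean() + outlier_sd * col_g.std(ddof=1))
            out.iloc[i, out.columns.get_loc(c)] = val
            changes["outliers"].append((data.index[i], c, val))
    if missing_rate > 0:
        mask = rng.random((len(data), len(columns))) < missing_rate
        for j, c in enumerate(columns):
            col_loc = out.columns.get_loc(c)
            if np.issubdtype(out[c].dtype, np.integer):
                out[c] = out[c].astype(float)
                col_loc = out.columns.get_loc(c)
            for i in np.nonzero(mask[:, j])[0]:
                out.iloc[i, col_loc] = np.nan
                changes["missing"].append((data.index[i], c))
    return out, changes


def simulate_ratings(
    n_items: int = 40,
    n_raters: int = 7,
    categories: Sequence[str] = (
        "cognitive_worry", "physiological_arousal", "both", "neither_unclear",
    ),
    true_categories: Sequence[str] | None = None,
    error_rate: float = 0.08,
    seed: int = 0,
) -> pd.DataFrame:
    """Items-by-raters categorical judgments with a planted consensus.

    Each rater reports the item's true category with probability
    1 - ``error_rate``, otherwise a uniformly random other category.
    """
    rng = np.random.default_rng(seed)
    cats = list(categories)
    if true_categories is None:
        true_categories = [cats[rng.integers(len(cats))] for _ in range(n_items)]
    if len(true_categories) != n_items:
        raise ValueError("need one true category per item")
    rows = {}
    for i, truth in enumerate(true_categories):
        judgments = []
        for _ in range(n_raters):
            if rng.random() < error_rate:
                others = [c for c in cats if c != truth]
                judgments.append(others[rng.integers(len(others))])
            else:
                judgments.append(truth)
        rows[f"item{i + 1:02d}"] = judgments
    return pd.DataFrame.from_dict(
        rows, orient="index", columns=[f"rater{r + 1}" for r in range(n_raters)]
    )


def simulate_study(
    n: int = 340,
    seed: int = 0,
    *,
    group_mix: Mapping[str, float] | None = None,
    factor_corr: Mapping[tuple[str, str], float] | None = None,
    group_latent_means: Mapping[str, Mapping[str, float]] | None = None,
    covariates: Sequence[str] = ("age", "sex", "ses"),
    covariate_effects: np.ndarray | None = None,
    likert: bool = True,
    item_thresholds: Sequence[float] = (-0.8, 0.2, 1.2),
    missing_rate: float = 0.002,
    outlier_count: int = 0,
) -> SyntheticDataset:
    """End-to-end study emulation: 40 anxiety items, trial-level span records,
    covariates and group labels, ready for the preprocessing pipeline.

    The 22 worry/arousal items and the span indicators come from the joint
    bifactor population; the 17 "neither" items are generated from the
    common-anxiety factor alone at the hypothesized item loading (.60), so
    their sum behaves like the reference composite.  The single "both" item
    loads weakly on all three anxiety factors.
    """
    if group_mix is None:
        group_mix = {"adhd": 197 / 340, "non_adhd": 143 / 340}
    if group_latent_means is None:
        group_latent_means = DEFAULT_GROUP_MEANS
    pop = joint_population(
        factor_corr=factor_corr or {},
        r_general=(factor_corr or {}).get(
            ("central_executive", "common_anxiety"), 0.0
        ),
        group_latent_means=group_latent_means,
        covariates=covariates,
        covariate_effects=covariate_effects,
    )
    ds = simulate_latents_and_indicators(pop, n, seed, group_mix=group_mix)
    rng = np.random.default_rng(np.random.SeedSequence([seed, 1]))
    st = pop.structure
    ca = ds.latents["common_anxiety"].to_numpy()
    cw = ds.latents["cognitive_worry"].to_numpy()
    pa = ds.latents["physiological_arousal"].to_numpy()

    # assemble the 40-item continuous matrix
    item_cols = [f"item{i:02d}" for i in range(1, 41)]
    items = pd.DataFrame(index=ds.indicators.index, columns=item_cols, dtype=float)
    for c in item_cols:
        if c in st.indicators:
            items[c] = ds.indicators[c]
    ln = 0.60
    for i in NEITHER_ITEMS:
        items[f"item{i:02d}"] = ln * ca + np.sqrt(1 - ln**2) * rng.standard_normal(n)
    lb = 0.4
    items["item40"] = (
        lb * ca + 0.2 * cw + 0.2 * pa
        + np.sqrt(1 - lb**2 - 2 * 0.2**2) * rng.standard_normal(n)
    )
    if likert:
        items = discretize_to_likert(items, item_thresholds)

    # span indicators -> raw score scale -> trial records
    wm_cols = [c for c in st.indicators if "_ss" in c]
    scores = pd.DataFrame(index=ds.indicators.index)
    for c in wm_cols:
        mu, sd = WM_INDICATOR_SCALE[c]
        s = int(c.rsplit("_ss", 1)[1])
        scores[c] = np.clip(mu + sd * ds.indicators[c], 0, s)
    trials = emit_wm_trials(scores, seed=int(rng.integers(2**31)))

    items_out = items.copy()
    changes: dict = {}
    if missing_rate or outlier_count:
        merged = pd.concat([items_out, ds.indicators[["group"]]], axis=1)
        merged, changes = inject_missing_and_outliers(
            merged,
            missing_rate=missing_rate,
            outlier_count=outlier_count,
            seed=int(rng.integers(2**31)),
            columns=item_cols,
        )
        items_out = merged[item_cols]

    ds.anxiety_items = items_out
    ds.wm_trials = trials
    ds.changes = changes
    return ds
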