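"""Tidy on-disk formats: wide item/indicator tables, long trial records,
population models as YAML, and a JSON run manifest recording seeds."""

from __future__ import annotations

import json
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
import yaml

from .simulate import PopulationModel, SyntheticDataset

__all__ = [
    "write_study",
    "read_items",
    "read_trials",
    "write_population_yaml",
    "read_population_yaml",
    "write_manifest",
    "read_manifest",
]


def write_study(ds: SyntheticDataset, outdir: str | Path) -> dict[str, Path]:
    """Write one simulated study: items+covariates+group wide CSV, long
    trial CSV, and a manifest with the seed."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {}
    cov_cols = [c for c in ("age", "sex", "ses", "group") if c in ds.indicators.columns]
    wide = ds.indicators[cov_cols].copy()
    if ds.anxiety_items is not None:
        wide = pd.concat([ds.anxiety_items, wide], axis=1)
    paths["items"] = outdir / "items.csv"
    wide.to_csv(paths["items"], index_label="subject")
    if ds.wm_trials is not None:
        paths["trials"] = outdir / "trials.csv"
        ds.wm_trials.to_csv(paths["trials"], index=False)
    paths["manifest"] = write_manifest(
        outdir / "manifest.json", seed=ds.seed, n=ds.n,
        files={k: str(v.name) for k, v in paths.items()},
    )
    return paths


def read_items(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, index_col="subject")


def read_trials(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path)


def write_population_yaml(pop: PopulationModel, path: str | Path) -> Path:
    """Serialize a population model (loadings, factor correlations, group
    means, covariate effects) to YAML."""
    st = pop.structure
    doc = {
        "indicators": list(st.indicators),
        "factors": list(st.factors),
        "factor_construct": list(st.factor_construct),
        "loadings": {
            st.indicators[i]: {
                st.factors[f]: float(pop.loadings[i, f])
                for f in range(st.m)
                if pop.loadings[i, f] != 0
            }
            for i in range(st.p)
        },
        "factor_corr": {
            f"{st.factors[a]}~~{st.factors[b]}": float(pop.factor_corr[a, b])
            for a in range(st.m)
            for b in range(a + 1, st.m)
            if pop.factor_corr[a, b] != 0
        },
        "group_latent_means": {
            g: dict(v) for g, v in pop.group_latent_means.items()
        },
        "covariates": list(pop.covariates),
    }
    if pop.covariate_effects is not None:
        doc["covariate_effects"] = {
            st.factors[f]: {
                pop.covariates[c]: float(pop.covariate_effects[f, c])
                for c in range(len(pop.covariates))
            }
            for f in range(st.m)
        }
    path = Path(path)
    path.write_text(yaml.safe_dump(doc, sort_keys=False))
    return path


def read_population_yaml(path: str | Path) -> PopulationModel:
    """Rebuild a population model from its YAML serialization."""
    from .specs import ModelStructure
    import itertools

    doc = yaml.safe_load(Path(path).read_text())
    indicators = tuple(doc["indicators"])
    factors = tuple(doc["factors"])
    constructs = tuple(doc["factor_construct"])
    p, m = len(indicators), len(factors)
    lam = np.zeros((p, m))
    lf = np.zeros((p, m), dtype=bool)
    for ind, row in doc["loadings"].items():
        i = indicators.index(ind)
        for fac, val in row.items():
            f = factors.index(fac)
            lam[i, f] = val
            lf[i, f] = True
    phi = np.eye(m)
    phi_free = np.zeros((m, m), dtype=bool)
    for a, b in itertools.combinations(range(m), 2):
        if constructs[a] != constructs[b]:
            phi_free[a, b] = phi_free[b, a] = True
    for key, val in doc.get("factor_corr", {}).items():
        fa, fb = key.split("~~")
        a, b = factors.index(fa), factors.index(fb)
        phi[a, b] = phi[b, a] = val
    st = ModelStructure(
        indicators=indicators, factors=factors, factor_construct=constructs,
        loading_free=lf, phi_free=phi_free,
        covariates=tuple(doc.get("covariates", ())),
    )
    gam = None
    if "covariate_effects" in doc:
        gam = np.zeros((m, len(st.covariates)))
        for fac, row in doc["covariate_effects"].items():
            for cov, val in row.items():
                gam[factors.index(fac), st.covariates.index(cov)] = val
    return PopulationModel(
        structure=st, loadings=lam, factor_corr=phi,
        group_latent_means=doc.get("group_latent_means", {}),
        covariate_effects=gam, covariates=st.covariates,
    )


def write_manifest(path: str | Path, **fields) -> Path:
    path = Path(path)
    path.write_text(json.dumps(fields, indent=2, default=str) + "\n")
    return path


def read_manifest(path: str | Path) -> dict:
    return json.loads(Path(path).read_text())
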