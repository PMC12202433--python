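"""Declarative bifactor model specifications.

A bifactor measurement model has one *general* factor on which every
indicator loads, plus orthogonal *specific* factors each claiming a subset
of indicators.  Identification follows the reference-facet convention: at
least one indicator per construct loads only on the general factor, which
anchors its meaning (common anxiety is anchored by the composite of items
judged neither worry nor arousal; the central executive is anchored by the
set-size-3 span conditions of both modalities).

Several specs can be combined into a joint multi-construct structure in
which factors from different constructs may covary while within-construct
orthogonality is retained.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

__all__ = [
    "BifactorSpec",
    "ModelStructure",
    "anxiety_spec",
    "wm_spec",
    "combine_specs",
    "WM_INDICATORS",
    "CW_ITEMS",
    "PA_ITEMS",
    "BOTH_ITEMS",
    "NEITHER_ITEMS",
    "NEITHER_COMPOSITE",
]

# MASC-2 item-pool classification (Obsessions/Compulsions items excluded,
# leaving 40 items): 11 cognitive-worry and 11 physiological-arousal items,
# one item judged to tap both (dropped from modeling), and 17 judged neither,
# which are summed into the reference composite.
CW_ITEMS: tuple[int, ...] = (3, 4, 7, 10, 14, 16, 22, 29, 30, 32, 33)
PA_ITEMS: tuple[int, ...] = (1, 6, 8, 12, 15, 18, 24, 27, 31, 34, 37)
BOTH_ITEMS: tuple[int, ...] = (40,)
NEITHER_ITEMS: tuple[int, ...] = (
    2, 5, 9, 11, 13, 17, 19, 20, 21, 23, 25, 26, 28, 35, 36, 38, 39,
)
NEITHER_COMPOSITE = "neither_composite"

# Phonological / visuospatial span indicators, set sizes 3-6.
WM_INDICATORS: tuple[str, ...] = tuple(
    f"{task}_ss{s}" for task in ("phonological", "visuospatial") for s in (3, 4, 5, 6)
)


def _item(i: int) -> str:
    return f"item{i:02d}"


@dataclass(frozen=True)
class BifactorSpec:
    """Loading pattern of a single-construct bifactor model.

    Parameters
    ----------
    construct : label of the construct (e.g. ``"anxiety"``).
    indicators : ordered indicator names.
    general : name of the general factor.
    specifics : mapping from specific-factor name to the tuple of member
        indicators.  Indicators in no specific factor are reference facets.
    """

    construct: str
    indicators: tuple[str, ...]
    general: str
    specifics: Mapping[str, tuple[str, ...]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if len(set(self.indicators)) != len(self.indicators):
            raise ValueError("duplicate indicator names")
        seen: dict[str, str] = {}
        for fac, members in self.specifics.items():
            if not members:
                raise ValueError(f"specific factor {fac!r} has no indicators")
            for ind in members:
                if ind not in self.indicators:
                    raise ValueError(f"{ind!r} in {fac!r} is not an indicator")
                if ind in seen:
                    raise ValueError(
                        f"indicator {ind!r} assigned to both {seen[ind]!r} and {fac!r}"
                    )
                seen[ind] = fac
        if not self.references:
            raise ValueError(
                "no reference indicator: every indicator belongs to a specific factor"
            )

    @property
    def references(self) -> tuple[str, ...]:
        in_specific = {i for mem in self.specifics.values() for i in mem}
        return tuple(i for i in self.indicators if i not in in_specific)

    @property
    def factor_names(self) -> tuple[str, ...]:
        return (self.general, *self.specifics)

    @property
    def n_indicators(self) -> int:
        return len(self.indicators)

    def specific_of(self, indicator: str) -> str | None:
        for fac, members in self.specifics.items():
            if indicator in members:
                return fac
        return None

    def one_factor(self) -> "BifactorSpec":
        """The nested 1-factor reduction: general factor only."""
        return BifactorSpec(self.construct, self.indicators, self.general, {})

    def drop_indicators(self, names: Sequence[str]) -> "BifactorSpec":
        """Remove indicators entirely (sensitivity analyses)."""
        names = set(names)
        missing = names - set(self.indicators)
        if missing:
            raise ValueError(f"unknown indicators: {sorted(missing)}")
        keep = tuple(i for i in self.indicators if i not in names)
        specifics = {}
        for fac, members in self.specifics.items():
            kept = tuple(i for i in members if i not in names)
            if len(kept) < 3:
                raise ValueError(
                    f"dropping {sorted(names)} leaves specific factor {fac!r} "
                    f"with {len(kept)} indicators (minimum 3)"
                )
            specifics[fac] = kept
        return BifactorSpec(self.construct, keep, self.general, specifics)

    def drop_from_specific(self, factor: str, names: Sequence[str]) -> "BifactorSpec":
        """Free indicators from one specific factor, keeping them on the general."""
        members = self.specifics[factor]
        kept = tuple(i for i in members if i not in set(names))
        if len(kept) < 3:
            raise ValueError(f"{factor!r} left with {len(kept)} indicators")
        specifics = dict(self.specifics)
        specifics[factor] = kept
        return BifactorSpec(self.construct, self.indicators, self.general, specifics)

    def structure(self, covariates: Sequence[str] = ()) -> "ModelStructure":
        return combine_specs(self, covariates=covariates)


@dataclass(frozen=True)
class ModelStructure:
    """Flattened loading/covariance pattern consumed by the estimator.

    ``loading_free[i, f]`` marks free cells of the indicator-by-factor
    loading matrix; ``phi_free`` marks free factor-covariance cells
    (cross-construct pairs only — within a construct all factor covariances
    are fixed to zero and factor/disturbance variances are fixed to one).
    """

    indicators: tuple[str, ...]
    factors: tuple[str, ...]
    factor_construct: tuple[str, ...]
    loading_free: np.ndarray
    phi_free: np.ndarray
    covariates: tuple[str, ...] = ()

    @property
    def p(self) -> int:
        return len(self.indicators)

    @property
    def m(self) -> int:
        return len(self.factors)

    @property
    def q(self) -> int:
        return len(self.covariates)

    @property
    def n_free_loadings(self) -> int:
        return int(self.loading_free.sum())

    @property
    def free_phi_pairs(self) -> list[tuple[int, int]]:
        a, b = np.nonzero(np.triu(self.phi_free, 1))
        return list(zip(a.tolist(), b.tolist()))

    def factor_index(self, name: str) -> int:
        return self.factors.index(name)


def combine_specs(
    *specs: BifactorSpec,
    covariates: Sequence[str] = (),
    correlate_cross: bool = True,
) -> ModelStructure:
    """Stack one or more construct specs into a joint estimable structure.

    Cross-construct factor covariances are free (when ``correlate_cross``);
    all within-construct covariances stay fixed at zero.
    """
    constructs = [s.construct for s in specs]
    if len(set(constructs)) != len(constructs):
        raise ValueError("construct labels must be unique")
    indicators: list[str] = []
    factors: list[str] = []
    factor_construct: list[str] = []
    for s in specs:
        for ind in s.indicators:
            if ind in indicators:
                raise ValueError(f"indicator {ind!r} appears in two constructs")
            indicators.append(ind)
        for f in s.factor_names:
            if f in factors:
                raise ValueError(f"factor name {f!r} appears in two constructs")
            factors.append(f)
            factor_construct.append(s.construct)
    p, m = len(indicators), len(factors)
    loading_free = np.zeros((p, m), dtype=bool)
    for s in specs:
        g = factors.index(s.general)
        for ind in s.indicators:
            loading_free[indicators.index(ind), g] = True
        for fac, members in s.specifics.items():
            fcol = factors.index(fac)
            for ind in members:
                loading_free[indicators.index(ind), fcol] = True
    phi_free = np.zeros((m, m), dtype=bool)
    if correlate_cross:
        for a in range(m):
            for b in range(m):
                if a != b and factor_construct[a] != factor_construct[b]:
                    phi_free[a, b] = True
    return ModelStructure(
        indicators=tuple(indicators),
        factors=tuple(factors),
        factor_construct=tuple(factor_construct),
        loading_free=loading_free,
        phi_free=phi_free,
        covariates=tuple(covariates),
    )


def anxiety_spec() -> BifactorSpec:
    """Anxiety bifactor-(S-1) model: 23 indicators.

    22 items load on common anxiety plus one of two 11-item specific factors
    (cognitive worry, physiological arousal); the 17-item "neither" composite
    is the reference facet, loading on the general factor only.
    """
    items = tuple(_item(i) for i in sorted(CW_ITEMS + PA_ITEMS))
    indicators = items + (NEITHER_COMPOSITE,)
    return BifactorSpec(
        construct="anxiety",
        indicators=indicators,
        general="common_anxiety",
        specifics={
            "cognitive_worry": tuple(_item(i) for i in CW_ITEMS),
            "physiological_arousal": tuple(_item(i) for i in PA_ITEMS),
        },
    )


def wm_spec() -> BifactorSpec:
    """Working-memory bifactor-(S·I-1) model: 8 span indicators.

    All eight load on the central executive; set sizes 4-6 of each task load
    on the matching short-term-memory specific factor, while both set-size-3
    indicators are reference facets (general only).
    """
    return BifactorSpec(
        construct="working_memory",
        indicators=WM_INDICATORS,
        general="central_executive",
        specifics={
            "phonological_stm": tuple(f"phonological_ss{s}" for s in (4, 5, 6)),
            "visuospatial_stm": tuple(f"visuospatial_ss{s}" for s in (4, 5, 6)),
        },
    )
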