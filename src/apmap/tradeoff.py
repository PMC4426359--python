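"""Antagonistic-pleiotropy scoring in entity x environment growth matrices.

Implements the screen applied to deletion-collection and natural-isolate
growth data: each environment column is scaled to zero mean and unit
variance, and an entity shows a trade-off between environments E1 and E2
when its standardized values sit strictly beyond +c in one environment and
strictly beyond -c in the other (c = 0.5 SD by default, 0.75 SD as the
stricter alternative). The *degree of antagonism* is the percentage of
trade-off entities among all entities that exceed the cutoff in either
environment.

Natural isolates are assigned one of three categories across a panel of
environments: I — a trade-off across at least one environment pair; II —
within +/-c everywhere; III — beyond c somewhere but never with an opposite
exceedance.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Literal

from .io_formats import PhenotypeMatrix


@dataclass(frozen=True)
class APCutoffs:
    """Trade-off cutoff in SD units; comparisons are strict inequalities."""

    cutoff: float = 0.5

    def __post_init__(self) -> None:
        if self.cutoff <= 0:
            raise ValueError("cutoff must be positive")


@dataclass(frozen=True)
class TradeOffCall:
    entity_id: str
    env1: str
    env2: str
    z1: float
    z2: float
    direction: Literal["up_in_E1", "up_in_E2"]


@dataclass(frozen=True)
class IsolateCategory:
    strain_id: str
    category: Literal["I", "II", "III"]


class DegenerateColumnError(ValueError):
    """A column cannot be standardized (constant or too few values)."""


def standardize_columns(matrix: PhenotypeMatrix) -> PhenotypeMatrix:
    """Scale each environment column to zero mean and unit sample variance.

    Uses the n-1 (sample) standard deviation over non-missing entries;
    missing cells stay missing. Idempotent.
    """
    v = matrix.values
    n_ok = v.notna().sum(axis=0)
    if (n_ok < 2).any():
        bad = n_ok.index[n_ok < 2].tolist()
        raise DegenerateColumnError(f"columns with < 2 values: {bad}")
    sd = v.std(axis=0, ddof=1, skipna=True)
    if (sd == 0).any() or sd.isna().any():
        bad = sd.index[(sd == 0) | sd.isna()].tolist()
        raise DegenerateColumnError(f"constant columns: {bad}")
    z = (v - v.mean(axis=0, skipna=True)) / sd
    return PhenotypeMatrix(z, standardized=True)


def _require_standardized(matrix: PhenotypeMatrix) -> None:
    if not matrix.standardized:
        raise ValueError("expected a standardized matrix; run standardize_columns")


def call_antagonistic_genes(
    z: PhenotypeMatrix,
    pair: tuple[str, str],
    cutoffs: APCutoffs = APCutoffs(),
) -> list[TradeOffCall]:
    """Entities strictly beyond +c in one environment and -c in the other."""
    _require_standardized(z)
    e1, e2 = pair
    c = cutoffs.cutoff
    z1 = z.values[e1]
    z2 = z.values[e2]
    up1 = (z1 > c) & (z2 < -c)
    up2 = (z1 < -c) & (z2 > c)
    calls = []
    for ent in z.values.index[(up1 | up2).fillna(False)]:
        direction = "up_in_E1" if z1[ent] > c else "up_in_E2"
        calls.append(TradeOffCall(str(ent), e1, e2, float(z1[ent]), float(z2[ent]), direction))
    return calls


def degree_of_antagonism(
    z: PhenotypeMatrix,
    pair: tuple[str, str],
    cutoffs: APCutoffs = APCutoffs(),
    *,
    denominator: Literal["union", "per_environment"] = "union",
) -> float | tuple[float, float]:
    """Percentage of trade-off entities among cutoff-exceeding entities.

    With ``denominator="union"`` (default) the denominator is the set of
    entities with |z| > c in E1 or E2; ``"per_environment"`` reports the two
    per-environment ratios instead. Returns 0 (with a warning) when no
    entity exceeds the cutoff.
    """
    _require_standardized(z)
    e1, e2 = pair
    c = cutoffs.cutoff
    n_calls = len(call_antagonistic_genes(z, pair, cutoffs))
    exceed1 = (z.values[e1].abs() > c).fillna(False)
    exceed2 = (z.values[e2].abs() > c).fillna(False)
    if denominator == "per_environment":
        out = []
        for exceed in (exceed1, exceed2):
            denom = int(exceed.sum())
            if denom == 0:
                warnings.warn("no entity exceeds the cutoff; degree set to 0")
                out.append(0.0)
            else:
                out.append(100.0 * n_calls / denom)
        return tuple(out)  # type: ignore[return-value]
    denom = int((exceed1 | exceed2).sum())
    if denom == 0:
        warnings.warn("no entity exceeds the cutoff; degree set to 0")
        return 0.0
    return 100.0 * n_calls / denom


def categorize_isolates(
    z: PhenotypeMatrix, cutoffs: APCutoffs = APCutoffs()
) -> list[IsolateCategory]:
    """Assign each strain a trade-off category across all environments.

    I: z > c in some environment and z < -c in another; II: |z| <= c
    everywhere; III: |z| > c somewhere without an opposite exceedance.
    """
    _require_standardized(z)
    if len(z.environment_ids) < 2:
        raise ValueError("need at least 2 environments")
    c = cutoffs.cutoff
    out = []
    for strain, row in z.values.iterrows():
        vals = row.dropna()
        has_up = bool((vals > c).any())
        has_down = bool((vals < -c).any())
        if has_up and has_down:
            cat = "I"
        elif has_up or has_down:
            cat = "III"
        else:
            cat = "II"
        out.append(IsolateCategory(str(strain), cat))
    return out
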