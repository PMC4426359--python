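"""Tajima's D from alignments and balancing-selection screening.

Tajima's D contrasts two estimators of the population mutation rate theta:
the mean number of pairwise differences (pi) and the segregating-site
estimator S / a1. Under neutrality at equilibrium their difference is near
zero; an excess of intermediate-frequency variants (as maintained by
balancing selection) drives D positive, an excess of rare variants drives
it negative.

    D = (pi - S / a1) / sqrt(e1 * S + e2 * S * (S - 1))

with, for n sequences,

    a1 = sum_{i=1}^{n-1} 1/i              a2 = sum_{i=1}^{n-1} 1/i^2
    b1 = (n + 1) / (3 (n - 1))            b2 = 2 (n^2 + n + 3) / (9 n (n - 1))
    c1 = b1 - 1/a1                        c2 = b2 - (n + 2)/(a1 n) + a2 / a1^2
    e1 = c1 / a1                          e2 = c2 / (a1^2 + a2)

Columns containing a gap or ambiguous base are excluded entirely (complete
deletion); columns with more than two alleles are excluded from both S and
pi and counted in a log, keeping both statistics on one biallelic site set.
Genes with D above a fixed cutoff (0.1 by default) are called as under
balancing selection, optionally requiring the call in every species panel
provided.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from .epistasis import ContingencyTable, fisher_exact
from .io_formats import AlignmentSet

logger = logging.getLogger(__name__)

_VALID = np.array(list("ACGT"))


@dataclass(frozen=True)
class TajimaStats:
    n: int
    S: int
    pi: float
    a1: float
    a2: float
    b1: float
    b2: float
    c1: float
    c2: float
    e1: float
    e2: float
    D: float


@dataclass(frozen=True)
class BalancingCall:
    gene_id: str
    species: str
    D: float
    called: bool


def site_stats(alignment: AlignmentSet) -> tuple[int, int, float]:
    """(n sequences, segregating sites S, mean pairwise differences pi).

    Complete deletion of gapped/ambiguous columns; >2-allele columns are
    dropped from both S and pi and logged.
    """
    if alignment.n_sequences < 4:
        raise ValueError("need at least 4 sequences")
    chars = alignment.chars
    n = chars.shape[0]
    clean = np.isin(chars, _VALID).all(axis=0)
    cols = chars[:, clean]
    S = 0
    pi_sum = 0.0
    n_pairs = n * (n - 1) / 2.0
    n_multi = 0
    for j in range(cols.shape[1]):
        col = cols[:, j]
        alleles, counts = np.unique(col, return_counts=True)
        if len(alleles) == 1:
            continue
        if len(alleles) > 2:
            n_multi += 1
            continue
        S += 1
        c = counts[0]
        pi_sum += c * (n - c) / n_pairs
    if n_multi:
        logger.info("%d columns with >2 alleles excluded", n_multi)
    return n, S, pi_sum


def tajima_constants(n: int) -> dict[str, float]:
    """The normalization constants of Tajima's D for n sequences."""
    if n < 2:
        raise ValueError("need n >= 2")
    i = np.arange(1, n)
    a1 = float((1.0 / i).sum())
    a2 = float((1.0 / i**2).sum())
    b1 = (n + 1) / (3.0 * (n - 1))
    b2 = 2.0 * (n**2 + n + 3) / (9.0 * n * (n - 1))
    c1 = b1 - 1.0 / a1
    c2 = b2 - (n + 2) / (a1 * n) + a2 / a1**2
    e1 = c1 / a1
    e2 = c2 / (a1**2 + a2)
    return {"a1": a1, "a2": a2, "b1": b1, "b2": b2, "c1": c1, "c2": c2, "e1": e1, "e2": e2}


def tajimas_d(alignment: AlignmentSet) -> TajimaStats:
    """Full Tajima statistics for one aligned gene; S = 0 is an error
    (D undefined)."""
    n, S, pi = site_stats(alignment)
    if S == 0:
        raise ValueError("no segregating sites: Tajima's D undefined")
    k = tajima_constants(n)
    D = (pi - S / k["a1"]) / np.sqrt(k["e1"] * S + k["e2"] * S * (S - 1))
    return TajimaStats(n=n, S=S, pi=pi, D=float(D), **k)


def balancing_calls(
    stats_by_gene: Mapping[str, Mapping[str, TajimaStats]],
    cutoff: float = 0.1,
    *,
    require_both_species: bool = False,
) -> list[BalancingCall]:
    """Call balancing selection where D > cutoff.

    ``stats_by_gene`` maps gene id -> species -> TajimaStats. With
    ``require_both_species``, a gene's calls are true only when D exceeds
    the cutoff in every species provided for that gene.
    """
    calls = []
    for gene, per_species in stats_by_gene.items():
        raw = {sp: st.D > cutoff for sp, st in per_species.items()}
        joint = all(raw.values())
        for sp, st in per_species.items():
            called = joint if require_both_species else raw[sp]
            calls.append(BalancingCall(gene, sp, st.D, called))
    return calls


def pathway_enrichment(
    pathway_calls: Sequence[bool], control_calls: Sequence[bool]
) -> tuple[ContingencyTable, float]:
    """Fisher test of balancing-selection calls in a pathway vs a control set."""
    if not len(pathway_calls) or not len(control_calls):
        raise ValueError("both gene sets must be non-empty")
    pc = sum(bool(x) for x in pathway_calls)
    cc = sum(bool(x) for x in control_calls)
    table = ContingencyTable(
        ((pc, len(pathway_calls) - pc), (cc, len(control_calls) - cc)),
        row_labels=("pathway", "control"),
        col_labels=("called", "not_called"),
    )
    return table, fisher_exact(table)
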