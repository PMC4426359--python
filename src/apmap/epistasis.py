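"""Targeted two-locus interaction mapping and the resolution-of-trade-offs test.

Candidate markers (single-environment hits plus scale/antagonistic GEI loci,
collapsed within a 60 kb window) are paired and each pair is tested for an
environment-dependent interaction on the slope phenotype: the model
``slope ~ g1 + g2 + g1:g2`` is contrasted against its additive reduction,
with significance from permuting the slope values and taking the maximum
interaction LOD over all tested pairs as the null statistic.

For each interacting pair, the four two-marker genotype-class means
(BB, BR, RB, RR; first letter = first marker, B = BY-like, R = RM-like) are
computed in both environments. A *crossover* is a sign change of a class
contrast between the environments:

* **heterozygous (mixed) crossover** — holding one marker's allele fixed,
  the other marker's allele contrast flips sign between environments for a
  contrast that involves a mixed (BR or RB) class;
* **parental crossover** — the BB vs RR contrast itself flips sign.

Counting crossovers in mixed versus parental combinations over all detected
interactions and testing the 2x2 table with Fisher's exact test quantifies
whether trade-offs visible in recombinant combinations are resolved
(absent) in the parental combinations.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass
from typing import Literal, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import special, stats

from .gei import GEILocusRecord, SlopeVector
from .io_formats import GenotypeMatrix, MarkerMap, PhenotypeMatrix

logger = logging.getLogger(__name__)

COMBOS = ("BB", "BR", "RB", "RR")


@dataclass(frozen=True)
class ContingencyTable:
    """2x2 nonnegative integer counts."""

    counts: tuple[tuple[int, int], tuple[int, int]]
    row_labels: tuple[str, str] = ("row1", "row2")
    col_labels: tuple[str, str] = ("col1", "col2")

    def __post_init__(self) -> None:
        for row in self.counts:
            for v in row:
                if v < 0:
                    raise ValueError("negative contingency count")

    @property
    def a(self) -> int:
        return self.counts[0][0]

    def as_array(self) -> np.ndarray:
        return np.array(self.counts, dtype=int)


@dataclass
class TwoLocusRecord:
    marker_a: str
    marker_b: str
    env1: str
    env2: str
    interaction_p: float
    interaction_lod: float
    within_env_p: dict[str, float]
    class_means: pd.DataFrame  # index COMBOS, columns MultiIndex (env, stat)
    heterozygous_crossover: bool | None = None
    parental_crossover: bool | None = None


# ---------------------------------------------------------------------------
# candidate collation
# ---------------------------------------------------------------------------


def collate_candidate_markers(
    single_env_p: Mapping[str, pd.Series],
    gei_records: Sequence[GEILocusRecord],
    marker_map: MarkerMap,
    *,
    p_cut: float = 1.0,
    window: int = 60_000,
) -> list[str]:
    """Union of single-environment hits (p < p_cut) and scale/antagonistic
    GEI loci, collapsed so that markers within ``window`` bp of a better
    already-kept candidate on the same chromosome are dropped."""
    best_p: dict[str, float] = {}
    for pmap in single_env_p.values():
        for marker, p in pmap.items():
            if pd.notna(p) and p < p_cut:
                best_p[marker] = min(p, best_p.get(marker, np.inf))
    for rec in gei_records:
        if rec.gei_class in ("scale", "antagonistic"):
            p = np.nanmin([rec.p_gei, rec.p_slope])
            best_p[rec.marker_id] = min(p, best_p.get(rec.marker_id, np.inf))
    if not best_p:
        return []
    t = marker_map.table
    order = sorted(best_p, key=lambda m: (best_p[m], t.index.get_loc(m)))
    kept: list[str] = []
    for m in order:
        chrom, pos = t.loc[m, "chromosome"], t.loc[m, "position"]
        if any(
            t.loc[k, "chromosome"] == chrom and abs(t.loc[k, "position"] - pos) <= window
            for k in kept
        ):
            continue
        kept.append(m)
    kept.sort(key=lambda m: t.index.get_loc(m))
    return kept


# ---------------------------------------------------------------------------
# the interaction scan
# ---------------------------------------------------------------------------


def _pair_design(genotypes: GenotypeMatrix, values: pd.Series, ma: str, mb: str):
    g = genotypes.calls[[ma, mb]]
    y = values.reindex(g.index)
    keep = y.notna() & g.notna().all(axis=1)
    g1 = g.loc[keep, ma].to_numpy(dtype=float)
    g2 = g.loc[keep, mb].to_numpy(dtype=float)
    return g1, g2, y[keep].to_numpy(dtype=float)


def _interaction_stats(g1, g2, y):
    """(interaction LOD, nominal F p, n) for slope ~ g1 + g2 + g1:g2 vs additive."""
    n = len(y)
    cell = (2 * g1 + g2).astype(int)  # 0=BB(0,0)?? order: g1 g2 -> 2*g1+g2
    counts = np.bincount(cell, minlength=4)
    if (counts == 0).any():
        return np.nan, np.nan, n
    sums = np.bincount(cell, weights=y, minlength=4)
    tss = (y**2).sum()
    rss_full = tss - (sums**2 / counts).sum()
    X = np.column_stack([np.ones(n), g1, g2])
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    rss_add = ((y - X @ beta) ** 2).sum()
    with np.errstate(divide="ignore", invalid="ignore"):
        lod = max(0.0, (n / 2.0) * np.log10(rss_add / rss_full))
        F = (rss_add - rss_full) / (rss_full / (n - 4))
        p = float(stats.f.sf(F, 1, n - 4))
    return lod, p, n


def two_locus_interaction_scan(
    genotypes: GenotypeMatrix,
    slope: SlopeVector,
    candidates: Sequence[str],
    n_perm: int,
    seed: int,
    *,
    phenotypes: PhenotypeMatrix | None = None,
    window: int = 60_000,
) -> list[TwoLocusRecord]:
    """Interaction scan over all admissible candidate pairs.

    Pairs on one chromosome closer than ``window`` bp are excluded (linkage
    artifacts); pairs with an empty two-marker genotype class are skipped
    with a log message. The permutation null is the maximum interaction LOD
    over all tested pairs under shuffles of the slope values. When
    ``phenotypes`` (standardized, containing the slope's environments) is
    given, the same interaction contrast is also fitted within each
    environment to fill per-environment nominal p-values.
    """
    if len(candidates) < 2:
        raise ValueError("need at least 2 candidate markers")
    t = genotypes.markers.table
    pairs = []
    for ma, mb in itertools.combinations(candidates, 2):
        same = t.loc[ma, "chromosome"] == t.loc[mb, "chromosome"]
        if same and abs(t.loc[ma, "position"] - t.loc[mb, "position"]) < window:
            continue
        pairs.append((ma, mb))
    designs = {}
    lods = {}
    for ma, mb in pairs:
        g1, g2, y = _pair_design(genotypes, slope.values, ma, mb)
        lod, _, _ = _interaction_stats(g1, g2, y)
        if np.isnan(lod):
            logger.info("pair (%s, %s) skipped: empty genotype class", ma, mb)
            continue
        designs[(ma, mb)] = (g1, g2, y)
        lods[(ma, mb)] = lod
    if not designs:
        return []
    rng = np.random.default_rng(seed)
    maxima = np.empty(n_perm)
    for b in range(n_perm):
        best = 0.0
        for g1, g2, y in designs.values():
            lod_b, _, _ = _interaction_stats(g1, g2, rng.permutation(y))
            if lod_b > best:
                best = lod_b
        maxima[b] = best
    records = []
    for (ma, mb), lod in lods.items():
        p = float((1.0 + (maxima >= lod).sum()) / (n_perm + 1.0))
        within: dict[str, float] = {}
        if phenotypes is not None:
            for env in (slope.env1, slope.env2):
                g1, g2, y = _pair_design(genotypes, phenotypes.values[env], ma, mb)
                _, p_env, _ = _interaction_stats(g1, g2, y)
                within[env] = p_env
        cm = (
            genotype_class_means(genotypes, phenotypes, (slope.env1, slope.env2), (ma, mb))
            if phenotypes is not None
            else pd.DataFrame()
        )
        records.append(
            TwoLocusRecord(
                ma, mb, slope.env1, slope.env2, p, float(lod), within, cm
            )
        )
    return records


def genotype_class_means(
    genotypes: GenotypeMatrix,
    phenotypes: PhenotypeMatrix,
    pair: tuple[str, str],
    markers: tuple[str, str],
) -> pd.DataFrame:
    """Means, SEs and counts of the 4 two-marker genotype classes per environment.

    Rows are BB, BR, RB, RR (first letter = first marker); columns are a
    MultiIndex (environment, {mean, se, n}); complete-case entities only.
    """
    ma, mb = markers
    e1, e2 = pair
    g = genotypes.calls[[ma, mb]]
    v = phenotypes.values[[e1, e2]].reindex(g.index)
    keep = g.notna().all(axis=1) & v.notna().all(axis=1)
    g1 = g.loc[keep, ma].to_numpy(dtype=int)
    g2 = g.loc[keep, mb].to_numpy(dtype=int)
    cell = 2 * g1 + g2
    data = {}
    for j, env in enumerate(pair):
        y = v.loc[keep, env].to_numpy(dtype=float)
        for k, combo in enumerate(COMBOS):
            sel = y[cell == k]
            if len(sel) == 0:
                raise ValueError(f"empty genotype class {combo} for ({ma}, {mb})")
            data.setdefault((env, "mean"), []).append(sel.mean())
            data.setdefault((env, "se"), []).append(
                sel.std(ddof=1) / np.sqrt(len(sel)) if len(sel) > 1 else np.nan
            )
            data.setdefault((env, "n"), []).append(len(sel))
    out = pd.DataFrame(data, index=list(COMBOS))
    out.columns = pd.MultiIndex.from_tuples(out.columns)
    return out


# ---------------------------------------------------------------------------
# crossover flags and the resolution test
# ---------------------------------------------------------------------------

# contrasts that hold one marker's allele fixed; each involves a mixed class
_MIXED_CONTRASTS = (("BB", "RB"), ("BR", "RR"), ("BB", "BR"), ("RB", "RR"))
_PARENTAL_CONTRAST = ("BB", "RR")


def _contrast_flips(cm: pd.DataFrame, a: str, b: str, envs: tuple[str, str]) -> bool:
    d1 = cm.loc[a, (envs[0], "mean")] - cm.loc[b, (envs[0], "mean")]
    d2 = cm.loc[a, (envs[1], "mean")] - cm.loc[b, (envs[1], "mean")]
    return bool(np.sign(d1) * np.sign(d2) < 0)


def resolution_flags(record: TwoLocusRecord) -> tuple[bool, bool]:
    """(heterozygous_crossover, parental_crossover) from the class means."""
    cm = record.class_means
    if cm.empty:
        raise ValueError("record has no class means; rerun with phenotypes")
    envs = (record.env1, record.env2)
    het = any(_contrast_flips(cm, a, b, envs) for a, b in _MIXED_CONTRASTS)
    par = _contrast_flips(cm, *_PARENTAL_CONTRAST, envs)
    record.heterozygous_crossover = het
    record.parental_crossover = par
    return het, par


def fisher_exact(
    table: ContingencyTable,
    sidedness: Literal["two_sided", "greater", "less"] = "two_sided",
) -> float:
    """Fisher's exact test by full hypergeometric enumeration.

    With margins fixed, the count in cell (1,1) is hypergeometric; the
    two-sided p sums the probabilities of all tables whose point probability
    does not exceed the observed one (minimum-likelihood convention).
    """
    arr = table.as_array()
    a, b = arr[0]
    c, d = arr[1]
    n = a + b + c + d
    r1, c1 = a + b, a + c
    lo, hi = max(0, r1 + c1 - n), min(r1, c1)
    support = np.arange(lo, hi + 1)
    lgam = special.gammaln(np.arange(n + 2))

    def log_comb(m, k):
        return lgam[m + 1] - lgam[k + 1] - lgam[m - k + 1]

    pmf = np.exp(
        log_comb(r1, support) + log_comb(n - r1, c1 - support) - log_comb(n, c1)
    )
    p_obs = pmf[support == a][0]
    if sidedness == "greater":
        p = pmf[support >= a].sum()
    elif sidedness == "less":
        p = pmf[support <= a].sum()
    else:
        p = pmf[pmf <= p_obs * (1 + 1e-12)].sum()
    return float(min(1.0, p))


def resolution_test(
    records: Sequence[TwoLocusRecord],
    sidedness: Literal["two_sided", "greater", "less"] = "two_sided",
) -> tuple[ContingencyTable, float]:
    """Contrast crossover counts in mixed vs parental combinations.

    Rows = {heterozygous contrasts, parental contrasts}; columns =
    {crossover, no crossover}; p from :func:`fisher_exact`.
    """
    if not records:
        raise ValueError("no two-locus records")
    flags = [
        (r.heterozygous_crossover, r.parental_crossover)
        if r.heterozygous_crossover is not None
        else resolution_flags(r)
        for r in records
    ]
    n = len(flags)
    het = sum(1 for h, _ in flags if h)
    par = sum(1 for _, p in flags if p)
    table = ContingencyTable(
        ((het, n - het), (par, n - par)),
        row_labels=("heterozygous", "parental"),
        col_labels=("crossover", "no_crossover"),
    )
    return table, fisher_exact(table, sidedness)
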