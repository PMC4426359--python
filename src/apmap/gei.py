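"""Gene-environment-interaction (GEI) mapping over environment pairs.

Two complementary scans identify loci whose allelic effect depends on the
environment:

* the **GEI scan** stacks the two standardized environment columns (each
  entity contributes two rows with an environment indicator) and contrasts
  the full model ``y ~ env + genotype + genotype:env`` against the additive
  model without the interaction; the GEI LOD is the LOD difference, and
  significance comes from permuting genotype labels across entities
  (keeping each entity's two rows together);
* the **slope scan** maps the per-entity difference of standardized values,
  slope = z(E2) - z(E1), as an ordinary single-trait QTL scan.

Loci with GEI permutation p < 0.1 and slope permutation p < 0.05 are the
significant GEI loci; each is then classified by per-environment Welch
t-tests between the allele groups at a Bonferroni-style per-test cutoff
(0.05 / 10 = 0.005 by default): significant in exactly one environment ->
environment specific; in both with same-signed allele contrast -> scale; in
both with opposite signs -> antagonistic (crossing reaction norms).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from . import qtl as qtl_mod
from .io_formats import GenotypeMatrix, PhenotypeMatrix
from .qtl import QTLPeak


def t_test_alpha(fw_alpha: float = 0.05, family_size: int = 10) -> float:
    """Per-test cutoff for the classification t-tests: fw_alpha / family_size."""
    if fw_alpha <= 0 or family_size < 1:
        raise ValueError("need fw_alpha > 0 and family_size >= 1")
    return fw_alpha / family_size


@dataclass(frozen=True)
class SlopeVector:
    """Per-entity slope z(E2) - z(E1) for one environment pair."""

    values: pd.Series
    env1: str
    env2: str
    n_dropped: int = 0


@dataclass(frozen=True)
class GEILocusRecord:
    marker_id: str
    chromosome: str
    position: int
    env1: str
    env2: str
    p_gei: float
    p_slope: float
    t_p1: float
    t_p2: float
    mean_by_e1: float
    mean_rm_e1: float
    mean_by_e2: float
    mean_rm_e2: float
    se_by_e1: float
    se_rm_e1: float
    se_by_e2: float
    se_rm_e2: float
    gei_class: Literal["env_specific", "scale", "antagonistic", "unclassified"]


@dataclass(frozen=True)
class ReactionNorm:
    """Allele x environment means with standard errors for one marker."""

    marker_id: str
    env1: str
    env2: str
    mean_by_e1: float
    mean_rm_e1: float
    mean_by_e2: float
    mean_rm_e2: float
    se_by_e1: float
    se_rm_e1: float
    se_by_e2: float
    se_rm_e2: float
    crossing: bool


# ---------------------------------------------------------------------------
# GEI scan (environment as covariate)
# ---------------------------------------------------------------------------


def _pair_arrays(
    genotypes: GenotypeMatrix, phenotypes: PhenotypeMatrix, pair: tuple[str, str]
):
    if not phenotypes.standardized:
        raise ValueError("GEI mapping expects standardized phenotypes")
    e1, e2 = pair
    v = phenotypes.values.reindex(genotypes.segregant_ids)
    keep = v[e1].notna() & v[e2].notna()
    y1 = v.loc[keep, e1].to_numpy(dtype=float)
    y2 = v.loc[keep, e2].to_numpy(dtype=float)
    G = genotypes.calls.loc[keep.index[keep]].to_numpy(dtype=float)
    mask = ~np.isnan(G)
    Gz = np.where(mask, G, 0.0)
    return Gz, mask, y1, y2


def _gei_lod(Gz, mask, y1, y2, xtx_inv=None):
    """Vectorized GEI LOD per marker; returns (lod, N_rows, xtx_inv)."""
    n_k = mask.sum(axis=0).astype(float)
    n1 = (Gz * mask).sum(axis=0)
    n0 = n_k - n1
    if xtx_inv is None:
        m = Gz.shape[1]
        xtx = np.empty((m, 3, 3))
        xtx[:, 0, 0] = 2 * n_k
        xtx[:, 0, 1] = xtx[:, 1, 0] = n_k
        xtx[:, 0, 2] = xtx[:, 2, 0] = 2 * n1
        xtx[:, 1, 1] = n_k
        xtx[:, 1, 2] = xtx[:, 2, 1] = n1
        xtx[:, 2, 2] = 2 * n1
        xtx_inv = np.linalg.inv(xtx)
    s11 = Gz.T @ y1  # env1, allele 1
    s21 = Gz.T @ y2
    t1 = mask.T @ y1
    t2 = mask.T @ y2
    s10 = t1 - s11
    s20 = t2 - s21
    T2 = mask.T @ (y1**2) + mask.T @ (y2**2)
    with np.errstate(divide="ignore", invalid="ignore"):
        rss_full = (
            T2
            - np.where(n0 > 0, (s10**2 + s20**2) / np.maximum(n0, 1), 0.0)
            - np.where(n1 > 0, (s11**2 + s21**2) / np.maximum(n1, 1), 0.0)
        )
        xty = np.stack([t1 + t2, t2, s11 + s21], axis=1)
        beta = np.einsum("mij,mj->mi", xtx_inv, xty)
        rss_add = T2 - np.einsum("mi,mi->m", beta, xty)
        lod = (2 * n_k / 2.0) * np.log10(rss_add / rss_full)
    lod = np.where((n0 == 0) | (n1 == 0), np.nan, lod)
    lod = np.where(np.isfinite(lod) & (lod < 0), 0.0, lod)
    return lod, 2 * n_k, xtx_inv


def gei_scan(
    genotypes: GenotypeMatrix,
    phenotypes: PhenotypeMatrix,
    pair: tuple[str, str],
    n_perm: int,
    seed: int,
) -> pd.DataFrame:
    """Per-marker GEI LOD with genome-wide permutation p-values.

    Returns a DataFrame indexed by marker with ``lod``, ``p`` (genome-wide,
    from permuting genotype labels across entities) and ``p_nominal``
    (single-marker F-test).
    """
    if n_perm < 100:
        raise ValueError("need at least 100 permutations")
    Gz, mask, y1, y2 = _pair_arrays(genotypes, phenotypes, pair)
    lod, N, xtx_inv = _gei_lod(Gz, mask, y1, y2)
    # nominal single-marker F-test for the interaction (1 df)
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.power(10.0, 2.0 * lod / N)  # RSS_add / RSS_full
        F = (ratio - 1.0) * (N - 4)
        p_nom = stats.f.sf(F, 1, N - 4)
    rng = np.random.default_rng(seed)
    n = len(y1)
    maxima = np.empty(n_perm)
    for b in range(n_perm):
        inv = rng.permutation(n)
        # permuting genotype rows == inverse-permuting both environment columns
        lod_b, _, _ = _gei_lod(Gz, mask, y1[inv], y2[inv], xtx_inv)
        maxima[b] = np.nanmax(lod_b)
    exceed = (maxima[None, :] >= lod[:, None]).sum(axis=1)
    p = np.where(np.isnan(lod), np.nan, (1.0 + exceed) / (n_perm + 1.0))
    t = genotypes.markers.table
    return pd.DataFrame(
        {
            "chromosome": t["chromosome"],
            "position": t["position"],
            "lod": lod,
            "p": p,
            "p_nominal": p_nom,
        },
        index=t.index,
    )


# ---------------------------------------------------------------------------
# slope mapping
# ---------------------------------------------------------------------------


def slope_phenotype(
    phenotypes: PhenotypeMatrix, pair: tuple[str, str]
) -> SlopeVector:
    """slope(entity) = z(E2) - z(E1); entities missing either value are dropped."""
    if not phenotypes.standardized:
        raise ValueError("slope is defined on standardized phenotypes")
    e1, e2 = pair
    v = phenotypes.values
    slope = v[e2] - v[e1]
    n_dropped = int(slope.isna().sum())
    return SlopeVector(slope.dropna(), e1, e2, n_dropped)


def slope_scan(
    genotypes: GenotypeMatrix,
    slope: SlopeVector,
    n_perm: int,
    seed: int,
    *,
    alpha: float = 0.05,
) -> tuple[pd.DataFrame, float]:
    """Single-trait QTL scan on the slope phenotype (delegates to qtl)."""
    return qtl_mod.permutation_pvalues(
        genotypes, slope.values, n_perm, seed, alpha=alpha
    )


def significant_gei_loci(
    gei: pd.DataFrame,
    slope: pd.DataFrame,
    *,
    alpha_gei: float = 0.1,
    alpha_slope: float = 0.05,
) -> list[str]:
    """Markers with GEI p < alpha_gei AND slope p < alpha_slope (strict)."""
    if not gei.index.equals(slope.index):
        raise ValueError("GEI and slope scans cover different markers")
    keep = (gei["p"] < alpha_gei) & (slope["p"] < alpha_slope)
    return list(gei.index[keep.fillna(False)])


# ---------------------------------------------------------------------------
# classification
# ---------------------------------------------------------------------------


def _allele_groups(
    genotypes: GenotypeMatrix, phenotypes: PhenotypeMatrix, marker: str, env: str
):
    g = genotypes.calls[marker]
    y = phenotypes.values[env].reindex(g.index)
    keep = g.notna() & y.notna()
    by = y[keep & (g == 0)].to_numpy()
    rm = y[keep & (g == 1)].to_numpy()
    return by, rm


def classify_gei_locus(
    genotypes: GenotypeMatrix,
    phenotypes: PhenotypeMatrix,
    pair: tuple[str, str],
    marker: str,
    *,
    alpha: float = 0.005,
    p_gei: float = float("nan"),
    p_slope: float = float("nan"),
) -> GEILocusRecord:
    """Classify one significant GEI locus by per-environment Welch t-tests.

    Significant (p < alpha) in exactly one environment -> ``env_specific``;
    in both with the RM-BY contrast same-signed -> ``scale``; opposite
    signs -> ``antagonistic``; otherwise ``unclassified``.
    """
    e1, e2 = pair
    stats_per_env = {}
    for env in pair:
        by, rm = _allele_groups(genotypes, phenotypes, marker, env)
        if len(by) < 2 or len(rm) < 2:
            raise ValueError(f"allele class with < 2 entities at {marker} in {env}")
        t = stats.ttest_ind(rm, by, equal_var=False)
        stats_per_env[env] = {
            "p": float(t.pvalue),
            "diff": float(rm.mean() - by.mean()),
            "mean_by": float(by.mean()),
            "mean_rm": float(rm.mean()),
            "se_by": float(by.std(ddof=1) / np.sqrt(len(by))),
            "se_rm": float(rm.std(ddof=1) / np.sqrt(len(rm))),
        }
    s1, s2 = stats_per_env[e1], stats_per_env[e2]
    sig1, sig2 = s1["p"] < alpha, s2["p"] < alpha
    if sig1 and sig2:
        cls = "scale" if np.sign(s1["diff"]) == np.sign(s2["diff"]) else "antagonistic"
    elif sig1 or sig2:
        cls = "env_specific"
    else:
        cls = "unclassified"
    row = genotypes.markers.table.loc[marker]
    return GEILocusRecord(
        marker_id=marker,
        chromosome=str(row["chromosome"]),
        position=int(row["position"]),
        env1=e1,
        env2=e2,
        p_gei=p_gei,
        p_slope=p_slope,
        t_p1=s1["p"],
        t_p2=s2["p"],
        mean_by_e1=s1["mean_by"],
        mean_rm_e1=s1["mean_rm"],
        mean_by_e2=s2["mean_by"],
        mean_rm_e2=s2["mean_rm"],
        se_by_e1=s1["se_by"],
        se_rm_e1=s1["se_rm"],
        se_by_e2=s2["se_by"],
        se_rm_e2=s2["se_rm"],
        gei_class=cls,  # type: ignore[arg-type]
    )


def reaction_norm(
    genotypes: GenotypeMatrix,
    phenotypes: PhenotypeMatrix,
    pair: tuple[str, str],
    marker: str,
) -> ReactionNorm:
    """Allele x environment means +/- SE; crossing iff the allele order of
    the means differs between the two environments."""
    e1, e2 = pair
    vals = {}
    for env in pair:
        by, rm = _allele_groups(genotypes, phenotypes, marker, env)
        if len(by) == 0 or len(rm) == 0:
            raise ValueError(f"empty allele class at {marker} in {env}")
        vals[env] = (
            by.mean(),
            rm.mean(),
            by.std(ddof=1) / np.sqrt(len(by)),
            rm.std(ddof=1) / np.sqrt(len(rm)),
        )
    d1 = vals[e1][1] - vals[e1][0]
    d2 = vals[e2][1] - vals[e2][0]
    return ReactionNorm(
        marker, e1, e2,
        mean_by_e1=vals[e1][0], mean_rm_e1=vals[e1][1],
        mean_by_e2=vals[e2][0], mean_rm_e2=vals[e2][1],
        se_by_e1=vals[e1][2], se_rm_e1=vals[e1][3],
        se_by_e2=vals[e2][2], se_rm_e2=vals[e2][3],
        crossing=bool(np.sign(d1) * np.sign(d2) < 0),
    )


def map_gei_pair(
    genotypes: GenotypeMatrix,
    phenotypes: PhenotypeMatrix,
    pair: tuple[str, str],
    n_perm: int,
    seed: int,
    *,
    alpha_gei: float = 0.1,
    alpha_slope: float = 0.05,
    alpha_t: float = 0.005,
) -> list[GEILocusRecord]:
    """Run the full GEI pipeline for one environment pair.

    GEI scan + slope scan, the joint significance filter, and the
    three-way classification of every significant locus.
    """
    g_scan = gei_scan(genotypes, phenotypes, pair, n_perm, seed)
    sl = slope_phenotype(phenotypes, pair)
    s_scan, _ = slope_scan(genotypes, sl, n_perm, seed + 1)
    markers = significant_gei_loci(
        g_scan, s_scan, alpha_gei=alpha_gei, alpha_slope=alpha_slope
    )
    return [
        classify_gei_locus(
            genotypes,
            phenotypes,
            pair,
            m,
            alpha=alpha_t,
            p_gei=float(g_scan.loc[m, "p"]),
            p_slope=float(s_scan.loc[m, "p"]),
        )
        for m in markers
    ]


# ---------------------------------------------------------------------------
# AP degree and scan overlap
# ---------------------------------------------------------------------------


def mapping_degree_of_antagonism(
    records: Sequence[GEILocusRecord], window: int = 60_000
) -> float:
    """Percentage of scale / environment-specific loci with a crossover nearby.

    A scale or env-specific locus counts toward the numerator when some
    antagonistic locus from a different environment pair lies within
    +/- ``window`` bp (inclusive) on the same chromosome.
    """
    antagonistic = [r for r in records if r.gei_class == "antagonistic"]
    others = [r for r in records if r.gei_class in ("scale", "env_specific")]
    if not others:
        return 0.0
    hits = 0
    for r in others:
        for a in antagonistic:
            if (a.env1, a.env2) == (r.env1, r.env2):
                continue
            if a.chromosome == r.chromosome and abs(a.position - r.position) <= window:
                hits += 1
                break
    return 100.0 * hits / len(others)


def slope_gei_overlap(
    slope_peaks: Sequence[QTLPeak],
    gei_peaks: Sequence[QTLPeak],
    window: int = 60_000,
) -> tuple[float, float]:
    """(percent of slope peaks with a GEI peak within the window, and the
    reverse percent); 0 when the corresponding list is empty."""

    def pct(a: Sequence[QTLPeak], b: Sequence[QTLPeak]) -> float:
        if not a:
            return 0.0
        hit = sum(
            1
            for pa in a
            if any(
                pb.chromosome == pa.chromosome and abs(pb.position - pa.position) <= window
                for pb in b
            )
        )
        return 100.0 * hit / len(a)

    return pct(slope_peaks, gei_peaks), pct(gei_peaks, slope_peaks)
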