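"""Single-environment QTL scans by marker regression.

For each biallelic marker the phenotype is regressed on the allele class and
the evidence is summarized as a LOD score,

    LOD = (n / 2) * log10(RSS0 / RSS1),

where RSS0 is the residual sum of squares of the mean-only model and RSS1
that of the per-allele-means model, over entities with both a genotype call
at the marker and a phenotype value (pairwise-complete). Genome-wide
significance comes from permuting the phenotype across entities and
comparing the observed LOD with the null distribution of the genome-wide
maximum LOD; p-values carry the +1 correction so the smallest attainable
value is 1 / (n_perm + 1).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io_formats import GenotypeMatrix


@dataclass(frozen=True)
class QTLPeak:
    marker_id: str
    chromosome: str
    position: int
    lod: float
    p: float
    environment_id: str


def _prepare(genotypes: GenotypeMatrix, phenotype: pd.Series):
    """Align entities, returning (G, mask, y) with NaNs zeroed in G."""
    y = phenotype.reindex(genotypes.segregant_ids)
    keep = y.notna().to_numpy()
    y = y.to_numpy(dtype=float)[keep]
    G = genotypes.calls.to_numpy(dtype=float)[keep]
    mask = ~np.isnan(G)
    Gz = np.where(mask, G, 0.0)
    return Gz, mask, y


def _lod_from_stats(Gz, mask, y):
    """Vectorized per-marker LOD from sufficient statistics.

    Returns (lod, n_used) arrays; markers with a single allele class get
    NaN LOD.
    """
    n_k = mask.sum(axis=0).astype(float)
    n1 = (Gz * mask).sum(axis=0)
    n0 = n_k - n1
    sum_y = (mask * y[:, None]).sum(axis=0)
    sum_y2 = (mask * (y**2)[:, None]).sum(axis=0)
    s1 = (Gz * y[:, None]).sum(axis=0)
    s0 = sum_y - s1
    with np.errstate(divide="ignore", invalid="ignore"):
        rss0 = sum_y2 - sum_y**2 / n_k
        rss1 = sum_y2 - np.where(n0 > 0, s0**2 / np.maximum(n0, 1), 0.0) - np.where(
            n1 > 0, s1**2 / np.maximum(n1, 1), 0.0
        )
        lod = 0.5 * n_k * np.log10(rss0 / rss1)
    lod = np.where((n0 == 0) | (n1 == 0), np.nan, lod)
    # numerical floor: RSS1 == RSS0 up to rounding -> 0, not tiny negatives
    lod = np.where(np.isfinite(lod) & (lod < 0), 0.0, lod)
    return lod, n_k


def lod_scan(
    genotypes: GenotypeMatrix, phenotype: pd.Series, *, min_entities: int = 10
) -> pd.DataFrame:
    """Marker-regression LOD at every marker for one environment.

    Returns a DataFrame indexed by marker id with columns ``chromosome``,
    ``position``, ``lod`` (NaN, with a warning, for markers with a single
    allele class among pairwise-complete entities).
    """
    Gz, mask, y = _prepare(genotypes, phenotype)
    if len(y) < min_entities:
        raise ValueError(f"need >= {min_entities} entities with phenotype values")
    n_k = mask.sum(axis=0)
    if (n_k < min_entities).any():
        raise ValueError(f"markers with < {min_entities} complete entities")
    lod, _ = _lod_from_stats(Gz, mask, y)
    if np.isnan(lod).any():
        n_bad = int(np.isnan(lod).sum())
        warnings.warn(f"{n_bad} marker(s) monomorphic among complete cases; LOD set to NaN")
    t = genotypes.markers.table
    return pd.DataFrame(
        {"chromosome": t["chromosome"], "position": t["position"], "lod": lod},
        index=t.index,
    )


def permutation_pvalues(
    genotypes: GenotypeMatrix,
    phenotype: pd.Series,
    n_perm: int,
    seed: int,
    *,
    alpha: float = 0.05,
) -> tuple[pd.DataFrame, float]:
    """Genome-wide permutation p-values for a marker-regression scan.

    The phenotype is shuffled across entities ``n_perm`` times; each
    marker's p is the +1-corrected fraction of permutations whose
    genome-wide maximum LOD reaches the marker's observed LOD. Also returns
    the (1 - alpha) quantile of the permuted maxima as the scan threshold.
    """
    if n_perm < 100:
        raise ValueError("need at least 100 permutations")
    scan = lod_scan(genotypes, phenotype)
    Gz, mask, y = _prepare(genotypes, phenotype)
    rng = np.random.default_rng(seed)
    maxima = np.empty(n_perm)
    for b in range(n_perm):
        yp = rng.permutation(y)
        lod_b, _ = _lod_from_stats(Gz, mask, yp)
        maxima[b] = np.nanmax(lod_b)
    obs = scan["lod"].to_numpy()
    exceed = (maxima[None, :] >= obs[:, None]).sum(axis=1)
    p = (1.0 + exceed) / (n_perm + 1.0)
    p = np.where(np.isnan(obs), np.nan, p)
    out = scan.copy()
    out["p"] = p
    threshold = float(np.quantile(maxima, 1.0 - alpha))
    return out, threshold


def select_peaks(
    scan: pd.DataFrame,
    threshold: float,
    min_separation: int = 60_000,
    *,
    environment_id: str = "",
) -> list[QTLPeak]:
    """Greedy peak calling: take the strongest supra-threshold marker, mask
    +/- ``min_separation`` bp around it on its chromosome, repeat. Ties go to
    the leftmost (map-order first) marker."""
    df = scan.dropna(subset=["lod"])
    df = df[df["lod"] >= threshold]
    order = np.lexsort(
        (np.arange(len(df)), -df["lod"].to_numpy())
    )  # by decreasing LOD, then map order
    taken: list[QTLPeak] = []
    masked = np.zeros(len(df), dtype=bool)
    chroms = df["chromosome"].to_numpy()
    pos = df["position"].to_numpy()
    for idx in order:
        if masked[idx]:
            continue
        row = df.iloc[idx]
        taken.append(
            QTLPeak(
                str(df.index[idx]),
                str(row["chromosome"]),
                int(row["position"]),
                float(row["lod"]),
                float(row["p"]) if "p" in df.columns else float("nan"),
                environment_id,
            )
        )
        near = (chroms == chroms[idx]) & (np.abs(pos - pos[idx]) <= min_separation)
        masked |= near
    taken.sort(key=lambda p: (p.chromosome, p.position))
    return taken


class CollinearLociError(ValueError):
    pass


def variance_explained(
    genotypes: GenotypeMatrix,
    phenotype: pd.Series,
    loci: list[str],
) -> tuple[pd.Series, float]:
    """Percent variance explained by a set of loci, jointly and per locus.

    Fits the multi-marker additive linear model on complete cases; the
    joint R^2 is reported in percent, and each locus's share is the drop in
    model R^2 when that marker is removed (type-III style).
    """
    sub = genotypes.calls[loci]
    y = phenotype.reindex(sub.index)
    keep = y.notna() & sub.notna().all(axis=1)
    X = sub[keep].to_numpy(dtype=float)
    yv = y[keep].to_numpy(dtype=float)
    n = len(yv)
    Xc = X - X.mean(axis=0)
    if np.linalg.matrix_rank(Xc) < X.shape[1]:
        corr = np.corrcoef(X.T)
        for i in range(len(loci)):
            for j in range(i + 1, len(loci)):
                if abs(corr[i, j]) > 1 - 1e-12:
                    raise CollinearLociError(f"collinear loci: {loci[i]}, {loci[j]}")
        raise CollinearLociError(f"collinear locus set: {loci}")

    def r2(cols: list[int]) -> float:
        A = np.column_stack([np.ones(n), X[:, cols]])
        resid = yv - A @ np.linalg.lstsq(A, yv, rcond=None)[0]
        tss = ((yv - yv.mean()) ** 2).sum()
        return 1.0 - (resid**2).sum() / tss

    full = r2(list(range(len(loci))))
    per = {}
    for i, locus in enumerate(loci):
        others = [j for j in range(len(loci)) if j != i]
        per[locus] = 100.0 * (full - (r2(others) if others else 0.0))
    return pd.Series(per), 100.0 * full
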