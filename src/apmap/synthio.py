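"""Synthetic inputs with planted ground truth for every pipeline stage.

The generators emulate the data classes of the study design — a biparental
haploid yeast cross with linkage, growth phenotypes with planted QTL of the
three gene-environment-interaction classes and environment-dependent
epistatic pairs, deletion-screen z-score matrices, natural-isolate growth
matrices, aligned sequence panels with tunable site-frequency spectra, and
Ras-mutant expression ratio panels — so the full analysis can be exercised
and validated without any external download.

All generators are pure functions of (specification, seed): crossing the
same seed twice yields byte-identical output. The phenotype model is linear
and additive with Gaussian noise,

    y(i, E) = sum_q beta_q(E) g_iq  +  sum_(a,b) gamma_ab(E) g_ia g_ib  +  eps,

with effects in phenotype-standard-deviation units; this is the minimal
structure the downstream linear scans assume. Recombination follows the
Haldane map function r = (1 - exp(-2 d / 100)) / 2 (d in centimorgans, no
interference).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Mapping, Sequence

import numpy as np
import pandas as pd

from .io_formats import AlignmentSet, GenotypeMatrix, MarkerMap, PhenotypeMatrix

GEIClass = Literal["env_specific", "scale", "antagonistic", "none"]


@dataclass(frozen=True)
class QTLSpec:
    """A planted single locus: additive RM-allele effect per environment (SD units)."""

    marker_id: str
    effects: dict[str, float]
    gei_class: GEIClass = "none"

    def __post_init__(self) -> None:
        nonzero = {e: v for e, v in self.effects.items() if v != 0.0}
        label = _classify_effects(nonzero)
        if self.gei_class != "none" and label != self.gei_class:
            raise ValueError(
                f"QTLSpec {self.marker_id}: effects {self.effects} imply class "
                f"{label!r}, not {self.gei_class!r}"
            )


def _classify_effects(nonzero: Mapping[str, float]) -> GEIClass:
    vals = list(nonzero.values())
    if len(vals) == 0:
        return "none"
    if len(vals) == 1:
        return "env_specific"
    signs = {np.sign(v) for v in vals}
    if len(signs) > 1:
        return "antagonistic"
    if len({abs(v) for v in vals}) > 1:
        return "scale"
    return "none"  # equal effects everywhere: no GEI


@dataclass(frozen=True)
class EpistasisSpec:
    """A planted marker-pair interaction with per-environment coefficients.

    ``compensatory`` marks pairs built so that each locus alone is
    antagonistic across the pair of environments while the two parental
    two-marker combinations (BB, RR) keep a same-signed contrast — the
    trade-off is resolved in the parental backgrounds and only visible in
    recombinant (mixed) combinations.
    """

    marker_a: str
    marker_b: str
    coefficients: dict[str, float]
    compensatory: bool = False


@dataclass(frozen=True)
class TruthTable:
    """The planted architecture a simulated phenotype set was built from."""

    qtls: tuple[QTLSpec, ...] = ()
    epistasis: tuple[EpistasisSpec, ...] = ()
    noise_sd: float | Mapping[str, float] = 1.0
    seed: int = 0

    def noise_for(self, environment: str) -> float:
        if isinstance(self.noise_sd, Mapping):
            return float(self.noise_sd[environment])
        return float(self.noise_sd)


# ---------------------------------------------------------------------------
# marker maps and the cross
# ---------------------------------------------------------------------------


def grid_marker_map(
    n_chromosomes: int = 10,
    markers_per_chromosome: int = 20,
    *,
    spacing_cm: float = 5.0,
    spacing_bp: int = 10_000,
) -> MarkerMap:
    """A regular marker grid: convenience map for simulations."""
    rows = []
    for c in range(1, n_chromosomes + 1):
        for j in range(markers_per_chromosome):
            rows.append(
                {
                    "marker_id": f"chr{c:02d}_m{j:03d}",
                    "chromosome": f"chr{c:02d}",
                    "position": 1 + j * spacing_bp,
                    "cm": j * spacing_cm,
                }
            )
    df = pd.DataFrame(rows).set_index("marker_id")
    return MarkerMap(df)


def haldane_recombination_fraction(d_cm: np.ndarray | float) -> np.ndarray | float:
    """Map distance (cM) -> recombination fraction, Haldane (no interference)."""
    d = np.asarray(d_cm, dtype=float)
    if np.any(d < 0):
        raise ValueError("negative genetic distance")
    return (1.0 - np.exp(-2.0 * d / 100.0)) / 2.0


def simulate_cross(
    n_segregants: int, marker_map: MarkerMap, seed: int
) -> GenotypeMatrix:
    """Simulate haploid segregants of a biparental cross.

    The first marker of each chromosome is Bernoulli(0.5); consecutive
    markers recombine with the Haldane fraction of their centimorgan
    distance (the ``cm`` column of the map).
    """
    if n_segregants < 2:
        raise ValueError("need at least 2 segregants")
    if len(marker_map) == 0:
        raise ValueError("empty marker map")
    if "cm" not in marker_map.table.columns:
        raise ValueError("marker map lacks a 'cm' genetic-distance column")
    rng = np.random.default_rng(seed)
    t = marker_map.table
    calls = np.empty((n_segregants, len(t)), dtype=float)
    col = 0
    for _, sub in t.groupby("chromosome", sort=False):
        m = len(sub)
        d = np.diff(sub["cm"].to_numpy())
        r = haldane_recombination_fraction(d)
        g = np.empty((n_segregants, m))
        g[:, 0] = rng.integers(0, 2, size=n_segregants)
        if m > 1:
            flips = rng.random((n_segregants, m - 1)) < r[None, :]
            g[:, 1:] = flips
            g = np.cumsum(g, axis=1) % 2  # cumulative crossovers flip phase
        calls[:, col : col + m] = g
        col += m
    frame = pd.DataFrame(
        calls,
        index=[f"seg{i:04d}" for i in range(n_segregants)],
        columns=t.index,
    )
    return GenotypeMatrix(frame, marker_map)


# ---------------------------------------------------------------------------
# phenotypes with planted architecture
# ---------------------------------------------------------------------------

# default planted per-environment effects (SD units) for each GEI class, on a
# pair of environments (E1, E2); all nonzero effects are >= 0.5 SD
DEFAULT_CLASS_EFFECTS: dict[str, tuple[float, float]] = {
    "env_specific": (0.5, 0.0),
    "scale": (1.0, 0.5),
    "antagonistic": (0.5, -0.5),
}


def planted_truth(
    marker_map: MarkerMap,
    environments: Sequence[str],
    *,
    n_per_class: int = 3,
    classes: Sequence[str] = ("env_specific", "scale", "antagonistic"),
    noise_sd: float = 1.0,
    seed: int = 0,
) -> TruthTable:
    """Place ``n_per_class`` QTL of each class on distinct chromosomes.

    Loci are assigned to the middle marker of successive chromosomes so that
    planted signals are unlinked from one another.
    """
    if len(environments) != 2:
        raise ValueError("planted_truth builds pairwise (two-environment) truths")
    chroms = list(dict.fromkeys(marker_map.table["chromosome"]))
    needed = n_per_class * len(classes)
    if needed > len(chroms):
        raise ValueError("not enough chromosomes to place unlinked planted loci")
    e1, e2 = environments
    qtls = []
    k = 0
    for cls in classes:
        a, b = DEFAULT_CLASS_EFFECTS[cls]
        for _ in range(n_per_class):
            sub = marker_map.table[marker_map.table["chromosome"] == chroms[k]]
            marker = sub.index[len(sub) // 2]
            qtls.append(QTLSpec(marker, {e1: a, e2: b}, gei_class=cls))  # type: ignore[arg-type]
            k += 1
    return TruthTable(tuple(qtls), (), noise_sd, seed)


def compensatory_pair_truth(
    marker_map: MarkerMap,
    environments: Sequence[str],
    *,
    n_pairs: int = 5,
    main_effect: float = 0.5,
    interaction: float = 0.5,
    offset: float = 0.2,
    noise_sd: float = 1.0,
    seed: int = 0,
) -> TruthTable:
    """Plant compensatory epistatic pairs across chromosomes.

    Each pair gets antagonistic, mutually opposed main effects
    (+e, -e) and (-e, +e) plus an interaction coefficient (offset,
    interaction + offset), so the slope-scale interaction equals
    ``interaction`` while the parental BB-RR contrast stays same-signed in
    both environments (no parental crossover); mixed-background contrasts
    flip sign between environments.
    """
    if len(environments) != 2:
        raise ValueError("compensatory pairs are defined on an environment pair")
    chroms = list(dict.fromkeys(marker_map.table["chromosome"]))
    if 2 * n_pairs > len(chroms):
        raise ValueError("not enough chromosomes for unlinked pairs")
    e1, e2 = environments
    qtls, pairs = [], []
    for p in range(n_pairs):
        sub_a = marker_map.table[marker_map.table["chromosome"] == chroms[2 * p]]
        sub_b = marker_map.table[marker_map.table["chromosome"] == chroms[2 * p + 1]]
        ma = sub_a.index[len(sub_a) // 2]
        mb = sub_b.index[len(sub_b) // 2]
        qtls.append(QTLSpec(ma, {e1: +main_effect, e2: -main_effect}, "antagonistic"))
        qtls.append(QTLSpec(mb, {e1: -main_effect, e2: +main_effect}, "antagonistic"))
        pairs.append(
            EpistasisSpec(
                ma, mb, {e1: offset, e2: interaction + offset}, compensatory=True
            )
        )
    return TruthTable(tuple(qtls), tuple(pairs), noise_sd, seed)


def simulate_phenotypes(
    genotypes: GenotypeMatrix,
    truth: TruthTable,
    environments: Sequence[str],
) -> tuple[PhenotypeMatrix, TruthTable]:
    """Additive + pairwise-epistatic phenotypes with Gaussian noise.

    value(entity, env) = sum_QTL effect * code + sum_pairs coeff * code_a *
    code_b + Normal(0, noise SD); returned unstandardized, with the truth
    echoed back for downstream recovery checks.
    """
    env = list(environments)
    marker_ids = set(genotypes.calls.columns)
    for q in truth.qtls:
        if q.marker_id not in marker_ids:
            raise ValueError(f"unknown marker in truth: {q.marker_id}")
        for e in q.effects:
            if e not in env:
                raise ValueError(f"unknown environment in QTLSpec: {e!r}")
    for p in truth.epistasis:
        if p.marker_a not in marker_ids or p.marker_b not in marker_ids:
            raise ValueError(f"unknown marker in epistasis spec: {p.marker_a}/{p.marker_b}")
        for e in p.coefficients:
            if e not in env:
                raise ValueError(f"unknown environment in EpistasisSpec: {e!r}")

    rng = np.random.default_rng(truth.seed)
    g = genotypes.calls
    n = genotypes.n_segregants
    out = np.zeros((n, len(env)))
    for j, e in enumerate(env):
        mean = np.zeros(n)
        for q in truth.qtls:
            eff = q.effects.get(e, 0.0)
            if eff:
                mean += eff * g[q.marker_id].to_numpy()
        for p in truth.epistasis:
            coef = p.coefficients.get(e, 0.0)
            if coef:
                mean += coef * g[p.marker_a].to_numpy() * g[p.marker_b].to_numpy()
        sd = truth.noise_for(e)
        out[:, j] = mean + (rng.normal(0.0, sd, size=n) if sd > 0 else 0.0)
    values = pd.DataFrame(out, index=genotypes.segregant_ids, columns=env)
    return PhenotypeMatrix(values, standardized=False), truth


# ---------------------------------------------------------------------------
# deletion screens and isolate panels
# ---------------------------------------------------------------------------


def simulate_deletion_screen(
    n_genes: int,
    environments: Sequence[str],
    planted: Sequence[tuple[str, tuple[str, str], str]] = (),
    *,
    background_sd: float = 1.0,
    planted_magnitude: float = 3.0,
    seed: int = 0,
) -> PhenotypeMatrix:
    """A gene x environment z-score-like screen with planted antagonistic genes.

    ``planted`` entries are (gene_id, (E1, E2), direction) with direction
    ``"up_in_E1"`` or ``"up_in_E2"``; planted genes get +/-``planted_magnitude``
    in the named pair so they survive the +/-0.5 SD rule after column
    standardization. Background cells are Normal(0, background_sd).
    """
    env = list(environments)
    if len(set((g, pair) for g, pair, _ in planted)) != len(planted):
        raise ValueError("duplicate planted gene/pair")
    genes = [f"gene{i:04d}" for i in range(n_genes)]
    gene_set = set(genes)
    rng = np.random.default_rng(seed)
    vals = rng.normal(0.0, background_sd, size=(n_genes, len(env)))
    for gene, (e1, e2), direction in planted:
        if gene not in gene_set:
            raise ValueError(f"planted gene {gene!r} outside the panel")
        if direction not in ("up_in_E1", "up_in_E2"):
            raise ValueError(f"bad direction {direction!r}")
        i = genes.index(gene)
        s = 1.0 if direction == "up_in_E1" else -1.0
        vals[i, env.index(e1)] = s * planted_magnitude
        vals[i, env.index(e2)] = -s * planted_magnitude
    return PhenotypeMatrix(pd.DataFrame(vals, index=genes, columns=env))


def simulate_isolates(
    n_strains: int,
    environments: Sequence[str],
    planted_categories: Mapping[str, str] = (),
    *,
    seed: int = 0,
) -> PhenotypeMatrix:
    """A strain x environment growth panel with planted trade-off categories.

    Planted strains get deterministic values: category I strains exceed
    +2.5 in one environment and fall below -2.5 in another; II strains stay
    within +/-0.2 everywhere; III strains exceed +2.5 one-sidedly. Background
    strains are Normal(0, 1). Margins are wide enough that the categories
    survive sample standardization of the panel.
    """
    env = list(environments)
    if len(env) < 2:
        raise ValueError("need at least 2 environments")
    planted_categories = dict(planted_categories)
    total = n_strains + len(planted_categories)
    if total < 4:
        raise ValueError("panel too small to standardize meaningfully")
    rng = np.random.default_rng(seed)
    bg_ids = [f"strain{i:03d}" for i in range(n_strains)]
    vals = rng.normal(0.0, 1.0, size=(n_strains, len(env)))
    rows = [pd.DataFrame(vals, index=bg_ids, columns=env)]
    for strain, cat in planted_categories.items():
        v = np.full(len(env), 0.1)
        if cat == "I":
            v[0], v[1] = 2.5, -2.5
        elif cat == "II":
            v[:] = rng.uniform(-0.2, 0.2, size=len(env))
        elif cat == "III":
            v[0] = 2.5
        else:
            raise ValueError(f"unknown category {cat!r}")
        rows.append(pd.DataFrame(v[None, :], index=[strain], columns=env))
    return PhenotypeMatrix(pd.concat(rows))


# ---------------------------------------------------------------------------
# alignments
# ---------------------------------------------------------------------------

AlignmentMode = Literal["balanced_two_clades", "singleton_excess", "uniform_random"]


def simulate_alignment(
    n_seqs: int,
    length: int,
    mode: AlignmentMode,
    n_segregating: int,
    seed: int = 0,
) -> AlignmentSet:
    """Alignments with a controlled site-frequency spectrum.

    ``balanced_two_clades`` places every derived allele on the same
    floor(n/2) sequences (intermediate frequencies, positive Tajima's D);
    ``singleton_excess`` gives each derived allele to exactly one sequence
    (negative D); ``uniform_random`` draws carrier counts uniformly on
    [1, n-1].
    """
    if n_seqs < 4:
        raise ValueError("need at least 4 sequences for a stable D")
    if n_segregating > length:
        raise ValueError("more segregating sites than alignment columns")
    rng = np.random.default_rng(seed)
    chars = np.full((n_seqs, length), "A", dtype="<U1")
    sites = rng.choice(length, size=n_segregating, replace=False)
    for k, site in enumerate(np.sort(sites)):
        if mode == "balanced_two_clades":
            carriers = np.arange(n_seqs // 2)
        elif mode == "singleton_excess":
            carriers = np.array([k % n_seqs])
        elif mode == "uniform_random":
            count = rng.integers(1, n_seqs)
            carriers = rng.choice(n_seqs, size=count, replace=False)
        else:
            raise ValueError(f"unknown mode {mode!r}")
        chars[carriers, site] = "G"
    ids = [f"seq{i:02d}" for i in range(n_seqs)]
    return AlignmentSet(ids, chars)


# ---------------------------------------------------------------------------
# expression panels
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ExpressionPanel:
    """Simulated Ras-pathway expression inputs with planted structure."""

    expression: pd.DataFrame  # gene x strain
    mutant_ratios: pd.DataFrame  # gene x mutant (treatment/reference ratios)
    responsive_genes: tuple[str, ...]
    group_labels: pd.Series  # planted cluster label (1/2) for responsive genes


def simulate_expression_panel(
    n_genes: int,
    n_strains: int,
    *,
    group_sizes: tuple[int, int] = (15, 20),
    delta: float = 5.0,
    noise_sd: float = 1.0,
    responsive_fold: float = 1.6,
    mutants: Sequence[str] = ("ras2_v19", "ras2_a22", "ira2"),
    seed: int = 0,
) -> ExpressionPanel:
    """Expression matrix with a planted two-cluster structure among Ras targets.

    The first ``sum(group_sizes)`` genes are responsive in all mutants (fold
    change ``responsive_fold`` > the 30% rule, alternating up/down); group-1
    genes are shifted up by ``delta * noise_sd`` in the first half of the
    strains, group-2 genes in the second half. Remaining genes are
    unstructured noise with near-1 mutant ratios.
    """
    if delta < 0:
        raise ValueError("delta must be nonnegative")
    k1, k2 = group_sizes
    if k1 + k2 > n_genes:
        raise ValueError("group sizes exceed the gene panel")
    rng = np.random.default_rng(seed)
    genes = [f"g{i:04d}" for i in range(n_genes)]
    strains = [f"strain{j:02d}" for j in range(n_strains)]

    expr = rng.normal(0.0, noise_sd, size=(n_genes, n_strains))
    half = n_strains // 2
    shift = delta * noise_sd
    expr[:k1, :half] += shift
    expr[k1 : k1 + k2, half:] += shift

    ratios = np.exp(rng.normal(0.0, 0.05, size=(n_genes, len(mutants))))
    for i in range(k1 + k2):
        fold = responsive_fold if i % 2 == 0 else 1.0 / responsive_fold
        ratios[i, :] = fold
    labels = pd.Series(
        [1] * k1 + [2] * k2, index=genes[: k1 + k2], name="group"
    )
    return ExpressionPanel(
        expression=pd.DataFrame(expr, index=genes, columns=strains),
        mutant_ratios=pd.DataFrame(ratios, index=genes, columns=list(mutants)),
        responsive_genes=tuple(genes[: k1 + k2]),
        group_labels=labels,
    )
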