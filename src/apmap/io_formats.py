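"""Readers and writers for the tabular and sequence formats the pipeline consumes.

Domain containers
-----------------
:class:`MarkerMap`
    Genomic coordinates (and optionally genetic-map positions) of biallelic
    markers.
:class:`GenotypeMatrix`
    Segregant x marker allele calls for a biparental haploid cross, coded
    0 = BY-like allele, 1 = RM-like allele, NaN = missing.
:class:`PhenotypeMatrix`
    Entity x environment continuous growth values, raw or column-standardized.
:class:`AlignmentSet`
    A multiple sequence alignment over {A, C, G, T, -, N}.

File formats are plain delimited text (TSV by default) and aligned FASTA;
coordinates are 1-based base pairs and intervals are inclusive.
"""

from __future__ import annotations

import dataclasses
import io
from dataclasses import dataclass
from pathlib import Path
from typing import Any, Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO


class FormatError(ValueError):
    """Raised when an input file violates the format contract."""


#: default mapping from on-disk allele symbols to internal {0, 1} codes
DEFAULT_ALLELE_CODING: dict[str, int] = {"0": 0, "1": 1, "BY": 0, "RM": 1, "B": 0, "R": 1}

#: symbols treated as a missing call / value on read
MISSING_TOKENS = {"", "NA", "NaN", "nan", "na", "."}


@dataclass(frozen=True)
class MarkerMap:
    """Ordered marker coordinates.

    Parameters
    ----------
    table
        DataFrame indexed by marker id with columns ``chromosome`` (str),
        ``position`` (int, 1-based bp) and optionally ``cm`` (genetic map
        position in centimorgans, used by the cross simulator).
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        t = self.table
        if not t.index.is_unique:
            dup = t.index[t.index.duplicated()].tolist()
            raise FormatError(f"duplicate marker ids: {dup}")
        for col in ("chromosome", "position"):
            if col not in t.columns:
                raise FormatError(f"marker map missing column {col!r}")
        for chrom, sub in t.groupby("chromosome", sort=False):
            pos = sub["position"].to_numpy()
            if not np.all(np.diff(pos) > 0):
                raise FormatError(
                    f"positions not strictly increasing on chromosome {chrom}"
                )

    @property
    def marker_ids(self) -> list[str]:
        return list(self.table.index)

    @property
    def chromosome(self) -> pd.Series:
        return self.table["chromosome"]

    @property
    def position(self) -> pd.Series:
        return self.table["position"]

    def __len__(self) -> int:
        return len(self.table)


@dataclass
class GenotypeMatrix:
    """Biallelic haploid genotype calls plus the genomic marker map.

    ``calls`` is a segregant x marker float DataFrame over {0.0, 1.0, NaN};
    0 is the BY-like allele, 1 the RM-like allele.
    """

    calls: pd.DataFrame
    markers: MarkerMap

    def __post_init__(self) -> None:
        if list(self.calls.columns) != self.markers.marker_ids:
            raise FormatError("genotype columns do not match the marker map")
        vals = self.calls.to_numpy(dtype=float)
        ok = np.isnan(vals) | (vals == 0.0) | (vals == 1.0)
        if not ok.all():
            bad = sorted(set(vals[~ok].tolist()))
            raise FormatError(f"genotype codes outside {{0, 1, missing}}: {bad}")

    @property
    def segregant_ids(self) -> list[str]:
        return list(self.calls.index)

    @property
    def n_segregants(self) -> int:
        return self.calls.shape[0]

    @property
    def n_markers(self) -> int:
        return self.calls.shape[1]

    def check_missingness(self, max_fraction: float) -> None:
        frac = self.calls.isna().mean(axis=0)
        bad = frac[frac > max_fraction]
        if len(bad):
            raise FormatError(
                f"markers exceed missingness limit {max_fraction}: "
                f"{bad.index.tolist()}"
            )


@dataclass
class PhenotypeMatrix:
    """Entity x environment continuous growth values.

    When ``standardized`` is set, every environment column has mean 0 and
    sample standard deviation (n-1 denominator) 1 over its non-missing
    entries, to within 1e-8.
    """

    values: pd.DataFrame
    standardized: bool = False

    def __post_init__(self) -> None:
        if self.standardized:
            v = self.values
            mu = v.mean(axis=0, skipna=True)
            sd = v.std(axis=0, ddof=1, skipna=True)
            if not (np.abs(mu.to_numpy()) < 1e-8).all() or not (
                np.abs(sd.to_numpy() - 1.0) < 1e-8
            ).all():
                raise FormatError(
                    "matrix flagged standardized but columns are not ~N(0, 1)-scaled"
                )

    @property
    def entity_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def environment_ids(self) -> list[str]:
        return list(self.values.columns)


@dataclass
class AlignmentSet:
    """Aligned sequences over {A, C, G, T, -, N} as an (n, L) char array."""

    sequence_ids: list[str]
    chars: np.ndarray  # shape (n_seqs, length), dtype '<U1'

    def __post_init__(self) -> None:
        if len(self.sequence_ids) < 2:
            raise FormatError("an alignment needs at least 2 sequences")
        if self.chars.ndim != 2 or self.chars.shape[0] != len(self.sequence_ids):
            raise FormatError("sequence ids and character matrix are inconsistent")

    @property
    def n_sequences(self) -> int:
        return self.chars.shape[0]

    @property
    def length(self) -> int:
        return self.chars.shape[1]

    @property
    def sequences(self) -> list[str]:
        return ["".join(row) for row in self.chars]


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------

_META_ROWS = ("chromosome", "position", "cm")


def read_genotype_table(
    path: str | Path,
    *,
    sep: str = "\t",
    allele_coding: Mapping[str, int] | None = None,
) -> GenotypeMatrix:
    """Read a segregant x marker genotype table.

    Layout: header row names the markers; the first rows whose index label is
    ``chromosome`` / ``position`` (and optionally ``cm``) carry the marker
    map; remaining rows are segregants. Allele symbols are mapped through
    ``allele_coding`` (default accepts 0/1 and BY/RM spellings); unmapped
    symbols or more than two distinct symbols in a column are format errors.
    """
    coding = dict(DEFAULT_ALLELE_CODING if allele_coding is None else allele_coding)
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split(sep)[1:]
    dup = pd.Index(header)[pd.Index(header).duplicated()].tolist()
    if dup:
        raise FormatError(f"duplicate marker ids: {dup}")
    raw = pd.read_csv(path, sep=sep, index_col=0, dtype=str, keep_default_na=False)
    raw.index.name = None
    raw.columns = pd.Index(header)
    meta_labels = [r for r in _META_ROWS if r in raw.index]
    if "chromosome" not in meta_labels or "position" not in meta_labels:
        raise FormatError("genotype table lacks 'chromosome'/'position' metadata rows")
    meta = raw.loc[meta_labels]
    body = raw.drop(index=meta_labels)

    map_df = pd.DataFrame(
        {
            "chromosome": meta.loc["chromosome"].astype(str),
            "position": meta.loc["position"].astype(int),
        },
        index=raw.columns,
    )
    if "cm" in meta_labels:
        map_df["cm"] = meta.loc["cm"].astype(float)
    markers = MarkerMap(map_df)

    calls = np.full(body.shape, np.nan)
    for j, marker in enumerate(body.columns):
        col = body.iloc[:, j].str.strip()
        present = ~col.isin(MISSING_TOKENS)
        symbols = sorted(set(col[present]))
        if len(symbols) > 2:
            raise FormatError(f"marker {marker!r} is not biallelic: symbols {symbols}")
        for sym in symbols:
            if sym not in coding:
                raise FormatError(f"marker {marker!r}: unknown allele symbol {sym!r}")
            calls[(col == sym) & present, j] = coding[sym]
    frame = pd.DataFrame(calls, index=body.index, columns=body.columns)
    return GenotypeMatrix(frame, markers)


def write_genotype_table(
    genotypes: GenotypeMatrix, path: str | Path, *, sep: str = "\t"
) -> None:
    """Write a genotype table in the layout :func:`read_genotype_table` expects."""
    t = genotypes.markers.table
    rows = {"chromosome": t["chromosome"].astype(str), "position": t["position"].astype(str)}
    if "cm" in t.columns:
        rows["cm"] = t["cm"].astype(str)
    meta = pd.DataFrame(rows).T
    meta.columns = genotypes.calls.columns
    body = genotypes.calls.map(lambda v: "NA" if pd.isna(v) else str(int(v)))
    out = pd.concat([meta, body])
    out.index.name = "segregant"
    out.to_csv(path, sep=sep)


def read_phenotype_table(path: str | Path, *, sep: str = "\t") -> PhenotypeMatrix:
    """Read an entity x environment growth table; blanks become missing."""
    with open(path) as fh:
        widths = {len(line.rstrip("\n").split(sep)) for line in fh if line.strip()}
    if len(widths) > 1:
        raise FormatError("ragged rows in phenotype table")
    raw = pd.read_csv(
        path, sep=sep, index_col=0, dtype=str, keep_default_na=False
    )
    raw.index.name = None
    vals = np.full(raw.shape, np.nan)
    for j in range(raw.shape[1]):
        col = raw.iloc[:, j].str.strip()
        present = ~col.isin(MISSING_TOKENS)
        try:
            vals[present.to_numpy(), j] = col[present].astype(float)
        except ValueError as exc:
            raise FormatError(
                f"non-numeric cell in column {raw.columns[j]!r}: {exc}"
            ) from exc
    return PhenotypeMatrix(
        pd.DataFrame(vals, index=raw.index, columns=raw.columns), standardized=False
    )


def write_phenotype_table(
    phenotypes: PhenotypeMatrix, path: str | Path, *, sep: str = "\t"
) -> None:
    out = phenotypes.values.copy()
    out.index.name = "entity"
    out.to_csv(path, sep=sep, na_rep="NA", float_format="%.10g")


_ALLOWED_CHARS = set("ACGTN-")


def read_fasta(path: str | Path) -> AlignmentSet:
    """Read an aligned FASTA file; bases are upcased, lengths must agree."""
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise FormatError(f"no FASTA records in {path}")
    if len(records) < 2:
        raise FormatError("an alignment needs at least 2 sequences")
    seqs = [str(r.seq).upper() for r in records]
    lengths = {len(s) for s in seqs}
    if len(lengths) != 1:
        raise FormatError(f"sequences are not aligned: lengths {sorted(lengths)}")
    bad = set("".join(seqs)) - _ALLOWED_CHARS
    if bad:
        raise FormatError(f"unexpected characters in alignment: {sorted(bad)}")
    chars = np.array([list(s) for s in seqs], dtype="<U1")
    return AlignmentSet([r.id for r in records], chars)


def write_fasta(alignment: AlignmentSet, path: str | Path) -> None:
    with open(path, "w") as fh:
        for sid, seq in zip(alignment.sequence_ids, alignment.sequences):
            fh.write(f">{sid}\n{seq}\n")


def _record_fields(record: Any) -> list[str]:
    if dataclasses.is_dataclass(record):
        return [f.name for f in dataclasses.fields(record)]
    if isinstance(record, Mapping):
        return list(record.keys())
    raise FormatError(f"unsupported record type {type(record).__name__}")


def _record_values(record: Any) -> dict[str, Any]:
    if dataclasses.is_dataclass(record):
        return dataclasses.asdict(record)
    return dict(record)


def _format_cell(v: Any) -> str:
    if v is None or (isinstance(v, float) and np.isnan(v)):
        return "NA"
    if isinstance(v, (float, np.floating)):
        return f"{v:.6g}"
    if isinstance(v, (tuple, list)):
        return ",".join(_format_cell(x) for x in v)
    return str(v)


def write_results_table(
    records: Sequence[Any],
    path: str | Path,
    *,
    fields: Iterable[str] | None = None,
) -> None:
    """Write homogeneous result records (dataclasses or mappings) as TSV.

    Column order follows the first record's field order; floats are printed
    at 6 significant digits; an empty record list yields a header-only file
    (which requires ``fields``).
    """
    records = list(records)
    if fields is None:
        if not records:
            raise FormatError("empty record list needs an explicit field list")
        fields = _record_fields(records[0])
    fields = list(fields)
    buf = io.StringIO()
    buf.write("\t".join(fields) + "\n")
    for rec in records:
        vals = _record_values(rec)
        if set(_record_fields(rec)) != set(fields):
            raise FormatError("records have differing fields")
        buf.write("\t".join(_format_cell(vals[f]) for f in fields) + "\n")
    Path(path).write_text(buf.getvalue())


def read_results_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", na_values=["NA"])
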