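"""Readers and writers for the tabular formats the pipeline consumes.

Expression matrices arrive as TSV with probes in rows and samples in
columns, either plain or wrapped in GEO series-matrix table markers.
Gene-set collections use GMT (one set per line). Sample metadata and qPCR
Ct tables are plain TSV with named header columns.

Gene symbols are uppercased at ingest; all downstream symbol matching
(modules, gene sets, signatures) is by exact uppercase symbol.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .errors import FormatError, ValidationError

_MISSING_TOKENS = {"", "NA", "N/A", "NAN", "NULL", "NONE"}

_TABLE_BEGIN = "!series_matrix_table_begin"
_TABLE_END = "!series_matrix_table_end"

SYMBOL_HEADER_NAMES = {"gene_symbol", "symbol", "gene", "genesymbol"}


# ---------------------------------------------------------------------------
# Domain containers
# ---------------------------------------------------------------------------

@dataclass
class ExpressionMatrix:
    """Normalized log2-scale expression, probes x samples.

    ``values`` is a float DataFrame indexed by probe id with one column per
    sample; missing entries are NaN. ``gene_symbols`` maps every probe id to
    an uppercase symbol ("" for unannotated probes).
    """

    values: pd.DataFrame
    gene_symbols: pd.Series

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if self.values.index.has_duplicates:
            dup = self.values.index[self.values.index.duplicated()][0]
            raise ValidationError(f"duplicate probe id: {dup!r}")
        if self.values.columns.has_duplicates:
            dup = self.values.columns[self.values.columns.duplicated()][0]
            raise ValidationError(f"duplicate sample id: {dup!r}")
        if not self.gene_symbols.index.equals(self.values.index):
            raise ValidationError("gene_symbols index must equal probe ids")

    @property
    def probe_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def n_probes(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    def probes_for_symbol(self, symbol: str) -> list[str]:
        symbol = symbol.upper()
        return list(self.gene_symbols.index[self.gene_symbols == symbol])

    def symbols(self) -> set[str]:
        """All non-empty symbols present on the matrix."""
        return set(self.gene_symbols[self.gene_symbols != ""].unique())


@dataclass(frozen=True)
class GeneSet:
    term_id: str
    name: str
    members: tuple[str, ...]
    family: str = "default"

    def __post_init__(self) -> None:
        if not self.members:
            raise ValidationError(f"gene set {self.term_id!r} has no members")
        if len(set(self.members)) != len(self.members):
            raise ValidationError(f"gene set {self.term_id!r} has duplicate members")


@dataclass
class GeneSetCollection:
    """A keyed collection of gene sets, each tagged with a family."""

    sets: dict[str, GeneSet] = field(default_factory=dict)

    def add(self, gene_set: GeneSet) -> None:
        self.sets[gene_set.term_id] = gene_set

    def __len__(self) -> int:
        return len(self.sets)

    def __iter__(self):
        return iter(self.sets.values())

    def __getitem__(self, term_id: str) -> GeneSet:
        return self.sets[term_id]

    def families(self) -> set[str]:
        return {s.family for s in self}

    def by_family(self, family: str) -> "GeneSetCollection":
        sub = GeneSetCollection()
        for s in self:
            if s.family == family:
                sub.add(s)
        return sub

    def merged(self, other: "GeneSetCollection") -> "GeneSetCollection":
        out = GeneSetCollection(dict(self.sets))
        for s in other:
            out.add(s)
        return out


METADATA_COLUMNS = ["sample_id", "site", "subgroup", "age",
                    "survival_time", "event", "mib1_class"]

VALID_SITES = {"ST", "PF", "SP", "unknown"}
VALID_MIB1 = {"high", "low", "unknown"}


# ---------------------------------------------------------------------------
# Expression matrix I/O
# ---------------------------------------------------------------------------

def _parse_cell(token: str) -> float:
    token = token.strip()
    if token.upper() in _MISSING_TOKENS:
        return np.nan
    try:
        return float(token)
    except ValueError:
        # non-numeric payloads become flagged-missing rather than an abort
        return np.nan


def read_expression_matrix(path: str | Path,
                           dialect: str = "plain-tsv") -> ExpressionMatrix:
    """Read a probes-x-samples TSV into an :class:`ExpressionMatrix`.

    Parameters
    ----------
    path:
        TSV file: header of sample ids, first column probe ids, optional
        second column of gene symbols (recognized by header name).
    dialect:
        ``"plain-tsv"`` or ``"series-matrix"``.  The series-matrix dialect
        reads only the block between the GEO table-begin/table-end markers
        when they are present.
    """
    if dialect not in ("plain-tsv", "series-matrix"):
        raise ValidationError(f"unknown dialect {dialect!r}")
    path = Path(path)
    lines = path.read_text().splitlines()
    if dialect == "series-matrix":
        lines = _extract_series_matrix_block(lines)
    lines = [ln for ln in lines if ln.strip() != ""]
    if not lines:
        raise FormatError(f"{path}: empty expression file")

    header = lines[0].rstrip("\n").split("\t")
    if len(header) < 2:
        raise FormatError(f"{path}: malformed header (need probe id column "
                          f"plus at least one sample): {lines[0]!r}")
    has_symbol_col = len(header) >= 2 and header[1].strip().lower() in SYMBOL_HEADER_NAMES
    first_data_col = 2 if has_symbol_col else 1
    sample_ids = [h.strip().strip('"') for h in header[first_data_col:]]
    if len(set(sample_ids)) != len(sample_ids):
        seen: set[str] = set()
        dup = next(s for s in sample_ids if s in seen or seen.add(s))
        raise FormatError(f"{path}: duplicate sample id in header: {dup!r}")

    probe_ids: list[str] = []
    symbols: list[str] = []
    rows: list[list[float]] = []
    ncols = len(header)
    for i, line in enumerate(lines[1:], start=2):
        fields = line.rstrip("\n").split("\t")
        if len(fields) != ncols:
            raise FormatError(f"{path}: ragged row at line {i}: expected "
                              f"{ncols} fields, got {len(fields)}")
        probe_ids.append(fields[0].strip().strip('"'))
        symbols.append(fields[1].strip().strip('"').upper() if has_symbol_col else "")
        rows.append([_parse_cell(c) for c in fields[first_data_col:]])

    if len(set(probe_ids)) != len(probe_ids):
        seen = set()
        dup = next(p for p in probe_ids if p in seen or seen.add(p))
        raise FormatError(f"{path}: duplicate probe id: {dup!r}")

    values = pd.DataFrame(rows, index=pd.Index(probe_ids, name="probe_id"),
                          columns=sample_ids, dtype=float)
    gene_symbols = pd.Series(symbols, index=values.index, name="gene_symbol")
    return ExpressionMatrix(values=values, gene_symbols=gene_symbols)


def _extract_series_matrix_block(lines: list[str]) -> list[str]:
    lowered = [ln.strip().lower() for ln in lines]
    if _TABLE_BEGIN in lowered:
        start = lowered.index(_TABLE_BEGIN) + 1
        end = lowered.index(_TABLE_END) if _TABLE_END in lowered else len(lines)
        return lines[start:end]
    # no markers: fall back to skipping "!" annotation lines
    return [ln for ln in lines if not ln.startswith("!")]


def write_expression_matrix(matrix: ExpressionMatrix, path: str | Path) -> None:
    """Write a matrix back to plain TSV (probe_id, gene_symbol, samples...)."""
    path = Path(path)
    with path.open("w") as fh:
        fh.write("probe_id\tgene_symbol\t" + "\t".join(matrix.sample_ids) + "\n")
        for probe in matrix.probe_ids:
            row = matrix.values.loc[probe]
            cells = ["NA" if not np.isfinite(v) else repr(float(v)) for v in row]
            fh.write(f"{probe}\t{matrix.gene_symbols[probe]}\t" + "\t".join(cells) + "\n")


# ---------------------------------------------------------------------------
# Gene sets (GMT)
# ---------------------------------------------------------------------------

def read_gene_sets(path: str | Path, family: str | None = None) -> GeneSetCollection:
    """Read a GMT file: ``term_id TAB description TAB member1 TAB ...``.

    Duplicate members within a line are collapsed (first occurrence kept);
    a line with no members is a format error. ``family`` defaults to the
    file stem.
    """
    path = Path(path)
    family = family if family is not None else path.stem
    collection = GeneSetCollection()
    for i, line in enumerate(path.read_text().splitlines(), start=1):
        if line.strip() == "":
            continue
        fields = line.rstrip("\n").split("\t")
        if len(fields) < 3:
            raise FormatError(f"{path}: GMT line {i} has fewer than 3 fields")
        term_id, name = fields[0].strip(), fields[1].strip()
        members: list[str] = []
        seen: set[str] = set()
        for m in fields[2:]:
            m = m.strip().upper()
            if m and m not in seen:
                seen.add(m)
                members.append(m)
        if not members:
            raise FormatError(f"{path}: GMT line {i} ({term_id}) has no members")
        collection.add(GeneSet(term_id=term_id, name=name,
                               members=tuple(members), family=family))
    return collection


def write_gene_sets(collection: GeneSetCollection, path: str | Path) -> None:
    with Path(path).open("w") as fh:
        for s in collection:
            fh.write(s.term_id + "\t" + s.name + "\t" + "\t".join(s.members) + "\n")


# ---------------------------------------------------------------------------
# Sample metadata
# ---------------------------------------------------------------------------

def read_sample_metadata(path: str | Path) -> pd.DataFrame:
    """Read the per-sample clinical table.

    Only ``sample_id`` is mandatory.  Missing optional columns yield
    "unknown" (site, mib1_class), NaN (age, survival_time) or <NA> (event);
    ``event`` accepts 0/1/TRUE/FALSE.
    """
    path = Path(path)
    df = pd.read_csv(path, sep="\t", dtype=str)
    df.columns = [c.strip().lower() for c in df.columns]
    if "sample_id" not in df.columns:
        raise FormatError(f"{path}: metadata must have a sample_id column")
    out = pd.DataFrame({"sample_id": df["sample_id"].astype(str)})
    out["site"] = (df["site"].fillna("unknown") if "site" in df.columns
                   else "unknown")
    out["subgroup"] = (df["subgroup"].fillna("unknown") if "subgroup" in df.columns
                       else "unknown")
    out["age"] = pd.to_numeric(df["age"], errors="coerce") if "age" in df.columns else np.nan
    out["survival_time"] = (pd.to_numeric(df["survival_time"], errors="coerce")
                            if "survival_time" in df.columns else np.nan)
    if "event" in df.columns:
        out["event"] = df["event"].map(_parse_event)
    else:
        out["event"] = pd.array([pd.NA] * len(df), dtype="Int64")
    out["mib1_class"] = (df["mib1_class"].fillna("unknown").str.lower()
                         if "mib1_class" in df.columns else "unknown")

    bad_site = ~out["site"].isin(VALID_SITES)
    if bad_site.any():
        out.loc[bad_site, "site"] = "unknown"
    if not out["mib1_class"].isin(VALID_MIB1).all():
        bad = out.loc[~out["mib1_class"].isin(VALID_MIB1), "mib1_class"].iloc[0]
        raise ValidationError(f"{path}: invalid mib1_class value {bad!r}")
    if (out["survival_time"].dropna() < 0).any():
        raise ValidationError(f"{path}: negative survival_time")
    if out["sample_id"].duplicated().any():
        dup = out.loc[out["sample_id"].duplicated(), "sample_id"].iloc[0]
        raise ValidationError(f"{path}: duplicate sample id {dup!r}")
    out["event"] = out["event"].astype("Int64")
    return out.set_index("sample_id", drop=False)


def _parse_event(token) -> object:
    if pd.isna(token):
        return pd.NA
    t = str(token).strip().upper()
    if t in ("1", "TRUE"):
        return 1
    if t in ("0", "FALSE"):
        return 0
    if t in _MISSING_TOKENS:
        return pd.NA
    raise ValidationError(f"cannot parse event flag {token!r}")


# ---------------------------------------------------------------------------
# qPCR Ct table
# ---------------------------------------------------------------------------

QPCR_COLUMNS = ["sample_id", "group", "target", "ct_target", "ct_actb", "ct_gapdh"]


def read_qpcr_table(path: str | Path) -> pd.DataFrame:
    """Read a qPCR Ct table with ACTB and GAPDH housekeeping columns.

    All three Ct columns must be finite and within (0, 45] on every row.
    """
    path = Path(path)
    df = pd.read_csv(path, sep="\t")
    df.columns = [c.strip().lower() for c in df.columns]
    missing = [c for c in QPCR_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: qPCR table missing columns {missing}")
    df = df[QPCR_COLUMNS].copy()
    df["target"] = df["target"].astype(str).str.upper()
    for col in ("ct_target", "ct_actb", "ct_gapdh"):
        vals = pd.to_numeric(df[col], errors="coerce")
        bad = ~np.isfinite(vals) | (vals <= 0) | (vals > 45)
        if bad.any():
            sample = df.loc[bad, "sample_id"].iloc[0]
            raise ValidationError(
                f"{path}: invalid {col} for sample {sample!r} "
                f"(must be finite and in (0, 45])")
        df[col] = vals
    return df


def write_tsv(df: pd.DataFrame, path: str | Path, float_format: str = "%.10g") -> None:
    """Write a pipeline output table with a header row, no index."""
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, sep="\t", index=False, float_format=float_format)
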