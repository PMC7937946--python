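"""Readers, writers and container types for the pipeline's external formats.

Counts travel as tab-separated gene × sample tables (genes in rows, header
row of sample identifiers, first column of gene identifiers).  Gene sets use
the GMT convention (name TAB description TAB member genes).  Sample metadata
and clinical tables are plain TSV.  Gene identifiers are opaque,
case-sensitive strings; any mapping between identifier schemes is the
caller's responsibility.
"""

from __future__ import annotations

import hashlib
import json
import logging
import warnings
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

ENDOTYPE_LABELS = ("A", "B", "other")
ANCA_LEVELS = ("PR3", "MPO", "PR3+MPO", "NEG", "unknown")


class FormatError(ValueError):
    """A file does not conform to its declared dialect."""


class IdentifierError(ValueError):
    """Duplicate or otherwise invalid gene/sample identifiers."""


class PackagingError(RuntimeError):
    """A packaged data file is missing or has been altered."""


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------


@dataclass
class CountMatrix:
    """Raw gene × sample read counts.

    Parameters
    ----------
    gene_ids, sample_ids
        Ordered, unique identifiers.
    counts
        Non-negative integer array of shape ``(n_genes, n_samples)``.
    """

    gene_ids: list[str]
    sample_ids: list[str]
    counts: np.ndarray

    def __post_init__(self) -> None:
        self.gene_ids = list(map(str, self.gene_ids))
        self.sample_ids = list(map(str, self.sample_ids))
        self.counts = np.asarray(self.counts)
        if len(set(self.gene_ids)) != len(self.gene_ids):
            raise IdentifierError("duplicate gene identifiers")
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise IdentifierError("duplicate sample identifiers")
        if self.counts.shape != (len(self.gene_ids), len(self.sample_ids)):
            raise FormatError(
                f"count array shape {self.counts.shape} does not match "
                f"{len(self.gene_ids)} genes x {len(self.sample_ids)} samples"
            )
        if len(self.gene_ids) < 2 or len(self.sample_ids) < 2:
            raise FormatError("a count matrix needs at least 2 genes and 2 samples")
        if not np.issubdtype(self.counts.dtype, np.integer):
            if not np.all(np.isfinite(self.counts)) or np.any(self.counts != np.round(self.counts)):
                raise FormatError("counts must be finite integers")
            self.counts = self.counts.astype(np.int64)
        if np.any(self.counts < 0):
            raise FormatError("counts must be non-negative")

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=self.gene_ids, columns=self.sample_ids)

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "CountMatrix":
        return cls(list(df.index), list(df.columns), df.to_numpy())

    def subset_genes(self, gene_ids: Sequence[str]) -> "CountMatrix":
        keep = [g for g in self.gene_ids if g in set(gene_ids)]
        idx = [self.gene_ids.index(g) for g in keep]
        return CountMatrix(keep, list(self.sample_ids), self.counts[idx, :])

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, CountMatrix):
            return NotImplemented
        return (
            self.gene_ids == other.gene_ids
            and self.sample_ids == other.sample_ids
            and np.array_equal(self.counts, other.counts)
        )


@dataclass
class GeneSet:
    name: str
    description: str
    gene_ids: frozenset[str]


@dataclass
class GeneSetCollection:
    """An ordered collection of named gene sets (GMT contents)."""

    sets: list[GeneSet] = field(default_factory=list)

    def __post_init__(self) -> None:
        names = [s.name for s in self.sets]
        if len(set(names)) != len(names):
            raise IdentifierError("duplicate gene-set names")
        for s in self.sets:
            if not s.gene_ids:
                raise FormatError(f"gene set {s.name!r} is empty")

    def __len__(self) -> int:
        return len(self.sets)

    def __iter__(self):
        return iter(self.sets)

    def __getitem__(self, name: str) -> GeneSet:
        for s in self.sets:
            if s.name == name:
                return s
        raise KeyError(name)

    def names(self) -> list[str]:
        return [s.name for s in self.sets]

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, GeneSetCollection):
            return NotImplemented
        return [(s.name, s.description, s.gene_ids) for s in self.sets] == [
            (s.name, s.description, s.gene_ids) for s in other.sets
        ]


# ---------------------------------------------------------------------------
# counts TSV
# ---------------------------------------------------------------------------


def read_counts(path: str | Path) -> CountMatrix:
    """Read a genes-in-rows count TSV into a :class:`CountMatrix`.

    The first column holds gene identifiers, the header row sample
    identifiers.  Cells must be non-negative integers; offending cells are
    reported by row and column.
    """
    df = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    if df.index.has_duplicates:
        dup = df.index[df.index.duplicated()][0]
        raise IdentifierError(f"duplicate gene id {dup!r} in {path}")
    if df.columns.has_duplicates:
        dup = df.columns[df.columns.duplicated()][0]
        raise IdentifierError(f"duplicate sample id {dup!r} in {path}")
    values = np.empty(df.shape, dtype=np.int64)
    for j, col in enumerate(df.columns):
        converted = pd.to_numeric(df[col], errors="coerce")
        bad = converted.isna() | (converted < 0) | (converted != np.floor(converted))
        if bad.any():
            row = df.index[bad.to_numpy()][0]
            raise FormatError(
                f"non-integer or negative count at gene {row!r}, sample {col!r} in {path}"
            )
        values[:, j] = converted.to_numpy(dtype=np.int64)
    return CountMatrix(list(df.index.astype(str)), list(df.columns.astype(str)), values)


def write_counts(cm: CountMatrix, path: str | Path) -> None:
    """Write a count matrix in the genes-in-rows TSV dialect."""
    df = cm.to_frame()
    df.index.name = "gene_id"
    df.to_csv(path, sep="\t")


# ---------------------------------------------------------------------------
# expression (real-valued) TSV — shared by VST output and general tables
# ---------------------------------------------------------------------------


def read_expression(path: str | Path) -> pd.DataFrame:
    """Read a real-valued gene × sample TSV (e.g. a VST matrix dump)."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.index.has_duplicates or df.columns.has_duplicates:
        raise IdentifierError(f"duplicate identifiers in {path}")
    return df


def write_expression(df: pd.DataFrame, path: str | Path) -> None:
    df = df.copy()
    df.index.name = "gene_id"
    df.to_csv(path, sep="\t", float_format="%.10g")


# ---------------------------------------------------------------------------
# GMT gene sets
# ---------------------------------------------------------------------------


def read_gmt(path: str | Path) -> GeneSetCollection:
    """Parse a GMT file, one gene set per line.

    Duplicate genes within a line are collapsed with a warning; a line with
    fewer than three fields is a format error reported with its line number.
    """
    sets: list[GeneSet] = []
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise FormatError(f"{path}:{lineno}: GMT line has fewer than 3 fields")
            name, desc, *genes = fields
            genes = [g for g in genes if g]
            if len(set(genes)) != len(genes):
                warnings.warn(
                    f"{path}:{lineno}: duplicate gene ids in set {name!r} collapsed",
                    stacklevel=2,
                )
            sets.append(GeneSet(name, desc, frozenset(genes)))
    return GeneSetCollection(sets)


def write_gmt(collection: GeneSetCollection, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for s in collection:
            fh.write("\t".join([s.name, s.description, *sorted(s.gene_ids)]) + "\n")


def read_gene_list(path: str | Path) -> list[str]:
    """Read a one-identifier-per-line gene list (blank lines, '#' comments skipped)."""
    out: list[str] = []
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            token = line.strip()
            if token and not token.startswith("#"):
                out.append(token)
    return out


# ---------------------------------------------------------------------------
# sample metadata
# ---------------------------------------------------------------------------


def read_samples(path: str | Path) -> pd.DataFrame:
    """Read a sample metadata TSV (sample_id plus categorical columns).

    Returns a DataFrame indexed by ``sample_id``; the index must be unique.
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    if "sample_id" not in df.columns:
        raise FormatError(f"{path}: sample table needs a 'sample_id' column")
    df = df.set_index("sample_id")
    if df.index.has_duplicates:
        raise IdentifierError(f"duplicate sample_id in {path}")
    return df


def write_samples(df: pd.DataFrame, path: str | Path) -> None:
    out = df.copy()
    out.index.name = "sample_id"
    out.to_csv(path, sep="\t")


def check_samples_match(cm: CountMatrix, samples: pd.DataFrame) -> None:
    missing = set(cm.sample_ids) - set(samples.index)
    if missing:
        raise IdentifierError(f"samples missing from metadata: {sorted(missing)}")


# ---------------------------------------------------------------------------
# packaged clinical fixtures
# ---------------------------------------------------------------------------

_FIXTURES = {
    "pediatric_cohort1": "clinical_pediatric_cohort1.tsv",
    "adult": "clinical_adult.tsv",
}


def _data_path(name: str) -> Path:
    ref = resources.files("endoseq.data").joinpath(name)
    with resources.as_file(ref) as p:
        return Path(p)


def load_clinical_fixture(cohort: str = "pediatric_cohort1") -> pd.DataFrame:
    """Load a packaged clinical table (pediatric discovery cohort or adults).

    The files are verified against stored SHA-256 digests so the packaged
    tables cannot drift silently.  Columns: patient_id (index), endotype,
    ema_class, anca, timepoint, sex, organ_systems (comma-joined tokens),
    activity_score (PVAS for children, BVAS for adults).
    """
    if cohort not in _FIXTURES:
        raise ValueError(f"unknown cohort {cohort!r}; choose from {sorted(_FIXTURES)}")
    fname = _FIXTURES[cohort]
    try:
        path = _data_path(fname)
        raw = path.read_bytes()
    except FileNotFoundError as exc:  # pragma: no cover - packaging failure
        raise PackagingError(f"packaged fixture {fname} is missing") from exc
    digests = json.loads(_data_path("fixture_checksums.json").read_text())
    observed = hashlib.sha256(raw).hexdigest()
    if observed != digests[fname]:
        raise PackagingError(f"fixture {fname} checksum mismatch: {observed}")
    df = pd.read_csv(path, sep="\t", dtype={"activity_score": int})
    return validate_clinical(df)


def validate_clinical(df: pd.DataFrame) -> pd.DataFrame:
    """Validate a clinical table against its invariants and index by patient."""
    required = {"patient_id", "endotype", "ema_class", "anca", "timepoint", "sex",
                "organ_systems", "activity_score"}
    missing = required - set(df.columns)
    if missing:
        raise FormatError(f"clinical table missing columns {sorted(missing)}")
    if df["patient_id"].duplicated().any():
        raise IdentifierError("duplicate patient_id in clinical table")
    bad = set(df["endotype"]) - set(ENDOTYPE_LABELS)
    if bad:
        raise FormatError(f"unknown endotype labels {sorted(bad)}")
    bad = set(df["anca"]) - set(ANCA_LEVELS)
    if bad:
        raise FormatError(f"unknown ANCA levels {sorted(bad)}")
    if (df["activity_score"].astype(int) < 0).any():
        raise FormatError("activity_score must be non-negative")
    return df.set_index("patient_id")


def default_globin_genes() -> list[str]:
    """Hemoglobin gene symbols removed before normalization (configurable)."""
    return read_gene_list(_data_path("globin_genes.txt"))


def default_anchor_genes() -> list[str]:
    """Neutrophil-degranulation marker genes used to orient the A/B labels."""
    return read_gene_list(_data_path("neutrophil_anchor_genes.txt"))
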