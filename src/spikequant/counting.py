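"""k-mer classification of reads and read-count table handling.

This is a desk-scale stand-in for a production mNGS chain (host alignment
and filtering, then taxonomic annotation against a reference database plus
the IS reference set). Reads are classified by exact k-mer lookup against
an index built over the IS panel, fixture genomes and a host fixture;
host-matching reads are filtered first, mirroring the usual
filter-then-annotate order. Count tables produced by an external pipeline
can be ingested instead via :func:`ingest_counts`.
"""
from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.SeqIO.QualityIO import FastqGeneralIterator

from .errors import ValidationError
from .panel import ISPanel, reverse_complement

logger = logging.getLogger(__name__)

CATEGORY_TYPES = ("host", "is", "taxon", "contaminant", "unassigned")


# ---------------------------------------------------------------------------
# Read-count table
# ---------------------------------------------------------------------------

@dataclass
class ReadCountTable:
    """Reads per category for one sequencing run.

    ``frame`` has columns ``category`` (unique), ``category_type`` (one of
    host / is / taxon / contaminant / unassigned) and ``reads`` (>= 0;
    real-valued tables arise from the simulator's exact-expectation mode).
    """

    frame: pd.DataFrame

    def __post_init__(self) -> None:
        required = {"category", "category_type", "reads"}
        missing = required - set(self.frame.columns)
        if missing:
            raise ValidationError(f"count table missing columns: {sorted(missing)}")
        self.frame = self.frame.loc[:, ["category", "category_type", "reads"]].reset_index(drop=True)
        if self.frame["category"].duplicated().any():
            dups = self.frame.loc[self.frame["category"].duplicated(), "category"].tolist()
            raise ValidationError(f"duplicate categories in count table: {dups}")
        bad_types = set(self.frame["category_type"]) - set(CATEGORY_TYPES)
        if bad_types:
            raise ValidationError(f"unknown category_type values: {sorted(bad_types)}")
        reads = pd.to_numeric(self.frame["reads"], errors="coerce")
        if reads.isna().any() or (reads < 0).any() or not np.isfinite(reads).all():
            raise ValidationError("reads must be finite and non-negative")
        self.frame["reads"] = reads.astype(float)

    @property
    def total_reads(self) -> float:
        return float(self.frame["reads"].sum())

    def reads_for(self, category: str) -> float:
        sel = self.frame.loc[self.frame["category"] == category, "reads"]
        if sel.empty:
            raise ValidationError(f"category not in count table: {category}")
        return float(sel.iloc[0])

    def has_category(self, category: str) -> bool:
        return bool((self.frame["category"] == category).any())

    def by_type(self, category_type: str) -> pd.DataFrame:
        return self.frame.loc[self.frame["category_type"] == category_type].reset_index(drop=True)

    def integer_counts(self) -> np.ndarray:
        """Counts as int64, rejecting fractional (expectation-mode) tables."""
        reads = self.frame["reads"].to_numpy()
        rounded = np.rint(reads)
        if not np.allclose(reads, rounded, atol=1e-9):
            raise ValidationError("count table holds fractional reads; integer counts required")
        return rounded.astype(np.int64)

    def to_tsv(self, path: str | Path) -> Path:
        path = Path(path)
        out = self.frame.copy()
        reads = out["reads"].to_numpy()
        if np.allclose(reads, np.rint(reads), atol=1e-9):
            out["reads"] = np.rint(reads).astype(np.int64)
        out.to_csv(path, sep="\t", index=False)
        return path

    @classmethod
    def from_rows(cls, rows: Iterable[tuple[str, str, float]]) -> "ReadCountTable":
        return cls(pd.DataFrame(rows, columns=["category", "category_type", "reads"]))


def ingest_counts(path: str | Path, panel: ISPanel | None = None) -> ReadCountTable:
    """Read and validate a count table TSV produced here or by an external
    pipeline. If ``panel`` is given, every panel molecule must be present as
    an ``is`` row (the error names the missing ids)."""
    path = Path(path)
    try:
        frame = pd.read_csv(path, sep="\t")
    except Exception as exc:  # malformed TSV
        raise ValidationError(f"cannot parse count table {path}: {exc}") from exc
    table = ReadCountTable(frame)
    if panel is not None:
        is_rows = set(table.by_type("is")["category"])
        missing = [m for m in panel.molecule_ids if m not in is_rows]
        if missing:
            raise ValidationError(f"count table is missing IS molecule rows: {missing}")
    return table


# ---------------------------------------------------------------------------
# k-mer index and classification
# ---------------------------------------------------------------------------

@dataclass
class KmerIndex:
    """Exact k-mer lookup: k-mer -> source id, with multi-source k-mers
    flagged ambiguous. Both strands are indexed, so reads never need to be
    reverse-complemented before lookup."""

    k: int
    mapping: dict[str, str] = field(default_factory=dict)
    ambiguous: set[str] = field(default_factory=set)
    source_types: dict[str, str] = field(default_factory=dict)

    @property
    def sources(self) -> list[str]:
        return list(self.source_types)


def build_index(
    sources: Sequence[tuple[str, str, str]],
    k: int = 25,
) -> KmerIndex:
    """Build a :class:`KmerIndex` from ``(source_id, category_type, sequence)``
    triples. k must not exceed the shortest source."""
    if not sources:
        raise ValidationError("no sources given")
    index = KmerIndex(k=k)
    for source_id, category_type, seq in sources:
        if source_id in index.source_types:
            raise ValidationError(f"duplicate source id: {source_id}")
        if category_type not in CATEGORY_TYPES:
            raise ValidationError(f"unknown category_type: {category_type}")
        seq = seq.upper()
        if len(seq) < k:
            raise ValidationError(f"source {source_id} shorter than k={k}")
        index.source_types[source_id] = category_type
        rc = reverse_complement(seq) if set(seq) <= set("ACGT") else None
        n = len(seq)
        for i in range(n - k + 1):
            fwd = seq[i : i + k]
            if not set(fwd) <= set("ACGT"):
                continue
            rev = rc[n - k - i : n - i] if rc is not None else reverse_complement(fwd)
            for kmer in (fwd, rev):
                if kmer in index.ambiguous:
                    continue
                owner = index.mapping.get(kmer)
                if owner is None:
                    index.mapping[kmer] = source_id
                elif owner != source_id:
                    del index.mapping[kmer]
                    index.ambiguous.add(kmer)
    return index


def index_from_fastas(
    fastas: Sequence[tuple[str | Path, str]],
    k: int = 25,
) -> KmerIndex:
    """Build an index from ``(fasta_path, category_type)`` pairs; every record
    id becomes a source."""
    sources = []
    for path, category_type in fastas:
        for record in SeqIO.parse(str(path), "fasta"):
            sources.append((record.id, category_type, str(record.seq)))
    return build_index(sources, k=k)


def classify_read(read: str, index: KmerIndex) -> str:
    """Classify one read.

    Any k-mer mapping uniquely to a host source short-circuits to that host
    source (host filtering runs before annotation). Otherwise the
    unique-mapping k-mers vote and the majority source wins; no unique hits
    or a tie yields ``unassigned``.
    """
    k = index.k
    read = read.upper()
    if len(read) < k:
        return "unassigned"
    votes: Counter[str] = Counter()
    for i in range(len(read) - k + 1):
        source = index.mapping.get(read[i : i + k])
        if source is not None:
            if index.source_types[source] == "host":
                return source
            votes[source] += 1
    if not votes:
        return "unassigned"
    ranked = votes.most_common(2)
    if len(ranked) > 1 and ranked[0][1] == ranked[1][1]:
        return "unassigned"
    return ranked[0][0]


def count_reads(fastq: str | Path, index: KmerIndex) -> ReadCountTable:
    """Classify every read of a FASTQ file into a count table.

    The table always contains one row per index source plus ``unassigned``,
    and conserves the input read count.
    """
    counts: Counter[str] = Counter()
    n_records = 0
    try:
        with open(fastq) as handle:
            for n_records, (_title, seq, _qual) in enumerate(FastqGeneralIterator(handle), start=1):
                counts[classify_read(seq, index)] += 1
    except ValueError as exc:
        raise ValidationError(f"malformed FASTQ record near record {n_records + 1}: {exc}") from exc
    rows = [
        (source, category_type, float(counts.get(source, 0)))
        for source, category_type in index.source_types.items()
    ]
    rows.append(("unassigned", "unassigned", float(counts.get("unassigned", 0))))
    return ReadCountTable.from_rows(rows)
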