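"""HERV proviral locus catalog: loading, validation, windowing and export.

The unit of analysis is the proviral locus — a genomic HERV insertion with
(near-)full-length retroviral gene structure.  A catalog pairs a multi-record
FASTA of locus sequences with a tab-delimited table of genomic placements
(``locus_id  chrom  start  end  strand  family``).  Coordinates are 0-based
half-open (BED convention) internally and in every emitted file; 1-based
tables are converted on load via ``one_based=True``.

Windowing partitions a locus into sequential, non-overlapping, fixed-length
windows; trailing bases shorter than one window belong to no window, so a
locus needs ``min_usable_windows × window_length`` bp (450 bp at defaults)
to ever be callable.
"""

from __future__ import annotations

import sys
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

__all__ = [
    "HervLocus",
    "HervCatalog",
    "WindowSpec",
    "CatalogError",
    "load_catalog",
    "write_catalog",
    "window_partition",
    "catalog_to_bed",
]

TABLE_COLUMNS = ("locus_id", "chrom", "start", "end", "strand", "family")

_VALID_STRANDS = frozenset({"+", "-", "."})


class CatalogError(ValueError):
    """Raised when a catalog violates a structural invariant."""


@dataclass(frozen=True)
class HervLocus:
    """One proviral locus: identity, genomic placement, family and sequence.

    ``start``/``end`` are 0-based half-open genomic coordinates.  ``family``
    is the canonical HERV group label and may be empty — family annotations
    are not guaranteed by every catalog.
    """

    locus_id: str
    chrom: str
    start: int
    end: int
    strand: str
    family: str
    sequence: str

    def __post_init__(self) -> None:
        if not self.locus_id:
            raise CatalogError("locus_id must be non-empty")
        if self.end <= self.start:
            raise CatalogError(
                f"locus {self.locus_id!r}: end ({self.end}) must exceed start ({self.start})"
            )
        if self.strand not in _VALID_STRANDS:
            raise CatalogError(
                f"locus {self.locus_id!r}: strand must be one of +, -, . (got {self.strand!r})"
            )
        if self.end - self.start != len(self.sequence):
            raise CatalogError(
                f"locus {self.locus_id!r}: span {self.end - self.start} bp does not match "
                f"sequence length {len(self.sequence)} bp"
            )

    @property
    def length(self) -> int:
        return len(self.sequence)


@dataclass
class HervCatalog:
    """Ordered collection of loci with an id-keyed sequence store."""

    loci: list[HervLocus] = field(default_factory=list)

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for locus in self.loci:
            if locus.locus_id in seen:
                raise CatalogError(f"duplicate locus_id {locus.locus_id!r}")
            seen.add(locus.locus_id)
        self._by_id = {locus.locus_id: locus for locus in self.loci}

    def __len__(self) -> int:
        return len(self.loci)

    def __iter__(self) -> Iterator[HervLocus]:
        return iter(self.loci)

    def __contains__(self, locus_id: str) -> bool:
        return locus_id in self._by_id

    def __getitem__(self, locus_id: str) -> HervLocus:
        return self._by_id[locus_id]

    @property
    def locus_ids(self) -> list[str]:
        return [locus.locus_id for locus in self.loci]

    def chromosomes(self) -> list[str]:
        """Distinct chromosome names in catalog order of first appearance."""
        out: list[str] = []
        seen: set[str] = set()
        for locus in self.loci:
            if locus.chrom not in seen:
                seen.add(locus.chrom)
                out.append(locus.chrom)
        return out


@dataclass(frozen=True)
class WindowSpec:
    """One fixed-length window of a locus; offsets are locus-relative, half-open."""

    locus_id: str
    index: int
    start_offset: int
    end_offset: int

    @property
    def length(self) -> int:
        return self.end_offset - self.start_offset


def window_partition(locus_length: int, window_length: int, locus_id: str = "") -> list[WindowSpec]:
    """Partition ``[0, locus_length)`` into full non-overlapping windows.

    Returns exactly ``floor(locus_length / window_length)`` windows; trailing
    remainder bases belong to no window.  Window *i* covers
    ``[i*window_length, (i+1)*window_length)``.
    """
    if window_length <= 0:
        raise ValueError(f"window_length must be positive (got {window_length})")
    if locus_length < 0:
        raise ValueError(f"locus_length must be non-negative (got {locus_length})")
    n = locus_length // window_length
    return [
        WindowSpec(locus_id, i, i * window_length, (i + 1) * window_length)
        for i in range(n)
    ]


def _parse_table(table_path: Path, one_based: bool) -> list[dict]:
    rows: list[dict] = []
    with open(table_path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if tuple(header) != TABLE_COLUMNS:
            raise CatalogError(
                f"locus table header must be {list(TABLE_COLUMNS)} (got {header})"
            )
        for lineno, line in enumerate(fh, start=2):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) != len(TABLE_COLUMNS):
                raise CatalogError(f"{table_path}:{lineno}: expected {len(TABLE_COLUMNS)} columns")
            rec = dict(zip(TABLE_COLUMNS, parts))
            start = int(rec["start"])
            end = int(rec["end"])
            if one_based:
                start -= 1  # 1-based inclusive start -> 0-based half-open
            rec["start"], rec["end"] = start, end
            rows.append(rec)
    return rows


def load_catalog(
    fasta_path: str | Path,
    loci_table_path: str | Path,
    one_based: bool = False,
    log: bool = True,
) -> HervCatalog:
    """Load and cross-validate a locus catalog from FASTA + TSV.

    Every FASTA record must have a table row and vice versa; a mismatch is a
    hard error naming the orphan ids.  Rows with ``end <= start`` or spans
    that disagree with the sequence length are rejected.
    """
    fasta_path = Path(fasta_path)
    loci_table_path = Path(loci_table_path)
    sequences = {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(fasta_path), "fasta")}
    rows = _parse_table(loci_table_path, one_based)

    table_ids = [r["locus_id"] for r in rows]
    if len(set(table_ids)) != len(table_ids):
        dupes = sorted({i for i in table_ids if table_ids.count(i) > 1})
        raise CatalogError(f"duplicate locus_id in table: {dupes}")
    orphan_seqs = sorted(set(sequences) - set(table_ids))
    orphan_rows = sorted(set(table_ids) - set(sequences))
    if orphan_seqs or orphan_rows:
        raise CatalogError(
            "catalog sequence/table mismatch; "
            f"FASTA-only ids: {orphan_seqs}; table-only ids: {orphan_rows}"
        )

    loci = [
        HervLocus(
            locus_id=r["locus_id"],
            chrom=r["chrom"],
            start=r["start"],
            end=r["end"],
            strand=r["strand"],
            family=r["family"],
            sequence=sequences[r["locus_id"]],
        )
        for r in rows
    ]
    catalog = HervCatalog(loci)
    if log:
        print(f"loaded {len(catalog)} HERV loci from {fasta_path.name}", file=sys.stderr)
    return catalog


def write_catalog(catalog: HervCatalog, fasta_path: str | Path, loci_table_path: str | Path) -> None:
    """Write a catalog back to FASTA + TSV (0-based half-open coordinates)."""
    records = [
        SeqRecord(Seq(locus.sequence), id=locus.locus_id, description="")
        for locus in catalog
    ]
    SeqIO.write(records, str(fasta_path), "fasta")
    with open(loci_table_path, "w") as fh:
        fh.write("\t".join(TABLE_COLUMNS) + "\n")
        for locus in catalog:
            fh.write(
                f"{locus.locus_id}\t{locus.chrom}\t{locus.start}\t{locus.end}"
                f"\t{locus.strand}\t{locus.family}\n"
            )


def catalog_to_bed(catalog_or_loci: HervCatalog | Iterable[HervLocus], path: str | Path | None = None) -> list[str]:
    """BED6 lines for the catalog (score column carries locus length)."""
    lines = [
        f"{locus.chrom}\t{locus.start}\t{locus.end}\t{locus.locus_id}\t{locus.length}\t{locus.strand}"
        for locus in catalog_or_loci
    ]
    if path is not None:
        Path(path).write_text("\n".join(lines) + ("\n" if lines else ""))
    return lines
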