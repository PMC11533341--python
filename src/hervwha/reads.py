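"""Read selection: cell-barcode extraction and alignment-identity filtering.

Single-cell alignments carry a cell barcode in the standard ``CB`` tag; one
cell cluster (e.g. CD14+ monocytes) is selected by intersecting that tag
with a plain-text barcode list.  Alignments to the locus reference are then
filtered by percent identity, computed from the SAM edit-distance tag
(``NM``) over the reference-consuming aligned length, so insertions and
deletions count as edits and soft-clipped bases are excluded.  The identity
threshold is inclusive: a 100-bp read with exactly one mismatch (99.0%)
passes at the default 99% cutoff.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import pysam

__all__ = [
    "BarcodeList",
    "AlignedRead",
    "FilterReport",
    "percent_identity",
    "filter_alignments",
    "extract_reads_by_barcode",
    "extract_bam_by_barcode",
    "read_sam",
    "write_sam",
]

BARCODE_TAG = "CB"
EDIT_DISTANCE_TAG = "NM"


@dataclass(frozen=True)
class BarcodeList:
    """Set of cell barcodes defining one cell cluster."""

    barcodes: frozenset[str]
    cluster_label: str = ""

    def __post_init__(self) -> None:
        if any(not b for b in self.barcodes):
            raise ValueError("barcodes must be non-empty strings")

    def __contains__(self, barcode: str) -> bool:
        return barcode in self.barcodes

    def __len__(self) -> int:
        return len(self.barcodes)

    @classmethod
    def from_file(cls, path: str | Path, cluster_label: str = "") -> "BarcodeList":
        """One barcode per line; blank lines ignored; duplicates collapsed."""
        with open(path) as fh:
            barcodes = frozenset(line.strip() for line in fh if line.strip())
        return cls(barcodes=barcodes, cluster_label=cluster_label or Path(path).stem)


@dataclass(frozen=True)
class AlignedRead:
    """One mapped read in reference space.

    ``base_calls`` holds the query base at each successive reference position
    from ``ref_start``; ``-`` marks a reference position the query deletes.
    Its length is therefore the reference-consuming aligned length.
    ``edit_distance`` is the NM-style count of mismatches plus indel bases.
    """

    read_id: str
    locus_id: str
    ref_start: int
    base_calls: str
    edit_distance: int
    barcode: str | None = None

    def __post_init__(self) -> None:
        if len(self.base_calls) == 0:
            raise ValueError(f"read {self.read_id!r}: aligned length must be positive")
        if self.edit_distance < 0 or self.edit_distance > len(self.base_calls):
            raise ValueError(
                f"read {self.read_id!r}: edit_distance {self.edit_distance} outside "
                f"[0, {len(self.base_calls)}]"
            )

    @property
    def aligned_length(self) -> int:
        return len(self.base_calls)

    @property
    def ref_end(self) -> int:
        return self.ref_start + self.aligned_length


@dataclass
class FilterReport:
    """Bookkeeping for a filtering pass; kept + dropped + untagged + skipped == total."""

    total: int = 0
    kept: int = 0
    dropped: int = 0
    untagged: int = 0
    skipped: int = 0
    notes: list[str] = field(default_factory=list)

    def as_dict(self) -> dict:
        return {
            "total": self.total,
            "kept": self.kept,
            "dropped": self.dropped,
            "untagged": self.untagged,
            "skipped": self.skipped,
            "notes": list(self.notes),
        }


def percent_identity(read: AlignedRead) -> float:
    """Percent identity = 100 × (aligned_length − edit_distance) / aligned_length."""
    return 100.0 * (read.aligned_length - read.edit_distance) / read.aligned_length


def extract_reads_by_barcode(
    reads: Iterable[AlignedRead], barcodes: BarcodeList
) -> tuple[list[AlignedRead], FilterReport]:
    """Keep exactly the reads whose barcode is in the list; order-preserving.

    Reads without a barcode tag are counted as untagged and dropped.
    """
    report = FilterReport()
    kept: list[AlignedRead] = []
    for read in reads:
        report.total += 1
        if read.barcode is None:
            report.untagged += 1
        elif read.barcode in barcodes:
            report.kept += 1
            kept.append(read)
        else:
            report.dropped += 1
    if report.kept == 0:
        report.notes.append("zero reads kept by barcode filter")
    return kept, report


def filter_alignments(
    reads: Iterable[AlignedRead], min_identity: float = 99.0
) -> tuple[list[AlignedRead], FilterReport]:
    """Retain reads with percent identity ≥ ``min_identity`` (inclusive)."""
    if not (0.0 < min_identity <= 100.0):
        raise ValueError(f"min_identity must be in (0, 100] (got {min_identity})")
    report = FilterReport()
    kept: list[AlignedRead] = []
    for read in reads:
        report.total += 1
        if percent_identity(read) >= min_identity:
            report.kept += 1
            kept.append(read)
        else:
            report.dropped += 1
    return kept, report


def _segment_to_read(seg: pysam.AlignedSegment) -> AlignedRead | None:
    """Convert a mapped primary pysam record; None when NM is missing."""
    if not seg.has_tag(EDIT_DISTANCE_TAG):
        return None
    query = seg.query_sequence or ""
    # Reference-space base calls: '-' where the query deletes a reference base.
    calls: list[str] = []
    for qpos, rpos in seg.get_aligned_pairs(matches_only=False):
        if rpos is None:  # insertion or soft clip: consumes no reference
            continue
        calls.append(query[qpos] if qpos is not None else "-")
    if not calls:
        return None
    barcode = seg.get_tag(BARCODE_TAG) if seg.has_tag(BARCODE_TAG) else None
    return AlignedRead(
        read_id=seg.query_name or "",
        locus_id=seg.reference_name or "",
        ref_start=seg.reference_start,
        base_calls="".join(calls),
        edit_distance=int(seg.get_tag(EDIT_DISTANCE_TAG)),
        barcode=barcode,
    )


def read_sam(path: str | Path, report: FilterReport | None = None) -> list[AlignedRead]:
    """Load mapped primary alignments from SAM/BAM as :class:`AlignedRead`.

    Unmapped, secondary and supplementary records are dropped (each read may
    contribute depth at most once per locus); records lacking an NM tag are
    counted as skipped, never passed silently.
    """
    own_report = report if report is not None else FilterReport()
    reads: list[AlignedRead] = []
    with pysam.AlignmentFile(str(path), check_sq=False) as fh:
        for seg in fh:
            own_report.total += 1
            if seg.is_unmapped or seg.is_secondary or seg.is_supplementary:
                own_report.dropped += 1
                continue
            read = _segment_to_read(seg)
            if read is None:
                own_report.skipped += 1
                continue
            own_report.kept += 1
            reads.append(read)
    if own_report.skipped:
        own_report.notes.append(f"{own_report.skipped} records lacked an NM tag or aligned bases")
    return reads


def write_sam(
    reads: Sequence[AlignedRead],
    path: str | Path,
    reference_lengths: dict[str, int],
) -> None:
    """Write reads as a SAM file against the given reference dictionary.

    Base calls are emitted as-is with deletion positions encoded in the
    CIGAR; mapping quality is fixed at 60 and qualities at Phred 37.
    """
    header = {
        "HD": {"VN": "1.6", "SO": "unknown"},
        "SQ": [{"SN": name, "LN": length} for name, length in reference_lengths.items()],
    }
    with pysam.AlignmentFile(str(path), "w", header=header) as out:
        tid = {name: i for i, name in enumerate(reference_lengths)}
        for read in reads:
            seg = pysam.AlignedSegment(out.header)
            seg.query_name = read.read_id
            seg.reference_id = tid[read.locus_id]
            seg.reference_start = read.ref_start
            seg.mapping_quality = 60
            seq = read.base_calls.replace("-", "")
            seg.query_sequence = seq
            seg.query_qualities = pysam.qualitystring_to_array("F" * len(seq))
            seg.cigartuples = _cigar_from_calls(read.base_calls)
            seg.set_tag(EDIT_DISTANCE_TAG, read.edit_distance, "i")
            if read.barcode is not None:
                seg.set_tag(BARCODE_TAG, read.barcode, "Z")
            out.write(seg)


def _cigar_from_calls(base_calls: str) -> list[tuple[int, int]]:
    """CIGAR (M/D runs) from reference-space base calls."""
    ops: list[tuple[int, int]] = []
    for ch in base_calls:
        op = 2 if ch == "-" else 0  # 0 = M, 2 = D
        if ops and ops[-1][0] == op:
            ops[-1] = (op, ops[-1][1] + 1)
        else:
            ops.append((op, 1))
    return [(op, n) for op, n in ops]


def extract_bam_by_barcode(
    in_path: str | Path,
    barcodes: BarcodeList,
    out_path: str | Path,
) -> FilterReport:
    """File-level barcode extraction: SAM/BAM in, same format records out."""
    report = FilterReport()
    with pysam.AlignmentFile(str(in_path), check_sq=False) as fh:
        mode = "wb" if str(out_path).endswith(".bam") else "w"
        with pysam.AlignmentFile(str(out_path), mode, template=fh) as out:
            for seg in fh:
                report.total += 1
                if not seg.has_tag(BARCODE_TAG):
                    report.untagged += 1
                    continue
                if seg.get_tag(BARCODE_TAG) in barcodes:
                    report.kept += 1
                    out.write(seg)
                else:
                    report.dropped += 1
    if report.kept == 0:
        report.notes.append("zero reads kept by barcode filter")
    return report
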