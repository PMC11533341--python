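"""The WHA core: pileup, window usability/identity, WSS score, locus call.

Window-based HERV alignment (WHA) compares aligned reads to each proviral
locus in sequential, non-overlapping 50-bp windows.  A window is *usable*
when every one of its positions is covered by at least one identity-filtered
read; a usable window *passes* when the majority-base consensus matches the
reference at ≥ 99% of window positions (ties break toward the reference).
The window similarity score (WSS) is the percentage of usable windows that
pass.  A locus is called

* ``positive``  — mean depth over the windowed span ≥ 3, ≥ 9 usable windows,
  and WSS exactly 100% (every usable window passed; integer comparison,
  never a rounded float);
* ``negative``  — any of those thresholds failed;
* ``uncallable`` — the locus is too short to ever host 9 full windows
  (< 450 bp at defaults).

Depth exactly at the minimum satisfies the criterion (the threshold is
inclusive).  "Depth" defaults to mean per-base coverage over the windowed
span ``[0, n_windows × window_length)``; raw read count is available via
``depth_mode="reads"``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Literal, Sequence

import numpy as np

from .catalog import HervCatalog, HervLocus, WindowSpec, window_partition
from .reads import AlignedRead

__all__ = [
    "CallingThresholds",
    "Pileup",
    "WindowResult",
    "LocusScore",
    "SampleCalls",
    "pileup_locus",
    "score_windows",
    "call_locus",
    "score_sample",
    "write_sample_tsv",
    "read_sample_tsv",
    "DEFAULT_THRESHOLDS",
]

_BASES = "ACGTN"
_BASE_INDEX = {b: i for i, b in enumerate(_BASES)}

# byte -> base-count row; unknown symbols count as N, '-' (deletion) as -1
_BYTE_INDEX = np.full(256, _BASE_INDEX["N"], dtype=np.int64)
for _b, _i in _BASE_INDEX.items():
    _BYTE_INDEX[ord(_b)] = _i
    _BYTE_INDEX[ord(_b.lower())] = _i
_BYTE_INDEX[ord("-")] = -1

Call = Literal["positive", "negative", "uncallable"]


@dataclass(frozen=True)
class CallingThresholds:
    """Tunable calling constants.

    Defaults give the 450-bp minimum callable span: 9 usable windows of
    50 bp each, with depth ≥ 3 and a 100% WSS requirement at 99% per-window
    identity.  ``min_alignment_identity`` is the per-read filter applied
    upstream of scoring.
    """

    window_length: int = 50
    min_depth: float = 3.0
    min_usable_windows: int = 9
    required_wss: float = 100.0
    min_alignment_identity: float = 99.0
    window_identity: float = 99.0
    depth_mode: Literal["mean", "reads"] = "mean"

    def __post_init__(self) -> None:
        if self.window_length <= 0 or self.min_usable_windows <= 0:
            raise ValueError("window_length and min_usable_windows must be positive")
        if self.min_depth <= 0 or self.window_identity <= 0 or self.min_alignment_identity <= 0:
            raise ValueError("thresholds must be strictly positive")
        if not (0 < self.required_wss <= 100):
            raise ValueError("required_wss must be in (0, 100]")

    @property
    def min_callable_span(self) -> int:
        """Minimum locus span (bp) that can ever satisfy the window criterion."""
        return self.min_usable_windows * self.window_length


DEFAULT_THRESHOLDS = CallingThresholds()


@dataclass
class Pileup:
    """Per-position depth and base counts over one locus.

    ``base_counts`` is a (5, L) array over A/C/G/T/N; ``depth`` counts reads
    covering each position (deleted positions consume depth but add no base).
    """

    locus_id: str
    depth: np.ndarray
    base_counts: np.ndarray
    n_reads: int
    clipped_reads: int = 0

    @property
    def length(self) -> int:
        return self.depth.shape[0]


def pileup_locus(reads: Iterable[AlignedRead], locus: HervLocus) -> Pileup:
    """Stack identity-filtered reads into per-position depth and base counts.

    Reads extending past the locus end are clipped (counted, not fatal).
    """
    L = locus.length
    depth = np.zeros(L, dtype=np.int64)
    counts = np.zeros((len(_BASES), L), dtype=np.int64)
    n_reads = 0
    clipped = 0
    for read in reads:
        if read.locus_id != locus.locus_id:
            raise ValueError(
                f"read {read.read_id!r} maps to {read.locus_id!r}, not {locus.locus_id!r}"
            )
        n_reads += 1
        start = read.ref_start
        calls = read.base_calls
        if start < 0:
            calls = calls[-start:]
            start = 0
            clipped += 1
        if start + len(calls) > L:
            calls = calls[: max(0, L - start)]
            clipped += 1
        if not calls:
            continue
        end = start + len(calls)
        depth[start:end] += 1
        rows = _BYTE_INDEX[np.frombuffer(calls.encode(), dtype=np.uint8)]
        called = rows >= 0  # '-' consumes depth but contributes no base
        np.add.at(counts, (rows[called], np.arange(start, end)[called]), 1)
    return Pileup(locus.locus_id, depth, counts, n_reads, clipped)


@dataclass(frozen=True)
class WindowResult:
    """Usability and consensus identity of one window."""

    window: WindowSpec
    covered_bases: int
    mean_depth: float
    usable: bool
    identity: float
    passed: bool


def _consensus_matches(pileup: Pileup, locus: HervLocus, start: int, end: int) -> int:
    """Count window positions where the majority base equals the reference.

    Ties break toward the reference base; a position whose reference base is
    among the top-count bases therefore matches.
    """
    counts = pileup.base_counts[:, start:end]
    maxima = counts.max(axis=0)
    matches = 0
    for i, pos in enumerate(range(start, end)):
        ref_base = locus.sequence[pos].upper()
        ref_idx = _BASE_INDEX.get(ref_base, _BASE_INDEX["N"])
        if maxima[i] > 0 and counts[ref_idx, i] == maxima[i]:
            matches += 1
    return matches


def score_windows(
    pileup: Pileup, locus: HervLocus, thresholds: CallingThresholds = DEFAULT_THRESHOLDS
) -> list[WindowResult]:
    """Score every full window of the locus against the reference.

    Identity is always divided by the full window length, so uncovered
    positions can never inflate identity — they void usability instead.
    """
    results: list[WindowResult] = []
    wlen = thresholds.window_length
    for window in window_partition(locus.length, wlen, locus.locus_id):
        seg = pileup.depth[window.start_offset : window.end_offset]
        covered = int((seg > 0).sum())
        usable = covered == wlen
        matches = _consensus_matches(pileup, locus, window.start_offset, window.end_offset)
        identity = 100.0 * matches / wlen
        passed = usable and identity >= thresholds.window_identity
        results.append(
            WindowResult(
                window=window,
                covered_bases=covered,
                mean_depth=float(seg.mean()),
                usable=usable,
                identity=identity,
                passed=passed,
            )
        )
    return results


@dataclass(frozen=True)
class LocusScore:
    """Per-sample WHA result for one locus."""

    locus_id: str
    depth: float
    n_windows: int
    n_usable: int
    n_passed: int
    call: Call

    @property
    def wss(self) -> float:
        """Window similarity score: percent of usable windows that passed."""
        return 100.0 * self.n_passed / self.n_usable if self.n_usable else 0.0


def call_locus(
    window_results: Sequence[WindowResult],
    pileup: Pileup,
    thresholds: CallingThresholds = DEFAULT_THRESHOLDS,
) -> LocusScore:
    """Combine window results into the ternary locus call.

    The 100%-WSS requirement is evaluated as the integer identity
    ``n_passed == n_usable`` (with at least one usable window), never as a
    rounded float comparison.
    """
    n_windows = len(window_results)
    n_usable = sum(1 for w in window_results if w.usable)
    n_passed = sum(1 for w in window_results if w.passed)
    span = n_windows * thresholds.window_length
    if thresholds.depth_mode == "reads":
        depth = float(pileup.n_reads)
    else:
        depth = float(pileup.depth[:span].mean()) if span else 0.0

    if n_windows < thresholds.min_usable_windows:
        call: Call = "uncallable"
    else:
        wss_met = (
            n_usable > 0 and n_passed == n_usable
            if thresholds.required_wss == 100.0
            else n_usable > 0 and 100.0 * n_passed / n_usable >= thresholds.required_wss
        )
        if (
            depth >= thresholds.min_depth
            and n_usable >= thresholds.min_usable_windows
            and wss_met
        ):
            call = "positive"
        else:
            call = "negative"
    return LocusScore(
        locus_id=pileup.locus_id,
        depth=depth,
        n_windows=n_windows,
        n_usable=n_usable,
        n_passed=n_passed,
        call=call,
    )


@dataclass
class SampleCalls:
    """One sample's WHA output: a LocusScore for every catalog locus."""

    sample_id: str
    condition_label: str = ""
    total_reads: int = 0
    scores: dict[str, LocusScore] = field(default_factory=dict)

    @property
    def positive_loci(self) -> set[str]:
        return {lid for lid, s in self.scores.items() if s.call == "positive"}

    def calls_vector(self, locus_order: Sequence[str]) -> list[str]:
        return [self.scores[lid].call for lid in locus_order]


def _group_by_locus(reads: Iterable[AlignedRead]) -> dict[str, list[AlignedRead]]:
    groups: dict[str, list[AlignedRead]] = {}
    for read in reads:
        groups.setdefault(read.locus_id, []).append(read)
    return groups


def score_sample(
    reads: Sequence[AlignedRead],
    catalog: HervCatalog,
    thresholds: CallingThresholds = DEFAULT_THRESHOLDS,
    sample_id: str = "",
    condition_label: str = "",
    replicate_check: bool = False,
) -> SampleCalls:
    """Score every catalog locus for one sample of pre-filtered reads.

    With ``replicate_check`` the whole scoring pass runs twice and the two
    call vectors must be identical — a determinism audit; a mismatch is a
    hard error signalling nondeterminism.
    """
    first = _score_once(reads, catalog, thresholds, sample_id, condition_label)
    if replicate_check:
        second = _score_once(reads, catalog, thresholds, sample_id, condition_label)
        order = catalog.locus_ids
        if first.calls_vector(order) != second.calls_vector(order) or first.scores != second.scores:
            raise RuntimeError(
                f"replicate check failed for sample {sample_id!r}: scoring is nondeterministic"
            )
    return first


def _score_once(
    reads: Sequence[AlignedRead],
    catalog: HervCatalog,
    thresholds: CallingThresholds,
    sample_id: str,
    condition_label: str,
) -> SampleCalls:
    by_locus = _group_by_locus(reads)
    unknown = set(by_locus) - set(catalog.locus_ids)
    if unknown:
        raise ValueError(f"reads map to loci absent from the catalog: {sorted(unknown)}")
    scores: dict[str, LocusScore] = {}
    for locus in catalog:
        pile = pileup_locus(by_locus.get(locus.locus_id, ()), locus)
        windows = score_windows(pile, locus, thresholds)
        scores[locus.locus_id] = call_locus(windows, pile, thresholds)
    return SampleCalls(
        sample_id=sample_id,
        condition_label=condition_label,
        total_reads=len(reads),
        scores=scores,
    )


_TSV_HEADER = ("locus_id", "depth", "n_usable", "n_passed", "wss", "call")


def write_sample_tsv(sample: SampleCalls, path: str | Path) -> None:
    """Per-sample TSV: ``locus_id depth n_usable n_passed wss call``; WSS to one decimal."""
    with open(path, "w") as fh:
        fh.write("\t".join(_TSV_HEADER) + "\n")
        for lid, s in sample.scores.items():
            fh.write(f"{lid}\t{s.depth:.4f}\t{s.n_usable}\t{s.n_passed}\t{s.wss:.1f}\t{s.call}\n")


def read_sample_tsv(path: str | Path, sample_id: str = "", condition_label: str = "") -> SampleCalls:
    """Reload a per-sample TSV; window totals are not stored so only n_usable is restored."""
    scores: dict[str, LocusScore] = {}
    with open(path) as fh:
        header = tuple(fh.readline().rstrip("\n").split("\t"))
        if header != _TSV_HEADER:
            raise ValueError(f"unexpected sample TSV header: {header}")
        for line in fh:
            lid, depth, n_usable, n_passed, _wss, call = line.rstrip("\n").split("\t")
            n_usable_i = int(n_usable)
            scores[lid] = LocusScore(
                locus_id=lid,
                depth=float(depth),
                n_windows=n_usable_i,
                n_usable=n_usable_i,
                n_passed=int(n_passed),
                call=call,  # type: ignore[arg-type]
            )
    return SampleCalls(sample_id=sample_id, condition_label=condition_label, scores=scores)
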