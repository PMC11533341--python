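"""Synthetic catalogs, barcoded reads and cohorts with truth tables.

The generator emulates the statistical structure the pipeline assumes:
a catalog of proviral loci scattered over the 23 human chromosomes, each
sample expressing only a subset of loci ("only a fraction are expressed"),
reads drawn uniformly along each expressed locus to a target mean depth
with per-base substitution errors, a per-cell barcode, and optional
per-locus dropout emulating the RNA loss seen in frozen samples.

Alignment records are emitted directly from known truth — positions and
edit distances are exact by construction, so no external aligner is
needed — and every draw flows from a single integer seed, making FASTQ,
SAM and truth byte-reproducible.  The error model is substitution-only:
edit distance equals mismatch count and identity arithmetic stays exact.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from .catalog import HervCatalog, HervLocus
from .reads import AlignedRead

__all__ = [
    "SimConfig",
    "SampleTruth",
    "CohortSim",
    "simulate_catalog",
    "simulate_sample",
    "simulate_cohort",
    "write_fastq",
]

_ALPHABET = np.frombuffer(b"ACGT", dtype=np.uint8)

# Human chromosome namespace for scattered locus placement.
_CHROM_NAMES = [f"chr{i}" for i in range(1, 23)] + ["chrX"]


@dataclass(frozen=True)
class SimConfig:
    """Study-condition knobs for the generator.

    Defaults describe a desk-scale cohort: 40 loci of 450-800 bp on 23
    chromosomes, 90-bp reads at 30× mean depth (10× the calling minimum,
    saturating every window), no substitution errors and no dropout.  A
    mandatory seed drives every draw.
    """

    n_loci: int = 40
    locus_length_range: tuple[int, int] = (450, 800)
    n_chromosomes: int = 23
    target_depth: float = 30.0
    read_length: int = 90
    substitution_rate: float = 0.0
    dropout_rate: float = 0.0
    n_barcodes: int = 8
    barcode_length: int = 12
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 <= self.substitution_rate <= 1 and 0 <= self.dropout_rate <= 1):
            raise ValueError("rates must be probabilities in [0, 1]")
        if self.read_length > self.locus_length_range[0]:
            raise ValueError("read_length must not exceed the minimum locus length")
        if not (1 <= self.n_chromosomes <= len(_CHROM_NAMES)):
            raise ValueError(f"n_chromosomes must be in [1, {len(_CHROM_NAMES)}]")


@dataclass
class SampleTruth:
    """Ground truth for one simulated sample."""

    sample_id: str
    expressed_loci: list[str]
    read_counts: dict[str, int]
    dropped_loci: list[str] = field(default_factory=list)
    skipped_loci: list[str] = field(default_factory=list)
    seed: int = 0

    def as_dict(self) -> dict:
        return {
            "sample_id": self.sample_id,
            "expressed_loci": list(self.expressed_loci),
            "read_counts": dict(self.read_counts),
            "dropped_loci": list(self.dropped_loci),
            "skipped_loci": list(self.skipped_loci),
            "seed": self.seed,
        }


def _random_sequence(rng: np.random.Generator, length: int) -> str:
    return _ALPHABET[rng.integers(0, 4, size=length)].tobytes().decode()


def simulate_catalog(config: SimConfig) -> HervCatalog:
    """Random-sequence loci scattered over ``n_chromosomes`` chromosomes.

    Deterministic under ``config.seed``; loci are named L0001, L0002, …
    and placed at non-overlapping coordinates along each chromosome.
    """
    rng = np.random.default_rng(config.seed)
    lo, hi = config.locus_length_range
    chrom_cursor = {c: 10_000 for c in _CHROM_NAMES[: config.n_chromosomes]}
    loci: list[HervLocus] = []
    for i in range(config.n_loci):
        length = int(rng.integers(lo, hi + 1))
        chrom = _CHROM_NAMES[int(rng.integers(0, config.n_chromosomes))]
        start = chrom_cursor[chrom]
        chrom_cursor[chrom] = start + length + int(rng.integers(1_000, 50_000))
        loci.append(
            HervLocus(
                locus_id=f"L{i + 1:04d}",
                chrom=chrom,
                start=start,
                end=start + length,
                strand="+" if rng.random() < 0.5 else "-",
                family=f"HERV-{'KWHFE'[int(rng.integers(0, 5))]}",
                sequence=_random_sequence(rng, length),
            )
        )
    return HervCatalog(loci)


def _mutate(rng: np.random.Generator, seq: str, rate: float) -> tuple[str, int]:
    """Apply i.i.d. substitutions; returns (read sequence, mismatch count)."""
    if rate == 0.0:
        return seq, 0
    arr = np.frombuffer(seq.encode(), dtype=np.uint8).copy()
    hits = np.nonzero(rng.random(arr.size) < rate)[0]
    for pos in hits:
        current = arr[pos]
        choices = _ALPHABET[_ALPHABET != current]
        arr[pos] = choices[int(rng.integers(0, choices.size))]
    return arr.tobytes().decode(), int(hits.size)


def simulate_sample(
    catalog: HervCatalog,
    expressed: Sequence[str],
    config: SimConfig,
    sample_id: str,
    seed: int | None = None,
) -> tuple[list[AlignedRead], SampleTruth]:
    """Draw barcoded reads from the expressed loci of one sample.

    Read start positions are drawn uniformly over ``[-(read_length-1),
    L-1]`` and clipped at the locus boundaries, so every position of the
    locus — including the first and last bases — has the same expected
    coverage (``target_depth``); boundary reads carry only their aligned
    part, as a real aligner would soft-clip them.  Dropout removes all
    reads of a locus with probability ``dropout_rate``.  Loci shorter than
    the read length are skipped with the skip recorded in the truth table.
    """
    sample_seed = config.seed if seed is None else seed
    rng = np.random.default_rng(sample_seed)
    barcodes = [_random_sequence(rng, config.barcode_length) for _ in range(config.n_barcodes)]
    truth = SampleTruth(sample_id=sample_id, expressed_loci=[], read_counts={}, seed=sample_seed)
    reads: list[AlignedRead] = []
    serial = 0
    for lid in expressed:
        locus = catalog[lid]
        if config.read_length > locus.length:
            truth.skipped_loci.append(lid)
            continue
        if config.dropout_rate > 0 and rng.random() < config.dropout_rate:
            truth.dropped_loci.append(lid)
            continue
        rl = config.read_length
        # starts over [-(rl-1), L-1]: every locus position is covered by
        # exactly rl of the L+rl-1 start values, so expected coverage is
        # uniform (= target_depth) across the whole locus
        n_starts = locus.length + rl - 1
        n_reads = int(round(config.target_depth * n_starts / rl))
        truth.expressed_loci.append(lid)
        truth.read_counts[lid] = n_reads
        starts = rng.integers(-(rl - 1), locus.length, size=n_reads)
        for start in np.sort(starts):
            lo = max(int(start), 0)
            hi = min(int(start) + rl, locus.length)
            fragment = locus.sequence[lo:hi]
            seq, n_mismatch = _mutate(rng, fragment, config.substitution_rate)
            reads.append(
                AlignedRead(
                    read_id=f"{sample_id}.r{serial:06d}",
                    locus_id=lid,
                    ref_start=lo,
                    base_calls=seq,
                    edit_distance=n_mismatch,
                    barcode=barcodes[int(rng.integers(0, config.n_barcodes))],
                )
            )
            serial += 1
    return reads, truth


@dataclass
class CohortSim:
    """A simulated cohort: reads per sample plus the full truth table."""

    samples: dict[str, list[AlignedRead]]
    truths: dict[str, SampleTruth]
    control_ids: list[str]
    case_ids: list[str]
    baseline_loci: list[str]
    shared_case_loci: list[str]
    case_specific_loci: dict[str, list[str]]

    def expected_unique_case_loci(self) -> set[str]:
        """Loci the differential filter must return at error 0 and full depth."""
        expected = set(self.shared_case_loci)
        for loci in self.case_specific_loci.values():
            expected |= set(loci)
        return expected

    def truth_json(self, path: str | Path) -> None:
        payload = {
            "control_ids": self.control_ids,
            "case_ids": self.case_ids,
            "baseline_loci": self.baseline_loci,
            "shared_case_loci": self.shared_case_loci,
            "case_specific_loci": self.case_specific_loci,
            "samples": {sid: t.as_dict() for sid, t in self.truths.items()},
        }
        Path(path).write_text(json.dumps(payload, indent=2) + "\n")


def simulate_cohort(
    catalog: HervCatalog,
    n_controls: int,
    n_cases: int,
    n_shared_case_loci: int,
    n_case_specific_loci: int = 0,
    baseline_fraction: float = 0.3,
    config: SimConfig = SimConfig(),
) -> CohortSim:
    """Controls express a baseline locus set; cases express baseline ∪ case loci.

    ``n_shared_case_loci`` loci are planted in every case (and no control),
    and each case additionally receives ``n_case_specific_loci`` private
    loci.  At error 0 and saturating depth the differential filter must
    recover exactly the planted case loci.
    """
    rng = np.random.default_rng(config.seed)
    ids = list(catalog.locus_ids)
    n_case_loci_total = n_shared_case_loci + n_case_specific_loci * n_cases
    n_baseline = int(round(baseline_fraction * (len(ids) - n_case_loci_total)))
    if n_case_loci_total + n_baseline > len(ids):
        raise ValueError("catalog too small for requested baseline and case loci")
    shuffled = list(rng.permutation(ids))
    shared_case = shuffled[:n_shared_case_loci]
    cursor = n_shared_case_loci
    case_specific: dict[str, list[str]] = {}
    case_ids = [f"case{i + 1:02d}" for i in range(n_cases)]
    for cid in case_ids:
        case_specific[cid] = shuffled[cursor : cursor + n_case_specific_loci]
        cursor += n_case_specific_loci
    baseline = sorted(shuffled[cursor : cursor + n_baseline])

    control_ids = [f"ctrl{i + 1:02d}" for i in range(n_controls)]
    samples: dict[str, list[AlignedRead]] = {}
    truths: dict[str, SampleTruth] = {}
    for i, sid in enumerate(control_ids):
        reads, truth = simulate_sample(
            catalog, baseline, config, sid, seed=config.seed + 1_000 + i
        )
        samples[sid], truths[sid] = reads, truth
    for i, sid in enumerate(case_ids):
        expressed = sorted(set(baseline) | set(shared_case) | set(case_specific[sid]))
        reads, truth = simulate_sample(
            catalog, expressed, config, sid, seed=config.seed + 2_000 + i
        )
        samples[sid], truths[sid] = reads, truth
    return CohortSim(
        samples=samples,
        truths=truths,
        control_ids=control_ids,
        case_ids=case_ids,
        baseline_loci=baseline,
        shared_case_loci=list(shared_case),
        case_specific_loci=case_specific,
    )


def write_fastq(reads: Sequence[AlignedRead], path: str | Path) -> None:
    """FASTQ export with the barcode carried in a tag-compatible comment."""
    with open(path, "w") as fh:
        for read in reads:
            seq = read.base_calls.replace("-", "")
            comment = f" CB:Z:{read.barcode}" if read.barcode else ""
            fh.write(f"@{read.read_id}{comment}\n{seq}\n+\n{'F' * len(seq)}\n")
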