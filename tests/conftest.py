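"""Shared fixtures: hand-built catalogs and seeded simulated cohorts."""

from __future__ import annotations

import numpy as np
import pytest

from hervwha import (
    AlignedRead,
    CallingThresholds,
    HervCatalog,
    HervLocus,
    SimConfig,
    build_presence_matrix,
    score_sample,
    simulate_catalog,
    simulate_cohort,
)


def random_sequence(rng: np.random.Generator, length: int) -> str:
    return "".join("ACGT"[i] for i in rng.integers(0, 4, size=length))


def tiling_reads(locus: HervLocus, read_length: int = 90, step: int = 30) -> list[AlignedRead]:
    """Perfect reads tiling the whole locus (full coverage, zero mismatches)."""
    starts = list(range(0, locus.length - read_length + 1, step))
    if starts and starts[-1] + read_length < locus.length:
        starts.append(locus.length - read_length)
    return [
        AlignedRead(
            read_id=f"{locus.locus_id}.t{i}",
            locus_id=locus.locus_id,
            ref_start=s,
            base_calls=locus.sequence[s : s + read_length],
            edit_distance=0,
        )
        for i, s in enumerate(starts)
    ]


@pytest.fixture(scope="session")
def thresholds() -> CallingThresholds:
    return CallingThresholds()


@pytest.fixture(scope="session")
def tiny_catalog() -> HervCatalog:
    """Three loci: callable 450 bp, callable 523 bp, uncallable 120 bp."""
    rng = np.random.default_rng(42)
    loci = [
        HervLocus("L1", "chr1", 1000, 1450, "+", "HERV-K", random_sequence(rng, 450)),
        HervLocus("L2", "chr2", 5000, 5523, "-", "HERV-W", random_sequence(rng, 523)),
        HervLocus("L3", "chr2", 9000, 9120, "+", "", random_sequence(rng, 120)),
    ]
    return HervCatalog(loci)


@pytest.fixture(scope="session")
def sim_config() -> SimConfig:
    return SimConfig(seed=7, n_loci=30)


@pytest.fixture(scope="session")
def sim_catalog(sim_config) -> HervCatalog:
    return simulate_catalog(sim_config)


@pytest.fixture(scope="session")
def small_cohort(sim_catalog, sim_config):
    """8 controls / 4 cases with 5 planted case-only loci, error-free."""
    return simulate_cohort(sim_catalog, 8, 4, 5, config=sim_config)


@pytest.fixture(scope="session")
def small_cohort_matrix(small_cohort, sim_catalog):
    samples = [
        score_sample(
            reads,
            sim_catalog,
            sample_id=sid,
            condition_label="control" if sid.startswith("ctrl") else "case",
        )
        for sid, reads in small_cohort.samples.items()
    ]
    return build_presence_matrix(samples)
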