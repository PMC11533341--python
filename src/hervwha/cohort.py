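"""Cross-sample analytics: presence matrix, pangenome-control differential
filter, Venn partitions, saturation curves, read subsampling and rank tests.

The central object is the presence matrix — loci × samples with ternary
calls (positive / negative / uncallable) and a parallel depth matrix; it
formalizes the per-sample call tables a spreadsheet workflow would hold.
Case-unique loci are those negative (by default: not positive) in *every*
control sample and positive in at least one case sample — the pangenome
control is a set of individually scored control samples, never a pooled
read file.  The saturation curve re-applies that filter over growing
control-prefix pools; because adding controls can only remove case-unique
loci, the curve is monotone non-increasing.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .reads import AlignedRead
from .scoring import SampleCalls

__all__ = [
    "PresenceMatrix",
    "VennPartition",
    "SaturationPoint",
    "RankTestResult",
    "build_presence_matrix",
    "unique_case_loci",
    "shared_unique",
    "saturation_curve",
    "subsample_reads",
    "depth_rank_test",
    "flag_significant_loci",
]

_CALL_CODE = {"positive": "P", "negative": "N", "uncallable": "U"}
_CODE_CALL = {v: k for k, v in _CALL_CODE.items()}


@dataclass
class PresenceMatrix:
    """Loci × samples grid of ternary calls with a parallel depth matrix.

    ``calls`` and ``depths`` are DataFrames indexed by locus_id with one
    column per sample; ``conditions`` maps sample_id → condition label.
    """

    calls: pd.DataFrame
    depths: pd.DataFrame
    conditions: dict[str, str]

    def __post_init__(self) -> None:
        if not self.calls.index.equals(self.depths.index) or not self.calls.columns.equals(
            self.depths.columns
        ):
            raise ValueError("calls and depths matrices must share loci and samples")
        if self.calls.isna().any().any():
            raise ValueError("every (locus, sample) cell must be populated")
        bad = set(np.unique(self.calls.values)) - set(_CALL_CODE)
        if bad:
            raise ValueError(f"invalid call values: {sorted(bad)}")

    @property
    def locus_ids(self) -> list[str]:
        return list(self.calls.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.calls.columns)

    def positive_mask(self) -> pd.DataFrame:
        return self.calls == "positive"

    def positive_loci(self, sample_id: str) -> set[str]:
        col = self.calls[sample_id]
        return set(col.index[col == "positive"])

    def to_tsv(self, calls_path: str | Path, depths_path: str | Path) -> None:
        """Export calls (cells P/N/U) and depths as loci-row TSVs.

        The first header cell carries the condition labels so a round-trip
        reload restores them.
        """
        coded = self.calls.replace(_CALL_CODE)
        coded.index.name = "locus_id"
        header_meta = ";".join(f"{s}={self.conditions.get(s, '')}" for s in self.sample_ids)
        with open(calls_path, "w") as fh:
            fh.write(f"#conditions\t{header_meta}\n")
            coded.to_csv(fh, sep="\t")
        d = self.depths.copy()
        d.index.name = "locus_id"
        # default float formatting is shortest-repr, which round-trips exactly
        d.to_csv(depths_path, sep="\t")

    @classmethod
    def from_tsv(cls, calls_path: str | Path, depths_path: str | Path) -> "PresenceMatrix":
        with open(calls_path) as fh:
            first = fh.readline()
            conditions: dict[str, str] = {}
            if first.startswith("#conditions"):
                meta = first.rstrip("\n").split("\t", 1)[1] if "\t" in first else ""
                for part in meta.split(";"):
                    if "=" in part:
                        k, v = part.split("=", 1)
                        conditions[k] = v
                calls = pd.read_csv(fh, sep="\t", index_col="locus_id", dtype=str)
            else:
                fh.seek(0)
                calls = pd.read_csv(fh, sep="\t", index_col="locus_id", dtype=str)
        calls = calls.replace(_CODE_CALL)
        depths = pd.read_csv(
            depths_path, sep="\t", index_col="locus_id", float_precision="round_trip"
        )
        depths.columns = depths.columns.astype(str)
        return cls(calls=calls, depths=depths, conditions=conditions)


def build_presence_matrix(samples: Sequence[SampleCalls]) -> PresenceMatrix:
    """Assemble scored samples into one matrix; all must share the catalog."""
    if not samples:
        raise ValueError("at least one scored sample is required")
    locus_order = list(samples[0].scores.keys())
    locus_set = set(locus_order)
    for s in samples[1:]:
        if set(s.scores.keys()) != locus_set:
            raise ValueError(
                f"sample {s.sample_id!r} was scored against a different catalog"
            )
    sample_ids = [s.sample_id for s in samples]
    if len(set(sample_ids)) != len(sample_ids):
        raise ValueError("duplicate sample_id in cohort")
    calls = pd.DataFrame(
        {s.sample_id: [s.scores[lid].call for lid in locus_order] for s in samples},
        index=pd.Index(locus_order, name="locus_id"),
    )
    depths = pd.DataFrame(
        {s.sample_id: [s.scores[lid].depth for lid in locus_order] for s in samples},
        index=pd.Index(locus_order, name="locus_id"),
    )
    conditions = {s.sample_id: s.condition_label for s in samples}
    return PresenceMatrix(calls=calls, depths=depths, conditions=conditions)


def unique_case_loci(
    matrix: PresenceMatrix,
    control_ids: set[str] | Sequence[str],
    case_ids: set[str] | Sequence[str],
    strict_negative: bool = False,
) -> set[str]:
    """Loci non-positive in every control and positive in ≥ 1 case.

    With ``strict_negative`` an uncallable control cell disqualifies the
    locus (only explicit negatives satisfy the control condition).
    """
    controls = list(control_ids)
    cases = list(case_ids)
    if not controls:
        raise ValueError("the differential filter is undefined without control samples")
    overlap = set(controls) & set(cases)
    if overlap:
        raise ValueError(f"control and case sets overlap: {sorted(overlap)}")
    missing = (set(controls) | set(cases)) - set(matrix.sample_ids)
    if missing:
        raise ValueError(f"samples absent from matrix: {sorted(missing)}")

    ctrl = matrix.calls[controls]
    ctrl_ok = (
        (ctrl == "negative").all(axis=1) if strict_negative else (ctrl != "positive").all(axis=1)
    )
    case_pos = (matrix.calls[cases] == "positive").any(axis=1) if cases else pd.Series(
        False, index=matrix.calls.index
    )
    keep = ctrl_ok & case_pos
    return set(keep.index[keep])


@dataclass(frozen=True)
class VennPartition:
    """Two-set Venn compartments over locus sets."""

    unique_a: frozenset[str]
    unique_b: frozenset[str]
    shared: frozenset[str]
    label_a: str = "A"
    label_b: str = "B"

    def counts(self) -> dict[str, int]:
        return {
            f"unique_{self.label_a}": len(self.unique_a),
            f"unique_{self.label_b}": len(self.unique_b),
            "shared": len(self.shared),
        }


def shared_unique(
    set_a: set[str], set_b: set[str], label_a: str = "A", label_b: str = "B"
) -> VennPartition:
    """Exact set algebra for the two-cohort Venn comparison."""
    a, b = set(set_a), set(set_b)
    return VennPartition(
        unique_a=frozenset(a - b),
        unique_b=frozenset(b - a),
        shared=frozenset(a & b),
        label_a=label_a,
        label_b=label_b,
    )


@dataclass(frozen=True)
class SaturationPoint:
    """One prefix of the control-pool saturation curve."""

    n_controls: int
    cumulative_control_reads: int
    n_case_unique_loci: int


def saturation_curve(
    matrix: PresenceMatrix,
    case_ids: Sequence[str],
    control_order: Sequence[str],
    read_counts: Mapping[str, int],
    strict_negative: bool = False,
) -> list[SaturationPoint]:
    """Case-unique locus count as controls are added one at a time.

    Point *k* applies the differential filter using the first *k* controls,
    with x the cumulative read count of those controls.  The curve starts at
    k = 1 (the filter is undefined with zero controls) and is monotone
    non-increasing in locus count.
    """
    points: list[SaturationPoint] = []
    cumulative = 0
    for k in range(1, len(control_order) + 1):
        prefix = list(control_order[:k])
        cumulative += int(read_counts[prefix[-1]])
        loci = unique_case_loci(matrix, prefix, case_ids, strict_negative=strict_negative)
        points.append(SaturationPoint(k, cumulative, len(loci)))
    return points


def subsample_reads(
    reads: Sequence[AlignedRead], n: int, seed: int
) -> list[AlignedRead]:
    """Uniform sample of ``n`` reads without replacement, reproducible by seed.

    Input order is preserved in the output (indices are drawn, then sorted).
    """
    if n < 0:
        raise ValueError("n must be non-negative")
    if n > len(reads):
        raise ValueError(f"cannot subsample {n} reads from {len(reads)}")
    rng = np.random.default_rng(seed)
    idx = np.sort(rng.choice(len(reads), size=n, replace=False))
    return [reads[i] for i in idx]


@dataclass(frozen=True)
class RankTestResult:
    """Two-sided Mann-Whitney U result; ``method`` records which branch ran."""

    u_statistic: float
    p_value: float
    method: str  # "exact" or "asymptotic"


def depth_rank_test(
    case_depths: Sequence[float], control_depths: Sequence[float]
) -> RankTestResult:
    """Two-sided Mann-Whitney U test of case vs control depths.

    Uses the exact null distribution when n + m ≤ 16 and there are no ties;
    otherwise the tie-corrected normal approximation (with continuity
    correction).  U is reported for the case sample (first argument).
    """
    x = np.asarray(case_depths, dtype=float)
    y = np.asarray(control_depths, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both depth vectors must be non-empty")
    pooled = np.concatenate([x, y])
    has_ties = np.unique(pooled).size < pooled.size
    if x.size + y.size <= 16 and not has_ties:
        method = "exact"
    else:
        method = "asymptotic"
    res = stats.mannwhitneyu(x, y, alternative="two-sided", method=method)
    return RankTestResult(float(res.statistic), float(res.pvalue), method)


def flag_significant_loci(
    matrix: PresenceMatrix,
    control_ids: Sequence[str],
    case_ids: Sequence[str],
    alpha: float = 0.05,
    min_case_positives: int = 2,
) -> pd.DataFrame:
    """Per-locus depth rank tests for loci positive in ≥ ``min_case_positives`` cases.

    Control depth is 0.0 (not missing) where a control has no coverage, so
    control vectors always have one entry per control sample.  No multiple-
    testing correction changes the ``significant`` flag; a Benjamini-
    Hochberg column (``p_bh``) is emitted alongside for transparency.
    """
    controls = list(control_ids)
    cases = list(case_ids)
    if not controls or not cases:
        raise ValueError("both control and case sets must be non-empty")
    rows = []
    for lid in matrix.locus_ids:
        case_calls = matrix.calls.loc[lid, cases]
        n_case_pos = int((case_calls == "positive").sum())
        if n_case_pos < min_case_positives:
            rows.append(
                {"locus_id": lid, "n_case_pos": n_case_pos, "U": math.nan, "p": math.nan,
                 "significant": False, "tested": False, "method": "not tested"}
            )
            continue
        res = depth_rank_test(
            matrix.depths.loc[lid, cases].to_numpy(),
            matrix.depths.loc[lid, controls].to_numpy(),
        )
        rows.append(
            {"locus_id": lid, "n_case_pos": n_case_pos, "U": res.u_statistic,
             "p": res.p_value, "significant": bool(res.p_value < alpha), "tested": True,
             "method": res.method}
        )
    table = pd.DataFrame(rows).set_index("locus_id")
    tested = table["tested"]
    table["p_bh"] = math.nan
    if tested.any():
        p = table.loc[tested, "p"].to_numpy()
        table.loc[tested, "p_bh"] = _benjamini_hochberg(p)
    return table


def _benjamini_hochberg(p: np.ndarray) -> np.ndarray:
    m = p.size
    order = np.argsort(p)
    adjusted = np.empty(m, dtype=float)
    running_min = 1.0
    for rank_from_top in range(m - 1, -1, -1):
        i = order[rank_from_top]
        running_min = min(running_min, p[i] * m / (rank_from_top + 1))
        adjusted[i] = running_min
    return adjusted
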