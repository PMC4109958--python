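"""Downstream filtering of externally produced fusion-transcript calls.

Discovery (deFuse-style) is out of scope; this module applies the
post-hoc filters in a fixed stage order: read support, adjacent genes,
presence in nonmalignant controls, then recurrence across samples.

The read-support rule has two readings of "fusions with fewer than 8
spanning reads and fewer than 5 split reads were filtered out":
``rule="conjunction"`` (default, literal) removes a call only when *both*
counts are below threshold; ``rule="disjunction"`` requires both
thresholds to be met, removing a call when *either* count falls short.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import pandas as pd


class FusionFilterError(ValueError):
    pass


@dataclass(frozen=True)
class FusionCall:
    sample_id: str
    gene_5prime: str
    gene_3prime: str
    spanning_reads: int
    split_reads: int
    adjacent_genes: bool = False
    seen_in_normals: bool = False

    def __post_init__(self) -> None:
        if self.spanning_reads < 0 or self.split_reads < 0:
            raise FusionFilterError("read counts must be non-negative")

    @property
    def pair_key(self) -> tuple[str, str]:
        """Recurrence identity: unordered pair with fixed 5'/3' orientation."""
        return (self.gene_5prime, self.gene_3prime)


STAGES = ("read_support", "adjacent_genes", "seen_in_normals", "recurrence")


def filter_fusions(
    calls: Sequence[FusionCall],
    min_spanning: int = 8,
    min_split: int = 5,
    min_recurrent_samples: int = 2,
    drop_adjacent: bool = True,
    drop_normal_seen: bool = True,
    rule: str = "conjunction",
) -> tuple[list[FusionCall], list[tuple[FusionCall, str]]]:
    """Apply the filter cascade; returns (retained calls, removal log).

    The log records each removed call with the stage that removed it.
    Filtering is idempotent and the output is always a subset of the input.
    """
    if min_spanning < 0 or min_split < 0 or min_recurrent_samples < 0:
        raise FusionFilterError("thresholds must be non-negative")
    if rule not in ("conjunction", "disjunction"):
        raise FusionFilterError(f"unknown rule {rule!r}")
    log: list[tuple[FusionCall, str]] = []

    survivors = []
    for call in calls:
        low_span = call.spanning_reads < min_spanning
        low_split = call.split_reads < min_split
        removed = (low_span and low_split) if rule == "conjunction" else (
            low_span or low_split
        )
        if removed:
            log.append((call, "read_support"))
        else:
            survivors.append(call)

    if drop_adjacent:
        kept = []
        for call in survivors:
            if call.adjacent_genes:
                log.append((call, "adjacent_genes"))
            else:
                kept.append(call)
        survivors = kept

    if drop_normal_seen:
        kept = []
        for call in survivors:
            if call.seen_in_normals:
                log.append((call, "seen_in_normals"))
            else:
                kept.append(call)
        survivors = kept

    sample_support: dict[tuple[str, str], set[str]] = {}
    for call in survivors:
        sample_support.setdefault(call.pair_key, set()).add(call.sample_id)
    kept = []
    for call in survivors:
        if len(sample_support[call.pair_key]) >= min_recurrent_samples:
            kept.append(call)
        else:
            log.append((call, "recurrence"))
    return kept, log


# ---------------------------------------------------------------------------
# TSV input-output (deFuse-like columns)

FUSION_COLUMNS = [
    "sample",
    "gene_5prime",
    "gene_3prime",
    "spanning_reads",
    "split_reads",
    "adjacent_genes",
    "seen_in_normals",
]


def read_fusions(path: str | Path) -> list[FusionCall]:
    df = pd.read_csv(path, sep="\t", dtype={"sample": str})
    missing = [c for c in FUSION_COLUMNS if c not in df.columns]
    if missing:
        raise FusionFilterError(f"{path}: missing columns {missing}")
    return [
        FusionCall(
            sample_id=str(r["sample"]),
            gene_5prime=str(r["gene_5prime"]),
            gene_3prime=str(r["gene_3prime"]),
            spanning_reads=int(r["spanning_reads"]),
            split_reads=int(r["split_reads"]),
            adjacent_genes=bool(r["adjacent_genes"]),
            seen_in_normals=bool(r["seen_in_normals"]),
        )
        for _, r in df.iterrows()
    ]


def write_fusions(calls: Sequence[FusionCall], path: str | Path) -> None:
    pd.DataFrame(
        {
            "sample": [c.sample_id for c in calls],
            "gene_5prime": [c.gene_5prime for c in calls],
            "gene_3prime": [c.gene_3prime for c in calls],
            "spanning_reads": [c.spanning_reads for c in calls],
            "split_reads": [c.split_reads for c in calls],
            "adjacent_genes": [c.adjacent_genes for c in calls],
            "seen_in_normals": [c.seen_in_normals for c in calls],
        }
    ).to_csv(path, sep="\t", index=False)
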