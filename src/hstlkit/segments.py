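"""Copy-number segment model and common-region derivation.

Segments are per-sample aCGH calls on 1-based inclusive coordinates (as
printed in cytogenetic reports). The module derives cohort-level regions:
the maximal interval carried in a qualifying state by *every* defining
sample (common deleted/gained/amplified regions, CDR/CGR/SAR) and
genome-wide recurrent imbalances shared by at least ``min_cases`` samples.

Whole-arm events described only at the karyotype level (isochromosomes,
rings, whole-chromosome trisomies) are expanded into explicit segments via
an :class:`ArmModel` that places the centromere.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

STATES = ("biallelic_loss", "loss", "neutral", "gain", "amplification")
LOSS_STATES = frozenset({"biallelic_loss", "loss"})
GAIN_STATES = frozenset({"gain", "amplification"})

#: copies at or above this count qualify a segment as an amplification
AMPLIFICATION_MIN_COPIES = 4

PLOIDY_BASELINE = 2


class SegmentError(ValueError):
    """Raised for invalid segments, regions or malformed SEG tables."""


@dataclass(frozen=True)
class Segment:
    """One copy-number call: a sample's state over a 1-based inclusive interval."""

    sample_id: str
    chromosome: str
    start_bp: int
    end_bp: int
    state: str
    copies: float | None = None

    def __post_init__(self) -> None:
        if self.state not in STATES:
            raise SegmentError(f"unknown state {self.state!r}")
        if self.start_bp < 1:
            raise SegmentError(f"start_bp must be >= 1, got {self.start_bp}")
        if self.start_bp > self.end_bp:
            raise SegmentError(
                f"start_bp {self.start_bp} > end_bp {self.end_bp} "
                f"({self.sample_id} chr{self.chromosome})"
            )
        if self.copies is not None:
            if self.copies < 0:
                raise SegmentError("copies must be non-negative")
            if self.state == "biallelic_loss" and self.copies != 0:
                raise SegmentError("biallelic_loss requires copies == 0")
            if self.state == "loss" and not self.copies < PLOIDY_BASELINE:
                raise SegmentError("loss requires copies below the ploidy baseline")

    @property
    def interval(self) -> tuple[int, int]:
        return (self.start_bp, self.end_bp)


@dataclass(frozen=True)
class Region:
    """A cohort-level interval shared by ``n_supporting`` samples.

    An empty region (no common interval) has ``start_bp``/``end_bp`` of
    ``None`` and ``n_supporting == 0``.
    """

    chromosome: str
    start_bp: int | None
    end_bp: int | None
    label: str
    supporting_samples: tuple[str, ...] = ()
    n_supporting: int = 0

    def __post_init__(self) -> None:
        if (self.start_bp is None) != (self.end_bp is None):
            raise SegmentError("start_bp and end_bp must both be set or both None")
        if self.start_bp is not None and self.start_bp > self.end_bp:
            raise SegmentError("region start_bp > end_bp")
        if self.is_empty and self.n_supporting != 0:
            raise SegmentError("empty region cannot have supporting samples")

    @property
    def is_empty(self) -> bool:
        return self.start_bp is None

    @classmethod
    def empty(cls, chromosome: str, label: str) -> "Region":
        return cls(chromosome, None, None, label)


@dataclass(frozen=True)
class ArmModel:
    """Chromosome arm coordinates: p arm, centromere, q arm end (1-based)."""

    chromosome: str
    centromere_start_bp: int
    centromere_end_bp: int
    q_end_bp: int
    p_start_bp: int = 1

    def __post_init__(self) -> None:
        if not (
            self.p_start_bp
            < self.centromere_start_bp
            < self.centromere_end_bp
            < self.q_end_bp
        ):
            raise SegmentError("arm model requires p_start < cen_start < cen_end < q_end")

    @property
    def p_arm(self) -> tuple[int, int]:
        return (self.p_start_bp, self.centromere_start_bp - 1)

    @property
    def q_arm(self) -> tuple[int, int]:
        return (self.centromere_end_bp + 1, self.q_end_bp)


# ---------------------------------------------------------------------------
# interval arithmetic


def intersect_intervals(
    intervals: Sequence[tuple[int, int]],
) -> tuple[int, int] | None:
    """Intersect 1-based inclusive intervals; ``None`` when they share no base.

    Commutative, associative and idempotent; the result is contained in every
    input interval.
    """
    if len(intervals) == 0:
        raise SegmentError("no intervals")
    start = max(s for s, _ in intervals)
    end = min(e for _, e in intervals)
    for s, e in intervals:
        if s > e:
            raise SegmentError(f"invalid interval ({s}, {e})")
    if start > end:
        return None
    return (start, end)


def union_runs(intervals: Iterable[tuple[int, int]]) -> list[tuple[int, int]]:
    """Merge 1-based inclusive intervals into maximal runs.

    Book-ended intervals ([1,5] and [6,10]) merge: their base-pair coverage
    is contiguous.
    """
    runs: list[tuple[int, int]] = []
    for s, e in sorted(intervals):
        if runs and s <= runs[-1][1] + 1:
            runs[-1] = (runs[-1][0], max(runs[-1][1], e))
        else:
            runs.append((s, e))
    return runs


def _intersect_run_lists(
    a: list[tuple[int, int]], b: list[tuple[int, int]]
) -> list[tuple[int, int]]:
    out: list[tuple[int, int]] = []
    i = j = 0
    while i < len(a) and j < len(b):
        s = max(a[i][0], b[j][0])
        e = min(a[i][1], b[j][1])
        if s <= e:
            out.append((s, e))
        if a[i][1] < b[j][1]:
            i += 1
        else:
            j += 1
    return out


# ---------------------------------------------------------------------------
# karyotype-level event expansion

ABERRATION_KINDS = (
    "isochromosome_q",
    "ring_with_breakpoints",
    "whole_chromosome_gain",
    "whole_chromosome_loss",
)


def expand_aberration(
    kind: str,
    arm_model: ArmModel,
    sample_id: str,
    breakpoints: tuple[int, int] | None = None,
) -> list[Segment]:
    """Expand a karyotype-level event into explicit copy-number segments.

    * ``isochromosome_q`` — one p arm lost, the q arm gained (e.g. i(7)(q10)).
    * ``ring_with_breakpoints`` — terminal losses distal to the (p, q)
      breakpoints, as in r(7) formed by TCRG-TCRB rearrangement.
    * ``whole_chromosome_gain`` / ``whole_chromosome_loss`` — end to end.
    """
    if arm_model is None:
        raise SegmentError(f"missing arm model for {kind}")
    chrom = arm_model.chromosome
    p_lo, p_hi = arm_model.p_arm
    q_lo, q_hi = arm_model.q_arm
    if kind == "isochromosome_q":
        return [
            Segment(sample_id, chrom, p_lo, p_hi, "loss"),
            Segment(sample_id, chrom, q_lo, q_hi, "gain"),
        ]
    if kind == "ring_with_breakpoints":
        if breakpoints is None:
            raise SegmentError("ring_with_breakpoints requires (p, q) breakpoints")
        b_p, b_q = breakpoints
        return [
            Segment(sample_id, chrom, arm_model.p_start_bp, b_p, "loss"),
            Segment(sample_id, chrom, b_q, arm_model.q_end_bp, "loss"),
        ]
    if kind == "whole_chromosome_gain":
        return [Segment(sample_id, chrom, arm_model.p_start_bp, arm_model.q_end_bp, "gain")]
    if kind == "whole_chromosome_loss":
        return [Segment(sample_id, chrom, arm_model.p_start_bp, arm_model.q_end_bp, "loss")]
    raise SegmentError(f"unknown aberration kind {kind!r}")


# ---------------------------------------------------------------------------
# cohort region derivation


def _sample_footprints(
    segments: Iterable[Segment],
    chromosome: str,
    qualifying_states: frozenset[str] | set[str],
) -> dict[str, list[tuple[int, int]]]:
    by_sample: dict[str, list[tuple[int, int]]] = {}
    for seg in segments:
        if seg.chromosome == chromosome and seg.state in qualifying_states:
            by_sample.setdefault(seg.sample_id, []).append(seg.interval)
    return {sid: union_runs(ivs) for sid, ivs in by_sample.items()}


def derive_common_region(
    segments: Sequence[Segment],
    chromosome: str,
    qualifying_states: Iterable[str],
    label: str,
    defining_samples: Sequence[str] | None = None,
) -> Region:
    """Maximal interval covered by a qualifying state in every defining sample.

    A sample's footprint is the union of its qualifying segments; the
    intersection across samples is taken over maximal runs and the longest
    common run is reported (ties broken by the smaller start coordinate).
    ``defining_samples`` defaults to every sample present in ``segments``;
    a defining sample without a qualifying segment on the chromosome is an
    error, an empty intersection an explicit empty Region.
    """
    states = frozenset(qualifying_states)
    footprints = _sample_footprints(segments, chromosome, states)
    if defining_samples is None:
        defining_samples = sorted({s.sample_id for s in segments})
    if not defining_samples:
        raise SegmentError("no defining samples")
    for sid in defining_samples:
        if sid not in footprints:
            raise SegmentError(
                f"sample {sid!r} has no segment in states {sorted(states)} "
                f"on chromosome {chromosome}"
            )
    common = footprints[defining_samples[0]]
    for sid in defining_samples[1:]:
        common = _intersect_run_lists(common, footprints[sid])
        if not common:
            return Region.empty(chromosome, label)
    # longest run; ties -> smaller start
    best = max(common, key=lambda iv: (iv[1] - iv[0], -iv[0]))
    return Region(
        chromosome=chromosome,
        start_bp=best[0],
        end_bp=best[1],
        label=label,
        supporting_samples=tuple(sorted(defining_samples)),
        n_supporting=len(defining_samples),
    )


def recurrent_regions(
    segments: Sequence[Segment],
    states: Iterable[str] | str,
    min_cases: int = 2,
) -> list[Region]:
    """Genome-wide maximal intervals where >= ``min_cases`` samples carry a state.

    Intervals are found by a coverage sweep over distinct-sample footprints
    and reported sorted by chromosome then start. ``supporting_samples``
    lists the samples whose footprint covers the *whole* emitted interval
    (so the Region invariant holds even where coverage is a staircase).
    """
    if min_cases < 1:
        raise SegmentError("min_cases must be >= 1")
    if isinstance(states, str):
        states = {states}
    states = frozenset(states)
    chroms = sorted({s.chromosome for s in segments if s.state in states})
    out: list[Region] = []
    for chrom in chroms:
        footprints = _sample_footprints(segments, chrom, states)
        events: list[tuple[int, int]] = []  # (position, delta)
        for runs in footprints.values():
            for s, e in runs:
                events.append((s, +1))
                events.append((e + 1, -1))
        events.sort()
        depth = 0
        run_start: int | None = None
        i = 0
        while i < len(events):
            pos = events[i][0]
            while i < len(events) and events[i][0] == pos:
                depth += events[i][1]
                i += 1
            if depth >= min_cases and run_start is None:
                run_start = pos
            elif depth < min_cases and run_start is not None:
                out.append(_make_recurrent(chrom, run_start, pos - 1, footprints))
                run_start = None
        # depth always returns to 0 after the last event, so run_start is closed
    return out


def _make_recurrent(
    chrom: str,
    start: int,
    end: int,
    footprints: dict[str, list[tuple[int, int]]],
) -> Region:
    covering = tuple(
        sorted(
            sid
            for sid, runs in footprints.items()
            if any(s <= start and end <= e for s, e in runs)
        )
    )
    return Region(
        chromosome=chrom,
        start_bp=start,
        end_bp=end,
        label="recurrent",
        supporting_samples=covering,
        n_supporting=len(covering),
    )


# ---------------------------------------------------------------------------
# SEG / BED input-output

SEG_COLUMNS = ["sample", "chrom", "start", "end", "state"]


def read_seg(path: str | Path) -> list[Segment]:
    """Read a tab-separated segment table (sample, chrom, start, end, state[, copies])."""
    df = pd.read_csv(path, sep="\t", dtype={"sample": str, "chrom": str})
    missing = [c for c in SEG_COLUMNS if c not in df.columns]
    if missing:
        raise SegmentError(f"{path}: missing columns {missing}")
    segments: list[Segment] = []
    for idx, row in df.iterrows():
        line_no = idx + 2  # header is line 1
        try:
            copies = row["copies"] if "copies" in df.columns and pd.notna(row["copies"]) else None
            segments.append(
                Segment(
                    sample_id=str(row["sample"]),
                    chromosome=str(row["chrom"]),
                    start_bp=int(row["start"]),
                    end_bp=int(row["end"]),
                    state=str(row["state"]),
                    copies=float(copies) if copies is not None else None,
                )
            )
        except (SegmentError, ValueError, TypeError) as exc:
            raise SegmentError(f"{path}, line {line_no}: {exc}") from exc
    return segments


def write_seg(segments: Sequence[Segment], path: str | Path) -> None:
    df = pd.DataFrame(
        {
            "sample": [s.sample_id for s in segments],
            "chrom": [s.chromosome for s in segments],
            "start": [s.start_bp for s in segments],
            "end": [s.end_bp for s in segments],
            "state": [s.state for s in segments],
            "copies": [s.copies for s in segments],
        }
    )
    df.to_csv(path, sep="\t", index=False)


def write_bed(regions: Sequence[Region], path: str | Path) -> None:
    """Write non-empty regions as BED (0-based half-open)."""
    with open(path, "w") as fh:
        for r in regions:
            if r.is_empty:
                continue
            name = f"{r.label}_n{r.n_supporting}"
            fh.write(f"{r.chromosome}\t{r.start_bp - 1}\t{r.end_bp}\t{name}\n")
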