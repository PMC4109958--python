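"""Minimal ISCN karyotype-string parser and cohort aneuploidy statistics.

Covers the token kinds that occur in hepatosplenic T-cell lymphoma
karyotypes — numeric gains/losses (+8, -Y), isochromosomes (i(7)(q10)),
rings (r(7)(p22q36)), derivatives, additions, deletions and markers.
Anything else is kept as ``kind="unknown"`` rather than dropped, so
tokenization is lossless. Array-CGH annotations (e.g. ``aCGH+8``) form an
independent evidence channel: trisomy detected only on the array still
counts toward the cohort aneuploidy rate.
"""

from __future__ import annotations

import math
import re
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

KINDS = (
    "chromosome_gain",
    "chromosome_loss",
    "isochromosome",
    "ring",
    "derivative",
    "addition",
    "deletion",
    "marker",
    "unknown",
)


class ISCNParseError(ValueError):
    """Raised on structurally invalid karyotype strings."""


@dataclass(frozen=True)
class Aberration:
    kind: str
    chromosome: str | None
    bands: str | None
    raw_token: str

    def __post_init__(self) -> None:
        if self.kind not in KINDS:
            raise ISCNParseError(f"unknown aberration kind {self.kind!r}")


@dataclass
class KaryotypeRecord:
    case_id: str
    raw_karyotype: str
    aberrations: list[Aberration] = field(default_factory=list)
    acgh_flags: list[str] = field(default_factory=list)
    clone_count_range: str | None = None

    @classmethod
    def from_strings(
        cls, case_id: str, karyotype: str, acgh_flags: Iterable[str] = ()
    ) -> "KaryotypeRecord":
        return cls(
            case_id=case_id,
            raw_karyotype=karyotype,
            aberrations=parse_iscn(karyotype),
            acgh_flags=[f.strip() for f in acgh_flags if f.strip()],
        )


_MODAL_RE = re.compile(r"^\d{1,3}(?:[–—-]\d{1,3})?$")
_SEX_RE = re.compile(r"^[XY]{1,4}$")
_GAIN_RE = re.compile(r"^\+(\d{1,2}|X|Y)$")
_LOSS_RE = re.compile(r"^[-−](\d{1,2}|X|Y)\??$")
_STRUCT_RE = re.compile(r"^(\+)?(i|r|der|add|del)\((.+?)\)(.*)$")
_MARKER_RE = re.compile(r"^\+?mar\w*$")
_BRACKET_RE = re.compile(r"\[[^\]]*\]")


def _check_parens(text: str) -> None:
    depth = 0
    for offset, ch in enumerate(text):
        if ch == "(":
            depth += 1
        elif ch == ")":
            depth -= 1
            if depth < 0:
                raise ISCNParseError(
                    f"unbalanced parentheses at character {offset}: {text!r}"
                )
    if depth != 0:
        raise ISCNParseError(f"unbalanced parentheses at character {len(text)}: {text!r}")


def _split_top_level(text: str) -> list[str]:
    """Split on commas outside parentheses."""
    tokens, depth, buf = [], 0, []
    for ch in text:
        if ch == "(":
            depth += 1
        elif ch == ")":
            depth -= 1
        if ch == "," and depth == 0:
            tokens.append("".join(buf).strip())
            buf = []
        else:
            buf.append(ch)
    tokens.append("".join(buf).strip())
    return [t for t in tokens if t]


def _classify(token: str) -> Aberration:
    if m := _GAIN_RE.match(token):
        return Aberration("chromosome_gain", m.group(1), None, token)
    if m := _LOSS_RE.match(token):
        return Aberration("chromosome_loss", m.group(1), None, token)
    if _MARKER_RE.match(token):
        return Aberration("marker", None, None, token)
    if m := _STRUCT_RE.match(token):
        op = m.group(2)
        chrom = m.group(3).split(";")[0].strip().rstrip("?") or None
        rest = m.group(4)
        bands_m = re.match(r"^\((.+?)\)", rest)
        bands = bands_m.group(1) if bands_m else None
        kind = {
            "i": "isochromosome",
            "r": "ring",
            "der": "derivative",
            "add": "addition",
            "del": "deletion",
        }[op]
        return Aberration(kind, chrom, bands, token)
    return Aberration("unknown", None, None, token)


def parse_iscn(karyotype: str) -> list[Aberration]:
    """Parse an ISCN karyotype string into Aberrations.

    The modal-number prefix and sex-chromosome designator are consumed;
    clone-count brackets (``[cp7]``, ``[12]``) and ``inc`` are stripped with
    a warning; unclassifiable tokens are emitted as ``kind="unknown"``.
    """
    if not karyotype or not karyotype.strip():
        raise ISCNParseError("empty karyotype string")
    _check_parens(karyotype)
    text = karyotype
    if _BRACKET_RE.search(text):
        warnings.warn("stripping clone-count annotations", stacklevel=2)
        text = _BRACKET_RE.sub("", text)
    tokens = _split_top_level(text)
    aberrations: list[Aberration] = []
    for i, token in enumerate(tokens):
        token = token.strip().rstrip(".")
        if not token:
            continue
        if token == "inc":
            warnings.warn("stripping 'inc' (incomplete karyotype)", stacklevel=2)
            continue
        if i == 0 and _MODAL_RE.match(token):
            continue  # modal chromosome number, e.g. "46" or "46-48"
        if i <= 1 and _SEX_RE.match(token):
            continue  # sex designator
        aberrations.append(_classify(token))
    return aberrations


def has_trisomy(record: KaryotypeRecord, chromosome: str) -> bool:
    """True iff a whole-chromosome gain is evidenced by karyotype or aCGH flag."""
    chromosome = str(chromosome)
    in_karyotype = any(
        ab.kind == "chromosome_gain" and ab.chromosome == chromosome
        for ab in record.aberrations
    )
    in_flags = f"aCGH+{chromosome}" in record.acgh_flags
    return in_karyotype or in_flags


def cohort_aneuploidy_rate(
    records: Sequence[KaryotypeRecord], chromosome: str
) -> dict[str, float]:
    """Cohort trisomy tally: ``{n_positive, n_total, percent}``.

    Percent is reported to one decimal, truncated toward zero (8/9 -> 88.8).
    """
    if not records:
        raise ISCNParseError("empty cohort")
    n_pos = sum(has_trisomy(r, chromosome) for r in records)
    n_total = len(records)
    percent = math.floor(1000.0 * n_pos / n_total) / 10.0
    return {"n_positive": n_pos, "n_total": n_total, "percent": percent}


def read_case_table(path: str | Path) -> list[KaryotypeRecord]:
    """Read a TSV with columns case_id, karyotype, acgh_flags (';'-separated)."""
    df = pd.read_csv(path, sep="\t", dtype=str).fillna("")
    for col in ("case_id", "karyotype"):
        if col not in df.columns:
            raise ISCNParseError(f"{path}: missing column {col!r}")
    records = []
    for _, row in df.iterrows():
        flags = row.get("acgh_flags", "")
        records.append(
            KaryotypeRecord.from_strings(
                row["case_id"], row["karyotype"], flags.split(";") if flags else ()
            )
        )
    return records
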