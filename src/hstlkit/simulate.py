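"""Synthetic HSTL-like cohort generator with ground-truth manifests.

Emulates the statistical structure the analysis assumes so every stage is
testable without external downloads: chromosome-7 copy-number archetypes
(isochromosome 7q cases with whole-arm 7p loss / 7q gain, ring-7 cases with
terminal losses at the TCRG/TCRB breakpoints and sub-arm 7q gain plus a
selectively amplified interval), a case-4-like complex profile that sets the
proximal CDR boundary, trisomy 8 at the cohort rate with a karyotype/aCGH
evidence split, planted consistently up/down signature genes, chromosome-7
dosage-effect genes (including a dosage-discordant CDR-up gene emulating
CHN2), Gaussian log2 microarray noise with optional lab batch offsets, and
a negative-binomial count arm for the RNA-seq-style comparisons.

All randomness flows from the mandatory config seed; equal seeds give
byte-identical cohorts.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from . import published
from .diffexpr import CountMatrix, ExpressionMatrix, log_fpkm_matrix
from .fusions import FusionCall
from .karyotype import KaryotypeRecord
from .segments import ArmModel, Segment, expand_aberration


class SimulationError(ValueError):
    pass


@dataclass
class CohortConfig:
    """Study-condition knobs for the synthetic cohort; the defaults follow the
    profiled cohort (6 isochromosome + 3 ring cases, trisomy-8 rate 8/9,
    breakpoints and regions at the printed coordinates)."""

    seed: int
    # genomic arm
    n_i7q: int = 6
    n_r7: int = 3
    n_complex: int = 1  # i(7)(q10) cases with a case-4-like proximal 7p loss
    arm_model: ArmModel = field(default_factory=lambda: published.CHR7_ARM)
    chr8_arm: ArmModel = field(default_factory=lambda: published.CHR8_ARM)
    r7_breakpoints: tuple[int, int] = (
        published.TCRG_BREAKPOINT_BP,
        published.TCRB_BREAKPOINT_BP,
    )
    complex_7p_loss: tuple[int, int] = published.CASE4_7P_LOSS
    cgr: tuple[int, int] = published.CGR
    sar: tuple[int, int] = published.SAR
    sar_copies: float = 5.0
    gain_margin_bp: int = 12_000_000  # per-case extension beyond the common gain
    breakpoint_jitter_bp: int = 0
    trisomy8_rate: float = 8.0 / 9.0
    acgh_only_trisomy_fraction: float = 3.0 / 8.0
    # expression arm
    n_genes: int = 2000
    n_reference_samples: int = 10
    n_hstl_samples: int = 10
    n_signature_up: int = 11
    n_signature_down: int = 13
    signature_effect_log2: float = 2.0
    n_cdr_genes: int = 60
    n_cgr_genes: int = 60
    n_chr8_genes: int = 40
    dosage_loss_effect_log2: float = -1.0
    dosage_gain_effect_log2: float = 1.0
    chr8_gain_effect_log2: float = 0.585
    n_dosage_discordant: int = 1
    discordant_effect_log2: float = 2.0
    noise_sd_log2: float = 0.5
    batch_sd_log2: float = 0.0
    n_labs: int = 2
    baseline_mean_log2: float = 7.0
    baseline_sd_log2: float = 1.5
    nb_dispersion: float = 0.1
    fpkm_pseudocount: float = 1.0

    def __post_init__(self) -> None:
        if self.seed is None:
            raise SimulationError("seed is mandatory")
        for name in ("n_i7q", "n_r7", "n_complex", "n_genes"):
            if getattr(self, name) < 0:
                raise SimulationError(f"{name} must be >= 0")
        if self.n_complex > self.n_i7q:
            raise SimulationError("n_complex cannot exceed n_i7q")
        planted = (
            self.n_signature_up
            + self.n_signature_down
            + self.n_cdr_genes
            + self.n_cgr_genes
            + self.n_chr8_genes
        )
        if planted > self.n_genes:
            raise SimulationError("planted gene count exceeds n_genes")

    @classmethod
    def null(cls, seed: int, **overrides) -> "CohortConfig":
        """A cohort with no planted expression effects (type-I error checks)."""
        defaults = dict(
            n_signature_up=0,
            n_signature_down=0,
            n_dosage_discordant=0,
            dosage_loss_effect_log2=0.0,
            dosage_gain_effect_log2=0.0,
            chr8_gain_effect_log2=0.0,
            discordant_effect_log2=0.0,
        )
        defaults.update(overrides)
        return cls(seed=seed, **defaults)


MA_GROUPS = ("HSTL", "PTCL", "NKTCL", "AITCL", "TCELLS", "GDTCELLS", "SPLEEN")
RNASEQ_GROUPS = ("HSTL", "PTCL", "TALL", "SPLEEN", "THYMUS")


def _rng(config: CohortConfig, stream: int) -> np.random.Generator:
    return np.random.default_rng([int(config.seed) % (2**31), stream])


def _case_ids(config: CohortConfig) -> tuple[list[str], list[str]]:
    i7q = [f"HSTL_i7q_{k + 1:02d}" for k in range(config.n_i7q)]
    r7 = [f"HSTL_r7_{k + 1:02d}" for k in range(config.n_r7)]
    return i7q, r7


def _jitter(rng: np.random.Generator, bp: int, amount: int, lo: int, hi: int) -> int:
    if amount <= 0:
        return bp
    return int(np.clip(bp + rng.integers(-amount, amount + 1), lo, hi))


def gen_segments(config: CohortConfig) -> tuple[list[Segment], dict]:
    """Per-case chromosome-7 (and trisomy-8) segments plus a truth manifest.

    The manifest records the intended common deleted/gained/amplified
    regions computed from the planted per-case intervals, so downstream
    derivation can be verified without re-deriving intent.
    """
    rng = _rng(config, 1)
    arm = config.arm_model
    p_lo, p_hi = arm.p_arm
    q_lo, q_hi = arm.q_arm
    b_p, b_q = config.r7_breakpoints
    jit = config.breakpoint_jitter_bp
    i7q_ids, r7_ids = _case_ids(config)

    segments: list[Segment] = []
    loss_intervals: dict[str, tuple[int, int]] = {}
    gain_intervals: dict[str, tuple[int, int]] = {}
    archetypes: dict[str, str] = {}

    for k, cid in enumerate(i7q_ids):
        archetypes[cid] = "i7q"
        if k < config.n_complex:
            archetypes[cid] = "i7q_complex"
            s, e = config.complex_7p_loss
            s = _jitter(rng, s, jit, 2, p_hi)
            e = _jitter(rng, e, jit, s, arm.q_end_bp)
            loss = (s, e)
        else:
            loss = (p_lo, p_hi)
        gain = (q_lo, q_hi)
        loss_intervals[cid] = loss
        gain_intervals[cid] = gain
        segments.append(Segment(cid, arm.chromosome, *loss, "loss"))
        segments.append(Segment(cid, arm.chromosome, *gain, "gain"))

    cgr_s, cgr_e = config.cgr
    for k, cid in enumerate(r7_ids):
        archetypes[cid] = "r7"
        tcrg = _jitter(rng, b_p, jit, 2, cgr_s - 1)
        tcrb = _jitter(rng, b_q, jit, cgr_e + 1, arm.q_end_bp)
        segments.append(Segment(cid, arm.chromosome, p_lo, tcrg, "loss"))
        segments.append(Segment(cid, arm.chromosome, tcrb, arm.q_end_bp, "loss"))
        loss_intervals[cid] = (p_lo, tcrg)  # p-arm footprint drives the CDR
        # sub-arm gains: the first case is flush with the common start, the
        # second flush with the common end, so their intersection is exact
        left = 0 if k == 0 else int(rng.integers(0, config.gain_margin_bp + 1))
        right = 0 if k == 1 or config.n_r7 == 1 else int(
            rng.integers(0, config.gain_margin_bp + 1)
        )
        gain = (max(q_lo, cgr_s - left), min(tcrb - 1, cgr_e + right))
        gain_intervals[cid] = gain
        segments.append(Segment(cid, arm.chromosome, *gain, "gain"))
        segments.append(
            Segment(cid, arm.chromosome, *config.sar, "amplification", config.sar_copies)
        )

    all_ids = i7q_ids + r7_ids
    n_cases = len(all_ids)
    n_tri = int(round(config.trisomy8_rate * n_cases))
    trisomy_ids = sorted(rng.choice(all_ids, size=n_tri, replace=False).tolist())
    for cid in trisomy_ids:
        segments.extend(
            expand_aberration("whole_chromosome_gain", config.chr8_arm, cid)
        )
    n_acgh_only = int(np.floor(config.acgh_only_trisomy_fraction * n_tri))
    acgh_only = sorted(
        rng.choice(trisomy_ids, size=n_acgh_only, replace=False).tolist()
    )

    manifest = {
        "cdr": _common_interval(loss_intervals.values()) if loss_intervals else None,
        "cgr": _common_interval(gain_intervals.values()) if gain_intervals else None,
        "sar": tuple(config.sar) if config.n_r7 > 0 else None,
        "archetypes": archetypes,
        "loss_intervals": loss_intervals,
        "gain_intervals": gain_intervals,
        "trisomy8_cases": trisomy_ids,
        "acgh_only_trisomy_cases": acgh_only,
        "n_cases": n_cases,
    }
    return segments, manifest


def _common_interval(intervals) -> tuple[int, int] | None:
    intervals = list(intervals)
    start = max(s for s, _ in intervals)
    end = min(e for _, e in intervals)
    return (start, end) if start <= end else None


def gen_karyotypes(manifest: dict) -> list[KaryotypeRecord]:
    """ISCN strings synthesized from each case's archetype.

    Trisomy-8 evidence is split between the karyotype channel (",+8") and
    the aCGH annotation channel ("aCGH+8") per the manifest, mirroring
    cohorts where cytogenetics misses the gain in low-tumor-burden samples.
    """
    records = []
    acgh_only = set(manifest["acgh_only_trisomy_cases"])
    trisomy = set(manifest["trisomy8_cases"])
    for cid, archetype in manifest["archetypes"].items():
        core = "r(7)(p22q36)" if archetype == "r7" else "i(7)(q10)"
        has_tri = cid in trisomy
        in_karyotype = has_tri and cid not in acgh_only
        modal = 47 if in_karyotype else 46
        tokens = [str(modal), "XY", core] + (["+8"] if in_karyotype else [])
        flags = ("aCGH+8",) if (has_tri and cid in acgh_only) else ()
        records.append(
            KaryotypeRecord.from_strings(cid, ",".join(tokens), flags)
        )
    return records


# ---------------------------------------------------------------------------
# expression arm


def _gene_metadata(config: CohortConfig) -> pd.DataFrame:
    """Deterministic gene placement: CDR, CGR and chr8 blocks, rest elsewhere."""
    n = config.n_genes
    genes = [f"G{k + 1:05d}" for k in range(n)]
    chroms = np.array(["1"] * n, dtype=object)
    positions = np.zeros(n, dtype=int)
    cursor = 0

    def place(count: int, chrom: str, lo: int, hi: int) -> slice:
        nonlocal cursor
        sl = slice(cursor, cursor + count)
        chroms[sl] = chrom
        positions[sl] = np.linspace(lo, hi, count, dtype=int) if count else []
        cursor += count
        return sl

    cdr_lo, cdr_hi = published.CDR
    cdr_sl = place(config.n_cdr_genes, "7", cdr_lo, cdr_hi)
    cgr_lo, cgr_hi = config.cgr
    cgr_sl = place(config.n_cgr_genes, "7", cgr_lo, cgr_hi)
    chr8_sl = place(config.n_chr8_genes, "8", 1_000_000, 140_000_000)
    rest = n - cursor
    other_chroms = [c for c in map(str, range(1, 23)) if c not in ("7", "8")]
    for k in range(rest):
        chroms[cursor + k] = other_chroms[k % len(other_chroms)]
        positions[cursor + k] = 1_000_000 + 10_000 * k
    df = pd.DataFrame({"chromosome": chroms, "position": positions}, index=genes)
    df.attrs["cdr_slice"] = cdr_sl
    df.attrs["cgr_slice"] = cgr_sl
    df.attrs["chr8_slice"] = chr8_sl
    return df


def _assign_roles(config: CohortConfig, meta: pd.DataFrame) -> dict[str, list[str]]:
    genes = list(meta.index)
    cdr = genes[meta.attrs["cdr_slice"]]
    cgr = genes[meta.attrs["cgr_slice"]]
    chr8 = genes[meta.attrs["chr8_slice"]]
    n_planted_region = len(cdr) + len(cgr) + len(chr8)
    pool = genes[n_planted_region:]
    sig_up = pool[: config.n_signature_up]
    sig_down = pool[config.n_signature_up : config.n_signature_up + config.n_signature_down]
    discordant = cdr[: config.n_dosage_discordant]
    return {
        "signature_up": sig_up,
        "signature_down": sig_down,
        "cdr_genes": cdr,
        "cgr_genes": cgr,
        "chr8_genes": chr8,
        "dosage_discordant": discordant,
    }


def _hstl_shift(config: CohortConfig, meta: pd.DataFrame, roles: dict) -> pd.Series:
    shift = pd.Series(0.0, index=meta.index)
    shift[roles["signature_up"]] = config.signature_effect_log2
    shift[roles["signature_down"]] = -config.signature_effect_log2
    shift[roles["cdr_genes"]] = config.dosage_loss_effect_log2
    shift[roles["dosage_discordant"]] = config.discordant_effect_log2
    shift[roles["cgr_genes"]] = config.dosage_gain_effect_log2
    shift[roles["chr8_genes"]] = config.chr8_gain_effect_log2
    return shift


def _sample_frame(groups: Sequence[str], config: CohortConfig, tag: str) -> pd.DataFrame:
    rows = []
    for group in groups:
        n = config.n_hstl_samples if group == "HSTL" else config.n_reference_samples
        for k in range(n):
            rows.append(
                {
                    "sample": f"{group}_{tag}_{k + 1:02d}",
                    "group": group,
                    "lab": f"lab{k % config.n_labs + 1}",
                }
            )
    return pd.DataFrame(rows).set_index("sample")


def gen_expression(config: CohortConfig) -> dict:
    """Microarray- and RNA-seq-style matrices with a planted-truth manifest.

    Returns ``{"microarray": ExpressionMatrix, "rnaseq": ExpressionMatrix,
    "counts": CountMatrix, "gene_metadata": DataFrame, "truth": dict}``.
    The RNA-seq expression matrix is log2(FPKM + pseudocount) computed from
    the negative-binomial counts.
    """
    meta = _gene_metadata(config)
    roles = _assign_roles(config, meta)
    shift = _hstl_shift(config, meta, roles)
    rng = _rng(config, 2)
    base = rng.normal(config.baseline_mean_log2, config.baseline_sd_log2, config.n_genes)
    base = pd.Series(base, index=meta.index)

    # microarray arm: Gaussian log2 noise, optional additive lab offsets
    ma_samples = _sample_frame(MA_GROUPS, config, "MA")
    mu = np.tile(base.to_numpy()[:, None], (1, len(ma_samples)))
    is_hstl = (ma_samples["group"] == "HSTL").to_numpy()
    mu[:, is_hstl] += shift.to_numpy()[:, None]
    values = mu + rng.normal(0.0, config.noise_sd_log2, mu.shape)
    if config.batch_sd_log2 > 0:
        labs = sorted(ma_samples["lab"].unique())
        offsets = {lab: rng.normal(0.0, config.batch_sd_log2, config.n_genes) for lab in labs}
        for j, lab in enumerate(ma_samples["lab"]):
            values[:, j] += offsets[lab]
    microarray = ExpressionMatrix(
        values=pd.DataFrame(values, index=meta.index, columns=ma_samples.index),
        groups=ma_samples["group"],
        labs=ma_samples["lab"],
        platform="microarray",
    )

    # RNA-seq arm: negative-binomial counts around the planted FPKM profile
    rs_samples = _sample_frame(RNASEQ_GROUPS, config, "RNA")
    gene_length = pd.Series(
        rng.integers(500, 10_001, config.n_genes), index=meta.index, name="length"
    )
    mapped = pd.Series(
        rng.integers(20_000_000, 40_000_001, len(rs_samples)),
        index=rs_samples.index,
        name="mapped_reads",
    )
    x = np.tile(base.to_numpy()[:, None], (1, len(rs_samples)))
    x[:, (rs_samples["group"] == "HSTL").to_numpy()] += shift.to_numpy()[:, None]
    target_fpkm = np.maximum(np.exp2(x) - config.fpkm_pseudocount, 0.0)
    mu_counts = (
        target_fpkm
        * (gene_length.to_numpy()[:, None] / 1e3)
        * (mapped.to_numpy()[None, :] / 1e6)
    )
    alpha = config.nb_dispersion
    if alpha > 0:
        n_param = 1.0 / alpha
        p_param = n_param / (n_param + np.maximum(mu_counts, 1e-12))
        counts = rng.negative_binomial(n_param, p_param)
        counts[mu_counts == 0] = 0
    else:
        counts = rng.poisson(mu_counts)
    count_matrix = CountMatrix(
        counts=pd.DataFrame(counts, index=meta.index, columns=rs_samples.index),
        gene_length_bp=gene_length,
        mapped_reads=mapped,
    )
    rnaseq = log_fpkm_matrix(
        count_matrix,
        groups=rs_samples["group"],
        labs=rs_samples["lab"],
        pseudocount=config.fpkm_pseudocount,
    )

    truth = {
        "roles": roles,
        "hstl_shift_log2": shift,
        "planted_consistent": sorted(roles["signature_up"] + roles["signature_down"]),
    }
    return {
        "microarray": microarray,
        "rnaseq": rnaseq,
        "counts": count_matrix,
        "gene_metadata": meta,
        "truth": truth,
    }


# ---------------------------------------------------------------------------
# fusion-call tables


@dataclass
class FusionSimConfig:
    """Mixture of calls spanning every filter stage."""

    seed: int
    n_samples: int = 4
    n_true_recurrent: int = 3
    n_low_both: int = 2
    n_split_only: int = 2  # spanning below threshold, split above
    n_adjacent: int = 2
    n_in_normals: int = 2
    n_private: int = 2


def gen_fusion_calls(
    config: FusionSimConfig,
    min_spanning: int = 8,
    min_split: int = 5,
) -> tuple[list[FusionCall], dict]:
    """Truth-labeled fusion tables; the manifest carries per-rule truth sets.

    Split-only calls (spanning below, split above threshold) survive the
    literal conjunction reading but not the disjunction reading, so the
    truth manifest records both retained sets keyed by rule.
    """
    rng = np.random.default_rng([int(config.seed) % (2**31), 7])
    samples = [f"HSTL_{k + 1:02d}" for k in range(config.n_samples)]
    calls: list[FusionCall] = []
    conj_truth: list[FusionCall] = []
    disj_truth: list[FusionCall] = []
    counter = 0

    def pair() -> tuple[str, str]:
        nonlocal counter
        counter += 1
        return (f"FUS{counter:03d}A", f"FUS{counter:03d}B")

    def two_samples() -> list[str]:
        return sorted(rng.choice(samples, size=2, replace=False).tolist())

    def high_span() -> int:
        return int(rng.integers(min_spanning, min_spanning + 20))

    def high_split() -> int:
        return int(rng.integers(min_split, min_split + 20))

    for _ in range(config.n_true_recurrent):
        g5, g3 = pair()
        for sid in two_samples():
            call = FusionCall(sid, g5, g3, high_span(), high_split())
            calls.append(call)
            conj_truth.append(call)
            disj_truth.append(call)
    for _ in range(config.n_low_both):
        g5, g3 = pair()
        for sid in two_samples():
            calls.append(
                FusionCall(
                    sid,
                    g5,
                    g3,
                    int(rng.integers(0, min_spanning)),
                    int(rng.integers(0, min_split)),
                )
            )
    for _ in range(config.n_split_only):
        g5, g3 = pair()
        for sid in two_samples():
            call = FusionCall(
                sid, g5, g3, int(rng.integers(0, min_spanning)), high_split()
            )
            calls.append(call)
            conj_truth.append(call)  # survives the conjunction reading only
    for _ in range(config.n_adjacent):
        g5, g3 = pair()
        for sid in two_samples():
            calls.append(
                FusionCall(sid, g5, g3, high_span(), high_split(), adjacent_genes=True)
            )
    for _ in range(config.n_in_normals):
        g5, g3 = pair()
        for sid in two_samples():
            calls.append(
                FusionCall(sid, g5, g3, high_span(), high_split(), seen_in_normals=True)
            )
    for _ in range(config.n_private):
        g5, g3 = pair()
        sid = str(rng.choice(samples))
        calls.append(FusionCall(sid, g5, g3, high_span(), high_split()))

    order = rng.permutation(len(calls))
    calls = [calls[i] for i in order]
    truth = {
        "conjunction": conj_truth,
        "disjunction": disj_truth,
    }
    return calls, truth
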