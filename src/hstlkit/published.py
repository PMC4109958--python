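"""Published hepatosplenic T-cell lymphoma (HSTL) study inputs.

Structured constants transcribed from the printed cohort report: the nine
case karyotypes with their aCGH annotations, the per-case chromosome-7
copy-number intervals (hg19), the r(7) breakpoints at the TCRG and TCRB
loci, and the 24-gene HSTL signature with representative gene coordinates.
These are *inputs* to the analysis — the common-region, aneuploidy-rate and
region-overlap computations are re-run on them, never looked up.
"""

from __future__ import annotations

from .segments import ArmModel, Segment

# hg19 chromosome scaffolding; the centromere gap is not printed in
# cytogenetic reports, so the p-side boundary is a packaged fixture
# (overridable wherever an ArmModel is accepted).
CHR7_ARM = ArmModel(
    chromosome="7",
    centromere_start_bp=57_900_000,
    centromere_end_bp=61_900_000,
    q_end_bp=159_138_663,
)
CHR8_ARM = ArmModel(
    chromosome="8",
    centromere_start_bp=43_800_000,
    centromere_end_bp=46_800_000,
    q_end_bp=146_364_022,
)

#: r(7) terminal-loss breakpoints: 7p14.1/TCRG and 7q32/TCRB
TCRG_BREAKPOINT_BP = 38_406_226
TCRB_BREAKPOINT_BP = 142_502_221

#: printed common regions (for cross-checking derived output, not as input)
CDR = (3_506_316, 38_406_226)   # common deleted region, 7p22.1p14.1
CGR = (86_259_620, 124_892_276)  # common gained region, 7q22.11q31.1
SAR = (86_259_620, 99_271_246)   # smaller amplified region within the CGR

#: printed 7q gain intervals of the two r(7) cases whose intersection
#: defines the CGR: case 1 7q21.12q33, case 3 7q21.11q31.33
R7_GAINS = {
    "case1": (86_259_620, 137_506_193),
    "case3": (79_158_260, 124_892_276),
}

#: case 4's monoallelic 7p loss (7p22.1p11) from its complex profile
CASE4_7P_LOSS = (3_506_316, 57_883_626)

R7_CASES = ("case1", "case2", "case3")
I7Q_CASES = ("case4", "case5", "case6", "case7", "case8", "case9")


def cohort_7p_loss_segments(arm: ArmModel = CHR7_ARM) -> list[Segment]:
    """The per-case 7p loss calls: r(7) cases as terminal losses up to the
    TCRG breakpoint, case 4 as its printed monoallelic loss, the remaining
    i(7)(q10) cases as whole-7p losses."""
    segs = [
        Segment(cid, arm.chromosome, arm.p_start_bp, TCRG_BREAKPOINT_BP, "loss")
        for cid in R7_CASES
    ]
    segs.append(Segment("case4", arm.chromosome, *CASE4_7P_LOSS, "loss"))
    p_lo, p_hi = arm.p_arm
    segs.extend(
        Segment(cid, arm.chromosome, p_lo, p_hi, "loss")
        for cid in I7Q_CASES
        if cid != "case4"
    )
    return segs


def cohort_7q_gain_segments(arm: ArmModel = CHR7_ARM) -> list[Segment]:
    """The printed sub-arm 7q gains of r(7) cases 1 and 3."""
    return [
        Segment(cid, arm.chromosome, s, e, "gain") for cid, (s, e) in R7_GAINS.items()
    ]


#: the nine case karyotypes (ISCN 2013) with aCGH trisomy-8 annotations
TABLE1_CASES: list[tuple[str, str, tuple[str, ...]]] = [
    ("case1", "46-48,XY,r(7),inc[8]", ()),
    ("case2", "47,XY,r(7)(p22q36),+8", ()),
    ("case3", "47,XX,r(7),+8,der(19)t(?;19)(?;p13)", ()),
    (
        "case4",
        "45-46,X,-Y,-4,der(7)add(7)(p22)add(7)(q32),i(7)(q10),+i(7)(q10),"
        "der(8)t(1;8)(q21;p23),-22,+mar1,+mar2[cp11]",
        ("aCGH+8",),
    ),
    ("case5", "46-47,XY,add(4)(p16),i(7)(q10),+8,+mar[cp6]", ()),
    ("case6", "43-45,X,-Y,i(7)(q10)[cp7]", ("aCGH+8",)),
    (
        "case7",
        "40-48,XY,+X,-5,i(7)(q10),+8,+10,add(11)(q22),inc[cp12]",
        ("aCGH+8",),
    ),
    (
        "case8",
        "46-47,XX,i(7)(q10),+i(7)(q10),+8,-10,add(15)(q26),add(22)(q13)[cp12]",
        (),
    ),
    ("case9", "46,XY,add(5)(q?),i(7)(q10),-10[cp15]", ("aCGH+8",)),
]


#: the 24-gene HSTL signature: (symbol, chromosome, representative position, direction)
SIGNATURE_GENES: list[tuple[str, str, int, str]] = [
    ("ABCB1", "7", 87_133_175, "up"),
    ("CD200R1", "3", 112_640_056, "up"),
    ("CD5L", "1", 157_800_704, "up"),
    ("ITGAD", "16", 31_404_633, "up"),
    ("PPP1R9A", "7", 94_536_948, "up"),
    ("S1PR5", "19", 10_623_623, "up"),
    ("TMEM178A", "2", 39_892_122, "up"),
    ("CHN2", "7", 29_234_120, "up"),
    ("CHSY3", "5", 129_240_165, "up"),
    ("FCRLB", "1", 161_691_353, "up"),
    ("PRDM16", "1", 2_985_732, "up"),
    ("CCR7", "17", 38_710_021, "down"),
    ("CD200", "3", 112_051_915, "down"),
    ("CD28", "2", 204_571_198, "down"),
    ("CD5", "11", 60_869_867, "down"),
    ("CD83", "6", 14_117_872, "down"),
    ("CXCR3", "X", 70_835_766, "down"),
    ("GPR183", "13", 99_946_784, "down"),
    ("SLAMF1", "1", 160_577_890, "down"),
    ("FAM134B", "5", 16_473_147, "down"),
    ("GZMK", "5", 54_320_081, "down"),
    ("CAMK4", "5", 110_559_351, "down"),
    ("PRRX1", "1", 170_631_869, "down"),
    ("CCL19", "9", 34_689_564, "down"),
]
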