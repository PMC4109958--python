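"""Two-group differential expression, cutoff grids and cross-comparison consistency.

The inference model is a per-gene general linear model: expression ~
intercept + group indicator (+ optional lab-of-origin dummies). Without
the covariate this is exactly the pooled-variance two-sample t-test. Each
comparison of the suite (tumor vs one reference group, on either the
microarray or the RNA-seq arm) gets its own Benjamini-Hochberg adjustment;
per-comparison hits at the fold-change/FDR cutoffs are merged into a gene x
comparison signed fold-change grid, from which consistently up- or
down-regulated genes are selected.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .segments import Region

GROUPS = (
    "HSTL",
    "PTCL",
    "NKTCL",
    "AITCL",
    "TALL",
    "TCELLS",
    "GDTCELLS",
    "SPLEEN",
    "THYMUS",
)

#: the default 10-comparison suite: (platform, reference group)
DEFAULT_SUITE: tuple[tuple[str, str], ...] = (
    ("microarray", "PTCL"),
    ("microarray", "NKTCL"),
    ("microarray", "AITCL"),
    ("microarray", "TCELLS"),
    ("microarray", "GDTCELLS"),
    ("microarray", "SPLEEN"),
    ("rnaseq", "PTCL"),
    ("rnaseq", "TALL"),
    ("rnaseq", "SPLEEN"),
    ("rnaseq", "THYMUS"),
)


class DiffExprError(ValueError):
    pass


@dataclass
class ExpressionMatrix:
    """Genes x samples log2 expression with per-sample group and lab labels."""

    values: pd.DataFrame  # index: gene_ids, columns: sample_ids
    groups: pd.Series  # index: sample_ids
    labs: pd.Series | None = None
    platform: str = "microarray"

    def __post_init__(self) -> None:
        if self.values.index.has_duplicates or self.values.index.isna().any():
            raise DiffExprError("gene ids must be unique and non-missing")
        if not self.values.columns.equals(self.groups.index):
            self.groups = self.groups.reindex(self.values.columns)
        if self.groups.isna().any():
            raise DiffExprError("every sample needs a group label")
        if not np.isfinite(self.values.to_numpy(dtype=float)).all():
            raise DiffExprError("expression values must be finite")
        if self.labs is not None:
            self.labs = self.labs.reindex(self.values.columns)

    @property
    def gene_ids(self) -> pd.Index:
        return self.values.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.values.columns

    def samples_in_group(self, group: str) -> list[str]:
        return list(self.groups.index[self.groups == group])


@dataclass
class CountMatrix:
    """Genes x samples integer read counts with gene lengths and library sizes."""

    counts: pd.DataFrame
    gene_length_bp: pd.Series
    mapped_reads: pd.Series

    def __post_init__(self) -> None:
        arr = self.counts.to_numpy()
        if (arr < 0).any() or not np.array_equal(arr, np.floor(arr)):
            raise DiffExprError("counts must be non-negative integers")
        self.gene_length_bp = self.gene_length_bp.reindex(self.counts.index)
        if (self.gene_length_bp < 1).any() or self.gene_length_bp.isna().any():
            raise DiffExprError("gene lengths must be >= 1 bp")
        self.mapped_reads = self.mapped_reads.reindex(self.counts.columns)


# ---------------------------------------------------------------------------
# core statistics


def signed_fc(delta_log2: float | np.ndarray) -> float | np.ndarray:
    """Signed fold change: +2^d for d >= 0, -2^(-d) for d < 0 (never in (-1, 1))."""
    d = np.asarray(delta_log2, dtype=float)
    if not np.isfinite(d).all():
        raise DiffExprError("delta_log2 must be finite")
    out = np.where(d >= 0, np.exp2(d), -np.exp2(-d))
    return float(out) if np.isscalar(delta_log2) or out.ndim == 0 else out


def bh_fdr(p_values: Sequence[float] | np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted q-values, input order preserved."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if ((p < 0) | (p > 1)).any() or not np.isfinite(p).all():
        raise DiffExprError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def fit_two_group(
    matrix: ExpressionMatrix,
    group_a: str,
    group_b: str,
    adjust_lab: bool = False,
) -> pd.DataFrame:
    """Per-gene GLM contrast of ``group_a`` minus ``group_b``.

    Returns a DataFrame indexed by gene with columns delta_log2, signed_fc,
    t_statistic, p_value, q_value (BH over all genes of the matrix).
    ``adjust_lab=True`` adds lab-of-origin dummy covariates to absorb batch
    offsets. Genes with zero residual variance and equal means get p = 1.
    """
    if group_a == group_b:
        raise DiffExprError("groups must be disjoint")
    samples_a = matrix.samples_in_group(group_a)
    samples_b = matrix.samples_in_group(group_b)
    for g, s in ((group_a, samples_a), (group_b, samples_b)):
        if len(s) < 2:
            raise DiffExprError(f"group {g!r} has fewer than 2 samples")
    cols = samples_a + samples_b
    y = matrix.values[cols].to_numpy(dtype=float)  # genes x n
    n = len(cols)
    indicator = np.array([1.0] * len(samples_a) + [0.0] * len(samples_b))
    design = [np.ones(n), indicator]
    if adjust_lab:
        if matrix.labs is None:
            raise DiffExprError("adjust_lab=True requires lab labels")
        labs = matrix.labs[cols]
        for lab in sorted(labs.dropna().unique())[1:]:  # reference level dropped
            design.append((labs == lab).to_numpy(dtype=float))
    X = np.column_stack(design)
    df_resid = n - np.linalg.matrix_rank(X)
    if df_resid < 1:
        raise DiffExprError("no residual degrees of freedom")

    XtX_inv = np.linalg.pinv(X.T @ X)
    H = XtX_inv @ X.T
    beta = y @ H.T  # genes x p
    resid = y - beta @ X.T
    sigma2 = (resid**2).sum(axis=1) / df_resid
    se = np.sqrt(np.maximum(sigma2 * XtX_inv[1, 1], 0.0))
    delta = beta[:, 1]
    with np.errstate(divide="ignore", invalid="ignore"):
        t = delta / se
    # degenerate genes: zero residual variance
    zero_se = se == 0
    t[zero_se & (delta == 0)] = 0.0
    t[zero_se & (delta > 0)] = np.inf
    t[zero_se & (delta < 0)] = -np.inf
    p = 2.0 * stats.t.sf(np.abs(t), df_resid)
    p[zero_se & (delta == 0)] = 1.0
    return pd.DataFrame(
        {
            "delta_log2": delta,
            "signed_fc": signed_fc(delta),
            "t_statistic": t,
            "p_value": p,
            "q_value": bh_fdr(p),
        },
        index=matrix.gene_ids,
    )


def apply_cutoffs(
    results: pd.DataFrame, abs_fc_min: float = 2.0, fdr_max: float = 0.05
) -> pd.DataFrame:
    """Genes with |signed FC| >= abs_fc_min and q <= fdr_max (both inclusive)."""
    keep = (results["signed_fc"].abs() >= abs_fc_min) & (results["q_value"] <= fdr_max)
    return results.loc[keep]


# ---------------------------------------------------------------------------
# the comparison suite


@dataclass
class ComparisonSuite:
    """Labeled per-comparison DE tables, each with its own BH adjustment."""

    tables: dict[str, pd.DataFrame]
    target_group: str = "HSTL"

    @property
    def comparison_ids(self) -> list[str]:
        return list(self.tables)

    def __len__(self) -> int:
        return len(self.tables)


def comparison_id(platform: str, reference: str) -> str:
    tag = {"microarray": "MA", "rnaseq": "RNAseq"}.get(platform, platform)
    return f"{tag}:vs_{reference}"


def run_comparison_suite(
    matrices: Mapping[str, ExpressionMatrix],
    suite: Sequence[tuple[str, str]] = DEFAULT_SUITE,
    target_group: str = "HSTL",
    adjust_lab: bool = False,
) -> ComparisonSuite:
    """Run one two-group inference per (platform, reference-group) pair."""
    tables: dict[str, pd.DataFrame] = {}
    for platform, reference in suite:
        if platform not in matrices:
            raise DiffExprError(f"no matrix for platform {platform!r}")
        matrix = matrices[platform]
        if reference not in set(matrix.groups):
            raise DiffExprError(
                f"reference group {reference!r} absent from the {platform} matrix"
            )
        tables[comparison_id(platform, reference)] = fit_two_group(
            matrix, target_group, reference, adjust_lab=adjust_lab
        )
    return ComparisonSuite(tables=tables, target_group=target_group)


@dataclass
class ConsistencyTable:
    """Gene x comparison grid of signed FC where the gene passed the cutoffs."""

    grid: pd.DataFrame  # NaN where the gene did not pass

    @property
    def n_up(self) -> pd.Series:
        return (self.grid > 0).sum(axis=1)

    @property
    def n_down(self) -> pd.Series:
        return (self.grid < 0).sum(axis=1)

    @property
    def n_significant(self) -> pd.Series:
        return self.grid.notna().sum(axis=1)


def merge_fc_table(
    suite: ComparisonSuite, abs_fc_min: float = 2.0, fdr_max: float = 0.05
) -> ConsistencyTable:
    """Apply cutoffs per comparison, then merge the passing signed FCs."""
    columns = {}
    for cid, table in suite.tables.items():
        passed = apply_cutoffs(table, abs_fc_min, fdr_max)
        columns[cid] = passed["signed_fc"]
    grid = pd.DataFrame(columns)
    all_genes = next(iter(suite.tables.values())).index
    return ConsistencyTable(grid=grid.reindex(all_genes))


def consistency_select(table: ConsistencyTable, min_comparisons: int) -> list[str]:
    """Genes significant with one consistent sign in >= min_comparisons comparisons.

    A single opposite-sign significance disqualifies a gene. Monotone:
    raising ``min_comparisons`` never adds genes.
    """
    if min_comparisons < 1:
        raise DiffExprError("min_comparisons must be >= 1")
    n_up, n_down = table.n_up, table.n_down
    keep = ((n_up >= min_comparisons) & (n_down == 0)) | (
        (n_down >= min_comparisons) & (n_up == 0)
    )
    return list(table.grid.index[keep])


# ---------------------------------------------------------------------------
# RNA-seq helpers


def fpkm(counts: CountMatrix) -> pd.DataFrame:
    """Fragments per kilobase of exon model per million mapped reads."""
    if (counts.mapped_reads <= 0).any():
        raise DiffExprError("mapped_reads must be positive")
    kb = counts.gene_length_bp.to_numpy(dtype=float)[:, None] / 1e3
    millions = counts.mapped_reads.to_numpy(dtype=float)[None, :] / 1e6
    return pd.DataFrame(
        counts.counts.to_numpy(dtype=float) / (kb * millions),
        index=counts.counts.index,
        columns=counts.counts.columns,
    )


def log_fpkm_matrix(
    counts: CountMatrix,
    groups: pd.Series,
    labs: pd.Series | None = None,
    pseudocount: float = 1.0,
) -> ExpressionMatrix:
    """log2(FPKM + pseudocount) expression matrix for the RNA-seq arm."""
    values = np.log2(fpkm(counts) + pseudocount)
    return ExpressionMatrix(values=values, groups=groups, labs=labs, platform="rnaseq")


def write_expression_tsv(matrix: ExpressionMatrix, path) -> None:
    """Genes x samples TSV with a two-row label header (#group, #lab)."""
    with open(path, "w") as fh:
        fh.write("gene\t" + "\t".join(map(str, matrix.sample_ids)) + "\n")
        fh.write("#group\t" + "\t".join(matrix.groups.astype(str)) + "\n")
        labs = (
            matrix.labs.astype(str)
            if matrix.labs is not None
            else pd.Series("NA", index=matrix.sample_ids)
        )
        fh.write("#lab\t" + "\t".join(labs) + "\n")
        matrix.values.to_csv(fh, sep="\t", header=False)


def read_expression_tsv(path, platform: str = "microarray") -> ExpressionMatrix:
    """Read the two-row-label-header TSV written by :func:`write_expression_tsv`."""
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        group_row = fh.readline().rstrip("\n").split("\t")
        lab_row = fh.readline().rstrip("\n").split("\t")
        if header[0] != "gene" or group_row[0] != "#group" or lab_row[0] != "#lab":
            raise DiffExprError(f"{path}: not an expression TSV (expected gene/#group/#lab header)")
        samples = header[1:]
        values = pd.read_csv(fh, sep="\t", header=None, index_col=0)
    values.columns = samples
    values.index.name = None
    groups = pd.Series(group_row[1:], index=samples)
    labs = pd.Series(lab_row[1:], index=samples)
    if (labs == "NA").all():
        labs = None
    return ExpressionMatrix(values=values, groups=groups, labs=labs, platform=platform)


def region_overlap(
    gene_positions: pd.DataFrame, region: Region
) -> pd.DataFrame:
    """Genes whose representative position falls inside a region (inclusive).

    ``gene_positions`` needs columns ``chromosome`` and ``position``.
    """
    if region.is_empty:
        return gene_positions.iloc[0:0]
    mask = (
        (gene_positions["chromosome"].astype(str) == region.chromosome)
        & (gene_positions["position"] >= region.start_bp)
        & (gene_positions["position"] <= region.end_bp)
    )
    return gene_positions.loc[mask]
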