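"""Minimal gene-signature selection by cluster-integrity-preserving elimination.

The discriminative power of a candidate geneset is judged by whether the
tumor samples form a pure, complete clade in a complete-linkage dendrogram
built on Pearson-correlation distance over robust-center-scaled expression.
Starting from a consistent candidate set, genes are greedily removed
(weakest evidence first) as long as that clade survives in *every* dataset;
the result is 1-minimal — removing any single retained gene breaks the
clade somewhere.

Everything here is deterministic: clustering ties are broken by the
lexicographically smallest member pair and the elimination order is fixed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .diffexpr import ExpressionMatrix

MAD_SCALE = 1.4826  # consistency factor: MAD of a normal ~ sigma / 1.4826


class SignatureError(ValueError):
    pass


# ---------------------------------------------------------------------------
# scaling and distance


def robust_center_scale(matrix: pd.DataFrame) -> tuple[pd.DataFrame, list[str]]:
    """Per-gene robust standardization: (x - median) / (MAD * 1.4826).

    Genes with zero MAD are centered but left unscaled (divisor 1) and
    returned in the flagged list.
    """
    if matrix.shape[1] < 2:
        raise SignatureError("robust scaling needs >= 2 samples")
    values = matrix.to_numpy(dtype=float)
    med = np.median(values, axis=1, keepdims=True)
    mad = np.median(np.abs(values - med), axis=1, keepdims=True)
    flagged = list(matrix.index[(mad == 0).ravel()])
    divisor = np.where(mad == 0, 1.0, mad * MAD_SCALE)
    return pd.DataFrame(
        (values - med) / divisor, index=matrix.index, columns=matrix.columns
    ), flagged


def pearson_distance(matrix: pd.DataFrame) -> pd.DataFrame:
    """Sample-sample distance d = 1 - Pearson r over gene profiles (in [0, 2])."""
    if matrix.shape[0] < 2:
        raise SignatureError("pearson distance needs >= 2 genes per profile")
    values = matrix.to_numpy(dtype=float)
    sd = values.std(axis=0)
    for sample, s in zip(matrix.columns, sd):
        if s == 0:
            raise SignatureError(f"sample {sample!r} has a zero-variance profile")
    r = np.corrcoef(values, rowvar=False)
    d = 1.0 - r
    np.fill_diagonal(d, 0.0)
    d = np.clip(d, 0.0, 2.0)
    return pd.DataFrame(d, index=matrix.columns, columns=matrix.columns)


# ---------------------------------------------------------------------------
# complete-linkage clustering


@dataclass(frozen=True)
class Dendrogram:
    """Agglomerative merge tree: leaves 0..n-1, internal node k = n + merge index."""

    leaves: tuple[str, ...]
    merges: tuple[tuple[int, int, float], ...]

    def __post_init__(self) -> None:
        if len(self.merges) != len(self.leaves) - 1:
            raise SignatureError("a dendrogram over n leaves needs n-1 merges")

    def node_leafsets(self) -> list[frozenset[str]]:
        """Leaf-name set of every node, leaves first then merges in order."""
        sets: list[frozenset[str]] = [frozenset({name}) for name in self.leaves]
        for a, b, _ in self.merges:
            sets.append(sets[a] | sets[b])
        return sets


def hclust_complete(distances: pd.DataFrame) -> Dendrogram:
    """Complete-linkage agglomeration with a deterministic tie-break.

    Candidate merges at the same height are ordered by the lexicographically
    smallest (min leaf, min leaf) pair of the two clusters. Merge heights
    are non-decreasing (complete linkage is reducible).
    """
    d = distances.to_numpy(dtype=float)
    if d.shape[0] != d.shape[1] or not np.allclose(d, d.T, atol=1e-12):
        raise SignatureError("distance matrix must be square and symmetric")
    labels = tuple(str(c) for c in distances.columns)
    n = len(labels)
    if n < 2:
        raise SignatureError("clustering needs >= 2 samples")
    # active clusters: node id -> (representative leaf name, member node ids)
    active: dict[int, tuple[str, list[int]]] = {
        i: (labels[i], [i]) for i in range(n)
    }
    # pairwise complete-link distances between active clusters
    dist: dict[tuple[int, int], float] = {
        (i, j): d[i, j] for i in range(n) for j in range(i + 1, n)
    }
    merges: list[tuple[int, int, float]] = []
    next_id = n
    while len(active) > 1:
        best_key = None
        best = (np.inf, ("", ""))
        for (i, j), dij in dist.items():
            reps = tuple(sorted((active[i][0], active[j][0])))
            cand = (dij, reps)
            if cand < best:
                best = cand
                best_key = (i, j)
        i, j = best_key
        height = best[0]
        rep = min(active[i][0], active[j][0])
        members = active[i][1] + active[j][1]
        del active[i], active[j]
        new_dist = {}
        for k in active:
            dik = dist[(min(i, k), max(i, k))]
            djk = dist[(min(j, k), max(j, k))]
            new_dist[(min(k, next_id), max(k, next_id))] = max(dik, djk)
        dist = {
            key: v for key, v in dist.items() if i not in key and j not in key
        }
        dist.update(new_dist)
        active[next_id] = (rep, members)
        merges.append((i, j, float(height)))
        next_id += 1
    return Dendrogram(leaves=labels, merges=tuple(merges))


def cluster_intact(dendrogram: Dendrogram, target_samples: Iterable[str]) -> bool:
    """True iff some dendrogram node's leaf set is exactly the target set."""
    targets = frozenset(target_samples)
    if not targets:
        raise SignatureError("empty target set")
    unknown = targets - set(dendrogram.leaves)
    if unknown:
        raise SignatureError(f"target samples not in the tree: {sorted(unknown)}")
    return any(ls == targets for ls in dendrogram.node_leafsets())


# ---------------------------------------------------------------------------
# minimal signature search


@dataclass
class SignatureResult:
    genes: list[str]
    ok: bool
    integrity: dict[str, bool]
    elimination_log: list[tuple[str, str, str]] = field(default_factory=list)

    @property
    def message(self) -> str:
        return "minimal signature found" if self.ok else "no valid signature"


def _dataset_intact(
    matrix: ExpressionMatrix,
    genes: Sequence[str],
    target_samples: frozenset[str],
    relaxed_purity: float | None = None,
) -> bool:
    sub = matrix.values.loc[list(genes)]
    scaled, _ = robust_center_scale(sub)
    if len(genes) < 3:
        # Pearson distance degenerates below three genes (undefined on one,
        # always +/-1 on two); use Euclidean distance on the scaled values so
        # elimination can evaluate, and reach, one- and two-gene signatures.
        x = scaled.to_numpy(dtype=float)
        diff = x[:, :, None] - x[:, None, :]
        dist = pd.DataFrame(
            np.sqrt((diff**2).sum(axis=0)),
            index=scaled.columns,
            columns=scaled.columns,
        )
    else:
        try:
            dist = pearson_distance(scaled)
        except SignatureError:
            return False  # a degenerate profile cannot support the clade
    tree = hclust_complete(dist)
    if relaxed_purity is None:
        return cluster_intact(tree, target_samples)
    return _relaxed_intact(tree, target_samples, relaxed_purity)


def _relaxed_intact(
    tree: Dendrogram, targets: frozenset[str], min_purity: float
) -> bool:
    """Non-default predicate: some node holds every target at purity >= theta."""
    for ls in tree.node_leafsets():
        if targets <= ls and len(targets) / len(ls) >= min_purity:
            return True
    return False


def evaluate_integrity(
    genes: Sequence[str],
    datasets: Mapping[str, ExpressionMatrix],
    target_group: str,
    exempt_samples: Mapping[str, Sequence[str]] | None = None,
    relaxed_purity: float | None = None,
) -> dict[str, bool]:
    """Per-dataset flag: do the target-group samples form an exact clade?"""
    flags = {}
    for name, matrix in datasets.items():
        exempt = set((exempt_samples or {}).get(name, ()))
        targets = frozenset(matrix.samples_in_group(target_group)) - exempt
        if not targets:
            raise SignatureError(f"dataset {name!r} has no {target_group} samples")
        flags[name] = _dataset_intact(matrix, genes, targets, relaxed_purity)
    return flags


def minimal_signature(
    candidate_genes: Sequence[str],
    datasets: Mapping[str, ExpressionMatrix] | Sequence[ExpressionMatrix],
    target_group: str,
    gene_scores: Mapping[str, float] | None = None,
    exempt_samples: Mapping[str, Sequence[str]] | None = None,
    relaxed_purity: float | None = None,
) -> SignatureResult:
    """Greedy backward elimination to a 1-minimal discriminative geneset.

    Candidates are visited weakest-evidence-first (ascending ``gene_scores``,
    typically the minimum |signed FC| across comparisons; ties and missing
    scores fall back to gene id). A removal is accepted iff the target clade
    stays intact in every dataset; passes repeat until none is accepted.
    If even the full candidate set fails integrity somewhere, an explicit
    "no valid signature" result is returned.
    """
    if not isinstance(datasets, Mapping):
        datasets = {f"dataset{i}": m for i, m in enumerate(datasets)}
    candidates = list(dict.fromkeys(candidate_genes))
    log: list[tuple[str, str, str]] = []
    if not candidates:
        return SignatureResult([], False, {k: False for k in datasets}, log)
    flags = evaluate_integrity(
        candidates, datasets, target_group, exempt_samples, relaxed_purity
    )
    if not all(flags.values()):
        return SignatureResult(list(candidates), False, flags, log)

    def order_key(g: str) -> tuple[float, str]:
        score = abs(gene_scores[g]) if gene_scores and g in gene_scores else np.inf
        return (score, g)

    retained = sorted(candidates, key=order_key)
    changed = True
    while changed:
        changed = False
        for gene in list(retained):
            if len(retained) == 1:
                if gene in retained:
                    log.append((gene, "kept", "sole remaining gene"))
                continue
            trial = [g for g in retained if g != gene]
            trial_flags = evaluate_integrity(
                trial, datasets, target_group, exempt_samples, relaxed_purity
            )
            if all(trial_flags.values()):
                retained = trial
                log.append((gene, "removed", "clade intact in all datasets"))
                changed = True
            else:
                broken = sorted(k for k, v in trial_flags.items() if not v)
                log.append((gene, "kept", f"clade breaks in {', '.join(broken)}"))
    final_flags = evaluate_integrity(
        retained, datasets, target_group, exempt_samples, relaxed_purity
    )
    return SignatureResult(sorted(retained), True, final_flags, log)


def verify_one_minimal(
    result: SignatureResult,
    datasets: Mapping[str, ExpressionMatrix],
    target_group: str,
    exempt_samples: Mapping[str, Sequence[str]] | None = None,
    relaxed_purity: float | None = None,
) -> bool:
    """Exhaustive single-gene knockout: every removal must break some dataset."""
    if not result.ok:
        return False
    for gene in result.genes:
        if len(result.genes) == 1:
            return True
        trial = [g for g in result.genes if g != gene]
        flags = evaluate_integrity(
            trial, datasets, target_group, exempt_samples, relaxed_purity
        )
        if all(flags.values()):
            return False
    return True
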