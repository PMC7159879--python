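"""Entropy screening, rank-sum comparison, and tree congruence.

Rapidly evolving components of conflict systems show elevated per-column
Shannon entropy in their alignments relative to conserved housekeeping
controls.  Entropy is computed in bits over the 20 standard residues after
excluding gaps and X, columns dominated by gaps are skipped, and component
profiles are compared with the Wilcoxon rank-sum (Mann-Whitney) test.
Congruence between core-component phylogenies is measured as normalized
Robinson-Foulds distance on the shared leaf set.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass

import dendropy
import numpy as np
from dendropy.calculate import treecompare
from scipy.stats import mannwhitneyu

from .model import Msa

MAX_ENTROPY = math.log2(20.0)
_EXACT_LIMIT = 12  # combined sample size up to which the rank-sum p is exact


@dataclass
class EntropyProfile:
    label: str
    column_entropies: list[float]
    mean_entropy: float
    n_columns_used: int
    n_columns_skipped: int


@dataclass
class RankSumResult:
    u_statistic: float
    p_value: float
    method: str  # "exact" or "normal"
    n_a: int
    n_b: int


@dataclass
class CongruenceResult:
    label_a: str
    label_b: str
    n_shared_leaves: int
    rf_distance: int
    normalized_rf: float


# ---------------------------------------------------------------------------
# entropy


def column_entropy(column: str) -> float | None:
    """Shannon entropy (bits) of one alignment column.

    Frequencies are taken over the 20 standard residues after removing gap
    characters and X; a column with no countable residue returns None.
    """
    residues = [c for c in column.upper() if c not in ("-", ".", "X")]
    if not residues:
        return None
    n = len(residues)
    counts: dict[str, int] = {}
    for c in residues:
        counts[c] = counts.get(c, 0) + 1
    h = -sum((v / n) * math.log2(v / n) for v in counts.values())
    return h


def mean_positional_entropy(
    msa: Msa, label: str = "", max_gap_fraction: float = 0.5
) -> EntropyProfile:
    """Per-column entropy profile, skipping gap-dominated columns."""
    if len(msa.rows) < 2:
        raise ValueError("alignment needs at least 2 rows")
    used: list[float] = []
    skipped = 0
    nrows = len(msa.rows)
    for j in range(msa.n_columns):
        col = msa.column(j)
        gap_fraction = sum(c in ("-", ".") for c in col) / nrows
        if gap_fraction > max_gap_fraction:
            skipped += 1
            continue
        h = column_entropy(col)
        if h is None:
            skipped += 1
            continue
        used.append(h)
    if not used:
        raise ValueError("all columns skipped; nothing to average")
    return EntropyProfile(
        label=label,
        column_entropies=used,
        mean_entropy=float(np.mean(used)),
        n_columns_used=len(used),
        n_columns_skipped=skipped,
    )


# ---------------------------------------------------------------------------
# rank-sum test


def _u_statistic(a: list[float], b: list[float]) -> float:
    """Mann-Whitney U of sample a (ties count one half)."""
    u = 0.0
    for x in a:
        for y in b:
            if x > y:
                u += 1.0
            elif x == y:
                u += 0.5
    return u


def rank_sum_test(a: list[float], b: list[float]) -> RankSumResult:
    """Two-sided Wilcoxon rank-sum test.

    For combined sample sizes up to 12 the p-value is exact, by enumerating
    every assignment of the pooled values to the two groups (a permutation
    formulation, hence correct under ties).  Larger samples use the normal
    approximation with tie and continuity corrections.
    """
    if not a or not b:
        raise ValueError("both samples must be non-empty")
    n1, n2 = len(a), len(b)
    u_obs = _u_statistic(a, b)
    if len(set(a) | set(b)) == 1:
        return RankSumResult(u_obs, 1.0, "degenerate", n1, n2)
    mu = n1 * n2 / 2.0
    if n1 + n2 <= _EXACT_LIMIT:
        pooled = list(a) + list(b)
        total = 0
        extreme = 0
        d_obs = abs(u_obs - mu)
        for idx in itertools.combinations(range(n1 + n2), n1):
            sel = set(idx)
            ga = [pooled[i] for i in sel]
            gb = [pooled[i] for i in range(n1 + n2) if i not in sel]
            u = _u_statistic(ga, gb)
            total += 1
            if abs(u - mu) >= d_obs - 1e-12:
                extreme += 1
        return RankSumResult(u_obs, extreme / total, "exact", n1, n2)
    res = mannwhitneyu(a, b, alternative="two-sided", method="asymptotic")
    return RankSumResult(float(res.statistic), float(res.pvalue), "normal", n1, n2)


# ---------------------------------------------------------------------------
# tree congruence


def rf_congruence(
    tree_a: dendropy.Tree,
    tree_b: dendropy.Tree,
    label_a: str = "a",
    label_b: str = "b",
) -> CongruenceResult:
    """Robinson-Foulds distance between two trees on their shared leaves.

    Both trees are pruned to the common leaf set (at least 4 leaves) and
    compared as unrooted topologies; the normalization divides by
    2*(n_shared - 3), the maximum for binary unrooted trees.
    """
    leaves_a = {l.taxon.label for l in tree_a.leaf_node_iter()}
    leaves_b = {l.taxon.label for l in tree_b.leaf_node_iter()}
    shared = sorted(leaves_a & leaves_b)
    if len(shared) < 4:
        raise ValueError(f"need >= 4 shared leaves, got {len(shared)}")
    tns = dendropy.TaxonNamespace(shared)
    ta = dendropy.Tree.get(
        data=tree_a.as_string(schema="newick"), schema="newick", taxon_namespace=tns
    )
    tb = dendropy.Tree.get(
        data=tree_b.as_string(schema="newick"), schema="newick", taxon_namespace=tns
    )
    for t in (ta, tb):
        t.retain_taxa_with_labels(shared)
        t.is_rooted = False
        t.collapse_basal_bifurcation()
        t.encode_bipartitions()
    rf = int(treecompare.symmetric_difference(ta, tb))
    denom = 2 * (len(shared) - 3)
    return CongruenceResult(
        label_a=label_a,
        label_b=label_b,
        n_shared_leaves=len(shared),
        rf_distance=rf,
        normalized_rf=rf / denom if denom else 0.0,
    )
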