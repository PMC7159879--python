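"""BLASTCLUST-style single-linkage protein clustering.

Proteins are compared by optimal local alignment under BLOSUM62 with affine
gaps, and an undirected similarity edge is drawn when both sequences are
covered to at least a fraction ``L`` of their lengths and the alignment's
bit score per aligned column ("score density") reaches ``S``.  Connected
components of the resulting graph are the clusters.  The default thresholds
(L = 0.9, S = 1.89 bits/column) are the classic settings for culling
near-identical sequences; looser values are used for classification-level
grouping.

Raw scores are converted to bits with the Karlin-Altschul formula
``(lambda * raw - ln K) / ln 2`` using the standard gapped-BLOSUM62
parameters (lambda = 0.267, K = 0.041 for gap open 11 / extend 1).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import networkx as nx
from Bio import Align
from Bio.Align import substitution_matrices

from .model import AA_ALPHABET, ProteinSeq


@dataclass
class ScoringParams:
    matrix: str = "BLOSUM62"
    gap_open: float = 11.0  # NCBI convention: gap of length g costs open + g*extend
    gap_extend: float = 1.0
    karlin_lambda: float = 0.267
    karlin_k: float = 0.041
    L: float = 0.9
    S: float = 1.89
    identity_mode: bool = False  # interpret S as percent identity instead of bits/column

    def __post_init__(self) -> None:
        if not (0 < self.L <= 1):
            raise ValueError("L must be in (0, 1]")
        if self.S <= 0:
            raise ValueError("S must be positive")
        if self.gap_open <= 0 or self.gap_extend <= 0:
            raise ValueError("gap penalties must be positive")


@dataclass(frozen=True)
class SimilarityEdge:
    protein_a: str
    protein_b: str
    raw_score: float
    bit_score: float
    density: float
    coverage_a: float
    coverage_b: float
    identity: float


@dataclass
class ClusterSet:
    """A disjoint partition of protein ids with one representative each."""

    clusters: list[frozenset[str]]
    representatives: list[str]
    member_to_cluster: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.member_to_cluster:
            for i, c in enumerate(self.clusters):
                for m in c:
                    self.member_to_cluster[m] = i

    def cluster_of(self, protein_id: str) -> int:
        return self.member_to_cluster[protein_id]

    def as_map(self) -> dict[str, int]:
        return dict(self.member_to_cluster)


def _make_aligner(params: ScoringParams) -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "local"
    aligner.substitution_matrix = substitution_matrices.load(params.matrix)
    # Biopython charges open_gap_score for the first gapped position, so the
    # NCBI "11/1" affine cost (11 + g) maps to open = -(open+extend), extend = -extend.
    aligner.open_gap_score = -(params.gap_open + params.gap_extend)
    aligner.extend_gap_score = -params.gap_extend
    return aligner


def align_pair(
    seq_a: ProteinSeq | str,
    seq_b: ProteinSeq | str,
    params: ScoringParams | None = None,
) -> tuple[float, int, float, float, float]:
    """Best local alignment of two protein sequences.

    Returns ``(raw_score, aligned_columns, coverage_a, coverage_b, identity)``
    where aligned columns count residue-residue pairs only (gap columns do
    not contribute), coverage_x is aligned residues of x over its length and
    identity is the fraction of identical aligned pairs.  A non-positive
    optimal score yields zero columns and coverages.
    """
    params = params or ScoringParams()
    a = seq_a.sequence if isinstance(seq_a, ProteinSeq) else seq_a
    b = seq_b.sequence if isinstance(seq_b, ProteinSeq) else seq_b
    for label, s in (("a", a), ("b", b)):
        if not s:
            raise ValueError(f"sequence {label} is empty")
        bad = set(s) - AA_ALPHABET
        if bad:
            raise ValueError(f"sequence {label}: residues outside alphabet {sorted(bad)}")
    aligner = _make_aligner(params)
    score = aligner.score(a, b)
    if score <= 0:
        return float(score), 0, 0.0, 0.0, 0.0
    aln = aligner.align(a, b)[0]
    blocks_a, blocks_b = aln.aligned
    cols = int(sum(e - s for s, e in blocks_a))
    ident = 0
    for (sa, ea), (sb, _eb) in zip(blocks_a, blocks_b):
        for k in range(ea - sa):
            if a[sa + k] == b[sb + k]:
                ident += 1
    return (
        float(aln.score),
        cols,
        cols / len(a),
        cols / len(b),
        ident / cols if cols else 0.0,
    )


def bit_score(raw_score: float, params: ScoringParams | None = None) -> float:
    """Karlin-Altschul bit score: (lambda*raw - ln K) / ln 2."""
    params = params or ScoringParams()
    return (params.karlin_lambda * raw_score - math.log(params.karlin_k)) / math.log(2)


def build_edges(
    seqs: list[ProteinSeq],
    params: ScoringParams | None = None,
    length_prefilter: bool = True,
) -> list[SimilarityEdge]:
    """All-vs-all similarity edges passing the L/S thresholds.

    With ``length_prefilter`` (exact, not heuristic) pairs whose length
    ratio is below L are skipped: the longer sequence can never reach
    coverage L in a pairwise alignment.
    """
    params = params or ScoringParams()
    if len(seqs) < 2:
        return []
    edges = []
    for i in range(len(seqs)):
        for j in range(i + 1, len(seqs)):
            a, b = seqs[i], seqs[j]
            if length_prefilter:
                ratio = min(len(a), len(b)) / max(len(a), len(b))
                if ratio < params.L:
                    continue
            raw, cols, cov_a, cov_b, ident = align_pair(a, b, params)
            if cols == 0:
                continue
            bits = bit_score(raw, params)
            density = bits / cols
            if cov_a < params.L or cov_b < params.L:
                continue
            if params.identity_mode:
                if ident * 100.0 < params.S:
                    continue
            elif density < params.S:
                continue
            edges.append(
                SimilarityEdge(
                    protein_a=a.protein_id,
                    protein_b=b.protein_id,
                    raw_score=raw,
                    bit_score=bits,
                    density=density,
                    coverage_a=cov_a,
                    coverage_b=cov_b,
                    identity=ident,
                )
            )
    return edges


def single_linkage(
    ids: list[str],
    edges: list[SimilarityEdge],
    lengths: dict[str, int] | None = None,
) -> ClusterSet:
    """Connected components of the similarity graph, singletons included.

    The representative of a cluster is its longest member (lexicographically
    smallest id on ties); without lengths, the smallest id.
    """
    id_set = set(ids)
    g = nx.Graph()
    g.add_nodes_from(ids)
    for e in edges:
        if e.protein_a not in id_set or e.protein_b not in id_set:
            raise ValueError(f"edge endpoint outside id set: {e.protein_a}/{e.protein_b}")
        g.add_edge(e.protein_a, e.protein_b)
    comps = [frozenset(c) for c in nx.connected_components(g)]
    comps.sort(key=lambda c: min(c))
    reps = []
    for c in comps:
        if lengths:
            reps.append(min(c, key=lambda m: (-lengths.get(m, 0), m)))
        else:
            reps.append(min(c))
    cs = ClusterSet(clusters=comps, representatives=reps)
    # partition property asserted on every run
    union = set().union(*comps) if comps else set()
    assert union == id_set and sum(len(c) for c in comps) == len(id_set)
    return cs


def cluster_proteins(
    seqs: list[ProteinSeq],
    params: ScoringParams | None = None,
) -> ClusterSet:
    """Convenience wrapper: edges + single linkage in one call."""
    params = params or ScoringParams()
    edges = build_edges(seqs, params)
    lengths = {s.protein_id: len(s) for s in seqs}
    return single_linkage([s.protein_id for s in seqs], edges, lengths)
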