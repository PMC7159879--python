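"""Domain-architecture resolution and network statistics.

The N->C order of non-overlapping domain hits on a protein is its
architecture string.  Architectures are summarized as a directed adjacency
network (arrowhead toward the C-terminal domain), and several statistics of
effector deployment are computed on top: effector-count distributions,
organism-level co-occurrence / mutual exclusivity, distinctness of effector
complements between paralogous systems, and the coupling of
effector-associated domains (EADs) between core components and stand-alone
effector proteins.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from statistics import mean, median
from typing import Iterable, Mapping, Sequence

from .enrichment import hypergeometric_lower_tail, hypergeometric_upper_tail
from .model import DomainHit

OVERLAP_TOLERANCE = 10  # residues two kept hits may share
# above this many hits per protein, exact selection falls back to greedy
_EXACT_LIMIT = 15


@dataclass(frozen=True)
class ArchitectureString:
    protein_id: str
    domains: tuple[str, ...]


@dataclass
class ArchNetwork:
    nodes: dict[str, int]
    edges: dict[tuple[str, str], int]
    edge_threshold_minor: int = 14
    edge_threshold_major: int = 148

    def edge_class(self, edge: tuple[str, str]) -> str:
        n = self.edges.get(edge, 0)
        if n > self.edge_threshold_major:
            return "major"
        if n > self.edge_threshold_minor:
            return "minor"
        return "background"


@dataclass
class CooccurrenceStats:
    n_both: int
    n_a_only: int
    n_b_only: int
    n_neither: int
    jaccard: float | None
    p_depletion: float
    p_enrichment: float


def _overlap(h1: DomainHit, h2: DomainHit) -> int:
    return max(0, min(h1.ali_end, h2.ali_end) - max(h1.ali_start, h2.ali_start) + 1)


def resolve_hits(
    hits: Sequence[DomainHit], overlap_tolerance: int = OVERLAP_TOLERANCE
) -> list[DomainHit]:
    """Select a non-overlapping hit set maximizing total bit score.

    Any two kept hits may overlap by at most ``overlap_tolerance`` residues.
    The selection is exact for proteins with a modest number of hits (ties
    broken toward higher-scoring, more N-terminal hits); very hit-dense
    proteins fall back to greedy selection by descending score, which
    coincides with the exact answer in all but adversarial cases.
    Returns the kept hits sorted by ali_start.
    """
    if not hits:
        return []
    pids = {h.protein_id for h in hits}
    if len(pids) > 1:
        raise ValueError(f"hits span multiple proteins: {sorted(pids)}")
    order = sorted(hits, key=lambda h: (-h.score, h.ali_start, h.ali_end, h.domain))
    if len(order) <= _EXACT_LIMIT:
        kept = _exact_select(order, overlap_tolerance)
    else:
        kept = _greedy_select(order, overlap_tolerance)
    return sorted(kept, key=lambda h: (h.ali_start, h.ali_end, h.domain))


def _compatible(subset: Sequence[DomainHit], tol: int) -> bool:
    return all(_overlap(a, b) <= tol for a, b in itertools.combinations(subset, 2))


def _exact_select(order: Sequence[DomainHit], tol: int) -> list[DomainHit]:
    n = len(order)
    best_key = None
    best: list[DomainHit] = []
    for mask in range(1 << n):
        subset = [order[i] for i in range(n) if mask >> i & 1]
        if not _compatible(subset, tol):
            continue
        total = sum(h.score for h in subset)
        # prefer higher total score; break ties toward the greedy-style
        # preference order (higher score first, then more N-terminal)
        tie = tuple(sorted((-h.score, h.ali_start, h.ali_end, h.domain) for h in subset))
        key = (-total, tie)
        if best_key is None or key < best_key:
            best_key, best = key, subset
    return best


def _greedy_select(order: Sequence[DomainHit], tol: int) -> list[DomainHit]:
    kept: list[DomainHit] = []
    for h in order:
        if all(_overlap(h, k) <= tol for k in kept):
            kept.append(h)
    return kept


def resolve_architecture(
    hits: Sequence[DomainHit], overlap_tolerance: int = OVERLAP_TOLERANCE
) -> ArchitectureString:
    kept = resolve_hits(hits, overlap_tolerance)
    return ArchitectureString(
        protein_id=kept[0].protein_id if kept else "",
        domains=tuple(h.domain for h in kept),
    )


# ---------------------------------------------------------------------------
# network


def build_network(
    architectures: Iterable[ArchitectureString | Sequence[str]],
    edge_threshold_minor: int = 14,
    edge_threshold_major: int = 148,
) -> ArchNetwork:
    """Count domain occurrences and ordered N->C adjacencies over proteins.

    A domain repeated within one protein increments its node count once per
    repeat; edge counts are adjacent ordered pairs summed over proteins, so
    the edge total equals sum(len(architecture) - 1).
    """
    nodes: dict[str, int] = {}
    edges: dict[tuple[str, str], int] = {}
    for arch in architectures:
        doms = list(arch.domains) if isinstance(arch, ArchitectureString) else list(arch)
        for d in doms:
            nodes[d] = nodes.get(d, 0) + 1
        for a, b in zip(doms, doms[1:]):
            edges[(a, b)] = edges.get((a, b), 0) + 1
    return ArchNetwork(
        nodes=nodes,
        edges=edges,
        edge_threshold_minor=edge_threshold_minor,
        edge_threshold_major=edge_threshold_major,
    )


def network_to_graph(net: ArchNetwork):
    """The adjacency network as a networkx DiGraph (for export/layout)."""
    import networkx as nx

    g = nx.DiGraph()
    for d, c in net.nodes.items():
        g.add_node(d, count=c)
    for (a, b), c in net.edges.items():
        g.add_edge(a, b, count=c, edge_class=net.edge_class((a, b)))
    return g


# ---------------------------------------------------------------------------
# statistics over system instances


def effector_count_distribution(instances: Sequence) -> dict:
    """Histogram of effector-domain counts per system instance."""
    counts = [len(inst.effectors) for inst in instances]
    hist: dict[int, int] = {}
    for c in counts:
        hist[c] = hist.get(c, 0) + 1
    return {
        "counts": counts,
        "histogram": dict(sorted(hist.items())),
        "mean": mean(counts) if counts else None,
        "median": median(counts) if counts else None,
    }


def overlap_and_exclusivity(
    presence_a: set[str], presence_b: set[str], universe: set[str]
) -> CooccurrenceStats:
    """Organism-level overlap of two systems with hypergeometric tails.

    Depletion (mutual exclusivity) is the lower-tail probability of seeing
    at most the observed co-occurrence given the margins; enrichment is the
    upper tail.
    """
    if not presence_a <= universe or not presence_b <= universe:
        raise ValueError("presence sets must be subsets of the universe")
    both = presence_a & presence_b
    union = presence_a | presence_b
    n_both = len(both)
    n_a = len(presence_a - presence_b)
    n_b = len(presence_b - presence_a)
    n_neither = len(universe) - len(union)
    m = len(presence_a)
    n = len(universe) - m
    k = len(presence_b)
    return CooccurrenceStats(
        n_both=n_both,
        n_a_only=n_a,
        n_b_only=n_b,
        n_neither=n_neither,
        jaccard=(n_both / len(union)) if union else None,
        p_depletion=hypergeometric_lower_tail(n_both, m, n, k),
        p_enrichment=hypergeometric_upper_tail(n_both, m, n, k) if n_both > 0 else 1.0,
    )


def paralog_distinctness(
    instances: Sequence, system_type: str | None = None
) -> dict:
    """Do paralogous systems within one organism carry distinct effectors?

    Reports the multi-system fraction (organisms with >= 2 instances among
    those with >= 1) and, among multi-system organisms, the fraction where
    every pair of instances differs in its effector multiset.
    """
    by_org: dict[str, list] = {}
    for inst in instances:
        if system_type is not None and inst.system_type != system_type:
            continue
        by_org.setdefault(inst.genome_id, []).append(inst)
    n_with = len(by_org)
    multi = {org: lst for org, lst in by_org.items() if len(lst) >= 2}
    per_org = {}
    n_distinct = 0
    for org, lst in multi.items():
        sets = [tuple(sorted(i.effectors)) for i in lst]
        distinct = all(a != b for a, b in itertools.combinations(sets, 2))
        per_org[org] = distinct
        n_distinct += distinct
    return {
        "n_organisms_with_system": n_with,
        "n_multi_system": len(multi),
        "multi_system_fraction": len(multi) / n_with if n_with else None,
        "distinctness_fraction": n_distinct / len(multi) if multi else None,
        "per_organism": per_org,
    }


def ead_coupling(
    architectures: Mapping[str, Sequence[str]],
    instances: Sequence,
    protein_genome: Mapping[str, str],
    ead_labels: set[str] | None = None,
) -> dict:
    """Coupling of EAD families between core components and effectors.

    For every EAD family and system-bearing genome two flags are raised:
    the EAD is fused to a core component of some system instance, and at
    least one *other* protein in the genome carries the same EAD fused to a
    non-core domain.  The co-presence contingency across genomes is tested
    with the upper-tail hypergeometric.
    """
    if ead_labels is None:
        ead_labels = {
            d for doms in architectures.values() for d in doms if d.startswith("EAD")
        }
    core_by_genome: dict[str, set[str]] = {}
    for inst in instances:
        core_by_genome.setdefault(inst.genome_id, set()).update(inst.run_protein_ids)
    prot_by_genome: dict[str, list[str]] = {}
    for pid, gid in protein_genome.items():
        prot_by_genome.setdefault(gid, []).append(pid)
    out = {}
    genomes = sorted(core_by_genome)
    for ead in sorted(ead_labels):
        rows = []
        for gid in genomes:
            cores = core_by_genome[gid]
            fused_core = any(ead in architectures.get(p, ()) for p in cores)
            fused_elsewhere = any(
                ead in architectures.get(p, ())
                and any(d != ead for d in architectures.get(p, ()))
                for p in prot_by_genome.get(gid, [])
                if p not in cores
            )
            rows.append({"genome_id": gid, "on_core": fused_core, "elsewhere": fused_elsewhere})
        n11 = sum(r["on_core"] and r["elsewhere"] for r in rows)
        n10 = sum(r["on_core"] and not r["elsewhere"] for r in rows)
        n01 = sum(not r["on_core"] and r["elsewhere"] for r in rows)
        n00 = len(rows) - n11 - n10 - n01
        m = n11 + n10
        n = n01 + n00
        k = n11 + n01
        p = hypergeometric_upper_tail(n11, m, n, k) if n11 > 0 else 1.0
        out[ead] = {
            "rows": rows,
            "contingency": (n11, n10, n01, n00),
            # among genomes where the EAD sits on a core component, how often
            # a second copy rides a non-core protein
            "coupling_rate": n11 / m if m else None,
            # fraction of all system-bearing genomes showing full coupling
            "coupled_fraction": n11 / len(rows) if rows else None,
            "p_upper": p,
        }
    return out
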