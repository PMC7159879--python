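"""Architecture resolution (vs an exhaustive selection oracle), network
counting conservation, and the effector/co-occurrence statistics."""

import itertools

import numpy as np
import pytest

from conflictscan.architectures import (
    build_network,
    ead_coupling,
    effector_count_distribution,
    overlap_and_exclusivity,
    paralog_distinctness,
    resolve_architecture,
    resolve_hits,
)
from conflictscan.neighborhoods import SystemInstance

from conftest import hit


def exhaustive_selection_oracle(hits, tol=10):
    """Best-total-score pairwise-compatible subset by brute force."""
    def overlap(a, b):
        return max(0, min(a.ali_end, b.ali_end) - max(a.ali_start, b.ali_start) + 1)

    best, best_score = [], -1.0
    for r in range(len(hits) + 1):
        for subset in itertools.combinations(hits, r):
            if any(overlap(a, b) > tol for a, b in itertools.combinations(subset, 2)):
                continue
            score = sum(h.score for h in subset)
            if score > best_score:
                best, best_score = list(subset), score
    return sorted(best, key=lambda h: h.ali_start), best_score


class TestResolveHits:
    def test_non_conflicting_hits_all_kept(self):
        hits = [hit("p", "A", 1, 100, 50), hit("p", "B", 150, 250, 40)]
        assert [h.domain for h in resolve_hits(hits)] == ["A", "B"]

    def test_overlapping_lower_score_dropped(self):
        hits = [hit("p", "A", 1, 100, 50), hit("p", "A2", 20, 90, 30)]
        assert [h.domain for h in resolve_hits(hits)] == ["A"]

    def test_equal_score_tie_prefers_smaller_start(self):
        hits = [hit("p", "L", 30, 120, 40), hit("p", "E", 1, 100, 40)]
        assert [h.domain for h in resolve_hits(hits)] == ["E"]

    def test_matches_exhaustive_oracle_on_random_instances(self, rng):
        for _ in range(40):
            n = int(rng.integers(1, 6))
            hits = []
            for i in range(n):
                s = int(rng.integers(1, 300))
                e = s + int(rng.integers(20, 120))
                hits.append(hit("p", f"D{i}", s, e, float(rng.integers(10, 90))))
            kept = resolve_hits(hits)
            oracle, oracle_score = exhaustive_selection_oracle(hits)
            assert sum(h.score for h in kept) == pytest.approx(oracle_score)

    def test_hits_from_multiple_proteins_rejected(self):
        with pytest.raises(ValueError):
            resolve_hits([hit("p", "A", 1, 10), hit("q", "B", 1, 10)])

    def test_architecture_orders_n_to_c(self):
        hits = [hit("p", "B", 200, 300, 40), hit("p", "A", 1, 100, 30)]
        arch = resolve_architecture(hits)
        assert arch.domains == ("A", "B")


class TestBuildNetwork:
    def test_counts_example(self):
        net = build_network([["A", "B"], ["A", "B"], ["A", "C"]])
        assert net.nodes == {"A": 3, "B": 2, "C": 1}
        assert net.edges == {("A", "B"): 2, ("A", "C"): 1}

    def test_single_domain_protein(self):
        net = build_network([["A"]])
        assert net.nodes == {"A": 1} and net.edges == {}

    def test_edge_total_conservation(self, rng):
        archs = []
        for _ in range(30):
            k = int(rng.integers(1, 6))
            archs.append([f"D{int(rng.integers(0, 8))}" for _ in range(k)])
        net = build_network(archs)
        assert sum(net.edges.values()) == sum(len(a) - 1 for a in archs)

    def test_edge_classes_by_threshold(self):
        net = build_network([["A", "B"]] * 200 + [["C", "D"]] * 20, 14, 148)
        assert net.edge_class(("A", "B")) == "major"
        assert net.edge_class(("C", "D")) == "minor"
        assert net.edge_class(("X", "Y")) == "background"


def _instance(genome, effectors, system="VMAP", i=0):
    return SystemInstance(
        system_type=system,
        genome_id=genome,
        component_genes={"vWA": f"{genome}_g{i}"},
        effectors=list(effectors),
        anchor_stop=100,
        replicon_length=1000,
        run_protein_ids=(f"{genome}_p{i}",),
    )


class TestEffectorStats:
    def test_mean_and_median(self):
        insts = [
            _instance("G1", ["A"]),
            _instance("G2", ["A", "B", "C"]),
            _instance("G3", ["A", "B", "D"]),
            _instance("G4", ["A", "B", "C", "D", "E"]),
        ]
        dist = effector_count_distribution(insts)
        assert dist["mean"] == 3 and dist["median"] == 3

    def test_empty_reports_na(self):
        dist = effector_count_distribution([])
        assert dist["mean"] is None and dist["histogram"] == {}

    def test_generator_effector_mean_recovered(self, small_dataset):
        means = [len(r["effectors"]) for r in small_dataset.ground_truth.planted]
        # drawn as 1 + Poisson(mean-1): expectation equals the config mean
        assert np.mean(means) == pytest.approx(
            small_dataset.config.effector_mean, abs=1.0
        )


class TestOverlapExclusivity:
    def test_jaccard_example(self):
        st = overlap_and_exclusivity({"1", "2", "3"}, {"3", "4"}, set("12345678"))
        assert st.jaccard == 0.25

    def test_identical_sets(self):
        st = overlap_and_exclusivity({"1", "2"}, {"1", "2"}, set("1234"))
        assert st.jaccard == 1.0 and st.p_depletion == 1.0

    def test_disjoint_sets_enumeration_value(self):
        # margins 4 and 4 in a universe of 8: P(X <= 0) = C(4,4)/C(8,4) = 1/70
        a, b = set("1234"), set("5678")
        st = overlap_and_exclusivity(a, b, set("12345678"))
        assert st.n_both == 0
        assert st.p_depletion == pytest.approx(1 / 70)

    def test_presence_outside_universe_raises(self):
        with pytest.raises(ValueError):
            overlap_and_exclusivity({"z"}, set(), {"a"})


class TestParalogDistinctness:
    def test_distinct_and_identical_pairs(self):
        insts = [
            _instance("G1", ["A", "B"], i=0),
            _instance("G1", ["C"], i=1),
            _instance("G2", ["A"], i=0),
            _instance("G2", ["A"], i=1),
            _instance("G3", ["A"], i=0),
        ]
        res = paralog_distinctness(insts)
        assert res["per_organism"] == {"G1": True, "G2": False}
        assert res["multi_system_fraction"] == pytest.approx(2 / 3)
        assert res["distinctness_fraction"] == pytest.approx(1 / 2)

    def test_multi_system_fraction_recovery(self, rng):
        # plant 40% multi-system organisms at n=500 and recover the rate
        insts = []
        n_multi = 0
        for i in range(500):
            multi = rng.random() < 0.4
            n_multi += multi
            insts.append(_instance(f"G{i}", ["A"], i=0))
            if multi:
                insts.append(_instance(f"G{i}", ["B"], i=1))
        res = paralog_distinctness(insts)
        assert res["multi_system_fraction"] == pytest.approx(n_multi / 500, abs=1e-9)
        assert abs(res["multi_system_fraction"] - 0.4) <= 0.05


class TestEadCoupling:
    def test_coupled_and_uncoupled_genomes(self):
        archs = {
            "G1_core": ("EAD1", "VMAP"),
            "G1_sat": ("EAD1", "Nuclease"),
            "G2_core": ("EAD1", "VMAP"),
        }
        insts = [
            _instance("G1", ["A"], i=0),
            _instance("G2", ["A"], i=0),
        ]
        insts[0].run_protein_ids = ("G1_core",)
        insts[1].run_protein_ids = ("G2_core",)
        pg = {"G1_core": "G1", "G1_sat": "G1", "G2_core": "G2"}
        res = ead_coupling(archs, insts, pg)
        rows = {r["genome_id"]: r for r in res["EAD1"]["rows"]}
        assert rows["G1"]["on_core"] and rows["G1"]["elsewhere"]
        assert rows["G2"]["on_core"] and not rows["G2"]["elsewhere"]
        assert res["EAD1"]["coupling_rate"] == pytest.approx(0.5)

    def test_generator_coupling_rate_recovered(self):
        from conflictscan.simulate import SimConfig, generate

        data = generate(
            SimConfig(seed=21, n_genomes=300, genes_per_genome=25,
                      p_system_given_mc={"VMAP": 0.5},
                      p_system_given_non_mc={"VMAP": 0.3},
                      decoy_rate=0.0, ead_coupling_prob=0.9)
        )
        by_protein = {}
        for h in data.hits:
            by_protein.setdefault(h.protein_id, []).append(h)
        archs = {
            pid: tuple(x.domain for x in resolve_hits(v))
            for pid, v in by_protein.items()
        }
        insts = []
        for rec in data.ground_truth.planted:
            genome = next(g for g in data.genomes if g.genome_id == rec["genome_id"])
            inst = _instance(rec["genome_id"], rec["effectors"])
            inst.run_protein_ids = tuple(
                genome.gene(g).protein_id for g in rec["component_genes"].values()
            )
            insts.append(inst)
        pg = {g2.protein_id: g.genome_id for g in data.genomes for g2 in g.genes}
        res = ead_coupling(archs, insts, pg)
        assert abs(res["EAD1"]["coupled_fraction"] - 0.9) <= 0.05
        assert res["EAD1"]["p_upper"] < 1e-4
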