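"""Neighborhood extraction, gene-order template matching and the three
conservation filters (gap, directionality, cross-phylum presence)."""

import dataclasses

import pytest

from conflictscan.neighborhoods import (
    Neighborhood,
    SystemTemplate,
    conserved_neighborhood_filter,
    extract_neighborhood,
    intergenic_gap,
    load_templates,
    match_template,
    scan_genomes,
)
from conflictscan.simulate import SimConfig, generate

from conftest import hit, make_gene, make_genome

VMAP_TEMPLATE = SystemTemplate(
    name="VMAP",
    required_components=["VMAP", "MoxR", "vWA"],
    anchor_role="vWA",
    effector_role="vWA",
    core_domain="vWA",
)


def ternary_genome(gap1=30, gap2=10, strands=("+", "+", "+")):
    """VMAP -> MoxR -> vWA run with configurable junction gaps/strands."""
    g1 = make_gene("g1", 1000, 1600, strands[0], protein="p1")
    g2 = make_gene("g2", 1601 + gap1, 2400 + gap1, strands[1], protein="p2")
    g3 = make_gene("g3", 2401 + gap1 + gap2, 3200 + gap1 + gap2, strands[2], protein="p3")
    return make_genome([g1, g2, g3])


TERNARY_HITS = {
    "p1": [hit("p1", "VMAP", 20, 180)],
    "p2": [hit("p2", "MoxR", 10, 250)],
    "p3": [hit("p3", "vWA", 15, 190), hit("p3", "TIR", 210, 260), hit("p3", "HAD", 270, 330)],
}


class TestIntergenicGap:
    def test_strictly_between_convention(self):
        a, b = make_gene("a", 100, 200), make_gene("b", 250, 400)
        assert intergenic_gap(a, b) == 49

    def test_adjacent_genes_have_zero_gap(self):
        a, b = make_gene("a", 100, 200), make_gene("b", 201, 300)
        assert intergenic_gap(a, b) == 0

    def test_overlap_floored_at_zero(self):
        a, b = make_gene("a", 100, 200), make_gene("b", 150, 300)
        assert intergenic_gap(a, b) == 0

    def test_different_replicons_raise(self):
        a = make_gene("a", 100, 200)
        b = make_gene("b", 250, 400, replicon="chr2")
        with pytest.raises(ValueError):
            intergenic_gap(a, b)


class TestExtractNeighborhood:
    def _genome(self, n=15):
        genes = [make_gene(f"g{i}", 1000 * i + 1, 1000 * i + 800) for i in range(n)]
        return make_genome(genes)

    def test_mid_replicon_full_window(self):
        nbhd = extract_neighborhood(self._genome(), "g7", window=5)
        assert len(nbhd.members) == 11
        assert nbhd.anchor.gene_id == "g7"

    def test_truncated_at_replicon_edge(self):
        nbhd = extract_neighborhood(self._genome(), "g0", window=5)
        assert len(nbhd.members) == 6

    def test_gaps_consistent_with_coordinates(self):
        nbhd = extract_neighborhood(self._genome(), "g7", window=3)
        recomputed = [
            intergenic_gap(a, b) for a, b in zip(nbhd.members, nbhd.members[1:])
        ]
        assert nbhd.gaps == recomputed

    def test_unknown_anchor_raises(self):
        with pytest.raises(KeyError):
            extract_neighborhood(self._genome(), "missing")


class TestMatchTemplate:
    def test_plus_strand_run_matches(self):
        genome = ternary_genome(gap1=30, gap2=10)
        nbhd = extract_neighborhood(genome, "g3", window=5)
        inst = match_template(nbhd, TERNARY_HITS, VMAP_TEMPLATE)
        assert inst is not None
        assert inst.component_genes == {"VMAP": "g1", "MoxR": "g2", "vWA": "g3"}
        # effectors are the domains C-terminal to the vWA core
        assert inst.effectors == ["HAD", "TIR"]
        assert inst.anchor_stop == genome.gene("g3").end

    def test_gap_above_70_rejected(self):
        genome = ternary_genome(gap1=120)
        nbhd = extract_neighborhood(genome, "g3", window=5)
        assert match_template(nbhd, TERNARY_HITS, VMAP_TEMPLATE) is None

    def test_strand_flip_rejected(self):
        genome = ternary_genome(strands=("+", "-", "+"))
        nbhd = extract_neighborhood(genome, "g3", window=5)
        assert match_template(nbhd, TERNARY_HITS, VMAP_TEMPLATE) is None

    def test_minus_strand_run_reads_reversed(self):
        # genomic order vWA, MoxR, VMAP on '-' equals tx order VMAP->MoxR->vWA
        g1 = make_gene("g1", 1000, 1600, "-", protein="p3")
        g2 = make_gene("g2", 1650, 2400, "-", protein="p2")
        g3 = make_gene("g3", 2450, 3200, "-", protein="p1")
        genome = make_genome([g1, g2, g3])
        nbhd = extract_neighborhood(genome, "g1", window=5)
        inst = match_template(nbhd, TERNARY_HITS, VMAP_TEMPLATE)
        assert inst is not None
        assert inst.component_genes["vWA"] == "g1"
        assert inst.anchor_stop == genome.gene("g1").start  # '-' strand stop

    def test_fused_components_satisfy_both_roles(self):
        # one protein carrying MoxR then vWA in N->C order plus a VMAP gene
        g1 = make_gene("g1", 1000, 1600, protein="p1")
        g2 = make_gene("g2", 1650, 3000, protein="pf")
        genome = make_genome([g1, g2])
        hits = {
            "p1": [hit("p1", "VMAP", 20, 180)],
            "pf": [hit("pf", "MoxR", 10, 250), hit("pf", "vWA", 270, 430)],
        }
        inst = match_template(
            extract_neighborhood(genome, "g2", 5), hits, VMAP_TEMPLATE
        )
        assert inst is not None
        assert inst.component_genes == {"VMAP": "g1", "MoxR": "g2", "vWA": "g2"}

    def test_wrong_gene_order_rejected(self):
        # MoxR before VMAP violates the 5'->3' grammar
        hits = {
            "p1": [hit("p1", "MoxR", 10, 250)],
            "p2": [hit("p2", "VMAP", 20, 180)],
            "p3": [hit("p3", "vWA", 15, 190)],
        }
        genome = ternary_genome()
        assert match_template(
            extract_neighborhood(genome, "g3", 5), hits, VMAP_TEMPLATE
        ) is None


class TestConservedFilter:
    def _candidates(self, phyla):
        out = []
        for i, phylum in enumerate(phyla):
            genes = [
                make_gene(f"a{i}", 100, 700, protein=f"x{i}", genome=f"G{i}"),
                make_gene(f"b{i}", 750, 1400, protein=f"y{i}", genome=f"G{i}"),
            ]
            nbhd = Neighborhood(
                anchor=genes[0],
                members=genes,
                gaps=[49],
                genome_id=f"G{i}",
                replicon_id="chr",
                replicon_length=100_000,
            )
            out.append((nbhd, phylum))
        return out

    def _cluster_map(self, n):
        cmap = {}
        for i in range(n):
            cmap[f"x{i}"] = 0
            cmap[f"y{i}"] = 1
        return cmap

    def test_two_phyla_retained(self):
        cands = self._candidates(["Actinobacteria", "Cyanobacteria"])
        kept = conserved_neighborhood_filter(cands, self._cluster_map(2))
        assert kept == cands

    def test_single_phylum_dropped(self):
        cands = self._candidates(["Actinobacteria"] * 3)
        assert conserved_neighborhood_filter(cands, self._cluster_map(3)) == []

    def test_retention_invariant_to_input_order(self):
        cands = self._candidates(
            ["Actinobacteria", "Cyanobacteria", "Actinobacteria"]
        )
        cmap = self._cluster_map(3)
        kept_fwd = conserved_neighborhood_filter(cands, cmap)
        kept_rev = conserved_neighborhood_filter(cands[::-1], cmap)
        assert {id(c[0]) for c in kept_fwd} == {id(c[0]) for c in kept_rev}

    def test_missing_cluster_assignment_raises(self):
        cands = self._candidates(["Actinobacteria", "Cyanobacteria"])
        with pytest.raises(ValueError, match="missing cluster"):
            conserved_neighborhood_filter(cands, {"x0": 0})


@pytest.fixture(scope="module")
def planted():
    data = generate(SimConfig(seed=5, n_genomes=120, genes_per_genome=50, decoy_rate=0.3))
    templates = load_templates()
    instances = scan_genomes(data.genomes, data.hits, templates, proteins=data.proteins)
    return data, instances


class TestScanGenomes:

    @staticmethod
    def _key(rec_or_inst):
        if isinstance(rec_or_inst, dict):
            return (rec_or_inst["genome_id"], tuple(sorted(rec_or_inst["component_genes"].items())))
        return (rec_or_inst.genome_id, tuple(sorted(rec_or_inst.component_genes.items())))

    def test_planted_systems_recovered_with_high_sensitivity(self, planted):
        data, instances = planted
        truth = {self._key(r) for r in data.ground_truth.planted}
        found = {self._key(i) for i in instances}
        assert len(truth) >= 10
        assert len(truth & found) / len(truth) >= 0.95

    def test_no_false_positives_from_decoys_or_background(self, planted):
        data, instances = planted
        truth = {self._key(r) for r in data.ground_truth.planted}
        found = {self._key(i) for i in instances}
        assert len(truth & found) / len(found) >= 0.95
        decoys = {self._key(r) for r in data.ground_truth.decoys}
        assert not (decoys & found)

    def test_emitted_instances_satisfy_all_filters(self, planted):
        data, instances = planted
        for inst in instances:
            genome = next(g for g in data.genomes if g.genome_id == inst.genome_id)
            run = sorted(
                (genome.gene(g) for g in inst.segment_gene_ids), key=lambda g: g.start
            )
            assert len({g.strand for g in run}) == 1
            for a, b in zip(run, run[1:]):
                assert intergenic_gap(a, b) <= 70

    def test_shuffled_domain_labels_yield_no_instances(self):
        import numpy as np

        data = generate(SimConfig(seed=9, n_genomes=20, genes_per_genome=40, decoy_rate=0.0))
        rng = np.random.default_rng(1)
        labels = sorted({h.domain for h in data.hits})
        perm = dict(zip(labels, [labels[i] for i in rng.permutation(len(labels))]))
        shuffled = [dataclasses.replace(h, domain=perm[h.domain]) for h in data.hits]
        instances = scan_genomes(
            data.genomes, shuffled, load_templates(), proteins=data.proteins
        )
        assert instances == []

    def test_raising_max_gap_never_decreases_instances(self, planted):
        data, instances = planted
        wide = [
            dataclasses.replace(t, max_gap=500) for t in load_templates()
        ]
        more = scan_genomes(data.genomes, data.hits, wide, proteins=data.proteins)
        assert len(more) >= len(instances)


def test_single_phylum_systems_excluded_without_relaxation():
    """Systems confined to one phylum fall to filter 3; relaxing admits them."""
    cfg = SimConfig(
        seed=13,
        n_genomes=25,
        genes_per_genome=40,
        phyla={"Actinobacteria": 1.0},
        decoy_rate=0.0,
    )
    data = generate(cfg)
    assert data.ground_truth.planted  # something was planted
    templates = load_templates()
    strict = scan_genomes(data.genomes, data.hits, templates, proteins=data.proteins)
    assert strict == []
    relaxed = scan_genomes(
        data.genomes, data.hits, templates, proteins=data.proteins,
        require_multi_phylum=False,
    )
    assert len(relaxed) >= len(data.ground_truth.planted)
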