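"""Seeded synthetic genomes with planted conflict systems and ground truth.

The generator emulates the statistical structure every pipeline stage
assumes: prokaryotic gene tables with operon-like strand runs and geometric
intergenic gaps; ternary-system neighborhoods planted with the correct gene
order (e.g. VMAP -> MoxR -> vWA, 5'->3' on one strand) and variable
effector complements; protein families emitted from consensus sequences at
controlled per-site divergence (fast families for the rapidly evolving
components, slow for conserved controls); per-organism multicellularity
flags with controlled conditional system-planting probabilities; and anchor
positions drawn uniformly or from a symmetric bimodal mixture along the
replicon (the two-arm bias of linear actinobacterial chromosomes).

Decoy neighborhoods each violate exactly one of the three conservation
filters (gap, strand, or single-phylum presence), so every filter's
rejection behavior is independently testable against the ground truth.

All randomness flows through one numpy Generator seeded once; stages draw
in a fixed order, so a fixed seed yields byte-identical output files.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np

from . import io as cio
from .model import DomainHit, GeneRecord, GenomeRecord, Msa, ProteinSeq

AA20 = np.array(list("ACDEFGHIKLMNPQRSTVWY"))

DEFAULT_PHYLA = {
    "Actinobacteria": 0.30,
    "Cyanobacteria": 0.20,
    "Proteobacteria": 0.20,
    "Planctomycetes": 0.15,
    "Firmicutes": 0.15,
}

# effector-domain pool with roughly Zipfian weights; labels follow the
# families recurrently deployed in the effector position
DEFAULT_EFFECTOR_POOL = {
    "Trypsin": 5.0,
    "Caspase": 4.0,
    "cNMP_cyclase": 4.0,
    "STY_kinase": 3.0,
    "TIR": 3.0,
    "Band7": 2.5,
    "HAD": 2.0,
    "wHTH": 2.0,
    "ParA": 1.5,
    "Lysozyme": 1.5,
    "SLOG": 1.0,
    "GGDEF_eff": 1.0,
}

BACKGROUND_DOMAINS = [
    "ABC_transporter",
    "MFS",
    "GGDEF",
    "HTH_araC",
    "Acyltransferase",
    "Radical_SAM",
    "PAS",
    "TPR",
]

# residue spans of the planted core-component domains
CORE_LAYOUT = {
    "VMAP": ("VMAP", 20, 240),
    "MoxR": ("MoxR", 10, 290),
    "vWA": ("vWA", 15, 190),  # effectors appended C-terminally
}
CORE_LENGTH = {"VMAP": 260, "MoxR": 300, "vWA": 210}
EFFECTOR_SEGMENT = 70  # residues per fused effector segment
CONTROL_FAMILY = "PolBeta"  # conserved housekeeping control, one per genome
FAST_FAMILIES = ("VMAP", "vWA")  # rapidly evolving components
EAD_LABEL = "EAD1"
_SYSTEM_ROLES = ("VMAP", "MoxR", "vWA")
_GAP_DECOY_RANGE = (120, 300)


@dataclass
class SimConfig:
    seed: int = 0
    n_genomes: int = 300
    phyla: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_PHYLA))
    multicellular_fraction: float = 0.277
    p_system_given_mc: dict[str, float] = field(default_factory=lambda: {"VMAP": 0.3})
    p_system_given_non_mc: dict[str, float] = field(default_factory=lambda: {"VMAP": 0.02})
    genes_per_genome: int = 200
    gene_length_mean: int = 750  # nt
    gene_length_sd: int = 200
    intergenic_gap_mean: float = 30.0
    planted_gap_mean: float = 20.0  # truncated at max_gap: planted systems stay valid
    max_gap: int = 70
    effector_pool: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_EFFECTOR_POOL)
    )
    effector_mean: float = 3.0  # mean fused effector domains per system
    theta_fast: float = 0.25
    theta_slow: float = 0.05
    position_mode: str = "bimodal"  # or "uniform"
    bimodal_modes: tuple[float, float] = (0.33, 0.67)
    bimodal_sd: float = 0.05
    decoy_rate: float = 0.1
    multi_system_fraction: float = 0.36
    ead_coupling_prob: float = 0.9
    hit_jitter: int = 3  # +/- residues on emitted hit coordinates
    background_domain_prob: float = 0.3

    def __post_init__(self) -> None:
        for name, p in [
            ("multicellular_fraction", self.multicellular_fraction),
            ("decoy_rate", self.decoy_rate),
            ("multi_system_fraction", self.multi_system_fraction),
            ("theta_fast", self.theta_fast),
            ("theta_slow", self.theta_slow),
            ("ead_coupling_prob", self.ead_coupling_prob),
        ]:
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")
        if abs(sum(self.phyla.values()) - 1.0) > 1e-9:
            raise ValueError("phylum proportions must sum to 1")
        if self.position_mode not in ("uniform", "bimodal"):
            raise ValueError("position_mode must be 'uniform' or 'bimodal'")
        if self.genes_per_genome < 12:
            raise ValueError("genes_per_genome too small to host planted systems")


@dataclass
class GroundTruth:
    planted: list[dict]
    decoys: list[dict]
    family_members: dict[str, list[str]]
    flags: dict[str, str]
    phyla: dict[str, str]
    position_mode: str

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=1, sort_keys=True)


@dataclass
class SimulatedData:
    genomes: list[GenomeRecord]
    proteins: list[ProteinSeq]
    hits: list[DomainHit]
    msas: dict[str, Msa]
    ground_truth: GroundTruth
    config: SimConfig

    def write(self, outdir) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        cio.write_gene_table(self.genomes, outdir / "gene_table.tsv")
        cio.write_protein_fasta(self.proteins, outdir / "proteins.fasta")
        cio.write_domain_hits(self.hits, outdir / "hits.tsv")
        cio.write_metadata(self.genomes, outdir / "metadata.tsv")
        for fam in sorted(self.msas):
            cio.write_msa_fasta(self.msas[fam], outdir / f"msa_{fam}.fasta")
        (outdir / "ground_truth.json").write_text(self.ground_truth.to_json())

    @property
    def metadata(self) -> dict[str, dict[str, str]]:
        return {
            g.genome_id: {
                "phylum": g.phylum,
                "multicellular": g.multicellular,
                "organism": g.organism,
            }
            for g in self.genomes
        }


# ---------------------------------------------------------------------------
# primitives


def random_protein(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(AA20, size=length))


def mutate(consensus: str, theta: float, rng: np.random.Generator) -> str:
    """Mutate each site independently w.p. theta to a different residue."""
    arr = np.array(list(consensus))
    mask = rng.random(len(arr)) < theta
    n = int(mask.sum())
    if n:
        alt = rng.integers(0, 19, size=n)  # uniform among the 19 alternatives
        cur = np.searchsorted(AA20, arr[mask])
        alt = alt + (alt >= cur)
        arr[mask] = AA20[alt]
    return "".join(arr)


def emit_family(
    consensus: str,
    n_seqs: int,
    theta: float,
    seed_or_rng,
    prefix: str = "seq",
) -> tuple[list[ProteinSeq], Msa]:
    """Emit a protein family from a consensus at per-site divergence theta.

    Each sequence mutates every consensus site independently with
    probability theta to a uniformly chosen different residue; because no
    indels are introduced, the ungapped stack of sequences is the family's
    alignment.
    """
    if not 0.0 <= theta <= 1.0:
        raise ValueError("theta must be in [0, 1]")
    rng = (
        seed_or_rng
        if isinstance(seed_or_rng, np.random.Generator)
        else np.random.default_rng(seed_or_rng)
    )
    seqs = [
        ProteinSeq(f"{prefix}{i:04d}", mutate(consensus, theta, rng))
        for i in range(n_seqs)
    ]
    return seqs, Msa(ids=[s.protein_id for s in seqs], rows=[s.sequence for s in seqs])


def sample_positions(
    n: int,
    mode: str,
    rng: np.random.Generator,
    modes: tuple[float, float] = (0.33, 0.67),
    sd: float = 0.05,
) -> np.ndarray:
    """Normalized anchor positions: uniform or symmetric bimodal on [0, 1]."""
    if mode == "uniform":
        return rng.random(n)
    if mode != "bimodal":
        raise ValueError(f"unknown position mode {mode!r}")
    out = np.empty(n)
    for i in range(n):
        x = -1.0
        while not 0.0 <= x <= 1.0:
            center = modes[int(rng.random() < 0.5)]
            x = rng.normal(center, sd)
        out[i] = x
    return out


def simulate_trait_presence(
    n_genomes: int,
    multicellular_fraction: float,
    p_given_mc: float,
    p_given_non_mc: float,
    rng: np.random.Generator,
) -> tuple[list[str], set[str]]:
    """Flags and system presence only (for enrichment calibration runs).

    Returns per-genome multicellularity flags ("True"/"False") and the set
    of genome ids carrying the system, drawn with the configured
    conditional probabilities.
    """
    flags, present = [], set()
    for i in range(n_genomes):
        mc = rng.random() < multicellular_fraction
        flags.append("True" if mc else "False")
        p = p_given_mc if mc else p_given_non_mc
        if rng.random() < p:
            present.add(f"G{i:04d}")
    return flags, present


# ---------------------------------------------------------------------------
# full generator


class _GeneSpec:
    __slots__ = ("strand", "gap_before", "sequence", "hits", "family", "block", "role")

    def __init__(self, strand, gap_before, sequence, hits, family="", block=None, role=None):
        self.strand = strand
        self.gap_before = gap_before
        self.sequence = sequence  # None -> random background protein
        self.hits = hits  # list of (domain, ali_start, ali_end, score)
        self.family = family
        self.block = block  # block key for planted/decoy systems
        self.role = role


def _geom_gap(rng: np.random.Generator, mean: float) -> int:
    return int(rng.geometric(1.0 / (mean + 1.0)) - 1)


def _system_block(
    gid: str,
    block_key: str,
    consensi: dict[str, str],
    eff_labels,
    eff_w,
    config: SimConfig,
    rng: np.random.Generator,
    msa_rows: dict | None,
    coupled: bool,
    family_suffix: str = "",
) -> tuple[list[_GeneSpec], dict]:
    """Gene specs for one ternary system block (tx order VMAP, MoxR, vWA)."""
    strand = "+" if rng.random() < 0.5 else "-"
    n_eff = 1 + int(rng.poisson(max(config.effector_mean - 1.0, 0.0)))
    effectors = [eff_labels[i] for i in rng.choice(len(eff_labels), size=n_eff, p=eff_w)]

    def jit(x: int) -> int:
        return int(x + rng.integers(-config.hit_jitter, config.hit_jitter + 1))

    comp_specs = []
    for role in _SYSTEM_ROLES:
        theta = config.theta_fast if role in FAST_FAMILIES else config.theta_slow
        seq = mutate(consensi[role], theta, rng)
        dhits = []
        offset = 0
        if role == "VMAP" and coupled:
            ead = mutate(consensi[EAD_LABEL], config.theta_fast, rng)
            seq = ead + seq
            offset = len(ead)
            dhits.append((EAD_LABEL, 1, offset, 80.0))
        dom, s, e = CORE_LAYOUT[role]
        dhits.append((dom, max(jit(s + offset), offset + 1), jit(e + offset), 200.0))
        if role == "vWA":
            for lab in effectors:
                seg = mutate(consensi["eff_" + lab], config.theta_fast, rng)
                s0 = len(seq) + 6
                seq = seq + "G" * 5 + seg
                dhits.append((lab, jit(s0), jit(len(seq)), 90.0))
        if msa_rows is not None and role in msa_rows:
            ids, rows = msa_rows[role]
            core = seq[offset : offset + CORE_LENGTH[role]]
            ids.append(f"{gid}_{role}_{len(ids)}")
            rows.append(core)
        gap = min(_geom_gap(rng, config.planted_gap_mean), config.max_gap)
        comp_specs.append(
            _GeneSpec(strand, gap, seq, dhits, family=role + family_suffix,
                      block=block_key, role=role)
        )
    if strand == "-":
        comp_specs = list(reversed(comp_specs))
    rec = {
        "genome_id": gid,
        "block": block_key,
        "template": "VMAP",
        "strand": strand,
        "effectors": sorted(effectors),
        "anchor_role": "vWA",
        "coupled": coupled,
    }
    return comp_specs, rec


def _ead_satellite(config, consensi, eff_labels, eff_w, rng) -> _GeneSpec:
    """Stand-alone protein carrying the same EAD fused to an effector domain."""
    lab = eff_labels[int(rng.choice(len(eff_labels), p=eff_w))]
    ead = mutate(consensi[EAD_LABEL], config.theta_fast, rng)
    seg = mutate(consensi["eff_" + lab], config.theta_fast, rng)
    seq = ead + "G" * 5 + seg
    dhits = [(EAD_LABEL, 1, len(ead), 75.0), (lab, len(ead) + 6, len(seq), 85.0)]
    strand = "+" if rng.random() < 0.5 else "-"
    return _GeneSpec(strand, _geom_gap(rng, config.intergenic_gap_mean), seq, dhits,
                     family="EAD_satellite")


def generate(config: SimConfig) -> SimulatedData:
    """Generate genomes, proteins, hits, alignments, metadata, ground truth."""
    rng = np.random.default_rng(config.seed)
    phyla = sorted(config.phyla)
    phyla_p = np.array([config.phyla[p] for p in phyla])
    eff_labels = sorted(config.effector_pool)
    eff_w = np.array([config.effector_pool[l] for l in eff_labels])
    eff_w = eff_w / eff_w.sum()

    # stage 1: family consensi, shared by every genome
    consensi = {fam: random_protein(rng, CORE_LENGTH[fam]) for fam in sorted(CORE_LENGTH)}
    consensi[CONTROL_FAMILY] = random_protein(rng, 250)
    consensi[EAD_LABEL] = random_protein(rng, 60)
    for label in eff_labels:
        consensi["eff_" + label] = random_protein(rng, EFFECTOR_SEGMENT - 5)
    # the single-phylum decoy family has its own, unrelated consensi
    decoy_consensi = dict(consensi)
    for fam in sorted(CORE_LENGTH):
        decoy_consensi[fam] = random_protein(rng, CORE_LENGTH[fam])

    genomes: list[GenomeRecord] = []
    proteins: list[ProteinSeq] = []
    hits: list[DomainHit] = []
    planted_records: list[dict] = []
    decoy_records: list[dict] = []
    family_members: dict[str, list[str]] = {}
    flags: dict[str, str] = {}
    phylum_of: dict[str, str] = {}
    msa_rows: dict[str, tuple[list, list]] = {
        fam: ([], []) for fam in ("VMAP", "MoxR", "vWA", CONTROL_FAMILY)
    }
    decoy_cycle = 0

    for gi in range(config.n_genomes):
        gid = f"G{gi:04d}"
        phylum = phyla[int(rng.choice(len(phyla), p=phyla_p))]
        mc = bool(rng.random() < config.multicellular_fraction)
        flags[gid] = "True" if mc else "False"
        phylum_of[gid] = phylum

        # stage 2: background genes with operon-like strand runs
        specs: list[_GeneSpec] = []
        prev_strand = "+"
        for _ in range(config.genes_per_genome):
            if rng.random() >= 0.75:
                prev_strand = "+" if prev_strand == "-" else "-"
            dhits = []
            if rng.random() < config.background_domain_prob:
                for di in range(int(rng.integers(1, 3))):
                    dom = BACKGROUND_DOMAINS[int(rng.integers(0, len(BACKGROUND_DOMAINS)))]
                    s = 1 + di * 80
                    dhits.append((dom, s, s + 59, float(rng.uniform(20, 60))))
            specs.append(
                _GeneSpec(prev_strand, _geom_gap(rng, config.intergenic_gap_mean), None, dhits)
            )

        # stage 3: conserved housekeeping control protein
        ctrl_seq = mutate(consensi[CONTROL_FAMILY], config.theta_slow, rng)
        ctrl = _GeneSpec(
            prev_strand,
            _geom_gap(rng, config.intergenic_gap_mean),
            ctrl_seq,
            [(CONTROL_FAMILY, 1, len(ctrl_seq), 150.0)],
            family=CONTROL_FAMILY,
        )
        ids, rows = msa_rows[CONTROL_FAMILY]
        ids.append(f"{gid}_{CONTROL_FAMILY}_{len(ids)}")
        rows.append(ctrl_seq)
        specs.insert(int(rng.integers(0, len(specs) + 1)), ctrl)

        # stage 4: planted systems
        blocks: list[tuple[float, list[_GeneSpec], dict | None]] = []
        n_sys = 0
        p = (
            config.p_system_given_mc.get("VMAP", 0.0)
            if mc
            else config.p_system_given_non_mc.get("VMAP", 0.0)
        )
        if rng.random() < p:
            n_sys = 2 if rng.random() < config.multi_system_fraction else 1
        coupled_genome = rng.random() < config.ead_coupling_prob
        for si in range(n_sys):
            key = f"{gid}_sys{si}"
            block, rec = _system_block(
                gid, key, consensi, eff_labels, eff_w, config, rng, msa_rows,
                coupled=coupled_genome,
            )
            if coupled_genome:
                block = block + [_ead_satellite(config, consensi, eff_labels, eff_w, rng)]
            x = float(
                sample_positions(
                    1, config.position_mode, rng, config.bimodal_modes, config.bimodal_sd
                )[0]
            )
            rec["target_position"] = x
            blocks.append((x, block, rec))

        # stage 5: at most one decoy per genome, one violation each
        if rng.random() < config.decoy_rate:
            decoy_type = ("gap", "strand", "phylum")[decoy_cycle % 3]
            decoy_cycle += 1
            if decoy_type == "phylum" and phylum != phyla[0]:
                decoy_type = "gap"  # single-phylum decoys live in one phylum only
            key = f"{gid}_decoy"
            use_cons = decoy_consensi if decoy_type == "phylum" else consensi
            suffix = "_decoyfam" if decoy_type == "phylum" else ""
            block, rec = _system_block(
                gid, key, use_cons, eff_labels, eff_w, config, rng, None,
                coupled=False, family_suffix=suffix,
            )
            rec["violation"] = decoy_type
            if decoy_type == "gap":
                # break filter 1 on one internal junction
                block[1].gap_before = int(rng.integers(*_GAP_DECOY_RANGE))
            elif decoy_type == "strand":
                flip = {"+": "-", "-": "+"}
                block[1].strand = flip[block[1].strand]  # break filter 2
            blocks.append((float(rng.random()), block, rec))

        # stage 6: insert blocks near their target normalized positions;
        # indices are fixed up front and applied right-to-left so earlier
        # insertions never shift later ones
        placed: list[tuple[int, list[_GeneSpec]]] = []
        used: set[int] = set()
        # spacing keeps blocks from interleaving; shrink it in small genomes
        spacing = min(15, max(6, (len(specs) + 1) // (2 * len(blocks) + 1)))
        for x, block, _rec in blocks:
            want = min(int(round(x * len(specs))), len(specs))
            # search outward from the target index for the nearest free slot
            idx = None
            for delta in range(0, len(specs) + spacing + 1):
                for cand in (want + delta, want - delta):
                    if 0 <= cand <= len(specs) and all(
                        abs(cand - u) >= spacing for u in used
                    ):
                        idx = cand
                        break
                if idx is not None:
                    break
            if idx is None:
                raise ValueError(
                    "genes_per_genome too small for the planted systems"
                )
            used.add(idx)
            placed.append((idx, block))
        for idx, block in sorted(placed, key=lambda t: -t[0]):
            specs[idx:idx] = block

        genome, g_prots, g_hits, components = _materialize(gid, phylum, flags[gid], specs, config, rng)
        genomes.append(genome)
        proteins.extend(g_prots)
        hits.extend(g_hits)
        for spec, gene in zip(specs, genome.genes):
            if spec.family:
                family_members.setdefault(spec.family, []).append(gene.protein_id)
        for _x, _block, rec in blocks:
            if rec is None:
                continue
            key = rec["block"]
            rec["component_genes"] = components[key]
            anchor_gene = genome.gene(components[key][rec["anchor_role"]])
            rec["anchor_stop"] = (
                anchor_gene.end if anchor_gene.strand == "+" else anchor_gene.start
            )
            rec["replicon_length"] = genome.replicons[anchor_gene.replicon_id]
            if "violation" in rec:
                decoy_records.append(rec)
            else:
                planted_records.append(rec)

    msas = {fam: Msa(ids=i, rows=r) for fam, (i, r) in msa_rows.items() if i}
    gt = GroundTruth(
        planted=planted_records,
        decoys=decoy_records,
        family_members=family_members,
        flags=flags,
        phyla=phylum_of,
        position_mode=config.position_mode,
    )
    return SimulatedData(
        genomes=genomes,
        proteins=proteins,
        hits=hits,
        msas=msas,
        ground_truth=gt,
        config=config,
    )


def _materialize(gid, phylum, flag, specs, config: SimConfig, rng):
    """Assign coordinates, ids and sequences; return genome, proteins, hits."""
    genes: list[GeneRecord] = []
    prots: list[ProteinSeq] = []
    dhits: list[DomainHit] = []
    components: dict[str, dict[str, str]] = {}
    pos = 1 + _geom_gap(rng, config.intergenic_gap_mean)
    rep = f"{gid}_chr"
    for i, spec in enumerate(specs):
        if spec.sequence is None:
            aa_len = max(
                int(rng.normal(config.gene_length_mean, config.gene_length_sd)) // 3, 50
            )
            spec.sequence = random_protein(rng, aa_len)
        nt_len = 3 * len(spec.sequence) + 3
        if i > 0:
            pos += spec.gap_before
        start, end = pos, pos + nt_len - 1
        pos = end + 1  # next gene's gap_before is added on the next iteration
        pid = f"{gid}_p{i:04d}"
        gene_id = f"{gid}_g{i:04d}"
        genes.append(
            GeneRecord(
                gene_id=gene_id,
                protein_id=pid,
                genome_id=gid,
                replicon_id=rep,
                start=start,
                end=end,
                strand=spec.strand,
            )
        )
        prots.append(ProteinSeq(pid, spec.sequence))
        L = len(spec.sequence)
        for dom, s, e, score in spec.hits:
            s2, e2 = max(1, min(int(s), L)), max(1, min(int(e), L))
            if s2 > e2:
                s2, e2 = e2, s2
            dhits.append(DomainHit(pid, dom, s2, e2, float(score), 1e-10))
        if spec.block is not None:
            components.setdefault(spec.block, {})[spec.role] = gene_id
    rep_len = pos + _geom_gap(rng, config.intergenic_gap_mean) + 50
    genome = GenomeRecord(
        genome_id=gid,
        organism=f"organism_{gid}",
        phylum=phylum,
        multicellular=flag,
        replicons={rep: rep_len},
        genes=genes,
    )
    return genome, prots, dhits, components
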