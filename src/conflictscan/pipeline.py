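"""End-to-end orchestration: simulate -> scan -> statistics -> report.

One :func:`run_pipeline` call executes every stage in a fixed order on
either a freshly simulated dataset or inputs loaded from disk, writes all
stage outputs as TSV/JSON under the output directory, and returns a
consolidated :class:`RunReport`.  Given a fixed seed the run is fully
reproducible.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

from . import io as cio
from .architectures import (
    build_network,
    effector_count_distribution,
    paralog_distinctness,
    resolve_architecture,
)
from .cluster import ScoringParams
from .enrichment import (
    length_peaks,
    multicell_enrichment,
    position_chi_square,
    positions_from_instances,
)
from .evostats import mean_positional_entropy, rank_sum_test
from .neighborhoods import CLASSIFY_PARAMS, load_templates, scan_genomes
from .simulate import SimConfig, SimulatedData, generate

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    out_dir: str = "conflictscan_run"
    seed: int = 0
    sim: SimConfig | None = None  # None -> load inputs from the paths below
    gene_table: str | None = None
    proteins_fasta: str | None = None
    hits_tsv: str | None = None
    metadata_tsv: str | None = None
    msa_paths: dict[str, str] = field(default_factory=dict)
    templates_path: str | None = None  # None -> shipped templates
    window: int = 5
    classify_params: ScoringParams = field(default_factory=lambda: CLASSIFY_PARAMS)
    n_bins: int = 20
    fold_positions: bool = False
    entropy_control: str = "PolBeta"
    write_inputs: bool = True

    def validate(self) -> None:
        if self.sim is None:
            for name in ("gene_table", "proteins_fasta", "hits_tsv", "metadata_tsv"):
                path = getattr(self, name)
                if path is None:
                    raise ValueError(f"no simulation config and no {name} given")
                if not Path(path).exists():
                    raise FileNotFoundError(f"{name}: {path}")
        if self.window < 0 or self.n_bins < 2:
            raise ValueError("window must be >= 0 and n_bins >= 2")


@dataclass
class RunReport:
    seed: int
    stage_counts: dict[str, int]
    instances_per_system: dict[str, int]
    enrichment: list[dict]
    entropy: list[dict]
    positions: dict
    lengths: dict
    effectors: dict
    paralogs: dict
    warnings: list[str]

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), indent=1, sort_keys=True, default=str)


def _load_inputs(config: RunConfig):
    genomes = cio.read_gene_table(config.gene_table)
    cio.apply_metadata(genomes, cio.read_metadata(config.metadata_tsv))
    proteins = cio.read_protein_fasta(config.proteins_fasta)
    hits = cio.read_domain_hits(config.hits_tsv, "tsv")
    msas = {label: cio.read_msa_fasta(p) for label, p in config.msa_paths.items()}
    return genomes, proteins, hits, msas, cio.read_metadata(config.metadata_tsv)


def run_pipeline(config: RunConfig) -> RunReport:
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    warnings: list[str] = []
    stage_counts: dict[str, int] = {}
    t0 = time.time()

    # stage: inputs
    if config.sim is not None:
        sim = dataclasses.replace(config.sim, seed=config.seed)
        data: SimulatedData = generate(sim)
        genomes, proteins, hits, msas = data.genomes, data.proteins, data.hits, data.msas
        metadata = data.metadata
        if config.write_inputs:
            data.write(out / "data")
    else:
        genomes, proteins, hits, msas, metadata = _load_inputs(config)
    stage_counts["genomes"] = len(genomes)
    stage_counts["proteins"] = len(proteins)
    stage_counts["domain_hits"] = len(hits)
    logger.info("inputs: %d genomes, %d proteins (%.1fs)", len(genomes), len(proteins), time.time() - t0)

    # stage: scan (template matching + conservation filters, clustering inside)
    templates = load_templates(config.templates_path)
    instances = scan_genomes(
        genomes,
        hits,
        templates,
        proteins=proteins,
        window=config.window,
        classify_params=config.classify_params,
    )
    stage_counts["instances"] = len(instances)
    per_system: dict[str, int] = {}
    for inst in instances:
        per_system[inst.system_type] = per_system.get(inst.system_type, 0) + 1
    cio.write_tsv(
        (
            {
                "system_type": i.system_type,
                "genome_id": i.genome_id,
                "replicon_id": i.replicon_id,
                "strand": i.strand,
                "anchor_stop": i.anchor_stop,
                "replicon_length": i.replicon_length,
                "component_genes": ";".join(f"{r}={g}" for r, g in i.component_genes.items()),
                "effectors": ";".join(i.effectors),
            }
            for i in instances
        ),
        out / "instances.tsv",
    )
    logger.info("scan: %d instances (%.1fs)", len(instances), time.time() - t0)

    # stage: architecture network over proteins with domain hits
    by_protein: dict[str, list] = {}
    for h in hits:
        by_protein.setdefault(h.protein_id, []).append(h)
    archs = [resolve_architecture(v) for v in by_protein.values()]
    net = build_network(archs)
    cio.write_tsv(
        (
            {"from": a, "to": b, "count": c, "edge_class": net.edge_class((a, b))}
            for (a, b), c in sorted(net.edges.items())
        ),
        out / "network_edges.tsv",
    )
    stage_counts["network_nodes"] = len(net.nodes)
    stage_counts["network_edges"] = len(net.edges)

    effectors = effector_count_distribution(instances)
    effectors_out = {k: v for k, v in effectors.items() if k != "counts"}
    paralogs = paralog_distinctness(instances)
    paralogs_out = {k: v for k, v in paralogs.items() if k != "per_organism"}

    # stage: entropy comparison of component alignments vs the control
    entropy_rows: list[dict] = []
    control = msas.get(config.entropy_control)
    control_profile = (
        mean_positional_entropy(control, config.entropy_control) if control else None
    )
    for label in sorted(msas):
        prof = mean_positional_entropy(msas[label], label)
        row = {
            "component": label,
            "mean_entropy": round(prof.mean_entropy, 4),
            "n_columns": prof.n_columns_used,
        }
        if control_profile and label != config.entropy_control:
            rs = rank_sum_test(prof.column_entropies, control_profile.column_entropies)
            row["p_vs_control"] = rs.p_value
        entropy_rows.append(row)
    cio.write_tsv(entropy_rows, out / "entropy.tsv")

    # stage: enrichment
    enr = multicell_enrichment(instances, metadata)
    enr_rows = [
        {
            "system": r.system,
            "q": r.inp.q if r.inp else "NA",
            "m": r.inp.m if r.inp else "NA",
            "n": r.inp.n if r.inp else "NA",
            "k": r.inp.k if r.inp else "NA",
            "p_upper": r.p_upper if r.p_upper is not None else "NA",
            "log10_p": r.log10_p if r.log10_p is not None else "NA",
            "fold": r.fold if r.fold is not None else "NA",
        }
        for r in enr
    ]
    cio.write_tsv(enr_rows, out / "enrichment.tsv")

    # stage: positional distribution
    if instances:
        pos = position_chi_square(
            positions_from_instances(instances), config.n_bins, config.fold_positions
        )
        if len(pos.positions) < config.n_bins:
            warnings.append(
                f"only {len(pos.positions)} positions for {config.n_bins} bins"
            )
        pos_out = {
            "n": len(pos.positions),
            "n_bins": pos.n_bins,
            "chi2": round(pos.chi2, 4),
            "df": pos.df,
            "p": pos.p,
            "folded": pos.folded,
        }
    else:
        pos_out = {}
        warnings.append("no instances; positional test skipped")

    # stage: length distribution of the effector-bearing component
    anchor_prots = {
        i.component_genes.get("vWA") or next(iter(i.component_genes.values()))
        for i in instances
    }
    gene_to_prot = {g.gene_id: g.protein_id for gr in genomes for g in gr.genes}
    prot_len = {p.protein_id: len(p) for p in proteins}
    lengths = [
        prot_len[gene_to_prot[g]] for g in anchor_prots if g in gene_to_prot
        and gene_to_prot[g] in prot_len
    ]
    if len(lengths) >= 10:
        ld = length_peaks(lengths)
        len_out = {
            "n": len(lengths),
            "peaks": ld.peak_centers,
            "bin_width": ld.bin_width,
        }
    else:
        len_out = {"n": len(lengths), "peaks": [], "bin_width": None}
        if instances:
            warnings.append("fewer than 10 component lengths; peaks not called")

    report = RunReport(
        seed=config.seed,
        stage_counts=stage_counts,
        instances_per_system=per_system,
        enrichment=enr_rows,
        entropy=entropy_rows,
        positions=pos_out,
        lengths=len_out,
        effectors=effectors_out,
        paralogs=paralogs_out,
        warnings=warnings,
    )
    (out / "report.json").write_text(report.to_json())
    (out / "report.md").write_text(_report_markdown(report))
    logger.info("pipeline done (%.1fs)", time.time() - t0)
    return report


def _report_markdown(report: RunReport) -> str:
    lines = ["# conflictscan run report", ""]
    lines.append(f"seed: {report.seed}")
    lines.append("")
    lines.append("## Stage record counts")
    for k, v in report.stage_counts.items():
        lines.append(f"- {k}: {v}")
    lines.append("")
    lines.append("## Instances per system")
    for k, v in sorted(report.instances_per_system.items()):
        lines.append(f"- {k}: {v}")
    lines.append("")
    lines.append("## Enrichment")
    for row in report.enrichment:
        lines.append(
            f"- {row['system']}: q={row['q']} k={row['k']} p={row['p_upper']}"
        )
    lines.append("")
    lines.append("## Entropy")
    for row in report.entropy:
        p = row.get("p_vs_control", "")
        lines.append(
            f"- {row['component']}: mean H = {row['mean_entropy']} bits"
            + (f", p vs control = {p}" if p != "" else "")
        )
    if report.positions:
        lines.append("")
        lines.append("## Positional test")
        lines.append(
            f"- chi2 = {report.positions['chi2']} (df {report.positions['df']}), "
            f"p = {report.positions['p']}"
        )
    if report.warnings:
        lines.append("")
        lines.append("## Warnings")
        for w in report.warnings:
            lines.append(f"- {w}")
    return "\n".join(lines) + "\n"
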