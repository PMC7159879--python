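"""Readers and writers for the external formats the pipeline touches.

Everything is normalized onto the data model in :mod:`conflictscan.model`:
GFF3 + FASTA or a flat gene-feature table for genomes, HMMER3 ``domtblout``
or TSV for domain hits, aligned FASTA for alignments, newick for trees.
Coordinates are 1-based inclusive throughout.

Malformed data rows are never dropped silently: features that merely lack a
protein_id are skipped with a logged warning, everything else raises.
"""

from __future__ import annotations

import csv
import logging
from pathlib import Path
from typing import Iterable

import dendropy
from Bio import SeqIO

from .model import DomainHit, GeneRecord, GenomeRecord, Msa, ProteinSeq

logger = logging.getLogger(__name__)

GENE_TABLE_COLUMNS = [
    "genome_id",
    "replicon_id",
    "replicon_length",
    "gene_id",
    "protein_id",
    "start",
    "end",
    "strand",
]


# ---------------------------------------------------------------------------
# genomes


def read_gff3_with_fasta(gff_path, fasta_path, genome_id: str | None = None) -> GenomeRecord:
    """Parse CDS features from a GFF3 file into a :class:`GenomeRecord`.

    Replicon lengths come from the companion genomic FASTA.  CDS features
    must carry an ``ID`` attribute; ``protein_id`` defaults to the ID when
    absent only if the feature also has no ``protein_id`` attribute -- in
    that case the feature is skipped with a warning, matching the contract
    that only protein-coding features with a resolvable product enter the
    pipeline.
    """
    gff_path = Path(gff_path)
    replicons = {rec.id: len(rec.seq) for rec in SeqIO.parse(str(fasta_path), "fasta")}
    genes: list[GeneRecord] = []
    gid = genome_id or gff_path.stem
    with open(gff_path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 9:
                raise ValueError(f"{gff_path}:{lineno}: expected 9 columns, got {len(parts)}")
            seqid, _source, ftype, start_s, end_s, _score, strand, _phase, attrs = parts
            if ftype != "CDS":
                continue
            try:
                start, end = int(start_s), int(end_s)
            except ValueError as exc:
                raise ValueError(f"{gff_path}:{lineno}: non-integer coordinate") from exc
            if start > end:
                raise ValueError(f"{gff_path}:{lineno}: start {start} > end {end}")
            if seqid not in replicons:
                raise ValueError(f"{gff_path}:{lineno}: unknown replicon {seqid!r}")
            attr = _parse_gff_attributes(attrs)
            feature_id = attr.get("ID")
            protein_id = attr.get("protein_id")
            if protein_id is None:
                logger.warning(
                    "%s:%d: CDS without protein_id skipped (ID=%s)",
                    gff_path, lineno, feature_id,
                )
                continue
            genes.append(
                GeneRecord(
                    gene_id=feature_id or protein_id,
                    protein_id=protein_id,
                    genome_id=gid,
                    replicon_id=seqid,
                    start=start,
                    end=end,
                    strand=strand,
                )
            )
    return GenomeRecord(genome_id=gid, replicons=replicons, genes=genes)


def _parse_gff_attributes(text: str) -> dict[str, str]:
    out = {}
    for chunk in text.split(";"):
        chunk = chunk.strip()
        if not chunk:
            continue
        if "=" not in chunk:
            raise ValueError(f"malformed GFF3 attribute {chunk!r}")
        k, v = chunk.split("=", 1)
        out[k] = v
    return out


def read_gene_table(tsv_path) -> list[GenomeRecord]:
    """Read the flat gene-feature table (one row per gene) into genomes."""
    per_genome: dict[str, dict] = {}
    with open(tsv_path) as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        missing = set(GENE_TABLE_COLUMNS) - set(reader.fieldnames or [])
        if missing:
            raise ValueError(f"{tsv_path}: missing columns {sorted(missing)}")
        for rowno, row in enumerate(reader, 2):
            gid = row["genome_id"]
            entry = per_genome.setdefault(gid, {"replicons": {}, "genes": [], "seen": set()})
            if row["gene_id"] in entry["seen"]:
                raise ValueError(
                    f"{tsv_path}:{rowno}: duplicate gene id {row['gene_id']} in {gid}"
                )
            entry["seen"].add(row["gene_id"])
            try:
                start, end = int(row["start"]), int(row["end"])
                rlen = int(row["replicon_length"])
            except ValueError as exc:
                raise ValueError(f"{tsv_path}:{rowno}: non-integer field") from exc
            if start > end:
                raise ValueError(f"{tsv_path}:{rowno}: start {start} > end {end}")
            prev = entry["replicons"].setdefault(row["replicon_id"], rlen)
            if prev != rlen:
                raise ValueError(
                    f"{tsv_path}:{rowno}: inconsistent length for replicon "
                    f"{row['replicon_id']}"
                )
            entry["genes"].append(
                GeneRecord(
                    gene_id=row["gene_id"],
                    protein_id=row["protein_id"],
                    genome_id=gid,
                    replicon_id=row["replicon_id"],
                    start=start,
                    end=end,
                    strand=row["strand"],
                )
            )
    return [
        GenomeRecord(genome_id=gid, replicons=e["replicons"], genes=e["genes"])
        for gid, e in sorted(per_genome.items())
    ]


def write_gene_table(genomes: Iterable[GenomeRecord], tsv_path) -> None:
    with open(tsv_path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(GENE_TABLE_COLUMNS)
        for gr in genomes:
            for g in gr.genes:
                w.writerow(
                    [
                        gr.genome_id,
                        g.replicon_id,
                        gr.replicons[g.replicon_id],
                        g.gene_id,
                        g.protein_id,
                        g.start,
                        g.end,
                        g.strand,
                    ]
                )


def read_metadata(tsv_path) -> dict[str, dict[str, str]]:
    """Read the organism metadata table (genome_id, phylum, multicellular)."""
    out: dict[str, dict[str, str]] = {}
    with open(tsv_path) as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        for row in reader:
            flag = row.get("multicellular", "NA")
            if flag not in ("True", "False", "NA"):
                raise ValueError(f"bad multicellular flag {flag!r} for {row['genome_id']}")
            out[row["genome_id"]] = {
                "phylum": row.get("phylum", ""),
                "multicellular": flag,
                "organism": row.get("organism", ""),
            }
    return out


def write_metadata(genomes: Iterable[GenomeRecord], tsv_path) -> None:
    with open(tsv_path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(["genome_id", "organism", "phylum", "multicellular"])
        for gr in genomes:
            w.writerow([gr.genome_id, gr.organism, gr.phylum, gr.multicellular])


def apply_metadata(genomes: Iterable[GenomeRecord], metadata: dict[str, dict[str, str]]) -> None:
    """Merge a metadata table onto genomes in place; absent genomes get NA."""
    for gr in genomes:
        meta = metadata.get(gr.genome_id)
        if meta is None:
            gr.multicellular = "NA"
            continue
        gr.phylum = meta.get("phylum", gr.phylum)
        gr.multicellular = meta.get("multicellular", "NA")
        gr.organism = meta.get("organism", gr.organism)


# ---------------------------------------------------------------------------
# proteins


def read_protein_fasta(path) -> list[ProteinSeq]:
    return [ProteinSeq(rec.id, str(rec.seq).upper()) for rec in SeqIO.parse(str(path), "fasta")]


def write_protein_fasta(proteins: Iterable[ProteinSeq], path) -> None:
    with open(path, "w") as fh:
        for p in proteins:
            fh.write(f">{p.protein_id}\n{p.sequence}\n")


# ---------------------------------------------------------------------------
# domain hits

# HMMER3 --domtblout column indices (whitespace-separated; 22 fixed columns
# before the free-text description):
#   0 target name, 3 query (profile) name, 13 this-domain bit score,
#   12 i-Evalue, 17 ali coord from, 18 ali coord to
_DOMTBL_MIN_COLS = 23


def read_domain_hits(path, dialect: str = "tsv") -> list[DomainHit]:
    if dialect == "tsv":
        return _read_hits_tsv(path)
    if dialect == "domtblout":
        return _read_hits_domtblout(path)
    raise ValueError(f"unknown dialect {dialect!r}")


def _read_hits_tsv(path) -> list[DomainHit]:
    hits = []
    with open(path) as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        required = {"protein_id", "domain", "ali_start", "ali_end", "score", "evalue"}
        missing = required - set(reader.fieldnames or [])
        if missing:
            raise ValueError(f"{path}: missing columns {sorted(missing)}")
        for rowno, row in enumerate(reader, 2):
            try:
                hits.append(
                    DomainHit(
                        protein_id=row["protein_id"],
                        domain=row["domain"],
                        ali_start=int(row["ali_start"]),
                        ali_end=int(row["ali_end"]),
                        score=float(row["score"]),
                        evalue=float(row["evalue"]),
                    )
                )
            except ValueError as exc:
                raise ValueError(f"{path}:{rowno}: {exc}") from exc
    return hits


def _read_hits_domtblout(path) -> list[DomainHit]:
    hits = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            if line.startswith("#") or not line.strip():
                continue
            parts = line.split()
            if len(parts) < _DOMTBL_MIN_COLS:
                raise ValueError(
                    f"{path}:{lineno}: expected >= {_DOMTBL_MIN_COLS} columns, "
                    f"got {len(parts)}"
                )
            try:
                hits.append(
                    DomainHit(
                        protein_id=parts[0],
                        domain=parts[3],
                        ali_start=int(parts[17]),
                        ali_end=int(parts[18]),
                        score=float(parts[13]),
                        evalue=float(parts[12]),
                    )
                )
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: {exc}") from exc
    return hits


def write_domain_hits(hits: Iterable[DomainHit], path) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(["protein_id", "domain", "ali_start", "ali_end", "score", "evalue"])
        for h in hits:
            w.writerow([h.protein_id, h.domain, h.ali_start, h.ali_end, h.score, h.evalue])


# ---------------------------------------------------------------------------
# alignments and trees


def read_msa_fasta(path) -> Msa:
    ids, rows = [], []
    for rec in SeqIO.parse(str(path), "fasta"):
        ids.append(rec.id)
        rows.append(str(rec.seq).upper())
    return Msa(ids=ids, rows=rows)


def write_msa_fasta(msa: Msa, path) -> None:
    with open(path, "w") as fh:
        for i, r in zip(msa.ids, msa.rows):
            fh.write(f">{i}\n{r}\n")


def read_newick(path_or_string) -> dendropy.Tree:
    """Read a single newick tree; duplicate leaf labels are an error."""
    src = str(path_or_string)
    try:
        if src.strip().endswith(";") and "(" in src:
            tree = dendropy.Tree.get(data=src, schema="newick")
        else:
            tree = dendropy.Tree.get(path=src, schema="newick")
    except dendropy.dataio.newickreader.NewickReader.NewickReaderDuplicateTaxonError as exc:
        raise ValueError(f"duplicate leaf labels in tree: {exc}") from exc
    labels = [leaf.taxon.label for leaf in tree.leaf_node_iter()]
    if len(set(labels)) != len(labels):
        raise ValueError("duplicate leaf labels in tree")
    return tree


def write_tsv(records: Iterable[dict], path, columns: list[str] | None = None) -> None:
    """Write dict records as a TSV with deterministic column order."""
    records = list(records)
    if columns is None:
        columns = []
        for rec in records:
            for k in rec:
                if k not in columns:
                    columns.append(k)
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(columns)
        for rec in records:
            w.writerow([rec.get(c, "") for c in columns])
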