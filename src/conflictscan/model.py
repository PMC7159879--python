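"""Core data model for the conflict-system discovery pipeline.

Coordinates are 1-based and inclusive on both ends (GFF3 convention) and
are kept that way internally.  Genes on the '-' strand still satisfy
``start <= end``; orientation is carried only in the ``strand`` field.
"""

from __future__ import annotations

from dataclasses import dataclass, field

AA_ALPHABET = frozenset("ACDEFGHIKLMNPQRSTVWYX")

MULTICELL_STATES = ("True", "False", "NA")


@dataclass(frozen=True)
class GeneRecord:
    """A single protein-coding gene on a replicon."""

    gene_id: str
    protein_id: str
    genome_id: str
    replicon_id: str
    start: int
    end: int
    strand: str

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError(
                f"gene {self.gene_id}: start {self.start} > end {self.end}"
            )
        if self.strand not in ("+", "-"):
            raise ValueError(f"gene {self.gene_id}: strand {self.strand!r} not in +/-")

    @property
    def length_nt(self) -> int:
        return self.end - self.start + 1


@dataclass
class GenomeRecord:
    """An annotated replicon set with organism metadata.

    ``multicellular`` is the curated trait flag used in the enrichment
    tests: "True", "False" or "NA" (no information).
    """

    genome_id: str
    organism: str = ""
    phylum: str = ""
    multicellular: str = "NA"
    replicons: dict[str, int] = field(default_factory=dict)
    genes: list[GeneRecord] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.multicellular not in MULTICELL_STATES:
            raise ValueError(
                f"genome {self.genome_id}: multicellular flag "
                f"{self.multicellular!r} not in {MULTICELL_STATES}"
            )
        self.sort_genes()
        self.validate()

    def sort_genes(self) -> None:
        self.genes.sort(key=lambda g: (g.replicon_id, g.start, g.end, g.gene_id))

    def validate(self) -> None:
        seen: set[str] = set()
        for g in self.genes:
            if g.gene_id in seen:
                raise ValueError(f"duplicate gene id {g.gene_id} in {self.genome_id}")
            seen.add(g.gene_id)
            if g.replicon_id not in self.replicons:
                raise ValueError(
                    f"gene {g.gene_id} references unknown replicon {g.replicon_id}"
                )
            if g.end > self.replicons[g.replicon_id]:
                raise ValueError(
                    f"gene {g.gene_id} end {g.end} exceeds replicon "
                    f"{g.replicon_id} length {self.replicons[g.replicon_id]}"
                )

    def genes_on(self, replicon_id: str) -> list[GeneRecord]:
        return [g for g in self.genes if g.replicon_id == replicon_id]

    def gene(self, gene_id: str) -> GeneRecord:
        for g in self.genes:
            if g.gene_id == gene_id:
                return g
        raise KeyError(f"gene {gene_id} not in genome {self.genome_id}")


@dataclass(frozen=True)
class ProteinSeq:
    protein_id: str
    sequence: str

    def __post_init__(self) -> None:
        if len(self.sequence) < 1:
            raise ValueError(f"protein {self.protein_id}: empty sequence")
        bad = set(self.sequence) - AA_ALPHABET
        if bad:
            raise ValueError(
                f"protein {self.protein_id}: residues outside alphabet: {sorted(bad)}"
            )

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class DomainHit:
    """One domain hit on a protein (alignment coordinates, 1-based)."""

    protein_id: str
    domain: str
    ali_start: int
    ali_end: int
    score: float
    evalue: float = 0.0

    def __post_init__(self) -> None:
        if not (1 <= self.ali_start <= self.ali_end):
            raise ValueError(
                f"hit {self.domain} on {self.protein_id}: bad coordinates "
                f"{self.ali_start}-{self.ali_end}"
            )
        if self.evalue < 0:
            raise ValueError("evalue must be non-negative")


@dataclass
class Msa:
    """A gapped multiple sequence alignment ('-' is the gap character)."""

    ids: list[str]
    rows: list[str]

    def __post_init__(self) -> None:
        if len(self.ids) != len(self.rows):
            raise ValueError("ids and rows differ in count")
        if len(set(self.ids)) != len(self.ids):
            raise ValueError("duplicate sequence ids in alignment")
        if self.rows:
            n = len(self.rows[0])
            for i, r in enumerate(self.rows):
                if len(r) != n:
                    raise ValueError(
                        f"ragged alignment: row {self.ids[i]} has length "
                        f"{len(r)}, expected {n}"
                    )

    @property
    def n_columns(self) -> int:
        return len(self.rows[0]) if self.rows else 0

    def column(self, j: int) -> str:
        return "".join(r[j] for r in self.rows)
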