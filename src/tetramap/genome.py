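"""Toy haploid genome models: chromosomes, gene models, reference sequence.

A :class:`GenomeModel` carries the physical map (chromosome names and
lengths in bp), the gene models used for coding-consequence calls, and the
uniform genetic-map rate (cM/Mbp) used by the meiosis simulator. Reference
sequences are plain ``{chromosome: str}`` dictionaries; FASTA and GFF3 are
the on-disk forms.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

__all__ = [
    "GeneModel",
    "GenomeModel",
    "GenomeConfigError",
    "build_genome_model",
    "synthesize_reference",
    "extract_cds",
    "cds_index_of",
    "write_fasta",
    "read_fasta",
    "write_gff3",
    "read_gff3",
]

_COMPLEMENT = str.maketrans("ACGTacgt", "TGCAtgca")

#: the 61 sense codons of the standard nuclear genetic code
SENSE_CODONS = tuple(
    c
    for c in ("".join(p) for p in itertools.product("ACGT", repeat=3))
    if c not in ("TAA", "TAG", "TGA")
)


class GenomeConfigError(ValueError):
    """Raised when a genome/gene configuration violates an invariant."""


@dataclass(frozen=True)
class GeneModel:
    """A single-transcript protein-coding gene.

    ``cds_intervals`` are 1-based inclusive genomic intervals, sorted and
    non-overlapping; their total length must be divisible by 3.
    ``transit_peptide_len`` (residues) supports mature-protein coordinates
    for chloroplast-targeted proteins; 0 means no transit peptide.
    """

    id: str
    chromosome: str
    cds_intervals: tuple[tuple[int, int], ...]
    strand: str
    transit_peptide_len: int = 0

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise GenomeConfigError(f"gene {self.id}: strand must be '+' or '-'")
        if not self.cds_intervals:
            raise GenomeConfigError(f"gene {self.id}: no CDS intervals")
        prev_end = 0
        for start, end in self.cds_intervals:
            if start < 1 or end < start:
                raise GenomeConfigError(
                    f"gene {self.id}: bad CDS interval ({start}, {end})"
                )
            if start <= prev_end:
                raise GenomeConfigError(
                    f"gene {self.id}: CDS intervals overlap or are unsorted"
                )
            prev_end = end
        if self.cds_length % 3 != 0:
            raise GenomeConfigError(
                f"gene {self.id}: CDS length {self.cds_length} not divisible by 3"
            )
        if self.transit_peptide_len < 0:
            raise GenomeConfigError(f"gene {self.id}: negative transit peptide")

    @property
    def cds_length(self) -> int:
        return sum(end - start + 1 for start, end in self.cds_intervals)

    @property
    def span(self) -> tuple[int, int]:
        return self.cds_intervals[0][0], self.cds_intervals[-1][1]

    def contains(self, pos: int) -> bool:
        """True if ``pos`` (1-based) falls inside a CDS interval."""
        return any(start <= pos <= end for start, end in self.cds_intervals)


@dataclass(frozen=True)
class GenomeModel:
    """Physical + genetic map of a haploid toy genome.

    genetic_map_rate is in centimorgan per Mbp, uniform along every
    chromosome (no hot/cold spots).
    """

    chromosomes: tuple[tuple[str, int], ...]
    genes: tuple[GeneModel, ...] = field(default=())
    genetic_map_rate: float = 6.0

    def __post_init__(self) -> None:
        if self.genetic_map_rate < 0:
            raise GenomeConfigError("genetic_map_rate must be >= 0")
        seen = set()
        for name, length in self.chromosomes:
            if length <= 0:
                raise GenomeConfigError(f"chromosome {name}: length must be > 0")
            if name in seen:
                raise GenomeConfigError(f"duplicate chromosome name {name}")
            seen.add(name)
        lengths = dict(self.chromosomes)
        for gene in self.genes:
            if gene.chromosome not in lengths:
                raise GenomeConfigError(
                    f"gene {gene.id}: unknown chromosome {gene.chromosome}"
                )
            if gene.span[1] > lengths[gene.chromosome]:
                raise GenomeConfigError(
                    f"gene {gene.id}: extends beyond end of {gene.chromosome}"
                )

    @property
    def total_length(self) -> int:
        return sum(length for _, length in self.chromosomes)

    def chromosome_length(self, name: str) -> int:
        for cname, length in self.chromosomes:
            if cname == name:
                return length
        raise KeyError(name)

    def gene(self, gene_id: str) -> GeneModel:
        for g in self.genes:
            if g.id == gene_id:
                return g
        raise KeyError(gene_id)

    def genes_on(self, chromosome: str) -> list[GeneModel]:
        return [g for g in self.genes if g.chromosome == chromosome]

    def genes_overlapping(self, chromosome: str, pos: int) -> list[GeneModel]:
        """Genes whose CDS contains the 1-based position ``pos``."""
        return [g for g in self.genes_on(chromosome) if g.contains(pos)]

    def locate(self, offset: int) -> tuple[str, int]:
        """Map a 0-based genome-wide offset to (chromosome, 1-based pos)."""
        for name, length in self.chromosomes:
            if offset < length:
                return name, offset + 1
            offset -= length
        raise IndexError("offset beyond genome end")


def build_genome_model(cfg) -> GenomeModel:
    """Deterministically lay out chromosomes and genes from a SimConfig.

    Chromosomes are named chr01, chr02, ... with equal length
    ``cfg.chromosome_length``. ``cfg.n_genes`` two-exon genes (two 300 bp
    CDS intervals separated by a 200 bp intron; 600 nt CDS = 200 codons)
    are spread evenly, alternating strand. Every second gene is given a
    31-residue transit peptide, emulating nuclear-encoded chloroplast
    proteins whose mature coordinates differ from precursor coordinates.
    """
    if cfg.n_chromosomes < 1:
        raise GenomeConfigError("need at least one chromosome")
    if cfg.n_genes < 1:
        raise GenomeConfigError("need at least one gene")
    chromosomes = tuple(
        (f"chr{i + 1:02d}", int(cfg.chromosome_length))
        for i in range(cfg.n_chromosomes)
    )
    per_chrom = [cfg.n_genes // cfg.n_chromosomes] * cfg.n_chromosomes
    for i in range(cfg.n_genes % cfg.n_chromosomes):
        per_chrom[i] += 1
    genes = []
    gene_no = 0
    for (cname, clen), n_here in zip(chromosomes, per_chrom):
        if n_here == 0:
            continue
        spacing = clen // (n_here + 1)
        if spacing < 1000:
            raise GenomeConfigError("chromosomes too short for requested genes")
        for k in range(n_here):
            gene_no += 1
            start = spacing * (k + 1)
            intervals = ((start, start + 299), (start + 500, start + 799))
            genes.append(
                GeneModel(
                    id=f"g{gene_no:02d}",
                    chromosome=cname,
                    cds_intervals=intervals,
                    strand="+" if gene_no % 2 else "-",
                    transit_peptide_len=31 if gene_no % 2 == 0 else 0,
                )
            )
    return GenomeModel(
        chromosomes=chromosomes,
        genes=tuple(genes),
        genetic_map_rate=float(cfg.genetic_map_rate),
    )


def transcription_order_positions(gene: GeneModel) -> list[int]:
    """Genomic positions of the CDS in transcription (5'→3' mRNA) order."""
    positions: list[int] = []
    for start, end in gene.cds_intervals:
        positions.extend(range(start, end + 1))
    if gene.strand == "-":
        positions.reverse()
    return positions


def cds_index_of(gene: GeneModel, pos: int) -> int | None:
    """1-based CDS coordinate of genomic position ``pos``, or None."""
    offset = 0
    intervals = gene.cds_intervals
    if gene.strand == "+":
        for start, end in intervals:
            if start <= pos <= end:
                return offset + (pos - start) + 1
            offset += end - start + 1
    else:
        for start, end in reversed(intervals):
            if start <= pos <= end:
                return offset + (end - pos) + 1
            offset += end - start + 1
    return None


def extract_cds(gene: GeneModel, reference: dict[str, str]) -> str:
    """Coding-strand CDS sequence of ``gene`` from the reference genome."""
    seq = reference[gene.chromosome]
    parts = [seq[start - 1 : end] for start, end in gene.cds_intervals]
    cds = "".join(parts)
    if gene.strand == "-":
        cds = cds.translate(_COMPLEMENT)[::-1]
    return cds


def synthesize_reference(model: GenomeModel, seed: int | np.random.Generator) -> dict[str, str]:
    """Random reference sequence consistent with the gene models.

    Intergenic/intronic sequence is uniform ACGT; CDS regions are rewritten
    with uniformly drawn sense codons so every gene translates without a
    premature stop.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    bases = np.frombuffer(b"ACGT", dtype="S1")
    reference: dict[str, np.ndarray] = {}
    for name, length in model.chromosomes:
        reference[name] = bases[rng.integers(0, 4, size=length)].copy()
    for gene in model.genes:
        n_codons = gene.cds_length // 3
        codons = rng.choice(len(SENSE_CODONS), size=n_codons)
        cds = "".join(SENSE_CODONS[i] for i in codons)
        strand_seq = cds if gene.strand == "+" else cds.translate(_COMPLEMENT)[::-1]
        arr = reference[gene.chromosome]
        offset = 0
        for start, end in gene.cds_intervals:
            n = end - start + 1
            arr[start - 1 : end] = np.frombuffer(
                strand_seq[offset : offset + n].encode(), dtype="S1"
            )
            offset += n
    return {name: arr.tobytes().decode() for name, arr in reference.items()}


# ---------------------------------------------------------------------------
# FASTA / GFF3 round trips


def write_fasta(reference: dict[str, str], path) -> None:
    records = [
        SeqRecord(Seq(seq), id=name, description="") for name, seq in reference.items()
    ]
    SeqIO.write(records, str(path), "fasta")


def read_fasta(path) -> dict[str, str]:
    return {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}


def write_gff3(model: GenomeModel, path) -> None:
    """Write gene models as GFF3 (gene + CDS features, phase computed)."""
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write("##gff-version 3\n")
        for name, length in model.chromosomes:
            fh.write(f"##sequence-region {name} 1 {length}\n")
        for gene in model.genes:
            span = gene.span
            fh.write(
                "\t".join(
                    [
                        gene.chromosome,
                        "tetramap",
                        "gene",
                        str(span[0]),
                        str(span[1]),
                        ".",
                        gene.strand,
                        ".",
                        f"ID={gene.id};transit_peptide_len={gene.transit_peptide_len}",
                    ]
                )
                + "\n"
            )
            intervals = gene.cds_intervals
            order = intervals if gene.strand == "+" else tuple(reversed(intervals))
            consumed = 0
            phases = {}
            for start, end in order:
                phases[(start, end)] = (3 - consumed % 3) % 3
                consumed += end - start + 1
            for i, (start, end) in enumerate(intervals):
                fh.write(
                    "\t".join(
                        [
                            gene.chromosome,
                            "tetramap",
                            "CDS",
                            str(start),
                            str(end),
                            ".",
                            gene.strand,
                            str(phases[(start, end)]),
                            f"ID=cds:{gene.id}.{i + 1};Parent={gene.id}",
                        ]
                    )
                    + "\n"
                )


def read_gff3(path, genetic_map_rate: float = 6.0) -> GenomeModel:
    """Reconstruct a GenomeModel from a GFF3 written by :func:`write_gff3`."""
    import gffutils

    db = gffutils.create_db(
        str(path), ":memory:", force=True, keep_order=True, merge_strategy="error"
    )
    chrom_lengths: dict[str, int] = {}
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            if line.startswith("##sequence-region"):
                _, name, _start, end = line.split()
                chrom_lengths[name] = int(end)
    genes = []
    for gene_feat in db.features_of_type("gene"):
        intervals = tuple(
            sorted(
                (cds.start, cds.end)
                for cds in db.children(gene_feat, featuretype="CDS")
            )
        )
        genes.append(
            GeneModel(
                id=gene_feat.id,
                chromosome=gene_feat.seqid,
                cds_intervals=intervals,
                strand=gene_feat.strand,
                transit_peptide_len=int(
                    gene_feat.attributes.get("transit_peptide_len", ["0"])[0]
                ),
            )
        )
        chrom_lengths.setdefault(gene_feat.seqid, gene_feat.end)
    chromosomes = tuple(sorted(chrom_lengths.items()))
    return GenomeModel(
        chromosomes=chromosomes,
        genes=tuple(sorted(genes, key=lambda g: g.id)),
        genetic_map_rate=genetic_map_rate,
    )


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string."""
    return seq.translate(_COMPLEMENT)[::-1]
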