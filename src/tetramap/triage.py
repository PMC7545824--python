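"""Per-strain variant triage: the filtering cascade of a haploid
mapping-by-sequencing screen.

Stages, in the order they are meant to compose: keep confidently-called
variants (frequency value strictly over the cutoff, default 80%), subtract
anything seen in wild-type reference call sets at *any* frequency, keep
only protein-changing (non-synonymous) variants, and finally intersect
independent experiments so only variants confirmed by every experiment
survive.
"""

from __future__ import annotations

from dataclasses import dataclass

from .genome import GeneModel, extract_cds
from .hgvs import (
    ReferenceMismatchError,
    apply_coding_change,
    genomic_to_coding,
)
from .variants import VariantTable

__all__ = [
    "TriageConfig",
    "frequency_filter",
    "subtract_variants",
    "select_nonsynonymous",
    "intersect_experiments",
]


@dataclass(frozen=True)
class TriageConfig:
    """Frequency-cutoff policy. The default keeps variants strictly over
    80%, tolerating ambiguous base calls in up to 20% of reads."""

    frequency_cutoff: float = 80.0
    keep_at_cutoff: bool = False

    def __post_init__(self) -> None:
        if not 0.0 <= self.frequency_cutoff <= 100.0:
            raise ValueError("frequency_cutoff must be in [0, 100]")

    def passes(self, frequency: float) -> bool:
        if self.keep_at_cutoff:
            return frequency >= self.frequency_cutoff
        return frequency > self.frequency_cutoff


def frequency_filter(table: VariantTable, cfg: TriageConfig) -> VariantTable:
    """Keep records whose frequency value passes the cutoff (order kept)."""
    return VariantTable.from_records(
        [r for r in table.records if cfg.passes(r.frequency)],
        provenance=f"{table.provenance}|freq>{cfg.frequency_cutoff}",
    )


def subtract_variants(
    table: VariantTable, references: list[VariantTable]
) -> VariantTable:
    """Remove any record whose site key appears in any reference table.

    Reference frequency is deliberately ignored: a variant present at any
    frequency in a phenotype-negative pool or wild-type strain cannot be
    the causative change.
    """
    drop: set[str] = set()
    for ref in references:
        drop |= ref.keys()
    return VariantTable.from_records(
        [r for r in table.records if r.key not in drop],
        provenance=f"{table.provenance}|subtracted",
    )


def select_nonsynonymous(
    table: VariantTable,
    reference: dict[str, str],
    genes: list[GeneModel],
) -> VariantTable:
    """Keep records that change a translated protein.

    Missense, nonsense, frameshift indels, in-frame CDS indels, and
    residue-altering MNPs are kept; intergenic, intronic, and synonymous
    records are dropped. A stated reference allele that disagrees with the
    genome raises (it signals mismatched inputs).
    """
    by_chrom: dict[str, list[GeneModel]] = {}
    for g in genes:
        by_chrom.setdefault(g.chromosome, []).append(g)
    kept = []
    for r in table.records:
        if r.chrom not in reference:
            raise KeyError(f"{r.key}: chromosome {r.chrom} absent from reference")
        overlapping = [
            g
            for g in by_chrom.get(r.chrom, [])
            if any(g.contains(r.pos + i) for i in range(max(len(r.ref), 1)))
        ]
        if not overlapping:
            continue
        if r.kind == "indel":
            # any CDS-overlapping indel alters the protein (frameshift or
            # in-frame insertion/deletion)
            kept.append(r)
            continue
        changes_protein = False
        for gene in overlapping:
            coding = genomic_to_coding(r, gene, reference)
            if coding is None:
                continue
            cds = extract_cds(gene, reference)
            if len(cds) % 3 != 0:  # defensive; GeneModel enforces this
                raise ReferenceMismatchError(f"gene {gene.id}: CDS not translatable")
            pc = apply_coding_change(cds, coding)
            if pc.consequence != "synonymous":
                changes_protein = True
                break
        if changes_protein:
            kept.append(r)
    return VariantTable.from_records(
        kept, provenance=f"{table.provenance}|nonsynonymous"
    )


def intersect_experiments(tables: list[VariantTable]) -> VariantTable:
    """Records whose site key is reported in every experiment.

    Frequencies come from the first table. Key-level associative and
    order-insensitive.
    """
    if len(tables) < 2:
        raise ValueError("need at least 2 experiments to intersect")
    common = set.intersection(*(t.keys() for t in tables))
    return VariantTable.from_records(
        [r for r in tables[0].records if r.key in common],
        provenance="intersection",
    )
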