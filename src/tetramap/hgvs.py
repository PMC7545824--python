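"""Coding-change (HGVS c.) parsing, application, and genomic projection.

Supports the two descriptor classes a point-mutagenesis screen produces:
CDS substitutions (``c.479C>T``) and equal-length delins / MNPs
(``c.2044_2045delCCinsTT``). Applying a change to a CDS translates the
affected codons with the standard nuclear genetic code and reports the
protein change in precursor coordinates; :func:`to_mature` shifts to
mature-protein coordinates by subtracting the transit-peptide length
(e.g. a chloroplast-imported enzyme whose Pro160 is Pro129 after cleavage
of a 31-residue transit peptide).
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass, replace

from Bio.Seq import Seq
from Bio.SeqUtils import seq3

from .genome import GeneModel, cds_index_of, revcomp
from .variants import VariantCall

__all__ = [
    "CodingChange",
    "ProteinChange",
    "HGVSParseError",
    "UnsupportedHGVSError",
    "ReferenceMismatchError",
    "parse_hgvs_c",
    "format_hgvs_c",
    "apply_coding_change",
    "to_mature",
    "genomic_to_coding",
]


class HGVSParseError(ValueError):
    """Descriptor text does not match a supported grammar."""


class UnsupportedHGVSError(HGVSParseError):
    """Recognized HGVS class outside the supported subset (splice/UTR/...)."""


class ReferenceMismatchError(ValueError):
    """Stated reference allele disagrees with the sequence (wrong transcript)."""


@dataclass(frozen=True)
class CodingChange:
    """A CDS-level nucleotide change, 1-based in coding coordinates."""

    cds_start: int
    cds_end: int
    ref_nt: str
    alt_nt: str

    def __post_init__(self) -> None:
        if self.cds_start < 1 or self.cds_end < self.cds_start:
            raise HGVSParseError("bad CDS positions")
        span = self.cds_end - self.cds_start + 1
        if len(self.ref_nt) != span:
            raise HGVSParseError("ref allele length does not match position span")
        if len(self.alt_nt) != len(self.ref_nt):
            raise UnsupportedHGVSError(
                "only substitutions and equal-length delins are supported"
            )
        if self.ref_nt == self.alt_nt:
            raise HGVSParseError("ref equals alt")


@dataclass(frozen=True)
class ProteinChange:
    """A protein-level consequence in precursor coordinates.

    ``position`` is the first affected codon, ceil(cds_start / 3).
    ``mature_position`` is set by :func:`to_mature`.
    """

    ref_aa: str
    position: int
    alt_aa: str
    consequence: str
    mature_position: int | None = None

    @property
    def label(self) -> str:
        """Three-letter style label, e.g. ``Pro682Phe``."""
        return f"{seq3(self.ref_aa)}{self.position}{seq3(self.alt_aa)}"

    @property
    def mature_label(self) -> str | None:
        if self.mature_position is None:
            return None
        return f"{seq3(self.ref_aa)}{self.mature_position}{seq3(self.alt_aa)}"


_SUB_RE = re.compile(r"^c\.(\d+)([ACGT])>([ACGT])$")
_DELINS_RE = re.compile(r"^c\.(\d+)_(\d+)del([ACGT]+)ins([ACGT]+)$")
_OFFSET_RE = re.compile(r"^c\.[\d*-]*\d+[+-]\d+")


def parse_hgvs_c(text: str) -> CodingChange:
    """Parse ``c.NX>Y`` or ``c.N_MdelXXinsYY`` into a CodingChange."""
    text = text.strip()
    if _OFFSET_RE.match(text) or text.startswith(("c.*", "c.-")):
        raise UnsupportedHGVSError(
            f"{text!r}: intronic/UTR offsets are not supported"
        )
    m = _SUB_RE.match(text)
    if m:
        pos = int(m.group(1))
        return CodingChange(pos, pos, m.group(2), m.group(3))
    m = _DELINS_RE.match(text)
    if m:
        start, end = int(m.group(1)), int(m.group(2))
        ref_nt, alt_nt = m.group(3), m.group(4)
        if end - start + 1 != len(ref_nt):
            raise HGVSParseError(
                f"{text!r}: deleted allele {ref_nt!r} does not span {start}_{end}"
            )
        if len(ref_nt) != len(alt_nt):
            raise UnsupportedHGVSError(
                f"{text!r}: only equal-length delins are supported"
            )
        return CodingChange(start, end, ref_nt, alt_nt)
    raise HGVSParseError(f"cannot parse coding-change descriptor {text!r}")


def format_hgvs_c(change: CodingChange) -> str:
    if change.cds_start == change.cds_end:
        return f"c.{change.cds_start}{change.ref_nt}>{change.alt_nt}"
    return (
        f"c.{change.cds_start}_{change.cds_end}"
        f"del{change.ref_nt}ins{change.alt_nt}"
    )


def apply_coding_change(cds: str, change: CodingChange) -> ProteinChange:
    """Apply a coding change to a CDS and report the protein consequence.

    The CDS length must be divisible by 3 and the stated reference allele
    must match the CDS at the stated positions; a mismatch signals the
    wrong transcript and raises :class:`ReferenceMismatchError`.
    """
    cds = cds.upper()
    if len(cds) % 3 != 0:
        raise ValueError(f"CDS length {len(cds)} not divisible by 3")
    if change.cds_end > len(cds):
        raise ReferenceMismatchError(
            f"change ends at {change.cds_end} but CDS has {len(cds)} nt"
        )
    observed = cds[change.cds_start - 1 : change.cds_end]
    if observed != change.ref_nt:
        raise ReferenceMismatchError(
            f"CDS has {observed!r} at {change.cds_start}_{change.cds_end}, "
            f"descriptor states {change.ref_nt!r}"
        )
    mutated = (
        cds[: change.cds_start - 1] + change.alt_nt + cds[change.cds_end :]
    )
    first_codon = math.ceil(change.cds_start / 3)
    last_codon = math.ceil(change.cds_end / 3)
    ref_codons = cds[(first_codon - 1) * 3 : last_codon * 3]
    alt_codons = mutated[(first_codon - 1) * 3 : last_codon * 3]
    ref_aa = str(Seq(ref_codons).translate())
    alt_aa = str(Seq(alt_codons).translate())
    if ref_aa == alt_aa:
        consequence = "synonymous"
    elif "*" in alt_aa:
        consequence = "nonsense"
    else:
        consequence = "missense"
    # report only the changed residues; keep position at the first change
    position = first_codon
    while len(ref_aa) > 1 and ref_aa[0] == alt_aa[0]:
        ref_aa, alt_aa = ref_aa[1:], alt_aa[1:]
        position += 1
    while len(ref_aa) > 1 and ref_aa[-1] == alt_aa[-1]:
        ref_aa, alt_aa = ref_aa[:-1], alt_aa[:-1]
    return ProteinChange(
        ref_aa=ref_aa, position=position, alt_aa=alt_aa, consequence=consequence
    )


def to_mature(pc: ProteinChange, transit_peptide_len: int) -> ProteinChange:
    """Shift a precursor-coordinate change to mature-protein coordinates."""
    if transit_peptide_len < 0:
        raise ValueError("transit peptide length must be >= 0")
    if transit_peptide_len == 0:
        return replace(pc, mature_position=pc.position)
    if pc.position <= transit_peptide_len:
        raise ValueError(
            f"residue {pc.position} lies inside the {transit_peptide_len}-residue "
            "transit peptide"
        )
    return replace(pc, mature_position=pc.position - transit_peptide_len)


def genomic_to_coding(
    v: VariantCall, gene: GeneModel, reference: dict[str, str]
) -> CodingChange | None:
    """Project a genomic substitution/MNP into CDS coordinates.

    Returns None (no coding effect) when the variant does not lie fully
    inside the gene's CDS. Alleles are reverse-complemented for
    minus-strand genes. The genomic reference allele is checked against
    the reference sequence.
    """
    if len(v.ref) != len(v.alt):
        raise UnsupportedHGVSError(
            f"{v.key}: only substitutions/MNPs map to coding changes here"
        )
    seq = reference[gene.chromosome]
    observed = seq[v.pos - 1 : v.pos - 1 + len(v.ref)]
    if observed != v.ref:
        raise ReferenceMismatchError(
            f"{v.key}: reference genome has {observed!r}"
        )
    indices = []
    for i in range(len(v.ref)):
        idx = cds_index_of(gene, v.pos + i)
        if idx is None:
            return None
        indices.append(idx)
    if gene.strand == "+":
        ref_nt, alt_nt = v.ref, v.alt
        start, end = indices[0], indices[-1]
    else:
        ref_nt, alt_nt = revcomp(v.ref), revcomp(v.alt)
        start, end = indices[-1], indices[0]
    if end - start + 1 != len(ref_nt):
        # variant straddles an intron boundary: bases map non-contiguously
        return None
    return CodingChange(cds_start=start, cds_end=end, ref_nt=ref_nt, alt_nt=alt_nt)
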