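"""Variant records, site keys, and VCF/TSV table IO.

The pipeline's atom is the :class:`VariantCall`: one called variant with a
*frequency value* — the percent of mapped reads at the site that report
the variant allele. Identity of a variant across samples is its site key
``chrom:pos:ref:alt``; frequency never enters identity.

On disk, tables are single-sample VCF 4.2 (frequency in FORMAT field
``VF``, percent with 2 decimals) or a fixed TSV dialect (tab-separated,
header ``chrom pos ref alt frequency strain_or_pool``, UTF-8, LF). VCF
parsing goes through cyvcf2; writing emits deterministic text so repeated
writes of the same table are byte-identical.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import pandas as pd

__all__ = [
    "VariantCall",
    "VariantTable",
    "VariantIOError",
    "site_key",
    "parse_site_key",
    "match_key",
    "read_variants",
    "write_variants",
]


class VariantIOError(ValueError):
    """Malformed variant record or file."""


def site_key(chrom: str, pos: int, ref: str, alt: str) -> str:
    """Canonical site key; equality of keys defines 'same variant'."""
    return f"{chrom}:{pos}:{ref}:{alt}"


def parse_site_key(key: str) -> tuple[str, int, str, str]:
    chrom, pos, ref, alt = key.split(":")
    return chrom, int(pos), ref, alt


@dataclass(frozen=True)
class VariantCall:
    """One called variant. ``frequency`` is in percent, [0, 100]."""

    chrom: str
    pos: int
    ref: str
    alt: str
    frequency: float
    source: str = ""

    def __post_init__(self) -> None:
        if self.ref == self.alt:
            raise VariantIOError(f"{self.key_str()}: ref equals alt")
        if not self.ref or not self.alt:
            raise VariantIOError("empty ref or alt allele")
        if not 0.0 <= self.frequency <= 100.0:
            raise VariantIOError(
                f"{self.key_str()}: frequency {self.frequency} outside [0, 100]"
            )
        if self.pos < 1:
            raise VariantIOError(f"{self.key_str()}: position must be 1-based")

    def key_str(self) -> str:
        return site_key(self.chrom, self.pos, self.ref, self.alt)

    @property
    def key(self) -> str:
        return self.key_str()

    @property
    def kind(self) -> str:
        """SNP (1 nt), MNP (equal length > 1) or indel."""
        if len(self.ref) == len(self.alt):
            return "SNP" if len(self.ref) == 1 else "MNP"
        return "indel"


def match_key(v: VariantCall) -> str:
    """Site key of a record; frequency and source play no part."""
    return v.key


def _sort_key(v: VariantCall) -> tuple:
    return (v.chrom, v.pos, v.ref, v.alt, v.source)


@dataclass(frozen=True)
class VariantTable:
    """An ordered, de-duplicated collection of variant calls.

    Unique on (chrom, pos, ref, alt, source), sorted by (chrom, pos).
    Construct with :meth:`from_records` to sort and validate.
    """

    records: tuple[VariantCall, ...]
    provenance: str = ""

    @classmethod
    def from_records(cls, records, provenance: str = "") -> "VariantTable":
        recs = sorted(records, key=_sort_key)
        seen = set()
        for r in recs:
            k = (r.key, r.source)
            if k in seen:
                raise VariantIOError(f"duplicate record {r.key} source={r.source}")
            seen.add(k)
        return cls(records=tuple(recs), provenance=provenance)

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    def keys(self) -> set[str]:
        return {r.key for r in self.records}

    def get(self, key: str) -> VariantCall | None:
        for r in self.records:
            if r.key == key:
                return r
        return None

    def with_provenance(self, provenance: str) -> "VariantTable":
        return replace(self, provenance=provenance)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "chrom": [r.chrom for r in self.records],
                "pos": [r.pos for r in self.records],
                "ref": [r.ref for r in self.records],
                "alt": [r.alt for r in self.records],
                "frequency": [r.frequency for r in self.records],
                "strain_or_pool": [r.source for r in self.records],
            }
        )


_TSV_COLUMNS = ["chrom", "pos", "ref", "alt", "frequency", "strain_or_pool"]


def write_variants(table: VariantTable, path, format: str) -> None:
    """Write a table as VCF 4.2 or TSV; output is bit-stable per input."""
    if format == "tsv":
        _write_tsv(table, path)
    elif format == "vcf":
        _write_vcf(table, path)
    else:
        raise VariantIOError(f"unknown format {format!r}")


def read_variants(path, format: str) -> VariantTable:
    if format == "tsv":
        return _read_tsv(path)
    if format == "vcf":
        return _read_vcf(path)
    raise VariantIOError(f"unknown format {format!r}")


def _write_tsv(table: VariantTable, path) -> None:
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write("\t".join(_TSV_COLUMNS) + "\n")
        for r in table.records:
            fh.write(
                f"{r.chrom}\t{r.pos}\t{r.ref}\t{r.alt}\t{r.frequency:.2f}\t{r.source}\n"
            )


def _read_tsv(path) -> VariantTable:
    try:
        df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    except Exception as exc:  # pragma: no cover - pandas message passthrough
        raise VariantIOError(f"cannot parse {path}: {exc}") from exc
    missing = [c for c in _TSV_COLUMNS if c not in df.columns]
    if missing:
        raise VariantIOError(f"{path}: missing columns {missing}")
    records = []
    for i, row in enumerate(df.itertuples(index=False), start=2):
        try:
            records.append(
                VariantCall(
                    chrom=str(row.chrom),
                    pos=int(row.pos),
                    ref=str(row.ref),
                    alt=str(row.alt),
                    frequency=float(row.frequency),
                    source="" if pd.isna(row.strain_or_pool) else str(row.strain_or_pool),
                )
            )
        except (VariantIOError, ValueError) as exc:
            raise VariantIOError(f"{path} line {i}: {exc}") from exc
    return VariantTable.from_records(records, provenance=str(path))


_VCF_HEADER = (
    "##fileformat=VCFv4.2\n"
    '##FORMAT=<ID=VF,Number=1,Type=Float,Description='
    '"Variant frequency: percent of mapped reads reporting the variant">\n'
)


def _write_vcf(table: VariantTable, path) -> None:
    sources = {r.source for r in table.records}
    if len(sources) > 1:
        raise VariantIOError(
            f"VCF output is single-sample; table has sources {sorted(sources)}"
        )
    sample = sources.pop() if sources else "sample"
    sample = sample or "sample"
    contigs = sorted({r.chrom for r in table.records})
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write(_VCF_HEADER)
        for c in contigs:
            fh.write(f"##contig=<ID={c}>\n")
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + sample + "\n"
        )
        for r in table.records:
            fh.write(
                f"{r.chrom}\t{r.pos}\t.\t{r.ref}\t{r.alt}\t.\t.\t.\tVF\t"
                f"{r.frequency:.2f}\n"
            )


def _read_vcf(path) -> VariantTable:
    import cyvcf2

    vcf = cyvcf2.VCF(str(path))
    samples = vcf.samples
    sample = samples[0] if samples else ""
    records = []
    for rec in vcf:
        try:
            vf = rec.format("VF")
        except KeyError:
            vf = None
        if vf is None:
            raise VariantIOError(
                f"{path}: record {rec.CHROM}:{rec.POS} lacks FORMAT field VF"
            )
        if not rec.ALT:
            raise VariantIOError(f"{path}: record {rec.CHROM}:{rec.POS} has no ALT")
        records.append(
            VariantCall(
                chrom=rec.CHROM,
                pos=rec.POS,
                ref=rec.REF,
                alt=rec.ALT[0],
                frequency=round(float(vf[0][0]), 2),
                source=sample if sample != "sample" else "",
            )
        )
    return VariantTable.from_records(records, provenance=str(path))
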