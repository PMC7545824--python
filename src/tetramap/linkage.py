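"""Origin tagging and clean-flank linkage analysis.

Every called variant in a phenotype-selected pool is tagged with its
origin — background wild type, outcross wild type, or novel
(mutagenesis-derived) — by key membership in the two wild-type panels
(trio-style). Because phenotype selection drags along the causative
locus's chromosomal neighbourhood from the mutagenized background, the
causative variant sits inside a large region devoid of outcross-strain
SNPs; the *clean flank* sizes quantify that, and candidates are ranked by
(clean-region size, then frequency value).
"""

from __future__ import annotations

from dataclasses import dataclass, replace

from .genome import GenomeModel
from .variants import VariantCall, VariantTable

__all__ = [
    "OriginTaggedVariant",
    "CandidateReport",
    "PanelContaminationError",
    "tag_origin",
    "clean_flank",
    "rank_candidates",
]

ORIGINS = ("background_wt", "outcross_wt", "novel")


class PanelContaminationError(ValueError):
    """A site key appears in both wild-type panels."""


@dataclass(frozen=True)
class OriginTaggedVariant:
    """A variant call labelled with its inferred origin and, once
    measured, the sizes (bp) of its flanks free of outcross SNPs."""

    call: VariantCall
    origin: str
    left_flank: int | None = None
    right_flank: int | None = None

    def __post_init__(self) -> None:
        if self.origin not in ORIGINS:
            raise ValueError(f"unknown origin {self.origin!r}")
        for f in (self.left_flank, self.right_flank):
            if f is not None and f < 0:
                raise ValueError("flanks must be >= 0")

    @property
    def region_size(self) -> int | None:
        if self.left_flank is None or self.right_flank is None:
            return None
        return self.left_flank + self.right_flank


def tag_origin(
    pool_table: VariantTable,
    background_panel: VariantTable,
    outcross_panel: VariantTable,
) -> list[OriginTaggedVariant]:
    """Tag each pool record by key membership in the wild-type panels."""
    bg_keys = background_panel.keys()
    oc_keys = outcross_panel.keys()
    overlap = bg_keys & oc_keys
    if overlap:
        raise PanelContaminationError(
            f"{len(overlap)} site keys present in both panels, "
            f"e.g. {sorted(overlap)[0]}"
        )
    tagged = []
    for r in pool_table.records:
        if r.key in bg_keys:
            origin = "background_wt"
        elif r.key in oc_keys:
            origin = "outcross_wt"
        else:
            origin = "novel"
        tagged.append(OriginTaggedVariant(call=r, origin=origin))
    return tagged


def clean_flank(
    candidate: OriginTaggedVariant,
    tagged: list[OriginTaggedVariant],
    model: GenomeModel,
) -> OriginTaggedVariant:
    """Measure the candidate's flanks free of outcross-origin variants.

    Flanks run to the nearest outcross-tagged variant on the same
    chromosome, or to the chromosome boundary (treated as position 0 on
    the left and the chromosome length on the right), so a chromosome with
    no outcross SNP yields a clean region of the full chromosome length.
    """
    chrom = candidate.call.chrom
    pos = candidate.call.pos
    length = model.chromosome_length(chrom)
    left_marker = 0
    right_marker = length
    for t in tagged:
        if t.origin != "outcross_wt" or t.call.chrom != chrom:
            continue
        if t.call.pos < pos:
            left_marker = max(left_marker, t.call.pos)
        elif t.call.pos > pos:
            right_marker = min(right_marker, t.call.pos)
    return replace(
        candidate, left_flank=pos - left_marker, right_flank=right_marker - pos
    )


@dataclass(frozen=True)
class CandidateReport:
    """Ranked causal candidates: novel variants sorted by clean-region
    size (desc), then frequency value (desc), ties broken by position."""

    candidates: tuple[OriginTaggedVariant, ...]

    @property
    def top(self) -> OriginTaggedVariant:
        return self.candidates[0]

    def to_dataframe(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "rank": range(1, len(self.candidates) + 1),
                "chrom": [c.call.chrom for c in self.candidates],
                "pos": [c.call.pos for c in self.candidates],
                "ref": [c.call.ref for c in self.candidates],
                "alt": [c.call.alt for c in self.candidates],
                "frequency": [c.call.frequency for c in self.candidates],
                "left_flank": [c.left_flank for c in self.candidates],
                "right_flank": [c.right_flank for c in self.candidates],
                "region_size": [c.region_size for c in self.candidates],
            }
        )


def rank_candidates(tagged: list[OriginTaggedVariant]) -> CandidateReport:
    """Rank novel variants as causal candidates.

    Requires at least one novel variant; flanks default to 0 when not yet
    measured so frequency decides among unmeasured candidates.
    """
    novel = [t for t in tagged if t.origin == "novel"]
    if not novel:
        raise ValueError("no novel variants to rank")
    ranked = sorted(
        novel,
        key=lambda t: (
            -(t.region_size or 0),
            -t.call.frequency,
            t.call.chrom,
            t.call.pos,
        ),
    )
    return CandidateReport(candidates=tuple(ranked))
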