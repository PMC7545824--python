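"""Bulked-segregant (pooled-progeny) causal filtering and frequency
diagnostics.

In a pool of phenotype-selected haploid progeny, the causative variant is
carried by every member and must be reported near 100%; unlinked real
variants sit near 50%, and a variant seen at *any* frequency in the
phenotype-negative pool is excluded from causality. The frequency
histogram reproduces the diagnostic view of a raw call set: a
mid-frequency artifact bulk versus a spike at exactly 100%.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .genome import GeneModel
from .triage import TriageConfig, frequency_filter, select_nonsynonymous, subtract_variants
from .variants import VariantTable

__all__ = ["PoolPair", "FrequencyHistogram", "pool_causal_filter", "frequency_histogram"]


@dataclass(frozen=True)
class PoolPair:
    """The two phenotype pools of one outcross plus wild-type references.

    ``tsp_table``: phenotype-positive pool; ``wt_table``: phenotype-negative
    pool; ``wt_refs``: background and outcross wild-type call sets. All
    four sources must be distinct sequencing preparations.
    """

    tsp_table: VariantTable
    wt_table: VariantTable
    wt_refs: tuple[VariantTable, ...]

    def __post_init__(self) -> None:
        labels = [self._label(self.tsp_table), self._label(self.wt_table)]
        labels += [self._label(t) for t in self.wt_refs]
        if len(set(labels)) != len(labels):
            raise ValueError(f"pool sources must be distinct, got {labels}")

    @staticmethod
    def _label(table: VariantTable) -> str:
        sources = {r.source for r in table.records}
        return sources.pop() if len(sources) == 1 else table.provenance


def pool_causal_filter(
    pp: PoolPair,
    reference: dict[str, str],
    genes: list[GeneModel],
    cfg: TriageConfig,
) -> VariantTable:
    """Candidate causative variants from a phenotype-pool pair.

    cutoff (phenotype-positive pool, frequency > cutoff) → subtract the
    phenotype-negative pool and both wild types at any frequency → keep
    non-synonymous records.
    """
    confident = frequency_filter(pp.tsp_table, cfg)
    cleaned = subtract_variants(confident, [pp.wt_table, *pp.wt_refs])
    return select_nonsynonymous(cleaned, reference, genes)


@dataclass(frozen=True)
class FrequencyHistogram:
    """Distribution summary of a call set's frequency values."""

    fraction_in_band: float
    fraction_at_100: float
    cumulative_x: tuple[float, ...]
    cumulative_y: tuple[float, ...]

    def fraction_at_most(self, x: float) -> float:
        """Fraction of records with frequency <= x."""
        idx = np.searchsorted(np.array(self.cumulative_x), x, side="right") - 1
        return self.cumulative_y[idx] if idx >= 0 else 0.0


def frequency_histogram(
    table: VariantTable, band: tuple[float, float] = (35.0, 65.0)
) -> FrequencyHistogram:
    """Band fraction, exact-100% fraction, and the cumulative curve.

    The band is half-open, (lo, hi]. "Exactly 100%" means equality after
    rounding to 2 decimals, matching how frequency values are reported.
    """
    if len(table) == 0:
        raise ValueError("cannot build a histogram from an empty table")
    lo, hi = band
    freqs = np.array([r.frequency for r in table.records])
    n = freqs.size
    fraction_in_band = float(np.mean((freqs > lo) & (freqs <= hi)))
    fraction_at_100 = float(np.mean(np.round(freqs, 2) == 100.0))
    xs = np.sort(np.unique(freqs))
    ys = np.searchsorted(np.sort(freqs), xs, side="right") / n
    return FrequencyHistogram(
        fraction_in_band=fraction_in_band,
        fraction_at_100=fraction_at_100,
        cumulative_x=tuple(float(x) for x in xs),
        cumulative_y=tuple(float(y) for y in ys),
    )
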