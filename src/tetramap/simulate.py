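"""Forward-genetics simulator for a haploid alga.

Generates everything the mapping pipeline consumes: a background wild type
and a divergent outcross strain (dense private SNP panel, S1D2-style), a
UV-mutagenized mutant whose selectable trait — called the TSP phenotype
throughout, after temperature-sensitive photoautotrophy, the classic
conditional screen in green algae — is caused by exactly one missense change,
tetrad meioses with Haldane (no-interference) crossovers on the
four-chromatid bundle, phenotype-selected backcross schemes, outcross
progeny pools, and pooled-sequencing variant tables with read-depth and
base-error noise plus mid-frequency artifact calls.

Model summary
-------------
* Haploidy: a strain is one allele per segregating site; the phenotype is
  carried iff the causative allele is carried (penetrance 1).
* Meiosis: per chromosome the number of chiasmata is Poisson(2d), where d
  is the map length in Morgans (uniform cM/Mbp rate); each chiasma picks
  one chromatid from each sister pair uniformly. Every inter-parental
  heterozygous site therefore segregates exactly 2:2, and the per-gamete
  recombination fraction between two loci follows Haldane's mapping
  function c = (1 - exp(-2d)) / 2.
* Pooled sequencing: per site, depth ~ Poisson(mean coverage); each read
  samples a uniformly-chosen pool member and is flipped with the base
  error rate; a variant is called when at least ``min_alt_reads`` reads
  support it. Artifact calls arise as a Poisson process along the genome
  with Beta-distributed frequency values, reproducing the mid-frequency
  bulk seen in real single-strain call sets.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
from Bio.Seq import Seq

from .genome import GenomeModel, SENSE_CODONS, transcription_order_positions
from .variants import VariantCall, VariantTable, parse_site_key, site_key

__all__ = [
    "SimConfig",
    "StrainGenome",
    "Tetrad",
    "SimulationError",
    "spawn_strains",
    "mutagenize",
    "meiosis_tetrad",
    "run_backcross_scheme",
    "run_outcross_pools",
    "simulate_pool_sequencing",
    "sequence_strain",
    "segregating_sites",
    "position_at_recombination_fraction",
]

_COMPL = {"A": "T", "C": "G", "G": "C", "T": "A"}

_CODON_TABLE = {c: str(Seq(c).translate()) for c in SENSE_CODONS}


class SimulationError(ValueError):
    """Invalid simulator input or configuration."""


@dataclass
class SimConfig:
    """All knobs of a simulated mapping experiment.

    One integer seed fixes every stochastic output. Defaults are the desk-
    scale study conditions: a 3 x 4 Mbp genome, an outcross SNP density of
    100/Mbp, 60 UV mutations (one causative), mean coverage 30, and a
    5-generation backcross.
    """

    seed: int = 0
    # genome section
    n_chromosomes: int = 3
    chromosome_length: int = 4_000_000
    n_genes: int = 30
    genetic_map_rate: float = 6.0  # cM per Mbp
    # strain panels
    n_background_snps: int = 150
    n_outcross_snps: int = 1200
    # mutagenesis
    n_mutations: int = 60
    causative_gene: str = "g12"
    # sequencing / variant calling
    mean_coverage: float = 30.0
    base_error_rate: float = 0.002
    min_alt_reads: int = 2
    artifact_variant_rate: float = 25.0  # artifact calls per Mbp
    artifact_frequency_beta: tuple[float, float] = (8.0, 8.0)
    # breeding designs
    n_tetrads: int = 25
    backcross_generations: int = 5

    def __post_init__(self) -> None:
        for name in (
            "mean_coverage",
            "base_error_rate",
            "artifact_variant_rate",
            "genetic_map_rate",
        ):
            if getattr(self, name) < 0:
                raise SimulationError(f"{name} must be >= 0")
        if not 0 <= self.base_error_rate < 0.5:
            raise SimulationError("base_error_rate must be in [0, 0.5)")
        a, b = self.artifact_frequency_beta
        if a <= 0 or b <= 0:
            raise SimulationError("artifact_frequency_beta shapes must be > 0")
        if self.n_mutations < 1:
            raise SimulationError("n_mutations must be >= 1 (the causative change)")
        if self.backcross_generations < 0:
            raise SimulationError("backcross_generations must be >= 0")
        if self.min_alt_reads < 1:
            raise SimulationError("min_alt_reads must be >= 1")

    @property
    def pool_size(self) -> int:
        """Progenies per phenotype pool: 2 carriers x n_tetrads."""
        return 2 * self.n_tetrads

    def rng(self) -> np.random.Generator:
        return np.random.default_rng(self.seed)


@dataclass
class StrainGenome:
    """Haploid genotype: which alternate alleles a strain carries.

    ``alleles`` maps site keys (chrom:pos:ref:alt) to 1 for carried
    alternate alleles; absent keys mean the reference allele.
    ``causative_site`` is set iff the strain carries the causative allele,
    which is equivalent (penetrance 1) to expressing the TSP phenotype.
    """

    strain_id: str
    mating_type: str
    alleles: dict[str, int] = field(default_factory=dict)
    causative_site: str | None = None

    def __post_init__(self) -> None:
        if self.mating_type not in ("+", "-"):
            raise SimulationError(
                f"{self.strain_id}: mating type must be '+' or '-'"
            )
        if self.causative_site is not None and not self.alleles.get(
            self.causative_site
        ):
            raise SimulationError(
                f"{self.strain_id}: causative_site set but allele not carried"
            )

    def carries(self, key: str) -> bool:
        return bool(self.alleles.get(key))

    @property
    def has_phenotype(self) -> bool:
        """TSP phenotype == carriage of the causative allele."""
        return self.causative_site is not None


@dataclass(frozen=True)
class Tetrad:
    """The four haploid products of one meiosis."""

    products: tuple[StrainGenome, StrainGenome, StrainGenome, StrainGenome]

    def __post_init__(self) -> None:
        if len(self.products) != 4:
            raise SimulationError("a tetrad has exactly 4 products")

    @property
    def n_phenotype_positive(self) -> int:
        return sum(p.has_phenotype for p in self.products)


# ---------------------------------------------------------------------------
# strain construction


def _sample_distinct_offsets(
    rng: np.random.Generator, genome_len: int, n: int, taken: set[int]
) -> np.ndarray:
    """n distinct genome offsets not in ``taken`` (uniform)."""
    if n == 0:
        return np.empty(0, dtype=np.int64)
    if n + len(taken) > genome_len:
        raise SimulationError("requested more sites than the genome holds")
    chosen: list[int] = []
    seen = set(taken)
    while len(chosen) < n:
        draw = rng.integers(0, genome_len, size=2 * (n - len(chosen)) + 8)
        for off in draw:
            off = int(off)
            if off not in seen:
                seen.add(off)
                chosen.append(off)
                if len(chosen) == n:
                    break
    return np.array(chosen, dtype=np.int64)


def _snp_keys_at(
    model: GenomeModel,
    reference: dict[str, str],
    offsets: np.ndarray,
    rng: np.random.Generator,
) -> list[str]:
    keys = []
    for off in offsets:
        chrom, pos = model.locate(int(off))
        ref = reference[chrom][pos - 1]
        alt = "ACGT".replace(ref, "")[rng.integers(0, 3)]
        keys.append(site_key(chrom, pos, ref, alt))
    return keys


def spawn_strains(
    model: GenomeModel,
    reference: dict[str, str],
    n_outcross_snps: int,
    n_background_snps: int = 150,
    seed: int | np.random.Generator = 0,
) -> tuple[StrainGenome, StrainGenome]:
    """Create the background wild type and a divergent outcross wild type.

    Both strains share the background SNP panel (their private differences
    from the reference assembly); the outcross strain additionally carries
    ``n_outcross_snps`` private SNPs placed uniformly, so the two strains
    differ at exactly that many sites. Mating types are opposite:
    background '+', outcross '-'.
    """
    if n_outcross_snps < 0 or n_background_snps < 0:
        raise SimulationError("SNP counts must be >= 0")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    genome_len = model.total_length
    bg_off = _sample_distinct_offsets(rng, genome_len, n_background_snps, set())
    oc_off = _sample_distinct_offsets(rng, genome_len, n_outcross_snps, set(map(int, bg_off)))
    bg_keys = _snp_keys_at(model, reference, bg_off, rng)
    oc_keys = _snp_keys_at(model, reference, oc_off, rng)
    background = StrainGenome(
        strain_id="background_wt",
        mating_type="+",
        alleles={k: 1 for k in bg_keys},
    )
    outcross = StrainGenome(
        strain_id="outcross_wt",
        mating_type="-",
        alleles={**{k: 1 for k in bg_keys}, **{k: 1 for k in oc_keys}},
    )
    return background, outcross


def _causative_change(
    gene, reference: dict[str, str], rng: np.random.Generator
) -> str:
    """Pick a missense substitution inside ``gene``; return its site key."""
    positions = transcription_order_positions(gene)
    n_codons = len(positions) // 3
    chrom_seq = reference[gene.chromosome]
    order = rng.permutation(n_codons)
    for codon_idx in order:
        cds_slice = positions[3 * codon_idx : 3 * codon_idx + 3]
        codon = "".join(
            chrom_seq[p - 1] if gene.strand == "+" else _COMPL[chrom_seq[p - 1]]
            for p in cds_slice
        )
        aa = _CODON_TABLE.get(codon)
        if aa is None:
            continue
        for within in rng.permutation(3):
            for alt_base in np.array(list("ACGT"))[rng.permutation(4)]:
                alt_base = str(alt_base)
                if alt_base == codon[within]:
                    continue
                mutated = codon[:within] + alt_base + codon[within + 1 :]
                new_aa = _CODON_TABLE.get(mutated)
                if new_aa is None or new_aa == aa:
                    continue  # nonsense or synonymous: keep looking
                genomic_pos = cds_slice[within]
                ref_base = chrom_seq[genomic_pos - 1]
                alt_genomic = alt_base if gene.strand == "+" else _COMPL[alt_base]
                return site_key(gene.chromosome, genomic_pos, ref_base, alt_genomic)
    raise SimulationError(
        f"gene {gene.id}: no missense substitution available"
    )


def mutagenize(
    strain: StrainGenome,
    model: GenomeModel,
    reference: dict[str, str],
    n_mutations: int,
    causative_gene: str,
    seed: int | np.random.Generator = 0,
    strain_id: str | None = None,
) -> StrainGenome:
    """UV-style random mutagenesis with one planted causative change.

    The returned strain carries ``n_mutations`` novel variants: exactly one
    missense change inside ``causative_gene`` (marked as the causative
    site) plus uniformly-placed incidental SNPs.
    """
    if n_mutations < 1:
        raise SimulationError("n_mutations must be >= 1")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    try:
        gene = model.gene(causative_gene)
    except KeyError as exc:
        raise SimulationError(f"unknown causative gene {causative_gene!r}") from exc
    causative_key = _causative_change(gene, reference, rng)

    taken = set()
    offset = 0
    chrom_offsets = {}
    for name, length in model.chromosomes:
        chrom_offsets[name] = offset
        offset += length
    for key in strain.alleles:
        c, p, _, _ = parse_site_key(key)
        taken.add(chrom_offsets[c] + p - 1)
    c, p, _, _ = parse_site_key(causative_key)
    taken.add(chrom_offsets[c] + p - 1)

    extra_off = _sample_distinct_offsets(rng, model.total_length, n_mutations - 1, taken)
    extra_keys = _snp_keys_at(model, reference, extra_off, rng)
    alleles = dict(strain.alleles)
    alleles[causative_key] = 1
    for k in extra_keys:
        alleles[k] = 1
    return StrainGenome(
        strain_id=strain_id or f"{strain.strain_id}_mut",
        mating_type=strain.mating_type,
        alleles=alleles,
        causative_site=causative_key,
    )


# ---------------------------------------------------------------------------
# meiosis


def _site_arrays(parent_a: StrainGenome, parent_b: StrainGenome):
    """Sorted union of both parents' known sites with per-parent alleles."""
    keys = sorted(
        set(parent_a.alleles) | set(parent_b.alleles),
        key=lambda k: (parse_site_key(k)[0], parse_site_key(k)[1]),
    )
    chroms = [parse_site_key(k)[0] for k in keys]
    pos = np.array([parse_site_key(k)[1] for k in keys], dtype=np.int64)
    a = np.array([1 if parent_a.carries(k) else 0 for k in keys], dtype=np.int8)
    b = np.array([1 if parent_b.carries(k) else 0 for k in keys], dtype=np.int8)
    return keys, chroms, pos, a, b


def _chromatid_origins(
    length: int,
    positions: np.ndarray,
    map_rate: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """Parental origin (0 = plus parent, 1 = minus parent) of each of the
    four chromatids at each site position on one chromosome.

    Chiasmata ~ Poisson(2d) with d the chromosome map length in Morgans;
    each chiasma exchanges the distal segments of one chromatid from each
    sister pair (no chromatid interference).
    """
    d_morgans = map_rate * (length / 1e6) / 100.0
    n_chi = rng.poisson(2.0 * d_morgans)
    origins = np.array([0, 0, 1, 1], dtype=np.int8)
    if n_chi == 0 or positions.size == 0:
        return np.tile(origins[:, None], (1, positions.size))
    xo_pos = np.sort(rng.integers(1, length, size=n_chi))
    picks = rng.integers(0, 2, size=(n_chi, 2))
    # each chiasma joins one chromatid from each homolog axis at its
    # position (i.e. one strand currently of each parental origin there):
    # crossovers are homologous exchanges, never same-origin (sister-like)
    # exchanges, which keeps the per-gamete process exactly Haldane
    breaks: list[list[int]] = [[0] for _ in range(4)]
    segs: list[list[int]] = [[0], [0], [1], [1]]
    cur = origins.copy()
    for x, (pa, pb) in zip(xo_pos, picks):
        a = int(np.flatnonzero(cur == 0)[pa])
        b = int(np.flatnonzero(cur == 1)[pb])
        cur[a], cur[b] = 1, 0
        for c, o in ((a, 1), (b, 0)):
            breaks[c].append(int(x))
            segs[c].append(o)
    out = np.empty((4, positions.size), dtype=np.int8)
    for c in range(4):
        idx = np.searchsorted(np.array(breaks[c]), positions, side="right") - 1
        out[c] = np.array(segs[c], dtype=np.int8)[idx]
    return out


def meiosis_tetrad(
    parent_plus: StrainGenome,
    parent_minus: StrainGenome,
    model: GenomeModel,
    seed: int | np.random.Generator = 0,
    tetrad_id: str = "t0",
) -> Tetrad:
    """One meiosis of a (+) x (-) cross; returns the four products.

    Every site heterozygous between the parents segregates exactly 2:2.
    Mating type is assigned 2:2 per tetrad as an unlinked Mendelian locus.
    """
    if parent_plus.mating_type == parent_minus.mating_type:
        raise SimulationError("parents must have opposite mating types")
    if parent_plus.mating_type != "+":
        parent_plus, parent_minus = parent_minus, parent_plus
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    keys, chroms, pos, a_allele, b_allele = _site_arrays(parent_plus, parent_minus)
    n = len(keys)
    product_alleles = np.empty((4, n), dtype=np.int8)
    chrom_arr = np.array(chroms)
    for cname, length in model.chromosomes:
        mask = chrom_arr == cname
        origins = _chromatid_origins(length, pos[mask], model.genetic_map_rate, rng)
        # independent assortment: random bivalent orientation at meiosis I
        # (which sister pair goes to which secondary cell) and random
        # orientation at meiosis II (order within each pair), independently
        # per chromosome
        pair_a, pair_b = ([0, 1], [2, 3]) if rng.integers(2) == 0 else ([2, 3], [0, 1])
        if rng.integers(2):
            pair_a = pair_a[::-1]
        if rng.integers(2):
            pair_b = pair_b[::-1]
        assignment = np.array(pair_a + pair_b)
        vals = np.where(origins == 0, a_allele[mask][None, :], b_allele[mask][None, :])
        product_alleles[:, mask] = vals[assignment]
    causative = parent_plus.causative_site or parent_minus.causative_site
    mating = rng.permutation(np.array(["+", "+", "-", "-"]))
    products = []
    for i in range(4):
        alleles = {k: 1 for k, v in zip(keys, product_alleles[i]) if v}
        products.append(
            StrainGenome(
                strain_id=f"{tetrad_id}.p{i + 1}",
                mating_type=str(mating[i]),
                alleles=alleles,
                causative_site=causative if causative in alleles else None,
            )
        )
    return Tetrad(products=tuple(products))


# ---------------------------------------------------------------------------
# breeding schemes


def run_backcross_scheme(
    mutant: StrainGenome,
    wt: StrainGenome,
    generations: int,
    model: GenomeModel,
    seed: int | np.random.Generator = 0,
) -> StrainGenome:
    """Repeated phenotype-selected backcrossing to the background wild type.

    Each generation: cross the current carrier to a background-wt clone of
    the opposite mating type, form one tetrad, and keep one of the two
    products that carry the causative allele. Unlinked incidental
    mutations are purged with probability 1/2 per generation.
    """
    if generations < 0:
        raise SimulationError("generations must be >= 0")
    if mutant.causative_site is None:
        raise SimulationError("mutant must carry a causative site")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    current = mutant
    for g in range(generations):
        partner_mt = "-" if current.mating_type == "+" else "+"
        partner = replace(wt, mating_type=partner_mt)
        if current.mating_type == "+":
            tet = meiosis_tetrad(current, partner, model, rng, tetrad_id=f"bc{g + 1}")
        else:
            tet = meiosis_tetrad(partner, current, model, rng, tetrad_id=f"bc{g + 1}")
        carriers = [p for p in tet.products if p.has_phenotype]
        current = carriers[int(rng.integers(len(carriers)))]
    return current


def run_outcross_pools(
    mutant: StrainGenome,
    outcross_wt: StrainGenome,
    n_tetrads: int,
    model: GenomeModel,
    seed: int | np.random.Generator = 0,
) -> tuple[list[StrainGenome], list[StrainGenome], list[Tetrad]]:
    """Outcross the mutant, dissect complete tetrads, pool by phenotype.

    Returns (tsp_pool, wt_pool, tetrads); each pool holds 2 x n_tetrads
    progenies because the causative site segregates 2:2 in every tetrad.
    """
    if n_tetrads < 1:
        raise SimulationError("n_tetrads must be >= 1")
    if mutant.causative_site is None:
        raise SimulationError("mutant must carry a causative site")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    if mutant.mating_type == outcross_wt.mating_type:
        raise SimulationError("mutant and outcross strain must differ in mating type")
    tsp_pool: list[StrainGenome] = []
    wt_pool: list[StrainGenome] = []
    tetrads: list[Tetrad] = []
    for t in range(n_tetrads):
        if mutant.mating_type == "+":
            tet = meiosis_tetrad(mutant, outcross_wt, model, rng, tetrad_id=f"oc{t + 1}")
        else:
            tet = meiosis_tetrad(outcross_wt, mutant, model, rng, tetrad_id=f"oc{t + 1}")
        tetrads.append(tet)
        for p in tet.products:
            (tsp_pool if p.has_phenotype else wt_pool).append(p)
    return tsp_pool, wt_pool, tetrads


# ---------------------------------------------------------------------------
# pooled sequencing


def segregating_sites(*strains: StrainGenome) -> list[str]:
    """Union of all alternate alleles known to any of the strains."""
    keys: set[str] = set()
    for s in strains:
        keys.update(s.alleles)
    return sorted(keys, key=lambda k: (parse_site_key(k)[0], parse_site_key(k)[1]))


def simulate_pool_sequencing(
    pool: list[StrainGenome],
    sites: list[str],
    cfg: SimConfig,
    seed: int | np.random.Generator | None = None,
    reference: dict[str, str] | None = None,
    model: GenomeModel | None = None,
    source: str = "pool",
) -> VariantTable:
    """Whole-genome sequencing of a pooled gDNA preparation.

    Per site: depth ~ Poisson(mean_coverage); each read is drawn from a
    uniformly-chosen pool member and flipped with the base error rate, so
    alt reads ~ Binomial(depth, f(1-e) + (1-f)e) with f the carrier
    fraction. A site is reported when depth > 0 and at least
    ``min_alt_reads`` reads support the variant; the frequency value is
    100 * alt/depth rounded to 2 decimals. When ``reference`` and ``model``
    are given, artifact calls are added as a Poisson process at
    ``artifact_variant_rate`` per Mbp with Beta-distributed frequencies.
    """
    if not pool:
        raise SimulationError("empty pool")
    rng = (
        seed
        if isinstance(seed, np.random.Generator)
        else np.random.default_rng(cfg.seed if seed is None else seed)
    )
    n_sites = len(sites)
    freq_alt = np.array(
        [sum(s.carries(k) for s in pool) / len(pool) for k in sites]
    )
    depth = rng.poisson(cfg.mean_coverage, size=n_sites)
    e = cfg.base_error_rate
    p_alt = freq_alt * (1 - e) + (1 - freq_alt) * e
    alt = np.zeros(n_sites, dtype=np.int64)
    pos_depth = depth > 0
    alt[pos_depth] = rng.binomial(depth[pos_depth], p_alt[pos_depth])
    records = []
    for k, d, a in zip(sites, depth, alt):
        if d == 0 or a < cfg.min_alt_reads:
            continue
        chrom, pos, ref, altb = parse_site_key(k)
        records.append(
            VariantCall(
                chrom=chrom,
                pos=pos,
                ref=ref,
                alt=altb,
                frequency=round(100.0 * a / d, 2),
                source=source,
            )
        )
    if reference is not None and model is not None and cfg.artifact_variant_rate > 0:
        existing = set(sites) | {r.key for r in records}
        n_art = rng.poisson(cfg.artifact_variant_rate * model.total_length / 1e6)
        a_shape, b_shape = cfg.artifact_frequency_beta
        offsets = rng.integers(0, model.total_length, size=n_art)
        freqs = rng.beta(a_shape, b_shape, size=n_art)
        for off, f in zip(offsets, freqs):
            chrom, pos = model.locate(int(off))
            ref = reference[chrom][pos - 1]
            altb = "ACGT".replace(ref, "")[rng.integers(0, 3)]
            key = site_key(chrom, pos, ref, altb)
            if key in existing:
                continue
            existing.add(key)
            records.append(
                VariantCall(
                    chrom=chrom,
                    pos=pos,
                    ref=ref,
                    alt=altb,
                    frequency=round(100.0 * f, 2),
                    source=source,
                )
            )
    return VariantTable.from_records(records, provenance=f"simulated:{source}")


def sequence_strain(
    strain: StrainGenome,
    sites: list[str],
    cfg: SimConfig,
    seed: int | np.random.Generator | None = None,
    reference: dict[str, str] | None = None,
    model: GenomeModel | None = None,
) -> VariantTable:
    """Single-strain whole-genome sequencing (a pool of one)."""
    return simulate_pool_sequencing(
        [strain], sites, cfg, seed=seed, reference=reference, model=model,
        source=strain.strain_id,
    )


def position_at_recombination_fraction(
    model: GenomeModel, chrom: str, pos: int, c: float
) -> int:
    """Position on ``chrom`` at per-gamete recombination fraction ``c``
    from ``pos``, by inverting Haldane's mapping function.

    d = -ln(1 - 2c) / 2 Morgans; distance_bp = d / rate. Prefers the
    rightward placement, falling back to the left if the chromosome ends.
    """
    if not 0 <= c < 0.5:
        raise SimulationError("recombination fraction must be in [0, 0.5)")
    if model.genetic_map_rate <= 0:
        raise SimulationError("map rate must be > 0 to place a linked site")
    d_morgans = -math.log(1.0 - 2.0 * c) / 2.0
    dist_bp = int(round(d_morgans * 100.0 / model.genetic_map_rate * 1e6))
    length = model.chromosome_length(chrom)
    if pos + dist_bp <= length:
        return pos + dist_bp
    if pos - dist_bp >= 1:
        return pos - dist_bp
    raise SimulationError(
        f"no position at recombination fraction {c} from {chrom}:{pos}"
    )
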