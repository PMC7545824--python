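"""End-to-end orchestration of the three mapping experiment designs.

``run_pipeline`` simulates a forward-genetics experiment (preliminary
single-strain sequencing, phenotype-pooled outcross, or iterated
backcross), pushes the resulting variant tables through the triage
cascade, ranks causal candidates, and — given an output directory —
writes a report TSV, a per-stage count trajectory, and a human-readable
summary with a reproducibility block (seed + config hash). A fixed
(seed, config) pair reproduces every artifact byte for byte.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .genome import GenomeModel, build_genome_model, synthesize_reference
from .linkage import (
    CandidateReport,
    OriginTaggedVariant,
    clean_flank,
    rank_candidates,
    tag_origin,
)
from .simulate import (
    SimConfig,
    SimulationError,
    StrainGenome,
    Tetrad,
    mutagenize,
    run_backcross_scheme,
    run_outcross_pools,
    segregating_sites,
    sequence_strain,
    simulate_pool_sequencing,
    spawn_strains,
)
from .triage import (
    TriageConfig,
    frequency_filter,
    intersect_experiments,
    select_nonsynonymous,
    subtract_variants,
)
from .variants import VariantTable, write_variants

__all__ = [
    "ExperimentDesign",
    "SegregationResult",
    "PipelineResult",
    "StageCount",
    "segregation_test",
    "run_pipeline",
    "colonies_per_mutant",
    "config_hash",
]

logger = logging.getLogger("tetramap")

DESIGN_KINDS = ("preliminary", "outcross_pooling", "backcross")


def colonies_per_mutant(n_screened: int, n_mutants: int) -> int:
    """Screening yield: colonies screened per mutant found (rounded)."""
    if n_mutants <= 0:
        raise ValueError("need at least one mutant")
    return round(n_screened / n_mutants)


@dataclass(frozen=True)
class SegregationResult:
    """Outcome of a tetrad segregation test for single-locus inheritance."""

    tetrads_tested: int
    tetrads_2_2: int

    @property
    def single_locus_consistent(self) -> bool:
        return self.tetrads_2_2 == self.tetrads_tested


def segregation_test(tetrads: list[Tetrad]) -> SegregationResult:
    """Count tetrads with exactly 2 phenotype-positive products.

    All-2:2 segregation is the classic evidence that one mutated locus
    causes the phenotype.
    """
    if not tetrads:
        raise ValueError("no tetrads to test")
    n_2_2 = sum(1 for t in tetrads if t.n_phenotype_positive == 2)
    return SegregationResult(tetrads_tested=len(tetrads), tetrads_2_2=n_2_2)


@dataclass(frozen=True)
class ExperimentDesign:
    """One of the three published experiment layouts plus overrides.

    ``parameters`` override SimConfig fields after the kind's defaults
    (preliminary/backcross sequence single strains at coverage 20, the
    pooled outcross at coverage 30).
    """

    kind: str
    parameters: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.kind not in DESIGN_KINDS:
            raise ValueError(f"unknown design kind {self.kind!r}")
        valid = {f.name for f in dataclasses.fields(SimConfig)}
        unknown = set(self.parameters) - valid
        if unknown:
            raise ValueError(f"unknown design parameters {sorted(unknown)}")

    _KIND_DEFAULTS = {
        "preliminary": {"mean_coverage": 20.0},
        "outcross_pooling": {"mean_coverage": 30.0},
        "backcross": {"mean_coverage": 20.0},
    }

    def configure(self, cfg: SimConfig) -> SimConfig:
        merged = dict(self._KIND_DEFAULTS[self.kind])
        merged.update(self.parameters)
        return dataclasses.replace(cfg, **merged)


@dataclass
class StageCount:
    stage: str
    n_in: int
    n_out: int


@dataclass
class PipelineResult:
    design: str
    report: CandidateReport
    counts: list[StageCount]
    seed: int
    config_hash: str
    tables: dict[str, VariantTable]
    causative_key: str


def config_hash(cfg: SimConfig, triage_cfg: TriageConfig) -> str:
    payload = json.dumps(
        {**dataclasses.asdict(cfg), **dataclasses.asdict(triage_cfg)},
        sort_keys=True,
        default=str,
    )
    return hashlib.sha256(payload.encode()).hexdigest()[:16]


@dataclass
class SimulatedCross:
    """Shared simulation prologue: genome, strains, mutagenized mutant."""

    model: GenomeModel
    reference: dict[str, str]
    background: StrainGenome
    outcross: StrainGenome
    mutant: StrainGenome

    @classmethod
    def from_config(cls, cfg: SimConfig, rng: np.random.Generator) -> "SimulatedCross":
        model = build_genome_model(cfg)
        reference = synthesize_reference(model, rng)
        background, outcross = spawn_strains(
            model,
            reference,
            n_outcross_snps=cfg.n_outcross_snps,
            n_background_snps=cfg.n_background_snps,
            seed=rng,
        )
        mutant = mutagenize(
            background,
            model,
            reference,
            n_mutations=cfg.n_mutations,
            causative_gene=cfg.causative_gene,
            seed=rng,
            strain_id="mutant",
        )
        return cls(model, reference, background, outcross, mutant)


def _staged_cascade(
    table: VariantTable,
    wt_tables: list[VariantTable],
    sim: SimulatedCross,
    triage_cfg: TriageConfig,
    counts: list[StageCount],
    label: str,
) -> VariantTable:
    """cutoff → subtract wild types → non-synonymous, with count logging."""
    confident = frequency_filter(table, triage_cfg)
    _log(counts, f"{label}:frequency_filter", len(table), len(confident))
    cleaned = subtract_variants(confident, wt_tables)
    _log(counts, f"{label}:subtract", len(confident), len(cleaned))
    nonsyn = select_nonsynonymous(cleaned, sim.reference, list(sim.model.genes))
    _log(counts, f"{label}:nonsynonymous", len(cleaned), len(nonsyn))
    return nonsyn


def _log(counts: list[StageCount], stage: str, n_in: int, n_out: int) -> None:
    counts.append(StageCount(stage=stage, n_in=n_in, n_out=n_out))
    logger.info("%s: %d -> %d records", stage, n_in, n_out)


def _report_without_linkage(
    table: VariantTable, sim: SimulatedCross
) -> CandidateReport:
    """Rank cascade survivors when no outcross panel is available.

    Survivors are novel by construction (wild types were subtracted);
    flanks run to the chromosome boundaries, so frequency decides.
    """
    tagged = [
        clean_flank(OriginTaggedVariant(call=r, origin="novel"), [], sim.model)
        for r in table.records
    ]
    return rank_candidates(tagged)


def run_pipeline(
    design: ExperimentDesign,
    cfg: SimConfig,
    triage_cfg: TriageConfig | None = None,
    out_dir: str | Path | None = None,
) -> PipelineResult:
    """Simulate one experiment design and map its causative mutation."""
    triage_cfg = triage_cfg or TriageConfig()
    cfg = design.configure(cfg)
    rng = np.random.default_rng(cfg.seed)
    sim = SimulatedCross.from_config(cfg, rng)
    counts: list[StageCount] = []
    tables: dict[str, VariantTable] = {}
    sites = segregating_sites(sim.background, sim.outcross, sim.mutant)

    try:
        if design.kind == "preliminary":
            report = _run_preliminary(sim, sites, cfg, triage_cfg, rng, counts, tables)
        elif design.kind == "outcross_pooling":
            report = _run_outcross(sim, sites, cfg, triage_cfg, rng, counts, tables)
        else:
            report = _run_backcross(sim, sites, cfg, triage_cfg, rng, counts, tables)
    except (SimulationError, ValueError) as exc:
        raise RuntimeError(f"{design.kind} pipeline failed: {exc}") from exc

    result = PipelineResult(
        design=design.kind,
        report=report,
        counts=counts,
        seed=cfg.seed,
        config_hash=config_hash(cfg, triage_cfg),
        tables=tables,
        causative_key=sim.mutant.causative_site,
    )
    if out_dir is not None:
        _write_outputs(result, Path(out_dir))
    return result


def _run_preliminary(sim, sites, cfg, triage_cfg, rng, counts, tables):
    mutant_tab = sequence_strain(
        sim.mutant, sites, cfg, seed=rng, reference=sim.reference, model=sim.model
    )
    bg_tab = sequence_strain(
        sim.background, sites, cfg, seed=rng, reference=sim.reference, model=sim.model
    )
    tables.update(mutant=mutant_tab, background_wt=bg_tab)
    survivors = _staged_cascade(
        mutant_tab, [bg_tab], sim, triage_cfg, counts, "preliminary"
    )
    tables["candidates"] = survivors
    return _report_without_linkage(survivors, sim)


def _run_outcross(sim, sites, cfg, triage_cfg, rng, counts, tables):
    tsp_pool, wt_pool, _ = run_outcross_pools(
        sim.mutant, sim.outcross, cfg.n_tetrads, sim.model, seed=rng
    )
    common = dict(seed=rng, reference=sim.reference, model=sim.model)
    tsp_tab = simulate_pool_sequencing(
        tsp_pool, sites, cfg, source="pool_tsp", **common
    )
    wt_tab = simulate_pool_sequencing(wt_pool, sites, cfg, source="pool_wt", **common)
    bg_tab = sequence_strain(sim.background, sites, cfg, **common)
    oc_tab = sequence_strain(sim.outcross, sites, cfg, **common)
    tables.update(
        pool_tsp=tsp_tab, pool_wt=wt_tab, background_wt=bg_tab, outcross_wt=oc_tab
    )
    survivors = _staged_cascade(
        tsp_tab, [wt_tab, bg_tab, oc_tab], sim, triage_cfg, counts, "pool"
    )
    tables["candidates"] = survivors
    # trio-style origin tagging on the full phenotype-positive pool table;
    # panels restricted to confident calls (single-strain real variants sit
    # near 100%, mid-frequency artifacts do not belong in a panel). The
    # outcross panel keeps only outcross-private SNPs: sites shared with the
    # background strain are not segregating markers in this cross.
    bg_panel = frequency_filter(bg_tab, triage_cfg)
    oc_panel = subtract_variants(frequency_filter(oc_tab, triage_cfg), [bg_tab])
    tagged_all = tag_origin(tsp_tab, bg_panel, oc_panel)
    survivor_keys = survivors.keys()
    measured = [
        clean_flank(t, tagged_all, sim.model)
        for t in tagged_all
        if t.call.key in survivor_keys
    ]
    _log(counts, "pool:linkage_candidates", len(survivors), len(measured))
    return rank_candidates(measured)


def _run_backcross(sim, sites, cfg, triage_cfg, rng, counts, tables):
    bc_strain = run_backcross_scheme(
        sim.mutant, sim.background, cfg.backcross_generations, sim.model, seed=rng
    )
    common = dict(seed=rng, reference=sim.reference, model=sim.model)
    mutant_tab = sequence_strain(sim.mutant, sites, cfg, **common)
    bg_tab = sequence_strain(sim.background, sites, cfg, **common)
    bc_sites = segregating_sites(sim.background, bc_strain)
    bc_tab = simulate_pool_sequencing(
        [bc_strain], bc_sites, cfg, source="backcross_g%d" % cfg.backcross_generations,
        **common,
    )
    tables.update(mutant=mutant_tab, background_wt=bg_tab, backcross=bc_tab)
    prelim = _staged_cascade(
        mutant_tab, [bg_tab], sim, triage_cfg, counts, "preliminary"
    )
    bc_res = _staged_cascade(bc_tab, [bg_tab], sim, triage_cfg, counts, "backcross")
    common_tab = intersect_experiments([bc_res, prelim])
    _log(counts, "intersect", len(bc_res) + len(prelim), len(common_tab))
    tables["candidates"] = common_tab
    return _report_without_linkage(common_tab, sim)


def _write_outputs(result: PipelineResult, out_dir: Path) -> None:
    out_dir.mkdir(parents=True, exist_ok=True)
    df = result.report.to_dataframe()
    df.to_csv(
        out_dir / "report.tsv", sep="\t", index=False, float_format="%.2f",
        lineterminator="\n",
    )
    with open(out_dir / "counts.tsv", "w", encoding="utf-8", newline="\n") as fh:
        fh.write("stage\tn_in\tn_out\n")
        for c in result.counts:
            fh.write(f"{c.stage}\t{c.n_in}\t{c.n_out}\n")
    for name, table in result.tables.items():
        write_variants(table, out_dir / f"{name}.tsv", "tsv")
    top = result.report.top
    with open(out_dir / "summary.txt", "w", encoding="utf-8", newline="\n") as fh:
        fh.write(f"design: {result.design}\n")
        fh.write(f"candidates: {len(result.report.candidates)}\n")
        fh.write(
            f"top candidate: {top.call.key} "
            f"frequency={top.call.frequency:.2f}% "
            f"clean_region={top.region_size} bp\n"
        )
        fh.write("count trajectory:\n")
        for c in result.counts:
            fh.write(f"  {c.stage}: {c.n_in} -> {c.n_out}\n")
        fh.write("reproducibility:\n")
        fh.write(f"  seed: {result.seed}\n")
        fh.write(f"  config_hash: {result.config_hash}\n")
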