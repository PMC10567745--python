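"""End-to-end orchestration: prioritise -> anatomy -> burden -> classify -> summarise.

The pipeline consumes a variant-observation table (real or simulated), the
gene metadata and a control-count table, and produces per-stage TSV outputs
plus a cohort summary mirroring the headline statistics of a splice-variant
survey: carrier proportions per disease, unique-variant shares per gene, the
splice-region location histogram, tool-concordance tallies, burden results
and classification tallies with RNA-driven transitions.
"""

from __future__ import annotations

import dataclasses
import logging
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

from . import io
from .acmg import (
    Classification,
    EvidenceCode,
    PathClass,
    assign_functional,
    assign_pm2_pp3,
    assign_pp1,
    assign_ps4,
    assign_pvs1,
    combine,
    reclassify_with_rna,
)
from .anatomy import FrameConsequence, Mechanism, Region, SpliceAnatomy
from .burden import BurdenResult, run_burden
from .models import (
    ConfigError,
    ControlCounts,
    Disease,
    ExclusionList,
    GeneMeta,
    VariantObservation,
)
from .prioritise import (
    FilterName,
    Mode,
    PrioritisationVerdict,
    Thresholds,
    concordance_tally,
    dedupe_observations,
    prioritise,
)
from .simulate import SimulatedCohort, SimulationConfig, simulate_cohort

logger = logging.getLogger("cardiosplice")

__all__ = [
    "PipelineConfig",
    "PipelineResult",
    "CohortSummary",
    "classify_variant",
    "run_pipeline",
    "summarise",
]


@dataclass
class PipelineConfig:
    """Input tables (or a simulation block), mode and output location."""

    variants: str | Path | None = None
    gene_meta: str | Path | None = None
    controls: str | Path | None = None
    simulation: SimulationConfig | None = None
    group_sizes: Mapping[Disease, int] | None = None
    mode: Mode = Mode.discovery
    alpha: float = 0.05
    run_burden: bool = True
    ancestry_stratum: str | None = None  # e.g. "nfe" for a European-only sensitivity run
    combiner: str = "points"
    out_dir: str | Path | None = None
    seed: int = 0


@dataclass
class VariantClassificationRecord:
    transcript: str
    hgvs_c: str
    gene: str
    disease: Disease
    before: Classification
    after: Classification | None
    transition: str  # upgrade / downgrade / no_change / "" (no RNA result)

    @property
    def final(self) -> Classification:
        return self.after if self.after is not None else self.before


@dataclass
class CohortSummary:
    total_participants: int
    total_carriers: int
    carrier_fraction: float
    per_disease: dict[str, dict]
    per_gene: dict[str, dict]
    unique_variants: int
    location_histogram: dict[str, int]
    essential_dinucleotide: dict[str, int]
    mechanism_histogram: dict[str, int]
    concordance: dict
    classification_tally: dict[str, int]
    transitions: dict[str, int]

    def as_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["carrier_percent"] = io.format_percent(self.carrier_fraction)
        return d


@dataclass
class PipelineResult:
    observations: list[VariantObservation]
    verdicts: list[PrioritisationVerdict]
    candidates: list[VariantObservation]
    candidate_verdicts: list[PrioritisationVerdict]
    burden: list[BurdenResult]
    classifications: list[VariantClassificationRecord]
    summary: CohortSummary
    gene_meta: dict[str, GeneMeta]
    control_table: dict[str, ControlCounts]
    group_sizes: dict[Disease, int]


def classify_variant(
    obs: VariantObservation,
    verdict: PrioritisationVerdict,
    meta: GeneMeta,
    combiner: str = "points",
) -> VariantClassificationRecord:
    """Classify one unique variant before and (when an RNA result exists)
    after its functional study.

    Before RNA: PVS1 for essential-dinucleotide site-loss variants (predicted
    loss of function), PS4 / PP1 from the evidence columns, PM2 / PP3 from
    rarity and tool concordance. After RNA: PP3 is dropped and PS3 / PM4 added
    according to the observed frame consequence.
    """
    anatomy = verdict.anatomy
    codes: set[EvidenceCode] = set()
    predicted_lof = (
        anatomy is not None
        and anatomy.essential_dinucleotide
        and anatomy.mechanism is Mechanism.site_loss
        and (meta.lof_mechanism or meta.is_ttn
             or meta.haploinsufficiency_score.value != "not_curated"
             or meta.lof_oe is not None)
    )
    if predicted_lof:
        pvs1 = assign_pvs1(meta, FrameConsequence.none, predicted_lof=True)
        if pvs1 is not None:
            codes.add(pvs1)
    ps4 = assign_ps4(obs.proband_count)
    if ps4 is not None:
        codes.add(ps4)
    pp1 = assign_pp1(obs.informative_meioses)
    if pp1 is not None:
        codes.add(pp1)
    codes |= assign_pm2_pp3(obs, verdict, rna_available=False)
    before = combine(codes, system=combiner)

    after, transition = None, ""
    if obs.functional_outcome is not None:
        after, transition = reclassify_with_rna(
            before, obs.functional_outcome, system=combiner
        )
    return VariantClassificationRecord(
        transcript=obs.transcript,
        hgvs_c=obs.hgvs_c,
        gene=obs.gene,
        disease=obs.disease,
        before=before,
        after=after,
        transition=transition,
    )


def _funnel(stage: str, n_in: int, n_pass: int) -> None:
    n_fail = n_in - n_pass
    assert n_in == n_pass + n_fail  # conservation at every filter
    logger.info("%s: %d in, %d passed, %d failed", stage, n_in, n_pass, n_fail)


def summarise(
    observations: Sequence[VariantObservation],
    verdicts: Sequence[PrioritisationVerdict],
    group_sizes: Mapping[Disease, int],
    classifications: Sequence[VariantClassificationRecord] = (),
) -> CohortSummary:
    """Cohort-level tallies over candidate observations and their verdicts."""
    candidates = [o for o, v in zip(observations, verdicts) if v.candidate]
    cand_verdicts = [v for v in verdicts if v.candidate]

    carriers_by_disease: dict[Disease, set[str]] = {}
    for obs in candidates:
        carriers_by_disease.setdefault(obs.disease, set()).add(obs.participant_id)
    total_participants = sum(group_sizes.values())
    total_carriers = sum(len(s) for s in carriers_by_disease.values())

    per_disease = {}
    for disease in sorted(group_sizes, key=lambda d: -group_sizes[d]):
        n = group_sizes[disease]
        k = len(carriers_by_disease.get(disease, set()))
        per_disease[disease.value] = {
            "participants": n,
            "carriers": k,
            "carrier_percent": io.format_percent(k / n if n else 0.0),
        }

    # unique-variant tallies
    unique: dict[tuple[str, str], tuple[VariantObservation, PrioritisationVerdict]] = {}
    for obs, v in zip(candidates, cand_verdicts):
        unique.setdefault(obs.variant_key, (obs, v))
    n_unique = len(unique)
    per_gene_counts = Counter(obs.gene for obs, _ in unique.values())
    per_gene = {
        gene: {
            "unique_variants": count,
            "share_percent": io.format_percent(count / n_unique if n_unique else 0.0),
        }
        for gene, count in per_gene_counts.most_common()
    }

    location = Counter()
    essential = Counter()
    mechanism = Counter()
    for obs, v in unique.values():
        anatomy = v.anatomy
        if anatomy is None:
            continue
        key = anatomy.region.value
        if anatomy.exon_edge:
            essential["exon_edge"] += 1
        location[key] += 1
        if anatomy.essential_dinucleotide:
            essential[
                "GT" if anatomy.region is Region.donor_site else "AG"
            ] += 1
        mechanism[anatomy.mechanism.value] += 1

    tally = concordance_tally([v for _, v in unique.values()])

    cls_tally = Counter()
    transitions = Counter()
    for rec in classifications:
        final = rec.final.cls
        key = "P_LP" if final in (PathClass.pathogenic, PathClass.likely_pathogenic) \
            else "VUS"
        cls_tally[key] += 1
        if rec.transition:
            transitions[rec.transition] += 1

    return CohortSummary(
        total_participants=total_participants,
        total_carriers=total_carriers,
        carrier_fraction=total_carriers / total_participants if total_participants else 0.0,
        per_disease=per_disease,
        per_gene=per_gene,
        unique_variants=n_unique,
        location_histogram=dict(location),
        essential_dinucleotide=dict(essential),
        mechanism_histogram=dict(mechanism),
        concordance=tally.as_dict(),
        classification_tally=dict(cls_tally),
        transitions=dict(transitions),
    )


def run_pipeline(cfg: PipelineConfig) -> PipelineResult:
    """Run every stage in order and (optionally) write all outputs."""
    # --- inputs ---------------------------------------------------------
    if cfg.simulation is not None:
        cohort = simulate_cohort(cfg.simulation)
        observations = cohort.observations
        gene_meta = cohort.gene_meta
        control_table = cohort.control_table
        group_sizes = dict(cohort.group_sizes)
    else:
        if cfg.variants is None or cfg.gene_meta is None:
            raise ConfigError("either a simulation block or variant + gene_meta tables")
        observations = io.read_variant_table(cfg.variants)
        gene_meta = io.read_gene_meta(cfg.gene_meta)
        control_table = io.read_control_table(cfg.controls) if cfg.controls else {}
        if cfg.group_sizes is None:
            raise ConfigError("group_sizes required when loading a variant table")
        group_sizes = dict(cfg.group_sizes)
    if cfg.run_burden and not control_table:
        raise ConfigError("burden testing requested but no control table supplied")

    if cfg.ancestry_stratum:
        pop = cfg.ancestry_stratum
        observations = [
            o for o in observations
            if o.af_subpops.get(pop) is None or o.af_subpops.get(pop, 0.0) < 1e-4
        ]

    # --- prioritisation + anatomy --------------------------------------
    exclusion = ExclusionList()
    verdicts = [
        prioritise(obs, gene_meta, mode=cfg.mode, exclusion=exclusion)
        for obs in observations
    ]
    candidates = [o for o, v in zip(observations, verdicts) if v.candidate]
    candidate_verdicts = [v for v in verdicts if v.candidate]
    _funnel("prioritise", len(observations), len(candidates))

    # --- burden ---------------------------------------------------------
    burden_results: list[BurdenResult] = []
    if cfg.run_burden:
        burden_verdicts = [
            prioritise(obs, gene_meta, mode=Mode.burden_75bp, exclusion=exclusion)
            for obs in observations
        ]
        burden_candidates = [
            o for o, v in zip(observations, burden_verdicts) if v.candidate
        ]
        _funnel("burden_region", len(observations), len(burden_candidates))
        for disease, n in sorted(group_sizes.items(), key=lambda kv: kv[0].value):
            burden_results.extend(
                run_burden(
                    burden_candidates, n, control_table, gene_meta, disease,
                    alpha=cfg.alpha,
                )
            )

    # --- classification -------------------------------------------------
    unique: dict[tuple[str, str], tuple[VariantObservation, PrioritisationVerdict]] = {}
    for obs, v in zip(candidates, candidate_verdicts):
        unique.setdefault(obs.variant_key, (obs, v))
    classifications = [
        classify_variant(obs, v, gene_meta[obs.gene], combiner=cfg.combiner)
        for obs, v in unique.values()
    ]

    summary = summarise(observations, verdicts, group_sizes, classifications)

    result = PipelineResult(
        observations=observations,
        verdicts=verdicts,
        candidates=candidates,
        candidate_verdicts=candidate_verdicts,
        burden=burden_results,
        classifications=classifications,
        summary=summary,
        gene_meta=gene_meta,
        control_table=control_table,
        group_sizes=group_sizes,
    )
    if cfg.out_dir is not None:
        write_outputs(result, cfg.out_dir)
    return result


def write_outputs(result: PipelineResult, out_dir: str | Path) -> dict[str, Path]:
    """Write every stage's output under ``out_dir``."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}

    verdict_rows = []
    seen = set()
    for obs, v in zip(result.observations, result.verdicts):
        if obs.variant_key in seen:
            continue
        seen.add(obs.variant_key)
        anatomy = v.anatomy or SpliceAnatomy(region=Region.exonic_other, offset=0)
        verdict_rows.append(
            {
                "transcript": obs.transcript,
                "hgvs_c": obs.hgvs_c,
                "gene": obs.gene,
                "candidate": v.candidate,
                "tools": ",".join(sorted(t.value for t in v.tools_flagging)),
                "failed_filters": ",".join(f.value for f in v.failed_filters),
                "region": anatomy.region.value,
                "offset": anatomy.offset,
                "essential_dinucleotide": anatomy.essential_dinucleotide,
                "mechanism": anatomy.mechanism.value,
            }
        )
    paths["verdicts"] = out / "verdicts.tsv"
    io.write_report(verdict_rows, paths["verdicts"])

    paths["burden"] = out / "burden.tsv"
    io.write_report(result.burden, paths["burden"])

    cls_rows = [
        {
            "transcript": r.transcript,
            "hgvs_c": r.hgvs_c,
            "gene": r.gene,
            "class_without_rna": r.before.cls.value,
            "evidence_without_rna": ";".join(r.before.tokens),
            "class_with_rna": r.after.cls.value if r.after else "",
            "evidence_with_rna": ";".join(r.after.tokens) if r.after else "",
            "transition": r.transition,
        }
        for r in result.classifications
    ]
    paths["classifications"] = out / "classifications.tsv"
    io.write_report(cls_rows, paths["classifications"])

    paths["summary"] = out / "summary.json"
    io.write_report(result.summary.as_dict(), paths["summary"], format="json")
    return paths
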