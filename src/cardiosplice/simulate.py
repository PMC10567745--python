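"""Synthetic cohort generator with the statistical structure the analysis assumes.

Emulates a 1242-participant clinical cohort split over seven disease groups
(HCM 720, SUD 203, DCM 143, BrS 66, LQTS 55, ACM 34, CPVT 21), per-gene
carrier rates for putative splice-disrupting variants, the observed
tool-concordance patterns, and a gnomAD-style per-gene control table with
coverage-adjusted denominators. Scores are generated to pass (or fail) each
tool's threshold with a safety margin (0.05 on probability scores, 0.5 MES
units), so boundary flakiness cannot occur; carrier draws are independent
Bernoulli trials at the configured rates. All randomness flows through a
single seeded :class:`numpy.random.Generator`.
"""

from __future__ import annotations

import dataclasses
import warnings
import zlib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from . import panels
from .models import (
    ControlCounts,
    DataError,
    Disease,
    FunctionalOutcome,
    GeneMeta,
    HaploinsufficiencyScore,
    OutcomeKind,
    SequencingMode,
    SpliceScores,
    VariantObservation,
)
from .prioritise import Thresholds, Tool, DEFAULT_THRESHOLDS

__all__ = [
    "SimulationConfig",
    "SimulatedCohort",
    "simulate_cohort",
    "simulate_null",
    "default_gene_meta",
    "replicate_null_rates",
    "replicate_enrichment",
]

#: Disease-group sizes of the emulated cohort (n = 1242).
DEFAULT_GROUP_SIZES: dict[Disease, int] = {
    Disease.HCM: 720,
    Disease.SUD: 203,
    Disease.DCM: 143,
    Disease.BrS: 66,
    Disease.LQTS: 55,
    Disease.ACM: 34,
    Disease.CPVT: 21,
}

#: Planted case excess (case rate minus control rate) for the genes with a
#: known enrichment in their disease; every other phenotype-concordant gene is
#: null (case rate equals the control rate).
PLANTED_EXCESS: dict[tuple[Disease, str], float] = {
    (Disease.HCM, "MYBPC3"): 0.082,
    (Disease.HCM, "MYH7"): 0.013,
    (Disease.DCM, "TTN"): 0.028,
    (Disease.DCM, "FLNC"): 0.027,
    (Disease.ACM, "PKP2"): 0.059,
    (Disease.LQTS, "KCNQ1"): 0.036,
}
# Cumulative per-gene carrier rate of qualifying rare splice variants in the
# control population (many distinct alleles, each at AF < 1e-4). Chosen so the
# expected cohort-wide carrier fraction lands near 10% at the default group
# sizes once the planted excesses are added.
DEFAULT_CONTROL_RATE = 0.0035
DEFAULT_CONTROL_N = 1.0e5        # mean individuals sequenced per gene (exomes)

#: Region mix over unique variants (weights follow the observed distribution
#: across donor / acceptor / exon-edge / deep-intronic / exonic-gain classes).
DEFAULT_REGION_WEIGHTS: dict[str, float] = {
    "donor_intronic": 24.0,
    "acceptor_intronic": 24.0,
    "exon_edge": 10.0,
    "deep_intronic": 25.0,
    "exonic_gain": 15.0,
}

#: Tool-agreement profiles: canonical-site variants over the number of
#: agreeing tools (of 4), non-canonical over MES/SpliceAI patterns.
DEFAULT_CANONICAL_PROFILE: dict[int, float] = {4: 25.0, 3: 11.0, 2: 8.0, 1: 1.0}
DEFAULT_NONCANONICAL_PROFILE: dict[str, float] = {
    "MES_only": 30.0,
    "both": 8.0,
    "SpliceAI_only": 2.0,
}

DEFAULT_OUTCOME_WEIGHTS: dict[OutcomeKind, float] = {
    OutcomeKind.exon_skip: 0.40,
    OutcomeKind.exon_extension: 0.20,
    OutcomeKind.intron_retention: 0.15,
    OutcomeKind.new_exon_inclusion: 0.10,
    OutcomeKind.no_change: 0.10,
    OutcomeKind.unreported_consequence: 0.05,
}

PROB_MARGIN = 0.05  # probability-score clearance around a threshold
MES_MARGIN = 0.5    # MES-unit clearance around a threshold


@dataclass
class SimulationConfig:
    seed: int = 0
    group_sizes: dict[Disease, int] = field(
        default_factory=lambda: dict(DEFAULT_GROUP_SIZES)
    )
    carrier_rates: dict[tuple[Disease, str], float] | None = None
    control_rate: float = DEFAULT_CONTROL_RATE
    control_n: Mapping[str, float] | float = DEFAULT_CONTROL_N
    region_weights: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_REGION_WEIGHTS)
    )
    canonical_profile: dict[int, float] = field(
        default_factory=lambda: dict(DEFAULT_CANONICAL_PROFILE)
    )
    noncanonical_profile: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_NONCANONICAL_PROFILE)
    )
    outcome_weights: dict[OutcomeKind, float] = field(
        default_factory=lambda: dict(DEFAULT_OUTCOME_WEIGHTS)
    )
    functional_study_fraction: float = 0.3
    recurrence: float = 0.0  # probability a new carrier reuses an existing variant
    thresholds: Thresholds = field(default_factory=Thresholds)

    def __post_init__(self) -> None:
        for d, n in self.group_sizes.items():
            if n <= 0:
                raise DataError(f"group size for {d} must be positive")
        if not 0.0 <= self.control_rate <= 1.0:
            raise DataError("control_rate outside [0, 1]")
        if self.carrier_rates is not None:
            for key, r in self.carrier_rates.items():
                if not 0.0 <= r <= 1.0:
                    raise DataError(f"carrier rate {key} outside [0, 1]")

    def resolved_carrier_rates(self) -> dict[tuple[Disease, str], float]:
        """Carrier rate for every (disease, concordant gene) pair."""
        if self.carrier_rates is not None:
            return dict(self.carrier_rates)
        rates: dict[tuple[Disease, str], float] = {}
        for disease in self.group_sizes:
            for gene in sorted(panels.panel_for(disease)):
                rates[(disease, gene)] = self.control_rate + PLANTED_EXCESS.get(
                    (disease, gene), 0.0
                )
        return rates

    def control_n_for(self, gene: str) -> float:
        if isinstance(self.control_n, Mapping):
            return float(self.control_n.get(gene, DEFAULT_CONTROL_N))
        return float(self.control_n)


@dataclass
class SimulatedCohort:
    observations: list[VariantObservation]
    control_table: dict[str, ControlCounts]
    gene_meta: dict[str, GeneMeta]
    group_sizes: dict[Disease, int]
    #: tool subset each unique variant was generated to trigger (ground truth)
    planted_tools: dict[tuple[str, str], frozenset[Tool]] = field(default_factory=dict)

    def write(self, out_dir: str | Path) -> dict[str, Path]:
        """Write the three TSVs consumed by the rest of the pipeline."""
        from . import io  # deferred to keep import graph simple

        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        paths = {
            "variants": out / "variants.tsv",
            "controls": out / "controls.tsv",
            "gene_meta": out / "gene_meta.tsv",
        }
        io.write_variant_table(self.observations, paths["variants"])
        io.write_control_table(self.control_table, paths["controls"])
        io.write_gene_meta(self.gene_meta, paths["gene_meta"])
        return paths


# Plausible loss-of-function annotations for the 32 definitive genes:
# (lof_mechanism, haploinsufficiency score, LoF o/e). LoF-mechanism genes are
# the truncating-variant diseases; sarcomeric missense genes are not.
_GENE_LOF_DEFAULTS: dict[str, tuple[bool, str, float]] = {
    "MYBPC3": (True, "3", 0.10),
    "TTN": (False, "not_curated", 0.40),
    "FLNC": (True, "3", 0.12),
    "PKP2": (True, "3", 0.08),
    "KCNQ1": (True, "3", 0.15),
    "DSP": (True, "3", 0.10),
    "LMNA": (True, "3", 0.20),
    "DSG2": (True, "2", 0.25),
    "DSC2": (True, "2", 0.30),
    "JUP": (False, "1", 0.40),
    "TMEM43": (False, "not_curated", 0.60),
    "RBM20": (False, "2", 0.30),
    "BAG3": (True, "3", 0.20),
    "SCN5A": (False, "2", 0.20),
    "KCNH2": (True, "3", 0.18),
    "MYH7": (False, "not_curated", 0.50),
    "TNNT2": (False, "not_curated", 0.45),
    "TNNI3": (False, "not_curated", 0.55),
    "TNNC1": (False, "not_curated", 0.60),
    "TPM1": (False, "not_curated", 0.30),
    "ACTC1": (False, "not_curated", 0.50),
    "MYL2": (False, "not_curated", 0.55),
    "MYL3": (False, "not_curated", 0.60),
    "PLN": (False, "1", 0.70),
    "DES": (False, "1", 0.45),
    "RYR2": (False, "not_curated", 0.80),
    "CASQ2": (False, "not_curated", 0.70),
    "TRDN": (False, "not_curated", 0.65),
    "TECRL": (False, "not_curated", 0.90),
    "CALM1": (False, "not_curated", 0.25),
    "CALM2": (False, "not_curated", 0.25),
    "CALM3": (False, "not_curated", 0.25),
}


def default_gene_meta(
    control_n: Mapping[str, float] | float = DEFAULT_CONTROL_N,
) -> dict[str, GeneMeta]:
    """Gene metadata for the 32 definitive genes with plausible LoF annotations."""
    meta = {}
    for gene in sorted(panels.ALL_GENES):
        lof, hi, oe = _GENE_LOF_DEFAULTS[gene]
        n = control_n.get(gene, DEFAULT_CONTROL_N) if isinstance(control_n, Mapping) \
            else control_n
        meta[gene] = GeneMeta(
            gene=gene,
            definitive_for=panels.diseases_for(gene),
            lof_mechanism=lof,
            haploinsufficiency_score=HaploinsufficiencyScore(hi),
            lof_oe=oe,
            mean_sequenced_controls=float(n),
            is_ttn=(gene == "TTN"),
        )
    return meta


def _draw_tool_subset(rng: np.random.Generator, cfg: SimulationConfig,
                      canonical: bool) -> frozenset[Tool]:
    if canonical:
        sizes = sorted(cfg.canonical_profile)
        weights = np.array([cfg.canonical_profile[k] for k in sizes], dtype=float)
        k = int(rng.choice(sizes, p=weights / weights.sum()))
        # MES applies to any canonical-site loss; draw which tools agree
        tools = list(Tool)
        rng.shuffle(tools)
        return frozenset(tools[:k])
    patterns = sorted(cfg.noncanonical_profile)
    weights = np.array([cfg.noncanonical_profile[p] for p in patterns], dtype=float)
    pattern = str(rng.choice(patterns, p=weights / weights.sum()))
    return {
        "MES_only": frozenset({Tool.MES}),
        "both": frozenset({Tool.MES, Tool.SpliceAI}),
        "SpliceAI_only": frozenset({Tool.SpliceAI}),
    }[pattern]


def _scores_for(rng: np.random.Generator, thr: Thresholds, tools: frozenset[Tool],
                canonical: bool, site_gain: bool) -> SpliceScores:
    """Scores that pass exactly the chosen tool subset, with safety margins."""
    def prob(hit: bool, cut: float) -> float:
        if hit:
            return float(rng.uniform(cut + PROB_MARGIN, min(1.0, cut + 0.45)))
        return float(rng.uniform(0.0, max(0.0, cut - PROB_MARGIN)))

    ada = prob(Tool.ADA in tools, thr.ada) if canonical else None
    rf = prob(Tool.RF in tools, thr.rf) if canonical else None
    spliceai = prob(Tool.SpliceAI in tools, thr.spliceai)

    if site_gain:
        if Tool.MES in tools:
            alt = float(rng.uniform(thr.mes_gain_min + MES_MARGIN,
                                    thr.mes_gain_min + 6.0))
        else:
            alt = float(rng.uniform(0.0, thr.mes_gain_min - MES_MARGIN))
        return SpliceScores(mes_ref=None, mes_alt=None, mes_delta=alt,
                            ada=ada, rf=rf, spliceai=spliceai)
    mes_ref = float(rng.uniform(6.0, 11.0))
    if Tool.MES in tools:
        drop = float(rng.uniform(thr.mes_loss_delta + MES_MARGIN,
                                 thr.mes_loss_delta + 5.0))
    else:
        drop = float(rng.uniform(0.0, thr.mes_loss_delta - MES_MARGIN))
    return SpliceScores(mes_ref=mes_ref, mes_alt=mes_ref - drop,
                        ada=ada, rf=rf, spliceai=spliceai)


def _draw_location(rng: np.random.Generator, cfg: SimulationConfig):
    """Returns (intron_offset, exon_boundary_distance, canonical, site_gain)."""
    kinds = sorted(cfg.region_weights)
    weights = np.array([cfg.region_weights[k] for k in kinds], dtype=float)
    kind = str(rng.choice(kinds, p=weights / weights.sum()))
    if kind == "donor_intronic":
        offset = int(rng.choice([1, 2, 3, 4, 5, 6], p=[0.3, 0.25, 0.1, 0.1, 0.2, 0.05]))
        return offset, None, True, False
    if kind == "acceptor_intronic":
        offset = -int(rng.choice(np.arange(1, 21),
                                 p=np.r_[[0.28, 0.28], np.full(18, 0.44 / 18)]))
        return offset, None, True, False
    if kind == "exon_edge":
        return 0, int(rng.choice([-1, 1])), True, False
    if kind == "deep_intronic":
        magnitude = int(rng.integers(21, 151))
        sign = int(rng.choice([-1, 1]))
        if sign > 0:
            magnitude = max(magnitude, 7)  # donor-side deep starts past +6
        return sign * magnitude, None, False, True
    return 0, None, False, True  # exonic_gain


def _draw_outcome(rng: np.random.Generator, cfg: SimulationConfig) -> FunctionalOutcome:
    kinds = sorted(cfg.outcome_weights, key=lambda k: k.value)
    weights = np.array([cfg.outcome_weights[k] for k in kinds], dtype=float)
    kind = kinds[int(rng.choice(len(kinds), p=weights / weights.sum()))]
    if kind in (OutcomeKind.no_change, OutcomeKind.unreported_consequence,
                OutcomeKind.impaired_protein_function, OutcomeKind.inconsistent):
        return FunctionalOutcome(kind)
    base = 3 * int(rng.integers(5, 41))
    length = base if rng.random() < 0.4 else base + int(rng.choice([1, 2]))
    if kind is OutcomeKind.intron_retention:
        return FunctionalOutcome(kind, affected_length_nt=length)
    return FunctionalOutcome(kind, affected_length_nt=length)


_BASES = np.array(list("ACGT"))


def simulate_cohort(cfg: SimulationConfig) -> SimulatedCohort:
    """Draw a full synthetic cohort: variant observations, control table and
    gene metadata. Fully reproducible from ``cfg.seed``."""
    rng = np.random.default_rng(cfg.seed)
    rates = cfg.resolved_carrier_rates()
    genes = sorted({g for (_, g) in rates} | set(panels.ALL_GENES))
    gene_meta = default_gene_meta({g: cfg.control_n_for(g) for g in genes})

    observations: list[VariantObservation] = []
    variant_pool: dict[str, list[VariantObservation]] = {}
    used_positions: set[tuple[str, int]] = set()
    planted_tools: dict[tuple[str, str], frozenset[Tool]] = {}
    participant_counter = 0

    for disease in sorted(cfg.group_sizes, key=lambda d: d.value):
        n = cfg.group_sizes[disease]
        for gene in sorted(panels.panel_for(disease)):
            rate = rates.get((disease, gene))
            if rate is None or rate == 0.0:
                continue
            expected = rate * n
            if expected > n:  # unreachable for rates in [0,1]; keep the contract
                warnings.warn(f"carrier rate for {disease}/{gene} capped")
            k = int(rng.binomial(n, rate))
            for _ in range(k):
                participant_counter += 1
                pid = f"{disease.value}-{participant_counter:05d}"
                pool = variant_pool.setdefault(gene, [])
                if pool and rng.random() < cfg.recurrence:
                    template = pool[int(rng.integers(len(pool)))]
                    obs = dataclasses.replace(
                        template, participant_id=pid, disease=disease
                    )
                    observations.append(obs)
                    continue
                offset, ebd, canonical, site_gain = _draw_location(rng, cfg)
                tools = _draw_tool_subset(rng, cfg, canonical)
                scores = _scores_for(rng, cfg.thresholds, tools, canonical, site_gain)
                while True:
                    cpos = int(rng.integers(100, 9000))
                    if (gene, cpos) not in used_positions:
                        used_positions.add((gene, cpos))
                        break
                ref, alt = rng.choice(_BASES, size=2, replace=False)
                off_txt = f"{offset:+d}" if offset else ""
                hgvs = f"c.{cpos}{off_txt}{ref}>{alt}"
                ac = int(rng.integers(0, 4))
                af = ac / 251496.0 if ac else 0.0
                outcome = (
                    _draw_outcome(rng, cfg)
                    if rng.random() < cfg.functional_study_fraction
                    else None
                )
                mode = SequencingMode(
                    str(rng.choice(["panel", "exome", "genome"], p=[0.36, 0.57, 0.07]))
                )
                obs = VariantObservation(
                    participant_id=pid,
                    disease=disease,
                    gene=gene,
                    transcript=f"NM_{zlib.crc32(gene.encode()) % 10**6:06d}.1",
                    hgvs_c=hgvs,
                    af_overall=af,
                    af_subpops={p: af for p in ("afr", "eas", "amr", "nfe", "sas")},
                    allele_count_controls=ac,
                    scores=scores,
                    proband_count=int(rng.geometric(0.45)),
                    informative_meioses=int(rng.choice(
                        np.arange(0, 11),
                        p=np.r_[[0.45, 0.15, 0.1], np.full(8, 0.3 / 8)],
                    )),
                    functional_outcome=outcome,
                    sequencing_mode=mode,
                    exon_boundary_distance=ebd,
                )
                pool.append(obs)
                observations.append(obs)
                planted_tools[obs.variant_key] = tools

    control_table = {}
    for gene in genes:
        n_gene = cfg.control_n_for(gene) * float(rng.uniform(0.8, 1.0))
        count = int(rng.binomial(int(round(n_gene)), cfg.control_rate))
        control_table[gene] = ControlCounts(
            gene=gene,
            qualifying_allele_count=float(count),
            mean_sequenced_individuals=n_gene,
        )
        gene_meta[gene] = dataclasses.replace(
            gene_meta[gene], mean_sequenced_controls=n_gene
        )

    return SimulatedCohort(
        observations=observations,
        control_table=control_table,
        gene_meta=gene_meta,
        group_sizes=dict(cfg.group_sizes),
        planted_tools=planted_tools,
    )


def simulate_null(cfg: SimulationConfig) -> SimulatedCohort:
    """Same generator with every gene's case carrier rate set equal to the
    control rate (enables type-I-error studies of the burden test)."""
    null_rates = {
        (disease, gene): cfg.control_rate
        for disease in cfg.group_sizes
        for gene in panels.panel_for(disease)
    }
    null_cfg = dataclasses.replace(cfg, carrier_rates=null_rates)
    return simulate_cohort(null_cfg)


def replicate_null_rates(
    disease: Disease,
    n_cases: int,
    control_rate: float,
    control_n: float,
    n_replicates: int,
    seed: int,
    alpha: float = 0.05,
    genes: Sequence[str] | None = None,
) -> float:
    """Family-wise rejection rate of the Bonferroni-corrected burden test over
    ``n_replicates`` null cohorts (case carrier rate == control rate).

    Operates at the carrier-count level — the only inputs the exact test
    consumes — so thousands of replicates run in seconds.
    """
    from scipy import stats

    rng = np.random.default_rng(seed)
    panel = sorted(genes if genes is not None else panels.panel_for(disease))
    m = len(panel)
    n_ctl = int(round(control_n))
    # draws: replicates x genes
    a = rng.binomial(n_cases, control_rate, size=(n_replicates, m))
    c = rng.binomial(n_ctl, control_rate, size=(n_replicates, m))
    total = n_cases + n_ctl
    p = stats.hypergeom.sf(a - 1, total, a + c, n_cases)
    reject_any = (p < alpha / m).any(axis=1)
    return float(reject_any.mean())


def replicate_enrichment(
    n_cases: int,
    case_rate: float,
    control_rate: float,
    control_n: float,
    n_replicates: int,
    seed: int,
    alpha: float = 0.05,
    m_tests: int = 8,
) -> tuple[float, float]:
    """(significance rate, mean excess) for a planted enriched gene over
    replicated cohorts, at a Bonferroni threshold of ``alpha / m_tests``."""
    from scipy import stats

    rng = np.random.default_rng(seed)
    n_ctl = int(round(control_n))
    a = rng.binomial(n_cases, case_rate, size=n_replicates)
    c = rng.binomial(n_ctl, control_rate, size=n_replicates)
    p = stats.hypergeom.sf(a - 1, n_cases + n_ctl, a + c, n_cases)
    sig_rate = float((p < alpha / m_tests).mean())
    mean_excess = float((a / n_cases - c / n_ctl).mean())
    return sig_rate, mean_excess
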