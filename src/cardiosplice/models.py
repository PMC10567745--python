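"""Domain types for splice-variant observations, gene metadata and functional outcomes.

The central record is :class:`VariantObservation` — one carrier x variant row, as
produced by clinical genetic testing: HGVS c. notation on a MANE transcript,
gnomAD-style allele frequencies, and pre-computed splice-prediction scores
(MaxEntScan, dbscSNV ADA/RF, SpliceAI). Scores are consumed as inputs; this
package never runs the predictors themselves.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from enum import Enum


class ConfigError(ValueError):
    """A table, dialect or configuration problem (missing column, bad enum, ...)."""


class DataError(ValueError):
    """A row-level data problem (malformed cell, negative frequency, ...)."""


class Disease(str, Enum):
    HCM = "HCM"    # hypertrophic cardiomyopathy
    DCM = "DCM"    # dilated cardiomyopathy
    ACM = "ACM"    # arrhythmogenic cardiomyopathy
    LQTS = "LQTS"  # long QT syndrome
    BrS = "BrS"    # Brugada syndrome
    CPVT = "CPVT"  # catecholaminergic polymorphic VT
    SUD = "SUD"    # sudden unexplained death

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


class SequencingMode(str, Enum):
    panel = "panel"
    exome = "exome"
    genome = "genome"


class ConsequenceAnnotation(str, Enum):
    missense = "missense"
    nonsense = "nonsense"
    synonymous = "synonymous"
    intronic = "intronic"
    splice_site = "splice_site"
    indel = "indel"


class OutcomeKind(str, Enum):
    """RNA-level consequence observed in a functional (RT-PCR) study."""

    exon_skip = "exon_skip"
    exon_extension = "exon_extension"
    exon_truncation = "exon_truncation"
    intron_retention = "intron_retention"
    new_exon_inclusion = "new_exon_inclusion"
    no_change = "no_change"
    impaired_protein_function = "impaired_protein_function"
    unreported_consequence = "unreported_consequence"
    inconsistent = "inconsistent"


#: Outcome kinds that change the length of the mature transcript and therefore
#: require ``affected_length_nt`` for frame arithmetic.
LENGTH_CHANGING_KINDS = frozenset(
    {
        OutcomeKind.exon_skip,
        OutcomeKind.exon_extension,
        OutcomeKind.exon_truncation,
        OutcomeKind.new_exon_inclusion,
    }
)


@dataclass(frozen=True)
class FunctionalOutcome:
    """Outcome of an RNA functional study of a putative splice variant."""

    kind: OutcomeKind
    affected_length_nt: int | None = None  # nucleotides added/removed from transcript

    def __post_init__(self) -> None:
        if self.affected_length_nt is not None and self.affected_length_nt < 0:
            raise DataError("affected_length_nt must be non-negative")
        if self.kind in LENGTH_CHANGING_KINDS and self.affected_length_nt is None:
            # Tolerated at construction (length may be asserted later), but the
            # frame arithmetic will refuse to guess; see anatomy.frame_consequence.
            pass


def _check_unit(name: str, value: float | None) -> None:
    if value is None:
        return
    if math.isnan(value):
        raise DataError(f"{name} is NaN; use None for missing")
    if not 0.0 <= value <= 1.0:
        raise DataError(f"{name}={value!r} outside [0, 1]")


@dataclass(frozen=True)
class SpliceScores:
    """Pre-computed splice-prediction scores for one variant.

    ``mes_ref`` / ``mes_alt`` are MaxEntScan scores of the affected (or created)
    site under the reference and alternate allele; ``mes_delta`` is alt - ref and
    may be supplied on its own when only a score difference is reported.
    ADA / RF (dbscSNV) and SpliceAI are probabilities in [0, 1].
    """

    mes_ref: float | None = None
    mes_alt: float | None = None
    mes_delta: float | None = None
    ada: float | None = None
    rf: float | None = None
    spliceai: float | None = None

    def __post_init__(self) -> None:
        _check_unit("ada", self.ada)
        _check_unit("rf", self.rf)
        _check_unit("spliceai", self.spliceai)
        if (
            self.mes_ref is not None
            and self.mes_alt is not None
            and self.mes_delta is not None
            and abs(self.mes_delta - (self.mes_alt - self.mes_ref)) > 1e-9
        ):
            raise DataError("mes_delta inconsistent with mes_alt - mes_ref")

    @property
    def effective_mes_delta(self) -> float | None:
        """alt - ref when both present, else the supplied delta."""
        if self.mes_ref is not None and self.mes_alt is not None:
            return self.mes_alt - self.mes_ref
        return self.mes_delta

    @property
    def effective_mes_alt(self) -> float | None:
        """Alternate-allele site score; for a de novo site with no reference
        score, the reported delta *is* the new site's score (ref taken as 0)."""
        if self.mes_alt is not None:
            return self.mes_alt
        if self.mes_delta is not None:
            return (self.mes_ref or 0.0) + self.mes_delta
        return None


#: gnomAD sub-population codes used by the five-population rarity rule.
SUBPOPULATIONS = ("afr", "eas", "amr", "nfe", "sas")

SUBPOPULATION_LABELS = {
    "afr": "African",
    "eas": "East Asian",
    "amr": "Latino",
    "nfe": "Non-Finnish European",
    "sas": "South Asian",
}


@dataclass(frozen=True)
class VariantObservation:
    """One carrier x variant observation from a disease cohort."""

    participant_id: str
    disease: Disease
    gene: str
    transcript: str
    hgvs_c: str
    chrom: str | None = None
    pos: int | None = None  # 1-based, on `reference_build`
    ref: str | None = None
    alt: str | None = None
    consequence: ConsequenceAnnotation | None = None
    af_overall: float | None = None
    af_subpops: dict[str, float] = field(default_factory=dict)
    allele_count_controls: int | None = None
    scores: SpliceScores = field(default_factory=SpliceScores)
    proband_count: int = 0
    informative_meioses: int = 0
    functional_outcome: FunctionalOutcome | None = None
    sequencing_mode: SequencingMode = SequencingMode.exome
    exon_boundary_distance: int | None = None
    reference_build: str = "GRCh38"  # declared, never enforced

    def __post_init__(self) -> None:
        if not self.gene:
            raise DataError("gene symbol is empty")
        if not self.participant_id:
            raise DataError("participant_id is empty")
        if self.pos is not None and self.pos < 1:
            raise DataError(f"pos={self.pos} must be >= 1")
        _check_unit("af_overall", self.af_overall)
        for pop, af in self.af_subpops.items():
            _check_unit(f"af_{pop}", af)
        if self.allele_count_controls is not None and self.allele_count_controls < 0:
            raise DataError("allele_count_controls must be non-negative")
        if self.proband_count < 0 or self.informative_meioses < 0:
            raise DataError("proband/meiosis counts must be non-negative")

    @property
    def variant_key(self) -> tuple[str, str]:
        """Unique-variant identity: the same (transcript, hgvs_c) in two carriers
        is one variant."""
        return (self.transcript, self.hgvs_c)

    def with_scores(self, **kwargs) -> "VariantObservation":
        return replace(self, scores=replace(self.scores, **kwargs))


class HaploinsufficiencyScore(str, Enum):
    """ClinGen gene-dosage haploinsufficiency rating."""

    score_3 = "3"          # sufficient evidence of dosage sensitivity
    score_2 = "2"          # emerging evidence
    score_1 = "1"          # little evidence
    not_curated = "not_curated"


@dataclass(frozen=True)
class GeneMeta:
    """Per-gene disease validity and loss-of-function annotations."""

    gene: str
    definitive_for: frozenset[Disease] = frozenset()
    lof_mechanism: bool = False  # loss-of-function is an established disease mechanism
    haploinsufficiency_score: HaploinsufficiencyScore = HaploinsufficiencyScore.not_curated
    lof_oe: float | None = None  # gnomAD observed/expected LoF ratio
    mean_sequenced_controls: float = 1.0  # gnomAD per-gene coverage denominator
    is_ttn: bool = False

    def __post_init__(self) -> None:
        if self.mean_sequenced_controls <= 0:
            raise DataError(f"{self.gene}: mean_sequenced_controls must be > 0")
        if self.lof_oe is not None and self.lof_oe < 0:
            raise DataError(f"{self.gene}: lof_oe must be >= 0")


@dataclass(frozen=True)
class ControlCounts:
    """gnomAD-like per-gene control arm: qualifying rare splice alleles and the
    mean number of individuals sequenced over the gene."""

    gene: str
    qualifying_allele_count: float
    mean_sequenced_individuals: float

    def __post_init__(self) -> None:
        if self.qualifying_allele_count < 0:
            raise DataError(f"{self.gene}: qualifying_allele_count must be >= 0")
        if self.mean_sequenced_individuals <= 0:
            raise DataError(f"{self.gene}: mean_sequenced_individuals must be > 0")


# The TNNT2 acceptor variant excluded in-study as a rare Oceanian polymorphism.
_DEFAULT_EXCLUSIONS = {
    ("NM_001276345.2", "c.601-1G>A"): "rare Oceanian polymorphism (TNNT2)",
}


@dataclass
class ExclusionList:
    """Variants excluded from prioritisation regardless of scores."""

    entries: dict[tuple[str, str], str] = field(
        default_factory=lambda: dict(_DEFAULT_EXCLUSIONS)
    )

    @classmethod
    def empty(cls) -> "ExclusionList":
        return cls(entries={})

    def add(self, transcript: str, hgvs_c: str, reason: str = "") -> None:
        self.entries[(transcript, _normalise_hgvs(hgvs_c))] = reason

    def __contains__(self, key: tuple[str, str] | VariantObservation) -> bool:
        if isinstance(key, VariantObservation):
            key = key.variant_key
        transcript, hgvs_c = key
        return (transcript, _normalise_hgvs(hgvs_c)) in self.entries


def _normalise_hgvs(hgvs_c: str) -> str:
    """Strip whitespace so 'c.601-1 G > A' and 'c.601-1G>A' compare equal."""
    return "".join(hgvs_c.split())
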