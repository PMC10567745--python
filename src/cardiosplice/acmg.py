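"""ACMG/AMP evidence rules engine for splice variants, with RNA-evidence reclassification.

Implements the criteria used for splice-variant classification in inherited
heart disease, at study-customised strengths:

* PVS1 ladder for predicted/confirmed loss-of-function, modulated by ClinGen
  dosage haploinsufficiency score and gnomAD LoF constraint (o/e < 0.35),
  with titin (TTN) capped at strong;
* PS4 by unrelated concordant-phenotype proband count (>=15 strong,
  >=6 moderate, >=2 supporting);
* PP1 by informative co-segregation meioses (>=7 strong, >=5 moderate,
  >=3 supporting);
* PS3 / PM4 from RNA functional studies (out-of-frame vs in-frame change);
* PM2 for rarity, PP3 for concordant in silico prediction (withheld once RNA
  evidence is available — a measured outcome supersedes a prediction).

Evidence combination defaults to the point system (supporting 1, moderate 2,
strong 4, very strong 8; VUS <= 5, likely pathogenic 6-9, pathogenic >= 10);
the categorical 2015 rule set is available as an alternative combiner.
Benign-side criteria are out of scope.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from enum import Enum
from typing import Iterable

from .anatomy import FrameConsequence, frame_consequence
from .models import (
    DataError,
    FunctionalOutcome,
    GeneMeta,
    HaploinsufficiencyScore,
    OutcomeKind,
    VariantObservation,
)
from .prioritise import PrioritisationVerdict

__all__ = [
    "Code",
    "Strength",
    "EvidenceCode",
    "PathClass",
    "Classification",
    "assign_pvs1",
    "assign_ps4",
    "assign_pp1",
    "assign_functional",
    "assign_pm2_pp3",
    "combine",
    "reclassify_with_rna",
    "STRENGTH_POINTS",
]


class Code(str, Enum):
    PVS1 = "PVS1"
    PS3 = "PS3"
    PS4 = "PS4"
    PM2 = "PM2"
    PM4 = "PM4"
    PP1 = "PP1"
    PP3 = "PP3"


class Strength(str, Enum):
    very_strong = "very_strong"
    strong = "strong"
    moderate = "moderate"
    supporting = "supporting"


STRENGTH_POINTS = {
    Strength.supporting: 1,
    Strength.moderate: 2,
    Strength.strong: 4,
    Strength.very_strong: 8,
}

#: Default strength of each code; modulation away from the default is written
#: with an underscore suffix (e.g. PS4_moderate, PP1_strong).
_DEFAULT_STRENGTH = {
    Code.PVS1: Strength.very_strong,
    Code.PS3: Strength.strong,
    Code.PS4: Strength.strong,
    Code.PM2: Strength.moderate,
    Code.PM4: Strength.moderate,
    Code.PP1: Strength.supporting,
    Code.PP3: Strength.supporting,
}

#: Maximum strength each code may be modulated to. PP1 may rise to strong
#: (co-segregation across many meioses); PP3 stays supporting — prediction
#: evidence is never upgraded, it is superseded by RNA results.
_STRENGTH_CEILING = {
    Code.PVS1: Strength.very_strong,
    Code.PS3: Strength.strong,
    Code.PS4: Strength.strong,
    Code.PM2: Strength.moderate,
    Code.PM4: Strength.moderate,
    Code.PP1: Strength.strong,
    Code.PP3: Strength.supporting,
}


@dataclass(frozen=True)
class EvidenceCode:
    code: Code
    strength: Strength
    basis: str = ""

    def __post_init__(self) -> None:
        if STRENGTH_POINTS[self.strength] > STRENGTH_POINTS[_STRENGTH_CEILING[self.code]]:
            raise DataError(
                f"{self.code.value} cannot exceed strength "
                f"{_STRENGTH_CEILING[self.code].value}"
            )

    @property
    def token(self) -> str:
        """Printed form, e.g. ``PS4_moderate`` or bare ``PM2`` at default strength."""
        if self.strength is _DEFAULT_STRENGTH[self.code]:
            return self.code.value
        return f"{self.code.value}_{self.strength.value}"

    @classmethod
    def from_token(cls, token: str) -> "EvidenceCode":
        """Parse ``PS4_moderate`` / ``PP1_strong`` / ``PM2`` style tokens."""
        parts = token.strip().split("_", 1)
        code = Code(parts[0])
        strength = Strength(parts[1]) if len(parts) > 1 else _DEFAULT_STRENGTH[code]
        return cls(code=code, strength=strength)


class PathClass(str, Enum):
    pathogenic = "pathogenic"
    likely_pathogenic = "likely_pathogenic"
    VUS = "VUS"


_CLASS_RANK = {PathClass.VUS: 0, PathClass.likely_pathogenic: 1, PathClass.pathogenic: 2}


@dataclass(frozen=True)
class Classification:
    cls: PathClass
    points: int
    codes: frozenset[EvidenceCode]

    @property
    def tokens(self) -> tuple[str, ...]:
        return tuple(sorted(c.token for c in self.codes))


def assign_pvs1(
    gene: GeneMeta,
    frame: FrameConsequence,
    predicted_lof: bool = True,
) -> EvidenceCode | None:
    """Loss-of-function ladder. Applies to variants causing (or predicted to
    cause) a frameshift/PTC: very strong where loss-of-function is an
    established mechanism or dosage haploinsufficiency is scored 3; strong for
    a score of 2 and for titin; moderate for a score of 1; supporting for
    uncurated genes under strong LoF constraint (o/e < 0.35)."""
    if frame is FrameConsequence.in_frame_change:
        return None  # a confirmed in-frame change is not loss of function
    if frame is not FrameConsequence.frameshift_ptc and not predicted_lof:
        return None
    hi = gene.haploinsufficiency_score
    if gene.is_ttn:
        return EvidenceCode(Code.PVS1, Strength.strong, "titin: emerging dosage evidence")
    if gene.lof_mechanism or hi is HaploinsufficiencyScore.score_3:
        return EvidenceCode(Code.PVS1, Strength.very_strong, "established LoF mechanism")
    if hi is HaploinsufficiencyScore.score_2:
        return EvidenceCode(Code.PVS1, Strength.strong, "haploinsufficiency score 2")
    if hi is HaploinsufficiencyScore.score_1:
        return EvidenceCode(Code.PVS1, Strength.moderate, "haploinsufficiency score 1")
    if gene.lof_oe is not None and gene.lof_oe < 0.35:
        return EvidenceCode(Code.PVS1, Strength.supporting, f"LoF o/e {gene.lof_oe} < 0.35")
    return None


def assign_ps4(proband_count: int) -> EvidenceCode | None:
    """Case-enrichment by unrelated concordant-phenotype proband count."""
    if proband_count < 0:
        raise DataError("proband_count must be non-negative")
    if proband_count >= 15:
        return EvidenceCode(Code.PS4, Strength.strong, f"{proband_count} probands")
    if proband_count >= 6:
        return EvidenceCode(Code.PS4, Strength.moderate, f"{proband_count} probands")
    if proband_count >= 2:
        return EvidenceCode(Code.PS4, Strength.supporting, f"{proband_count} probands")
    return None


def assign_pp1(meioses: int) -> EvidenceCode | None:
    """Co-segregation by informative meioses."""
    if meioses < 0:
        raise DataError("meioses must be non-negative")
    if meioses >= 7:
        return EvidenceCode(Code.PP1, Strength.strong, f"{meioses} meioses")
    if meioses >= 5:
        return EvidenceCode(Code.PP1, Strength.moderate, f"{meioses} meioses")
    if meioses >= 3:
        return EvidenceCode(Code.PP1, Strength.supporting, f"{meioses} meioses")
    return None


def assign_functional(
    outcome: FunctionalOutcome,
    frame: FrameConsequence | None = None,
) -> EvidenceCode | None:
    """RNA functional evidence: PS3 for an out-of-frame change, PM4 for an
    in-frame change; a normal splicing result yields no pathogenic code."""
    if outcome.kind is OutcomeKind.unreported_consequence:
        warnings.warn("functional study with unreported consequence; no code assigned")
        return None
    if frame is None:
        frame = frame_consequence(outcome)
    if frame is FrameConsequence.frameshift_ptc:
        return EvidenceCode(Code.PS3, Strength.strong, outcome.kind.value)
    if frame is FrameConsequence.in_frame_change:
        return EvidenceCode(Code.PM4, Strength.moderate, outcome.kind.value)
    return None


#: control allele counts at or below this are "near-zero" for PM2
PM2_MAX_CONTROL_AC = 1


def assign_pm2_pp3(
    obs: VariantObservation,
    verdict: PrioritisationVerdict,
    rna_available: bool = False,
) -> set[EvidenceCode]:
    """Rarity (PM2) and in silico concordance (PP3).

    PM2 requires the rarity filter to pass with at most a near-zero control
    allele count; PP3 requires at least one flagging tool and is withheld once
    an RNA result exists (measured outcome supersedes prediction)."""
    from .prioritise import FilterName  # local import to avoid cycle at module load

    codes: set[EvidenceCode] = set()
    freq_ok = FilterName.frequency not in verdict.failed_filters
    near_zero = obs.allele_count_controls is None or (
        obs.allele_count_controls <= PM2_MAX_CONTROL_AC
    )
    if freq_ok and near_zero:
        codes.add(EvidenceCode(Code.PM2, Strength.moderate, "absent/near-absent in controls"))
    if verdict.tools_flagging and not rna_available:
        tools = ",".join(sorted(t.value for t in verdict.tools_flagging))
        codes.add(EvidenceCode(Code.PP3, Strength.supporting, f"flagged by {tools}"))
    return codes


def _combine_points(codes: frozenset[EvidenceCode]) -> Classification:
    points = sum(STRENGTH_POINTS[c.strength] for c in codes)
    if points >= 10:
        cls = PathClass.pathogenic
    elif points >= 6:
        cls = PathClass.likely_pathogenic
    else:
        cls = PathClass.VUS
    return Classification(cls=cls, points=points, codes=codes)


def _combine_categorical(codes: frozenset[EvidenceCode]) -> Classification:
    """The 2015 categorical combining rules, counted by (modulated) strength."""
    vs = sum(1 for c in codes if c.strength is Strength.very_strong)
    s = sum(1 for c in codes if c.strength is Strength.strong)
    m = sum(1 for c in codes if c.strength is Strength.moderate)
    p = sum(1 for c in codes if c.strength is Strength.supporting)

    pathogenic = (
        (vs >= 1 and (s >= 1 or m >= 2 or (m >= 1 and p >= 1) or p >= 2))
        or vs >= 2
        or s >= 2
        or (s == 1 and (m >= 3 or (m >= 2 and p >= 2) or (m >= 1 and p >= 4)))
    )
    likely = (
        (vs >= 1 and m >= 1)
        or (s >= 1 and 1 <= m <= 2)
        or (s >= 1 and p >= 2)
        or m >= 3
        or (m >= 2 and p >= 2)
        or (m >= 1 and p >= 4)
    )
    if pathogenic:
        cls = PathClass.pathogenic
    elif likely:
        cls = PathClass.likely_pathogenic
    else:
        cls = PathClass.VUS
    points = sum(STRENGTH_POINTS[c.strength] for c in codes)
    return Classification(cls=cls, points=points, codes=codes)


def combine(
    codes: Iterable[EvidenceCode],
    system: str = "points",
) -> Classification:
    """Combine evidence codes into a pathogenicity class."""
    codes = frozenset(codes)
    if system == "points":
        return _combine_points(codes)
    if system == "categorical":
        return _combine_categorical(codes)
    raise DataError(f"unknown combining system {system!r}")


def reclassify_with_rna(
    before: Classification,
    outcome: FunctionalOutcome,
    system: str = "points",
) -> tuple[Classification, str]:
    """Fold an RNA functional result into an existing classification.

    Drops PP3 (prediction superseded), adds PS3 or PM4 per the observed frame
    consequence, recombines, and labels the transition as ``upgrade``,
    ``downgrade`` or ``no_change``.
    """
    codes = {c for c in before.codes if c.code is not Code.PP3}
    functional = assign_functional(outcome)
    if functional is not None:
        codes.add(functional)
    after = combine(codes, system=system)
    delta = _CLASS_RANK[after.cls] - _CLASS_RANK[before.cls]
    transition = "upgrade" if delta > 0 else "downgrade" if delta < 0 else "no_change"
    return after, transition
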