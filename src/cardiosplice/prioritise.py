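"""In silico prioritisation of putative splice-disrupting variants.

A variant is a candidate when it is (i) in a gene definitively associated with
the carrier's disease, (ii) rare in the control population (overall and every
sub-population allele frequency < 1e-4; allele count <= 15 when reported),
(iii) within the surveyed region for the chosen mode, (iv) not on the
exclusion list, and (v) flagged by at least one splice-prediction tool:

* MaxEntScan (MES): splice-site variant reducing the site score by > 4, or a
  new site scoring > 4 with an increase of > 4 over the reference sequence
  (a de novo site with no reference score counts the reference as 0);
* dbscSNV ADA or RF > 0.6 (evaluable only at canonical splice sites);
* SpliceAI max delta score > 0.5.

All thresholds are strict inequalities; boundary values fail.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Mapping, Sequence

from .anatomy import Mechanism, Region, SpliceAnatomy, analyse_variant
from .models import (
    ConfigError,
    DataError,
    Disease,
    ExclusionList,
    GeneMeta,
    SpliceScores,
    SUBPOPULATIONS,
    VariantObservation,
)

__all__ = [
    "Tool",
    "Thresholds",
    "FilterName",
    "Mode",
    "PrioritisationVerdict",
    "ConcordanceTally",
    "frequency_filter",
    "region_filter",
    "tool_calls",
    "prioritise",
    "concordance_tally",
    "DEFAULT_THRESHOLDS",
]

BURDEN_INTRON_REACH = 75  # bp of flanking intron reliably covered by exome capture


class Tool(str, Enum):
    MES = "MES"
    ADA = "ADA"
    RF = "RF"
    SpliceAI = "SpliceAI"


class FilterName(str, Enum):
    panel = "panel"
    frequency = "frequency"
    region = "region"
    exclusion_list = "exclusion_list"
    no_tool = "no_tool"


class Mode(str, Enum):
    #: exome-compatible region rule used for case/control burden testing
    burden_75bp = "burden_75bp"
    #: no region restriction (genome-sequenced participants contribute deep intronics)
    discovery = "discovery"


@dataclass(frozen=True)
class Thresholds:
    """Tool calling thresholds; defaults are the tool developers' recommendations."""

    max_af: float = 1e-4
    max_ac: int = 15
    mes_loss_delta: float = 4.0
    mes_gain_min: float = 4.0
    mes_gain_delta: float = 4.0
    ada: float = 0.6
    rf: float = 0.6
    spliceai: float = 0.5


DEFAULT_THRESHOLDS = Thresholds()


@dataclass(frozen=True)
class PrioritisationVerdict:
    candidate: bool
    tools_flagging: frozenset[Tool] = frozenset()
    failed_filters: tuple[FilterName, ...] = ()
    anatomy: SpliceAnatomy | None = None

    def __post_init__(self) -> None:
        ok = not self.failed_filters and bool(self.tools_flagging)
        if self.candidate != ok:
            raise DataError("candidate flag inconsistent with filters/tools")


def frequency_filter(
    obs: VariantObservation,
    threshold: float = DEFAULT_THRESHOLDS.max_af,
    max_ac: int = DEFAULT_THRESHOLDS.max_ac,
) -> bool:
    """Rarity rule: overall AF and every reported sub-population AF below the
    threshold, and (when reported) control allele count <= max_ac. Missing
    frequencies pass — absence from controls is consistent with rarity."""
    afs = [obs.af_overall, *(obs.af_subpops.get(p) for p in SUBPOPULATIONS)]
    for af in afs:
        if af is None:
            continue
        if af < 0:
            raise DataError(f"negative allele frequency {af}")
        if af >= threshold:
            return False
    if obs.allele_count_controls is not None and obs.allele_count_controls > max_ac:
        return False
    return True


def region_filter(anatomy: SpliceAnatomy, mode: Mode = Mode.burden_75bp) -> bool:
    """Region rule: in burden mode only exonic positions and the first/last
    75 bp of intron count (exome capture reach); discovery mode keeps all."""
    if Mode(mode) is Mode.discovery:
        return True
    return abs(anatomy.offset) <= BURDEN_INTRON_REACH


def tool_calls(
    scores: SpliceScores,
    anatomy: SpliceAnatomy,
    thresholds: Thresholds = DEFAULT_THRESHOLDS,
) -> frozenset[Tool]:
    """Which tools flag the variant as splice-disrupting. Missing scores never
    flag; ADA/RF are only evaluable for canonical-splice-site variants."""
    flags: set[Tool] = set()
    canonical = anatomy.region in (Region.donor_site, Region.acceptor_site)

    delta = scores.effective_mes_delta
    alt = scores.effective_mes_alt
    if anatomy.mechanism is Mechanism.site_loss:
        if delta is not None and -delta > thresholds.mes_loss_delta:
            flags.add(Tool.MES)
    elif anatomy.mechanism is Mechanism.site_gain:
        ref = scores.mes_ref or 0.0
        if (
            alt is not None
            and alt > thresholds.mes_gain_min
            and (alt - ref) > thresholds.mes_gain_delta
        ):
            flags.add(Tool.MES)

    if canonical:
        if scores.ada is not None and scores.ada > thresholds.ada:
            flags.add(Tool.ADA)
        if scores.rf is not None and scores.rf > thresholds.rf:
            flags.add(Tool.RF)
    if scores.spliceai is not None and scores.spliceai > thresholds.spliceai:
        flags.add(Tool.SpliceAI)
    return frozenset(flags)


def prioritise(
    obs: VariantObservation,
    gene_meta: Mapping[str, GeneMeta],
    mode: Mode = Mode.discovery,
    exclusion: ExclusionList | None = None,
    thresholds: Thresholds = DEFAULT_THRESHOLDS,
) -> PrioritisationVerdict:
    """Full prioritisation of one observation.

    SUD participants have no single concordant phenotype, so any definitively
    disease-associated gene qualifies for them.
    """
    if obs.gene not in gene_meta:
        raise ConfigError(f"gene {obs.gene!r} absent from gene metadata")
    meta = gene_meta[obs.gene]
    exclusion = ExclusionList() if exclusion is None else exclusion

    anatomy = analyse_variant(
        obs.hgvs_c, obs.scores, exon_boundary_distance=obs.exon_boundary_distance
    )
    failed: list[FilterName] = []

    concordant = obs.disease is Disease.SUD or obs.disease in meta.definitive_for
    if not concordant:
        failed.append(FilterName.panel)
    if not frequency_filter(obs, thresholds.max_af, thresholds.max_ac):
        failed.append(FilterName.frequency)
    if not region_filter(anatomy, mode):
        failed.append(FilterName.region)
    if obs in exclusion:
        failed.append(FilterName.exclusion_list)

    tools = tool_calls(obs.scores, anatomy, thresholds)
    if not tools:
        failed.append(FilterName.no_tool)

    return PrioritisationVerdict(
        candidate=not failed,
        tools_flagging=tools,
        failed_filters=tuple(failed),
        anatomy=anatomy,
    )


@dataclass
class ConcordanceTally:
    """Tool-agreement histograms over unique flagged variants.

    Canonical splice-site variants can be scored by all four tools; outside
    canonical sites only MaxEntScan and SpliceAI apply.
    """

    canonical: Counter = field(default_factory=Counter)  # number of tools -> count
    noncanonical: Counter = field(default_factory=Counter)  # pattern -> count

    def as_dict(self) -> dict:
        return {
            "canonical_by_n_tools": {k: self.canonical.get(k, 0) for k in (1, 2, 3, 4)},
            "noncanonical": {
                k: self.noncanonical.get(k, 0)
                for k in ("MES_only", "both", "SpliceAI_only")
            },
        }


def concordance_tally(
    verdicts: Sequence[PrioritisationVerdict],
    anatomies: Sequence[SpliceAnatomy] | None = None,
) -> ConcordanceTally:
    """Tally tool agreement; input verdicts must already be deduplicated to
    unique variants. Variants with no flagging tool are not counted."""
    tally = ConcordanceTally()
    for i, v in enumerate(verdicts):
        anatomy = anatomies[i] if anatomies is not None else v.anatomy
        if anatomy is None:
            raise ConfigError("verdict carries no anatomy and none supplied")
        tools = v.tools_flagging
        if not tools:
            continue
        if anatomy.region in (Region.donor_site, Region.acceptor_site):
            tally.canonical[len(tools)] += 1
        else:
            has_mes, has_sai = Tool.MES in tools, Tool.SpliceAI in tools
            if has_mes and has_sai:
                tally.noncanonical["both"] += 1
            elif has_mes:
                tally.noncanonical["MES_only"] += 1
            elif has_sai:
                tally.noncanonical["SpliceAI_only"] += 1
    return tally


def dedupe_observations(
    observations: Iterable[VariantObservation],
) -> list[VariantObservation]:
    """First observation per unique (transcript, hgvs_c) variant."""
    seen: dict[tuple[str, str], VariantObservation] = {}
    for obs in observations:
        seen.setdefault(obs.variant_key, obs)
    return list(seen.values())
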