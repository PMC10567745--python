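"""Splice-region anatomy: HGVS c.-notation parsing, region taxonomy and frame arithmetic.

The taxonomy follows the operational splice-site definition used in clinical
splice-variant surveys: the donor site spans the last 3 exonic and first 6
intronic nucleotides of an exon/intron junction (near-invariant GT at +1/+2);
the acceptor site spans the last 20 intronic and first 3 exonic nucleotides
(near-invariant AG at -2/-1). Intronic variants outside both windows are deep
intronic; remaining exonic variants are "exonic other". Deep-intronic and
exonic variants typically act by creating a new (cryptic) splice site
(site gain), splice-site variants by weakening an existing one (site loss).
"""

from __future__ import annotations

import re
from dataclasses import dataclass, replace
from enum import Enum

from .models import (
    DataError,
    FunctionalOutcome,
    LENGTH_CHANGING_KINDS,
    OutcomeKind,
    SpliceScores,
)

__all__ = [
    "Region",
    "Mechanism",
    "FrameConsequence",
    "HgvsPosition",
    "SpliceAnatomy",
    "HgvsParseError",
    "parse_hgvs_offset",
    "classify_region",
    "infer_mechanism",
    "analyse_variant",
    "frame_consequence",
    "in_frame_amino_acids",
]

# Donor window: exonic -3..-1 | intronic +1..+6. Acceptor: intronic -20..-1 | exonic +1..+3.
DONOR_INTRON_MAX = 6
ACCEPTOR_INTRON_MAX = 20
EXONIC_WINDOW = 3


class HgvsParseError(ValueError):
    """The HGVS c. string could not be parsed; callers must flag, never skip."""


class Region(str, Enum):
    donor_site = "donor_site"
    acceptor_site = "acceptor_site"
    deep_intronic = "deep_intronic"
    exonic_other = "exonic_other"


class Mechanism(str, Enum):
    site_loss = "site_loss"
    site_gain = "site_gain"
    ambiguous = "ambiguous"


class FrameConsequence(str, Enum):
    frameshift_ptc = "frameshift_ptc"
    in_frame_change = "in_frame_change"
    none = "none"


@dataclass(frozen=True)
class HgvsPosition:
    """Parsed HGVS c. position: coding position, intronic offset and edit.

    Offset sign convention: ``+k`` is the k-th intronic nucleotide after an
    exon (donor side); ``-k`` the k-th intronic nucleotide before an exon
    (acceptor side); exonic positions have offset 0.
    """

    coding_pos: int
    intron_offset: int
    edit: str


@dataclass(frozen=True)
class SpliceAnatomy:
    """Where a variant sits relative to splice signals, and how it likely acts."""

    region: Region
    offset: int  # intronic offset (0 for exonic variants)
    exon_offset: int | None = None  # signed distance to the nearest exon end (exonic only)
    exon_edge: bool = False  # first or last nucleotide of an exon
    essential_dinucleotide: bool = False  # GT +1/+2 or AG -2/-1
    mechanism: Mechanism = Mechanism.ambiguous
    parse_ok: bool = True
    minor_intron: bool = False  # AT/AC (U12) intron annotation flag; no special scoring

    def __post_init__(self) -> None:
        if self.essential_dinucleotide and self.region not in (
            Region.donor_site,
            Region.acceptor_site,
        ):
            raise DataError("essential dinucleotide implies a donor/acceptor region")


_HGVS_RE = re.compile(
    r"""^c\.
        (?P<pos1>\*?\d+)(?P<off1>[+-]\d+)?
        (?:_(?P<pos2>\*?\d+)(?P<off2>[+-]\d+)?)?
        (?P<edit>(?:[ACGTacgt]+>[ACGTacgt]+|delins[ACGTacgt]+|del[ACGTacgt0-9]*|
                    dup[ACGTacgt0-9]*|ins[ACGTacgt]+))$""",
    re.VERBOSE,
)


def parse_hgvs_offset(hgvs_c: str) -> HgvsPosition:
    """Parse an HGVS c. substitution / small deletion / insertion.

    For a range (e.g. ``c.100-3_100-1del``) the reported position is the most
    splice-proximal affected nucleotide (smallest |intronic offset|), which is
    the nucleotide that determines the region classification.

    Raises :class:`HgvsParseError` on anything unparseable.
    """
    cleaned = "".join(hgvs_c.split())
    m = _HGVS_RE.match(cleaned)
    if not m:
        raise HgvsParseError(f"unparseable HGVS c. notation: {hgvs_c!r}")
    pos1 = int(m.group("pos1").lstrip("*"))
    off1 = int(m.group("off1") or 0)
    edit = m.group("edit")
    if m.group("pos2") is not None:
        pos2 = int(m.group("pos2").lstrip("*"))
        off2 = int(m.group("off2") or 0)
        # most splice-proximal end of the range wins
        if abs(off2) < abs(off1):
            pos1, off1 = pos2, off2
    return HgvsPosition(coding_pos=pos1, intron_offset=off1, edit=edit)


def classify_region(
    offset: int | HgvsPosition,
    exon_boundary_distance: int | None = None,
) -> SpliceAnatomy:
    """Classify a parsed position into the splice-region taxonomy.

    ``exon_boundary_distance`` applies to exonic variants only, with sign
    convention: ``-k`` = k-th nucleotide from the exon's 3' end (donor side;
    -1 is the last exonic nucleotide), ``+k`` = k-th nucleotide from the
    exon's 5' start (acceptor side; +1 is the first). ``None`` means unknown,
    in which case exonic variants fall to ``exonic_other``.
    """
    if isinstance(offset, HgvsPosition):
        offset = offset.intron_offset

    if offset > 0:
        region = Region.donor_site if offset <= DONOR_INTRON_MAX else Region.deep_intronic
        return SpliceAnatomy(
            region=region,
            offset=offset,
            essential_dinucleotide=offset in (1, 2),
            mechanism=(
                Mechanism.site_loss if region is Region.donor_site else Mechanism.ambiguous
            ),
        )
    if offset < 0:
        region = (
            Region.acceptor_site if offset >= -ACCEPTOR_INTRON_MAX else Region.deep_intronic
        )
        return SpliceAnatomy(
            region=region,
            offset=offset,
            essential_dinucleotide=offset in (-1, -2),
            mechanism=(
                Mechanism.site_loss if region is Region.acceptor_site else Mechanism.ambiguous
            ),
        )

    # exonic
    ebd = exon_boundary_distance
    if ebd is not None and -EXONIC_WINDOW <= ebd <= -1:
        return SpliceAnatomy(
            region=Region.donor_site, offset=0, exon_offset=ebd, exon_edge=(ebd == -1),
            mechanism=Mechanism.site_loss,
        )
    if ebd is not None and 1 <= ebd <= EXONIC_WINDOW:
        return SpliceAnatomy(
            region=Region.acceptor_site, offset=0, exon_offset=ebd, exon_edge=(ebd == 1),
            mechanism=Mechanism.site_loss,
        )
    return SpliceAnatomy(region=Region.exonic_other, offset=0, exon_offset=ebd)


def infer_mechanism(anatomy: SpliceAnatomy, scores: SpliceScores) -> Mechanism:
    """Site loss for splice-site variants; site gain for deep-intronic/exonic
    variants with a new-site signal (MaxEntScan new site > 4 with increase > 4,
    or SpliceAI > 0.5); otherwise ambiguous."""
    if anatomy.region in (Region.donor_site, Region.acceptor_site):
        return Mechanism.site_loss
    alt = scores.effective_mes_alt
    ref = scores.mes_ref or 0.0
    mes_gain = alt is not None and alt > 4.0 and (alt - ref) > 4.0
    spliceai_gain = scores.spliceai is not None and scores.spliceai > 0.5
    if mes_gain or spliceai_gain:
        return Mechanism.site_gain
    return Mechanism.ambiguous


def analyse_variant(
    hgvs_c: str,
    scores: SpliceScores | None = None,
    exon_boundary_distance: int | None = None,
    minor_intron: bool = False,
) -> SpliceAnatomy:
    """Parse + classify + infer mechanism in one step.

    An unparseable HGVS string yields ``exonic_other`` with ``parse_ok=False``
    (flagged, never silently skipped).
    """
    scores = scores or SpliceScores()
    try:
        pos = parse_hgvs_offset(hgvs_c)
    except HgvsParseError:
        return SpliceAnatomy(region=Region.exonic_other, offset=0, parse_ok=False)
    anatomy = classify_region(pos, exon_boundary_distance)
    anatomy = replace(
        anatomy,
        mechanism=infer_mechanism(anatomy, scores),
        minor_intron=minor_intron,
    )
    return anatomy


def frame_consequence(
    outcome: FunctionalOutcome,
    allow_in_frame_retention: bool = False,
) -> FrameConsequence:
    """Frame arithmetic on an RNA-level outcome.

    A transcript-length change that is a multiple of 3 is an in-frame change;
    anything else frameshifts and introduces a premature termination codon
    (PTC). Intron retention is treated as frameshift/PTC unless the caller
    asserts (``allow_in_frame_retention``) that the retained sequence is a
    multiple of 3 and free of in-frame stop codons — retained introns almost
    always contain stops.
    """
    kind = outcome.kind
    if kind in (
        OutcomeKind.no_change,
        OutcomeKind.impaired_protein_function,
        OutcomeKind.unreported_consequence,
        OutcomeKind.inconsistent,
    ):
        return FrameConsequence.none
    if kind is OutcomeKind.intron_retention:
        if (
            allow_in_frame_retention
            and outcome.affected_length_nt is not None
            and outcome.affected_length_nt % 3 == 0
        ):
            return FrameConsequence.in_frame_change
        return FrameConsequence.frameshift_ptc
    if kind in LENGTH_CHANGING_KINDS:
        n = outcome.affected_length_nt
        if n is None:
            raise DataError(f"{kind.value}: affected_length_nt required for frame arithmetic")
        if n == 0:
            return FrameConsequence.none
        return FrameConsequence.in_frame_change if n % 3 == 0 else FrameConsequence.frameshift_ptc
    raise DataError(f"unhandled outcome kind {kind!r}")  # pragma: no cover


def in_frame_amino_acids(affected_length_nt: int) -> int:
    """Amino acids added/removed by an in-frame change (75 nt -> 25 aa)."""
    if affected_length_nt % 3 != 0:
        raise DataError("not an in-frame length")
    return affected_length_nt // 3
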