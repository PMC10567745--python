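"""Splice-region anatomy and tool calling on six RNA-confirmed variants.

Each variant is placed in the splice-region taxonomy (donor / acceptor /
deep intronic / exonic) from its HGVS c. notation, its mechanism inferred
(loss of an existing site vs gain of a new one), and the in silico tools
that flag it are derived from its published scores.
"""

from cardiosplice.anatomy import analyse_variant
from cardiosplice.demo import rna_confirmed_variants
from cardiosplice.prioritise import tool_calls

print(f"{'variant':<22}{'region':<15}{'offset':>7}  {'essential':<10}"
      f"{'mechanism':<11}tools")
for dv in rna_confirmed_variants():
    obs = dv.observation
    anatomy = analyse_variant(obs.hgvs_c, obs.scores, obs.exon_boundary_distance)
    tools = ",".join(sorted(t.value for t in tool_calls(obs.scores, anatomy)))
    print(
        f"{obs.gene + ' ' + obs.hgvs_c:<22}{anatomy.region.value:<15}"
        f"{anatomy.offset:>7}  {str(anatomy.essential_dinucleotide):<10}"
        f"{anatomy.mechanism.value:<11}{tools}"
    )

print(
    "\nDonor-site variants sit in the -3..+6 window around the exon end, "
    "acceptor-site in -20..+3 around the exon start; a variant flagged by "
    "more tools is a stronger splice-disruption candidate."
)
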