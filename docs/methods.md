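# Methods

## Scope and data model

`cardiosplice` analyses *observations* — one row per carrier × variant — in
people with an inherited heart disease (HCM, DCM, ACM, LQTS, BrS, CPVT) or
unexplained sudden death (SUD). Each observation carries HGVS c. notation on a
MANE transcript, gnomAD-style allele frequencies and counts, pre-computed
splice-prediction scores (MaxEntScan, dbscSNV ADA/RF, SpliceAI), and optional
proband / co-segregation / RNA-study evidence. Genomic coordinates are 1-based
and fully closed (VCF convention) on a declared but unenforced reference
build; HGVS c. notation is the primary key for splice anatomy, and a unique
variant is a `(transcript, hgvs_c)` pair — one variant in two carriers counts
once in variant tallies and twice in carrier tallies. Missing values stay
missing end to end; a missing score never flags a tool and is never coerced
to 0.

## Splice-region taxonomy

The donor site spans the last 3 exonic and first 6 intronic nucleotides of a
junction; the acceptor site the last 20 intronic and first 3 exonic
nucleotides. The acceptor window is a single −20..+3 region — the
polypyrimidine tract is not modelled separately. Essential dinucleotides are
intronic +1/+2 (GT) and −2/−1 (AG). Intronic variants outside both windows
are deep intronic; exonic variants outside both exon-edge windows are "exonic
other". Exonic classification requires the distance to the nearest exon
boundary (signed: −k from the exon 3' end, +k from the 5' start), supplied as
an input column; without it an exonic variant falls to "exonic other" rather
than guessing. Small deletions spanning a boundary are classified by their
most splice-proximal affected nucleotide. Minor (AT/AC, U12) introns carry an
annotation flag only — no special scoring. Mechanism: donor/acceptor-site
variants are site losses; deep-intronic and other exonic variants are site
gains when they show a new-site signal (MaxEntScan new site > 4 with an
increase > 4, or SpliceAI > 0.5), otherwise ambiguous.

Frame arithmetic: a transcript-length change divisible by 3 is an in-frame
change of `nt/3` amino acids; anything else frameshifts to a premature
termination codon. Intron retention defaults to frameshift/PTC — retained
introns almost always contain in-frame stops — unless the caller asserts an
in-frame, stop-free retention.

## Prioritisation

All thresholds are strict inequalities (boundary values fail), and a variant
is a candidate if *any* tool flags it; the concordance tally records how many
did. ADA/RF are only evaluable at canonical splice sites. For a de novo
splice-site gain with no reference site, the reference MaxEntScan score is
taken as 0, so a single reported score difference acts as both the new site's
score and its increase. The rarity rule applies the overall and the five
gnomAD sub-population frequencies (African, East Asian, Latino, Non-Finnish
European, South Asian) at < 10⁻⁴, plus allele count ≤ 15 when reported; both
are applied whenever both columns are present. Phenotype concordance maps
each disease to its ClinGen-definitive gene panel (HCM 8, DCM 12, ACM 8,
LQTS 6, BrS 1, CPVT 7 genes; 32 unique genes in total); SUD, lacking a single
concordant phenotype, uses the union. A configurable exclusion list removes
known population-specific polymorphisms (by default one TNNT2 acceptor
variant that is a rare Oceanian polymorphism). Two region modes exist:
*discovery* (no region restriction; genome-sequenced participants contribute
deep intronic variants) and *burden* (exonic positions plus the first/last
75 bp of intron, the region exome capture covers reliably in both cases and
controls).

## Burden testing

For each gene in a disease's definitive panel, the 2×2 table is distinct case
carriers vs the disease-group size, against qualifying rare splice alleles vs
the mean number of control individuals sequenced over that gene (rounded to
integers for the exact test; frequencies and the case excess use the
unrounded values). Each qualifying control allele is assumed to be a distinct
carrier, defensible at allele frequencies below 10⁻⁴. The control qualifying
set is taken as filtered by the same rarity + region + tool rules as the
cases (symmetry); a control table built under rarity + region only is equally
valid input — the choice lives in the table, not the code. Significance is a
one-sided (enrichment in cases) Fisher's exact test via the hypergeometric
survival function, with Bonferroni correction per disease over its panel size
`m` (recorded in the output); restricting to one ancestry stratum is a filter
on the inputs, not a different test. Post-hoc power per gene uses the
observed frequencies with Cohen's arcsine effect size and the one-sided
two-proportion normal approximation at level `α/m`, matching the standard
`pwr`-style calculation; at a null effect it returns `α/m` by convention.

## ACMG/AMP engine

Evidence codes and strengths follow the study-customised scheme: the PVS1
ladder (very strong when loss of function is an established mechanism or the
ClinGen haploinsufficiency score is 3; strong for score 2 *and for titin*,
which is checked first so TTN is capped at strong; moderate for score 1;
supporting for uncurated genes with LoF o/e < 0.35), PS4 by unrelated
concordant probands (≥15 strong / ≥6 moderate / ≥2 supporting), PP1 by
informative meioses (≥7 strong / ≥5 moderate / ≥3 supporting), PM2 when the
rarity filter passes with a near-zero control allele count (≤ 1), PP3 when at
least one tool flags, and PS3 (out-of-frame) / PM4 (in-frame) from RNA
studies. PP3 and functional codes are mutually exclusive: an RNA result
supersedes prediction, so reclassification drops PP3, adds PS3/PM4 and
recombines. Combination uses the point system (supporting 1 / moderate 2 /
strong 4 / very strong 8; VUS ≤ 5, likely pathogenic 6–9, pathogenic ≥ 10)
because it reproduces 11 of the 12 published classifications in the bundled
six-variant case series; the 2015 categorical rule set is available behind
`combine(..., system="categorical")`. The one discrepancy (family 014
pre-RNA: PS4_moderate + PM2 + PP1 + PP3 scores 6 points yet was reported as
VUS) is carried as a documented property, not resolved. Benign-side criteria
are out of scope — no variant in this setting uses them. In the pipeline,
PVS1 is applied before RNA evidence only to essential-dinucleotide site-loss
variants (predicted loss of function); proband and meiosis counts are input
columns, never mined.

## Synthetic cohort generator

The generator emulates the study conditions: 1242 participants split HCM 720,
SUD 203, DCM 143, BrS 66, LQTS 55, ACM 34, CPVT 21. Six (disease, gene) pairs
carry planted case excesses over controls — MYBPC3 8.2% and MYH7 1.3% in HCM,
TTN 2.8% and FLNC 2.7% in DCM, PKP2 5.9% in ACM, KCNQ1 3.6% in LQTS — and
every other concordant gene is null (case rate equals the control rate). The
per-gene control rate defaults to 0.35%, a plausible cumulative carrier rate
of many distinct rare qualifying alleles, chosen so the expected cohort-wide
carrier fraction lands near the observed ~10%; the control denominator
defaults to 10⁵ individuals with per-gene coverage jitter. Variant locations
follow the observed region mix (donor 24 : acceptor 24 : exon-edge 10 : deep
intronic 25 : exonic gain 15), and tool agreement follows the observed
concordance profiles (canonical sites 25:11:8:1 over 4/3/2/1 tools;
non-canonical 30:8:2 over MES-only / both / SpliceAI-only). Scores are
generated to pass exactly the drawn tool subset with safety margins (0.05 on
probability scores, 0.5 MES units) so boundary flakiness cannot occur. All
randomness flows through one seeded generator; same seed, byte-identical
tables. A recurrence parameter lets carriers share founder-style variants.

What the generator does **not** emulate: linkage between sequencing mode and
deep-intronic ascertainment (panel/exome carriers can receive deep intronic
variants that a real panel would miss), participants carrying more than one
candidate variant, relatedness beyond a meiosis count, ancestry structure in
the sub-population frequencies, and per-gene length effects on variant counts.
Passing tests on synthetic cohorts therefore demonstrate the statistical
machinery (calibration, recovery, determinism), not ascertainment realism.

## Numerical choices and problem sizes

Fisher p-values come from `scipy.stats.hypergeom.sf`, checked exhaustively
against an independent exact enumeration over binomial coefficients for all
2×2 tables with total ≤ 60 (maximum deviation ~4 × 10⁻¹⁶); P(X ≥ 0) is fixed
at 1, covering the degenerate empty table. The closed-form power is checked
against a 10⁵-replicate Monte-Carlo of the one-sided arcsine z-test at five
parameter settings with moderate-to-large samples (agreement within ±0.01;
at very small expected counts the binomial lattice makes the z-test itself
lumpy, which is a property of the test, not the formula). Replicated
calibration studies (2000 null cohorts for family-wise type-I error, 200
enriched cohorts for recovery) run at the carrier-count level — the only
inputs the exact test consumes — so they complete in seconds. Percentages are
rendered round-half-up to one decimal; p-values in scientific notation.
Control denominators are rounded half-to-even only at the exact-test boundary.

## Known limitations

No branchpoint, enhancer/silencer or UTR analysis; no prediction of which
cryptic site is used; no translation of mutant transcripts; no
covariate-adjusted or kernel burden methods; no automated literature mining
for proband counts; no HGVS validation against a reference genome and no
liftover. The VCF reader ingests only SpliceAI-style INFO annotations and is
optional.
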