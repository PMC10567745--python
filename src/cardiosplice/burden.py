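"""Coverage-adjusted rare splice-variant burden testing against population controls.

Per gene and disease, the number of distinct case carriers of qualifying rare
splice variants is compared with the qualifying allele count in a gnomAD-like
control cohort. The control denominator is the mean number of individuals
sequenced over that gene (coverage varies across exome targets), rounded to an
integer for the exact test. Enrichment in cases is assessed with a one-sided
Fisher's exact test; Bonferroni correction is applied per disease over the
number of definitively disease-associated genes tested for that disease.

Post-hoc power uses Cohen's effect size for proportions
``h = 2 asin(sqrt(p1)) - 2 asin(sqrt(p2))`` and the one-sided normal
approximation for two unequal samples,
``power = Phi(|h| * sqrt(n1 n2 / (n1 + n2)) - z_{1-alpha})``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy import stats

from .models import ConfigError, ControlCounts, DataError, Disease, GeneMeta, VariantObservation

__all__ = [
    "BurdenResult",
    "fisher_one_sided",
    "run_burden",
    "power_two_proportions",
    "cohen_h",
    "carriers_per_gene",
]


def fisher_one_sided(a, b, c, d):
    """One-sided (enrichment-in-cases) Fisher's exact test on the 2x2 table

    ==============  ==========  ==============
    .               carriers    non-carriers
    cases           a           b
    controls        c           d
    ==============  ==========  ==============

    Returns the exact upper-tail hypergeometric probability P(X >= a) given
    the table margins. Accepts scalars or equally shaped integer arrays.
    """
    a, b, c, d = (np.asarray(x) for x in (a, b, c, d))
    for arr in (a, b, c, d):
        if np.any(arr < 0):
            raise DataError("counts must be non-negative")
        if not np.issubdtype(arr.dtype, np.integer):
            if np.any(arr != np.floor(arr)):
                raise DataError("counts must be integers")
    total = a + b + c + d
    p = stats.hypergeom.sf(a - 1, total, a + c, a + b)
    # P(X >= 0) is 1 by definition; also covers the degenerate empty table
    p = np.where(a == 0, 1.0, np.minimum(p, 1.0))
    if p.ndim == 0:
        return float(p)
    return p


def cohen_h(p1: float, p2: float) -> float:
    """Arcsine-transformed effect size for two proportions."""
    for p in (p1, p2):
        if not 0.0 <= p <= 1.0:
            raise DataError(f"proportion {p} outside [0, 1]")
    return 2.0 * math.asin(math.sqrt(p1)) - 2.0 * math.asin(math.sqrt(p2))


def power_two_proportions(
    p1: float,
    p2: float,
    n1: int,
    n2: int,
    alpha: float = 0.05,
) -> float:
    """One-sided power of the two-proportion test with unequal sample sizes."""
    if n1 <= 0 or n2 <= 0:
        raise DataError("sample sizes must be positive")
    if not 0.0 < alpha < 1.0:
        raise DataError("alpha must be in (0, 1)")
    h = abs(cohen_h(p1, p2))
    z_crit = stats.norm.ppf(1.0 - alpha)
    return float(stats.norm.cdf(h * math.sqrt(n1 * n2 / (n1 + n2)) - z_crit))


@dataclass(frozen=True)
class BurdenResult:
    gene: str
    disease: Disease
    case_carriers: int
    case_n: int
    control_qualifying: float
    control_n: float
    case_freq: float
    control_freq: float
    excess: float
    p_one_sided: float
    m_tests: int
    significant: bool
    power: float | None

    def __post_init__(self) -> None:
        if not 0 <= self.case_carriers <= self.case_n:
            raise DataError("case carriers outside [0, case_n]")
        if abs(self.excess - (self.case_freq - self.control_freq)) > 1e-12:
            raise DataError("excess must equal case_freq - control_freq")


def carriers_per_gene(
    observations: Iterable[VariantObservation], disease: Disease
) -> dict[str, int]:
    """Distinct case carriers per gene: a participant with two qualifying
    variants in one gene counts once."""
    carriers: dict[str, set[str]] = {}
    for obs in observations:
        if obs.disease is disease:
            carriers.setdefault(obs.gene, set()).add(obs.participant_id)
    return {g: len(s) for g, s in carriers.items()}


def run_burden(
    case_obs: Sequence[VariantObservation],
    case_n: int,
    control_table: Mapping[str, ControlCounts],
    gene_meta: Mapping[str, GeneMeta],
    disease: Disease,
    alpha: float = 0.05,
) -> list[BurdenResult]:
    """Burden test for every gene definitively associated with ``disease``.

    ``case_obs`` must already be restricted to qualifying observations (rare by
    the five-sub-population rule, within the exome-compatible 75 bp region,
    tool-flagged); this function only counts, tests and corrects. For SUD the
    panel is every gene in the metadata (all definitive genes).
    """
    if case_n <= 0:
        raise DataError("case_n must be positive")
    if disease is Disease.SUD:
        panel = sorted(gene_meta)
    else:
        panel = sorted(g for g, m in gene_meta.items() if disease in m.definitive_for)
    if not panel:
        raise ConfigError(f"no definitive genes for disease {disease.value}")
    m_tests = len(panel)
    carrier_counts = carriers_per_gene(case_obs, disease)

    results: list[BurdenResult] = []
    for gene in panel:
        a = carrier_counts.get(gene, 0)
        if gene in control_table:
            ctl = control_table[gene]
            c_real, n_real = ctl.qualifying_allele_count, ctl.mean_sequenced_individuals
        else:
            # gene absent from the control table: no qualifying alleles observed
            c_real, n_real = 0.0, gene_meta[gene].mean_sequenced_controls
        # each qualifying rare allele is assumed to be a distinct carrier
        c_int = int(round(c_real))
        n_int = int(round(n_real))
        case_freq = a / case_n
        control_freq = c_real / n_real
        p = fisher_one_sided(a, case_n - a, c_int, max(n_int - c_int, 0))
        power = (
            power_two_proportions(case_freq, control_freq, case_n, n_int, alpha / m_tests)
            if case_freq != control_freq
            else alpha / m_tests
        )
        results.append(
            BurdenResult(
                gene=gene,
                disease=disease,
                case_carriers=a,
                case_n=case_n,
                control_qualifying=c_real,
                control_n=n_real,
                case_freq=case_freq,
                control_freq=control_freq,
                excess=case_freq - control_freq,
                p_one_sided=p,
                m_tests=m_tests,
                significant=bool(p < alpha / m_tests),
                power=power,
            )
        )
    return results
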