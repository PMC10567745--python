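"""Definitive disease-gene panels for the inherited heart diseases.

The 32 genes below are the ClinGen-curated, definitively disease-associated
cardiomyopathy and arrhythmia genes. Each disease maps to its phenotypically
concordant definitive genes; sudden unexplained death (SUD), having no single
concordant phenotype, maps to the union of all 32.
"""

from __future__ import annotations

from .models import Disease

DISEASE_PANELS: dict[Disease, frozenset[str]] = {
    Disease.HCM: frozenset(
        {"MYBPC3", "MYH7", "TNNT2", "TNNI3", "TPM1", "ACTC1", "MYL2", "MYL3"}
    ),
    Disease.DCM: frozenset(
        {
            "TTN", "LMNA", "MYH7", "TNNT2", "TNNC1", "DES",
            "RBM20", "BAG3", "FLNC", "SCN5A", "PLN", "DSP",
        }
    ),
    Disease.ACM: frozenset(
        {"PKP2", "DSP", "DSG2", "DSC2", "JUP", "TMEM43", "PLN", "DES"}
    ),
    Disease.LQTS: frozenset(
        {"KCNQ1", "KCNH2", "SCN5A", "CALM1", "CALM2", "CALM3"}
    ),
    Disease.BrS: frozenset({"SCN5A"}),
    Disease.CPVT: frozenset(
        {"RYR2", "CASQ2", "CALM1", "CALM2", "CALM3", "TRDN", "TECRL"}
    ),
}

#: All 32 definitively disease-associated genes (union over diseases).
ALL_GENES: frozenset[str] = frozenset().union(*DISEASE_PANELS.values())

DISEASE_PANELS[Disease.SUD] = ALL_GENES

assert len(ALL_GENES) == 32


def panel_for(disease: Disease) -> frozenset[str]:
    """Genes retrieved for a participant with the given diagnosis."""
    return DISEASE_PANELS[disease]


def diseases_for(gene: str) -> frozenset[Disease]:
    """Diseases (excluding SUD) for which the gene is definitively associated."""
    return frozenset(
        d for d, genes in DISEASE_PANELS.items() if d is not Disease.SUD and gene in genes
    )
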