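"""Reference values from the published seven-cohort breast cancer analysis.

The original study combined GSEA results from seven TN vs ER+(HER2−)
cohorts — GSE25055, GSE25065, TCGA-BRCA, METABRIC discovery and
validation, and the E2100 and E2197 trial cohorts — against the MSigDB
transcription-factor-target collection.  The per-cohort p-values,
consensus signatures and perturbation overlaps reprinted here are used
as fixtures: feeding them back through this package's Stouffer
combination, signature and overlap code must reproduce the published
summary numbers.

Per-cohort p-values are as printed (three decimals; ``0.0`` cells are
display-rounded permutation floors and need clipping before use).
"""

from __future__ import annotations

__all__ = [
    "COHORT_ORDER",
    "COHORT_SIZES",
    "COHORT_ARMS",
    "TOTAL_SAMPLES",
    "MOTIF_PVALUES",
    "SIGNATURES",
    "PERTURBATION_FOUND",
]

#: Cohort column order used by the per-motif p-value rows below.
COHORT_ORDER: tuple[str, ...] = (
    "E2100",
    "E2197",
    "GSE25055",
    "GSE25065",
    "METABRIC_DISCOVERY",
    "METABRIC_VALIDATION",
    "TCGA_BRCA",
)

#: (n_TN, n_ER+) per cohort.
COHORT_ARMS: dict[str, tuple[int, int]] = {
    "E2100": (49, 65),
    "E2197": (191, 382),
    "GSE25055": (114, 165),
    "GSE25065": (64, 123),
    "METABRIC_DISCOVERY": (69, 344),
    "METABRIC_VALIDATION": (52, 184),
    "TCGA_BRCA": (58, 228),
}

COHORT_SIZES: dict[str, int] = {
    name: tn + er for name, (tn, er) in COHORT_ARMS.items()
}

TOTAL_SAMPLES: int = 2088

#: Published per-cohort GSEA p-values (cohorts in COHORT_ORDER) for the
#: promoter-motif sets used in the worked examples.
MOTIF_PVALUES: dict[str, tuple[float, ...]] = {
    "V$HIF1_Q5": (0.428, 0.002, 0.002, 0.103, 0.006, 0.041, 0.003),
    "V$AP1FJ_Q2": (0.202, 0.065, 0.256, 0.385, 0.158, 0.148, 0.132),
    "V$AP1_Q2": (0.253, 0.146, 0.116, 0.376, 0.158, 0.141, 0.088),
}

#: Published consensus promoter-motif signatures (genes enriched in the
#: maximum number of cohorts).  The V$GNCF_01 spelling follows the
#: published signature table.
SIGNATURES: dict[str, tuple[str, ...]] = {
    "V$GNCF_01": (
        "ABTB2", "AMD1", "BCL11A", "BCL11B", "FGF9",
        "ITGB8", "MALL", "NFIB", "NFIL3", "RASAL1",
    ),
    "V$E2F_01": (
        "AMD1", "DNMT1", "E2F3", "MCM3", "MCM4",
        "MYC", "NASP", "RANBP1", "SMC4",
    ),
}

#: Published signature genes found inside perturbation _DN sets.
PERTURBATION_FOUND: dict[str, dict[str, tuple[str, ...]]] = {
    "BLUM_RESPONSE_TO_SALIRASIB_DN": {
        "V$E2F_01": ("DNMT1", "MCM3", "NASP", "RANBP1", "SMC4"),
        "V$E2F_Q3": (
            "CDC25A", "CDC45", "CDK1", "DNMT1", "EZH2", "FBXO5", "GMNN",
            "KIF15", "MCM3", "MCM6", "NASP", "PLK4", "POLA2", "RANBP1",
            "USP1",
        ),
        "KTGGYRSGAA_UNKNOWN": (
            "EZH2", "MCM3", "MCM6", "POLD1", "RANBP1", "RFC4", "SYNCRIP",
        ),
    },
    "KRIGE_RESPONSE_TO_TOSEDOSTAT_24HR_DN": {
        "V$E2F_01": ("AMD1", "MYC", "NASP", "RANBP1", "SMC4"),
    },
}
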