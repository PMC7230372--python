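"""Mode-of-inheritance vocabulary shared by filtering, scoring and phenotype.

Candidate genotypes are assembled under per-genotype sub-modes (the
frequency cutoff differs between a recessive homozygote and a compound
heterozygote), but results are reported and evaluated under the coarser
analysis modes AD/AR/XD/XR/MT.
"""

from __future__ import annotations

from enum import Enum

__all__ = ["ModeOfInheritance", "AnalysisMoi", "DiseaseMoi", "moi_compatible"]


class AnalysisMoi(str, Enum):
    """Reporting-level mode of inheritance (one ranked table per mode)."""

    AD = "AD"
    AR = "AR"
    XD = "XD"
    XR = "XR"
    MT = "MT"


class ModeOfInheritance(str, Enum):
    """Genotype-level inheritance sub-mode, as configured with its own MAF cutoff."""

    AD = "AD"
    AR_HOM = "AR_HOM"
    AR_COMPHET = "AR_COMPHET"
    XD = "XD"
    XR_HOM = "XR_HOM"
    XR_COMPHET = "XR_COMPHET"
    MT = "MT"

    @property
    def analysis_moi(self) -> AnalysisMoi:
        return _ANALYSIS_GROUP[self]

    @classmethod
    def from_config_key(cls, key: str) -> "ModeOfInheritance":
        try:
            return _CONFIG_KEYS[key]
        except KeyError:
            raise ValueError(f"unknown inheritanceModes key: {key!r}") from None

    @property
    def config_key(self) -> str:
        return _CONFIG_KEYS_INV[self]


_ANALYSIS_GROUP = {
    ModeOfInheritance.AD: AnalysisMoi.AD,
    ModeOfInheritance.AR_HOM: AnalysisMoi.AR,
    ModeOfInheritance.AR_COMPHET: AnalysisMoi.AR,
    ModeOfInheritance.XD: AnalysisMoi.XD,
    ModeOfInheritance.XR_HOM: AnalysisMoi.XR,
    ModeOfInheritance.XR_COMPHET: AnalysisMoi.XR,
    ModeOfInheritance.MT: AnalysisMoi.MT,
}

# the YAML dialect key names of the analysis configuration
_CONFIG_KEYS = {
    "AUTOSOMAL_DOMINANT": ModeOfInheritance.AD,
    "AUTOSOMAL_RECESSIVE_HOM_ALT": ModeOfInheritance.AR_HOM,
    "AUTOSOMAL_RECESSIVE_COMP_HET": ModeOfInheritance.AR_COMPHET,
    "X_DOMINANT": ModeOfInheritance.XD,
    "X_RECESSIVE_HOM_ALT": ModeOfInheritance.XR_HOM,
    "X_RECESSIVE_COMP_HET": ModeOfInheritance.XR_COMPHET,
    "MITOCHONDRIAL": ModeOfInheritance.MT,
}
_CONFIG_KEYS_INV = {v: k for k, v in _CONFIG_KEYS.items()}


class DiseaseMoi(str, Enum):
    """Mode of inheritance annotated on a human disease."""

    AD = "AD"
    AR = "AR"
    XD = "XD"
    XR = "XR"
    MT = "MT"
    UNKNOWN = "UNKNOWN"


_DOMINANT = {DiseaseMoi.AD, DiseaseMoi.XD}
_RECESSIVE = {DiseaseMoi.AR, DiseaseMoi.XR}


def moi_compatible(disease: DiseaseMoi, candidate: AnalysisMoi) -> bool:
    """Is a candidate genotype's inheritance mode consistent with a disease annotation?

    Dominant annotations (AD/XD) match dominant candidates, recessive (AR/XR)
    match recessive candidates; an UNKNOWN annotation never triggers the
    phenotype-score penalty.
    """
    if disease is DiseaseMoi.UNKNOWN:
        return True
    if disease is DiseaseMoi.MT:
        return candidate is AnalysisMoi.MT
    if disease in _DOMINANT:
        return candidate in (AnalysisMoi.AD, AnalysisMoi.XD)
    return candidate in (AnalysisMoi.AR, AnalysisMoi.XR)
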