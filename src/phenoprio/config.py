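"""Analysis configuration: the YAML dialect driving a prioritization run.

The accepted key names mirror the tool's analysis YML: ``genomeAssembly``,
``vcf``, ``hpoIds``, ``inheritanceModes`` (per-mode MAF cutoffs in percent),
``analysisMode``, ``frequencySources``, ``pathogenicitySources`` and an
ordered ``steps`` list of filter/prioritiser entries
(``qualityFilter``/``variantEffectFilter``/``frequencyFilter``/
``pathogenicityFilter``/``inheritanceFilter``/``omimPrioritiser``/
``hiPhivePrioritiser``).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import yaml

from .inheritance import ModeOfInheritance
from .variants import Consequence, DEFAULT_REMOVE_EFFECTS

__all__ = ["AnalysisConfig", "DEFAULT_FREQUENCY_SOURCES", "DEFAULT_PATHOGENICITY_SOURCES"]

DEFAULT_FREQUENCY_SOURCES = (
    "LOCAL",
    "THOUSAND_GENOMES",
    "TOPMED",
    "UK10K",
    "GNOMAD_E_NFE",
)

DEFAULT_PATHOGENICITY_SOURCES = ("POLYPHEN", "MUTATION_TASTER", "SIFT")

DEFAULT_INHERITANCE_CUTOFFS: dict[ModeOfInheritance, float] = {
    ModeOfInheritance.AD: 0.1,
    ModeOfInheritance.AR_HOM: 0.5,
    ModeOfInheritance.AR_COMPHET: 2.0,
    ModeOfInheritance.XD: 0.1,
    ModeOfInheritance.XR_HOM: 0.5,
    ModeOfInheritance.XR_COMPHET: 2.0,
}

_STEP_NAMES = (
    "qualityFilter",
    "variantEffectFilter",
    "frequencyFilter",
    "pathogenicityFilter",
    "inheritanceFilter",
    "omimPrioritiser",
    "hiPhivePrioritiser",
)


@dataclass(frozen=True)
class AnalysisConfig:
    genome_assembly: str = "hg19"
    vcf_path: str | None = None
    hpo_ids: tuple[str, ...] = ()
    inheritance_modes: Mapping[ModeOfInheritance, float] = field(
        default_factory=lambda: dict(DEFAULT_INHERITANCE_CUTOFFS)
    )
    analysis_mode: str = "PASS_ONLY"
    frequency_sources: tuple[str, ...] = DEFAULT_FREQUENCY_SOURCES
    pathogenicity_sources: tuple[str, ...] = DEFAULT_PATHOGENICITY_SOURCES
    steps: tuple[str, ...] = _STEP_NAMES
    min_quality: float = 30.0
    remove_effects: tuple[Consequence, ...] = DEFAULT_REMOVE_EFFECTS
    max_frequency: float = 2.0
    keep_non_pathogenic: bool = True

    def __post_init__(self) -> None:
        if self.analysis_mode not in ("PASS_ONLY", "FULL"):
            raise ValueError(f"unknown analysisMode: {self.analysis_mode}")
        for moi, cutoff in self.inheritance_modes.items():
            if cutoff <= 0:
                raise ValueError(f"cutoff for {moi.value} must be positive")
        unknown = [s for s in self.steps if s not in _STEP_NAMES]
        if unknown:
            raise ValueError(f"unknown step(s): {unknown}")

    @property
    def run_hiphive(self) -> bool:
        return "hiPhivePrioritiser" in self.steps

    @property
    def run_omim(self) -> bool:
        return "omimPrioritiser" in self.steps

    def with_vcf(self, vcf_path, hpo_ids: Sequence[str]) -> "AnalysisConfig":
        return replace(self, vcf_path=str(vcf_path), hpo_ids=tuple(hpo_ids))

    # -- YAML dialect -------------------------------------------------------
    @classmethod
    def from_yaml(cls, path) -> "AnalysisConfig":
        with open(path) as fh:
            doc = yaml.safe_load(fh)
        return cls.from_dict(doc)

    @classmethod
    def from_dict(cls, doc: Mapping) -> "AnalysisConfig":
        analysis = doc.get("analysis", doc)
        modes = {
            ModeOfInheritance.from_config_key(k): float(v)
            for k, v in (analysis.get("inheritanceModes") or {}).items()
        }
        steps_raw = analysis.get("steps")
        step_names: list[str] = []
        kwargs: dict = {}
        if steps_raw is None:
            step_names = list(_STEP_NAMES)
        else:
            entries: list[tuple[str, Mapping]] = []
            if isinstance(steps_raw, Mapping):
                entries = [(k, v or {}) for k, v in steps_raw.items()]
            else:
                for item in steps_raw:
                    if isinstance(item, str):
                        entries.append((item, {}))
                    else:
                        for k, v in item.items():
                            entries.append((k, v or {}))
            for name, opts in entries:
                if name not in _STEP_NAMES:
                    raise ValueError(f"unknown step: {name}")
                step_names.append(name)
                if name == "qualityFilter" and "minQuality" in opts:
                    kwargs["min_quality"] = float(opts["minQuality"])
                elif name == "variantEffectFilter" and "remove" in opts:
                    kwargs["remove_effects"] = tuple(
                        Consequence(label) for label in opts["remove"]
                    )
                elif name == "frequencyFilter" and "maxFrequency" in opts:
                    kwargs["max_frequency"] = float(opts["maxFrequency"])
                elif name == "pathogenicityFilter" and "keepNonPathogenic" in opts:
                    kwargs["keep_non_pathogenic"] = bool(opts["keepNonPathogenic"])
        return cls(
            genome_assembly=analysis.get("genomeAssembly", "hg19"),
            vcf_path=analysis.get("vcf"),
            hpo_ids=tuple(analysis.get("hpoIds") or ()),
            inheritance_modes=modes or dict(DEFAULT_INHERITANCE_CUTOFFS),
            analysis_mode=analysis.get("analysisMode", "PASS_ONLY"),
            frequency_sources=tuple(
                analysis.get("frequencySources") or DEFAULT_FREQUENCY_SOURCES
            ),
            pathogenicity_sources=tuple(
                analysis.get("pathogenicitySources") or DEFAULT_PATHOGENICITY_SOURCES
            ),
            steps=tuple(step_names),
            **kwargs,
        )

    def to_dict(self) -> dict:
        steps: list = []
        for name in self.steps:
            if name == "qualityFilter":
                steps.append({name: {"minQuality": self.min_quality}})
            elif name == "variantEffectFilter":
                steps.append({name: {"remove": [c.value for c in self.remove_effects]}})
            elif name == "frequencyFilter":
                steps.append({name: {"maxFrequency": self.max_frequency}})
            elif name == "pathogenicityFilter":
                steps.append({name: {"keepNonPathogenic": self.keep_non_pathogenic}})
            else:
                steps.append({name: {}})
        return {
            "analysis": {
                "genomeAssembly": self.genome_assembly,
                "vcf": self.vcf_path,
                "hpoIds": list(self.hpo_ids),
                "inheritanceModes": {
                    moi.config_key: cutoff
                    for moi, cutoff in self.inheritance_modes.items()
                },
                "analysisMode": self.analysis_mode,
                "frequencySources": list(self.frequency_sources),
                "pathogenicitySources": list(self.pathogenicity_sources),
                "steps": steps,
            }
        }

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    @classmethod
    def default(cls) -> "AnalysisConfig":
        """The full phenotype-aware configuration (all steps enabled)."""
        return cls()

    @classmethod
    def variant_only(cls) -> "AnalysisConfig":
        """Variant-score-only configuration: both prioritisers disabled."""
        return cls(
            steps=tuple(
                s
                for s in _STEP_NAMES
                if s not in ("omimPrioritiser", "hiPhivePrioritiser")
            )
        )
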