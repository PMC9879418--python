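"""Analysis configuration: one object holding every threshold and option
the pipeline uses, loadable from a YAML file layered over the bundled
defaults."""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Union

import yaml

from .core import Element
from .mortality import AgeClassScheme
from .osteometry import SexClass, SexRuleConfig, WithersFactors
from .pathology import IndexFormula, IndexVariant, ReferencePopulation
from .resources import (
    default_age_class_scheme,
    load_default_config_dict,
    load_reference_populations,
)

__all__ = ["AnalysisConfig"]


def _deep_update(base: dict, override: dict) -> dict:
    out = dict(base)
    for key, value in override.items():
        if isinstance(value, dict) and isinstance(out.get(key), dict):
            out[key] = _deep_update(out[key], value)
        else:
            out[key] = value
    return out


@dataclass
class AnalysisConfig:
    formula: IndexFormula = field(default_factory=IndexFormula.pathological)
    sex_rules: SexRuleConfig = field(default_factory=SexRuleConfig)
    withers_factors: WithersFactors = field(default_factory=WithersFactors)
    traction_threshold: float = 0.75
    n_boot: int = 2000
    boot_level: float = 0.95
    seed: int = 0
    scheme: AgeClassScheme = field(default_factory=default_age_class_scheme)
    references: list[ReferencePopulation] = field(default_factory=load_reference_populations)

    @classmethod
    def from_yaml(cls, path: Optional[Union[str, Path]] = None) -> "AnalysisConfig":
        """Build a config from a YAML file; keys not given fall back to the
        bundled defaults."""
        raw = load_default_config_dict()
        if path is not None:
            with open(path, "r", encoding="utf-8") as fh:
                user = yaml.safe_load(fh) or {}
            raw = _deep_update(raw, user)
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "AnalysisConfig":
        idx = raw.get("index", {})
        formula = IndexFormula(
            variant=IndexVariant(idx.get("variant", "normalised_sum")),
            oa_present_is_high=bool(idx.get("oa_present_is_high", True)),
        )
        sr = raw.get("sex_rules", {})
        sex_rules = SexRuleConfig(
            bd_female_max=float(sr.get("bd_female_max", 63.0)),
            bd_male_min=float(sr.get("bd_male_min", 65.0)),
            gracility_cow_max=float(sr.get("gracility_cow_max", 17.0)),
            gracility_bull_range=tuple(sr.get("gracility_bull_range", (17.0, 20.0))),
            ox_gl_min=float(sr.get("ox_gl_min", 215.0)),
            ox_gracility_range=tuple(sr.get("ox_gracility_range", (15.0, 17.5))),
        )
        wf_raw = raw.get("withers_factors")
        if wf_raw:
            factors = {}
            for element_name, by_sex in wf_raw.items():
                for sex_name, factor in by_sex.items():
                    factors[(Element.parse(element_name), SexClass(sex_name))] = float(factor)
            withers = WithersFactors(factors=factors)
        else:
            withers = WithersFactors()
        scheme = (
            AgeClassScheme.from_dict(raw["age_classes"])
            if "age_classes" in raw
            else default_age_class_scheme()
        )
        boot = raw.get("bootstrap", {})
        return cls(
            formula=formula,
            sex_rules=sex_rules,
            withers_factors=withers,
            traction_threshold=float(raw.get("traction_threshold", 0.75)),
            n_boot=int(boot.get("n_boot", 2000)),
            boot_level=float(boot.get("level", 0.95)),
            seed=int(raw.get("seed", 0)),
            scheme=scheme,
        )

    def canonical_dict(self) -> dict:
        """Stable, JSON-serialisable view used for the config hash."""
        return {
            "index": {
                "variant": self.formula.variant.value,
                "included_features": list(self.formula.included_features),
                "oa_present_is_high": self.formula.oa_present_is_high,
            },
            "traction_threshold": self.traction_threshold,
            "sex_rules": {
                "bd_female_max": self.sex_rules.bd_female_max,
                "bd_male_min": self.sex_rules.bd_male_min,
                "gracility_cow_max": self.sex_rules.gracility_cow_max,
                "gracility_bull_range": list(self.sex_rules.gracility_bull_range),
                "ox_gl_min": self.sex_rules.ox_gl_min,
                "ox_gracility_range": list(self.sex_rules.ox_gracility_range),
            },
            "withers_factors": {
                f"{el.value}:{sx.value}": f
                for (el, sx), f in sorted(
                    self.withers_factors.factors.items(), key=lambda kv: (kv[0][0].value, kv[0][1].value)
                )
            },
            "bootstrap": {"n_boot": self.n_boot, "level": self.boot_level},
            "seed": self.seed,
            "age_classes": [
                {
                    "label": c.label,
                    "lower_months": c.lower_months,
                    "upper_months": c.upper_months,
                    "mws_min": c.mws_min,
                    "mws_max": c.mws_max,
                }
                for c in self.scheme
            ],
        }

    def config_hash(self) -> str:
        blob = json.dumps(self.canonical_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]
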