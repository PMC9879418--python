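"""Metapodial osteometrics: traction index, sexing and withers height.

Three quantitative tools work from the distal and diaphyseal measurements of
cattle metapodials (metacarpal = forelimb, metatarsal = hindlimb cannon
bone):

* the traction index e/D1, describing remodelling/extension of the distal
  medial condyle — values at or above 0.75 are consistent with draught use;
* osteometric sexing, either from distal breadth Bd (cows below 63 mm, bulls
  above 65 mm, the band between ambiguous) or from the gracility index
  SD/GL × 100 read jointly with greatest length GL: slender shafts (< 17)
  are cows, robust shafts (17–20) bulls, and very long bones (> 215 mm) with
  intermediate gracility (15–17.5) are candidate early-castrated males (oxen)
  — the castrate rule is evaluated first because its gracility band overlaps
  the cow band and length is what separates them;
* withers (shoulder) height, as GL times an element- and sex-specific
  multiplier (the Matolcsi factors), converted mm → cm.

Boundary comparisons are carried out in decimal arithmetic on the supplied
values, so a measurement written "63" or "0.75" lands on the documented side
of its threshold regardless of binary floating-point representation.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from decimal import Decimal
from typing import Optional, Union

import numpy as np
import pandas as pd

from .core import Assemblage, Element

__all__ = [
    "SexClass",
    "SexMethod",
    "SexRuleConfig",
    "SexAssignment",
    "WithersFactors",
    "TractionVerdict",
    "TractionClassification",
    "gracility_index",
    "sex_by_bd",
    "sex_by_gracility",
    "traction_index",
    "classify_traction",
    "withers_height",
    "specimen_summary",
]

Number = Union[int, float, str, Decimal]


def _dec(x: Number) -> Decimal:
    """Decimal view of a supplied measurement for exact threshold comparison."""
    if isinstance(x, Decimal):
        return x
    if isinstance(x, float):
        return Decimal(repr(x))
    return Decimal(str(x))


class SexClass(str, enum.Enum):
    FEMALE = "female"
    MALE = "male"
    CASTRATE_CANDIDATE = "castrate_candidate"
    AMBIGUOUS = "ambiguous"


class SexMethod(str, enum.Enum):
    BD_THRESHOLD = "bd_threshold"
    GRACILITY = "gracility"


class TractionVerdict(str, enum.Enum):
    TRACTION_CONSISTENT = "traction_consistent"
    NOT_INDICATED = "not_indicated"


@dataclass(frozen=True)
class SexRuleConfig:
    """Thresholds of the osteometric sexing rules (all lengths mm)."""

    bd_female_max: float = 63.0
    bd_male_min: float = 65.0
    gracility_cow_max: float = 17.0
    gracility_bull_range: tuple[float, float] = (17.0, 20.0)
    ox_gl_min: float = 215.0
    ox_gracility_range: tuple[float, float] = (15.0, 17.5)

    def __post_init__(self):
        if not self.bd_female_max <= self.bd_male_min:
            raise ValueError("bd_female_max must not exceed bd_male_min")
        for name in ("gracility_bull_range", "ox_gracility_range"):
            lo, hi = getattr(self, name)
            if not lo <= hi:
                raise ValueError(f"{name} must be well-ordered")


@dataclass(frozen=True)
class SexAssignment:
    specimen_id: str
    method: SexMethod
    klass: SexClass
    rule_fired: str

    def __post_init__(self):
        if not self.rule_fired:
            raise ValueError("rule_fired must be non-empty")


@dataclass(frozen=True)
class WithersFactors:
    """Multipliers mapping metapodial GL (mm) to withers height (cm).

    Keyed by (element, sex class); defaults follow the factor set
    conventionally attributed to Matolcsi (1970) and are editable config,
    not a claim of authority. All factors are dimensionless and applied as
    GL × factor / 10.
    """

    factors: dict[tuple[Element, SexClass], float] = field(
        default_factory=lambda: {
            (Element.METACARPAL, SexClass.FEMALE): 6.03,
            (Element.METACARPAL, SexClass.MALE): 6.33,
            (Element.METACARPAL, SexClass.CASTRATE_CANDIDATE): 6.18,
            (Element.METATARSAL, SexClass.FEMALE): 5.33,
            (Element.METATARSAL, SexClass.MALE): 5.62,
            (Element.METATARSAL, SexClass.CASTRATE_CANDIDATE): 5.45,
        }
    )

    def __post_init__(self):
        for key, factor in self.factors.items():
            if not (4.0 < factor < 8.0):
                raise ValueError(f"withers factor out of range for {key}: {factor}")

    def get(self, element: Element, klass: SexClass) -> float:
        try:
            return self.factors[(element, klass)]
        except KeyError:
            raise KeyError(
                f"no withers factor for ({element.value}, {klass.value})"
            ) from None


@dataclass(frozen=True)
class TractionClassification:
    specimen_id: str
    e: float
    D1: float
    index: float
    verdict: TractionVerdict


def gracility_index(GL: Number, SD: Number) -> float:
    """Shaft slenderness SD/GL × 100 of a metapodial (dimensionless)."""
    gl, sd = float(GL), float(SD)
    if gl <= 0 or sd <= 0:
        raise ValueError(f"GL and SD must be positive (GL={GL}, SD={SD})")
    if sd >= gl:
        raise ValueError(f"SD must be smaller than GL (GL={GL}, SD={SD})")
    return sd / gl * 100.0


def sex_by_bd(Bd: Number, cfg: Optional[SexRuleConfig] = None, specimen_id: str = "") -> SexAssignment:
    """Sex a metacarpal from its distal breadth.

    Strict inequalities at both cut-offs: measurements on the boundaries fall
    into the ambiguous band, where small bulls and large cows overlap.
    """
    cfg = cfg or SexRuleConfig()
    bd = _dec(Bd)
    if bd <= 0:
        raise ValueError(f"Bd must be positive (got {Bd})")
    if bd < _dec(cfg.bd_female_max):
        klass, rule = SexClass.FEMALE, f"Bd {Bd} < {cfg.bd_female_max} mm"
    elif bd > _dec(cfg.bd_male_min):
        klass, rule = SexClass.MALE, f"Bd {Bd} > {cfg.bd_male_min} mm"
    else:
        klass, rule = (
            SexClass.AMBIGUOUS,
            f"Bd {Bd} within {cfg.bd_female_max}-{cfg.bd_male_min} mm overlap band",
        )
    return SexAssignment(specimen_id, SexMethod.BD_THRESHOLD, klass, rule)


def sex_by_gracility(
    GL: Number, SD: Number, cfg: Optional[SexRuleConfig] = None, specimen_id: str = ""
) -> SexAssignment:
    """Sex a metapodial from gracility index and greatest length.

    Rule precedence is total and deterministic: the castrate (ox) rule —
    long bone, intermediate gracility — fires first, then the cow band, then
    the bull band; anything else is ambiguous.
    """
    cfg = cfg or SexRuleConfig()
    index = gracility_index(GL, SD)
    idx = _dec(index)
    gl = _dec(GL)
    ox_lo, ox_hi = cfg.ox_gracility_range
    bull_lo, bull_hi = cfg.gracility_bull_range
    if gl > _dec(cfg.ox_gl_min) and _dec(ox_lo) <= idx <= _dec(ox_hi):
        klass = SexClass.CASTRATE_CANDIDATE
        rule = f"GL {GL} > {cfg.ox_gl_min} mm and gracility {index:.2f} in [{ox_lo}, {ox_hi}]"
    elif idx < _dec(cfg.gracility_cow_max):
        klass = SexClass.FEMALE
        rule = f"gracility {index:.2f} < {cfg.gracility_cow_max}"
    elif _dec(bull_lo) <= idx <= _dec(bull_hi):
        klass = SexClass.MALE
        rule = f"gracility {index:.2f} in [{bull_lo}, {bull_hi}]"
    else:
        klass = SexClass.AMBIGUOUS
        rule = f"gracility {index:.2f} outside all configured bands"
    return SexAssignment(specimen_id, SexMethod.GRACILITY, klass, rule)


def traction_index(e: Number, D1: Number) -> float:
    """Medial-condyle remodelling ratio e/D1 of a distal metapodial."""
    e_, d1 = float(e), float(D1)
    if e_ <= 0 or d1 <= 0:
        raise ValueError(f"e and D1 must be positive (e={e}, D1={D1})")
    return e_ / d1


def classify_traction(
    index: Number, threshold: Number = Decimal("0.75")
) -> TractionVerdict:
    """Inclusive rule: an index equal to or higher than the threshold marks
    remodelling consistent with traction."""
    if _dec(index) <= 0:
        raise ValueError(f"index must be positive (got {index})")
    if _dec(index) >= _dec(threshold):
        return TractionVerdict.TRACTION_CONSISTENT
    return TractionVerdict.NOT_INDICATED


def withers_height(
    GL: Number,
    element: Element,
    klass: SexClass,
    factors: Optional[WithersFactors] = None,
) -> float:
    """Withers height in cm from metapodial greatest length in mm."""
    factors = factors or WithersFactors()
    gl = float(GL)
    if gl <= 0:
        raise ValueError(f"GL must be positive (got {GL})")
    return gl * factors.get(element, klass) / 10.0


def _withers_interval(
    GL: float, element: Element, klass: SexClass, factors: WithersFactors
) -> tuple[float, float]:
    """Height as an interval: a point for a determined sex, the min–max over
    candidate factors when the sex is ambiguous (no factor is imposed)."""
    if klass != SexClass.AMBIGUOUS:
        h = withers_height(GL, element, klass, factors)
        return h, h
    candidates = [
        factors.factors[(element, k)]
        for k in (SexClass.FEMALE, SexClass.MALE, SexClass.CASTRATE_CANDIDATE)
        if (element, k) in factors.factors
    ]
    if not candidates:
        raise KeyError(f"no withers factor candidates for {element.value}")
    return GL * min(candidates) / 10.0, GL * max(candidates) / 10.0


def specimen_summary(
    a: Assemblage,
    cfg: Optional[SexRuleConfig] = None,
    factors: Optional[WithersFactors] = None,
    traction_threshold: Number = Decimal("0.75"),
) -> pd.DataFrame:
    """Per-metapodial synthesis: sex by both methods, GL, gracility index,
    withers height, traction index and verdict. Quantities whose inputs are
    missing stay NaN/None — nothing is imputed. Expects the sexing-analysable
    subset."""
    cfg = cfg or SexRuleConfig()
    factors = factors or WithersFactors()
    rows = []
    for s in a:
        gl = s.measurement("GL")
        sd = s.measurement("SD")
        bd = s.measurement("Bd")
        e = s.measurement("e")
        d1 = s.measurement("D1")

        sex_bd = (
            sex_by_bd(bd, cfg, s.specimen_id).klass.value
            if bd is not None and s.element == Element.METACARPAL
            else None
        )
        gracility = None
        sex_grac = None
        if gl is not None and sd is not None:
            gracility = gracility_index(gl, sd)
            sex_grac = sex_by_gracility(gl, sd, cfg, s.specimen_id).klass

        wh_low = wh_high = np.nan
        if gl is not None and sex_grac is not None:
            try:
                wh_low, wh_high = _withers_interval(gl, s.element, sex_grac, factors)
            except KeyError:
                pass

        t_index = verdict = None
        if e is not None and d1 is not None:
            t_index = traction_index(e, d1)
            verdict = classify_traction(t_index, traction_threshold).value

        rows.append(
            {
                "specimen_id": s.specimen_id,
                "element": s.element.value,
                "individual_id": s.individual_id,
                "sex_bd": sex_bd,
                "sex_gracility": sex_grac.value if sex_grac is not None else None,
                "GL_mm": gl,
                "gracility_index": gracility,
                "withers_cm_low": wh_low,
                "withers_cm_high": wh_high,
                "traction_index": t_index,
                "traction_verdict": verdict,
            }
        )
    columns = [
        "specimen_id", "element", "individual_id", "sex_bd", "sex_gracility",
        "GL_mm", "gracility_index", "withers_cm_low", "withers_cm_high",
        "traction_index", "traction_verdict",
    ]
    return pd.DataFrame(rows, columns=columns)
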