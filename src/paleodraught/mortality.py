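"""Age-at-death from mandibular tooth wear and MNI-based kill-off profiles.

Each mandible carries a Grant mandible wear stage (MWS), an ordinal score of
tooth eruption and attrition. An age-class scheme maps disjoint, contiguous
MWS ranges onto labelled age classes with absolute month bounds (the
published absolute-age classes may overlap; only the MWS ranges must be
disjoint, so age assignment is a total function on the scheme's domain).

The minimum number of individuals (MNI) per class follows the standard
side-matching convention: MNI = max(left count, right count), with
unknown-side mandibles counted only when they exceed that maximum. The
kill-off profile is the distribution of class MNIs over total MNI.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Optional, Union

import pandas as pd
import yaml

from .core import Side

__all__ = [
    "MandibleAgeRecord",
    "AgeClass",
    "AgeClassScheme",
    "assign_age_class",
    "mni_by_age_class",
    "killoff_profile",
    "KillOffProfile",
]


@dataclass(frozen=True)
class MandibleAgeRecord:
    """One mandible's wear record, ready for age-class assignment."""

    specimen_id: str
    side: Side
    mws: int
    stage_basis: str = "wear"


@dataclass(frozen=True)
class AgeClass:
    label: str
    lower_months: float
    upper_months: float
    mws_min: int
    mws_max: int

    def __post_init__(self):
        if self.mws_min > self.mws_max:
            raise ValueError(f"{self.label}: mws range inverted")
        if self.lower_months > self.upper_months:
            raise ValueError(f"{self.label}: age bounds inverted")

    def contains(self, mws: int) -> bool:
        return self.mws_min <= mws <= self.mws_max


@dataclass(frozen=True)
class AgeClassScheme:
    """Ordered age classes covering a contiguous MWS domain."""

    classes: tuple[AgeClass, ...]

    def __post_init__(self):
        if not self.classes:
            raise ValueError("scheme must contain at least one class")
        prev = None
        for c in self.classes:
            if prev is not None:
                if c.mws_min != prev.mws_max + 1:
                    raise ValueError(
                        f"MWS ranges must be disjoint and contiguous: "
                        f"{prev.label} ends at {prev.mws_max}, {c.label} starts at {c.mws_min}"
                    )
                if c.lower_months < prev.lower_months:
                    raise ValueError("age-class lower bounds must be non-decreasing")
            prev = c

    @property
    def mws_domain(self) -> tuple[int, int]:
        return self.classes[0].mws_min, self.classes[-1].mws_max

    @property
    def labels(self) -> list[str]:
        return [c.label for c in self.classes]

    def __iter__(self):
        return iter(self.classes)

    @classmethod
    def from_yaml(cls, path: Union[str, Path]) -> "AgeClassScheme":
        with open(path, "r", encoding="utf-8") as fh:
            raw = yaml.safe_load(fh)
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "AgeClassScheme":
        classes = tuple(
            AgeClass(
                label=str(c["label"]),
                lower_months=float(c["lower_months"]),
                upper_months=float(c["upper_months"]),
                mws_min=int(c["mws_min"]),
                mws_max=int(c["mws_max"]),
            )
            for c in raw["classes"]
        )
        return cls(classes=classes)


def assign_age_class(r: MandibleAgeRecord, scheme: AgeClassScheme) -> str:
    """Label of the unique class whose MWS range contains the record's MWS."""
    for c in scheme:
        if c.contains(r.mws):
            return c.label
    lo, hi = scheme.mws_domain
    raise ValueError(
        f"{r.specimen_id}: MWS {r.mws} outside scheme domain [{lo}, {hi}]"
    )


def mni_by_age_class(
    records: Iterable[MandibleAgeRecord], scheme: AgeClassScheme
) -> dict[str, int]:
    """MNI per age class from sided mandible counts.

    Per class: MNI = max(left, right); unknown-side mandibles only raise the
    count when they outnumber that side maximum (overflow rule), since fewer
    unknowns than the dominant side could all pair with it.
    """
    tallies: dict[str, dict[Side, int]] = {
        label: {Side.LEFT: 0, Side.RIGHT: 0, Side.UNKNOWN: 0} for label in scheme.labels
    }
    for r in records:
        label = assign_age_class(r, scheme)
        tallies[label][r.side] += 1
    out = {}
    for label, t in tallies.items():
        sided = max(t[Side.LEFT], t[Side.RIGHT])
        out[label] = max(sided, t[Side.UNKNOWN])
    return out


@dataclass
class KillOffProfile:
    """MNI count and proportion per age class, in scheme order."""

    labels: list[str]
    mni: list[int]
    total_mni: int

    @property
    def empty(self) -> bool:
        return self.total_mni == 0

    @property
    def proportions(self) -> list[float]:
        if self.empty:
            return [float("nan")] * len(self.mni)
        return [m / self.total_mni for m in self.mni]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"age_class": self.labels, "mni": self.mni, "proportion": self.proportions}
        )

    def proportion_of(self, label: str) -> float:
        return self.proportions[self.labels.index(label)]


def killoff_profile(
    counts: dict[str, int], scheme: Optional[AgeClassScheme] = None
) -> KillOffProfile:
    """Kill-off profile (proportions of total MNI) from per-class MNI counts.

    When a scheme is given, classes are rendered in scheme order and classes
    absent from ``counts`` appear with MNI 0.
    """
    if scheme is not None:
        labels = scheme.labels
        mni = [int(counts.get(label, 0)) for label in labels]
    else:
        labels = list(counts.keys())
        mni = [int(v) for v in counts.values()]
    if any(m < 0 for m in mni):
        raise ValueError("MNI counts must be non-negative")
    return KillOffProfile(labels=labels, mni=mni, total_mni=sum(mni))
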