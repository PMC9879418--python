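"""Core domain types for cattle-bone assemblage analysis.

A specimen is one bone record: skeletal element, body side, fore/hindlimb
(anterior/posterior) designation, distal epiphyseal fusion state, linear
measurements in mm keyed by von den Driesch codes, ordinal pathology scores
for the five draught-related foot-bone features, and — for mandibles — a
Grant mandible-wear-stage record. An assemblage is an ordered, uniquely keyed
collection of specimens from one site.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field, replace
from typing import Iterator, Mapping, Optional

__all__ = [
    "Element",
    "Limb",
    "Side",
    "Fusion",
    "OAState",
    "MEASUREMENT_CODES",
    "PATHOLOGY_FEATURES",
    "ORDINAL_FEATURES",
    "OA_FEATURES",
    "PathologyScores",
    "MandibleRecord",
    "Specimen",
    "Assemblage",
]


class _StrEnum(str, enum.Enum):
    def __str__(self) -> str:  # serialise as the bare value
        return self.value

    @classmethod
    def parse(cls, text: str):
        """Case-insensitive parse; raises ValueError naming the enum."""
        key = str(text).strip().lower()
        for member in cls:
            if member.value == key:
                return member
        raise ValueError(f"{cls.__name__}: unknown value {text!r}")


class Element(_StrEnum):
    PHALANX1 = "phalanx1"
    PHALANX2 = "phalanx2"
    PHALANX3 = "phalanx3"
    METACARPAL = "metacarpal"
    METATARSAL = "metatarsal"
    MANDIBLE = "mandible"
    OTHER = "other"


METAPODIALS = (Element.METACARPAL, Element.METATARSAL)


class Limb(_StrEnum):
    ANTERIOR = "anterior"
    POSTERIOR = "posterior"
    UNKNOWN = "unknown"


class Side(_StrEnum):
    LEFT = "left"
    RIGHT = "right"
    UNKNOWN = "unknown"


class Fusion(_StrEnum):
    FUSED = "fused"
    UNFUSED = "unfused"
    UNKNOWN = "unknown"


class OAState(_StrEnum):
    """Osteoarthritis on an articular surface, recorded present/absent."""

    ABSENT = "absent"
    PRESENT = "present"


#: Closed set of accepted von den Driesch-style measurement codes (all mm):
#: GL greatest length, SD smallest diaphysis breadth, Bd distal breadth,
#: e and D1 the distal medial-condyle dimensions of the traction index.
MEASUREMENT_CODES = ("GL", "SD", "Bd", "e", "D1")

ORDINAL_FEATURES = ("pex", "dex", "plip")
OA_FEATURES = ("oa_prox", "oa_dist")
PATHOLOGY_FEATURES = ORDINAL_FEATURES + OA_FEATURES


@dataclass(frozen=True)
class PathologyScores:
    """Scores for the five draught-related foot-bone features.

    ``pex`` (proximal exostosis), ``dex`` (distal exostosis) and ``plip``
    (proximal lipping) are ordinal 1–4, where 1 means no pathology.
    Osteoarthritis on the proximal/distal articular surface is present/absent.
    Any field may be None (not recorded).
    """

    pex: Optional[int] = None
    dex: Optional[int] = None
    plip: Optional[int] = None
    oa_prox: Optional[OAState] = None
    oa_dist: Optional[OAState] = None

    def get(self, feature: str):
        if feature not in PATHOLOGY_FEATURES:
            raise KeyError(f"unknown pathology feature {feature!r}")
        return getattr(self, feature)

    @property
    def complete(self) -> bool:
        return all(self.get(f) is not None for f in PATHOLOGY_FEATURES)

    def violations(self) -> list[str]:
        out = []
        for f in ORDINAL_FEATURES:
            v = self.get(f)
            if v is not None and v not in (1, 2, 3, 4):
                out.append(f"{f}: score outside 1-4 (got {v})")
        return out


@dataclass(frozen=True)
class MandibleRecord:
    """Mandibular tooth eruption/wear record (Grant mandible wear stage)."""

    mws: int
    stage_basis: str = "wear"  # "wear" or "eruption"

    def __post_init__(self):
        if self.stage_basis not in ("wear", "eruption"):
            raise ValueError(f"stage_basis must be wear/eruption, got {self.stage_basis!r}")


@dataclass(frozen=True)
class Specimen:
    specimen_id: str
    element: Element
    limb: Limb = Limb.UNKNOWN
    side: Side = Side.UNKNOWN
    distal_fusion: Fusion = Fusion.UNKNOWN
    measurements: Mapping[str, float] = field(default_factory=dict)
    pathology: Optional[PathologyScores] = None
    mandible_wear: Optional[MandibleRecord] = None
    individual_id: Optional[str] = None

    def __post_init__(self):
        if not self.specimen_id:
            raise ValueError("specimen_id must be non-empty")
        for code, value in self.measurements.items():
            if code not in MEASUREMENT_CODES:
                raise ValueError(
                    f"{self.specimen_id}: unknown measurement code {code!r} "
                    f"(accepted: {', '.join(MEASUREMENT_CODES)})"
                )
            if not value > 0:
                raise ValueError(
                    f"{self.specimen_id}: non-positive measurement {code}={value}"
                )

    def measurement(self, code: str) -> Optional[float]:
        return self.measurements.get(code)

    def replace(self, **changes) -> "Specimen":
        return replace(self, **changes)


@dataclass
class Assemblage:
    """A validated collection of specimens with provenance metadata."""

    specimens: list[Specimen]
    site_name: str = ""
    notes: str = ""

    def __post_init__(self):
        seen: dict[str, int] = {}
        for s in self.specimens:
            seen[s.specimen_id] = seen.get(s.specimen_id, 0) + 1
        dups = sorted(k for k, n in seen.items() if n > 1)
        if dups:
            raise ValueError(f"duplicate specimen_id in assemblage: {dups}")

    def __len__(self) -> int:
        return len(self.specimens)

    def __iter__(self) -> Iterator[Specimen]:
        return iter(self.specimens)

    def subset(self, specimens: list[Specimen], note: str = "") -> "Assemblage":
        return Assemblage(
            specimens=list(specimens),
            site_name=self.site_name,
            notes=(self.notes + ("; " if self.notes and note else "") + note),
        )

    def by_element(self, *elements: Element) -> list[Specimen]:
        return [s for s in self.specimens if s.element in elements]
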