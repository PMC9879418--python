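"""Reading, writing, validation and subsetting of specimen tables.

The canonical table layout is one wide row per specimen with the header

    specimen_id, element, limb, side, distal_fusion, individual_id,
    GL, SD, Bd, e, D1, pex, dex, plip, oa_prox, oa_dist, mws

Delimiter (comma or tab) is auto-detected from the header line. A
``column_map`` argument lets a caller rename whatever layout their source
table uses onto this schema. Rows that fail type coercion are collected into
a row-error report rather than silently dropped; structural problems
(missing mandatory columns, duplicate ids, unknown columns) are hard errors.
"""

from __future__ import annotations

import dataclasses
import enum
import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Union

import pandas as pd

from .core import (
    MEASUREMENT_CODES,
    METAPODIALS,
    OA_FEATURES,
    ORDINAL_FEATURES,
    Assemblage,
    Element,
    Fusion,
    Limb,
    MandibleRecord,
    OAState,
    PathologyScores,
    Side,
    Specimen,
)

__all__ = [
    "COLUMNS",
    "Analysis",
    "RowError",
    "ValidationFinding",
    "ValidationReport",
    "assemblage_from_dataframe",
    "read_assemblage",
    "write_assemblage",
    "validate_assemblage",
    "select_analysable",
]

META_COLUMNS = ("specimen_id", "element", "limb", "side", "distal_fusion", "individual_id")
SCORE_COLUMNS = ORDINAL_FEATURES + OA_FEATURES
COLUMNS = META_COLUMNS + MEASUREMENT_CODES + SCORE_COLUMNS + ("mws",)
MANDATORY = ("specimen_id", "element")


class Analysis(str, enum.Enum):
    """Analysable-subset selectors for the downstream stages."""

    PHALANX_INDEX = "phalanx_index"
    METAPODIAL_INDEX = "metapodial_index"
    SEXING = "sexing"
    MORTALITY = "mortality"


@dataclass(frozen=True)
class RowError:
    row: int  # 0-based data-row index
    specimen_id: str
    reason: str


@dataclass(frozen=True)
class ValidationFinding:
    specimen_id: str
    severity: str  # "error" or "warning"
    message: str


@dataclass
class ValidationReport:
    findings: list[ValidationFinding] = field(default_factory=list)

    def __bool__(self) -> bool:
        return bool(self.findings)

    @property
    def empty(self) -> bool:
        return not self.findings

    def errors(self) -> list[ValidationFinding]:
        return [f for f in self.findings if f.severity == "error"]

    def to_json(self) -> str:
        return json.dumps(
            [dataclasses.asdict(f) for f in self.findings], indent=2, sort_keys=True
        )


def _is_missing(value) -> bool:
    if value is None:
        return True
    if isinstance(value, float) and math.isnan(value):
        return True
    return str(value).strip().lower() in ("", "nan", "none")


def _detect_delimiter(header_line: str) -> str:
    if "\t" in header_line:
        return "\t"
    return ","


def _parse_row(row: pd.Series, idx: int) -> Specimen:
    element = Element.parse(row["element"])
    limb = Limb.parse(row["limb"]) if not _is_missing(row.get("limb")) else Limb.UNKNOWN
    side = Side.parse(row["side"]) if not _is_missing(row.get("side")) else Side.UNKNOWN
    fusion = (
        Fusion.parse(row["distal_fusion"])
        if not _is_missing(row.get("distal_fusion"))
        else Fusion.UNKNOWN
    )

    measurements = {}
    for code in MEASUREMENT_CODES:
        raw = row.get(code)
        if _is_missing(raw):
            continue
        value = float(raw)
        if not value > 0:
            raise ValueError(f"non-positive measurement {code}={raw}")
        measurements[code] = value

    scores = {}
    for feat in ORDINAL_FEATURES:
        raw = row.get(feat)
        if _is_missing(raw):
            continue
        value = int(float(raw))
        if value not in (1, 2, 3, 4):
            raise ValueError(f"{feat} score outside 1-4 (got {raw})")
        scores[feat] = value
    for feat in OA_FEATURES:
        raw = row.get(feat)
        if _is_missing(raw):
            continue
        scores[feat] = OAState.parse(raw)
    pathology = PathologyScores(**scores) if scores else None

    mandible = None
    if not _is_missing(row.get("mws")):
        mandible = MandibleRecord(mws=int(float(row["mws"])))

    return Specimen(
        specimen_id=str(row["specimen_id"]).strip(),
        element=element,
        limb=limb,
        side=side,
        distal_fusion=fusion,
        measurements=measurements,
        pathology=pathology,
        mandible_wear=mandible,
        individual_id=None
        if _is_missing(row.get("individual_id"))
        else str(row["individual_id"]).strip(),
    )


def assemblage_from_dataframe(
    df: pd.DataFrame,
    column_map: Optional[dict[str, str]] = None,
    site_name: str = "",
    source: str = "dataframe",
) -> tuple[Assemblage, list[RowError]]:
    """Build an :class:`Assemblage` from a table in the canonical schema.

    Returns ``(assemblage, row_errors)``: rows failing type coercion are
    reported, never silently dropped. Missing mandatory columns, unknown
    columns and duplicate specimen ids are hard failures.
    """
    if column_map:
        df = df.rename(columns=column_map)

    missing = [c for c in MANDATORY if c not in df.columns]
    if missing:
        raise ValueError(f"{source}: missing mandatory columns: {missing}")
    unknown = [c for c in df.columns if c not in COLUMNS]
    if unknown:
        raise ValueError(
            f"{source}: unknown columns {unknown}; accepted columns are "
            f"{list(COLUMNS)} (use column_map to rename)"
        )

    ids = df["specimen_id"].astype(str).str.strip()
    dup = sorted(ids[ids.duplicated()].unique().tolist())
    if dup:
        raise ValueError(f"{source}: duplicate specimen_id: {dup}")

    specimens: list[Specimen] = []
    errors: list[RowError] = []
    for pos, (idx, row) in enumerate(df.iterrows()):
        try:
            specimens.append(_parse_row(row, pos))
        except (ValueError, KeyError) as exc:
            errors.append(
                RowError(row=pos, specimen_id=str(row.get("specimen_id", "?")), reason=str(exc))
            )
    return Assemblage(specimens=specimens, site_name=site_name), errors


def read_assemblage(
    path: Union[str, Path],
    column_map: Optional[dict[str, str]] = None,
    site_name: str = "",
) -> tuple[Assemblage, list[RowError]]:
    """Read a specimen table (CSV or TSV, auto-detected) into an
    :class:`Assemblage`; see :func:`assemblage_from_dataframe` for the
    error contract."""
    path = Path(path)
    with open(path, "r", encoding="utf-8") as fh:
        header_line = fh.readline()
    sep = _detect_delimiter(header_line)
    df = pd.read_csv(path, sep=sep, dtype=str, keep_default_na=False)
    return assemblage_from_dataframe(
        df, column_map=column_map, site_name=site_name or path.stem, source=path.name
    )


def _fmt_num(value: Optional[float]) -> str:
    if value is None:
        return ""
    # shortest round-tripping decimal form; integers without trailing .0
    if float(value) == int(value):
        return str(int(value))
    return repr(float(value))


def write_assemblage(assemblage: Assemblage, path: Union[str, Path], sep: str = ",") -> None:
    """Write the canonical wide-table form (stable column order and number
    formatting, so read-write-read is the identity on canonical files)."""
    rows = []
    for s in assemblage:
        row = {
            "specimen_id": s.specimen_id,
            "element": s.element.value,
            "limb": s.limb.value,
            "side": s.side.value,
            "distal_fusion": s.distal_fusion.value,
            "individual_id": s.individual_id or "",
        }
        for code in MEASUREMENT_CODES:
            row[code] = _fmt_num(s.measurements.get(code))
        for feat in ORDINAL_FEATURES:
            v = s.pathology.get(feat) if s.pathology else None
            row[feat] = "" if v is None else str(v)
        for feat in OA_FEATURES:
            v = s.pathology.get(feat) if s.pathology else None
            row[feat] = "" if v is None else v.value
        row["mws"] = str(s.mandible_wear.mws) if s.mandible_wear else ""
        rows.append(row)
    df = pd.DataFrame(rows, columns=list(COLUMNS))
    df.to_csv(path, sep=sep, index=False, lineterminator="\n")


def validate_assemblage(a: Assemblage) -> ValidationReport:
    """Check typed invariants specimen by specimen. Never raises; an empty
    report means every invariant holds."""
    report = ValidationReport()

    def add(sid: str, severity: str, message: str) -> None:
        report.findings.append(ValidationFinding(sid, severity, message))

    for s in a:
        if s.pathology is not None:
            for msg in s.pathology.violations():
                add(s.specimen_id, "error", msg)
            if s.element == Element.PHALANX1 and s.limb == Limb.UNKNOWN:
                add(s.specimen_id, "error", "limb unknown on a first phalanx with pathology scores")
        if s.element in METAPODIALS:
            if s.measurement("Bd") is not None and s.distal_fusion == Fusion.UNFUSED:
                add(s.specimen_id, "warning", "distal measurement on unfused element")
        if s.element == Element.MANDIBLE and s.mandible_wear is None:
            add(s.specimen_id, "error", "mandible row without tooth-wear record")
        if s.element != Element.MANDIBLE and s.mandible_wear is not None:
            add(s.specimen_id, "error", "tooth-wear record on a postcranial element")
    return report


def _one_per_limb_per_individual(specimens: list[Specimen]) -> list[Specimen]:
    """Keep at most one anterior and one posterior phalanx per individual
    (lowest specimen_id wins); specimens without individual_id are all kept."""
    chosen: dict[tuple[str, Limb], Specimen] = {}
    loose: list[Specimen] = []
    for s in sorted(specimens, key=lambda s: s.specimen_id):
        if s.individual_id is None:
            loose.append(s)
            continue
        key = (s.individual_id, s.limb)
        if key not in chosen:
            chosen[key] = s
    keep = set(id(s) for s in chosen.values()) | set(id(s) for s in loose)
    return [s for s in specimens if id(s) in keep]


def select_analysable(a: Assemblage, analysis: Union[Analysis, str]) -> Assemblage:
    """Select the subset of specimens usable for a downstream analysis.

    - PHALANX_INDEX: first phalanges with complete pathology scores and a
      known anterior/posterior designation; at most one phalanx per limb per
      individual when individuals are linked.
    - METAPODIAL_INDEX: distally fused metapodials carrying both condyle
      measurements (e and D1).
    - SEXING: distally fused metapodials with Bd, or with GL and SD.
    - MORTALITY: mandibles with a tooth-wear record.
    """
    if isinstance(analysis, str):
        try:
            analysis = Analysis(analysis.lower())
        except ValueError:
            raise ValueError(f"unknown analysis label {analysis!r}") from None

    if analysis == Analysis.PHALANX_INDEX:
        keep = [
            s
            for s in a
            if s.element == Element.PHALANX1
            and s.pathology is not None
            and s.pathology.complete
            and s.limb != Limb.UNKNOWN
        ]
        keep = _one_per_limb_per_individual(keep)
    elif analysis == Analysis.METAPODIAL_INDEX:
        keep = [
            s
            for s in a
            if s.element in METAPODIALS
            and s.distal_fusion == Fusion.FUSED
            and s.measurement("e") is not None
            and s.measurement("D1") is not None
        ]
    elif analysis == Analysis.SEXING:
        keep = [
            s
            for s in a
            if s.element in METAPODIALS
            and s.distal_fusion == Fusion.FUSED
            and (
                s.measurement("Bd") is not None
                or (s.measurement("GL") is not None and s.measurement("SD") is not None)
            )
        ]
    else:  # MORTALITY
        keep = [s for s in a if s.element == Element.MANDIBLE and s.mandible_wear is not None]

    return a.subset(keep, note=f"selected:{analysis.value}")
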