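"""Model/results interface tying the analysis stages together.

:class:`TractionAnalysis` is built from an assemblage (or a CSV/TSV table,
or a pandas DataFrame in the canonical schema) plus an
:class:`~paleodraught.config.AnalysisConfig`. Its :meth:`~TractionAnalysis.fit`
runs every stage whose inputs are present — pathology indices and hindlimb
bias on first phalanges, traction classification, osteometric sexing and
withers heights on metapodials, the MNI kill-off profile on mandibles, and
the reference-herd comparison — and returns a :class:`TractionResults`
carrying the estimates, their uncertainties and a ``summary()`` table.
Stages degrade gracefully: a missing input marks its section unavailable
rather than failing the fit.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Union

import numpy as np
import pandas as pd

from . import __version__
from .config import AnalysisConfig
from .core import Assemblage, Element, Limb, Side
from .io import (
    Analysis,
    RowError,
    ValidationReport,
    assemblage_from_dataframe,
    read_assemblage,
    select_analysable,
    validate_assemblage,
)
from .mortality import (
    KillOffProfile,
    MandibleAgeRecord,
    killoff_profile,
    mni_by_age_class,
)
from .osteometry import (
    classify_traction,
    sex_by_bd,
    sex_by_gracility,
    specimen_summary,
    traction_index,
)
from .pathology import (
    IndexSummary,
    LimbBias,
    compare_reference,
    index_summary,
    limb_bias,
    stage_distribution,
)

__all__ = ["TractionAnalysis", "TractionResults", "run_analysis"]


def _df_records(df: Optional[pd.DataFrame]):
    if df is None:
        return None
    clean = df.replace({np.nan: None})
    return clean.to_dict(orient="records")


@dataclass
class TractionResults:
    """Fitted results of a :class:`TractionAnalysis`.

    Sections that could not be computed (missing inputs) are None, with the
    reason recorded in ``unavailable``.
    """

    model: "TractionAnalysis"
    validation: ValidationReport
    index_summary: Optional[IndexSummary]
    stage_distributions: Optional[pd.DataFrame]
    limb_bias: Optional[LimbBias]
    traction_table: Optional[pd.DataFrame]
    sex_assignments: Optional[pd.DataFrame]
    synthesis_table: Optional[pd.DataFrame]
    killoff: Optional[KillOffProfile]
    mandible_mni: Optional[int]
    element_mni: Optional[int]
    reference_comparison: Optional[pd.DataFrame]
    unavailable: dict[str, str] = field(default_factory=dict)
    metadata: dict = field(default_factory=dict)

    # -- presentation ------------------------------------------------------

    def summary(self) -> str:
        lines = []
        meta = self.metadata
        lines.append("Draught-cattle osteological analysis")
        lines.append("=" * 68)
        lines.append(f"Site: {meta.get('site_name', '')!s:<30} Specimens: {meta.get('n_specimens', 0)}")
        lines.append(
            f"Seed: {meta.get('seed')}   Config hash: {meta.get('config_hash')}   "
            f"paleodraught {meta.get('version')}"
        )
        lines.append("")
        if self.index_summary is not None:
            s = self.index_summary
            lines.append("Pathological index on first phalanges")
            lines.append("-" * 68)
            lines.append(f"{'limb':<12}{'n':>5}{'mean PI':>12}{'mean MPI':>12}")
            lines.append(f"{'anterior':<12}{s.n_anterior:>5}{s.mean_pi_anterior:>12.3f}{s.mean_mpi_anterior:>12.3f}")
            lines.append(f"{'posterior':<12}{s.n_posterior:>5}{s.mean_pi_posterior:>12.3f}{s.mean_mpi_posterior:>12.3f}")
        if self.limb_bias is not None:
            b = self.limb_bias
            flag = "excludes 0" if b.excludes_zero else "includes 0"
            lines.append(
                f"Hindlimb MPI bias (post - ant): {b.difference:+.4f}  "
                f"{int(b.level * 100)}% CI [{b.ci_low:+.4f}, {b.ci_high:+.4f}] ({flag}; "
                f"{b.n_boot} bootstrap replicates)"
            )
        if self.traction_table is not None and len(self.traction_table):
            n_pos = int((self.traction_table["verdict"] == "traction_consistent").sum())
            lines.append("")
            lines.append(
                f"Traction index e/D1 on {len(self.traction_table)} fused metapodials: "
                f"{n_pos} at or above threshold"
            )
        if self.synthesis_table is not None and len(self.synthesis_table):
            counts = self.synthesis_table["sex_gracility"].value_counts(dropna=True).to_dict()
            lines.append(f"Sexing (gracility method): {counts}")
            hi = self.synthesis_table["withers_cm_high"].max()
            lo = self.synthesis_table["withers_cm_low"].min()
            if not (pd.isna(lo) or pd.isna(hi)):
                lines.append(f"Withers height range: {lo:.1f}-{hi:.1f} cm")
        if self.killoff is not None and not self.killoff.empty:
            lines.append("")
            lines.append(f"Kill-off profile (mandible MNI = {self.killoff.total_mni}; "
                         f"element-based MNI = {self.element_mni})")
            lines.append("-" * 68)
            for label, mni, prop in zip(
                self.killoff.labels, self.killoff.mni, self.killoff.proportions
            ):
                lines.append(f"{label:<12}{mni:>5}{prop:>10.1%}")
        for section, reason in sorted(self.unavailable.items()):
            lines.append(f"[section unavailable] {section}: {reason}")
        return "\n".join(lines)

    def to_json_dict(self) -> dict:
        b = self.limb_bias
        out = {
            "metadata": self.metadata,
            "validation_findings": [dataclasses.asdict(f) for f in self.validation.findings],
            "index_summary": None
            if self.index_summary is None
            else {
                k: (None if isinstance(v, float) and math.isnan(v) else v)
                for k, v in dataclasses.asdict(self.index_summary).items()
            },
            "stage_distributions": _df_records(self.stage_distributions),
            "limb_bias": None
            if b is None
            else {
                "difference": b.difference,
                "ci_low": b.ci_low,
                "ci_high": b.ci_high,
                "excludes_zero": b.excludes_zero,
                "n_anterior": b.n_anterior,
                "n_posterior": b.n_posterior,
                "n_boot": b.n_boot,
                "seed": b.seed,
                "level": b.level,
            },
            "traction": _df_records(self.traction_table),
            "sex_assignments": _df_records(self.sex_assignments),
            "synthesis": _df_records(self.synthesis_table),
            "killoff": None
            if self.killoff is None
            else {
                "age_classes": self.killoff.labels,
                "mni": self.killoff.mni,
                "proportions": None if self.killoff.empty else self.killoff.proportions,
                "total_mni": self.killoff.total_mni,
                "element_based_mni": self.element_mni,
            },
            "reference_comparison": _df_records(self.reference_comparison),
            "unavailable": self.unavailable,
        }
        return out

    def to_json(self) -> str:
        return json.dumps(self.to_json_dict(), indent=2, sort_keys=True)

    def save(self, outdir: Union[str, Path]) -> Path:
        """Write the bundle: CSV tables, one JSON summary and a readable
        report. Returns the output directory."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        for name, df in (
            ("stage_distributions", self.stage_distributions),
            ("traction", self.traction_table),
            ("sex_assignments", self.sex_assignments),
            ("synthesis", self.synthesis_table),
            ("reference_comparison", self.reference_comparison),
        ):
            if df is not None:
                df.to_csv(outdir / f"{name}.csv", index=False, lineterminator="\n")
        if self.index_summary is not None:
            self.index_summary.to_frame().to_csv(
                outdir / "index_summary.csv", index=False, lineterminator="\n"
            )
        if self.killoff is not None:
            self.killoff.to_frame().to_csv(
                outdir / "killoff.csv", index=False, lineterminator="\n"
            )
        (outdir / "summary.json").write_text(self.to_json() + "\n", encoding="utf-8")
        (outdir / "report.txt").write_text(self.summary() + "\n", encoding="utf-8")
        return outdir


class TractionAnalysis:
    """Osteological draught-cattle analysis of one assemblage."""

    def __init__(self, assemblage: Assemblage, config: Optional[AnalysisConfig] = None):
        self.assemblage = assemblage
        self.config = config or AnalysisConfig()
        self.row_errors: list[RowError] = []

    # -- constructors ------------------------------------------------------

    @classmethod
    def from_csv(
        cls,
        path: Union[str, Path],
        config: Optional[AnalysisConfig] = None,
        column_map: Optional[dict[str, str]] = None,
    ) -> "TractionAnalysis":
        assemblage, errors = read_assemblage(path, column_map=column_map)
        model = cls(assemblage, config)
        model.row_errors = errors
        return model

    @classmethod
    def from_dataframe(
        cls, df: pd.DataFrame, config: Optional[AnalysisConfig] = None, site_name: str = ""
    ) -> "TractionAnalysis":
        assemblage, errors = assemblage_from_dataframe(df, site_name=site_name or "dataframe")
        model = cls(assemblage, config)
        model.row_errors = errors
        return model

    # -- fitting -----------------------------------------------------------

    def fit(self, seed: Optional[int] = None, n_boot: Optional[int] = None) -> TractionResults:
        cfg = self.config
        seed = cfg.seed if seed is None else int(seed)
        n_boot = cfg.n_boot if n_boot is None else int(n_boot)
        a = self.assemblage
        unavailable: dict[str, str] = {}

        validation = validate_assemblage(a)

        # pathology on first phalanges
        phal = select_analysable(a, Analysis.PHALANX_INDEX)
        if len(phal):
            idx_summary = index_summary(phal, cfg.formula)
            dists = []
            for feature in ("pex", "dex", "plip"):
                for limb in (Limb.ANTERIOR, Limb.POSTERIOR, None):
                    d = stage_distribution(phal, feature, limb)
                    for stage, count in d.counts.items():
                        dists.append(
                            {
                                "feature": feature,
                                "limb": d.limb,
                                "stage": stage,
                                "count": count,
                                "frequency": None if d.total == 0 else count / d.total,
                            }
                        )
            stage_df = pd.DataFrame(dists)
            if idx_summary.n_anterior > 0 and idx_summary.n_posterior > 0:
                bias = limb_bias(phal, cfg.formula, n_boot=n_boot, seed=seed, level=cfg.boot_level)
            else:
                bias = None
                unavailable["limb_bias"] = "one limb has no analysable phalanges"
            refcmp = compare_reference(
                idx_summary, cfg.references, query_name=a.site_name or "query"
            )
        else:
            idx_summary = stage_df = bias = refcmp = None
            unavailable["pathology_index"] = "no analysable first phalanges"

        # metapodial osteometrics
        sexing = select_analysable(a, Analysis.SEXING)
        if len(sexing):
            synthesis = specimen_summary(
                sexing, cfg.sex_rules, cfg.withers_factors, cfg.traction_threshold
            )
            sex_rows = []
            for s in sexing:
                bd = s.measurement("Bd")
                if bd is not None and s.element == Element.METACARPAL:
                    sex_rows.append(dataclasses.asdict(sex_by_bd(bd, cfg.sex_rules, s.specimen_id)))
                gl, sd = s.measurement("GL"), s.measurement("SD")
                if gl is not None and sd is not None:
                    sex_rows.append(
                        dataclasses.asdict(sex_by_gracility(gl, sd, cfg.sex_rules, s.specimen_id))
                    )
            sex_df = pd.DataFrame(sex_rows)
            if len(sex_df):
                sex_df["method"] = sex_df["method"].map(lambda m: m.value)
                sex_df["klass"] = sex_df["klass"].map(lambda k: k.value)
        else:
            synthesis = sex_df = None
            unavailable["sexing"] = "no fused metapodials with the required measurements"

        metap = select_analysable(a, Analysis.METAPODIAL_INDEX)
        if len(metap):
            t_rows = []
            for s in metap:
                idx = traction_index(s.measurement("e"), s.measurement("D1"))
                t_rows.append(
                    {
                        "specimen_id": s.specimen_id,
                        "element": s.element.value,
                        "e_mm": s.measurement("e"),
                        "D1_mm": s.measurement("D1"),
                        "index": idx,
                        "verdict": classify_traction(idx, cfg.traction_threshold).value,
                    }
                )
            traction_df = pd.DataFrame(t_rows)
        else:
            traction_df = None
            unavailable["traction_index"] = "no fused metapodials with e and D1"

        # mortality
        mand = select_analysable(a, Analysis.MORTALITY)
        if len(mand):
            records = [
                MandibleAgeRecord(
                    specimen_id=s.specimen_id, side=s.side, mws=s.mandible_wear.mws
                )
                for s in mand
            ]
            counts = mni_by_age_class(records, cfg.scheme)
            killoff = killoff_profile(counts, cfg.scheme)
            mandible_mni = killoff.total_mni
        else:
            killoff = mandible_mni = None
            unavailable["killoff"] = "no mandibles with tooth-wear records"

        element_mni = self._element_mni(a)

        metadata = {
            "site_name": a.site_name,
            "n_specimens": len(a),
            "n_row_errors": len(self.row_errors),
            "seed": seed,
            "n_boot": n_boot,
            "config_hash": cfg.config_hash(),
            "version": __version__,
        }

        return TractionResults(
            model=self,
            validation=validation,
            index_summary=idx_summary,
            stage_distributions=stage_df,
            limb_bias=bias,
            traction_table=traction_df,
            sex_assignments=sex_df,
            synthesis_table=synthesis,
            killoff=killoff,
            mandible_mni=mandible_mni,
            element_mni=element_mni,
            reference_comparison=refcmp,
            unavailable=unavailable,
            metadata=metadata,
        )

    @staticmethod
    def _element_mni(a: Assemblage) -> int:
        """Element-based MNI: the most demanding single element type.

        Sided elements use max(left, right, unknown); first phalanges, of
        which a skeleton has eight, use ceil(count / 8)."""
        best = 0
        for element in (Element.METACARPAL, Element.METATARSAL, Element.MANDIBLE):
            tally = {Side.LEFT: 0, Side.RIGHT: 0, Side.UNKNOWN: 0}
            for s in a.by_element(element):
                tally[s.side] += 1
            best = max(best, max(tally[Side.LEFT], tally[Side.RIGHT]), tally[Side.UNKNOWN])
        n_ph1 = len(a.by_element(Element.PHALANX1))
        best = max(best, math.ceil(n_ph1 / 8))
        return best


def run_analysis(
    assemblage_path: Union[str, Path],
    config_path: Optional[Union[str, Path]] = None,
    outdir: Optional[Union[str, Path]] = None,
    seed: Optional[int] = None,
) -> TractionResults:
    """Load, validate, fit and (optionally) write the full report bundle."""
    config = AnalysisConfig.from_yaml(config_path)
    model = TractionAnalysis.from_csv(assemblage_path, config=config)
    results = model.fit(seed=seed)
    if outdir is not None:
        results.save(outdir)
    return results
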