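"""End-to-end parameter recovery on synthetic assemblages.

Given a generated assemblage and its ground-truth herd table, classify each
individual as worked/unworked from the bones alone (any fused metapodial
with a traction-consistent e/D1) and compare with the truth: the recovered
worked fraction among osteometrically male/castrate individuals estimates
the generator's ``traction_fraction``, and sensitivity/specificity measure
how cleanly the e/D1 rule separates the two cohorts.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import pandas as pd

from .config import AnalysisConfig
from .core import Assemblage
from .io import Analysis, select_analysable
from .osteometry import SexClass, specimen_summary

__all__ = ["RecoveryResult", "recover_worked_fraction"]

_ELIGIBLE = (SexClass.MALE.value, SexClass.CASTRATE_CANDIDATE.value)


@dataclass(frozen=True)
class RecoveryResult:
    estimated_worked_fraction: float
    true_worked_fraction: float
    sensitivity: float
    specificity: float
    n_eligible: int
    n_classified: int


def recover_worked_fraction(
    assemblage: Assemblage,
    truth: pd.DataFrame,
    config: Optional[AnalysisConfig] = None,
    adult_min_months: float = 30.0,
) -> RecoveryResult:
    cfg = config or AnalysisConfig()
    sexing = select_analysable(assemblage, Analysis.SEXING)
    table = specimen_summary(sexing, cfg.sex_rules, cfg.withers_factors, cfg.traction_threshold)
    if not len(table):
        raise ValueError("no fused metapodials to classify")

    per_ind = table.dropna(subset=["individual_id"]).groupby("individual_id").agg(
        flagged=("traction_verdict", lambda v: bool((v == "traction_consistent").any())),
        any_classified=("traction_verdict", lambda v: bool(v.notna().any())),
        sexed_eligible=("sex_gracility", lambda v: bool(v.isin(_ELIGIBLE).any())),
    )

    eligible = per_ind[per_ind["sexed_eligible"]]
    n_eligible = len(eligible)
    est = float(eligible["flagged"].mean()) if n_eligible else float("nan")

    merged = per_ind[per_ind["any_classified"]].merge(
        truth.set_index("individual_id")[["worked"]], left_index=True, right_index=True
    )
    worked = merged[merged["worked"]]
    unworked = merged[~merged["worked"]]
    sens = float(worked["flagged"].mean()) if len(worked) else float("nan")
    spec = float((~unworked["flagged"]).mean()) if len(unworked) else float("nan")

    adults = truth[truth["age_months"] >= adult_min_months]
    elig_true = adults[adults["sex"].isin(("bull", "castrate"))]
    true_frac = float(elig_true["worked"].mean()) if len(elig_true) else float("nan")

    return RecoveryResult(
        estimated_worked_fraction=est,
        true_worked_fraction=true_frac,
        sensitivity=sens,
        specificity=spec,
        n_eligible=n_eligible,
        n_classified=int(len(merged)),
    )
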