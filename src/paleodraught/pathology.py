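"""Ordinal pathology scoring and the pathological index on first phalanges.

Five draught-related features are scored on each first phalanx: proximal
exostosis (pex), distal exostosis (dex) and proximal lipping (plip) on an
ordinal 1–4 scale (1 = no pathology), and osteoarthritis on the proximal and
distal articular surfaces recorded present/absent. The pathological index
(PI) condenses the five scores into a unit-interval severity; the modified
pathological index (MPI) omits distal exostosis because that feature tracks
the animal's age rather than its workload.

The default closed form is the normalised sum

    PI = sum_f (score_f - 1) / sum_f (max_f - 1)

over the included features, with osteoarthritis coded absent→1 / present→2 so
that more pathology always raises the index; a per-feature mean variant is
selectable. Both are 0 for a pathology-free bone and 1 at maximal scores.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field, replace
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

from .core import (
    OA_FEATURES,
    PATHOLOGY_FEATURES,
    Assemblage,
    Limb,
    OAState,
    PathologyScores,
)

__all__ = [
    "IndexVariant",
    "IndexFormula",
    "pathological_index",
    "modified_pathological_index",
    "StageDistribution",
    "stage_distribution",
    "IndexSummary",
    "index_summary",
    "LimbBias",
    "limb_bias",
    "ReferencePopulation",
    "compare_reference",
]


class IndexVariant(str, enum.Enum):
    NORMALISED_SUM = "normalised_sum"
    FEATURE_MEAN = "feature_mean"


_DEFAULT_MAX = {"pex": 4, "dex": 4, "plip": 4, "oa_prox": 2, "oa_dist": 2}


@dataclass(frozen=True)
class IndexFormula:
    """Configuration of the pathological-index computation.

    ``oa_present_is_high`` keeps the index monotone in pathology (absent→1,
    present→2). Flipping it reproduces the literal historical coding in which
    presence is written as score 1.
    """

    variant: IndexVariant = IndexVariant.NORMALISED_SUM
    included_features: tuple[str, ...] = PATHOLOGY_FEATURES
    feature_max: dict[str, int] = field(default_factory=lambda: dict(_DEFAULT_MAX))
    oa_present_is_high: bool = True

    def __post_init__(self):
        if not self.included_features:
            raise ValueError("included_features must be non-empty")
        unknown = [f for f in self.included_features if f not in PATHOLOGY_FEATURES]
        if unknown:
            raise ValueError(f"unknown features {unknown}")
        for f in self.included_features:
            if self.feature_max.get(f, 0) < 2:
                raise ValueError(f"feature_max[{f!r}] must be >= 2")

    def without(self, *features: str) -> "IndexFormula":
        kept = tuple(f for f in self.included_features if f not in features)
        return replace(self, included_features=kept)

    @classmethod
    def pathological(cls, variant: IndexVariant = IndexVariant.NORMALISED_SUM) -> "IndexFormula":
        """The five-feature pathological index."""
        return cls(variant=variant)

    @classmethod
    def modified(cls, variant: IndexVariant = IndexVariant.NORMALISED_SUM) -> "IndexFormula":
        """The modified index: distal exostosis (age-linked) omitted."""
        return cls(variant=variant).without("dex")


def _numeric_score(s: PathologyScores, feature: str, formula: IndexFormula) -> int:
    value = s.get(feature)
    if value is None:
        raise ValueError(f"missing score for included feature {feature!r}")
    if feature in OA_FEATURES:
        if formula.oa_present_is_high:
            return 2 if value == OAState.PRESENT else 1
        return 1 if value == OAState.PRESENT else 2
    return int(value)


def pathological_index(s: PathologyScores, f: Optional[IndexFormula] = None) -> float:
    """Unit-interval pathology severity of one phalanx under formula ``f``."""
    f = f or IndexFormula.pathological()
    if f.variant == IndexVariant.NORMALISED_SUM:
        num = sum(_numeric_score(s, feat, f) - 1 for feat in f.included_features)
        den = sum(f.feature_max[feat] - 1 for feat in f.included_features)
        return num / den
    parts = [
        (_numeric_score(s, feat, f) - 1) / (f.feature_max[feat] - 1)
        for feat in f.included_features
    ]
    return float(np.mean(parts))


def modified_pathological_index(s: PathologyScores, f: Optional[IndexFormula] = None) -> float:
    """Pathological index with distal exostosis removed from the feature set."""
    f = f or IndexFormula.pathological()
    return pathological_index(s, f.without("dex"))


@dataclass
class StageDistribution:
    """Counts and relative frequencies of scoring stages for one feature."""

    feature: str
    limb: str  # "anterior", "posterior" or "combined"
    counts: dict[int, int]
    total: int

    @property
    def frequencies(self) -> dict[int, float]:
        if self.total == 0:
            return {k: float("nan") for k in self.counts}
        return {k: v / self.total for k, v in self.counts.items()}

    @property
    def empty(self) -> bool:
        return self.total == 0


def stage_distribution(
    a: Assemblage, feature: str, limb: Optional[Limb] = None
) -> StageDistribution:
    """Stage-frequency distribution of one feature over the scored phalanges.

    ``limb=None`` combines anterior and posterior. Input should already be
    filtered to the index-analysable phalanges.
    """
    if feature not in PATHOLOGY_FEATURES:
        raise ValueError(f"unknown pathology feature {feature!r}")
    stages = (1, 2) if feature in OA_FEATURES else (1, 2, 3, 4)
    counts = {k: 0 for k in stages}
    for s in a:
        if s.pathology is None:
            continue
        if limb is not None and s.limb != limb:
            continue
        value = s.pathology.get(feature)
        if value is None:
            continue
        if feature in OA_FEATURES:
            value = 2 if value == OAState.PRESENT else 1
        counts[int(value)] += 1
    return StageDistribution(
        feature=feature,
        limb=limb.value if limb is not None else "combined",
        counts=counts,
        total=sum(counts.values()),
    )


@dataclass
class IndexSummary:
    """Per-limb sample size and mean PI / mean MPI (NaN when n = 0)."""

    n_anterior: int
    n_posterior: int
    mean_pi_anterior: float
    mean_pi_posterior: float
    mean_mpi_anterior: float
    mean_mpi_posterior: float

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "limb": ["anterior", "posterior"],
                "n": [self.n_anterior, self.n_posterior],
                "mean_pi": [self.mean_pi_anterior, self.mean_pi_posterior],
                "mean_mpi": [self.mean_mpi_anterior, self.mean_mpi_posterior],
            }
        )


def _per_limb_indices(a: Assemblage, f: IndexFormula) -> dict[Limb, tuple[list[float], list[float]]]:
    out = {Limb.ANTERIOR: ([], []), Limb.POSTERIOR: ([], [])}
    for s in a:
        if s.pathology is None or s.limb not in out:
            continue
        pi, mpi = out[s.limb]
        pi.append(pathological_index(s.pathology, f))
        mpi.append(modified_pathological_index(s.pathology, f))
    return out


def _mean(values: Sequence[float]) -> float:
    return float(np.mean(values)) if values else float("nan")


def index_summary(a: Assemblage, f: Optional[IndexFormula] = None) -> IndexSummary:
    """Arithmetic means of PI and MPI per limb over the scored phalanges."""
    f = f or IndexFormula.pathological()
    per = _per_limb_indices(a, f)
    ant_pi, ant_mpi = per[Limb.ANTERIOR]
    post_pi, post_mpi = per[Limb.POSTERIOR]
    return IndexSummary(
        n_anterior=len(ant_pi),
        n_posterior=len(post_pi),
        mean_pi_anterior=_mean(ant_pi),
        mean_pi_posterior=_mean(post_pi),
        mean_mpi_anterior=_mean(ant_mpi),
        mean_mpi_posterior=_mean(post_mpi),
    )


@dataclass
class LimbBias:
    """Posterior-minus-anterior contrast of mean MPI with a bootstrap CI."""

    difference: float
    ci_low: float
    ci_high: float
    excludes_zero: bool
    n_anterior: int
    n_posterior: int
    n_boot: int
    seed: int
    level: float = 0.95


def limb_bias(
    a: Assemblage,
    f: Optional[IndexFormula] = None,
    n_boot: int = 2000,
    seed: int = 0,
    level: float = 0.95,
) -> LimbBias:
    """Hindlimb bias of the modified pathological index.

    Draught work loads the hindlimb preferentially, so worked herds show a
    positive posterior-minus-anterior difference in mean MPI. The percentile
    bootstrap resamples specimens within each limb (``n_boot`` replicates,
    seeded and bit-reproducible).
    """
    f = f or IndexFormula.pathological()
    per = _per_limb_indices(a, f)
    ant = np.asarray(per[Limb.ANTERIOR][1], dtype=float)
    post = np.asarray(per[Limb.POSTERIOR][1], dtype=float)
    if ant.size == 0 or post.size == 0:
        raise ValueError(
            f"limb_bias requires both limbs represented (anterior n={ant.size}, "
            f"posterior n={post.size})"
        )
    diff = float(post.mean() - ant.mean())
    rng = np.random.default_rng(seed)
    idx_a = rng.integers(0, ant.size, size=(n_boot, ant.size))
    idx_p = rng.integers(0, post.size, size=(n_boot, post.size))
    boot = post[idx_p].mean(axis=1) - ant[idx_a].mean(axis=1)
    alpha = (1.0 - level) / 2.0
    lo, hi = np.quantile(boot, [alpha, 1.0 - alpha])
    return LimbBias(
        difference=diff,
        ci_low=float(lo),
        ci_high=float(hi),
        excludes_zero=bool(lo > 0.0 or hi < 0.0),
        n_anterior=int(ant.size),
        n_posterior=int(post.size),
        n_boot=n_boot,
        seed=seed,
        level=level,
    )


@dataclass(frozen=True)
class ReferencePopulation:
    """Published comparator herd: per-limb mean index values with provenance.

    ``draught`` marks herds worked all their life (the positive baseline);
    means may be missing (None) for a limb a study did not report.
    """

    name: str
    mean_mpi_anterior: Optional[float] = None
    mean_mpi_posterior: Optional[float] = None
    mean_pi_anterior: Optional[float] = None
    mean_pi_posterior: Optional[float] = None
    draught: bool = False
    provenance: str = ""

    def __post_init__(self):
        for attr in ("mean_mpi_anterior", "mean_mpi_posterior", "mean_pi_anterior", "mean_pi_posterior"):
            v = getattr(self, attr)
            if v is not None and not (0.0 <= v <= 1.0):
                raise ValueError(f"{self.name}: {attr}={v} outside [0, 1]")


def compare_reference(
    s: IndexSummary, refs: Iterable[ReferencePopulation], query_name: str = "query"
) -> pd.DataFrame:
    """Rank the query herd's mean MPI among reference populations.

    Returns one row per (population, limb) mean, sorted ascending, with a
    flag for whether the query exceeds each reference and a note when the
    query sits between the non-draught and draught references — the ordering
    a worked-but-less-intensively herd produces.
    """
    refs = list(refs)
    if not refs:
        raise ValueError("refs must be non-empty")
    rows = []
    query_means = {
        "anterior": s.mean_mpi_anterior,
        "posterior": s.mean_mpi_posterior,
    }
    for limb, qmean in query_means.items():
        if np.isnan(qmean):
            continue
        rows.append(
            {"population": query_name, "limb": limb, "mean_mpi": qmean,
             "source": "this analysis", "is_query": True, "query_exceeds": np.nan,
             "note": ""}
        )
        draught_means, other_means = [], []
        for r in refs:
            rmean = getattr(r, f"mean_mpi_{limb}")
            if rmean is None:
                continue
            (draught_means if r.draught else other_means).append(rmean)
            rows.append(
                {"population": r.name, "limb": limb, "mean_mpi": rmean,
                 "source": r.provenance, "is_query": False,
                 "query_exceeds": qmean > rmean, "note": ""}
            )
        if draught_means and other_means:
            if max(other_means) < qmean < min(draught_means):
                for row in rows:
                    if row["is_query"] and row["limb"] == limb:
                        row["note"] = "intermediate, draught-like ordering"
    table = pd.DataFrame(rows)
    return table.sort_values(["limb", "mean_mpi"], kind="mergesort").reset_index(drop=True)
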