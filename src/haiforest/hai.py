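"""Healthy Aging Index (HAI) scoring and age adjustment.

The HAI is a composite physiological-aging score built from five indicators,
each representing one organ system:

* systolic blood pressure (mmHg, cardiovascular),
* random plasma glucose (mmol/L, glucose metabolism),
* plasma creatinine (mmol/L, kidney),
* forced vital capacity (L, lung),
* a global cognition z-score (brain).

Each indicator is scored 0 (least healthy), 1 (intermediate) or 2
(healthiest) against published cut-off bands; creatinine and forced vital
capacity have sex-specific bands, and the cognition bands are anchored at
the cohort's empirical 10th percentile and at zero. The total HAI is the
sum of the five subscores (0-10, higher is healthier). Because age dominates
the raw score, the analysis outcome is the *age-adjusted* HAI: the mean
total of all participants of the same completed age is subtracted from each
individual's total, so every age group has mean 0 by construction.

Boundary policy: the bands printed for the index overlap at their shared
endpoints (e.g. "high" is ``>= 143`` while "intermediate" is ``126-143``).
This module resolves them deterministically: the least-healthy comparator is
applied first (``value >= high_cut`` scores 0 for risk-increasing
indicators), then the healthiest strict inequality, and the middle band is
the remainder. For the protective indicators (FVC, cognition) the bands are
mirrored, except that the healthiest cognition band is the strict ``> 0``
printed for it, so an exact 0 falls in the middle band.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

INDICATORS = ("sbp", "glucose", "creatinine", "fvc", "cognition")

#: Default cut-off configuration. ``direction`` is "risk" when larger values
#: are less healthy and "protective" when larger values are healthier.
#: ``cuts`` maps sex (or "any") to (low_cut, high_cut) in the indicator's
#: units; for protective indicators low_cut bounds the least-healthy band
#: and high_cut the healthiest.
DEFAULT_CUTOFFS: dict[str, dict] = {
    "sbp": {"direction": "risk", "units": "mmHg", "cuts": {"any": (126.0, 143.0)}},
    "glucose": {"direction": "risk", "units": "mmol/L", "cuts": {"any": (5.6, 11.1)}},
    "creatinine": {
        "direction": "risk",
        "units": "mmol/L",
        "cuts": {"male": (97.2, 114.9), "female": (70.7, 88.4)},
    },
    "fvc": {
        "direction": "protective",
        "units": "L",
        "cuts": {"male": (3.2, 3.8), "female": (2.1, 2.6)},
    },
    # Cognition cuts are in z-score units; the lower cut is the cohort's
    # empirical 10th percentile, supplied at scoring time.
    "cognition": {"direction": "protective", "units": "z", "cuts": {"any": (None, 0.0)}},
}

SEX_SPECIFIC = frozenset(
    name for name, cfg in DEFAULT_CUTOFFS.items() if "any" not in cfg["cuts"]
)


@dataclass(frozen=True)
class IndicatorPanel:
    """One participant's five indicator measurements at the outcome wave."""

    participant_id: str
    sex: str
    age_w6: float
    sbp: float
    glucose: float
    creatinine: float
    fvc: float
    cognition_z: float

    def __post_init__(self) -> None:
        if self.sex not in ("male", "female"):
            raise ValueError(f"sex must be 'male' or 'female', got {self.sex!r}")
        for name in ("sbp", "glucose", "creatinine", "fvc"):
            v = getattr(self, name)
            if not np.isfinite(v) or v <= 0:
                raise ValueError(f"{name} must be strictly positive and finite, got {v}")
        if not np.isfinite(self.cognition_z):
            raise ValueError("cognition_z must be finite")


@dataclass
class HAIScore:
    participant_id: str
    subscores: dict[str, int] = field(default_factory=dict)
    total: int = 0
    age_adjusted: float | None = None


def load_cutoffs(path) -> dict[str, dict]:
    """Load a cut-off configuration from YAML.

    The file follows the ``DEFAULT_CUTOFFS`` structure: per indicator a
    ``direction``, ``units`` and ``cuts`` mapping of sex (or ``any``) to a
    ``[low, high]`` pair. Indicators absent from the file keep their
    shipped defaults.
    """
    import copy
    from pathlib import Path

    import yaml

    loaded = yaml.safe_load(Path(path).read_text())
    cutoffs = copy.deepcopy(DEFAULT_CUTOFFS)
    for name, cfg in loaded.items():
        if name not in cutoffs:
            raise KeyError(f"unknown indicator {name!r} in cut-off config")
        merged = {**cutoffs[name], **cfg}
        merged["cuts"] = {k: tuple(v) for k, v in merged["cuts"].items()}
        cutoffs[name] = merged
    return cutoffs


def score_indicator(
    indicator_name: str,
    value: float,
    sex: str | None = None,
    cognition_p10: float | None = None,
    cutoffs: Mapping[str, dict] | None = None,
) -> int:
    """Score one indicator value into the 0/1/2 band.

    Parameters
    ----------
    indicator_name
        One of ``sbp``, ``glucose``, ``creatinine``, ``fvc``, ``cognition``.
    value
        Measurement in the indicator's units (z-score for cognition).
    sex
        Required for the sex-specific indicators (creatinine, fvc).
    cognition_p10
        Empirical 10th-percentile z-score threshold; required for cognition.
    """
    cutoffs = cutoffs if cutoffs is not None else DEFAULT_CUTOFFS
    if indicator_name not in cutoffs:
        raise KeyError(f"unknown indicator {indicator_name!r}")
    if not np.isfinite(value):
        raise ValueError(f"{indicator_name} value must be finite, got {value}")
    cfg = cutoffs[indicator_name]
    cuts = cfg["cuts"]
    if "any" in cuts:
        lo, hi = cuts["any"]
    else:
        if sex not in cuts:
            raise ValueError(
                f"indicator {indicator_name!r} is sex-specific; sex must be one of "
                f"{sorted(cuts)}, got {sex!r}"
            )
        lo, hi = cuts[sex]
    if indicator_name == "cognition":
        if cognition_p10 is None:
            raise ValueError("cognition requires the cognition_p10 threshold")
        lo = cognition_p10

    if cfg["direction"] == "risk":
        if value >= hi:
            return 0
        if value < lo:
            return 2
        return 1
    # protective: least-healthy band first, then the healthiest strict/weak
    # inequality as printed (> 0 for cognition, >= high cut for fvc).
    if value < lo:
        return 0
    if indicator_name == "cognition":
        return 2 if value > hi else 1
    return 2 if value >= hi else 1


def compute_hai(
    panel: IndicatorPanel,
    cognition_p10: float,
    cutoffs: Mapping[str, dict] | None = None,
) -> HAIScore:
    """Score all five indicators for one participant and sum them.

    Only complete panels are accepted; ``IndicatorPanel`` construction
    already rejects non-finite values, matching the complete-case inclusion
    criterion of the analysis.
    """
    values = {
        "sbp": panel.sbp,
        "glucose": panel.glucose,
        "creatinine": panel.creatinine,
        "fvc": panel.fvc,
        "cognition": panel.cognition_z,
    }
    missing = [k for k, v in values.items() if v is None or not np.isfinite(v)]
    if missing:
        raise ValueError(f"panel is missing indicator values: {missing}")
    subscores = {
        name: score_indicator(name, v, sex=panel.sex, cognition_p10=cognition_p10, cutoffs=cutoffs)
        for name, v in values.items()
    }
    return HAIScore(
        participant_id=panel.participant_id,
        subscores=subscores,
        total=int(sum(subscores.values())),
    )


def cognition_percentile_threshold(z_scores: Sequence[float]) -> float:
    """Empirical 10th percentile of a cognition z-score sample.

    Uses the linear-interpolation quantile definition (numpy's default
    "linear" method). At least 10 finite values are required.
    """
    z = np.asarray(z_scores, dtype=float)
    z = z[np.isfinite(z)]
    if z.size < 10:
        raise ValueError(f"need >= 10 finite values to estimate a 10th percentile, got {z.size}")
    return float(np.quantile(z, 0.10))


def age_adjust(scores: pd.DataFrame, min_bin_size: int = 1) -> pd.DataFrame:
    """Mean-center HAI totals within integer-age groups.

    ``scores`` must have columns ``total`` and ``age``; a column
    ``age_adjusted`` is added: the individual's total minus the mean total
    of all participants with the same completed age (floor of ``age``).
    With ``min_bin_size > 1``, ages whose bin holds fewer participants are
    pooled with the nearest adjacent age bin until every bin reaches the
    minimum; the default leaves every single-year age as its own group.
    """
    if len(scores) == 0:
        raise ValueError("age_adjust requires a non-empty score table")
    out = scores.copy()
    age_group = np.floor(out["age"].to_numpy(dtype=float)).astype(int)
    if min_bin_size > 1:
        age_group = _pool_sparse_bins(age_group, min_bin_size)
    out["age_group"] = age_group
    out["age_adjusted"] = out["total"] - out.groupby("age_group")["total"].transform("mean")
    return out


def _pool_sparse_bins(age_group: np.ndarray, min_bin_size: int) -> np.ndarray:
    """Merge each under-filled age bin with its nearest neighbouring bin."""
    group = age_group.copy()
    while True:
        labels, counts = np.unique(group, return_counts=True)
        small = labels[counts < min_bin_size]
        if small.size == 0 or labels.size == 1:
            return group
        a = small[0]
        others = labels[labels != a]
        nearest = others[np.argmin(np.abs(others - a))]
        group[group == a] = nearest


def score_cohort(
    outcome: pd.DataFrame,
    cognition_p10: float | None = None,
    cutoffs: Mapping[str, dict] | None = None,
    min_bin_size: int = 1,
) -> pd.DataFrame:
    """Score a full outcome table and age-adjust within it.

    ``outcome`` follows the pipeline schema: participant_id, sex, age_w6,
    sbp_mmHg, glucose_mmol_L, creatinine_mmol_L, fvc_L, cognition_z. When
    ``cognition_p10`` is None the threshold is the empirical 10th percentile
    of this population's cognition z-scores.
    """
    if cognition_p10 is None:
        cognition_p10 = cognition_percentile_threshold(outcome["cognition_z"])
    rows = []
    for rec in outcome.itertuples(index=False):
        panel = IndicatorPanel(
            participant_id=str(rec.participant_id),
            sex=rec.sex,
            age_w6=float(rec.age_w6),
            sbp=float(rec.sbp_mmHg),
            glucose=float(rec.glucose_mmol_L),
            creatinine=float(rec.creatinine_mmol_L),
            fvc=float(rec.fvc_L),
            cognition_z=float(rec.cognition_z),
        )
        s = compute_hai(panel, cognition_p10=cognition_p10, cutoffs=cutoffs)
        rows.append(
            {
                "participant_id": s.participant_id,
                **{f"score_{k}": v for k, v in s.subscores.items()},
                "total": s.total,
                "age": float(rec.age_w6),
            }
        )
    scored = pd.DataFrame(rows)
    scored = age_adjust(scored, min_bin_size=min_bin_size)
    scored.attrs["cognition_p10"] = float(cognition_p10)
    return scored
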