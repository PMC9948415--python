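"""Longitudinal exposure summarization.

Exposures measured repeatedly over waves 1-5 are collapsed into
per-participant features before modelling:

* **AUE** (area under the exposure): the arithmetic mean of a continuous
  exposure over its measured waves.
* **TOE** (trend of the exposure): the least-squares slope of the exposure
  on the wave index, i.e. the average change per 5-year wave interval.
* **percent_of_time**: for binary exposures, 100 x the fraction of observed
  waves in which the exposure was "yes".
* **transitioned_no_to_yes**: 1 when the first observed wave is "no" and
  the last observed wave is "yes", else 0.

Summaries use only a participant's observed waves; exposures measured in a
subset of waves (e.g. diet in waves 2-4 only) are summarized over exactly
those waves. Participants with no observed wave for an exposure receive the
column median of the computed feature (a simple, documented single-value
imputation; the pipeline otherwise assumes complete outcome data).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

SUMMARY_KINDS = ("aue", "toe", "percent_of_time", "transitioned_no_to_yes")
DOMAINS = ("demographic", "lifestyle", "environmental", "biological")


@dataclass(frozen=True)
class ExposureDescriptor:
    """Metadata describing how one exposure column is summarized.

    ``dtype`` is ``continuous`` (AUE/TOE), ``binary`` (percent summaries)
    or ``ordinal`` (numeric-coded levels, summarized like continuous).
    Non-time-varying exposures (``time_varying=False``, e.g. educational
    level or sex) enter the feature matrix as a single baseline value.
    """

    name: str
    domain: str
    dtype: str
    waves_measured: tuple[int, ...] = (1, 2, 3, 4, 5)
    summaries: tuple[str, ...] = ()
    time_varying: bool = True

    def __post_init__(self) -> None:
        if self.domain not in DOMAINS:
            raise ValueError(f"unknown domain {self.domain!r}")
        if self.dtype not in ("continuous", "binary", "ordinal"):
            raise ValueError(f"unknown dtype {self.dtype!r}")
        if not self.waves_measured:
            raise ValueError(f"{self.name}: waves_measured must be nonempty")
        if not self.time_varying:
            if self.summaries:
                raise ValueError(
                    f"{self.name}: non-time-varying exposures take no longitudinal summary"
                )
            return
        allowed = (
            ("aue", "toe") if self.dtype in ("continuous", "ordinal")
            else ("percent_of_time", "transitioned_no_to_yes")
        )
        bad = [s for s in self.summaries if s not in allowed]
        if bad:
            raise ValueError(f"{self.name}: summaries {bad} not valid for dtype {self.dtype}")

    @property
    def feature_names(self) -> list[str]:
        if not self.time_varying:
            return [self.name]
        return [f"{self.name}__{s}" for s in self.summaries]


def default_summaries(dtype: str, time_varying: bool = True) -> tuple[str, ...]:
    if not time_varying:
        return ()
    if dtype in ("continuous", "ordinal"):
        return ("aue", "toe")
    return ("percent_of_time", "transitioned_no_to_yes")


def compute_aue(values_by_wave: Mapping[int, float] | pd.Series) -> float:
    """Mean of the observed wave values; NaN when nothing was observed."""
    v = _observed(values_by_wave)[1]
    if v.size == 0:
        return float("nan")
    return float(np.mean(v))


def compute_toe(values_by_wave: Mapping[int, float] | pd.Series) -> float:
    """OLS slope of value on wave index: change per wave interval.

    With exactly two observed waves this reduces to the difference divided
    by the wave-index gap. Fewer than two observed waves yields NaN.
    """
    w, v = _observed(values_by_wave)
    if v.size < 2:
        return float("nan")
    w = w - w.mean()
    return float(np.dot(w, v - v.mean()) / np.dot(w, w))


def percent_of_time(values_by_wave: Mapping[int, float] | pd.Series) -> float:
    """Percentage (0-100) of observed waves in which a binary exposure is yes."""
    v = _observed(values_by_wave)[1]
    if v.size == 0:
        return float("nan")
    _check_binary(v)
    return float(100.0 * np.mean(v))


def transitioned_no_to_yes(values_by_wave: Mapping[int, float] | pd.Series) -> float:
    """1 if the first observed wave is no and the last is yes, else 0.

    This is a first-versus-last rule: intermediate switches do not count.
    """
    v = _observed(values_by_wave)[1]
    if v.size < 2:
        return float("nan")
    _check_binary(v)
    return float(v[0] == 0 and v[-1] == 1)


_SUMMARY_FUNCS = {
    "aue": compute_aue,
    "toe": compute_toe,
    "percent_of_time": percent_of_time,
    "transitioned_no_to_yes": transitioned_no_to_yes,
}


def _observed(values_by_wave) -> tuple[np.ndarray, np.ndarray]:
    if isinstance(values_by_wave, pd.Series):
        waves = values_by_wave.index.to_numpy(dtype=float)
        vals = values_by_wave.to_numpy(dtype=float)
    else:
        waves = np.array(sorted(values_by_wave), dtype=float)
        vals = np.array([values_by_wave[int(w)] for w in waves], dtype=float)
    order = np.argsort(waves)
    waves, vals = waves[order], vals[order]
    keep = np.isfinite(vals)
    return waves[keep], vals[keep]


def _check_binary(v: np.ndarray) -> None:
    if not np.all(np.isin(v, (0.0, 1.0))):
        raise ValueError("binary summaries require values coded 0 (no) / 1 (yes)")


@dataclass
class FeatureMatrix:
    """Participants x summarized-exposure features with provenance."""

    data: pd.DataFrame  # indexed by participant_id
    provenance: dict[str, dict] = field(default_factory=dict)

    @property
    def feature_names(self) -> list[str]:
        return list(self.data.columns)

    @property
    def n_features(self) -> int:
        return self.data.shape[1]


def build_feature_matrix(
    wave_table: pd.DataFrame,
    descriptors: Sequence[ExposureDescriptor],
    impute: str = "median",
) -> FeatureMatrix:
    """Summarize a long-format wave table into the participant x feature matrix.

    ``wave_table`` has one row per participant per wave, with columns
    ``participant_id``, ``wave`` and one column per exposure (NaN where the
    exposure was not measured). Every exposure column must be covered by a
    descriptor and vice versa. Each requested (exposure, summary) pair
    becomes a ``<exposure>__<summary>`` column; baseline (non-time-varying)
    exposures become single columns under their own name. Features that are
    missing for a participant (no observed wave) are imputed with the
    feature's median across participants.
    """
    meta_cols = {"participant_id", "generation", "wave", "age_at_wave"}
    exposure_cols = [c for c in wave_table.columns if c not in meta_cols]
    desc_names = [d.name for d in descriptors]
    orphans_cols = sorted(set(exposure_cols) - set(desc_names))
    orphans_desc = sorted(set(desc_names) - set(exposure_cols))
    if orphans_cols or orphans_desc:
        raise ValueError(
            "descriptor/column mismatch: columns without descriptor "
            f"{orphans_cols}; descriptors without column {orphans_desc}"
        )

    ids = wave_table["participant_id"].drop_duplicates().to_numpy()
    cols: dict[str, pd.Series] = {}
    provenance: dict[str, dict] = {}
    for d in descriptors:
        sub = wave_table[wave_table["wave"].isin(d.waves_measured)]
        wide = sub.pivot(index="participant_id", columns="wave", values=d.name)
        wide = wide.reindex(ids)
        if not d.time_varying:
            # baseline value: first measured wave
            first_wave = min(d.waves_measured)
            col = wide[first_wave] if first_wave in wide.columns else pd.Series(np.nan, index=wide.index)
            cols[d.name] = col.astype(float)
            provenance[d.name] = _prov(d, "baseline")
            continue
        for s in d.summaries:
            feat = _summarize_wide(wide, s)
            name = f"{d.name}__{s}"
            cols[name] = feat.astype(float)
            provenance[name] = _prov(d, s)

    data = pd.DataFrame(cols, index=pd.Index(ids, name="participant_id"))
    if impute == "median":
        data = data.fillna(data.median())
    elif impute != "none":
        raise ValueError(f"unknown impute policy {impute!r}")
    return FeatureMatrix(data=data, provenance=provenance)


def _summarize_wide(wide: pd.DataFrame, summary: str) -> pd.Series:
    """Vectorized summary over a participants x waves matrix.

    Row-wise equivalent of the scalar summary functions (which remain the
    reference definitions); NaN marks unobserved waves and propagates as
    the missing-feature marker.
    """
    import warnings

    waves = wide.columns.to_numpy(dtype=float)
    v = wide.to_numpy(dtype=float)
    obs = np.isfinite(v)
    n_obs = obs.sum(axis=1)
    with warnings.catch_warnings(), np.errstate(invalid="ignore"):
        # all-NaN rows legitimately yield NaN (missing-feature marker)
        warnings.simplefilter("ignore", RuntimeWarning)
        if summary == "aue":
            out = np.where(n_obs >= 1, np.nanmean(np.where(obs, v, np.nan), axis=1), np.nan)
        elif summary == "percent_of_time":
            vals = v[obs]
            if not np.all(np.isin(vals, (0.0, 1.0))):
                raise ValueError("binary summaries require values coded 0 (no) / 1 (yes)")
            out = np.where(n_obs >= 1, 100.0 * np.nanmean(np.where(obs, v, np.nan), axis=1), np.nan)
        elif summary == "toe":
            w = np.where(obs, waves[None, :], np.nan)
            wbar = np.nanmean(w, axis=1, keepdims=True)
            vbar = np.nanmean(np.where(obs, v, np.nan), axis=1, keepdims=True)
            dw = np.where(obs, w - wbar, 0.0)
            dv = np.where(obs, v - vbar, 0.0)
            denom = (dw**2).sum(axis=1)
            out = np.where(n_obs >= 2, (dw * dv).sum(axis=1) / np.where(denom > 0, denom, np.nan), np.nan)
        elif summary == "transitioned_no_to_yes":
            vals = v[obs]
            if not np.all(np.isin(vals, (0.0, 1.0))):
                raise ValueError("binary summaries require values coded 0 (no) / 1 (yes)")
            first_idx = np.argmax(obs, axis=1)
            last_idx = v.shape[1] - 1 - np.argmax(obs[:, ::-1], axis=1)
            rows = np.arange(v.shape[0])
            first = v[rows, first_idx]
            last = v[rows, last_idx]
            out = np.where(n_obs >= 2, ((first == 0) & (last == 1)).astype(float), np.nan)
        else:
            raise KeyError(summary)
    return pd.Series(out, index=wide.index)


def _prov(d: ExposureDescriptor, summary: str) -> dict:
    return {
        "exposure": d.name,
        "domain": d.domain,
        "dtype": d.dtype,
        "summary": summary,
        "waves_measured": list(d.waves_measured),
    }
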