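"""Classical descriptives: recoding, complete cases, totals, Cronbach alpha.

Raw answers arrive on a 5-point frequency format (0 no, 1 sometimes,
2 regularly, 3 often, 4 very often or constantly) and are scored 0/1/2 by
collapsing the top three options. Scale totals are plain sums; internal
consistency is Cronbach's alpha with a 0.8 floor conventionally read as
acceptable for this instrument.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .responses import ResponseMatrix

__all__ = [
    "recode_raw",
    "complete_cases",
    "scale_totals",
    "cronbach_alpha",
    "alpha_if_deleted",
    "scale_summary",
    "ScaleSummary",
]

log = logging.getLogger(__name__)


def recode_raw(raw: pd.DataFrame, scale_map, covariates=None) -> ResponseMatrix:
    """Collapse 5-point raw codes to the 0/1/2 scoring: 0->0, 1->1,
    {2,3,4}->2. Missing cells are preserved, never imputed.

    Input already on the 0..2 scoring (max observed code <= 2) is passed
    through unchanged (logged). Out-of-range codes are reported with their
    person/item coordinates.
    """
    vals = raw.to_numpy(dtype=float)
    finite = ~np.isnan(vals)
    bad = finite & ((vals < 0) | (vals > 4) | (vals != np.round(vals)))
    if bad.any():
        i, j = np.argwhere(bad)[0]
        raise ValueError(
            f"raw code out of range {{0..4}}: person {raw.index[i]!r}, "
            f"item {raw.columns[j]!r} has {vals[i, j]!r}"
        )
    if not finite.any() or np.nanmax(vals) <= 2:
        log.info("input already on the 0/1/2 scoring; recode skipped")
        coded = vals
    else:
        coded = np.minimum(vals, 2.0)
    frame = pd.DataFrame(coded, index=raw.index, columns=raw.columns)
    return ResponseMatrix(frame, scale_map, covariates)


def complete_cases(rm: ResponseMatrix) -> tuple[ResponseMatrix, list]:
    """Drop every person with any missing cell; report who was excluded.

    Returns the filtered matrix and the exclusion list; the retention
    percentage (one decimal) is logged, mirroring explicit
    retained/approached reporting.
    """
    mask = rm.codes.notna().all(axis=1)
    excluded = list(rm.codes.index[~mask])
    if not mask.any():
        raise ValueError("complete-case filtering removed every person")
    retained = rm.select_persons(rm.codes.index[mask])
    pct = retention_percent(int(mask.sum()), rm.n_persons)
    log.info("complete cases: %d/%d retained (%.1f%%), %d excluded",
             mask.sum(), rm.n_persons, pct, len(excluded))
    return retained, excluded


def retention_percent(n_retained: int, n_total: int) -> float:
    """Complete-case retention, percent to one decimal (e.g. 379/408 -> 92.9)."""
    return round(100.0 * n_retained / n_total, 1)


def scale_totals(rm: ResponseMatrix, scale: str) -> pd.Series:
    """Per-person total score on one scale (sum of item codes)."""
    vals = rm.values_for(scale)
    return pd.Series(vals.sum(axis=1), index=rm.codes.index, name=scale)


def cronbach_alpha(rm: ResponseMatrix, scale: str) -> float:
    """Cronbach's alpha: (k/(k-1)) (1 - sum item variances / total variance),
    sample variances with denominator n-1."""
    vals = rm.values_for(scale).astype(float)
    n, k = vals.shape
    if k < 2:
        raise ValueError("Cronbach alpha needs at least 2 items")
    if n < 2:
        raise ValueError("Cronbach alpha needs at least 2 persons")
    total_var = vals.sum(axis=1).var(ddof=1)
    if total_var <= 0:
        raise ValueError(f"scale {scale!r} has zero total-score variance")
    item_vars = vals.var(axis=0, ddof=1).sum()
    return float(k / (k - 1) * (1.0 - item_vars / total_var))


def alpha_if_deleted(rm: ResponseMatrix, scale: str) -> dict[str, float]:
    """Cronbach alpha of the scale with each single item removed."""
    ids = rm.items_in(scale)
    if len(ids) < 3:
        raise ValueError("alpha-if-deleted needs at least 3 items")
    out = {}
    for drop in ids:
        keep = [i for i in ids if i != drop]
        sub = ResponseMatrix(rm.codes[keep], {i: scale for i in keep})
        out[drop] = cronbach_alpha(sub, scale)
    return out


@dataclass
class ScaleSummary:
    """Step-1 descriptives for one scale."""

    scale: str
    n: int
    mean_total: float
    se_mean: float
    median: float
    min: int
    max: int
    cronbach_alpha: float
    alpha_if_deleted: dict[str, float] = field(repr=False)

    def to_row(self) -> dict:
        return {
            "scale": self.scale, "n": self.n, "mean": self.mean_total,
            "se": self.se_mean, "median": self.median,
            "min": self.min, "max": self.max, "alpha": self.cronbach_alpha,
        }


def scale_summary(rm: ResponseMatrix, scale: str) -> ScaleSummary:
    """Mean total (with SE = SD/sqrt(n), n-1 denominator SD), median,
    observed range, and internal consistency for one scale."""
    totals = scale_totals(rm, scale)
    n = len(totals)
    return ScaleSummary(
        scale=scale,
        n=n,
        mean_total=float(totals.mean()),
        se_mean=float(totals.std(ddof=1) / np.sqrt(n)),
        median=float(totals.median()),
        min=int(totals.min()),
        max=int(totals.max()),
        cronbach_alpha=cronbach_alpha(rm, scale),
        alpha_if_deleted=alpha_if_deleted(rm, scale),
    )
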