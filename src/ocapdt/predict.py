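"""Responder/non-responder prediction from PVD metrics.

The statistical core of the package: sorted-midpoint threshold search with
correctly-predicted-outcome (CPO) counting, Wilson score intervals for the
binomial prediction accuracy, the two-stage decision rule (any perfused
vessels inside the tumour means failure; otherwise success iff peri-tumour
PVD does not exceed the threshold), and reconstruction of the full
per-scenario summary table over a cohort.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import norm

from .cohort import REGIONS, TIMEPOINTS, CohortTable

__all__ = [
    "Scenario",
    "ThresholdSearchResult",
    "WilsonInterval",
    "PredictionCriterion",
    "optimal_threshold",
    "cpo_at_threshold",
    "wilson_interval",
    "classify_outcome",
    "evaluate_table",
    "predict_cohort",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class Scenario:
    region: str
    timepoint: str

    def __post_init__(self) -> None:
        if self.region not in REGIONS:
            raise ValueError(f"region must be one of {REGIONS}, got {self.region!r}")
        if self.timepoint not in TIMEPOINTS:
            raise ValueError(f"timepoint must be one of {TIMEPOINTS}, got {self.timepoint!r}")


ALL_SCENARIOS = tuple(
    Scenario(region, timepoint) for timepoint in TIMEPOINTS for region in REGIONS
)


@dataclass(frozen=True)
class ThresholdSearchResult:
    threshold_pvd: float
    cpo: int
    n: int

    @property
    def accuracy(self) -> float:
        return self.cpo / self.n


@dataclass(frozen=True)
class WilsonInterval:
    lower: float
    upper: float
    confidence: float = 0.95
    z: float = 1.959964

    def as_percent(self) -> tuple[int, int]:
        """Bounds rounded to the nearest integer percent (reporting convention)."""
        return int(np.rint(100.0 * self.lower)), int(np.rint(100.0 * self.upper))


@dataclass(frozen=True)
class PredictionCriterion:
    """Two-stage decision rule at 24 h.

    ``tumour_epsilon`` is the largest tumour PVD still regarded as "no
    perfused vessels" (default 0: any residual tumour perfusion means
    failure); ``peri_threshold`` is the peri-tumour PVD limit (default 1 %).
    """

    tumour_epsilon: float = 0.0
    peri_threshold: float = 1.0

    def __post_init__(self) -> None:
        if self.tumour_epsilon < 0 or self.peri_threshold < 0:
            raise ValueError("criterion thresholds must be >= 0")


def _responder_mask(outcomes: np.ndarray) -> np.ndarray:
    outcomes = np.asarray(outcomes)
    if outcomes.dtype == bool:
        return outcomes
    return outcomes == "responder"


def cpo_at_threshold(
    values: np.ndarray, outcomes: np.ndarray, threshold: float
) -> int:
    """Correct predictions under the rule "PVD <= threshold => responder"."""
    values = np.asarray(values, dtype=float)
    resp = _responder_mask(outcomes)
    predicted_resp = values <= threshold
    return int(np.sum(predicted_resp == resp))


def optimal_threshold(values: np.ndarray, outcomes: np.ndarray) -> ThresholdSearchResult:
    """Best midpoint threshold under "PVD <= threshold => responder".

    Candidates are the midpoints between consecutive sorted unique values
    plus a below-minimum and an above-maximum boundary; only these can
    change the decision, so the search is equivalent to an exhaustive scan
    over all real thresholds.  Ties break toward the smallest threshold
    (favouring sensitivity to residual perfusion).
    """
    values = np.asarray(values, dtype=float)
    resp = _responder_mask(outcomes)
    if values.size < 2:
        raise ValueError("threshold search needs at least 2 animals")
    if resp.all() or not resp.any():
        raise ValueError("threshold search needs both outcome classes")
    uniq = np.unique(values)
    candidates = np.concatenate(
        [[uniq[0] - 1.0], (uniq[:-1] + uniq[1:]) / 2.0, [uniq[-1] + 1.0]]
    )
    best: ThresholdSearchResult | None = None
    for thr in candidates:  # ascending, so ties keep the smallest threshold
        cpo = cpo_at_threshold(values, resp, thr)
        if best is None or cpo > best.cpo:
            best = ThresholdSearchResult(threshold_pvd=float(thr), cpo=cpo, n=values.size)
    assert best is not None
    return best


def wilson_interval(
    k: int, n: int, confidence: float = 0.95, z: float | None = None
) -> WilsonInterval:
    """Wilson score interval for a binomial proportion k/n."""
    if n <= 0:
        raise ValueError("n must be positive")
    if not 0 <= k <= n:
        raise ValueError(f"k={k} must be in [0, n={n}]")
    if z is None:
        z = float(norm.ppf(0.5 + confidence / 2.0))
    z2 = z * z
    denom = n + z2
    centre = (k + z2 / 2.0) / denom
    half = z * np.sqrt(k * (n - k) / n + z2 / 4.0) / denom
    # endpoints are analytically exact at k=0 and k=n; avoid rounding drift
    lower = 0.0 if k == 0 else float(np.clip(centre - half, 0.0, 1.0))
    upper = 1.0 if k == n else float(np.clip(centre + half, 0.0, 1.0))
    return WilsonInterval(lower=lower, upper=upper, confidence=confidence, z=z)


def classify_outcome(
    tumour_pvd: float,
    peri_pvd: float,
    criterion: PredictionCriterion | None = None,
) -> str:
    """Two-stage rule: tumour perfusion first, then the peri-tumour limit."""
    criterion = criterion or PredictionCriterion()
    if tumour_pvd < 0 or peri_pvd < 0:
        raise ValueError("PVD values must be >= 0")
    if tumour_pvd > criterion.tumour_epsilon:
        return "non-responder"
    return "responder" if peri_pvd <= criterion.peri_threshold else "non-responder"


def evaluate_table(cohort: CohortTable) -> pd.DataFrame:
    """Per-scenario optimal threshold, CPO and Wilson interval over a cohort.

    One row per (region, timepoint) scenario; scenarios with missing
    measurements are skipped with a log entry.  ``ci_low``/``ci_high`` are
    integer percent (reporting convention); exact proportions are kept in
    ``ci_low_exact``/``ci_high_exact``.
    """
    rows = []
    for scen in ALL_SCENARIOS:
        try:
            values, labels = cohort.values(scen.region, scen.timepoint)
        except KeyError:
            logger.warning(
                "scenario (%s, %s): missing measurements, skipped", scen.region, scen.timepoint
            )
            continue
        result = optimal_threshold(values, labels)
        ci = wilson_interval(result.cpo, result.n)
        lo_pct, hi_pct = ci.as_percent()
        rows.append(
            {
                "region": scen.region,
                "timepoint": scen.timepoint,
                "threshold_pvd": result.threshold_pvd,
                "cpo": result.cpo,
                "n": result.n,
                "accuracy": result.accuracy,
                "ci_low": lo_pct,
                "ci_high": hi_pct,
                "ci_low_exact": ci.lower,
                "ci_high_exact": ci.upper,
            }
        )
    return pd.DataFrame(rows)


def predict_cohort(
    cohort: CohortTable,
    criterion: PredictionCriterion | None = None,
    timepoint: str = "24h",
) -> pd.DataFrame:
    """Per-animal combined-rule predictions at one time point."""
    criterion = criterion or PredictionCriterion()
    rows = []
    for rec in cohort.records:
        predicted = classify_outcome(
            rec.pvd[("tumour", timepoint)], rec.pvd[("peri-tumour", timepoint)], criterion
        )
        rows.append(
            {
                "animal_id": rec.animal_id,
                "tumour_pvd": rec.pvd[("tumour", timepoint)],
                "peri_tumour_pvd": rec.pvd[("peri-tumour", timepoint)],
                "predicted": predicted,
                "actual": rec.outcome,
                "correct": predicted == rec.outcome,
            }
        )
    return pd.DataFrame(rows)
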