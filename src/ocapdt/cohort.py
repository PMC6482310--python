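"""Synthetic treatment cohorts with the statistical structure of the study.

A cohort is a set of animals, each carrying a histology-derived outcome
label (responder = necrosis > 95 % at day 7) and perfused-vessel-density
(PVD, %) measurements for two regions (tumour, peri-tumour) at four time
points (pre-treatment, 0 h, 5 h, 24 h post treatment).  The default cohort
reproduces the published composition: 31 animals (18 responders / 13
non-responders), 8 of the 13 non-responders with zero tumour PVD at 24 h,
peri-tumour 24 h group statistics 0.38 +/- 0.22 % (responders) versus
2.21 +/- 0.86 % (non-responders), and complete separation of the two groups
at 24 h with extremes 0.8 % / 1.2 % (so the midpoint threshold is 1.0 %).

Group statistics are interpreted as the target sample moments of the
*emitted* values.  Because PVD values are truncated at zero and the 24 h
peri-tumour values are additionally clamped to the separation extremes,
drawing directly from N(mean, sd) would bias the emitted moments; the
generator therefore calibrates latent normal parameters by moment-matching
the clipped normal (see docs/methods.md).
"""

from __future__ import annotations

import functools
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import optimize, stats

__all__ = [
    "REGIONS",
    "TIMEPOINTS",
    "OUTCOMES",
    "GroupStats",
    "CohortSpec",
    "AnimalRecord",
    "CohortTable",
    "generate_cohort",
]

REGIONS = ("tumour", "peri-tumour")
TIMEPOINTS = ("pre", "0h", "5h", "24h")
OUTCOMES = ("responder", "non-responder")

COHORT_CSV_COLUMNS = ["animal_id", "outcome", "region", "timepoint", "pvd_percent"]


@dataclass(frozen=True)
class GroupStats:
    """Target mean and SD (%) of a (outcome, region, timepoint) cell."""

    mean: float
    sd: float

    def __post_init__(self) -> None:
        if self.sd < 0:
            raise ValueError(f"SD must be >= 0, got {self.sd}")
        if self.mean < 0:
            raise ValueError(f"PVD mean must be >= 0, got {self.mean}")


def default_group_pvd_params() -> dict[tuple[str, str, str], GroupStats]:
    """Published group statistics where printed; monotone interpolation elsewhere.

    Peri-tumour pre and 24 h cells are the printed values; 0 h and 5 h
    means/SDs interpolate linearly between them.  Tumour pre-treatment
    defaults to 4.5 +/- 1.0 % (unprinted), decaying monotonically to the
    24 h state: responders reach exactly zero; the non-responder 24 h cell
    parameterises only the *perfused* (non-zero) subset of that group.
    """
    return {
        ("responder", "tumour", "pre"): GroupStats(4.5, 1.0),
        ("responder", "tumour", "0h"): GroupStats(3.0, 0.8),
        ("responder", "tumour", "5h"): GroupStats(1.5, 0.5),
        ("responder", "tumour", "24h"): GroupStats(0.0, 0.0),
        ("non-responder", "tumour", "pre"): GroupStats(4.5, 1.0),
        ("non-responder", "tumour", "0h"): GroupStats(3.5, 0.9),
        ("non-responder", "tumour", "5h"): GroupStats(2.5, 0.8),
        ("non-responder", "tumour", "24h"): GroupStats(1.0, 0.5),
        ("responder", "peri-tumour", "pre"): GroupStats(3.14, 0.57),
        ("responder", "peri-tumour", "0h"): GroupStats(2.22, 0.45),
        ("responder", "peri-tumour", "5h"): GroupStats(1.30, 0.34),
        ("responder", "peri-tumour", "24h"): GroupStats(0.38, 0.22),
        ("non-responder", "peri-tumour", "pre"): GroupStats(3.29, 0.59),
        ("non-responder", "peri-tumour", "0h"): GroupStats(2.93, 0.68),
        ("non-responder", "peri-tumour", "5h"): GroupStats(2.57, 0.77),
        ("non-responder", "peri-tumour", "24h"): GroupStats(2.21, 0.86),
    }


@dataclass
class CohortSpec:
    n_responders: int = 18
    n_nonresponders: int = 13
    n_nonresp_zero_tumour_24h: int = 8
    group_pvd_params: dict[tuple[str, str, str], GroupStats] = field(
        default_factory=default_group_pvd_params
    )
    #: (max responder, min non-responder) peri-tumour PVD at 24 h, %
    separation_extremes: tuple[float, float] = (0.8, 1.2)
    #: smallest PVD a perfused non-responder tumour can show at 24 h, %
    tumour_positive_floor: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_responders < 0 or self.n_nonresponders < 0:
            raise ValueError("group sizes must be non-negative")
        if not 0 <= self.n_nonresp_zero_tumour_24h <= self.n_nonresponders:
            raise ValueError(
                f"n_nonresp_zero_tumour_24h={self.n_nonresp_zero_tumour_24h} must be "
                f"between 0 and n_nonresponders={self.n_nonresponders}"
            )
        lo, hi = self.separation_extremes
        if not lo < hi:
            raise ValueError(
                f"separation extremes must satisfy max_responder < min_non-responder, "
                f"got {self.separation_extremes}"
            )
        if lo < 0:
            raise ValueError("separation extremes must be non-negative PVD values")
        for key in self.group_pvd_params:
            outcome, region, timepoint = key
            if outcome not in OUTCOMES or region not in REGIONS or timepoint not in TIMEPOINTS:
                raise ValueError(f"unknown group_pvd_params key {key}")


@dataclass
class AnimalRecord:
    animal_id: str
    outcome: str
    pvd: dict[tuple[str, str], float]  # (region, timepoint) -> PVD %

    def __post_init__(self) -> None:
        if self.outcome not in OUTCOMES:
            raise ValueError(f"outcome must be one of {OUTCOMES}, got {self.outcome!r}")
        for key, value in self.pvd.items():
            if not 0.0 <= value <= 100.0:
                raise ValueError(f"PVD out of [0, 100] for {self.animal_id} {key}: {value}")


@dataclass
class CohortTable:
    records: list[AnimalRecord]
    provenance: CohortSpec | None = None

    def __len__(self) -> int:
        return len(self.records)

    def values(self, region: str, timepoint: str) -> tuple[np.ndarray, np.ndarray]:
        """PVD values and outcome labels for one (region, timepoint) scenario."""
        vals = np.array([r.pvd[(region, timepoint)] for r in self.records])
        labels = np.array([r.outcome for r in self.records])
        return vals, labels

    def to_dataframe(self) -> pd.DataFrame:
        rows = [
            {
                "animal_id": r.animal_id,
                "outcome": r.outcome,
                "region": region,
                "timepoint": timepoint,
                "pvd_percent": r.pvd[(region, timepoint)],
            }
            for r in self.records
            for region in REGIONS
            for timepoint in TIMEPOINTS
        ]
        return pd.DataFrame(rows, columns=COHORT_CSV_COLUMNS)

    def to_csv(self, path: str | Path) -> None:
        self.to_dataframe().to_csv(path, index=False)

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame) -> "CohortTable":
        missing = set(COHORT_CSV_COLUMNS) - set(df.columns)
        if missing:
            raise ValueError(f"cohort table missing columns: {sorted(missing)}")
        records = []
        for animal_id, sub in df.groupby("animal_id", sort=False):
            outcomes = sub["outcome"].unique()
            if len(outcomes) != 1:
                raise ValueError(f"inconsistent outcome labels for animal {animal_id}")
            pvd = {
                (row.region, row.timepoint): float(row.pvd_percent)
                for row in sub.itertuples()
            }
            records.append(AnimalRecord(str(animal_id), str(outcomes[0]), pvd))
        return cls(records=records)

    @classmethod
    def from_csv(cls, path: str | Path) -> "CohortTable":
        return cls.from_dataframe(pd.read_csv(path))


def _clipped_normal_moments(
    mu: float, sigma: float, lo: float | None, hi: float | None
) -> tuple[float, float]:
    """Mean and SD of clip(N(mu, sigma), lo, hi) (winsorised normal)."""
    a = -np.inf if lo is None else (lo - mu) / sigma
    b = np.inf if hi is None else (hi - mu) / sigma
    p_lo = stats.norm.cdf(a)
    p_hi = stats.norm.sf(b)
    p_mid = max(1.0 - p_lo - p_hi, 0.0)
    e1 = 0.0
    e2 = 0.0
    if p_mid > 0:
        m_mid, v_mid = stats.truncnorm.stats(a, b, loc=mu, scale=sigma, moments="mv")
        e1 += p_mid * float(m_mid)
        e2 += p_mid * (float(v_mid) + float(m_mid) ** 2)
    if lo is not None:
        e1 += p_lo * lo
        e2 += p_lo * lo**2
    if hi is not None:
        e1 += p_hi * hi
        e2 += p_hi * hi**2
    return e1, float(np.sqrt(max(e2 - e1**2, 0.0)))


@functools.lru_cache(maxsize=256)
def _calibrate_clipped_normal(
    mean: float, sd: float, lo: float | None, hi: float | None
) -> tuple[float, float]:
    """Latent (mu, sigma) such that clip(N(mu, sigma), lo, hi) has the target moments."""
    if hi is not None and lo is not None:
        max_sd = np.sqrt((mean - lo) * (hi - mean)) if lo < mean < hi else 0.0
        if not lo <= mean <= hi or sd >= max_sd:
            raise ValueError(
                f"group statistics mean={mean}, sd={sd} are infeasible on the "
                f"clamped interval [{lo}, {hi}]"
            )
    if lo is not None and hi is None and mean <= lo:
        raise ValueError(f"group mean {mean} must exceed the lower clamp {lo}")

    def residual(p: np.ndarray) -> list[float]:
        mu, log_sigma = p
        e, s = _clipped_normal_moments(mu, float(np.exp(log_sigma)), lo, hi)
        return [e - mean, s - sd]

    sol = optimize.root(residual, x0=[mean, np.log(sd)], method="hybr")
    if not sol.success or max(abs(r) for r in sol.fun) > 1e-8:
        raise ValueError(
            f"could not calibrate latent normal for target mean={mean}, sd={sd} "
            f"on [{lo}, {hi}]: {sol.message}"
        )
    return float(sol.x[0]), float(np.exp(sol.x[1]))


def _draw_cell(
    rng: np.random.Generator,
    n: int,
    target: GroupStats,
    lo: float | None,
    hi: float | None,
) -> np.ndarray:
    """n draws whose clipped population moments match the target stats."""
    lo_eff = 0.0 if lo is None else lo
    if target.sd == 0.0:
        value = min(max(target.mean, lo_eff), hi) if hi is not None else max(target.mean, lo_eff)
        return np.full(n, value)
    mu, sigma = _calibrate_clipped_normal(target.mean, target.sd, lo_eff, hi)
    x = rng.normal(mu, sigma, size=n)
    return np.clip(x, lo_eff, hi)


def _animal_rng(master_seed: int, index: int) -> np.random.Generator:
    # fixed arithmetic so each animal's draws are individually reproducible
    return np.random.default_rng(np.random.SeedSequence(entropy=master_seed, spawn_key=(index,)))


def generate_cohort(spec: CohortSpec) -> CohortTable:
    """Generate a cohort with the configured group statistics.

    Per group and (region, timepoint) cell, values are drawn from a
    moment-calibrated clipped normal (clip at 0; the 24 h peri-tumour cells
    clip at the separation extremes).  The maximum responder and the
    minimum non-responder peri-tumour 24 h values are then set exactly to
    the extremes, so the cohort exhibits complete separation at 24 h and a
    midpoint threshold equal to their average, at every seed.  Responder
    tumour PVD at 24 h is zero; exactly ``n_nonresp_zero_tumour_24h``
    non-responders have zero tumour PVD at 24 h, the remainder draw
    positive values floored at ``tumour_positive_floor``.
    """
    ext_lo, ext_hi = spec.separation_extremes
    n_resp, n_nonresp = spec.n_responders, spec.n_nonresponders
    params = spec.group_pvd_params

    def cell(outcome: str, region: str, timepoint: str) -> GroupStats:
        try:
            return params[(outcome, region, timepoint)]
        except KeyError as exc:
            raise ValueError(f"group_pvd_params missing cell {(outcome, region, timepoint)}") from exc

    # per-animal draws in a fixed (region, timepoint) order
    table: dict[tuple[str, str, str], np.ndarray] = {}
    for outcome, n in (("responder", n_resp), ("non-responder", n_nonresp)):
        offset = 0 if outcome == "responder" else n_resp
        rngs = [_animal_rng(spec.seed, offset + i) for i in range(n)]
        for region in REGIONS:
            for timepoint in TIMEPOINTS:
                target = cell(outcome, region, timepoint)
                if region == "peri-tumour" and timepoint == "24h":
                    lo, hi = (0.0, ext_lo) if outcome == "responder" else (ext_hi, None)
                elif (
                    region == "tumour" and timepoint == "24h" and outcome == "non-responder"
                ):
                    lo, hi = spec.tumour_positive_floor, None
                else:
                    lo, hi = 0.0, None
                vals = np.concatenate(
                    [_draw_cell(rng, 1, target, lo, hi) for rng in rngs]
                ) if n else np.empty(0)
                table[(outcome, region, timepoint)] = vals

    # force the separation extremes exactly (midpoint threshold = their mean)
    if n_resp:
        v = table[("responder", "peri-tumour", "24h")]
        v[np.argmax(v)] = ext_lo
    if n_nonresp:
        v = table[("non-responder", "peri-tumour", "24h")]
        v[np.argmin(v)] = ext_hi

    # tumour 24 h: responders all zero; a seed-chosen subset of non-responders zero
    if n_resp:
        target = cell("responder", "tumour", "24h")
        if target.mean == 0.0 and target.sd == 0.0:
            table[("responder", "tumour", "24h")] = np.zeros(n_resp)
    if n_nonresp:
        master = np.random.default_rng(
            np.random.SeedSequence(entropy=spec.seed, spawn_key=(10_000,))
        )
        zero_idx = master.permutation(n_nonresp)[: spec.n_nonresp_zero_tumour_24h]
        table[("non-responder", "tumour", "24h")][zero_idx] = 0.0

    records: list[AnimalRecord] = []
    for outcome, n, prefix in (("responder", n_resp, "R"), ("non-responder", n_nonresp, "N")):
        for i in range(n):
            pvd = {
                (region, timepoint): float(table[(outcome, region, timepoint)][i])
                for region in REGIONS
                for timepoint in TIMEPOINTS
            }
            records.append(AnimalRecord(f"{prefix}{i + 1:02d}", outcome, pvd))
    return CohortTable(records=records, provenance=replace(spec))
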