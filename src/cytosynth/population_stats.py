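"""Per-population biosynthesis statistics.

Transformed medians and median shifts relative to a control condition
(a log-fold-change analog on the arcsinh scale), IdU-positive fractions
with the 4% reporting rule, ordinary nonparametric bootstrap confidence
intervals for the median (R = 1000, 95% percentile CI by default), and the
star notation for Friedman-Rafsky p-value bins.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .io_core import EventTable
from .preprocess import DEFAULT_COFACTOR, DEFAULT_IDU_THRESHOLD, idu_positive

__all__ = [
    "StatParams",
    "BootstrapSummary",
    "transformed_median",
    "median_shift",
    "idu_fraction_report",
    "bootstrap_median",
    "shift_table",
    "star_bins",
]


@dataclass
class StatParams:
    bootstrap_R: int = 1000
    ci_level: float = 0.95
    idu_threshold: float = DEFAULT_IDU_THRESHOLD
    idu_report_min: float = 0.04
    cofactor: float = DEFAULT_COFACTOR
    seed: int = 0

    def __post_init__(self) -> None:
        if self.bootstrap_R < 1:
            raise ValueError("bootstrap_R must be >= 1")
        if not 0 < self.ci_level < 1:
            raise ValueError("ci_level must be in (0, 1)")


@dataclass
class BootstrapSummary:
    point_estimate: float
    boot_median: float
    ci_low: float
    ci_high: float
    R: int

    def __post_init__(self) -> None:
        if not (self.ci_low <= self.boot_median <= self.ci_high):
            raise ValueError("bootstrap summary out of order")


def transformed_median(values: np.ndarray, cofactor: float = DEFAULT_COFACTOR) -> float:
    """Median on the arcsinh scale.

    The transform is strictly monotone, so for odd n without ties this
    equals the arcsinh of the raw median.
    """
    values = np.asarray(values, dtype=float)
    if values.size == 0:
        raise ValueError("no values")
    return float(np.median(np.arcsinh(values / cofactor)))


def median_shift(
    pop_values: np.ndarray, control_values: np.ndarray, cofactor: float = DEFAULT_COFACTOR
) -> float:
    """Difference of arcsinh-transformed medians, population minus control."""
    return transformed_median(pop_values, cofactor) - transformed_median(
        control_values, cofactor
    )


def idu_fraction_report(
    parent: EventTable, params: StatParams | None = None
) -> tuple[float, tuple[EventTable, EventTable] | None]:
    """IdU-positive fraction of a parent population, with the reporting rule.

    The positive/negative split is returned only when more than
    ``idu_report_min`` (default 4%) of the parent is IdU positive;
    otherwise the split is suppressed and only the fraction reported.
    """
    params = params or StatParams()
    pos = idu_positive(parent, threshold=params.idu_threshold)
    fraction = float(pos.mean()) if parent.n_events else 0.0
    if fraction > params.idu_report_min:
        return fraction, (parent.subset(pos), parent.subset(~pos))
    return fraction, None


def bootstrap_median(
    values: np.ndarray, params: StatParams | None = None, seed: int | None = None
) -> BootstrapSummary:
    """Ordinary nonparametric bootstrap of the median, percentile CI.

    R resamples of size n with replacement; deterministic given the seed.
    """
    params = params or StatParams()
    x = np.asarray(values, dtype=float)
    n = x.size
    if n == 0:
        raise ValueError("cannot bootstrap an empty sample")
    rng = np.random.default_rng(params.seed if seed is None else seed)
    R = params.bootstrap_R
    reps = np.empty(R)
    chunk = max(1, int(2e7) // max(n, 1))
    for lo in range(0, R, chunk):
        r = min(chunk, R - lo)
        idx = rng.integers(0, n, size=(r, n))
        reps[lo : lo + r] = np.median(x[idx], axis=1)
    alpha = 1.0 - params.ci_level
    lo_q, hi_q = np.quantile(reps, [alpha / 2, 1 - alpha / 2])
    return BootstrapSummary(
        point_estimate=float(np.median(x)),
        boot_median=float(np.median(reps)),
        ci_low=float(lo_q),
        ci_high=float(hi_q),
        R=R,
    )


def shift_table(
    values_by_group: Mapping[tuple[str, str], np.ndarray],
    channels: Sequence[str],
    control_condition: str,
    cofactor: float = DEFAULT_COFACTOR,
) -> pd.DataFrame:
    """Median-shift matrix over (population, condition) groups.

    ``values_by_group`` maps (population, condition) to a raw-count event
    matrix with one column per entry of ``channels`` (populations matched
    across conditions by name, events pooled across same-annotation
    clusters). Cells are differences of arcsinh-transformed medians versus
    the same population in the control condition; the control column is
    identically zero, and a population absent at a condition yields NaN,
    not zero.
    """
    populations = sorted({p for p, _ in values_by_group})
    conditions = list(dict.fromkeys(c for _, c in values_by_group))
    if control_condition not in conditions:
        raise ValueError(f"control condition {control_condition!r} not present")
    index = pd.MultiIndex.from_product(
        [populations, conditions], names=["population", "condition"]
    )
    out = pd.DataFrame(np.nan, index=index, columns=list(channels))
    for pop in populations:
        ctrl = values_by_group.get((pop, control_condition))
        if ctrl is None:
            continue
        for cond in conditions:
            vals = values_by_group.get((pop, cond))
            if vals is None:
                continue
            for j, ch in enumerate(channels):
                out.loc[(pop, cond), ch] = median_shift(
                    vals[:, j], ctrl[:, j], cofactor
                )
    return out


def star_bins(p: float) -> str:
    """Significance stars for FR p-values, per decade-of-seven bins.

    "*" for 1e-14 < p < 1e-7, "**" for 1e-21 < p < 1e-14, "***" for
    1e-28 < p < 1e-21, "****" for p < 1e-28, empty otherwise.
    """
    if not 0 <= p <= 1:
        raise ValueError("p must be in [0, 1]")
    if p < 1e-28:
        return "****"
    if p < 1e-21:
        return "***"
    if p < 1e-14:
        return "**"
    if p < 1e-7:
        return "*"
    return ""
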