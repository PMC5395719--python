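"""Binomial downsampling of TMB: measurement deviation vs megabases sequenced.

Each replicate draws the number of observed mutations when sequencing ``mb``
megabases of a genome whose true burden is ``true_tmb`` mutations/Mb:
k ~ Binomial(n = round(mb * 1e6), p = true_tmb * 1e-6); the observed TMB is
k / mb and the deviation is reported as 100 * |observed - true| / true.
Summary quantiles (10th, 50th, 90th) use linear interpolation between order
statistics.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd


class DownsampleError(ValueError):
    pass


@dataclass
class DownsampleResult:
    true_tmb: float
    mb_sequenced: float
    n_reps: int
    deviations: np.ndarray = field(repr=False)
    median: float = 0.0
    q10: float = 0.0
    q90: float = 0.0

    def __post_init__(self) -> None:
        if len(self.deviations) != self.n_reps:
            raise DownsampleError("deviations length must equal n_reps")


def simulate_observed_tmb(
    true_tmb: float,
    mb: float,
    n_reps: int = 1000,
    seed: int | np.random.Generator = 0,
) -> DownsampleResult:
    """Simulate the percent deviation of observed TMB at a given territory."""
    if true_tmb <= 0:
        raise DownsampleError(f"true_tmb must be > 0, got {true_tmb}")
    if mb <= 0:
        raise DownsampleError(f"mb must be > 0, got {mb}")
    if n_reps < 1:
        raise DownsampleError(f"n_reps must be >= 1, got {n_reps}")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    n = int(round(mb * 1e6))
    p = true_tmb * 1e-6
    if p > 1:
        raise DownsampleError(f"true_tmb {true_tmb} implies p > 1")
    k = rng.binomial(n, p, size=n_reps)
    observed = k / mb
    deviations = 100.0 * np.abs(observed - true_tmb) / true_tmb
    q10, med, q90 = np.quantile(deviations, [0.1, 0.5, 0.9])
    return DownsampleResult(
        true_tmb=true_tmb,
        mb_sequenced=mb,
        n_reps=n_reps,
        deviations=deviations,
        median=float(med),
        q10=float(q10),
        q90=float(q90),
    )


def deviation_grid(
    tmb_levels: Sequence[float],
    mb_grid: Sequence[float],
    n_reps: int = 1000,
    seed: int = 0,
) -> pd.DataFrame:
    """One DownsampleResult summary row per (true TMB, Mb) pair.

    Reproducible under a fixed seed: each cell gets its own substream so the
    grid shape does not perturb the draws of other cells.
    """
    if len(tmb_levels) == 0 or len(mb_grid) == 0:
        raise DownsampleError("tmb_levels and mb_grid must be non-empty")
    ss = np.random.SeedSequence(seed)
    children = ss.spawn(len(tmb_levels) * len(mb_grid))
    rows = []
    i = 0
    for tmb in tmb_levels:
        for mb in mb_grid:
            res = simulate_observed_tmb(
                tmb, mb, n_reps, np.random.default_rng(children[i])
            )
            i += 1
            rows.append(
                {
                    "true_tmb": tmb,
                    "mb": mb,
                    "n_reps": n_reps,
                    "median_deviation_pct": res.median,
                    "q10_deviation_pct": res.q10,
                    "q90_deviation_pct": res.q90,
                }
            )
    return pd.DataFrame(rows)


def analytic_relative_sd(true_tmb: float, mb: float) -> float:
    """Closed-form relative SD (fraction) of observed TMB: sqrt((1-p)/(n p))."""
    n = int(round(mb * 1e6))
    p = true_tmb * 1e-6
    return float(np.sqrt((1 - p) / (n * p)))
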