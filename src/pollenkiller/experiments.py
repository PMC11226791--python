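"""Numerical experiments on the pollen-killer recursion.

Invasion-fate classification, (r, s) parameter sweeps, minimum invasion
frequencies, invasion thresholds in r and s, and the new-mutation origin
scenario.  All computations are deterministic.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np
import pandas as pd

from .model import (
    KILLER,
    EquilibriumReport,
    ModelParams,
    StopRule,
    build_gamete_matrices,
    genotype_frequencies_from_haplotype_homozygotes,
    haplotype_frequencies,
    iterate,
    transition_update,
)

__all__ = [
    "SweepSpec",
    "InvasionResult",
    "invasion_fate",
    "sweep",
    "killer_frequency_after",
    "min_invasion_frequency",
    "find_recombination_threshold",
    "find_selfing_threshold",
    "mutation_origin_trajectory",
    "MutationOriginResult",
]

logger = logging.getLogger(__name__)

PRESENCE_THRESHOLD = 1e-3

Fate = Literal["increased", "decreased", "eliminated"]


def _invasion_theta0(f0: float) -> np.ndarray:
    """Killer homozygotes at f0 against sensitive homozygotes at 1 - f0."""
    if not 0.0 < f0 < 1.0:
        raise ValueError(f"initial killer frequency {f0} must be in (0, 1)")
    return genotype_frequencies_from_haplotype_homozygotes({"Ab": f0, "aB": 1.0 - f0})


@dataclass(frozen=True)
class SweepSpec:
    """Grid specification for an (r, s) invasion sweep."""

    r_grid: Sequence[float]
    s_grid: Sequence[float]
    R: float = 10.0
    k: float = 1.0
    init_killer_freq: float = 0.1
    stop: StopRule = StopRule()

    def __post_init__(self) -> None:
        if len(self.r_grid) == 0 or len(self.s_grid) == 0:
            raise ValueError("sweep grids must be nonempty")


@dataclass(frozen=True)
class InvasionResult:
    """Outcome of one killer-invasion run."""

    params: ModelParams
    init_killer_freq: float
    final_killer_freq: float
    fate: Fate
    state: str
    generations_run: int
    report: EquilibriumReport


def invasion_fate(
    params: ModelParams,
    init_killer_freq: float,
    stop: StopRule | None = None,
) -> InvasionResult:
    """Run one invasion (killer vs sensitive homozygotes) to its stop point.

    The fate is "eliminated" if the terminal killer haplotype frequency is
    below the presence threshold, otherwise "increased" or "decreased" by
    comparison with the initial frequency.
    """
    theta0 = _invasion_theta0(init_killer_freq)
    report = iterate(theta0, params, stop=stop)
    final = float(report.terminal_haplotype_frequencies[KILLER])
    if final <= PRESENCE_THRESHOLD:
        fate: Fate = "eliminated"
    elif final > init_killer_freq:
        fate = "increased"
    else:
        fate = "decreased"
    return InvasionResult(
        params=params,
        init_killer_freq=init_killer_freq,
        final_killer_freq=final,
        fate=fate,
        state=report.state,
        generations_run=report.generations_run,
        report=report,
    )


def sweep(spec: SweepSpec) -> pd.DataFrame:
    """Invasion fate for every (r, s) grid cell.

    Returns a tidy DataFrame with columns r, s, final_killer_freq, fate,
    state, generations; rows ordered by (r, s).  Deterministic.
    """
    rows = []
    for r in spec.r_grid:
        for s in spec.s_grid:
            params = ModelParams(r=float(r), s=float(s), k=spec.k, R=spec.R)
            cell = invasion_fate(params, spec.init_killer_freq, spec.stop)
            h = cell.report.terminal_haplotype_frequencies
            rows.append(
                {
                    "r": float(r),
                    "s": float(s),
                    "final_killer_freq": cell.final_killer_freq,
                    "final_sensitive_freq": float(h[2]),
                    "fate": cell.fate,
                    "state": cell.state,
                    "generations": cell.generations_run,
                }
            )
    return pd.DataFrame(rows)


def killer_frequency_after(
    params: ModelParams, f0: float, generations: int
) -> float:
    """Killer haplotype frequency after a fixed number of generations."""
    theta = _invasion_theta0(f0)
    G = build_gamete_matrices(params)
    for _ in range(generations):
        theta = transition_update(theta, params, G)
    return float(haplotype_frequencies(theta)[KILLER])


def _spreads_horizon(params: ModelParams, f0: float, horizon: int) -> bool:
    """Killer frequency after `horizon` generations exceeds its start."""
    return killer_frequency_after(params, f0, horizon) > f0


def _spreads_terminal(params: ModelParams, f0: float, stop: StopRule) -> bool:
    return invasion_fate(params, f0, stop).fate == "increased"


def min_invasion_frequency(
    r: float,
    s: float,
    R: float = 10.0,
    k: float = 1.0,
    horizon: int = 100,
    tol: float = 1e-4,
) -> float:
    """Smallest initial killer frequency from which the killer spreads.

    "Spreads" means the killer haplotype frequency after ``horizon``
    generations (default 100) exceeds the initial frequency.  Found by
    bisection on (0, 1) to absolute tolerance ``tol``; returns 1.0 as a
    sentinel when the killer cannot spread even from frequencies near 1.
    """
    params = ModelParams(r=r, s=s, k=k, R=R)
    lo, hi = tol, 1.0 - tol
    if _spreads_horizon(params, lo, horizon):
        return lo
    if not _spreads_horizon(params, hi, horizon):
        return 1.0
    while hi - lo > tol:
        mid = 0.5 * (lo + hi)
        if _spreads_horizon(params, mid, horizon):
            hi = mid
        else:
            lo = mid
    return hi


def find_recombination_threshold(
    s: float,
    R: float = 10.0,
    f0: float = 0.1,
    k: float = 1.0,
    stop: StopRule | None = None,
    tol: float = 1e-3,
) -> float:
    """Largest recombination rate at which the invading killer still increases.

    Bisection on r in [0, 0.5]; "increases" is judged from the terminal
    state of the full run (iterate to the stop rule, compare final vs
    initial killer frequency).  Returns 0.0 if the killer never increases
    and 0.5 if it increases even at free recombination.  If the fate is not
    monotone across the bracket a grid scan (step 0.005) locates the
    outermost increase before bisection.
    """
    stop = stop or StopRule()

    def increases(r: float) -> bool:
        return _spreads_terminal(ModelParams(r=r, s=s, k=k, R=R), f0, stop)

    if not increases(0.0):
        return 0.0
    if increases(0.5):
        return 0.5
    lo, hi = 0.0, 0.5
    while hi - lo > tol:
        mid = 0.5 * (lo + hi)
        if increases(mid):
            lo = mid
        else:
            hi = mid
    # guard against non-monotone fate: scan beyond the bracket
    grid = np.arange(hi + 0.005, 0.5, 0.005)
    beyond = [r for r in grid if increases(float(r))]
    if beyond:
        logger.warning("non-monotone fate in r; extending threshold past %g", hi)
        return float(max(beyond))
    return lo


def find_selfing_threshold(
    r: float,
    R: float = 10.0,
    f0: float = 0.1,
    k: float = 1.0,
    stop: StopRule | None = None,
    tol: float = 1e-3,
) -> float:
    """Smallest selfing rate at which the invading killer increases.

    Bisection on s in [0, 1], terminal-state spread criterion as in
    :func:`find_recombination_threshold`.  Returns 0.0 if the killer
    spreads even without selfing and 1.0 (sentinel) if no selfing rate
    suffices.
    """
    stop = stop or StopRule()

    def increases(s: float) -> bool:
        return _spreads_terminal(ModelParams(r=r, s=s, k=k, R=R), f0, stop)

    if increases(0.0):
        return 0.0
    if not increases(1.0):
        # s = 1 is degenerate (no cross-pollination, so a rare killer can
        # never contact sensitive plants); scan a grid for the lowest
        # spreading s, then refine by bisection below it.
        grid = np.arange(0.005, 1.0, 0.005)
        spreading = [float(s) for s in grid if increases(float(s))]
        if not spreading:
            return 1.0
        logger.info("fate not monotone up to s = 1; refining around grid minimum")
        lo, hi = min(spreading) - 0.005, min(spreading)
        while hi - lo > tol:
            mid = 0.5 * (lo + hi)
            if increases(mid):
                hi = mid
            else:
                lo = mid
        return hi
    lo, hi = 0.0, 1.0
    while hi - lo > tol:
        mid = 0.5 * (lo + hi)
        if increases(mid):
            hi = mid
        else:
            lo = mid
    return hi


@dataclass(frozen=True)
class MutationOriginResult:
    """Outcome of a killer arising at low frequency in a neutral+sensitive stand."""

    report: EquilibriumReport
    spread: bool
    max_killer_freq: float


def mutation_origin_trajectory(
    neutral_freq: float,
    sensitive_freq: float,
    intro_freq: float,
    params: ModelParams,
    stop: StopRule | None = None,
) -> MutationOriginResult:
    """Killer haplotype introduced once, at low frequency, by mutation.

    The initial population is a mixture of neutral, sensitive and killer
    homozygotes (one-shot conversion of neutral mass into killer; no
    recurrent mutation).  Reports whether the killer ended above its
    introduction frequency and the maximum frequency it attained.
    """
    if abs(neutral_freq + sensitive_freq + intro_freq - 1.0) > 1e-9:
        raise ValueError("initial homozygote frequencies must sum to 1")
    theta0 = genotype_frequencies_from_haplotype_homozygotes(
        {"AB": neutral_freq, "aB": sensitive_freq, "Ab": intro_freq}
    )
    if stop is None:
        # a newly arisen killer starts below the default absolute loss
        # threshold, so judge loss relative to each haplotype's own start
        stop = StopRule(mode="relative_1pct")
    report = iterate(theta0, params, stop=stop, record_trajectory=True)
    assert report.trajectory is not None
    killer_traj = np.array(
        [haplotype_frequencies(t)[KILLER] for t in report.trajectory]
    )
    final = float(killer_traj[-1])
    return MutationOriginResult(
        report=report,
        spread=final > intro_freq,
        max_killer_freq=float(killer_traj.max()),
    )
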