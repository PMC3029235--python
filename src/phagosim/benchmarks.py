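"""Synthetic experiment-like target trajectories.

Single-cell phagocytosis assays report, per event, a noisy target-position
trace together with population statistics of the push-out distance, the
engulfment duration and the fastest inward speed.  This module generates
traces that emulate those observations - a smooth skeleton (outward rise to
the push-out peak, then linear inward motion at the internalization speed
until completion) plus i.i.d. Gaussian tracking noise - so that the metric
extraction and comparison stages can be exercised and validated without any
experimental data.  The skeleton is an emulation of the published population
statistics, not a mechanistic model.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.interpolate import PchipInterpolator
from scipy.stats import truncnorm

from .errors import ConfigurationError, InputError
from .interface import MN_PER_M_TO_PN_PER_UM, cortical_tension
from .observables import COMPLETION_FRACTION, bench_summary
from .scenarios import make_scenario

#: published population statistics per scenario:
#: push-out mean/SD (µm), engulfment-time mean/SD (s), inward speed (nm/s)
POPULATION_STATS = {
    "zymosan": dict(pushout_mean=1.03, pushout_sd=0.30,
                    time_mean=167.0, time_sd=73.0, speed=33.0),
    "antibody": dict(pushout_mean=0.12, pushout_sd=0.14,
                     time_mean=66.0, time_sd=19.0, speed=33.0),
}

DEFAULT_NOISE_SD = 0.05   # µm, sub-pixel tracking scale
SAMPLING_DT = 1.0         # s


@dataclass
class BenchmarkTrace:
    """One synthetic single-target trajectory."""

    time: np.ndarray              # s
    position: np.ndarray          # µm, noisy, outward positive
    tension: np.ndarray           # mN/m
    engulfed_fraction: np.ndarray
    true_params: dict = field(default_factory=dict)


def _draw_truncated(rng, mean, sd, lower=0.0):
    a = (lower - mean) / sd
    return float(truncnorm.rvs(a, np.inf, loc=mean, scale=sd, random_state=rng))


def gen_trace(
    scenario: str,
    seed: int,
    noise_sd: float = DEFAULT_NOISE_SD,
) -> BenchmarkTrace:
    """Generate one noisy experiment-like trace, reproducible per seed.

    The generating parameters (push-out ``d*``, completion time ``T*``,
    inward speed ``v*``) are drawn from the published population statistics
    (truncated at zero where applicable); the noise-free skeleton reproduces
    them exactly under the observables module.
    """
    if scenario not in POPULATION_STATS:
        raise ConfigurationError(f"unknown benchmark scenario {scenario!r}")
    stats = POPULATION_STATS[scenario]
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 2977]))

    d_star = _draw_truncated(rng, stats["pushout_mean"], stats["pushout_sd"])
    T_star = _draw_truncated(rng, stats["time_mean"], stats["time_sd"], lower=20.0)
    v_star = stats["speed"] / 1000.0          # µm/s

    # piecewise skeleton: cubic-smoothed rise to the push-out peak, exactly
    # linear inward motion at v* until completion, then a plateau (the
    # internalized target rides with the cell)
    t_peak = max(5.0, 0.25 * T_star)
    t_end = T_star * 1.2
    d_end = d_star - v_star * (T_star - t_peak)
    rise = PchipInterpolator(
        np.array([0.0, 0.5 * t_peak, t_peak]),
        np.array([0.0, 0.75 * d_star, d_star]),
    )

    grid = np.arange(0.0, t_end + 1e-9, SAMPLING_DT)
    grid = np.unique(np.concatenate([grid, [t_peak, T_star, t_end]]))
    pos = np.empty_like(grid)
    m_rise = grid <= t_peak
    m_desc = (grid > t_peak) & (grid <= T_star)
    pos[m_rise] = rise(grid[m_rise])
    pos[m_desc] = d_star - v_star * (grid[m_desc] - t_peak)
    pos[grid > T_star] = d_end
    if noise_sd > 0:
        pos = pos + rng.normal(0.0, noise_sd, size=len(grid))

    # covered-fraction ramp crossing the completion threshold exactly at T*;
    # contact (nonzero coverage) starts at t=0
    frac = np.clip(grid / T_star, 1e-9, 1.0) * COMPLETION_FRACTION
    frac[grid >= T_star] = np.minimum(
        COMPLETION_FRACTION + (grid[grid >= T_star] - T_star) * 1e-4, 1.0
    )
    cfg = make_scenario(scenario)
    tension = np.array([cortical_tension(t, cfg) for t in grid]) / MN_PER_M_TO_PN_PER_UM

    return BenchmarkTrace(
        time=grid,
        position=pos,
        tension=tension,
        engulfed_fraction=frac,
        true_params=dict(
            pushout_um=d_star, completion_s=T_star,
            inward_speed_nm_per_s=stats["speed"], noise_sd_um=noise_sd,
            scenario=scenario, seed=int(seed),
        ),
    )


def gen_cohort(scenario: str, n: int, seed: int,
               noise_sd: float = DEFAULT_NOISE_SD):
    """Generate ``n`` independent traces (child seeds derived from the master
    seed) and summarize their metrics via the observables module.

    Returns (traces, summary) where summary holds mean and SD of each metric.
    """
    if n < 1:
        raise InputError("cohort size must be at least 1")
    ss = np.random.SeedSequence(int(seed))
    child_seeds = [int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(n)]
    traces = [gen_trace(scenario, s, noise_sd) for s in child_seeds]

    push, times, speeds = [], [], []
    for tr in traces:
        s = bench_summary(tr)
        push.append(s.push_out_distance)
        times.append(s.engulfment_time)
        speeds.append(s.max_inward_speed)
    times = [x for x in times if x is not None]
    summary = {
        "n": n,
        "pushout_mean": float(np.mean(push)),
        "pushout_sd": float(np.std(push, ddof=1)) if n > 1 else 0.0,
        "time_mean": float(np.mean(times)),
        "time_sd": float(np.std(times, ddof=1)) if len(times) > 1 else 0.0,
        "speed_mean": float(np.mean(speeds)),
        "speed_sd": float(np.std(speeds, ddof=1)) if n > 1 else 0.0,
    }
    return traces, summary


def gen_tension_timeline(scenario: str, t_grid) -> np.ndarray:
    """Prescribed cortical-tension timeline (mN/m) on the given grid; shares
    the piecewise-linear law used by the simulation."""
    t_grid = np.asarray(t_grid, float)
    if np.any(np.diff(t_grid) <= 0):
        raise InputError("time grid must be strictly increasing")
    cfg = make_scenario(scenario)
    return np.array([cortical_tension(t, cfg) for t in t_grid]) / MN_PER_M_TO_PN_PER_UM
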