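"""Respiratory trace generator with hysteresis and breath-to-breath variability.

The primary signal is a per-cycle raised-cosine-power waveform
``level + amplitude * (1 - cos^4(pi (t - t0) / T))`` whose flat top is the
end-exhale plateau (positive peaks = end-exhale), with per-cycle
amplitude, period and baseline drawn from configured spreads.  The
secondary signal is the same waveform evaluated with a phase lead so that
(primary, secondary) trajectories trace hysteresis loops.  Breath-holds
stop the waveform clock, freezing both components at the current phase.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ..exceptions import ConfigurationError

__all__ = ["BreathingConfig", "BreathingTrace", "generate_breathing"]


@dataclass
class BreathingConfig:
    """Distributional parameters of the breathing trace.

    Amplitude and baseline are in dimensionless respiratory-depth units
    (the ground-truth coefficient maps carry the mm scale); periods in
    seconds.
    """

    period_mean_s: float = 4.0
    period_sd_s: float = 0.4
    amplitude_mean: float = 1.0
    amplitude_sd: float = 0.15
    baseline_sd: float = 0.06
    phase_lead_fraction: float = 1.0 / 8.0  # fraction of the mean period
    breath_holds: tuple = ()  # ((start_s, duration_s), ...)


@dataclass
class BreathingTrace:
    """Sampled respiratory state plus the generating cycle parameters."""

    times_s: np.ndarray
    primary: np.ndarray
    secondary: np.ndarray
    cycle_params: list  # dicts: start_s (virtual), period_s, amplitude, baseline
    breath_hold_intervals: list
    _eval: callable = field(repr=False, default=None)
    _virtual: callable = field(repr=False, default=None)

    def value_at(self, times):
        """Primary and secondary components at arbitrary times (seconds)."""
        tau = self._virtual(np.asarray(times, float))
        return self._eval(tau)


def _draw_cycles(rng, cfg: BreathingConfig, span_s: float) -> list:
    cycles = []
    t = 0.0
    while t < span_s + cfg.period_mean_s:
        period = max(1.0, rng.normal(cfg.period_mean_s, cfg.period_sd_s))
        amplitude = max(0.1, rng.normal(cfg.amplitude_mean, cfg.amplitude_sd))
        baseline = rng.normal(0.0, cfg.baseline_sd)
        cycles.append(
            {"start_s": t, "period_s": period, "amplitude": amplitude, "baseline": baseline}
        )
        t += period
    return cycles


def generate_breathing(
    duration_s: float,
    frame_rate_hz: float,
    config: BreathingConfig | None = None,
    seed: int = 0,
) -> BreathingTrace:
    """Generate a seeded breathing trace sampled at the frame rate.

    The returned trace also carries the underlying waveform so that the
    exact respiratory state at arbitrary intermediate times (e.g. the
    interleaved motion-frame times) can be queried via ``value_at``.
    """
    cfg = config or BreathingConfig()
    if duration_s <= 0 or frame_rate_hz <= 0:
        raise ConfigurationError("duration and frame rate must be positive")
    if cfg.period_sd_s < 0 or cfg.amplitude_sd < 0 or cfg.baseline_sd < 0:
        raise ConfigurationError("variability spreads must be >= 0")
    holds = [tuple(map(float, h)) for h in cfg.breath_holds]
    for start, dur in holds:
        if dur < 0 or start < 0 or start + dur > duration_s:
            raise ConfigurationError(
                f"breath-hold ({start}, {dur}) outside acquisition duration {duration_s}"
            )

    rng = np.random.default_rng(seed)
    lead = cfg.phase_lead_fraction * cfg.period_mean_s
    cycles = _draw_cycles(rng, cfg, duration_s + lead)
    starts = np.array([c["start_s"] for c in cycles])
    ends = starts + np.array([c["period_s"] for c in cycles])
    levels = np.array([c["baseline"] for c in cycles])
    amps = np.array([c["amplitude"] for c in cycles])
    periods = np.array([c["period_s"] for c in cycles])
    # trough level interpolates linearly between consecutive cycles so the
    # waveform is continuous across cycle boundaries
    next_levels = np.append(levels[1:], levels[-1])

    def waveform(tau):
        tau = np.atleast_1d(np.asarray(tau, float))
        idx = np.clip(np.searchsorted(ends, tau, side="right"), 0, len(cycles) - 1)
        frac = np.clip((tau - starts[idx]) / periods[idx], 0.0, 1.0)
        level = levels[idx] + (next_levels[idx] - levels[idx]) * frac
        return level + amps[idx] * (1.0 - np.cos(np.pi * frac) ** 4)

    def virtual_time(t):
        t = np.atleast_1d(np.asarray(t, float))
        tau = t.copy()
        for start, dur in holds:
            tau = tau - np.clip(tau - start, 0.0, dur)
        return tau

    def evaluate(tau):
        return waveform(tau), waveform(tau + lead)

    times = np.arange(0.0, duration_s, 1.0 / frame_rate_hz)
    primary, secondary = evaluate(virtual_time(times))
    return BreathingTrace(
        times_s=times,
        primary=primary,
        secondary=secondary,
        cycle_params=cycles,
        breath_hold_intervals=[(s, s + d) for s, d in holds],
        _eval=evaluate,
        _virtual=virtual_time,
    )
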