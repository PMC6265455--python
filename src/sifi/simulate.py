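"""Synthetic-data generators with known ground truth.

Every experimental input of the analysis pipeline can be generated here with
its true parameters recorded, so each analysis stage is verifiable by
parameter recovery:

* a Gaussian instrument response function (IRF) of configurable FWHM;
* TCSPC decays: multi-exponential emission convolved with the IRF over the
  pulse repetition period, flat background, Poisson counting noise, scaled
  to the acquisition stopping rule (expected counts in the peak channel);
* single-molecule intensity traces: a two-state continuous-time Markov chain
  (open/closed hairpin) observed through frame integration, with the exact
  within-frame state occupancy setting each frame's expected brightness;
* abasic-position lifetime profiles: a damped ~10 bp cosine modulation on a
  baseline, plus a near-nick dip, realised as conformer-population exchange
  between the stacked and unstacked Cy3 states and emitted either as summary
  values or as full simulated decays.

All generators are deterministic functions of their seed.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .histogram import DecayHistogram
from .instrument import ABASIC_HAIRPIN, InstrumentConfig, PhotophysicsModel
from .smkinetics import IntensityTrace
from . import tcspc

__all__ = [
    "simulate_irf",
    "simulate_decay",
    "simulate_trace",
    "simulate_position_profile",
    "TraceSimConfig",
    "ProfileSimConfig",
    "NearFieldDip",
    "PositionProfileDataset",
]


# ---------------------------------------------------------------------------
# IRF and decays


def simulate_irf(
    cfg: InstrumentConfig, seed: int = 0, noiseless: bool = False
) -> DecayHistogram:
    """Generate a Gaussian IRF histogram.

    The peak expected count equals ``cfg.peak_target``; for the default
    120 ps FWHM on 8 ps channels the total is well above 1e5 counts, as in a
    real IRF acquisition. ``noiseless=True`` returns the analytic expected
    curve (no Poisson draw).
    """
    t = (np.arange(cfg.n_channels) + 0.5) * cfg.channel_width
    sigma = cfg.irf_sigma
    expected = cfg.peak_target * np.exp(-0.5 * ((t - cfg.irf_position) / sigma) ** 2)
    if noiseless:
        counts = expected
    else:
        rng = np.random.default_rng(seed)
        counts = rng.poisson(expected).astype(float)
    return DecayHistogram(
        channel_width=cfg.channel_width,
        counts=counts,
        kind="irf",
        metadata={
            "channel_width_ps": cfg.channel_width * 1e3,
            "rep_rate_mhz": cfg.rep_rate,
            "irf_fwhm_ps": cfg.irf_fwhm * 1e3,
            "seed": seed,
            "noiseless": noiseless,
        },
    )


def simulate_decay(
    model: PhotophysicsModel,
    cfg: InstrumentConfig,
    irf: DecayHistogram,
    seed: int = 0,
    noiseless: bool = False,
) -> DecayHistogram:
    """Generate a TCSPC decay for ``model`` measured through ``irf``.

    The expected curve is the circular convolution of the IRF with the
    multi-exponential decay over one repetition period, scaled so that the
    expected peak-channel count (including background) equals
    ``cfg.peak_target``; counts are then drawn once from Poisson statistics,
    reproducing the "accumulate until N counts in the peak channel"
    stopping rule without event-by-event simulation.
    """
    if irf.n_channels != cfg.n_channels or not np.isclose(
        irf.channel_width, cfg.channel_width
    ):
        raise ValueError("IRF is not on the instrument's channel grid")
    if any(t < cfg.channel_width for t in model.lifetimes):
        warnings.warn(
            "a lifetime is shorter than one channel and will not be resolvable",
            stacklevel=2,
        )
    signal = tcspc.expected_curve(
        irf.counts,
        cfg.channel_width,
        model.lifetimes,
        model.amplitudes,
        background=0.0,
        irf_shift=0.0,
        n_period=cfg.n_period_channels,
        n_out=cfg.n_channels,
    )
    scale = (cfg.peak_target - cfg.background_rate) / signal.max()
    if scale <= 0:
        raise ValueError("peak_target must exceed the background rate")
    expected = signal * scale + cfg.background_rate
    if noiseless:
        counts = expected
    else:
        rng = np.random.default_rng(seed)
        counts = rng.poisson(expected).astype(float)
    return DecayHistogram(
        channel_width=cfg.channel_width,
        counts=counts,
        kind="decay",
        metadata={
            "channel_width_ps": cfg.channel_width * 1e3,
            "rep_rate_mhz": cfg.rep_rate,
            "peak_target": cfg.peak_target,
            "seed": seed,
            "noiseless": noiseless,
            "true_lifetimes_ns": list(model.lifetimes),
            "true_amplitudes": list(model.amplitudes),
            "true_background": cfg.background_rate,
            "label": model.label,
        },
    )


# ---------------------------------------------------------------------------
# single-molecule traces


@dataclass(frozen=True)
class TraceSimConfig:
    """Two-state trace simulation parameters.

    ``k_open`` is the closed->open rate and ``k_close`` the open->closed
    rate (both s^-1). ``i_open`` is the mean open-state (dim) signal in
    counts/frame and ``enhancement`` the closed/open brightness ratio.
    """

    k_open: float = 1.0
    k_close: float = 1.0
    frame_time: float = 0.050
    i_open: float = 100.0
    enhancement: float = 2.5
    bleach_rate: float = 0.0
    duration: float = 100.0
    noise_model: str = "poisson"
    background: float = 0.0
    read_noise_sd: float = 3.0
    start_state: Optional[str] = None  # "open", "closed" or None (stationary)

    def __post_init__(self) -> None:
        if self.k_open < 0 or self.k_close < 0 or self.bleach_rate < 0:
            raise ValueError("rates must be non-negative")
        if self.enhancement < 1:
            raise ValueError("enhancement must be >= 1")
        if self.frame_time <= 0:
            raise ValueError("frame_time must be positive")
        if self.duration < 10 * self.frame_time:
            raise ValueError("duration must cover at least 10 frames")
        if self.noise_model not in ("poisson", "poisson+gaussian_background"):
            raise ValueError(f"unknown noise_model {self.noise_model!r}")
        if self.start_state not in (None, "open", "closed"):
            raise ValueError("start_state must be 'open', 'closed' or None")


def _markov_path(cfg: TraceSimConfig, rng: np.random.Generator):
    """Jump segments [(t_start, t_end, state), ...] of the hidden chain."""
    if cfg.start_state is not None:
        state = 1 if cfg.start_state == "closed" else 0
    else:
        total = cfg.k_open + cfg.k_close
        p_closed = cfg.k_close / total if total > 0 else 0.5
        state = 1 if rng.random() < p_closed else 0
    segments = []
    t = 0.0
    while t < cfg.duration:
        rate = cfg.k_open if state == 1 else cfg.k_close
        dt = rng.exponential(1.0 / rate) if rate > 0 else np.inf
        end = min(t + dt, cfg.duration)
        segments.append((t, end, state))
        t = end
        state = 1 - state
    return segments


def simulate_trace(cfg: TraceSimConfig, seed: int = 0) -> IntensityTrace:
    """Simulate one single-molecule trace with its ground-truth state path.

    Each frame's expected signal is the exact time-weighted mixture of the
    open and closed brightness over the hidden Markov path within that frame
    (conformational exchange and photophysics are far faster than the frame
    time, so frames time-average whatever state mixture they contain).
    ``truth_state`` labels each frame by its majority-occupancy state; the
    full jump path is kept in ``metadata["segments"]``.
    """
    rng = np.random.default_rng(seed)
    n_frames = int(np.floor(cfg.duration / cfg.frame_time))
    if n_frames < 10:
        raise ValueError("duration must cover at least 10 frames")
    segments = _markov_path(cfg, rng)

    closed_occ = np.zeros(n_frames)
    for t0, t1, state in segments:
        if state != 1:
            continue
        f0 = int(t0 / cfg.frame_time)
        f1 = min(int(math.ceil(t1 / cfg.frame_time)), n_frames)
        for f in range(f0, f1):
            lo = f * cfg.frame_time
            hi = lo + cfg.frame_time
            closed_occ[f] += max(0.0, min(t1, hi) - max(t0, lo))
    closed_occ /= cfg.frame_time

    signal = cfg.i_open * (1.0 + (cfg.enhancement - 1.0) * closed_occ)

    bleach_time = None
    if cfg.bleach_rate > 0:
        bleach_time = rng.exponential(1.0 / cfg.bleach_rate)
        frames_t = np.arange(n_frames) * cfg.frame_time
        alive = np.clip((bleach_time - frames_t) / cfg.frame_time, 0.0, 1.0)
        signal = signal * alive

    expected = signal + cfg.background
    intensities = rng.poisson(expected).astype(float)
    if cfg.noise_model == "poisson+gaussian_background":
        intensities = intensities + rng.normal(0.0, cfg.read_noise_sd, n_frames)

    truth = (closed_occ >= 0.5).astype(int)
    return IntensityTrace(
        frame_time=cfg.frame_time,
        intensities=intensities,
        truth_state=truth,
        metadata={
            "seed": seed,
            "config": cfg,
            "segments": segments,
            "bleach_time": bleach_time,
            "closed_occupancy": closed_occ,
        },
    )


# ---------------------------------------------------------------------------
# abasic-position profiles


@dataclass(frozen=True)
class NearFieldDip:
    """Gaussian lifetime dip next to the nick (direct stacking into the
    abasic site dominates within the first few base pairs)."""

    depth: float = 0.45  # ns
    width: float = 2.0  # bp (Gaussian sigma)


@dataclass(frozen=True)
class ProfileSimConfig:
    """Ground truth for an abasic-position lifetime profile.

    The true intensity-weighted lifetime at abasic position ``x`` (bp from
    the nick, 1-based) is

        tau(x) = baseline + A cos(2 pi x / P - phase) exp(-x / damping)
                 - dip.depth * exp(-(x - 1)^2 / (2 dip.width^2))

    With the defaults (P = 10 bp, phase = pi) the modulation peaks at 15 bp,
    crosses the baseline again near 19 bp, and the damping keeps the
    oscillation visible across the ~2 helical turns the positions span. Each position carries
    ``n_decays_total`` replicate measurements split as evenly as possible
    across ``n_experiments`` independent experiments.
    """

    positions: tuple = (1, 2, 3, 5, 7, 9, 11, 13, 15, 17, 19, 21)
    baseline_tau: float = 1.9  # ns, intensity-weighted, no-abasic control
    mod_amplitude: float = 0.12  # ns
    period: float = 10.0  # bp
    phase: float = math.pi  # radians
    damping_length: float = 25.0  # bp
    nearfield_dip: NearFieldDip = field(default_factory=NearFieldDip)
    noise_sd: float = 0.05  # ns, per-decay replicate scatter
    lifetime_jitter: float = 0.02  # fractional sample-to-sample lifetime drift
    n_experiments: int = 3
    n_decays_total: int = 13
    seed: int = 0

    def __post_init__(self) -> None:
        pos = tuple(self.positions)
        if any(p < 1 for p in pos) or any(b <= a for a, b in zip(pos, pos[1:])):
            raise ValueError("positions must be strictly increasing and >= 1")
        if self.period <= 0:
            raise ValueError("period must be positive")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.n_experiments < 1 or self.n_decays_total < self.n_experiments:
            raise ValueError("need at least one decay per experiment")

    def true_profile(self, x) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        cosine = self.mod_amplitude * np.cos(
            2.0 * np.pi * x / self.period - self.phase
        ) * np.exp(-x / self.damping_length)
        dip = -self.nearfield_dip.depth * np.exp(
            -((x - 1.0) ** 2) / (2.0 * self.nearfield_dip.width**2)
        )
        return self.baseline_tau + cosine + dip


def _amplitudes_for_tau_int(
    target: float, lifetimes, alpha_mid: float = 0.25
) -> np.ndarray:
    """Stacked/unstacked population exchange reaching a target tau_bar.

    The intermediate population is held fixed while the stacked (long) and
    unstacked (short) populations trade off, mirroring the conformer
    exchange that underlies the lifetime modulation. Solved by bisection;
    targets outside the reachable range are clipped to it.
    """
    t_long, t_mid, t_short = lifetimes
    lo, hi = 1e-3, 1.0 - alpha_mid - 1e-3

    def tau_int(a_long):
        amps = np.array([a_long, alpha_mid, 1.0 - alpha_mid - a_long])
        taus = np.array([t_long, t_mid, t_short])
        return (amps * taus**2).sum() / (amps * taus).sum()

    t_lo, t_hi = tau_int(lo), tau_int(hi)
    target = float(np.clip(target, min(t_lo, t_hi) + 1e-9, max(t_lo, t_hi) - 1e-9))
    a = brentq(lambda a_: tau_int(a_) - target, lo, hi, xtol=1e-12)
    return np.array([a, alpha_mid, 1.0 - alpha_mid - a])


def _experiment_split(n_total: int, n_experiments: int):
    base = n_total // n_experiments
    extra = n_total % n_experiments
    return [base + (1 if i >= n_experiments - extra else 0) for i in range(n_experiments)]


@dataclass
class PositionProfileDataset:
    """Simulated abasic-position dataset: one record per decay measurement.

    ``table`` holds the exact per-decay photophysics (lifetimes, amplitudes
    and derived summaries); in ``mode="decays"`` each record also has a
    simulated decay histogram in ``decays`` keyed by
    ``(position, experiment, replicate)`` (control rows use position 0), and
    the per-decay fitted summaries are produced by :meth:`decay_summaries`.
    """

    config: ProfileSimConfig
    table: pd.DataFrame
    mode: str
    irf: Optional[DecayHistogram] = None
    decays: dict = field(default_factory=dict)
    instrument: Optional[InstrumentConfig] = None

    CONTROL_POSITION = 0

    def decay_summaries(
        self, n_components: int = 3, n_restarts: int = 2, progress: bool = False
    ) -> pd.DataFrame:
        """Per-decay lifetime summaries.

        In summary mode these are the generator's exact values; in decays
        mode every histogram is fitted by tri-exponential reconvolution and
        the summaries are taken from the fits, exercising the full pipeline.
        """
        if self.mode == "summary":
            return self.table.copy()
        rows = []
        keys = list(self.decays)
        iterator = keys
        if progress:
            from tqdm import tqdm

            iterator = tqdm(keys, desc="fitting decays")
        for key in iterator:
            position, experiment, replicate = key
            fit = tcspc.fit_reconvolution(
                self.decays[key],
                self.irf,
                n_components=n_components,
                n_restarts=n_restarts,
                init=list(ABASIC_HAIRPIN.lifetimes),
            )
            f = fit.f_intensity
            rows.append(
                {
                    "position": position,
                    "experiment": experiment,
                    "replicate": replicate,
                    "tau_long": fit.lifetimes[0],
                    "tau_mid": fit.lifetimes[1],
                    "tau_short": fit.lifetimes[2],
                    "tau_amp": fit.amp_weighted,
                    "tau_int": fit.intensity_weighted,
                    "f_long": f[0],
                    "f_mid": f[1],
                    "f_short": f[2],
                    "chi2_reduced": fit.chi2_reduced,
                }
            )
        return pd.DataFrame(rows)


def simulate_position_profile(
    cfg: ProfileSimConfig,
    mode: str = "decays",
    instrument: Optional[InstrumentConfig] = None,
    photophysics: PhotophysicsModel = ABASIC_HAIRPIN,
) -> PositionProfileDataset:
    """Simulate the abasic-position experiment, control construct included.

    For every (position, experiment, replicate) a target intensity-weighted
    lifetime ``true_profile(position) + N(0, noise_sd)`` is realised by
    stacked/unstacked population exchange on ``photophysics`` (component
    lifetimes additionally jittered by ``lifetime_jitter`` per decay, since
    the three lifetimes vary slightly from sample to sample). ``mode``
    selects summary records (fast) or full simulated decays routed through
    the TCSPC channel (end-to-end).
    """
    if mode not in ("summary", "decays"):
        raise ValueError("mode must be 'summary' or 'decays'")
    if instrument is None:
        # a 16.4 ns window (2048 x 8 ps) spans >6 lifetimes of the slowest
        # component and keeps the per-decay fits quick
        instrument = InstrumentConfig(n_channels=2048)
    rng = np.random.default_rng(cfg.seed)
    irf = None
    if mode == "decays":
        irf = simulate_irf(instrument, seed=int(rng.integers(2**31 - 1)))

    split = _experiment_split(cfg.n_decays_total, cfg.n_experiments)
    rows = []
    decays = {}
    all_positions = [PositionProfileDataset.CONTROL_POSITION, *cfg.positions]
    for position in all_positions:
        if position == PositionProfileDataset.CONTROL_POSITION:
            truth = cfg.baseline_tau
        else:
            truth = float(cfg.true_profile(position))
        replicate = 0
        for experiment, n_rep in enumerate(split, start=1):
            for _ in range(n_rep):
                replicate += 1
                target = truth + rng.normal(0.0, cfg.noise_sd)
                taus = np.asarray(photophysics.lifetimes) * np.exp(
                    rng.normal(0.0, cfg.lifetime_jitter, 3)
                )
                amps = _amplitudes_for_tau_int(target, taus)
                f = tcspc.fractional_intensities(taus, amps)
                rows.append(
                    {
                        "position": position,
                        "experiment": experiment,
                        "replicate": replicate,
                        "tau_long": taus[0],
                        "tau_mid": taus[1],
                        "tau_short": taus[2],
                        "tau_amp": tcspc.amplitude_weighted_lifetime(taus, amps),
                        "tau_int": tcspc.intensity_weighted_lifetime(taus, amps),
                        "f_long": f[0],
                        "f_mid": f[1],
                        "f_short": f[2],
                        "true_tau_int": truth,
                    }
                )
                if mode == "decays":
                    model = PhotophysicsModel(
                        lifetimes=tuple(taus), amplitudes=tuple(amps)
                    )
                    decays[(position, experiment, replicate)] = simulate_decay(
                        model,
                        instrument,
                        irf,
                        seed=int(rng.integers(2**31 - 1)),
                    )
    return PositionProfileDataset(
        config=cfg,
        table=pd.DataFrame(rows),
        mode=mode,
        irf=irf,
        decays=decays,
        instrument=instrument,
    )
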