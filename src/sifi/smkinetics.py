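"""Two-state kinetics from single-molecule fluorescence intensity traces.

A surface-immobilised DNA hairpin carrying a single Cy3 reports its
open/closed state through stacking-induced fluorescence increase: the closed
conformation is brighter by up to ~2.5x. Traces recorded at ~50 ms frame
time are segmented into the two intensity levels, dwell times in each state
are collected, and opening/closing rate constants are estimated from the
exponential dwell-time distributions.

Because photoisomerization and stacking/unstacking are orders of magnitude
faster than the frame time, each frame reports the time-averaged brightness
of whichever conformation the hairpin occupies, so a two-level description
is adequate.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from sklearn.mixture import GaussianMixture

__all__ = [
    "IntensityTrace",
    "StateSegmentation",
    "DwellSet",
    "RateEstimates",
    "segment_trace",
    "extract_dwells",
    "DwellTimeModel",
    "fit_dwell_times",
    "enhancement_factor",
]

OPEN, CLOSED = 0, 1


@dataclass
class IntensityTrace:
    """A framed single-molecule intensity time trace.

    ``truth_state`` (1 = closed/bright, 0 = open/dim) is carried by
    simulated traces for parameter-recovery testing.
    """

    frame_time: float
    intensities: np.ndarray
    truth_state: Optional[np.ndarray] = None
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.intensities = np.asarray(self.intensities, dtype=float)
        if self.frame_time <= 0:
            raise ValueError("frame_time must be positive")
        if self.intensities.size < 10:
            raise ValueError("trace must contain at least 10 frames")
        if self.truth_state is not None:
            self.truth_state = np.asarray(self.truth_state, dtype=int)
            if self.truth_state.shape != self.intensities.shape:
                raise ValueError("truth_state length must match intensities")

    @property
    def n_frames(self) -> int:
        return self.intensities.size


@dataclass
class StateSegmentation:
    """Frame-wise open/closed assignment of a trace."""

    states: np.ndarray  # 0 = open, 1 = closed
    threshold: float
    level_means: tuple  # (open, closed)
    level_stds: tuple = (np.nan, np.nan)
    bleach_frame: Optional[int] = None
    no_transitions: bool = False

    def __post_init__(self) -> None:
        self.states = np.asarray(self.states, dtype=int)
        if not self.no_transitions and not self.level_means[1] > self.level_means[0]:
            raise ValueError("closed level must exceed open level")

    @property
    def n_transitions(self) -> int:
        s = self.valid_states
        return int(np.count_nonzero(np.diff(s)))

    @property
    def valid_states(self) -> np.ndarray:
        """States up to the bleach frame (photobleached tail excluded)."""
        if self.bleach_frame is None:
            return self.states
        return self.states[: self.bleach_frame]


@dataclass
class DwellSet:
    """Dwell durations per state, in seconds.

    The first and last dwell of a trace are censored (their true extent is
    unknown) and excluded from rate fitting by default.
    """

    open_dwells: np.ndarray
    closed_dwells: np.ndarray
    open_censored: np.ndarray
    closed_censored: np.ndarray
    frame_time: float
    no_transitions: bool = False

    def uncensored(self, state: str) -> np.ndarray:
        d = self.open_dwells if state == "open" else self.closed_dwells
        c = self.open_censored if state == "open" else self.closed_censored
        return d[~c]

    @staticmethod
    def pool(dwellsets: list) -> "DwellSet":
        """Pool dwells from many molecules into one set for aggregate fitting."""
        if not dwellsets:
            raise ValueError("no dwell sets to pool")
        ft = dwellsets[0].frame_time
        return DwellSet(
            open_dwells=np.concatenate([d.open_dwells for d in dwellsets]),
            closed_dwells=np.concatenate([d.closed_dwells for d in dwellsets]),
            open_censored=np.concatenate([d.open_censored for d in dwellsets]),
            closed_censored=np.concatenate([d.closed_censored for d in dwellsets]),
            frame_time=ft,
        )


@dataclass
class RateEstimates:
    """Opening and closing rate constants with standard errors."""

    k_open: float
    k_open_se: float
    k_close: float
    k_close_se: float
    n_transitions: int
    n_molecules: int = 1
    method: str = "mle"

    def summary(self) -> str:
        return (
            "Two-state dwell-time rate estimates\n"
            "===================================\n"
            f"k_open  = {self.k_open:.4f} +/- {self.k_open_se:.4f} s^-1\n"
            f"k_close = {self.k_close:.4f} +/- {self.k_close_se:.4f} s^-1\n"
            f"transitions: {self.n_transitions}   molecules: {self.n_molecules}   "
            f"method: {self.method}"
        )


# ---------------------------------------------------------------------------
# segmentation


def segment_trace(trace: IntensityTrace, min_separation: float = 2.0) -> StateSegmentation:
    """Threshold a trace into open/closed states.

    A two-component Gaussian mixture is fitted to the intensity histogram;
    the threshold is the midpoint of the two component means. If the two
    modes are closer than ``min_separation`` pooled standard deviations (or
    a one-component model is preferred by BIC), the trace is returned as a
    single-state segmentation with ``no_transitions`` set.

    Photobleaching is detected first, as a terminal run of frames (>= 5)
    falling below 30% of the early-trace level with no recovery; those
    frames are excluded before the mixture is fitted and from all
    downstream analysis.
    """
    full = trace.intensities
    n = full.size

    # terminal photobleach: the dye goes dark in a single irreversible step
    bleach_frame = None
    ref = float(np.median(full[: max(10, n // 10)]))
    if ref > 0:
        dark = full < 0.3 * ref
        if dark[-1]:
            onset = n - 1
            while onset > 0 and dark[onset - 1]:
                onset -= 1
            if n - onset >= 5:
                bleach_frame = onset

    live = full if bleach_frame is None else full[:bleach_frame]
    if live.size < 10:
        m = float(full.mean())
        return StateSegmentation(
            states=np.zeros(n, dtype=int),
            threshold=m,
            level_means=(m, m),
            bleach_frame=bleach_frame,
            no_transitions=True,
        )

    x = live.reshape(-1, 1)
    if np.ptp(x) == 0:
        m = float(x[0, 0])
        return StateSegmentation(
            states=np.zeros(n, dtype=int),
            threshold=m,
            level_means=(m, m),
            bleach_frame=bleach_frame,
            no_transitions=True,
        )
    gmm2 = GaussianMixture(n_components=2, n_init=3, random_state=0).fit(x)
    gmm1 = GaussianMixture(n_components=1, random_state=0).fit(x)
    means = np.sort(gmm2.means_.ravel())
    sds = np.sqrt(gmm2.covariances_.ravel())[np.argsort(gmm2.means_.ravel())]
    pooled_sd = float(np.sqrt(np.mean(sds**2)))
    separation = (means[1] - means[0]) / max(pooled_sd, 1e-12)
    if gmm1.bic(x) <= gmm2.bic(x) or separation < min_separation:
        m = float(x.mean())
        return StateSegmentation(
            states=np.zeros(n, dtype=int),
            threshold=m,
            level_means=(m, m),
            bleach_frame=bleach_frame,
            no_transitions=True,
        )
    threshold = float(means.mean())
    states = (full > threshold).astype(int)
    if bleach_frame is not None:
        states[bleach_frame:] = OPEN

    seg = StateSegmentation(
        states=states,
        threshold=threshold,
        level_means=(float(means[0]), float(means[1])),
        level_stds=(float(sds[0]), float(sds[1])),
        bleach_frame=bleach_frame,
        no_transitions=False,
    )
    if seg.n_transitions == 0:
        seg.no_transitions = True
    return seg


# ---------------------------------------------------------------------------
# dwell extraction


def _runs(states: np.ndarray):
    """(state, length) for each maximal run of equal states."""
    edges = np.flatnonzero(np.diff(states)) + 1
    bounds = np.concatenate([[0], edges, [states.size]])
    return [(int(states[a]), int(b - a)) for a, b in zip(bounds[:-1], bounds[1:])]


def extract_dwells(
    seg: StateSegmentation, frame_time: float, min_frames: int = 1
) -> DwellSet:
    """Convert a segmentation into dwell durations.

    The first and last run are flagged censored. Runs shorter than
    ``min_frames`` are kept but can be filtered by callers; the default of
    one frame keeps every resolvable dwell.
    """
    states = seg.valid_states
    runs = _runs(states)
    if seg.no_transitions or len(runs) < 2:
        return DwellSet(
            open_dwells=np.array([]),
            closed_dwells=np.array([]),
            open_censored=np.array([], dtype=bool),
            closed_censored=np.array([], dtype=bool),
            frame_time=frame_time,
            no_transitions=True,
        )
    od, cd, oc, cc = [], [], [], []
    for i, (state, length) in enumerate(runs):
        if length < min_frames:
            continue
        censored = i == 0 or i == len(runs) - 1
        if state == OPEN:
            od.append(length * frame_time)
            oc.append(censored)
        else:
            cd.append(length * frame_time)
            cc.append(censored)
    return DwellSet(
        open_dwells=np.asarray(od),
        closed_dwells=np.asarray(cd),
        open_censored=np.asarray(oc, dtype=bool),
        closed_censored=np.asarray(cc, dtype=bool),
        frame_time=frame_time,
    )


# ---------------------------------------------------------------------------
# rate fitting


def _flip_probability(dwells_s: np.ndarray, frame_time: float):
    """Per-frame escape probability and its variance from frame-quantised
    dwells (geometric likelihood: p_hat = n / sum(m))."""
    m = np.maximum(np.round(dwells_s / frame_time).astype(int), 1)
    n = m.size
    p = n / m.sum()
    if p >= 1.0:  # every dwell exactly one frame: rate at resolution limit
        p = 1.0 - 1.0 / (2.0 * m.sum())
    return p, p**2 * (1.0 - p) / n


def _sampled_chain_mle(open_dwells, closed_dwells, frame_time: float):
    """Rates from the frame-sampled two-state chain, missed events included.

    The frame-labelled state sequence is the continuous-time two-state
    chain observed at the frame period dt, for which the per-frame flip
    probabilities are exactly

        p_open   = (k_close / K) (1 - exp(-K dt))      (open -> closed)
        p_closed = (k_open  / K) (1 - exp(-K dt))      (closed -> open)

    with K = k_open + k_close. Inverting these (K = -ln(1 - p_open -
    p_closed)/dt, then splitting K by the flip-probability ratio) corrects
    both the half-frame discretisation bias of a naive 1/mean estimate and
    the dwells missed entirely because they are shorter than a frame —
    already >20% of events at k dt = 0.25. Standard errors propagate from
    the geometric-likelihood variances of the two flip probabilities by the
    delta method.
    """
    p_o, var_o = _flip_probability(open_dwells, frame_time)
    p_c, var_c = _flip_probability(closed_dwells, frame_time)

    def rates(po, pc):
        s = min(po + pc, 1.0 - 1e-12)
        big_k = -np.log1p(-s) / frame_time
        return big_k * po / s, big_k * pc / s  # (k_close, k_open)

    k_close, k_open = rates(p_o, p_c)
    eps = 1e-7
    d_po = (np.array(rates(p_o + eps, p_c)) - np.array(rates(p_o - eps, p_c))) / (2 * eps)
    d_pc = (np.array(rates(p_o, p_c + eps)) - np.array(rates(p_o, p_c - eps))) / (2 * eps)
    var = d_po**2 * var_o + d_pc**2 * var_c  # (var k_close, var k_open)
    return float(k_open), float(np.sqrt(var[1])), float(k_close), float(np.sqrt(var[0]))


def _histogram_lsq(dwells_s: np.ndarray, frame_time: float):
    """Single-exponential least-squares fit to the dwell-time histogram.

    Mirrors the conventional analysis of pooled dwell histograms: bins of one
    frame, empty leading bin excluded, unweighted fit of log-counts.
    """
    m = np.maximum(np.round(dwells_s / frame_time).astype(int), 1)
    counts = np.bincount(m)[1:]  # bin zero (sub-frame) excluded
    centers = (np.arange(1, counts.size + 1)) * frame_time
    keep = counts > 0
    if keep.sum() < 3:
        raise ValueError("too few occupied histogram bins for a least-squares fit")
    y = np.log(counts[keep].astype(float))
    t = centers[keep]
    coef, cov = np.polyfit(t, y, 1, w=np.sqrt(counts[keep]), cov=True)
    k = -coef[0]
    se = float(np.sqrt(cov[0, 0]))
    return float(k), se


class DwellTimeModel:
    """Exponential dwell-time model for pooled open/closed dwells.

    Parameters
    ----------
    dwells : DwellSet
        Pooled dwells (censored first/last dwells are excluded).
    min_dwells : int
        Minimum uncensored dwells per state required to fit.
    """

    def __init__(self, dwells: DwellSet, min_dwells: int = 20, n_molecules: int = 1):
        self.dwells = dwells
        self.min_dwells = min_dwells
        self.n_molecules = n_molecules

    def fit(self, method: str = "mle") -> RateEstimates:
        """Estimate k_open (from closed dwells) and k_close (from open dwells).

        ``method="mle"`` inverts the frame-sampled chain likelihood
        (discretisation and missed-event corrected); ``method="histogram"``
        reproduces the least-squares fit to the dwell-time histogram for
        parity with conventional analysis.
        """
        open_d = self.dwells.uncensored("open")
        closed_d = self.dwells.uncensored("closed")
        for name, d in (("open", open_d), ("closed", closed_d)):
            if d.size < self.min_dwells:
                raise ValueError(
                    f"too few uncensored {name} dwells ({d.size} < {self.min_dwells})"
                )
        if method == "mle":
            k_open, k_open_se, k_close, k_close_se = _sampled_chain_mle(
                open_d, closed_d, self.dwells.frame_time
            )
        else:
            # the rate of leaving the closed state is the opening rate
            k_open, k_open_se = _histogram_lsq(closed_d, self.dwells.frame_time)
            k_close, k_close_se = _histogram_lsq(open_d, self.dwells.frame_time)
        return RateEstimates(
            k_open=k_open,
            k_open_se=k_open_se,
            k_close=k_close,
            k_close_se=k_close_se,
            n_transitions=open_d.size + closed_d.size,
            n_molecules=self.n_molecules,
            method=method,
        )


def fit_dwell_times(dwells: DwellSet, method: str = "mle", **kwargs) -> RateEstimates:
    """Functional wrapper around :class:`DwellTimeModel`."""
    return DwellTimeModel(dwells, **kwargs).fit(method=method)


# ---------------------------------------------------------------------------
# enhancement


def enhancement_factor(
    trace: IntensityTrace,
    seg: StateSegmentation,
    background: float = 0.0,
    exclude_boundary: bool = True,
):
    """Closed/open ratio of background-subtracted state-conditional means.

    Frames at dwell boundaries contain a mixture of both levels (the state
    switches inside the frame); with ``exclude_boundary`` they are dropped
    from the conditional means, which removes the resulting bias towards 1.
    Returns ``(ratio, se)`` with the error propagated from the standard
    errors of the two state means.
    """
    states = seg.valid_states
    x = trace.intensities[: states.size]
    keep = np.ones(states.size, dtype=bool)
    if exclude_boundary and states.size > 2:
        switch = np.diff(states) != 0
        keep[1:][switch] = False
        keep[:-1][switch] = False
    xo = x[keep & (states == OPEN)]
    xc = x[keep & (states == CLOSED)]
    if xo.size == 0 or xc.size == 0:
        raise ValueError("both states must be populated to form an enhancement ratio")
    mo = xo.mean() - background
    mc = xc.mean() - background
    if mo <= 0:
        raise ValueError("open-level mean does not exceed background")
    so = xo.std(ddof=1) / np.sqrt(xo.size) if xo.size > 1 else 0.0
    sc = xc.std(ddof=1) / np.sqrt(xc.size) if xc.size > 1 else 0.0
    ratio = mc / mo
    se = ratio * np.sqrt((sc / mc) ** 2 + (so / mo) ** 2)
    return float(ratio), float(se)
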