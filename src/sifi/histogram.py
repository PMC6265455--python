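"""Photon-count histograms for time-correlated single-photon counting (TCSPC).

A :class:`DecayHistogram` is the common container for both fluorescence decays
and instrument response functions (IRFs): photon counts per fixed-width time
channel, plus a small metadata map that travels with the histogram through
file I/O and fitting.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal

import numpy as np

__all__ = ["DecayHistogram", "measure_fwhm"]

#: Minimum number of channels for a histogram to be usable in analysis.
MIN_CHANNELS = 16


@dataclass
class DecayHistogram:
    """Photon counts per time channel.

    Parameters
    ----------
    channel_width : float
        Width of one time channel in nanoseconds (8 ps = 0.008 ns for the
        reference instrument).
    counts : numpy.ndarray
        Non-negative photon counts, one entry per channel.
    kind : {"decay", "irf"}
        Whether this histogram is a fluorescence decay or an instrument
        response function.
    metadata : dict
        Free-form key/value pairs (seed, rep rate, simulation truth, ...);
        preserved losslessly by the text readers/writers.
    """

    channel_width: float
    counts: np.ndarray
    kind: Literal["decay", "irf"] = "decay"
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=float)
        if self.channel_width <= 0:
            raise ValueError("channel_width must be positive")
        if self.counts.ndim != 1 or self.counts.size < MIN_CHANNELS:
            raise ValueError(f"counts must be 1-D with >= {MIN_CHANNELS} channels")
        if np.any(self.counts < 0):
            raise ValueError("counts must be non-negative")
        if self.kind not in ("decay", "irf"):
            raise ValueError(f"unknown histogram kind {self.kind!r}")

    @property
    def n_channels(self) -> int:
        return self.counts.size

    @property
    def times(self) -> np.ndarray:
        """Channel-centre times in nanoseconds."""
        return (np.arange(self.n_channels) + 0.5) * self.channel_width

    @property
    def total_counts(self) -> float:
        return float(self.counts.sum())

    @property
    def peak_channel(self) -> int:
        return int(np.argmax(self.counts))

    def same_grid(self, other: "DecayHistogram") -> bool:
        return (
            self.n_channels == other.n_channels
            and np.isclose(self.channel_width, other.channel_width)
        )


def measure_fwhm(hist: DecayHistogram) -> float:
    """Full width at half maximum of a single-peaked histogram, in ns.

    The half-maximum crossings on either side of the peak are located by
    linear interpolation between the two bracketing channels, the standard
    way an instrument-response width is read off a measured IRF.
    """
    y = hist.counts
    peak = int(np.argmax(y))
    half = y[peak] / 2.0
    if y[peak] <= 0:
        raise ValueError("histogram has no counts")

    # walk left from the peak to the first channel below half maximum
    left = peak
    while left > 0 and y[left] > half:
        left -= 1
    if y[left] > half:
        raise ValueError("left half-maximum crossing outside histogram")
    x_left = left + (half - y[left]) / (y[left + 1] - y[left])

    right = peak
    n = y.size
    while right < n - 1 and y[right] > half:
        right += 1
    if y[right] > half:
        raise ValueError("right half-maximum crossing outside histogram")
    x_right = right - 1 + (y[right - 1] - half) / (y[right - 1] - y[right])

    return (x_right - x_left) * hist.channel_width
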