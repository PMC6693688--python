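"""Flash kinetics: on/off segmentation of tracked intensity, duty cycles,
blink rate, and the across-fish averaged power spectrum.

A track's peak-intensity series is binarised at a level (default: half the
track's 95th-percentile intensity, robust to single hot frames), run-length
encoded, and the interior runs — those with both edges observed — provide
on/off durations. A flash is an interior on-run followed by its off-run;
duty cycle is on/(on+off) and the blink rate is flashes per second of
complete-cycle time. The spectrum is the periodogram of the mean-removed
binary state, averaged across fish, with the peak sought above 0.5 Hz.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.signal import periodogram

from .errors import InvalidConfigError, UndefinedValueError
from .linking import Track

__all__ = [
    "intensity_series",
    "FlashTrain",
    "segment_flashes",
    "FlashStats",
    "flash_stats",
    "FlashSpectrum",
    "flash_spectrum",
]


def intensity_series(track: Track) -> pd.Series:
    """Peak intensity per frame over the track's full span (first to last
    frame); frames inside bridged gaps are NaN and segment as off."""
    if len(track) == 0:
        raise InvalidConfigError("track is empty")
    span = np.arange(track.frames[0], track.frames[-1] + 1)
    series = pd.Series(np.nan, index=span, name="peak")
    series.loc[track.frames] = track.peaks
    return series


def _runs(states: np.ndarray) -> list[tuple[bool, int]]:
    """Run-length encode a boolean sequence as (state, length) pairs."""
    out: list[tuple[bool, int]] = []
    start = 0
    for k in range(1, len(states) + 1):
        if k == len(states) or states[k] != states[start]:
            out.append((bool(states[start]), k - start))
            start = k
    return out


@dataclass
class FlashTrain:
    """Binary on/off state per frame for one fish, with interval lists in
    seconds derived from interior (complete) runs only."""

    fps: float
    states: np.ndarray
    on_intervals: np.ndarray = field(init=False)
    off_intervals: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        self.states = np.asarray(self.states, dtype=bool)
        runs = _runs(self.states)
        interior = runs[1:-1] if len(runs) >= 3 else []
        self.on_intervals = np.array([n / self.fps for s, n in interior if s])
        self.off_intervals = np.array([n / self.fps for s, n in interior if not s])

    @property
    def duration_s(self) -> float:
        return len(self.states) / self.fps

    def interior_runs(self) -> list[tuple[bool, int]]:
        runs = _runs(self.states)
        return runs[1:-1] if len(runs) >= 3 else []


def segment_flashes(series: pd.Series | np.ndarray, fps: float, level: float | None = None) -> FlashTrain:
    """Binarise an intensity series into a FlashTrain.

    ``level=None`` uses half of the series' 95th-percentile intensity.
    Missing values (NaN) are treated as off. Leading/trailing partial runs
    remain in ``states`` but are excluded from the interval lists.
    """
    values = np.asarray(pd.Series(series).to_numpy(), dtype=float)
    if values.size < 2:
        raise InvalidConfigError("series must have length >= 2")
    finite = values[np.isfinite(values)]
    if level is None:
        if finite.size == 0:
            raise UndefinedValueError("cannot derive a level from an all-missing series")
        level = 0.5 * float(np.percentile(finite, 95))
    states = np.where(np.isfinite(values), values >= level, False)
    return FlashTrain(fps=fps, states=states)


@dataclass(frozen=True)
class FlashStats:
    mean_on_s: float
    mean_off_s: float
    duty_cycles: np.ndarray  # per complete flash, in [0, 1]
    blink_rate_hz: float  # flashes per second of complete-cycle time
    n_flashes: int


def flash_stats(trains: list[FlashTrain]) -> FlashStats:
    """Aggregate per-flash statistics over one or more flash trains.

    A complete flash is an interior on-run immediately followed by an
    interior off-run; incomplete first/last cycles are excluded to avoid
    truncation bias. Raises when no complete cycle exists.
    """
    duty = []
    on_s, off_s, cycle_s = [], [], []
    for train in trains:
        runs = train.interior_runs()
        on_s.extend(n / train.fps for s, n in runs if s)
        off_s.extend(n / train.fps for s, n in runs if not s)
        for k in range(len(runs) - 1):
            (s1, n1), (s2, n2) = runs[k], runs[k + 1]
            if s1 and not s2:
                t_on, t_off = n1 / train.fps, n2 / train.fps
                duty.append(t_on / (t_on + t_off))
                cycle_s.append(t_on + t_off)
    if not duty:
        raise UndefinedValueError("no complete on/off cycle in any train")
    return FlashStats(
        mean_on_s=float(np.mean(on_s)),
        mean_off_s=float(np.mean(off_s)) if off_s else float("nan"),
        duty_cycles=np.asarray(duty),
        blink_rate_hz=len(duty) / float(np.sum(cycle_s)),
        n_flashes=len(duty),
    )


@dataclass(frozen=True)
class FlashSpectrum:
    frequencies: np.ndarray  # Hz
    power: np.ndarray  # mean across fish
    peak_frequency_hz: float


def flash_spectrum(trains: list[FlashTrain], fps: float, min_freq_hz: float = 0.5) -> FlashSpectrum:
    """Across-fish averaged periodogram of the mean-removed binary state.

    Each train must span at least 2 s (≈0.5 Hz resolution). Shorter trains
    in a mixed set are zero-padded to the longest record; that rescales
    per-train power but not peak location. The peak is the frequency of
    maximum mean power above ``min_freq_hz``; an error is raised if there is
    no power there (e.g. constant-on trains).
    """
    if not trains:
        raise InvalidConfigError("at least one train required")
    for train in trains:
        if train.duration_s < 2.0:
            raise InvalidConfigError("each train must span at least 2 s")
    nfft = max(len(t.states) for t in trains)
    spectra = []
    freqs = None
    for train in trains:
        x = train.states.astype(float)
        x = x - x.mean()
        freqs, pxx = periodogram(x, fs=fps, nfft=nfft, window="boxcar", detrend=False)
        spectra.append(pxx)
    power = np.mean(spectra, axis=0)
    sel = freqs > min_freq_hz
    if not np.any(sel) or np.all(power[sel] == 0):
        raise UndefinedValueError(f"no spectral power above {min_freq_hz} Hz")
    peak = float(freqs[sel][np.argmax(power[sel])])
    return FlashSpectrum(frequencies=freqs, power=power, peak_frequency_hz=peak)
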