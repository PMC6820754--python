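"""Signal conditioning: Butterworth filtering and pseudorandom epoching.

The conditioning chain mirrors a standard resting-state MEG workflow: a
causal high-pass (0.5 Hz) to remove drift, a mains notch (50 Hz), and a
zero-phase low-pass (35 Hz) restricting analysis to cortical broadband
activity; the continuous recording is then cut into a fixed number of
non-overlapping epochs drawn pseudo-randomly after discarding the first
minute.  All three filters are applied to the continuous recording before
epoching (the passband is the same either way and epoch edges see no filter
transients).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal as sp_signal

from .cohort import SourceTimeSeries

__all__ = ["EpochSet", "apply_filters", "segment_epochs"]


@dataclass
class EpochSet:
    """Equal-length node x sample segments cut from one recording."""

    epochs: list[np.ndarray]
    fs: float
    epoch_starts: np.ndarray
    subject_id: str = ""

    def __post_init__(self) -> None:
        self.epoch_starts = np.asarray(self.epoch_starts, dtype=int)
        shapes = {e.shape for e in self.epochs}
        if len(shapes) > 1:
            raise ValueError(f"epochs have mixed shapes: {shapes}")

    @property
    def n_epochs(self) -> int:
        return len(self.epochs)

    @property
    def epoch_len(self) -> int:
        return self.epochs[0].shape[1] if self.epochs else 0


def apply_filters(
    series: SourceTimeSeries,
    highpass_hz: float = 0.5,
    notch_hz: float = 50.0,
    lowpass_hz: float = 35.0,
    order: int = 4,
    notch_q: float = 30.0,
) -> SourceTimeSeries:
    """High-pass (causal), notch, and low-pass (zero-phase) a recording.

    The high-pass is a forward-only Butterworth of the given order (causal,
    as drift removal on a continuous stream); the notch is a second-order IIR
    with quality factor ``notch_q`` applied causally; the low-pass is a
    Butterworth applied forward-backward, hence zero net phase in the band
    that carries the connectivity analysis.
    """
    nyq = series.fs / 2.0
    if not (0 < highpass_hz < lowpass_hz < nyq):
        raise ValueError(
            f"need 0 < highpass ({highpass_hz}) < lowpass ({lowpass_hz}) < Nyquist ({nyq})"
        )
    if not (0 < notch_hz < nyq):
        raise ValueError(f"notch frequency {notch_hz} outside (0, {nyq})")
    x = series.data
    sos_hp = sp_signal.butter(order, highpass_hz, btype="highpass", fs=series.fs, output="sos")
    x = sp_signal.sosfilt(sos_hp, x, axis=1)
    b_notch, a_notch = sp_signal.iirnotch(notch_hz, notch_q, fs=series.fs)
    x = sp_signal.lfilter(b_notch, a_notch, x, axis=1)
    sos_lp = sp_signal.butter(order, lowpass_hz, btype="lowpass", fs=series.fs, output="sos")
    x = sp_signal.sosfiltfilt(sos_lp, x, axis=1)
    return SourceTimeSeries(data=x, fs=series.fs, subject_id=series.subject_id)


def segment_epochs(
    series: SourceTimeSeries,
    n_epochs: int = 8,
    epoch_seconds: float = 8.0,
    exclude_seconds: float = 60.0,
    seed: int = 0,
    max_tries: int = 10_000,
) -> EpochSet:
    """Cut ``n_epochs`` non-overlapping epochs at pseudo-random starts.

    Start indices are rejection-sampled uniformly from the admissible range
    (everything after the excluded initial segment) until a pairwise
    non-overlapping draw is found; the draw is deterministic under ``seed``.
    """
    epoch_len = int(round(epoch_seconds * series.fs))
    first_valid = int(round(exclude_seconds * series.fs))
    last_valid_start = series.n_samples - epoch_len
    available = series.n_samples - first_valid
    needed = n_epochs * epoch_len
    if epoch_len < 1 or n_epochs < 1:
        raise ValueError("n_epochs and epoch_seconds must be positive")
    if available < needed or last_valid_start < first_valid:
        raise ValueError(
            f"recording holds {max(available, 0)} samples after the excluded "
            f"{exclude_seconds} s but {needed} are needed for "
            f"{n_epochs} epochs of {epoch_seconds} s"
        )
    rng = np.random.default_rng(seed)
    for _ in range(max_tries):
        starts = np.sort(rng.integers(first_valid, last_valid_start + 1, size=n_epochs))
        if np.all(np.diff(starts) >= epoch_len):
            break
    else:
        raise RuntimeError(
            f"could not place {n_epochs} non-overlapping epochs in {max_tries} tries; "
            "recording may be too tightly packed"
        )
    epochs = [series.data[:, s : s + epoch_len].copy() for s in starts]
    return EpochSet(epochs=epochs, fs=series.fs, epoch_starts=starts, subject_id=series.subject_id)
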