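"""Core in-memory containers shared across the pipeline.

Event tables (task events, detected bursts, ground-truth bursts) are plain
:class:`pandas.DataFrame` objects with fixed column sets; the raw signal is a
small dataclass wrapping a ``(n_channels, n_samples)`` array.  All times are
seconds from recording start and all intervals are half-open ``[onset, offset)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

#: Column set of a detected-burst table (one row per HFO event).
HFO_EVENT_COLUMNS = [
    "subject", "channel", "onset", "offset", "peak_time",
    "dominant_freq", "freq_min", "freq_max", "freq_span",
    "peak_z", "peak_amplitude",
]

#: Column set of a task-event table (BIDS-style events.tsv layout).
TASK_EVENT_COLUMNS = ["onset", "duration", "trial_type", "item", "recalled"]

#: Recognised task-event types.
TRIAL_TYPES = {"COUNTDOWN", "WORD", "DISTRACTOR", "RECALL", "CUE"}


@dataclass
class SignalRecord:
    """Multichannel LFP time series with sampling metadata.

    Parameters
    ----------
    data : ndarray, shape (n_channels, n_samples)
        Voltage samples in microvolts.
    fs : float
        Sampling rate in Hz.
    channels : list of str
        Channel labels, one per row of ``data``.
    subject : str
        Subject identifier.
    units : str
        Physical units of the samples (informational).
    """

    data: np.ndarray
    fs: float
    channels: list[str]
    subject: str = "S01"
    units: str = "uV"

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValueError("data must be 2-D (channels x samples)")
        if self.fs <= 0:
            raise ValueError("sampling rate must be positive")
        if len(self.channels) != self.data.shape[0]:
            raise ValueError(
                f"channel count mismatch: {len(self.channels)} labels for "
                f"{self.data.shape[0]} rows"
            )

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration(self) -> float:
        """Recording length in seconds."""
        return self.data.shape[1] / self.fs

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.n_samples) / self.fs


@dataclass
class BurstSpec:
    """Specification of one injected oscillatory burst.

    The burst is a sinusoid of ``frequency`` Hz under a smooth envelope whose
    total duration is ``n_cycles / frequency`` seconds, centred at
    ``center_time``.  ``amplitude`` is the peak of the envelope in microvolts.
    """

    channel: int
    center_time: float
    frequency: float
    n_cycles: int = 6
    amplitude: float = 10.0
    envelope: str = "hann"
    phase: float = 0.0

    def __post_init__(self) -> None:
        if not (60.0 <= self.frequency <= 600.0):
            raise ValueError("burst frequency must lie in [60, 600] Hz")
        if self.n_cycles < 4:
            raise ValueError("bursts must contain at least 4 cycles")

    @property
    def duration(self) -> float:
        return self.n_cycles / self.frequency

    @property
    def onset(self) -> float:
        return self.center_time - self.duration / 2.0

    @property
    def offset(self) -> float:
        return self.center_time + self.duration / 2.0
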