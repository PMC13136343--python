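"""Synthetic multichannel iEEG with known injected HFO bursts.

The generator emulates the statistical structure of intracranial recordings
during a verbal free-recall task: 1/f^alpha background noise, transient
oscillatory bursts (>= 4 cycles) at controllable SNR, channel groups that
co-burst within tens of milliseconds, and burst-rate modulation locked to the
task schedule (5-s countdown, 12-word encoding list, 20-s arithmetic
distractor, 30-s free recall).  Every injected burst is recorded in a
ground-truth table so downstream detection and coincidence analyses can be
validated by parameter recovery.

All randomness flows from a single master seed; each subject receives an
independent child stream, and within a subject the noise and the event-placing
streams are separate so that the background signal is bit-identical with and
without bursts.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .types import BurstSpec, SignalRecord, TASK_EVENT_COLUMNS

# Free-recall task schedule (seconds)
COUNTDOWN_S = 5.0          # five digits, one per second
WORD_DISPLAY_S = 1.5
ISI_S = 1.0
WORDS_PER_LIST = 12
DISTRACTOR_S = 20.0
RECALL_BLOCK_S = 30.0
MIN_RECALL_SEPARATION_S = 1.5
LIST_GAP_S = 5.0

#: length of one full free-recall list, countdown through end of recall
LIST_LENGTH_S = (COUNTDOWN_S + WORDS_PER_LIST * (WORD_DISPLAY_S + ISI_S)
                 + DISTRACTOR_S + RECALL_BLOCK_S)

# region pool for the synthetic channel table; labels resolve through the
# default lobe map shipped with cohfo.anatomy
_REGION_POOL = [
    "Hippocampus", "Superior frontal gyrus", "Superior parietal gyrus",
    "Middle temporal gyrus", "Calcarine cortex", "Amygdala",
    "Middle frontal gyrus", "Angular gyrus", "Inferior temporal gyrus",
    "Cuneus", "Parahippocampal gyrus", "Precentral gyrus",
]


class InvalidConfigError(ValueError):
    """Raised when a simulation configuration violates its invariants."""


@dataclass
class RateProfile:
    """Task-locked modulation of the per-channel burst rate.

    The instantaneous rate is ``baseline_rate`` multiplied by a gain that is
    ``encode_gain`` while a word is on the screen, rises by a Gaussian bump of
    height ``recall_peak_gain`` (SD ``recall_peak_sd``) at each recall
    vocalization onset, and dips by a factor ``pre_recall_dip_gain`` in a
    Gaussian trough centred ``pre_recall_dip_center`` seconds before each
    recall onset.
    """

    baseline_rate: float = 0.8          # bursts/s/channel (ripple-range baseline)
    recall_peak_gain: float = 1.0
    recall_peak_sd: float = 0.075       # s; FWHM ~175 ms, a sharp onset peak
    pre_recall_dip_gain: float = 1.0    # < 1 produces a pre-recall trough
    pre_recall_dip_center: float = 1.0  # s before recall onset
    pre_recall_dip_sd: float = 0.200    # s
    encode_gain: float = 1.0

    def __post_init__(self) -> None:
        if self.baseline_rate < 0:
            raise InvalidConfigError("baseline_rate must be >= 0")
        for name in ("recall_peak_gain", "pre_recall_dip_gain", "encode_gain"):
            if getattr(self, name) < 0:
                raise InvalidConfigError(f"{name} must be >= 0")


@dataclass
class CoincidenceGroupSpec:
    """A set of channels that burst together around shared group times."""

    members: tuple[int, ...]
    jitter_sd: float = 0.002        # s; spread of member times around group time
    participation_prob: float = 1.0

    def __post_init__(self) -> None:
        self.members = tuple(self.members)
        if len(set(self.members)) != len(self.members) or len(self.members) < 2:
            raise InvalidConfigError("group members must be >= 2 distinct channels")
        if self.jitter_sd < 0:
            raise InvalidConfigError("jitter_sd must be >= 0")
        if not (0.0 <= self.participation_prob <= 1.0):
            raise InvalidConfigError("participation_prob must lie in [0, 1]")


@dataclass
class SimConfig:
    """Full description of one synthetic multi-subject recording session."""

    n_subjects: int = 1
    n_channels: int = 8
    fs: float = 5000.0
    duration: float | None = None       # s; default = task schedule length
    noise_exponent: float = 1.0         # alpha of the 1/f^alpha background
    noise_rms: float = 20.0             # microvolts
    n_lists: int = 3
    seed: int = 0
    recall_prob: float = 0.3            # per-word probability of later recall
    burst_freq_range: tuple[float, float] = (80.0, 200.0)
    burst_n_cycles: int = 6
    burst_snr: float = 6.0      # envelope peak / 60-800 Hz in-band noise RMS
    coincidence_groups: list[CoincidenceGroupSpec] = field(default_factory=list)
    rate_profile: RateProfile = field(default_factory=RateProfile)

    def __post_init__(self) -> None:
        if min(self.n_subjects, self.n_channels, self.n_lists) < 1:
            raise InvalidConfigError("all counts must be >= 1")
        if self.fs <= 0:
            raise InvalidConfigError("sampling rate must be positive")
        if self.fs < 2.0 * self.burst_freq_range[1]:
            raise InvalidConfigError("fs must be >= twice the maximum burst frequency")
        if self.duration is None:
            self.duration = self.schedule_length
        if self.duration <= 0:
            raise InvalidConfigError("duration must be positive")
        if self.duration < self.schedule_length:
            raise InvalidConfigError(
                f"duration {self.duration:.1f} s is shorter than the task "
                f"schedule ({self.schedule_length:.1f} s)"
            )
        for g in self.coincidence_groups:
            if max(g.members) >= self.n_channels:
                raise InvalidConfigError("group member index out of range")

    @property
    def schedule_length(self) -> float:
        return self.n_lists * (LIST_LENGTH_S + LIST_GAP_S)


# ---------------------------------------------------------------------------
# background noise
# ---------------------------------------------------------------------------

def generate_pink_noise(config: SimConfig,
                        rng: np.random.Generator | None = None,
                        subject: str = "S01") -> SignalRecord:
    """Generate 1/f^alpha background noise by spectral shaping.

    White Gaussian noise is transformed to the frequency domain, its spectrum
    multiplied by ``f**(-alpha/2)`` (DC removed), and transformed back; each
    channel is then rescaled to exactly ``noise_rms``.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    n = int(round(config.fs * config.duration))
    if n <= 0:
        raise InvalidConfigError("fs * duration must yield at least one sample")
    freqs = np.fft.rfftfreq(n, d=1.0 / config.fs)
    shape = np.zeros_like(freqs)
    shape[1:] = freqs[1:] ** (-config.noise_exponent / 2.0)
    data = np.empty((config.n_channels, n))
    for c in range(config.n_channels):
        white = rng.standard_normal(n)
        x = np.fft.irfft(np.fft.rfft(white) * shape, n=n)
        sd = x.std()
        data[c] = x * (config.noise_rms / sd) if sd > 0 else x
    names = channel_names(config.n_channels)
    return SignalRecord(data=data, fs=config.fs, channels=names, subject=subject)


def channel_names(n_channels: int, per_shaft: int = 8) -> list[str]:
    """Synthetic channel labels grouped into electrode shafts A1..A8, B1.."""
    names = []
    for i in range(n_channels):
        shaft, contact = divmod(i, per_shaft)
        names.append(f"{chr(ord('A') + shaft)}{contact + 1}")
    return names


def band_rms_fraction(f_lo: float, f_hi: float, config: SimConfig) -> float:
    """Expected fraction of the noise RMS inside a frequency band.

    Follows from the programmed power spectrum ``S(f) = f**-alpha`` between
    the first nonzero frequency bin and Nyquist.
    """
    alpha = config.noise_exponent
    f_min = 1.0 / config.duration
    f_nyq = config.fs / 2.0

    def integral(a: float, b: float) -> float:
        if abs(alpha - 1.0) < 1e-12:
            return math.log(b / a)
        return (b ** (1.0 - alpha) - a ** (1.0 - alpha)) / (1.0 - alpha)

    lo = max(f_lo, f_min)
    hi = min(f_hi, f_nyq)
    if hi <= lo:
        return 0.0
    return math.sqrt(integral(lo, hi) / integral(f_min, f_nyq))


# ---------------------------------------------------------------------------
# burst waveforms
# ---------------------------------------------------------------------------

_ENVELOPES = {
    "hann": lambda n: np.hanning(n),
    "rect": lambda n: np.ones(n),
}


def make_burst_waveform(spec: BurstSpec, fs: float) -> np.ndarray:
    """Realize one burst: a sinusoid under the named envelope.

    The carrier is a cosine whose peak coincides with the envelope maximum at
    the burst centre (plus ``spec.phase``), so the peak absolute sample is
    within a fraction of a percent of ``spec.amplitude``.
    """
    if spec.frequency >= fs / 2.0:
        raise ValueError(
            f"burst frequency {spec.frequency} Hz aliases at fs={fs} Hz")
    n = int(round(fs * spec.n_cycles / spec.frequency))
    if n < 2:
        return np.zeros(n)
    t = np.arange(n) / fs
    half = (n - 1) / (2.0 * fs)
    carrier = np.cos(2.0 * np.pi * spec.frequency * (t - half) + spec.phase)
    try:
        env = _ENVELOPES[spec.envelope](n)
    except KeyError:
        raise ValueError(f"unknown envelope {spec.envelope!r}") from None
    return spec.amplitude * env * carrier


def inject_bursts(signal: SignalRecord, specs: list[BurstSpec]) -> SignalRecord:
    """Return a copy of ``signal`` with burst waveforms added in place."""
    data = signal.data.copy()
    n = signal.n_samples
    for spec in specs:
        wave = make_burst_waveform(spec, signal.fs)
        start = int(round((spec.center_time - spec.duration / 2.0) * signal.fs))
        if start < 0 or start + wave.size > n:
            raise ValueError(
                f"burst at {spec.center_time:.3f} s does not fit the recording")
        data[spec.channel, start:start + wave.size] += wave
    return SignalRecord(data=data, fs=signal.fs, channels=list(signal.channels),
                        subject=signal.subject, units=signal.units)


# ---------------------------------------------------------------------------
# task schedule
# ---------------------------------------------------------------------------

def generate_task_schedule(config: SimConfig,
                           rng: np.random.Generator | None = None,
                           task: str = "fr") -> pd.DataFrame:
    """Generate the event table of a free-recall (or cued-recall) session.

    Each list runs countdown (5 digits of 1 s), word encoding (12 words shown
    for 1.5 s with 1.0 s inter-stimulus interval), a 20-s arithmetic
    distractor, and a 30-s recall block.  Recall-vocalization onsets are drawn
    uniformly within the recall block with a minimum separation of 1.5 s, one
    per word flagged as recalled (probability ``recall_prob``).  The cued
    variant ("pal") encodes six word pairs and emits a CUE event before each
    recall attempt.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    if task not in ("fr", "pal"):
        raise InvalidConfigError(f"unknown task {task!r}")
    rows: list[dict] = []
    for li in range(config.n_lists):
        t0 = li * (LIST_LENGTH_S + LIST_GAP_S)
        if t0 + LIST_LENGTH_S > config.duration + 1e-9:
            raise InvalidConfigError("task schedule exceeds recording duration")
        for d in range(5):
            rows.append(dict(onset=t0 + d, duration=1.0, trial_type="COUNTDOWN",
                             item=str(5 - d), recalled=False))
        enc_t0 = t0 + COUNTDOWN_S
        if task == "fr":
            n_items = WORDS_PER_LIST
            items = [f"word{li * WORDS_PER_LIST + k:03d}" for k in range(n_items)]
        else:
            n_items = WORDS_PER_LIST // 2
            items = [f"pair{li * n_items + k:03d}" for k in range(n_items)]
        recalled = rng.random(n_items) < config.recall_prob
        for k in range(n_items):
            rows.append(dict(onset=enc_t0 + k * (WORD_DISPLAY_S + ISI_S),
                             duration=WORD_DISPLAY_S, trial_type="WORD",
                             item=items[k], recalled=bool(recalled[k])))
        dist_t0 = enc_t0 + n_items * (WORD_DISPLAY_S + ISI_S)
        if task == "pal":
            dist_t0 = enc_t0 + WORDS_PER_LIST * (WORD_DISPLAY_S + ISI_S)
        n_problems = int(DISTRACTOR_S // 4)
        for k in range(n_problems):
            rows.append(dict(onset=dist_t0 + 4.0 * k, duration=4.0,
                             trial_type="DISTRACTOR", item=f"eq{k}",
                             recalled=False))
        rec_t0 = dist_t0 + DISTRACTOR_S
        if task == "fr":
            words = [items[k] for k in range(n_items) if recalled[k]]
            onsets = _draw_recall_onsets(rng, len(words), rec_t0)
            for t, w in zip(onsets, words):
                rows.append(dict(onset=t, duration=1.0, trial_type="RECALL",
                                 item=w, recalled=True))
        else:
            cue_step = RECALL_BLOCK_S / n_items
            for k in range(n_items):
                cue_t = rec_t0 + k * cue_step
                rows.append(dict(onset=cue_t, duration=1.0, trial_type="CUE",
                                 item=items[k], recalled=bool(recalled[k])))
                if recalled[k]:
                    rows.append(dict(onset=cue_t + 1.0 + rng.uniform(0.0, 0.5),
                                     duration=1.0, trial_type="RECALL",
                                     item=items[k], recalled=True))
    df = pd.DataFrame(rows, columns=TASK_EVENT_COLUMNS)
    return df.sort_values("onset", kind="stable").reset_index(drop=True)


def _draw_recall_onsets(rng: np.random.Generator, n: int, t0: float,
                        block: float = RECALL_BLOCK_S,
                        min_sep: float = MIN_RECALL_SEPARATION_S) -> np.ndarray:
    """Uniform recall onsets within the block with a minimum separation."""
    if n == 0:
        return np.array([])
    usable = block - 1.0  # keep vocalization inside the block
    for _ in range(200):
        t = np.sort(rng.uniform(0.0, usable, size=n))
        if n == 1 or np.all(np.diff(t) >= min_sep):
            return t0 + t
    # fall back to evenly spaced onsets with small jitter
    base = np.linspace(0.0, usable - min_sep, n)
    return t0 + base + rng.uniform(0.0, min_sep / 2.0, size=n)


# ---------------------------------------------------------------------------
# rate modulation and dataset synthesis
# ---------------------------------------------------------------------------

def rate_gain(times: np.ndarray, task: pd.DataFrame,
              profile: RateProfile) -> np.ndarray:
    """Evaluate the multiplicative rate gain at the given times."""
    times = np.asarray(times, dtype=float)
    gain = np.ones_like(times)
    words = task[task.trial_type == "WORD"]
    if profile.encode_gain != 1.0 and len(words):
        inside = np.zeros(times.shape, dtype=bool)
        for onset, dur in zip(words.onset.to_numpy(), words.duration.to_numpy()):
            inside |= (times >= onset) & (times < onset + dur)
        gain[inside] *= profile.encode_gain
    recalls = task[task.trial_type == "RECALL"].onset.to_numpy()
    for t_r in recalls:
        if profile.recall_peak_gain != 1.0:
            bump = np.exp(-0.5 * ((times - t_r) / profile.recall_peak_sd) ** 2)
            gain *= 1.0 + (profile.recall_peak_gain - 1.0) * bump
        if profile.pre_recall_dip_gain != 1.0:
            c = t_r - profile.pre_recall_dip_center
            trough = np.exp(-0.5 * ((times - c) / profile.pre_recall_dip_sd) ** 2)
            gain *= 1.0 - (1.0 - profile.pre_recall_dip_gain) * trough
    return np.maximum(gain, 0.0)


def _draw_point_process(rng: np.random.Generator, rate: float,
                        duration: float, task: pd.DataFrame,
                        profile: RateProfile) -> np.ndarray:
    """Inhomogeneous Poisson draw via thinning against a numerical bound."""
    if rate <= 0:
        return np.array([])
    grid = np.arange(0.0, duration, 0.01)
    gmax = float(rate_gain(grid, task, profile).max()) * 1.05 + 1e-12
    n = rng.poisson(rate * gmax * duration)
    t = rng.uniform(0.0, duration, size=n)
    keep = rng.random(n) * gmax < rate_gain(t, task, profile)
    return np.sort(t[keep])


def simulate_dataset(config: SimConfig, synthesize_signal: bool = True,
                     task: str = "fr"):
    """Generate a full synthetic dataset for every subject.

    Returns
    -------
    signals : list of SignalRecord (empty when ``synthesize_signal`` is False)
    task_events : DataFrame with a ``subject`` column
    ground_truth : DataFrame listing every injected burst
    channel_table : DataFrame (subject, channel, x, y, z, region, group, tissue)
    """
    master = np.random.SeedSequence(config.seed)
    subject_seeds = master.spawn(config.n_subjects)
    signals: list[SignalRecord] = []
    all_tasks, all_truth, all_chan = [], [], []
    for si, seq in enumerate(subject_seeds):
        subject = f"S{si + 1:02d}"
        noise_rng, event_rng, chan_rng = (np.random.default_rng(s)
                                          for s in seq.spawn(3))
        task_df = generate_task_schedule(config, rng=event_rng, task=task)
        truth = _draw_subject_bursts(config, task_df, event_rng)
        truth.insert(0, "subject", subject)
        tdf = task_df.copy()
        tdf.insert(0, "subject", subject)
        chan = _synthetic_channel_table(config, chan_rng, subject)
        if synthesize_signal:
            sig = generate_pink_noise(config, rng=noise_rng, subject=subject)
            specs = [BurstSpec(channel=int(r.channel), center_time=r.center_time,
                               frequency=r.frequency, n_cycles=int(r.n_cycles),
                               amplitude=r.amplitude, phase=r.phase)
                     for r in truth.itertuples()]
            sig = inject_bursts(sig, specs)
            signals.append(sig)
        all_tasks.append(tdf)
        all_truth.append(truth)
        all_chan.append(chan)
    task_events = pd.concat(all_tasks, ignore_index=True)
    ground_truth = pd.concat(all_truth, ignore_index=True)
    channel_table = pd.concat(all_chan, ignore_index=True)
    return signals, task_events, ground_truth, channel_table


def _draw_subject_bursts(config: SimConfig, task: pd.DataFrame,
                         rng: np.random.Generator) -> pd.DataFrame:
    """Draw all burst times/parameters for one subject."""
    profile = config.rate_profile
    f_lo, f_hi = config.burst_freq_range
    rows: list[dict] = []
    grouped = {}
    for gi, g in enumerate(config.coincidence_groups):
        for m in g.members:
            grouped[m] = gi

    def margin(freq: float) -> float:
        return 0.5 * config.burst_n_cycles / freq + 0.05

    def add(channel: int, t: float, group_id: float) -> None:
        freq = rng.uniform(f_lo, f_hi)
        m = margin(freq)
        t = min(max(t, m), config.duration - m)
        amp = (config.burst_snr * config.noise_rms
               * band_rms_fraction(60.0, 800.0, config))
        rows.append(dict(channel=channel, center_time=t, frequency=freq,
                         n_cycles=config.burst_n_cycles, amplitude=amp,
                         phase=rng.uniform(0.0, 2.0 * np.pi),
                         group_id=group_id))

    # shared group bursts
    for gi, g in enumerate(config.coincidence_groups):
        group_times = _draw_point_process(rng, profile.baseline_rate,
                                          config.duration, task, profile)
        for t in group_times:
            for m in g.members:
                if rng.random() < g.participation_prob:
                    add(m, t + rng.normal(0.0, g.jitter_sd), float(gi))

    # independent background; members of a group get the complementary rate
    for c in range(config.n_channels):
        if c in grouped:
            p = config.coincidence_groups[grouped[c]].participation_prob
            rate = profile.baseline_rate * (1.0 - p)
        else:
            rate = profile.baseline_rate
        for t in _draw_point_process(rng, rate, config.duration, task, profile):
            add(c, t, np.nan)

    df = pd.DataFrame(rows, columns=["channel", "center_time", "frequency",
                                     "n_cycles", "amplitude", "phase",
                                     "group_id"])
    df["onset"] = df.center_time - 0.5 * df.n_cycles / df.frequency
    df["offset"] = df.center_time + 0.5 * df.n_cycles / df.frequency
    return df.sort_values(["channel", "onset"], kind="stable").reset_index(drop=True)


def _synthetic_channel_table(config: SimConfig, rng: np.random.Generator,
                             subject: str) -> pd.DataFrame:
    """Fabricate MNI coordinates, regions and shaft groups for each channel."""
    names = channel_names(config.n_channels)
    rows = []
    n_shafts = (config.n_channels + 7) // 8
    for s in range(n_shafts):
        origin = rng.uniform(-60.0, 60.0, size=3)
        direction = rng.standard_normal(3)
        direction /= np.linalg.norm(direction)
        region_offset = rng.integers(0, len(_REGION_POOL))
        for c in range(8):
            idx = s * 8 + c
            if idx >= config.n_channels:
                break
            pos = origin + direction * (8.0 * c)
            region = _REGION_POOL[(region_offset + c // 3) % len(_REGION_POOL)]
            rows.append(dict(subject=subject, channel=names[idx],
                             x=round(float(pos[0]), 2), y=round(float(pos[1]), 2),
                             z=round(float(pos[2]), 2), region=region,
                             group=chr(ord('A') + s),
                             tissue="gray" if rng.random() < 0.8 else "white"))
    return pd.DataFrame(rows)
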