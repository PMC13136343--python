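"""Per-channel HFO burst detection.

The detector decomposes each channel into 38 logarithmically spaced band-pass
filters (60-800 Hz), extracts Hilbert amplitude envelopes, normalizes them with
a sliding z-score over 10-s windows, and applies a dual-threshold rule:
candidate segments exceed z > 2 for at least three oscillation cycles of the
band frequency; candidates overlapping in time across bands are merged into a
single event whose dominant frequency is the centre of the band with the
highest z-score; accepted events must exceed a peak z of 3 and last at least
four cycles at their dominant frequency, contain at least one full oscillation
cycle above the peak threshold, and survive a frequency-span specificity filter
(k-means, k = 2) that rejects spectrally diffuse events.

Filtering is zero-phase: the windowed-sinc FIR magnitude response is applied
twice (|H|^2) in the frequency domain, the exact circular equivalent of
forward-backward filtering, and the analytic signal of each band is obtained
from the same spectrum so that band waveform and envelope share one inverse
FFT per band.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.signal import firwin
from sklearn.cluster import KMeans

from .types import HFO_EVENT_COLUMNS, SignalRecord


class MontageError(ValueError):
    """Raised for bipolar pairs that cross electrode groups."""


@dataclass
class FilterBankSpec:
    """Layout of the detection filter bank.

    ``transition_width`` is expressed in seconds; the FIR transition bandwidth
    is its reciprocal (0.200 s -> 5 Hz) and the windowed-sinc order follows
    from it.  Band edges are 39 log-spaced frequencies from ``f_lo`` to
    ``f_hi`` defining 38 contiguous passbands; the -6 dB point of each
    single-pass filter sits at the band edge.
    """

    n_bands: int = 38
    f_lo: float = 60.0
    f_hi: float = 800.0
    transition_width: float = 0.200  # s

    def __post_init__(self) -> None:
        if self.n_bands < 2:
            raise ValueError("need at least 2 bands")
        if not (0 < self.f_lo < self.f_hi):
            raise ValueError("band edges must satisfy 0 < f_lo < f_hi")

    def edges(self) -> np.ndarray:
        return np.geomspace(self.f_lo, self.f_hi, self.n_bands + 1)


@dataclass
class DetectorParams:
    """Thresholds of the dual-threshold detection rule."""

    candidate_z: float = 2.0
    peak_z: float = 3.0
    candidate_min_cycles: int = 3
    event_min_cycles: int = 4
    z_window: float = 10.0  # s

    def __post_init__(self) -> None:
        if self.peak_z < self.candidate_z:
            raise ValueError("peak_z must be >= candidate_z")
        if not (1 <= self.candidate_min_cycles <= self.event_min_cycles):
            raise ValueError("event_min_cycles >= candidate_min_cycles >= 1")
        if self.z_window <= 0:
            raise ValueError("z_window must be positive")


# ---------------------------------------------------------------------------
# montage
# ---------------------------------------------------------------------------

def adjacent_pairs(channels: list[str],
                   groups: dict[str, str] | None = None) -> list[tuple[str, str]]:
    """Adjacent-contact pairs within each electrode shaft.

    When no explicit group map is given, the shaft is the alphabetic prefix of
    the channel label (A1, A2 -> shaft A).
    """
    if groups is None:
        groups = {c: c.rstrip("0123456789") for c in channels}
    pairs = []
    for a, b in zip(channels[:-1], channels[1:]):
        if groups.get(a) == groups.get(b):
            pairs.append((a, b))
    return pairs


def bipolar_rereference(signal: SignalRecord,
                        montage: list[tuple[str, str]] | None = None,
                        groups: dict[str, str] | None = None) -> SignalRecord:
    """Bipolar montage: one derived channel per adjacent pair, first minus second."""
    if montage is None:
        montage = adjacent_pairs(signal.channels, groups)
    if groups is None:
        groups = {c: c.rstrip("0123456789") for c in signal.channels}
    index = {c: i for i, c in enumerate(signal.channels)}
    rows, names = [], []
    for a, b in montage:
        if a not in index or b not in index:
            raise MontageError(f"montage pair ({a}, {b}) names unknown channels")
        if groups.get(a) != groups.get(b):
            raise MontageError(
                f"pair ({a}, {b}) crosses electrode groups "
                f"({groups.get(a)} vs {groups.get(b)})")
        rows.append(signal.data[index[a]] - signal.data[index[b]])
        names.append(f"{a}-{b}")
    return SignalRecord(data=np.array(rows).reshape(len(rows), -1), fs=signal.fs,
                        channels=names, subject=signal.subject,
                        units=signal.units)


# ---------------------------------------------------------------------------
# filter bank
# ---------------------------------------------------------------------------

class FilterBank:
    """Zero-phase log-spaced FIR band-pass bank bound to a sampling rate."""

    def __init__(self, spec: FilterBankSpec | None = None, fs: float = 5000.0,
                 on_high_f_hi: str = "raise"):
        spec = spec or FilterBankSpec()
        if spec.f_hi >= fs / 2.0:
            if on_high_f_hi == "clip":
                spec = FilterBankSpec(n_bands=spec.n_bands, f_lo=spec.f_lo,
                                      f_hi=0.95 * fs / 2.0,
                                      transition_width=spec.transition_width)
            else:
                raise ValueError(
                    f"f_hi={spec.f_hi} Hz is not below Nyquist ({fs / 2} Hz); "
                    "pass on_high_f_hi='clip' to reduce automatically")
        self.spec = spec
        self.fs = float(fs)
        self.edges = spec.edges()
        self.centers = np.sqrt(self.edges[:-1] * self.edges[1:])
        delta_f = 1.0 / spec.transition_width
        numtaps = int(np.ceil(3.3 * fs / delta_f))
        self.numtaps = numtaps + 1 - numtaps % 2  # odd length, linear phase
        self._taps = [
            firwin(self.numtaps, [self.edges[b], self.edges[b + 1]],
                   pass_zero=False, fs=fs)
            for b in range(spec.n_bands)
        ]
        self._gain_cache: dict[int, np.ndarray] = {}

    @property
    def n_bands(self) -> int:
        return self.spec.n_bands

    def band_of(self, freq: float) -> int:
        """Index of the band containing ``freq``."""
        k = int(np.searchsorted(self.edges, freq, side="right")) - 1
        if not (0 <= k < self.n_bands):
            raise ValueError(f"{freq} Hz lies outside the bank")
        return k

    def _gains(self, n: int) -> np.ndarray:
        """|H_b(f)|^2 of every band on the length-n DFT grid (two-pass gain)."""
        cached = self._gain_cache.get(n)
        if cached is not None:
            return cached
        gains = np.empty((self.n_bands, n))
        for b, taps in enumerate(self._taps):
            h = np.fft.fft(taps, n=n)
            gains[b] = np.abs(h) ** 2
        self._gain_cache = {n: gains}
        return gains

    @staticmethod
    def _analytic_mask(n: int) -> np.ndarray:
        """Spectral mask turning a real DFT into its analytic signal."""
        mask = np.zeros(n)
        mask[0] = 1.0
        if n % 2 == 0:
            mask[1:n // 2] = 2.0
            mask[n // 2] = 1.0
        else:
            mask[1:(n + 1) // 2] = 2.0
        return mask

    def analytic(self, x: np.ndarray) -> np.ndarray:
        """Analytic signal of every zero-phase band-filtered copy of ``x``.

        Returns a complex array of shape (n_bands, n); the real part is the
        band waveform and the magnitude its Hilbert envelope.
        """
        x = np.asarray(x, dtype=float)
        n = x.size
        masked = np.fft.fft(x) * self._analytic_mask(n)
        gains = self._gains(n)
        out = np.empty((self.n_bands, n), dtype=complex)
        for b in range(self.n_bands):
            out[b] = np.fft.ifft(masked * gains[b])
        return out

    def filter_band(self, x: np.ndarray, band: int) -> np.ndarray:
        """Zero-phase band-filtered waveform of a single band."""
        n = np.asarray(x).size
        gains = self._gains(n)
        return np.fft.ifft(np.fft.fft(x) * gains[band]).real


def make_filterbank(spec: FilterBankSpec | None = None, fs: float = 5000.0,
                    **kw) -> FilterBank:
    return FilterBank(spec, fs, **kw)


def band_rms(x: np.ndarray, fs: float, f_lo: float = 60.0,
             f_hi: float = 800.0) -> float:
    """RMS of a signal restricted to a frequency band (brickwall FFT mask).

    The default band is the detector's full 60-800 Hz range; burst SNR is
    conventionally expressed relative to this value.
    """
    x = np.asarray(x, dtype=float)
    spectrum = np.fft.rfft(x)
    freqs = np.fft.rfftfreq(x.size, d=1.0 / fs)
    spectrum[(freqs < f_lo) | (freqs > f_hi)] = 0.0
    return float(np.fft.irfft(spectrum, n=x.size).std())


def band_envelope(band_signal: np.ndarray) -> np.ndarray:
    """Instantaneous amplitude of an already band-limited signal."""
    from scipy.signal import hilbert
    x = np.asarray(band_signal, dtype=float)
    return np.abs(hilbert(x))


# ---------------------------------------------------------------------------
# sliding z-score
# ---------------------------------------------------------------------------

def sliding_zscore(envelope: np.ndarray, fs: float,
                   z_window: float = 10.0) -> np.ndarray:
    """Per-sample z-score against a centred moving window.

    The window is ``z_window`` seconds wide and truncated (not padded) at the
    recording edges.  Samples whose local SD is zero get z = 0.
    """
    x = np.asarray(envelope, dtype=float)
    n = x.size
    w = int(round(z_window * fs))
    if n < w:
        raise ValueError(f"envelope shorter than the z-score window ({w} samples)")
    half = w // 2
    c1 = np.concatenate(([0.0], np.cumsum(x)))
    c2 = np.concatenate(([0.0], np.cumsum(x * x)))
    idx = np.arange(n)
    lo = np.maximum(idx - half, 0)
    hi = np.minimum(idx + half + 1, n)
    count = (hi - lo).astype(float)
    mean = (c1[hi] - c1[lo]) / count
    var = np.maximum((c2[hi] - c2[lo]) / count - mean * mean, 0.0)
    sd = np.sqrt(var)
    z = np.zeros(n)
    # relative floor absorbs floating-point residue on near-constant input
    ok = sd > 1e-6 * (np.abs(x).max() + 1e-30)
    z[ok] = (x[ok] - mean[ok]) / sd[ok]
    return z


# ---------------------------------------------------------------------------
# candidates, merging, thresholds
# ---------------------------------------------------------------------------

@dataclass
class Candidate:
    """A maximal above-threshold run in one band of one channel."""

    band: int
    start: int              # sample index, inclusive
    end: int                # sample index, exclusive
    peak_z: float
    peak_sample: int
    peak_amplitude: float
    seg_signal: np.ndarray = field(repr=False)   # band waveform over [start, end)
    seg_z: np.ndarray = field(repr=False)


def detect_candidates(z: np.ndarray, band_freq: float, fs: float,
                      params: DetectorParams,
                      band: int = 0,
                      band_signal: np.ndarray | None = None,
                      envelope: np.ndarray | None = None) -> list[Candidate]:
    """Maximal runs with z above the candidate threshold lasting at least
    ``candidate_min_cycles / band_freq`` seconds."""
    above = z > params.candidate_z
    if not above.any():
        return []
    d = np.diff(above.astype(np.int8))
    starts = np.flatnonzero(d == 1) + 1
    ends = np.flatnonzero(d == -1) + 1
    if above[0]:
        starts = np.concatenate(([0], starts))
    if above[-1]:
        ends = np.concatenate((ends, [above.size]))
    min_len = params.candidate_min_cycles / band_freq * fs
    out = []
    for s, e in zip(starts, ends):
        if e - s < min_len:
            continue
        seg_z = z[s:e]
        k = int(np.argmax(seg_z))
        amp = float(envelope[s + k]) if envelope is not None else float("nan")
        seg = band_signal[s:e].copy() if band_signal is not None else np.empty(0)
        out.append(Candidate(band=band, start=int(s), end=int(e),
                             peak_z=float(seg_z[k]), peak_sample=int(s + k),
                             peak_amplitude=amp, seg_signal=seg,
                             seg_z=seg_z.copy()))
    return out


@dataclass
class MergedEvent:
    """Candidates from several bands fused by temporal overlap."""

    start: int
    end: int
    members: list[Candidate]

    @property
    def dominant(self) -> Candidate:
        return max(self.members, key=lambda c: c.peak_z)


def merge_across_bands(candidates: list[Candidate],
                       band_gap: int | None = 1) -> list[MergedEvent]:
    """Fuse temporally overlapping candidates across bands, transitively.

    With the default ``band_gap=1`` only candidates in the same or adjacent
    bands link directly (transitive chains still span many bands), so a burst
    whose energy occupies a contiguous run of bands merges into one event
    while an unrelated excursion in a distant band stays separate — distant
    merging lets background fluctuations hijack the dominant-frequency and
    peak-time estimates.  ``band_gap=None`` links any pair of overlapping
    candidates regardless of band.
    """
    if not candidates:
        return []
    n = len(candidates)
    parent = list(range(n))

    def find(i: int) -> int:
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    def union(i: int, j: int) -> None:
        ri, rj = find(i), find(j)
        if ri != rj:
            parent[rj] = ri

    order = sorted(range(n), key=lambda i: candidates[i].start)
    for ai in range(n):
        i = order[ai]
        ci = candidates[i]
        for aj in range(ai + 1, n):
            j = order[aj]
            cj = candidates[j]
            if cj.start >= ci.end:
                break
            if band_gap is None or abs(ci.band - cj.band) <= band_gap:
                union(i, j)
    groups: dict[int, list[Candidate]] = {}
    for i in range(n):
        groups.setdefault(find(i), []).append(candidates[i])
    events = [MergedEvent(start=min(c.start for c in members),
                          end=max(c.end for c in members),
                          members=sorted(members, key=lambda c: c.band))
              for members in groups.values()]
    return sorted(events, key=lambda ev: (ev.start, ev.end))


def apply_dual_threshold(events: list[MergedEvent], bank: FilterBank,
                         fs: float, params: DetectorParams) -> list[MergedEvent]:
    """Keep events with peak z above threshold and at least
    ``event_min_cycles`` at the dominant frequency."""
    kept = []
    for ev in events:
        dom = ev.dominant
        if dom.peak_z <= params.peak_z:
            continue
        dom_freq = bank.centers[dom.band]
        if (ev.end - ev.start) / fs < params.event_min_cycles / dom_freq:
            continue
        kept.append(ev)
    return kept


def verify_cycles(event: MergedEvent, params: DetectorParams) -> bool:
    """True iff one full oscillation cycle of the dominant-band waveform lies
    entirely inside the z > peak_z region.

    A cycle is the span between two consecutive same-direction zero crossings
    of the mean-subtracted band signal.
    """
    dom = event.dominant
    sig = dom.seg_signal
    if sig.size < 3:
        return False
    x = sig - sig.mean()
    above = dom.seg_z > params.peak_z
    sign = np.sign(x)
    sign[sign == 0] = 1
    rising = np.flatnonzero((sign[:-1] < 0) & (sign[1:] > 0)) + 1
    falling = np.flatnonzero((sign[:-1] > 0) & (sign[1:] < 0)) + 1
    for crossings in (rising, falling):
        for a, b in zip(crossings[:-1], crossings[1:]):
            if above[a:b + 1].all():
                return True
    return False


# ---------------------------------------------------------------------------
# specificity filter
# ---------------------------------------------------------------------------

def specificity_filter(events: pd.DataFrame, seed: int = 0,
                       min_centroid_ratio: float = 2.0,
                       max_reject_frac: float = 0.5,
                       min_diffuse_span: float = 150.0,
                       force: bool = False):
    """Reject spectrally diffuse events by k-means (k = 2) on frequency span.

    The cluster with the larger mean span is labelled diffuse.  Rejection
    only takes place when the clusters are clearly separated (wide centroid
    at least ``min_centroid_ratio`` times the narrow one), the wide centroid
    is diffuse in absolute terms (at least ``min_diffuse_span`` Hz — a
    spectrally diffuse transient occupies a sizable fraction of the 60-800 Hz
    range, whereas a legitimate burst spans a few tens of Hz), and the
    diffuse cluster is not the majority (artifact populations are assumed to
    be a minority).  Otherwise all events pass through with a warning.
    ``force=True`` skips the guards.

    Returns ``(kept, rejected)`` DataFrames partitioning the input.
    """
    empty = events.iloc[0:0]
    if len(events) < 2:
        return events.copy(), empty.copy()
    spans = events["freq_span"].to_numpy(dtype=float)
    if np.ptp(spans) == 0:
        warnings.warn("all frequency spans identical; specificity filter passes"
                      " everything through")
        return events.copy(), empty.copy()
    km = KMeans(n_clusters=2, n_init=10, random_state=seed)
    labels = km.fit_predict(spans.reshape(-1, 1))
    centers = km.cluster_centers_.ravel()
    wide = int(np.argmax(centers))
    is_wide = labels == wide
    if not force:
        narrow_c = max(centers.min(), 1e-9)
        if centers.max() < min_centroid_ratio * narrow_c:
            warnings.warn("span clusters not separated; no events rejected")
            return events.copy(), empty.copy()
        if centers.max() < min_diffuse_span:
            warnings.warn("wide cluster is not spectrally diffuse; "
                          "no events rejected")
            return events.copy(), empty.copy()
        if is_wide.mean() > max_reject_frac:
            warnings.warn("diffuse cluster is the majority; no events rejected")
            return events.copy(), empty.copy()
    return events.loc[~is_wide].copy(), events.loc[is_wide].copy()


# ---------------------------------------------------------------------------
# full chain
# ---------------------------------------------------------------------------

def detect_channel(x: np.ndarray, bank: FilterBank, fs: float,
                   params: DetectorParams) -> list[MergedEvent]:
    """Run the candidate/merge/threshold/verification chain on one channel.

    Bands are processed one at a time from a shared FFT of the channel to
    keep the working set to a single band.
    """
    x = np.asarray(x, dtype=float)
    n = x.size
    masked = np.fft.fft(x) * bank._analytic_mask(n)
    gains = bank._gains(n)
    candidates: list[Candidate] = []
    for b in range(bank.n_bands):
        analytic = np.fft.ifft(masked * gains[b])
        band_sig = analytic.real
        env = np.abs(analytic)
        z = sliding_zscore(env, fs, params.z_window)
        candidates.extend(detect_candidates(
            z, bank.centers[b], fs, params, band=b,
            band_signal=band_sig, envelope=env))
    merged = merge_across_bands(candidates)
    passed = apply_dual_threshold(merged, bank, fs, params)
    return [ev for ev in passed if verify_cycles(ev, params)]


def detect_hfos(signal: SignalRecord, spec: FilterBankSpec | None = None,
                params: DetectorParams | None = None,
                analysis_band: tuple[float, float] | None = (60.0, 600.0),
                apply_specificity: bool = True, seed: int = 0,
                **bank_kw) -> pd.DataFrame:
    """Detect HFO bursts on every channel of a recording.

    Returns a table with one row per event (columns
    :data:`cohfo.types.HFO_EVENT_COLUMNS`), sorted by (channel, onset).
    Events whose dominant frequency falls outside ``analysis_band`` are
    excluded; the spectral specificity filter runs across all channels of the
    recording.
    """
    params = params or DetectorParams()
    bank = FilterBank(spec, signal.fs, **bank_kw)
    rows = []
    for ci, name in enumerate(signal.channels):
        for ev in detect_channel(signal.data[ci], bank, signal.fs, params):
            dom = ev.dominant
            dom_freq = float(bank.centers[dom.band])
            bands = [c.band for c in ev.members]
            rows.append(dict(
                subject=signal.subject, channel=name,
                onset=ev.start / signal.fs, offset=ev.end / signal.fs,
                peak_time=dom.peak_sample / signal.fs,
                dominant_freq=dom_freq,
                freq_min=float(bank.edges[min(bands)]),
                freq_max=float(bank.edges[max(bands) + 1]),
                freq_span=float(bank.edges[max(bands) + 1] - bank.edges[min(bands)]),
                peak_z=dom.peak_z, peak_amplitude=dom.peak_amplitude,
            ))
    events = pd.DataFrame(rows, columns=HFO_EVENT_COLUMNS)
    if analysis_band is not None and len(events):
        lo, hi = analysis_band
        events = events[(events.dominant_freq >= lo)
                        & (events.dominant_freq <= hi)]
    if apply_specificity and len(events) >= 2:
        events, _ = specificity_filter(events, seed=seed)
    return (events.sort_values(["channel", "onset"], kind="stable")
                  .reset_index(drop=True))
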