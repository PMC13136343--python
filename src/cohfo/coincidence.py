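"""Peri-event rasters and coincident-HFO probability traces.

Detected bursts are reduced to point events at their envelope peak, binned
into binary channels x 10-ms-bin rasters aligned to task events within a
+/-1.5 s window, and scanned for coincidences: an HFO on one channel is a
co-HFO when any other channel carries an HFO within +/-50 ms (+/-5 bins).
Channels are classified as correlated or non-correlated by the maximum of
their pairwise Pearson correlations over the session rasters (threshold
r > 0.5 by default, with r > 0.3 / r > 0.7 sensitivity settings), and per-bin
co-HFO counts are turned into probability traces: averaged within subject,
rescaled to a per-second rate (x100 for 10-ms bins), then normalized so each
full trace sums to one.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

DEFAULT_BIN_WIDTH = 0.010   # s
DEFAULT_WINDOW = 1.5        # s, half-width of the peri-event window
DEFAULT_HALFWIDTH_BINS = 5  # +/-50 ms coincidence window at 10-ms bins
DEFAULT_THRESHOLD = 0.5     # correlated-class Pearson r cutoff


@dataclass
class BurstRaster:
    """Binary channels x bins matrix aligned to one task event."""

    matrix: np.ndarray           # (n_channels, n_bins) of 0/1
    channels: list[str]
    align_time: float
    bin_width: float = DEFAULT_BIN_WIDTH
    window: float = DEFAULT_WINDOW
    subject: str = "S01"

    @property
    def n_bins(self) -> int:
        return self.matrix.shape[1]

    @property
    def bin_centers(self) -> np.ndarray:
        edges = -self.window + self.bin_width * np.arange(self.n_bins)
        return edges + self.bin_width / 2.0


@dataclass
class CoincidenceTraces:
    """Normalized and per-second co-HFO probability traces.

    ``table`` is long format with columns (condition, channel_class,
    bin_center_s, probability, per_second_rate).  Each full probability
    vector sums to one; the per-second vector is the per-bin rate scaled by
    1/bin_width.
    """

    table: pd.DataFrame
    bin_width: float = DEFAULT_BIN_WIDTH
    window: float = DEFAULT_WINDOW
    flags: list[str] = field(default_factory=list)
    #: long table (value, condition, subject, bin) of per-subject mean co-HFO
    #: counts in the correlated class, the substrate of per-bin mixed models
    subject_table: pd.DataFrame | None = None


def build_raster(events: pd.DataFrame, align_times: np.ndarray,
                 channels: list[str], bin_width: float = DEFAULT_BIN_WIDTH,
                 window: float = DEFAULT_WINDOW,
                 duration: float | None = None,
                 subject: str = "S01") -> list[BurstRaster]:
    """Bin event peak times into one binary raster per align time.

    Bin ``b`` of channel ``c`` is one iff at least one event peak falls in the
    half-open interval ``[t0 - window + b*bin_width, t0 - window +
    (b+1)*bin_width)``.  Align times closer than ``window`` to a recording
    edge are skipped when ``duration`` is given (truncated trials are excluded
    from probability averaging).
    """
    n_bins = int(round(2.0 * window / bin_width))
    chan_index = {c: i for i, c in enumerate(channels)}
    ch = events["channel"].map(chan_index).to_numpy(dtype=float)
    t = events["peak_time"].to_numpy(dtype=float)
    ok = ~np.isnan(ch)
    ch, t = ch[ok].astype(int), t[ok]
    rasters = []
    for t0 in np.asarray(align_times, dtype=float):
        if duration is not None and (t0 - window < 0 or t0 + window > duration):
            continue
        b = np.floor((t - (t0 - window)) / bin_width).astype(int)
        inside = (b >= 0) & (b < n_bins)
        mat = np.zeros((len(channels), n_bins), dtype=np.int8)
        mat[ch[inside], b[inside]] = 1
        rasters.append(BurstRaster(matrix=mat, channels=list(channels),
                                   align_time=float(t0), bin_width=bin_width,
                                   window=window, subject=subject))
    return rasters


def cohfo_flags(matrix: np.ndarray,
                halfwidth_bins: int = DEFAULT_HALFWIDTH_BINS) -> np.ndarray:
    """Boolean mask of channel-bins whose HFO coincides with another channel.

    Entry (i, t) is True iff ``matrix[i, t] == 1`` and some channel j != i has
    an HFO in bins ``[t - halfwidth_bins, t + halfwidth_bins]``.
    """
    m = np.asarray(matrix)
    if m.ndim != 2:
        raise ValueError("raster must be 2-D")
    kernel = np.ones(2 * halfwidth_bins + 1)
    # windowed count of HFOs around each bin, per channel and in total
    smeared = np.apply_along_axis(
        lambda r: np.convolve(r, kernel, mode="same"), 1, m.astype(float))
    total = smeared.sum(axis=0, keepdims=True)
    others = total - smeared
    return (m > 0) & (others > 0)


def count_cohfo(raster: BurstRaster | np.ndarray,
                halfwidth_bins: int = DEFAULT_HALFWIDTH_BINS) -> np.ndarray:
    """Per-bin count of co-HFO-flagged channel-bins.

    Each channel-bin contributes at most once regardless of how many partner
    channels it coincides with.  A single-channel raster yields all zeros.
    """
    m = raster.matrix if isinstance(raster, BurstRaster) else np.asarray(raster)
    if m.shape[0] < 2:
        return np.zeros(m.shape[1], dtype=int)
    return cohfo_flags(m, halfwidth_bins).sum(axis=0).astype(int)


def pairwise_correlation(series: np.ndarray) -> np.ndarray:
    """Pearson correlation matrix between channel time series.

    Zero-variance channels get r = 0 off-diagonal (and 1 on the diagonal).
    """
    x = np.asarray(series, dtype=float)
    if x.ndim != 2 or x.shape[0] < 2:
        raise ValueError("need >= 2 equal-length channel series")
    sd = x.std(axis=1)
    degenerate = sd == 0
    if degenerate.any():
        warnings.warn(f"{int(degenerate.sum())} zero-variance channel(s); "
                      "their correlations are set to 0")
    with np.errstate(invalid="ignore", divide="ignore"):
        r = np.corrcoef(x)
    r[np.isnan(r)] = 0.0
    r[degenerate, :] = 0.0
    r[:, degenerate] = 0.0
    np.fill_diagonal(r, 1.0)
    return r


def classify_and_sort(corr: np.ndarray, labels: list[str],
                      threshold: float = DEFAULT_THRESHOLD):
    """Score channels by their maximum off-diagonal correlation.

    Returns ``(order, correlated, scores)``: channel indices sorted by score
    descending (ties broken by label), a boolean correlated-class mask
    (score > threshold) in original channel order, and the scores.
    """
    r = np.asarray(corr, dtype=float)
    n = r.shape[0]
    off = r.copy()
    np.fill_diagonal(off, -np.inf)
    scores = off.max(axis=1)
    order = sorted(range(n), key=lambda i: (-scores[i], labels[i]))
    correlated = scores > threshold
    return np.array(order), correlated, scores


def cohfo_probability(counts_by_subject: dict[str, np.ndarray],
                      bin_width: float = DEFAULT_BIN_WIDTH):
    """Average per-bin co-HFO rates across subjects and normalize.

    ``counts_by_subject`` maps subject id to an (n_trials, n_bins) array of
    per-bin co-HFO counts (or an already averaged 1-D per-bin rate).  The
    subject mean rates are averaged across subjects, scaled to per-second
    (x 1/bin_width), and the full vector normalized to sum to one.

    Returns ``(probability, per_second, flags)``.
    """
    means = []
    for arr in counts_by_subject.values():
        a = np.asarray(arr, dtype=float)
        means.append(a if a.ndim == 1 else a.mean(axis=0))
    rate = np.mean(means, axis=0)
    per_second = rate / bin_width
    total = per_second.sum()
    flags: list[str] = []
    if total <= 0:
        flags.append("all-zero counts; probability undefined")
        return np.zeros_like(rate), per_second, flags
    return per_second / total, per_second, flags


# ---------------------------------------------------------------------------
# session-level analysis
# ---------------------------------------------------------------------------

def _align_times(task: pd.DataFrame, stratum: str) -> np.ndarray:
    """Onset times for a named stratum of task events."""
    t = task
    if stratum in ("COUNTDOWN", "WORD", "DISTRACTOR", "RECALL", "CUE"):
        sel = t[t.trial_type == stratum]
    elif stratum == "WORD_RECALLED":
        sel = t[(t.trial_type == "WORD") & (t.recalled.astype(bool))]
    elif stratum == "WORD_FORGOTTEN":
        sel = t[(t.trial_type == "WORD") & (~t.recalled.astype(bool))]
    else:
        raise ValueError(f"unknown stratum {stratum!r}")
    return sel.onset.to_numpy(dtype=float)


CONTRASTS = {
    "recalled-vs-forgotten": ("WORD_RECALLED", "WORD_FORGOTTEN"),
    "phase-vs-phase": ("COUNTDOWN", "WORD", "DISTRACTOR", "RECALL"),
    "cue-locked-vs-vocalization-locked": ("CUE", "RECALL"),
}


def session_traces(events: pd.DataFrame, task: pd.DataFrame,
                   strata: tuple[str, ...] = ("RECALL",),
                   channels_by_subject: dict[str, list[str]] | None = None,
                   threshold: float = DEFAULT_THRESHOLD,
                   bin_width: float = DEFAULT_BIN_WIDTH,
                   window: float = DEFAULT_WINDOW,
                   halfwidth_bins: int = DEFAULT_HALFWIDTH_BINS,
                   duration: float | None = None) -> CoincidenceTraces:
    """Full coincidence analysis over one or more event strata.

    Per subject and stratum: peri-event rasters are built at the stratum's
    align times, channels classified by pairwise correlation of the
    concatenated rasters, co-HFO flags computed per trial on the full raster
    and counted separately inside the correlated and non-correlated classes,
    and per-bin mean counts averaged within the subject.  Subject means are
    then combined into normalized probability traces per (stratum, class).
    """
    flags: list[str] = []
    subjects = sorted(set(events.subject) | set(task.subject))
    n_bins = int(round(2 * window / bin_width))
    results: dict[tuple[str, str], dict[str, np.ndarray]] = {}
    subject_rows: list[dict] = []
    for stratum in strata:
        per_subject: dict[str, dict[str, np.ndarray]] = {}
        for subj in subjects:
            ev = events[events.subject == subj]
            tk = task[task.subject == subj]
            if channels_by_subject is not None:
                channels = list(channels_by_subject[subj])
            else:
                channels = sorted(ev.channel.unique())
            if len(channels) < 2:
                continue
            aligns = _align_times(tk, stratum)
            rasters = build_raster(ev, aligns, channels, bin_width, window,
                                   duration=duration, subject=subj)
            if not rasters:
                continue
            concat = np.concatenate([r.matrix for r in rasters], axis=1)
            corr = pairwise_correlation(concat)
            _, correlated, _ = classify_and_sort(corr, channels, threshold)
            counts = {"correlated": np.zeros((len(rasters), n_bins)),
                      "non-correlated": np.zeros((len(rasters), n_bins))}
            for ti, r in enumerate(rasters):
                f = cohfo_flags(r.matrix, halfwidth_bins)
                counts["correlated"][ti] = f[correlated].sum(axis=0)
                counts["non-correlated"][ti] = f[~correlated].sum(axis=0)
            per_subject[subj] = counts
            mean_corr = counts["correlated"].mean(axis=0)
            subject_rows.extend(
                dict(value=float(mean_corr[b]), condition=stratum,
                     subject=subj, bin=b) for b in range(n_bins))
        if not per_subject:
            flags.append(f"stratum {stratum}: no usable trials; excluded")
            continue
        for cls in ("correlated", "non-correlated"):
            by_subj = {s: c[cls] for s, c in per_subject.items()}
            prob, per_sec, fl = cohfo_probability(by_subj, bin_width)
            flags.extend(f"{stratum}/{cls}: {m}" for m in fl)
            results[(stratum, cls)] = {"probability": prob,
                                       "per_second": per_sec}
    centers = -window + bin_width * (np.arange(n_bins) + 0.5)
    rows = []
    for (stratum, cls), vec in results.items():
        for b in range(n_bins):
            rows.append(dict(condition=stratum, channel_class=cls,
                             bin_center_s=centers[b],
                             probability=vec["probability"][b],
                             per_second_rate=vec["per_second"][b]))
    table = pd.DataFrame(rows, columns=["condition", "channel_class",
                                        "bin_center_s", "probability",
                                        "per_second_rate"])
    subject_table = pd.DataFrame(subject_rows,
                                 columns=["value", "condition", "subject",
                                          "bin"])
    return CoincidenceTraces(table=table, bin_width=bin_width, window=window,
                             flags=flags, subject_table=subject_table)


def contrast_traces(events: pd.DataFrame, task: pd.DataFrame, contrast: str,
                    **kw) -> CoincidenceTraces:
    """Paired traces for a named contrast (identical binning per stratum)."""
    try:
        strata = CONTRASTS[contrast]
    except KeyError:
        raise ValueError(
            f"unknown contrast {contrast!r}; one of {sorted(CONTRASTS)}"
        ) from None
    return session_traces(events, task, strata=strata, **kw)
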