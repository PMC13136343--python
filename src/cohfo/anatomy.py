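"""Anatomical summaries of co-bursting networks.

Channels arrive with atlas region labels already assigned (the imaging and
atlas lookup are upstream of this package); a configurable label-to-lobe map
groups them into occipital, parietal, temporal, frontal and limbic lobes,
where the limbic set comprises hippocampus, amygdala, posterior cingulate and
parahippocampal cortex.  On top of that grouping the module quantifies the
spatial extent of correlated co-bursting (pairwise Euclidean distances in MNI
mm), per-lobe proportions of correlated channels, and per-channel
word-engagement frequencies.
"""

from __future__ import annotations

import importlib.resources
from io import StringIO

import numpy as np
import pandas as pd

LOBES = ("occipital", "parietal", "temporal", "frontal", "limbic")

CHANNEL_TABLE_COLUMNS = ["channel", "x", "y", "z", "region", "group", "tissue"]


def default_lobe_map() -> dict[str, str]:
    """Region-label to lobe mapping shipped with the package."""
    text = (importlib.resources.files("cohfo") / "data" / "lobe_map.tsv").read_text()
    df = pd.read_csv(StringIO(text), sep="\t")
    return {r.region.strip().lower(): r.lobe for r in df.itertuples()}


def assign_lobes(channels: pd.DataFrame,
                 lobe_map: dict[str, str] | None = None) -> pd.DataFrame:
    """Add a ``lobe`` column from region labels (case-insensitive match).

    Unknown regions become ``unassigned`` and are excluded from lobe-level
    analyses; their count is available from the returned table.
    """
    if "region" not in channels.columns:
        raise ValueError("channel table lacks a 'region' column")
    lobe_map = lobe_map or default_lobe_map()
    out = channels.copy()
    out["lobe"] = [lobe_map.get(str(r).strip().lower(), "unassigned")
                   for r in out["region"]]
    return out


def pair_distances(channels: pd.DataFrame,
                   pairs: list[tuple[str, str]],
                   bin_edges: np.ndarray | None = None):
    """Euclidean distances (mm) between correlated channel pairs.

    Pairs with missing coordinates are skipped and counted.  Returns
    ``(distances, histogram_counts, bin_edges, n_skipped)``; default bins are
    10-mm wide from 0 to 200 mm.
    """
    if bin_edges is None:
        bin_edges = np.arange(0.0, 210.0, 10.0)
    coords = {r.channel: np.array([r.x, r.y, r.z], dtype=float)
              for r in channels.itertuples()}
    dists, skipped = [], 0
    for a, b in pairs:
        pa, pb = coords.get(a), coords.get(b)
        if pa is None or pb is None or np.isnan(pa).any() or np.isnan(pb).any():
            skipped += 1
            continue
        dists.append(float(np.linalg.norm(pa - pb)))
    dists = np.asarray(dists)
    hist, _ = np.histogram(dists, bins=bin_edges)
    return dists, hist, bin_edges, skipped


def lobe_proportions(classes: pd.DataFrame, channels: pd.DataFrame,
                     gray_only: bool = False) -> pd.DataFrame:
    """Per-subject, per-lobe proportion of correlated channels.

    ``classes`` has columns (subject, channel, correlated); ``channels`` is a
    lobe-annotated channel table with a ``subject`` column.  The
    non-correlated proportion is the complement, so rows sum to one.  Lobes
    with zero channels for a subject are omitted for that subject; group
    means across subjects are provided in a companion frame accessible by
    ``groupby`` on the result.
    """
    ch = channels
    if gray_only and "tissue" in ch.columns:
        ch = ch[ch.tissue == "gray"]
    merged = classes.merge(ch[["subject", "channel", "lobe"]],
                           on=["subject", "channel"], how="inner")
    merged = merged[merged.lobe != "unassigned"]
    rows = []
    for (subj, lobe), grp in merged.groupby(["subject", "lobe"]):
        frac = float(grp["correlated"].astype(bool).mean())
        rows.append(dict(subject=subj, lobe=lobe, correlated=frac,
                         non_correlated=1.0 - frac, n_channels=len(grp)))
    return pd.DataFrame(rows, columns=["subject", "lobe", "correlated",
                                       "non_correlated", "n_channels"])


def engagement_frequency(participation: pd.DataFrame) -> pd.DataFrame:
    """Per-channel engagement: proportion of words with co-HFO participation.

    ``participation`` is long format with columns (subject, channel, word,
    phase, participated); ``phase`` is typically ``encoding`` or ``recall``.
    For each channel and phase the engagement is the participated fraction of
    that subject's word pool; zero analyzed words make the value undefined
    and the channel is dropped with a flag column on the result attrs.
    """
    required = {"subject", "channel", "word", "phase", "participated"}
    missing = required - set(participation.columns)
    if missing:
        raise ValueError(f"missing columns: {sorted(missing)}")
    rows = []
    dropped = 0
    for (subj, chan, phase), grp in participation.groupby(
            ["subject", "channel", "phase"]):
        n_words = grp["word"].nunique()
        if n_words == 0:
            dropped += 1
            continue
        engaged = grp.groupby("word")["participated"].any().sum()
        rows.append(dict(subject=subj, channel=chan, phase=phase,
                         engagement=float(engaged) / n_words,
                         n_words=int(n_words)))
    out = pd.DataFrame(rows, columns=["subject", "channel", "phase",
                                      "engagement", "n_words"])
    out.attrs["n_dropped"] = dropped
    return out


def normalize_by_implanted(engagement: pd.DataFrame,
                           channels: pd.DataFrame) -> pd.DataFrame:
    """Express per-subject engaged-channel counts as a fraction of that
    subject's implanted channels (comparability across coverage)."""
    counts = channels.groupby("subject")["channel"].nunique()
    out = engagement.copy()
    out["implanted"] = out["subject"].map(counts)
    out["engaged_fraction_of_implanted"] = out["engagement"] / out["implanted"]
    return out
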