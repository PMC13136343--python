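"""File formats and run configuration.

Signals are stored as a flat little-endian float32 binary per subject with a
JSON sidecar (sampling rate, channel names, units); event tables are
tab-separated with a header row.  Run configurations are plain YAML with
strict unknown-key rejection so parameter drift is caught before any
computation.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .types import HFO_EVENT_COLUMNS, TASK_EVENT_COLUMNS, TRIAL_TYPES, SignalRecord


class FormatError(ValueError):
    """Raised for malformed containers or event tables."""


# ---------------------------------------------------------------------------
# signal container
# ---------------------------------------------------------------------------

def write_signal(directory: str | Path, signal: SignalRecord) -> Path:
    """Write one subject's samples (.bin, float32 LE) plus JSON sidecar."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    bin_path = directory / f"{signal.subject}.bin"
    signal.data.astype("<f4").tofile(bin_path)
    sidecar = dict(subject=signal.subject, fs=signal.fs,
                   channels=list(signal.channels), units=signal.units,
                   n_samples=int(signal.n_samples))
    (directory / f"{signal.subject}.json").write_text(
        json.dumps(sidecar, indent=2, sort_keys=True) + "\n")
    return bin_path


def read_signal(path: str | Path, fs_override: float | None = None) -> SignalRecord:
    """Read a signal container (pass the .bin path or its sidecar)."""
    path = Path(path)
    if path.suffix == ".json":
        side_path, bin_path = path, path.with_suffix(".bin")
    else:
        side_path, bin_path = path.with_suffix(".json"), path
    if not side_path.exists() or not bin_path.exists():
        raise FormatError(f"missing container part for {path}")
    meta = json.loads(side_path.read_text())
    fs = fs_override if fs_override is not None else meta.get("fs", 0)
    if not fs or fs <= 0:
        raise FormatError(f"invalid sampling rate in sidecar: {meta.get('fs')}")
    channels = meta["channels"]
    raw = np.fromfile(bin_path, dtype="<f4")
    expected = len(channels) * int(meta["n_samples"])
    if raw.size != expected:
        raise FormatError(
            f"sample count mismatch in {bin_path.name}: expected {expected} "
            f"values ({4 * expected} bytes), found {raw.size} "
            f"({4 * raw.size} bytes)")
    data = raw.astype(float).reshape(len(channels), -1)
    return SignalRecord(data=data, fs=float(fs), channels=channels,
                        subject=meta.get("subject", bin_path.stem),
                        units=meta.get("units", "uV"))


# ---------------------------------------------------------------------------
# event tables
# ---------------------------------------------------------------------------

def write_events(path: str | Path, events: pd.DataFrame) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    events.to_csv(path, sep="\t", index=False, float_format="%.6f")
    return path


def read_events(path: str | Path, kind: str = "task") -> pd.DataFrame:
    """Read and validate a task-event or HFO-event table.

    ``kind`` is ``"task"`` or ``"hfo"``.  Unknown trial types and non-numeric
    onsets are rejected with the offending line numbers (1-based, counting
    the header as line 1).
    """
    path = Path(path)
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = TASK_EVENT_COLUMNS if kind == "task" else HFO_EVENT_COLUMNS
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise FormatError(f"{path.name}: missing required column(s) {missing}")
    numeric_cols = (["onset", "duration"] if kind == "task" else
                    [c for c in HFO_EVENT_COLUMNS
                     if c not in ("subject", "channel")])
    for col in numeric_cols:
        converted = pd.to_numeric(df[col], errors="coerce")
        bad = df.index[converted.isna() & df[col].notna()]
        if len(bad):
            lines = [int(i) + 2 for i in bad[:5]]
            raise FormatError(
                f"{path.name}: non-numeric {col!r} value(s) at line(s) {lines}")
        df[col] = converted
    if kind == "task":
        unknown = ~df["trial_type"].isin(TRIAL_TYPES)
        if unknown.any():
            lines = [int(i) + 2 for i in df.index[unknown][:5]]
            raise FormatError(
                f"{path.name}: unknown trial_type at line(s) {lines}")
        df["recalled"] = df["recalled"].astype(str).str.lower().isin(
            ("true", "1", "yes"))
    return df


# ---------------------------------------------------------------------------
# run configuration
# ---------------------------------------------------------------------------

#: recognised configuration keys, per stage
CONFIG_SCHEMA: dict[str, set[str]] = {
    "": {"seed", "out", "verbosity", "threads", "stages"},
    "simulator": {"n_subjects", "n_channels", "fs", "duration",
                  "noise_exponent", "noise_rms", "n_lists", "recall_prob",
                  "burst_freq_range", "burst_n_cycles", "burst_snr",
                  "coincidence_groups", "rate_profile", "task"},
    "rate_profile": {"baseline_rate", "recall_peak_gain", "recall_peak_sd",
                     "pre_recall_dip_gain", "pre_recall_dip_center",
                     "pre_recall_dip_sd", "encode_gain"},
    "coincidence_groups": {"members", "jitter_sd", "participation_prob"},
    "detector": {"candidate_z", "peak_z", "candidate_min_cycles",
                 "event_min_cycles", "z_window", "n_bands", "f_lo", "f_hi",
                 "transition_width", "analysis_band", "apply_specificity"},
    "coincidence": {"threshold", "bin_width", "window", "halfwidth_bins",
                    "strata", "contrast"},
    "cluster": {"n_boot", "jitter_min", "jitter_max", "n_clusters"},
    "stats": {"alpha", "fdr_q", "n_perm"},
    "anatomy": {"gray_only", "lobe_map"},
}


class ConfigError(ValueError):
    """Raised for unknown or inconsistent configuration keys."""


_STAGES = {"simulator", "detector", "coincidence", "cluster", "stats",
           "anatomy"}


def validate_config(cfg: dict) -> dict:
    """Reject unknown keys anywhere in the configuration tree."""
    def check(mapping: dict, schema_key: str, where: str) -> None:
        allowed = set(CONFIG_SCHEMA[schema_key])
        if schema_key == "":
            allowed |= _STAGES
        for key, value in mapping.items():
            if key not in allowed:
                raise ConfigError(f"unknown configuration key {where}{key!r}")
            if isinstance(value, dict) and key in CONFIG_SCHEMA:
                check(value, key, f"{where}{key}.")
            elif key == "coincidence_groups" and isinstance(value, list):
                for g in value:
                    check(g, "coincidence_groups", f"{where}{key}[].")

    cfg = cfg or {}
    check(cfg, "", "")
    return cfg


def load_config(path: str | Path) -> dict:
    with open(path) as fh:
        return validate_config(yaml.safe_load(fh) or {})


# ---------------------------------------------------------------------------
# manifest
# ---------------------------------------------------------------------------

def file_sha256(path: str | Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def write_manifest(out_dir: str | Path, config: dict, seed: int,
                   outputs: list[Path]) -> Path:
    """Record parameters, seed, software version and output hashes."""
    from . import __version__
    out_dir = Path(out_dir)

    def key(p: Path) -> str:
        try:
            return str(p.relative_to(out_dir))
        except ValueError:
            return p.name

    manifest = dict(
        version=__version__,
        seed=seed,
        config=config,
        outputs={key(p): file_sha256(p) for p in sorted(outputs)},
    )
    path = out_dir / "manifest.json"
    path.write_text(json.dumps(manifest, indent=2, sort_keys=True,
                               default=str) + "\n")
    return path
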