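"""File formats and configuration.

Spike events travel as a long-format CSV (cell_id, mouse_id, condition,
t_s, event_type) with an optional metadata sidecar ``<stem>.meta.csv``
carrying per-cell recording start, duration and injection time; without
the sidecar the duration is inferred from the event span.  All times are
seconds; minutes appear only in behavioral tables whose columns say so.

Run configuration is a flat ``key = value`` text file; unknown keys and
malformed lines are errors that name the offending key or line.
"""

from __future__ import annotations

from dataclasses import dataclass, fields
from pathlib import Path
import warnings

import numpy as np
import pandas as pd

from .errors import ConfigError, SchemaError
from .metrics import MetricOptions
from .synthetic import CohortDataset, SpikeTrain

__all__ = [
    "RunConfig",
    "read_spike_csv",
    "write_spike_csv",
    "write_summary_csv",
    "read_config",
    "write_config",
]

SPIKE_COLUMNS = ["cell_id", "mouse_id", "condition", "t_s", "event_type"]
META_COLUMNS = ["cell_id", "t_start_s", "duration_s", "t_injection_s"]
_FLOAT_FMT = "%.9g"


@dataclass(frozen=True)
class RunConfig:
    """Pipeline configuration with provenance-friendly defaults."""

    bin_width_s: float = 0.001
    max_isi_s: float = 1.0
    min_isis: int = 100
    exclude_complex: bool = True
    bin_width_min: float = 10.0
    seed: int = 0
    log_level: str = "INFO"

    def metric_options(self) -> MetricOptions:
        return MetricOptions(
            bin_width_s=self.bin_width_s,
            max_isi_s=self.max_isi_s,
            min_isis=self.min_isis,
            exclude_complex=self.exclude_complex,
        )


def _meta_path(path: Path) -> Path:
    return path.with_suffix(".meta.csv")


def write_spike_csv(trains, path) -> None:
    """Serialize trains to the long-format CSV plus the metadata sidecar."""
    path = Path(path)
    rows = []
    meta = []
    for tr in trains:
        for t in tr.simple_spikes:
            rows.append((tr.cell_id, tr.mouse_id, tr.condition, t, "simple"))
        for t in tr.complex_spikes:
            rows.append((tr.cell_id, tr.mouse_id, tr.condition, t, "complex"))
        meta.append(
            (
                tr.cell_id,
                tr.t_start_s,
                tr.duration_s,
                "" if tr.t_injection_s is None else tr.t_injection_s,
            )
        )
    df = pd.DataFrame(rows, columns=SPIKE_COLUMNS)
    df = df.sort_values(["cell_id", "t_s"], kind="stable")
    df.to_csv(path, index=False, float_format=_FLOAT_FMT)
    pd.DataFrame(meta, columns=META_COLUMNS).to_csv(
        _meta_path(path), index=False, float_format=_FLOAT_FMT
    )


def read_spike_csv(path) -> list[SpikeTrain]:
    """Load spike trains, grouping events by cell.

    Unsorted event times are sorted with a warning.  Without a metadata
    sidecar, the recording window is inferred as [min t, max t].
    """
    path = Path(path)
    try:
        df = pd.read_csv(path)
    except pd.errors.EmptyDataError as e:
        raise SchemaError(f"{path}: empty file without header") from e
    missing = [c for c in SPIKE_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing required columns {missing}")
    if len(df) == 0:
        return []
    t_num = pd.to_numeric(df["t_s"], errors="coerce")
    bad = np.nonzero(t_num.isna().to_numpy())[0]
    if bad.size:
        raise SchemaError(
            f"{path}: non-numeric t_s at data line {int(bad[0]) + 2}"
        )
    df["t_s"] = t_num
    invalid = ~df["event_type"].isin(["simple", "complex"])
    if invalid.any():
        raise SchemaError(
            f"{path}: invalid event_type at data line {int(np.nonzero(invalid.to_numpy())[0][0]) + 2}"
        )
    meta = None
    mp = _meta_path(path)
    if mp.exists():
        meta = pd.read_csv(mp).set_index("cell_id")
    trains = []
    for cell_id, sub in df.groupby("cell_id", sort=True):
        ss = sub.loc[sub["event_type"] == "simple", "t_s"].to_numpy()
        cs = sub.loc[sub["event_type"] == "complex", "t_s"].to_numpy()
        for name, ev in (("simple", ss), ("complex", cs)):
            if ev.size > 1 and np.any(np.diff(ev) < 0):
                warnings.warn(f"{cell_id}: {name} events unsorted; sorting")
        ss, cs = np.sort(ss), np.sort(cs)
        if meta is not None and cell_id in meta.index:
            row = meta.loc[cell_id]
            t_start = float(row["t_start_s"])
            duration = float(row["duration_s"])
            t_inj = row["t_injection_s"]
            t_inj = None if pd.isna(t_inj) else float(t_inj)
        else:
            all_t = sub["t_s"].to_numpy()
            t_start = float(all_t.min())
            duration = float(all_t.max() - all_t.min()) or 1.0
            t_inj = None
        trains.append(
            SpikeTrain(
                cell_id=str(cell_id),
                mouse_id=str(sub["mouse_id"].iloc[0]),
                condition=str(sub["condition"].iloc[0]),
                t_start_s=t_start,
                duration_s=duration,
                simple_spikes=ss,
                complex_spikes=cs,
                t_injection_s=t_inj,
            )
        )
    return trains


def write_summary_csv(report, path) -> None:
    """Write an ExperimentReport's per-condition table (9 sig. digits)."""
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    report.summary_table.to_csv(path, index=False, float_format=_FLOAT_FMT)


def write_cohort(dataset: CohortDataset, out_dir) -> None:
    """Cohort CSV plus the ground-truth sidecar table."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    write_spike_csv(dataset.trains, out / "spikes.csv")
    dataset.ground_truth.to_csv(
        out / "ground_truth.csv", index=False, float_format=_FLOAT_FMT
    )


_CONFIG_TYPES = {f.name: f.type for f in fields(RunConfig)}


def _parse_value(key: str, raw: str):
    default = getattr(RunConfig(), key)
    if isinstance(default, bool):
        if raw.lower() in ("true", "1", "yes"):
            return True
        if raw.lower() in ("false", "0", "no"):
            return False
        raise ConfigError(f"key {key!r}: expected a boolean, got {raw!r}")
    if isinstance(default, int):
        return int(raw)
    if isinstance(default, float):
        return float(raw)
    return raw


def read_config(path) -> RunConfig:
    """Parse the flat key-value configuration file."""
    path = Path(path)
    values = {}
    valid = set(_CONFIG_TYPES)
    for lineno, line in enumerate(path.read_text().splitlines(), start=1):
        stripped = line.strip()
        if not stripped or stripped.startswith("#"):
            continue
        if "=" not in stripped:
            raise ConfigError(f"{path}:{lineno}: malformed line (expected key = value)")
        key, _, raw = stripped.partition("=")
        key, raw = key.strip(), raw.strip()
        if key not in valid:
            raise ConfigError(
                f"{path}:{lineno}: unknown key {key!r}; valid keys: {sorted(valid)}"
            )
        try:
            values[key] = _parse_value(key, raw)
        except ValueError as e:
            raise ConfigError(f"{path}:{lineno}: {e}") from e
    return RunConfig(**values)


def write_config(config: RunConfig, path) -> None:
    lines = [f"{f.name} = {getattr(config, f.name)}" for f in fields(RunConfig)]
    Path(path).write_text("\n".join(lines) + "\n")
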