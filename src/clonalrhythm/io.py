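"""Delimited-text readers/writers, configuration, seeding, and provenance.

All artifacts are plain tab-separated text with a mandatory header row and a
commented provenance header (config hash, seed, package version) so a run can
be reproduced exactly.  Plate tables have time (hours) in the first column
and one column per well; pedigree, rhythm-parameter, and expression tables
are tidy frames.  Expression count tables carry a probe-annotation sidecar
(probe_id, probe_class).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .rhythm import TimeSeries
from .simulate import CountMatrix, ExpressionSimConfig, SimConfig


class FormatError(ValueError):
    """Malformed input table."""


def config_hash(config: object) -> str:
    """Stable short hash of a configuration mapping or dataclass."""
    if dataclasses.is_dataclass(config) and not isinstance(config, type):
        payload = dataclasses.asdict(config)
    else:
        payload = dict(config)  # type: ignore[arg-type]
    blob = json.dumps(payload, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:12]


def provenance_header(config: object, seed: int | None = None) -> str:
    parts = [f"config_hash={config_hash(config)}", f"version={__version__}"]
    if seed is not None:
        parts.insert(1, f"seed={seed}")
    return "# " + " ".join(parts)


def spawn_seeds(global_seed: int, names: list[str]) -> dict[str, int]:
    """Deterministic per-stage child seeds from one global seed."""
    children = np.random.SeedSequence(global_seed).spawn(len(names))
    return {
        name: int(child.generate_state(1, dtype=np.uint32)[0]) & 0x7FFFFFFF
        for name, child in zip(names, children)
    }


def _write_frame(df: pd.DataFrame, path: Path | str, header: str | None) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        if header:
            fh.write(header + "\n")
        df.to_csv(fh, sep="\t", index=False, lineterminator="\n")


def write_table(
    df: pd.DataFrame,
    path: Path | str,
    config: object | None = None,
    seed: int | None = None,
) -> None:
    """Write a tidy frame as TSV with a provenance comment line."""
    header = provenance_header(config, seed) if config is not None else None
    _write_frame(df, path, header)


def read_table(path: Path | str) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#")


def write_plate_table(
    plate: list[TimeSeries],
    path: Path | str,
    config: object | None = None,
    seed: int | None = None,
) -> None:
    """Plate matrix: first column time_h, one column per well."""
    if not plate:
        raise ValueError("empty plate")
    ref = plate[0].time
    data = {"time_h": ref}
    for ts in plate:
        if len(ts.time) != len(ref) or np.max(np.abs(ts.time - ref)) > 1e-9:
            raise FormatError(f"well {ts.well_id!r} not on the shared grid")
        data[ts.well_id] = ts.values
    header = provenance_header(config, seed) if config is not None else None
    _write_frame(pd.DataFrame(data), path, header)


def read_plate_table(path: Path | str) -> list[TimeSeries]:
    """Read a plate matrix; rejects malformed grids, skips incomplete wells.

    Raises :class:`FormatError` (with the offending line number) on
    non-monotone or duplicated time points; wells containing missing values
    are dropped with a printed reason rather than failing the whole plate.
    """
    df = pd.read_csv(path, sep="\t", comment="#")
    if df.shape[1] < 2:
        raise FormatError("plate table needs a time column and >= 1 well")
    time = df.iloc[:, 0].to_numpy(dtype=float)
    diffs = np.diff(time)
    bad = np.where(diffs <= 0)[0]
    if len(bad):
        # +2 for header, +1 for 1-based numbering of the later row
        raise FormatError(
            f"non-monotone/duplicated time at line {int(bad[0]) + 3} of {path}"
        )
    if len(time) >= 2 and np.ptp(diffs) > 1e-9:
        raise FormatError(f"non-uniform time grid in {path}")
    out: list[TimeSeries] = []
    for col in df.columns[1:]:
        vals = df[col].to_numpy(dtype=float)
        if np.isnan(vals).any():
            print(f"rejecting well {col!r}: missing values")
            continue
        out.append(TimeSeries(time=time, values=vals, well_id=str(col)))
    return out


def write_count_matrix(
    cm: CountMatrix,
    counts_path: Path | str,
    annotation_path: Path | str,
    config: object | None = None,
    seed: int | None = None,
) -> None:
    """Counts as samples x probes TSV plus a (probe_id, probe_class) sidecar."""
    header = provenance_header(config, seed) if config is not None else None
    counts = cm.counts.reset_index().rename(columns={"index": "sample_id"})
    if cm.periods is not None:
        counts.insert(1, "period_h", cm.periods.to_numpy())
    _write_frame(counts, counts_path, header)
    ann = pd.DataFrame(
        {"probe_id": cm.probe_class.index, "probe_class": cm.probe_class.to_numpy()}
    )
    _write_frame(ann, annotation_path, header)


def read_count_matrix(
    counts_path: Path | str, annotation_path: Path | str
) -> CountMatrix:
    df = pd.read_csv(counts_path, sep="\t", comment="#")
    ann = pd.read_csv(annotation_path, sep="\t", comment="#")
    if "sample_id" not in df.columns:
        raise FormatError("count table must have a sample_id column")
    df = df.set_index("sample_id")
    df.index.name = None
    periods = None
    if "period_h" in df.columns:
        periods = df.pop("period_h")
    classes = pd.Series(
        ann["probe_class"].to_numpy(), index=ann["probe_id"].to_numpy()
    )
    missing = set(df.columns) - set(classes.index)
    if missing:
        raise FormatError(f"probes without annotation: {sorted(missing)[:5]}")
    return CountMatrix(
        counts=df.astype(int), probe_class=classes.reindex(df.columns),
        periods=periods,
    )


# --- run configuration ------------------------------------------------------

_SIM_KEYS = {f.name for f in dataclasses.fields(SimConfig)}
_EXPR_KEYS = {f.name for f in dataclasses.fields(ExpressionSimConfig)}
_STAGE_KEYS = {
    "simulation": _SIM_KEYS,
    "expression": _EXPR_KEYS,
    "selection": {
        "n_generations", "clones_per_generation", "tail_fraction",
        "measure_via_fit", "repeat_measurements",
    },
    "pedigree": {"n_founders", "progeny_per_parent", "n_generations"},
    "rhythm": {"window"},
    "stability": {"neighborhood", "min_separation", "max_cycles"},
    "run": {"seed", "outdir", "log_level"},
}


def load_run_config(path: Path | str) -> dict:
    """Parse and validate a YAML run configuration; unknown keys are rejected."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    if not isinstance(raw, dict):
        raise FormatError("run configuration must be a mapping")
    unknown_sections = set(raw) - set(_STAGE_KEYS)
    if unknown_sections:
        raise FormatError(f"unknown config sections: {sorted(unknown_sections)}")
    for section, content in raw.items():
        if content is None:
            continue
        bad = set(content) - _STAGE_KEYS[section]
        if bad:
            raise FormatError(
                f"unknown keys in section {section!r}: {sorted(bad)}"
            )
    return raw


def sim_config_from_run(raw: dict, seed: int | None = None) -> SimConfig:
    kwargs = dict(raw.get("simulation") or {})
    if "period_bounds" in kwargs:
        kwargs["period_bounds"] = tuple(kwargs["period_bounds"])
    if seed is not None:
        kwargs["seed"] = seed
    return SimConfig(**kwargs)
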