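"""CSV/YAML input validation, output writing, and run manifests.

Canonical on-disk formats (all UTF-8, header row required):

* coordinates CSV — long form, columns ``assessor, product, x_cm, y_cm``;
* citations CSV — long form, one citation per row, columns
  ``assessor, product, descriptor`` (a wide products x descriptors count
  matrix is accepted via ``wide=True``);
* samples CSV — columns ``sample, tss, ta`` plus optional
  ``weight_a, weight_b, weight_c`` and ``l_star, a_star, b_star``;
* wheel — JSON (canonical) or YAML config;
* run config — YAML, round-trips through :func:`load_config` /
  :func:`dump_config`.

Validation errors carry the file and row so a failing run names the exact
offending record. Every pipeline run directory receives a ``manifest.json``
echoing the configuration, seed and package version, sufficient to
reproduce the run.
"""

from __future__ import annotations

import json
import os
import tempfile
from dataclasses import asdict, dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .mfa import MappingSheet, sheets_from_frame
from .physchem import JuiceSample
from .stats import CitationTable

__all__ = [
    "ValidationError",
    "RunConfig",
    "load_config",
    "dump_config",
    "read_coordinates",
    "read_citations",
    "read_samples",
    "write_atomic",
    "write_manifest",
]


class ValidationError(ValueError):
    """Input failed validation; message names the file, row and rule."""


@dataclass
class RunConfig:
    """Paths and parameters for one pipeline run; all randomness uses ``seed``."""

    corpus_dir: str | None = None
    wheel_file: str | None = None
    coordinates_csv: str | None = None
    citations_csv: str | None = None
    samples_csv: str | None = None
    output_dir: str = "senslex-out"
    min_doc_fraction: float = 0.10
    fusion_threshold: float = 0.50
    n_max: int = 5
    min_citations: int = 3
    alpha: float = 0.05
    n_boot: int = 500
    coverage: float = 0.95
    brima_k: float = 10.0
    ratio_threshold: float = 20.0
    seed: int = 0
    extra: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        checks = [
            (0 < self.min_doc_fraction <= 1, "min_doc_fraction must be in (0, 1]"),
            (0 < self.fusion_threshold <= 1, "fusion_threshold must be in (0, 1]"),
            (self.n_max >= 1, "n_max must be >= 1"),
            (self.min_citations >= 1, "min_citations must be >= 1"),
            (0 < self.alpha < 1, "alpha must be in (0, 1)"),
            (self.n_boot >= 2, "n_boot must be >= 2"),
            (0 < self.coverage < 1, "coverage must be in (0, 1)"),
            (self.brima_k > 0, "brima_k must be positive"),
        ]
        for ok, msg in checks:
            if not ok:
                raise ValidationError(msg)


def load_config(path: str | Path) -> RunConfig:
    raw = yaml.safe_load(Path(path).read_text("utf-8")) or {}
    known = {f for f in RunConfig.__dataclass_fields__ if f != "extra"}
    kwargs = {k: v for k, v in raw.items() if k in known}
    extra = {k: v for k, v in raw.items() if k not in known}
    return RunConfig(**kwargs, extra=extra)


def dump_config(config: RunConfig, path: str | Path) -> None:
    raw = asdict(config)
    raw.update(raw.pop("extra"))
    Path(path).write_text(yaml.safe_dump(raw, sort_keys=True), "utf-8")


def _read_csv(path: str | Path, required: set[str]) -> pd.DataFrame:
    path = Path(path)
    try:
        frame = pd.read_csv(path)
    except Exception as exc:  # malformed CSV: surface file + parser message
        raise ValidationError(f"{path}: cannot parse CSV ({exc})") from exc
    missing = required - set(frame.columns)
    if missing:
        raise ValidationError(f"{path}: missing required columns {sorted(missing)}")
    return frame


def read_coordinates(path: str | Path) -> list[MappingSheet]:
    """Read and validate a long-form coordinates CSV into mapping sheets."""
    frame = _read_csv(path, {"assessor", "product", "x_cm", "y_cm"})
    for col in ("x_cm", "y_cm"):
        bad = frame.index[pd.to_numeric(frame[col], errors="coerce").isna()]
        if len(bad):
            raise ValidationError(
                f"{path}: row {bad[0] + 2}: {col} is not numeric"  # +2: header + 0-base
            )
    try:
        return sheets_from_frame(frame)
    except ValueError as exc:
        raise ValidationError(f"{path}: {exc}") from exc


def read_citations(
    path: str | Path,
    selectable: tuple[str, ...] | None = None,
    n_max: int = 5,
    wide: bool = False,
) -> CitationTable:
    """Read a citations CSV (long canonical form; wide counts with ``wide``).

    With ``selectable`` given, every descriptor must belong to the wheel's
    selectable set; the 1..n_max-citations-per-record rule is enforced.
    """
    if wide:
        frame = _read_csv(path, {"product"}).set_index("product")
        long_rows = []
        for product, row in frame.iterrows():
            for desc, count in row.items():
                for r in range(int(count)):
                    long_rows.append((f"assessor{r + 1}", product, desc))
        frame = pd.DataFrame(long_rows, columns=["assessor", "product", "descriptor"])
    else:
        frame = _read_csv(path, {"assessor", "product", "descriptor"})
    try:
        return CitationTable.from_frame(frame, selectable=selectable, n_max=n_max)
    except ValueError as exc:
        raise ValidationError(f"{path}: {exc}") from exc


def read_samples(path: str | Path) -> list[JuiceSample]:
    """Read and validate a physicochemical samples CSV."""
    frame = _read_csv(path, {"sample", "tss", "ta"})
    samples = []
    for i, row in frame.iterrows():
        weights = None
        if {"weight_a", "weight_b", "weight_c"} <= set(frame.columns) and pd.notna(
            row.get("weight_a")
        ):
            weights = (float(row["weight_a"]), float(row["weight_b"]), float(row["weight_c"]))
        lab = None
        if {"l_star", "a_star", "b_star"} <= set(frame.columns) and pd.notna(row.get("l_star")):
            lab = (float(row["l_star"]), float(row["a_star"]), float(row["b_star"]))
        try:
            samples.append(
                JuiceSample(
                    name=str(row["sample"]),
                    tss=float(row["tss"]),
                    ta=float(row["ta"]),
                    weights=weights,
                    lab=lab,
                )
            )
        except ValueError as exc:
            raise ValidationError(f"{path}: row {i + 2}: {exc}") from exc
    if not samples:
        raise ValidationError(f"{path}: no sample rows")
    return samples


def write_atomic(frame: pd.DataFrame, path: str | Path, **to_csv_kwargs) -> None:
    """Write a CSV atomically: tmp file in the target directory, then rename."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    fd, tmp = tempfile.mkstemp(dir=path.parent, suffix=".tmp")
    try:
        with os.fdopen(fd, "w", encoding="utf-8", newline="") as fh:
            frame.to_csv(fh, **to_csv_kwargs)
        os.replace(tmp, path)
    except BaseException:
        if os.path.exists(tmp):
            os.unlink(tmp)
        raise


def write_manifest(output_dir: str | Path, config: RunConfig, command: str) -> Path:
    """Drop a machine-readable manifest (config echo + seed + version)."""
    out = Path(output_dir)
    out.mkdir(parents=True, exist_ok=True)
    raw = asdict(config)
    raw.update(raw.pop("extra"))
    manifest = {"command": command, "senslex_version": __version__, "config": raw}
    path = out / "manifest.json"
    path.write_text(json.dumps(manifest, indent=2, sort_keys=True), "utf-8")
    return path
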