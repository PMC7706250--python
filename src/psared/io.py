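"""Reading PSA iteration tables and run configuration.

A probabilistic sensitivity analysis (PSA) produces one (incremental effect,
incremental cost) pair per Monte-Carlo iteration.  This module reads such
tables from CSV or XLSX into a validated :class:`PsaSample` and reads the
run configuration (grid resolution, contour levels, decorations) into a
:class:`RunConfig`.
"""

from __future__ import annotations

import csv
import io as _io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "PsaSample",
    "RunConfig",
    "PsaIoError",
    "read_psa_table",
    "load_config",
    "write_psa_table",
    "DEFAULT_N_BINS",
    "DEFAULT_LEVELS",
]

#: Grid resolution recommended for smooth density images.
DEFAULT_N_BINS = 1000
#: Conventional cumulative-probability contour levels.
DEFAULT_LEVELS = (0.1, 0.5, 0.95)


class PsaIoError(ValueError):
    """Raised for unreadable or invalid PSA input tables and configs."""


@dataclass(frozen=True)
class PsaSample:
    """Paired incremental-effect / incremental-cost draws from a PSA.

    Parameters
    ----------
    effects
        Incremental effects (e.g. QALYs), one value per PSA iteration.
    costs
        Incremental costs (currency units), aligned with ``effects``.
    """

    effects: np.ndarray
    costs: np.ndarray

    def __post_init__(self) -> None:
        eff = np.asarray(self.effects, dtype=float)
        cost = np.asarray(self.costs, dtype=float)
        if eff.ndim != 1 or cost.ndim != 1:
            raise PsaIoError("effects and costs must be one-dimensional")
        if eff.size != cost.size:
            raise PsaIoError(
                f"effects ({eff.size}) and costs ({cost.size}) differ in length"
            )
        if eff.size < 2:
            raise PsaIoError("a PSA sample needs at least 2 iterations")
        if not np.all(np.isfinite(eff)) or not np.all(np.isfinite(cost)):
            raise PsaIoError("all PSA values must be finite")
        # Zero spread on an axis is permitted here (degenerate fixtures are
        # legal data); automatic bandwidth selection rejects it downstream.
        object.__setattr__(self, "effects", eff)
        object.__setattr__(self, "costs", cost)

    @property
    def n_iterations(self) -> int:
        return int(self.effects.size)

    def __len__(self) -> int:
        return self.n_iterations


@dataclass(frozen=True)
class RunConfig:
    """Validated run configuration for the PSA-ReD pipeline."""

    n_bins: int = DEFAULT_N_BINS
    contour_levels: tuple[float, ...] = DEFAULT_LEVELS
    wtp_thresholds: tuple[float, ...] = ()
    base_case: Optional[tuple[float, float]] = None
    zoom_window: Optional[tuple[float, float, float, float]] = None
    title: str = ""
    xlabel: str = "Incremental QALYs"
    ylabel: str = "Incremental costs"
    legend_title: str = "Relative density"
    font_family: Optional[str] = None
    font_size: Optional[float] = None

    def __post_init__(self) -> None:
        if int(self.n_bins) < 2:
            raise PsaIoError(f"n_bins must be >= 2, got {self.n_bins}")
        object.__setattr__(self, "n_bins", int(self.n_bins))

        levels = tuple(dict.fromkeys(float(v) for v in self.contour_levels))
        if not levels:
            raise PsaIoError("at least one contour level is required")
        for lv in levels:
            if not (0.0 < lv < 1.0):
                raise PsaIoError(
                    f"contour level {lv} must lie strictly inside (0, 1)"
                )
        if any(b <= a for a, b in zip(levels, levels[1:])):
            raise PsaIoError(f"contour levels must be strictly ascending: {levels}")
        object.__setattr__(self, "contour_levels", levels)

        wtp = tuple(float(v) for v in self.wtp_thresholds)
        for lam in wtp:
            if not np.isfinite(lam) or lam < 0:
                raise PsaIoError(f"WTP threshold must be finite and >= 0, got {lam}")
        object.__setattr__(self, "wtp_thresholds", wtp)

        if self.base_case is not None:
            bc = (float(self.base_case[0]), float(self.base_case[1]))
            if not all(np.isfinite(bc)):
                raise PsaIoError("base case point must be finite")
            object.__setattr__(self, "base_case", bc)

        if self.zoom_window is not None:
            x0, x1, y0, y1 = (float(v) for v in self.zoom_window)
            if not (x0 < x1 and y0 < y1):
                raise PsaIoError(
                    f"zoom window must satisfy x0 < x1 and y0 < y1, got "
                    f"({x0}, {x1}, {y0}, {y1})"
                )
            object.__setattr__(self, "zoom_window", (x0, x1, y0, y1))


def _sniff_delimiter(text: str) -> str:
    try:
        return csv.Sniffer().sniff(text, delimiters=",;\t").delimiter
    except csv.Error:
        return ","


def _select_columns(
    df: pd.DataFrame, column_spec: Optional[Sequence] = None
) -> pd.DataFrame:
    """Resolve the effect and cost columns of a raw table.

    Default convention: first column = incremental effects (x), second =
    incremental costs (y).  A ``column_spec`` of two names or two integer
    positions overrides it; columns named ``effects``/``costs`` (any case)
    are picked up automatically.
    """
    if column_spec is not None:
        if len(column_spec) != 2:
            raise PsaIoError("column_spec must name exactly two columns")
        cols = []
        for c in column_spec:
            if isinstance(c, int):
                if c >= df.shape[1]:
                    raise PsaIoError(f"column index {c} out of range")
                cols.append(df.iloc[:, c])
            else:
                if c not in df.columns:
                    raise PsaIoError(f"column {c!r} not found in table")
                cols.append(df[c])
        return pd.concat(cols, axis=1)

    lower = {str(c).strip().lower(): c for c in df.columns}
    if "effects" in lower and "costs" in lower:
        return df[[lower["effects"], lower["costs"]]]
    if df.shape[1] < 2:
        raise PsaIoError(
            f"expected at least two numeric columns, found {df.shape[1]}"
        )
    return df.iloc[:, :2]


def _coerce_numeric(df: pd.DataFrame, n_header_rows: int) -> PsaSample:
    # Cell-wise float() keeps the parse exact to the last ulp (round-trip)
    # and lets errors name the offending row.
    values = np.empty((len(df), 2), dtype=float)
    for j in range(2):
        col = df.iloc[:, j].to_numpy()
        for i, cell in enumerate(col):
            row = i + 1 + n_header_rows
            if cell is None or (isinstance(cell, float) and np.isnan(cell)):
                raise PsaIoError(f"missing value in data row {row}")
            try:
                v = float(cell)
            except (TypeError, ValueError):
                raise PsaIoError(
                    f"non-numeric value {cell!r} in data row {row} (column "
                    f"{df.columns[j]!r}); decimal separator must be '.'"
                ) from None
            if not np.isfinite(v):
                raise PsaIoError(f"non-finite value {cell!r} in data row {row}")
            values[i, j] = v
    return PsaSample(effects=values[:, 0], costs=values[:, 1])


def read_psa_table(
    path: str | Path, column_spec: Optional[Sequence] = None
) -> PsaSample:
    """Read a two-column PSA iteration table from CSV or XLSX.

    The first column holds incremental effects, the second incremental
    costs, unless ``column_spec`` (two names or two integer positions)
    says otherwise.  A single non-numeric header row is detected and
    skipped.  Row order is preserved and values are never rescaled.
    """
    path = Path(path)
    if not path.exists():
        raise PsaIoError(f"input file not found: {path}")

    if path.suffix.lower() in {".xlsx", ".xlsm"}:
        raw = pd.read_excel(path, sheet_name=0, header=None, dtype=object)
    else:
        text = path.read_text()
        if not text.strip():
            raise PsaIoError(f"input file is empty: {path}")
        delim = _sniff_delimiter(text.splitlines()[0])
        raw = pd.read_csv(
            _io.StringIO(text), sep=delim, header=None, dtype=object,
            skip_blank_lines=True, float_precision="round_trip",
        )

    if raw.empty:
        raise PsaIoError(f"no data rows in {path}")

    # Header detection: if the first row is not fully numeric, treat it as
    # column names.
    first = raw.iloc[0]
    header_numeric = pd.to_numeric(first, errors="coerce").notna().all()
    n_header = 0
    if not header_numeric:
        raw = raw.iloc[1:].reset_index(drop=True)
        raw.columns = [str(v).strip() for v in first]
        n_header = 1
    if raw.empty:
        raise PsaIoError(f"no data rows in {path}")

    selected = _select_columns(raw, column_spec)
    return _coerce_numeric(selected, n_header)


def write_psa_table(sample: PsaSample, path: str | Path) -> Path:
    """Write a PsaSample as a two-column CSV (header ``effects,costs``).

    Uses ``repr``-precision floats so that a read-back round-trips exactly.
    """
    path = Path(path)
    if not path.parent.is_dir():
        raise PsaIoError(f"directory does not exist: {path.parent}")
    with open(path, "w", newline="") as fh:
        fh.write("effects,costs\n")
        for e, c in zip(sample.effects, sample.costs):
            fh.write(f"{float(e)!r},{float(c)!r}\n")
    return path


_CONFIG_KEYS = {
    "n_bins", "contour_levels", "wtp_thresholds", "base_case", "zoom_window",
    "title", "xlabel", "ylabel", "legend_title", "font_family", "font_size",
}


def load_config(path: str | Path | None = None, **overrides) -> RunConfig:
    """Build a RunConfig from an optional YAML file plus keyword overrides.

    Defaults are 1000 bins and contour levels (0.1, 0.5, 0.95).  Keyword
    arguments take precedence over file values.
    """
    values: dict = {}
    if path is not None:
        path = Path(path)
        if not path.exists():
            raise PsaIoError(f"config file not found: {path}")
        loaded = yaml.safe_load(path.read_text()) or {}
        if not isinstance(loaded, dict):
            raise PsaIoError("config file must contain a key-value mapping")
        unknown = set(loaded) - _CONFIG_KEYS
        if unknown:
            raise PsaIoError(f"unknown config keys: {sorted(unknown)}")
        values.update(loaded)
    values.update({k: v for k, v in overrides.items() if v is not None})
    return RunConfig(**values)
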