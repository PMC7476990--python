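"""Recording and feature-table I/O plus the shared domain types.

A recording is a multichannel unipolar electrogram sampled at ``fs`` Hz from
a rows x cols electrode grid held against the tissue, together with its
pacing metadata and experimental condition (baseline ``BL`` or carbenoxolone
``CBX``).  Recordings serialize to a self-contained CSV dialect:

* ``#key=value`` metadata header lines (fs, grid geometry, pacing, condition,
  site, dose),
* one header row of channel names ``ch01..chNN``,
* one row per sample, one column per channel, ``repr``-faithful decimals so a
  write/read round trip is bit-exact.

Feature tables (:class:`StudyTable`) are long-format CSVs with one row per
beat x channel: six key columns followed by the 19 morphology features and
the stimulus-to-(-dV/dt)max latency.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .config import STANDARD_CYCLE_LENGTHS_MS
from .errors import (
    MetadataError,
    SchemaError,
    ShapeError,
    UnsupportedFormatError,
)

CONDITIONS = ("BL", "CBX")

#: Table-ordered names of the 19 morphology features.
FEATURE_NAMES: tuple[str, ...] = (
    "rs_interval",
    "qr_interval",
    "qs_interval",
    "egm_duration",
    "q_point",
    "r_point",
    "s_point",
    "endpoint_amplitude",
    "rs_gradient",
    "qr_gradient",
    "s_endpoint_gradient",
    "fractionation_index",
    "r_width",
    "s_width",
    "rs_ratio",
    "rs_width_ratio",
    "rs_width_over_duration",
    "dvdt_max",
    "amplitude",
)

#: Latency from the pacing stimulus to the time of (-dV/dt)max, ms.
LATENCY_NAME = "stim_to_dvdt_latency"

ALL_FEATURE_COLUMNS: tuple[str, ...] = FEATURE_NAMES + (LATENCY_NAME,)

KEY_COLUMNS: tuple[str, ...] = (
    "heart_id",
    "condition",
    "site_index",
    "channel",
    "beat_index",
    "cycle_length",
)

STUDY_COLUMNS: tuple[str, ...] = KEY_COLUMNS + ALL_FEATURE_COLUMNS


# --------------------------------------------------------------------------
# domain types
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class ElectrodeGrid:
    """A rows x cols mapping-catheter electrode grid.

    ``pitch`` is the inter-electrode spacing (mm), ``height`` the electrode
    elevation above the tissue plane (mm) and ``origin`` the 2D position of
    electrode 1 (mm).  Channels run row-major from the origin corner; an
    optional in-plane rotation (degrees, about the origin) models catheter
    orientation.
    """

    rows: int = 4
    cols: int = 4
    pitch: float = 3.0
    height: float = 0.5
    origin: tuple[float, float] = (0.0, 0.0)
    rotation_deg: float = 0.0

    def __post_init__(self) -> None:
        if self.rows < 1 or self.cols < 1:
            raise ShapeError(f"grid must be at least 1x1, got {self.rows}x{self.cols}")
        if self.pitch <= 0:
            raise ShapeError(f"pitch must be > 0, got {self.pitch}")
        if self.height < 0:
            raise ShapeError(f"height must be >= 0, got {self.height}")

    @property
    def n_electrodes(self) -> int:
        return self.rows * self.cols

    def positions(self) -> np.ndarray:
        """(n_electrodes, 3) electrode coordinates in mm, channel 1 first."""
        jj, ii = np.meshgrid(np.arange(self.cols), np.arange(self.rows))
        x = jj.ravel() * self.pitch
        y = ii.ravel() * self.pitch
        th = math.radians(self.rotation_deg)
        xr = x * math.cos(th) - y * math.sin(th) + self.origin[0]
        yr = x * math.sin(th) + y * math.cos(th) + self.origin[1]
        z = np.full_like(xr, self.height)
        return np.column_stack([xr, yr, z])


@dataclass(frozen=True)
class PacingProtocol:
    """Steady-pacing metadata: cycle length (ms) and stimulus times (ms).

    ``stimulus_times`` may be empty when pacing annotations were not
    exported; downstream code then falls back to artefact detection.
    """

    cycle_length: float
    stimulus_times: tuple[float, ...] = ()
    pacing_site_label: str = "LV-base"
    enforce_standard_cycle: bool = True
    #: tolerance on inter-stimulus gaps, ms (one sample at 1 kHz)
    tolerance_ms: float = 1.0

    def __post_init__(self) -> None:
        if self.cycle_length <= 0:
            raise MetadataError(f"cycle_length must be > 0, got {self.cycle_length}")
        if self.enforce_standard_cycle and self.cycle_length not in STANDARD_CYCLE_LENGTHS_MS:
            raise MetadataError(
                f"cycle_length {self.cycle_length} not in the standard protocol "
                f"{STANDARD_CYCLE_LENGTHS_MS}; pass enforce_standard_cycle=False "
                "to override"
            )
        st = tuple(float(t) for t in self.stimulus_times)
        object.__setattr__(self, "stimulus_times", st)
        if len(st) >= 2:
            gaps = np.diff(st)
            if np.any(gaps <= 0):
                raise MetadataError("stimulus_times must be strictly increasing")
            if np.any(np.abs(gaps - self.cycle_length) > self.tolerance_ms):
                raise MetadataError(
                    "consecutive stimulus times must differ by cycle_length "
                    f"+/- {self.tolerance_ms} ms"
                )


@dataclass
class EgmRecording:
    """Multichannel unipolar EGM samples plus acquisition metadata.

    ``samples`` is a (channels x time) float array in mV.  Sites 1-12 are
    left-ventricular epicardium, 13-16 left-atrial; ``region`` is derived.
    """

    samples: np.ndarray
    fs: float
    grid: ElectrodeGrid
    pacing: PacingProtocol
    site_index: int = 1
    condition: str = "BL"
    dose_ml: float = 0.0

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 2:
            raise ShapeError("samples must be a 2D (channels x time) array")
        if self.fs <= 0:
            raise MetadataError(f"fs must be > 0, got {self.fs}")
        if self.samples.shape[0] != self.grid.n_electrodes:
            raise ShapeError(
                f"{self.samples.shape[0]} channels but grid has "
                f"{self.grid.n_electrodes} electrodes"
            )
        if not (1 <= self.site_index <= 16):
            raise MetadataError(f"site_index must be in 1..16, got {self.site_index}")
        if self.condition not in CONDITIONS:
            raise MetadataError(f"condition must be one of {CONDITIONS}")
        if self.dose_ml < 0:
            raise MetadataError("dose_ml must be >= 0")
        if np.isnan(self.samples).any():
            raise MetadataError("samples contain NaN")

    @property
    def region(self) -> str:
        """"LV" for sites 1-12, "LA" for sites 13-16."""
        return "LV" if self.site_index <= 12 else "LA"

    @property
    def n_channels(self) -> int:
        return self.samples.shape[0]

    @property
    def n_samples(self) -> int:
        return self.samples.shape[1]

    @property
    def times_ms(self) -> np.ndarray:
        return np.arange(self.n_samples) * (1000.0 / self.fs)

    def copy_with(self, samples: np.ndarray) -> "EgmRecording":
        return EgmRecording(
            samples=samples,
            fs=self.fs,
            grid=self.grid,
            pacing=self.pacing,
            site_index=self.site_index,
            condition=self.condition,
            dose_ml=self.dose_ml,
        )

    def equals(self, other: "EgmRecording") -> bool:
        return (
            np.array_equal(self.samples, other.samples)
            and self.fs == other.fs
            and self.grid == other.grid
            and self.pacing == other.pacing
            and self.site_index == other.site_index
            and self.condition == other.condition
            and self.dose_ml == other.dose_ml
        )


# --------------------------------------------------------------------------
# recording CSV dialect
# --------------------------------------------------------------------------

_FMT_VERSION = "egmorph-recording v1"


def write_recording(rec: EgmRecording, path: str | Path, format: str = "csv") -> Path:
    """Serialize a recording; ``read_recording`` inverts it bit-exactly (csv)."""
    if format == "wfdb":
        raise UnsupportedFormatError(
            "WFDB output is not available in this build; use format='csv'"
        )
    if format != "csv":
        raise UnsupportedFormatError(f"unknown recording format {format!r}")
    path = Path(path)
    g, p = rec.grid, rec.pacing
    lines = [
        f"#{_FMT_VERSION}",
        f"#fs={float(rec.fs)!r}",
        f"#rows={g.rows}",
        f"#cols={g.cols}",
        f"#pitch={float(g.pitch)!r}",
        f"#height={float(g.height)!r}",
        f"#origin={float(g.origin[0])!r},{float(g.origin[1])!r}",
        f"#rotation_deg={float(g.rotation_deg)!r}",
        f"#cycle_length={float(p.cycle_length)!r}",
        "#stimulus_times=" + ",".join(repr(float(t)) for t in p.stimulus_times),
        f"#pacing_site_label={p.pacing_site_label}",
        f"#enforce_standard_cycle={int(p.enforce_standard_cycle)}",
        f"#condition={rec.condition}",
        f"#site_index={rec.site_index}",
        f"#dose_ml={float(rec.dose_ml)!r}",
        ",".join(f"ch{i + 1:02d}" for i in range(rec.n_channels)),
    ]
    body = "\n".join(
        ",".join(repr(float(v)) for v in rec.samples[:, j])
        for j in range(rec.n_samples)
    )
    path.write_text("\n".join(lines) + ("\n" + body if body else "") + "\n")
    return path


def read_recording(path: str | Path, format: str = "csv") -> EgmRecording:
    """Read a recording written by :func:`write_recording`."""
    if format == "wfdb":
        raise UnsupportedFormatError(
            "WFDB input is not available in this build; use format='csv'"
        )
    if format != "csv":
        raise UnsupportedFormatError(f"unknown recording format {format!r}")
    path = Path(path)
    meta: dict[str, str] = {}
    channel_header: list[str] | None = None
    rows: list[list[float]] = []
    with path.open() as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line:
                continue
            if line.startswith("#"):
                if "=" in line:
                    key, _, val = line[1:].partition("=")
                    meta[key.strip()] = val
                continue
            if channel_header is None:
                channel_header = line.split(",")
                continue
            rows.append([float(v) for v in line.split(",")])
    if channel_header is None:
        raise MetadataError(f"{path}: no channel header row found")
    required = ("fs", "rows", "cols", "pitch", "height", "cycle_length",
                "condition", "site_index", "dose_ml")
    missing = [k for k in required if k not in meta]
    if missing:
        raise MetadataError(f"{path}: missing metadata key(s) {missing}")
    try:
        origin = tuple(float(v) for v in meta.get("origin", "0.0,0.0").split(","))
        grid = ElectrodeGrid(
            rows=int(meta["rows"]),
            cols=int(meta["cols"]),
            pitch=float(meta["pitch"]),
            height=float(meta["height"]),
            origin=(origin[0], origin[1]),
            rotation_deg=float(meta.get("rotation_deg", "0.0")),
        )
        stim_raw = meta.get("stimulus_times", "")
        stim = tuple(float(v) for v in stim_raw.split(",")) if stim_raw else ()
        pacing = PacingProtocol(
            cycle_length=float(meta["cycle_length"]),
            stimulus_times=stim,
            pacing_site_label=meta.get("pacing_site_label", ""),
            enforce_standard_cycle=bool(int(meta.get("enforce_standard_cycle", "1"))),
        )
        samples = np.array(rows, dtype=float).T if rows else np.empty((len(channel_header), 0))
        if rows and len(channel_header) != samples.shape[0]:
            raise ShapeError("channel header does not match sample columns")
        return EgmRecording(
            samples=samples,
            fs=float(meta["fs"]),
            grid=grid,
            pacing=pacing,
            site_index=int(meta["site_index"]),
            condition=meta["condition"],
            dose_ml=float(meta["dose_ml"]),
        )
    except (KeyError, ValueError) as exc:
        if isinstance(exc, (MetadataError, ShapeError)):
            raise
        raise MetadataError(f"{path}: malformed metadata ({exc})") from exc


# --------------------------------------------------------------------------
# study / feature tables
# --------------------------------------------------------------------------

class StudyTable:
    """Long-format container of per-beat feature vectors for a whole study.

    Thin wrapper around a :class:`pandas.DataFrame` with a fixed column
    order: six keys (heart, condition, site, channel, beat, cycle length)
    followed by the 19 morphology features and the stimulus latency.
    Undefined features are NaN.  Keys must be unique per beat.
    """

    columns = STUDY_COLUMNS

    def __init__(self, df: pd.DataFrame, validate: bool = True):
        missing = [c for c in STUDY_COLUMNS if c not in df.columns]
        if missing:
            raise SchemaError(f"feature table missing column(s) {missing}")
        extra = [c for c in df.columns if c not in STUDY_COLUMNS]
        if extra:
            raise SchemaError(f"unknown feature column(s) {extra}")
        self.df = df.loc[:, list(STUDY_COLUMNS)].reset_index(drop=True)
        if validate:
            self._validate()

    def _validate(self) -> None:
        bad = set(self.df["condition"].unique()) - set(CONDITIONS)
        if bad:
            raise SchemaError(f"unknown condition value(s) {sorted(bad)}")
        keys = ["heart_id", "condition", "site_index", "channel", "beat_index"]
        if self.df.duplicated(subset=keys).any():
            raise SchemaError("duplicate (heart, condition, site, channel, beat) keys")

    def __len__(self) -> int:
        return len(self.df)

    def __eq__(self, other: object) -> bool:
        return isinstance(other, StudyTable) and self.df.equals(other.df)

    @classmethod
    def from_records(cls, records: Iterable[dict]) -> "StudyTable":
        df = pd.DataFrame(list(records), columns=list(STUDY_COLUMNS))
        return cls(df)

    @classmethod
    def empty(cls) -> "StudyTable":
        return cls(pd.DataFrame(columns=list(STUDY_COLUMNS)), validate=False)

    def features(self, condition: str | None = None) -> pd.DataFrame:
        df = self.df
        if condition is not None:
            df = df[df["condition"] == condition]
        return df.loc[:, list(ALL_FEATURE_COLUMNS)]

    def concat(self, other: "StudyTable") -> "StudyTable":
        return StudyTable(pd.concat([self.df, other.df], ignore_index=True))


def write_feature_table(table: StudyTable, path: str | Path) -> Path:
    """Write a study table as plain CSV with stable column order.

    Two writes of an equal table are byte-identical (floats via ``repr``).
    """
    path = Path(path)
    lines = [",".join(STUDY_COLUMNS)]
    for row in table.df.itertuples(index=False):
        cells = []
        for col, v in zip(STUDY_COLUMNS, row):
            if col in ("heart_id", "condition"):
                cells.append(str(v))
            elif col in ("site_index", "channel", "beat_index"):
                cells.append(str(int(v)))
            else:
                fv = float(v)
                cells.append("" if math.isnan(fv) else repr(fv))
        lines.append(",".join(cells))
    path.write_text("\n".join(lines) + "\n")
    return path


def read_feature_table(path: str | Path) -> StudyTable:
    """Read a CSV written by :func:`write_feature_table`."""
    path = Path(path)
    df = pd.read_csv(path, dtype={"heart_id": str, "condition": str})
    if len(df) == 0:
        # preserve schema check on header-only files
        return StudyTable(df.reindex(columns=list(STUDY_COLUMNS))
                          if list(df.columns) == list(STUDY_COLUMNS) else df,
                          validate=False)
    for col in ("site_index", "channel", "beat_index"):
        if col in df.columns:
            df[col] = df[col].astype(int)
    return StudyTable(df)
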