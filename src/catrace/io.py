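"""Reading and writing ROI mean-intensity tables and event lists.

The input contract matches Fiji "Multi Measure" style exports: a header
row of text labels, then numeric rows only; the first (or a named)
column is the x axis, holding either time in ms or frame numbers, and
every remaining column is one ROI.  Both ``.xlsx`` (openpyxl via pandas)
and ``.csv`` are accepted with the identical contract.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .model import AcquisitionMeta, Recording

__all__ = [
    "TableLayout",
    "read_trace_table",
    "attach_reference",
    "write_trace_table",
    "read_ephys_csv",
    "events_to_frame",
]

#: maximum relative jitter tolerated in an explicit time column
_MAX_TIME_JITTER = 1e-3


@dataclass
class TableLayout:
    """Column-mapping description for an ROI table.

    ``x_kind`` says what the x column holds: "time_ms" (times in ms) or
    "frame" (0- or 1-based frame numbers; ``frame_rate`` is then
    required to synthesize times).  ``x_column`` names the x column;
    ``None`` means the first column.  ``sheet`` selects an XLSX sheet by
    name (default: first sheet).
    """

    x_kind: str = "time_ms"
    x_column: Optional[str] = None
    frame_rate: Optional[float] = None
    sheet: Optional[str] = None

    def __post_init__(self) -> None:
        if self.x_kind not in ("time_ms", "frame"):
            raise ValueError(f"x_kind must be time_ms|frame, got {self.x_kind!r}")


def _read_raw_table(path: Path, layout: TableLayout) -> pd.DataFrame:
    if not path.exists():
        raise FileNotFoundError(f"input table not found: {path}")
    if path.suffix.lower() in (".xlsx", ".xlsm"):
        sheet = layout.sheet if layout.sheet is not None else 0
        return pd.read_excel(path, sheet_name=sheet, header=0, dtype=object)
    return pd.read_csv(path, header=0, dtype=object, float_precision="round_trip")


def _validate_numeric(df: pd.DataFrame, path: Path) -> pd.DataFrame:
    """Enforce the header/body contract, returning a float frame.

    Errors name the offending cell in spreadsheet coordinates (1-based
    rows, the header being row 1).
    """
    for header in df.columns:
        try:
            float(str(header))
        except ValueError:
            continue
        raise ValueError(
            f"{path.name}: row 1 must contain text column headers, "
            f"found numeric value {header!r}"
        )
    out = {}
    for col in df.columns:
        coerced = pd.to_numeric(df[col], errors="coerce")
        bad = coerced.isna()
        if bad.any():
            row = int(np.flatnonzero(bad.to_numpy())[0])
            raise ValueError(
                f"{path.name}: non-numeric cell at row {row + 2}, "
                f"column {col!r} (value {df[col].iloc[row]!r})"
            )
        # Python's float() is correctly rounded, so a %.17g write/read
        # round trip is bit-identical (pandas' converters are not)
        out[col] = np.array([float(v) for v in df[col]], dtype=float)
    return pd.DataFrame(out)


def _time_axis(x: np.ndarray, layout: TableLayout) -> tuple[np.ndarray, float]:
    """Return (times_ms, frame_rate) from the x column."""
    if layout.x_kind == "frame":
        if layout.frame_rate is None:
            raise ValueError(
                "x column holds frame numbers but no frame_rate was given "
                "in the layout"
            )
        dt = 1000.0 / layout.frame_rate
        times = (x - x[0]) * dt
        return times, layout.frame_rate
    dts = np.diff(x)
    if np.any(dts <= 0):
        raise ValueError("time column must be strictly increasing")
    dt = float(np.median(dts))
    if np.max(np.abs(dts - dt)) > _MAX_TIME_JITTER * dt:
        raise ValueError(
            "time column is not uniformly sampled (jitter exceeds "
            f"{_MAX_TIME_JITTER:.1%} of the frame interval)"
        )
    return np.asarray(x, dtype=float), 1000.0 / dt


def read_trace_table(path: str | Path, layout: TableLayout | None = None) -> list[Recording]:
    """Read an ROI table into one :class:`Recording` per ROI column.

    The first row must contain text headers; all following rows must be
    numeric.  One column (``layout.x_column`` or the first) is the time
    or frame axis; each remaining column becomes a Recording whose
    ``roi_id`` is its header, in column order, row order preserved.
    """
    path = Path(path)
    layout = layout or TableLayout()
    df = _validate_numeric(_read_raw_table(path, layout), path)
    if df.shape[1] < 2:
        raise ValueError(f"{path.name}: need an x column plus at least one ROI column")
    if df.shape[0] < 2:
        raise ValueError(f"{path.name}: need at least 2 data rows")

    x_col = layout.x_column if layout.x_column is not None else df.columns[0]
    if x_col not in df.columns:
        raise ValueError(f"{path.name}: x column {x_col!r} not found")
    times, frame_rate = _time_axis(df[x_col].to_numpy(), layout)
    meta = AcquisitionMeta(frame_rate=frame_rate, start_time=float(times[0]))

    recordings = []
    for col in df.columns:
        if col == x_col:
            continue
        recordings.append(Recording(meta=meta, roi_id=str(col), signal=df[col].to_numpy()))
    return recordings


def attach_reference(
    recordings: list[Recording],
    path: str | Path,
    layout: TableLayout | None = None,
) -> list[Recording]:
    """Attach a reference-channel table to matching Recordings.

    Pairing is by ROI header, not column order.  Every signal ROI must
    appear in the reference table and the row counts must agree.
    """
    refs = read_trace_table(path, layout)
    by_id = {r.roi_id: r for r in refs}
    missing = [r.roi_id for r in recordings if r.roi_id not in by_id]
    if missing:
        raise ValueError(
            "reference table is missing ROI column(s): " + ", ".join(missing)
        )
    out = []
    for rec in recordings:
        ref = by_id[rec.roi_id]
        if ref.n_frames != rec.n_frames:
            raise ValueError(
                f"ROI {rec.roi_id!r}: reference has {ref.n_frames} rows, "
                f"signal has {rec.n_frames}"
            )
        out.append(
            Recording(
                meta=rec.meta,
                roi_id=rec.roi_id,
                signal=rec.signal,
                reference=ref.signal,
                mode=rec.mode,
            )
        )
    return out


def write_trace_table(
    recordings: Sequence[Recording],
    path: str | Path,
    channel: str = "signal",
    time_column: str = "time_ms",
) -> None:
    """Write Recordings back to the table format ``read_trace_table`` reads.

    All recordings must share a time axis.  CSV output uses repr-exact
    float formatting so a write/read round trip is bit-identical.
    """
    path = Path(path)
    if not recordings:
        raise ValueError("no recordings to write")
    n = recordings[0].n_frames
    data: dict[str, np.ndarray] = {time_column: recordings[0].times}
    for rec in recordings:
        if rec.n_frames != n:
            raise ValueError("all recordings must have the same length")
        values = rec.signal if channel == "signal" else rec.reference
        if values is None:
            raise ValueError(f"ROI {rec.roi_id!r} has no {channel} channel")
        data[rec.roi_id] = values
    df = pd.DataFrame(data)
    if path.suffix.lower() == ".xlsx":
        df.to_excel(path, index=False)
    else:
        df.to_csv(path, index=False, float_format="%.17g")


def read_ephys_csv(path: str | Path):
    """Read a miniature-event list (two columns: time_ms, amplitude_mV)."""
    from .stats import EphysEvent

    path = Path(path)
    df = _validate_numeric(_read_raw_table(path, TableLayout()), path)
    if df.shape[1] < 2:
        raise ValueError(f"{path.name}: expected columns time_ms, amplitude_mV")
    t, a = df.columns[:2]
    events = [
        EphysEvent(time=float(row[t]), amplitude=float(row[a]))
        for _, row in df.iterrows()
    ]
    return sorted(events, key=lambda e: e.time)


def events_to_frame(events, roi_id: str = "") -> pd.DataFrame:
    """Tabulate CaEvents as one row per event for CSV export."""
    rows = []
    for e in events:
        rows.append(
            {
                "roi": roi_id,
                "peak_time_ms": e.peak_time,
                "amplitude": e.amplitude,
                "tau_rise_ms": e.tau_rise,
                "tau_decay_ms": e.tau_decay,
                "onset_time_ms": e.onset_time,
                "fit_rss": e.fit_rss,
                "source": e.source,
                "label": e.label,
            }
        )
    columns = [
        "roi",
        "peak_time_ms",
        "amplitude",
        "tau_rise_ms",
        "tau_decay_ms",
        "onset_time_ms",
        "fit_rss",
        "source",
        "label",
    ]
    return pd.DataFrame(rows, columns=columns)
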