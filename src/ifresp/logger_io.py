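"""Readers and writers for respirometry logger files.

The package's native exchange format ("generic format") is a plain-text
table with columns ``Date.Time``, ``Phase``, ``Temp`` and one ``Ox.i``
column per chamber, tab-delimited on write and tab-or-whitespace tolerant
on read.  Vendor exports (AutoResp-style multichannel files, Q-box Aqua,
and AquaResp summaries paired with OxyView or PyroScience logs) are handled
through configurable column-mapping dialects; the shipped defaults are
best-effort profiles validated against synthetic fixtures, since vendor
layouts drift between versions.
"""

from __future__ import annotations

import datetime as _dt
import json
import warnings
from dataclasses import dataclass
from pathlib import Path

import pandas as pd

from .core import DataError, ExperimentInfo, MeasurementSet, PhaseSpan, segment_phases

__all__ = [
    "LoggerDialect",
    "get_dialect",
    "import_test",
    "import_meas",
    "convert_aquaresp",
    "export_results",
    "read_generic",
    "write_generic",
    "write_set",
    "read_set",
]

_DATE_FORMATS = {
    "DMY": "%d/%m/%Y %H:%M:%S",
    "MDY": "%m/%d/%Y %H:%M:%S",
    "YMD": "%Y-%m-%d %H:%M:%S",
}


@dataclass(frozen=True)
class LoggerDialect:
    """Column layout of one logger export flavour.

    ``temp_cols`` holds either a single shared temperature column or one per
    chamber (averaged on import, since the generic format carries one
    temperature series).
    """

    name: str
    header_skip: int
    delimiter: str | None  # None = tab preferred, whitespace tolerated
    datetime_col: int
    phase_col: int
    temp_cols: tuple[int, ...]
    o2_cols: tuple[int, ...]
    date_format: str = "DMY"
    strict_width: bool = False  # require exactly max(col)+1 fields per line

    def __post_init__(self) -> None:
        cols = [self.datetime_col, self.phase_col, *self.temp_cols, *self.o2_cols]
        if len(set(cols)) != len(cols):
            raise DataError(f"dialect {self.name}: column positions must be distinct")
        if not self.o2_cols:
            raise DataError(f"dialect {self.name}: needs at least one O2 column")
        if self.date_format not in _DATE_FORMATS:
            raise DataError(f"unknown date format {self.date_format!r} (DMY/MDY/YMD)")


DIALECT_NAMES = ("fishresp", "autoresp", "qboxaqua", "aquaresp_presens", "aquaresp_pyroscience")


def get_dialect(name: str, n_chamber: int, date_format: str = "DMY") -> LoggerDialect:
    """Shipped dialect profiles, parameterised by chamber count."""
    name = name.lower()
    if n_chamber < 1:
        raise DataError("n_chamber must be >= 1")
    if name in ("fishresp", "generic"):  # the community name for this layout, and ours
        name = "fishresp"
        return LoggerDialect(
            name, header_skip=1, delimiter=None,
            datetime_col=0, phase_col=1, temp_cols=(2,),
            o2_cols=tuple(range(3, 3 + n_chamber)),
            date_format=date_format, strict_width=True,
        )
    if name == "autoresp":
        # after the header block: datetime, phase, salinity, then (temp, ox) pairs
        return LoggerDialect(
            name, header_skip=38, delimiter="\t",
            datetime_col=0, phase_col=1,
            temp_cols=tuple(3 + 2 * i for i in range(n_chamber)),
            o2_cols=tuple(4 + 2 * i for i in range(n_chamber)),
            date_format=date_format,
        )
    if name == "qboxaqua":
        if n_chamber != 1:
            raise DataError("Q-box Aqua exports are single-chamber")
        return LoggerDialect(
            name, header_skip=1, delimiter="\t",
            datetime_col=0, phase_col=1, temp_cols=(2,), o2_cols=(3,),
            date_format=date_format,
        )
    if name in ("aquaresp_presens", "aquaresp_pyroscience"):
        raise DataError(
            f"{name} files are not imported directly; run convert_aquaresp() first, "
            "then import the resulting generic-format file"
        )
    raise DataError(f"unknown logger dialect {name!r}; known: {DIALECT_NAMES}")


def _num(token: str) -> float:
    """Parse a number, tolerating European decimal commas."""
    return float(token.replace(",", "."))


def _split(line: str, delimiter: str | None, merge_datetime: bool) -> list[str]:
    line = line.rstrip("\r\n")
    if delimiter is not None:
        return line.split(delimiter)
    if "\t" in line:
        return line.split("\t")
    tokens = line.split()
    # whitespace-split puts the date and clock time in separate tokens
    if merge_datetime and len(tokens) >= 2 and ":" in tokens[1]:
        tokens = [tokens[0] + " " + tokens[1], *tokens[2:]]
    return tokens


def parse_logger_file(path, dialect: LoggerDialect, n_chamber: int) -> pd.DataFrame:
    """Parse a logger export into a tidy frame (time, phase, temp, o2_1..o2_n).

    Errors carry the 1-based line number of the offending row.
    """
    if len(dialect.o2_cols) != n_chamber:
        raise DataError(
            f"dialect maps {len(dialect.o2_cols)} O2 columns but n_chamber={n_chamber}"
        )
    fmt = _DATE_FORMATS[dialect.date_format]
    need = max(dialect.datetime_col, dialect.phase_col, *dialect.temp_cols, *dialect.o2_cols) + 1
    rows = []
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            if lineno <= dialect.header_skip or not line.strip():
                continue
            fields = _split(line, dialect.delimiter, merge_datetime=True)
            if len(fields) < need or (dialect.strict_width and len(fields) != need):
                raise DataError(
                    f"{path}: line {lineno}: expected {need} columns, got {len(fields)} "
                    f"(chamber-count mismatch?)"
                )
            try:
                ts = _dt.datetime.strptime(fields[dialect.datetime_col].strip(), fmt)
                temp = sum(_num(fields[c]) for c in dialect.temp_cols) / len(dialect.temp_cols)
                o2 = [_num(fields[c]) if fields[c].strip() not in ("", "NA", "NaN") else float("nan")
                      for c in dialect.o2_cols]
            except ValueError as exc:
                raise DataError(f"{path}: line {lineno}: {exc}") from None
            rows.append([pd.Timestamp(ts), fields[dialect.phase_col].strip(), temp, *o2])
    if not rows:
        raise DataError(f"{path}: no data rows (empty file or header_skip too large)")
    cols = ["time", "phase", "temp"] + [f"o2_{i + 1}" for i in range(n_chamber)]
    return pd.DataFrame(rows, columns=cols)


def _to_chamber_columns(df: pd.DataFrame, info: ExperimentInfo) -> pd.DataFrame:
    o2_cols = [c for c in df.columns if c.startswith("o2_")]
    if len(o2_cols) != len(info.chambers):
        raise DataError(
            f"file has {len(o2_cols)} O2 columns but metadata describes "
            f"{len(info.chambers)} chambers"
        )
    return df.rename(columns=dict(zip(o2_cols, info.chamber_ids)))


def _resolve_dialect(logger, n_chamber: int, date_format: str) -> LoggerDialect:
    if isinstance(logger, LoggerDialect):
        return logger
    return get_dialect(logger, n_chamber, date_format)


def import_test(
    path,
    info: ExperimentInfo,
    logger="fishresp",
    n_chamber: int | None = None,
    date_format: str = "DMY",
) -> MeasurementSet:
    """Import a blank (animal-free) background-respiration test.

    Only the measurement phase(s) of the test are retained; flush and wait
    rows carry no background signal.
    """
    n_chamber = n_chamber or len(info.chambers)
    dialect = _resolve_dialect(logger, n_chamber, date_format)
    df = _to_chamber_columns(parse_logger_file(path, dialect, n_chamber), info)
    meas = df[df["phase"].str.startswith("M")].reset_index(drop=True)
    if meas.empty:
        raise DataError(f"{path}: no measurement-phase rows in background test")
    segment_phases(meas)  # validates labels and monotone time
    return MeasurementSet(info=info, data=meas, kind="background_test")


def _parse_clock(s: str) -> _dt.time:
    return _dt.datetime.strptime(s, "%H:%M:%S").time()


def _in_window(t: _dt.time, start: _dt.time, stop: _dt.time) -> bool:
    if start == stop:  # degenerate window = full 24 h
        return True
    if start < stop:
        return start <= t <= stop
    return t >= start or t <= stop  # wraps midnight


def import_meas(
    path,
    info: ExperimentInfo,
    logger="fishresp",
    n_chamber: int | None = None,
    start_measure: str | None = None,
    stop_measure: str | None = None,
    date_format: str = "DMY",
) -> MeasurementSet:
    """Import metabolic-rate measurements, keeping M-phases inside a clock window.

    A phase is retained iff both its first and last timestamps fall inside
    the (midnight-aware) ``start_measure``–``stop_measure`` window; retained
    phases are re-labelled M1..Mn in time order.  Equal start and stop times
    mean the full 24 h.
    """
    n_chamber = n_chamber or len(info.chambers)
    dialect = _resolve_dialect(logger, n_chamber, date_format)
    df = _to_chamber_columns(parse_logger_file(path, dialect, n_chamber), info)
    spans = [p for p in segment_phases(df) if p.is_measurement]
    if not spans:
        raise DataError(f"{path}: file contains no measurement phases")

    if (start_measure is None) != (stop_measure is None):
        raise DataError("start_measure and stop_measure must be given together")
    if start_measure is not None:
        w0, w1 = _parse_clock(start_measure), _parse_clock(stop_measure)
        kept = [
            p for p in spans
            if _in_window(p.start.time(), w0, w1) and _in_window(p.end.time(), w0, w1)
        ]
    else:
        kept = spans
    if not kept:
        raise DataError(
            f"{path}: none of the {len(spans)} measurement phases fall inside "
            f"{start_measure}–{stop_measure}"
        )
    kept.sort(key=lambda p: p.start)
    parts = []
    for i, span in enumerate(kept, start=1):
        part = df[(df["time"] >= span.start) & (df["time"] <= span.end)].copy()
        part["phase"] = f"M{i}"
        parts.append(part)
    out = pd.concat(parts, ignore_index=True)
    return MeasurementSet(info=info, data=out, kind="measurement")


# ---------------------------------------------------------------------------
# Generic-format reading/writing

GENERIC_HEADER = ["Date.Time", "Phase", "Temp"]


def read_generic(path) -> tuple[pd.DataFrame, list[str]]:
    """Read a generic-format file without chamber metadata.

    Returns the frame (time, phase, temp, Ox.1..Ox.N) and the O2 column names.
    """
    with open(path, encoding="utf-8") as fh:
        header = fh.readline()
    if not header.strip():
        raise DataError(f"{path}: empty file")
    n_o2 = len(_split(header, None, merge_datetime=False)) - len(GENERIC_HEADER)
    if n_o2 < 1:
        raise DataError(f"{path}: header lists no O2 columns")
    dialect = get_dialect("fishresp", n_o2)
    df = parse_logger_file(path, dialect, n_o2)
    o2_cols = [f"Ox.{i + 1}" for i in range(n_o2)]
    df = df.rename(columns=dict(zip([f"o2_{i + 1}" for i in range(n_o2)], o2_cols)))
    return df, o2_cols


def _fmt_time(ts: pd.Timestamp, date_format: str = "DMY") -> str:
    return ts.strftime(_DATE_FORMATS[date_format])


def write_generic(df: pd.DataFrame, o2_cols, path, date_format: str = "DMY") -> Path:
    """Write a (time, phase, temp, O2...) frame in the generic tab format."""
    path = Path(path)
    ordered = df[["time", "phase", "temp", *o2_cols]]
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write("\t".join(GENERIC_HEADER + [f"Ox.{i + 1}" for i in range(len(o2_cols))]) + "\n")
        for time, phase, temp, *o2 in ordered.itertuples(index=False, name=None):
            vals = "\t".join(f"{v:.9f}" for v in o2)
            fh.write(f"{_fmt_time(time, date_format)}\t{phase}\t{temp:.3f}\t{vals}\n")
    return path


# ---------------------------------------------------------------------------
# AquaResp conversion

_SUMMARY_KEYS = {"start": "start", "experimentstart": "start",
                 "flush": "flush", "flushtime": "flush",
                 "wait": "wait", "waittime": "wait",
                 "measure": "measure", "measuretime": "measure",
                 "cycles": "cycles"}


def _read_summary(path) -> dict:
    out: dict = {}
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            if ":" not in line:
                continue
            key, _, value = line.partition(":")
            canon = _SUMMARY_KEYS.get(key.strip().lower().replace(" ", ""))
            if canon is None:
                continue
            out[canon] = value.strip()
    for req in ("start", "flush", "wait", "measure"):
        if req not in out:
            raise DataError(f"{path}: summary lacks required field {req!r}")
    start = None
    for fmt in ("%d/%m/%Y %H:%M:%S", "%Y-%m-%d %H:%M:%S"):
        try:
            start = _dt.datetime.strptime(out["start"], fmt)
            break
        except ValueError:
            continue
    if start is None:
        raise DataError(f"{path}: cannot parse experiment start {out['start']!r}")
    flush, wait, measure = (float(out[k]) for k in ("flush", "wait", "measure"))
    if measure <= 0:
        raise DataError("summary reports a non-positive measurement duration")
    if flush < 0 or wait < 0:
        raise DataError("summary reports negative flush/wait durations")
    return {
        "start": pd.Timestamp(start), "flush": flush, "wait": wait, "measure": measure,
        "cycles": int(out["cycles"]) if "cycles" in out else None,
    }


def convert_aquaresp(logger_path, summary_path, out_path, flavour: str) -> Path:
    """Rebuild phase labels for an AquaResp run and emit a generic-format file.

    ``flavour`` selects the probe-logger layout: ``presens`` (OxyView-style,
    semicolon-delimited ``Date;Time;Logtime;Oxygen;Temp``) or ``pyroscience``
    (tab-delimited ``Date  Time  dt  Oxygen  Temp``).  Phase labels F/W/M are
    reconstructed from the summary's cycle timing; timestamps preceding the
    experiment start are a timing inconsistency and abort the conversion.
    """
    if flavour not in ("presens", "pyroscience"):
        raise DataError(f"unknown AquaResp flavour {flavour!r}")
    summary = _read_summary(summary_path)
    delim = ";" if flavour == "presens" else "\t"
    cycle_len = summary["flush"] + summary["wait"] + summary["measure"]
    rows = []
    with open(logger_path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            if lineno == 1 or not line.strip():
                continue
            fields = line.rstrip("\r\n").split(delim)
            if len(fields) < 5:
                raise DataError(
                    f"{logger_path}: line {lineno}: expected 5 {flavour} fields, got "
                    f"{len(fields)} (wrong flavour?)"
                )
            try:
                ts = _dt.datetime.strptime(
                    fields[0].strip() + " " + fields[1].strip(), "%d/%m/%Y %H:%M:%S"
                )
                o2, temp = _num(fields[3]), _num(fields[4])
            except ValueError as exc:
                raise DataError(f"{logger_path}: line {lineno}: {exc}") from None
            elapsed = (pd.Timestamp(ts) - summary["start"]).total_seconds()
            if elapsed < 0:
                raise DataError(
                    f"{logger_path}: line {lineno}: timestamp precedes the experiment "
                    f"start in the summary"
                )
            cycle, pos = int(elapsed // cycle_len), elapsed % cycle_len
            if summary["cycles"] is not None and cycle >= summary["cycles"]:
                continue
            if pos < summary["flush"]:
                label = f"F{cycle + 1}"
            elif pos < summary["flush"] + summary["wait"]:
                label = f"W{cycle + 1}"
            else:
                label = f"M{cycle + 1}"
            rows.append([pd.Timestamp(ts), label, temp, o2])
    if not rows:
        raise DataError(f"{logger_path}: no data rows")
    df = pd.DataFrame(rows, columns=["time", "phase", "temp", "Ox.1"])
    return write_generic(df, ["Ox.1"], out_path)


# ---------------------------------------------------------------------------
# Results export

def export_results(smr, amr=None, path=None, simplify: bool = True, ms: bool = False):
    """Build (and optionally write) the results table.

    ``smr``/``amr`` are MRResult objects for the two measured traits.  With
    ``simplify`` one row per fish is emitted; otherwise one row per retained
    phase.  With ``ms`` both traits are required and absolute, mass-specific
    and factorial metabolic scopes are appended.
    """
    from .rates import metabolic_scope  # local: rates imports nothing from here

    traits = [smr] + ([amr] if amr is not None else [])
    if ms and amr is None:
        raise DataError("metabolic scope requires both traits")
    if amr is not None:
        smr_ids = set(smr.summary["animal_id"])
        amr_ids = set(amr.summary["animal_id"])
        for missing in sorted(smr_ids - amr_ids):
            raise DataError(f"animal {missing!r} present in {smr.trait} but absent from {amr.trait}")
        for missing in sorted(amr_ids - smr_ids):
            raise DataError(f"animal {missing!r} present in {amr.trait} but absent from {smr.trait}")

    if simplify:
        out = traits[0].summary[["animal_id", "mass_g", "volume_ml", "do_unit"]].copy()
        out = out.rename(columns={"animal_id": "ID", "mass_g": "Mass.g", "volume_ml": "Volume.mL",
                                  "do_unit": "DO.unit"})
        for mr in traits:
            s = mr.summary.set_index("animal_id")
            out[f"{mr.trait}.bg.pct"] = s["bg_percent"].reindex(out["ID"]).to_numpy()
            out[f"{mr.trait}.abs"] = s["mo2_abs"].reindex(out["ID"]).to_numpy()
            out[f"{mr.trait}.mass"] = s["mo2_mass"].reindex(out["ID"]).to_numpy()
        if ms:
            scope = metabolic_scope(smr, amr).set_index("animal_id")
            out["Scope.abs"] = scope["scope_abs"].reindex(out["ID"]).to_numpy()
            out["Scope.mass"] = scope["scope_mass"].reindex(out["ID"]).to_numpy()
            out["Scope.factorial"] = scope["scope_factorial"].reindex(out["ID"]).to_numpy()
    else:
        frames = []
        for mr in traits:
            rec = mr.records.copy()
            rec.insert(0, "Trait", mr.trait)
            frames.append(rec)
        out = pd.concat(frames, ignore_index=True)
        if ms:
            warnings.warn("metabolic scope is only attached to simplified exports")

    if path is not None:
        path = Path(path)
        sep = "\t" if path.suffix.lower() == ".txt" else ","
        out.to_csv(path, sep=sep, index=False, float_format="%.6f", lineterminator="\n")
    return out


# ---------------------------------------------------------------------------
# Intermediate persistence (lets CLI stages compose through plain files)

_META_PREFIX = "#ifresp\t"


def write_set(meas: MeasurementSet, path) -> Path:
    """Persist a MeasurementSet (raw or corrected) as a self-describing text file."""
    path = Path(path)
    meta = {
        "kind": meas.kind,
        "corrected": meas.corrected,
        "do_unit": meas.info.do_unit,
        "chambers": meas.info.chamber_ids,
        "method": meas.background.method if meas.background is not None else None,
        "phase_background": {f"{c}|{p}": b for (c, p), b in meas.phase_background.items()},
        "removed": sorted(list(t) for t in meas.removed),
    }
    chambers = meas.info.chamber_ids
    raw_cols = [f"{c}.raw" for c in chambers if f"{c}.raw" in meas.data.columns]
    ordered = meas.data[["time", "phase", "temp", *chambers, *raw_cols]]
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write(_META_PREFIX + json.dumps(meta, sort_keys=True) + "\n")
        fh.write("\t".join(["Date.Time", "Phase", "Temp", *chambers, *raw_cols]) + "\n")
        for time, phase, temp, *vals in ordered.itertuples(index=False, name=None):
            nums = "\t".join(f"{v:.9f}" for v in vals)
            fh.write(f"{_fmt_time(time)}\t{phase}\t{temp:.3f}\t{nums}\n")
    return path


def read_set(path, info: ExperimentInfo) -> MeasurementSet:
    """Reload a MeasurementSet written by :func:`write_set`."""
    from .background import BackgroundModel

    with open(path, encoding="utf-8") as fh:
        first = fh.readline()
        if not first.startswith(_META_PREFIX):
            raise DataError(f"{path}: not an ifresp measurement-set file")
        meta = json.loads(first[len(_META_PREFIX):])
        header = fh.readline().rstrip("\r\n").split("\t")
        rows = []
        for lineno, line in enumerate(fh, start=3):
            if not line.strip():
                continue
            fields = line.rstrip("\r\n").split("\t")
            if len(fields) != len(header):
                raise DataError(f"{path}: line {lineno}: ragged row")
            ts = _dt.datetime.strptime(fields[0], _DATE_FORMATS["DMY"])
            rows.append([pd.Timestamp(ts), fields[1], float(fields[2]),
                         *[float(v) for v in fields[3:]]])
    df = pd.DataFrame(rows, columns=["time", "phase", "temp", *header[3:]])
    if meta["chambers"] != info.chamber_ids:
        raise DataError(
            f"{path}: file chambers {meta['chambers']} do not match metadata "
            f"{info.chamber_ids}"
        )
    background = None
    if meta["corrected"]:
        # per-phase corrections are already baked into the data; the reloaded
        # model is inert and only records provenance
        background = BackgroundModel(method="precomputed")
    return MeasurementSet(
        info=info,
        data=df,
        kind=meta["kind"],
        corrected=meta["corrected"],
        background=background,
        phase_background={
            (k.split("|")[0], k.split("|")[1]): v for k, v in meta["phase_background"].items()
        },
        removed=frozenset(tuple(t) for t in meta["removed"]),
    )
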