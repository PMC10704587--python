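"""Flat text formats for raw SIM data and results.

ScanFrame file layout (UTF-8, tab-separated)::

    # siftquant-scanframes v1
    # t_r = 0.0057
    # P_g = 0.46
    # ...                       (instrument header, key = value)
    # icf_anchors = {"19": 1.3, "28": 1.0, ...}   (JSON, signed m/z keys)
    # telemetry.<key> = <value>  (free-form instrument telemetry)
    frame  timestamp  ion_label  mz  counts  dwell  role  reagent_label  analyte_id
    0      0.0        O2+        32  600000  0.06   reagent  -  -

One line per SIM record; ``-`` marks an absent optional field.  The header
carries one InstrumentState for the whole file (matching how the instrument
stores run-level configuration alongside point-by-point counts).  Unknown
``telemetry.*`` keys are preserved on read.

No public vendor raw-data format exists; :class:`VendorReader` is the
converter stub interface future vendor readers implement.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Iterable, Optional, Protocol

import pandas as pd

from .calibration import PerformanceCheckResult
from .icf import ICFCurve
from .records import InstrumentState, ScanFrame, SIMRecord

__all__ = [
    "read_scanframes",
    "write_scanframes",
    "read_check_result",
    "write_check_result",
    "write_results",
    "VendorReader",
]

MAGIC = "# siftquant-scanframes v1"
COLUMNS = ["frame", "timestamp", "ion_label", "mz", "counts", "dwell",
           "role", "reagent_label", "analyte_id"]

_STATE_FIELDS = ("t_r", "P_g", "T_g", "phi_c", "phi_s",
                 "attenuation_factor", "makeup_dilution")


class VendorReader(Protocol):
    """Converter stub: future vendor raw-file readers implement this."""

    def read(self, path: str | Path) -> list[ScanFrame]: ...


def write_scanframes(frames: Iterable[ScanFrame], path: str | Path,
                     telemetry: Optional[dict[str, str]] = None) -> None:
    frames = list(frames)
    path = Path(path)
    state = next((f.instrument for f in frames if f.instrument is not None),
                 None)
    with path.open("w", encoding="utf-8") as fh:
        fh.write(MAGIC + "\n")
        if state is not None:
            for field in _STATE_FIELDS:
                fh.write(f"# {field} = {getattr(state, field)!r}\n")
            anchors = {str(mz): val
                       for mz, val in state.icf_curve.anchors.items()}
            fh.write(f"# icf_anchors = {json.dumps(anchors)}\n")
        for key, val in (telemetry or {}).items():
            fh.write(f"# telemetry.{key} = {val}\n")
        fh.write("\t".join(COLUMNS) + "\n")
        for i, frame in enumerate(frames):
            for rec in frame.records:
                row = [str(i), repr(frame.timestamp), rec.ion_label,
                       str(rec.mz), repr(rec.counts), repr(rec.dwell),
                       rec.role, rec.reagent_label or "-",
                       rec.analyte_id or "-"]
                fh.write("\t".join(row) + "\n")


def read_scanframes(path: str | Path,
                    ) -> tuple[list[ScanFrame], dict[str, str]]:
    """Read a ScanFrame file; returns (frames, telemetry).

    Malformed lines raise with their line number.  The instrument header is
    attached to every frame; a missing ``t_r`` header leaves frames without
    instrument state (quantitation then requires an explicit check result).
    """
    path = Path(path)
    header: dict[str, str] = {}
    telemetry: dict[str, str] = {}
    rows: list[tuple[int, list[str]]] = []
    saw_columns = False
    with path.open("r", encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            if line.startswith("#"):
                if lineno == 1:
                    if line != MAGIC:
                        raise ValueError(
                            f"{path}:1: not a siftquant scanframes file")
                    continue
                body = line[1:].strip()
                if "=" not in body:
                    raise ValueError(f"{path}:{lineno}: malformed header line")
                key, _, val = body.partition("=")
                key, val = key.strip(), val.strip()
                if key.startswith("telemetry."):
                    telemetry[key[len("telemetry."):]] = val
                else:
                    header[key] = val
                continue
            fields = line.split("\t")
            if not saw_columns:
                if fields != COLUMNS:
                    raise ValueError(
                        f"{path}:{lineno}: unexpected column header {fields}")
                saw_columns = True
                continue
            if len(fields) != len(COLUMNS):
                raise ValueError(
                    f"{path}:{lineno}: expected {len(COLUMNS)} fields, "
                    f"got {len(fields)}")
            rows.append((lineno, fields))

    state = None
    if "t_r" not in header and (set(header) & set(_STATE_FIELDS)
                                or "icf_anchors" in header):
        raise ValueError(
            f"{path}: instrument header is missing t_r; re-run the "
            "performance check or re-export the raw data")
    if "t_r" in header:
        missing = [f for f in _STATE_FIELDS if f not in header]
        if missing or "icf_anchors" not in header:
            raise ValueError(
                f"{path}: incomplete instrument header (missing "
                f"{missing + (['icf_anchors'] if 'icf_anchors' not in header else [])})")
        anchors = {int(mz): float(v)
                   for mz, v in json.loads(header["icf_anchors"]).items()}
        state = InstrumentState(
            icf_curve=ICFCurve(anchors=anchors),
            **{f: float(header[f]) for f in _STATE_FIELDS})

    by_frame: dict[int, dict] = {}
    for lineno, fields in rows:
        try:
            idx = int(fields[0])
            rec = SIMRecord(
                ion_label=fields[2], mz=int(fields[3]),
                counts=float(fields[4]), dwell=float(fields[5]),
                role=fields[6],
                reagent_label=None if fields[7] == "-" else fields[7],
                analyte_id=None if fields[8] == "-" else fields[8])
        except (ValueError, TypeError) as exc:
            raise ValueError(f"{path}:{lineno}: malformed record: {exc}") from exc
        slot = by_frame.setdefault(idx, {"timestamp": float(fields[1]),
                                         "records": []})
        slot["records"].append(rec)
    frames = [ScanFrame(timestamp=slot["timestamp"], records=slot["records"],
                        instrument=state)
              for _, slot in sorted(by_frame.items())]
    return frames, telemetry


def write_check_result(result: PerformanceCheckResult, path: str | Path) -> None:
    Path(path).write_text(
        json.dumps(result.model_dump(mode="json"), indent=1, sort_keys=True)
        + "\n", encoding="utf-8")


def read_check_result(path: str | Path) -> PerformanceCheckResult:
    payload = json.loads(Path(path).read_text(encoding="utf-8"))
    return PerformanceCheckResult.model_validate(payload)


def write_results(results: pd.DataFrame, path: str | Path) -> None:
    """Write a results table (per-frame, per-analyte) as TSV."""
    results.to_csv(path, sep="\t", index=False)
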