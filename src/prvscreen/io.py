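"""Readers and writers for the cohort and interval CSV schemas.

Two delimited text formats carry a cohort:

- **intervals** (long format): ``participant_id, reading_index, beat_index,
  interval_ms`` — one row per beat, acquisition order given by ``beat_index``.
- **participants**: one row per participant with ECG ground truth, rhythm
  class, arrhythmia/pacing/subgroup flags and the device label.

Booleans are serialised as lowercase ``true``/``false``; KMCM labels as the
lowercase tokens ``normal|possible_af|unclassified|blank`` (blank is an
explicit token — an empty cell is a schema error).  Validation failures are
fatal and name the offending file row (1-based, counting the header).
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Dict, Iterable, List, Sequence, Tuple, Union

import pandas as pd

from .cohort import ParticipantRecord, RhythmClass
from .kmcm import KmcmLabel
from .prv import PRVResult, PulseIntervalSeries

__all__ = [
    "SchemaError",
    "write_intervals",
    "read_intervals",
    "write_participants",
    "write_cohort",
    "load_cohort",
    "write_prv_results",
    "load_run_config_file",
]

PARTICIPANT_COLUMNS = (
    "participant_id", "ecg_af", "rhythm", "non_af_arrhythmia", "paced",
    "prior_af_diagnosis", "age_ge_65", "af_risk_ge_5pct", "high_chads2",
    "high_cha2ds2vasc", "kmcm_label",
)
INTERVAL_COLUMNS = ("participant_id", "reading_index", "beat_index", "interval_ms")
_BOOL_COLUMNS = (
    "ecg_af", "non_af_arrhythmia", "paced", "prior_af_diagnosis",
    "age_ge_65", "af_risk_ge_5pct", "high_chads2", "high_cha2ds2vasc",
)


class SchemaError(ValueError):
    """A cohort file violates its documented schema; message names the row."""


def _bool_str(b: bool) -> str:
    return "true" if b else "false"


def _parse_bool(value: str, row: int, column: str, path: Path) -> bool:
    if value == "true":
        return True
    if value == "false":
        return False
    raise SchemaError(
        f"{path}, row {row}: column {column!r} must be 'true' or 'false', got {value!r}"
    )


def write_intervals(records: Iterable[ParticipantRecord], path: Union[str, Path]) -> None:
    rows = []
    for rec in records:
        for reading in rec.readings:
            for b, iv in enumerate(reading.intervals, start=1):
                rows.append(
                    (rec.participant_id, reading.reading_index, b, float(iv))
                )
    pd.DataFrame(rows, columns=list(INTERVAL_COLUMNS)).to_csv(path, index=False)


def read_intervals(path: Union[str, Path]) -> Dict[Tuple[str, int], PulseIntervalSeries]:
    """Read a long-format interval table into per-(participant, reading) series."""
    path = Path(path)
    df = pd.read_csv(path, dtype={"participant_id": str})
    missing = set(INTERVAL_COLUMNS) - set(df.columns)
    if missing:
        raise SchemaError(f"{path}: missing columns {sorted(missing)}")
    bad = df.index[
        ~pd.to_numeric(df["interval_ms"], errors="coerce").gt(0).fillna(False)
    ]
    if len(bad):
        row = int(bad[0]) + 2  # +1 header, +1 one-based
        raise SchemaError(
            f"{path}, row {row}: interval_ms must be a positive number, "
            f"got {df.loc[bad[0], 'interval_ms']!r}"
        )
    dup = df.duplicated(subset=["participant_id", "reading_index", "beat_index"])
    if dup.any():
        row = int(df.index[dup][0]) + 2
        raise SchemaError(f"{path}, row {row}: duplicate (participant, reading, beat) key")

    series: Dict[Tuple[str, int], PulseIntervalSeries] = {}
    for (pid, ridx), grp in df.groupby(["participant_id", "reading_index"], sort=True):
        grp = grp.sort_values("beat_index")
        series[(str(pid), int(ridx))] = PulseIntervalSeries(
            participant_id=str(pid),
            reading_index=int(ridx),
            intervals=grp["interval_ms"].to_numpy(dtype=float),
        )
    return series


def write_participants(records: Iterable[ParticipantRecord], path: Union[str, Path]) -> None:
    rows = []
    for rec in records:
        rows.append(
            {
                "participant_id": rec.participant_id,
                "ecg_af": _bool_str(rec.ecg_af),
                "rhythm": RhythmClass(rec.rhythm).value,
                "non_af_arrhythmia": _bool_str(rec.non_af_arrhythmia),
                "paced": _bool_str(rec.paced),
                "prior_af_diagnosis": _bool_str(rec.prior_af_diagnosis),
                "age_ge_65": _bool_str(rec.age_ge_65),
                "af_risk_ge_5pct": _bool_str(rec.af_risk_ge_5pct),
                "high_chads2": _bool_str(rec.high_chads2),
                "high_cha2ds2vasc": _bool_str(rec.high_cha2ds2vasc),
                "kmcm_label": KmcmLabel(rec.kmcm_label).value,
            }
        )
    pd.DataFrame(rows, columns=list(PARTICIPANT_COLUMNS)).to_csv(path, index=False)


def write_cohort(
    records: Sequence[ParticipantRecord], out_dir: Union[str, Path]
) -> Dict[str, Path]:
    """Write participants.csv + intervals.csv into ``out_dir``; return the paths."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "participants": out / "participants.csv",
        "intervals": out / "intervals.csv",
    }
    write_participants(records, paths["participants"])
    write_intervals(records, paths["intervals"])
    return paths


def load_cohort(
    participants_path: Union[str, Path], intervals_path: Union[str, Path]
) -> List[ParticipantRecord]:
    """Join the participants and intervals tables into ParticipantRecords.

    Readings are ordered by ``reading_index``; every participant must have at
    least one reading.  Duplicate participant rows, unknown labels and
    malformed values abort with the offending row number.
    """
    participants_path = Path(participants_path)
    series = read_intervals(intervals_path)

    df = pd.read_csv(participants_path, dtype=str, keep_default_na=False)
    missing = set(PARTICIPANT_COLUMNS) - set(df.columns)
    if missing:
        raise SchemaError(f"{participants_path}: missing columns {sorted(missing)}")
    dup = df.duplicated(subset=["participant_id"])
    if dup.any():
        row = int(df.index[dup][0]) + 2
        raise SchemaError(f"{participants_path}, row {row}: duplicate participant_id")

    by_pid: Dict[str, List[PulseIntervalSeries]] = {}
    for (pid, _ridx), s in sorted(series.items()):
        by_pid.setdefault(pid, []).append(s)

    records: List[ParticipantRecord] = []
    for i, raw in df.iterrows():
        row = int(i) + 2
        pid = raw["participant_id"]
        try:
            rhythm = RhythmClass(raw["rhythm"])
        except ValueError:
            raise SchemaError(
                f"{participants_path}, row {row}: unknown rhythm {raw['rhythm']!r}"
            ) from None
        try:
            label = KmcmLabel(raw["kmcm_label"])
        except ValueError:
            raise SchemaError(
                f"{participants_path}, row {row}: unknown kmcm_label {raw['kmcm_label']!r}"
            ) from None
        readings = by_pid.get(pid)
        if not readings:
            raise SchemaError(
                f"{participants_path}, row {row}: participant {pid!r} has no interval rows"
            )
        records.append(
            ParticipantRecord(
                participant_id=pid,
                ecg_af=_parse_bool(raw["ecg_af"], row, "ecg_af", participants_path),
                rhythm=rhythm,
                non_af_arrhythmia=_parse_bool(
                    raw["non_af_arrhythmia"], row, "non_af_arrhythmia", participants_path
                ),
                paced=_parse_bool(raw["paced"], row, "paced", participants_path),
                prior_af_diagnosis=_parse_bool(
                    raw["prior_af_diagnosis"], row, "prior_af_diagnosis", participants_path
                ),
                age_ge_65=_parse_bool(raw["age_ge_65"], row, "age_ge_65", participants_path),
                af_risk_ge_5pct=_parse_bool(
                    raw["af_risk_ge_5pct"], row, "af_risk_ge_5pct", participants_path
                ),
                high_chads2=_parse_bool(
                    raw["high_chads2"], row, "high_chads2", participants_path
                ),
                high_cha2ds2vasc=_parse_bool(
                    raw["high_cha2ds2vasc"], row, "high_cha2ds2vasc", participants_path
                ),
                kmcm_label=label,
                readings=tuple(sorted(readings, key=lambda s: s.reading_index)),
            )
        )
    return records


def write_prv_results(results: Iterable[PRVResult], path: Union[str, Path]) -> None:
    """One row per (participant, reading) with all PRVResult fields."""
    rows = [
        {
            "participant_id": r.participant_id,
            "reading_index": r.reading_index,
            "sarv": r.sarv, "rmssd": r.rmssd, "sd": r.sd, "cv": r.cv,
            "relative_range": r.relative_range, "ipp": r.ipp,
            "n_beats_raw": r.n_beats_raw, "n_beats_used": r.n_beats_used,
            "low_beat_flag": _bool_str(r.low_beat_flag),
        }
        for r in results
    ]
    pd.DataFrame(rows).to_csv(path, index=False)


def load_run_config_file(path: Union[str, Path]) -> dict:
    """Parse a JSON or YAML run-configuration file into a plain dict."""
    path = Path(path)
    text = path.read_text(encoding="utf-8")
    if path.suffix.lower() in (".yaml", ".yml"):
        import yaml

        data = yaml.safe_load(text)
    else:
        data = json.loads(text)
    if not isinstance(data, dict):
        raise SchemaError(f"{path}: configuration must be a mapping")
    return data
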