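"""Plain-text readers and writers for the pipeline's artifacts.

Waveforms are two-column delimited text (time_s, pressure) with a header
comment carrying the subject id and sampling rate; tables are CSV via
pandas. All formats round-trip losslessly enough for analysis (waveform
samples at %.8g).
"""

from __future__ import annotations

import re
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import ValidationError
from .mlharness import SubjectPrediction
from .simulate import WaveformRecord

__all__ = [
    "write_waveform",
    "read_waveform",
    "write_features",
    "read_features",
    "write_predictions",
    "read_predictions",
]

_HEADER_RE = re.compile(
    r"#\s*subject_id=(?P<sid>\S+)\s+sampling_rate_hz=(?P<fs>\S+)\s+duration_s=(?P<dur>\S+)"
)


def write_waveform(record: WaveformRecord, path: str | Path) -> None:
    path = Path(path)
    t = np.arange(len(record.samples)) / record.sampling_rate_hz
    header = (
        f"subject_id={record.subject_id} "
        f"sampling_rate_hz={record.sampling_rate_hz:g} "
        f"duration_s={record.duration_s:g}\n"
        "time_s\tpressure"
    )
    np.savetxt(path, np.column_stack([t, record.samples]), fmt="%.8g",
               delimiter="\t", header=header)


def read_waveform(path: str | Path) -> WaveformRecord:
    path = Path(path)
    with open(path) as fh:
        first = fh.readline()
    match = _HEADER_RE.match(first)
    if not match:
        raise ValidationError(f"{path}: missing waveform header comment")
    data = np.loadtxt(path, comments="#")
    return WaveformRecord(
        subject_id=match["sid"],
        samples=data[:, 1],
        sampling_rate_hz=float(match["fs"]),
        duration_s=float(match["dur"]),
    )


def write_features(features: pd.DataFrame, path: str | Path) -> None:
    """Features CSV, indexed by subject_id; missing values as empty fields."""
    features.to_csv(path, index_label="subject_id")


def read_features(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, index_col="subject_id")


def write_predictions(preds: list[SubjectPrediction], path: str | Path) -> None:
    pd.DataFrame(
        [
            dict(
                subject_id=p.subject_id,
                cohort=p.cohort,
                mmse=p.mmse,
                probability_ad=p.probability_ad,
            )
            for p in preds
        ]
    ).to_csv(path, index=False)


def read_predictions(path: str | Path) -> list[SubjectPrediction]:
    frame = pd.read_csv(path)
    required = {"subject_id", "cohort", "mmse", "probability_ad"}
    missing = required - set(frame.columns)
    if missing:
        raise ValidationError(f"{path}: predictions CSV lacks columns {sorted(missing)}")
    return [
        SubjectPrediction(
            subject_id=str(r.subject_id),
            probability_ad=float(r.probability_ad),
            mmse=int(r.mmse),
            cohort=str(r.cohort),
        )
        for r in frame.itertuples()
    ]
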