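"""Plain-text signal record I/O.

Records travel as CSV with columns ``index`` (or ``time``), ``ppg`` and
optional per-sample ``sbp``/``dbp`` label columns; one record per file.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .synthetic_data import SignalRecord

__all__ = ["read_record_csv", "write_record_csv"]


def write_record_csv(record: SignalRecord, path) -> None:
    pd.DataFrame(
        {
            "index": np.arange(len(record)),
            "ppg": record.ppg,
            "sbp": record.sbp,
            "dbp": record.dbp,
        }
    ).to_csv(path, index=False)


def read_record_csv(path, fs: float = 125.0) -> SignalRecord:
    df = pd.read_csv(path)
    if "ppg" not in df.columns:
        raise ValueError(f"{path}: record CSV needs a 'ppg' column")
    if "time" in df.columns and len(df) > 1:
        dt = float(np.median(np.diff(df["time"].to_numpy())))
        if dt > 0:
            fs = 1.0 / dt
    n = len(df)
    sbp = df["sbp"].to_numpy(float) if "sbp" in df.columns else np.full(n, np.nan)
    dbp = df["dbp"].to_numpy(float) if "dbp" in df.columns else np.full(n, np.nan)
    return SignalRecord(
        ppg=df["ppg"].to_numpy(float), fs=fs, sbp=sbp, dbp=dbp,
        record_id=Path(path).stem,
    )
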