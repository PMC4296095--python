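"""CSV/JSON interchange for epochs, cohort tables and model reports.

Epochs travel as long-format CSV with columns ``participant_id, epoch_id,
time_s, acc_vt, acc_ml, acc_ap`` (SI units, m/s^2). Range (+/- 6 g) and
sample-count checks are applied per epoch at read time; violating epochs are
rejected with a reason, not silently repaired.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import InvalidParameterError
from .types import AccelEpoch

log = logging.getLogger(__name__)

EPOCH_COLUMNS = ["participant_id", "epoch_id", "time_s", "acc_vt", "acc_ml", "acc_ap"]


def write_epochs_csv(epochs, path) -> None:
    """Write an iterable of epochs as one long-format CSV."""
    frames = []
    for ep in epochs:
        n = ep.n_samples
        frames.append(
            pd.DataFrame(
                {
                    "participant_id": ep.participant_id or "",
                    "epoch_id": ep.epoch_id or "",
                    "time_s": np.arange(n) / ep.sample_rate,
                    "acc_vt": ep.vt,
                    "acc_ml": ep.ml,
                    "acc_ap": ep.ap,
                }
            )
        )
    pd.concat(frames, ignore_index=True).to_csv(path, index=False, float_format="%.6f")


def read_epochs(
    path,
    sample_rate: float = 100.0,
    expected_duration: float | None = 10.0,
):
    """Read and validate epochs from a long-format CSV.

    Returns ``(epochs, rejected)`` where ``rejected`` maps epoch ids to the
    reason they failed validation (wrong sample count, out-of-range
    acceleration, missing axis values).
    """
    df = pd.read_csv(path)
    missing = [c for c in EPOCH_COLUMNS if c not in df.columns]
    if missing:
        raise InvalidParameterError(f"epoch CSV missing columns: {missing}")
    df[["participant_id", "epoch_id"]] = (
        df[["participant_id", "epoch_id"]].fillna("").astype(str)
    )
    expected_samples = (
        int(round(sample_rate * expected_duration)) if expected_duration else None
    )
    epochs = []
    rejected: dict[str, str] = {}
    for (pid, eid), grp in df.groupby(["participant_id", "epoch_id"], sort=True):
        if grp[["acc_vt", "acc_ml", "acc_ap"]].isna().any().any():
            rejected[str(eid)] = "missing axis samples"
            continue
        ep = AccelEpoch(
            vt=grp["acc_vt"].to_numpy(),
            ml=grp["acc_ml"].to_numpy(),
            ap=grp["acc_ap"].to_numpy(),
            sample_rate=sample_rate,
            participant_id=str(pid),
            epoch_id=str(eid),
        )
        try:
            ep.validate(expected_samples=expected_samples)
        except InvalidParameterError as exc:
            rejected[str(eid)] = str(exc)
            continue
        epochs.append(ep)
    if rejected:
        log.warning("read_epochs: rejected %d epochs", len(rejected))
    return epochs, rejected


def write_json(obj, path) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, default=_json_default))


def _json_default(o):
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    if isinstance(o, np.ndarray):
        return o.tolist()
    raise TypeError(f"not JSON serializable: {type(o)}")
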