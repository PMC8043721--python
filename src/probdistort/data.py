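"""Core containers for trial-level behavioral data.

The unit of analysis is one trial of a non-stationary Bernoulli forecasting
task: a subject watches a ring drawn from a box whose green-ring probability
occasionally changes, and maintains a slider reporting the probability that
the next ring is green.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: Required columns of a trial-level behavioral table, in canonical order.
COLUMNS = [
    "subject_id",
    "session",
    "trial",
    "ring",
    "true_p",
    "report",
    "response_time_s",
]


class DataError(ValueError):
    """Malformed or internally inconsistent behavioral data."""


class ConfigError(ValueError):
    """Invalid configuration values."""


@dataclass
class BehaviorDataset:
    """One row per (subject, session, trial) behavioral record.

    Parameters
    ----------
    frame : pandas.DataFrame
        Must carry :data:`COLUMNS`. ``true_p`` may be NaN for externally
        collected data where the generative parameter is unknown.
    provenance : str
        ``"synthetic"`` for simulator output, ``"external"`` otherwise.
    """

    frame: pd.DataFrame
    provenance: str = "synthetic"

    def __post_init__(self) -> None:
        missing = [c for c in COLUMNS if c not in self.frame.columns]
        if missing:
            raise DataError(f"missing columns: {missing}")
        self.frame = self.frame[COLUMNS].reset_index(drop=True)
        self.validate()
        self.frame = self.frame.astype({"ring": np.int64})

    def validate(self) -> None:
        f = self.frame
        rings = f["ring"].to_numpy()
        bad = np.flatnonzero(~np.isin(rings, (0, 1)))
        if bad.size:
            raise DataError(f"non-binary ring value on row {bad[0]}")
        r = f["report"].to_numpy(float)
        bad = np.flatnonzero(~((r >= 0.0) & (r <= 1.0)))
        if bad.size:
            raise DataError(f"report outside [0, 1] on row {bad[0]}")
        tp = f["true_p"].to_numpy(float)
        ok = np.isnan(tp) | ((tp > 0.0) & (tp < 1.0))
        bad = np.flatnonzero(~ok)
        if bad.size:
            raise DataError(f"true_p outside (0, 1) on row {bad[0]}")
        # one record per (subject, session, trial), trials consecutive from 1
        for (subj, sess), g in f.groupby(["subject_id", "session"], sort=False):
            t = g["trial"].to_numpy()
            if not np.array_equal(t, np.arange(1, len(t) + 1)):
                raise DataError(
                    f"trials not consecutive from 1 for subject {subj}, "
                    f"session {sess}"
                )

    @property
    def n_records(self) -> int:
        return len(self.frame)

    @property
    def subjects(self) -> list:
        return list(pd.unique(self.frame["subject_id"]))

    def groupby_session(self):
        """Iterate ``((subject_id, session), frame)`` in stored order."""
        return self.frame.groupby(["subject_id", "session"], sort=False)

    def __eq__(self, other) -> bool:  # byte-identical check for determinism
        if not isinstance(other, BehaviorDataset):
            return NotImplemented
        return self.provenance == other.provenance and self.frame.equals(
            other.frame
        )


def concat(datasets: list[BehaviorDataset]) -> BehaviorDataset:
    if not datasets:
        raise ConfigError("nothing to concatenate")
    prov = datasets[0].provenance
    frame = pd.concat([d.frame for d in datasets], ignore_index=True)
    return BehaviorDataset(frame, provenance=prov)
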