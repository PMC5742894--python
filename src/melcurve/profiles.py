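"""Measured melatonin profiles and their CSV dialect.

A profile is one subject's set of (clock time, plasma concentration)
samples — in the motivating studies, blood drawn every 3 h over 24 h and
assayed for melatonin (pg/mL).  Profiles are exchanged as CSV with
columns ``subject_id, group, time_h, concentration_pg_ml`` (header
mandatory, dot decimal, UTF-8); times are decimal hours.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "MelatoninProfile",
    "ProfileError",
    "PROFILE_COLUMNS",
    "read_profiles_csv",
    "write_profiles_csv",
]

PROFILE_COLUMNS = ["subject_id", "group", "time_h", "concentration_pg_ml"]

#: minimum number of samples: one more than the model's free parameters
MIN_SAMPLES = 5


class ProfileError(ValueError):
    """A profile or profile table violates the input contract."""


@dataclass
class MelatoninProfile:
    """One subject's measured melatonin time series.

    ``times`` are decimal hours, reduced modulo 24 into [0, 24) and
    required to be unique after reduction; ``concentrations`` are pg/mL
    and non-negative.  At least five samples are required so the
    four-parameter curve is overdetermined.
    """

    subject_id: str
    group: str
    times: np.ndarray
    concentrations: np.ndarray
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float) % 24.0
        y = np.asarray(self.concentrations, dtype=float)
        if t.ndim != 1 or y.ndim != 1 or t.size != y.size:
            raise ProfileError(
                f"subject {self.subject_id!r}: times and concentrations must be "
                "1-D and equally long"
            )
        if t.size < MIN_SAMPLES:
            raise ProfileError(
                f"subject {self.subject_id!r}: at least {MIN_SAMPLES} samples "
                f"required, got {t.size}"
            )
        if not np.isfinite(t).all() or not np.isfinite(y).all():
            raise ProfileError(f"subject {self.subject_id!r}: non-finite sample")
        if (y < 0).any():
            raise ProfileError(
                f"subject {self.subject_id!r}: negative concentration"
            )
        if np.unique(t).size != t.size:
            raise ProfileError(
                f"subject {self.subject_id!r}: sample times not unique mod 24"
            )
        order = np.argsort(t)
        self.times = t[order]
        self.concentrations = y[order]

    @property
    def n_samples(self) -> int:
        return int(self.times.size)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "subject_id": self.subject_id,
                "group": self.group,
                "time_h": self.times,
                "concentration_pg_ml": self.concentrations,
            }
        )


def _validate_table(df: pd.DataFrame) -> None:
    missing = [c for c in PROFILE_COLUMNS if c not in df.columns]
    if missing:
        raise ProfileError(f"profile table is missing columns: {missing}")
    if len(df) == 0:
        raise ProfileError("profile table contains no rows")
    for col in ("time_h", "concentration_pg_ml"):
        bad = df.index[pd.to_numeric(df[col], errors="coerce").isna()]
        if len(bad):
            # +2: header line plus 1-based numbering, matching the file
            rows = [int(i) + 2 for i in bad[:5]]
            raise ProfileError(f"non-numeric {col} at file row(s) {rows}")


def profiles_from_frame(df: pd.DataFrame) -> list[MelatoninProfile]:
    """Split a long-format profile table into per-subject profiles."""
    _validate_table(df)
    out = []
    for sid, sub in df.groupby("subject_id", sort=False):
        groups = sub["group"].unique()
        if len(groups) != 1:
            raise ProfileError(f"subject {sid!r} appears in several groups: {list(groups)}")
        out.append(
            MelatoninProfile(
                subject_id=str(sid),
                group=str(groups[0]),
                times=sub["time_h"].to_numpy(dtype=float),
                concentrations=sub["concentration_pg_ml"].to_numpy(dtype=float),
            )
        )
    return out


def read_profiles_csv(path) -> list[MelatoninProfile]:
    """Read the standard profile CSV into per-subject profiles."""
    df = pd.read_csv(path, dtype={"subject_id": str, "group": str})
    return profiles_from_frame(df)


def write_profiles_csv(profiles, path) -> None:
    """Write profiles to the standard CSV dialect (stable column order)."""
    frames = [p.to_frame() for p in profiles]
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)
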