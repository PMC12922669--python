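"""CSV interchange for trial logs, awareness tables and coded trials.

All artifacts are plain CSV with a leading ``#`` comment header embedding
the package version, the seed and the configuration digest, so any output
can be traced back to the exact run that produced it.  Readers skip comment
lines, so the files also open cleanly in ordinary CSV tools.
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd

from . import __version__
from .simulate import AWARENESS_COLUMNS, TRIAL_COLUMNS

__all__ = [
    "write_csv",
    "read_trials",
    "read_awareness",
    "validate_trials",
    "validate_awareness",
]

_POSITIONS = {"left", "middle", "right"}
_LABELS = {"frequent", "infrequent"}


def _header(meta: dict | None) -> str:
    fields = {"generator": f"rrcl {__version__}"}
    fields.update(meta or {})
    return "".join(f"# {k}={v}\n" for k, v in fields.items())


def write_csv(df: pd.DataFrame, path, meta: dict | None = None) -> Path:
    """Write a DataFrame as CSV with a provenance comment header."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        fh.write(_header(meta))
        df.to_csv(fh, index=False, na_rep="")
    return path


def _read(path) -> pd.DataFrame:
    return pd.read_csv(path, comment="#", skip_blank_lines=True)


def validate_trials(df: pd.DataFrame, path="<trials>") -> pd.DataFrame:
    missing = [c for c in TRIAL_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing trial-log columns {missing}")
    for col in ("stimulus", "response"):
        bad = df.index[~df[col].isin(_POSITIONS)]
        if len(bad):
            raise ValueError(
                f"{path}: column {col!r} has invalid value "
                f"{df.loc[bad[0], col]!r} at row {int(bad[0])}"
            )
    if (df["rt_ms"] <= 0).any():
        row = int(df.index[df["rt_ms"] <= 0][0])
        raise ValueError(f"{path}: non-positive rt_ms at row {row}")
    mismatch = (df["accuracy"].astype(int) == 1) != (df["stimulus"] == df["response"])
    if mismatch.any():
        row = int(df.index[mismatch][0])
        raise ValueError(
            f"{path}: accuracy flag inconsistent with stimulus/response at row {row}"
        )
    return df


def validate_awareness(df: pd.DataFrame, path="<awareness>") -> pd.DataFrame:
    missing = [c for c in AWARENESS_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing awareness columns {missing}")
    for col in ("true_label", "judged_label"):
        bad = df.index[~df[col].isin(_LABELS)]
        if len(bad):
            raise ValueError(
                f"{path}: column {col!r} has invalid value "
                f"{df.loc[bad[0], col]!r} at row {int(bad[0])}"
            )
    counts = df.groupby("participant").size()
    wrong = counts[counts != 6]
    if len(wrong):
        pid = wrong.index[0]
        raise ValueError(
            f"{path}: participant {pid!r} has {int(wrong.iloc[0])} judgments, expected 6"
        )
    return df


def read_trials(path) -> pd.DataFrame:
    """Read and validate a trial-log CSV."""
    return validate_trials(_read(path), str(path))


def read_awareness(path) -> pd.DataFrame:
    """Read and validate an awareness-table CSV."""
    return validate_awareness(_read(path), str(path))
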