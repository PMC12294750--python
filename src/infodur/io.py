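"""Token-table I/O, run configuration and reproducible seeding.

A *token table* is the package's sole input format: one row per word token
with the word itself, its context (the immediately preceding word in the
utterance) and, optionally, the token's duration.  Durations are stored
internally in natural-log seconds; Tables of results refer to them as
``duration_log``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

log = logging.getLogger("infodur")

WORD_COL = "word"
CONTEXT_COL = "context"
DURATION_LOG_COL = "duration_log"


@dataclass
class RunConfig:
    """Configuration for a full run (CLI or scripted).

    Parameters
    ----------
    master_seed : int
        Root of every random stream in the run; replicate streams are
        derived with :func:`derive_seed`.
    alpha : float
        Two-sided significance level used throughout, in (0, 1).
    log_base : {"e", "2"}
        Base for surprisal/predictability.  Natural log (nats) by default;
        the choice rescales coefficients linearly and nothing else.
    n_reps : int
        Number of null replicates.
    """

    master_seed: int = 0
    alpha: float = 0.05
    log_base: str = "e"
    n_reps: int = 1000
    word_col: str = WORD_COL
    context_col: str = CONTEXT_COL
    duration_col: str = "duration"
    duration_unit: str = "seconds"
    formula: str = "duration_log ~ predictability + informativity"
    paths: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not 0.0 < self.alpha < 1.0:
            raise ValueError(f"alpha must lie in (0, 1), got {self.alpha}")
        if self.n_reps < 1:
            raise ValueError(f"n_reps must be >= 1, got {self.n_reps}")
        if self.log_base not in ("e", "2"):
            raise ValueError(f"log_base must be 'e' or '2', got {self.log_base!r}")
        if self.duration_unit not in ("seconds", "log-seconds"):
            raise ValueError(f"unknown duration_unit {self.duration_unit!r}")


def load_config(path: str | Path) -> RunConfig:
    """Load a :class:`RunConfig` from a YAML file (unknown keys rejected)."""
    with open(path, "r", encoding="utf-8") as fh:
        raw = yaml.safe_load(fh) or {}
    if not isinstance(raw, dict):
        raise ValueError(f"config file {path} must contain a mapping")
    known = RunConfig.__dataclass_fields__.keys()
    unknown = set(raw) - set(known)
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    return RunConfig(**raw)


def derive_seed(master_seed: int, replicate_index: int) -> int:
    """Derive a per-replicate seed from a master seed.

    Uses :class:`numpy.random.SeedSequence` spawn keys, so distinct
    replicate indices give statistically independent streams and the same
    ``(master_seed, replicate_index)`` pair always gives the same seed.
    The result fits in 31 bits.
    """
    if replicate_index < 0:
        raise ValueError("replicate_index must be >= 0")
    ss = np.random.SeedSequence(entropy=int(master_seed), spawn_key=(int(replicate_index),))
    return int(ss.generate_state(1, dtype=np.uint32)[0] % (2**31))


def _delimiter_for(path: Path) -> str:
    return "\t" if path.suffix.lower() in (".tsv", ".tab") else ","


def read_token_table(
    path: str | Path,
    duration_unit: str = "seconds",
    word_col: str = WORD_COL,
    context_col: str = CONTEXT_COL,
    duration_col: str | None = "duration",
) -> pd.DataFrame:
    """Read a token table from TSV/CSV.

    Parameters
    ----------
    path
        File to read; delimiter inferred from extension (``.tsv``/``.tab``
        tab, anything else comma).  UTF-8, header row required.
    duration_unit : {"seconds", "log-seconds"}
        Unit of the duration column in the file.  Seconds are converted to
        natural-log seconds on read.
    word_col, context_col, duration_col
        Column names in the file.  ``duration_col=None`` (or an absent
        column) yields a table without durations, sufficient for frequency
        statistics.

    Returns
    -------
    pandas.DataFrame
        Columns ``word``, ``context`` and (when available) ``duration_log``;
        index named ``token_id``.  Rows with a missing/empty word or
        context are dropped with a logged count.
    """
    if duration_unit not in ("seconds", "log-seconds"):
        raise ValueError(f"unknown duration_unit {duration_unit!r}")
    path = Path(path)
    df = pd.read_csv(path, sep=_delimiter_for(path), dtype={word_col: str, context_col: str})
    for col in (word_col, context_col):
        if col not in df.columns:
            raise ValueError(f"{path}: required column {col!r} not found "
                             f"(available: {list(df.columns)})")
    out = pd.DataFrame(
        {
            WORD_COL: df[word_col].astype("string").str.strip(),
            CONTEXT_COL: df[context_col].astype("string").str.strip(),
        }
    )
    bad = out[WORD_COL].isna() | (out[WORD_COL] == "") | out[CONTEXT_COL].isna() | (out[CONTEXT_COL] == "")
    if bad.any():
        log.warning("%s: dropped %d row(s) with missing word/context", path, int(bad.sum()))

    if duration_col is not None and duration_col not in df.columns:
        # fall back to the package's own output naming
        for cand in (DURATION_LOG_COL, "duration"):
            if cand in df.columns:
                duration_col = cand
                if cand == DURATION_LOG_COL and duration_unit == "seconds":
                    duration_unit = "log-seconds"
                break
    if duration_col is not None and duration_col in df.columns:
        dur = pd.to_numeric(df[duration_col], errors="coerce")
        if duration_unit == "seconds":
            nonpos = dur.notna() & (dur <= 0) & ~bad
            if nonpos.any():
                row = int(np.flatnonzero(nonpos.to_numpy())[0])
                raise ValueError(
                    f"{path}: non-positive duration in seconds at row {row} "
                    f"(value {dur.iloc[row]})"
                )
            out[DURATION_LOG_COL] = np.log(dur)
        else:
            out[DURATION_LOG_COL] = dur
        if not np.isfinite(out.loc[~bad, DURATION_LOG_COL].astype(float)).all():
            raise ValueError(f"{path}: non-finite log duration after conversion")

    out = out[~bad].reset_index(drop=True)
    out[WORD_COL] = out[WORD_COL].astype(str)
    out[CONTEXT_COL] = out[CONTEXT_COL].astype(str)
    out.index.name = "token_id"
    return out


def write_token_table(tokens: pd.DataFrame, path: str | Path) -> None:
    """Write a token table (durations stay in log seconds)."""
    path = Path(path)
    cols = [WORD_COL, CONTEXT_COL] + ([DURATION_LOG_COL] if DURATION_LOG_COL in tokens else [])
    tokens[cols].to_csv(path, sep=_delimiter_for(path), index=False)
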