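"""TSV readers/writers for score tables, submissions and reports.

All on-disk tables are plain TSV with a header row. Columns:

* score table: ``target  model  metric  value``
* QMODE1 submissions: ``predictor  target  model  score  qscore``
* QMODE2 submissions: ``predictor  target  model  chain  residue_index  local_estimate``
* QMODE3 submissions: ``predictor  target  rank  model``
* pLDDT RMSD table: ``predictor  target  model  granularity  rmsd``
"""

from __future__ import annotations

from pathlib import Path
from typing import Sequence, Union

import pandas as pd

PathLike = Union[str, Path]

SCORE_TABLE_COLUMNS = ("target", "model", "metric", "value")
QMODE1_COLUMNS = ("predictor", "target", "model", "score", "qscore")
QMODE2_COLUMNS = ("predictor", "target", "model", "chain", "residue_index", "local_estimate")
QMODE3_COLUMNS = ("predictor", "target", "rank", "model")
PLDDT_RMSD_COLUMNS = ("predictor", "target", "model", "granularity", "rmsd")


def _read(path: PathLike, columns: Sequence[str]) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in columns if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required columns {missing}")
    return df


def _write(df: pd.DataFrame, path: PathLike) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, sep="\t", index=False)


def read_score_table(path: PathLike) -> pd.DataFrame:
    return _read(path, SCORE_TABLE_COLUMNS)


def write_score_table(df: pd.DataFrame, path: PathLike) -> None:
    _write(df[list(SCORE_TABLE_COLUMNS)], path)


def read_qmode1_submissions(path: PathLike) -> pd.DataFrame:
    return _read(path, QMODE1_COLUMNS)


def read_qmode2_submissions(path: PathLike) -> pd.DataFrame:
    return _read(path, QMODE2_COLUMNS)


def read_qmode3_submissions(path: PathLike) -> pd.DataFrame:
    return _read(path, QMODE3_COLUMNS)


def read_plddt_rmsd(path: PathLike) -> pd.DataFrame:
    return _read(path, PLDDT_RMSD_COLUMNS)


def write_table(df: pd.DataFrame, path: PathLike) -> None:
    """Write any report table as TSV with a header row."""
    _write(df, path)
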