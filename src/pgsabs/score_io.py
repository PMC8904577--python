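"""Score-file reading and standardization against a reference population.

Batch input is a plain TSV with one row per individual (columns ``IID`` and
``SCORE``, or ``FID``/``IID``/``SCORE``), or a PLINK2 ``.sscore`` file,
recognized by its ``#FID``/``#IID`` header tokens and its ``SCORE1_AVG`` /
``SCORE1_SUM`` score columns.  Raw scores are standardized to Z-scores with
the mean and SD of scores in an ancestry-matched reference sample; the
conversions downstream assume this standardization.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from pgsabs.errors import DomainError

__all__ = ["ScoreTable", "read_score_table", "standardize_scores"]

_SSCORE_SCORE_COLUMNS = ("SCORE1_AVG", "SCORE1_SUM", "SCORE_AVG", "SCORE_SUM")


@dataclass(frozen=True)
class ScoreTable:
    """Per-individual polygenic scores, raw or standardized."""

    ids: np.ndarray = field(repr=False)
    scores: np.ndarray = field(repr=False)
    standardized: bool = False

    def __post_init__(self) -> None:
        ids = np.asarray(self.ids, dtype=object)
        scores = np.asarray(self.scores, dtype=float)
        if ids.shape != scores.shape or ids.ndim != 1:
            raise DomainError("ids and scores must be 1-D arrays of equal length")
        if len(ids) == 0:
            raise DomainError("score table is empty")
        dup_mask = pd.Index(ids).duplicated()
        if dup_mask.any():
            dup = ids[dup_mask][0]
            raise DomainError(f"duplicate individual id {dup!r} in score table")
        bad = ~np.isfinite(scores)
        if bad.any():
            raise DomainError(
                f"non-finite score for individual {ids[np.flatnonzero(bad)[0]]!r}"
            )
        object.__setattr__(self, "ids", ids)
        object.__setattr__(self, "scores", scores)

    def __len__(self) -> int:
        return len(self.ids)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"IID": self.ids, "SCORE": self.scores})


def read_score_table(
    path: str | Path, fmt: str = "auto", standardized: bool = False
) -> ScoreTable:
    """Read per-individual scores from a TSV or PLINK2 .sscore file.

    ``fmt`` is ``"tsv"``, ``"sscore"``, or ``"auto"`` (sniff: a header
    starting with ``#`` and containing a PLINK score column is .sscore).
    Malformed rows are reported with their line number.
    """
    path = Path(path)
    if not path.exists():
        raise DomainError(f"score file not found: {path}")
    with open(path) as fh:
        header_line = fh.readline()
    if not header_line.strip():
        raise DomainError(f"score file is empty: {path}")
    header = header_line.lstrip("#").rstrip("\n").split("\t")

    if fmt == "auto":
        is_sscore = header_line.startswith("#") and any(
            c in header for c in _SSCORE_SCORE_COLUMNS
        )
        fmt = "sscore" if is_sscore else "tsv"

    if fmt == "sscore":
        df = pd.read_csv(path, sep="\t")
        df.columns = [c.lstrip("#") for c in df.columns]
        id_col = "IID" if "IID" in df.columns else None
        score_col = next((c for c in _SSCORE_SCORE_COLUMNS if c in df.columns), None)
        if id_col is None or score_col is None:
            raise DomainError(
                f"{path}: not a recognizable .sscore file "
                f"(need IID and one of {_SSCORE_SCORE_COLUMNS})"
            )
    elif fmt == "tsv":
        df = pd.read_csv(path, sep="\t")
        cols = {c.upper(): c for c in df.columns}
        id_col = cols.get("IID") or cols.get("ID")
        score_col = cols.get("SCORE") or cols.get("PGS") or cols.get("Z")
        if id_col is None or score_col is None:
            raise DomainError(
                f"{path}: need an id column (IID/ID) and a score column (SCORE/PGS/Z); "
                f"found {list(df.columns)}"
            )
    else:
        raise DomainError(f"unknown score file format {fmt!r}")

    raw = df[score_col]
    scores = pd.to_numeric(raw, errors="coerce")
    bad = scores.isna() & raw.notna() | raw.isna()
    if bad.any():
        line = int(bad.idxmax()) + 2  # +1 header, +1 one-based
        raise DomainError(f"{path}: non-numeric or missing score on line {line}")
    return ScoreTable(
        ids=df[id_col].astype(str).to_numpy(dtype=object),
        scores=scores.to_numpy(dtype=float),
        standardized=standardized,
    )


def standardize_scores(table: ScoreTable, ref_mean: float, ref_sd: float) -> ScoreTable:
    """Standardize raw scores to Z-scores against a reference mean and SD."""
    if ref_sd <= 0:
        raise DomainError(f"reference SD must be > 0, got {ref_sd}")
    if table.standardized:
        raise DomainError(
            "score table is already standardized; refusing to standardize twice"
        )
    return replace(table, scores=(table.scores - ref_mean) / ref_sd, standardized=True)
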