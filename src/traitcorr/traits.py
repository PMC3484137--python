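"""Binary trait tables with explicit missing data.

The on-disk dialect is a tab-separated file: header row of character
names, one row per taxon (first column ``taxon``), cells in {0, 1, -}.
A dash means missing/inapplicable and is treated as total ambiguity by
the likelihood machinery, never as a third state.
"""

from __future__ import annotations

import io
from typing import Iterable

import numpy as np
import pandas as pd

__all__ = ["TraitMatrix", "TraitTableError", "read_trait_table"]

MISSING = "-"


class TraitTableError(ValueError):
    """Raised for malformed trait tables."""


class TraitMatrix:
    """Taxa x binary characters, stored as a float frame (0.0, 1.0, NaN)."""

    def __init__(self, frame: pd.DataFrame):
        if frame.index.has_duplicates:
            dups = sorted(frame.index[frame.index.duplicated()].unique())
            raise TraitTableError(f"duplicate taxon rows: {dups}")
        vals = frame.to_numpy(dtype=float)
        bad = ~(np.isnan(vals) | (vals == 0.0) | (vals == 1.0))
        if bad.any():
            r, c = np.argwhere(bad)[0]
            raise TraitTableError(
                f"non-binary value {frame.iat[r, c]!r} for taxon "
                f"{frame.index[r]!r}, character {frame.columns[c]!r}")
        self.frame = frame.astype(float)

    @property
    def taxa(self) -> list[str]:
        return list(self.frame.index)

    @property
    def characters(self) -> list[str]:
        return list(self.frame.columns)

    def states(self, character: str) -> dict[str, int | None]:
        """Per-taxon state for one character; None where missing."""
        if character not in self.frame.columns:
            raise KeyError(f"unknown character: {character!r}")
        col = self.frame[character]
        return {t: (None if np.isnan(v) else int(v)) for t, v in col.items()}

    def n_observed(self, character: str) -> int:
        return int(self.frame[character].notna().sum())

    def subset(self, taxa: Iterable[str]) -> "TraitMatrix":
        return TraitMatrix(self.frame.loc[list(taxa)])

    def to_tsv(self, dest) -> None:
        out = self.frame.copy()
        out = out.map(lambda v: MISSING if np.isnan(v) else str(int(v)))
        out.index.name = "taxon"
        out.to_csv(dest, sep="\t")

    def __eq__(self, other):
        return isinstance(other, TraitMatrix) and self.frame.equals(other.frame)

    def __repr__(self):
        return f"<TraitMatrix {len(self.taxa)} taxa x {len(self.characters)} characters>"


def read_trait_table(source) -> TraitMatrix:
    """Read a tab-separated trait table; '-' cells become missing.

    Raises :class:`TraitTableError` for empty input, ragged rows,
    duplicate taxa, or non-binary cell values.
    """
    if isinstance(source, str) and "\t" in source:
        source = io.StringIO(source)
    try:
        df = pd.read_csv(source, sep="\t", index_col=0, dtype=str,
                         keep_default_na=False)
    except pd.errors.EmptyDataError as exc:
        raise TraitTableError("empty trait table") from exc
    except Exception as exc:
        raise TraitTableError(f"could not read trait table: {exc}") from exc
    if df.shape[1] == 0 or df.shape[0] == 0:
        raise TraitTableError("trait table has no data rows or no characters")
    if df.isin([""]).any().any():
        raise TraitTableError("ragged row: empty cell found")

    def convert(v: str):
        v = v.strip()
        if v in (MISSING, "−"):  # ASCII dash or unicode minus
            return np.nan
        if v in ("0", "1"):
            return float(v)
        raise TraitTableError(f"non-binary cell value: {v!r}")

    return TraitMatrix(df.map(convert))
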