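"""Tab-separated report writing with deterministic columns and formats.

Report rows are dataclasses; column order is field order, floats print
with two decimals by default (log-likelihoods, Bayes factors) and a
per-field ``fmt`` metadata override (e.g. ``"%.4f"`` for probabilities).
Missing/not-applicable values are written as ``NA``.
"""

from __future__ import annotations

import dataclasses
import io
from typing import Sequence

import pandas as pd

__all__ = ["write_table", "read_table", "format_row"]

NA = "NA"
DEFAULT_FLOAT_FMT = "%.2f"


def _format_value(value, fmt: str | None) -> str:
    if value is None:
        return NA
    if isinstance(value, float):
        return (fmt or DEFAULT_FLOAT_FMT) % value
    if isinstance(value, (list, tuple)):
        return ",".join(_format_value(v, fmt) for v in value)
    return str(value)


def format_row(row) -> dict[str, str]:
    """Format one dataclass report row into an ordered dict of strings."""
    out = {}
    for f in dataclasses.fields(row):
        out[f.name] = _format_value(getattr(row, f.name), f.metadata.get("fmt"))
    return out


def write_table(rows: Sequence, destination, fieldnames: Sequence[str] | None = None) -> str:
    """Write homogeneous report rows as TSV; returns the rendered text.

    ``destination`` may be a path, a file object, or None (render only).
    An empty row list with explicit ``fieldnames`` yields a header-only
    table; without fieldnames the row type cannot be inferred and an
    error is raised.
    """
    if rows:
        first = rows[0]
        if not dataclasses.is_dataclass(first):
            raise TypeError("report rows must be dataclass instances")
        names = [f.name for f in dataclasses.fields(first)]
        for r in rows:
            if type(r) is not type(first):
                raise TypeError("report rows must be homogeneous")
        lines = ["\t".join(names)]
        lines += ["\t".join(format_row(r).values()) for r in rows]
    else:
        if fieldnames is None:
            raise ValueError("cannot write an empty table without fieldnames")
        names = list(fieldnames)
        lines = ["\t".join(names)]
    text = "\n".join(lines) + "\n"
    if destination is not None:
        if hasattr(destination, "write"):
            destination.write(text)
        else:
            with open(destination, "w") as fh:
                fh.write(text)
    return text


def read_table(source) -> pd.DataFrame:
    """Read back a report TSV (NA -> NaN), for round-tripping and tests."""
    if isinstance(source, str) and "\t" in source:
        source = io.StringIO(source)
    return pd.read_csv(source, sep="\t", na_values=[NA], keep_default_na=False)
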