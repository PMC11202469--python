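"""Plain-text series I/O and result writers.

Series files hold one sample per line (a single-column CSV with an optional
header is tolerated).  Curves go to tidy TSV with columns scale, q, Hq, Cq;
feature summaries go to JSON with the full run configuration echoed so every
artifact records how it was produced.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Sequence

import numpy as np

from .exceptions import SeriesParseError
from .plane import PlaneCurve, PlaneFeatures

__all__ = ["read_series", "write_series", "write_curve_tsv", "write_features_json"]


def read_series(path) -> np.ndarray:
    """Read a one-column numeric series from a text/CSV file.

    A single header line is skipped automatically.  Any other unparsable
    line raises :class:`SeriesParseError` naming the line number.
    """
    path = Path(path)
    values: list[float] = []
    header_allowed = True
    with path.open() as fh:
        for lineno, raw in enumerate(fh, start=1):
            token = raw.strip().rstrip(",").strip()
            if not token:
                continue
            try:
                value = float(token)
            except ValueError:
                if header_allowed:
                    header_allowed = False
                    continue
                raise SeriesParseError(
                    f"{path}: line {lineno}: cannot parse {token!r} as a number"
                ) from None
            header_allowed = False
            if not np.isfinite(value):
                raise SeriesParseError(f"{path}: line {lineno}: non-finite value {token!r}")
            values.append(value)
    if not values:
        raise SeriesParseError(f"{path}: no numeric data found")
    return np.array(values)


def write_series(path, x) -> None:
    """Write a series one value per line, round-trippable to full precision."""
    arr = np.asarray(getattr(x, "values", x), dtype=float)
    Path(path).write_text("".join(f"{float(v)!r}\n" for v in arr))


def write_curve_tsv(path, curves: Sequence[PlaneCurve]) -> None:
    """Tidy TSV with columns scale, q, Hq, Cq (12 significant digits)."""
    with Path(path).open("w") as fh:
        fh.write("scale\tq\tHq\tCq\n")
        for c in curves:
            for qi, hi, ci in zip(c.q, c.Hq, c.Cq):
                fh.write(f"{c.scale}\t{qi:.12g}\t{hi:.12g}\t{ci:.12g}\n")


def write_features_json(path, features: Sequence[PlaneFeatures], config: dict) -> None:
    """Feature summary JSON: one block per scale plus the echoed run config."""
    payload = {"config": config, "features": [f.as_dict() for f in features]}
    Path(path).write_text(json.dumps(payload, indent=2) + "\n")
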