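"""CSV input/output for titration datasets and solved curves.

Dialect: comma-separated, ``.`` decimal, molar units, with a
``#``-prefixed metadata header carrying composition, seed and noise
provenance as JSON so that datasets round-trip losslessly.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .synthetic import TitrationDataset

__all__ = ["write_titration_csv", "load_titration_csv", "write_curve_csv"]

_META_PREFIX = "# meta: "


class FormatError(ValueError):
    pass


def write_titration_csv(dataset: TitrationDataset, path) -> None:
    path = Path(path)
    with path.open("w") as fh:
        fh.write(_META_PREFIX + json.dumps(dataset.metadata) + "\n")
        fh.write("ca_free_molar,saturation,weight\n")
        for ca, y, w in zip(dataset.ca_free, dataset.Y, dataset.weight):
            fh.write(f"{float(ca)!r},{float(y)!r},{float(w)!r}\n")


def load_titration_csv(path) -> TitrationDataset:
    """Read a dataset, restoring metadata and sorting by calcium.

    Raises :class:`FormatError` naming any missing column, and a
    row-level error with the 1-based line number for non-numeric data.
    """
    path = Path(path)
    metadata: dict = {}
    header_lines = 0
    with path.open() as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            header_lines += 1
            if line.startswith(_META_PREFIX):
                metadata = json.loads(line[len(_META_PREFIX):])
    raw = pd.read_csv(path, comment="#", dtype=str)
    required = ["ca_free_molar", "saturation"]
    for col in required:
        if col not in raw.columns:
            raise FormatError(f"{path}: missing required column {col!r}")
    cols = {}
    for col in raw.columns:
        try:
            cols[col] = raw[col].astype(float).to_numpy()
        except ValueError:
            bad = raw[col][pd.to_numeric(raw[col], errors="coerce").isna()]
            line_no = int(bad.index[0]) + header_lines + 2  # +header row, 1-based
            raise FormatError(
                f"{path}: non-numeric value {bad.iloc[0]!r} in column {col!r} "
                f"at line {line_no}"
            ) from None
    order = np.argsort(cols["ca_free_molar"])
    weight = cols.get("weight", np.ones(len(order)))
    return TitrationDataset(
        ca_free=cols["ca_free_molar"][order],
        Y=cols["saturation"][order],
        weight=weight[order],
        metadata=metadata,
    )


def write_curve_csv(curve, path, metadata: Mapping[str, object] | None = None) -> None:
    """Write a solved saturation curve (ca, Y, free targets) to CSV."""
    path = Path(path)
    df = curve.to_dataframe()
    with path.open("w") as fh:
        if metadata:
            fh.write(_META_PREFIX + json.dumps(dict(metadata)) + "\n")
        df.to_csv(fh, index=False)
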