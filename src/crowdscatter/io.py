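"""Columnar text formats shared by all analysis stages.

Every curve (scattering, correlogram, intermediate scattering function,
viscosity series) travels as whitespace-separated columns preceded by
``# key = value`` header lines carrying units and sample metadata.
"""

from __future__ import annotations

import numpy as np

__all__ = ["write_columns", "read_columns"]


def write_columns(path, columns: dict[str, np.ndarray], metadata: dict) -> None:
    """Write named columns with a ``# key = value`` header block."""
    names = list(columns)
    data = np.column_stack([np.asarray(columns[n], dtype=float) for n in names])
    with open(path, "w") as fh:
        for key, val in metadata.items():
            fh.write(f"# {key} = {val}\n")
        fh.write("# columns: " + " ".join(names) + "\n")
        for row in data:
            fh.write(" ".join(f"{v:.10g}" for v in row) + "\n")


def read_columns(path) -> tuple[dict[str, np.ndarray], dict[str, str]]:
    """Read columns and metadata written by :func:`write_columns`.

    Also accepts plain three-column files without a ``# columns:`` line,
    in which case columns are named ``col0, col1, ...``.
    """
    meta: dict[str, str] = {}
    names: list[str] | None = None
    rows: list[list[float]] = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            if line.startswith("#"):
                body = line[1:].strip()
                if body.startswith("columns:"):
                    names = body.partition(":")[2].split()
                elif "=" in body:
                    key, _, val = body.partition("=")
                    meta[key.strip()] = val.strip()
                continue
            rows.append([float(tok) for tok in line.replace(",", " ").split()])
    arr = np.array(rows)
    if names is None:
        names = [f"col{k}" for k in range(arr.shape[1])]
    cols = {name: arr[:, k].copy() for k, name in enumerate(names)}
    return cols, meta
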