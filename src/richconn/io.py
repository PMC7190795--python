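"""Plain-text readers/writers for connectivity matrices and cohort tables.

Matrices are whitespace-delimited N x N tables without row labels, preceded
by a single comment line ``# atlas=<name> n=<N>``. The reader is tolerant:
comma-delimited files and missing headers are accepted.
"""
from __future__ import annotations

import io as _io
import re
from pathlib import Path

import numpy as np


def write_matrix(path, matrix: np.ndarray, atlas_name: str = "synthetic") -> None:
    m = np.asarray(matrix)
    n = m.shape[0]
    if m.shape != (n, n):
        raise ValueError("matrix must be square")
    header = f"atlas={atlas_name} n={n}"
    fmt = "%d" if np.issubdtype(m.dtype, np.integer) else "%.10g"
    np.savetxt(path, m, fmt=fmt, delimiter="\t", header=header)


def read_matrix(path) -> tuple[np.ndarray, str | None]:
    """Read a matrix file; returns (matrix, atlas name or None)."""
    text = Path(path).read_text()
    atlas_name = None
    rows = []
    for line in text.splitlines():
        line = line.strip()
        if not line:
            continue
        if line.startswith("#"):
            m = re.search(r"atlas=(\S+)", line)
            if m:
                atlas_name = m.group(1)
            continue
        rows.append(line.replace(",", " "))
    mat = np.loadtxt(_io.StringIO("\n".join(rows)))
    if mat.ndim == 1:  # single row
        mat = mat.reshape(1, -1)
    return mat, atlas_name


def subject_matrix_paths(directory, subject_id: str) -> tuple[Path, Path]:
    d = Path(directory)
    return d / f"{subject_id}_fn.tsv", d / f"{subject_id}_fa.tsv"
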