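"""Reading and writing the plain-text formats used throughout the package.

All tabular data travels as labelled tab-separated matrices (first row =
column labels, first column = row labels).  Ontologies are two-column
``child<TAB>parent`` edge lists; disease-to-term mappings are two-column
``disease<TAB>term`` files.  Lines starting with ``#`` are comments.
"""

from __future__ import annotations

import os
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

# %.17g round-trips IEEE doubles exactly, comfortably beyond the 12
# significant digits the matrix dialect guarantees.
_FLOAT_FMT = "%.17g"


def write_labelled_matrix(path: str | os.PathLike, values: np.ndarray,
                          row_labels: Sequence[str],
                          col_labels: Sequence[str]) -> None:
    df = pd.DataFrame(np.asarray(values), index=list(row_labels),
                      columns=list(col_labels))
    df.to_csv(path, sep="\t", float_format=_FLOAT_FMT)


def read_labelled_matrix(path: str | os.PathLike):
    """Return ``(values, row_labels, col_labels)`` from a labelled TSV."""
    df = pd.read_csv(path, sep="\t", index_col=0, comment="#")
    return df.to_numpy(dtype=float), [str(x) for x in df.index], [str(c) for c in df.columns]


def write_edge_list(path: str | os.PathLike,
                    edges: Iterable[tuple[str, str]]) -> None:
    with open(path, "w") as fh:
        for u, v in edges:
            fh.write(f"{u}\t{v}\n")


def read_edge_list(path: str | os.PathLike) -> list[tuple[str, str]]:
    edges = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise ValueError(f"malformed edge line: {line!r}")
            edges.append((parts[0], parts[1]))
    return edges


def read_mapping(path: str | os.PathLike) -> dict[str, str]:
    return dict(read_edge_list(path))


def write_mapping(path: str | os.PathLike, mapping: dict[str, str]) -> None:
    write_edge_list(path, mapping.items())
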