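"""File formats: binary data matrices, network JSON, BoolNet text, configs.

Data matrices are TSV/CSV with a header row of gene names, rows =
observations, columns = genes.  Continuous expression is binarized by the
per-gene mean threshold (strictly greater -> 1).  Networks are stored in a
JSON schema and can be exported to BoolNet-compatible "targets, factors"
text for interoperability with other Boolean-network tools.
"""

from __future__ import annotations

import json
import warnings
from pathlib import Path
from typing import List, Optional, Tuple, Union

import numpy as np
import pandas as pd

from .functions import BooleanFunction, enumerate_functions
from .model import DataMatrix
from .topology import NetworkModel, Topology, is_valid_topology

__all__ = [
    "read_data_matrix",
    "write_data_matrix",
    "binarize",
    "drop_missing",
    "read_network",
    "write_network",
    "write_boolnet",
]


def _read_table(path: Union[str, Path]) -> pd.DataFrame:
    path = Path(path)
    sep = "," if path.suffix.lower() == ".csv" else "\t"
    return pd.read_csv(path, sep=sep, comment="#")


def read_data_matrix(path: Union[str, Path], mode: str = "independent") -> DataMatrix:
    """Read a binary TSV/CSV matrix (header = gene names)."""
    df = _read_table(path)
    if df.isna().any().any():
        r, c = next(zip(*np.where(df.isna().values)))
        raise ValueError(
            f"missing value at row {r + 1}, column {df.columns[c]!r}: "
            "remove incomplete observations first (drop_missing)"
        )
    vals = df.to_numpy()
    bad = ~np.isin(vals, (0, 1))
    if bad.any():
        r, c = next(zip(*np.where(bad)))
        raise ValueError(
            f"non-binary value {vals[r, c]!r} at row {r + 1}, column "
            f"{df.columns[c]!r}: binarize continuous data first (binarize)"
        )
    return DataMatrix(
        values=vals.astype(np.int8), mode=mode, names=tuple(map(str, df.columns))
    )


def write_data_matrix(X: DataMatrix, path: Union[str, Path], header: str = "") -> None:
    path = Path(path)
    sep = "," if path.suffix.lower() == ".csv" else "\t"
    names = X.names or tuple(f"g{i}" for i in range(X.n))
    with open(path, "w") as fh:
        if header:
            for line in header.splitlines():
                fh.write(f"# {line}\n")
        fh.write(sep.join(names) + "\n")
        for row in X.values:
            fh.write(sep.join(str(int(v)) for v in row) + "\n")


def binarize(
    values: np.ndarray, names: Optional[Tuple[str, ...]] = None, mode: str = "independent"
) -> DataMatrix:
    """Per-gene mean threshold: strictly above the column mean -> 1, else 0."""
    values = np.asarray(values, dtype=float)
    if np.isnan(values).any():
        raise ValueError("binarize requires complete data; use drop_missing first")
    means = values.mean(axis=0)
    const = values.std(axis=0) == 0
    if const.any():
        warnings.warn(
            f"{int(const.sum())} constant column(s) binarize to all zeros",
            stacklevel=2,
        )
    return DataMatrix(
        values=(values > means).astype(np.int8), mode=mode, names=names
    )


def drop_missing(values: np.ndarray) -> Tuple[np.ndarray, List[int]]:
    """Delete every observation row containing a missing value.

    Returns the complete matrix and the dropped row indices.
    """
    values = np.asarray(values, dtype=float)
    bad = np.isnan(values).any(axis=1)
    if bad.all():
        raise ValueError("every row contains a missing value")
    return values[~bad], list(np.where(bad)[0])


# -- network JSON ---------------------------------------------------------

def write_network(
    model: NetworkModel, path: Union[str, Path], names: Optional[Tuple[str, ...]] = None
) -> None:
    names = names or tuple(f"g{i}" for i in range(model.topology.n))
    relations = []
    for i, pa in enumerate(model.topology.parents):
        if not pa:
            continue
        f = model.functions[i]
        relations.append(
            {
                "target": names[i],
                "parents": [names[p] for p in pa],
                "function_label": f.label,
                "truth_table": list(f.table),
            }
        )
    with open(path, "w") as fh:
        json.dump({"nodes": list(names), "relations": relations}, fh, indent=1)


def read_network(path: Union[str, Path]) -> Tuple[NetworkModel, Tuple[str, ...]]:
    with open(path) as fh:
        doc = json.load(fh)
    names = tuple(doc["nodes"])
    index = {name: i for i, name in enumerate(names)}
    n = len(names)
    parents: List[Tuple[int, ...]] = [() for _ in range(n)]
    funcs: List[Optional[BooleanFunction]] = [None] * n
    for rel in doc["relations"]:
        tname = rel["target"]
        if tname not in index:
            raise ValueError(f"unknown target node {tname!r}")
        i = index[tname]
        try:
            pa = tuple(sorted(index[p] for p in rel["parents"]))
        except KeyError as e:
            raise ValueError(f"unknown parent node {e.args[0]!r}") from None
        table = tuple(int(v) for v in rel["truth_table"])
        arity = len(pa)
        if len(table) != 2**arity:
            raise ValueError(
                f"node {tname!r}: truth table length {len(table)} does not "
                f"match arity {arity}"
            )
        fam = enumerate_functions(arity)
        match = next((f for f in fam if f.table == table), None)
        if match is None:
            raise ValueError(f"node {tname!r}: degenerate or unknown truth table")
        parents[i] = pa
        funcs[i] = match
    topo = Topology(n, tuple(parents))
    if not is_valid_topology(topo):
        raise ValueError("network file defines a cyclic topology")
    return NetworkModel(topo, tuple(funcs)), names


# -- BoolNet export -------------------------------------------------------

def _boolnet_formula(f: BooleanFunction, names: Tuple[str, ...]) -> str:
    """Render a function in BoolNet syntax (!, &, |); XOR forms expand to
    their AND/OR/NOT equivalents."""
    a = names[0]
    if f.arity == 1:
        return a if f.table == (0, 1) else f"!{a}"
    b = names[1]
    forms = {
        (0, 0, 0, 1): f"{a} & {b}",
        (0, 0, 1, 0): f"{a} & !{b}",
        (0, 1, 0, 0): f"!{a} & {b}",
        (0, 1, 1, 0): f"({a} & !{b}) | (!{a} & {b})",
        (0, 1, 1, 1): f"{a} | {b}",
        (1, 0, 0, 0): f"!{a} & !{b}",
        (1, 0, 0, 1): f"({a} & {b}) | (!{a} & !{b})",
        (1, 0, 1, 1): f"{a} | !{b}",
        (1, 1, 0, 1): f"!{a} | {b}",
        (1, 1, 1, 0): f"!{a} | !{b}",
    }
    return forms[f.table]


def write_boolnet(
    model: NetworkModel, path: Union[str, Path], names: Optional[Tuple[str, ...]] = None
) -> None:
    """Export as BoolNet 'targets, factors' text; roots reference themselves."""
    names = names or tuple(f"g{i}" for i in range(model.topology.n))
    with open(path, "w") as fh:
        fh.write("targets, factors\n")
        for i, pa in enumerate(model.topology.parents):
            if not pa:
                fh.write(f"{names[i]}, {names[i]}\n")
            else:
                pnames = tuple(names[p] for p in pa)
                fh.write(f"{names[i]}, {_boolnet_formula(model.functions[i], pnames)}\n")
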