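"""TSV/JSON/GraphML readers and writers for every pipeline artifact.

Conventions: feature-by-sample matrices are TSVs whose first column holds the
feature id and whose header row holds sample ids; the missing-value token is
the empty string ("NA" is accepted on read, never written); floats are
written in shortest round-trip form so a write/read/write cycle is
byte-stable.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "read_matrix",
    "write_matrix",
    "read_samples",
    "write_samples",
    "read_pairs",
    "write_pairs",
    "read_edges",
    "write_edges",
    "write_json",
    "read_json",
    "write_graphml",
]

_MISSING_READ = {"", "NA"}


def _fmt(v: float) -> str:
    if np.isnan(v):
        return ""
    if v == int(v) and abs(v) < 1e15:
        return str(int(v))
    return repr(float(v))


def read_matrix(path) -> pd.DataFrame:
    """Feature x sample TSV -> float DataFrame (NaN = missing).

    Rejects ragged rows, duplicated feature ids, and non-numeric cells with
    the offending line number.
    """
    path = Path(path)
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if len(header) < 2:
            raise ValueError(f"{path}:1: expected a feature-id column plus sample columns")
        samples = header[1:]
        ids, rows = [], []
        for ln, line in enumerate(fh, 2):
            parts = line.rstrip("\n").split("\t")
            if len(parts) != len(header):
                raise ValueError(
                    f"{path}:{ln}: ragged row ({len(parts)} fields, expected {len(header)})"
                )
            ids.append(parts[0])
            vals = []
            for ci, cell in enumerate(parts[1:]):
                if cell in _MISSING_READ:
                    vals.append(np.nan)
                    continue
                try:
                    vals.append(float(cell))
                except ValueError:
                    raise ValueError(
                        f"{path}:{ln}: non-numeric value {cell!r} in column {samples[ci]}"
                    ) from None
            rows.append(vals)
    if len(set(ids)) != len(ids):
        dupes = sorted({i for i in ids if ids.count(i) > 1})
        raise ValueError(f"{path}: duplicated feature ids {dupes[:5]}")
    df = pd.DataFrame(rows, index=ids, columns=samples, dtype=float)
    df.index.name = header[0]
    return df


def write_matrix(df: pd.DataFrame, path, index_name: str = "feature") -> None:
    path = Path(path)
    name = df.index.name or index_name
    with open(path, "w") as fh:
        fh.write("\t".join([name, *map(str, df.columns)]) + "\n")
        for fid, row in zip(df.index, df.to_numpy(dtype=float)):
            fh.write(str(fid) + "\t" + "\t".join(_fmt(v) for v in row) + "\n")


def read_samples(path) -> pd.DataFrame:
    meta = pd.read_csv(path, sep="\t", dtype={"sample_id": str, "treatment": str})
    need = {"sample_id", "week", "treatment"}
    if not need <= set(meta.columns):
        raise ValueError(f"{path}: sample table needs columns {sorted(need)}")
    meta["week"] = meta["week"].astype(int)
    return meta


def write_samples(meta: pd.DataFrame, path) -> None:
    meta.to_csv(path, sep="\t", index=False)


def read_pairs(path) -> list[tuple[str, str]]:
    """Two-column id TSV with a header line."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    if df.shape[1] < 2:
        raise ValueError(f"{path}: expected two id columns")
    return [(str(a), str(b)) for a, b in df.iloc[:, :2].itertuples(index=False)]


def write_pairs(pairs, path, header: tuple[str, str]) -> None:
    with open(path, "w") as fh:
        fh.write("\t".join(header) + "\n")
        for a, b in sorted(pairs):
            fh.write(f"{a}\t{b}\n")


def read_edges(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"source": str, "target": str})
    need = {"source", "target", "beta", "r2"}
    if not need <= set(df.columns):
        raise ValueError(f"{path}: edge list needs columns {sorted(need)}")
    return df


def write_edges(edges: pd.DataFrame, path) -> None:
    e = edges.sort_values(["source", "target"]).reset_index(drop=True).copy()
    with open(path, "w") as fh:
        fh.write("\t".join(e.columns) + "\n")
        for row in e.itertuples(index=False):
            cells = [
                _fmt(float(v)) if isinstance(v, (float, np.floating)) else str(v) for v in row
            ]
            fh.write("\t".join(cells) + "\n")


def write_json(obj, path) -> None:
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True)
        fh.write("\n")


def read_json(path):
    with open(path) as fh:
        return json.load(fh)


def write_graphml(net, path, module_of: dict[str, int] | None = None) -> None:
    """Attribute-rich GraphML export of a network (optionally module-labelled)."""
    g = net.to_networkx(directed=False) if hasattr(net, "to_networkx") else net
    if module_of:
        for n in g.nodes:
            g.nodes[n]["module"] = int(module_of.get(n, -1))
    nx.write_graphml(g, path)
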