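"""Readers and writers for the tabular and graph artefacts of the pipeline.

Input tables are plain delimited text: a spectral-count matrix (proteins x
samples), a two-column molecular-weight table, and a STRING-style edge export
``(protein_a, protein_b, combined_score)``.  Outputs are CSV tables plus
GraphML/SIF networks, listed in a JSON manifest.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Mapping

import networkx as nx
import numpy as np
import pandas as pd

__all__ = [
    "read_spc_matrix",
    "read_molecular_weights",
    "read_edge_table",
    "normalize_by_mw",
    "filter_shared_proteins",
    "write_sif",
    "write_outputs",
]


def _sniff_delimiter(path: str | Path) -> str:
    """Auto-detection limited to tab vs comma; an explicit flag overrides."""
    with open(path) as fh:
        first = fh.readline()
    if "\t" in first:
        return "\t"
    if "," in first:
        return ","
    raise ValueError(f"{path}: could not detect a tab or comma delimiter")


def read_spc_matrix(path: str | Path, delimiter: str | None = None) -> pd.DataFrame:
    """Read a spectral-count matrix: first row sample ids, first column protein ids.

    Values must be non-negative numbers (real-valued counts are accepted since
    some upstream tools emit averaged spectra).  Duplicated identifiers,
    missing cells and negative or non-numeric cells are rejected with the
    offending coordinates.
    """
    delimiter = delimiter or _sniff_delimiter(path)
    df = pd.read_csv(path, sep=delimiter, index_col=0)
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    for axis, name in ((df.index, "protein"), (df.columns, "sample")):
        dupes = axis[axis.duplicated()].unique().tolist()
        if dupes:
            raise ValueError(f"{path}: duplicate {name} ids: {dupes}")
    numeric = df.apply(pd.to_numeric, errors="coerce")
    bad = numeric.isna()
    if bad.to_numpy().any():
        prot, samp = next(zip(*np.nonzero(bad.to_numpy())))
        raise ValueError(
            f"{path}: non-numeric or missing value at "
            f"(protein={df.index[prot]!r}, sample={df.columns[samp]!r})"
        )
    neg = numeric < 0
    if neg.to_numpy().any():
        prot, samp = next(zip(*np.nonzero(neg.to_numpy())))
        raise ValueError(
            f"{path}: negative count at "
            f"(protein={df.index[prot]!r}, sample={df.columns[samp]!r})"
        )
    return numeric.astype(float)


def read_molecular_weights(path: str | Path, delimiter: str | None = None) -> pd.Series:
    """Read a two-column (protein_id, molecular weight) table into a Series.

    Weights must be strictly positive (they divide the counts); duplicated
    proteins are rejected.
    """
    delimiter = delimiter or _sniff_delimiter(path)
    df = pd.read_csv(path, sep=delimiter)
    if df.shape[1] != 2:
        raise ValueError(f"{path}: expected two columns (protein_id, weight)")
    ids = df.iloc[:, 0].astype(str)
    dupes = ids[ids.duplicated()].unique().tolist()
    if dupes:
        raise ValueError(f"{path}: duplicate protein ids: {dupes}")
    weights = pd.to_numeric(df.iloc[:, 1], errors="coerce")
    if weights.isna().any():
        raise ValueError(f"{path}: non-numeric molecular weight")
    if (weights <= 0).any():
        bad = ids[weights.to_numpy() <= 0].tolist()
        raise ValueError(f"{path}: non-positive molecular weight for {bad}")
    mw = pd.Series(weights.to_numpy(dtype=float), index=pd.Index(ids, name="protein"))
    mw.name = "molecular_weight"
    return mw


def read_edge_table(
    path: str | Path,
    delimiter: str | None = None,
    columns: tuple[str, str, str] | tuple[int, int, int] = (0, 1, 2),
) -> pd.DataFrame:
    """Read a STRING-style edge export into a cleaned edge table.

    ``columns`` selects the (protein_a, protein_b, score) columns by name or
    position.  Self-pairs are dropped and symmetric duplicates merged keeping
    the maximum score; the number of dropped self-pairs is recorded in
    ``result.attrs["n_self_pairs"]``.
    """
    delimiter = delimiter or _sniff_delimiter(path)
    raw = pd.read_csv(path, sep=delimiter)
    try:
        if all(isinstance(c, int) for c in columns):
            sub = raw.iloc[:, list(columns)].copy()
        else:
            sub = raw.loc[:, list(columns)].copy()
    except (KeyError, IndexError) as exc:
        raise ValueError(f"{path}: missing edge columns {columns}") from exc
    sub.columns = ["protein_a", "protein_b", "score"]
    sub["protein_a"] = sub["protein_a"].astype(str)
    sub["protein_b"] = sub["protein_b"].astype(str)
    score = pd.to_numeric(sub["score"], errors="coerce")
    if score.isna().any():
        # +2: header line plus 1-based numbering
        line = int(np.nonzero(score.isna().to_numpy())[0][0]) + 2
        raise ValueError(f"{path}: malformed score on line {line}")
    sub["score"] = score.astype(float)

    self_mask = sub["protein_a"] == sub["protein_b"]
    n_self = int(self_mask.sum())
    sub = sub.loc[~self_mask]
    pairs = [
        tuple(sorted(ab)) for ab in zip(sub["protein_a"], sub["protein_b"])
    ]
    canon = pd.DataFrame(
        {
            "protein_a": [a for a, _ in pairs],
            "protein_b": [b for _, b in pairs],
            "score": sub["score"].to_numpy(),
        }
    )
    merged = (
        canon.groupby(["protein_a", "protein_b"], as_index=False)["score"]
        .max()
        .sort_values(["protein_a", "protein_b"], ignore_index=True)
    )
    merged.attrs["n_self_pairs"] = n_self
    return merged


def normalize_by_mw(spc: pd.DataFrame, mw: pd.Series) -> pd.DataFrame:
    """Divide each protein's counts by its molecular weight.

    This is the only transformation applied to the counts; zeros are kept and
    handled by :func:`filter_shared_proteins` downstream.
    """
    missing = spc.index.difference(mw.index).tolist()
    if missing:
        raise ValueError(f"proteins missing from the molecular-weight table: {missing}")
    return spc.div(mw.reindex(spc.index), axis=0)


def filter_shared_proteins(weights: pd.DataFrame) -> tuple[pd.DataFrame, list[str]]:
    """Keep only proteins quantified in every sample (all values > 0).

    A single zero anywhere removes the protein: the retained set is shared
    across all samples, so every per-sample network is built on one common
    master network.  Returns ``(kept, removed_ids)``; row order is preserved.
    """
    mask = (weights > 0).all(axis=1)
    kept = weights.loc[mask]
    removed = weights.index[~mask].tolist()
    if kept.empty:
        raise ValueError("no shared proteins: every protein has a zero in some sample")
    return kept, removed


def write_sif(graph: nx.Graph, path: str | Path, interaction: str = "pp") -> None:
    """Write a network in Cytoscape's simple interaction format."""
    with open(path, "w") as fh:
        isolated = [n for n in graph.nodes if graph.degree(n) == 0]
        for u, v in sorted(tuple(sorted((str(a), str(b)))) for a, b in graph.edges):
            fh.write(f"{u}\t{interaction}\t{v}\n")
        for n in sorted(str(n) for n in isolated):
            fh.write(f"{n}\n")


def write_outputs(
    out_dir: str | Path,
    tables: Mapping[str, pd.DataFrame] | None = None,
    graphs: Mapping[str, nx.Graph] | None = None,
    formats: tuple[str, ...] = ("csv", "graphml", "sif"),
    extra: Mapping[str, object] | None = None,
) -> dict:
    """Write result tables (CSV) and networks (GraphML and/or SIF).

    Returns the manifest — a dict listing every written file with its row or
    node/edge counts — and saves it as ``manifest.json`` in ``out_dir``.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"files": {}, **(dict(extra) if extra else {})}
    for name, table in (tables or {}).items():
        fname = f"{name}.csv"
        table.to_csv(out / fname)
        manifest["files"][fname] = {"kind": "table", "rows": int(table.shape[0])}
    for name, graph in (graphs or {}).items():
        entry = {
            "kind": "network",
            "nodes": graph.number_of_nodes(),
            "edges": graph.number_of_edges(),
        }
        if "graphml" in formats:
            exportable = graph.copy()
            # GraphML holds only scalar attributes; flatten provenance lists
            for key, value in list(exportable.graph.items()):
                if isinstance(value, (list, tuple, set, frozenset)):
                    exportable.graph[key] = ",".join(map(str, value))
            nx.write_graphml(exportable, out / f"{name}.graphml")
            manifest["files"][f"{name}.graphml"] = entry
        if "sif" in formats:
            write_sif(graph, out / f"{name}.sif")
            manifest["files"][f"{name}.sif"] = entry
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest
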