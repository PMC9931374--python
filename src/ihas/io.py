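"""Readers and writers for the pipeline's delimited-text formats.

All matrices are TSV with the feature id in the first column and sample ids
in the header.  Survival tables have columns ``sample, time_days, event``;
clinical tables are long-format ``sample, feature, value``; networks are
directed two-column edge lists ``source, target``; gene sets use GMT.
"""

from __future__ import annotations

import json
from pathlib import Path

import networkx as nx
import pandas as pd


def write_matrix(df: pd.DataFrame, path: str | Path, index_label: str = "feature") -> None:
    df.to_csv(path, sep="\t", index_label=index_label, float_format="%.10g")


def read_matrix(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=0)


def write_survival(df: pd.DataFrame, path: str | Path) -> None:
    df.loc[:, ["sample", "time_days", "event"]].to_csv(path, sep="\t", index=False)


def read_survival(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"sample": str})
    df["event"] = df["event"].astype(int)
    return df


def write_clinical(df: pd.DataFrame, path: str | Path) -> None:
    df.loc[:, ["sample", "feature", "value"]].to_csv(path, sep="\t", index=False)


def read_clinical(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", dtype=str)


def write_network(graph: nx.DiGraph, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("source\ttarget\n")
        for u, v in graph.edges():
            fh.write(f"{u}\t{v}\n")


def read_network(path: str | Path) -> nx.DiGraph:
    df = pd.read_csv(path, sep="\t", dtype=str)
    graph = nx.DiGraph()
    graph.add_edges_from(df.itertuples(index=False, name=None))
    return graph


def _jsonable(o):
    if hasattr(o, "item"):  # numpy scalars
        return o.item()
    if isinstance(o, set):
        return sorted(o)
    raise TypeError(f"not JSON serializable: {type(o)}")


def write_json(obj, path: str | Path) -> None:
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True, default=_jsonable)


def read_json(path: str | Path):
    with open(path) as fh:
        return json.load(fh)


def read_gmt(path: str | Path) -> dict[str, set[str]]:
    """Read a GMT gene-set file: ``name <tab> description <tab> genes...``."""
    sets: dict[str, set[str]] = {}
    with open(path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) >= 3 and parts[0]:
                sets[parts[0]] = set(g for g in parts[2:] if g)
    return sets


def write_gmt(sets: dict[str, set[str]], path: str | Path) -> None:
    with open(path, "w") as fh:
        for name, genes in sets.items():
            fh.write("\t".join([name, name] + sorted(genes)) + "\n")


def write_jsonl(records: list[dict], path: str | Path) -> None:
    with open(path, "w") as fh:
        for rec in records:
            fh.write(json.dumps(rec, sort_keys=True) + "\n")


def read_jsonl(path: str | Path) -> list[dict]:
    with open(path) as fh:
        return [json.loads(line) for line in fh if line.strip()]
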