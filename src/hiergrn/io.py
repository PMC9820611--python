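"""File dialects: expression TSV, gene lists, network exports, summaries.

All tabular files are tab-separated UTF-8 without quoting; every writer
iterates in sorted order so outputs are deterministic for a given input.
"""

from __future__ import annotations

import json
from typing import Iterable

import pandas as pd

from .expression import ExpressionMatrix
from .grn import HierarchicalGRN
from .validation import ValidationRecord

__all__ = [
    "read_expression_tsv",
    "write_expression_tsv",
    "read_gene_list",
    "read_deg_table",
    "write_deg_table",
    "write_network",
    "read_network_graphml",
    "read_validation_records",
    "write_json",
]

NETWORK_FORMATS = ("sif", "graphml", "tsv")


def read_expression_tsv(path) -> ExpressionMatrix:
    """Read the gene x sample TSV dialect (header of ``t<hours>h_r<rep>`` IDs)."""
    return ExpressionMatrix.from_tsv(path)


def write_expression_tsv(matrix: ExpressionMatrix, path) -> None:
    matrix.to_tsv(path)


def read_gene_list(path) -> list[str]:
    """One gene ID per line; blank lines and #-comments ignored."""
    out = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if line and not line.startswith("#"):
                out.append(line)
    if not out:
        raise ValueError(f"{path}: empty gene list")
    return out


def read_deg_table(path) -> pd.DataFrame:
    table = pd.read_csv(path, sep="\t")
    required = {"gene_id", "time_point", "fold_change", "fdr", "is_deg"}
    missing = required - set(table.columns)
    if missing:
        raise ValueError(f"{path}: DEG table missing columns {sorted(missing)}")
    table["is_deg"] = table["is_deg"].astype(bool)
    return table


def write_deg_table(table: pd.DataFrame, path) -> None:
    table.to_csv(path, sep="\t", index=False)


def _sorted_edges(grn: HierarchicalGRN):
    return sorted(grn.edges, key=lambda e: (e.source, e.target))


def write_network(grn: HierarchicalGRN, fmt: str, path) -> None:
    """Write the network as SIF, GraphML (layer/edge attributes) or provenance TSV."""
    if fmt not in NETWORK_FORMATS:
        raise ValueError(f"unknown network format {fmt!r}; options: {NETWORK_FORMATS}")
    if fmt == "sif":
        with open(path, "w") as fh:
            for e in _sorted_edges(grn):
                fh.write(f"{e.source}\tregulates\t{e.target}\n")
    elif fmt == "graphml":
        import networkx as nx

        nx.write_graphml(grn.to_networkx(), path)
    else:
        with open(path, "w") as fh:
            fh.write("source\ttarget\tlayer_pair\tr_xy\tpartial_r\tn_triples\n")
            for e in _sorted_edges(grn):
                fh.write(
                    f"{e.source}\t{e.target}\t{e.layer_pair}\t"
                    f"{e.best_r_xy!r}\t{e.best_partial!r}\t{len(e.triples)}\n"
                )


def read_network_graphml(path):
    """Round-trip reader for the GraphML export (returns a networkx DiGraph)."""
    import networkx as nx

    return nx.read_graphml(path)


def read_validation_records(path) -> list[ValidationRecord]:
    """Validation TSV: tf, target, layer_pair, frag1..frag4, qrt_fc, qrt_p.

    Missing qRT values are written as ``NA``.
    """
    records = []
    truthy = {"1", "true", "t", "yes"}
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        expected = ["tf", "target", "layer_pair", "frag1", "frag2", "frag3",
                    "frag4", "qrt_fc", "qrt_p"]
        if header != expected:
            raise ValueError(f"{path}: expected header {expected}, got {header}")
        for lineno, line in enumerate(fh, start=2):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) != 9:
                raise ValueError(f"{path}: line {lineno}: expected 9 columns")
            frags = tuple(p.strip().lower() in truthy for p in parts[3:7])
            fc = None if parts[7] in ("", "NA") else float(parts[7])
            p = None if parts[8] in ("", "NA") else float(parts[8])
            records.append(ValidationRecord(
                tf_id=parts[0], target_id=parts[1], layer_pair=parts[2],
                chip_fragments=frags, qrt_fold_change=fc, qrt_p=p,
            ))
    if not records:
        raise ValueError(f"{path}: no validation records")
    return records


def write_json(obj, path) -> None:
    """Deterministic JSON (sorted keys, fixed separators, trailing newline)."""
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True)
        fh.write("\n")
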