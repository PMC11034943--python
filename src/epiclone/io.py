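"""Readers and writers for the plain-text formats the pipeline exchanges.

All genomic coordinates are 0-based half-open (BED convention). Count
matrices travel as MatrixMarket ``.mtx`` files with ``features.tsv`` /
``barcodes.tsv`` index files alongside, mirroring the 10x convention.
"""

from __future__ import annotations

import json
import os
from typing import Mapping

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp

FRAGMENT_COLUMNS = ["chrom", "start", "end", "barcode", "count"]
BED_COLUMNS = ["chrom", "start", "end", "name", "score"]


def read_fragments(path: str) -> pd.DataFrame:
    """Read a 10x-style 5-column fragments file (chrom, start, end, barcode, count)."""
    df = pd.read_csv(
        path, sep="\t", comment="#", header=None, names=FRAGMENT_COLUMNS,
        dtype={"chrom": str, "start": np.int64, "end": np.int64,
               "barcode": str, "count": np.int64},
    )
    bad = df.index[(df["start"] < 0) | (df["end"] <= df["start"])]
    if len(bad):
        raise ValueError(f"malformed fragment record at line {bad[0] + 1}")
    return df


def write_fragments(df: pd.DataFrame, path: str) -> None:
    df[FRAGMENT_COLUMNS].to_csv(path, sep="\t", header=False, index=False)


def read_bed(path: str) -> pd.DataFrame:
    """Read BED3+ intervals; extra columns are kept as name/score when present."""
    df = pd.read_csv(path, sep="\t", comment="#", header=None)
    df.columns = BED_COLUMNS[: df.shape[1]] + list(df.columns[len(BED_COLUMNS):])
    return df


def write_bed(df: pd.DataFrame, path: str) -> None:
    cols = [c for c in BED_COLUMNS if c in df.columns]
    df[cols].to_csv(path, sep="\t", header=False, index=False)


def read_gmt(path: str) -> dict[str, list[str]]:
    """Read gene sets from GMT (name, description, genes...)."""
    sets: dict[str, list[str]] = {}
    with open(path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 3 or not parts[0]:
                continue
            sets[parts[0]] = [g for g in parts[2:] if g]
    return sets


def write_gmt(gene_sets: Mapping[str, list[str]], path: str) -> None:
    with open(path, "w") as fh:
        for name, genes in gene_sets.items():
            fh.write("\t".join([name, "na", *genes]) + "\n")


def read_count_matrix(directory: str, prefix: str = "") -> pd.DataFrame:
    """Read an MTX triplet (matrix.mtx + features.tsv + barcodes.tsv) as a
    dense features x samples DataFrame."""
    mat = scipy.io.mmread(os.path.join(directory, prefix + "matrix.mtx"))
    features = pd.read_csv(
        os.path.join(directory, prefix + "features.tsv"), sep="\t", header=None
    )[0].astype(str)
    barcodes = pd.read_csv(
        os.path.join(directory, prefix + "barcodes.tsv"), sep="\t", header=None
    )[0].astype(str)
    dense = np.asarray(sp.coo_matrix(mat).todense())
    return pd.DataFrame(dense, index=features, columns=barcodes)


def write_count_matrix(counts: pd.DataFrame, directory: str, prefix: str = "") -> None:
    os.makedirs(directory, exist_ok=True)
    mat = sp.coo_matrix(np.asarray(counts.values))
    scipy.io.mmwrite(os.path.join(directory, prefix + "matrix.mtx"), mat)
    pd.Series(counts.index).to_csv(
        os.path.join(directory, prefix + "features.tsv"),
        sep="\t", header=False, index=False)
    pd.Series(counts.columns).to_csv(
        os.path.join(directory, prefix + "barcodes.tsv"),
        sep="\t", header=False, index=False)


def write_manifest(entries: Mapping[str, int], path: str) -> None:
    """Write a {filename: row count} manifest as JSON."""
    with open(path, "w") as fh:
        json.dump(dict(entries), fh, indent=2, sort_keys=True)
        fh.write("\n")


def read_manifest(path: str) -> dict[str, int]:
    with open(path) as fh:
        return json.load(fh)
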