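"""TSV / FASTA / GMT readers and writers for the pipeline's on-disk formats.

All tabular formats are plain TSV.  Expression: feature ids in the first
column, sample ids in the header.  Labels: two columns (sample, condition)
with an optional third (matched normal sample id).  Clinical: the fixed
schema ``sample os_time os_event rfs_time rfs_event age gender stage adjc
adjc_type`` (rfs_* and adjc_type may be empty).  Edge lists: one edge per
row.  Floats are written with a fixed "%.10g" format so that rewriting the
same data is byte-identical.
"""

from __future__ import annotations

import json
from pathlib import Path

import pandas as pd

from .containers import ExpressionMatrix, RawExpressionTable, ReferenceGRN

FLOAT_FMT = "%.10g"

CLINICAL_COLUMNS = [
    "sample", "os_time", "os_event", "rfs_time", "rfs_event",
    "age", "gender", "stage", "adjc", "adjc_type",
]


def read_expression_tsv(path: str | Path, platform: str = "rnaseq_tpm") -> RawExpressionTable:
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index = df.index.astype(str)
    return RawExpressionTable(df.astype(float), platform=platform)


def write_expression_tsv(values: pd.DataFrame, path: str | Path) -> None:
    values.to_csv(path, sep="\t", float_format=FLOAT_FMT, index_label="gene")


def read_labels_tsv(path: str | Path) -> tuple[pd.Series, dict[str, str] | None]:
    """Return (condition series indexed by sample, pairing or None)."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    if df.shape[1] < 2:
        raise ValueError("labels TSV needs at least (sample, condition) columns")
    cond = pd.Series(df.iloc[:, 1].values, index=df.iloc[:, 0].values)
    pairing = None
    if df.shape[1] >= 3:
        third = df.iloc[:, 2]
        pairs = {s: m for s, m in zip(df.iloc[:, 0], third) if isinstance(m, str) and m}
        pairing = pairs or None
    return cond, pairing


def write_labels_tsv(condition: pd.Series, path: str | Path,
                     pairing: dict[str, str] | None = None) -> None:
    df = pd.DataFrame({"sample": condition.index, "condition": condition.values})
    if pairing is not None:
        df["matched_normal"] = [pairing.get(s, "") for s in condition.index]
    df.to_csv(path, sep="\t", index=False)


def read_expression_matrix(expr_path: str | Path, labels_path: str | Path) -> ExpressionMatrix:
    df = pd.read_csv(expr_path, sep="\t", index_col=0)
    df.index = df.index.astype(str)
    cond, pairing = read_labels_tsv(labels_path)
    return ExpressionMatrix(df.astype(float), cond, pairing)


def read_clinical_tsv(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    if "sample" not in df.columns:
        raise ValueError("clinical TSV needs a 'sample' column")
    return df.set_index("sample")


def write_clinical_tsv(df: pd.DataFrame, path: str | Path) -> None:
    out = df.reset_index() if df.index.name == "sample" else df
    out.to_csv(path, sep="\t", index=False, float_format=FLOAT_FMT)


def read_edges_tsv(path: str | Path) -> ReferenceGRN:
    df = pd.read_csv(path, sep="\t")
    if not {"tf", "target"}.issubset(df.columns):
        raise ValueError("edge TSV needs 'tf' and 'target' columns")
    for col, default in (("score", 0.0), ("p_promoter", 1.0)):
        if col not in df.columns:
            df[col] = default
    return ReferenceGRN(df[["tf", "target", "score", "p_promoter"]])


def write_edges_tsv(grn: ReferenceGRN, path: str | Path) -> None:
    grn.edges.to_csv(path, sep="\t", index=False, float_format=FLOAT_FMT)


def read_fasta(path: str | Path) -> dict[str, str]:
    """Promoter FASTA: header token = gene symbol, sequence uppercased."""
    seqs: dict[str, str] = {}
    name = None
    chunks: list[str] = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            if line.startswith(">"):
                if name is not None:
                    seqs[name] = "".join(chunks).upper()
                name = line[1:].split()[0]
                chunks = []
            else:
                chunks.append(line)
    if name is not None:
        seqs[name] = "".join(chunks).upper()
    return seqs


def read_probe_map(path: str | Path) -> dict[str, set[str]]:
    """Two-column TSV: probe, comma-separated gene symbols."""
    out: dict[str, set[str]] = {}
    df = pd.read_csv(path, sep="\t", dtype=str)
    for probe, genes in zip(df.iloc[:, 0], df.iloc[:, 1]):
        gene_set = {g for g in str(genes).split(",") if g and g != "nan"}
        if not gene_set:
            raise ValueError(f"probe {probe} maps to no genes")
        out[str(probe)] = gene_set
    if not out:
        raise ValueError("empty probe map")
    return out


def read_gmt(path: str | Path) -> dict[str, set[str]]:
    """GMT gene sets: name, description, genes..."""
    sets: dict[str, set[str]] = {}
    with open(path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) >= 3:
                sets[parts[0]] = {g for g in parts[2:] if g}
    return sets


def write_json(obj, path: str | Path) -> None:
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True)
        fh.write("\n")
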