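"""Readers and writers for every on-disk format the pipeline consumes.

Rank lists and annotation tables are plain TSV; the expression matrix uses
the CellRanger-style MatrixMarket bundle (genes x cells triplets with
feature and barcode sidecars) plus a labels CSV; assay and competition
tables are CSV.  All readers validate schemas and reject malformed rows
with the offending record named.
"""

from __future__ import annotations

import json
from pathlib import Path

import pandas as pd
import scipy.io as sio
import scipy.sparse as sp

from .gotit import FALSE, TRUE, UNKNOWN
from .markers import ExpressionMatrix
from .rankprod import ScoredGeneList
from .valstats import CompetitionCounts

__all__ = [
    "read_rank_list",
    "write_rank_list",
    "read_annotations",
    "write_annotations",
    "read_expression_bundle",
    "write_expression_bundle",
    "read_assay_table",
    "read_competition_table",
    "write_truth",
]

_FLAGS = {TRUE, FALSE, UNKNOWN}
_ANNOTATION_COLUMNS = [
    "gene_id",
    "pub_count_angiogenesis",
    "pub_count_tip",
    "previously_described_tip",
    "secreted",
    "disease_link",
    "disease_note",
    "perturbagen_available",
]


def read_rank_list(path: str | Path, pre_ranked: bool = False) -> ScoredGeneList:
    """One dataset's marker list from TSV (gene_id, score) or (gene_id, rank).

    Pre-ranked input is converted to scores by negation so that rank 1
    becomes the top score.
    """
    path = Path(path)
    df = pd.read_csv(path, sep="\t")
    value_col = "rank" if pre_ranked else "score"
    for col in ("gene_id", value_col):
        if col not in df.columns:
            raise ValueError(f"{path.name}: missing required column {col!r}")
    bad = df.index[pd.to_numeric(df[value_col], errors="coerce").isna()]
    if len(bad):
        raise ValueError(f"{path.name}: non-numeric {value_col} at row {int(bad[0]) + 2}")
    scores = df[value_col].to_numpy(dtype=float)
    if pre_ranked:
        scores = -scores
    return ScoredGeneList(dataset_id=path.stem, genes=list(df["gene_id"]), scores=scores)


def write_rank_list(gene_list: ScoredGeneList, path: str | Path) -> None:
    pd.DataFrame({"gene_id": gene_list.genes, "score": gene_list.scores}).to_csv(
        path, sep="\t", index=False
    )


def read_annotations(path: str | Path) -> pd.DataFrame:
    """Annotation TSV with three-valued flags; unknown never collapses to false."""
    path = Path(path)
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    for col in _ANNOTATION_COLUMNS:
        if col not in df.columns:
            raise ValueError(f"{path.name}: missing required column {col!r}")
    for col in ("pub_count_angiogenesis", "pub_count_tip"):
        nums = pd.to_numeric(df[col], errors="coerce")
        bad = df.index[nums.isna()]
        if len(bad):
            raise ValueError(f"{path.name}: non-numeric {col} at row {int(bad[0]) + 2}")
        df[col] = nums.astype(int)
    for col in ("previously_described_tip", "secreted", "disease_link"):
        vals = df[col].str.lower()
        bad = df.index[~vals.isin(_FLAGS)]
        if len(bad):
            raise ValueError(
                f"{path.name}: {col}={df.loc[bad[0], col]!r} at row {int(bad[0]) + 2} "
                "is not true/false/unknown"
            )
        df[col] = vals
    df["perturbagen_available"] = df["perturbagen_available"].str.lower().map(
        {"true": True, "false": False}
    )
    if df["perturbagen_available"].isna().any():
        bad = df.index[df["perturbagen_available"].isna()][0]
        raise ValueError(f"{path.name}: perturbagen_available must be true/false at row {int(bad) + 2}")
    if df["gene_id"].duplicated().any():
        dup = df.loc[df["gene_id"].duplicated(), "gene_id"].iloc[0]
        raise ValueError(f"{path.name}: duplicate gene_id {dup!r}")
    return df.set_index("gene_id", drop=False)


def write_annotations(annotations: pd.DataFrame, path: str | Path) -> None:
    out = annotations.reset_index(drop=True)[_ANNOTATION_COLUMNS].copy()
    out["perturbagen_available"] = out["perturbagen_available"].map(
        {True: "true", False: "false"}
    )
    out.to_csv(path, sep="\t", index=False)


def read_expression_bundle(
    mtx_path: str | Path,
    features_path: str | Path,
    barcodes_path: str | Path,
    labels_path: str | Path,
) -> ExpressionMatrix:
    """MatrixMarket triplets + sidecars + labels CSV -> validated ExpressionMatrix.

    On-disk orientation (genes x cells or cells x genes) is auto-detected
    from the sidecar lengths; internally the matrix is always cells x genes.
    """
    mtx = sp.csr_matrix(sio.mmread(mtx_path))
    features = pd.read_csv(features_path, sep="\t", header=None)[0].astype(str).tolist()
    barcodes = pd.read_csv(barcodes_path, sep="\t", header=None)[0].astype(str).tolist()

    if mtx.shape == (len(features), len(barcodes)):
        mtx = sp.csr_matrix(mtx.T)
    elif mtx.shape != (len(barcodes), len(features)):
        raise ValueError(
            f"matrix shape {mtx.shape} matches neither genes x cells "
            f"({len(features)}, {len(barcodes)}) nor cells x genes"
        )

    labels = pd.read_csv(labels_path)
    if "barcode" not in labels.columns or "cluster" not in labels.columns:
        raise ValueError(f"{Path(labels_path).name}: need columns barcode,cluster[,condition]")
    if labels["barcode"].duplicated().any():
        dup = labels.loc[labels["barcode"].duplicated(), "barcode"].iloc[0]
        raise ValueError(f"duplicate barcode {dup!r} in labels")
    labels = labels.set_index("barcode")
    missing = [b for b in barcodes if b not in labels.index]
    if missing:
        raise ValueError(f"barcode {missing[0]!r} present in matrix but absent from labels")

    conditions = None
    if "condition" in labels.columns:
        conditions = labels["condition"].astype(str)
    return ExpressionMatrix(
        counts=mtx,
        gene_ids=features,
        barcodes=barcodes,
        cell_labels=labels["cluster"].astype(str),
        conditions=conditions,
    )


def write_expression_bundle(matrix: ExpressionMatrix, out_dir: str | Path) -> dict[str, Path]:
    """Write the CellRanger-style bundle (genes x cells on disk) plus labels CSV."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = {
        "mtx": out_dir / "matrix.mtx",
        "features": out_dir / "features.tsv",
        "barcodes": out_dir / "barcodes.tsv",
        "labels": out_dir / "labels.csv",
    }
    sio.mmwrite(str(paths["mtx"]), sp.coo_matrix(matrix.counts.T), field="integer")
    pd.Series(matrix.gene_ids).to_csv(paths["features"], sep="\t", index=False, header=False)
    pd.Series(matrix.barcodes).to_csv(paths["barcodes"], sep="\t", index=False, header=False)
    labels = pd.DataFrame({"barcode": matrix.barcodes, "cluster": matrix.cell_labels.to_numpy()})
    if matrix.conditions is not None:
        labels["condition"] = matrix.conditions.to_numpy()
    labels.to_csv(paths["labels"], index=False)
    return paths


def read_assay_table(path: str | Path) -> pd.DataFrame:
    """Tidy assay CSV: columns group, replicate_id, value."""
    df = pd.read_csv(path)
    for col in ("group", "value"):
        if col not in df.columns:
            raise ValueError(f"{Path(path).name}: missing required column {col!r}")
    bad = df.index[pd.to_numeric(df["value"], errors="coerce").isna()]
    if len(bad):
        raise ValueError(f"{Path(path).name}: non-numeric value at row {int(bad[0]) + 2}")
    return df


def read_competition_table(path: str | Path, p0: float = 0.5) -> dict[str, CompetitionCounts]:
    """Competition CSV: columns condition, k_silenced_at_tip, n_tips_total."""
    df = pd.read_csv(path)
    for col in ("condition", "k_silenced_at_tip", "n_tips_total"):
        if col not in df.columns:
            raise ValueError(f"{Path(path).name}: missing required column {col!r}")
    return {
        str(r["condition"]): CompetitionCounts(
            int(r["k_silenced_at_tip"]), int(r["n_tips_total"]), p0=p0
        )
        for _, r in df.iterrows()
    }


def write_truth(truth: dict, path: str | Path) -> None:
    with open(path, "w") as fh:
        json.dump(truth, fh, indent=2, sort_keys=True)
        fh.write("\n")
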