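"""Cross-library comparison of ribonucleotide incorporation profiles.

Each library is summarized by eight features — percent rA/rC/rG/rU per
strand — z-scored per feature across libraries, then hierarchically
clustered (complete linkage, Euclidean).  This is the sample-profile
analysis that separates cell lines whose nucleotide pools favour different
ribonucleotides (e.g. raised rC versus raised rG incorporation).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist

from .quantify import BASES_RNA, QuantResult

__all__ = ["ProfileMatrix", "Dendrogram", "build_profiles", "zscore",
           "hcluster", "export_heatmap", "read_heatmap_tsv"]

COLUMNS = tuple(f"{strand}:{b}" for strand in ("H", "L") for b in BASES_RNA)


@dataclass
class ProfileMatrix:
    """Libraries × 8 features (strand H/L × base A/C/G/U).

    On the ``percent`` scale each row's four H-features sum to 100 and the
    four L-features sum to 100; on the ``zscore`` scale each non-constant
    column has mean 0 and sample standard deviation 1.
    """

    library_ids: list[str]
    values: np.ndarray  # shape (n_libraries, 8)
    scale: str = "percent"
    columns: tuple[str, ...] = COLUMNS

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.library_ids), len(self.columns)):
            raise ValueError("matrix shape does not match ids/columns")


@dataclass
class Dendrogram:
    """Agglomeration result: scipy-style merge list and the leaf order."""

    merges: np.ndarray  # scipy linkage matrix, shape (n-1, 4)
    leaf_order: list[int]
    linkage: str = "complete"
    library_ids: list[str] = field(default_factory=list)


def build_profiles(results: list[tuple[str, QuantResult]]) -> ProfileMatrix:
    """Percent-scale profile matrix from per-library quantification
    results (identity percentages per strand; cut-site reads were already
    excluded by the mask in digested libraries)."""
    if len(results) < 2:
        raise ValueError("need at least two libraries to build a profile matrix")
    ids, rows = [], []
    for lib_id, res in results:
        row = []
        for strand in ("H", "L"):
            if strand not in res.identity_percent:
                raise ValueError(f"{lib_id}: missing strand {strand}")
            row.extend(res.identity_percent[strand][b] for b in BASES_RNA)
        ids.append(lib_id)
        rows.append(row)
    return ProfileMatrix(library_ids=ids, values=np.array(rows), scale="percent")


def zscore(matrix: ProfileMatrix) -> ProfileMatrix:
    """Standardize each feature across libraries (sample sd, n-1).

    A constant feature carries no contrast; it is set to all zeros with a
    warning rather than producing NaNs.
    """
    if matrix.values.shape[0] < 2:
        raise ValueError("z-scoring needs at least two libraries")
    means = matrix.values.mean(axis=0)
    sds = matrix.values.std(axis=0, ddof=1)
    z = np.zeros_like(matrix.values)
    for j in range(matrix.values.shape[1]):
        if sds[j] == 0:
            warnings.warn(
                f"feature {matrix.columns[j]} is constant across libraries; "
                "z-scores set to 0"
            )
        else:
            z[:, j] = (matrix.values[:, j] - means[j]) / sds[j]
    return ProfileMatrix(
        library_ids=list(matrix.library_ids), values=z, scale="zscore",
        columns=matrix.columns,
    )


def hcluster(matrix: ProfileMatrix, linkage: str = "complete") -> Dendrogram:
    """Agglomerative clustering of library rows (Euclidean distance).

    Returns the merge list (scipy linkage format: row i merges clusters
    Z[i,0] and Z[i,1] at height Z[i,2]) and the dendrogram leaf order.
    scipy breaks distance ties deterministically by cluster index.
    """
    if linkage not in ("complete", "average", "single"):
        raise ValueError(f"unsupported linkage {linkage!r}")
    if matrix.values.shape[0] < 2:
        raise ValueError("clustering needs at least two libraries")
    if np.isnan(matrix.values).any():
        raise ValueError("matrix contains NaN")
    Z = hierarchy.linkage(matrix.values, method=linkage, metric="euclidean")
    order = hierarchy.leaves_list(Z).tolist()
    return Dendrogram(
        merges=Z, leaf_order=order, linkage=linkage,
        library_ids=list(matrix.library_ids),
    )


def cophenetic_siblings(dendro: Dendrogram, i: int, j: int) -> bool:
    """True if leaves i and j merge with each other before either merges
    with anything else (sibling leaves)."""
    n = len(dendro.library_ids)
    for a, b, _h, _c in dendro.merges:
        a, b = int(a), int(b)
        if {a, b} == {i, j}:
            return True
        if a in (i, j) or b in (i, j):
            return False
    return False


def export_heatmap(
    matrix: ProfileMatrix,
    dendro: Dendrogram,
    path: str | Path,
    figure_path: str | Path | None = None,
) -> None:
    """Heatmap-ready TSV with rows in dendrogram leaf order; optionally a
    simple matplotlib rendering."""
    if len(dendro.leaf_order) != matrix.values.shape[0]:
        raise ValueError("dendrogram and matrix dimensions disagree")
    with open(path, "w") as fh:
        fh.write("library\t" + "\t".join(matrix.columns) + "\n")
        for i in dendro.leaf_order:
            vals = "\t".join(f"{v:.10g}" for v in matrix.values[i])
            fh.write(f"{matrix.library_ids[i]}\t{vals}\n")
    if figure_path is not None:
        import matplotlib
        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        ordered = matrix.values[dendro.leaf_order]
        fig, ax = plt.subplots(figsize=(6, 0.5 * len(dendro.leaf_order) + 2))
        im = ax.imshow(ordered, aspect="auto", cmap="RdBu_r")
        ax.set_xticks(range(len(matrix.columns)), matrix.columns, rotation=90)
        ax.set_yticks(
            range(len(dendro.leaf_order)),
            [matrix.library_ids[i] for i in dendro.leaf_order],
        )
        fig.colorbar(im, ax=ax, label=matrix.scale)
        fig.tight_layout()
        fig.savefig(figure_path, dpi=150)
        plt.close(fig)


def read_heatmap_tsv(path: str | Path) -> ProfileMatrix:
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        columns = tuple(header[1:])
        ids, rows = [], []
        for line in fh:
            fields = line.rstrip("\n").split("\t")
            ids.append(fields[0])
            rows.append([float(v) for v in fields[1:]])
    return ProfileMatrix(
        library_ids=ids, values=np.array(rows), scale="unknown", columns=columns
    )
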