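"""Expression normalisation, variable-gene selection, clustering and PCA.

The counts matrix is genes x samples (nonnegative integers).  Counts are
normalised with median-of-ratios size factors followed by a log2(x + 1)
transform — a variance-stabilising surrogate adequate for the downstream
distance computations.  Variable genes are selected with a data-driven knee
rule on the per-gene interquartile range (IQR): genes are sorted by
ascending IQR and the knee is the point of the curve farthest from the
chord joining its first and last points; genes above the knee's IQR are
retained.  Samples are then clustered hierarchically on 1 − Pearson
correlation with Ward linkage, and projected by PCA on the most variable
genes.

``pt_rd_copair_rate`` quantifies whether each post-treatment sample sits
closest to its own pre-treatment tumor rather than to the contralateral
tumor — the expression-level fingerprint of tumor identity.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform


def normalize_counts(matrix: pd.DataFrame) -> pd.DataFrame:
    """Median-of-ratios normalisation followed by log2(x + 1).

    Size factors are the per-sample median ratio to the geometric-mean
    reference over genes expressed in every sample; when no such gene
    exists the total-count ratio is used instead (with a warning).  The
    transform is invariant (to numerical precision) to scaling any sample's
    counts by a positive constant.
    """
    if matrix.shape[1] < 2:
        raise ValueError("at least two samples are required")
    counts = matrix.to_numpy(dtype=float)
    if (counts < 0).any():
        raise ValueError("counts must be nonnegative")
    totals = counts.sum(axis=0)
    if (totals <= 0).any():
        raise ValueError("every sample must have positive total counts")

    everywhere = (counts > 0).all(axis=1)
    if everywhere.any():
        log_ref = np.log(counts[everywhere]).mean(axis=1)
        ratios = np.log(counts[everywhere]) - log_ref[:, None]
        size_factors = np.exp(np.median(ratios, axis=0))
    else:
        warnings.warn(
            "no gene is expressed in all samples; falling back to total-count size factors",
            stacklevel=2,
        )
        size_factors = totals / np.exp(np.mean(np.log(totals)))
    normed = np.log2(counts / size_factors[None, :] + 1.0)
    return pd.DataFrame(normed, index=matrix.index, columns=matrix.columns)


@dataclass
class GeneSelection:
    """Result of the IQR knee rule: the sorted curve, knee and gene set."""

    iqr: pd.Series  # per-gene IQR, ascending
    knee_index: int
    threshold: float
    selected: list[str]


def _chord_distances(y: np.ndarray) -> np.ndarray:
    """Perpendicular distance of each point (i, y_i) to the first-last chord."""
    n = len(y)
    x = np.arange(n, dtype=float)
    x0, y0 = x[0], y[0]
    dx, dy = x[-1] - x0, y[-1] - y0
    norm = np.hypot(dx, dy)
    if norm == 0:
        return np.zeros(n)
    return np.abs(dy * (x - x0) - dx * (y - y0)) / norm


def iqr_knee_select(matrix: pd.DataFrame) -> GeneSelection:
    """Select variable genes by the knee of the ascending IQR curve.

    Computes each gene's IQR across samples (on the normalised matrix),
    sorts ascending, finds the point farthest from the line between the
    first and last point of the curve (first index on ties — deterministic
    and conservative, keeping more genes) and selects the genes whose IQR is
    strictly greater than the IQR at the knee.
    """
    values = matrix.to_numpy(dtype=float)
    iqr = np.percentile(values, 75, axis=1) - np.percentile(values, 25, axis=1)
    series = pd.Series(iqr, index=matrix.index, name="iqr").sort_values(kind="stable")
    y = series.to_numpy()
    if len(np.unique(y)) < 3:
        raise ValueError(
            "fewer than 3 distinct IQR values: knee undefined; consider a fixed-count selection"
        )
    if y[0] == y[-1]:
        raise ValueError("degenerate IQR curve (all equal); knee undefined")
    dist = _chord_distances(y)
    knee = int(np.argmax(dist))
    threshold = float(y[knee])
    selected = series.index[series.to_numpy() > threshold].tolist()
    return GeneSelection(iqr=series, knee_index=knee, threshold=threshold, selected=selected)


def correlation_distance_matrix(matrix: pd.DataFrame, genes: list[str] | None = None) -> pd.DataFrame:
    """Sample-sample distance 1 − Pearson r over the given genes."""
    sub = matrix.loc[genes] if genes is not None else matrix
    arr = sub.to_numpy(dtype=float)
    sd = arr.std(axis=0)
    flat = np.where(sd == 0)[0]
    if len(flat):
        raise ValueError(f"zero-variance sample(s): {list(sub.columns[flat])}")
    corr = np.corrcoef(arr.T)
    dist = 1.0 - corr
    np.fill_diagonal(dist, 0.0)
    dist = np.maximum((dist + dist.T) / 2.0, 0.0)
    return pd.DataFrame(dist, index=sub.columns, columns=sub.columns)


@dataclass
class SampleClustering:
    """Hierarchical clustering of samples on correlation distance."""

    linkage: np.ndarray
    distance: pd.DataFrame
    labels: list[str]

    def cut(self, k: int) -> pd.Series:
        flat = hierarchy.fcluster(self.linkage, k, criterion="maxclust")
        return pd.Series(flat, index=self.labels, name="cluster")


def hcluster_samples(matrix: pd.DataFrame, genes: list[str] | None = None) -> SampleClustering:
    """Ward-linkage hierarchical clustering on 1 − Pearson distance.

    Samples are ordered by label before clustering so the merge order is
    deterministic under ties.  Ward linkage on a correlation distance does
    not satisfy Ward's Euclidean assumption; it is used here as the
    conventional pairing for expression profiles.
    """
    if matrix.shape[1] < 2:
        raise ValueError("at least two samples are required")
    ordered = matrix[sorted(matrix.columns)]
    dist = correlation_distance_matrix(ordered, genes)
    condensed = squareform(dist.to_numpy(), checks=False)
    link = hierarchy.linkage(condensed, method="ward")
    return SampleClustering(linkage=link, distance=dist, labels=list(dist.columns))


@dataclass
class PcaResult:
    scores: pd.DataFrame
    variance_explained: np.ndarray
    genes_used: list[str]


def pca_scores(matrix: pd.DataFrame, n_genes: int = 3000) -> PcaResult:
    """PCA of samples on the most variable genes.

    Genes are ranked by IQR and the top ``n_genes`` kept (all genes, with a
    warning, when fewer are available); rows are gene-centred and the
    samples projected onto the principal axes via SVD.  Variance explained
    per component is reported as a fraction of total variance.
    """
    if matrix.shape[1] < 2:
        raise ValueError("PCA requires at least two samples")
    values = matrix.to_numpy(dtype=float)
    iqr = np.percentile(values, 75, axis=1) - np.percentile(values, 25, axis=1)
    if n_genes < len(matrix):
        order = np.argsort(-iqr, kind="stable")[:n_genes]
    else:
        if n_genes > len(matrix):
            warnings.warn(
                f"requested {n_genes} genes but only {len(matrix)} available; using all",
                stacklevel=2,
            )
        order = np.arange(len(matrix))
    genes_used = matrix.index[np.sort(order)].tolist()
    sub = values[np.sort(order)]
    centered = sub - sub.mean(axis=1, keepdims=True)
    # samples as observations: SVD of the samples x genes matrix
    u, s, _ = np.linalg.svd(centered.T, full_matrices=False)
    n_comp = min(centered.shape[1] - 1, centered.shape[0])
    n_comp = max(n_comp, 1)
    scores = u[:, :n_comp] * s[:n_comp]
    # deterministic sign: largest-magnitude loading of each component positive
    for j in range(scores.shape[1]):
        k = np.argmax(np.abs(scores[:, j]))
        if scores[k, j] < 0:
            scores[:, j] = -scores[:, j]
    total = (s**2).sum()
    var_exp = (s[:n_comp] ** 2) / total if total > 0 else np.zeros(n_comp)
    frame = pd.DataFrame(
        scores,
        index=matrix.columns,
        columns=[f"PC{i + 1}" for i in range(scores.shape[1])],
    )
    return PcaResult(scores=frame, variance_explained=var_exp, genes_used=genes_used)


def pt_rd_copair_rate(
    distance: pd.DataFrame,
    sample_meta: pd.DataFrame,
) -> tuple[float, float]:
    """Fraction of RD samples nearest (in expression) to their own PT.

    For every residual-disease sample with a matched primary tumor (same
    patient, same side, same focus when present) in the distance matrix,
    finds its nearest other sample and reports (rate matched-PT nearest,
    rate contralateral-tumor nearest).  RD samples without a matched PT are
    excluded with a warning.
    """
    meta = sample_meta.set_index("sample_id") if "sample_id" in sample_meta.columns else sample_meta
    meta = meta.loc[distance.index]
    has_focus = "focus" in meta.columns

    def match_key(s):
        key = (meta.loc[s, "patient_id"], meta.loc[s, "side"])
        if has_focus:
            focus = meta.loc[s, "focus"]
            key += ("" if pd.isna(focus) or focus == "." else str(focus),)
        return key

    pt_by_key = {
        match_key(s): s for s in distance.index if meta.loc[s, "timepoint"] == "PT"
    }
    rd_samples = [s for s in distance.index if meta.loc[s, "timepoint"] == "RD"]
    n_own = n_contra = n_eval = 0
    for rd in rd_samples:
        own_pt = pt_by_key.get(match_key(rd))
        if own_pt is None:
            warnings.warn(f"RD sample {rd} has no matched PT; excluded", stacklevel=2)
            continue
        row = distance.loc[rd].drop(rd)
        nearest = row.sort_index().idxmin()  # deterministic under ties
        n_eval += 1
        if nearest == own_pt:
            n_own += 1
        elif meta.loc[nearest, "patient_id"] == meta.loc[rd, "patient_id"] and meta.loc[
            nearest, "side"
        ] != meta.loc[rd, "side"]:
            n_contra += 1
    if n_eval == 0:
        raise ValueError("no RD sample with a matched PT present")
    return n_own / n_eval, n_contra / n_eval
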