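"""Immune contexture and T cell receptor repertoire statistics.

Inputs are the outputs of upstream tools rather than raw reads: immune
profiles are LM22-style absolute abundances of 22 immune subsets per sample
(as produced by deconvolution in absolute mode), and TCR repertoires are
per-sample tables of beta-chain CDR3 sequences with read counts.

The dissimilarity index between two samples is the sum over the 22 subsets
of the squared abundance difference; block means of that index (within PT
samples, within RD samples, across, within left-right or PT-RD pairs)
summarise how treatment reshapes the immune contexture.  Repertoire
diversity uses the Chao-1 richness estimator and the D50 index; sharing
statistics count clonotypes common to sample pairs and "public" clonotypes
seen across patients.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats

#: Canonical order of the 22 LM22 immune subsets.
LM22_SUBSETS: list[str] = [
    "B cells naive",
    "B cells memory",
    "Plasma cells",
    "T cells CD8",
    "T cells CD4 naive",
    "T cells CD4 memory resting",
    "T cells CD4 memory activated",
    "T cells follicular helper",
    "T cells regulatory (Tregs)",
    "T cells gamma delta",
    "NK cells resting",
    "NK cells activated",
    "Monocytes",
    "Macrophages M0",
    "Macrophages M1",
    "Macrophages M2",
    "Dendritic cells resting",
    "Dendritic cells activated",
    "Mast cells resting",
    "Mast cells activated",
    "Eosinophils",
    "Neutrophils",
]


def dissimilarity_index(x: pd.Series, y: pd.Series) -> float:
    """Immune-contexture dissimilarity between two samples.

    Sum over the immune subsets of the squared abundance difference.
    Symmetric, nonnegative, zero exactly for identical profiles.
    """
    if isinstance(x, pd.Series) and isinstance(y, pd.Series):
        if list(x.index) != list(y.index):
            raise ValueError("immune profiles must share identical subset order")
    a = np.asarray(x, dtype=float)
    b = np.asarray(y, dtype=float)
    if a.shape != b.shape:
        raise ValueError("immune profiles must have equal length")
    d = a - b
    return float(d @ d)


def dissimilarity_matrix(profiles: pd.DataFrame) -> pd.DataFrame:
    """Full pairwise dissimilarity matrix (samples in rows of ``profiles``)."""
    mat = profiles.to_numpy(dtype=float)
    sq = (mat[:, None, :] - mat[None, :, :]) ** 2
    return pd.DataFrame(sq.sum(axis=2), index=profiles.index, columns=profiles.index)


@dataclass
class DissimilarityBlocks:
    """Block means of the pairwise dissimilarity matrix, with contrasts."""

    matrix: pd.DataFrame
    block_means: pd.Series
    p_values: pd.Series


def _pair_values(matrix: pd.DataFrame, pairs: list[tuple[str, str]]) -> np.ndarray:
    return np.array([matrix.loc[a, b] for a, b in pairs], dtype=float)


def dissimilarity_block_means(
    profiles: pd.DataFrame,
    sample_meta: pd.DataFrame,
) -> DissimilarityBlocks:
    """Mean dissimilarity within and across sample blocks.

    ``sample_meta`` must carry ``patient_id``, ``side`` and ``timepoint``
    (PT/RD) for every row of ``profiles``.  Computes the full pairwise
    matrix plus the mean over: PT-PT pairs, RD-RD pairs, PT-RD cross pairs,
    the left-right PT pairs of each patient, and each patient's matched
    PT-RD pairs.  Wilcoxon rank-sum p-values are reported for the PT-PT vs
    RD-RD and within-pair vs rest contrasts; singleton blocks yield NaN.
    """
    meta = sample_meta.set_index("sample_id") if "sample_id" in sample_meta.columns else sample_meta
    meta = meta.loc[profiles.index]
    mat = dissimilarity_matrix(profiles)

    pt = [s for s in profiles.index if meta.loc[s, "timepoint"] == "PT"]
    rd = [s for s in profiles.index if meta.loc[s, "timepoint"] == "RD"]
    pt_pairs = list(combinations(pt, 2))
    rd_pairs = list(combinations(rd, 2))
    cross_pairs = [(a, b) for a in pt for b in rd]

    lr_pairs = []
    for _, grp in meta.groupby("patient_id"):
        sides = grp[grp["timepoint"] == "PT"]
        left = sides[sides["side"] == "left"].index.tolist()
        right = sides[sides["side"] == "right"].index.tolist()
        lr_pairs.extend([(a, b) for a in left for b in right])
    ptrd_pairs = []
    for _, grp in meta.groupby(["patient_id", "side"]):
        pts = grp[grp["timepoint"] == "PT"].index.tolist()
        rds = grp[grp["timepoint"] == "RD"].index.tolist()
        ptrd_pairs.extend([(a, b) for a in pts for b in rds])

    blocks = {
        "PT-PT": _pair_values(mat, pt_pairs),
        "RD-RD": _pair_values(mat, rd_pairs),
        "PT-RD": _pair_values(mat, cross_pairs),
        "left-right pairs": _pair_values(mat, lr_pairs),
        "PT-RD pairs": _pair_values(mat, ptrd_pairs),
    }
    means = pd.Series(
        {name: (float(v.mean()) if len(v) else float("nan")) for name, v in blocks.items()},
        name="mean_dissimilarity",
    )

    pvals = {}
    if len(blocks["PT-PT"]) and len(blocks["RD-RD"]):
        pvals["PT-PT vs RD-RD"] = float(
            stats.mannwhitneyu(blocks["PT-PT"], blocks["RD-RD"], alternative="two-sided").pvalue
        )
    else:
        pvals["PT-PT vs RD-RD"] = float("nan")
    all_pairs = set(pt_pairs) | set(rd_pairs) | {tuple(p) for p in cross_pairs}
    for name in ("left-right pairs", "PT-RD pairs"):
        pair_list = lr_pairs if name == "left-right pairs" else ptrd_pairs
        inside = {tuple(sorted(p)) for p in pair_list}
        rest = [p for p in all_pairs if tuple(sorted(p)) not in inside]
        if len(pair_list) and len(rest):
            pvals[f"{name} vs rest"] = float(
                stats.mannwhitneyu(
                    blocks[name], _pair_values(mat, rest), alternative="two-sided"
                ).pvalue
            )
        else:
            pvals[f"{name} vs rest"] = float("nan")
    return DissimilarityBlocks(matrix=mat, block_means=means, p_values=pd.Series(pvals))


# ---------------------------------------------------------------------------
# TILs


def til_change_category(pre: float | None, post: float | None) -> str | None:
    """Categorise the change in stromal TIL level under neoadjuvant treatment.

    Levels are compared after rounding to the nearest integer percent (TILs
    are scored in whole percent in routine practice): equal rounded values
    are ``stable``, a lower post-treatment value is ``decreased`` and a
    higher one ``increased``.  Missing values yield ``None`` so incomplete
    records can be excluded from denominators.
    """
    if pre is None or post is None or (isinstance(pre, float) and np.isnan(pre)) or (
        isinstance(post, float) and np.isnan(post)
    ):
        return None
    for v, name in ((pre, "pre"), (post, "post")):
        if not 0 <= v <= 100:
            raise ValueError(f"{name} TIL level must be in [0, 100], got {v}")
    a, b = round(float(pre)), round(float(post))
    if b < a:
        return "decreased"
    if b > a:
        return "increased"
    return "stable"


# ---------------------------------------------------------------------------
# TCR repertoires


def _counts(table: pd.DataFrame) -> np.ndarray:
    if len(table) == 0:
        raise ValueError("clonotype table is empty")
    counts = table["count"].to_numpy()
    if (counts < 1).any() or not np.issubdtype(counts.dtype, np.integer):
        counts = counts.astype(float)
        if (counts < 1).any() or (counts != np.round(counts)).any():
            raise ValueError("clonotype counts must be positive integers")
        counts = counts.astype(int)
    return counts


def chao1(table: pd.DataFrame) -> float:
    """Chao-1 nonparametric estimate of clonotype richness.

    S_obs + f1² / (2 f2) using singleton (f1) and doubleton (f2) counts;
    when no doubletons are present the bias-corrected form
    S_obs + f1 (f1 − 1) / 2 is used.  Always ≥ observed richness, with
    equality exactly when there are no singletons.
    """
    counts = _counts(table)
    s_obs = len(counts)
    f1 = int((counts == 1).sum())
    f2 = int((counts == 2).sum())
    if f2 > 0:
        return s_obs + f1 * f1 / (2.0 * f2)
    return s_obs + f1 * (f1 - 1) / 2.0


def d50(table: pd.DataFrame) -> int:
    """Number of dominant clonotypes jointly occupying half the repertoire.

    Clonotypes are taken in decreasing count order (ties broken by CDR3
    sequence for determinism); returns the minimal number whose cumulative
    frequency reaches 50% of total reads.
    """
    if len(table) == 0:
        raise ValueError("clonotype table is empty")
    ordered = table.sort_values(["count", "cdr3"], ascending=[False, True])
    counts = ordered["count"].to_numpy(float)
    cum = np.cumsum(counts)
    return int(np.searchsorted(cum, 0.5 * counts.sum()) + 1)


@dataclass
class RepertoireSharing:
    """Pairwise clonotype sharing and cross-patient (public) clonotypes."""

    pairwise: pd.DataFrame
    public_clonotypes: list[str]
    occupancy: pd.DataFrame


def repertoire_sharing(
    tables: dict[str, pd.DataFrame],
    sample_patients: dict[str, str] | None = None,
) -> RepertoireSharing:
    """Clonotype sharing across a cohort of repertoires.

    For every pair of samples, counts the distinct CDR3 sequences present in
    both.  When ``sample_patients`` maps samples to patients, public
    clonotypes are the sequences observed in samples of at least two
    distinct patients; otherwise, in at least two samples.  The occupancy
    table lists, per clonotype, the number of samples (and patients)
    carrying it.
    """
    if len(tables) < 2:
        raise ValueError("at least two repertoires are required")
    samples = sorted(tables)
    seqs = {s: set(tables[s]["cdr3"]) for s in samples}
    pair = pd.DataFrame(0, index=samples, columns=samples, dtype=int)
    for a, b in combinations(samples, 2):
        n = len(seqs[a] & seqs[b])
        pair.loc[a, b] = pair.loc[b, a] = n

    occupancy_rows = {}
    for s in samples:
        for c in seqs[s]:
            occupancy_rows.setdefault(c, []).append(s)
    occ = pd.DataFrame(
        {
            "cdr3": list(occupancy_rows),
            "n_samples": [len(v) for v in occupancy_rows.values()],
        }
    )
    if sample_patients is not None:
        occ["n_patients"] = [
            len({sample_patients[s] for s in occupancy_rows[c]}) for c in occ["cdr3"]
        ]
        public = sorted(occ.loc[occ["n_patients"] >= 2, "cdr3"])
    else:
        public = sorted(occ.loc[occ["n_samples"] >= 2, "cdr3"])
    occ = occ.sort_values("cdr3").reset_index(drop=True)
    return RepertoireSharing(pairwise=pair, public_clonotypes=public, occupancy=occ)
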