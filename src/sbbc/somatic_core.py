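"""Somatic variant filtering, driver annotation, sample QC and clone tracking.

Operates on MAF-like mutation tables (one row per variant call) carrying, per
record: ``sample_id, chrom, pos, ref, alt, gene, consequence, vaf, pop_af,
somatic_score, trinucleotide_channel``.  A variant is identified by the key
``(chrom, pos, ref, alt)`` within a sample.

The clone model is deliberately simple: per-variant cancer cell fractions
(CCFs) are obtained by purity/copy-number correction of the VAF and grouped
by one-dimensional agglomeration, which is sufficient to track emergence and
extinction of subclones between a primary tumor (PT) and its residual
disease (RD) at the resolution this package targets.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

MUTATION_COLUMNS = [
    "sample_id",
    "chrom",
    "pos",
    "ref",
    "alt",
    "gene",
    "consequence",
    "vaf",
    "pop_af",
    "somatic_score",
    "trinucleotide_channel",
]

#: Consequence classes that can qualify a variant as a driver when the gene
#: is in the cancer gene census: splice site, nonsense, frameshift and
#: non-synonymous SNVs/indels.
DRIVER_CONSEQUENCES = frozenset(
    {"splice_site", "nonsense", "frameshift_indel", "missense", "inframe_indel"}
)

VALID_CONSEQUENCES = DRIVER_CONSEQUENCES | {"synonymous", "other"}

MUTATION_KEY = ["chrom", "pos", "ref", "alt"]


def mutation_keys(records: pd.DataFrame) -> set[tuple]:
    """Return the set of (chrom, pos, ref, alt) identity keys of a table."""
    return set(map(tuple, records[MUTATION_KEY].itertuples(index=False, name=None)))


@dataclass
class FilterReport:
    """Counts of records removed by each somatic-filter rule."""

    n_input: int
    n_removed_pop_af: int
    n_removed_score: int
    n_retained: int


def filter_somatic_variants(
    records: pd.DataFrame,
    af_max: float = 0.2,
    score_min: float = 0.5,
) -> tuple[pd.DataFrame, FilterReport]:
    """Remove presumed-germline and low-confidence calls.

    A record is removed when its population allele frequency (the maximum of
    the dbSNP/ExAC-style frequencies) is strictly greater than ``af_max``, or
    when its somatic confidence score is strictly below ``score_min``.
    Survivors are returned in input order.

    Higher somatic scores mean higher confidence, so calls scoring below the
    threshold are dropped; the threshold is configurable.

    Returns the filtered table and a :class:`FilterReport` with the number of
    records each rule removed (a record failing both rules is counted under
    both).
    """
    for col in ("pop_af", "somatic_score"):
        if col not in records.columns:
            raise ValueError(f"mutation table lacks required column {col!r}")
        bad = records[col].isna()
        if bad.any():
            key = records.loc[bad.idxmax(), MUTATION_KEY].tolist() if set(
                MUTATION_KEY
            ).issubset(records.columns) else records.index[bad][0]
            raise ValueError(f"missing {col} for record {key}")
    germline = records["pop_af"].to_numpy(float) > af_max
    low_score = records["somatic_score"].to_numpy(float) < score_min
    keep = ~(germline | low_score)
    report = FilterReport(
        n_input=len(records),
        n_removed_pop_af=int(germline.sum()),
        n_removed_score=int(low_score.sum()),
        n_retained=int(keep.sum()),
    )
    return records.loc[keep].copy(), report


def annotate_drivers(records: pd.DataFrame, census_genes: set[str]) -> pd.DataFrame:
    """Flag putative driver mutations.

    A record is a driver when its consequence is a splice-site, nonsense,
    frameshift or non-synonymous (missense / in-frame indel) change AND its
    gene belongs to the supplied cancer gene census.  Returns a copy with a
    boolean ``driver`` column.
    """
    if not census_genes:
        raise ValueError("census gene set must be non-empty")
    out = records.copy()
    out["driver"] = records["consequence"].isin(DRIVER_CONSEQUENCES) & records[
        "gene"
    ].isin(set(census_genes))
    return out


@dataclass
class QcDecision:
    """Retain/discard decision for a residual-disease sample."""

    retain: bool
    reasons: list[str] = field(default_factory=list)
    purity: float = float("nan")
    relative_difference: float = float("nan")


def qc_retain_rd(
    pt_mutation_count: int,
    rd_mutation_count: int,
    rd_purity: float,
    purity_min: float = 0.3,
    rel_diff_max: float = 0.25,
    combine: str = "and",
) -> QcDecision:
    """Quality-control rule for post-treatment (RD) samples.

    The relative difference between the PT and RD mutation burdens is
    ``|PT - RD| / PT`` (the pre-treatment specimen is the reference).  By
    default a sample is discarded only when *both* criteria fire: purity
    below ``purity_min`` and relative difference above ``rel_diff_max``;
    ``combine="or"`` discards when either fires.
    """
    if pt_mutation_count == 0:
        raise ValueError("PT mutation count is zero; relative difference undefined")
    if pt_mutation_count < 0 or rd_mutation_count < 0:
        raise ValueError("mutation counts must be nonnegative")
    if not 0 < rd_purity <= 1:
        raise ValueError(f"purity must be in (0, 1], got {rd_purity}")
    if combine not in ("and", "or"):
        raise ValueError("combine must be 'and' or 'or'")

    rel_diff = abs(pt_mutation_count - rd_mutation_count) / pt_mutation_count
    reasons = []
    if rd_purity < purity_min:
        reasons.append(f"purity {rd_purity:.3g} < {purity_min}")
    if rel_diff > rel_diff_max:
        reasons.append(f"relative mutation-count difference {rel_diff:.3g} > {rel_diff_max}")
    fired = len(reasons)
    discard = fired == 2 if combine == "and" else fired >= 1
    return QcDecision(
        retain=not discard,
        reasons=reasons,
        purity=rd_purity,
        relative_difference=rel_diff,
    )


@dataclass
class Clone:
    """A group of mutations at a common cancer cell fraction."""

    clone_id: str
    ccf: float
    members: frozenset
    parent: str | None = None

    def __post_init__(self):
        if not self.members:
            raise ValueError("clone must have at least one member mutation")
        if not 0 <= self.ccf <= 1:
            raise ValueError(f"clone CCF must be in [0, 1], got {self.ccf}")


def ccf_from_vaf(
    vaf: np.ndarray, purity: float, copy_number: np.ndarray | float = 2.0
) -> np.ndarray:
    """Purity/copy-number corrected cancer cell fraction.

    CCF = VAF * (purity * CN + (1 - purity) * 2) / purity, clipped to [0, 1].
    Assumes one mutated copy per carrying cell.
    """
    if not 0 < purity <= 1:
        raise ValueError(f"purity must be in (0, 1], got {purity}")
    cn = np.asarray(copy_number, dtype=float)
    ccf = np.asarray(vaf, float) * (purity * cn + (1.0 - purity) * 2.0) / purity
    return np.clip(ccf, 0.0, 1.0)


def cluster_ccf(
    records: pd.DataFrame,
    purity: float,
    copy_number_per_site: pd.Series | float = 2.0,
    gap: float = 0.15,
) -> list[Clone]:
    """Group mutations into clones by 1-D clustering of their CCFs.

    Per-record CCFs are sorted and split wherever consecutive cluster centers
    differ by at least ``gap``; adjacent clusters closer than the gap are
    merged.  Each clone's CCF is the median of its members' CCFs, and the
    clone with the largest CCF is the trunk (parent of all others, ordered by
    decreasing CCF).  An empty record set yields an empty clone list.
    """
    if len(records) == 0:
        return []
    if isinstance(copy_number_per_site, pd.Series):
        cn = copy_number_per_site.reindex(records.index).fillna(2.0).to_numpy(float)
    else:
        cn = float(copy_number_per_site)
    ccf = ccf_from_vaf(records["vaf"].to_numpy(float), purity, cn)
    keys = list(map(tuple, records[MUTATION_KEY].itertuples(index=False, name=None)))

    order = np.argsort(ccf, kind="stable")
    sorted_ccf = ccf[order]
    # single-linkage style sweep: start a new cluster when the running
    # cluster mean is more than `gap` below the next point
    clusters: list[list[int]] = [[int(order[0])]]
    centers: list[float] = [float(sorted_ccf[0])]
    for idx, value in zip(order[1:], sorted_ccf[1:]):
        if value - centers[-1] < gap:
            clusters[-1].append(int(idx))
            centers[-1] = float(np.mean(ccf[clusters[-1]]))
        else:
            clusters.append([int(idx)])
            centers.append(float(value))

    clones = []
    for members in clusters:
        med = float(np.median(ccf[members]))
        clones.append((med, frozenset(keys[i] for i in members)))
    clones.sort(key=lambda c: -c[0])
    out: list[Clone] = []
    for rank, (med, members) in enumerate(clones):
        parent = None if rank == 0 else out[rank - 1].clone_id
        out.append(Clone(clone_id=f"clone{rank + 1}", ccf=med, members=members, parent=parent))
    return out


def track_clones(
    pt_clones: list[Clone],
    rd_clones: list[Clone],
    jaccard_min: float = 0.5,
) -> pd.DataFrame:
    """Match PT clones to RD clones and label emergence/extinction.

    Each PT clone is matched to the RD clone with maximal Jaccard overlap of
    member mutations, provided the overlap reaches ``jaccard_min``; each RD
    clone can absorb only one PT clone (best match wins).  Unmatched PT
    clones are ``extinct``, unmatched RD clones ``emergent``.  The result is
    a fish-plot-ready table with columns ``clone, ccf_pt, ccf_rd, status,
    delta_ccf``.
    """

    def jaccard(a: frozenset, b: frozenset) -> float:
        union = len(a | b)
        return len(a & b) / union if union else 0.0

    pairs = []
    for i, pc in enumerate(pt_clones):
        for j, rc in enumerate(rd_clones):
            score = jaccard(pc.members, rc.members)
            if score >= jaccard_min:
                pairs.append((score, i, j))
    pairs.sort(key=lambda t: (-t[0], t[1], t[2]))
    pt_match: dict[int, int] = {}
    rd_used: set[int] = set()
    for score, i, j in pairs:
        if i not in pt_match and j not in rd_used:
            pt_match[i] = j
            rd_used.add(j)

    rows = []
    for i, pc in enumerate(pt_clones):
        if i in pt_match:
            rc = rd_clones[pt_match[i]]
            rows.append((pc.clone_id, pc.ccf, rc.ccf, "matched", rc.ccf - pc.ccf))
        else:
            rows.append((pc.clone_id, pc.ccf, 0.0, "extinct", -pc.ccf))
    for j, rc in enumerate(rd_clones):
        if j not in rd_used:
            rows.append((f"rd_{rc.clone_id}", 0.0, rc.ccf, "emergent", rc.ccf))
    return pd.DataFrame(rows, columns=["clone", "ccf_pt", "ccf_rd", "status", "delta_ccf"])
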