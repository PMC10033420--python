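"""Genomic relatedness of tumor pairs.

Three orthogonal layers of evidence are quantified for a pair of tumors
(left vs right breast, primary vs residual disease, or two foci of a
multicentric tumor):

* **shared somatic mutations** — the percentage 100 * 2|A∩B| / (|A| + |B|)
  of mutations (identified by chromosome, position, ref and alt allele)
  present in both tumors, and the Venn partition behind it;
* **copy-number profile similarity** — cosine similarity of the gene-level
  total-copy-number profiles after subtracting the diploid reference (2), so
  that the metric reflects gains and losses rather than the shared diploid
  background;
* **mutational-signature exposures** — each tumor's 96-channel trinucleotide
  spectrum refit against a catalogue of reference signatures (by default 13
  processes recurrently active in breast cancer) by sum-constrained
  nonnegative least squares.

A simple, fully configurable decision rule then calls each pair independent
or clonally related.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize

from .somatic_core import MUTATION_KEY, mutation_keys  # noqa: F401  (re-export)

# ---------------------------------------------------------------------------
# trinucleotide channels


def _build_channels() -> list[str]:
    subs = ["C>A", "C>G", "C>T", "T>A", "T>C", "T>G"]
    bases = "ACGT"
    return [f"{f}[{s}]{t}" for s in subs for f in bases for t in bases]


#: The 96 single-base-substitution classes (pyrimidine-centered, ordered by
#: substitution then 5' then 3' flank), matching the COSMIC convention.
TRINUCLEOTIDE_CHANNELS: list[str] = _build_channels()

#: Names of the 13 mutational processes recurrently observed in breast
#: cancer (COSMIC v2 numbering).
BREAST_SIGNATURE_NAMES: list[str] = [
    "Signature.1",
    "Signature.2",
    "Signature.3",
    "Signature.5",
    "Signature.6",
    "Signature.8",
    "Signature.10",
    "Signature.13",
    "Signature.17",
    "Signature.18",
    "Signature.20",
    "Signature.26",
    "Signature.30",
]


def toy_breast_catalogue() -> pd.DataFrame:
    """A synthetic 96x13 signature catalogue for tests and simulations.

    The columns are named after the 13 breast-cancer signatures but their
    profiles are generated deterministically (fixed internal seed), with a
    few biologically motivated accents: clock-like C>T at CpG-like channels
    for Signature.1, APOBEC-style T[C>X]N mass for Signatures 2/13 and a
    flat profile for the HRD-like Signature.3.  Real COSMIC matrices can be
    supplied instead wherever a catalogue is accepted.
    """
    rng = np.random.default_rng(96_130)
    cols = {}
    channels = TRINUCLEOTIDE_CHANNELS
    for name in BREAST_SIGNATURE_NAMES:
        base = rng.dirichlet(np.full(96, 0.35))
        if name == "Signature.1":
            accent = np.array([2.0 if c.endswith("G") and "[C>T]" in c else 0.0 for c in channels])
        elif name in ("Signature.2", "Signature.13"):
            sub = "[C>T]" if name == "Signature.2" else "[C>G]"
            accent = np.array([2.0 if c.startswith("T") and sub in c else 0.0 for c in channels])
        elif name == "Signature.3":
            accent = np.full(96, 0.5)
        else:
            accent = np.zeros(96)
        profile = base + accent / max(accent.sum(), 1.0)
        cols[name] = profile / profile.sum()
    return pd.DataFrame(cols, index=pd.Index(channels, name="channel"))


def validate_catalogue(catalogue: pd.DataFrame) -> np.ndarray:
    """Check a signature catalogue and return it as a (96, k) array."""
    mat = np.asarray(catalogue, dtype=float)
    if mat.shape[0] != 96:
        raise ValueError(f"catalogue must have 96 channel rows, got {mat.shape[0]}")
    if mat.shape[1] < 2:
        raise ValueError("catalogue must contain at least 2 signatures")
    if (mat < 0).any():
        raise ValueError("catalogue probabilities must be nonnegative")
    sums = mat.sum(axis=0)
    if not np.allclose(sums, 1.0, atol=1e-6):
        raise ValueError("each catalogue column must sum to 1 (tolerance 1e-6)")
    return mat


# ---------------------------------------------------------------------------
# shared mutations


def shared_mutation_percentage(set_a: set, set_b: set) -> float:
    """Percentage of mutations shared by two tumors.

    100 * 2|A∩B| / (|A| + |B|); symmetric, bounded in [0, 100], and equal to
    100 exactly when the two sets are identical.
    """
    a, b = set(set_a), set(set_b)
    total = len(a) + len(b)
    if total == 0:
        raise ValueError("shared mutation percentage undefined for two empty sets")
    return 100.0 * 2.0 * len(a & b) / total


def mutation_venn(set_a: set, set_b: set) -> tuple[int, int, int]:
    """Venn partition (a_only, shared, b_only) of two mutation sets."""
    a, b = set(set_a), set(set_b)
    shared = len(a & b)
    return len(a) - shared, shared, len(b) - shared


# ---------------------------------------------------------------------------
# copy number


def cna_cosine_similarity(
    p: pd.Series | np.ndarray,
    q: pd.Series | np.ndarray,
    reference: float = 2.0,
) -> tuple[float, float]:
    """Cosine similarity of two copy-number profiles around the diploid state.

    The diploid reference copy number is subtracted from both profiles so
    the similarity is driven by gains and losses.  Profiles must share label
    order.  Returns ``(similarity, distance)`` with distance = 1 − similarity.
    A profile entirely at reference has no direction and raises.
    """
    if isinstance(p, pd.Series) and isinstance(q, pd.Series):
        if not p.index.equals(q.index):
            raise ValueError("copy-number profiles must share identical label order")
    x = np.asarray(p, dtype=float) - reference
    y = np.asarray(q, dtype=float) - reference
    if x.shape != y.shape:
        raise ValueError("profiles must have equal length")
    nx, ny = np.linalg.norm(x), np.linalg.norm(y)
    if nx == 0 or ny == 0:
        raise ValueError("cosine similarity undefined for a profile entirely at reference")
    sim = float(np.dot(x, y) / (nx * ny))
    return sim, 1.0 - sim


# ---------------------------------------------------------------------------
# mutational signatures


def spectrum_from_records(records: pd.DataFrame) -> np.ndarray:
    """96-channel trinucleotide spectrum (counts) of a mutation table."""
    channels = records["trinucleotide_channel"].to_numpy()
    if len(channels) == 0:
        return np.zeros(96, dtype=int)
    if channels.min() < 0 or channels.max() > 95:
        raise ValueError("trinucleotide_channel values must be in [0, 95]")
    return np.bincount(channels.astype(int), minlength=96)


def fit_signature_exposures(
    spectrum: np.ndarray,
    catalogue: pd.DataFrame,
) -> tuple[pd.Series, float]:
    """Refit a spectrum against a signature catalogue.

    Minimises ``|| spectrum/Σspectrum − catalogue @ e ||²`` subject to
    ``e ≥ 0`` and ``Σe = 1`` (sequential quadratic programming on the exact
    quadratic objective).  Returns the exposure vector (indexed by signature
    name) and the residual norm of the fit.
    """
    counts = np.asarray(spectrum, dtype=float)
    if counts.shape != (96,):
        raise ValueError(f"spectrum must have exactly 96 channels, got {counts.shape}")
    if counts.sum() <= 0:
        raise ValueError("spectrum must contain at least one mutation")
    mat = validate_catalogue(catalogue)
    target = counts / counts.sum()
    k = mat.shape[1]

    def objective(e):
        r = mat @ e - target
        return float(r @ r)

    def grad(e):
        return 2.0 * mat.T @ (mat @ e - target)

    x0 = np.full(k, 1.0 / k)
    res = optimize.minimize(
        objective,
        x0,
        jac=grad,
        method="SLSQP",
        bounds=[(0.0, 1.0)] * k,
        constraints=[{"type": "eq", "fun": lambda e: e.sum() - 1.0, "jac": lambda e: np.ones(k)}],
        options={"maxiter": 500, "ftol": 1e-14},
    )
    exposures = np.clip(res.x, 0.0, None)
    exposures = exposures / exposures.sum()
    residual = float(np.linalg.norm(mat @ exposures - target))
    names = list(catalogue.columns) if isinstance(catalogue, pd.DataFrame) else list(range(k))
    return pd.Series(exposures, index=names, name="exposure"), residual


def cohort_signature_percentages(
    exposures: pd.DataFrame,
    sample_meta: pd.DataFrame,
) -> pd.Series:
    """Cohort-level signature percentages over primary-tumor samples.

    ``exposures`` holds one row per PT sample (signatures in columns);
    ``sample_meta`` maps each of those samples to ``patient_id`` and
    ``side``.  Multicentric foci from the same side of a patient are first
    averaged into one patient-side value, so a patient with several sampled
    foci does not dominate the cohort mean; the cohort mean is then scaled
    to percentages (which sum to 100).
    """
    if len(exposures) == 0:
        raise ValueError("no PT exposures supplied")
    meta = sample_meta.set_index("sample_id") if "sample_id" in sample_meta.columns else sample_meta
    missing = [s for s in exposures.index if s not in meta.index]
    if missing:
        raise ValueError(f"samples missing from metadata: {missing}")
    groups = exposures.groupby(
        [meta.loc[exposures.index, "patient_id"].to_numpy(), meta.loc[exposures.index, "side"].to_numpy()]
    ).mean()
    pct = groups.mean(axis=0) * 100.0
    return pct


# ---------------------------------------------------------------------------
# pair classification


@dataclass
class PairCall:
    """Relatedness call for a tumor pair, with the evidence that produced it."""

    label: str  # "independent" | "clonal"
    shared_count: int
    shared_percentage: float
    cna_similarity: float | None = None
    evidence: tuple[str, ...] = ()


def classify_pair(
    shared_count: int,
    shared_percentage: float,
    cna_similarity: float | None = None,
    min_shared_count: int = 2,
    min_shared_percentage: float = 10.0,
) -> PairCall:
    """Call a tumor pair clonally related or independent.

    The pair is ``clonal`` when the number of shared mutations reaches
    ``min_shared_count`` or the shared-mutation percentage reaches
    ``min_shared_percentage``; otherwise ``independent``.  Copy-number
    similarity is carried along as context but does not enter the default
    rule.  Both thresholds are explicit configuration.
    """
    evidence = []
    if shared_count >= min_shared_count:
        evidence.append(f"shared mutation count {shared_count} >= {min_shared_count}")
    if shared_percentage >= min_shared_percentage:
        evidence.append(
            f"shared mutation percentage {shared_percentage:.3g} >= {min_shared_percentage:.3g}"
        )
    label = "clonal" if evidence else "independent"
    if not evidence:
        evidence.append("no sharing criterion met")
    return PairCall(
        label=label,
        shared_count=shared_count,
        shared_percentage=shared_percentage,
        cna_similarity=cna_similarity,
        evidence=tuple(evidence),
    )
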