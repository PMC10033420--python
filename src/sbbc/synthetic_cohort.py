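"""Synthetic synchronous-bilateral-breast-cancer (sBBC) cohort generator.

Emulates, with known ground truth, the statistical structure the analysis
modules assume:

* a clinical cohort of tumor *pairs* (two breasts of one patient) in which
  most pairs are subtype-concordant, TIL levels depend on the tumor's own
  subtype plus an interaction with the contralateral tumor's concordance
  status, and pCR follows a logistic model with the same interaction;
* a sequenced sub-cohort with a shared germline variant set per patient and
  per-tumor somatic mutations drawn from tumor-specific mutational-signature
  mixtures, organised into clones (trunk CCF 1 plus stick-broken subclones);
  left and right tumors share no somatic mutation in ``independent`` mode,
  or a configurable trunk fraction in ``clonal`` (multicentric-like) mode;
* residual-disease (RD) samples evolved from their primary tumor (PT) by
  clone extinction and the emergence of a private clone, with a configurable
  number of low-purity RD samples planted to exercise the QC rule;
* arm-level copy-number events with gains favoured at 1q/8q/17q and losses
  at 4p/8p/6q/13q/16q, largely conserved from PT to RD and independent
  between sides;
* an expression layer in which PT and RD of the same tumor are more
  correlated than the left and right tumors of a patient;
* immune profiles (22 LM22 subsets, absolute scale) whose RD draws shift
  mass toward M2/M0 macrophages and resting CD4 memory T cells;
* TCR repertoires with Zipf-distributed clone sizes drawn from mostly
  sample-private pools plus patient-shared and cohort-public pools.

Every ``simulate_*`` function is deterministic under a fixed ``seed`` and
draws from its own seed substream, so the layers can be generated in any
order.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .immune_tcr import LM22_SUBSETS
from .relatedness import BREAST_SIGNATURE_NAMES, TRINUCLEOTIDE_CHANNELS, toy_breast_catalogue

SUBTYPES = ("luminal", "TNBC", "HER2+")

# seed substreams, one per generated layer
_CLINICAL, _GENOMES, _EXPRESSION, _IMMUNE, _TCR = range(5)

CHROM_ARMS = [f"{c}{arm}" for c in range(1, 23) for arm in ("p", "q")]
GAIN_FAVORED_ARMS = {"1q", "8q", "17q"}
LOSS_FAVORED_ARMS = {"4p", "8p", "6q", "13q", "16q"}

#: Small census of recurrent breast-cancer driver genes used when planting
#: driver mutations.
DEFAULT_CENSUS_GENES = (
    "TP53",
    "PIK3CA",
    "GATA3",
    "MAP3K1",
    "AKT1",
    "PTEN",
    "CDH1",
    "BRCA1",
    "BRCA2",
    "ERBB2",
)

_CONSEQUENCES = ("missense", "synonymous", "nonsense", "splice_site", "frameshift_indel", "inframe_indel", "other")
_CONSEQUENCE_P = (0.55, 0.15, 0.05, 0.03, 0.05, 0.02, 0.15)


def _default_subtype_weights() -> dict[str, float]:
    # cohort repartition: luminal vastly dominant, TNBC and HER2+ rare
    return {"luminal": 0.876, "TNBC": 0.072, "HER2+": 0.052}


def _default_til_baselines() -> dict[str, float]:
    # mean stromal TIL % per subtype; TNBC most infiltrated
    return {"luminal": 15.0, "TNBC": 35.0, "HER2+": 25.0}


def _default_pcr_logit() -> dict[str, float]:
    # reference cell = luminal tumor in a concordant pair, pCR rate ~6%;
    # luminal tumors in discordant pairs ~22%; TNBC/HER2+ rates unmodified
    # by concordance (~35% / ~30%)
    return {
        "intercept": math.log(0.06 / 0.94),
        "TNBC": math.log(0.35 / 0.65) - math.log(0.06 / 0.94),
        "HER2+": math.log(0.30 / 0.70) - math.log(0.06 / 0.94),
        "discordant_luminal": math.log(0.22 / 0.78) - math.log(0.06 / 0.94),
    }


def _default_signature_mix() -> dict[str, np.ndarray]:
    idx = {name: i for i, name in enumerate(BREAST_SIGNATURE_NAMES)}
    sporadic = np.full(13, 0.4)
    for name, a in (("Signature.1", 6.0), ("Signature.2", 2.5), ("Signature.5", 4.0), ("Signature.13", 2.0)):
        sporadic[idx[name]] = a
    brca = np.full(13, 0.4)
    for name, a in (("Signature.3", 8.0), ("Signature.1", 3.0), ("Signature.8", 2.0)):
        brca[idx[name]] = a
    return {"sporadic": sporadic, "brca": brca}


def _default_immune_alpha() -> dict[str, np.ndarray]:
    base = np.ones(22)
    top = {"Macrophages M2": 4.0, "T cells CD4 memory resting": 3.5, "Macrophages M1": 3.0}
    pt = base.copy()
    for name, a in top.items():
        pt[LM22_SUBSETS.index(name)] = a
    rd = pt.copy()
    for name, a in (("Macrophages M2", 3.0), ("Macrophages M0", 2.0), ("T cells CD4 memory resting", 2.0)):
        rd[LM22_SUBSETS.index(name)] += a
    # lower total concentration: post-treatment profiles shift toward
    # M2/M0/CD4-resting *and* disperse more than pre-treatment ones
    rd *= 14.0 / rd.sum()
    return {"PT": pt, "RD": rd}


@dataclass
class SimConfig:
    """Parameters of the synthetic cohort.

    Clinical defaults are calibrated so the default cohort statistically
    resembles the sBBC setting: 84.7% concordant pairs, a heavily luminal
    subtype repartition, subtype-dependent TIL baselines (TNBC > luminal)
    and a luminal-only pCR/TIL boost in discordant pairs.  Genomic defaults
    put ~151.5 somatic mutations in each tumor and sequence a 6-patient
    sub-cohort.
    """

    n_pairs: int = 313
    p_concordant: float = 0.847
    subtype_weights: dict[str, float] = field(default_factory=_default_subtype_weights)
    til_baselines: dict[str, float] = field(default_factory=_default_til_baselines)
    til_sd: float = 12.0
    til_interaction_delta: float = 12.0
    pcr_logit_params: dict[str, float] = field(default_factory=_default_pcr_logit)
    p_nac: float = 0.85

    # sequenced sub-cohort
    n_sequenced_pairs: int = 6
    pair_mode: str = "independent"  # "independent" | "clonal"
    clonal_pair_trunk_fraction: float = 0.0
    mutations_per_tumor_mean: float = 151.5
    n_germline_variants: int = 30
    n_artifact_calls: int = 5
    p_brca_carrier: float = 13 / 313
    signature_mix_by_genotype: dict[str, np.ndarray] = field(default_factory=_default_signature_mix)
    n_clones: int = 3
    trunk_mutation_fraction: float = 0.6
    rd_clone_retention: float = 0.7
    rd_private_mutations: int = 25
    vaf_noise_sd: float = 0.01
    purity_range: tuple[float, float] = (0.4, 0.9)
    n_low_purity_rd: int = 2
    genes_per_arm: int = 5
    arm_event_prob_favored: float = 0.5
    arm_event_prob_background: float = 0.08
    rd_arm_flip_prob: float = 0.05

    # expression layer
    n_genes: int = 1500
    expression_module_size: int = 100
    expression_module_effect: float = 1.0
    ptrd_correlation: float = 0.9
    leftright_correlation: float = 0.3
    expression_latent_scale: float = 0.6
    expression_poisson_noise: bool = True

    # immune layer
    immune_dirichlet_params: dict[str, np.ndarray] = field(default_factory=_default_immune_alpha)
    rd_immune_shift: bool = True
    immune_total_mass: float = 1.0

    # TCR layer
    tcr_zipf_exponent: float = 2.0
    tcr_clonotypes_per_sample: int = 150
    tcr_pool_props: tuple[float, float, float] = (0.9, 0.07, 0.03)  # private, patient, public

    seed: int = 0

    def validate(self) -> None:
        def check_prob(name, value):
            if not 0.0 <= value <= 1.0:
                raise ValueError(f"{name} must be a probability in [0, 1], got {value}")

        check_prob("p_concordant", self.p_concordant)
        check_prob("p_nac", self.p_nac)
        check_prob("p_brca_carrier", self.p_brca_carrier)
        check_prob("rd_clone_retention", self.rd_clone_retention)
        check_prob("clonal_pair_trunk_fraction", self.clonal_pair_trunk_fraction)
        check_prob("trunk_mutation_fraction", self.trunk_mutation_fraction)
        if set(self.subtype_weights) != set(SUBTYPES):
            raise ValueError(f"subtype_weights must cover exactly {SUBTYPES}")
        if abs(sum(self.subtype_weights.values()) - 1.0) > 1e-9:
            raise ValueError("subtype_weights must sum to 1")
        for name in ("n_pairs", "n_sequenced_pairs", "n_clones", "n_genes", "tcr_clonotypes_per_sample"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")
        lo, hi = self.purity_range
        if not (0.0 < lo <= hi <= 1.0):
            raise ValueError(f"purity_range must be within (0, 1], got {self.purity_range}")
        if self.pair_mode not in ("independent", "clonal"):
            raise ValueError(f"pair_mode must be 'independent' or 'clonal', got {self.pair_mode!r}")
        if self.pair_mode == "independent" and self.clonal_pair_trunk_fraction > 0:
            raise ValueError(
                "clonal_pair_trunk_fraction > 0 requires pair_mode='clonal'"
            )
        if abs(sum(self.tcr_pool_props) - 1.0) > 1e-9:
            raise ValueError("tcr_pool_props must sum to 1")
        if self.mutations_per_tumor_mean <= 0:
            raise ValueError("mutations_per_tumor_mean must be strictly positive")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["signature_mix_by_genotype"] = {
            k: list(map(float, v)) for k, v in self.signature_mix_by_genotype.items()
        }
        d["immune_dirichlet_params"] = {
            k: list(map(float, v)) for k, v in self.immune_dirichlet_params.items()
        }
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SimConfig":
        d = dict(d)
        if "signature_mix_by_genotype" in d:
            d["signature_mix_by_genotype"] = {
                k: np.asarray(v, float) for k, v in d["signature_mix_by_genotype"].items()
            }
        if "immune_dirichlet_params" in d:
            d["immune_dirichlet_params"] = {
                k: np.asarray(v, float) for k, v in d["immune_dirichlet_params"].items()
            }
        if "purity_range" in d:
            d["purity_range"] = tuple(d["purity_range"])
        if "tcr_pool_props" in d:
            d["tcr_pool_props"] = tuple(d["tcr_pool_props"])
        cfg = cls(**d)
        cfg.validate()
        return cfg


@dataclass
class GenomicCohort:
    """Sequenced sub-cohort: sample metadata, mutation calls and CNA segments."""

    sample_meta: pd.DataFrame  # sample_id, patient_id, side, timepoint, focus, purity, subtype
    mutations: pd.DataFrame  # MAF-like; includes germline and artifact calls
    cna: pd.DataFrame  # SEG-like long table


@dataclass
class GroundTruth:
    """Generative truth recorded alongside the synthetic genomes."""

    pair_relatedness: dict[str, str]  # patient -> independent | clonal
    exposures: pd.DataFrame  # sample x 13 true signature exposures
    clones: dict[str, list[tuple[float, frozenset]]]  # sample -> [(ccf, member keys)]
    somatic_keys: dict[str, set]  # sample -> true somatic (chrom,pos,ref,alt) keys
    low_purity_rd: list[str]
    pcr_logit_params: dict[str, float] = field(default_factory=dict)
    til_interaction_delta: float = 0.0


# ---------------------------------------------------------------------------
# clinical layer


def simulate_clinical_cohort(config: SimConfig) -> pd.DataFrame:
    """Simulate the tumor-level clinical table (two rows per patient).

    Pair concordance is drawn first; a concordant pair receives one subtype
    for both tumors, a discordant pair two distinct subtypes, so the
    recorded concordance label always equals ``left.subtype ==
    right.subtype``.  Stromal TILs are subtype baseline plus the
    luminal-discordant interaction delta plus Gaussian noise truncated to
    [0, 100]; pCR is Bernoulli under the configured logistic model and is
    staged back into ypT/ypN labels and residual positive node counts.
    """
    config.validate()
    rng = np.random.default_rng([config.seed, _CLINICAL])
    names = list(SUBTYPES)
    weights = np.array([config.subtype_weights[s] for s in names])

    rows = []
    for p in range(1, config.n_pairs + 1):
        patient = f"patient{p}"
        concordant = rng.random() < config.p_concordant
        if concordant:
            subtype = names[rng.choice(len(names), p=weights)]
            pair_subtypes = (subtype, subtype)
        else:
            first = names[rng.choice(len(names), p=weights)]
            rest = [s for s in names if s != first]
            w = np.array([config.subtype_weights[s] for s in rest])
            second = rest[rng.choice(len(rest), p=w / w.sum())]
            pair_subtypes = (first, second)
        concordance = "concordant" if pair_subtypes[0] == pair_subtypes[1] else "discordant"
        treatment = "NAC" if rng.random() < config.p_nac else "NET"
        for side, subtype in zip(("left", "right"), pair_subtypes):
            til = config.til_baselines[subtype]
            if subtype == "luminal" and concordance == "discordant":
                til += config.til_interaction_delta
            stromal_pre = float(np.clip(til + rng.normal(0, config.til_sd), 0, 100))
            intratumoral_pre = float(np.clip(0.4 * stromal_pre + rng.normal(0, 4), 0, 100))
            stromal_post = float(np.clip(stromal_pre + rng.normal(-2, 10), 0, 100))

            lp = config.pcr_logit_params
            logit = lp["intercept"]
            if subtype in ("TNBC", "HER2+"):
                logit += lp[subtype]
            if subtype == "luminal" and concordance == "discordant":
                logit += lp["discordant_luminal"]
            pcr = bool(rng.random() < 1.0 / (1.0 + math.exp(-logit)))
            if pcr:
                ypt, ypn, nodes = ("ypTis" if rng.random() < 0.3 else "ypT0"), "ypN0", 0
            else:
                ypt = f"ypT{rng.choice([1, 2, 3], p=[0.5, 0.35, 0.15])}"
                node_negative = rng.random() < 0.6
                ypn = "ypN0" if node_negative else f"ypN{rng.choice([1, 2], p=[0.8, 0.2])}"
                nodes = 0 if node_negative else int(1 + rng.poisson(2))
            rows.append(
                {
                    "patient_id": patient,
                    "side": side,
                    "subtype": subtype,
                    "grade": int(rng.choice([1, 2, 3], p=[0.15, 0.5, 0.35])),
                    "clinical_t_stage": int(rng.choice([1, 2, 3], p=[0.35, 0.5, 0.15])),
                    "stromal_til_pre": stromal_pre,
                    "intratumoral_til_pre": intratumoral_pre,
                    "stromal_til_post": stromal_post,
                    "treatment": treatment,
                    "pcr": pcr,
                    "ypT": ypt,
                    "ypN": ypn,
                    "post_nac_positive_nodes": nodes,
                    "concordance": concordance,
                }
            )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# genomes


def _channel_alleles(channel: int) -> tuple[str, str]:
    sub = TRINUCLEOTIDE_CHANNELS[channel]
    return sub[2], sub[4]  # e.g. "A[C>A]G" -> ("C", "A")


def _draw_mutation_rows(
    rng: np.random.Generator,
    n: int,
    channel_probs: np.ndarray,
    patient: str,
    pos_counter: list[int],
    census: tuple[str, ...],
) -> list[dict]:
    rows = []
    channels = rng.choice(96, size=n, p=channel_probs)
    for ch in channels:
        pos_counter[0] += 1
        ref, alt = _channel_alleles(int(ch))
        is_driver_gene = rng.random() < 0.03
        gene = census[rng.integers(len(census))] if is_driver_gene else f"GENE{rng.integers(1, 20000):05d}"
        rows.append(
            {
                "chrom": f"chr{rng.integers(1, 23)}",
                "pos": 1_000_000 + pos_counter[0],
                "ref": ref,
                "alt": alt,
                "gene": gene,
                "consequence": str(rng.choice(_CONSEQUENCES, p=_CONSEQUENCE_P)),
                "pop_af": float(rng.uniform(0.0, 0.2)) if rng.random() < 0.1 else 0.0,
                "somatic_score": float(rng.uniform(0.6, 1.0)),
                "trinucleotide_channel": int(ch),
                "_patient": patient,
            }
        )
    return rows


def _stick_breaking_ccfs(rng: np.random.Generator, n_clones: int) -> np.ndarray:
    """Trunk CCF 1 plus descending subclone CCFs from a stick-breaking draw."""
    ccfs = [1.0]
    remaining = 0.9
    for _ in range(n_clones - 1):
        frac = rng.beta(2.0, 2.0)
        ccfs.append(remaining * frac)
        remaining *= 1 - frac * 0.5
    sub = sorted(ccfs[1:], reverse=True)
    return np.array([1.0] + sub)


def _assign_clones(rng: np.random.Generator, n_mut: int, config: SimConfig) -> np.ndarray:
    """Clone index per mutation: trunk holds ``trunk_mutation_fraction``."""
    n_clones = config.n_clones
    if n_clones == 1:
        return np.zeros(n_mut, dtype=int)
    probs = np.empty(n_clones)
    probs[0] = config.trunk_mutation_fraction
    probs[1:] = (1 - config.trunk_mutation_fraction) / (n_clones - 1)
    return rng.choice(n_clones, size=n_mut, p=probs)


def _vafs(rng, ccfs, purity, noise_sd):
    expected = ccfs * purity / 2.0  # diploid, one mutated copy
    return np.clip(expected + rng.normal(0, noise_sd, size=len(ccfs)), 0.005, 1.0)


def _draw_arm_events(rng: np.random.Generator, config: SimConfig) -> dict[str, int]:
    events = {}
    for arm in CHROM_ARMS:
        p_gain = config.arm_event_prob_favored if arm in GAIN_FAVORED_ARMS else config.arm_event_prob_background
        p_loss = config.arm_event_prob_favored if arm in LOSS_FAVORED_ARMS else config.arm_event_prob_background
        u = rng.random()
        if u < p_gain:
            events[arm] = +1
        elif u < p_gain + p_loss:
            events[arm] = -1
        else:
            events[arm] = 0
    return events


def simulate_tumor_genomes(config: SimConfig) -> tuple[GenomicCohort, GroundTruth]:
    """Simulate the sequenced sub-cohort (mutations, clones, purity, CNAs).

    Each sequenced patient receives a shared germline variant set (emitted
    in every sample with population allele frequency above the somatic
    filter's cutoff), two per-side somatic mutation sets drawn from the
    tumor's signature mixture and partitioned into clones, low-confidence
    artifact calls, an RD sample evolved from each PT by subclone dropout
    plus a private emergent clone, and arm-level copy-number events.  In
    ``independent`` mode left and right share no somatic mutation; in
    ``clonal`` mode they share the configured trunk fraction.  The first
    ``n_low_purity_rd`` right-side RD samples are planted with purity below
    0.3 and a mutation burden differing from the PT by more than 25%.
    """
    config.validate()
    rng = np.random.default_rng([config.seed, _GENOMES])
    catalogue = toy_breast_catalogue().to_numpy()
    mix = config.signature_mix_by_genotype

    meta_rows: list[dict] = []
    mut_frames: list[pd.DataFrame] = []
    cna_rows: list[dict] = []
    exposures_rows: dict[str, np.ndarray] = {}
    clones_truth: dict[str, list[tuple[float, frozenset]]] = {}
    somatic_keys: dict[str, set] = {}
    relatedness: dict[str, str] = {}
    low_purity_planted: list[str] = []

    n_seq = min(config.n_sequenced_pairs, config.n_pairs)
    names = list(SUBTYPES)
    weights = np.array([config.subtype_weights[s] for s in names])

    n_planted = 0
    for p in range(1, n_seq + 1):
        patient = f"patient{p}"
        relatedness[patient] = config.pair_mode
        carrier = rng.random() < config.p_brca_carrier
        alpha = mix["brca"] if carrier else mix["sporadic"]
        pos_counter = [p * 10_000_000]

        # germline variants, shared by every sample of the patient
        germline = _draw_mutation_rows(
            rng, config.n_germline_variants, np.full(96, 1 / 96), patient, pos_counter, DEFAULT_CENSUS_GENES
        )
        for row in germline:
            row["pop_af"] = float(rng.uniform(0.25, 0.6))

        trunk_shared_rows: list[dict] = []
        n_per_side = 0
        if config.pair_mode == "clonal":
            # both tumors of a clonal pair carry the same burden so the
            # shared fraction equals the configured trunk fraction
            n_per_side = max(1, int(rng.poisson(config.mutations_per_tumor_mean)))
            n_shared = int(round(config.clonal_pair_trunk_fraction * n_per_side))
            exp_shared = rng.dirichlet(alpha)
            trunk_shared_rows = _draw_mutation_rows(
                rng, n_shared, catalogue @ exp_shared, patient, pos_counter, DEFAULT_CENSUS_GENES
            )

        for side, side_code in (("left", "L"), ("right", "R")):
            exposure = rng.dirichlet(alpha)
            channel_probs = catalogue @ exposure
            if config.pair_mode == "clonal":
                n_private = n_per_side - len(trunk_shared_rows)
                private = _draw_mutation_rows(rng, n_private, channel_probs, patient, pos_counter, DEFAULT_CENSUS_GENES)
                somatic_rows = [dict(r) for r in trunk_shared_rows] + private
            else:
                n_mut = max(1, int(rng.poisson(config.mutations_per_tumor_mean)))
                somatic_rows = _draw_mutation_rows(rng, n_mut, channel_probs, patient, pos_counter, DEFAULT_CENSUS_GENES)

            n_mut = len(somatic_rows)
            ccf_levels = _stick_breaking_ccfs(rng, config.n_clones)
            clone_idx = _assign_clones(rng, n_mut, config)
            if config.pair_mode == "clonal" and trunk_shared_rows:
                clone_idx[: len(trunk_shared_rows)] = 0  # shared trunk stays clonal
            purity_pt = float(rng.uniform(*config.purity_range))

            pt_id = f"PT{p}_{side_code}"
            rd_id = f"RD{p}_{side_code}"
            keys = [(r["chrom"], r["pos"], r["ref"], r["alt"]) for r in somatic_rows]
            somatic_keys[pt_id] = set(keys)
            exposures_rows[pt_id] = exposure
            clones_truth[pt_id] = [
                (float(ccf_levels[c]), frozenset(k for k, ci in zip(keys, clone_idx) if ci == c))
                for c in range(config.n_clones)
                if (clone_idx == c).any()
            ]

            pt_vaf = _vafs(rng, ccf_levels[clone_idx], purity_pt, config.vaf_noise_sd)
            pt_rows = []
            for r, v in zip(somatic_rows, pt_vaf):
                row = dict(r)
                row["vaf"] = float(v)
                row["sample_id"] = pt_id
                pt_rows.append(row)
            for r in germline:
                row = dict(r)
                row["vaf"] = float(np.clip(0.5 + rng.normal(0, 0.03), 0.05, 1.0))
                row["sample_id"] = pt_id
                pt_rows.append(row)
            artifacts = _draw_mutation_rows(
                rng, config.n_artifact_calls, np.full(96, 1 / 96), patient, pos_counter, DEFAULT_CENSUS_GENES
            )
            for r in artifacts:
                r["somatic_score"] = float(rng.uniform(0.0, 0.45))
                r["vaf"] = float(rng.uniform(0.02, 0.2))
                r["sample_id"] = pt_id
                pt_rows.append(r)

            # residual disease: drop non-retained subclones, add a private clone
            plant_low_purity = side_code == "R" and n_planted < config.n_low_purity_rd
            retained_clones = [0] + [
                c for c in range(1, config.n_clones) if rng.random() < config.rd_clone_retention
            ]
            if plant_low_purity:
                retained_clones = [0]
            keep = np.isin(clone_idx, retained_clones)
            if plant_low_purity:
                # drop part of the trunk too, pushing the burden difference past QC
                keep &= rng.random(n_mut) < 0.55
                purity_rd = float(rng.uniform(0.10, 0.28))
                n_planted += 1
                low_purity_planted.append(rd_id)
            else:
                purity_rd = float(rng.uniform(*config.purity_range))

            emergent_ccf = float(rng.uniform(0.2, 0.6))
            emergent = _draw_mutation_rows(
                rng, config.rd_private_mutations, channel_probs, patient, pos_counter, DEFAULT_CENSUS_GENES
            )
            rd_rows = []
            rd_keys = []
            rd_truth: dict[int, list] = {}
            kept_rows = [r for r, k in zip(somatic_rows, keep) if k]
            kept_ccf = ccf_levels[clone_idx[keep]]
            kept_idx = clone_idx[keep]
            rd_vaf = _vafs(rng, kept_ccf, purity_rd, config.vaf_noise_sd)
            for r, v, ci in zip(kept_rows, rd_vaf, kept_idx):
                row = dict(r)
                row["vaf"] = float(v)
                row["sample_id"] = rd_id
                rd_rows.append(row)
                key = (r["chrom"], r["pos"], r["ref"], r["alt"])
                rd_keys.append(key)
                rd_truth.setdefault(int(ci), []).append(key)
            em_vaf = _vafs(rng, np.full(len(emergent), emergent_ccf), purity_rd, config.vaf_noise_sd)
            for r, v in zip(emergent, em_vaf):
                row = dict(r)
                row["vaf"] = float(v)
                row["sample_id"] = rd_id
                rd_rows.append(row)
                rd_keys.append((r["chrom"], r["pos"], r["ref"], r["alt"]))
            for r in germline:
                row = dict(r)
                row["vaf"] = float(np.clip(0.5 + rng.normal(0, 0.03), 0.05, 1.0))
                row["sample_id"] = rd_id
                rd_rows.append(row)

            somatic_keys[rd_id] = set(rd_keys)
            exposures_rows[rd_id] = exposure
            truth_list = [
                (float(ccf_levels[c]), frozenset(rd_truth[c])) for c in sorted(rd_truth)
            ]
            if emergent:
                truth_list.append(
                    (emergent_ccf, frozenset((r["chrom"], r["pos"], r["ref"], r["alt"]) for r in emergent))
                )
            clones_truth[rd_id] = truth_list

            subtype = names[rng.choice(len(names), p=weights)]
            for sid, tp, pur in ((pt_id, "PT", purity_pt), (rd_id, "RD", purity_rd)):
                meta_rows.append(
                    {
                        "sample_id": sid,
                        "patient_id": patient,
                        "side": side,
                        "timepoint": tp,
                        "focus": ".",
                        "purity": pur,
                        "subtype": subtype,
                    }
                )

            # copy number: RD inherits the PT arm events with rare flips
            pt_events = _draw_arm_events(rng, config)
            rd_events = {
                arm: (ev if rng.random() > config.rd_arm_flip_prob else -ev if ev else int(rng.choice([-1, 1])))
                for arm, ev in pt_events.items()
            }
            for sid, events in ((pt_id, pt_events), (rd_id, rd_events)):
                for arm, ev in events.items():
                    chrom = f"chr{arm[:-1]}"
                    for g in range(config.genes_per_arm):
                        cna_rows.append(
                            {
                                "sample_id": sid,
                                "chrom": chrom,
                                "start": g * 1_000_000 + 1,
                                "end": (g + 1) * 1_000_000,
                                "label": f"CNA_{arm}_{g}",
                                "total_cn": 2 + ev,
                                "cnloh_flag": int(ev == 0 and rng.random() < 0.05),
                            }
                        )

            mut_frames.append(pd.DataFrame(pt_rows))
            mut_frames.append(pd.DataFrame(rd_rows))

    mutations = pd.concat(mut_frames, ignore_index=True).drop(columns="_patient")
    mutations = mutations[
        ["sample_id", "chrom", "pos", "ref", "alt", "gene", "consequence", "vaf", "pop_af", "somatic_score", "trinucleotide_channel"]
    ]
    cohort = GenomicCohort(
        sample_meta=pd.DataFrame(meta_rows),
        mutations=mutations,
        cna=pd.DataFrame(cna_rows),
    )
    truth = GroundTruth(
        pair_relatedness=relatedness,
        exposures=pd.DataFrame(exposures_rows, index=BREAST_SIGNATURE_NAMES).T,
        clones=clones_truth,
        somatic_keys=somatic_keys,
        low_purity_rd=low_purity_planted,
        pcr_logit_params=dict(config.pcr_logit_params),
        til_interaction_delta=config.til_interaction_delta,
    )
    return cohort, truth


# ---------------------------------------------------------------------------
# expression


def simulate_expression(config: SimConfig, cohort: GenomicCohort) -> pd.DataFrame:
    """Simulate a genes x samples integer count matrix for the sub-cohort.

    Each sample's latent profile combines a patient component (weight
    ``leftright_correlation``), a tumor component shared between a PT and
    its RD (weight ``ptrd_correlation``) and sample noise, so PT-RD pairs
    correlate more strongly than the left and right tumors of a patient.
    Subtype-specific gene modules (hormone, proliferation, immune) shift
    block means; counts are Poisson around the exponentiated latent rate.
    """
    config.validate()
    rng = np.random.default_rng([config.seed, _EXPRESSION])
    meta = cohort.sample_meta
    g = config.n_genes
    base = rng.normal(np.log(100.0), 0.8, size=g)

    m = config.expression_module_size
    modules = {"hormone": slice(0, m), "proliferation": slice(m, 2 * m), "immune": slice(2 * m, 3 * m)}
    subtype_shift = {
        "luminal": {"hormone": +1.0, "proliferation": -0.5, "immune": -0.3},
        "TNBC": {"hormone": -1.0, "proliferation": +1.0, "immune": +0.6},
        "HER2+": {"hormone": -0.2, "proliferation": +0.5, "immune": +0.3},
    }

    r_pt = math.sqrt(min(max(config.ptrd_correlation, 0.0), 1.0))
    r_lr = math.sqrt(min(max(config.leftright_correlation, 0.0), 1.0))

    patient_latent = {pid: rng.normal(size=g) for pid in meta["patient_id"].unique()}
    tumor_latent: dict[tuple, np.ndarray] = {}
    cols = {}
    for row in meta.itertuples(index=False):
        tkey = (row.patient_id, row.side, row.focus)
        if tkey not in tumor_latent:
            tumor_latent[tkey] = r_lr * patient_latent[row.patient_id] + math.sqrt(
                max(1 - r_lr**2, 0.0)
            ) * rng.normal(size=g)
        latent = r_pt * tumor_latent[tkey] + math.sqrt(max(1 - r_pt**2, 0.0)) * rng.normal(size=g)
        log_mu = base + config.expression_latent_scale * latent
        for mod, sl in modules.items():
            log_mu[sl] = log_mu[sl] + config.expression_module_effect * subtype_shift[row.subtype][mod]
        mu = np.exp(log_mu)
        if config.expression_poisson_noise:
            counts = rng.poisson(mu)
        else:
            counts = np.round(mu).astype(int)
        cols[row.sample_id] = counts
    genes = [f"GENE{i:05d}" for i in range(1, g + 1)]
    return pd.DataFrame(cols, index=pd.Index(genes, name="gene"))


# ---------------------------------------------------------------------------
# immune


def simulate_immune_profiles(config: SimConfig, cohort: GenomicCohort) -> pd.DataFrame:
    """Simulate 22-subset absolute immune abundances per sample.

    Profiles are Dirichlet draws scaled by a Gamma-distributed total mass;
    RD samples use the shifted concentration vector (more M2/M0 macrophage
    and resting CD4 memory mass) unless ``rd_immune_shift`` is disabled.
    """
    config.validate()
    rng = np.random.default_rng([config.seed, _IMMUNE])
    alphas = config.immune_dirichlet_params
    rows = {}
    for row in cohort.sample_meta.itertuples(index=False):
        key = row.timepoint if (config.rd_immune_shift and row.timepoint in alphas) else "PT"
        alpha = np.asarray(alphas[key], dtype=float)
        mass = config.immune_total_mass * rng.gamma(10.0, 0.1)
        rows[row.sample_id] = rng.dirichlet(alpha) * mass
    return pd.DataFrame(rows, index=pd.Index(LM22_SUBSETS, name="subset")).T


# ---------------------------------------------------------------------------
# TCR


_AA = "ACDEFGHIKLMNPQRSTVWY"


def _cdr3(rng: np.random.Generator) -> str:
    middle = "".join(rng.choice(list(_AA), size=int(rng.integers(6, 12))))
    return f"CASS{middle}F"


def simulate_tcr_repertoires(config: SimConfig, cohort: GenomicCohort) -> dict[str, pd.DataFrame]:
    """Simulate per-sample clonotype tables with Zipf-distributed counts.

    Clonotypes are drawn from three pools with configurable proportions:
    sample-private sequences (the majority), a per-patient shared pool and
    a small cohort-public pool — so most distinct sequences occur in exactly
    one sample while some recur within a patient or across patients.
    """
    config.validate()
    rng = np.random.default_rng([config.seed, _TCR])
    meta = cohort.sample_meta
    public_pool = [_cdr3(rng) for _ in range(60)]
    patient_pools = {
        pid: [_cdr3(rng) for _ in range(80)] for pid in meta["patient_id"].unique()
    }
    p_private, p_patient, p_public = config.tcr_pool_props

    tables = {}
    for row in meta.itertuples(index=False):
        seqs: dict[str, int] = {}
        while len(seqs) < config.tcr_clonotypes_per_sample:
            u = rng.random()
            if u < p_private:
                seq = _cdr3(rng)
            elif u < p_private + p_patient:
                pool = patient_pools[row.patient_id]
                seq = pool[rng.integers(len(pool))]
            else:
                seq = public_pool[rng.integers(len(public_pool))]
            count = int(min(rng.zipf(config.tcr_zipf_exponent), 10_000))
            seqs[seq] = seqs.get(seq, 0) + count
        table = pd.DataFrame(
            {"cdr3": list(seqs), "count": list(seqs.values())}
        ).sort_values("cdr3", ignore_index=True)
        tables[row.sample_id] = table
    return tables
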