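import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from sbbc.relatedness import (
    BREAST_SIGNATURE_NAMES,
    TRINUCLEOTIDE_CHANNELS,
    classify_pair,
    cna_cosine_similarity,
    cohort_signature_percentages,
    fit_signature_exposures,
    mutation_venn,
    shared_mutation_percentage,
    spectrum_from_records,
    toy_breast_catalogue,
)


class TestSharedMutationPercentage:
    def test_identity_is_100(self):
        s = {("chr1", i, "C", "A") for i in range(50)}
        assert shared_mutation_percentage(s, s) == 100.0

    def test_disjoint_is_0(self):
        a = {("chr1", i, "C", "A") for i in range(10)}
        b = {("chr2", i, "C", "A") for i in range(10)}
        assert shared_mutation_percentage(a, b) == 0.0

    def test_formula(self):
        a = set(range(10))
        b = set(range(30))  # |A∩B| = 10, |A|+|B| = 40
        assert shared_mutation_percentage(a, b) == pytest.approx(50.0)

    def test_two_empty_sets_error(self):
        with pytest.raises(ValueError):
            shared_mutation_percentage(set(), set())

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(
        a=st.sets(st.integers(0, 60), min_size=1, max_size=40),
        b=st.sets(st.integers(0, 60), min_size=1, max_size=40),
    )
    def test_symmetric_bounded_100_iff_identical(self, a, b):
        pct = shared_mutation_percentage(a, b)
        assert pct == shared_mutation_percentage(b, a)
        assert 0.0 <= pct <= 100.0
        assert (pct == 100.0) == (a == b)


class TestMutationVenn:
    @pytest.mark.parametrize(
        "a,b,expected",
        [
            ({1, 2, 3, 4, 5}, {1, 2, 3, 4, 5}, (0, 5, 0)),
            ({1, 2, 3}, {4, 5, 6, 7}, (3, 0, 4)),
            ({1, 2, 3}, {2, 3, 4, 5}, (1, 2, 2)),
        ],
    )
    def test_examples(self, a, b, expected):
        assert mutation_venn(a, b) == expected

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(
        a=st.sets(st.integers(0, 40), max_size=30),
        b=st.sets(st.integers(0, 40), max_size=30),
    )
    def test_partition_consistency(self, a, b):
        a_only, shared, b_only = mutation_venn(a, b)
        assert a_only + shared == len(a)
        assert b_only + shared == len(b)


class TestCnaCosine:
    def test_identity(self):
        p = pd.Series([3, 2, 1, 2], index=list("abcd"))
        sim, dist = cna_cosine_similarity(p, p)
        assert sim == pytest.approx(1.0)
        assert dist == pytest.approx(0.0)

    def test_antisymmetry(self):
        p = pd.Series([3, 2, 3, 2])
        q = pd.Series([1, 2, 1, 2])
        sim, _ = cna_cosine_similarity(p, q)
        assert sim == pytest.approx(-1.0)

    def test_hand_computed_value(self):
        p = pd.Series([3, 2, 1, 2])  # p-2 = (1, 0, -1, 0)
        q = pd.Series([3, 2, 2, 2])  # q-2 = (1, 0, 0, 0)
        sim, _ = cna_cosine_similarity(p, q)
        assert sim == pytest.approx(1 / np.sqrt(2), abs=1e-12)

    def test_all_reference_profile_errors(self):
        with pytest.raises(ValueError, match="reference"):
            cna_cosine_similarity(pd.Series([2, 2, 2]), pd.Series([3, 2, 1]))

    def test_mismatched_labels_error(self):
        p = pd.Series([3, 1], index=["a", "b"])
        q = pd.Series([3, 1], index=["b", "a"])
        with pytest.raises(ValueError, match="label"):
            cna_cosine_similarity(p, q)

    def test_scaling_invariance_of_deviation(self):
        rng = np.random.default_rng(3)
        dev = rng.integers(-2, 3, size=30).astype(float)
        dev[0] = 1  # ensure non-reference
        p = pd.Series(dev + 2)
        q = pd.Series(3 * dev + 2)
        sim, _ = cna_cosine_similarity(p, q)
        assert sim == pytest.approx(1.0, abs=1e-12)

    def test_brute_force_oracle(self):
        rng = np.random.default_rng(17)
        for _ in range(100):
            p = rng.integers(0, 6, size=25).astype(float)
            q = rng.integers(0, 6, size=25).astype(float)
            if (p == 2).all() or (q == 2).all():
                continue
            dot = sum((pi - 2) * (qi - 2) for pi, qi in zip(p, q))
            np_ = sum((pi - 2) ** 2 for pi in p) ** 0.5
            nq = sum((qi - 2) ** 2 for qi in q) ** 0.5
            sim, dist = cna_cosine_similarity(pd.Series(p), pd.Series(q))
            assert sim == pytest.approx(dot / (np_ * nq), abs=1e-12)
            assert dist == pytest.approx(1 - dot / (np_ * nq), abs=1e-12)


def records_with_channels(channels):
    n = len(channels)
    return pd.DataFrame(
        {
            "trinucleotide_channel": channels,
            "chrom": ["chr1"] * n,
            "pos": range(n),
            "ref": ["C"] * n,
            "alt": ["A"] * n,
        }
    )


class TestSpectrum:
    def test_empty_records_zero_vector(self):
        spec = spectrum_from_records(records_with_channels([]))
        assert spec.shape == (96,)
        assert spec.sum() == 0

    def test_counts_per_channel(self):
        spec = spectrum_from_records(records_with_channels([0, 0, 0, 95]))
        assert spec[0] == 3
        assert spec[95] == 1
        assert spec.sum() == 4

    def test_out_of_range_channel_errors(self):
        with pytest.raises(ValueError):
            spectrum_from_records(records_with_channels([96]))

    def test_pure_signature_spectrum_is_multinomial(self, catalogue):
        """Sampling 500 mutations from one signature gives a spectrum that
        passes a chi-square goodness-of-fit against that column in nearly
        all replicates."""
        col = catalogue["Signature.3"].to_numpy()
        passed = 0
        for seed in range(20):
            rng = np.random.default_rng(seed)
            spec = np.bincount(rng.choice(96, size=500, p=col), minlength=96)
            # pool rare channels so every expected count is >= 5
            expected = col * 500
            mask = expected >= 5.0
            obs = np.append(spec[mask], spec[~mask].sum())
            exp = np.append(expected[mask], expected[~mask].sum())
            p = stats.chisquare(obs, exp * obs.sum() / exp.sum()).pvalue
            passed += p > 0.01
        assert passed >= 19


class TestSignatureRefitting:
    def test_pure_signature_limit(self, catalogue):
        spectrum = np.round(catalogue["Signature.2"].to_numpy() * 100000).astype(int)
        exposures, residual = fit_signature_exposures(spectrum, catalogue)
        assert exposures["Signature.2"] == pytest.approx(1.0, abs=1e-4)
        assert residual < 1e-4

    def test_equal_mixture_of_orthogonal_toy_signatures(self):
        cat = pd.DataFrame(
            {
                "A": np.r_[np.full(48, 1 / 48), np.zeros(48)],
                "B": np.r_[np.zeros(48), np.full(48, 1 / 48)],
            },
            index=TRINUCLEOTIDE_CHANNELS,
        )
        rng = np.random.default_rng(5)
        mix = 0.5 * cat["A"].to_numpy() + 0.5 * cat["B"].to_numpy()
        spectrum = np.bincount(rng.choice(96, size=10000, p=mix), minlength=96)
        exposures, _ = fit_signature_exposures(spectrum, cat)
        assert exposures["A"] == pytest.approx(0.5, abs=0.02)
        assert exposures["B"] == pytest.approx(0.5, abs=0.02)

    def test_grid_search_oracle_two_signatures(self, catalogue):
        """The constrained least-squares fit agrees with an exhaustive
        grid search (step 0.01) on two-signature problems."""
        cat = catalogue[["Signature.1", "Signature.13"]]
        mat = cat.to_numpy()
        rng = np.random.default_rng(23)
        for _ in range(10):
            w = rng.uniform(0, 1)
            mix = w * mat[:, 0] + (1 - w) * mat[:, 1]
            spectrum = np.bincount(rng.choice(96, size=3000, p=mix), minlength=96)
            target = spectrum / spectrum.sum()
            grid = np.arange(0, 1.0001, 0.01)
            errs = [np.linalg.norm(mat @ np.array([g, 1 - g]) - target) for g in grid]
            best = grid[int(np.argmin(errs))]
            exposures, _ = fit_signature_exposures(spectrum, cat)
            assert exposures.iloc[0] == pytest.approx(best, abs=0.02)

    def test_three_signature_recovery_rmse(self, catalogue):
        rng = np.random.default_rng(29)
        names = list(catalogue.columns)
        errors = []
        for _ in range(20):
            chosen = rng.choice(len(names), size=3, replace=False)
            true = np.zeros(len(names))
            true[chosen] = rng.dirichlet(np.ones(3))
            mix = catalogue.to_numpy() @ true
            spectrum = np.bincount(rng.choice(96, size=5000, p=mix), minlength=96)
            exposures, _ = fit_signature_exposures(spectrum, catalogue)
            errors.append(np.sqrt(np.mean((exposures.to_numpy() - true) ** 2)))
        assert np.mean(errors) < 0.05

    def test_catalogue_validation(self):
        bad = pd.DataFrame({"A": np.full(95, 1 / 95)})
        with pytest.raises(ValueError):
            fit_signature_exposures(np.ones(96), bad)

    def test_empty_spectrum_errors(self, catalogue):
        with pytest.raises(ValueError):
            fit_signature_exposures(np.zeros(96), catalogue)


class TestCohortSignaturePercentages:
    def _meta(self, entries):
        return pd.DataFrame(entries, columns=["sample_id", "patient_id", "side"])

    def test_single_sample(self):
        exp = pd.DataFrame({"A": [0.7], "B": [0.3]}, index=["PT1_L"])
        meta = self._meta([("PT1_L", "p1", "left")])
        pct = cohort_signature_percentages(exp, meta)
        assert pct["A"] == pytest.approx(70.0)
        assert pct["B"] == pytest.approx(30.0)

    def test_symmetric_two_samples(self):
        exp = pd.DataFrame({"A": [1.0, 0.0], "B": [0.0, 1.0]}, index=["PT1_L", "PT2_L"])
        meta = self._meta([("PT1_L", "p1", "left"), ("PT2_L", "p2", "left")])
        pct = cohort_signature_percentages(exp, meta)
        assert pct["A"] == pytest.approx(50.0)

    def test_multicentric_foci_averaged_before_cohort_mean(self):
        """Two same-side foci (0.8,0.2) and (0.6,0.4) average to (0.7,0.3)
        first; with another patient at (0.5,0.5) the cohort is (60,40)."""
        exp = pd.DataFrame(
            {"A": [0.8, 0.6, 0.5], "B": [0.2, 0.4, 0.5]},
            index=["PT6A_L", "PT6B_L", "PT1_L"],
        )
        meta = self._meta(
            [("PT6A_L", "p6", "left"), ("PT6B_L", "p6", "left"), ("PT1_L", "p1", "left")]
        )
        pct = cohort_signature_percentages(exp, meta)
        assert pct["A"] == pytest.approx(60.0)
        assert pct["B"] == pytest.approx(40.0)

    def test_percentages_sum_to_100(self):
        rng = np.random.default_rng(2)
        exp = pd.DataFrame(
            rng.dirichlet(np.ones(13), size=6),
            columns=BREAST_SIGNATURE_NAMES,
            index=[f"PT{i}_L" for i in range(6)],
        )
        meta = self._meta([(f"PT{i}_L", f"p{i}", "left") for i in range(6)])
        assert cohort_signature_percentages(exp, meta).sum() == pytest.approx(100.0, abs=1e-6)

    def test_empty_errors(self):
        with pytest.raises(ValueError):
            cohort_signature_percentages(pd.DataFrame(), self._meta([]))


class TestClassifyPair:
    def test_no_sharing_is_independent(self):
        assert classify_pair(0, 0.0).label == "independent"

    def test_two_shared_mutations_is_clonal(self):
        call = classify_pair(2, 1.5)
        assert call.label == "clonal"
        assert any("count" in e for e in call.evidence)

    def test_single_low_percentage_shared_is_independent(self):
        assert classify_pair(1, 1.0).label == "independent"

    def test_high_percentage_triggers(self):
        assert classify_pair(1, 50.0).label == "clonal"


class TestSimulatedPairStructure:
    def test_clonal_mode_pairs_called_clonal(self):
        from sbbc.synthetic_cohort import SimConfig, simulate_tumor_genomes

        cfg = SimConfig(
            n_pairs=3,
            n_sequenced_pairs=3,
            pair_mode="clonal",
            clonal_pair_trunk_fraction=0.8,
            mutations_per_tumor_mean=100,
            seed=13,
        )
        cohort, truth = simulate_tumor_genomes(cfg)
        for p in range(1, 4):
            left, right = truth.somatic_keys[f"PT{p}_L"], truth.somatic_keys[f"PT{p}_R"]
            pct = shared_mutation_percentage(left, right)
            assert pct == pytest.approx(80.0, abs=8.0)
            assert classify_pair(len(left & right), pct).label == "clonal"

    def test_ptrd_cna_distance_below_leftright(self, bundle):
        from sbbc.io_cli import run_relatedness

        pairs = run_relatedness(bundle)
        by_type = pairs.groupby("pair_type")["cna_cosine_distance"].mean()
        assert by_type["PT-RD"] < by_type["left-right"]
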