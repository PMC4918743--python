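"""The synthetic-data generators and their ground-truth contracts."""

import numpy as np
import pytest

from sigscar import (
    SimulationConfig,
    build_catalogue,
    classify_indels,
    mann_whitney_u,
    fisher_exact_two_tailed,
    build_contingency,
    simulate_annotations,
    simulate_cohort,
    simulate_indel_cohort,
    simulate_reference_and_variants,
    simulate_signatures,
)
from sigscar.channels import CHANNELS


class TestSimulateSignatures:
    def test_single_signature_normalized(self):
        (sig,) = simulate_signatures(1, seed=0)
        assert sig.values.sum() == pytest.approx(1.0, abs=1e-9)

    def test_pairwise_separation_postcondition(self):
        sigs = simulate_signatures(3, min_pairwise_cosine_distance=0.7, seed=1)
        for i in range(3):
            for j in range(i + 1, 3):
                assert sigs[i].cosine(sigs[j]) <= 0.3 + 1e-12

    def test_seed_reproducibility(self):
        a = simulate_signatures(4, seed=7)
        b = simulate_signatures(4, seed=7)
        for x, y in zip(a, b):
            assert np.array_equal(x.values, y.values)

    def test_rejection_budget_error(self):
        with pytest.raises(RuntimeError, match="separation"):
            simulate_signatures(
                30, concentration=50.0, min_pairwise_cosine_distance=0.99,
                seed=2, max_attempts=50,
            )


class TestSimulateCohort:
    def test_fixed_burden_fixes_column_sums(self):
        sigs = simulate_signatures(1, seed=3)
        config = SimulationConfig(
            n_samples=10, burden_mu=np.log(500), burden_sigma=0.0,
            signature_of_interest=None, seed=4,
        )
        matrix, _ = simulate_cohort(config, sigs)
        assert (matrix.sum(axis=0) == 500).all()

    def test_channel_means_match_planted_mixture(self):
        """Law of large numbers: empirical channel frequencies approach the
        planted signature mixture."""
        sigs = simulate_signatures(2, seed=5)
        config = SimulationConfig(
            n_samples=200, burden_mu=np.log(2000), burden_sigma=0.0,
            signature_of_interest=None, sparsity=0.0, seed=6,
        )
        matrix, truth = simulate_cohort(config, sigs)
        S = np.column_stack([s.values for s in sigs])
        expected = S @ truth.true_exposures.to_numpy()
        observed = matrix.to_numpy()
        totals = observed.sum(axis=0)
        # aggregate over the cohort; tolerance 3 standard errors channel-wise
        agg_expected = expected.sum(axis=1)
        agg_observed = observed.sum(axis=1)
        se = np.sqrt(np.maximum(agg_expected, 1.0))
        assert (np.abs(agg_observed - agg_expected) < 4 * se + 5).all()
        assert (totals == truth.true_exposures.sum(axis=0).round()).all()

    def test_ground_truth_dimensions(self):
        sigs = simulate_signatures(3, seed=8)
        config = SimulationConfig(n_samples=12, k_signatures=3, seed=9)
        matrix, truth = simulate_cohort(config, sigs)
        assert matrix.shape == (96, 12)
        assert truth.true_exposures.shape == (3, 12)
        assert set(truth.true_calls) == set(matrix.columns)

    def test_positive_fraction_zero_and_one(self):
        sigs = simulate_signatures(2, seed=10)
        none = SimulationConfig(n_samples=20, positive_fraction=0.0, seed=11)
        all_ = SimulationConfig(n_samples=20, positive_fraction=1.0, seed=11)
        _, truth_none = simulate_cohort(none, sigs)
        _, truth_all = simulate_cohort(all_, sigs)
        assert not any(truth_none.true_calls.values())
        assert all(truth_all.true_calls.values())


class TestReferenceAndVariants:
    def test_no_snvs_gives_zero_catalogue(self):
        _, variants, expected = simulate_reference_and_variants(100, 0, seed=0)
        assert variants == [] and expected.sum() == 0

    def test_purine_refs_map_to_pyrimidine_channels(self):
        reference, variants, expected = simulate_reference_and_variants(3000, 300, seed=1)
        # all planted mass lies in pyrimidine-centric channels by construction
        nonzero = [CHANNELS[i] for i in np.flatnonzero(expected)]
        assert all(c.ref in "CT" for c in nonzero)
        g_to_a = [v for v in variants if v.ref == "G" and v.alt == "A"]
        assert g_to_a  # planted purine events exist and landed in C>T channels

    def test_round_trip_exact(self):
        reference, variants, expected = simulate_reference_and_variants(5000, 400, seed=2)
        catalogue, excluded = build_catalogue(variants, reference)
        assert excluded == []
        assert np.array_equal(catalogue.counts, expected)


class TestIndelCohort:
    reference = {
        "chrSim": "".join(np.random.default_rng(123).choice(list("ACGT"), size=100_000))
    }

    def test_null_enrichment_not_significant(self):
        config = SimulationConfig(mh_base_rate=60.0, mh_enrichment=1.0, filler_indel_rate=30.0)
        calls = {f"S{i:02d}": i < 25 for i in range(50)}
        records, _ = simulate_indel_cohort(config, self.reference, calls, seed=13)
        _, counts = classify_indels(records, self.reference)
        for s in calls:
            counts.setdefault(s, 0)
        pos = [counts[s] for s in calls if calls[s]]
        neg = [counts[s] for s in calls if not calls[s]]
        _, p = mann_whitney_u(pos, neg)
        assert p > 0.05

    def test_every_planted_mh_deletion_recovered_no_filler(self):
        config = SimulationConfig(mh_base_rate=50.0, mh_enrichment=4.0, filler_indel_rate=40.0)
        calls = {f"S{i}": i < 2 for i in range(8)}
        records, truth = simulate_indel_cohort(config, self.reference, calls, seed=14)
        annotated, counts = classify_indels(records, self.reference, min_size=3, min_mh=1)
        assert len(annotated) == len(records)
        assert sum(counts.values()) == sum(truth.true_indel_labels)
        # and per record: every planted label matches the classification
        from sigscar.indels import counts_microhomology

        for record, planted in zip(annotated, truth.true_indel_labels):
            assert counts_microhomology(record) == planted


class TestAnnotations:
    def test_seed_reproducibility(self):
        calls = {f"S{i}": i < 3 for i in range(30)}
        a = simulate_annotations(30, 0.07, 15.0, calls, seed=5)
        b = simulate_annotations(30, 0.07, 15.0, calls, seed=5)
        assert a == b

    def test_null_odds_calibration(self):
        """With no planted association the Fisher p is not systematically small."""
        rng = np.random.default_rng(6)
        pvals = []
        for trial in range(40):
            calls = {f"S{i:03d}": bool(rng.random() < 0.3) for i in range(80)}
            annotations = simulate_annotations(80, 0.3, 1.0, calls, seed=int(rng.integers(2**31)))
            table = build_contingency(annotations, calls, "discohesive_growth", (True,))
            pvals.append(fisher_exact_two_tailed(table))
        assert 0.2 <= float(np.median(pvals)) <= 1.0

    def test_planted_association_detected(self):
        """Strong planted odds in the Table-1-like regime yields small p for
        most seeds."""
        rng = np.random.default_rng(7)
        hits = 0
        trials = 30
        for _ in range(trials):
            calls = {f"S{i:03d}": i < 12 for i in range(100)}
            annotations = simulate_annotations(
                100, 0.07, 15.0, calls, seed=int(rng.integers(2**31))
            )
            table = build_contingency(annotations, calls, "discohesive_growth", (True,))
            if fisher_exact_two_tailed(table) < 0.01:
                hits += 1
        assert hits >= 0.9 * trials


def test_config_validation():
    with pytest.raises(ValueError):
        SimulationConfig(noise_model="gaussian")
    with pytest.raises(ValueError):
        SimulationConfig(positive_fraction=1.5)
    with pytest.raises(ValueError):
        SimulationConfig(mh_enrichment=0.0)
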