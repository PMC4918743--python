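"""Constrained exposure refitting and candidate-set selection."""

import itertools

import numpy as np
import pytest

from sigscar import (
    MutationalCatalogue,
    SampleFeatures,
    Signature,
    SignatureSet,
    SimulationConfig,
    call_signature_present,
    fit_cohort,
    fit_exposures,
    select_subset,
    simulate_cohort,
    simulate_signatures,
)


def catalogue_from(counts) -> MutationalCatalogue:
    return MutationalCatalogue("s", np.asarray(counts, dtype=int))


@pytest.fixture
def flagged_registry() -> SignatureSet:
    """A registry in the style of the COSMIC signature pages: signature 6
    requires repeat indels, signature 3 microhomology indels."""
    rng = np.random.default_rng(42)
    members = {
        "signature 1": frozenset(),
        "signature 3": frozenset({"indels_with_microhomology"}),
        "signature 5": frozenset(),
        "signature 6": frozenset({"indels_at_repeats"}),
        "signature 18": frozenset(),
    }
    signatures = [
        Signature(name=name, values=rng.dirichlet(np.ones(96)), feature_flags=flags)
        for name, flags in members.items()
    ]
    return SignatureSet(
        signatures=signatures,
        registry={
            "neuroblastoma": ["signature 1", "signature 5", "signature 18"],
            "colorectal": ["signature 1", "signature 3", "signature 5", "signature 6"],
        },
    )


class TestSelectSubset:
    def test_neuroblastoma_default_set(self, flagged_registry):
        features = SampleFeatures(cancer_type="neuroblastoma")
        Q = select_subset(features, flagged_registry)
        assert Q.names == ["signature 1", "signature 5", "signature 18"]

    def test_repeat_indel_signature_excluded_without_indels(self, flagged_registry):
        features = SampleFeatures(cancer_type="colorectal", n_indels_at_repeats=0)
        Q = select_subset(features, flagged_registry)
        assert "signature 6" not in Q.names

    def test_flagged_signature_retained_above_threshold(self, flagged_registry):
        features = SampleFeatures(
            cancer_type="colorectal", n_indels_at_repeats=10, n_indels_microhomology=25
        )
        Q = select_subset(features, flagged_registry)
        assert set(Q.names) == {"signature 1", "signature 3", "signature 5", "signature 6"}

    def test_unflagged_registry_passes_through(self, flagged_registry):
        features = SampleFeatures(cancer_type="neuroblastoma")
        Q = select_subset(features, flagged_registry)
        assert Q.names == flagged_registry.registry["neuroblastoma"]

    def test_unknown_cancer_type_lists_known(self, flagged_registry):
        with pytest.raises(KeyError, match="neuroblastoma"):
            select_subset(SampleFeatures(cancer_type="martian"), flagged_registry)


class TestFitExposures:
    def test_exact_disjoint_mixture(self, disjoint_signatures):
        # disjoint uniform supports: exact mixture 4800*s1 + 2400*s2
        counts = np.zeros(96, dtype=int)
        counts[:48] = 100
        counts[48:] = 50
        exposure = fit_exposures(catalogue_from(counts), disjoint_signatures)
        assert exposure.exposures["s1"] == pytest.approx(4800, rel=1e-9)
        assert exposure.exposures["s2"] == pytest.approx(2400, rel=1e-9)
        assert exposure.residual_norm < 1e-6

    def test_single_signature_equality_binds(self, disjoint_signatures):
        counts = np.ones(96, dtype=int)
        Q = disjoint_signatures.subset(["s1"])
        exposure = fit_exposures(catalogue_from(counts), Q)
        assert exposure.exposures["s1"] == pytest.approx(96, rel=1e-9)

    def test_zero_total(self, disjoint_signatures):
        exposure = fit_exposures(catalogue_from(np.zeros(96)), disjoint_signatures)
        assert exposure.total == 0
        assert all(e == 0.0 for e in exposure.exposures.values())
        assert exposure.residual_norm == 0.0

    def test_empty_set_is_error(self, disjoint_signatures):
        with pytest.raises(ValueError):
            fit_exposures(catalogue_from(np.ones(96)), SignatureSet(signatures=[]))

    def test_constraints_always_satisfied(self, rng):
        sigs = simulate_signatures(4, seed=3)
        Q = SignatureSet(signatures=sigs)
        S = Q.matrix()
        for _ in range(25):
            total = int(rng.integers(1, 5000))
            counts = rng.multinomial(total, S @ rng.dirichlet(np.ones(4)))
            exposure = fit_exposures(catalogue_from(counts), Q)
            values = np.array(list(exposure.exposures.values()))
            assert (values >= 0).all()
            assert (values <= total + 1e-6).all()
            assert values.sum() == pytest.approx(total, rel=1e-9)

    def test_objective_at_most_integer_grid_minimum(self, rng):
        """Exhaustive-enumeration oracle: no integer split beats the solver."""
        for _ in range(10):
            k = int(rng.integers(2, 4))
            total = int(rng.integers(5, 41))
            sigs = simulate_signatures(k, seed=rng)
            Q = SignatureSet(signatures=sigs)
            S = Q.matrix()
            counts = rng.multinomial(total, S @ rng.dirichlet(np.ones(k)))
            exposure = fit_exposures(catalogue_from(counts), Q)
            best = min(
                np.linalg.norm(counts - S @ np.array(split, dtype=float))
                for split in itertools.product(range(total + 1), repeat=k - 1)
                if sum(split) <= total
                for split in [list(split) + [total - sum(split)]]
            )
            assert exposure.residual_norm <= best + 1e-6

    def test_invariant_to_signature_rescaling(self, rng):
        """Signatures are densities on load, so uniform rescaling is a no-op."""
        raw = rng.dirichlet(np.ones(96), size=3)
        a = SignatureSet(signatures=[Signature(f"s{i}", v) for i, v in enumerate(raw)])
        b = SignatureSet(signatures=[Signature(f"s{i}", 7.5 * v) for i, v in enumerate(raw)])
        counts = rng.multinomial(500, raw.T @ np.array([0.2, 0.5, 0.3]))
        ea = fit_exposures(catalogue_from(counts), a)
        eb = fit_exposures(catalogue_from(counts), b)
        assert ea.exposures == pytest.approx(eb.exposures, rel=1e-9)


class TestPresenceCall:
    def test_boundaries(self, disjoint_signatures):
        counts = np.zeros(96, dtype=int)
        counts[:48] = 2  # total 96, all signature s1
        exposure = fit_exposures(catalogue_from(counts), disjoint_signatures)
        assert call_signature_present(exposure, "s1")
        assert not call_signature_present(exposure, "s2")
        assert not call_signature_present(exposure, "s1", min_mutations=1e9)
        with pytest.raises(KeyError):
            call_signature_present(exposure, "nope")

    def test_nine_below_ten_boundary(self, disjoint_signatures):
        counts = np.zeros(96, dtype=int)
        counts[:48] = 48  # 2304 total; give s2 a small share via mixture
        exposure = fit_exposures(
            catalogue_from(counts), disjoint_signatures.subset(["s1"])
        )
        exposure.exposures = {"s1": exposure.total - 9.0, "s2": 9.0}
        assert not call_signature_present(exposure, "s2", min_mutations=10, min_fraction=0.0)


class TestFitCohort:
    def test_single_sample_reduces_to_fit_exposures(self, disjoint_signatures):
        import pandas as pd

        counts = np.zeros(96, dtype=int)
        counts[:48] = 10
        matrix = pd.DataFrame({"only": counts})
        cohort = fit_cohort(matrix, None, disjoint_signatures)
        single = fit_exposures(catalogue_from(counts), disjoint_signatures)
        assert cohort[0].exposures == pytest.approx(single.exposures)

    def test_sample_order_permutation(self):
        sigs = simulate_signatures(3, seed=20)
        config = SimulationConfig(
            n_samples=10, signature_of_interest=None, burden_sigma=0.0, seed=21
        )
        matrix, _ = simulate_cohort(config, sigs)
        registry = SignatureSet(signatures=sigs)
        forward = {e.sample_id: e.exposures for e in fit_cohort(matrix, None, registry)}
        shuffled = matrix[matrix.columns[::-1]]
        backward = {e.sample_id: e.exposures for e in fit_cohort(shuffled, None, registry)}
        assert forward == backward

    def test_recovery_error_shrinks_with_mutation_count(self):
        """More mutations per sample means better exposure recovery."""
        sigs = simulate_signatures(3, min_pairwise_cosine_distance=0.7, seed=22)
        registry = SignatureSet(signatures=sigs)
        errors = []
        for burden in (1_000, 100_000):
            config = SimulationConfig(
                n_samples=25, burden_mu=np.log(burden), burden_sigma=0.0,
                signature_of_interest=None, sparsity=0.0, seed=23,
            )
            matrix, truth = simulate_cohort(config, sigs)
            exposures = fit_cohort(matrix, None, registry)
            err = np.mean(
                [
                    np.abs(
                        np.array([e.exposures[s.name] for s in sigs])
                        - truth.true_exposures[e.sample_id].to_numpy()
                    ).sum() / e.total
                    for e in exposures
                ]
            )
            errors.append(err)
        assert errors[1] < errors[0]
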