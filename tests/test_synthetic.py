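"""Generators: selection dynamics, sequencing noise, Spec-seq and plants."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from casdms.codons import NONSENSE, SYNONYMOUS, WT_ID, enumerate_nnk_variants
from casdms.synthetic import (
    EffectConfig,
    EffectMap,
    assign_effects,
    simulate_counts,
    simulate_plant_alleles,
    simulate_screen,
    simulate_selection,
    simulate_specseq,
    specseq_fraction_probabilities,
)


def _effects(weights: dict) -> EffectMap:
    s = pd.Series(weights, dtype=float)
    return EffectMap(weights=s, aa_weights=s)


class TestSimulateSelection:
    def test_one_round_closed_form(self):
        f0 = pd.Series({"a": 0.5, "b": 0.5})
        traj = simulate_selection(f0, _effects({"a": 1.0, "b": 0.5}), 1)
        assert traj.rounds[1]["a"] == pytest.approx(2 / 3)
        assert traj.rounds[1]["b"] == pytest.approx(1 / 3)

    def test_equal_weights_leave_frequencies_unchanged(self):
        f0 = pd.Series({"a": 0.2, "b": 0.3, "c": 0.5})
        traj = simulate_selection(f0, _effects({"a": 2.0, "b": 2.0, "c": 2.0}), 4)
        for f in traj.rounds:
            assert np.allclose(f, f0)

    def test_zero_weight_is_absorbing(self):
        f0 = pd.Series({"a": 0.5, "b": 0.5})
        traj = simulate_selection(f0, _effects({"a": 0.0, "b": 1.0}), 3)
        assert all(f["a"] == 0.0 for f in traj.rounds[1:])

    def test_tables_sum_to_one(self):
        f0 = pd.Series({"a": 0.1, "b": 0.6, "c": 0.3})
        traj = simulate_selection(f0, _effects({"a": 0.2, "b": 1.0, "c": 3.0}), 4)
        assert traj.n_rounds == 4 and len(traj.rounds) == 5
        for f in traj.rounds:
            assert abs(f.sum() - 1.0) < 1e-9
            assert (f >= 0).all()

    def test_order_preserving(self):
        f0 = pd.Series({"a": 0.25, "b": 0.25, "c": 0.5})
        traj = simulate_selection(f0, _effects({"a": 1.5, "b": 0.7, "c": 1.0}), 4)
        for f in traj.rounds[1:]:
            assert f["a"] > f["b"]  # w(a) > w(b), equal start

    def test_all_zero_weights_error(self):
        f0 = pd.Series({"a": 1.0})
        with pytest.raises(ValueError, match="degenerate"):
            simulate_selection(f0, _effects({"a": 0.0}), 1)

    def test_unnormalized_input_error(self):
        with pytest.raises(ValueError, match="sum to 1"):
            simulate_selection(pd.Series({"a": 0.5}), _effects({"a": 1.0}), 1)


class TestSimulateCounts:
    def test_depth_zero(self):
        f = pd.Series({"a": 0.5, "b": 0.5})
        assert simulate_counts(f, 0, 1).sum() == 0

    def test_single_variant_gets_full_depth(self):
        assert simulate_counts(pd.Series({"a": 1.0}), 1234, 1)["a"] == 1234

    def test_multinomial_moments(self):
        # f=0.01 at depth 1e6: expectation 1e4, sigma ~ 99.5; stay within 4 sigma
        f = pd.Series({"v": 0.01, "rest": 0.99})
        draws = [simulate_counts(f, 10**6, seed)["v"] for seed in range(10)]
        sigma = np.sqrt(10**6 * 0.01 * 0.99)
        assert all(abs(d - 10**4) < 4 * sigma for d in draws)

    def test_reproducible_under_seed(self):
        f = pd.Series({"a": 0.3, "b": 0.7})
        assert simulate_counts(f, 1000, 5).equals(simulate_counts(f, 1000, 5))


class TestAssignEffects:
    def test_no_effects_config_gives_all_neutral(self, reference_small):
        variants = enumerate_nnk_variants(reference_small)
        em = assign_effects(variants, EffectConfig(0.0, 0.0, 0.0), seed=1)
        for v in variants:
            expected = 0.0 if v.consequence == NONSENSE else 1.0
            assert em.weights[v.id] == expected

    def test_synonymous_and_nonsense_are_forced(self, reference_small):
        variants = enumerate_nnk_variants(reference_small)
        em = assign_effects(variants, EffectConfig(0.3, 0.3, 0.2), seed=2)
        for v in variants:
            if v.consequence == SYNONYMOUS:
                assert em.weights[v.id] == 1.0
            elif v.consequence == NONSENSE:
                assert em.weights[v.id] == 0.0
        assert em.weights[WT_ID] == 1.0

    def test_codons_of_one_substitution_share_weight(self, reference_small):
        variants = enumerate_nnk_variants(reference_small)
        em = assign_effects(variants, EffectConfig(0.3, 0.3, 0.1), seed=3)
        for v in variants:
            if v.consequence == "missense":
                assert em.weights[v.id] == em.aa_weights[v.aa_id]

    def test_determinism(self, reference_small):
        variants = enumerate_nnk_variants(reference_small)
        a = assign_effects(variants, seed=42)
        b = assign_effects(variants, seed=42)
        assert a.weights.equals(b.weights)

    def test_invalid_fractions_rejected(self):
        with pytest.raises(ValueError):
            EffectConfig(frac_beneficial=0.8, frac_deleterious=0.5)
        with pytest.raises(ValueError):
            EffectConfig(frac_beneficial=-0.1)


class TestSimulateScreen:
    def test_bit_reproducible(self):
        a = simulate_screen(n_codons=10, depth=5000, seed=3)
        b = simulate_screen(n_codons=10, depth=5000, seed=3)
        assert a.table.counts.equals(b.table.counts)
        assert a.reference.nt_seq == b.reference.nt_seq

    def test_samples_and_depth(self, small_screen):
        assert len(small_screen.table.samples) == 6  # 3 reps x rounds {3,4}
        assert (small_screen.table.totals() == small_screen.depth).all()

    def test_neutral_expected_frequencies_stable(self, small_screen):
        # among surviving mass, w=1 variants keep equal expected frequency
        traj = small_screen.trajectory
        w = small_screen.effects.weights
        neutral = w.index[(w == 1.0)]
        r3, r4 = traj.rounds[3][neutral], traj.rounds[4][neutral]
        np.testing.assert_allclose(r4 / r4.sum(), r3 / r3.sum(), rtol=1e-9)

    def test_bottleneck_mode_differs_between_replicates(self):
        sim = simulate_screen(n_codons=5, depth=10000, bottleneck=2000, seed=4)
        c = sim.table.counts
        assert not c["rep1_round3"].equals(c["rep2_round3"])


class TestSimulateSpecseq:
    def test_perfect_match_has_zero_penalty(self, spec_truth):
        assert spec_truth.ddG([spec_truth.target_seq])[0] == 0.0

    def test_lower_penalty_binds_more_at_any_mu(self, spec_truth):
        target = spec_truth.target_seq
        # find one weak and one strong single mismatch
        entries = []
        for pos in range(3):
            for b in "ACGT":
                if b != target[pos]:
                    s = target[:pos] + b + target[pos + 1 :]
                    entries.append((spec_truth.ddG([s])[0], s))
        entries.sort()
        weak, strong = entries[0][1], entries[-1][1]
        for mu in (-2.0, 0.0, 2.0):
            probs = specseq_fraction_probabilities(
                spec_truth, [target, weak, strong], mu=mu
            )
            assert probs.loc[weak, "bound"] > probs.loc[strong, "bound"]

    def test_fraction_probabilities_normalized(self, spec_truth):
        lib = [spec_truth.target_seq, "A" + spec_truth.target_seq[1:]]
        probs = specseq_fraction_probabilities(spec_truth, lib)
        np.testing.assert_allclose(probs.sum(axis=0), 1.0, atol=1e-12)

    def test_length_mismatch_error(self, spec_truth):
        with pytest.raises(ValueError, match="length"):
            simulate_specseq(spec_truth, ["ACGT"], 100, seed=0)

    def test_reproducible(self, spec_truth):
        lib = [spec_truth.target_seq, "A" + spec_truth.target_seq[1:]]
        a = simulate_specseq(spec_truth, lib, 1000, seed=8)
        b = simulate_specseq(spec_truth, lib, 1000, seed=8)
        assert a.counts.equals(b.counts)


class TestSimulatePlants:
    def test_all_wt_profile(self):
        sim = simulate_plant_alleles(n_plants=10, profile={"WT": 1.0}, seed=1)
        for t in sim.tables:
            assert t.wt_fraction == 1.0

    def test_homozygous_profile_has_one_dominant_mutant(self):
        sim = simulate_plant_alleles(
            n_plants=10, profile={"biallelic_homozygous": 1.0}, seed=2
        )
        for t in sim.tables:
            top = max(t.alleles, key=lambda a: a.frequency)
            assert top.descriptor != "WT" and top.frequency > 0.9

    def test_frequencies_sum_to_one(self):
        sim = simulate_plant_alleles(n_plants=50, chimeric_noise=0.3, seed=3)
        for t in sim.tables:
            assert abs(sum(a.frequency for a in t.alleles) - 1.0) < 0.01

    def test_unknown_class_rejected(self):
        with pytest.raises(ValueError, match="unknown genotype classes"):
            simulate_plant_alleles(profile={"hemizygous": 1.0})


@settings(derandomize=True, max_examples=25)
@given(
    weights=st.lists(st.floats(0.1, 5.0), min_size=2, max_size=6),
    n_rounds=st.integers(1, 5),
)
def test_selection_preserves_normalization_property(weights, n_rounds):
    ids = [f"v{i}" for i in range(len(weights))]
    f0 = pd.Series(1.0 / len(ids), index=ids)
    em = _effects(dict(zip(ids, weights)))
    traj = simulate_selection(f0, em, n_rounds)
    for f in traj.rounds:
        assert abs(f.sum() - 1.0) < 1e-9
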