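"""Mismatch libraries, binding/cleavage scores, energy-model fits, logos."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest

from casdms.specificity import (
    EnergyModel,
    FitError,
    binding_energy,
    cleavage_score,
    energy_to_pwm,
    enumerate_mismatch_library,
    fit_energy_model,
    harmonic_weights,
    mismatch_class_size,
    plot_logo,
    replicate_correlation,
    write_meme,
)
from casdms.synthetic import simulate_specseq


def brute_force_library_size(target: str, k: int) -> int:
    """Oracle: enumerate all 4^L sequences and count Hamming distance <= k."""
    return sum(
        1
        for s in itertools.product("ACGT", repeat=len(target))
        if sum(a != b for a, b in zip(s, target)) <= k
    )


class TestEnumerateMismatchLibrary:
    def test_acgt_k1_has_13_sequences(self):
        assert len(enumerate_mismatch_library("ACGT", 1)) == 13

    def test_acgt_k2_has_67_sequences(self):
        assert len(enumerate_mismatch_library("ACGT", 2)) == 67

    def test_k0_is_only_the_target(self):
        lib = enumerate_mismatch_library("ACGTAC", 0)
        assert lib.sequences == ["ACGTAC"]

    @pytest.mark.parametrize("target,k", [("ACGTA", 1), ("ACGTA", 2), ("TTTACG", 2)])
    def test_matches_brute_force_hamming_enumeration(self, target, k):
        lib = enumerate_mismatch_library(target, k)
        assert len(lib) == brute_force_library_size(target, k)
        # analytic class sizes agree too
        assert len(lib) == sum(
            mismatch_class_size(len(target), j) for j in range(k + 1)
        )
        # annotations are correct Hamming distances
        for seq, n in lib.members["n_mismatches"].items():
            assert sum(a != b for a, b in zip(seq, target)) == n

    def test_sampled_mode_quota(self):
        lib = enumerate_mismatch_library(
            "ACGTACGT", 3, mode="sampled", quota_per_k=5, seed=1
        )
        counts = lib.members["n_mismatches"].value_counts()
        assert counts[0] == 1 and all(counts[k] == 5 for k in (1, 2, 3))

    def test_sampled_quota_clipped_with_warning(self):
        with pytest.warns(UserWarning, match="clipped"):
            lib = enumerate_mismatch_library(
                "ACGT", 1, mode="sampled", quota_per_k=100, seed=1
            )
        assert len(lib) == 13  # 1 + full class of 12

    def test_invalid_target_rejected(self):
        with pytest.raises(ValueError):
            enumerate_mismatch_library("ACGU", 1)


class TestBindingEnergy:
    def test_reference_scores_zero_and_known_ratio(self):
        counts = pd.DataFrame(
            {"bound": {"REF": 100, "MUT": 50}, "unbound": {"REF": 100, "MUT": 200}}
        )
        ddg = binding_energy(counts, "REF", alpha=0.0)
        assert ddg["REF"] == 0.0
        assert ddg["MUT"] == pytest.approx(math.log(4), abs=1e-12)

    def test_invariant_to_uniform_count_scaling(self):
        counts = pd.DataFrame(
            {"bound": {"REF": 80, "MUT": 20}, "unbound": {"REF": 40, "MUT": 60}}
        )
        a = binding_energy(counts, "REF", alpha=0.0)
        b = binding_energy(counts * 2, "REF", alpha=0.0)
        np.testing.assert_allclose(a, b, atol=1e-12)

    def test_missing_reference_errors(self):
        counts = pd.DataFrame({"bound": {"MUT": 5}, "unbound": {"MUT": 5}})
        with pytest.raises(KeyError, match="reference"):
            binding_energy(counts, "REF")


class TestCleavageScore:
    def test_reference_zero_and_ln10(self):
        counts = pd.DataFrame(
            {
                "mock": {"REF": 5000, "MUT": 100},
                "cleaved": {"REF": 5000, "MUT": 10},
            }
        )
        d = cleavage_score(counts, "REF", alpha=0.0)
        assert d["REF"] == 0.0
        # totals cancel against the reference anchor: d = ln(m/c) - ln(m_ref/c_ref)
        assert d["MUT"] == pytest.approx(math.log(10), abs=1e-12)
        assert d["MUT"] > 2.0  # efficiently cleaved -> strongly depleted

    def test_uncleavable_sequence_scores_negative(self):
        counts = pd.DataFrame(
            {"mock": {"REF": 100, "MUT": 100}, "cleaved": {"REF": 50, "MUT": 400}}
        )
        d = cleavage_score(counts, "REF", alpha=0.0)
        assert d["MUT"] < 0

    def test_zero_mock_totals_error(self):
        counts = pd.DataFrame({"mock": {"REF": 0}, "cleaved": {"REF": 10}})
        with pytest.raises(ValueError, match="mock totals"):
            cleavage_score(counts, "REF")


class TestFitEnergyModel:
    def test_single_mismatch_library_fits_exactly(self):
        target = "ACGT"
        lib = enumerate_mismatch_library(target, 1)
        truth = {}
        rng = np.random.default_rng(2)
        scores = {}
        for seq in lib.sequences:
            diff = [(i, b) for i, (b, t) in enumerate(zip(seq, target)) if b != t]
            if not diff:
                scores[seq] = 0.0
            else:
                (i, b) = diff[0]
                truth[(i + 1, b)] = float(rng.uniform(0.2, 3.0))
                scores[seq] = truth[(i + 1, b)]
        model = fit_energy_model(pd.Series(scores), target)
        for (pos, base), eps in truth.items():
            assert model.matrix.at[pos, base] == pytest.approx(eps, abs=1e-10)
        assert model.rmse == pytest.approx(0.0, abs=1e-10)

    def test_noiseless_round_trip_recovers_truth(self, spec_truth):
        lib = enumerate_mismatch_library(spec_truth.target_seq, 2)
        counts = simulate_specseq(
            spec_truth, lib.sequences, 10**6, seed=0, analytic=True
        )
        ddg = binding_energy(counts.counts, spec_truth.target_seq, alpha=0.0)
        model = fit_energy_model(ddg, spec_truth.target_seq)
        err = np.abs(
            model.matrix.to_numpy() - spec_truth.energy_matrix.to_numpy()
        )
        assert np.nanmean(err) < 1e-6

    def test_unobserved_parameters_are_missing_not_zero(self):
        target = "ACGT"
        scores = pd.Series({"ACGT": 0.0, "CCGT": 1.5})  # only one mismatch observed
        model = fit_energy_model(scores, target)
        assert model.matrix.at[1, "C"] == pytest.approx(1.5)
        assert np.isnan(model.matrix.at[2, "A"])
        # target bases remain exact zeros
        for i, b in enumerate(target, start=1):
            assert model.matrix.at[i, b] == 0.0

    def test_rank_deficient_design_raises(self):
        # two penalties only ever observed together cannot be separated
        scores = pd.Series({"ACGT": 0.0, "CAGT": 2.0})
        with pytest.raises(FitError, match="unidentifiable"):
            fit_energy_model(scores, "ACGT")


class TestReplicateCorrelation:
    def test_identical_replicates(self):
        s = pd.Series({"a": 1.0, "b": 2.0, "c": 0.5})
        r, n = replicate_correlation(s, s)
        assert r == pytest.approx(1.0) and n == 3

    def test_negated_replicate(self):
        s = pd.Series({"a": 1.0, "b": 2.0, "c": 0.5})
        r, _ = replicate_correlation(s, -s)
        assert r == pytest.approx(-1.0)

    def test_insufficient_overlap_errors(self):
        a = pd.Series({"a": 1.0, "b": 2.0})
        with pytest.raises(ValueError, match="shared"):
            replicate_correlation(a, a)


class TestLogoExport:
    def test_zero_energies_give_uniform_zero_information(self):
        target = "AC"
        matrix = pd.DataFrame(0.0, index=[1, 2], columns=list("ACGT"))
        pwm = energy_to_pwm(EnergyModel(target, matrix))
        np.testing.assert_allclose(pwm.probs.to_numpy(), 0.25, atol=1e-12)
        np.testing.assert_allclose(pwm.information(), 0.0, atol=1e-12)

    def test_large_penalties_make_target_modal_two_bits(self):
        target = "AC"
        matrix = pd.DataFrame(10.0, index=[1, 2], columns=list("ACGT"))
        matrix.at[1, "A"] = 0.0
        matrix.at[2, "C"] = 0.0
        pwm = energy_to_pwm(EnergyModel(target, matrix))
        assert pwm.probs.at[1, "A"] > 0.999
        assert (pwm.information() > 1.99).all()

    def test_rows_sum_to_one_and_missing_positions_uniform(self):
        target = "AC"
        matrix = pd.DataFrame(1.0, index=[1, 2], columns=list("ACGT"))
        matrix.at[1, "A"] = 0.0
        matrix.at[2, "C"] = 0.0
        matrix.at[2, "G"] = np.nan
        pwm = energy_to_pwm(EnergyModel(target, matrix))
        np.testing.assert_allclose(pwm.probs.sum(axis=1), 1.0, atol=1e-12)
        assert pwm.missing_positions == [2]
        np.testing.assert_allclose(pwm.probs.loc[2], 0.25, atol=1e-12)

    def test_meme_export_round_trips(self, tmp_path):
        target = "ACG"
        matrix = pd.DataFrame(
            np.random.default_rng(1).uniform(0, 2, (3, 4)),
            index=[1, 2, 3],
            columns=list("ACGT"),
        )
        for i, b in enumerate(target, start=1):
            matrix.at[i, b] = 0.0
        pwm = energy_to_pwm(EnergyModel(target, matrix))
        path = tmp_path / "model.meme"
        write_meme(pwm, path, name="test_motif")
        text = path.read_text()
        assert text.startswith("MEME version 4")
        assert "MOTIF test_motif" in text
        rows = [
            [float(x) for x in line.split()]
            for line in text.splitlines()
            if line and line[0].isdigit()
        ]
        np.testing.assert_allclose(
            np.array(rows), pwm.probs.to_numpy(), atol=5e-7
        )

    def test_logo_rendering_writes_file(self, tmp_path, spec_truth):
        model = EnergyModel(spec_truth.target_seq, spec_truth.energy_matrix)
        out = tmp_path / "logo.png"
        plot_logo(model, out, title="binding")
        assert out.stat().st_size > 0


def test_harmonic_weights_are_harmonic_means():
    counts = pd.DataFrame({"bound": {"s": 100}, "unbound": {"s": 50}})
    w = harmonic_weights(counts, ("bound", "unbound"), alpha=0.0)
    assert w["s"] == pytest.approx(2 / (1 / 100 + 1 / 50))
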