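"""Spike-in calibration and the truncated-Poisson mean-ribosome-load fit."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from transdyn import (
    SimConfig,
    absolute_counts,
    estimate_loads,
    fit_poisson_load,
    fraction_probabilities,
    load_pmf,
    mrl_truncated,
    per_nucleotide_load,
    simulate_fraction_table,
)


def make_table(rows):
    return pd.DataFrame(rows, columns=["gene_id", "fraction_label", "replicate", "tpm", "is_spikein"])


def renorm_pmf_oracle(lam: float) -> np.ndarray:
    p = np.array([lam ** k / math.factorial(k) * math.exp(-lam) for k in range(11)])
    return p / p.sum()


class TestAbsoluteCounts:
    def test_methods_formula(self):
        table = make_table([
            ("g1", "1", 1, 500.0, False),
            ("g2", "1", 1, 0.0, False),
            ("spike", "1", 1, 1e5, True),
        ])
        out = absolute_counts(table, spikein_total=1000).set_index("gene_id")["molecules"]
        assert out["g1"] == pytest.approx(5.0)
        assert out["g2"] == 0.0

    def test_invariant_to_common_fraction_rescaling(self):
        cfg = SimConfig(seed=10, n_genes=5, n_replicates=1, depth=2e4)
        table, _ = simulate_fraction_table(cfg)
        base = absolute_counts(table, cfg.n_spikein_molecules)
        scaled = table.copy()
        one = scaled["fraction_label"] == "3"
        scaled.loc[one, "tpm"] *= 7.5
        out = absolute_counts(scaled, cfg.n_spikein_molecules)
        pd.testing.assert_frame_equal(base, out)

    def test_zero_spikein_fraction_dropped(self, caplog):
        table = make_table([
            ("g1", "1", 1, 500.0, False),
            ("g1", "2", 1, 400.0, False),
            ("spike", "1", 1, 1e5, True),
            ("spike", "2", 1, 0.0, True),
        ])
        out = absolute_counts(table, 1000)
        assert set(out["fraction_label"]) == {"1"}

    def test_missing_spikeins_rejected(self):
        table = make_table([("g1", "1", 1, 500.0, False)])
        with pytest.raises(ValueError, match="spike-in"):
            absolute_counts(table, 1000)


class TestFractionProbabilities:
    def test_free_and_40S_merge_into_k0(self):
        counts = pd.DataFrame({
            "gene_id": ["g"] * 3,
            "fraction_label": ["free", "40S", "1"],
            "replicate": [1, 1, 1],
            "molecules": [2.0, 3.0, 5.0],
        })
        p = fraction_probabilities(counts)
        assert p["p0"].iloc[0] == pytest.approx(0.5)
        assert p["p1"].iloc[0] == pytest.approx(0.5)
        assert p[[f"p{k}" for k in range(11)]].iloc[0].sum() == pytest.approx(1.0, abs=1e-9)

    def test_label_keyed_not_order_keyed(self):
        counts = pd.DataFrame({
            "gene_id": ["g"] * 4,
            "fraction_label": ["free", "2", "40S", "1"],
            "replicate": 1,
            "molecules": [1.0, 4.0, 1.0, 2.0],
        })
        p1 = fraction_probabilities(counts)
        p2 = fraction_probabilities(counts.sample(frac=1.0, random_state=0))
        pd.testing.assert_frame_equal(p1, p2)

    def test_all_zero_gene_excluded(self):
        counts = pd.DataFrame({
            "gene_id": ["dead"] * 2 + ["live"] * 2,
            "fraction_label": ["free", "1"] * 2,
            "replicate": 1,
            "molecules": [0.0, 0.0, 1.0, 1.0],
        })
        p = fraction_probabilities(counts)
        assert list(p["gene_id"]) == ["live"]


class TestPoissonFit:
    def test_recovers_lambda_from_exact_renormalized_pmf(self):
        """Fit vs an independent brute-force grid oracle on the factorial-
        formula pmf renormalized over k = 0..10."""
        p = renorm_pmf_oracle(3.0)
        lam, chi2, flags = fit_poisson_load(p, tail="renormalize")
        assert lam == pytest.approx(3.0, abs=1e-3)
        # brute force at step 1e-4
        grid = np.arange(2.9, 3.1, 1e-4)
        scores = []
        for g in grid:
            q = renorm_pmf_oracle(g)
            scores.append((((p - q) ** 2) / q).sum())
        assert lam == pytest.approx(grid[int(np.argmin(scores))], abs=2e-4)
        assert chi2 < 1e-10

    @pytest.mark.parametrize("lam", [0.1, 0.5, 2.0, 5.0, 8.0, 9.9])
    @pytest.mark.parametrize("tail", ["collapse", "renormalize"])
    def test_self_consistent_on_exact_pmf(self, lam, tail):
        lhat, _, _ = fit_poisson_load(load_pmf(lam, tail=tail), tail=tail)
        assert lhat == pytest.approx(lam, abs=1e-3)

    def test_all_mass_at_zero_is_degenerate(self):
        p = np.zeros(11)
        p[0] = 1.0
        lam, chi2, flags = fit_poisson_load(p)
        assert lam == 0.0 and chi2 == 0.0 and flags == "degenerate"

    def test_rejects_bad_vectors(self):
        with pytest.raises(ValueError):
            fit_poisson_load(np.ones(11))
        with pytest.raises(ValueError):
            fit_poisson_load(np.ones(5) / 5)

    @given(st.floats(min_value=0.05, max_value=9.5))
    @settings(max_examples=25, deadline=None)
    def test_self_consistency_property(self, lam):
        lhat, _, _ = fit_poisson_load(load_pmf(lam))
        assert abs(lhat - lam) < 1e-3


class TestTruncatedMean:
    def test_weighted_mean_examples(self):
        p = np.zeros(11)
        p[1] = p[2] = 0.5
        assert mrl_truncated(p) == pytest.approx(1.5)
        p0 = np.zeros(11)
        p0[0] = 1.0
        assert mrl_truncated(p0) == 0.0

    def test_matches_lambda_when_tail_negligible(self):
        for lam in (0.5, 1.0, 2.0):
            assert mrl_truncated(load_pmf(lam)) == pytest.approx(lam, rel=5e-3)

    def test_never_exceeds_poisson_lambda_on_exact_pmf(self):
        """The truncated mean saturates below the true load once tail mass
        beyond the resolved fractions appears."""
        for lam in np.arange(0.5, 10.0, 0.5):
            m = mrl_truncated(load_pmf(lam))
            assert m <= 10.0
            assert m <= lam + 1e-9

    @given(st.lists(st.floats(min_value=0.0, max_value=1.0), min_size=11, max_size=11))
    @settings(max_examples=50, deadline=None)
    def test_bounded_by_support(self, raw):
        total = sum(raw)
        if total == 0:
            return
        p = np.array(raw) / total
        assert 0.0 <= mrl_truncated(p) <= 10.0


class TestPerNucleotideLoad:
    def test_arithmetic(self):
        assert per_nucleotide_load(4.0, 2000) == pytest.approx(0.002)
        assert per_nucleotide_load(0.0, 1500) == 0.0
        assert per_nucleotide_load(4.0, 1000) == pytest.approx(2 * per_nucleotide_load(4.0, 2000))

    def test_missing_length_gives_none(self):
        assert per_nucleotide_load(4.0, None) is None


class TestEndToEnd:
    def test_recovery_on_simulated_fractions(self):
        lambdas = np.repeat([0.5, 1.0, 2.0, 4.0, 8.0], 8)
        cfg = SimConfig(seed=21, n_replicates=1)
        table, truth = simulate_fraction_table(cfg, lambdas=lambdas)
        est = estimate_loads(table, cfg.n_spikein_molecules)
        m = est.merge(truth, on="gene_id")
        rel = (m["lambda"] - m["truth_lambda"]).abs() / m["truth_lambda"]
        assert rel.median() < 0.05

    def test_pooled_and_per_replicate_agree_noise_free(self):
        cfg = SimConfig(seed=22, n_genes=5, fraction_noise="none", n_replicates=2)
        table, truth = simulate_fraction_table(cfg)
        per_rep = estimate_loads(table, cfg.n_spikein_molecules, pool_replicates=False)
        pooled = estimate_loads(table, cfg.n_spikein_molecules, pool_replicates=True)
        merged = per_rep.merge(pooled, on="gene_id", suffixes=("_rep", "_pool"))
        np.testing.assert_allclose(merged["lambda_rep"], merged["lambda_pool"], atol=1e-4)

    def test_per_nt_column_present_with_lengths(self):
        cfg = SimConfig(seed=23, n_genes=3, fraction_noise="none", n_replicates=1)
        table, truth = simulate_fraction_table(cfg)
        lengths = pd.Series(2000.0, index=truth["gene_id"])
        est = estimate_loads(table, cfg.n_spikein_molecules, lengths=lengths)
        np.testing.assert_allclose(est["mrl_per_nt"], est["lambda"] / 2000.0)
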