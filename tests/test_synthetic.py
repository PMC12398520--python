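"""The generators must invert exactly under their own closed forms."""

import math

import numpy as np
import pandas as pd
import pandas.testing as pdt
import pytest

from transdyn import (
    InvalidConfigError,
    SimConfig,
    simulate_footprints,
    simulate_fraction_table,
    simulate_psilac,
    simulate_runoff_coverage,
)
from transdyn.polysome import absolute_counts


def poisson_pmf_oracle(lam: float, k: int) -> float:
    """Independent factorial-formula evaluation of the Poisson pmf."""
    return lam ** k / math.factorial(k) * math.exp(-lam)


def collapsed_pmf_oracle(lam: float) -> np.ndarray:
    p = np.array([poisson_pmf_oracle(lam, k) for k in range(11)])
    p[10] = 1.0 - sum(poisson_pmf_oracle(lam, k) for k in range(10))
    return p


class TestFractionTable:
    def test_noise_free_fractions_match_poisson_pmf(self):
        """With expected counts, per-fraction molecule proportions equal the
        tail-collapsed Poisson pmf evaluated by the factorial formula."""
        cfg = SimConfig(seed=7, n_genes=1, fraction_noise="none", n_replicates=1)
        table, truth = simulate_fraction_table(cfg, lambdas=[2.0])
        counts = absolute_counts(table, cfg.n_spikein_molecules)
        counts["k"] = counts["fraction_label"].map({"free": 0, "40S": 0, **{str(k): k for k in range(1, 11)}})
        p = counts.groupby("k")["molecules"].sum()
        p = (p / p.sum()).to_numpy()
        np.testing.assert_allclose(p, collapsed_pmf_oracle(2.0), rtol=1e-9)

    def test_fixed_seed_reproducible(self):
        cfg = dict(seed=1, n_genes=5, n_replicates=1, depth=5e3)
        t1, tr1 = simulate_fraction_table(SimConfig(**cfg))
        t2, tr2 = simulate_fraction_table(SimConfig(**cfg))
        pdt.assert_frame_equal(t1, t2)
        pdt.assert_frame_equal(tr1, tr2)

    def test_lambda_zero_puts_all_endogenous_mass_at_k0(self):
        cfg = SimConfig(seed=3, n_genes=4, fraction_noise="none", n_replicates=1)
        table, _ = simulate_fraction_table(cfg, lambdas=[0.0] * 4)
        endo = table[~table["is_spikein"]]
        poly = endo[~endo["fraction_label"].isin(["free", "40S"])]
        assert (poly["tpm"] == 0).all()
        # polysome fractions then contain spike-in material only
        spike = table[table["is_spikein"] & ~table["fraction_label"].isin(["free", "40S"])]
        sums = spike.groupby(["fraction_label", "replicate"])["tpm"].sum()
        np.testing.assert_allclose(sums.to_numpy(), 1e6, rtol=1e-9)

    def test_molecule_totals_conserved_and_spikeins_equal(self):
        cfg = SimConfig(seed=5, n_genes=8, fraction_noise="none", n_replicates=1)
        table, truth = simulate_fraction_table(cfg)
        counts = absolute_counts(table, cfg.n_spikein_molecules)
        recovered = counts.groupby("gene_id")["molecules"].sum()
        expected = truth.set_index("gene_id")["truth_molecules"].astype(float)
        np.testing.assert_allclose(
            recovered[expected.index].to_numpy(), expected.to_numpy(), rtol=1e-6
        )

    def test_lambda_range_outside_unit_interval_rejected(self):
        with pytest.raises(InvalidConfigError):
            SimConfig(lambda_range=(0.5, 12.0))
        cfg = SimConfig(seed=0, n_genes=1)
        with pytest.raises(InvalidConfigError):
            simulate_fraction_table(cfg, lambdas=[11.0])


class TestPsilac:
    def test_noise_free_decay_matches_closed_form(self):
        cfg = SimConfig(seed=2, psilac_cv=0.0, psilac_times=(0.0, 100.0))
        series, truth = simulate_psilac(cfg, k_values=[0.01])
        for _, pep in series.groupby("peptide_id"):
            i0 = pep.loc[pep["time_min"] == 0, "intensity"].iloc[0]
            i100 = pep.loc[pep["time_min"] == 100, "intensity"].iloc[0]
            assert i100 / i0 == pytest.approx(math.exp(-1.0), rel=1e-12)

    def test_peptides_share_protein_rate_but_not_amplitude(self):
        cfg = SimConfig(seed=9, psilac_cv=0.0, psilac_max_peptides=10)
        series, truth = simulate_psilac(cfg, k_values=[0.02] * 3)
        t = np.asarray(cfg.psilac_times)
        for _, pep in series.groupby("peptide_id"):
            y = pep.sort_values("time_min")["intensity"].to_numpy()
            khat = -np.polyfit(t, np.log(y), 1)[0]
            assert khat == pytest.approx(0.02, rel=1e-9)
        amps = series[series["time_min"] == 0].groupby("peptide_id")["intensity"].first()
        assert amps.nunique() == len(amps)

    def test_non_increasing_times_rejected(self):
        with pytest.raises(InvalidConfigError):
            SimConfig(psilac_times=(0.0, 10.0, 10.0))


class TestRunoff:
    @pytest.mark.parametrize("tau,front", [(80.0, 400), (180.0, 900)])
    def test_front_at_rate_times_time(self, tau, front):
        cfg = SimConfig(seed=4, runoff_rate=5.0, runoff_times=(0.0, tau),
                        n_runoff_genes=2, n_replicates=1, runoff_noise_floor=0.05)
        cov = simulate_runoff_coverage(cfg)
        for _, g in cov[cov["time_s"] == tau].groupby("gene_id"):
            g = g.sort_values("codon_index")
            base = g["coverage"].iloc[-1]
            np.testing.assert_allclose(g.loc[g["codon_index"] < front, "coverage"], 0.05 * base)
            np.testing.assert_allclose(g.loc[g["codon_index"] >= front, "coverage"], base)

    def test_time_zero_profile_is_flat(self):
        cfg = SimConfig(seed=4, n_runoff_genes=2, n_replicates=1)
        cov = simulate_runoff_coverage(cfg)
        for _, g in cov[cov["time_s"] == 0].groupby("gene_id"):
            assert g["coverage"].nunique() == 1

    def test_zero_rate_rejected(self):
        with pytest.raises(InvalidConfigError):
            SimConfig(runoff_rate=0.0)


class TestFootprints:
    def test_offset_map_inverts_placement(self):
        """With a single length class the stated offset recovers the sampled
        A-site codon from the 5' position exactly."""
        cfg = SimConfig(seed=6, n_footprints=2000, n_transcripts=5,
                        cds_length_range=(100, 150),
                        footprint_length_probs={29: 1.0}, psite_offsets={29: 12})
        transcripts, models, fps = simulate_footprints(cfg)
        utr5 = models.set_index("transcript_id")["utr5_len"]
        asite = (fps["pos5"] + 12 + 3 - fps["transcript_id"].map(utr5)) // 3
        assert (asite == fps["asite_codon"]).all()

    def test_fixed_seed_reproducible(self):
        cfg = dict(seed=8, n_footprints=500, n_transcripts=3, cds_length_range=(60, 80))
        _, m1, f1 = simulate_footprints(SimConfig(**cfg))
        _, m2, f2 = simulate_footprints(SimConfig(**cfg))
        pdt.assert_frame_equal(f1, f2)
        pdt.assert_frame_equal(m1, m2)

    def test_cds_lengths_are_codon_multiples(self):
        cfg = SimConfig(seed=8, n_footprints=100, n_transcripts=4, cds_length_range=(60, 80))
        _, models, _ = simulate_footprints(cfg)
        assert (models["cds_len"] % 3 == 0).all()
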