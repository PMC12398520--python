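"""Synthetic data with known ground truth for every estimator in the package.

Each generator emits tables with exactly the statistical structure the
corresponding estimator assumes — Poisson ribosome loads partitioned into
polysome fractions with equal spike-in totals, exponentially decaying heavy
peptide intensities, a run-off coverage front advancing at a fixed codon/s
rate, and footprints placed with length-dependent P-site offsets — together
with a truth table of the generating parameters.
"""

from __future__ import annotations

import itertools
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import poisson

from .config import FRACTION_LABELS, K_MAX, InvalidConfigError, SimConfig

STOP_CODONS = ("TAA", "TAG", "TGA")
#: The 61 sense codons, lexicographically ordered.
SENSE_CODONS: tuple[str, ...] = tuple(
    c for c in ("".join(t) for t in itertools.product("ACGT", repeat=3)) if c not in STOP_CODONS
)


def _rng(config: SimConfig, rng: np.random.Generator | None, salt: int) -> np.random.Generator:
    """Per-generator stream: independent simulators from one config seed."""
    if rng is not None:
        return rng
    return np.random.default_rng(np.random.SeedSequence([int(config.seed), salt]))


def truncated_load_pmf(lam: float | np.ndarray, k_max: int = K_MAX) -> np.ndarray:
    """Probability of k = 0..k_max ribosomes, with mass above k_max pooled
    into the last bin (the deepest resolved polysome fraction collects
    everything heavier)."""
    lam = np.atleast_1d(np.asarray(lam, dtype=float))
    k = np.arange(k_max + 1)
    p = poisson.pmf(k[None, :], lam[:, None])
    p[:, k_max] = poisson.sf(k_max - 1, lam)
    return np.squeeze(p)


# ---------------------------------------------------------------------------
# polysome fractions
# ---------------------------------------------------------------------------

def simulate_fraction_table(
    config: SimConfig,
    lambdas: Sequence[float] | None = None,
    rng: np.random.Generator | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate spike-in-annotated TPM tables over polysome fractions.

    Per gene a total mRNA molecule count is drawn, molecules are assigned to
    fractions according to the Poisson(lambda) load distribution (mass at
    k >= 11 pooled into fraction 10, the k = 0 mass split between the free
    and 40S fractions), an identical spike-in total S is added to every
    fraction, and TPMs are computed per fraction library — either from
    expected counts (``fraction_noise="none"``) or after multinomial read
    resampling at the configured depth.

    Returns
    -------
    (table, truth)
        ``table``: long DataFrame with columns gene_id, fraction_label,
        replicate, tpm, is_spikein. ``truth``: gene_id, truth_lambda,
        truth_molecules.
    """
    config.validate()
    rng = _rng(config, rng, salt=1)
    n = config.n_genes
    if lambdas is None:
        lam = rng.uniform(*config.lambda_range, size=n)
    else:
        lam = np.asarray(list(lambdas), dtype=float)
        if lam.min() < 0 or lam.max() > 10:
            raise InvalidConfigError("lambda values must lie within [0, 10]")
        n = lam.size
    gene_ids = np.array([f"gene{i:05d}" for i in range(n)])
    spike_ids = np.array([f"SIRV{i:03d}" for i in range(config.n_spikein_species)])

    totals = np.maximum(1, np.round(rng.lognormal(np.log(1e4), 1.0, size=n))).astype(np.int64)
    pmf = np.atleast_2d(truncated_load_pmf(lam))

    noise = config.fraction_noise != "none"
    labels = list(config.fraction_labels)
    n_frac = len(labels)
    # molecule counts per gene x physical fraction (free, 40S, 1..10)
    mol = np.zeros((n, n_frac))
    if noise:
        counts_k = np.empty((n, K_MAX + 1), dtype=np.int64)
        for i in range(n):
            counts_k[i] = rng.multinomial(totals[i], pmf[i])
        free = rng.binomial(counts_k[:, 0], 0.5)
    else:
        counts_k = totals[:, None] * pmf
        free = counts_k[:, 0] / 2.0
    mol[:, 0] = free
    mol[:, 1] = counts_k[:, 0] - free
    mol[:, 2:] = counts_k[:, 1:]

    spike_per_species = np.full(config.n_spikein_species, config.n_spikein_molecules / config.n_spikein_species)

    rows = []
    for j, label in enumerate(labels):
        frac_mol = np.concatenate([mol[:, j], spike_per_species])
        frac_total = frac_mol.sum()
        for rep in range(1, config.n_replicates + 1):
            if noise and frac_total > 0:
                reads = rng.multinomial(int(round(config.depth)), frac_mol / frac_total)
                tpm = reads / reads.sum() * 1e6
            else:
                tpm = frac_mol / frac_total * 1e6 if frac_total > 0 else np.zeros_like(frac_mol)
            rows.append(pd.DataFrame({
                "gene_id": np.concatenate([gene_ids, spike_ids]),
                "fraction_label": label,
                "replicate": rep,
                "tpm": tpm,
                "is_spikein": np.concatenate([np.zeros(n, bool), np.ones(config.n_spikein_species, bool)]),
            }))
    table = pd.concat(rows, ignore_index=True)
    truth = pd.DataFrame({"gene_id": gene_ids, "truth_lambda": lam, "truth_molecules": totals})
    return table, truth


# ---------------------------------------------------------------------------
# pSILAC
# ---------------------------------------------------------------------------

def simulate_psilac(
    config: SimConfig,
    k_values: Sequence[float] | None = None,
    rng: np.random.Generator | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate heavy-peptide intensity time courses.

    Each protein gets a true accumulation rate k (log-uniform over
    ``psilac_k_range`` unless ``k_values`` is given) shared by its 1..max
    peptides; each peptide decays as I0 * exp(-k t) with a peptide-specific
    amplitude I0 and multiplicative log-normal noise of the configured CV.

    Returns ``(series, truth)`` where ``series`` has columns protein_id,
    peptide_id, label, replicate, time_min, intensity and ``truth`` has
    protein_id, truth_k.
    """
    config.validate()
    rng = _rng(config, rng, salt=2)
    t = np.asarray(config.psilac_times, dtype=float)
    if k_values is None:
        lo, hi = config.psilac_k_range
        k = np.exp(rng.uniform(np.log(lo), np.log(hi), size=config.psilac_n_proteins))
    else:
        k = np.asarray(list(k_values), dtype=float)
    n_prot = k.size
    sigma = np.sqrt(np.log1p(config.psilac_cv ** 2))

    recs = []
    for i in range(n_prot):
        pid = f"P{i:05d}"
        n_pep = int(rng.integers(1, config.psilac_max_peptides + 1))
        for j in range(n_pep):
            i0 = rng.lognormal(np.log(1e5), 1.0)
            clean = i0 * np.exp(-k[i] * t)
            if sigma > 0:
                noise = rng.lognormal(-sigma ** 2 / 2, sigma, size=t.size)
            else:
                noise = np.ones_like(t)
            label = "heavy-K" if rng.random() < 0.5 else "heavy-R"
            recs.append(pd.DataFrame({
                "protein_id": pid,
                "peptide_id": f"{pid}_pep{j}",
                "label": label,
                "replicate": 1,
                "time_min": t,
                "intensity": clean * noise,
            }))
    series = pd.concat(recs, ignore_index=True)
    truth = pd.DataFrame({"protein_id": [f"P{i:05d}" for i in range(n_prot)], "truth_k": k})
    return series, truth


# ---------------------------------------------------------------------------
# harringtonine run-off coverage
# ---------------------------------------------------------------------------

def simulate_runoff_coverage(
    config: SimConfig,
    rate: float | None = None,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Simulate per-codon footprint coverage during a run-off time course.

    At time tau after the initiation block the region upstream of the front
    at ``rate * tau`` codons is depleted to ``runoff_noise_floor`` of the
    gene's baseline; beyond the front, coverage stays at baseline. The
    tau = 0 profile is uniform. Long-format DataFrame: gene_id, codon_index,
    coverage, time_s, replicate.
    """
    config.validate()
    rng = _rng(config, rng, salt=3)
    v = float(rate if rate is not None else config.runoff_rate)
    if v <= 0:
        raise InvalidConfigError("run-off rate must be positive")
    lo, hi = config.cds_length_range
    lengths = rng.integers(lo, hi + 1, size=config.n_runoff_genes)
    baselines = rng.lognormal(np.log(2.0), 0.5, size=config.n_runoff_genes)
    sigma = np.sqrt(np.log1p(config.runoff_cv ** 2))

    frames = []
    for g in range(config.n_runoff_genes):
        pos = np.arange(lengths[g])
        for tau in config.runoff_times:
            front = v * tau
            prof = np.where(pos < front, config.runoff_noise_floor, 1.0) * baselines[g]
            for rep in range(1, config.n_replicates + 1):
                cov = prof
                if sigma > 0:
                    cov = prof * rng.lognormal(-sigma ** 2 / 2, sigma, size=prof.size)
                frames.append(pd.DataFrame({
                    "gene_id": f"gene{g:04d}",
                    "codon_index": pos,
                    "coverage": cov,
                    "time_s": tau,
                    "replicate": rep,
                }))
    return pd.concat(frames, ignore_index=True)


# ---------------------------------------------------------------------------
# footprints + CDS sequences
# ---------------------------------------------------------------------------

def simulate_footprints(
    config: SimConfig,
    rng: np.random.Generator | None = None,
) -> tuple[dict[str, str], pd.DataFrame, pd.DataFrame]:
    """Simulate transcripts and ribosome footprints with known placement.

    Transcripts are a 5'UTR, a CDS (ATG + random sense codons + TAA, length
    in ``cds_length_range`` codons), and a 3'UTR. Footprints are drawn by
    sampling an A-site codon (weight = transcript abundance x per-codon dwell
    weight, with an initiation-proximal bonus on the first decoded codon),
    a read length from ``footprint_length_probs``, and placing the 5' end at
    ``utr5 + 3*codon - (psite_offset + 3)`` so the stated length->offset map
    inverts the construction exactly (up to optional +-1 nt frame jitter).

    Returns
    -------
    (transcripts, models, footprints)
        ``transcripts``: transcript_id -> full transcript sequence.
        ``models``: transcript_id, utr5_len, cds_len, utr3_len (nt).
        ``footprints``: transcript_id, pos5, length, asite_codon (the truth
        column used by recovery tests).
    """
    config.validate()
    rng = _rng(config, rng, salt=4)
    n_tx = config.n_transcripts
    lo, hi = config.cds_length_range
    cds_codons = rng.integers(lo, hi + 1, size=n_tx)
    tx_ids = [f"tx{i:04d}" for i in range(n_tx)]
    tx_weight = rng.lognormal(0.0, 1.0, size=n_tx)

    sense = np.array(SENSE_CODONS)
    weight_lookup = np.array([float(config.codon_weights.get(c, 1.0)) for c in SENSE_CODONS])

    transcripts: dict[str, str] = {}
    codon_idx_by_tx: list[np.ndarray] = []
    utr5, utr3 = config.utr5_length, config.utr3_length
    bases = np.array(list("ACGT"))
    slot_tx, slot_codon, slot_w = [], [], []
    for i, tx in enumerate(tx_ids):
        body_idx = rng.integers(0, len(SENSE_CODONS), size=cds_codons[i] - 2)
        codon_idx_by_tx.append(body_idx)
        cds = "ATG" + "".join(sense[body_idx]) + "TAA"
        u5 = "".join(rng.choice(bases, size=utr5)) if utr5 else ""
        u3 = "".join(rng.choice(bases, size=utr3)) if utr3 else ""
        transcripts[tx] = u5 + cds + u3
        # eligible A-site codons: 1 .. L-2 (not the start, not the stop)
        w = weight_lookup[body_idx] * tx_weight[i]
        w[0] *= config.footprint_start_bias
        slot_tx.append(np.full(w.size, i, dtype=np.int32))
        slot_codon.append(np.arange(1, cds_codons[i] - 1, dtype=np.int32))
        slot_w.append(w)

    slot_tx = np.concatenate(slot_tx)
    slot_codon = np.concatenate(slot_codon)
    p = np.concatenate(slot_w)
    p = p / p.sum()

    pick = rng.choice(p.size, size=config.n_footprints, p=p)
    tx_i = slot_tx[pick]
    a_codon = slot_codon[pick]

    lens = np.array(sorted(config.footprint_length_probs))
    lp = np.array([config.footprint_length_probs[int(l)] for l in lens], dtype=float)
    lp = lp / lp.sum()
    length = rng.choice(lens, size=config.n_footprints, p=lp)
    offset = np.array([config.psite_offsets[int(l)] for l in lens])
    off_by_len = dict(zip(lens.tolist(), offset.tolist()))
    asite_off = np.vectorize(off_by_len.get)(length) + 3

    pos5 = utr5 + 3 * a_codon - asite_off
    if config.frame_jitter > 0:
        j = config.frame_jitter
        pos5 = pos5 + rng.choice([-1, 0, 1], size=pos5.size, p=[j / 2, 1 - j, j / 2])

    footprints = pd.DataFrame({
        "transcript_id": np.array(tx_ids)[tx_i],
        "pos5": pos5.astype(int),
        "length": length.astype(int),
        "asite_codon": a_codon.astype(int),
    })
    models = pd.DataFrame({
        "transcript_id": tx_ids,
        "utr5_len": utr5,
        "cds_len": (3 * cds_codons).astype(int),
        "utr3_len": utr3,
    })
    return transcripts, models, footprints


def cds_sequences(transcripts: Mapping[str, str], models: pd.DataFrame) -> dict[str, str]:
    """Extract CDS sequences from full transcript sequences."""
    m = models.set_index("transcript_id")
    out = {}
    for tx, seq in transcripts.items():
        u5 = int(m.at[tx, "utr5_len"])
        c = int(m.at[tx, "cds_len"])
        out[tx] = seq[u5:u5 + c]
    return out
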