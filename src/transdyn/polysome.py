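"""Mean ribosome load (MRL) from spike-in-calibrated polysome fractions.

The gradient resolves mRNAs carrying 0 (free and 40S), 1 (80S), 2 (disome),
... up to 10 ribosomes. An equal amount S of spike-in molecules in every
fraction converts per-fraction TPMs into absolute molecule counts

    M_i^k = TPM_i^k * S / TPM_S^k,

where TPM_S^k is the summed spike-in TPM of fraction k. Normalizing M_i^k
over fractions gives the probability p_i^k that a molecule of gene i carries
k ribosomes; under a low ribosome density the loads are Poisson distributed,
and fitting the truncated Poisson pmf to p_i^k by minimum Pearson chi-square
yields the mean ribosome load lambda. The plain truncated weighted mean
sum_k k * p_k, the classical MRL estimate, is reported alongside: it
saturates for heavily loaded transcripts, which is precisely what the
Poisson fit corrects.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from functools import lru_cache
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import minimize_scalar
from scipy.stats import poisson

from .config import K_MAX

logger = logging.getLogger(__name__)

#: map from physical fraction label to ribosome count
LABEL_TO_K: dict[str, int] = {"free": 0, "40S": 0, **{str(k): k for k in range(1, K_MAX + 1)}}

_QMIN = 1e-12  # chi-square cells with smaller model mass are skipped


@dataclass
class LoadEstimate:
    """Per-gene (per-replicate) mean-ribosome-load estimate."""

    gene_id: str
    lam: float
    chi2: float
    mrl_truncated: float
    total_molecules: float
    n_fractions_used: int
    replicate: object = None
    mrl_per_nt: float | None = None
    flags: str = ""


def load_pmf(lam: float, k_max: int = K_MAX, tail: str = "collapse") -> np.ndarray:
    """Model probability of observing a molecule in fraction k = 0..k_max.

    ``tail="collapse"`` pools Poisson mass above k_max into the last bin —
    the deepest resolved fraction collects everything heavier, matching how
    the gradient is pooled. ``tail="renormalize"`` instead conditions the
    pmf on k <= k_max.
    """
    k = np.arange(k_max + 1)
    q = poisson.pmf(k, lam)
    if tail == "collapse":
        q[k_max] = poisson.sf(k_max - 1, lam)
    elif tail == "renormalize":
        s = q.sum()
        if s > 0:
            q = q / s
    else:
        raise ValueError(f"unknown tail mode {tail!r}")
    return q


def absolute_counts(table: pd.DataFrame, spikein_total: float) -> pd.DataFrame:
    """Convert per-fraction TPMs into absolute molecule counts.

    Parameters
    ----------
    table
        Long DataFrame with columns gene_id, fraction_label, replicate, tpm,
        is_spikein.
    spikein_total
        S, the known total number of spike-in molecules added to every
        fraction.

    Returns a DataFrame (gene_id, fraction_label, replicate, molecules) with
    spike-in rows removed. Fractions whose summed spike-in TPM is zero carry
    no calibration and are dropped with a warning.
    """
    required = {"gene_id", "fraction_label", "replicate", "tpm", "is_spikein"}
    missing = required - set(table.columns)
    if missing:
        raise ValueError(f"fraction table is missing columns: {sorted(missing)}")
    if not table["is_spikein"].any():
        raise ValueError("fraction table contains no spike-in rows")

    spike_tpm = (
        table[table["is_spikein"]]
        .groupby(["fraction_label", "replicate"], observed=True)["tpm"].sum()
        .rename("tpm_spike")
    )
    endo = table[~table["is_spikein"]].merge(
        spike_tpm.reset_index(), on=["fraction_label", "replicate"], how="left"
    )
    bad = endo["tpm_spike"].isna() | (endo["tpm_spike"] <= 0)
    if bad.any():
        dropped = endo.loc[bad, ["fraction_label", "replicate"]].drop_duplicates()
        logger.warning(
            "dropping %d fraction/replicate libraries with zero spike-in TPM: %s",
            len(dropped), dropped.to_records(index=False).tolist(),
        )
        endo = endo[~bad]
    endo = endo.assign(molecules=endo["tpm"] * spikein_total / endo["tpm_spike"])
    return endo[["gene_id", "fraction_label", "replicate", "molecules"]]


def fraction_probabilities(
    counts: pd.DataFrame, pool_replicates: bool = False
) -> pd.DataFrame:
    """Per-gene probability vector over k = 0..10 ribosomes.

    The two physical zero-ribosome fractions (free, 40S) are summed into the
    k = 0 bin. Replicates are kept separate unless ``pool_replicates``.
    Genes with zero total count are excluded (logged). Output is wide:
    gene_id, (replicate,) p0..p10, total_molecules, n_fractions_used; each
    row's p-vector sums to 1.
    """
    df = counts.copy()
    df["k"] = df["fraction_label"].map(LABEL_TO_K)
    if df["k"].isna().any():
        bad = sorted(df.loc[df["k"].isna(), "fraction_label"].unique())
        raise ValueError(f"unknown fraction labels: {bad}")
    keys = ["gene_id"] if pool_replicates else ["gene_id", "replicate"]
    nfrac = df.groupby(keys, observed=True)["fraction_label"].nunique().rename("n_fractions_used")
    mat = (
        df.groupby(keys + ["k"], observed=True)["molecules"].sum()
        .unstack("k", fill_value=0.0)
        .reindex(columns=range(K_MAX + 1), fill_value=0.0)
    )
    totals = mat.sum(axis=1)
    zero = totals <= 0
    if zero.any():
        logger.info("excluding %d gene(s) with zero total molecules", int(zero.sum()))
        mat, totals, nfrac = mat[~zero], totals[~zero], nfrac[~zero]
    probs = mat.div(totals, axis=0)
    probs.columns = [f"p{k}" for k in range(K_MAX + 1)]
    out = probs.reset_index()
    out["total_molecules"] = totals.values
    out["n_fractions_used"] = nfrac.reindex(mat.index).values
    return out


def _chi2(p: np.ndarray, q: np.ndarray) -> float:
    m = q > _QMIN
    return float((((p[m] - q[m]) ** 2 / q[m])).sum())


def _neg_loglik(p: np.ndarray, q: np.ndarray) -> float:
    m = (q > _QMIN) & (p > 0)
    return float(-(p[m] * np.log(q[m])).sum())


@lru_cache(maxsize=8)
def _grid_pmf(tail: str, grid_step: float) -> tuple[np.ndarray, np.ndarray]:
    """Precomputed (lambda grid, model pmf matrix) for the coarse scan."""
    grid = np.arange(0.0, 10.0 + grid_step / 2, grid_step)
    k = np.arange(K_MAX + 1)
    q = poisson.pmf(k[None, :], grid[:, None])
    if tail == "collapse":
        q[:, K_MAX] = poisson.sf(K_MAX - 1, grid)
    elif tail == "renormalize":
        q = q / q.sum(axis=1, keepdims=True)
    else:
        raise ValueError(f"unknown tail mode {tail!r}")
    return grid, q


def fit_poisson_load(
    p: Sequence[float],
    tail: str = "collapse",
    method: str = "chi2",
    grid_step: float = 0.01,
) -> tuple[float, float, str]:
    """Fit the truncated-Poisson load model to a fraction-probability vector.

    Minimizes the Pearson chi-square between ``p`` (length 11, k = 0..10)
    and the model pmf over a coarse lambda grid on [0, 10] followed by local
    refinement (|d lambda| < 1e-4); ``method="mle"`` maximizes the
    multinomial log-likelihood instead. The chi-square at the optimum is
    returned as a relative quality score; without error estimates on p it is
    not an absolute goodness-of-fit test.

    Returns ``(lam, chi2, flags)``.
    """
    p = np.asarray(p, dtype=float)
    if p.shape != (K_MAX + 1,):
        raise ValueError(f"expected a probability vector of length {K_MAX + 1}")
    if abs(p.sum() - 1.0) > 1e-6:
        raise ValueError("fraction probabilities must sum to 1")
    if p[0] >= 1.0:
        return 0.0, 0.0, "degenerate"

    obj = _chi2 if method == "chi2" else _neg_loglik if method == "mle" else None
    if obj is None:
        raise ValueError(f"unknown method {method!r}")

    grid, qmat = _grid_pmf(tail, grid_step)
    if method == "chi2":
        mask = qmat > _QMIN
        with np.errstate(divide="ignore", invalid="ignore"):
            cells = np.where(mask, (p[None, :] - qmat) ** 2 / qmat, 0.0)
        scores = cells.sum(axis=1)
    else:
        mask = (qmat > _QMIN) & (p[None, :] > 0)
        with np.errstate(divide="ignore", invalid="ignore"):
            cells = np.where(mask, -p[None, :] * np.log(np.where(mask, qmat, 1.0)), 0.0)
        scores = cells.sum(axis=1)
    i = int(np.argmin(scores))
    lo = grid[max(i - 1, 0)]
    hi = grid[min(i + 1, grid.size - 1)]
    res = minimize_scalar(
        lambda lam: obj(p, load_pmf(lam, tail=tail)),
        bounds=(lo, hi), method="bounded", options={"xatol": 1e-5},
    )
    lam = float(res.x)
    chi2 = _chi2(p, load_pmf(lam, tail=tail))
    return lam, chi2, ""


def mrl_truncated(p: Sequence[float]) -> float:
    """Classical mean ribosome load: the expectation sum_k k*p_k over the
    resolved fractions, with no correction for the unresolved tail."""
    p = np.asarray(p, dtype=float)
    return float(np.dot(np.arange(p.size), p))


def per_nucleotide_load(lam: float, transcript_length: float | None) -> float | None:
    """Ribosomes per nucleotide: lambda / transcript length."""
    if transcript_length is None or (isinstance(transcript_length, float) and np.isnan(transcript_length)):
        return None
    if transcript_length <= 0:
        raise ValueError("transcript_length must be positive")
    return float(lam) / float(transcript_length)


def estimate_loads(
    table: pd.DataFrame,
    spikein_total: float,
    pool_replicates: bool = False,
    lengths: Mapping[str, float] | pd.Series | None = None,
    tail: str = "collapse",
    method: str = "chi2",
) -> pd.DataFrame:
    """Full pipeline: TPM table -> per-gene LoadEstimate rows.

    With ``pool_replicates=False`` (default) the Poisson fit runs per
    replicate and a per-gene summary averages lambda across replicates;
    otherwise counts are pooled first and a single fit is made per gene.
    ``lengths`` (gene_id -> transcript length, nt) adds the per-nucleotide
    load lambda / length.
    """
    counts = absolute_counts(table, spikein_total)
    probs = fraction_probabilities(counts, pool_replicates=pool_replicates)
    pcols = [f"p{k}" for k in range(K_MAX + 1)]

    recs = []
    for _, row in probs.iterrows():
        p = row[pcols].to_numpy(dtype=float)
        lam, chi2, flags = fit_poisson_load(p, tail=tail, method=method)
        recs.append({
            "gene_id": row["gene_id"],
            "replicate": row.get("replicate"),
            "lambda": lam,
            "chi2": chi2,
            "mrl_truncated": mrl_truncated(p),
            "total_molecules": row["total_molecules"],
            "n_fractions_used": row["n_fractions_used"],
            "flags": flags,
        })
    fits = pd.DataFrame(recs)

    if pool_replicates:
        out = fits.drop(columns=["replicate"])
    else:
        out = (
            fits.groupby("gene_id", observed=True)
            .agg(**{
                "lambda": ("lambda", "mean"),
                "chi2": ("chi2", "mean"),
                "mrl_truncated": ("mrl_truncated", "mean"),
                "total_molecules": ("total_molecules", "sum"),
                "n_fractions_used": ("n_fractions_used", "max"),
                "n_replicates": ("replicate", "nunique"),
                "flags": ("flags", lambda s: ";".join(sorted(set(x for x in s if x)))),
            })
            .reset_index()
        )
    if lengths is not None:
        lengths = pd.Series(lengths)
        out["mrl_per_nt"] = [
            per_nucleotide_load(l, lengths.get(g)) for g, l in zip(out["gene_id"], out["lambda"])
        ]
    return out
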