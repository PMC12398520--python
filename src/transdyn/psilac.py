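"""Protein synthesis rates from pulsed-SILAC heavy-peptide time courses.

After the heavy-to-light medium switch the heavy signal of each peptide
decays as I(t) = I0 * exp(-k t). Because the model is linear in I0 the
amplitude is projected out analytically, leaving a one-dimensional profiled
least-squares problem in the accumulation rate k. Rates below 1e-5 /min are
treated as spurious and discarded; surviving peptide rates of the same
protein are averaged (spread = max - min kept as a crude fluctuation
measure) and normalized by the protein copy number per cell.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import minimize_scalar

logger = logging.getLogger(__name__)

#: rates below this are considered spurious (1/min); the boundary itself is kept
SPURIOUS_THRESHOLD = 1e-5

STATUS_OK = "ok"
STATUS_SPURIOUS = "discarded-spurious"
STATUS_INSUFFICIENT = "discarded-insufficient"


@dataclass
class PeptideRate:
    peptide_id: str
    k: float | None
    i0: float | None
    sse: float | None
    status: str


def profiled_amplitude(k: float, t: np.ndarray, intensity: np.ndarray) -> float:
    """Optimal I0 for fixed k: the least-squares projection
    sum I_t e^{-kt} / sum e^{-2kt}."""
    w = np.exp(-k * t)
    denom = float(np.dot(w, w))
    return float(np.dot(intensity, w)) / denom


def profiled_sse(k: float, t: np.ndarray, intensity: np.ndarray) -> float:
    """Sum of squared residuals at the profiled amplitude."""
    w = np.exp(-k * t)
    i0 = float(np.dot(intensity, w)) / float(np.dot(w, w))
    r = intensity - i0 * w
    return float(np.dot(r, r))


def fit_peptide(
    times: np.ndarray,
    intensities: np.ndarray,
    peptide_id: str = "",
    k_bounds: tuple[float, float] = (0.0, 1.0),
) -> PeptideRate:
    """Fit I(t) = I0 exp(-k t) to one peptide's heavy-intensity series.

    The profiled objective is scanned on a coarse grid over ``k_bounds``
    (zero plus a geometric grid) and refined by bounded 1-D minimization to
    a relative tolerance of 1e-6 in k. At least 3 finite, positive
    intensities are required; otherwise the peptide is marked
    ``discarded-insufficient``.
    """
    t = np.asarray(times, dtype=float)
    y = np.asarray(intensities, dtype=float)
    keep = np.isfinite(t) & np.isfinite(y)
    t, y = t[keep], y[keep]
    if (y > 0).sum() < 3:
        return PeptideRate(peptide_id, None, None, None, STATUS_INSUFFICIENT)

    lo, hi = k_bounds
    grid = np.concatenate([[lo], np.geomspace(max(lo, 1e-7), hi, 200)])
    sse = np.array([profiled_sse(k, t, y) for k in grid])
    i = int(np.argmin(sse))
    b_lo = grid[max(i - 1, 0)]
    b_hi = grid[min(i + 1, grid.size - 1)]
    if b_hi <= b_lo:
        k_opt = float(grid[i])
    else:
        res = minimize_scalar(
            profiled_sse, args=(t, y), bounds=(b_lo, b_hi), method="bounded",
            options={"xatol": max(1e-12, 1e-6 * max(grid[i], 1e-4))},
        )
        k_opt = float(res.x)
        if profiled_sse(k_opt, t, y) > sse[i]:
            k_opt = float(grid[i])
    return PeptideRate(
        peptide_id, k_opt, profiled_amplitude(k_opt, t, y), profiled_sse(k_opt, t, y), STATUS_OK
    )


def filter_spurious(rate: PeptideRate) -> PeptideRate:
    """Mark rates smaller than 1e-5 /min as spurious (the boundary value is
    retained: the cut is strictly 'smaller than')."""
    if rate.status != STATUS_OK:
        return rate
    if rate.k < SPURIOUS_THRESHOLD:
        return PeptideRate(rate.peptide_id, rate.k, rate.i0, rate.sse, STATUS_SPURIOUS)
    return rate


def fit_all_peptides(series: pd.DataFrame, k_bounds: tuple[float, float] = (0.0, 1.0)) -> pd.DataFrame:
    """Fit and filter every peptide in a long intensity table.

    ``series`` columns: protein_id, peptide_id, time_min, intensity and
    optionally replicate/label. Returns one row per (peptide, replicate):
    protein_id, peptide_id, replicate, k, i0, sse, status.
    """
    if "replicate" not in series.columns:
        series = series.assign(replicate=1)
    recs = []
    for (prot, pep, rep), grp in series.groupby(
        ["protein_id", "peptide_id", "replicate"], observed=True, sort=True
    ):
        r = filter_spurious(fit_peptide(grp["time_min"].to_numpy(), grp["intensity"].to_numpy(), pep, k_bounds))
        recs.append({
            "protein_id": prot, "peptide_id": pep, "replicate": rep,
            "k": r.k, "i0": r.i0, "sse": r.sse, "status": r.status,
        })
    return pd.DataFrame(recs)


def aggregate_protein(rates: pd.DataFrame) -> pd.DataFrame:
    """Average ok peptide rates per protein (and replicate).

    Intensities of different peptides are not comparable but their rates
    are, so the mean is unweighted; the spread (max - min) is kept as a
    crude fluctuation measure. Proteins with no surviving peptide are
    omitted (count logged).
    """
    ok = rates[rates["status"] == STATUS_OK]
    n_dropped = rates["protein_id"].nunique() - ok["protein_id"].nunique()
    if n_dropped:
        logger.info("omitting %d protein(s) with no usable peptide rate", n_dropped)
    if ok.empty:
        return pd.DataFrame(columns=["protein_id", "replicate", "k_mean", "k_spread", "n_peptides"])
    out = (
        ok.groupby(["protein_id", "replicate"], observed=True)["k"]
        .agg(k_mean="mean", k_max="max", k_min="min", n_peptides="count")
        .reset_index()
    )
    out["k_spread"] = out["k_max"] - out["k_min"]
    out["n_peptides"] = out["n_peptides"].astype(int)
    return out[["protein_id", "replicate", "k_mean", "k_spread", "n_peptides"]]


def normalize_by_copy_number(
    proteins: pd.DataFrame,
    copy_numbers: pd.Series | dict,
    mode: str = "as-stated",
) -> pd.DataFrame:
    """Attach per-cell synthesis rates.

    ``mode="as-stated"`` divides the accumulation rate by the copy number
    (synthesis_rate = k_mean / N). ``mode="steady-state"`` uses the
    steady-state balance s = k * N instead. Both are exposed because the two
    conventions differ and the choice matters only as a per-protein scaling;
    the mode used is recorded in the ``normalization_mode`` column.
    Proteins without a copy number keep an empty synthesis_rate.
    """
    if mode not in ("as-stated", "steady-state"):
        raise ValueError(f"unknown normalization mode {mode!r}")
    cn = pd.Series(copy_numbers, dtype=float)
    if (cn <= 0).any():
        raise ValueError("copy numbers must be positive")
    out = proteins.copy()
    out["copies_per_cell"] = out["protein_id"].map(cn)
    if mode == "as-stated":
        out["synthesis_rate"] = out["k_mean"] / out["copies_per_cell"]
    else:
        out["synthesis_rate"] = out["k_mean"] * out["copies_per_cell"]
    out["normalization_mode"] = mode
    return out


def estimate_rates(
    series: pd.DataFrame,
    copy_numbers: pd.Series | dict | None = None,
    mode: str = "as-stated",
    k_bounds: tuple[float, float] = (0.0, 1.0),
) -> pd.DataFrame:
    """Full pipeline: peptide intensity series -> per-protein synthesis rates."""
    rates = fit_all_peptides(series, k_bounds=k_bounds)
    proteins = aggregate_protein(rates)
    if copy_numbers is not None:
        proteins = normalize_by_copy_number(proteins, copy_numbers, mode=mode)
    return proteins
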