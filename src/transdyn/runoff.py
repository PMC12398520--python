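"""Global translation elongation rate from harringtonine run-off profiles.

Harringtonine traps initiating ribosomes at start codons while elongating
ribosomes run off the message; after tau seconds the 5'-most ~v*tau codons
are depleted of footprints. Pooled-replicate coverage is aligned at the
start codon across long genes, averaged in 5-codon windows, and normalized
to the mean coverage of the 800-1000-codon region. The "starting location"
of each time point is where the normalized curve first reaches 0.5 walking
from the start codon; the slope of starting location versus run-off time is
the global elongation rate in codons/s (numerically aa/s).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import linregress

logger = logging.getLogger(__name__)

WINDOW_CODONS = 5
NORM_REGION = (800, 1000)  # codons, half-open
MIN_METAGENE_CODONS = 1000
DEPLETION_FRACTION = 0.5  # region coverage below this fraction of the
                          # untreated reference flags a depleted region


@dataclass
class MetageneCurve:
    """Start-codon-aligned, window-averaged, region-normalized coverage."""

    centers: np.ndarray  # codon coordinate of each window center
    values: np.ndarray   # normalized coverage per window
    time_s: float
    n_genes: int
    normalized: bool = True
    norm_region_depleted: bool = False
    region_raw_mean: float = float("nan")  # pre-normalization region coverage


@dataclass
class RunoffFit:
    slope: float          # codons/s == aa/s
    intercept: float      # codons
    r2: float
    times_used: list = field(default_factory=list)
    start_locations: dict = field(default_factory=dict)


def build_metagene(
    coverage: pd.DataFrame,
    time_s: float,
    window: int = WINDOW_CODONS,
    norm_region: tuple[int, int] = NORM_REGION,
    min_length: int | None = MIN_METAGENE_CODONS,
    per_gene_norm: bool = False,
) -> MetageneCurve:
    """Build the metagene curve for one run-off time point.

    ``coverage`` is long-format per-codon coverage (gene_id, codon_index,
    coverage, time_s[, replicate]); replicates are pooled by summation.
    Genes shorter than ``min_length`` codons are excluded (set ``None`` to
    keep them; they then contribute only to positions they cover). Coverage
    is combined position-wise across covering genes (depth-weighted;
    ``per_gene_norm`` first scales each gene to unit mean), averaged in
    half-open ``window``-codon bins, and divided by the mean over windows
    fully inside ``norm_region``.
    """
    df = coverage[coverage["time_s"] == time_s]
    if df.empty:
        raise ValueError(f"no coverage rows at time_s={time_s}")
    pooled = df.groupby(["gene_id", "codon_index"], observed=True)["coverage"].sum()

    gene_len = pooled.groupby("gene_id").size()
    if min_length is not None:
        keep = gene_len[gene_len >= min_length].index
        if keep.empty:
            raise ValueError(f"no gene reaches {min_length} codons; cannot build metagene")
        pooled = pooled[pooled.index.get_level_values("gene_id").isin(keep)]
        gene_len = gene_len[keep]
    n_genes = int(gene_len.size)
    max_len = int(gene_len.max())

    total = np.zeros(max_len)
    ncover = np.zeros(max_len)
    for gene, sub in pooled.groupby("gene_id"):
        idx = sub.index.get_level_values("codon_index").to_numpy()
        vals = sub.to_numpy(dtype=float)
        if per_gene_norm:
            m = vals.mean()
            if m > 0:
                vals = vals / m
        total[idx] += vals
        ncover[idx] += 1
    covered = ncover > 0
    mean_cov = np.zeros(max_len)
    mean_cov[covered] = total[covered] / ncover[covered]

    n_win = max_len // window
    binned = mean_cov[: n_win * window].reshape(n_win, window).mean(axis=1)
    centers = np.arange(n_win) * window + (window - 1) / 2 + 0.5  # center of [wj, wj+w)

    j0, j1 = norm_region[0] // window, norm_region[1] // window
    in_region = (np.arange(n_win) >= j0) & (np.arange(n_win) < j1)
    normalized = True
    region_mean = float(binned[in_region].mean()) if in_region.any() else float("nan")
    if in_region.any() and region_mean > 0:
        binned = binned / region_mean
    else:
        normalized = False
        logger.warning("empty normalization region %s at t=%ss; curve left unnormalized", norm_region, time_s)
    return MetageneCurve(centers=centers, values=binned, time_s=float(time_s),
                         n_genes=n_genes, normalized=normalized,
                         region_raw_mean=region_mean)


def find_start_location(curve: MetageneCurve, threshold: float = 0.5) -> float | None:
    """First codon position where normalized coverage reaches ``threshold``.

    The first window at or above the threshold is located walking from the
    start codon; the exact crossing is refined by linear interpolation
    between the previous and current window centers. Returns ``None`` when
    the curve never reaches the threshold (the time point is then excluded
    from the rate fit).
    """
    above = curve.values >= threshold
    if not above.any():
        logger.warning("metagene at t=%ss never reaches %.2f", curve.time_s, threshold)
        return None
    j = int(np.argmax(above))
    if j == 0:
        return 0.0
    y0, y1 = curve.values[j - 1], curve.values[j]
    x0, x1 = curve.centers[j - 1], curve.centers[j]
    if y1 == y0:
        return float(x1)
    return float(x0 + (threshold - y0) / (y1 - y0) * (x1 - x0))


def fit_elongation_rate(
    locations: dict[float, float],
    include_t0: bool = False,
) -> RunoffFit:
    """Elongation rate as the slope of starting location vs run-off time.

    ``locations`` maps time (s) to starting location (codons); ``None``
    values are ignored. The tau = 0 point is excluded by default: the drug
    has not acted yet and its curve only checks that the profile is flat.
    """
    pairs = [(t, x) for t, x in sorted(locations.items())
             if x is not None and (include_t0 or t > 0)]
    if len(pairs) < 2:
        raise ValueError("need at least 2 time points with detected start locations")
    t = np.array([p[0] for p in pairs], dtype=float)
    x = np.array([p[1] for p in pairs], dtype=float)
    if np.unique(t).size < 2:
        raise ValueError("degenerate time vector: all times identical")
    res = linregress(t, x)
    return RunoffFit(
        slope=float(res.slope), intercept=float(res.intercept),
        r2=float(res.rvalue ** 2), times_used=t.tolist(),
        start_locations={float(a): float(b) for a, b in pairs},
    )


def run_runoff_analysis(
    coverage: pd.DataFrame,
    window: int = WINDOW_CODONS,
    norm_region: tuple[int, int] = NORM_REGION,
    min_length: int | None = MIN_METAGENE_CODONS,
    per_gene_norm: bool = False,
    include_t0: bool = False,
) -> tuple[dict[float, MetageneCurve], RunoffFit]:
    """Metagene curves for every time point plus the elongation-rate fit."""
    times = sorted(coverage["time_s"].unique())
    curves = {
        t: build_metagene(coverage, t, window=window, norm_region=norm_region,
                          min_length=min_length, per_gene_norm=per_gene_norm)
        for t in times
    }
    # At fast rates / late times the run-off front overruns the
    # normalization region itself; normalizing by the depleted region then
    # rescales the residual floor towards 1 and the 0.5-crossing loses its
    # meaning. The earliest time point (untreated when 0 s is present, same
    # genes either way) provides the reference coverage for the region;
    # time points whose region has lost more than half of it are excluded.
    reference = curves[times[0]].region_raw_mean
    for c in curves.values():
        if np.isfinite(reference) and reference > 0 and np.isfinite(c.region_raw_mean):
            c.norm_region_depleted = bool(c.region_raw_mean < DEPLETION_FRACTION * reference)
            if c.norm_region_depleted:
                logger.warning(
                    "normalization region coverage at t=%ss fell to %.2fx the "
                    "reference; time point excluded from the rate fit",
                    c.time_s, c.region_raw_mean / reference,
                )
    locations = {
        t: (find_start_location(c) if not c.norm_region_depleted else None)
        for t, c in curves.items()
    }
    fit = fit_elongation_rate(locations, include_t0=include_t0)
    return curves, fit
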