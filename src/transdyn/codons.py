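"""A-site codon enrichment: observed over expected codon usage.

A codon decoded slowly dwells longer in the ribosomal A-site and is
over-represented among footprints. The observed usage of codon c is the
proportion of footprints with c at their A-site (a read-length-dependent
offset from the 5' end); the expected usage is the codon composition of the
coding regions, averaged with weights proportional to the footprint count
of each CDS. Their ratio is the enrichment. To avoid library-preparation
artifacts at the CDS boundaries, the first 15 codons after the start and
the last 5 codons before the stop are excluded from both sides of the
ratio.
"""

from __future__ import annotations

import logging
from typing import Mapping

import numpy as np
import pandas as pd
from Bio.Seq import Seq

from .synthetic import SENSE_CODONS, STOP_CODONS

logger = logging.getLogger(__name__)

START_EXCLUDE = 15  # codons after the start codon
STOP_EXCLUDE = 5    # codons before the stop codon

#: codon -> single-letter amino acid for the 61 sense codons
AMINO_ACIDS: dict[str, str] = {c: str(Seq(c).translate()) for c in SENSE_CODONS}


def _codon_list(cds: str) -> list[str]:
    if len(cds) % 3 != 0:
        raise ValueError("CDS length must be a multiple of 3")
    return [cds[i:i + 3].upper() for i in range(0, len(cds), 3)]


def expected_usage(
    cds_seqs: Mapping[str, str],
    footprint_counts: Mapping[str, float],
    start_exclude: int = START_EXCLUDE,
    stop_exclude: int = STOP_EXCLUDE,
) -> pd.Series:
    """Footprint-weighted average codon usage of the coding regions.

    Per CDS the codon frequencies are computed over codons
    ``[start_exclude, L - stop_exclude)``; per-CDS frequency vectors are
    averaged with weights proportional to ``footprint_counts`` and
    renormalized to sum to 1. CDSs too short to retain any codon after the
    exclusions are skipped (logged).
    """
    acc = pd.Series(0.0, index=list(SENSE_CODONS))
    total_w = 0.0
    n_skipped = 0
    for tx, seq in cds_seqs.items():
        w = float(footprint_counts.get(tx, 0.0))
        if w <= 0:
            continue
        codons = _codon_list(seq)
        body = codons[start_exclude: len(codons) - stop_exclude]
        body = [c for c in body if c in AMINO_ACIDS]
        if not body:
            n_skipped += 1
            continue
        freq = pd.Series(body).value_counts(normalize=True).reindex(SENSE_CODONS, fill_value=0.0)
        acc += w * freq
        total_w += w
    if n_skipped:
        logger.info("skipped %d CDS(s) shorter than the exclusion windows", n_skipped)
    if total_w <= 0:
        raise ValueError("no CDS with positive footprint weight")
    out = acc / total_w
    return out / out.sum()


def observed_usage(
    footprints: pd.DataFrame,
    cds_seqs: Mapping[str, str],
    asite_offsets: Mapping[int, int],
    utr5: Mapping[str, int] | int = 0,
    start_exclude: int = START_EXCLUDE,
    stop_exclude: int = STOP_EXCLUDE,
) -> tuple[pd.Series, dict[str, int]]:
    """Proportion of footprints with each codon at the A-site.

    The A-site codon index of a footprint is
    ``floor((pos5 + offset[length] - utr5) / 3)`` relative to the start
    codon (frame ambiguity resolved by floor division). Footprints are
    dropped — with per-reason counters — when their length is missing from
    the offset map, their transcript is unknown, the A-site falls outside
    the CDS or on a stop codon, or inside the excluded boundary windows.

    Returns ``(observed, dropped)``: a probability vector over the 61 sense
    codons and the drop counters.
    """
    if isinstance(utr5, int):
        utr5_map = {tx: utr5 for tx in cds_seqs}
    else:
        utr5_map = dict(utr5)

    codons_by_tx = {tx: np.array(_codon_list(seq)) for tx, seq in cds_seqs.items()}
    dropped = {"unknown_length": 0, "unknown_transcript": 0, "outside_cds": 0,
               "stop_codon": 0, "excluded_window": 0}

    off = footprints["length"].map(lambda l: asite_offsets.get(int(l)))
    known_len = off.notna()
    dropped["unknown_length"] = int((~known_len).sum())
    df = footprints.loc[known_len, ["transcript_id", "pos5"]].copy()
    df["offset"] = off[known_len].astype(int)

    known_tx = df["transcript_id"].isin(codons_by_tx.keys())
    dropped["unknown_transcript"] = int((~known_tx).sum())
    df = df[known_tx]

    collected: list[np.ndarray] = []
    for tx, grp in df.groupby("transcript_id", observed=True, sort=False):
        codons = codons_by_tx[tx]
        idx = (grp["pos5"].to_numpy() + grp["offset"].to_numpy() - utr5_map.get(tx, 0)) // 3
        inside = (idx >= 0) & (idx < codons.size)
        dropped["outside_cds"] += int((~inside).sum())
        idx = idx[inside]
        kept = (idx >= start_exclude) & (idx < codons.size - stop_exclude)
        dropped["excluded_window"] += int((~kept).sum())
        collected.append(codons[idx[kept]])
    hits = np.concatenate(collected) if collected else np.array([], dtype=str)
    is_stop = np.isin(hits, STOP_CODONS)
    dropped["stop_codon"] = int(is_stop.sum())
    hits = hits[~is_stop]
    if hits.size == 0:
        raise ValueError("no footprints retained after filtering")
    observed = (
        pd.Series(hits).value_counts(normalize=True).reindex(SENSE_CODONS, fill_value=0.0)
    )
    return observed, dropped


def enrichment(observed: pd.Series, expected: pd.Series, n_reads: int | None = None) -> pd.DataFrame:
    """Elementwise observed/expected ratio over the 61 sense codons.

    Codons with zero expected and zero observed usage get a missing
    enrichment; zero expected with positive observed is flagged as
    inconsistent (the codon was seen at A-sites but never in the weighted
    coding regions).
    """
    if list(observed.index) != list(expected.index):
        raise ValueError("observed and expected must share the same codon support")
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = observed / expected
    flags = pd.Series("", index=observed.index)
    both_zero = (expected == 0) & (observed == 0)
    ratio[both_zero] = np.nan
    inconsistent = (expected == 0) & (observed > 0)
    ratio[inconsistent] = np.nan
    flags[inconsistent] = "inconsistent"
    out = pd.DataFrame({
        "codon": observed.index,
        "amino_acid": [AMINO_ACIDS[c] for c in observed.index],
        "observed": observed.values,
        "expected": expected.values,
        "enrichment": ratio.values,
        "flag": flags.values,
    })
    if n_reads is not None:
        out["n_reads"] = n_reads
    return out


def compute_codon_enrichment(
    footprints: pd.DataFrame,
    cds_seqs: Mapping[str, str],
    asite_offsets: Mapping[int, int],
    utr5: Mapping[str, int] | int = 0,
    start_exclude: int = START_EXCLUDE,
    stop_exclude: int = STOP_EXCLUDE,
) -> pd.DataFrame:
    """Full pipeline: footprints + CDS sequences -> 61-codon enrichment table.

    Expected-usage weights are the per-CDS footprint counts of the same
    sample being analyzed.
    """
    counts = footprints.groupby("transcript_id", observed=True).size().to_dict()
    expected = expected_usage(cds_seqs, counts, start_exclude, stop_exclude)
    observed, dropped = observed_usage(
        footprints, cds_seqs, asite_offsets, utr5, start_exclude, stop_exclude
    )
    n_reads = int(len(footprints) - sum(dropped.values()))
    table = enrichment(observed, expected, n_reads=n_reads)
    table.attrs["dropped"] = dropped
    return table
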