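"""Footprint bookkeeping and ribo-seq quantification/QC statistics.

Covers the standard post-alignment checks of a ribosome-profiling library —
read-length distribution, per-length P-site offsets, reading-frame
periodicity, 5'UTR/CDS/3'UTR read partitioning — plus TPM/RPKM
quantification and translation efficiency (footprint TPM over mRNA TPM)
with its between-condition log2 fold-change.

Coordinates are 0-based half-open throughout; a transcript is laid out as
5'UTR [0, u), CDS [u, u+c), 3'UTR [u+c, u+c+t).
"""

from __future__ import annotations

import logging
from typing import Mapping

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

OFFSET_SEARCH = (10, 14)   # plausible P-site offsets, nt (inclusive)
MIN_READS_PER_LENGTH = 500


def length_distribution(footprints: pd.DataFrame) -> pd.DataFrame:
    """Histogram of footprint read lengths: count and proportion per length."""
    counts = footprints["length"].value_counts().sort_index()
    return pd.DataFrame({
        "length": counts.index.astype(int),
        "count": counts.values,
        "proportion": counts.values / counts.values.sum(),
    })


def estimate_psite_offsets(
    footprints: pd.DataFrame,
    models: pd.DataFrame,
    search: tuple[int, int] = OFFSET_SEARCH,
    min_reads: int = MIN_READS_PER_LENGTH,
) -> pd.DataFrame:
    """Per-read-length P-site offset from 5' ends near start codons.

    For each read length the distances (start codon position - pos5) are
    tabulated over the ``search`` window and the modal distance is the
    offset — reads of initiating ribosomes pile up with their P-site on the
    start codon. Length classes with fewer than ``min_reads`` total reads
    are assigned the global modal offset and flagged.

    Returns columns length, offset, n_reads_in_window, flag.
    """
    start = models.set_index("transcript_id")["utr5_len"]
    unknown = ~footprints["transcript_id"].isin(start.index)
    if unknown.any():
        logger.warning("ignoring %d footprints on unknown transcripts", int(unknown.sum()))
    fp = footprints[~unknown]
    d = fp["transcript_id"].map(start).to_numpy() - fp["pos5"].to_numpy()
    lengths = fp["length"].to_numpy()
    lo, hi = search
    in_win = (d >= lo) & (d <= hi)
    if not in_win.any():
        raise ValueError(
            "no reads with 5' ends within the offset search window near start "
            "codons; supply an explicit offset map instead"
        )

    class_sizes = fp["length"].value_counts()
    global_hist = pd.Series(d[in_win]).value_counts()
    global_mode = int(global_hist.idxmax())

    recs = []
    for length in sorted(class_sizes.index):
        sel = in_win & (lengths == length)
        hist = pd.Series(d[sel]).value_counts()
        if class_sizes[length] >= min_reads and not hist.empty:
            recs.append({"length": int(length), "offset": int(hist.idxmax()),
                         "n_reads_in_window": int(sel.sum()), "flag": ""})
        else:
            recs.append({"length": int(length), "offset": global_mode,
                         "n_reads_in_window": int(sel.sum()), "flag": "global-modal-offset"})
    return pd.DataFrame(recs)


def _psite_positions(footprints: pd.DataFrame, offsets: Mapping[int, int] | pd.DataFrame) -> np.ndarray:
    if isinstance(offsets, pd.DataFrame):
        offsets = dict(zip(offsets["length"].astype(int), offsets["offset"].astype(int)))
    off = footprints["length"].map(lambda l: offsets.get(int(l)))
    if off.isna().any():
        raise ValueError("offset map is missing lengths present in the footprints")
    return footprints["pos5"].to_numpy() + off.to_numpy(dtype=int)


def frame_proportions(
    footprints: pd.DataFrame,
    offsets: Mapping[int, int] | pd.DataFrame,
    models: pd.DataFrame,
) -> pd.Series:
    """Proportion of reads whose P-site lands in each reading frame (0/1/2),
    relative to the annotated start codon."""
    start = models.set_index("transcript_id")["utr5_len"]
    psite = _psite_positions(footprints, offsets)
    frame = (psite - footprints["transcript_id"].map(start).to_numpy()) % 3
    counts = pd.Series(frame).value_counts().reindex([0, 1, 2], fill_value=0)
    return counts / counts.sum()


def region_proportions(
    footprints: pd.DataFrame,
    offsets: Mapping[int, int] | pd.DataFrame,
    models: pd.DataFrame,
) -> pd.Series:
    """Proportion of reads whose P-site falls in the 5'UTR, CDS, or 3'UTR.

    Reads whose P-site lies outside the transcript are excluded from the
    three-way proportion and reported under the ``outside`` attribute.
    """
    m = models.set_index("transcript_id")
    psite = _psite_positions(footprints, offsets)
    tx = footprints["transcript_id"]
    u5 = tx.map(m["utr5_len"]).to_numpy()
    cds = tx.map(m["cds_len"]).to_numpy()
    u3 = tx.map(m["utr3_len"]).to_numpy()
    total_len = u5 + cds + u3
    inside = (psite >= 0) & (psite < total_len)
    region = np.where(psite < u5, "5'UTR", np.where(psite < u5 + cds, "CDS", "3'UTR"))
    counts = pd.Series(region[inside]).value_counts().reindex(["5'UTR", "CDS", "3'UTR"], fill_value=0)
    out = counts / counts.sum()
    out.attrs["outside"] = int((~inside).sum())
    return out


def quantify(
    counts: pd.Series | Mapping[str, float],
    lengths: pd.Series | Mapping[str, float],
) -> pd.DataFrame:
    """TPM and RPKM from per-transcript read counts and lengths (nt).

    TPM: per-length read rates scaled to sum to 1e6. RPKM: reads per
    kilobase per million mapped reads. For footprints the natural length is
    the CDS length; pass transcript lengths for RNA-seq parity.
    """
    counts = pd.Series(counts, dtype=float)
    lengths = pd.Series(lengths, dtype=float).reindex(counts.index)
    if lengths.isna().any():
        raise ValueError("missing lengths for some transcripts")
    if (lengths <= 0).any():
        raise ValueError("lengths must be positive")
    total = counts.sum()
    if total <= 0:
        raise ValueError("zero total counts; nothing to quantify")
    rate = counts / lengths
    tpm = rate / rate.sum() * 1e6
    rpkm = counts / (lengths / 1e3) / (total / 1e6)
    return pd.DataFrame({"count": counts, "length": lengths, "tpm": tpm, "rpkm": rpkm})


def translation_efficiency(ribo_tpm: pd.Series, rna_tpm: pd.Series) -> pd.Series:
    """TE = footprint TPM / mRNA TPM, per gene; undefined where mRNA TPM is 0
    or the gene is missing from either table."""
    common = ribo_tpm.index.intersection(rna_tpm.index)
    te = ribo_tpm[common] / rna_tpm[common].where(rna_tpm[common] > 0)
    te.name = "te"
    return te


def te_log2_fold_change(te_cond1: pd.Series, te_cond2: pd.Series) -> pd.Series:
    """log2(TE_cond2 / TE_cond1) for genes with positive TE in both
    conditions; everything else is excluded (count in ``attrs``)."""
    common = te_cond1.index.intersection(te_cond2.index)
    a, b = te_cond1[common], te_cond2[common]
    ok = (a > 0) & (b > 0) & a.notna() & b.notna()
    out = np.log2(b[ok] / a[ok])
    out.name = "log2fc_te"
    out.attrs["n_excluded"] = int(len(te_cond1.index.union(te_cond2.index)) - ok.sum())
    return out
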