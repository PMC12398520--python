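"""Readers and writers for the tabular and sequence formats used here.

Tables are plain TSV (header row, UTF-8). Sequences go through Biopython;
aligned footprints can be read from SAM/BAM via pysam and coverage tracks
from BigWig via pyBigWig.
"""

from __future__ import annotations

from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord


def read_tsv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_tsv(df: pd.DataFrame, path: str | Path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, sep="\t", index=False)


def read_fasta(path: str | Path) -> dict[str, str]:
    """FASTA -> id -> uppercase sequence."""
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(seqs: Mapping[str, str], path: str | Path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    records = (SeqRecord(Seq(s), id=name, description="") for name, s in seqs.items())
    SeqIO.write(records, str(path), "fasta")


def read_footprints_sam(path: str | Path) -> pd.DataFrame:
    """Footprint records from a transcriptome-aligned SAM/BAM file.

    Keeps mapped primary alignments; transcript_id is the reference name,
    pos5 the 0-based leftmost position, length the query length.
    """
    import pysam

    mode = "rb" if str(path).endswith(".bam") else "r"
    recs = []
    with pysam.AlignmentFile(str(path), mode, check_sq=False) as fh:
        for aln in fh:
            if aln.is_unmapped or aln.is_secondary or aln.is_supplementary:
                continue
            recs.append((aln.reference_name, aln.reference_start, aln.query_length))
    return pd.DataFrame(recs, columns=["transcript_id", "pos5", "length"])


def load_coverage_bigwig(
    paths: Mapping[float, str | Path] | Iterable[tuple[float, str | Path]],
    replicate: int = 1,
) -> pd.DataFrame:
    """Per-codon coverage from one BigWig per run-off time point.

    ``paths`` maps time_s -> BigWig file with per-nucleotide coverage in
    transcript (CDS) coordinates; nucleotide coverage is summed into codons.
    Returns the long format used by the run-off module (gene_id,
    codon_index, coverage, time_s, replicate).
    """
    import numpy as np
    import pyBigWig

    items = paths.items() if isinstance(paths, Mapping) else paths
    frames = []
    for time_s, path in items:
        bw = pyBigWig.open(str(path))
        try:
            for gene, length in bw.chroms().items():
                vals = np.nan_to_num(np.array(bw.values(gene, 0, length), dtype=float))
                n_codon = length // 3
                cov = vals[: n_codon * 3].reshape(n_codon, 3).sum(axis=1)
                frames.append(pd.DataFrame({
                    "gene_id": gene,
                    "codon_index": np.arange(n_codon),
                    "coverage": cov,
                    "time_s": float(time_s),
                    "replicate": replicate,
                }))
        finally:
            bw.close()
    return pd.concat(frames, ignore_index=True)
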