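"""Configuration for the synthetic-data generators.

A single :class:`SimConfig` carries the parameters of every generator so a
whole simulated experiment (polysome fractions, pSILAC time course, run-off
coverage, footprints) can be reproduced from one seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Mapping, Sequence

#: Fraction labels of the polysome gradient: two physical zero-ribosome
#: fractions (free mRNPs and 40S-bound), then 1..10 ribosomes. Material
#: heavier than the 10-some pools into the last resolved fraction.
FRACTION_LABELS: tuple[str, ...] = ("free", "40S") + tuple(str(k) for k in range(1, 11))

#: Highest polysome fraction the gradient resolves (ribosomes per mRNA).
K_MAX: int = 10


class InvalidConfigError(ValueError):
    """Raised when a :class:`SimConfig` violates its invariants."""


def _default_length_probs() -> dict[int, float]:
    # footprint length mix peaked at 29-30 nt, as nuclease-protected
    # fragments of elongating ribosomes are
    return {27: 0.05, 28: 0.20, 29: 0.35, 30: 0.30, 31: 0.10}


def _default_psite_offsets() -> dict[int, int]:
    # nt from the footprint 5' end to the P-site codon, per read length
    return {27: 11, 28: 12, 29: 12, 30: 13, 31: 13}


@dataclass
class SimConfig:
    """Ground-truth parameters of a simulated translation-dynamics study.

    Parameters
    ----------
    seed
        Seed for all random draws; a fixed seed gives byte-identical outputs.
    n_genes
        Number of endogenous genes in the polysome-fraction simulation.
    lambda_range
        Range of mean ribosome loads (ribosomes/mRNA) drawn per gene;
        must lie within [0, 10], the resolved range of the gradient.
    n_spikein_molecules
        Total spike-in molecules S added to every fraction (identical across
        fractions by design of the spike-in protocol).
    n_spikein_species
        Number of distinct spike-in transcripts sharing S equally.
    fraction_labels
        Ordered gradient fraction labels; free and 40S both carry zero
        elongating ribosomes.
    depth
        Expected sequencing read count per fraction library.
    n_replicates
        Biological replicates per experiment.
    fraction_noise
        ``"multinomial"`` resamples reads at the given depth;
        ``"none"`` uses expected counts directly (noise-free limit).
    psilac_times
        pSILAC chase time points in minutes after the heavy-to-light switch.
    psilac_k_range
        Range of true per-protein accumulation rates (1/min), sampled
        log-uniformly (protein turnover spans orders of magnitude).
    psilac_cv
        Coefficient of variation of the multiplicative (log-normal)
        intensity noise.
    psilac_n_proteins, psilac_max_peptides
        Number of proteins and maximum peptides per protein (1..max).
    runoff_rate
        Elongation rate of the simulated run-off front, codons/s.
    runoff_times
        Harringtonine treatment durations in seconds (0 = untreated).
    runoff_noise_floor
        Residual coverage behind the run-off front, as a fraction of the
        gene's baseline (scanning/background signal).
    runoff_cv
        CV of multiplicative log-normal noise on coverage (0 = noise-free).
    n_runoff_genes
        Genes in the run-off simulation; all are long enough to span the
        800-1000-codon metagene normalization region.
    cds_length_range
        CDS lengths in codons (inclusive), start and stop codons included.
    n_footprints, n_transcripts
        Footprint reads and transcripts in the footprint simulation.
    utr5_length, utr3_length
        UTR lengths (nt) flanking each simulated CDS.
    footprint_length_probs
        Distribution of footprint lengths (27-31 nt).
    psite_offsets
        Length -> P-site offset map (nt); the A-site sits 3 nt downstream.
    codon_weights
        Relative A-site dwell weight per codon (unspecified codons weigh 1);
        the knob for planting codon-specific dwell biases.
    footprint_start_bias
        Extra sampling weight on the first decoded codon, emulating the
        initiation-proximal pile-up real libraries show.
    frame_jitter
        Probability that a footprint 5' end is displaced by +-1 nt,
        softening the 3-nt periodicity.
    """

    seed: int = 0
    # polysome fractions
    n_genes: int = 200
    lambda_range: tuple[float, float] = (0.5, 8.0)
    n_spikein_molecules: int = 100_000
    n_spikein_species: int = 10
    fraction_labels: tuple[str, ...] = FRACTION_LABELS
    depth: float = 1e5
    n_replicates: int = 3
    fraction_noise: str = "multinomial"
    # pSILAC
    psilac_times: tuple[float, ...] = (0.0, 10.0, 30.0, 60.0, 120.0, 240.0, 360.0, 480.0, 660.0)
    psilac_k_range: tuple[float, float] = (1e-3, 0.05)
    psilac_cv: float = 0.1
    psilac_n_proteins: int = 200
    psilac_max_peptides: int = 10
    # harringtonine run-off
    runoff_rate: float = 4.55
    runoff_times: tuple[float, ...] = (0.0, 80.0, 90.0, 100.0, 120.0, 150.0, 180.0)
    runoff_noise_floor: float = 0.05
    runoff_cv: float = 0.0
    n_runoff_genes: int = 20
    cds_length_range: tuple[int, int] = (1000, 1500)
    # footprints
    n_footprints: int = 200_000
    n_transcripts: int = 50
    utr5_length: int = 60
    utr3_length: int = 60
    footprint_length_probs: Mapping[int, float] = field(default_factory=_default_length_probs)
    psite_offsets: Mapping[int, int] = field(default_factory=_default_psite_offsets)
    codon_weights: Mapping[str, float] = field(default_factory=dict)
    footprint_start_bias: float = 3.0
    frame_jitter: float = 0.0

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        lo, hi = self.lambda_range
        if not (0.0 <= lo <= hi <= 10.0):
            raise InvalidConfigError(
                f"lambda_range must lie within [0, 10], got {self.lambda_range!r}"
            )
        for name, times in (("psilac_times", self.psilac_times), ("runoff_times", self.runoff_times)):
            t = list(times)
            if any(x < 0 for x in t):
                raise InvalidConfigError(f"{name} must be non-negative")
            if any(b <= a for a, b in zip(t, t[1:])):
                raise InvalidConfigError(f"{name} must be strictly increasing")
        if len(self.psilac_times) < 2:
            raise InvalidConfigError("psilac_times needs at least 2 time points")
        if self.runoff_rate <= 0:
            raise InvalidConfigError("runoff_rate must be positive")
        lo_c, hi_c = self.cds_length_range
        if not (0 < lo_c <= hi_c):
            raise InvalidConfigError("cds_length_range must be positive and ordered")
        if self.n_spikein_molecules <= 0:
            raise InvalidConfigError("n_spikein_molecules must be positive")
        if self.fraction_noise not in ("multinomial", "none"):
            raise InvalidConfigError("fraction_noise must be 'multinomial' or 'none'")
        if not 0.0 <= self.frame_jitter <= 1.0:
            raise InvalidConfigError("frame_jitter must be in [0, 1]")

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: Mapping) -> "SimConfig":
        d = dict(d)
        for key in ("lambda_range", "psilac_k_range", "cds_length_range",
                    "psilac_times", "runoff_times", "fraction_labels"):
            if key in d and isinstance(d[key], Sequence) and not isinstance(d[key], str):
                d[key] = tuple(d[key])
        if "footprint_length_probs" in d:
            d["footprint_length_probs"] = {int(k): float(v) for k, v in d["footprint_length_probs"].items()}
        if "psite_offsets" in d:
            d["psite_offsets"] = {int(k): int(v) for k, v in d["psite_offsets"].items()}
        return cls(**d)
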