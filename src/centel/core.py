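"""Core domain types shared across the pipeline.

Coordinates are 1-based inclusive everywhere in memory; conversion to 0-based
half-open happens only in the BED writer.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd

__all__ = [
    "GenomeModel",
    "ElementRecord",
    "ContactMap",
    "Hit",
    "LTRLocus",
    "CentromereCall",
    "CentromerePointSet",
    "CentromereRegion",
    "WindowTrack",
    "OrfRecord",
    "DivergenceEstimate",
]


@dataclass(frozen=True)
class GenomeModel:
    """Chromosome names/lengths, analysis bin size and (for simulations) the
    true centromere midpoints."""

    chrom_names: tuple[str, ...]
    chrom_lengths: Mapping[str, int]
    bin_size: int = 100_000
    true_centromeres: Mapping[str, int] | None = None

    def __post_init__(self) -> None:
        if self.bin_size < 1:
            raise ValueError("bin_size must be >= 1")
        for name in self.chrom_names:
            length = self.chrom_lengths[name]
            if length < 2 * self.bin_size:
                raise ValueError(
                    f"chromosome {name} length {length} < 2 x bin_size {self.bin_size}"
                )
        if self.true_centromeres is not None:
            for name in self.chrom_names:
                mid = self.true_centromeres[name]
                if not 1 <= mid <= self.chrom_lengths[name]:
                    raise ValueError(f"centromere midpoint of {name} out of bounds")

    @property
    def genome_length(self) -> int:
        return sum(self.chrom_lengths[c] for c in self.chrom_names)

    def n_bins(self, chrom: str) -> int:
        return -(-self.chrom_lengths[chrom] // self.bin_size)


@dataclass
class ElementRecord:
    """One annotated repeat/gene interval (1-based inclusive)."""

    chrom: str
    start: int
    end: int
    family: str
    element_id: str
    strand: str = "+"
    sequence: str | None = None
    compartment: str | None = None  # "cen" / "arm" (generator bookkeeping)
    age_mya: float | None = None

    def __post_init__(self) -> None:
        if self.start < 1 or self.end < self.start:
            raise ValueError(f"bad interval for {self.element_id}: [{self.start}, {self.end}]")

    @property
    def midpoint(self) -> int:
        return (self.start + self.end) // 2

    @property
    def length(self) -> int:
        return self.end - self.start + 1


class ContactMap:
    """Binned symmetric Hi-C contact map.

    Internally dense (toy scale); externally a sparse COO triplet table plus a
    bin index mapping bin id -> (chrom, 1-based start).
    """

    def __init__(self, bins: pd.DataFrame, counts: np.ndarray, bin_size: int):
        bins = bins.reset_index(drop=True)
        if not {"chrom", "start"} <= set(bins.columns):
            raise ValueError("bins table needs 'chrom' and 'start' columns")
        counts = np.asarray(counts, dtype=float)
        n = len(bins)
        if counts.shape != (n, n):
            raise ValueError(f"counts shape {counts.shape} != ({n}, {n})")
        if (counts < 0).any():
            raise ValueError("negative contact counts")
        if not np.allclose(counts, counts.T):
            raise ValueError("contact matrix is not symmetric")
        self.bins = bins
        self.counts = counts
        self.bin_size = int(bin_size)
        self._chrom_slices: dict[str, slice] = {}
        for chrom in bins["chrom"].unique():
            idx = np.flatnonzero((bins["chrom"] == chrom).to_numpy())
            if len(idx) and not np.array_equal(idx, np.arange(idx[0], idx[-1] + 1)):
                raise ValueError(f"bins of {chrom} are not contiguous")
            self._chrom_slices[chrom] = slice(int(idx[0]), int(idx[-1]) + 1)

    @property
    def chroms(self) -> list[str]:
        return list(self._chrom_slices)

    def chrom_slice(self, chrom: str) -> slice:
        return self._chrom_slices[chrom]

    def trans_block(self, chrom_a: str, chrom_b: str) -> np.ndarray:
        """View of the (A x B) inter-chromosomal block."""
        return self.counts[self._chrom_slices[chrom_a], self._chrom_slices[chrom_b]]

    def bin_midpoint_bp(self, global_bin: int) -> int:
        start = int(self.bins.loc[global_bin, "start"])
        return start - 1 + self.bin_size // 2

    def copy(self) -> "ContactMap":
        return ContactMap(self.bins.copy(), self.counts.copy(), self.bin_size)


@dataclass(frozen=True)
class Hit:
    """One homology hit supporting an LTR locus (Gag-Pol evidence)."""

    target: str
    side: str  # "left" | "right" | "internal"
    coverage: float  # fraction of the target covered
    evalue: float
    identity: float  # percent
    domains: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.side not in ("left", "right", "internal"):
            raise ValueError(f"bad hit side {self.side!r}")
        if not 0.0 <= self.coverage <= 1.0:
            raise ValueError(f"coverage {self.coverage} outside [0, 1]")


@dataclass
class LTRLocus:
    """An LTR retrotransposon locus: paired (or single) LTRs plus hit evidence."""

    locus_id: str
    chrom: str
    scaffold_length: int
    ltr5: tuple[int, int]
    ltr3: tuple[int, int] | None = None
    hits: tuple[Hit, ...] = ()
    ltr5_seq: str | None = None
    ltr3_seq: str | None = None
    class_label: str | None = None  # "I" | "S" | "T"
    cluster_id: int | None = None
    true_age_mya: float | None = None
    flagged: bool = False
    flag_reason: str | None = None


@dataclass
class CentromereCall:
    chrom: str
    bin_index: int  # within-chromosome bin index
    point_bp: int
    objective_contribution: float


@dataclass
class CentromerePointSet:
    calls: dict[str, CentromereCall]
    objective: float
    iterations: int
    restarts: int
    best_restart: int
    converged: bool = True

    def point(self, chrom: str) -> int:
        return self.calls[chrom].point_bp


@dataclass
class CentromereRegion:
    """Refined centromeric region, snapped to window boundaries."""

    chrom: str
    start: int
    end: int
    flagged: bool = False

    @property
    def size_mb(self) -> float:
        return round((self.end - self.start + 1) / 1e6, 1)

    @property
    def midpoint(self) -> float:
        return (self.start + self.end) / 2

    def contains(self, pos: int) -> bool:
        return self.start <= pos <= self.end


@dataclass
class WindowTrack:
    """Non-overlapping windowed values tiling one chromosome."""

    chrom: str
    window_size: int
    values: np.ndarray
    kind: str = "density"

    def window_of(self, pos: int) -> int:
        return (pos - 1) // self.window_size


@dataclass(frozen=True)
class OrfRecord:
    element_id: str
    strand: str
    frame: int
    start: int  # 1-based on the input sequence, forward coordinates
    end: int
    length: int  # nt, stop codon excluded
    orf_id: str = ""


@dataclass(frozen=True)
class DivergenceEstimate:
    """Kimura two-parameter divergence and the derived insertion time."""

    P: float
    Q: float
    K: float
    sites: int
    rate: float | None = None
    censored: bool = False

    @property
    def t_years(self) -> float | None:
        if self.rate is None or self.censored:
            return None
        return self.K / (2.0 * self.rate)

    @property
    def t_mya(self) -> float | None:
        t = self.t_years
        return None if t is None else t / 1e6
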