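"""Genome layouts: chromosomes, fixed-size bins, and the minimum CNA unit.

A :class:`GenomeLayout` fixes the coordinate system shared by every
copy-number profile in a dataset: an ordered list of chromosomes with
lengths in base pairs, a uniform bin size, and the size ``M`` of the
smallest modelled copy-number alteration (the "region" unit used by the
simulator).  Coordinates are 0-based half-open internally; the tabular
formats use 1-based inclusive coordinates.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field


#: hg38 autosome lengths in bp (chr1..chr22), the default human layout.
HG38_AUTOSOMES: tuple[tuple[str, int], ...] = (
    ("chr1", 248_956_422),
    ("chr2", 242_193_529),
    ("chr3", 198_295_559),
    ("chr4", 190_214_555),
    ("chr5", 181_538_259),
    ("chr6", 170_805_979),
    ("chr7", 159_345_973),
    ("chr8", 145_138_636),
    ("chr9", 138_394_717),
    ("chr10", 133_797_422),
    ("chr11", 135_086_622),
    ("chr12", 133_275_309),
    ("chr13", 114_364_328),
    ("chr14", 107_043_718),
    ("chr15", 101_991_189),
    ("chr16", 90_338_345),
    ("chr17", 83_257_441),
    ("chr18", 80_373_285),
    ("chr19", 58_617_616),
    ("chr20", 64_444_167),
    ("chr21", 46_709_983),
    ("chr22", 50_818_468),
)

#: Minimum CNA size in bp: variants are classified as CNAs above ~1 kbp.
DEFAULT_REGION_SIZE = 1_000

DEFAULT_BIN_SIZE = 1_000_000


@dataclass(frozen=True)
class GenomeLayout:
    """Chromosome lengths plus the binning scheme of a CNP dataset.

    Parameters
    ----------
    chromosomes:
        Ordered ``(name, length_bp)`` pairs.
    bin_size:
        Width of a copy-number bin in bp.  Must be at least ``region_size``.
    region_size:
        Minimum CNA unit ``M`` in bp (simulator resolution).
    arm_fraction:
        Fraction of each chromosome's length assigned to the short arm,
        used for arm-level clonal events.
    """

    chromosomes: tuple[tuple[str, int], ...] = HG38_AUTOSOMES
    bin_size: int = DEFAULT_BIN_SIZE
    region_size: int = DEFAULT_REGION_SIZE
    arm_fraction: float = 0.5
    _index: dict = field(init=False, repr=False, compare=False, default=None)

    def __post_init__(self) -> None:
        if not self.chromosomes:
            raise ValueError("layout needs at least one chromosome")
        for name, length in self.chromosomes:
            if length <= 0:
                raise ValueError(f"chromosome {name!r} has non-positive length")
        if self.bin_size <= 0 or self.region_size <= 0:
            raise ValueError("bin_size and region_size must be positive")
        if self.bin_size < self.region_size:
            raise ValueError("bin_size must be >= region_size")
        if not 0.0 < self.arm_fraction < 1.0:
            raise ValueError("arm_fraction must lie in (0, 1)")
        object.__setattr__(
            self, "_index", {name: i for i, (name, _) in enumerate(self.chromosomes)}
        )

    @property
    def chrom_names(self) -> tuple[str, ...]:
        return tuple(name for name, _ in self.chromosomes)

    def length(self, chrom: str) -> int:
        return self.chromosomes[self._index[chrom]][1]

    def n_bins(self, chrom: str) -> int:
        """Number of bins on ``chrom`` (ceil of length / bin_size)."""
        return math.ceil(self.length(chrom) / self.bin_size)

    def n_regions(self, chrom: str) -> int:
        """Number of M-sized regions on ``chrom``."""
        return math.ceil(self.length(chrom) / self.region_size)

    @property
    def regions_per_bin(self) -> int:
        return self.bin_size // self.region_size

    @property
    def total_bins(self) -> int:
        """Total bins over all chromosomes (one allele)."""
        return sum(self.n_bins(c) for c in self.chrom_names)

    def bin_edges(self, chrom: str) -> list[tuple[int, int]]:
        """0-based half-open bp intervals of the bins on ``chrom``."""
        length = self.length(chrom)
        return [
            (start, min(start + self.bin_size, length))
            for start in range(0, length, self.bin_size)
        ]


def uniform_layout(
    n_chromosomes: int,
    chrom_length: int = 100_000_000,
    bin_size: int = DEFAULT_BIN_SIZE,
    region_size: int = DEFAULT_REGION_SIZE,
    arm_fraction: float = 0.5,
) -> GenomeLayout:
    """Layout with ``n_chromosomes`` equal-length chromosomes (non-human runs)."""
    chroms = tuple(
        (f"chr{i + 1}", chrom_length) for i in range(n_chromosomes)
    )
    return GenomeLayout(chroms, bin_size, region_size, arm_fraction)
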