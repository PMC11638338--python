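"""Copy-number and breakpoint profiles of single cells.

A copy-number profile (CNP) stores, per chromosome and allele, a vector of
non-negative integer copy numbers over the ordered fixed-size bins of a
:class:`~dicelineage.genome.GenomeLayout`.  A breakpoint profile stores the
successive differences ``b_i = c_{i+1} - c_i`` of a CNP, computed
independently per chromosome (there are no breakpoints across chromosome
boundaries).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np

from .genome import GenomeLayout

#: key of a per-chromosome/allele vector: (chromosome name, allele index).
ChromAllele = tuple[str, int]


def _validate_vectors(
    data: Mapping[ChromAllele, np.ndarray], layout: GenomeLayout, cell_id: str
) -> dict[ChromAllele, np.ndarray]:
    out: dict[ChromAllele, np.ndarray] = {}
    for (chrom, allele), vec in data.items():
        arr = np.asarray(vec)
        if not np.issubdtype(arr.dtype, np.integer):
            if not np.all(np.equal(np.mod(arr, 1), 0)):
                raise ValueError(
                    f"cell {cell_id!r}, {chrom} allele {allele}: non-integer copy number"
                )
            arr = arr.astype(np.int64)
        else:
            arr = arr.astype(np.int64)
        if np.any(arr < 0):
            i = int(np.argmax(arr < 0))
            raise ValueError(
                f"cell {cell_id!r}, {chrom} allele {allele}, bin {i + 1}: "
                "negative copy number"
            )
        expected = layout.n_bins(chrom)
        if arr.shape != (expected,):
            raise ValueError(
                f"cell {cell_id!r}, {chrom} allele {allele}: expected {expected} bins, "
                f"got {arr.shape[0]}"
            )
        out[(chrom, allele)] = arr
    return out


@dataclass
class CopyNumberProfile:
    """Integer copy numbers of one cell over the bins of a genome layout.

    ``allele_mode`` is ``"total"`` (one vector per chromosome, allele index
    0) or ``"allele"`` (two vectors per chromosome, allele indices 0 and 1).
    With the 22 human autosomes this gives the K = 22 (total) or K = 44
    (allele-specific) chromosome vectors over which all distances sum.
    """

    cell_id: str
    layout: GenomeLayout
    data: dict[ChromAllele, np.ndarray]
    allele_mode: str = "total"

    def __post_init__(self) -> None:
        if self.allele_mode not in ("total", "allele"):
            raise ValueError(f"unknown allele_mode {self.allele_mode!r}")
        n_alleles = 1 if self.allele_mode == "total" else 2
        expected_keys = {
            (chrom, a) for chrom in self.layout.chrom_names for a in range(n_alleles)
        }
        if set(self.data) != expected_keys:
            missing = expected_keys - set(self.data)
            extra = set(self.data) - expected_keys
            raise ValueError(
                f"cell {self.cell_id!r}: profile keys do not match layout "
                f"(missing {sorted(missing)[:3]}, extra {sorted(extra)[:3]})"
            )
        self.data = _validate_vectors(self.data, self.layout, self.cell_id)

    @property
    def n_alleles(self) -> int:
        return 1 if self.allele_mode == "total" else 2

    def keys(self) -> list[ChromAllele]:
        """Vector keys in canonical (chromosome, allele) order."""
        return [
            (chrom, a)
            for chrom in self.layout.chrom_names
            for a in range(self.n_alleles)
        ]

    def vector(self) -> np.ndarray:
        """All copy numbers concatenated in canonical key order."""
        return np.concatenate([self.data[k] for k in self.keys()])

    def total(self) -> "CopyNumberProfile":
        """Collapse an allele-specific profile to total copy numbers."""
        if self.allele_mode == "total":
            return self
        data = {
            (chrom, 0): self.data[(chrom, 0)] + self.data[(chrom, 1)]
            for chrom in self.layout.chrom_names
        }
        return CopyNumberProfile(self.cell_id, self.layout, data, "total")

    def same_layout(self, other: "CopyNumberProfile") -> bool:
        return self.layout == other.layout and self.allele_mode == other.allele_mode

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, CopyNumberProfile):
            return NotImplemented
        return (
            self.cell_id == other.cell_id
            and self.same_layout(other)
            and all(np.array_equal(self.data[k], other.data[k]) for k in self.keys())
        )


@dataclass
class BreakpointProfile:
    """Successive copy-number differences of a CNP, per chromosome/allele."""

    cell_id: str
    layout: GenomeLayout
    data: dict[ChromAllele, np.ndarray]
    allele_mode: str = "total"

    def keys(self) -> list[ChromAllele]:
        n_alleles = 1 if self.allele_mode == "total" else 2
        return [
            (chrom, a)
            for chrom in self.layout.chrom_names
            for a in range(n_alleles)
        ]

    def vector(self) -> np.ndarray:
        parts = [self.data[k] for k in self.keys()]
        if not parts:
            return np.zeros(0, dtype=np.int64)
        return np.concatenate(parts)


def to_breakpoints(profile: CopyNumberProfile) -> BreakpointProfile:
    """Breakpoint profile of ``profile``: b_i = c_{i+1} - c_i per chromosome.

    Each chromosome/allele vector of length ``n`` yields a breakpoint vector
    of length ``n - 1`` (empty for single-bin chromosomes); chromosomes are
    differenced independently.
    """
    data = {key: np.diff(vec) for key, vec in profile.data.items()}
    return BreakpointProfile(profile.cell_id, profile.layout, data, profile.allele_mode)


@dataclass
class CloneAssignment:
    """Mapping from cell id to clone label; unlisted cells are unassigned."""

    labels: dict[str, str] = field(default_factory=dict)

    def clones(self) -> dict[str, set[str]]:
        """Clone label -> set of member cell ids."""
        out: dict[str, set[str]] = {}
        for cell, label in self.labels.items():
            out.setdefault(label, set()).add(cell)
        return out

    def cells(self) -> set[str]:
        return set(self.labels)


def check_shared_layout(profiles: Iterable[CopyNumberProfile]) -> None:
    """Raise if the profiles do not share one layout and allele mode."""
    profiles = list(profiles)
    if not profiles:
        raise ValueError("empty profile list")
    first = profiles[0]
    for p in profiles[1:]:
        if p.layout != first.layout:
            raise ValueError(
                f"cell {p.cell_id!r}: genome layout differs from {first.cell_id!r}"
            )
        if p.allele_mode != first.allele_mode:
            raise ValueError(
                f"cell {p.cell_id!r}: allele_mode {p.allele_mode!r} differs from "
                f"{first.allele_mode!r}"
            )
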