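"""Readers and writers for the tabular CNP, clone, and matrix formats.

Two tab-separated CNP layouts are supported, both with a header row and
1-based inclusive coordinates:

* **long** — columns ``cell  chrom  start  end  cn`` with an optional
  second copy-number column ``cn_b``; the presence of ``cn_b`` switches the
  dataset to allele-specific mode.
* **wide** — one row per cell (first column ``cell``), one column per bin
  named ``chrom:start-end``; allele-specific wide tables carry two columns
  per bin, suffixed ``|a`` and ``|b``.

Bins must tile each chromosome contiguously with a uniform width (the last
bin of a chromosome may be truncated).  Round trips are bit-exact on the
integer copy numbers.
"""

from __future__ import annotations

from typing import Iterable, Optional

import numpy as np
import pandas as pd

from .genome import DEFAULT_REGION_SIZE, GenomeLayout
from .profiles import CloneAssignment, CopyNumberProfile, check_shared_layout


def _layout_from_bins(bins: dict[str, list[tuple[int, int]]]) -> GenomeLayout:
    """Infer a GenomeLayout from per-chromosome 1-based inclusive bins."""
    bin_size: Optional[int] = None
    chroms: list[tuple[str, int]] = []
    for chrom, edges in bins.items():
        edges = sorted(edges)
        prev_end = 0
        for i, (start, end) in enumerate(edges):
            if start != prev_end + 1 or end < start:
                raise ValueError(
                    f"{chrom}: bins do not tile the chromosome at {start}-{end}"
                )
            width = end - start + 1
            last = i == len(edges) - 1
            if bin_size is None:
                if not last:
                    bin_size = width
            elif width != bin_size and not (last and width < bin_size):
                raise ValueError(
                    f"{chrom}: bin {start}-{end} has width {width}, expected {bin_size}"
                )
            prev_end = end
        chroms.append((chrom, prev_end))
    if bin_size is None:  # every chromosome has a single bin
        bin_size = max(length for _, length in chroms)
    region = min(DEFAULT_REGION_SIZE, bin_size)
    return GenomeLayout(tuple(chroms), bin_size, region)


def _profiles_from_long(df: pd.DataFrame) -> tuple[list[CopyNumberProfile], GenomeLayout]:
    allele_specific = "cn_b" in df.columns
    cn_cols = ["cn", "cn_b"] if allele_specific else ["cn"]
    for col in cn_cols:
        vals = df[col]
        if not np.issubdtype(vals.dtype, np.integer):
            bad = df[~np.equal(np.mod(vals, 1), 0) | vals.isna()]
            if len(bad):
                row = bad.iloc[0]
                raise ValueError(
                    f"cell {row['cell']!r}, {row['chrom']}:{row['start']}: "
                    f"non-integer copy number {row[col]!r}"
                )
            df[col] = vals.astype(np.int64)
        neg = df[df[col] < 0]
        if len(neg):
            row = neg.iloc[0]
            raise ValueError(
                f"cell {row['cell']!r}, {row['chrom']}:{row['start']}: "
                "negative copy number"
            )

    first_cell = df["cell"].iloc[0]
    ref = df[df["cell"] == first_cell]
    chrom_order = list(dict.fromkeys(ref["chrom"]))
    bins = {
        chrom: list(
            zip(ref[ref["chrom"] == chrom]["start"], ref[ref["chrom"] == chrom]["end"])
        )
        for chrom in chrom_order
    }
    layout = _layout_from_bins(bins)
    mode = "allele" if allele_specific else "total"

    profiles = []
    for cell, group in df.groupby("cell", sort=False):
        data: dict = {}
        for chrom in chrom_order:
            sub = group[group["chrom"] == chrom].sort_values("start")
            expected = bins[chrom]
            got = list(zip(sub["start"], sub["end"]))
            if got != expected:
                raise ValueError(
                    f"cell {cell!r}, {chrom}: bins inconsistent with cell "
                    f"{first_cell!r}"
                )
            data[(chrom, 0)] = sub["cn"].to_numpy()
            if allele_specific:
                data[(chrom, 1)] = sub["cn_b"].to_numpy()
        profiles.append(CopyNumberProfile(str(cell), layout, data, mode))
    return profiles, layout


def _parse_wide_column(col: str) -> tuple[str, int, int, int]:
    name, allele = col, 0
    if name.endswith("|a"):
        name = name[:-2]
    elif name.endswith("|b"):
        name, allele = name[:-2], 1
    chrom, _, span = name.partition(":")
    start_s, _, end_s = span.partition("-")
    try:
        return chrom, int(start_s), int(end_s), allele
    except ValueError as exc:
        raise ValueError(f"malformed bin column {col!r}") from exc


def _profiles_from_wide(df: pd.DataFrame) -> tuple[list[CopyNumberProfile], GenomeLayout]:
    cells = df.iloc[:, 0].astype(str)
    bin_cols = list(df.columns[1:])
    parsed = [_parse_wide_column(c) for c in bin_cols]
    allele_specific = any(a == 1 for *_, a in parsed)
    mode = "allele" if allele_specific else "total"

    bins: dict[str, list[tuple[int, int]]] = {}
    for chrom, start, end, allele in parsed:
        if allele == 0:
            bins.setdefault(chrom, []).append((start, end))
    layout = _layout_from_bins(bins)

    col_by_key: dict[tuple[str, int, int], str] = {}
    for col, (chrom, start, end, allele) in zip(bin_cols, parsed):
        col_by_key[(chrom, start, allele)] = col

    profiles = []
    for i, cell in enumerate(cells):
        data: dict = {}
        for chrom in layout.chrom_names:
            edges = sorted(bins[chrom])
            for allele in range(2 if allele_specific else 1):
                cols = [col_by_key[(chrom, s, allele)] for s, _ in edges]
                vals = df.loc[df.index[i], cols].to_numpy()
                data[(chrom, allele)] = vals
        try:
            profiles.append(CopyNumberProfile(cell, layout, data, mode))
        except ValueError as exc:
            raise ValueError(str(exc)) from exc
    return profiles, layout


def read_cnp_table(path, format_hint: Optional[str] = None):
    """Read a CNP table (long or wide TSV).

    Returns ``(profiles, layout)``.  ``format_hint`` may be ``"long"`` or
    ``"wide"``; by default the format is detected from the header.
    """
    df = pd.read_csv(path, sep="\t")
    if df.empty:
        raise ValueError(f"{path}: empty CNP table")
    if format_hint is None:
        format_hint = "long" if {"cell", "chrom", "start", "end", "cn"} <= set(
            df.columns
        ) else "wide"
    if format_hint == "long":
        return _profiles_from_long(df)
    if format_hint == "wide":
        return _profiles_from_wide(df)
    raise ValueError(f"unknown format hint {format_hint!r}")


def write_cnp_table(
    profiles: Iterable[CopyNumberProfile], path, format: str = "long"
) -> None:
    """Write profiles as a TSV table (``format``: ``"long"`` or ``"wide"``)."""
    profiles = list(profiles)
    check_shared_layout(profiles)
    layout = profiles[0].layout
    mode = profiles[0].allele_mode

    if format == "long":
        records = []
        for p in profiles:
            for chrom in layout.chrom_names:
                for i, (b0, b1) in enumerate(layout.bin_edges(chrom)):
                    rec = {
                        "cell": p.cell_id,
                        "chrom": chrom,
                        "start": b0 + 1,
                        "end": b1,
                        "cn": int(p.data[(chrom, 0)][i]),
                    }
                    if mode == "allele":
                        rec["cn_b"] = int(p.data[(chrom, 1)][i])
                    records.append(rec)
        pd.DataFrame.from_records(records).to_csv(path, sep="\t", index=False)
    elif format == "wide":
        columns: list[str] = []
        keys: list[tuple[str, int, int]] = []
        for chrom in layout.chrom_names:
            for i, (b0, b1) in enumerate(layout.bin_edges(chrom)):
                base = f"{chrom}:{b0 + 1}-{b1}"
                if mode == "allele":
                    columns += [base + "|a", base + "|b"]
                    keys += [(chrom, 0, i), (chrom, 1, i)]
                else:
                    columns.append(base)
                    keys.append((chrom, 0, i))
        rows = {
            p.cell_id: [int(p.data[(chrom, a)][i]) for chrom, a, i in keys]
            for p in profiles
        }
        df = pd.DataFrame.from_dict(rows, orient="index", columns=columns)
        df.index.name = "cell"
        df.to_csv(path, sep="\t")
    else:
        raise ValueError(f"unknown format {format!r}")


def read_clone_table(path) -> CloneAssignment:
    """Read a two-column (cell, clone) TSV; a header row is optional."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    if list(df.columns[:2]) != ["cell", "clone"]:
        df = pd.read_csv(path, sep="\t", dtype=str, header=None, names=["cell", "clone"])
    return CloneAssignment(dict(zip(df["cell"], df["clone"])))


def write_clone_table(clones: CloneAssignment, path) -> None:
    pd.DataFrame(
        {"cell": list(clones.labels), "clone": list(clones.labels.values())}
    ).to_csv(path, sep="\t", index=False)


def write_distance_matrix(ids, matrix: np.ndarray, path, format: str = "tsv") -> None:
    """Write a distance matrix as TSV or square PHYLIP."""
    matrix = np.asarray(matrix)
    if format == "tsv":
        pd.DataFrame(matrix, index=ids, columns=ids).to_csv(path, sep="\t")
    elif format == "phylip":
        with open(path, "w") as fh:
            fh.write(f"{len(ids)}\n")
            for name, row in zip(ids, matrix):
                fh.write(name + "  " + "  ".join(f"{x:.6f}" for x in row) + "\n")
    else:
        raise ValueError(f"unknown format {format!r}")


def read_distance_matrix(path) -> tuple[list[str], np.ndarray]:
    """Read a TSV distance matrix written by :func:`write_distance_matrix`."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    return [str(i) for i in df.index], df.to_numpy(dtype=float)
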