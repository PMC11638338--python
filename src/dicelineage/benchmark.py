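"""Replication harness: simulate → infer → evaluate, over seeded replicates.

A *setting* names a simulation scenario (baseline or four-clone trees, at
one of the three noise presets).  Each replicate simulates a dataset,
reconstructs the lineage with both the standard-root (DICE-star) and
breakpoint-root (DICE-bar) balanced-minimum-evolution pipelines, and
scores them against the ground truth; results are returned per replicate
with the mean appended.
"""

from __future__ import annotations

import dataclasses
from typing import Optional

import numpy as np
import pandas as pd

from .distances import DICE_BAR, DICE_STAR
from .evaluation import clone_f1, nrfd
from .phylogeny import infer_lineage
from .simulate import NOISE_PRESETS, SimulationConfig, simulate

#: setting name -> (n_clones, noise preset name)
SETTINGS: dict[str, tuple[int, str]] = {
    "baseline-none": (0, "none"),
    "baseline-low": (0, "low"),
    "baseline-high": (0, "high"),
    "clones4-none": (4, "none"),
    "clones4-low": (4, "low"),
    "clones4-high": (4, "high"),
}

METHODS = {"dice-star": DICE_STAR, "dice-bar": DICE_BAR}


def replicate_seeds(seed: int, n: int) -> list[int]:
    """Independent per-replicate seeds derived from one master seed."""
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    return [int(s) for s in rng.integers(0, 2**31 - 1, size=n)]


def run_benchmark(
    setting: str,
    n_replicates: int,
    seed: int,
    n_cells: int = 250,
    lam: Optional[float] = None,
    spr: bool = True,
) -> pd.DataFrame:
    """Run ``n_replicates`` simulate/infer/eval rounds of ``setting``.

    Returns a table with one row per (replicate, method) plus ``mean``
    rows; columns are the normalized RF distance and, for clone settings,
    the clone-detection F1.  Fully deterministic for a given seed.
    """
    if setting not in SETTINGS:
        raise ValueError(
            f"unknown setting {setting!r}; valid: {', '.join(sorted(SETTINGS))}"
        )
    n_clones, preset = SETTINGS[setting]
    config = SimulationConfig(n_cells=n_cells, n_clones=n_clones)
    if lam is not None:
        config = dataclasses.replace(config, lam=lam)
    noise = NOISE_PRESETS[preset]

    rows = []
    for rep, rep_seed in enumerate(replicate_seeds(seed, n_replicates)):
        truth = simulate(config, noise, rep_seed)
        for method, variant in METHODS.items():
            tree = infer_lineage(truth.noisy, variant, method="balme", do_spr=spr)
            row = {
                "setting": setting,
                "replicate": rep,
                "seed": rep_seed,
                "method": method,
                "nrfd": nrfd(truth.tree, tree),
            }
            if n_clones:
                row["clone_f1"] = clone_f1(tree, truth.clones)
            rows.append(row)
    df = pd.DataFrame(rows)
    means = (
        df.groupby("method", sort=True)
        .mean(numeric_only=True)
        .drop(columns=["replicate", "seed"])
        .reset_index()
    )
    means.insert(0, "setting", setting)
    means.insert(1, "replicate", "mean")
    return pd.concat([df, means], ignore_index=True)
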