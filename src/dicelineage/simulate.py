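"""Coalescent simulation of single-cell copy-number data.

The generative model mirrors the standard single-cell CNA simulation
pipeline: a neutral-coalescent cell lineage tree; a diploid founder genome
represented per allele as an ordered array of minimum-CNA-size regions
(``M`` bp, tracked as interval runs so hg38-scale genomes stay cheap);
Poisson numbers of segmental gains/deletions accumulated along every edge
(with a 10x burst on the founder edge and optional whole-genome
duplication); optional clonal expansions marked by chromosome-arm and
whole-chromosome CNAs at selected ancestral nodes; noise-free binned
profiles obtained by mapping surviving regions back to reference bins; and
two error models — segment-boundary resampling and per-bin Gaussian
jitter — that turn clean profiles into realistically noisy ones.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence, Union

import numpy as np
from scipy.stats import norm

from .genome import GenomeLayout
from .profiles import CloneAssignment, CopyNumberProfile
from .tree import CellLineageTree, TreeNode

Runs = list[tuple[int, int]]
#: per (chromosome, allele): ordered reference-region intervals (region units)
GenomeState = dict[tuple[str, int], Runs]

SeedLike = Union[int, np.random.SeedSequence, np.random.Generator, None]


def _rng(seed: SeedLike) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


@dataclass(frozen=True)
class SimulationConfig:
    """Generative parameters of one simulated dataset.

    Defaults follow the common single-cell CNA regime: 250 cells over the
    22 hg38 autosomes, 1 Mbp bins, minimum CNA size M = 1 kbp, a mean of
    ``lam`` = 2 segmental CNAs per edge with a 10x founder burst, mean CNA
    length ``beta`` = 5 Mbp (exponential), mean extra copies per gain
    ``delta`` = 2 (geometric), and even gain/deletion and allele odds.
    """

    n_cells: int = 250
    layout: GenomeLayout = field(default_factory=GenomeLayout)
    lam: float = 2.0                 # mean segmental CNAs per edge
    founder_multiplier: float = 10.0  # founder-edge event burst
    alpha: float = 0.5               # P(event hits allele 1)
    p_gain: float = 0.5              # P(gain) vs deletion
    beta: float = 5_000_000.0        # mean CNA length, bp
    delta: float = 2.0               # mean extra copies of a gain
    wgd: bool = False
    n_clones: int = 0
    clonal_events: int = 2           # chromosomal CNAs per clone ancestor
    p_arm: float = 0.75              # P(arm-level) vs whole-chromosome
    p_chrom_del: float = 0.5         # P(deletion) for chromosomal CNAs (0.8 with WGD)
    growth: float = 1.0              # exponential growth rate (branch times only)

    def __post_init__(self) -> None:
        if self.n_cells < 3:
            raise ValueError("n_cells must be at least 3")
        if self.lam < 0 or self.founder_multiplier < 0:
            raise ValueError("event rates must be non-negative")
        for name in ("alpha", "p_gain", "p_arm", "p_chrom_del"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")
        if self.beta < self.layout.region_size:
            raise ValueError("mean CNA length must be >= region size")
        if self.delta < 1:
            raise ValueError("delta (mean extra copies) must be >= 1")
        if self.n_clones and self.n_clones >= self.n_cells / 2:
            raise ValueError("n_clones must be < n_cells / 2")

    @property
    def effective_p_chrom_del(self) -> float:
        return 0.8 if self.wgd and self.p_chrom_del == 0.5 else self.p_chrom_del


@dataclass(frozen=True)
class NoiseConfig:
    """Boundary (``r_b``) and jitter (``r_j``) error rates."""

    r_b: float = 0.0
    r_j: float = 0.0

    def __post_init__(self) -> None:
        if self.r_b < 0 or self.r_j < 0:
            raise ValueError("noise rates must be non-negative")

    @property
    def is_none(self) -> bool:
        return self.r_b == 0.0 and self.r_j == 0.0


#: the three canonical noise presets
NOISE_PRESETS: dict[str, NoiseConfig] = {
    "none": NoiseConfig(0.0, 0.0),
    "low": NoiseConfig(0.02, 0.1),
    "high": NoiseConfig(0.04, 0.1),
}


@dataclass
class GroundTruth:
    """Everything one simulated dataset produces."""

    tree: CellLineageTree
    clean: list[CopyNumberProfile]
    noisy: list[CopyNumberProfile]
    clones: CloneAssignment
    events: list[dict]
    config: SimulationConfig
    noise: NoiseConfig


# ---------------------------------------------------------------------------
# ground-truth tree


def sample_tree(n_cells: int, growth: float = 1.0, seed: SeedLike = None) -> CellLineageTree:
    """Neutral-coalescent cell lineage tree with ``n_cells`` leaves.

    Topology: uniformly chosen pair merges (Kingman coalescent).  Branch
    lengths are coalescent waiting times, time-changed for an exponentially
    growing population when ``growth`` > 0; they are cosmetic — events are
    drawn per edge, not per unit time.
    """
    if n_cells < 3:
        raise ValueError("need at least 3 cells")
    rng = _rng(seed)
    lineages: list[tuple[TreeNode, float]] = [
        (TreeNode(name=f"cell_{i + 1}"), 0.0) for i in range(n_cells)
    ]
    t = 0.0
    anc = 0
    while len(lineages) > 1:
        k = len(lineages)
        w = rng.exponential(2.0 / (k * (k - 1)))
        if growth > 0:
            w = math.log1p(growth * w) / growth
        t += w
        i, j = sorted(rng.choice(k, size=2, replace=False))
        (a, ha), (b, hb) = lineages[i], lineages[j]
        anc += 1
        parent = TreeNode(name=f"node_{anc}")
        a.length = t - ha
        b.length = t - hb
        parent.children = [a, b]
        lineages = [lineages[m] for m in range(k) if m not in (i, j)]
        lineages.append((parent, t))
    return CellLineageTree(lineages[0][0])


# ---------------------------------------------------------------------------
# genome evolution


def _diploid(layout: GenomeLayout) -> GenomeState:
    return {
        (chrom, allele): [(0, layout.n_regions(chrom))]
        for chrom in layout.chrom_names
        for allele in (0, 1)
    }


def _runs_len(runs: Runs) -> int:
    return sum(b - a for a, b in runs)


def _split_runs(runs: Runs, pos: int) -> tuple[Runs, Runs]:
    """Split at current-genome coordinate ``pos`` (region units)."""
    left: Runs = []
    right: Runs = []
    acc = 0
    for a, b in runs:
        length = b - a
        if acc + length <= pos:
            left.append((a, b))
        elif acc >= pos:
            right.append((a, b))
        else:
            cut = a + (pos - acc)
            left.append((a, cut))
            right.append((cut, b))
        acc += length
    return left, right


def _apply_segment(runs: Runs, start: int, length: int, gain: bool, copies: int) -> Runs:
    left, rest = _split_runs(runs, start)
    mid, right = _split_runs(rest, length)
    if gain:
        return left + mid * (copies + 1) + right
    return left + right


def _segmental_event(genome: GenomeState, config: SimulationConfig, rng) -> Optional[dict]:
    layout = config.layout
    M = layout.region_size
    for _ in range(20):  # bounded retries when a chromosome copy is empty
        allele = 1 if rng.random() < config.alpha else 0
        keys = [(c, allele) for c in layout.chrom_names]
        lengths = np.array([_runs_len(genome[k]) for k in keys], dtype=float)
        total = lengths.sum()
        if total == 0:
            continue
        ci = rng.choice(len(keys), p=lengths / total)
        chrom, _ = keys[ci]
        L = int(lengths[ci])
        gain = rng.random() < config.p_gain
        length_bp = rng.exponential(config.beta)
        n_regions = max(1, math.ceil(length_bp / M))
        n_regions = min(n_regions, L)  # events past the end are truncated
        start = int(rng.integers(0, L - n_regions + 1))
        copies = int(rng.geometric(1.0 / config.delta)) if gain else 0
        genome[(chrom, allele)] = _apply_segment(
            genome[(chrom, allele)], start, n_regions, gain, copies
        )
        return {
            "kind": "segmental",
            "chrom": chrom,
            "allele": allele,
            "type": "gain" if gain else "deletion",
            "start_region": start,
            "n_regions": n_regions,
            "copies": copies,
        }
    return None


def _chromosomal_event(genome: GenomeState, config: SimulationConfig, rng) -> Optional[dict]:
    layout = config.layout
    for _ in range(20):
        chrom = layout.chrom_names[rng.integers(len(layout.chrom_names))]
        allele = int(rng.integers(2))
        runs = genome[(chrom, allele)]
        L = _runs_len(runs)
        if L == 0:
            continue
        arm_level = rng.random() < config.p_arm
        deletion = rng.random() < config.effective_p_chrom_del
        if arm_level:
            boundary = max(1, min(L - 1, round(layout.arm_fraction * L))) if L > 1 else L
            short_arm = rng.random() < 0.5
            start, length = (0, boundary) if short_arm else (boundary, L - boundary)
            if length == 0:
                start, length = 0, L
            genome[(chrom, allele)] = _apply_segment(runs, start, length, not deletion, 1)
            scope = "arm"
        else:
            genome[(chrom, allele)] = [] if deletion else runs * 2
            scope = "chromosome"
            start, length = 0, L
        return {
            "kind": "chromosomal",
            "chrom": chrom,
            "allele": allele,
            "type": "deletion" if deletion else "duplication",
            "scope": scope,
            "start_region": start,
            "n_regions": length,
            "copies": 1,
        }
    return None


def _clade_leaf_sets(tree: CellLineageTree) -> dict[str, frozenset[str]]:
    below: dict[int, frozenset[str]] = {}
    out: dict[str, frozenset[str]] = {}
    for node in tree.postorder():
        if node.is_leaf:
            below[id(node)] = frozenset((node.name,))
        else:
            clade = frozenset().union(*(below[id(c)] for c in node.children))
            below[id(node)] = clade
            out[node.name] = clade
    return out


def select_clone_ancestors(tree: CellLineageTree, n_clones: int) -> list[str]:
    """Pick ``n_clones`` disjoint ancestral nodes by clade size.

    Preference goes to clades whose size is closest to ``n / n_clones``
    and within ``[n/(4 n_clones), n/n_clones]``; out-of-range clades are
    used only when the preferred pool cannot supply enough disjoint
    choices.
    """
    n = tree.n_leaves
    clades = _clade_leaf_sets(tree)
    clades = {
        name: s for name, s in clades.items() if 1 < len(s) < n
    }
    target = n / n_clones
    lo, hi = n / (4 * n_clones), n / n_clones
    ranked = sorted(
        clades.items(), key=lambda kv: (abs(len(kv[1]) - target), len(kv[1]), kv[0])
    )
    in_range = [kv for kv in ranked if lo <= len(kv[1]) <= hi]
    out_range = [kv for kv in ranked if not lo <= len(kv[1]) <= hi]

    chosen: list[tuple[str, frozenset[str]]] = []
    for pool in (in_range, out_range):
        for name, s in pool:
            if len(chosen) == n_clones:
                break
            if all(not (s & t) for _, t in chosen):
                chosen.append((name, s))
    if len(chosen) < n_clones:
        raise ValueError(f"cannot place {n_clones} disjoint clones on this tree")
    return [name for name, _ in chosen]


def evolve(
    tree: CellLineageTree, config: SimulationConfig, seed: SeedLike = None
) -> tuple[dict[str, GenomeState], list[dict], CloneAssignment]:
    """Evolve genomes along ``tree``; returns per-node genomes, the event
    log, and the clone assignment induced by the selected clone ancestors.

    The root receives ``Poisson(founder_multiplier * lam)`` segmental
    events (plus WGD when configured); every other node receives
    ``Poisson(lam)`` segmental events, and clone-ancestor nodes receive
    ``clonal_events`` additional chromosome-arm / whole-chromosome CNAs
    before their segmental events.
    """
    rng = _rng(seed)
    clone_nodes: dict[str, str] = {}
    if config.n_clones:
        for i, name in enumerate(select_clone_ancestors(tree, config.n_clones)):
            clone_nodes[name] = f"clone_{i + 1}"

    genomes: dict[str, GenomeState] = {}
    events: list[dict] = []

    def apply_events(node: TreeNode, genome: GenomeState, is_root: bool) -> None:
        if is_root:
            if config.wgd:
                for key in genome:
                    genome[key] = genome[key] * 2
                events.append({"kind": "wgd", "node": node.name})
            n_seg = rng.poisson(config.founder_multiplier * config.lam)
        else:
            if not node.is_leaf and node.name in clone_nodes:
                for _ in range(config.clonal_events):
                    ev = _chromosomal_event(genome, config, rng)
                    if ev:
                        ev["node"] = node.name
                        events.append(ev)
            n_seg = rng.poisson(config.lam)
        for _ in range(n_seg):
            ev = _segmental_event(genome, config, rng)
            if ev:
                ev["node"] = node.name
                events.append(ev)

    stack: list[tuple[TreeNode, Optional[str]]] = [(tree.root, None)]
    while stack:
        node, parent_name = stack.pop()
        if parent_name is None:
            genome = _diploid(config.layout)
        else:
            genome = {k: list(v) for k, v in genomes[parent_name].items()}
        apply_events(node, genome, parent_name is None)
        genomes[node.name] = genome
        for child in node.children:
            stack.append((child, node.name))

    labels: dict[str, str] = {}
    clade_sets = _clade_leaf_sets(tree)
    for anc, label in clone_nodes.items():
        for cell in clade_sets[anc]:
            labels[cell] = label
    return genomes, events, CloneAssignment(labels)


# ---------------------------------------------------------------------------
# profiles


def _bin_counts(runs: Runs, n_bins: int, per_bin: int, n_regions: int) -> np.ndarray:
    counts = np.zeros(n_bins)
    for a, b in runs:
        f = a // per_bin
        l = (b - 1) // per_bin
        if f == l:
            counts[f] += b - a
        else:
            counts[f] += (f + 1) * per_bin - a
            counts[l] += b - l * per_bin
            if l > f + 1:
                counts[f + 1 : l] += per_bin
    denom = np.full(n_bins, per_bin, dtype=float)
    denom[-1] = n_regions - (n_bins - 1) * per_bin
    return np.floor(counts / denom + 0.5).astype(np.int64)  # round half up


def to_profiles(
    genomes: dict[str, GenomeState], layout: GenomeLayout
) -> list[CopyNumberProfile]:
    """Noise-free binned allele-specific profiles from genome states.

    Each bin's copy number is the mean copy count of the reference
    M-regions it covers, rounded half-up; an unmutated diploid genome maps
    to 1 in every allele bin.
    """
    per_bin = layout.regions_per_bin
    out = []
    for cell, genome in genomes.items():
        data = {}
        for chrom in layout.chrom_names:
            n_bins = layout.n_bins(chrom)
            n_regions = layout.n_regions(chrom)
            for allele in (0, 1):
                data[(chrom, allele)] = _bin_counts(
                    genome[(chrom, allele)], n_bins, per_bin, n_regions
                )
        out.append(CopyNumberProfile(cell, layout, data, "allele"))
    return out


# ---------------------------------------------------------------------------
# noise models


def jitter_flip_probability(c: int, r_j: float) -> float:
    """Probability that jitter changes a bin with copy number ``c``.

    The redrawn value is Normal(c, (c r_j)^2) rounded to the nearest
    integer, so the bin changes exactly when the draw lands more than 0.5
    away from ``c``: ``2 (1 - Phi(0.5 / (c r_j)))``.
    """
    if c <= 0 or r_j == 0:
        return 0.0
    return float(2.0 * (1.0 - norm.cdf(0.5 / (c * r_j))))


def apply_jitter(
    profile: CopyNumberProfile, r_j: float, seed: SeedLike = None
) -> CopyNumberProfile:
    """Per-bin Gaussian jitter: each bin with copy number ``c`` is redrawn
    from Normal(c, (c r_j)^2), rounded, and clamped at zero."""
    if r_j < 0:
        raise ValueError("r_j must be non-negative")
    rng = _rng(seed)
    data = {}
    for key, vec in profile.data.items():
        if r_j == 0:
            data[key] = vec.copy()
            continue
        draw = vec + rng.standard_normal(vec.shape) * vec * r_j
        data[key] = np.maximum(np.rint(draw), 0).astype(np.int64)
    return CopyNumberProfile(profile.cell_id, profile.layout, data, profile.allele_mode)


#: segment-length saturation (bins) of the boundary-noise SD; boundary
#: mis-calling in CNA callers is local to the breakpoint, so the error
#: stops growing once a segment is much longer than the caller's window.
BOUNDARY_SD_SATURATION = 7


def boundary_shift_sd(seg_len: int, r_b: float, saturation: int = BOUNDARY_SD_SATURATION) -> float:
    """SD (in bins) of a segment's redrawn length under boundary noise.

    The variance is proportional to the error rate and to the segment
    length up to a saturation of ``saturation`` bins:
    ``sd = sqrt(r_b * min(L, saturation))``.  Saturating keeps the error
    local to the breakpoint instead of growing linearly with segment size;
    the constant is calibrated so that the default low/high presets
    reproduce the breakpoint precision/recall of realistic CNA callers.
    """
    return math.sqrt(r_b * min(seg_len, saturation))


def apply_boundary(
    profile: CopyNumberProfile,
    r_b: float,
    seed: SeedLike = None,
    saturation: int = BOUNDARY_SD_SATURATION,
) -> CopyNumberProfile:
    """Segment-boundary resampling noise.

    Per chromosome/allele vector, maximal equal-copy runs are scanned left
    to right; each segment's length is redrawn from a Gaussian centred on
    its length with SD :func:`boundary_shift_sd`, rounded to whole bins
    and clamped to >= 1 (and capped so later segments keep at least one
    bin); the final segment absorbs the residual, conserving the
    chromosome's bin count.  The boundary with the next segment shifts
    accordingly: extension overwrites neighbour bins with this segment's
    value, shrinkage cedes bins to the neighbour.
    """
    if r_b < 0:
        raise ValueError("r_b must be non-negative")
    rng = _rng(seed)
    data = {}
    for key, vec in profile.data.items():
        n = len(vec)
        change = np.nonzero(np.diff(vec))[0]
        if r_b == 0 or len(change) == 0:
            data[key] = vec.copy()
            continue
        starts = np.concatenate([[0], change + 1])
        seg_lens = np.diff(np.concatenate([starts, [n]]))
        vals = vec[starts]
        m = len(vals)
        new_lens = np.empty(m, dtype=np.int64)
        remaining = n
        for i in range(m - 1):
            L = int(seg_lens[i])
            nl = int(round(rng.normal(L, boundary_shift_sd(L, r_b, saturation))))
            nl = max(1, min(nl, remaining - (m - 1 - i)))
            new_lens[i] = nl
            remaining -= nl
        new_lens[m - 1] = remaining
        data[key] = np.repeat(vals, new_lens)
    return CopyNumberProfile(profile.cell_id, profile.layout, data, profile.allele_mode)


def apply_noise(
    profile: CopyNumberProfile, noise: NoiseConfig, seed: SeedLike = None
) -> CopyNumberProfile:
    """Boundary noise first, then jitter (the canonical order)."""
    rng = _rng(seed)
    return apply_jitter(apply_boundary(profile, noise.r_b, rng), noise.r_j, rng)


# ---------------------------------------------------------------------------
# full pipeline


def simulate(
    config: SimulationConfig = SimulationConfig(),
    noise: NoiseConfig = NOISE_PRESETS["none"],
    seed: SeedLike = None,
) -> GroundTruth:
    """Run the full generator: tree, genomes, clean and noisy profiles.

    All randomness flows from ``seed`` through three named streams (tree,
    events, noise), so reruns with the same seed reproduce every artifact
    bit for bit; with the ``none`` noise preset the noisy profiles equal
    the clean ones.
    """
    if isinstance(seed, np.random.SeedSequence):
        ss = seed
    else:
        ss = np.random.SeedSequence(seed)
    tree_rng, event_rng, noise_rng = (np.random.default_rng(s) for s in ss.spawn(3))

    tree = sample_tree(config.n_cells, config.growth, tree_rng)
    genomes, events, clones = evolve(tree, config, event_rng)
    leaf_genomes = {name: genomes[name] for name in tree.leaf_names()}
    clean = to_profiles(leaf_genomes, config.layout)
    if noise.is_none:
        noisy = [
            CopyNumberProfile(
                p.cell_id, p.layout, {k: v.copy() for k, v in p.data.items()}, p.allele_mode
            )
            for p in clean
        ]
    else:
        noisy = [apply_noise(p, noise, noise_rng) for p in clean]
    return GroundTruth(tree, clean, noisy, clones, events, config, noise)
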