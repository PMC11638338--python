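"""Coalescent tree sampling, genome evolution, binning, and noise models."""

import math

import numpy as np
import pytest
from scipy import stats

from dicelineage.genome import GenomeLayout, uniform_layout
from dicelineage.simulate import (
    NOISE_PRESETS,
    NoiseConfig,
    SimulationConfig,
    apply_boundary,
    apply_jitter,
    boundary_shift_sd,
    evolve,
    jitter_flip_probability,
    sample_tree,
    select_clone_ancestors,
    simulate,
    to_profiles,
    _diploid,
)

from conftest import make_profile


@pytest.fixture
def small_config():
    layout = uniform_layout(2, chrom_length=20_000_000)
    return SimulationConfig(n_cells=6, layout=layout)


class TestSampleTree:
    def test_node_and_edge_counts(self):
        t = sample_tree(3, seed=0)
        nodes = list(t.postorder())
        assert len(nodes) == 5  # 3 leaves + 2 ancestors
        assert sum(len(n.children) for n in nodes) == 4  # edges

    def test_determinism(self):
        a = sample_tree(20, seed=7)
        b = sample_tree(20, seed=7)
        assert a.to_newick() == b.to_newick()

    def test_rooted_binary(self):
        t = sample_tree(25, seed=1)
        for node in t.postorder():
            assert len(node.children) in (0, 2)
        assert t.n_leaves == 25

    def test_quartet_topologies_uniform(self):
        # under the Kingman coalescent the three unrooted quartet
        # topologies are equally likely
        counts = {"cell_2": 0, "cell_3": 0, "cell_4": 0}
        for seed in range(1500):
            t = sample_tree(4, seed=seed)
            side = next(iter(t.bipartitions()))
            if "cell_1" not in side:
                side = frozenset(t.leaf_names()) - side
            partner = next(iter(side - {"cell_1"}))
            counts[partner] += 1
        chi2 = sum((c - 500) ** 2 / 500 for c in counts.values())
        # chi-square with 2 dof: reject only below the 0.001 quantile
        assert chi2 < stats.chi2.ppf(0.999, df=2), counts

    def test_too_few_cells_rejected(self):
        with pytest.raises(ValueError):
            sample_tree(2, seed=0)


class TestEvolve:
    def test_lambda_zero_keeps_leaves_diploid(self, small_config):
        import dataclasses

        cfg = dataclasses.replace(small_config, lam=0.0)
        tree = sample_tree(cfg.n_cells, seed=3)
        genomes, events, clones = evolve(tree, cfg, seed=3)
        assert events == []
        ref = _diploid(cfg.layout)
        for name in tree.leaf_names():
            assert genomes[name] == ref

    def test_wgd_doubles_every_region(self, small_config):
        import dataclasses

        cfg = dataclasses.replace(small_config, lam=0.0, wgd=True)
        tree = sample_tree(cfg.n_cells, seed=4)
        genomes, events, _ = evolve(tree, cfg, seed=4)
        assert [e["kind"] for e in events] == ["wgd"]
        for name in tree.leaf_names():
            for (chrom, allele), runs in genomes[name].items():
                n_regions = cfg.layout.n_regions(chrom)
                assert sorted(runs) == [(0, n_regions), (0, n_regions)]

    def test_poisson_event_rate(self):
        # mean segmental events per non-root edge ~ Poisson(lam)
        layout = uniform_layout(2, chrom_length=50_000_000)
        cfg = SimulationConfig(n_cells=800, layout=layout, lam=2.0)
        tree = sample_tree(cfg.n_cells, seed=5)
        _, events, _ = evolve(tree, cfg, seed=5)
        root_name = tree.root.name
        non_root = [e for e in events if e["node"] != root_name]
        n_edges = 2 * cfg.n_cells - 2
        mean = len(non_root) / n_edges
        se = math.sqrt(cfg.lam / n_edges)
        assert abs(mean - cfg.lam) < 3 * se

    def test_clone_labels_are_clades(self):
        layout = uniform_layout(2, chrom_length=20_000_000)
        cfg = SimulationConfig(n_cells=40, layout=layout, n_clones=3)
        tree = sample_tree(cfg.n_cells, seed=6)
        _, _, clones = evolve(tree, cfg, seed=6)
        clade_sets = {
            frozenset(members) for members in clones.clones().values()
        }
        tree_clades = set(tree.clades())
        assert len(clade_sets) == 3
        assert clade_sets <= tree_clades
        # disjoint
        all_cells = [c for s in clade_sets for c in s]
        assert len(all_cells) == len(set(all_cells))

    def test_clone_ancestor_sizes_near_target(self):
        tree = sample_tree(100, seed=7)
        names = select_clone_ancestors(tree, 4)
        sets = {n: s for n, s in zip(names, [None] * 4)}
        clades = {
            node.name: frozenset(c)
            for node, c in zip(tree.postorder(), tree.clades())
            if not node.is_leaf
        }
        sizes = [len(clades[n]) for n in names]
        assert all(100 / 16 <= s <= 100 / 4 + 1 for s in sizes)


class TestToProfiles:
    def test_unmutated_diploid_is_all_ones(self, small_config):
        layout = small_config.layout
        profiles = to_profiles({"c": _diploid(layout)}, layout)
        for key, vec in profiles[0].data.items():
            assert np.all(vec == 1)

    def test_three_bin_gain_reads_two(self):
        layout = uniform_layout(1, chrom_length=10_000_000)
        genome = _diploid(layout)
        # +1 copy of regions [2000, 5000) = bins 3..5 fully
        runs = genome[("chr1", 0)]
        genome[("chr1", 0)] = [(0, 5000), (2000, 5000), (5000, 10000)]
        p = to_profiles({"c": genome}, layout)[0]
        assert p.data[("chr1", 0)].tolist() == [1, 1, 2, 2, 2, 1, 1, 1, 1, 1]

    def test_half_bin_gain_rounds_up(self):
        layout = uniform_layout(1, chrom_length=10_000_000)
        genome = _diploid(layout)
        # +1 copy of half the regions of bin 1 -> mean 1.5 -> rounds to 2
        genome[("chr1", 0)] = [(0, 500), (0, 10000)]
        p = to_profiles({"c": genome}, layout)[0]
        assert p.data[("chr1", 0)][0] == 2
        assert np.all(p.data[("chr1", 0)][1:] == 1)


class TestJitter:
    def test_zero_rate_is_identity(self, tiny_layout):
        p = make_profile(tiny_layout, {"chr1": [2, 3, 1, 0, 2], "chr2": [1, 1, 4]})
        q = apply_jitter(p, 0.0, seed=0)
        assert p == q

    def test_zero_copy_bins_never_change(self, tiny_layout):
        p = make_profile(tiny_layout, {"chr1": [0, 0, 0, 0, 0], "chr2": [0, 0, 0]})
        q = apply_jitter(p, 0.5, seed=1)
        assert p == q

    @pytest.mark.parametrize(
        "c,expected_pct", [(3, 9.56), (2, 1.24)]
    )
    def test_flip_fraction_matches_gaussian_tail(self, c, expected_pct):
        # closed form
        assert 100 * jitter_flip_probability(c, 0.1) == pytest.approx(
            expected_pct, abs=0.01
        )
        # Monte Carlo on one million bins
        layout = uniform_layout(1, chrom_length=10**12, bin_size=10**6)
        p = make_profile(layout, {"chr1": np.full(10**6, c)})
        q = apply_jitter(p, 0.1, seed=2)
        frac = float((q.data[("chr1", 0)] != c).mean())
        assert frac == pytest.approx(expected_pct / 100, abs=3e-3)


class TestBoundary:
    def test_zero_rate_is_identity(self, tiny_layout):
        p = make_profile(tiny_layout, {"chr1": [2, 2, 3, 3, 3], "chr2": [1, 2, 2]})
        assert p == apply_boundary(p, 0.0, seed=0)

    def test_single_segment_chromosome_unchanged(self):
        layout = uniform_layout(1, chrom_length=30_000_000)
        p = make_profile(layout, {"chr1": [2] * 30})
        assert p == apply_boundary(p, 0.2, seed=1)

    def test_boundary_shift_distribution(self):
        # two 10-bin segments: the boundary shift follows the rounded
        # Gaussian with the model's stated SD (direct-sampling oracle)
        layout = uniform_layout(1, chrom_length=20_000_000)
        vec = [2] * 10 + [3] * 10
        p = make_profile(layout, {"chr1": vec})
        rng = np.random.default_rng(3)
        sd = boundary_shift_sd(10, 0.1)
        shifts = []
        for _ in range(20_000):
            q = apply_boundary(p, 0.1, rng)
            boundary = int(np.nonzero(np.diff(q.data[("chr1", 0)]))[0][0])
            shifts.append(boundary - 9)
        shifts = np.array(shifts)
        expected = np.rint(rng.normal(0.0, sd, size=200_000))
        expected = np.clip(expected, -9, 9)
        for k in (-2, -1, 0, 1, 2):
            got = float((shifts == k).mean())
            want = float((expected == k).mean())
            assert got == pytest.approx(want, abs=0.02), k

    def test_bin_counts_conserved(self, tiny_layout):
        rng = np.random.default_rng(4)
        from conftest import random_profiles

        for p in random_profiles(tiny_layout, 5, rng, allele_mode="allele"):
            q = apply_boundary(p, 0.1, rng)
            r = apply_jitter(q, 0.2, rng)
            for key in p.keys():
                assert len(q.data[key]) == len(p.data[key])
                assert len(r.data[key]) == len(p.data[key])
            # boundary noise permutes segment lengths, never values
            for key in p.keys():
                assert set(np.unique(q.data[key])) <= set(np.unique(p.data[key]))


class TestSimulatePipeline:
    def test_deterministic_given_seed(self, small_config):
        a = simulate(small_config, NOISE_PRESETS["low"], seed=11)
        b = simulate(small_config, NOISE_PRESETS["low"], seed=11)
        assert a.tree.to_newick() == b.tree.to_newick()
        for pa, pb in zip(a.noisy, b.noisy):
            assert pa == pb

    def test_none_preset_noisy_equals_clean(self, small_config):
        gt = simulate(small_config, NOISE_PRESETS["none"], seed=12)
        for c, n in zip(gt.clean, gt.noisy):
            assert c == n

    def test_lambda_zero_profiles_identical(self, small_config):
        import dataclasses

        cfg = dataclasses.replace(small_config, lam=0.0)
        gt = simulate(cfg, NOISE_PRESETS["none"], seed=13)
        ref = gt.clean[0]
        for p in gt.clean[1:]:
            for key in ref.keys():
                assert np.array_equal(p.data[key], ref.data[key])

    def test_hg38_layout_has_over_5700_allele_bins(self):
        layout = GenomeLayout()
        assert 2 * layout.total_bins > 5700

    def test_invalid_configs_rejected(self):
        with pytest.raises(ValueError):
            SimulationConfig(n_cells=2)
        with pytest.raises(ValueError):
            SimulationConfig(alpha=1.5)
        with pytest.raises(ValueError):
            NoiseConfig(r_b=-0.1)
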