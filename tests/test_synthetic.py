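"""Generators: distributional checks, determinism, and the canonical fixture."""

import numpy as np
import pytest
from scipy import stats

from radphylo import phylo
from radphylo.asr import mk_transition_matrix
from radphylo.distance import p_distance_matrix
from radphylo.genotypes import ValidationError
from radphylo.synthetic import (
    FIXTURE_GROUPS,
    GroupSpec,
    canonical_tree,
    generate_admixed_genotypes,
    generate_hierarchical_groups,
    make_ribes_fixture,
    simulate_mk_characters,
)


class TestAdmixedGenerator:
    def test_single_population_mean_dosage(self):
        """K=1, f=0.5 everywhere: column mean dosage ~ 1 within 3 SE."""
        n_loci = 10_000
        gm = generate_admixed_genotypes(
            30, n_loci, K=1,
            q_matrix=np.ones((30, 1)),
            f_matrix=np.full((1, n_loci), 0.5),
            seed=0,
        )
        mean = gm.dosages.mean()
        se = np.sqrt(2 * 0.5 * 0.5 / (30 * n_loci))
        assert abs(mean - 1.0) < 3 * se

    def test_two_separated_populations_distance_structure(self):
        q = np.zeros((20, 2))
        q[:10, 0] = 1.0
        q[10:, 1] = 1.0
        f = np.vstack([np.full(2000, 0.05), np.full(2000, 0.95)])
        gm = generate_admixed_genotypes(20, 2000, K=2, q_matrix=q, f_matrix=f, seed=1)
        dm = p_distance_matrix(gm).values
        within = np.concatenate([dm[:10, :10][np.triu_indices(10, 1)],
                                 dm[10:, 10:][np.triu_indices(10, 1)]])
        between = dm[:10, 10:].ravel()
        assert between.mean() > within.mean()

    def test_determinism_and_validation(self):
        a = generate_admixed_genotypes(10, 50, K=3, seed=42)
        b = generate_admixed_genotypes(10, 50, K=3, seed=42)
        assert a == b
        with pytest.raises(ValidationError, match="sum to 1"):
            generate_admixed_genotypes(
                2, 5, K=2, q_matrix=np.array([[0.6, 0.6], [0.5, 0.5]]), seed=0
            )
        with pytest.raises(ValidationError, match=r"\(0, 1\)"):
            generate_admixed_genotypes(
                2, 2, K=1, f_matrix=np.array([[0.0, 0.5]]), seed=0
            )

    @pytest.mark.parametrize("n_per,bound", [(50, 0.05), (250, 0.02)])
    def test_unadmixed_groups_recover_generating_frequencies(self, n_per, bound):
        """Per-group empirical frequencies converge to the generating F at the
        binomial rate: MAE ~ sqrt(2/pi) * E[sqrt(p(1-p))] / sqrt(2n)."""
        n_loci = 5000
        q = np.zeros((2 * n_per, 2))
        q[:n_per, 0] = 1.0
        q[n_per:, 1] = 1.0
        rng = np.random.default_rng(5)
        f = rng.uniform(0.05, 0.95, size=(2, n_loci))
        gm = generate_admixed_genotypes(2 * n_per, n_loci, 2, q, f, seed=6)
        emp = np.vstack([
            gm.dosages[:n_per].mean(axis=0) / 2,
            gm.dosages[n_per:].mean(axis=0) / 2,
        ])
        mae = np.abs(emp - f).mean()
        assert mae < bound
        theory = np.sqrt(2 / np.pi) * np.sqrt(f * (1 - f) / (2 * n_per)).mean()
        assert mae == pytest.approx(theory, rel=0.1)


class TestHierarchicalGroups:
    def test_shape_and_ids(self):
        gm = generate_hierarchical_groups(
            [GroupSpec("x", 2, 0.2), GroupSpec("y", 3, 0.2)], 1, seed=0
        )
        assert gm.dosages.shape == (5, 1)
        assert gm.sample_ids == ["x1", "x2", "y1", "y2", "y3"]
        with pytest.raises(ValidationError):
            generate_hierarchical_groups([GroupSpec("x", 2, 0.2)], 10, seed=0)

    def test_two_groups_monophyletic_under_bootstrap(self):
        gm = generate_hierarchical_groups(
            [GroupSpec("p", 6, 0.3), GroupSpec("q", 6, 0.3)], 5000, seed=3
        )
        tree = phylo.bootstrap_support(gm, n_replicates=100, seed=1)
        group = frozenset(f"p{i + 1}" for i in range(6))
        assert phylo.edge_supports(tree)[group] >= 99.0

    def test_vanishing_drift_gives_negligible_fst(self):
        """c -> 0: Hudson F_ST between groups stays below 0.01."""
        n_per, n_loci = 30, 4000
        gm = generate_hierarchical_groups(
            [GroupSpec("x", n_per, 1e-4), GroupSpec("y", n_per, 1e-4)],
            n_loci, seed=8,
        )
        g = gm.dosages.astype(float)
        p1 = g[:n_per].mean(axis=0) / 2
        p2 = g[n_per:].mean(axis=0) / 2
        # Hudson estimator: numerator (p1-p2)^2 - within-pop sampling terms
        h1 = p1 * (1 - p1) * 2 * n_per / (2 * n_per - 1)
        h2 = p2 * (1 - p2) * 2 * n_per / (2 * n_per - 1)
        num = (p1 - p2) ** 2 - h1 / (2 * n_per) - h2 / (2 * n_per)
        den = p1 * (1 - p2) + p2 * (1 - p1)
        fst = num.sum() / den.sum()
        assert abs(fst) < 0.01


class TestMkSimulator:
    def test_zero_rate_freezes_root_state(self):
        tree = canonical_tree()
        cm = simulate_mk_characters(tree, 20, k=3, rate=0.0, seed=0)
        assert (cm.states == cm.states[0]).all()

    def test_saturation_approaches_uniform(self):
        tree = phylo.parse_newick("((a:30,b:30):30,(c:30,d:30):30);")
        tree.is_rooted = True
        cm = simulate_mk_characters(tree, 2000, k=3, rate=1.0, seed=1)
        for row in cm.states:
            chi2 = stats.chisquare(np.bincount(row, minlength=3))
            assert chi2.pvalue > 1e-4

    def test_single_branch_change_fraction_matches_closed_form(self):
        """k=2: P(change) = 1/2 - 1/2 exp(-2 alpha t)."""
        alpha, t, n = 0.7, 0.9, 4000
        tree = phylo.parse_newick(f"(a:{t},b:0.0);")
        tree.is_rooted = True
        cm = simulate_mk_characters(tree, n, k=2, rate=alpha, seed=2)
        ia = cm.sample_ids.index("a")
        ib = cm.sample_ids.index("b")  # zero-length branch: b keeps the root state
        changed = (cm.states[ia] != cm.states[ib]).mean()
        expect = 0.5 - 0.5 * np.exp(-2 * alpha * t)
        se = np.sqrt(expect * (1 - expect) / n)
        assert abs(changed - expect) < 4 * se
        # and it matches the transition matrix entry
        assert mk_transition_matrix(2, alpha, t)[0, 1] == pytest.approx(expect)

    def test_k_validation(self):
        with pytest.raises(ValidationError):
            simulate_mk_characters(canonical_tree(), 5, k=1, rate=0.1, seed=0)


class TestRibesFixture:
    def test_sample_codes_and_counts(self, fixture_bundle):
        geno = fixture_bundle.genotypes
        assert geno.n_samples == 52
        assert geno.sample_ids[:4] == ["A1", "A2", "A3", "B1"]
        assert geno.sample_ids[-1] == "F23"
        assert sum(FIXTURE_GROUPS.values()) == 52

    def test_gland_character_counts(self, fixture_bundle):
        """Gland present in exactly the 5 gland-bearing-clade samples."""
        chars = fixture_bundle.characters
        gland = chars.states[:, chars.character_names.index("gland")]
        present = [s for s, g in zip(chars.sample_ids, gland) if g == 1]
        assert present == ["D1", "D2", "D3", "D4", "D5"]

    def test_inflorescence_state_counts(self, fixture_bundle):
        chars = fixture_bundle.characters
        inflor = chars.states[:, chars.character_names.index("inflorescence")]
        counts = dict(zip(*np.unique(inflor, return_counts=True)))
        assert {int(k): int(v) for k, v in counts.items()} == {0: 44, 1: 3, 2: 5}

    def test_metadata_matches_printed_table(self, fixture_bundle):
        meta = fixture_bundle.metadata
        assert list(meta["code"]) == fixture_bundle.genotypes.sample_ids
        assert meta.loc[meta["code"] == "C5", "scientific_name"].item() == (
            "Ribes stenocarpum"
        )
        assert meta.loc[meta["code"] == "F2", "note"].str.len().item() > 0

    def test_deterministic_bundles(self, tmp_path):
        from radphylo.synthetic import write_fixture

        a = make_ribes_fixture(seed=3, n_loci=120)
        b = make_ribes_fixture(seed=3, n_loci=120)
        write_fixture(a, tmp_path / "a")
        write_fixture(b, tmp_path / "b")
        for name in ("genotypes.tsv", "characters.tsv", "metadata.tsv",
                     "canonical_tree.nwk"):
            assert (tmp_path / "a" / name).read_bytes() == (
                tmp_path / "b" / name
            ).read_bytes()

    def test_canonical_tree_structure(self, fixture_bundle):
        tree = fixture_bundle.canonical_tree
        assert tree.is_rooted
        labels = sorted(lf.taxon.label for lf in tree.leaf_node_iter())
        assert len(labels) == 52
        sides = [
            frozenset(lf.taxon.label for lf in ch.leaf_iter())
            for ch in tree.seed_node.child_nodes()
        ]
        ab = frozenset([f"A{i+1}" for i in range(3)] + [f"B{i+1}" for i in range(15)])
        assert ab in sides
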