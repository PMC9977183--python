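"""Ground-truth structure of the synthetic study generator."""

import numpy as np
import pytest

from morphollr import procrustes, synthetic
from morphollr.llr import p_matrix, projected_variance, vector_angle
from morphollr.ordination import pca
from morphollr.synthetic import (
    clades_at_depth,
    make_shape_system,
    make_truth,
    simulate_populations,
    simulate_species,
    simulate_tree,
)


class TestTree:
    def test_requested_tips_and_unit_depth(self):
        tree = simulate_tree(17, seed=0)
        assert tree.n_tips == 17
        np.testing.assert_allclose(tree.tip_depths(), 1.0, atol=1e-9)
        assert tree.is_ultrametric()

    def test_seed_determinism(self):
        assert simulate_tree(10, seed=5).as_newick() == simulate_tree(10, seed=5).as_newick()

    def test_different_seeds_differ(self):
        assert simulate_tree(10, seed=5).as_newick() != simulate_tree(10, seed=6).as_newick()

    def test_branch_lengths_positive(self):
        tree = simulate_tree(40, seed=3)
        D = tree.patristic_matrix()
        off = D[~np.eye(40, dtype=bool)]
        assert off.min() > 0

    def test_topologies_vary_at_n4(self):
        """Yule trees at n=4 produce both balanced and ladder topologies
        (brute-force check over many seeds; both classes must appear)."""
        shapes = set()
        for s in range(60):
            t = simulate_tree(4, seed=s)
            # balanced iff both root children have 2 descendant tips
            kids = t.root.child_nodes()
            sizes = tuple(sorted(len(list(c.leaf_iter())) for c in kids))
            shapes.add(sizes)
        assert (2, 2) in shapes and (1, 3) in shapes


class TestShapeSystem:
    def test_basis_orthonormal(self):
        s = make_shape_system(12, seed=1)
        np.testing.assert_allclose(s.basis.T @ s.basis, np.eye(s.k), atol=1e-10)
        assert s.k == 3 * 12 - 7

    def test_deterministic(self):
        a, b = make_shape_system(10, seed=4), make_shape_system(10, seed=4)
        np.testing.assert_array_equal(a.mean_shape, b.mean_shape)
        np.testing.assert_array_equal(a.basis, b.basis)

    def test_crea_displacement_survives_gpa_linearization(self):
        """Displacing the mean along the designated allometric direction and
        re-superimposing recovers a tangent displacement within 2 degrees of
        that direction (small deformation)."""
        s = make_shape_system(12, seed=2)
        c = 0.01
        configs = [s.mean_shape, s.to_landmarks(c * s.crea_direction),
                   s.to_landmarks(-c * s.crea_direction)]
        res = procrustes.gpa(configs)
        from morphollr.procrustes import _optimal_rotation

        R = _optimal_rotation(res.consensus, s.mean_shape)
        d = ((res.basis @ (res.tangent[1] - res.tangent[0])).reshape(-1, 3) @ R)
        true_d = (s.basis @ s.crea_direction).reshape(-1, 3)
        assert vector_angle(d.ravel(), true_d.ravel(), fold=True) < 2.0


class TestSimulateSpecies:
    def test_zero_diet_coupling_decouples_diet_from_size(self):
        """With diet_coupling=0 the correlation between size and percent
        grass is centred on zero (200 replicates, 3 MC SE)."""
        tree = simulate_tree(30, seed=7)
        sysm = make_shape_system(10, seed=7)
        truth = make_truth(tree, sysm, diet_coupling=0.0, seed=7)
        cors = []
        for rep in range(200):
            _, log_cs, grass = simulate_species(tree, truth, seed=rep)
            cors.append(np.corrcoef(log_cs, grass)[0, 1])
        mean = np.mean(cors)
        se = np.std(cors, ddof=1) / np.sqrt(len(cors))
        assert abs(mean) < 3 * se + 0.02

    def test_isotropic_rate_matches_matrix_normal_oracle(self):
        """With an isotropic rate matrix the generator's PC1 variance
        fraction falls inside the range produced by an independent
        matrix-normal simulation under the same tree (phylogenetic
        correlation inflates eigenvalue spread above 1/k, and the generator
        must reproduce exactly that, no more)."""
        tree = simulate_tree(80, seed=8)
        sysm = make_shape_system(10, seed=8)
        k = sysm.k
        truth = make_truth(tree, sysm, rate_eccentricity=1.0 / k, seed=8)
        means, _, _ = simulate_species(tree, truth, seed=3)
        obs = pca(means).var_fraction[0]
        # oracle: direct matrix-normal draws, isotropic column covariance
        L = np.linalg.cholesky(tree.vcv())
        rng_o = np.random.default_rng(123)
        fracs = [
            pca(L @ rng_o.standard_normal((80, k))).var_fraction[0]
            for _ in range(60)
        ]
        assert min(fracs) <= obs <= max(fracs)
        # and far from the eccentric regime where PC1 carries >=35%
        assert obs < 0.3

    def test_strong_eccentricity_aligns_pc1_with_crea(self):
        """rate_eccentricity=0.9: interspecific PC1 within 10 degrees of the
        allometric direction at n=130."""
        tree = simulate_tree(130, seed=9)
        sysm = make_shape_system(10, seed=9)
        truth = make_truth(tree, sysm, rate_eccentricity=0.9, seed=9)
        means, _, _ = simulate_species(tree, truth, seed=4)
        o = pca(means)
        ang = vector_angle(o.vectors[:, 0], truth.crea_direction, fold=True)
        assert ang < 10.0

    def test_seed_determinism(self):
        tree = simulate_tree(12, seed=10)
        sysm = make_shape_system(10, seed=10)
        truth = make_truth(tree, sysm, seed=10)
        a = simulate_species(tree, truth, seed=5)
        b = simulate_species(tree, truth, seed=5)
        for x, y in zip(a, b):
            np.testing.assert_array_equal(x, y)


class TestSimulatePopulations:
    def test_no_variation_reproduces_species_mean(self):
        tree = simulate_tree(5, seed=11)
        sysm = make_shape_system(10, seed=11)
        truth = make_truth(tree, sysm, p_trace=0.0, seed=11)
        means = np.zeros((5, sysm.k))
        configs = simulate_populations(means, np.zeros(5), truth, 3,
                                       noise_sd=0.0, seed=1)
        # all specimens of one species identical up to rigid motion
        from morphollr.procrustes import procrustes_distance

        sp0 = [c.coords for c in configs if c.species_id == tree.taxa[0]]
        assert procrustes_distance(sp0[0], sp0[1]) < 1e-8

    def test_p_matrix_recovery_from_large_sample(self):
        """P estimated from 500 specimens approaches the generating P
        (relative Frobenius error < 25%; dominated by sampling noise and the
        small digitizing-noise floor)."""
        tree = simulate_tree(5, seed=12)
        sysm = make_shape_system(10, seed=12)
        truth = make_truth(tree, sysm, seed=12)
        s = tree.taxa[0]
        means = np.zeros((5, sysm.k))
        configs = simulate_populations(means, np.zeros(5), truth,
                                       {s: 500}, noise_sd=0.001, seed=2)
        res = procrustes.gpa(configs)
        P_est = p_matrix(res.tangent, s).P
        # compare in the generator frame via the basis change
        from morphollr.procrustes import _optimal_rotation

        R = _optimal_rotation(res.consensus, sysm.mean_shape)
        Rblk = np.kron(np.eye(sysm.p), R)
        M = sysm.basis.T @ Rblk.T @ res.basis  # generator <- gpa basis map
        P_in_truth = M @ P_est @ M.T
        err = np.linalg.norm(P_in_truth - truth.p_true[s]) / np.linalg.norm(
            truth.p_true[s]
        )
        assert err < 0.25

    def test_vproj_ordering_tracks_alignment(self):
        """Across species, V_proj of the estimated P along the true
        allometric direction decreases with the true P-to-CREA angle
        (Spearman rho < -0.8 with 100 specimens per species)."""
        from scipy.stats import spearmanr

        tree = simulate_tree(30, seed=13)
        sysm = make_shape_system(10, seed=13)
        truth = make_truth(tree, sysm, n_intraspecific=30, seed=13)
        means, log_cs, _ = simulate_species(tree, truth, seed=6)
        configs = simulate_populations(means, np.zeros(30), truth, 100,
                                       noise_sd=0.005, seed=3)
        res = procrustes.gpa(configs)
        from morphollr.procrustes import _optimal_rotation

        R = _optimal_rotation(res.consensus, sysm.mean_shape)
        Rblk = np.kron(np.eye(sysm.p), R)
        crea_gpa = res.basis.T @ Rblk @ sysm.basis @ truth.crea_direction
        crea_gpa /= np.linalg.norm(crea_gpa)
        sp = np.asarray(res.species_ids)
        vproj, align = [], []
        for s in tree.taxa:
            P = p_matrix(res.tangent[sp == s], s)
            vproj.append(projected_variance(P, crea_gpa))
            align.append(truth.alignment_true[s])
        rho = spearmanr(vproj, align).statistic
        assert rho < -0.8

    def test_seed_determinism(self):
        tree = simulate_tree(5, seed=14)
        sysm = make_shape_system(10, seed=14)
        truth = make_truth(tree, sysm, seed=14)
        means = np.zeros((5, sysm.k))
        a = simulate_populations(means, np.zeros(5), truth, 3, seed=9)
        b = simulate_populations(means, np.zeros(5), truth, 3, seed=9)
        for x, y in zip(a, b):
            np.testing.assert_array_equal(x.coords, y.coords)


def test_clade_labels_nested(small_study):
    tree = small_study["tree"]
    fams = clades_at_depth(tree, 0.2)
    subs = clades_at_depth(tree, 0.45)
    # every subfamily maps into exactly one family
    pairs = {(subs[t], fams[t]) for t in tree.taxa}
    sub_to_fam = {}
    for sub, fam in pairs:
        assert sub_to_fam.setdefault(sub, fam) == fam


def test_generated_study_counts(small_study):
    study = small_study["study"]
    counts = study.specimen_counts()
    intra = [s for s, f in study.in_intraspecific_set.items() if f]
    assert len(intra) == 8
    assert all(counts[s] >= 27 for s in intra)
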