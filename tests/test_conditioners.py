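"""Conditioner framework: exact constraints, soft gradients, composition."""

import numpy as np
import pytest

from bbdiff import (DiffusionSchedule, GaussianToyDenoiser, IdentityPrior,
                    PolymerPrior, SamplerSettings, compose,
                    helix_content_log_prob, make_classifier_conditioner,
                    make_distance_conditioner, make_ideal_helix,
                    make_ideal_strand, make_shape_conditioner,
                    make_substructure_conditioner, make_symmetry_conditioner,
                    make_symmetry_group, reverse_sample, reverse_sample_array,
                    symmetry_deviation, tessellate)
from bbdiff.ot import sinkhorn_divergence


def finite_difference(fn, x, idx, eps=1e-6):
    grad = np.zeros(len(idx) * 3).reshape(len(idx), 3)
    for a, i in enumerate(idx):
        for d in range(3):
            xp, xm = x.copy(), x.copy()
            xp[i, d] += eps
            xm[i, d] -= eps
            grad[a, d] = (fn(xp) - fn(xm)) / (2 * eps)
    return grad


class TestSymmetryGroups:
    @pytest.mark.parametrize("name,order", [("C1", 1), ("C4", 4), ("D3", 6),
                                            ("T", 12), ("O", 24), ("I", 60)])
    def test_orders_and_closure(self, name, order):
        g = make_symmetry_group(name)
        assert g.order == order
        # the multiplication table exists iff closure held to 1e-8
        assert g.table.shape == (order, order)
        assert np.allclose(g.matrices[0], np.eye(3))

    def test_unknown_group_rejected(self):
        with pytest.raises(ValueError):
            make_symmetry_group("X7")


class TestSymmetryConditioner:
    def test_c4_tessellation_counts(self):
        au = make_ideal_helix(50)
        complex_ = tessellate(au, make_symmetry_group("C4"))
        assert complex_.n_residues == 200
        assert len(complex_.chains) == 4

    def test_hard_transform_idempotent(self):
        group = make_symmetry_group("D2")
        cond = make_symmetry_conditioner(group)
        cond.setup(20)
        x = np.random.default_rng(0).standard_normal((20, 3)) * 10
        once = cond.hard_transform(x, 0.5)
        twice = cond.hard_transform(once, 0.5)
        assert np.abs(twice - once).max() < 1e-6

    @pytest.mark.parametrize("name", ["C3", "D2", "T", "O"])
    def test_exact_group_invariance(self, name):
        group = make_symmetry_group(name)
        au = make_ideal_helix(15)
        complex_ = tessellate(au, group)
        assert symmetry_deviation(complex_, group) < 1e-6

    def test_soft_energy_vanishes_on_symmetric_input(self):
        group = make_symmetry_group("C3")
        cond = make_symmetry_conditioner(group, soft_weight=2.0)
        cond.setup(10)
        au = np.random.default_rng(1).standard_normal((10, 3)) * 5
        sym = cond.hard_transform(au, 0.0)
        assert cond.energy(sym) < 1e-20
        asym = sym + np.random.default_rng(2).standard_normal(sym.shape)
        assert cond.energy(asym) > 0.01


class TestSubstructureConditioner:
    def test_full_clamp_returns_reference_at_t0(self, schedule):
        ref = make_ideal_helix(30)
        cond = make_substructure_conditioner(ref, np.ones(30, bool),
                                             PolymerPrior(30), schedule)
        out = cond.hard_transform(np.zeros((30, 3)), 0.0)
        assert np.array_equal(out, ref.ca)

    def test_clamp_idempotent_at_fixed_t(self, schedule):
        ref = make_ideal_helix(30)
        mask = np.zeros(30, bool)
        mask[5:15] = True
        cond = make_substructure_conditioner(ref, mask, PolymerPrior(30), schedule)
        x = np.random.default_rng(3).standard_normal((30, 3)) * 8
        once = cond.hard_transform(x, 0.42)
        assert np.array_equal(cond.hard_transform(once, 0.42), once)

    def test_mask_longer_than_sampled_structure_rejected(self, schedule):
        ref = make_ideal_helix(30)
        cond = make_substructure_conditioner(ref, np.ones(30, bool),
                                             PolymerPrior(30), schedule)
        with pytest.raises(ValueError, match="longer"):
            cond.hard_transform(np.zeros((20, 3)), 0.5)

    def test_empty_mask_matches_unconditional(self, schedule, trained_denoiser):
        ref = make_ideal_helix(25)
        cond = make_substructure_conditioner(ref, np.zeros(25, bool),
                                             PolymerPrior(25), schedule)
        settings = SamplerSettings(n_steps=40, seed=11)
        a = reverse_sample(PolymerPrior(25), schedule, trained_denoiser,
                           settings, 25, [cond])
        b = reverse_sample(PolymerPrior(25), schedule, trained_denoiser,
                           settings, 25, [])
        assert np.array_equal(a.coords, b.coords)

    def test_half_clamp_exact_and_free_half_varies(self, schedule,
                                                   trained_denoiser):
        ref = make_ideal_helix(50)
        mask = np.zeros(50, bool)
        mask[:25] = True
        prior = PolymerPrior(50)
        cond = make_substructure_conditioner(ref, mask, prior, schedule)
        outs = [reverse_sample(prior, schedule, trained_denoiser,
                               SamplerSettings(n_steps=60, seed=s), 50, [cond])
                for s in (1, 2)]
        for s in outs:
            assert np.abs(s.ca[:25] - ref.ca[:25]).max() == 0.0
        assert np.abs(outs[0].ca[25:] - outs[1].ca[25:]).max() > 0.1


class TestDistanceConditioner:
    def test_zero_at_target_distance(self):
        cond = make_distance_conditioner([(0, 1)], [3.8], 2.0)
        x = np.array([[0.0, 0, 0], [3.8, 0, 0]])
        assert cond.energy(x) == 0.0
        assert np.abs(cond.energy_gradient(x)).max() == 0.0

    def test_gradient_matches_finite_differences(self):
        cond = make_distance_conditioner([(0, 5), (2, 8)], [6.0, 10.0], 1.5)
        x = make_ideal_helix(12).ca.copy()
        grad = cond.energy_gradient(x)
        idx = [0, 2, 5, 8]
        fd = finite_difference(lambda c: cond.energy(c), x, idx)
        assert np.abs(grad[idx] - fd).max() / np.abs(fd).max() < 1e-5

    def test_identical_pair_indices_rejected(self):
        with pytest.raises(ValueError):
            make_distance_conditioner([(3, 3)], [5.0])

    def test_sampled_distance_moves_toward_target_with_k(self):
        # 2-point toy with an analytic Gaussian denoiser: stronger restraints
        # pull the mean sampled distance toward the target
        sched = DiffusionSchedule(n_steps=120)
        mu = np.array([0.0, 0, 0, 4.0, 0, 0])
        den = GaussianToyDenoiser(mu, np.eye(6), sched)
        target = 8.0
        means = []
        for k in (0.0, 1.0, 10.0):
            conds = [] if k == 0 else [make_distance_conditioner([(0, 1)],
                                                                 [target], k)]
            x = reverse_sample_array(IdentityPrior(2), sched, den.contract(),
                                     SamplerSettings(n_steps=120, seed=7),
                                     (400, 2, 3), conds)
            means.append(np.linalg.norm(x[:, 1] - x[:, 0], axis=1).mean())
        assert means[0] < means[1] < means[2] <= target + 0.5


class TestShapeConditioner:
    def test_coincident_clouds_have_near_zero_gradient(self):
        pts = 2.0 * np.random.default_rng(0).standard_normal((15, 3))
        cond = make_shape_conditioner(pts, epsilon=0.1)
        g_same = cond.energy_gradient(pts)
        g_far = cond.energy_gradient(pts + 20.0)
        assert np.linalg.norm(g_same) < 1e-3 * np.linalg.norm(g_far)

    def test_single_point_clouds_cost_is_squared_distance(self):
        cond = make_shape_conditioner(np.array([[0.0, 0, 0]]), epsilon=0.5)
        assert np.isclose(cond.energy(np.array([[3.0, 0, 0]])), 9.0)

    def test_gradient_matches_finite_differences(self):
        rng = np.random.default_rng(1)
        x = rng.standard_normal((12, 3))
        y = rng.standard_normal((10, 3)) * 2 + 1

        def cost(c):
            v, _, _ = sinkhorn_divergence(c, y, 1.0, max_iters=5000, tol=1e-12)
            return v

        _, grad, _ = sinkhorn_divergence(x, y, 1.0, max_iters=5000, tol=1e-12)
        fd = finite_difference(cost, x, [0, 4, 9], eps=1e-5)
        assert np.abs(grad[[0, 4, 9]] - fd).max() / np.abs(fd).max() < 1e-5

    def test_nonconvergent_iterations_warn_and_return(self):
        rng = np.random.default_rng(2)
        x = rng.standard_normal((10, 3))
        with pytest.warns(RuntimeWarning, match="converge"):
            v, g, _ = sinkhorn_divergence(x, x + 30.0, 0.05, max_iters=5)
        assert np.isfinite(v) and np.all(np.isfinite(g))

    def test_guided_toy_sampling_reduces_transport_cost(self):
        # "L"-shaped target cloud; guidance lowers the OT cost versus unguided
        sched = DiffusionSchedule(n_steps=100)
        arm = np.linspace(0, 6, 6)
        cloud = np.concatenate([np.stack([np.zeros(6), arm, np.zeros(6)], 1),
                                np.stack([arm[1:4], np.zeros(3), np.zeros(3)], 1)])
        n_pts = 9
        den = GaussianToyDenoiser(np.zeros(3 * n_pts), 4.0 * np.eye(3 * n_pts),
                                  sched)
        cond = make_shape_conditioner(cloud, epsilon=1.0, weight=0.3,
                                      max_iters=200)
        costs = {"guided": [], "free": []}
        for seed in range(12):
            settings = SamplerSettings(n_steps=100, seed=seed)
            for label, conds in (("guided", [cond]), ("free", [])):
                x = reverse_sample_array(IdentityPrior(n_pts), sched,
                                         den.contract(), settings,
                                         (n_pts, 3), conds)
                v, _, _ = sinkhorn_divergence(x, cloud, 1.0)
                costs[label].append(v)
        assert np.mean(costs["guided"]) < np.mean(costs["free"])


class TestClassifierConditioner:
    def test_zero_guidance_scale_is_unconditional(self, schedule,
                                                  trained_denoiser):
        cond = make_classifier_conditioner(helix_content_log_prob, 0.0)
        settings = SamplerSettings(n_steps=40, seed=3)
        a = reverse_sample(PolymerPrior(20), schedule, trained_denoiser,
                           settings, 20, [cond])
        b = reverse_sample(PolymerPrior(20), schedule, trained_denoiser,
                           settings, 20, [])
        assert np.array_equal(a.coords, b.coords)

    def test_helix_scores_above_extended_chain(self):
        helix_score, _ = helix_content_log_prob(make_ideal_helix(30).ca)
        strand_score, _ = helix_content_log_prob(make_ideal_strand(30).ca)
        assert helix_score > strand_score + 0.5

    def test_toy_classifier_gradient_matches_finite_differences(self):
        x = make_ideal_helix(20).ca + 0.3 * np.random.default_rng(4).standard_normal((20, 3))
        _, grad = helix_content_log_prob(x)
        fd = finite_difference(lambda c: helix_content_log_prob(c)[0], x, [0, 7, 13])
        assert np.abs(grad[[0, 7, 13]] - fd).max() / np.abs(fd).max() < 1e-5

    def test_guidance_increases_classifier_score(self):
        # Gaussian toy over a CA trace: guidance toward helix-like i,i+4
        # spacing raises the mean classifier score monotonically
        sched = DiffusionSchedule(n_steps=100)
        n = 12
        base = np.linspace(0, 3.8 * (n - 1), n)
        mu = np.stack([base, np.zeros(n), np.zeros(n)], 1).ravel()
        den = GaussianToyDenoiser(mu, 4.0 * np.eye(3 * n), sched)
        scores = []
        for scale in (0.0, 1.0, 5.0):
            conds = [make_classifier_conditioner(helix_content_log_prob, scale)]
            vals = []
            for seed in range(10):
                x = reverse_sample_array(IdentityPrior(n), sched, den.contract(),
                                         SamplerSettings(n_steps=100, seed=seed),
                                         (n, 3), conds)
                vals.append(helix_content_log_prob(x)[0])
            scores.append(np.mean(vals))
        assert scores[0] < scores[1] < scores[2]


class TestCompose:
    def test_empty_composition_is_noop(self):
        cond = compose([])
        x = np.random.default_rng(5).standard_normal((8, 3))
        assert cond.hard_transform(x, 0.3) is x
        assert cond.score_contribution(x, 0.3) is None

    def test_single_member_matches_member(self):
        group = make_symmetry_group("C3")
        alone = make_symmetry_conditioner(group)
        alone.setup(10)
        wrapped = compose([make_symmetry_conditioner(group)])
        wrapped.setup(10)
        x = np.random.default_rng(6).standard_normal((10, 3)) * 5
        assert np.allclose(alone.hard_transform(x, 0.1),
                           wrapped.hard_transform(x, 0.1))

    def test_symmetry_plus_consistent_distance_stays_symmetric(self, schedule,
                                                               trained_denoiser):
        group = make_symmetry_group("C3")
        n_au = 12
        sym = make_symmetry_conditioner(group)
        # restrain the same residue pair inside every subunit
        pairs = [(k * n_au + 1, k * n_au + 7) for k in range(3)]
        dist = make_distance_conditioner(pairs, [9.0] * 3, 0.5)
        stack = compose([sym, dist])
        out = reverse_sample(PolymerPrior(n_au), schedule, trained_denoiser,
                             SamplerSettings(n_steps=50, seed=2), n_au, [stack])
        assert out.n_residues == 36
        assert symmetry_deviation(out.ca, group) < 1e-6
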