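import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from hydrasite.sites import HydrationSite, WaterPrediction
from hydrasite.site_predictor import (LossConfig, SiteModel,
                                      initialize_waters, mixture_loss,
                                      mixture_loss_grad, normalize_weights)
from hydrasite.structure_io import Atom, ProteinStructure, featurize


def _clone_rigid(structure, R, t):
    s = ProteinStructure([
        Atom(a.element, a.atom_name, a.residue_name, a.residue_index,
             a.chain_id, R @ a.coord + t) for a in structure.atoms])
    s.sasa = np.asarray(structure.sasa).copy()
    return s


class TestInitializeWaters:
    def test_threshold_is_strict(self, toy_structure):
        s = ProteinStructure(toy_structure.atoms)
        s.sasa = np.full(len(s), 0.05)
        assert len(initialize_waters(s)) == 0

    def test_fully_buried_structure_seeds_nothing(self, toy_structure):
        s = ProteinStructure(toy_structure.atoms)
        s.sasa = np.zeros(len(s))
        assert len(initialize_waters(s)) == 0

    def test_one_node_per_exposed_atom(self, toy_structure):
        seeds = initialize_waters(toy_structure)
        mask = np.asarray(toy_structure.sasa) > 0.1
        assert len(seeds) == mask.sum()
        np.testing.assert_array_equal(seeds, toy_structure.coords[mask])

    def test_requires_sasa(self, toy_structure):
        s = ProteinStructure(toy_structure.atoms)
        with pytest.raises(ValueError):
            initialize_waters(s)


class TestNormalizeWeights:
    def test_uniform(self):
        np.testing.assert_allclose(normalize_weights([1, 1, 1, 1]), 0.25)

    def test_single_element(self):
        np.testing.assert_allclose(normalize_weights([0.7]), [1.0])

    def test_closed_form(self):
        rng = np.random.default_rng(0)
        w = rng.uniform(0.01, 1, size=20)
        np.testing.assert_allclose(normalize_weights(w), w / w.sum())

    def test_all_zero_rejected(self):
        with pytest.raises(ValueError):
            normalize_weights([0.0, 0.0])


def _random_case(rng, n_pred=3, n_ref=2):
    preds = [WaterPrediction(x=rng.normal(scale=2, size=3),
                             w=float(rng.uniform(0.1, 0.9)))
             for _ in range(n_pred)]
    refs = [HydrationSite(center=rng.normal(scale=2, size=3),
                          occupancy=float(rng.uniform(0.5, 1.0)))
            for _ in range(n_ref)]
    return preds, refs


class TestMixtureLoss:
    def test_minimum_at_matching_configuration(self):
        """L1 at predictions == references beats 100 random perturbations."""
        rng = np.random.default_rng(1)
        refs = [HydrationSite(center=rng.normal(scale=3, size=3),
                              occupancy=1.0) for _ in range(4)]
        base = [WaterPrediction(x=r.center.copy(), w=0.5) for r in refs]
        _, l1_base, _ = mixture_loss(base, refs)
        for _ in range(100):
            pert = [WaterPrediction(x=p.x + rng.normal(scale=0.5, size=3),
                                    w=min(1.0, max(0.0, p.w + rng.normal(scale=0.1))))
                    for p in base]
            try:
                _, l1_pert, _ = mixture_loss(pert, refs)
            except ValueError:
                continue
            assert l1_base <= l1_pert + 1e-12

    def test_raw_weight_scale_invariance(self):
        rng = np.random.default_rng(2)
        preds, refs = _random_case(rng)
        l_a, l1_a, l2_a = mixture_loss(preds, refs)
        doubled = [WaterPrediction(x=p.x, w=min(1.0, p.w)) for p in preds]
        halved = [WaterPrediction(x=p.x, w=p.w / 2) for p in preds]
        l_b, l1_b, l2_b = mixture_loss(halved, refs)
        assert l1_a == pytest.approx(l1_b, rel=1e-12)
        assert l2_a == pytest.approx(l2_b, rel=1e-12)

    def test_rigid_motion_invariance(self):
        rng = np.random.default_rng(3)
        preds, refs = _random_case(rng, 5, 3)
        R = Rotation.random(random_state=rng).as_matrix()
        t = rng.uniform(-5, 5, 3)
        moved_p = [WaterPrediction(x=R @ p.x + t, w=p.w) for p in preds]
        moved_r = [HydrationSite(center=R @ r.center + t, occupancy=r.occupancy)
                   for r in refs]
        assert mixture_loss(preds, refs)[0] == pytest.approx(
            mixture_loss(moved_p, moved_r)[0], abs=1e-6)

    def test_component_order_invariance(self):
        rng = np.random.default_rng(4)
        preds, refs = _random_case(rng, 5, 3)
        assert mixture_loss(preds, refs)[0] == pytest.approx(
            mixture_loss(preds[::-1], refs[::-1])[0], rel=1e-12)

    def test_occupancy_filter_applied(self):
        rng = np.random.default_rng(5)
        preds, refs = _random_case(rng)
        low = refs + [HydrationSite(center=np.array([50.0, 0, 0]),
                                    occupancy=0.4)]
        assert mixture_loss(preds, refs)[0] == pytest.approx(
            mixture_loss(preds, low)[0], rel=1e-12)

    def test_gradients_match_finite_differences(self):
        """Analytic grads vs central differences on a 3-pred/2-ref case."""
        rng = np.random.default_rng(6)
        preds, refs = _random_case(rng, 3, 2)
        _, gx, gw = mixture_loss_grad(preds, refs)
        eps = 1e-6

        def loss_of(xs, ws):
            p = [WaterPrediction(x=x, w=w) for x, w in zip(xs, ws)]
            return mixture_loss(p, refs)[0]

        xs = np.array([p.x for p in preds])
        ws = np.array([p.w for p in preds])
        for i in range(3):
            for j in range(3):
                xp, xm = xs.copy(), xs.copy()
                xp[i, j] += eps
                xm[i, j] -= eps
                fd = (loss_of(xp, ws) - loss_of(xm, ws)) / (2 * eps)
                assert gx[i, j] == pytest.approx(fd, rel=1e-4, abs=1e-10)
            wp, wm = ws.copy(), ws.copy()
            wp[i] += eps
            wm[i] -= eps
            fd = (loss_of(xs, wp) - loss_of(xs, wm)) / (2 * eps)
            assert gw[i] == pytest.approx(fd, rel=1e-4, abs=1e-10)

    def test_empty_inputs_rejected(self):
        rng = np.random.default_rng(7)
        preds, refs = _random_case(rng)
        with pytest.raises(ValueError):
            mixture_loss([], refs)
        with pytest.raises(ValueError):
            mixture_loss(preds, [])
        with pytest.raises(ValueError):
            mixture_loss(preds, [HydrationSite(center=np.zeros(3),
                                               occupancy=0.3)])


class TestSiteModelForward:
    def test_deterministic_inference(self, toy_structure):
        model = SiteModel(hidden=16, seed=0)
        a = model.predict_raw(toy_structure)
        b = model.predict_raw(toy_structure)
        np.testing.assert_array_equal([p.x for p in a], [p.x for p in b])
        np.testing.assert_array_equal([p.w for p in a], [p.w for p in b])

    def test_equivariance_under_rigid_motion(self, toy_structure):
        model = SiteModel(hidden=16, seed=0)
        base = model.predict_raw(toy_structure)
        rng = np.random.default_rng(11)
        R = Rotation.random(random_state=rng).as_matrix()
        t = rng.uniform(-8, 8, 3)
        moved = model.predict_raw(_clone_rigid(toy_structure, R, t))
        x_base = np.array([p.x for p in base])
        x_moved = np.array([p.x for p in moved])
        assert np.abs(x_moved - (x_base @ R.T + t)).max() < 1e-5
        assert np.abs(np.array([p.w for p in base])
                      - np.array([p.w for p in moved])).max() < 1e-5

    def test_protein_coordinates_bit_unchanged(self, toy_structure):
        model = SiteModel(hidden=16, seed=0)
        seeds = initialize_waters(toy_structure)
        atom_feats = featurize(toy_structure)
        water_feats = featurize(toy_structure, node_type="water")[
            np.asarray(toy_structure.sasa) > 0.1]
        log = []
        model.forward(toy_structure.coords, atom_feats, seeds, water_feats,
                      coord_log=log)
        n_p = len(toy_structure)
        assert len(log) == model.n_layers
        for snapshot in log:
            np.testing.assert_array_equal(snapshot[:n_p],
                                          toy_structure.coords)

    def test_zero_edges_leaves_waters_in_place(self):
        # two far-apart atoms, one water each: no graph edges at 6 A
        atoms = [Atom("C", "CA", "ALA", i + 1, "A", np.array([40.0 * i, 0, 0]))
                 for i in range(2)]
        s = ProteinStructure(atoms)
        s.sasa = np.ones(2)
        model = SiteModel(hidden=8, seed=0)
        preds = model.predict_raw(s)
        x = np.array([p.x for p in preds])
        # waters coincide with their seed atoms: only self-pairs at d=0 exist,
        # whose relative position vector is zero, so coordinates cannot move
        np.testing.assert_allclose(x, s.coords, atol=1e-12)

    def test_atom_permutation_invariance(self, toy_structure):
        model = SiteModel(hidden=16, seed=0)
        base = model.predict_raw(toy_structure)
        rng = np.random.default_rng(13)
        perm = rng.permutation(len(toy_structure))
        permuted = ProteinStructure([toy_structure.atoms[i] for i in perm])
        permuted.sasa = np.asarray(toy_structure.sasa)[perm]
        moved = model.predict_raw(permuted)
        a = sorted((tuple(np.round(p.x, 5)), round(p.w, 5)) for p in base)
        b = sorted((tuple(np.round(p.x, 5)), round(p.w, 5)) for p in moved)
        for (xa, wa), (xb, wb) in zip(a, b):
            assert np.abs(np.array(xa) - np.array(xb)).max() < 1e-5
            assert abs(wa - wb) < 1e-5

    def test_weights_in_unit_interval(self, toy_structure):
        model = SiteModel(hidden=16, seed=1)
        preds = model.predict_raw(toy_structure)
        assert all(0.0 <= p.w <= 1.0 for p in preds)

    def test_checkpoint_roundtrip(self, toy_structure, tmp_path):
        from hydrasite.io_utils import load_checkpoint, save_checkpoint
        model = SiteModel(hidden=8, seed=3)
        path = tmp_path / "m.ckpt"
        save_checkpoint(path, "site", model.config(),
                        model.store.state_dict())
        kind, config, state = load_checkpoint(path)
        clone = SiteModel.from_config(config, state)
        a = model.predict_raw(toy_structure)
        b = clone.predict_raw(toy_structure)
        np.testing.assert_array_equal([p.x for p in a], [p.x for p in b])
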