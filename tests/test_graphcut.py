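"""Four-term graph-cut energy: unaries, pairwise kernel, global min-cut."""

import itertools

import numpy as np
import pytest

from hepatoseg import Volume, default_phantom
from hepatoseg.core import LESION, VESSEL, Mask
from hepatoseg.graphcut import (EnergyField, IntensityModel, TermWeights,
                                assemble_energy, boundary_term, boundary_weight,
                                data_term, fit_intensity_models,
                                min_cut_labeling, min_cut_segment,
                                remove_vessels, vessel_eligible_mask)


def random_toy_field(rng, max_nodes=12):
    n = int(rng.integers(2, max_nodes + 1))
    m = int(rng.integers(1, n * (n - 1) // 2 + 1))
    edges = set()
    while len(edges) < m:
        i, j = rng.integers(0, n, 2)
        if i != j:
            edges.add((min(i, j), max(i, j)))
    return EnergyField(
        roi=np.ones((n, 1, 1), bool),
        unary_object=rng.uniform(0, 3, n),
        unary_background=rng.uniform(0, 3, n),
        pair_i=np.array([e[0] for e in edges]),
        pair_j=np.array([e[1] for e in edges]),
        pair_w=rng.uniform(0, 2, len(edges)),
    )


def exhaustive_minimum(field):
    n = field.n_nodes
    best_e, best_lab = np.inf, None
    for lab in itertools.product([0, 1], repeat=n):
        e = field.energy_of(np.array(lab, dtype=bool))
        if e < best_e:
            best_e, best_lab = e, np.array(lab, dtype=bool)
    return best_e, best_lab


class TestIntensityModel:
    def test_gaussian_parameter_recovery(self):
        rng = np.random.default_rng(0)
        shape = (30, 30, 30)
        data = rng.normal(120, 10, shape)
        tumor = np.zeros(shape, bool)
        tumor[:10] = True
        data[tumor] = rng.normal(70, 8, data[tumor].shape)
        model = fit_intensity_models(Volume(data), np.ones(shape, bool), tumor)
        assert abs(model.object_params["mu"] - 70) < 2
        assert abs(model.background_params["mu"] - 120) < 2

    def test_identical_classes_give_matching_densities(self):
        rng = np.random.default_rng(1)
        data = rng.normal(100, 12, (20, 20, 20))
        half = np.zeros((20, 20, 20), bool)
        half[:, :, ::2] = True
        model = fit_intensity_models(Volume(data), np.ones((20, 20, 20), bool), half)
        grid = np.linspace(0, 255, 100)
        assert np.allclose(model.p_object(grid), model.p_background(grid), rtol=0.3)

    def test_density_floor(self):
        model = IntensityModel(object_params={"mu": 100, "sigma": 2},
                               background_params={"mu": 100, "sigma": 2})
        grid = np.linspace(0, 255, 256)
        assert model.p_object(grid).min() >= 1e-6

    def test_empty_class_rejected(self):
        vol = Volume(np.zeros((4, 4, 4)))
        with pytest.raises(ValueError, match="non-empty"):
            fit_intensity_models(vol, np.ones((4, 4, 4), bool),
                                 np.zeros((4, 4, 4), bool))


class TestDataTerm:
    def test_equal_likelihoods_cost_ln_two(self):
        m = IntensityModel(object_params={"mu": 70, "sigma": 10},
                           background_params={"mu": 120, "sigma": 10})
        vol = Volume(np.full((2, 2, 2), 95.0))   # equidistant from both means
        co, cb = data_term(vol, m)
        assert np.allclose(co, np.log(2))
        assert np.allclose(cb, np.log(2))

    def test_posterior_odds_arithmetic(self):
        # P(I|O) = 0.2, P(I|B) = 0.6  ->  object cost = -ln 0.25
        m = IntensityModel(kind="histogram",
                           object_params={"edges": np.array([0.0, 255.0]),
                                          "density": np.array([0.2])},
                           background_params={"edges": np.array([0.0, 255.0]),
                                              "density": np.array([0.6])})
        co, cb = data_term(Volume(np.full((1, 1, 1), 100.0)), m)
        assert co[0, 0, 0] == pytest.approx(-np.log(0.25))
        assert cb[0, 0, 0] == pytest.approx(-np.log(0.75))

    def test_dominant_class_costs(self):
        m = IntensityModel(object_params={"mu": 70, "sigma": 5},
                           background_params={"mu": 200, "sigma": 5})
        co, cb = data_term(Volume(np.full((1, 1, 1), 70.0)), m)
        assert co[0, 0, 0] < 1e-4      # bounded by the density floor
        assert cb[0, 0, 0] > 10


class TestBoundaryTerm:
    @pytest.mark.parametrize("delta,sigma,expected", [
        (0.0, 5.0, 1.0),
        (np.sqrt(50.0), 5.0, 0.5),     # (dI)^2 = 2 sigma^2
        (10.0, 5.0, 1.0 / 3.0),
    ])
    def test_contrast_kernel_values(self, delta, sigma, expected):
        assert boundary_weight(delta, sigma) == pytest.approx(expected)

    def test_nonpositive_sigma_rejected(self):
        with pytest.raises(ValueError):
            boundary_weight(1.0, 0.0)

    def test_distance_weighting_uses_spacing(self):
        vol = Volume(np.zeros((3, 3, 3)), spacing=(1.0, 2.0, 4.0))
        weights = dict()
        for off, w in boundary_term(vol, sigma=5.0):
            weights[off] = w.flat[0]
        assert weights[(1, 0, 0)] == pytest.approx(1.0)
        assert weights[(0, 1, 0)] == pytest.approx(0.5)
        assert weights[(0, 0, 1)] == pytest.approx(0.25)


class TestAssembly:
    def make_toy(self, weights=None):
        data = np.array([[[70.0], [120.0]], [[75.0], [118.0]]])
        vol = Volume(data)
        m = IntensityModel(object_params={"mu": 70, "sigma": 10},
                           background_params={"mu": 120, "sigma": 10})
        return vol, m

    def test_zero_aux_weights_reduce_to_data_plus_boundary(self):
        vol, m = self.make_toy()
        liver = np.ones(vol.shape, bool)
        aux = np.random.default_rng(0).uniform(0, 5, vol.shape)
        f0 = assemble_energy(vol, liver, m,
                             vessel_energy=aux, blob_energy=aux,
                             weights=TermWeights(enhance=0, shape=0))
        f_plain = assemble_energy(vol, liver, m)
        lab = np.array([1, 0, 0, 1], dtype=bool)
        assert f0.energy_of(lab) == pytest.approx(f_plain.energy_of(lab))

    def test_hand_computed_energy_on_2x2x1(self):
        vol, m = self.make_toy()
        liver = np.ones(vol.shape, bool)
        f = assemble_energy(vol, liver, m, sigma=10.0)
        co, cb = data_term(vol, m)
        lab = np.array([1, 0, 0, 1], dtype=bool)   # order of np.argwhere(roi)
        flat_o = co.ravel()
        flat_b = cb.ravel()
        unary = flat_o[0] + flat_b[1] + flat_b[2] + flat_o[3]
        d = vol.data
        pair = 0.0
        # label-discordant 6-neighbour pairs: all four in-plane edges here
        for (a, b) in [((0, 0, 0), (1, 0, 0)), ((0, 1, 0), (1, 1, 0)),
                       ((0, 0, 0), (0, 1, 0)), ((1, 0, 0), (1, 1, 0))]:
            pair += boundary_weight(d[a] - d[b], 10.0)
        assert f.energy_of(lab) == pytest.approx(unary + pair)

    def test_misaligned_maps_rejected(self):
        vol, m = self.make_toy()
        with pytest.raises(ValueError, match="shape"):
            assemble_energy(vol, np.ones(vol.shape, bool), m,
                            vessel_energy=np.zeros((5, 5, 5)))


class TestMinCut:
    def test_matches_exhaustive_enumeration_on_random_toys(self):
        rng = np.random.default_rng(42)
        for _ in range(100):
            field = random_toy_field(rng)
            lab = min_cut_labeling(field)
            best_e, _ = exhaustive_minimum(field)
            assert field.energy_of(lab) == pytest.approx(best_e, abs=1e-6)

    def test_dominated_unaries_give_all_object(self):
        n = 6
        field = EnergyField(roi=np.ones((n, 1, 1), bool),
                            unary_object=np.zeros(n),
                            unary_background=np.full(n, 10.0),
                            pair_i=np.arange(n - 1), pair_j=np.arange(1, n),
                            pair_w=np.ones(n - 1))
        assert min_cut_labeling(field).all()

    def test_stronger_pairwise_never_cuts_more_edges(self):
        rng = np.random.default_rng(3)
        base = random_toy_field(rng, max_nodes=10)
        cuts = []
        for coef in (0.25, 0.5, 1.0, 2.0, 4.0):
            f = EnergyField(roi=base.roi, unary_object=base.unary_object,
                            unary_background=base.unary_background,
                            pair_i=base.pair_i, pair_j=base.pair_j,
                            pair_w=base.pair_w * coef)
            lab = min_cut_labeling(f)
            cuts.append(int((lab[f.pair_i] != lab[f.pair_j]).sum()))
        assert all(a >= b for a, b in zip(cuts, cuts[1:]))

    def test_attained_energy_not_above_all_background(self):
        rng = np.random.default_rng(4)
        for _ in range(10):
            field = random_toy_field(rng)
            lab = min_cut_labeling(field)
            assert (field.energy_of(lab)
                    <= field.energy_of(np.zeros(field.n_nodes, bool)) + 1e-9)


class TestVesselRemoval:
    def test_zero_map_is_noop_and_extremes(self):
        from hepatoseg.graphcut import Segmentation
        mask = np.zeros((8, 8, 8), np.uint8)
        mask[2:6, 2:6, 2:6] = LESION
        seg = Segmentation(mask=Mask(mask), energy=0.0)
        same = remove_vessels(seg, np.zeros((8, 8, 8)), threshold=0.5)
        assert np.array_equal(same.mask.data, mask)
        inf = remove_vessels(seg, np.random.default_rng(0).random((8, 8, 8)),
                             threshold=np.inf)
        assert np.array_equal(inf.mask.data, mask)
        none = remove_vessels(seg, np.zeros((8, 8, 8)), threshold=0.0)
        assert not (none.mask.data == LESION).any()
        assert (none.mask.data == VESSEL).any()

    def test_eligible_mask_extremes(self):
        liver = np.ones((4, 4, 4), bool)
        resp = np.random.default_rng(1).random((4, 4, 4))
        assert vessel_eligible_mask(liver, resp, 0.0).sum() == 0
        assert vessel_eligible_mask(liver, resp, np.inf).all()

    def test_removal_contract_matches_threshold_exactly(self):
        from hepatoseg.graphcut import Segmentation
        rng = np.random.default_rng(5)
        resp = rng.random((10, 10, 10))
        mask = np.full((10, 10, 10), LESION, np.uint8)
        seg = Segmentation(mask=Mask(mask), energy=0.0)
        cleaned = remove_vessels(seg, resp, threshold=0.4)
        assert np.array_equal(cleaned.mask.data == VESSEL, resp >= 0.4)
        assert np.array_equal(cleaned.mask.data == LESION, resp < 0.4)

    def test_phantom_tube_voxels_absent_from_final_tumor_mask(self):
        from hepatoseg.graphcut import fit_intensity_models
        from hepatoseg.pipeline import run_tumor_pipeline
        train = default_phantom(seed=0, grid_shape=(48, 48, 48), n_lesions=1)
        test = default_phantom(seed=3, grid_shape=(48, 48, 48), n_lesions=1)
        model = fit_intensity_models(train.volume, train.truth.data > 0,
                                     train.truth.data == LESION)
        res = run_tumor_pipeline(test.volume, test.truth.data > 0, model)
        tube = test.truth.data == VESSEL
        excluded = 1.0 - ((res.tumor.data == LESION) & tube).sum() / tube.sum()
        assert excluded >= 0.95
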