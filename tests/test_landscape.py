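"""Order parameters, free-energy surfaces and basin clustering."""

import numpy as np
import pytest

from _oracles import dbscan_oracle, partitions_equal
from acudyn import landscape, synthio
from acudyn.landscape import (
    GAS_CONSTANT_KCAL,
    boltzmann_invert,
    categorize_and_populate,
    compute_order_parameters,
    free_energy_surface,
    optics_cluster,
)
from acudyn.structio import Atom, Structure, Trajectory


def _toy_dimer_frame(opening=20.0, jack_a=15.0, jack_b=25.0):
    """One-frame dimer with hand-placed domain pseudo-atoms."""
    atoms = []
    coords = []
    for chain, x0, jack in (("A", 0.0, jack_a), ("B", opening, jack_b)):
        for resnum in range(1, 215):
            atoms.append(Atom(chain, resnum, "GLY", "CA", "C"))
            if resnum <= 134:
                coords.append([x0, 0.0, 0.0])
            else:
                coords.append([x0, jack, 0.0])
    top = Structure(atoms, np.array(coords))
    return Trajectory(top, top.coords[None, :, :])


class TestOrderParameters:
    def test_planted_opening_distance(self):
        traj = _toy_dimer_frame(opening=20.0)
        ops = compute_order_parameters(traj)
        assert ops.opening[0] == pytest.approx(20.0, abs=1e-9)

    def test_jacking_aggregation_rules(self):
        traj = _toy_dimer_frame(jack_a=15.0, jack_b=25.0)
        # COM(135-214) sits `jack` above COM(1-134) but the bateman range
        # includes residues 1-134 only, so per-monomer jacking is exact
        assert compute_order_parameters(traj, aggregation="max").jacking[0] == pytest.approx(25.0)
        assert compute_order_parameters(traj, aggregation="mean").jacking[0] == pytest.approx(20.0)
        per = compute_order_parameters(traj, aggregation="per-monomer")
        np.testing.assert_allclose(per.jacking_per_monomer[0], [15.0, 25.0])

    def test_generator_ground_truth_recovered(self, small_dimer):
        traj, truth = small_dimer
        ops = compute_order_parameters(traj)
        np.testing.assert_allclose(ops.opening, truth.opening, atol=1e-6)
        np.testing.assert_allclose(ops.jacking, truth.jacking, atol=1e-6)

    def test_missing_chain_errors(self, small_dimer):
        traj, _ = small_dimer
        with pytest.raises(ValueError, match="chain Z"):
            compute_order_parameters(traj, monomer_chains=("A", "Z"))


class TestFreeEnergySurface:
    def test_single_occupied_bin_is_zero_rest_undefined(self):
        x = np.full(50, 10.0)
        y = np.full(50, 20.0)
        fes = free_energy_surface(x, y, bins=5)
        defined = ~fes.delta_g.mask
        assert defined.sum() == 1
        assert fes.delta_g[defined][0] == 0.0

    def test_analytic_ratio_identities(self):
        # P = {Pmax, Pmax/e} -> dG = {0, RT}; P = {Pmax, Pmax/2} -> {0, RT ln 2}
        rt = GAS_CONSTANT_KCAL * 310.0
        dg = boltzmann_invert(np.array([[1.0, 1.0 / np.e, 0.5, 0.0]]) / (1 + 1 / np.e + 0.5))
        assert dg[0, 0] == 0.0
        assert dg[0, 1] == pytest.approx(rt, rel=1e-12)
        assert dg[0, 2] == pytest.approx(rt * np.log(2.0), rel=1e-12)
        assert dg.mask[0, 3]

    def test_minimum_zero_at_modal_bin(self, rng):
        fes = free_energy_surface(rng.normal(size=4000), rng.normal(size=4000), bins=30)
        assert fes.delta_g.min() == 0.0
        i, j = np.unravel_index(np.argmax(fes.probability), fes.probability.shape)
        assert fes.delta_g[i, j] == 0.0
        assert (fes.delta_g.compressed() >= 0.0).all()
        assert fes.probability.sum() == pytest.approx(1.0, abs=1e-12)

    def test_invariant_to_positive_rescaling_of_probability(self, rng):
        p = rng.uniform(size=(8, 8))
        a = boltzmann_invert(p / p.sum())
        b = boltzmann_invert(3.7 * p)
        np.testing.assert_allclose(a.filled(-1), b.filled(-1), atol=1e-12)

    def test_harmonic_limit_curvature(self):
        """Fine-binned FES of an isotropic Gaussian is quadratic with
        curvature RT/sigma^2 (slope RT/(2 sigma^2) against r^2)."""
        rng = np.random.default_rng(7)
        sigma = 1.2
        xy = rng.normal(scale=sigma, size=(100000, 2))
        fes = free_energy_surface(xy[:, 0], xy[:, 1], bins=80)
        xc = 0.5 * (fes.x_edges[:-1] + fes.x_edges[1:])
        yc = 0.5 * (fes.y_edges[:-1] + fes.y_edges[1:])
        xx, yy = np.meshgrid(xc, yc, indexing="ij")
        q = (xx - xy[:, 0].mean()) ** 2 + (yy - xy[:, 1].mean()) ** 2
        ok = (~fes.delta_g.mask) & (q < (2.5 * sigma) ** 2) & (
            fes.probability * len(xy) >= 50
        )
        slope = np.polyfit(q[ok], fes.delta_g.data[ok], 1)[0]
        expected = fes.rt / (2.0 * sigma**2)
        assert slope == pytest.approx(expected, rel=0.05)

    def test_non_finite_input_rejected(self):
        with pytest.raises(ValueError, match="finite"):
            free_energy_surface(np.array([1.0, np.nan]), np.array([1.0, 2.0]))


from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays


@settings(max_examples=50, deadline=None, derandomize=True)
@given(
    prob=arrays(np.float64, (6, 6), elements=st.floats(0.0, 1.0)),
    scale=st.floats(1e-3, 1e3),
)
def test_boltzmann_inversion_properties(prob, scale):
    """For any non-degenerate probability grid: min dG = 0 at the modal bin,
    all defined dG >= 0, and a positive rescaling leaves dG unchanged."""
    if prob.max() <= 0:
        return
    dg = boltzmann_invert(prob)
    assert dg.min() == 0.0
    assert (dg.compressed() >= 0.0).all()
    i, j = np.unravel_index(np.argmax(prob), prob.shape)
    assert dg[i, j] == 0.0
    rescaled = boltzmann_invert(prob * scale)
    np.testing.assert_allclose(dg.filled(-1.0), rescaled.filled(-1.0), atol=1e-9)


class TestOpticsCluster:
    def _blobs(self, rng, centers, n_each=200, scale=1.0):
        pts = np.concatenate(
            [rng.normal(loc=c, scale=scale, size=(n_each, 2)) for c in centers]
        )
        truth = np.repeat(np.arange(len(centers)), n_each)
        return pts, truth

    def test_three_separated_blobs_recovered(self):
        rng = np.random.default_rng(1)
        pts, truth = self._blobs(rng, [(0, 0), (10, 0), (0, 10)], scale=1.0)
        res = optics_cluster(pts, min_samples=50, standardize=False)
        assert res.n_clusters == 3
        # map each found cluster to its majority truth blob
        correct = 0
        for lab in range(res.n_clusters):
            mask = res.labels == lab
            counts = np.bincount(truth[mask], minlength=3)
            correct += counts.max()
        assert correct / len(pts) >= 0.99

    def test_single_blob_mostly_one_cluster(self):
        rng = np.random.default_rng(1)
        pts = rng.normal(size=(300, 2))
        res = optics_cluster(pts, min_samples=50)
        assert res.n_clusters == 1
        assert (res.labels == 0).mean() >= 0.95

    def test_eps_cut_matches_brute_force_dbscan(self, rng):
        from _oracles import core_mask

        for centers, n_each, eps in (
            ([(0, 0), (8, 0)], 120, 0.9),
            ([(0, 0), (6, 6), (12, 0)], 80, 0.8),
            ([(0, 0)], 250, 1.0),
        ):
            pts, _ = self._blobs(rng, centers, n_each=n_each)
            res = optics_cluster(pts, min_samples=10, extraction="eps-cut",
                                 eps=eps, standardize=False)
            oracle = dbscan_oracle(pts, eps=eps, min_samples=10)
            # core-point partition must match exactly (border points are
            # order-dependent in both algorithms, so only cores are compared)
            cores = core_mask(pts, eps=eps, min_samples=10)
            assert partitions_equal(res.labels, oracle, restrict=cores)
            assert not np.any(res.labels[cores] == -1)
            assert not np.any(oracle[cores] == -1)

    def test_too_few_points_rejected(self, rng):
        with pytest.raises(ValueError, match="min_samples"):
            optics_cluster(rng.normal(size=(10, 2)), min_samples=50)

    def test_population_fractions_sum_below_one(self, rng):
        pts, _ = self._blobs(rng, [(0, 0), (12, 0)], n_each=150)
        res = optics_cluster(pts, min_samples=15)
        assert (res.table["population"] >= 0).all()
        assert res.table["population"].sum() <= 1.0 + 1e-12


class TestCategories:
    def test_centroid_categories_by_threshold(self):
        import pandas as pd

        table = pd.DataFrame(
            {
                "label": [0, 1, 2],
                "count": [600, 300, 100],
                "population": [0.6, 0.3, 0.1],
                "centroid_opening_A": [20.0, 32.0, 22.0],
                "centroid_jacking_A": [14.0, 14.1, 26.0],
            }
        )
        res = categorize_and_populate(
            landscape.BasinResult(np.zeros(1000), np.zeros(1000), np.arange(1000), table),
            opening_threshold=26.0,
            jacking_threshold=20.0,
        )
        assert list(res["category"]) == ["closed/compact", "open/compact", "extended"]

    def test_all_frames_one_state_population_one(self):
        spec = synthio.DimerSpec(
            n_frames=400,
            states=(synthio.StateSpec(20.0, 15.0, ((0.5, 0), (0, 0.5)), "only"),),
            populations=(1.0,),
            seed=5,
        )
        traj, _ = synthio.gen_dimer_trajectory(spec)
        ops = compute_order_parameters(traj)
        res = optics_cluster(ops.points(), min_samples=20, extraction="eps-cut", eps=1.0)
        table = categorize_and_populate(res)
        assert table["population"].iloc[0] == pytest.approx(1.0, abs=0.02)
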