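"""GrabCut core: trimap, GMM fitting, energy terms, exact min-cut."""

import itertools

import numpy as np
import pytest
from skimage.draw import ellipse

from dermseg.boxes import BoundingBox
from dermseg.grabcut import (
    TRIMAP_BG,
    TRIMAP_FG,
    TRIMAP_UNKNOWN,
    GmmModel,
    GrabCutConfig,
    GrabCutError,
    ModelDegeneracyError,
    SmoothnessParams,
    assign_components,
    build_graph,
    compute_beta,
    data_term,
    fit_gmm,
    grabcut_segment,
    init_trimap,
    min_cut,
    total_energy,
)

LOG_2PI = np.log(2 * np.pi)


def brute_force_min_energy(image, trimap, gmm, params):
    """Exhaustive minimum of the energy over labelings of unknown pixels.

    Uses the per-pixel best mixture component for each class, matching
    what assign_components selects.
    """
    h, w = image.shape[:2]
    flat = image.reshape(-1, 3).astype(float)
    tri = trimap.reshape(-1)
    unknown = np.flatnonzero(tri == TRIMAP_UNKNOWN)
    best = np.inf
    for bits in itertools.product([0, 1], repeat=len(unknown)):
        lab = np.where(tri == TRIMAP_FG, 1, 0).astype(np.uint8)
        lab[unknown] = bits
        comps = assign_components(flat, lab, gmm)
        e = total_energy(lab.reshape(h, w), comps, gmm, image, params)
        best = min(best, e)
    return best


def random_instance(rng, h=4, w=4, n_unknown=6, gamma=None):
    image = rng.integers(0, 256, size=(h, w, 3)).astype(np.uint8)
    trimap = np.full((h, w), TRIMAP_BG, dtype=np.uint8)
    flatpos = rng.choice(h * w, size=n_unknown, replace=False)
    trimap.reshape(-1)[flatpos] = TRIMAP_UNKNOWN
    labels = (trimap.reshape(-1) != TRIMAP_BG).astype(np.uint8)
    comps = rng.integers(0, 2, size=h * w).astype(np.int32)
    gmm = fit_gmm(image.reshape(-1, 3), labels, comps, 2)
    params = SmoothnessParams(
        gamma=float(gamma if gamma is not None else rng.uniform(0, 20)),
        beta=compute_beta(image, 8),
        connectivity=8,
    )
    return image, trimap, gmm, params


class TestInitTrimap:
    def test_region_counts(self):
        tri = init_trimap((10, 10), BoundingBox(2, 2, 8, 8))
        assert (tri == TRIMAP_UNKNOWN).sum() == 36
        assert (tri == TRIMAP_BG).sum() == 64

    def test_no_foreground_at_init(self):
        tri = init_trimap((10, 10), BoundingBox(2, 2, 8, 8))
        assert (tri == TRIMAP_FG).sum() == 0

    def test_full_image_rect_rejected(self):
        with pytest.raises(GrabCutError):
            init_trimap((10, 10), BoundingBox(0, 0, 10, 10))


class TestFitGmm:
    def test_constant_pixels_single_component(self):
        pixels = np.full((50, 3), 37.0)
        labels = np.array([0] * 25 + [1] * 25)
        gmm = fit_gmm(pixels, labels, np.zeros(50, int), 1)
        assert np.allclose(gmm.means[1, 0], [37, 37, 37])
        assert np.allclose(gmm.covariances[1, 0], np.eye(3) * 1e-3)
        assert gmm.weights[1, 0] == 1.0

    def test_two_clusters_recover_centroids(self, rng):
        a = rng.normal([200, 30, 30], 0.0, size=(40, 3))
        b = rng.normal([20, 180, 90], 0.0, size=(60, 3))
        pixels = np.vstack([a, b])
        labels = np.ones(100, int)
        labels[:0] = 0
        # background needs at least one pixel
        labels[0] = 0
        comps = np.array([0] * 40 + [1] * 60)
        gmm = fit_gmm(pixels, labels, comps, 2)
        assert np.allclose(gmm.means[1, 0], [200, 30, 30], atol=1e-9)
        assert np.allclose(gmm.means[1, 1], [20, 180, 90], atol=1e-9)

    def test_weights_normalized_per_class(self, rng):
        pixels = rng.uniform(0, 255, size=(80, 3))
        labels = (rng.uniform(size=80) < 0.5).astype(int)
        comps = rng.integers(0, 5, size=80)
        gmm = fit_gmm(pixels, labels, comps, 5)
        assert np.allclose(gmm.weights.sum(axis=1), [1.0, 1.0])

    def test_empty_class_rejected(self, rng):
        pixels = rng.uniform(0, 255, size=(10, 3))
        with pytest.raises(ModelDegeneracyError):
            fit_gmm(pixels, np.ones(10, int), np.zeros(10, int), 2)


class TestAssignComponents:
    def test_single_component(self, rng):
        pixels = rng.uniform(0, 255, size=(20, 3))
        labels = np.array([0, 1] * 10)
        gmm = fit_gmm(pixels, labels, np.zeros(20, int), 1)
        assert np.all(assign_components(pixels, labels, gmm) == 0)

    def test_pixel_at_mean_wins(self):
        means = np.array([[[10.0, 10, 10], [200.0, 200, 200]]] * 2)
        gmm = GmmModel.from_parameters(
            weights=np.full((2, 2), 0.5),
            means=means,
            covariances=np.tile(np.eye(3), (2, 2, 1, 1)),
        )
        comp = assign_components(np.array([[200.0, 200, 200]]), np.array([1]), gmm)
        assert comp[0] == 1

    def test_matches_exhaustive_argmax(self, rng):
        pixels = rng.uniform(0, 255, size=(20, 3))
        labels = (rng.uniform(size=20) < 0.5).astype(int)
        comps0 = rng.integers(0, 3, size=20)
        gmm = fit_gmm(pixels, labels, comps0, 3)
        got = assign_components(pixels, labels, gmm)
        for i in range(20):
            energies = [
                data_term(pixels[i], labels[i], c, gmm) for c in range(3)
            ]
            assert got[i] == int(np.argmin(energies))


class TestDataTerm:
    def unit_gmm(self, weight=1.0):
        return GmmModel.from_parameters(
            weights=np.array([[weight], [weight]]),
            means=np.zeros((2, 1, 3)),
            covariances=np.tile(np.eye(3), (2, 1, 1, 1)),
        )

    def test_at_mean_is_gaussian_normalizer(self):
        gmm = self.unit_gmm()
        assert data_term(np.zeros(3), 0, 0, gmm) == pytest.approx(1.5 * LOG_2PI)

    def test_halving_weight_adds_log2(self):
        full = data_term(np.zeros(3), 0, 0, self.unit_gmm(1.0))
        half = data_term(np.zeros(3), 0, 0, self.unit_gmm(0.5))
        assert half - full == pytest.approx(np.log(2))

    def test_monotone_in_distance(self):
        gmm = self.unit_gmm()
        near = data_term(np.array([1.0, 0, 0]), 0, 0, gmm)
        far = data_term(np.array([3.0, 0, 0]), 0, 0, gmm)
        assert far > near

    def test_zero_weight_infinite(self):
        gmm = self.unit_gmm(1.0)
        gmm.weights[0, 0] = 0.0
        assert data_term(np.zeros(3), 0, 0, gmm) == np.inf


class TestBeta:
    def test_constant_image_zero(self):
        assert compute_beta(np.full((8, 8, 3), 55, np.uint8)) == 0.0

    def test_two_pixel_closed_form(self):
        img = np.zeros((1, 2, 3))
        img[0, 1, 0] = 10.0
        assert compute_beta(img, 4) == pytest.approx(1 / 200)

    def test_intensity_scaling_homogeneity(self, rng):
        img = rng.uniform(0, 50, size=(6, 6, 3))
        assert compute_beta(img * 2, 8) == pytest.approx(compute_beta(img, 8) / 4)


class TestEnergy:
    def make_gmm(self, rng):
        pixels = rng.uniform(0, 255, size=(30, 3))
        labels = np.array([0, 1] * 15)
        return pixels, labels, fit_gmm(pixels, labels, rng.integers(0, 2, 30), 2)

    def test_uniform_labels_no_smoothness(self, rng):
        image = rng.integers(0, 256, size=(4, 4, 3)).astype(np.uint8)
        labels = np.ones((4, 4), np.uint8)
        flat = image.reshape(-1, 3).astype(float)
        gmm = GmmModel.from_parameters(
            weights=np.ones((2, 1)),
            means=np.full((2, 1, 3), 128.0),
            covariances=np.tile(np.eye(3) * 900.0, (2, 1, 1, 1)),
        )
        comps = np.zeros((4, 4), int)
        params = SmoothnessParams(gamma=10.0, beta=0.01)
        e = total_energy(labels, comps, gmm, image, params)
        # with V = 0 the energy is the summed data terms
        expected = sum(
            data_term(flat[i], 1, 0, gmm) for i in range(16)
        )
        assert e == pytest.approx(expected)

    def test_two_pixel_closed_form(self):
        image = np.zeros((1, 2, 3))
        image[0, 0] = [10, 20, 30]
        image[0, 1] = [50, 20, 30]
        gmm = GmmModel.from_parameters(
            weights=np.ones((2, 1)),
            means=np.array([[[10.0, 20, 30]], [[50.0, 20, 30]]]),
            covariances=np.tile(np.eye(3), (2, 1, 1, 1)),
        )
        params = SmoothnessParams(gamma=7.0, beta=0.001, connectivity=4)
        labels = np.array([[0, 1]], np.uint8)
        comps = np.zeros((1, 2), int)
        u1 = data_term(image[0, 0], 0, 0, gmm)
        u2 = data_term(image[0, 1], 1, 0, gmm)
        v = 7.0 * np.exp(-0.001 * 1600)
        e = total_energy(labels, comps, gmm, image, params)
        assert e == pytest.approx(u1 + u2 + v)

    def test_gamma_zero_energy_is_data_only(self, rng):
        image = rng.integers(0, 256, size=(3, 5, 3)).astype(np.uint8)
        labels = (rng.uniform(size=(3, 5)) < 0.5).astype(np.uint8)
        flat = image.reshape(-1, 3).astype(float)
        gmm = fit_gmm(flat, labels.reshape(-1), np.zeros(15, int), 1)
        comps = np.zeros((3, 5), int)
        e0 = total_energy(labels, comps, gmm, image, SmoothnessParams(gamma=0.0, beta=0.01))
        e1 = total_energy(labels, comps, gmm, image, SmoothnessParams(gamma=5.0, beta=0.01))
        assert e0 <= e1


class TestGraphAndCut:
    def test_background_pixels_never_foreground(self, rng):
        image, trimap, gmm, params = random_instance(rng)
        labels = min_cut(build_graph(image, trimap, gmm, params))
        assert not labels[trimap == TRIMAP_BG].any()

    def test_gamma_zero_cut_is_per_pixel_argmin(self, rng):
        image, trimap, gmm, params = random_instance(rng, gamma=0.0)
        labels = min_cut(build_graph(image, trimap, gmm, params)).reshape(-1)
        flat = image.reshape(-1, 3).astype(float)
        tri = trimap.reshape(-1)
        for i in np.flatnonzero(tri == TRIMAP_UNKNOWN):
            d0 = min(data_term(flat[i], 0, c, gmm) for c in range(2))
            d1 = min(data_term(flat[i], 1, c, gmm) for c in range(2))
            if d0 != d1:
                assert labels[i] == int(d1 < d0)

    def test_graph_sizes_on_3x3(self, rng):
        image = rng.integers(0, 256, size=(3, 3, 3)).astype(np.uint8)
        trimap = init_trimap((3, 3), BoundingBox(1, 1, 2, 2))
        labels = (trimap.reshape(-1) != TRIMAP_BG).astype(np.uint8)
        # single unknown pixel; fit needs at least one pixel per class
        gmm = fit_gmm(image.reshape(-1, 3), labels, np.zeros(9, int), 1)
        params = SmoothnessParams(gamma=1.0, beta=0.001)
        g = build_graph(image, trimap, gmm, params)
        assert g.source_cap.shape == (9,) and g.sink_cap.shape == (9,)
        # 8-connectivity on 3×3: 6 horizontal + 6 vertical + 4 + 4 diagonal
        assert len(g.edge_cap) == 20

    def test_dominant_terminals(self):
        # all unknown pixels overwhelmingly cheaper as foreground
        image = np.full((3, 3, 3), 100, np.uint8)
        trimap = np.full((3, 3), TRIMAP_UNKNOWN, np.uint8)
        trimap[0, 0] = TRIMAP_BG
        gmm = GmmModel.from_parameters(
            weights=np.ones((2, 1)),
            means=np.array([[[0.0, 0, 0]], [[100.0, 100, 100]]]),
            covariances=np.tile(np.eye(3), (2, 1, 1, 1)),
        )
        params = SmoothnessParams(gamma=0.0, beta=0.0)
        labels = min_cut(build_graph(image, trimap, gmm, params))
        assert labels[trimap == TRIMAP_UNKNOWN].all()
        assert not labels[0, 0]

    def test_cut_matches_enumeration_small(self, rng):
        for _ in range(20):
            image, trimap, gmm, params = random_instance(rng, n_unknown=6)
            labels = min_cut(build_graph(image, trimap, gmm, params))
            comps = assign_components(image.reshape(-1, 3), labels.reshape(-1), gmm)
            e_cut = total_energy(labels, comps, gmm, image, params)
            e_min = brute_force_min_energy(image, trimap, gmm, params)
            assert e_cut == pytest.approx(e_min, abs=1e-4)

    def test_flow_value_matches_energy_offset(self, rng):
        """Max-flow value = energy of the cut labeling minus the
        label-independent constant (the per-pixel cheaper data term)."""
        from scipy.sparse import csr_matrix

        image, trimap, gmm, params = random_instance(rng, n_unknown=8)
        g = build_graph(image, trimap, gmm, params)
        labels = min_cut(g)
        comps = assign_components(image.reshape(-1, 3), labels.reshape(-1), gmm)
        e_cut = total_energy(labels, comps, gmm, image, params)
        flat = image.reshape(-1, 3).astype(float)
        tri = trimap.reshape(-1)
        const = 0.0
        for i in range(flat.shape[0]):
            d0 = min(data_term(flat[i], 0, c, gmm) for c in range(2))
            if tri[i] == TRIMAP_BG:
                const += d0
            else:
                d1 = min(data_term(flat[i], 1, c, gmm) for c in range(2))
                const += min(d0, d1)
        # recompute the cut cost from the labeling and graph capacities
        cut_cost = 0.0
        lab = labels.reshape(-1)
        for i in np.flatnonzero(tri != TRIMAP_BG):
            d0 = min(data_term(flat[i], 0, c, gmm) for c in range(2))
            d1 = min(data_term(flat[i], 1, c, gmm) for c in range(2))
            cut_cost += (d0 if lab[i] == 0 else d1) - min(d0, d1)
        for a, b, cap in zip(g.edge_a, g.edge_b, g.edge_cap):
            if lab[a] != lab[b]:
                cut_cost += cap
        assert e_cut - const == pytest.approx(cut_cost, abs=1e-6)


class TestGrabcutSegment:
    @staticmethod
    def two_color_scene(seed):
        rng = np.random.default_rng(seed)
        img = np.full((80, 80, 3), (205, 155, 140), np.uint8)
        cy, cx = rng.integers(30, 50, size=2)
        ry, rx = rng.integers(12, 20, size=2)
        rr, cc = ellipse(cy, cx, ry, rx, shape=(80, 80))
        gt = np.zeros((80, 80), bool)
        gt[rr, cc] = True
        img[gt] = (95, 55, 50)
        rect = BoundingBox(
            max(0, cx - rx - 6), max(0, cy - ry - 6), min(80, cx + rx + 6), min(80, cy + ry + 6)
        )
        return img, gt, rect

    def test_exact_recovery_on_separable_colors(self):
        for seed in range(3):
            img, gt, rect = self.two_color_scene(seed)
            mask = grabcut_segment(img, rect, GrabCutConfig())
            assert np.array_equal(mask, gt)

    def test_mask_inside_rectangle(self, hairless_sample):
        s = hairless_sample
        rect = BoundingBox(s.gt_box.x1 - 3, s.gt_box.y1 - 3, s.gt_box.x2 + 3, s.gt_box.y2 + 3)
        mask = grabcut_segment(s.hairless_image, rect, GrabCutConfig())
        outside = np.ones_like(mask)
        y1, y2 = int(np.floor(rect.y1)), int(np.ceil(rect.y2))
        x1, x2 = int(np.floor(rect.x1)), int(np.ceil(rect.x2))
        outside[y1:y2, x1:x2] = False
        assert not mask[outside].any()

    def test_energy_trace_non_increasing(self, hairless_sample):
        s = hairless_sample
        rect = BoundingBox(s.gt_box.x1 - 3, s.gt_box.y1 - 3, s.gt_box.x2 + 3, s.gt_box.y2 + 3)
        _, trace = grabcut_segment(
            s.hairless_image, rect, GrabCutConfig(max_iterations=6), return_trace=True
        )
        assert all(b <= a for a, b in zip(trace, trace[1:]))

    def test_deterministic(self, hairless_sample):
        s = hairless_sample
        rect = BoundingBox(s.gt_box.x1 - 3, s.gt_box.y1 - 3, s.gt_box.x2 + 3, s.gt_box.y2 + 3)
        a = grabcut_segment(s.hairless_image, rect, GrabCutConfig(seed=3))
        b = grabcut_segment(s.hairless_image, rect, GrabCutConfig(seed=3))
        assert np.array_equal(a, b)
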