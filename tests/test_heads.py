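import numpy as np
import pytest
from skimage.draw import disk

from uavpheno.errors import ContractError
from uavpheno.geometry import PlotImage
from uavpheno.heads import (
    HeadCluster,
    HeadCount,
    classify_and_count,
    cluster_shapes,
    count_heads,
    head_mask,
    kde_circularity_thresholds,
    kde_density,
    silverman_bandwidth,
)
from uavpheno.indices import BinaryMask
from uavpheno.radiometry import BANDS

SOIL = {"blue": 0.08, "green": 0.12, "red": 0.15, "red_edge": 0.17, "nir": 0.18}
LEAF = {"blue": 0.04, "green": 0.08, "red": 0.05, "red_edge": 0.30, "nir": 0.50}
RED_HEAD = {"blue": 0.10, "green": 0.14, "red": 0.18, "red_edge": 0.21, "nir": 0.55}
WHITE_HEAD = {"blue": 0.28, "green": 0.30, "red": 0.30, "red_edge": 0.33, "nir": 0.90}


def plot_image(head_centres=(), head_radius=6.0, head_spectra=RED_HEAD,
               leaf_fraction=0.4, shape=(120, 200), noise=0.01, seed=0):
    rng = np.random.default_rng(seed)
    bands = {b: np.full(shape, SOIL[b]) for b in BANDS}
    truth_head = np.zeros(shape, bool)
    n_leaf = int(leaf_fraction * shape[0] * shape[1] / 80)
    for _ in range(n_leaf):
        rr, cc = disk((rng.uniform(0, shape[0]), rng.uniform(0, shape[1])),
                      rng.uniform(3, 7), shape=shape)
        for b in BANDS:
            bands[b][rr, cc] = LEAF[b]
    for centre in head_centres:
        rr, cc = disk(centre, head_radius, shape=shape)
        for b in BANDS:
            bands[b][rr, cc] = head_spectra[b]
        truth_head[rr, cc] = True
    if noise:
        for b in BANDS:
            bands[b] *= rng.lognormal(0.0, noise, shape)
    img = PlotImage(plot_id="p", capture_id="c", bands=bands,
                    valid_mask=np.ones(shape, bool), origin=(0, 0))
    return img, truth_head


class TestHeadMask:
    def test_mask_matches_rendered_heads(self):
        centres = [(30, 30), (30, 100), (90, 60), (90, 160)]
        img, truth = plot_image(centres)
        mask, qc = head_mask(img)
        assert not qc
        # agreement within a morphology-eroded boundary ring
        from skimage.morphology import erosion as binary_erosion, disk as mdisk
        core = binary_erosion(truth, mdisk(2))
        assert mask.values[core].all()
        from skimage.morphology import dilation as binary_dilation
        grown = binary_dilation(truth, mdisk(2))
        assert not mask.values[~grown].any()

    def test_all_leaf_canopy_empty_mask(self):
        img, _ = plot_image([], leaf_fraction=3.0)
        mask, _ = head_mask(img)
        assert not mask.values.any()

    def test_white_heads_detected_without_retuning(self):
        centres = [(30, 30), (60, 120), (90, 60)]
        img, truth = plot_image(centres, head_spectra=WHITE_HEAD)
        mask, _ = head_mask(img)
        from skimage.morphology import erosion as binary_erosion, disk as mdisk
        core = binary_erosion(truth, mdisk(2))
        assert mask.values[core].all()

    def test_degenerate_flat_image(self):
        img, _ = plot_image([], leaf_fraction=0.0, noise=0.0)
        img2 = PlotImage("p", "c", {b: np.full((10, 10), 0.2) for b in BANDS},
                         np.ones((10, 10), bool), (0, 0))
        mask, qc = head_mask(img2)
        assert not mask.values.any()
        assert "degenerate_gemi_histogram" in qc


def render_chain(k, r=6.0, s=1.1, angle=0.0, shape=(100, 160), centre=(50, 60)):
    m = np.zeros(shape, bool)
    dx, dy = np.cos(angle) * s * r, np.sin(angle) * s * r
    offsets = {1: [(0, 0)], 2: [(-dx / 2, -dy / 2), (dx / 2, dy / 2)],
               3: [(-dx, -dy), (0, 0), (dx, dy)]}[k]
    for ox, oy in offsets:
        rr, cc = disk((centre[0] + oy, centre[1] + ox), r, shape=shape)
        m[rr, cc] = True
    return m


class TestClusterShapes:
    def test_disc_circularity_in_discretization_band(self):
        m = np.zeros((60, 60), bool)
        rr, cc = disk((30, 30), 20, shape=m.shape)
        m[rr, cc] = True
        (c,) = cluster_shapes(BinaryMask(m), 10)
        assert 0.85 <= c.circularity <= 1.05

    def test_square_circularity_closed_form(self):
        # analytic square: 4*pi*s^2 / (4s)^2 = pi/4; the marching-squares
        # contour clips the four corners, so allow a small band around it
        m = np.zeros((40, 40), bool)
        m[10:30, 10:30] = True
        (c,) = cluster_shapes(BinaryMask(m), 10)
        assert c.circularity == pytest.approx(np.pi / 4, abs=0.05)

    def test_dumbbell_below_single_disc(self):
        single = cluster_shapes(BinaryMask(render_chain(1, r=20.0, s=0.75)), 10)[0]
        m = np.zeros((100, 160), bool)
        for cx in (60, 90):  # two discs r=20, centres 30 px apart
            rr, cc = disk((50, cx), 20, shape=m.shape)
            m[rr, cc] = True
        (dumbbell,) = cluster_shapes(BinaryMask(m), 10)
        assert dumbbell.circularity < single.circularity
        # pixel-level oracle: area equals the mask's pixel count within the
        # half-pixel contour band
        assert dumbbell.area_px == pytest.approx(m.sum(), rel=0.05)

    def test_anti_monotone_in_chain_length(self):
        rng = np.random.default_rng(3)
        means = []
        for k in (1, 2, 3):
            vals = [cluster_shapes(
                BinaryMask(render_chain(k, r=6.5, s=1.2, angle=a)), 10)[0].circularity
                for a in rng.uniform(-0.4, 0.4, 8)]
            means.append(np.mean(vals))
        assert means[0] > means[1] > means[2]

    def test_min_area_respected(self):
        m = np.zeros((30, 30), bool)
        m[5:7, 5:7] = True  # area 4
        assert cluster_shapes(BinaryMask(m), 10) == []
        assert len(cluster_shapes(BinaryMask(m), 4)) == 1

    def test_invalid_cluster_fields_rejected(self):
        with pytest.raises(ContractError):
            HeadCluster(contour=np.zeros((3, 2)), area_px=0.0, perimeter_px=1.0,
                        circularity=0.0)


def mixture_density(grid, values, bandwidth):
    """Closed-form Gaussian mixture evaluated on a dense grid (oracle)."""
    out = np.zeros_like(grid)
    for v in values:
        out += np.exp(-0.5 * ((grid - v) / bandwidth) ** 2)
    return out / (len(values) * bandwidth * np.sqrt(2 * np.pi))


class TestKdeThresholds:
    def test_two_clumps_single_minimum(self):
        values = [0.9, 0.88, 0.91, 0.6, 0.58]
        thr = kde_circularity_thresholds(values, bandwidth=0.05)
        assert len(thr) == 1
        assert 0.6 < thr[0] < 0.88
        # position matches a dense-grid scan of the analytic mixture
        dense = np.linspace(0, 1.3, 4096)
        d = mixture_density(dense, values, 0.05)
        interior = (d[1:-1] < d[:-2]) & (d[1:-1] <= d[2:])
        candidates = dense[1:-1][interior]
        candidates = candidates[(candidates > min(values)) & (candidates < max(values))]
        assert len(candidates) == 1
        grid_step = 1.3 / 511
        assert abs(thr[0] - candidates[0]) <= grid_step + 1.3 / 4095

    def test_identical_values_no_thresholds(self):
        assert kde_circularity_thresholds([0.8] * 10) == []

    def test_single_value_no_thresholds(self):
        assert kde_circularity_thresholds([0.9]) == []

    def test_three_clumps_two_thresholds(self, rng):
        values = np.concatenate([0.9 + rng.uniform(-0.01, 0.01, 5),
                                 0.65 + rng.uniform(-0.01, 0.01, 5),
                                 0.45 + rng.uniform(-0.01, 0.01, 5)])
        thr = kde_circularity_thresholds(values, bandwidth=0.03)
        assert len(thr) == 2
        assert 0.66 < thr[0] < 0.89
        assert 0.46 < thr[1] < 0.64

    def test_at_most_two_thresholds(self, rng):
        values = np.concatenate([c + rng.uniform(-0.005, 0.005, 4)
                                 for c in (0.95, 0.8, 0.65, 0.5, 0.35)])
        thr = kde_circularity_thresholds(values, bandwidth=0.02)
        assert len(thr) <= 2

    def test_empty_rejected(self):
        with pytest.raises(ContractError):
            kde_circularity_thresholds([])

    def test_bandwidth_floor(self):
        assert silverman_bandwidth(np.array([0.5, 0.5001])) == pytest.approx(0.015)

    def test_kde_density_integrates_to_one(self):
        grid = np.linspace(-2, 3, 4000)
        d = kde_density(np.array([0.2, 0.8, 0.5]), grid, 0.05)
        assert np.trapezoid(d, grid) == pytest.approx(1.0, abs=1e-3)


def cluster_with(circ):
    return HeadCluster(contour=np.zeros((4, 2)), area_px=10.0, perimeter_px=10.0,
                       circularity=circ)


class TestClassifyAndCount:
    def test_formula_arithmetic(self):
        clusters = [cluster_with(0.95)] * 5 + [cluster_with(0.7)] * 2 + \
                   [cluster_with(0.4)]
        out = classify_and_count(clusters, [0.8, 0.55])
        assert (out.n_single, out.n_double, out.n_triple) == (5, 2, 1)
        assert out.n_heads == 12

    def test_no_thresholds_all_single(self):
        out = classify_and_count([cluster_with(0.5)] * 7, [])
        assert out.n_single == 7
        assert out.n_heads == 7

    def test_interval_assignment(self):
        clusters = [cluster_with(c) for c in (0.95, 0.93, 0.70, 0.40)]
        out = classify_and_count(clusters, [0.80, 0.55])
        assert (out.n_single, out.n_double, out.n_triple) == (2, 1, 1)
        assert out.n_heads == 7

    def test_single_threshold_two_classes(self):
        clusters = [cluster_with(c) for c in (0.9, 0.6, 0.5)]
        out = classify_and_count(clusters, [0.7])
        assert (out.n_single, out.n_double, out.n_triple) == (1, 2, 0)

    def test_multiplicity_capped_at_three(self):
        out = classify_and_count([cluster_with(0.1)], [0.8, 0.5])
        assert all(c.multiplicity <= 3 for c in [cluster_with(0.1)] if c.multiplicity)
        assert out.n_triple == 1

    def test_unsorted_thresholds_rejected(self):
        with pytest.raises(ContractError):
            classify_and_count([cluster_with(0.9)], [0.5, 0.8])

    def test_count_identity_holds(self, rng):
        for _ in range(20):
            clusters = [cluster_with(c) for c in rng.uniform(0.2, 1.0, 15)]
            thr = sorted(rng.uniform(0.3, 0.9, rng.integers(0, 3)), reverse=True)
            out = classify_and_count(clusters, [float(t) for t in thr])
            assert out.n_heads == out.n_single + 2 * out.n_double + 3 * out.n_triple


def composed_plot(n_single, n_double, n_triple, spectra=RED_HEAD, seed=0,
                  r=6.5, s=1.2):
    """Plot image with a known head-cluster composition on a jittered grid."""
    rng = np.random.default_rng(seed)
    kinds = [1] * n_single + [2] * n_double + [3] * n_triple
    rng.shuffle(kinds)
    shape = (240, 400)
    slots = [(30 + 45 * j, 35 + 48 * i) for j in range(5) for i in range(8)]
    order = rng.permutation(len(slots))[:len(kinds)]
    bands = {b: np.full(shape, SOIL[b]) for b in BANDS}
    for _ in range(120):
        rr, cc = disk((rng.uniform(0, shape[0]), rng.uniform(0, shape[1])),
                      rng.uniform(3, 6), shape=shape)
        for b in BANDS:
            bands[b][rr, cc] = LEAF[b]
    for slot, k in zip(order, kinds):
        cy, cx = slots[slot]
        angle = rng.uniform(-0.4, 0.4)
        dx, dy = np.cos(angle) * s * r, np.sin(angle) * s * r
        offsets = {1: [(0, 0)], 2: [(-dx / 2, -dy / 2), (dx / 2, dy / 2)],
                   3: [(-dx, -dy), (0, 0), (dx, dy)]}[k]
        for ox, oy in offsets:
            rr, cc = disk((cy + oy, cx + ox), r, shape=shape)
            for b in BANDS:
                bands[b][rr, cc] = spectra[b]
    for b in BANDS:
        bands[b] = bands[b] * rng.lognormal(0, 0.01, shape)
    return PlotImage("p", "c", bands, np.ones(shape, bool), (0, 0))


class TestCountHeads:
    def test_known_composition_recovered(self):
        img = composed_plot(14, 6, 4, seed=1)
        out = count_heads(img)
        true = 14 + 2 * 6 + 3 * 4
        assert abs(out.n_heads - true) <= 0.05 * true

    def test_classification_accuracy_balanced(self):
        # >= 10 clusters per class; >= 95% assigned the right multiplicity
        ok = 0
        total = 0
        for seed in (2, 3):
            img = composed_plot(12, 11, 10, seed=seed)
            out = count_heads(img)
            total += 33
            ok += 33 - (abs(out.n_single - 12) + abs(out.n_double - 11)
                        + abs(out.n_triple - 10))
        assert ok / total >= 0.95

    def test_colour_robustness_red_vs_white(self):
        red = count_heads(composed_plot(10, 5, 3, spectra=RED_HEAD, seed=4))
        white = count_heads(composed_plot(10, 5, 3, spectra=WHITE_HEAD, seed=4))
        assert (red.n_single, red.n_double, red.n_triple) == \
            (white.n_single, white.n_double, white.n_triple)

    def test_fewer_than_four_clusters_all_single(self):
        img = composed_plot(2, 1, 0, seed=5)
        out = count_heads(img)
        assert out.thresholds == []
        assert out.n_double == 0 and out.n_triple == 0
        assert "too_few_clusters_for_kde" in out.qc_flags

    def test_count_identity_on_output(self):
        out = count_heads(composed_plot(9, 4, 2, seed=6))
        assert out.n_heads == out.n_single + 2 * out.n_double + 3 * out.n_triple
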