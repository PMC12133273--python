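"""Localization statistics: hand-computed values, brute-force oracles,
scale behaviour and geometric invariances."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from nucloc import (
    CellImage,
    MetricConfig,
    NucleusMask,
    bodvard,
    caihao,
    granados,
    ground_truth_localization,
    hu_eta1,
    logg,
    nuclear_concentration,
    petrenko,
    quantify_all,
    sunnaker,
)
from nucloc.data_model import LocalizationValue
from conftest import random_cell


def cell_from_values(values, shape=None):
    """A CellImage whose in-mask pixels are exactly `values`, row-major."""
    values = np.asarray(values, dtype=float)
    n = values.size
    side = int(np.ceil(np.sqrt(n)))
    shape = shape or (side, side)
    fluor = np.zeros(shape)
    mask = np.zeros(shape, dtype=bool)
    mask.ravel()[:n] = True
    fluor.ravel()[:n] = values
    return CellImage(fluor=fluor, cell_mask=mask)


# ---------------------------------------------------------------------------
# Ground truth and concentration
# ---------------------------------------------------------------------------

class TestGroundTruth:
    def test_uniform_cell_gives_one(self):
        img = cell_from_values(np.full(20, 7.0))
        nuc = np.zeros_like(img.cell_mask)
        nuc.ravel()[3:8] = True
        assert ground_truth_localization(img, NucleusMask(nuc)).value == 1.0

    def test_hand_cell(self, hand_cell):
        img, nuc = hand_cell
        val = ground_truth_localization(img, nuc).value
        assert val == pytest.approx(6.0 / 2.8, rel=1e-12)  # 2.142857...

    def test_nucleus_equals_cell_gives_one(self):
        img = cell_from_values([1.0, 5.0, 3.0, 9.0])
        assert (
            ground_truth_localization(img, NucleusMask(img.cell_mask)).value == 1.0
        )

    def test_empty_nucleus_errors(self):
        img = cell_from_values([1.0, 2.0])
        with pytest.raises(ValueError):
            ground_truth_localization(img, NucleusMask(np.zeros_like(img.cell_mask)))

    def test_concentration_recovers_nuclear_mean(self, hand_cell):
        img, nuc = hand_cell
        loc = ground_truth_localization(img, nuc)
        cell_mean = img.fluor[img.cell_mask].mean()  # 2.8
        assert nuclear_concentration(loc, cell_mean) == pytest.approx(6.0, rel=1e-12)

    def test_concentration_rejects_proxy_scales(self):
        v = LocalizationValue(value=2.0, method_tag="granados")
        with pytest.raises(ValueError):
            nuclear_concentration(v, 3.5)
        assert nuclear_concentration(
            LocalizationValue(2.0, "ground_truth"), 3.5
        ) == pytest.approx(7.0)


# ---------------------------------------------------------------------------
# Hand-arithmetic examples for every proxy statistic
# ---------------------------------------------------------------------------

class TestHandExamples:
    def test_petrenko_top_fifth(self):
        img = cell_from_values(np.arange(1.0, 11.0))
        assert petrenko(img).value == pytest.approx(9.5)  # mean of {9, 10}

    def test_petrenko_fraction_one_is_cell_mean(self):
        img = cell_from_values(np.arange(1.0, 11.0))
        cfg = MetricConfig(petrenko_fraction=1.0)
        assert petrenko(img, cfg).value == pytest.approx(5.5)

    def test_sunnaker_two_pixels(self):
        img = cell_from_values([2.0, 4.0])
        assert sunnaker(img).value == pytest.approx(1 / 3)

    def test_logg_two_level(self):
        img = cell_from_values([5.0, 5.0, 5.0, 1.0, 1.0, 1.0])
        assert logg(img).value == pytest.approx(5.0)

    def test_granados_example(self):
        img = cell_from_values([9, 9, 9, 9, 9, 1, 1, 1, 1, 3])
        assert granados(img).value == pytest.approx(9.0)

    def test_caihao_example(self):
        img = cell_from_values([9, 9, 9, 9, 9, 1, 1, 1, 1, 3])
        assert caihao(img).value == pytest.approx(7.6)

    def test_bodvard_plateau_over_background(self):
        """A bright plateau larger than the disc over flat background:
        with light smoothing the peak sits inside the plateau and the
        ratio approaches plateau/background."""
        fluor = np.full((17, 17), 2.0)
        fluor[5:12, 5:12] = 8.0
        img = CellImage(fluor=fluor, cell_mask=np.ones((17, 17), bool))
        cfg = MetricConfig(bodvard_sigma=0.5, bodvard_radius=2)
        assert bodvard(img, cfg).value == pytest.approx(4.0, rel=0.02)

    def test_hu_point_mass_is_zero(self):
        fluor = np.zeros((9, 9))
        fluor[4, 4] = 10.0
        img = CellImage(fluor=fluor, cell_mask=np.ones((9, 9), bool))
        assert hu_eta1(img).value == pytest.approx(0.0, abs=1e-15)


class TestConstantImage:
    """On a constant cell every statistic takes its degenerate value."""

    def test_all_methods(self):
        img = cell_from_values(np.full(30, 4.0))
        nuc = np.zeros_like(img.cell_mask)
        nuc.ravel()[5:9] = True
        values, failures = quantify_all(img, NucleusMask(nuc))
        assert failures == {}
        assert values["ground_truth"].value == 1.0
        assert values["petrenko"].value == 4.0
        assert values["sunnaker"].value == 0.0
        assert values["logg"].value == 1.0
        assert values["granados"].value == 1.0
        assert values["bodvard"].value == pytest.approx(1.0)
        assert values["caihao"].value == 0.0
        assert np.isfinite(values["hu1"].value)


# ---------------------------------------------------------------------------
# Brute-force oracle equivalence
# ---------------------------------------------------------------------------

def bruteforce_metrics(img, cfg):
    """Independent implementations via explicit python sorting, ties broken
    by (intensity, row-major index) descending like the library."""
    import math

    pix = [
        (img.fluor[y, x], y * img.fluor.shape[1] + x)
        for y, x in zip(*np.nonzero(img.cell_mask))
    ]
    pix.sort(key=lambda p: (-p[0], p[1]))
    vals = [p[0] for p in pix]
    n = len(vals)
    out = {}
    kp = math.ceil(cfg.petrenko_fraction * n)
    out["petrenko"] = sum(vals[:kp]) / kp
    mean = sum(vals) / n
    out["sunnaker"] = math.sqrt(sum((v - mean) ** 2 for v in vals) / n) / mean
    top3 = vals[: cfg.logg_k]
    rest3 = vals[cfg.logg_k :]
    out["logg"] = (sum(top3) / len(top3)) / (sum(rest3) / len(rest3))
    top5 = vals[: cfg.granados_k]
    rest5 = sorted(vals[cfg.granados_k :])
    m = len(rest5)
    median = (
        rest5[m // 2] if m % 2 else 0.5 * (rest5[m // 2 - 1] + rest5[m // 2])
    )
    out["granados"] = (sum(top5) / len(top5)) / median
    topc = vals[: cfg.caihao_k]
    restc = vals[cfg.caihao_k :]
    out["caihao"] = sum(topc) / len(topc) - sum(restc) / len(restc)
    return out


def bruteforce_eta1(img):
    """Double-loop intensity-weighted moments."""
    h, w = img.fluor.shape
    m00 = my = mx = 0.0
    for y in range(h):
        for x in range(w):
            if img.cell_mask[y, x]:
                wgt = img.fluor[y, x]
                m00 += wgt
                my += wgt * y
                mx += wgt * x
    cy, cx = my / m00, mx / m00
    mu20 = mu02 = 0.0
    for y in range(h):
        for x in range(w):
            if img.cell_mask[y, x]:
                wgt = img.fluor[y, x]
                mu20 += wgt * (y - cy) ** 2
                mu02 += wgt * (x - cx) ** 2
    return (mu20 + mu02) / m00**2


@pytest.mark.parametrize("seed", range(25))
def test_topk_metrics_match_bruteforce(seed):
    rng = np.random.default_rng(seed)
    img = random_cell(rng, shape=(10, 10))
    if img.n_cell_pixels < 8:
        return
    cfg = MetricConfig()
    expected = bruteforce_metrics(img, cfg)
    got = {
        "petrenko": petrenko(img, cfg).value,
        "sunnaker": sunnaker(img, cfg).value,
        "logg": logg(img, cfg).value,
        "granados": granados(img, cfg).value,
        "caihao": caihao(img, cfg).value,
    }
    for tag in expected:
        assert got[tag] == pytest.approx(expected[tag], rel=1e-10), tag


@pytest.mark.parametrize("seed", range(5))
def test_hu_matches_double_loop_and_skimage(seed):
    rng = np.random.default_rng(seed)
    img = random_cell(rng, shape=(9, 9))
    ours = hu_eta1(img).value
    assert ours == pytest.approx(bruteforce_eta1(img), rel=1e-10)
    # cross-check against the established library on the masked image
    from skimage.measure import moments_central, moments_normalized

    masked = np.where(img.cell_mask, img.fluor, 0.0)
    nu = moments_normalized(moments_central(masked))
    assert ours == pytest.approx(nu[2, 0] + nu[0, 2], rel=1e-8)


# ---------------------------------------------------------------------------
# Scale behaviour and invariances
# ---------------------------------------------------------------------------

@given(k=st.floats(0.1, 50), seed=st.integers(0, 100))
@settings(max_examples=40, deadline=None)
def test_scale_behaviour_under_intensity_multiplication(k, seed):
    """Ratio statistics and the CV are invariant under multiplying all
    pixels by k; the brightest-20% mean and the bright-minus-rest
    difference scale linearly; eta1 scales as 1/k (intensity appears
    once in the numerator moments, squared in the normalization)."""
    rng = np.random.default_rng(seed)
    img = random_cell(rng, shape=(10, 10))
    if img.n_cell_pixels < 10:
        return
    scaled = CellImage(fluor=img.fluor * k, cell_mask=img.cell_mask)
    cfg = MetricConfig()
    for fn in (sunnaker, logg, granados, bodvard):
        assert fn(scaled, cfg).value == pytest.approx(fn(img, cfg).value, rel=1e-9)
    assert petrenko(scaled, cfg).value == pytest.approx(
        k * petrenko(img, cfg).value, rel=1e-9
    )
    assert caihao(scaled, cfg).value == pytest.approx(
        k * caihao(img, cfg).value, rel=1e-9
    )
    assert hu_eta1(scaled).value == pytest.approx(
        hu_eta1(img).value / k, rel=1e-9
    )


def test_ground_truth_scale_invariance(hand_cell):
    img, nuc = hand_cell
    scaled = CellImage(fluor=img.fluor * 13.0, cell_mask=img.cell_mask)
    assert ground_truth_localization(scaled, nuc).value == pytest.approx(
        ground_truth_localization(img, nuc).value, rel=1e-12
    )


def test_caihao_translation_invariance(rng):
    img = random_cell(rng, shape=(10, 10))
    shifted = CellImage(fluor=np.where(img.cell_mask, img.fluor + 17.0, 0.0),
                        cell_mask=img.cell_mask)
    assert caihao(shifted).value == pytest.approx(caihao(img).value, rel=1e-9)


@pytest.mark.parametrize("seed", range(10))
def test_eta1_translation_and_rotation_invariance(seed):
    rng = np.random.default_rng(seed)
    img = random_cell(rng, shape=(9, 9))
    base = hu_eta1(img).value
    # embed in a larger frame and translate by integer offsets
    for dy, dx in [(3, 0), (0, 5), (2, 4)]:
        fluor = np.zeros((20, 20))
        mask = np.zeros((20, 20), bool)
        fluor[dy : dy + 9, dx : dx + 9] = img.fluor
        mask[dy : dy + 9, dx : dx + 9] = img.cell_mask
        assert hu_eta1(CellImage(fluor=fluor, cell_mask=mask)).value == pytest.approx(
            base, rel=1e-12
        )
    for k in (1, 2, 3):  # 90-degree rotations
        rot = CellImage(
            fluor=np.rot90(img.fluor, k).copy(),
            cell_mask=np.rot90(img.cell_mask, k).copy(),
        )
        assert hu_eta1(rot).value == pytest.approx(base, rel=1e-12)


def test_eta1_spatial_scale_invariance_on_upsampled_image(rng):
    """Block-upsampling the image (a discrete spatial rescale) leaves the
    normalized moment unchanged up to discretization."""
    img = random_cell(rng, shape=(8, 8))
    up = CellImage(
        fluor=np.kron(img.fluor, np.ones((4, 4))),
        cell_mask=np.kron(img.cell_mask, np.ones((4, 4))).astype(bool),
    )
    assert hu_eta1(up).value == pytest.approx(hu_eta1(img).value, rel=0.05)


def test_monotonicity_in_nuclear_contrast():
    """On noise-free two-level cells, the ratio/difference statistics all
    increase strictly with nuclear enrichment."""
    from nucloc import NucleusMask, make_scene
    from nucloc.synthetic_cells import SceneParams

    tracked = {"ground_truth": [], "logg": [], "granados": [], "caihao": []}
    for target in (1.2, 1.6, 2.0, 2.4):
        scene = make_scene(
            SceneParams(
                target_loc=target, shot_noise=False, read_noise_sd=0, psf_sigma=0
            )
        )
        values, _ = quantify_all(scene.image, NucleusMask(scene.true_nucleus))
        for tag in tracked:
            tracked[tag].append(values[tag].value)
    for tag, series in tracked.items():
        assert np.all(np.diff(series) > 0), tag


def test_quantify_all_without_nucleus(rng):
    img = random_cell(rng, shape=(12, 12))
    values, failures = quantify_all(img)
    assert "ground_truth" not in values
    assert len(values) == 7 and failures == {}


def test_quantify_all_records_failures_not_aborts():
    img = cell_from_values([1.0, 2.0, 3.0])  # too few pixels for top-5 stats
    values, failures = quantify_all(img)
    assert "granados" in failures and "caihao" in failures
    assert "petrenko" in values  # the applicable ones still succeed
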