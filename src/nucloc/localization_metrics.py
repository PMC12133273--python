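"""Nuclear-localization statistics computed from single-cell images.

The reference statistic is the ground-truth localization

    l = <I_nuc> / <I_cell>

the ratio of the mean fluorescence over the nuclear pixels to the mean
over all cell pixels (nucleus included).  ``l = 1`` means the tagged
protein is uniformly distributed; larger values mean nuclear enrichment.
Computing it requires a nucleus mask from an independent nuclear marker.

Seven published proxy statistics estimate localization from the spatial
inhomogeneity of the protein's own fluorescence, without a marker:

========== ==========================================================
petrenko   mean intensity of the brightest 20% of pixels
sunnaker   coefficient of variation of the pixel intensities
logg       mean of the 3 brightest pixels / mean of the rest
granados   mean of the 5 brightest pixels / median of the rest
bodvard    median of a Gaussian-smoothed disc centred on the brightest
           smoothed pixel / median of the remaining smoothed pixels
caihao     mean of the 5 brightest pixels minus mean of the rest
hu1        first Hu invariant moment eta1 = eta20 + eta02, treating
           fluorescence as mass
========== ==========================================================

All statistics operate on in-mask pixels only.  "Remaining pixels"
always means in-mask pixels not in the selected bright set.  Top-k
selection breaks intensity ties by row-major pixel index, so results are
deterministic.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .data_model import CellImage, LocalizationValue, NucleusMask


@dataclass
class MetricConfig:
    """Tunable parameters of the proxy statistics.

    ``petrenko_fraction`` is the brightest-pixel fraction (count is
    ``ceil(fraction * N)`` so tiny cells keep at least one pixel);
    ``logg_k``/``granados_k``/``caihao_k`` are the bright-pixel counts of
    the respective ratios; ``bodvard_sigma``/``bodvard_radius`` set the
    Gaussian smoothing (px) and disc radius (px); ``cv_ddof`` selects the
    population (0) or sample (1) standard deviation for the coefficient
    of variation.
    """

    petrenko_fraction: float = 0.20
    logg_k: int = 3
    granados_k: int = 5
    caihao_k: int = 5
    bodvard_sigma: float = 1.0
    bodvard_radius: int = 3
    cv_ddof: int = 0

    def __post_init__(self) -> None:
        if not (0 < self.petrenko_fraction <= 1):
            raise ValueError("petrenko_fraction must be in (0, 1]")
        for name in ("logg_k", "granados_k", "caihao_k", "bodvard_radius"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be a positive integer")
        if self.bodvard_sigma <= 0:
            raise ValueError("bodvard_sigma must be positive")
        if self.cv_ddof not in (0, 1):
            raise ValueError("cv_ddof must be 0 or 1")


DEFAULT_METRIC_CONFIG = MetricConfig()


def _sorted_cell_pixels(img: CellImage) -> np.ndarray:
    """In-mask fluor pixels sorted descending by (intensity, row-major index)."""
    flat_idx = np.flatnonzero(img.cell_mask.ravel())
    vals = img.fluor.ravel()[flat_idx]
    order = np.lexsort((flat_idx, -vals))
    return vals[order]


def _split_top_rest(img: CellImage, k: int) -> tuple[np.ndarray, np.ndarray]:
    vals = _sorted_cell_pixels(img)
    if vals.size <= k:
        raise ValueError(f"need more than {k} cell pixels, have {vals.size}")
    return vals[:k], vals[k:]


# ---------------------------------------------------------------------------
# Ground truth
# ---------------------------------------------------------------------------

def ground_truth_localization(img: CellImage, nuc: NucleusMask) -> LocalizationValue:
    """l = mean fluorescence in the nucleus / mean over the whole cell."""
    if nuc.is_empty:
        raise ValueError("nucleus mask is empty")
    if (nuc.mask & ~img.cell_mask).any():
        raise ValueError("nucleus mask extends outside the cell mask")
    cell_mean = img.fluor[img.cell_mask].mean()
    if cell_mean <= 0:
        raise ValueError("mean cell intensity must be positive")
    nuc_mean = img.fluor[nuc.mask].mean()
    return LocalizationValue(value=float(nuc_mean / cell_mean), method_tag="ground_truth")


def nuclear_concentration(loc: LocalizationValue, mean_cell_intensity: float) -> float:
    """Recover the nuclear concentration <I_nuc> as l * <I_cell>.

    Only localization-scale estimates (ground truth or the trained
    network) can be converted; the proxy statistics live on their own
    scales.
    """
    if loc.method_tag not in ("ground_truth", "cnn"):
        raise ValueError(
            "only ground_truth or cnn values are on the localization scale"
        )
    if mean_cell_intensity <= 0:
        raise ValueError("mean cell intensity must be positive")
    return loc.value * mean_cell_intensity


# ---------------------------------------------------------------------------
# Proxy statistics
# ---------------------------------------------------------------------------

def petrenko(img: CellImage, cfg: MetricConfig = DEFAULT_METRIC_CONFIG) -> LocalizationValue:
    vals = _sorted_cell_pixels(img)
    k = math.ceil(cfg.petrenko_fraction * vals.size)
    return LocalizationValue(value=float(vals[:k].mean()), method_tag="petrenko")


def sunnaker(img: CellImage, cfg: MetricConfig = DEFAULT_METRIC_CONFIG) -> LocalizationValue:
    vals = img.cell_pixels()
    if vals.size < 2:
        raise ValueError("need at least 2 cell pixels")
    mean = vals.mean()
    if mean <= 0:
        raise ValueError("mean cell intensity must be positive")
    return LocalizationValue(
        value=float(vals.std(ddof=cfg.cv_ddof) / mean), method_tag="sunnaker"
    )


def logg(img: CellImage, cfg: MetricConfig = DEFAULT_METRIC_CONFIG) -> LocalizationValue:
    top, rest = _split_top_rest(img, cfg.logg_k)
    rest_mean = rest.mean()
    if rest_mean <= 0:
        raise ValueError("mean of remaining pixels must be positive")
    return LocalizationValue(value=float(top.mean() / rest_mean), method_tag="logg")


def granados(img: CellImage, cfg: MetricConfig = DEFAULT_METRIC_CONFIG) -> LocalizationValue:
    top, rest = _split_top_rest(img, cfg.granados_k)
    rest_median = np.median(rest)
    if rest_median <= 0:
        raise ValueError("median of remaining pixels must be positive")
    return LocalizationValue(
        value=float(top.mean() / rest_median), method_tag="granados"
    )


def caihao(img: CellImage, cfg: MetricConfig = DEFAULT_METRIC_CONFIG) -> LocalizationValue:
    top, rest = _split_top_rest(img, cfg.caihao_k)
    return LocalizationValue(
        value=float(top.mean() - rest.mean()), method_tag="caihao"
    )


def bodvard(img: CellImage, cfg: MetricConfig = DEFAULT_METRIC_CONFIG) -> LocalizationValue:
    """Disc-median to background-median ratio on the smoothed image.

    The in-mask image is Gaussian-smoothed (mask-normalized so pixels
    outside the cell do not dilute the smoothing), the brightest smoothed
    in-mask pixel located, and the median of smoothed pixels within
    ``bodvard_radius`` of it (intersected with the cell mask) divided by
    the median of the remaining in-mask smoothed pixels.
    """
    mask = img.cell_mask
    weights = ndimage.gaussian_filter(mask.astype(float), cfg.bodvard_sigma)
    smoothed = ndimage.gaussian_filter(img.fluor * mask, cfg.bodvard_sigma)
    with np.errstate(invalid="ignore", divide="ignore"):
        smoothed = np.where(weights > 0, smoothed / weights, 0.0)

    in_vals = smoothed[mask]
    peak_flat = np.flatnonzero(mask.ravel())[np.argmax(in_vals)]
    py, px = np.unravel_index(peak_flat, mask.shape)
    yy, xx = np.mgrid[0 : mask.shape[0], 0 : mask.shape[1]]
    disc = ((yy - py) ** 2 + (xx - px) ** 2) <= cfg.bodvard_radius**2
    disc &= mask
    rest = mask & ~disc
    if not disc.any():
        raise ValueError("disc empty after intersection with the cell mask")
    if not rest.any():
        raise ValueError("no remaining pixels outside the disc")
    rest_median = np.median(smoothed[rest])
    if rest_median <= 0:
        raise ValueError("median of remaining pixels must be positive")
    return LocalizationValue(
        value=float(np.median(smoothed[disc]) / rest_median), method_tag="bodvard"
    )


def hu_eta1(img: CellImage) -> LocalizationValue:
    """First Hu invariant moment of the masked fluorescence distribution.

    eta1 = eta20 + eta02 with eta_pq = mu_pq / mu00^(1 + (p+q)/2), where
    mu_pq are intensity-weighted central moments over in-mask pixels
    (pixels outside the mask carry zero mass).  Invariant to translation
    and rotation of the cell; a tight nuclear spot gives a small value,
    a spread-out distribution a large one.
    """
    w = np.where(img.cell_mask, img.fluor, 0.0)
    m00 = w.sum()
    if m00 <= 0:
        raise ValueError("total in-mask intensity must be positive")
    yy, xx = np.mgrid[0 : w.shape[0], 0 : w.shape[1]]
    cy = (w * yy).sum() / m00
    cx = (w * xx).sum() / m00
    mu20 = (w * (yy - cy) ** 2).sum()
    mu02 = (w * (xx - cx) ** 2).sum()
    eta1 = (mu20 + mu02) / m00**2
    return LocalizationValue(value=float(eta1), method_tag="hu1")


#: Proxy statistics applicable without a nucleus mask, in a fixed order.
PROXY_METHODS = {
    "petrenko": petrenko,
    "sunnaker": sunnaker,
    "logg": logg,
    "granados": granados,
    "bodvard": bodvard,
    "caihao": caihao,
    "hu1": lambda img, cfg: hu_eta1(img),
}


def quantify_all(
    img: CellImage,
    nuc: NucleusMask | None = None,
    cfg: MetricConfig = DEFAULT_METRIC_CONFIG,
) -> tuple[dict[str, LocalizationValue], dict[str, str]]:
    """Apply every applicable statistic to one cell.

    Returns ``(values, failures)``: values keyed by method tag, and any
    per-method error messages.  Ground truth is included iff a nucleus
    mask is provided.  A failing method is recorded, never a global abort.
    """
    values: dict[str, LocalizationValue] = {}
    failures: dict[str, str] = {}
    if nuc is not None:
        try:
            values["ground_truth"] = ground_truth_localization(img, nuc)
        except ValueError as exc:
            failures["ground_truth"] = str(exc)
    for tag, fn in PROXY_METHODS.items():
        try:
            values[tag] = fn(img, cfg)
        except ValueError as exc:
            failures[tag] = str(exc)
    return values, failures
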