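"""Synthetic single-cell scenes with known nuclear localization.

Emulates trapped-yeast single-cell crops: an elliptical cell (~8–16 px
semi-axes at 60x magnification), a disc nucleus, and three channels —
tagged-protein fluorescence, bright-field, and a nuclear marker.  The
fluorescence field is piecewise constant (uniform cytoplasm, uniform
brighter nucleus) with the nucleus level solved analytically so that the
noise-free image realizes a requested localization ``l*`` exactly.
Optional PSF blur, Poisson shot noise, and Gaussian read noise make
scenes realistic; the realized localization of the *noise-free* field is
recorded before noise, so every downstream method can be scored against
a known truth.

Time series emulate a glucose-switch experiment: a baseline level before
the switch, exponential relaxation to a new level after it, and optional
telegraph-process bursts that transiently move the factor to the
stimulated level before the switch (the spontaneous nuclear entry/exit
seen for stress factors in unstressed cells).
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import ndimage

from .data_model import CellImage, CellTimeSeries

# Bright-field rendering constants (arbitrary units).
_BRIGHT_BASE = 100.0
_BRIGHT_RING = -35.0  # dark cell outline
_BRIGHT_NUCLEUS = -8.0  # faint nucleus shading
_BRIGHT_NOISE_SD = 2.0


@dataclass
class SceneParams:
    """Parameters of one synthetic cell.

    Intensities are in photons per pixel.  ``target_loc`` is the nuclear
    localization ``l*`` the noise-free fluorescence field must realize
    (1 = uniform; values in [1, 3] cover the physiological range).
    ``marker_contrast`` is the nucleus-to-background intensity ratio of
    the nuclear-marker channel, bimodal by construction.
    """

    image_size: tuple[int, int] = (64, 64)
    cell_axes: tuple[float, float] = (12.0, 9.0)  # semi-axes (a, b) px
    nucleus_radius: float = 3.0
    nucleus_offset: tuple[float, float] = (0.0, 0.0)  # (dy, dx) px
    target_loc: float = 1.5
    cyto_intensity: float = 100.0
    marker_contrast: float = 5.0
    marker_background: float = 30.0
    psf_sigma: float = 1.0
    read_noise_sd: float = 5.0
    shot_noise: bool = True
    seed: int = 0
    n_z_planes: int = 1  # >1 renders defocused planes and max-projects

    def __post_init__(self) -> None:
        a, b = self.cell_axes
        dy, dx = self.nucleus_offset
        if a <= 0 or b <= 0 or self.nucleus_radius <= 0:
            raise ValueError("cell axes and nucleus radius must be positive")
        r = self.nucleus_radius
        # nucleus fully inside the cell ellipse (conservative check)
        if a - r <= 0 or b - r <= 0 or (dy / (a - r)) ** 2 + (dx / (b - r)) ** 2 > 1:
            raise ValueError("nucleus not fully inside the cell")
        if self.target_loc < 1:
            raise ValueError("target_loc must be >= 1")
        if self.cyto_intensity <= 0:
            raise ValueError("cyto_intensity must be positive")


@dataclass
class SyntheticScene:
    """A rendered cell with its ground truth.

    ``true_loc`` is the localization realized by the noise-free
    (pre-noise, post-blur) fluorescence field; with noise disabled,
    computing the ground-truth statistic on ``image`` with
    ``true_nucleus`` reproduces it exactly.
    """

    image: CellImage
    true_nucleus: np.ndarray
    true_loc: float
    params: SceneParams


@dataclass
class DynamicsParams:
    """Time-series dynamics for a glucose-switch experiment.

    ``pre_loc``/``post_loc`` are the localization levels before/after the
    environment switch at frame ``switch_index``; after the switch the
    level relaxes exponentially at ``response_rate`` per frame.
    ``burst_rate`` (per-frame entry rate) and ``burst_duration`` (mean
    frames per burst) drive a two-state telegraph process that lifts
    pre-switch frames to the stimulated level, emulating spontaneous
    nuclear entry/exit.  ``direction='exit'`` models factors that leave
    the nucleus on stimulation: the high level is pre-switch.

    Three slow processes emulate real time-lapse acquisition:
    ``expression_cv`` (lognormal frame-to-frame fluctuation of the
    cell's overall intensity), ``bleach_rate`` (fractional photobleach
    decay per frame), and ``growth_rate`` (fractional growth of the
    cell axes per frame — cells grow over hours of imaging).  The
    localization itself is intensity-scale free, but statistics that
    track raw brightness are exposed to these drifts, as on real data.
    """

    n_timepoints: int = 60
    switch_index: int = 30
    pre_loc: float = 1.2
    post_loc: float = 2.2
    response_rate: float = 0.5
    burst_rate: float = 0.0
    burst_duration: float = 2.0
    direction: str = "enter"
    expression_cv: float = 0.10
    bleach_rate: float = 0.003
    growth_rate: float = 0.005

    def __post_init__(self) -> None:
        if self.direction not in ("enter", "exit"):
            raise ValueError("direction must be 'enter' or 'exit'")
        if not (0 <= self.switch_index < self.n_timepoints):
            raise ValueError("switch_index out of range")
        if min(self.response_rate, self.burst_rate, self.burst_duration) < 0:
            raise ValueError("rates must be >= 0")
        if min(self.expression_cv, self.bleach_rate, self.growth_rate) < 0:
            raise ValueError("drift parameters must be >= 0")


# ---------------------------------------------------------------------------
# Geometry and intensity solution
# ---------------------------------------------------------------------------

def _masks(p: SceneParams) -> tuple[np.ndarray, np.ndarray]:
    h, w = p.image_size
    cy, cx = (h - 1) / 2.0, (w - 1) / 2.0
    yy, xx = np.mgrid[0:h, 0:w]
    a, b = p.cell_axes
    cell = ((yy - cy) / a) ** 2 + ((xx - cx) / b) ** 2 <= 1.0
    dy, dx = p.nucleus_offset
    nuc = (yy - cy - dy) ** 2 + (xx - cx - dx) ** 2 <= p.nucleus_radius**2
    return cell, nuc & cell


def solve_nucleus_level(
    target_loc: float, n_nuc_px: int, n_cell_px: int, cyto_intensity: float
) -> float:
    """Nucleus intensity n* realizing ``target_loc`` for given pixel counts.

    Inverts l = n / ((n*n_nuc + c*(n_cell - n_nuc)) / n_cell) for n.
    Requires 1 <= target_loc < n_cell_px / n_nuc_px (larger values would
    need negative cytoplasm).
    """
    if n_nuc_px < 1 or n_cell_px <= n_nuc_px:
        raise ValueError("need 1 <= n_nuc_px < n_cell_px")
    max_loc = n_cell_px / n_nuc_px
    if not (1 <= target_loc < max_loc):
        raise ValueError(
            f"target_loc must lie in [1, {max_loc:.3f}) for this geometry"
        )
    return (
        target_loc
        * cyto_intensity
        * (n_cell_px - n_nuc_px)
        / (n_cell_px - target_loc * n_nuc_px)
    )


def _blur(field: np.ndarray, p: SceneParams) -> np.ndarray:
    """PSF blur; with several Z planes, defocused blurs are max-projected."""
    if p.n_z_planes > 1:
        planes = []
        for z in range(p.n_z_planes):
            dz = abs(z - (p.n_z_planes - 1) / 2.0)
            sigma = p.psf_sigma * (1.0 + 0.5 * dz)
            planes.append(ndimage.gaussian_filter(field, sigma))
        return np.max(planes, axis=0)
    if p.psf_sigma > 0:
        return ndimage.gaussian_filter(field, p.psf_sigma)
    return field.copy()


def _render_channel(
    field: np.ndarray, p: SceneParams, rng: np.random.Generator
) -> np.ndarray:
    """Apply PSF blur, shot noise and read noise to a noise-free field."""
    out = _blur(field, p)
    if p.shot_noise:
        out = rng.poisson(np.clip(out, 0, None)).astype(float)
    if p.read_noise_sd > 0:
        out = out + rng.normal(0.0, p.read_noise_sd, out.shape)
    return np.clip(out, 0.0, None)


def _unblurred_field(p: SceneParams, cell: np.ndarray, nuc: np.ndarray) -> np.ndarray:
    n_star = solve_nucleus_level(
        p.target_loc, int(nuc.sum()), int(cell.sum()), p.cyto_intensity
    )
    field = np.where(cell, p.cyto_intensity, 0.0)
    field[nuc] = n_star
    return field


def make_scene(p: SceneParams) -> SyntheticScene:
    """Render one synthetic cell.

    The noise-free fluorescence field is uniform cytoplasm plus a uniform
    nucleus at the analytically solved level, then optionally PSF-blurred;
    its realized localization is recorded as ``true_loc`` before noise.
    The marker channel is a bright nucleus on a dim cell (bimodal by
    construction); the bright-field channel is a dark cell-edge ring with
    faint nucleus shading.
    """
    cell, nuc = _masks(p)
    rng = np.random.default_rng(p.seed)

    raw = _unblurred_field(p, cell, nuc)
    noise_free = _blur(raw, p)
    true_loc = float(noise_free[nuc].mean() / noise_free[cell].mean())

    if p.shot_noise or p.read_noise_sd > 0:
        fluor = _render_channel(raw, p, rng)
    else:
        fluor = noise_free

    marker_field = np.where(cell, p.marker_background, 0.0)
    marker_field[nuc] = p.marker_background * p.marker_contrast
    marker = _render_channel(marker_field, p, rng)

    ring = cell & ~ndimage.binary_erosion(cell, iterations=2)
    bright_field = np.full(p.image_size, _BRIGHT_BASE)
    bright_field[ring] += _BRIGHT_RING
    bright_field[nuc] += _BRIGHT_NUCLEUS
    bright = ndimage.gaussian_filter(bright_field, max(p.psf_sigma, 0.5))
    bright = np.clip(
        bright + rng.normal(0.0, _BRIGHT_NOISE_SD, bright.shape), 0.0, None
    )

    img = CellImage(
        fluor=fluor, bright=bright, marker=marker, cell_mask=cell, cell_id=p.seed
    )
    return SyntheticScene(image=img, true_nucleus=nuc, true_loc=true_loc, params=p)


def _unblurred_field(p: SceneParams, cell: np.ndarray, nuc: np.ndarray) -> np.ndarray:
    n_star = solve_nucleus_level(
        p.target_loc, int(nuc.sum()), int(cell.sum()), p.cyto_intensity
    )
    field = np.where(cell, p.cyto_intensity, 0.0)
    field[nuc] = n_star
    return field


def make_timeseries(p: SceneParams, d: DynamicsParams) -> CellTimeSeries:
    """Render a glucose-switch time series for one cell.

    The noise-free target localization follows a step-plus-relaxation
    profile: ``pre`` before the switch, exponential relaxation from
    ``pre`` toward ``post`` after it, with optional telegraph bursts to
    the stimulated level before the switch.  Each frame is rendered by
    :func:`make_scene` with a per-frame seed derived from the master
    seed, and the series carries the switch index.
    """
    pre, post = d.pre_loc, d.post_loc
    if d.direction == "exit" and post > pre:
        pre, post = post, pre
    stim_level = max(pre, post) if d.direction == "enter" else min(pre, post)

    ss = np.random.SeedSequence(p.seed)
    frame_seeds = [int(c.generate_state(1)[0] % 2**31) for c in ss.spawn(d.n_timepoints + 1)]
    rng = np.random.default_rng(frame_seeds[-1])

    # telegraph occupancy: on-rate burst_rate, off-rate 1/burst_duration
    kon = d.burst_rate
    koff = 1.0 / d.burst_duration if d.burst_duration > 0 else np.inf
    p_on = kon / (kon + koff) if kon > 0 else 0.0
    state = rng.random() < p_on

    loc = np.empty(d.n_timepoints)
    intensity = np.empty(d.n_timepoints)
    for t in range(d.n_timepoints):
        if t < d.switch_index:
            base = pre
            if kon > 0:
                if state:
                    base = stim_level
                # per-frame transition for the next frame
                state = (
                    rng.random() >= min(koff, 1.0)
                    if state
                    else rng.random() < min(kon, 1.0)
                )
            loc[t] = base
        else:
            dt = t - d.switch_index
            decay = 1.0 if dt == 0 else float(np.exp(-d.response_rate * dt))
            loc[t] = post + (pre - post) * decay
        # photobleach decay plus mean-one lognormal expression fluctuation
        flicker = (
            rng.lognormal(-0.5 * d.expression_cv**2, d.expression_cv)
            if d.expression_cv > 0
            else 1.0
        )
        intensity[t] = p.cyto_intensity * np.exp(-d.bleach_rate * t) * flicker

    h, w = p.image_size
    max_axis = min(h, w) / 2.0 - 2.0
    scenes = []
    for t in range(d.n_timepoints):
        grow = (1.0 + d.growth_rate) ** t
        axes = (
            min(p.cell_axes[0] * grow, max_axis),
            min(p.cell_axes[1] * grow, max_axis),
        )
        pt = replace(
            p,
            target_loc=float(loc[t]),
            cyto_intensity=float(intensity[t]),
            cell_axes=axes,
            seed=frame_seeds[t],
        )
        scene = make_scene(pt)
        scene.image.timepoint = t
        scene.image.cell_id = p.seed
        scenes.append(scene)
    return CellTimeSeries(
        cell_id=p.seed,
        timepoints=list(range(d.n_timepoints)),
        values=scenes,
        switch_index=d.switch_index,
    )


def make_dataset(
    n_cells: int,
    loc_range: tuple[float, float] = (1.0, 3.0),
    noise_grid: Optional[Sequence[dict]] = None,
    seed: int = 0,
    expression_sigma: float = 0.25,
) -> tuple[list[SyntheticScene], pd.DataFrame]:
    """Generate a population of cells with jittered geometry.

    ``l*`` is sampled uniformly over ``loc_range``; cell semi-axes,
    nucleus radius and offset are jittered within the trapped-yeast
    range, and each cell's overall expression level is drawn lognormally
    (``expression_sigma`` in log space) around the default intensity, as
    protein abundance varies severalfold between cells.  ``noise_grid``
    optionally cycles parameter overrides (dicts of :class:`SceneParams`
    fields) across cells.  Returns the scenes and a truth table
    (cell_id, true_loc, geometry, expression) ready for CSV export.
    Fully reproducible from ``seed``.
    """
    if n_cells < 1:
        raise ValueError("n_cells must be >= 1")
    lo, hi = loc_range
    if hi < lo:
        raise ValueError("empty localization range")
    rng = np.random.default_rng(seed)
    ss = np.random.SeedSequence(seed)
    scene_seeds = [int(c.generate_state(1)[0] % 2**31) for c in ss.spawn(n_cells)]

    scenes: list[SyntheticScene] = []
    rows = []
    for i in range(n_cells):
        target = float(rng.uniform(lo, hi))
        # spans newborn through grown/old trapped cells, the size range a
        # multi-hour time-lapse produces
        a = float(rng.uniform(9.0, 17.0))
        b = float(rng.uniform(7.0, 13.0))
        r = float(rng.uniform(2.5, 3.8))
        max_off = 0.5 * min(a, b) - r
        if max_off > 0:
            dy = float(rng.uniform(-max_off, max_off))
            dx = float(rng.uniform(-max_off, max_off))
        else:
            dy = dx = 0.0
        expression = float(
            rng.lognormal(-0.5 * expression_sigma**2, expression_sigma)
            if expression_sigma > 0
            else 1.0
        )
        overrides = (
            dict(noise_grid[i % len(noise_grid)]) if noise_grid else {}
        )
        fields = SceneParams.__dataclass_fields__
        overrides.setdefault("cyto_intensity", fields["cyto_intensity"].default * expression)
        p = SceneParams(
            cell_axes=(a, b),
            nucleus_radius=r,
            nucleus_offset=(dy, dx),
            target_loc=target,
            seed=scene_seeds[i],
            **overrides,
        )
        scene = make_scene(p)
        scene.image.cell_id = i
        scenes.append(scene)
        rows.append(
            {
                "cell_id": i,
                "true_loc": scene.true_loc,
                "target_loc": target,
                "cell_a": a,
                "cell_b": b,
                "nucleus_radius": r,
                "cyto_intensity": p.cyto_intensity,
                "seed": scene_seeds[i],
            }
        )
    return scenes, pd.DataFrame(rows)
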