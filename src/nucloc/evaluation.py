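"""Method-comparison machinery for localization estimates.

The proxy statistics and the network live on incommensurate scales, so
comparisons use scale-free summaries:

* centred log2 ratios of prediction to ground truth, whose standard
  deviation and skewness measure a method's spread and asymmetry after
  removing its multiplicative bias;
* Pearson correlation and Kraskov-Stoegbauer-Grassberger (KSG)
  k-nearest-neighbour mutual information with the ground truth;
* per-timepoint and per-cell RMSE on min-max-normalized time series.

Some statistics run opposite to localization on real data (e.g. the
brightest-20% mean when expression falls as the factor enters the
nucleus); a per-method orientation can invert them before normalization
and shift them before log transforms.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy import stats
from scipy.spatial import cKDTree
from scipy.special import digamma

from .data_model import ClassBands


@dataclass
class MethodOrientation:
    """How to align one method's raw statistic with localization.

    ``invert`` negates the series before min-max normalization (for
    statistics that decrease with localization); ``positivity_shift`` is
    added before log transforms only (for statistics that can be
    non-positive).
    """

    method_tag: str
    invert: bool = False
    positivity_shift: float = 0.0


#: Display-convention defaults: the disc-median ratio can dip below zero
#: after background subtraction, so it is shifted by +1 before logs.
DEFAULT_ORIENTATIONS = {
    "bodvard": MethodOrientation("bodvard", positivity_shift=1.0),
}


def orientation_for(method_tag: str) -> MethodOrientation:
    return DEFAULT_ORIENTATIONS.get(method_tag, MethodOrientation(method_tag))


def calibrate_orientation(
    method_tag: str, preds, truths, shift: float | None = None
) -> MethodOrientation:
    """Set ``invert`` from the sign of the correlation on a calibration set.

    A statistic whose Pearson correlation with ground truth is negative
    on the calibration data is marked inverted; the positivity shift is
    kept from the registry unless overridden.
    """
    base = orientation_for(method_tag)
    r = stats.pearsonr(np.asarray(preds, float), np.asarray(truths, float))[0]
    return replace(
        base,
        invert=bool(r < 0),
        positivity_shift=base.positivity_shift if shift is None else shift,
    )


@dataclass
class ErrorSummary:
    """Per-method error statistics against the ground truth."""

    method_tag: str
    sd: float
    skewness: float
    pearson_r: float
    mutual_info: float  # nats
    rmse_by_timepoint: np.ndarray
    rmse_by_cell: np.ndarray

    def __post_init__(self) -> None:
        if self.sd < 0:
            raise ValueError("sd must be >= 0")


# ---------------------------------------------------------------------------
# Error transforms
# ---------------------------------------------------------------------------

def centred_log2_errors(preds, truths, orient: MethodOrientation | None = None):
    """log2(pred/truth) centred to zero mean across cells.

    The centring removes each method's multiplicative bias so that
    spread and asymmetry are comparable across methods.  The orientation
    shift is applied to predictions before the log; non-positive ratios
    are an error naming the offending cells.
    """
    p = np.asarray(preds, dtype=float)
    t = np.asarray(truths, dtype=float)
    if p.shape != t.shape:
        raise ValueError("predictions and truths differ in length")
    shift = orient.positivity_shift if orient is not None else 0.0
    p = p + shift
    bad = np.flatnonzero((p <= 0) | (t <= 0))
    if bad.size:
        raise ValueError(f"non-positive ratio at cells {bad.tolist()[:10]}")
    e = np.log2(p / t)
    return e - e.mean()


def minmax_normalize(series, orient: MethodOrientation | None = None):
    """Rescale a time series to [0, 1], negating first if inverted."""
    x = np.asarray(series, dtype=float)
    if orient is not None and orient.invert:
        x = -x
    lo, hi = x.min(), x.max()
    if hi == lo:
        raise ValueError("constant series has no min-max normalization")
    return (x - lo) / (hi - lo)


def rmse_by_timepoint(preds: np.ndarray, truths: np.ndarray) -> np.ndarray:
    """Per-timepoint RMSE over cells for (cells x time) matrices."""
    p = np.atleast_2d(np.asarray(preds, dtype=float))
    t = np.atleast_2d(np.asarray(truths, dtype=float))
    if p.shape != t.shape:
        raise ValueError("prediction and truth matrices differ in shape")
    return np.sqrt(np.mean((p - t) ** 2, axis=0))


def rmse_by_cell(preds: np.ndarray, truths: np.ndarray) -> np.ndarray:
    """Per-cell RMSE over timepoints for (cells x time) matrices."""
    p = np.atleast_2d(np.asarray(preds, dtype=float))
    t = np.atleast_2d(np.asarray(truths, dtype=float))
    if p.shape != t.shape:
        raise ValueError("prediction and truth matrices differ in shape")
    return np.sqrt(np.mean((p - t) ** 2, axis=1))


# ---------------------------------------------------------------------------
# Mutual information (KSG estimator)
# ---------------------------------------------------------------------------

def mutual_information_knn(x, y, k: int = 3) -> float:
    """KSG k-nearest-neighbour mutual information in nats (algorithm 1).

    MI = psi(k) + psi(N) - < psi(n_x + 1) + psi(n_y + 1) > where n_x and
    n_y count points strictly within the max-norm distance to the k-th
    joint-space neighbour.  Clipped at zero (the estimator can be
    slightly negative for independent data).
    """
    x = np.asarray(x, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    n = x.size
    if y.size != n:
        raise ValueError("x and y differ in length")
    if n < 20:
        raise ValueError("need at least 20 samples")
    if k < 1 or k >= n:
        raise ValueError("k must satisfy 1 <= k < N")

    joint = np.column_stack([x, y])
    tree = cKDTree(joint)
    # distance to the k-th neighbour in the max norm (query includes self)
    dist, _ = tree.query(joint, k=k + 1, p=np.inf)
    eps = dist[:, -1]

    xs = np.sort(x)
    ys = np.sort(y)
    # strict count: points with |x_j - x_i| < eps_i, minus the point itself
    nx = (
        np.searchsorted(xs, x + eps, side="left")
        - np.searchsorted(xs, x - eps, side="right")
    ) - 1
    ny = (
        np.searchsorted(ys, y + eps, side="left")
        - np.searchsorted(ys, y - eps, side="right")
    ) - 1
    mi = digamma(k) + digamma(n) - np.mean(digamma(nx + 1) + digamma(ny + 1))
    return float(max(mi, 0.0))


# ---------------------------------------------------------------------------
# Summaries and classification
# ---------------------------------------------------------------------------

def summarize_method(
    preds,
    truths,
    orient: MethodOrientation | None = None,
    k: int = 3,
    normalize_rmse: bool = True,
) -> ErrorSummary:
    """Assemble the full error summary for one method.

    ``preds`` and ``truths`` are (cells x time) matrices (1-D inputs are
    treated as single-timepoint columns).  Log-ratio spread/skewness,
    correlation and mutual information are computed on the flattened
    values; the RMSE families on per-cell min-max-normalized series by
    default (raw series with ``normalize_rmse=False``), since the methods
    live on incommensurate scales.
    """
    p = np.atleast_2d(np.asarray(preds, dtype=float))
    t = np.atleast_2d(np.asarray(truths, dtype=float))
    if p.shape != t.shape:
        raise ValueError("prediction and truth matrices differ in shape")
    orient = orient or MethodOrientation("ground_truth")

    flat_p, flat_t = p.ravel(), t.ravel()
    errors = centred_log2_errors(flat_p, flat_t, orient)
    sd = float(errors.std())
    skew = float(stats.skew(errors, bias=False)) if errors.size > 2 else 0.0
    if np.ptp(flat_p) == 0 or np.ptp(flat_t) == 0:
        r = 0.0
    else:
        r = float(stats.pearsonr(flat_p, flat_t)[0])
    mi = mutual_information_knn(flat_p, flat_t, k=k) if flat_p.size >= 20 else 0.0

    flat_series = any(np.ptp(row) == 0 for row in p) or any(
        np.ptp(row) == 0 for row in t
    )
    if normalize_rmse and p.shape[1] >= 2 and not flat_series:
        pn = np.stack([minmax_normalize(row, orient) for row in p])
        tn = np.stack([minmax_normalize(row) for row in t])
    else:  # constant series carry no dynamics; fall back to raw scales
        pn, tn = p, t
    return ErrorSummary(
        method_tag=orient.method_tag,
        sd=sd,
        skewness=skew,
        pearson_r=r,
        mutual_info=mi,
        rmse_by_timepoint=rmse_by_timepoint(pn, tn),
        rmse_by_cell=rmse_by_cell(pn, tn),
    )


def classify_cells(values, bands: ClassBands = ClassBands()) -> np.ndarray:
    """Label each localization estimate.

    ``artifact`` (<= low band: typically poorly segmented cells),
    ``cytoplasmic`` (between the bands), or ``nuclear`` (> high band).
    Boundary values sit with the lower class.
    """
    v = np.asarray(values, dtype=float)
    if not np.isfinite(v).all():
        raise ValueError("values must be finite")
    labels = np.where(
        v <= bands.low, "artifact", np.where(v <= bands.high, "cytoplasmic", "nuclear")
    )
    return labels


def timeseries_rmse_table(
    series_values: dict[str, np.ndarray],
    truths: np.ndarray,
    orientations: dict[str, MethodOrientation] | None = None,
) -> dict[str, float]:
    """Mean per-cell RMSE for several methods on one benchmark.

    ``series_values`` maps method tags to (cells x time) matrices;
    ``truths`` is the matching ground-truth matrix.  Series are
    min-max-normalized per cell (with each method's orientation) before
    the RMSE, and orientations default to calibration against the
    flattened ground truth.
    """
    truths = np.asarray(truths, dtype=float)
    out = {}
    for tag, mat in series_values.items():
        mat = np.asarray(mat, dtype=float)
        if orientations and tag in orientations:
            orient = orientations[tag]
        else:
            orient = calibrate_orientation(tag, mat.ravel(), truths.ravel())
        pn = np.stack([minmax_normalize(row, orient) for row in mat])
        tn = np.stack([minmax_normalize(row) for row in truths])
        out[tag] = float(rmse_by_cell(pn, tn).mean())
    return out
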