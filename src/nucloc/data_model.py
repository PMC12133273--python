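"""Domain types and on-disk I/O for single-cell localization analysis.

The unit of analysis is one segmented cell at one timepoint: a fluorescence
image of the tagged protein (max projection over Z), optionally a matching
bright-field projection and a nuclear-marker fluorescence image, plus a
binary cell mask.  All downstream quantification consumes these
:class:`CellImage` objects.

Conventions
-----------
* Arrays are row-major with 0-based pixel indices.
* Masks are full-frame boolean arrays, never bounding boxes.
* Pixels are promoted to ``float64`` on read; 16-bit unsigned and 32-bit
  float TIFF inputs are both accepted and the source bit depth is recorded.
* Channel order on disk is declared (argument or sidecar JSON), never
  inferred from pixel statistics.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger("nucloc")

#: Recognised channel names for on-disk stacks.
CHANNEL_NAMES = ("fluor", "bright", "marker")

#: Method tags a LocalizationValue may carry.
METHOD_TAGS = frozenset(
    {
        "ground_truth",
        "petrenko",
        "sunnaker",
        "logg",
        "granados",
        "bodvard",
        "caihao",
        "hu1",
        "cnn",
    }
)

#: Decimal precision used when writing measurement CSVs.
CSV_DECIMALS = 9


class FormatError(ValueError):
    """Raised when an on-disk stack or mask does not match the declared layout."""


class DegenerateImageError(ValueError):
    """Raised when an image admits no threshold (e.g. all pixels equal)."""


@dataclass
class CellImage:
    """Multi-channel pixel data for one cell at one timepoint.

    Parameters
    ----------
    fluor
        2-D array of non-negative fluorescence intensities (arbitrary
        units) for the tagged protein, max-projected over Z.
    cell_mask
        2-D boolean array, same shape as ``fluor``, true on cell pixels.
    bright, marker
        Optional 2-D arrays, same shape: bright-field projection and
        nuclear-marker fluorescence.
    cell_id
        Opaque identifier of the tracked cell.
    timepoint
        Integer frame index (5-minute frames in typical time-lapse data).
    source_depth
        Bit depth of the source pixels, recorded at read time.
    """

    fluor: np.ndarray
    cell_mask: np.ndarray
    bright: Optional[np.ndarray] = None
    marker: Optional[np.ndarray] = None
    cell_id: object = None
    timepoint: int = 0
    source_depth: Optional[str] = None

    def __post_init__(self) -> None:
        self.fluor = np.asarray(self.fluor, dtype=float)
        self.cell_mask = np.asarray(self.cell_mask, dtype=bool)
        if self.fluor.ndim != 2:
            raise ValueError("fluor must be 2-D")
        if self.cell_mask.shape != self.fluor.shape:
            raise ValueError("cell_mask shape differs from fluor shape")
        for name in ("bright", "marker"):
            arr = getattr(self, name)
            if arr is not None:
                arr = np.asarray(arr, dtype=float)
                if arr.shape != self.fluor.shape:
                    raise ValueError(f"{name} shape differs from fluor shape")
                setattr(self, name, arr)
        if not self.cell_mask.any():
            raise ValueError("cell_mask has no true pixel")
        if not np.isfinite(self.fluor).all() or (self.fluor < 0).any():
            raise ValueError("fluor values must be finite and non-negative")

    @property
    def n_cell_pixels(self) -> int:
        return int(self.cell_mask.sum())

    def cell_pixels(self, channel: str = "fluor") -> np.ndarray:
        """In-mask pixel values of ``channel`` as a 1-D array."""
        arr = getattr(self, channel)
        if arr is None:
            raise ValueError(f"channel {channel!r} not present")
        return arr[self.cell_mask]


@dataclass
class NucleusMask:
    """Binary mask of nuclear pixels within one cell.

    ``mask`` must be contained in the parent cell's mask.  An all-false
    mask is legal but must be explicitly flagged via :attr:`is_empty`.
    """

    mask: np.ndarray
    method_tag: str = "otsu"

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.mask.ndim != 2:
            raise ValueError("mask must be 2-D")

    @property
    def is_empty(self) -> bool:
        return not self.mask.any()

    @property
    def n_pixels(self) -> int:
        return int(self.mask.sum())


@dataclass(frozen=True)
class LocalizationValue:
    """A scalar quantification of nuclear localization.

    ``method_tag`` names the producing method; ``ground_truth`` values are
    the nuclear-to-cell mean-intensity ratio and are strictly positive.
    """

    value: float
    method_tag: str

    def __post_init__(self) -> None:
        if self.method_tag not in METHOD_TAGS:
            raise ValueError(f"unknown method_tag {self.method_tag!r}")
        if not np.isfinite(self.value):
            raise ValueError("value must be finite")
        if self.method_tag == "ground_truth" and self.value <= 0:
            raise ValueError("ground-truth localization must be positive")


@dataclass(frozen=True)
class ClassBands:
    """Localization bands separating segmentation artifacts, cytoplasmic
    and nuclear cells.

    Cells below ``low`` are treated as poorly segmented; between ``low``
    and ``high`` as predominantly cytoplasmic; above ``high`` as
    predominantly nuclear.
    """

    low: float = 1.15
    high: float = 1.65

    def __post_init__(self) -> None:
        if not (0 < self.low < self.high):
            raise ValueError("bands must satisfy 0 < low < high")


@dataclass
class CellTimeSeries:
    """Ordered per-timepoint observations for one tracked cell.

    ``values`` holds either :class:`LocalizationValue` objects or raw
    :class:`CellImage` frames, one per entry of ``timepoints``.
    ``switch_index`` marks the frame at which the environment changed
    (e.g. a glucose drop), if any.
    """

    cell_id: object
    timepoints: Sequence[int]
    values: Sequence[object]
    switch_index: Optional[int] = None

    def __post_init__(self) -> None:
        tps = np.asarray(self.timepoints)
        if len(tps) != len(self.values):
            raise ValueError("values and timepoints differ in length")
        if len(tps) > 1 and not (np.diff(tps) > 0).all():
            raise ValueError("timepoints must be strictly increasing")
        if self.switch_index is not None and not (
            0 <= self.switch_index < len(tps)
        ):
            raise ValueError("switch_index out of range")

    def __len__(self) -> int:
        return len(self.timepoints)


# ---------------------------------------------------------------------------
# On-disk I/O
# ---------------------------------------------------------------------------

def _load_sidecar_channels(path: Path) -> Optional[Sequence[str]]:
    sidecar = path.with_suffix(path.suffix + ".json")
    if sidecar.exists():
        meta = json.loads(sidecar.read_text())
        return meta.get("channels")
    return None


def _record_depth(arr: np.ndarray) -> str:
    return str(arr.dtype)


def _to_tcyx(stack: np.ndarray, n_channels: int) -> np.ndarray:
    """Coerce a TIFF page stack to (T, C, Y, X), max-projecting any Z axis.

    Accepted layouts: (Y, X), (C, Y, X), (T, C, Y, X) and (T, C, Z, Y, X);
    the Z axis, when present, is collapsed by pixelwise maximum.
    """
    if stack.ndim == 2:
        stack = stack[None, None]
    elif stack.ndim == 3:
        if stack.shape[0] % n_channels:
            raise FormatError(
                f"page count {stack.shape[0]} not a multiple of the "
                f"{n_channels} declared channels"
            )
        t = stack.shape[0] // n_channels
        stack = stack.reshape(t, n_channels, *stack.shape[1:])
    elif stack.ndim == 4:
        if stack.shape[1] != n_channels:
            raise FormatError(
                f"axis 1 has {stack.shape[1]} channels, expected {n_channels}"
            )
    elif stack.ndim == 5:
        if stack.shape[1] != n_channels:
            raise FormatError(
                f"axis 1 has {stack.shape[1]} channels, expected {n_channels}"
            )
        stack = stack.max(axis=2)  # max projection over Z
    else:
        raise FormatError(f"unsupported stack dimensionality {stack.ndim}")
    return stack


def read_cell_stack(
    path,
    masks_path,
    channels: Optional[Sequence[str]] = None,
) -> list[CellImage]:
    """Read a multi-page TIFF stack plus a label-image mask into CellImages.

    Parameters
    ----------
    path
        Multi-page TIFF.  Pages are ordered timepoint-major then channel,
        or carry explicit (T, C[, Z], Y, X) axes; any Z axis is collapsed
        by pixelwise maximum at read time.
    masks_path
        Label image (TIFF/PNG): each cell has a unique positive integer
        label, 0 is background.  Either a single frame reused for all
        timepoints or one frame per timepoint.
    channels
        Channel order on disk, a subset of ``("fluor", "bright", "marker")``
        starting with ``fluor``.  If omitted, a sidecar ``<path>.json``
        with a ``"channels"`` key is consulted; failing that, a single
        channel is assumed to be ``fluor``.

    Returns
    -------
    list of CellImage, one per (label, timepoint), sorted by (timepoint,
    label).  Labels present in no mask frame yield a warning, not an error.
    """
    import tifffile

    path = Path(path)
    masks_path = Path(masks_path)
    if channels is None:
        channels = _load_sidecar_channels(path)
    if channels is None:
        channels = ("fluor",)
    unknown = set(channels) - set(CHANNEL_NAMES)
    if unknown:
        raise FormatError(f"unknown channel names {sorted(unknown)}")
    if "fluor" not in channels:
        raise FormatError("channel layout must include 'fluor'")

    raw = tifffile.imread(path)
    depth = _record_depth(raw)
    stack = _to_tcyx(np.asarray(raw), len(channels))

    if masks_path.suffix.lower() in {".tif", ".tiff"}:
        labels = tifffile.imread(masks_path)
    else:
        from imageio.v3 import imread as _imread  # PNG label images

        labels = _imread(masks_path)
    labels = np.asarray(labels)
    if labels.ndim == 2:
        labels = np.broadcast_to(labels, (stack.shape[0], *labels.shape))
    elif labels.ndim == 3 and labels.shape[0] != stack.shape[0]:
        raise FormatError(
            f"mask has {labels.shape[0]} frames, stack has {stack.shape[0]}"
        )
    if labels.shape[-2:] != stack.shape[-2:]:
        raise FormatError(
            f"image shape {stack.shape[-2:]} differs from mask shape "
            f"{labels.shape[-2:]}"
        )

    all_labels = np.unique(labels)
    all_labels = all_labels[all_labels > 0]
    if all_labels.size == 0:
        logger.warning("label image %s contains no cells", masks_path)
        return []

    out: list[CellImage] = []
    for t in range(stack.shape[0]):
        frame = {name: stack[t, i].astype(float) for i, name in enumerate(channels)}
        for lab in all_labels:
            mask = labels[t] == lab
            if not mask.any():
                logger.warning(
                    "label %d absent from mask frame %d; skipped", lab, t
                )
                continue
            out.append(
                CellImage(
                    fluor=frame["fluor"],
                    bright=frame.get("bright"),
                    marker=frame.get("marker"),
                    cell_mask=mask,
                    cell_id=int(lab),
                    timepoint=t,
                    source_depth=depth,
                )
            )
    return out


def write_measurements(records: Iterable, path) -> None:
    """Write (cell_id, timepoint, method, value) records to CSV.

    The file round-trips losslessly at ``CSV_DECIMALS`` decimal places via
    :func:`read_measurements`.  Empty record collections are an error, not
    an empty file.
    """
    if isinstance(records, pd.DataFrame):
        df = records.copy()
        df.columns = ["cell_id", "timepoint", "method", "value"]
    else:
        records = list(records)
        if not records:
            raise ValueError("no records to write")
        df = pd.DataFrame(
            records, columns=["cell_id", "timepoint", "method", "value"]
        )
    if df.empty:
        raise ValueError("no records to write")
    df.to_csv(path, index=False, float_format=f"%.{CSV_DECIMALS}g")


def read_measurements(path) -> pd.DataFrame:
    """Read a measurements CSV written by :func:`write_measurements`."""
    df = pd.read_csv(path)
    expected = ["cell_id", "timepoint", "method", "value"]
    if list(df.columns) != expected:
        raise FormatError(f"expected columns {expected}, got {list(df.columns)}")
    return df


def write_cell_stack(path, frames: np.ndarray, channels: Sequence[str]) -> None:
    """Write a (T, C, Y, X) float array as a multi-page TIFF with a sidecar
    JSON declaring the channel order."""
    import tifffile

    path = Path(path)
    frames = np.asarray(frames, dtype=np.float32)
    if frames.ndim != 4:
        raise ValueError("expected a (T, C, Y, X) array")
    tifffile.imwrite(path, frames)
    sidecar = path.with_suffix(path.suffix + ".json")
    sidecar.write_text(json.dumps({"channels": list(channels)}))
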