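"""Reading, writing and linearization of dual-view CEUS cine loops.

A clinical CEUS recording is a cine loop showing a side-by-side view: the
B-mode (tissue) image in one pane and the contrast-specific image in the
other.  This module splits the two panes, validates the acquisition
metadata (frame times, pixel spacing, dynamic range) and converts the
log-compressed contrast gray levels back to linear relative echo power.

Supported containers: multi-frame DICOM, TIFF stacks, and ``.npz`` array
archives (the simulator's native format).  Lesion masks are binary rasters
(PNG/TIFF, nonzero = lesion) tied to named frame indices.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path
from typing import Mapping

import numpy as np
import yaml


class CineError(ValueError):
    """Invalid cine data or metadata."""


class LayoutError(CineError):
    """Side-by-side pane geometry is inconsistent with the frames."""


class AnnotationError(ValueError):
    """Invalid lesion annotation (empty mask, out-of-range frame...)."""


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class Cine:
    """A dual-view cine loop.

    Attributes
    ----------
    bmode, ceus : ndarray, shape (T, H, W)
        B-mode and contrast frame stacks.  ``ceus`` holds gray levels until
        :func:`linearize` is applied, after which it holds linear relative
        echo power in ``(0, 1]``.
    times : ndarray, shape (T,)
        Acquisition time of each frame in seconds, strictly increasing.
    spacing_mm : tuple of float
        Pixel spacing (row, col) in mm; isotropic spacing is assumed by the
        analysis but both axes are recorded.
    dynamic_range_db : float
        Log-compression dynamic range of the contrast pane, in dB.
    gray_max : float
        Gray level that maps to unit relative power (255 for 8-bit data).
    linearized : bool
        Whether ``ceus`` currently holds linear power.
    """

    bmode: np.ndarray
    ceus: np.ndarray
    times: np.ndarray
    spacing_mm: tuple[float, float]
    dynamic_range_db: float
    gray_max: float = 255.0
    linearized: bool = False

    def __post_init__(self) -> None:
        self.bmode = np.asarray(self.bmode, dtype=np.float64)
        self.ceus = np.asarray(self.ceus, dtype=np.float64)
        self.times = np.asarray(self.times, dtype=np.float64)
        if self.bmode.ndim != 3 or self.ceus.ndim != 3:
            raise CineError("bmode and ceus must be T x H x W stacks")
        if self.bmode.shape != self.ceus.shape:
            raise CineError(
                f"pane shapes differ: bmode {self.bmode.shape} vs "
                f"ceus {self.ceus.shape}"
            )
        if self.times.shape != (self.bmode.shape[0],):
            raise CineError("times must have one entry per frame")
        if np.any(np.diff(self.times) <= 0):
            raise CineError("frame times must be strictly increasing")
        if min(self.spacing_mm) <= 0:
            raise CineError("spacing_mm must be positive")
        if self.dynamic_range_db <= 0:
            raise CineError("dynamic_range_db must be positive")
        if self.linearized and np.any(self.ceus < 0):
            raise CineError("linearized ceus values must be >= 0")

    @property
    def n_frames(self) -> int:
        return self.bmode.shape[0]

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.bmode.shape

    @property
    def frame_rate(self) -> float:
        """Median frame rate in Hz."""
        return 1.0 / float(np.median(np.diff(self.times)))


@dataclasses.dataclass
class LesionAnnotation:
    """Manual lesion delineation on 1-3 named frames plus a label.

    ``ref_frame`` is the frame on which the radiologist indicated the
    lesion; it anchors the valid-frame correlation filter and the mean-TIC
    mask.
    """

    masks: dict[int, np.ndarray]
    ref_frame: int
    label: str = "unknown"

    def __post_init__(self) -> None:
        if not self.masks:
            raise AnnotationError("at least one mask is required")
        if not 1 <= len(self.masks) <= 3:
            raise AnnotationError("expected 1-3 masks, got %d" % len(self.masks))
        for idx, m in self.masks.items():
            m = np.asarray(m).astype(bool)
            if m.ndim != 2:
                raise AnnotationError(f"mask at frame {idx} is not 2-D")
            if not m.any():
                raise AnnotationError(f"mask at frame {idx} is empty")
            self.masks[idx] = m
        if self.ref_frame not in self.masks:
            raise AnnotationError(
                f"reference frame {self.ref_frame} has no mask"
            )
        if self.label not in ("benign", "malignant", "unknown"):
            raise AnnotationError(f"unknown label {self.label!r}")

    def validate_against(self, cine: Cine) -> None:
        """Check mask geometry and frame indices against a cine."""
        T, H, W = cine.shape
        for idx, m in self.masks.items():
            if not 0 <= idx < T:
                raise AnnotationError(f"mask frame {idx} outside [0, {T})")
            if m.shape != (H, W):
                raise AnnotationError(
                    f"mask at frame {idx} has shape {m.shape}, expected {(H, W)}"
                )

    @property
    def mask_union(self) -> np.ndarray:
        out = np.zeros_like(next(iter(self.masks.values())), dtype=bool)
        for m in self.masks.values():
            out |= m
        return out


# ---------------------------------------------------------------------------
# Linearization
# ---------------------------------------------------------------------------

def linearize_values(
    gray: np.ndarray, dynamic_range_db: float, gray_max: float = 255.0
) -> np.ndarray:
    """Invert log compression: gray level -> linear relative echo power.

    ``power(g) = 10 ** (DR * (g / G - 1) / 10)`` so that the maximum gray
    level ``G`` maps to unit relative power and gray 0 maps to
    ``10**(-DR/10)``.  The echo-power convention (divisor 10, not 20) is
    used because downstream TIC features are expressed in relative power;
    it is the package default, configurable at the call site.
    """
    g = np.asarray(gray, dtype=np.float64)
    if gray_max <= 0 or dynamic_range_db <= 0:
        raise CineError("gray_max and dynamic_range_db must be positive")
    if np.any(g < 0) or np.any(g > gray_max):
        raise CineError(f"gray levels outside [0, {gray_max}]")
    return 10.0 ** (dynamic_range_db * (g / gray_max - 1.0) / 10.0)


def log_compress_values(
    power: np.ndarray, dynamic_range_db: float, gray_max: float = 255.0
) -> np.ndarray:
    """Forward log compression (inverse of :func:`linearize_values`).

    Powers below the dynamic-range floor clip to gray 0; powers above 1
    clip to ``gray_max``.
    """
    p = np.asarray(power, dtype=np.float64)
    if np.any(p < 0):
        raise CineError("echo power must be non-negative")
    with np.errstate(divide="ignore"):
        g = gray_max * (1.0 + 10.0 * np.log10(p) / dynamic_range_db)
    return np.clip(g, 0.0, gray_max)


def linearize(cine: Cine) -> Cine:
    """Return a copy of *cine* with the contrast pane in linear power."""
    if cine.linearized:
        raise CineError("cine is already linearized")
    ceus = linearize_values(cine.ceus, cine.dynamic_range_db, cine.gray_max)
    return dataclasses.replace(cine, ceus=ceus, linearized=True)


# ---------------------------------------------------------------------------
# Loading
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class Layout:
    """Side-by-side pane geometry and acquisition metadata.

    Pane boxes are half-open ``(r0, r1, c0, c1)`` pixel boxes, 0-based.
    Metadata not present in the container header (times, spacing, dynamic
    range) is supplied here, typically parsed from a YAML/JSON sidecar.
    """

    bmode_box: tuple[int, int, int, int]
    ceus_box: tuple[int, int, int, int]
    times: np.ndarray | None = None
    spacing_mm: tuple[float, float] | None = None
    dynamic_range_db: float | None = None
    gray_max: float | None = None

    @classmethod
    def from_sidecar(cls, path: str | Path) -> "Layout":
        path = Path(path)
        with open(path) as fh:
            meta = json.load(fh) if path.suffix == ".json" else yaml.safe_load(fh)
        missing = [k for k in ("bmode_box", "ceus_box") if k not in meta]
        if missing:
            raise CineError(f"sidecar missing required field(s): {missing}")
        return cls(
            bmode_box=tuple(meta["bmode_box"]),
            ceus_box=tuple(meta["ceus_box"]),
            times=np.asarray(meta["times"], float) if "times" in meta else None,
            spacing_mm=tuple(meta["spacing_mm"]) if "spacing_mm" in meta else None,
            dynamic_range_db=meta.get("dynamic_range_db"),
            gray_max=meta.get("gray_max"),
        )


def split_panes(
    frames: np.ndarray, layout: Layout
) -> tuple[np.ndarray, np.ndarray]:
    """Split T x H x W frames into (bmode, ceus) stacks per the layout."""
    T, H, W = frames.shape
    boxes = {"bmode": layout.bmode_box, "ceus": layout.ceus_box}
    for name, (r0, r1, c0, c1) in boxes.items():
        if not (0 <= r0 < r1 <= H and 0 <= c0 < c1 <= W):
            raise LayoutError(
                f"{name} box {(r0, r1, c0, c1)} exceeds frame {H}x{W}"
            )
    br = layout.bmode_box
    cr = layout.ceus_box
    # overlap check on column ranges when row ranges intersect
    rows_overlap = br[0] < cr[1] and cr[0] < br[1]
    cols_overlap = br[2] < cr[3] and cr[2] < br[3]
    if rows_overlap and cols_overlap:
        raise LayoutError("bmode and ceus pane boxes overlap")
    bmode = frames[:, br[0]:br[1], br[2]:br[3]]
    ceus = frames[:, cr[0]:cr[1], cr[2]:cr[3]]
    if bmode.shape != ceus.shape:
        raise LayoutError(
            f"pane boxes give different shapes {bmode.shape[1:]} vs {ceus.shape[1:]}"
        )
    return bmode, ceus


def _read_frames(path: Path) -> np.ndarray:
    suffix = path.suffix.lower()
    if suffix in (".tif", ".tiff"):
        import tifffile

        return np.asarray(tifffile.imread(path))
    if suffix in (".dcm", ".dicom"):
        import pydicom

        ds = pydicom.dcmread(path)
        arr = ds.pixel_array
        if arr.ndim == 2:
            arr = arr[None]
        return np.asarray(arr)
    if suffix == ".npz":
        with np.load(path) as z:
            return np.asarray(z["frames"])
    raise CineError(f"unsupported cine container: {path.suffix}")


def load_cine(path: str | Path, layout: Layout) -> Cine:
    """Load a side-by-side cine and split it into panes.

    ``layout`` supplies the pane boxes and any metadata the container
    header does not carry.  The returned cine is *not* linearized.
    """
    path = Path(path)
    frames = _read_frames(path).astype(np.float64)
    if frames.ndim != 3:
        raise CineError(f"expected a T x H x W stack, got shape {frames.shape}")
    bmode, ceus = split_panes(frames, layout)
    for field in ("times", "spacing_mm", "dynamic_range_db"):
        if getattr(layout, field) is None:
            raise CineError(f"missing metadata field: {field}")
    gray_max = layout.gray_max
    if gray_max is None:
        gray_max = 255.0 if frames.max() <= 255 else 65535.0
    return Cine(
        bmode=bmode,
        ceus=ceus,
        times=np.asarray(layout.times, float),
        spacing_mm=layout.spacing_mm,
        dynamic_range_db=float(layout.dynamic_range_db),
        gray_max=float(gray_max),
    )


def save_cine(path: str | Path, cine: Cine) -> None:
    """Write a cine as a side-by-side ``.npz`` archive plus embedded metadata."""
    if cine.linearized:
        raise CineError("save_cine expects log-compressed gray levels")
    frames = np.concatenate([cine.bmode, cine.ceus], axis=2)
    np.savez_compressed(
        Path(path),
        frames=frames,
        times=cine.times,
        spacing_mm=np.asarray(cine.spacing_mm),
        dynamic_range_db=cine.dynamic_range_db,
        gray_max=cine.gray_max,
        split_col=cine.bmode.shape[2],
    )


def load_saved_cine(path: str | Path) -> Cine:
    """Round-trip loader for :func:`save_cine` archives."""
    with np.load(Path(path)) as z:
        frames = z["frames"]
        split = int(z["split_col"])
        H, W = frames.shape[1:]
        layout = Layout(
            bmode_box=(0, H, 0, split),
            ceus_box=(0, H, split, W),
            times=z["times"],
            spacing_mm=tuple(z["spacing_mm"]),
            dynamic_range_db=float(z["dynamic_range_db"]),
            gray_max=float(z["gray_max"]),
        )
        bmode, ceus = split_panes(frames, layout)
        return Cine(
            bmode=bmode,
            ceus=ceus,
            times=layout.times,
            spacing_mm=layout.spacing_mm,
            dynamic_range_db=layout.dynamic_range_db,
            gray_max=layout.gray_max,
        )


def _read_mask(path: str | Path) -> np.ndarray:
    path = Path(path)
    suffix = path.suffix.lower()
    if suffix in (".png", ".tif", ".tiff"):
        import imageio.v3 as iio

        arr = np.asarray(iio.imread(path))
        if arr.ndim == 3:  # collapse RGB(A)
            arr = arr[..., 0]
        return arr != 0
    if suffix == ".npy":
        return np.load(path) != 0
    if suffix in (".nii", ".gz"):
        import nibabel as nib

        return np.asarray(nib.load(str(path)).dataobj).squeeze() != 0
    raise AnnotationError(f"unsupported mask format: {path.suffix}")


def load_annotation(
    mask_paths: Mapping[int, str | Path],
    ref_frame: int,
    label: str = "unknown",
    cine: Cine | None = None,
) -> LesionAnnotation:
    """Load 1-3 lesion masks keyed by frame index.

    Masks are binary rasters (nonzero = lesion).  When *cine* is given the
    masks are validated against its geometry.
    """
    masks = {int(i): _read_mask(p) for i, p in mask_paths.items()}
    ann = LesionAnnotation(masks=masks, ref_frame=ref_frame, label=label)
    if cine is not None:
        ann.validate_against(cine)
    return ann
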