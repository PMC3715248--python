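"""Core data types and readers/writers for vineyard scene bundles.

A scene bundle holds one RGB image plus three co-registered narrow-band
images (centre wavelengths 635, 660 and 880 nm), all the same size, with an
optional ground-truth label map. Bands are stored on disk as lossless 16-bit
greyscale TIFF, the RGB image as 16-bit 3-channel TIFF, label maps as 8-bit
indexed PNG with a JSON legend, and a JSON sidecar ties the files together.
All intensities are normalised to [0, 1] at load time; downstream maths is
floating point. Bands are assumed pixel-registered (sequential capture
through a filter wheel on a static rig); no registration is attempted.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from enum import IntEnum
from pathlib import Path

import numpy as np
import tifffile
from PIL import Image

from .errors import DimensionMismatchError, MissingChannelError, VinesegError

__all__ = [
    "VineClass",
    "LabelMap",
    "Mask",
    "SceneBundle",
    "ColourImage",
    "PALETTE",
    "load_scene",
    "save_scene",
    "write_labelmap",
    "read_labelmap",
]

WAVELENGTHS_NM = (635, 660, 880)
BAND_NAMES = ("band635", "band660", "band880")


class VineClass(IntEnum):
    """The five evaluation classes plus UNLABELED.

    The integer order (FRUIT, STEM, LEAF, BRANCH, BACKGROUND) is also the
    fixed row/column order of confusion matrices.
    """

    FRUIT = 0
    STEM = 1
    LEAF = 2
    BRANCH = 3
    BACKGROUND = 4
    UNLABELED = 5


#: Display palette: magenta fruits, orange stems, green leaves, yellow
#: branches, white background; black marks unlabeled pixels.
PALETTE: dict[VineClass, tuple[int, int, int]] = {
    VineClass.FRUIT: (255, 0, 255),
    VineClass.STEM: (255, 165, 0),
    VineClass.LEAF: (0, 128, 0),
    VineClass.BRANCH: (255, 255, 0),
    VineClass.BACKGROUND: (255, 255, 255),
    VineClass.UNLABELED: (0, 0, 0),
}

EVAL_CLASSES = (
    VineClass.FRUIT,
    VineClass.STEM,
    VineClass.LEAF,
    VineClass.BRANCH,
    VineClass.BACKGROUND,
)


@dataclass
class LabelMap:
    """Per-pixel categorical map over the five classes plus UNLABELED."""

    values: np.ndarray  # H×W uint8 of VineClass codes

    def __post_init__(self):
        v = np.asarray(self.values)
        if v.ndim != 2:
            raise DimensionMismatchError(f"label map must be 2-D, got {v.shape}")
        if v.size and (v.min() < 0 or v.max() > max(VineClass)):
            raise VinesegError("label map contains unknown class codes")
        self.values = v.astype(np.uint8)

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def is_complete(self) -> bool:
        """True when no pixel is UNLABELED."""
        return not np.any(self.values == VineClass.UNLABELED)

    def class_counts(self) -> dict[VineClass, int]:
        counts = np.bincount(self.values.ravel(), minlength=len(VineClass))
        return {cls: int(counts[cls]) for cls in VineClass}


@dataclass
class Mask:
    """Boolean pixel claim of one pipeline stage.

    TRUE means the pixel is claimed by this stage and excluded from all
    later stages. Masks compose by logical OR.
    """

    values: np.ndarray
    stage_name: str

    def __post_init__(self):
        v = np.asarray(self.values)
        if v.dtype != bool:
            raise TypeError("mask values must be boolean")
        if v.ndim != 2:
            raise DimensionMismatchError(f"mask must be 2-D, got {v.shape}")
        self.values = v

    def __or__(self, other: "Mask") -> "Mask":
        if self.values.shape != other.values.shape:
            raise DimensionMismatchError("cannot OR masks of different shapes")
        return Mask(self.values | other.values, f"{self.stage_name}+{other.stage_name}")

    @property
    def count(self) -> int:
        return int(self.values.sum())


@dataclass
class ColourImage:
    """An image in CIE L*a*b*: L* in [0, 100], a*/b* unbounded chromaticity."""

    lab: np.ndarray

    def __post_init__(self):
        lab = np.asarray(self.lab, dtype=np.float64)
        if lab.ndim != 3 or lab.shape[2] != 3:
            raise DimensionMismatchError(f"expected H×W×3 Lab, got {lab.shape}")
        if not np.all(np.isfinite(lab)):
            raise VinesegError("non-finite L*a*b* values")
        self.lab = lab

    @property
    def ab(self) -> np.ndarray:
        """The two chromaticity layers, shape H×W×2."""
        return self.lab[..., 1:3]


def _check_raster(name: str, arr: np.ndarray, shape, channels: int | None):
    if channels is None:
        ok = arr.ndim == 2
    else:
        ok = arr.ndim == 3 and arr.shape[2] == channels
    if not ok:
        raise DimensionMismatchError(f"channel '{name}' has unexpected shape {arr.shape}")
    if arr.shape[:2] != shape:
        raise DimensionMismatchError(
            f"channel '{name}' shape {arr.shape[:2]} does not match RGB shape {shape}"
        )
    if not np.all(np.isfinite(arr)):
        raise VinesegError(f"channel '{name}' contains NaN/Inf pixels")
    if arr.min() < 0.0 or arr.max() > 1.0:
        raise VinesegError(f"channel '{name}' intensities outside [0, 1]")


@dataclass
class SceneBundle:
    """Registered RGB + {635, 660, 880} nm rasters with optional truth."""

    rgb: np.ndarray
    band635: np.ndarray
    band660: np.ndarray
    band880: np.ndarray
    truth: LabelMap | None = None
    scene_id: str = "scene"

    def __post_init__(self):
        self.rgb = np.asarray(self.rgb, dtype=np.float64)
        if self.rgb.ndim != 3 or self.rgb.shape[2] != 3:
            raise DimensionMismatchError(f"channel 'rgb' has unexpected shape {self.rgb.shape}")
        if self.rgb.size == 0:
            raise VinesegError("empty scene bundle")
        shape = self.rgb.shape[:2]
        _check_raster("rgb", self.rgb, shape, 3)
        for name in BAND_NAMES:
            arr = np.asarray(getattr(self, name), dtype=np.float64)
            _check_raster(name, arr, shape, None)
            setattr(self, name, arr)
        if self.truth is not None and self.truth.shape != shape:
            raise DimensionMismatchError(
                f"truth shape {self.truth.shape} does not match RGB shape {shape}"
            )

    @property
    def shape(self) -> tuple[int, int]:
        return self.rgb.shape[:2]

    def band(self, wavelength_nm: int) -> np.ndarray:
        try:
            return getattr(self, f"band{wavelength_nm}")
        except AttributeError:
            raise MissingChannelError(f"no band at {wavelength_nm} nm") from None


# ---------------------------------------------------------------------------
# raster codecs

_U16 = 65535


def _normalise_loaded(name: str, arr: np.ndarray) -> np.ndarray:
    if arr.dtype == np.uint8:
        return arr.astype(np.float64) / 255.0
    if arr.dtype == np.uint16:
        return arr.astype(np.float64) / _U16
    arr = arr.astype(np.float64)
    if not np.all(np.isfinite(arr)):
        raise VinesegError(f"channel '{name}' contains NaN/Inf pixels")
    if arr.size and (arr.min() < 0.0 or arr.max() > 1.0):
        raise VinesegError(f"channel '{name}' float data outside [0, 1]")
    return arr


def _read_raster(name: str, path: Path) -> np.ndarray:
    if not path.exists():
        raise MissingChannelError(f"channel '{name}': file not found: {path}")
    try:
        if path.suffix.lower() in (".tif", ".tiff"):
            arr = tifffile.imread(path)
        else:
            arr = np.asarray(Image.open(path))
    except Exception as exc:  # noqa: BLE001 - decoder variety
        raise VinesegError(f"channel '{name}': cannot decode {path}: {exc}") from exc
    return _normalise_loaded(name, arr)


def _write_raster16(path: Path, arr: np.ndarray) -> None:
    data = np.round(np.clip(arr, 0.0, 1.0) * _U16).astype(np.uint16)
    tifffile.imwrite(path, data)


# ---------------------------------------------------------------------------
# scene bundle I/O


def load_scene(source) -> SceneBundle:
    """Load a scene bundle.

    ``source`` is either a directory written by :func:`save_scene`
    (containing a ``scene.json`` sidecar) or a mapping
    ``{"rgb": path, "band635": path, "band660": path, "band880": path,
    "truth": path (optional)}``.
    """
    truth_path = None
    scene_id = "scene"
    if isinstance(source, (str, Path)):
        directory = Path(source)
        sidecar = directory / "scene.json"
        if not sidecar.exists():
            raise MissingChannelError(f"no scene.json sidecar in {directory}")
        meta = json.loads(sidecar.read_text())
        scene_id = meta.get("scene_id", directory.name)
        files = meta.get("channel_files", {})
        paths = {}
        for name in ("rgb", *BAND_NAMES):
            if name not in files:
                raise MissingChannelError(f"sidecar lists no file for channel '{name}'")
            paths[name] = directory / files[name]
        if meta.get("truth_file"):
            truth_path = directory / meta["truth_file"]
    else:
        paths = {name: Path(p) for name, p in dict(source).items() if name != "truth"}
        for name in ("rgb", *BAND_NAMES):
            if name not in paths:
                raise MissingChannelError(f"no path given for channel '{name}'")
        if dict(source).get("truth"):
            truth_path = Path(dict(source)["truth"])

    channels = {name: _read_raster(name, paths[name]) for name in ("rgb", *BAND_NAMES)}
    truth = read_labelmap(truth_path) if truth_path else None
    return SceneBundle(
        rgb=channels["rgb"],
        band635=channels["band635"],
        band660=channels["band660"],
        band880=channels["band880"],
        truth=truth,
        scene_id=scene_id,
    )


def save_scene(bundle: SceneBundle, directory) -> dict[str, Path]:
    """Write a bundle as lossless 16-bit TIFFs plus a JSON sidecar.

    Returns the mapping of channel name to written file. The truth map, if
    present, is written as an indexed PNG with its legend.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    files: dict[str, Path] = {}
    _write_raster16(directory / "rgb.tiff", bundle.rgb)
    files["rgb"] = directory / "rgb.tiff"
    for name in BAND_NAMES:
        path = directory / f"{name}.tiff"
        _write_raster16(path, getattr(bundle, name))
        files[name] = path
    meta = {
        "scene_id": bundle.scene_id,
        "wavelengths_nm": list(WAVELENGTHS_NM),
        "channel_files": {name: path.name for name, path in files.items()},
        "truth_file": None,
    }
    if bundle.truth is not None:
        truth_path = directory / "truth.png"
        write_labelmap(bundle.truth, truth_path, allow_partial=True)
        files["truth"] = truth_path
        meta["truth_file"] = truth_path.name
    (directory / "scene.json").write_text(json.dumps(meta, indent=2))
    return files


# ---------------------------------------------------------------------------
# label map I/O


def _legend_path(path: Path) -> Path:
    return path.with_suffix(path.suffix + ".legend.json")


def write_labelmap(labels: LabelMap, path, allow_partial: bool = False) -> Path:
    """Write a label map as an indexed PNG plus a JSON class legend.

    Raises on UNLABELED pixels unless ``allow_partial`` is set, in which
    case a sixth (black) palette entry is used.
    """
    if not allow_partial and not labels.is_complete():
        raise VinesegError(
            "label map contains UNLABELED pixels (pass allow_partial=True to keep them)"
        )
    path = Path(path)
    img = Image.fromarray(labels.values, mode="P")
    palette = np.zeros((256, 3), dtype=np.uint8)
    for cls, rgb in PALETTE.items():
        palette[int(cls)] = rgb
    img.putpalette(palette.ravel().tolist())
    img.save(path)
    legend = {cls.name: {"index": int(cls), "rgb": list(PALETTE[cls])} for cls in VineClass}
    _legend_path(path).write_text(json.dumps(legend, indent=2))
    return path


def read_labelmap(path) -> LabelMap:
    """Read an indexed-PNG label map written by :func:`write_labelmap`.

    The legend is used to map palette indices back to classes, so the
    palette/legend/class correspondence stays bijective.
    """
    path = Path(path)
    if not path.exists():
        raise MissingChannelError(f"label map not found: {path}")
    img = Image.open(path)
    values = np.asarray(img)
    legend_file = _legend_path(path)
    if legend_file.exists():
        legend = json.loads(legend_file.read_text())
        remap = np.full(256, int(VineClass.UNLABELED), dtype=np.uint8)
        for name, entry in legend.items():
            remap[int(entry["index"])] = int(VineClass[name])
        values = remap[values]
    return LabelMap(values)
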