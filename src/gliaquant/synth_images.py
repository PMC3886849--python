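"""Synthetic immunofluorescence section images with known stained fraction.

Each synthetic section emulates a single-channel epifluorescence montage of
fetal cerebral white matter: a narrow, symmetric low-intensity background
mode (unstained tissue + camera background) and a broad brighter mode of
marker-labeled pixels (GFAP astrocytes or Iba1 microglia).  Labeled pixels
are laid down as overlapping disk stamps so lesions look blob-like rather
than salt-and-pepper, but the ground truth is bookkept per pixel: exactly
``round(true_fraction * |ROI|)`` pixels are drawn from the signal
distribution and recorded in ``truth_mask``.

Intensity model: truncated (clipped-to-bit-range) Gaussians for both modes.
The default geometry is a 512x512 8-bit frame with a full-frame ROI.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Literal, Sequence

import numpy as np
import pandas as pd
from skimage.draw import disk

Marker = Literal["GFAP", "Iba1"]

#: default intensity model (8-bit). The background mode is deliberately much
#: narrower than the signal mode: in real montages unstained tissue is nearly
#: uniformly dark while specific staining spans a wide intensity range, and a
#: narrow background mode is what keeps the three-highest-bins peak locator
#: anchored on background even in heavily stained sections.
DEFAULT_BG_MEAN = 30.0
DEFAULT_BG_SD = 1.2
DEFAULT_SIGNAL_MEAN = 160.0
DEFAULT_SIGNAL_SD = 30.0
DEFAULT_BLOB_RADIUS = 5

#: per-section jitter SD applied to the animal-level true fraction,
#: representing section-to-section variability behind triplicate averaging.
DEFAULT_SECTION_JITTER_SD = 0.02


@dataclass
class ImageSpec:
    """Parameters of one synthetic section image."""

    width: int = 512
    height: int = 512
    bit_depth: int = 8
    true_fraction: float = 0.0
    bg_mean: float = DEFAULT_BG_MEAN
    bg_sd: float = DEFAULT_BG_SD
    signal_mean: float = DEFAULT_SIGNAL_MEAN
    signal_sd: float = DEFAULT_SIGNAL_SD
    blob_radius: int = DEFAULT_BLOB_RADIUS
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.true_fraction <= 1.0:
            raise ValueError(f"true_fraction {self.true_fraction} outside [0, 1]")
        if self.bit_depth not in (8, 16):
            raise ValueError("bit_depth must be 8 or 16")
        if self.width < 1 or self.height < 1:
            raise ValueError("image dimensions must be positive")

    @property
    def max_intensity(self) -> int:
        return 2 ** self.bit_depth - 1

    @property
    def well_separated(self) -> bool:
        """Background and signal modes at least 4 SD apart."""
        return self.bg_mean + 4 * self.bg_sd < self.signal_mean - 4 * self.signal_sd


@dataclass
class IntensityImage:
    """A grayscale section image plus ROI (and, for synthetic images, truth)."""

    pixels: np.ndarray                       # 2D unsigned ints
    roi_mask: np.ndarray                     # 2D bool, same shape
    truth_mask: np.ndarray | None = None     # 2D bool; subset of roi_mask
    bit_depth: int = 8

    def __post_init__(self) -> None:
        if self.pixels.shape != self.roi_mask.shape:
            raise ValueError("pixels and roi_mask shapes differ")
        if self.truth_mask is not None:
            if self.truth_mask.shape != self.pixels.shape:
                raise ValueError("truth_mask shape differs from pixels")
            if np.any(self.truth_mask & ~self.roi_mask):
                raise ValueError("truth_mask must be a subset of roi_mask")

    @property
    def truth_fraction(self) -> float:
        """Ground-truth stained fraction of the ROI (synthetic images only)."""
        if self.truth_mask is None:
            raise ValueError("image has no ground-truth mask")
        return float(self.truth_mask.sum() / self.roi_mask.sum())


def _check_overflow(mean: float, sd: float, lo: float, hi: float,
                    label: str) -> None:
    """Reject intensity distributions whose tail mass beyond the bit range
    exceeds 0.1% (clipping would visibly distort the mode symmetry)."""
    from scipy.stats import norm

    if sd == 0:
        tail = 0.0 if lo <= mean <= hi else 1.0
    else:
        tail = norm.cdf(lo, mean, sd) + norm.sf(hi, mean, sd)
    if tail > 0.001:
        raise ValueError(
            f"{label} distribution overflows the bit range for "
            f"{tail:.2%} of pixels (limit 0.1%)"
        )


def _stamp_truth_mask(
    roi: np.ndarray, n_target: int, radius: int, rng: np.random.Generator
) -> np.ndarray:
    """Union of random disks inside the ROI holding exactly n_target pixels."""
    truth = np.zeros_like(roi)
    if n_target == 0:
        return truth
    h, w = roi.shape
    n_roi = int(roi.sum())
    if n_target >= n_roi:
        return roi.copy()
    count = 0
    while count < n_target:
        r = int(rng.integers(0, h))
        c = int(rng.integers(0, w))
        rr, cc = disk((r, c), radius, shape=roi.shape)
        keep = roi[rr, cc] & ~truth[rr, cc]
        new_px = int(keep.sum())
        if new_px == 0:
            continue
        if count + new_px > n_target:
            # trim the final stamp to land exactly on the target count
            sel = rng.choice(new_px, size=n_target - count, replace=False)
            rr, cc = rr[keep], cc[keep]
            truth[rr[sel], cc[sel]] = True
            count = n_target
        else:
            truth[rr[keep], cc[keep]] = True
            count += new_px
    return truth


def generate_section_image(
    spec: ImageSpec, roi_mask: np.ndarray | None = None
) -> IntensityImage:
    """Render one synthetic section per the spec; deterministic per seed."""
    rng = np.random.default_rng(spec.seed)
    shape = (spec.height, spec.width)
    roi = np.ones(shape, dtype=bool) if roi_mask is None else roi_mask.astype(bool)
    if roi.shape != shape:
        raise ValueError("roi_mask shape does not match spec geometry")
    n_roi = int(roi.sum())
    if n_roi == 0:
        raise ValueError("ROI is empty")
    _check_overflow(spec.bg_mean, spec.bg_sd, 0, spec.max_intensity, "background")
    _check_overflow(spec.signal_mean, spec.signal_sd, 0, spec.max_intensity, "signal")
    n_signal = int(round(spec.true_fraction * n_roi))
    truth = _stamp_truth_mask(roi, n_signal, spec.blob_radius, rng)

    bg = rng.normal(spec.bg_mean, spec.bg_sd, size=shape)
    pixels = np.round(np.clip(bg, 0, spec.max_intensity))
    if n_signal:
        sig = rng.normal(spec.signal_mean, spec.signal_sd, size=n_signal)
        pixels[truth] = np.round(np.clip(sig, 0, spec.max_intensity))
    dtype = np.uint8 if spec.bit_depth == 8 else np.uint16
    return IntensityImage(
        pixels=pixels.astype(dtype), roi_mask=roi, truth_mask=truth,
        bit_depth=spec.bit_depth,
    )


def generate_animal_sections(
    severity: float,
    marker: Marker,
    calib: Callable[[float], float] | dict[float, float],
    seed: int,
    n_sections: int = 3,
    jitter_sd: float = DEFAULT_SECTION_JITTER_SD,
    max_fraction: float = 1.0,
    **spec_kwargs,
) -> list[IntensityImage]:
    """Triplicate sections for one animal and marker.

    ``calib`` maps latent injury severity to the animal-level true stained
    fraction; it must be monotone non-decreasing.  Each section's fraction is
    the animal fraction plus Gaussian section-level jitter (SD ``jitter_sd``),
    clipped to [0, ``max_fraction``] — sections obey the same physical
    ceiling as the animal-level fractions.
    """
    calib_fn = _as_calibration(calib)
    rng = np.random.default_rng(seed)
    base = float(calib_fn(severity))
    images = []
    for k in range(n_sections):
        frac = float(np.clip(base + rng.normal(0.0, jitter_sd),
                             0.0, max_fraction))
        spec = ImageSpec(
            true_fraction=frac,
            seed=int(rng.integers(0, 2**31 - 1)),
            **spec_kwargs,
        )
        images.append(generate_section_image(spec))
    return images


def _as_calibration(calib) -> Callable[[float], float]:
    """Validate and normalize a severity->fraction calibration mapping."""
    if callable(calib):
        return calib
    keys = sorted(calib)
    vals = [calib[k] for k in keys]
    if any(b < a for a, b in zip(vals, vals[1:])):
        raise ValueError("calibration mapping must be monotone non-decreasing")

    def interp(s: float) -> float:
        return float(np.interp(s, keys, vals))

    return interp


# ---------------------------------------------------------------------------
# disk I/O: TIFF images + sidecar CSV manifest

MANIFEST_COLUMNS = [
    "animal_id", "marker", "section_index", "true_fraction", "path", "roi_path",
]


def save_image(image: IntensityImage, path: str | Path) -> None:
    import tifffile

    tifffile.imwrite(str(path), image.pixels)


def save_mask(mask: np.ndarray, path: str | Path) -> None:
    import tifffile

    tifffile.imwrite(str(path), (mask.astype(np.uint8) * 255))


def load_image(path: str | Path, roi_path: str | Path | None = None,
               bit_depth: int = 8) -> IntensityImage:
    import tifffile

    pixels = tifffile.imread(str(path))
    if roi_path is not None:
        roi = tifffile.imread(str(roi_path)) > 0
    else:
        roi = np.ones_like(pixels, dtype=bool)
    return IntensityImage(pixels=pixels, roi_mask=roi, bit_depth=bit_depth)


@dataclass
class ImageManifest:
    """Sidecar table locating every written section image."""

    rows: list[dict] = field(default_factory=list)

    def add(self, animal_id: str, marker: str, section_index: int,
            true_fraction: float, path: str, roi_path: str = "") -> None:
        self.rows.append(dict(
            animal_id=animal_id, marker=marker, section_index=section_index,
            true_fraction=true_fraction, path=path, roi_path=roi_path,
        ))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.rows, columns=MANIFEST_COLUMNS)

    def write(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def read(cls, path: str | Path) -> "ImageManifest":
        df = pd.read_csv(path, keep_default_na=False)
        missing = set(MANIFEST_COLUMNS) - set(df.columns)
        if missing:
            raise ValueError(f"manifest missing columns: {sorted(missing)}")
        return cls(rows=df.to_dict("records"))
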