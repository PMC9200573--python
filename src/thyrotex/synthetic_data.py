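"""Synthetic ultrasound-like texture images with controllable second-order statistics.

Real B-mode images of thyroid nodules are dominated by speckle — multiplicative
interference noise — superimposed on slowly varying tissue texture.  The
generator here emulates that structure with three interpretable ingredients:

* a latent Gaussian random field smoothed at a configurable correlation
  length (the "tissue" texture; shorter correlation length and larger
  contrast amplitude give visibly rougher, higher-contrast texture),
* unit-mean multiplicative Gamma speckle, the standard first-order model
  for fully developed B-mode speckle, and
* additive Gaussian acquisition noise.

Two texture specifications — one per class — let benign and malignant images
differ in exactly the second-order statistics that the co-occurrence and
wavelet features downstream are designed to measure.  The default class
balance mirrors a clinical series of 322 malignant and 128 benign nodule
images.
"""

from __future__ import annotations

import csv
import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
from PIL import Image
from scipy import ndimage

__all__ = [
    "TextureSpec",
    "SyntheticConfig",
    "LabeledImageSet",
    "generate_dataset",
    "save_dataset",
    "load_dataset",
    "default_config",
]

#: ratio of malignant to benign images in the emulated clinical series
CLINICAL_MALIGNANT = 322
CLINICAL_BENIGN = 128


class ConfigurationError(ValueError):
    """Raised when a synthetic-data configuration violates an invariant."""


@dataclass(frozen=True)
class TextureSpec:
    """Second-order texture description of one nodule class.

    Parameters
    ----------
    base_intensity:
        Mean gray level of the tissue, in the native (continuous) intensity
        scale of the generator.
    correlation_length:
        Gaussian smoothing scale of the latent field, in pixels. Larger
        values give smoother, more slowly varying texture.
    contrast_amplitude:
        Standard-deviation-like amplitude of the texture fluctuations,
        in gray-level units.
    orientation_deg:
        Optional anisotropy direction in degrees. When set, the latent field
        is smoothed more strongly along this direction (3:1 aspect), giving
        oriented, streaky texture.
    """

    base_intensity: float = 120.0
    correlation_length: float = 2.0
    contrast_amplitude: float = 20.0
    orientation_deg: float | None = None

    def validate(self) -> None:
        if not self.correlation_length > 0:
            raise ConfigurationError(
                f"correlation_length must be > 0, got {self.correlation_length}"
            )
        if self.contrast_amplitude < 0:
            raise ConfigurationError(
                f"contrast_amplitude must be >= 0, got {self.contrast_amplitude}"
            )


# Defaults give two classes separable through second-order statistics:
# malignant texture is rougher (shorter correlation length) and has four
# times the contrast amplitude of benign texture.
DEFAULT_BENIGN = TextureSpec(
    base_intensity=120.0, correlation_length=4.0, contrast_amplitude=10.0
)
DEFAULT_MALIGNANT = TextureSpec(
    base_intensity=120.0, correlation_length=1.5, contrast_amplitude=40.0
)

#: Gaussian smoothing scale (pixels) of the speckle field.  B-mode speckle
#: has a finite grain size set by the imaging point-spread function; a
#: pixel-white field would overstate its high-frequency content.
DEFAULT_SPECKLE_GRAIN = 1.5


@dataclass(frozen=True)
class SyntheticConfig:
    """Full description of a synthetic labeled image set.

    ``speckle_shape`` is the Gamma shape parameter of the unit-mean
    multiplicative speckle (scale = 1/shape); larger shape means milder
    speckle.  ``speckle_shape=None`` disables speckle entirely (the
    shape → ∞ limit).  ``speckle_grain`` is the spatial correlation scale of
    the speckle field in pixels (0 = pixel-white).  ``gaussian_noise_sd`` is
    the standard deviation of additive acquisition noise in gray-level
    units.

    ``heterogeneity`` models biological variation between nodules of the
    same class: each image's correlation length and contrast amplitude are
    multiplied by independent lognormal(0, heterogeneity) factors, so the
    TextureSpec fields are class-typical values rather than exact per-image
    parameters.  Set to 0 for identically distributed images.
    """

    image_size: tuple[int, int] = (64, 64)
    n_benign: int = CLINICAL_BENIGN
    n_malignant: int = CLINICAL_MALIGNANT
    benign_texture: TextureSpec = field(default_factory=lambda: DEFAULT_BENIGN)
    malignant_texture: TextureSpec = field(default_factory=lambda: DEFAULT_MALIGNANT)
    speckle_shape: float | None = 10.0
    speckle_grain: float = DEFAULT_SPECKLE_GRAIN
    gaussian_noise_sd: float = 2.0
    heterogeneity: float = 0.2
    seed: int = 0

    def validate(self) -> None:
        rows, cols = self.image_size
        if rows < 16 or cols < 16:
            raise ConfigurationError(
                f"image_size must be at least (16, 16), got {self.image_size}"
            )
        if self.n_benign < 0:
            raise ConfigurationError(f"n_benign must be >= 0, got {self.n_benign}")
        if self.n_malignant < 0:
            raise ConfigurationError(
                f"n_malignant must be >= 0, got {self.n_malignant}"
            )
        if self.n_benign + self.n_malignant < 1:
            raise ConfigurationError("n_benign + n_malignant must be >= 1")
        if self.speckle_shape is not None and not self.speckle_shape > 0:
            raise ConfigurationError(
                f"speckle_shape must be > 0 or None, got {self.speckle_shape}"
            )
        if self.speckle_grain < 0:
            raise ConfigurationError(
                f"speckle_grain must be >= 0, got {self.speckle_grain}"
            )
        if self.heterogeneity < 0:
            raise ConfigurationError(
                f"heterogeneity must be >= 0, got {self.heterogeneity}"
            )
        if self.gaussian_noise_sd < 0:
            raise ConfigurationError(
                f"gaussian_noise_sd must be >= 0, got {self.gaussian_noise_sd}"
            )
        self.benign_texture.validate()
        self.malignant_texture.validate()

    def to_dict(self) -> dict[str, Any]:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict[str, Any]) -> "SyntheticConfig":
        d = dict(d)
        for key in ("benign_texture", "malignant_texture"):
            if key in d and isinstance(d[key], dict):
                d[key] = TextureSpec(**d[key])
        if "image_size" in d:
            d["image_size"] = tuple(d["image_size"])
        return cls(**d)


@dataclass
class LabeledImageSet:
    """Grayscale images with binary labels (0 = benign, 1 = malignant)."""

    images: list[np.ndarray]
    labels: list[int]
    meta: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if len(self.images) != len(self.labels):
            raise ValueError(
                f"{len(self.images)} images but {len(self.labels)} labels"
            )
        for lab in self.labels:
            if lab not in (0, 1):
                raise ValueError(f"labels must be 0 or 1, got {lab!r}")

    def __len__(self) -> int:
        return len(self.images)


def default_config(n_total: int = 200, seed: int = 0, **overrides: Any) -> SyntheticConfig:
    """A separable two-class configuration with the clinical 322:128 balance.

    ``n_total`` images are split between the classes in the 322:128
    proportion (malignant rounded up).
    """
    n_mal = int(round(n_total * CLINICAL_MALIGNANT / (CLINICAL_MALIGNANT + CLINICAL_BENIGN)))
    n_mal = min(max(n_mal, 1), n_total - 1) if n_total >= 2 else n_total
    return SyntheticConfig(
        n_benign=n_total - n_mal, n_malignant=n_mal, seed=seed, **overrides
    )


def _latent_texture(
    shape: tuple[int, int], spec: TextureSpec, rng: np.random.Generator
) -> np.ndarray:
    """Smoothed, unit-variance Gaussian random field (anisotropic if oriented)."""
    rows, cols = shape
    if spec.orientation_deg is None:
        white = rng.standard_normal((rows, cols))
        fieldv = ndimage.gaussian_filter(
            white, sigma=spec.correlation_length, mode="wrap"
        )
    else:
        # Smooth axis-aligned with a 3:1 aspect on a larger canvas, rotate,
        # then crop — gives streaks along orientation_deg.
        pad = int(np.ceil(0.5 * max(rows, cols)))
        big = rng.standard_normal((rows + 2 * pad, cols + 2 * pad))
        fieldv = ndimage.gaussian_filter(
            big,
            sigma=(spec.correlation_length, 3.0 * spec.correlation_length),
            mode="wrap",
        )
        fieldv = ndimage.rotate(
            fieldv, angle=spec.orientation_deg, reshape=False, order=1, mode="reflect"
        )
        fieldv = fieldv[pad : pad + rows, pad : pad + cols]
    sd = fieldv.std()
    if sd > 0:
        fieldv = fieldv / sd
    return fieldv


def _render_image(
    spec: TextureSpec, config: SyntheticConfig, rng: np.random.Generator
) -> np.ndarray:
    if config.heterogeneity > 0:
        spec = dataclasses.replace(
            spec,
            correlation_length=spec.correlation_length
            * rng.lognormal(0.0, config.heterogeneity),
            contrast_amplitude=spec.contrast_amplitude
            * rng.lognormal(0.0, config.heterogeneity),
        )
    clean = spec.base_intensity + spec.contrast_amplitude * _latent_texture(
        config.image_size, spec, rng
    )
    clean = np.clip(clean, 0.0, None)
    if config.speckle_shape is not None:
        speckle = rng.gamma(
            shape=config.speckle_shape,
            scale=1.0 / config.speckle_shape,
            size=config.image_size,
        )
        if config.speckle_grain > 0:
            # finite speckle-cell size: correlate the field and restore unit mean
            speckle = ndimage.gaussian_filter(
                speckle, sigma=config.speckle_grain, mode="wrap"
            )
            speckle = speckle / speckle.mean()
        clean = clean * speckle
    if config.gaussian_noise_sd > 0:
        clean = clean + rng.normal(0.0, config.gaussian_noise_sd, config.image_size)
    return np.clip(clean, 0.0, None)


def generate_dataset(config: SyntheticConfig) -> LabeledImageSet:
    """Generate a labeled image set; a pure function of (config, seed).

    Images are emitted benign-first, then malignant, each drawn from its
    class texture specification with independent speckle and noise
    realizations.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    images: list[np.ndarray] = []
    labels: list[int] = []
    for _ in range(config.n_benign):
        images.append(_render_image(config.benign_texture, config, rng))
        labels.append(0)
    for _ in range(config.n_malignant):
        images.append(_render_image(config.malignant_texture, config, rng))
        labels.append(1)
    return LabeledImageSet(images, labels, meta={"config": config.to_dict()})


# ---------------------------------------------------------------------------
# On-disk format: 16-bit grayscale PNGs + a CSV manifest `filename,label`.
# Internal pixel values are continuous; quantization to uint16 happens only
# at save time, on a per-dataset linear scale recorded in the config JSON.

_PNG_MAX = 65535


def save_dataset(image_set: LabeledImageSet, directory: str | Path) -> Path:
    """Write one 16-bit PNG per image plus a ``manifest.csv``; returns manifest path.

    Pixel values are linearly mapped onto the uint16 range using a scale
    shared across the whole set, recorded in ``config.json`` so that
    :func:`load_dataset` can invert it exactly up to the 16-bit rounding.
    """
    if str(directory) == "":
        raise IOError("output directory path is empty")
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)

    peak = max((float(img.max()) for img in image_set.images), default=1.0)
    scale = _PNG_MAX / peak if peak > 0 else 1.0

    manifest = directory / "manifest.csv"
    with open(manifest, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["filename", "label"])
        for i, (img, lab) in enumerate(zip(image_set.images, image_set.labels)):
            name = f"img_{i:04d}.png"
            coded = np.round(np.asarray(img, dtype=float) * scale)
            coded = np.clip(coded, 0, _PNG_MAX).astype(np.uint16)
            Image.fromarray(coded).save(directory / name)
            writer.writerow([name, lab])

    provenance = dict(image_set.meta)
    provenance["png_scale"] = scale
    with open(directory / "config.json", "w") as fh:
        json.dump(provenance, fh, indent=2, sort_keys=True)
    return manifest


def load_dataset(manifest: str | Path) -> LabeledImageSet:
    """Load a saved image set; rows are returned in manifest order.

    Pixel values are mapped back to the generator's intensity scale when the
    sidecar ``config.json`` records the save-time scale; otherwise raw
    16-bit values are returned.
    """
    manifest = Path(manifest)
    if not manifest.exists():
        raise IOError(f"manifest not found: {manifest}")
    directory = manifest.parent

    scale = 1.0
    meta: dict[str, Any] = {}
    sidecar = directory / "config.json"
    if sidecar.exists():
        with open(sidecar) as fh:
            meta = json.load(fh)
        scale = float(meta.get("png_scale", 1.0))

    images: list[np.ndarray] = []
    labels: list[int] = []
    with open(manifest, newline="") as fh:
        for row in csv.DictReader(fh):
            path = directory / row["filename"]
            if not path.exists():
                raise IOError(f"image file not found: {path}")
            label = int(row["label"])
            if label not in (0, 1):
                raise ValueError(
                    f"label for {row['filename']} must be 0 or 1, got {label}"
                )
            arr = np.array(Image.open(path), dtype=float) / scale
            images.append(arr)
            labels.append(label)
    meta.setdefault("source", str(manifest))
    return LabeledImageSet(images, labels, meta=meta)
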