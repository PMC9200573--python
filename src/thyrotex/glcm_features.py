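"""Gray-level co-occurrence matrix (GLCM) texture features.

The GLCM of a quantized image counts, for a fixed pixel displacement
(delta_row, delta_col), how often gray levels q and z occur at the two ends
of the displacement.  A single offset makes the matrix sensitive to image
rotation, so the matrix is built at four offsets sweeping 180 degrees at a
common distance delta —

    0 degrees   (0,  +delta)   horizontal pairs
    45 degrees  (-delta, +delta)  right-diagonal pairs
    90 degrees  (-delta, 0)    vertical pairs
    135 degrees (-delta, -delta)  left-diagonal pairs

— and the ten second-order statistics (autocorrelation, contrast,
correlation, cluster prominence, cluster shade, dissimilarity, energy,
entropy, homogeneity, maximum probability) are averaged over the sweep,
which makes the pooled feature vector exactly invariant to 90-degree image
rotations.

Accumulation is asymmetric (pairs are counted in one direction per offset);
the rotational coverage comes from the sweep, not from symmetrizing each
matrix.  A ``symmetric`` flag is available for the transposed-accumulation
convention.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "QuantizedImage",
    "OffsetSpec",
    "CooccurrenceMatrix",
    "GlcmMarginals",
    "TextureFeatureVector",
    "FEATURE_NAMES",
    "sweep_offsets",
    "quantize",
    "compute_glcm",
    "glcm_marginals",
    "texture_features",
    "extract_fglcm",
]

FEATURE_NAMES = ("AC", "CT", "CR", "CP", "CS", "D", "EN", "ET", "H", "MP")

#: (delta_row, delta_col) for the four sweep orientations, in degrees
_SWEEP = {0: (0, 1), 45: (-1, 1), 90: (-1, 0), 135: (-1, -1)}


@dataclass(frozen=True)
class QuantizedImage:
    """Integer image with values in [0, levels-1] plus its quantization record."""

    levels: int
    data: np.ndarray
    quantization: tuple[float, float, int]  # (min, max, levels) of the source

    def __post_init__(self) -> None:
        if self.levels < 2:
            raise ValueError(f"levels must be >= 2, got {self.levels}")
        if self.data.min() < 0 or self.data.max() > self.levels - 1:
            raise ValueError("quantized values out of [0, levels-1]")


@dataclass(frozen=True)
class OffsetSpec:
    """One co-occurrence displacement: distance delta at one of the four
    sweep orientations (degrees)."""

    delta: int = 1
    orientation: int = 0

    def __post_init__(self) -> None:
        if self.delta < 1:
            raise ValueError(f"delta must be >= 1, got {self.delta}")
        if self.orientation not in _SWEEP:
            raise ValueError(
                f"orientation must be one of {sorted(_SWEEP)}, got {self.orientation}"
            )

    @property
    def displacement(self) -> tuple[int, int]:
        dr, dc = _SWEEP[self.orientation]
        return dr * self.delta, dc * self.delta


def sweep_offsets(delta: int = 1) -> list[OffsetSpec]:
    """The four offsets covering 180 degrees at distance ``delta``."""
    return [OffsetSpec(delta=delta, orientation=o) for o in sorted(_SWEEP)]


@dataclass(frozen=True)
class CooccurrenceMatrix:
    counts: np.ndarray
    offset: OffsetSpec
    normalized: bool
    probabilities: np.ndarray | None = None

    @property
    def levels(self) -> int:
        return self.counts.shape[0]

    @property
    def P(self) -> np.ndarray:
        if not self.normalized or self.probabilities is None:
            raise ValueError("co-occurrence matrix is not normalized")
        return self.probabilities


@dataclass(frozen=True)
class GlcmMarginals:
    """Means/SDs of the row (mu_e, sigma_e) and column (mu_g, sigma_g)
    marginal index distributions of a normalized GLCM."""

    mu_e: float
    mu_g: float
    sigma_e: float
    sigma_g: float


@dataclass
class TextureFeatureVector:
    """The ten co-occurrence statistics for one image (or one offset).

    ``degenerate_correlation`` flags the case sigma_e * sigma_g == 0, where
    correlation is undefined and reported as 0.
    """

    AC: float
    CT: float
    CR: float
    CP: float
    CS: float
    D: float
    EN: float
    ET: float
    H: float
    MP: float
    degenerate_correlation: bool = False

    def as_array(self) -> np.ndarray:
        return np.array([getattr(self, n) for n in FEATURE_NAMES], dtype=float)

    @classmethod
    def from_array(cls, values: np.ndarray, degenerate: bool = False) -> "TextureFeatureVector":
        return cls(*(float(v) for v in values), degenerate_correlation=degenerate)


def quantize(image: np.ndarray, levels: int) -> QuantizedImage:
    """Linear min-max binning into ``levels`` equal-width bins.

    The maximum value maps to levels-1.  A constant image maps entirely to
    level 0 (its range is empty, so every pixel falls in the first bin).
    """
    if levels < 2:
        raise ValueError(f"levels must be >= 2, got {levels}")
    image = np.asarray(image, dtype=float)
    lo, hi = float(image.min()), float(image.max())
    if hi == lo:
        data = np.zeros(image.shape, dtype=np.intp)
    else:
        data = np.floor((image - lo) / (hi - lo) * levels).astype(np.intp)
        np.clip(data, 0, levels - 1, out=data)
    return QuantizedImage(levels=levels, data=data, quantization=(lo, hi, levels))


def compute_glcm(
    q_image: QuantizedImage, offset: OffsetSpec, normalize: bool = True
) -> CooccurrenceMatrix:
    """Count co-occurring level pairs at ``offset`` over all valid positions.

    counts[q, z] is the number of pixel pairs (e, g), (e+dr, g+dc) with
    values (q, z); normalization divides by the total pair count.
    """
    dr, dc = offset.displacement
    rows, cols = q_image.data.shape
    if abs(dr) >= rows or abs(dc) >= cols:
        raise ValueError(
            f"offset displacement {(dr, dc)} exceeds image extent {(rows, cols)}"
        )
    # valid anchor positions: those whose displaced partner stays in bounds
    r0, r1 = max(0, -dr), min(rows, rows - dr)
    c0, c1 = max(0, -dc), min(cols, cols - dc)
    first = q_image.data[r0:r1, c0:c1]
    second = q_image.data[r0 + dr : r1 + dr, c0 + dc : c1 + dc]
    L = q_image.levels
    counts = np.bincount(
        (first * L + second).ravel(), minlength=L * L
    ).reshape(L, L)
    probabilities = None
    if normalize:
        total = counts.sum()
        probabilities = counts / total if total > 0 else counts.astype(float)
    return CooccurrenceMatrix(
        counts=counts, offset=offset, normalized=normalize, probabilities=probabilities
    )


def glcm_marginals(glcm: CooccurrenceMatrix) -> GlcmMarginals:
    """Mean and SD of the row/column index marginals of a normalized GLCM."""
    P = glcm.P
    L = glcm.levels
    idx = np.arange(L, dtype=float)
    p_row = P.sum(axis=1)
    p_col = P.sum(axis=0)
    mu_e = float(idx @ p_row)
    mu_g = float(idx @ p_col)
    sigma_e = float(np.sqrt(((idx - mu_e) ** 2) @ p_row))
    sigma_g = float(np.sqrt(((idx - mu_g) ** 2) @ p_col))
    return GlcmMarginals(mu_e, mu_g, sigma_e, sigma_g)


def texture_features(glcm: CooccurrenceMatrix) -> TextureFeatureVector:
    """The ten co-occurrence statistics of one normalized GLCM.

    Entropy uses base-2 logarithm with the 0*log(0) = 0 continuity
    convention; correlation with a degenerate marginal (sigma_e*sigma_g = 0)
    is reported as 0 with ``degenerate_correlation=True``.
    """
    P = glcm.P
    L = glcm.levels
    q = np.arange(L, dtype=float)[:, None]
    z = np.arange(L, dtype=float)[None, :]
    marg = glcm_marginals(glcm)

    AC = float(np.sum(q * z * P))
    CT = float(np.sum((q - z) ** 2 * P))
    centered = q + z - marg.mu_e - marg.mu_g
    CP = float(np.sum(centered**4 * P))
    CS = float(np.sum(centered**3 * P))
    D = float(np.sum(np.abs(q - z) * P))
    EN = float(np.sum(P**2))
    nz = P[P > 0]
    ET = float(-np.sum(nz * np.log2(nz)))
    H = float(np.sum(P / (1.0 + np.abs(q - z))))
    MP = float(P.max())

    degenerate = marg.sigma_e * marg.sigma_g == 0
    if degenerate:
        CR = 0.0
    else:
        CR = float(
            np.sum((q - marg.mu_e) * (z - marg.mu_g) * P)
            / (marg.sigma_e * marg.sigma_g)
        )
    return TextureFeatureVector(
        AC=AC, CT=CT, CR=CR, CP=CP, CS=CS, D=D, EN=EN, ET=ET, H=H, MP=MP,
        degenerate_correlation=degenerate,
    )


def extract_fglcm(
    image: np.ndarray,
    levels: int = 32,
    delta: int = 1,
    symmetric: bool = False,
) -> TextureFeatureVector:
    """Orientation-averaged co-occurrence features of a grayscale image.

    Quantize, build the GLCM at the four sweep offsets, compute the ten
    statistics per offset, and take the arithmetic mean over offsets.
    ``symmetric=True`` adds the transposed counts before normalizing
    (the symmetric-accumulation convention).
    """
    q_image = quantize(image, levels)
    vectors = []
    any_degenerate = False
    for offset in sweep_offsets(delta):
        glcm = compute_glcm(q_image, offset, normalize=not symmetric)
        if symmetric:
            counts = glcm.counts + glcm.counts.T
            total = counts.sum()
            glcm = CooccurrenceMatrix(
                counts=counts,
                offset=offset,
                normalized=True,
                probabilities=counts / total if total > 0 else counts.astype(float),
            )
        feats = texture_features(glcm)
        any_degenerate |= feats.degenerate_correlation
        vectors.append(feats.as_array())
    mean = np.mean(vectors, axis=0)
    return TextureFeatureVector.from_array(mean, degenerate=any_degenerate)
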