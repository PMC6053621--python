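"""Patch descriptors: CCV (colour), GLCM statistics (texture), EHD (edges).

Each 20x20 patch is summarised by three complementary blocks that are
concatenated into one row of the feature matrix [f1C | f2G | f3E]:

* **CCV** — colour coherence vector: per quantized colour, counts of
  coherent pixels (members of an 8-connected same-colour component of size
  >= tau) and incoherent pixels, after a light 3x3 mean blur.
* **GLCM** — five statistics (contrast, correlation, energy, homogeneity,
  entropy) of symmetric, normalized gray-level co-occurrence matrices at the
  configured (distance, angle) offsets.
* **EHD** — the MPEG-7 edge histogram: the patch is split into a grid of
  subimages, each tiled with 2x2 blocks; the five edge operators (vertical,
  horizontal, 45, 135, non-directional) vote per block when the strongest
  response clears a threshold, and votes are normalized by block count.

All extractors are pure and deterministic.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage.feature import graycomatrix

__all__ = [
    "FeatureConfig",
    "FeatureMatrix",
    "ccv",
    "glcm_features",
    "ehd",
    "feature_matrix",
    "luminance",
    "EHD_OPERATORS",
]

# ITU-R BT.601 luma weights; fixed so results are bit-exact across platforms.
_LUMA = np.array([0.299, 0.587, 0.114])

# MPEG-7 edge operators on 2x2 block means, in fixed order:
# vertical, horizontal, diagonal 45deg, diagonal 135deg, non-directional.
_S2 = np.sqrt(2.0)
EHD_OPERATORS = np.array(
    [
        [[1.0, -1.0], [1.0, -1.0]],
        [[1.0, 1.0], [-1.0, -1.0]],
        [[_S2, 0.0], [0.0, -_S2]],
        [[0.0, _S2], [-_S2, 0.0]],
        [[2.0, -2.0], [-2.0, 2.0]],
    ]
)

_GLCM_STATS = ("contrast", "correlation", "energy", "homogeneity", "entropy")


@dataclass(frozen=True)
class FeatureConfig:
    """Descriptor parameters (the field-standard defaults; D = 228).

    CCV: 4 bins/channel (64 quantized colours), coherence threshold 4 px
    (1% of the patch area, the usual CCV convention).  GLCM: 16 gray levels,
    distance 1 at 0/45/90/135 degrees.  EHD: 4x4 subimage grid with the
    MPEG-7 vote threshold 11.
    """

    ccv_bins_per_channel: int = 4
    ccv_coherence_threshold: int = 4
    ccv_blur: bool = True
    glcm_levels: int = 16
    glcm_offsets: tuple[tuple[int, int], ...] = ((1, 0), (1, 45), (1, 90), (1, 135))
    glcm_stats: tuple[str, ...] = _GLCM_STATS
    ehd_grid: int = 4
    ehd_edge_threshold: float = 11.0
    patch_size: int = 20

    def __post_init__(self) -> None:
        if self.ccv_bins_per_channel < 1 or self.ccv_coherence_threshold < 1:
            raise ValueError("CCV bins and coherence threshold must be >= 1")
        if self.glcm_levels < 2:
            raise ValueError("glcm_levels must be >= 2")
        if not self.glcm_offsets or not self.glcm_stats:
            raise ValueError("GLCM offsets and stats must be nonempty")
        unknown = set(self.glcm_stats) - set(_GLCM_STATS)
        if unknown:
            raise ValueError(f"unknown GLCM statistics: {sorted(unknown)}")
        if self.ehd_grid < 1 or self.ehd_grid * 2 > self.patch_size:
            raise ValueError("ehd_grid^2 subimages (each >= 2x2) must fit in the patch")

    @property
    def ccv_dim(self) -> int:
        return 2 * self.ccv_bins_per_channel**3

    @property
    def glcm_dim(self) -> int:
        return len(self.glcm_stats) * len(self.glcm_offsets)

    @property
    def ehd_dim(self) -> int:
        return 5 * self.ehd_grid**2

    @property
    def total_dim(self) -> int:
        return self.ccv_dim + self.glcm_dim + self.ehd_dim


@dataclass
class FeatureMatrix:
    """samples x D block matrix with named block spans (half-open)."""

    values: np.ndarray
    block_spans: dict[str, tuple[int, int]]

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_features(self) -> int:
        return self.values.shape[1]

    def block(self, name: str) -> np.ndarray:
        lo, hi = self.block_spans[name]
        return self.values[:, lo:hi]

    def column_names(self) -> list[str]:
        names = [""] * self.n_features
        for block, (lo, hi) in self.block_spans.items():
            for j in range(lo, hi):
                names[j] = f"{block}.{j - lo}"
        return names

    def to_csv(self, path) -> None:
        """Write the matrix with block.dimension column headers."""
        import pandas as pd

        pd.DataFrame(self.values, columns=self.column_names()).to_csv(path, index=False)


def luminance(patch: np.ndarray) -> np.ndarray:
    """BT.601 luma of an 8-bit RGB patch, float in [0, 255]."""
    return patch.astype(float) @ _LUMA


def _quantize_colors(patch: np.ndarray, bins: int, blur: bool) -> np.ndarray:
    # exact integer arithmetic: the 3x3 mean (edge-replicating borders) is
    # kept as a window sum, and quantization compares sum*bins against
    # 256*9, so no float rounding can flip a bin at a boundary
    img = patch.astype(np.int64)
    if blur:
        padded = np.pad(img, ((1, 1), (1, 1), (0, 0)), mode="symmetric")
        total = np.zeros_like(img)
        for dr in range(3):
            for dc in range(3):
                total += padded[dr : dr + img.shape[0], dc : dc + img.shape[1]]
        q = np.clip(total * bins // (256 * 9), 0, bins - 1)
    else:
        q = np.clip(img * bins // 256, 0, bins - 1)
    return q[:, :, 0] * bins * bins + q[:, :, 1] * bins + q[:, :, 2]


def ccv(patch: np.ndarray, config: FeatureConfig = FeatureConfig()) -> np.ndarray:
    """Colour coherence vector, interleaved (coherent_b, incoherent_b)."""
    if patch.dtype != np.uint8:
        raise ValueError("patch must be 8-bit RGB")
    bins = config.ccv_bins_per_channel
    tau = config.ccv_coherence_threshold
    colors = _quantize_colors(patch, bins, config.ccv_blur)
    out = np.zeros(2 * bins**3)
    struct8 = np.ones((3, 3), dtype=bool)
    for c in np.unique(colors):
        comp, n = ndimage.label(colors == c, structure=struct8)
        sizes = np.bincount(comp.ravel())[1:]
        out[2 * c] = sizes[sizes >= tau].sum()
        out[2 * c + 1] = sizes[sizes < tau].sum()
    return out


def _glcm_stat_values(p: np.ndarray, stats: tuple[str, ...]) -> list[float]:
    levels = p.shape[0]
    i = np.arange(levels)[:, None].astype(float)
    j = np.arange(levels)[None, :].astype(float)
    vals = []
    for s in stats:
        if s == "contrast":
            vals.append(float((p * (i - j) ** 2).sum()))
        elif s == "energy":
            vals.append(float((p**2).sum()))
        elif s == "homogeneity":
            vals.append(float((p / (1.0 + (i - j) ** 2)).sum()))
        elif s == "entropy":
            nz = p[p > 0]
            vals.append(float(-(nz * np.log2(nz)).sum()))
        else:  # correlation; 0 by convention for zero-variance patches
            mi = float((p * i).sum())
            mj = float((p * j).sum())
            vi = float((p * (i - mi) ** 2).sum())
            vj = float((p * (j - mj) ** 2).sum())
            if vi <= 0 or vj <= 0:
                vals.append(0.0)
            else:
                vals.append(float((p * (i - mi) * (j - mj)).sum() / np.sqrt(vi * vj)))
    return vals


def _quantize_gray(patch: np.ndarray, levels: int) -> np.ndarray:
    lum = luminance(patch)
    return np.clip((lum * levels / 256.0).astype(int), 0, levels - 1).astype(np.uint8)


def glcm_features(patch: np.ndarray, config: FeatureConfig = FeatureConfig()) -> np.ndarray:
    """GLCM statistics per (distance, angle) offset, offsets-major order."""
    if patch.dtype != np.uint8:
        raise ValueError("patch must be 8-bit")
    q = _quantize_gray(patch, config.glcm_levels)
    vals: list[float] = []
    for dist, angle_deg in config.glcm_offsets:
        p = graycomatrix(
            q,
            distances=[dist],
            angles=[np.deg2rad(angle_deg)],
            levels=config.glcm_levels,
            symmetric=True,
            normed=True,
        )[:, :, 0, 0]
        vals.extend(_glcm_stat_values(p, config.glcm_stats))
    return np.array(vals)


def ehd(patch: np.ndarray, config: FeatureConfig = FeatureConfig()) -> np.ndarray:
    """MPEG-7 edge histogram, 5 bins per subimage, subimage-major order."""
    if patch.dtype != np.uint8:
        raise ValueError("patch must be 8-bit")
    g = config.ehd_grid
    lum = luminance(patch)
    sub = patch.shape[0] // g
    nb = sub // 2  # 2x2 blocks per subimage side; leftover rows/cols ignored
    hist = np.zeros((g * g, 5))
    for si in range(g):
        for sj in range(g):
            tile = lum[si * sub : (si + 1) * sub, sj * sub : (sj + 1) * sub]
            for bi in range(nb):
                for bj in range(nb):
                    block = tile[2 * bi : 2 * bi + 2, 2 * bj : 2 * bj + 2]
                    resp = np.abs((EHD_OPERATORS * block[None]).sum(axis=(1, 2)))
                    k = int(np.argmax(resp))
                    if resp[k] >= config.ehd_edge_threshold:
                        hist[si * g + sj, k] += 1
    return (hist / (nb * nb)).ravel()


def feature_matrix(patchset, config: FeatureConfig = FeatureConfig()) -> FeatureMatrix:
    """One row per patch; blocks ordered f1C, f2G, f3E with recorded spans."""
    if len(patchset) == 0:
        raise ValueError("patchset is empty")
    rows = []
    for idx, patch in enumerate(patchset.patches):
        try:
            rows.append(np.concatenate([ccv(patch, config),
                                        glcm_features(patch, config),
                                        ehd(patch, config)]))
        except Exception as exc:
            raise type(exc)(f"patch {idx}: {exc}") from exc
    values = np.asarray(rows)
    if not np.isfinite(values).all():
        raise ValueError("non-finite feature values")
    d1, d2 = config.ccv_dim, config.glcm_dim
    spans = {
        "f1C": (0, d1),
        "f2G": (d1, d1 + d2),
        "f3E": (d1 + d2, config.total_dim),
    }
    return FeatureMatrix(values=values, block_spans=spans)
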