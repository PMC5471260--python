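"""3D radiomic feature extraction on mask-restricted CT volumes.

The original-image inventory is the classic 48-feature set:

* 13 shape features (mesh volume/area based, PCA axis based),
* 12 first-order intensity statistics,
* 23 textural features: 17 from the gray-level co-occurrence matrix (GLCM),
  1 from the gray-level size-zone matrix (GLSZM, size-zone variability) and
  5 run-length (RLGL) features.

Each filtered image (LoG scale or wavelet sub-band) contributes the 12
statistics and 23 textural features again; shape is filter-invariant and
computed once.  Feature names are ``<filter>.<family>.<feature>`` with
filter ``orig``, ``log.sigma<s>`` or ``wv.<subband>``.

Texture matrices use a fixed-bin-width discretization (default 25 HU)
anchored at the in-mask minimum, 13 unique 3D directions at distance 1 for
GLCM/RLGL (features averaged over directions), and 26-connected zones for
the GLSZM.  Declared-undefined values (e.g. GLCM correlation or skewness on
a constant region) are NaN and logged; downstream statistics exclude them
pairwise.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage
from scipy.spatial import ConvexHull, QhullError
from scipy.spatial.distance import pdist
from skimage.measure import marching_cubes, mesh_surface_area
from sklearn.base import BaseEstimator, TransformerMixin

from .filters import FilterBankConfig, apply_filter_bank
from .volume import RegionMask, VoxelVolume, require_extractable

__all__ = [
    "DiscretizedRegion",
    "DIRECTIONS_3D",
    "discretize",
    "shape_features",
    "intensity_statistics",
    "glcm_features",
    "glcm_matrix",
    "glszm_size_zone_variability",
    "glszm_matrix",
    "rlgl_features",
    "extract_features",
    "RadiomicFeatureExtractor",
    "SHAPE_FEATURES",
    "STATS_FEATURES",
    "GLCM_FEATURES",
    "RLGL_FEATURES",
    "feature_names",
]

logger = logging.getLogger(__name__)

#: the 13 unique 3D offsets (one per +/- direction pair)
DIRECTIONS_3D: tuple[tuple[int, int, int], ...] = tuple(
    (dx, dy, dz)
    for dx in (-1, 0, 1)
    for dy in (-1, 0, 1)
    for dz in (-1, 0, 1)
    if (dx, dy, dz) > (0, 0, 0) or (dx > 0)
)
assert len(DIRECTIONS_3D) == 13

SHAPE_FEATURES = (
    "volume",
    "surface_area",
    "sphericity",
    "compactness1",
    "compactness2",
    "spherical_disproportion",
    "surface_to_volume_ratio",
    "max_3d_diameter",
    "major_axis_length",
    "minor_axis_length",
    "least_axis_length",
    "elongation",
    "flatness",
)

STATS_FEATURES = (
    "energy",
    "entropy",
    "kurtosis",
    "maximum",
    "mean",
    "mean_absolute_deviation",
    "median",
    "minimum",
    "range",
    "root_mean_square",
    "skewness",
    "standard_deviation",
)

GLCM_FEATURES = (
    "autocorrelation",
    "cluster_prominence",
    "cluster_shade",
    "cluster_tendency",
    "contrast",
    "correlation",
    "difference_entropy",
    "dissimilarity",
    "energy",
    "entropy",
    "homogeneity",
    "inverse_difference_moment",
    "inverse_variance",
    "maximum_probability",
    "sum_average",
    "sum_entropy",
    "sum_variance",
)

RLGL_FEATURES = (
    "short_run_emphasis",
    "long_run_emphasis",
    "gray_level_nonuniformity",
    "run_length_nonuniformity",
    "run_percentage",
)


# --------------------------------------------------------------------------
# discretization

@dataclass
class DiscretizedRegion:
    """In-mask voxels labeled with contiguous gray levels 1..Ng.

    ``levels`` is a full-grid integer array; 0 is the out-of-mask sentinel.
    Level(v) = floor((HU(v) - hu_min) / bin_width) + 1 with hu_min the
    in-mask minimum, so the labeling is invariant to HU shifts.
    """

    levels: np.ndarray
    n_levels: int
    bin_width_hu: float
    hu_min: float

    @property
    def mask(self) -> np.ndarray:
        return self.levels > 0

    @property
    def n_voxels(self) -> int:
        return int((self.levels > 0).sum())


def discretize(volume: VoxelVolume, mask: RegionMask, bin_width_hu: float = 25.0) -> DiscretizedRegion:
    if bin_width_hu <= 0:
        raise ValueError("bin width must be positive")
    require_extractable(volume, mask)
    m = mask.voxels
    vals = volume.intensities[m].astype(float)
    hu_min = float(vals.min())
    levels = np.zeros(volume.shape, dtype=np.int32)
    levels[m] = np.floor((volume.intensities[m] - hu_min) / bin_width_hu).astype(np.int64) + 1
    return DiscretizedRegion(levels, int(levels.max()), float(bin_width_hu), hu_min)


# --------------------------------------------------------------------------
# shape

#: pre-mesh smoothing scale; the 0.5 level-set of the smoothed mask removes
#: the staircase-facet area bias of a raw binary marching-cubes mesh
_MESH_SMOOTH_SIGMA_MM = 0.6


def _surface_area(mask: np.ndarray, spacing: tuple[float, float, float]) -> float:
    pad = [int(np.ceil(3 * _MESH_SMOOTH_SIGMA_MM / d)) + 1 for d in spacing]
    padded = np.pad(mask.astype(float), [(p, p) for p in pad])
    smoothed = ndimage.gaussian_filter(
        padded, sigma=[_MESH_SMOOTH_SIGMA_MM / d for d in spacing]
    )
    # tiny structures get smoothed below the level set; mesh the raw mask then
    source = smoothed if smoothed.max() > 0.65 else padded
    verts, faces, _, _ = marching_cubes(source, level=0.5, spacing=spacing)
    area = float(mesh_surface_area(verts, faces))
    # isoperimetric floor: no body of volume V has less area than the sphere;
    # guards degenerate meshes so sphericity cannot exceed 1
    v_total = float(mask.sum()) * float(np.prod(spacing))
    return max(area, (36.0 * np.pi * v_total**2) ** (1.0 / 3.0))


def _max_diameter(coords: np.ndarray) -> float:
    """Largest pairwise distance between boundary voxel centers (mm)."""
    if len(coords) == 1:
        return 0.0
    pts = coords
    if len(coords) >= 8:
        try:
            hull = ConvexHull(coords)
            pts = coords[hull.vertices]
        except QhullError:  # degenerate (flat/collinear) point sets
            pass
    if len(pts) > 4000:  # chunked fallback, avoids a huge pdist
        best = 0.0
        for i in range(0, len(pts), 512):
            d = np.linalg.norm(pts[i:i + 512, None, :] - pts[None, :, :], axis=-1)
            best = max(best, float(d.max()))
        return best
    return float(pdist(pts).max())


def shape_features(mask: RegionMask, spacing: tuple[float, float, float] | None = None) -> dict[str, float]:
    """The 13 shape features of a binary tumor mask (physical units, mm)."""
    spacing = tuple(spacing if spacing is not None else mask.spacing)
    m = mask.voxels
    n = int(m.sum())
    if n < 1:
        raise ValueError("empty mask")
    voxel_vol = float(np.prod(spacing))
    V = n * voxel_vol
    A = _surface_area(m, spacing)
    sphericity = np.pi ** (1.0 / 3.0) * (6.0 * V) ** (2.0 / 3.0) / A
    R = (3.0 * V / (4.0 * np.pi)) ** (1.0 / 3.0)

    idx = np.argwhere(m).astype(float) * np.asarray(spacing)
    eroded = ndimage.binary_erosion(m)
    boundary = np.argwhere(m & ~eroded).astype(float) * np.asarray(spacing)

    if n >= 2:
        cov = np.cov(idx, rowvar=False)
        eigvals = np.sort(np.linalg.eigvalsh(cov))[::-1]
        eigvals = np.clip(eigvals, 0.0, None)
        major, minor, least = (4.0 * np.sqrt(eigvals)).tolist()
        elong = float(np.sqrt(eigvals[1] / eigvals[0])) if eigvals[0] > 0 else np.nan
        flat = float(np.sqrt(eigvals[2] / eigvals[0])) if eigvals[0] > 0 else np.nan
    else:
        major = minor = least = 0.0
        elong = flat = np.nan
        logger.info("single-voxel mask: elongation/flatness undefined")

    return {
        "volume": V,
        "surface_area": A,
        "sphericity": float(sphericity),
        "compactness1": float(V / (np.sqrt(np.pi) * A ** 1.5)),
        "compactness2": float(36.0 * np.pi * V**2 / A**3),
        "spherical_disproportion": float(A / (4.0 * np.pi * R**2)),
        "surface_to_volume_ratio": float(A / V),
        "max_3d_diameter": _max_diameter(boundary),
        "major_axis_length": major,
        "minor_axis_length": minor,
        "least_axis_length": least,
        "elongation": elong,
        "flatness": flat,
    }


# --------------------------------------------------------------------------
# first-order statistics

def intensity_statistics(volume: VoxelVolume, mask: RegionMask,
                         entropy_bin_width_hu: float = 25.0) -> dict[str, float]:
    """The 12 first-order statistics of in-mask intensities.

    Entropy uses a fixed-width histogram (default 25 HU) anchored at the
    in-mask minimum; standard deviation is the population form; skewness and
    excess kurtosis are undefined (NaN) on constant regions.
    """
    require_extractable(volume, mask)
    v = volume.intensities[mask.voxels].astype(float)
    mean = float(v.mean())
    sd = float(v.std(ddof=0))
    centered = v - mean
    if sd > 0:
        skew = float((centered**3).mean() / sd**3)
        kurt = float((centered**4).mean() / sd**4 - 3.0)
    else:
        skew = kurt = np.nan
        logger.info("constant region: skewness/kurtosis undefined")
    edges = np.arange(v.min(), v.max() + 2 * entropy_bin_width_hu, entropy_bin_width_hu)
    p = np.histogram(v, bins=edges)[0].astype(float)
    p = p[p > 0] / p.sum()
    return {
        "energy": float((v**2).sum()),
        "entropy": float(-(p * np.log2(p)).sum()),
        "kurtosis": kurt,
        "maximum": float(v.max()),
        "mean": mean,
        "mean_absolute_deviation": float(np.abs(centered).mean()),
        "median": float(np.median(v)),
        "minimum": float(v.min()),
        "range": float(v.max() - v.min()),
        "root_mean_square": float(np.sqrt((v**2).mean())),
        "skewness": skew,
        "standard_deviation": sd,
    }


# --------------------------------------------------------------------------
# GLCM

def _offset_slices(shape, offset):
    """Slice pair (src, dst) addressing voxel pairs at the given offset."""
    src, dst = [], []
    for n, d in zip(shape, offset):
        if d >= 0:
            src.append(slice(0, n - d))
            dst.append(slice(d, n))
        else:
            src.append(slice(-d, n))
            dst.append(slice(0, n + d))
    return tuple(src), tuple(dst)


def glcm_matrix(disc: DiscretizedRegion, offset: tuple[int, int, int]) -> np.ndarray:
    """Symmetric normalized GLCM for one (direction x distance) offset.

    Returns the Ng x Ng probability matrix; all-zero if the offset yields no
    in-mask voxel pair.
    """
    L = disc.levels
    src, dst = _offset_slices(L.shape, offset)
    a, b = L[src].ravel(), L[dst].ravel()
    ok = (a > 0) & (b > 0)
    a, b = a[ok] - 1, b[ok] - 1
    ng = disc.n_levels
    counts = np.bincount(a * ng + b, minlength=ng * ng).reshape(ng, ng).astype(float)
    counts += counts.T  # symmetric accumulation
    total = counts.sum()
    return counts / total if total > 0 else counts


def _glcm_features_single(p: np.ndarray) -> dict[str, float]:
    ng = p.shape[0]
    i = np.arange(1, ng + 1, dtype=float)
    I, J = np.meshgrid(i, i, indexing="ij")
    px = p.sum(axis=1)  # == py by symmetry
    mu = float((i * px).sum())
    var = float(((i - mu) ** 2 * px).sum())

    eps_log = lambda q: np.log2(q, out=np.zeros_like(q), where=q > 0)  # noqa: E731

    autocorr = float((I * J * p).sum())
    ipj = I + J
    imj = np.abs(I - J)
    # p_{x+y}(k), k = 2..2Ng ; p_{x-y}(k), k = 0..Ng-1
    pxpy = np.bincount((I + J).astype(int).ravel(), weights=p.ravel())[2:]
    pxmy = np.bincount(np.abs(I - J).astype(int).ravel(), weights=p.ravel())
    k_sum = np.arange(2, 2 * ng + 1, dtype=float)
    sum_avg = float((k_sum * pxpy).sum())

    out = {
        "autocorrelation": autocorr,
        "cluster_prominence": float(((ipj - 2 * mu) ** 4 * p).sum()),
        "cluster_shade": float(((ipj - 2 * mu) ** 3 * p).sum()),
        "cluster_tendency": float(((ipj - 2 * mu) ** 2 * p).sum()),
        "contrast": float(((I - J) ** 2 * p).sum()),
        "correlation": float((autocorr - mu * mu) / var) if var > 0 else np.nan,
        "difference_entropy": float(-(pxmy * eps_log(pxmy)).sum()),
        "dissimilarity": float((imj * p).sum()),
        "energy": float((p**2).sum()),
        "entropy": float(-(p * eps_log(p)).sum()),
        "homogeneity": float((p / (1.0 + imj)).sum()),
        "inverse_difference_moment": float((p / (1.0 + (I - J) ** 2)).sum()),
        "inverse_variance": float((p[imj > 0] / imj[imj > 0] ** 2).sum()),
        "maximum_probability": float(p.max()),
        "sum_average": sum_avg,
        "sum_entropy": float(-(pxpy * eps_log(pxpy)).sum()),
        "sum_variance": float(((k_sum - sum_avg) ** 2 * pxpy).sum()),
    }
    return out


def glcm_features(disc: DiscretizedRegion, distance: int = 1) -> dict[str, float]:
    """The 17 GLCM features averaged over the 13 unique 3D directions.

    Directions contributing no voxel pair are excluded from the average; the
    correlation feature is NaN for directions with zero gray-level variance
    and averaged over the defined directions only.
    """
    if distance < 1:
        raise ValueError("GLCM distance must be >= 1")
    per_dir: list[dict[str, float]] = []
    for d in DIRECTIONS_3D:
        offset = tuple(distance * c for c in d)
        p = glcm_matrix(disc, offset)
        if p.sum() > 0:
            per_dir.append(_glcm_features_single(p))
    if not per_dir:
        logger.warning("no valid voxel pair in any GLCM direction; features NaN")
        return {k: np.nan for k in GLCM_FEATURES}
    out = {}
    for k in GLCM_FEATURES:
        vals = np.array([f[k] for f in per_dir], dtype=float)
        defined = vals[~np.isnan(vals)]
        out[k] = float(defined.mean()) if defined.size else np.nan
    return out


# --------------------------------------------------------------------------
# GLSZM

_STRUCT_26 = np.ones((3, 3, 3), dtype=bool)


def glszm_matrix(disc: DiscretizedRegion) -> dict[int, np.ndarray]:
    """Zone sizes per gray level: level -> array of 26-connected zone sizes."""
    zones: dict[int, np.ndarray] = {}
    for g in range(1, disc.n_levels + 1):
        binary = disc.levels == g
        if not binary.any():
            continue
        lab, nz = ndimage.label(binary, structure=_STRUCT_26)
        sizes = np.bincount(lab.ravel())[1:]
        zones[g] = sizes
    return zones


def glszm_size_zone_variability(disc: DiscretizedRegion) -> float:
    """Size-zone variability: (1/Nz) * sum_s (number of zones of size s)^2.

    Large when zone sizes repeat (many equal-size zones), i.e. for
    fragmented, heterogeneous regions.
    """
    zones = glszm_matrix(disc)
    all_sizes = np.concatenate([s for s in zones.values()])
    nz = all_sizes.size
    per_size = np.bincount(all_sizes)
    return float((per_size.astype(float) ** 2).sum() / nz)


# --------------------------------------------------------------------------
# run length

def _runs_along(disc: DiscretizedRegion, direction: tuple[int, int, int]):
    """(levels, lengths) of maximal in-mask same-level runs along a direction.

    Voxels are sorted into lines (a line = maximal lattice path along the
    direction); a run breaks on line change, on a gap in the mask, or on a
    gray-level change.
    """
    L = disc.levels
    coords = np.argwhere(L > 0)
    lev = L[L > 0].astype(np.int64)
    d = np.asarray(direction)
    t = coords @ d  # strictly increasing by 1 along a line... up to |d|^2
    # parametrize: along a line v = start + k*d, (v . d) increments by |d|^2
    step = int(d @ d)
    k = t // step  # integer "position" along the line (t = const mod step? no)
    # line id: v - k*d identifies the line uniquely; keep t for gap detection
    base = coords - np.outer(t // step, d)  # may mix lines if t not multiple
    # correct parametrization: k such that v - k*d is constant per line.
    # v . d = (base . d) + k*step -> k = (t - base.d)/step; using k = t//step
    # gives base = v - (t//step)*d which IS constant along the line because
    # consecutive line voxels differ by exactly d (t by step).
    order = np.lexsort((k, base[:, 2], base[:, 1], base[:, 0]))
    base_s, k_s, lev_s = base[order], k[order], lev[order]
    new_line = np.ones(len(k_s), dtype=bool)
    if len(k_s) > 1:
        same = np.all(base_s[1:] == base_s[:-1], axis=1)
        contiguous = k_s[1:] == k_s[:-1] + 1
        same_lev = lev_s[1:] == lev_s[:-1]
        new_line[1:] = ~(same & contiguous & same_lev)
    run_id = np.cumsum(new_line) - 1
    lengths = np.bincount(run_id)
    run_levels = lev_s[new_line]
    return run_levels, lengths


def rlgl_features(disc: DiscretizedRegion) -> dict[str, float]:
    """The 5 run-length features averaged over the 13 unique 3D directions."""
    n_vox = disc.n_voxels
    acc = {k: [] for k in RLGL_FEATURES}
    for d in DIRECTIONS_3D:
        levels, lengths = _runs_along(disc, d)
        r = lengths.astype(float)
        nr = float(len(r))
        gl_counts = np.bincount(levels)
        rl_counts = np.bincount(lengths)
        acc["short_run_emphasis"].append(float((1.0 / r**2).sum() / nr))
        acc["long_run_emphasis"].append(float((r**2).sum() / nr))
        acc["gray_level_nonuniformity"].append(float((gl_counts.astype(float) ** 2).sum() / nr))
        acc["run_length_nonuniformity"].append(float((rl_counts.astype(float) ** 2).sum() / nr))
        acc["run_percentage"].append(nr / n_vox)
    return {k: float(np.mean(v)) for k, v in acc.items()}


# --------------------------------------------------------------------------
# assembly

def feature_names(filter_config: FilterBankConfig | None = None) -> list[str]:
    """Deterministic column inventory for a given filter configuration."""
    names = [f"orig.shape.{f}" for f in SHAPE_FEATURES]
    names += [f"orig.stats.{f}" for f in STATS_FEATURES]
    names += _texture_names("orig")
    if filter_config is not None:
        for filt in filter_config.filter_names:
            names += [f"{filt}.stats.{f}" for f in STATS_FEATURES]
            names += _texture_names(filt)
    return names


def _texture_names(prefix: str) -> list[str]:
    names = [f"{prefix}.glcm.{f}" for f in GLCM_FEATURES]
    names.append(f"{prefix}.glszm.size_zone_variability")
    names += [f"{prefix}.rlgl.{f}" for f in RLGL_FEATURES]
    return names


def _stats_and_texture(volume: VoxelVolume, mask: RegionMask, prefix: str,
                       bin_width_hu: float, glcm_distance: int) -> dict[str, float]:
    out = {f"{prefix}.stats.{k}": v
           for k, v in intensity_statistics(volume, mask, bin_width_hu).items()}
    disc = discretize(volume, mask, bin_width_hu)
    out.update({f"{prefix}.glcm.{k}": v for k, v in glcm_features(disc, glcm_distance).items()})
    out[f"{prefix}.glszm.size_zone_variability"] = glszm_size_zone_variability(disc)
    out.update({f"{prefix}.rlgl.{k}": v for k, v in rlgl_features(disc).items()})
    return out


def extract_features(
    volume: VoxelVolume,
    mask: RegionMask,
    filter_config: FilterBankConfig | None = None,
    bin_width_hu: float = 25.0,
    glcm_distance: int = 1,
) -> pd.Series:
    """Full feature vector for one subject.

    48 original-image features, plus 35 (12 statistics + 23 textural) per
    filtered image; discretization is recomputed per filtered image so the
    fixed bin width applies to each image's own dynamic range.
    """
    require_extractable(volume, mask)
    values: dict[str, float] = {}
    values.update({f"orig.shape.{k}": v for k, v in shape_features(mask, volume.spacing).items()})
    values.update(_stats_and_texture(volume, mask, "orig", bin_width_hu, glcm_distance))
    if filter_config is not None:
        for name, img in apply_filter_bank(volume, filter_config):
            values.update(_stats_and_texture(img, mask, name, bin_width_hu, glcm_distance))
    return pd.Series(values)[feature_names(filter_config)]


class RadiomicFeatureExtractor(BaseEstimator, TransformerMixin):
    """Transformer turning (volume, mask) subjects into a feature table.

    Parameters
    ----------
    filter_config : FilterBankConfig or None
        Filtered-image inventory; None extracts the 48 original features only.
    bin_width_hu : float
        Fixed discretization bin width for texture matrices and the
        first-order entropy histogram.
    glcm_distance : int
        Voxel-pair offset distance for the GLCM.

    The input ``X`` to :meth:`transform` is a sequence of subjects, each
    either a ``(VoxelVolume, RegionMask)`` pair or an object exposing
    ``.volume`` and ``.mask`` (and optionally ``.subject_id`` used as the
    row index).
    """

    def __init__(self, filter_config: FilterBankConfig | None = None,
                 bin_width_hu: float = 25.0, glcm_distance: int = 1):
        self.filter_config = filter_config
        self.bin_width_hu = bin_width_hu
        self.glcm_distance = glcm_distance

    def fit(self, X=None, y=None) -> "RadiomicFeatureExtractor":
        if self.bin_width_hu <= 0:
            raise ValueError("bin_width_hu must be positive")
        if self.glcm_distance < 1:
            raise ValueError("glcm_distance must be >= 1")
        self.feature_names_ = feature_names(self.filter_config)
        return self

    def get_feature_names_out(self, input_features=None):
        return np.asarray(self.feature_names_, dtype=object)

    @staticmethod
    def _unpack(item):
        if hasattr(item, "volume") and hasattr(item, "mask"):
            sid = getattr(item, "subject_id", None)
            if sid is None and hasattr(item, "semantic"):
                sid = item.semantic.subject_id
            return item.volume, item.mask, sid
        volume, mask = item
        return volume, mask, None

    def transform(self, X) -> pd.DataFrame:
        if not hasattr(self, "feature_names_"):
            self.fit()
        rows, index = [], []
        for i, item in enumerate(X):
            volume, mask, sid = self._unpack(item)
            rows.append(extract_features(volume, mask, self.filter_config,
                                         self.bin_width_hu, self.glcm_distance))
            index.append(sid if sid is not None else i)
        return pd.DataFrame(rows, index=pd.Index(index, name="subject_id"))
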