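"""Synthetic CT tumor phantoms driven by the nine semantic scores.

Each phantom is a star-convex radial body: the surface radius in direction
``u`` is ``r(u) = R_ell(u) * (1 + lobulation(u) + spiculation(u))`` where
``R_ell`` is an ellipsoidal base radius (eccentricity grows with the contour
score), the lobulation term is a random smooth low-angular-frequency field
and the spiculation term a high-frequency one, each with amplitude linear in
its semantic score.  Concavity subtracts spherical "bite" caps at the
surface, breaking star-convexity only locally.  The binary semantic features
carve or stamp internal structure: cavitation an air cavity (<= -900 HU),
air bronchogram an air tube, calcification small bright spots (<= 3 mm, so
they do not distort the overall structure).  Texture selects the interior
intensity regime (GGO < part-solid < solid median HU) with vessel-like
bright strands preserved in sub-solid tumors.  The border is blurred with a
Gaussian whose sigma grows with the border-definition score, then Gaussian
noise is added.

The mask is the rendered support *before* blurring; background is lung
parenchyma at -800 HU.  All randomness is keyed by the spec seed; cohort
generation derives subject seeds from the master seed by the counter scheme
``SeedSequence([master_seed, subject_index])``.

The score-to-knob constants below were calibrated once so that the package's
direction properties hold (sphericity falls with lobulation, spiculation,
concavity and cavitation; size-zone variability and intensity heterogeneity
rise with cavitation; median HU rises with texture) and then frozen.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import ndimage

from .semantic import (
    SCORE_RANGES,
    SEMANTIC_FEATURES,
    CohortTable,
    SemanticRecord,
)
from .volume import RegionMask, VoxelVolume

__all__ = [
    "TABLE1_MARGINALS",
    "PhenotypeSpec",
    "PhantomSubject",
    "sample_semantic_scores",
    "build_phantom",
    "generate_cohort",
]

#: default score marginals: the study cohort's observed proportions (n=258)
TABLE1_MARGINALS: dict[str, dict[int, float]] = {
    "cavitation": {0: 106 / 258, 1: 152 / 258},
    "air_bronchogram": {0: 116 / 258, 1: 142 / 258},
    "calcification": {0: 229 / 258, 1: 29 / 258},
    "texture": {1: 6 / 258, 2: 68 / 258, 3: 184 / 258},
    "border_definition": {1: 13 / 258, 2: 178 / 258, 3: 67 / 258},
    "contour": {1: 17 / 258, 2: 26 / 258, 3: 166 / 258, 4: 49 / 258},
    "lobulation": {1: 10 / 258, 2: 115 / 258, 3: 102 / 258, 4: 31 / 258},
    "spiculation": {1: 63 / 258, 2: 85 / 258, 3: 110 / 258},
    "concavity": {1: 9 / 258, 2: 156 / 258, 3: 93 / 258},
}

# ---- frozen score-to-knob constants (per-unit-score, see module docstring)
LOBULATION_AMP_PER_SCORE = 0.09      # relative radius RMS per score step
SPICULATION_AMP_PER_SCORE = 0.03
CAVITATION_EXTRA_AMP = 0.12           # extra irregularity of cavitating tumors
CONTOUR_ECCENTRICITY_PER_SCORE = 0.09
CONCAVITY_DEPTH_PER_SCORE = 0.22      # bite depth, fraction of base radius
BORDER_BLUR_SIGMA_MM = {1: 0.3, 2: 0.8, 3: 1.5}
TEXTURE_BASE_HU = {1: -600.0, 2: -350.0, 3: 30.0}
BACKGROUND_HU = -800.0
AIR_HU = -1000.0
TUBE_HU = -950.0
NOISE_SD_HU = 30.0
NECROSIS_MOTTLE_SD_HU = 60.0          # density mottle of necrotic (cavitated) tumors
NECROSIS_MOTTLE_SCALE_MM = 0.8
CAVITY_FRACTION = 0.25                # cavity volume / tumor volume
CALCIFICATION_HU_RANGE = (300.0, 800.0)
CALCIFICATION_RADIUS_MM = (1.0, 1.5)  # spots stay small (<= 3 mm across)
BRONCHOGRAM_TUBE_RADIUS_MM = 1.2
STRAND_HU = -100.0                    # vessel-like strands in sub-solid tumors
STRAND_RADIUS_MM = 0.8


@dataclass
class PhenotypeSpec:
    """Ground-truth generator knobs for one phantom, derived from scores."""

    semantic: SemanticRecord
    base_radius_mm: float = 12.0
    seed: int = 0
    lobulation_amplitude: float = field(init=False)
    spiculation_amplitude: float = field(init=False)
    concavity_depth: float = field(init=False)
    contour_eccentricity: float = field(init=False)
    border_blur_sigma_mm: float = field(init=False)
    base_hu: float = field(init=False)
    noise_sd_hu: float = NOISE_SD_HU
    cavity_fraction: float = CAVITY_FRACTION
    calcification_count: int = field(init=False)
    bronchogram_tube_radius_mm: float = BRONCHOGRAM_TUBE_RADIUS_MM

    def __post_init__(self) -> None:
        if self.base_radius_mm <= 0:
            raise ValueError("base radius must be positive")
        s = self.semantic
        self.lobulation_amplitude = LOBULATION_AMP_PER_SCORE * (s.lobulation - 1)
        if s.cavitation:
            self.lobulation_amplitude += CAVITATION_EXTRA_AMP
        self.spiculation_amplitude = SPICULATION_AMP_PER_SCORE * (s.spiculation - 1)
        self.concavity_depth = CONCAVITY_DEPTH_PER_SCORE * (s.concavity - 1)
        self.contour_eccentricity = CONTOUR_ECCENTRICITY_PER_SCORE * (s.contour - 1)
        self.border_blur_sigma_mm = BORDER_BLUR_SIGMA_MM[s.border_definition]
        self.base_hu = TEXTURE_BASE_HU[s.texture]
        rng = np.random.default_rng(self.seed)
        self.calcification_count = int(rng.integers(1, 4)) if s.calcification else 0

    def max_radius_mm(self) -> float:
        """Conservative bound on the rendered tumor extent."""
        amp = 2.0 * (self.lobulation_amplitude + self.spiculation_amplitude)
        return self.base_radius_mm * (1.0 + self.contour_eccentricity) * (1.0 + amp)

    def to_dict(self) -> dict:
        return {
            "subject_id": self.semantic.subject_id,
            "semantic": self.semantic.as_dict(),
            "base_radius_mm": self.base_radius_mm,
            "seed": int(self.seed),
            "lobulation_amplitude": self.lobulation_amplitude,
            "spiculation_amplitude": self.spiculation_amplitude,
            "concavity_depth": self.concavity_depth,
            "contour_eccentricity": self.contour_eccentricity,
            "border_blur_sigma_mm": self.border_blur_sigma_mm,
            "base_hu": self.base_hu,
            "noise_sd_hu": self.noise_sd_hu,
            "cavity_fraction": self.cavity_fraction,
            "calcification_count": self.calcification_count,
            "bronchogram_tube_radius_mm": self.bronchogram_tube_radius_mm,
        }


@dataclass
class PhantomSubject:
    volume: VoxelVolume
    mask: RegionMask
    semantic: SemanticRecord
    truth: PhenotypeSpec

    @property
    def subject_id(self) -> str:
        return self.semantic.subject_id


def sample_semantic_scores(
    n: int,
    marginals: dict[str, dict[int, float]] | None = None,
    seed: int = 0,
) -> CohortTable:
    """Draw ``n`` independent semantic records from per-feature marginals.

    Defaults to the study cohort's observed score proportions.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    marg = dict(TABLE1_MARGINALS)
    if marginals:
        marg.update(marginals)
    for feat, probs in marg.items():
        legal = set(SCORE_RANGES[feat])
        if set(probs) - legal:
            raise ValueError(
                f"{feat}: marginal assigns mass to illegal scores "
                f"{sorted(set(probs) - legal)}"
            )
        if abs(sum(probs.values()) - 1.0) > 1e-9:
            raise ValueError(f"{feat}: marginal must sum to 1")
    rng = np.random.default_rng(seed)
    records = []
    for i in range(n):
        scores = {}
        for feat in SEMANTIC_FEATURES:
            keys = sorted(marg[feat])
            p = np.array([marg[feat][k] for k in keys])
            scores[feat] = int(rng.choice(keys, p=p / p.sum()))
        records.append(SemanticRecord(subject_id=f"S{i:04d}", **scores))
    return CohortTable(records)


def _angular_field(u: np.ndarray, rng: np.random.Generator,
                   freq_range: tuple[float, float], n_terms: int = 6) -> np.ndarray:
    """Random smooth unit-RMS field on directions ``u`` (N x 3 unit vectors).

    Sum of cosines of random plane waves restricted to the sphere; the wave
    number range sets the angular scale (low = lobes, high = spikes).
    """
    total = np.zeros(len(u))
    for _ in range(n_terms):
        k = rng.normal(size=3)
        k *= rng.uniform(*freq_range) / np.linalg.norm(k)
        phase = rng.uniform(0, 2 * np.pi)
        total += np.cos(u @ k + phase)
    # each cosine has variance 1/2 over the sphere
    return total / np.sqrt(n_terms / 2.0)


def build_phantom(
    spec: PhenotypeSpec,
    grid_shape: tuple[int, int, int] = (64, 64, 64),
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0),
) -> PhantomSubject:
    """Render one phantom volume + mask from a phenotype spec."""
    shape = tuple(int(g) for g in grid_shape)
    spacing = tuple(float(s) for s in spacing)
    half_extent = [0.5 * (g - 1) * d for g, d in zip(shape, spacing)]
    margin = [2 * d for d in spacing]
    needed = spec.max_radius_mm()
    if any(needed > he - m for he, m in zip(half_extent, margin)):
        min_shape = tuple(int(np.ceil(2 * (needed + m) / d)) + 1
                          for m, d in zip(margin, spacing))
        raise ValueError(
            f"tumor (max extent {needed:.1f} mm) does not fit grid {shape} with a "
            f"2-voxel margin; minimum grid shape {min_shape}"
        )

    rng = np.random.default_rng(spec.seed)
    s = spec.semantic
    R = spec.base_radius_mm

    axes = [np.arange(g) * d - he for g, d, he in zip(shape, spacing, half_extent)]
    X, Y, Z = np.meshgrid(*axes, indexing="ij")
    coords = np.stack([X, Y, Z], axis=-1)
    r = np.linalg.norm(coords, axis=-1)
    with np.errstate(invalid="ignore", divide="ignore"):
        u = coords / r[..., None]
    u[r == 0] = (1.0, 0.0, 0.0)

    # candidate shell: evaluate the angular fields only where they can matter
    shell = r <= spec.max_radius_mm() + max(spacing)
    uf = u[shell].reshape(-1, 3)
    lob = _angular_field(uf, rng, (2.0, 4.0)) * spec.lobulation_amplitude
    spic = _angular_field(uf, rng, (9.0, 14.0)) * spec.spiculation_amplitude

    e = spec.contour_eccentricity
    semiaxes = np.array([1.0 + e, 1.0, 1.0 / (1.0 + e)])
    r_ell = R / np.linalg.norm(uf / semiaxes, axis=1)
    # clip to the extent bound promised by max_radius_mm (2-RMS envelope)
    hi = 1.0 + 2.0 * (spec.lobulation_amplitude + spec.spiculation_amplitude)
    r_surf = r_ell * np.clip(1.0 + lob + spic, 0.2, hi)

    inside = np.zeros(shape, dtype=bool)
    inside[shell] = r[shell] <= r_surf

    # concavity: subtract spherical caps ("bites") at random surface points
    n_bites = s.concavity - 1
    for _ in range(n_bites):
        b = rng.normal(size=3)
        b /= np.linalg.norm(b)
        r_bite = 0.5 * R
        depth = spec.concavity_depth * R
        center_b = (R + r_bite - depth) * b
        inside &= np.linalg.norm(coords - center_b, axis=-1) >= r_bite

    if not inside.any():
        raise ValueError("degenerate spec: rendered tumor support is empty")
    mask = RegionMask(inside, spacing)

    # ---- intensities
    vol = np.full(shape, BACKGROUND_HU)
    vol[inside] = spec.base_hu
    if s.texture == 2:  # part-solid: solid core within the hazy interior
        core = r <= 0.55 * R
        vol[inside & core] = TEXTURE_BASE_HU[3]
    if s.texture in (1, 2):  # vessel-like bright strands survive in GGO
        for _ in range(3):
            p0 = rng.uniform(-0.4, 0.4, size=3) * R
            d = rng.normal(size=3)
            d /= np.linalg.norm(d)
            t = (coords - p0) @ d
            dist = np.linalg.norm(coords - p0 - t[..., None] * d, axis=-1)
            vol[inside & (dist <= STRAND_RADIUS_MM)] = STRAND_HU

    if s.cavitation:
        r_cav = spec.cavity_fraction ** (1.0 / 3.0) * R
        offset = rng.uniform(-0.15, 0.15, size=3) * R
        cavity = np.linalg.norm(coords - offset, axis=-1) <= r_cav
        # satellite air pockets: cavitation fragments the interior
        for _ in range(int(rng.integers(2, 5))):
            p0 = rng.uniform(-0.55, 0.55, size=3) * R
            r_b = rng.uniform(0.12, 0.3) * R
            cavity |= np.linalg.norm(coords - p0, axis=-1) <= r_b
        vol[inside & cavity] = AIR_HU

    if s.air_bronchogram:
        p0 = rng.uniform(-0.2, 0.2, size=3) * R
        d = rng.normal(size=3)
        d /= np.linalg.norm(d)
        t = (coords - p0) @ d
        dist = np.linalg.norm(coords - p0 - t[..., None] * d, axis=-1)
        vol[inside & (dist <= spec.bronchogram_tube_radius_mm)] = TUBE_HU

    for _ in range(spec.calcification_count):
        # spots inside the tumor, away from the surface
        p0 = rng.uniform(-0.5, 0.5, size=3) * R
        radius = rng.uniform(*CALCIFICATION_RADIUS_MM)
        hu = rng.uniform(*CALCIFICATION_HU_RANGE)
        spot = np.linalg.norm(coords - p0, axis=-1) <= radius
        vol[inside & spot] = hu

    sigma_vox = [spec.border_blur_sigma_mm / d for d in spacing]
    vol = ndimage.gaussian_filter(vol, sigma=sigma_vox, mode="nearest")
    if s.cavitation:
        # necrosis: fine-grained density mottle; applied after the border
        # blur because it is a tissue property, not an interface one
        mottle = ndimage.gaussian_filter(
            rng.normal(size=shape), sigma=[NECROSIS_MOTTLE_SCALE_MM / d for d in spacing]
        )
        vol[inside] += mottle[inside] * (NECROSIS_MOTTLE_SD_HU / mottle.std())
    vol += rng.normal(0.0, spec.noise_sd_hu, size=shape)

    return PhantomSubject(
        volume=VoxelVolume(vol, spacing),
        mask=mask,
        semantic=s,
        truth=spec,
    )


def subject_seed(master_seed: int, index: int) -> int:
    """Per-subject seed: counter scheme SeedSequence([master, index])."""
    return int(np.random.SeedSequence([int(master_seed), int(index)])
               .generate_state(1)[0] % (2**31))


def make_cohort(
    n: int,
    seed: int = 0,
    marginals: dict[str, dict[int, float]] | None = None,
    grid_shape: tuple[int, int, int] = (64, 64, 64),
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0),
    base_radius_range_mm: tuple[float, float] = (8.0, 11.0),
) -> list[PhantomSubject]:
    """Generate ``n`` phantoms in memory (no I/O)."""
    cohort = sample_semantic_scores(n, marginals, seed=seed)
    subjects = []
    for i, (sid, row) in enumerate(cohort.frame.iterrows()):
        sseed = subject_seed(seed, i)
        radius = float(np.random.default_rng(sseed).uniform(*base_radius_range_mm))
        record = SemanticRecord(subject_id=sid, **row.to_dict())
        spec = PhenotypeSpec(semantic=record, base_radius_mm=radius, seed=sseed)
        subjects.append(build_phantom(spec, grid_shape, spacing))
    return subjects


def generate_cohort(
    n: int,
    out_dir: str | Path,
    seed: int = 0,
    marginals: dict[str, dict[int, float]] | None = None,
    grid_shape: tuple[int, int, int] = (64, 64, 64),
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0),
    base_radius_range_mm: tuple[float, float] = (8.0, 11.0),
) -> CohortTable:
    """Generate and write a cohort: NIfTI volume/mask pairs, semantic CSV,
    ground-truth JSON.  Deterministic under the master seed."""
    from . import io as rio  # local import: keep the generator importable alone

    if n < 1:
        raise ValueError("n must be >= 1")
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    subjects = make_cohort(n, seed, marginals, grid_shape, spacing,
                           base_radius_range_mm)
    truth = []
    for subj in subjects:
        sid = subj.subject_id
        rio.write_volume(subj.volume, out / f"{sid}_volume.nii.gz")
        rio.write_mask(subj.mask, out / f"{sid}_mask.nii.gz")
        truth.append(subj.truth.to_dict())
    cohort = CohortTable([s.semantic for s in subjects])
    rio.write_semantic_scores(cohort, out / "semantic_scores.csv")
    with open(out / "ground_truth.json", "w") as fh:
        json.dump({"master_seed": int(seed), "subjects": truth}, fh, indent=1)
    return cohort
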