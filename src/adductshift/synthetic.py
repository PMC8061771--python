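"""Ground-truthed synthetic colon-mucosa IMS datasets.

The generator emulates the statistical structure the downstream analysis
assumes: a raster of epithelium (crypt bands invaginating into the stroma)
and lamina propria at 10 µm pixel spacing; a PC panel plus SM d34:1 whose
per-class H+/Na+/K+ adduct partition differs between the healthy condition
(balanced Na/K) and the adenomatous condition (K-enriched); optional linear
abundance gradients along the crypt axis for selected species; Gaussian ppm
mass jitter; multiplicative lognormal intensity noise; uniform chemical-noise
peaks; per-pixel TIC variation; and instrument-style merging of ion channels
closer than the resolving power can separate.

Every draw comes from one seeded NumPy generator consumed in a fixed order,
so a dataset is reproducible bit-for-bit from its configuration alone.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np

from .preprocess import IMSDataset, Spectrum
from .registry import ADDUCT_LABELS, ADDUCTS, LipidRegistry, LipidSpecies, colon_panel

_CATION_MASSES = [ADDUCTS[a].cation_mass for a in ADDUCT_LABELS]

__all__ = [
    "EPITHELIUM",
    "LAMINA_PROPRIA",
    "BACKGROUND",
    "TissueLayout",
    "AdductPartition",
    "SpeciesProfile",
    "SimulationConfig",
    "GroundTruth",
    "build_layout",
    "simulate_dataset",
    "merge_unresolved_channels",
    "healthy_partition",
    "adenoma_partition",
    "default_profiles",
    "preset_config",
]

BACKGROUND = 0
EPITHELIUM = 1
LAMINA_PROPRIA = 2

LABEL_NAMES = {BACKGROUND: "background", EPITHELIUM: "epithelium", LAMINA_PROPRIA: "lamina_propria"}
COMPARTMENTS = ("epithelium", "lamina_propria")


@dataclass
class TissueLayout:
    """A 2-D label raster with per-pixel differentiation axes.

    ``crypt_axis`` is defined on epithelial pixels only and runs from 0 at
    the crypt base to 1 at the crypt top (luminal surface); ``mucosa_axis``
    plays the same role for stromal pixels (basal -> luminal).  Non-member
    pixels hold NaN.
    """

    grid: np.ndarray  # (height, width) int8 labels
    pixel_spacing: float  # µm
    crypt_axis: np.ndarray  # (height, width) float, NaN off-epithelium
    mucosa_axis: np.ndarray  # (height, width) float, NaN off-stroma
    crypt_centers: list[int] = field(default_factory=list)

    @property
    def height(self) -> int:
        return int(self.grid.shape[0])

    @property
    def width(self) -> int:
        return int(self.grid.shape[1])

    def mask(self, label: int) -> np.ndarray:
        return self.grid == label

    def axis_at(self, y: int, x: int) -> float:
        """The differentiation-axis value of a tissue pixel (crypt or mucosa axis)."""
        if self.grid[y, x] == EPITHELIUM:
            return float(self.crypt_axis[y, x])
        if self.grid[y, x] == LAMINA_PROPRIA:
            return float(self.mucosa_axis[y, x])
        raise ValueError(f"pixel ({x}, {y}) is background")


def build_layout(width: int, height: int, n_crypts: int, seed: int) -> TissueLayout:
    """Place ``n_crypts`` U-shaped epithelial bands in a lamina-propria field.

    Each crypt is two vertical single-pixel epithelial arms joined at the
    base, invaginating from near the top of the raster (luminal side) down
    into the stroma; ``crypt_axis`` increases monotonically from the base of
    each arm to its top.  Deterministic for a given seed.
    """
    if width < 16 or height < 16:
        raise ValueError("layout must be at least 16x16 pixels")
    if n_crypts < 1:
        raise ValueError("need at least one crypt")
    margin = 2
    x_lo, x_hi = margin + 1, width - margin - 2  # leave room for both arms
    usable = x_hi - x_lo + 1
    if n_crypts * 5 > usable:
        raise ValueError(
            f"cannot place {n_crypts} crypts in a width-{width} raster; widen the grid"
        )
    rng = np.random.default_rng(seed)
    slots = np.linspace(x_lo, x_hi, n_crypts + 2)[1:-1]
    centers = sorted(int(round(s)) + int(rng.integers(-1, 2)) for s in slots)

    grid = np.full((height, width), BACKGROUND, dtype=np.int8)
    grid[margin : height - margin, margin : width - margin] = LAMINA_PROPRIA

    y_top = margin + 1
    y_base = height - margin - 2
    crypt_axis = np.full((height, width), np.nan)
    for cx in centers:
        for arm_x in (cx - 1, cx + 1):
            ys = np.arange(y_top, y_base + 1)
            grid[ys, arm_x] = EPITHELIUM
            crypt_axis[ys, arm_x] = (y_base - ys) / (y_base - y_top)
        grid[y_base, cx] = EPITHELIUM  # base connector pixel
        crypt_axis[y_base, cx] = 0.0

    mucosa_axis = np.full((height, width), np.nan)
    lp = grid == LAMINA_PROPRIA
    yy = np.tile(np.arange(height)[:, None], (1, width))
    mucosa_axis[lp] = np.clip((y_base - yy[lp]) / (y_base - y_top), 0.0, 1.0)

    return TissueLayout(grid, 10.0, crypt_axis, mucosa_axis, centers)


@dataclass(frozen=True)
class AdductPartition:
    """Per-class (f_H, f_Na, f_K) intensity fractions; must sum to one."""

    lipid_class: str
    f_H: float
    f_Na: float
    f_K: float

    def __post_init__(self) -> None:
        fracs = (self.f_H, self.f_Na, self.f_K)
        if any(f < 0 or f > 1 for f in fracs):
            raise ValueError(f"fractions must lie in [0, 1], got {fracs}")
        if abs(sum(fracs) - 1.0) > 1e-9:
            raise ValueError(f"fractions must sum to 1, got {sum(fracs)!r}")

    @property
    def fractions(self) -> np.ndarray:
        return np.array([self.f_H, self.f_Na, self.f_K])

    @property
    def na_k_pair(self) -> tuple[float, float]:
        """The (Na, K) pair renormalized over Na+K — the biomarker scale."""
        s = self.f_Na + self.f_K
        return self.f_Na / s, self.f_K / s


@dataclass(frozen=True)
class SpeciesProfile:
    """Base abundance of one species and its linear slope along the tissue axis."""

    species: LipidSpecies
    base_abundance: float
    gradient_slope: float = 0.0

    def __post_init__(self) -> None:
        if self.base_abundance <= 0:
            raise ValueError("base_abundance must be positive")
        if abs(self.gradient_slope) > 1:
            raise ValueError("|gradient_slope| must not exceed 1")


def healthy_partition(lipid_class: str) -> AdductPartition:
    """Healthy mucosa: Na:K pair ratio 0.5:0.5 (H fraction fixed at 0.30)."""
    return AdductPartition(lipid_class, 0.30, 0.35, 0.35)


def adenoma_partition(lipid_class: str) -> AdductPartition:
    """Adenomatous mucosa: K-enriched, Na:K pair ratio 0.3:0.7."""
    return AdductPartition(lipid_class, 0.30, 0.21, 0.49)


# Base abundances (arbitrary units) for the packaged panel, plus the
# condition-dependent fold changes seen between healthy and adenomatous
# epithelium (PC 34:1 up; PC 36:2, 36:3 and 38:4 down or mildly down;
# the rest unaltered).
_BASE_ABUNDANCE = {
    "PC 32:0": 80.0,
    "PC 34:1": 120.0,
    "PC 34:2": 100.0,
    "PC 36:1": 70.0,
    "PC 36:2": 90.0,
    "PC 36:3": 60.0,
    "PC 36:4": 75.0,
    "PC 38:4": 65.0,
    "SM d34:1": 50.0,
}
_ADENOMA_FOLD = {"PC 34:1": 1.5, "PC 36:2": 0.7, "PC 36:3": 0.7, "PC 38:4": 0.8}
# Only these species show a gradient along the crypt axis.
_GRADIENT_SLOPE = {"PC 32:0": -0.4, "PC 38:4": 0.4}


def default_profiles(condition: str, registry: Optional[LipidRegistry] = None) -> list[SpeciesProfile]:
    """The packaged colon-panel abundance profiles for one condition."""
    registry = registry or colon_panel()
    profiles = []
    for sp in registry.species:
        base = _BASE_ABUNDANCE.get(sp.display_name, 50.0)
        if condition == "adenoma":
            base *= _ADENOMA_FOLD.get(sp.display_name, 1.0)
        profiles.append(
            SpeciesProfile(sp, base, _GRADIENT_SLOPE.get(sp.display_name, 0.0))
        )
    return profiles


@dataclass
class SimulationConfig:
    """Everything needed to regenerate one synthetic section bit-for-bit."""

    condition: str  # "healthy" | "adenoma"
    partitions: dict[str, dict[str, AdductPartition]]  # compartment -> class -> partition
    profiles: list[SpeciesProfile]
    mz_jitter_sigma: float = 1.5  # ppm; ~95% of peaks within 3 ppm
    intensity_cv: float = 0.2
    n_noise_peaks: int = 50
    tic_cv: float = 0.3
    noise_intensity_median: float = 0.15  # arbitrary units, same scale as abundances
    noise_intensity_sigma: float = 1.2  # lognormal sigma of chemical-noise peaks
    mass_range: tuple[float, float] = (480.0, 1000.0)
    resolving_power: Optional[float] = 100_000.0  # R at m/z 400; None = infinite
    seed: int = 0

    def __post_init__(self) -> None:
        if self.mz_jitter_sigma < 0 or self.intensity_cv < 0 or self.tic_cv < 0:
            raise ValueError("noise levels must be non-negative")
        if self.mass_range[0] >= self.mass_range[1]:
            raise ValueError("mass_range low must be below high")
        if self.condition not in ("healthy", "adenoma"):
            raise ValueError(f"unknown condition {self.condition!r}")


def preset_config(condition: str, seed: int = 0, **overrides) -> SimulationConfig:
    """The stated-world preset for one condition (same partition in both compartments)."""
    maker = healthy_partition if condition == "healthy" else adenoma_partition
    classes = {"PC", "SM"}
    partitions = {comp: {cls: maker(cls) for cls in classes} for comp in COMPARTMENTS}
    return SimulationConfig(
        condition=condition,
        partitions=partitions,
        profiles=default_profiles(condition),
        seed=seed,
        **overrides,
    )


@dataclass
class GroundTruth:
    """Noiseless per-pixel, per-species, per-adduct intensities plus provenance."""

    pixels: np.ndarray  # (n, 2) x, y
    labels: np.ndarray  # (n,) compartment names
    axis_values: np.ndarray  # (n,) crypt/mucosa axis per pixel
    species_names: list[str]
    adducts: tuple[str, ...]
    intensities: np.ndarray  # (n, n_species, 3), noiseless
    partitions: dict[str, dict[str, AdductPartition]]
    layout: TissueLayout
    config: SimulationConfig

    def species_index(self, name: str) -> int:
        return self.species_names.index(name)

    def class_fractions(self, compartment: str, lipid_class: str) -> np.ndarray:
        """Empirical (H, Na, K) fractions of one class over one compartment."""
        classes = np.array([n.split()[0] for n in self.species_names])
        sel = classes == lipid_class
        rows = self.labels == compartment
        sums = self.intensities[rows][:, sel, :].sum(axis=(0, 1))
        return sums / sums.sum()

    def total_abundance(self, pixel_row: int, species: str) -> float:
        return float(self.intensities[pixel_row, self.species_index(species), :].sum())


def merge_unresolved_channels(
    mz: np.ndarray, intensity: np.ndarray, resolving_power: float
) -> tuple[np.ndarray, np.ndarray]:
    """Sum peaks the instrument cannot separate into one centroid.

    The resolving power of an orbitrap-style analyzer decays as
    ``R(mz) = R400 * sqrt(400 / mz)``, so the FWHM at m/z is
    ``mz / R(mz) = mz**1.5 / (R400 * 20)``.  Adjacent peaks closer than the
    FWHM at their midpoint are summed into an intensity-weighted centroid.
    Passes repeat until nothing merges, which makes the operation idempotent.
    """
    if resolving_power <= 0:
        raise ValueError("resolving_power must be positive")
    mz = np.asarray(mz, dtype=float)
    intensity = np.asarray(intensity, dtype=float)
    order = np.argsort(mz, kind="stable")
    mz, intensity = mz[order], intensity[order]
    while mz.size > 1:
        mid = 0.5 * (mz[1:] + mz[:-1])
        fwhm = mid**1.5 / (resolving_power * 20.0)
        close = np.diff(mz) < fwhm
        if not close.any():
            break
        # group maximally-connected runs of close neighbours
        group = np.zeros(mz.size, dtype=np.int64)
        group[1:] = np.cumsum(~close)
        n_groups = group[-1] + 1
        new_int = np.zeros(n_groups)
        np.add.at(new_int, group, intensity)
        wm = np.zeros(n_groups)
        np.add.at(wm, group, intensity * mz)
        counts = np.zeros(n_groups)
        np.add.at(counts, group, np.ones_like(mz))
        plain = np.zeros(n_groups)
        np.add.at(plain, group, mz)
        # weighted centroid; fall back to plain mean if a group has zero intensity
        with np.errstate(invalid="ignore"):
            new_mz = np.where(new_int > 0, wm / np.where(new_int > 0, new_int, 1.0), plain / counts)
        if new_mz.size == mz.size:
            break
        mz, intensity = new_mz, new_int
    return mz, intensity


def simulate_dataset(
    layout: TissueLayout, config: SimulationConfig
) -> tuple[IMSDataset, GroundTruth]:
    """Emit one centroided peak list per tissue pixel plus the generating truth.

    For each species and adduct the noiseless intensity at a pixel is
    ``base * (1 + slope * axis) * f_adduct``; the emitted intensity multiplies
    in lognormal peak noise (CV = ``intensity_cv``) and a per-pixel TIC
    factor (CV = ``tic_cv``), both with unit mean.  Peak m/z are the
    theoretical channel values perturbed by Gaussian ppm jitter; decoy
    chemical-noise peaks are drawn uniformly over the mass range; finally,
    channels closer than the configured resolving power allows are merged.
    """
    rng = np.random.default_rng(config.seed)

    species = [p.species for p in config.profiles]
    n_species = len(species)
    for comp in COMPARTMENTS:
        if comp not in config.partitions:
            raise ValueError(f"no adduct partitions configured for compartment {comp!r}")
        for sp in species:
            if sp.lipid_class not in config.partitions[comp]:
                raise ValueError(
                    f"species {sp.display_name} has no {comp} partition for class {sp.lipid_class}"
                )

    tissue = np.argwhere((layout.grid == EPITHELIUM) | (layout.grid == LAMINA_PROPRIA))
    n_pix = tissue.shape[0]
    labels = np.array(
        [LABEL_NAMES[int(layout.grid[y, x])] for y, x in tissue], dtype=object
    )
    axis_vals = np.array([layout.axis_at(y, x) for y, x in tissue])

    # Noiseless truth: (n_pix, n_species, 3)
    base = np.array([p.base_abundance for p in config.profiles])
    slope = np.array([p.gradient_slope for p in config.profiles])
    abundance = base[None, :] * (1.0 + slope[None, :] * axis_vals[:, None])
    frac = np.empty((n_pix, n_species, 3))
    for comp in COMPARTMENTS:
        rows = labels == comp
        if not rows.any():
            continue
        f = np.stack(
            [config.partitions[comp][sp.lipid_class].fractions for sp in species]
        )  # (n_species, 3)
        frac[rows] = f[None, :, :]
    truth = abundance[:, :, None] * frac

    # Multiplicative noise, all drawn in one fixed order for reproducibility.
    def lognormal_unit_mean(cv: float, size) -> np.ndarray:
        if cv == 0:
            return np.ones(size)
        sigma = math.sqrt(math.log(1.0 + cv * cv))
        return rng.lognormal(mean=-0.5 * sigma * sigma, sigma=sigma, size=size)

    peak_noise = lognormal_unit_mean(config.intensity_cv, truth.shape)
    tic_factor = lognormal_unit_mean(config.tic_cv, n_pix)
    noisy = truth * peak_noise * tic_factor[:, None, None]

    theo_mz = np.array(
        [sp.neutral_mass + cat for sp in species for cat in _CATION_MASSES]
    ).reshape(n_species, 3)
    if config.mz_jitter_sigma > 0:
        jitter = rng.normal(0.0, config.mz_jitter_sigma * 1e-6, size=(n_pix, n_species, 3))
    else:
        jitter = np.zeros((n_pix, n_species, 3))
    obs_mz = theo_mz[None, :, :] * (1.0 + jitter)

    lo, hi = config.mass_range
    if config.n_noise_peaks > 0:
        noise_mz = rng.uniform(lo, hi, size=(n_pix, config.n_noise_peaks))
        noise_int = rng.lognormal(
            mean=math.log(config.noise_intensity_median),
            sigma=config.noise_intensity_sigma,
            size=(n_pix, config.n_noise_peaks),
        )
    else:
        noise_mz = np.empty((n_pix, 0))
        noise_int = np.empty((n_pix, 0))

    spectra: list[Spectrum] = []
    for i in range(n_pix):
        y, x = int(tissue[i, 0]), int(tissue[i, 1])
        mz = np.concatenate([obs_mz[i].ravel(), noise_mz[i]])
        inten = np.concatenate([noisy[i].ravel(), noise_int[i]])
        inside = (mz >= lo) & (mz <= hi)
        mz, inten = mz[inside], inten[inside]
        order = np.argsort(mz, kind="stable")
        mz, inten = mz[order], inten[order]
        if config.resolving_power is not None:
            mz, inten = merge_unresolved_channels(mz, inten, config.resolving_power)
        spectra.append(Spectrum(x, y, mz, inten, str(labels[i])))

    dataset = IMSDataset(
        spectra,
        width=layout.width,
        height=layout.height,
        pixel_spacing=layout.pixel_spacing,
        mass_range=config.mass_range,
    )
    dataset.log(
        "simulate",
        condition=config.condition,
        seed=config.seed,
        n_pixels=n_pix,
        resolving_power=config.resolving_power,
    )

    ground_truth = GroundTruth(
        pixels=tissue[:, ::-1].copy(),  # store as (x, y)
        labels=labels,
        axis_values=axis_vals,
        species_names=[sp.display_name for sp in species],
        adducts=ADDUCT_LABELS,
        intensities=truth,
        partitions=config.partitions,
        layout=layout,
        config=config,
    )
    return dataset, ground_truth
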