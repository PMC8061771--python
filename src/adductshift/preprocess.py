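"""Per-pixel spectrum containers and the normalize / align / filter stages.

The processing order follows standard imaging-MS practice: TIC-normalize each
pixel spectrum, build a common mass axis across the raster by clustering
observed m/z values (each spectrum's peaks are then re-addressed to the shared
reference channels), and finally drop peaks below a relative intensity
threshold.  Because the threshold is relative to each spectrum's base peak,
the retained peak set commutes with normalization; this is asserted by the
test suite rather than assumed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional

import numpy as np

__all__ = [
    "Spectrum",
    "IMSDataset",
    "AlignedAxis",
    "tic_normalize",
    "filter_low_intensity",
    "align_to_axis",
    "normalize_dataset",
    "filter_dataset",
]


@dataclass
class Spectrum:
    """A centroided peak list for one raster pixel.

    Peaks are stored as parallel ``mz`` / ``intensity`` arrays sorted
    ascending in m/z; ``label`` is the tissue compartment the pixel belongs
    to (``"epithelium"``, ``"lamina_propria"`` or ``""`` when unknown).
    """

    x: int
    y: int
    mz: np.ndarray
    intensity: np.ndarray
    label: str = ""

    def __post_init__(self) -> None:
        self.mz = np.asarray(self.mz, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.mz.shape != self.intensity.shape:
            raise ValueError("mz and intensity must have equal length")
        if np.any(self.intensity < 0):
            raise ValueError("peak intensities must be non-negative")
        if self.mz.size > 1 and np.any(np.diff(self.mz) < 0):
            order = np.argsort(self.mz, kind="stable")
            self.mz = self.mz[order]
            self.intensity = self.intensity[order]

    @property
    def tic(self) -> float:
        """Total ion current: the sum of all peak intensities."""
        return float(self.intensity.sum())

    @property
    def n_peaks(self) -> int:
        return int(self.mz.size)

    def copy(self) -> "Spectrum":
        return Spectrum(self.x, self.y, self.mz.copy(), self.intensity.copy(), self.label)


@dataclass
class IMSDataset:
    """A raster of pixel spectra with acquisition metadata and a processing log."""

    spectra: list[Spectrum]
    width: int
    height: int
    pixel_spacing: float = 10.0  # µm
    mass_range: tuple[float, float] = (480.0, 1000.0)
    processing_log: list[dict] = field(default_factory=list)

    def __post_init__(self) -> None:
        seen: set[tuple[int, int]] = set()
        for sp in self.spectra:
            key = (sp.x, sp.y)
            if key in seen:
                raise ValueError(f"more than one spectrum at pixel {key}")
            seen.add(key)

    @property
    def n_spectra(self) -> int:
        return len(self.spectra)

    def log(self, operation: str, **params) -> None:
        self.processing_log.append({"operation": operation, **params})

    def pixels(self) -> np.ndarray:
        return np.array([(sp.x, sp.y) for sp in self.spectra], dtype=int)

    def labels(self) -> np.ndarray:
        return np.array([sp.label for sp in self.spectra], dtype=object)

    def copy(self) -> "IMSDataset":
        return IMSDataset(
            [sp.copy() for sp in self.spectra],
            self.width,
            self.height,
            self.pixel_spacing,
            self.mass_range,
            [dict(entry) for entry in self.processing_log],
        )


def tic_normalize(spectrum: Spectrum) -> Optional[Spectrum]:
    """Scale a spectrum so its intensities sum to one; m/z values untouched.

    An empty or zero-TIC spectrum cannot be normalized; it is flagged with a
    warning and ``None`` is returned so the caller can exclude it.
    """
    tic = spectrum.tic
    if spectrum.n_peaks == 0 or tic <= 0:
        warnings.warn(
            f"spectrum at pixel ({spectrum.x}, {spectrum.y}) has zero TIC; excluded",
            stacklevel=2,
        )
        return None
    return Spectrum(spectrum.x, spectrum.y, spectrum.mz, spectrum.intensity / tic, spectrum.label)


def filter_low_intensity(spectrum: Spectrum, fraction: float = 0.005) -> Spectrum:
    """Drop peaks below ``fraction`` of the spectrum's base-peak intensity.

    The base peak itself always survives.  An empty spectrum is returned
    unchanged.
    """
    if not 0 <= fraction < 1:
        raise ValueError(f"fraction must be in [0, 1), got {fraction}")
    if spectrum.n_peaks == 0 or fraction == 0:
        return spectrum
    threshold = fraction * spectrum.intensity.max()
    keep = spectrum.intensity >= threshold
    return Spectrum(spectrum.x, spectrum.y, spectrum.mz[keep], spectrum.intensity[keep], spectrum.label)


def normalize_dataset(dataset: IMSDataset) -> IMSDataset:
    """TIC-normalize every spectrum; zero-TIC pixels are dropped with a warning."""
    out = []
    for sp in dataset.spectra:
        norm = tic_normalize(sp)
        if norm is not None:
            out.append(norm)
    result = IMSDataset(
        out,
        dataset.width,
        dataset.height,
        dataset.pixel_spacing,
        dataset.mass_range,
        [dict(e) for e in dataset.processing_log],
    )
    result.log("tic_normalize", excluded=dataset.n_spectra - len(out))
    return result


def filter_dataset(dataset: IMSDataset, fraction: float = 0.005) -> IMSDataset:
    """Apply the relative-intensity filter to every spectrum (per-spectrum base peak)."""
    result = IMSDataset(
        [filter_low_intensity(sp, fraction) for sp in dataset.spectra],
        dataset.width,
        dataset.height,
        dataset.pixel_spacing,
        dataset.mass_range,
        [dict(e) for e in dataset.processing_log],
    )
    result.log("filter_low_intensity", fraction=fraction)
    return result


@dataclass
class AlignedAxis:
    """A common reference mass axis plus the peak-level membership mapping.

    ``ref_mz`` holds the intensity-weighted centroid of every reference
    channel, strictly increasing.  ``members`` records, for every original
    peak, which spectrum it came from, which channel it was mapped to, its
    observed m/z and its intensity — the raw material for mass-accuracy QC.
    """

    ref_mz: np.ndarray
    member_spectrum: np.ndarray  # (n_peaks,) spectrum index
    member_channel: np.ndarray  # (n_peaks,) reference channel index
    member_mz: np.ndarray  # (n_peaks,) observed m/z before re-addressing
    member_intensity: np.ndarray
    tolerance_ppm: float

    @property
    def n_channels(self) -> int:
        return int(self.ref_mz.size)


def align_to_axis(dataset: IMSDataset, tolerance_ppm: float = 6.0) -> tuple[IMSDataset, AlignedAxis]:
    """Build a shared mass axis by greedy 1-D clustering of observed m/z.

    All peaks across the raster are pooled and sorted; a new reference channel
    is opened whenever the next m/z lies more than ``tolerance_ppm`` above the
    current channel's running intensity-weighted centroid.  Each spectrum's
    peaks are then re-addressed to their channel's centroid; peaks of one
    spectrum falling on the same channel are summed, so per-spectrum total
    intensity is conserved exactly.
    """
    if tolerance_ppm <= 0:
        raise ValueError("tolerance must be positive")

    all_mz = np.concatenate([sp.mz for sp in dataset.spectra]) if dataset.spectra else np.empty(0)
    all_int = (
        np.concatenate([sp.intensity for sp in dataset.spectra]) if dataset.spectra else np.empty(0)
    )
    all_idx = np.concatenate(
        [np.full(sp.n_peaks, i, dtype=np.int64) for i, sp in enumerate(dataset.spectra)]
    ) if dataset.spectra else np.empty(0, dtype=np.int64)

    order = np.argsort(all_mz, kind="stable")
    mz_sorted = all_mz[order]
    int_sorted = all_int[order]

    n = mz_sorted.size
    channel_of = np.empty(n, dtype=np.int64)
    centroids: list[float] = []
    tol = tolerance_ppm * 1e-6
    # Greedy scan with a running intensity-weighted centroid per cluster.
    w_sum = 0.0
    wm_sum = 0.0
    current = -1
    for i in range(n):
        mz = mz_sorted[i]
        w = int_sorted[i]
        if current >= 0 and (mz - wm_sum / w_sum) <= tol * (wm_sum / w_sum):
            wm_sum += w * mz
            w_sum += w
            centroids[current] = wm_sum / w_sum
        else:
            current += 1
            w_sum = w if w > 0 else 1e-300
            wm_sum = w_sum * mz
            centroids.append(mz)
        channel_of[i] = current

    ref_mz = np.asarray(centroids, dtype=float)
    member_channel = np.empty(n, dtype=np.int64)
    member_channel[order] = channel_of  # back to original peak order

    axis = AlignedAxis(
        ref_mz=ref_mz,
        member_spectrum=all_idx,
        member_channel=member_channel,
        member_mz=all_mz,
        member_intensity=all_int,
        tolerance_ppm=tolerance_ppm,
    )

    # Re-address each spectrum onto the shared axis, summing duplicates.
    new_spectra: list[Spectrum] = []
    start = 0
    for i, sp in enumerate(dataset.spectra):
        stop = start + sp.n_peaks
        chans = member_channel[start:stop]
        start = stop
        uniq, inverse = np.unique(chans, return_inverse=True)
        summed = np.zeros(uniq.size)
        np.add.at(summed, inverse, sp.intensity)
        new_spectra.append(Spectrum(sp.x, sp.y, ref_mz[uniq], summed, sp.label))

    result = IMSDataset(
        new_spectra,
        dataset.width,
        dataset.height,
        dataset.pixel_spacing,
        dataset.mass_range,
        [dict(e) for e in dataset.processing_log],
    )
    result.log("align_to_axis", tolerance_ppm=tolerance_ppm, n_channels=axis.n_channels)
    return result, axis
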