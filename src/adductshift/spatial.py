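"""Path profiles, ROI summaries, the Na+/K+ pair-ratio statistic, and
healthy-vs-adenoma group comparisons.

The biomarker is the [Na+]/[K+] pair ratio of a lipid species: its Na and K
adduct intensities renormalized to sum to one.  The H+ adduct is excluded
from the pair, and the statistic is invariant to any global rescaling of a
spectrum — in particular to the choice of TIC normalization — and, because
the partition is assumed shared within a class, to abundance gradients along
the crypt.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .deconvolve import DeconvolvedTable
from .synthetic import EPITHELIUM, LABEL_NAMES, TissueLayout

__all__ = [
    "na_k_fractions",
    "PixelPath",
    "PathProfile",
    "trace_crypt_path",
    "extract_path_profile",
    "roi_summary",
    "GroupComparison",
    "compare_groups",
]


def na_k_fractions(i_na, i_k):
    """The (f_Na, f_K) pair fractions: Na and K intensities renormalized over Na+K.

    Element-wise on arrays.  Where both intensities are zero the pair ratio
    is undefined and NaN is returned (never 0.5).
    """
    i_na = np.asarray(i_na, dtype=float)
    i_k = np.asarray(i_k, dtype=float)
    if np.any(i_na < 0) or np.any(i_k < 0):
        raise ValueError("adduct intensities must be non-negative")
    total = i_na + i_k
    with np.errstate(invalid="ignore", divide="ignore"):
        f_na = np.where(total > 0, i_na / np.where(total > 0, total, 1.0), np.nan)
    f_k = 1.0 - f_na
    if f_na.ndim == 0:
        return float(f_na), float(f_k)
    return f_na, f_k


@dataclass
class PixelPath:
    """An ordered 8-connected chain of pixels from P0 to Pf within one compartment."""

    pixels: list[tuple[int, int]]  # (x, y)
    compartment: str
    pixel_spacing: float = 10.0  # µm

    def __post_init__(self) -> None:
        if len(self.pixels) < 10:
            raise ValueError(f"a path needs at least 10 pixels, got {len(self.pixels)}")
        if len(set(self.pixels)) != len(self.pixels):
            raise ValueError("path revisits a pixel")
        for (x0, y0), (x1, y1) in zip(self.pixels, self.pixels[1:]):
            if max(abs(x1 - x0), abs(y1 - y0)) != 1:
                raise ValueError(
                    f"consecutive path pixels must be 8-neighbors; ({x0},{y0})->({x1},{y1})"
                )

    @property
    def arc_length(self) -> np.ndarray:
        """Cumulative distance along the path in µm (diagonal steps count sqrt(2))."""
        steps = [0.0]
        for (x0, y0), (x1, y1) in zip(self.pixels, self.pixels[1:]):
            step = np.hypot(x1 - x0, y1 - y0) * self.pixel_spacing
            steps.append(steps[-1] + step)
        return np.asarray(steps)

    def reversed(self) -> "PixelPath":
        return PixelPath(list(reversed(self.pixels)), self.compartment, self.pixel_spacing)

    @classmethod
    def from_waypoints(
        cls,
        waypoints: Sequence[tuple[int, int]],
        compartment: str,
        pixel_spacing: float = 10.0,
    ) -> "PixelPath":
        """Densify ordered waypoints into an 8-connected pixel chain."""
        if len(waypoints) < 2:
            raise ValueError("need at least two waypoints")
        chain: list[tuple[int, int]] = []
        for (x0, y0), (x1, y1) in zip(waypoints, waypoints[1:]):
            for px in _bresenham8(x0, y0, x1, y1):
                if not chain or chain[-1] != px:
                    chain.append(px)
        return cls(chain, compartment, pixel_spacing)


def _bresenham8(x0: int, y0: int, x1: int, y1: int) -> Iterable[tuple[int, int]]:
    """8-connected raster line from (x0, y0) to (x1, y1), endpoints included."""
    dx, dy = abs(x1 - x0), abs(y1 - y0)
    sx = 1 if x1 >= x0 else -1
    sy = 1 if y1 >= y0 else -1
    err = dx - dy
    x, y = x0, y0
    while True:
        yield x, y
        if x == x1 and y == y1:
            return
        e2 = 2 * err
        if e2 > -dy:
            err -= dy
            x += sx
        if e2 < dx:
            err += dx
            y += sy


def trace_crypt_path(layout: TissueLayout, crypt: int = 0, arm: str = "left") -> PixelPath:
    """Auto-trace one epithelial crypt arm from base (P0) to top (Pf)."""
    if crypt >= len(layout.crypt_centers):
        raise ValueError(f"layout has {len(layout.crypt_centers)} crypts, asked for #{crypt}")
    cx = layout.crypt_centers[crypt]
    arm_x = cx - 1 if arm == "left" else cx + 1
    ys = [y for y in range(layout.height) if layout.grid[y, arm_x] == EPITHELIUM]
    ys.sort(key=lambda y: layout.crypt_axis[y, arm_x])  # base -> top
    return PixelPath([(arm_x, y) for y in ys], "epithelium", layout.pixel_spacing)


@dataclass
class PathProfile:
    """Per-pixel adduct tracks and Na/K pair fractions along one path."""

    frame: pd.DataFrame  # long: position, arc_um, pixel, species, I_H, I_Na, I_K, f_Na, f_K
    path: PixelPath
    smoothed: Optional[pd.DataFrame] = None

    def track(self, species: str) -> pd.DataFrame:
        return self.frame[self.frame["species"] == species].reset_index(drop=True)


def extract_path_profile(
    table: DeconvolvedTable,
    path: PixelPath,
    species: Optional[Sequence[str]] = None,
    smooth_window: Optional[int] = None,
) -> PathProfile:
    """Corrected adduct intensities and pair fractions at every path pixel.

    Pixels where a species was not detected emit missing values.  Optional
    centered moving-average smoothing (odd ``smooth_window``, in pixels) is
    applied to each track for plotting only; the raw frame is always kept.
    """
    wide = table.frame.pivot_table(
        index=["pixel_x", "pixel_y"], columns=["species", "adduct"], values="intensity",
        aggfunc="sum",
    )
    available = set(wide.index)
    missing_px = [p for p in path.pixels if p not in available]
    if missing_px:
        raise ValueError(
            f"path pixel {missing_px[0]} has no deconvolved spectrum "
            f"({len(missing_px)} of {len(path.pixels)} missing)"
        )
    wanted = list(species) if species is not None else sorted(
        {s for s, _ in wide.columns}
    )
    arc = path.arc_length
    rows = []
    for k, (x, y) in enumerate(path.pixels):
        rec = wide.loc[(x, y)]
        for name in wanted:
            vals = {}
            for adduct in ("H", "Na", "K"):
                vals[adduct] = rec.get((name, adduct), np.nan)
            f_na, f_k = na_k_fractions(
                0.0 if np.isnan(vals["Na"]) else vals["Na"],
                0.0 if np.isnan(vals["K"]) else vals["K"],
            )
            rows.append(
                {
                    "position": k,
                    "arc_um": arc[k],
                    "pixel_x": x,
                    "pixel_y": y,
                    "species": name,
                    "I_H": vals["H"],
                    "I_Na": vals["Na"],
                    "I_K": vals["K"],
                    "f_Na": f_na,
                    "f_K": f_k,
                }
            )
    frame = pd.DataFrame(rows)

    smoothed = None
    if smooth_window is not None:
        if smooth_window < 1 or smooth_window % 2 == 0:
            raise ValueError("smooth_window must be a positive odd integer")
        smoothed = frame.copy()
        cols = ["I_H", "I_Na", "I_K", "f_Na", "f_K"]
        smoothed[cols] = (
            frame.groupby("species")[cols]
            .transform(lambda s: s.rolling(smooth_window, center=True, min_periods=1).mean())
        )
    return PathProfile(frame, path, smoothed)


def roi_summary(
    table: DeconvolvedTable,
    compartment: str,
    layout: Optional[TissueLayout] = None,
) -> pd.DataFrame:
    """Per-species, per-adduct mean ± SEM over all pixels of one compartment.

    Also reports the pair-ratio columns per species: ``mean_fK`` (mean of the
    per-pixel K pair fraction, pixels with Na+K = 0 excluded) and
    ``pooled_fK`` (K share of the summed Na and K intensities).  For a
    single-pixel compartment the SEM is reported as 0 by convention.
    """
    if layout is not None:
        code = {v: k for k, v in LABEL_NAMES.items()}[compartment]
        if not layout.mask(code).any():
            raise ValueError(f"compartment {compartment!r} is empty in this layout")
    sel = table.frame[table.frame["compartment"] == compartment]
    if sel.empty:
        raise ValueError(f"no deconvolved pixels in compartment {compartment!r}")

    wide = sel.pivot_table(
        index=["pixel_x", "pixel_y"], columns=["species", "adduct"], values="intensity",
        aggfunc="sum",
    )
    rows = []
    for name in sorted({s for s, _ in wide.columns}):
        rec: dict = {"species": name, "compartment": compartment}
        for adduct in ("H", "Na", "K"):
            col = wide[(name, adduct)] if (name, adduct) in wide.columns else pd.Series(dtype=float)
            vals = col.dropna()
            rec[f"mean_{adduct}"] = vals.mean() if len(vals) else np.nan
            rec[f"sem_{adduct}"] = (
                vals.std(ddof=1) / np.sqrt(len(vals)) if len(vals) > 1 else 0.0
            )
            rec[f"n_{adduct}"] = int(len(vals))
        na = wide[(name, "Na")] if (name, "Na") in wide.columns else None
        k = wide[(name, "K")] if (name, "K") in wide.columns else None
        if na is not None and k is not None:
            pair = pd.concat([na, k], axis=1).dropna()
            f_na, f_k = na_k_fractions(pair.iloc[:, 0].to_numpy(), pair.iloc[:, 1].to_numpy())
            f_k = f_k[~np.isnan(f_k)]
            rec["mean_fK"] = float(np.mean(f_k)) if f_k.size else np.nan
            rec["sem_fK"] = float(np.std(f_k, ddof=1) / np.sqrt(f_k.size)) if f_k.size > 1 else 0.0
            tot_na, tot_k = float(pair.iloc[:, 0].sum()), float(pair.iloc[:, 1].sum())
            rec["pooled_fK"] = (
                tot_k / (tot_na + tot_k) if tot_na + tot_k > 0 else np.nan
            )
            rec["n_pixels"] = int(len(pair))
        else:
            rec["mean_fK"] = rec["sem_fK"] = rec["pooled_fK"] = np.nan
            rec["n_pixels"] = 0
        rows.append(rec)
    return pd.DataFrame(rows)


@dataclass
class GroupComparison:
    """Healthy-vs-adenoma statistics at the subject level.

    ``adducts``: per species/adduct group means ± SEM with a two-sided t
    statistic and p-value; ``fractions``: same for the K pair fraction;
    ``proportions``: each species' three adduct means rescaled to sum to one
    within each group (stacked-bar style).
    """

    adducts: pd.DataFrame
    fractions: pd.DataFrame
    proportions: pd.DataFrame
    paired: bool
    n_healthy: int
    n_adenoma: int


def _ttest(a: np.ndarray, b: np.ndarray, paired: bool) -> tuple[float, float]:
    a = a[~np.isnan(a)]
    b = b[~np.isnan(b)]
    if paired:
        if a.size != b.size or a.size < 2:
            return np.nan, np.nan
        if np.allclose(a, b):
            return 0.0, 1.0
        res = stats.ttest_rel(a, b)
    else:
        if a.size < 2 or b.size < 2:
            return np.nan, np.nan
        if np.allclose(a.mean(), b.mean()) and np.allclose(np.concatenate([a, b]).std(), 0):
            return 0.0, 1.0
        res = stats.ttest_ind(a, b)
    t, p = float(res.statistic), float(res.pvalue)
    if np.isnan(t) and np.isclose(a.mean(), b.mean()):
        # identical groups with zero variance: no evidence of a difference
        return 0.0, 1.0
    return t, p


def compare_groups(
    healthy: Sequence[pd.DataFrame],
    adenoma: Sequence[pd.DataFrame],
    paired: bool = False,
    adjust: bool = False,
) -> GroupComparison:
    """Compare per-subject ROI summaries between conditions with Student's t-tests.

    ``healthy`` and ``adenoma`` are lists of ``roi_summary`` frames, one per
    subject section, so the test units are subjects, not pixels.  The paired
    test requires equal subject counts.  ``adjust`` applies Benjamini-Hochberg
    across species within each adduct (off by default).
    """
    if paired and len(healthy) != len(adenoma):
        raise ValueError("paired comparison needs equal subject counts")
    if min(len(healthy), len(adenoma)) < 2:
        raise ValueError("need at least two subjects per group")

    def stack(frames: Sequence[pd.DataFrame], col: str) -> pd.DataFrame:
        return pd.concat(
            [f.set_index("species")[col].rename(i) for i, f in enumerate(frames)], axis=1
        )

    species = sorted(
        set.intersection(*(set(f["species"]) for f in list(healthy) + list(adenoma)))
    )

    adduct_rows = []
    for adduct in ("H", "Na", "K"):
        h = stack(healthy, f"mean_{adduct}").loc[species]
        a = stack(adenoma, f"mean_{adduct}").loc[species]
        for name in species:
            hv, av = h.loc[name].to_numpy(float), a.loc[name].to_numpy(float)
            t, p = _ttest(hv, av, paired)
            adduct_rows.append(
                {
                    "species": name,
                    "adduct": adduct,
                    "mean_healthy": np.nanmean(hv),
                    "sem_healthy": np.nanstd(hv, ddof=1) / np.sqrt(np.sum(~np.isnan(hv))),
                    "mean_adenoma": np.nanmean(av),
                    "sem_adenoma": np.nanstd(av, ddof=1) / np.sqrt(np.sum(~np.isnan(av))),
                    "t": t,
                    "p": p,
                    "test": "paired t" if paired else "unpaired t",
                    "n_healthy": int(np.sum(~np.isnan(hv))),
                    "n_adenoma": int(np.sum(~np.isnan(av))),
                }
            )
    adducts = pd.DataFrame(adduct_rows)
    if adjust:
        from statsmodels.stats.multitest import multipletests

        for adduct in ("H", "Na", "K"):
            m = adducts["adduct"] == adduct
            ok = m & adducts["p"].notna()
            if ok.any():
                adducts.loc[ok, "p_adj"] = multipletests(
                    adducts.loc[ok, "p"], method="fdr_bh"
                )[1]

    frac_rows = []
    h = stack(healthy, "mean_fK").loc[species]
    a = stack(adenoma, "mean_fK").loc[species]
    for name in species:
        hv, av = h.loc[name].to_numpy(float), a.loc[name].to_numpy(float)
        t, p = _ttest(hv, av, paired)
        frac_rows.append(
            {
                "species": name,
                "mean_fK_healthy": np.nanmean(hv),
                "mean_fK_adenoma": np.nanmean(av),
                "t": t,
                "p": p,
                "test": "paired t" if paired else "unpaired t",
            }
        )
    fractions = pd.DataFrame(frac_rows)

    prop_rows = []
    for cond, frames in (("healthy", healthy), ("adenoma", adenoma)):
        for name in species:
            means = np.array(
                [
                    np.nanmean(stack(frames, f"mean_{adduct}").loc[name].to_numpy(float))
                    for adduct in ("H", "Na", "K")
                ]
            )
            total = means.sum()
            props = means / total if total > 0 else np.full(3, np.nan)
            prop_rows.append(
                {
                    "condition": cond,
                    "species": name,
                    "prop_H": props[0],
                    "prop_Na": props[1],
                    "prop_K": props[2],
                }
            )
    proportions = pd.DataFrame(prop_rows)

    return GroupComparison(adducts, fractions, proportions, paired, len(healthy), len(adenoma))
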