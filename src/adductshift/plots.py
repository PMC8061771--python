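"""Plotting helpers: adduct tracks along a path and stacked adduct proportions."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

from .spatial import PathProfile

__all__ = ["plot_path_profile", "plot_proportions", "plot_demo"]

_ADDUCT_COLORS = {"H": "#777777", "Na": "#1f77b4", "K": "#d62728"}


def plot_path_profile(profile: PathProfile, species: str, out_file: "str | Path") -> Path:
    """Adduct intensity tracks plus the 0-1 Na/K ratio band for one species."""
    track = (profile.smoothed if profile.smoothed is not None else profile.frame)
    track = track[track["species"] == species]
    fig, (ax0, ax1) = plt.subplots(
        2, 1, sharex=True, figsize=(6, 4), height_ratios=[2, 1]
    )
    for adduct in ("H", "Na", "K"):
        ax0.plot(track["arc_um"], track[f"I_{adduct}"], label=f"[M+{adduct}]+",
                 color=_ADDUCT_COLORS[adduct])
    ax0.set_ylabel("corrected intensity")
    ax0.set_title(species)
    ax0.legend(fontsize=8)
    ax1.plot(track["arc_um"], track["f_Na"], color=_ADDUCT_COLORS["Na"], label="f_Na")
    ax1.plot(track["arc_um"], track["f_K"], color=_ADDUCT_COLORS["K"], label="f_K")
    ax1.axhline(0.5, color="k", lw=0.5, ls=":")
    ax1.set_ylim(0, 1)
    ax1.set_xlabel("distance along path (µm), P0 → Pf")
    ax1.set_ylabel("pair fraction")
    fig.tight_layout()
    out_file = Path(out_file)
    fig.savefig(out_file, dpi=120)
    plt.close(fig)
    return out_file


def plot_proportions(proportions, out_file: "str | Path") -> Path:
    """Stacked normalized H/Na/K proportions per species, one bar group per condition."""
    species = sorted(proportions["species"].unique())
    conditions = list(dict.fromkeys(proportions["condition"]))
    x = np.arange(len(species), dtype=float)
    width = 0.38
    fig, ax = plt.subplots(figsize=(1.0 + 0.9 * len(species), 3.5))
    for ci, cond in enumerate(conditions):
        sub = proportions[proportions["condition"] == cond].set_index("species").loc[species]
        bottom = np.zeros(len(species))
        for adduct in ("H", "Na", "K"):
            vals = sub[f"prop_{adduct}"].to_numpy()
            ax.bar(
                x + (ci - 0.5) * width,
                vals,
                width,
                bottom=bottom,
                color=_ADDUCT_COLORS[adduct],
                edgecolor="white",
                label=f"[M+{adduct}]+" if ci == 0 else None,
                alpha=1.0 if ci == 0 else 0.75,
            )
            bottom += vals
    ax.set_xticks(x)
    ax.set_xticklabels(species, rotation=45, ha="right", fontsize=8)
    ax.set_ylabel("normalized adduct proportion")
    ax.set_title(" vs ".join(conditions) + " (left/right bars)")
    ax.legend(fontsize=8)
    fig.tight_layout()
    out_file = Path(out_file)
    fig.savefig(out_file, dpi=120)
    plt.close(fig)
    return out_file


def plot_demo(result, out_dir: "str | Path") -> None:
    from .spatial import extract_path_profile, trace_crypt_path

    out = Path(out_dir)
    plot_proportions(result.comparison.proportions, out / "adduct_proportions.png")
    for arm in ("healthy", "adenoma"):
        subject = result.arm(arm)[0]
        path = trace_crypt_path(subject.layout, crypt=0)
        profile = extract_path_profile(subject.table, path, smooth_window=5)
        for species in ("PC 34:1", "PC 32:0"):
            safe = species.replace(" ", "_").replace(":", "-")
            plot_path_profile(profile, species, out / f"path_{arm}_{safe}.png")
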