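"""Exact-mass bookkeeping for lipid species and their singly charged cation adducts.

Neutral monoisotopic masses are computed from elemental formulas rather than
hard-coded.  For a glycerophosphocholine with ``n`` total acyl carbons and
``d`` double bonds the composition is ``C(n+8) H(2n-2d+16) N O8 P``; for a
d-series sphingomyelin (one sphingoid base hydroxyl pattern, total chain
carbons ``n``, total double bonds ``d``) it is ``C(n+5) H(2n-2d+13) N2 O6 P``.
Cation masses are atomic masses minus one electron mass, which is what a
high-resolution analyzer actually measures: at m/z < 1000 the electron mass
already amounts to ~0.7 ppm and matters for sub-3-ppm matching.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

__all__ = [
    "ATOMIC_MASS",
    "ELECTRON_MASS",
    "ADDUCTS",
    "LipidSpecies",
    "AdductIon",
    "IonChannel",
    "LipidRegistry",
    "ppm_error",
    "colon_panel",
    "load_panel",
    "COLON_PANEL",
]

# CODATA / IUPAC 2021 monoisotopic atomic masses (Da). Single source of truth
# for every m/z the package emits.
ATOMIC_MASS: dict[str, float] = {
    "H": 1.00782503207,
    "C": 12.0,
    "N": 14.0030740048,
    "O": 15.9949146196,
    "P": 30.97376163,
    "Na": 22.9897692809,
    "K": 38.96370668,
}

ELECTRON_MASS: float = 0.00054857990907  # Da

ADDUCT_LABELS = ("H", "Na", "K")


def formula_mass(formula: dict[str, int]) -> float:
    """Monoisotopic mass of an elemental composition."""
    try:
        return sum(ATOMIC_MASS[el] * count for el, count in formula.items())
    except KeyError as exc:  # pragma: no cover - guards panel typos
        raise KeyError(f"no monoisotopic mass registered for element {exc}") from exc


def _pc_formula(carbons: int, double_bonds: int) -> dict[str, int]:
    return {"C": carbons + 8, "H": 2 * carbons - 2 * double_bonds + 16, "N": 1, "O": 8, "P": 1}


def _sm_formula(carbons: int, double_bonds: int) -> dict[str, int]:
    return {"C": carbons + 5, "H": 2 * carbons - 2 * double_bonds + 13, "N": 2, "O": 6, "P": 1}


_FORMULAS = {"PC": _pc_formula, "SM": _sm_formula}


@dataclass(frozen=True)
class LipidSpecies:
    """A lipid class plus carbon/double-bond composition, e.g. ``PC 34:1``."""

    lipid_class: str
    carbons: int
    double_bonds: int
    neutral_mass: float
    display_name: str

    def __post_init__(self) -> None:
        if self.carbons <= 0:
            raise ValueError(f"carbons must be positive, got {self.carbons}")
        if self.double_bonds < 0:
            raise ValueError(f"double_bonds must be non-negative, got {self.double_bonds}")
        if self.neutral_mass <= 0:
            raise ValueError(f"neutral_mass must be positive, got {self.neutral_mass}")

    @classmethod
    def from_composition(
        cls,
        lipid_class: str,
        carbons: int,
        double_bonds: int,
        neutral_mass: float | None = None,
    ) -> "LipidSpecies":
        """Build a species, computing the neutral mass from its formula unless overridden."""
        if lipid_class not in _FORMULAS:
            raise ValueError(
                f"unknown lipid class {lipid_class!r}; registered classes: {sorted(_FORMULAS)}"
            )
        if neutral_mass is None:
            neutral_mass = formula_mass(_FORMULAS[lipid_class](carbons, double_bonds))
        prefix = "SM d" if lipid_class == "SM" else f"{lipid_class} "
        name = f"{prefix}{carbons}:{double_bonds}"
        return cls(lipid_class, carbons, double_bonds, neutral_mass, name)

    @classmethod
    def parse(cls, name: str) -> "LipidSpecies":
        """Parse a display name such as ``"PC 34:1"`` or ``"SM d34:1"``."""
        parts = name.strip().split()
        if len(parts) != 2:
            raise ValueError(f"cannot parse species name {name!r}")
        lipid_class, comp = parts
        comp = comp.lstrip("d")
        carbons, _, double_bonds = comp.partition(":")
        return cls.from_composition(lipid_class, int(carbons), int(double_bonds))

    @property
    def formula(self) -> dict[str, int]:
        return _FORMULAS[self.lipid_class](self.carbons, self.double_bonds)


@dataclass(frozen=True)
class AdductIon:
    """A singly charged cation adduct; cation mass = atomic mass - one electron."""

    label: str
    cation_mass: float
    charge: int = 1

    def __post_init__(self) -> None:
        if self.cation_mass <= 0:
            raise ValueError("cation_mass must be positive")


ADDUCTS: dict[str, AdductIon] = {
    label: AdductIon(label, ATOMIC_MASS[label] - ELECTRON_MASS) for label in ADDUCT_LABELS
}


@dataclass(frozen=True)
class IonChannel:
    """One (species, adduct) ion with its theoretical m/z."""

    species: LipidSpecies
    adduct: AdductIon

    @property
    def theoretical_mz(self) -> float:
        return self.species.neutral_mass + self.adduct.cation_mass

    @property
    def name(self) -> str:
        return f"[{self.species.display_name}+{self.adduct.label}]+"


def ppm_error(mz_obs: float, mz_theo: float) -> float:
    """Absolute relative mass deviation in parts per million."""
    if mz_theo <= 0:
        raise ValueError(f"theoretical m/z must be positive, got {mz_theo}")
    return 1e6 * abs(mz_obs - mz_theo) / mz_theo


class LipidRegistry:
    """A panel of lipid species and the adduct ion channels they can produce.

    The default matching tolerance is 9 ppm (the worst-case accuracy of the
    assignment step); candidates worse than 3 ppm additionally carry a
    warning flag since accuracy is typically better than that.
    """

    DEFAULT_TOLERANCE_PPM = 9.0
    WARN_PPM = 3.0

    def __init__(self, species: Iterable[LipidSpecies] = ()) -> None:
        self._species: dict[str, LipidSpecies] = {}
        for sp in species:
            self.add(sp)

    def add(self, species: LipidSpecies) -> None:
        existing = self._species.get(species.display_name)
        if existing is not None and existing != species:
            raise ValueError(f"conflicting registration for {species.display_name}")
        self._species[species.display_name] = species

    def __len__(self) -> int:
        return len(self._species)

    def __contains__(self, name: str) -> bool:
        return name in self._species

    @property
    def species(self) -> list[LipidSpecies]:
        return list(self._species.values())

    def get(self, name: str) -> LipidSpecies:
        try:
            return self._species[name]
        except KeyError:
            raise KeyError(f"species {name!r} is not registered") from None

    def channels(self) -> list[IonChannel]:
        """All registered (species, adduct) channels, ascending by theoretical m/z."""
        chans = [
            IonChannel(sp, ADDUCTS[a]) for sp in self._species.values() for a in ADDUCT_LABELS
        ]
        chans.sort(key=lambda c: c.theoretical_mz)
        return chans

    def adduct_mz(self, species: "LipidSpecies | str", adduct: str) -> float:
        """Theoretical m/z of [species + adduct]+ (charge 1)."""
        if isinstance(species, str):
            species = self.get(species)
        elif species.display_name not in self._species:
            raise KeyError(f"species {species.display_name!r} is not registered")
        if adduct not in ADDUCTS:
            raise KeyError(f"adduct {adduct!r} is not registered (have {ADDUCT_LABELS})")
        return species.neutral_mass + ADDUCTS[adduct].cation_mass

    def match_candidates(
        self, mz_obs: float, tolerance_ppm: float | None = None
    ) -> list[tuple[IonChannel, float]]:
        """All registered channels within ``tolerance_ppm`` of an observed m/z.

        Returns (channel, ppm_error) pairs sorted ascending by error; an empty
        list is a valid result.
        """
        if not self._species:
            raise ValueError("registry is empty")
        tol = self.DEFAULT_TOLERANCE_PPM if tolerance_ppm is None else float(tolerance_ppm)
        if tol <= 0:
            raise ValueError("tolerance must be positive")
        hits = []
        for chan in self.channels():
            err = ppm_error(mz_obs, chan.theoretical_mz)
            if err <= tol:
                hits.append((chan, err))
        hits.sort(key=lambda t: (t[1], t[0].species.display_name, t[0].adduct.label))
        return hits


# The PC species followed along the colon crypt plus the single consistently
# detected sphingomyelin.
COLON_PANEL: tuple[tuple[str, int, int], ...] = (
    ("PC", 32, 0),
    ("PC", 34, 1),
    ("PC", 34, 2),
    ("PC", 36, 1),
    ("PC", 36, 2),
    ("PC", 36, 3),
    ("PC", 36, 4),
    ("PC", 38, 4),
    ("SM", 34, 1),
)


def colon_panel() -> LipidRegistry:
    """The packaged colon-mucosa panel: eight PC species plus SM d34:1."""
    return LipidRegistry(
        LipidSpecies.from_composition(cls, n, d) for cls, n, d in COLON_PANEL
    )


def load_panel(path: "str | Path") -> LipidRegistry:
    """Load a panel definition from TSV or YAML.

    TSV columns: ``class``, ``carbons``, ``double_bonds`` and an optional
    ``mass`` override.  YAML: a list of mappings with the same keys.
    """
    path = Path(path)
    rows: list[dict] = []
    if path.suffix.lower() in {".yaml", ".yml"}:
        import yaml

        with open(path) as fh:
            rows = yaml.safe_load(fh) or []
    else:
        import csv

        with open(path, newline="") as fh:
            rows = list(csv.DictReader(fh, delimiter="\t"))
    registry = LipidRegistry()
    for row in rows:
        mass = row.get("mass")
        mass = float(mass) if mass not in (None, "") else None
        registry.add(
            LipidSpecies.from_composition(
                str(row["class"]), int(row["carbons"]), int(row["double_bonds"]), mass
            )
        )
    return registry
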