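"""Synthetic FTIR spectra with known ground truth.

Generates every input the pipeline needs without measured data:

* a component band library (inulin, gluten, starch, glycerol, sorbitol,
  propylene glycol) with characteristic band positions of the bread model
  system's ingredients;
* full model-system spectra mixed from the library by formulation weight
  ratios, with optional linear baseline drift and additive Gaussian noise;
* amide I composites (1590–1710 cm⁻¹) whose five Gaussian–Lorentzian bands
  carry prescribed fractional areas — the secondary-structure ground truth;
* starch fingerprint spectra (900–1200 cm⁻¹) whose baseline-corrected
  1047/1022 cm⁻¹ height ratio equals a prescribed target exactly;
* normally distributed replicate measurement sets for the statistics layer.

Every generator returns ``(Spectrum, truth)`` where ``truth`` is a plain
dict recording the exact weights/band parameters/targets, and is a pure
function of its parameters and the seed.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np

from .bandfit import Band, band_area, gl_profile
from .preprocess import BaselineSpec, baseline_correct
from .spectra import Spectrum, uniform_grid
from .stats import GroupedMeasurements

__all__ = [
    "Formulation",
    "NoiseSpec",
    "ComponentLibrary",
    "default_library",
    "generate_model_spectrum",
    "generate_amide_i",
    "generate_fingerprint",
    "generate_replicates",
    "AMIDE_CENTERS",
]

#: default amide I sub-band centers (cm⁻¹), ascending: intermolecular
#: β-sheet, unassigned (random coil), α-helix, β-turn, intramolecular β-sheet
AMIDE_CENTERS = (1627.0, 1645.0, 1654.0, 1670.0, 1685.0)


@dataclass(frozen=True)
class Formulation:
    """Weight ratios of one model-system blend.

    Defaults are the base blend: inulin 0.8, gluten 1, starch 7 (inulin at
    10% of gluten + starch), polyols absent, and 3 parts water per part
    total solids.  Polyol levels of 1% and 5% of the gluten + starch +
    inulin mass correspond to weights 0.088 and 0.44 on this 8.8 basis.
    """

    inulin: float = 0.8
    gluten: float = 1.0
    starch: float = 7.0
    glycerol: float = 0.0
    sorbitol: float = 0.0
    propylene_glycol: float = 0.0
    water_ratio: float = 3.0

    def __post_init__(self):
        for name, value in asdict(self).items():
            if value < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.inulin + self.gluten + self.starch <= 0:
            raise ValueError("gluten + starch + inulin must be > 0")

    @classmethod
    def with_polyol(cls, polyol: str, level_pct: float) -> "Formulation":
        """Base blend plus ``polyol`` at ``level_pct``% of the solids mass."""
        base = cls()
        solids = base.inulin + base.gluten + base.starch
        if polyol not in ("glycerol", "sorbitol", "propylene_glycol"):
            raise ValueError(f"unknown polyol {polyol!r}")
        return cls(**{**asdict(base), polyol: level_pct / 100.0 * solids})

    def component_weights(self) -> dict:
        return {
            "inulin": self.inulin,
            "gluten": self.gluten,
            "starch": self.starch,
            "glycerol": self.glycerol,
            "sorbitol": self.sorbitol,
            "propylene_glycol": self.propylene_glycol,
        }


@dataclass(frozen=True)
class NoiseSpec:
    """Additive Gaussian noise and linear baseline drift."""

    sigma: float = 0.0
    baseline_slope: float = 0.0
    baseline_offset: float = 0.0
    seed: int = 0

    def __post_init__(self):
        if self.sigma < 0:
            raise ValueError("sigma must be >= 0")

    def apply(self, nu: np.ndarray, absorbance: np.ndarray) -> np.ndarray:
        out = absorbance + self.baseline_offset + self.baseline_slope * (nu - nu[0])
        if self.sigma > 0:
            rng = np.random.default_rng(self.seed)
            out = out + rng.normal(0.0, self.sigma, size=nu.size)
        return out


# ---------------------------------------------------------------------------
# component library
# ---------------------------------------------------------------------------

# Band POSITIONS follow the ingredients' characteristic FTIR assignments
# (polyol C-O/O-H bands, starch and inulin polysaccharide C-O/C-C bands,
# gluten C-H/N-H stretches).  Heights (0.2-1.0 AU) and widths (10-60 cm⁻¹)
# are package inventions chosen to look plausible; they carry no measured
# meaning.
_LIBRARY_BANDS = {
    "glycerol": [
        (3300.0, 0.6, 60.0), (2917.0, 0.4, 30.0), (1145.0, 0.7, 25.0),
        (962.0, 0.5, 20.0),
    ],
    "sorbitol": [
        (3300.0, 0.6, 60.0), (2917.0, 0.4, 30.0), (1411.0, 0.4, 25.0),
        (1084.0, 0.8, 22.0), (1046.0, 0.9, 20.0), (890.0, 0.3, 18.0),
    ],
    "propylene_glycol": [
        (3300.0, 0.6, 60.0), (2917.0, 0.4, 30.0), (1442.0, 0.5, 22.0),
        (1374.0, 0.4, 20.0),
    ],
    "starch": [
        (3300.0, 0.7, 60.0), (2930.0, 0.3, 30.0), (1150.0, 0.6, 24.0),
        (1080.0, 0.8, 24.0), (1010.0, 1.0, 26.0),
    ],
    "gluten": [
        (3397.0, 0.7, 60.0), (2934.0, 0.4, 30.0), (1654.0, 0.9, 28.0),
        (1560.0, 0.5, 26.0),
    ],
    "inulin": [
        (3300.0, 0.7, 60.0), (2930.0, 0.3, 30.0), (1653.0, 0.5, 30.0),
        (1030.0, 0.9, 28.0), (700.0, 0.2, 40.0),
    ],
}


@dataclass(frozen=True)
class ComponentLibrary:
    """Per-component Gaussian–Lorentzian band sets on a common grid."""

    bands: dict  # component name -> tuple of Band
    grid: np.ndarray

    def component_spectrum(self, name: str) -> np.ndarray:
        out = np.zeros_like(self.grid)
        for b in self.bands[name]:
            out += gl_profile(self.grid, b)
        return out

    def components(self) -> list:
        return list(self.bands)


def default_library(grid: np.ndarray | None = None, eta: float = 0.5) -> ComponentLibrary:
    """The built-in six-component band library on a 400–4000 cm⁻¹ grid."""
    if grid is None:
        grid = uniform_grid(400.0, 4000.0, 4.0)
    grid = np.asarray(grid, dtype=float)
    bands = {
        name: tuple(Band(c, h, w, eta) for c, h, w in entries)
        for name, entries in _LIBRARY_BANDS.items()
    }
    return ComponentLibrary(bands=bands, grid=grid)


def generate_model_spectrum(
    formulation: Formulation,
    library: ComponentLibrary | None = None,
    noise: NoiseSpec = NoiseSpec(),
) -> tuple[Spectrum, dict]:
    """Weighted component mix + baseline drift + noise, with truth record."""
    library = library or default_library()
    weights = formulation.component_weights()
    if sum(weights.values()) == 0:
        raise ValueError("all-zero formulation")
    total = sum(weights.values())
    ab = np.zeros_like(library.grid)
    norm_weights = {}
    for name, w in weights.items():
        if w == 0:
            continue
        frac = w / total
        norm_weights[name] = frac
        ab += frac * library.component_spectrum(name)
    ab = noise.apply(library.grid, ab)
    spec = Spectrum(
        library.grid.copy(),
        ab,
        label="synthetic model system",
        metadata={"generator": "model", "seed": str(noise.seed)},
    )
    truth = {
        "weights": norm_weights,
        "raw_weights": weights,
        "bands": {
            name: [(b.center, b.height, b.fwhm, b.eta) for b in library.bands[name]]
            for name in norm_weights
        },
        "noise": asdict(noise),
    }
    return spec, truth


def generate_amide_i(
    fractions,
    centers=AMIDE_CENTERS,
    fwhm: float = 20.0,
    eta: float = 0.5,
    total_area: float = 10.0,
    noise: NoiseSpec = NoiseSpec(),
    grid_step: float = 1.0,
) -> tuple[Spectrum, dict]:
    """Amide I composite whose band areas equal ``fractions``/100 × total_area.

    ``fractions`` aligns with ``centers`` (default ascending 1627/1645/1654/
    1670/1685 cm⁻¹ — intermolecular β-sheet, unassigned, α-helix, β-turn,
    intramolecular β-sheet) and must sum to 100.  Grid: 1590–1710 cm⁻¹.
    """
    fractions = np.asarray(fractions, dtype=float)
    centers = np.asarray(centers, dtype=float)
    if fractions.size != centers.size:
        raise ValueError("fractions and centers differ in length")
    if np.any(fractions < 0):
        raise ValueError("fractions must be >= 0")
    if abs(fractions.sum() - 100.0) > 1e-9:
        raise ValueError("fractions must sum to 100")
    shape_area = fwhm * (eta * np.pi / 2 + (1 - eta) * 0.5 * np.sqrt(np.pi / np.log(2)))
    bands = []
    for frac, center in zip(fractions, centers):
        area = frac / 100.0 * total_area
        bands.append(Band(float(center), area / shape_area, fwhm, eta))
    grid = uniform_grid(1590.0, 1710.0, grid_step)
    ab = np.zeros_like(grid)
    for b in bands:
        ab += gl_profile(grid, b)
    ab = noise.apply(grid, ab)
    spec = Spectrum(
        grid, ab, label="synthetic amide I",
        metadata={"generator": "amide_i", "seed": str(noise.seed)},
    )
    truth = {
        "fractions_pct": fractions.tolist(),
        "centers": centers.tolist(),
        "bands": [(b.center, b.height, b.fwhm, b.eta) for b in bands],
        "areas": [band_area(b) for b in bands],
        "total_area": total_area,
        "noise": asdict(noise),
    }
    return spec, truth


def generate_fingerprint(
    target_ratio: float,
    noise: NoiseSpec = NoiseSpec(),
    h0: float = 0.5,
    anchors: tuple = (900.0, 1200.0),
    fwhm: float = 18.0,
    eta: float = 0.5,
    water_band_height: float = 0.3,
) -> tuple[Spectrum, dict]:
    """Starch fingerprint whose corrected 1047/1022 height ratio is ``target_ratio``.

    Three pseudo-Voigt bands sit at 1047 (ordered starch), 1022 (amorphous
    starch) and 995 cm⁻¹ (water-sensitive).  The 995 band height is fixed;
    the 1047/1022 amplitudes solve the 2×2 linear system making the TOTAL
    spectrum's baseline-corrected heights at 1047 and 1022 equal
    (target_ratio·h0, h0).  Grid: 900–1200 cm⁻¹ at 1 cm⁻¹.
    """
    if target_ratio <= 0:
        raise ValueError("target_ratio must be > 0")
    grid = uniform_grid(anchors[0], anchors[-1], 1.0)
    baseline = BaselineSpec(anchors=anchors)

    def corrected_height(profile: np.ndarray, nu: float) -> float:
        s = Spectrum(grid, profile)
        return baseline_correct(s, baseline).value_at(nu)

    basis = {c: gl_profile(grid, Band(c, 1.0, fwhm, eta)) for c in (1047.0, 1022.0, 995.0)}
    water = water_band_height * basis[995.0]
    # corrected height at a point is linear in the band amplitudes
    a_mat = np.array(
        [
            [corrected_height(basis[1047.0], 1047.0), corrected_height(basis[1022.0], 1047.0)],
            [corrected_height(basis[1047.0], 1022.0), corrected_height(basis[1022.0], 1022.0)],
        ]
    )
    rhs = np.array(
        [
            target_ratio * h0 - corrected_height(water, 1047.0),
            h0 - corrected_height(water, 1022.0),
        ]
    )
    amp_1047, amp_1022 = np.linalg.solve(a_mat, rhs)
    ab = amp_1047 * basis[1047.0] + amp_1022 * basis[1022.0] + water
    ab = noise.apply(grid, ab)
    spec = Spectrum(
        grid, ab, label="synthetic starch fingerprint",
        metadata={"generator": "fingerprint", "seed": str(noise.seed)},
    )
    truth = {
        "target_ratio": target_ratio,
        "h0": h0,
        "amplitudes": {"1047": float(amp_1047), "1022": float(amp_1022),
                       "995": water_band_height},
        "fwhm": fwhm,
        "eta": eta,
        "noise": asdict(noise),
    }
    return spec, truth


def generate_replicates(
    group_means: dict,
    sigma: float,
    n: int = 3,
    seed: int = 0,
    alpha: float = 0.05,
) -> GroupedMeasurements:
    """i.i.d. normal replicates per group (deterministic under ``seed``)."""
    if n < 2:
        raise ValueError("need n >= 2 replicates")
    if sigma < 0:
        raise ValueError("sigma must be >= 0")
    rng = np.random.default_rng(seed)
    groups = [
        (label, mean + rng.normal(0.0, sigma, size=n) if sigma > 0 else np.full(n, mean))
        for label, mean in group_means.items()
    ]
    return GroupedMeasurements(groups, alpha=alpha)
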