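"""Synthetic wear surfaces and cohorts for testing the whole pipeline.

Two layers of synthetic data are provided:

* deterministic analytic surfaces (planes, sinusoids, checkerboards,
  egg-boxes, Gaussian bumps, ...) with closed-form texture parameters, used
  as oracles for the metrology code;
* stochastic wear textures: an isotropic Gaussian random field background
  (the polish/abrasion haze of a tooth surface) overlaid with subtractive
  scratch and pit features whose density and depth encode an ordinal "diet
  level".  Feature insertion only removes material, mirroring real wear,
  which keeps the skewness behaviour physical.

Cohorts mirror the dietary study design: one aquarium sample of six teeth,
three wild specimens of six teeth each, eight within-tooth repeats taken as
disjoint crops of a single larger parent surface, and one unknown-diet
specimen of six teeth.  The generating parameters for every surface are
recorded in a truth table, which is the oracle for recovery tests.
"""

from __future__ import annotations

import math
import warnings as _warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ParameterError
from .surface_io import HeightMap, ISO_PARAMETER_ORDER, SpecimenTable

__all__ = [
    "CohortDesign",
    "SpecimenSpec",
    "TextureLevel",
    "DEFAULT_TEXTURE_MAP",
    "analytic_surface",
    "gaussian_random_field",
    "add_scratches",
    "add_pits",
    "make_cohort",
    "default_design",
    "make_parameter_table",
    "designed_effect_table",
    "DESIGNED_EFFECT_PARAMETERS",
]

#: Default field of view: 146 x 111 µm at 0.44 µm lateral sampling.
DEFAULT_NX = 332
DEFAULT_NY = 252
DEFAULT_DX = 0.44
DEFAULT_DY = 0.44


# ---------------------------------------------------------------------------
# Analytic oracle surfaces
# ---------------------------------------------------------------------------

def _coords(nx: int, ny: int, dx: float, dy: float):
    x = np.arange(nx) * dx
    y = np.arange(ny) * dy
    return np.meshgrid(x, y)


def analytic_surface(kind: str, params: dict | None = None,
                     nx: int = 64, ny: int = 64,
                     dx: float = DEFAULT_DX, dy: float = DEFAULT_DY
                     ) -> HeightMap:
    """Deterministic closed-form surface of the given kind.

    Kinds and their parameters (heights in µm):

    - ``flat``: constant ``offset`` (default 0);
    - ``plane``: ``slope_x``, ``slope_y`` (µm per µm);
    - ``quadratic``: coefficients ``a0 a1 a2 a3 a4 a5`` of
      ``a0 + a1 x + a2 y + a3 x² + a4 xy + a5 y²``;
    - ``sinusoid``: ``amplitude``, ``wavelength`` (along x), ``phase``;
    - ``checkerboard``: ``height`` (cells of ±height, 1 sample per cell);
    - ``eggbox``: ``amplitude``, ``wavelength``
      (``A sin(2πx/λ) sin(2πy/λ)``);
    - ``bumps``: ``bumps`` = list of ``(x, y, height, sigma)`` Gaussian
      bumps on a flat base;
    - ``uniform_noise``: heights i.i.d. uniform on ``[-a, a]``
      (``amplitude``, ``seed``).

    Periodic kinds warn when the field does not hold an integer number of
    periods (edge bias in moment parameters).
    """
    p = dict(params or {})
    X, Y = _coords(nx, ny, dx, dy)
    if kind == "flat":
        z = np.full((ny, nx), float(p.get("offset", 0.0)))
    elif kind == "plane":
        z = p.get("slope_x", 0.0) * X + p.get("slope_y", 0.0) * Y
    elif kind == "quadratic":
        a = [p.get(f"a{i}", 0.0) for i in range(6)]
        z = (a[0] + a[1] * X + a[2] * Y + a[3] * X ** 2 + a[4] * X * Y
             + a[5] * Y ** 2)
    elif kind == "sinusoid":
        A = float(p.get("amplitude", 1.0))
        lam = float(p.get("wavelength", 10.0))
        _check_periods(nx * dx, lam, kind)
        z = A * np.sin(2.0 * np.pi * X / lam + p.get("phase", 0.0))
    elif kind == "checkerboard":
        h = float(p.get("height", 0.5))
        ii, jj = np.meshgrid(np.arange(nx), np.arange(ny))
        z = np.where((ii + jj) % 2 == 0, h, -h).astype(float)
    elif kind == "eggbox":
        A = float(p.get("amplitude", 1.0))
        lam = float(p.get("wavelength", 10.0))
        _check_periods(nx * dx, lam, kind)
        _check_periods(ny * dy, lam, kind)
        z = A * np.sin(2.0 * np.pi * X / lam) * np.sin(2.0 * np.pi * Y / lam)
    elif kind == "bumps":
        z = np.zeros((ny, nx))
        for (bx, by, h, sigma) in p.get("bumps", []):
            z += h * np.exp(-((X - bx) ** 2 + (Y - by) ** 2)
                            / (2.0 * sigma ** 2))
    elif kind == "uniform_noise":
        a = float(p.get("amplitude", 1.0))
        rng = np.random.default_rng(p.get("seed", 0))
        z = rng.uniform(-a, a, size=(ny, nx))
    else:
        raise ParameterError(f"unknown analytic surface kind {kind!r}")
    meta = {"generator": kind, "generator_params": p}
    return HeightMap(z, dx, dy, meta=meta)


def _check_periods(extent: float, wavelength: float, kind: str) -> None:
    n = extent / wavelength
    if abs(n - round(n)) > 1e-9:
        _warnings.warn(
            f"{kind}: field holds a non-integer number of periods "
            f"({n:.3f}); moment parameters carry edge bias",
            RuntimeWarning, stacklevel=3)


# ---------------------------------------------------------------------------
# Gaussian random field background
# ---------------------------------------------------------------------------

def gaussian_random_field(nx: int, ny: int, dx: float, dy: float,
                          sq: float, corr_len: float,
                          seed=None) -> HeightMap:
    """Stationary isotropic Gaussian field with ACF exp(-r²/ℓ²).

    Synthesized spectrally (circulant embedding on the torus) and scaled
    so the sample RMS height equals ``sq`` exactly.  ``seed`` may be an
    integer or a ``numpy.random.Generator``.  Deterministic per seed.
    """
    if corr_len < dx:
        raise ParameterError(
            f"corr_len {corr_len} must be >= sample spacing {dx}")
    if corr_len > min(nx * dx, ny * dy) / 4.0:
        _warnings.warn("correlation length exceeds a quarter of the field: "
                       "Sal may be undefined", RuntimeWarning, stacklevel=2)
    rng = (seed if isinstance(seed, np.random.Generator)
           else np.random.default_rng(seed))
    # minimal-image lag distances on the torus
    tx = np.minimum(np.arange(nx), nx - np.arange(nx)) * dx
    ty = np.minimum(np.arange(ny), ny - np.arange(ny)) * dy
    r2 = ty[:, None] ** 2 + tx[None, :] ** 2
    acf = np.exp(-r2 / corr_len ** 2)
    spectrum = np.clip(np.fft.fft2(acf).real, 0.0, None)
    noise = rng.standard_normal((ny, nx))
    z = np.fft.ifft2(np.fft.fft2(noise) * np.sqrt(spectrum)).real
    z -= z.mean()
    rms = np.sqrt(np.mean(z ** 2))
    if rms > 0:
        z *= sq / rms
    meta = {"generator": "grf", "sq": sq, "corr_len": corr_len}
    return HeightMap(z, dx, dy, meta=meta)


# ---------------------------------------------------------------------------
# Wear features (subtractive)
# ---------------------------------------------------------------------------

def add_scratches(m: HeightMap, density: float, depth: float,
                  width: float, orientation_conc: float = 0.0,
                  seed=None) -> HeightMap:
    """Subtract elongate Gaussian-profile grooves (microwear scratches).

    The number of scratches is Poisson with mean ``density x area``; each
    is a straight segment of random length (quarter to full field
    diagonal) with a groove of Gaussian cross-section (``depth`` µm deep,
    ``width`` µm profile sigma).  Orientations follow a von Mises law
    around 0 with concentration ``orientation_conc`` (0 = isotropic).
    """
    if density < 0:
        raise ParameterError("density must be >= 0")
    if density > 0 and depth <= 0:
        raise ParameterError("scratch depth must be positive")
    if density > 0 and width < m.dx:
        raise ParameterError("scratch width must be >= sample spacing")
    rng = (seed if isinstance(seed, np.random.Generator)
           else np.random.default_rng(seed))
    out = m.copy()
    area = m.nx * m.dx * m.ny * m.dy
    n = int(rng.poisson(density * area))
    if n == 0:
        out.meta["scratches"] = 0
        return out
    X, Y = _coords(m.nx, m.ny, m.dx, m.dy)
    lx, ly = m.nx * m.dx, m.ny * m.dy
    diag = math.hypot(lx, ly)
    for _ in range(n):
        cx = rng.uniform(0.0, lx)
        cy = rng.uniform(0.0, ly)
        if orientation_conc > 0:
            theta = rng.vonmises(0.0, orientation_conc)
        else:
            theta = rng.uniform(-np.pi, np.pi)
        half = 0.5 * rng.uniform(0.25, 1.0) * diag
        ux, uy = math.cos(theta), math.sin(theta)
        # distance from each node to the segment
        relx, rely = X - cx, Y - cy
        t = np.clip(relx * ux + rely * uy, -half, half)
        d2 = (relx - t * ux) ** 2 + (rely - t * uy) ** 2
        out.heights -= depth * np.exp(-d2 / (2.0 * width ** 2))
    out.meta["scratches"] = n
    return out


def add_pits(m: HeightMap, density: float, depth: float,
             radius: float, seed=None) -> HeightMap:
    """Subtract Poisson-placed circular Gaussian depressions (pits).

    ``radius`` is the Gaussian sigma of the depression profile in µm.
    """
    if density < 0:
        raise ParameterError("density must be >= 0")
    if density > 0 and (depth <= 0 or radius < m.dx):
        raise ParameterError("pit depth must be > 0 and radius >= spacing")
    rng = (seed if isinstance(seed, np.random.Generator)
           else np.random.default_rng(seed))
    out = m.copy()
    area = m.nx * m.dx * m.ny * m.dy
    n = int(rng.poisson(density * area))
    if n == 0:
        out.meta["pits"] = 0
        return out
    X, Y = _coords(m.nx, m.ny, m.dx, m.dy)
    lx, ly = m.nx * m.dx, m.ny * m.dy
    for _ in range(n):
        cx = rng.uniform(0.0, lx)
        cy = rng.uniform(0.0, ly)
        r2 = (X - cx) ** 2 + (Y - cy) ** 2
        out.heights -= depth * np.exp(-r2 / (2.0 * radius ** 2))
    out.meta["pits"] = n
    return out


# ---------------------------------------------------------------------------
# Cohort design
# ---------------------------------------------------------------------------

@dataclass
class TextureLevel:
    """Generating texture parameters for one diet level."""

    base_sq: float          # µm, RMS of the background field
    corr_len: float         # µm, background correlation length
    scratch_density: float  # scratches / µm²
    scratch_depth: float    # µm
    scratch_width: float    # µm (profile sigma)
    pit_density: float      # pits / µm²
    pit_depth: float        # µm
    pit_radius: float       # µm (profile sigma)


#: Diet level -> texture.  Roughness (background Sq, feature depth and
#: density) increases monotonically with the proportion of elasmobranch
#: prey, so "rougher with diet" holds by construction.
DEFAULT_TEXTURE_MAP: dict[int, TextureLevel] = {
    1: TextureLevel(0.25, 3.0, 2.0e-4, 0.30, 1.0, 1.0e-4, 0.30, 1.5),
    2: TextureLevel(0.35, 3.0, 3.0e-4, 0.45, 1.0, 1.5e-4, 0.45, 1.5),
    3: TextureLevel(0.45, 3.0, 4.0e-4, 0.60, 1.0, 2.0e-4, 0.60, 1.5),
    4: TextureLevel(0.55, 3.0, 5.0e-4, 0.75, 1.0, 2.5e-4, 0.75, 1.5),
}


@dataclass
class SpecimenSpec:
    """One specimen in a cohort design."""

    label: str
    diet_level: int | None     # 1..4, or None for unknown diet
    n_teeth: int
    within_tooth: bool = False  # repeats cropped from one parent surface
    texture_level: int | None = None  # generating level (defaults to diet)


@dataclass
class CohortDesign:
    """Design of a synthetic cohort.

    ``texture_map`` must be monotone in diet level for base Sq and feature
    depths (checked), so that higher diet rank means rougher surfaces.
    """

    specimens: list
    texture_map: dict = field(
        default_factory=lambda: dict(DEFAULT_TEXTURE_MAP))
    nx: int = DEFAULT_NX
    ny: int = DEFAULT_NY
    dx: float = DEFAULT_DX
    dy: float = DEFAULT_DY
    seed: int = 0

    def __post_init__(self) -> None:
        levels = sorted(self.texture_map)
        for lv in levels:
            t = self.texture_map[lv]
            if t.base_sq <= 0 or t.scratch_density < 0 or t.pit_density < 0:
                raise ParameterError(f"invalid texture at level {lv}")
        for a, b in zip(levels, levels[1:]):
            ta, tb = self.texture_map[a], self.texture_map[b]
            if not (tb.base_sq >= ta.base_sq
                    and tb.scratch_depth >= ta.scratch_depth
                    and tb.pit_depth >= ta.pit_depth):
                raise ParameterError(
                    "texture_map must be monotone in diet level "
                    "(base_sq and feature depths)")


def default_design(nx: int = DEFAULT_NX, ny: int = DEFAULT_NY,
                   dx: float = DEFAULT_DX, dy: float = DEFAULT_DY,
                   seed: int = 0,
                   unknown_texture_level: int = 1) -> CohortDesign:
    """The study-mirror design: 6 aquarium teeth (diet level 1), eight
    within-tooth repeats on a level-2 specimen, three wild specimens of six
    teeth (levels 2-4), and six teeth of an unknown-diet specimen generated
    at ``unknown_texture_level``."""
    specimens = [
        SpecimenSpec("1", 1, 6),
        SpecimenSpec("2", 2, 6),
        SpecimenSpec("2a", 2, 8, within_tooth=True),
        SpecimenSpec("3", 3, 6),
        SpecimenSpec("4", 4, 6),
        SpecimenSpec("5", None, 6, texture_level=unknown_texture_level),
    ]
    return CohortDesign(specimens, nx=nx, ny=ny, dx=dx, dy=dy, seed=seed)


@dataclass
class CohortResult:
    """Surfaces plus the generating truth table."""

    surfaces: list          # HeightMap per tooth/site sample
    truth: pd.DataFrame     # one row per surface: labels + generator params


def _make_wear_surface(nx: int, ny: int, dx: float, dy: float,
                       tex: TextureLevel, rng: np.random.Generator
                       ) -> HeightMap:
    m = gaussian_random_field(nx, ny, dx, dy, tex.base_sq, tex.corr_len,
                              seed=rng)
    m = add_scratches(m, tex.scratch_density, tex.scratch_depth,
                      tex.scratch_width, seed=rng)
    m = add_pits(m, tex.pit_density, tex.pit_depth, tex.pit_radius, seed=rng)
    return m


def make_cohort(design: CohortDesign) -> CohortResult:
    """Generate every surface of a cohort design plus its truth table.

    Ordinary specimens get independent surfaces per tooth; within-tooth
    specimens get disjoint crops of a single larger parent surface, so
    their between-sample variance reflects only local heterogeneity of one
    tooth, mirroring repeated sampling across a single labial surface.
    """
    rng = np.random.default_rng(design.seed)
    surfaces: list[HeightMap] = []
    rows = []
    for spec in design.specimens:
        level = spec.texture_level or spec.diet_level
        if level is None:
            raise ParameterError(
                f"specimen {spec.label!r}: no diet or texture level")
        tex = design.texture_map[level]
        if spec.within_tooth:
            tiles_x = math.ceil(math.sqrt(spec.n_teeth))
            tiles_y = math.ceil(spec.n_teeth / tiles_x)
            parent = _make_wear_surface(tiles_x * design.nx,
                                        tiles_y * design.ny,
                                        design.dx, design.dy, tex, rng)
            crops = []
            for ty in range(tiles_y):
                for tx in range(tiles_x):
                    crops.append(parent.heights[
                        ty * design.ny:(ty + 1) * design.ny,
                        tx * design.nx:(tx + 1) * design.nx])
            crops = crops[:spec.n_teeth]
            sample_maps = [HeightMap(c - c.mean(), design.dx, design.dy)
                           for c in crops]
        else:
            sample_maps = [_make_wear_surface(design.nx, design.ny,
                                              design.dx, design.dy, tex, rng)
                           for _ in range(spec.n_teeth)]
        for i, m in enumerate(sample_maps):
            sid = f"{spec.label}-{i + 1:02d}"
            m.meta.update({"specimen_id": spec.label, "sample_id": sid,
                           "group": spec.label})
            surfaces.append(m)
            rows.append({
                "sample_id": sid, "specimen_id": spec.label,
                "group": spec.label,
                "diet_rank": spec.diet_level,
                "texture_level": level,
                "within_tooth": spec.within_tooth,
                "base_sq": tex.base_sq, "corr_len": tex.corr_len,
                "scratch_density": tex.scratch_density,
                "scratch_depth": tex.scratch_depth,
                "pit_density": tex.pit_density,
                "pit_depth": tex.pit_depth,
            })
    return CohortResult(surfaces, pd.DataFrame(rows))


# ---------------------------------------------------------------------------
# Table-level cohorts (for the statistics stage)
# ---------------------------------------------------------------------------

#: Plausible per-parameter (mean, sd) for table-level simulation, on the
#: scale of real microwear parameter tables.
_TABLE_BASE: dict[str, tuple[float, float]] = {
    "Sq": (0.40, 0.08), "Ssk": (-0.30, 0.25), "Sku": (3.2, 0.5),
    "Sp": (1.2, 0.25), "Sv": (1.5, 0.30), "Sz": (2.7, 0.45),
    "Sds": (0.02, 0.004), "Str": (0.6, 0.12), "Sal": (4.0, 0.8),
    "Sdq": (0.25, 0.05), "Ssc": (0.15, 0.03), "Sdr": (3.0, 0.6),
    "Vmp": (0.02, 0.004), "Vmc": (0.45, 0.09), "Vvc": (0.60, 0.12),
    "Vvv": (0.06, 0.012), "Spk": (0.35, 0.07), "Sk": (1.0, 0.2),
    "Svk": (0.55, 0.11), "Smr1": (10.0, 2.0), "Smr2": (88.0, 2.5),
    "S5z": (2.2, 0.4), "Sa": (0.32, 0.06),
}


#: Parameters carrying the designed dietary effect in effect cohorts, and
#: the direction of the shift (summit density falls with rougher diets,
#: as observed in real wear textures; the rest rise).
DESIGNED_EFFECT_PARAMETERS: dict[str, float] = {
    "Sq": +1.0, "Sds": -1.0, "Sal": +1.0, "Vmc": +1.0, "Sk": +1.0,
}


def designed_effect_table(seed: int = 0, shift_sd: float = 2.5,
                          groups: dict[str, int] | None = None,
                          effect_group: str = "4") -> SpecimenTable:
    """Study-design parameter table with a designed 5-parameter effect.

    The most elasmobranch-rich sample (group ``effect_group``) is shifted
    by ``shift_sd`` standard deviations in the five designated parameters
    of :data:`DESIGNED_EFFECT_PARAMETERS`; all other parameters are null.
    The default 2.5 SD is conservative relative to the effect sizes real
    dietary contrasts produce in wear textures.
    """
    groups = groups or {"1": 6, "2": 6, "2a": 8, "3": 6, "4": 6}
    effects = {effect_group: {p: sign * shift_sd for p, sign
                              in DESIGNED_EFFECT_PARAMETERS.items()}}
    return make_parameter_table(groups, effects=effects, seed=seed,
                                diet_ranks={"1": 1, "2": 2, "3": 3,
                                            "4": 4})


def make_parameter_table(groups: dict[str, int],
                         effects: dict[str, dict[str, float]] | None = None,
                         seed: int = 0,
                         diet_ranks: dict[str, int] | None = None
                         ) -> SpecimenTable:
    """Simulate a texture-parameter table directly (no surfaces).

    ``groups`` maps group label to sample size; every parameter is drawn
    independently Gaussian at realistic location/scale.  ``effects`` maps
    group label to ``{parameter: shift in SD units}``, producing designed
    group differences for power and false-positive studies of the
    statistics stage in isolation.
    """
    rng = np.random.default_rng(seed)
    effects = effects or {}
    rows = []
    counter = 0
    for label, n in groups.items():
        shift = effects.get(label, {})
        for _ in range(n):
            counter += 1
            row = {"sample_id": f"S{counter:03d}", "specimen_id": label,
                   "group": label}
            if diet_ranks and label in diet_ranks:
                row["diet_rank"] = diet_ranks[label]
            for param in ISO_PARAMETER_ORDER:
                mu, sd = _TABLE_BASE[param]
                row[param] = rng.normal(
                    mu + shift.get(param, 0.0) * sd, sd)
            rows.append(row)
    return SpecimenTable(pd.DataFrame(rows))
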