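"""Areal surface-texture parameters (ISO 25178-2 style) on a roughness surface.

Given a mean-zero, void-free, scale-limited surface the module computes the
23 parameters used for dietary discrimination from tooth microwear:

* height parameters ``Sq, Sa, Ssk, Sku, Sp, Sv, Sz`` — moments and extremes
  of the height distribution;
* the areal material ratio (Abbott–Firestone) curve, and from it the
  functional volume parameters ``Vmp, Vmc, Vvc, Vvv`` and the core family
  ``Sk, Spk, Svk, Smr1, Smr2`` (minimum-slope 40%-width secant construction);
* spatial parameters ``Sal, Str`` from the areal autocorrelation function;
* hybrid parameters ``Sdq, Sdr`` from surface gradients;
* feature parameters ``Sds, Ssc, S5z`` from prominence-pruned summits.

Feature parameters follow the classic summit conventions: a summit is an
8-neighbour strict local maximum whose topographic prominence is at least a
configurable fraction of ``Sz`` (Wolf-style pruning, default 5%); dales are
treated symmetrically on the inverted surface.

Heights and spacings are in µm throughout; volumes come out in µm³/µm²,
``Sdr``, ``Smr1`` and ``Smr2`` in percent, ``Sds`` in summits/µm².
"""

from __future__ import annotations

import warnings as _warnings
from dataclasses import dataclass, field, fields as _dc_fields

import numpy as np

from .errors import ParameterError
from .preprocess import RoughnessSurface
from .surface_io import ISO_PARAMETER_ORDER

__all__ = [
    "ParameterRecord",
    "MaterialRatioCurve",
    "height_parameters",
    "material_ratio_curve",
    "volume_parameters",
    "core_parameters",
    "spatial_parameters",
    "hybrid_parameters",
    "feature_parameters",
    "compute_all",
    "compute_parameter_table",
]


@dataclass
class ParameterRecord:
    """The 23 areal texture parameters of one surface.

    Undefined values (e.g. ``Ssk`` of a constant surface, ``Sal`` of a
    never-decaying autocorrelation) are NaN with an entry in ``warnings``.
    """

    Sq: float
    Ssk: float
    Sku: float
    Sp: float
    Sv: float
    Sz: float
    Sds: float
    Str: float
    Sal: float
    Sdq: float
    Ssc: float
    Sdr: float
    Vmp: float
    Vmc: float
    Vvc: float
    Vvv: float
    Spk: float
    Sk: float
    Svk: float
    Smr1: float
    Smr2: float
    S5z: float
    Sa: float
    warnings: list = field(default_factory=list)

    def as_dict(self) -> dict:
        """Parameters in canonical order (no warnings)."""
        return {name: getattr(self, name) for name in ISO_PARAMETER_ORDER}

    @classmethod
    def parameter_names(cls) -> tuple:
        return tuple(f.name for f in _dc_fields(cls) if f.name != "warnings")


@dataclass
class MaterialRatioCurve:
    """Areal material ratio curve c(p): height at material ratio p (%).

    ``p`` is a dense uniform grid over [0, 100]; ``c`` is non-increasing,
    with c(0) the highest and c(100) the lowest height of the surface.
    """

    p: np.ndarray
    c: np.ndarray

    def __post_init__(self) -> None:
        if len(self.p) < 1000:
            raise ParameterError("material ratio grid must have >= 1000 points")
        if np.any(np.diff(self.c) > 1e-12):
            raise ParameterError("material ratio curve must be non-increasing")

    def height_at(self, p) -> np.ndarray:
        """Interpolated height at material ratio ``p`` (%)."""
        return np.interp(p, self.p, self.c)

    def material_ratio_at(self, height) -> np.ndarray:
        """Material ratio (%) at which the curve crosses ``height``."""
        # c is non-increasing; interp needs ascending x
        return np.interp(-np.asarray(height, float), -self.c[::-1],
                         self.p[::-1])


def _surface_array(surf) -> tuple[np.ndarray, float, float]:
    if isinstance(surf, RoughnessSurface):
        return surf.heights, surf.dx, surf.dy
    raise TypeError("expected a RoughnessSurface")


# ---------------------------------------------------------------------------
# Height parameters
# ---------------------------------------------------------------------------

def height_parameters(surf: RoughnessSurface) -> dict:
    """Moment and extreme-value parameters of the height distribution.

    Sq is the RMS height, Sa the mean absolute height, Ssk and Sku the
    standardized third and fourth moments, Sp/Sv the maximum peak height
    and valley depth, Sz = Sp + Sv.
    """
    z, _, _ = _surface_array(surf)
    zf = z.ravel()
    sq = float(np.sqrt(np.mean(zf ** 2)))
    sa = float(np.mean(np.abs(zf)))
    sp = float(zf.max())
    sv = float(-zf.min())
    if sq == 0.0:
        _warnings.warn("constant surface: Ssk and Sku undefined",
                       RuntimeWarning, stacklevel=2)
        ssk = float("nan")
        sku = float("nan")
    else:
        ssk = float(np.mean(zf ** 3) / sq ** 3)
        sku = float(np.mean(zf ** 4) / sq ** 4)
    return {"Sq": sq, "Sa": sa, "Ssk": ssk, "Sku": sku,
            "Sp": sp, "Sv": sv, "Sz": sp + sv}


# ---------------------------------------------------------------------------
# Material ratio curve and functional parameters
# ---------------------------------------------------------------------------

def material_ratio_curve(surf: RoughnessSurface,
                         n_points: int = 2001) -> MaterialRatioCurve:
    """Areal material ratio (Abbott–Firestone) curve of the surface.

    c(p) is the height below which the fraction of material is 1 - p/100:
    the p-th upper quantile of the height distribution, linearly
    interpolated between order statistics and evaluated on a dense uniform
    grid of ``n_points`` ratios.
    """
    z, _, _ = _surface_array(surf)
    p = np.linspace(0.0, 100.0, n_points)
    c = np.quantile(z.ravel(), 1.0 - p / 100.0, method="linear")
    c = np.minimum.accumulate(c)  # guard against round-off non-monotonicity
    return MaterialRatioCurve(p, c)


def volume_parameters(curve: MaterialRatioCurve, p: float = 10.0,
                      q: float = 80.0) -> dict:
    """Functional volume parameters from the material ratio curve.

    ``Vm(r)`` is the material volume above the height c(r) (per unit area);
    ``Vv(r)`` the void volume below c(r).  Vmp is peak material volume at
    ratio ``p``, Vmc the core material volume between ``p`` and ``q``, Vvc
    the core void volume, Vvv the dale void volume at ``q``.
    """
    if not 0.0 < p < q < 100.0:
        raise ParameterError(f"need 0 < p < q < 100, got p={p} q={q}")

    def vm(r: float) -> float:
        cr = float(curve.height_at(r))
        mask = curve.p <= r
        u = np.append(curve.p[mask], r)
        cu = np.append(curve.c[mask], cr)
        return float(np.trapezoid(cu - cr, u) / 100.0)

    def vv(r: float) -> float:
        cr = float(curve.height_at(r))
        mask = curve.p >= r
        u = np.concatenate(([r], curve.p[mask]))
        cu = np.concatenate(([cr], curve.c[mask]))
        return float(np.trapezoid(cr - cu, u) / 100.0)

    vmp = vm(p)
    vmc = vm(q) - vm(p)
    vvv = vv(q)
    vvc = vv(p) - vv(q)
    return {"Vmp": vmp, "Vmc": vmc, "Vvc": vvc, "Vvv": vvv}


def core_parameters(curve: MaterialRatioCurve,
                    secant_width: float = 40.0) -> dict:
    """Core roughness parameters by the minimum-slope secant construction.

    The 40%-width secant of least slope along the material ratio curve is
    extended to p = 0 and p = 100, giving the core bounds; Sk is their
    difference, Smr1/Smr2 the ratios where the curve crosses the bounds,
    and Spk/Svk the heights of area-equivalent triangles of the peak
    region above Smr1 and the dale region below Smr2.
    """
    pgrid, c = curve.p, curve.c
    dp = pgrid[1] - pgrid[0]
    width_idx = int(round(secant_width / dp))
    drops = c[:len(c) - width_idx] - c[width_idx:]
    i_min = int(np.argmin(drops))  # ties resolve to the smallest starting p
    min_drop = float(drops[i_min])
    near_ties = np.sum(np.isclose(drops, min_drop, rtol=1e-9, atol=1e-12))
    if near_ties > 1:
        _warnings.warn(
            "degenerate material ratio curve: minimum-slope secant not "
            "unique; using the smallest starting ratio", RuntimeWarning,
            stacklevel=2)
    p_star = float(pgrid[i_min])
    slope = -min_drop / secant_width  # µm per % (non-positive)
    z1 = float(c[i_min] + slope * (0.0 - p_star))    # equivalent line at p=0
    z2 = float(c[i_min] + slope * (100.0 - p_star))  # equivalent line at p=100
    sk = z1 - z2

    # Smr1: ratio where the curve crosses the upper core bound z1
    below = c <= z1
    if below[0]:
        smr1 = 0.0
    else:
        i = int(np.argmax(below))
        smr1 = float(np.interp(-z1, -c[i - 1:i + 1], pgrid[i - 1:i + 1]))
    # Smr2: ratio where the curve crosses the lower core bound z2
    above = c >= z2
    if above[-1]:
        smr2 = 100.0
    else:
        i = len(c) - int(np.argmax(above[::-1])) - 1
        smr2 = float(np.interp(-z2, -c[i:i + 2], pgrid[i:i + 2]))

    if smr1 <= 0.0:
        spk = 0.0
    else:
        mask = pgrid <= smr1
        u = np.append(pgrid[mask], smr1)
        cu = np.append(c[mask], z1)
        a1 = float(np.trapezoid(cu - z1, u) / 100.0)
        spk = 2.0 * a1 / (smr1 / 100.0)
    if smr2 >= 100.0:
        svk = 0.0
    else:
        mask = pgrid >= smr2
        u = np.concatenate(([smr2], pgrid[mask]))
        cu = np.concatenate(([z2], c[mask]))
        a2 = float(np.trapezoid(z2 - cu, u) / 100.0)
        svk = 2.0 * a2 / ((100.0 - smr2) / 100.0)
    return {"Sk": sk, "Spk": spk, "Svk": svk, "Smr1": smr1, "Smr2": smr2}


# ---------------------------------------------------------------------------
# Spatial parameters
# ---------------------------------------------------------------------------

def _autocorrelation(z: np.ndarray) -> np.ndarray:
    """Normalized circular areal autocorrelation, origin at the centre."""
    zc = z - z.mean()
    spec = np.abs(np.fft.fft2(zc)) ** 2
    acf = np.real(np.fft.ifft2(spec))
    acf /= acf[0, 0]
    return np.fft.fftshift(acf)


def spatial_parameters(surf: RoughnessSurface, s: float = 0.2,
                       n_directions: int = 360) -> dict:
    """Autocorrelation length Sal and texture aspect ratio Str.

    The normalized areal autocorrelation R(τ) is scanned radially in
    ``n_directions`` directions; in each, the first lag where R drops to
    the threshold ``s`` is found with subcell linear interpolation.  Sal is
    the shortest such decay distance, Str the ratio of the shortest to the
    longest.  Directions in which R never decays within the half-size lag
    window are capped at the window radius; if no direction decays, both
    parameters are undefined (NaN) and a warning is emitted.
    """
    if not 0.0 < s < 1.0:
        raise ParameterError(f"threshold s must be in (0,1), got {s}")
    z, dx, dy = _surface_array(surf)
    ny, nx = z.shape
    if np.ptp(z) == 0.0:
        _warnings.warn("constant surface: autocorrelation undefined, "
                       "Sal/Str undefined", RuntimeWarning, stacklevel=2)
        return {"Sal": float("nan"), "Str": float("nan")}
    R = _autocorrelation(z)
    cy, cx = ny // 2, nx // 2
    r_max = min(cx * dx, cy * dy)  # half-size lag window, µm
    step = 0.5 * min(dx, dy)
    radii = np.arange(0.0, r_max + step, step)
    theta = np.linspace(0.0, 2.0 * np.pi, n_directions, endpoint=False)
    # sample R along every ray with bilinear interpolation
    xs = (np.cos(theta)[:, None] * radii[None, :]) / dx + cx
    ys = (np.sin(theta)[:, None] * radii[None, :]) / dy + cy
    from scipy.ndimage import map_coordinates
    samples = map_coordinates(R, [ys.ravel(), xs.ravel()], order=1,
                              mode="nearest").reshape(len(theta), len(radii))
    decayed = samples <= s
    crossing = np.full(len(theta), np.nan)
    has = decayed.any(axis=1)
    for j in np.nonzero(has)[0]:
        k = int(np.argmax(decayed[j]))
        if k == 0:
            crossing[j] = 0.0
        else:
            r0, r1 = radii[k - 1], radii[k]
            v0, v1 = samples[j, k - 1], samples[j, k]
            crossing[j] = r0 + (v0 - s) / (v0 - v1) * (r1 - r0)
    if not has.any():
        _warnings.warn("autocorrelation never decays below threshold "
                       "within the half-size window: Sal/Str undefined",
                       RuntimeWarning, stacklevel=2)
        return {"Sal": float("nan"), "Str": float("nan")}
    sal = float(np.nanmin(crossing))
    dist = np.where(has, crossing, r_max)  # non-decaying rays cap at window
    str_ = float(sal / np.max(dist))
    return {"Sal": sal, "Str": str_}


# ---------------------------------------------------------------------------
# Hybrid parameters
# ---------------------------------------------------------------------------

def hybrid_parameters(surf: RoughnessSurface) -> dict:
    """Gradient-based parameters.

    Sdq is the RMS surface slope; Sdr the developed interfacial area ratio
    in percent (excess of true area over projected area).  Gradients use
    central differences, one-sided at the edges.
    """
    z, dx, dy = _surface_array(surf)
    zy, zx = np.gradient(z, dy, dx)
    g2 = zx ** 2 + zy ** 2
    sdq = float(np.sqrt(np.mean(g2)))
    sdr = float(100.0 * np.mean(np.sqrt(1.0 + g2) - 1.0))
    return {"Sdq": sdq, "Sdr": sdr}


# ---------------------------------------------------------------------------
# Feature parameters
# ---------------------------------------------------------------------------

def _strict_local_maxima(z: np.ndarray) -> np.ndarray:
    """Boolean mask of 8-neighbour strict local maxima (border excluded)."""
    core = z[1:-1, 1:-1]
    strict = np.ones(core.shape, dtype=bool)
    for dr in (-1, 0, 1):
        for dc in (-1, 0, 1):
            if dr == 0 and dc == 0:
                continue
            strict &= core > z[1 + dr:z.shape[0] - 1 + dr,
                               1 + dc:z.shape[1] - 1 + dc]
    mask = np.zeros_like(z, dtype=bool)
    mask[1:-1, 1:-1] = strict
    return mask


def _peak_prominences(z: np.ndarray) -> dict:
    """Topographic prominence of every strict local maximum.

    Water-level flooding from the top: pixels are activated in descending
    height order and merged with 8-connected activated neighbours.  When a
    component merges into one with a higher peak, the lower peak's
    prominence is its height minus the merge level.  The global maximum
    has prominence equal to the full height range.
    """
    ny, nx = z.shape
    order = np.argsort(z, axis=None)[::-1]
    parent = np.full(ny * nx, -1, dtype=np.int64)
    peak_of = np.empty(ny * nx, dtype=np.int64)  # root -> peak pixel index
    flat = z.ravel()
    prominence: dict[int, float] = {}

    def find(a: int) -> int:
        root = a
        while parent[root] != root:
            root = parent[root]
        while parent[a] != root:
            parent[a], a = root, parent[a]
        return root

    for pix in order:
        r, c = divmod(int(pix), nx)
        roots = set()
        for dr in (-1, 0, 1):
            for dc in (-1, 0, 1):
                if dr == 0 and dc == 0:
                    continue
                rr, cc = r + dr, c + dc
                if 0 <= rr < ny and 0 <= cc < nx:
                    nb = rr * nx + cc
                    if parent[nb] != -1:
                        roots.add(find(nb))
        if not roots:
            parent[pix] = pix
            peak_of[pix] = pix
            continue
        roots = sorted(roots, key=lambda rt: flat[peak_of[rt]], reverse=True)
        main = roots[0]
        parent[pix] = main
        for other in roots[1:]:
            prominence[int(peak_of[other])] = float(
                flat[peak_of[other]] - flat[pix])
            parent[other] = main
    # surviving roots (global maximum of each remaining component)
    for pix in range(ny * nx):
        if parent[pix] == pix:
            prominence[int(peak_of[pix])] = float(flat[peak_of[pix]]
                                                  - flat.min())
    return prominence


def _summits(z: np.ndarray, threshold: float) -> list[tuple[int, int]]:
    strict = _strict_local_maxima(z)
    if not strict.any():
        return []
    prom = _peak_prominences(z)
    nx = z.shape[1]
    out = []
    for r, c in np.argwhere(strict):
        p = prom.get(int(r * nx + c), 0.0)
        if p >= threshold and p > 0.0:
            out.append((int(r), int(c)))
    return out


def feature_parameters(surf: RoughnessSurface,
                       pruning_pct: float = 5.0) -> dict:
    """Summit density Sds, mean summit curvature Ssc and ten-point height S5z.

    Summits are strict 8-neighbour local maxima whose prominence is at
    least ``pruning_pct`` percent of Sz; dales are found symmetrically on
    the inverted surface.  Ssc is the mean of -(z_xx + z_yy)/2 over summits
    (central second differences); S5z is the mean height of the five
    highest summits plus the mean depth of the five deepest dales.
    """
    if pruning_pct < 0:
        raise ParameterError("pruning threshold must be non-negative")
    z, dx, dy = _surface_array(surf)
    sz = float(z.max() - z.min())
    threshold = pruning_pct / 100.0 * sz
    area = z.shape[1] * dx * z.shape[0] * dy
    summits = _summits(z, threshold)
    dales = _summits(-z, threshold)
    sds = len(summits) / area
    if summits:
        curv = []
        for r, c in summits:
            zxx = (z[r, c + 1] - 2 * z[r, c] + z[r, c - 1]) / dx ** 2
            zyy = (z[r + 1, c] - 2 * z[r, c] + z[r - 1, c]) / dy ** 2
            curv.append(-(zxx + zyy) / 2.0)
        ssc = float(np.mean(curv))
    else:
        _warnings.warn("no summits: Ssc undefined", RuntimeWarning,
                       stacklevel=2)
        ssc = float("nan")
    peak_heights = sorted((z[r, c] for r, c in summits), reverse=True)
    dale_depths = sorted((-z[r, c] for r, c in dales), reverse=True)
    if len(peak_heights) < 5 or len(dale_depths) < 5:
        _warnings.warn("fewer than five summits or dales: S5z computed "
                       "over available extrema", RuntimeWarning,
                       stacklevel=2)
    top = float(np.mean(peak_heights[:5])) if peak_heights else 0.0
    bot = float(np.mean(dale_depths[:5])) if dale_depths else 0.0
    s5z = top + bot
    return {"Sds": sds, "Ssc": ssc, "S5z": s5z}


# ---------------------------------------------------------------------------
# Full record
# ---------------------------------------------------------------------------

def compute_all(surf: RoughnessSurface, s: float = 0.2, p: float = 10.0,
                q: float = 80.0, pruning_pct: float = 5.0) -> ParameterRecord:
    """Compute all 23 texture parameters of a roughness surface.

    Per-parameter warnings (undefined values, degenerate constructions)
    are collected into ``ParameterRecord.warnings``.
    """
    collected: list[str] = []
    with _warnings.catch_warnings(record=True) as wlist:
        _warnings.simplefilter("always")
        vals: dict = {}
        vals.update(height_parameters(surf))
        curve = material_ratio_curve(surf)
        vals.update(volume_parameters(curve, p=p, q=q))
        vals.update(core_parameters(curve))
        vals.update(spatial_parameters(surf, s=s))
        vals.update(hybrid_parameters(surf))
        vals.update(feature_parameters(surf, pruning_pct=pruning_pct))
        collected = [str(w.message) for w in wlist]
    return ParameterRecord(warnings=collected, **vals)


def compute_parameter_table(maps, preprocess_config=None, s: float = 0.2,
                            p: float = 10.0, q: float = 80.0,
                            pruning_pct: float = 5.0):
    """Run the standard chain and parameter computation over many surfaces.

    Each raw height map is preprocessed with :func:`~dmta.preprocess.
    standard_chain` and reduced to its 23-parameter record; rows carry the
    ``sample_id``/``specimen_id``/``group`` tags from ``HeightMap.meta``.
    Returns a :class:`~dmta.surface_io.SpecimenTable`.
    """
    import pandas as pd

    from .preprocess import standard_chain
    from .surface_io import SpecimenTable

    rows = []
    for m in maps:
        rough = standard_chain(m, preprocess_config)
        rec = compute_all(rough, s=s, p=p, q=q, pruning_pct=pruning_pct)
        row = {k: m.meta[k] for k in ("sample_id", "specimen_id", "group")
               if k in m.meta}
        row.update(rec.as_dict())
        rows.append(row)
    return SpecimenTable(pd.DataFrame(rows))
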