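"""R2* estimation engines.

Three fitters are provided, mirroring the three acquisition/processing
chains being compared:

* :func:`truncation_fit` — mono-exponential fit that iteratively discards
  trailing echoes buried in the noise floor (reference method, fat-saturated
  acquisitions).
* :func:`dixon_magnitude_fit` — water/fat/R2* fit of magnitude data via a
  variable-projection-style grid over (R2*, fat fraction) with a closed-form
  amplitude solve at each node and local nonlinear refinement.
* :func:`noise_corrected_fit` — same signal model wrapped in the Rician
  first-moment operator, with the noise level a known input rather than a
  free parameter.

Plus :func:`detect_and_reverse_swap`, the rule-based organ-level surrogate
for global fat/water swap detection.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np
from scipy.optimize import least_squares

from .signal import (EchoSeries, FatSpectrum, NoiseModel, Protocol,
                     fat_dephasing, rician_expectation)

__all__ = [
    "FitConfig",
    "FitResult",
    "truncation_fit",
    "dixon_magnitude_fit",
    "noise_corrected_fit",
    "fit_voxels",
    "detect_and_reverse_swap",
]


@dataclass(frozen=True)
class FitConfig:
    """Optimizer settings shared by the fitting engines.

    ``mode`` controls how the near-degenerate water-dominant/fat-dominant
    pair of minima of the magnitude model is resolved: ``"prefer_water"``
    always returns the water-dominant solution (the product-like behaviour
    whose failure mode is the classic F/W swap), ``"global"`` returns the
    lower-residual one.
    """

    r2star_min: float = 0.0
    r2star_max: float = 1200.0
    r2star_step: float = 2.0
    pdff_step: float = 0.02
    truncation_k: float = 2.0
    max_iter: int = 200
    tol: float = 1e-8
    swap_tol: float = 0.05
    r2star_cap: float | None = None
    mode: str = "prefer_water"

    def __post_init__(self) -> None:
        if self.r2star_min < 0 or self.r2star_step <= 0:
            raise ValueError("r2star grid must have min >= 0 and step > 0")
        if not self.r2star_max > self.r2star_min:
            raise ValueError("degenerate r2star grid")
        if not 0 < self.pdff_step <= 0.5:
            raise ValueError("pdff_step must be in (0, 0.5]")
        if self.tol <= 0:
            raise ValueError("tol must be > 0")
        if self.mode not in ("prefer_water", "global"):
            raise ValueError("mode must be 'prefer_water' or 'global'")


@dataclass(frozen=True)
class FitResult:
    """Per-voxel (or per-ROI) estimate from one engine."""

    r2star_hat: float
    w_hat: float | None = None
    f_hat: float | None = None
    pdff_hat: float | None = None
    n_echoes_used: int = 0
    residual: float = 0.0
    converged: bool = True
    swap_flag: bool = False
    capped: bool = False


# ---------------------------------------------------------------------------
# truncation (reference) fit
# ---------------------------------------------------------------------------

def _monoexp_ls(te: np.ndarray, s: np.ndarray,
                config: FitConfig) -> tuple[float, float, float, bool]:
    """Bounded least-squares fit of A*exp(-R*te); returns (A, R, SSR, ok)."""
    # log-linear start from strictly positive samples
    pos = s > 0
    if pos.sum() >= 2:
        coef = np.polyfit(te[pos], np.log(s[pos]), 1)
        r0 = max(0.0, float(-coef[0]))
        a0 = float(np.exp(coef[1]))
    else:
        r0, a0 = 0.0, float(s.max(initial=0.0))
    a0 = max(a0, 1e-12)

    def resid(p):
        return p[0] * np.exp(-p[1] * te) - s

    sol = least_squares(resid, x0=[a0, min(r0, 5e3)],
                        bounds=([0.0, 0.0], [np.inf, np.inf]),
                        xtol=config.tol, ftol=config.tol, gtol=config.tol,
                        max_nfev=50 * config.max_iter)
    ssr = float(np.sum(sol.fun ** 2))
    return float(sol.x[0]), float(sol.x[1]), ssr, bool(sol.success)


def truncation_fit(series: EchoSeries, noise: NoiseModel,
                   config: FitConfig | None = None) -> FitResult:
    """Mono-exponential R2* fit with noise-floor echo truncation.

    Echoes whose fitted model value falls below ``truncation_k * sigma``
    are dropped from the tail and the fit repeated, until stable or only
    three echoes remain.  Deterministic for fixed input.
    """
    config = config or FitConfig()
    te, s = series.te, series.magnitude
    if te.size < 3:
        raise ValueError("truncation_fit needs at least 3 echoes")
    if not np.any(s > 0):
        return FitResult(r2star_hat=float("nan"), n_echoes_used=0,
                         residual=float("nan"), converged=False)

    thresh = config.truncation_k * noise.sigma
    m = te.size
    a = r = ssr = 0.0
    ok = True
    for _ in range(te.size):
        a, r, ssr, ok = _monoexp_ls(te[:m], s[:m], config)
        model = a * np.exp(-r * te[:m])
        keep = m
        while keep > 3 and model[keep - 1] < thresh:
            keep -= 1
        if keep == m:
            break
        m = keep
    return FitResult(r2star_hat=r, w_hat=a, f_hat=None, pdff_hat=None,
                     n_echoes_used=m, residual=ssr, converged=ok)


# ---------------------------------------------------------------------------
# magnitude Dixon fit
# ---------------------------------------------------------------------------

def _model_magnitude(w: float, f: float, r: float,
                     c: np.ndarray, te: np.ndarray) -> np.ndarray:
    return np.abs(w + c * f) * np.exp(-r * te)


def _grids(config: FitConfig) -> tuple[np.ndarray, np.ndarray]:
    r_grid = np.arange(config.r2star_min,
                       config.r2star_max + 0.5 * config.r2star_step,
                       config.r2star_step)
    phi_grid = np.arange(0.0, 1.0 + 1e-12, config.pdff_step)
    if phi_grid[-1] < 1.0:
        phi_grid = np.append(phi_grid, 1.0)
    return r_grid, phi_grid


def _dixon_grid_scan(S: np.ndarray, te: np.ndarray, c: np.ndarray,
                     config: FitConfig):
    """Vectorized (R2*, pdff) grid scan with closed-form amplitude.

    ``S``: (V, n) magnitude samples.  Returns the grids plus per-node
    amplitude and residual arrays of shape (V, R, P).
    """
    r_grid, phi_grid = _grids(config)
    g = np.abs((1.0 - phi_grid)[:, None] + phi_grid[:, None] * c[None, :])
    decay = np.exp(-np.outer(r_grid, te))
    m = decay[:, None, :] * g[None, :, :]                     # (R, P, n)
    mm = np.einsum("rpn,rpn->rp", m, m)
    sm = np.einsum("vn,rpn->vrp", S, m)
    amp = np.clip(sm, 0.0, None) / mm[None, :, :]
    ss = np.einsum("vn,vn->v", S, S)
    resid = ss[:, None, None] - amp * np.clip(sm, 0.0, None)
    return r_grid, phi_grid, amp, np.clip(resid, 0.0, None)


def _refine(w0: float, f0: float, r0: float, s: np.ndarray, c: np.ndarray,
            te: np.ndarray, config: FitConfig):
    """Bounded nonlinear refinement of (w, f, R2*) from a grid node."""

    def resid(p):
        return _model_magnitude(p[0], p[1], p[2], c, te) - s

    sol = least_squares(resid, x0=[max(w0, 0.0), max(f0, 0.0), max(r0, 0.0)],
                        bounds=([0.0, 0.0, 0.0], [np.inf, np.inf, np.inf]),
                        xtol=config.tol, ftol=config.tol, gtol=config.tol,
                        max_nfev=50 * config.max_iter)
    w, f, r = (float(v) for v in sol.x)
    return w, f, r, float(np.sum(sol.fun ** 2)), bool(sol.success)


def _pdff(w: float, f: float) -> float:
    total = w + f
    return f / total if total > 0 else 0.0


def _resolve_sides(cands: list[tuple], config: FitConfig, scale: float):
    """Pick the reported solution among refined candidates.

    ``cands`` entries are (w, f, r, ssr, ok).  Water-dominant means
    pdff <= 0.5.  Returns (chosen, swap_flag).
    """
    water = [c for c in cands if _pdff(c[0], c[1]) <= 0.5]
    fat = [c for c in cands if _pdff(c[0], c[1]) > 0.5]
    best_water = min(water, key=lambda c: c[3]) if water else None
    best_fat = min(fat, key=lambda c: c[3]) if fat else None
    fudge = 1e-12 * max(scale, 1.0)

    if config.mode == "global" or best_water is None:
        chosen = min(cands, key=lambda c: c[3])
    else:
        chosen = best_water
    other = best_fat if _pdff(chosen[0], chosen[1]) <= 0.5 else best_water
    swap = (other is not None
            and other[3] <= chosen[3] * (1.0 + config.swap_tol) + fudge)
    return chosen, swap


def dixon_magnitude_fit(series: EchoSeries, spectrum: FatSpectrum,
                        protocol: Protocol,
                        config: FitConfig | None = None) -> FitResult:
    """Water/fat/R2* fit of a magnitude echo series.

    A grid over (R2*, fat fraction) with a closed-form amplitude solve at
    each node locates the two candidate basins (water-dominant and
    fat-dominant); each is refined by bounded nonlinear least squares.
    ``config.mode`` picks the reported basin; ``swap_flag`` is set when the
    discarded basin's residual is competitive (within ``swap_tol``),
    i.e. when the water/fat assignment is ambiguous from magnitude data.
    """
    config = config or FitConfig()
    te, s = series.te, series.magnitude
    if te.size < 4:
        raise ValueError("dixon_magnitude_fit needs at least 4 echoes")
    c = fat_dephasing(spectrum, te, protocol.field_strength)
    r_grid, phi_grid, amp, resid = _dixon_grid_scan(s[None, :], te, c, config)
    return _dixon_from_scan(s, te, c, r_grid, phi_grid,
                            amp[0], resid[0], config)


def _dixon_from_scan(s, te, c, r_grid, phi_grid, amp, resid,
                     config: FitConfig) -> FitResult:
    water_p = phi_grid <= 0.5
    cands = []
    for side in (water_p, ~water_p):
        if not np.any(side):
            continue
        sub = resid[:, side]
        ri, pi = np.unravel_index(np.argmin(sub), sub.shape)
        phi = phi_grid[side][pi]
        a = amp[:, side][ri, pi]
        cands.append(_refine(a * (1 - phi), a * phi, r_grid[ri],
                             s, c, te, config))
    scale = float(np.sum(s ** 2))
    chosen, swap = _resolve_sides(cands, config, scale)
    w, f, r, ssr, ok = chosen
    capped = False
    if config.r2star_cap is not None and r > config.r2star_cap:
        r, capped = float(config.r2star_cap), True
    return FitResult(r2star_hat=r, w_hat=w, f_hat=f, pdff_hat=_pdff(w, f),
                     n_echoes_used=te.size, residual=ssr, converged=ok,
                     swap_flag=swap, capped=capped)


# ---------------------------------------------------------------------------
# noise-corrected fit
# ---------------------------------------------------------------------------

def noise_corrected_fit(series: EchoSeries, spectrum: FatSpectrum,
                        protocol: Protocol, noise: NoiseModel,
                        config: FitConfig | None = None) -> FitResult:
    """First-moment noise-corrected water/fat/R2* fit.

    Minimizes sum_n (|s_n| - E_sigma{|(w + c_n f) exp(-R2* te_n)|})^2 over
    nonnegative (w, f, R2*), with sigma a known input.  Initialized from
    :func:`dixon_magnitude_fit`; with sigma = 0 the expectation operator is
    the identity and the initializer's solution is returned unchanged.
    """
    config = config or FitConfig()
    init = dixon_magnitude_fit(series, spectrum, protocol, config)
    if noise.sigma == 0:
        return init
    te, s = series.te, series.magnitude
    c = fat_dephasing(spectrum, te, protocol.field_strength)
    sigma = noise.sigma

    def resid(p):
        nu = _model_magnitude(p[0], p[1], p[2], c, te)
        return rician_expectation(nu, sigma) - s

    x0 = [max(init.w_hat, 0.0), max(init.f_hat, 0.0), max(init.r2star_hat, 0.0)]
    sol = least_squares(resid, x0=x0,
                        bounds=([0.0, 0.0, 0.0], [np.inf, np.inf, np.inf]),
                        xtol=config.tol, ftol=config.tol, gtol=config.tol,
                        max_nfev=50 * config.max_iter)
    w, f, r = (float(v) for v in sol.x)
    capped = False
    if config.r2star_cap is not None and r > config.r2star_cap:
        r, capped = float(config.r2star_cap), True
    return FitResult(r2star_hat=r, w_hat=w, f_hat=f, pdff_hat=_pdff(w, f),
                     n_echoes_used=te.size, residual=float(np.sum(sol.fun ** 2)),
                     converged=bool(sol.success), swap_flag=init.swap_flag,
                     capped=capped)


# ---------------------------------------------------------------------------
# map-level fitting and swap handling
# ---------------------------------------------------------------------------

_ENGINES = ("truncation", "dixon", "noise_corrected")


def fit_voxels(stack: np.ndarray, voxel_index: np.ndarray, engine: str,
               protocol: Protocol, spectrum: FatSpectrum | None = None,
               noise: NoiseModel | None = None,
               config: FitConfig | None = None) -> dict[str, np.ndarray]:
    """Fit a subset of voxels of a (rows, cols, n_echoes) magnitude stack.

    ``voxel_index`` is a boolean mask over the spatial grid.  Returns flat
    arrays (ordered like ``np.flatnonzero(mask)``) of the FitResult fields.
    The Dixon engines share one vectorized grid scan across all requested
    voxels before per-voxel refinement.
    """
    config = config or FitConfig()
    if engine not in _ENGINES:
        raise ValueError(f"unknown engine {engine!r}; choose from {_ENGINES}")
    if stack.shape[:-1] != voxel_index.shape:
        raise ValueError("stack and voxel mask shapes disagree")
    te = protocol.echo_times
    if stack.shape[-1] != te.size:
        raise ValueError("stack echo dimension does not match protocol")
    S = stack[voxel_index]                                    # (V, n)
    nvox = S.shape[0]
    out = {k: np.zeros(nvox) for k in
           ("r2star", "w", "f", "pdff", "residual")}
    out["swap"] = np.zeros(nvox, dtype=bool)
    out["converged"] = np.zeros(nvox, dtype=bool)

    if engine == "truncation":
        for i in range(nvox):
            fr = truncation_fit(EchoSeries(te, S[i]), noise, config)
            _store(out, i, fr)
        return out

    c = fat_dephasing(spectrum, te, protocol.field_strength)
    r_grid, phi_grid, amp, resid = _dixon_grid_scan(S, te, c, config)
    for i in range(nvox):
        fr = _dixon_from_scan(S[i], te, c, r_grid, phi_grid,
                              amp[i], resid[i], config)
        if engine == "noise_corrected" and noise.sigma > 0:
            fr = _nc_refine(S[i], te, c, noise.sigma, fr, config)
        _store(out, i, fr)
    return out


def _nc_refine(s, te, c, sigma, init: FitResult,
               config: FitConfig) -> FitResult:
    def resid(p):
        nu = _model_magnitude(p[0], p[1], p[2], c, te)
        return rician_expectation(nu, sigma) - s

    sol = least_squares(resid,
                        x0=[max(init.w_hat, 0.0), max(init.f_hat, 0.0),
                            max(init.r2star_hat, 0.0)],
                        bounds=([0.0, 0.0, 0.0], [np.inf, np.inf, np.inf]),
                        xtol=config.tol, ftol=config.tol, gtol=config.tol,
                        max_nfev=50 * config.max_iter)
    w, f, r = (float(v) for v in sol.x)
    capped = False
    if config.r2star_cap is not None and r > config.r2star_cap:
        r, capped = float(config.r2star_cap), True
    return replace(init, r2star_hat=r, w_hat=w, f_hat=f, pdff_hat=_pdff(w, f),
                   residual=float(np.sum(sol.fun ** 2)),
                   converged=bool(sol.success), capped=capped)


def _store(out: dict, i: int, fr: FitResult) -> None:
    out["r2star"][i] = fr.r2star_hat
    out["w"][i] = fr.w_hat if fr.w_hat is not None else np.nan
    out["f"][i] = fr.f_hat if fr.f_hat is not None else np.nan
    out["pdff"][i] = fr.pdff_hat if fr.pdff_hat is not None else np.nan
    out["residual"][i] = fr.residual
    out["swap"][i] = fr.swap_flag
    out["converged"][i] = fr.converged


def detect_and_reverse_swap(fit_maps: dict[str, np.ndarray],
                            liver_mask: np.ndarray,
                            reverse: bool = True):
    """Organ-level global fat/water swap detection (rule-based surrogate).

    If the median fitted fat fraction over the liver mask exceeds 0.5 the
    water/fat maps are considered globally exchanged.  With ``reverse``
    the maps are corrected in a copy (w <-> f, pdff -> 1 - pdff); otherwise
    the maps are returned untouched and only the flag reports the swap.
    """
    liver_mask = np.asarray(liver_mask, dtype=bool)
    if not np.any(liver_mask):
        raise ValueError("liver mask is empty")
    pdff = np.asarray(fit_maps["pdff"], dtype=float)
    if pdff.shape == liver_mask.shape:
        median = float(np.nanmedian(pdff[liver_mask]))
    else:  # flat arrays aligned with the mask's selected voxels
        median = float(np.nanmedian(pdff))
    swapped = median > 0.5
    report = {"swap": bool(swapped), "median_pdff": median,
              "reversed": bool(swapped and reverse)}
    if not (swapped and reverse):
        return dict(fit_maps), report
    corrected = dict(fit_maps)
    corrected["w"] = np.array(fit_maps["f"], copy=True)
    corrected["f"] = np.array(fit_maps["w"], copy=True)
    corrected["pdff"] = 1.0 - pdff
    return corrected, report
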