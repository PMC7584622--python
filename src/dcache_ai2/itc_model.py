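"""One-site ITC binding model: simulation, dilution correction, fitting.

Model
-----
An isothermal titration injects ligand (syringe concentration ``Ls``)
into a cell of volume ``V0`` holding macromolecule at ``M0``.  Each
injection of volume ``v_i`` displaces cell contents, so total
concentrations follow the displacement recursion

    M_i = M_{i-1} (1 - v_i/V0)
    L_i = L_{i-1} (1 - v_i/V0) + Ls v_i/V0 .

With one class of ``n`` independent sites of dissociation constant
``Kd``, the bound-complex concentration is the root of
``Kd [PL] = (n M - [PL])(L - [PL])``:

    [PL]_i = ((n M_i + L_i + Kd) - sqrt((n M_i + L_i + Kd)^2
              - 4 n M_i L_i)) / 2

and the heat evolved by injection i (µJ) is

    q_i = ΔH V0 ([PL]_i - [PL]_{i-1} (1 - v_i/V0)) + q_offset ,

ΔH in J/mol, plus optional i.i.d. Gaussian noise.  The ``(1 - v/V0)``
factor accounts for complex displaced out of the active volume.

Fitting is nonlinear least squares over (log10 Kd, n, ΔH, q_offset),
multi-start on a log-spaced Kd grid, best residual sum of squares wins;
``n`` may be clamped (customary for low-Wiseman-c titrations, where
stoichiometry is not identifiable).  The Wiseman parameter
``c = n M0 / Kd`` is reported as a fit-quality diagnostic.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.optimize import least_squares


@dataclass(frozen=True)
class TitrationProtocol:
    """Injection schedule and cell contents (SI units)."""

    syringe_conc_M: float
    cell_conc_M: float
    cell_volume_L: float = 1.0e-3
    injection_volumes_L: tuple[float, ...] = (10.0e-6,) * 25
    temperature_K: float = 293.15

    def __post_init__(self) -> None:
        if self.cell_volume_L <= 0 or self.temperature_K <= 0:
            raise ValueError("cell volume and temperature must be positive")
        if self.syringe_conc_M < 0 or self.cell_conc_M < 0:
            raise ValueError("concentrations must be non-negative")
        if any(v <= 0 for v in self.injection_volumes_L):
            raise ValueError("injection volumes must be positive")
        if sum(self.injection_volumes_L) > 0.5 * self.cell_volume_L:
            raise ValueError("total injected volume exceeds half the cell volume")

    @property
    def n_injections(self) -> int:
        return len(self.injection_volumes_L)


@dataclass(frozen=True)
class OneSiteParams:
    """Kd (mol/L), stoichiometry n (sites), ΔH (J/mol), background heat (µJ)."""

    Kd: float
    n: float = 1.0
    dH: float = -40_000.0
    q_offset: float = 0.0

    def __post_init__(self) -> None:
        if self.Kd <= 0 or self.n <= 0:
            raise ValueError("Kd and n must be positive")


@dataclass(frozen=True)
class Thermogram:
    """Per-injection heats in µJ, optionally with a dilution control."""

    heats_uJ: tuple[float, ...]
    control_uJ: tuple[float, ...] | None = None

    def __post_init__(self) -> None:
        if not all(math.isfinite(q) for q in self.heats_uJ):
            raise ValueError("non-finite heat value")
        if self.control_uJ is not None and \
                len(self.control_uJ) != len(self.heats_uJ):
            raise ValueError("control length differs from thermogram length")

    def __len__(self) -> int:
        return len(self.heats_uJ)


@dataclass(frozen=True)
class FitResult:
    params: OneSiteParams
    stderr: dict[str, float]
    rss: float
    wiseman_c: float
    converged: bool
    n_fixed: bool
    warnings: tuple[str, ...] = ()


def bound_complex(total_sites_M: float | np.ndarray,
                  total_ligand_M: float | np.ndarray,
                  Kd: float) -> float | np.ndarray:
    """Equilibrium bound-complex concentration for one-site binding.

    Uses the numerically stable root of the binding quadratic
    ``[PL]^2 - (S + L + Kd)[PL] + S L = 0`` (smaller root, the
    physical one, computed via the product of roots to avoid
    cancellation when binding is tight).
    """
    s = np.asarray(total_sites_M, dtype=float)
    l = np.asarray(total_ligand_M, dtype=float)
    b = s + l + Kd
    disc = b * b - 4.0 * s * l
    assert np.all(disc >= -1e-30), "binding quadratic has negative discriminant"
    root_big = (b + np.sqrt(np.maximum(disc, 0.0))) / 2.0
    with np.errstate(invalid="ignore", divide="ignore"):
        pl = np.where(root_big > 0, s * l / root_big, 0.0)
    return float(pl) if pl.ndim == 0 else pl


def injection_heats(protocol: TitrationProtocol,
                    params: OneSiteParams) -> np.ndarray:
    """Noise-free per-injection heats (µJ) under the displacement model."""
    V0 = protocol.cell_volume_L
    M = protocol.cell_conc_M
    L = 0.0
    pl_prev = 0.0
    heats = np.empty(protocol.n_injections)
    for i, v in enumerate(protocol.injection_volumes_L):
        d = 1.0 - v / V0
        M *= d
        L = L * d + protocol.syringe_conc_M * v / V0
        pl = bound_complex(params.n * M, L, params.Kd)
        heats[i] = params.dH * V0 * (pl - pl_prev * d) * 1e6 + params.q_offset
        pl_prev = pl
    return heats


def simulate_titration(protocol: TitrationProtocol, params: OneSiteParams,
                       noise_sd_uJ: float = 0.0,
                       seed: int | np.random.Generator | None = None,
                       ) -> Thermogram:
    """Simulate one titration; fixed seed gives bit-reproducible output."""
    if noise_sd_uJ < 0:
        raise ValueError("noise_sd must be non-negative")
    heats = injection_heats(protocol, params)
    if noise_sd_uJ > 0:
        rng = (seed if isinstance(seed, np.random.Generator)
               else np.random.default_rng(seed))
        heats = heats + rng.normal(0.0, noise_sd_uJ, size=heats.shape)
    return Thermogram(heats_uJ=tuple(float(q) for q in heats))


def subtract_dilution(thermogram: Thermogram,
                      control: Thermogram | None = None) -> Thermogram:
    """Elementwise heat-of-dilution correction."""
    if control is None:
        if thermogram.control_uJ is None:
            raise ValueError("no dilution control supplied")
        control_heats = thermogram.control_uJ
    else:
        control_heats = control.heats_uJ
    if len(control_heats) != len(thermogram):
        raise ValueError(
            f"control has {len(control_heats)} injections, "
            f"thermogram has {len(thermogram)}"
        )
    corrected = tuple(q - c for q, c in zip(thermogram.heats_uJ, control_heats))
    return Thermogram(heats_uJ=corrected)


def wiseman_c(protocol: TitrationProtocol, params: OneSiteParams) -> float:
    """Wiseman parameter c = n·M0/Kd (isotherm-shape diagnostic)."""
    return params.n * protocol.cell_conc_M / params.Kd


_LOG10_KD_BOUNDS = (-12.0, -1.0)
_N_BOUNDS = (0.05, 10.0)


def fit_one_site(thermogram: Thermogram, protocol: TitrationProtocol,
                 fix_n: float | None = None,
                 n_starts: int = 8,
                 discard_first: bool = False,
                 weights: np.ndarray | None = None) -> FitResult:
    """Fit (Kd, n, ΔH, q_offset) to a dilution-corrected thermogram.

    Multi-start weighted least squares with Kd log-parameterized;
    starting Kd values are log-spaced across the plausible affinity
    range and the best residual sum of squares wins.  ``fix_n`` clamps
    the stoichiometry (recommended when c = n·M0/Kd < 1, where n and
    ΔH are not jointly identifiable).  Non-convergence is flagged on
    the result, not raised.
    """
    heats = np.asarray(thermogram.heats_uJ, dtype=float)
    mask = np.ones(len(heats), dtype=bool)
    if discard_first:
        mask[0] = False
    n_free = 3 if fix_n is not None else 4
    if mask.sum() < max(6, n_free + 1):
        raise ValueError("too few injections for a one-site fit")
    w = np.ones(mask.sum()) if weights is None else np.asarray(weights)[mask]

    def model(theta: np.ndarray) -> np.ndarray:
        if fix_n is None:
            log_kd, n, dh, q0 = theta
        else:
            log_kd, dh, q0 = theta
            n = fix_n
        p = OneSiteParams(Kd=10.0 ** log_kd, n=n, dH=dh, q_offset=q0)
        return injection_heats(protocol, p)[mask]

    def residuals(theta: np.ndarray) -> np.ndarray:
        return (model(theta) - heats[mask]) * w

    # crude ΔH scale from total heat assuming full saturation of the cell
    total_q_J = float(np.sum(heats[mask])) * 1e-6
    sat_moles = protocol.cell_conc_M * protocol.cell_volume_L
    dh0 = total_q_J / sat_moles if sat_moles > 0 else -4e4
    if dh0 == 0.0:
        dh0 = -4e4

    kd_starts = np.logspace(-9.5, -3.0, max(2, n_starts))
    lo, hi = [], []
    if fix_n is None:
        lo = [_LOG10_KD_BOUNDS[0], _N_BOUNDS[0], -1e7, -1e6]
        hi = [_LOG10_KD_BOUNDS[1], _N_BOUNDS[1], 1e7, 1e6]
    else:
        lo = [_LOG10_KD_BOUNDS[0], -1e7, -1e6]
        hi = [_LOG10_KD_BOUNDS[1], 1e7, 1e6]

    best = None
    for kd0 in kd_starts:
        for dh_scale in (1.0, 2.5):
            if fix_n is None:
                theta0 = np.array([math.log10(kd0), 1.0, dh0 * dh_scale, 0.0])
            else:
                theta0 = np.array([math.log10(kd0), dh0 * dh_scale, 0.0])
            try:
                sol = least_squares(residuals, theta0, bounds=(lo, hi),
                                    method="trf", xtol=1e-12, ftol=1e-12)
            except ValueError:
                continue
            rss = float(np.sum(sol.fun ** 2))
            if best is None or rss < best[0]:
                best = (rss, sol)
    if best is None:
        raise RuntimeError("all fit starts failed")
    rss, sol = best

    if fix_n is None:
        log_kd, n, dh, q0 = sol.x
    else:
        log_kd, dh, q0 = sol.x
        n = fix_n
    params = OneSiteParams(Kd=10.0 ** log_kd, n=float(n), dH=float(dh),
                           q_offset=float(q0))

    stderr = _standard_errors(sol, fix_n, params, mask.sum())
    c = wiseman_c(protocol, params)
    warns = []
    if c < 1.0:
        warns.append(f"Wiseman c = {c:.3g} < 1: Kd poorly constrained")
    elif c > 1000.0:
        warns.append(f"Wiseman c = {c:.3g} > 1000: isotherm too steep for Kd")
    if not sol.success:
        warns.append("optimizer did not report convergence")
    return FitResult(params=params, stderr=stderr, rss=rss, wiseman_c=c,
                     converged=bool(sol.success), n_fixed=fix_n is not None,
                     warnings=tuple(warns))


def _standard_errors(sol, fix_n, params: OneSiteParams,
                     n_points: int) -> dict[str, float]:
    """Asymptotic standard errors from the Jacobian at the optimum."""
    J = sol.jac
    dof = max(n_points - J.shape[1], 1)
    s2 = float(np.sum(sol.fun ** 2)) / dof
    try:
        cov = s2 * np.linalg.inv(J.T @ J)
        se = np.sqrt(np.maximum(np.diag(cov), 0.0))
    except np.linalg.LinAlgError:
        se = np.full(J.shape[1], np.nan)
    if fix_n is None:
        se_logkd, se_n, se_dh, se_q0 = se
    else:
        se_logkd, se_dh, se_q0 = se
        se_n = 0.0
    return {
        "Kd": float(params.Kd * math.log(10) * se_logkd),
        "n": float(se_n),
        "dH": float(se_dh),
        "q_offset": float(se_q0),
    }
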