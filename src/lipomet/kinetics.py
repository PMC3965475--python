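"""Steady-state population-balance model of ApoB-containing lipoproteins.

The model follows particles over a discrete grid of diameters spanning LDL
through VLDL.  Particles are produced by the liver with a log-normal size
density, shrink one bin at a time through lipolysis (lipoprotein lipase,
LPL, acting preferentially on large triglyceride-rich particles; hepatic
lipase, HL, on small remnants), attach to the liver, and are taken up.
At steady state the balance in bin ``i`` (bins ordered small -> large) is

    (lambda_i + a_i) * c_i = P_i + lambda_{i+1} * c_{i+1}

with ``lambda_i = k_lpl * f_L(d_i) + k_hl * f_H(d_i)`` the total lipolysis
rate, ``a_i = k_att * g(d_i)`` the liver-attachment rate, and ``P_i`` the
production influx.  Lipolysis out of the smallest bin exits the system.
Attached particles are internalized (taken up) at rate ``k_upt`` with no
detachment, so the attachment flux equals the uptake flux at steady state
and ``k_upt`` only sets the size of the liver-attached pool; it is not
identifiable from a plasma profile and is tied to ``k_att`` in canonical
form.

Concentrations are invariant under joint rescaling of the production flux
and all four rate constants, so fitted parameters are reported in the
canonical form ``f_prod_total = 1``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Callable, Dict, Mapping, Tuple

import numpy as np
from scipy.optimize import least_squares
from scipy.special import expit
from scipy.stats import qmc

from .errors import (
    ConvergenceError,
    DegenerateModelError,
    InvalidParameterError,
    UnfittableProfileError,
)

__all__ = [
    "SizeGrid",
    "KineticParameters",
    "ParticleProfile",
    "ProcessFluxes",
    "LipaseShapes",
    "FitConfig",
    "FitDiagnostics",
    "steady_state_concentrations",
    "process_fluxes",
    "fit_kinetic_parameters",
    "RANGE_NAMES",
    "PROCESS_NAMES",
]

#: The three diameter ranges over which process fluxes are aggregated.
RANGE_NAMES = ("VLDL_to_LDL", "VLDL_only", "IDL_to_LDL")

#: The six modeled processes whose range-wise fluxes form indicator ratios.
PROCESS_NAMES = (
    "production",
    "total_lipolysis",
    "lpl_lipolysis",
    "hl_lipolysis",
    "attachment",
    "uptake",
)


# ---------------------------------------------------------------------------
# size grid


@dataclass(frozen=True)
class SizeGrid:
    """Discrete particle-diameter grid with named subclasses and ranges.

    Parameters
    ----------
    bin_diameters
        Strictly increasing bin-center diameters in nm (index 0 is the
        smallest particle).
    subclass_map
        Named subclasses -> half-open bin index ranges ``(lo, hi)``.
        Subclasses must tile the grid without gaps or overlaps.
    class_ranges
        Named aggregation ranges (``VLDL_to_LDL``, ``VLDL_only``,
        ``IDL_to_LDL``) -> half-open bin index ranges.
    """

    bin_diameters: np.ndarray
    subclass_map: Dict[str, Tuple[int, int]]
    class_ranges: Dict[str, Tuple[int, int]]

    def __post_init__(self):
        d = np.asarray(self.bin_diameters, dtype=float)
        object.__setattr__(self, "bin_diameters", d)
        if d.ndim != 1 or d.size < 3:
            raise ValueError("grid needs at least 3 bins")
        if np.any(d <= 0) or np.any(np.diff(d) <= 0):
            raise ValueError("bin diameters must be positive and strictly increasing")
        covered = np.zeros(d.size, dtype=int)
        for name, (lo, hi) in self.subclass_map.items():
            if not (0 <= lo < hi <= d.size):
                raise ValueError(f"subclass {name!r} range {(lo, hi)} out of bounds")
            covered[lo:hi] += 1
        if np.any(covered != 1):
            raise ValueError("subclasses must tile the grid exactly once")
        v = self.class_ranges.get("VLDL_only")
        i = self.class_ranges.get("IDL_to_LDL")
        w = self.class_ranges.get("VLDL_to_LDL")
        if v and i and w:
            if not (i[1] == v[0] and w == (i[0], v[1])):
                raise ValueError("VLDL_only and IDL_to_LDL must partition VLDL_to_LDL")

    @property
    def n_bins(self) -> int:
        return int(self.bin_diameters.size)

    @property
    def subclass_names(self) -> Tuple[str, ...]:
        return tuple(self.subclass_map)

    def range_slice(self, range_name: str) -> slice:
        try:
            lo, hi = self.class_ranges[range_name]
        except KeyError:
            raise KeyError(
                f"unknown range {range_name!r}; expected one of {RANGE_NAMES}"
            ) from None
        return slice(lo, hi)

    def subclass_sums(self, bin_values: np.ndarray) -> Dict[str, float]:
        return {
            name: float(np.sum(bin_values[lo:hi]))
            for name, (lo, hi) in self.subclass_map.items()
        }

    @classmethod
    def default(
        cls,
        n_bins: int = 60,
        d_min: float = 19.0,
        d_max: float = 80.0,
        subclass_boundaries: Mapping[str, Tuple[float, float]] | None = None,
    ) -> "SizeGrid":
        """Conventional NMR-style grid: 60 log-spaced bins over 19-80 nm,
        LDL 19-23 nm (three sub-bands), IDL 23-27 nm, VLDL 27-80 nm (three
        sub-bands)."""
        if subclass_boundaries is None:
            subclass_boundaries = {
                "LDL_small": (19.0, 20.5),
                "LDL_medium": (20.5, 21.7),
                "LDL_large": (21.7, 23.0),
                "IDL": (23.0, 27.0),
                "VLDL_small": (27.0, 35.0),
                "VLDL_medium": (35.0, 60.0),
                "VLDL_large": (60.0, d_max + 1e-9),
            }
        d = np.geomspace(d_min, d_max, n_bins)
        subclass_map: Dict[str, Tuple[int, int]] = {}
        for name, (lo_d, hi_d) in subclass_boundaries.items():
            idx = np.nonzero((d >= lo_d - 1e-12) & (d < hi_d))[0]
            if idx.size == 0:
                raise ValueError(f"subclass {name!r} captures no bins")
            subclass_map[name] = (int(idx[0]), int(idx[-1]) + 1)
        # contiguity check happens in __post_init__
        vldl_lo = subclass_map["VLDL_small"][0]
        class_ranges = {
            "VLDL_to_LDL": (0, n_bins),
            "VLDL_only": (vldl_lo, n_bins),
            "IDL_to_LDL": (0, vldl_lo),
        }
        return cls(d, subclass_map, class_ranges)


# ---------------------------------------------------------------------------
# kinetic parameters and size-dependence shapes


@dataclass(frozen=True)
class LipaseShapes:
    """Size dependence of the lipolysis and attachment rates.

    LPL activity rises with diameter (triglyceride-rich substrate), HL
    activity falls with diameter (remnant substrate); both are logistic in
    d with configurable midpoint/scale in nm.  Attachment is size-neutral
    by default.
    """

    lpl_midpoint: float = 30.0
    lpl_scale: float = 2.0
    hl_midpoint: float = 26.0
    hl_scale: float = 2.0
    attachment: Callable[[np.ndarray], np.ndarray] | None = None

    def f_lpl(self, d: np.ndarray) -> np.ndarray:
        return expit((np.asarray(d, float) - self.lpl_midpoint) / self.lpl_scale)

    def f_hl(self, d: np.ndarray) -> np.ndarray:
        return expit(-(np.asarray(d, float) - self.hl_midpoint) / self.hl_scale)

    def f_att(self, d: np.ndarray) -> np.ndarray:
        if self.attachment is None:
            return np.ones_like(np.asarray(d, float))
        return np.asarray(self.attachment(np.asarray(d, float)), float)


DEFAULT_SHAPES = LipaseShapes()

_PARAM_FIELDS = ("f_prod_total", "prod_mu", "prod_sigma", "k_lpl", "k_hl", "k_att", "k_upt")


@dataclass(frozen=True)
class KineticParameters:
    """Production flux and first-order rate constants of the six processes.

    Attributes
    ----------
    f_prod_total
        Total particle production flux, nmol/L per hour.
    prod_mu, prod_sigma
        Median (nm) and log-space width of the log-normal production size
        density.
    k_lpl, k_hl
        LPL and HL lipolysis rate scales, per hour.
    k_att
        Liver attachment rate scale, per hour.
    k_upt
        Uptake rate of liver-attached particles, per hour.  Sets only the
        attached-pool size; tied to ``k_att`` in canonical form.
    """

    f_prod_total: float
    prod_mu: float
    prod_sigma: float
    k_lpl: float
    k_hl: float
    k_att: float
    k_upt: float

    def __post_init__(self):
        # production-density location/width must be strictly positive; the
        # flux and rate constants may be exactly zero (absent process)
        for name in _PARAM_FIELDS:
            v = getattr(self, name)
            if not np.isfinite(v) or v < 0:
                raise InvalidParameterError(f"{name} must be non-negative, got {v}")
        for name in ("prod_mu", "prod_sigma"):
            if getattr(self, name) <= 0:
                raise InvalidParameterError(f"{name} must be strictly positive")

    def scaled(self, alpha: float) -> "KineticParameters":
        """Jointly rescale production and all rate constants by ``alpha``.
        Steady-state concentrations are invariant under this map."""
        if alpha <= 0:
            raise InvalidParameterError("scale factor must be positive")
        return replace(
            self,
            f_prod_total=self.f_prod_total * alpha,
            k_lpl=self.k_lpl * alpha,
            k_hl=self.k_hl * alpha,
            k_att=self.k_att * alpha,
            k_upt=self.k_upt * alpha,
        )

    def canonical(self) -> "KineticParameters":
        """Resolve the scale non-identifiability: ``f_prod_total = 1``."""
        if self.f_prod_total == 0:
            raise InvalidParameterError("cannot canonicalize zero production")
        scaled = self.scaled(1.0 / self.f_prod_total)
        return replace(scaled, f_prod_total=1.0)  # exact, not f*(1/f)

    def as_dict(self) -> Dict[str, float]:
        return {name: float(getattr(self, name)) for name in _PARAM_FIELDS}


# ---------------------------------------------------------------------------
# forward model


@dataclass(frozen=True)
class ParticleProfile:
    """Per-bin and per-subclass particle concentrations (nmol/L)."""

    grid: SizeGrid
    bin_concentrations: np.ndarray
    subclass_concentrations: Dict[str, float] = field(default_factory=dict)

    def __post_init__(self):
        c = np.asarray(self.bin_concentrations, dtype=float)
        object.__setattr__(self, "bin_concentrations", c)
        if c.shape != (self.grid.n_bins,):
            raise ValueError("bin_concentrations length must match grid")
        if np.any(c < 0):
            raise ValueError("concentrations must be non-negative")
        if not self.subclass_concentrations:
            object.__setattr__(
                self, "subclass_concentrations", self.grid.subclass_sums(c)
            )

    @property
    def total(self) -> float:
        return float(self.bin_concentrations.sum())


def _rates(params: KineticParameters, grid: SizeGrid, shapes: LipaseShapes):
    d = grid.bin_diameters
    lam_lpl = params.k_lpl * shapes.f_lpl(d)
    lam_hl = params.k_hl * shapes.f_hl(d)
    att = params.k_att * shapes.f_att(d)
    return lam_lpl, lam_hl, att


def production_density(params: KineticParameters, grid: SizeGrid) -> np.ndarray:
    """Per-bin production influx P_i (nmol/L/h), log-normal in diameter and
    normalized so that sum(P) = f_prod_total."""
    z = (np.log(grid.bin_diameters) - np.log(params.prod_mu)) / params.prod_sigma
    logw = -0.5 * z * z
    w = np.exp(logw - logw.max())  # stable even for extreme mu/sigma
    total = w.sum()
    if not np.isfinite(total) or total <= 0:
        raise DegenerateModelError("production density vanishes on the grid")
    return params.f_prod_total * w / total


def steady_state_concentrations(
    params: KineticParameters,
    grid: SizeGrid,
    shapes: LipaseShapes = DEFAULT_SHAPES,
    production: np.ndarray | None = None,
) -> ParticleProfile:
    """Solve the steady-state balance by downward recursion from the
    largest bin.

    ``production`` overrides the log-normal production density with an
    explicit per-bin influx vector (used by tests and custom scenarios).
    """
    lam_lpl, lam_hl, att = _rates(params, grid, shapes)
    lam = lam_lpl + lam_hl
    P = production_density(params, grid) if production is None else np.asarray(production, float)
    if P.shape != (grid.n_bins,):
        raise ValueError("production vector length must match grid")
    out = lam + att
    n = grid.n_bins
    c = np.zeros(n)
    inflow = 0.0  # lipolysis influx from the (absent) bin above the top
    for i in range(n - 1, -1, -1):
        influx = P[i] + inflow
        if out[i] <= 0.0:
            if influx > 0.0:
                raise DegenerateModelError(
                    f"bin {i} has zero outflow rate but inflow {influx:g}"
                )
            c[i] = 0.0
            inflow = 0.0
            continue
        c[i] = influx / out[i]
        inflow = lam[i] * c[i]
    return ParticleProfile(grid=grid, bin_concentrations=c)


# ---------------------------------------------------------------------------
# process fluxes


@dataclass(frozen=True)
class ProcessFluxes:
    """Range-aggregated fluxes of the six modeled processes (nmol/L/h).

    ``boundary_influx`` is the lipolysis flux entering the range across its
    upper diameter boundary (zero when the range contains the largest bin);
    ``influx`` is production + boundary influx.  ``mean_hl_rate_constant``
    is the concentration-weighted mean HL rate constant over the range
    (per hour).
    """

    range_name: str
    production: float
    boundary_influx: float
    lpl_lipolysis: float
    hl_lipolysis: float
    total_lipolysis: float
    attachment: float
    uptake: float
    mean_hl_rate_constant: float

    @property
    def influx(self) -> float:
        return self.production + self.boundary_influx

    def by_process(self) -> Dict[str, float]:
        return {
            "production": self.production,
            "total_lipolysis": self.total_lipolysis,
            "lpl_lipolysis": self.lpl_lipolysis,
            "hl_lipolysis": self.hl_lipolysis,
            "attachment": self.attachment,
            "uptake": self.uptake,
        }


def process_fluxes(
    params: KineticParameters,
    profile: ParticleProfile,
    range_name: str,
    shapes: LipaseShapes = DEFAULT_SHAPES,
    production: np.ndarray | None = None,
) -> ProcessFluxes:
    """Aggregate the six process fluxes over one named diameter range."""
    grid = profile.grid
    sl = grid.range_slice(range_name)
    lam_lpl, lam_hl, att = _rates(params, grid, shapes)
    P = production_density(params, grid) if production is None else np.asarray(production, float)
    c = profile.bin_concentrations
    f_lpl = float(np.sum(lam_lpl[sl] * c[sl]))
    f_hl = float(np.sum(lam_hl[sl] * c[sl]))
    f_att = float(np.sum(att[sl] * c[sl]))
    top = sl.stop
    if top >= grid.n_bins:
        boundary = 0.0
    else:
        boundary = float((lam_lpl[top] + lam_hl[top]) * c[top])
    c_sum = float(np.sum(c[sl]))
    mean_hl = float(np.sum(lam_hl[sl] * c[sl]) / c_sum) if c_sum > 0 else 0.0
    return ProcessFluxes(
        range_name=range_name,
        production=float(np.sum(P[sl])),
        boundary_influx=boundary,
        lpl_lipolysis=f_lpl,
        hl_lipolysis=f_hl,
        total_lipolysis=f_lpl + f_hl,
        attachment=f_att,
        uptake=f_att,
        mean_hl_rate_constant=mean_hl,
    )


def smallest_bin_exit_flux(
    params: KineticParameters,
    profile: ParticleProfile,
    shapes: LipaseShapes = DEFAULT_SHAPES,
) -> float:
    """Lipolysis flux leaving the system through the smallest bin."""
    lam_lpl, lam_hl, _ = _rates(params, profile.grid, shapes)
    return float((lam_lpl[0] + lam_hl[0]) * profile.bin_concentrations[0])


# ---------------------------------------------------------------------------
# inverse fitting


@dataclass(frozen=True)
class FitConfig:
    """Settings for the inverse fit of canonical kinetic parameters.

    The five free parameters (prod_mu, prod_sigma, k_lpl, k_hl, k_att) are
    optimized in log space with ``f_prod_total`` fixed to 1 and ``k_upt``
    tied to ``k_att``.  Residuals are relative subclass misfits
    ``(model - obs) / (obs + eps)``.
    """

    n_starts: int = 10
    seed: int = 0
    eps: float = 1e-6
    bound_lo: float = 1e-6
    bound_hi: float = 1e6
    ftol: float = 1e-12
    xtol: float = 1e-14
    max_nfev: int = 400
    early_stop_objective: float = 1e-16
    min_nonzero_subclasses: int = 4


@dataclass(frozen=True)
class FitDiagnostics:
    objective: float
    n_iterations: int
    winning_start: int
    converged: bool
    n_starts_run: int


def _pack(params: KineticParameters) -> np.ndarray:
    return np.log(
        [params.prod_mu, params.prod_sigma, params.k_lpl, params.k_hl, params.k_att]
    )


def _unpack(x: np.ndarray) -> KineticParameters:
    mu, sigma, k_lpl, k_hl, k_att = np.exp(x)
    return KineticParameters(
        f_prod_total=1.0,
        prod_mu=mu,
        prod_sigma=sigma,
        k_lpl=k_lpl,
        k_hl=k_hl,
        k_att=k_att,
        k_upt=k_att,
    )


def model_subclass_concentrations(
    params: KineticParameters, grid: SizeGrid, shapes: LipaseShapes = DEFAULT_SHAPES
) -> np.ndarray:
    profile = steady_state_concentrations(params, grid, shapes)
    return np.array([profile.subclass_concentrations[s] for s in grid.subclass_names])


def _start_box(grid: SizeGrid, obs_total: float, config: FitConfig):
    """Log-space sampling box for multistart initial points.  Rate starts
    are centered on 1/total concentration, the scale the balance equation
    itself implies for canonical (unit-production) parameters."""
    rate_center = np.log(1.0 / max(obs_total, 1e-12))
    lo = np.array(
        [np.log(grid.bin_diameters[2]), np.log(0.05), rate_center - 3.0,
         rate_center - 3.0, rate_center - 3.0]
    )
    hi = np.array(
        [np.log(grid.bin_diameters[-3]), np.log(1.0), rate_center + 3.0,
         rate_center + 3.0, rate_center + 3.0]
    )
    log_lo = np.log(config.bound_lo)
    log_hi = np.log(config.bound_hi)
    return np.clip(lo, log_lo, log_hi), np.clip(hi, log_lo, log_hi)


def fit_kinetic_parameters(
    observed: ParticleProfile | Mapping[str, float],
    grid: SizeGrid | None = None,
    config: FitConfig = FitConfig(),
    shapes: LipaseShapes = DEFAULT_SHAPES,
) -> Tuple[KineticParameters, FitDiagnostics]:
    """Fit canonical kinetic parameters to an observed subclass profile.

    Multi-start trust-region least squares on log-parameters; the winning
    start is the one with the lowest relative-residual objective.  Raises
    :class:`UnfittableProfileError` for profiles with fewer than
    ``config.min_nonzero_subclasses`` nonzero subclasses and
    :class:`ConvergenceError` (carrying best-effort parameters) if no
    start converges.
    """
    if isinstance(observed, ParticleProfile):
        grid = observed.grid
        obs = np.array(
            [observed.subclass_concentrations[s] for s in grid.subclass_names]
        )
    else:
        if grid is None:
            raise ValueError("grid is required when passing subclass concentrations")
        obs = np.array([float(observed[s]) for s in grid.subclass_names])
    if np.any(obs < 0):
        raise UnfittableProfileError("negative subclass concentration")
    if np.count_nonzero(obs) < config.min_nonzero_subclasses:
        raise UnfittableProfileError(
            f"need at least {config.min_nonzero_subclasses} nonzero subclasses"
        )

    denom = obs + config.eps
    log_lo = np.log(config.bound_lo)
    log_hi = np.log(config.bound_hi)

    def residuals(x: np.ndarray) -> np.ndarray:
        model = model_subclass_concentrations(_unpack(x), grid, shapes)
        return (model - obs) / denom

    lo, hi = _start_box(grid, float(obs.sum()), config)
    sampler = qmc.LatinHypercube(d=5, seed=config.seed)
    starts = lo + sampler.random(config.n_starts) * (hi - lo)

    best = None
    best_obj = np.inf
    best_start = -1
    total_nfev = 0
    any_converged = False
    for s_idx in range(config.n_starts):
        res = least_squares(
            residuals,
            starts[s_idx],
            bounds=(log_lo, log_hi),
            method="trf",
            ftol=config.ftol,
            xtol=config.xtol,
            gtol=None,
            max_nfev=config.max_nfev,
        )
        total_nfev += res.nfev
        obj = 2.0 * res.cost  # sum of squared residuals
        if res.status > 0:
            any_converged = True
        if obj < best_obj:
            best_obj = obj
            best = res.x
            best_start = s_idx
        if obj < config.early_stop_objective:
            break

    diagnostics = FitDiagnostics(
        objective=float(best_obj),
        n_iterations=int(total_nfev),
        winning_start=int(best_start),
        converged=bool(any_converged),
        n_starts_run=int(s_idx + 1),
    )
    params = _unpack(best)
    if not any_converged:
        raise ConvergenceError(
            "no optimizer start converged", parameters=params, diagnostics=diagnostics
        )
    return params, diagnostics
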