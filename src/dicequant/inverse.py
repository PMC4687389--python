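"""Least-squares calibration of sorption parameters against CT profiles.

The tunable parameters of the staining model are the per-zone partition
coefficients (one per distinct zone *name*) and the boundary iodine flux.
:class:`StainTransportModel` holds the observed concentration profiles and a
template domain; :meth:`StainTransportModel.fit` minimises the sum of squared
residuals between modelled total concentration and the observations over all
(day, position) points, running the forward solver at every candidate.

Because partition coefficients and the flux span orders of magnitude, the
optimiser works internally in log10 of each parameter (trust-region
reflective least squares with box bounds); the forward model is smooth in
the parameters but has no analytic gradient, so finite differences are used.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import least_squares

from .domain import SECONDS_PER_DAY, SolverConfig, ZonedDomain
from .profiles import LineProfile
from .solver import profiles_at_scan_days

__all__ = ["FitSpec", "StainTransportModel", "StainTransportResults", "fit", "profile_loss"]

#: Wide default bounds bracketing physiological sorption and bath-driven flux.
DEFAULT_BOUNDS = {"kd": (1.0, 1000.0), "nbc": (1e-8, 1e-4)}

#: Coarser-than-default discretisation used during fitting: each forward
#: solve costs ~3000 implicit steps on ~320 cells, keeping a full four-
#: parameter calibration to a couple of minutes.
DEFAULT_FIT_SOLVER = SolverConfig(n_cells=320, time_step=900.0, output_times=(0.0,))


@dataclass(frozen=True)
class FitSpec:
    """Which parameters are free, their bounds, and the starting point.

    ``free_parameters`` are ``"kd:<zone name>"`` entries (tying all zones of
    that name) plus optionally ``"nbc"``.  Bounds and initial guesses are
    keyed the same way; missing entries fall back to defaults (bounds) or the
    template's current values (guesses).
    """

    free_parameters: tuple[str, ...]
    bounds: dict[str, tuple[float, float]] = field(default_factory=dict)
    initial_guess: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.free_parameters:
            raise ValueError("at least one free parameter is required")
        for name in self.free_parameters:
            if name != "nbc" and not name.startswith("kd:"):
                raise ValueError(f"unknown parameter {name!r}; use 'kd:<zone>' or 'nbc'")
        for name, (lo, hi) in self.bounds.items():
            if not (0 < lo < hi):
                raise ValueError(f"bounds for {name!r} must satisfy 0 < low < high")
        for name, val in self.initial_guess.items():
            lo, hi = self._bounds_for(name)
            if not lo <= val <= hi:
                raise ValueError(f"initial guess for {name!r} ({val}) is outside bounds")

    def _bounds_for(self, name: str) -> tuple[float, float]:
        if name in self.bounds:
            return self.bounds[name]
        return DEFAULT_BOUNDS["nbc"] if name == "nbc" else DEFAULT_BOUNDS["kd"]


def _apply_params(template: ZonedDomain, names, values) -> ZonedDomain:
    kds: dict[str, float] = {}
    nbc = None
    for name, val in zip(names, values):
        if name == "nbc":
            nbc = float(val)
        else:
            kds[name.split(":", 1)[1]] = float(val)
    return template.with_parameters(partition_coeffs=kds, boundary_flux=nbc)


class StainTransportModel:
    """Three-zone diffusion-sorption staining model bound to observed profiles.

    Parameters
    ----------
    observed : sequence of LineProfile
        Converted profiles (``conc`` filled, mmol/L) at two or more distinct
        effective staining days — a single day cannot separate sorption from
        flux.
    template : ZonedDomain
        Domain supplying geometry, porosity, bulk density, diffusivity and
        the initial values of the parameters being calibrated.
    spec : FitSpec, optional
        Free parameters/bounds/guess; defaults to the three per-zone-name
        partition coefficients plus the boundary flux.
    solver_config : SolverConfig, optional
        Discretisation for the forward solves (output times are set
        automatically from the observed days).
    """

    def __init__(
        self,
        observed,
        template: ZonedDomain,
        spec: FitSpec | None = None,
        solver_config: SolverConfig | None = None,
    ) -> None:
        self.observed = tuple(observed)
        if not self.observed:
            raise ValueError("at least one observed profile is required")
        for p in self.observed:
            if p.conc is None:
                raise ValueError(f"profile {p.scan_id!r} has no concentrations; convert it first")
        days = sorted({float(p.effective_day) for p in self.observed})
        if len(days) < 2:
            raise ValueError(
                "need observations at >= 2 distinct effective days to identify flux vs sorption"
            )
        if all(np.all(p.conc == 0) for p in self.observed):
            raise ValueError("all observations are zero: parameters are unidentifiable")
        self.template = template
        self.days = tuple(days)
        if spec is None:
            zone_names = list(dict.fromkeys(z.name for z in template.zones))
            spec = FitSpec(tuple(f"kd:{n}" for n in zone_names) + ("nbc",))
        self.spec = spec
        self.solver_config = solver_config or DEFAULT_FIT_SOLVER
        self._nfev = 0

    @classmethod
    def from_dataframe(
        cls, df, template: ZonedDomain, spec: FitSpec | None = None, **kwargs
    ) -> "StainTransportModel":
        """Build from a long-format frame with columns ``scan_id``,
        ``actual_day``, ``effective_day``, ``position_m``, ``conc_mmol_per_L``."""
        profiles = []
        for sid, grp in df.groupby("scan_id", sort=False):
            grp = grp.sort_values("position_m")
            profiles.append(
                LineProfile(
                    scan_id=str(sid),
                    actual_day=float(grp["actual_day"].iloc[0]),
                    effective_day=float(grp["effective_day"].iloc[0]),
                    positions=grp["position_m"].to_numpy(),
                    grayscale=np.zeros(len(grp)),
                    conc=grp["conc_mmol_per_L"].to_numpy(),
                )
            )
        return cls(profiles, template, spec=spec, **kwargs)

    # -- forward machinery -------------------------------------------------

    def _template_values(self) -> dict[str, float]:
        vals: dict[str, float] = {}
        for name in self.spec.free_parameters:
            if name == "nbc":
                vals[name] = self.template.boundary_flux
            else:
                zname = name.split(":", 1)[1]
                matches = [z for z in self.template.zones if z.name == zname]
                if not matches:
                    raise KeyError(f"template has no zone named {zname!r}")
                vals[name] = matches[0].partition_coeff
        return vals

    def start_params(self) -> dict[str, float]:
        """Initial guess: FitSpec entries, falling back to template values."""
        vals = self._template_values()
        vals.update(self.spec.initial_guess)
        return {k: vals[k] for k in self.spec.free_parameters}

    def simulate(self, params: dict[str, float] | None = None):
        """Forward-solve at the given (or template) parameter values."""
        names = self.spec.free_parameters
        values = [params[n] for n in names] if params else list(self._template_values().values())
        domain = _apply_params(self.template, names, values)
        return profiles_at_scan_days(domain, self.days, self.solver_config)

    def _residuals(self, values) -> np.ndarray:
        self._nfev += 1
        try:
            field_ = self.simulate(dict(zip(self.spec.free_parameters, values)))
        except Exception as exc:
            raise RuntimeError(
                f"forward solve failed at parameters "
                f"{dict(zip(self.spec.free_parameters, map(float, values)))}: {exc}"
            ) from exc
        parts = []
        for p in self.observed:
            pred = field_.interp_total(p.effective_day * SECONDS_PER_DAY, p.positions)
            parts.append(pred - p.conc)
        return np.concatenate(parts)

    def loss(self, params: dict[str, float]) -> float:
        """Sum of squared residuals over all (day, position) observations."""
        values = [params[n] for n in self.spec.free_parameters]
        for name, val in zip(self.spec.free_parameters, values):
            lo, hi = self.spec._bounds_for(name)
            if not lo <= val <= hi:
                raise ValueError(f"parameter {name!r} = {val} outside bounds [{lo}, {hi}]")
        r = self._residuals(values)
        return float(np.dot(r, r))

    # -- fitting ------------------------------------------------------------

    def fit(
        self,
        start_params: dict[str, float] | None = None,
        max_nfev: int = 400,
        xtol: float = 1e-10,
        ftol: float = 1e-12,
    ) -> "StainTransportResults":
        """Bounded least squares in log10-parameter space.

        Deterministic given the data, template, and starting point.  If the
        iteration budget is exhausted the best-so-far parameters are returned
        with ``converged`` False.
        """
        names = self.spec.free_parameters
        start = self.start_params()
        if start_params:
            start.update(start_params)
        x0 = np.log10([start[n] for n in names])
        lo = np.log10([self.spec._bounds_for(n)[0] for n in names])
        hi = np.log10([self.spec._bounds_for(n)[1] for n in names])
        self._nfev = 0

        def resid_log(x):
            return self._residuals(10.0**x)

        sol = least_squares(
            resid_log,
            x0,
            bounds=(lo, hi),
            method="trf",
            x_scale="jac",
            diff_step=1e-4,
            max_nfev=max_nfev,
            xtol=xtol,
            ftol=ftol,
        )
        params = dict(zip(names, 10.0**sol.x))
        return StainTransportResults(
            model=self,
            params=params,
            loss=float(2.0 * sol.cost),
            converged=bool(sol.status > 0),
            message=str(sol.message),
            n_forward_solves=self._nfev,
            start=dict(zip(names, 10.0**x0)),
        )


@dataclass(frozen=True)
class StainTransportResults:
    """Fitted staining-model parameters with diagnostics."""

    model: StainTransportModel
    params: dict[str, float]
    loss: float
    converged: bool
    message: str
    n_forward_solves: int
    start: dict[str, float]

    def predicted(self):
        """Forward field at the fitted parameters."""
        return self.model.simulate(self.params)

    def comparison(self):
        """Per-day/pooled RMSE of the fitted model against the observations."""
        from .profiles import compare

        return compare(self.predicted(), self.model.observed)

    def plot(self, ax=None):
        """Fitted model curves overlaid on the observed profiles."""
        from .plotting import plot_concentration_profiles

        return plot_concentration_profiles(self.predicted(), self.model.observed, ax=ax)

    def summary(self) -> str:
        lines = [
            "Diffusion-sorption staining model fit",
            "=" * 53,
            f"{'parameter':<16}{'start':>12}{'fitted':>14}  units",
            "-" * 53,
        ]
        for name in self.model.spec.free_parameters:
            unit = "m*mmol/(L*s)" if name == "nbc" else "L/kg"
            lines.append(
                f"{name:<16}{self.start[name]:>12.4g}{self.params[name]:>14.6g}  {unit}"
            )
        lines += [
            "-" * 53,
            f"sum of squared residuals: {self.loss:.6g} (mmol/L)^2",
            f"forward solves: {self.n_forward_solves}   converged: {self.converged}",
            self.message,
        ]
        return "\n".join(lines)


def fit(observed, template: ZonedDomain, spec: FitSpec, **kwargs) -> StainTransportResults:
    """Functional entry point: build a :class:`StainTransportModel` and fit it."""
    solver_config = kwargs.pop("solver_config", None)
    model = StainTransportModel(observed, template, spec=spec, solver_config=solver_config)
    return model.fit(**kwargs)


def profile_loss(params: dict[str, float], observed, template: ZonedDomain, **kwargs) -> float:
    """Sum-of-squares objective at ``params`` (keys as in :class:`FitSpec`)."""
    spec = FitSpec(tuple(params.keys()))
    model = StainTransportModel(
        observed, template, spec=spec, solver_config=kwargs.pop("solver_config", None)
    )
    return model.loss(params)
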