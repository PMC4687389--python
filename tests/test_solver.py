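"""Transport solver: conservation, oracles, convergence, monotonicity."""

import numpy as np
import pytest
from scipy.special import erfc

from dicequant.domain import (
    SECONDS_PER_DAY,
    SolverConfig,
    TissueZone,
    ZonedDomain,
)
from dicequant.solver import (
    build_grid,
    penetration_depth,
    profiles_at_scan_days,
    simulate,
)


def constant_flux_closed_form(x, t, influx, theta, diffusivity_eff, capacity):
    """Semi-infinite constant-surface-flux solution of the heat equation.

    For beta*c_t = (theta*D)*c_xx with -theta*D*c_x(0) = influx on x >= 0:
    c(x,t) = (influx/(theta*D)) * sqrt(4 a t) * ierfc(x / sqrt(4 a t)),
    a = theta*D/beta, ierfc(z) = exp(-z^2)/sqrt(pi) - z*erfc(z).
    Written directly from the classical formula, independent of the stepper.
    """
    theta_d = capacity * diffusivity_eff  # theta*D = beta * a
    s = np.sqrt(4.0 * diffusivity_eff * t)
    z = np.asarray(x) / s
    ierfc = np.exp(-(z**2)) / np.sqrt(np.pi) - z * erfc(z)
    return influx / theta_d * s * ierfc


def single_zone_domain(length=0.2, kd=200.0, flux=1.4e-6):
    zone = TissueZone("muscle", 0.0, length, 0.8, 0.265, kd)
    return ZonedDomain((zone,), length, 1e-9, flux)


def test_no_source_stays_zero(ref_domain):
    domain = ref_domain.with_parameters(boundary_flux=0.0)
    field = profiles_at_scan_days(domain, [0, 5], SolverConfig(n_cells=60, time_step=3600.0))
    assert np.all(field.pore_conc == 0.0)
    assert np.all(field.total_conc == 0.0)


def test_mass_balance_matches_influx(day_field, ref_domain):
    """The spatial integral of total concentration grows as flux * time."""
    for day in (5, 15, 30):
        t = day * SECONDS_PER_DAY
        expected = ref_domain.boundary_flux * t
        assert day_field.total_mass(t) == pytest.approx(expected, rel=1e-3)


def test_total_is_capacity_times_pore(day_field, ref_domain):
    beta = ref_domain.capacity_profile(day_field.positions)
    assert np.allclose(day_field.total_conc, beta * day_field.pore_conc, rtol=1e-12)


def test_matches_constant_flux_closed_form():
    """Homogeneous, effectively semi-infinite column against the ierfc solution."""
    domain = single_zone_domain()
    zone = domain.zones[0]
    t = 30 * SECONDS_PER_DAY
    cfg = SolverConfig(n_cells=800, time_step=600.0, output_times=(t,))
    field = simulate(domain, cfg)
    a_eff = zone.porosity * domain.diffusion_coeff / (
        zone.porosity + zone.bulk_density * zone.partition_coeff
    )
    exact = constant_flux_closed_form(
        field.positions, t, domain.boundary_flux, zone.porosity, a_eff,
        zone.porosity + zone.bulk_density * zone.partition_coeff,
    )
    numeric = field.pore_at(t)
    # boundary value within 0.5 %
    assert numeric[0] == pytest.approx(exact[0], rel=5e-3)
    # whole active profile within 0.5 % of the boundary magnitude
    assert np.max(np.abs(numeric - exact)) < 5e-3 * exact[0]


def test_self_convergence_under_refinement(ref_domain):
    """Halving cell size and time step moves the day-30 profile < 0.5 %."""
    t = 30 * SECONDS_PER_DAY
    coarse = simulate(ref_domain, SolverConfig(n_cells=300, time_step=480.0, output_times=(t,)))
    fine = simulate(ref_domain, SolverConfig(n_cells=600, time_step=240.0, output_times=(t,)))
    on_coarse = np.interp(coarse.positions, fine.positions, fine.total_at(t))
    scale = np.max(fine.total_at(t))
    assert np.max(np.abs(coarse.total_at(t) - on_coarse)) < 5e-3 * scale


def test_agrees_with_explicit_euler_oracle(ref_domain):
    """Brute-force explicit integration on the same coarse grid, small horizon."""
    t_end = 1.0 * SECONDS_PER_DAY
    cfg = SolverConfig(n_cells=36, time_step=10.0, output_times=(t_end,))
    field = simulate(ref_domain, cfg)

    centers, widths, zone_idx = build_grid(ref_domain, cfg.n_cells)
    theta_d = np.array([z.porosity * ref_domain.diffusion_coeff for z in ref_domain.zones])
    beta = np.array(
        [z.porosity + z.bulk_density * z.partition_coeff for z in ref_domain.zones]
    )[zone_idx]
    half = 0.5 * widths / theta_d[zone_idx]
    g = 1.0 / (half[:-1] + half[1:])
    dt_exp = 2.0  # well under the explicit stability limit for this grid
    c = np.zeros(len(centers))
    n_steps = int(round(t_end / dt_exp))
    for _ in range(n_steps):
        flux = g * (c[1:] - c[:-1])
        dc = np.zeros_like(c)
        dc[:-1] += flux
        dc[1:] -= flux
        dc[0] += ref_domain.boundary_flux
        c = c + dt_exp * dc / (beta * widths)
    scale = max(c.max(), 1e-300)
    assert np.max(np.abs(field.pore_at(t_end) - c)) < 1e-2 * scale


def test_zone_structure_vanishes_when_parameters_equal(ref_domain):
    """Equal K_d and rho_b in all zones must reproduce the single-zone run."""
    t = 5 * SECONDS_PER_DAY
    uniform = ref_domain.with_parameters({"skin": 150.0, "connective": 150.0, "muscle": 150.0})
    zones = tuple(
        TissueZone(z.name, z.x_start, z.x_end, z.porosity, 0.2, z.partition_coeff)
        for z in uniform.zones
    )
    three = ZonedDomain(zones, uniform.length, uniform.diffusion_coeff, uniform.boundary_flux)
    one = ZonedDomain(
        (TissueZone("only", 0.0, three.length, 0.8, 0.2, 150.0),),
        three.length, three.diffusion_coeff, three.boundary_flux,
    )
    cfg3 = SolverConfig(n_cells=300, time_step=600.0, output_times=(t,))
    f3 = simulate(three, cfg3)
    f1 = simulate(one, cfg3)
    interp = np.interp(f3.positions, f1.positions, f1.pore_at(t))
    assert np.max(np.abs(f3.pore_at(t) - interp)) < 5e-3 * f1.pore_at(t).max()


def test_pore_profile_monotone_in_space(day_field):
    for i in range(len(day_field.times)):
        row = day_field.pore_conc[i]
        assert np.all(np.diff(row) <= 1e-12 * max(row.max(), 1.0))


def test_concentration_grows_with_staining_day(day_field):
    """Constant influx: concentration at every depth is non-decreasing in time."""
    for earlier, later in zip(day_field.total_conc, day_field.total_conc[1:]):
        assert np.all(later >= earlier - 1e-12)
    d15 = day_field.total_at(15 * SECONDS_PER_DAY)
    d30 = day_field.total_at(30 * SECONDS_PER_DAY)
    assert d30[0] > d15[0]


class TestPenetrationDepth:
    def test_zero_field_gives_zero(self, ref_domain):
        field = profiles_at_scan_days(
            ref_domain.with_parameters(boundary_flux=0.0),
            [0],
            SolverConfig(n_cells=60, time_step=3600.0),
        )
        assert penetration_depth(field, 0.0, 0.5) == 0.0

    def test_monotone_in_fraction(self, day_field):
        t = 5 * SECONDS_PER_DAY
        depths = [penetration_depth(day_field, t, f) for f in (0.01, 0.1, 0.5, 0.9)]
        assert depths == sorted(depths, reverse=True)

    def test_rejects_bad_inputs(self, day_field):
        with pytest.raises(ValueError):
            penetration_depth(day_field, 5 * SECONDS_PER_DAY, 1.5)
        with pytest.raises(KeyError):
            day_field.total_at(123.456)


def test_negative_days_rejected(ref_domain):
    with pytest.raises(Exception):
        profiles_at_scan_days(ref_domain, [-1.0])


def test_grid_resolves_every_zone(ref_domain):
    _, _, zone_idx = build_grid(ref_domain, 600)
    counts = np.bincount(zone_idx)
    assert np.all(counts >= 3)
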