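"""Inverse calibration: objective behaviour, identifiability, recovery."""

import numpy as np
import pytest

from dicequant.domain import SECONDS_PER_DAY, SolverConfig
from dicequant.inverse import FitSpec, StainTransportModel, fit, profile_loss
from dicequant.profiles import LineProfile
from dicequant.solver import profiles_at_scan_days

TRUTH = {"kd:skin": 200.0, "kd:connective": 100.0, "kd:muscle": 200.0, "nbc": 1.4e-6}


@pytest.fixture(scope="module")
def quick_config():
    """Very coarse discretisation for objective-shape tests."""
    return SolverConfig(n_cells=120, time_step=1800.0)


@pytest.fixture(scope="module")
def quick_observations(ref_domain, quick_config):
    field = profiles_at_scan_days(ref_domain, [5, 15], quick_config)
    pos = np.linspace(0.0, 0.015, 76)
    out = []
    for day, sid in [(5.0, "A"), (15.0, "C")]:
        conc = field.interp_total(day * SECONDS_PER_DAY, pos)
        out.append(LineProfile(sid, day, day, pos, np.zeros_like(pos), conc=conc))
    return out


class TestProfileLoss:
    def test_zero_at_generating_truth(self, quick_observations, ref_domain, quick_config):
        loss = profile_loss(TRUTH, quick_observations, ref_domain, solver_config=quick_config)
        assert loss == pytest.approx(0.0, abs=1e-12)

    def test_doubling_flux_increases_loss(self, quick_observations, ref_domain, quick_config):
        doubled = dict(TRUTH, nbc=2.8e-6)
        assert profile_loss(
            doubled, quick_observations, ref_domain, solver_config=quick_config
        ) > profile_loss(TRUTH, quick_observations, ref_domain, solver_config=quick_config)

    def test_invariant_to_observation_order(self, quick_observations, ref_domain, quick_config):
        params = dict(TRUTH, **{"kd:muscle": 150.0})
        a = profile_loss(params, quick_observations, ref_domain, solver_config=quick_config)
        b = profile_loss(
            params, list(reversed(quick_observations)), ref_domain, solver_config=quick_config
        )
        assert a == pytest.approx(b, rel=1e-12)

    def test_out_of_bounds_rejected(self, quick_observations, ref_domain, quick_config):
        with pytest.raises(ValueError):
            profile_loss(
                dict(TRUTH, nbc=1.0), quick_observations, ref_domain, solver_config=quick_config
            )


class TestIdentifiability:
    def test_one_dimensional_sweeps_dip_at_truth(
        self, quick_observations, ref_domain, quick_config
    ):
        """Fixing three parameters at truth, the fourth's loss is minimal at truth."""
        sweeps = {
            "kd:skin": (100.0, 200.0, 400.0),
            "kd:connective": (50.0, 100.0, 200.0),
            "kd:muscle": (100.0, 200.0, 400.0),
            "nbc": (0.7e-6, 1.4e-6, 2.8e-6),
        }
        for name, (lo, mid, hi) in sweeps.items():
            losses = [
                profile_loss(
                    dict(TRUTH, **{name: v}),
                    quick_observations,
                    ref_domain,
                    solver_config=quick_config,
                )
                for v in (lo, mid, hi)
            ]
            assert losses[1] < losses[0] and losses[1] < losses[2]


class TestFit:
    def test_recovers_generating_parameters(
        self, noiseless_observations, ref_domain, coarse_config
    ):
        """Noiseless day-5/15/30 profiles: all four parameters within 5 %."""
        spec = FitSpec(
            ("kd:skin", "kd:connective", "kd:muscle", "nbc"),
            initial_guess={"kd:skin": 50, "kd:connective": 50, "kd:muscle": 50, "nbc": 5e-7},
        )
        res = fit(noiseless_observations, ref_domain, spec, solver_config=coarse_config)
        assert res.converged
        for name, truth in TRUTH.items():
            assert res.params[name] == pytest.approx(truth, rel=0.05)
        start_loss = profile_loss(
            res.start, noiseless_observations, ref_domain, solver_config=coarse_config
        )
        assert res.loss <= start_loss

    def test_recovery_under_multiplicative_noise(self, ref_domain, coarse_config):
        """5 % multiplicative noise at fixed seed: parameters within 15 %."""
        field = profiles_at_scan_days(ref_domain, [5, 15, 30], coarse_config)
        rng = np.random.default_rng(7)
        pos = np.linspace(0.0, 0.015, 151)
        obs = []
        for day, sid in [(5.0, "A"), (15.0, "C"), (30.0, "D")]:
            conc = field.interp_total(day * SECONDS_PER_DAY, pos)
            noisy = np.clip(conc * (1.0 + rng.normal(0.0, 0.05, conc.shape)), 0.0, None)
            obs.append(LineProfile(sid, day, day, pos, np.zeros_like(pos), conc=noisy))
        spec = FitSpec(
            ("kd:skin", "kd:connective", "kd:muscle", "nbc"),
            initial_guess={"kd:skin": 50, "kd:connective": 50, "kd:muscle": 50, "nbc": 5e-7},
        )
        res = fit(obs, ref_domain, spec, solver_config=coarse_config)
        for name, truth in TRUTH.items():
            assert res.params[name] == pytest.approx(truth, rel=0.15)

    def test_zero_flux_data_fits_zero_flux(self, ref_domain, quick_config):
        """Observations generated without influx drive the fitted flux to its floor."""
        zero = ref_domain.with_parameters(boundary_flux=0.0)
        field = profiles_at_scan_days(zero, [5, 15], quick_config)
        pos = np.linspace(0.0, 0.015, 51)
        obs = [
            LineProfile(
                sid, d, d, pos, np.zeros_like(pos),
                conc=field.interp_total(d * SECONDS_PER_DAY, pos) + 1e-9,
            )
            for d, sid in [(5.0, "A"), (15.0, "C")]
        ]
        spec = FitSpec(("nbc",), initial_guess={"nbc": 5e-7})
        res = fit(obs, ref_domain, spec, solver_config=quick_config)
        assert res.params["nbc"] <= 2e-8  # pinned at the lower bound

    def test_initial_guess_insensitivity(self, quick_observations, ref_domain, quick_config):
        """Two in-bounds starts on noiseless data reach the same optimum within 1 %."""
        spec = FitSpec(("kd:muscle", "nbc"))
        model = StainTransportModel(
            quick_observations, ref_domain, spec=spec, solver_config=quick_config
        )
        r1 = model.fit({"kd:muscle": 60.0, "nbc": 4e-7})
        r2 = model.fit({"kd:muscle": 500.0, "nbc": 5e-6})
        for name in spec.free_parameters:
            assert r1.params[name] == pytest.approx(r2.params[name], rel=0.01)

    def test_degenerate_inputs_rejected(self, quick_observations, ref_domain):
        zeros = [
            LineProfile(p.scan_id, p.actual_day, p.effective_day, p.positions,
                        p.grayscale, conc=np.zeros_like(p.conc))
            for p in quick_observations
        ]
        with pytest.raises(ValueError):
            StainTransportModel(zeros, ref_domain)
        with pytest.raises(ValueError):
            StainTransportModel(quick_observations[:1], ref_domain)

    def test_summary_reports_parameters(self, quick_observations, ref_domain, quick_config):
        spec = FitSpec(("nbc",))
        res = fit(quick_observations, ref_domain, spec, solver_config=quick_config)
        text = res.summary()
        assert "nbc" in text and "sum of squared residuals" in text

    def test_from_dataframe_roundtrip(self, quick_observations, ref_domain, quick_config):
        import pandas as pd

        frames = []
        for p in quick_observations:
            frames.append(
                pd.DataFrame(
                    {
                        "scan_id": p.scan_id,
                        "actual_day": p.actual_day,
                        "effective_day": p.effective_day,
                        "position_m": p.positions,
                        "conc_mmol_per_L": p.conc,
                    }
                )
            )
        model = StainTransportModel.from_dataframe(
            pd.concat(frames), ref_domain, solver_config=quick_config
        )
        assert model.loss(TRUTH) == pytest.approx(0.0, abs=1e-12)
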