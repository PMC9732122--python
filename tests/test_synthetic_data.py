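import numpy as np
import pytest

from diazodiel.budgets import normalize_od
from diazodiel.errors import ConfigError, InfeasibleTargetError
from diazodiel.frr_etr import EtrContext, etr_from_yields
from diazodiel.light import DielLightProfile
from diazodiel.n2_fixation import AraVial, ethylene_production_rate, n2_rate
from diazodiel.synthetic_data import (
    SyntheticTruth,
    crocosphaera_like,
    cyanothece_like,
    generate_diel_dataset,
    yields_for_etr,
)


class TestYieldsForEtr:
    def test_zero_target_gives_zero_photochemistry(self):
        y = yields_for_etr(0.0, 300.0, 0.5, 100.0)
        assert y.Fp == y.Fmp

    def test_fvfm_fixes_fm(self):
        y = yields_for_etr(0.1, 300.0, 0.5, 100.0)
        assert y.F0 == 1.0
        assert y.Fm == pytest.approx(2.0)

    def test_round_trip_through_etr_equation(self):
        """Inversion followed by the forward ETR formula reproduces the
        target for 100 random (target, E, fvfm, chl) draws."""
        rng = np.random.default_rng(42)
        for _ in range(100):
            e = rng.uniform(10.0, 1500.0)
            fvfm = rng.uniform(0.2, 0.7)
            chl = rng.uniform(20.0, 300.0)
            target = rng.uniform(0.0, 3.0)
            y = yields_for_etr(target, e, fvfm, chl)
            got = etr_from_yields(y, EtrContext(chl=chl))
            assert got == pytest.approx(target, rel=1e-10, abs=1e-12)

    def test_infeasible_target_rejected(self):
        with pytest.raises(InfeasibleTargetError):
            yields_for_etr(1e6, 1.0, 0.5, 100.0)


@pytest.fixture(scope="module")
def croco_dataset():
    truth = crocosphaera_like(noise_cv=0.0, seed=3)
    return truth, generate_diel_dataset(truth, DielLightProfile(e_max=400.0))


class TestGenerateDielDataset:
    def test_same_seed_byte_identical(self, tmp_path):
        paths = []
        for run in ("a", "b"):
            truth = cyanothece_like(noise_cv=0.08, seed=11)
            ds = generate_diel_dataset(truth, DielLightProfile(e_max=130.0))
            paths.append(ds.write(tmp_path / run))
        for f in sorted(p.name for p in paths[0].iterdir()):
            assert (paths[0] / f).read_bytes() == (paths[1] / f).read_bytes(), f

    def test_different_seeds_differ(self, tmp_path):
        frames = []
        for seed in (1, 2):
            truth = cyanothece_like(noise_cv=0.08, seed=seed)
            frames.append(
                generate_diel_dataset(truth, DielLightProfile(e_max=130.0)).od
            )
        assert not np.allclose(frames[0]["od735"], frames[1]["od735"])

    def test_ethylene_mass_non_decreasing(self, croco_dataset):
        _, ds = croco_dataset
        assert (ds.ethylene_vials["t1_ppm"] >= ds.ethylene_vials["t0_ppm"]).all()

    def test_ethylene_slope_is_four_times_scheduled_n2(self, croco_dataset):
        """Noise-free vials return exactly the scheduled N2 rate."""
        truth, ds = croco_dataset
        for row in ds.ethylene_vials.itertuples():
            vial = AraVial(
                c2h4_t0=row.t0_ppm, c2h4_t1=row.t1_ppm,
                headspace_vol=row.headspace_ml, sample_vol=row.sample_ml,
                t_inc=row.dt_h, chl=truth.chl / 1000.0,
            )
            recovered = n2_rate(ethylene_production_rate(vial))
            scheduled = truth.n2fix_schedule[float(row.vial)]
            assert recovered == pytest.approx(scheduled, abs=1e-9)

    def test_od_amplitude_matches_preset(self, croco_dataset):
        """Open-ocean preset: normalized OD735 peaks ~2.3-fold over its 1L
        value, well above the coastal preset's damped amplitude."""
        _, ds = croco_dataset
        norm = normalize_od(ds.od["t_h"], ds.od["od735"])
        assert float(norm.max()) == pytest.approx(2.3, abs=0.01)
        assert norm[0] < 1.05  # starts near the anchor value

    def test_od_rises_in_light_falls_in_dark(self, croco_dataset):
        _, ds = croco_dataset
        od = ds.od
        mid_light = od.loc[(od.t_h > 2) & (od.t_h < 10), "od735"]
        assert mid_light.is_monotonic_increasing
        night = od.loc[(od.t_h > 13) & (od.t_h < 23), "od735"]
        assert night.is_monotonic_decreasing

    def test_frrf_ladders_at_sampled_light_hours(self, croco_dataset):
        _, ds = croco_dataset
        assert sorted(ds.frrf_tables) == [1.0, 3.0, 5.0, 7.0, 9.0, 11.0]
        for table in ds.frrf_tables.values():
            assert len(table) == 11
            assert table["E"].iloc[0] == 0.0
            assert table["E"].iloc[-1] == pytest.approx(1500.0)

    def test_negative_noise_cv_rejected(self):
        with pytest.raises(ConfigError):
            crocosphaera_like(noise_cv=-0.1)

    def test_nonzero_fixation_restricted_to_dark(self):
        truth = cyanothece_like(noise_cv=0.0)
        for hour, rate in truth.n2fix_schedule.items():
            if rate > 0:
                assert 12.0 <= hour < 24.0


def test_truth_json_round_trip(croco_dataset):
    truth, _ = croco_dataset
    back = SyntheticTruth.from_json(truth.to_json())
    assert back.species == truth.species
    assert back.pe_params_c.ek == pytest.approx(truth.pe_params_c.ek, rel=1e-15)
    assert back.n2fix_schedule == truth.n2fix_schedule
    assert back.seed == truth.seed
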