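import math

import numpy as np
import pytest

from genreduce.fermentation import (
    MOLAR_MASSES,
    TimeSeries,
    fold_change,
    rate_table,
    read_tidy_csv,
    round_sig,
    specific_growth_rate,
    specific_production_rate,
    total_phenazine_mass_rate,
)
from genreduce.simulate import FermSimConfig, fermentation_tidy_frame, generate_fermentation


def _series(times, biomass, conc=None, strain="s"):
    return TimeSeries(
        strain=strain,
        times=np.asarray(times, float),
        biomass=np.asarray(biomass, float),
        concentrations={k: np.asarray(v, float) for k, v in (conc or {}).items()},
    )


class TestGrowthRate:
    def test_exponential_sampling_recovers_mu(self):
        mu = 0.1226
        s = _series([14.0, 24.0], [0.5 * math.exp(mu * 14), 0.5 * math.exp(mu * 24)])
        assert specific_growth_rate(s, (14, 24)) == pytest.approx(mu, abs=1e-12)

    def test_constant_biomass_gives_zero(self):
        s = _series([14.0, 24.0], [2.0, 2.0])
        assert specific_growth_rate(s, (14, 24)) == 0.0

    def test_scale_invariance(self):
        s1 = _series([14.0, 24.0], [1.0, 3.0])
        s2 = _series([14.0, 24.0], [0.5, 1.5])
        assert specific_growth_rate(s1, (14, 24)) == pytest.approx(
            specific_growth_rate(s2, (14, 24))
        )

    def test_nonpositive_biomass_is_error(self):
        s = _series([14.0, 24.0], [0.0, 2.0])
        with pytest.raises(ValueError, match="positive"):
            specific_growth_rate(s, (14, 24))


class TestProductionRate:
    def _flat(self, c1, c2):
        return _series([14.0, 24.0], [2.0, 2.0], {"PCA": [c1, c2]})

    def test_no_concentration_change_gives_zero(self):
        assert specific_production_rate(self._flat(10.0, 10.0), "PCA", (14, 24)) == 0.0

    def test_linear_in_delta_c(self):
        q1 = specific_production_rate(self._flat(0.0, 50.0), "PCA", (14, 24))
        q2 = specific_production_rate(self._flat(0.0, 100.0), "PCA", (14, 24))
        assert q2 == pytest.approx(2 * q1)

    def test_units_flat_biomass_closed_form(self):
        # dC = 224.22 mg/L over 10 h at X = 2 g/L -> 1 mmol/L / 20 g h/L
        q = specific_production_rate(self._flat(0.0, 224.22), "PCA", (14, 24))
        assert q == pytest.approx(0.05)

    def test_missing_analyte_is_error(self):
        with pytest.raises(ValueError, match="2OHPHZ"):
            specific_production_rate(self._flat(0, 1), "2OHPHZ", (14, 24))

    def test_mass_rate_from_delta_c_in_grams_matches_molar_identity(self):
        """Unit consistency: q_mass from dC in g equals q_molar * M / 1000."""
        s = self._flat(0.0, 123.4)
        q_molar = specific_production_rate(s, "PCA", (14, 24))
        dc_g = 123.4e-3  # g/L
        q_mass = dc_g / (2.0 * 10.0)
        assert q_mass == pytest.approx(q_molar * MOLAR_MASSES.PCA / 1000.0)


class TestTotalMassRate:
    def test_parent_strain_identity(self):
        q = {"PCA": 0.0061, "2OHPCA": 0.0064, "2OHPHZ": 0.0008}
        assert round_sig(total_phenazine_mass_rate(q), 2) == 0.0031

    def test_high_producer_identity(self):
        q = {"PCA": 0.0202, "2OHPCA": 0.0015, "2OHPHZ": 0.0035}
        assert round_sig(total_phenazine_mass_rate(q), 2) == 0.0056

    def test_all_zero(self):
        assert total_phenazine_mass_rate({a: 0.0 for a in ("PCA", "2OHPCA", "2OHPHZ")}) == 0.0

    def test_missing_analyte_is_error(self):
        with pytest.raises(ValueError, match="missing"):
            total_phenazine_mass_rate({"PCA": 0.01})


class TestFoldChange:
    @pytest.mark.parametrize(
        "mutant,parent,expected",
        [(0.0092, 0.0008, 11.5), (0.0202, 0.0061, 3.3), (0.0076, 0.0061, 1.2), (1.0, 1.0, 1.0)],
    )
    def test_reported_ratios(self, mutant, parent, expected):
        assert round(fold_change(mutant, parent), 1) == expected

    def test_zero_denominator_is_error(self):
        with pytest.raises(ValueError):
            fold_change(1.0, 0.0)


class TestParameterRecovery:
    def test_noise_free_recovery_is_exact(self):
        cfg = FermSimConfig()  # planted mu = 0.1226, q_PCA = 0.0061
        s = generate_fermentation(cfg)[0]
        assert specific_growth_rate(s, (14, 24)) == pytest.approx(0.1226, abs=1e-12)
        assert specific_production_rate(s, "PCA", (14, 24)) == pytest.approx(
            0.0061, rel=1e-12
        )

    def test_noisy_recovery_within_five_percent(self):
        cfg = FermSimConfig(noise_cv=0.02, seed=2024)
        reps = generate_fermentation(cfg, n_replicates=3)
        mu = np.mean([specific_growth_rate(r, (14, 24)) for r in reps])
        q = np.mean([specific_production_rate(r, "PCA", (14, 24)) for r in reps])
        assert abs(mu - 0.1226) / 0.1226 < 0.05
        assert abs(q - 0.0061) / 0.0061 < 0.05

    def test_arithmetic_mean_flag_changes_estimate(self):
        s = generate_fermentation(FermSimConfig())[0]
        q_log = specific_production_rate(s, "PCA", (14, 24), biomass_mean="logarithmic")
        q_arith = specific_production_rate(s, "PCA", (14, 24), biomass_mean="arithmetic")
        assert q_log == pytest.approx(0.0061, rel=1e-12)
        assert q_arith < q_log  # arithmetic mean overweights late biomass


class TestTableAndIO:
    def test_rate_table_round_trip_via_tidy_csv(self, tmp_path):
        series = generate_fermentation(FermSimConfig(strain="parent"))
        df = fermentation_tidy_frame(series)
        path = tmp_path / "ferm.csv"
        df.to_csv(path, index=False)
        loaded = read_tidy_csv(path)
        table = rate_table(loaded, (14, 24))
        row = table.set_index("strain").loc["parent"]
        assert row["mu_per_h"] == pytest.approx(0.1226)
        assert row["q_PCA_mmol_g_h"] == pytest.approx(0.0061)
        assert row["q_total_g_g_h"] == pytest.approx(0.0031)

    def test_time_series_validation(self):
        with pytest.raises(ValueError, match="increasing"):
            _series([1.0, 1.0], [1.0, 1.0])
        with pytest.raises(ValueError, match="negative"):
            _series([1.0, 2.0], [1.0, -1.0])
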