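"""Remobilization trait engine: unit bridges, identities, regressions."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from nrespec import (
    OrganTimepoint,
    compute_plot_traits,
    n_accumulation,
    nra_contributions,
    remobilization,
    trait_regression,
    trait_regression_matrix,
    whole_plant,
)
from nrespec.exceptions import DomainError, LabelError, UndefinedMetricError


def _tp(organ, stage, n_mass, dm):
    return OrganTimepoint(organ, stage, n_mass, dm)


class TestAccumulation:
    def test_unit_bridge(self):
        # g/kg x kg/ha = g/ha; /1000 -> kg N/ha
        assert n_accumulation(_tp("TL1", "anthesis", 20.0, 5000.0)) == pytest.approx(100.0)

    def test_continuity_at_zero(self):
        assert n_accumulation(_tp("TL1", "anthesis", 0.001, 100.0)) == pytest.approx(1e-4)

    def test_random_grid_matches_product_oracle(self, rng):
        for n_mass in rng.uniform(1, 50, 10):
            for dm in rng.uniform(100, 9000, 10):
                got = n_accumulation(_tp("TL2", "maturity", n_mass, dm))
                assert got == pytest.approx(n_mass * dm / 1000.0, rel=1e-15)

    def test_non_positive_inputs_rejected(self):
        with pytest.raises(DomainError):
            _tp("TL1", "anthesis", -1.0, 100.0)
        with pytest.raises(DomainError):
            _tp("TL1", "anthesis", 10.0, 0.0)


class TestRemobilization:
    def test_nra_nre_arithmetic(self):
        # NAA 100 -> 25 kg/ha: NRA 75, NRE 75%
        entry = remobilization(
            _tp("TL1", "anthesis", 20.0, 5000.0), _tp("TL1", "maturity", 10.0, 2500.0)
        )
        assert entry.nra == pytest.approx(75.0)
        assert entry.nre == pytest.approx(0.75)
        assert entry.nre_percent == pytest.approx(75.0)

    def test_delta_n_mass_arithmetic(self):
        entry = remobilization(
            _tp("TL1", "anthesis", 40.0, 1000.0), _tp("TL1", "maturity", 10.0, 1000.0)
        )
        assert entry.delta_n_mass == pytest.approx(0.75)
        assert entry.nre == pytest.approx(0.75)  # DM unchanged -> identities coincide

    def test_net_gain_flagged_not_clamped(self):
        entry = remobilization(
            _tp("Chaff", "anthesis", 10.0, 1000.0), _tp("Chaff", "maturity", 15.0, 1000.0)
        )
        assert entry.nre < 0 and entry.net_gain

    def test_organ_mismatch_rejected(self):
        with pytest.raises(LabelError):
            remobilization(
                _tp("TL1", "anthesis", 20.0, 1000.0), _tp("TL2", "maturity", 10.0, 1000.0)
            )


class TestWholePlant:
    def _entry(self, organ, naa_a, nre):
        dm = 1000.0
        return remobilization(
            _tp(organ, "anthesis", naa_a, dm),
            _tp(organ, "maturity", naa_a * (1 - nre), dm),
        )

    def test_two_organ_weighted_mean(self):
        wp = whole_plant([self._entry("TL1", 50.0, 0.6), self._entry("TL2", 50.0, 0.8)])
        assert wp.nre == pytest.approx(0.7)

    def test_single_organ_identity(self):
        e = self._entry("TIN1", 30.0, 0.5)
        wp = whole_plant([e])
        assert wp.nre == pytest.approx(e.nre)
        assert wp.naa_anthesis == e.naa_anthesis

    def test_weighted_mean_identity_nine_organs(self, rng):
        entries = [
            self._entry(o, naa, nre)
            for o, naa, nre in zip(
                ["TL1", "TL2", "TL3", "RLs", "TIN1", "TIN2", "TIN3", "RINs", "Chaff"],
                rng.uniform(5, 40, 9),
                rng.uniform(0.2, 0.9, 9),
            )
        ]
        wp = whole_plant(entries)
        weights = np.array([e.naa_anthesis for e in entries])
        nres = np.array([e.nre for e in entries])
        assert abs(wp.nre - np.sum(weights * nres) / weights.sum()) < 1e-12

    def test_order_invariant_bitwise(self, rng):
        entries = [self._entry(o, naa, 0.5) for o, naa in
                   zip(["TL1", "TIN1", "Chaff"], rng.uniform(5, 40, 3))]
        a = whole_plant(entries)
        b = whole_plant(entries[::-1])
        assert a.naa_anthesis == b.naa_anthesis and a.nre == b.nre

    def test_duplicate_organ_rejected(self):
        e = self._entry("TL1", 10.0, 0.5)
        with pytest.raises(LabelError):
            whole_plant([e, e])

    def test_include_organs_subset(self):
        entries = [self._entry("TL1", 50.0, 0.6), self._entry("Chaff", 50.0, 0.8)]
        wp = whole_plant(entries, include_organs=["TL1"])
        assert wp.nre == pytest.approx(0.6)


class TestContributions:
    def _entry(self, organ, nra):
        return remobilization(
            _tp(organ, "anthesis", 10.0 + nra, 1000.0), _tp(organ, "maturity", 10.0, 1000.0)
        )

    def test_equal_split(self):
        entries = [self._entry(o, 5.0) for o in ("TL1", "TL2", "TL3", "RLs")]
        contrib = nra_contributions(entries)
        assert all(v == pytest.approx(0.25) for v in contrib.values())

    def test_concentrated(self):
        entries = [self._entry("TL1", 8.0)]
        entries.append(
            remobilization(_tp("TIN1", "anthesis", 5.0, 1000.0), _tp("TIN1", "maturity", 5.0, 1000.0))
        )
        contrib = nra_contributions(entries)
        assert contrib["TL1"] == pytest.approx(1.0) and contrib["TIN1"] == pytest.approx(0.0)

    def test_normalization_oracle(self, rng):
        nras = rng.uniform(1, 10, 6)
        organs = ["TL1", "TL2", "TL3", "TIN1", "TIN2", "Chaff"]
        entries = [self._entry(o, v) for o, v in zip(organs, nras)]
        contrib = nra_contributions(entries)
        for o, v in zip(organs, nras):
            assert contrib[o] == pytest.approx(v / nras.sum(), rel=1e-12)
        assert sum(contrib.values()) == pytest.approx(1.0)

    def test_zero_total_rejected(self):
        entries = [
            remobilization(_tp("TL1", "anthesis", 10.0, 1000.0), _tp("TL1", "maturity", 10.0, 1000.0))
        ]
        with pytest.raises(UndefinedMetricError):
            nra_contributions(entries)


class TestTraitRegression:
    def test_exact_linearity(self):
        x = np.array([1.0, 2.0, 3.0, 4.0])
        fit = trait_regression(x, 2 * x)
        assert fit.r2 == pytest.approx(1.0)
        assert fit.slope == pytest.approx(2.0)
        assert fit.intercept == pytest.approx(0.0, abs=1e-12)

    def test_independent_noise_r2_near_zero(self):
        r2s = []
        for s in range(20):
            rng = np.random.default_rng(s)
            fit = trait_regression(rng.normal(size=200), rng.normal(size=200))
            r2s.append(fit.r2)
        assert np.median(r2s) < 0.05

    def test_closed_form_oracle(self, rng):
        x = rng.uniform(0, 1, 6)
        y = 1.5 * x + rng.normal(0, 0.1, 6)
        fit = trait_regression(x, y)
        # independent closed-form OLS + t-test
        sxx = np.sum((x - x.mean()) ** 2)
        slope = np.sum((x - x.mean()) * (y - y.mean())) / sxx
        intercept = y.mean() - slope * x.mean()
        resid = y - intercept - slope * x
        se = np.sqrt(np.sum(resid**2) / 4 / sxx)
        t = slope / se
        p = 2 * stats.t.sf(abs(t), 4)
        r2 = 1 - np.sum(resid**2) / np.sum((y - y.mean()) ** 2)
        assert fit.slope == pytest.approx(slope, rel=1e-10)
        assert fit.intercept == pytest.approx(intercept, rel=1e-10)
        assert fit.r2 == pytest.approx(r2, rel=1e-10)
        assert fit.p_value == pytest.approx(p, rel=1e-8)

    def test_constant_regressor_rejected(self):
        with pytest.raises(DomainError):
            trait_regression(np.ones(5), np.arange(5.0))


class TestTidyInterface:
    def _stage_df(self):
        rows = []
        for plot in ("p1", "p2", "p3", "p4"):
            shift = {"p1": 0.0, "p2": 0.05, "p3": -0.05, "p4": 0.1}[plot]
            for organ, nre in (("TL1", 0.7), ("TIN1", 0.5)):
                rows.append(
                    dict(plot_id=plot, organ=organ, stage="anthesis", N_mass=30.0, DM=1000.0)
                )
                rows.append(
                    dict(
                        plot_id=plot,
                        organ=organ,
                        stage="maturity",
                        N_mass=30.0 * (1 - nre - shift),
                        DM=1000.0,
                    )
                )
        return pd.DataFrame(rows)

    def test_plot_traits_and_regression_matrix(self):
        traits = compute_plot_traits(self._stage_df())
        wp = traits[traits["organ"] == "whole_plant"]
        assert len(wp) == 4
        organ_rows = traits[traits["organ"] != "whole_plant"]
        # equal DM at both stages: NRE == delta_N_mass row by row
        np.testing.assert_allclose(organ_rows["NRE"], organ_rows["delta_N_mass"], atol=1e-14)
        matrix = trait_regression_matrix(traits)
        assert set(matrix["organ"]) == {"TL1", "TIN1"}
        # identical shifts drive both organs and the whole plant: R2 = 1
        assert matrix["R2_NREwhole_vs_NREorgan"].min() > 0.999

    def test_missing_stage_rejected(self):
        df = self._stage_df().iloc[1:]
        with pytest.raises(LabelError):
            compute_plot_traits(df)
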