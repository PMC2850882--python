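import numpy as np
import pytest

import p38compete as pc
from p38compete.hillfit import FitNotConverged


def fourpl(d, top, bottom, ic50, hill):
    return bottom + (top - bottom) / (1.0 + (d / ic50) ** hill)


GRID = np.concatenate([[0.0], np.geomspace(0.1, 1e4, 12)])


class TestFitHill:
    def test_noise_free_parameters_recovered_exactly(self):
        y = fourpl(GRID, 1.0, 0.0, 10.0, 1.0)
        fit = pc.fit_hill(GRID, y)
        assert fit.converged and not fit.censored
        assert fit.ic50 == pytest.approx(10.0, rel=1e-6)
        assert fit.top == pytest.approx(1.0, rel=1e-6)
        assert fit.bottom == pytest.approx(0.0, abs=1e-8)
        assert fit.hill_slope == pytest.approx(1.0, rel=1e-6)

    def test_scale_equivariance(self):
        y = fourpl(GRID, 1.0, 0.05, 25.0, 1.3)
        f1 = pc.fit_hill(GRID, y)
        f2 = pc.fit_hill(GRID * 1e3, y)
        assert f2.ic50 == pytest.approx(f1.ic50 * 1e3, rel=1e-9)

    def test_flat_data_returns_sentinel(self):
        fit = pc.fit_hill(GRID, np.ones_like(GRID))
        assert not fit.converged
        assert fit.ic50 is None
        with pytest.raises(FitNotConverged):
            fit.ic50_or_raise()

    def test_too_few_doses_returns_sentinel(self):
        d = np.array([0.0, 1.0, 10.0, 100.0])
        fit = pc.fit_hill(d, fourpl(d, 1, 0, 10, 1))
        assert not fit.converged

    def test_censoring_beyond_max_dose(self):
        d = np.concatenate([[0.0], np.geomspace(0.01, 10.0, 10)])
        y = fourpl(d, 1.0, 0.0, 400.0, 1.0)  # transition beyond the grid
        fit = pc.fit_hill(d, y)
        if fit.converged:
            assert fit.censored
            assert fit.report_ic50().startswith(">")

    def test_geometric_error_is_fold_scale(self):
        rng = np.random.default_rng(0)
        y = fourpl(GRID, 1.0, 0.0, 10.0, 1.0) * np.exp(
            rng.normal(0, np.log(1.2), GRID.size))
        fit = pc.fit_hill(GRID, y)
        assert fit.converged
        assert fit.gsd_fold is not None and fit.gsd_fold > 1.0

    def test_monte_carlo_recovery_within_1p5_fold(self):
        """n = 4 replicates at geometric SD 1.2 recover the true IC50 within
        1.5-fold in >= 95% of seeded trials."""
        truth = fourpl(GRID, 1.0, 0.0, 10.0, 1.0)
        hits = 0
        trials = 100
        for seed in range(trials):
            noisy = pc.attach_noise(
                truth, pc.NoiseModel(geometric_sd=1.2, n_replicates=4, seed=seed))
            m = noisy.mean(axis=0)
            fit = pc.fit_hill(GRID, m, weights=1.0 / np.maximum(m, 1e-3))
            if fit.converged and abs(np.log(fit.ic50 / 10.0)) <= np.log(1.5):
                hits += 1
        assert hits >= 0.95 * trials


class TestDerivedMetrics:
    @pytest.mark.parametrize(
        "atf2_uM, mk2_uM, expected",
        [(0.92, 7.75, 0.12),   # reported single-assay pair
         (0.12, 3.6, 0.03),    # reported dual-assay pair
         (1.0, 1.0, 1.0)],
    )
    def test_selectivity_ratio_reporting(self, atf2_uM, mk2_uM, expected):
        value, lower = pc.selectivity_ratio(atf2_uM, mk2_uM)
        assert not lower
        assert pc.round_selectivity(value) == expected

    def test_censored_atf2_gives_lower_bound(self):
        value, lower = pc.selectivity_ratio(400.0, 23.4, atf2_censored=True)
        assert lower
        assert pc.round_selectivity(value) == 17.0

    def test_reciprocal_identity(self):
        a, b = 0.35, 0.11
        assert pc.selectivity_ratio(a, b)[0] * pc.selectivity_ratio(b, a)[0] \
            == pytest.approx(1.0, rel=1e-12)

    def test_selectivity_rejects_nonpositive(self):
        with pytest.raises(ValueError):
            pc.selectivity_ratio(0.0, 1.0)

    @pytest.mark.parametrize(
        "single, dual, expected",
        [(0.35, 0.02, 17.5),   # reported ATF2 single->dual shift
         (1.0, 1.0, 1.0),
         (0.02, 0.35, 0.0571)],
    )
    def test_shift_factor(self, single, dual, expected):
        assert pc.shift_factor(single, dual) == pytest.approx(expected, rel=1e-3)

    @pytest.mark.parametrize(
        "n, v_pl, uM",
        [(6.02214076e5, 1.0, 1.0),
         (6.02214076e5, 0.38, 2.6316),   # PBMC cell volume
         (0.0, 1.09, 0.0)],
    )
    def test_molecules_to_uM(self, n, v_pl, uM):
        assert pc.molecules_to_uM(n, v_pl) == pytest.approx(uM, rel=1e-4)

    def test_molecules_to_uM_rejects_bad_volume(self):
        with pytest.raises(ValueError):
            pc.molecules_to_uM(1e5, 0.0)

    def test_selectivity_report(self):
        rep = pc.SelectivityReport(
            ic50_atf2=0.12, ic50_mk2=3.6,
            ic50_atf2_single=0.92, ic50_mk2_single=7.75)
        assert pc.round_selectivity(rep.selectivity) == 0.03
        assert rep.shift_atf2 == pytest.approx(0.92 / 0.12)
        assert rep.formatted_selectivity() == "0.03"
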