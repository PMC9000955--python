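"""Grid scan, fit error, best fit with bounds, susceptibilities."""

import numpy as np
import pandas as pd
import pytest

from crmacro import EnsembleParams, simulate_replicates
from crmacro.fitting import (
    CORE_STATS,
    FitResult,
    ScanTable,
    best_fit,
    fit_error,
    global_susceptibility,
    local_susceptibility,
    scan_grid,
)
from crmacro.stats import core_statistics


def toy_scan(rows):
    frame = pd.DataFrame(rows)
    for name in CORE_STATS:
        if f"{name}_sd" not in frame:
            frame[f"{name}_sd"] = 0.0
    if "valid" not in frame:
        frame["valid"] = True
    return ScanTable(frame)


def synthetic_scan(f, axes):
    """Scan table whose statistic means are deterministic functions."""
    import itertools

    rows = []
    for M, S, sigma, k in itertools.product(*axes.values()):
        stats = f(M, S, sigma, k)
        rows.append(
            dict(M=M, S=S, sigma=sigma, k=k, valid=True,
                 **{f"{n}_mean": stats[n] for n in CORE_STATS},
                 **{f"{n}_sd": 0.0 for n in CORE_STATS})
        )
    return ScanTable(pd.DataFrame(rows))


AXES = {"M": [10.0, 20.0, 30.0], "S": [0.1, 0.5, 0.9],
        "sigma": [0.1, 0.3, 0.5], "k": [0.2, 0.6, 1.0]}


def linear_stats(M, S, sigma, k):
    return {"alpha_bar": M, "beta": 2 - S, "sigma_dl": 2 * sigma, "s_bar": -k}


class TestScanGrid:
    def test_single_point_matches_direct_replicates(self):
        p = EnsembleParams(N=10, M=8, S=0.1, sigma=0.2, k=0.8, T=30, seed=3)
        scan = scan_grid(p, {"M": [8]}, n_instances=2)
        assert len(scan.frame) == 1
        row = scan.frame.iloc[0]
        seed = int(np.random.SeedSequence([3, 0]).generate_state(1)[0] % 2**31)
        reps = simulate_replicates(p.replace(seed=seed), n_instances=2)
        stats = [core_statistics(s) for s in reps]
        for name in CORE_STATS:
            assert np.isclose(
                row[f"{name}_mean"], np.mean([d[name] for d in stats])
            )

    def test_checkpoint_resume_reuses_rows(self, tmp_path):
        p = EnsembleParams(N=10, M=8, S=0.1, sigma=0.2, k=0.8, T=25, seed=3)
        ck = tmp_path / "scan.tsv"
        first = scan_grid(p, {"k": [0.5, 1.0]}, n_instances=1, checkpoint=ck)
        again = scan_grid(p, {"k": [0.5, 1.0]}, n_instances=1, checkpoint=ck)
        pd.testing.assert_frame_equal(first.frame, again.frame)

    def test_unknown_axis_rejected(self):
        p = EnsembleParams(N=5, M=4, S=0.1, sigma=0.2, k=0.8, T=5)
        with pytest.raises(ValueError, match="axis"):
            scan_grid(p, {"Q": [1]})


class TestFitError:
    def test_zero_for_identical_stats(self):
        scan = synthetic_scan(linear_stats, AXES)
        stats = linear_stats(20.0, 0.5, 0.3, 0.6)
        assert fit_error(stats, stats, scan) == 0.0

    def test_symmetric_and_additive(self):
        scan = synthetic_scan(linear_stats, AXES)
        a = linear_stats(10.0, 0.1, 0.1, 0.2)
        b = linear_stats(30.0, 0.9, 0.5, 1.0)
        assert np.isclose(fit_error(a, b, scan), fit_error(b, a, scan))

    def test_hand_computed_two_row_toy(self):
        rows = [
            dict(M=10.0, S=0.1, sigma=0.1, k=0.5, alpha_bar_mean=10.0,
                 beta_mean=1.0, sigma_dl_mean=0.2, s_bar_mean=-0.5),
            dict(M=20.0, S=0.1, sigma=0.1, k=0.5, alpha_bar_mean=14.0,
                 beta_mean=2.0, sigma_dl_mean=0.6, s_bar_mean=-0.9),
        ]
        scan = toy_scan(rows)
        model = dict(alpha_bar=10.0, beta=1.0, sigma_dl=0.2, s_bar=-0.5)
        data = dict(alpha_bar=14.0, beta=2.0, sigma_dl=0.6, s_bar=-0.9)
        # each statistic differs by exactly its two-row SD (ddof=1)
        sds = [np.std([10, 14], ddof=1), np.std([1, 2], ddof=1),
               np.std([0.2, 0.6], ddof=1), np.std([-0.5, -0.9], ddof=1)]
        expected = sum(abs(d) / s for d, s in zip([4.0, 1.0, 0.4, 0.4], sds))
        assert np.isclose(fit_error(model, data, scan), expected)

    def test_degenerate_scan_sd_rejected(self):
        rows = [
            dict(M=10.0, S=0.1, sigma=0.1, k=0.5, alpha_bar_mean=10.0,
                 beta_mean=1.0, sigma_dl_mean=0.2, s_bar_mean=-0.5),
            dict(M=20.0, S=0.1, sigma=0.1, k=0.5, alpha_bar_mean=10.0,
                 beta_mean=2.0, sigma_dl_mean=0.6, s_bar_mean=-0.9),
        ]
        scan = toy_scan(rows)
        with pytest.raises(ValueError, match="degenerate"):
            fit_error(linear_stats(1, 1, 1, 1), linear_stats(1, 1, 1, 1), scan)


class TestBestFit:
    def test_recovers_generating_grid_point_on_synthetic_table(self):
        scan = synthetic_scan(linear_stats, AXES)
        truth = linear_stats(20.0, 0.9, 0.1, 1.0)
        result = best_fit(scan, truth)
        assert result.best == {"M": 20.0, "S": 0.9, "sigma": 0.1, "k": 1.0}
        assert result.error == 0.0

    def test_unique_zero_error_row_has_nonzero_bounds(self):
        scan = synthetic_scan(linear_stats, AXES)
        result = best_fit(scan, linear_stats(20.0, 0.5, 0.3, 0.6))
        for w, (lo, hi) in result.bounds.items():
            assert lo <= result.best[w] <= hi
            assert hi > lo

    def test_bounds_contain_best_and_stay_on_axis(self):
        scan = synthetic_scan(linear_stats, AXES)
        result = best_fit(scan, linear_stats(10.0, 0.1, 0.5, 0.2))
        assert result.bounds["M"][0] >= 10.0
        assert result.bounds["S"][0] >= 0.1


class TestSusceptibility:
    def test_insensitive_statistic_has_zero_susceptibility(self):
        scan = synthetic_scan(linear_stats, AXES)
        assert global_susceptibility(scan, "beta", "k").C == 0.0

    def test_exact_linear_response_closed_form(self):
        # s_bar = -k on a uniform 3-level axis, constant in other axes:
        # C = (k_min - k_max) / SD(-k over all rows)
        scan = synthetic_scan(linear_stats, AXES)
        c = global_susceptibility(scan, "s_bar", "k").C
        vals = scan.valid["s_bar_mean"].to_numpy()
        expected = (-1.0 - (-0.2)) / np.std(vals, ddof=1)
        assert np.isclose(c, expected)

    def test_n_over_m_axis_is_reversed(self):
        scan = synthetic_scan(linear_stats, AXES)
        # alpha_bar = M increases with M, so susceptibility to N/M < 0
        assert global_susceptibility(scan, "alpha_bar", "N_over_M").C < 0
        assert global_susceptibility(scan, "alpha_bar", "M").C > 0

    def test_local_equals_global_when_other_axes_have_one_level(self):
        axes = {"M": [10.0], "S": [0.5], "sigma": [0.3], "k": [0.2, 0.6, 1.0]}
        scan = synthetic_scan(linear_stats, axes)
        best = FitResult(
            best={"M": 10.0, "S": 0.5, "sigma": 0.3, "k": 0.6}, error=0.0, bounds={}
        )
        g = global_susceptibility(scan, "s_bar", "k").C
        l = local_susceptibility(scan, best, "s_bar", "k").C
        assert np.isclose(g, l)

    def test_single_level_axis_rejected(self):
        axes = dict(AXES, k=[0.5])
        scan = synthetic_scan(linear_stats, axes)
        with pytest.raises(ValueError, match="levels"):
            global_susceptibility(scan, "s_bar", "k")
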