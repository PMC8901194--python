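import itertools

import numpy as np
import pandas as pd
import pytest

from nirscr import (EventBlock, HemoSeries, SimConfig, baseline_threshold,
                    build_design, fit_glm_nnls, label_responder, t_value)
from nirscr.activation import DEFAULT_T_THRESHOLDS

FS = 8.98


def _events():
    return (EventBlock("left", 30.0, 16.0), EventBlock("right", 70.0, 16.0))


def _nnls_oracle(y, X, mask):
    """Exhaustive sign-support enumeration for the mixed-constraint problem."""
    free = np.flatnonzero(~mask)
    nuis = np.flatnonzero(mask)
    best = np.inf
    for r in range(len(nuis) + 1):
        for subset in itertools.combinations(nuis, r):
            cols = np.concatenate([free, np.array(subset, int)])
            sol, *_ = np.linalg.lstsq(X[:, cols], y, rcond=None)
            w = sol[len(free):]
            if np.any(w < -1e-12):
                continue
            resid = y - X[:, cols] @ sol
            best = min(best, resid @ resid)
    return best


# ---------------------------------------------------------------------------
# design construction


def test_design_column_count_without_shorts():
    n = int(150 * FS)
    d = build_design(_events(), n, FS)
    assert d.n_columns == 7          # 2 conditions x 3 kernels + constant
    assert not d.nonneg_mask.any()
    assert set(d.canonical_cols) == {"left", "right"}


def test_design_with_eight_shorts_has_fifteen_columns():
    n = int(150 * FS)
    rng = np.random.default_rng(0)
    shorts = rng.normal(0, 1, (n, 8))
    d = build_design(_events(), n, FS, shorts)
    assert d.n_columns == 15
    assert d.nonneg_mask.sum() == 8
    assert not d.nonneg_mask[:7].any()
    # nuisance columns are mean-centered
    assert np.allclose(d.X[:, d.nonneg_mask].mean(axis=0), 0, atol=1e-12)


def test_empty_event_list_gives_baseline_design():
    n = 500
    rng = np.random.default_rng(1)
    d = build_design((), n, FS, rng.normal(0, 1, (n, 3)))
    assert d.names[0] == "constant"
    assert d.n_columns == 4
    assert d.canonical_cols == {}


def test_derivatives_orthogonal_to_canonical():
    n = int(150 * FS)
    d = build_design(_events(), n, FS)
    for cond in ("left", "right"):
        c = d.canonical_cols[cond]
        assert abs(d.X[:, c] @ d.X[:, c + 1]) < 1e-8
        assert abs(d.X[:, c] @ d.X[:, c + 2]) < 1e-8


# ---------------------------------------------------------------------------
# constrained GLM solver


def test_nuisance_column_fitted_exactly_when_it_explains_y():
    n = 400
    rng = np.random.default_rng(2)
    shorts = np.abs(rng.normal(0, 1, (n, 2)))
    d = build_design((), n, FS, shorts)
    y = 2.0 * d.X[:, d.names.index("short_0")]
    fit = fit_glm_nnls(y, d)
    assert fit.beta[d.names.index("short_0")] == pytest.approx(2.0, abs=1e-8)
    assert fit.beta[d.names.index("short_1")] == pytest.approx(0.0, abs=1e-8)


def test_anticorrelated_nuisance_clamped_to_zero():
    n = 400
    rng = np.random.default_rng(3)
    s = rng.normal(0, 1, (n, 1))
    d = build_design((), n, FS, s)
    y = -1.5 * (s[:, 0] - s[:, 0].mean()) + 0.01 * rng.normal(0, 1, n)
    fit = fit_glm_nnls(y, d)
    assert fit.beta[d.names.index("short_0")] == 0.0
    assert len(fit.active_nuisance) == 0


def test_reduces_to_ols_with_no_nuisance():
    n = int(150 * FS)
    rng = np.random.default_rng(4)
    d = build_design(_events(), n, FS)
    y = rng.normal(0, 1, n)
    fit = fit_glm_nnls(y, d)
    closed_form, *_ = np.linalg.lstsq(d.X, y, rcond=None)
    np.testing.assert_allclose(fit.beta, closed_form, atol=1e-9)
    assert fit.dof == n - d.n_columns


@pytest.mark.parametrize("seed", range(5))
def test_matches_exhaustive_enumeration_oracle(seed):
    rng = np.random.default_rng(seed)
    n, p_free, p_nuis = 120, 2, 4
    X = np.column_stack([np.ones(n),
                         rng.normal(0, 1, (n, p_free - 1 + p_nuis))])
    mask = np.zeros(p_free + p_nuis, bool)
    mask[p_free:] = True
    names = ["constant"] + [f"x{i}" for i in range(p_free - 1 + p_nuis)]
    from nirscr.activation import DesignMatrix

    d = DesignMatrix(X, tuple(names), mask, FS)
    for _ in range(20):
        y = rng.normal(0, 1, n)
        fit = fit_glm_nnls(y, d)
        assert fit.rss == pytest.approx(_nnls_oracle(y, X, mask), abs=1e-8)


def test_singular_free_block_raises():
    n = 200
    X = np.column_stack([np.ones(n), np.ones(n)])
    from nirscr.activation import DesignMatrix

    d = DesignMatrix(X, ("constant", "dup"), np.array([False, False]), FS)
    y = np.random.default_rng(0).normal(0, 1, n)
    with pytest.raises(np.linalg.LinAlgError):
        fit_glm_nnls(y, d)


# ---------------------------------------------------------------------------
# t-values


def test_null_t_centred_on_zero():
    n = int(150 * FS)
    d = build_design(_events(), n, FS)
    rng = np.random.default_rng(5)
    ts = []
    for _ in range(300):
        fit = fit_glm_nnls(rng.normal(0, 1, n), d)
        ts.append(t_value(fit, d, "left"))
    assert -0.2 < np.mean(ts) < 0.2


def test_t_scales_linearly_with_amplitude():
    n = int(150 * FS)
    d = build_design(_events(), n, FS)
    rng = np.random.default_rng(6)
    noise = rng.normal(0, 0.3, n)
    sig = d.X[:, d.canonical_cols["left"]]
    t1 = t_value(fit_glm_nnls(sig + noise, d), d, "left")
    t2 = t_value(fit_glm_nnls(2 * sig + noise, d), d, "left")
    assert t2 / t1 == pytest.approx(2.0, rel=0.15)


def test_zero_residual_fit_capped_with_warning():
    n = int(150 * FS)
    d = build_design(_events(), n, FS)
    y = 0.5 * d.X[:, d.canonical_cols["left"]]
    fit = fit_glm_nnls(y, d)
    with pytest.warns(UserWarning, match="cap"):
        t = t_value(fit, d, "left")
    assert t == pytest.approx(1e6)


def test_unknown_condition_rejected():
    n = int(150 * FS)
    d = build_design(_events(), n, FS)
    fit = fit_glm_nnls(np.random.default_rng(0).normal(0, 1, n), d)
    with pytest.raises(ValueError, match="condition"):
        t_value(fit, d, "bimanual")


# ---------------------------------------------------------------------------
# baseline-derived thresholds


def test_shipped_default_thresholds():
    assert DEFAULT_T_THRESHOLDS == {"SCR": 30.0, "NR": 22.0}


def _white_rest(montage, sd, seed, duration_s=700.0):
    rng = np.random.default_rng(seed)
    n = int(duration_s * FS)
    return HemoSeries(rng.normal(0, sd, (n, 24)), rng.normal(0, sd, (n, 24)),
                      FS, montage)


def test_threshold_scale_invariance(montage):
    cfg = SimConfig(n_trials=8, baseline_start_s=60, baseline_end_s=30)
    kw = dict(n_draws=150, tag="NR", protocol_cfg=cfg,
              rng=np.random.default_rng(0))
    t1 = baseline_threshold(_white_rest(montage, 1.0, 1), **kw)
    kw["rng"] = np.random.default_rng(0)
    t2 = baseline_threshold(_white_rest(montage, 2.0, 2), **kw)
    assert t2 == pytest.approx(t1, rel=0.10)


def test_threshold_errors(montage):
    rest = _white_rest(montage, 1.0, 0, duration_s=100.0)
    cfg = SimConfig(n_trials=8, baseline_start_s=60, baseline_end_s=30)
    with pytest.raises(ValueError, match="draws"):
        baseline_threshold(rest, n_draws=10, protocol_cfg=cfg)
    with pytest.raises(ValueError, match="shorter"):
        baseline_threshold(rest, n_draws=100, protocol_cfg=cfg,
                           rng=np.random.default_rng(0))
    tasked = rest.copy_with(events=(EventBlock("left", 1.0, 5.0),))
    with pytest.raises(ValueError, match="task"):
        baseline_threshold(tasked, n_draws=100, protocol_cfg=cfg)


# ---------------------------------------------------------------------------
# responder labeling


def _table(per_run_max):
    rows = []
    for (sess, run), t in zip(
        [(1, 1), (1, 2), (2, 1), (2, 2)], per_run_max
    ):
        rows.append({"subject": 1, "session": sess, "run": run,
                     "tag": "SCR", "chromophore": "o2hb", "t": t})
    return pd.DataFrame(rows)


@pytest.mark.parametrize("maxima,expected", [
    ((31.0, 35.0, 40.0, 44.0), "strong"),   # mean 37.5
    ((14.0, 20.0, 24.0, 22.0), "weak"),     # mean 20
    ((30.0, 30.0, 30.0, 30.0), "weak"),     # boundary: strict inequality
])
def test_responder_label_rule(maxima, expected):
    assert label_responder(_table(maxima), 1, threshold=30.0) == expected


def test_missing_runs_listed():
    tbl = _table((31.0, 35.0, 40.0, 44.0))
    tbl = tbl[~((tbl.session == 2) & (tbl.run == 2))]
    with pytest.raises(ValueError, match=r"\(2, 2\)"):
        label_responder(tbl, 1)
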