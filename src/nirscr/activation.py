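"""GLM activation estimation with multichannel non-negative short-channel
regression.

The design matrix holds, per condition, the boxcar-convolved canonical HRF
plus temporal and dispersion derivatives (orthogonalized against the
canonical column), a constant, and — for short-channel-regressed (SCR) fits —
the mean-centered short-channel hemoglobin series as nuisance regressors.
Nuisance weights are constrained to be non-negative: a scalp signal can only
*add* to a long channel, never subtract, and the constraint prevents the
regression from inflating the task estimate by fitting inverted scalp
signals.  The mixed problem

    min ||y - F b - N w||^2   s.t.  w >= 0   (b free)

is solved exactly by block elimination: the free columns F are projected
out, the reduced problem is solved by active-set NNLS, and b is recovered by
back-substitution.

The activation statistic is the t-value of the canonical-HRF coefficient,
computed on the design restricted to the free columns plus the *active*
(nonzero-weight) nuisance columns, with degrees of freedom
``n - n_free - n_active``.  Significance thresholds are derived empirically:
the full task protocol is repeatedly placed at random within rest data and
refitted, and the 95th percentile of the absolute null t-values is the
threshold (shipped defaults 30 for SCR and 22 for unregressed data).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import nnls as _scipy_nnls

from .hrf import condition_regressor
from .io import CONDITIONS, HemoSeries
from .quality import SHORT_QUALITY_DB, short_channel_quality

__all__ = [
    "DesignMatrix",
    "GLMFit",
    "build_design",
    "fit_glm_nnls",
    "t_value",
    "baseline_threshold",
    "label_responder",
    "DEFAULT_T_THRESHOLDS",
    "T_CEILING",
]

#: shipped significance thresholds (95% baseline-null point) per tag
DEFAULT_T_THRESHOLDS = {"SCR": 30.0, "NR": 22.0}

#: cap for t on zero-residual fits
T_CEILING = 1e6

_ACTIVE_TOL = 1e-10


@dataclass
class DesignMatrix:
    X: np.ndarray                      # [n_samples, n_columns]
    names: tuple[str, ...]
    nonneg_mask: np.ndarray            # True for nuisance (>=0) columns
    fs: float
    canonical_cols: dict[str, int] = field(default_factory=dict)

    def __post_init__(self):
        self.X = np.asarray(self.X, float)
        self.nonneg_mask = np.asarray(self.nonneg_mask, bool)
        if self.X.shape[1] != self.nonneg_mask.size or len(self.names) != self.nonneg_mask.size:
            raise ValueError("column bookkeeping mismatch")
        if sum(n == "constant" for n in self.names) != 1:
            raise ValueError("design must contain exactly one constant column")

    @property
    def n_columns(self) -> int:
        return self.X.shape[1]


def _orthogonalize(v: np.ndarray, against: np.ndarray) -> np.ndarray:
    denom = against @ against
    if denom == 0:
        return v
    return v - (v @ against) / denom * against


def build_design(
    events,
    n_samples: int,
    fs: float,
    short_nuisance: np.ndarray | None = None,
    nuisance_names: tuple[str, ...] | None = None,
    conditions: tuple[str, ...] = CONDITIONS,
    column_filter=None,
) -> DesignMatrix:
    """Assemble the GLM design for one chromophore.

    ``short_nuisance`` is an ``[n_samples, m]`` array of short-channel series
    (same chromophore, same filtering as the data); columns are mean-centered
    and flagged non-negative.  ``column_filter`` (series -> series) is applied
    to the task regressors so they live in the same band as filtered data —
    without it the band-pass would shrink the amplitude estimates.  With no
    events the design degenerates to constant + nuisance (baseline mode).
    """
    cols, names = [], []
    canonical_cols: dict[str, int] = {}
    present = [c for c in conditions
               if any(e.condition == c for e in events)] or list(conditions)
    if events:
        for cond in present:
            can = condition_regressor(events, cond, n_samples, fs, "canonical")
            td = condition_regressor(events, cond, n_samples, fs, "temporal_derivative")
            dd = condition_regressor(events, cond, n_samples, fs, "dispersion_derivative")
            if column_filter is not None:
                can, td, dd = column_filter(can), column_filter(td), column_filter(dd)
            td = _orthogonalize(td, can)
            dd = _orthogonalize(dd, can)
            canonical_cols[cond] = len(cols)
            cols += [can, td, dd]
            names += [f"hrf_{cond}", f"tderiv_{cond}", f"dderiv_{cond}"]
    cols.append(np.ones(n_samples))
    names.append("constant")
    n_task = len(cols)
    if short_nuisance is not None:
        short_nuisance = np.asarray(short_nuisance, float)
        if short_nuisance.shape[0] != n_samples:
            raise ValueError("nuisance length mismatch")
        for j in range(short_nuisance.shape[1]):
            cols.append(short_nuisance[:, j] - short_nuisance[:, j].mean())
            names.append(
                nuisance_names[j] if nuisance_names else f"short_{j}"
            )
    mask = np.zeros(len(cols), bool)
    mask[n_task:] = True
    return DesignMatrix(np.column_stack(cols), tuple(names), mask, fs, canonical_cols)


def passing_short_nuisance(
    hemo_filtered: HemoSeries,
    hemo_unfiltered: HemoSeries,
    chromophore: str,
    threshold_db: float = SHORT_QUALITY_DB,
) -> tuple[np.ndarray, tuple[str, ...]]:
    """Short-channel regressor block: channels passing the 12 dB quality check.

    Quality is judged on the *unfiltered* series (the pulse must be present);
    the regressors themselves come from the filtered series so they live in
    the same band as the data.  Raises if no short channel passes.
    """
    cols, names = [], []
    for ci in hemo_filtered.montage.short_indices:
        _, ok = short_channel_quality(hemo_unfiltered, int(ci))
        if ok:
            cols.append(hemo_filtered.chromophore(chromophore)[:, int(ci)])
            names.append(f"short_{int(ci)}")
        else:
            warnings.warn(f"short channel {int(ci)} fails the quality check; excluded")
    if not cols:
        raise ValueError("no usable short channels for SCR")
    return np.column_stack(cols), tuple(names)


@dataclass
class GLMFit:
    beta: np.ndarray
    sigma2: float
    dof: int
    active_nuisance: np.ndarray        # indices (into columns) of active nuisance
    rss: float
    n_samples: int
    tag: str = "NR"


def fit_glm_nnls(y: np.ndarray, design: DesignMatrix, tag: str = "NR") -> GLMFit:
    """Least squares with non-negativity on the nuisance block (exact)."""
    y = np.asarray(y, float)
    X, mask = design.X, design.nonneg_mask
    n, p = X.shape
    if n <= p:
        raise ValueError("need more samples than columns")
    F, N = X[:, ~mask], X[:, mask]
    beta = np.zeros(p)
    if N.shape[1] == 0:
        bf, _, rank, _ = np.linalg.lstsq(F, y, rcond=None)
        if rank < F.shape[1]:
            raise np.linalg.LinAlgError("unconstrained design block is singular")
        beta[~mask] = bf
        w = np.zeros(0)
    else:
        coefF, res, rank, _ = np.linalg.lstsq(F, np.column_stack([N, y]), rcond=None)
        if rank < F.shape[1]:
            raise np.linalg.LinAlgError("unconstrained design block is singular")
        proj = F @ coefF
        N_res = N - proj[:, :-1]
        y_res = y - proj[:, -1]
        w, _ = _scipy_nnls(N_res, y_res)
        bf, *_ = np.linalg.lstsq(F, y - N @ w, rcond=None)
        beta[~mask] = bf
        beta[mask] = w
    resid = y - X @ beta
    rss = float(resid @ resid)
    scale = max(float(w.max()), 1.0) if w.size else 1.0
    active = np.flatnonzero(mask)[w > _ACTIVE_TOL * scale] if w.size else np.array([], int)
    dof = n - int((~mask).sum()) - active.size
    if dof <= 0:
        raise ValueError("non-positive degrees of freedom")
    sigma2 = rss / dof
    return GLMFit(beta, sigma2, dof, active, rss, n, tag)


def t_value(fit: GLMFit, design: DesignMatrix, condition: str) -> float:
    """t of the canonical-HRF coefficient for ``condition``.

    The standard error comes from the design restricted to free columns plus
    the active nuisance set.  Zero-residual fits are capped at ``T_CEILING``.
    """
    if condition not in design.canonical_cols:
        raise ValueError(f"no canonical column for condition {condition!r}")
    col = design.canonical_cols[condition]
    free = np.flatnonzero(~design.nonneg_mask)
    keep = np.concatenate([free, fit.active_nuisance])
    Xr = design.X[:, keep]
    pos = int(np.flatnonzero(keep == col)[0])
    xtx_inv = np.linalg.pinv(Xr.T @ Xr)
    var = fit.sigma2 * xtx_inv[pos, pos]
    if var <= 0 or fit.sigma2 == 0:
        warnings.warn("zero-residual fit; t capped")
        return float(np.sign(fit.beta[col]) * T_CEILING) if fit.beta[col] else 0.0
    t = float(fit.beta[col] / np.sqrt(var))
    if abs(t) > T_CEILING:
        warnings.warn("near-zero residual; t capped")
    return float(np.clip(t, -T_CEILING, T_CEILING))


# ---------------------------------------------------------------------------
# baseline-derived thresholds


def baseline_threshold(
    rest_series: HemoSeries,
    n_draws: int = 1000,
    tag: str = "NR",
    protocol_cfg=None,
    rng: np.random.Generator | None = None,
    chromophore: str = "o2hb",
    rest_unfiltered: HemoSeries | None = None,
    quantile: float = 0.95,
    column_filter=None,
) -> float:
    """Empirical activation threshold from task-free rest data.

    For each draw, a freshly randomized full 30-trial protocol is placed at a
    random admissible shift within the rest recording and fitted to a random
    long channel; the ``quantile`` of the pooled absolute null t-values is
    returned.  ``tag='SCR'`` includes the rest recording's short channels as
    non-negative nuisance regressors.
    """
    from .simulate import SimConfig, make_protocol  # local import: avoids cycle

    if any(True for _ in rest_series.events):
        raise ValueError("rest series must contain no task events")
    if n_draws < 100:
        raise ValueError("need at least 100 draws")
    cfg = protocol_cfg or SimConfig()
    rng = rng or np.random.default_rng(0)
    n = rest_series.n_samples
    t_rest = n / rest_series.fs
    nuisance = nuis_names = None
    if tag == "SCR":
        ref = rest_unfiltered or rest_series
        nuisance, nuis_names = passing_short_nuisance(rest_series, ref, chromophore)
    y_all = rest_series.chromophore(chromophore)
    long_idx = rest_series.montage.long_indices
    tvals = []
    for _ in range(n_draws):
        events = make_protocol(cfg, rng)
        span = max(e.offset for e in events)
        slack = t_rest - span
        if slack < 0:
            raise ValueError(
                f"rest data ({t_rest:.0f} s) shorter than the protocol ({span:.0f} s)"
            )
        shift = rng.uniform(-cfg.baseline_start_s, slack - cfg.baseline_start_s)
        shifted = tuple(
            type(e)(e.condition, e.onset + shift, e.duration) for e in events
        )
        design = build_design(shifted, n, rest_series.fs, nuisance, nuis_names,
                              column_filter=column_filter)
        ch = int(rng.choice(long_idx))
        fit = fit_glm_nnls(y_all[:, ch], design, tag)
        for cond in design.canonical_cols:
            tvals.append(abs(t_value(fit, design, cond)))
    return float(np.quantile(tvals, quantile))


# ---------------------------------------------------------------------------
# responder labeling


def label_responder(
    table: pd.DataFrame,
    subject: int,
    threshold: float = DEFAULT_T_THRESHOLDS["SCR"],
    tag: str = "SCR",
    chromophore: str = "o2hb",
) -> str:
    """'strong' iff the per-run maximal t, averaged over the four runs,
    strictly exceeds ``threshold``.

    ``table`` is a tidy activation table with columns subject, session, run,
    tag, chromophore, t.
    """
    sel = table[
        (table["subject"] == subject)
        & (table["tag"] == tag)
        & (table["chromophore"] == chromophore)
    ]
    expected = {(s, r) for s in (1, 2) for r in (1, 2)}
    got = set(map(tuple, sel[["session", "run"]].drop_duplicates().to_numpy()))
    missing = expected - got
    if missing:
        raise ValueError(f"missing runs for subject {subject}: {sorted(missing)}")
    per_run_max = sel.groupby(["session", "run"])["t"].max()
    return "strong" if per_run_max.mean() > threshold else "weak"
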