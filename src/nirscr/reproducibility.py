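"""Test-retest statistics on activation tables.

Session agreement is quantified three ways, always on t-values at the ROI
contralateral to the moved hand (right hand -> ROI 1, left M1; left hand ->
ROI 5, right M1), with the two runs of a session averaged first:

* Pearson correlation between sessions across subjects, with a Fisher-z 95 %
  confidence interval;
* intraclass correlation for absolute agreement under a two-way random
  effects model — ICC(2,1) for single measurements and ICC(2,k) for
  session-averaged measurements — with F-distribution confidence intervals
  (McGraw & Wong formulation), interpreted as poor (<0.40), fair
  (0.40-0.60), good (0.60-0.75) or excellent (>=0.75);
* MAE%, the mean absolute session-2-minus-session-1 difference scaled by the
  range of the pooled observed values (in percent).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "IccResult",
    "session_correlation",
    "icc_two_way_random",
    "mae_percent",
    "interpret_icc",
    "reproducibility_report",
    "CONTRALATERAL_M1_ROI",
]

#: moved hand -> ROI over the contralateral primary motor cortex
CONTRALATERAL_M1_ROI = {"right": 1, "left": 5}


def interpret_icc(icc: float) -> str:
    if icc < 0.40:
        return "poor"
    if icc < 0.60:
        return "fair"
    if icc < 0.75:
        return "good"
    return "excellent"


def session_correlation(tbl: pd.DataFrame) -> tuple[float, tuple[float, float], float]:
    """Pearson r across subjects with Fisher-z 95 % CI and two-sided p."""
    x = np.asarray(tbl["session1_t"], float)
    y = np.asarray(tbl["session2_t"], float)
    n = x.size
    if n < 3:
        raise ValueError("need at least 3 subjects")
    if x.std() == 0 or y.std() == 0:
        raise ValueError("zero variance in a session column")
    r, p = stats.pearsonr(x, y)
    z = np.arctanh(np.clip(r, -1 + 1e-15, 1 - 1e-15))
    half = stats.norm.ppf(0.975) / np.sqrt(n - 3)
    ci = (float(np.tanh(z - half)), float(np.tanh(z + half)))
    return float(r), ci, float(p)


@dataclass
class IccResult:
    icc_single: float
    icc_average: float
    ci_single: tuple[float, float]
    ci_average: tuple[float, float]
    n_subjects: int
    k_sessions: int

    @property
    def interpretation_single(self) -> str:
        return interpret_icc(self.icc_single)

    @property
    def interpretation_average(self) -> str:
        return interpret_icc(self.icc_average)


def _mean_squares(data: np.ndarray) -> tuple[float, float, float]:
    """Two-way ANOVA mean squares: rows (subjects), columns, error."""
    n, k = data.shape
    grand = data.mean()
    row_means = data.mean(axis=1)
    col_means = data.mean(axis=0)
    ss_rows = k * np.sum((row_means - grand) ** 2)
    ss_cols = n * np.sum((col_means - grand) ** 2)
    ss_total = np.sum((data - grand) ** 2)
    ss_err = ss_total - ss_rows - ss_cols
    msr = ss_rows / (n - 1)
    msc = ss_cols / (k - 1)
    mse = ss_err / ((n - 1) * (k - 1))
    return float(msr), float(msc), float(mse)


def icc_two_way_random(tbl: pd.DataFrame | np.ndarray, alpha: float = 0.05) -> IccResult:
    """ICC(2,1) and ICC(2,k), absolute agreement, with F-based CIs.

    ``tbl`` is either a subjects x sessions array or a DataFrame with
    ``session1_t``/``session2_t`` columns.
    """
    if isinstance(tbl, pd.DataFrame):
        cols = [c for c in tbl.columns if c.startswith("session")]
        data = tbl[sorted(cols)].to_numpy(float)
    else:
        data = np.asarray(tbl, float)
    n, k = data.shape
    if n < 3:
        raise ValueError("need at least 3 subjects")
    msr, msc, mse = _mean_squares(data)

    denom_single = msr + (k - 1) * mse + k / n * (msc - mse)
    icc1 = (msr - mse) / denom_single if denom_single != 0 else 0.0
    denom_avg = msr + (msc - mse) / n
    icck = (msr - mse) / denom_avg if denom_avg != 0 else 0.0

    # McGraw & Wong F-based interval for ICC(A,1)
    a = k * icc1 / (n * (1 - icc1)) if icc1 < 1 else np.inf
    b = 1 + k * icc1 * (n - 1) / (n * (1 - icc1)) if icc1 < 1 else np.inf
    if np.isfinite(a) and (a * msc + b * mse) > 0:
        v = (a * msc + b * mse) ** 2 / (
            (a * msc) ** 2 / (k - 1) + (b * mse) ** 2 / ((n - 1) * (k - 1))
        )
        f1 = stats.f.ppf(1 - alpha / 2, n - 1, v)
        f2 = stats.f.ppf(1 - alpha / 2, v, n - 1)
        lo1 = n * (msr - f1 * mse) / (
            f1 * (k * msc + (k * n - k - n) * mse) + n * msr
        )
        hi1 = n * (f2 * msr - mse) / (
            k * msc + (k * n - k - n) * mse + n * f2 * msr
        )
    else:
        lo1 = hi1 = 1.0
    # averaged-measure bounds via Spearman-Brown on the single-measure bounds
    def _sb(r: float) -> float:
        return k * r / (1 + (k - 1) * r) if (1 + (k - 1) * r) != 0 else 1.0

    return IccResult(
        float(icc1), float(icck),
        (float(lo1), float(hi1)),
        (float(_sb(lo1)), float(_sb(hi1))),
        n, k,
    )


def mae_percent(tbl: pd.DataFrame) -> float:
    """100 x mean |t_s2 - t_s1| / range of the pooled session values."""
    x = np.asarray(tbl["session1_t"], float)
    y = np.asarray(tbl["session2_t"], float)
    pooled = np.concatenate([x, y])
    rng = pooled.max() - pooled.min()
    if rng == 0:
        raise ValueError("zero range of observed values")
    return float(100.0 * np.mean(np.abs(y - x)) / rng)


def session_pair_table(
    roi_table: pd.DataFrame,
    chromophore: str,
    condition: str,
    tag: str,
    roi: int | None = None,
) -> pd.DataFrame:
    """Subjects x sessions t at the contralateral-M1 ROI, runs averaged."""
    roi = roi if roi is not None else CONTRALATERAL_M1_ROI[condition]
    sel = roi_table[
        (roi_table["chromophore"] == chromophore)
        & (roi_table["condition"] == condition)
        & (roi_table["tag"] == tag)
        & (roi_table["roi"] == roi)
    ]
    per = sel.groupby(["subject", "session"])["t"].mean().unstack("session")
    missing = per.index[per.isna().any(axis=1)]
    if len(missing):
        raise ValueError(f"missing sessions for subjects {list(missing)}")
    out = pd.DataFrame({
        "subject": per.index,
        "session1_t": per[1].to_numpy(),
        "session2_t": per[2].to_numpy(),
    }).reset_index(drop=True)
    return out


def reproducibility_report(roi_table: pd.DataFrame) -> pd.DataFrame:
    """One row per (chromophore x condition x tag): r, ICCs, CIs, MAE%.

    ``roi_table`` is the tidy ROI-level activation table with columns
    subject, session, run, roi, chromophore, condition, tag, t.
    """
    rows = []
    for tag in ("NR", "SCR"):
        for chrom in ("o2hb", "hhb"):
            for cond in ("right", "left"):
                tbl = session_pair_table(roi_table, chrom, cond, tag)
                r, r_ci, p = session_correlation(tbl)
                icc = icc_two_way_random(tbl)
                rows.append({
                    "tag": tag, "chromophore": chrom, "condition": cond,
                    "roi": CONTRALATERAL_M1_ROI[cond],
                    "n_subjects": len(tbl),
                    "pearson_r": r, "pearson_ci_lo": r_ci[0],
                    "pearson_ci_hi": r_ci[1], "pearson_p": p,
                    "icc_single": icc.icc_single,
                    "icc_single_lo": icc.ci_single[0],
                    "icc_single_hi": icc.ci_single[1],
                    "icc_average": icc.icc_average,
                    "icc_average_lo": icc.ci_average[0],
                    "icc_average_hi": icc.ci_average[1],
                    "interpretation": icc.interpretation_single,
                    "mae_percent": mae_percent(tbl),
                })
    return pd.DataFrame(rows)


def report_markdown(report: pd.DataFrame) -> str:
    lines = [
        "| tag | chromophore | hand | ICC(2,1) [95% CI] | ICC(2,k) [95% CI] | r | MAE% |",
        "|---|---|---|---|---|---|---|",
    ]
    for _, r in report.iterrows():
        lines.append(
            f"| {r.tag} | {r.chromophore} | {r.condition} "
            f"| {r.icc_single:.2f} [{r.icc_single_lo:.2f}, {r.icc_single_hi:.2f}] "
            f"| {r.icc_average:.2f} [{r.icc_average_lo:.2f}, {r.icc_average_hi:.2f}] "
            f"| {r.pearson_r:.2f} | {r.mae_percent:.1f} |"
        )
    return "\n".join(lines)
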