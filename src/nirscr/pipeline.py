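"""End-to-end study analysis: preprocessing, activation tables, quality,
reproducibility and BCI classification over a whole (simulated or loaded)
test-retest study."""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .activation import build_design, fit_glm_nnls, passing_short_nuisance, t_value
from .bci import (apply_adaptive_scr, build_trial_dataset, causal_filter,
                  evaluate_session, train_classifier)
from .io import CONDITIONS, RawRecording
from .preprocess import bandpass_taps, preprocess_recording, zero_phase
from .quality import quality_report
from .reproducibility import reproducibility_report
from .simulate import Study

__all__ = ["StudyAnalysis", "analyze_recording", "analyze_study", "roi_table"]

TAGS = ("NR", "SCR")


def analyze_recording(rec: RawRecording, motion_correction: bool = True) -> dict:
    """Process one run: hemoglobin series, quality report, channelwise GLM.

    Returns a dict with the quality report, the processed series and a tidy
    channel-level table of t-values and canonical-HRF amplitude estimates for
    both the unregressed (NR) and short-channel-regressed (SCR) fits.
    """
    hemo_raw, hemo_filt = preprocess_recording(rec, motion_correction=motion_correction)
    qrep = quality_report(rec, hemo_raw)
    meta = rec.meta
    rows = []
    n = hemo_filt.n_samples
    taps = bandpass_taps(rec.fs)
    col_filter = lambda x: zero_phase(taps, x)  # noqa: E731
    for chrom in ("o2hb", "hhb"):
        designs = {}
        designs["NR"] = build_design(rec.events, n, rec.fs, column_filter=col_filter)
        try:
            nuis, nuis_names = passing_short_nuisance(hemo_filt, hemo_raw, chrom)
            designs["SCR"] = build_design(rec.events, n, rec.fs, nuis, nuis_names,
                                          column_filter=col_filter)
        except ValueError:
            warnings.warn("no usable short channels; SCR fit skipped for this run")
        y = hemo_filt.chromophore(chrom)
        for tag, design in designs.items():
            for ci in rec.montage.long_indices:
                fit = fit_glm_nnls(y[:, int(ci)], design, tag)
                for cond in design.canonical_cols:
                    rows.append({
                        "subject": meta.get("subject"),
                        "session": meta.get("session"),
                        "run": meta.get("run"),
                        "channel": int(ci),
                        "roi": rec.montage.channels[int(ci)].roi_id,
                        "chromophore": chrom,
                        "condition": cond,
                        "tag": tag,
                        "t": t_value(fit, design, cond),
                        "beta": float(fit.beta[design.canonical_cols[cond]]),
                    })
    return {
        "quality": qrep,
        "hemo_raw": hemo_raw,
        "hemo_filt": hemo_filt,
        "channel_table": pd.DataFrame(rows),
    }


def roi_table(channel_table: pd.DataFrame) -> pd.DataFrame:
    """ROI value = arithmetic mean of its two long channels."""
    keys = ["subject", "session", "run", "roi", "chromophore", "condition", "tag"]
    return channel_table.groupby(keys, as_index=False)[["t", "beta"]].mean()


@dataclass
class StudyAnalysis:
    channel_table: pd.DataFrame
    roi_table: pd.DataFrame
    quality_table: pd.DataFrame
    bci_table: pd.DataFrame | None = None
    truths: dict = field(default_factory=dict)

    def reproducibility(self) -> pd.DataFrame:
        return reproducibility_report(self.roi_table)


def _bci_session(records: list[dict], source: str, seed: int) -> float:
    """Train on run 1, test on run 2 of one subject-session; accuracy %."""
    datasets = {}
    for r in sorted(records, key=lambda r: r["run"]):
        series = causal_filter(r["hemo_raw"])
        if source == "SCR":
            series = apply_adaptive_scr(series)
        datasets[r["run"]] = build_trial_dataset(series, source)
    model = train_classifier(datasets[1], seed=seed)
    res = evaluate_session(model, datasets[2], datasets[1].feature_names)
    return res.accuracy_pct


def analyze_study(
    study: Study,
    run_bci: bool = True,
    bci_sources: tuple[str, ...] = ("SCR",),
    motion_correction: bool = True,
    seed: int = 0,
) -> StudyAnalysis:
    """Run the full offline chain (and optionally the pseudo-online BCI)."""
    chan_tables, qual_rows, truths = [], [], {}
    processed: dict[tuple[int, int], list[dict]] = {}
    for rec_info in study.records:
        rec = rec_info["recording"]
        out = analyze_recording(rec, motion_correction=motion_correction)
        chan_tables.append(out["channel_table"])
        key = (rec_info["subject"], rec_info["session"])
        processed.setdefault(key, []).append(
            {"run": rec_info["run"], "hemo_raw": out["hemo_raw"]}
        )
        q = out["quality"]
        qual_rows.append({
            "subject": rec_info["subject"], "session": rec_info["session"],
            "run": rec_info["run"],
            "mean_intensity_v": float(
                q.mean_intensity_v[rec.montage.long_indices].mean()
            ),
            "snr_db": float(q.snr_db[rec.montage.long_indices].mean()),
            "short_pass_rate": q.short_pass_rate,
            "mayer_amplitude": q.mayer_amplitude,
            "screening_pass": q.screening_pass,
        })
        truths[(rec_info["subject"], rec_info["session"], rec_info["run"])] = \
            rec_info["truth"]
    channel_table = pd.concat(chan_tables, ignore_index=True)
    bci_table = None
    if run_bci:
        bci_rows = []
        for (subject, session), records in sorted(processed.items()):
            if len(records) < 2:
                continue
            for source in bci_sources:
                acc = _bci_session(records, source, seed)
                bci_rows.append({
                    "subject": subject, "session": session,
                    "source": source, "accuracy_pct": acc,
                })
        bci_table = pd.DataFrame(bci_rows)
    return StudyAnalysis(
        channel_table, roi_table(channel_table), pd.DataFrame(qual_rows),
        bci_table, truths,
    )
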