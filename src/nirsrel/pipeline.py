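"""End-to-end orchestration: simulate -> preprocess -> separate -> GLM ->
reliability report, with a reproducible manifest.

The reliability report mirrors the standard test-retest reporting layout:
a group activation-map agreement table (pattern r, significant-channel
counts, R_QUANTITY, R_OVERLAP), a per-subject agreement table, an ICC
table per ROI (single-channel and cluster level, single-session and
two-session-average), a between-session amplitude comparison table
(paired t, Cohen's d), and block-averaged time-course correlations.
"""
from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .config import MEASURES, PipelineConfig
from .errors import ConfigurationError
from .glm import (ActivationMap, build_design_matrix, fit_glm_cochrane_orcutt,
                  group_level_map, one_sided_p, subject_activation_channels)
from .hms import separate_recording
from .preprocess import preprocess_recording
from .reliability import (block_average, classify_effect_size,
                          classify_reliability, cluster_amplitude, icc_oneway,
                          overlap_counts, paired_test, pattern_correlation,
                          r_overlap, r_quantity, timecourse_correlation)
from .simulate import simulate_cohort

log = logging.getLogger("nirsrel")

_FLOAT_FORMAT = "%.10g"


@dataclass
class PipelineResult:
    config: PipelineConfig
    recordings: list
    haemo: dict  # (subject, session) -> HaemoSeries (with components)
    glm_table: pd.DataFrame
    group_maps: dict  # (session, condition, measure) -> ActivationMap
    report: dict  # table name -> DataFrame
    manifest: dict = field(default_factory=dict)


def _fit_stage(recordings, haemo_by_rec, glm_cfg, conditions, n_channels):
    """Fit the GLM for every recording, measure, and channel."""
    rows = []
    for rec in recordings:
        series = haemo_by_rec[(rec.subject, rec.session)]
        dm = build_design_matrix(rec.design, rec.fs, glm_cfg.hrf_duration_s)
        for measure in MEASURES:
            data = series.measure(measure)
            for ch in range(n_channels):
                fit = fit_glm_cochrane_orcutt(
                    data[ch], dm, iterate=glm_cfg.iterate_cochrane_orcutt
                )
                p_cond = {
                    c: float(one_sided_p(fit.coef(c)[2], fit.dof, measure))
                    for c in conditions
                }
                for c in conditions:
                    beta, se, t = fit.coef(c)
                    rows.append({
                        "subject": rec.subject,
                        "session": rec.session,
                        "measure": measure,
                        "condition": c,
                        "channel": ch + 1,
                        "beta": beta,
                        "se": se,
                        "t": t,
                        "dof": fit.dof,
                        "rho": fit.rho,
                        "p": p_cond[c],
                    })
    table = pd.DataFrame(rows)
    # Single-subject FDR: family = channels within subject x session x
    # condition x measure.
    table["significant"] = False
    for _, idx in table.groupby(["subject", "session", "condition", "measure"]).groups.items():
        sub = table.loc[idx].sort_values("channel")
        sig = set(subject_activation_channels(sub["p"].to_numpy(), q=glm_cfg.q))
        table.loc[idx, "significant"] = table.loc[idx, "channel"].isin(sig)
    return table


def _beta_matrix(glm_table, session, condition, measure, subjects, n_channels):
    sub = glm_table[(glm_table["session"] == session)
                    & (glm_table["condition"] == condition)
                    & (glm_table["measure"] == measure)]
    pivot = sub.pivot(index="subject", columns="channel", values="beta")
    pivot = pivot.loc[list(subjects), list(range(1, n_channels + 1))]
    return pivot.to_numpy()


def _group_pattern_table(group_maps, conditions):
    rows = []
    for condition in conditions:
        for measure in MEASURES:
            m1 = group_maps[(1, condition, measure)]
            m2 = group_maps[(2, condition, measure)]
            a1, a2, aov = overlap_counts(m1.significant, m2.significant)
            r = pattern_correlation(m1.t_values, m2.t_values)
            rq = r_quantity(a1, a2)
            ro = r_overlap(a1, a2, aov)
            rows.append({
                "condition": condition, "measure": measure,
                "n_significant_session1": a1, "n_significant_session2": a2,
                "n_overlap": aov, "pattern_r": r,
                "r_quantity": rq, "r_overlap": ro,
                "pattern_r_label": classify_reliability(max(min(r, 1.0), -1.0)) if not np.isnan(r) else "n/a",
                "r_quantity_label": classify_reliability(rq),
                "r_overlap_label": classify_reliability(ro),
            })
    return pd.DataFrame(rows)


def _subject_pattern_table(glm_table, conditions, subjects, n_channels):
    rows = []
    for subject in subjects:
        for condition in conditions:
            for measure in MEASURES:
                maps = {}
                sigs = {}
                for session in (1, 2):
                    sub = glm_table[(glm_table["subject"] == subject)
                                    & (glm_table["session"] == session)
                                    & (glm_table["condition"] == condition)
                                    & (glm_table["measure"] == measure)].sort_values("channel")
                    maps[session] = sub["t"].to_numpy()
                    sigs[session] = tuple(sub.loc[sub["significant"], "channel"])
                a1, a2, aov = overlap_counts(sigs[1], sigs[2])
                rows.append({
                    "subject": subject, "condition": condition, "measure": measure,
                    "pattern_r": pattern_correlation(maps[1], maps[2]),
                    "n_significant_session1": a1, "n_significant_session2": a2,
                    "r_quantity": r_quantity(a1, a2),
                    "r_overlap": r_overlap(a1, a2, aov),
                })
    return pd.DataFrame(rows)


def _icc_table(glm_table, conditions, subjects, n_channels, roi_channels):
    rows = []
    for condition in conditions:
        for measure in MEASURES:
            mats = {
                session: _beta_matrix(glm_table, session, condition, measure,
                                      subjects, n_channels)
                for session in (1, 2)
            }
            for roi, channels in roi_channels.items():
                singles, averages = [], []
                for ch in channels:
                    data = np.column_stack([mats[1][:, ch - 1], mats[2][:, ch - 1]])
                    res = icc_oneway(data)
                    singles.append(res.icc_single)
                    averages.append(res.icc_average)
                cluster = np.column_stack([
                    cluster_amplitude(mats[1], channels),
                    cluster_amplitude(mats[2], channels),
                ])
                cres = icc_oneway(cluster)
                rows.append({
                    "condition": condition, "measure": measure, "roi": roi,
                    "single_channel_icc_single_mean": float(np.mean(singles)),
                    "single_channel_icc_single_min": float(np.min(singles)),
                    "single_channel_icc_single_max": float(np.max(singles)),
                    "single_channel_icc_average_mean": float(np.mean(averages)),
                    "single_channel_icc_average_min": float(np.min(averages)),
                    "single_channel_icc_average_max": float(np.max(averages)),
                    "cluster_icc_single": cres.icc_single,
                    "cluster_icc_average": cres.icc_average,
                    "cluster_icc_single_label": classify_reliability(cres.icc_single),
                    "cluster_icc_average_label": classify_reliability(cres.icc_average),
                })
    return pd.DataFrame(rows)


def _amplitude_table(glm_table, conditions, subjects, n_channels, roi_channels):
    rows = []
    for condition in conditions:
        for measure in MEASURES:
            mats = {
                session: _beta_matrix(glm_table, session, condition, measure,
                                      subjects, n_channels)
                for session in (1, 2)
            }
            for roi, channels in roi_channels.items():
                c1 = cluster_amplitude(mats[1], channels)
                c2 = cluster_amplitude(mats[2], channels)
                res = paired_test(c1, c2)
                rows.append({
                    "condition": condition, "measure": measure, "roi": roi,
                    "mean_session1": float(c1.mean()), "sd_session1": float(c1.std(ddof=1)),
                    "mean_session2": float(c2.mean()), "sd_session2": float(c2.std(ddof=1)),
                    "direction": res.direction, "t": res.t, "p": res.p,
                    "cohens_d": res.d,
                    "effect_size_label": classify_effect_size(res.d),
                })
    return pd.DataFrame(rows)


def _timecourse_table(recordings, haemo_by_rec, conditions, roi_channels, rel_cfg):
    """Between-session correlation of grand-average ROI response time courses."""
    rows = []
    for condition in conditions:
        for measure in MEASURES:
            for roi, channels in roi_channels.items():
                grand = {}
                for session in (1, 2):
                    epochs = []
                    for rec in recordings:
                        if rec.session != session:
                            continue
                        series = haemo_by_rec[(rec.subject, rec.session)]
                        roi_series = series.measure(measure)[
                            np.asarray(channels, int) - 1
                        ].mean(axis=0)
                        _, mean_epoch = block_average(
                            roi_series, rec.fs, rec.design.onsets[condition],
                            window_s=rel_cfg.window_s, baseline_s=rel_cfg.baseline_s,
                        )
                        epochs.append(mean_epoch)
                    grand[session] = np.mean(epochs, axis=0)
                r = timecourse_correlation(grand[1], grand[2])
                rows.append({
                    "condition": condition, "measure": measure, "roi": roi,
                    "timecourse_r": r,
                    "timecourse_r_label": classify_reliability(max(min(r, 1.0), -1.0)) if not np.isnan(r) else "n/a",
                })
    return pd.DataFrame(rows)


def run_pipeline(config: PipelineConfig = None, out_dir=None,
                 keep_intermediates: bool = False) -> PipelineResult:
    """Execute the full pipeline on a simulated cohort.

    With the same configuration and seed the pipeline is bit-reproducible:
    all report tables are written with a fixed float format and stable row
    ordering, so repeated runs produce byte-identical report files.
    """
    config = config or PipelineConfig()
    sim = dataclasses.replace(config.simulation, seed=config.resolved_seed())
    if sim.n_sessions != 2:
        raise ConfigurationError(
            f"the reliability stage requires exactly 2 sessions, got {sim.n_sessions}"
        )

    log.info("simulating cohort: %d subjects x %d sessions", sim.n_subjects, sim.n_sessions)
    recordings = simulate_cohort(sim)

    log.info("preprocessing and separating %d recordings", len(recordings))
    haemo_by_rec = {}
    for rec in recordings:
        haemo = preprocess_recording(rec, config.preprocessing)
        haemo = separate_recording(haemo, config.hms)
        haemo_by_rec[(rec.subject, rec.session)] = haemo

    conditions = list(sim.conditions)
    subjects = sorted({rec.subject for rec in recordings})
    n_channels = sim.n_channels

    log.info("fitting GLMs")
    glm_table = _fit_stage(recordings, haemo_by_rec, config.glm, conditions, n_channels)

    log.info("group-level maps and reliability metrics")
    group_maps = {}
    for session in (1, 2):
        for condition in conditions:
            for measure in MEASURES:
                betas = _beta_matrix(glm_table, session, condition, measure,
                                     subjects, n_channels)
                group_maps[(session, condition, measure)] = group_level_map(
                    betas, measure, q=config.glm.q, condition=condition,
                    session=session,
                )

    report = {
        "group_pattern": _group_pattern_table(group_maps, conditions),
        "subject_pattern": _subject_pattern_table(glm_table, conditions, subjects, n_channels),
        "icc": _icc_table(glm_table, conditions, subjects, n_channels, sim.roi_channels),
        "amplitude": _amplitude_table(glm_table, conditions, subjects, n_channels, sim.roi_channels),
        "timecourse": _timecourse_table(recordings, haemo_by_rec, conditions,
                                        sim.roi_channels, config.reliability),
    }

    result = PipelineResult(
        config=config,
        recordings=recordings,
        haemo=haemo_by_rec,
        glm_table=glm_table,
        group_maps=group_maps,
        report=report,
    )
    if out_dir is not None:
        result.manifest = write_report(result, out_dir, keep_intermediates=keep_intermediates)
    return result


def write_report(result: PipelineResult, out_dir, keep_intermediates: bool = False) -> dict:
    """Write report tables (+ optional GLM table) and a run manifest.

    Report files are deterministic; run metadata (timestamps) lives only
    in the manifest so repeated runs produce byte-identical reports.
    """
    out = Path(out_dir)
    report_dir = out / "report"
    report_dir.mkdir(parents=True, exist_ok=True)
    written = {}
    for name, table in result.report.items():
        path = report_dir / f"{name}.csv"
        table.to_csv(path, index=False, float_format=_FLOAT_FORMAT)
        written[f"report/{name}.csv"] = _sha256(path)
    if keep_intermediates:
        glm_path = out / "glm_results.csv"
        result.glm_table.to_csv(glm_path, index=False, float_format=_FLOAT_FORMAT)
        written["glm_results.csv"] = _sha256(glm_path)

    rq = (result.report["group_pattern"]
          .set_index(["condition", "measure"])["r_quantity"].round(6).dropna())
    summary = {
        "n_subjects": result.config.simulation.n_subjects,
        "n_sessions": result.config.simulation.n_sessions,
        "seed": result.config.resolved_seed(),
        "group_r_quantity": {f"{c}|{m}": v for (c, m), v in rq.items()},
    }
    summary_path = report_dir / "summary.json"
    summary_path.write_text(json.dumps(summary, indent=2, sort_keys=True))
    written["report/summary.json"] = _sha256(summary_path)

    import datetime

    manifest = {
        "package": "nirsrel",
        "version": __version__,
        "seed": result.config.resolved_seed(),
        "config": result.config.to_dict(),
        "checksums": written,
        "written_at": datetime.datetime.now(datetime.timezone.utc).isoformat(),
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True, default=str))
    return manifest


def _sha256(path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()
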