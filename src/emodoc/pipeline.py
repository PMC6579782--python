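"""End-to-end orchestration: simulate -> preprocess -> ERP statistics ->
PLV networks -> graph metrics -> group inference.

Every stage writes plain TSV/JSON into the output directory together with
a provenance record (config hash + seed), and a rerun with the same
config produces byte-identical result files.
"""

from __future__ import annotations

import hashlib
import json
import logging
import os
from dataclasses import replace

import numpy as np
import pandas as pd

from . import erp as erp_mod
from . import graph as graph_mod
from . import inference, plv
from .config import RunConfig
from .montage import Montage, standard_montage
from .preprocessing import EpochSet, preprocess_recording
from .synth import (
    EMOTIONAL,
    STANDARD,
    Recording,
    generate_oddball_sequence,
    subject_seed,
    synthesize_subject,
)

logger = logging.getLogger(__name__)

CONTRAST_CONDITIONS = (EMOTIONAL, STANDARD)  # emotional minus neutral
RESULT_FILES = (
    "subjects.tsv",
    "erp_stats.tsv",
    "erp_summary.json",
    "plv_edges.tsv",
    "graph_metrics.tsv",
    "anova.json",
    "edge_contrasts.tsv",
)


def config_hash(config: RunConfig) -> str:
    canon = json.dumps(config.to_dict(), sort_keys=True)
    return hashlib.sha256(canon.encode()).hexdigest()[:16]


def iter_subjects(config: RunConfig, montage: Montage | None = None):
    """Yield (subject_id, group, Recording) one at a time (memory-friendly)."""
    if montage is None:
        montage = standard_montage()
    for gi, (group, template) in enumerate(config.group_specs().items()):
        for si in range(config.n_per_group):
            sseed = subject_seed(config.seed, gi, si)
            spec = replace(template, seed=sseed)
            events = generate_oddball_sequence(
                *config.oddball_counts, seed=sseed, rate=config.rate
            )
            yield f"{group}{si + 1:02d}", group, synthesize_subject(
                spec, montage, events, config.rate
            )


def _stable_id(name: str) -> int:
    """Deterministic small integer from a subject name (hash() is salted)."""
    return int(hashlib.sha1(name.encode()).hexdigest()[:8], 16) % 100_000


def preprocess_subject(rec: Recording, config: RunConfig) -> EpochSet:
    return preprocess_recording(
        rec,
        hp_hz=config.hp_hz,
        lp_hz=config.lp_hz,
        notch_hz=config.notch_hz,
        window_ms=config.window_ms,
        baseline_ms=config.baseline_ms,
        reject_uv=config.reject_uv,
    )


def analyze_subject(
    subject: str, group: str, epochs: EpochSet, config: RunConfig
) -> dict:
    """Condition ERPs, condition PLV matrices and graph metrics for one subject."""
    waveforms = {
        cond: erp_mod.condition_average(epochs, cond) for cond in CONTRAST_CONDITIONS
    }
    components = []
    for comp in ("N1", "P3a", "LPP"):
        meas = erp_mod.ComponentMeasure.default(comp)
        for cond, wf in waveforms.items():
            components.append(
                {
                    "subject": subject,
                    "group": group,
                    "condition": cond,
                    "component": comp,
                    "mean_amplitude_uv": erp_mod.measure_component(wf, meas),
                }
            )

    phases = plv.instantaneous_phase(epochs, band_hz=config.plv_band_hz)
    n_match = None
    if config.match_trial_counts:
        n_match = min(
            int(epochs.condition_trials(c).sum()) for c in CONTRAST_CONDITIONS
        )
    matrices = {}
    metrics = {}
    for cond in CONTRAST_CONDITIONS:
        m = plv.condition_plv(
            phases,
            cond,
            window_ms=config.plv_window_ms,
            n_trials=n_match,
            seed=subject_seed(config.seed, 997, _stable_id(subject)),
            subject=subject,
            group=group,
        )
        matrices[cond] = m
        g = graph_mod.WeightedGraph.from_plv(m)
        metrics[cond] = graph_mod.network_metrics(
            g, with_sigma=config.with_sigma, n_rand=config.n_rand, seed=config.seed
        )
    return {
        "waveforms": waveforms,
        "components": components,
        "matrices": matrices,
        "metrics": metrics,
    }


def _scalp_waveform_stack(results: list[dict], montage: Montage, cond: str) -> np.ndarray:
    rows = [montage.index(c) for c in montage.scalp_channels]
    return np.stack([r["waveforms"][cond].mean[rows] for r in results])


def group_erp_stats(
    results: list[dict], groups: list[str], montage: Montage, config: RunConfig
) -> tuple[pd.DataFrame, dict]:
    """Per-group mass-univariate emotional-vs-neutral contrast."""
    times = results[0]["waveforms"][STANDARD].times_ms
    scalp = montage.scalp_channels
    rows, summary = [], {}
    for group in dict.fromkeys(groups):
        sel = [r for r, g in zip(results, groups) if g == group]
        emo = _scalp_waveform_stack(sel, montage, EMOTIONAL)
        neu = _scalp_waveform_stack(sel, montage, STANDARD)
        res = erp_mod.mass_univariate_paired_t(
            emo, neu, n_perm=config.n_perm, q=config.q, seed=config.seed
        )
        ch_idx, t_idx = np.nonzero(np.ones_like(res.t, dtype=bool))
        rows.append(
            pd.DataFrame(
                {
                    "group": group,
                    "channel": np.asarray(scalp)[ch_idx],
                    "time_ms": times[t_idx],
                    "t": res.t[ch_idx, t_idx],
                    "p_raw": res.p_raw[ch_idx, t_idx],
                    "p_adj": res.p_adj[ch_idx, t_idx],
                    "sig": res.sig_mask[ch_idx, t_idx],
                }
            )
        )
        sig_ch, sig_t = np.nonzero(res.sig_mask)
        summary[group] = {
            "n_significant_cells": int(res.sig_mask.sum()),
            "channels_with_significance": sorted(
                {scalp[i] for i in sig_ch}
            ),
            "significant_time_range_ms": (
                [float(times[sig_t].min()), float(times[sig_t].max())]
                if sig_t.size
                else None
            ),
            "n_perm": res.n_perm,
            "q": res.q,
        }
    return pd.concat(rows, ignore_index=True), summary


def edge_contrast_tables(
    results: list[dict], groups: list[str], config: RunConfig
) -> pd.DataFrame:
    """Within-group condition contrasts plus between-group contrasts."""
    frames = []
    order = list(dict.fromkeys(groups))
    by_group = {
        g: [r for r, gg in zip(results, groups) if gg == g] for g in order
    }
    for g in order:
        mats_e = [r["matrices"][EMOTIONAL] for r in by_group[g]]
        mats_n = [r["matrices"][STANDARD] for r in by_group[g]]
        if len(mats_e) < 2:
            logger.warning("group %s underpowered (n=%d); condition contrast skipped",
                           g, len(mats_e))
            continue
        res = inference.edgewise_contrast(mats_e, mats_n, paired=True, alpha=config.alpha)
        df = res.edges.copy()
        df.insert(0, "contrast", f"{g}:emotional-neutral")
        frames.append(df)
    for cond in CONTRAST_CONDITIONS:
        for ga, gb in (("MCS", "HC"), ("UWS", "HC"), ("UWS", "MCS")):
            if ga not in by_group or gb not in by_group:
                continue
            ma = [r["matrices"][cond] for r in by_group[ga]]
            mb = [r["matrices"][cond] for r in by_group[gb]]
            if len(ma) < 2 or len(mb) < 2:
                continue
            res = inference.edgewise_contrast(ma, mb, paired=False, alpha=config.alpha)
            df = res.edges.copy()
            df.insert(0, "contrast", f"{ga}-{gb}:{cond}")
            frames.append(df)
    return pd.concat(frames, ignore_index=True)


def property_tables(results: list[dict], subjects: list[str], groups: list[str]) -> dict:
    tables = {}
    for metric in ("C", "L", "Ge", "Le"):
        rows = []
        for subj, group, r in zip(subjects, groups, results):
            for cond in CONTRAST_CONDITIONS:
                rows.append(
                    {
                        "subject": subj,
                        "group": group,
                        "condition": cond,
                        "value": getattr(r["metrics"][cond], metric),
                    }
                )
        tables[metric] = pd.DataFrame(rows)
    return tables


def run_pipeline(config: RunConfig, out_dir) -> dict:
    """Run every stage and write the result bundle; returns the summary."""
    config.validate()
    os.makedirs(out_dir, exist_ok=True)
    montage = standard_montage()
    logger.info("pipeline start: %d subjects/group, seed %d", config.n_per_group, config.seed)

    subjects, groups, results, comp_rows, plv_rows = [], [], [], [], []
    underpowered = config.n_per_group < 2
    for subject, group, rec in iter_subjects(config, montage):
        logger.info("processing %s", subject)
        epochs = preprocess_subject(rec, config)
        res = analyze_subject(subject, group, epochs, config)
        subjects.append(subject)
        groups.append(group)
        results.append(res)
        comp_rows.extend(res["components"])
        for cond, m in res["matrices"].items():
            iu = np.triu_indices(len(m.channel_names), k=1)
            plv_rows.append(
                pd.DataFrame(
                    {
                        "subject": subject,
                        "group": group,
                        "condition": cond,
                        "ch_a": np.asarray(m.channel_names)[iu[0]],
                        "ch_b": np.asarray(m.channel_names)[iu[1]],
                        "plv": m.plv[iu],
                        "n_trials": m.n_trials,
                    }
                )
            )

    meta = pd.DataFrame({"subject": subjects, "group": groups})
    meta.to_csv(os.path.join(out_dir, "subjects.tsv"), sep="\t", index=False)

    if underpowered:
        erp_table = pd.DataFrame(
            columns=["group", "channel", "time_ms", "t", "p_raw", "p_adj", "sig"]
        )
        erp_summary = {
            g: "underpowered: fewer than 2 subjects" for g in dict.fromkeys(groups)
        }
    else:
        erp_table, erp_summary = group_erp_stats(results, groups, montage, config)
    erp_table.to_csv(os.path.join(out_dir, "erp_stats.tsv"), sep="\t", index=False)
    pd.DataFrame(comp_rows).to_csv(
        os.path.join(out_dir, "component_amplitudes.tsv"), sep="\t", index=False
    )

    pd.concat(plv_rows, ignore_index=True).to_csv(
        os.path.join(out_dir, "plv_edges.tsv"), sep="\t", index=False
    )

    tables = property_tables(results, subjects, groups)
    metric_frames = []
    anova_payload = {}
    for metric, table in tables.items():
        wide = table.pivot(index=["subject", "group"], columns="condition", values="value")
        metric_frames.append(
            wide.rename(columns=lambda c: f"{metric}_{c}").reset_index()
        )
        if underpowered:
            anova_payload[metric] = "underpowered: fewer than 2 subjects per group"
            continue
        res = inference.mixed_rm_anova(table)
        payload = res.to_dict()
        payload["posthoc_group"] = inference.bonferroni_posthoc(
            table, alpha=config.alpha
        ).to_dict(orient="records")
        payload["simple_effects"] = inference.simple_effects(
            table, conditions=CONTRAST_CONDITIONS, alpha=config.alpha
        ).to_dict(orient="records")
        anova_payload[metric] = payload
    merged = metric_frames[0]
    for frame in metric_frames[1:]:
        merged = merged.merge(frame, on=["subject", "group"])
    merged.to_csv(os.path.join(out_dir, "graph_metrics.tsv"), sep="\t", index=False)

    if underpowered:
        edge_table = pd.DataFrame()
        logger.warning("group statistics flagged underpowered (n_per_group=%d)",
                       config.n_per_group)
    else:
        edge_table = edge_contrast_tables(results, groups, config)
    edge_table.to_csv(os.path.join(out_dir, "edge_contrasts.tsv"), sep="\t", index=False)

    summary = {
        "erp": erp_summary,
        "anova": anova_payload,
        "underpowered": underpowered,
        "edge_mask_cardinality": {},
    }
    if len(edge_table):
        for contrast, sub in edge_table.groupby("contrast"):
            summary["edge_mask_cardinality"][contrast] = {
                "uncorrected": int(sub["sig_uncorrected"].sum()),
                "bonferroni": int(sub["sig_bonferroni"].sum()),
            }
    with open(os.path.join(out_dir, "erp_summary.json"), "w") as fh:
        json.dump(erp_summary, fh, indent=1, sort_keys=True)
    with open(os.path.join(out_dir, "anova.json"), "w") as fh:
        json.dump(anova_payload, fh, indent=1, sort_keys=True)
    with open(os.path.join(out_dir, "provenance.json"), "w") as fh:
        json.dump(
            {"config": config.to_dict(), "config_hash": config_hash(config),
             "seed": config.seed, "result_files": list(RESULT_FILES)},
            fh, indent=1, sort_keys=True,
        )
    with open(os.path.join(out_dir, "summary.json"), "w") as fh:
        json.dump(summary, fh, indent=1, sort_keys=True, default=str)
    logger.info("pipeline done: results in %s", out_dir)
    return summary
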