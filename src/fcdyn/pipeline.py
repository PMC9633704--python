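"""End-to-end orchestration: connectivity -> meta-matrix -> decay-model
fits -> proximal/distal measures -> structure-function summaries -> cohort
ordinal regressions."""

from __future__ import annotations

import logging
import warnings

import numpy as np
import pandas as pd

from . import io as fio
from .complexity import DegenerateSeriesWarning, UndefinedMeasureWarning
from .metamatrix import build_meta_matrix, build_tdsm, tdsm_fit
from .ordstats import run_cohort_analysis
from .profiles import distal_measures, proximal_series, summarize_series
from .structfunc import struct_func_series, struct_func_summary
from .synth import StructuralConnectome, Subject
from .windows import RegionTimeSeries, sliding_window_connectivity

__all__ = ["compute_subject_measures", "run_pipeline"]

log = logging.getLogger(__name__)


def _subset_ts(ts: RegionTimeSeries, region_ids) -> RegionTimeSeries:
    idx = [ts.region_ids.index(r) for r in region_ids]
    return RegionTimeSeries(values=ts.values[:, idx],
                            tr_seconds=ts.tr_seconds,
                            region_ids=tuple(region_ids))


def _subset_sc(sc: StructuralConnectome, all_ids, region_ids):
    idx = [list(all_ids).index(r) for r in region_ids]
    return StructuralConnectome(weights=sc.weights[np.ix_(idx, idx)])


def compute_subject_measures(
    ts: RegionTimeSeries,
    sc: StructuralConnectome | None,
    config: fio.PipelineConfig,
    truncate_to: int | None = None,
    measures: set[str] | None = None,
) -> dict[str, float]:
    """All per-subject scalar measures for one region set.

    Measure names follow ``<family>_<parameters>_<statistic>``:
    tdsm fits (one per metric x kind), proximal sub-diagonal summaries
    (per max-lag), distal meta-matrix summaries (per exclusion lag k),
    and structure-function complexities. ``truncate_to`` cuts the
    connectivity series to a cohort-wide common number of windows before
    the meta-matrix is built. ``measures`` optionally restricts the
    measure families computed ({"tdsm", "proximal", "distal",
    "structfunc"}).
    """
    wanted = measures or {"tdsm", "proximal", "distal", "structfunc"}
    cs = sliding_window_connectivity(ts, window_length=config.window_length,
                                     step=config.step,
                                     taper_sigma=config.taper_sigma)
    if truncate_to is not None:
        cs = cs.truncated(truncate_to)
    out: dict[str, float] = {}
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", DegenerateSeriesWarning)
        warnings.simplefilter("ignore", UndefinedMeasureWarning)
        for metric in config.mm_metrics:
            mm = build_meta_matrix(cs, metric=metric)
            tag = "" if metric == "pearson" else f"{metric}_"
            if "tdsm" in wanted:
                for kind in config.tdsm_kinds:
                    model = build_tdsm(mm.n_windows, kind)
                    out[f"{tag}tdsm_fit_{kind}"] = tdsm_fit(mm, model)
            if "proximal" in wanted:
                for lag in config.proximal_lags:
                    ps = proximal_series(mm, max_lag=lag)
                    ms = summarize_series(ps.values, bins=config.bins,
                                          sampen_m=config.sampen_m,
                                          sampen_r=config.sampen_r)
                    for name, val in ms.as_dict().items():
                        out[f"{tag}prox_lag{lag}_{name}"] = val
            if "distal" in wanted:
                for k in config.distal_k:
                    ds = distal_measures(mm, k, mode=config.distal_mode,
                                         bins=config.bins,
                                         sampen_m=config.sampen_m,
                                         sampen_r=config.sampen_r)
                    for name, val in ds.measures.as_dict().items():
                        out[f"{tag}dmm_k{k}_{name}"] = val
                    out[f"{tag}dmm_k{k}_mean_max"] = ds.mean_max_similarity
        if "structfunc" in wanted and sc is not None:
            sf = struct_func_series(cs, sc, metric=config.sf_metric,
                                    rank=config.sf_rank)
            summ = struct_func_summary(sf, bins=config.bins,
                                       sampen_m=config.sampen_m,
                                       sampen_r=config.sampen_r)
            out["sf_sample_entropy"] = summ.sample_entropy
            out["sf_etc_norm"] = summ.effort_to_compress_norm
            out["sf_max_similarity"] = summ.max_similarity
    return out


def run_pipeline(config: fio.PipelineConfig,
                 subjects: list[Subject]) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Run the full analysis over a cohort.

    Returns a tidy per-subject measures table (subject_id, condition,
    subset, measure, value) and the cohort-level ordinal regression
    results (one row per measure x subset). Subjects failing at any stage
    are flagged and skipped; the failure list is logged.
    """
    subsets: dict[str, list | None] = {"whole": None}
    if config.region_subsets:
        subsets.update(config.region_subsets)
    min_windows = min(
        (s.timeseries.n_timepoints - config.window_length) // config.step + 1
        for s in subjects)
    rows = []
    failures = []
    for subj in subjects:
        for subset_name, region_ids in subsets.items():
            try:
                ts = subj.timeseries
                sc = subj.connectome
                if region_ids is not None:
                    ts = _subset_ts(ts, region_ids)
                    sc = _subset_sc(sc, subj.timeseries.region_ids, region_ids)
                vals = compute_subject_measures(ts, sc, config,
                                                truncate_to=min_windows)
            except Exception as exc:  # noqa: BLE001 - keep cohort running
                failures.append((subj.subject_id, subset_name, str(exc)))
                continue
            for name, val in vals.items():
                rows.append({"subject_id": subj.subject_id,
                             "condition": subj.condition,
                             "subset": subset_name,
                             "measure": name, "value": val})
    if failures:
        log.warning("pipeline failures: %s", failures)
    measures_df = pd.DataFrame(rows)
    results = []
    for subset_name in subsets:
        sub = measures_df[measures_df["subset"] == subset_name]
        if sub.empty:
            continue
        res = run_cohort_analysis(sub, config.condition_order)
        res.insert(0, "subset", subset_name)
        results.append(res)
    results_df = pd.concat(results, ignore_index=True) if results else pd.DataFrame()
    return measures_df, results_df
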