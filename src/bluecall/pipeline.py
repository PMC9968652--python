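"""End-to-end pipeline: synth -> detect -> evaluate -> classify ->
call metrics -> detection range -> BRT -> heatwave stats -> whaling.

Stages communicate only through files in the package's documented formats
(WAV, selection-table TSV, CSV, JSON), so any synthetic stage input can be
replaced by real data without code changes. A JSON manifest records every
stage's parameters, seed, outputs, and their SHA-256 hashes; rerunning
with the same config and seed reproduces the hashes exactly.
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io as bcio
from .brt import extract_env_series, fit_brt, partial_dependence
from .call_metrics import annual_cycle, daily_summary, song_intensity_index, summaries_frame
from .classify import bootstrap_evaluate, extract_features
from .evaluate import detector_metrics, match_detections
from .mixed import (
    fit_year_lmm,
    foraging_reproduction_lmm,
    summer_subset,
    tukey_pairwise_labeled,
)
from .propagation import band_noise_percentile, detection_area, make_grid
from .spectro import DCALL_THRESHOLD, SONG_THRESHOLD, compute_spectrogram, detect_calls
from .synth import (
    GridSpec,
    synth_call_series,
    synth_catches,
    synth_clip,
    synth_env,
)
from .templates import detector_spectrogram, make_template_bank
from .types import DCALL_PROPAGATION, SONG_PROPAGATION, Detection
from .whaling import assign_all, fetal_curve, filter_region, infer_birth_conception

STAGES = [
    "synth",
    "detect",
    "evaluate",
    "classify",
    "call_metrics",
    "detection_range",
    "brt",
    "heatwave_stats",
    "whaling",
]


@dataclass
class RunConfig:
    """Configuration for a full pipeline run (demo scale by default)."""

    seed: int = 0
    sites: list[str] = field(default_factory=lambda: ["siteA", "siteB"])
    site_positions: dict = field(
        default_factory=lambda: {"siteA": (166.0, -44.5), "siteB": (167.5, -45.5)}
    )
    n_days: int = 30
    start_date: str = "2017-01-01"
    clip_duration_s: float = 120.0
    events_per_clip: int = 3
    snr_db: float = 12.0
    call_type: str = "dcall"
    song_threshold: float = SONG_THRESHOLD
    dcall_threshold: float = DCALL_THRESHOLD
    series_years: list[int] = field(default_factory=lambda: [2016, 2017, 2018])
    series_sites: list[str] = field(
        default_factory=lambda: ["s1", "s2", "s3", "s4", "s5"]
    )
    heatwave_year: int = 2017
    heatwave_anom_c: float = 3.0
    n_catches: int = 300
    n_boot: int = 25
    brt_max_trees: int = 1500
    grid_depth_m: float = 300.0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        unknown = set(raw) - set(cls.__dataclass_fields__)
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        cfg = cls(**raw)
        cfg.validate()
        return cfg

    def validate(self) -> None:
        if self.n_days < 1 or self.clip_duration_s <= 0:
            raise ValueError("n_days and clip_duration_s must be positive")
        if not 0 < self.song_threshold <= 1 or not 0 < self.dcall_threshold <= 1:
            raise ValueError("thresholds must be in (0, 1]")
        for s in self.sites:
            if s not in self.site_positions:
                raise ValueError(f"site {s} missing from site_positions")


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _write_json(path: Path, obj) -> None:
    path.write_text(json.dumps(obj, indent=2, sort_keys=True, default=str) + "\n")


class PipelineError(RuntimeError):
    def __init__(self, stage: str, message: str):
        super().__init__(f"stage {stage!r}: {message}")
        self.stage = stage


def run_pipeline(config: RunConfig, out_dir: str | Path) -> Path:
    """Run every stage, writing outputs and a reproducibility manifest.

    Returns the run directory. A stage failure raises
    :class:`PipelineError` naming the stage; outputs of completed stages
    are preserved.
    """
    config.validate()
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"config": asdict(config), "stages": {}}
    state: dict = {}

    for stage in STAGES:
        t0 = time.time()
        stage_dir = out / stage
        stage_dir.mkdir(exist_ok=True)
        try:
            outputs = _STAGE_FUNCS[stage](config, stage_dir, state)
        except PipelineError:
            raise
        except Exception as exc:  # noqa: BLE001 - halt with stage context
            _write_json(out / "manifest.json", manifest)
            raise PipelineError(stage, str(exc)) from exc
        manifest["stages"][stage] = {
            "elapsed_s": round(time.time() - t0, 3),
            "outputs": {str(p.relative_to(out)): _sha256(p) for p in sorted(outputs)},
        }
    _write_json(out / "manifest.json", manifest)
    return out


# ---------------------------------------------------------------------------
# stages
# ---------------------------------------------------------------------------


def _stage_synth(cfg: RunConfig, d: Path, state: dict) -> list[Path]:
    rng = np.random.default_rng(cfg.seed)
    outputs = []
    dates = pd.date_range(cfg.start_date, periods=cfg.n_days, freq="D")
    clips = {}
    truths = {}
    for site in cfg.sites:
        for date in dates:
            n_ev = cfg.events_per_clip
            dur = cfg.clip_duration_s
            times = np.sort(
                rng.choice(np.arange(10, int(dur) - 15, 5), size=n_ev, replace=False)
            ).astype(float)
            clip, anns = synth_clip(
                dur,
                cfg.call_type,
                times,
                snr_db=cfg.snr_db,
                seed=int(rng.integers(2**31 - 1)),
                site_id=site,
            )
            tag = f"{site}_{date.strftime('%Y%m%d')}"
            wav = d / f"{tag}.wav"
            tsv = d / f"{tag}_truth.txt"
            bcio.write_wav(wav, clip)
            bcio.write_selection_table(tsv, anns)
            outputs += [wav, tsv]
            clips[tag] = (site, date, clip)
            truths[tag] = anns

    env = synth_env(
        pd.date_range(f"{min(cfg.series_years)}-01-01", f"{max(cfg.series_years)}-12-31"),
        GridSpec(),
        heatwave_windows=[
            (f"{cfg.heatwave_year}-01-01", f"{cfg.heatwave_year}-03-01", cfg.heatwave_anom_c)
        ],
        seed=cfg.seed + 1,
    )
    env_csv = d / "env.csv"
    bcio.write_env_csv(env_csv, env.data)
    outputs.append(env_csv)

    series_frames = []
    for i, site in enumerate(cfg.series_sites):
        pos = (166.0 + 0.3 * i, -45.5 + 0.3 * i)
        env_site = extract_env_series(env, pos, radius_km=40.0)
        _, series = synth_call_series(
            env_site, seed=cfg.seed + 10 + i, site_id=site
        )
        series_frames.append(series)
    series = pd.concat(series_frames, ignore_index=True)
    series_csv = d / "call_series.csv"
    series.to_csv(series_csv, index=False, float_format="%.6f")
    outputs.append(series_csv)

    catches = synth_catches(cfg.n_catches, seed=cfg.seed + 2)
    catches_csv = d / "catches.csv"
    bcio.write_catches_csv(catches_csv, catches)
    outputs.append(catches_csv)

    state.update(clips=clips, truths=truths, env=env, series=series, catches=catches)
    return outputs


def _stage_detect(cfg: RunConfig, d: Path, state: dict) -> list[Path]:
    bank = make_template_bank(cfg.call_type, seed=cfg.seed + 100)
    threshold = cfg.song_threshold if cfg.call_type == "song" else cfg.dcall_threshold
    outputs = []
    detections = {}
    for tag, (site, date, clip) in state["clips"].items():
        spec = detector_spectrogram(clip, cfg.call_type)
        dets = detect_calls(spec, bank, threshold=threshold)
        tsv = d / f"{tag}_detections.txt"
        bcio.write_selection_table(tsv, dets, extra_scores=True)
        outputs.append(tsv)
        detections[tag] = dets
        state.setdefault("specs", {})[tag] = spec
    state["detections"] = detections
    return outputs


def _stage_evaluate(cfg: RunConfig, d: Path, state: dict) -> list[Path]:
    tp = fp = fn = 0
    per_clip = []
    hours = 0.0
    for tag, dets in state["detections"].items():
        mr = match_detections(dets, state["truths"][tag])
        tp += mr.tp
        fp += mr.fp
        fn += mr.fn
        hours += cfg.clip_duration_s / 3600.0
        per_clip.append({"clip": tag, "tp": mr.tp, "fp": mr.fp, "fn": mr.fn})
    pooled = {
        "precision": tp / (tp + fp) if tp + fp else None,
        "recall": tp / (tp + fn) if tp + fn else None,
        "false_alarm_rate_per_h": fp / hours,
        "recording_hours": hours,
        "tp": tp,
        "fp": fp,
        "fn": fn,
    }
    metrics_json = d / "detector_metrics.json"
    _write_json(metrics_json, pooled)
    audit_csv = d / "per_clip_matches.csv"
    pd.DataFrame(per_clip).to_csv(audit_csv, index=False)
    state["detector_metrics"] = pooled
    return [metrics_json, audit_csv]


def _stage_classify(cfg: RunConfig, d: Path, state: dict) -> list[Path]:
    # features for true calls from matched detections; false-positive
    # exemplars from noise-only boxes at matched sizes
    rows = []
    rng = np.random.default_rng(cfg.seed + 200)
    for tag, dets in state["detections"].items():
        spec = state["specs"][tag]
        mr = match_detections(dets, state["truths"][tag])
        for det, _ in mr.true_positives:
            rows.append({**extract_features(spec, det), "label": 1})
        # noise boxes mimic false positives: same box geometry, random time
        for det, _ in mr.true_positives:
            t0 = float(rng.uniform(0, cfg.clip_duration_s - (det.end_s - det.start_s) - 1))
            truth_times = [(a.start_s, a.end_s) for a in state["truths"][tag]]
            if any(t0 < e and t0 + (det.end_s - det.start_s) > s for s, e in truth_times):
                continue
            fake = Detection(
                start_s=t0,
                end_s=t0 + (det.end_s - det.start_s),
                low_hz=det.low_hz,
                high_hz=det.high_hz,
                score=0.0,
                call_type=det.call_type,
            )
            rows.append({**extract_features(spec, fake), "label": 0})
    feats = pd.DataFrame(rows)
    feats_csv = d / "features.csv"
    feats.to_csv(feats_csv, index=False, float_format="%.6f")
    report = bootstrap_evaluate(
        feats.drop(columns="label"),
        feats["label"].to_numpy(),
        n_boot=cfg.n_boot,
        seed=cfg.seed + 201,
    )
    report_json = d / "classifier_report.json"
    _write_json(report_json, {"means": report.means, "sds": report.sds, "n_boot": report.n_boot})
    state["classifier_report"] = report
    return [feats_csv, report_json]


def _stage_call_metrics(cfg: RunConfig, d: Path, state: dict) -> list[Path]:
    summaries = []
    for tag, (site, date, clip) in state["clips"].items():
        spec = compute_spectrogram(clip, window_samples=3000)
        sii = song_intensity_index(spec)
        dets = state["detections"][tag]
        dcalls = dets if cfg.call_type == "dcall" else []
        songs = dets if cfg.call_type == "song" else []
        summaries.append(daily_summary(site, date, dcalls, songs, sii))
    df = summaries_frame(summaries)
    summaries_csv = d / "daily_summaries.csv"
    df.to_csv(summaries_csv, index=False, float_format="%.6f")
    cycle = annual_cycle(df, "dcall_count")
    cycle_csv = d / "annual_cycle_dcall.csv"
    cycle.to_csv(cycle_csv, index=False, float_format="%.6f")
    state["summaries"] = df
    return [summaries_csv, cycle_csv]


def _stage_detection_range(cfg: RunConfig, d: Path, state: dict) -> list[Path]:
    params = DCALL_PROPAGATION if cfg.call_type == "dcall" else SONG_PROPAGATION
    rows = []
    for tag, (site, date, clip) in state["clips"].items():
        spec = state["specs"][tag]
        noise = band_noise_percentile(spec, params.band, site_id=site)
        grid = make_grid(*cfg.site_positions[site], depth_m=cfg.grid_depth_m)
        est = detection_area(
            cfg.site_positions[site], params, noise, grid,
            tl_model="spherical", call_type=cfg.call_type, date=date,
        )
        rows.append(
            {
                "site_id": site,
                "date": date,
                "call_type": cfg.call_type,
                "noise_db": noise.level_db,
                "area_km2": est.area_km2,
                "cell_count": est.cell_count,
            }
        )
    areas_csv = d / "detection_areas.csv"
    pd.DataFrame(rows).to_csv(areas_csv, index=False, float_format="%.4f")
    state["areas"] = pd.DataFrame(rows)
    return [areas_csv]


def _stage_brt(cfg: RunConfig, d: Path, state: dict) -> list[Path]:
    env = state["env"]
    series = state["series"]
    frames = []
    for i, site in enumerate(cfg.series_sites[:2]):  # demo: two sites
        pos = (166.0 + 0.3 * i, -45.5 + 0.3 * i)
        env_site = extract_env_series(env, pos, radius_km=40.0)
        sub = series[series["site_id"] == site].merge(env_site, on="date")
        frames.append(sub)
    data = pd.concat(frames, ignore_index=True)
    data["detection_area_km2"] = float(state["areas"]["area_km2"].mean())
    predictors = ["log_npp", "sst", "sst_anom", "month", "detection_area_km2"]
    outputs = []
    results = {}
    for response, kind in (("dcall_count", "poisson"), ("song_intensity_index", "gaussian")):
        ydata = data.copy()
        if kind == "poisson":
            ydata[response] = ydata[response].round().astype(int)
        fit = fit_brt(
            ydata, response, predictors, response_kind=kind,
            max_trees=cfg.brt_max_trees, seed=cfg.seed + 300,
        )
        pdp = partial_dependence(fit, "log_npp")
        pdp_csv = d / f"pdp_log_npp_{response}.csv"
        pdp.to_csv(pdp_csv, index=False, float_format="%.6f")
        outputs.append(pdp_csv)
        results[response] = {
            "response_kind": kind,
            "n_trees": fit.n_trees,
            "cv_dev": fit.cv_dev,
            "cv_cor": fit.cv_cor,
            "relative_influence": fit.relative_influence.round(4).to_dict(),
        }
    brt_json = d / "brt_fits.json"
    _write_json(brt_json, results)
    outputs.append(brt_json)
    state["brt_results"] = results
    return outputs


def _stage_heatwave_stats(cfg: RunConfig, d: Path, state: dict) -> list[Path]:
    series = state["series"].copy()
    env = state["env"]
    env_means = []
    for i, site in enumerate(cfg.series_sites):
        pos = (166.0 + 0.3 * i, -45.5 + 0.3 * i)
        es = extract_env_series(env, pos, radius_km=40.0)
        es["site_id"] = site
        env_means.append(es)
    envd = pd.concat(env_means, ignore_index=True)
    panel = series.merge(envd, on=["date", "site_id"])
    panel = summer_subset(panel, cfg.series_years)

    results = {}
    contrasts_rows = []
    for response in ("sst", "log_npp", "dcall_count"):
        fit = fit_year_lmm(panel, response)
        contrasts = tukey_pairwise_labeled(fit, str(min(cfg.series_years)))
        results[response] = {
            "chi_square": fit.chi_square,
            "p_value": fit.p_value,
            "random_intercept_sd": fit.random_intercept_sd,
        }
        for c in contrasts:
            contrasts_rows.append(
                {
                    "response": response,
                    "pair": "-".join(c.pair),
                    "estimate": c.estimate,
                    "adjusted_p": c.adjusted_p,
                }
            )

    # summer D-call mean vs subsequent fall song intensity per site-year
    dates = pd.DatetimeIndex(series["date"])
    series["year"] = dates.year
    summer_mask = (dates.month == 1) | ((dates.month == 2) & (dates.day <= 28))
    fall_mask = dates.month.isin([4, 5, 6])
    pairs = (
        series[summer_mask]
        .groupby(["site_id", "year"])["dcall_count"]
        .mean()
        .rename("summer_dcall_mean")
        .reset_index()
        .merge(
            series[fall_mask]
            .groupby(["site_id", "year"])["song_intensity_index"]
            .mean()
            .rename("fall_sii_mean")
            .reset_index(),
            on=["site_id", "year"],
        )
    )
    frl = foraging_reproduction_lmm(pairs)
    results["foraging_song"] = {
        "slope": frl.slope,
        "chi_square": frl.chi_square,
        "p_value": frl.p_value,
    }
    stats_json = d / "mixed_models.json"
    _write_json(stats_json, results)
    contrasts_csv = d / "tukey_contrasts.csv"
    pd.DataFrame(contrasts_rows).to_csv(contrasts_csv, index=False, float_format="%.6f")
    state["mixed_results"] = results
    return [stats_json, contrasts_csv]


def _stage_whaling(cfg: RunConfig, d: Path, state: dict) -> list[Path]:
    assigned = assign_all(state["catches"])
    audit_csv = d / "assignment_audit.csv"
    pd.DataFrame(
        [
            {
                "date": a.record.date,
                "lat": a.record.lat,
                "lon": a.record.lon,
                "body_length_m": a.record.body_length_m,
                "subspecies": a.subspecies,
                "rule": a.rule,
            }
            for a in assigned
        ]
    ).to_csv(audit_csv, index=False, float_format="%.4f")
    nz = filter_region(assigned)
    curve = fetal_curve(nz)
    est = infer_birth_conception(curve)
    curve_csv = d / "fetal_curve.csv"
    pd.DataFrame({"doy": curve.doy, "fetal_length_cm": curve.length_cm}).to_csv(
        curve_csv, index=False, float_format="%.4f"
    )
    phen_json = d / "phenology.json"
    _write_json(
        phen_json,
        {
            "birth_doy": est.birth_doy,
            "birth_window": est.birth_window,
            "conception_doy": est.conception_doy,
            "conception_window": est.conception_window,
            "n_records": curve.n_records,
        },
    )
    state["phenology"] = est
    return [audit_csv, curve_csv, phen_json]


_STAGE_FUNCS = {
    "synth": _stage_synth,
    "detect": _stage_detect,
    "evaluate": _stage_evaluate,
    "classify": _stage_classify,
    "call_metrics": _stage_call_metrics,
    "detection_range": _stage_detection_range,
    "brt": _stage_brt,
    "heatwave_stats": _stage_heatwave_stats,
    "whaling": _stage_whaling,
}
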