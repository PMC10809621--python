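"""End-to-end orchestration: raw recordings to cross-validated predictions.

``run_full`` executes segmentation → feature extraction → aggregation →
outcome imputation → association screening → the prediction grid for each
dataset variant (uncentered and individually centered), writing CSV/JSON
artifacts and a manifest with row counts per stage. ``demo`` generates a
synthetic cohort with planted HRV–cognition coupling and runs the full
pipeline on it.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import aggregation as agg
from . import association as assoc
from . import prediction as pred
from .features import FEATURE_REGISTRY, extract_all
from .io_e4 import (
    CHANNEL_FILES,
    COMPOSITES,
    Channel,
    read_assessments,
    read_channel,
    read_ibi,
    read_subjects,
)
from .outcomes import GompertzShape, center_features, center_outcomes, impute_series
from .segmentation import (
    SEGMENT_SECONDS,
    QCThresholds,
    fill_small_gaps,
    restrict_ibi,
    segment_day,
)

__all__ = ["PipelineConfig", "run_full", "demo"]

log = logging.getLogger("wearcog")


@dataclass
class PipelineConfig:
    data_dir: str
    out_dir: str
    utc_offset: float = 0.0
    thresholds: QCThresholds = field(default_factory=QCThresholds)
    candidate_span: tuple[int, int] = (21 * 3600, 9 * 3600)
    window_duration_s: int = 5 * 3600
    min_daily_samples: int = 4
    interval_days: int = 10
    observation_days: int = 70
    imputation_method: str = "gompertz"
    gompertz_shape: GompertzShape = field(default_factory=GompertzShape)
    r2_prune: float = 0.95
    variants: tuple[str, ...] = ("uncentered", "centered")
    outcomes: tuple[str, ...] = COMPOSITES
    schemes: tuple[str, ...] = ("loso", "loio")
    selection_thresholds: tuple[float, ...] = pred.DEFAULT_THRESHOLDS
    algorithms: tuple[str, ...] = pred.ALGORITHMS
    feature_sets: tuple[str, ...] = ("combined", "physio")
    run_lmer: bool = True
    run_grid: bool = True
    seed: int = 0
    age_range: tuple[float, float] = (50.0, 70.0)

    def config_hash(self) -> str:
        """Hash of the analysis settings (filesystem locations excluded)."""
        payload = {k: str(v) for k, v in asdict(self).items()
                   if k not in ("data_dir", "out_dir")}
        blob = json.dumps(payload, sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


# ---------------------------------------------------------------------------
# stage 1: segmentation + feature extraction
# ---------------------------------------------------------------------------

def _session_dirs(data_dir: Path) -> list[tuple[str, Path]]:
    out = []
    for subj_dir in sorted(p for p in data_dir.iterdir() if p.is_dir()):
        for sess in sorted(p for p in subj_dir.iterdir() if p.is_dir()):
            if any((sess / f).exists() for f in CHANNEL_FILES.values()):
                out.append((subj_dir.name, sess))
    return out


def extract_features(cfg: PipelineConfig) -> pd.DataFrame:
    """Segment every session and compute the per-window feature catalogue."""
    data_dir = Path(cfg.data_dir)
    fvs = []
    for sid, sess in _session_dirs(data_dir):
        recs = {}
        for ch, fname in CHANNEL_FILES.items():
            if ch is Channel.ACC:
                continue  # accelerometer-based analyses out of scope
            path = sess / fname
            if path.exists():
                recs[ch] = read_channel(path, ch)
        ibi_path = sess / "IBI.csv"
        ibi = read_ibi(ibi_path) if ibi_path.exists() else None

        # windows keyed (date, start_clock) across channels
        windows: dict[tuple[int, int], dict] = {}
        for ch, rec in recs.items():
            t_local = rec.start_time + cfg.utc_offset
            d0 = int(np.floor(t_local / 86_400))
            d1 = int(np.floor((t_local + rec.duration) / 86_400))
            for date in range(d0, d1 + 1):
                for seg in segment_day(rec, date, cfg.utc_offset, subject_id=sid):
                    seg = fill_small_gaps(seg, cfg.thresholds.max_gap_s)
                    windows.setdefault((date, seg.start_clock), {})[ch] = seg
        for (date, clock), segs in sorted(windows.items()):
            ibi_seg = None
            if ibi is not None:
                ibi_seg = restrict_ibi(ibi, date * 86_400.0 + clock, cfg.utc_offset)
            fvs.append(extract_all(segs, ibi_seg, cfg.thresholds,
                                   utc_offset=cfg.utc_offset))
    table = agg.feature_table(fvs)
    log.info("extracted %d 5-min feature rows", len(table))
    return table


# ---------------------------------------------------------------------------
# stage 2: aggregation to the interval dataset
# ---------------------------------------------------------------------------

def build_interval_dataset(cfg: PipelineConfig, rows: pd.DataFrame) -> dict:
    """IBI filter, night window, daily medians, interval means, pruning."""
    window = agg.select_night_window(
        rows.dropna(subset=["HRMean"]) if "HRMean" in rows else rows,
        cfg.candidate_span, cfg.window_duration_s,
    )
    kept_rows = agg.require_ibi(rows)
    daily = agg.daily_aggregate(kept_rows, window, cfg.min_daily_samples)
    intervals = agg.interval_aggregate(daily, cfg.interval_days, cfg.observation_days)
    feature_cols = [n for n, _ in FEATURE_REGISTRY if n in intervals.columns]
    min_rows = min(3, max(len(intervals), 1))
    usable = [c for c in feature_cols if intervals[c].notna().sum() >= min_rows]
    if len(intervals) >= 3:
        kept, dropped = agg.drop_redundant_features(intervals[usable], cfg.r2_prune)
    else:  # too few rows to assess redundancy
        kept, dropped = usable, {}
    return {
        "window": window,
        "rows_after_ibi": len(kept_rows),
        "daily": daily,
        "intervals": intervals,
        "features_kept": kept,
        "features_dropped": dropped,
    }


# ---------------------------------------------------------------------------
# stage 3: outcomes + dataset variants
# ---------------------------------------------------------------------------

def attach_outcomes(cfg: PipelineConfig, intervals: pd.DataFrame,
                    feature_cols: list[str]) -> dict[str, pd.DataFrame]:
    """Join demographics and imputed composite scores; build both variants."""
    data_dir = Path(cfg.data_dir)
    subjects = read_subjects(data_dir / "subjects.csv", cfg.age_range).frame.copy()
    subjects["sex"] = subjects["sex"].map({"female": 1.0, "male": 0.0})
    pairs = {p.subject_id: p for p in read_assessments(data_dir / "assessments.csv")}
    n_int = cfg.observation_days // cfg.interval_days

    base = intervals.merge(subjects, on="subject_id", how="inner")
    out: dict[str, pd.DataFrame] = {}
    for variant in cfg.variants:
        df = base.copy()
        for comp in COMPOSITES:
            col = np.full(len(df), np.nan)
            for sid, p in pairs.items():
                series = impute_series(
                    p.baseline[comp], p.post[comp], n_int,
                    method=cfg.imputation_method, shape=cfg.gompertz_shape,
                    seed=cfg.seed, subject_id=sid, composite=comp,
                )
                if variant == "centered":
                    series = center_outcomes(series, p.baseline[comp], p.post[comp])
                mask = (df["subject_id"] == sid).to_numpy()
                idx = df.loc[mask, "interval"].to_numpy(dtype=int) - 1
                col[mask] = series.values[idx]
            df[comp] = col
        if variant == "centered":
            df = center_features(df, feature_cols)
        out[variant] = df.dropna(subset=list(COMPOSITES)).reset_index(drop=True)
    return out


# ---------------------------------------------------------------------------
# stages 4–5: association + prediction
# ---------------------------------------------------------------------------

def screen_associations(cfg: PipelineConfig, dataset: pd.DataFrame,
                        feature_cols: list[str]) -> dict[str, pd.DataFrame]:
    X = dataset[feature_cols]
    Y = dataset[list(cfg.outcomes)]
    table = assoc.correlation_screen(X, Y)
    sig = assoc.significant_pairs(table)
    out = {"correlations": table, "significant": sig}
    if cfg.run_lmer:
        out["lmer"] = assoc.lmer_screen_all(X, Y, dataset["subject_id"].to_numpy())
    return out


def run_prediction(cfg: PipelineConfig, dataset: pd.DataFrame,
                   feature_cols: list[str], variant: str) -> dict:
    grids = {}
    for scheme in cfg.schemes:
        for outcome in cfg.outcomes:
            grids[(scheme, outcome)] = pred.model_grid(
                dataset, feature_cols, outcome, scheme=scheme,
                thresholds=cfg.selection_thresholds, variant=variant,
                seed=cfg.seed, algorithms=cfg.algorithms,
                feature_sets=cfg.feature_sets,
            )
    return {"grids": grids, "report": pred.report(grids)}


# ---------------------------------------------------------------------------
# orchestration
# ---------------------------------------------------------------------------

def run_full(cfg: PipelineConfig) -> dict:
    """Run every stage; write artifacts and a manifest under ``cfg.out_dir``."""
    out_dir = Path(cfg.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"config_hash": cfg.config_hash(), "stages": {}}

    rows = extract_features(cfg)
    manifest["stages"]["segments"] = len(rows)
    built = build_interval_dataset(cfg, rows)
    manifest["stages"]["rows_after_ibi"] = built["rows_after_ibi"]
    manifest["stages"]["daily_rows"] = len(built["daily"])
    manifest["stages"]["interval_rows"] = len(built["intervals"])
    manifest["night_window_start_clock"] = built["window"].start_clock
    manifest["features_kept"] = len(built["features_kept"])

    feature_cols = built["features_kept"]
    datasets = attach_outcomes(cfg, built["intervals"], feature_cols)
    results: dict = {"window": built["window"], "datasets": datasets,
                     "feature_cols": feature_cols, "associations": {},
                     "prediction": {}, "manifest": manifest}

    for variant, df in datasets.items():
        df.to_csv(out_dir / f"interval_dataset_{variant}.csv", index=False)
        manifest["stages"][f"dataset_rows_{variant}"] = len(df)
        scr = screen_associations(cfg, df, feature_cols)
        scr["correlations"].to_csv(out_dir / f"associations_{variant}.csv", index=False)
        results["associations"][variant] = scr
        if cfg.run_grid:
            pr = run_prediction(cfg, df, feature_cols, variant)
            pr["report"]["best"].to_csv(out_dir / f"results_{variant}.csv", index=False)
            results["prediction"][variant] = pr

    with open(out_dir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return results


def demo(
    seed: int = 0,
    out_dir: str | Path | None = None,
    n_subjects: int = 17,
    observation_days: int = 70,
    coupling_slope: float = 12.0,
    outcomes: tuple[str, ...] = ("executive_function",),
    run_lmer: bool = False,
    algorithms: tuple[str, ...] = pred.ALGORITHMS,
    feature_sets: tuple[str, ...] = ("combined",),
    variants: tuple[str, ...] = ("uncentered", "centered"),
    wear_nights_per_interval: int = 2,
    **sim_kwargs,
) -> dict:
    """Generate a synthetic cohort with planted HF-power coupling to the
    executive-function score and run the full pipeline on it."""
    import tempfile

    from .synthetic import SimulationConfig, generate_cohort

    if out_dir is None:
        out_dir = tempfile.mkdtemp(prefix="wearcog_demo_")
    out_dir = Path(out_dir)
    sim = SimulationConfig(
        n_subjects=n_subjects,
        observation_days=observation_days,
        wear_nights_per_interval=wear_nights_per_interval,
        coupling=[("hf_amp_ms", coupling_slope)],
        seed=seed,
        **sim_kwargs,
    )
    data_dir, truths = generate_cohort(sim, out_dir / "data")
    cfg = PipelineConfig(
        data_dir=str(data_dir),
        out_dir=str(out_dir / "run"),
        observation_days=observation_days,
        outcomes=outcomes,
        run_lmer=run_lmer,
        algorithms=algorithms,
        feature_sets=feature_sets,
        variants=variants,
        seed=seed,
    )
    results = run_full(cfg)
    results["truths"] = truths
    results["sim_config"] = sim
    return results
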