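"""End-to-end pipeline: prefilter -> fit -> QC -> land-correct -> summarise.

All stages are driven by one :class:`PipelineConfig`; every output sidecar
records the global seed and a hash of the configuration so identical
(config, seed) pairs reproduce outputs exactly.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import io as dio
from .model import (
    ArgosErrorModel,
    McmcConfig,
    TrackTooShortError,
    run_mcmc,
    summarize_posterior,
)
from .prefilter import prefilter
from .landcorrect import correct_track, is_on_land
from .qc import derive_track_metrics, flag_tracks, regression_table
from .summaries import (
    BehaviorThresholds,
    aggregate_tracks,
    classify_track_locations,
    daily_steps,
    per_track_summary,
    seasonal_mode_proportions,
)

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Everything the pipeline needs, in one place."""

    fixes_csv: str = ""
    landmask_geojson: str = ""
    output_dir: str = "dcrws_output"
    mcmc: McmcConfig = field(default_factory=McmcConfig)
    error_model: ArgosErrorModel = field(default_factory=ArgosErrorModel)
    thresholds: BehaviorThresholds = field(default_factory=BehaviorThresholds)
    min_total_locs: int = 10
    seed: int = 0

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def config_hash(self) -> str:
        """Hash of the analytic configuration (file paths excluded)."""
        payload = {
            k: v
            for k, v in self.to_dict().items()
            if k not in ("fixes_csv", "landmask_geojson", "output_dir")
        }
        blob = json.dumps(payload, sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


def load_config(path: str | Path) -> PipelineConfig:
    """Load a pipeline config from YAML; absent keys keep their defaults."""
    raw = yaml.safe_load(Path(path).read_text()) or {}
    kwargs: dict = {}
    for key in ("fixes_csv", "landmask_geojson", "output_dir", "min_total_locs", "seed"):
        if key in raw:
            kwargs[key] = raw[key]
    if "mcmc" in raw:
        kwargs["mcmc"] = McmcConfig(**raw["mcmc"])
    if "error_model" in raw:
        kwargs["error_model"] = ArgosErrorModel(**raw["error_model"])
    if "thresholds" in raw:
        kwargs["thresholds"] = BehaviorThresholds(**raw["thresholds"])
    return PipelineConfig(**kwargs)


def default_config_yaml() -> str:
    """All defaults as a YAML document (the `show-config` payload)."""
    return yaml.safe_dump(PipelineConfig().to_dict(), sort_keys=True)


@dataclass
class PipelineResult:
    """In-memory products of one pipeline run."""

    filtered_fixes: pd.DataFrame
    tracks: dict  # ptt -> corrected daily-track DataFrame
    qc_metrics: dict  # ptt -> TrackQcMetrics
    deviances: dict  # ptt -> deviance
    excluded: dict  # ptt -> reason
    regression: pd.DataFrame | None
    track_summaries: pd.DataFrame
    cohort_mean: pd.Series | None
    seasonal: pd.DataFrame
    output_dir: Path


def _track_seed(global_seed: int, index: int) -> int:
    return (global_seed * 100_003 + 7 * index + 1) % (2**31)


def run_pipeline(config: PipelineConfig) -> PipelineResult:
    """Run every stage for every platform and write the output bundle.

    Per-track failures (too-short span, QC exclusion) remove that track
    from the cohort products with a logged reason; they never abort the
    run.  Identical (config, seed) pairs give identical outputs.
    """
    out_dir = Path(config.output_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    stamp = {"seed": config.seed, "config_hash": config.config_hash()}

    fixes = dio.read_fixes(config.fixes_csv)
    landmask = dio.read_landmask(config.landmask_geojson)
    filtered = prefilter(fixes)
    dio.write_fixes(filtered, out_dir / "fixes_filtered.csv")

    tracks: dict = {}
    metrics: dict = {}
    deviances: dict = {}
    summaries: dict = {}
    excluded: dict = {}
    classified_frames = []

    ptts = sorted(filtered["ptt"].astype(str).unique())
    for idx, ptt in enumerate(ptts):
        sub = filtered[filtered["ptt"].astype(str) == ptt]
        mcmc_cfg = dataclasses.replace(config.mcmc, seed=_track_seed(config.seed, idx))
        try:
            samples = run_mcmc(sub, config.error_model, mcmc_cfg)
        except TrackTooShortError as exc:
            excluded[ptt] = f"unmodelable: {exc}"
            logger.warning("track %s excluded: %s", ptt, exc)
            continue
        post = summarize_posterior(samples, ptt=ptt)
        metrics[ptt] = derive_track_metrics(sub, post.df, ptt=ptt)
        deviances[ptt] = post.deviance
        corrected = correct_track(post.df, landmask)
        tracks[ptt] = corrected
        dio.write_track(corrected, out_dir / f"track_{ptt}.csv")
        dio.write_json(
            {
                **stamp,
                "ptt": ptt,
                "deviance": post.deviance,
                "dic": post.dic,
                "params": post.param_summary,
                "mcmc_seed": mcmc_cfg.seed,
                "n_corrected": int(corrected["corrected"].sum()),
            },
            out_dir / f"track_{ptt}.json",
        )

    decisions = flag_tracks(list(metrics.values()), config.min_total_locs)
    for ptt, (keep, reason) in decisions.items():
        if not keep:
            excluded[ptt] = reason
            tracks.pop(ptt, None)

    regression = (
        regression_table(list(metrics.values()), deviances) if len(metrics) >= 3 else None
    )

    for ptt, corrected in tracks.items():
        steps = daily_steps(corrected, config.thresholds)
        summaries[ptt] = per_track_summary(steps, ptt=ptt)
        classified_frames.append(
            classify_track_locations(corrected, config.thresholds).assign(ptt=ptt)
        )

    track_rows = (
        pd.DataFrame(summaries).T if summaries else pd.DataFrame()
    )
    cohort_mean = aggregate_tracks(track_rows) if len(track_rows) else None
    classified = (
        pd.concat(classified_frames, ignore_index=True)
        if classified_frames
        else pd.DataFrame(columns=["label", "season"])
    )
    seasonal = (
        seasonal_mode_proportions(classified) if len(classified) else pd.DataFrame()
    )

    # residual on-land check: the land correction guarantees ocean output
    for ptt, corrected in tracks.items():
        for _, row in corrected.iterrows():
            assert not is_on_land(row["lon"], row["lat"], landmask), (ptt, row["date"])

    if regression is not None:
        regression.to_csv(out_dir / "regression_table.csv", index=False)
    if len(track_rows):
        track_rows.rename_axis("ptt").to_csv(out_dir / "track_summaries.csv")
    if cohort_mean is not None:
        cohort_mean.rename("cohort_mean").to_csv(out_dir / "cohort_mean.csv")
    if len(seasonal):
        seasonal.to_csv(out_dir / "seasonal_proportions.csv", index=False)
    if len(classified):
        _write_classified_geojson(classified, out_dir / "classified_locations.geojson")
    dio.write_json(
        {
            **stamp,
            "qc_metrics": {p: m.as_dict() for p, m in metrics.items()},
            "deviances": deviances,
            "excluded": excluded,
        },
        out_dir / "qc_report.json",
    )

    return PipelineResult(
        filtered_fixes=filtered,
        tracks=tracks,
        qc_metrics=metrics,
        deviances=deviances,
        excluded=excluded,
        regression=regression,
        track_summaries=track_rows,
        cohort_mean=cohort_mean,
        seasonal=seasonal,
        output_dir=out_dir,
    )


def _write_classified_geojson(classified: pd.DataFrame, path: Path) -> None:
    features = [
        {
            "type": "Feature",
            "properties": {
                "ptt": str(row.get("ptt", "")),
                "date": pd.Timestamp(row["date"]).strftime("%Y-%m-%d"),
                "label": row["label"],
                "season": row["season"],
            },
            "geometry": {
                "type": "Point",
                "coordinates": [float(row["lon"]), float(row["lat"])],
            },
        }
        for _, row in classified.iterrows()
    ]
    Path(path).write_text(
        json.dumps({"type": "FeatureCollection", "features": features}, sort_keys=True)
    )
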