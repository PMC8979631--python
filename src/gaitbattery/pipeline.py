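"""End-to-end orchestration: simulate -> extract -> classify -> report.

All tabular outputs are flat CSVs; the run configuration is echoed into
every output directory for reproducibility.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .evaluation import (
    MODEL_SUBSETS,
    battery_frame,
    fit_overall_model,
    group_compare,
    run_battery,
)
from .features import registry
from .features.complexity import complexity_vector
from .features.frequency import spectral_vector
from .features.magnitude import magnitude_vector
from .features.regularity import regularity_vector
from .features.spatiotemporal import spatiotemporal_vector
from .plsda import DEFAULT_CV_SEED, DEFAULT_K_FOLDS, save_model
from .segmentation import preprocess
from .synthetic import Cohort, CohortConfig, generate_cohort
from .types import DEMOGRAPHIC_COLUMNS, GaitError

logger = logging.getLogger(__name__)

MAX_SKIP_FRACTION = 0.10

DOMAIN_EXTRACTORS = {
    "spatiotemporal": None,  # needs sensor height; handled specially
    "frequency": spectral_vector,
    "regularity": regularity_vector,
    "magnitude": magnitude_vector,
    "complexity": complexity_vector,
}


@dataclass
class RunConfig:
    """Run settings; every field is echoed verbatim to the outputs."""

    out_dir: str
    seed: int = 0
    n_pd: int = 81
    n_cl: int = 61
    duration: float = 120.0
    fs: float = 100.0
    effect_scale: float = 1.0
    domains: tuple = tuple(registry.DOMAINS)
    subsets: tuple = tuple(MODEL_SUBSETS)
    a_max: int = 10
    k_folds: int = DEFAULT_K_FOLDS
    cv_seed: int = DEFAULT_CV_SEED
    mode: str = "cv"

    REQUIRED = ("out_dir",)

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        data.update({k: v for k, v in overrides.items() if v is not None})
        for key in cls.REQUIRED:
            if key not in data:
                raise GaitError(f"missing config key: {key!r}")
        known = set(cls.__dataclass_fields__)
        unknown = set(data) - known
        if unknown:
            raise GaitError(f"unknown config keys: {sorted(unknown)}")
        for tup in ("domains", "subsets"):
            if tup in data and data[tup] is not None:
                data[tup] = tuple(data[tup])
        return cls(**data)

    def echo(self, out_dir: str | Path) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        with open(out / "run_config.yaml", "w") as fh:
            yaml.safe_dump({k: (list(v) if isinstance(v, tuple) else v)
                            for k, v in asdict(self).items()}, fh)


def _subject_iter(cohort):
    if isinstance(cohort, Cohort):
        for s in cohort.subjects:
            yield {"subject_id": s.recording.subject_id,
                   "group": s.params.group, "recording": s.recording,
                   "events": s.events, "demographics": s.demographics,
                   "sensor_height": s.params.sensor_height}
    else:
        yield from cohort


def extract_subject(recording, events, sensor_height: float,
                    domains=registry.DOMAINS) -> dict[str, float]:
    """The full 210-characteristic vector for one subject (preprocesses
    internally); restrict `domains` to compute a subset (others NaN)."""
    rec = preprocess(recording)
    out: dict[str, float] = {}
    if "spatiotemporal" in domains:
        out.update(spatiotemporal_vector(rec, events, sensor_height))
    for name, fn in DOMAIN_EXTRACTORS.items():
        if fn is not None and name in domains:
            out.update(fn(rec, events))
    full = {name: out.get(name, np.nan) for name in registry.FEATURE_NAMES}
    return full


def extract_features(cohort, domains=registry.DOMAINS) -> pd.DataFrame:
    """One row per subject: subject_id, group, then the 210 gait feature
    columns in registry order.  Unreadable subjects are skipped with a
    logged reason; the run fails if more than 10 % are skipped.
    """
    rows, skipped = [], []
    subjects = list(_subject_iter(cohort))
    for sub in subjects:
        try:
            feats = extract_subject(sub["recording"], sub["events"],
                                    sub["sensor_height"], domains=domains)
        except GaitError as exc:
            logger.warning("subject %s skipped: %s", sub["subject_id"], exc)
            skipped.append(sub["subject_id"])
            continue
        row = {"subject_id": sub["subject_id"], "group": sub["group"]}
        row.update(feats)
        rows.append(row)
    if len(skipped) > MAX_SKIP_FRACTION * len(subjects):
        raise GaitError(
            f"{len(skipped)}/{len(subjects)} subjects unreadable "
            f"(> {MAX_SKIP_FRACTION:.0%}): {skipped[:5]}")
    return pd.DataFrame(rows, columns=["subject_id", "group",
                                       *registry.FEATURE_NAMES])


def demographics_design(demo_frame: pd.DataFrame) -> pd.DataFrame:
    """Numeric demographic block (age, sex 0/1, height, weight, bmi,
    moca) aligned to a cohort demographics table."""
    out = pd.DataFrame({
        "age": demo_frame["age"].astype(float),
        "sex": (demo_frame["sex"] == "M").astype(float),
        "height": demo_frame.get("height_m", demo_frame.get("height")),
        "weight": demo_frame.get("weight_kg", demo_frame.get("weight")),
        "bmi": demo_frame["bmi"].astype(float),
        "moca": demo_frame["moca"].astype(float),
    })
    return out[list(DEMOGRAPHIC_COLUMNS)].astype(float)


def classify(features: pd.DataFrame, demographics: pd.DataFrame,
             config: RunConfig, out_dir: Path | None = None) -> dict:
    """Battery + VIP + group statistics; optionally write reports/."""
    labels = features["group"].to_numpy()
    gait = features[list(registry.FEATURE_NAMES)]
    dem = demographics_design(demographics)
    reports = run_battery(gait, dem, labels, subsets=config.subsets,
                          k_folds=config.k_folds, seed=config.cv_seed,
                          a_max=config.a_max, mode=config.mode)
    overall_subset = ("all_gait_dem" if "all_gait_dem" in config.subsets
                      else list(config.subsets)[-1])
    model, vip = fit_overall_model(gait, dem, labels, subset=overall_subset,
                                   k_folds=config.k_folds,
                                   seed=config.cv_seed, a_max=config.a_max)
    influential = vip.loc[vip["vip_average"] > 1.0, "feature"]
    stats = group_compare(gait, labels)
    corr = gait[influential[influential.isin(gait.columns)]].corr()

    if out_dir is not None:
        rep = Path(out_dir) / "reports"
        rep.mkdir(parents=True, exist_ok=True)
        battery_frame(reports).to_csv(rep / "battery.csv", index=False)
        vip.to_csv(rep / "vip.csv", index=False)
        stats.to_csv(rep / "group_stats.csv", index=False)
        corr.to_csv(rep / "vip_correlations.csv")
        for name, r in reports.items():
            r.roc_curve.to_csv(rep / f"roc_{name}.csv", index=False)
        save_model(model, rep / "overall_model")
    return {"reports": reports, "vip": vip, "group_stats": stats,
            "model": model, "correlations": corr}


def run_all(config: RunConfig) -> dict:
    """simulate -> extract -> classify -> report, with logging."""
    t0 = time.time()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    config.echo(out)
    logger.info("gaitbattery %s run starting (seed=%d)",
                __version__, config.seed)

    cohort_cfg = CohortConfig(n_pd=config.n_pd, n_cl=config.n_cl,
                              seed=config.seed, duration=config.duration,
                              fs=config.fs,
                              effect_scale=config.effect_scale)
    cohort = generate_cohort(cohort_cfg, out_dir=out / "cohort")
    logger.info("cohort written (%d subjects) at %.1fs",
                len(cohort.subjects), time.time() - t0)

    features = extract_features(cohort, domains=config.domains)
    features.to_csv(out / "features.csv", index=False)
    registry.registry_frame().to_csv(out / "feature_registry.csv",
                                     index=False)
    logger.info("features extracted at %.1fs", time.time() - t0)

    results = classify(features, cohort.demographics_frame, config,
                       out_dir=out)
    logger.info("battery complete at %.1fs", time.time() - t0)

    meta = {"version": __version__, "seed": config.seed,
            "elapsed_s": round(time.time() - t0, 1),
            "n_subjects": len(cohort.subjects)}
    with open(out / "run_log.json", "w") as fh:
        json.dump(meta, fh, indent=2)
    return results
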