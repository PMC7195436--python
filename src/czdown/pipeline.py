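"""End-to-end orchestration: simulate -> features -> rhythms/synchrony ->
forecast -> clusters, driven by one YAML-able config dict.

Every stage's output is written under the configured output directory and
stamped with the config hash; reruns with an identical config are
bit-identical because all randomness flows from the single top-level seed.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd

from . import clusters as clusters_mod
from . import forecaster, synthetic
from .features import FeatureSeries, compute_features
from .segments import SeizureCatalog


class StageError(RuntimeError):
    def __init__(self, stage: str, code: str, message: str):
        super().__init__(f"[{stage}:{code}] {message}")
        self.stage = stage
        self.code = code


DEFAULT_CONFIG = {
    "seed": 0,
    "out_dir": "czdown_out",
    "stages": ["simulate", "features", "forecast", "clusters"],
    "simulate": {"render": "features"},
    "forecast": {"methods": ["m1", "m2", "random"], "n_random": 100},
    "clusters": {"span_days": 4.0},
}


def config_hash(config: dict) -> str:
    return hashlib.sha256(json.dumps(config, sort_keys=True, default=str)
                          .encode()).hexdigest()[:12]


def _sim_config(config: dict) -> synthetic.SimulatorConfig:
    kwargs = {k: v for k, v in config.get("simulate", {}).items()
              if k not in ("render",)}
    kwargs.setdefault("seed", config.get("seed", 0))
    return synthetic.SimulatorConfig(**kwargs)


def run_pipeline(config: dict) -> dict:
    """Execute enabled stages in dependency order; return the report bundle."""
    cfg = {**DEFAULT_CONFIG, **config}
    cfg["simulate"] = {**DEFAULT_CONFIG["simulate"], **cfg.get("simulate", {})}
    cfg["forecast"] = {**DEFAULT_CONFIG["forecast"], **cfg.get("forecast", {})}
    cfg["clusters"] = {**DEFAULT_CONFIG["clusters"], **cfg.get("clusters", {})}
    out_dir = Path(cfg["out_dir"])
    out_dir.mkdir(parents=True, exist_ok=True)
    stamp = config_hash(cfg)
    bundle: dict = {"config_hash": stamp, "reports": {}}

    rec = None
    features: FeatureSeries | None = None
    catalog: SeizureCatalog | None = None

    if "simulate" in cfg["stages"]:
        try:
            sim_cfg = _sim_config(cfg)
            rec = synthetic.simulate_recording(sim_cfg,
                                               render=cfg["simulate"]["render"])
        except Exception as exc:   # noqa: BLE001 - stage boundary
            raise StageError("simulate", "SIM_FAIL", str(exc)) from exc
        catalog = rec.seizure_catalog
        catalog.to_csv(out_dir / "seizures.csv")
        if rec.segments is not None:
            rec.segments.to_hdf5(out_dir / "recording.h5")
        synthetic.write_ground_truth(rec, out_dir / "ground_truth.h5")
        bundle["n_seizures"] = len(catalog)

    if "features" in cfg["stages"]:
        try:
            if rec is not None and rec.features is not None:
                features = rec.features
            elif rec is not None and rec.segments is not None:
                features = compute_features(rec.segments)
            elif "features_csv" in cfg:
                features = FeatureSeries.from_csv(cfg["features_csv"])
            else:
                raise StageError("features", "NO_INPUT", "no segment or feature input")
        except StageError:
            raise
        except Exception as exc:   # noqa: BLE001
            raise StageError("features", "FEAT_FAIL", str(exc)) from exc
        features.to_csv(out_dir / "features.csv")

    if "forecast" in cfg["stages"]:
        if features is None or catalog is None:
            raise StageError("forecast", "NO_INPUT", "forecast needs features + seizures")
        fc_cfg = forecaster.ForecastConfig(seed=cfg["seed"])
        methods = cfg["forecast"]["methods"]
        try:
            if "m1" in methods:
                rep = forecaster.forecast_m1(features, catalog, fc_cfg)
                bundle["reports"]["m1"] = rep.to_dict()
            if "random" in methods:
                rnd = forecaster.forecast_random(
                    features, catalog, fc_cfg,
                    n_realizations=cfg["forecast"]["n_random"])
                bundle["reports"]["random"] = {
                    "method": "random",
                    "products": rnd["products"].tolist(),
                    "reference_product":
                        rnd["reference_report"].performance_product,
                    "degenerate": rnd["degenerate"],
                }
            if "m2" in methods:
                m2 = forecaster.forecast_m2(features, catalog, fc_cfg)
                bundle["reports"]["m2"] = m2.report.to_dict()
        except (forecaster.UntrainableError,
                forecaster.InsufficientHistoryError,
                forecaster.NoFeasibleSolutionError) as exc:
            raise StageError("forecast", "FC_FAIL", str(exc)) from exc
        for name, rep in bundle["reports"].items():
            with open(out_dir / f"forecast_{name}.json", "w") as fh:
                json.dump(rep, fh, indent=2)

    if "clusters" in cfg["stages"]:
        if features is None or catalog is None or len(catalog) < 2:
            bundle["reports"]["clusters"] = {"skipped": "needs features + >=2 seizures"}
        else:
            try:
                ca = clusters_mod.analyze_clusters(
                    features, channel=0, catalog=catalog,
                    span_days=cfg["clusters"]["span_days"])
            except Exception as exc:   # noqa: BLE001
                raise StageError("clusters", "CL_FAIL", str(exc)) from exc
            cl_report = {
                "has_clusters": bool(ca.has_clusters),
                "lead_time_s": float(ca.lead_time_s),
                "n_lead": int(ca.lead_mask.sum()),
                "notes": ca.notes,
            }
            bundle["reports"]["clusters"] = cl_report
            pd.DataFrame({
                "rel_time_h": ca.rel_time_s / 3600.0,
                "mean_acfw": ca.mean_acfw, "se_acfw": ca.se_acfw,
                "mean_var": ca.mean_var, "se_var": ca.se_var,
                "follower_density": ca.follower_density,
            }).to_csv(out_dir / "cluster_profiles.csv", index=False)
            with open(out_dir / "clusters.json", "w") as fh:
                json.dump(cl_report, fh, indent=2)

    with open(out_dir / "bundle.json", "w") as fh:
        json.dump(bundle, fh, indent=2, default=str)
    return bundle


def summarize(reports: list[dict]) -> pd.DataFrame:
    """Cross-run summary table of forecast reports."""
    if not reports:
        raise ValueError("no reports to summarize")
    rows = []
    for rep in reports:
        if "performance_product" not in rep:
            raise ValueError("schema mismatch: not a forecast report")
        rows.append({
            "method": rep.get("method", "?"),
            "sensitivity_high": rep["seizure_fractions"][2],
            "seizures_low": rep["seizure_fractions"][0],
            "time_low": rep["time_fractions"][0],
            "time_high": rep["time_fractions"][2],
            "performance_product": rep["performance_product"],
            "mean_risk": rep.get("mean_risk", np.nan),
        })
    return pd.DataFrame(rows)
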