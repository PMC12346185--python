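"""End-to-end pipeline orchestration and schema validation.

Stages run in the order the intervention is built: simulate (synthetic
cohort) -> profile (latent profiles + simplified tree) -> risk (CVD
probability harness) -> limits (per-profile intake ranges) -> advise
(two-level recommendations).  Each stage logs row counts in/out and the
run report records seeds, versions and per-stage counts so a fixed
config and seed reproduce byte-identical artifacts.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import cohort as cohort_mod
from . import limits as limits_mod
from . import profiles as profiles_mod
from . import recommend as recommend_mod
from . import risk as risk_mod

logger = logging.getLogger("nutriprofile")

ALL_STAGES = ("simulate", "profile", "risk", "limits", "advise")


def configure_logging(verbose: bool = False) -> None:
    level = logging.DEBUG if verbose else logging.INFO
    logging.basicConfig(level=level, format="%(name)s %(levelname)s %(message)s")
    logger.setLevel(level)


@dataclass
class PipelineConfig:
    seed: int = 83988
    n_participants: int = 2000
    out_dir: str = "pipeline_out"
    stages: tuple[str, ...] = ALL_STAGES
    threshold: float = recommend_mod.DEFAULT_THRESHOLD
    n_bins: int = 4
    censor_age: float = 68.0
    delta_r: float = 0.01
    predictor_set: str = "fpp"
    model_family: str = "lda"
    k_imputations: int = 5
    knn_k: int = 5
    extra: dict = field(default_factory=dict)

    @classmethod
    def from_yaml(cls, path: str) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        kwargs = {k: v for k, v in raw.items() if k in known}
        extra = {k: v for k, v in raw.items() if k not in known}
        cfg = cls(**kwargs)
        cfg.extra = extra
        if "stages" in kwargs:
            cfg.stages = tuple(kwargs["stages"])
        return cfg

    def validate(self) -> None:
        for s in self.stages:
            if s not in ALL_STAGES:
                raise ValueError(f"unknown stage '{s}'")
        if not 0 < self.threshold < 1:
            raise ValueError("threshold must be in (0, 1)")
        if self.n_bins < 2:
            raise ValueError("n_bins must be >= 2")
        if self.censor_age <= 0:
            raise ValueError("censor_age must be positive")
        if self.predictor_set not in risk_mod.PREDICTOR_SPECS:
            raise ValueError(f"unknown predictor set '{self.predictor_set}'")
        if self.model_family not in risk_mod.MODEL_FAMILIES:
            raise ValueError(f"unknown model family '{self.model_family}'")


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the enabled stages; returns the run report (also written to
    ``report.json`` in the output directory)."""
    config.validate()
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    report: dict = {"seed": config.seed, "stages": {},
                    "config": {k: v for k, v in dataclasses.asdict(config).items()
                               if k != "extra"}}

    cohort = None
    data = None
    if "simulate" in config.stages:
        cohort = cohort_mod.generate_cohort(
            cohort_mod.CohortConfig(n_participants=config.n_participants,
                                    seed=config.seed,
                                    censor_age=config.censor_age))
        data = cohort.data
        path = out_dir / "cohort.csv"
        cohort_mod.write_cohort(cohort, str(path))
        logger.info("simulate: generated %d participants -> %s", len(data), path)
        report["stages"]["simulate"] = {"rows_in": 0, "rows_out": len(data),
                                        "artifact": str(path)}

    needs_data = set(config.stages) & {"profile", "risk", "limits", "advise"}
    if needs_data and data is None:
        path = out_dir / "cohort.csv"
        if not path.exists():
            raise FileNotFoundError(
                f"stage dependency missing: cohort artifact '{path}' not found; "
                "run the simulate stage first")
        data = cohort_mod.read_cohort(str(path))

    if "profile" in config.stages:
        liking = data[cohort_mod.liking_columns()]
        tree = profiles_mod.canonical_tree()
        predicted = tree.classify_frame(
            liking.fillna(liking.mean()))
        data = data.copy()
        data["profile"] = predicted.values
        path = out_dir / "profiles.csv"
        predicted.to_frame().to_csv(path, index=False)
        tree_path = out_dir / "tree.json"
        tree_path.write_text(json.dumps(tree.to_json(), indent=2))
        logger.info("profile: %d rows in, %d labelled -> %s", len(data),
                    predicted.notna().sum(), path)
        report["stages"]["profile"] = {"rows_in": len(data),
                                       "rows_out": int(predicted.notna().sum()),
                                       "artifact": str(path)}

    risk_result = None
    if "risk" in config.stages:
        if "profile" not in data.columns:
            raise FileNotFoundError("stage dependency missing: profile labels; "
                                    "run the profile stage first")
        risk_result = risk_mod.run_harness(
            data, spec=config.predictor_set, family=config.model_family,
            k=config.knn_k, m=config.k_imputations, seed=config.seed)
        # score every participant from an imputation-completed design table
        table = risk_mod.build_predictor_set(data, config.predictor_set)
        completed = risk_mod.impute_knn(table, k=config.knn_k, m=1,
                                        seed=config.seed)[0]
        p = risk_result.model.predict_risk(completed)
        data = data.copy()
        data["p_cvd"] = p
        path = out_dir / "metrics.csv"
        pd.DataFrame([risk_result.metrics]).to_csv(path, index=False)
        logger.info("risk: %d rows, pooled metrics %s", len(data), risk_result.metrics)
        report["stages"]["risk"] = {"rows_in": len(data), "rows_out": len(data),
                                    "metrics": risk_result.metrics,
                                    "threshold": risk_result.threshold,
                                    "artifact": str(path)}

    if "limits" in config.stages:
        if "profile" not in data.columns:
            raise FileNotFoundError("stage dependency missing: profile labels; "
                                    "run the profile stage first")
        prepared = limits_mod.prepare_survival_cohort(data, config.censor_age)
        rows = []
        for prof in cohort_mod.PROFILES:
            for nut in limits_mod.LEVEL2_NUTRIENTS:
                try:
                    res = limits_mod.derive_limits(prepared, prof, nut,
                                                   n_bins=config.n_bins,
                                                   censor_age=config.censor_age)
                except ValueError as exc:
                    logger.warning("limits: %s/%s skipped (%s)", prof, nut, exc)
                    continue
                rows.append({"profile": prof, "nutrient": nut,
                             "min_val": res.min_val, "max_val": res.max_val,
                             "best_bin": res.best_bin})
        limits_df = pd.DataFrame(rows)
        path = out_dir / "limits.csv"
        limits_df.to_csv(path, index=False)
        logger.info("limits: %d rows in, %d after preparation, %d cells -> %s",
                    len(data), len(prepared), len(limits_df), path)
        report["stages"]["limits"] = {"rows_in": len(data),
                                      "rows_filtered": len(prepared),
                                      "rows_out": len(limits_df),
                                      "artifact": str(path)}

    if "advise" in config.stages:
        if "p_cvd" not in data.columns:
            raise FileNotFoundError("stage dependency missing: CVD probabilities; "
                                    "run the risk stage first")
        params = limits_mod.packaged_params()
        bundles = []
        for _, row in data.iterrows():
            user = recommend_mod.UserState(
                profile=row["profile"], p_cvd=float(row["p_cvd"]),
                intakes={n: row[n] for n in limits_mod.LEVEL2_NUTRIENTS
                         if pd.notna(row.get(n))},
                portions={f: row[f"portions_{f}"] for f in cohort_mod.PORTION_FOODS
                          if pd.notna(row.get(f"portions_{f}"))})
            bundle = recommend_mod.compose_advice(user, params,
                                                  threshold=config.threshold)
            bundles.append(recommend_mod.bundle_to_dict(bundle))
        path = out_dir / "advice.json"
        path.write_text(json.dumps(bundles, indent=2))
        logger.info("advise: %d users advised -> %s", len(bundles), path)
        report["stages"]["advise"] = {"rows_in": len(data),
                                      "rows_out": len(bundles),
                                      "artifact": str(path)}

    (out_dir / "report.json").write_text(json.dumps(report, indent=2, default=str))
    return report


# ---------------------------------------------------------------------------
# Schema validation
# ---------------------------------------------------------------------------

COHORT_REQUIRED_COLUMNS = list(cohort_mod.CLINICAL_COLUMNS) + \
    list(cohort_mod.ALL_NUTRIENTS) + ["cvd", "onset_age", "censored"]


def validate_schema(path: str, schema_name: str) -> list[str]:
    """Validate a file against a named schema.  Returns a list of
    violations (empty = ok); unreadable files raise."""
    if schema_name == "cohort":
        return _validate_cohort(pd.read_csv(path))
    if schema_name == "params":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        try:
            limits_mod.validate_params_schema(raw)
        except ValueError as exc:
            return [str(exc)]
        return []
    if schema_name == "tree":
        with open(path) as fh:
            raw = json.load(fh)
        return _validate_tree(raw)
    raise ValueError(f"unknown schema '{schema_name}'")


def _validate_cohort(df: pd.DataFrame) -> list[str]:
    errors = []
    for col in COHORT_REQUIRED_COLUMNS:
        if col not in df.columns:
            errors.append(f"missing required column '{col}'")
    liking = [c for c in df.columns if c.startswith(cohort_mod.LIKING_PREFIX)]
    if len(liking) == 0:
        errors.append("no liking-score columns found")
    for col in liking:
        vals = df[col].dropna()
        if len(vals) and ((vals < 1) | (vals > 9)).any():
            errors.append(f"liking column '{col}' outside the 1-9 scale")
    if "cvd" in df.columns:
        vals = df["cvd"].dropna()
        if len(vals) and not vals.isin([0, 1]).all():
            errors.append("column 'cvd' must be binary")
    return errors


def _validate_tree(raw: dict) -> list[str]:
    errors = []
    if "nodes" not in raw:
        return ["tree file missing 'nodes'"]
    ids = {n.get("id") for n in raw["nodes"]}
    for n in raw["nodes"]:
        is_leaf = n.get("item") is None
        if not is_leaf:
            for side in ("left", "right"):
                if n.get(side) not in ids:
                    errors.append(f"node {n.get('id')}: {side} child missing")
        if "class" not in n:
            errors.append(f"node {n.get('id')}: missing predicted class")
    if len(raw.get("item_subset", [])) > 14:
        errors.append("item_subset exceeds 14 items")
    return errors
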