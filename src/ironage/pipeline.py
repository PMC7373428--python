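"""Configuration-driven orchestration: validated table I/O, stage execution
in dependency order, and a machine-readable run report with provenance
(config hash, seeds, package versions).
"""

from __future__ import annotations

import hashlib
import json
import sys
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = ["PipelineConfig", "RunReport", "read_source_table",
           "write_cohort_csv", "run_pipeline", "STAGE_REGISTRY"]

SCHEMAS = {
    "cohort": {
        "required": ["arm", "day", "event"],
        "optional": ["animal_id", "replicate", "temperature_C"],
    },
    "proportions": {
        "required": ["group", "successes", "trials"],
        "optional": ["dose", "age"],
    },
    "measurements": {
        "required": ["value", "group"],
        "optional": ["dose", "age"],
    },
}


def read_source_table(path, schema: str) -> pd.DataFrame:
    """Read and validate a delimited source-data table against a schema.

    Column names are normalized (stripped, lower-cased); unrecognized extra
    columns are preserved untouched.  Rows failing validation are rejected
    with their (0-based) row indices.
    """
    if schema not in SCHEMAS:
        raise ValueError(f"unknown schema {schema!r}; "
                         f"expected one of {sorted(SCHEMAS)}")
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"source table not found: {path}")
    df = pd.read_csv(path)
    rename = {c: c.strip().lower() for c in df.columns}
    # keep canonical capitalization for temperature_C
    rename = {c: ("temperature_C" if c.strip().lower() == "temperature_c"
                  else c.strip().lower()) for c in df.columns}
    df = df.rename(columns=rename)
    spec = SCHEMAS[schema]
    missing = [c for c in spec["required"] if c not in df.columns]
    if missing:
        raise ValueError(
            f"{path}: missing mandatory column(s) {missing}; expected schema "
            f"{schema!r} with columns {spec['required']} "
            f"(+ optional {spec['optional']})")

    bad: list[int] = []
    if schema == "cohort":
        day = pd.to_numeric(df["day"], errors="coerce")
        event = pd.to_numeric(df["event"], errors="coerce")
        bad = df.index[(day.isna()) | (day <= 0)
                       | (~event.isin([0, 1]))].tolist()
    elif schema == "proportions":
        k = pd.to_numeric(df["successes"], errors="coerce")
        n = pd.to_numeric(df["trials"], errors="coerce")
        bad = df.index[k.isna() | n.isna() | (k < 0) | (k > n)].tolist()
    elif schema == "measurements":
        v = pd.to_numeric(df["value"], errors="coerce")
        bad = df.index[v.isna()].tolist()
    if bad:
        raise ValueError(f"{path}: {len(bad)} row(s) fail {schema!r} "
                         f"validation at indices {bad[:20]}")
    return df


def write_cohort_csv(cohort: pd.DataFrame, path) -> None:
    cohort.to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Stages
# ---------------------------------------------------------------------------

@dataclass
class PipelineConfig:
    stages: list[dict]
    out_dir: str = "results"
    seed: int = 0

    @classmethod
    def from_file(cls, path) -> "PipelineConfig":
        import yaml
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        return cls(stages=raw["stages"], out_dir=raw.get("out_dir", "results"),
                   seed=int(raw.get("seed", 0)))


@dataclass
class RunReport:
    stages: list[dict] = field(default_factory=list)
    provenance: dict = field(default_factory=dict)

    @property
    def ok(self) -> bool:
        return all(s["status"] in ("ok", "skipped") for s in self.stages)

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump({"stages": self.stages, "provenance": self.provenance},
                      fh, indent=2, default=str)


def _stage_simulate_lifespan(params, ctx, out_dir, seed):
    from .simulate import default_lifespan_config, gen_lifespan
    cfg = default_lifespan_config(seed=params.get("seed", seed),
                                  **params.get("overrides", {}))
    cohort, truth = gen_lifespan(cfg)
    path = out_dir / "lifespan_cohort.csv"
    write_cohort_csv(cohort, path)
    ctx["cohort"] = cohort
    return {"n_animals": len(cohort), "pure_scaling": truth["pure_scaling"],
            "table": str(path)}


def _stage_load_cohort(params, ctx, out_dir, seed):
    ctx["cohort"] = read_source_table(params["path"], "cohort")
    return {"n_animals": len(ctx["cohort"]), "path": params["path"]}


def _stage_km_logrank(params, ctx, out_dir, seed):
    from .survival import km_curve, logrank
    cohort = ctx["cohort"]
    medians = {}
    for arm, sub in cohort.groupby("arm"):
        medians[arm] = km_curve(sub).median
    chi2, df, p = logrank(cohort)
    out = {"medians": medians, "logrank_chi2": chi2, "logrank_df": df,
           "logrank_p": p}
    pd.DataFrame([{"arm": a, "km_median": m} for a, m in medians.items()]
                 ).to_csv(out_dir / "km_medians.csv", index=False)
    return out


def _stage_rescaling_test(params, ctx, out_dir, seed):
    from .survival import ks_rescaling_test, fisher_combine
    cohort = ctx["cohort"]
    n_perm = int(params.get("n_perm", 500))
    results = []
    if "replicate" in cohort.columns and cohort["replicate"].nunique() > 1:
        for rep, sub in cohort.groupby("replicate"):
            r = ks_rescaling_test(sub, n_perm=n_perm, seed=seed + int(rep))
            results.append({"replicate": rep, "D": r.D, "p": r.p})
        chi2, df, p = fisher_combine([r["p"] for r in results])
        pooled = {"fisher_chi2": chi2, "fisher_df": df, "pooled_p": p}
    else:
        r = ks_rescaling_test(cohort, n_perm=n_perm, seed=seed)
        results.append({"replicate": 0, "D": r.D, "p": r.p})
        pooled = {"pooled_p": r.p}
    pd.DataFrame(results).to_csv(out_dir / "rescaling_test.csv", index=False)
    return {"per_replicate": results, **pooled}


def _stage_frailty_fit(params, ctx, out_dir, seed):
    from .survival import fit_weibull_gamma, lrt_select
    cohort = ctx["cohort"]
    specs = [("dlog_b",), ("dlog_b", "dlog_k"),
             ("dlog_b", "dlog_sigma2"), ("dlog_b", "dlog_k", "dlog_sigma2")]
    fits = [fit_weibull_gamma(cohort, departures=s) for s in specs]
    best, table = lrt_select(fits)
    table.to_csv(out_dir / "frailty_model_selection.csv", index=False)
    return {"best_model": best.model_label, "loglik": best.loglik,
            "params": best.params}


STAGE_REGISTRY = {
    "simulate_lifespan": _stage_simulate_lifespan,
    "load_cohort": _stage_load_cohort,
    "km_logrank": _stage_km_logrank,
    "rescaling_test": _stage_rescaling_test,
    "frailty_fit": _stage_frailty_fit,
}

# stages that need a cohort in context (from simulate_lifespan or load_cohort)
_NEEDS_COHORT = {"km_logrank", "rescaling_test", "frailty_fit"}


def run_pipeline(config: PipelineConfig) -> RunReport:
    """Execute the requested stages in order.

    A failed stage is recorded with its error; downstream stages that depend
    on its outputs are skipped.  The report carries a provenance block
    (config hash, seed, package versions) sufficient to re-run any stage.
    """
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    # fail fast on missing input paths
    for stage in config.stages:
        p = stage.get("params", {}).get("path")
        if p is not None and not Path(p).exists():
            raise FileNotFoundError(f"stage {stage['kind']!r}: input path "
                                    f"does not exist: {p}")

    cfg_hash = hashlib.sha256(
        json.dumps(config.stages, sort_keys=True, default=str).encode()
    ).hexdigest()[:16]
    import ironage
    report = RunReport(provenance={
        "config_hash": cfg_hash, "seed": config.seed,
        "versions": {"ironage": ironage.__version__,
                     "numpy": np.__version__, "pandas": pd.__version__,
                     "python": sys.version.split()[0]},
    })

    ctx: dict = {}
    failed = False
    for stage in config.stages:
        kind = stage["kind"]
        params = stage.get("params", {})
        if kind not in STAGE_REGISTRY:
            raise ValueError(f"unknown stage kind {kind!r}")
        if failed and kind in _NEEDS_COHORT and "cohort" not in ctx:
            report.stages.append({"kind": kind, "status": "skipped",
                                  "reason": "upstream failure"})
            continue
        t0 = time.perf_counter()
        try:
            out = STAGE_REGISTRY[kind](params, ctx, out_dir, config.seed)
            report.stages.append({"kind": kind, "status": "ok",
                                  "elapsed_s": time.perf_counter() - t0,
                                  "output": out})
        except Exception as err:  # recorded, downstream dependents skipped
            failed = True
            report.stages.append({"kind": kind, "status": "failed",
                                  "error": f"{type(err).__name__}: {err}"})
            print(f"[ironage] stage {kind} failed: {err}", file=sys.stderr)
    report.to_json(out_dir / "run_report.json")
    return report
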