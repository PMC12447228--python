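"""End-to-end pipeline orchestration.

Runs the stages simulate/ingest -> dosimetry -> preprocess -> GLM battery
-> PLS-SEM -> reports from a single config mapping, with one master seed
split deterministically per stage, stage-level timing/warning capture and
a JSON manifest sufficient to reproduce the run.
"""

from __future__ import annotations

import json
import time
import warnings
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__, chem, datasets, glm, preprocess
from .model_spec import SemModel
from .pls import PLSPathModel, prune_indicators

__all__ = ["ConfigError", "load_config", "run_pipeline", "render_reports"]

_STAGES = ("simulate", "dosimetry", "preprocess", "glm", "sem", "reports")


class ConfigError(ValueError):
    """Invalid run configuration (raised before any computation)."""


def load_config(path: str) -> dict:
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise ConfigError(f"config {path!r} must be a mapping")
    return cfg


def _stage_seeds(master: int) -> dict[str, int]:
    ss = np.random.SeedSequence(int(master))
    states = ss.generate_state(len(_STAGES))
    return {stage: int(s % (2**31)) for stage, s in zip(_STAGES, states)}


def _load_input(cfg: dict, seed: int) -> pd.DataFrame:
    src = cfg.get("input", {"mode": "synthetic-experiment"})
    mode = src.get("mode", "synthetic-experiment")
    if mode == "csv":
        path = src.get("path")
        if not path or not Path(path).exists():
            raise ConfigError(f"input csv not found: {path!r}")
        return datasets.read_sample_table(path)
    if mode == "synthetic-experiment":
        design = datasets.ExperimentDesign(seed=src.get("seed", seed),
                                           n_missing=src.get("n_missing", 4))
        pop = datasets.study_population(pruned=False)
        return datasets.sample_experiment(design, pop,
                                          noise_scale=src.get("noise_scale", 1.0))
    if mode == "synthetic-population":
        pop = datasets.study_population(pruned=src.get("pruned", True),
                                        n=src.get("n", 5000),
                                        seed=src.get("seed", seed))
        return datasets.sample_population(pop)
    raise ConfigError(f"unknown input mode {mode!r}")


def run_pipeline(config: dict, out_dir: str | None = None) -> dict:
    """Execute the configured stages and write reports plus a manifest.

    Returns the manifest mapping.  Any stage failure is re-raised with a
    stage label; config problems raise :class:`ConfigError` before any
    computation starts.
    """
    if not isinstance(config, dict):
        raise ConfigError("config must be a mapping")
    out = Path(out_dir or config.get("output_dir", "multistress_run"))
    master_seed = int(config.get("seed", 0))
    seeds = _stage_seeds(master_seed)
    manifest: dict = {
        "version": __version__,
        "master_seed": master_seed,
        "stage_seeds": seeds,
        "stages": {},
        "warnings": [],
    }
    results: dict = {}
    sem_cfg = config.get("sem", {})
    if sem_cfg is not None and "model" in sem_cfg and sem_cfg["model"] is not None:
        try:
            SemModel.from_dict(sem_cfg["model"])
        except Exception as exc:
            raise ConfigError(f"invalid sem model spec: {exc}") from exc

    def _stage(name: str, fn):
        t0 = time.perf_counter()
        with warnings.catch_warnings(record=True) as caught:
            warnings.simplefilter("always")
            try:
                value = fn()
            except ConfigError:
                raise
            except Exception as exc:
                raise RuntimeError(f"stage {name!r} failed: {exc}") from exc
        manifest["warnings"] += [f"{name}: {w.message}" for w in caught]
        manifest["stages"][name] = {"seconds": round(time.perf_counter() - t0, 3),
                                    "completed": True}
        return value

    # -- simulate / ingest -------------------------------------------------
    table = _stage("simulate", lambda: _load_input(config, seeds["simulate"]))
    manifest["stages"]["simulate"]["n_rows"] = int(len(table))
    results["table"] = table
    required = config.get("required_columns", [])
    missing_cols = [c for c in required if c not in table.columns]
    if missing_cols:
        raise ConfigError(f"input lacks required columns: {missing_cols}")

    # -- dosimetry ---------------------------------------------------------
    congener_path = config.get("congener_table")
    if congener_path:
        def _dosimetry():
            records = chem.read_congener_table(congener_path)
            return chem.total_activity(records)
        results["dosimetry"] = _stage("dosimetry", _dosimetry)

    # -- preprocess --------------------------------------------------------
    prep = config.get("preprocessing", {})
    impute_cols = prep.get("impute", [c for c in datasets.PHOTOMETRY_COLUMNS
                                      if c in table.columns])

    def _preprocess():
        if table[[c for c in impute_cols if c in table.columns]].isna().any().any():
            res = preprocess.em_impute(table, columns=[c for c in impute_cols
                                                       if c in table.columns])
            return res.completed
        return table

    completed = _stage("preprocess", _preprocess)
    results["completed"] = completed

    # -- GLM battery -------------------------------------------------------
    glm_cfg = config.get("glm", {})
    if glm_cfg is not None:
        results["glm"] = _stage(
            "glm",
            lambda: glm.run_glm_battery(
                completed,
                battery=glm_cfg.get("battery"),
                alpha=glm_cfg.get("alpha", 0.05),
                prune=glm_cfg.get("prune", True),
            ),
        )

    # -- PLS-SEM -----------------------------------------------------------
    if sem_cfg is not None:
        def _sem():
            if sem_cfg.get("model"):
                model = SemModel.from_dict(sem_cfg["model"])
            else:
                model = datasets.study_model(pruned=False)
                model = SemModel(
                    blocks={c: [i for i in b if i in completed.columns]
                            for c, b in model.blocks.items()
                            if any(i in completed.columns for i in b)},
                    paths=tuple((s, t) for s, t in model.paths
                                if s in model.blocks and t in model.blocks),
                )
            boot_cfg = sem_cfg.get("bootstrap", {})
            if sem_cfg.get("prune", True):
                model = prune_indicators(
                    completed, model,
                    loading_cutoff=sem_cfg.get("loading_cutoff", 0.5),
                    n_boot=sem_cfg.get("prune_n_boot", 200),
                    seed=seeds["sem"],
                )
            res = PLSPathModel(completed, model).fit()
            boot = res.bootstrap(
                n_boot=boot_cfg.get("n_boot", 1000),
                seed=boot_cfg.get("seed", seeds["sem"]),
                ci_levels=tuple(boot_cfg.get("ci_levels", (0.05, 0.95))),
            )
            return res, boot

        results["sem"] = _stage("sem", _sem)

    # -- reports -----------------------------------------------------------
    _stage("reports", lambda: render_reports(results, out, config))
    manifest["output_dir"] = str(out)
    out.mkdir(parents=True, exist_ok=True)
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, default=str)
    return manifest


def render_reports(results: dict, out_dir, config: dict | None = None) -> list[str]:
    """Write the report CSVs for whatever stages produced results.

    GLM output is written in the screening-table shape (response,
    predictor, link, estimate, SE, Wald, p, S_beta); SEM output in the
    path-table shape (hypothesis, path, beta, t, p, f2, ci_low, ci_high)
    plus an outer-assessment CSV, an HTMT matrix CSV, an optional DOT file
    and a plain-text summary of significant effects.
    """
    config = config or {}
    payload = {k: v for k, v in results.items() if k in ("glm", "sem", "dosimetry")}
    if not payload:
        warnings.warn("no stage produced results; nothing to report")
        return []
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written: list[str] = []
    summary_lines: list[str] = []

    if "dosimetry" in payload:
        df = payload["dosimetry"].to_frame()
        df.to_csv(out / "chemical_activity.csv", index=False)
        written.append("chemical_activity.csv")
        summary_lines.append(
            f"Total mixture chemical activity: {payload['dosimetry'].total_activity:.4f}"
        )

    if "glm" in payload:
        df = payload["glm"].rename(columns={"se": "SE", "wald": "Wald", "s_beta": "S_beta"})
        df.to_csv(out / "glm_effects.csv", index=False)
        written.append("glm_effects.csv")
        sig = payload["glm"][payload["glm"]["p"] < 0.05]
        for _, row in sig.iterrows():
            cat = glm.classify_s(row["s_beta"]) if np.isfinite(row["s_beta"]) else "n/a"
            summary_lines.append(
                f"GLM: {row['predictor']} affects {row['response']} "
                f"(p={row['p']:.3g}, S_beta={row['s_beta']:.3f}, {cat})"
            )

    if "sem" in payload:
        res, boot = payload["sem"]
        f2 = res.f2()
        labels = (config.get("sem") or {}).get("hypothesis_labels", {})
        rows = []
        for (s, t), beta in res.path_coefficients.items():
            st = boot.per_edge[(s, t)]
            rows.append({
                "hypothesis": labels.get(f"{s} -> {t}", ""),
                "path": f"{s} -> {t}",
                "beta": beta,
                "t": st["t"],
                "p": st["p"],
                "f2": f2[(s, t)],
                "ci_low": st["ci_low"],
                "ci_high": st["ci_high"],
            })
            if st["p"] < 0.05:
                from .reliability import classify_f2
                summary_lines.append(
                    f"SEM: {s} -> {t} beta={beta:+.3f} (p={st['p']:.3g}, "
                    f"f2={f2[(s, t)]:.3f}, {classify_f2(f2[(s, t)])})"
                )
        pd.DataFrame(rows).to_csv(out / "sem_paths.csv", index=False)
        written.append("sem_paths.csv")
        res.outer_assessment().to_csv(out / "sem_outer_assessment.csv")
        written.append("sem_outer_assessment.csv")
        res.htmt_matrix().to_csv(out / "sem_htmt.csv")
        written.append("sem_htmt.csv")
        (out / "sem_model.dot").write_text(res.model.to_dot())
        written.append("sem_model.dot")
        summary_lines.append(f"SEM fit: SRMR = {res.srmr():.4f}")

    (out / "summary.txt").write_text("\n".join(summary_lines) + "\n")
    written.append("summary.txt")
    return written
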