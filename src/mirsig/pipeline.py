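"""End-to-end pipeline orchestration with a reproducibility manifest.

A single YAML/JSON config drives the stages
simulate (or ingest) -> normalize -> discover (or load the published
signature) -> evaluate -> random-signature null -> target enrichment.
Each stage logs its seed, reads only files named in the config/manifest,
and records SHA-256 hashes of its inputs and outputs; re-running an
identical config reproduces identical hashes for the deterministic stages.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time as _time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .containers import ExpressionMatrix, SurvivalCohort
from .enrichment import pathway_enrichment, read_gmt, TargetMap
from .evaluation import evaluate_signature, multivariate_analysis, subset_comparison
from .normalize import filter_expressed, normalize_pipeline, background_correct
from .random_null import (
    evaluate_null,
    frequency_enrichment,
    generate_random_signatures,
    percentile_rank,
)
from .signature import SignatureResults, discover_signature, published_signature
from .simulate import SimConfig, simulate_cohort

logger = logging.getLogger("mirsig.pipeline")


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


@dataclass
class RunManifest:
    """Reproducibility record of one pipeline run."""

    config_hash: str
    seed: int
    version: str
    stages: dict = field(default_factory=dict)
    started: float = 0.0
    finished: float = 0.0

    def record(self, stage: str, outputs: dict[str, Path], seed: int | None = None) -> None:
        self.stages[stage] = {
            "seed": seed,
            "outputs": {str(name): _sha256(Path(p)) for name, p in outputs.items()},
        }

    def to_json(self, path) -> None:
        payload = {
            "config_hash": self.config_hash,
            "seed": self.seed,
            "version": self.version,
            "stages": self.stages,
            "started": self.started,
            "finished": self.finished,
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1)

    def deterministic_view(self) -> dict:
        """Everything except wall-clock timestamps."""
        return {
            "config_hash": self.config_hash,
            "seed": self.seed,
            "version": self.version,
            "stages": self.stages,
        }


class ConfigError(ValueError):
    """The run configuration violates the schema."""


_KNOWN_SECTIONS = {
    "outdir",
    "seed",
    "simulate",
    "ingest",
    "normalize",
    "discover",
    "evaluate",
    "null",
    "enrich",
}


def load_config(path_or_dict) -> dict:
    if isinstance(path_or_dict, (str, Path)):
        with open(path_or_dict) as fh:
            cfg = yaml.safe_load(fh)
    else:
        cfg = dict(path_or_dict)
    if not isinstance(cfg, dict):
        raise ConfigError("config must be a mapping")
    unknown = set(cfg) - _KNOWN_SECTIONS
    if unknown:
        raise ConfigError(f"unknown config sections: {sorted(unknown)}")
    if "outdir" not in cfg:
        raise ConfigError("config requires 'outdir'")
    cfg.setdefault("seed", 0)
    return cfg


def run_pipeline(config) -> RunManifest:
    """Execute the configured stages and write outputs + manifest to outdir."""
    cfg = load_config(config)
    outdir = Path(cfg["outdir"])
    outdir.mkdir(parents=True, exist_ok=True)
    seed = int(cfg["seed"])
    config_hash = hashlib.sha256(
        json.dumps(cfg, sort_keys=True, default=str).encode()
    ).hexdigest()
    manifest = RunManifest(config_hash=config_hash, seed=seed, version=__version__)
    manifest.started = _time.time()

    # --- simulate or ingest ----------------------------------------------
    sim_cfg_dict = dict(cfg.get("simulate") or {})
    enabled = sim_cfg_dict.pop("enabled", True)
    if enabled:
        sim_cfg = SimConfig(seed=seed, **sim_cfg_dict)
        cohorts = {}
        outputs = {}
        for role in ("train", "validation"):
            expr, surv, truth = simulate_cohort(sim_cfg, role)
            e_path = outdir / f"{role}_expr_raw.tsv"
            s_path = outdir / f"{role}_surv.tsv"
            g_path = outdir / f"{role}_truth.json"
            expr.to_tsv(e_path)
            surv.to_tsv(s_path)
            truth.to_json(g_path)
            cohorts[role] = (expr, surv)
            outputs.update(
                {f"{role}_expr": e_path, f"{role}_surv": s_path, f"{role}_truth": g_path}
            )
        manifest.record("simulate", outputs, seed=seed)
        logger.info("simulate: wrote %d files (seed=%d)", len(outputs), seed)
    else:
        ingest = cfg.get("ingest") or {}
        try:
            cohorts = {
                role: (
                    ExpressionMatrix.read_tsv(ingest[f"{role}_expr"]),
                    SurvivalCohort.read_tsv(ingest[f"{role}_surv"]),
                )
                for role in ("train", "validation")
            }
        except KeyError as exc:
            raise ConfigError(f"ingest section missing {exc}") from exc

    # --- normalize --------------------------------------------------------
    norm_cfg = cfg.get("normalize") or {}
    use_train_params = bool(norm_cfg.get("use_train_params", False))
    (tr_raw, tr_surv), (va_raw, va_surv) = cohorts["train"], cohorts["validation"]
    tr_bg, _ = background_correct(tr_raw)
    expressed = filter_expressed(tr_bg, min_nonzero_frac=norm_cfg.get("min_nonzero_frac", 0.8))
    tr_norm, tr_params = normalize_pipeline(tr_raw)
    va_norm, _ = normalize_pipeline(va_raw, tr_params if use_train_params else None)
    pool = [m for m in expressed if m in tr_norm.values.index and m in va_norm.values.index]
    tr_model_expr = tr_norm.subset_probes(pool)
    va_model_expr = va_norm.subset_probes(pool)
    norm_out = {}
    for name, obj in (("train_expr_norm", tr_norm), ("validation_expr_norm", va_norm)):
        p = outdir / f"{name}.tsv"
        obj.to_tsv(p)
        norm_out[name] = p
    params_path = outdir / "normalization_params.json"
    tr_params.to_json(params_path)
    norm_out["params"] = params_path
    pool_path = outdir / "expressed_pool.txt"
    pool_path.write_text("\n".join(pool) + "\n")
    norm_out["pool"] = pool_path
    manifest.record("normalize", norm_out)
    logger.info("normalize: %d expressed probes retained", len(pool))

    # --- discover or load published --------------------------------------
    disc_cfg = dict(cfg.get("discover") or {})
    use_published = not disc_cfg.pop("enabled", True)
    if use_published:
        model = published_signature()
        present = [m for m in model.mirna_ids if m in tr_model_expr.values.index]
        if len(present) < model.k:
            missing = set(model.mirna_ids) - set(present)
            raise ConfigError(f"published signature miRNAs absent from data: {sorted(missing)}")
        model.calibrate_cutpoint(tr_model_expr)
    else:
        model = discover_signature(
            tr_model_expr,
            tr_surv,
            evp_target=disc_cfg.pop("evp_target", 5.0),
            k_override=disc_cfg.pop("k", None),
            **disc_cfg,
        )
    model_path = outdir / "model.json"
    model.to_json(model_path)
    manifest.record("discover", {"model": model_path})
    logger.info("model: %s (k=%d, cutpoint=%.4f)", model.provenance, model.k, model.cutpoint)

    # --- evaluate ---------------------------------------------------------
    eval_cfg = cfg.get("evaluate") or {}
    eval_times = eval_cfg.get("eval_times", [1, 2, 3, 4, 5])
    eval_out = {}
    reports = {}
    for label, e, s in (
        ("training", tr_model_expr, tr_surv),
        ("validation", va_model_expr, va_surv),
    ):
        rep = evaluate_signature(model, e, s, eval_times, cohort_label=label)
        p = outdir / f"evaluation_{label}.json"
        rep.to_json(p)
        eval_out[label] = p
        reports[label] = rep
    subsets = subset_comparison(
        model, tr_model_expr, tr_surv, va_model_expr, va_surv, eval_times
    )
    sub_path = outdir / "subset_comparison.tsv"
    subsets.to_csv(sub_path, sep="\t", index=False)
    eval_out["subsets"] = sub_path
    combined_surv = SurvivalCohort(
        pd.concat([tr_surv.data, va_surv.data], ignore_index=True)
    )
    combined_groups = pd.concat(
        [
            model.stratify(tr_model_expr).group,
            model.stratify(va_model_expr).group,
        ],
        ignore_index=True,
    )
    try:
        mv = multivariate_analysis(combined_groups, combined_surv)
        mv_path = outdir / "multivariate.tsv"
        mv["table"].to_csv(mv_path, sep="\t")
        eval_out["multivariate"] = mv_path
    except ValueError as exc:
        logger.warning("multivariate analysis skipped: %s", exc)
    manifest.record("evaluate", eval_out)

    # --- random-signature null -------------------------------------------
    null_cfg = cfg.get("null") or {}
    if null_cfg.get("enabled", True):
        sizes = null_cfg.get("sizes", list(range(2, 11)))
        n_per_size = int(null_cfg.get("n_per_size", 10000))
        pool_cap = null_cfg.get("pool_cap")
        null_pool = pool[: int(pool_cap)] if pool_cap else pool
        sigs = generate_random_signatures(null_pool, sizes, n_per_size, seed=seed)
        null = evaluate_null(
            sigs,
            tr_model_expr,
            tr_surv,
            va_model_expr,
            va_surv,
            pool=null_pool,
            include_singletons=null_cfg.get("include_singletons", True),
            seed=seed,
        )
        null_path = outdir / "null_distribution.tsv"
        null.to_tsv(null_path)
        obs = reports["validation"]
        rank_payload = {}
        if np.isfinite(obs.logrank_p) and np.isfinite(obs.binary_hr):
            p_pct, hr_pct = percentile_rank(obs.logrank_p, obs.binary_hr, null)
            rank_payload = {"p_percentile": p_pct, "hr_percentile": hr_pct}
        freq = frequency_enrichment(
            null,
            significance_threshold=null_cfg.get(
                "significance_threshold",
                obs.logrank_p if np.isfinite(obs.logrank_p) and obs.logrank_p > 0 else 0.05,
            ),
        )
        freq_path = outdir / "frequency_enrichment.tsv"
        freq.to_csv(freq_path, sep="\t", index=False)
        rank_path = outdir / "null_percentiles.json"
        with open(rank_path, "w") as fh:
            json.dump({**null.manifest(), **rank_payload}, fh, indent=1)
        manifest.record(
            "null", {"null": null_path, "frequency": freq_path, "percentiles": rank_path},
            seed=seed,
        )
        logger.info("null: %d signatures evaluated", len(null.records))

    # --- enrichment -------------------------------------------------------
    enr_cfg = cfg.get("enrich") or {}
    if enr_cfg.get("enabled", False):
        try:
            targets = TargetMap.read_tsv(enr_cfg["targets"])
            pathways = read_gmt(enr_cfg["gmt"])
        except KeyError as exc:
            raise ConfigError(f"enrich section missing {exc}") from exc
        query = targets.targets_of(model.mirna_ids)
        table = pathway_enrichment(query, pathways, targets.background)
        enr_path = outdir / "enrichment.tsv"
        table.to_csv(enr_path, sep="\t", index=False)
        manifest.record("enrich", {"enrichment": enr_path})

    manifest.finished = _time.time()
    manifest.to_json(outdir / "manifest.json")
    return manifest
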