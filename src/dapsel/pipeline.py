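"""End-to-end orchestration: simulate -> read -> batch-correct ->
(marginal | elastic net | SSVS) -> select -> pool, with a run manifest.

Every run is deterministic given the config and global seed.  Result tables
are written atomically (temp file + rename) so partial outputs are never
mistaken for finished ones.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import os
import tempfile
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .batch import correct_batch, fit_lmm, run_pca
from .data import (
    Comparison,
    IntensityMatrix,
    build_comparisons,
    read_intensity_table,
)
from .enet import ENConfig, enet_table, tune_nested_cv
from .marginal import adjust_bonferroni, fit_marginal, marginal_table
from .selection import bfdr_select, classify_direction, dap_table, pool_comparisons
from .ssvs import SSVSConfig, compute_pip, run_gibbs, ssvs_table
from .synthetic import SimConfig, generate_dataset, write_dataset

logger = logging.getLogger("dapsel")

ALL_METHODS = ("marginal", "enet", "ssvs")


@dataclass
class PipelineConfig:
    matrix_path: str | None = None
    meta_path: str | None = None
    out_dir: str = "dapsel_out"
    simulate: bool = False
    log_transform: bool = False
    methods: tuple = ALL_METHODS
    alpha: float = 0.05            # Bonferroni and BFDR control level
    seed: int = 1
    scale: str = "full"            # "full" (3000 features) or "test" (500)
    sim: SimConfig | None = None
    enet: ENConfig | None = None
    ssvs: SSVSConfig | None = None

    def __post_init__(self):
        if not 0.0 < self.alpha < 1.0:
            raise ValueError("alpha must lie in (0, 1)")
        for m in self.methods:
            if m not in ALL_METHODS:
                raise ValueError(f"unknown method {m!r}")


def config_from_yaml(path: str | Path) -> PipelineConfig:
    raw = yaml.safe_load(Path(path).read_text()) or {}
    sim = SimConfig(**raw.pop("sim")) if "sim" in raw else None
    enet = ENConfig(**raw.pop("enet")) if "enet" in raw else None
    ssvs = SSVSConfig(**raw.pop("ssvs")) if "ssvs" in raw else None
    if "methods" in raw:
        raw["methods"] = tuple(raw["methods"])
    return PipelineConfig(sim=sim, enet=enet, ssvs=ssvs, **raw)


def _config_hash(cfg: PipelineConfig) -> str:
    def enc(obj):
        if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
            return {k: enc(v) for k, v in dataclasses.asdict(obj).items()}
        if isinstance(obj, (list, tuple)):
            return [enc(v) for v in obj]
        if hasattr(obj, "tolist"):
            return obj.tolist()
        return obj
    blob = json.dumps(enc(cfg), sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def _atomic_write(df: pd.DataFrame, path: Path) -> None:
    fd, tmp = tempfile.mkstemp(dir=path.parent, suffix=".tmp")
    os.close(fd)
    try:
        df.to_csv(tmp, sep="\t", index=False)
        os.replace(tmp, path)
    finally:
        if os.path.exists(tmp):
            os.unlink(tmp)


def _default_sim(cfg: PipelineConfig) -> SimConfig:
    n_features = 500 if cfg.scale == "test" else 3000
    return SimConfig(n_features=n_features, seed=cfg.seed)


def run_pipeline(cfg: PipelineConfig):
    """Run all enabled stages; returns (ComparisonSummary, out_dir)."""
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    if cfg.simulate:
        sim = cfg.sim or _default_sim(cfg)
        data, truth = generate_dataset(sim)
        write_dataset(
            data, truth, out / "matrix.tsv", out / "metadata.csv", out / "truth.json"
        )
        logger.info("simulated %d features x %d samples", data.n_features, data.n_samples)
    else:
        if cfg.matrix_path is None or cfg.meta_path is None:
            raise ValueError("matrix_path and meta_path required unless simulate=True")
        data = read_intensity_table(cfg.matrix_path, cfg.meta_path, cfg.log_transform)

    # batch correction + PCA QC
    fit = fit_lmm(data)
    logger.info(
        "LMM variance components: var_r=%.4g var_s=%.4g var_e=%.4g (loglik %.2f)",
        fit.var_r, fit.var_s, fit.var_e, fit.loglik,
    )
    adjusted = correct_batch(data, fit)
    n_pcs = min(data.n_samples - 1, data.n_features, 5)
    pca_before = run_pca(data, n_pcs)
    pca_after = run_pca(adjusted, n_pcs)
    _atomic_write(pca_before.scores.reset_index(names="sample_id"), out / "pca_before.tsv")
    _atomic_write(pca_after.scores.reset_index(names="sample_id"), out / "pca_after.tsv")
    adj_out = adjusted.values.copy()
    adj_out.index.name = "feature_id"
    _atomic_write(adj_out.reset_index(), out / "adjusted_matrix.tsv")

    comparisons = build_comparisons(data.samples)
    records = []
    for k, cmp in enumerate(comparisons):
        if "marginal" in cfg.methods:
            fits = fit_marginal(adjusted, cmp)
            sel = adjust_bonferroni(fits, cfg.alpha, comparison=cmp.name)
            _atomic_write(marginal_table(fits, sel), out / f"marginal_{cmp.name}.tsv")
            stats = pd.Series({f.feature_id: f.beta_k for f in fits})
            records += classify_direction(sel, stats, axis=cmp.axis)
        if "enet" in cfg.methods:
            encfg = cfg.enet or ENConfig(seed=cfg.seed)
            enfit = tune_nested_cv(adjusted, cmp, encfg)
            _atomic_write(enet_table(enfit), out / f"enet_{cmp.name}.tsv")
            side = {
                "lambda": enfit.lambda_,
                "omega": enfit.omega,
                "cv_surface": enfit.cv_deviance.to_dict(orient="list"),
            }
            (out / f"enet_{cmp.name}.json").write_text(json.dumps(side, indent=1))
            from .marginal import SelectionResult
            sel = SelectionResult(
                method="elastic_net", comparison=cmp.name,
                selected_ids=enfit.selected,
                control={"lambda": enfit.lambda_, "omega": enfit.omega},
            )
            records += classify_direction(sel, enfit.betas, axis=cmp.axis)
        if "ssvs" in cfg.methods:
            sscfg = cfg.ssvs or SSVSConfig(seed=cfg.seed)
            sscfg = dataclasses.replace(sscfg, seed=sscfg.seed + k)
            draws = run_gibbs(adjusted, cmp, sscfg)
            summary = compute_pip(draws, sscfg)
            sel = bfdr_select(summary, cfg.alpha, comparison=cmp.name)
            _atomic_write(ssvs_table(summary, sel.selected_ids), out / f"ssvs_{cmp.name}.tsv")
            records += classify_direction(sel, summary.post_mean_beta, axis=cmp.axis)

    summary = None
    if records:
        _atomic_write(dap_table(records), out / "dap_table.tsv")
        summary = pool_comparisons(records)
        (out / "overlap_summary.json").write_text(
            json.dumps(
                {
                    "axis_unions": summary.axis_unions,
                    "method_counts": summary.method_counts,
                    "pairwise_intersections": summary.pairwise_intersections,
                    "overall_total": summary.overall_total,
                },
                indent=1,
            )
        )

    manifest = {
        "dapsel_version": __version__,
        "config_hash": _config_hash(cfg),
        "seed": cfg.seed,
        "methods": list(cfg.methods),
        "alpha": cfg.alpha,
        "n_features": data.n_features,
        "n_samples": data.n_samples,
        "comparisons": [c.name for c in comparisons],
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1))
    return summary, out
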