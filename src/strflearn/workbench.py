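"""End-to-end experiment orchestration at configurable scale.

``run_experiment`` chains the full pipeline — stimulus synthesis, peripheral
model, patch extraction and whitening, ensemble learning over a grid of
(objective, correlation interval, constraint mode), per-STRF metrics,
clustering with merge, and a summary report — persisting every stage's
artifact so any stage can be resumed from disk.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__, audspec, clustering, ensembles, io, learning, patches, stimgen, strfmetrics

logger = logging.getLogger(__name__)


@dataclass
class ExperimentConfig:
    """Fully serializable description of one experiment."""

    total_duration_s: float = 180.0
    segment_duration_s: float = 3.0
    class_fractions: tuple = (0.5, 0.25, 0.25)
    var_fraction: float = 0.95
    K: int = 400
    objectives: list = field(default_factory=lambda: [["sustained", 125.0], ["sparse", 0.0]])
    modes: list = field(default_factory=lambda: ["response"])
    mu: float = 1.0
    max_iter: int = 30
    tol: float = 1e-4
    seed: int = 0
    n_clusters: int = 12
    outdir: str = "strflearn_run"

    def __post_init__(self):
        # normalize YAML-roundtripped containers
        self.class_fractions = tuple(float(f) for f in self.class_fractions)
        self.objectives = [[str(k), float(n)] for k, n in self.objectives]
        self.modes = [str(m) for m in self.modes]

    def validate(self) -> None:
        stimgen.StimulusRecipe(
            total_duration_s=self.total_duration_s,
            segment_duration_s=self.segment_duration_s,
            class_fractions=tuple(self.class_fractions),
            seed=self.seed,
        )
        if self.K < 1:
            raise ValueError("K must be >= 1")
        if not (0 < self.var_fraction <= 1):
            raise ValueError("var_fraction must lie in (0, 1]")
        for kind, n_ms in self.objectives:
            if kind == "sustained":
                learning.ObjectiveConfig(kind="sustained", N_ms=float(n_ms))
            elif kind != "sparse":
                raise ValueError(f"unknown objective kind {kind!r}")
        for m in self.modes:
            if m not in ("response", "shape"):
                raise ValueError(f"unknown constraint mode {m!r}")

    @classmethod
    def from_yaml(cls, path) -> "ExperimentConfig":
        with open(path) as f:
            data = yaml.safe_load(f) or {}
        cfg = cls(**data)
        cfg.validate()
        return cfg

    def to_yaml(self, path) -> None:
        with open(path, "w") as f:
            yaml.safe_dump(asdict(self), f)


def _ensemble_name(kind: str, n_ms: float, mode: str) -> str:
    tag = f"{kind}_N{int(n_ms)}" if kind == "sustained" else kind
    return f"{tag}_{mode}"


def run_experiment(config: ExperimentConfig, resume: bool = True) -> dict:
    """Execute the pipeline, returning a dict of artifact paths.

    Stages whose artifact file already exists are skipped when ``resume`` is
    true, so a failed run can be restarted from its last completed stage.
    """
    config.validate()
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    provenance = {"config": asdict(config), "version": __version__}
    (out / "config.json").write_text(json.dumps(provenance, indent=2))
    artifacts = {"config": out / "config.json"}

    # 1. stimulus
    wav_path = out / "stimulus.wav"
    artifacts["stimulus"] = wav_path
    if not (resume and wav_path.exists()):
        recipe = stimgen.StimulusRecipe(
            total_duration_s=config.total_duration_s,
            segment_duration_s=config.segment_duration_s,
            class_fractions=tuple(config.class_fractions),
            seed=config.seed,
        )
        stimgen.gen_stimulus_ensemble(recipe).write_wav(wav_path)
        logger.info("stage stimulus: wrote %s", wav_path)

    # 2. auditory spectrogram
    spec_path = out / "spectrogram.h5"
    artifacts["spectrogram"] = spec_path
    if not (resume and spec_path.exists()):
        wav = stimgen.Waveform.read_wav(wav_path)
        io.save_spectrogram(spec_path, audspec.compute_spectrogram(wav))
        logger.info("stage spectrogram: wrote %s", spec_path)

    # 3. patches + whitening
    whit_path = out / "whitening.h5"
    pp_path = out / "patches.h5"
    artifacts["whitening"] = whit_path
    artifacts["patches"] = pp_path
    if not (resume and whit_path.exists() and pp_path.exists()):
        spec = io.load_spectrogram(spec_path)
        pm = patches.preprocess_patches(patches.extract_patches(spec))
        model = patches.fit_whitening(pm, var_fraction=config.var_fraction)
        io.save_patches(pp_path, pm)
        io.save_whitening(whit_path, model)
        logger.info("stage patches: D=%d T=%d M=%d", pm.D, pm.T, model.M)

    # 4. learning grid
    model = io.load_whitening(whit_path)
    pm = io.load_patches(pp_path)
    Z = patches.apply_whitening(pm, model)
    ens_paths = {}
    for mode in config.modes:
        for kind, n_ms in config.objectives:
            name = _ensemble_name(kind, n_ms, mode)
            path = out / f"ensemble_{name}.h5"
            ens_paths[name] = path
            if resume and path.exists():
                continue
            obj = (
                learning.ObjectiveConfig(kind="sustained", N_ms=float(n_ms))
                if kind == "sustained"
                else learning.ObjectiveConfig(kind="sparse")
            )
            K = min(config.K, model.M) if mode == "response" else config.K
            data = Z if mode == "response" else pm
            ens, trace = learning.fit_ensemble(
                data if mode == "response" else pm,
                K=K,
                objective=obj,
                mode=mode,
                mu=config.mu,
                max_iter=config.max_iter,
                tol=config.tol,
                seed=config.seed,
                whitening=model if mode == "response" else None,
            )
            if ens.patch_shape is None:
                ens.patch_shape = pm.patch_shape
            io.save_ensemble(path, ens, trace)
            logger.info("stage learn %s: Psi=%.4g (%s)", name, trace.objectives[-1], trace.stop_reason)
    artifacts["ensembles"] = ens_paths

    # 5. per-STRF metrics
    metrics_path = out / "metrics.csv"
    artifacts["metrics"] = metrics_path
    if not (resume and metrics_path.exists()):
        rows = []
        for name, path in ens_paths.items():
            ens, _ = io.load_ensemble(path)
            Y = learning.compute_responses(ens, Z if ens.constraint_mode == "response" else pm)
            contrib = None
            if ens.objective.kind == "sustained":
                contrib, _ = learning.per_filter_contribution(ens, Y)
            for i, patch in enumerate(ens.strf_patches()):
                m = strfmetrics.compute_metrics(patch)
                rows.append(
                    {
                        "ensemble": name,
                        "strf": i,
                        "spi": m.spi,
                        "br_hz": m.br_hz,
                        "bs_cpo": m.bs_cpo,
                        "dsi": m.dsi,
                        "compactness": m.compactness,
                        "rate_cutoff6db_hz": m.rate_cutoff6db_hz,
                        "scale_cutoff6db_cpo": m.scale_cutoff6db_cpo,
                        "contribution": float(contrib[i]) if contrib is not None else np.nan,
                    }
                )
        pd.DataFrame(rows).to_csv(metrics_path, index=False)
        logger.info("stage metrics: wrote %s", metrics_path)

    # 6. clustering (pooled over ensembles) + merge
    labels_path = out / "clusters.csv"
    artifacts["clusters"] = labels_path
    if not (resume and labels_path.exists()):
        metrics = pd.read_csv(metrics_path)
        pool, keys = [], []
        for name, path in ens_paths.items():
            ens, _ = io.load_ensemble(path)
            for i, patch in enumerate(ens.strf_patches()):
                pool.append(patch)
                keys.append((name, i))
        W = clustering.similarity_matrix(pool)
        k = min(config.n_clusters, len(pool) - 1)
        initial = clustering.spectral_cluster(W, k=k, seed=config.seed)
        mrows = metrics.set_index(["ensemble", "strf"]).loc[keys]
        merged = clustering.merge_clusters(
            initial, mrows["spi"].to_numpy(), mrows["compactness"].to_numpy()
        )
        pd.DataFrame(
            {
                "ensemble": [k0 for k0, _ in keys],
                "strf": [i for _, i in keys],
                "initial_label": initial,
                "merged_label": merged,
            }
        ).to_csv(labels_path, index=False)
        logger.info("stage cluster: %d -> %d classes", k, len(np.unique(merged)))

    # 7. summary report
    report_path = out / "report.json"
    artifacts["report"] = report_path
    if not (resume and report_path.exists()):
        report = summary_report(artifacts)
        report_path.write_text(json.dumps(report, indent=2))
        logger.info("stage report: wrote %s", report_path)
    return artifacts


def summary_report(artifacts: dict) -> dict:
    """Per-ensemble statistic tables (means of the per-STRF metrics, class
    membership counts, and class-distribution entropy)."""
    metrics = pd.read_csv(artifacts["metrics"])
    labels = pd.read_csv(artifacts["clusters"])
    required = {"spi", "br_hz", "bs_cpo", "dsi", "compactness"}
    missing = required - set(metrics.columns)
    if missing:
        raise ValueError(f"metrics table missing columns: {sorted(missing)}")

    report = {"ensembles": {}}
    for name, grp in metrics.groupby("ensemble"):
        entry = {
            "n_strfs": int(len(grp)),
            "mean_spi": float(grp["spi"].mean()),
            "mean_br_hz": float(grp["br_hz"].mean()),
            "mean_bs_cpo": float(grp["bs_cpo"].mean()),
            "mean_dsi": float(grp["dsi"].mean()),
            "mean_compactness": float(np.nanmean(grp["compactness"].to_numpy())),
            "mean_rate_cutoff6db_hz": float(grp["rate_cutoff6db_hz"].mean()),
            "mean_scale_cutoff6db_cpo": float(grp["scale_cutoff6db_cpo"].mean()),
        }
        lab = labels[labels["ensemble"] == name]["merged_label"].to_numpy()
        if lab.size:
            entry["class_counts"] = {int(c): int(n) for c, n in zip(*np.unique(lab, return_counts=True))}
            entry["class_entropy_bits"] = clustering.class_entropy(lab)
        report["ensembles"][name] = entry
    report["n_classes"] = int(labels["merged_label"].nunique())
    report["pooled_entropy_bits"] = clustering.class_entropy(labels["merged_label"].to_numpy())
    return report
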