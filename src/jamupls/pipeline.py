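"""End-to-end orchestration: simulate -> PCA -> PLS-DA -> permutation test
-> N-PLS-DA -> clustergram, with a manifest of content-hashed outputs.

Each stage consumes only files written by earlier stages, so stages can be
rerun independently; identical configuration and seeds reproduce identical
hashes.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import cluster, npls, pca, permtest, pls
from .errors import ConfigError
from .formulary import (
    build_tensor,
    read_activity_table,
    read_usage_table,
    to_dummy,
    write_activity_table,
    write_usage_table,
)
from .simulate import GeneratorConfig, default_config, simulate_formulary

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "run_all"]


@dataclass
class RunConfig:
    """Configuration for a full pipeline run on synthetic or file inputs."""

    output_dir: str
    usage_path: str | None = None       # existing inputs; when None, simulate
    activity_path: str | None = None
    generator: GeneratorConfig | None = None
    n_components: int = 3
    cv_folds: int = 10
    n_permutations: int = 199
    alpha: float = 0.05
    npls_components: int = 2
    threshold: float = 0.3
    significance_mode: str = "one-vs-rest"
    seed: int = 0

    def __post_init__(self) -> None:
        has_files = self.usage_path is not None and self.activity_path is not None
        if not has_files and self.generator is None:
            self.generator = default_config(seed=self.seed)
        if self.usage_path is not None and not Path(self.usage_path).exists():
            raise ConfigError(f"usage table not found: {self.usage_path}")
        if self.activity_path is not None and not Path(self.activity_path).exists():
            raise ConfigError(f"activity table not found: {self.activity_path}")

    @classmethod
    def from_json(cls, path) -> "RunConfig":
        raw = json.loads(Path(path).read_text())
        gen = raw.pop("generator", None)
        cfg = cls(**raw)
        if gen is not None:
            cfg.generator = GeneratorConfig.from_json(json.dumps(gen))
        return cfg


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_all(cfg: RunConfig) -> dict:
    """Execute all stages in order; return (and write) the output manifest."""
    out = Path(cfg.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict[str, dict[str, str]] = {}

    def record(stage: str, *paths: Path) -> None:
        manifest.setdefault(stage, {})
        for p in paths:
            manifest[stage][p.name] = _sha256(p)

    def stage(name):
        def wrap(fn):
            t0 = time.perf_counter()
            try:
                fn()
            except Exception as exc:
                raise RuntimeError(f"stage {name!r} failed: {exc}") from exc
            logger.info("stage %s done in %.2fs", name, time.perf_counter() - t0)
        return wrap

    # -- stage 1: inputs -----------------------------------------------------
    usage_path = out / "usage.tsv"
    activity_path = out / "activity.tsv"

    @stage("simulate")
    def _inputs():
        if cfg.usage_path is not None:
            usage, labels = read_usage_table(cfg.usage_path)
            activities = read_activity_table(cfg.activity_path)
            write_usage_table(usage_path, usage, labels)
            write_activity_table(activity_path, activities)
            record("simulate", usage_path, activity_path)
        else:
            usage, labels, activities, truth = simulate_formulary(cfg.generator)
            write_usage_table(usage_path, usage, labels)
            write_activity_table(activity_path, activities)
            truth_path = out / "ground_truth.json"
            truth_path.write_text(truth.to_json())
            gen_path = out / "generator_config.json"
            gen_path.write_text(cfg.generator.to_json())
            record("simulate", usage_path, activity_path, truth_path, gen_path)

    usage, labels = read_usage_table(usage_path)
    activities = read_activity_table(activity_path)
    class_names = tuple(dict.fromkeys(labels.labels))
    if cfg.generator is not None:
        class_names = cfg.generator.resolved_class_names()
    dummy = to_dummy(labels, class_names)

    # -- stage 2: PCA biplot -------------------------------------------------
    @stage("pca-biplot")
    def _pca():
        freq = pca.build_frequency_matrix(usage, labels, class_names)
        model = pca.fit_pca(freq)
        coords = pca.biplot_coords(model)
        files = []
        f = out / "frequency.tsv"
        freq.to_csv(f, sep="\t", index_label="plant_id")
        files.append(f)
        f = out / "eigenvalues.tsv"
        pd.DataFrame(
            {"eigenvalue": model.eigenvalues,
             "cumulative_variance": np.cumsum(model.eigenvalues)
             / max(model.eigenvalues.sum(), np.finfo(float).tiny)}
        ).to_csv(f, sep="\t", index_label="component")
        files.append(f)
        f = out / "biplot_points.tsv"
        pd.DataFrame(coords.points, index=list(usage.plant_ids),
                     columns=["PC1", "PC2"]).to_csv(f, sep="\t", index_label="plant_id")
        files.append(f)
        f = out / "biplot_vectors.tsv"
        pd.DataFrame(coords.vectors, index=list(class_names),
                     columns=["PC1", "PC2"]).to_csv(f, sep="\t", index_label="efficacy")
        files.append(f)
        record("pca-biplot", *files)

    # -- stage 3: PLS-DA -----------------------------------------------------
    X = usage.X.astype(float)
    Y = dummy.Y.astype(float)

    @stage("plsda")
    def _plsda():
        model = pls.fit_pls(X, Y, cfg.n_components)
        pred = pls.classify(pls.predict(model, X), class_names)
        cm = pls.confusion(list(labels.labels), list(pred), class_names)
        cv_acc = pls.cross_validate(
            X, list(labels.labels), class_names, cfg.n_components,
            n_folds=cfg.cv_folds, seed=cfg.seed,
        )
        f1 = out / "confusion.tsv"
        cm.to_table().to_csv(f1, sep="\t", index_label="Observed efficacy")
        f2 = out / "plsda_summary.json"
        f2.write_text(json.dumps({
            "n_components": cfg.n_components,
            "overall_percent_correct": cm.overall_percent_correct,
            "cv_accuracy": cv_acc,
            "per_class_percent_correct": dict(
                zip(class_names, cm.per_class_percent_correct.tolist())
            ),
        }, indent=2))
        record("plsda", f1, f2)

    # -- stage 4: permutation test -------------------------------------------
    @stage("permtest")
    def _permtest():
        result = permtest.permutation_test(
            X, Y, cfg.n_components, n_permutations=cfg.n_permutations,
            alpha=cfg.alpha, seed=cfg.seed,
            plant_ids=usage.plant_ids, class_names=class_names,
        )
        f1 = out / "pvalues.tsv"
        pd.DataFrame(result.p_values, index=list(usage.plant_ids),
                     columns=list(class_names)).to_csv(f1, sep="\t", index_label="plant_id")
        f2 = out / "significant_plants.tsv"
        pd.DataFrame(result.significant, index=list(usage.plant_ids),
                     columns=list(class_names)).to_csv(f2, sep="\t", index_label="plant_id")
        f3 = out / "significance_summary.tsv"
        permtest.summary_table(result).to_csv(f3, sep="\t", index=False)
        record("permtest", f1, f2, f3)

    # -- stage 5: N-PLS-DA ---------------------------------------------------
    tensor = build_tensor(usage, activities)

    @stage("npls")
    def _npls():
        model = npls.fit_npls(tensor, dummy, cfg.npls_components)
        pred = pls.classify(npls.predict_npls(model, tensor), class_names)
        cm = pls.confusion(list(labels.labels), list(pred), class_names)
        sig = npls.activity_significance(
            tensor, dummy, n_components=cfg.npls_components,
            threshold=cfg.threshold, mode=cfg.significance_mode,
        )
        f1 = out / "npls_summary.json"
        f1.write_text(json.dumps({
            "n_components": cfg.npls_components,
            "overall_percent_correct": cm.overall_percent_correct,
        }, indent=2))
        Bt = model.coefficients_tensor()
        J, K, L = Bt.shape
        long = pd.DataFrame({
            "plant_id": np.repeat(list(usage.plant_ids), K * L),
            "activity_id": np.tile(np.repeat(list(activities.activity_ids), L), J),
            "efficacy": np.tile(list(class_names), J * K),
            "coefficient": Bt.ravel(),
        })
        f2 = out / "npls_coefficients.tsv"
        long.to_csv(f2, sep="\t", index=False)
        f3 = out / "activity_significance.tsv"
        pd.DataFrame(sig.S, index=list(sig.activity_ids),
                     columns=list(sig.class_names)).to_csv(f3, sep="\t", index_label="activity_id")
        record("npls", f1, f2, f3)

    # -- stage 6: clustergram ------------------------------------------------
    @stage("clustergram")
    def _clustergram():
        sig_df = pd.read_csv(out / "activity_significance.tsv", sep="\t", index_col=0)
        result = cluster.clustergram(sig_df)
        f1 = out / "clustergram.tsv"
        result.matrix.to_csv(f1, sep="\t", index_label="activity_id")
        f2 = out / "activities.nwk"
        f2.write_text(cluster.to_newick(result.row_tree) + "\n")
        f3 = out / "efficacies.nwk"
        f3.write_text(cluster.to_newick(result.col_tree) + "\n")
        record("clustergram", f1, f2, f3)

    manifest_path = out / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest
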