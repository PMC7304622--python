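"""End-to-end experiment orchestration.

Stages (each reads only files written by earlier stages, so any stage
can be rerun independently from a populated output directory):

  generate -> train (per variant) -> explain (per variant) ->
  cluster -> metrics -> report

``generate`` renders the baseline geometry once and derives the binary
and standardized variants from it, so a sample_id denotes the same
specimen in every variant.  ``explain`` computes LRP relevance maps and
56x56 descriptors for every variant; ``cluster`` runs SpRAy only on the
variants that carry inner structure (baseline, standardized) — binary
relevance maps vary only along the otolith contour and are excluded.
Everything is deterministic given the config and its seeds.
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__ as _pkg_version
from . import network, synthetic
from .classifier import OtolithAgeClassifier
from .config import ExperimentConfig
from .groups import AGE_GROUPS, assign_age_group, average_relevance_map, \
    select_display_ages
from .lrp import RuleParams, audit_conservation, compute_relevance_map
from .metrics import AgePair, mean_cv_by_group, rmse
from .spray import HeatmapDescriptor, SpRAy, make_descriptor, \
    permutation_null_f1


@dataclass
class ExperimentReport:
    outdir: Path
    f1_table: pd.DataFrame
    metrics_table: pd.DataFrame
    provenance: dict


def _config_hash(config: ExperimentConfig) -> str:
    blob = json.dumps(config.to_dict(), sort_keys=True).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def _log(stage: str, seed: int, t0: float, msg: str = "done") -> None:
    print(f"[{stage}] seed={seed} elapsed={time.perf_counter() - t0:.1f}s {msg}")


# ---------------------------------------------------------------------------
# stages


def stage_generate(config: ExperimentConfig, outdir: Path) -> None:
    """Render the dataset in every configured variant and write PNGs plus
    the manifest CSV."""
    t0 = time.perf_counter()
    outdir = Path(outdir)
    g = config.generator
    split = synthetic.generate_dataset(
        n_per_age=g.n_per_age, ages=g.ages, variant="baseline",
        canvas_size=g.canvas_size, split_fraction=g.split_fraction,
        seed=config.seed, separability=g.separability)

    (outdir / "data" / "masks").mkdir(parents=True, exist_ok=True)
    for variant in config.variants:
        (outdir / "data" / variant).mkdir(parents=True, exist_ok=True)

    for part in (split.train, split.test):
        for base in part:
            synthetic.save_mask_png(
                base, outdir / "data" / "masks" / f"{base.sample_id}.png")
            for variant in config.variants:
                s = synthetic.apply_variant(
                    base, variant, g.standardized_vertical_extent)
                synthetic.save_png(
                    s, outdir / "data" / variant / f"{s.sample_id}.png")

    synthetic.write_manifest(split, outdir / "data" / "manifest.csv")
    config.save(outdir / "config.yaml")
    n = len(split.train) + len(split.test)
    _log("generate", config.seed, t0, f"{n} samples x {len(config.variants)} variants")


def _load_images(outdir: Path, variant: str, sample_ids: list[str]) -> np.ndarray:
    return np.stack([
        synthetic.load_png(outdir / "data" / variant / f"{sid}.png")
        for sid in sample_ids])


def _train_seed(config: ExperimentConfig, variant: str) -> int:
    return (config.seed + 101 * (config.variants.index(variant) + 1)) % (2 ** 31)


def stage_train(config: ExperimentConfig, outdir: Path, variant: str) -> None:
    """Train one classifier on the given variant's training images."""
    t0 = time.perf_counter()
    outdir = Path(outdir)
    manifest = pd.read_csv(outdir / "data" / "manifest.csv")
    train_rows = manifest[manifest["split"] == "train"]
    X = _load_images(outdir, variant, train_rows["sample_id"].tolist())
    y = train_rows["age"].to_numpy()

    clf = OtolithAgeClassifier(
        conv_channels=tuple(config.network.conv_channels),
        dense_units=config.network.dense_units,
        epochs=config.train.epochs,
        batch_size=config.train.batch_size,
        learning_rate=config.train.learning_rate,
        augment=config.train.augment,
        random_state=_train_seed(config, variant),
    )
    clf.fit(X, y)

    (outdir / "models").mkdir(exist_ok=True)
    network.save_checkpoint(clf.model_, outdir / "models" / f"{variant}.npz")
    pd.DataFrame(clf.history_).to_csv(
        outdir / "models" / f"{variant}_log.csv", index=False)
    acc = clf.history_[-1]["accuracy"] if clf.history_ else float("nan")
    _log("train", _train_seed(config, variant), t0,
         f"variant={variant} final_train_acc={acc:.3f}")


def stage_explain(config: ExperimentConfig, outdir: Path, variant: str) -> None:
    """Predict every sample, compute its LRP map, and condense it to a
    56x56 descriptor; write the descriptor archive and manifest."""
    t0 = time.perf_counter()
    outdir = Path(outdir)
    manifest = pd.read_csv(outdir / "data" / "manifest.csv")
    model = network.load_checkpoint(outdir / "models" / f"{variant}.npz")
    rule = RuleParams(alpha=config.lrp.alpha, beta=config.lrp.beta,
                      stabilizer=config.lrp.stabilizer)

    rows, grids = [], []
    for rec in manifest.itertuples(index=False):
        image = synthetic.load_png(
            outdir / "data" / variant / f"{rec.sample_id}.png")
        mask = synthetic.load_png(
            outdir / "data" / "masks" / f"{rec.sample_id}.png") > 0.5
        x = network.normalize(image, model.normalization_stats)
        trace = network.forward(model, x)
        predicted = int(model.class_labels[int(np.argmax(trace.logits[0]))])
        target = rec.age if config.lrp.target == "read" else predicted
        rmap = compute_relevance_map(model, x, target_class=int(target),
                                     params=rule, trace=trace)
        report = audit_conservation(rmap)
        desc = make_descriptor(
            rmap.scores, mask, sample_id=rec.sample_id,
            predicted_age=predicted, variant=variant,
            out_size=config.spray.out_size,
            intermediate_size=config.spray.intermediate_size)
        grids.append(desc.grid.ravel())
        rows.append({
            "sample_id": rec.sample_id, "read_age": rec.age,
            "predicted_age": predicted, "split": rec.split,
            "target_class": int(target),
            "conservation_dev": report.max_relative_deviation,
        })

    (outdir / "explain").mkdir(exist_ok=True)
    pd.DataFrame(rows).to_csv(
        outdir / "explain" / f"{variant}_manifest.csv", index=False)
    np.savez(
        outdir / "explain" / f"{variant}_descriptors.npz",
        matrix=np.stack(grids).astype(np.float32),
        sample_id=np.array(manifest["sample_id"], dtype="U"),
    )
    _log("explain", config.seed, t0, f"variant={variant} n={len(rows)}")


def _load_descriptors(outdir: Path, variant: str,
                      config: ExperimentConfig) -> tuple[pd.DataFrame, np.ndarray]:
    man = pd.read_csv(outdir / "explain" / f"{variant}_manifest.csv")
    with np.load(outdir / "explain" / f"{variant}_descriptors.npz") as d:
        matrix = d["matrix"].astype(float)
    return man, matrix


def stage_cluster(config: ExperimentConfig, outdir: Path) -> None:
    """SpRAy over each consecutive age-group pair and clustering variant:
    spectral 2-clustering, best-matching F1, permutation-null p-value,
    and a t-SNE embedding CSV."""
    t0 = time.perf_counter()
    outdir = Path(outdir)
    (outdir / "cluster").mkdir(exist_ok=True)
    rows = []
    for variant in config.spray.cluster_variants:
        man, matrix = _load_descriptors(outdir, variant, config)
        age_col = ("predicted_age" if config.spray.group_by == "predicted"
                   else "read_age")
        groups = man[age_col].map(assign_age_group)
        for pair in config.spray.pairs:
            sel = groups.isin(pair).to_numpy()
            pair_name = "+".join(pair)
            n = int(sel.sum())
            if n < 6 or groups[sel].nunique() < 2:
                rows.append({"variant": variant, "pair": pair_name, "n": n,
                             "f1": float("nan"), "null_mean": float("nan"),
                             "p_value": float("nan")})
                continue
            spray = SpRAy(n_clusters=2, random_state=config.seed)
            spray.fit(matrix[sel])
            group_labels = groups[sel].to_numpy()
            f1 = spray.score_f1(group_labels)
            null = permutation_null_f1(
                spray.labels_, group_labels,
                n_permutations=config.spray.n_permutations, seed=config.seed)
            p = float((1 + np.sum(null >= f1)) / (1 + len(null)))
            rows.append({"variant": variant, "pair": pair_name, "n": n,
                         "f1": f1, "null_mean": float(null.mean()),
                         "p_value": p})
            emb = spray.embed(perplexity=config.spray.perplexity)
            pd.DataFrame({
                "sample_id": man.loc[sel, "sample_id"].to_numpy(),
                "x": emb.coordinates[:, 0], "y": emb.coordinates[:, 1],
                "predicted_age": man.loc[sel, "predicted_age"].to_numpy(),
                "split": man.loc[sel, "split"].to_numpy(),
                "cluster": spray.labels_,
            }).to_csv(outdir / "cluster" /
                      f"embedding_{variant}_{pair_name}.csv", index=False)
    pd.DataFrame(rows).to_csv(outdir / "cluster" / "f1.csv", index=False)
    _log("cluster", config.seed, t0, f"{len(rows)} pair/variant runs")


def stage_metrics(config: ExperimentConfig, outdir: Path) -> None:
    """RMSE and per-group mean CV (1.5 x IQR-filtered) per variant/split."""
    t0 = time.perf_counter()
    outdir = Path(outdir)
    (outdir / "metrics").mkdir(exist_ok=True)
    rows = []
    for variant in config.variants:
        man = pd.read_csv(outdir / "explain" / f"{variant}_manifest.csv")
        for split_name in ("train", "test"):
            sub = man[man["split"] == split_name]
            pairs = [AgePair(read_age=int(r.read_age),
                             predicted_age=int(r.predicted_age),
                             sample_id=r.sample_id, variant=variant,
                             split=split_name)
                     for r in sub.itertuples(index=False)]
            if not pairs:
                continue
            overall_rmse = rmse(pairs)
            for summ in mean_cv_by_group(pairs, variant=variant,
                                         split=split_name):
                rows.append({
                    "variant": variant, "split": split_name,
                    "group": summ.group, "n": summ.n,
                    "n_excluded": summ.n_excluded,
                    "mean_cv": summ.mean_cv, "rmse": overall_rmse,
                })
    pd.DataFrame(rows).to_csv(outdir / "metrics" / "metrics.csv", index=False)
    _log("metrics", config.seed, t0)


def stage_report(config: ExperimentConfig, outdir: Path) -> ExperimentReport:
    """Collate tables, render average-map panels and the CV bubble plot,
    and write the JSON report index with a provenance block."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    t0 = time.perf_counter()
    outdir = Path(outdir)
    rep_dir = outdir / "report"
    rep_dir.mkdir(exist_ok=True)

    f1_table = pd.read_csv(outdir / "cluster" / "f1.csv")
    metrics_table = pd.read_csv(outdir / "metrics" / "metrics.csv")

    # average relevance maps per predicted age, top-4 ages per group
    avg_arrays = {}
    for variant in config.spray.cluster_variants:
        man, matrix = _load_descriptors(outdir, variant, config)
        counts = man["predicted_age"].value_counts().to_dict()
        for group in AGE_GROUPS:
            ages = select_display_ages(counts, group)
            if not ages:
                continue
            fig, axes = plt.subplots(1, len(ages),
                                     figsize=(2.2 * len(ages), 2.6))
            axes = np.atleast_1d(axes)
            for ax, age in zip(axes, ages):
                sel = (man["predicted_age"] == age).to_numpy()
                descs = [HeatmapDescriptor(
                    grid=matrix[i].reshape(config.spray.out_size, -1),
                    sample_id=man["sample_id"].iloc[i],
                    predicted_age=age, variant=variant)
                    for i in np.flatnonzero(sel)]
                avg = average_relevance_map(descs)
                avg_arrays[f"{variant}_age{age:02d}"] = avg.grid
                ax.imshow(avg.grid, cmap="Reds", vmin=0, vmax=1)
                ax.set_title(f"age {age} (n={avg.n_samples})", fontsize=8)
                ax.axis("off")
            fig.suptitle(f"{variant} / {group}", fontsize=9)
            fig.tight_layout()
            fig.savefig(rep_dir / f"average_maps_{variant}_{group}.png",
                        dpi=120)
            plt.close(fig)
    np.savez(rep_dir / "average_maps.npz", **avg_arrays)

    # CV bubble plot (circle radius ~ group size)
    fig, axes = plt.subplots(1, 2, figsize=(9, 3.5), sharey=True)
    for ax, split_name in zip(axes, ("train", "test")):
        sub = metrics_table[metrics_table["split"] == split_name]
        for vi, variant in enumerate(config.variants):
            vsub = sub[sub["variant"] == variant]
            xs = np.arange(len(vsub)) + 0.2 * vi
            ax.scatter(xs, vsub["mean_cv"], s=5 * vsub["n"],
                       alpha=0.6, label=variant)
            ax.set_xticks(np.arange(len(vsub)))
            ax.set_xticklabels(vsub["group"], rotation=30, fontsize=7)
        ax.set_title(split_name)
        ax.set_ylabel("mean CV (%)")
    axes[0].legend(fontsize=7)
    fig.tight_layout()
    fig.savefig(rep_dir / "cv_bubble.png", dpi=120)
    plt.close(fig)

    provenance = {
        "config": config.to_dict(),
        "config_hash": _config_hash(config),
        "seed": config.seed,
        "package_version": _pkg_version,
        "numpy_version": np.__version__,
    }
    report = {
        "provenance": provenance,
        "f1": f1_table.to_dict(orient="records"),
        "metrics": metrics_table.to_dict(orient="records"),
    }
    with open(rep_dir / "report.json", "w") as fh:
        json.dump(report, fh, indent=2)
    _log("report", config.seed, t0)
    return ExperimentReport(outdir=outdir, f1_table=f1_table,
                            metrics_table=metrics_table,
                            provenance=provenance)


def run_experiment(config: ExperimentConfig, outdir: str | Path) -> ExperimentReport:
    """generate -> train/explain per variant -> cluster -> metrics -> report."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    stage_generate(config, outdir)
    for variant in config.variants:
        stage_train(config, outdir, variant)
        stage_explain(config, outdir, variant)
    stage_cluster(config, outdir)
    stage_metrics(config, outdir)
    return stage_report(config, outdir)
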