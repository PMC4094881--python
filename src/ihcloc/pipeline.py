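"""End-to-end experiment orchestration.

``run_experiment`` drives the full chain on one feature combination:

    generate/load -> stain separation -> global + local features
    -> SDA selection (per training fold) -> binary-relevance SVMs
    -> threshold tuning -> decision -> five metrics

under protein-based 2-fold cross-validation (no protein's images appear in
both folds).  ``compare_combinations`` repeats the run over feature
combinations sharing one dataset and emits comparison tables: subset
accuracy per combination and the five-metric table.

Feature combinations and their widths before selection:

    SLFs       840   (836 wavelet-Haralick + 4 DNA-protein overlap)
    SLFs_LBP   1096  (SLFs + 256 LBP)
    SLFs_CLBP  1040  (SLFs + 200 CLBP)
    SLFs_LTrP  1607  (SLFs + 767 LTrP)
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

from . import __version__
from .classify import (DEFAULT_C_GRID, DEFAULT_GAMMA_GRID, BinaryRelevanceSVM,
                       label_matrix, protein_twofold_split)
from .core import CLASS_NAMES, Dataset, StainModel
from .evaluation import compute_metrics, decide, tune_threshold
from .feature_selection import sda_select_multilabel
from .global_features import WaveletConfig, dna_overlap_block, haralick_block
from .local_features import clbp_histogram, lbp_histogram, ltrp_histograms
from .preprocessing import hue_qc, linear_separation
from .synthetic import generate_dataset, read_dataset

log = logging.getLogger(__name__)

COMBINATIONS = ("SLFs", "SLFs_LBP", "SLFs_CLBP", "SLFs_LTrP")
#: feature-name prefix -> block tag used in rank reports
BLOCK_PREFIXES = {"har_": "H", "int_": "H", "dna_": "D",
                  "lbp_": "L", "clbp_": "C", "ltrp_": "T"}
COMBINATION_BLOCKS = {
    "SLFs": ("H", "D"),
    "SLFs_LBP": ("H", "D", "L"),
    "SLFs_CLBP": ("H", "D", "C"),
    "SLFs_LTrP": ("H", "D", "T"),
}
EXPECTED_WIDTHS = {"SLFs": 840, "SLFs_LBP": 1096,
                   "SLFs_CLBP": 1040, "SLFs_LTrP": 1607}


@dataclass
class RunConfig:
    """Configuration of one end-to-end run."""

    combination: str = "SLFs_CLBP"
    wavelet_name: str = "db6"
    seed: int = 0
    # dataset (ignored when manifest is given)
    n_proteins: int = 24
    images_per_protein: int = 4
    multilabel_fraction: float = 0.25
    image_size: tuple[int, int] = (96, 96)
    noise_sd: float = 0.02
    manifest: str | None = None
    # QC: statistic always computed for audit; filtering only if a
    # threshold is set
    hue_threshold: float | None = None
    # SDA
    f_enter: float = 3.84
    f_remove: float = 2.71
    max_features: int = 100
    # SVM
    c_grid: tuple = DEFAULT_C_GRID
    gamma_grid: tuple = DEFAULT_GAMMA_GRID
    inner_cv: int = 3
    # decision threshold
    threshold_lo: float = -2.0
    threshold_hi: float = 2.0
    threshold_step: float = 0.1
    guarantee: bool = True
    output_dir: str | None = None

    def __post_init__(self) -> None:
        if self.combination not in COMBINATIONS:
            raise ValueError(f"combination must be one of {COMBINATIONS}")

    def dataset_key(self) -> str:
        """Hash of everything that determines the extracted feature table."""
        payload = json.dumps([
            self.manifest, self.n_proteins, self.images_per_protein,
            self.multilabel_fraction, list(self.image_size), self.noise_sd,
            self.seed, self.wavelet_name,
        ])
        return hashlib.sha1(payload.encode()).hexdigest()[:12]


def block_tag(feature_name: str) -> str:
    for prefix, tag in BLOCK_PREFIXES.items():
        if feature_name.startswith(prefix):
            return tag
    raise ValueError(f"unrecognised feature name {feature_name!r}")


def load_or_generate(cfg: RunConfig) -> Dataset:
    if cfg.manifest is not None:
        return read_dataset(cfg.manifest)
    stain = StainModel(noise_sd=cfg.noise_sd)
    return generate_dataset(
        cfg.n_proteins, cfg.images_per_protein, cfg.multilabel_fraction,
        image_size=cfg.image_size, seed=cfg.seed, stain_model=stain,
    )


def extract_features(dataset: Dataset, wavelet_name: str = "db6",
                     stain_model: StainModel | None = None) -> pd.DataFrame:
    """Per-image feature table with all descriptor blocks.

    Columns: protein_id, image_id, hue (audit statistic), label_<class>
    (+/-1) and every feature of all four blocks; combination subsets are
    taken by column-name prefix downstream.
    """
    if stain_model is None:
        stain_model = StainModel()
    wcfg = WaveletConfig(wavelet_name=wavelet_name)
    rows = []
    t0 = time.time()
    for rec, img in dataset.iter_images():
        qc = hue_qc(img)
        pair = linear_separation(img, stain_model)
        blocks = [
            haralick_block(pair.protein, wcfg),
            dna_overlap_block(pair),
            lbp_histogram(pair.protein),
            clbp_histogram(pair.protein),
            ltrp_histograms(pair.protein),
        ]
        row: dict = {"protein_id": rec.protein_id, "image_id": img.source_id,
                     "hue": qc.mean_hue}
        for name, yval in zip(CLASS_NAMES, rec.label_vector()):
            row[f"label_{name}"] = yval
        for b in blocks:
            row.update(zip(b.names, b.values))
        rows.append(row)
    log.info("extracted features for %d images in %.1fs", len(rows),
             time.time() - t0)
    return pd.DataFrame(rows)


def feature_columns(df: pd.DataFrame, combination: str) -> list[str]:
    blocks = COMBINATION_BLOCKS[combination]
    meta = {"protein_id", "image_id", "hue"}
    cols = [c for c in df.columns
            if c not in meta and not c.startswith("label_")
            and block_tag(c) in blocks]
    if len(cols) != EXPECTED_WIDTHS[combination]:
        raise RuntimeError(
            f"{combination}: expected {EXPECTED_WIDTHS[combination]} features, "
            f"got {len(cols)}")
    return cols


def _cached_features(cfg: RunConfig, dataset: Dataset) -> pd.DataFrame:
    if cfg.output_dir is None:
        return extract_features(dataset, cfg.wavelet_name,
                                StainModel(noise_sd=cfg.noise_sd))
    cache_dir = Path(cfg.output_dir) / "cache"
    cache_dir.mkdir(parents=True, exist_ok=True)
    path = cache_dir / f"features_{cfg.dataset_key()}.parquet"
    if path.exists():
        log.info("feature cache hit: %s", path)
        return pd.read_parquet(path)
    df = extract_features(dataset, cfg.wavelet_name,
                          StainModel(noise_sd=cfg.noise_sd))
    try:
        df.to_parquet(path)
    except Exception:  # parquet engine unavailable: fall back to CSV
        path = path.with_suffix(".csv")
        df.to_csv(path, index=False)
    return df


def _fold_frames(df: pd.DataFrame, fold_ids: list[str]) -> pd.DataFrame:
    return df[df["protein_id"].isin(fold_ids)].reset_index(drop=True)


def _tune_threshold_cv(cfg: RunConfig, train_df: pd.DataFrame,
                       cols: list[str], train_records) -> float:
    """Threshold tuned on held-out scores from an internal protein split."""
    sub = protein_twofold_split(Dataset(records=list(train_records)),
                               seed=cfg.seed + 1)
    scores, truths = [], []
    for a, b in ((0, 1), (1, 0)):
        ids_fit = [r.protein_id for r in sub[a]]
        ids_val = [r.protein_id for r in sub[b]]
        fit_df = _fold_frames(train_df, ids_fit)
        val_df = _fold_frames(train_df, ids_val)
        ycols = [f"label_{n}" for n in CLASS_NAMES]
        Yf = fit_df[ycols].to_numpy(float)
        if np.all(Yf.max(axis=0) < 0) or len(fit_df) < 4:
            continue
        res = BinaryRelevanceSVM(
            fit_df[cols].to_numpy(float), Yf,
            c_grid=cfg.c_grid, gamma_grid=cfg.gamma_grid,
            inner_cv=cfg.inner_cv, seed=cfg.seed,
        ).fit()
        scores.append(res.decision_scores(val_df[cols].to_numpy(float)))
        truths.append(val_df[ycols].to_numpy(float))
    if not scores:
        return 0.0
    return tune_threshold(
        np.vstack(scores), np.vstack(truths),
        grid_lo=cfg.threshold_lo, grid_hi=cfg.threshold_hi,
        step=cfg.threshold_step, guarantee=cfg.guarantee,
    )


def run_experiment(cfg: RunConfig, dataset: Dataset | None = None,
                   features: pd.DataFrame | None = None) -> dict:
    """Execute the full pipeline on both folds; returns the RunReport dict.

    ``dataset``/``features`` may be passed in to share work between
    combinations (see :func:`compare_combinations`).
    """
    t_start = time.time()
    if dataset is None:
        dataset = load_or_generate(cfg)
    if features is None:
        features = _cached_features(cfg, dataset)
    if cfg.hue_threshold is not None:
        keep = features["hue"] <= cfg.hue_threshold
        log.info("hue QC: keeping %d/%d images", int(keep.sum()), len(keep))
        features = features[keep].reset_index(drop=True)

    cols = feature_columns(features, cfg.combination)
    ycols = [f"label_{n}" for n in CLASS_NAMES]
    folds = protein_twofold_split(dataset, seed=cfg.seed)

    fold_reports = []
    all_pred, all_truth = [], []
    for f, (train_recs, test_recs) in enumerate([(folds[0], folds[1]),
                                                 (folds[1], folds[0])]):
        train_df = _fold_frames(features, [r.protein_id for r in train_recs])
        test_df = _fold_frames(features, [r.protein_id for r in test_recs])
        X_train = train_df[cols].to_numpy(float)
        Y_train = train_df[ycols].to_numpy(float)

        sda = sda_select_multilabel(
            X_train, Y_train, f_enter=cfg.f_enter, f_remove=cfg.f_remove,
            max_features=cfg.max_features,
        )
        sel_cols = [cols[i] for i in sda.selected]
        if not sel_cols:
            log.warning("fold %d: SDA selected nothing; using all features", f)
            sel_cols = cols
        block_counts: dict[str, int] = {}
        for c in sel_cols:
            tag = block_tag(c)
            block_counts[tag] = block_counts.get(tag, 0) + 1

        T = _tune_threshold_cv(cfg, train_df, sel_cols, train_recs)
        res = BinaryRelevanceSVM(
            train_df[sel_cols].to_numpy(float), Y_train,
            c_grid=cfg.c_grid, gamma_grid=cfg.gamma_grid,
            inner_cv=cfg.inner_cv, seed=cfg.seed,
        ).fit()
        res.threshold = T
        res.selected_features = sda.selected

        scores = res.decision_scores(test_df[sel_cols].to_numpy(float))
        pred = decide(scores, T, guarantee=cfg.guarantee)
        truth = test_df[ycols].to_numpy(float)
        metrics = compute_metrics(pred, truth)
        all_pred.append(pred)
        all_truth.append(truth)

        fold_reports.append({
            "fold": f,
            "n_train_images": len(train_df),
            "n_test_images": len(test_df),
            "n_selected": len(sel_cols),
            "selected_block_counts": block_counts,
            "selected_rank_tags": [block_tag(c) for c in sel_cols],
            "selected_features": sel_cols,
            "threshold": T,
            "metrics": metrics.as_dict(),
        })
        log.info("fold %d (%s): %d selected, T=%.2f, subset acc %.3f",
                 f, cfg.combination, len(sel_cols), T,
                 metrics.subset_accuracy)

    pooled = compute_metrics(np.vstack(all_pred), np.vstack(all_truth))
    mean_metrics = {
        k: float(np.mean([fr["metrics"][k] for fr in fold_reports]))
        for k in ("subset_accuracy", "accuracy", "recall", "precision",
                  "average_label_accuracy")
    }
    report = {
        "combination": cfg.combination,
        "config": _jsonable(asdict(cfg)),
        "version": __version__,
        "n_features_in": len(cols),
        "folds": fold_reports,
        "mean_metrics": mean_metrics,
        "pooled_metrics": pooled.as_dict(),
        "runtime_s": round(time.time() - t_start, 2),
    }
    if cfg.output_dir is not None:
        out = Path(cfg.output_dir)
        out.mkdir(parents=True, exist_ok=True)
        with open(out / f"run_{cfg.combination}_{cfg.seed}.json", "w") as fh:
            json.dump(report, fh, indent=2)
    return report


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, np.generic):
        return obj.item()
    return obj


def compare_combinations(cfgs: list[RunConfig]) -> dict:
    """Run several combinations on one shared dataset and tabulate.

    All configs must agree on the dataset parameters and seed.  Returns a
    dict with the per-combination subset-accuracy table and the
    five-metric comparison table (both as DataFrame ``to_dict`` records)
    plus the raw reports.
    """
    keys = {c.dataset_key() for c in cfgs}
    if len(keys) != 1:
        raise ValueError("all configs must share dataset parameters and seed")
    base = cfgs[0]
    dataset = load_or_generate(base)
    features = _cached_features(base, dataset)

    reports = {c.combination: run_experiment(c, dataset, features)
               for c in cfgs}
    subset_rows = [{"combination": name,
                    "subset_accuracy": rep["mean_metrics"]["subset_accuracy"]}
                   for name, rep in reports.items()]
    metric_rows = [{"combination": name, **rep["mean_metrics"]}
                   for name, rep in reports.items()]
    return {
        "subset_accuracy_table": subset_rows,
        "metrics_table": metric_rows,
        "reports": reports,
    }
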