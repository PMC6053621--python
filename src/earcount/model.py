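"""Training orchestration and the single-file model archive.

One archive bundles everything inference needs — min-max normalization,
the importance table, the optional KPCA projection and the fitted twin
SVM together with the SLIC/feature configurations — so a trained model is
one portable file and there is no train/serve skew.

Training follows the five-step workflow: superpixel patches from labeled
scenes, the three descriptors, min-max normalization, importance weighting,
KPCA fusion, then a small grid search and the final TWSVM fit on a balanced
subsample of patches (the dual QP and the kernel expansion both scale with
the reference-matrix size, so the subsample size is the problem-size dial).
"""

from __future__ import annotations

import io
import json
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np
from scipy.ndimage import distance_transform_edt

from . import twsvm as _twsvm
from .features import FeatureConfig, FeatureMatrix, feature_matrix
from .superpixel import LabeledPatchSet, SlicConfig, extract_patches, label_patches, slic_segment
from .synthetic_data import Scene
from .weighting import (
    ImportanceTable,
    KpcaModel,
    NormalizationParams,
    apply_normalizer,
    apply_weights,
    fit_normalizer,
    importance,
    kpca_fit,
    kpca_transform,
)

__all__ = [
    "TrainConfig",
    "EarCountModel",
    "collect_patches",
    "fit_model",
    "transform_features",
    "predict_patch_labels",
    "save_model",
    "load_model",
]


@dataclass(frozen=True)
class TrainConfig:
    """Training-time choices; defaults are desk-scale but fully configurable.

    ``curation_min_ratio`` emulates the manual curation of the training
    patches: a patch enters the ear training class only if at least that
    fraction of its superpixel is ear (inference and evaluation keep the
    zero-ratio labels untouched).  ``gamma_grid`` holds multiples of the
    data-driven base bandwidth 1/(D * Var(X)) of the features entering the
    classifier, so the search covers the same relative range whatever scale
    the weighting/KPCA stage leaves.  The (c, gamma) pair is selected by a
    grid search validated on held-out training scenes at the counting level
    (patch-level CV accuracy saturates near 1 and cannot rank bandwidths);
    ``validation_fraction`` of the scenes (at least 2, when available) are
    held out for that purpose, and the final model is refit on all scenes.
    """

    max_per_class: int = 1500
    curation_min_ratio: float = 0.15
    use_kpca: bool = True
    variance_retained: float = 0.95
    kpca_gamma: float | None = None  # None -> 1/(D * Var(X))
    c_grid: tuple[float, ...] = (1.0,)
    gamma_grid: tuple[float, ...] = (1.5, 2.0, 3.0)
    validation_fraction: float = 0.2
    validation_min_area: int = 50
    mining_rounds: int = 3
    eps: float = 1e-6
    seed: int = 0


@dataclass
class EarCountModel:
    slic_config: SlicConfig
    feature_config: FeatureConfig
    normalizer: NormalizationParams
    importance_table: ImportanceTable
    kpca: KpcaModel | None
    classifier: _twsvm.TwsvmModel
    cv_best: tuple[float, float] | None = None


def _scene_data(scene, slic_config, feature_config):
    spmap = slic_segment(scene.image, slic_config)
    patchset = extract_patches(scene.image, spmap, feature_config.patch_size)
    labeled = label_patches(patchset, spmap, scene.mask)
    fm = feature_matrix(labeled, feature_config)
    ear = np.bincount(spmap.labels.ravel(),
                      weights=scene.mask.ravel().astype(float), minlength=spmap.K)
    area = np.bincount(spmap.labels.ravel(), minlength=spmap.K)
    ratio = (ear / area)[patchset.superpixel_ids]
    # centroid distance to the nearest ear pixel: patches farther than half a
    # window diagonal cannot see any ear, so they are safe mining negatives
    dist = distance_transform_edt(~scene.mask.astype(bool))
    cent = np.rint(spmap.centers).astype(int)
    far = dist[cent[:, 0].clip(0, scene.mask.shape[0] - 1),
               cent[:, 1].clip(0, scene.mask.shape[1] - 1)] > 16.0
    return fm, labeled.labels, ratio, spmap, far[patchset.superpixel_ids]


def collect_patches(
    scenes: list[Scene],
    slic_config: SlicConfig,
    feature_config: FeatureConfig,
) -> tuple[FeatureMatrix, np.ndarray, np.ndarray]:
    """Features, zero-ratio labels and superpixel ear fractions per patch."""
    blocks, labels, ratios = [], [], []
    spans = None
    for scene in scenes:
        fm, lab, ratio, _, _ = _scene_data(scene, slic_config, feature_config)
        blocks.append(fm.values)
        labels.append(lab)
        ratios.append(ratio)
        spans = fm.block_spans
    return (
        FeatureMatrix(values=np.vstack(blocks), block_spans=spans),
        np.concatenate(labels),
        np.concatenate(ratios),
    )


def _training_subsample(
    labels: np.ndarray, ratios: np.ndarray, per_class: int,
    min_ratio: float, seed: int,
) -> np.ndarray:
    """Balanced, curated training indices (ear class: ratio >= min_ratio)."""
    rng = np.random.default_rng(seed)
    keep = []
    for cls in (0, 1):
        idx = np.flatnonzero(labels == cls)
        if cls == 1:
            core = idx[ratios[idx] >= min_ratio]
            # fall back to the raw class if curation would empty it
            idx = core if len(core) > 0 else idx
        if len(idx) == 0:
            raise ValueError(f"training scenes produced no class-{cls} patches")
        if len(idx) > per_class:
            idx = rng.choice(idx, size=per_class, replace=False)
        keep.append(np.sort(idx))
    return np.concatenate(keep)


class _Stack:
    """Transform chain + classifier fitted on a set of per-scene data."""

    def __init__(self, scene_data, train_config):
        values = np.vstack([d[0].values for d in scene_data])
        spans = scene_data[0][0].block_spans
        labels = np.concatenate([d[1] for d in scene_data])
        ratios = np.concatenate([d[2] for d in scene_data])
        keep = _training_subsample(labels, ratios, train_config.max_per_class,
                                   train_config.curation_min_ratio,
                                   train_config.seed)
        fm = FeatureMatrix(values=values[keep], block_spans=spans)
        self.labels = labels[keep]
        self.normalizer = fit_normalizer(fm)
        normed = apply_normalizer(self.normalizer, fm)
        self.table = importance(normed, self.labels)
        weighted = apply_weights(normed, self.table)
        self.kpca = None
        features = weighted
        if train_config.use_kpca:
            self.kpca = kpca_fit(weighted, bandwidth=train_config.kpca_gamma,
                                 variance_retained=train_config.variance_retained)
            features = kpca_transform(self.kpca, weighted)
        self.features = features.values
        var = float(self.features.var())
        self.gamma_base = (1.0 / (self.features.shape[1] * var)) if var > 0 else 1.0
        self.eps = train_config.eps

    def transform(self, fm: FeatureMatrix) -> np.ndarray:
        out = apply_weights(apply_normalizer(self.normalizer, fm), self.table)
        if self.kpca is not None:
            out = kpca_transform(self.kpca, out)
        return out.values

    def fit_classifier(self, c: float, gamma_mult: float) -> _twsvm.TwsvmModel:
        return _twsvm.fit(
            self.features[self.labels == 1], self.features[self.labels == 0],
            c1=c, c2=c, gamma=gamma_mult * self.gamma_base, eps=self.eps,
        )

    def fit_mined_classifier(
        self, c: float, gamma_mult: float,
        z_pool: np.ndarray, label_pool: np.ndarray, far_pool: np.ndarray,
        rounds: int,
    ) -> _twsvm.TwsvmModel:
        """Fit, then absorb hard negatives from the training pool.

        Only background patches farther than half a window diagonal from any
        ear are eligible: nearer patches legitimately show ear pixels in
        their window and would poison the background class.
        """
        clf = self.fit_classifier(c, gamma_mult)
        z_train, y_train = self.features, self.labels
        taken = np.zeros(len(label_pool), dtype=bool)
        for _ in range(max(rounds, 0)):
            pred = _twsvm.predict(clf, z_pool)
            mined = (label_pool == 0) & (pred == 1) & far_pool & ~taken
            if not mined.any():
                break
            taken |= mined
            z_train = np.vstack([z_train, z_pool[mined]])
            y_train = np.concatenate([y_train, np.zeros(int(mined.sum()), dtype=int)])
            clf = _twsvm.fit(z_train[y_train == 1], z_train[y_train == 0],
                             c1=c, c2=c, gamma=gamma_mult * self.gamma_base,
                             eps=self.eps)
        return clf


def _validation_count_error(classifier, stack, val_data, min_area) -> int:
    from .pipeline import count_regions, median_filter_binary  # late: avoids cycle

    err = 0
    for z, spmap, true_count in val_data:
        pred = _twsvm.predict(classifier, z)
        mask = median_filter_binary(pred[spmap.labels].astype(bool))
        err += abs(count_regions(mask, 8, min_area).count - true_count)
    return err


def fit_model(
    scenes: list[Scene],
    slic_config: SlicConfig = SlicConfig(),
    feature_config: FeatureConfig = FeatureConfig(),
    train_config: TrainConfig = TrainConfig(),
) -> EarCountModel:
    """Train the full stack from ground-truthed scenes.

    With enough scenes, a fraction is held out to pick (c, gamma) by the
    counting error of the assembled pipeline; the returned model is then
    refit on every scene at the selected parameters.
    """
    if not scenes:
        raise ValueError("fit_model needs at least one scene")
    data = [_scene_data(s, slic_config, feature_config) for s in scenes]

    n_val = int(round(train_config.validation_fraction * len(scenes)))
    n_val = min(max(n_val, 2), len(scenes) - 1) if len(scenes) >= 4 else 0
    if n_val > 0 and (len(train_config.c_grid) > 1 or len(train_config.gamma_grid) > 1):
        # the deployed model is exactly the validated one: the transform
        # chain is fitted on the fit-subset and the selected classifier is
        # returned without refitting, so the validation estimate applies
        # directly to what segment_image will use.
        rng = np.random.default_rng(train_config.seed)
        order = rng.permutation(len(scenes))
        val_idx, fit_idx = order[:n_val], order[n_val:]
        fit_data = [data[i] for i in fit_idx]
        stack = _Stack(fit_data, train_config)
        z_pool = np.vstack([stack.transform(d[0]) for d in fit_data])
        label_pool = np.concatenate([d[1] for d in fit_data])
        far_pool = np.concatenate([d[4] for d in fit_data])
        val_data = [(stack.transform(data[i][0]), data[i][3], scenes[i].count)
                    for i in val_idx]
        best = None
        for c in sorted(set(train_config.c_grid)):
            for g in sorted(set(train_config.gamma_grid)):
                clf = stack.fit_mined_classifier(c, g, z_pool, label_pool,
                                                 far_pool, train_config.mining_rounds)
                err = _validation_count_error(clf, stack, val_data,
                                              train_config.validation_min_area)
                if best is None or err < best[0]:
                    best = (err, c, g, clf)
        _, c_best, g_best, classifier = best
    else:
        stack = _Stack(data, train_config)
        z_pool = np.vstack([stack.transform(d[0]) for d in data])
        label_pool = np.concatenate([d[1] for d in data])
        far_pool = np.concatenate([d[4] for d in data])
        c_best, g_best = 1.0, 2.0
        classifier = stack.fit_mined_classifier(c_best, g_best, z_pool,
                                                label_pool, far_pool,
                                                train_config.mining_rounds)

    return EarCountModel(
        slic_config=slic_config,
        feature_config=feature_config,
        normalizer=stack.normalizer,
        importance_table=stack.table,
        kpca=stack.kpca,
        classifier=classifier,
        cv_best=(c_best, g_best * stack.gamma_base),
    )


def transform_features(model: EarCountModel, fm: FeatureMatrix) -> FeatureMatrix:
    """Apply the model's normalize -> weight -> (KPCA) chain to raw features."""
    if fm.n_features != model.normalizer.min_.shape[0]:
        raise ValueError(
            f"feature dimension {fm.n_features} does not match the model "
            f"({model.normalizer.min_.shape[0]})"
        )
    out = apply_weights(apply_normalizer(model.normalizer, fm), model.importance_table)
    if model.kpca is not None:
        out = kpca_transform(model.kpca, out)
    return out


def predict_patch_labels(model: EarCountModel, patchset: LabeledPatchSet) -> np.ndarray:
    fm = feature_matrix(patchset, model.feature_config)
    feats = transform_features(model, fm)
    return _twsvm.predict(model.classifier, feats.values)


def save_model(model: EarCountModel, path: str | Path) -> None:
    """Write the archive: one .npz with arrays plus a JSON metadata entry."""
    meta = {
        "format": "earcount-model",
        "version": 1,
        "slic_config": asdict(model.slic_config),
        "feature_config": asdict(model.feature_config),
        "cv_best": list(model.cv_best) if model.cv_best else None,
        "classifier": {k: getattr(model.classifier, k)
                       for k in ("b1", "b2", "c1", "c2", "gamma", "eps",
                                 "kernel", "norm1", "norm2")},
        "has_kpca": model.kpca is not None,
    }
    arrays = {
        "norm_min": model.normalizer.min_,
        "norm_max": model.normalizer.max_,
        "imp_k": model.importance_table.k,
        "imp_I": model.importance_table.I,
        "imp_W": model.importance_table.W,
        "imp_W_combined": model.importance_table.W_combined,
        "twsvm_C": model.classifier.C,
        "twsvm_w1": model.classifier.w1,
        "twsvm_w2": model.classifier.w2,
    }
    if model.kpca is not None:
        meta["kpca"] = {"gamma": model.kpca.gamma,
                        "explained_fraction": model.kpca.explained_fraction,
                        "grand_mean": model.kpca.grand_mean}
        arrays.update(
            kpca_reference=model.kpca.reference,
            kpca_alphas=model.kpca.alphas,
            kpca_eigenvalues=model.kpca.eigenvalues,
            kpca_col_means=model.kpca.col_means,
        )
    buf = io.BytesIO()
    np.savez(buf, meta=np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8), **arrays)
    Path(path).write_bytes(buf.getvalue())


def load_model(path: str | Path) -> EarCountModel:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"model archive not found: {path}")
    with np.load(path) as data:
        meta = json.loads(bytes(data["meta"]).decode())
        if meta.get("format") != "earcount-model":
            raise ValueError(f"{path} is not an earcount model archive")
        slic_meta = dict(meta["slic_config"])
        feat_meta = dict(meta["feature_config"])
        feat_meta["glcm_offsets"] = tuple(tuple(o) for o in feat_meta["glcm_offsets"])
        feat_meta["glcm_stats"] = tuple(feat_meta["glcm_stats"])
        cls_meta = meta["classifier"]
        classifier = _twsvm.TwsvmModel(
            C=data["twsvm_C"], w1=data["twsvm_w1"], b1=cls_meta["b1"],
            w2=data["twsvm_w2"], b2=cls_meta["b2"], c1=cls_meta["c1"],
            c2=cls_meta["c2"], gamma=cls_meta["gamma"], eps=cls_meta["eps"],
            kernel=cls_meta["kernel"], norm1=cls_meta["norm1"],
            norm2=cls_meta["norm2"],
        )
        kpca = None
        if meta["has_kpca"]:
            kpca = KpcaModel(
                reference=data["kpca_reference"],
                gamma=meta["kpca"]["gamma"],
                alphas=data["kpca_alphas"],
                eigenvalues=data["kpca_eigenvalues"],
                explained_fraction=meta["kpca"]["explained_fraction"],
                col_means=data["kpca_col_means"],
                grand_mean=meta["kpca"]["grand_mean"],
            )
        return EarCountModel(
            slic_config=SlicConfig(**slic_meta),
            feature_config=FeatureConfig(**feat_meta),
            normalizer=NormalizationParams(min_=data["norm_min"], max_=data["norm_max"]),
            importance_table=ImportanceTable(
                k=data["imp_k"], I=data["imp_I"], W=data["imp_W"],
                W_combined=data["imp_W_combined"],
            ),
            kpca=kpca,
            classifier=classifier,
            cv_best=tuple(meta["cv_best"]) if meta.get("cv_best") else None,
        )
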