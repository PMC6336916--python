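"""Vertex-wise lesion classification.

Training rows are built from the manually labelled lesion vertices
(label 1) and, for each of them, the homotopic vertex of the healthy
contralateral hemisphere (label 0), which balances the classes by
construction.  Features are PCA-reduced and fed to a small feedforward
neural network (one hidden layer of 10 logistic units by default) trained
on cross-entropy with early stopping on a validation split: 70 % of the
rows train the network and the remaining 30 % are split equally into
validation and test sets.  Subject-level k-fold cross-validation wraps the
whole procedure; per-vertex probability maps are thresholded and connected
suprathreshold components on the mesh become detection clusters.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.sparse.csgraph import connected_components
from sklearn.decomposition import PCA
from sklearn.model_selection import train_test_split
from sklearn.neural_network import MLPClassifier

from .features import FeatureBundle
from .surface import (HomotopicCorrespondence, SurfaceScalarMap,
                      TriangleMesh, VertexLabel)

#: Base per-vertex features, in registry (column) order.
BASE_FEATURES = ["thickness", "gwc", "mean_curvature", "sulcal_depth", "lcd",
                 "flair_00", "flair_25", "flair_50", "flair_75",
                 "flair_m05", "flair_m10", "pet_hypo",
                 "doughnut_gwc", "doughnut_thickness", "doughnut_flair_50"]


def default_registry() -> list[str]:
    """Base features plus the interhemispheric asymmetry of each."""
    return BASE_FEATURES + [f"asym_{n}" for n in BASE_FEATURES]


# ----------------------------------------------------------------------
# subject container
# ----------------------------------------------------------------------

@dataclass
class SubjectFeatures:
    """Normalized feature bundles and labels for one subject."""

    subject_id: str
    bundles: dict[str, FeatureBundle]          # keys 'lh', 'rh'
    corr: HomotopicCorrespondence
    meshes: dict[str, TriangleMesh]            # surface used for clustering
    group: str = "patient"                     # 'patient' or 'control'
    lesion_hemi: str | None = None
    lesion: VertexLabel | None = None
    resection: VertexLabel | None = None

    @property
    def is_patient(self) -> bool:
        return self.group == "patient"


def assemble_training_set(subjects: list[SubjectFeatures],
                          feature_names: list[str] | None = None
                          ) -> pd.DataFrame:
    """Lesion vertices (label 1) plus their contralateral homotopic
    counterparts (label 0), with features in registry order.

    Rows with any masked feature are dropped symmetrically: if either
    member of a homotopic pair is invalid, both rows are dropped, which
    keeps the classes balanced.
    """
    if feature_names is None:
        feature_names = default_registry()
    frames = []
    for subj in subjects:
        if not subj.is_patient:
            continue
        if subj.lesion is None or len(subj.lesion) == 0:
            warnings.warn(f"subject {subj.subject_id}: empty lesion label, "
                          "skipped")
            continue
        hemi = subj.lesion_hemi
        other = "rh" if hemi == "lh" else "lh"
        idx = subj.lesion.indices
        if hemi == "lh":
            hom = subj.corr.left_to_right[idx]
        else:
            hom = subj.corr.right_to_left[idx]
        X_les = subj.bundles[hemi].matrix(feature_names)[idx]
        X_hom = subj.bundles[other].matrix(feature_names)[hom]
        ok = np.isfinite(X_les).all(axis=1) & np.isfinite(X_hom).all(axis=1)
        for hemi_k, verts, X, label in ((hemi, idx[ok], X_les[ok], 1),
                                        (other, hom[ok], X_hom[ok], 0)):
            df = pd.DataFrame(X, columns=feature_names)
            df.insert(0, "label", label)
            df.insert(0, "vertex", verts)
            df.insert(0, "hemisphere", hemi_k)
            df.insert(0, "subject", subj.subject_id)
            frames.append(df)
    if not frames:
        raise ValueError("no training rows: no patient has a usable lesion")
    return pd.concat(frames, ignore_index=True)


# ----------------------------------------------------------------------
# PCA
# ----------------------------------------------------------------------

@dataclass
class PCAModel:
    mean_: np.ndarray
    components_: np.ndarray                    # (k, p_kept)
    explained_variance_ratio_: np.ndarray
    kept_columns: np.ndarray                   # indices into input columns
    retained_variance: float

    @property
    def n_components(self) -> int:
        return len(self.components_)

    def transform(self, X: np.ndarray) -> np.ndarray:
        Xk = np.asarray(X)[:, self.kept_columns]
        return (Xk - self.mean_) @ self.components_.T


def fit_pca(X: np.ndarray, retained_variance: float = 0.95) -> PCAModel:
    """Smallest number of components reaching the retained-variance target.

    Constant columns are dropped with a warning before decomposition;
    ``retained_variance=1.0`` keeps the full numerical rank.
    """
    X = np.asarray(X, dtype=np.float64)
    if not np.all(np.isfinite(X)):
        raise ValueError("feature matrix contains non-finite values")
    ptp = X.max(axis=0) - X.min(axis=0)
    kept = np.flatnonzero(ptp > 0)
    if len(kept) < X.shape[1]:
        warnings.warn(f"dropping {X.shape[1] - len(kept)} constant "
                      "feature columns before PCA")
    Xk = X[:, kept]
    pca = PCA(n_components=None, svd_solver="full")
    pca.fit(Xk)
    evr = pca.explained_variance_ratio_
    if retained_variance >= 1.0:
        tol = max(Xk.shape) * np.finfo(float).eps
        k = int((pca.singular_values_ > tol * pca.singular_values_[0]).sum())
    else:
        k = int(np.searchsorted(np.cumsum(evr), retained_variance) + 1)
        k = min(k, len(evr))
    return PCAModel(mean_=pca.mean_, components_=pca.components_[:k],
                    explained_variance_ratio_=evr[:k], kept_columns=kept,
                    retained_variance=retained_variance)


# ----------------------------------------------------------------------
# feedforward network
# ----------------------------------------------------------------------

@dataclass
class ANNConfig:
    hidden_sizes: tuple[int, ...] = (10,)
    activation: str = "logistic"
    learning_rate: float = 1e-3
    max_epochs: int = 400
    seed: int = 0
    test_fraction: float = 0.15
    val_fraction: float = 0.15
    n_iter_no_change: int = 20


def _sigmoid(x: np.ndarray) -> np.ndarray:
    out = np.empty_like(x)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


_ACTIVATIONS = {"logistic": _sigmoid,
                "tanh": np.tanh,
                "relu": lambda x: np.maximum(x, 0.0),
                "identity": lambda x: x}


@dataclass
class TrainedDetector:
    """Serializable PCA + feedforward-network vertex classifier."""

    feature_names: list[str]
    pca: PCAModel
    weights: list[np.ndarray]                  # layer weight matrices
    biases: list[np.ndarray]
    hidden_activation: str = "logistic"
    out_activation: str = "logistic"
    metadata: dict = field(default_factory=dict)

    @property
    def feature_hash(self) -> str:
        import hashlib
        return hashlib.sha256(
            json.dumps(self.feature_names).encode()).hexdigest()[:16]

    def forward(self, X_pca: np.ndarray) -> np.ndarray:
        act = _ACTIVATIONS[self.hidden_activation]
        h = np.asarray(X_pca, dtype=np.float64)
        for W, b in zip(self.weights[:-1], self.biases[:-1]):
            h = act(h @ W + b)
        z = h @ self.weights[-1] + self.biases[-1]
        return _ACTIVATIONS[self.out_activation](z).ravel()

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        """Lesion probability per row of a raw feature matrix."""
        X = np.asarray(X, dtype=np.float64)
        if X.shape[1] != len(self.feature_names):
            raise ValueError(
                f"expected {len(self.feature_names)} feature columns, "
                f"got {X.shape[1]}")
        return self.forward(self.pca.transform(X))

    # -- persistence ---------------------------------------------------
    def save(self, path) -> None:
        arrays = {"pca_mean": self.pca.mean_,
                  "pca_components": self.pca.components_,
                  "pca_evr": self.pca.explained_variance_ratio_,
                  "pca_kept": self.pca.kept_columns}
        for i, (W, b) in enumerate(zip(self.weights, self.biases)):
            arrays[f"W{i}"] = W
            arrays[f"b{i}"] = b
        manifest = json.dumps({
            "feature_names": self.feature_names,
            "feature_hash": self.feature_hash,
            "n_layers": len(self.weights),
            "hidden_activation": self.hidden_activation,
            "out_activation": self.out_activation,
            "retained_variance": self.pca.retained_variance,
            "metadata": self.metadata})
        np.savez(path, __manifest__=np.frombuffer(manifest.encode(),
                                                  dtype=np.uint8), **arrays)

    @classmethod
    def load(cls, path) -> "TrainedDetector":
        with np.load(path) as z:
            m = json.loads(bytes(z["__manifest__"]).decode())
            pca = PCAModel(mean_=z["pca_mean"],
                           components_=z["pca_components"],
                           explained_variance_ratio_=z["pca_evr"],
                           kept_columns=z["pca_kept"],
                           retained_variance=m["retained_variance"])
            weights = [z[f"W{i}"] for i in range(m["n_layers"])]
            biases = [z[f"b{i}"] for i in range(m["n_layers"])]
        return cls(feature_names=m["feature_names"], pca=pca,
                   weights=weights, biases=biases,
                   hidden_activation=m["hidden_activation"],
                   out_activation=m["out_activation"],
                   metadata=m["metadata"])


def train_ann(X_pca: np.ndarray, y: np.ndarray, config: ANNConfig,
              feature_names: list[str] | None = None,
              pca: PCAModel | None = None) -> TrainedDetector:
    """Train the feedforward network on PCA scores.

    Splits off ``test_fraction`` of the rows for a final held-out estimate;
    the network itself early-stops on a validation split of the remainder
    sized so validation is ``val_fraction`` of the whole (70/15/15 by
    default).  Fully deterministic given ``config.seed``.
    """
    X_pca = np.asarray(X_pca, dtype=np.float64)
    y = np.asarray(y).astype(int).ravel()
    classes = np.unique(y)
    if len(classes) < 2:
        raise ValueError("training labels contain a single class")
    # canonical row order: training is invariant to input permutations
    order = np.lexsort(np.column_stack([X_pca, y]).T[::-1])
    X_pca, y = X_pca[order], y[order]
    X_rest, X_te, y_rest, y_te = train_test_split(
        X_pca, y, test_size=config.test_fraction, stratify=y,
        random_state=config.seed)
    val_of_rest = config.val_fraction / (1.0 - config.test_fraction)
    X_tr, X_va, y_tr, y_va = train_test_split(
        X_rest, y_rest, test_size=val_of_rest, stratify=y_rest,
        random_state=config.seed + 1)
    clf = MLPClassifier(hidden_layer_sizes=config.hidden_sizes,
                        activation=config.activation,
                        solver="adam",
                        learning_rate_init=config.learning_rate,
                        max_iter=1,
                        random_state=config.seed)
    # one adam epoch per partial_fit call; early stopping monitors the
    # validation cross-entropy and the best-epoch weights are restored
    best_loss = np.inf
    best_weights = None
    epochs_run = 0
    stall = 0
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for epoch in range(config.max_epochs):
            clf.partial_fit(X_tr, y_tr, classes=[0, 1])
            epochs_run = epoch + 1
            p_va = np.clip(clf.predict_proba(X_va)[:, 1], 1e-12, 1 - 1e-12)
            val_loss = -np.mean(y_va * np.log(p_va) +
                                (1 - y_va) * np.log(1 - p_va))
            if not np.isfinite(val_loss) or not np.isfinite(clf.loss_):
                raise RuntimeError(f"training diverged at epoch {epoch}: "
                                   f"loss={clf.loss_}, val={val_loss}")
            if val_loss < best_loss - 1e-6:
                best_loss = val_loss
                best_weights = ([W.copy() for W in clf.coefs_],
                                [b.copy() for b in clf.intercepts_])
                stall = 0
            else:
                stall += 1
                if stall >= config.n_iter_no_change:
                    break
    if best_weights is not None:
        clf.coefs_, clf.intercepts_ = best_weights
    clf.n_iter_ = epochs_run
    if pca is None:
        # identity PCA over the score space
        p = X_pca.shape[1]
        pca = PCAModel(mean_=np.zeros(p), components_=np.eye(p),
                       explained_variance_ratio_=np.ones(p) / p,
                       kept_columns=np.arange(p), retained_variance=1.0)
    det = TrainedDetector(
        feature_names=feature_names or
        [f"pc{i}" for i in range(X_pca.shape[1])],
        pca=pca,
        weights=[np.asarray(W) for W in clf.coefs_],
        biases=[np.asarray(b).ravel() for b in clf.intercepts_],
        hidden_activation=config.activation,
        out_activation="logistic",
        metadata={"seed": config.seed, "epochs_run": int(clf.n_iter_),
                  "loss": float(clf.loss_),
                  "val_loss": float(best_loss),
                  "train_accuracy": float(clf.score(X_tr, y_tr)),
                  "test_accuracy": float(clf.score(X_te, y_te)),
                  "split": [1 - config.test_fraction - config.val_fraction,
                            config.val_fraction, config.test_fraction]})
    return det


def train_detector(X: np.ndarray, y: np.ndarray,
                   feature_names: list[str],
                   retained_variance: float = 0.95,
                   config: ANNConfig | None = None) -> TrainedDetector:
    """PCA reduction followed by network training on the scores."""
    config = config or ANNConfig()
    pca = fit_pca(X, retained_variance)
    det = train_ann(pca.transform(X), y, config,
                    feature_names=feature_names, pca=pca)
    return det


# ----------------------------------------------------------------------
# probability maps and clusters
# ----------------------------------------------------------------------

def predict_probability_map(detector: TrainedDetector,
                            bundle: FeatureBundle) -> SurfaceScalarMap:
    """Per-vertex lesion probability; masked vertices stay NaN."""
    missing = [n for n in detector.feature_names if n not in bundle]
    if missing:
        raise KeyError(f"bundle lacks features required by the detector: "
                       f"{missing}")
    X = bundle.matrix(detector.feature_names)
    ok = np.isfinite(X).all(axis=1)
    probs = np.full(len(X), np.nan)
    if ok.any():
        probs[ok] = detector.predict_proba(X[ok])
    return SurfaceScalarMap(probs, name="lesion_probability", units="p")


@dataclass
class DetectionCluster:
    vertices: np.ndarray
    peak_probability: float
    area_mm2: float
    centroid_vertex: int
    hemisphere: str | None = None


def threshold_and_cluster(prob_map: SurfaceScalarMap, mesh: TriangleMesh,
                          threshold: float,
                          min_area_mm2: float = 0.0,
                          hemisphere: str | None = None
                          ) -> list[DetectionCluster]:
    """Connected suprathreshold components, largest peak first."""
    if not 0.0 < threshold < 1.0:
        raise ValueError("threshold must be in (0, 1)")
    prob_map.check_mesh(mesh)
    p = prob_map.values
    supra = np.flatnonzero(np.nan_to_num(p, nan=-1.0) >= threshold)
    if supra.size == 0:
        return []
    sub = mesh.adjacency[supra][:, supra]
    n_comp, labels = connected_components(sub, directed=False)
    areas = mesh.vertex_areas
    clusters = []
    for c in range(n_comp):
        verts = supra[labels == c]
        area = float(areas[verts].sum())
        if area < min_area_mm2:
            continue
        peak_local = verts[np.argmax(p[verts])]
        w = areas[verts][:, None]
        center = (mesh.vertices[verts] * w).sum(axis=0) / w.sum()
        d2 = np.sum((mesh.vertices[verts] - center) ** 2, axis=1)
        clusters.append(DetectionCluster(
            vertices=verts, peak_probability=float(p[peak_local]),
            area_mm2=area, centroid_vertex=int(verts[np.argmin(d2)]),
            hemisphere=hemisphere))
    clusters.sort(key=lambda c: -c.peak_probability)
    return clusters


def subject_probability_maps(detector: TrainedDetector,
                             subject: SubjectFeatures
                             ) -> dict[str, SurfaceScalarMap]:
    return {h: predict_probability_map(detector, b)
            for h, b in subject.bundles.items()}


def detect_subject(subject: SubjectFeatures,
                   prob_maps: dict[str, SurfaceScalarMap],
                   threshold: float,
                   min_area_mm2: float = 25.0) -> dict:
    """Patient-level call: clusters on both hemispheres, 'major' cluster =
    highest peak probability; a patient is detected when the major cluster
    overlaps the lesion label."""
    clusters: list[DetectionCluster] = []
    for hemi, pmap in prob_maps.items():
        clusters.extend(threshold_and_cluster(
            pmap, subject.meshes[hemi], threshold, min_area_mm2,
            hemisphere=hemi))
    clusters.sort(key=lambda c: -c.peak_probability)
    detected = False
    if clusters and subject.lesion is not None and len(subject.lesion):
        top = clusters[0]
        if top.hemisphere == subject.lesion_hemi:
            detected = bool(np.intersect1d(top.vertices,
                                           subject.lesion.indices).size)
    return {"clusters": clusters, "any_cluster": bool(clusters),
            "detected": detected}


def choose_threshold(subjects: list[SubjectFeatures],
                     prob_maps: dict[str, dict[str, SurfaceScalarMap]],
                     grid: np.ndarray | None = None,
                     min_area_mm2: float = 25.0) -> float:
    """Probability threshold maximizing Youden J = detection rate minus
    control false-positive rate over the supplied subjects.  Ties resolve
    to the highest threshold."""
    if grid is None:
        grid = np.round(np.arange(0.50, 0.96, 0.05), 2)
    patients = [s for s in subjects if s.is_patient]
    controls = [s for s in subjects if not s.is_patient]
    best_t, best_j = float(grid[0]), -np.inf
    for t in grid:
        det = fp = 0
        for s in patients:
            det += detect_subject(s, prob_maps[s.subject_id], t,
                                  min_area_mm2)["detected"]
        for s in controls:
            fp += detect_subject(s, prob_maps[s.subject_id], t,
                                 min_area_mm2)["any_cluster"]
        j = (det / len(patients) if patients else 0.0) - \
            (fp / len(controls) if controls else 0.0)
        if j >= best_j:
            best_j, best_t = j, float(t)
    return best_t


# ----------------------------------------------------------------------
# cross-validation
# ----------------------------------------------------------------------

@dataclass
class CrossValidationResult:
    fold_metrics: pd.DataFrame
    per_subject: pd.DataFrame
    aggregate: dict

    @property
    def detection_rate(self) -> float:
        pat = self.per_subject[self.per_subject.group == "patient"]
        return float((pat.times_detected > 0.5 * pat.times_held_out).mean())

    @property
    def control_fp_rate(self) -> float:
        con = self.per_subject[self.per_subject.group == "control"]
        return float((con.times_flagged > 0.5 * con.times_held_out).mean())


def _stratified_folds(subjects: list[SubjectFeatures], k: int,
                      rng: np.random.Generator) -> list[list[SubjectFeatures]]:
    folds: list[list[SubjectFeatures]] = [[] for _ in range(k)]
    for group in ("patient", "control"):
        members = [s for s in subjects if s.group == group]
        order = rng.permutation(len(members))
        offset = int(rng.integers(k))
        for pos, idx in enumerate(order):
            folds[(pos + offset) % k].append(members[idx])
    return folds


def cross_validate(subjects: list[SubjectFeatures], k: int = 5,
                   iterations: int = 100, seed: int = 0,
                   feature_names: list[str] | None = None,
                   retained_variance: float = 0.95,
                   ann_config: ANNConfig | None = None,
                   min_area_mm2: float = 25.0,
                   threshold_grid: np.ndarray | None = None
                   ) -> CrossValidationResult:
    """Subject-level k-fold cross-validation repeated ``iterations`` times.

    Fold assignment is at subject level (vertex-level folds would leak
    within-subject correlation) and stratified by group so every fold holds
    both patients and controls.  Each fold trains a fresh PCA + network on
    the remaining subjects, picks its probability threshold by Youden J on
    those training subjects, and evaluates the held-out subjects at patient
    level.  Deterministic given ``seed``.
    """
    if k < 2:
        raise ValueError("k must be >= 2")
    n_pat = sum(s.is_patient for s in subjects)
    n_con = len(subjects) - n_pat
    if n_pat < k or len(subjects) < k:
        raise ValueError(f"need at least k={k} patients to fold "
                         f"(have {n_pat})")
    feature_names = feature_names or default_registry()
    rng = np.random.default_rng(seed)
    rows = []
    counts = {s.subject_id: {"group": s.group, "held": 0, "detected": 0,
                             "flagged": 0} for s in subjects}
    for it in range(iterations):
        folds = _stratified_folds(subjects, k, rng)
        for fi, held_out in enumerate(folds):
            train_subjects = [s for f in folds for s in f
                              if f is not held_out]
            df = assemble_training_set(train_subjects, feature_names)
            X = df[feature_names].to_numpy()
            y = df["label"].to_numpy()
            cfg = ann_config or ANNConfig()
            cfg = ANNConfig(**{**cfg.__dict__,
                               "seed": int(rng.integers(2 ** 31))})
            det = train_detector(X, y, feature_names, retained_variance, cfg)
            pm = {s.subject_id: subject_probability_maps(det, s)
                  for s in train_subjects + held_out}
            thr = choose_threshold(train_subjects, pm, threshold_grid,
                                   min_area_mm2)
            tp = fn = fp = tn = 0
            for s in held_out:
                res = detect_subject(s, pm[s.subject_id], thr, min_area_mm2)
                counts[s.subject_id]["held"] += 1
                if s.is_patient:
                    counts[s.subject_id]["detected"] += res["detected"]
                    tp += res["detected"]
                    fn += not res["detected"]
                else:
                    counts[s.subject_id]["flagged"] += res["any_cluster"]
                    fp += res["any_cluster"]
                    tn += not res["any_cluster"]
            total = tp + fn + fp + tn
            rows.append({"iteration": it, "fold": fi, "threshold": thr,
                         "tp": tp, "fn": fn, "fp": fp, "tn": tn,
                         "sensitivity": tp / (tp + fn) if tp + fn else np.nan,
                         "specificity": tn / (tn + fp) if tn + fp else np.nan,
                         "accuracy": (tp + tn) / total if total else np.nan})
    fold_metrics = pd.DataFrame(rows)
    per_subject = pd.DataFrame(
        [{"subject": sid, "group": c["group"], "times_held_out": c["held"],
          "times_detected": c["detected"], "times_flagged": c["flagged"]}
         for sid, c in counts.items()])
    agg = {}
    for m in ("sensitivity", "specificity", "accuracy"):
        agg[f"{m}_mean"] = float(fold_metrics[m].mean())
        agg[f"{m}_sd"] = float(fold_metrics[m].std(ddof=1))
    return CrossValidationResult(fold_metrics=fold_metrics,
                                 per_subject=per_subject, aggregate=agg)
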