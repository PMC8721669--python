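"""TLS composition clustering and cross-cohort assignment.

The procedure: per-TLS densities of the five composition features get a
pseudo-count ε (default 0.01 cells/mm²), a natural-log transform, and a
z-scale using the mean and sample SD of the *training* (untreated) cohort.
k-means (Lloyd, k-means++ seeding, ``n_init`` restarts, best WSS kept) is
fitted over a range of k; the elbow — the k maximizing the second difference
of the within-cluster-sum-of-squares curve — selects k. A new (e.g. treated)
cohort is assigned by nearest centroid in the frozen scaled space; means,
SDs and centroids are never refitted on the new cohort.

WSS monotonicity in k is guaranteed by augmenting each k's restarts with a
warm start that splits the loosest cluster of the k−1 solution.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans

from .errors import ConfigError, InputError, SchemaError
from .phenotyping import TLS_FEATURES

log = logging.getLogger(__name__)

FEATURE_COLUMNS = tuple(f"density_{ph}" for ph in TLS_FEATURES)


@dataclass
class ScalingModel:
    """Frozen ε/log/z-score transform fitted on the training cohort."""

    pseudo_count: float
    mean: np.ndarray
    sd: np.ndarray
    feature_names: tuple[str, ...] = TLS_FEATURES
    log_base: str = "e"
    sd_ddof: int = 1

    def transform(self, densities: np.ndarray) -> np.ndarray:
        x = np.log(np.asarray(densities, float) + self.pseudo_count)
        return (x - self.mean) / self.sd

    def to_dict(self) -> dict:
        return {
            "pseudo_count": self.pseudo_count,
            "mean": self.mean.tolist(),
            "sd": self.sd.tolist(),
            "feature_names": list(self.feature_names),
            "log_base": self.log_base,
            "sd_ddof": self.sd_ddof,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ScalingModel":
        return cls(
            pseudo_count=d["pseudo_count"],
            mean=np.asarray(d["mean"], float),
            sd=np.asarray(d["sd"], float),
            feature_names=tuple(d["feature_names"]),
            log_base=d.get("log_base", "e"),
            sd_ddof=d.get("sd_ddof", 1),
        )


def preprocess(
    features: np.ndarray,
    pseudo_count: float = 0.01,
    scaling: ScalingModel | None = None,
) -> tuple[np.ndarray, ScalingModel]:
    """ε-shifted log z-scaling of a TLS × feature density matrix.

    When no :class:`ScalingModel` is given one is fitted (columns of the
    output then have mean 0 and sample SD 1); otherwise the stored
    training-cohort transform is applied unchanged.
    """
    features = np.asarray(features, float)
    if features.ndim != 2:
        raise InputError("feature matrix must be 2-D (TLS × features)")
    if (features < 0).any():
        raise InputError("densities must be nonnegative")
    if scaling is None:
        x = np.log(features + pseudo_count)
        mean = x.mean(axis=0)
        sd = x.std(axis=0, ddof=1)
        degenerate = (sd < 1e-9) | ~np.isfinite(sd)
        if degenerate.any():
            bad = int(np.where(degenerate)[0][0])
            raise InputError(
                f"degenerate feature {TLS_FEATURES[bad]!r}: zero variance"
            )
        scaling = ScalingModel(pseudo_count=pseudo_count, mean=mean, sd=sd)
        return (x - mean) / sd, scaling
    if features.shape[1] != len(scaling.feature_names):
        raise SchemaError("feature count does not match scaling model")
    return scaling.transform(features), scaling


@dataclass
class KMeansModel:
    """k-means fit over a k range, with WSS curve and chosen-k centroids."""

    k_range: tuple[int, ...]
    wss: dict[int, float]
    centroids_by_k: dict[int, np.ndarray]
    seed: int
    n_init: int
    max_iter: int
    k: int | None = None
    converged: dict[int, bool] = field(default_factory=dict)
    label_order_by_k: dict[int, np.ndarray] = field(default_factory=dict)

    @property
    def centroids(self) -> np.ndarray:
        if self.k is None:
            raise ConfigError("k not selected yet")
        return self.centroids_by_k[self.k]

    def wss_curve(self) -> np.ndarray:
        return np.array([self.wss[k] for k in self.k_range])

    def to_dict(self) -> dict:
        return {
            "k": self.k,
            "k_range": list(self.k_range),
            "wss": {str(k): v for k, v in self.wss.items()},
            "centroids": None if self.k is None else self.centroids.tolist(),
            "seed": self.seed,
            "n_init": self.n_init,
            "max_iter": self.max_iter,
            "label_order": "descending centroid total (scaled space), 1-based",
        }

    @classmethod
    def from_dict(cls, d: dict) -> "KMeansModel":
        k = d["k"]
        model = cls(
            k_range=tuple(d["k_range"]),
            wss={int(kk): v for kk, v in d["wss"].items()},
            centroids_by_k={},
            seed=d["seed"],
            n_init=d["n_init"],
            max_iter=d["max_iter"],
            k=k,
        )
        if k is not None:
            model.centroids_by_k[k] = np.asarray(d["centroids"], float)
        return model


def _order_labels(centroids: np.ndarray) -> np.ndarray:
    """Renumber clusters by descending centroid total in scaled space.

    k-means labels are arbitrary; a deterministic order (cluster 1 = highest
    overall scaled density) makes labels comparable across runs.
    """
    totals = centroids.sum(axis=1)
    return np.argsort(-totals, kind="stable")


def fit_kmeans(
    scaled: np.ndarray,
    k_range: tuple[int, ...] = tuple(range(1, 11)),
    max_iter: int = 300,
    n_init: int = 10,
    seed: int = 0,
) -> KMeansModel:
    """Fit k-means for every k in ``k_range``; keep best-WSS solutions.

    For each k, ``n_init`` k-means++ restarts plus one warm start derived
    from the previous k's solution with its loosest cluster split — this
    nested initialization makes the WSS curve non-increasing in k.
    Deterministic given ``seed``.
    """
    scaled = np.asarray(scaled, float)
    n = scaled.shape[0]
    if n < max(k_range):
        raise ConfigError(
            f"{n} rows cannot support k up to {max(k_range)}"
        )
    wss: dict[int, float] = {}
    cents: dict[int, np.ndarray] = {}
    converged: dict[int, bool] = {}
    orders: dict[int, np.ndarray] = {}
    prev_centroids: np.ndarray | None = None
    for k in k_range:
        km = KMeans(
            n_clusters=k,
            init="k-means++",
            n_init=n_init,
            max_iter=max_iter,
            random_state=seed,
        ).fit(scaled)
        best_inertia, best_centers, best_iter = (
            km.inertia_, km.cluster_centers_, km.n_iter_,
        )
        if prev_centroids is not None and len(prev_centroids) == k - 1:
            warm = _split_loosest(scaled, prev_centroids)
            km_w = KMeans(
                n_clusters=k, init=warm, n_init=1, max_iter=max_iter
            ).fit(scaled)
            if km_w.inertia_ < best_inertia:
                best_inertia, best_centers, best_iter = (
                    km_w.inertia_, km_w.cluster_centers_, km_w.n_iter_,
                )
        wss[k] = float(best_inertia)
        cents[k] = best_centers
        converged[k] = bool(best_iter < max_iter)
        orders[k] = _order_labels(best_centers)
        prev_centroids = best_centers
    return KMeansModel(
        k_range=tuple(k_range),
        wss=wss,
        centroids_by_k=cents,
        seed=seed,
        n_init=n_init,
        max_iter=max_iter,
        converged=converged,
        label_order_by_k=orders,
    )


def _split_loosest(scaled: np.ndarray, centroids: np.ndarray) -> np.ndarray:
    """Warm start for k+1: previous centroids plus the point farthest from
    its assigned centroid (splitting the loosest cluster)."""
    d2 = ((scaled[:, None, :] - centroids[None, :, :]) ** 2).sum(-1)
    worst = int(np.argmax(d2.min(axis=1)))
    return np.vstack([centroids, scaled[worst]])


def select_k(
    wss_curve: np.ndarray | dict[int, float],
    mode: str = "elbow",
    k_range: tuple[int, ...] | None = None,
) -> int:
    """Choose k: ``elbow`` maximizes the second difference of WSS;
    ``fixed:<k>`` returns the requested k."""
    if isinstance(wss_curve, dict):
        k_range = tuple(sorted(wss_curve))
        wss = np.array([wss_curve[k] for k in k_range])
    else:
        wss = np.asarray(wss_curve, float)
        if k_range is None:
            k_range = tuple(range(1, len(wss) + 1))
    if mode.startswith("fixed:"):
        k = int(mode.split(":", 1)[1])
        if k not in k_range:
            raise ConfigError(f"fixed k={k} outside k_range {k_range}")
        log.info("k selection mode=fixed -> k=%d", k)
        return k
    if mode != "elbow":
        raise ConfigError(f"unknown k-selection mode {mode!r}")
    if len(wss) < 3:
        raise ConfigError("elbow selection needs a WSS curve over >= 3 k values")
    d2 = wss[:-2] - 2 * wss[1:-1] + wss[2:]
    if np.allclose(d2, 0):
        log.warning("WSS decays linearly; elbow undefined, returning smallest k")
        return k_range[0]
    k = k_range[int(np.argmax(d2)) + 1]
    log.info("k selection mode=elbow -> k=%d", k)
    return k


@dataclass
class ClusterAssignment:
    """Nearest-centroid labels (1-based) and distances in scaled space."""

    labels: np.ndarray
    distances: np.ndarray


def assign(
    features_new: np.ndarray,
    scaling: ScalingModel,
    model: KMeansModel,
) -> ClusterAssignment:
    """Assign TLS to the nearest trained centroid.

    ``features_new`` are raw densities; they are scaled with the *training*
    cohort's stored means/SDs, never refitted. Ties go to the lowest label.
    Labels are 1-based in the deterministic descending-total order.
    """
    z, _ = preprocess(features_new, scaling.pseudo_count, scaling)
    centroids = model.centroids
    order = _order_labels(centroids)
    d = np.sqrt(((z[:, None, :] - centroids[None, order, :]) ** 2).sum(-1))
    labels = np.argmin(d, axis=1) + 1  # argmin takes the lowest index on ties
    return ClusterAssignment(
        labels=labels, distances=d[np.arange(len(labels)), labels - 1]
    )


def training_labels(
    scaled: np.ndarray, model: KMeansModel
) -> np.ndarray:
    """1-based nearest-centroid labels of the training matrix itself."""
    centroids = model.centroids
    order = _order_labels(centroids)
    d = ((scaled[:, None, :] - centroids[None, order, :]) ** 2).sum(-1)
    return np.argmin(d, axis=1) + 1


def cluster_summaries(
    records: pd.DataFrame, manifest: pd.DataFrame, k: int
) -> pd.DataFrame:
    """Per-patient TLS cluster fractions by count and by relative area.

    Fractions over clusters sum to 1 per patient for both measures; patients
    with zero TLS are excluded (logged). Outcome labels are joined from the
    manifest for group comparisons.
    """
    if "cluster" not in records.columns:
        raise SchemaError("records have no cluster labels")
    rows = []
    outcomes = manifest.set_index("patient_id")["outcome"]
    cohorts = manifest.set_index("patient_id")["cohort"]
    for pid in manifest["patient_id"]:
        grp = records[records["patient_id"] == pid]
        if grp.empty:
            log.info("patient %s excluded from cluster summaries: zero TLS", pid)
            continue
        total_n = len(grp)
        total_area = grp["area_mm2"].sum()
        for c in range(1, k + 1):
            sub = grp[grp["cluster"] == c]
            rows.append(
                {
                    "patient_id": pid,
                    "cohort": cohorts[pid],
                    "outcome": outcomes[pid],
                    "cluster": c,
                    "n_tls": len(sub),
                    "count_fraction": len(sub) / total_n,
                    "area_fraction": sub["area_mm2"].sum() / total_area,
                }
            )
    return pd.DataFrame(rows)


def save_model(
    path: str | Path, scaling: ScalingModel, model: KMeansModel,
    extra: dict | None = None,
) -> None:
    """Serialize scaling + k-means model to JSON (bit-exact re-assignment)."""
    doc = {"scaling": scaling.to_dict(), "kmeans": model.to_dict()}
    if extra:
        doc.update(extra)
    with open(path, "w") as fh:
        json.dump(doc, fh, indent=1)


def load_model(path: str | Path) -> tuple[ScalingModel, KMeansModel]:
    with open(path) as fh:
        doc = json.load(fh)
    return (
        ScalingModel.from_dict(doc["scaling"]),
        KMeansModel.from_dict(doc["kmeans"]),
    )
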