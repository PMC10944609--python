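"""Integration benchmarking: k-means labeling, ARI/NMI against ground-truth
cell types, silhouette-derived batch-mixing (BASW) and cell-purity (CASW)
scores with their arithmetic (ASW) and harmonic (F1) combinations, and the
repeated stratified-subsampling protocol.

Conventions: silhouettes use Euclidean distance on the embedding as given;
CASW = (1 + s_celltype)/2 rescales the mean cell-type silhouette to [0, 1]
(higher = purer clusters); BASW = 1 - (1 + s_batch)/2 so that well-mixed
batches (negative or zero batch silhouette) score high. ASW is the
arithmetic mean of the two and F1 their harmonic mean, so F1 <= ASW always.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans
from sklearn.metrics import (
    adjusted_rand_score,
    normalized_mutual_info_score,
    silhouette_samples,
)

logger = logging.getLogger(__name__)

__all__ = ["MetricsReport", "kmeans_labels", "ari", "nmi", "asw_components", "evaluate"]

METRIC_NAMES = ("ARI", "NMI", "BASW", "CASW", "ASW", "F1")


@dataclass
class MetricsReport:
    """Per-replicate metric values plus their mean and standard deviation."""

    replicates: pd.DataFrame  # one row per replicate, columns METRIC_NAMES
    k: int
    fraction: float

    @property
    def n_replicates(self) -> int:
        return len(self.replicates)

    @property
    def mean(self) -> pd.Series:
        return self.replicates.mean()

    @property
    def sd(self) -> pd.Series:
        return self.replicates.std(ddof=1) if len(self.replicates) > 1 else self.replicates.iloc[0] * 0.0

    def to_json(self, path: str | Path | None = None) -> dict:
        payload = {
            "n_replicates": self.n_replicates,
            "fraction": self.fraction,
            "k": self.k,
            "mean": {k: float(v) for k, v in self.mean.items()},
            "sd": {k: float(v) for k, v in self.sd.items()},
            "replicates": self.replicates.to_dict(orient="records"),
        }
        if path is not None:
            Path(path).write_text(json.dumps(payload, indent=2))
        return payload

    def to_csv(self, path: str | Path) -> None:
        frame = self.replicates.copy()
        frame.insert(0, "replicate", np.arange(1, len(frame) + 1))
        summary = pd.DataFrame([["mean", *self.mean.tolist()], ["sd", *self.sd.tolist()]],
                               columns=frame.columns)
        pd.concat([frame, summary]).to_csv(path, index=False)


def kmeans_labels(Z: np.ndarray, n_clusters: int, seed: int = 0) -> np.ndarray:
    """Deterministic k-means labeling of an embedding."""
    if n_clusters > len(Z):
        raise ValueError("n_clusters exceeds the number of points")
    km = KMeans(n_clusters=n_clusters, random_state=seed, n_init=10)
    return km.fit_predict(np.asarray(Z, dtype=np.float64))


def ari(labels_a, labels_b) -> float:
    return float(adjusted_rand_score(labels_a, labels_b))


def nmi(labels_a, labels_b) -> float:
    return float(normalized_mutual_info_score(labels_a, labels_b))


def _mean_silhouette(Z: np.ndarray, labels: np.ndarray) -> float:
    labels = np.asarray(labels)
    uniq, counts = np.unique(labels, return_counts=True)
    if len(uniq) < 2:
        logger.info("silhouette: single label class; mean silhouette set to 0")
        return 0.0
    if (counts < 2).any():
        logger.info("silhouette: %d singleton classes contribute 0", int((counts < 2).sum()))
    return float(silhouette_samples(np.asarray(Z, dtype=np.float64), labels).mean())


def asw_components(Z: np.ndarray, celltype_labels, batch_labels) -> tuple[float, float, float, float]:
    """(BASW, CASW, ASW, F1) from the embedding and the two label vectors."""
    s_cell = _mean_silhouette(Z, np.asarray(celltype_labels))
    s_batch = _mean_silhouette(Z, np.asarray(batch_labels))
    casw = (1.0 + s_cell) / 2.0
    basw = 1.0 - (1.0 + s_batch) / 2.0
    asw = (basw + casw) / 2.0
    f1 = 0.0 if basw + casw == 0 else 2.0 * basw * casw / (basw + casw)
    return basw, casw, asw, f1


def evaluate(
    Z: np.ndarray,
    celltype_labels,
    batch_labels,
    n_replicates: int = 10,
    fraction: float = 0.95,
    seed: int = 0,
) -> MetricsReport:
    """Repeated stratified-subsampling evaluation on an embedding.

    Each replicate keeps ceil(fraction * n_t) cells of every cell type,
    clusters the subsample with k-means (k = number of cell types present)
    and computes all six metrics. ``fraction=1, n_replicates=1`` is the
    no-sampling path used for large datasets.
    """
    Z = np.asarray(Z, dtype=np.float64)
    celltype_labels = np.asarray([str(x) for x in celltype_labels])
    batch_labels = np.asarray([str(x) for x in batch_labels])
    rng = np.random.default_rng(seed)
    types = np.unique(celltype_labels)
    rows = []
    for _ in range(n_replicates):
        keep = []
        for t in types:
            idx = np.flatnonzero(celltype_labels == t)
            n_keep = int(np.ceil(fraction * idx.size))
            keep.append(rng.choice(idx, size=n_keep, replace=False) if n_keep < idx.size else idx)
        keep = np.sort(np.concatenate(keep))
        Zs, cts, bts = Z[keep], celltype_labels[keep], batch_labels[keep]
        k = len(np.unique(cts))
        pred = kmeans_labels(Zs, k, seed=seed)
        basw, casw, asw, f1 = asw_components(Zs, cts, bts)
        rows.append({"ARI": ari(cts, pred), "NMI": nmi(cts, pred),
                     "BASW": basw, "CASW": casw, "ASW": asw, "F1": f1})
    return MetricsReport(replicates=pd.DataFrame(rows), k=len(types), fraction=fraction)
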