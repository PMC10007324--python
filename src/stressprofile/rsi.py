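"""The Resilience to Stress Index (RSI).

Each stage of a stress profile forms its own cluster of standardized
physiological samples; the geometry of the stage centroids summarizes how
far the subject's physiology was pushed and how far it came back.  With

* ΔR — the Euclidean distance between the centroids of the last two
  stages (the final stressor and the final recovery), and
* ΔS — the largest Euclidean distance from the baseline centroid to any
  other stage centroid (the maximal excursion),

the index is RSI = ΔR / ΔS.  A value near 1 means the subject moved all
the way back from the maximal excursion toward their own baseline; values
near 0 mean the final recovery left physiology where the last stressor
put it.

Centroids are computed in full-rank PCA space.  Because every principal
component is retained, the PCA is an orthogonal transform and preserves
Euclidean distances exactly: the index is identical whether computed on
PCA scores or directly on the standardized channels.  The rotation is
kept because it decorrelates the axes and makes the per-stage clusters
directly plottable, not because it changes the index.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np
from sklearn.decomposition import PCA

from .preprocess import PreprocessConfig, preprocess_session
from .protocol import ProtocolDefinition, Recording, StageSegments

__all__ = [
    "PCAModel",
    "StageCentroids",
    "RSIResult",
    "fit_full_pca",
    "stage_centroids",
    "compute_rsi",
    "session_rsi",
]


@dataclass(frozen=True)
class PCAModel:
    """Full-rank PCA fit: orthonormal loadings, centering offsets and
    explained-variance fractions."""

    loadings: np.ndarray  # (n_features, n_components), columns orthonormal
    mean: np.ndarray
    explained_variance_ratio: np.ndarray

    def transform(self, X: np.ndarray) -> np.ndarray:
        return (np.asarray(X, dtype=float) - self.mean) @ self.loadings


class StageCentroids(dict):
    """Map stage index -> centroid vector of that stage's transformed samples."""


def fit_full_pca(matrix: np.ndarray) -> tuple[PCAModel, np.ndarray]:
    """Fit PCA retaining all components and return the model and scores.

    The input should already be standardized.  All components are kept, so
    the scores are a rotation of the centered input and pairwise Euclidean
    distances are preserved.  A constant channel is rejected (it should
    have been caught by the scaler upstream); perfectly collinear channels
    are allowed and simply produce a zero explained-variance component.
    """
    X = np.asarray(matrix, dtype=float)
    if X.ndim != 2:
        raise ValueError("fit_full_pca expects a 2-D matrix")
    n, p = X.shape
    if n < p:
        raise ValueError(f"need at least as many rows ({n}) as channels ({p})")
    bad = np.flatnonzero(X.std(axis=0) <= 0)
    if bad.size:
        raise ValueError(f"rank-deficient input: constant channel(s) at column {bad.tolist()}")
    pca = PCA(n_components=p, svd_solver="full")
    scores = pca.fit_transform(X)
    model = PCAModel(
        loadings=pca.components_.T,
        mean=pca.mean_,
        explained_variance_ratio=pca.explained_variance_ratio_,
    )
    return model, scores


def stage_centroids(scores: np.ndarray, segments: StageSegments) -> StageCentroids:
    """Arithmetic mean of each stage's score rows."""
    S = np.asarray(scores, dtype=float)
    out = StageCentroids()
    for k in sorted(segments):
        start, end = segments[k]
        if end <= start:
            raise ValueError(f"stage {k} is empty")
        out[k] = S[start:end].mean(axis=0)
    return out


@dataclass(frozen=True)
class RSIResult:
    """RSI for one session, with the distances it is built from.

    baseline_distances[i] is the distance from the baseline centroid to
    stage i+2 (stages 2..K); delta_s is their maximum.
    """

    subject_id: str
    session: str
    delta_r: float
    delta_s: float
    rsi: float
    baseline_distances: np.ndarray
    n_components: int

    def to_dict(self) -> dict:
        return {
            "subject": self.subject_id,
            "session": self.session,
            "delta_r": self.delta_r,
            "delta_s": self.delta_s,
            "rsi": self.rsi,
            "baseline_distances": [float(d) for d in self.baseline_distances],
            "n_components": self.n_components,
        }

    def to_json(self, **kwargs) -> str:
        return json.dumps(self.to_dict(), **kwargs)


def compute_rsi(
    centroids: StageCentroids,
    protocol: ProtocolDefinition,
    *,
    subject_id: str = "",
    session: str = "other",
    clip: bool = False,
) -> RSIResult:
    """Evaluate RSI = ΔR / ΔS from the per-stage centroids.

    ΔR is the distance between the centroids of the last two stages; ΔS is
    the maximum distance from the baseline (stage 1) centroid to any later
    stage centroid.  The ratio is not clipped by default; ``clip=True``
    caps it at 1 for presentation alongside cohorts reported that way.
    """
    K = protocol.n_stages
    missing = [k for k in range(1, K + 1) if k not in centroids]
    if missing:
        raise ValueError(f"missing centroid(s) for stage(s) {missing}")
    c = {k: np.asarray(centroids[k], dtype=float) for k in range(1, K + 1)}
    delta_r = float(np.linalg.norm(c[K - 1] - c[K]))
    baseline_distances = np.array(
        [np.linalg.norm(c[1] - c[k]) for k in range(2, K + 1)], dtype=float
    )
    delta_s = float(baseline_distances.max())
    if delta_s == 0.0:
        raise ValueError("degenerate session: every stage centroid coincides with the baseline")
    rsi = delta_r / delta_s
    if clip:
        rsi = min(rsi, 1.0)
    return RSIResult(
        subject_id=subject_id,
        session=session,
        delta_r=delta_r,
        delta_s=delta_s,
        rsi=rsi,
        baseline_distances=baseline_distances,
        n_components=c[1].size,
    )


def session_rsi(
    recording: Recording,
    protocol: ProtocolDefinition,
    config: PreprocessConfig | None = None,
    *,
    use_pca: bool = True,
    clip: bool = False,
) -> RSIResult:
    """Full per-session pipeline: preprocess, (PCA), centroids, RSI.

    Standardization and PCA are fit on this session alone — every session
    is measured against its own calibration.  ``use_pca=False`` skips the
    rotation; by orthogonal invariance the result is unchanged.
    """
    cfg = config or PreprocessConfig()
    clean, segments, _ = preprocess_session(recording, protocol, cfg)
    X = clean.samples
    if use_pca:
        _, X = fit_full_pca(X)
    centroids = stage_centroids(X, segments)
    return compute_rsi(
        centroids,
        protocol,
        subject_id=recording.subject_id,
        session=recording.session,
        clip=clip,
    )
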