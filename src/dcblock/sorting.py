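"""Template spike sorting: PCA + k-means on concatenated 3-channel waveforms,
inter-spike-interval (ISI) contamination refinement, and transfer of the
template clustering solution to other recording sets of the same response.

The template recording is a pre-DC set.  Waveforms are concatenated across
the three channels of the group, reduced to the first 10 principal
components, and clustered with k-means; k is chosen from a candidate range
by maximum mean silhouette.  Clusters with >= 1% of ISIs <= 1 ms are isolated
and re-clustered (k = 2 in the same PC space) up to four times before being
excluded.  Transfer assigns events of other sets to the nearest non-excluded
centroid with a distance outlier gate.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from sklearn.cluster import KMeans
from sklearn.decomposition import PCA
from sklearn.metrics import silhouette_score

from .preprocess import SpikeEvent, stack_waveforms, event_times

log = logging.getLogger(__name__)

CONTAMINATION_THRESHOLD = 0.01     # ">= 1% of ISIs" (inclusive)
ISI_LIMIT_S = 1e-3                 # "<= 1 ms" (inclusive)
MAX_REITERATIONS = 4

CLEAN, EXCLUDED = "clean", "excluded"


@dataclass
class ClusterInfo:
    state: str = CLEAN             # clean | reiterated | excluded
    n_reiterations: int = 0
    q95_distance: float = np.nan   # 95th pct distance to own centroid (template)


@dataclass
class ClusterSolution:
    pca: PCA
    centroids: np.ndarray                       # k x n_components
    assignments: np.ndarray                     # per template event, -1 = none
    clusters: dict[int, ClusterInfo] = field(default_factory=dict)
    seed: int = 0
    silhouette_by_k: dict[int, float] = field(default_factory=dict)

    @property
    def k(self) -> int:
        return len(self.centroids)

    def active_clusters(self) -> list[int]:
        return [c for c, info in self.clusters.items() if info.state != EXCLUDED]


@dataclass
class Unit:
    unit_id: int
    channel_group: int
    modality: str                                # may become multimodal_excluded
    spike_times: dict[str, np.ndarray] = field(default_factory=dict)  # set_id -> s
    template_set_id: str | None = None
    cluster: int | None = None


def contamination_fraction(times_s: np.ndarray) -> float:
    """Fraction of inter-spike intervals <= 1 ms; 0 for fewer than 2 spikes.

    The comparison is inclusive on both sides of the printed rule ("1% or
    more ... <= 1 ms"): flag iff fraction >= 0.01, with ISI == 1.0 ms counted.
    """
    times_s = np.sort(np.asarray(times_s, dtype=float))
    if times_s.size < 2:
        return 0.0
    isi = np.diff(times_s)
    return float(np.mean(isi <= ISI_LIMIT_S * (1 + 1e-9)))


def is_contaminated(times_s: np.ndarray,
                    threshold: float = CONTAMINATION_THRESHOLD) -> bool:
    return contamination_fraction(times_s) >= threshold


def _fit_q95(solution: ClusterSolution, Z: np.ndarray) -> None:
    for c, info in solution.clusters.items():
        mask = solution.assignments == c
        if mask.any():
            d = np.linalg.norm(Z[mask] - solution.centroids[c], axis=1)
            info.q95_distance = float(np.percentile(d, 95))


def fit_template_clustering(events: list[SpikeEvent], k_range=range(2, 9),
                            seed: int = 0, n_components: int = 10,
                            n_restarts: int = 10,
                            min_silhouette: float = 0.3) -> ClusterSolution:
    """Fit the template clustering solution on a pre-DC recording's events.

    PCA retains ``n_components`` components (or fewer at 95% explained
    variance); k-means is run with ``n_restarts`` restarts per k and k chosen
    by maximum mean silhouette.  If even the best silhouette is below
    ``min_silhouette`` (or there are too few events) everything is kept in a
    single cluster.
    """
    X = stack_waveforms(events)
    n = len(X)
    k_range = [k for k in k_range if k >= 2]
    n_components = int(min(n_components, X.shape[1], max(1, n)))
    pca = PCA(n_components=n_components, random_state=seed)
    var = pca.fit(X).explained_variance_ratio_ if n else np.array([1.0])
    keep = int(np.searchsorted(np.cumsum(var), 0.95) + 1)
    if keep < n_components:
        pca = PCA(n_components=keep, random_state=seed).fit(X)
    Z = pca.transform(X)

    single_fallback = n < 10 * max(k_range, default=2)
    if single_fallback:
        log.warning("only %d events; falling back to a single cluster", n)
    sil: dict[int, float] = {}
    best = None
    if not single_fallback:
        for k in k_range:
            km = KMeans(n_clusters=k, n_init=n_restarts, random_state=seed).fit(Z)
            sil[k] = float(silhouette_score(Z, km.labels_))
            if best is None or sil[k] > sil[best[0]]:
                best = (k, km)
    if best is None or sil[best[0]] < min_silhouette:
        centroids = Z.mean(axis=0, keepdims=True) if n else np.zeros((1, pca.n_components_))
        assignments = np.zeros(n, dtype=int)
    else:
        centroids, assignments = best[1].cluster_centers_, best[1].labels_
    solution = ClusterSolution(
        pca=pca, centroids=np.asarray(centroids), assignments=np.asarray(assignments),
        clusters={c: ClusterInfo() for c in range(len(centroids))},
        seed=seed, silhouette_by_k=sil)
    _fit_q95(solution, Z)
    return solution


def refine_contaminated(solution: ClusterSolution, events: list[SpikeEvent],
                        max_iters: int = MAX_REITERATIONS,
                        threshold: float = CONTAMINATION_THRESHOLD) -> ClusterSolution:
    """Isolate and re-cluster ISI-contaminated clusters.

    Each flagged cluster's events are re-clustered with k = 2 in the template
    PC space; the resulting sub-clusters are re-checked and the reiteration
    count inherited, so a lineage still flagged after ``max_iters``
    reiterations is marked excluded.  Clean clusters are untouched.
    """
    times = event_times(events)
    Z = solution.pca.transform(stack_waveforms(events))
    centroids = [c for c in solution.centroids]
    assignments = solution.assignments.copy()
    clusters = {c: ClusterInfo(i.state, i.n_reiterations, i.q95_distance)
                for c, i in solution.clusters.items()}
    queue = list(clusters)
    while queue:
        c = queue.pop(0)
        info = clusters[c]
        if info.state == EXCLUDED:
            continue
        mask = assignments == c
        if not is_contaminated(times[mask], threshold):
            continue
        if info.n_reiterations >= max_iters:
            info.state = EXCLUDED
            log.info("cluster %d excluded after %d reiterations", c, info.n_reiterations)
            continue
        if mask.sum() < 2:
            info.state = EXCLUDED
            continue
        km = KMeans(n_clusters=2, n_init=10, random_state=solution.seed).fit(Z[mask])
        idx = np.flatnonzero(mask)
        new_a, new_b = len(centroids), len(centroids) + 1
        centroids.extend([km.cluster_centers_[0], km.cluster_centers_[1]])
        assignments[idx[km.labels_ == 0]] = new_a
        assignments[idx[km.labels_ == 1]] = new_b
        for nc in (new_a, new_b):
            clusters[nc] = ClusterInfo("reiterated", info.n_reiterations + 1)
            queue.append(nc)
        del clusters[c]
    out = ClusterSolution(pca=solution.pca, centroids=np.asarray(centroids),
                          assignments=assignments, clusters=clusters,
                          seed=solution.seed, silhouette_by_k=solution.silhouette_by_k)
    _fit_q95(out, Z)
    return out


def apply_clustering(solution: ClusterSolution, events: list[SpikeEvent],
                     outlier_mult: float = 3.0) -> np.ndarray:
    """Assign another set's events to the template solution.

    Events are projected onto the template PC basis and assigned to the
    nearest non-excluded centroid; an event farther than ``outlier_mult``
    times that cluster's 95th-percentile template distance is left
    unassigned (-1).
    """
    X = stack_waveforms(events)
    if X.shape[1] != solution.pca.n_features_in_:
        raise ValueError("waveform dimensionality does not match the template solution")
    Z = solution.pca.transform(X)
    active = solution.active_clusters()
    if not active:
        return -np.ones(len(events), dtype=int)
    C = solution.centroids[active]
    d = np.linalg.norm(Z[:, None, :] - C[None, :, :], axis=2)
    nearest = np.argmin(d, axis=1)
    out = np.array([active[i] for i in nearest], dtype=int)
    dmin = d[np.arange(len(events)), nearest]
    gate = np.array([outlier_mult * solution.clusters[c].q95_distance for c in out])
    out[dmin > gate] = -1
    return out


def classify_modality(unit: Unit, tactile_probe_counts=None, alpha: float = 0.05):
    """Label a unit by its template paradigm's modality, then apply the
    one-directional multimodal exclusion: a non-tactile unit that also shows
    a significant evoked response to the tactile probe becomes
    ``multimodal_excluded``.  ``tactile_probe_counts`` is the (pre, post)
    per-trial count pair array from the tactile probe recording; if missing
    for a non-tactile unit the label is retained but flagged unverified.

    Returns (label, verified).
    """
    from .evoked import classify_evoked

    label = unit.modality
    if label == "tactile" or label == "multimodal_excluded":
        return label, True
    if tactile_probe_counts is None:
        log.warning("unit %d: no tactile probe; modality label unverified", unit.unit_id)
        return label, False
    pre, post = np.asarray(tactile_probe_counts).T
    if classify_evoked(pre, post, alpha=alpha).evoked:
        return "multimodal_excluded", True
    return label, True
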