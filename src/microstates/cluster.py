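"""Microstate map estimation: GFP peaks, polarity-invariant modified
K-means, silhouette model selection, two-level clustering and map labeling.

The modified K-means treats a scalp map and its negation as the same state:
peaks are assigned to the cluster whose map has the highest squared spatial
correlation with them, and each cluster map is re-estimated as the first
principal eigenvector of the outer-product sum of its members, which is
sign-free by construction.  The objective is the global explained variance

    GEV = sum_p GFP_p^2 r^2(x_p, map_{a(p)}) / sum_p GFP_p^2,

the fraction of GFP-weighted topographic variance explained by the assigned
maps.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import linear_sum_assignment
from sklearn.metrics import silhouette_score

from .preprocess import Recording

CLASS_NAMES = ("A", "B", "C", "D")


# ---------------------------------------------------------------------------
# GFP

@dataclass(frozen=True)
class GFPSeries:
    """Per-sample global field power (spatial SD across channels, in uV)."""

    values: np.ndarray
    rate: float
    segments: list[tuple[int, int]]


def gfp(rec: Recording) -> GFPSeries:
    """Global field power: population SD of the scalp potential per sample."""
    if rec.reference != "average":
        raise ValueError("GFP requires an average-referenced recording")
    values = rec.data.std(axis=0, ddof=0)
    return GFPSeries(values=values, rate=rec.rate, segments=list(rec.segments))


def gfp_peaks(series: GFPSeries) -> np.ndarray:
    """Indices of strict local GFP maxima, found within each segment only."""
    out = []
    v = series.values
    for start, stop in series.segments:
        if stop - start < 3:
            continue
        seg = v[start:stop]
        hits = np.flatnonzero((seg[1:-1] > seg[:-2]) & (seg[1:-1] > seg[2:])) + 1
        out.append(hits + start)
    if not out:
        return np.empty(0, dtype=int)
    return np.concatenate(out)


# ---------------------------------------------------------------------------
# map containers

def _normalize_maps(maps: np.ndarray) -> np.ndarray:
    maps = maps - maps.mean(axis=1, keepdims=True)
    norms = np.linalg.norm(maps, axis=1, keepdims=True)
    if np.any(norms < 1e-12):
        raise ValueError("zero-variance map cannot be normalized")
    return maps / norms


@dataclass
class MapSet:
    """K topographic maps, each zero-mean and unit-L2-norm across channels."""

    maps: np.ndarray                       # (K, n_channels)
    class_labels: tuple[str, ...] | None = None
    provenance: tuple = ("unknown",)

    def __post_init__(self) -> None:
        self.maps = np.asarray(self.maps, dtype=float)
        if self.maps.ndim != 2 or self.maps.shape[0] < 1:
            raise ValueError("maps must be a (K, n_channels) matrix with K >= 1")
        if not np.allclose(self.maps.mean(axis=1), 0.0, atol=1e-9):
            raise ValueError("maps must be zero-mean across channels")
        if not np.allclose(np.linalg.norm(self.maps, axis=1), 1.0, atol=1e-9):
            raise ValueError("maps must be unit-norm across channels")
        if self.class_labels is not None and len(self.class_labels) != self.n_maps:
            raise ValueError("one class label per map required")

    @property
    def n_maps(self) -> int:
        return self.maps.shape[0]

    @property
    def n_channels(self) -> int:
        return self.maps.shape[1]


def spatial_correlation(a: np.ndarray, b: np.ndarray) -> float:
    """Absolute Pearson correlation between two maps across channels."""
    a = np.asarray(a, dtype=float) - np.mean(a)
    b = np.asarray(b, dtype=float) - np.mean(b)
    na, nb = np.linalg.norm(a), np.linalg.norm(b)
    if na < 1e-12 or nb < 1e-12:
        raise ValueError("zero-variance map has no defined spatial correlation")
    return float(abs(a @ b) / (na * nb))


# ---------------------------------------------------------------------------
# modified K-means, statsmodels-style model/results pair

class ModifiedKMeans:
    """Polarity-invariant K-means over GFP-peak topographies.

    Parameters
    ----------
    peak_maps : (n_peaks, n_channels) array
        Topographies at GFP peaks.  They are zero-meaned and unit-normed
        internally; the GEV weights use the original peak GFP.
    n_clusters : int
        Number of microstate classes K.
    peak_gfp : optional (n_peaks,) array
        GFP at each peak, used as sqrt of the GEV weight.  Defaults to the
        spatial SD of each supplied peak map.
    """

    def __init__(self, peak_maps: np.ndarray, n_clusters: int,
                 peak_gfp: np.ndarray | None = None):
        peak_maps = np.asarray(peak_maps, dtype=float)
        if peak_maps.ndim != 2:
            raise ValueError("peak_maps must be 2-D (n_peaks, n_channels)")
        n_peaks = peak_maps.shape[0]
        if not 1 <= n_clusters <= n_peaks:
            raise ValueError(f"need 1 <= K <= n_peaks, got K={n_clusters}, n_peaks={n_peaks}")
        if peak_gfp is None:
            peak_gfp = peak_maps.std(axis=1, ddof=0)
        self.peak_gfp = np.asarray(peak_gfp, dtype=float)
        if self.peak_gfp.shape != (n_peaks,):
            raise ValueError("peak_gfp must have one entry per peak")
        self.n_clusters = int(n_clusters)
        self.X = _normalize_maps(peak_maps)
        self.weights = self.peak_gfp ** 2
        # GFP-scaled maps for the update step: outer-product sums over these
        # carry the GFP^2 weights of the GEV objective, which makes the
        # eigenvector update monotone in GEV
        self.Xw = self.X * self.peak_gfp[:, None]

    # -- internals ---------------------------------------------------------
    def _gev(self, maps: np.ndarray, assign: np.ndarray) -> float:
        r = np.einsum("pc,pc->p", self.X, maps[assign])
        return float(self.weights @ (r ** 2) / self.weights.sum())

    def _update_map(self, members: np.ndarray) -> np.ndarray:
        # first principal eigenvector of X^T X over the members: sign-free mean map
        cov = members.T @ members
        vals, vecs = np.linalg.eigh(cov)
        v = vecs[:, -1]
        v = v - v.mean()
        n = np.linalg.norm(v)
        if n < 1e-12:          # degenerate: fall back to the strongest member
            v = members[0] - members[0].mean()
            n = np.linalg.norm(v)
        return v / n

    def _fit_once(self, rng: np.random.Generator, max_iter: int, tol: float):
        X, K = self.X, self.n_clusters
        idx = rng.choice(X.shape[0], size=K, replace=False)
        maps = X[idx].copy()
        prev_gev = -np.inf
        gev_trace: list[float] = []
        assign = np.zeros(X.shape[0], dtype=int)
        converged = False
        for it in range(1, max_iter + 1):
            corr = X @ maps.T                      # (n_peaks, K)
            assign = np.argmax(corr ** 2, axis=1)  # ties -> lowest index (argmax semantics)
            for k in range(K):
                if not np.any(assign == k):
                    # reseed with the worst-explained peak
                    explained = np.max((X @ maps.T) ** 2, axis=1)
                    worst = int(np.argmin(explained))
                    maps[k] = X[worst]
                    assign[worst] = k
                maps[k] = self._update_map(self.Xw[assign == k])
            corr = X @ maps.T
            assign = np.argmax(corr ** 2, axis=1)
            gev = self._gev(maps, assign)
            gev_trace.append(gev)
            if gev < prev_gev - 1e-12:
                raise AssertionError("GEV decreased across an iteration")
            if gev - prev_gev < tol:
                converged = True
                prev_gev = gev
                break
            prev_gev = gev
        return maps, assign, prev_gev, gev_trace, converged

    def _polish(self, maps: np.ndarray, assign: np.ndarray,
                max_sweeps: int = 20) -> tuple[np.ndarray, np.ndarray]:
        """Hartigan-style refinement of the best restart.

        For an assignment with per-cluster optimal maps the objective is
        sum_k lambda_max(C_k) with C_k the GFP-weighted outer-product sum,
        so a single-point move is scored by two rank-1 eigenvalue
        re-evaluations.  Moves that increase the objective are applied until
        a sweep makes none; this escapes Lloyd fixed points whose basin the
        peak-seeded restarts cannot reach.
        """
        K = self.n_clusters
        if K < 2 or self.X.shape[0] <= K:
            return maps, assign
        assign = assign.copy()
        cov = np.stack([self.Xw[assign == k].T @ self.Xw[assign == k]
                        for k in range(K)])
        lam = np.array([np.linalg.eigvalsh(c)[-1] for c in cov])
        scale = max(lam.sum(), 1e-12)
        counts = np.bincount(assign, minlength=K)
        for _ in range(max_sweeps):
            moved = False
            for p in range(self.X.shape[0]):
                a = assign[p]
                if counts[a] <= 1:
                    continue
                outer = np.outer(self.Xw[p], self.Xw[p])
                lam_a = np.linalg.eigvalsh(cov[a] - outer)[-1]
                best_gain, best_b, best_lam_b = 0.0, -1, 0.0
                for b in range(K):
                    if b == a:
                        continue
                    lam_b = np.linalg.eigvalsh(cov[b] + outer)[-1]
                    gain = (lam_a + lam_b) - (lam[a] + lam[b])
                    if gain > best_gain:
                        best_gain, best_b, best_lam_b = gain, b, lam_b
                if best_b >= 0 and best_gain > 1e-12 * scale:
                    cov[a] -= outer
                    cov[best_b] += outer
                    lam[a], lam[best_b] = lam_a, best_lam_b
                    counts[a] -= 1
                    counts[best_b] += 1
                    assign[p] = best_b
                    moved = True
            if not moved:
                break
        maps = np.array([self._update_map(self.Xw[assign == k]) for k in range(K)])
        corr = self.X @ maps.T
        assign = np.argmax(corr ** 2, axis=1)
        return maps, assign

    # -- public API --------------------------------------------------------
    def fit(self, n_init: int = 10, max_iter: int = 100, tol: float = 1e-6,
            seed: int | np.random.Generator | None = None,
            polish: bool = True) -> "ModifiedKMeansResults":
        """Best-of-``n_init`` restarts; each restart iterates assignment and
        eigenvector updates until the GEV gain drops below ``tol``.  The
        winning restart gets a Hartigan single-point refinement."""
        rng = np.random.default_rng(seed)
        best = None
        for _ in range(n_init):
            maps, assign, gev, trace, conv = self._fit_once(rng, max_iter, tol)
            if best is None or gev > best[2]:
                best = (maps, assign, gev, trace, conv)
        maps, assign, gev, trace, conv = best
        if polish:
            maps, assign = self._polish(maps, assign)
            gev = max(gev, self._gev(maps, assign))
            trace = trace + [gev]
        mapset = MapSet(maps=maps, provenance=("fit",))
        return ModifiedKMeansResults(model=self, mapset=mapset, assignments=assign,
                                     gev=gev, n_iter=len(trace), converged=conv,
                                     gev_trace=tuple(trace))


@dataclass
class ModifiedKMeansResults:
    """Fitted microstate maps with assignments and explained variance."""

    model: ModifiedKMeans
    mapset: MapSet
    assignments: np.ndarray
    gev: float
    n_iter: int
    converged: bool
    gev_trace: tuple[float, ...] = field(default=(), repr=False)

    def __post_init__(self) -> None:
        if not 0.0 <= self.gev <= 1.0 + 1e-12:
            raise ValueError("GEV must lie in [0, 1]")
        if len(self.assignments) != self.model.X.shape[0]:
            raise ValueError("one assignment per peak required")

    def summary(self) -> str:
        lines = [
            "Modified K-means microstate fit",
            f"  clusters (K)       : {self.mapset.n_maps}",
            f"  peaks              : {len(self.assignments)}",
            f"  GEV                : {self.gev:.4f}",
            f"  iterations         : {self.n_iter}  (converged: {self.converged})",
        ]
        counts = np.bincount(self.assignments, minlength=self.mapset.n_maps)
        for k, c in enumerate(counts):
            lines.append(f"  cluster {k}: {c} peaks")
        return "\n".join(lines)

    def plot_maps(self, layout=None, axes=None):
        from .plotting import plot_mapset
        return plot_mapset(self.mapset, layout=layout, axes=axes)


def modified_kmeans(peak_maps: np.ndarray, n_clusters: int, n_init: int = 10,
                    max_iter: int = 100, tol: float = 1e-6,
                    seed=None, peak_gfp: np.ndarray | None = None) -> ModifiedKMeansResults:
    """Functional wrapper around :class:`ModifiedKMeans`."""
    model = ModifiedKMeans(peak_maps, n_clusters, peak_gfp=peak_gfp)
    return model.fit(n_init=n_init, max_iter=max_iter, tol=tol, seed=seed)


# ---------------------------------------------------------------------------
# model selection and two-level clustering

def correlation_distances(peak_maps: np.ndarray) -> np.ndarray:
    """Pairwise polarity-invariant distances d = 1 - |r| between maps."""
    X = _normalize_maps(np.asarray(peak_maps, dtype=float))
    d = 1.0 - np.abs(X @ X.T)
    np.fill_diagonal(d, 0.0)
    return np.clip(d, 0.0, None)


def silhouette_k(peak_maps: np.ndarray, k_range, seed=None,
                 n_init: int = 10) -> tuple[int, dict[int, float]]:
    """Pick K by the mean silhouette under the 1 - |r| distance.

    For each candidate K a modified K-means fit supplies the labels; the
    silhouette uses the polarity-invariant correlation distance so a map and
    its negation are zero distance apart.
    """
    peak_maps = np.asarray(peak_maps, dtype=float)
    n = peak_maps.shape[0]
    k_range = list(k_range)
    if not k_range or min(k_range) < 2 or max(k_range) > n - 1:
        raise ValueError(f"k_range must lie within [2, {n - 1}]")
    rng = np.random.default_rng(seed)
    dist = correlation_distances(peak_maps)
    scores: dict[int, float] = {}
    for k in k_range:
        fit = modified_kmeans(peak_maps, k, n_init=n_init,
                              seed=rng.integers(2 ** 31))
        scores[k] = float(silhouette_score(dist, fit.assignments, metric="precomputed"))
    best = max(scores, key=lambda k: (scores[k], -k))
    return best, scores


def two_level_cluster(recordings: list[Recording], n_clusters: int = 4,
                      seed=None, n_init: int = 10) -> MapSet:
    """Subject-level then group-level clustering.

    Each subject contributes K maps fitted to its own GFP peaks; the
    concatenated subject maps are clustered again to give the group maps.
    """
    if not recordings:
        raise ValueError("need at least one subject recording")
    rng = np.random.default_rng(seed)
    subject_maps = []
    for rec in recordings:
        series = gfp(rec)
        peaks = gfp_peaks(series)
        if len(peaks) < n_clusters:
            raise ValueError("recording has fewer GFP peaks than clusters")
        fit = modified_kmeans(rec.data[:, peaks].T, n_clusters, n_init=n_init,
                              seed=rng.integers(2 ** 31),
                              peak_gfp=series.values[peaks])
        subject_maps.append(fit.mapset.maps)
    stacked = np.concatenate(subject_maps, axis=0)
    group_fit = modified_kmeans(stacked, n_clusters, n_init=n_init,
                                seed=rng.integers(2 ** 31))
    out = group_fit.mapset
    out.provenance = ("group",)
    return out


def label_maps(maps: MapSet, reference: MapSet) -> tuple[MapSet, np.ndarray]:
    """Assign class labels by optimal matching against a labelled reference.

    Solves the bipartite assignment maximizing total |spatial correlation|
    (Hungarian algorithm) and returns the relabelled, reordered MapSet
    together with the full |r| matrix (rows: reference classes, columns
    reordered maps).
    """
    if maps.n_maps != reference.n_maps or maps.n_channels != reference.n_channels:
        raise ValueError("map set and reference must share K and channel count")
    cost = np.abs(reference.maps @ maps.maps.T)      # rows ref, cols candidate
    row, col = linear_sum_assignment(-cost)
    order = col[np.argsort(row)]
    labels = reference.class_labels or tuple(str(i) for i in range(maps.n_maps))
    relabelled = MapSet(maps=maps.maps[order].copy(), class_labels=tuple(labels),
                        provenance=maps.provenance)
    corr = np.abs(reference.maps @ relabelled.maps.T)
    return relabelled, corr
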