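"""Backfitting reference maps to continuous EEG and microstate statistics.

Every sample is labelled with the reference map that best matches its
instantaneous topography, ignoring polarity; a sliding majority vote then
removes the brief label flickers that occur between GFP peaks, and run
statistics (occurrence, coverage, mean duration) are computed within
contiguous segments only.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .cluster import MapSet
from .preprocess import Recording


@dataclass
class LabelSequence:
    """Per-sample microstate class assignment."""

    labels: np.ndarray                       # (n_samples,), int class indices
    rate: float
    segments: list[tuple[int, int]]
    class_names: tuple[str, ...]

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=int)
        if self.labels.ndim != 1:
            raise ValueError("labels must be 1-D")
        k = len(self.class_names)
        if self.labels.size and (self.labels.min() < 0 or self.labels.max() >= k):
            raise ValueError("label outside class range")
        total = sum(stop - start for start, stop in self.segments)
        if total != self.labels.size:
            raise ValueError("segments do not tile the label array")

    @property
    def n_samples(self) -> int:
        return self.labels.size

    @property
    def n_classes(self) -> int:
        return len(self.class_names)


@dataclass(frozen=True)
class MicrostateStats:
    """Per-class occurrence (1/s), coverage (%) and mean duration (ms).

    Classes that never occur get occurrence 0, coverage 0 and a missing
    (NaN) mean duration.  For every class with at least one run the identity
    occurrence * mean_duration(s) == coverage(fraction) holds exactly.
    """

    class_names: tuple[str, ...]
    occurrence: np.ndarray         # runs per second
    coverage: np.ndarray           # percent of analyzed time
    mean_duration: np.ndarray      # ms, NaN when the class is absent
    n_runs: np.ndarray
    total_time: float              # seconds analyzed

    def to_dict(self) -> dict[str, dict[str, float]]:
        return {
            name: {
                "occurrence": float(self.occurrence[i]),
                "coverage": float(self.coverage[i]),
                "mean_duration": float(self.mean_duration[i]),
            }
            for i, name in enumerate(self.class_names)
        }


@dataclass(frozen=True)
class RatioStats:
    """Class C over class D ratios of the three temporal parameters."""

    occurrence: float
    coverage: float
    mean_duration: float


def backfit(rec: Recording, reference: MapSet) -> LabelSequence:
    """Label each sample with the best |correlation| reference map.

    Polarity is ignored.  Zero-variance (flat) samples inherit the previous
    sample's label, or the first valid label after them at a segment start.
    """
    if rec.reference != "average":
        raise ValueError("backfit requires an average-referenced recording")
    if rec.n_channels != reference.n_channels:
        raise ValueError("channel count mismatch between recording and reference maps")
    X = rec.data - rec.data.mean(axis=0, keepdims=True)
    norms = np.linalg.norm(X, axis=0)
    corr = np.abs(reference.maps @ X)               # (K, n_samples), unnormalized
    labels = np.argmax(corr, axis=0)
    flat = norms < 1e-12
    if np.any(flat):
        for start, stop in rec.segments:
            seg_flat = flat[start:stop]
            if not seg_flat.any():
                continue
            idx = np.arange(stop - start)
            valid = ~seg_flat
            if not valid.any():
                raise ValueError("segment contains only zero-variance samples")
            # previous valid label; leading flats take the first valid one
            prev = np.maximum.accumulate(np.where(valid, idx, -1))
            first_valid = idx[valid][0]
            prev = np.where(prev < 0, first_valid, prev)
            labels[start:stop] = labels[start:stop][prev]
    names = reference.class_labels or tuple(str(i) for i in range(reference.n_maps))
    return LabelSequence(labels=labels, rate=rec.rate,
                         segments=list(rec.segments), class_names=tuple(names))


def smooth_labels(seq: LabelSequence, window_ms: float = 82.0,
                  max_passes: int = 10) -> LabelSequence:
    """Sliding majority vote over a centred window, iterated to a fixed point.

    The full window spans ``round(window_ms * rate / 1000)`` samples (21 at
    256 Hz for the 82 ms default).  Votes are counted within the enclosing
    segment only, the window is truncated at segment edges, and the
    incumbent label wins ties.  Passes repeat until nothing changes or
    ``max_passes`` is reached, which removes isolated runs shorter than
    half a window wedged between longer runs.

    Majority voting alone has one pathological fixed point: a strictly
    alternating two-class sequence, where every sample holds a one-vote
    self-majority.  A final minimum-duration pass therefore merges any run
    shorter than ``ceil(w / 2)`` samples into its longer neighbouring run
    (shortest run first; ties resolve to the earlier run / left neighbour),
    so no sub-half-window flicker survives smoothing.
    """
    if window_ms <= 0:
        raise ValueError("window must be positive")
    w = int(round(window_ms * seq.rate / 1000.0))
    w = max(w, 1)
    half = w // 2
    shortest = min(stop - start for start, stop in seq.segments)
    if w > shortest:
        raise ValueError(f"window ({w} samples) longer than shortest segment ({shortest})")
    K = seq.n_classes
    labels = seq.labels.copy()
    for _ in range(max_passes):
        changed = False
        for start, stop in seq.segments:
            seg = labels[start:stop]
            n = seg.size
            onehot = np.zeros((K, n + 1))
            np.add.at(onehot, (seg, np.arange(n) + 1), 1.0)
            csum = np.cumsum(onehot, axis=1)       # (K, n+1)
            idx = np.arange(n)
            lo = np.maximum(idx - half, 0)
            hi = np.minimum(idx + half + 1, n)
            counts = csum[:, hi] - csum[:, lo]     # (K, n) votes per class
            best = counts.max(axis=0)
            incumbent = counts[seg, idx]
            new = np.where(incumbent >= best, seg, np.argmax(counts, axis=0))
            if np.any(new != seg):
                labels[start:stop] = new
                changed = True
        if not changed:
            break
    min_len = (w + 1) // 2
    for start, stop in seq.segments:
        labels[start:stop] = _enforce_min_run(labels[start:stop], min_len)
    return LabelSequence(labels=labels, rate=seq.rate,
                         segments=list(seq.segments), class_names=seq.class_names)


def _enforce_min_run(seg: np.ndarray, min_len: int) -> np.ndarray:
    """Merge runs shorter than ``min_len`` into their longer neighbour."""
    # run-length encode
    runs = []                                  # [class, length]
    bounds = np.flatnonzero(np.diff(seg)) + 1
    edges = np.concatenate([[0], bounds, [seg.size]])
    for a, b in zip(edges[:-1], edges[1:]):
        runs.append([int(seg[a]), int(b - a)])
    while len(runs) > 1:
        lengths = [r[1] for r in runs]
        i = int(np.argmin(lengths))
        if lengths[i] >= min_len:
            break
        if i == 0:
            j = 1
        elif i == len(runs) - 1:
            j = i - 1
        else:
            j = i - 1 if runs[i - 1][1] >= runs[i + 1][1] else i + 1
        runs[j][1] += runs[i][1]
        del runs[i]
        # neighbouring runs of one class may now be adjacent
        k = 1
        while k < len(runs):
            if runs[k][0] == runs[k - 1][0]:
                runs[k - 1][1] += runs[k][1]
                del runs[k]
            else:
                k += 1
    return np.repeat([r[0] for r in runs], [r[1] for r in runs])


def _runs(seq: LabelSequence):
    """Yield (class_index, run_length) for maximal runs within segments."""
    for start, stop in seq.segments:
        seg = seq.labels[start:stop]
        if seg.size == 0:
            continue
        bounds = np.flatnonzero(np.diff(seg)) + 1
        edges = np.concatenate([[0], bounds, [seg.size]])
        for a, b in zip(edges[:-1], edges[1:]):
            yield int(seg[a]), int(b - a)


def compute_stats(seq: LabelSequence) -> MicrostateStats:
    """Occurrence, coverage and mean duration per class from a label sequence.

    A run is a maximal span of one class inside a contiguous segment; runs
    touching segment edges count like any other (the induced truncation
    bias on mean duration is negligible for recordings much longer than a
    sojourn).
    """
    if seq.n_samples == 0:
        raise ValueError("empty label sequence")
    K = seq.n_classes
    n_runs = np.zeros(K, dtype=int)
    n_samples = np.zeros(K, dtype=int)
    for k, length in _runs(seq):
        n_runs[k] += 1
        n_samples[k] += length
    total_time = seq.n_samples / seq.rate
    occurrence = n_runs / total_time
    coverage = 100.0 * n_samples / seq.n_samples
    with np.errstate(invalid="ignore", divide="ignore"):
        mean_duration = np.where(n_runs > 0,
                                 1000.0 * n_samples / np.maximum(n_runs, 1) / seq.rate,
                                 np.nan)
    return MicrostateStats(class_names=seq.class_names, occurrence=occurrence,
                           coverage=coverage, mean_duration=mean_duration,
                           n_runs=n_runs, total_time=total_time)


def cd_ratios(stats: MicrostateStats, numerator: str = "C",
              denominator: str = "D") -> RatioStats:
    """Elementwise class-C over class-D ratios of the temporal parameters."""
    try:
        ci = stats.class_names.index(numerator)
        di = stats.class_names.index(denominator)
    except ValueError as exc:
        raise ValueError(f"classes {numerator}/{denominator} not present") from exc
    out = {}
    for name in ("occurrence", "coverage", "mean_duration"):
        c, d = getattr(stats, name)[ci], getattr(stats, name)[di]
        if not np.isfinite(d) or d == 0:
            warnings.warn(f"class {denominator} absent: {name} ratio undefined")
            out[name] = np.nan
        else:
            out[name] = float(c / d)
    return RatioStats(**out)
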