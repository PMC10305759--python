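"""Synthetic resting-state EEG cohorts with known microstate ground truth.

The generator emulates eyes-closed 19-channel recordings: a semi-Markov
sequence of four quasi-stable topographies (gamma-distributed sojourns,
~80-100 ms), each radiated as a 10 Hz alpha carrier with a slowly drifting
envelope and a random polarity per sojourn, plus spatially independent
1/f background noise.  Group-level perturbations (e.g. a shortened class-D
sojourn in a disease-like group) are applied to the sequence generator, so
the realized per-subject statistics and between-group effect sizes are
known exactly and every downstream stage has a recovery target.

All randomness flows from a single integer seed through per-subject
substreams, so a cohort is bit-reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .backfit import LabelSequence, compute_stats
from .cluster import CLASS_NAMES, MapSet
from .layout import SensorLayout, make_layout
from .preprocess import Recording

#: directional patterns on the unit sphere for the four canonical classes:
#: A left-posterior/right-anterior, B right-posterior/left-anterior,
#: C anterior-posterior symmetric, D fronto-central versus peripheral.
_TEMPLATE_DIRECTIONS = {
    "A": (-1.0, -0.6, 0.1),
    "B": (1.0, -0.6, 0.1),
    "C": (0.0, -1.0, 0.9),
}


def make_template_maps(layout: SensorLayout, seed: int = 0,
                       perturbation: float = 0.08,
                       max_abs_corr: float = 0.7) -> MapSet:
    """Four smooth canonical-class topographies with a seeded perturbation.

    Each map is a linear field over the electrode positions (class D is the
    vertex-radial field), plus a small random smooth component, then
    zero-meaned and unit-normed.  Raises if any pair correlates above
    ``max_abs_corr`` in magnitude.
    """
    rng = np.random.default_rng(seed)
    pos = layout.positions
    maps = []
    for name in ("A", "B", "C"):
        d = np.asarray(_TEMPLATE_DIRECTIONS[name], dtype=float)
        d /= np.linalg.norm(d)
        maps.append(pos @ d)
    maps.append(pos[:, 2].copy())                    # class D
    maps = np.array(maps)
    maps = maps - maps.mean(axis=1, keepdims=True)
    maps /= np.linalg.norm(maps, axis=1, keepdims=True)
    if perturbation > 0:
        # smooth random tilt, scaled relative to each normalized base map
        tilt = (pos @ rng.standard_normal((4, 3)).T).T
        tilt = tilt - tilt.mean(axis=1, keepdims=True)
        tilt /= np.linalg.norm(tilt, axis=1, keepdims=True)
        maps = maps + perturbation * tilt
        maps = maps - maps.mean(axis=1, keepdims=True)
        maps /= np.linalg.norm(maps, axis=1, keepdims=True)
    corr = np.abs(maps @ maps.T)
    off = corr[~np.eye(4, dtype=bool)]
    if off.max() > max_abs_corr:
        raise ValueError(
            f"template maps too similar: max |r| = {off.max():.3f} > {max_abs_corr}")
    return MapSet(maps=maps, class_labels=CLASS_NAMES, provenance=("template",))


def simulate_label_sequence(mean_durations_ms, occurrence_weights, rate: float,
                            n_samples: int, seed=None,
                            gamma_shape: float = 2.0) -> LabelSequence:
    """Semi-Markov class sequence with gamma sojourns.

    Sojourn lengths are gamma(``gamma_shape``) with the class's target mean
    (converted to samples, floored at one sample); the next class is drawn
    from the occurrence weights with the current class excluded.
    """
    mean_durations_ms = np.asarray(mean_durations_ms, dtype=float)
    weights = np.asarray(occurrence_weights, dtype=float)
    if np.any(mean_durations_ms <= 0):
        raise ValueError("mean durations must be positive")
    if np.any(weights < 0) or weights.sum() <= 0:
        raise ValueError("occurrence weights must be non-negative with positive sum")
    if n_samples < 1:
        raise ValueError("n_samples must be >= 1")
    if rate <= 0:
        raise ValueError("rate must be positive")
    K = len(weights)
    rng = np.random.default_rng(seed)
    mean_samples = mean_durations_ms * rate / 1000.0
    labels = np.empty(n_samples, dtype=int)
    current = int(rng.choice(K, p=weights / weights.sum()))
    pos = 0
    while pos < n_samples:
        dur = int(round(rng.gamma(gamma_shape, mean_samples[current] / gamma_shape)))
        dur = max(dur, 1)
        labels[pos:pos + dur] = current
        pos += dur
        if K > 1:
            w = weights.copy()
            w[current] = 0.0
            if w.sum() <= 0:
                raise ValueError("no class with positive weight to switch to")
            current = int(rng.choice(K, p=w / w.sum()))
    return LabelSequence(labels=labels, rate=rate, segments=[(0, n_samples)],
                         class_names=CLASS_NAMES[:K] if K <= 4
                         else tuple(str(i) for i in range(K)))


def _one_over_f_noise(rng: np.random.Generator, n_channels: int, n_samples: int,
                      rate: float, floor_hz: float = 1.0) -> np.ndarray:
    """Spatially white noise with 1/f-shaped amplitude spectrum."""
    white = rng.standard_normal((n_channels, n_samples))
    freqs = np.fft.rfftfreq(n_samples, d=1.0 / rate)
    shape = 1.0 / np.sqrt(np.maximum(freqs, floor_hz))
    spec = np.fft.rfft(white, axis=1) * shape
    return np.fft.irfft(spec, n=n_samples, axis=1)


def _alpha_envelope(rng: np.random.Generator, n_samples: int, rate: float,
                    tau_s: float = 0.5, depth: float = 0.5) -> np.ndarray:
    """Slowly varying positive envelope from an Ornstein-Uhlenbeck process."""
    dt = 1.0 / rate
    a = np.exp(-dt / tau_s)
    b = np.sqrt(1.0 - a * a)
    x = np.empty(n_samples)
    x[0] = rng.standard_normal()
    eps = rng.standard_normal(n_samples - 1)
    for i in range(1, n_samples):
        x[i] = a * x[i - 1] + b * eps[i - 1]
    return np.exp(depth * x - depth * depth / 2.0)


def render_eeg(labels: LabelSequence, maps: MapSet, snr: float = 4.0,
               seed=None, alpha_hz: float = 10.0,
               amplitude_uv: float = 20.0) -> Recording:
    """Forward-model a label sequence into an average-referenced recording.

    signal(t) = s_j * map[label(t)] * a(t) + noise(t), with a(t) a
    10 Hz carrier under a slow random envelope, s_j a random polarity per
    sojourn, and 1/f noise scaled so that state-signal RMS / noise RMS
    equals ``snr``.  Pass ``snr=np.inf`` for a noiseless rendering.
    """
    if labels.n_classes > maps.n_maps:
        raise ValueError("label sequence uses more classes than the map set provides")
    if not snr > 0:
        raise ValueError("snr must be positive")
    rng = np.random.default_rng(seed)
    n = labels.n_samples
    rate = labels.rate
    t = np.arange(n) / rate
    carrier = np.sin(2 * np.pi * alpha_hz * t + rng.uniform(0, 2 * np.pi))
    env = _alpha_envelope(rng, n, rate)
    # random polarity per sojourn
    lab = labels.labels
    run_starts = np.concatenate([[0], np.flatnonzero(np.diff(lab)) + 1])
    flips = rng.integers(0, 2, size=run_starts.size) * 2 - 1
    signs = np.repeat(flips, np.diff(np.concatenate([run_starts, [n]])))
    amp = amplitude_uv * carrier * env * signs
    clean = maps.maps[lab].T * amp                   # (n_channels, n)
    clean -= clean.mean(axis=0, keepdims=True)
    if np.isfinite(snr):
        noise = _one_over_f_noise(rng, maps.n_channels, n, rate)
        noise -= noise.mean(axis=0, keepdims=True)
        clean_rms = np.sqrt(np.mean(clean ** 2))
        noise_rms = np.sqrt(np.mean(noise ** 2))
        data = clean + noise * (clean_rms / (snr * noise_rms))
        data -= data.mean(axis=0, keepdims=True)
    else:
        data = clean
    layout = make_layout() if maps.n_channels == 19 else None
    if layout is None:
        raise ValueError("render_eeg requires the 19-channel layout")
    # the data are physically average-referenced (zero channel mean), but the
    # tag stays "native" so the canonical preprocessing chain -- which always
    # re-references -- accepts simulated and disk-loaded recordings alike
    return Recording(data=data, rate=rate, layout=layout,
                     annotations=[(0.0, n / rate, "eyes_closed")],
                     reference="native", segments=list(labels.segments))


# ---------------------------------------------------------------------------
# cohorts

@dataclass(frozen=True)
class CohortSpec:
    """Generative settings for a multi-group synthetic cohort.

    ``group_scales`` maps a group name to per-class multiplicative factors
    on mean duration and/or occurrence weight, e.g.
    ``{"disease": {"duration": {"D": 0.6}}}`` shortens class-D sojourns.

    ``subject_cv`` is the coefficient of variation of a per-subject,
    per-class lognormal random effect on the mean sojourn duration:
    individuals differ in their true microstate dynamics, and without this
    between-subject dispersion a group effect size would be an artifact of
    recording length.  0.15 is mid-range for the dispersion reported in
    resting-state cohorts.
    """

    groups: tuple[tuple[str, int], ...] = (("control", 10), ("disease", 10))
    mean_durations_ms: tuple[float, ...] = (80.0, 80.0, 80.0, 80.0)
    occurrence_weights: tuple[float, ...] = (1.0, 1.0, 1.0, 1.0)
    group_scales: dict = field(default_factory=dict)
    subject_cv: float = 0.15
    gamma_shape: float = 2.0
    snr: float = 4.0
    duration_s: float = 60.0
    rate: float = 256.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.groups:
            raise ValueError("cohort spec lists no groups")
        if any(n < 1 for _, n in self.groups):
            raise ValueError("each group needs at least one subject")
        if not self.snr > 0:
            raise ValueError("snr must be positive")
        if any(d <= 0 for d in self.mean_durations_ms):
            raise ValueError("durations must be positive")
        if self.rate <= 0 or self.duration_s <= 0:
            raise ValueError("rate and duration must be positive")


@dataclass
class GroundTruth:
    """What the generator actually realized, per subject and per group."""

    maps: MapSet
    subjects: list[dict]            # subject, group, true label sequence, stats
    effect_sizes: dict              # group -> class -> parameter -> Cohen's d vs control

    def subject_stats(self, subject: str) -> dict:
        for rec in self.subjects:
            if rec["subject"] == subject:
                return rec["stats"]
        raise KeyError(subject)


def _cohens_d(x: np.ndarray, y: np.ndarray) -> float:
    nx, ny = len(x), len(y)
    sp = np.sqrt(((nx - 1) * np.var(x, ddof=1) + (ny - 1) * np.var(y, ddof=1))
                 / (nx + ny - 2))
    if sp == 0:
        return 0.0
    return float((np.mean(x) - np.mean(y)) / sp)


def simulate_cohort(spec: CohortSpec) -> tuple[dict[str, list[Recording]], GroundTruth]:
    """Simulate every subject of a cohort and tabulate the ground truth.

    Returns recordings grouped by group name, and a :class:`GroundTruth`
    whose per-subject statistics are computed from the true label sequences
    and whose effect sizes are Cohen's d of each group against the first
    (control) group.
    """
    root = np.random.SeedSequence(spec.seed)
    layout = make_layout()
    maps = make_template_maps(layout, seed=spec.seed)
    n_samples = int(round(spec.duration_s * spec.rate))
    recordings: dict[str, list[Recording]] = {}
    subjects = []
    demo_rng = np.random.default_rng(root.spawn(1)[0])
    for gi, (group, n_subj) in enumerate(spec.groups):
        scales = spec.group_scales.get(group, {})
        dur = np.asarray(spec.mean_durations_ms, dtype=float).copy()
        wts = np.asarray(spec.occurrence_weights, dtype=float).copy()
        for cls, f in scales.get("duration", {}).items():
            dur[CLASS_NAMES.index(cls)] *= f
        for cls, f in scales.get("occurrence", {}).items():
            wts[CLASS_NAMES.index(cls)] *= f
        recordings[group] = []
        for si in range(n_subj):
            sub_seed = np.random.SeedSequence(spec.seed, spawn_key=(gi, si))
            fx_rng, seq_rng, render_rng = [np.random.default_rng(s)
                                           for s in sub_seed.spawn(3)]
            if spec.subject_cv > 0:
                sigma = np.sqrt(np.log1p(spec.subject_cv ** 2))
                factors = np.exp(fx_rng.normal(-sigma ** 2 / 2, sigma, size=dur.size))
            else:
                factors = np.ones(dur.size)
            seq = simulate_label_sequence(dur * factors, wts, spec.rate, n_samples,
                                          seed=seq_rng, gamma_shape=spec.gamma_shape)
            rec = render_eeg(seq, maps, snr=spec.snr, seed=render_rng)
            sid = f"sub-{gi:02d}{si + 1:03d}"
            recordings[group].append(rec)
            subjects.append({
                "subject": sid,
                "group": group,
                "labels": seq,
                "stats": compute_stats(seq),
                "age": float(np.round(demo_rng.normal(30.0, 8.0), 1)),
                "sex": ("F", "M")[int(demo_rng.integers(0, 2))],
            })
    control = spec.groups[0][0]
    effect_sizes: dict = {}
    params = ("occurrence", "coverage", "mean_duration")
    for group, _ in spec.groups[1:]:
        effect_sizes[group] = {}
        for ci, cls in enumerate(CLASS_NAMES):
            effect_sizes[group][cls] = {}
            for p in params:
                xg = np.array([getattr(s["stats"], p)[ci] for s in subjects
                               if s["group"] == group])
                xc = np.array([getattr(s["stats"], p)[ci] for s in subjects
                               if s["group"] == control])
                effect_sizes[group][cls][p] = _cohens_d(xg, xc)
    truth = GroundTruth(maps=maps, subjects=subjects, effect_sizes=effect_sizes)
    return recordings, truth
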