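"""Preprocessing of resting-state EEG recordings.

The pipeline order is fixed: zero-phase bandpass on the continuous record,
selection of the annotated eyes-closed spans, average re-referencing, single
bad-channel interpolation, then an alpha-dominance quality check on the
power spectrum.  Filtering precedes segmentation so that filter edge
effects fall outside the retained spans, and re-referencing follows
segmentation so that artifacts in discarded spans cannot spread spatially.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
from scipy import signal as sps

from .layout import SensorLayout

#: conventional band edges (Hz) used by the dominance check; 8-13 is alpha
BANDS = {"delta": (0.5, 4.0), "theta": (4.0, 8.0), "alpha": (8.0, 13.0), "beta": (13.0, 30.0)}


@dataclass
class Recording:
    """A multichannel EEG record (microvolts) with annotations.

    ``segments`` lists the (start, stop) sample spans of contiguous data in
    ``data``; after segment selection the record is a concatenation of
    non-contiguous spans and downstream stages must never treat a splice as
    continuous time.
    """

    data: np.ndarray                 # (n_channels, n_samples), microvolts
    rate: float                      # Hz
    layout: SensorLayout
    annotations: list[tuple[float, float, str]] = field(default_factory=list)
    bads: list[str] = field(default_factory=list)
    reference: str = "native"        # "native" | "average"
    segments: list[tuple[int, int]] | None = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2 or self.data.shape[0] != self.layout.n_channels:
            raise ValueError("data must be (n_channels, n_samples) matching the layout")
        if self.rate <= 0:
            raise ValueError("sampling rate must be positive")
        dur = self.n_samples / self.rate
        for onset, length, _ in self.annotations:
            if onset < 0 or onset + length > dur + 1e-9:
                raise ValueError("annotation outside record bounds")
        if self.segments is None:
            self.segments = [(0, self.n_samples)]

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration(self) -> float:
        return self.n_samples / self.rate

    def copy(self, **changes) -> "Recording":
        out = dataclasses.replace(self, **changes)
        if "data" not in changes:
            out.data = self.data.copy()
        return out


@dataclass(frozen=True)
class PSDReport:
    """Channel-averaged Welch spectrum with band powers and the QC verdict."""

    frequencies: np.ndarray
    power: np.ndarray                # (n_channels, n_freqs)
    band_power: dict[str, float]
    alpha_dominant: bool


def bandpass(rec: Recording, low: float = 0.5, high: float = 40.0) -> Recording:
    """Zero-phase Butterworth bandpass of the full continuous record.

    Applied before any segmentation so edge transients fall outside the
    retained spans.  4th-order Butterworth run forward-backward
    (``sosfiltfilt``), which preserves the timing of topographic features.
    """
    nyq = rec.rate / 2.0
    if not (0 < low < high < nyq):
        raise ValueError(f"band ({low}, {high}) invalid for Nyquist {nyq} Hz")
    if len(rec.segments) != 1:
        raise ValueError("bandpass must run on the continuous record, before segment selection")
    sos = sps.butter(4, [low, high], btype="bandpass", fs=rec.rate, output="sos")
    return rec.copy(data=sps.sosfiltfilt(sos, rec.data, axis=1))


def select_segments(rec: Recording, label: str = "eyes_closed") -> Recording:
    """Keep only the spans annotated with ``label``, concatenated.

    Span boundaries are recorded in ``segments`` so later stages never run a
    microstate across a splice.
    """
    spans = []
    for onset, length, lab in rec.annotations:
        if lab == label:
            start = int(round(onset * rec.rate))
            stop = int(round((onset + length) * rec.rate))
            spans.append((start, min(stop, rec.n_samples)))
    if not spans:
        raise ValueError(f"no usable segment: no annotation labelled {label!r}")
    spans.sort()
    pieces, bounds, cursor = [], [], 0
    for start, stop in spans:
        pieces.append(rec.data[:, start:stop])
        bounds.append((cursor, cursor + stop - start))
        cursor += stop - start
    return rec.copy(data=np.concatenate(pieces, axis=1), annotations=[], segments=bounds)


def average_reference(rec: Recording) -> Recording:
    """Subtract the instantaneous channel mean (common average reference)."""
    if rec.reference == "average":
        raise ValueError("recording is already average-referenced")
    data = rec.data - rec.data.mean(axis=0, keepdims=True)
    return rec.copy(data=data, reference="average")


def interpolate_bad(rec: Recording) -> Recording:
    """Interpolate a single bad channel; refuse recordings with more.

    Mirrors the study's inclusion rule: one artifacted channel is tolerated
    and interpolated, more than one excludes the recording.  Interpolation is
    an inverse-squared great-circle-distance weighted mean of the good
    channels.
    """
    if not rec.bads:
        return rec.copy()
    if len(rec.bads) > 1:
        raise ValueError(f"exclude recording: {len(rec.bads)} bad channels ({rec.bads})")
    bad_idx = rec.layout.index(rec.bads[0])
    pos = rec.layout.positions
    good = [i for i in range(rec.n_channels) if i != bad_idx]
    cosang = np.clip(pos[good] @ pos[bad_idx], -1.0, 1.0)
    dist = np.arccos(cosang)
    w = 1.0 / np.maximum(dist, 1e-6) ** 2
    w = w / w.sum()
    data = rec.data.copy()
    data[bad_idx] = w @ rec.data[good]
    return rec.copy(data=data, bads=[])


def alpha_dominance(rec: Recording, nperseg_s: float = 2.0) -> PSDReport:
    """Welch PSD QC: is mean alpha (8-13 Hz) power the largest band power?

    2-s Hann windows, 50 % overlap, averaged over channels.  The record is
    alpha-dominant when the 8-13 Hz mean power exceeds the mean power in
    each of the delta, theta and beta bands.
    """
    if rec.duration < 4.0:
        raise ValueError("record too short for the spectral QC (need >= 4 s)")
    nperseg = int(round(nperseg_s * rec.rate))
    freqs, pxx = sps.welch(rec.data, fs=rec.rate, window="hann",
                           nperseg=nperseg, noverlap=nperseg // 2, axis=1)
    mean_psd = pxx.mean(axis=0)
    band_power = {}
    for name, (lo, hi) in BANDS.items():
        sel = (freqs >= lo) & (freqs < hi)
        band_power[name] = float(mean_psd[sel].mean()) if sel.any() else 0.0
    alpha = band_power["alpha"]
    dominant = all(alpha > band_power[b] for b in ("delta", "theta", "beta"))
    return PSDReport(frequencies=freqs, power=pxx, band_power=band_power,
                     alpha_dominant=dominant)


def preprocess_recording(rec: Recording, low: float = 0.5, high: float = 40.0,
                         segment_label: str = "eyes_closed") -> tuple[Recording, PSDReport]:
    """Run the full fixed-order preprocessing chain on one recording."""
    out = bandpass(rec, low, high)
    out = select_segments(out, segment_label)
    out = average_reference(out)
    out = interpolate_bad(out)
    report = alpha_dominance(out)
    return out, report
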