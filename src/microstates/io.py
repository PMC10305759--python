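"""EDF+ writing and BIDS-like cohort round-trip.

The writer emits minimal continuous EDF+ (16-bit, 1-s data records, one
"EDF Annotations" signal carrying the annotation list); reading goes
through MNE's native EDF reader.  A cohort is laid out BIDS-style:

    cohort/
      participants.tsv                      # participant_id, group, age, sex
      truth.json                            # generator ground truth (synthetic cohorts)
      sub-XXX/eeg/sub-XXX_task-rest_eeg.edf
      sub-XXX/eeg/sub-XXX_task-rest_channels.tsv
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .layout import make_layout
from .preprocess import Recording
from .simulate import CohortSpec, GroundTruth, simulate_cohort

_ANN_SAMPLES = 60  # 120 bytes of annotation space per 1-s record


def _field(value, width: int) -> bytes:
    s = str(value)
    if len(s) > width:
        raise ValueError(f"EDF header field too long: {s!r}")
    return s.ljust(width).encode("ascii")


def write_edf(rec: Recording, path) -> None:
    """Write a recording as continuous EDF+ (physical unit microvolts).

    The record duration is 1 s, so the sampling rate must be an integer;
    the signal is zero-padded to a whole number of seconds.
    """
    path = Path(path)
    rate = int(round(rec.rate))
    if abs(rate - rec.rate) > 1e-9:
        raise ValueError("EDF writer requires an integer sampling rate")
    n_records = int(np.ceil(rec.n_samples / rate))
    data = np.zeros((rec.n_channels, n_records * rate))
    data[:, :rec.n_samples] = rec.data
    # per-channel symmetric physical range -> 16-bit digital
    pmax = np.maximum(np.abs(data).max(axis=1) * 1.0001, 1e-3)
    dig = np.round(data / pmax[:, None] * 32767).astype("<i2")
    ns = rec.n_channels + 1

    header = b"".join([
        _field("0", 8),
        _field("X X X X", 80),
        _field("Startdate X X X X", 80),
        _field("01.01.00", 8),
        _field("00.00.00", 8),
        _field(256 * (ns + 1), 8),
        _field("EDF+C", 44),
        _field(n_records, 8),
        _field(1, 8),
        _field(ns, 4),
    ])
    labels = [name for name in rec.layout.channel_names] + ["EDF Annotations"]
    fields = []
    for width, values in [
        (16, labels),
        (80, [""] * ns),
        (8, ["uV"] * rec.n_channels + [""]),
        (8, [f"{-p:.6g}"[:8] for p in pmax] + ["-1"]),
        (8, [f"{p:.6g}"[:8] for p in pmax] + ["1"]),
        (8, ["-32768"] * rec.n_channels + ["-32768"]),
        (8, ["32767"] * rec.n_channels + ["32767"]),
        (80, [""] * ns),
        (8, [rate] * rec.n_channels + [_ANN_SAMPLES]),
        (32, [""] * ns),
    ]:
        fields.append(b"".join(_field(v, width) for v in values))
    with open(path, "wb") as fh:
        fh.write(header + b"".join(fields))
        annots = sorted(rec.annotations)
        for r in range(n_records):
            for ch in range(rec.n_channels):
                fh.write(dig[ch, r * rate:(r + 1) * rate].tobytes())
            tal = f"+{r}\x14\x14\x00".encode("ascii")
            if r == 0:
                for onset, dur, label in annots:
                    tal += (f"+{onset:g}\x15{dur:g}\x14{label}\x14\x00"
                            .encode("ascii"))
            if len(tal) > 2 * _ANN_SAMPLES:
                raise ValueError("annotation text exceeds the reserved space")
            fh.write(tal.ljust(2 * _ANN_SAMPLES, b"\x00"))


def read_edf(path, bads: list[str] | None = None) -> Recording:
    """Read an EDF/EDF+ file into a Recording (microvolts) via MNE.

    Channel labels are normalized through the 10-20 synonym table
    (T7<->T3 etc.) so modern and classic montage names both resolve.
    """
    import mne

    from .layout import CHANNEL_SYNONYMS

    raw = mne.io.read_raw_edf(path, preload=True, verbose="error")
    layout = make_layout()
    names = [CHANNEL_SYNONYMS.get(n.strip(), n.strip()) for n in raw.ch_names]
    picks = [names.index(name) for name in layout.channel_names]
    data = raw.get_data(picks=picks) * 1e6
    annotations = [(float(a["onset"]), float(a["duration"]), str(a["description"]))
                   for a in raw.annotations]
    return Recording(data=data, rate=float(raw.info["sfreq"]), layout=layout,
                     annotations=annotations, bads=list(bads or []))


# ---------------------------------------------------------------------------
# cohort trees

def write_cohort(spec: CohortSpec, root) -> Path:
    """Simulate a cohort and write it as a BIDS-like EDF+ tree."""
    recordings, truth = simulate_cohort(spec)
    return write_cohort_data(recordings, truth, root)


def write_cohort_data(recordings: dict[str, list], truth: GroundTruth, root) -> Path:
    root = Path(root)
    root.mkdir(parents=True, exist_ok=True)
    rows = []
    by_subject = {s["subject"]: s for s in truth.subjects}
    idx = 0
    order = []
    for group, recs in recordings.items():
        for rec in recs:
            sid = truth.subjects[idx]["subject"]
            assert truth.subjects[idx]["group"] == group
            order.append((sid, group, rec))
            idx += 1
    for sid, group, rec in order:
        meta = by_subject[sid]
        eeg_dir = root / sid / "eeg"
        eeg_dir.mkdir(parents=True, exist_ok=True)
        write_edf(rec, eeg_dir / f"{sid}_task-rest_eeg.edf")
        chan = pd.DataFrame({
            "name": rec.layout.channel_names,
            "status": ["bad" if n in rec.bads else "good"
                       for n in rec.layout.channel_names],
        })
        chan.to_csv(eeg_dir / f"{sid}_task-rest_channels.tsv", sep="\t", index=False)
        rows.append({"participant_id": sid, "group": group,
                     "age": meta["age"], "sex": meta["sex"]})
    pd.DataFrame(rows).to_csv(root / "participants.tsv", sep="\t", index=False)
    payload = {
        "maps": truth.maps.maps.tolist(),
        "class_labels": list(truth.maps.class_labels),
        "effect_sizes": truth.effect_sizes,
        "subjects": {
            s["subject"]: {
                "group": s["group"],
                "stats": s["stats"].to_dict(),
            } for s in truth.subjects
        },
    }
    (root / "truth.json").write_text(json.dumps(payload, indent=1))
    return root


def read_cohort(root) -> tuple[pd.DataFrame, dict[str, Recording]]:
    """Load a BIDS-like cohort: participants table and recordings by subject."""
    root = Path(root)
    part = pd.read_csv(root / "participants.tsv", sep="\t")
    recordings = {}
    for sid in part["participant_id"]:
        eeg_dir = root / sid / "eeg"
        chan_path = eeg_dir / f"{sid}_task-rest_channels.tsv"
        bads = []
        if chan_path.exists():
            chan = pd.read_csv(chan_path, sep="\t")
            bads = list(chan.loc[chan["status"] == "bad", "name"])
        recordings[sid] = read_edf(eeg_dir / f"{sid}_task-rest_eeg.edf", bads=bads)
    return part, recordings


def read_truth(root) -> dict:
    return json.loads((Path(root) / "truth.json").read_text())


def stats_frame(stats_by_subject: dict[str, tuple[str, "MicrostateStats"]]) -> pd.DataFrame:
    """Tidy (subject, group, class, occurrence, coverage, mean_duration) table."""
    rows = []
    for sid, (group, st) in stats_by_subject.items():
        for i, cls in enumerate(st.class_names):
            rows.append({"subject": sid, "group": group, "class": cls,
                         "occurrence": st.occurrence[i],
                         "coverage": st.coverage[i],
                         "mean_duration": st.mean_duration[i]})
    return pd.DataFrame(rows)
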