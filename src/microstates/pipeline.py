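"""End-to-end cohort pipeline: preprocessing and QC, control-group map
estimation, backfitting to every subject, temporal statistics and the
group-comparison grid.

The stage order mirrors the analysis protocol: maps are estimated by
two-level clustering in the control group only, labelled A-D against the
canonical templates, then backfitted to all subjects (controls included) so
each group's parameters are measured against the same reference
topographies.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from datetime import datetime, timezone
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io as mio
from .backfit import backfit, cd_ratios, compute_stats, smooth_labels
from .cluster import MapSet, label_maps, two_level_cluster
from .inference import anova_adjusted, compare_all
from .layout import make_layout
from .preprocess import Recording, preprocess_recording
from .simulate import make_template_maps

__version__ = "0.1.0"


@dataclass
class PipelineConfig:
    """All tunable settings of a pipeline run, with protocol defaults."""

    cohort_root: str = "."
    output_dir: str = "results"
    band: tuple[float, float] = (0.5, 40.0)
    segment_label: str = "eyes_closed"
    n_clusters: int = 4
    k_range: tuple[int, ...] | None = None       # silhouette selection if set
    smoothing_window_ms: float = 82.0
    rope: tuple[float, float] = (-0.1, 0.1)
    rope_threshold: float = 0.95
    hdi_mass: float = 0.90
    draws: int = 10000
    control_group: str = "control"
    require_alpha_dominance: bool = True
    seed: int = 0

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        cfg = cls(**raw)
        for name in ("band", "rope"):
            setattr(cfg, name, tuple(getattr(cfg, name)))
        if cfg.k_range is not None:
            cfg.k_range = tuple(cfg.k_range)
        return cfg

    def to_yaml(self, path) -> None:
        d = dataclasses.asdict(self)
        d["band"] = list(self.band)
        d["rope"] = list(self.rope)
        if self.k_range is not None:
            d["k_range"] = list(self.k_range)
        Path(path).write_text(yaml.safe_dump(d, sort_keys=True))

    def digest(self) -> str:
        return hashlib.sha256(
            json.dumps(dataclasses.asdict(self), sort_keys=True, default=list)
            .encode()).hexdigest()[:16]


@dataclass
class RunManifest:
    """Inclusion/exclusion accounting for every screened subject."""

    version: str
    config_digest: str
    subjects: dict[str, dict] = field(default_factory=dict)
    started: str = ""
    finished: str = ""

    def mark(self, subject: str, included: bool, reason: str = "") -> None:
        if subject in self.subjects:
            raise ValueError(f"subject {subject} screened twice")
        self.subjects[subject] = {"included": included, "reason": reason}

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), indent=1)


@dataclass
class PipelineResults:
    """Everything a pipeline run produces, in memory."""

    manifest: RunManifest
    group_maps: MapSet
    map_correlations: np.ndarray
    stats: pd.DataFrame
    ratios: pd.DataFrame
    best: pd.DataFrame
    anova: pd.DataFrame
    silhouette: dict[int, float] | None = None


def screen_subjects(recordings: dict[str, Recording], config: PipelineConfig,
                    manifest: RunManifest) -> dict[str, Recording]:
    """Preprocess every subject, recording inclusion/exclusion decisions."""
    included = {}
    for sid, rec in recordings.items():
        try:
            clean, report = preprocess_recording(rec, *config.band,
                                                 segment_label=config.segment_label)
            if config.require_alpha_dominance and not report.alpha_dominant:
                manifest.mark(sid, False, "alpha band not dominant")
                continue
        except ValueError as exc:
            manifest.mark(sid, False, str(exc))
            continue
        manifest.mark(sid, True)
        included[sid] = clean
    return included


def analyze_cohort(recordings: dict[str, Recording], participants: pd.DataFrame,
                   config: PipelineConfig) -> PipelineResults:
    """Run every analysis stage on already-loaded recordings.

    ``participants`` must have columns participant_id, group, age, sex and a
    row for every recording.
    """
    groups = dict(zip(participants["participant_id"], participants["group"]))
    if config.control_group not in set(groups.values()):
        raise ValueError(f"no control group {config.control_group!r} in the cohort")
    manifest = RunManifest(version=__version__, config_digest=config.digest(),
                           started=datetime.now(timezone.utc).isoformat())
    included = screen_subjects(recordings, config, manifest)
    if not included:
        raise ValueError("empty cohort after quality control")
    control_ids = [sid for sid in included if groups[sid] == config.control_group]
    if not control_ids:
        raise ValueError("no control subject survived quality control")

    rng = np.random.default_rng(config.seed)
    silhouette = None
    n_clusters = config.n_clusters
    if config.k_range is not None:
        from .cluster import gfp, gfp_peaks, modified_kmeans, silhouette_k
        subject_maps = []
        for sid in control_ids:
            rec = included[sid]
            series = gfp(rec)
            peaks = gfp_peaks(series)
            fit = modified_kmeans(rec.data[:, peaks].T, max(config.k_range),
                                  seed=rng.integers(2 ** 31),
                                  peak_gfp=series.values[peaks])
            subject_maps.append(fit.mapset.maps)
        n_clusters, silhouette = silhouette_k(np.concatenate(subject_maps),
                                              config.k_range,
                                              seed=rng.integers(2 ** 31))

    control_maps = two_level_cluster([included[s] for s in control_ids],
                                     n_clusters, seed=rng.integers(2 ** 31))
    reference = make_template_maps(make_layout(), seed=0, perturbation=0.0)
    if n_clusters == reference.n_maps:
        control_maps, corr = label_maps(control_maps, reference)
    else:
        corr = np.abs(control_maps.maps @ control_maps.maps.T)
    control_maps.provenance = ("control-reference",)

    stats_by_subject, ratio_rows = {}, []
    for sid, rec in included.items():
        seq = smooth_labels(backfit(rec, control_maps), config.smoothing_window_ms)
        st = compute_stats(seq)
        stats_by_subject[sid] = (groups[sid], st)
        if "C" in st.class_names and "D" in st.class_names:
            import warnings
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                r = cd_ratios(st)
            ratio_rows.append({"subject": sid, "group": groups[sid],
                               "occurrence": r.occurrence, "coverage": r.coverage,
                               "mean_duration": r.mean_duration})
    stats = mio.stats_frame(stats_by_subject)
    ratios = pd.DataFrame(ratio_rows)

    best = compare_all(stats, config.control_group,
                       ratios=ratios if not ratios.empty else None,
                       rope=config.rope, draws=config.draws,
                       seed=rng.integers(2 ** 31),
                       rope_threshold=config.rope_threshold,
                       hdi_mass=config.hdi_mass)

    demo = participants.set_index("participant_id")
    anova_rows = []
    disease = stats[stats["group"] != config.control_group]
    for cls in ("C", "D"):
        for param in ("occurrence", "coverage", "mean_duration"):
            sub = disease[disease["class"] == cls].dropna(subset=[param])
            if sub["group"].nunique() < 2 or sub.groupby("group").size().min() < 3:
                continue
            res = anova_adjusted(sub[param], sub["group"],
                                 demo.loc[sub["subject"], "age"],
                                 demo.loc[sub["subject"], "sex"])
            anova_rows.append({"target": cls, "parameter": param,
                               "F": res.f_stat, "df_num": res.df_num,
                               "df_den": res.df_den, "p": res.p_value,
                               "levene_p": res.levene_p})
    anova = pd.DataFrame(anova_rows)
    manifest.finished = datetime.now(timezone.utc).isoformat()
    return PipelineResults(manifest=manifest, group_maps=control_maps,
                           map_correlations=corr, stats=stats, ratios=ratios,
                           best=best, anova=anova, silhouette=silhouette)


def run_pipeline(config: PipelineConfig) -> PipelineResults:
    """Load a BIDS-like cohort from disk, analyze it, persist all outputs."""
    participants, recordings = mio.read_cohort(config.cohort_root)
    results = analyze_cohort(recordings, participants, config)
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    config.to_yaml(out / "config_resolved.yaml")
    (out / "manifest.json").write_text(results.manifest.to_json())
    columns = (list(make_layout().channel_names)
               if results.group_maps.n_channels == 19 else None)
    maps_df = pd.DataFrame(results.group_maps.maps,
                           index=list(results.group_maps.class_labels or
                                      range(results.group_maps.n_maps)),
                           columns=columns)
    maps_df.to_csv(out / "group_maps.csv")
    results.stats.to_csv(out / "stats.csv", index=False)
    results.ratios.to_csv(out / "ratios.csv", index=False)
    results.best.to_csv(out / "best_comparisons.csv", index=False)
    results.anova.to_csv(out / "anova.csv", index=False)
    if results.silhouette is not None:
        pd.Series(results.silhouette, name="silhouette").rename_axis("K") \
            .to_csv(out / "silhouette.csv")
    return results
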