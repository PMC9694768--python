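"""End-to-end orchestration: synth → noise → preprocess → features → stats → classify.

One :class:`PipelineConfig` drives the whole experiment; a single global
seed fans out to per-stage seed sequences (spawn keys documented below),
so every stage is independently reproducible.  Outputs are written both
machine-readable (CSV/JSON) and human-readable (markdown).

Seed fan-out (``numpy.random.SeedSequence(seed, spawn_key=...)``):
``(0,)`` cohort synthesis, ``(2, s, k)`` noise for subject s at SNR
target index k, ``(3,)`` statistics Monte-Carlo.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .classify import RfConfig, run_experiments
from .features import FeatureConfig, estimate_psd, extract_features
from .io import (
    FEATURE_COLUMNS,
    EggRecord,
    SegmentPlan,
    read_feature_table,
    write_feature_table,
)
from .noise import measure_inband_snr, scale_noise_to_snr
from .preprocess import FilterSpec, Segment, bandpass, segment_and_label, select_channel
from .stats import categorical_report, nausea_report, robustness_report, to_markdown
from .synth import SynthConfig, generate_cohort

__all__ = ["PipelineConfig", "run_all", "validate_external", "build_feature_table"]

DEFAULT_SNR_TARGETS = (-20.0, -10.0, 0.0, 10.0, 20.0)


@dataclass
class PipelineConfig:
    """Full experiment configuration."""

    synth: SynthConfig = field(default_factory=SynthConfig)
    n_subjects: int = 17
    snr_targets_db: tuple[float, ...] = DEFAULT_SNR_TARGETS
    filter_spec: FilterSpec = field(default_factory=FilterSpec)
    features: FeatureConfig = field(default_factory=FeatureConfig)
    rf: RfConfig = field(default_factory=RfConfig)
    alpha: float = 0.05
    seed: int = 0
    skip_noise: bool = False
    skip_classifier: bool = False

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        kw = dict(d)
        if "synth" in kw:
            kw["synth"] = SynthConfig(**kw["synth"])
        if "filter_spec" in kw:
            kw["filter_spec"] = FilterSpec(**kw["filter_spec"])
        if "features" in kw:
            kw["features"] = FeatureConfig(**kw["features"])
        if "rf" in kw:
            kw["rf"] = RfConfig(**kw["rf"])
        for tup_key in ("snr_targets_db",):
            if tup_key in kw:
                kw[tup_key] = tuple(kw[tup_key])
        return cls(**kw)


def _snr_tag(target_db: float) -> str:
    return f"{target_db:g}dB"


def build_feature_table(
    segments: list[Segment],
    config: FeatureConfig,
    snr_tag: str = "original",
    references: list[Segment] | None = None,
) -> pd.DataFrame:
    """Feature table (one row per segment) with metadata columns.

    ``references`` supplies the noiseless twins whose standard deviations
    fix the sample-entropy tolerances of noisy segments.
    """
    rows = []
    for i, seg in enumerate(segments):
        if references is not None:
            ref = references[i]
            ref_sd = float(np.std(ref.samples))
            ref_psd_sd = float(np.std(estimate_psd(ref.samples, ref.fs, config).inband_psd))
        else:
            ref_sd = ref_psd_sd = None
        feats = extract_features(seg, config, r_reference_sd=ref_sd,
                                 r_reference_psd_sd=ref_psd_sd)
        rows.append({"subject_id": seg.subject_id, "condition": seg.condition,
                     "nausea": seg.nausea, "snr_tag": snr_tag, **feats})
    return pd.DataFrame(rows)


def _noisy_record(
    record: EggRecord, plan: SegmentPlan, target_db: float, seed_key: tuple
) -> tuple[EggRecord, np.ndarray]:
    """Raw noisy twin plus the per-channel noise components.

    One independent white-noise realisation per (segment, channel), each
    scaled against that segment's raw power, so every segment sits at the
    target SNR before filtering.  Filtering happens downstream on the
    whole record.
    """
    noisy = np.empty_like(record.channels)
    noises = np.zeros_like(record.channels)
    for c in range(record.n_channels):
        for g, (_, start, end) in enumerate(plan.intervals):
            i0 = int(round((start - record.start_time) * record.fs))
            i1 = int(round((end - record.start_time) * record.fs))
            rng = np.random.default_rng(
                np.random.SeedSequence(seed_key[0], spawn_key=seed_key[1:] + (g, c))
            )
            noises[c, i0:i1] = scale_noise_to_snr(
                record.channels[c, i0:i1], rng.standard_normal(i1 - i0), target_db
            )
        noisy[c] = record.channels[c] + noises[c]
    twin = EggRecord(record.subject_id, noisy, record.fs, record.start_time,
                     record.artifact_mask.copy(), record.events.copy())
    return twin, noises


def run_all(config: PipelineConfig, outdir: str | Path | None = None) -> dict:
    """Run the full experiment; optionally write the report bundle.

    Returns a dict with the feature tables, achieved-SNR summary,
    robustness/nausea/categorical reports, classifier results and a
    provenance manifest.
    """
    plan = SegmentPlan.default(config.synth.duration_s)
    records, labels = generate_cohort(config.synth, config.n_subjects, seed=config.seed)

    channels = [select_channel(r) for r in records]
    orig_segments: list[Segment] = []
    for r, ch in zip(records, channels):
        orig_segments.extend(segment_and_label(r, plan, ch, config.filter_spec))
    original_table = build_feature_table(orig_segments, config.features, "original")

    noisy_tables: dict[str, pd.DataFrame] = {}
    achieved: dict[str, dict] = {}
    if not config.skip_noise:
        for k, target in enumerate(config.snr_targets_db):
            tag = _snr_tag(target)
            noisy_segments: list[Segment] = []
            per_seg_db: list[float] = []
            pooled_sig = pooled_noise = 0.0
            for s, (r, ch) in enumerate(zip(records, channels)):
                twin, noises = _noisy_record(r, plan, target, (config.seed, 2, s, k))
                noisy_segments.extend(segment_and_label(twin, plan, ch, config.filter_spec))
                db = measure_inband_snr(r.channels[ch], noises[ch], config.filter_spec, r.fs)
                per_seg_db.append(db)
                pooled_sig += float(np.mean(np.square(bandpass(r.channels[ch], config.filter_spec, r.fs))))
                pooled_noise += float(np.mean(np.square(bandpass(noises[ch], config.filter_spec, r.fs))))
            noisy_tables[tag] = build_feature_table(
                noisy_segments, config.features, tag, references=orig_segments
            )
            achieved[tag] = {
                "target_db": target,
                "per_record_mean_db": float(np.mean(per_seg_db)),
                "pooled_db": 10.0 * float(np.log10(pooled_sig / pooled_noise)),
            }

    stats_seed = int(np.random.SeedSequence(config.seed, spawn_key=(3,)).generate_state(1)[0] % 2**31)
    reports: dict[str, pd.DataFrame] = {}
    if noisy_tables:
        reports["robustness"] = robustness_report(original_table, noisy_tables, config.alpha)
    nausea_frames = [nausea_report(original_table, config.alpha).assign(snr_tag="original")]
    cat_frames = [categorical_report(original_table, config.features.sampent_threshold,
                                     seed=stats_seed, alpha=config.alpha).assign(snr_tag="original")]
    for tag, t in noisy_tables.items():
        nausea_frames.append(nausea_report(t, config.alpha).assign(snr_tag=tag))
        cat_frames.append(categorical_report(t, config.features.sampent_threshold,
                                             seed=stats_seed, alpha=config.alpha).assign(snr_tag=tag))
    reports["nausea"] = pd.concat(nausea_frames, ignore_index=True)
    reports["categorical"] = pd.concat(cat_frames, ignore_index=True)

    classifier = None
    if not config.skip_classifier:
        classifier = run_experiments(original_table, noisy_tables, config.rf)

    manifest = {
        "version": __version__,
        "seed": config.seed,
        "n_subjects": config.n_subjects,
        "n_segments": len(orig_segments),
        "n_positive": int(original_table["nausea"].sum()),
        "snr_targets_db": list(config.snr_targets_db),
        "rf_seed": config.rf.seed,
        "n_trees": config.rf.n_trees,
        "mtry_grid": list(config.rf.mtry_grid),
    }
    bundle = {
        "original_table": original_table,
        "noisy_tables": noisy_tables,
        "achieved_snr": achieved,
        "reports": reports,
        "classifier": classifier,
        "manifest": manifest,
    }
    if outdir is not None:
        _write_bundle(bundle, Path(outdir))
    return bundle


def _write_bundle(bundle: dict, outdir: Path) -> None:
    outdir.mkdir(parents=True, exist_ok=True)
    write_feature_table(bundle["original_table"], outdir / "features_original.csv")
    for tag, t in bundle["noisy_tables"].items():
        write_feature_table(t, outdir / f"features_{tag}.csv")
    for name, df in bundle["reports"].items():
        df.to_csv(outdir / f"report_{name}.csv", index=False)
        (outdir / f"report_{name}.md").write_text(to_markdown(df))
    if bundle["classifier"] is not None:
        payload = {
            variant: {tag: res.to_dict() | {"importance_top5": res.importance[:5]}
                      for tag, res in by_tag.items()}
            for variant, by_tag in bundle["classifier"].items()
        }
        (outdir / "classifier.json").write_text(json.dumps(payload, indent=2))
    (outdir / "achieved_snr.json").write_text(json.dumps(bundle["achieved_snr"], indent=2))
    (outdir / "manifest.json").write_text(json.dumps(bundle["manifest"], indent=2))


def validate_external(
    path: str | Path,
    column_map: dict[str, str] | None = None,
    rf_config: RfConfig = RfConfig(),
    alpha: float = 0.05,
) -> dict:
    """Run the statistics and classifier stages on an externally supplied
    feature table (e.g. the study authors' shared CSV).

    ``column_map`` maps external column names to the canonical schema.
    Raises a mapping error listing candidate columns when features are
    missing after mapping.
    """
    df = pd.read_csv(path)
    if column_map:
        df = df.rename(columns=column_map)
    if "snr_tag" not in df.columns:
        df["snr_tag"] = "original"
    if "subject_id" not in df.columns and "subject" in df.columns:
        df = df.rename(columns={"subject": "subject_id"})
    needed = ["subject_id", "condition", "nausea"] + FEATURE_COLUMNS
    missing = [c for c in needed if c not in df.columns]
    if missing:
        raise ValueError(
            f"unmapped columns {missing}; available candidates: {sorted(df.columns)}"
        )
    table = df[["subject_id", "condition", "nausea", "snr_tag"] + FEATURE_COLUMNS].copy()
    results = {
        "n_rows": len(table),
        "n_positive": int(table["nausea"].sum()),
        "nausea_report": nausea_report(table, alpha),
        "categorical_report": categorical_report(table, seed=rf_config.seed, alpha=alpha),
        "classifier": run_experiments(table, {}, rf_config),
    }
    return results
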