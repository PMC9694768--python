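"""Synthetic EGG cohort generator.

Emulates the qualitative structure of cutaneous electrogastrograms: a
~3 cpm gastric slow wave of µV-scale amplitude whose frequency wanders
slowly (AR(1) jitter on the instantaneous frequency), sub-1-cpm baseline
drift, wideband instrumentation noise, and sporadic short high-amplitude
motion-artifact spikes.  The nausea state shifts the slow wave to a
higher frequency, raises its amplitude and widens the frequency jitter —
the canonical dysrhythmic signature of nausea.

These are phenomenological signals for exercising the pipeline; they make
no claim of physiological conduction modelling.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .io import CONDITIONS, EggRecord, SegmentPlan

__all__ = ["SynthConfig", "generate_segment", "generate_cohort", "inject_artifacts"]


@dataclass
class SynthConfig:
    """Parameters of the synthetic EGG generator.

    Defaults mirror the recording protocol this generator emulates:
    2 Hz sampling, four ~7 min session segments, a 3 cpm baseline slow
    wave, and a nausea state at 6 cpm with larger amplitude and jitter.
    Amplitudes are order-of-magnitude µV values; the real-data amplitude
    distribution is not characterised, so these are synthetic by design.
    """

    fs: float = 2.0                      # Hz
    duration_s: float = 420.0            # per segment (~7 min drive scenes)
    f_base: float = 3.0                  # cpm, normogastric rhythm
    f_nausea: float = 6.0                # cpm, tachygastric shift
    amp_base: float = 100.0              # µV
    amp_nausea: float = 150.0            # µV
    freq_jitter_sd_base: float = 0.15    # cpm
    freq_jitter_sd_nausea: float = 0.6   # cpm
    jitter_ar_coef: float = 0.99         # AR(1) coefficient of the jitter
    drift_amp: float = 200.0             # µV
    drift_freq: float = 0.3              # cpm, sub-band baseline wander
    wideband_sd: float = 10.0            # µV white-noise floor
    artifact_rate: float = 0.5           # spikes per minute
    artifact_amp: float = 1000.0         # µV
    artifact_width_s: float = 1.5
    nausea_prevalence: float = 0.176     # fraction of segments labelled 1
    n_channels: int = 3
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("f_base", "f_nausea"):
            f = getattr(self, name)
            if not 1.0 < f < 10.0:
                raise ValueError(f"{name}={f} cpm outside the (1, 10) cpm analysis band")
        for name in ("amp_base", "amp_nausea", "drift_amp", "wideband_sd", "artifact_amp"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if not 0.0 <= self.nausea_prevalence <= 1.0:
            raise ValueError("nausea_prevalence must be in [0, 1]")


def inject_artifacts(
    signal: np.ndarray,
    rate: float,
    amp: float,
    width_s: float,
    fs: float,
    seed: int | np.random.Generator = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Add Poisson-placed biphasic spikes; return (signal, boolean mask).

    Spike onsets follow a homogeneous Poisson process of ``rate`` events
    per minute; each spike is one biphasic (single-cycle sine) transient
    of peak amplitude ``amp`` µV and total width ``width_s`` seconds.
    The mask is True exactly on affected samples.
    """
    if rate < 0:
        raise ValueError("artifact rate must be non-negative")
    width = int(round(width_s * fs))
    if width < 1:
        raise ValueError(f"artifact width {width_s}s is below one sample at fs={fs}")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    out = np.array(signal, dtype=float, copy=True)
    mask = np.zeros(out.size, dtype=bool)
    n_events = rng.poisson(rate * out.size / fs / 60.0)
    pulse = amp * np.sin(2 * np.pi * np.arange(width) / width)
    for start in rng.integers(0, max(out.size - width, 1), size=n_events):
        out[start : start + width] += pulse[: out.size - start]
        mask[start : start + width] = True
    return out, mask


def _slow_wave(cfg: SynthConfig, state: str, rng: np.random.Generator) -> np.ndarray:
    """Amplitude-modulated sinusoid with AR(1) instantaneous-frequency jitter."""
    n = int(round(cfg.duration_s * cfg.fs))
    if state == "baseline":
        f0, amp, jitter_sd = cfg.f_base, cfg.amp_base, cfg.freq_jitter_sd_base
    elif state == "nausea":
        f0, amp, jitter_sd = cfg.f_nausea, cfg.amp_nausea, cfg.freq_jitter_sd_nausea
    else:
        raise ValueError(f"state must be 'baseline' or 'nausea', got {state!r}")
    phi = cfg.jitter_ar_coef
    if jitter_sd > 0:
        innov = rng.normal(0.0, jitter_sd * np.sqrt(1 - phi**2), size=n)
        jitter = np.empty(n)
        j = rng.normal(0.0, jitter_sd)  # start at stationarity
        for i in range(n):
            j = phi * j + innov[i]
            jitter[i] = j
    else:
        jitter = np.zeros(n)
    f_inst_hz = (f0 + jitter) / 60.0
    phase = 2 * np.pi * np.cumsum(f_inst_hz) / cfg.fs
    return amp * np.sin(phase)


def generate_segment(
    config: SynthConfig, state: str, seed: int | np.random.Generator | None = None
) -> EggRecord:
    """Generate one synthetic EGG segment in the given state.

    Deterministic per seed.  Channels share the state parameters but have
    independent jitter, noise and artifact streams, so channel selection
    by artifact count is a meaningful downstream step.
    """
    if seed is None:
        seed = config.seed
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    n = int(round(config.duration_s * config.fs))
    t = np.arange(n) / config.fs
    channels = np.empty((config.n_channels, n))
    masks = np.empty((config.n_channels, n), dtype=bool)
    for c in range(config.n_channels):
        x = _slow_wave(config, state, rng)
        if config.drift_amp > 0:
            drift_phase = rng.uniform(0, 2 * np.pi)
            x = x + config.drift_amp * np.sin(
                2 * np.pi * config.drift_freq / 60.0 * t + drift_phase
            )
        if config.wideband_sd > 0:
            x = x + rng.normal(0.0, config.wideband_sd, size=n)
        x, mask = inject_artifacts(
            x, config.artifact_rate, config.artifact_amp, config.artifact_width_s,
            config.fs, rng,
        )
        channels[c], masks[c] = x, mask
    return EggRecord(
        subject_id="synthetic", channels=channels, fs=config.fs, artifact_mask=masks
    )


def assign_nausea_labels(
    n_subjects: int, prevalence: float, rng: np.random.Generator
) -> np.ndarray:
    """Boolean label matrix (n_subjects, 4); positives go to non-baseline
    segments first, since baseline precedes sickness induction."""
    n_pos = int(round(prevalence * 4 * n_subjects))
    labels = np.zeros((n_subjects, 4), dtype=bool)
    # slots ordered: all drive/rest slots first, baselines only on overflow
    non_base = [(s, c) for s in range(n_subjects) for c in (1, 2, 3)]
    base = [(s, 0) for s in range(n_subjects)]
    order = list(rng.permutation(len(non_base)))
    slots = [non_base[i] for i in order] + base
    for s, c in slots[:n_pos]:
        labels[s, c] = True
    return labels


def generate_cohort(
    config: SynthConfig, n_subjects: int = 17, seed: int | None = None
) -> tuple[list[EggRecord], list[dict]]:
    """Generate a cohort of full-session recordings plus segment labels.

    Each subject's record concatenates four segments (baseline, highway,
    countryside, rest).  A nausea-positive segment is generated from the
    nausea state and receives a button-press event at a random time
    inside it.  The number of positive segments is
    ``round(prevalence * 4 * n_subjects)``.

    Returns
    -------
    records : list of EggRecord
    labels : list of dict
        One per segment with keys subject_id, condition, nausea.
    """
    if n_subjects < 1:
        raise ValueError("n_subjects must be >= 1")
    if seed is None:
        seed = config.seed
    root = np.random.SeedSequence(seed)
    label_rng = np.random.default_rng(root.spawn(1)[0])
    nausea = assign_nausea_labels(n_subjects, config.nausea_prevalence, label_rng)

    records: list[EggRecord] = []
    labels: list[dict] = []
    seg_cfg = replace(config)
    for s in range(n_subjects):
        subject_id = f"S{s + 1:02d}"
        chans, masks, events = [], [], []
        for c, condition in enumerate(CONDITIONS):
            state = "nausea" if nausea[s, c] else "baseline"
            seg_seed = np.random.SeedSequence(entropy=seed, spawn_key=(1 + s, c))
            rng = np.random.default_rng(seg_seed)
            rec = generate_segment(seg_cfg, state, rng)
            chans.append(rec.channels)
            masks.append(rec.artifact_mask)
            if nausea[s, c]:
                events.append(c * config.duration_s + rng.uniform(0, config.duration_s))
            labels.append(
                {"subject_id": subject_id, "condition": condition, "nausea": int(nausea[s, c])}
            )
        records.append(
            EggRecord(
                subject_id=subject_id,
                channels=np.concatenate(chans, axis=1),
                fs=config.fs,
                artifact_mask=np.concatenate(masks, axis=1),
                events=np.array(events),
            )
        )
    return records, labels


def default_plan(config: SynthConfig) -> SegmentPlan:
    """Segment plan matching :func:`generate_cohort`'s session layout."""
    return SegmentPlan.default(config.duration_s)
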