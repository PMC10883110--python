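"""Synthetic resting-state EEG cohorts with known microstate structure.

The generator emulates the qualitative structure the downstream analysis
assumes: piecewise-stable scalp topographies (80-120 ms segments drawn
from a small set of template maps, with random polarity per segment),
amplitude envelopes that produce realistic GFP peaks, additive sensor
noise, and — the planted ground truth — group-specific extra coupling
between chosen channel pairs confined to chosen microstates.

Every segment's amplitude time course is a Hann bump (with a floor, so
boundary samples never vanish) multiplied by a smooth low-pass noise
modulation: each segment therefore contains at least one interior GFP
maximum, and consecutive segments meet at low-amplitude troughs, as real
microstate data do.

On top of the rank-1 template component, every channel carries
independent smooth residual activity proportional to its local signal.
Coupling correlates the residuals of a planted channel pair within the
planted state's segments through variance-preserving mixing with a
shared instantaneous latent (the MI measure used downstream is
lag-free, so instantaneous mixing is the minimal sufficient mechanism);
channel marginals stay identical in distribution across groups, making
the planted pair's joint dependence the only group difference.

Per-subject amplitude and noise-level jitter model cohort heterogeneity;
they make window-level features overlap between groups the way real
patient cohorts do.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
from scipy import signal as sps

from .montage import CHANNELS_32
from .signal_core import Recording, write_recording_text
from .microstates import TemplateSet

GROUPS = ("MCS", "VS")


@dataclass(frozen=True)
class Coupling:
    """Planted extra dependence: (state, channel pair, group, strength)."""

    state: int
    pair: tuple[int, int]
    group: str
    strength: float


@dataclass
class SyntheticConfig:
    """Study conditions of the simulated cohort.

    Defaults follow the target study design: 32 channels at 250 Hz,
    5 minutes per subject, five microstate classes with 80-120 ms
    segments, and 16 subjects per group.
    """

    n_channels: int = 32
    fs: float = 250.0
    duration: float = 300.0
    k_states: int = 5
    segment_duration_ms: tuple[float, float] = (80.0, 120.0)
    noise_sd: float = 1.0
    amplitude: float = 20.0
    coupling: list[Coupling] = field(default_factory=list)
    n_per_group: tuple[int, int] = (16, 16)
    seed: int = 0
    # realism knobs
    envelope_base: float = 0.25
    modulation_depth: float = 0.3
    modulation_cutoff_hz: float = 15.0
    residual_frac: float = 0.5
    subject_amp_range: tuple[float, float] = (0.8, 1.2)
    subject_noise_range: tuple[float, float] = (0.75, 1.3)
    pink_noise: bool = False

    def __post_init__(self) -> None:
        if self.n_channels < 2:
            raise ValueError("need at least 2 channels")
        if self.fs <= 0:
            raise ValueError("sampling rate must be positive")
        lo, hi = self.segment_duration_ms
        if not 0 < lo <= hi:
            raise ValueError("segment duration range must satisfy 0 < min <= max")
        for c in self.coupling:
            i, j = c.pair
            if i == j or not (0 <= i < self.n_channels and 0 <= j < self.n_channels):
                raise ValueError(f"coupling pair {c.pair} must be distinct channels < n_channels")
            if not 0 <= c.strength < 1:
                raise ValueError("coupling strength must lie in [0, 1)")
            if c.group not in GROUPS:
                raise ValueError(f"coupling group must be one of {GROUPS}")
            if not 0 <= c.state < self.k_states:
                raise ValueError("coupling state must be a valid state index")

    @property
    def n_samples(self) -> int:
        return int(round(self.duration * self.fs))


@dataclass
class GroundTruth:
    """Per-subject generative ground truth."""

    true_labels: np.ndarray
    true_templates: TemplateSet
    planted_pairs: list[Coupling]
    segment_starts: np.ndarray
    segment_durations_ms: np.ndarray
    seed: int


@dataclass
class CohortManifest:
    true_templates: TemplateSet
    subjects: dict[str, GroundTruth]
    planted: dict[str, list[Coupling]]
    config: SyntheticConfig


def generate_template_maps(k: int, n_channels: int, seed: int) -> TemplateSet:
    """Random zero-mean, unit-norm, mutually orthogonal topographies.

    Average-reference-consistent maps live in the zero-sum subspace of
    dimension n_channels - 1, so at most that many orthogonal maps exist.
    Orthogonality makes all pairwise spatial correlations zero, well
    below the 0.7 separation bound required of a usable template set.
    """
    if k < 2:
        raise ValueError("need at least 2 template maps")
    if k > n_channels - 1:
        raise ValueError(
            f"at most n_channels - 1 = {n_channels - 1} zero-mean orthogonal maps exist"
        )
    rng = np.random.default_rng(seed)
    maps = rng.standard_normal((k, n_channels))
    maps -= maps.mean(axis=1, keepdims=True)
    # Gram-Schmidt within the zero-sum subspace
    for i in range(k):
        for j in range(i):
            maps[i] -= (maps[i] @ maps[j]) * maps[j]
        norm = np.linalg.norm(maps[i])
        if norm < 1e-12:  # pragma: no cover - probability zero
            raise RuntimeError("degenerate random draw")
        maps[i] /= norm
    labels = list(CHANNELS_32[:n_channels]) if n_channels <= len(CHANNELS_32) else None
    return TemplateSet(maps=maps, level="truth", channel_labels=labels)


def strong_effect_coupling(
    templates: TemplateSet,
    n_pairs: int = 2,
    strength: float = 0.8,
    group: str = "MCS",
) -> list[Coupling]:
    """Plant couplings where each state carries signal.

    For every template, the channels with the largest absolute weights
    are paired off (1st with 2nd, 3rd with 4th, ...): coupling channels
    that barely participate in a state would produce a vanishing effect,
    so a strong-effect experiment plants its pairs on the state's most
    active channels.
    """
    out = []
    for state in range(templates.k):
        order = np.argsort(-np.abs(templates.maps[state]))
        for p in range(n_pairs):
            i, j = int(order[2 * p]), int(order[2 * p + 1])
            out.append(
                Coupling(state=state, pair=(min(i, j), max(i, j)),
                         group=group, strength=strength)
            )
    return out


def draw_segment_plan(
    rng: np.random.Generator,
    n_samples: int,
    fs: float,
    dur_range_ms: tuple[float, float],
) -> tuple[np.ndarray, np.ndarray]:
    """Draw uniform segment durations and map them onto sample boundaries.

    Returns (durations_ms, boundaries); durations are the continuous
    uniform draws (last one truncated by the recording end), boundaries
    are cumulative-rounded sample offsets with boundaries[0] = 0 and
    boundaries[-1] = n_samples.
    """
    lo, hi = dur_range_ms
    total_ms = n_samples / fs * 1000.0
    # generous over-draw, then trim
    n_guess = int(total_ms / lo) + 8
    draws = rng.uniform(lo, hi, size=n_guess)
    while draws.sum() < total_ms:  # pragma: no cover - rare top-up
        draws = np.concatenate([draws, rng.uniform(lo, hi, size=16)])
    cum = np.cumsum(draws)
    n_seg = int(np.searchsorted(cum, total_ms)) + 1
    draws = draws[:n_seg]
    cum = cum[:n_seg]
    bounds = np.minimum(np.round(cum * fs / 1000.0).astype(np.intp), n_samples)
    bounds = np.concatenate(([0], bounds))
    bounds[-1] = n_samples
    keep = np.flatnonzero(np.diff(bounds) > 0)
    durations = draws[keep]
    bounds = np.concatenate(([0], bounds[1:][keep]))
    durations[-1] = (bounds[-1] - bounds[-2]) / fs * 1000.0
    return durations, bounds


def _smooth_noise(
    rng: np.random.Generator,
    n: int,
    fs: float,
    cutoff: float,
    shape: tuple[int, ...] | None = None,
) -> np.ndarray:
    """Unit-variance low-pass-filtered Gaussian noise (rows independent)."""
    raw = rng.standard_normal(shape if shape is not None else n)
    sos = sps.butter(2, cutoff, btype="lowpass", fs=fs, output="sos")
    z = sps.sosfiltfilt(sos, raw, axis=-1)
    sd = z.std(axis=-1, keepdims=True)
    return np.divide(z, sd, out=z, where=sd > 0)


def generate_subject_recording(
    templates: TemplateSet,
    config: SyntheticConfig,
    group: str,
    seed: int,
    subject_id: str = "",
) -> tuple[Recording, GroundTruth]:
    """Simulate one subject's recording from the shared template truth."""
    if templates.n_channels != config.n_channels:
        raise ValueError("template channel count does not match the config")
    if templates.k != config.k_states:
        raise ValueError("template count does not match k_states")
    if group not in GROUPS:
        raise ValueError(f"group must be one of {GROUPS}")
    rng = np.random.default_rng(seed)
    n = config.n_samples
    fs = config.fs

    durations_ms, bounds = draw_segment_plan(rng, n, fs, config.segment_duration_ms)
    n_seg = len(durations_ms)

    # state sequence without immediate repeats
    states = np.empty(n_seg, dtype=np.int64)
    states[0] = rng.integers(config.k_states)
    steps = rng.integers(1, config.k_states, size=n_seg - 1) if n_seg > 1 else []
    for i, step in enumerate(steps, start=1):
        states[i] = (states[i - 1] + step) % config.k_states

    signs = rng.choice([-1.0, 1.0], size=n_seg)
    seg_amps = rng.uniform(0.5, 1.5, size=n_seg)

    amp = np.empty(n)
    labels = np.empty(n, dtype=np.int64)
    base = config.envelope_base
    for s in range(n_seg):
        a, b = bounds[s], bounds[s + 1]
        bump = base + (1.0 - base) * np.hanning(b - a + 2)[1:-1]
        amp[a:b] = signs[s] * seg_amps[s] * bump
        labels[a:b] = states[s]

    if config.modulation_depth > 0:
        mod = _smooth_noise(rng, n, fs, config.modulation_cutoff_hz)
        amp *= np.clip(1.0 + config.modulation_depth * mod, 0.05, None)

    subj_amp = config.amplitude * rng.uniform(*config.subject_amp_range)
    data = templates.maps[labels].T * (subj_amp * amp)

    # Residual per-channel activity: each channel carries an independent
    # smooth waveform scaled by residual_frac times its own local signal
    # component (signed template weight times envelope), so scalp data
    # are not rank-1 within a segment. Coupling correlates the residuals
    # of a planted pair inside the planted state's segments by
    # variance-preserving mixing with a shared latent; the mixing weights
    # sqrt(1-strength), sqrt(strength) make `strength` the residual
    # correlation of the pair. Because the residual rides on the signed
    # template weight, the induced dependence always reinforces the
    # pair's baseline correlation, raising its mutual information.
    # Channel marginals — variance, topography statistics, GFP — are
    # identical in distribution across groups, so the planted pair's
    # joint dependence is the only group difference.
    if config.residual_frac > 0:
        resid = _smooth_noise(rng, n, fs, config.modulation_cutoff_hz,
                              shape=(config.n_channels, n))
        for c in config.coupling:
            # draw the latent for every rule so signals are seed-comparable
            z = _smooth_noise(rng, n, fs, config.modulation_cutoff_hz)
            if c.group != group:
                continue
            mask = labels == c.state
            keep, share = math.sqrt(1.0 - c.strength), math.sqrt(c.strength)
            for ch in c.pair:
                resid[ch, mask] = keep * resid[ch, mask] + share * z[mask]
        envelope = subj_amp * np.abs(amp)
        data = data + config.residual_frac * (
            templates.maps[labels].T * envelope * resid
        )

    if config.noise_sd > 0:
        noise_sd = config.noise_sd * rng.uniform(*config.subject_noise_range)
        if config.pink_noise:
            white = rng.standard_normal(data.shape)
            spec = np.fft.rfft(white, axis=1)
            freqs = np.fft.rfftfreq(n, d=1.0 / fs)
            spec /= np.maximum(freqs, 1.0) ** 0.5
            noise = np.fft.irfft(spec, n=n, axis=1)
            noise /= noise.std(axis=1, keepdims=True)
            data = data + noise_sd * noise
        else:
            data = data + noise_sd * rng.standard_normal(data.shape)

    planted = [c for c in config.coupling if c.group == group]

    ch_labels = templates.channel_labels or [f"CH{i}" for i in range(config.n_channels)]
    rec = Recording(
        data=data, fs=fs, channel_labels=list(ch_labels),
        subject_id=subject_id, group=group,
    )
    truth = GroundTruth(
        true_labels=labels,
        true_templates=templates,
        planted_pairs=planted,
        segment_starts=bounds[:-1],
        segment_durations_ms=durations_ms,
        seed=seed,
    )
    return rec, truth


def generate_cohort(
    config: SyntheticConfig,
) -> tuple[list[tuple[Recording, str]], CohortManifest]:
    """Simulate the full two-group cohort from one master seed."""
    n_mcs, n_vs = config.n_per_group
    if min(n_mcs, n_vs) < 1:
        raise ValueError("each group needs at least one subject")
    ss = np.random.SeedSequence(config.seed)
    children = ss.spawn(1 + n_mcs + n_vs)
    template_seed = int(children[0].generate_state(1)[0] >> 1)
    templates = generate_template_maps(config.k_states, config.n_channels, template_seed)

    recordings: list[tuple[Recording, str]] = []
    subjects: dict[str, GroundTruth] = {}
    plan = [("MCS", i) for i in range(n_mcs)] + [("VS", i) for i in range(n_vs)]
    for child, (group, i) in zip(children[1:], plan):
        sid = f"{group}{i + 1:02d}"
        subj_seed = int(child.generate_state(1)[0] >> 1)
        rec, truth = generate_subject_recording(
            templates, config, group, seed=subj_seed, subject_id=sid
        )
        recordings.append((rec, group))
        subjects[sid] = truth
    planted = {g: [c for c in config.coupling if c.group == g] for g in GROUPS}
    manifest = CohortManifest(
        true_templates=templates, subjects=subjects, planted=planted, config=config
    )
    return recordings, manifest


def make_strong_effect_config(seed: int, **overrides) -> SyntheticConfig:
    """A cohort config with strong planted coupling in every state.

    The template maps the cohort will use are derived from the master
    seed first (exactly as :func:`generate_cohort` derives them), and the
    couplings are planted on each state's most active channels, so the
    returned config reproduces the same cohort with known strong ground
    truth.
    """
    base = SyntheticConfig(seed=seed, **overrides)
    template_seed = int(np.random.SeedSequence(seed).spawn(1)[0].generate_state(1)[0] >> 1)
    templates = generate_template_maps(base.k_states, base.n_channels, template_seed)
    coupling = strong_effect_coupling(templates)
    return SyntheticConfig(seed=seed, coupling=coupling, **overrides)


def write_cohort(
    recordings: list[tuple[Recording, str]],
    manifest: CohortManifest,
    out_dir: str | Path,
) -> Path:
    """Write per-subject delimited matrices plus a JSON cohort manifest."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    for rec, _group in recordings:
        write_recording_text(
            rec, out_dir / f"{rec.subject_id}.tsv",
            meta={"seed": manifest.subjects[rec.subject_id].seed},
        )
    cfg = asdict(manifest.config)
    cfg["coupling"] = [asdict(c) for c in manifest.config.coupling]
    payload = {
        "config": cfg,
        "subjects": {
            sid: {"group": rec_group, "seed": manifest.subjects[sid].seed}
            for (rec, rec_group), sid in (
                ((r, g), r.subject_id) for r, g in recordings
            )
        },
        "planted": {
            g: [asdict(c) for c in cs] for g, cs in manifest.planted.items()
        },
    }
    (out_dir / "manifest.json").write_text(json.dumps(payload, indent=1))
    return out_dir
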