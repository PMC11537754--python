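"""Synthetic experimental design, epoched EEG and behaviour.

This module emulates the statistical structure the analysis assumes, with
known ground truth:

* **Design** — three SF blocks (BSF/LSF/HSF) of 330 trials each: 110 per
  trial type (neutral, fear-left, fear-right), 10 of which per type are
  fixation-colour-change catch trials that are removed before ERP
  averaging (leaving 100/300/900 usable trials).
* **Epochs** — pooled-parietal waveforms built from Gaussian component
  bumps (P1, N170, EPN), plus a lateralized asymmetry bump added to the
  electrode pool *contralateral* to the fearful face whose magnitude
  depends on SF band and stimulated hemiretina, 1/f ("pink") noise per
  channel, per-trial latency jitter, and occasional injected artifacts.
* **Behaviour** — binomial hits/false alarms on the catch task and
  shifted-lognormal reaction times per emotion x SF cell.

The lateralized asymmetry amplitude ``a(sf, hemiretina)`` is calibrated in
*window-mean* units: the injected bump is scaled so that the expected mean
of the contra-ipsi difference over the canonical 155-170 ms window equals
``a`` exactly (the calibration uses the latency-jitter-convolved expected
bump shape, so the definition is jitter-invariant).

All randomness flows from a single seed through ``numpy.random.SeedSequence``
spawning, so every output is byte-reproducible.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterator, Sequence

import numpy as np
import pandas as pd

from .conditions import SF_BANDS, TRIAL_TYPES, ConditionLabel
from .timegrid import N_SAMPLES, SRATE_HZ, T0_MS, times_ms, window_mean_values

__all__ = [
    "CHANNELS",
    "EEG_CHANNELS",
    "EYE_CHANNEL",
    "LEFT_POOL",
    "RIGHT_POOL",
    "TrialRecord",
    "ComponentSpec",
    "GroundTruth",
    "Epoch",
    "BehaviorRecord",
    "make_design",
    "design_frame",
    "usable_counts",
    "gaussian_bump",
    "pink_noise",
    "expected_pool_template",
    "expected_asymmetry_wave",
    "simulate_epoch",
    "simulate_subject_epochs",
    "SubjectSpec",
    "SimulatedDataset",
    "simulate_dataset",
    "simulate_behavior",
    "simulate_condition_averages",
    "write_epochs_tsv",
    "read_epochs_tsv",
]

LEFT_POOL = ("PO7", "P7", "P9")
RIGHT_POOL = ("PO8", "P8", "P10")
EYE_CHANNEL = "EOG"
EEG_CHANNELS = LEFT_POOL + RIGHT_POOL
CHANNELS = EEG_CHANNELS + (EYE_CHANNEL,)

#: Calibration window for the lateralized asymmetry amplitude (ms).
ASYM_CALIBRATION_WINDOW_MS = (155.0, 170.0)


@dataclass(frozen=True)
class TrialRecord:
    """One trial of the presentation design."""

    block_sf: str
    trial_type: str
    is_catch: bool
    onset_jitter_s: float


def make_design(
    trials_per_variation: int = 110,
    catch_per_variation: int = 10,
    blocks: Sequence[str] = SF_BANDS,
    seed: int = 0,
) -> list[TrialRecord]:
    """Build the trial sequence: per block, ``trials_per_variation`` trials of
    each of the three trial types, with catch flags drawn uniformly without
    replacement within each type, shuffled within block.

    Defaults give 330 trials per block (990 total) and, after catch removal,
    100 usable trials per condition, 300 per block and 900 in total.
    """
    if catch_per_variation > trials_per_variation:
        raise ValueError("catch_per_variation cannot exceed trials_per_variation")
    rng = np.random.default_rng(seed)
    design: list[TrialRecord] = []
    for sf in blocks:
        block: list[TrialRecord] = []
        for ttype in TRIAL_TYPES:
            catch_idx = set(rng.choice(trials_per_variation, size=catch_per_variation, replace=False).tolist())
            for i in range(trials_per_variation):
                block.append(
                    TrialRecord(
                        block_sf=sf,
                        trial_type=ttype,
                        is_catch=i in catch_idx,
                        onset_jitter_s=float(rng.uniform(0.5, 1.0)),
                    )
                )
        order = rng.permutation(len(block))
        design.extend(block[i] for i in order)
    return design


def design_frame(design: Sequence[TrialRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "block_sf": [t.block_sf for t in design],
            "trial_type": [t.trial_type for t in design],
            "is_catch": [t.is_catch for t in design],
            "onset_jitter_s": [t.onset_jitter_s for t in design],
        }
    )


def usable_counts(design: Sequence[TrialRecord]) -> dict:
    """Trial bookkeeping: totals and usable (non-catch) counts."""
    df = design_frame(design)
    usable = df[~df.is_catch]
    per_cell = usable.groupby(["block_sf", "trial_type"]).size()
    return {
        "total": len(df),
        "per_block": df.groupby("block_sf").size().to_dict(),
        "usable_total": len(usable),
        "usable_per_block": usable.groupby("block_sf").size().to_dict(),
        "usable_per_condition": per_cell.to_dict(),
    }


# ---------------------------------------------------------------------------
# Ground truth and waveform primitives
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ComponentSpec:
    """One ERP component as a Gaussian bump: amp * exp(-(t-peak)^2 / (2 w^2))."""

    name: str
    amplitude_uv: float
    peak_ms: float
    width_ms: float

    def __post_init__(self) -> None:
        if self.width_ms <= 0:
            raise ValueError(f"component {self.name}: width must be > 0")
        if not np.isfinite(self.amplitude_uv):
            raise ValueError(f"component {self.name}: amplitude must be finite")


#: Default component set. The EPN is simulated as a positive deflection whose
#: printed means are positive; "more negative" conditions reduce it.
DEFAULT_COMPONENTS = (
    ComponentSpec("P1", 4.0, 110.0, 15.0),
    ComponentSpec("N170", -4.0, 170.0, 15.0),
    ComponentSpec("EPN", 2.5, 250.0, 35.0),
)


def _default_asymmetry() -> dict:
    # Nonzero nasal-hemiretina asymmetry for broadband faces only.
    return {("BSF", "nasal"): -0.9}


@dataclass(frozen=True)
class GroundTruth:
    """Generative parameters of the simulated dataset.

    Parameters
    ----------
    components
        ERP component bumps added identically to both parietal pools.
    asymmetry_uv
        ``{(sf, hemiretina): a}`` lateralized amplitudes in µV, in
        155-170 ms *window-mean* units; missing keys mean 0. The bump is
        added only to the pool contralateral to the fearful face.
    asym_peak_ms, asym_width_ms
        Shape of the asymmetry bump (defaults: the N170 parameters).
    noise_sd_uv
        Time-domain SD of the per-channel 1/f noise, µV.
    latency_jitter_sd_ms
        SD of the per-trial Gaussian latency shift applied to all bumps.
    between_subject_sd_uv
        SD of per-subject offsets, drawn independently per (sf, hemiretina)
        cell, added to the asymmetry amplitude (creates a realistic
        subject x condition error term).
    artifact_prob
        Per-trial probability of an injected artifact (eye deflection or
        EEG spike) that the rejection stage should catch.
    """

    components: tuple[ComponentSpec, ...] = DEFAULT_COMPONENTS
    asymmetry_uv: dict = field(default_factory=_default_asymmetry)
    asym_peak_ms: float = 170.0
    asym_width_ms: float = 15.0
    noise_sd_uv: float = 2.0
    eye_noise_sd_uv: float = 10.0
    latency_jitter_sd_ms: float = 5.0
    between_subject_sd_uv: float = 0.5
    artifact_prob: float = 0.02
    p_hit: dict = field(default_factory=lambda: {"neutral": 0.91, "fear": 0.89})
    p_false_alarm: float = 0.01
    rt_mean_s: dict = field(default_factory=lambda: {"BSF": 1.48, "HSF": 1.47, "LSF": 1.46})
    rt_fear_slowdown_s: float = 0.01
    rt_sd_s: float = 0.29

    def __post_init__(self) -> None:
        if self.asym_width_ms <= 0:
            raise ValueError("asym_width_ms must be > 0")
        for v in self.asymmetry_uv.values():
            if not np.isfinite(v):
                raise ValueError("asymmetry amplitudes must be finite")
        for bad in ("noise_sd_uv", "latency_jitter_sd_ms", "between_subject_sd_uv"):
            if getattr(self, bad) < 0:
                raise ValueError(f"{bad} must be >= 0")

    def asymmetry(self, sf: str, hemiretina: str | None) -> float:
        if hemiretina is None:
            return 0.0
        return float(self.asymmetry_uv.get((sf, hemiretina), 0.0))


@dataclass
class Epoch:
    """One trial's channels x samples µV matrix on the canonical time grid."""

    data: np.ndarray
    label: ConditionLabel
    channels: tuple[str, ...] = CHANNELS
    srate_hz: float = SRATE_HZ
    t0_ms: float = T0_MS

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2 or self.data.shape[0] != len(self.channels):
            raise ValueError("epoch data must be (n_channels, n_samples)")

    @property
    def times_ms(self) -> np.ndarray:
        return times_ms(self.data.shape[1], self.t0_ms, self.srate_hz)

    def channel(self, name: str) -> np.ndarray:
        try:
            return self.data[self.channels.index(name)]
        except ValueError:
            raise KeyError(f"channel {name!r} not in epoch") from None


@dataclass(frozen=True)
class BehaviorRecord:
    """Catch-task behaviour for one subject in one emotion x SF cell."""

    subject: int
    sf: str
    emotion: str
    n_signal: int
    n_noise: int
    hits: int
    false_alarms: int
    rts_s: tuple[float, ...]

    def __post_init__(self) -> None:
        if not (0 <= self.hits <= self.n_signal):
            raise ValueError("hits out of range")
        if not (0 <= self.false_alarms <= self.n_noise):
            raise ValueError("false alarms out of range")


def gaussian_bump(t_ms: np.ndarray, amplitude_uv: float, peak_ms: float, width_ms: float) -> np.ndarray:
    return amplitude_uv * np.exp(-((t_ms - peak_ms) ** 2) / (2.0 * width_ms**2))


def _jitter_convolved(comp: ComponentSpec, jitter_sd_ms: float) -> ComponentSpec:
    """Expected bump after Gaussian latency jitter (closed-form convolution).

    A Gaussian bump of width w jittered by N(0, j^2) has expectation a
    Gaussian of width sqrt(w^2 + j^2) and amplitude scaled by
    w / sqrt(w^2 + j^2).
    """
    w = np.hypot(comp.width_ms, jitter_sd_ms)
    return replace(comp, amplitude_uv=comp.amplitude_uv * comp.width_ms / w, width_ms=float(w))


def expected_pool_template(gt: GroundTruth, t_ms: np.ndarray | None = None, jittered: bool = True) -> np.ndarray:
    """Expected (trial-averaged) pooled-parietal component sum, µV."""
    t = times_ms() if t_ms is None else np.asarray(t_ms, dtype=float)
    out = np.zeros_like(t)
    for comp in gt.components:
        c = _jitter_convolved(comp, gt.latency_jitter_sd_ms) if jittered else comp
        out += gaussian_bump(t, c.amplitude_uv, c.peak_ms, c.width_ms)
    return out


def _asym_unit_scale(gt: GroundTruth) -> float:
    """Bump peak amplitude giving an expected calibration-window mean of 1 µV."""
    t = times_ms()
    shape = _jitter_convolved(
        ComponentSpec("asym", 1.0, gt.asym_peak_ms, gt.asym_width_ms), gt.latency_jitter_sd_ms
    )
    m = window_mean_values(
        gaussian_bump(t, shape.amplitude_uv, shape.peak_ms, shape.width_ms), *ASYM_CALIBRATION_WINDOW_MS
    )
    return 1.0 / m


def expected_asymmetry_wave(gt: GroundTruth, amplitude_uv: float, t_ms: np.ndarray | None = None) -> np.ndarray:
    """Expected contra-ipsi asymmetry waveform for a window-mean amplitude ``a``."""
    t = times_ms() if t_ms is None else np.asarray(t_ms, dtype=float)
    shape = _jitter_convolved(
        ComponentSpec("asym", 1.0, gt.asym_peak_ms, gt.asym_width_ms), gt.latency_jitter_sd_ms
    )
    return amplitude_uv * _asym_unit_scale(gt) * gaussian_bump(t, shape.amplitude_uv, shape.peak_ms, shape.width_ms)


def pink_noise(rng: np.random.Generator, shape: tuple[int, ...], sd: float, srate_hz: float = SRATE_HZ) -> np.ndarray:
    """1/f-power noise with exact ensemble time-domain SD ``sd``.

    Spectral amplitude weights scale as f^(-1/2) (power ~ 1/f), the DC
    weight is zero, and the weights are normalized analytically so that the
    ensemble variance of every sample equals ``sd**2`` — averaging k
    independent draws therefore has SD exactly ``sd/sqrt(k)``.
    """
    if sd == 0:
        return np.zeros(shape)
    n = shape[-1]
    freqs = np.fft.rfftfreq(n, d=1.0 / srate_hz)
    w = np.zeros_like(freqs)
    w[1:] = freqs[1:] ** -0.5
    # Var(x_t) = (w0^2 + 4*sum(w_mid^2) + w_nyq^2) / n^2 for unit-variance
    # real/imaginary spectral coefficients.
    mid = w[1:-1] if n % 2 == 0 else w[1:]
    nyq = w[-1] if n % 2 == 0 else 0.0
    var = (4.0 * np.sum(mid**2) + nyq**2) / n**2
    w *= sd / np.sqrt(var)
    z = rng.standard_normal(shape[:-1] + (len(freqs),)) + 1j * rng.standard_normal(shape[:-1] + (len(freqs),))
    return np.fft.irfft(w * z, n=n, axis=-1)


def _trial_pool_signals(
    gt: GroundTruth,
    label: ConditionLabel,
    jitter_ms: float,
    asym_amplitude_uv: float,
) -> tuple[np.ndarray, np.ndarray]:
    """Noise-free (left_pool, right_pool) signals for one trial."""
    t = times_ms()
    base = np.zeros(N_SAMPLES)
    for comp in gt.components:
        base += gaussian_bump(t, comp.amplitude_uv, comp.peak_ms + jitter_ms, comp.width_ms)
    left = base.copy()
    right = base.copy()
    field_side = label.fear_field
    if field_side is not None and asym_amplitude_uv != 0.0:
        bump = asym_amplitude_uv * _asym_unit_scale(gt) * gaussian_bump(
            t, 1.0, gt.asym_peak_ms + jitter_ms, gt.asym_width_ms
        )
        if field_side == "left":  # contralateral = right hemisphere pool
            right += bump
        else:
            left += bump
    return left, right


def simulate_epoch(
    label: ConditionLabel,
    gt: GroundTruth,
    seed: int | np.random.Generator = 0,
    subject_asym_offset_uv: float = 0.0,
    inject_artifact: bool | None = None,
) -> Epoch:
    """Simulate a single epoch (all channels) for one trial.

    The lateralized bump is added only to the three channels of the pool
    contralateral to the fearful face; the eye channel carries noise only,
    unless an artifact is injected.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    jitter = float(rng.normal(0.0, gt.latency_jitter_sd_ms)) if gt.latency_jitter_sd_ms > 0 else 0.0
    a = gt.asymmetry(label.sf, label.fear_hemiretina)
    if label.fear_field is not None:
        a += subject_asym_offset_uv
    left_sig, right_sig = _trial_pool_signals(gt, label, jitter, a)
    data = np.zeros((len(CHANNELS), N_SAMPLES))
    for i, ch in enumerate(CHANNELS):
        if ch in LEFT_POOL:
            data[i] = left_sig
        elif ch in RIGHT_POOL:
            data[i] = right_sig
    noise = pink_noise(rng, (len(EEG_CHANNELS), N_SAMPLES), gt.noise_sd_uv)
    data[: len(EEG_CHANNELS)] += noise
    data[-1] = pink_noise(rng, (N_SAMPLES,), gt.eye_noise_sd_uv)
    do_artifact = (rng.uniform() < gt.artifact_prob) if inject_artifact is None else inject_artifact
    if do_artifact:
        t = times_ms()
        sign = float(rng.choice([-1, 1]))
        onset = float(rng.uniform(0.0, 400.0))
        if rng.uniform() < 0.5:
            # Saccade-like eye step: 130 µV for 100-300 ms. Band-limited
            # enough to survive the 0.1-40 Hz filter and exceed ±60 µV
            # even after demeaning/baseline correction.
            dur = float(rng.uniform(100.0, 300.0))
            data[-1] += sign * 130.0 / (1.0 + np.exp(-(t - onset) / 5.0)) / (1.0 + np.exp((t - onset - dur) / 5.0))
        else:
            # Muscle burst on a random EEG channel: 160 µV, ~15 ms wide
            # (spectral content well below the 40 Hz low-pass).
            ch = int(rng.integers(len(EEG_CHANNELS)))
            data[ch] += sign * 160.0 * np.exp(-((t - onset) ** 2) / (2.0 * 15.0**2))
    return Epoch(data=data, label=label)


def simulate_subject_epochs(
    design: Sequence[TrialRecord],
    viewing_eye: str,
    gt: GroundTruth,
    seed: int | np.random.Generator,
    asym_offsets: dict | None = None,
) -> list[Epoch]:
    """Simulate the usable (non-catch) epochs of one subject, in design order."""
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    offsets = asym_offsets or {}
    epochs = []
    for trial in design:
        if trial.is_catch:
            continue
        label = ConditionLabel(viewing_eye=viewing_eye, sf=trial.block_sf, trial_type=trial.trial_type)
        off = float(offsets.get((label.sf, label.fear_hemiretina), 0.0)) if label.fear_field else 0.0
        epochs.append(simulate_epoch(label, gt, rng, subject_asym_offset_uv=off))
    return epochs


# ---------------------------------------------------------------------------
# Dataset-level simulation
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SubjectSpec:
    """Reproducible per-subject parameters (seeded from the master seed)."""

    subject: int
    viewing_eye: str
    epoch_seed: tuple[int, ...]
    behavior_seed: tuple[int, ...]
    asym_offsets: dict


@dataclass
class SimulatedDataset:
    """Lazy container for a simulated multi-subject experiment.

    Epochs are generated on demand per subject (they are large); design,
    subject specs and behaviour are materialized.
    """

    gt: GroundTruth
    design: list[TrialRecord]
    subjects: list[SubjectSpec]
    behavior: list[BehaviorRecord]

    def subject_epochs(self, spec: SubjectSpec) -> list[Epoch]:
        rng = np.random.default_rng(spec.epoch_seed)
        return simulate_subject_epochs(self.design, spec.viewing_eye, self.gt, rng, spec.asym_offsets)

    def iter_subjects(self) -> Iterator[SubjectSpec]:
        return iter(self.subjects)

    def behavior_frame(self) -> pd.DataFrame:
        rows = []
        for b in self.behavior:
            rows.append(
                {
                    "subject": b.subject,
                    "sf": b.sf,
                    "emotion": b.emotion,
                    "n_signal": b.n_signal,
                    "n_noise": b.n_noise,
                    "hits": b.hits,
                    "false_alarms": b.false_alarms,
                    "mean_rt_s": float(np.mean(b.rts_s)) if b.rts_s else np.nan,
                }
            )
        return pd.DataFrame(rows)


def simulate_behavior(
    subject: int, design: Sequence[TrialRecord], gt: GroundTruth, rng: np.random.Generator
) -> list[BehaviorRecord]:
    """Sample catch-task behaviour per emotion x SF cell.

    Catch (fixation colour change) trials are the signal trials; all other
    trials are noise trials. RTs for hits follow a shifted lognormal with
    the configured cell mean and SD.
    """
    df = design_frame(design)
    df["emotion"] = np.where(df.trial_type == "neutral", "neutral", "fear")
    records = []
    for (sf, emo), cell in df.groupby(["block_sf", "emotion"], sort=False):
        n_signal = int(cell.is_catch.sum())
        n_noise = int((~cell.is_catch).sum())
        hits = int(rng.binomial(n_signal, gt.p_hit[emo]))
        fas = int(rng.binomial(n_noise, gt.p_false_alarm))
        mu_target = gt.rt_mean_s[sf] + (gt.rt_fear_slowdown_s if emo == "fear" else 0.0)
        shift = 0.2
        m, s = mu_target - shift, gt.rt_sd_s
        sigma2 = np.log(1.0 + (s / m) ** 2)
        mu = np.log(m) - sigma2 / 2.0
        rts = shift + rng.lognormal(mu, np.sqrt(sigma2), size=hits)
        records.append(
            BehaviorRecord(
                subject=subject,
                sf=sf,
                emotion=emo,
                n_signal=n_signal,
                n_noise=n_noise,
                hits=hits,
                false_alarms=fas,
                rts_s=tuple(np.round(rts, 6)),
            )
        )
    return records


def simulate_dataset(
    n_subjects: int = 36,
    gt: GroundTruth | None = None,
    seed: int = 0,
    trials_per_variation: int = 110,
    catch_per_variation: int = 10,
) -> SimulatedDataset:
    """Design + subject specs + behaviour for a full experiment.

    Viewing eye is counterbalanced (even subject index -> left eye). Each
    subject receives independent asymmetry offsets per (sf, hemiretina)
    cell with SD ``gt.between_subject_sd_uv``.
    """
    if n_subjects < 2:
        raise ValueError("need at least 2 subjects")
    gt = gt or GroundTruth()
    ss = np.random.SeedSequence(seed)
    design_seed, *subject_seeds = ss.spawn(1 + n_subjects)
    design = make_design(trials_per_variation, catch_per_variation, seed=int(design_seed.generate_state(1)[0] % 2**31))
    subjects = []
    behavior: list[BehaviorRecord] = []
    for i, sseq in enumerate(subject_seeds):
        off_seq, ep_seq, beh_seq = sseq.spawn(3)
        off_rng = np.random.default_rng(off_seq)
        offsets = {
            (sf, hemi): float(off_rng.normal(0.0, gt.between_subject_sd_uv))
            for sf in SF_BANDS
            for hemi in ("nasal", "temporal")
        }
        spec = SubjectSpec(
            subject=i + 1,
            viewing_eye="left" if i % 2 == 0 else "right",
            epoch_seed=tuple(ep_seq.generate_state(4).tolist()),
            behavior_seed=tuple(beh_seq.generate_state(4).tolist()),
            asym_offsets=offsets,
        )
        subjects.append(spec)
        behavior.extend(simulate_behavior(spec.subject, design, gt, np.random.default_rng(spec.behavior_seed)))
    return SimulatedDataset(gt=gt, design=design, subjects=subjects, behavior=behavior)


def simulate_condition_averages(
    spec: SubjectSpec,
    gt: GroundTruth,
    n_trials_per_condition: int = 100,
) -> dict:
    """Exact-distribution fast path for a subject's condition-average pools.

    Returns ``{(sf, trial_type): (left_pool, right_pool)}`` waveforms whose
    distribution matches averaging ``n_trials_per_condition`` simulated
    trials: the deterministic part is the jitter-convolved expected
    template (+ expected asymmetry bump in the contralateral pool), and the
    noise is pool-level pink noise with SD
    ``noise_sd / sqrt(3 * n_trials)`` (three pooled channels).
    """
    rng = np.random.default_rng(spec.epoch_seed)
    template = expected_pool_template(gt)
    pool_sd = gt.noise_sd_uv / np.sqrt(3.0 * n_trials_per_condition)
    out = {}
    for sf in SF_BANDS:
        for ttype in TRIAL_TYPES:
            label = ConditionLabel(viewing_eye=spec.viewing_eye, sf=sf, trial_type=ttype)
            left = template + pink_noise(rng, (N_SAMPLES,), pool_sd)
            right = template + pink_noise(rng, (N_SAMPLES,), pool_sd)
            if label.fear_field is not None:
                hemi = label.fear_hemiretina
                a = gt.asymmetry(sf, hemi) + float(spec.asym_offsets.get((sf, hemi), 0.0))
                bump = expected_asymmetry_wave(gt, a)
                if label.fear_field == "left":
                    right = right + bump
                else:
                    left = left + bump
            out[(sf, ttype)] = (left, right)
    return out


# ---------------------------------------------------------------------------
# Serialization: long-format TSV + JSON sidecar
# ---------------------------------------------------------------------------


def write_epochs_tsv(epochs: Sequence[Epoch], path: str | Path, sidecar: dict | None = None) -> None:
    """Write epochs as long-format TSV (trial, channel, time_ms, uv) + JSON sidecar."""
    path = Path(path)
    frames = []
    for i, ep in enumerate(epochs):
        t = ep.times_ms
        for c, ch in enumerate(ep.channels):
            frames.append(
                pd.DataFrame({"trial": i, "channel": ch, "time_ms": np.round(t, 6), "uv": np.round(ep.data[c], 6)})
            )
    pd.concat(frames, ignore_index=True).to_csv(path, sep="\t", index=False)
    meta = {
        "srate_hz": epochs[0].srate_hz if epochs else SRATE_HZ,
        "t0_ms": epochs[0].t0_ms if epochs else T0_MS,
        "channels": list(epochs[0].channels) if epochs else list(CHANNELS),
        "labels": [
            {"viewing_eye": ep.label.viewing_eye, "sf": ep.label.sf, "trial_type": ep.label.trial_type}
            for ep in epochs
        ],
    }
    if sidecar:
        meta.update(sidecar)
    path.with_suffix(".json").write_text(json.dumps(meta, indent=1))


def read_epochs_tsv(path: str | Path) -> list[Epoch]:
    path = Path(path)
    meta = json.loads(path.with_suffix(".json").read_text())
    df = pd.read_csv(path, sep="\t")
    channels = tuple(meta["channels"])
    epochs = []
    for i, lab in enumerate(meta["labels"]):
        sub = df[df.trial == i]
        data = np.stack([sub[sub.channel == ch].sort_values("time_ms").uv.to_numpy() for ch in channels])
        epochs.append(
            Epoch(
                data=data,
                label=ConditionLabel(**lab),
                channels=channels,
                srate_hz=meta["srate_hz"],
                t0_ms=meta["t0_ms"],
            )
        )
    return epochs
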