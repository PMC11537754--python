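"""Hemiretinal asymmetry construction.

The core statistic of the package: for fearful-face trials, the N2pc
difference waveform (contralateral minus ipsilateral parietal pool with
respect to the fearful face's visual field) is computed separately for
nasal- and temporal-hemiretina presentations, and the temporal N2pc is
subtracted from the nasal N2pc per SF band. A naso-temporal processing
asymmetry appears as a nonzero "hemiretinal difference waveform"; window
means of this wave feed the repeated-measures statistics.

The construction is eye-agnostic by design: the hemiretina label and the
contra/ipsi assignment both flip with the viewing eye, so counterbalancing
eyes across subjects leaves the waveforms unchanged in expectation.

Neutral-only trials have no lateralized fearful face and never enter this
module.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd

from .conditions import map_hemiretina
from .erp_measures import CANONICAL_WINDOWS
from .preprocessing import ERPWaveform
from .timegrid import times_ms, window_mean_values

__all__ = [
    "N2pcWave",
    "HemiDiffWave",
    "map_hemiretina",
    "n2pc",
    "hemiretinal_difference",
    "export_epoch_means",
    "subject_hemiretinal_waves",
]


@dataclass
class N2pcWave:
    """Contralateral-minus-ipsilateral difference waveform (µV per sample)."""

    values: np.ndarray
    srate_hz: float
    t0_ms: float
    hemiretina: str
    sf: str
    viewing_eye: str
    stimulus_field: str
    n_trials: int

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)

    @property
    def times_ms(self) -> np.ndarray:
        return times_ms(len(self.values), self.t0_ms, self.srate_hz)


@dataclass
class HemiDiffWave:
    """Nasal-minus-temporal difference of N2pc waveforms, per SF band."""

    values: np.ndarray
    srate_hz: float
    t0_ms: float
    sf: str

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)

    @property
    def times_ms(self) -> np.ndarray:
        return times_ms(len(self.values), self.t0_ms, self.srate_hz)


def _check_axes(a, b) -> None:
    if len(a.values) != len(b.values) or a.srate_hz != b.srate_hz or a.t0_ms != b.t0_ms:
        raise ValueError("waveforms do not share a time axis")


def n2pc(
    left_pool: ERPWaveform,
    right_pool: ERPWaveform,
    stimulus_field: str,
    viewing_eye: str,
) -> N2pcWave:
    """Contra-ipsi difference with respect to the fearful face's visual field.

    A left-field face is processed contralaterally by the *right*
    hemisphere, so contra = right pool and the wave is right - left; a
    right-field face gives left - right. The hemiretina label follows from
    the viewing eye via :func:`map_hemiretina`.
    """
    if stimulus_field not in ("left", "right"):
        raise ValueError(f"unknown stimulus field {stimulus_field!r}")
    _check_axes(left_pool, right_pool)
    if left_pool.n_trials < 1 or right_pool.n_trials < 1:
        raise ValueError("pools must average at least one trial")
    if stimulus_field == "left":
        values = right_pool.values - left_pool.values
    else:
        values = left_pool.values - right_pool.values
    sf = left_pool.label.sf if left_pool.label is not None else "BSF"
    return N2pcWave(
        values=values,
        srate_hz=left_pool.srate_hz,
        t0_ms=left_pool.t0_ms,
        hemiretina=map_hemiretina(viewing_eye, stimulus_field),
        sf=sf,
        viewing_eye=viewing_eye,
        stimulus_field=stimulus_field,
        n_trials=min(left_pool.n_trials, right_pool.n_trials),
    )


def hemiretinal_difference(nasal: N2pcWave, temporal: N2pcWave) -> HemiDiffWave:
    """First argument's N2pc minus the second's, pointwise, for one SF band.

    Called with the (nasal, temporal) pair this is the canonical
    nasal-minus-temporal hemiretinal difference; swapping the arguments
    flips the sign exactly. The pair must cover both hemiretinae and share
    an SF band.
    """
    if {nasal.hemiretina, temporal.hemiretina} != {"nasal", "temporal"}:
        raise ValueError("arguments must cover the nasal and temporal hemiretinae")
    if nasal.sf != temporal.sf:
        raise ValueError(f"SF mismatch: {nasal.sf} vs {temporal.sf}")
    _check_axes(nasal, temporal)
    return HemiDiffWave(
        values=nasal.values - temporal.values, srate_hz=nasal.srate_hz, t0_ms=nasal.t0_ms, sf=nasal.sf
    )


def export_epoch_means(wave: HemiDiffWave) -> dict[str, float]:
    """Mean amplitude of the hemiretinal difference wave in the four canonical windows."""
    return {
        name: float(window_mean_values(wave.values, lo, hi, wave.t0_ms, wave.srate_hz))
        for name, (lo, hi) in CANONICAL_WINDOWS.items()
    }


def subject_hemiretinal_waves(
    pools_by_condition: Mapping[tuple[str, str], tuple[ERPWaveform, ERPWaveform]],
    viewing_eye: str,
) -> tuple[dict[tuple[str, str], N2pcWave], dict[str, HemiDiffWave]]:
    """Per-subject N2pc and hemiretinal difference waves from condition pools.

    ``pools_by_condition`` maps ``(sf, trial_type)`` — fear trials only —
    to that condition's (left pool, right pool) averages. Returns the N2pc
    waves keyed by ``(sf, hemiretina)`` and the hemiretinal difference
    wave per SF.
    """
    n2pcs: dict[tuple[str, str], N2pcWave] = {}
    for (sf, ttype), (left, right) in pools_by_condition.items():
        if ttype == "neutral":
            raise ValueError("neutral trials have no lateralized fearful face")
        field = "left" if ttype == "fear_left" else "right"
        wave = n2pc(left, right, field, viewing_eye)
        n2pcs[(sf, wave.hemiretina)] = wave
    hemidiff = {}
    for sf in sorted({sf for sf, _ in n2pcs}):
        hemidiff[sf] = hemiretinal_difference(n2pcs[(sf, "nasal")], n2pcs[(sf, "temporal")])
    return n2pcs, hemidiff


def window_mean_table(hemidiffs_by_subject: Mapping[int, Mapping[str, HemiDiffWave]]) -> pd.DataFrame:
    """Long-format (subject, sf, window, mean_uv) table for the statistics module."""
    rows = []
    for subject, by_sf in hemidiffs_by_subject.items():
        for sf, wave in by_sf.items():
            for window, mean_uv in export_epoch_means(wave).items():
                rows.append({"subject": subject, "sf": sf, "window": window, "mean_uv": mean_uv})
    return pd.DataFrame(rows)
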