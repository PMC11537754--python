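"""End-to-end orchestration: synthesize -> preprocess -> measure -> hemiretinal
analysis -> statistics -> report.

A run is fully reproducible from a :class:`RunConfig` (serializable to
YAML) plus its seed: per-subject random substreams are derived
deterministically from the master seed, outputs carry content checksums,
and re-running the same config writes byte-identical files.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
import yaml

from .conditions import SF_BANDS, ConditionLabel
from .erp_measures import CANONICAL_WINDOWS, detect_peaks
from .hemiretinal import subject_hemiretinal_waves, window_mean_table
from .preprocessing import (
    ERPWaveform,
    RejectionPolicy,
    average_condition,
    baseline_correct,
    filter_epochs,
    reject_artifacts,
)
from .stats import behavioural_analysis, bonferroni_posthoc, rm_anova
from .synthetic_data import (
    GroundTruth,
    SimulatedDataset,
    SubjectSpec,
    design_frame,
    simulate_condition_averages,
    simulate_dataset,
    usable_counts,
)
from .timegrid import SRATE_HZ, T0_MS, times_ms, window_mean_values

__all__ = ["RunConfig", "RunResult", "run_pipeline", "make_figures", "power_simulation"]


@dataclass(frozen=True)
class RunConfig:
    """Everything needed to reproduce a pipeline run."""

    seed: int = 7
    n_subjects: int = 36
    trials_per_variation: int = 110
    catch_per_variation: int = 10
    noise_sd_uv: float = 2.0
    latency_jitter_sd_ms: float = 5.0
    between_subject_sd_uv: float = 0.5
    artifact_prob: float = 0.02
    asymmetry_uv: Mapping[str, float] = field(
        default_factory=lambda: {"BSF:nasal": -0.9}
    )  # "SF:hemiretina" -> µV (155-170 ms window-mean units)
    eye_thresh_uv: float = 60.0
    eeg_thresh_uv: float = 100.0
    apply_filter: bool = True
    include_behaviour: bool = True
    gg_correction: bool = False
    d_convention: str = "dz"
    out_dir: str = "runs/default"

    def ground_truth(self) -> GroundTruth:
        asym = {}
        for key, val in dict(self.asymmetry_uv).items():
            sf, hemi = key.split(":")
            asym[(sf, hemi)] = float(val)
        return GroundTruth(
            asymmetry_uv=asym,
            noise_sd_uv=self.noise_sd_uv,
            latency_jitter_sd_ms=self.latency_jitter_sd_ms,
            between_subject_sd_uv=self.between_subject_sd_uv,
            artifact_prob=self.artifact_prob,
        )

    def rejection_policy(self) -> RejectionPolicy:
        return RejectionPolicy(eye_thresh_uv=self.eye_thresh_uv, eeg_thresh_uv=self.eeg_thresh_uv)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump({**asdict(self), "asymmetry_uv": dict(self.asymmetry_uv)}, sort_keys=True))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        return cls(**yaml.safe_load(Path(path).read_text()))


@dataclass
class RunResult:
    config: RunConfig
    out_dir: Path
    counts: pd.DataFrame
    peak_measures: pd.DataFrame
    hemidiff_means: pd.DataFrame
    anovas: dict
    behaviour: dict | None
    grand_averages: dict


def _process_subject(
    spec: SubjectSpec, dataset: SimulatedDataset, config: RunConfig
) -> tuple[dict, dict, dict]:
    """One subject through preprocessing and averaging.

    Returns (stage counts, condition pools {(sf, trial_type): pools dict},
    emotion-level bilateral waveforms {(sf, emotion): ERPWaveform}).
    """
    epochs = dataset.subject_epochs(spec)
    n_usable = len(epochs)
    if config.apply_filter:
        epochs = filter_epochs(epochs)
    epochs = [baseline_correct(ep) for ep in epochs]
    kept, rejection_log = reject_artifacts(epochs, config.rejection_policy())
    pools: dict = {}
    emotion_waves: dict = {}
    for sf in SF_BANDS:
        for ttype in ("neutral", "fear_left", "fear_right"):
            sel = average_condition(kept, lambda l, sf=sf, tt=ttype: l.sf == sf and l.trial_type == tt)
            pools[(sf, ttype)] = sel
        # Emotion x SF analysis: fearful collapses both presentation fields.
        fear = average_condition(kept, lambda l, sf=sf: l.sf == sf and l.trial_type != "neutral")
        emotion_waves[(sf, "fear")] = fear["bilateral"]
        emotion_waves[(sf, "neutral")] = pools[(sf, "neutral")]["bilateral"]
    counts = {
        "subject": spec.subject,
        "generated": len(dataset.design),
        "catch_removed": len(dataset.design) - n_usable,
        "usable": n_usable,
        "rejected": len(rejection_log),
        "rejected_eye": sum(1 for r in rejection_log if r["reason"] == "eye"),
        "rejected_eeg": sum(1 for r in rejection_log if r["reason"] == "eeg"),
        "averaged": len(kept),
    }
    return counts, pools, emotion_waves


def run_pipeline(config: RunConfig) -> RunResult:
    """Execute the full analysis and write the run directory."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    gt = config.ground_truth()
    dataset = simulate_dataset(
        n_subjects=config.n_subjects,
        gt=gt,
        seed=config.seed,
        trials_per_variation=config.trials_per_variation,
        catch_per_variation=config.catch_per_variation,
    )
    config.to_yaml(out / "config.yaml")
    design_frame(dataset.design).to_csv(out / "design.csv", index=False)

    log_lines = [f"[design] trials={len(dataset.design)} usable={usable_counts(dataset.design)['usable_total']}"]
    count_rows, peak_rows = [], []
    n2pc_mean_rows: list[dict] = []
    hemidiffs_by_subject: dict[int, dict] = {}
    n2pc_sum: dict = {}
    hemidiff_sum: dict = {}
    emotion_sum: dict = {}

    for spec in dataset.iter_subjects():
        counts, pools, emotion_waves = _process_subject(spec, dataset, config)
        count_rows.append(counts)
        log_lines.append(
            f"[subject {spec.subject:02d}] eye={spec.viewing_eye} usable={counts['usable']} "
            f"rejected={counts['rejected']} (eye={counts['rejected_eye']}, eeg={counts['rejected_eeg']})"
        )
        # Emotion x SF peak measures on bilateral pools.
        for (sf, emotion), wave in emotion_waves.items():
            for comp, pm in detect_peaks(wave).items():
                peak_rows.append(
                    {
                        "subject": spec.subject,
                        "sf": sf,
                        "emotion": emotion,
                        "component": comp,
                        "latency_ms": pm.latency_ms,
                        "amplitude_uv": pm.amplitude_uv,
                        "flag": pm.flag or "",
                    }
                )
            key = (sf, emotion)
            emotion_sum.setdefault(key, np.zeros(len(wave.values)))
            emotion_sum[key] += wave.values
        # Hemiretinal construction on fear-trial pools.
        fear_pools = {
            (sf, tt): (p["left_parietal"], p["right_parietal"])
            for (sf, tt), p in pools.items()
            if tt != "neutral"
        }
        n2pcs, hemidiff = subject_hemiretinal_waves(fear_pools, spec.viewing_eye)
        hemidiffs_by_subject[spec.subject] = hemidiff
        for (sf, hemi), wave in n2pcs.items():
            n2pc_sum.setdefault((sf, hemi), np.zeros(len(wave.values)))
            n2pc_sum[(sf, hemi)] += wave.values
            for window, (lo, hi) in CANONICAL_WINDOWS.items():
                n2pc_mean_rows.append(
                    {"subject": spec.subject, "sf": sf, "hemiretina": hemi, "window": window,
                     "mean_uv": float(window_mean_values(wave.values, lo, hi, wave.t0_ms, wave.srate_hz))}
                )
        for sf, wave in hemidiff.items():
            hemidiff_sum.setdefault(sf, np.zeros(len(wave.values)))
            hemidiff_sum[sf] += wave.values

    n = config.n_subjects
    counts_df = pd.DataFrame(count_rows)
    peaks_df = pd.DataFrame(peak_rows)
    means_df = window_mean_table(hemidiffs_by_subject)

    # Grand averages (for figures and the report).
    t = times_ms()
    grand = {
        "emotion": {k: v / n for k, v in emotion_sum.items()},
        "n2pc": {k: v / n for k, v in n2pc_sum.items()},
        "hemidiff": {k: v / n for k, v in hemidiff_sum.items()},
        "times_ms": t,
    }

    # --- Statistics ---------------------------------------------------
    def safe_rm_anova(frame, dv, within):
        """Degenerate (zero-error-variance) analyses are flagged, not fatal."""
        try:
            out = rm_anova(frame, dv=dv, subject="subject", within=within, correction=config.gg_correction)
            out["note"] = ""
            return out
        except ZeroDivisionError:
            return pd.DataFrame(
                [{"effect": " * ".join(within), "F": np.nan, "df1": 0, "df2": 0, "p": np.nan,
                  "eta_p2": np.nan, "SS_effect": np.nan, "SS_error": 0.0,
                  "note": "degenerate: zero error variance"}]
            )

    anovas: dict = {}
    for comp in ("P1", "N170", "EPN"):
        sub = peaks_df[peaks_df.component == comp]
        anovas[f"emotion_sf_amplitude_{comp}"] = safe_rm_anova(sub, "amplitude_uv", ["emotion", "sf"])
        anovas[f"emotion_sf_latency_{comp}"] = safe_rm_anova(sub, "latency_ms", ["emotion", "sf"])
    n2pc_means_df = pd.DataFrame(n2pc_mean_rows)
    posthocs = {}
    for window in CANONICAL_WINDOWS:
        sub = means_df[means_df.window == window]
        anovas[f"hemiretinal_sf_{window}"] = safe_rm_anova(sub, "mean_uv", ["sf"])
        # follow-up on the origin of any asymmetry: hemiretina x SF on N2pc means
        n2sub = n2pc_means_df[n2pc_means_df.window == window]
        anovas[f"n2pc_hemiretina_sf_{window}"] = safe_rm_anova(n2sub, "mean_uv", ["hemiretina", "sf"])
        wide = sub.pivot(index="subject", columns="sf", values="mean_uv")
        posthocs[window] = bonferroni_posthoc(
            {
                "BSF-LSF": (wide["BSF"].to_numpy(), wide["LSF"].to_numpy()),
                "BSF-HSF": (wide["BSF"].to_numpy(), wide["HSF"].to_numpy()),
                "LSF-HSF": (wide["LSF"].to_numpy(), wide["HSF"].to_numpy()),
            },
            d_convention=config.d_convention,
        )
    behaviour = None
    if config.include_behaviour:
        behaviour = behavioural_analysis(dataset.behavior_frame(), correction=config.gg_correction)

    # --- Outputs -------------------------------------------------------
    counts_df.to_csv(out / "trial_counts.csv", index=False)
    peaks_df.to_csv(out / "peak_measures.csv", index=False, float_format="%.6f")
    means_df.to_csv(out / "hemidiff_window_means.csv", index=False, float_format="%.6f")
    n2pc_means_df.to_csv(out / "n2pc_window_means.csv", index=False, float_format="%.6f")
    anova_frames = []
    for name, frame in anovas.items():
        f = frame.copy()
        f.insert(0, "analysis", name)
        anova_frames.append(f)
    pd.concat(anova_frames, ignore_index=True).to_csv(out / "anova_results.csv", index=False, float_format="%.8g")
    ph_rows = [
        {"window": w, "pair": r.pair, "t": r.t, "df": r.df, "p_raw": r.p_raw, "p_bonf": r.p_bonf,
         "cohen_d": r.cohen_d, "flag": r.flag or ""}
        for w, results in posthocs.items()
        for r in results
    ]
    pd.DataFrame(ph_rows).to_csv(out / "posthoc_results.csv", index=False, float_format="%.8g")
    if behaviour is not None:
        behaviour["cell_table"].to_csv(out / "behaviour_cells.csv", index=False, float_format="%.6f")
        for key in ("rt_anova", "dprime_anova"):
            behaviour[key].to_csv(out / f"{key}.csv", index=False, float_format="%.8g")
    _write_waveform_tsvs(out, grand)
    _write_report(out, config, counts_df, peaks_df, means_df, anovas, posthocs, behaviour)
    (out / "log.txt").write_text("\n".join(log_lines) + "\n")
    _write_checksums(out)
    return RunResult(
        config=config,
        out_dir=out,
        counts=counts_df,
        peak_measures=peaks_df,
        hemidiff_means=means_df,
        anovas=anovas,
        behaviour=behaviour,
        grand_averages=grand,
    )


def _grand_average_frames(grand: dict) -> tuple[pd.DataFrame, pd.DataFrame]:
    t = grand["times_ms"]
    cols = {"time_ms": np.round(t, 6)}
    for (sf, emotion), v in sorted(grand["emotion"].items()):
        cols[f"{sf}_{emotion}_uv"] = np.round(v, 6)
    erp = pd.DataFrame(cols)
    cols = {"time_ms": np.round(t, 6)}
    for (sf, hemi), v in sorted(grand["n2pc"].items()):
        cols[f"{sf}_{hemi}_uv"] = np.round(v, 6)
    for sf, v in sorted(grand["hemidiff"].items()):
        cols[f"{sf}_hemidiff_uv"] = np.round(v, 6)
    return erp, pd.DataFrame(cols)


def _write_waveform_tsvs(out: Path, grand: dict, prefix: str = "grand_average") -> None:
    erp, hemi = _grand_average_frames(grand)
    erp.to_csv(out / f"{prefix}_erp.tsv", sep="\t", index=False)
    hemi.to_csv(out / f"{prefix}_hemiretinal.tsv", sep="\t", index=False)


def _md_table(df: pd.DataFrame, floatfmt: str = "%.4g") -> str:
    d = df.copy()
    for c in d.columns:
        if d[c].dtype.kind == "f":
            d[c] = d[c].map(lambda x: floatfmt % x)
    header = "| " + " | ".join(map(str, d.columns)) + " |"
    sep = "|" + "---|" * len(d.columns)
    body = ["| " + " | ".join(map(str, row)) + " |" for row in d.itertuples(index=False)]
    return "\n".join([header, sep, *body])


def _write_report(out, config, counts_df, peaks_df, means_df, anovas, posthocs, behaviour) -> None:
    lines = ["# Hemiretinal asymmetry pipeline report", ""]
    lines += [f"Seed {config.seed}; {config.n_subjects} subjects.", ""]
    lines += ["## Trial bookkeeping", "", _md_table(counts_df), ""]
    cell = (
        peaks_df.groupby(["component", "emotion", "sf"])[["latency_ms", "amplitude_uv"]]
        .mean()
        .reset_index()
    )
    lines += ["## Emotion x SF peak measures (group means)", "", _md_table(cell), ""]
    hw = means_df.groupby(["window", "sf"])["mean_uv"].agg(["mean", "std"]).reset_index()
    lines += ["## Hemiretinal difference window means (µV)", "", _md_table(hw), ""]
    lines += ["## Repeated-measures ANOVAs", ""]
    for name, frame in anovas.items():
        lines += [f"### {name}", "", _md_table(frame.drop(columns=["SS_effect", "SS_error"])), ""]
    lines += ["## Post hoc comparisons (hemiretinal windows, Bonferroni)", ""]
    for window, results in posthocs.items():
        df = pd.DataFrame(
            [{"pair": r.pair, "t": r.t, "p_bonf": r.p_bonf, "cohen_d": r.cohen_d} for r in results]
        )
        lines += [f"### {window}", "", _md_table(df), ""]
    if behaviour is not None:
        dp = behaviour["cell_table"].groupby(["emotion"])["d_prime"].mean().reset_index()
        lines += ["## Behaviour", "", _md_table(dp), ""]
        lines += ["### RT ANOVA", "", _md_table(behaviour["rt_anova"].drop(columns=["SS_effect", "SS_error"])), ""]
        lines += ["### d' ANOVA", "", _md_table(behaviour["dprime_anova"].drop(columns=["SS_effect", "SS_error"])), ""]
    (out / "report.md").write_text("\n".join(lines))


def _write_checksums(out: Path) -> None:
    sums = {}
    for p in sorted(out.iterdir()):
        if p.name == "checksums.json" or p.is_dir():
            continue
        sums[p.name] = hashlib.sha256(p.read_bytes()).hexdigest()
    (out / "checksums.json").write_text(json.dumps(sums, indent=1, sort_keys=True))


# ---------------------------------------------------------------------------
# Figures
# ---------------------------------------------------------------------------


def make_figures(result: RunResult, out_dir: str | Path | None = None) -> list[Path]:
    """Grand-average ERP overlay and N2pc/hemiretinal-difference panels (SVG).

    The plotted series are exported alongside as TSV so figures and
    pipeline outputs can be diffed.
    """
    import matplotlib

    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    out = Path(out_dir) if out_dir is not None else result.out_dir
    out.mkdir(parents=True, exist_ok=True)
    # Export the plotted series next to the figures so the two can be diffed
    # against the pipeline waveform TSVs (identical content by construction).
    erp_frame, hemi_frame = _grand_average_frames(result.grand_averages)
    erp_frame.to_csv(out / "fig_erp_by_sf.tsv", sep="\t", index=False)
    hemi_frame.to_csv(out / "fig_hemiretinal.tsv", sep="\t", index=False)
    t = result.grand_averages["times_ms"]
    colors = {"BSF": "black", "HSF": "tab:blue", "LSF": "tab:red"}
    paths = []

    fig, ax = plt.subplots(figsize=(7, 4.5))
    for (sf, emotion), v in sorted(result.grand_averages["emotion"].items()):
        ax.plot(t, v, color=colors[sf], linestyle="-" if emotion == "fear" else ":", label=f"{sf} {emotion}")
    ax.axvline(0, color="grey", lw=0.5)
    ax.set(xlabel="time (ms)", ylabel="µV", title="Grand-average parietal ERP by SF and emotion")
    ax.legend(fontsize=7, ncol=2)
    p = out / "fig_erp_by_sf.svg"
    fig.savefig(p, metadata={"Date": None})
    plt.close(fig)
    paths.append(p)

    fig, axes = plt.subplots(1, 2, figsize=(10, 4), sharey=True)
    for (sf, hemi), v in sorted(result.grand_averages["n2pc"].items()):
        axes[0].plot(t, v, color=colors[sf], linestyle="-" if hemi == "nasal" else "--", label=f"{sf} {hemi}")
    axes[0].set(xlabel="time (ms)", ylabel="µV", title="N2pc (contra - ipsi)")
    axes[0].legend(fontsize=7)
    for sf, v in sorted(result.grand_averages["hemidiff"].items()):
        axes[1].plot(t, v, color=colors[sf], label=sf)
    axes[1].set(xlabel="time (ms)", title="Hemiretinal difference (nasal - temporal)")
    axes[1].legend(fontsize=7)
    for ax in axes:
        ax.axvline(0, color="grey", lw=0.5)
        ax.axhline(0, color="grey", lw=0.5)
    p = out / "fig_hemiretinal.svg"
    fig.savefig(p, metadata={"Date": None})
    plt.close(fig)
    paths.append(p)
    return paths


# ---------------------------------------------------------------------------
# Replicated simulations (power / recovery)
# ---------------------------------------------------------------------------


def power_simulation(
    n_reps: int = 200,
    n_subjects: int = 36,
    gt: GroundTruth | None = None,
    seed: int = 0,
    n_trials_per_condition: int = 100,
    alpha: float = 0.05,
    window: str = "N170",
) -> dict:
    """Replicate the hemiretinal SF analysis on fast-path simulated data.

    Each replicate draws per-subject condition averages from the exact
    trial-average distribution, runs the hemiretinal construction and the
    one-way SF RM ANOVA on the given window's means, and records the
    BSF - HSF contrast. Returns the rejection rate, the mean contrast and
    its Monte-Carlo SE.
    """
    gt = gt or GroundTruth()
    lo, hi = CANONICAL_WINDOWS[window]
    master = np.random.SeedSequence(seed)
    pvals, contrasts = [], []
    for rep_seq in master.spawn(n_reps):
        off_seq, noise_seq = rep_seq.spawn(2)
        off_rng = np.random.default_rng(off_seq)
        rows = []
        for subj in range(n_subjects):
            eye = "left" if subj % 2 == 0 else "right"
            spec = SubjectSpec(
                subject=subj + 1,
                viewing_eye=eye,
                epoch_seed=tuple(noise_seq.spawn(1)[0].generate_state(4).tolist()),
                behavior_seed=(0,),
                asym_offsets={
                    (sf, hemi): float(off_rng.normal(0.0, gt.between_subject_sd_uv))
                    for sf in SF_BANDS
                    for hemi in ("nasal", "temporal")
                },
            )
            waves = simulate_condition_averages(spec, gt, n_trials_per_condition)
            fear_pools = {}
            for sf in SF_BANDS:
                for tt in ("fear_left", "fear_right"):
                    left, right = waves[(sf, tt)]
                    label = ConditionLabel(viewing_eye=eye, sf=sf, trial_type=tt)
                    mk = lambda v, pool: ERPWaveform(
                        values=v, srate_hz=SRATE_HZ, t0_ms=T0_MS, pool=pool, label=label,
                        n_trials=n_trials_per_condition,
                    )
                    fear_pools[(sf, tt)] = (mk(left, "left_parietal"), mk(right, "right_parietal"))
            _, hemidiff = subject_hemiretinal_waves(fear_pools, eye)
            for sf, wave in hemidiff.items():
                rows.append(
                    {"subject": subj + 1, "sf": sf,
                     "mean_uv": float(window_mean_values(wave.values, lo, hi))}
                )
        df = pd.DataFrame(rows)
        res = rm_anova(df, dv="mean_uv", subject="subject", within=["sf"])
        pvals.append(float(res.p.iloc[0]))
        wide = df.pivot(index="subject", columns="sf", values="mean_uv")
        contrasts.append(float((wide["BSF"] - wide["HSF"]).mean()))
    pvals = np.asarray(pvals)
    contrasts = np.asarray(contrasts)
    true_contrast = (gt.asymmetry("BSF", "nasal") - gt.asymmetry("BSF", "temporal")) - (
        gt.asymmetry("HSF", "nasal") - gt.asymmetry("HSF", "temporal")
    )
    return {
        "n_reps": n_reps,
        "rejection_rate": float((pvals < alpha).mean()),
        "mean_contrast_uv": float(contrasts.mean()),
        "se_contrast_uv": float(contrasts.std(ddof=1) / np.sqrt(n_reps)),
        "true_contrast_uv": float(true_contrast),
    }
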