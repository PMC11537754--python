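"""Repeated-measures statistics and signal detection.

* :func:`rm_anova` — fully-within-subject balanced factorial ANOVA via a
  complete sums-of-squares decomposition (subject, every effect, every
  effect x subject error term). F for effect A uses the A x subject
  interaction as the error term; partial eta squared is
  SS_effect / (SS_effect + SS_error). No sphericity correction is applied
  by default (integer dfs); Greenhouse-Geisser correction is available as
  an option.
* :func:`bonferroni_posthoc` — paired t-tests with Bonferroni-corrected p
  values and Cohen's d (d_z convention by default: mean of differences
  over SD of differences; d_av available).
* :func:`d_prime` — z(hit rate) - z(false-alarm rate), with extreme rates
  0 and 1 substituted by 1e-8 and 0.999999999 respectively.
* :func:`behavioural_analysis` — 2 (emotion) x 3 (SF) RM ANOVAs on mean
  correct-response RTs and per-cell d'.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sstats

__all__ = [
    "RATE_FLOOR",
    "RATE_CEIL",
    "DPrime",
    "PosthocResult",
    "rm_anova",
    "bonferroni_posthoc",
    "d_prime",
    "behavioural_analysis",
]

RATE_FLOOR = 1e-8
RATE_CEIL = 0.999999999


def _pivot_cells(df: pd.DataFrame, dv: str, subject: str, within: Sequence[str]):
    """Balanced (n_subjects, l1, ..., lk) cell array; averages replicates."""
    levels = [list(pd.unique(df[f])) for f in within]
    subjects = list(pd.unique(df[subject]))
    grouped = df.groupby([subject, *within], sort=False)[dv].mean()
    expected = len(subjects) * int(np.prod([len(l) for l in levels]))
    if len(grouped) != expected:
        raise ValueError("design is not balanced: every subject needs every cell")
    shape = (len(subjects), *[len(l) for l in levels])
    arr = np.empty(shape)
    arr[:] = np.nan
    sub_idx = {s: i for i, s in enumerate(subjects)}
    lev_idx = [{l: i for i, l in enumerate(ls)} for ls in levels]
    for key, val in grouped.items():
        s, *cells = key if isinstance(key, tuple) else (key,)
        arr[(sub_idx[s], *[lev_idx[j][c] for j, c in enumerate(cells)])] = val
    if np.isnan(arr).any():
        raise ValueError("design is not balanced: missing cells")
    return arr, subjects, levels


def _effect_term(Y: np.ndarray, axes: tuple[int, ...]) -> np.ndarray:
    """Inclusion-exclusion effect estimate for the factor subset ``axes``.

    Broadcast over the full grid, so ``(term ** 2).sum()`` is the classical
    sum of squares with its replication multiplicity built in.
    """
    all_axes = tuple(range(Y.ndim))
    term = np.zeros_like(Y)
    for r in range(len(axes) + 1):
        for sub in itertools.combinations(axes, r):
            margin_axes = tuple(a for a in all_axes if a not in sub)
            margin = Y.mean(axis=margin_axes, keepdims=True) if margin_axes else Y
            term = term + (-1.0) ** (len(axes) - len(sub)) * margin
    return term


def _gg_epsilon(Y: np.ndarray, axes: tuple[int, ...], levels: Sequence[int]) -> float:
    """Greenhouse-Geisser epsilon for one within effect.

    Built from orthonormal contrasts of the effect subspace (Kronecker
    product of per-factor contrast bases, identity-direction 1/sqrt(l) for
    factors outside the effect), applied to the subject x cells matrix.
    """
    n_sub = Y.shape[0]
    M = Y.reshape(n_sub, -1)
    C = np.ones((1, 1))
    for ax, l in enumerate(levels, start=1):
        if ax in axes:
            # orthonormal basis of the centered subspace
            basis = np.linalg.qr(np.eye(l) - 1.0 / l)[0][:, : l - 1]
        else:
            basis = np.full((l, 1), 1.0 / np.sqrt(l))
        C = np.kron(C, basis)
    D = M @ C
    S = np.cov(D, rowvar=False)
    S = np.atleast_2d(S)
    k = S.shape[0]
    return float(np.trace(S) ** 2 / (k * np.sum(S * S.T)))


def rm_anova(
    data: pd.DataFrame,
    dv: str,
    subject: str,
    within: Sequence[str],
    correction: bool = False,
) -> pd.DataFrame:
    """Balanced fully-within repeated-measures ANOVA.

    Parameters
    ----------
    data
        Long-format table with one row per subject x cell (replicates are
        averaged first).
    dv, subject, within
        Column names of the dependent variable, the subject identifier and
        the within-subject factors.
    correction
        If True, add Greenhouse-Geisser-corrected dfs and p values.

    Returns
    -------
    DataFrame with one row per effect: effect, F, df1, df2, p, eta_p2
    (plus eps_gg, df1_gg, df2_gg, p_gg when ``correction``).
    """
    Y, subjects, levels = _pivot_cells(data, dv, subject, within)
    n_sub = len(subjects)
    if n_sub < 2:
        raise ValueError("need at least 2 subjects")
    n_levels = [len(l) for l in levels]
    # numerical floor for "no variance at all" (identical data across levels)
    ss_floor = 1e-12 * max(float(((Y - Y.mean()) ** 2).sum()), 1.0)
    rows = []
    for r in range(1, len(within) + 1):
        for combo in itertools.combinations(range(1, len(within) + 1), r):
            ss_eff = float((_effect_term(Y, combo) ** 2).sum())
            ss_err = float((_effect_term(Y, (0, *combo)) ** 2).sum())
            df1 = int(np.prod([n_levels[a - 1] - 1 for a in combo]))
            df2 = df1 * (n_sub - 1)
            if ss_err <= ss_floor:
                if ss_eff > ss_floor:
                    raise ZeroDivisionError("zero error variance: degenerate data for RM ANOVA")
                # no effect and no error: define F = 0 (identical data across levels)
                F = 0.0
                ss_eff = ss_err = 0.0
            else:
                F = (ss_eff / df1) / (ss_err / df2)
            row = {
                "effect": " * ".join(within[a - 1] for a in combo),
                "F": F,
                "df1": df1,
                "df2": df2,
                "p": float(sstats.f.sf(F, df1, df2)),
                "eta_p2": ss_eff / (ss_eff + ss_err) if (ss_eff + ss_err) > 0 else 0.0,
                "SS_effect": ss_eff,
                "SS_error": ss_err,
            }
            if correction:
                eps = _gg_epsilon(Y, combo, n_levels)
                row["eps_gg"] = eps
                row["df1_gg"] = df1 * eps
                row["df2_gg"] = df2 * eps
                row["p_gg"] = float(sstats.f.sf(F, df1 * eps, df2 * eps))
            rows.append(row)
    return pd.DataFrame(rows)


@dataclass(frozen=True)
class PosthocResult:
    pair: str
    t: float
    df: int
    p_raw: float
    p_bonf: float
    cohen_d: float
    flag: str | None = None


def bonferroni_posthoc(
    pairs: Mapping[str, tuple[np.ndarray, np.ndarray]],
    m: int | None = None,
    d_convention: str = "dz",
) -> list[PosthocResult]:
    """Paired t-tests over a family of comparisons with Bonferroni correction.

    ``m`` defaults to the family size. ``d_convention``: "dz" (mean diff /
    SD of diffs) or "dav" (mean diff / average of the two SDs).
    """
    if d_convention not in ("dz", "dav"):
        raise ValueError("d_convention must be 'dz' or 'dav'")
    m = len(pairs) if m is None else m
    out = []
    for name, (x, y) in pairs.items():
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        if x.shape != y.shape:
            raise ValueError(f"pair {name!r}: unequal lengths")
        diff = x - y
        n = len(diff)
        sd = float(diff.std(ddof=1))
        if sd == 0.0:
            out.append(PosthocResult(name, 0.0, n - 1, 1.0, 1.0, 0.0, flag="degenerate:zero-variance"))
            continue
        t = float(diff.mean() / (sd / np.sqrt(n)))
        p_raw = float(2 * sstats.t.sf(abs(t), n - 1))
        if d_convention == "dz":
            d = float(diff.mean() / sd)
        else:
            d = float(diff.mean() / ((x.std(ddof=1) + y.std(ddof=1)) / 2.0))
        out.append(PosthocResult(name, t, n - 1, p_raw, min(1.0, m * p_raw), d))
    return out


@dataclass(frozen=True)
class DPrime:
    hit_rate: float
    fa_rate: float
    d_prime: float


def d_prime(hits: int, n_signal: int, false_alarms: int, n_noise: int) -> DPrime:
    """Signal-detection sensitivity d' = z(hit rate) - z(false-alarm rate).

    Rates of exactly 0 or 1 are substituted with 1e-8 and 0.999999999 so
    the normal quantile stays finite.
    """
    if n_signal <= 0 or n_noise <= 0:
        raise ValueError("signal and noise trial counts must be positive")
    if not (0 <= hits <= n_signal) or not (0 <= false_alarms <= n_noise):
        raise ValueError("counts out of range")
    hr = hits / n_signal
    fa = false_alarms / n_noise
    hr = RATE_FLOOR if hr == 0.0 else (RATE_CEIL if hr == 1.0 else hr)
    fa = RATE_FLOOR if fa == 0.0 else (RATE_CEIL if fa == 1.0 else fa)
    return DPrime(hr, fa, float(sstats.norm.ppf(hr) - sstats.norm.ppf(fa)))


def behavioural_analysis(behavior: pd.DataFrame, correction: bool = False) -> dict:
    """RT and d' 2 (emotion) x 3 (SF) repeated-measures ANOVAs.

    ``behavior`` is the long-format per-subject-per-cell table produced by
    the synthetic-data module (columns: subject, sf, emotion, n_signal,
    n_noise, hits, false_alarms, mean_rt_s). Analyses run on subject-level
    cell means, the statistically appropriate unit.
    """
    df = behavior.copy()
    df["d_prime"] = [
        d_prime(int(r.hits), int(r.n_signal), int(r.false_alarms), int(r.n_noise)).d_prime
        for r in df.itertuples()
    ]
    rt = rm_anova(df, dv="mean_rt_s", subject="subject", within=["emotion", "sf"], correction=correction)
    dp = rm_anova(df, dv="d_prime", subject="subject", within=["emotion", "sf"], correction=correction)
    return {"rt_anova": rt, "dprime_anova": dp, "cell_table": df}
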