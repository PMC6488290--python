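"""Multiunit activity: extraction, epoching, channel statistics, taxonomy.

The MUA envelope is obtained by pairwise vertical re-referencing of the
probe contacts, high-pass filtering at 1000 Hz, full-wave rectification and
low-pass filtering at 200 Hz (4th-order Butterworth, applied forward and
backward so response latencies are not shifted). Trials are epoched from
2 s before to 3 s after stimulus onset and z-scored against the mean/SD of
the 3 s preceding each onset. Channel-level statistics are one-tailed t
tests on the area under the z-MUA (AUC, z·s) in 1 s baseline and response
windows; channels are then classified into a three-set Venn taxonomy
(social / laser / cs) and screened for habituation across trials, with a
Bayesian t test quantifying evidence for *no* habituation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import integrate, signal, stats

from .synth import ContinuousRecording, TrialSchedule
from .venn import VennCounts
from .windows import (
    BASELINE_WINDOW,
    EPOCH_SPAN,
    Z_REFERENCE_SECONDS,
    response_window,
)

# --------------------------------------------------------------------------
# signal chain

def pairwise_rereference(rec: ContinuousRecording) -> ContinuousRecording:
    """Difference of vertically adjacent contacts on each shaft.

    A shaft of 6 contacts yields 5 difference channels (contact_i −
    contact_{i+1}); a 5-shaft probe yields 25. Common-mode signal present
    on both contacts of a pair cancels exactly.
    """
    diffs, names, shaft_map, parents = [], [], [], []
    k = 0
    for s, contacts in enumerate(rec.shaft_map):
        if len(contacts) < 2:
            raise ValueError(f"shaft {s} has fewer than 2 contacts")
        col = []
        for a, b in zip(contacts[:-1], contacts[1:]):
            diffs.append(rec.data[a] - rec.data[b])
            names.append(f"sh{s}d{len(col)}")
            parents.append((a, b))
            col.append(k)
            k += 1
        shaft_map.append(col)
    return ContinuousRecording(
        data=np.asarray(diffs, dtype=np.float32),
        fs_hz=rec.fs_hz,
        shaft_map=shaft_map,
        channel_names=names,
        meta={"parent_contacts": parents},
    )


def extract_mua(
    x: np.ndarray,
    fs_hz: float,
    highpass_hz: float = 1000.0,
    lowpass_hz: float = 200.0,
    order: int = 4,
) -> np.ndarray:
    """MUA envelope: zero-phase high-pass, rectify, zero-phase low-pass.

    Accepts a single trace or a (channels × samples) matrix; output has the
    same shape and is non-negative up to filter ringing.
    """
    x = np.asarray(x, dtype=float)
    if not np.all(np.isfinite(x)):
        raise ValueError("non-finite samples in input")
    if fs_hz <= 2 * highpass_hz:
        raise ValueError("sampling rate too low for the high-pass cutoff")
    sos_hp = signal.butter(order, highpass_hz, "highpass", fs=fs_hz, output="sos")
    sos_lp = signal.butter(order, lowpass_hz, "lowpass", fs=fs_hz, output="sos")
    y = signal.sosfiltfilt(sos_hp, x, axis=-1)
    y = np.abs(y)
    return signal.sosfiltfilt(sos_lp, y, axis=-1)


# --------------------------------------------------------------------------
# epoching

@dataclass
class MuaEpochSet:
    """z-scored MUA epochs: (channels × trials × time).

    ``times`` spans (−2, +3) s around onset; each trial of each channel is
    z-scored by its own 3 s pre-onset mean/SD, so the reference window has
    mean 0 / SD 1 by construction. ``excluded`` flags trials rejected by
    the artifact screen (never silently deleted). ``degenerate`` flags
    channel×trial cells whose pre-onset SD was zero (left unscaled).
    """

    z: np.ndarray
    times: np.ndarray
    schedule: TrialSchedule
    excluded: np.ndarray = field(default=None)
    degenerate: np.ndarray = field(default=None)

    def __post_init__(self):
        if self.excluded is None:
            self.excluded = np.zeros(self.z.shape[1], dtype=bool)
        if self.degenerate is None:
            self.degenerate = np.zeros(self.z.shape[:2], dtype=bool)

    @property
    def n_channels(self) -> int:
        return self.z.shape[0]

    @property
    def n_trials(self) -> int:
        return self.z.shape[1]

    def trials_of(self, condition: str, include_excluded: bool = False) -> np.ndarray:
        m = self.schedule.conditions == condition
        if not include_excluded:
            m &= ~self.excluded
        return np.flatnonzero(m)


def epoch_and_ztransform(
    mua: np.ndarray,
    fs_hz: float,
    schedule: TrialSchedule,
    span: tuple[float, float] = EPOCH_SPAN,
    z_reference_s: float = Z_REFERENCE_SECONDS,
) -> MuaEpochSet:
    """Epoch the MUA matrix around every onset and z-score per trial.

    The z reference is the ``z_reference_s`` seconds before onset, which
    may extend before the epoch span; trials whose reference or span fall
    outside the recording raise (no silent truncation).
    """
    mua = np.atleast_2d(np.asarray(mua, dtype=float))
    n_ch, n_samp = mua.shape
    pre = max(-span[0], z_reference_s)
    i_span = (int(round(span[0] * fs_hz)), int(round(span[1] * fs_hz)))
    n_time = i_span[1] - i_span[0]
    onsets = schedule.onsets
    z = np.empty((n_ch, len(onsets), n_time))
    degenerate = np.zeros((n_ch, len(onsets)), dtype=bool)
    for j, onset in enumerate(onsets):
        i0 = int(round(onset * fs_hz))
        if i0 - int(round(pre * fs_hz)) < 0 or i0 + i_span[1] > n_samp:
            raise ValueError(f"trial at {onset:.3f} s extends past the recording")
        ref = mua[:, i0 - int(round(z_reference_s * fs_hz)) : i0]
        mu = ref.mean(axis=1)
        sd = ref.std(axis=1, ddof=0)
        seg = mua[:, i0 + i_span[0] : i0 + i_span[1]]
        bad = sd == 0
        degenerate[:, j] = bad
        sd_safe = np.where(bad, 1.0, sd)
        z[:, j, :] = (seg - mu[:, None]) / sd_safe[:, None]
    times = (np.arange(i_span[0], i_span[1]) + 0.5) / fs_hz
    return MuaEpochSet(z=z, times=times, schedule=schedule, degenerate=degenerate)


def detect_artifact_trials(
    epochs: MuaEpochSet,
    z_hi: float = 8.0,
    z_lo: float = -5.0,
    channel_fraction: float = 0.5,
) -> np.ndarray:
    """Flag trials with extreme z-MUA across many channels.

    A trial is flagged iff the fraction of channels containing any sample
    above ``z_hi`` or below ``z_lo`` reaches ``channel_fraction``. Flags
    are recorded on ``epochs.excluded`` and returned.
    """
    extreme = ((epochs.z > z_hi) | (epochs.z < z_lo)).any(axis=2)  # ch × trial
    frac = extreme.mean(axis=0)
    flags = frac >= channel_fraction
    epochs.excluded = epochs.excluded | flags
    return flags


# --------------------------------------------------------------------------
# AUC and activation tests

def auc(epoch: np.ndarray, times: np.ndarray, window: tuple[float, float]) -> float | np.ndarray:
    """Trapezoidal time-integral of z-MUA over a window (units z·s).

    ``epoch`` may be 1-D (time) or N-D with time last; returns the integral
    per leading index.
    """
    m = (times >= window[0]) & (times <= window[1])
    if not m.any() or window[0] < times[0] - 1e-9 or window[1] > times[-1] + 1e-9:
        raise ValueError("window outside epoch span")
    return integrate.trapezoid(np.asarray(epoch)[..., m], times[m], axis=-1)


def window_aucs(epochs: MuaEpochSet, window: tuple[float, float]) -> np.ndarray:
    """AUC per channel × trial over a fixed peri-onset window."""
    return auc(epochs.z, epochs.times, window)


def test_activation(
    baseline_aucs: np.ndarray,
    response_aucs: np.ndarray,
    paired: bool = True,
    alpha: float = 0.01,
    tail: str = "greater",
) -> tuple[float, float, bool]:
    """One-tailed t test for activation (response > baseline or A > B).

    Paired (matched trials against their own baseline) or two-sample
    (across conditions). Zero-variance data yield no test: t = 0, p = 1,
    flag False.
    """
    b = np.asarray(baseline_aucs, float)
    r = np.asarray(response_aucs, float)
    if paired and len(b) != len(r):
        raise ValueError("paired test requires equal-length vectors")
    if min(len(b), len(r)) < 2:
        raise ValueError("need at least 2 observations per group")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        if paired:
            res = stats.ttest_rel(r, b, alternative=tail)
        else:
            res = stats.ttest_ind(r, b, alternative=tail)
    t, p = float(res.statistic), float(res.pvalue)
    if not np.isfinite(t):
        return 0.0, 1.0, False
    return t, p, bool(p < alpha)


# --------------------------------------------------------------------------
# channel classification

CONTRASTS = (
    "HighShockObs>Baseline",
    "HighLaser>Baseline",
    "CS>Baseline",
    "HighShockObs>CtrlShockObs",
    "HighLaser>CtrlLaser",
)

RESPONSIVE_CONTRASTS = CONTRASTS[:3]


def channel_stats(
    epoch_sets: dict[str, MuaEpochSet],
    alpha: float = 0.01,
    deactivation: bool = False,
) -> pd.DataFrame:
    """Per-channel contrast statistics over the three sessions.

    ``epoch_sets`` maps session id → epoched z-MUA. Baseline contrasts are
    paired t tests of response-window vs baseline-window AUC across that
    condition's trials; condition contrasts (High vs Ctrl) are two-sample
    t tests across trials. With ``deactivation`` the tail flips to scan for
    stimulus-triggered decreases.
    """
    tail = "less" if deactivation else "greater"
    rows = []
    for session, high_cond, contrast_base, contrast_ctrl in (
        ("ShockObs", "High", "HighShockObs>Baseline", "HighShockObs>CtrlShockObs"),
        ("Laser", "High", "HighLaser>Baseline", "HighLaser>CtrlLaser"),
        ("CS", "CS", "CS>Baseline", None),
    ):
        ep = epoch_sets.get(session)
        if ep is None:
            continue
        win = response_window(session)
        resp = window_aucs(ep, win)
        base = window_aucs(ep, BASELINE_WINDOW)
        hi = ep.trials_of(high_cond)
        for ch in range(ep.n_channels):
            t, p, flag = test_activation(
                base[ch, hi], resp[ch, hi], paired=True, alpha=alpha, tail=tail
            )
            rows.append((ch, contrast_base, t, p, flag))
        if contrast_ctrl is not None:
            ctrl = ep.trials_of("Ctrl")
            for ch in range(ep.n_channels):
                t, p, flag = test_activation(
                    resp[ch, ctrl], resp[ch, hi], paired=False, alpha=alpha, tail=tail
                )
                rows.append((ch, contrast_ctrl, t, p, flag))
    return pd.DataFrame(rows, columns=["channel", "contrast", "t", "p", "flag"])


def classify_channels(stats_df: pd.DataFrame) -> tuple[VennCounts, pd.DataFrame]:
    """Venn taxonomy from per-channel contrast flags.

    Responsive = any of the three vs-baseline contrasts significant; among
    responsive channels the social/laser flags come from the High-vs-Ctrl
    contrasts and the cs flag from CS>Baseline. A "mirror channel" is
    social AND (laser OR cs).
    """
    table = stats_df.pivot(index="channel", columns="contrast", values="flag")
    missing = [c for c in CONTRASTS if c not in table.columns]
    if missing:
        raise ValueError(f"missing contrasts: {missing}")
    table = table.fillna(False).astype(bool)
    responsive = table[list(RESPONSIVE_CONTRASTS)].any(axis=1)
    flags = pd.DataFrame(
        {
            "responsive": responsive,
            "social": table["HighShockObs>CtrlShockObs"] & responsive,
            "laser": table["HighLaser>CtrlLaser"] & responsive,
            "cs": table["CS>Baseline"] & responsive,
        }
    )
    flags["mirror"] = flags["social"] & (flags["laser"] | flags["cs"])
    counts = VennCounts.from_flags(
        flags["social"], flags["laser"], flags["cs"], flags["responsive"]
    )
    return counts, flags


# --------------------------------------------------------------------------
# habituation

@dataclass
class HabituationResult:
    per_condition: pd.DataFrame  # condition, t, p, mean_first5, mean_last5
    anova: pd.DataFrame  # pingouin two-way RM table
    interaction_F: float
    interaction_p: float


def habituation_test(
    epoch_sets: dict[str, MuaEpochSet],
    conditions: dict[str, str] | None = None,
    n_edge: int = 5,
    tail: str = "two-sided",
) -> HabituationResult:
    """First-5 vs last-5 trial AUC comparison per condition + 3×2 RM ANOVA.

    For each channel the response-window AUC is averaged over the first and
    last ``n_edge`` trials of each condition; a population paired t test is
    run per condition (two-tailed by default: both decreases and increases
    are reported) and a repeated-measures ANOVA with factors condition ×
    epoch tests whether habituation differs across conditions.
    """
    import pingouin as pg

    conditions = conditions or {"ShockObs": "High", "Laser": "High", "CS": "CS"}
    rows, long = [], []
    for session, cond in conditions.items():
        ep = epoch_sets[session]
        idx = ep.trials_of(cond)
        if len(idx) < 2 * n_edge:
            raise ValueError(f"need >= {2 * n_edge} {cond} trials in {session}")
        aucs = window_aucs(ep, response_window(session))[:, idx]
        first = aucs[:, :n_edge].mean(axis=1)
        last = aucs[:, -n_edge:].mean(axis=1)
        res = stats.ttest_rel(first, last, alternative=tail)
        t_stat, p_val = float(res.statistic), float(res.pvalue)
        if not np.isfinite(t_stat):  # zero-variance differences: no evidence
            t_stat, p_val = 0.0, 1.0
        rows.append((session, t_stat, p_val, first.mean(), last.mean()))
        for ch in range(len(first)):
            long.append((ch, session, "first", first[ch]))
            long.append((ch, session, "last", last[ch]))
    per_cond = pd.DataFrame(
        rows, columns=["condition", "t", "p", "mean_first", "mean_last"]
    )
    df = pd.DataFrame(long, columns=["channel", "condition", "epoch", "auc"])
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        table = pg.rm_anova(
            data=df, dv="auc", within=["condition", "epoch"], subject="channel"
        )
    inter = table[table["Source"].str.contains(r"\*")].iloc[0]
    p_col = "p_unc" if "p_unc" in table.columns else "p-unc"
    return HabituationResult(
        per_condition=per_cond,
        anova=table,
        interaction_F=float(inter["F"]),
        interaction_p=float(inter[p_col]),
    )


# --------------------------------------------------------------------------
# Bayesian null t test

def bayes_factor_null(
    t: float, n: int, prior_scale: float = 0.707, one_tailed: bool = True
) -> float:
    """BF0+ for a one-sample t statistic: H0 (δ=0) against H+ (δ>0).

    The alternative places a Cauchy prior (scale ``prior_scale``) on the
    standardized effect δ, truncated to positive values when one-tailed.
    The marginal likelihood under H+ is the noncentral-t density integrated
    over the prior by adaptive quadrature; values above 30 are
    conventionally "very strong" evidence for the null.
    """
    if not np.isfinite(t):
        raise ValueError("non-finite t")
    if n < 2:
        raise ValueError("need n >= 2")
    df = n - 1
    rt_n = np.sqrt(n)

    def nct_pdf(delta):
        with np.errstate(all="ignore"):
            v = stats.nct.pdf(t, df, delta * rt_n)
        return v if np.isfinite(v) else 0.0  # underflow far from t

    lo = 0.0 if one_tailed else -np.inf
    norm = 2.0 if one_tailed else 1.0

    def integrand(d):
        return nct_pdf(d) * norm * stats.cauchy.pdf(d, scale=prior_scale)

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        if one_tailed:
            m1 = integrate.quad(integrand, 0.0, 1.0, limit=200)[0]
            m1 += integrate.quad(integrand, 1.0, np.inf, limit=200)[0]
        else:
            m1 = integrate.quad(integrand, -1.0, 1.0, limit=200)[0]
            m1 += integrate.quad(integrand, 1.0, np.inf, limit=200)[0]
            m1 += integrate.quad(integrand, -np.inf, -1.0, limit=200)[0]
    m0 = stats.t.pdf(t, df)
    return float(m0 / m1)
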