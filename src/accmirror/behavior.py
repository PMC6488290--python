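"""Behavioral and audio analyses.

Covers the observer/demonstrator behavioral readouts that accompany the
neural analyses: the head-orientation attention score, freezing
percentages over fixed epochs, trial-triggered audio spectrograms with
random-effects (one value per animal) pixel-wise t tests, instantaneous
firing rate and the spike-triggered spectrogram, the muscimol 2×2×2 mixed
ANOVA, and the effect-size / sample-size arithmetic used to plan the
experiments.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .synth import AudioEnergyTrack, Ethogram

# --------------------------------------------------------------------------
# attention and freezing

def attention_score(alpha_deg: float | np.ndarray) -> float | np.ndarray:
    """Attention from the observer-to-demonstrator head angle α.

    1 for α ≤ 30° (facing the demonstrator within the ±30° cone), 0 for
    α ≥ 150° (facing away within ±30° of 180°), linear in between:
    (150 − α)/120. α = 70° scores 0.66 (two decimals).
    """
    a = np.asarray(alpha_deg, float)
    if np.any(a < 0) or np.any(a > 180):
        raise ValueError("angle must lie in [0, 180] degrees")
    score = np.clip((150.0 - a) / 120.0, 0.0, 1.0)
    return float(score) if np.isscalar(alpha_deg) else score


#: Epoch convention for the muscimol freezing analysis: baseline is the
#: first 720 s of the test, the test epoch the following 720 s.
BASELINE_EPOCH = (0.0, 720.0)
TEST_EPOCH = (720.0, 1440.0)


def freezing_percentage(
    ethogram: Ethogram | pd.DataFrame, epoch: tuple[float, float]
) -> float:
    """Percent of an epoch spent freezing; bouts clipped at epoch edges."""
    t0, t1 = epoch
    if t1 <= t0:
        raise ValueError("zero-length epoch")
    df = ethogram.intervals if isinstance(ethogram, Ethogram) else ethogram
    fz = df[df["behavior"] == "freezing"]
    total = np.sum(
        np.clip(np.minimum(fz["stop_s"], t1) - np.maximum(fz["start_s"], t0), 0, None)
    )
    return 100.0 * float(total) / (t1 - t0)


# --------------------------------------------------------------------------
# trial-triggered spectrograms

@dataclass
class SpectrogramStack:
    """Aligned per-trial (or per-moment) time × frequency energy windows."""

    stack: np.ndarray  # n_trials × n_freqs × n_times
    lags: np.ndarray  # s relative to onset, bin centers
    freqs: np.ndarray

    @property
    def grand_average(self) -> np.ndarray:
        return self.stack.mean(axis=0)


def trial_triggered_spectrogram(
    track: AudioEnergyTrack,
    onsets: np.ndarray,
    window: tuple[float, float] = (-2.0, 3.0),
) -> SpectrogramStack:
    """Stack the audio-energy track around every onset and grand-average."""
    dt = track.dt
    i_lo = int(round(window[0] / dt))
    i_hi = int(round(window[1] / dt))
    lags = (np.arange(i_lo, i_hi) + 0.5) * dt
    segs = []
    for onset in np.asarray(onsets, float):
        i_on = int(np.searchsorted(track.times, onset))
        if i_on + i_lo < 0 or i_on + i_hi > track.energy.shape[1]:
            raise ValueError(f"onset {onset:.2f} s too near the track edge")
        segs.append(track.energy[:, i_on + i_lo : i_on + i_hi])
    return SpectrogramStack(stack=np.array(segs), lags=lags, freqs=track.freqs)


def pixel_ttest(
    stacks_a: np.ndarray,
    stacks_b: np.ndarray,
    p_threshold: float = 0.001,
    tail: str = "greater",
) -> tuple[np.ndarray, np.ndarray]:
    """Random-effects matched-pair t test at every time–frequency pixel.

    Inputs are per-animal average spectrograms (animals × freqs × times),
    the same animals in both conditions. Returns the significance mask at
    ``p_threshold`` (uncorrected) and the p map.
    """
    a = np.asarray(stacks_a, float)
    b = np.asarray(stacks_b, float)
    if a.shape != b.shape:
        raise ValueError("condition stacks must have identical shapes")
    if a.shape[0] < 2:
        raise ValueError("need at least 2 animals")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = stats.ttest_rel(a, b, axis=0, alternative=tail)
    p = np.where(np.isfinite(res.pvalue), res.pvalue, 1.0)
    return p < p_threshold, p


# --------------------------------------------------------------------------
# spike-triggered spectrogram

def instantaneous_rate(spike_times: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Instantaneous firing rate: 1 / inter-spike interval.

    Returns (times, rates), one value per spike after the first. Duplicate
    spike times (zero ISI) are an error.
    """
    t = np.asarray(spike_times, float)
    if len(t) < 2:
        raise ValueError("need at least 2 spikes")
    isi = np.diff(t)
    if np.any(isi <= 0):
        raise ValueError("zero or negative inter-spike interval")
    return t[1:], 1.0 / isi


def spike_triggered_spectrogram(
    rate_times: np.ndarray,
    rates: np.ndarray,
    track: AudioEnergyTrack,
    top_pct: float = 5.0,
    half_window_s: float = 5.0,
    exclude_before_s: float = 0.0,
) -> SpectrogramStack:
    """Average de-meaned spectrogram around moments of unusually high firing.

    Qualifying moments have instantaneous rate in the top ``top_pct``% of
    all rates, occur after ``exclude_before_s`` (e.g. skipping the initial
    baseline), and admit a full ±``half_window_s`` window inside the track.
    From each local window the per-frequency mean over the whole analyzed
    period is subtracted, isolating power *changes* associated with spiking.
    """
    rate_times = np.asarray(rate_times, float)
    rates = np.asarray(rates, float)
    thresh = np.percentile(rates, 100.0 - top_pct)
    sel = rate_times[(rates >= thresh) & (rate_times >= exclude_before_s)]
    dt = track.dt
    half = int(round(half_window_s / dt))
    session_mean = track.energy[:, track.times >= exclude_before_s].mean(axis=1)
    segs = []
    for t in sel:
        i = int(np.searchsorted(track.times, t))
        if i - half < 0 or i + half > track.energy.shape[1]:
            continue
        segs.append(track.energy[:, i - half : i + half] - session_mean[:, None])
    if not segs:
        raise ValueError("no qualifying high-firing moments inside the track")
    lags = (np.arange(-half, half) + 0.5) * dt
    return SpectrogramStack(stack=np.array(segs), lags=lags, freqs=track.freqs)


# --------------------------------------------------------------------------
# muscimol mixed ANOVA

@dataclass
class MuscimolAnovaResult:
    """Paired/group t tests and the 2×2×2 mixed ANOVA table.

    The ANOVA has group (muscimol vs saline) between subjects and session
    (Shock vs CS) × epoch (baseline vs test) within subjects. With all
    factors at 2 levels every effect reduces to a t test on a per-subject
    contrast score, with F = t² on (1, n₁+n₂−2) degrees of freedom; the
    three-way interaction tests whether the session-specific freezing
    increase differs between groups.
    """

    paired_t: pd.DataFrame  # group, session, t, p (one-tailed test > baseline)
    group_t: pd.DataFrame  # session, t, p (two-sample on test-epoch freezing)
    anova: pd.DataFrame  # effect, F, df1, df2, p
    interaction_F: float
    interaction_p: float

    def summary(self) -> str:
        i = self.anova.set_index("effect")
        row = i.loc["group*session*epoch"]
        return (
            f"3-way interaction: F(1,{int(row['df2'])}) = {row['F']:.2f}, "
            f"p = {row['p']:.4g}"
        )


def _pooled_two_sample_t(x1, x2):
    n1, n2 = len(x1), len(x2)
    s2 = ((n1 - 1) * np.var(x1, ddof=1) + (n2 - 1) * np.var(x2, ddof=1)) / (n1 + n2 - 2)
    if s2 == 0:
        return 0.0, n1 + n2 - 2
    t = (np.mean(x1) - np.mean(x2)) / np.sqrt(s2 * (1 / n1 + 1 / n2))
    return float(t), n1 + n2 - 2


def muscimol_anova(table: pd.DataFrame) -> MuscimolAnovaResult:
    """Freezing analysis of the deactivation experiment.

    ``table`` columns: animal_id, group ∈ {muscimol, saline}, session ∈
    {Shock, CS}, epoch ∈ {baseline, test}, freezing (percent). Every animal
    must have all 4 session×epoch cells.
    """
    need = {"animal_id", "group", "session", "epoch", "freezing"}
    if not need <= set(table.columns):
        raise ValueError(f"table must have columns {sorted(need)}")
    wide = table.pivot_table(
        index=["animal_id", "group"], columns=["session", "epoch"], values="freezing"
    )
    cells = [("Shock", "baseline"), ("Shock", "test"), ("CS", "baseline"), ("CS", "test")]
    if wide.isna().any().any() or any(c not in wide.columns for c in cells):
        raise ValueError("incomplete table: every animal needs 2 sessions × 2 epochs")

    groups = wide.index.get_level_values("group")
    paired_rows, group_rows = [], []
    for session in ("Shock", "CS"):
        for grp in ("muscimol", "saline"):
            sub = wide[groups == grp]
            if len(sub) == 0:
                continue
            res = stats.ttest_rel(
                sub[(session, "test")], sub[(session, "baseline")], alternative="greater"
            )
            t = float(res.statistic) if np.isfinite(res.statistic) else 0.0
            p = float(res.pvalue) if np.isfinite(res.statistic) else 1.0
            paired_rows.append((grp, session, t, p))
        t, dfree = _pooled_two_sample_t(
            wide[groups == "saline"][(session, "test")].to_numpy(),
            wide[groups == "muscimol"][(session, "test")].to_numpy(),
        )
        group_rows.append((session, t, 2 * stats.t.sf(abs(t), dfree)))

    # -- contrast-score decomposition of the 2x2x2 mixed design ---------
    g1 = wide[groups == "muscimol"].to_numpy()  # columns follow `cells` order
    g2 = wide[groups == "saline"].to_numpy()
    order = [list(wide.columns).index(c) for c in cells]
    g1, g2 = g1[:, order], g2[:, order]
    # columns: Shock-bl, Shock-test, CS-bl, CS-test
    contrasts = {
        "session": np.array([1, 1, -1, -1]) / 2.0,
        "epoch": np.array([-1, 1, -1, 1]) / 2.0,
        "session*epoch": np.array([-1, 1, 1, -1]) / 2.0,
    }
    n1, n2 = len(g1), len(g2)
    df2 = n1 + n2 - 2
    rows = []
    # between-subjects main effect: subject means across the 4 cells
    t_g, _ = _pooled_two_sample_t(g1.mean(axis=1), g2.mean(axis=1))
    rows.append(("group", t_g**2, 1, df2, stats.f.sf(t_g**2, 1, df2)))
    for name, c in contrasts.items():
        s1, s2 = g1 @ c, g2 @ c
        pooled = ((n1 - 1) * np.var(s1, ddof=1) + (n2 - 1) * np.var(s2, ddof=1)) / df2
        se_within = np.sqrt(max(pooled, 0.0) * (1 / n1 + 1 / n2)) / 2.0
        grand = (np.mean(s1) + np.mean(s2)) / 2.0  # unweighted marginal mean
        t_w = grand / se_within if se_within > 0 else 0.0
        rows.append((name, t_w**2, 1, df2, stats.f.sf(t_w**2, 1, df2)))
        t_i, _ = _pooled_two_sample_t(s1, s2)
        rows.append((f"group*{name}", t_i**2, 1, df2, stats.f.sf(t_i**2, 1, df2)))
    anova = pd.DataFrame(rows, columns=["effect", "F", "df1", "df2", "p"])
    inter = anova.set_index("effect").loc["group*session*epoch"]
    return MuscimolAnovaResult(
        paired_t=pd.DataFrame(paired_rows, columns=["group", "session", "t", "p"]),
        group_t=pd.DataFrame(group_rows, columns=["session", "t", "p"]),
        anova=anova,
        interaction_F=float(inter["F"]),
        interaction_p=float(inter["p"]),
    )


def simulate_freezing_table(
    n_muscimol: int = 6,
    n_saline: int = 8,
    baseline: float = 10.0,
    shock_increase: float = 50.0,
    cs_increase: float = 50.0,
    muscimol_shock_reduction: float = 33.0,
    sd: float = 8.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Synthetic muscimol freezing table (group sizes 6 vs 8 by default).

    Muscimol blunts the Shock-test freezing increase by
    ``muscimol_shock_reduction`` percentage points and leaves CS intact —
    the planted pattern the 3-way interaction should detect.
    """
    rng = np.random.default_rng(seed)
    rows = []
    for grp, n in (("muscimol", n_muscimol), ("saline", n_saline)):
        for i in range(n):
            aid = f"{grp[:3]}{i}"
            shock_test = baseline + shock_increase - (
                muscimol_shock_reduction if grp == "muscimol" else 0.0
            )
            vals = {
                ("Shock", "baseline"): baseline,
                ("Shock", "test"): shock_test,
                ("CS", "baseline"): baseline,
                ("CS", "test"): baseline + cs_increase,
            }
            for (sess, epoch), mu in vals.items():
                rows.append(
                    (aid, grp, sess, epoch, float(np.clip(rng.normal(mu, sd), 0, 100)))
                )
    return pd.DataFrame(
        rows, columns=["animal_id", "group", "session", "epoch", "freezing"]
    )


# --------------------------------------------------------------------------
# power / sample-size arithmetic

def cohens_d(mu1: float, mu0: float, sd: float) -> float:
    """Standardized mean difference (μ1 − μ0)/σ."""
    if sd <= 0:
        raise ValueError("sd must be > 0")
    return (mu1 - mu0) / sd


def sample_size(
    d: float, alpha: float = 0.05, power: float = 0.8, one_sided: bool = True
) -> int:
    """Per-group n for a two-sample t test, normal approximation, rounded up."""
    if not (0 < alpha < 1 and 0 < power < 1):
        raise ValueError("alpha and power must be in (0, 1)")
    if d <= 0:
        raise ValueError("effect size must be > 0")
    za = stats.norm.ppf(1 - alpha) if one_sided else stats.norm.ppf(1 - alpha / 2)
    zb = stats.norm.ppf(power)
    n = 2 * ((za + zb) / d) ** 2
    return max(2, math.ceil(n))


def mirror_yield(
    cells_per_animal: float, target_cells: int, loss_rate: float = 0.0
) -> int:
    """Animals needed to reach a target cell yield, inflated for losses."""
    if cells_per_animal <= 0 or target_cells <= 0 or not 0 <= loss_rate < 1:
        raise ValueError("invalid yield arguments")
    n = math.ceil(target_cells / cells_per_animal)
    return math.ceil(n / (1.0 - loss_rate)) if loss_rate else n
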