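"""Single-cell mirror-neuron taxonomy and spike-density functions.

Per-trial spike counts in 1 s baseline and response windows feed one-tailed
Wilcoxon signed-rank tests (response vs its own baseline, p < 0.05) and
rank-sum tests across conditions. Cells are classified into the three-set
Venn taxonomy (social / laser / cs), with the derived classes:

- mirror            — social AND (laser OR cs)
- pain mirror       — social AND laser AND NOT cs
- fear mirror       — social AND cs AND NOT laser
- unselective       — social AND laser AND cs
- selective pain mirror — social AND laser AND (HighLaser > CS by rank-sum)

Over-representation of multi-condition responders is assessed with exact
binomial tail probabilities, and the channel- vs cell-level Venn
distributions are compared with a Pearson χ² over the 7 regions.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import logsumexp

from .synth import SpikeTrain, TrialSchedule
from .venn import REGIONS, VennCounts
from .windows import (
    BASELINE_WINDOW,
    SDF_BASELINE_WINDOW,
    SDF_SPAN,
    response_window,
)

# --------------------------------------------------------------------------
# spike counts

def count_spikes(
    spike_times: np.ndarray,
    onsets: np.ndarray,
    window: tuple[float, float],
) -> np.ndarray:
    """Per-trial spike counts in a peri-onset window, half-open [start, end)."""
    t = np.sort(np.asarray(spike_times, float))
    onsets = np.asarray(onsets, float)
    if len(onsets) > 1:
        span = window[1] - window[0]
        if np.any(np.diff(np.sort(onsets)) < span):
            raise ValueError("overlapping trial windows")
    lo = np.searchsorted(t, onsets + window[0], side="left")
    hi = np.searchsorted(t, onsets + window[1], side="left")
    return (hi - lo).astype(int)


@dataclass
class CellStats:
    """Per-cell count vectors and contrast p values across sessions."""

    unit_id: str
    counts: dict[tuple[str, str, str], np.ndarray]  # (session, condition, window)
    p_values: dict[str, float] = field(default_factory=dict)

    def counts_of(self, session: str, condition: str, which: str = "response"):
        return self.counts[(session, condition, which)]


def cell_counts(
    train: SpikeTrain, schedule: TrialSchedule
) -> dict[tuple[str, str, str], np.ndarray]:
    """Baseline and response count vectors for every condition of a session."""
    win = response_window(schedule.session_id)
    out = {}
    for cond in pd.unique(schedule.conditions):
        onsets = schedule.onsets_for(cond)
        out[(schedule.session_id, cond, "baseline")] = count_spikes(
            train.times, onsets, BASELINE_WINDOW
        )
        out[(schedule.session_id, cond, "response")] = count_spikes(
            train.times, onsets, win
        )
    return out


# --------------------------------------------------------------------------
# nonparametric tests

def wilcoxon_response(
    baseline: np.ndarray, response: np.ndarray, alternative: str = "greater"
) -> float:
    """One-tailed Wilcoxon signed-rank p for response > baseline.

    Exact null distribution for n < 25 (ties handled by mid-ranks inside
    the exact permutation distribution); normal approximation for larger
    n. All-zero differences carry no evidence: p = 1.
    """
    b = np.asarray(baseline, float)
    r = np.asarray(response, float)
    if len(b) != len(r) or len(b) < 5:
        raise ValueError("need paired vectors of length >= 5")
    d = r - b
    nz = d[d != 0]
    if len(nz) == 0:
        return 1.0
    method = "exact" if len(nz) < 25 else "approx"
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = stats.wilcoxon(r, b, alternative=alternative, method=method)
    return float(res.pvalue)


def ranksum_greater(a: np.ndarray, b: np.ndarray) -> float:
    """One-tailed Wilcoxon rank-sum p for a > b (unpaired).

    Computed as the equivalent Mann-Whitney U test with mid-rank tie
    correction (spike counts tie heavily).
    """
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return float(stats.mannwhitneyu(a, b, alternative="greater").pvalue)


# --------------------------------------------------------------------------
# taxonomy

CELL_CONTRASTS = (
    "HighShockObs>Baseline",
    "HighLaser>Baseline",
    "CS>Baseline",
    "HighShockObs>CtrlShockObs",
    "HighLaser>CtrlLaser",
    "HighLaser>CS",
)


def cell_stats(
    train_by_session: dict[str, SpikeTrain],
    schedules: dict[str, TrialSchedule],
) -> CellStats:
    """All count vectors and contrast p values for one tracked cell.

    Baseline contrasts use the signed-rank test; condition contrasts
    (High vs Ctrl, and HighLaser vs CS response counts) use the rank-sum
    test. CS is tested against baseline only, to remain sensitive to any
    salient sound.
    """
    counts: dict[tuple[str, str, str], np.ndarray] = {}
    uid = None
    for sess, train in train_by_session.items():
        uid = train.unit_id
        counts.update(cell_counts(train, schedules[sess]))
    p = {}
    p["HighShockObs>Baseline"] = wilcoxon_response(
        counts[("ShockObs", "High", "baseline")], counts[("ShockObs", "High", "response")]
    )
    p["HighLaser>Baseline"] = wilcoxon_response(
        counts[("Laser", "High", "baseline")], counts[("Laser", "High", "response")]
    )
    p["CS>Baseline"] = wilcoxon_response(
        counts[("CS", "CS", "baseline")], counts[("CS", "CS", "response")]
    )
    p["HighShockObs>CtrlShockObs"] = ranksum_greater(
        counts[("ShockObs", "High", "response")], counts[("ShockObs", "Ctrl", "response")]
    )
    p["HighLaser>CtrlLaser"] = ranksum_greater(
        counts[("Laser", "High", "response")], counts[("Laser", "Ctrl", "response")]
    )
    p["HighLaser>CS"] = ranksum_greater(
        counts[("Laser", "High", "response")], counts[("CS", "CS", "response")]
    )
    return CellStats(unit_id=uid, counts=counts, p_values=p)


def classify_cells(
    all_stats: list[CellStats], alpha: float = 0.05
) -> tuple[pd.DataFrame, VennCounts]:
    """Taxonomy flags per cell and the Venn counts over responsive cells."""
    rows = []
    for cs in all_stats:
        p = cs.p_values
        missing = [c for c in CELL_CONTRASTS if c not in p]
        if missing:
            raise ValueError(f"{cs.unit_id}: missing contrasts {missing}")
        responsive = (
            p["HighShockObs>Baseline"] < alpha
            or p["HighLaser>Baseline"] < alpha
            or p["CS>Baseline"] < alpha
        )
        social = responsive and p["HighShockObs>CtrlShockObs"] < alpha
        laser = responsive and p["HighLaser>CtrlLaser"] < alpha
        cs_flag = responsive and p["CS>Baseline"] < alpha
        mirror = social and (laser or cs_flag)
        rows.append(
            {
                "unit_id": cs.unit_id,
                "responsive": responsive,
                "social": social,
                "laser": laser,
                "cs": cs_flag,
                "mirror": mirror,
                "pain_mirror": social and laser and not cs_flag,
                "fear_mirror": social and cs_flag and not laser,
                "unselective_mirror": social and laser and cs_flag,
                "selective_pain_mirror": social and laser and p["HighLaser>CS"] < alpha,
            }
        )
    taxonomy = pd.DataFrame(rows)
    counts = VennCounts.from_flags(
        taxonomy["social"], taxonomy["laser"], taxonomy["cs"], taxonomy["responsive"]
    )
    return taxonomy, counts


def assigned_profiles(taxonomy: pd.DataFrame) -> pd.Series:
    """Single class label per cell from its taxonomy flags.

    Mirror subclasses take precedence (unselective > pain > fear), then the
    single-condition classes, else nonresponsive. This is the mapping used
    to score recovery of a known synthetic composition.
    """

    def one(row):
        if row["unselective_mirror"]:
            return "unselective_mirror"
        if row["pain_mirror"]:
            return "pain_mirror"
        if row["fear_mirror"]:
            return "fear_mirror"
        if row["social"]:
            return "social_only"
        if row["laser"]:
            return "laser_only"
        if row["cs"]:
            return "cs_only"
        return "nonresponsive"

    return taxonomy.set_index("unit_id").apply(one, axis=1)


# --------------------------------------------------------------------------
# over-representation and Venn comparison

def binomial_overrep(k: int, n: int, p0: float) -> float:
    """Exact upper-tail binomial probability P(X ≥ k | n, p0).

    Summed in log space (logsumexp over the tail log-pmf) so extreme tails
    (e.g. < 1e-14) remain accurate.
    """
    if not 0 <= k <= n:
        raise ValueError("need 0 <= k <= n")
    if not 0 < p0 < 1:
        raise ValueError("need 0 < p0 < 1")
    if k == 0:
        return 1.0
    ks = np.arange(k, n + 1)
    return float(np.exp(logsumexp(stats.binom.logpmf(ks, n, p0))))


def venn_chi2(counts_a: VennCounts, counts_b: VennCounts) -> tuple[float, int, float]:
    """Pearson χ² comparing two Venn-region distributions (2×7 table).

    Expected counts come from the pooled region proportions. Regions empty
    in both groups are dropped with the degrees of freedom reduced.
    """
    a, b = counts_a.as_vector(), counts_b.as_vector()
    keep = (a + b) > 0
    dropped = [r for r, k in zip(REGIONS, keep) if not k]
    if dropped:
        warnings.warn(f"dropping empty Venn regions: {dropped}", stacklevel=2)
    table = np.vstack([a[keep], b[keep]])
    chi2, p, dof, _ = stats.chi2_contingency(table, correction=False)
    return float(chi2), int(dof), float(p)


# --------------------------------------------------------------------------
# spike-density functions

@dataclass
class SdfProfile:
    """Normalized spike-density traces of one cell.

    ``traces[condition]`` is the trial-averaged, baseline-subtracted rate
    on ``times``; all conditions are divided by the single cross-condition
    maximum taken within the experimental windows, so a value of 1 marks
    the cell's maximum firing rate across conditions. ``normalized`` is
    False when the cell fired nowhere (zero max — normalization skipped).
    """

    unit_id: str
    times: np.ndarray
    traces: dict[str, np.ndarray]
    baseline_offsets: dict[str, float]
    norm_constant: float
    normalized: bool


def _sdf_kernels(dt: float, tau_ms: float = 200.0, sigma_ms: float = 50.0):
    tau, sigma = tau_ms / 1000.0, sigma_ms / 1000.0
    t_exp = np.arange(0.0, 5 * tau, dt)
    k_exp = np.exp(-t_exp / tau)
    k_exp /= k_exp.sum() * dt
    t_g = np.arange(-4 * sigma, 4 * sigma + dt / 2, dt)
    k_g = np.exp(-0.5 * (t_g / sigma) ** 2)
    k_g /= k_g.sum() * dt
    return k_exp, k_g, len(t_g) // 2


def spike_density_trace(
    spike_times: np.ndarray,
    onsets: np.ndarray,
    span: tuple[float, float] = SDF_SPAN,
    dt: float = 0.001,
    tau_ms: float = 200.0,
    sigma_ms: float = 50.0,
) -> tuple[np.ndarray, np.ndarray]:
    """Trial-averaged smoothed firing rate (Hz) on a peri-onset grid.

    Spikes are binned at ``dt``, averaged over trials, and convolved with a
    causal exponential kernel (τ = 200 ms) then a Gaussian (σ = 50 ms);
    both kernels have unit area so spike count is conserved.
    """
    if len(onsets) < 1:
        raise ValueError("need at least one trial")
    k_exp, k_g, g_half = _sdf_kernels(dt, tau_ms, sigma_ms)
    pad = (len(k_exp) + len(k_g)) * dt
    edges = np.arange(span[0] - pad, span[1] + pad + dt / 2, dt)
    acc = np.zeros(len(edges) - 1)
    t = np.sort(np.asarray(spike_times, float))
    for onset in onsets:
        acc += np.histogram(t - onset, bins=edges)[0]
    rate = acc / (len(onsets) * dt)
    # causal exponential: output at i from inputs <= i
    sm = np.convolve(rate, k_exp * dt, mode="full")[: len(rate)]
    # zero-lag Gaussian
    sm = np.convolve(sm, k_g * dt, mode="full")[g_half : g_half + len(rate)]
    centers = (edges[:-1] + edges[1:]) / 2
    m = (centers >= span[0]) & (centers < span[1])
    return centers[m], sm[m]


def spike_density(
    train: SpikeTrain,
    schedule: TrialSchedule,
    conditions: list[str] | None = None,
    dt: float = 0.001,
) -> SdfProfile:
    """Per-condition normalized SDF for one cell in one session."""
    conditions = conditions or list(pd.unique(schedule.conditions))
    win = response_window(schedule.session_id)
    times = None
    raw, offsets = {}, {}
    for cond in conditions:
        onsets = schedule.onsets_for(cond)
        times, tr = spike_density_trace(train.times, onsets, dt=dt)
        base = (times >= SDF_BASELINE_WINDOW[0]) & (times < SDF_BASELINE_WINDOW[1])
        offsets[cond] = float(tr[base].mean())
        raw[cond] = tr - offsets[cond]
    in_win = (times >= win[0]) & (times < win[1])
    norm = max((tr[in_win].max() for tr in raw.values()), default=0.0)
    normalized = norm > 0
    traces = {c: (tr / norm if normalized else tr) for c, tr in raw.items()}
    return SdfProfile(
        unit_id=train.unit_id,
        times=times,
        traces=traces,
        baseline_offsets=offsets,
        norm_constant=float(norm),
        normalized=normalized,
    )


def normalize_across_sessions(profiles: dict[str, SdfProfile]) -> dict[str, SdfProfile]:
    """Re-normalize one cell's per-session profiles by the single maximum
    across all sessions' experimental windows."""
    norm = max(p.norm_constant for p in profiles.values())
    if norm <= 0:
        return profiles
    out = {}
    for sess, p in profiles.items():
        scale = p.norm_constant / norm if p.normalized else 1.0 / norm
        out[sess] = SdfProfile(
            unit_id=p.unit_id,
            times=p.times,
            traces={c: tr * scale for c, tr in p.traces.items()},
            baseline_offsets=p.baseline_offsets,
            norm_constant=norm,
            normalized=True,
        )
    return out


def population_sdf(
    profiles: list[SdfProfile], condition: str
) -> tuple[np.ndarray, np.ndarray, np.ndarray | None]:
    """Pointwise mean ± SEM of normalized SDFs over a cell population.

    With fewer than 2 cells the SEM is undefined and returned as None.
    """
    if not profiles:
        raise ValueError("empty population")
    stack = np.vstack([p.traces[condition] for p in profiles])
    mean = stack.mean(axis=0)
    sem = stats.sem(stack, axis=0) if len(profiles) >= 2 else None
    return profiles[0].times, mean, sem
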