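"""Cross-session single-unit identity cleanup.

A unit isolated in the shock-observation session defines a reference mean
waveform; spikes recorded in the other sessions are accepted as the same
cell only if they survive, in order: (1) a waveform-correlation filter
(Pearson r with the reference ≥ 0.85), (2) a peak-amplitude filter (within
±15% of the reference peak), and (3) a session-level baseline firing-rate
ratio filter (≤ 8, computed *after* steps 1–2 removed spikes). Sessions
with a firing rate below 0.06 Hz are dropped entirely. All boundary values
are kept — the removal rules are strict inequalities ("lower than",
"beyond", "higher than") — and every removal is recorded in an audit trail
so input counts always reconcile with kept + removed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

MIN_WAVEFORM_CORR = 0.85
AMPLITUDE_TOL = 0.15
MAX_RATE_RATIO = 8.0
MIN_RATE_HZ = 0.06


@dataclass
class UnitSessionRecord:
    """One unit's data in one session."""

    unit_id: str
    session_id: str
    spike_times: np.ndarray
    waveforms: np.ndarray  # n_spikes × n_samples, row-aligned with spike_times
    session_duration: float
    baseline_period: tuple[float, float] | None = None

    def __post_init__(self):
        self.spike_times = np.asarray(self.spike_times, float)
        self.waveforms = np.atleast_2d(np.asarray(self.waveforms, float))
        if len(self.spike_times) != len(self.waveforms):
            raise ValueError("spike_times and waveforms must align row-for-row")

    @property
    def n_spikes(self) -> int:
        return len(self.spike_times)

    def firing_rate(self) -> float:
        """Whole-session mean rate (Hz)."""
        return self.n_spikes / self.session_duration

    def baseline_rate(self) -> float:
        if self.baseline_period is None:
            return self.firing_rate()
        t0, t1 = self.baseline_period
        n = np.sum((self.spike_times >= t0) & (self.spike_times < t1))
        return float(n) / (t1 - t0)


@dataclass
class FilterResult:
    kept: np.ndarray  # boolean mask over input spikes
    reasons: np.ndarray  # per-spike removal reason ("" = kept)

    @property
    def n_kept(self) -> int:
        return int(self.kept.sum())

    @property
    def n_removed(self) -> int:
        return int((~self.kept).sum())


def _pearson_rows(snippets: np.ndarray, reference: np.ndarray) -> np.ndarray:
    """Row-wise Pearson correlation with the reference; NaN for
    zero-variance rows."""
    x = snippets - snippets.mean(axis=1, keepdims=True)
    r = reference - reference.mean()
    denom = np.linalg.norm(x, axis=1) * np.linalg.norm(r)
    with np.errstate(invalid="ignore", divide="ignore"):
        out = (x @ r) / denom
    out[denom == 0] = np.nan
    return out


def waveform_corr_filter(
    snippets: np.ndarray, reference: np.ndarray, min_r: float = MIN_WAVEFORM_CORR
) -> FilterResult:
    """Keep spikes whose waveform correlates with the reference at r ≥ min_r.

    Zero-variance snippets cannot be correlated and are removed with
    reason "degenerate".
    """
    snippets = np.atleast_2d(np.asarray(snippets, float))
    reference = np.asarray(reference, float)
    if snippets.shape[1] != len(reference) or len(reference) < 3:
        raise ValueError("snippet length must equal reference length >= 3")
    r = _pearson_rows(snippets, reference)
    reasons = np.full(len(snippets), "", dtype=object)
    reasons[np.isnan(r)] = "degenerate"
    reasons[(~np.isnan(r)) & (r < min_r)] = "correlation"
    return FilterResult(kept=reasons == "", reasons=reasons)


def amplitude_filter(
    snippets: np.ndarray, reference: np.ndarray, tol: float = AMPLITUDE_TOL
) -> FilterResult:
    """Keep spikes with peak |amplitude| within ±tol of the reference peak.

    Peak = max absolute value (peak polarity is not assumed); the
    boundaries (1−tol, 1+tol) are kept.
    """
    snippets = np.atleast_2d(np.asarray(snippets, float))
    ref_peak = np.max(np.abs(np.asarray(reference, float)))
    if ref_peak == 0:
        raise ValueError("zero reference peak amplitude")
    ratio = np.max(np.abs(snippets), axis=1) / ref_peak
    keep = (ratio >= 1.0 - tol) & (ratio <= 1.0 + tol)
    reasons = np.where(keep, "", "amplitude").astype(object)
    return FilterResult(kept=keep, reasons=reasons)


def rate_ratio_filter(
    rate_shock: float, rate_other: float, max_ratio: float = MAX_RATE_RATIO
) -> bool:
    """Keep (True) iff the symmetric rate ratio is ≤ max_ratio.

    Symmetric: max(a/b, b/a), so drift in either direction is excluded.
    A zero rate on one side with a nonzero other is an infinite ratio
    (removed); both zero is degenerate (removed).
    """
    if rate_shock < 0 or rate_other < 0:
        raise ValueError("rates must be >= 0")
    if rate_shock == 0 and rate_other == 0:
        return False
    if rate_shock == 0 or rate_other == 0:
        return False
    ratio = max(rate_shock / rate_other, rate_other / rate_shock)
    return ratio <= max_ratio


def min_rate_filter(rate: float, min_hz: float = MIN_RATE_HZ) -> bool:
    """Keep (True) iff rate ≥ min_hz (the boundary is kept)."""
    if rate < 0:
        raise ValueError("rate must be >= 0")
    return rate >= min_hz


@dataclass
class TrackingResult:
    """Kept per-session records plus the removal audit trail."""

    kept: dict[tuple[str, str], UnitSessionRecord]  # (unit, session) -> record
    audit: pd.DataFrame  # unit_id, session_id, stage, n_removed, reason

    def sessions_kept(self, unit_id: str) -> list[str]:
        return [s for (u, s) in self.kept if u == unit_id]


def track_units(
    records: list[UnitSessionRecord],
    min_r: float = MIN_WAVEFORM_CORR,
    amp_tol: float = AMPLITUDE_TOL,
    max_ratio: float = MAX_RATE_RATIO,
    min_rate_hz: float = MIN_RATE_HZ,
    reference_session: str = "ShockObs",
) -> TrackingResult:
    """Apply the cleanup to every unit across its sessions, in order.

    The reference waveform is the mean snippet of the unit's
    ``reference_session`` record (which must exist). Spike-level filters
    (correlation, then amplitude on the survivors) run on the non-reference
    sessions; the rate-ratio test compares the reference-session baseline
    rate against each other session's baseline rate computed from the
    spikes that survived steps 1–2; finally any session (including the
    reference) below the minimum whole-session rate is dropped.
    """
    by_unit: dict[str, list[UnitSessionRecord]] = {}
    for rec in records:
        by_unit.setdefault(rec.unit_id, []).append(rec)

    kept: dict[tuple[str, str], UnitSessionRecord] = {}
    audit_rows = []

    def log(u, s, stage, n, reason):
        audit_rows.append((u, s, stage, int(n), reason))

    for unit_id, recs in by_unit.items():
        ref_rec = next((r for r in recs if r.session_id == reference_session), None)
        if ref_rec is None:
            raise ValueError(f"unit {unit_id}: no {reference_session} session")
        reference = ref_rec.waveforms.mean(axis=0)
        surviving: dict[str, UnitSessionRecord] = {reference_session: ref_rec}

        for rec in recs:
            if rec.session_id == reference_session:
                continue
            res1 = waveform_corr_filter(rec.waveforms, reference, min_r)
            for reason in ("correlation", "degenerate"):
                n = np.sum(res1.reasons == reason)
                if n:
                    log(unit_id, rec.session_id, "waveform_corr", n, reason)
            wf = rec.waveforms[res1.kept]
            times = rec.spike_times[res1.kept]
            if len(wf):
                res2 = amplitude_filter(wf, reference, amp_tol)
                if res2.n_removed:
                    log(unit_id, rec.session_id, "amplitude", res2.n_removed, "amplitude")
                wf, times = wf[res2.kept], times[res2.kept]
            surviving[rec.session_id] = UnitSessionRecord(
                unit_id,
                rec.session_id,
                times,
                wf if len(wf) else np.empty((0, rec.waveforms.shape[1])),
                rec.session_duration,
                rec.baseline_period,
            )

        ref_base = surviving[reference_session].baseline_rate()
        for sess, rec in list(surviving.items()):
            if sess != reference_session and not rate_ratio_filter(
                ref_base, rec.baseline_rate(), max_ratio
            ):
                log(unit_id, sess, "rate_ratio", rec.n_spikes, "rate_ratio")
                del surviving[sess]
        for sess, rec in list(surviving.items()):
            if not min_rate_filter(rec.firing_rate(), min_rate_hz):
                log(unit_id, sess, "min_rate", rec.n_spikes, "min_rate")
                del surviving[sess]

        for sess, rec in surviving.items():
            kept[(unit_id, sess)] = rec

    audit = pd.DataFrame(
        audit_rows, columns=["unit_id", "session_id", "stage", "n_removed", "reason"]
    )
    return TrackingResult(kept=kept, audit=audit)
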