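"""Canonical analysis epochs shared by the MUA and single-cell stages.

All statistics in this package are computed on spike counts or z-scored
MUA integrated over 1 s windows. The baseline window always directly
precedes stimulus onset; the response window starts at onset for the
shock-observation and conditioned-sound sessions and is delayed by
300 ms for the laser session, whose nociceptive input travels on
slower-conducting (unmyelinated) fibers.
"""

from __future__ import annotations

SESSION_TYPES = ("ShockObs", "Laser", "CS")

#: (start, end) in seconds relative to stimulus onset; length 1 s everywhere
#: so no condition is favored by a longer integration window.
BASELINE_WINDOW = (-1.2, -0.2)

RESPONSE_WINDOWS = {
    "ShockObs": (0.0, 1.0),
    "CS": (0.0, 1.0),
    "Laser": (0.3, 1.3),
}

#: Epoch span for MUA trial extraction.
EPOCH_SPAN = (-2.0, 3.0)

#: z-scoring reference: mean/SD of this many seconds before onset.
Z_REFERENCE_SECONDS = 3.0

#: SDF grid and baseline-removal window for spike-density functions.
SDF_SPAN = (-2.2, 3.0)
SDF_BASELINE_WINDOW = (-2.2, -1.2)


def response_window(session_id: str) -> tuple[float, float]:
    """Response window for a session type; raises on unknown sessions."""
    try:
        return RESPONSE_WINDOWS[session_id]
    except KeyError:
        raise ValueError(f"unknown session type: {session_id!r}") from None
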