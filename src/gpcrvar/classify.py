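"""Gain/loss-of-function calls from WT-vs-variant distance shifts.

The classifier encodes the activation geometry of the heterodimeric
receptor: on activation the TM6 helices of the two subunits come together
(the active-state TM6/TM6 interface) while TM5 helices move apart, and the
TM4 helices also separate.  A variant whose simulations shift TM6 closer
and TM5 apart relative to wild type is therefore called GAIN_OF_FUNCTION;
the opposite pattern is LOSS_OF_FUNCTION.  TM4 separation corroborates a
gain call but is never decisive.

Venus-fly-trap-domain (VFTD) evidence — how far the LB1–LB2 lobe distance
has moved from the open (inactive, ~41.5 Å) toward the closed (active,
~34.5 Å) reference separation — is reported alongside and flagged when it
contradicts the TM call, but the TM helix distances take precedence: they
are the more reliable criterion for activity alterations at the trajectory
lengths this analysis targets.

Significance of a distance shift uses an effect-size rule rather than a
frame-wise hypothesis test: trajectory frames are strongly autocorrelated,
so a shift counts only when |Δ| ≥ max(min_effect_A, k·pooled_sd).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from .errors import EvidenceError, PairingError, ParameterError
from .geometry import DistanceSeries

__all__ = [
    "ReferenceDistances",
    "DistanceShift",
    "VftdEvidence",
    "StateCall",
    "compare_distance_series",
    "vftd_closure_index",
    "classify_variant",
    "GAIN_OF_FUNCTION",
    "LOSS_OF_FUNCTION",
    "INDETERMINATE",
]

GAIN_OF_FUNCTION = "GAIN_OF_FUNCTION"
LOSS_OF_FUNCTION = "LOSS_OF_FUNCTION"
INDETERMINATE = "INDETERMINATE"


@dataclass(frozen=True)
class ReferenceDistances:
    """Reference LB1–LB2 lobe separations of the GB1 VFTD, in Å.

    The defaults are the midpoints of the simulated ranges (active 34–35 Å,
    inactive 41–42 Å); the literature cryo-EM values (33 / 41 Å) are kept
    for reference.
    """

    vftd_active: float = 34.5
    vftd_inactive: float = 41.5
    literature_active: float = 33.0
    literature_inactive: float = 41.0

    def __post_init__(self) -> None:
        if not self.vftd_inactive > self.vftd_active:
            raise ParameterError("vftd_inactive must exceed vftd_active")


@dataclass(frozen=True)
class DistanceShift:
    """Mean separation change of one segment pair, variant minus WT."""

    pair_label: str
    wt_mean: float
    var_mean: float
    delta: float
    pooled_sd: float
    significant: bool


@dataclass(frozen=True)
class VftdEvidence:
    shift: DistanceShift
    closure_index_wt: float
    closure_index_var: float


@dataclass
class StateCall:
    call: str
    tm_evidence: list[DistanceShift]
    vftd_evidence: VftdEvidence | None
    concordant: bool

    def to_json(self, path: str | Path, extra: dict | None = None) -> None:
        doc = {
            "call": self.call,
            "concordant": self.concordant,
            "tm_evidence": [vars(s) for s in self.tm_evidence],
            "vftd_evidence": None
            if self.vftd_evidence is None
            else {
                "shift": vars(self.vftd_evidence.shift),
                "closure_index_wt": self.vftd_evidence.closure_index_wt,
                "closure_index_var": self.vftd_evidence.closure_index_var,
            },
            "note": (
                "Calls describe conformational bias in simulation; in-cell "
                "efficacy additionally depends on surface expression and "
                "adaptation, which this analysis does not model."
            ),
        }
        if extra:
            doc.update(extra)
        Path(path).write_text(json.dumps(doc, indent=2))


def _equilibrated(series: DistanceSeries, fraction: float) -> np.ndarray:
    n = series.n_frames
    start = int(np.floor(n * fraction))
    if start >= n:
        start = n - 1
    return series.filtered[start:]


def compare_distance_series(
    wt: DistanceSeries,
    var: DistanceSeries,
    min_effect_A: float = 1.0,
    k: float = 2.0,
    equilibration_fraction: float = 0.1,
) -> DistanceShift:
    """Mean shift (variant − WT) of a segment-pair distance.

    Means are taken over the Gaussian-filtered series after discarding an
    initial equilibration fraction of frames.  The shift is significant iff
    |Δ| ≥ max(min_effect_A, k · pooled_sd).
    """
    if set(wt.pair_label) != set(var.pair_label):
        raise PairingError(
            f"cannot compare pairs {wt.pair_label} and {var.pair_label}"
        )
    if not (0 <= equilibration_fraction < 1):
        raise ParameterError("equilibration_fraction must be in [0, 1)")
    a = _equilibrated(wt, equilibration_fraction)
    b = _equilibrated(var, equilibration_fraction)
    wt_mean = float(np.mean(a))
    var_mean = float(np.mean(b))
    delta = var_mean - wt_mean
    sd_a = float(np.std(a, ddof=1)) if len(a) > 1 else 0.0
    sd_b = float(np.std(b, ddof=1)) if len(b) > 1 else 0.0
    pooled = float(np.sqrt((sd_a**2 + sd_b**2) / 2.0))
    significant = abs(delta) >= max(min_effect_A, k * pooled)
    return DistanceShift(
        pair_label="-".join(sorted(set(wt.pair_label))) if isinstance(wt.pair_label, tuple) else str(wt.pair_label),
        wt_mean=wt_mean,
        var_mean=var_mean,
        delta=delta,
        pooled_sd=pooled,
        significant=significant,
    )


def vftd_closure_index(
    series: DistanceSeries, refs: ReferenceDistances = ReferenceDistances()
) -> float:
    """Where the lobe separation sits between the open and closed references.

    0 at the inactive (open) reference, 1 at the active (closed) reference,
    deliberately unclamped so over-closure or over-opening is visible.
    """
    span = refs.vftd_inactive - refs.vftd_active
    if span == 0:
        raise ParameterError("reference span is zero")
    return (refs.vftd_inactive - series.mean_filtered) / span


def _find(shifts: Sequence[DistanceShift], tag: str) -> DistanceShift | None:
    for s in shifts:
        if tag.upper() in s.pair_label.upper():
            return s
    return None


def classify_variant(
    tm_shifts: Sequence[DistanceShift],
    vftd: VftdEvidence | None = None,
    refs: ReferenceDistances = ReferenceDistances(),
) -> StateCall:
    """Call gain/loss-of-function from TM4/TM5/TM6 distance shifts.

    GAIN requires a significant TM6 decrease together with a significant
    TM5 increase; LOSS the mirror pattern; anything else is INDETERMINATE.
    TM4 separation corroborates a gain (TM4 helices move apart during
    activation) but never decides the call.  VFTD evidence is reported and
    flagged discordant when it opposes the TM call, never overriding it.
    """
    tm6 = _find(tm_shifts, "TM6")
    if tm6 is None:
        raise EvidenceError("classification requires the TM6 pair shift")
    tm5 = _find(tm_shifts, "TM5")
    call = INDETERMINATE
    if tm5 is not None:
        if tm6.significant and tm6.delta < 0 and tm5.significant and tm5.delta > 0:
            call = GAIN_OF_FUNCTION
        elif tm6.significant and tm6.delta > 0 and tm5.significant and tm5.delta < 0:
            call = LOSS_OF_FUNCTION

    concordant = True
    if vftd is not None and call != INDETERMINATE:
        # VFTD supports GAIN when the variant lobes are more closed than WT
        vftd_direction = np.sign(vftd.shift.delta)
        if call == GAIN_OF_FUNCTION and vftd_direction > 0:
            concordant = False
        if call == LOSS_OF_FUNCTION and vftd_direction < 0:
            concordant = False
    return StateCall(
        call=call,
        tm_evidence=list(tm_shifts),
        vftd_evidence=vftd,
        concordant=concordant,
    )
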