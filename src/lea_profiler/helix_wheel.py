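"""Helical-wheel amphipathicity analysis and a hydropathy TMH scan.

An ideal alpha-helix advances 100 degrees per residue around the wheel, so an
11-residue window covers just over three turns.  The hydrophobic moment is
the Eisenberg vector sum of per-residue hydrophobicities at their wheel
angles, normalised by window length - the HeliQuest convention, computed on
the Fauchere-Pliska octanol scale by default.  A large moment relative to the
mean hydrophobicity marks an amphipathic helix; a window presenting separate
hydrophobic, positive and negative arcs is flagged as an A-type helix.

The transmembrane-candidate scan is a deliberately simple hydropathy
heuristic: windows of ~19 residues with mean Kyte-Doolittle hydropathy above
1.6, the classic signature of a bilayer-spanning helix.  It is a screening
aid, not a topology predictor.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

from lea_profiler.physchem import KYTE_DOOLITTLE, HydropathyScale, net_formal_charge

#: Fauchere-Pliska octanol-water transfer free energies (kcal/mol).
FAUCHERE_PLISKA_VALUES = {
    "A": 0.31, "R": -1.01, "N": -0.60, "D": -0.77, "C": 1.54,
    "Q": -0.22, "E": -0.64, "G": 0.00, "H": 0.13, "I": 1.80,
    "L": 1.70, "K": -0.99, "M": 1.23, "F": 1.79, "P": 0.72,
    "S": -0.04, "T": 0.26, "W": 2.25, "Y": 0.96, "V": 1.22,
}
FAUCHERE_PLISKA = HydropathyScale("Fauchere-Pliska", FAUCHERE_PLISKA_VALUES)

HYDROPHOBIC_FACE_RESIDUES = frozenset("AVLIMFWC")
POSITIVE_RESIDUES = frozenset("KR")
NEGATIVE_RESIDUES = frozenset("DE")

MIN_WHEEL_WINDOW = 6
MAX_WHEEL_WINDOW = 54


@dataclass(frozen=True)
class FaceSegment:
    """A maximal contiguous arc of same-kind residues on the wheel."""

    kind: str  # "hydrophobic" | "positive" | "negative"
    member_indices: tuple[int, ...]  # window indices, in wheel order
    arc_span: float  # degrees


@dataclass(frozen=True)
class HelixWindow:
    residues: str
    delta: float
    mu_h: float
    mean_h: float
    z: int
    positions: tuple[float, ...]  # per-residue wheel angle, degrees mod 360
    start: int = 0  # 0-based offset within the parent sequence


def hydrophobic_moment(
    window: str,
    scale: HydropathyScale = FAUCHERE_PLISKA,
    delta: float = 100.0,
) -> float:
    """Eisenberg hydrophobic moment magnitude, normalised by window length.

    mu_H = | sum_n H_n (cos n*delta, sin n*delta) | / N.
    """
    if not window:
        raise ValueError("window must be non-empty")
    step = math.radians(delta)
    x = sum(scale[ch] * math.cos(n * step) for n, ch in enumerate(window))
    y = sum(scale[ch] * math.sin(n * step) for n, ch in enumerate(window))
    return math.hypot(x, y) / len(window)


def _faces(window: str, delta: float) -> list[FaceSegment]:
    """Maximal contiguous arcs of hydrophobic / positive / negative residues,
    contiguity taken in wheel-angle order (circular)."""
    n = len(window)
    order = sorted(range(n), key=lambda i: ((i * delta) % 360.0, i))
    kinds = {
        "hydrophobic": HYDROPHOBIC_FACE_RESIDUES,
        "positive": POSITIVE_RESIDUES,
        "negative": NEGATIVE_RESIDUES,
    }
    faces: list[FaceSegment] = []
    for kind, members in kinds.items():
        mask = [window[i] in members for i in order]
        if all(mask):
            faces.append(FaceSegment(kind, tuple(order), 360.0))
            continue
        runs: list[list[int]] = []
        # walk the circle starting just after a non-member so runs never wrap-split
        offset = mask.index(False)
        current: list[int] = []
        for k in range(n):
            idx = (offset + 1 + k) % n
            if mask[idx]:
                current.append(order[idx])
            elif current:
                runs.append(current)
                current = []
        if current:
            runs.append(current)
        for run in runs:
            # run is stored in circular wheel order, so the span is the
            # angle from first to last member walking forwards (handles
            # arcs that cross 0 degrees)
            first = (run[0] * delta) % 360.0
            last = (run[-1] * delta) % 360.0
            span = 0.0 if len(run) == 1 else (last - first) % 360.0
            faces.append(FaceSegment(kind, tuple(run), span))
    return faces


def wheel_and_faces(
    window: str,
    scale: HydropathyScale = FAUCHERE_PLISKA,
    delta: float = 100.0,
) -> tuple[HelixWindow, list[FaceSegment]]:
    """Helical-wheel assignment plus face segmentation for one window."""
    if not (MIN_WHEEL_WINDOW <= len(window) <= MAX_WHEEL_WINDOW):
        raise ValueError(
            f"window length {len(window)} outside [{MIN_WHEEL_WINDOW}, {MAX_WHEEL_WINDOW}]"
        )
    wheel = HelixWindow(
        residues=window,
        delta=delta,
        mu_h=hydrophobic_moment(window, scale, delta),
        mean_h=sum(scale[ch] for ch in window) / len(window),
        z=net_formal_charge(window),
        positions=tuple((n * delta) % 360.0 for n in range(len(window))),
    )
    return wheel, _faces(window, delta)


def is_a_type(faces: list[FaceSegment]) -> bool:
    """A-type helix: hydrophobic, positive and negative faces all present."""
    kinds = {f.kind for f in faces}
    return {"hydrophobic", "positive", "negative"} <= kinds


def scan_best_window(
    sequence: str,
    width: int = 11,
    scale: HydropathyScale = FAUCHERE_PLISKA,
    delta: float = 100.0,
) -> HelixWindow:
    """The ``width``-residue window maximising mu_H; ties -> smallest start."""
    if len(sequence) < width:
        raise ValueError("sequence shorter than window width")
    best_start, best_mu = 0, -1.0
    for start in range(len(sequence) - width + 1):
        mu = hydrophobic_moment(sequence[start : start + width], scale, delta)
        if mu > best_mu:
            best_start, best_mu = start, mu
    window = sequence[best_start : best_start + width]
    wheel, _ = wheel_and_faces(window, scale, delta)
    return HelixWindow(
        residues=wheel.residues, delta=wheel.delta, mu_h=wheel.mu_h,
        mean_h=wheel.mean_h, z=wheel.z, positions=wheel.positions, start=best_start,
    )


def tmh_candidate_scan(
    sequence: str,
    width: int = 19,
    min_mean_kd: float = 1.6,
    scale: HydropathyScale = KYTE_DOOLITTLE,
) -> list[tuple[int, int, float]]:
    """Non-overlapping hydrophobic windows that could span a bilayer.

    All ``width``-windows with mean hydropathy >= ``min_mean_kd`` are
    candidates; they are accepted greedily by descending mean (ties by
    smaller start), discarding overlaps.  Returns 0-based half-open
    ``(start, end, mean)`` tuples sorted by start.
    """
    if width > len(sequence):
        raise ValueError("width longer than sequence")
    candidates = []
    for start in range(len(sequence) - width + 1):
        mean = sum(scale[ch] for ch in sequence[start : start + width]) / width
        if mean >= min_mean_kd:
            candidates.append((start, start + width, mean))
    chosen: list[tuple[int, int, float]] = []
    for start, end, mean in sorted(candidates, key=lambda c: (-c[2], c[0])):
        if all(end <= s or start >= e for s, e, _ in chosen):
            chosen.append((start, end, mean))
    return sorted(chosen)
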