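"""Geometric beta-turn detection and typing from backbone dihedrals.

A four-residue window i..i+3 is a beta-turn when Ca(i)-Ca(i+3) <= 0.7 nm
and the two central residues are not part of a helix.  Types are assigned
by the nearest ideal-angle template in the Hutchinson-Thornton convention:

    I   : (-60, -30) / (-90,   0)
    I'  : ( 60,  30) / ( 90,   0)
    II  : (-60, 120) / ( 80,   0)
    II' : ( 60,-120) / (-80,   0)

with a tolerance of +/-30 degrees per angle, one angle allowed +/-45.
Windows inside the Ca threshold that match no template are type IV/other.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .builder import Conformation, measure_dihedrals
from .geometry import wrap_deg

logger = logging.getLogger(__name__)

__all__ = [
    "TurnCall",
    "IDEAL_TEMPLATES",
    "detect_turns_structural",
    "ensemble_turn_consensus",
    "chirality_consistency",
]

IDEAL_TEMPLATES = {
    "I": ((-60.0, -30.0), (-90.0, 0.0)),
    "I_prime": ((60.0, 30.0), (90.0, 0.0)),
    "II": ((-60.0, 120.0), (80.0, 0.0)),
    "II_prime": ((60.0, -120.0), (-80.0, 0.0)),
}

CA_THRESHOLD_NM = 0.7
ANGLE_TOL = 30.0
ANGLE_TOL_ONE = 45.0
HELIX_CENTER = (-60.0, -45.0)
HELIX_TOL = 30.0


@dataclass(frozen=True)
class TurnCall:
    start: int
    end: int
    ca_distance: float  # nm, Ca(i)-Ca(i+3)
    dihedrals: tuple  # ((phi, psi) at i+1, (phi, psi) at i+2)
    turn_type: str  # {"I", "I_prime", "II", "II_prime", "IV/other", "none"}


def _match_template(d1, d2):
    """Nearest template whose four angle deviations fit the tolerance."""
    best, best_dev = None, None
    for name, (t1, t2) in IDEAL_TEMPLATES.items():
        devs = [
            abs(wrap_deg(d1[0] - t1[0])), abs(wrap_deg(d1[1] - t1[1])),
            abs(wrap_deg(d2[0] - t2[0])), abs(wrap_deg(d2[1] - t2[1])),
        ]
        over = [d for d in devs if d > ANGLE_TOL]
        if len(over) > 1 or (over and over[0] > ANGLE_TOL_ONE):
            continue
        score = sum(d ** 2 for d in devs)
        if best_dev is None or score < best_dev:
            best, best_dev = name, score
    return best or "IV/other"


def _is_helical(phi, psi):
    return (abs(wrap_deg(phi - HELIX_CENTER[0])) <= HELIX_TOL
            and abs(wrap_deg(psi - HELIX_CENTER[1])) <= HELIX_TOL)


def detect_turns_structural(conf: Conformation,
                            ca_threshold: float = CA_THRESHOLD_NM) -> list:
    """Scan all 4-residue windows for chain reversals and type them.

    Windows spanning chain breaks (missing backbone) are skipped with a
    logged notice.  A window whose central residues sit inside a >=4-residue
    helical run is rejected as helix, not a turn.
    """
    seq = conf.sequence
    dihedrals = {r: (phi, psi) for r, phi, psi, _ in measure_dihedrals(conf)}

    helical = {
        r for r, (phi, psi) in dihedrals.items()
        if phi is not None and psi is not None and _is_helical(phi, psi)
    }
    in_helix = set()
    run = []
    for r in sorted(helical) + [None]:
        if run and (r is None or r != run[-1] + 1):
            if len(run) >= 4:
                in_helix.update(run)
            run = []
        if r is not None:
            run.append(r)

    calls = []
    for start in range(seq.start, seq.end - 2):
        end = start + 3
        try:
            ca_i = conf.coord[conf.atom_index(start, "CA")]
            ca_j = conf.coord[conf.atom_index(end, "CA")]
        except KeyError:
            logger.info("window %d-%d spans a chain break; skipped", start, end)
            continue
        d1, d2 = dihedrals.get(start + 1), dihedrals.get(start + 2)
        if d1 is None or d2 is None or None in d1 or None in d2:
            logger.info("window %d-%d lacks central dihedrals; skipped", start, end)
            continue
        dist = float(np.linalg.norm(ca_i - ca_j))
        if dist > ca_threshold:
            continue
        if (start + 1) in in_helix and (start + 2) in in_helix:
            continue
        calls.append(TurnCall(start, end, dist, (d1, d2), _match_template(d1, d2)))
    return calls


def ensemble_turn_consensus(ensemble, min_fraction: float = 0.6) -> list:
    """Consensus turn calls across an ensemble of conformations.

    A window is called when at least ``min_fraction`` of the snapshots
    contain a turn there; the type is decided by plurality.  Ties are
    reported as ``indeterminate(a|b)``.  Returns (TurnCall, fraction) pairs
    where the call carries the mean Ca distance and circular-mean dihedrals.
    """
    snapshots = getattr(ensemble, "snapshots", ensemble)
    if len(snapshots) == 0:
        return []
    per_window: dict = {}
    for snap in snapshots:
        for call in detect_turns_structural(snap):
            per_window.setdefault((call.start, call.end), []).append(call)
    out = []
    for (start, end), calls in sorted(per_window.items()):
        fraction = len(calls) / len(snapshots)
        if fraction < min_fraction:
            continue
        votes: dict = {}
        for c in calls:
            votes[c.turn_type] = votes.get(c.turn_type, 0) + 1
        top = max(votes.values())
        winners = sorted(t for t, v in votes.items() if v == top)
        turn_type = winners[0] if len(winners) == 1 else (
            "indeterminate(" + "|".join(winners) + ")"
        )
        mean_ca = float(np.mean([c.ca_distance for c in calls]))

        def circ_mean(vals):
            ang = np.radians(vals)
            return float(np.degrees(np.arctan2(np.mean(np.sin(ang)),
                                               np.mean(np.cos(ang)))))

        d1 = tuple(circ_mean([c.dihedrals[0][k] for c in calls]) for k in (0, 1))
        d2 = tuple(circ_mean([c.dihedrals[1][k] for c in calls]) for k in (0, 1))
        out.append((TurnCall(start, end, mean_ca, (d1, d2), turn_type), fraction))
    return out


def chirality_consistency(call: TurnCall, conf: Conformation) -> str:
    """'warn' when a II' call puts an L-amino acid (not Gly) at i+1.

    The i+1 position of a type II' turn requires a positive phi, which is
    strained for L-residues; D-Pro and Gly accommodate it naturally.
    """
    if call.turn_type != "II_prime":
        return "pass"
    code = conf.sequence.code(call.start + 1)
    chir = conf.sequence.chirality(call.start + 1)
    if chir == "L" and code != "GLY":
        return "warn"
    return "pass"
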