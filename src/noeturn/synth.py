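"""Ground-truth generators: planted-turn conformers, back-calculated NOESY
crosspeaks and synthetic shift tables, plus the bundled assignment/NOE
fixtures for the two designed amyloid-beta peptides.

The forward model mirrors the analysis assumptions: a proton pair closer
than the observability cutoff (default 0.5 nm, the restraint accepted
range) yields a crosspeak whose intensity class is binned by distance
(<=0.27 strong, <=0.33 medium, else weak), and each peak is independently
dropped with a configurable false-negative rate.  No relaxation-matrix or
lineshape physics is implied.
"""
from __future__ import annotations

import importlib.resources
import logging
import warnings
from dataclasses import dataclass
from typing import NamedTuple

import numpy as np

from .builder import CapSpec, Conformation, build_extended, set_torsions
from .noe import NoePeak, NoeSet
from .sequences import (PROLINE_CODES, Sequence, ab21_43_sequence,
                        ab42_sequence, parse_sequence)
from .shifts import RandomCoilTable, ShiftRecord, ShiftTable, load_random_coil, parse_shift_table
from .turns import IDEAL_TEMPLATES

logger = logging.getLogger(__name__)

__all__ = [
    "TurnSpec",
    "ObservableSpec",
    "make_turn_peptide",
    "back_calculate_noes",
    "simulate_shift_table",
    "fixture_paper",
    "PaperFixture",
]


@dataclass(frozen=True)
class TurnSpec:
    start: int
    turn_type: str = "II_prime"  # {"I", "II_prime"} (any ideal template works)
    jitter: float = 0.0  # Gaussian sd on each set angle, degrees
    seed: int = 0

    def __post_init__(self):
        if self.jitter < 0:
            raise ValueError("angular jitter must be >= 0")
        if self.turn_type not in IDEAL_TEMPLATES:
            raise ValueError(f"unknown turn type {self.turn_type!r}")


@dataclass(frozen=True)
class ObservableSpec:
    noe_cutoff: float = 0.5  # nm
    false_negative_rate: float = 0.0
    shift_noise_sd: float = 0.0  # ppm
    seed: int = 0

    def __post_init__(self):
        if not 0.0 <= self.false_negative_rate <= 1.0:
            raise ValueError("false_negative_rate must be in [0, 1]")
        if self.noe_cutoff < 0:
            raise ValueError("noe_cutoff must be >= 0")


def make_turn_peptide(sequence, spec: TurnSpec, caps: CapSpec | None = None) -> Conformation:
    """Extended chain with ideal turn-template dihedrals planted at
    ``spec.start .. start+3`` (template angles at i+1 and i+2, plus jitter).

    Proline phi stays ring-pinned; a II' template with an L-residue (not
    Gly) at i+1 is geometrically strained and triggers a warning but is
    still built.
    """
    if isinstance(sequence, str):
        sequence = parse_sequence(sequence)
    if spec.start + 3 > sequence.end:
        raise ValueError(f"turn at {spec.start} runs past the sequence end")
    conf = build_extended(sequence, caps or CapSpec())
    rng = np.random.default_rng(spec.seed)
    (phi1, psi1), (phi2, psi2) = IDEAL_TEMPLATES[spec.turn_type]
    i1, i2 = spec.start + 1, spec.start + 2
    if spec.turn_type == "II_prime":
        code1 = sequence.code(i1)
        if sequence.chirality(i1) == "L" and code1 != "GLY":
            warnings.warn(
                f"II_prime turn with L-{code1} at position {i1}: "
                "positive phi is strained", stacklevel=2,
            )
    for res, phi, psi in ((i1, phi1, psi1), (i2, phi2, psi2)):
        j = rng.normal(0.0, spec.jitter, size=2) if spec.jitter else np.zeros(2)
        if sequence.code(res) in PROLINE_CODES:
            conf = set_torsions(conf, res, psi=psi + j[1])  # phi is ring-pinned
        else:
            conf = set_torsions(conf, res, phi=phi + j[0], psi=psi + j[1])
    return conf


def _proton_groups(conf: Conformation):
    """(residue, label) -> atom ids for the observable protons: HA, HN and
    the proline Hd group."""
    groups = []
    for res in conf.sequence.indices:
        code = conf.sequence.code(res)
        for label in ("HA", "HN") + (("HD",) if code in PROLINE_CODES else ()):
            try:
                ids = conf.resolve_protons(res, label)
            except KeyError:
                continue
            groups.append(((res, "HN" if label == "HN" else label), ids))
    return groups


def back_calculate_noes(conf: Conformation, spec: ObservableSpec) -> NoeSet:
    """Crosspeaks for every close Ha/HN/Hd proton-group pair.

    Group distances are r^-6 effective sums (so glycine Ha2/Ha3 and the two
    proline Hd protons act as one pseudo-atom, as they do spectrally).  Each
    contact gives two symmetric crosspeaks (one either side of the NOESY
    diagonal) and each crosspeak is dropped independently with
    ``false_negative_rate``; the contact is lost only when both are.
    """
    rng = np.random.default_rng(spec.seed)
    groups = _proton_groups(conf)
    peaks = []
    for a in range(len(groups)):
        (res_a, lab_a), ids_a = groups[a]
        for b in range(a + 1, len(groups)):
            (res_b, lab_b), ids_b = groups[b]
            d = conf.group_distance(ids_a, ids_b)
            if d > spec.noe_cutoff:
                continue
            if spec.false_negative_rate:
                lost_upper = rng.random() < spec.false_negative_rate
                lost_lower = rng.random() < spec.false_negative_rate
                if lost_upper and lost_lower:
                    continue
            cls = "strong" if d <= 0.27 else ("medium" if d <= 0.33 else "weak")
            peaks.append(NoePeak(res_a, lab_a, res_b, lab_b, cls))
    return NoeSet(peaks)


def simulate_shift_table(sequence, turns=(), spec: ObservableSpec | None = None,
                         peptide_id: str = "synthetic") -> ShiftTable:
    """Random-coil reference shifts + Gaussian noise + small systematic
    offsets (+0.05 ppm Ha at the two central turn residues).  Prolines get
    no NH record.  Deterministic for a fixed seed."""
    if isinstance(sequence, str):
        sequence = parse_sequence(sequence)
    spec = spec or ObservableSpec()
    rng = np.random.default_rng(spec.seed)
    ref = load_random_coil()
    offset = {}
    for t in turns:
        offset[t.start + 1] = offset.get(t.start + 1, 0.0) + 0.05
        offset[t.start + 2] = offset.get(t.start + 2, 0.0) + 0.05
    records = []
    for res in sequence.indices:
        code = sequence.code(res)
        for nuc in ("NH", "HA"):
            if nuc == "NH" and code in PROLINE_CODES:
                continue
            val = ref.reference(code, nuc)
            if nuc == "HA":
                val += offset.get(res, 0.0)
            if spec.shift_noise_sd:
                val += rng.normal(0.0, spec.shift_noise_sd)
            records.append(ShiftRecord(res, code, nuc, val))
    return ShiftTable(peptide_id, sequence, records)


class PaperFixture(NamedTuple):
    shifts_full: ShiftTable
    shifts_truncated: ShiftTable
    noes_full: NoeSet
    noes_truncated: NoeSet
    sequence_full: Sequence
    sequence_truncated: Sequence


def _data(name: str) -> str:
    return importlib.resources.files("noeturn.data").joinpath(name).read_text()


def fixture_paper() -> PaperFixture:
    """The bundled assignment tables and NOESY crosspeak enumerations for
    the full-length (1-42) and truncated (21-43) Nle35/D-Pro37 peptides."""
    seq_full, seq_trunc = ab42_sequence(), ab21_43_sequence()
    return PaperFixture(
        parse_shift_table(_data("shifts_ab42_nle35p37.tsv"), seq_full,
                          "Ab42Nle35p37"),
        parse_shift_table(_data("shifts_ab21_43_nle35p37.tsv"), seq_trunc,
                          "Ab21-43Nle35p37"),
        NoeSet.from_tsv(_data("noes_ab42_nle35p37.tsv")),
        NoeSet.from_tsv(_data("noes_ab21_43_nle35p37.tsv")),
        seq_full,
        seq_trunc,
    )
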