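"""Peptide sequences with paper-style numbering and non-standard residues.

Sequences are written in one-letter code with three-letter insertions in
braces for non-standard residues, e.g. ``"AEDVGSNKGAIIGL{NLE}V{DPR}GVVIAT"``.
A lowercase ``p`` is accepted as shorthand for D-proline (DPR).  Numbering
need not start at 1: the 21-43 fragment of the amyloid-beta mutant starts
at residue 21.
"""
from __future__ import annotations

from dataclasses import dataclass, field

ONE_TO_THREE = {
    "A": "ALA", "R": "ARG", "N": "ASN", "D": "ASP", "C": "CYS",
    "Q": "GLN", "E": "GLU", "G": "GLY", "H": "HIS", "I": "ILE",
    "L": "LEU", "K": "LYS", "M": "MET", "F": "PHE", "P": "PRO",
    "S": "SER", "T": "THR", "W": "TRP", "Y": "TYR", "V": "VAL",
}
THREE_TO_ONE = {v: k for k, v in ONE_TO_THREE.items()}
THREE_TO_ONE.update({"NLE": "J", "DPR": "p"})

SUPPORTED_CODES = frozenset(ONE_TO_THREE.values()) | {"NLE", "DPR"}
PROLINE_CODES = frozenset({"PRO", "DPR"})

#: the full-length designed mutant, residues 1-42 (Nle35, D-Pro37)
AB42_NLE35P37 = "DAEFRHDSGYEVHHQKLVFFAEDVGSNKGAIIGL{NLE}V{DPR}GVVIA"
#: the truncated construct, residues 21-43
AB21_43_NLE35P37 = "AEDVGSNKGAIIGL{NLE}V{DPR}GVVIAT"


class SequenceError(ValueError):
    pass


@dataclass(frozen=True)
class Sequence:
    """Residue codes with explicit (paper) numbering."""

    codes: tuple[str, ...]
    start: int = 1
    label: str = ""

    def __post_init__(self):
        for c in self.codes:
            if c not in SUPPORTED_CODES:
                raise SequenceError(
                    f"unsupported residue code {c!r}; supported: "
                    + ", ".join(sorted(SUPPORTED_CODES))
                )

    def __len__(self) -> int:
        return len(self.codes)

    @property
    def end(self) -> int:
        return self.start + len(self.codes) - 1

    @property
    def indices(self) -> range:
        return range(self.start, self.end + 1)

    def __contains__(self, res_index: int) -> bool:
        return self.start <= res_index <= self.end

    def code(self, res_index: int) -> str:
        if res_index not in self:
            raise SequenceError(
                f"residue {res_index} outside sequence range "
                f"{self.start}-{self.end}"
            )
        return self.codes[res_index - self.start]

    def is_proline(self, res_index: int) -> bool:
        return self.code(res_index) in PROLINE_CODES

    def chirality(self, res_index: int) -> str:
        code = self.code(res_index)
        if code == "GLY":
            return "achiral"
        return "D" if code == "DPR" else "L"

    def subsequence(self, start: int, end: int) -> "Sequence":
        """Inclusive residue-index window as a new Sequence."""
        if start not in self or end not in self or end < start:
            raise SequenceError(f"window {start}-{end} outside {self.start}-{self.end}")
        return Sequence(
            self.codes[start - self.start : end - self.start + 1], start, self.label
        )

    def __str__(self) -> str:
        out = []
        for c in self.codes:
            one = THREE_TO_ONE.get(c)
            out.append(one if one and c not in ("NLE", "DPR") else "{" + c + "}")
        return "".join(out)


def parse_sequence(text: str, start: int = 1, label: str = "") -> Sequence:
    """Parse a one-letter string with ``{XXX}`` escapes into a Sequence."""
    codes: list[str] = []
    i = 0
    while i < len(text):
        ch = text[i]
        if ch == "{":
            j = text.index("}", i)
            codes.append(text[i + 1 : j].upper())
            i = j + 1
        elif ch == "p":
            codes.append("DPR")
            i += 1
        elif ch.upper() in ONE_TO_THREE:
            codes.append(ONE_TO_THREE[ch.upper()])
            i += 1
        elif ch.isspace():
            i += 1
        else:
            raise SequenceError(f"cannot parse sequence character {ch!r} at {i}")
    return Sequence(tuple(codes), start, label)


def ab42_sequence() -> Sequence:
    return parse_sequence(AB42_NLE35P37, start=1, label="Ab42Nle35p37")


def ab21_43_sequence() -> Sequence:
    return parse_sequence(AB21_43_NLE35P37, start=21, label="Ab21-43Nle35p37")
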