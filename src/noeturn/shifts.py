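"""Chemical-shift assignment tables and secondary-shift (CSI-style) analysis.

Reads the wide assignment-table dialect used for the amyloid-beta mutant
peptides (columns ``Amino acid, NH, aH, bH, Others`` with Greek-letter
nucleus labels), normalises Greek labels to HA/HB/HG/HD/HE, and computes
random-coil-referenced secondary shifts.  A "1,405"-style decimal comma in a
cell (a typesetting artefact) is read as 1.405; commas between full decimal
numbers separate branch values.
"""
from __future__ import annotations

import importlib.resources
import re
from dataclasses import dataclass, field

from .sequences import ONE_TO_THREE, SUPPORTED_CODES, PROLINE_CODES, Sequence

__all__ = [
    "ShiftRecord",
    "ShiftTable",
    "RandomCoilTable",
    "ShiftParseError",
    "ShiftValidationError",
    "parse_shift_table",
    "parse_nmrstar_shifts",
    "load_random_coil",
    "secondary_shifts",
    "csi_segments",
    "write_shift_table",
    "write_long_tsv",
]

GREEK_TO_LATIN = {"α": "A", "β": "B", "γ": "G", "δ": "D", "ε": "E", "ζ": "Z", "η": "H"}
_LATIN_GREEK = {v: k for k, v in GREEK_TO_LATIN.items()}
_RES_CELL = re.compile(r"^([A-Za-z]{1,3})(\d+)$")
_SPECIAL_CODES = {"NL": "NLE", "DP": "DPR"}


class ShiftParseError(ValueError):
    pass


class ShiftValidationError(ValueError):
    pass


@dataclass(frozen=True, order=True)
class ShiftRecord:
    residue_index: int
    residue_code: str
    nucleus: str  # NH, HA, HB, HG, HD, HE with optional branch digit
    shift: float  # ppm

    def __post_init__(self):
        if not 0.0 < self.shift < 12.0:
            raise ShiftValidationError(
                f"proton shift {self.shift} ppm outside (0, 12) at "
                f"residue {self.residue_index} {self.nucleus}"
            )
        if self.residue_code == "DPR" and self.nucleus.startswith("NH"):
            raise ShiftValidationError(
                f"proline (residue {self.residue_index}) cannot carry an NH shift"
            )


@dataclass
class ShiftTable:
    peptide_id: str
    sequence: Sequence
    records: list = field(default_factory=list)

    def __post_init__(self):
        seen = set()
        last_index = None
        for rec in self.records:
            if rec.residue_index not in self.sequence:
                raise ShiftValidationError(
                    f"residue {rec.residue_index} not in sequence "
                    f"{self.sequence.start}-{self.sequence.end}"
                )
            if self.sequence.code(rec.residue_index) != rec.residue_code:
                raise ShiftValidationError(
                    f"residue {rec.residue_index} is "
                    f"{self.sequence.code(rec.residue_index)} in the sequence "
                    f"but {rec.residue_code} in the table"
                )
            key = (rec.residue_index, rec.nucleus)
            if key in seen:
                raise ShiftValidationError(f"duplicate shift entry for {key}")
            seen.add(key)
            if last_index is not None and rec.residue_index < last_index:
                raise ShiftValidationError("residue indices must be non-decreasing")
            last_index = rec.residue_index

    @property
    def residues(self) -> list:
        return sorted({r.residue_index for r in self.records})

    def get(self, residue_index: int, nucleus: str):
        for r in self.records:
            if r.residue_index == residue_index and r.nucleus == nucleus:
                return r.shift
        return None


class RandomCoilTable(dict):
    """(residue_code, nucleus) -> reference shift in ppm."""

    def reference(self, residue_code: str, nucleus: str) -> float:
        base = nucleus.rstrip("0123456789")
        for key in ((residue_code, nucleus), (residue_code, base)):
            if key in self:
                return self[key]
        raise ShiftValidationError(
            f"no random-coil reference for ({residue_code}, {nucleus})"
        )


# ---------------------------------------------------------------------------
# parsing


def _parse_residue_cell(cell: str, row_no: int):
    m = _RES_CELL.match(cell.strip())
    if not m:
        raise ShiftParseError(f"row {row_no}: cannot parse residue cell {cell!r}")
    letters, num = m.group(1), int(m.group(2))
    if letters.upper() in _SPECIAL_CODES:
        code = _SPECIAL_CODES[letters.upper()]
    elif len(letters) == 1 and letters.upper() in ONE_TO_THREE:
        code = ONE_TO_THREE[letters.upper()]
    elif letters.upper() in SUPPORTED_CODES:
        code = letters.upper()
    else:
        raise ShiftParseError(f"row {row_no}: unknown residue code {letters!r} in {cell!r}")
    return code, num


def _parse_values(text: str) -> list:
    """Numbers from a cell; '1,405' is a decimal comma, '1.9, 2.1' two values."""
    text = text.strip()
    if not text or text == "-":
        return []
    if re.fullmatch(r"\d+,\d+", text):
        return [float(text.replace(",", "."))]
    out = []
    for tok in text.split(","):
        tok = tok.strip()
        if not tok:
            continue
        try:
            out.append(float(tok))
        except ValueError as exc:
            raise ShiftParseError(f"cannot parse shift value {tok!r}") from exc
    return out


def _normalize_nucleus(label: str) -> str:
    label = label.strip()
    if label.upper() in ("NH", "HN"):
        return "NH"
    label = "".join(GREEK_TO_LATIN.get(ch, ch) for ch in label)
    label = label.upper()
    if label.endswith("H"):  # table dialect writes aH, bH, gH ...
        label = "H" + label[:-1]
    return label


_OTHERS_LABEL = re.compile(r"([αβγδεζη]H|NH)")


def _parse_others(cell: str):
    """Yield (nucleus, [values]) pairs from an 'Others' cell."""
    for group in cell.split(";"):
        group = group.strip()
        if not group or group == "-":
            continue
        labels = list(_OTHERS_LABEL.finditer(group))
        if not labels:
            raise ShiftParseError(f"cannot find a nucleus label in {group!r}")
        for k, m in enumerate(labels):
            end = labels[k + 1].start() if k + 1 < len(labels) else len(group)
            values = group[m.end():end].strip().rstrip(",").strip()
            yield _normalize_nucleus(m.group(1)), _parse_values(values)


def _emit(records, index, code, nucleus, values):
    if not values:
        return
    if len(values) == 1:
        records.append(ShiftRecord(index, code, nucleus, values[0]))
    else:
        for k, v in enumerate(values, start=1):
            records.append(ShiftRecord(index, code, f"{nucleus}{k}", v))


def parse_shift_table(text: str, sequence: Sequence, peptide_id: str = "") -> ShiftTable:
    """Parse a wide assignment table (header: Amino acid, NH, aH, bH, Others)."""
    lines = [
        ln for ln in text.splitlines() if ln.strip() and not ln.lstrip().startswith("#")
    ]
    if not lines:
        return ShiftTable(peptide_id, sequence, [])
    delim = "\t" if "\t" in lines[0] else ","
    header = [h.strip() for h in lines[0].split(delim)]
    if not header or "amino" not in header[0].lower():
        raise ShiftParseError(f"expected an 'Amino acid' header column, got {header!r}")
    nuclei = [_normalize_nucleus(h) for h in header[1:]]
    records: list = []
    for row_no, ln in enumerate(lines[1:], start=2):
        cells = [c.strip() for c in ln.split(delim)]
        if not cells[0]:
            continue
        code, index = _parse_residue_cell(cells[0], row_no)
        for nuc, cell in zip(nuclei, cells[1:]):
            if nuc == "HOTHERS" or nuc.startswith("HOTHER") or "OTHER" in nuc:
                for sub_nuc, values in _parse_others(cell):
                    _emit(records, index, code, sub_nuc, values)
            else:
                _emit(records, index, code, nuc, _parse_values(cell))
    return ShiftTable(peptide_id, sequence, records)


def parse_nmrstar_shifts(text: str, sequence: Sequence, peptide_id: str = "") -> ShiftTable:
    """Minimal NMR-STAR reader restricted to the _Atom_chem_shift loop."""
    lines = text.splitlines()
    tags: list = []
    rows: list = []
    in_loop = in_data = False
    for ln in lines:
        s = ln.strip()
        if s == "loop_":
            in_loop, in_data, tags = True, False, []
            continue
        if in_loop and s.startswith("_"):
            tags.append(s.split(".")[-1] if "." in s else s.lstrip("_"))
            continue
        if in_loop and s == "stop_":
            in_loop = in_data = False
            continue
        if in_loop and tags and s and not s.startswith("_"):
            in_data = True
            if any(t.lower() in ("val", "atom_id") for t in tags):
                rows.append(s.split())
    low = [t.lower() for t in tags] if tags else []
    records = []
    for row in rows:
        vals = dict(zip(low, row))
        try:
            idx = int(vals.get("seq_id") or vals.get("comp_index_id"))
            code = vals["comp_id"].upper()
            atom = vals["atom_id"].upper()
            val = float(vals["val"])
        except (KeyError, TypeError, ValueError) as exc:
            raise ShiftParseError(f"bad _Atom_chem_shift row {row!r}") from exc
        nucleus = "NH" if atom in ("H", "HN") else atom
        _emit(records, idx, code, nucleus, [val])
    return ShiftTable(peptide_id, sequence, records)


# ---------------------------------------------------------------------------
# random-coil reference and secondary shifts


def load_random_coil() -> RandomCoilTable:
    """Bundled Wishart-style random-coil 1H reference shifts."""
    text = (
        importlib.resources.files("noeturn.data")
        .joinpath("random_coil_1h.tsv")
        .read_text()
    )
    table = RandomCoilTable()
    for ln in text.splitlines():
        if not ln.strip() or ln.startswith("#") or ln.startswith("residue"):
            continue
        code, nuc, val = ln.split("\t")
        table[(code, nuc)] = float(val)
    return table


def secondary_shifts(table: ShiftTable, ref: RandomCoilTable | None = None,
                     nuclei=("HA", "NH")) -> list:
    """Observed minus random-coil shifts, per residue, for HA and NH.

    Residues absent from the table are omitted (never zero-filled).
    """
    ref = load_random_coil() if ref is None else ref
    out = []
    for rec in table.records:
        base = rec.nucleus.rstrip("0123456789")
        if base not in nuclei:
            continue
        delta = rec.shift - ref.reference(rec.residue_code, rec.nucleus)
        out.append((rec.residue_index, base, delta))
    return out


def csi_segments(deltas, threshold: float = 0.1, min_run: int = 4) -> list:
    """Chemical-shift-index style segments from HA secondary shifts.

    ``deltas`` is an iterable of (residue_index, delta) or
    (residue_index, nucleus, delta) restricted to HA.  A residue is labelled
    ``strand`` above +threshold, ``helix`` below -threshold, else ``coil``;
    only runs of >= ``min_run`` consecutive identically labelled non-coil
    residues are reported as (start, end, label) segments.
    """
    if min_run < 1:
        raise ValueError(f"min_run must be >= 1, got {min_run}")
    labelled = {}
    for item in deltas:
        if len(item) == 3:
            idx, nuc, d = item
            if nuc != "HA":
                continue
        else:
            idx, d = item
        labelled[idx] = "strand" if d > threshold else ("helix" if d < -threshold else "coil")
    segments = []
    run_start = run_label = prev = None
    for idx in sorted(labelled):
        lab = labelled[idx]
        if run_label == lab and prev is not None and idx == prev + 1:
            prev = idx
        else:
            if run_label in ("strand", "helix") and prev - run_start + 1 >= min_run:
                segments.append((run_start, prev, run_label))
            run_start, run_label, prev = idx, lab, idx
    if run_label in ("strand", "helix") and prev - run_start + 1 >= min_run:
        segments.append((run_start, prev, run_label))
    return segments


# ---------------------------------------------------------------------------
# writers


def _format_value(v: float) -> str:
    return f"{v:g}"


def write_shift_table(table: ShiftTable) -> str:
    """Serialise back to the wide dialect; re-parsing yields identical records."""
    from .sequences import THREE_TO_ONE

    rows = ["Amino acid\tNH\tαH\tβH\tOthers"]
    for idx in table.residues:
        code = table.sequence.code(idx)
        per: dict[str, list] = {}
        for rec in table.records:
            if rec.residue_index != idx:
                continue
            base = rec.nucleus.rstrip("0123456789")
            per.setdefault(base, []).append(rec.shift)
        one = {"NLE": "NL", "DPR": "dP"}.get(code, THREE_TO_ONE.get(code, code))
        cells = [f"{one}{idx}"]
        for nuc in ("NH", "HA", "HB"):
            cells.append(", ".join(_format_value(v) for v in per.pop(nuc, [])))
        others = []
        for nuc in sorted(per):
            label = _LATIN_GREEK.get(nuc[1], nuc[1]) + "H"
            others.append(label + " " + ", ".join(_format_value(v) for v in per[nuc]))
        cells.append("; ".join(others))
        rows.append("\t".join(cells).rstrip("\t"))
    return "\n".join(rows) + "\n"


def write_long_tsv(table: ShiftTable) -> str:
    """Normalised long format: peptide_id, residue_index, code, nucleus, ppm."""
    rows = ["peptide_id\tresidue_index\tresidue_code\tnucleus\tshift_ppm"]
    for rec in table.records:
        rows.append(
            f"{table.peptide_id}\t{rec.residue_index}\t{rec.residue_code}"
            f"\t{rec.nucleus}\t{rec.shift:g}"
        )
    return "\n".join(rows) + "\n"
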