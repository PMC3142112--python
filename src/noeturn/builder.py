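"""All-atom capped peptide construction in ideal internal coordinates.

Residue geometry (bond lengths, angles, in-residue torsions, connectivity,
elements) is taken from the chemical component dictionary bundled with
biotite and converted into a NeRF Z-matrix per residue type, rooted on the
backbone N-CA-C triad.  Chains are assembled residue by residue from backbone
torsions (phi, psi, omega); side chains ride rigidly in the local frame.
D-proline is generated as the exact mirror image of L-proline's internal
coordinates, so the two templates differ only in torsion signs.

Internally everything is in nm; the chemical component dictionary's Angstrom
coordinates are converted once at template-build time.
"""
from __future__ import annotations

import functools
from dataclasses import dataclass, field

import numpy as np
import biotite.structure as struc
import biotite.structure.info as struc_info

from .geometry import angle, dihedral, place_atom, rotate_about_axis, wrap_deg
from .sequences import PROLINE_CODES, SUPPORTED_CODES, Sequence, parse_sequence

__all__ = [
    "CapSpec",
    "Conformation",
    "BuildError",
    "build_extended",
    "build_chain",
    "set_torsions",
    "measure_dihedrals",
    "write_pdb",
    "read_pdb",
]

# ideal backbone geometry (Engh-Huber-like), nm and degrees
B_C_N = 0.1329
B_N_CA = 0.1458
B_CA_C = 0.1525
B_C_O = 0.1231
B_N_H = 0.1010
B_N_CH3 = 0.1449  # N-methyl cap
B_C_CH3 = 0.1505  # acetyl cap
A_CA_C_N = 116.2
A_C_N_CA = 121.7
A_N_CA_C = 111.0
A_CA_C_O = 120.8
A_C_N_H = 119.2

PHI_RING = {"PRO": -75.0, "DPR": 75.0}
DEFAULT_CHI1 = -60.0


class BuildError(ValueError):
    pass


@dataclass(frozen=True)
class CapSpec:
    """Terminal capping: neutral acetyl / N-methyl groups or free termini."""

    n_cap: str = "acetyl"  # {"acetyl", "none"}
    c_cap: str = "n_methyl"  # {"n_methyl", "none"}

    def __post_init__(self):
        if self.n_cap not in ("acetyl", "none"):
            raise BuildError(f"unknown n_cap {self.n_cap!r}")
        if self.c_cap not in ("n_methyl", "none"):
            raise BuildError(f"unknown c_cap {self.c_cap!r}")


# ---------------------------------------------------------------------------
# residue templates


@dataclass(frozen=True)
class _ZEntry:
    name: str
    p: str  # bonded parent
    g: str
    a: str
    bond: float  # nm
    angle: float  # deg
    torsion: float  # deg


@dataclass(frozen=True)
class _Template:
    code: str
    entries: tuple[_ZEntry, ...]  # side chain + HA etc., BFS order
    nterm_h: tuple[_ZEntry, ...]  # H (and H2) for a free N-terminus
    bonds: tuple[tuple[str, str], ...]  # in-residue bonds among kept atoms
    elements: dict
    atom_order: tuple[str, ...]  # heavy+H order for output


def _ccd_structure(code: str):
    arr = struc_info.residue(code)
    if arr is None:
        raise BuildError(f"no template for residue code {code!r}")
    return arr


@functools.lru_cache(maxsize=None)
def _template(code: str) -> _Template:
    """Z-matrix template for an amino-acid residue, rooted on N-CA-C."""
    if code == "DPR":
        return _mirror_template(_template("PRO"), "DPR")
    if code not in SUPPORTED_CODES:
        raise BuildError(
            f"unsupported residue code {code!r}; supported: "
            + ", ".join(sorted(SUPPORTED_CODES))
        )
    arr = _ccd_structure(code)
    names = list(arr.atom_name)
    coord = {n: arr.coord[i] * 0.1 for i, n in enumerate(names)}  # nm
    elements = {n: str(arr.element[i]).capitalize() for i, n in enumerate(names)}
    adj: dict[str, set[str]] = {n: set() for n in names}
    bl, _ = arr.bonds.get_all_bonds()
    for i, n in enumerate(names):
        for j in bl[i]:
            if j >= 0:
                adj[n].add(names[j])

    drop = {"OXT", "HXT"}
    if code in PROLINE_CODES:
        drop |= {"H", "H2"}  # ring nitrogen: amide/amine H never kept

    # BFS from CA; N- and C-attached atoms are handled specially elsewhere
    refparent = {"CA": "N", "N": "C"}
    entries: list[_ZEntry] = []
    placed = ["N", "CA", "C"]
    queue = ["CA"]
    seen = set(placed) | drop | {"O"}
    while queue:
        p = queue.pop(0)
        for x in sorted(adj[p]):
            if x in seen or x in ("N", "C", "O"):
                continue
            seen.add(x)
            g = refparent[p]
            a = refparent[g]
            entries.append(
                _ZEntry(
                    x,
                    p,
                    g,
                    a,
                    float(np.linalg.norm(coord[x] - coord[p])),
                    angle(coord[g], coord[p], coord[x]),
                    dihedral(coord[a], coord[g], coord[p], coord[x]),
                )
            )
            refparent[x] = p
            placed.append(x)
            queue.append(x)

    # default chi1: rotate everything on the CA-CB axis so the first gamma
    # heavy atom sits at -60 deg (skipped for the proline ring)
    if code not in PROLINE_CODES:
        gammas = [e for e in entries if e.p == "CB" and not e.name.startswith("H")]
        if gammas:
            delta = DEFAULT_CHI1 - gammas[0].torsion
            entries = [
                _ZEntry(e.name, e.p, e.g, e.a, e.bond, e.angle,
                        float(wrap_deg(e.torsion + delta))) if e.p == "CB" else e
                for e in entries
            ]

    # free N-terminus hydrogens (H, H2) referenced to the in-residue frame
    nterm = []
    for hname in ("H", "H2"):
        if hname in names and hname not in drop and hname in adj["N"]:
            nterm.append(
                _ZEntry(
                    hname, "N", "CA", "C",
                    float(np.linalg.norm(coord[hname] - coord["N"])),
                    angle(coord["CA"], coord["N"], coord[hname]),
                    dihedral(coord["C"], coord["CA"], coord["N"], coord[hname]),
                )
            )

    kept = {"N", "CA", "C", "O"} | {e.name for e in entries}
    bonds = []
    done = set()
    for n in names:
        if n not in kept:
            continue
        for m in adj[n]:
            if m in kept and (m, n) not in done:
                bonds.append((n, m))
                done.add((n, m))

    order = [n for n in names if n in kept]
    return _Template(code, tuple(entries), tuple(nterm), tuple(bonds), elements, tuple(order))


def _mirror_template(tmpl: _Template, code: str) -> _Template:
    flip = lambda e: _ZEntry(e.name, e.p, e.g, e.a, e.bond, e.angle, -e.torsion)
    return _Template(
        code,
        tuple(flip(e) for e in tmpl.entries),
        tuple(flip(e) for e in tmpl.nterm_h),
        tmpl.bonds,
        tmpl.elements,
        tmpl.atom_order,
    )


# ---------------------------------------------------------------------------
# the Conformation container


class Conformation:
    """All-atom coordinates of one capped peptide chain (nm).

    Array-of-fields layout like an AtomArray; ``res_index`` uses the paper's
    residue numbering, caps get ``start-1`` / ``end+1`` with codes ACE/NME.
    """

    def __init__(self, atom_name, res_index, res_code, element, coord, bonds,
                 sequence: Sequence):
        self.atom_name = np.asarray(atom_name, dtype="U6")
        self.res_index = np.asarray(res_index, dtype=int)
        self.res_code = np.asarray(res_code, dtype="U3")
        self.element = np.asarray(element, dtype="U2")
        self.coord = np.asarray(coord, dtype=float)
        self.bonds = np.asarray(bonds, dtype=int).reshape(-1, 2)
        self.sequence = sequence
        self._index = {
            (int(r), n): i
            for i, (r, n) in enumerate(zip(self.res_index, self.atom_name))
        }

    # -- bookkeeping -------------------------------------------------------
    def __len__(self) -> int:
        return len(self.atom_name)

    def copy(self) -> "Conformation":
        return Conformation(
            self.atom_name, self.res_index, self.res_code, self.element,
            self.coord.copy(), self.bonds, self.sequence,
        )

    @property
    def chirality(self) -> dict:
        return {i: self.sequence.chirality(i) for i in self.sequence.indices}

    def atom_index(self, res_index: int, atom_name: str) -> int:
        key = (int(res_index), atom_name)
        if key not in self._index:
            raise KeyError(f"no atom {atom_name} in residue {res_index}")
        return self._index[key]

    def has_atom(self, res_index: int, atom_name: str) -> bool:
        return (int(res_index), atom_name) in self._index

    def resolve_protons(self, res_index: int, label: str) -> list[int]:
        """Concrete atom ids for an NMR proton label (HN, HA, HB, HD...).

        Branch-ambiguous labels (e.g. HD on proline) resolve to every
        matching proton; distances to such groups are r^-6 effective sums.
        """
        label = label.upper()
        if label in ("HN", "NH", "H"):
            label = "H"
            if self.has_atom(res_index, "H"):
                return [self.atom_index(res_index, "H")]
            raise KeyError(f"residue {res_index} has no amide proton")
        hits = [
            i
            for i in np.nonzero(self.res_index == res_index)[0]
            if self.element[i] == "H"
            and (self.atom_name[i] == label
                 or (self.atom_name[i].startswith(label)
                     and self.atom_name[i][len(label):].isdigit()))
        ]
        if not hits:
            raise KeyError(f"no proton {label} in residue {res_index}")
        return [int(i) for i in hits]

    def distance(self, i: int, j: int) -> float:
        return float(np.linalg.norm(self.coord[i] - self.coord[j]))

    def group_distance(self, ids_i, ids_j) -> float:
        """Effective distance between proton groups: (sum r^-6)^(-1/6)."""
        d = np.linalg.norm(
            self.coord[np.asarray(ids_i)][:, None, :]
            - self.coord[np.asarray(ids_j)][None, :, :],
            axis=-1,
        )
        return float(np.sum(d ** -6.0) ** (-1.0 / 6.0))


# ---------------------------------------------------------------------------
# chain assembly


def build_extended(sequence, caps: CapSpec | None = None,
                   phi: float = -120.0, psi: float = 120.0) -> Conformation:
    """Build an extended-coil chain (phi, psi) = (-120, +120) throughout.

    Proline phi is pinned to its ring value (-75 for PRO, +75 for DPR).
    """
    if isinstance(sequence, str):
        sequence = parse_sequence(sequence)
    caps = caps or CapSpec()
    torsions = {}
    for i in sequence.indices:
        code = sequence.code(i)
        torsions[i] = (PHI_RING.get(code, phi), psi, 180.0)
    return build_chain(sequence, torsions, caps)


def build_chain(sequence: Sequence, torsions: dict, caps: CapSpec) -> Conformation:
    """Assemble a chain from per-residue (phi, psi, omega) torsions."""
    seq = sequence
    phi = {i: torsions[i][0] for i in seq.indices}
    psi = {i: torsions[i][1] for i in seq.indices}
    omega = {i: torsions[i][2] for i in seq.indices}
    for i in seq.indices:
        code = seq.code(i)
        if code in PROLINE_CODES:
            ring = PHI_RING[code]
            if abs(wrap_deg(phi[i] - ring)) > 15.0:
                phi[i] = ring  # pinned; build never strains the ring

    pos: dict[tuple[int, str], np.ndarray] = {}
    first, last = seq.start, seq.end
    ace, nme = caps.n_cap == "acetyl", caps.c_cap == "n_methyl"

    # ---- pass 1: backbone heavy atoms ------------------------------------
    if ace:
        pos[(first - 1, "CH3")] = np.zeros(3)
        pos[(first - 1, "C")] = np.array([B_C_CH3, 0.0, 0.0])
        prev = (first - 1, "CH3"), (first - 1, "C")
        a = np.radians(180.0 - A_CA_C_N)
        pos[(first, "N")] = pos[(first - 1, "C")] + B_C_N * np.array(
            [np.cos(a), np.sin(a), 0.0]
        )
        prev_n_torsion_ref = pos[(first - 1, "CH3")]
    else:
        pos[(first, "N")] = np.zeros(3)

    for i in seq.indices:
        if i == first and not ace:
            pos[(i, "CA")] = np.array([B_N_CA, 0.0, 0.0])
            a = np.radians(180.0 - A_N_CA_C)
            pos[(i, "C")] = pos[(i, "CA")] + B_CA_C * np.array(
                [np.cos(a), np.sin(a), 0.0]
            )
            continue
        if i == first:  # after ACE
            pos[(i, "CA")] = place_atom(
                prev_n_torsion_ref, pos[(first - 1, "C")], pos[(i, "N")],
                B_N_CA, A_C_N_CA, omega[i],
            )
        else:
            pos[(i, "N")] = place_atom(
                pos[(i - 1, "N")], pos[(i - 1, "CA")], pos[(i - 1, "C")],
                B_C_N, A_CA_C_N, psi[i - 1],
            )
            pos[(i, "CA")] = place_atom(
                pos[(i - 1, "CA")], pos[(i - 1, "C")], pos[(i, "N")],
                B_N_CA, A_C_N_CA, omega[i],
            )
        pos[(i, "C")] = place_atom(
            pos[(i - 1, "C")] if i > first else pos[(first - 1, "C")],
            pos[(i, "N")], pos[(i, "CA")],
            B_CA_C, A_N_CA_C, phi[i],
        )
    if nme:
        pos[(last + 1, "N")] = place_atom(
            pos[(last, "N")], pos[(last, "CA")], pos[(last, "C")],
            B_C_N, A_CA_C_N, psi[last],
        )
        pos[(last + 1, "C")] = place_atom(
            pos[(last, "CA")], pos[(last, "C")], pos[(last + 1, "N")],
            B_N_CH3, A_C_N_CA, 180.0,
        )

    # ---- pass 2: carbonyls, amide and side-chain atoms -------------------
    def psi_for_O(i):  # O is anti to the next amide nitrogen
        return wrap_deg(psi[i] - 180.0)

    if ace:
        pos[(first - 1, "O")] = place_atom(
            pos[(first, "N")], pos[(first - 1, "CH3")], pos[(first - 1, "C")],
            B_C_O, A_CA_C_O, 180.0,
        )
        for k, tau in zip(("H1", "H2", "H3"), (60.0, 180.0, 300.0)):
            pos[(first - 1, k)] = place_atom(
                pos[(first - 1, "O")], pos[(first - 1, "C")],
                pos[(first - 1, "CH3")], 0.1092, 109.5, tau,
            )

    for i in seq.indices:
        code = seq.code(i)
        tmpl = _template(code)
        n, ca, c = pos[(i, "N")], pos[(i, "CA")], pos[(i, "C")]
        pos[(i, "O")] = place_atom(n, ca, c, B_C_O, A_CA_C_O, psi_for_O(i))
        if code not in PROLINE_CODES:
            if i > first or ace:
                prev = i - 1
                pos[(i, "H")] = place_atom(
                    pos[(prev, "O")], pos[(prev, "C")], n, B_N_H, A_C_N_H, 180.0
                )
            else:
                for e in tmpl.nterm_h:
                    pos[(i, e.name)] = place_atom(c, ca, n, e.bond, e.angle, e.torsion)
        for e in tmpl.entries:
            pos[(i, e.name)] = place_atom(
                pos[(i, e.a)], pos[(i, e.g)], pos[(i, e.p)],
                e.bond, e.angle, e.torsion,
            )
        if i == last and not nme:  # carboxylate OXT in the carbonyl plane
            pos[(i, "OXT")] = place_atom(n, ca, c, 0.1249, 117.0, psi[i])

    if nme:
        pos[(last + 1, "H")] = place_atom(
            pos[(last, "O")], pos[(last, "C")], pos[(last + 1, "N")],
            B_N_H, A_C_N_H, 180.0,
        )
        for k, tau in zip(("H1", "H2", "H3"), (60.0, 180.0, 300.0)):
            pos[(last + 1, k)] = place_atom(
                pos[(last, "C")], pos[(last + 1, "N")], pos[(last + 1, "C")],
                0.1092, 109.5, tau,
            )

    # ---- assemble arrays and bonds ---------------------------------------
    names, resi, resc, elem, coords = [], [], [], [], []

    def emit(i, code, order):
        for nme_ in order:
            if (i, nme_) in pos:
                names.append(nme_)
                resi.append(i)
                resc.append(code)
                elem.append("H" if nme_.startswith("H") else nme_[0])
                coords.append(pos[(i, nme_)])

    if ace:
        emit(first - 1, "ACE", ("CH3", "C", "O", "H1", "H2", "H3"))
    for i in seq.indices:
        code = seq.code(i)
        tmpl = _template(code)
        order = ["N", "H", "H2", "CA"] + [
            x for x in tmpl.atom_order if x not in ("N", "CA", "C", "O", "H", "H2")
        ] + ["C", "O", "OXT"]
        emit(i, code, order)
    if nme:
        emit(last + 1, "NME", ("N", "H", "C", "H1", "H2", "H3"))

    conf = Conformation(names, resi, resc, elem, np.array(coords), np.zeros((0, 2)),
                        seq)
    bonds = []
    for i in seq.indices:
        tmpl = _template(seq.code(i))
        for a_, b_ in tmpl.bonds:
            if conf.has_atom(i, a_) and conf.has_atom(i, b_):
                bonds.append((conf.atom_index(i, a_), conf.atom_index(i, b_)))
        for h in ("H", "H2"):
            if conf.has_atom(i, h):
                bonds.append((conf.atom_index(i, "N"), conf.atom_index(i, h)))
        if conf.has_atom(i, "OXT"):
            bonds.append((conf.atom_index(i, "C"), conf.atom_index(i, "OXT")))
        if i > first:
            bonds.append((conf.atom_index(i - 1, "C"), conf.atom_index(i, "N")))
    if ace:
        a0 = first - 1
        for x, y in (("CH3", "C"), ("C", "O"), ("CH3", "H1"), ("CH3", "H2"),
                     ("CH3", "H3")):
            bonds.append((conf.atom_index(a0, x), conf.atom_index(a0, y)))
        bonds.append((conf.atom_index(a0, "C"), conf.atom_index(first, "N")))
    if nme:
        z = last + 1
        for x, y in (("N", "H"), ("N", "C"), ("C", "H1"), ("C", "H2"), ("C", "H3")):
            bonds.append((conf.atom_index(z, x), conf.atom_index(z, y)))
        bonds.append((conf.atom_index(last, "C"), conf.atom_index(z, "N")))
    conf.bonds = np.array(sorted(set(map(lambda t: tuple(sorted(t)), bonds))),
                          dtype=int).reshape(-1, 2)
    return conf


# ---------------------------------------------------------------------------
# torsion measurement and manipulation


def measure_dihedrals(conf: Conformation):
    """Backbone (phi, psi, omega) per residue; terminal caps count as
    neighbours, so capped chains have phi/psi defined everywhere.

    Returns a list of (res_index, phi, psi, omega); undefined angles are None.
    """
    out = []
    for i in conf.sequence.indices:
        for a in ("N", "CA", "C"):
            if not conf.has_atom(i, a):
                raise BuildError(f"missing backbone atom {a} in residue {i}")
        n, ca, c = (conf.coord[conf.atom_index(i, x)] for x in ("N", "CA", "C"))
        prev_c = conf.coord[conf.atom_index(i - 1, "C")] if conf.has_atom(i - 1, "C") else None
        prev_ca_name = "CH3" if conf.has_atom(i - 1, "CH3") else "CA"
        prev_ca = (
            conf.coord[conf.atom_index(i - 1, prev_ca_name)]
            if conf.has_atom(i - 1, prev_ca_name) else None
        )
        next_n = conf.coord[conf.atom_index(i + 1, "N")] if conf.has_atom(i + 1, "N") else None
        phi = dihedral(prev_c, n, ca, c) if prev_c is not None else None
        psi = dihedral(n, ca, c, next_n) if next_n is not None else None
        om = (
            dihedral(prev_ca, prev_c, n, ca)
            if prev_c is not None and prev_ca is not None else None
        )
        out.append((i, phi, psi, om))
    return out


def _moving_set(conf: Conformation, res_index: int, which: str) -> np.ndarray:
    """Atom ids that move when the torsion rotates (C-terminal side)."""
    code = conf.sequence.code(res_index)
    adj: dict[int, list[int]] = {}
    for a, b in conf.bonds:
        adj.setdefault(int(a), []).append(int(b))
        adj.setdefault(int(b), []).append(int(a))
    if which == "phi":
        i_ax0 = conf.atom_index(res_index, "N")
        i_ax1 = conf.atom_index(res_index, "CA")
        if code in PROLINE_CODES:
            # the ring pins phi; only the carbonyl side may swing a little
            start = conf.atom_index(res_index, "C")
            block = {conf.atom_index(res_index, "CA")}
        else:
            start, block = i_ax1, {i_ax0}
    elif which == "psi":
        i_ax0 = conf.atom_index(res_index, "CA")
        i_ax1 = conf.atom_index(res_index, "C")
        start, block = i_ax1, {i_ax0}
    else:
        raise BuildError(f"unknown torsion {which!r}")
    seen, queue = set(block) | {start}, [start]
    while queue:
        x = queue.pop()
        for y in adj.get(x, ()):
            if y not in seen:
                seen.add(y)
                queue.append(y)
    moving = np.array(sorted(seen - block - {i_ax1} if which == "phi" and code in PROLINE_CODES
                             else seen - block), dtype=int)
    # the axis atom itself never moves
    moving = moving[(moving != i_ax0) & (moving != i_ax1)]
    return moving, i_ax0, i_ax1


class TorsionConstraintError(ValueError):
    pass


def set_torsions(conf: Conformation, res_index: int,
                 phi: float | None = None, psi: float | None = None) -> Conformation:
    """Return a new conformation with the requested backbone dihedrals.

    The N-terminal side of the chain stays fixed; everything C-terminal of
    the rotated bond moves rigidly.  Proline phi is ring-pinned and may only
    move within +/-15 degrees of its template value.
    """
    new = conf.copy()
    code = conf.sequence.code(res_index)
    if phi is not None:
        if code in PROLINE_CODES and abs(wrap_deg(phi - PHI_RING[code])) > 15.0:
            raise TorsionConstraintError(
                f"{code} phi is ring-constrained near {PHI_RING[code]}; "
                f"requested {phi}"
            )
        _apply_torsion(new, res_index, "phi", phi)
    if psi is not None:
        _apply_torsion(new, res_index, "psi", psi)
    return new


def _current_torsion(conf, res_index, which):
    i = res_index
    if which == "phi":
        ids = [(i - 1, "C"), (i, "N"), (i, "CA"), (i, "C")]
    else:
        ids = [(i, "N"), (i, "CA"), (i, "C"), (i + 1, "N")]
    try:
        pts = [conf.coord[conf.atom_index(r, a)] for r, a in ids]
    except KeyError as exc:
        raise BuildError(f"torsion {which} undefined at residue {i}: {exc}")
    return dihedral(*pts)


def _apply_torsion(conf, res_index, which, target):
    current = _current_torsion(conf, res_index, which)
    delta = wrap_deg(target - current)
    if abs(delta) < 1e-9:
        return
    moving, ax0, ax1 = _moving_set(conf, res_index, which)
    axis = conf.coord[ax1] - conf.coord[ax0]
    conf.coord[moving] = rotate_about_axis(
        conf.coord[moving], conf.coord[ax1], axis, delta
    )


# ---------------------------------------------------------------------------
# PDB I/O (biotite; Angstrom at the boundary)


def _to_atom_array(conf: Conformation) -> struc.AtomArray:
    n = len(conf)
    arr = struc.AtomArray(n)
    arr.coord = conf.coord * 10.0
    arr.chain_id = np.full(n, "A")
    arr.res_id = conf.res_index
    arr.res_name = conf.res_code
    arr.atom_name = conf.atom_name
    arr.element = np.char.upper(conf.element)
    arr.hetero = np.isin(conf.res_code, ("ACE", "NME", "NLE", "DPR"))
    arr.set_annotation("occupancy", np.ones(n))
    return arr


def write_pdb(path, conformations) -> None:
    """Write one or more conformations as a (multi-MODEL) PDB file."""
    from biotite.structure.io.pdb import PDBFile

    if isinstance(conformations, Conformation):
        conformations = [conformations]
    template = _to_atom_array(conformations[0])
    stack = struc.stack([template] * len(conformations))
    stack.coord = np.array([c.coord * 10.0 for c in conformations])
    f = PDBFile()
    f.set_structure(stack)
    f.write(str(path))


def read_pdb(path, sequence: Sequence | None = None) -> list[Conformation]:
    """Read a (multi-MODEL) PDB written by this package back into
    Conformations.  Bond connectivity is rebuilt from residue templates."""
    from biotite.structure.io.pdb import PDBFile

    f = PDBFile.read(str(path))
    stack = f.get_structure(model=None)
    if stack.stack_depth() == 0:
        return []
    first = stack[0]
    mask = ~np.isin(first.res_name, ("HOH",))
    first = first[mask]
    if sequence is None:
        codes, idx = [], []
        for rid in np.unique(first.res_id):
            code = str(first.res_name[first.res_id == rid][0])
            if code in ("ACE", "NME"):
                continue
            codes.append(code)
            idx.append(int(rid))
        sequence = Sequence(tuple(codes), start=min(idx))
    caps = CapSpec(
        "acetyl" if "ACE" in first.res_name else "none",
        "n_methyl" if "NME" in first.res_name else "none",
    )
    ref = build_extended(sequence, caps)
    out = []
    for m in range(stack.stack_depth()):
        arr = stack[m][mask]
        conf = ref.copy()
        lookup = {
            (int(r), str(a)): k
            for k, (r, a) in enumerate(zip(arr.res_id, arr.atom_name))
        }
        for k in range(len(conf)):
            key = (int(conf.res_index[k]), str(conf.atom_name[k]))
            if key in lookup:
                conf.coord[k] = arr.coord[lookup[key]] * 0.1
        out.append(conf)
    return out
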