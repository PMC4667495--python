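"""Molecular data model, MDL SDF (V2000) I/O and geometry.

Units are fixed package-wide: coordinates and interatomic distances in
angstrom (A), charges in elementary-charge units. No unit conversion is
performed anywhere — published EEM parameter conventions assume angstrom.

Atom indices are 0-based in memory and 1-based in every file format, per
SDF convention.
"""

from __future__ import annotations

import io
import os
from dataclasses import dataclass, field
from typing import IO, Iterable, Iterator

import numpy as np
from scipy.spatial.distance import cdist

from .errors import DegenerateGeometryError, SDFParseError

# Elements recognized without complaint; anything else is still carried
# through (downstream coverage/solve decide applicability).
COMMON_ELEMENTS = frozenset(
    "H He Li Be B C N O F Ne Na Mg Al Si P S Cl Ar K Ca Fe Zn Se Br I".split())

#: default guard against near-coincident atoms (well below any bond length)
DEFAULT_MIN_DISTANCE = 0.5


@dataclass
class Atom:
    """One atom: identity, 3D position (A) and formal charge (e)."""

    index: int
    element: str
    position: np.ndarray
    formal_charge: int = 0

    def __post_init__(self) -> None:
        self.position = np.asarray(self.position, dtype=float)
        if self.position.shape != (3,):
            raise ValueError(f"atom {self.index}: position must be a 3-vector")
        if not np.all(np.isfinite(self.position)):
            raise ValueError(f"atom {self.index}: non-finite coordinates")
        if not self.element:
            raise ValueError(f"atom {self.index}: empty element symbol")


@dataclass(frozen=True)
class Bond:
    """Bond between atoms ``a`` and ``b`` with integer order 1-3.

    ``aromatic_flag`` records that the input encoded the bond as the SDF
    aromatic dialect (type 4); the stored order is then 2.
    """

    a: int
    b: int
    order: int
    aromatic_flag: bool = False

    def __post_init__(self) -> None:
        if self.a == self.b:
            raise ValueError(f"bond joins atom {self.a} to itself")
        if self.order not in (1, 2, 3):
            raise ValueError(f"bond order {self.order} outside {{1,2,3}}")
        if self.aromatic_flag and self.order != 2:
            raise ValueError("aromatic bonds must carry order 2")

    @property
    def pair(self) -> tuple[int, int]:
        return (self.a, self.b) if self.a < self.b else (self.b, self.a)


@dataclass
class Molecule:
    id: str
    atoms: list[Atom]
    bonds: list[Bond]
    total_charge: int = 0

    def __post_init__(self) -> None:
        n = len(self.atoms)
        seen: set[tuple[int, int]] = set()
        for bond in self.bonds:
            if not (0 <= bond.a < n and 0 <= bond.b < n):
                raise ValueError(
                    f"molecule {self.id!r}: bond ({bond.a},{bond.b}) "
                    f"references atoms outside 0..{n - 1}")
            if bond.pair in seen:
                raise ValueError(
                    f"molecule {self.id!r}: duplicate bond {bond.pair}")
            seen.add(bond.pair)

    @property
    def n_atoms(self) -> int:
        return len(self.atoms)

    def coordinates(self) -> np.ndarray:
        """(N, 3) array of positions in A."""
        return np.array([a.position for a in self.atoms], dtype=float)

    def elements(self) -> list[str]:
        return [a.element for a in self.atoms]


#: N x N symmetric matrix of interatomic distances (A), zero diagonal.
DistanceMatrix = np.ndarray


def distance_matrix(m: Molecule,
                    min_distance: float = DEFAULT_MIN_DISTANCE
                    ) -> DistanceMatrix:
    """All-pairs Euclidean distances in A.

    Raises :class:`DegenerateGeometryError` when any off-diagonal distance
    falls below ``min_distance``: such geometries produce near-singular EEM
    matrices and are refused early, naming the offending atom pair.
    """
    coords = m.coordinates()
    dist = cdist(coords, coords)
    np.fill_diagonal(dist, 0.0)
    if m.n_atoms > 1:
        off = dist + np.diag(np.full(m.n_atoms, np.inf))
        i, j = np.unravel_index(np.argmin(off), off.shape)
        if off[i, j] < min_distance:
            raise DegenerateGeometryError(m.id, int(i), int(j),
                                          float(off[i, j]), min_distance)
    return dist


# ---------------------------------------------------------------------------
# SDF (MDL V2000) reading
# ---------------------------------------------------------------------------

# legacy atom-block charge column: code -> formal charge (4 = radical)
_LEGACY_CHARGE = {0: 0, 1: 3, 2: 2, 3: 1, 4: 0, 5: -1, 6: -2, 7: -3}


def _open_text(source) -> tuple[IO[str], bool]:
    if isinstance(source, (str, os.PathLike)):
        return open(source, "r", encoding="utf-8"), True
    if isinstance(source, (bytes, bytearray)):
        return io.StringIO(source.decode("utf-8")), True
    return source, False


def iter_sdf_records(source) -> Iterator[tuple[int, int, list[str]]]:
    """Yield ``(ordinal, first_line_number, lines)`` per ``$$$$`` record.

    Ordinals and line numbers are 1-based. An unterminated trailing record
    (content after the last ``$$$$``) raises :class:`SDFParseError`.
    """
    stream, close = _open_text(source)
    try:
        ordinal = 0
        start = 1
        lines: list[str] = []
        lineno = 0
        for lineno, raw in enumerate(stream, start=1):
            line = raw.rstrip("\n").rstrip("\r")
            if line.strip() == "$$$$":
                ordinal += 1
                yield ordinal, start, lines
                lines = []
                start = lineno + 1
            else:
                lines.append(line)
        if any(line.strip() for line in lines):
            raise SDFParseError("unterminated SDF record (missing '$$$$')",
                                record=ordinal + 1, line=lineno)
    finally:
        if close:
            stream.close()


def _int_field(line: str, lo: int, hi: int, what: str, record: int,
               lineno: int) -> int:
    text = line[lo:hi].strip()
    try:
        return int(text)
    except ValueError:
        raise SDFParseError(f"cannot parse {what} from {text!r}",
                            record=record, line=lineno) from None


def _float_field(line: str, lo: int, hi: int, what: str, record: int,
                 lineno: int) -> float:
    text = line[lo:hi].strip()
    try:
        return float(text)
    except ValueError:
        raise SDFParseError(f"cannot parse {what} from {text!r}",
                            record=record, line=lineno) from None


def parse_sdf_record(lines: list[str], ordinal: int = 1,
                     first_line: int = 1) -> Molecule:
    """Parse one V2000 molfile record (without the ``$$$$`` terminator)."""
    if len(lines) < 4:
        raise SDFParseError("record shorter than the 4 header lines",
                            record=ordinal, line=first_line)
    title = lines[0].strip()
    counts_line = lines[3]
    counts_no = first_line + 3
    if "V3000" in counts_line:
        raise SDFParseError("V3000 records are not supported",
                            record=ordinal, line=counts_no)
    n_atoms = _int_field(counts_line, 0, 3, "atom count", ordinal, counts_no)
    n_bonds = _int_field(counts_line, 3, 6, "bond count", ordinal, counts_no)
    if n_atoms < 0 or n_bonds < 0:
        raise SDFParseError("negative counts", record=ordinal, line=counts_no)
    if len(lines) < 4 + n_atoms + n_bonds:
        raise SDFParseError(
            f"record truncated: expected {n_atoms} atom and {n_bonds} bond "
            f"lines", record=ordinal, line=first_line + len(lines) - 1)

    atoms: list[Atom] = []
    for k in range(n_atoms):
        line = lines[4 + k]
        lineno = first_line + 4 + k
        x = _float_field(line, 0, 10, "x coordinate", ordinal, lineno)
        y = _float_field(line, 10, 20, "y coordinate", ordinal, lineno)
        z = _float_field(line, 20, 30, "z coordinate", ordinal, lineno)
        symbol = line[31:34].strip()
        if not symbol:
            raise SDFParseError("empty element symbol",
                                record=ordinal, line=lineno)
        charge_code = 0
        if len(line) >= 39 and line[36:39].strip():
            charge_code = _int_field(line, 36, 39, "charge code",
                                     ordinal, lineno)
        charge = _LEGACY_CHARGE.get(charge_code, 0)
        atoms.append(Atom(index=k, element=symbol, position=(x, y, z),
                          formal_charge=charge))

    bonds: list[Bond] = []
    seen_pairs: set[tuple[int, int]] = set()
    for k in range(n_bonds):
        line = lines[4 + n_atoms + k]
        lineno = first_line + 4 + n_atoms + k
        a = _int_field(line, 0, 3, "bond atom index", ordinal, lineno)
        b = _int_field(line, 3, 6, "bond atom index", ordinal, lineno)
        t = _int_field(line, 6, 9, "bond type", ordinal, lineno)
        if not (1 <= a <= n_atoms and 1 <= b <= n_atoms) or a == b:
            raise SDFParseError(
                f"bond ({a},{b}) out of range for {n_atoms} atoms",
                record=ordinal, line=lineno)
        if t not in (1, 2, 3, 4):
            raise SDFParseError(f"bond type {t} outside {{1,2,3,4}}",
                                record=ordinal, line=lineno)
        # aromatic dialect: normalize to a double bond, remember the flag
        order, aromatic = (2, True) if t == 4 else (t, False)
        bond = Bond(a=a - 1, b=b - 1, order=order, aromatic_flag=aromatic)
        if bond.pair in seen_pairs:
            raise SDFParseError(f"duplicate bond between atoms {a} and {b}",
                                record=ordinal, line=lineno)
        seen_pairs.add(bond.pair)
        bonds.append(bond)

    # property block: "M  CHG" supersedes the atom-block charge column
    chg_seen = False
    for k, line in enumerate(lines[4 + n_atoms + n_bonds:]):
        lineno = first_line + 4 + n_atoms + n_bonds + k
        if line.startswith("M  END"):
            break
        if line.startswith("M  CHG"):
            if not chg_seen:
                for atom in atoms:
                    atom.formal_charge = 0
                chg_seen = True
            fields = line[9:].split()
            if len(fields) % 2:
                raise SDFParseError("odd number of fields on M  CHG line",
                                    record=ordinal, line=lineno)
            for idx_s, chg_s in zip(fields[::2], fields[1::2]):
                try:
                    idx, chg = int(idx_s), int(chg_s)
                except ValueError:
                    raise SDFParseError("non-integer M  CHG entry",
                                        record=ordinal, line=lineno) from None
                if not 1 <= idx <= n_atoms:
                    raise SDFParseError(
                        f"M  CHG atom index {idx} out of range",
                        record=ordinal, line=lineno)
                atoms[idx - 1].formal_charge = chg

    mol_id = title if title else f"record{ordinal}"
    total = sum(a.formal_charge for a in atoms)
    return Molecule(id=mol_id, atoms=atoms, bonds=bonds, total_charge=total)


def iter_sdf(source) -> Iterator[Molecule]:
    """Stream molecules from a multi-record SDF (path or text stream)."""
    for ordinal, start, lines in iter_sdf_records(source):
        yield parse_sdf_record(lines, ordinal, start)


def read_sdf(source) -> list[Molecule]:
    return list(iter_sdf(source))


# ---------------------------------------------------------------------------
# SDF writing (for fixtures and the synthetic generator)
# ---------------------------------------------------------------------------

def write_sdf(molecules: Iterable[Molecule], sink) -> None:
    """Write molecules as concatenated V2000 records.

    Coordinates are printed with 4 decimals (the V2000 field precision);
    aromatic-flagged bonds are emitted as type 4.
    """
    stream, close = (open(sink, "w", encoding="utf-8"), True) \
        if isinstance(sink, (str, os.PathLike)) else (sink, False)
    try:
        for m in molecules:
            stream.write(f"{m.id}\n  eemkit\n\n")
            stream.write(f"{m.n_atoms:3d}{len(m.bonds):3d}  0  0  0  0"
                         f"  0  0  0  0999 V2000\n")
            for a in m.atoms:
                x, y, z = a.position
                stream.write(f"{x:10.4f}{y:10.4f}{z:10.4f} {a.element:<3s}"
                             f" 0  0  0  0  0  0  0  0  0  0  0  0\n")
            for b in m.bonds:
                t = 4 if b.aromatic_flag else b.order
                stream.write(f"{b.a + 1:3d}{b.b + 1:3d}{t:3d}  0\n")
            charged = [(a.index + 1, a.formal_charge) for a in m.atoms
                       if a.formal_charge != 0]
            for k in range(0, len(charged), 8):
                chunk = charged[k:k + 8]
                stream.write(f"M  CHG{len(chunk):3d}")
                for idx, chg in chunk:
                    stream.write(f" {idx:3d} {chg:3d}")
                stream.write("\n")
            stream.write("M  END\n$$$$\n")
    finally:
        if close:
            stream.close()


# ---------------------------------------------------------------------------
# Charge files
# ---------------------------------------------------------------------------
#
# Plain-text format, one block per molecule, blank-line separated:
#
#   <id> <N> <Q> <chi_bar>
#   <index1> <element> <type_key> <charge>
#   ...
#
# Indices 1-based; charges with 9 decimal places.

@dataclass
class ChargeFileRecord:
    """One molecule's block from a charge file."""

    molecule_id: str
    n_atoms: int
    total_charge: int
    chi_bar: float
    elements: list[str] = field(default_factory=list)
    type_keys: list[str] = field(default_factory=list)
    charges: np.ndarray = field(default_factory=lambda: np.empty(0))


def write_charges(m: Molecule, result, sink) -> None:
    """Write one molecule's charges (ends with a blank separator line).

    ``result`` needs ``charges`` (length N) and ``chi_bar`` attributes.
    """
    from .atom_typing import assign_atom_types

    charges = np.asarray(result.charges, dtype=float)
    if charges.shape != (m.n_atoms,):
        raise ValueError(
            f"molecule {m.id!r}: {charges.size} charges for "
            f"{m.n_atoms} atoms")
    types = assign_atom_types(m)
    sink.write(f"{m.id} {m.n_atoms} {m.total_charge} {result.chi_bar:.9f}\n")
    for atom, atype, q in zip(m.atoms, types, charges):
        sink.write(f"{atom.index + 1} {atom.element} {atype.key} "
                   f"{q:.9f}\n")
    sink.write("\n")


def read_charges(source) -> dict[str, ChargeFileRecord]:
    """Read a (possibly concatenated) charge file, keyed by molecule id."""
    stream, close = _open_text(source)
    try:
        records: dict[str, ChargeFileRecord] = {}
        block: list[str] = []
        for raw in list(stream) + [""]:
            line = raw.rstrip("\n")
            if line.strip():
                block.append(line)
                continue
            if not block:
                continue
            header = block[0].split()
            if len(header) < 4:
                raise ValueError(f"malformed charge header: {block[0]!r}")
            # id may contain spaces: peel N, Q, chi_bar off the right
            chi = float(header[-1])
            q_total = int(header[-2])
            n = int(header[-3])
            mol_id = " ".join(header[:-3])
            if len(block) - 1 != n:
                raise ValueError(
                    f"molecule {mol_id!r}: header says {n} atoms, block has "
                    f"{len(block) - 1} charge lines")
            elements, keys, charges = [], [], np.empty(n)
            for k, entry in enumerate(block[1:]):
                fields = entry.split()
                if len(fields) != 4:
                    raise ValueError(
                        f"molecule {mol_id!r}: malformed charge line "
                        f"{entry!r}")
                if int(fields[0]) != k + 1:
                    raise ValueError(
                        f"molecule {mol_id!r}: atom lines out of order")
                elements.append(fields[1])
                keys.append(fields[2])
                charges[k] = float(fields[3])
            records[mol_id] = ChargeFileRecord(
                molecule_id=mol_id, n_atoms=n, total_charge=q_total,
                chi_bar=chi, elements=elements, type_keys=keys,
                charges=charges)
            block = []
        return records
    finally:
        if close:
            stream.close()
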