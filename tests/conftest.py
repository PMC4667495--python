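import io

import numpy as np
import pytest

from eemkit import Atom, Bond, Molecule

# ---------------------------------------------------------------------------
# Hand-authored fixtures
# ---------------------------------------------------------------------------

# ethanol: 9 atoms (C C O + 6 H), 8 single bonds, neutral
ETHANOL_ATOMS = [
    ("C", (-0.888, 0.168, -0.010)),
    ("C", (0.592, 0.043, 0.245)),
    ("O", (1.247, 1.283, 0.057)),
    ("H", (-1.361, -0.740, 0.354)),
    ("H", (-1.328, 1.023, 0.495)),
    ("H", (-1.069, 0.309, -1.073)),
    ("H", (1.042, -0.740, -0.375)),
    ("H", (0.767, -0.219, 1.288)),
    ("H", (2.179, 1.155, 0.258)),
]
ETHANOL_BONDS = [(0, 1, 1), (1, 2, 1), (0, 3, 1), (0, 4, 1), (0, 5, 1),
                 (1, 6, 1), (1, 7, 1), (2, 8, 1)]


def _v2000_record(title, atoms, bonds, charges=()):
    lines = [title, "  fixture", ""]
    lines.append(f"{len(atoms):3d}{len(bonds):3d}  0  0  0  0  0  0  0  0"
                 "999 V2000")
    for el, (x, y, z) in atoms:
        lines.append(f"{x:10.4f}{y:10.4f}{z:10.4f} {el:<3s} 0  0  0  0  0"
                     "  0  0  0  0  0  0  0")
    for a, b, t in bonds:
        lines.append(f"{a + 1:3d}{b + 1:3d}{t:3d}  0")
    if charges:
        body = "".join(f" {i + 1:3d} {c:3d}" for i, c in charges)
        lines.append(f"M  CHG{len(charges):3d}{body}")
    lines.append("M  END")
    lines.append("$$$$")
    return "\n".join(lines) + "\n"


@pytest.fixture
def ethanol_sdf_text():
    return _v2000_record("ethanol", ETHANOL_ATOMS, ETHANOL_BONDS)


@pytest.fixture
def ethanol():
    atoms = [Atom(index=i, element=el, position=pos)
             for i, (el, pos) in enumerate(ETHANOL_ATOMS)]
    bonds = [Bond(a, b, t) for a, b, t in ETHANOL_BONDS]
    return Molecule(id="ethanol", atoms=atoms, bonds=bonds, total_charge=0)


@pytest.fixture
def benzene():
    """Six aromatic ring carbons (type-4 dialect), no hydrogens."""
    r = 1.39
    atoms = [Atom(index=i, element="C",
                  position=(r * np.cos(i * np.pi / 3),
                            r * np.sin(i * np.pi / 3), 0.0))
             for i in range(6)]
    bonds = [Bond(i, (i + 1) % 6, 2, aromatic_flag=True) for i in range(6)]
    return Molecule(id="benzene", atoms=atoms, bonds=bonds, total_charge=0)


def make_record_text(title, atoms, bonds, charges=()):
    return _v2000_record(title, atoms, bonds, charges)


def as_stream(text):
    return io.StringIO(text)


# small atom-type pool whose types all appear often in tiny training sets
SMALL_POOL = ((("H", 1), 5.0), (("C", 1), 2.0), (("C", 2), 3.0),
              (("O", 2), 1.0))

# the eight-type drug-like pool used for parameter-recovery experiments
RECOVERY_POOL = tuple(((el, o), float(w)) for (el, o), w in {
    ("H", 1): 57119, ("C", 1): 15220, ("C", 2): 38097, ("N", 1): 4151,
    ("N", 2): 3383, ("O", 1): 5016, ("O", 2): 5793, ("S", 1): 1034,
}.items())
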