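"""Seeded generator of geometrically plausible molecules, ground-truth
parameter sets and reference charges.

The generator stands in for curated drug-like training/test collections:
it emits connected molecules whose atom-type composition follows the
relative frequencies observed in large drug-like compound sets, with 3D
coordinates satisfying distance constraints. Geometry is
*plausibility-only* (bond lengths and a minimum pair separation) — EEM
depends only on distances, atom types and the total charge, so valence
and torsional realism are deliberately not pursued.

RNG protocol: a single master seed deterministically derives independent
streams per molecule (and separate streams for parameters and noise), so
changing ``n_molecules`` never reshuffles earlier molecules.

Ground-truth parameter sets are emitted in the package's canonical scale
(mean hardness B = 1 over the pool's types): the parameter scale is a
gauge freedom of the EEM charge map, and sharing the convention with the
fitter is what makes absolute parameter recovery well-posed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .atom_typing import assign_atom_types
from .eem_core import EEMParameterSet, solve_eem
from .errors import GenerationError
from .mol_model import Atom, Bond, Molecule
from .param_fit import TrainingExample

# Atom-type occurrence counts in a large drug-like training collection,
# used as default sampling weights. Keys are (element, maximal bond order).
DRUGLIKE_TYPE_WEIGHTS: dict[tuple[str, int], int] = {
    ("H", 1): 57119,
    ("C", 1): 15220, ("C", 2): 38097, ("C", 3): 345,
    ("N", 1): 4151, ("N", 2): 3383, ("N", 3): 345,
    ("O", 1): 5016, ("O", 2): 5793,
    ("F", 1): 938,
    ("P", 1): 153, ("P", 2): 251,
    ("S", 1): 1034, ("S", 2): 1391,
    ("Cl", 1): 1084,
    ("Br", 1): 336,
    ("I", 1): 1734,
}

_PARAMS_STREAM = (0,)      # spawn keys of the derived RNG streams
_MOL_STREAM = 1
_NOISE_STREAM = 2


def _default_pool() -> tuple[tuple[tuple[str, int], float], ...]:
    return tuple((key, float(w)) for key, w in DRUGLIKE_TYPE_WEIGHTS.items())


@dataclass
class GeneratorConfig:
    seed: int = 0
    n_molecules: int = 100
    atoms_range: tuple[int, int] = (3, 30)
    element_pool: tuple[tuple[tuple[str, int], float], ...] = \
        field(default_factory=_default_pool)
    min_pair_distance: float = 1.0        # A, any atom pair
    bond_length_range: tuple[float, float] = (1.0, 1.8)   # A, bonded pairs
    charge_noise_sigma: float = 0.0       # e, i.i.d. noise on ref charges
    a_range: tuple[float, float] = (1.5, 4.0)
    b_range: tuple[float, float] = (0.3, 1.6)
    kappa_range: tuple[float, float] = (0.1, 0.9)
    kappa: float | None = None            # fixed truth kappa, else sampled
    extra_bond_prob: float = 0.2          # chance per eligible close pair

    def __post_init__(self) -> None:
        if self.n_molecules < 0:
            raise ValueError("n_molecules must be >= 0")
        if not (1 <= self.atoms_range[0] <= self.atoms_range[1]):
            raise ValueError("atoms_range must satisfy 1 <= min <= max")
        for lo, hi, what in ((self.bond_length_range[0],
                              self.bond_length_range[1], "bond_length"),
                             (self.a_range[0], self.a_range[1], "A"),
                             (self.b_range[0], self.b_range[1], "B"),
                             (self.kappa_range[0], self.kappa_range[1],
                              "kappa")):
            if not lo < hi:
                raise ValueError(f"{what} range must have lo < hi")
        if any(w <= 0 for _, w in self.element_pool):
            raise ValueError("pool weights must be positive")
        if not any(order == 1 for (_, order), _ in self.element_pool):
            raise ValueError("pool must contain at least one order-1 type")
        if self.min_pair_distance <= 0:
            raise ValueError("min_pair_distance must be positive")
        if self.bond_length_range[0] < self.min_pair_distance:
            raise ValueError(
                "bond lengths below min_pair_distance are unsatisfiable")

    def pool_type_keys(self) -> list[str]:
        return sorted(f"{el}{order}" for (el, order), _ in self.element_pool)


def _stream(config: GeneratorConfig, *key: int) -> np.random.Generator:
    return np.random.default_rng(
        np.random.SeedSequence(config.seed, spawn_key=tuple(key)))


def _sample_types(config: GeneratorConfig, rng: np.random.Generator,
                  n: int) -> list[tuple[str, int]]:
    pool = [key for key, _ in config.element_pool]
    weights = np.array([w for _, w in config.element_pool], dtype=float)
    weights /= weights.sum()

    def draw(max_order: int) -> tuple[str, int]:
        ok = [k for k, (key, _) in enumerate(config.element_pool)
              if key[1] <= max_order]
        w = weights[ok] / weights[ok].sum()
        return pool[ok[rng.choice(len(ok), p=w)]]

    if n == 1:
        return [draw(1)]       # isolated atoms carry order 1 by definition
    types = [pool[i] for i in rng.choice(len(pool), size=n, p=weights)]
    # repair: an order-o atom (o >= 2) needs a partner of order >= o
    while True:
        o3 = [i for i, t in enumerate(types) if t[1] == 3]
        o2 = [i for i, t in enumerate(types) if t[1] == 2]
        if len(o3) == 1:
            types[o3[0]] = draw(2)
            continue
        if len(o2) == 1 and not o3:
            types[o2[0]] = draw(1)
            continue
        break
    return types


def _build_tree(types: list[tuple[str, int]], rng: np.random.Generator
                ) -> list[Bond]:
    """Spanning tree whose edge orders realize every atom's target order."""
    o3 = [i for i, t in enumerate(types) if t[1] == 3]
    o2 = [i for i, t in enumerate(types) if t[1] == 2]
    o1 = [i for i, t in enumerate(types) if t[1] == 1]
    rng.shuffle(o3)
    rng.shuffle(o2)
    rng.shuffle(o1)
    bonds: list[Bond] = []
    placed: list[int] = []
    for chain, order in ((o3, 3), (o2, 2)):
        for prev, cur in zip(chain, chain[1:]):
            bonds.append(Bond(prev, cur, order))
        if chain:
            if placed:     # bridge the order-3 chain to the order-2 chain
                bridge_order = 2 if len(chain) == 1 else 1
                bonds.append(Bond(placed[-1], chain[0], bridge_order))
            placed.extend(chain)
    for i in o1:
        if placed:
            parent = placed[int(rng.integers(len(placed)))]
            bonds.append(Bond(parent, i, 1))
        placed.append(i)
    return bonds


def _embed(n: int, bonds: list[Bond], config: GeneratorConfig,
           rng: np.random.Generator) -> np.ndarray | None:
    """Sequential stochastic embedding along the spanning tree."""
    children: dict[int, list[int]] = {i: [] for i in range(n)}
    adjacency: dict[int, list[int]] = {i: [] for i in range(n)}
    for b in bonds:
        adjacency[b.a].append(b.b)
        adjacency[b.b].append(b.a)
    # BFS order from atom appearing first in the bond list (or atom 0)
    root = bonds[0].a if bonds else 0
    order = [root]
    parent = {root: None}
    queue = [root]
    while queue:
        cur = queue.pop(0)
        for nxt in adjacency[cur]:
            if nxt not in parent:
                parent[nxt] = cur
                order.append(nxt)
                queue.append(nxt)
    if len(order) != n:
        return None        # disconnected tree: construction bug guard
    pos = np.zeros((n, 3))
    placed = [root]
    lo, hi = config.bond_length_range
    for atom in order[1:]:
        anchor = pos[parent[atom]]
        for _ in range(200):
            direction = rng.normal(size=3)
            norm = np.linalg.norm(direction)
            if norm < 1e-12:
                continue
            candidate = anchor + rng.uniform(lo, hi) * direction / norm
            dists = np.linalg.norm(pos[placed] - candidate, axis=1)
            if np.all(dists >= config.min_pair_distance):
                pos[atom] = candidate
                placed.append(atom)
                break
        else:
            return None
    return pos


def make_molecule(config: GeneratorConfig, rng: np.random.Generator,
                  mol_id: str = "synthetic") -> Molecule:
    """One connected molecule whose assigned atom types equal the
    sampled (element, order) list exactly."""
    n = int(rng.integers(config.atoms_range[0], config.atoms_range[1] + 1))
    types = _sample_types(config, rng, n)
    tree = _build_tree(types, rng)
    pos = None
    for _ in range(50):
        pos = _embed(n, tree, config, rng)
        if pos is not None:
            break
    if pos is None:
        raise GenerationError(
            f"embedding failed for {mol_id!r} after bounded retries; "
            "re-seed or relax distance constraints")
    bonds = list(tree)
    bonded = {b.pair for b in bonds}
    if n > 1 and config.extra_bond_prob > 0:
        # extra single bonds between geometrically close pairs: they never
        # change an atom's maximal bond order
        diff = pos[:, None, :] - pos[None, :, :]
        dist = np.sqrt((diff ** 2).sum(axis=2))
        lo, hi = config.bond_length_range
        for i in range(n):
            for j in range(i + 1, n):
                if (i, j) in bonded or not lo <= dist[i, j] <= hi:
                    continue
                if rng.random() < config.extra_bond_prob:
                    bonds.append(Bond(i, j, 1))
                    bonded.add((i, j))
    atoms = [Atom(index=i, element=el, position=pos[i])
             for i, (el, _) in enumerate(types)]
    return Molecule(id=mol_id, atoms=atoms, bonds=bonds, total_charge=0)


def make_molecules(config: GeneratorConfig) -> list[Molecule]:
    """``n_molecules`` molecules from per-index derived RNG streams."""
    out = []
    for k in range(config.n_molecules):
        rng = _stream(config, _MOL_STREAM, k)
        out.append(make_molecule(config, rng,
                                 mol_id=f"syn-{config.seed}-{k}"))
    return out


def sample_paramset(rng: np.random.Generator, type_keys: list[str],
                    a_range: tuple[float, float] = (1.5, 4.0),
                    b_range: tuple[float, float] = (0.3, 1.6),
                    kappa_range: tuple[float, float] = (0.1, 0.9),
                    kappa: float | None = None,
                    canonical_scale: bool = True,
                    name: str = "synthetic-truth") -> EEMParameterSet:
    """Random valid parameter set over the given type keys.

    With ``canonical_scale`` the sampled B values are rescaled to mean 1
    (the package's reporting convention for fitted sets), leaving their
    spread within roughly the sampled range.
    """
    a = rng.uniform(*a_range, size=len(type_keys))
    b = rng.uniform(*b_range, size=len(type_keys))
    if canonical_scale:
        b = b / b.mean()
    k = float(rng.uniform(*kappa_range)) if kappa is None else float(kappa)
    entries = {key: (float(ai), float(bi))
               for key, ai, bi in zip(type_keys, a, b)}
    return EEMParameterSet(name=name, kappa=k, entries=entries,
                           metadata={"scheme": "synthetic",
                                     "scale_convention":
                                         "mean B = 1" if canonical_scale
                                         else "raw"})


def make_ground_truth(config: GeneratorConfig
                      ) -> tuple[EEMParameterSet, list[TrainingExample]]:
    """Ground-truth parameter set plus training examples.

    Reference charges are the exact EEM solution under the truth; when
    ``charge_noise_sigma`` > 0, i.i.d. Gaussian noise is added and then
    projected back onto the charge-conservation hyperplane (the noise
    mean is removed), so every example still sums to Q exactly.
    """
    truth = sample_paramset(
        _stream(config, *_PARAMS_STREAM), config.pool_type_keys(),
        a_range=config.a_range, b_range=config.b_range,
        kappa_range=config.kappa_range, kappa=config.kappa)
    examples = []
    for k, mol in enumerate(make_molecules(config)):
        q = solve_eem(mol, truth,
                      min_distance=0.5 * config.min_pair_distance).charges
        if config.charge_noise_sigma > 0:
            noise_rng = _stream(config, _NOISE_STREAM, k)
            noise = noise_rng.normal(0.0, config.charge_noise_sigma,
                                     size=mol.n_atoms)
            noise -= noise.mean()          # conservation projection
            q = q + noise
        examples.append(TrainingExample(molecule=mol, ref_charges=q,
                                        scheme_label="synthetic"))
    return truth, examples
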