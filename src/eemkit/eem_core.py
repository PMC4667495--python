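"""EEM matrix assembly and solve.

The Electronegativity Equalization Method determines partial atomic
charges q_1..q_N and the molecular electronegativity chi_bar from one
linear system per molecule::

    [ B_1      k/R_12 ... k/R_1N  -1 ] [ q_1 ]   [ -A_1 ]
    [ k/R_21   B_2    ... k/R_2N  -1 ] [ q_2 ]   [ -A_2 ]
    [  ...                        ...] [ ... ] = [  ... ]
    [ k/R_N1   k/R_N2 ... B_N     -1 ] [ q_N ]   [ -A_N ]
    [ 1        1      ... 1        0 ] [ chi ]   [  Q   ]

A_t (per-type electronegativity offset), B_t (per-type hardness, > 0) and
the global screening constant kappa are the empirical parameters; R_ij are
interatomic distances in angstrom and Q is the total molecular charge.
The last row enforces charge conservation. Only differences between A
values affect the charges (a uniform shift is absorbed by chi_bar), and a
joint rescaling of (A, B, kappa) leaves the charges unchanged as well; see
the methods note on gauge freedoms.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.linalg

from .atom_typing import AtomType, assign_atom_types
from .errors import MissingParametersError, SingularSystemError
from .mol_model import (DEFAULT_MIN_DISTANCE, DistanceMatrix, Molecule,
                        distance_matrix)

#: condition-number ceiling above which a solve is refused
DEFAULT_COND_THRESHOLD = 1e10

#: residual tolerance of the solved system, relative to max(1, |Q|)
SOLVE_RESIDUAL_TOL = 1e-10


@dataclass
class EEMParameterSet:
    """Global kappa plus per-atom-type (A, B) empirical parameters.

    Entry keys are either ``"El<order>"`` (e.g. ``"C2"``) or a bare
    element symbol (e.g. ``"C"``), the latter acting as a wildcard that
    matches any bond order — the convention used by several legacy
    published sets. When both exist, the specific key wins.
    """

    name: str
    kappa: float
    entries: dict[str, tuple[float, float]]
    metadata: dict[str, str] = field(default_factory=dict)

    def resolve(self, atom_type: AtomType) -> tuple[float, float] | None:
        """(A, B) for an atom type; specific key beats element wildcard."""
        hit = self.entries.get(atom_type.key)
        if hit is None:
            hit = self.entries.get(atom_type.element)
        return hit

    def type_keys(self) -> list[str]:
        return sorted(self.entries)


@dataclass
class ChargeResult:
    """Per-atom charges plus the molecular electronegativity chi_bar."""

    charges: np.ndarray
    chi_bar: float
    parameter_set_name: str


def missing_types(m: Molecule, params: EEMParameterSet) -> list[str]:
    """Distinct atom-type keys of ``m`` that ``params`` cannot resolve.

    This single routine defines "covered" for both the solver and the
    coverage module.
    """
    unresolved = {t.key for t in assign_atom_types(m)
                  if params.resolve(t) is None}
    return sorted(unresolved)


def build_eem_system(m: Molecule, dist: DistanceMatrix,
                     params: EEMParameterSet
                     ) -> tuple[np.ndarray, np.ndarray]:
    """Assemble the (N+1) x (N+1) EEM matrix and right-hand side."""
    missing = missing_types(m, params)
    if missing:
        raise MissingParametersError(m.id, missing)
    n = m.n_atoms
    a_vec = np.empty(n)
    b_vec = np.empty(n)
    for i, t in enumerate(assign_atom_types(m)):
        a_vec[i], b_vec[i] = params.resolve(t)

    matrix = np.zeros((n + 1, n + 1))
    with np.errstate(divide="ignore"):
        inv = np.where(dist > 0, 1.0 / np.where(dist > 0, dist, 1.0), 0.0)
    matrix[:n, :n] = params.kappa * inv
    matrix[np.arange(n), np.arange(n)] = b_vec
    matrix[:n, n] = -1.0
    matrix[n, :n] = 1.0
    rhs = np.empty(n + 1)
    rhs[:n] = -a_vec
    rhs[n] = float(m.total_charge)
    return matrix, rhs


def solve_eem(m: Molecule, params: EEMParameterSet, *,
              min_distance: float = DEFAULT_MIN_DISTANCE,
              cond_threshold: float = DEFAULT_COND_THRESHOLD
              ) -> ChargeResult:
    """Solve the EEM system for one molecule.

    Dense direct solve with partial pivoting; molecules at the scale this
    package targets are at most a few hundred atoms. Refuses (rather than
    returning garbage) when the condition number exceeds
    ``cond_threshold`` or the verified residual is out of tolerance.
    """
    dist = distance_matrix(m, min_distance=min_distance)
    matrix, rhs = build_eem_system(m, dist, params)
    cond = np.linalg.cond(matrix)
    if not np.isfinite(cond) or cond > cond_threshold:
        raise SingularSystemError(
            m.id, f"EEM matrix condition number {cond:.3e} exceeds "
                  f"{cond_threshold:.1e}")
    solution = scipy.linalg.solve(matrix, rhs)
    # one step of iterative refinement keeps the verified residual tight
    residual = rhs - matrix @ solution
    solution = solution + scipy.linalg.solve(matrix, residual)
    tol = SOLVE_RESIDUAL_TOL * max(1.0, abs(float(m.total_charge)))
    residual_norm = float(np.max(np.abs(rhs - matrix @ solution)))
    if residual_norm > tol:
        raise SingularSystemError(
            m.id, f"solve residual {residual_norm:.3e} above {tol:.1e}")
    charges = solution[:-1]
    if abs(charges.sum() - m.total_charge) > tol:
        raise SingularSystemError(
            m.id, "total charge not conserved by the solution")
    return ChargeResult(charges=charges, chi_bar=float(solution[-1]),
                        parameter_set_name=params.name)
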