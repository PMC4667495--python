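"""Independent oracles the tests check the implementation against.

Everything here is deliberately written from first principles — explicit
loops, textbook constructions — and never calls the code paths it is
used to verify.
"""

import math

import numpy as np


def r_squared_brute(q_eem, q_ref):
    """Literal transcription of the squared Pearson correlation."""
    n = len(q_eem)
    me = sum(q_eem) / n
    mr = sum(q_ref) / n
    num = sum((q_eem[i] - me) * (q_ref[i] - mr) for i in range(n)) ** 2
    den = (sum((q_eem[i] - me) ** 2 for i in range(n))
           * sum((q_ref[i] - mr) ** 2 for i in range(n)))
    return num / den


def rmsd_brute(q_eem, q_ref):
    n = len(q_eem)
    return math.sqrt(sum((q_eem[i] - q_ref[i]) ** 2 for i in range(n)) / n)


def mean_abs_brute(q_eem, q_ref):
    n = len(q_eem)
    return sum(abs(q_eem[i] - q_ref[i]) for i in range(n)) / n


def distances_brute(coords):
    """All-pairs Euclidean distances via an explicit double loop."""
    n = len(coords)
    out = np.zeros((n, n))
    for i in range(n):
        for j in range(n):
            s = 0.0
            for k in range(3):
                s += (coords[i][k] - coords[j][k]) ** 2
            out[i, j] = math.sqrt(s)
    return out


def energy_min_charges(mol, params):
    """Constrained quadratic minimizer of the EEM energy.

    Minimizes E(q) = sum_i (A_i q_i + 1/2 B_i q_i^2)
                     + 1/2 kappa sum_{i != j} q_i q_j / R_ij
    subject to sum q = Q, by null-space reduction of the constraint and a
    dense solve of the reduced normal equations — a different route than
    the bordered (KKT) system the solver assembles.
    """
    from eemkit.atom_typing import assign_atom_types

    coords = mol.coordinates()
    n = mol.n_atoms
    a_vec = np.empty(n)
    b_vec = np.empty(n)
    for i, t in enumerate(assign_atom_types(mol)):
        a_vec[i], b_vec[i] = params.resolve(t)
    hess = np.diag(b_vec)
    for i in range(n):
        for j in range(n):
            if i != j:
                hess[i, j] = params.kappa / np.linalg.norm(
                    coords[i] - coords[j])
    q0 = np.full(n, mol.total_charge / n)
    if n == 1:
        return q0
    # columns e_i - e_n span the sum-zero hyperplane
    basis = np.zeros((n, n - 1))
    basis[:-1, :] = np.eye(n - 1)
    basis[-1, :] = -1.0
    reduced = basis.T @ hess @ basis
    rhs = -basis.T @ (a_vec + hess @ q0)
    y = np.linalg.solve(reduced, rhs)
    return q0 + basis @ y
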