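"""Quality criteria comparing EEM charges against reference charges.

Three statistics, computed over a set of atoms (one molecule or a pool):

* R^2 — squared Pearson correlation between the two charge vectors;
* RMSD — root mean square deviation, in elementary charges;
* mean absolute deviation (Delta-bar).

The headline aggregation is *pooled over atoms*: the charge vectors of
all covered molecules are concatenated and one statistic triple is
computed, which is how a single quality figure per parameter set is
conventionally reported. Per-molecule statistics are available alongside
and are clearly labeled as such. Atoms of molecules a parameter set does
not cover are excluded entirely.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .errors import UndefinedStatisticError


@dataclass
class ChargePair:
    """EEM and reference charge vectors for one molecule."""

    q_eem: np.ndarray
    q_ref: np.ndarray
    molecule_id: str = ""

    def __post_init__(self) -> None:
        self.q_eem = np.asarray(self.q_eem, dtype=float)
        self.q_ref = np.asarray(self.q_ref, dtype=float)
        if self.q_eem.ndim != 1 or self.q_eem.shape != self.q_ref.shape:
            raise ValueError(
                f"molecule {self.molecule_id!r}: charge vectors must be "
                f"1-D and equal length")
        if self.q_eem.size < 1:
            raise ValueError("empty charge vectors")


def _vectors(q_eem, q_ref=None) -> tuple[np.ndarray, np.ndarray]:
    if q_ref is None:
        if not isinstance(q_eem, ChargePair):
            raise TypeError("expected a ChargePair or two vectors")
        return q_eem.q_eem, q_eem.q_ref
    return np.asarray(q_eem, dtype=float), np.asarray(q_ref, dtype=float)


def r_squared(q_eem, q_ref=None) -> float:
    """Squared Pearson correlation coefficient.

    Symmetric in its arguments and invariant to affine rescaling of
    either vector. Raises :class:`UndefinedStatisticError` when either
    vector is constant (zero variance): the statistic is undefined there,
    not 0 and not 1.
    """
    a, b = _vectors(q_eem, q_ref)
    da = a - a.mean()
    db = b - b.mean()
    va = float(da @ da)
    vb = float(db @ db)
    # a constant vector may carry rounding noise from the mean subtraction
    eps = np.finfo(float).eps

    def _constant(values, variance):
        scale = max(1.0, float(np.max(np.abs(values))))
        return variance <= (4 * eps * scale) ** 2 * values.size

    if _constant(a, va) or _constant(b, vb):
        raise UndefinedStatisticError(
            "R^2 undefined: at least one charge vector is constant")
    cov = float(da @ db)
    return cov * cov / (va * vb)


def rmsd(q_eem, q_ref=None) -> float:
    """Root mean square deviation over the pooled atoms."""
    a, b = _vectors(q_eem, q_ref)
    return float(np.sqrt(np.mean((a - b) ** 2)))


def mean_abs_dev(q_eem, q_ref=None) -> float:
    """Average absolute error (Delta-bar) over the pooled atoms."""
    a, b = _vectors(q_eem, q_ref)
    return float(np.mean(np.abs(a - b)))


@dataclass
class QualityReport:
    r2: float
    rmsd: float
    mean_abs: float
    n_atoms: int
    n_molecules: int
    coverage_fraction: float = 1.0
    r2_undefined: bool = False


def pooled_quality(pairs: Sequence[ChargePair],
                   coverage_fraction: float | None = None
                   ) -> QualityReport:
    """Pooled statistics over the concatenated atoms of all pairs.

    ``coverage_fraction`` may be supplied by the caller (e.g. covered /
    total molecules of a larger collection); it defaults to 1.
    """
    if not pairs:
        raise ValueError("pooled_quality requires at least one ChargePair")
    q_eem = np.concatenate([p.q_eem for p in pairs])
    q_ref = np.concatenate([p.q_ref for p in pairs])
    undefined = False
    try:
        r2 = r_squared(q_eem, q_ref)
    except UndefinedStatisticError:
        r2, undefined = math.nan, True
    return QualityReport(
        r2=r2, rmsd=rmsd(q_eem, q_ref), mean_abs=mean_abs_dev(q_eem, q_ref),
        n_atoms=int(q_eem.size), n_molecules=len(pairs),
        coverage_fraction=(1.0 if coverage_fraction is None
                           else float(coverage_fraction)),
        r2_undefined=undefined)


def per_molecule_quality(pairs: Iterable[ChargePair]) -> pd.DataFrame:
    """Per-molecule statistics (distribution view, not the headline)."""
    rows = []
    for p in pairs:
        try:
            r2 = r_squared(p)
        except UndefinedStatisticError:
            r2 = math.nan
        rows.append({"molecule_id": p.molecule_id, "n_atoms": p.q_eem.size,
                     "r2": r2, "rmsd": rmsd(p), "mean_abs": mean_abs_dev(p)})
    return pd.DataFrame(rows,
                        columns=["molecule_id", "n_atoms", "r2", "rmsd",
                                 "mean_abs"])


def quality_tsv(reports: dict[str, QualityReport], sink) -> None:
    """One row per parameter set: set_name, r2, rmsd, mean_abs, coverage."""
    sink.write("set_name\tr2\trmsd\tmean_abs\tcoverage\n")
    for name, rep in reports.items():
        r2 = "NA" if rep.r2_undefined else f"{rep.r2:.6f}"
        sink.write(f"{name}\t{r2}\t{rep.rmsd:.6f}\t{rep.mean_abs:.6f}\t"
                   f"{rep.coverage_fraction:.6f}\n")
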