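"""Parameter-set coverage of molecule collections.

A molecule is *covered* by a parameter set when every one of its atom
types resolves to an entry (specific key or element wildcard). Coverage
shares its resolution routine with the solver, so "covered" is exactly
"solve_eem would not raise a missing-parameter error".

Input streaming is single-pass with constant memory per molecule, so
multi-million-record SDF files are feasible; records that fail to parse
are counted as *unreadable* — a third category, since coverage is a
statement about atom types, not file hygiene.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable

from .eem_core import EEMParameterSet, missing_types
from .errors import SDFParseError
from .mol_model import Molecule, iter_sdf_records, parse_sdf_record


@dataclass
class CoverageReport:
    total: int
    covered: int
    fraction: float
    missing_type_tally: dict[str, int] = field(default_factory=dict)
    unreadable: int = 0

    @property
    def empty(self) -> bool:
        """Flag for a vacuous report (no readable molecules)."""
        return self.total == 0


def molecule_is_covered(m: Molecule, params: EEMParameterSet
                        ) -> tuple[bool, list[str]]:
    """(covered, distinct unresolved type keys)."""
    missing = missing_types(m, params)
    return (not missing), missing


def coverage_report(molecules: Iterable[Molecule],
                    params: EEMParameterSet,
                    unreadable: int = 0) -> CoverageReport:
    """Tally coverage and per-type blame over a molecule stream."""
    total = 0
    covered = 0
    tally: dict[str, int] = {}
    for m in molecules:
        total += 1
        ok, missing = molecule_is_covered(m, params)
        if ok:
            covered += 1
        else:
            for key in missing:
                tally[key] = tally.get(key, 0) + 1
    fraction = covered / total if total else 0.0
    return CoverageReport(total=total, covered=covered, fraction=fraction,
                          missing_type_tally=dict(sorted(tally.items())),
                          unreadable=unreadable)


def coverage_report_sdf(source, params: EEMParameterSet) -> CoverageReport:
    """Stream an SDF, counting unparseable records separately."""
    unreadable = 0

    def molecules():
        nonlocal unreadable
        for ordinal, start, lines in iter_sdf_records(source):
            try:
                yield parse_sdf_record(lines, ordinal, start)
            except SDFParseError:
                unreadable += 1

    report = coverage_report(molecules(), params)
    report.unreadable = unreadable
    return report


def coverage_tsv(reports: dict[str, CoverageReport], sink,
                 top_n: int = 5) -> None:
    """TSV: set_name, total, covered, fraction, top missing types."""
    sink.write("set_name\ttotal\tcovered\tfraction\ttop_missing_types\n")
    for name, rep in reports.items():
        top = sorted(rep.missing_type_tally.items(),
                     key=lambda kv: (-kv[1], kv[0]))[:top_n]
        top_s = ",".join(f"{k}:{n}" for k, n in top) or "-"
        sink.write(f"{name}\t{rep.total}\t{rep.covered}\t"
                   f"{rep.fraction:.6f}\t{top_s}\n")
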