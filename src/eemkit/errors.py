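"""Exception hierarchy shared by all eemkit modules."""

from __future__ import annotations


class EEMError(Exception):
    """Base class for all eemkit-specific errors."""


class SDFParseError(EEMError):
    """Malformed SDF input. Carries the record ordinal (1-based) and the
    file line number where parsing failed."""

    def __init__(self, message: str, record: int | None = None,
                 line: int | None = None):
        loc = []
        if record is not None:
            loc.append(f"record {record}")
        if line is not None:
            loc.append(f"line {line}")
        where = f" ({', '.join(loc)})" if loc else ""
        super().__init__(f"{message}{where}")
        self.record = record
        self.line = line


class DegenerateGeometryError(EEMError):
    """Two atoms closer than the configured minimum distance."""

    def __init__(self, molecule_id: str, i: int, j: int, distance: float,
                 minimum: float):
        super().__init__(
            f"molecule {molecule_id!r}: atoms {i} and {j} are "
            f"{distance:.4f} A apart (minimum {minimum:g} A)")
        self.pair = (i, j)
        self.distance = distance


class MissingParametersError(EEMError):
    """A molecule contains atom types absent from the parameter set."""

    def __init__(self, molecule_id: str, missing: list[str]):
        super().__init__(
            f"molecule {molecule_id!r}: no parameters for atom type(s) "
            + ", ".join(sorted(missing)))
        self.molecule_id = molecule_id
        self.missing = sorted(missing)


class SingularSystemError(EEMError):
    """The EEM matrix is numerically singular or too ill-conditioned."""

    def __init__(self, molecule_id: str, detail: str):
        super().__init__(f"molecule {molecule_id!r}: {detail}")
        self.molecule_id = molecule_id


class UndefinedStatisticError(EEMError):
    """Statistic undefined for the given input (e.g. constant vector)."""


class ParamsetFormatError(EEMError):
    """Malformed parameter-set file. Carries the 1-based line number."""

    def __init__(self, message: str, line: int | None = None):
        where = f" (line {line})" if line is not None else ""
        super().__init__(f"{message}{where}")
        self.line = line


class FitError(EEMError):
    """Parameterization failed (degenerate design, unphysical result...)."""


class SparseTypeError(FitError):
    """Atom types with too few atoms to be parameterized."""

    def __init__(self, types: dict[str, int], minimum: int):
        msg = ", ".join(f"{t} ({n} atoms)" for t, n in sorted(types.items()))
        super().__init__(
            f"atom types below the minimum of {minimum} atoms: {msg}")
        self.types = types


class GenerationError(EEMError):
    """Synthetic-structure generation failed after bounded retries."""
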