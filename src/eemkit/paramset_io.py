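"""Read, write and validate EEM parameter-set files (``.eem``).

Format — UTF-8 plain text, hand-editable and diff-friendly::

    # scheme: B3LYP/6-311G/NPA        <- "# key: value" comments become
    # any free-form comment              metadata; others are ignored
    kappa 0.44
    H1 2.396 0.959
    C  2.464 0.526                    <- bare element = wildcard for all
    C2 2.482 0.464                       bond orders; specific key wins

The first non-comment line must be ``kappa <float>``; every further
non-comment line is ``<key> <A> <B>``. Duplicate keys are rejected.
"""

from __future__ import annotations

import os
import re
from dataclasses import dataclass

from .eem_core import EEMParameterSet
from .errors import ParamsetFormatError

_KEY_RE = re.compile(r"^([A-Z][a-z]?)([1-9][0-9]*)?$")


@dataclass(frozen=True)
class Finding:
    severity: str          # "error" | "info"
    message: str


def parse_entry_key(key: str) -> tuple[str, int | None]:
    """Split ``"C2"`` -> ("C", 2); bare ``"C"`` -> ("C", None)."""
    m = _KEY_RE.match(key)
    if not m:
        raise ValueError(f"malformed atom-type key {key!r}")
    element, order = m.group(1), m.group(2)
    return element, (int(order) if order is not None else None)


def read_paramset(source, name: str | None = None) -> EEMParameterSet:
    """Parse a ``.eem`` file from a path or text stream."""
    if isinstance(source, (str, os.PathLike)):
        default_name = os.path.splitext(os.path.basename(source))[0]
        with open(source, "r", encoding="utf-8") as fh:
            lines = fh.readlines()
    else:
        default_name = "paramset"
        lines = list(source)

    kappa: float | None = None
    entries: dict[str, tuple[float, float]] = {}
    metadata: dict[str, str] = {}
    for lineno, raw in enumerate(lines, start=1):
        line = raw.strip()
        if not line:
            continue
        if line.startswith("#"):
            body = line.lstrip("#").strip()
            if ":" in body:
                key, _, value = body.partition(":")
                if key.strip():
                    metadata[key.strip()] = value.strip()
            continue
        fields = line.split()
        if kappa is None:
            if fields[0] != "kappa" or len(fields) != 2:
                raise ParamsetFormatError(
                    "first non-comment line must be 'kappa <float>'",
                    line=lineno)
            try:
                kappa = float(fields[1])
            except ValueError:
                raise ParamsetFormatError(
                    f"non-numeric kappa {fields[1]!r}",
                    line=lineno) from None
            continue
        if len(fields) != 3:
            raise ParamsetFormatError(
                f"expected '<type> <A> <B>', got {line!r}", line=lineno)
        key = fields[0]
        try:
            parse_entry_key(key)
        except ValueError as exc:
            raise ParamsetFormatError(str(exc), line=lineno) from None
        if key in entries:
            raise ParamsetFormatError(f"duplicate type key {key!r}",
                                      line=lineno)
        try:
            a, b = float(fields[1]), float(fields[2])
        except ValueError:
            raise ParamsetFormatError(
                f"non-numeric A/B on entry {key!r}", line=lineno) from None
        entries[key] = (a, b)
    if kappa is None:
        raise ParamsetFormatError("missing 'kappa' line")
    if not entries:
        raise ParamsetFormatError("parameter set has no entries")
    return EEMParameterSet(name=name or default_name, kappa=kappa,
                           entries=entries, metadata=metadata)


def _sort_key(key: str) -> tuple[str, int]:
    element, order = parse_entry_key(key)
    return element, (0 if order is None else order)  # wildcard first


def write_paramset(params: EEMParameterSet, sink) -> None:
    """Deterministic writer: metadata comments, kappa, sorted entries.

    Values are written in shortest-roundtrip decimal form, so a
    write/read roundtrip reproduces them exactly. Refuses invalid sets
    (any error-level finding from :func:`validate_paramset`).
    """
    problems = [f for f in validate_paramset(params)
                if f.severity == "error"]
    if problems:
        raise ValueError("refusing to write invalid parameter set: "
                         + "; ".join(f.message for f in problems))
    close = False
    if isinstance(sink, (str, os.PathLike)):
        sink, close = open(sink, "w", encoding="utf-8"), True
    try:
        for key in sorted(params.metadata):
            sink.write(f"# {key}: {params.metadata[key]}\n")
        sink.write(f"kappa {params.kappa!r}\n")
        for key in sorted(params.entries, key=_sort_key):
            a, b = params.entries[key]
            sink.write(f"{key} {float(a)!r} {float(b)!r}\n")
    finally:
        if close:
            sink.close()


def validate_paramset(params: EEMParameterSet) -> list[Finding]:
    """Structural and physical checks; findings, caller decides."""
    findings: list[Finding] = []
    if not params.entries:
        findings.append(Finding("error", "parameter set has no entries"))
    if not params.kappa > 0:
        findings.append(Finding("error",
                                f"kappa {params.kappa!r} must be > 0"))
    wildcards: set[str] = set()
    specific: set[str] = set()
    for key, (a, b) in params.entries.items():
        try:
            element, order = parse_entry_key(key)
        except ValueError as exc:
            findings.append(Finding("error", str(exc)))
            continue
        if order is None:
            wildcards.add(element)
        else:
            specific.add(element)
            if order not in (1, 2, 3):
                findings.append(Finding(
                    "error", f"{key}: bond order {order} outside {{1,2,3}}"))
        if not (a == a and b == b):  # NaN guard
            findings.append(Finding("error", f"{key}: non-finite A/B"))
        if b <= 0:
            findings.append(Finding(
                "error", f"{key}: hardness B = {b:g} must be positive"))
    for element in sorted(wildcards & specific):
        findings.append(Finding(
            "info", f"element {element}: both wildcard and specific "
                    f"entries present (specific key wins)"))
    return findings
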