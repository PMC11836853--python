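"""Clinical code normalisation and the named code groups the algorithms use.

ICD-10 diagnosis and OPCS-4 procedure codes appear in the wild in mixed
spellings — dotted ("E83.1"), undotted ("E831"), lower case, padded with
whitespace. Every comparison in this package happens on a *normalised* form:
upper case with dots and whitespace removed, which makes the two spellings of
a code identical.

Code groups are sets of normalised prefixes. Matching is prefix matching, so
a three-character ICD-10 category such as ``D56`` (thalassaemia) captures all
of its four-character children (``D560``, ``D561``, ...), mirroring how
admitted-patient-care extracts store four-character codes without dots.

The shipped defaults define:

* ``G1`` — non-haemochromatosis conditions treated with venesection
  (polycythaemia vera, secondary polycythaemia, porphyria cutanea tarda);
* ``G2`` — haematological conditions associated with transfusion-related
  iron overload (thalassaemia, myelodysplasia, the leukaemias, ...);
* ``E831`` — the cohort-defining "disorders of iron metabolism" diagnosis;
* ``X362`` — the venesection procedure.

Users may load their own groups from a YAML mapping of group name to a list
of code strings in any dot dialect.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from enum import Enum
from importlib import resources
from pathlib import Path
from typing import Mapping, Sequence, Union

import yaml

__all__ = [
    "CodeSystem",
    "ClinicalCode",
    "CodeGroup",
    "InvalidCodeError",
    "normalize_code",
    "matches",
    "load_groups",
    "groups_from_yaml",
    "default_groups",
]


class InvalidCodeError(ValueError):
    """Raised for empty or malformed clinical codes."""


class CodeSystem(str, Enum):
    ICD10 = "ICD10"
    OPCS4 = "OPCS4"


# Normalised (dot-free, upper-case) shapes. OPCS-4 is letter + digits;
# ICD-10 allows a trailing letter in some national extensions.
_NORMALIZED_RE = {
    CodeSystem.ICD10: re.compile(r"^[A-Z][0-9A-Z]+$"),
    CodeSystem.OPCS4: re.compile(r"^[A-Z][0-9]+$"),
}
_PREFIX_RE = re.compile(r"^[A-Z][0-9A-Z]*$")


def _strip(raw: str) -> str:
    return re.sub(r"[.\s]", "", raw).upper()


@dataclass(frozen=True)
class ClinicalCode:
    """A single diagnosis or procedure code with its normalised form."""

    raw: str
    normalized: str
    system: CodeSystem


def normalize_code(raw: str, system: CodeSystem | str) -> ClinicalCode:
    """Normalise ``raw`` to upper case with dots and whitespace removed.

    Normalisation is idempotent: normalising an already-normalised code is a
    no-op. Raises :class:`InvalidCodeError` for empty input or a code that
    does not look like a code of ``system``.
    """
    system = CodeSystem(system)
    normalized = _strip(raw)
    if not normalized:
        raise InvalidCodeError(f"empty clinical code ({raw!r})")
    if not _NORMALIZED_RE[system].match(normalized):
        raise InvalidCodeError(f"{raw!r} is not a valid {system.value} code")
    return ClinicalCode(raw=raw, normalized=normalized, system=system)


@dataclass(frozen=True)
class CodeGroup:
    """A named set of normalised code prefixes with prefix-match semantics."""

    name: str
    prefixes: frozenset[str]

    def __post_init__(self) -> None:
        if not self.prefixes:
            raise InvalidCodeError(f"code group {self.name!r} is empty")
        for p in self.prefixes:
            if not _PREFIX_RE.match(p):
                raise InvalidCodeError(
                    f"group {self.name!r}: prefix {p!r} is not normalised"
                )
        for p in self.prefixes:
            for q in self.prefixes:
                if p != q and q.startswith(p):
                    raise InvalidCodeError(
                        f"group {self.name!r}: prefix {p!r} shadows {q!r}"
                    )

    def matches(self, code: Union[ClinicalCode, str]) -> bool:
        normalized = code.normalized if isinstance(code, ClinicalCode) else _strip(code)
        return any(normalized.startswith(p) for p in self.prefixes)


def matches(code: Union[ClinicalCode, str], group: CodeGroup) -> bool:
    """True iff some prefix of ``group`` is a leading substring of ``code``."""
    return group.matches(code)


def load_groups(mapping: Mapping[str, Sequence[str]]) -> dict[str, CodeGroup]:
    """Build validated :class:`CodeGroup` objects from a name → codes mapping.

    Codes may use any dot dialect; they are normalised here.
    """
    groups: dict[str, CodeGroup] = {}
    for name, codes in mapping.items():
        if isinstance(codes, str):
            codes = [codes]
        prefixes = frozenset(_strip(str(c)) for c in codes)
        if "" in prefixes:
            raise InvalidCodeError(f"group {name!r} contains an empty code")
        groups[str(name)] = CodeGroup(name=str(name), prefixes=prefixes)
    return groups


def groups_from_yaml(path: Union[str, Path]) -> dict[str, CodeGroup]:
    """Load code groups from a YAML file mapping group name to code list."""
    with open(path, "r", encoding="utf-8") as fh:
        mapping = yaml.safe_load(fh)
    if not isinstance(mapping, dict):
        raise InvalidCodeError(f"{path}: expected a mapping of group name to codes")
    return load_groups(mapping)


def default_groups() -> dict[str, CodeGroup]:
    """The shipped groups: G1, G2, E831 and X362."""
    text = resources.files("hhpheno.data").joinpath("code_groups.yaml").read_text()
    return load_groups(yaml.safe_load(text))
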