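"""Declarative phenotyping rules over per-patient code features.

Each algorithm is a data object, not a code branch: include patients whose
episodes carry the iron-metabolism diagnosis E83.1, require at least
``min_venesections`` episodes containing the venesection procedure X36.2,
then drop patients carrying any code in the named exclusion groups. The
seven shipped rules form a ladder from the raw E83.1 cohort ("0") to the
strictest rule ("6", at least ten venesection episodes with both exclusion
groups applied). Thresholds are inclusive ("five or more").
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

from .cohort import PatientRecord

__all__ = ["AlgorithmSpec", "Prediction", "builtin_algorithms", "classify", "run_algorithm"]


@dataclass(frozen=True)
class AlgorithmSpec:
    """One phenotyping rule.

    Parameters
    ----------
    name
        Short identifier ("0".."6" for the shipped rules).
    min_venesections
        Minimum number of episodes containing X36.2 (0 disables the
        requirement). Inclusive threshold.
    exclude_groups
        Names of code groups whose carriers are excluded (subset of
        {"G1", "G2"} for the shipped rules). Exclusions apply after
        inclusion.
    require_e831
        Always true for the shipped rules; kept explicit so custom rules
        can relax it.
    """

    name: str
    min_venesections: int = 0
    exclude_groups: frozenset[str] = field(default_factory=frozenset)
    require_e831: bool = True

    def __post_init__(self) -> None:
        if self.min_venesections < 0:
            raise ValueError("min_venesections must be non-negative")
        object.__setattr__(self, "exclude_groups", frozenset(self.exclude_groups))


@dataclass(frozen=True)
class Prediction:
    patient_id: str
    algorithm: str
    label: bool


def builtin_algorithms() -> list[AlgorithmSpec]:
    """The seven shipped rules, from the raw E83.1 cohort to the strictest."""
    return [
        AlgorithmSpec("0", 0, frozenset()),
        AlgorithmSpec("1", 0, frozenset({"G1", "G2"})),
        AlgorithmSpec("2", 1, frozenset()),
        AlgorithmSpec("3", 1, frozenset({"G1"})),
        AlgorithmSpec("4", 1, frozenset({"G1", "G2"})),
        AlgorithmSpec("5", 5, frozenset({"G1", "G2"})),
        AlgorithmSpec("6", 10, frozenset({"G1", "G2"})),
    ]


def get_algorithm(name: str, specs: Sequence[AlgorithmSpec] | None = None) -> AlgorithmSpec:
    specs = list(specs) if specs is not None else builtin_algorithms()
    for spec in specs:
        if spec.name == str(name):
            return spec
    raise KeyError(f"unknown algorithm {name!r}; known: {[s.name for s in specs]}")


_GROUP_FLAGS: Mapping[str, str] = {"G1": "has_g1_code", "G2": "has_g2_code"}


def classify(patient: PatientRecord, spec: AlgorithmSpec) -> bool:
    """Pure boolean rule: inclusion, venesection threshold, then exclusions."""
    if spec.require_e831 and not patient.has_e831:
        return False
    if patient.venesection_episodes < spec.min_venesections:
        return False
    for group in spec.exclude_groups:
        try:
            flag = _GROUP_FLAGS[group]
        except KeyError:
            raise KeyError(
                f"algorithm {spec.name!r} excludes unknown group {group!r}"
            ) from None
        if getattr(patient, flag):
            return False
    return True


def run_algorithm(
    patients: Iterable[PatientRecord], spec: AlgorithmSpec
) -> list[Prediction]:
    """Apply one rule to every patient; one prediction per patient."""
    predictions = [
        Prediction(patient_id=p.patient_id, algorithm=spec.name, label=classify(p, spec))
        for p in patients
    ]
    if not predictions:
        raise ValueError("no patients to classify")
    return predictions
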