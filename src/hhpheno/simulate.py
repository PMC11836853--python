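"""Synthetic inpatient cohort calibrated to the validation study's structure.

The generator emulates the gold-standard cohort of a published validation
study of code-based haemochromatosis phenotyping: 787 adult patients who
acquired the iron-metabolism diagnosis E83.1 over five years of
admitted-patient-care episodes, 9264 episodes in all, with the joint
distribution of chart-review diagnosis × venesection exposure fixed to the
study's published counts (479 C282Y homozygotes, 416 of them venesected;
159 patients without haemochromatosis gene mutations; and so on).

What the study does *not* print — how many treated patients fall in the
1–4 / 5–9 / ≥10 venesection-episode strata, and which patients carry G1/G2
exclusion codes — is **derived** by integer inversion of the published
sensitivity/specificity/PPV/NPV percentages (1 dp) against the class totals
479/308: for each algorithm the unique integer (tp, tn) pair reproducing
all four printed metrics is recovered, and differences between successive
algorithms pin down the exclusion-code carriage and venesection strata.
The inversion is a hard constraint checked at blueprint construction; an
inconsistent printed table raises :class:`InfeasibleBlueprintError`.

Only nuisance attributes (patient ids, dates, ages, sexes, within-stratum
venesection counts, filler admissions and distractor codes) are random;
every count that enters an accuracy table is fixed by the blueprint, so the
end-to-end pipeline reproduces the published accuracy tables for any seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from datetime import date, timedelta
from pathlib import Path
from typing import Mapping, Optional, Sequence, Union

import numpy as np

from .accuracy import ContingencyTable, round_half_up
from .codesets import CodeSystem, default_groups, normalize_code
from .cohort import (
    CATEGORY_DISPLAY,
    STUDY_WINDOW,
    Episode,
    GoldCategory,
    GoldLabel,
    write_episodes,
    write_gold_labels,
)

__all__ = [
    "TABLE_CATEGORY_COUNTS",
    "CALIBRATION_ACCURACY",
    "InfeasibleBlueprintError",
    "CohortBlueprint",
    "SyntheticCohort",
    "derive_strata",
    "generate",
    "write_fixture",
]


class InfeasibleBlueprintError(ValueError):
    """The blueprint's constraint set is internally inconsistent."""


#: Published diagnosis/genotype × venesection exposure of the gold-standard
#: cohort: category → (total patients, patients with ≥1 venesection episode).
TABLE_CATEGORY_COUNTS: dict[GoldCategory, tuple[int, int]] = {
    GoldCategory.C282Y_HOM: (479, 416),
    GoldCategory.C282Y_H63D: (107, 81),
    GoldCategory.C282Y_X: (17, 7),
    GoldCategory.H63D_HOM: (5, 5),
    GoldCategory.H63D_X: (5, 4),
    GoldCategory.HH_GENE_UNKNOWN: (10, 10),
    GoldCategory.RARER_MUTATION: (5, 5),
    GoldCategory.TRANSFUSION_OVERLOAD: (17, 6),
    GoldCategory.HYPERFERRITINAEMIA: (73, 24),
    GoldCategory.POLYCYTHAEMIA_VERA: (10, 10),
    GoldCategory.SECONDARY_POLYCYTHAEMIA: (4, 4),
    GoldCategory.PCT: (4, 3),
    GoldCategory.INCORRECT_CODING: (51, 6),
}

#: Published accuracy of algorithms 1–6 (percent, 1 dp):
#: algorithm → (sensitivity, specificity, PPV, NPV). These printed values
#: are the calibration input the strata are inverted from.
CALIBRATION_ACCURACY: dict[str, tuple[float, float, float, float]] = {
    "1": (98.7, 11.0, 63.3, 85.0),
    "2": (86.8, 46.4, 71.6, 69.4),
    "3": (86.2, 50.3, 73.0, 70.1),
    "4": (85.8, 53.9, 74.3, 70.9),
    "5": (76.4, 55.8, 72.9, 60.4),
    "6": (53.9, 71.1, 74.4, 49.8),
}

# Which gold categories carry planted exclusion codes, among venesected and
# non-venesected patients. Totals are forced by the inversion (12 venesected
# G1 carriers, 11 venesected G2 carriers, 11 non-venesected carriers among
# non-homozygotes; 3+2 venesected and 1 non-venesected among homozygotes);
# the split across categories follows the study's false-positive breakdown
# (8 of the 17 venesected patients with G1-category diagnoses keep no G1
# code; transfusion-overload patients carry G2 codes; the remainder is an
# explicit blueprint assumption).
HOM_VEN_G1 = 3  # homozygotes incorrectly co-coded as polycythaemia
HOM_VEN_G2 = 2  # homozygotes with concurrent leukaemia
HOM_NONVEN_G2 = 1  # assumption: the sixth homozygote carrier, untreated

NONHOM_VEN_G1_PLAN: dict[GoldCategory, int] = {
    GoldCategory.POLYCYTHAEMIA_VERA: 5,
    GoldCategory.SECONDARY_POLYCYTHAEMIA: 3,
    GoldCategory.PCT: 1,
    GoldCategory.C282Y_H63D: 1,
    GoldCategory.HYPERFERRITINAEMIA: 2,
}
NONHOM_VEN_G2_PLAN: dict[GoldCategory, int] = {
    GoldCategory.TRANSFUSION_OVERLOAD: 6,
    GoldCategory.C282Y_H63D: 2,
    GoldCategory.HYPERFERRITINAEMIA: 2,
    GoldCategory.C282Y_X: 1,
}
NONHOM_NONVEN_G2_PLAN: dict[GoldCategory, int] = {
    GoldCategory.TRANSFUSION_OVERLOAD: 11,
}

# Innocuous distractor diagnoses for filler admissions; none matches the
# E831/G1/G2 groups.
_DISTRACTOR_CODES = (
    "I10", "E119", "J449", "K219", "M545", "N390", "R073",
    "I489", "E785", "F329", "G409", "L309", "K590", "R104",
)


def _render1(numerator: int, denominator: int) -> float:
    return round_half_up(100.0 * numerator / denominator)


def derive_strata(
    metrics: Mapping[str, tuple[float, float, float, float]] = CALIBRATION_ACCURACY,
    class_totals: tuple[int, int] = (479, 308),
) -> dict[str, ContingencyTable]:
    """Invert printed accuracy percentages to integer contingency tables.

    For each algorithm, searches the integers near sensitivity×P and
    specificity×N for the (tp, tn) pair whose 2×2 table reproduces all four
    printed metrics at 1 dp (half-up). Raises
    :class:`InfeasibleBlueprintError` if no integer cell works; if several
    do, the pair closest to the real-valued inversion is taken.
    """
    positives, negatives = class_totals
    tables: dict[str, ContingencyTable] = {}
    for name, (sens, spec, ppv, npv) in metrics.items():
        tp_center = sens * positives / 100.0
        tn_center = spec * negatives / 100.0
        candidates: list[tuple[float, ContingencyTable]] = []
        for tp in range(max(0, round(tp_center) - 3), min(positives, round(tp_center) + 3) + 1):
            for tn in range(max(0, round(tn_center) - 3), min(negatives, round(tn_center) + 3) + 1):
                fn, fp = positives - tp, negatives - tn
                if tp + fp == 0 or fn + tn == 0:
                    continue
                if (
                    _render1(tp, positives) == sens
                    and _render1(tn, negatives) == spec
                    and _render1(tp, tp + fp) == ppv
                    and _render1(tn, fn + tn) == npv
                ):
                    distance = abs(tp - tp_center) + abs(tn - tn_center)
                    candidates.append((distance, ContingencyTable(tp, fp, fn, tn)))
        if not candidates:
            raise InfeasibleBlueprintError(
                f"algorithm {name}: no integer contingency table reproduces the "
                f"printed metrics {metrics[name]} with class totals {class_totals}"
            )
        tables[name] = min(candidates, key=lambda c: c[0])[1]
    return tables


@dataclass(frozen=True)
class CohortBlueprint:
    """Everything the generator needs; validated at construction.

    The venesection-frequency strata and exclusion-code carriage are not
    free parameters — they are recomputed from ``calibration`` via
    :func:`derive_strata` and audited against the category plans and
    algorithm-nesting monotonicity.
    """

    category_counts: Mapping[GoldCategory, tuple[int, int]] = field(
        default_factory=lambda: dict(TABLE_CATEGORY_COUNTS)
    )
    calibration: Mapping[str, tuple[float, float, float, float]] = field(
        default_factory=lambda: dict(CALIBRATION_ACCURACY)
    )
    total_episodes: int = 9264
    male_patients: int = 460  # of 787 (58.4%)
    hom_age_mean: float = 59.0
    other_age_mean: float = 69.0
    age_sd: float = 13.0
    min_age: int = 18
    max_age: int = 100
    window: tuple[date, date] = STUDY_WINDOW
    rng_seed: int = 0
    n_distractors: int = 0  # extra non-E83.1 patients outside the cohort
    geometric_tail_p: float = 0.3  # shape of the ≥10 venesection stratum

    # ---- derived structure -------------------------------------------------

    @property
    def n_patients(self) -> int:
        return sum(total for total, _ in self.category_counts.values())

    @property
    def class_totals(self) -> tuple[int, int]:
        positives = self.category_counts[GoldCategory.C282Y_HOM][0]
        return positives, self.n_patients - positives

    @property
    def contingency_targets(self) -> dict[str, ContingencyTable]:
        return derive_strata(self.calibration, self.class_totals)

    @property
    def hom_strata(self) -> tuple[int, int, int]:
        """Venesected homozygotes without exclusion codes in the 1–4 / 5–9 / ≥10 strata."""
        t = self.contingency_targets
        return (t["4"].tp - t["5"].tp, t["5"].tp - t["6"].tp, t["6"].tp)

    @property
    def nonhom_strata(self) -> tuple[int, int, int]:
        """Venesected non-homozygotes without exclusion codes, same strata."""
        t = self.contingency_targets
        return (t["4"].fp - t["5"].fp, t["5"].fp - t["6"].fp, t["6"].fp)

    def __post_init__(self) -> None:
        counts = self.category_counts
        for cat, (total, venesected) in counts.items():
            if not 0 <= venesected <= total:
                raise InfeasibleBlueprintError(
                    f"{cat.value}: venesected {venesected} exceeds total {total}"
                )
        targets = self.contingency_targets
        positives, negatives = self.class_totals
        hom_ven = counts[GoldCategory.C282Y_HOM][1]
        nonhom_ven = sum(
            v for c, (_, v) in counts.items() if c is not GoldCategory.C282Y_HOM
        )

        # Nesting monotonicity of the derived targets (2 ⊇ 3 ⊇ 4 ⊇ 5 ⊇ 6).
        order = ["2", "3", "4", "5", "6"]
        for a, b in zip(order, order[1:]):
            if not (targets[a].tp >= targets[b].tp and targets[a].fp >= targets[b].fp):
                raise InfeasibleBlueprintError(
                    f"derived targets break nesting between algorithms {a} and {b}"
                )

        # Homozygote carriage must reconcile with the inversion.
        hom_carriers = positives - targets["1"].tp
        if HOM_VEN_G1 != targets["2"].tp - targets["3"].tp:
            raise InfeasibleBlueprintError("homozygote G1 carriage disagrees with inversion")
        if HOM_VEN_G2 != targets["3"].tp - targets["4"].tp:
            raise InfeasibleBlueprintError("homozygote G2 carriage disagrees with inversion")
        if HOM_VEN_G1 + HOM_VEN_G2 + HOM_NONVEN_G2 != hom_carriers:
            raise InfeasibleBlueprintError(
                f"homozygote exclusion carriers {hom_carriers} not matched by plan"
            )

        # Non-homozygote carriage plans.
        ven_g1 = sum(NONHOM_VEN_G1_PLAN.values())
        ven_g2 = sum(NONHOM_VEN_G2_PLAN.values())
        nonven = sum(NONHOM_NONVEN_G2_PLAN.values())
        if ven_g1 != targets["2"].fp - targets["3"].fp:
            raise InfeasibleBlueprintError("venesected non-homozygote G1 plan disagrees")
        if ven_g2 != targets["3"].fp - targets["4"].fp:
            raise InfeasibleBlueprintError("venesected non-homozygote G2 plan disagrees")
        if ven_g1 + ven_g2 + nonven != targets["1"].tn:
            raise InfeasibleBlueprintError("non-homozygote exclusion carriers disagree")
        for plan, pick_ven in (
            (NONHOM_VEN_G1_PLAN, True),
            (NONHOM_VEN_G2_PLAN, True),
            (NONHOM_NONVEN_G2_PLAN, False),
        ):
            for cat, k in plan.items():
                total, venesected = counts[cat]
                available = venesected if pick_ven else total - venesected
                if k > available:
                    raise InfeasibleBlueprintError(
                        f"{cat.value}: plan requests {k} carriers but only "
                        f"{available} patients available"
                    )
        overlap = set(NONHOM_VEN_G1_PLAN) & set(NONHOM_VEN_G2_PLAN)
        for cat in overlap:
            total, venesected = counts[cat]
            need = NONHOM_VEN_G1_PLAN[cat] + NONHOM_VEN_G2_PLAN[cat]
            if need > venesected:
                raise InfeasibleBlueprintError(f"{cat.value}: G1+G2 plan exceeds venesected")

        # Strata must partition the eligible venesected patients.
        if sum(self.hom_strata) != hom_ven - HOM_VEN_G1 - HOM_VEN_G2:
            raise InfeasibleBlueprintError("homozygote venesection strata do not partition")
        if sum(self.nonhom_strata) != nonhom_ven - ven_g1 - ven_g2:
            raise InfeasibleBlueprintError("non-homozygote venesection strata do not partition")

        if not 0 <= self.male_patients <= self.n_patients:
            raise InfeasibleBlueprintError("male_patients out of range")
        # Every patient needs an index episode and every venesection its own
        # episode; the stratum floors give the minimum feasible volume.
        floors = (
            self.n_patients
            + sum(n * lo for n, lo in zip(self.hom_strata, (1, 5, 10)))
            + sum(n * lo for n, lo in zip(self.nonhom_strata, (1, 5, 10)))
            + (HOM_VEN_G1 + HOM_VEN_G2 + ven_g1 + ven_g2)
        )
        if self.total_episodes < floors:
            raise InfeasibleBlueprintError(
                f"total_episodes {self.total_episodes} below feasible minimum {floors}"
            )

    @classmethod
    def default(cls, seed: int = 0, n_distractors: int = 0) -> "CohortBlueprint":
        return cls(rng_seed=seed, n_distractors=n_distractors)

    def to_dict(self) -> dict:
        targets = self.contingency_targets
        return {
            "n_patients": self.n_patients,
            "total_episodes": self.total_episodes,
            "class_totals": list(self.class_totals),
            "category_counts": {
                CATEGORY_DISPLAY[c]: list(v) for c, v in self.category_counts.items()
            },
            "contingency_targets": {
                name: [t.tp, t.fp, t.fn, t.tn] for name, t in targets.items()
            },
            "hom_strata_1to4_5to9_ge10": list(self.hom_strata),
            "nonhom_strata_1to4_5to9_ge10": list(self.nonhom_strata),
            "male_patients": self.male_patients,
            "age_model": {
                "hom_mean": self.hom_age_mean,
                "other_mean": self.other_age_mean,
                "sd": self.age_sd,
                "min": self.min_age,
                "max": self.max_age,
            },
            "window": [self.window[0].isoformat(), self.window[1].isoformat()],
            "rng_seed": self.rng_seed,
            "n_distractors": self.n_distractors,
        }


@dataclass(frozen=True)
class SyntheticCohort:
    episodes: list[Episode]
    labels: list[GoldLabel]
    blueprint: CohortBlueprint
    seed: int


@dataclass
class _PatientPlan:
    category: GoldCategory
    venesected: bool
    has_g1: bool = False
    has_g2: bool = False
    venesections: int = 0
    patient_id: str = ""
    age: int = 0
    sex: str = "F"
    n_filler: int = 0


def _build_plans(bp: CohortBlueprint) -> list[_PatientPlan]:
    """Fixed-order patient plans with exclusion-code carriage assigned."""
    plans: list[_PatientPlan] = []
    for cat in GoldCategory:
        total, venesected = bp.category_counts[cat]
        if cat is GoldCategory.C282Y_HOM:
            g1_ven, g2_ven, g2_nonven = HOM_VEN_G1, HOM_VEN_G2, HOM_NONVEN_G2
        else:
            g1_ven = NONHOM_VEN_G1_PLAN.get(cat, 0)
            g2_ven = NONHOM_VEN_G2_PLAN.get(cat, 0)
            g2_nonven = NONHOM_NONVEN_G2_PLAN.get(cat, 0)
        for i in range(total):
            is_ven = i < venesected
            if is_ven:
                has_g1 = i < g1_ven
                has_g2 = g1_ven <= i < g1_ven + g2_ven
            else:
                has_g1 = False
                has_g2 = (i - venesected) < g2_nonven
            plans.append(_PatientPlan(cat, is_ven, has_g1, has_g2))
    return plans


def _assign_venesection_counts(
    plans: Sequence[_PatientPlan], bp: CohortBlueprint, rng: np.random.Generator
) -> None:
    """Draw per-patient venesection-episode counts honouring the strata."""

    def draw(stratum: int) -> int:
        if stratum == 0:
            return int(rng.integers(1, 5))
        if stratum == 1:
            return int(rng.integers(5, 10))
        # ≥10: floor plus a capped geometric tail.
        return 10 + min(int(rng.geometric(bp.geometric_tail_p)) - 1, 15)

    for is_hom, strata in ((True, bp.hom_strata), (False, bp.nonhom_strata)):
        eligible = [
            p
            for p in plans
            if (p.category is GoldCategory.C282Y_HOM) == is_hom
            and p.venesected
            and not (p.has_g1 or p.has_g2)
        ]
        membership = np.repeat([0, 1, 2], strata)
        rng.shuffle(membership)
        if len(membership) != len(eligible):
            raise InfeasibleBlueprintError("stratum totals do not match eligible patients")
        for plan, stratum in zip(eligible, membership):
            plan.venesections = draw(int(stratum))
    # Carriers are excluded from every venesection-threshold rule, so their
    # counts are free; keep them low.
    for p in plans:
        if p.venesected and (p.has_g1 or p.has_g2):
            p.venesections = int(rng.integers(1, 5))


def _trim_to_budget(plans: Sequence[_PatientPlan], budget: int) -> None:
    """Shave ≥10-stratum tails (never below 10) if the draw exceeds budget."""
    excess = sum(p.venesections for p in plans) + len(plans) - budget
    if excess <= 0:
        return
    tails = sorted(
        (p for p in plans if p.venesections > 10),
        key=lambda p: p.venesections,
        reverse=True,
    )
    for p in tails:
        if excess <= 0:
            break
        cut = min(p.venesections - 10, excess)
        p.venesections -= cut
        excess -= cut
    if excess > 0:
        raise InfeasibleBlueprintError("episode budget below stratum floors")


def _plant_code(prefix: str, rng: np.random.Generator) -> str:
    """A concrete code under a group prefix (3-char categories get a child)."""
    return prefix if len(prefix) >= 4 else prefix + str(int(rng.integers(0, 10)))


def generate(blueprint: Optional[CohortBlueprint] = None, seed: Optional[int] = None) -> SyntheticCohort:
    """Generate the calibrated synthetic cohort.

    Identical ``(blueprint, seed)`` reproduces the cohort bit-for-bit;
    different seeds change only nuisance attributes (ids, ages, dates,
    within-stratum counts), never the accuracy tables.
    """
    bp = blueprint if blueprint is not None else CohortBlueprint.default()
    seed = bp.rng_seed if seed is None else int(seed)
    rng = np.random.default_rng(seed)
    groups = default_groups()
    g1_prefixes = sorted(groups["G1"].prefixes)
    g2_prefixes = sorted(groups["G2"].prefixes)

    plans = _build_plans(bp)
    n = len(plans)
    _assign_venesection_counts(plans, bp, rng)
    _trim_to_budget(plans, bp.total_episodes)

    # Nuisance attributes.
    id_order = rng.permutation(n)
    width = max(4, len(str(n)))
    male = np.zeros(n, dtype=bool)
    male[rng.permutation(n)[: bp.male_patients]] = True
    filler_total = bp.total_episodes - n - sum(p.venesections for p in plans)
    filler = rng.multinomial(filler_total, np.full(n, 1.0 / n))
    for i, p in enumerate(plans):
        p.patient_id = f"SYN{id_order[i] + 1:0{width}d}"
        mean = bp.hom_age_mean if p.category is GoldCategory.C282Y_HOM else bp.other_age_mean
        p.age = int(np.clip(round(rng.normal(mean, bp.age_sd)), bp.min_age, bp.max_age))
        p.sex = "M" if male[i] else "F"
        p.n_filler = int(filler[i])

    window_days = (bp.window[1] - bp.window[0]).days
    e831 = normalize_code("E83.1", CodeSystem.ICD10)
    x362 = normalize_code("X36.2", CodeSystem.OPCS4)

    episodes: list[Episode] = []
    for p in plans:
        n_ep = 1 + p.venesections + p.n_filler
        offsets = np.sort(rng.integers(0, window_days + 1, size=n_ep))
        extra: list = []
        if p.has_g1:
            extra.append(_plant_code(str(rng.choice(g1_prefixes)), rng))
        if p.has_g2:
            extra.append(_plant_code(str(rng.choice(g2_prefixes)), rng))
        for k, off in enumerate(offsets):
            admission = bp.window[0] + timedelta(days=int(off))
            age = p.age + int(off - offsets[0]) // 365
            if k == 0:
                diagnoses = [e831] + [
                    normalize_code(c, CodeSystem.ICD10) for c in extra
                ]
                procedures: list = []
            elif k <= p.venesections:
                diagnoses = [e831]
                procedures = [x362]
            else:
                diagnoses = [
                    normalize_code(str(rng.choice(_DISTRACTOR_CODES)), CodeSystem.ICD10)
                ]
                procedures = []
            episodes.append(
                Episode(
                    patient_id=p.patient_id,
                    episode_id=f"{p.patient_id}-E{k + 1:03d}",
                    admission_date=admission,
                    age_at_admission=age,
                    sex=p.sex,
                    diagnoses=tuple(diagnoses),
                    procedures=tuple(procedures),
                )
            )

    # Optional distractor patients (not part of the gold-labelled cohort):
    # the first is an under-age E83.1 carrier, the rest never carry E83.1;
    # baseline selection must remove them all.
    for d in range(bp.n_distractors):
        pid = f"DIS{d + 1:03d}"
        underage = d == 0
        n_ep = int(rng.integers(1, 4))
        offsets = np.sort(rng.integers(0, window_days + 1, size=n_ep))
        age = 17 if underage else int(rng.integers(18, 90))
        sex = "M" if rng.integers(0, 2) else "F"
        for k, off in enumerate(offsets):
            code = "E83.1" if (underage and k == 0) else str(rng.choice(_DISTRACTOR_CODES))
            episodes.append(
                Episode(
                    patient_id=pid,
                    episode_id=f"{pid}-E{k + 1:03d}",
                    admission_date=bp.window[0] + timedelta(days=int(off)),
                    age_at_admission=age,
                    sex=sex,
                    diagnoses=(normalize_code(code, CodeSystem.ICD10),),
                    procedures=(),
                )
            )

    episodes.sort(key=lambda e: (e.patient_id, e.admission_date, e.episode_id))
    labels = sorted(
        (GoldLabel(patient_id=p.patient_id, category=p.category) for p in plans),
        key=lambda l: l.patient_id,
    )
    return SyntheticCohort(episodes=episodes, labels=labels, blueprint=bp, seed=seed)


def write_fixture(cohort: SyntheticCohort, out_dir: Union[str, Path]) -> dict[str, Path]:
    """Write episodes.csv, labels.csv and manifest.json under ``out_dir``."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "episodes": out / "episodes.csv",
        "labels": out / "labels.csv",
        "manifest": out / "manifest.json",
    }
    write_episodes(cohort.episodes, paths["episodes"])
    write_gold_labels(cohort.labels, paths["labels"])
    manifest = {
        "seed": cohort.seed,
        "n_patients": len(cohort.labels),
        "n_episodes": len(cohort.episodes),
        "blueprint": cohort.blueprint.to_dict(),
    }
    paths["manifest"].write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    return paths
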