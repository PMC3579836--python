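"""Kin-discrimination (KD) and individual-discrimination (ID) triad design.

A KD triad shows a parent (target) above two same-sex, age-matched
(<= 2 years apart) alternatives: the parent's offspring (match) and an
individual demonstrably unrelated for two generations to both (decoy).
An ID triad shows a frontal target above a three-quarter view of the
same animal (match) and of an unrelated age/sex-matched animal (decoy).
Sessions of 32 KD + 12 ID trials are produced by restricted
randomization: the session is partitioned into four quarters, each
holding two trials of every KD condition and three ID trials, with the
correct side counterbalanced 22 left / 22 right.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .kinship import (
    KinshipCalculator,
    expected_relatedness,
    unrelated_two_generations,
)
from .pedigree import Pedigree

__all__ = [
    "Triad",
    "SessionSchedule",
    "DesignError",
    "KD_CONDITIONS",
    "ID_CONDITIONS",
    "build_kd_triads",
    "build_id_triads",
    "randomize_session",
    "distinct_animals",
    "validate_kd_triads",
    "validate_id_triads",
    "validate_schedule",
]

KD_CONDITIONS = ("mother-daughter", "mother-son", "father-daughter", "father-son")
ID_CONDITIONS = ("male-left", "male-right", "female-left", "female-right")

#: decoys must stay below this expected relatedness when ancestry is
#: incompletely resolved (the two-generation screen's r bound)
DECOY_R_THRESHOLD = 0.063

MIN_AGE_YEARS = 4.0
AGE_TOLERANCE_YEARS = 2.0


class DesignError(RuntimeError):
    """Raised when the image inventory cannot fill the design."""


@dataclass(frozen=True)
class Triad:
    triad_id: str
    kind: str  # "KD" or "ID"
    condition: str
    target: str  # individual ids
    match: str
    decoy: str
    target_image: str
    match_image: str
    decoy_image: str
    facing: str | None = None  # ID triads: "left" or "right"


@dataclass
class SessionSchedule:
    """Participant-specific restricted-randomized trial order."""

    participant: str
    trials: pd.DataFrame  # position, triad_id, side_correct
    break_after: int = 22  # pause between the session halves


class _Inventory:
    """Indexed view of an image-inventory table."""

    def __init__(self, inventory: pd.DataFrame, pedigree: Pedigree):
        self.pedigree = pedigree
        self.frontal: dict[str, dict] = {}
        self.three_quarter: dict[tuple[str, str], dict] = {}
        for row in inventory.to_dict("records"):
            ind = str(row["individual_id"])
            if ind not in pedigree:
                continue
            if row["orientation"] == "frontal":
                self.frontal.setdefault(ind, row)
            elif row["orientation"] == "three_quarter_left":
                self.three_quarter.setdefault((ind, "left"), row)
            elif row["orientation"] == "three_quarter_right":
                self.three_quarter.setdefault((ind, "right"), row)

    def age(self, ind: str, row: dict) -> float:
        return float(row["photo_date"]) - self.pedigree.birth(ind)


def _screen_unrelated(
    a: str,
    b: str,
    pedigree: Pedigree,
    unresolved: Mapping[str, Sequence[str]] | None,
    avoidance_r: float,
) -> bool:
    if unrelated_two_generations(a, b, pedigree, unresolved=unresolved):
        return True
    if unresolved and (a in unresolved or b in unresolved):
        er = expected_relatedness(a, b, pedigree, unresolved, avoidance_r=avoidance_r)
        return er.expected_r < DECOY_R_THRESHOLD
    return False


def build_kd_triads(
    pedigree: Pedigree,
    inventory: pd.DataFrame,
    seed: int = 0,
    n_per_condition: int = 8,
    target_reuses: int = 5,
    age_tolerance: float = AGE_TOLERANCE_YEARS,
    min_age: float = MIN_AGE_YEARS,
    unresolved: Mapping[str, Sequence[str]] | None = None,
    avoidance_r: float = 0.25,
    max_attempts: int = 50,
) -> list[Triad]:
    """Build the kin-discrimination stimulus set.

    Exactly ``target_reuses`` father images are used twice, once as the
    target of a father-daughter and once of a father-son triad
    (mirroring the scarcity of well-imaged genetically assigned sires);
    every other image and individual appears exactly once, so the
    default design (32 triads, 5 single reuses) spans 91 distinct
    animals.  Matching is randomized greedy with restarts; an infeasible
    inventory raises :class:`DesignError` naming the unfillable
    condition.
    """
    inv = _Inventory(inventory, pedigree)
    kin = KinshipCalculator.from_pedigree(pedigree)

    adults = {
        ind: row
        for ind, row in inv.frontal.items()
        if inv.age(ind, row) >= min_age
    }
    dyads: dict[str, list[tuple[str, str]]] = {c: [] for c in KD_CONDITIONS}
    for child in pedigree.ids:
        if child not in adults:
            continue
        for parent in pedigree.parents(child):
            if parent is None or parent not in adults:
                continue
            line = "mother" if pedigree.sex(parent) == "F" else "father"
            kid = "daughter" if pedigree.sex(child) == "F" else "son"
            dyads[f"{line}-{kid}"].append((parent, child))

    last_failure = "unknown"
    for attempt in range(max_attempts):
        rng = np.random.default_rng((int(seed), 11, attempt))
        result = _try_build_kd(
            pedigree, inv, kin, adults, dyads, rng,
            n_per_condition, target_reuses, age_tolerance,
            unresolved, avoidance_r,
        )
        if isinstance(result, list):
            return result
        last_failure = result
    raise DesignError(f"could not fill KD design: {last_failure}")


def _try_build_kd(
    pedigree, inv, kin, adults, dyads, rng,
    n_per_condition, target_reuses, age_tolerance, unresolved, avoidance_r,
):
    used: set[str] = set()
    chosen: dict[str, list[tuple[str, str]]] = {c: [] for c in KD_CONDITIONS}

    # fathers reused across the two paternal conditions
    shared_fathers = []
    if target_reuses > 0:
        fd = {p for p, _ in dyads["father-daughter"]}
        fs = {p for p, _ in dyads["father-son"]}
        both = sorted(fd & fs)
        rng.shuffle(both)
        shared_fathers = both[:target_reuses]
        if len(shared_fathers) < target_reuses:
            return (
                "not enough fathers with both adult daughters and sons "
                "(conditions father-daughter, father-son)"
            )
        for father in shared_fathers:
            used.add(father)
            for cond in ("father-daughter", "father-son"):
                options = [
                    (p, c) for p, c in dyads[cond] if p == father and c not in used
                ]
                if not options:
                    return f"no unused offspring for reused father in {cond}"
                pick = options[int(rng.integers(len(options)))]
                chosen[cond].append(pick)
                used.add(pick[1])

    for cond in KD_CONDITIONS:
        pool = list(dyads[cond])
        rng.shuffle(pool)
        for parent, child in pool:
            if len(chosen[cond]) >= n_per_condition:
                break
            if parent in used or child in used:
                continue
            chosen[cond].append((parent, child))
            used.update((parent, child))
        if len(chosen[cond]) < n_per_condition:
            return f"condition {cond} unfillable: too few parent-offspring dyads"

    triads: list[Triad] = []
    serial = 1
    for cond in KD_CONDITIONS:
        for parent, child in chosen[cond]:
            decoy = _pick_decoy(
                target=parent, match=child, pedigree=pedigree, inv=inv,
                adults=adults, used=used, age_tolerance=age_tolerance,
                unresolved=unresolved, avoidance_r=avoidance_r,
            )
            if decoy is None:
                return f"condition {cond} unfillable: no admissible decoy"
            used.add(decoy)
            triads.append(
                Triad(
                    triad_id=f"KD{serial:02d}",
                    kind="KD",
                    condition=cond,
                    target=parent,
                    match=child,
                    decoy=decoy,
                    target_image=inv.frontal[parent]["image_id"],
                    match_image=inv.frontal[child]["image_id"],
                    decoy_image=inv.frontal[decoy]["image_id"],
                )
            )
            serial += 1
    return triads


def _pick_decoy(
    target, match, pedigree, inv, adults, used, age_tolerance,
    unresolved, avoidance_r,
):
    match_row = inv.frontal[match]
    match_age = inv.age(match, match_row)
    match_sex = pedigree.sex(match)
    lighting = match_row["lighting_class"]
    candidates = []
    for ind, row in adults.items():
        if ind in used or ind in (target, match):
            continue
        if pedigree.sex(ind) != match_sex:
            continue
        if row["lighting_class"] != lighting:
            continue
        gap = abs(inv.age(ind, row) - match_age)
        if gap > age_tolerance:
            continue
        candidates.append((gap, ind))
    # smallest age gap first, lexicographic id as the tie-break
    for gap, ind in sorted(candidates):
        if _screen_unrelated(ind, target, pedigree, unresolved, avoidance_r) and (
            _screen_unrelated(ind, match, pedigree, unresolved, avoidance_r)
        ):
            return ind
    return None


def build_id_triads(
    pedigree: Pedigree,
    inventory: pd.DataFrame,
    seed: int = 0,
    n_per_sex: int = 6,
    age_tolerance: float = AGE_TOLERANCE_YEARS,
    min_age: float = MIN_AGE_YEARS,
    exclude: Sequence[str] = (),
    age_range: tuple[float, float] | None = None,
    unresolved: Mapping[str, Sequence[str]] | None = None,
    avoidance_r: float = 0.25,
    max_attempts: int = 50,
) -> list[Triad]:
    """Build the individual-discrimination set.

    Twelve triads by default: six per sex, and within each sex half the
    three-quarter image pairs face left, half right.  ``age_range``
    (e.g. the KD parents-and-offspring span) restricts the sampled ages;
    ``exclude`` keeps KD animals out of the ID set.
    """
    if n_per_sex % 2:
        raise ValueError("n_per_sex must be even (left/right facings are balanced)")
    inv = _Inventory(inventory, pedigree)
    excluded = set(exclude)

    def usable(ind: str) -> bool:
        row = inv.frontal.get(ind)
        if row is None or ind in excluded:
            return False
        age = inv.age(ind, row)
        if age < min_age:
            return False
        if age_range is not None and not (age_range[0] <= age <= age_range[1]):
            return False
        return (ind, "left") in inv.three_quarter and (
            ind,
            "right",
        ) in inv.three_quarter

    by_sex = {"M": [], "F": []}
    for ind in inv.frontal:
        if usable(ind):
            by_sex[pedigree.sex(ind)].append(ind)
    for sex_code, name in (("M", "male"), ("F", "female")):
        if len(by_sex[sex_code]) < 2 * n_per_sex:
            raise DesignError(
                f"inventory cannot fill {name} ID triads "
                f"({len(by_sex[sex_code])} usable individuals, "
                f"{2 * n_per_sex} needed)"
            )

    last_failure = "unknown"
    for attempt in range(max_attempts):
        rng = np.random.default_rng((int(seed), 13, attempt))
        triads: list[Triad] = []
        used: set[str] = set()
        serial = 1
        failed = None
        for sex_code, name in (("M", "male"), ("F", "female")):
            pool = sorted(by_sex[sex_code])
            rng.shuffle(pool)
            facings = ["left"] * (n_per_sex // 2) + ["right"] * (n_per_sex // 2)
            built = 0
            for subject in pool:
                if built >= n_per_sex:
                    break
                if subject in used:
                    continue
                facing = facings[built]
                subj_row = inv.three_quarter[(subject, facing)]
                decoy = _pick_id_decoy(
                    subject, facing, pool, used, inv, pedigree,
                    age_tolerance, subj_row, unresolved, avoidance_r,
                )
                if decoy is None:
                    continue
                used.update((subject, decoy))
                triads.append(
                    Triad(
                        triad_id=f"ID{serial:02d}",
                        kind="ID",
                        condition=f"{name}-{facing}",
                        target=subject,
                        match=subject,
                        decoy=decoy,
                        target_image=inv.frontal[subject]["image_id"],
                        match_image=subj_row["image_id"],
                        decoy_image=inv.three_quarter[(decoy, facing)]["image_id"],
                        facing=facing,
                    )
                )
                serial += 1
                built += 1
            if built < n_per_sex:
                failed = f"could not fill {name} ID triads (decoy constraints)"
                break
        if failed is None:
            return triads
        last_failure = failed
    raise DesignError(f"could not fill ID design: {last_failure}")


def _pick_id_decoy(
    subject, facing, pool, used, inv, pedigree, age_tolerance, subj_row,
    unresolved, avoidance_r,
):
    subj_age = inv.age(subject, subj_row)
    lighting = subj_row["lighting_class"]
    candidates = []
    for ind in pool:
        if ind == subject or ind in used:
            continue
        row = inv.three_quarter[(ind, facing)]
        if row["lighting_class"] != lighting:
            continue
        gap = abs(inv.age(ind, row) - subj_age)
        if gap > age_tolerance:
            continue
        candidates.append((gap, ind))
    for gap, ind in sorted(candidates):
        if _screen_unrelated(ind, subject, pedigree, unresolved, avoidance_r):
            return ind
    return None


# ---------------------------------------------------------------------------
# session randomization
# ---------------------------------------------------------------------------


def randomize_session(
    kd_triads: Sequence[Triad],
    id_triads: Sequence[Triad],
    participant: str,
    participant_seed: int,
) -> SessionSchedule:
    """Restricted randomization of the 44 trials for one participant.

    The session is split into four quarters of 11 trials; each quarter
    holds two triads of every KD condition and three ID trials (ID
    conditions rotate so each appears once in three of the four
    quarters).  The correct side is counterbalanced exactly 22 left /
    22 right: four of the eight triads per KD condition are left, and
    the ID left quota is rotated over conditions.
    """
    kd = list(kd_triads)
    idt = list(id_triads)
    if len(kd) != 32 or len(idt) != 12:
        raise ValueError("session needs exactly 32 KD and 12 ID triads")
    rng = np.random.default_rng((int(participant_seed), 17))

    sides: dict[str, str] = {}
    kd_by_cond: dict[str, list[Triad]] = {c: [] for c in KD_CONDITIONS}
    for t in kd:
        kd_by_cond[t.condition].append(t)
    for cond, group in kd_by_cond.items():
        if len(group) != 8:
            raise ValueError(f"KD condition {cond} has {len(group)} triads, not 8")
        marks = np.array(["left"] * 4 + ["right"] * 4)
        rng.shuffle(marks)
        for t, s in zip(group, marks):
            sides[t.triad_id] = str(s)

    id_by_cond: dict[str, list[Triad]] = {c: [] for c in ID_CONDITIONS}
    for t in idt:
        id_by_cond[t.condition].append(t)
    quotas = [2, 2, 1, 1]  # lefts per ID condition: 6 left / 6 right overall
    cond_order = list(ID_CONDITIONS)
    rng.shuffle(cond_order)
    for cond, quota in zip(cond_order, quotas):
        group = id_by_cond[cond]
        if len(group) != 3:
            raise ValueError(f"ID condition {cond} has {len(group)} triads, not 3")
        marks = np.array(["left"] * quota + ["right"] * (3 - quota))
        rng.shuffle(marks)
        for t, s in zip(group, marks):
            sides[t.triad_id] = str(s)

    # quarter assignment
    quarters: list[list[Triad]] = [[] for _ in range(4)]
    for cond, group in kd_by_cond.items():
        order = np.array(group, dtype=object)
        rng.shuffle(order)
        for q in range(4):
            quarters[q].extend(order[2 * q : 2 * q + 2])
    id_stacks = {
        c: list(rng.permutation(np.array(id_by_cond[c], dtype=object)))
        for c in ID_CONDITIONS
    }
    for q in range(4):
        for i in range(3):
            cond = ID_CONDITIONS[(q + i) % 4]
            quarters[q].append(id_stacks[cond].pop())

    rows = []
    position = 1
    for q in range(4):
        block = np.array(quarters[q], dtype=object)
        rng.shuffle(block)
        for t in block:
            rows.append(
                {
                    "position": position,
                    "triad_id": t.triad_id,
                    "side_correct": sides[t.triad_id],
                }
            )
            position += 1
    return SessionSchedule(
        participant=participant, trials=pd.DataFrame(rows), break_after=22
    )


# ---------------------------------------------------------------------------
# validation
# ---------------------------------------------------------------------------


def distinct_animals(triads: Sequence[Triad]) -> int:
    out: set[str] = set()
    for t in triads:
        out.update((t.target, t.match, t.decoy))
    return len(out)


def validate_kd_triads(
    triads: Sequence[Triad],
    pedigree: Pedigree,
    inventory: pd.DataFrame,
    n_per_condition: int = 8,
    age_tolerance: float = AGE_TOLERANCE_YEARS,
    min_age: float = MIN_AGE_YEARS,
    unresolved: Mapping[str, Sequence[str]] | None = None,
) -> None:
    """Re-check every KD invariant; raises AssertionError on violation."""
    inv = _Inventory(inventory, pedigree)
    kin = KinshipCalculator.from_pedigree(pedigree)
    counts = {c: 0 for c in KD_CONDITIONS}
    image_uses: dict[str, int] = {}
    target_conditions: dict[str, set[str]] = {}
    match_or_decoy: set[str] = set()
    for t in triads:
        assert t.kind == "KD"
        counts[t.condition] += 1
        assert t.target in pedigree.parents(t.match), "match must be offspring of target"
        assert kin.r(t.target, t.match) >= 0.5 - 1e-12
        assert pedigree.sex(t.decoy) == pedigree.sex(t.match)
        match_row, decoy_row = inv.frontal[t.match], inv.frontal[t.decoy]
        assert abs(inv.age(t.match, match_row) - inv.age(t.decoy, decoy_row)) <= (
            age_tolerance + 1e-9
        )
        assert match_row["lighting_class"] == decoy_row["lighting_class"]
        for ind, row in ((t.target, inv.frontal[t.target]), (t.match, match_row), (t.decoy, decoy_row)):
            assert inv.age(ind, row) >= min_age - 1e-9
        assert len({t.target, t.match, t.decoy}) == 3
        assert _screen_unrelated(t.decoy, t.target, pedigree, unresolved, 0.25)
        assert _screen_unrelated(t.decoy, t.match, pedigree, unresolved, 0.25)
        for img in (t.target_image, t.match_image, t.decoy_image):
            image_uses[img] = image_uses.get(img, 0) + 1
        target_conditions.setdefault(t.target_image, set()).add(t.condition)
        assert t.match_image not in match_or_decoy
        assert t.decoy_image not in match_or_decoy
        match_or_decoy.update((t.match_image, t.decoy_image))
    assert all(n == n_per_condition for n in counts.values()), counts
    for img, n in image_uses.items():
        assert n <= 2, f"image {img} used {n} times"
        if n == 2:
            assert len(target_conditions.get(img, ())) == 2, (
                "reused images must be targets in two different conditions"
            )


def validate_id_triads(
    triads: Sequence[Triad],
    pedigree: Pedigree,
    inventory: pd.DataFrame,
    n_per_sex: int = 6,
    age_tolerance: float = AGE_TOLERANCE_YEARS,
    unresolved: Mapping[str, Sequence[str]] | None = None,
) -> None:
    inv = _Inventory(inventory, pedigree)
    counts = {c: 0 for c in ID_CONDITIONS}
    for t in triads:
        assert t.kind == "ID"
        counts[t.condition] += 1
        assert t.target == t.match, "ID match is the same individual"
        assert t.target_image != t.match_image
        assert pedigree.sex(t.decoy) == pedigree.sex(t.target)
        assert t.decoy != t.target
        srow = inv.three_quarter[(t.target, t.facing)]
        drow = inv.three_quarter[(t.decoy, t.facing)]
        assert srow["lighting_class"] == drow["lighting_class"]
        assert abs(inv.age(t.target, srow) - inv.age(t.decoy, drow)) <= (
            age_tolerance + 1e-9
        )
        assert _screen_unrelated(t.decoy, t.target, pedigree, unresolved, 0.25)
    sexes = {"male": 0, "female": 0}
    facing = {("male", "left"): 0, ("male", "right"): 0,
              ("female", "left"): 0, ("female", "right"): 0}
    for cond, n in counts.items():
        sex, face = cond.split("-")
        sexes[sex] += n
        facing[(sex, face)] += n
    assert sexes["male"] == sexes["female"] == n_per_sex, counts
    assert all(v == n_per_sex // 2 for v in facing.values()), counts


def validate_schedule(
    schedule: SessionSchedule, triads: Sequence[Triad]
) -> None:
    """Re-check the 44-trial schedule invariants."""
    by_id = {t.triad_id: t for t in triads}
    trials = schedule.trials
    assert len(trials) == 44
    assert list(trials["position"]) == list(range(1, 45))
    kinds = [by_id[t].kind for t in trials["triad_id"]]
    assert kinds.count("KD") == 32 and kinds.count("ID") == 12
    conds = [by_id[t].condition for t in trials["triad_id"]]
    for c in KD_CONDITIONS:
        assert conds.count(c) == 8
    sides = list(trials["side_correct"])
    assert sides.count("left") == 22 and sides.count("right") == 22
    # even interleaving: every quarter holds 2 of each KD condition + 3 IDs
    for q in range(4):
        block = conds[11 * q : 11 * (q + 1)]
        for c in KD_CONDITIONS:
            assert block.count(c) == 2, (q, c, block)
        assert sum(1 for c in block if c in ID_CONDITIONS) == 3
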