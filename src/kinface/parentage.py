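"""Sire assignment by demographic filtering, exclusion and likelihood.

The decision rule mirrors standard practice for a pedigreed colony
genotyped at ~21 STR loci:

1. candidate sires are the males of reproductive age present (by
   census) at least 200 days before the offspring's birth;
2. a candidate is *testable* only when mother-candidate-offspring trios
   share >= 12 typed loci (or father-offspring duos >= 15);
3. a unique zero-mismatch candidate whose rivals can all be excluded at
   two or more loci is accepted on exclusion alone; if some rival can be
   excluded at only one locus the assignment must additionally be
   supported by the likelihood method at the 95% confidence level
   (top LOD with a delta above a simulation-derived critical value);
4. otherwise paternity stays unresolved.

LOD scores are natural-log likelihood ratios of "candidate is the sire"
against "the sire is a random population male", with a simple
genotyping-error mixture (each observed genotype is correct with
probability 1-e, a random Hardy-Weinberg genotype with probability e).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .genotypes import GenotypeTable
from .pedigree import Pedigree

__all__ = [
    "CandidateProfile",
    "PaternityAssignment",
    "CriticalDelta",
    "GrandsireResult",
    "LodCalculator",
    "NEG_LOD",
    "candidate_sires",
    "locus_compatible",
    "exclusion_profiles",
    "lod_score",
    "confidence_critical_delta",
    "assign_paternity",
    "assign_grandsires",
    "assignment_summary",
]

logger = logging.getLogger(__name__)

#: finite stand-in for a -infinity LOD (keeps sorting stable)
NEG_LOD = -1.0e9


def _lod_gap(top: float, second: float) -> float:
    """LOD gap with the runner-up floored at zero.

    A fully excluded runner-up (sentinel LOD) would otherwise produce an
    astronomical, meaningless delta; flooring keeps critical values on
    the scale of real LOD differences.
    """
    return max(0.0, top - max(second, 0.0))

TRIO_MIN_COMMON = 12
DUO_MIN_COMMON = 15
LEAD_DAYS = 200.0


@dataclass
class CandidateProfile:
    candidate: str
    n_common_loci: int
    n_mismatches: int
    testable: bool
    mode: str  # "trio" or "duo"
    lod: float | None = None

    def __post_init__(self):
        if not 0 <= self.n_mismatches <= max(self.n_common_loci, 0):
            raise ValueError("mismatches outside [0, n_common_loci]")


@dataclass
class PaternityAssignment:
    offspring: str
    sire: str | None
    basis: str  # exclusion_strict | likelihood_confirmed | unresolved
    profiles: list[CandidateProfile] = field(default_factory=list)
    delta: float = float("nan")
    confidence_level: str = "none"  # none | 95%
    n_untestable: int = 0


# ---------------------------------------------------------------------------
# demographic filtering
# ---------------------------------------------------------------------------


def candidate_sires(
    offspring: str,
    pedigree: Pedigree,
    census: pd.DataFrame,
    min_age_years: float = 5.0,
    lead_days: float = LEAD_DAYS,
) -> set[str]:
    """Males of at least ``min_age_years`` whose census interval covers the
    conception reference time (birth minus ``lead_days``)."""
    birth = pedigree.birth(offspring)
    if not np.isfinite(birth):
        raise ValueError(f"offspring {offspring!r} has no birth date")
    t_ref = birth - lead_days / 365.25
    out: set[str] = set()
    start = dict(zip(census["id"].astype(str), census["start"]))
    end = dict(zip(census["id"].astype(str), census["end"]))
    for male in pedigree.males:
        if male == offspring:
            continue
        b = pedigree.birth(male)
        if not np.isfinite(b) or t_ref - b < min_age_years:
            continue
        if male in start and not (start[male] <= t_ref <= end[male]):
            continue
        if male not in start:
            continue
        out.add(male)
    return out


# ---------------------------------------------------------------------------
# Mendelian compatibility
# ---------------------------------------------------------------------------


def _allowed_paternal(
    go: tuple[int, int], gm: tuple[int, int] | None
) -> tuple[set[int], bool]:
    """Alleles a sire must carry, plus a maternal-mismatch flag.

    Trio mode derives the possible paternal alleles from mother and
    offspring; when mother and offspring share no allele the locus falls
    back to duo logic (any offspring allele) and is flagged.
    """
    x, y = go
    if gm is None:
        return {x, y}, False
    mx = x in gm
    my = y in gm
    if x == y:
        return ({x}, False) if mx else ({x}, True)
    if mx and my:
        return {x, y}, False
    if mx:
        return {y}, False
    if my:
        return {x}, False
    return {x, y}, True


def locus_compatible(
    offspring_gt: tuple[int, int],
    candidate_gt: tuple[int, int],
    mother_gt: tuple[int, int] | None = None,
) -> bool:
    """True iff the candidate carries an allele it could have transmitted."""
    allowed, _ = _allowed_paternal(tuple(offspring_gt), mother_gt)
    return bool(allowed & set(candidate_gt))


def _mismatch_arrays(
    off: np.ndarray,
    cands: np.ndarray,
    mother: np.ndarray | None,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Vectorized mismatch/common-locus counts.

    Parameters: offspring ``(L, 2)``, candidates ``(C, L, 2)``, mother
    ``(L, 2)`` or None.  Returns ``(n_mismatch, n_trio_common,
    n_duo_common)`` each of shape ``(C,)``.
    """
    typed_o = (off >= 0).all(axis=1)
    typed_c = (cands >= 0).all(axis=2)
    x, y = off[:, 0], off[:, 1]
    if mother is not None:
        typed_m = (mother >= 0).all(axis=1)
        mx = (mother == x[:, None]).any(axis=1)
        my = (mother == y[:, None]).any(axis=1)
        hom = x == y
        mismatch_m = typed_m & ~(mx | my)
        # Paternal allele x is possible iff the mother can supply the other
        # offspring allele (y), and vice versa; homozygous offspring need
        # the mother to carry x and the sire to carry x as well.  Loci with
        # an untyped mother or a maternal mismatch fall back to duo logic.
        duo_locus = ~typed_m | mismatch_m
        allow_x = duo_locus | np.where(hom, mx, my)
        allow_y = duo_locus | mx
    else:
        typed_m = np.zeros_like(typed_o)
        mismatch_m = np.zeros_like(typed_o)
        allow_x = np.ones_like(typed_o)
        allow_y = np.ones_like(typed_o)

    carries_x = (cands[:, :, 0] == x) | (cands[:, :, 1] == x)
    carries_y = (cands[:, :, 0] == y) | (cands[:, :, 1] == y)
    compatible = (allow_x & carries_x) | (allow_y & carries_y)
    duo_common = typed_o & typed_c
    trio_common = duo_common & typed_m & ~mismatch_m
    n_mm = (duo_common & ~compatible).sum(axis=1)
    return (
        n_mm.astype(int),
        trio_common.sum(axis=1).astype(int),
        duo_common.sum(axis=1).astype(int),
    )


def exclusion_profiles(
    offspring: str,
    candidates: Sequence[str],
    table: GenotypeTable,
    mother: str | None = None,
    trio_min: int = TRIO_MIN_COMMON,
    duo_min: int = DUO_MIN_COMMON,
) -> list[CandidateProfile]:
    """Mismatch and common-locus profile for every candidate.

    A candidate below the common-locus threshold (12 for trios, 15 for
    duos) is marked untestable, never excluded.
    """
    if not candidates:
        raise ValueError("candidate set is empty")
    off = table.row(offspring)
    mom = table.row(mother) if mother is not None and mother in table else None
    cands = np.stack([table.row(c) for c in candidates])
    n_mm, n_trio, n_duo = _mismatch_arrays(off, cands, mom)
    profiles = []
    for i, cand in enumerate(candidates):
        if mom is not None and n_trio[i] >= trio_min:
            mode, common, testable = "trio", int(n_trio[i]), True
        elif n_duo[i] >= duo_min:
            mode, common, testable = "duo", int(n_duo[i]), True
        else:
            mode = "trio" if mom is not None else "duo"
            common, testable = int(n_duo[i]), False
        profiles.append(
            CandidateProfile(
                candidate=str(cand),
                n_common_loci=max(common, int(n_mm[i])),
                n_mismatches=int(n_mm[i]),
                testable=testable,
                mode=mode,
            )
        )
    return profiles


# ---------------------------------------------------------------------------
# likelihood
# ---------------------------------------------------------------------------


class LodCalculator:
    """Cached per-locus paternity likelihood ratios.

    ``freqs`` is one frequency vector per locus (indexed by allele
    code); ``error_rate`` is the probability that an observed genotype
    is a random population genotype rather than the true one.  Observed
    alleles with zero recorded frequency are floored at the smallest
    positive frequency of the locus (logged once).
    """

    def __init__(self, freqs: Sequence[np.ndarray], error_rate: float):
        if not 0.0 <= error_rate < 1.0:
            raise ValueError("error_rate must be in [0, 1)")
        self.freqs = [np.asarray(f, dtype=float) for f in freqs]
        self.e = float(error_rate)
        self._cache: dict[tuple, float] = {}
        self._floored = False

    def _p(self, j: int, allele: int) -> float:
        f = self.freqs[j]
        value = f[allele] if 0 <= allele < len(f) else 0.0
        if value <= 0.0:
            floor = float(f[f > 0].min())
            if not self._floored:
                logger.warning(
                    "observed allele with zero recorded frequency; "
                    "flooring at the smallest locus frequency"
                )
                self._floored = True
            return floor
        return float(value)

    def _phwe(self, j: int, g: tuple[int, int]) -> float:
        a, b = g
        pa, pb = self._p(j, a), self._p(j, b)
        return pa * pa if a == b else 2 * pa * pb

    @staticmethod
    def _trans(go: tuple[int, int], gm: tuple[int, int], gc: tuple[int, int]) -> float:
        total = 0.0
        for ma in gm:
            for pa in gc:
                if tuple(sorted((ma, pa))) == go:
                    total += 0.25
        return total

    def _one_parent(self, j: int, go: tuple[int, int], gpar: tuple[int, int]) -> float:
        x, y = go
        total = 0.0
        for ma in gpar:
            if x == y:
                if ma == x:
                    total += 0.5 * self._p(j, x)
            elif ma == x:
                total += 0.5 * self._p(j, y)
            elif ma == y:
                total += 0.5 * self._p(j, x)
        return total

    def locus_lr(
        self,
        j: int,
        go: tuple[int, int],
        gc: tuple[int, int],
        gm: tuple[int, int] | None,
    ) -> float:
        """Likelihood ratio (sire vs random male) at locus ``j``.

        Maternal-mismatch loci (mother and offspring share no allele)
        fall back to the duo formula.
        """
        go = tuple(sorted(go))
        gc = tuple(sorted(gc))
        gm = tuple(sorted(gm)) if gm is not None else None
        if gm is not None and not (set(go) & set(gm)):
            gm = None  # maternal mismatch: duo logic at this locus
        key = (j, go, gc, gm)
        cached = self._cache.get(key)
        if cached is not None:
            return cached
        e = self.e
        po = self._phwe(j, go)
        if gm is None:
            poc = self._one_parent(j, go, gc)
            num = (1 - e) ** 2 * poc + (2 * e - e * e) * po
            den = po
        else:
            t = self._trans(go, gm, gc)
            pom = self._one_parent(j, go, gm)
            poc = self._one_parent(j, go, gc)
            num = (
                (1 - e) ** 3 * t
                + e * (1 - e) ** 2 * (po + poc + pom)
                + (3 * e * e * (1 - e) + e**3) * po
            )
            den = (
                (1 - e) ** 3 * pom
                + e * (1 - e) ** 2 * (2 * po + pom)
                + (3 * e * e * (1 - e) + e**3) * po
            )
        lr = num / den if den > 0 else 0.0
        self._cache[key] = lr
        return lr

    def lod(
        self,
        off: np.ndarray,
        cand: np.ndarray,
        mother: np.ndarray | None,
    ) -> float:
        """Summed ln LR over loci typed in offspring and candidate."""
        total = 0.0
        for j in range(len(self.freqs)):
            if off[j, 0] < 0 or cand[j, 0] < 0:
                continue
            gm = None
            if mother is not None and mother[j, 0] >= 0:
                gm = (int(mother[j, 0]), int(mother[j, 1]))
            lr = self.locus_lr(
                j,
                (int(off[j, 0]), int(off[j, 1])),
                (int(cand[j, 0]), int(cand[j, 1])),
                gm,
            )
            if lr <= 0.0:
                return NEG_LOD
            total += float(np.log(lr))
        # a candidate sharing no typed locus with the offspring scores 0
        return total


def lod_score(
    offspring: str,
    candidate: str,
    table: GenotypeTable,
    allele_freqs: Sequence[np.ndarray],
    error_rate: float,
    mother: str | None = None,
) -> float:
    calc = LodCalculator(allele_freqs, error_rate)
    mom = table.row(mother) if mother is not None and mother in table else None
    return calc.lod(table.row(offspring), table.row(candidate), mom)


# ---------------------------------------------------------------------------
# confidence simulation
# ---------------------------------------------------------------------------


@dataclass
class CriticalDelta:
    delta: float
    level: float
    success_rate: float  # proportion correct among assignments at the delta
    n_reps: int


def _draw_genotype(rng, p: np.ndarray) -> tuple[int, int]:
    return int(rng.choice(len(p), p=p)), int(rng.choice(len(p), p=p))


def confidence_critical_delta(
    allele_freqs: Sequence[np.ndarray],
    n_candidates: int,
    prop_sampled: float = 1.0,
    prop_loci_typed: float = 1.0,
    error_rate: float = 0.0,
    n_reps: int = 1000,
    level: float = 0.95,
    seed: int = 0,
) -> CriticalDelta:
    """Simulation-derived critical LOD gap for the requested confidence.

    Offspring are simulated from random true sires; in each replicate
    the LOD gap (delta) between the top two candidates is recorded
    together with whether the top candidate is the true sire.  The
    returned delta is the smallest threshold at which the proportion of
    correct assignments *among assignments made* reaches ``level``.
    """
    if level not in (0.80, 0.95):
        raise ValueError("level must be 0.80 or 0.95")
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    if n_candidates < 2:
        warnings.warn("degenerate simulation with one candidate; delta = 0")
        return CriticalDelta(delta=0.0, level=level, success_rate=1.0, n_reps=n_reps)
    rng = np.random.default_rng(seed)
    L = len(allele_freqs)
    calc = LodCalculator(allele_freqs, error_rate)

    def observe(g: np.ndarray) -> np.ndarray:
        out = g.copy()
        for j in range(L):
            if rng.random() < error_rate:
                out[j] = _draw_genotype(rng, allele_freqs[j])
            if rng.random() > prop_loci_typed:
                out[j] = (-1, -1)
        return out

    deltas = np.empty(n_reps)
    correct = np.zeros(n_reps, dtype=bool)
    for r in range(n_reps):
        mother = np.array([_draw_genotype(rng, p) for p in allele_freqs])
        sire = np.array([_draw_genotype(rng, p) for p in allele_freqs])
        off = np.array(
            [
                (
                    mother[j, int(rng.integers(2))],
                    sire[j, int(rng.integers(2))],
                )
                for j in range(L)
            ]
        )
        genos = [sire] + [
            np.array([_draw_genotype(rng, p) for p in allele_freqs])
            for _ in range(n_candidates - 1)
        ]
        sampled = rng.random() < prop_sampled
        if not sampled:
            genos[0] = np.array([_draw_genotype(rng, p) for p in allele_freqs])
        obs_off = observe(off)
        obs_mother = observe(mother)
        lods = [calc.lod(obs_off, observe(g), obs_mother) for g in genos]
        order = np.argsort(lods)[::-1]
        deltas[r] = _lod_gap(lods[order[0]], lods[order[1]])
        correct[r] = sampled and order[0] == 0

    order = np.argsort(deltas)[::-1]
    sorted_correct = correct[order]
    frac = np.cumsum(sorted_correct) / np.arange(1, n_reps + 1)
    ok = np.nonzero(frac >= level)[0]
    if len(ok) == 0:
        warnings.warn("requested confidence unattainable; returning max delta")
        return CriticalDelta(
            delta=float(deltas.max()), level=level, success_rate=float(frac[0]),
            n_reps=n_reps,
        )
    best = int(ok.max())  # largest assignment set still meeting the level
    # if every assignment meets the level, any positive gap qualifies
    delta = 0.0 if best == n_reps - 1 else float(deltas[order[best]])
    return CriticalDelta(
        delta=delta,
        level=level,
        success_rate=float(frac[best]),
        n_reps=n_reps,
    )


# ---------------------------------------------------------------------------
# assignment
# ---------------------------------------------------------------------------


def assign_paternity(
    offspring: str,
    candidates: Sequence[str],
    table: GenotypeTable,
    mother: str | None = None,
    allele_freqs: Sequence[np.ndarray] | None = None,
    error_rate: float = 0.0,
    critical_delta: float | None = None,
    trio_min: int = TRIO_MIN_COMMON,
    duo_min: int = DUO_MIN_COMMON,
) -> PaternityAssignment:
    """Apply the exclusion + likelihood decision rule to one offspring.

    * a unique zero-mismatch candidate, all rivals excludable at >= 2
      loci: accepted on strict exclusion;
    * a unique zero-mismatch candidate with some rival excludable at
      exactly 1 locus: accepted only when it also carries the top LOD
      with a gap of at least ``critical_delta`` (95% confidence);
    * zero or multiple zero-mismatch candidates: unresolved.

    Candidates below the common-locus thresholds are untestable: they
    are reported but take no part in the comparison.
    """
    candidates = sorted(set(candidates))
    profiles = exclusion_profiles(
        offspring, candidates, table, mother=mother, trio_min=trio_min, duo_min=duo_min
    )
    testable = [p for p in profiles if p.testable]
    n_untestable = len(profiles) - len(testable)
    zero = [p for p in testable if p.n_mismatches == 0]

    def unresolved() -> PaternityAssignment:
        return PaternityAssignment(
            offspring=offspring,
            sire=None,
            basis="unresolved",
            profiles=profiles,
            n_untestable=n_untestable,
        )

    if len(zero) != 1:
        return unresolved()
    focal = zero[0]
    rivals = [p for p in testable if p is not focal]
    min_rival = min((p.n_mismatches for p in rivals), default=None)
    if min_rival is None or min_rival >= 2:
        return PaternityAssignment(
            offspring=offspring,
            sire=focal.candidate,
            basis="exclusion_strict",
            profiles=profiles,
            confidence_level="none",
            n_untestable=n_untestable,
        )
    # some rival excludable at only one locus: require likelihood support
    if allele_freqs is None or critical_delta is None:
        return unresolved()
    calc = LodCalculator(allele_freqs, error_rate)
    mom = table.row(mother) if mother is not None and mother in table else None
    off = table.row(offspring)
    for p in testable:
        p.lod = calc.lod(off, table.row(p.candidate), mom)
    top, second = sorted(testable, key=lambda p: p.lod, reverse=True)[:2]
    delta = _lod_gap(top.lod, second.lod)
    if top is focal and delta >= critical_delta:
        return PaternityAssignment(
            offspring=offspring,
            sire=focal.candidate,
            basis="likelihood_confirmed",
            profiles=profiles,
            delta=delta,
            confidence_level="95%",
            n_untestable=n_untestable,
        )
    out = unresolved()
    out.delta = delta
    return out


@dataclass
class GrandsireResult:
    focal: str
    branch: str  # "maternal" or "paternal"
    parent: str | None
    assignment: PaternityAssignment | None
    skipped_reason: str | None = None


def assign_grandsires(
    focal_ids: Sequence[str],
    pedigree: Pedigree,
    table: GenotypeTable,
    census: pd.DataFrame,
    allele_freqs: Sequence[np.ndarray] | None = None,
    error_rate: float = 0.0,
    critical_delta: float | None = None,
    min_age_years: float = 5.0,
    lead_days: float = LEAD_DAYS,
    assigned_parents: Mapping[str, tuple[str | None, str | None]] | None = None,
) -> list[GrandsireResult]:
    """Cascade sire assignment one generation up.

    For each focal individual, the sire of its dam (maternal
    grandfather) and of its sire (paternal grandfather) is sought by the
    same candidate-filter + decision rule, with the parent's own dam as
    the trio mother when genotyped.  Ungenotyped parents are skipped
    with a reason.
    """
    results = []
    for focal in focal_ids:
        parent_pair = (
            assigned_parents[focal]
            if assigned_parents is not None and focal in assigned_parents
            else pedigree.parents(focal)
        )
        for branch, parent in zip(("maternal", "paternal"), parent_pair):
            if parent is None:
                results.append(
                    GrandsireResult(focal, branch, None, None, "parent unknown")
                )
                continue
            if not table.is_genotyped(parent):
                results.append(
                    GrandsireResult(focal, branch, parent, None, "parent ungenotyped")
                )
                continue
            cands = candidate_sires(
                parent, pedigree, census, min_age_years=min_age_years,
                lead_days=lead_days,
            )
            cands = {c for c in cands if c in table}
            if not cands:
                results.append(
                    GrandsireResult(focal, branch, parent, None, "no candidates")
                )
                continue
            grandmother = pedigree.dam(parent)
            assignment = assign_paternity(
                parent,
                sorted(cands),
                table,
                mother=grandmother,
                allele_freqs=allele_freqs,
                error_rate=error_rate,
                critical_delta=critical_delta,
            )
            results.append(GrandsireResult(focal, branch, parent, assignment))
    return results


def assignment_summary(assignments: Sequence[PaternityAssignment]) -> dict:
    """Counts and completion percentage (one decimal, half-up rounding)."""
    from decimal import ROUND_HALF_UP, Decimal

    n = len(assignments)
    assigned = [a for a in assignments if a.sire is not None]
    basis_counts: dict[str, int] = {}
    for a in assignments:
        basis_counts[a.basis] = basis_counts.get(a.basis, 0) + 1
    percent = float(
        Decimal(repr(100.0 * len(assigned) / n)).quantize(
            Decimal("0.1"), rounding=ROUND_HALF_UP
        )
    ) if n else float("nan")
    return {
        "n_offspring": n,
        "n_assigned": len(assigned),
        "percent_assigned": percent,
        "basis_counts": basis_counts,
    }
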