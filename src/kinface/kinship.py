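"""Pedigree kinship, relatedness and unrelatedness screening.

Relatedness is defined throughout as r = 2f where f is the kinship
coefficient (probability that one allele drawn at random from each of
two individuals is identical by descent).  Unknown parents are treated
as unique, mutually unrelated founders, so every reported r is a lower
bound with respect to unrecorded ancestry.  The decoy-screening rules
used in triad construction (two-generation unrelatedness, expected
relatedness under unresolved paternity) live here as well.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from itertools import product
from typing import Mapping, Sequence

from .pedigree import Pedigree, PedigreeError

__all__ = [
    "KinshipCalculator",
    "KinshipResult",
    "ExpectedRelatedness",
    "kinship_coefficient",
    "relatedness",
    "round_relatedness",
    "unrelated_two_generations",
    "expected_relatedness",
]


class KinshipCalculator:
    """Memoized recursive kinship over dam/sire maps.

    Operates on raw parent dictionaries so the pedigree simulator can
    query relatedness incrementally while the pedigree is still being
    grown (kinship of an existing pair never changes when new
    individuals are appended, so the memo table stays valid).
    """

    def __init__(
        self,
        dam: Mapping[str, str | None],
        sire: Mapping[str, str | None],
    ):
        self._dam = dam
        self._sire = sire
        self._memo: dict[tuple[str, str], float] = {}
        self._depth: dict[str, int] = {}

    @classmethod
    def from_pedigree(cls, pedigree: Pedigree) -> "KinshipCalculator":
        return cls(pedigree._dam, pedigree._sire)

    def depth(self, individual: str) -> int:
        d = self._depth.get(individual)
        if d is not None:
            return d
        stack = [individual]
        while stack:
            node = stack[-1]
            if node in self._depth:
                stack.pop()
                continue
            parents = [
                p
                for p in (self._dam.get(node), self._sire.get(node))
                if p is not None
            ]
            pending = [p for p in parents if p not in self._depth]
            if pending:
                stack.extend(pending)
                if len(stack) > 100000:
                    raise PedigreeError("pedigree recursion limit; cycle suspected")
                continue
            stack.pop()
            self._depth[node] = (
                1 + max(self._depth[p] for p in parents) if parents else 0
            )
        return self._depth[individual]

    def f(self, a: str, b: str) -> float:
        """Kinship coefficient f(a, b)."""
        if a == b:
            dam, sire = self._dam.get(a), self._sire.get(a)
            if dam is None or sire is None:
                return 0.5
            return 0.5 * (1.0 + self.f(dam, sire))
        key = (a, b) if a < b else (b, a)
        cached = self._memo.get(key)
        if cached is not None:
            return cached
        # Recurse on the individual deeper in the pedigree; at equal depth
        # neither can be an ancestor of the other, so either choice is valid
        # (the lexicographically larger one keeps the memo key stable).
        da, db = self.depth(a), self.depth(b)
        if da > db or (da == db and a > b):
            x, other = a, b
        else:
            x, other = b, a
        dam, sire = self._dam.get(x), self._sire.get(x)
        value = 0.0
        if dam is not None:
            value += 0.5 * self.f(dam, other)
        if sire is not None:
            value += 0.5 * self.f(sire, other)
        self._memo[key] = value
        return value

    def r(self, a: str, b: str) -> float:
        """Relatedness r = 2f (no inbreeding normalization)."""
        return 2.0 * self.f(a, b)


@dataclass(frozen=True)
class KinshipResult:
    pair: tuple[str, str]
    f: float
    r: float
    generations_checked: int = 0


@dataclass(frozen=True)
class ExpectedRelatedness:
    pair: tuple[str, str]
    candidate_sires: dict[str, list[tuple[str, float]]] = field(default_factory=dict)
    expected_r: float = 0.0


def kinship_coefficient(a: str, b: str, pedigree: Pedigree) -> float:
    """Kinship coefficient between two pedigree members."""
    for i in (a, b):
        if i not in pedigree:
            raise KeyError(f"{i!r} not in pedigree")
    return KinshipCalculator.from_pedigree(pedigree).f(a, b)


def relatedness(a: str, b: str, pedigree: Pedigree) -> KinshipResult:
    f = kinship_coefficient(a, b, pedigree)
    return KinshipResult(pair=(a, b), f=f, r=2.0 * f)


def round_relatedness(r: float, decimals: int = 3) -> float:
    """Round half-up for reporting (0.0625 prints as 0.063, not 0.062)."""
    q = Decimal(10) ** -decimals
    return float(Decimal(repr(r)).quantize(q, rounding=ROUND_HALF_UP))


def _screen_set(
    x: str,
    pedigree: Pedigree,
    unresolved: Mapping[str, Sequence[str]] | None,
) -> set[str] | None:
    """Self + known parents + grandparents, plus candidate sires standing in
    for unknown sires.  Returns None when ancestry is partially unknown and
    no candidate information covers the gap (the caller must not then treat
    the pair as certified-unrelated)."""
    unresolved = unresolved or {}
    out = {x}
    members = [x] + [p for p in pedigree.parents(x) if p is not None]
    for depth, member in enumerate(members):
        dam, sire = pedigree.parents(member)
        if pedigree.is_founder(member):
            continue  # base-population founder: assumed unrelated stock
        for parent, known in (("dam", dam), ("sire", sire)):
            if known is not None:
                out.add(known)
            elif member in unresolved and parent == "sire":
                out.update(unresolved[member])
            else:
                return None
    return out


def unrelated_two_generations(
    a: str,
    b: str,
    pedigree: Pedigree,
    unresolved: Mapping[str, Sequence[str]] | None = None,
) -> bool:
    """True iff the two individuals demonstrably share no member of
    {self, parents, grandparents}.

    Founders (both parents unrecorded) count as base population and are
    assumed unrelated.  An individual with a recorded dam but unknown
    sire is *not* silently treated as unrelated: its non-excluded
    candidate sires (``unresolved[id]``) stand in for the missing link,
    and without candidate information the predicate returns False so the
    expected-relatedness path must be consulted instead.
    """
    if a == b:
        raise ValueError("two-generation unrelatedness needs distinct individuals")
    sa = _screen_set(a, pedigree, unresolved)
    sb = _screen_set(b, pedigree, unresolved)
    if sa is None or sb is None:
        return False
    return not (sa & sb)


def expected_relatedness(
    a: str,
    b: str,
    pedigree: Pedigree,
    unresolved: Mapping[str, Sequence[str]],
    avoidance_r: float = 0.25,
) -> ExpectedRelatedness:
    """Probability-weighted relatedness when paternity is unresolved.

    For each member of the pair listed in ``unresolved``, the unknown
    sire is replaced in turn by each non-excluded candidate and r is
    recomputed with that candidate grafted in.  Candidate weights are
    uniform after zeroing candidates whose relatedness to the
    individual's dam reaches ``avoidance_r`` (the configurable
    inbreeding-avoidance adjustment); if every candidate is zeroed the
    weights fall back to uniform with a warning.  When both members are
    unresolved, the two choices are independent (product weights).
    """
    base = KinshipCalculator.from_pedigree(pedigree)
    members = [x for x in dict.fromkeys((a, b)) if x in unresolved]
    if not members:
        return ExpectedRelatedness(pair=(a, b), expected_r=base.r(a, b))

    weight_sets: dict[str, list[tuple[str, float]]] = {}
    for x in members:
        candidates = list(unresolved[x])
        if not candidates:
            raise ValueError(f"empty candidate-sire set for {x!r}")
        dam = pedigree.dam(x)
        blocked = _descendants(pedigree, x) | {x}  # grafting these would cycle
        raw = []
        for c in candidates:
            ok = c not in blocked
            if ok and dam is not None and base.r(c, dam) >= avoidance_r:
                ok = False
            raw.append((c, 1.0 if ok else 0.0))
        total = sum(w for _, w in raw)
        if total == 0.0:
            warnings.warn(
                f"all candidate sires of {x!r} zero-weighted by the "
                "inbreeding-avoidance rule; falling back to uniform weights",
                stacklevel=2,
            )
            raw = [(c, 1.0) for c, _ in raw if c not in blocked]
            if not raw:
                raise ValueError(
                    f"no graftable candidate sires for {x!r} (all would cycle)"
                )
            total = float(len(raw))
        weight_sets[x] = [(c, w / total) for c, w in raw if w > 0.0]

    expected = 0.0
    for combo in product(*(weight_sets[x] for x in members)):
        graft = {x: c for x, (c, _) in zip(members, combo)}
        weight = 1.0
        for _, (_, w) in zip(members, combo):
            weight *= w
        grafted = pedigree.graft(graft)
        expected += weight * KinshipCalculator.from_pedigree(grafted).r(a, b)
    return ExpectedRelatedness(
        pair=(a, b), candidate_sires=weight_sets, expected_r=expected
    )


def _descendants(pedigree: Pedigree, individual: str) -> set[str]:
    children: dict[str, list[str]] = {}
    for child in pedigree.ids:
        for p in pedigree.parents(child):
            if p is not None:
                children.setdefault(p, []).append(child)
    out: set[str] = set()
    frontier = [individual]
    while frontier:
        node = frontier.pop()
        for c in children.get(node, ()):
            if c not in out:
                out.add(c)
                frontier.append(c)
    return out
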