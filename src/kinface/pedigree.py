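"""Pedigree container: demographic records plus dam/sire links.

The pedigree is the substrate for kinship queries, candidate-sire
filtering and triad construction.  Individuals are identified by string
ids; birth is stored as a fractional year so that day-resolution rules
(such as the 200-day conception lead used in paternity screening) can be
expressed without a calendar.  Missing parents are represented as
``None`` and are treated downstream as unique, mutually unrelated
founders.
"""

from __future__ import annotations

from typing import Iterable, Mapping

import networkx as nx
import numpy as np
import pandas as pd

__all__ = ["Pedigree", "PedigreeError", "read_pedigree_tsv", "write_pedigree_tsv"]


class PedigreeError(ValueError):
    """Raised for structurally invalid pedigrees (cycles, unknown parents)."""


def _clean_parent(value) -> str | None:
    if value is None:
        return None
    if isinstance(value, float) and np.isnan(value):
        return None
    value = str(value).strip()
    return value or None


class Pedigree:
    """Immutable pedigree over records (id, sex, birth, dam, sire).

    Parameters
    ----------
    table:
        DataFrame with columns ``id`` (unique strings), ``sex`` ("F"/"M"),
        ``birth`` (fractional year, NaN allowed), ``dam`` and ``sire``
        (parent ids or missing).

    Raises
    ------
    PedigreeError
        If ids are duplicated, a parent id is not itself a record, a
        parent has the wrong sex, or the parent-child graph has a cycle.
    """

    def __init__(self, table: pd.DataFrame):
        required = {"id", "sex", "birth", "dam", "sire"}
        missing = required - set(table.columns)
        if missing:
            raise PedigreeError(f"pedigree table lacks columns: {sorted(missing)}")
        table = table.reset_index(drop=True).copy()
        ids = [str(i) for i in table["id"]]
        if len(set(ids)) != len(ids):
            raise PedigreeError("duplicate individual ids in pedigree")
        self.table = table
        self.ids: list[str] = ids
        self._idset = set(ids)
        self._sex: dict[str, str] = dict(zip(ids, (str(s) for s in table["sex"])))
        self._birth: dict[str, float] = dict(
            zip(ids, (float(b) if pd.notna(b) else np.nan for b in table["birth"]))
        )
        self._dam: dict[str, str | None] = dict(
            zip(ids, (_clean_parent(d) for d in table["dam"]))
        )
        self._sire: dict[str, str | None] = dict(
            zip(ids, (_clean_parent(s) for s in table["sire"]))
        )
        for child in ids:
            for parent, want in ((self._dam[child], "F"), (self._sire[child], "M")):
                if parent is None:
                    continue
                if parent not in self._idset:
                    raise PedigreeError(f"parent {parent!r} of {child!r} not in pedigree")
                if self._sex[parent] != want:
                    raise PedigreeError(
                        f"parent {parent!r} of {child!r} has sex "
                        f"{self._sex[parent]!r}, expected {want!r}"
                    )
        self._check_acyclic()
        self._depth: dict[str, int] = {}

    # -- structure ---------------------------------------------------------

    def _check_acyclic(self) -> None:
        g = nx.DiGraph()
        g.add_nodes_from(self.ids)
        for child in self.ids:
            for parent in (self._dam[child], self._sire[child]):
                if parent is not None:
                    g.add_edge(parent, child)
        if not nx.is_directed_acyclic_graph(g):
            cycle = nx.find_cycle(g)
            raise PedigreeError(f"pedigree contains a cycle: {cycle}")

    def __contains__(self, individual: str) -> bool:
        return individual in self._idset

    def __len__(self) -> int:
        return len(self.ids)

    def sex(self, individual: str) -> str:
        return self._sex[individual]

    def birth(self, individual: str) -> float:
        return self._birth[individual]

    def dam(self, individual: str) -> str | None:
        return self._dam[individual]

    def sire(self, individual: str) -> str | None:
        return self._sire[individual]

    def parents(self, individual: str) -> tuple[str | None, str | None]:
        return self._dam[individual], self._sire[individual]

    def is_founder(self, individual: str) -> bool:
        return self._dam[individual] is None and self._sire[individual] is None

    @property
    def founders(self) -> list[str]:
        return [i for i in self.ids if self.is_founder(i)]

    @property
    def males(self) -> list[str]:
        return [i for i in self.ids if self._sex[i] == "M"]

    @property
    def females(self) -> list[str]:
        return [i for i in self.ids if self._sex[i] == "F"]

    def depth(self, individual: str) -> int:
        """Generation number: founders 0, child = 1 + max(parent depths)."""
        cached = self._depth.get(individual)
        if cached is not None:
            return cached
        stack = [individual]
        while stack:
            node = stack[-1]
            if node in self._depth:
                stack.pop()
                continue
            pending = [
                p
                for p in self.parents(node)
                if p is not None and p not in self._depth
            ]
            if pending:
                stack.extend(pending)
                continue
            stack.pop()
            parent_depths = [
                self._depth[p] for p in self.parents(node) if p is not None
            ]
            self._depth[node] = 1 + max(parent_depths) if parent_depths else 0
        return self._depth[individual]

    def ancestors(self, individual: str, max_generations: int | None = None) -> set[str]:
        """Known ancestors of ``individual`` (excluding itself).

        ``max_generations=1`` gives parents, ``2`` parents + grandparents.
        """
        out: set[str] = set()
        frontier = {individual}
        generation = 0
        while frontier and (max_generations is None or generation < max_generations):
            frontier = {
                p
                for child in frontier
                for p in self.parents(child)
                if p is not None
            }
            out |= frontier
            generation += 1
        return out

    def graft(self, sires: Mapping[str, str]) -> "Pedigree":
        """Return a new pedigree with the given individuals' sires replaced.

        Used to evaluate relatedness under hypothetical (unresolved)
        paternity assignments.
        """
        table = self.table.copy()
        sire_col = [
            sires.get(i, self._sire[i]) for i in self.ids
        ]
        table["sire"] = sire_col
        return Pedigree(table)

    def subset_frame(self, individuals: Iterable[str]) -> pd.DataFrame:
        keep = set(individuals)
        return self.table[self.table["id"].astype(str).isin(keep)].copy()


def write_pedigree_tsv(pedigree: Pedigree, path) -> None:
    """Write id, sex, birth_year, dam, sire (blank for missing parents)."""
    df = pedigree.table.copy()
    df = df.rename(columns={"birth": "birth_year"})
    df[["id", "sex", "birth_year", "dam", "sire"]].to_csv(
        path, sep="\t", index=False, na_rep=""
    )


def read_pedigree_tsv(path) -> Pedigree:
    df = pd.read_csv(path, sep="\t", dtype={"id": str, "dam": str, "sire": str})
    if "birth_year" in df.columns:
        df = df.rename(columns={"birth_year": "birth"})
    return Pedigree(df)
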