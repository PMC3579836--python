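"""Diploid STR genotype table with per-locus missingness.

Alleles are small non-negative integers; a missing allele is coded -1
and loci are either fully typed or fully missing for an individual (the
unit of typing is the locus).  The on-disk format is a TSV with an id
column and two columns per locus (``<locus>.1``, ``<locus>.2``), blanks
for missing calls; a GenePop writer is provided for interoperability
with population-genetics software.
"""

from __future__ import annotations

from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = ["GenotypeTable", "read_genotypes_tsv", "write_genotypes_tsv", "write_genepop"]

MISSING = -1


class GenotypeTable:
    """Per-individual, per-locus diploid allele pairs.

    Parameters
    ----------
    ids:
        Individual identifiers, one per row.
    loci:
        Locus names, one per data column pair.
    data:
        Integer array of shape ``(n_individuals, n_loci, 2)``; missing
        alleles are ``-1`` (both alleles of an untyped locus are -1).
    """

    def __init__(self, ids: Sequence[str], loci: Sequence[str], data: np.ndarray):
        data = np.asarray(data, dtype=np.int32)
        if data.shape != (len(ids), len(loci), 2):
            raise ValueError(
                f"data shape {data.shape} != ({len(ids)}, {len(loci)}, 2)"
            )
        self.ids = [str(i) for i in ids]
        self.loci = [str(l) for l in loci]
        self.data = data
        self._row = {i: k for k, i in enumerate(self.ids)}
        self._col = {l: k for k, l in enumerate(self.loci)}

    def __contains__(self, individual: str) -> bool:
        return individual in self._row

    @property
    def n_individuals(self) -> int:
        return len(self.ids)

    @property
    def n_loci(self) -> int:
        return len(self.loci)

    def row(self, individual: str) -> np.ndarray:
        """(n_loci, 2) allele array for one individual."""
        return self.data[self._row[individual]]

    def genotype(self, individual: str, locus: str) -> tuple[int, int] | None:
        """Sorted allele pair, or None if the locus is untyped."""
        a, b = self.data[self._row[individual], self._col[locus]]
        if a == MISSING or b == MISSING:
            return None
        return (int(a), int(b)) if a <= b else (int(b), int(a))

    def typed_mask(self) -> np.ndarray:
        """(n, L) boolean: locus typed for individual."""
        return (self.data >= 0).all(axis=2)

    def n_typed_loci(self, individual: str) -> int:
        return int(self.typed_mask()[self._row[individual]].sum())

    def locus_column(self, locus: str) -> np.ndarray:
        """(n, 2) allele array across individuals at one locus."""
        return self.data[:, self._col[locus], :]

    def is_genotyped(self, individual: str) -> bool:
        return individual in self._row and bool(
            (self.data[self._row[individual]] >= 0).any()
        )

    def subset(self, individuals: Iterable[str]) -> "GenotypeTable":
        keep = [i for i in individuals if i in self._row]
        rows = [self._row[i] for i in keep]
        return GenotypeTable(keep, self.loci, self.data[rows])

    def to_frame(self) -> pd.DataFrame:
        cols: dict[str, object] = {"id": self.ids}
        for j, locus in enumerate(self.loci):
            for k in (0, 1):
                vals = self.data[:, j, k].astype(object)
                cols[f"{locus}.{k + 1}"] = [v if v >= 0 else None for v in vals]
        return pd.DataFrame(cols)

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "GenotypeTable":
        ids = [str(i) for i in df["id"]]
        pair_cols = [c for c in df.columns if c != "id"]
        loci = []
        for c in pair_cols:
            base = c.rsplit(".", 1)[0]
            if base not in loci:
                loci.append(base)
        data = np.full((len(ids), len(loci), 2), MISSING, dtype=np.int32)
        for j, locus in enumerate(loci):
            for k in (0, 1):
                col = df[f"{locus}.{k + 1}"]
                vals = pd.to_numeric(col, errors="coerce")
                data[:, j, k] = np.where(vals.notna(), vals.fillna(MISSING), MISSING)
        return cls(ids, loci, data)


def write_genotypes_tsv(table: GenotypeTable, path) -> None:
    table.to_frame().to_csv(path, sep="\t", index=False, na_rep="")


def read_genotypes_tsv(path) -> GenotypeTable:
    return GenotypeTable.from_frame(pd.read_csv(path, sep="\t", dtype={"id": str}))


def write_genepop(table: GenotypeTable, path, title: str = "kinface export") -> None:
    """GenePop 4 format, one population, 3-digit allele codes (allele + 1;
    000 = missing)."""
    with open(path, "w") as fh:
        fh.write(title + "\n")
        for locus in table.loci:
            fh.write(locus + "\n")
        fh.write("POP\n")
        for i, ind in enumerate(table.ids):
            codes = []
            for j in range(table.n_loci):
                a, b = table.data[i, j]
                ca = 0 if a < 0 else int(a) + 1
                cb = 0 if b < 0 else int(b) + 1
                codes.append(f"{ca:03d}{cb:03d}")
            fh.write(f"{ind}, " + " ".join(codes) + "\n")
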