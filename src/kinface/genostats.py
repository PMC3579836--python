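"""Per-locus diagnostic statistics for STR genotype databases.

Observed and unbiased expected heterozygosity, polymorphic information
content, a seedable Monte-Carlo exact Hardy-Weinberg test (alleles are
permuted among genotypes, conditioning on the observed allele counts),
a heterozygote-deficit z-score used to flag possible null alleles, and
the mother-offspring mismatch rate used as the database-wide typing
error estimate.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .genotypes import GenotypeTable, MISSING
from .pedigree import Pedigree

__all__ = [
    "LocusSummary",
    "allele_frequencies",
    "locus_summary",
    "locus_summaries",
    "summarize_loci",
    "hwe_exact_mc",
    "mother_offspring_error_rate",
]


@dataclass(frozen=True)
class LocusSummary:
    locus: str
    n_typed: int
    k: int
    allele_freqs: dict[int, float]
    Ho: float
    He: float
    PIC: float
    hwe_p: float  # NaN when undefined (monomorphic locus)
    null_allele_z: float
    null_allele_flag: bool


def _typed_rows(genotypes_at_locus: np.ndarray) -> np.ndarray:
    g = np.asarray(genotypes_at_locus)
    return g[(g >= 0).all(axis=1)]


def allele_frequencies(genotypes_at_locus: np.ndarray) -> dict[int, float]:
    """Allele frequency = allele count / (2 x typed individuals)."""
    typed = _typed_rows(genotypes_at_locus)
    if len(typed) == 0:
        raise ValueError("all genotypes missing at locus")
    alleles, counts = np.unique(typed.ravel(), return_counts=True)
    total = counts.sum()
    return {int(a): float(c) / total for a, c in zip(alleles, counts)}


def hwe_exact_mc(
    genotypes_at_locus: np.ndarray,
    n_perm: int = 10_000,
    seed: int = 0,
) -> float:
    """Monte-Carlo exact Hardy-Weinberg test.

    The pooled alleles are permuted among genotypes ``n_perm`` times
    (which samples the null conditional on allele counts) and the
    chi-square distance between genotype counts and their HWE
    expectations is compared with the observed value.  Returns
    ``(1 + #{T* >= T}) / (n_perm + 1)``.
    """
    typed = _typed_rows(genotypes_at_locus)
    n = len(typed)
    if n < 2:
        raise ValueError("need >= 2 typed individuals for HWE test")
    alleles = np.unique(typed.ravel())
    k = len(alleles)
    if k < 2:
        return float("nan")
    remap = {int(a): i for i, a in enumerate(alleles)}
    g = np.vectorize(remap.get)(typed)
    code = k * np.minimum(g[:, 0], g[:, 1]) + np.maximum(g[:, 0], g[:, 1])
    n_codes = k * k

    pool = g.ravel()
    counts = np.bincount(pool, minlength=k)
    p = counts / (2.0 * n)
    expected = np.zeros(n_codes)
    for i in range(k):
        for j in range(i, k):
            e = n * (p[i] ** 2 if i == j else 2 * p[i] * p[j])
            expected[k * i + j] = e
    live = expected > 0

    def stat(codes: np.ndarray) -> float:
        obs = np.bincount(codes, minlength=n_codes)
        return float(((obs[live] - expected[live]) ** 2 / expected[live]).sum())

    t_obs = stat(code)
    rng = np.random.default_rng(seed)
    perms = np.tile(pool, (n_perm, 1))
    perms = rng.permuted(perms, axis=1).reshape(n_perm, n, 2)
    lo = np.minimum(perms[:, :, 0], perms[:, :, 1])
    hi = np.maximum(perms[:, :, 0], perms[:, :, 1])
    codes = k * lo + hi
    flat = codes + n_codes * np.arange(n_perm)[:, None]
    obs = np.bincount(flat.ravel(), minlength=n_codes * n_perm).reshape(
        n_perm, n_codes
    )
    t_null = ((obs[:, live] - expected[live]) ** 2 / expected[live]).sum(axis=1)
    exceed = int((t_null >= t_obs - 1e-12).sum())
    return (1 + exceed) / (n_perm + 1)


def locus_summary(
    genotypes_at_locus: np.ndarray,
    locus: str = "locus",
    n_perm: int = 10_000,
    seed: int = 0,
    unbiased_he: bool = True,
    null_z_threshold: float = 3.0,
) -> LocusSummary:
    """Full diagnostic summary of one locus.

    He uses Nei's small-sample correction ``2n/(2n-1)`` by default
    (disable with ``unbiased_he=False`` for raw gene diversity);
    PIC = 1 - sum p_i^2 - sum_{i<j} 2 p_i^2 p_j^2.  A monomorphic locus
    reports He = PIC = 0 with an undefined (NaN) HWE p-value.
    """
    typed = _typed_rows(genotypes_at_locus)
    n = len(typed)
    if n < 2:
        raise ValueError("need >= 2 typed individuals")
    freqs = allele_frequencies(typed)
    p = np.array(list(freqs.values()))
    k = len(p)
    ho = float((typed[:, 0] != typed[:, 1]).mean())
    sum_p2 = float((p**2).sum())
    he = 1.0 - sum_p2
    if unbiased_he:
        he *= 2 * n / (2 * n - 1.0)
    # sum_{i<j} 2 p_i^2 p_j^2 = (sum p^2)^2 - sum p^4
    pic = 1.0 - sum_p2 - (sum_p2**2 - float((p**4).sum()))
    if k < 2:
        he = pic = 0.0
        hwe_p = float("nan")
    else:
        hwe_p = hwe_exact_mc(typed, n_perm=n_perm, seed=seed)
    he_raw = (1.0 - sum_p2) if k >= 2 else 0.0
    if he_raw > 0:
        null_z = (ho - he_raw) / np.sqrt(he_raw * (1 - he_raw) / n)
    else:
        null_z = 0.0
    return LocusSummary(
        locus=locus,
        n_typed=n,
        k=k,
        allele_freqs=freqs,
        Ho=ho,
        He=float(he),
        PIC=float(pic),
        hwe_p=hwe_p,
        null_allele_z=float(null_z),
        null_allele_flag=bool(null_z < -null_z_threshold),
    )


def locus_summaries(
    table: GenotypeTable,
    n_perm: int = 10_000,
    seed: int = 0,
    unbiased_he: bool = True,
) -> pd.DataFrame:
    """One LocusSummary row per locus of a genotype table."""
    rows = []
    for j, locus in enumerate(table.loci):
        s = locus_summary(
            table.data[:, j, :],
            locus=locus,
            n_perm=n_perm,
            seed=seed + j,
            unbiased_he=unbiased_he,
        )
        rows.append(
            {
                "locus": s.locus,
                "n_typed": s.n_typed,
                "k": s.k,
                "Ho": s.Ho,
                "He": s.He,
                "PIC": s.PIC,
                "hwe_p": s.hwe_p,
                "null_allele_z": s.null_allele_z,
                "null_allele_flag": s.null_allele_flag,
            }
        )
    return pd.DataFrame(rows)


def summarize_loci(summaries: pd.DataFrame) -> pd.DataFrame:
    """Across-locus mean +/- SD footer for the numeric diagnostics."""
    cols = ["k", "Ho", "He", "PIC"]
    return pd.DataFrame(
        {
            "statistic": cols,
            "mean": [summaries[c].mean() for c in cols],
            "sd": [summaries[c].std(ddof=1) for c in cols],
        }
    )


def mother_offspring_error_rate(
    pedigree: Pedigree, table: GenotypeTable
) -> float:
    """Fraction of genotyped dam-offspring pairs with a Mendelian mismatch.

    A pair mismatches when, at one or more loci typed in both, mother
    and offspring share no allele.  This is the database-wide typing
    error diagnostic; it requires at least one genotyped pair.
    """
    n_pairs = 0
    n_mismatched = 0
    for child in pedigree.ids:
        dam = pedigree.dam(child)
        if dam is None or child not in table or dam not in table:
            continue
        gc = table.row(child)
        gm = table.row(dam)
        both = ((gc >= 0).all(axis=1)) & ((gm >= 0).all(axis=1))
        if not both.any():
            continue
        n_pairs += 1
        c, m = gc[both], gm[both]
        share = (
            (c[:, 0:1] == m) | (c[:, 1:2] == m)
        ).any(axis=1)
        if (~share).any():
            n_mismatched += 1
    if n_pairs == 0:
        raise ValueError("no genotyped dam-offspring pairs")
    return n_mismatched / n_pairs
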