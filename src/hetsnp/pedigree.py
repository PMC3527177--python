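"""Coefficient of parentage, heterozygosity and marker-based dissimilarity.

The coefficient of parentage (COP, Malecot coancestry) between two
individuals is the probability that alleles drawn at random from each are
identical by descent.  Cultivars are treated as non-inbred (F = 0), so
the self-coancestry is (1 + F)/2 = 0.5 and founders are pairwise
unrelated.  Heterozygosity is the fraction of a sample's scored markers
called AB; dissimilarity is the allele-sharing distance averaged over
shared scored loci.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .io import MISSING, GenotypeMatrix, PedigreeTable

_ALLELE_DOSE = {"AA": 0, "AB": 1, "BB": 2}


def cop(pedigree: PedigreeTable, x: str, y: str, _memo: dict | None = None) -> float:
    """Malecot coancestry f(x, y) under F = 0 for all individuals.

    f(x, x) = 0.5; f(x, y) = (f(sire_x, y) + f(dam_x, y)) / 2, descending
    the individual of greater pedigree depth (the standard tabular-method
    guard); unknown parents contribute 0; distinct founders are unrelated.
    """
    for ind in (x, y):
        if ind not in pedigree.parents:
            raise KeyError(f"pedigree: unknown individual {ind}")
    memo: dict = {} if _memo is None else _memo

    def f(a: str, b: str) -> float:
        if a == b:
            return 0.5
        key = (a, b) if a <= b else (b, a)
        if key in memo:
            return memo[key]
        # descend the deeper individual so recursion always terminates
        if pedigree.depth(a) < pedigree.depth(b):
            a, b = b, a
        sire, dam = pedigree.parents[a]
        if sire is None and dam is None:
            val = 0.0
        else:
            val = 0.5 * sum(f(p, b) for p in (sire, dam) if p is not None)
        memo[key] = val
        return val

    return f(x, y)


def cop_matrix(pedigree: PedigreeTable, ids: list[str] | None = None) -> pd.DataFrame:
    """Symmetric COP matrix over ``ids`` (default: every individual)."""
    ids = list(ids) if ids is not None else pedigree.individuals
    memo: dict = {}
    m = pd.DataFrame(0.0, index=ids, columns=ids)
    for i, a in enumerate(ids):
        for b in ids[i:]:
            v = cop(pedigree, a, b, _memo=memo)
            m.loc[a, b] = v
            m.loc[b, a] = v
    return m


def heterozygosity(calls) -> float:
    """Percentage of scored (non-missing) markers called AB for one sample."""
    vals = [c for c in calls if c != MISSING]
    if not vals:
        raise ValueError("heterozygosity undefined: all calls missing")
    return 100.0 * sum(c == "AB" for c in vals) / len(vals)


def dissimilarity(sample_i, sample_j) -> float:
    """Allele-sharing distance between two genotype vectors, in [0, 1].

    Per locus d = |dose_i - dose_j| / 2 where dose counts B alleles
    (AA-AA 0, AA-AB 0.5, AA-BB 1, AB-AB 0), averaged over loci scored in
    both samples.
    """
    gi, gj = list(sample_i), list(sample_j)
    if len(gi) != len(gj):
        raise ValueError("genotype vectors differ in length")
    dists = [
        abs(_ALLELE_DOSE[a] - _ALLELE_DOSE[b]) / 2.0
        for a, b in zip(gi, gj)
        if a != MISSING and b != MISSING
    ]
    if not dists:
        raise ValueError("no shared scored loci")
    return float(np.mean(dists))


def dissimilarity_matrix(gm: GenotypeMatrix) -> pd.DataFrame:
    ids = gm.samples
    m = pd.DataFrame(0.0, index=ids, columns=ids)
    for i, a in enumerate(ids):
        for b in ids[i + 1 :]:
            d = dissimilarity(gm.sample(a), gm.sample(b))
            m.loc[a, b] = d
            m.loc[b, a] = d
    return m


def correlate(x_vector, y_vector) -> float:
    """Pearson correlation between two equal-length vectors (n >= 3)."""
    x = np.asarray(x_vector, dtype=float)
    y = np.asarray(y_vector, dtype=float)
    if x.shape != y.shape or x.size < 3:
        raise ValueError("need equal-length vectors of at least 3 values")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("correlation undefined for zero-variance input")
    return float(stats.pearsonr(x, y)[0])
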