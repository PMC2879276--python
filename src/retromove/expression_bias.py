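"""Sex-biased expression classification and summaries.

A (gene, species) cell of the expression matrix is a signed log male/female
ratio plus a significance flag (the flags originate from replicate-level
Mann-Whitney U tests corrected for false discovery rate).  A cell is
male-biased when positive and significant, female-biased when negative and
significant, unbiased when assayed but not significant.  The module also
provides the replicate-level machinery (exact / tie-corrected-normal
Mann-Whitney, Benjamini-Hochberg step-up) used on synthetic or user
replicate data, and a configurable testis-expression call.
"""

from __future__ import annotations

from itertools import combinations
from math import comb
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .types import ExpressionMatrix, RetromoveError

MALE = "male"
FEMALE = "female"
UNBIASED = "unbiased"
MISSING = "missing"
CLASSES = (MALE, FEMALE, UNBIASED, MISSING)


def classify_cell(value: Optional[float], significant: bool) -> str:
    """Sex-bias class of one cell (positive = male-biased by convention)."""
    if value is None or (isinstance(value, float) and np.isnan(value)):
        return MISSING
    if significant and value > 0:
        return MALE
    if significant and value < 0:
        return FEMALE
    return UNBIASED


def classify_matrix(matrix: ExpressionMatrix) -> dict[str, dict[str, str]]:
    return {
        g: {
            sp: classify_cell(matrix.values[g][sp], matrix.significant[g][sp])
            for sp in matrix.species
        }
        for g in matrix.genes
    }


def count_class(
    matrix: ExpressionMatrix, cls: str, exclude: Iterable[str] = ()
) -> int:
    """Number of (gene, species) cells of the given class, omitting genes
    in ``exclude``."""
    skip = set(exclude)
    classes = classify_matrix(matrix)
    return sum(
        1
        for g in matrix.genes
        if g not in skip
        for sp in matrix.species
        if classes[g][sp] == cls
    )


def gene_consistency(matrix: ExpressionMatrix, gene: str) -> Optional[str]:
    """The gene's class when identical across all assayed species, else None.

    Missing cells are ignored; fewer than 2 assayed cells raises (no
    cross-species comparison is possible).
    """
    cells = [
        classify_cell(matrix.values[gene][sp], matrix.significant[gene][sp])
        for sp in matrix.species
    ]
    informative = [c for c in cells if c != MISSING]
    if len(informative) < 2:
        raise RetromoveError(f"{gene}: fewer than 2 assayed species")
    return informative[0] if len(set(informative)) == 1 else None


def consistent_genes(matrix: ExpressionMatrix) -> dict[str, str]:
    """All genes with the same class in every assayed species."""
    result = {}
    for g in matrix.genes:
        try:
            cls = gene_consistency(matrix, g)
        except RetromoveError:
            continue
        if cls is not None:
            result[g] = cls
    return result


def species_fraction_class(
    matrix: ExpressionMatrix, gene: str, cls: str
) -> float:
    """Fraction of the gene's assayed species falling in the given class."""
    cells = [
        classify_cell(matrix.values[gene][sp], matrix.significant[gene][sp])
        for sp in matrix.species
    ]
    informative = [c for c in cells if c != MISSING]
    if not informative:
        raise RetromoveError(f"{gene}: no assayed species")
    return sum(1 for c in informative if c == cls) / len(informative)


# ---------------------------------------------------------------------------
# replicate-level machinery


def _u_statistic(x: Sequence[float], y: Sequence[float]) -> float:
    u = 0.0
    for xi in x:
        for yj in y:
            if xi > yj:
                u += 1.0
            elif xi == yj:
                u += 0.5
    return u


def mann_whitney_bias(
    male: Sequence[float], female: Sequence[float]
) -> tuple[float, float]:
    """Two-sided Mann-Whitney U test of male vs female replicate values.

    For combined sample size <= 10 the p-value is computed by exact
    enumeration of all group assignments of the pooled values (tie-safe);
    larger samples use the tie-corrected normal approximation.  Returns
    (U of the male sample, two-sided p).
    """
    x, y = list(male), list(female)
    if not x or not y:
        raise ValueError("need at least one replicate per sex")
    n, m = len(x), len(y)
    u_obs = _u_statistic(x, y)
    if len(set(x) | set(y)) == 1:
        return u_obs, 1.0
    if n + m <= 10:
        pooled = x + y
        mid = n * m / 2.0
        dev_obs = abs(u_obs - mid)
        hits = 0
        total = comb(n + m, n)
        for picks in combinations(range(n + m), n):
            gx = [pooled[i] for i in picks]
            gy = [pooled[i] for i in range(n + m) if i not in picks]
            if abs(_u_statistic(gx, gy) - mid) >= dev_obs - 1e-12:
                hits += 1
        return u_obs, hits / total
    res = stats.mannwhitneyu(x, y, alternative="two-sided", method="asymptotic")
    return u_obs, float(res.pvalue)


def bh_fdr(pvals: Sequence[float], q: float = 0.05) -> list[bool]:
    """Benjamini-Hochberg step-up significance flags at FDR level ``q``."""
    p = np.asarray(pvals, dtype=float)
    if p.size == 0:
        return []
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    reject, *_ = multipletests(p, alpha=q, method="fdr_bh")
    return [bool(r) for r in reject]


def matrix_from_replicates(
    replicates: Mapping[tuple[str, str], tuple[Sequence[float], Sequence[float]]],
    species: Sequence[str],
    q: float = 0.05,
) -> ExpressionMatrix:
    """Build an expression matrix from per-cell (male, female) replicate
    values: the bias value is mean(male) - mean(female) and significance is
    Mann-Whitney + BH-FDR across all assayed cells."""
    keys = sorted(replicates)
    pvals = []
    for key in keys:
        male, female = replicates[key]
        _, p = mann_whitney_bias(male, female)
        pvals.append(p)
    flags = dict(zip(keys, bh_fdr(pvals, q)))
    genes = sorted({g for g, _ in keys})
    values = {g: {sp: None for sp in species} for g in genes}
    sig = {g: {sp: False for sp in species} for g in genes}
    bold = {g: {sp: False for sp in species} for g in genes}
    for (g, sp), (male, female) in replicates.items():
        values[g][sp] = float(np.mean(male) - np.mean(female))
        sig[g][sp] = flags[(g, sp)]
    return ExpressionMatrix(
        species=tuple(species), values=values, significant=sig, retro_copy=bold
    )


def testis_expressed(
    profile: Mapping[str, float],
    threshold: float = 100.0,
    enrichment: Optional[float] = None,
) -> bool:
    """Configurable testis-expression call on a per-tissue intensity profile.

    True when the testis signal reaches ``threshold`` and, when an
    ``enrichment`` ratio is given, testis/ovary >= enrichment.
    """
    testis = profile.get("testis")
    if testis is None:
        raise RetromoveError("profile lacks a testis signal")
    if testis < threshold:
        return False
    if enrichment is not None:
        ovary = profile.get("ovary", 0.0)
        if ovary > 0 and testis / ovary < enrichment:
            return False
    return True


def summarize_expression(
    matrix: ExpressionMatrix, male_outlier_genes: Iterable[str] = ("CG5029",)
) -> dict:
    """Headline expression summary: significant female / male cell counts
    (male excluding the configured outlier genes), per-outlier male species
    fraction, and the cross-species-consistent gene set."""
    outliers = tuple(male_outlier_genes)
    consistent = consistent_genes(matrix)
    return {
        "female_cells": count_class(matrix, FEMALE),
        "male_cells": count_class(matrix, MALE),
        "male_cells_excluding": {
            "genes": list(outliers),
            "count": count_class(matrix, MALE, exclude=outliers),
        },
        "male_fraction_per_outlier": {
            g: species_fraction_class(matrix, g, MALE)
            for g in outliers
            if g in matrix.genes
        },
        "consistent_genes": dict(sorted(consistent.items())),
        "n_genes": len(matrix.genes),
        "n_species": len(matrix.species),
    }
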