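"""Per-stage genetic diversity indices and the fixation-index permutation test.

Indices follow standard population-genetic usage for codominant markers:

* ``k`` — number of distinct alleles per locus; ``A`` — mean over loci.
* ``Ar`` — allelic richness rarefied to a common gene count ``g`` by the
  hypergeometric formula ``Ar = sum_a [1 - C(2N - N_a, g) / C(2N, g)]``,
  i.e. the expected number of distinct alleles in a random subsample of
  ``g`` gene copies.
* ``Ap`` — private alleles: alleles seen in exactly one stage.
* ``Ho`` — observed heterozygosity; ``HE`` — Nei's unbiased expected
  heterozygosity ``(2n/(2n-1)) (1 - sum p^2)``.
* ``F = 1 - Ho/HE`` — fixation index; multilocus F is the ratio of summed
  ``HE - Ho`` to summed ``HE`` over loci, tested against zero by Monte Carlo
  permutation of allele copies among individuals within each locus (the
  Hardy-Weinberg null), with a Bonferroni flag across the stage-level tests.
"""

from __future__ import annotations

from dataclasses import dataclass
from math import comb

import numpy as np
import pandas as pd

from palmflow.genotype_io import MISSING, GenotypeDataset, allele_frequencies

DEFAULT_SEED = 20140000


def allele_counts(data: GenotypeDataset, stage: str | None = None):
    """Distinct-allele count per locus, the total, and the mean A.

    Returns
    -------
    (k, total, A) : (dict locus -> int, int, float)
    """
    sub = data.subset(stage) if stage is not None else data
    k: dict[str, int] = {}
    for j, loc in enumerate(sub.loci):
        calls = sub.genotypes[:, j, :]
        k[loc] = int(np.unique(calls[calls != MISSING]).size)
    total = sum(k.values())
    return k, total, total / len(sub.loci)


def allelic_richness(
    data: GenotypeDataset, stage: str | None = None, rarefaction_n: int = 2
):
    """Rarefied allelic richness per locus and its mean over loci.

    ``rarefaction_n`` is the common gene count ``g`` (number of gene copies
    drawn without replacement).  With ``g`` equal to the full gene count the
    formula reduces to the raw allele count ``k``.
    """
    if rarefaction_n < 2:
        raise ValueError("rarefaction_n must be >= 2")
    sub = data.subset(stage) if stage is not None else data
    ar: dict[str, float] = {}
    for j, loc in enumerate(sub.loci):
        calls = sub.genotypes[:, j, :]
        alleles = calls[calls != MISSING]
        n_genes = alleles.size
        if n_genes < rarefaction_n:
            raise ValueError(
                f"locus {loc!r}: gene count {n_genes} < rarefaction_n"
            )
        _, counts = np.unique(alleles, return_counts=True)
        denom = comb(n_genes, rarefaction_n)
        ar[loc] = float(
            sum(
                1.0 - comb(n_genes - int(na), rarefaction_n) / denom
                for na in counts
            )
        )
    return ar, float(np.mean(list(ar.values())))


def private_alleles(data: GenotypeDataset) -> dict[str, int]:
    """Count alleles observed in exactly one stage, per stage."""
    stages = sorted(set(data.stages))
    if len(stages) < 2:
        raise ValueError("private alleles need at least 2 stages")
    seen: dict[str, set[tuple[str, int]]] = {s: set() for s in stages}
    for s in stages:
        mask = data.stage_mask(s)
        for j, loc in enumerate(data.loci):
            calls = data.genotypes[mask, j, :]
            for a in np.unique(calls[calls != MISSING]):
                seen[s].add((loc, int(a)))
    ap = {}
    for s in stages:
        others = set().union(*(seen[t] for t in stages if t != s))
        ap[s] = len(seen[s] - others)
    return ap


def heterozygosities(data: GenotypeDataset, stage: str | None = None):
    """Observed and unbiased expected heterozygosity per locus and their means.

    Returns
    -------
    (ho, he, ho_mean, he_mean) : per-locus dicts and multilocus means.
    """
    sub = data.subset(stage) if stage is not None else data
    ho: dict[str, float] = {}
    he: dict[str, float] = {}
    for j, loc in enumerate(sub.loci):
        calls = sub.genotypes[:, j, :]
        ok = calls[:, 0] != MISSING
        n = int(ok.sum())
        if n < 2:
            continue
        g = calls[ok]
        ho[loc] = float(np.mean(g[:, 0] != g[:, 1]))
        _, counts = np.unique(g.ravel(), return_counts=True)
        p = counts / (2 * n)
        he[loc] = float((2 * n / (2 * n - 1)) * (1.0 - np.sum(p**2)))
    if not ho:
        raise ValueError("no locus with >= 2 non-missing individuals")
    return ho, he, float(np.mean(list(ho.values()))), float(np.mean(list(he.values())))


def _multilocus_F(ho: dict[str, float], he: dict[str, float]) -> float:
    """Ratio of summed heterozygote deficits to summed HE over loci."""
    loci = [l for l in he if he[l] > 0]
    num = sum(he[l] - ho[l] for l in loci)
    den = sum(he[l] for l in loci)
    return num / den


def fixation_index(
    data: GenotypeDataset,
    stage: str | None = None,
    n_perm: int = 1000,
    alpha: float = 0.05,
    n_tests: int = 1,
    seed: int | None = DEFAULT_SEED,
):
    """Multilocus fixation index with a Monte Carlo permutation test.

    The null distribution shuffles the 2n allele copies among individuals
    within each locus independently (Hardy-Weinberg proportions), and the
    two-sided p-value is the proportion of permuted ``|F*| >= |F|`` (the
    observed statistic counts as one permutation).  ``n_tests`` sets the
    Bonferroni family size for the significance flag.

    Returns
    -------
    dict with keys ``F``, ``F_per_locus``, ``p_value``, ``significant``.
    """
    sub = data.subset(stage) if stage is not None else data
    ho, he, _, _ = heterozygosities(sub)
    excluded = [l for l in he if he[l] <= 0]
    F_per_locus = {
        l: 1.0 - ho[l] / he[l] for l in he if he[l] > 0
    }
    F_obs = _multilocus_F(ho, he)

    rng = np.random.default_rng(seed)
    # allele pools per retained locus (non-missing copies only)
    pools = []
    for j, loc in enumerate(sub.loci):
        if loc in excluded or loc not in he:
            pools.append(None)
            continue
        calls = sub.genotypes[:, j, :]
        g = calls[calls[:, 0] != MISSING]
        pools.append((loc, g.ravel().copy()))
    exceed = 1  # observed included
    for _ in range(n_perm):
        ho_p: dict[str, float] = {}
        he_p: dict[str, float] = {}
        for item in pools:
            if item is None:
                continue
            loc, pool = item
            perm = rng.permutation(pool).reshape(-1, 2)
            ho_p[loc] = float(np.mean(perm[:, 0] != perm[:, 1]))
            he_p[loc] = he[loc]  # allele frequencies unchanged by shuffling
        F_star = _multilocus_F(ho_p, he_p)
        if abs(F_star) >= abs(F_obs) - 1e-15:
            exceed += 1
    p = exceed / (n_perm + 1)
    return {
        "F": F_obs,
        "F_per_locus": F_per_locus,
        "p_value": p,
        "significant": p < alpha / max(n_tests, 1),
        "excluded_loci": excluded,
        "n_perm": n_perm,
        "seed": seed,
    }


@dataclass
class DiversitySummary:
    """Per-stage diversity table mirroring the classic k/Ar/Ap/A/Ho/HE/F layout."""

    table: pd.DataFrame
    per_locus: dict[str, pd.DataFrame]


def diversity_summary(
    data: GenotypeDataset,
    rarefaction_n: int | None = None,
    n_perm: int = 1000,
    alpha: float = 0.05,
    seed: int | None = DEFAULT_SEED,
) -> DiversitySummary:
    """Full per-stage diversity table: n, k, Ar, Ap, A, Ho, HE, F, F p-value.

    ``rarefaction_n`` defaults to the minimum per-locus gene count across
    stages, the largest rarefaction depth valid for every stage.
    """
    stages = sorted(set(data.stages))
    if rarefaction_n is None:
        g_min = None
        for s in stages:
            sub = data.subset(s)
            for j in range(len(sub.loci)):
                calls = sub.genotypes[:, j, :]
                n_genes = int((calls != MISSING).sum())
                g_min = n_genes if g_min is None else min(g_min, n_genes)
        rarefaction_n = max(int(g_min), 2)
    ap = private_alleles(data) if len(stages) > 1 else {s: 0 for s in stages}
    rows = []
    per_locus = {}
    for s in stages:
        sub = data.subset(s)
        k, k_total, A = allele_counts(sub)
        ar, ar_mean = allelic_richness(sub, rarefaction_n=rarefaction_n)
        ho, he, ho_mean, he_mean = heterozygosities(sub)
        fx = fixation_index(
            sub, n_perm=n_perm, alpha=alpha, n_tests=len(stages), seed=seed
        )
        rows.append(
            {
                "stage": s,
                "n": sub.n,
                "k": k_total,
                "Ar": ar_mean,
                "Ap": ap[s],
                "A": A,
                "Ho": ho_mean,
                "HE": he_mean,
                "F": fx["F"],
                "F_p": fx["p_value"],
                "F_significant": fx["significant"],
            }
        )
        per_locus[s] = pd.DataFrame(
            {
                "locus": list(k),
                "k": [k[l] for l in k],
                "Ar": [ar[l] for l in k],
                "Ho": [ho.get(l, np.nan) for l in k],
                "HE": [he.get(l, np.nan) for l in k],
            }
        )
    return DiversitySummary(table=pd.DataFrame(rows), per_locus=per_locus)
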