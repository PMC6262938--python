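"""Spatial genetic structure: Loiselle coancestry, correlograms, bk and Sp.

The pairwise coancestry (kinship) coefficient of Loiselle et al. is computed
for every pair of individuals relative to the sample allele frequencies.  For
locus ``l`` with reference frequencies ``p_a`` and individual allele dosages
``p_ia`` (0, 1/2 or 1 per allele):

    f_ij,l = [ sum_a (p_ia - p_a)(p_ja - p_a) + w_l / (n_l - 1) ] / w_l,
    w_l    = sum_a p_a (1 - p_a),

with ``n_l`` the number of genotyped individuals at the locus; the multilocus
theta_ij is the w_l-weighted mean over loci (monomorphic loci carry zero
weight and drop out).

SGS is summarised by (i) a correlogram of mean theta over distance classes
with a permutation envelope (individual spatial positions shuffled against
genotypes), and (ii) the regression slope ``bk`` of theta_ij on ln(d_ij) over
all pairs, its permutation p-value, and the scaled statistic

    Sp = -bk / (1 - theta_1),

where ``theta_1`` is the mean coancestry within the first distance class.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from palmflow.genotype_io import (
    MISSING,
    AlleleFrequencyTable,
    GenotypeDataset,
    allele_frequencies,
    pairwise_distances,
)

DEFAULT_SEED = 20140000


@dataclass
class CoancestryMatrix:
    """Pairwise multilocus Loiselle coancestry for one stage sample."""

    stage: str | None
    theta: np.ndarray  # (n, n) symmetric; diagonal is NaN (not a pair)
    ids: list[str]
    locus_weights: dict[str, float]

    @property
    def pair_values(self) -> np.ndarray:
        iu = np.triu_indices(len(self.ids), k=1)
        return self.theta[iu]


@dataclass
class Correlogram:
    bounds: np.ndarray  # upper bounds (m), strictly increasing
    mean_distance: np.ndarray
    n_pairs: np.ndarray
    theta_mean: np.ndarray
    ci_low: np.ndarray
    ci_high: np.ndarray
    significant: np.ndarray
    n_perm: int

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "class": np.arange(1, len(self.bounds) + 1),
                "upper_bound_m": self.bounds,
                "mean_distance_m": self.mean_distance,
                "n_pairs": self.n_pairs,
                "theta": self.theta_mean,
                "ci_low": self.ci_low,
                "ci_high": self.ci_high,
                "significant": self.significant,
            }
        )


@dataclass
class SGSSummary:
    theta1: float
    first_class_bound: float
    bk: float
    bk_p_value: float
    sp: float
    n_perm: int
    seed: int | None
    n_pairs: int
    excluded_zero_distance_pairs: int = 0


def loiselle_coancestry(
    data: GenotypeDataset,
    stage: str | None = None,
    freqs: AlleleFrequencyTable | None = None,
) -> CoancestryMatrix:
    """Multilocus Loiselle coancestry matrix for one stage.

    Reference frequencies default to the analysed stage's own sample (each
    stage analysed independently); pass ``freqs`` to override.
    """
    sub = data.subset(stage) if stage is not None else data
    if freqs is None:
        freqs = allele_frequencies(sub)
    n = sub.n
    num = np.zeros((n, n))
    den = np.zeros((n, n))
    weights: dict[str, float] = {}
    for j, loc in enumerate(sub.loci):
        if loc not in freqs.freqs:
            continue
        alleles, p = freqs.as_arrays(loc)
        w = float(np.sum(p * (1.0 - p)))
        weights[loc] = w
        if w <= 0:  # monomorphic: zero weight, excluded
            continue
        calls = sub.genotypes[:, j, :]
        ok = calls[:, 0] != MISSING
        n_l = int(ok.sum())
        if n_l < 2:
            continue
        # dosage matrix: individual allele frequency p_ia in {0, .5, 1}
        dosage = (
            (calls[:, :, None] == alleles[None, None, :]).sum(axis=1) / 2.0
        )
        X = dosage - p[None, :]
        X[~ok] = 0.0
        M = X @ X.T + w / (n_l - 1)
        V = np.outer(ok, ok).astype(float)
        num += V * M
        den += V * w
    with np.errstate(invalid="ignore", divide="ignore"):
        theta = np.where(den > 0, num / np.where(den > 0, den, 1.0), np.nan)
    np.fill_diagonal(theta, np.nan)
    return CoancestryMatrix(
        stage=stage, theta=theta, ids=list(sub.ids), locus_weights=weights
    )


def build_distance_classes(
    distances: np.ndarray, n_classes: int = 10
) -> np.ndarray:
    """Equal-frequency distance-class upper bounds from a distance matrix.

    Pairs tied exactly on a boundary fall in the lower class.  Returns the
    strictly increasing array of upper bounds (last = max distance).
    """
    d = _pair_vector(distances)
    if np.unique(d).size < n_classes:
        raise ValueError(
            f"need >= {n_classes} distinct pairwise distances, "
            f"got {np.unique(d).size}"
        )
    qs = np.quantile(d, np.arange(1, n_classes + 1) / n_classes)
    bounds = np.unique(qs)
    if bounds.size < n_classes:
        warnings.warn(
            f"tied distances collapse {n_classes} classes to {bounds.size}"
        )
    return bounds


def _pair_vector(mat: np.ndarray) -> np.ndarray:
    iu = np.triu_indices(mat.shape[0], k=1)
    return mat[iu]


def _class_labels(distances: np.ndarray, bounds: np.ndarray) -> np.ndarray:
    """Per-pair class index (n, n); boundary ties go to the lower class."""
    lab = np.searchsorted(bounds, distances, side="left")
    return np.minimum(lab, len(bounds) - 1)


def sgs_correlogram(
    coancestry: CoancestryMatrix,
    distances: np.ndarray,
    bounds: np.ndarray | None = None,
    n_classes: int = 10,
    n_perm: int = 10000,
    ci: float = 0.95,
    seed: int | None = DEFAULT_SEED,
) -> Correlogram:
    """Mean coancestry per distance class with a permutation envelope.

    The null shuffles individual spatial positions against genotypes and
    recomputes the per-class means; the envelope is the central ``ci``
    interval of the permuted means, and a class is flagged significant when
    the observed mean falls outside it.
    """
    theta = coancestry.theta
    n = theta.shape[0]
    if distances.shape != (n, n):
        raise ValueError("distance matrix not conformable with coancestry")
    if bounds is None:
        bounds = build_distance_classes(distances, n_classes)
    iu = np.triu_indices(n, k=1)
    labels = _class_labels(distances, bounds)[iu]
    th = theta[iu]
    d = distances[iu]
    n_cls = len(bounds)
    counts = np.bincount(labels, minlength=n_cls)
    with np.errstate(invalid="ignore"):
        obs = np.bincount(labels, weights=th, minlength=n_cls) / counts
        mean_d = np.bincount(labels, weights=d, minlength=n_cls) / counts

    rng = np.random.default_rng(seed)
    perm_means = np.empty((n_perm, n_cls))
    flat_labels = labels
    for b in range(n_perm):
        p = rng.permutation(n)
        tp = theta[np.ix_(p, p)][iu]
        perm_means[b] = (
            np.bincount(flat_labels, weights=tp, minlength=n_cls) / counts
        )
    alpha = (1.0 - ci) / 2.0
    lo = np.nanquantile(perm_means, alpha, axis=0)
    hi = np.nanquantile(perm_means, 1.0 - alpha, axis=0)
    sig = (obs < lo) | (obs > hi)
    empty = counts == 0
    lo[empty] = np.nan
    hi[empty] = np.nan
    sig[empty] = False
    return Correlogram(
        bounds=bounds,
        mean_distance=mean_d,
        n_pairs=counts,
        theta_mean=obs,
        ci_low=lo,
        ci_high=hi,
        significant=sig,
        n_perm=n_perm,
    )


def sp_statistic(
    coancestry: CoancestryMatrix,
    distances: np.ndarray,
    bounds: np.ndarray | None = None,
    n_classes: int = 10,
    n_perm: int = 10000,
    seed: int | None = DEFAULT_SEED,
) -> SGSSummary:
    """Regression slope bk of theta on ln distance, its permutation test, Sp.

    ``bk`` is the least-squares slope over all individual pairs; the p-value
    permutes spatial positions and counts ``|bk*| >= |bk|``; theta_1 is the
    observed mean coancestry in the first distance class.
    """
    theta = coancestry.theta
    n = theta.shape[0]
    if bounds is None:
        bounds = build_distance_classes(distances, n_classes)
    iu = np.triu_indices(n, k=1)
    d = distances[iu]
    th = theta[iu]
    keep = d > 0
    n_zero = int((~keep).sum())
    if n_zero:
        warnings.warn(f"excluding {n_zero} zero-distance pair(s) from regression")
    lnd_full = np.where(d > 0, np.log(np.where(d > 0, d, 1.0)), np.nan)

    def slope(th_vec: np.ndarray) -> float:
        m = keep & np.isfinite(th_vec)
        z = lnd_full[m] - lnd_full[m].mean()
        y = th_vec[m]
        return float(np.sum(z * (y - y.mean())) / np.sum(z * z))

    bk = slope(th)
    rng = np.random.default_rng(seed)
    exceed = 1
    for _ in range(n_perm):
        p = rng.permutation(n)
        tp = theta[np.ix_(p, p)][iu]
        if abs(slope(tp)) >= abs(bk) - 1e-18:
            exceed += 1
    p_value = exceed / (n_perm + 1)

    labels = _class_labels(distances, bounds)[iu]
    theta1 = float(np.nanmean(th[labels == 0]))
    sp = -bk / (1.0 - theta1)
    return SGSSummary(
        theta1=theta1,
        first_class_bound=float(bounds[0]),
        bk=bk,
        bk_p_value=p_value,
        sp=sp,
        n_perm=n_perm,
        seed=seed,
        n_pairs=int(keep.sum()),
        excluded_zero_distance_pairs=n_zero,
    )


def sp_from_components(bk: float, theta1: float) -> float:
    """Sp = -bk / (1 - theta_1), the scaled SGS intensity statistic."""
    return -bk / (1.0 - theta1)


def analyze_stage_sgs(
    data: GenotypeDataset,
    stage: str | None,
    n_classes: int = 10,
    n_perm: int = 10000,
    seed: int | None = DEFAULT_SEED,
) -> tuple[Correlogram, SGSSummary]:
    """Convenience wrapper: coancestry -> classes -> correlogram + summary."""
    sub = data.subset(stage) if stage is not None else data
    cm = loiselle_coancestry(sub)
    dist = pairwise_distances(sub)
    bounds = build_distance_classes(dist, n_classes)
    corr = sgs_correlogram(cm, dist, bounds=bounds, n_perm=n_perm, seed=seed)
    summ = sp_statistic(cm, dist, bounds=bounds, n_perm=n_perm, seed=seed)
    return corr, summ
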