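"""Spatially explicit neighborhood mating model with an exponential-power kernel.

Each offspring with mother ``m`` is decomposed into three mating events:
self-fertilisation with probability ``s``, siring by pollen immigrating from
outside the plot with probability ``mp``, and siring by a within-plot male
``f`` with probability ``1 - s - mp``, weighted by the dispersal kernel
evaluated at the mother-father distance:

    L_o = s T(g_o | g_m, g_m) + mp P_bg(g_o | g_m)
          + (1 - s - mp) sum_{f != m} w_f T(g_o | g_m, g_f),
    w_f  propto  p(d_mf; a, b),

where the isotropic exponential-power kernel (density per unit area) is

    p(r) = b / (2 pi a^2 Gamma(2/b)) exp(-(r/a)^b),

with scale ``a`` (m) and shape ``b`` (b = 1 exponential, b = 2 Gaussian,
b < 1 fat-tailed) and mean dispersal distance delta = a Gamma(3/b)/Gamma(2/b).
``P_bg`` is Mendelian sampling of the paternal gamete from the population
allele pool.  Transition probabilities share the parentage module's
error-tolerant form.  Mothers are either fixed (e.g. the nearer parent from a
categorical assignment, or simulation truth) or marginalised over all
candidates with a seed kernel on offspring-mother distances, in which case
the seed kernel's (a, b) join the fit.

The likelihood is maximised over (s, mp, a, b) by multi-start Nelder-Mead on
transformed parameters (stick-breaking logits for s and mp, logs for a, b).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.optimize import minimize
from scipy.special import gammaln

from palmflow.genotype_io import (
    MISSING,
    AlleleFrequencyTable,
    GenotypeDataset,
    allele_frequencies,
)
from palmflow.parentage import _lod_arrays

DEFAULT_SEED = 20140000
_B_MIN, _B_MAX = 0.1, 8.0


@dataclass
class KernelParams:
    """Exponential-power dispersal kernel: scale a (m) and shape b."""

    a: float
    b: float

    def __post_init__(self) -> None:
        if self.a <= 0 or self.b <= 0:
            raise ValueError("kernel scale and shape must be positive")

    @property
    def delta(self) -> float:
        """Mean dispersal distance a Gamma(3/b) / Gamma(2/b)."""
        return kernel_mean_distance(self)


def exp_power_pdf(r, params: KernelParams) -> np.ndarray:
    """Kernel density per unit area at distance r (integrates to 1 over R^2)."""
    r = np.asarray(r, dtype=float)
    a, b = params.a, params.b
    norm = b / (2.0 * np.pi * a**2 * np.exp(gammaln(2.0 / b)))
    return norm * np.exp(-((r / a) ** b))


def kernel_mean_distance(params: KernelParams) -> float:
    """Mean dispersal distance delta = a Gamma(3/b) / Gamma(2/b)."""
    b = params.b
    return params.a * float(np.exp(gammaln(3.0 / b) - gammaln(2.0 / b)))


def sample_kernel(
    params: KernelParams, size: int, rng: np.random.Generator
) -> np.ndarray:
    """Draw 2-D displacements from the kernel (radius via Gamma(2/b), t^(1/b))."""
    t = rng.gamma(2.0 / params.b, 1.0, size=size)
    r = params.a * t ** (1.0 / params.b)
    phi = rng.uniform(0.0, 2.0 * np.pi, size=size)
    return np.column_stack([r * np.cos(phi), r * np.sin(phi)])


@dataclass
class NeighborhoodFit:
    s: float
    mp: float
    kernel: KernelParams
    seed_kernel: KernelParams | None
    delta: float
    loglik: float
    converged: bool
    n_offspring: int
    n_starts: int
    mother_mode: str


class NeighborhoodModel:
    """Precomputed genotype likelihood arrays for fast (s, mp, a, b) evaluation.

    The genotype transition products are parameter-free, so they are computed
    once; each likelihood evaluation is then a small weighted sum.
    """

    def __init__(
        self,
        data: GenotypeDataset,
        mothers: list[str] | None = None,
        candidate_stage: str = "reproductive",
        candidate_ids: list[str] | None = None,
        freqs: AlleleFrequencyTable | None = None,
        error_rate: float = 0.01,
    ):
        if candidate_ids is not None:
            cand_mask = np.array([i in set(candidate_ids) for i in data.ids])
        else:
            cand_mask = data.stage_mask(candidate_stage)
        off_mask = ~cand_mask
        if freqs is None:
            freqs = allele_frequencies(data)
        cand_idx = np.flatnonzero(cand_mask)
        off_idx = np.flatnonzero(off_mask)
        self.cand_ids = [data.ids[i] for i in cand_idx]
        self.off_ids = [data.ids[i] for i in off_idx]
        cand_geno = data.genotypes[cand_idx]
        off_geno = data.genotypes[off_idx]
        lod_pair, _, lod_single, _, logP = _lod_arrays(
            off_geno, cand_geno, data.loci, freqs, error_rate
        )
        # likelihood ratios relative to the unrelated hypothesis
        self.R_pair = np.exp(lod_pair)  # (k, m, m): T(g_o|g_m,g_f)/P(g_o)
        self.R_single = np.exp(lod_single)  # (k, m): background-pollen term
        self.logP = logP
        self.D = np.linalg.norm(
            data.coords[cand_idx][:, None, :] - data.coords[cand_idx][None, :, :],
            axis=2,
        )
        self.d_om = np.linalg.norm(
            data.coords[off_idx][:, None, :] - data.coords[cand_idx][None, :, :],
            axis=2,
        )
        self.mother_idx: np.ndarray | None
        if mothers is not None:
            lut = {c: i for i, c in enumerate(self.cand_ids)}
            keep, midx = [], []
            for i, mid in enumerate(mothers):
                if mid is not None and mid in lut:
                    keep.append(i)
                    midx.append(lut[mid])
            if not keep:
                raise ValueError("no offspring with a resolvable mother")
            self.n_excluded = len(self.off_ids) - len(keep)
            keep = np.asarray(keep)
            self.R_pair = self.R_pair[keep]
            self.R_single = self.R_single[keep]
            self.logP = self.logP[keep]
            self.d_om = self.d_om[keep]
            self.off_ids = [self.off_ids[i] for i in keep]
            self.mother_idx = np.asarray(midx)
        else:
            self.mother_idx = None
            self.n_excluded = 0
        self.k = self.R_pair.shape[0]
        self.m = len(self.cand_ids)

    def _pollen_weights(self, kernel: KernelParams) -> np.ndarray:
        """(m, m) row-normalised kernel weights over fathers f != m."""
        W = np.exp(-((self.D / kernel.a) ** np.clip(kernel.b, _B_MIN, _B_MAX)))
        np.fill_diagonal(W, 0.0)
        rows = W.sum(axis=1, keepdims=True)
        if np.any(rows <= 0) or not np.all(np.isfinite(rows)):
            raise FloatingPointError("kernel weight normalisation underflow")
        return W / rows

    def loglik(
        self,
        s: float,
        mp: float,
        kernel: KernelParams,
        seed_kernel: KernelParams | None = None,
    ) -> float:
        """Total log-likelihood; adds the constant sum of ln P(g_o)."""
        if s < 0 or mp < 0 or s + mp > 1:
            raise ValueError("need s, mp >= 0 and s + mp <= 1")
        W = self._pollen_weights(kernel)
        diag = np.arange(self.m)
        selfing = self.R_pair[:, diag, diag]  # (k, m)
        within = np.einsum("kmf,mf->km", self.R_pair, W)
        per_mother = s * selfing + mp * self.R_single + (1 - s - mp) * within
        if self.mother_idx is not None:
            L = per_mother[np.arange(self.k), self.mother_idx]
        else:
            if seed_kernel is None:
                raise ValueError(
                    "marginal mother mode requires a seed kernel"
                )
            V = np.exp(
                -(
                    (self.d_om / seed_kernel.a)
                    ** np.clip(seed_kernel.b, _B_MIN, _B_MAX)
                )
            )
            rows = V.sum(axis=1, keepdims=True)
            if np.any(rows <= 0):
                raise FloatingPointError("seed kernel weights underflow")
            V = V / rows
            L = np.einsum("km,km->k", V, per_mother)
        if np.any(L <= 0) or not np.all(np.isfinite(L)):
            return -np.inf
        return float(np.sum(np.log(L)) + np.sum(self.logP))


def nm_loglikelihood(
    data: GenotypeDataset,
    mothers: list[str] | None,
    s: float,
    mp: float,
    kernel: KernelParams,
    seed_kernel: KernelParams | None = None,
    candidate_stage: str = "reproductive",
    freqs: AlleleFrequencyTable | None = None,
    error_rate: float = 0.01,
) -> float:
    """One-shot neighborhood-model log-likelihood (see NeighborhoodModel)."""
    nm = NeighborhoodModel(
        data,
        mothers=mothers,
        candidate_stage=candidate_stage,
        freqs=freqs,
        error_rate=error_rate,
    )
    return nm.loglik(s, mp, kernel, seed_kernel=seed_kernel)


def _sigmoid(x: np.ndarray | float) -> np.ndarray | float:
    return 1.0 / (1.0 + np.exp(-x))


def _unpack(u: np.ndarray, marginal: bool):
    s = float(_sigmoid(u[0]))
    mp = float((1.0 - s) * _sigmoid(u[1]))
    a = float(np.exp(u[2]))
    b = float(np.clip(np.exp(u[3]), _B_MIN, _B_MAX))
    kernel = KernelParams(a=a, b=b)
    seed_kernel = None
    if marginal:
        seed_kernel = KernelParams(
            a=float(np.exp(u[4])),
            b=float(np.clip(np.exp(u[5]), _B_MIN, _B_MAX)),
        )
    return s, mp, kernel, seed_kernel


def fit_neighborhood_model(
    data: GenotypeDataset,
    mothers: list[str] | None = None,
    candidate_stage: str = "reproductive",
    candidate_ids: list[str] | None = None,
    freqs: AlleleFrequencyTable | None = None,
    error_rate: float = 0.01,
    starts: int = 8,
    seed: int | None = DEFAULT_SEED,
    init_scale: float = 100.0,
) -> NeighborhoodFit:
    """Maximum-likelihood fit of (s, mp, a, b) [+ seed kernel if marginal].

    With ``mothers`` given (id per offspring, None entries excluded), the
    mother of each offspring is fixed; otherwise mothers are marginalised
    over all candidates with a jointly fitted seed kernel.  Multi-start
    Nelder-Mead on transformed parameters; the best converged point wins, and
    a non-converged best point is returned flagged.
    """
    nm = NeighborhoodModel(
        data,
        mothers=mothers,
        candidate_stage=candidate_stage,
        candidate_ids=candidate_ids,
        freqs=freqs,
        error_rate=error_rate,
    )
    marginal = mothers is None
    rng = np.random.default_rng(seed)

    def neg(u: np.ndarray) -> float:
        try:
            s, mp, kern, skern = _unpack(u, marginal)
            return -nm.loglik(s, mp, kern, seed_kernel=skern)
        except (FloatingPointError, ValueError, OverflowError):
            return np.inf

    ndim = 6 if marginal else 4
    base = np.zeros(ndim)
    base[0] = -2.0  # s ~ 0.12
    base[1] = -0.5  # mp ~ 0.33 of the remainder
    base[2] = np.log(init_scale)
    base[3] = 0.0  # b = 1
    if marginal:
        base[4] = np.log(max(init_scale / 3.0, 1.0))
        base[5] = 0.0
    best = None
    any_converged = False
    for _ in range(max(starts, 1)):
        u0 = base + rng.normal(0.0, 1.0, size=ndim)
        res = minimize(
            neg, u0, method="Nelder-Mead",
            options={"maxiter": 4000, "xatol": 1e-5, "fatol": 1e-7},
        )
        if best is None or res.fun < best.fun:
            best = res
        any_converged = any_converged or bool(res.success)
    if not any_converged:
        warnings.warn("no Nelder-Mead start converged; returning best point")
    s, mp, kernel, seed_kernel = _unpack(best.x, marginal)
    return NeighborhoodFit(
        s=s,
        mp=mp,
        kernel=kernel,
        seed_kernel=seed_kernel,
        delta=kernel_mean_distance(kernel),
        loglik=-float(best.fun),
        converged=any_converged,
        n_offspring=nm.k,
        n_starts=max(starts, 1),
        mother_mode="marginal" if marginal else "fixed",
    )
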