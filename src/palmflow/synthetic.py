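"""Forward simulator of mapped SSR populations with known pedigree.

The generator mirrors the sampled system: a ~10 ha plot with ~59 reproductive
adults and ~189 regenerated offspring, 18 microsatellite loci with 4-18
alleles each, mixed mating (selfing rate ~0.04, pollen immigration ~0.4),
fat-tailed pollen dispersal, short-distance seed dispersal, and class-I
genotyping error.  Every offspring's true mother, father (or immigrant
status), and true pollen/seed distances are recorded, so parentage and
kernel-fitting routines can be scored against ground truth.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from palmflow.genotype_io import GenotypeDataset, write_genotypes
from palmflow.neighborhood import KernelParams, sample_kernel

IMMIGRANT = "IMMIGRANT"


@dataclass
class SimulationConfig:
    """Study-like defaults: 10 ha plot, 59 adults, 189 offspring, 18 loci."""

    plot_width: float = 316.23  # sqrt(10 ha)
    plot_height: float = 316.23
    n_adults: int = 59
    adult_process: str = "uniform"  # or "clustered"
    cluster_parents: int = 6
    cluster_sd: float = 30.0
    offspring_per_stage: dict[str, int] = field(
        default_factory=lambda: {"immature": 70, "young": 60, "seedling": 59}
    )
    n_loci: int = 18
    alleles_min: int = 4
    alleles_max: int = 18
    dirichlet_alpha: float = 0.5  # frequency sharpness (smaller = more uneven)
    selfing_rate: float = 0.04
    pollen_immigration: float = 0.40
    pollen_kernel: KernelParams = field(
        default_factory=lambda: KernelParams(a=250.0, b=1.0)
    )
    seed_kernel: KernelParams = field(
        default_factory=lambda: KernelParams(a=30.0, b=1.0)
    )
    error_rate: float = 0.01
    missing_rate: float = 0.02
    immigrant_divergence: float = 0.0  # Dirichlet resampling weight, 0 = same pool
    seed: int = 20140000

    def __post_init__(self) -> None:
        if self.selfing_rate + self.pollen_immigration > 1:
            raise ValueError("selfing_rate + pollen_immigration must be <= 1")
        if self.n_adults < 2 or self.n_loci < 1:
            raise ValueError("counts must be positive")
        if self.plot_width <= 0 or self.plot_height <= 0:
            raise ValueError("plot area must be positive")
        if min(self.offspring_per_stage.values(), default=0) < 0:
            raise ValueError("offspring counts must be non-negative")

    @property
    def n_offspring(self) -> int:
        return sum(self.offspring_per_stage.values())


@dataclass
class SyntheticTruth:
    """Ground-truth pedigree and mating parameters of one simulation."""

    table: pd.DataFrame  # per offspring: mother, father/IMMIGRANT, selfed, distances
    config: SimulationConfig

    def __post_init__(self) -> None:
        t = self.table
        if ((t["selfed"]) & (t["mother"] != t["father"])).any():
            raise ValueError("selfed offspring must have mother == father")
        if ((t["father"] == IMMIGRANT) & t["selfed"]).any():
            raise ValueError("immigrant-sired offspring cannot be selfed")


def _locus_frequencies(cfg: SimulationConfig, rng: np.random.Generator):
    """Per-locus allele codes and Dirichlet frequency vectors."""
    out = []
    for _ in range(cfg.n_loci):
        n_all = int(rng.integers(cfg.alleles_min, cfg.alleles_max + 1))
        codes = np.arange(100, 100 + 2 * n_all, 2)  # even fragment sizes
        p = rng.dirichlet(np.full(n_all, cfg.dirichlet_alpha))
        # keep every allele actually drawable
        p = np.maximum(p, 1e-3)
        p = p / p.sum()
        out.append((codes, p))
    return out


def _hwe_genotypes(
    loci_freqs, n: int, rng: np.random.Generator
) -> np.ndarray:
    geno = np.zeros((n, len(loci_freqs), 2), dtype=np.int64)
    for j, (codes, p) in enumerate(loci_freqs):
        geno[:, j, 0] = rng.choice(codes, size=n, p=p)
        geno[:, j, 1] = rng.choice(codes, size=n, p=p)
    return geno


def _reflect(x: np.ndarray, lo: float, hi: float) -> np.ndarray:
    """Reflect coordinates into [lo, hi] (period-2 folding)."""
    width = hi - lo
    y = np.mod(x - lo, 2.0 * width)
    y = np.where(y > width, 2.0 * width - y, y)
    return y + lo


def simulate_population(
    config: SimulationConfig, rng: np.random.Generator | None = None
):
    """Simulate one mapped population; returns (GenotypeDataset, SyntheticTruth).

    Adults are placed by the configured spatial process and drawn from the
    per-locus frequency vectors.  Each offspring draws a uniform mother, then
    selfs with probability s, is sired by an immigrant with probability mp,
    or by a within-plot father with kernel-density weights at the pairwise
    distance; its position is the mother's plus a seed-kernel displacement
    reflected at the plot boundary.  Observed genotypes are perturbed by the
    class-I error model and masked at the missing rate.
    """
    cfg = config
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    # adult positions
    if cfg.adult_process == "uniform":
        ax = rng.uniform(0, cfg.plot_width, cfg.n_adults)
        ay = rng.uniform(0, cfg.plot_height, cfg.n_adults)
    elif cfg.adult_process == "clustered":
        cx = rng.uniform(0, cfg.plot_width, cfg.cluster_parents)
        cy = rng.uniform(0, cfg.plot_height, cfg.cluster_parents)
        which = rng.integers(0, cfg.cluster_parents, cfg.n_adults)
        ax = _reflect(cx[which] + rng.normal(0, cfg.cluster_sd, cfg.n_adults),
                      0, cfg.plot_width)
        ay = _reflect(cy[which] + rng.normal(0, cfg.cluster_sd, cfg.n_adults),
                      0, cfg.plot_height)
    else:
        raise ValueError(f"unknown adult process {cfg.adult_process!r}")
    adult_coords = np.column_stack([ax, ay])
    loci_freqs = _locus_frequencies(cfg, rng)
    loci_names = [f"ssr{j + 1:02d}" for j in range(cfg.n_loci)]
    adult_geno = _hwe_genotypes(loci_freqs, cfg.n_adults, rng)
    adult_ids = [f"A{i + 1:03d}" for i in range(cfg.n_adults)]

    if cfg.immigrant_divergence > 0:
        imm_freqs = []
        for codes, p in loci_freqs:
            q = rng.dirichlet(p * len(p) / cfg.immigrant_divergence)
            q = np.maximum(q, 1e-4)
            imm_freqs.append((codes, q / q.sum()))
    else:
        imm_freqs = loci_freqs

    # pairwise adult distances and kernel weights for within-plot siring
    D = np.linalg.norm(
        adult_coords[:, None, :] - adult_coords[None, :, :], axis=2
    )
    W = np.exp(-((D / cfg.pollen_kernel.a) ** cfg.pollen_kernel.b))
    np.fill_diagonal(W, 0.0)
    rows = W.sum(axis=1)
    if np.any(rows <= 0) or not np.all(np.isfinite(rows)):
        raise ValueError(
            "pollen kernel underflows over the candidate set; "
            "use a larger scale or narrower plot"
        )
    W = W / rows[:, None]

    n_off = cfg.n_offspring
    stages = [s for s, c in cfg.offspring_per_stage.items() for _ in range(c)]
    off_ids = [f"O{i + 1:03d}" for i in range(n_off)]
    mothers = rng.integers(0, cfg.n_adults, size=n_off)
    u = rng.random(n_off)
    selfed = u < cfg.selfing_rate
    immigrant = (~selfed) & (u < cfg.selfing_rate + cfg.pollen_immigration)
    fathers = np.full(n_off, -1)
    fathers[selfed] = mothers[selfed]
    for i in np.flatnonzero(~selfed & ~immigrant):
        fathers[i] = rng.choice(cfg.n_adults, p=W[mothers[i]])

    geno = np.zeros((n_off, cfg.n_loci, 2), dtype=np.int64)
    imm_geno = _hwe_genotypes(imm_freqs, n_off, rng)  # pool of immigrant gametes
    for j in range(cfg.n_loci):
        pick_m = rng.integers(0, 2, n_off)
        geno[:, j, 0] = adult_geno[mothers, j, pick_m]
        pick_f = rng.integers(0, 2, n_off)
        within = fathers >= 0
        geno[within, j, 1] = adult_geno[
            fathers[within], j, pick_f[within]
        ]
        geno[~within, j, 1] = imm_geno[~within, j, 0]

    # seed dispersal: mother position + kernel displacement, reflected
    disp = sample_kernel(cfg.seed_kernel, n_off, rng)
    off_coords = np.column_stack(
        [
            _reflect(adult_coords[mothers, 0] + disp[:, 0], 0, cfg.plot_width),
            _reflect(adult_coords[mothers, 1] + disp[:, 1], 0, cfg.plot_height),
        ]
    )
    pollen_d = np.where(
        selfed, 0.0, np.where(fathers >= 0, D[mothers, fathers], np.nan)
    )
    seed_d = np.linalg.norm(off_coords - adult_coords[mothers], axis=1)

    # observation layer: class-I error then missingness, adults included
    all_geno = np.concatenate([adult_geno, geno])
    n_all = all_geno.shape[0]
    if cfg.error_rate > 0:
        hwe_pool = _hwe_genotypes(loci_freqs, n_all, rng)
        err = rng.random((n_all, cfg.n_loci)) < cfg.error_rate
        all_geno = np.where(err[:, :, None], hwe_pool, all_geno)
    if cfg.missing_rate > 0:
        miss = rng.random((n_all, cfg.n_loci)) < cfg.missing_rate
        all_geno = np.where(miss[:, :, None], 0, all_geno)

    data = GenotypeDataset(
        ids=adult_ids + off_ids,
        stages=["reproductive"] * cfg.n_adults + stages,
        coords=np.vstack([adult_coords, off_coords]),
        loci=loci_names,
        genotypes=all_geno,
    )
    truth = SyntheticTruth(
        table=pd.DataFrame(
            {
                "offspring": off_ids,
                "mother": [adult_ids[i] for i in mothers],
                "father": [
                    adult_ids[f] if f >= 0 else IMMIGRANT for f in fathers
                ],
                "selfed": selfed,
                "pollen_distance": pollen_d,
                "seed_distance": seed_d,
            }
        ),
        config=cfg,
    )
    return data, truth


def write_fixtures(
    dataset: GenotypeDataset, truth: SyntheticTruth, out_dir
) -> dict[str, Path]:
    """Write CSV + GenePop genotypes, coordinates, truth table, config snapshot."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "csv": out / "genotypes.csv",
        "genepop": out / "genotypes.gen",
        "coords": out / "coordinates.csv",
        "truth": out / "truth.csv",
        "config": out / "config.json",
    }
    write_genotypes(dataset, paths["csv"], dialect="csv")
    write_genotypes(
        dataset, paths["genepop"], dialect="genepop", coords_path=paths["coords"]
    )
    truth.table.to_csv(paths["truth"], index=False)
    cfg = asdict(truth.config)
    with open(paths["config"], "w") as fh:
        json.dump(cfg, fh, indent=2, default=float)
    return paths
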