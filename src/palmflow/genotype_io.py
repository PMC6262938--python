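"""Data model and I/O for mapped, stage-labelled diploid SSR genotypes.

The universal input of the pipeline is a sample of individually mapped plants,
each labelled with an ontogenetic stage (reproductive, immature, young,
seedling, or any free label), genotyped at a set of codominant microsatellite
loci.  Genotypes are unordered pairs of positive integer allele codes
(fragment sizes are fine; codes are opaque and never binned here); a call is
either complete (two alleles) or missing.

Two file dialects are supported:

* CSV with header ``id,stage,x,y,<locus>.1,<locus>.2,...`` and ``0`` as the
  missing-allele code;
* GenePop (4- or 6-digit allele encoding, ``0000``/``000000`` missing), with
  coordinates supplied in a separate CSV (``id,stage,x,y``) since GenePop
  carries no spatial information.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial.distance import squareform, pdist

MISSING = 0

STAGES = ("reproductive", "immature", "young", "seedling")


@dataclass
class GenotypeDataset:
    """Mapped diploid genotypes for one sample of individuals.

    Attributes
    ----------
    ids : list of str
        Unique individual identifiers.
    stages : list of str
        Ontogenetic stage label per individual.
    coords : ndarray, shape (n, 2)
        Planar x/y coordinates in meters.
    loci : list of str
        Ordered locus names.
    genotypes : ndarray of int, shape (n, n_loci, 2)
        Allele codes; ``0`` in both slots marks a missing call.  Within a
        call the pair is unordered; the stored order is not meaningful.
    """

    ids: list[str]
    stages: list[str]
    coords: np.ndarray
    loci: list[str]
    genotypes: np.ndarray

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        self.genotypes = np.asarray(self.genotypes, dtype=np.int64)
        self.validate()

    # -- invariants -------------------------------------------------------
    def validate(self) -> None:
        n = len(self.ids)
        if n < 2:
            raise ValueError("dataset needs at least 2 individuals")
        if len(self.loci) < 1:
            raise ValueError("dataset needs at least 1 locus")
        if len(set(self.ids)) != n:
            dupes = {i for i in self.ids if self.ids.count(i) > 1}
            raise ValueError(f"duplicate individual ids: {sorted(dupes)}")
        if self.coords.shape != (n, 2) or not np.all(np.isfinite(self.coords)):
            raise ValueError("coordinates must be finite and shaped (n, 2)")
        if self.genotypes.shape != (n, len(self.loci), 2):
            raise ValueError("genotype array must be shaped (n, n_loci, 2)")
        # no half-calls: alleles are both present or both missing
        half = (self.genotypes == MISSING).sum(axis=2) == 1
        if half.any():
            i, l = np.argwhere(half)[0]
            raise ValueError(
                f"half-called genotype for individual {self.ids[i]!r} "
                f"at locus {self.loci[l]!r}"
            )
        if (self.genotypes < 0).any():
            raise ValueError("allele codes must be non-negative integers")

    # -- convenience ------------------------------------------------------
    @property
    def n(self) -> int:
        return len(self.ids)

    def stage_mask(self, stage: str | None) -> np.ndarray:
        if stage is None:
            return np.ones(self.n, dtype=bool)
        return np.array([s == stage for s in self.stages])

    def subset(self, mask_or_stage) -> "GenotypeDataset":
        """Restrict to a boolean mask, an id list, or a stage label."""
        if isinstance(mask_or_stage, str):
            mask = self.stage_mask(mask_or_stage)
        else:
            mask = np.asarray(mask_or_stage)
            if mask.dtype != bool:
                keep = set(mask.tolist())
                mask = np.array([i in keep for i in self.ids])
        idx = np.flatnonzero(mask)
        if idx.size < 2:
            raise ValueError("subset leaves fewer than 2 individuals")
        return GenotypeDataset(
            ids=[self.ids[i] for i in idx],
            stages=[self.stages[i] for i in idx],
            coords=self.coords[idx],
            loci=list(self.loci),
            genotypes=self.genotypes[idx],
        )

    def drop_ids(self, exclude: list[str]) -> "GenotypeDataset":
        """Remove an explicit exclusion list of individual ids."""
        excl = set(exclude)
        mask = np.array([i not in excl for i in self.ids])
        return self.subset(mask)

    def missing_mask(self) -> np.ndarray:
        """Boolean (n, n_loci): True where the call is missing."""
        return self.genotypes[:, :, 0] == MISSING

    def to_dataframe(self) -> pd.DataFrame:
        cols: dict[str, object] = {
            "id": self.ids,
            "stage": self.stages,
            "x": self.coords[:, 0],
            "y": self.coords[:, 1],
        }
        for j, loc in enumerate(self.loci):
            cols[f"{loc}.1"] = self.genotypes[:, j, 0]
            cols[f"{loc}.2"] = self.genotypes[:, j, 1]
        return pd.DataFrame(cols)

    def __eq__(self, other) -> bool:
        if not isinstance(other, GenotypeDataset):
            return NotImplemented
        if self.ids != other.ids or self.stages != other.stages:
            return False
        if self.loci != other.loci:
            return False
        if not np.allclose(self.coords, other.coords):
            return False
        # allele order within a call is not meaningful
        return np.array_equal(
            np.sort(self.genotypes, axis=2), np.sort(other.genotypes, axis=2)
        )


@dataclass
class AlleleFrequencyTable:
    """Per-locus relative allele frequencies from non-missing calls.

    ``freqs[locus]`` maps allele code to relative frequency; ``gene_counts``
    holds 2 x (non-missing individuals) per locus.  Loci that were entirely
    missing in the requested subset are dropped and recorded in
    ``dropped_loci``.
    """

    loci: list[str]
    freqs: dict[str, dict[int, float]]
    gene_counts: dict[str, int]
    dropped_loci: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        for loc in self.loci:
            tot = sum(self.freqs[loc].values())
            if abs(tot - 1.0) > 1e-9:
                raise ValueError(f"frequencies at {loc!r} sum to {tot}, not 1")
            if any(p <= 0 or p > 1 for p in self.freqs[loc].values()):
                raise ValueError(f"frequency out of (0, 1] at {loc!r}")

    def alleles(self, locus: str) -> list[int]:
        return sorted(self.freqs[locus])

    def as_arrays(self, locus: str) -> tuple[np.ndarray, np.ndarray]:
        a = np.array(self.alleles(locus))
        p = np.array([self.freqs[locus][x] for x in a])
        return a, p


def allele_frequencies(
    data: GenotypeDataset, subset: str | None = None
) -> AlleleFrequencyTable:
    """Tally per-locus allele frequencies, optionally within one stage.

    Missing calls contribute nothing; a locus with no calls in the subset is
    dropped with a warning.
    """
    if subset is not None:
        data = data.subset(subset)
    freqs: dict[str, dict[int, float]] = {}
    gene_counts: dict[str, int] = {}
    kept, dropped = [], []
    for j, loc in enumerate(data.loci):
        calls = data.genotypes[:, j, :]
        alleles = calls[calls != MISSING]
        if alleles.size == 0:
            dropped.append(loc)
            warnings.warn(f"locus {loc!r} entirely missing in subset; dropped")
            continue
        vals, counts = np.unique(alleles, return_counts=True)
        total = int(alleles.size)
        freqs[loc] = {int(v): c / total for v, c in zip(vals, counts)}
        gene_counts[loc] = total
        kept.append(loc)
    if not kept:
        raise ValueError("no locus has any genotype calls in the subset")
    return AlleleFrequencyTable(
        loci=kept, freqs=freqs, gene_counts=gene_counts, dropped_loci=dropped
    )


def pairwise_distances(data: GenotypeDataset) -> np.ndarray:
    """Euclidean distance matrix d_xy in meters (symmetric, zero diagonal)."""
    return squareform(pdist(data.coords))


def lonlat_to_planar(
    lon: np.ndarray, lat: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Project GPS lon/lat (degrees) to local planar meters.

    Equirectangular projection about the plot centroid; adequate for plots of
    a few tens of hectares where the projection error is far below GPS noise.
    """
    lon = np.asarray(lon, dtype=float)
    lat = np.asarray(lat, dtype=float)
    R = 6_371_000.0
    lat0 = np.mean(lat)
    lon0 = np.mean(lon)
    x = np.radians(lon - lon0) * R * math.cos(math.radians(lat0))
    y = np.radians(lat - lat0) * R
    return x, y


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------


def read_genotypes(
    path, dialect: str = "csv", coords_path=None
) -> GenotypeDataset:
    """Read a genotype file in the ``csv`` or ``genepop`` dialect.

    GenePop files carry no coordinates or stage labels, so ``coords_path``
    (a CSV ``id,stage,x,y``) is required for that dialect.
    """
    if dialect == "csv":
        return _read_csv(path)
    if dialect == "genepop":
        if coords_path is None:
            raise ValueError("genepop dialect requires coords_path")
        return _read_genepop(path, coords_path)
    raise ValueError(f"unsupported dialect {dialect!r}")


def _read_csv(path) -> GenotypeDataset:
    df = pd.read_csv(path, dtype={"id": str, "stage": str})
    required = ["id", "stage", "x", "y"]
    for col in required:
        if col not in df.columns:
            raise ValueError(f"missing required column {col!r}")
    allele_cols = [c for c in df.columns if c not in required]
    loci: list[str] = []
    for c in allele_cols:
        base, _, suf = c.rpartition(".")
        if suf not in ("1", "2") or not base:
            raise ValueError(f"allele column {c!r} does not match '<locus>.1/2'")
        if base not in loci:
            loci.append(base)
    for loc in loci:
        if f"{loc}.1" not in df.columns or f"{loc}.2" not in df.columns:
            raise ValueError(f"locus {loc!r} has an odd number of allele columns")
    ids = df["id"].tolist()
    if len(set(ids)) != len(ids):
        dupes = df["id"][df["id"].duplicated()].tolist()
        raise ValueError(f"duplicate id(s): {dupes}")
    geno = np.zeros((len(df), len(loci), 2), dtype=np.int64)
    for j, loc in enumerate(loci):
        for k in (1, 2):
            col = df[f"{loc}.{k}"]
            bad = col.isna() | ~col.astype(str).str.fullmatch(r"\d+")
            if bad.any():
                row = int(np.flatnonzero(bad.to_numpy())[0])
                raise ValueError(
                    f"malformed allele value at line {row + 2} "
                    f"(id {ids[row]!r}, column {loc}.{k})"
                )
            geno[:, j, k - 1] = col.astype(int)
    return GenotypeDataset(
        ids=ids,
        stages=df["stage"].tolist(),
        coords=df[["x", "y"]].to_numpy(float),
        loci=loci,
        genotypes=geno,
    )


def _read_genepop(path, coords_path) -> GenotypeDataset:
    with open(path) as fh:
        lines = [ln.rstrip("\n") for ln in fh]
    if len(lines) < 3:
        raise ValueError("genepop file too short")
    body = lines[1:]  # first line is a free title
    # locus names: either one comma-separated line or one per line up to POP
    loci: list[str] = []
    i = 0
    while i < len(body) and body[i].strip().upper() != "POP":
        loci.extend(t.strip() for t in body[i].split(",") if t.strip())
        i += 1
    if i == len(body):
        raise ValueError("no POP line found")
    ids: list[str] = []
    calls: list[list[tuple[int, int]]] = []
    for lineno, ln in enumerate(body[i:], start=i + 2):
        if ln.strip().upper() == "POP" or not ln.strip():
            continue
        if "," not in ln:
            raise ValueError(f"malformed genepop row at line {lineno}: no comma")
        ident, _, rest = ln.partition(",")
        ident = ident.strip()
        toks = rest.split()
        if len(toks) != len(loci):
            raise ValueError(
                f"line {lineno}: expected {len(loci)} genotypes, got {len(toks)}"
            )
        row = []
        for tok in toks:
            if len(tok) not in (4, 6) or not tok.isdigit():
                raise ValueError(f"line {lineno}: bad genotype token {tok!r}")
            w = len(tok) // 2
            a, b = int(tok[:w]), int(tok[w:])
            if (a == 0) != (b == 0):
                raise ValueError(f"line {lineno}: half-missing call {tok!r}")
            row.append((a, b))
        if ident in ids:
            raise ValueError(f"duplicate id {ident!r} at line {lineno}")
        ids.append(ident)
        calls.append(row)
    meta = pd.read_csv(coords_path, dtype={"id": str, "stage": str}).set_index("id")
    missing_meta = [i for i in ids if i not in meta.index]
    if missing_meta:
        raise ValueError(f"ids without coordinates: {missing_meta}")
    return GenotypeDataset(
        ids=ids,
        stages=[meta.loc[i, "stage"] for i in ids],
        coords=meta.loc[ids, ["x", "y"]].to_numpy(float),
        loci=loci,
        genotypes=np.array(calls, dtype=np.int64),
    )


def write_genotypes(
    data: GenotypeDataset, path, dialect: str = "csv", coords_path=None
) -> None:
    """Write a dataset in the ``csv`` or ``genepop`` dialect (round-trip safe)."""
    if dialect == "csv":
        data.to_dataframe().to_csv(path, index=False)
        return
    if dialect == "genepop":
        width = 6 if int(data.genotypes.max(initial=0)) > 99 else 4
        w = width // 2
        with open(path, "w") as fh:
            fh.write("palmflow genepop export\n")
            for loc in data.loci:
                fh.write(loc + "\n")
            fh.write("POP\n")
            for i, ident in enumerate(data.ids):
                toks = [
                    f"{a:0{w}d}{b:0{w}d}" for a, b in data.genotypes[i]
                ]
                fh.write(f"{ident}, " + " ".join(toks) + "\n")
        if coords_path is not None:
            pd.DataFrame(
                {
                    "id": data.ids,
                    "stage": data.stages,
                    "x": data.coords[:, 0],
                    "y": data.coords[:, 1],
                }
            ).to_csv(coords_path, index=False)
        return
    raise ValueError(f"unsupported dialect {dialect!r}")
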