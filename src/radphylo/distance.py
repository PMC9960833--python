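"""Genotype p-distance between accessions.

The per-site dissimilarity between two diploid genotypes at a biallelic SNP is

* 0   if both are the same homozygote,
* 1   if they are opposite homozygotes,
* 0.5 if exactly one is heterozygous,
* ``het_het`` (default 0.5) if both are heterozygous,

and the pairwise distance D_ij is the mean of the per-site values over the
sites where both accessions have a genotype call (pairwise-complete
averaging; the effective number of shared sites is reported per pair).

With ``het_het=0`` the per-site value reduces to |g_i - g_j| / 2, the
standard allele-sharing distance on dosages.  The default 0.5 scores a
heterozygote/heterozygote site as half-different, which treats any site
involving a heterozygote uniformly.
"""

from __future__ import annotations

import os
from dataclasses import dataclass

import numpy as np

from .genotypes import MISSING, GenotypeMatrix, ValidationError


@dataclass
class DistanceMatrix:
    """Symmetric pairwise distance matrix with per-pair shared-site counts."""

    sample_ids: list[str]
    values: np.ndarray
    n_sites_used: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.n_sites_used = np.asarray(self.n_sites_used, dtype=np.int64)
        n = len(self.sample_ids)
        if self.values.shape != (n, n) or self.n_sites_used.shape != (n, n):
            raise ValidationError("distance matrix shape does not match sample_ids")
        if not np.allclose(self.values, self.values.T):
            raise ValidationError("distance matrix must be symmetric")
        if np.any(np.diag(self.values) != 0):
            raise ValidationError("distance matrix diagonal must be zero")
        if self.values.min() < 0 or self.values.max() > 1:
            raise ValidationError("p-distances must lie in [0, 1]")

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def pair(self, a: str, b: str) -> float:
        i, j = self.sample_ids.index(a), self.sample_ids.index(b)
        return float(self.values[i, j])


def site_distance(g1: int, g2: int, het_het: float = 0.5):
    """Per-site genotype dissimilarity; returns None if either call is missing."""
    for g in (g1, g2):
        if g not in (0, 1, 2, MISSING):
            raise ValidationError(f"genotype {g!r} outside {{0,1,2,{MISSING}}}")
    if g1 == MISSING or g2 == MISSING:
        return None
    if g1 == 1 and g2 == 1:
        return het_het
    if g1 == 1 or g2 == 1:
        return 0.5
    return 0.0 if g1 == g2 else 1.0


def p_distance_matrix(
    genotypes: GenotypeMatrix,
    het_het: float = 0.5,
    min_shared_sites: int = 1,
) -> DistanceMatrix:
    """All-pairs p-distance with pairwise-complete site averaging.

    Raises if any pair shares fewer than ``min_shared_sites`` called sites,
    listing the offending pairs.
    """
    if genotypes.n_samples < 2:
        raise ValidationError("need at least 2 samples for a distance matrix")
    g = genotypes.dosages.astype(np.float64)
    called = genotypes.dosages != MISSING
    g[~called] = 0.0
    het = (genotypes.dosages == 1).astype(np.float64)

    calledf = called.astype(np.float64)
    n_shared = calledf @ calledf.T

    # sum over shared sites of |g_i - g_j|/2, computed without an explicit
    # site loop: |a-b| = a + b - 2*min(a,b), and for dosages in {0,1,2}
    # min(a,b) = a*b - het_a*het_b*(ab==1 case correction) ... simpler and
    # still fast at these scales: pairwise broadcast in blocks.
    n = genotypes.n_samples
    dist_sum = np.empty((n, n))
    hh_count = np.empty((n, n))
    for i in range(n):
        both = called[i] & called
        diff = np.abs(g[i] - g) / 2.0
        dist_sum[i] = np.where(both, diff, 0.0).sum(axis=1)
        hh_count[i] = (both & (het[i] == 1) & (het == 1)).sum(axis=1)

    # het/het sites contribute 0 under |.|/2; add het_het for each
    dist_sum += het_het * hh_count

    too_few = np.argwhere(np.triu(n_shared < min_shared_sites, k=1))
    if too_few.size:
        pairs = [
            f"({genotypes.sample_ids[i]}, {genotypes.sample_ids[j]})" for i, j in too_few
        ]
        raise ValidationError(
            f"pair(s) with fewer than {min_shared_sites} shared called sites: "
            + ", ".join(pairs)
        )

    with np.errstate(invalid="ignore", divide="ignore"):
        values = np.where(n_shared > 0, dist_sum / np.maximum(n_shared, 1), 0.0)
    np.fill_diagonal(values, 0.0)
    values = (values + values.T) / 2.0  # exact symmetry against float noise
    return DistanceMatrix(list(genotypes.sample_ids), values, n_shared.astype(np.int64))


def write_phylip(dist: DistanceMatrix, path: str | os.PathLike) -> None:
    """Square PHYLIP-style matrix: sample count line, then label + row."""
    with open(path, "w", newline="\n") as fh:
        fh.write(f"{dist.n_samples}\n")
        for sid, row in zip(dist.sample_ids, dist.values):
            fh.write(sid + "\t" + "\t".join(f"{v:.10g}" for v in row) + "\n")


def read_phylip(path: str | os.PathLike) -> DistanceMatrix:
    with open(path) as fh:
        n = int(fh.readline())
        ids, rows = [], []
        for _ in range(n):
            parts = fh.readline().split()
            ids.append(parts[0])
            rows.append([float(x) for x in parts[1:]])
    values = np.array(rows)
    # shared-site counts are not stored in PHYLIP; mark unknown as 1
    return DistanceMatrix(ids, values, np.ones_like(values, dtype=np.int64))


def write_lower_triangle(dist: DistanceMatrix, path: str | os.PathLike) -> None:
    with open(path, "w", newline="\n") as fh:
        for i, sid in enumerate(dist.sample_ids):
            cells = "\t".join(f"{v:.10g}" for v in dist.values[i, :i])
            fh.write(sid + ("\t" + cells if cells else "") + "\n")
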