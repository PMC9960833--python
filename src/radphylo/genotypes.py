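"""Core in-memory containers for diploid SNP genotypes and discrete characters.

Genotypes are stored as allele dosages: the count of the alternate allele at a
biallelic site, so 0 and 2 are the two homozygotes and 1 is the heterozygote.
Missing calls are stored as the reserved sentinel :data:`MISSING` (-1); every
downstream computation consults the mask rather than treating the sentinel as
a dosage.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

#: Reserved integer marking a missing genotype call.
MISSING: int = -1

PLOIDY: int = 2


class ValidationError(ValueError):
    """Raised when a container or operation input violates its contract."""


def _check_unique(ids, what: str) -> None:
    if len(set(ids)) != len(ids):
        raise ValidationError(f"{what} must be unique")


@dataclass
class GenotypeMatrix:
    """Samples x loci diploid dosage matrix.

    Parameters
    ----------
    sample_ids : list of str
        Unique accession identifiers, one per row.
    locus_ids : list of str
        Unique locus identifiers, one per column.  Loci are opaque labels;
        no genomic coordinates are modelled (RAD loci are reference-free).
    dosages : ndarray of int, shape (n_samples, n_loci)
        Entries in {0, 1, 2} or :data:`MISSING`.
    """

    sample_ids: list[str]
    locus_ids: list[str]
    dosages: np.ndarray

    def __post_init__(self) -> None:
        self.sample_ids = list(self.sample_ids)
        self.locus_ids = list(self.locus_ids)
        self.dosages = np.asarray(self.dosages, dtype=np.int16)
        if self.dosages.ndim != 2:
            raise ValidationError("dosages must be 2-D (samples x loci)")
        if self.dosages.shape != (len(self.sample_ids), len(self.locus_ids)):
            raise ValidationError(
                f"dosage shape {self.dosages.shape} does not match "
                f"{len(self.sample_ids)} samples x {len(self.locus_ids)} loci"
            )
        _check_unique(self.sample_ids, "sample_ids")
        _check_unique(self.locus_ids, "locus_ids")
        valid = np.isin(self.dosages, (0, 1, 2, MISSING))
        if not valid.all():
            bad = np.unique(self.dosages[~valid])
            raise ValidationError(f"invalid dosage values {bad.tolist()}; expected 0/1/2 or {MISSING}")

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_loci(self) -> int:
        return len(self.locus_ids)

    @property
    def missing_mask(self) -> np.ndarray:
        """Boolean samples x loci mask, True where the call is missing."""
        return self.dosages == MISSING

    def subset_loci(self, index: np.ndarray) -> "GenotypeMatrix":
        """Return a new matrix restricted (or resampled) to the given locus indices."""
        index = np.asarray(index)
        ids = [self.locus_ids[i] for i in index]
        # resampling with replacement duplicates ids; disambiguate
        if len(set(ids)) != len(ids):
            ids = [f"{lid}#{j}" for j, lid in enumerate(ids)]
        return GenotypeMatrix(list(self.sample_ids), ids, self.dosages[:, index])

    def reorder_samples(self, order: list[int]) -> "GenotypeMatrix":
        return GenotypeMatrix(
            [self.sample_ids[i] for i in order], list(self.locus_ids), self.dosages[order, :]
        )

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, GenotypeMatrix):
            return NotImplemented
        return (
            self.sample_ids == other.sample_ids
            and self.locus_ids == other.locus_ids
            and np.array_equal(self.dosages, other.dosages)
        )


@dataclass
class CharacterMatrix:
    """Samples x characters integer-coded morphological states.

    ``n_states`` declares k for each character; codes must lie in [0, k).
    ``state_labels`` maps character name -> state code -> human label
    (e.g. inflorescence: 0 raceme, 1 umbel, 2 short raceme).
    """

    sample_ids: list[str]
    character_names: list[str]
    states: np.ndarray
    n_states: dict[str, int]
    state_labels: dict[str, dict[int, str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.sample_ids = list(self.sample_ids)
        self.character_names = list(self.character_names)
        self.states = np.asarray(self.states, dtype=np.int16)
        if self.states.shape != (len(self.sample_ids), len(self.character_names)):
            raise ValidationError("state matrix shape does not match id lists")
        _check_unique(self.sample_ids, "sample_ids")
        _check_unique(self.character_names, "character_names")
        for j, name in enumerate(self.character_names):
            k = self.n_states.get(name)
            if k is None or k < 2:
                raise ValidationError(f"character {name!r} must declare k >= 2 states")
            col = self.states[:, j]
            bad = np.flatnonzero((col < 0) | (col >= k))
            if bad.size:
                raise ValidationError(
                    f"character {name!r}: sample {self.sample_ids[bad[0]]!r} has state "
                    f"{int(col[bad[0]])} outside [0, {k})"
                )

    def column(self, name: str) -> dict[str, int]:
        """Tip-state mapping {sample_id: state} for one character."""
        j = self.character_names.index(name)
        return {sid: int(s) for sid, s in zip(self.sample_ids, self.states[:, j])}

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, CharacterMatrix):
            return NotImplemented
        return (
            self.sample_ids == other.sample_ids
            and self.character_names == other.character_names
            and np.array_equal(self.states, other.states)
            and self.n_states == other.n_states
        )
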