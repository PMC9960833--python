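"""Readers and writers for genotype matrices, character tables, and metadata.

Supported formats, all plain text (UTF-8, tab-delimited, LF endings):

* minimal VCF v4.2 carrying only the GT subfield (read via cyvcf2);
* a genotype dosage table (rows = samples, columns = loci, cells 0/1/2/NA);
* a character table (rows = samples, one integer-coded column per character);
* a sample metadata table.

Only biallelic SNP records are accepted from VCF; multi-allelic records are
skipped (counted, and reported through the ``skipped`` attribute and a
warning) because the p-distance and the admixture likelihood are defined on
biallelic dosages only.
"""

from __future__ import annotations

import logging
import os
from pathlib import Path

import numpy as np
import pandas as pd
from cyvcf2 import VCF

from .genotypes import MISSING, CharacterMatrix, GenotypeMatrix, ValidationError

logger = logging.getLogger(__name__)


class ParseError(ValueError):
    """Raised when an input file violates the expected dialect."""


# ---------------------------------------------------------------------------
# VCF
# ---------------------------------------------------------------------------

def read_vcf(path: str | os.PathLike) -> GenotypeMatrix:
    """Read a VCF with GT calls into a samples x loci dosage matrix.

    ``0/0 -> 0``, ``0/1``/``1/0`` -> 1, ``1/1`` -> 2, ``./.`` -> missing;
    phased separators are treated identically.  Record order becomes locus
    order.  Multi-allelic records are skipped and counted on the returned
    matrix's ``skipped_multiallelic`` attribute.
    """
    path = os.fspath(path)
    vcf = VCF(path)
    samples = list(vcf.samples)
    if not samples:
        raise ParseError(f"{path}: VCF declares no samples")
    locus_ids: list[str] = []
    rows: list[np.ndarray] = []
    skipped = 0
    for rec in vcf:
        if len(rec.ALT) != 1:
            skipped += 1
            continue
        if "GT" not in (rec.FORMAT or []):
            raise ParseError(f"{path}: record {rec.CHROM}:{rec.POS} has no GT field")
        name = rec.ID if rec.ID not in (None, ".") else f"{rec.CHROM}:{rec.POS}"
        locus_ids.append(name)
        # gt_types codes: 0 hom-ref, 1 het, 2 missing, 3 hom-alt
        gt = rec.gt_types.astype(np.int16)
        dos = np.where(gt == 0, 0, np.where(gt == 1, 1, np.where(gt == 3, 2, MISSING)))
        rows.append(dos)
    vcf.close()
    if skipped:
        logger.warning("%s: skipped %d multi-allelic record(s)", path, skipped)
    dosages = (
        np.array(rows, dtype=np.int16).T
        if rows
        else np.empty((len(samples), 0), dtype=np.int16)
    )
    gm = GenotypeMatrix(samples, locus_ids, dosages)
    gm.skipped_multiallelic = skipped
    return gm


_GT_STRINGS = {0: "0/0", 1: "0/1", 2: "1/1", MISSING: "./."}

_VCF_HEADER = (
    "##fileformat=VCFv4.2\n"
    '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n'
    "##contig=<ID=syn>\n"
)


def write_vcf(genotypes: GenotypeMatrix, path: str | os.PathLike) -> None:
    """Emit a minimal VCF v4.2 (CHROM=syn, POS=1-based locus index, REF=A, ALT=C)."""
    with open(path, "w", newline="\n") as fh:
        fh.write(_VCF_HEADER)
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(genotypes.sample_ids)
            + "\n"
        )
        for j, lid in enumerate(genotypes.locus_ids):
            calls = "\t".join(_GT_STRINGS[int(g)] for g in genotypes.dosages[:, j])
            fh.write(f"syn\t{j + 1}\t{lid}\tA\tC\t.\t.\t.\tGT\t{calls}\n")


# ---------------------------------------------------------------------------
# Dosage table
# ---------------------------------------------------------------------------

def read_genotype_table(path: str | os.PathLike) -> GenotypeMatrix:
    """Read a TSV with a header row of locus ids and first column of sample ids."""
    path = os.fspath(path)
    with open(path) as fh:
        header = fh.readline().rstrip("\n")
        if not header:
            raise ParseError(f"{path}: empty file")
        cols = header.split("\t")
        locus_ids = cols[1:]
        n_cols = len(cols)
        sample_ids: list[str] = []
        rows: list[list[int]] = []
        for lineno, line in enumerate(fh, start=2):
            parts = line.rstrip("\n").split("\t")
            if len(parts) != n_cols:
                raise ParseError(
                    f"{path}: row {lineno} has {len(parts)} fields, expected {n_cols}"
                )
            sample_ids.append(parts[0])
            row = []
            for cell in parts[1:]:
                if cell == "NA":
                    row.append(MISSING)
                else:
                    try:
                        row.append(int(cell))
                    except ValueError:
                        raise ParseError(
                            f"{path}: row {lineno}: non-integer cell {cell!r}"
                        ) from None
            rows.append(row)
    dosages = (
        np.array(rows, dtype=np.int16)
        if rows
        else np.empty((0, len(locus_ids)), dtype=np.int16)
    )
    return GenotypeMatrix(sample_ids, locus_ids, dosages)


def write_genotype_table(genotypes: GenotypeMatrix, path: str | os.PathLike) -> None:
    with open(path, "w", newline="\n") as fh:
        fh.write("sample\t" + "\t".join(genotypes.locus_ids) + "\n")
        for sid, row in zip(genotypes.sample_ids, genotypes.dosages):
            cells = ("NA" if g == MISSING else str(int(g)) for g in row)
            fh.write(sid + "\t" + "\t".join(cells) + "\n")


# ---------------------------------------------------------------------------
# Character table
# ---------------------------------------------------------------------------

def read_character_table(
    path: str | os.PathLike,
    n_states: dict[str, int],
    state_labels: dict[str, dict[int, str]] | None = None,
) -> CharacterMatrix:
    """Read a TSV of integer-coded character states.

    ``n_states`` declares k per character; a state code >= k raises a
    validation error naming the sample and character.
    """
    path = os.fspath(path)
    df = pd.read_csv(path, sep="\t", dtype=str)
    if df.shape[0] == 0:
        raise ParseError(f"{path}: no samples")
    sample_ids = df.iloc[:, 0].tolist()
    names = list(df.columns[1:])
    missing_decl = [n for n in names if n not in n_states]
    if missing_decl:
        raise ValidationError(f"no declared state count for character(s) {missing_decl}")
    try:
        states = df.iloc[:, 1:].astype(int).to_numpy()
    except ValueError as exc:
        raise ParseError(f"{path}: non-integer character state ({exc})") from None
    return CharacterMatrix(sample_ids, names, states, dict(n_states), state_labels or {})


def write_character_table(characters: CharacterMatrix, path: str | os.PathLike) -> None:
    df = pd.DataFrame(
        characters.states, index=characters.sample_ids, columns=characters.character_names
    )
    df.to_csv(path, sep="\t", index_label="sample", lineterminator="\n")


# ---------------------------------------------------------------------------
# Metadata
# ---------------------------------------------------------------------------

def read_metadata(path: str | os.PathLike) -> pd.DataFrame:
    """Read a sample metadata TSV (first column = sample code)."""
    return pd.read_csv(path, sep="\t", dtype=str)


def write_metadata(df: pd.DataFrame, path: str | os.PathLike) -> None:
    df.to_csv(path, sep="\t", index=False, lineterminator="\n")


def package_data_path(name: str) -> Path:
    """Path of a data table shipped with the package."""
    return Path(__file__).parent / "data" / name
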