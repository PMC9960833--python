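"""Pipeline orchestration: stage sequencing, per-sample summaries, and the
packaged printed-table statistics.

A run goes: ingest (or simulate) genotypes -> per-sample summary -> p-distance
matrix -> neighbor-joining tree with locus-bootstrap supports -> midpoint
rooting -> PCA with Tracy-Widom tests -> admixture K sweep with CV -> Mk1
ancestral-state reconstruction of the character table on the rooted tree.
Every stage writes a plain-text artifact into the output directory, so stages
are independently inspectable, and the whole run is a pure function of the
config: identical config (including seed) reproduces byte-identical outputs.

One global seed expands into per-stage seeds by drawing eight 31-bit
integers from ``default_rng(seed)`` in a fixed order (simulate, bootstrap,
admixture, cv, and spares); the expansion is recorded in the report.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import admixture as admix
from . import asr as asr_mod
from . import distance as dist_mod
from . import io as io_mod
from . import pca as pca_mod
from . import phylo as phylo_mod
from . import synthetic
from .genotypes import MISSING, GenotypeMatrix, ValidationError

logger = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    """A stage failure, wrapped with the stage name."""


# ---------------------------------------------------------------------------
# Per-sample summaries and the packaged printed table
# ---------------------------------------------------------------------------

def summarize_genotypes(genotypes: GenotypeMatrix) -> pd.DataFrame:
    """Per-sample site counts with a totals row.

    Columns: n_sites (called), n_missing, n_heterozygous, n_homozygous_nonref.
    """
    d = genotypes.dosages
    df = pd.DataFrame(
        {
            "n_sites": (d != MISSING).sum(axis=1),
            "n_missing": (d == MISSING).sum(axis=1),
            "n_heterozygous": (d == 1).sum(axis=1),
            "n_homozygous_nonref": (d == 2).sum(axis=1),
        },
        index=pd.Index(genotypes.sample_ids, name="sample"),
    )
    totals = df.sum()
    totals.name = "Total"
    out = pd.concat([df, totals.to_frame().T])
    out.index.name = "sample"
    return out


def load_printed_table1() -> pd.DataFrame:
    """The packaged verbatim copy of the study's sequencing/SNP summary table.

    Returns the 52 per-sample rows with numeric columns parsed (printed
    thousands separators stripped); the printed Average/Total rows are
    dropped — statistics are recomputed from the per-sample rows.
    """
    raw = pd.read_csv(io_mod.package_data_path("table1.tsv"), sep="\t", dtype=str)
    samples = raw[~raw["Code"].isin(["Average", "Total"])].copy()
    for col in ["Clean Reads Number (M)", "Q_20_ (%)", "Homo SNPs", "Hete SNPs",
                "Total SNPs"]:
        samples[col] = samples[col].str.replace(",", "", regex=False).astype(float)
    return samples.reset_index(drop=True)


def printed_table1_statistics() -> dict[str, float]:
    """Desk statistics recomputed from the packaged per-sample rows."""
    t = load_printed_table1()
    homo = t["Homo SNPs"].sum()
    hete = t["Hete SNPs"].sum()
    reads = t["Clean Reads Number (M)"]
    snps = t["Total SNPs"]
    return {
        "grand_total_snps": float(homo + hete),
        "homo_total_snps": float(homo),
        "hete_total_snps": float(hete),
        "mean_clean_reads_m": float(reads.sum() / len(t)),
        "max_total_snps": float(snps.max()),
        "min_total_snps": float(snps.min()),
        "max_clean_reads_m": float(reads.max()),
        "min_clean_reads_m": float(reads.min()),
        "n_samples": float(len(t)),
    }


# ---------------------------------------------------------------------------
# Config and report
# ---------------------------------------------------------------------------

@dataclass
class PipelineConfig:
    """Settings for a full run; defaults follow the study's stated settings
    (1000 bootstrap replicates, K swept from 2 to 7)."""

    output_dir: str = "radphylo_out"
    # either a genotype table path ...
    genotype_table: str | None = None
    vcf: str | None = None
    character_table: str | None = None
    # ... or a simulation spec (the canonical fixture)
    simulate_fixture: bool = False
    n_loci: int = 5000
    # analysis settings
    het_het: float = 0.5
    n_bootstrap: int = 1000
    k_min: int = 2
    k_max: int = 7
    cv_folds: int = 5
    n_components: int = 10
    admixture_starts: int = 3
    admixture_max_iter: int = 1000
    seed: int = 0

    def validate(self) -> None:
        if self.k_min > self.k_max:
            raise ValidationError(f"K range ({self.k_min}, {self.k_max}) is inverted")
        if self.n_bootstrap < 1:
            raise ValidationError("n_bootstrap must be >= 1")
        if not (self.simulate_fixture or self.genotype_table or self.vcf):
            raise ValidationError("no input: set simulate_fixture or an input path")

    def hash(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


@dataclass
class SummaryReport:
    """Artifacts and provenance of a completed run."""

    config: PipelineConfig
    stage_seeds: dict[str, int]
    files: dict[str, str] = field(default_factory=dict)
    optimal_k: int | None = None
    log: list[str] = field(default_factory=list)

    def write(self, path) -> None:
        payload = {
            "config": asdict(self.config),
            "config_hash": self.config.hash(),
            "stage_seeds": self.stage_seeds,
            "files": self.files,
            "optimal_k": self.optimal_k,
            "log": self.log,
        }
        with open(path, "w", newline="\n") as fh:
            json.dump(payload, fh, indent=2, sort_keys=True)
            fh.write("\n")


def stage_seeds(seed: int) -> dict[str, int]:
    """Deterministic expansion of the global seed into per-stage seeds."""
    draws = np.random.default_rng(seed).integers(0, 2**31 - 1, size=8)
    names = ["simulate", "bootstrap", "admixture", "cv", "spare1", "spare2",
             "spare3", "spare4"]
    return {name: int(v) for name, v in zip(names, draws)}


# ---------------------------------------------------------------------------
# Full run
# ---------------------------------------------------------------------------

def _stage(name: str):
    def deco(fn):
        def wrapped(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except PipelineError:
                raise
            except Exception as exc:
                raise PipelineError(f"stage {name!r} failed: {exc}") from exc
        return wrapped
    return deco


def run_full_pipeline(config: PipelineConfig) -> SummaryReport:
    """Execute all stages in order; any stage failure aborts with the stage
    name, keeping partial outputs."""
    config.validate()
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    seeds = stage_seeds(config.seed)
    report = SummaryReport(config, seeds)

    def record(key: str, path: Path) -> None:
        report.files[key] = str(path)
        report.log.append(f"wrote {path}")

    @_stage("ingest")
    def ingest():
        if config.simulate_fixture:
            bundle = synthetic.make_ribes_fixture(
                seed=seeds["simulate"], n_loci=config.n_loci
            )
            synthetic.write_fixture(bundle, outdir / "fixture")
            record("genotypes", outdir / "fixture" / "genotypes.tsv")
            record("characters", outdir / "fixture" / "characters.tsv")
            return bundle.genotypes, bundle.characters
        if config.genotype_table:
            geno = io_mod.read_genotype_table(config.genotype_table)
        else:
            geno = io_mod.read_vcf(config.vcf)
        chars = None
        if config.character_table:
            raise ValidationError(
                "character_table requires declared state counts; use the library API"
            )
        return geno, chars

    genotypes, characters = ingest()
    report.log.append(
        f"genotypes: {genotypes.n_samples} samples x {genotypes.n_loci} loci"
    )

    @_stage("summarize")
    def do_summary():
        summary = summarize_genotypes(genotypes)
        path = outdir / "sample_summary.tsv"
        summary.to_csv(path, sep="\t", lineterminator="\n")
        record("sample_summary", path)

    do_summary()

    @_stage("distance")
    def do_distance():
        dm = dist_mod.p_distance_matrix(genotypes, het_het=config.het_het)
        dist_mod.write_phylip(dm, outdir / "distances.phylip")
        record("distances", outdir / "distances.phylip")
        return dm

    dm = do_distance()

    @_stage("nj+bootstrap")
    def do_tree():
        tree = phylo_mod.bootstrap_support(
            genotypes,
            n_replicates=config.n_bootstrap,
            seed=seeds["bootstrap"],
            het_het=config.het_het,
        )
        phylo_mod.write_newick(tree, outdir / "nj_bootstrap.nwk")
        record("nj_tree", outdir / "nj_bootstrap.nwk")
        rooted = phylo_mod.midpoint_root(tree)
        phylo_mod.write_newick(rooted, outdir / "nj_rooted.nwk")
        record("nj_rooted", outdir / "nj_rooted.nwk")
        return rooted

    rooted = do_tree()

    @_stage("pca")
    def do_pca():
        n_comp = min(config.n_components, genotypes.n_samples - 1, genotypes.n_loci)
        res = pca_mod.run_pca(genotypes, n_components=n_comp)
        pca_mod.write_coordinates(res, outdir / "pca_coordinates.tsv")
        pca_mod.write_tw_report(res, outdir / "pca_tracy_widom.tsv")
        record("pca_coordinates", outdir / "pca_coordinates.tsv")
        record("pca_tw", outdir / "pca_tracy_widom.tsv")

    do_pca()

    @_stage("admixture")
    def do_admixture():
        sweep = admix.sweep_k(
            genotypes,
            k_min=config.k_min,
            k_max=config.k_max,
            seed=seeds["admixture"],
            n_folds=config.cv_folds,
            n_starts=config.admixture_starts,
            max_iter=config.admixture_max_iter,
        )
        sweep.frame().to_csv(outdir / "k_sweep.tsv", sep="\t", index=False,
                             lineterminator="\n")
        record("k_sweep", outdir / "k_sweep.tsv")
        for k, fit in sweep.fits.items():
            fit.write_q(outdir / f"admixture_K{k}.Q")
            record(f"Q_K{k}", outdir / f"admixture_K{k}.Q")
        return sweep

    sweep = do_admixture()
    report.optimal_k = sweep.optimal_k
    report.log.append(f"optimal K by CV: {sweep.optimal_k}")

    @_stage("asr")
    def do_asr():
        if characters is None:
            report.log.append("no character table; skipping reconstruction")
            return
        results = asr_mod.reconstruct_all(rooted, characters)
        for res in results:
            path = outdir / f"asr_{res.character}.tsv"
            res.write_tsv(path)
            record(f"asr_{res.character}", path)

    do_asr()

    report.write(outdir / "report.json")
    record("report", outdir / "report.json")
    return report
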