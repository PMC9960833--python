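"""Synthetic genotype, tree, and character generators.

The study design these generators emulate: 52 diploid accessions in six
genetically differentiated groups (two supergroups), tens of thousands of
biallelic RAD SNPs, occasional admixed individuals, and two integer-coded
morphological characters (gland absent/present; inflorescence raceme /
umbel / short raceme) concentrated in particular clades.

Group differentiation follows the Balding–Nichols model: given an ancestral
allele frequency p and a drift coefficient c in (0,1), a group's frequency is
Beta(p(1-c)/c, (1-p)(1-c)/c), giving E[freq] = p and Var = c*p*(1-p) — so c
plays the role of an F_ST-like divergence with one tunable parameter.
Admixed genotypes follow the admixture model itself: g ~ Binomial(2, Q F).

All generators are deterministic under a fixed seed, and genotypes carry no
missing data unless ``missing_rate`` is set.
"""

from __future__ import annotations

from dataclasses import dataclass

import dendropy
import numpy as np
import pandas as pd

from .asr import MkModel
from .genotypes import MISSING, CharacterMatrix, GenotypeMatrix, ValidationError
from .io import package_data_path

GLAND_LABELS = {0: "absent", 1: "present"}
INFLORESCENCE_LABELS = {0: "raceme", 1: "umbel", 2: "short raceme"}

#: Fixture group sizes, in code order (52 samples total).
FIXTURE_GROUPS = {"A": 3, "B": 15, "C": 5, "D": 5, "E": 1, "F": 23}


@dataclass
class GroupSpec:
    """One differentiated group: label, size, Balding–Nichols drift."""

    group_label: str
    n_samples: int
    drift: float

    def __post_init__(self) -> None:
        if self.n_samples < 1:
            raise ValidationError("n_samples must be >= 1")
        if not (0.0 < self.drift < 1.0):
            raise ValidationError("drift must lie strictly in (0, 1)")


def _apply_missing(dosages: np.ndarray, missing_rate: float, rng) -> np.ndarray:
    if missing_rate > 0:
        mask = rng.random(dosages.shape) < missing_rate
        dosages = np.where(mask, MISSING, dosages)
    return dosages


def generate_admixed_genotypes(
    n_samples: int,
    n_loci: int,
    K: int,
    q_matrix: np.ndarray | None = None,
    f_matrix: np.ndarray | None = None,
    seed: int = 0,
    missing_rate: float = 0.0,
) -> GenotypeMatrix:
    """Genotypes under the admixture model g ~ Binomial(2, Q F).

    If ``q_matrix`` is omitted, rows are drawn from a symmetric
    Dirichlet(0.2) — mostly-assigned individuals with occasional admixture.
    If ``f_matrix`` is omitted, entries are Uniform(0.05, 0.95).
    """
    if K < 1:
        raise ValidationError("K must be >= 1")
    rng = np.random.default_rng(seed)
    if q_matrix is None:
        q = rng.dirichlet(np.full(K, 0.2), size=n_samples)
    else:
        q = np.asarray(q_matrix, dtype=float)
        if q.shape != (n_samples, K):
            raise ValidationError(f"q_matrix shape {q.shape} != ({n_samples}, {K})")
        if np.any(np.abs(q.sum(axis=1) - 1.0) > 1e-8):
            raise ValidationError("q_matrix rows must sum to 1 within 1e-8")
        if q.min() < 0:
            raise ValidationError("q_matrix entries must be nonnegative")
    if f_matrix is None:
        f = rng.uniform(0.05, 0.95, size=(K, n_loci))
    else:
        f = np.asarray(f_matrix, dtype=float)
        if f.shape != (K, n_loci):
            raise ValidationError(f"f_matrix shape {f.shape} != ({K}, {n_loci})")
        if f.min() <= 0.0 or f.max() >= 1.0:
            raise ValidationError("f_matrix entries must lie strictly in (0, 1)")
    pi = q @ f
    dosages = rng.binomial(2, pi).astype(np.int16)
    dosages = _apply_missing(dosages, missing_rate, rng)
    return GenotypeMatrix(
        [f"s{i + 1}" for i in range(n_samples)],
        [f"L{j + 1}" for j in range(n_loci)],
        dosages,
    )


def balding_nichols_frequencies(
    ancestral: np.ndarray, drift: float, rng: np.random.Generator
) -> np.ndarray:
    """Group allele frequencies drawn around the ancestral ones."""
    c = drift
    a = ancestral * (1.0 - c) / c
    b = (1.0 - ancestral) * (1.0 - c) / c
    return np.clip(rng.beta(a, b), 1e-9, 1.0 - 1e-9)


def generate_hierarchical_groups(
    groups: list[GroupSpec],
    n_loci: int,
    seed: int = 0,
    missing_rate: float = 0.0,
) -> GenotypeMatrix:
    """Discrete differentiated groups under Balding–Nichols drift.

    Sample ids are ``<group_label><index>`` with 1-based indices.
    """
    if len(groups) < 2:
        raise ValidationError("need at least 2 groups")
    if n_loci < 1:
        raise ValidationError("n_loci must be >= 1")
    rng = np.random.default_rng(seed)
    ancestral = rng.uniform(0.1, 0.9, size=n_loci)
    sample_ids: list[str] = []
    blocks = []
    for spec in groups:
        freq = balding_nichols_frequencies(ancestral, spec.drift, rng)
        blocks.append(rng.binomial(2, freq, size=(spec.n_samples, n_loci)))
        sample_ids.extend(f"{spec.group_label}{i + 1}" for i in range(spec.n_samples))
    dosages = np.vstack(blocks).astype(np.int16)
    dosages = _apply_missing(dosages, missing_rate, rng)
    return GenotypeMatrix(
        sample_ids, [f"L{j + 1}" for j in range(n_loci)], dosages
    )


def simulate_mk_characters(
    tree: dendropy.Tree,
    n_chars: int,
    k: int,
    rate: float,
    seed: int = 0,
) -> CharacterMatrix:
    """Evolve discrete characters down a rooted tree under the Mk model.

    The root state is uniform on the k states; each branch applies the
    closed-form Mk transition probabilities.
    """
    if k < 2:
        raise ValidationError("k must be >= 2")
    if rate < 0:
        raise ValidationError("rate must be nonnegative")
    if not tree.is_rooted:
        raise ValidationError("tree must be rooted")
    rng = np.random.default_rng(seed)
    model = MkModel(k, rate) if rate > 0 else None
    leaves = [lf.taxon.label for lf in tree.leaf_node_iter()]
    states = {lf: np.empty(n_chars, dtype=np.int16) for lf in leaves}
    node_state: dict[int, np.ndarray] = {}
    root = tree.seed_node
    node_state[id(root)] = rng.integers(0, k, size=n_chars)
    for node in tree.preorder_node_iter():
        if node is root:
            pass
        else:
            t = node.edge.length or 0.0
            if t < 0:
                raise ValidationError("negative branch length")
            parent_states = node_state[id(node.parent_node)]
            if rate == 0 or t == 0:
                cur = parent_states.copy()
            else:
                P = model.transition_matrix(t)
                u = rng.random(n_chars)
                cum = np.cumsum(P, axis=1)
                cur = (u[:, None] > cum[parent_states]).sum(axis=1).astype(np.int16)
            node_state[id(node)] = cur
        if node.is_leaf():
            states[node.taxon.label] = node_state[id(node)]
    names = [f"char{j + 1}" for j in range(n_chars)]
    matrix = np.column_stack([states[lf] for lf in leaves]).T
    return CharacterMatrix(leaves, names, matrix, {n: k for n in names})


# ---------------------------------------------------------------------------
# Canonical six-clade fixture
# ---------------------------------------------------------------------------

def _balanced_subtree(labels: list[str], taxa, edge: float) -> dendropy.Node:
    """Balanced binary subtree over the ordered labels, all edges ``edge``."""
    if len(labels) == 1:
        return dendropy.Node(taxon=taxa.get_taxon(labels[0]))
    mid = (len(labels) + 1) // 2
    node = dendropy.Node()
    for part in (labels[:mid], labels[mid:]):
        child = _balanced_subtree(part, taxa, edge)
        node.add_child(child)
        child.edge.length = edge
    return node


def fixture_sample_codes() -> list[str]:
    return [
        f"{g}{i + 1}" for g, n in FIXTURE_GROUPS.items() for i in range(n)
    ]


def canonical_tree(
    within_branch: float = 0.02, stem_branch: float = 0.1
) -> dendropy.Tree:
    """Rooted fixture topology ((A,B),((C,D),(E1,F))) with balanced clades.

    Within-clade branch lengths default to 0.02 and stem branches to 0.1 —
    a stated fixture convention, not an estimate.
    """
    codes = {g: [f"{g}{i + 1}" for i in range(n)] for g, n in FIXTURE_GROUPS.items()}
    taxa = dendropy.TaxonNamespace(fixture_sample_codes())
    tree = dendropy.Tree(taxon_namespace=taxa)

    def clade(group: str) -> dendropy.Node:
        node = _balanced_subtree(codes[group], taxa, within_branch)
        node.edge.length = stem_branch
        return node

    def join(a: dendropy.Node, b: dendropy.Node) -> dendropy.Node:
        node = dendropy.Node()
        node.add_child(a)
        node.add_child(b)
        node.edge.length = stem_branch
        return node

    left = join(clade("A"), clade("B"))
    right = join(join(clade("C"), clade("D")), join(clade("E"), clade("F")))
    root = dendropy.Node()
    root.add_child(left)
    root.add_child(right)
    left.edge.length = stem_branch
    right.edge.length = stem_branch
    tree.seed_node = root
    tree.is_rooted = True
    return tree


def fixture_characters() -> CharacterMatrix:
    """The two coded morphological characters over the 52 fixture samples.

    Gland present only in the D clade (the gland-bearing subgenus);
    inflorescence umbel in the A clade, short raceme in the C clade,
    raceme elsewhere.
    """
    codes = fixture_sample_codes()
    gland = np.array([1 if c.startswith("D") else 0 for c in codes])
    inflor = np.array(
        [1 if c.startswith("A") else 2 if c.startswith("C") else 0 for c in codes]
    )
    return CharacterMatrix(
        codes,
        ["gland", "inflorescence"],
        np.column_stack([gland, inflor]),
        {"gland": 2, "inflorescence": 3},
        {"gland": dict(GLAND_LABELS), "inflorescence": dict(INFLORESCENCE_LABELS)},
    )


def fixture_metadata() -> pd.DataFrame:
    """Sample metadata: code, scientific name (as printed), group, note.

    The printed source table lists F2 as Ribes tenue although the F group
    otherwise comprises the raceme-bearing bisexual-flower subgenus; the
    printed name is kept and the discrepancy flagged in the note column.
    """
    t2 = pd.read_csv(package_data_path("table2.tsv"), sep="\t", dtype=str)
    df = pd.DataFrame(
        {
            "code": t2["Code"],
            "scientific_name": t2["Scientific Name"],
            "group": t2["Code"].str[0],
            "geographic_location": t2["Geographic Location"],
        }
    )
    df["note"] = ""
    df.loc[df["code"] == "F2", "note"] = (
        "printed name Ribes tenue conflicts with the group's other members; "
        "kept as printed"
    )
    return df


@dataclass
class FixtureBundle:
    """Canonical 52-sample six-clade fixture."""

    genotypes: GenotypeMatrix
    characters: CharacterMatrix
    metadata: pd.DataFrame
    canonical_tree: dendropy.Tree


def make_ribes_fixture(
    seed: int = 0,
    n_loci: int = 5000,
    group_drift: float = 0.2,
    supergroup_drift: float = 0.1,
    missing_rate: float = 0.0,
) -> FixtureBundle:
    """Build the canonical fixture: genotypes, characters, metadata, tree.

    Genotypes use two-level Balding–Nichols drift — ancestral frequencies
    Uniform(0.1, 0.9), a supergroup layer ({A,B} vs {C,D,E,F}) at
    ``supergroup_drift``, then per-group frequencies at ``group_drift`` —
    so the six groups are discrete and nested in two major branches.
    """
    rng = np.random.default_rng(seed)
    ancestral = rng.uniform(0.1, 0.9, size=n_loci)
    super_freq = {
        s: balding_nichols_frequencies(ancestral, supergroup_drift, rng)
        for s in ("AB", "CDEF")
    }
    sample_ids: list[str] = []
    blocks = []
    for g, n in FIXTURE_GROUPS.items():
        base = super_freq["AB"] if g in ("A", "B") else super_freq["CDEF"]
        freq = balding_nichols_frequencies(base, group_drift, rng)
        blocks.append(rng.binomial(2, freq, size=(n, n_loci)))
        sample_ids.extend(f"{g}{i + 1}" for i in range(n))
    dosages = np.vstack(blocks).astype(np.int16)
    dosages = _apply_missing(dosages, missing_rate, rng)
    genotypes = GenotypeMatrix(
        sample_ids, [f"L{j + 1}" for j in range(n_loci)], dosages
    )
    return FixtureBundle(
        genotypes, fixture_characters(), fixture_metadata(), canonical_tree()
    )


def write_fixture(bundle: FixtureBundle, outdir) -> None:
    """Serialize the bundle as genotype/character/metadata TSVs + Newick."""
    from pathlib import Path

    from . import io as _io
    from .phylo import write_newick

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    _io.write_genotype_table(bundle.genotypes, outdir / "genotypes.tsv")
    _io.write_character_table(bundle.characters, outdir / "characters.tsv")
    _io.write_metadata(bundle.metadata, outdir / "metadata.tsv")
    write_newick(bundle.canonical_tree, outdir / "canonical_tree.nwk")
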