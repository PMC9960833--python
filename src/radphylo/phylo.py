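"""Neighbor-joining trees, locus-bootstrap supports, rooting, and Newick I/O.

Trees are :class:`dendropy.Tree` objects throughout; leaf taxon labels are
sample ids.  Bootstrap supports live on internal edges as the head node's
label (the usual Newick internal-label convention), as percentages in
[0, 100].

The neighbor-joining agglomeration is implemented here rather than delegated
because the contract pins down behaviour libraries leave open: ties in the
Q-criterion are broken by the lowest (row, column) index pair, and negative
estimated branch lengths are clamped to zero with the clamp count recorded
on the returned tree (``tree.nj_clamped``).
"""

from __future__ import annotations

import logging

import dendropy
import numpy as np

from .distance import DistanceMatrix, p_distance_matrix
from .genotypes import GenotypeMatrix, ValidationError

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# Neighbor joining
# ---------------------------------------------------------------------------

def neighbor_joining(dist: DistanceMatrix) -> dendropy.Tree:
    """Saitou–Nei neighbor joining; returns an unrooted tree.

    The returned tree's seed node has degree 3 (fully unresolved root),
    matching the 2n-3 edge count of an unrooted binary tree.
    """
    n = dist.n_samples
    if n < 3:
        raise ValidationError("neighbor joining requires at least 3 samples")
    if not np.isfinite(dist.values).all():
        raise ValidationError("non-finite distances")

    taxa = dendropy.TaxonNamespace(dist.sample_ids)
    tree = dendropy.Tree(taxon_namespace=taxa)
    nodes: list[dendropy.Node] = []
    for sid in dist.sample_ids:
        node = dendropy.Node(taxon=taxa.get_taxon(sid))
        nodes.append(node)

    d = dist.values.astype(float).copy()
    active = list(range(n))
    clamped = 0

    def clamp(x: float) -> float:
        nonlocal clamped
        if x < 0:
            clamped += 1
            return 0.0
        return x

    while len(active) > 3:
        r = len(active)
        sub = d[np.ix_(active, active)]
        sums = sub.sum(axis=1)
        q = (r - 2) * sub - sums[:, None] - sums[None, :]
        np.fill_diagonal(q, np.inf)
        # lowest (row, col) pair among minima: argmin scans row-major, so the
        # first occurrence is exactly the lowest index pair
        flat = int(np.argmin(q))
        i, j = divmod(flat, r)
        if i > j:
            i, j = j, i
        dij = sub[i, j]
        li = dij / 2.0 + (sums[i] - sums[j]) / (2.0 * (r - 2))
        lj = dij - li
        ai, aj = active[i], active[j]
        parent = dendropy.Node()
        parent.add_child(nodes[ai])
        nodes[ai].edge.length = clamp(li)
        parent.add_child(nodes[aj])
        nodes[aj].edge.length = clamp(lj)
        # distances from the new node to the remaining taxa
        rest = [a for k, a in enumerate(active) if k not in (i, j)]
        new_d = 0.5 * (d[ai, rest] + d[aj, rest] - dij)
        nodes.append(parent)
        d = np.pad(d, ((0, 1), (0, 1)))
        d[-1, rest] = new_d
        d[rest, -1] = new_d
        active = rest + [len(nodes) - 1]

    # join the last three nodes on a central (seed) node via three-point formulas
    a, b, c = active
    la = clamp((d[a, b] + d[a, c] - d[b, c]) / 2.0)
    lb = clamp((d[a, b] + d[b, c] - d[a, c]) / 2.0)
    lc = clamp((d[a, c] + d[b, c] - d[a, b]) / 2.0)
    center = dendropy.Node()
    for node, ln in ((nodes[a], la), (nodes[b], lb), (nodes[c], lc)):
        center.add_child(node)
        node.edge.length = ln
    tree.seed_node = center
    tree.is_rooted = False
    tree.nj_clamped = clamped
    if clamped:
        logger.info("neighbor joining clamped %d negative branch length(s)", clamped)
    return tree


# ---------------------------------------------------------------------------
# Bipartitions
# ---------------------------------------------------------------------------

def _leafset(node: dendropy.Node) -> frozenset[str]:
    return frozenset(lf.taxon.label for lf in node.leaf_iter())


def _canonical(side: frozenset[str], all_leaves: frozenset[str]) -> frozenset[str]:
    other = all_leaves - side
    if len(side) < len(other):
        return side
    if len(other) < len(side):
        return other
    return side if tuple(sorted(side)) < tuple(sorted(other)) else other


def bipartitions(tree: dendropy.Tree) -> set[frozenset[str]]:
    """Nontrivial bipartitions (one per internal edge), canonicalized to the
    smaller side (lexicographic tie-break for even splits)."""
    all_leaves = frozenset(lf.taxon.label for lf in tree.leaf_node_iter())
    out: set[frozenset[str]] = set()
    for node in tree.preorder_node_iter():
        if node is tree.seed_node or node.is_leaf():
            continue
        below = _leafset(node)
        if 2 <= len(below) <= len(all_leaves) - 2:
            out.add(_canonical(below, all_leaves))
    return out


# ---------------------------------------------------------------------------
# Bootstrap
# ---------------------------------------------------------------------------

def bootstrap_support(
    genotypes: GenotypeMatrix,
    n_replicates: int = 1000,
    seed: int = 0,
    het_het: float = 0.5,
    identity_resample: bool = False,
) -> dendropy.Tree:
    """NJ tree annotated with locus-bootstrap supports.

    Loci (columns) are resampled with replacement, distances and the NJ tree
    recomputed per replicate, and each original-tree bipartition's support is
    the percentage of replicates whose tree contains it.  ``identity_resample``
    disables resampling (every replicate re-uses the original loci) and exists
    for self-consistency checks.
    """
    if n_replicates < 1:
        raise ValidationError("n_replicates must be >= 1")
    rng = np.random.default_rng(seed)
    base = neighbor_joining(p_distance_matrix(genotypes, het_het=het_het))
    base_bips = bipartitions(base)
    counts = {bip: 0 for bip in base_bips}
    failures = 0
    for _ in range(n_replicates):
        if identity_resample:
            idx = np.arange(genotypes.n_loci)
        else:
            idx = rng.integers(0, genotypes.n_loci, size=genotypes.n_loci)
        try:
            rep_tree = neighbor_joining(
                p_distance_matrix(genotypes.subset_loci(idx), het_het=het_het)
            )
        except ValidationError as exc:
            failures += 1
            logger.warning("bootstrap replicate failed: %s", exc)
            continue
        rep_bips = bipartitions(rep_tree)
        for bip in base_bips:
            if bip in rep_bips:
                counts[bip] += 1
    if failures > n_replicates / 2:
        raise ValidationError(f"{failures}/{n_replicates} bootstrap replicates failed")
    ok = n_replicates - failures
    all_leaves = frozenset(lf.taxon.label for lf in base.leaf_node_iter())
    for node in base.preorder_node_iter():
        if node is base.seed_node or node.is_leaf():
            continue
        below = _leafset(node)
        if 2 <= len(below) <= len(all_leaves) - 2:
            support = 100.0 * counts[_canonical(below, all_leaves)] / ok
            node.label = f"{support:g}"
    return base


def edge_supports(tree: dendropy.Tree) -> dict[frozenset[str], float]:
    """Map canonical bipartition -> support read off internal-node labels."""
    all_leaves = frozenset(lf.taxon.label for lf in tree.leaf_node_iter())
    out = {}
    for node in tree.preorder_node_iter():
        if node is tree.seed_node or node.is_leaf() or node.label is None:
            continue
        below = _leafset(node)
        if 2 <= len(below) <= len(all_leaves) - 2:
            out[_canonical(below, all_leaves)] = float(node.label)
    return out


# ---------------------------------------------------------------------------
# Rooting
# ---------------------------------------------------------------------------

def midpoint_root(tree: dendropy.Tree) -> dendropy.Tree:
    """Root at the midpoint of the longest leaf-to-leaf path.

    The input is not modified.  Ties between equally long paths are broken
    by the lexicographically smallest leaf pair.
    """
    total = sum(e.length or 0.0 for e in tree.preorder_edge_iter())
    if total <= 0:
        raise ValidationError(
            "all branch lengths are zero; midpoint rooting undefined — root explicitly"
        )
    work = tree.clone(depth=1)

    pdm = work.phylogenetic_distance_matrix()
    leaves = sorted(work.taxon_namespace, key=lambda t: t.label)
    best = None
    for i, t1 in enumerate(leaves):
        for t2 in leaves[i + 1 :]:
            plen = pdm.patristic_distance(t1, t2)
            key = (-plen, t1.label, t2.label)
            if best is None or key < best[0]:
                best = (key, t1, t2)
    _, t1, t2 = best
    half = -best[0][0] / 2.0

    # walk from t1's leaf toward t2's leaf, accumulating edge lengths
    n1 = work.find_node_with_taxon_label(t1.label)
    n2 = work.find_node_with_taxon_label(t2.label)
    mrca = pdm.mrca(t1, t2)
    path = []  # edges from n1 up to mrca, then down to n2
    node = n1
    while node is not mrca:
        path.append(("up", node))
        node = node.parent_node
    down = []
    node = n2
    while node is not mrca:
        down.append(("down", node))
        node = node.parent_node
    path.extend(reversed(down))

    cum = 0.0
    for direction, node in path:
        elen = node.edge.length or 0.0
        if cum + elen >= half - 1e-15:
            # split node.edge at distance (half - cum) from the end nearer t1
            offset = half - cum
            if direction == "up":
                length_child_side = offset
            else:
                length_child_side = elen - offset
            # bisect the edge at the midpoint, then root at the new node
            parent = node.parent_node
            mid = dendropy.Node()
            parent.remove_child(node)
            parent.add_child(mid)
            mid.edge.length = elen - length_child_side
            mid.add_child(node)
            node.edge.length = length_child_side
            work.reroot_at_node(mid, update_bipartitions=False)
            work.is_rooted = True
            return work
        cum += elen
    raise AssertionError("midpoint not found on the longest path")  # pragma: no cover


def path_length_matrix(tree: dendropy.Tree) -> DistanceMatrix:
    """Leaf-to-leaf patristic distances, ordered by sorted leaf label."""
    pdm = tree.phylogenetic_distance_matrix()
    taxa = sorted(
        (lf.taxon for lf in tree.leaf_node_iter()), key=lambda t: t.label
    )
    n = len(taxa)
    m = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            m[i, j] = m[j, i] = pdm.patristic_distance(taxa[i], taxa[j])
    return DistanceMatrix([t.label for t in taxa], m, np.ones((n, n), dtype=np.int64))


def least_squares_residual(tree: dendropy.Tree, dist: DistanceMatrix) -> float:
    """Mean squared difference between tree path lengths and input distances."""
    pdm = tree.phylogenetic_distance_matrix()
    taxa = {t.label: t for t in tree.taxon_namespace}
    resid = 0.0
    count = 0
    for i, a in enumerate(dist.sample_ids):
        for b in dist.sample_ids[i + 1 :]:
            j = dist.sample_ids.index(b)
            resid += (pdm.patristic_distance(taxa[a], taxa[b]) - dist.values[i, j]) ** 2
            count += 1
    return resid / count


# ---------------------------------------------------------------------------
# Newick I/O
# ---------------------------------------------------------------------------

def write_newick(tree: dendropy.Tree, path=None) -> str:
    """Serialize with 10-significant-digit branch lengths and internal-node
    labels (supports) preserved; returns the string, optionally writing it."""
    s = tree.as_string(
        schema="newick",
        real_value_format_specifier=".10g",
        suppress_rooting=True,
        unquoted_underscores=True,
    ).strip() + "\n"
    if path is not None:
        with open(path, "w", newline="\n") as fh:
            fh.write(s)
    return s


def parse_newick(text: str, rooted: bool | None = None) -> dendropy.Tree:
    """Parse a Newick string; internal node labels are kept (support values)."""
    try:
        tree = dendropy.Tree.get(
            data=text,
            schema="newick",
            suppress_internal_node_taxa=True,
            preserve_underscores=True,
        )
    except Exception as exc:  # dendropy raises assorted error classes
        raise ValidationError(f"newick parse error: {exc}") from exc
    if rooted is not None:
        tree.is_rooted = rooted
    return tree


def read_newick(path, rooted: bool | None = None) -> dendropy.Tree:
    with open(path) as fh:
        return parse_newick(fh.read(), rooted=rooted)
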