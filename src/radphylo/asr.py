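"""Mk ("Markov k-state one-parameter") ancestral-state reconstruction.

The Mk model is a continuous-time Markov chain on k character states with a
single rate alpha for every state-to-state change.  Its transition
probabilities have the closed form

    P_ii(t) = 1/k + (k-1)/k * exp(-k*alpha*t)
    P_ij(t) = 1/k -   1/k  * exp(-k*alpha*t)      (i != j)

and the stationary distribution is uniform, which is also used as the root
prior.  Tip-state likelihoods are combined by Felsenstein's pruning
algorithm (postorder partial likelihoods with per-node rescaling); the rate
is estimated by bounded one-dimensional maximization of that likelihood; and
per-node marginal state probabilities come from the standard upward/downward
message passing, equivalent to re-rooting at each node (the chain is
reversible, so the total likelihood is invariant to root placement along a
branch).

This machinery doubles as fixed-topology likelihood evaluation for discrete
data; no topology search is performed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import dendropy
import numpy as np
import pandas as pd
from scipy.optimize import minimize_scalar

from .genotypes import CharacterMatrix, ValidationError

logger = logging.getLogger(__name__)

_MIN_BRANCH = 1e-9


@dataclass
class MkModel:
    """k states, one rate; rows of the transition matrix sum to 1 for t >= 0."""

    k: int
    alpha: float

    def __post_init__(self) -> None:
        if self.k < 2:
            raise ValidationError("Mk model requires k >= 2 states")
        if self.alpha < 0:
            raise ValidationError("rate alpha must be nonnegative")

    def transition_matrix(self, t: float) -> np.ndarray:
        return mk_transition_matrix(self.k, self.alpha, t)


def mk_transition_matrix(k: int, alpha: float, t: float) -> np.ndarray:
    """Closed-form Mk transition matrix for elapsed time t."""
    if k < 2:
        raise ValidationError("k must be >= 2")
    if t < 0:
        raise ValidationError("negative branch length")
    if alpha < 0:
        raise ValidationError("negative rate")
    e = np.exp(-k * alpha * t)
    p_same = 1.0 / k + (k - 1.0) / k * e
    p_diff = 1.0 / k - 1.0 / k * e
    P = np.full((k, k), p_diff)
    np.fill_diagonal(P, p_same)
    return P


# ---------------------------------------------------------------------------
# Tree bookkeeping
# ---------------------------------------------------------------------------

def node_keys(tree: dendropy.Tree) -> dict[int, str]:
    """Deterministic node identifiers: tips keep their taxon label, internal
    nodes get ``nd<i>`` by preorder position.  The tree is not modified, and
    any existing internal labels (e.g. bootstrap supports) are ignored."""
    keys: dict[int, str] = {}
    i = 0
    for node in tree.preorder_node_iter():
        if node.is_leaf():
            keys[id(node)] = node.taxon.label
        else:
            keys[id(node)] = f"nd{i}"
            i += 1
    return keys


def _branch_length(node: dendropy.Node) -> float:
    t = node.edge.length
    if t is None:
        t = 0.0
    if t < 0:
        raise ValidationError("negative branch length")
    return max(t, _MIN_BRANCH)


def _check_tips(tree: dendropy.Tree, tip_states: dict[str, int], k: int) -> None:
    for lf in tree.leaf_node_iter():
        lbl = lf.taxon.label
        if lbl not in tip_states:
            raise ValidationError(f"no state for leaf {lbl!r}")
        s = tip_states[lbl]
        if not (0 <= s < k):
            raise ValidationError(f"leaf {lbl!r} has state {s} outside [0, {k})")


def mrca_label(tree: dendropy.Tree, tip_labels) -> str:
    """Deterministic identifier of the most recent common ancestor of the tips
    (consistent with the node ids used in reconstruction results)."""
    node = tree.mrca(taxon_labels=list(tip_labels))
    return node_keys(tree)[id(node)]


# ---------------------------------------------------------------------------
# Pruning likelihood
# ---------------------------------------------------------------------------

def _partials(
    tree: dendropy.Tree, tip_states: dict[str, int], model: MkModel
) -> tuple[dict, float]:
    """Postorder partial likelihoods with rescaling; returns (partials, logscale)."""
    k = model.k
    partials: dict[int, np.ndarray] = {}
    logscale = 0.0
    for node in tree.postorder_node_iter():
        if node.is_leaf():
            vec = np.zeros(k)
            vec[tip_states[node.taxon.label]] = 1.0
        else:
            vec = np.ones(k)
            for child in node.child_nodes():
                P = model.transition_matrix(_branch_length(child))
                vec = vec * (P @ partials[id(child)])
            top = vec.max()
            if top <= 0:
                raise ValidationError("zero likelihood: impossible tip configuration")
            vec = vec / top
            logscale += np.log(top)
        partials[id(node)] = vec
    return partials, logscale


def tree_loglikelihood_mk(
    tree: dendropy.Tree, tip_states: dict[str, int], model: MkModel
) -> float:
    """Log-likelihood of the tip states under Mk with a uniform root prior."""
    _check_tips(tree, tip_states, model.k)
    partials, logscale = _partials(tree, tip_states, model)
    root = partials[id(tree.seed_node)]
    return float(np.log(root.mean()) + logscale)


def estimate_rate_ml(
    tree: dendropy.Tree,
    tip_states: dict[str, int],
    k: int,
    bounds: tuple[float, float] = (1e-8, 100.0),
) -> tuple[float, float]:
    """ML estimate of the single Mk rate by bounded scalar maximization.

    A coarse log-spaced grid brackets the optimum before Brent refinement,
    guarding against the flat likelihood plateaus of the no-change and
    saturation regimes.  Deterministic.
    """
    _check_tips(tree, tip_states, k)

    def nll(log_a: float) -> float:
        return -tree_loglikelihood_mk(tree, tip_states, MkModel(k, 10.0**log_a))

    lo, hi = np.log10(bounds[0]), np.log10(bounds[1])
    grid = np.linspace(lo, hi, 60)
    vals = np.array([nll(x) for x in grid])
    i = int(np.argmin(vals))
    a = grid[max(i - 1, 0)]
    b = grid[min(i + 1, len(grid) - 1)]
    res = minimize_scalar(nll, bounds=(a, b), method="bounded",
                          options={"xatol": 1e-10})
    if not res.success:  # pragma: no cover
        raise ValidationError(f"rate optimization failed: {res.message}; "
                              f"grid bracket [{a}, {b}]")
    # accept the better of grid best and refined point (flat plateaus)
    if vals[i] < res.fun:
        return float(10.0 ** grid[i]), float(-vals[i])
    return float(10.0**res.x), float(-res.fun)


# ---------------------------------------------------------------------------
# Marginal reconstruction
# ---------------------------------------------------------------------------

@dataclass
class MkAncestralResults:
    """Marginal ancestral-state reconstruction for one character.

    ``probabilities`` maps node label (tips included) to the k-vector of
    marginal state probabilities; ``most_probable`` holds the argmax state,
    ties broken toward the lower state code.
    """

    character: str
    k: int
    alpha: float
    log_likelihood: float
    probabilities: dict[str, np.ndarray]
    most_probable: dict[str, int]
    root_label: str
    state_labels: dict[int, str] = field(default_factory=dict)

    def probability(self, node_label: str, state: int) -> float:
        return float(self.probabilities[node_label][state])

    def frame(self) -> pd.DataFrame:
        rows = []
        for label, vec in self.probabilities.items():
            for s, p in enumerate(vec):
                rows.append(
                    {
                        "node": label,
                        "state": s,
                        "state_label": self.state_labels.get(s, str(s)),
                        "probability": p,
                    }
                )
        return pd.DataFrame(rows)

    def summary(self) -> str:
        lines = [
            f"Mk1 ancestral-state reconstruction: {self.character}",
            "=" * (40 + len(self.character)),
            f"states k: {self.k}   ML rate alpha: {self.alpha:.6g}",
            f"log-likelihood: {self.log_likelihood:.4f}",
            f"root node: {self.root_label}",
        ]
        root = self.probabilities[self.root_label]
        for s, p in enumerate(root):
            lbl = self.state_labels.get(s, str(s))
            lines.append(f"  P(root = {lbl}) = {p:.4f}")
        return "\n".join(lines)

    def write_tsv(self, path) -> None:
        self.frame().to_csv(path, sep="\t", index=False, lineterminator="\n")


def marginal_ancestral_states(
    tree: dendropy.Tree,
    tip_states: dict[str, int],
    model: MkModel,
    character: str = "character",
    state_labels: dict[int, str] | None = None,
) -> MkAncestralResults:
    """Per-node marginal state probabilities by upward/downward passing."""
    _check_tips(tree, tip_states, model.k)
    keys = node_keys(tree)
    k = model.k
    partials, logscale = _partials(tree, tip_states, model)
    loglik = float(np.log(partials[id(tree.seed_node)].mean()) + logscale)

    # downward messages: above[v](s) = P(evidence outside v's subtree, state at v = s)
    above: dict[int, np.ndarray] = {id(tree.seed_node): np.full(k, 1.0 / k)}
    probabilities: dict[str, np.ndarray] = {}
    most_probable: dict[str, int] = {}
    for node in tree.preorder_node_iter():
        av = above[id(node)]
        vec = av * partials[id(node)]
        total = vec.sum()
        if total <= 0:
            raise ValidationError("zero marginal normalization")
        vec = vec / total
        key = keys[id(node)]
        probabilities[key] = vec
        best = int(np.argmax(vec))
        ties = np.flatnonzero(np.isclose(vec, vec[best], rtol=0, atol=1e-12))
        if len(ties) > 1:
            logger.info("marginal tie at node %s; keeping lowest state %d", key, best)
        most_probable[key] = best
        children = node.child_nodes()
        for child in children:
            sib = np.ones(k)
            for other in children:
                if other is child:
                    continue
                Po = model.transition_matrix(_branch_length(other))
                sib = sib * (Po @ partials[id(other)])
            msg = av * sib
            Pc = model.transition_matrix(_branch_length(child))
            down = Pc.T @ msg
            top = down.max()
            above[id(child)] = down / top if top > 0 else down

    return MkAncestralResults(
        character, k, model.alpha, loglik, probabilities, most_probable,
        keys[id(tree.seed_node)], state_labels or {},
    )


class MkAncestralModel:
    """Fixed-topology Mk1 model of one discrete character on a rooted tree.

    ``fit()`` estimates the rate by maximum likelihood and returns the
    marginal reconstruction as an :class:`MkAncestralResults`.
    """

    def __init__(
        self,
        tree: dendropy.Tree,
        tip_states: dict[str, int],
        k: int,
        character: str = "character",
        state_labels: dict[int, str] | None = None,
    ):
        if not tree.is_rooted:
            raise ValidationError("ancestral reconstruction requires a rooted tree")
        _check_tips(tree, tip_states, k)
        self.tree = tree
        self.tip_states = dict(tip_states)
        self.k = k
        self.character = character
        self.state_labels = state_labels or {}

    def loglike(self, alpha: float) -> float:
        return tree_loglikelihood_mk(self.tree, self.tip_states, MkModel(self.k, alpha))

    def fit(self, bounds: tuple[float, float] = (1e-8, 100.0)) -> MkAncestralResults:
        alpha, _ = estimate_rate_ml(self.tree, self.tip_states, self.k, bounds)
        return marginal_ancestral_states(
            self.tree, self.tip_states, MkModel(self.k, alpha),
            character=self.character, state_labels=self.state_labels,
        )


def reconstruct_all(
    tree: dendropy.Tree, characters: CharacterMatrix
) -> list[MkAncestralResults]:
    """ML-Mk1 reconstruction of every character in the matrix on one tree."""
    leaves = {lf.taxon.label for lf in tree.leaf_node_iter()}
    samples = set(characters.sample_ids)
    if leaves != samples:
        diff = sorted(leaves.symmetric_difference(samples))
        raise ValidationError(f"tree leaves and character samples differ: {diff}")
    results = []
    for name in characters.character_names:
        model = MkAncestralModel(
            tree,
            characters.column(name),
            characters.n_states[name],
            character=name,
            state_labels=characters.state_labels.get(name, {}),
        )
        results.append(model.fit())
    return results
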