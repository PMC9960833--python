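"""Maximum-likelihood admixture model: ancestry proportions and ancestral
allele frequencies, with cross-validated choice of the number of ancestral
populations K.

Model
-----
Each individual i carries ancestry proportions q_i (a point on the K-simplex)
and each ancestral population k carries an allele frequency f_kl at locus l.
The observed dosage is binomial,

    g_il ~ Binomial(2, pi_il),     pi_il = sum_k q_ik f_kl,

so the log-likelihood is sum over called entries of
g*ln(pi) + (2-g)*ln(1-pi).  Fitting alternates the classic expected-allele-
count EM updates for Q and F, which keep Q rows exactly on the simplex and
increase the likelihood monotonically (asserted every iteration).

K is chosen by entry-level cross-validation: called genotype entries are
partitioned into folds, each fold is masked and the model refitted, and the
fold error is the mean squared difference between the masked dosage and its
fitted expectation 2*pi (divided by 2).  The K minimizing the mean CV error
is reported as optimal, ties going to the smaller K.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .genotypes import MISSING, GenotypeMatrix, ValidationError

logger = logging.getLogger(__name__)

_F_EPS = 1e-6


def _validate_qf(n: int, L: int, K: int, Q: np.ndarray, F: np.ndarray) -> None:
    if Q.shape != (n, K) or F.shape != (K, L):
        raise ValidationError(f"Q/F shapes {Q.shape}/{F.shape} inconsistent with "
                              f"{n} samples x {L} loci x K={K}")
    if np.any(np.abs(Q.sum(axis=1) - 1.0) > 1e-8):
        raise ValidationError("Q rows must sum to 1 within 1e-8")
    if np.any(Q < -1e-12):
        raise ValidationError("Q entries must be nonnegative")
    if F.min() <= 0.0 or F.max() >= 1.0:
        raise ValidationError("F entries must lie strictly in (0, 1)")


def admixture_loglikelihood(
    genotypes: GenotypeMatrix, Q: np.ndarray, F: np.ndarray
) -> float:
    """Binomial log-likelihood of (Q, F); missing entries contribute nothing."""
    Q = np.asarray(Q, dtype=float)
    F = np.asarray(F, dtype=float)
    K = Q.shape[1] if Q.ndim == 2 else 0
    _validate_qf(genotypes.n_samples, genotypes.n_loci, K, Q, F)
    g = genotypes.dosages.astype(float)
    w = (genotypes.dosages != MISSING).astype(float)
    g = np.where(w > 0, g, 0.0)
    pi = Q @ F
    if pi.min() <= 0.0 or pi.max() >= 1.0:
        raise ValidationError("model allele frequencies pi outside (0,1)")
    return float(np.sum(w * (g * np.log(pi) + (2.0 - g) * np.log1p(-pi))))


@dataclass
class AdmixtureResults:
    """Fitted admixture model: point estimates and fit diagnostics."""

    K: int
    sample_ids: list[str]
    locus_ids: list[str]
    Q: np.ndarray
    F: np.ndarray
    log_likelihood: float
    n_iterations: int
    converged: bool
    cv_error: float | None = None
    loglik_path: np.ndarray = field(default=None, repr=False)

    def q_frame(self) -> pd.DataFrame:
        cols = [f"pop{k + 1}" for k in range(self.K)]
        return pd.DataFrame(self.Q, index=self.sample_ids, columns=cols)

    def major_component(self) -> pd.Series:
        """Per sample, the index (1-based) of its largest ancestry component."""
        return pd.Series(self.Q.argmax(axis=1) + 1, index=self.sample_ids)

    def summary(self) -> str:
        lines = [
            "Admixture model fit",
            "===================",
            f"K (ancestral populations): {self.K}",
            f"samples: {len(self.sample_ids)}   loci: {len(self.locus_ids)}",
            f"log-likelihood: {self.log_likelihood:.4f}",
            f"iterations: {self.n_iterations}   converged: {self.converged}",
        ]
        if self.cv_error is not None:
            lines.append(f"cross-validation error: {self.cv_error:.6f}")
        counts = self.major_component().value_counts().sort_index()
        lines.append("samples per majority component: "
                     + ", ".join(f"pop{k}: {v}" for k, v in counts.items()))
        return "\n".join(lines)

    def write_q(self, path) -> None:
        """ADMIXTURE-style .Q: one whitespace-delimited row per sample."""
        np.savetxt(path, self.Q, fmt="%.6f")

    def write_p(self, path) -> None:
        """ADMIXTURE-style .P: one row per locus, K columns."""
        np.savetxt(path, self.F.T, fmt="%.6f")


class AdmixtureModel:
    """K-ancestral-population admixture model for a genotype matrix.

    Examples
    --------
    >>> model = AdmixtureModel(genotypes, K=3)
    >>> res = model.fit(seed=1)
    >>> res.Q.shape
    (60, 3)
    """

    def __init__(self, genotypes: GenotypeMatrix, K: int):
        if K < 1:
            raise ValidationError("K must be >= 1")
        if genotypes.n_samples < K:
            raise ValidationError("need at least K samples")
        self.genotypes = genotypes
        self.K = K
        self._g = genotypes.dosages.astype(float)
        self._w = (genotypes.dosages != MISSING).astype(float)
        self._g = np.where(self._w > 0, self._g, 0.0)

    # -- EM core -----------------------------------------------------------

    def _loglik(self, Q: np.ndarray, F: np.ndarray, w: np.ndarray) -> float:
        pi = np.clip(Q @ F, _F_EPS, 1.0 - _F_EPS)
        return float(np.sum(w * (self._g * np.log(pi) + (2.0 - self._g) * np.log1p(-pi))))

    def _em(
        self,
        Q: np.ndarray,
        F: np.ndarray,
        w: np.ndarray,
        tol: float,
        max_iter: int,
    ) -> tuple[np.ndarray, np.ndarray, float, int, bool, np.ndarray]:
        g = self._g
        a = w * g            # derived-allele counts, zeroed where masked
        b = w * (2.0 - g)
        denom_q = 2.0 * w.sum(axis=1)
        if np.any(denom_q == 0):
            raise ValidationError("a sample has no called genotypes")
        ll_prev = -np.inf
        path = []
        converged = False
        it = 0
        for it in range(1, max_iter + 1):
            pi = np.clip(Q @ F, _F_EPS, 1.0 - _F_EPS)
            ra = a / pi                  # n x L
            rb = b / (1.0 - pi)
            # expected allele-origin counts u_ikl = ra_il q_ik f_kl and
            # v_ikl = rb_il q_ik (1-f_kl); their marginal sums are matmuls
            Fc = 1.0 - F
            Qnew = (Q * (ra @ F.T) + Q * (rb @ Fc.T)) / denom_q[:, None]
            usum = F * (Q.T @ ra)        # K x L
            vsum = Fc * (Q.T @ rb)
            Q = Qnew / Qnew.sum(axis=1, keepdims=True)   # guard float drift
            with np.errstate(invalid="ignore"):
                F = np.where(usum + vsum > 0, usum / np.maximum(usum + vsum, 1e-300), F)
            F = np.clip(F, _F_EPS, 1.0 - _F_EPS)
            ll = self._loglik(Q, F, w)
            if ll < ll_prev - 1e-6 * max(1.0, abs(ll_prev)):
                raise AssertionError(
                    f"EM log-likelihood decreased: {ll_prev} -> {ll}"
                )
            path.append(ll)
            if ll - ll_prev < tol:
                converged = True
                ll_prev = ll
                break
            ll_prev = ll
        return Q, F, ll_prev, it, converged, np.array(path)

    def _init(self, rng: np.random.Generator, w: np.ndarray):
        n, L = self._g.shape
        Q = rng.dirichlet(np.ones(self.K), size=n)
        Q = np.clip(Q, 1e-6, None)
        Q = Q / Q.sum(axis=1, keepdims=True)
        called = w.sum(axis=0)
        mean_f = np.where(called > 0, self._g.sum(axis=0) / np.maximum(2 * called, 1), 0.5)
        F = np.clip(
            mean_f[None, :] + rng.uniform(-0.1, 0.1, size=(self.K, L)),
            _F_EPS, 1.0 - _F_EPS,
        )
        return Q, F

    def fit(
        self,
        seed: int = 0,
        tol: float = 1e-6,
        max_iter: int = 2000,
        n_starts: int = 5,
        _mask: np.ndarray | None = None,
    ) -> AdmixtureResults:
        """EM from ``n_starts`` random initializations; best likelihood wins.

        ``_mask`` (internal, for cross-validation) marks entries to hold out
        of the fit in addition to missing data.
        """
        w = self._w if _mask is None else self._w * (~_mask)
        rng = np.random.default_rng(seed)
        best = None
        for _ in range(n_starts):
            Q0, F0 = self._init(rng, w)
            Q, F, ll, it, conv, path = self._em(Q0, F0, w, tol, max_iter)
            if best is None or ll > best[2]:
                best = (Q, F, ll, it, conv, path)
        Q, F, ll, it, conv, path = best
        if not conv:
            logger.warning("EM did not converge in %d iterations (K=%d)", it, self.K)
        return AdmixtureResults(
            self.K,
            list(self.genotypes.sample_ids),
            list(self.genotypes.locus_ids),
            Q, F, ll, it, conv, loglik_path=path,
        )

    # -- cross-validation ---------------------------------------------------

    def cv_folds(self, n_folds: int, seed: int) -> list[np.ndarray]:
        """Partition called entries into ``n_folds`` boolean masks."""
        called = np.argwhere(self._w > 0)
        if len(called) < n_folds:
            raise ValidationError("fewer called entries than folds")
        rng = np.random.default_rng(seed)
        perm = rng.permutation(len(called))
        masks = []
        for f in range(n_folds):
            sel = called[perm[f::n_folds]]
            mask = np.zeros_like(self._w, dtype=bool)
            mask[sel[:, 0], sel[:, 1]] = True
            if not mask.any():
                raise ValidationError(f"fold {f} holds no entries")
            masks.append(mask)
        return masks

    def cross_validation_error(
        self,
        n_folds: int = 5,
        seed: int = 0,
        tol: float = 1e-4,
        max_iter: int = 500,
        n_starts: int = 1,
    ) -> float:
        """Mean over folds of the masked-entry squared dosage error / 2."""
        masks = self.cv_folds(n_folds, seed)
        errors = []
        for f, mask in enumerate(masks):
            res = self.fit(
                seed=seed + 1000 * (f + 1), tol=tol, max_iter=max_iter,
                n_starts=n_starts, _mask=mask,
            )
            pi = np.clip(res.Q @ res.F, _F_EPS, 1.0 - _F_EPS)
            g = self.genotypes.dosages.astype(float)
            err = np.mean((g[mask] - 2.0 * pi[mask]) ** 2) / 2.0
            errors.append(err)
        return float(np.mean(errors))


@dataclass
class KSweepReport:
    """Per-K fits and CV errors over a K range, with the CV-optimal K."""

    k_values: list[int]
    log_likelihoods: list[float]
    cv_errors: list[float]
    optimal_k: int
    fits: dict[int, AdmixtureResults] = field(default_factory=dict, repr=False)

    def frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "K": self.k_values,
                "log_likelihood": self.log_likelihoods,
                "cv_error": self.cv_errors,
                "optimal": [k == self.optimal_k for k in self.k_values],
            }
        )

    def summary(self) -> str:
        lines = ["K sweep (cross-validated)", "========================="]
        for k, ll, cv in zip(self.k_values, self.log_likelihoods, self.cv_errors):
            star = "  <- optimal" if k == self.optimal_k else ""
            lines.append(f"K={k}: logL={ll:.2f}  CV={cv:.6f}{star}")
        return "\n".join(lines)


def fit_admixture(
    genotypes: GenotypeMatrix,
    K: int,
    seed: int = 0,
    tol: float = 1e-6,
    max_iter: int = 2000,
    n_starts: int = 5,
) -> AdmixtureResults:
    return AdmixtureModel(genotypes, K).fit(
        seed=seed, tol=tol, max_iter=max_iter, n_starts=n_starts
    )


def cross_validation_error(
    genotypes: GenotypeMatrix, K: int, n_folds: int = 5, seed: int = 0, **kw
) -> float:
    return AdmixtureModel(genotypes, K).cross_validation_error(
        n_folds=n_folds, seed=seed, **kw
    )


def sweep_k(
    genotypes: GenotypeMatrix,
    k_min: int = 2,
    k_max: int = 7,
    seed: int = 0,
    n_folds: int = 5,
    tol: float = 1e-5,
    max_iter: int = 1000,
    n_starts: int = 3,
) -> KSweepReport:
    """Fit and cross-validate every K in [k_min, k_max]; optimal K minimizes
    the CV error (ties toward smaller K)."""
    if k_min > k_max:
        raise ValidationError(f"k_min={k_min} exceeds k_max={k_max}")
    ks, lls, cvs, fits = [], [], [], {}
    for k in range(k_min, k_max + 1):
        model = AdmixtureModel(genotypes, k)
        res = model.fit(seed=seed, tol=tol, max_iter=max_iter, n_starts=n_starts)
        res.cv_error = model.cross_validation_error(
            n_folds=n_folds, seed=seed, tol=max(tol, 1e-4),
            max_iter=min(max_iter, 500), n_starts=1,
        )
        ks.append(k)
        lls.append(res.log_likelihood)
        cvs.append(res.cv_error)
        fits[k] = res
    optimal = ks[int(np.argmin(cvs))]  # argmin takes the first (smallest K) tie
    return KSweepReport(ks, lls, cvs, optimal, fits)


def match_columns(Q_fit: np.ndarray, Q_true: np.ndarray) -> np.ndarray:
    """Resolve label switching: permute fitted columns to best match truth.

    Returns the permuted copy of ``Q_fit`` minimizing mean absolute error
    against ``Q_true`` over all column permutations (exact for the small K
    used in tests; K <= 8)."""
    from itertools import permutations

    K = Q_true.shape[1]
    best, best_err = None, np.inf
    for perm in permutations(range(K)):
        err = np.abs(Q_fit[:, perm] - Q_true).mean()
        if err < best_err:
            best_err, best = err, Q_fit[:, list(perm)]
    return best
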