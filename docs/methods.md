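# Methods

`radphylo` implements the computational chain of a RAD-seq phylogenetic
study design: pairwise genotype p-distances, neighbor-joining (NJ) trees
with locus-bootstrap supports, principal component analysis with
Tracy–Widom significance tests, admixture-model inference of population
structure with cross-validated choice of the number of ancestral
populations K, and Mk1 maximum-likelihood ancestral-state reconstruction of
discrete morphological characters. A synthetic-data module generates
genotype matrices, trees, and characters with the statistical structure the
analyses assume, including a canonical 52-sample, six-clade fixture.

## Genotype p-distance

Genotypes are diploid dosages g ∈ {0, 1, 2} at biallelic SNPs. The per-site
dissimilarity between accessions i and j is

    d_ij(l) = 0    both the same homozygote
            = 1    opposite homozygotes
            = 0.5  exactly one heterozygote
            = h    both heterozygous (h = `het_het`, default 0.5)

and D_ij = Σ_l d_ij(l) / L_ij, where L_ij counts the sites at which both
samples have calls (pairwise-complete averaging; L_ij is reported per pair
in `n_sites_used`). Pairwise deletion was chosen over complete-case loci
because it does not bias D downward for high-missingness pairs; both
conventions are expressible (complete-case reduces to dropping loci with
any missing call before the computation).

The default h = 0.5 scores a shared heterozygote as half-different. This
has the consequence that two distinct samples with identical genotypes have
D = n_het/(2L) > 0 whenever they share heterozygous sites; with h = 0 the
measure reduces to the allele-sharing distance mean |g_i − g_j| / 2, which
is zero for identical samples. Both conventions are tested; the default
follows the literal case table of the source method.

## Neighbor joining and bootstrap

NJ is the standard Saitou–Nei agglomeration on the Q-criterion,

    Q(i,j) = (r − 2) d(i,j) − Σ_k d(i,k) − Σ_k d(j,k),

with two behaviours pinned down because they are usually left to the
implementation: ties in Q are broken by the lowest (row, column) index pair
of the current working matrix, and negative estimated branch lengths are
clamped to zero with the clamp count recorded on the tree. The final three
lineages join on a central node by the three-point formulas, giving an
unrooted tree with a degree-3 seed node (2n − 3 edges). NJ is consistent on
additive matrices; the suite verifies exact recovery (topology and path
lengths to 1e-9) of random 8-leaf additive trees and agreement with
scikit-bio's independent implementation.

Bootstrap supports resample loci (columns) with replacement — the standard
phylogenetic bootstrap — recompute distances and the NJ tree per replicate,
and report, for each internal edge of the original tree, the percentage of
replicates whose tree contains the same bipartition. Supports annotate the
original tree; they never alter its topology or lengths. The default is
1000 replicates.

Rooting, where needed (ancestral-state reconstruction), is by midpoint: the
root is placed halfway along the longest leaf-to-leaf path, with ties
broken by the lexicographically smallest leaf pair. Midpoint rooting was
chosen because the study design includes no outgroup.

## PCA and Tracy–Widom tests

Each locus column is centered and divided by sqrt(p̂(1 − p̂)) with the
shrunk frequency estimate p̂ = (1 + Σ_i g_il) / (2 + 2n) — the binomial
(genetic-drift) variance scaling. Missing entries are mean-imputed per
locus before normalization (they land exactly at zero after centering);
zero-variance loci are dropped. Sample coordinates are eigenvectors of the
sample × sample covariance scaled by sqrt(eigenvalue); each eigenvector's
sign is fixed by making its largest-magnitude entry positive, so results
are bit-for-bit reproducible.

The significance of each leading eigenvalue is assessed against the
Tracy–Widom (GOE) distribution. With m' effective markers and n samples,
the normalized eigenvalue ℓ = n'λ₁/Σλ (n' = n − 1; centering costs one
degree of freedom) is standardized by

    μ = (√(m'−1) + √n')² / m'
    σ = (√(m'−1) + √n') / m' · (1/√(m'−1) + 1/√n')^{1/3}

and referred to TW₁. Successive eigenvalues are tested after removing the
preceding components (tail renormalization, n' decremented per step). The
n − 1 convention is the one that calibrates: on 200 structureless 50×2000
replicates it rejects at 2% for nominal 5% (mildly conservative, consistent
with genotype data not being exactly Gaussian), whereas using n rejects at
21%.

The embedded TW₁ quantile table (p ∈ [1e-6, 0.5], log-linear interpolation;
p outside the table is reported at the nearer bound) was generated by
numerically integrating the Hastings–McLeod solution of Painlevé II
(q'' = sq + 2q³, q ~ Ai(s) at +∞) with DOP853 at rtol 1e-12 and the
Tracy–Widom determinantal formulas F₁² = F₂ · exp(−∫q); it reproduces the
published GOE significance points 0.9793 / 2.0234 / 3.2724 at
p = 0.05 / 0.01 / 0.001. The effective marker count defaults to the
observed locus count; a moment-based estimator from the eigenvalue spread
is available as an option (`effective_markers="estimated"`).

## Admixture model

Each individual i has ancestry proportions q_i on the K-simplex and each
ancestral population k allele frequencies f_kl, with

    g_il ~ Binomial(2, π_il),   π_il = Σ_k q_ik f_kl.

Fitting maximizes the binomial log-likelihood Σ [g ln π + (2 − g) ln(1−π)]
over called entries by the classic expected-allele-count EM (the FRAPPE
updates): responsibilities apportion each observed allele among the K
origins, then Q rows and F entries are reset to expected fractions. These
updates keep Q exactly on the simplex and increase the likelihood
monotonically — asserted at every iteration, which is the main internal
correctness check. F is clipped to [1e-6, 1 − 1e-6]. The fit restarts from
`n_starts` random initializations (Q ~ Dirichlet(1), F = empirical
frequency ± uniform noise) and keeps the best final likelihood; EM rather
than quasi-Newton block relaxation was chosen for implementability and the
monotone-likelihood invariant, the contract being the fitted likelihood,
not the optimizer's path. Convergence is declared when the log-likelihood
improves by less than `tol` (default 1e-6); non-convergence at `max_iter`
returns the fit flagged `converged=False` with a warning.

K is selected by entry-level cross-validation: called genotype entries are
partitioned uniformly at random into `n_folds` folds (default 5); each fold
is masked, the model refitted without it, and the fold error is
mean((g − 2π̂)²)/2 over the masked entries. The squared-dosage error is
used instead of deviance residuals for numerical robustness near π = 0, 1;
on well-separated data it has the same argmin behaviour. The CV-optimal K
minimizes the mean fold error, ties going to the smaller K. Label switching
between runs is resolved only in tests (best column permutation), never
silently in outputs.

At desk scale, entry-masking CV on the canonical fixture is conservative:
it reliably prefers K > 2 over K = 2 but its minimum can sit below the
number of simulated groups, because the supergroup layer makes the last
few splits carry little held-out predictive signal relative to their extra
parameters (see the sweep test for the exact property asserted).

## Mk1 ancestral-state reconstruction

The Mk1 model is a continuous-time Markov chain on k states with one rate α
for every state-to-state change; transition probabilities have the closed
form P_ii(t) = 1/k + (k−1)/k · e^{−kαt}, P_ij(t) = 1/k − 1/k · e^{−kαt},
and the stationary distribution is uniform, which is also the root prior.
Tip likelihoods combine by Felsenstein pruning with per-node rescaling.
The rate is estimated by bounded maximization of the log-likelihood over
log₁₀ α ∈ [−8, 2]: a 60-point grid brackets the optimum, then Brent
refinement — the grid guards against the flat plateaus of the no-change
(α → 0) and saturation (α → ∞) regimes, and the procedure is deterministic.
Per-node marginal probabilities come from standard upward/downward message
passing (equivalent to re-rooting at each node; the chain is reversible, so
the total likelihood is invariant to root placement along a branch, which
the suite asserts). Zero-length branches are perturbed to 1e-9. Ties in the
most-probable state go to the lower state code. Characters are
reconstructed independently. The implementation agrees to ≥6 digits with
R's `phytools::fitMk`/`ancr` (ER model) on the fixture, and exactly with
exhaustive enumeration over internal-state assignments on small trees.

## Synthetic data and the canonical fixture

Two generator families:

* **Admixture generator** — g ~ Binomial(2, QF) with Q rows defaulting to
  symmetric Dirichlet(0.2) (mostly-assigned individuals with occasional
  admixture) and F entries to Uniform(0.05, 0.95).
* **Balding–Nichols groups** — ancestral frequencies p ~ Uniform(0.1, 0.9);
  each group's frequency is Beta(p(1−c)/c, (1−p)(1−c)/c) with drift c, so
  E[freq] = p and Var = c·p(1−p): c acts as an F_ST-like divergence with
  one tunable parameter.

The canonical fixture mirrors a 52-sample, six-clade design: codes A1–A3,
B1–B15, C1–C5, D1–D5, E1, F1–F23, with metadata taken from the packaged
printed tables. Genotypes use two-level Balding–Nichols drift — a
supergroup layer ({A,B} vs {C,D,E,F}) at c = 0.1, then per-group
frequencies at c = 0.2 (5000 loci by default) — values chosen once as a
realistic strong-differentiation regime for subgenus-level divergence.
Characters: gland present (1) exactly in D1–D5; inflorescence umbel (1) in
A1–A3, short raceme (2) in C1–C5, raceme (0) elsewhere.

The canonical tree is a stated convention, not an estimate: rooted topology
((A,B), ((C,D), (E1,F))), stem branches 0.1, within-clade branches 0.02,
with each clade a deterministic balanced binary subtree over its
code-ordered tips. Balanced (rather than ladder) clades keep the longest
leaf-to-leaf path crossing the central edge, so midpoint rooting recovers
the two-supergroup split. Under this convention the ML-Mk1 reconstruction
places ≥ 0.998 probability on the expected state at every clade ancestor;
at the root, the raceme state carries 0.947 (canonical root) / 0.970
(midpoint root) — the three umbel tips sit only two stems from the root, so
a few percent of posterior mass remains on the derived states there. These
are the numbers `scripts/acceptance.py` recomputes.

What the generators do **not** emulate: linkage disequilibrium between loci
(all loci independent), RAD-specific ascertainment and allele dropout,
sequencing error, realistic site-frequency spectra, non-random missingness
(missing data are off by default; an optional `missing_rate` masks entries
uniformly), and mutation on the fixture tree (fixture genotypes come from
the drift model, not from simulating down the canonical tree). Passing
tests therefore demonstrate the correctness and calibration of the
algorithms under their own model assumptions, not robustness to these
real-data features.

## Numerical and interface choices

* Missing dosage sentinel −1; every downstream computation is mask-aware
  (distance: pairwise deletion; admixture: masked entries contribute
  nothing; PCA: per-locus mean imputation).
* Distance matrices are symmetrized exactly ((D + Dᵀ)/2) to remove float
  noise; the diagonal is set to 0 by definition.
* Multi-allelic VCF records never reach the analyses: they are skipped and
  counted at parse time.
* Newick output carries 10 significant digits and supports as internal
  node labels; parse∘write preserves topology, lengths, and supports.
* One global pipeline seed expands into per-stage seeds by drawing eight
  31-bit integers from `default_rng(seed)` in a fixed order; the expansion
  is recorded in the run report, so a run is replayable from its report.
* Pipeline defaults follow the study's stated settings: 1000 bootstrap
  replicates, K swept 2–7.

## Test problem sizes

The suite runs at desk scale, chosen to finish in minutes on one CPU while
keeping each check statistically meaningful: NJ additivity at 8 leaves;
pruning-vs-enumeration at ≤ 6 leaves; Tracy–Widom null calibration on 200
replicates of 50×2000; admixture recovery at 60×5000 (K = 3); CV model
selection on 10 replicates of 60×400 (three groups, drift 0.3); bootstrap
properties at 5000 loci / 100 replicates; end-to-end pipeline determinism
at 200 loci with 10 bootstraps. The fixture-wide tests use a reduced
1500-locus fixture.

## Known limitations

* No ML topology search or substitution-model selection: the Mk machinery
  evaluates likelihoods on a fixed topology only.
* No LD pruning before PCA/admixture; with linked loci the Tracy–Widom
  test needs the effective-marker option.
* The CV error is squared-dosage, not deviance; at extreme allele
  frequencies the two can rank near-tied K differently.
* Entry-level CV at fixture scale is conservative about the last splits of
  a hierarchical design (see above).
* Bootstrap supports are bipartition-based; no consensus-tree construction
  beyond support mapping.
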