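# Methods

This note records the models implemented in `pdzcoupling`, the defaults and
why they were chosen, what the synthetic-data generators do and do not
emulate, and the numerical conventions that affect results.

## Motif scanning

Internal PDZ-binding motifs rarely match a consensus template exactly, so
the scanner scores rather than matches. A template is an ordered list of
residue classes (`X` = any; `Φa` = {A,V,L,I,M}; `Φs` = {S,T}; literals;
alternations like `D/G`). Each window position scores 1 for class
membership, `s_cons` (default 0.5) when the residue shares a fixed
conservative-substitution group ({D,E}, {N,Q}, {S,T}, {K,R}, {F,Y,W},
{A,V,L,I,M}) with an allowed residue, and 0 otherwise; the window score is
the positional mean, and windows pass when score ≥ `min_score` (default
0.8) with at most `max_strict_mismatches` (default 1) zero-scoring
positions. The defaults were chosen so that a Gln occupying the Φs slot of
`W-Φs-D-X-P` — one strict mismatch, score 4/5 — is still reported: that is
the boundary case an internal-motif search must tolerate. Both thresholds,
the substitution groups and `s_cons` are parameters. Ties are broken by
descending score, then ascending start, then template order. `X` in a
*target* sequence matches nothing. Note the asymmetry this implies: the
search is deliberately permissive, and specificity comes from conservation
across orthologs, not from the score alone.

P-position numbering anchors at the aspartate whose side chain mimics the
free C-terminal carboxylate: that residue is P₀, C-terminal neighbours are
P₁, P₂, …, N-terminal ones P₋₁, P₋₂, …. A peptide with several aspartates
is ambiguous and requires an explicit anchor index; guessing is refused.

## Trajectory statistics

**Superposition.** All fluctuation statistics first superpose every frame
onto the mean structure by the Kabsch algorithm (SVD of the weighted
covariance, reflections excluded), iterated twice because the mean is
itself frame-dependent. This removes dependence on an arbitrary laboratory
frame. Important caveat: when trajectories are *generated* in a fixed frame
with no rigid-body motion (as this package's synthetic generator does),
superposition should be switched off (`fit=False`) — removing a best-fit
rigid motion from data that has none injects weak global anticorrelations,
which is enough to push white-noise eigenvalues past a significance null.

**RMSF.** `RMSF_i = √⟨|r_i(t) − r̄_i|²⟩`, per selected atom, RMS-combined
per residue. For isotropic per-axis fluctuation σ the expected value is
σ√3.

**Interaction propensity.** Cell (i, j) is the fraction of frames in which
the minimum distance between peptide residue i's side-chain heavy atoms and
*any* heavy atom of domain residue j lies strictly below the cutoff
(default 4 Å). The asymmetric atom scope (side chain on the peptide side,
whole residue on the domain side) reflects how the statistic is phrased in
practice; both scopes and the cutoff are parameters. A distance exactly at
the cutoff is a non-contact — the strictness only matters for constructed
fixtures. Glycine uses its Cα as side-chain proxy (configurable); hydrogens
are always excluded.

**Secondary structure.** β-strand propensity is the fraction of frames with
φ ∈ [−180°, −45°] and ψ ∈ [45°, 180°] ∪ [−180°, −120°], computed from
backbone N/CA/C dihedrals. These boxes are this package's operational
definition — generous enough to cover extended and polyproline-adjacent
strands while excluding the α-basin; no assignment algorithm (DSSP etc.) is
invoked. Chain-terminal residues lack φ or ψ and are reported as missing
(NaN), never as 0.

**Residue deviation.** Two conformers are paired by (chain, residue index),
globally superposed on all paired Cα, and the per-residue Cα displacement
reported. With one locally displaced residue among many, the global fit
absorbs a small fraction of the displacement (order 1/N), which is why the
recovery tests use 50-residue chains and a 5% tolerance.

## Dynamical coupling and sectors

The raw coupling matrix is the displacement covariance
`raw_ij = ⟨Δr_i·Δr_j⟩` (3-D dot products, Å²); the normalised form divides
by `√(raw_ii·raw_jj)` and is the default output, with entries defined 0
where a variance vanishes. Replicates are merged by frame concatenation
before analysis, which equals the frame-weighted pooled covariance about
the pooled mean.

Sector extraction proceeds in four steps, all parameterised:

1. **Mode retention.** With `n_components="auto"`, an eigenvalue is
   significant when it exceeds the maximum eigenvalue over `n_null`
   (default 100) surrogate matrices in which each residue's displacement
   series is independently permuted across frames — preserving every
   marginal, destroying all coupling. This requires the displacement
   series, which `dccm()` attaches to its output. A fixed count is also
   supported (e.g. to mirror an expected five-component structure).
2. **ICA rotation.** Retained eigenvectors are rotated by FastICA. Sector
   loading patterns are one-sided spikes (a minority of residues, large
   same-sign loadings) and are therefore strongly *skewed*, whereas the
   symmetric mixture of two comparable sectors is bimodal and can score
   higher on kurtosis-style contrasts (for two 10-of-50 blocks the mixture
   has excess kurtosis −0.5 against the spike's +0.25, so logcosh-FastICA
   converges to the mixture). The rotation therefore uses the cubic
   contrast with five seed-derived restarts and keeps the solution with the
   largest total |skewness| of loadings. Components are ordered by the
   Rayleigh quotient of their loading vector against the coupling matrix,
   signs fixed so the dominant loading is positive. Deterministic given the
   seed, and stable across reseeding on block-structured matrices.
3. **Membership.** A residue joins the component of its largest absolute
   loading when that loading reaches the `loading_quantile` quantile
   (default 0.9) of all pooled |loadings|. The quantile should reflect the
   expected member fraction: for a fixture with 20 planted members among
   n·k = 100 loadings the appropriate value is 1 − 20/100 = 0.8, and the
   interpolated quantile then falls in the wide gap between member and
   background loadings. The conservative 0.9 default suits exploratory use
   where sectors are expected to be small.
4. **Sector merging.** Components whose member sets remain strongly coupled
   belong to one sector. Because the mean of |half-normal noise| (0.80σ)
   exceeds its median (0.67σ), comparing the inter-component mean |c_ij|
   against the matrix median alone would systematically merge *independent*
   components; the criterion therefore also requires the inter-component
   coupling to exceed `merge_ratio` (default 0.5) times the geometric mean
   of the two intra-component couplings.

## Binding and kinetics fits

Exchange decays are fitted as `y(t) = y∞ + (y₀−y∞)e^(−kt)` by
Levenberg–Marquardt in (y∞, amplitude, log k), initialised from a
log-linearised fit and multi-started over a log-spaced rate grid; a trace
with no resolvable decaying amplitude returns a flagged, non-converged
result rather than raising. Standard errors come from the Gauss–Newton
covariance, with the delta method mapping se(log k) to se(k). Relative
activities are rate ratios with quadrature-propagated relative errors.

Titrations are fitted as `y = U + (B−U)·f_b` with the exact 1:1 bound
fraction from the quadratic mass balance, evaluated in the
cancellation-free form `f_b = 2L / (b + √(b² − 4LR))`, `b = L + R + K_d`.
This handles receptor depletion and tends to the hyperbola `L/(K_d+L)` as
R → 0; note the exact solution lies *below* the hyperbola evaluated at
total ligand, since binding consumes free ligand. The fit is multi-started
over log-spaced K_d values spanning the concentration range; a K_d landing
outside [min conc/100, max conc×100] is flagged poorly determined. Thermal
or thermophoretic signal physics is not modelled: responses are treated as
affine in bound fraction, which keeps the model identifiable from a single
dilution series.

## Synthetic data: what it does and does not emulate

The generators reproduce the *statistical designs* of the measurements the
pipeline consumes, with planted ground truth:

- Gaussian Cα trajectories draw i.i.d. per-frame, per-axis displacements
  from a planted covariance, so the normalised DCCM converges to the
  planted correlation at rate ~F^(−1/2). They have **no temporal
  autocorrelation, no anharmonicity and no rigid-body diffusion** — DCCM
  and sector analysis depend only on the stationary covariance, so
  temporal structure is deliberately out of scope. Passing recovery tests
  therefore demonstrates correctness of the estimators, not robustness to
  slow MD convergence.
- Scripted complexes place a side-chain proxy at 0.8× / 2× the cutoff in a
  seeded-shuffled choice of frames, making propensities exact frame counts;
  they contain no binding physics.
- Titrations use a 16-point 1:2 dilution from 3.4 mM with 50 nM receptor
  and 2% multiplicative Gaussian noise; exchange traces use multiplicative
  noise around a clean exponential. Real measurements add baseline drift
  and concentration errors that are not modelled.
- Ortholog sets mutate a reference sequence per column (motif columns at
  1 − conservation, flanks at 1 − background identity) with uniform
  substitution — no phylogenetic correlation structure.

All generators are bit-reproducible given their seed.

## Problem sizes used in validation

Sector recovery uses 50 residues, two 10-residue blocks at ρ = 0.8, 2000
frames; at these sizes the block eigenvalues (≈ 1 + 9ρ ≈ 8.2) separate from
the shuffle-null edge (≈ 1.2) by a wide margin, making recovery a sharp
pass/fail signal rather than a marginal one. RMSF and DCCM convergence
checks use 5000 frames, where the F^(−1/2) sampling error (~1%, bound 5%)
is comfortably inside tolerance. Affinity recovery follows the 16-point
triplicate dilution design; with 2% noise the pooled-fit K_d standard error
is ~2–3%, against a 10% recovery tolerance.

## Known limitations

- No insertion codes, altloc beyond occupancy resolution, or mmCIF; the
  plain-text `xyzt` trajectory format and multi-model PDB are the only
  trajectory inputs (binary MD formats can be converted externally).
- The scanner does not construct alignments; conservation profiling
  requires pre-aligned input.
- Sector analysis assumes an approximately stationary trajectory; no
  convergence diagnostics are provided.
- The β/non-β dihedral classification is binary; no helix/turn classes.
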