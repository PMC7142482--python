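# Methods

This note records the models, numerical choices and known limitations behind
`nmrflux`, in the order the pipeline runs.

## Synthetic data model

Real cell/EV/media NMR cohorts and the proteomics supplements they pair with
are rarely redistributable, so the package generates its own inputs and
treats the generator as first-class, tested code.

**Reference spectra.** Pure-metabolite standards are sums of Lorentzian
lines — the natural NMR line shape; Gaussian/Voigt profiles are out of
scope. Each standard is normalized to unit *summed* intensity over the
acquisition grid, the convention for library standards, so fitted
coefficients share one scale. The default grid is 32,768 points over
−0.5…10 ppm, the analysis window of a typical 600 MHz ¹H metabolomics
spectrum. The built-in panel contains 20 synthetic stand-ins for database
standards; names and approximate shifts follow common ¹H assignments
(lactate 1.33/4.11 ppm, glycine 3.55 ppm, oxidized/reduced glutathione,
5-oxoproline, tryptophan aromatics at 7.3–7.7 ppm, …) with amplitudes
loosely tracking proton counts. They are labelled synthetic and make no
claim to reproduce measured multiplet structure (no J-coupling physics).

**Mixtures.** A sample spectrum is Σᵢ cᵢ·referenceᵢ plus three perturbations:

| parameter | meaning | default |
|---|---|---|
| `noise_sd` | Gaussian noise sd, intensity units | 0 (demo 5 × 10⁻⁴ ≈ 1–2 % of max signal) |
| `shift_jitter_sd` | per-metabolite rigid ppm shift sd (pH-driven variation); per-peak jitter is available but off by default | 0 (demo 5 × 10⁻⁴ ppm) |
| `baseline_amp` | peak amplitude of a random degree-3 polynomial drift, mirroring the polynomial baseline correction applied to real spectra | 0 |
| `biological_cv` | lognormal sd of per-replicate concentration variation | 0.1 |

With all three at zero the mixture is exactly linear in the concentrations
(asserted pointwise to 1 × 10⁻¹² relative), which anchors the exact-recovery
tests. Fixed seed ⇒ bit-identical output.

**Cohorts.** Groups are (cell line, source) pairs — glioblastoma lines LN18,
A172, U118 and normal astrocytes NHA crossed with cell, EV and media
sources. Group effects are multiplicative factors on the group mean;
replicate concentrations are base × effect × lognormal(0, CV). The default
of 3 biological replicates per group is a design choice of this package
(replicate counts in comparable studies are study-specific); it is the
smallest size at which every class supports within-group variance estimates,
and it is configurable. A biological CV of 0.1 keeps small-replicate realism
without drowning planted 3-fold effects.

What the generator does *not* emulate: multiplet fine structure, solvent
ridges and imperfect water suppression, phase errors, line-width variation
between samples, peak-density crowding of a full 50-metabolite assignment.
Passing recovery tests therefore demonstrate correctness of the estimation
machinery under the stated noise model, not instrument-grade robustness.

## Preprocessing

Apodization multiplies FID point k by exp(−π·lb·k·dwell); `lb` is in Hz with
default 1 (the conventional reading of an "exp 1" line-broadening setting).
The Fourier stage maps the centered DFT onto ppm via the spectrometer
frequency; a global phase-correction hook exists but is a recorded no-op
because synthetic spectra are generated phased.

Two normalizations are provided: by the integrated reference (DSS) peak over
±0.05 ppm, and by total area over the −0.5…10 ppm window; both are
scale-invariant maps. Synthetic mixtures are generated directly on the
common standard scale (as if already reference-normalized), so the demo
pipeline does not renormalize them; `quantify_cohort` refuses cohorts whose
normalization histories differ, since mixing modes puts samples on
incomparable scales.

The residual water band (4.5–5.0 ppm) is excluded by default before
statistics. This is a package decision — sensible for aqueous extracts — not
a requirement of the estimation machinery.

**Alignment.** Shifts are integer grid bins only, and vacated edge points
repeat the boundary value (no zeros injected into normalized spectra).
Global alignment maximizes the circular FFT cross-correlation with the
reference over lags |ℓ| ≤ 50 (configurable); ties resolve to the smallest
|lag|, then the negative one, making the estimate reproducible and exactly
checkable by an exhaustive-lag oracle. Interval co-shifting applies the same
estimator per interval against a pointwise median (or mean, or indexed)
target, leaving points outside the intervals untouched.

Two practical caveats, both consequences of integer shifts with edge fill
and both visible in the tests: (1) co-shifting spectra that carry *no*
actual shift jitter can apply spurious ±1-bin shifts, because a one-bin
offset of an off-grid-centered peak can marginally raise the raw
correlation — alignment belongs in the chain only when shift variation is
expected; (2) interval edges should sit in quiet spectral regions, since
edge-filling the shoulder of a strong peak biases the correlation. Both are
standard practice for interval co-shifting.

## Quantification

The constrained linear fit min ‖s − Mᵀc‖² s.t. c ≥ 0 is solved by
Levenberg–Marquardt on c = u², which preserves an unconstrained LM iteration
while enforcing the bound exactly. The start is a PLS regression of the
spectrum on the library rows (min(10, n) components by default; the count
mainly affects iteration count, not the optimum) with negative coefficients
clipped. Numerical details:

- the start is floored at 10⁻³ of its maximum so no coordinate begins on the
  stationary boundary u = 0, where LM cannot move it;
- convergence tolerances are ftol = xtol = 10⁻¹², capped at 500 iterations
  per coefficient; the tight tolerance is needed for the 10⁻⁶ agreement
  contract with the exact NNLS solve;
- coefficients below 10⁻⁹ of the largest are snapped to exactly zero and the
  remaining support re-polished by a second LM pass (zeros are stationary
  and stay put), reproducing the active-set structure of the NNLS optimum;
- libraries with condition number above 10⁸ trigger a warning — coefficients
  of collinear standards are not identifiable, and such instances are
  excluded from oracle comparisons.

Because the model is linear, LM-with-squaring and active-set NNLS must agree
at the optimum; the suite checks ≤ 10⁻⁶ relative agreement per coefficient
on 100 random well-conditioned 20-metabolite instances on the full 32,768
point grid, plus non-negativity on pure noise, permutation equivariance, and
monotone degradation of recovery error with noise level.

Fitted values are relative concentrations on the library's unit-intensity
scale; absolute (mM) quantification, per-peak lineshape refitting and
binning-based profiling are out of scope.

## Statistics

- **Scaling**: z-scores per metabolite column (default) or over the whole
  matrix; both are exposed because "mean 0, sd 1 across samples and
  metabolites" is ambiguous between the two. sd uses ddof = 1;
  zero-variance columns map to 0 with a warning.
- **ANOVA ranking**: one-way F per metabolite, descending, with a panel rule
  F > 5 (threshold configurable; 3 is a common looser choice). F is
  invariant under affine transforms of a metabolite, so ranking is
  insensitive to units.
- **PCA**: SVD of the column-centered matrix; explained-variance fractions
  are non-increasing and sum to 1 over all components. Loading signs are
  fixed (largest-magnitude loading positive) for determinism.
- **Hierarchical ordering**: agglomerative clustering (Euclidean/average by
  default — the conventional heat-map choice) for display ordering only.
- **Correlation differences**: Δr = r_A − r_B with Pearson r on unscaled
  relative concentrations, pooling a cell line's EV and media samples per
  table; zero-variance metabolites are marked undefined rather than imputed.
- **Over-representation**: upper-tail hypergeometric p per pathway set
  against the quantified-metabolite universe; exact against enumeration for
  small universes. No multiple-testing correction by default; a
  Benjamini–Hochberg option exists. Pathway sets travel as GMT text.

## Flux modeling

Models carry a stoichiometric matrix, per-reaction bounds, boolean GPR rules
over declared genes, and exactly one objective (biomass/maintenance)
reaction. GPR evaluation follows the standard gene-to-reaction mapping
convention AND → min, OR → max; reactions without a rule map to an
"unconstrained" marker and are never penalized, since no protein evidence
can be absent for spontaneous or non-enzymatic steps.

FBA and GIMME solve LPs with HiGHS (scipy.optimize.linprog), which is
deterministic for fixed input. Protein presence is boolean — present = 100,
absent = 0 — so any expression cutoff strictly between 0 and 100 is
equivalent; the default is 50. The objective-maintenance fraction defaults
to 0.9 and is always logged, as the appropriate threshold is
application-specific. GIMME splits reversible reactions into non-negative
forward/backward parts so the |v| penalty is linear; the recombined flux
vector, the objective value and the inconsistency score
Σ (cutoff − eᵢ)·|vᵢ| are returned. Among degenerate optima only the
objective value and the score are contractual; the flux vector itself may
vary between solvers.

Toy networks (chain, branched alternative routes, a TCA fragment
cit→icit→akg→succ→fum→mal, and a glutathione branch gthrd⇄gthox vs
5-oxoproline) keep every model at ≤ 8 reactions so two brute-force oracles
stay exact: FBA objectives are checked against full vertex enumeration of
the flux polytope, and GIMME scores against enumeration of all activation
patterns of penalized reactions with a restricted LP per pattern. Raising
the objective fraction can never lower the score (tested over a fraction
grid), and an all-present profile always scores 0.

Subnetwork extraction keeps reactions with |v| > 10⁻⁹ and their metabolites,
flagging metabolites that touch exactly one active reaction as dead ends. An
all-zero solution yields an empty submodel, which therefore has no objective
reaction — the one place the model type allows a missing objective.

Model I/O: a documented JSON schema (field-compatible with the common
constraint-based JSON dialect) and SBML Level 3 + FBC v2 via libsbml, with
BiGG-style `M_`/`R_`/`G_` prefixes added on write and stripped on read
(identifiers such as `5oxpro` are not valid SBML SIds). Genome-scale models
are readable; tests and the demo configuration use the toy networks only.
Flux-variability analysis and other context-specific methods (iMAT,
FASTCORE) are out of scope.

## Orchestration and problem sizes

The `run` command executes simulate → preprocess → quantify →
rank/PCA/corr-diff/ORA → flux from one TOML config (flags > config >
defaults), skips stages whose inputs are supplied externally, and writes a
provenance sidecar (tool version, seed, config hash stable under key
reordering, stage parameters, timestamp) next to every artifact. All
randomness derives from the single configured seed; two runs under one seed
produce byte-identical CSVs (timestamps live only in the sidecars).

Default problem sizes, chosen as the package's standard working scale: the
32,768-point grid for everything spectral; 20-metabolite libraries; cohorts
of 2–12 groups × 3 replicates; 100 random instances for the fit-vs-NNLS
contract; toy networks for all flux oracle checks. The acceptance script
(`scripts/acceptance.py`) recomputes every headline number from scratch at
these sizes in about a minute on one CPU.
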