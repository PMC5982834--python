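# Methods

## The competition model

Transcription in *E. coli* is carried out by a limiting pool of core RNA
polymerase (E) that must bind a sigma factor before it can recognize
promoters. The package models the stationary-phase competition between the
housekeeping factor σ70 and the general stress factor σ38, together with
the two regulators that tilt it:

* **Rsd**, an anti-sigma factor that sequesters free σ70;
* **6S RNA**, a non-coding RNA that sequesters the assembled Eσ70
  holoenzyme (and with it a core polymerase).

Two nested variants are implemented.

**Holoenzyme variant** (binding only):

```
E   + σ70  <->  Eσ70          K_E_sigma70
E   + σ38  <->  Eσ38          K_E_sigma38
Rsd + σ70  <->  Rsd·σ70       K_Rsd
6S  + Eσ70 <->  6S·Eσ70       K_6S
```

**Full variant** adds sequence-nonspecific chromosomal binding (one shared
dissociation constant `K_NS` for E, Eσ70 and Eσ38 — they are assumed to
stick to bulk DNA equally), cognate promoters (one shared `K_EsigmaP` for
both promoter classes, both taken equal in stationary phase), promoter
clearance at rate `c` (the promoter-bound holoenzyme initiates, releasing
the promoter *and the sigma factor*) and completion of elongation at rate
`e` (the elongating polymerase Ee returns to the free E pool):

```
E    + DNA <->  E·DNA,   Eσ + DNA <-> Eσ·DNA        K_NS
Eσ   + P   <->  Eσ·P                                K_EsigmaP
Eσ·P  --c-->  Ee + σ + P
Ee    --e-->  E   (+ one transcript)
```

Transcripts are produced but not degraded in this reaction scheme, so they
have no steady-state *level*; the model's observable is the steady
transcription **flux** per promoter class, `rate = e·[Ee] = c·[Eσ·P]`.
Steady state is therefore defined over all species except the transcript.

### Parameters

Defaults (stationary-phase estimates; units as stated) live in
`ModelParameters` and in `src/sigmacomp/data/default_parameters.yaml`:

| parameter | meaning | default |
|---|---|---|
| `E_total` | total core RNA polymerase | 4.3 uM |
| `sigma70_total` / `sigma38_total` | total σ70 / σ38 | 12.0 / 2.7 uM |
| `Rsd_total` / `RNA6S_total` | total Rsd / 6S RNA | 10.4 / 13 uM |
| `DNA_total_sites` | nonspecific sites per cell | 4.6e6 |
| `P70_count` / `P38_count` | cognate promoters per cell | 200 / 200 |
| `cell_volume` | cell volume | 1e-15 L |
| `K_E_sigma70` / `K_E_sigma38` | E–sigma binding | 3.3 / 15.2 nM |
| `K_Rsd` / `K_6S` | sequestration | 32 / 131 nM |
| `K_NS` / `K_EsigmaP` | DNA / promoter binding | 1e-4 / 1e-7 M |
| `clearance_rate_c` / `elongation_escape_rate_e` | initiation / completion | 0.005 / 0.021 s^-1 |

Per-cell copy numbers are converted to molar by the single helper
`counts_to_molar(n, V) = n / (N_A · V)`; pools are exposed in uM, all
internal arithmetic is in M. `operon_length` (1000 nt) is carried for
provenance only: the completion rate `e` is specified directly rather than
derived from elongation speed over length.

### Steady-state definition and solver

With every reversible reaction equilibrated, the steady state is the
solution of the equilibrium relations plus one conservation relation per
total (E, σ70, σ38, Rsd, 6S, DNA sites, each promoter class), with the
flux-cycle closure `[Ee] = (c/e)·[Eσ·P]`. Eliminating complexes leaves a
system in the free concentrations (E, σ70) — holoenzyme variant — or
(E, σ70, σ38) — full variant. Each conservation relation is strictly
monotone in its own free concentration (every complex grows with the free
species it contains), so the solver uses nested Brent brackets:

* outermost: free E on `[0, E_total]` against E conservation;
* inner: free σ70 (and, full variant, free σ38) on `[0, σ_total]`; the two
  sigma problems couple only weakly (through depletion of free nonspecific
  DNA, a ≤ 5% effect at the defaults) and are alternated to convergence.

Brackets guarantee nonnegativity by construction and make the solution
unique. Tolerances: Brent at relative 8.9e-16; a solution is accepted when
the largest conservation residual relative to its total is ≤ 1e-10
(reported as `residual_norm`). On any bracketing failure the solver falls
back to ODE integration (below) and accepts at 1e-8.

Degenerate inputs: a zero total fixes the corresponding free species at
exactly zero; all-zero totals short-circuit to the zero state; a zero
dissociation constant is rejected (singular equilibrium), as is `e = 0`
with `c > 0` (the elongating pool would grow without bound).

### The independent kinetic route

`ode_oracle` integrates the mass-action kinetics directly (BDF,
rtol 1e-10), in expanding time stages until
`max |dX/dt| / max(X, 1e-18 M) <= 1e-10 s^-1`. On-rates are a free choice:
every reversible step uses `kon` with off-rate `kon·K`, and for the pure
binding network the equilibrium depends on the K values only (a test
doubles `kon` and checks the state is unchanged). For the full variant the
irreversible clearance flux perturbs the promoter-binding balance by
O(c/(kon·K)), so `kon` must be fast compared with clearance; the default
1e9 M^-1 s^-1 (near diffusion limit) keeps the perturbation below ~1e-3
on the worst species. This is why the algebraic route and the kinetic
route are compared at 1e-6 relative for the holoenzyme variant but only at
5e-3 for the full variant: the residual difference is the physically real
O(c/(kon·K)) departure from pure equilibrium, not solver error.

### Scenarios, threshold, robustness

Knockout approximations are encoded as named scenarios (overrides applied
before multipliers): `rsd_zero`/`ssrS_zero` remove one regulator and
nothing else; `rsd_ko_sim` additionally raises 6S RNA 2.3-fold and
`ssrS_ko_sim` halves Rsd and E and raises σ38 by 50%, matching the
secondary changes the deletion strains actually display. The 2.3-fold 6S
increase is applied to the default total (13 uM -> 29.9 uM).

`find_rsd_threshold` bisects total Rsd on `[0, 2x default]` (tolerance
0.01 uM) for the point where the 6S-knockout's σ38 transcription rate
equals the *unperturbed* wild-type rate; with the defaults it lands at
9.45 uM, inside the 8–10.4 uM window where reducing Rsd alone flips the
knockout below wild-type.

`robustness_scan` multiplies and divides each of the 16 mechanistic
parameters (all totals, all six K's, `c`, `e`; cell volume and operon
length excluded as non-mechanistic) by a fold factor and asks, per
perturbation, whether plain 6S removal drops σ38 transcription below the
*matched* (identically perturbed) wild-type. At tenfold, no single
perturbation does — the experimentally observed direction requires the
accompanying Rsd/E/σ38 changes, not a parameter tweak. Note the two
comparisons differ: the threshold op compares against the default
wild-type, the scan against a matched wild-type; at e.g. Rsd/2.08 the
knockout falls below the former but not the latter (both facts are
tested).

## The count pipeline

The analysis definitions operate on a gene x sample integer count matrix
with (strain, phase, replicate) metadata — five strains (wild-type, Δrsd,
ΔssrS, the double knockout, ΔrpoS) by five growth phases (early/mid
exponential, transition, stationary, late stationary) by two replicates.

* **Filter.** A gene is kept iff some sample exceeds 10 reads.
* **Normalization.** Median-of-ratios size factors over genes with
  all-positive counts (the DESeq scale concept without its machinery).
* **DE calling** per (mutant, phase) vs wild-type: log2 fold change of
  normalized group means with pseudocount 0.5 (sign convention: mutant
  minus wild-type); a negative-binomial Wald test on the log scale with a
  **single dispersion shared across genes** — two replicates cannot
  support gene-wise dispersion, so α is pooled by method-of-moments: per
  gene and replicate group, `Var(K/s) ≈ μ·mean(1/s) + α·μ²`, and the
  excess variances are combined by regression-through-origin on μ² (the
  ratio-of-sums form is robust to the χ²-skew of two-replicate variances;
  a per-gene median would bias α low and make the test anticonservative).
  Benjamini–Hochberg adjustment runs over filtered genes only; "DE" means
  |log2fc| ≥ 1 and adjusted p < 0.05 and passing the filter. On pure-null
  synthetic data the realized false-positive proportion at padj < 0.05 is
  ~1e-4, comfortably calibrated.
* **Regulon shift.** Two-sided Wilcoxon rank-sum of a gene set's log2 fold
  changes against all other filtered genes, with set/background medians
  and the fraction of the set below zero. This is the statistic that
  detects coherent sub-twofold regulation invisible to per-gene DE calls.
* **Non-additivity.** Genes DE in the double knockout whose single-
  knockout fold changes sum to less than twofold
  (|log2fc_rsd + log2fc_ssrS| < 1).
* **Dose dependence.** Genes whose fold change keeps one strict sign and
  strictly grows in magnitude across the five ordered phases and is DE in
  the final phase. The monotonicity criterion is a package choice (no
  canonical definition exists); the strictness and the final-phase DE
  requirement are switchable (`require_strict_increase`,
  `require_final_de`).

## The synthetic generator

`synthetic.generate` draws negative-binomial counts
(`Var = μ + α·μ²`) around lognormal gene means (median 500, log-sd 0.5 —
a typical RNA-seq mean-expression spread), scaled by optional per-sample
library factors, with log2 effects planted on named gene sets per (strain,
phase). Identical spec and seed give byte-identical output; dispersion 0
degenerates to Poisson.

The default template mirrors the biological structure the pipeline is
meant to detect: a 300-gene σ38 regulon 2–8-fold down in ΔrpoS and subtly
down (log2 −0.15, i.e. the ~10% median decrease that motivates the shift
statistic) in Δrsd and ΔssrS; 100 genes 4-fold up only in the double
knockout; 30 genes down in ΔssrS with magnitude growing each phase (log2
−1.0 → −4.8); and a 200-gene constitutive-σ70 null set. The non-additive
and dose profiles were fixed a priori by a power calculation at the
template's dispersion (0.05) and design (2 vs 2 replicates): the standard
error of a per-phase log2 fold change is ≈ 0.33, so planted magnitudes sit
far enough from the |log2fc| ≥ 1 call line, and successive dose steps are
large enough (0.8–1.1 log2), for recovery to be the expected outcome
rather than a coin flip. A planted effect exactly at the twofold line
would by construction be called in only ~half the genes.

What the generator does *not* emulate: gene length and GC biases,
correlated genes within operons, gene-wise dispersion trends, outlier
replicates, or compositional (mRNA-fraction) artifacts between strains.
Passing the recovery tests therefore shows the statistics are implemented
correctly and calibrated under clean NB sampling — not that real data
meet these assumptions.

## Problem sizes and runtime choices

Sweeps default to ~80–200 grid points (each point an independent
millisecond-scale solve); the solver cross-validation uses 100 random
parameter sets within tenfold of the defaults; the null-calibration check
averages 20 seeds of a 2000-gene experiment; the default synthetic
experiment is 3300 genes x 50 samples. These sizes make the whole suite
run in well under a minute of model time while leaving every statistic
with ample resolution.

## Known limitations

* The equilibrium closure assumes binding is fast relative to clearance;
  the kinetic route quantifies (and bounds) the resulting approximation.
* No growth-phase dynamics, dilution, or other sigma factors (σ32, σ54);
  no Crl or ppGpp mechanisms — the model is a stationary-phase snapshot.
* The shared-dispersion NB Wald test is a deliberate simplification of
  shrinkage-based DE machinery; with only two replicates per group it
  trades per-gene dispersion resolution for calibration.
* Dataset-dependent gene counts from real experiments are not
  reproducible from synthetic data and are out of scope; the recovery
  suite checks detection of planted analogues instead.
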