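# Methods

This note documents the models, defaults and numerical choices behind
`retinotune`, and what its synthetic fixtures do and do not demonstrate.

## The moiety and its internal coordinates

All features are functions of the heavy atoms of the chromophore–lysine
moiety (LYS+RET): retinal carbons C1–C20 (β-ionone ring C1–C6, polyene chain
C7–C15, methyls C16–C20) and the lysine-296 heavy atoms N, CA, C, O, CB, CG,
CD, CE, NZ, where NZ is the Schiff-base nitrogen (the sketch label "N+" is
accepted as an input alias).  The feature set is a registry of 19 internal
coordinates: 15 torsions (four atoms each) and 4 geometric bond angles
(three atoms each).

Three definitions are fixed by the source analysis — Torsion 3
(C15–C14–C13–C20), Torsion 12 (C19–C9–C8–C7) and Angle 3 (C3–C7–C8) — and
Angle 2 is the bond angle at the Schiff-base nitrogen (CE–NZ–C15).  The atom
tuples for the remaining slots were never published; the default registry
fills them from standard retinal connectivity (conjugated-chain torsions,
methyl torsions, Schiff-base and lysine side-chain torsions) and flags each
one `inferred`.  Inferred entries keep the 19-slot structure exercised
end-to-end but must not be read as a reconstruction of the original feature
set; a user registry file (one `name | kind | atoms` line per definition)
overrides the default.

Torsions use the IUPAC sign convention (0° = *cis*, right-hand rule about
the p2→p3 axis, range (−180°, 180°]); geometric angles lie in [0°, 180°].
Both are computed with atan2 formulations that are stable near 0° and 180°.
Degenerate geometry (zero-length bond, collinear torsion axis) raises an
error instead of returning NaN: a silent NaN would propagate into medians
and corrupt the modelling table undetected.

## Per-pigment summaries

**Medians.**  Each pigment is summarised by the median of each parameter's
per-frame series.  Torsion medians are circular: the series is re-centred on
its circular mean, the ordinary median is taken, and the result is mapped
back to (−180°, 180°].  For unimodal series away from the branch seam this
equals the plain median; for series straddling ±180° (common for near-trans
backbone torsions) it avoids the gross artefact of averaging +179° with
−179°.  The seam case {175°, −175°, 179°} evaluates to 179°, which matches
an enumeration over branch choices.

**RMSF.**  Per-atom root-mean-square fluctuation is the standard
sqrt(mean‖v_t − v̄‖²).  The source text prints the formula without the
square and root, an evident typographical truncation; the standard form is
the default here.  Whether frames were superposed before the published RMSF
was computed is also unstated, so alignment is a flag: by default each frame
is least-squares superposed (Kabsch) onto the mean structure of the selected
atoms, with one refinement of the mean, matching common MD practice; `align=False`
computes raw fluctuations.  The area under the RMSF profile (AUC) is the
trapezoidal integral over atom index with unit spacing.

**Distributions.**  Frequency histograms default to 2° bins — narrow enough
to resolve the few-degree width difference between paralog groups without
empty-bin noise — and are normalised to unit mass.  The paralog comparison
pools per-frame values by group after removing each pigment's central value
(circular mean for torsions), so its interquartile range and variance
measure fluctuation width rather than between-pigment offsets.

## Model selection

With 11 pigments and 19 candidate medians, model selection follows a
screen-then-enumerate design:

1. **Screen**: rank parameters by squared Pearson correlation with
   experimental λ_max; constant parameters are dropped with a warning.  The
   original procedure additionally rejected parameters whose relationship
   was judged non-linear on visual inspection; that subjective step is
   encoded as a declarative exclusion list whose default is the complement
   of the seven-parameter shortlist {Torsion 3, 9, 10, 11, 12, Angle 1,
   Angle 3}, keeping the pipeline deterministic while leaving the judgement
   overridable as configuration data.
2. **Exhaustive search**: every non-empty subset of the shortlist is fit by
   OLS (2⁷ − 1 = 127 models) and ranked by
   BIC = n·ln(RSS/n) + (k+1)·ln(n), the leaps/regsubsets convention with
   additive constants dropped (rank-equivalent to the full Gaussian
   likelihood form).  RSS is floored at 1e−12 so numerically perfect fits
   keep a finite score; ties break toward fewer terms, then lexicographic
   term order.  Saturated (n ≤ k+1) and rank-deficient subsets are skipped.
3. **Window**: all models within +2 BIC of the best are reported.  When one
   model must be chosen from the window (the species-fold re-selection), the
   tie-break prefers fewest terms, then lowest BIC — the overfitting-averse
   reading of a near-tie at this sample size.

OLS itself is a numpy least-squares solve with explicit rank checking that
names the collinear terms; the test suite cross-checks coefficients, RSS and
R² against statsmodels as an independent oracle.

## Validation

*Leave-one-pigment-out* keeps the term set fixed and re-estimates only the
coefficients on each 10-pigment fold; the out-of-sample R² is the squared
Pearson correlation between the 11 held-out predictions and experiment.
*Leave-one-species-out* removes both paralogs of a two-paralog species
(four species qualify in the reference table) and reruns the full screen →
search → window procedure on the remaining nine pigments.  Because an R²
over a 2-point hold-out is not meaningful, the species-fold report labels
three variants: over the nine training pigments, over the two held-out
pigments (NaN below three points), and over all eleven.

Predictions warn when a median lies outside the training range of a term,
since extrapolation is the documented failure mode for out-of-range
conformations.  The published coefficient sets (the full model and the four
species-excluded models) are bundled as a registry that round-trips through
JSON bit-identically.

## Synthetic fixtures

The generators define the package's test conditions:

* **Median tables** mirror the study scale — 11 pigments, 7 species, 4
  two-paralog species — and draw each pigment's parameter means from
  independent normal priors centred on the idealized moiety geometry.  λ_max
  is then *defined* as the published three-term model evaluated at the means
  plus Normal(0, σ) noise.  The default σ = 6.8 nm is the residual scale
  implied by the reported mean absolute prediction error of 5.44 nm
  (mean|ε| = σ·√(2/π) for Gaussian residuals); the spreads of the three
  generating means are sized so the implied λ_max range spans roughly the
  88 nm violet-to-blue window of the real pigments.  The standard-normal
  noise draw is scaled by σ after sampling, so datasets generated with one
  seed at different σ share means and standardized noise — coefficient
  errors are then exactly linear in σ, which the monotonicity tests exploit.
* **Angle series** fluctuate around those means with paralog-dependent
  widths — wrapped normal for torsions, truncated normal on [0°, 180°] for
  geometric angles — defaulting to 2° (Sws2a, and the unduplicated Sws2) vs
  8° (Sws2b), the wide/narrow contrast used throughout the distribution
  tests.
* **Coordinates**: a single angle definition can be realised exactly (to
  1e−9°) by inverse geometry, and a full 29-atom trajectory is produced by
  adding iid Gaussian coordinate jitter (default 0.05 Å) to an idealized
  z-matrix structure of the moiety (trans polyene, 11-*cis* kink, gauche
  lysine side chain).  The idealized structure is plausible, not
  energy-minimised; it exists to exercise the extraction path.
* **Recovery experiment**: replicated tables are pushed through screen →
  subset search → fit; it reports the rate at which the generating terms are
  recovered (both exactly and as a subset of the selection) and coefficient
  bias/RMSE from refitting the true term set.

What passing these tests shows: the arithmetic, bookkeeping and selection
machinery are correct, and the pipeline recovers a known sparse linear
signal at the study's sample size and noise level.  What it does not show:
that real MD trajectories of Sws2 homology models satisfy the generative
assumptions (unimodal fluctuations, linear median–λ_max coupling,
independent parameters).  The synthetic fixtures make no claim of physical
realism — no force field, membrane or solvent — and results on them do not
certify predictive accuracy on new opsins.

## Problem sizes and determinism

Default test and acceptance-script sizes are desk-scale choices: 100–1000
frames per synthetic trajectory or series, 100 replicates for the recovery
and IQR-ordering experiments, 1000 random instances for the geometry-oracle
comparison.  All randomness flows from explicit integer seeds through
numpy's `SeedSequence`, so every reported number is reproducible; pipeline
artifacts embed the SHA-256 hash of their configuration, and reruns with an
identical configuration are bit-identical.

## Known limitations

* The 16 inferred angle definitions are stand-ins; conclusions about any
  specific inferred angle transfer to real data only if the atom tuple
  matches the original analysis.
* Binary MD formats (XTC/DCD) are out of scope; convert externally to
  multi-MODEL PDB, XYZ or long CSV.
* Small-n best-subset selection with BIC occasionally admits a spurious
  term at realistic noise (the recovery experiment quantifies this); the
  +2-BIC window is reported precisely so near-equivalent models are visible
  rather than hidden behind a single winner.
* No vitamin-A₂ (porphyropsin) conversion is provided; predictions are on
  the A₁ scale, and no uncertainty intervals beyond fold-wise errors are
  computed.
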