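# Methods

This note documents the models, defaults and numerical choices behind
each pipeline stage, what the synthetic generators do and do not
emulate, and the design decisions taken where more than one reasonable
convention exists.

## Docking-score triage

Scores are best-pose binding energies in kcal/mol (lower = more
favourable), one row per compound per RNA target; any pose-level
aggregation (e.g. minimum over 25 poses) happens upstream of the table
contract. Hits satisfy `score < mean − k·SD` with the **sample**
(n−1-denominator) standard deviation — a screening table is a sample of
chemical space, not the population — and a **strict** inequality, so a
zero-variance table yields no hits and boundary compounds are excluded.
Default k = 2.

Selectivity filtering reuses the same rule symmetrically: a primary hit
is removed when it passes `mean − k·SD` on **any** counter-screen
target, each counter table scored against its own distribution. This is
a deliberate choice — no separate "also bound" criterion exists for the
counter screens, and reusing the one selection rule keeps the filter
parameter-free. A hit absent from a counter table is treated as not
binding that target (with a logged warning). Ranking of the retained
hits is by ascending primary score with lexicographic tie-breaks for
determinism; the top-n cut is a pure rank cut.

Similarity ranking uses Morgan (circular, ECFP-like) fingerprints,
radius 2, 2048 bits, Tanimoto coefficient — the field's default 2D
similarity stack — and is configurable because nothing in the problem
pins down one fingerprint.

## FID assay

The dye calibration (varying RNA at fixed dye) is fitted to
`Y = Bmax·X/(KD + X)` by nonlinear least squares (lmfit / Levenberg–
Marquardt, ftol 1e-10), initialised at `Bmax0 = max(Y)` and `KD0` = the
concentration nearest half of `Bmax0`, both bounded positive. Standard
errors come from the fit covariance. At least five distinct RNA
concentrations including 0 are required; an all-zero response is
rejected as "flat response". The screen's working RNA concentration at
initial fraction bound f is the exact inversion `X = f·KD/(1−f)`
(f = 0.1 by default; a 458.1 nM KD puts it at 50.9 nM).

`%FID = 100·(F0 − F)/F0` with F0 the per-replicate mean of the RNA+dye
blank wells. Negative values (fluorescence enhancement) are kept, not
clipped, so enhancers form a third class. A compound is a **hit** only
when *every* replicate displaces by strictly more than the ±15% band —
the conservative reading of "in duplicate", which avoids single-well
false positives — and an **enhancer** when every replicate is below
−15%. Control wells (dye+ligand vs dye-only, RNA+ligand vs RNA-only)
flag `dye_interactor` / `intrinsic_fluorophore` when the relative
increase exceeds the same 15% band; one consistent threshold is used
because no separate control criterion is defined, and it is
configurable. Buffer-only wells, when present, are subtracted from all
readings first (logged either way). Nominal total concentrations are
used throughout; no ligand-depletion correction is applied.

## STD-NMR

Spectra are (ppm, intensity) traces on a uniform, strictly decreasing
axis. Noise σ is the standard deviation of the **raw** trace in a
configurable signal-free region (default 10–12 ppm). Peak detection
takes local maxima of the 3-point-boxcar-smoothed trace above
`snr_min·σ(raw)` (snr_min default 3.0), excluding the residual-water
(4.6–5.0 ppm) and DMSO (2.45–2.55 ppm) windows. Estimating σ before
smoothing is what gives the detector its specificity: smoothing reduces
per-point noise by √3, so the effective threshold sits near 5.2
smoothed-σ and a whole-spectrum scan of pure noise essentially never
fires, while genuine peaks (linewidths of several points) pass almost
unattenuated. No lineshape fitting is done — the call is
presence/absence.

A compound is *testable* iff its plain 1D spectrum has at least one
detectable peak; a testable compound is a *binder* iff its (off − on)
difference spectrum has one. Difference formation requires axes equal
to 1e-6 ppm per point. The choice of on-resonance frequency (4.9 vs
5.5 ppm) is recorded in metadata but not decided by the code, since no
rule determines it from the data.

## HSQC titrations

CSPs use the literal weighting `sqrt(δH² + 0.14·δC²)`. The printed form
of this expression is ambiguous between weighting δC² by 0.14 and
weighting δC by 0.14 before squaring (the Williamson convention); the
literal reading is the default and the alternative is available as
`convention="scaled"`. Significance flagging uses CSP ≥ mean + 1·SD of
the quantifiable CSPs (overlap-excluded peaks carry a status and stay
out of the statistics); at least 3 quantifiable values are required,
and a zero-variance profile flags nothing.

The region map for construct positions 20–52 ships as an overridable
default. Its boundaries are an approximate reconstruction of the
hairpin's secondary structure — stem arms flanking two mismatches
(positions 25 and 45), a junction triplet on each side of the apical
loop (30–32 and 40–41), the apical loop (33–39) and the dicing-site
bulge (42–44). Users with an exact secondary structure should supply
their own `position=region` file.

**Intermediate exchange.** Fraction bound is `B = 1 − V(X)/V(0)` of the
*free-state* peak: V(X) is the observed volume at ligand concentration
X and V(0) its reference volume, since trackable resonances broaden and
lose volume as binding progresses. B is clipped to [0, 1] with
out-of-range values logged. Pooled per-residue B values are fitted to
`B(X) = Bmax·X/(KD+X) + NS·X`. NS is described as a slope, so the
nonspecific term carries a concentration factor by default; the
constant-offset reading (`+ NS`) is available via `ns_term="constant"`.
Initialisation: KD0 at the half-max concentration, Bmax0 = max
response, NS0 = 0; KD bounded positive. The `saturated` flag is set
when the fitted specific fraction bound exceeds 0.95 within the sampled
range; an unsaturated fit reports KD as a lower bound
(`"> max tested"`) rather than a point estimate.

**Fast exchange.** CSP trajectories against the 0 μM reference are
pooled and fitted to `CSP(X) = Bmax·X/(KD+X)`. When the maximum
observed CSP is below 0.8 of the fitted Bmax the trajectory has not
approached its plateau, so KD is likewise reported as a lower bound.
Pooling assumes the chosen residues share similar endpoint amplitudes;
the residues entering either fit are a user choice because no rule
selects them from the data.

## Synthetic data

Generators are deterministic per seed (NumPy `default_rng`) and
bit-reproducible. Noise is multiplicative Gaussian for intensity-like
quantities (fluorescence, peak volumes) — instrument response scales
with signal — and additive for 1D spectral baselines. Docking scores
are Normal(mean, sd) with planted compounds at exact z-offsets. FID
displacement uses the apparent-KD competitive approximation
`KD' = KD·(1 + L/KD_L)` with no ternary-equilibrium solving, which
keeps a closed-form oracle for every planted truth. STD pairs are
Lorentzian mixtures; a binder's on-resonance amplitudes shrink by the
attenuation factor, a non-binder's differ only in noise. HSQC
titrations move peaks by `fb(X) = X/(KD+X)` times the endpoint shifts
(fast) or scale free-peak volumes by `1 − [Bmax·fb(X) + NS·X]`
(intermediate), clipping negative noisy volumes at zero.

The 40-compound screen fixture plants: 22 STD-testable compounds of
which exactly 7 (A1, A5, A9, B7, C4, C6, RA3) receive 30% on-resonance
attenuation; 4 competitive displacement hits (DA1, A1, C11, DA2) at
KD_L = 100 μM (≈47% displacement at the fb-0.1 design point);
11 enhancers at +40% of the blank; and +50% control-well artefacts for
the dye-interacting and intrinsically fluorescent compounds. Effect
sizes sit far from every threshold so the classification outcome is
stable across seeds; threshold-boundary behaviour is exercised
separately in unit tests. What the generators do **not** emulate:
realistic lineshapes, relaxation, peak overlap in 2D spectra, plate
position effects, or compound-specific spectral signatures — so passing
tests demonstrate correctness of the analysis rules and estimators
under the stated statistical assumptions, not robustness to every
artefact of real instrument data.

## Reporting

Hit rates are rounded half-up to integer percent (7/40 → 18%). Absent
stage results render as "ND", which is distinct from a lower-bound KD
such as "> 1000": not-detected versus not-saturated. Fold-affinity
comparisons propagate lower bounds (`">1000"` over 29.10 → `">34.4"`).

## Problem sizes and tolerances

Parameter-recovery checks use 100-seed Monte Carlo at 2% noise with
titrations of 41 points (0–200 μM in 5 μM steps), a size at which the
median recovered KD sits within ~2% of truth; the null-calibration
check for the STD detector uses 1000 noise-only spectrum pairs of 1201
points. Noiseless fixed-point checks on the fitters use 1e-6 relative
tolerance; exact arithmetic identities are asserted to 1e-9 or tighter.

## Known limitations

* The counter-screen "also binds" rule and the control-well band are
  package conventions, not experimentally derived criteria.
* The apparent-KD displacement model ignores dye and ligand depletion;
  at dye fraction bound 0.1 this is a small error but it is a model
  choice, not physics.
* The intermediate-exchange forward model treats total occupancy
  > 1 (strong nonspecific term at high X) by clipping volumes at zero,
  which biases fits in that regime; keep NS·X + Bmax·fb(X) below 1
  over the sampled range.
* Binary STD calls carry no epitope information; slow-exchange
  titrations are out of scope.
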