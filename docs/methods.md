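# Methods

## The projection model

A residue whose amide crosspeak exchanges rapidly between an "open"
environment (chemical shift δO) and a "closed" one (δC) resonates at the
population-weighted average δ = (1 − f)δO + f·δC. Given reference spectra
that realize the two endpoints — a construct lacking the C-terminal tail
(open) and a phosphorylated construct with the tail fully engaged (closed) —
the closed fraction of any other construct is estimated per residue by
orthogonal projection of the query peak onto the O→C segment in weighted
coordinates (δH, α·δN). We use the glycine-free convention α = 0.14; the
value is a convention, not a fit, and is exposed everywhere
(`--alpha`). The projection coefficient is reported both raw and clamped to
[−0.25, 1.25]: the clamp tolerates noise at the endpoints while the raw
value keeps pathological geometry visible.

Two quality gates accompany every estimate:

* `min_sep` (default 0.02 weighted ppm): residues whose O–C separation is
  below this carry no usable axis and report no f̂. The default is 4× the
  default peak-position noise, so an axis is never built out of noise.
* `perp_tol` (default 0.015 weighted ppm, 3× the default noise sd): peaks
  farther than this from their axis are flagged off-vector. A large d⊥
  means the perturbation is not a two-state population shift — the
  signature of a direct chemical perturbation such as a nearby mutation.

Pathway classification applies the same projection with different anchors
(phosphorylated construct vs tail-truncated construct, query = truncated
construct saturated with free phosphopeptide). Scores ≥ 0.75 are labelled
linker-independent, ≤ 0.25 linker-dependent, otherwise mixed; the
literature grades this as a colour gradient, so the cutoffs are our choice
and are parameters of the function. Signs are preserved so that
opposite-direction displacements along the axis remain visible.

## The N-site exchange model

`ExchangeScheme` composes 1–3 slowly exchanging manifolds, each with an
internal fast open⇌closed equilibrium (closed fraction f_m per residue,
K_m = f_m/(1 − f_m) = k_on/k_off), plus an optional ligand-bound state.
`predict_peaks` applies the timescale-separation collapse rule: one peak
per populated manifold at the internal average position, intensity equal to
the manifold population (normalized to 1 per residue).

The rule is checked, not assumed: `bloch_mcconnell_1d` computes the exact
steady-state absorption lineshape of the flattened site model (each
manifold's O and C as explicit sites) by matrix inversion,
S(ν) = Re 1ᵀ[i(2πν − Ω) + R₂ − K]⁻¹ p, with the kinetic generator K
required to conserve magnetization (columns sum to zero) and satisfy
detailed balance with the stated populations. A single site yields a
Lorentzian of FWHM R₂/π Hz and unit population carries integrated area π
regardless of regime, which the tests use as conservation checks.
`collapse_check` treats the two spectral dimensions as independent 1D
problems (positions and intensities, not full 2D lineshapes, are the
observable), converts ppm with 600/60.8 Hz per ppm (¹H/¹⁵N at 14.1 T),
extracts maxima and inter-minimum areas from the numerical spectrum, and
compares them with the collapse rule. Exchange rates are specified relative
to |Δω|: scale > 10 is fast, < 0.1 slow, otherwise the report is marked
exchange-broadened; predicted peaks closer than twice the linewidth floor
are declared unresolvable rather than failed, mirroring crosspeaks that
cannot be located in crowded spectra.

### Titration

The phosphopeptide binds open sub-states only. With apo free energies fixed
by the apo populations, the bound fraction at free-ligand concentration L is
the single-site isotherm with W_O·L/K_d, where W_O = Σ p_m(1 − f_m) is the
apo open weight — equivalently an apparent dissociation constant
K_d(1 + K_closed), K_closed = (1 − W_O)/W_O: intramolecular closure
competes with the intermolecular ligand. Free ligand is solved with Brent's
method on the scalar mass balance to |residual| < 10⁻¹⁰·[protein]; each
manifold drains in proportion to its population (fast internal exchange
re-equilibrates instantly), so manifold ratios are titration-invariant
while the O:P fraction grows monotonically. K_d is an input (the real
peptide binds with K_d below ~15 µM; the synthetic default is 10 µM), not a
fitted output: self-association in the real system precludes lineshape
fitting of absolute rates, which is also why no rate fitting is attempted
anywhere in the package.

### Scheme fitting

`fit_scheme` assumes manifold populations are residue-independent (the slow
process is a global property such as a proline isomer state) while closed
fractions are residue-specific. Peaks within a residue are ranked by
intensity and assigned to manifolds consistently across residues; the
population of rank r is the across-residue median of the rank-r intensity
share (robust to individual overlapped or misassigned peaks), renormalized;
f comes from the projection of each peak. The rms spread of intensity
shares is returned as a goodness-of-fit so the residue-independence
assumption stays auditable rather than silently imposed.

## Trajectory statistics

*Contacts.* A frame is a single contact event when the minimum distance
over all selected atom pairs is below the cutoff (2.5 Å default), however
many pairs touch. Heavy atoms only by default — a 2.5 Å cutoff sits in
hydrogen-bond range where proton inclusion is ambiguous — with
`include_hydrogens` to flip. The probability series is a stride-1 sliding
mean with the window given in ns (1 ns default) and converted by the frame
interval, truncating partial windows.

*PCA.* Frames from all replicas are merged, least-squares superposed
(Kabsch) onto the iteratively refined mean of the PCA selection itself —
the fit group equals the analysis group, a choice the source data leave
open — and the 3N-coordinate covariance is eigendecomposed. Convergence
between trajectory sets is judged by the interval Jaccard (|∩|/|∪|) of
projection ranges on a given eigenvector; 0.5 is the default threshold
separating condition-specific from shared modes. Per-residue RMSF of
eigenvector k is √(λ_k Σ v²) over the residue's components, so residue
RMSF² sums exactly to λ_k.

*Dihedral mutual information.* MI in nats between torsion series on a fixed
24-bin (15°) circular grid with Miller–Madow bias correction
(+[(m_x−1)+(m_y−1)−(m_xy−1)]/2N). Fixed equal-width bins were chosen over
adaptive schemes for testability: the identical-series value is exactly
ln b + (b−1)/2N, the independence bias is bounded by (b−1)²/2N, and the
narrow wrapped-Gaussian pair approaches −½ln(1−ρ²). A warning fires below
b²/5 frames. Residue-pair MI sums over the two residues' torsion
combinations; the diagonal is excluded. Condition differences are tested
per element with a two-sided Welch t-test across replicas (α = 0.05
default, optional Benjamini–Hochberg); non-significant elements are zeroed
in the filtered matrix.

## The synthetic generator

The generator emulates the statistical structure the analyses assume, not
the physics that produces it:

* **Peak lists** — residues drawn from the tandem-SH2 numbering (545–790)
  with six pre-C-terminal reporters (757–770) always present; per-residue
  O–C weighted separations U(0.1, 0.3) ppm in random directions (typical
  well-resolved amide dispersion); isotropic Gaussian noise in weighted
  space, sd 0.005 ppm (typical HSQC centroid precision, and small against
  every separation); intensities proportional to manifold populations with
  2% lognormal jitter. The wild-type construct has heterogeneous planted
  f ~ U(0.05, 0.95) (reporters U(0.45, 0.95) so the mutant's −0.35 shift
  toward open never clips at the floor); two- and three-manifold constructs
  have populations (0.7, 0.3) and (0.5, 0.3, 0.2) with well-separated f per
  manifold; the mutant adds a 0.1 weighted-ppm off-vector offset at the
  reporter nearest residue 765.
* **Titrations** — populations from the exchange model's own equilibrium;
  bound-state shifts placed off the O–C axis.
* **Toy trajectories** — spatially separated atom groups: a tail atom whose
  core distance follows a discrete telegraph process (per-frame transition
  probability 1 − e^{−k·dt}, exact for the sampled grid; stationary
  probability p₀₁/(p₀₁+p₁₀)); a null contact pair with identical rates in
  both conditions; a symmetric two-atom stretch mode (amplitude 1 Å in one
  condition, absent in the other) whose zero net translation and torque
  make the planted eigenvalue exactly Var(s)/2 under superposition;
  torsion quadruples whose fourth atom is placed by exact
  internal-coordinate construction from wrapped-Gaussian angles (σ = 45°,
  pair correlation ρ = 0 vs 0.8 across conditions, plus an uncorrelated
  null residue); isotropic 0.02 Å jitter throughout. Default study size:
  4 replicas per condition, 2000 frames at 0.1 ns.

What passing recovery tests therefore shows: the estimators extract planted
populations, fractions, rates and correlations at realistic noise. What it
does not show: robustness to spectral overlap and peak-picking error,
force-field realism, conformational kinetics beyond two-state switching, or
assignment transfer between constructs (done upstream by the user).

## Detection defaults in the pipeline

The recovery stage flags a condition effect only when it is statistically
significant across replicas *and* exceeds a minimum effect size: MI
difference p < 0.05 and |ΔMI| > 0.05 nats; contact difference p < 0.05 and
|Δp| > 0.1; per-residue f shift |Δf̂| > 4·√2·noise/|C−O|; off-vector
detection d⊥ > 6× noise sd (deliberately stricter than the 3× QC flag);
PCA mode overlap < 0.5. Pure significance thresholds at α = 0.05 would
flag noise-level differences in a constant fraction of elements over
repeated runs; the effect-size floors sit several standard deviations above
the noise of each statistic while remaining far below every planted effect.
The mutant-shift effect counts as detected when at least half of the
planted reporter residues exceed their per-residue threshold.

## Numerical choices and degenerate inputs

* Lineshape grids: 6000 points spanning the site range ±6 separations
  ±20 R₂; conservation holds to <1% under this truncation.
* Degenerate O/C shifts reject rate scaling (no |Δω| to scale by);
  all-identical PCA frames yield zero eigenvalues and a `degenerate` flag;
  identical reference lists produce all-uninformative axes rather than an
  error.
* Major-peak selection: highest intensity, ties broken by lowest peak
  index.
* Peak-list text format stores shifts at 1e-4 ppm, so write→read
  round-trips are value-identical at that precision.
* All stochastic steps derive their generators from a single seed via
  `numpy` seed sequences; identical truth + seed reproduces byte-identical
  outputs, which the pipeline verifies by hashing its own CSV tables.
* Problem sizes in the standard checks (100-residue peak lists; 4+4
  replicas × 1500–2000 frames; 10-seed pipeline sweeps; 20 random schemes
  for the oracle comparison) keep each suite in the seconds-to-a-minute
  range while leaving every tolerance comfortably resolved.

## Known limitations

* The titration model treats the bound state as one species; isomer
  manifolds of the complex are not resolved (their shifts are assumed
  degenerate at δ_OP).
* `collapse_check` compares 1D maxima per dimension; genuinely 2D lineshape
  effects (differential broadening along a tilted axis) are out of scope.
* The MI estimator's fixed binning trades efficiency for exactness of its
  calibration values; adaptive estimators would be more sample-efficient at
  small n.
* Manifold populations are assumed residue-independent during fitting; the
  reported intensity-share residual is the audit trail for that assumption,
  not a correction.
* No peak picking: the package consumes centroid lists, as produced by
  standard spectral analysis software.
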