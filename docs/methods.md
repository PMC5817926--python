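# Methods

## The five-state kinetic model

A polyprotein domain under piecewise-constant force is modelled as a
continuous-time Markov chain over five states: natively folded (F),
extended chaperone-free (E), extended chaperone-bound (E·C), collapsed
chaperone-free (M, for the molten-globule-like intermediate) and collapsed
chaperone-bound (M·C). The generator switches with the force regime at a
fixed 10 pN threshold — the protocols only ever use ~0 pN against
≥ 30 pN, so the exact cut is immaterial:

| transition | regime | rate | meaning |
|---|---|---|---|
| F → E | pulse | k_u | mechanical unfolding at the reference force |
| M(·C) → E(·C) | pulse | k_uc | re-extension of the labile collapsed state |
| E ⇌ E·C | both | k_on_ext·[C], k_off_ext | chaperone exchange on the extended chain |
| E → M | quench | k_c | collapse at zero force |
| M → F | quench | k_f0 | folding from the collapsed state |
| M ⇌ M·C | quench | k_on_coll·[C], k_off_coll | chaperone exchange on the collapsed state |

Assumptions worth stating explicitly:

* **Bound states never fold.** Chaperone binding acts as a holdase.
* **A bound extended chain does not collapse**; it must release the
  chaperone first (consistent with the observed slow-down of collapse when
  the chain is held extended longer in chaperone).
* **No force law on k_u.** The unfolding rate is stored per reference
  force (120 pN for ubiquitin/I27, 100 pN for Z1-like substrates); the
  experiments measure single forces, so a Bell-type extrapolation would be
  unconstrained.
* **fold_competence** (default 1, 0.75 for ubiquitin emulation) is the
  fraction of domains able to fold at all. It is applied as a partition of
  domains at prediction/simulation time rather than as a sixth state: the
  experimental plateau below 100% is thereby reproduced without extra
  kinetics. Incompetent domains evolve with k_f0 = 0.
* **Optional force-dependent association.** k_on_ext can carry a
  multiplier exp(−ΔΔG(F)/k_BT) derived from a dihedral-remodeling energy
  profile (below); it equals 1 at the profile's minimum-energy force.

Because the force is piecewise constant, propagation is exact: each
segment applies exp(Q Δt) (eigendecomposition with an expm fallback), so
no ODE-solver tolerance enters. Populations are renormalized against
accumulated round-off and conserved to better than 1e-9.

**Predicted refolding yield.** The experimental yield is the ratio of
test-pulse to initial-pulse unfolding steps. In the model this is the
folded fraction at the end of the quench, times fold_competence: collapsed
domains re-extend under the test force quickly (k_uc default 50 s⁻¹) and
without a folded-domain step, so only F produces test steps. When no
initial state is given, leading `unfold` segments are skipped and the
population starts fully extended at their end; the initial pulse exists to
create the unfolded ensemble, and conditioning on "unfolded in the initial
pulse" is exact in that limit.

### Reference parameter values

The chaperone-free reference rates used throughout tests and examples:
k_u = 0.93 s⁻¹ (120 pN), k_f0 = 0.52 s⁻¹, k_c = 10 s⁻¹ (fast collapse, so
the observed single-exponential folding rate ≈ k_f0), fold_competence
0.75. DnaJ-like binding to the extended state uses
k_on_ext = 4.55 × 10⁴ M⁻¹s⁻¹ and k_off_ext = 4.28 × 10⁻² s⁻¹: these are
the unique pair consistent with a dissociation constant of 9.4 × 10⁻⁷ M
and a yield-versus-t_ext decay rate k_on[C] + k_off = 0.27 s⁻¹ at 5 µM.
DnaK-like binding to the collapsed state uses
k_on_coll = 1.5 × 10⁵ M⁻¹s⁻¹, k_off_coll = 2.1 × 10⁻² s⁻¹
(K_d = 1.4 × 10⁻⁷ M), chosen so the kinetic competition between folding
(k_f0) and binding (k_on[C]) caps the quench-time plateau near 30% of the
fold-competent pool.

## Synthetic force-clamp experiments

The generator is the package's data source and defines its study
conditions. Per recording, the number of tethered domains is uniform on
[pickup_min, n_domains_max] (defaults 5–9 for the ubiquitin nonamer),
which exercises the downstream step-count QC. Domains are independent;
each recording draws an own RNG stream from the master seed (SeedSequence
spawning), so recordings reproduce individually. Trajectories are exact
Gillespie realisations with per-segment rate refresh — waiting times that
overrun a segment boundary are discarded and redrawn at the boundary,
which is exact for time-homogeneous segments.

Traces are rendered as a per-(state, force-regime) baseline lookup —
20 nm per unfolded domain under pulse force (25 nm for Z1-like
substrates), 0 at quench — plus white Gaussian noise (default 1 nm SD at
1 kHz). Collapsed states under pulling force are assigned the extended
length: they are mechanically labile and extend essentially instantly
without a discrete step. What the generator deliberately does **not**
emulate: worm-like-chain elasticity (constant baselines suffice for
staircase geometry; WLC rendering is an extension point), instrument
drift and 1/f noise, cantilever dynamics and the ~3 ms force-settling
transient, and surface-adhesion artifacts. Passing tests therefore show
correctness of the analysis chain on idealised staircases, not robustness
to every instrumental pathology.

## Trace analysis

**Step detection** is penalized L2 binary segmentation of the extension
signal of each constant-force pulse region, with a minimum internal
segment length of min_dwell (default 5 ms) and penalty
10 σ̂² ln n, where σ̂ is a robust noise scale from the median absolute
first difference. Level changes d > 0 are accepted as m simultaneous
steps when |d − m·step| ≤ 0.35·step for m = round(d/step) ≥ 1 —
near-coincident unfolding events in a multi-domain polyprotein appear as
one jump of twice the step size. Segments at region edges may be shorter
than min_dwell (a step right at the pulse start is still real), and jumps
falling between multiplicity windows trigger a local re-segmentation with
a relaxed middle-segment length, recovering event pairs separated by less
than the dwell. The detector is deterministic; benchmarked precision and
recall are both ≥ 0.99 at 1-nm noise, 1 kHz, 20-nm steps.

**Unfolding kinetics.** Traces with ≥ 6 events (config-exposed) enter the
P(u) estimate: per-trace cumulative step counts rescaled to [0, 1], then
averaged on a common grid, then fitted to 1 − exp(−k_u t). Normalizing
per trace before averaging weights each trajectory equally; the pooled
alternative (sum all, then normalize) weights by event count and is not
used. Degenerate inputs (all steps at t = 0) return a typed failure, not
a number.

**Refolding yield.** QC keeps recordings with ≥ 5 initial-pulse steps
(config-exposed) and an end-of-initial versus end-of-test extension
mismatch below 10% of the unfolded length (the criterion is stated
experimentally without a tolerance; 10% of total length cleanly separates
same-molecule from changed-tether recordings at nominal noise). The
pooled yield Σ steps_test / Σ steps_initial treats each unfolded domain
as one independent observation; the per-recording mean ratio is exposed
separately for comparison. Errors come from a nonparametric bootstrap
(500 resamples, each recording one data point), reproducible under seed.

**Yield-curve fits** are weighted (1/sem²) nonlinear least squares with
log-linearized starting values: A(1 − e^(−kt)) for quench-time sweeps and
Y∞ + (Y0 − Y∞)e^(−kt) for extended-time sweeps. Zero SEMs are replaced
by the median positive SEM; flat curves return a typed failure flag.

## Binding-constant estimation

`ChaperoneBindingModel` couples yield curves from up to three protocol
families (t_q, t_ext, force sweeps) to the five-state model. The two
chaperone-free reference rates (unfolding F → E and folding M → F) are
held fixed at their measured values; the binding constants are optimized
in log10 space under bounds k_on ∈ [10², 10⁸] M⁻¹s⁻¹,
k_off ∈ [10⁻⁴, 10²] s⁻¹ (positivity plus generous coverage of reported
chaperone kinetics), minimizing χ² = Σ ((y_obs − y_model)/sem)² by
L-BFGS-B from 16 Latin-hypercube starts (seeded) plus the base-scheme
start. Standard errors of log10 rates come from the numerical χ² Hessian
(cov = 2 H⁻¹). χ² profiles (`profile`) refit the remaining free
parameters on a grid and warn when flat — the standard identifiability
diagnostic. Force-sweep data can be fitted either with an independent
k_on_ext per force (default; the force coupling has no assumed closed
form) or through the dihedral-energy multiplier.

A caveat established during validation: with yield curves at
experiment-sized trajectory counts (a few hundred domains per point), the
collapsed-state dissociation rate is only weakly identified from a
quench-time sweep — its information lives in the slow late-quench creep
of the yield, which is comparable to counting noise. Point estimates of
K_d(coll) from a single synthetic dataset scatter by more than a factor
of two; recovery studies should therefore report medians over replicates,
as the package's own tests do.

## Dihedral-remodeling energetics

The cost of constraining the five consensus-fragment (φ, ψ) couples
(ubiquitin LYS48…ASP52; flanking residues excluded) to their bound-state
values is ΔG(F) = −Σ_res ln p_{res,F}(φ\*, ψ\*) in k_BT, per replicate;
the replicate mean and SD are computed per force (SD before
normalization) and the mean profile is shifted so its minimum over forces
is exactly zero. Densities on the torus come from a 5°-bin 2D histogram
with a Laplace pseudo-count spread over all bins — strictly positive and
integrating to one — or optionally a product von Mises kernel KDE (exact
periodicity, no binning; normalized via the scaled Bessel function
i0e so large kernel concentrations stay finite). Angles are wrapped to
(−180°, 180°]. The histogram estimator carries bin-averaging bias where
the log-density gradient is steep (up to ~0.1 k_BT for references a bin
away from a κ ≈ 12 basin); the KDE option trades that for smoothing bias.
Energies are reported in k_BT with no temperature conversion. Bound
reference angles are configuration inputs (deriving them requires a
simulation of the chaperone–substrate complex, out of scope); the
packaged demonstration values are synthetic.

The synthetic sample generator draws from per-residue von Mises mixtures
whose weights shift with force (logistic switches). The demonstration
scenario moves the central β-sheet couple (GLN49/LEU50) into the extended
β basin as force rises while the outer residues (LYS48/GLU51/ASP52) leave
their relaxed low-force basins, producing a U-shaped ΔG(F) with an
interior minimum near 150 pN — cheap binding at intermediate force. This
emulation reproduces the qualitative mechanism, not any measured
energy value.

Ramachandran classification uses coarse rectangular regions —
β/PPII (φ ∈ [−180°, −45°), ψ ∈ [45°, 180°)), αR (φ < 0, ψ ∈ [−120°, 45°)),
αL (φ ≥ 0, ψ ∈ [−60°, 90°)), else "other" — sufficient to state which
basin a residue occupies, not a contour-level analysis.

## Motif scanning

The Hsp40 consensus is matched literally as 7 positions:
G / any / [LMQ] / not-P / any / not-P / not-{C,I,M,P,V,W}; all
overlapping matches are reported, with 1-based inclusive coordinates and
an offset for parent numbering (so the capped ubiquitin fragment numbered
from 45 reports its match at 47–53). Ambiguity codes (B, J, O, U, X, Z)
are accepted in input but fail every position including wildcards — the
conservative choice; other characters raise with the offending letters
listed. The literature's "approximately eight residues" footprint is
noted but the pattern is implemented as the 7 positions that reproduce
both canonical examples. The DnaK scanner is explicitly a heuristic:
sliding-window mean Kyte–Doolittle hydropathy plus a Leu/Ile-fraction
bonus (default 0.5), windows of 5, threshold 2.0.

## Pipeline, units, determinism

One YAML config drives simulate → analyze → fit (any subset); unknown
keys are rejected with their dotted location. Units are uniform: seconds,
piconewtons, molar, nm, rates in 1/s or 1/(M s), energies in k_BT. Every
output JSON carries a hash of the scientific config content, and all
randomness descends from the single master seed through named
SeedSequence streams, so identical configs and seeds give byte-identical
results files.

## Problem sizes used in the shipped analyses

The packaged recovery analyses run at the study's printed per-condition
trajectory counts (e.g. 37/56/36/46/44/26 trajectories across the
quench-time grid, 195 staircase recordings for unfolding kinetics, ~7
domains per trajectory); the detector benchmark uses 500 traces, the
stochastic/deterministic agreement check 10,000 domains, and K_d recovery
20 synthetic replicates. These sizes make the statistical checks sharp at
the stated tolerances while keeping a full run inexpensive.

## Known limitations

* The chaperone mechanism is a holdase partition: ATP cycling, GrpE
  nucleotide exchange and DnaJ → DnaK substrate hand-off are not modelled;
  a foldase effect can only be emulated generically through
  fold_competence / k_f0.
* Whether a bound extended chain may collapse while bound is an
  assumption (forbidden here), not a measured fact.
* Extension rendering is baseline + steps, not polymer elasticity.
* Single-exponential dwell models only; no model selection for
  heterogeneous kinetics.
* The dihedral module's basin scenario and bound-reference angles are
  synthetic stand-ins; measured ΔG magnitudes (e.g. a ~3 k_BT maximum at
  high force) require the original trajectory data and are not
  reproduced here.
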