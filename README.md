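# chapfold

Chaperone-modulated mechanical protein folding: kinetics, simulation and
analysis of single-molecule force-clamp experiments.

When a polyprotein (e.g. a ubiquitin nonamer) is held under constant force,
each domain unfolds in a discrete ~20-nm extension step. Dropping the force
to zero for a quench time *t*<sub>q</sub> lets domains collapse and refold;
restretching counts how many regained mechanical stability. Hsp40/Hsp70
chaperones (DnaJ, DnaK) intercept this cycle by binding specific substrate
conformations — DnaJ the mechanically extended chain (through a sequence
motif), DnaK·ADP the molten-globule-like collapsed state — and holding the
substrate unfolded. `chapfold` provides the computational machinery for this
experimental program, with a synthetic force-clamp generator standing in for
the instrument.

## The model

A domain occupies one of five states,
{folded, extended·free, extended·bound, collapsed·free, collapsed·bound},
with master equation dP/dt = Q(F) P. The generator Q switches with the
force regime:

* **pulse** (F > 10 pN): folded → extended·free at *k*<sub>u</sub>;
  collapsed → extended at *k*<sub>uc</sub> (bound/free preserved);
  extended·free ⇌ extended·bound at *k*<sub>on</sub><sup>ext</sup>·[C] and
  *k*<sub>off</sub><sup>ext</sup>;
* **quench** (F ≈ 0): extended·free → collapsed·free at *k*<sub>c</sub>;
  collapsed·free → folded at *k*<sub>f0</sub>; chaperone exchange on both
  extended and collapsed conformations.

Bound domains cannot fold, and a bound extended chain must release the
chaperone before collapsing. Because force protocols are piecewise
constant, propagation uses exact per-segment matrix exponentials, and the
stochastic twin (per-domain Gillespie simulation) agrees with it by
construction. Binding constants are estimated by χ² fits of predicted
refolding yields to measured (or simulated) yield curves across
quench-time, extended-time and force sweeps; each chaperone–conformation
pair then has a dissociation constant
*K*<sub>d</sub> = *k*<sub>off</sub>/*k*<sub>on</sub>.

Two further components round out the toolkit:

* **dihedral energetics** — the free-energy cost, at pulling force F, of
  remodeling the backbone dihedrals of the chaperone-binding fragment to
  their bound-state values, ΔG(F) = −Σ ln p<sub>F</sub>(φ\*, ψ\*) in
  k<sub>B</sub>T, estimated from (φ, ψ) samples (a von Mises mixture
  generator stands in for MD);
* **motif scanning** — the type-I Hsp40 consensus
  `G X [LMQ] {P} X {P} {CIMPVW}` and a sliding-window hydrophobicity
  heuristic for DnaK's five-residue Leu/Ile-rich target patches.

## Worked example

```python
import numpy as np
from chapfold import (KineticScheme, predict_yield_curve,
                      equilibrium_unbound_fraction, scan_dnaj_consensus)

ubi  = KineticScheme(k_u=0.93, k_c=10.0, k_f0=0.52, fold_competence=0.75)
dnaj = ubi.replace(k_on_ext=4.55e4, k_off_ext=4.28e-2, chaperone_conc=5e-6)

predict_yield_curve(ubi, [0.5, 1, 2, 5, 10, 15], vary="t_q")
# array([0.14 , 0.28 , 0.47 , 0.691, 0.746, 0.75 ])
```

The chaperone-free yield saturates at the 75% fold-competence plateau with
an effective ~0.5 s⁻¹ folding rate; at *t*<sub>q</sub> = 5 s it is ≈ 0.69.
Holding the unfolded chain extended for *t*<sub>ext</sub> seconds in 5 µM
DnaJ before the quench lets the chaperone bind and block refolding:

```python
predict_yield_curve(dnaj, [1, 2, 3, 5, 10, 15, 30], vary="t_ext", t_q_s=5.0)
# array([0.561, 0.472, 0.403, 0.312, 0.217, 0.192, 0.184])

equilibrium_unbound_fraction(9.4e-7, 5e-6)   # K_d, [DnaJ]
# 0.158  -> x 0.65 chaperone-free yield ~ 10% residual refolding

scan_dnaj_consensus("FAGKQLEDGRT", offset=45)
# [MotifMatch(seq_id='seq', start=47, end=53, match='GKQLEDG')]
```

The yield decays exponentially in *t*<sub>ext</sub> at
*k*<sub>on</sub>[C] + *k*<sub>off</sub> ≈ 0.27 s⁻¹ toward the equilibrium
residual; the ubiquitin sequence carries exactly one DnaJ consensus motif,
at positions 47–53. Fitting binding constants to yield curves follows the
statsmodels pattern — build a model from data, fit, read the results:

```python
from chapfold.fitting import ChaperoneBindingModel
model = ChaperoneBindingModel(curves, base_scheme,
                              free=("k_on_ext", "k_off_ext"))
print(model.fit(seed=0).summary())
# Chaperone binding kinetics: chi-square fit
# ==========================================================
# curves: 2   points: 13   free parameters: 2
# chi2 = 7.788   df = 11   converged: True
# ----------------------------------------------------------
# parameter               estimate   se(log10)
# k_on_ext               4.804e+04       0.036
# k_off_ext                0.05066       0.053
# ----------------------------------------------------------
# K_d(ext)               1.055e-06 M
```

(Here `curves` are synthetic yield curves generated at experiment-sized
trajectory counts from a scheme with K_d = 9.4 × 10⁻⁷ M; the fit recovers
it within ~12%.)

A command line wraps the same pipeline; each subcommand chain mirrors one
experiment type:

```bash
chapfold all -c examples/run.yaml -o results_run   # simulate + analyze + fit
chapfold scan FAGKQLEDGRT --offset 45
chapfold dihedral --seed 3 --forces 50,100,150,200,300
```

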