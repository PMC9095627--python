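# persist-circuits

Mechanistic models and flow-cytometry analysis for **cleavage-regulated RNA
circuits** — synthetic gene networks in which CRISPR Cas6/Cas13-family
endoribonucleases (endoRNases) act as RNA-level activators and repressors.

An endoRNase cleaves a short hairpin placed in a transcript's UTR. In the
**5' OFF position**, cleavage decapitates the transcript and destroys
expression; in the **3' ON cassette** (stabilizer – hairpin – degradation
repeats), cleavage removes the degradation tags and rescues expression.
Because the same enzyme can do both at once, compact circuits — cascades,
feed-forward loops, all 16 two-input Boolean gates, and a two-node toggle —
can be built from a small orthogonal enzyme set.

The package is aimed at people modelling such circuits or validating
poly-transfection cytometry analyses. It provides:

* `persist.registry` — the nine-enzyme catalogue (4× Cas6: Csy4, Cse3,
  CasE, Cas6; 5× Cas13: LwaCas13a, PspCas13b, PguCas13b, RanCas13b,
  RfxCas13d), their hairpins (including the CasE-resistant Cse3* mutant)
  and the cross-reactivity matrix.
* `persist.model` — steady-state/ODE kinetics of regulated transcripts.
  Each transcript has an uncut species *U* and a stabilized species *S*:

  dU/dt = αc − (d₀ + d_fast(n) + k_on + k_off)·U
  dS/dt = k_on·U − (d_slow + k_off)·S

  with saturating cleavage k = a·v_rel·v_max·E/(K+E) in the enzyme level
  E, and proteins P following kp·(U+S) − d_p·P.
* `persist.gates` — constructions and simulation-based verification of all
  16 Boolean functions under one shared 10-fold threshold band.
* `persist.synthetic` — a poly-transfection event generator
  (zero-inflated lognormal uptake, intra-complex copy correlation,
  spectral bleed-through, autofluorescence, multiplicative noise).
* `persist.pipeline` — compensation from single-color controls, positive
  gating, log-binning, slope fits, normalized fold change, Michaelis–Menten
  fits, logic calls, bistable quadrant fractions, ±TSA induction ratios.
* a `persist` CLI (`simulate`, `analyze`, `gates`, `toggle`, `fixtures`).

## Worked example

```python
from persist import default_registry, deg_ladder, ModelParams
from persist.gates import enumerate_gates
from persist.experiments import panel_fold_changes, triplex_rescue_fold

registry = default_registry()
params = ModelParams()

print(deg_ladder([0, 8, 30], params))
df, n_pass, n_single = enumerate_gates(registry, params)
print(n_pass, "of 16 gates pass;", n_single, "are single-transcript")
panel = panel_fold_changes()
print(panel[["enzyme", "off_fold", "on_fold"]].head(3).round(1))
print("RNase-P rescue fold:", round(triplex_rescue_fold(), 1))
```

prints

```
{0: 1.0, 8: 12.000000000000002, 30: 351.0}
16 of 16 gates pass; 10 are single-transcript
  enzyme  off_fold  on_fold
0   Csy4    3070.3    630.1
1   Cse3    2855.5    625.2
2   CasE    2978.2    628.1
RNase-P rescue fold: 166.0
```

Reading: thirty degradation-motif repeats reduce reporter output 351-fold;
every Boolean function verifies against its truth table under the shared
band, ten of them with a single engineered transcript; Csy4 is the
strongest repressor in the panel; and adding a constitutively cleaved
RNase-P site in front of the degradation tags rescues expression 166-fold.

A full synthetic experiment:

```sh
persist simulate --seed 7 --out run/     # toggle events + controls
persist toggle --seed 7 --out toggle.csv # fixed points + quadrant report
persist gates --out gates.csv            # 16-row truth-table report
```

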