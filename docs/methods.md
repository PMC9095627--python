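# Methods

## Transcript model

Every engineered transcript is a two-species scheme. The uncut mRNA *U* is
produced at `alpha * copies` (a.u./h) and lost to: baseline decay `d0`;
degradation-repeat decay `d_fast(n)` when the transcript carries a 3' ON
cassette with `n` wt1 repeats; ON-site cleavage `k_on`, which *converts* U
into the stabilized species *S*; and 5'-site cleavage `k_off`, which
destroys the transcript outright. S exists only for ON-cassette
transcripts, decays at the slow rate `d_slow` (the stabilizer protects the
cleaved 3' end), and is still destroyed by 5' cleavage — a 5' cut
decapitates cleaved and uncut transcripts alike, which is what makes
dual-regulated (NIMPLY-style) transcripts work. Both species translate at
`kp`; proteins decay at `dp`, or `dp_pest` for PEST-tagged payloads
(intermediates regulated by another enzyme are always PEST-tagged so that
layered circuits settle within the experiment).

Cleavage of one site by one enzyme at protein level `E` proceeds at

    k = activity * vmax_rel * vmax * E / (K + E)

— first order (Michaelis) in the enzyme, scaled by the cross-reactivity
fraction `activity` (1 for cognate pairs). Rates from several enzymes or
several sites add. The constitutive RNase-P site adds a fixed `k_rnasep`
to `k_on`.

Acyclic circuits are solved in closed form (the enzyme-level dependency
graph is a DAG, so damped fixed-point iteration lands exactly after one
pass per layer); feedback circuits go through the ODE integrator (LSODA,
rtol 1e-8) or, per-cell and vectorized, through an RK4 scheme with mRNA at
quasi-steady state — mRNA relaxes in minutes against the hours-long
protein scale, and the tests pin the ODE endpoint to the closed form at
1e-6 relative on acyclic circuits.

## Default calibration

Units are arbitrary (a.u. protein; copies; hours). Defaults live in
`src/persist/data/default_config.yaml`:

| parameter | default | meaning |
|---|---|---|
| `d0` | 0.1/h | plain mRNA decay (≈7 h half-life) |
| `d_slow` | 0.05/h | decay of the stabilizer-protected species |
| `d_fast` knots | 0/0.3/1.1/6/35 at n=0/4/8/16/30 | repeat-count ladder |
| `kp`, `dp`, `dp_pest` | 1, 0.1, 0.5 | translation; fluorophore/PEST decay |
| `vmax`, `K` | 310/h, ~1000 a.u. | cleavage capacity and half-saturation |
| `k_rnasep` | 10.805/h | constitutive RNase-P cleavage |

The ladder knots put the 30-repeat reduction at 351-fold. `k_rnasep` is
solved in closed form so the triplex/RNase-P rescue ratio
`(D/(D+r))·(1+r/d_slow)` equals 166 at `D = d0 + d_fast(30)`.

`vmax` deserves a comment. With Michaelis cleavage the coherent
feed-forward loop's dynamic range has a hard ceiling: writing the input
enzyme's repression fold as `F = 1 + vmax_E/d0`, the cFFL fold can never
exceed `F` (the intermediate's protein swing *is* `F`, and the
reporter-side gains telescope against it). Reaching the ≥1000-fold cFFL
range therefore forces `F ≳ 2500`, i.e. OFF-repression folds of a few
thousand rather than a few hundred. We calibrate to the composite-device
range and accept inflated single-switch folds; all single-switch checks
are one-sided (at least 300-fold OFF, at least 100-fold ON), which the
calibration satisfies.

## A provable limit: the two-node toggle is monostable

The mutual-repression + self-ON-activation toggle cannot be bistable under
these kinetics, for any parameter values. At the symmetric fixed point the
destabilizing eigenvalue of the enzyme-level return map reduces
analytically to

    lambda = sigma_f * k_on / (d_slow + k_on),   sigma_f = K/(K+E) <= 1

which is strictly below 1 — the degradation-ladder terms cancel exactly.
Multi-site variants change the algebra but the supremum is still exactly 1
(for m parallel sites the two contributions sum to 2/(m+1) + (m-1)/(m+1)),
and pure cross-repression (whose double hit on U and S looks Hill-2-like)
also sups at 1. A numeric scan over repeats × copies × K × d_slow
confirms a 0.975 plateau and zero bistable combinations. Real toggles of
this architecture presumably lean on ultrasensitivity the first-order rate
law excludes — enzyme–substrate sequestration or zero-order effects. We
keep the rate law as specified and report the consequences honestly: the
fixed-point solver finds one stable state for the default toggle, and the
generated-event state exclusivity saturates near 94% rather than 97%
(balanced-ratio cells settle in a partially repressed mixed state; the
rest of the gap is compensation-noise leakage of the 5% EYFP→mKO2 bleed
under 25% measurement CV).

## Synthetic data generator

The generator reproduces the statistics the pipeline relies on, nothing
more: per-complex Bernoulli(0.6) transfection × lognormal dose (ln-σ 1.2),
within-complex lognormal jitter tuned to a 0.95 log-copy correlation
(markers track payloads), steady-state rendering at 48 h, linear
bleed-through (5% EYFP→mKO2, 2% mKO2→EYFP, 1% tagBFP→EYFP as
placeholders), lognormal autofluorescence (channel medians ~25–50 a.u.)
and 25% multiplicative measurement CV. One master seed deterministically
spawns per-stage streams. Not modelled: doublets/debris, scatter gating,
detector saturation, acquisition drift, cell-cycle or extrinsic expression
noise. Passing tests therefore show estimator correctness under the
assumed noise structure, not robustness to instrument pathologies.

## Pipeline choices

* **Compensation** — spillover per fluorophore is the median of bright-cell
  secondary/primary ratios (background-median subtracted, brightest two
  decades anchored at the 99.5th percentile). A least-squares slope is
  attenuated ~1/(1+cv²) by measurement noise on the primary channel; the
  ratio median is unbiased under symmetric multiplicative noise and
  recovers planted bleed within ~2%. Unmixing is multiplication by the
  inverse mixing matrix; negative unmixed values are kept.
* **Gating** — positive threshold at the 99.9th percentile of the
  compensated untransfected table, per channel.
* **Binning** — 20 log-spaced bins over the positive marker range, bins
  with <20 cells dropped; the reported shading statistic is the maximum
  over bins of the per-bin IQR.
* **Fold change** — linear-scale OLS (free intercept) of output on marker
  over gated cells; normalized fold is the site-pair slope ratio divided by
  the no-site-pair slope ratio, reciprocal convention for activation.
  Raw cells are fitted; bin medians are kept for reporting only.
* **Saturation fits** — `baseline + vmax·x/(K+x)` on bin medians,
  multi-start in K from the binned-range quartiles; a K̂ beyond the data
  range sets an uncertainty flag instead of pretending precision.
* **Logic calls** — outputs normalized to the larger of the gate's own
  maximum and a constitutive-reporter reference, then called against the
  shared band (10^-1.5, 10^-0.5). The reference matters for the FALSE
  gate, whose four conditions are all dim: self-normalization alone would
  promote its noise floor to 1.
* **Bistability classification** — per-channel thresholds at the geometric
  midpoint between background median and the single-node control's 95th
  percentile; quadrant fractions over double-positive (both markers) cells.

## Gate library

Single transcripts realize conjunctions of negated literals (5' sites) AND
a disjunction of positive literals (ON sites) — exactly ten functions:
TRUE, FALSE, A, B, NOT A, NOT B, OR, NOR and both NIMPLYs (FALSE is an ON
cassette with no sites, i.e. constitutively degraded). The other six route
composite terms through the Cse3 intermediate read via the CasE-resistant
Cse3* hairpin: two 5'-gated Cse3 transcripts give NAND at the enzyme
level, whence AND (inverted readout) and NAND; two NIMPLY-shaped Cse3
transcripts give XOR, whence XNOR; one NIMPLY-shaped Cse3 gives the
implications. Intermediates are dosed low (3 copies vs 100 for the
reporter) so the degraded-intermediate leak cannot drag ON conditions into
the gray band; all 16 margins stay above 1.5-fold.

## Known limitations

* Calibration trades single-switch realism for composite-device range (see
  above); absolute a.u. are not mapped to any instrument.
* The toggle's deterministic bistability target is unattainable under the
  specified rate law (proof sketch above); exclusivity tops out near 94%.
* The generator's uptake dispersion and transfected fraction are
  conventions, not measurements; the config marks them as placeholders.
* Off-target activities beyond the three documented cross-reactive pairs
  are zero placeholders pending quantitative data.
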