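# Default calibration and study conditions.
#
# Keys marked [anchored] reproduce magnitudes reported for the platform
# (degradation-ladder fold, RNase-P rescue fold, enzyme orthogonality
# structure).  Keys marked [placeholder] are conventions chosen to give
# realistic cytometry-like data; they are not measured quantities.

registry:
  # vmax_rel: cognate cleavage capacity relative to the strongest enzyme
  # (Csy4); ordering keeps Csy4 a slightly stronger repressor than CasE.
  # K: enzyme half-saturation level in protein a.u.  [placeholder ordering,
  # anchored at the top by the calibrated dynamic ranges]
  enzymes:
    Csy4:       {family: Cas6,  vmax_rel: 1.00, K: 1000.0, pest_available: true}
    Cse3:       {family: Cas6,  vmax_rel: 0.93, K: 1000.0, pest_available: true}
    CasE:       {family: Cas6,  vmax_rel: 0.97, K: 1000.0, pest_available: true}
    Cas6:       {family: Cas6,  vmax_rel: 0.55, K: 1500.0, pest_available: false}
    LwaCas13a:  {family: Cas13, vmax_rel: 0.60, K: 1200.0, pest_available: false}
    PspCas13b:  {family: Cas13, vmax_rel: 0.70, K: 1000.0, pest_available: false}
    PguCas13b:  {family: Cas13, vmax_rel: 0.65, K: 1200.0, pest_available: false}
    RanCas13b:  {family: Cas13, vmax_rel: 0.60, K: 1200.0, pest_available: false}
    RfxCas13d:  {family: Cas13, vmax_rel: 0.75, K: 1000.0, pest_available: false}
  # One cognate hairpin site per enzyme, plus the Cse3* U5A mutant hairpin
  # whose cognate enzyme is still Cse3 but which CasE cannot cleave.
  sites:
    Csy4-site:      {cognate: Csy4,      description: wild-type Csy4 hairpin}
    Cse3-site:      {cognate: Cse3,      description: wild-type Cse3 hairpin (also cleaved by CasE)}
    Cse3star-site:  {cognate: Cse3,      description: U5A mutant hairpin, CasE-resistant}
    CasE-site:      {cognate: CasE,      description: wild-type CasE hairpin}
    Cas6-site:      {cognate: Cas6,      description: wild-type Cas6 hairpin}
    LwaCas13a-site: {cognate: LwaCas13a, description: LwaCas13a direct repeat}
    PspCas13b-site: {cognate: PspCas13b, description: PspCas13b direct repeat}
    PguCas13b-site: {cognate: PguCas13b, description: PguCas13b direct repeat}
    RanCas13b-site: {cognate: RanCas13b, description: RanCas13b direct repeat}
    RfxCas13d-site: {cognate: RfxCas13d, description: RfxCas13d direct repeat}
  # Off-target activities as fractions of cognate capacity.  Only the three
  # documented cross-reactive pairs are nonzero; the full quantitative
  # off-target landscape is otherwise unpublished, so remaining entries are
  # zero.  [structure anchored; magnitudes placeholder]
  off_target:
    - {enzyme: CasE,      site: Cse3-site,      activity: 0.8}
    - {enzyme: RanCas13b, site: PguCas13b-site, activity: 0.5}
    - {enzyme: PguCas13b, site: RanCas13b-site, activity: 0.5}

model:
  d0: 0.1          # baseline mRNA decay, 1/h (half-life ~7 h)
  d_slow: 0.05     # decay of the cleaved, stabilizer-protected species, 1/h
  kp: 1.0          # translation, protein a.u. per mRNA a.u. per h
  dp: 0.1          # fluorophore decay/dilution, 1/h
  dp_pest: 0.5     # PEST-tagged payload decay, 1/h
  vmax: 310.0      # maximal cognate cleavage rate at enzyme saturation, 1/h
                   # [anchored: calibrated so the coherent-FFL dynamic range
                   #  reaches its reported magnitude; see docs/methods.md]
  k_rnasep: 10.805 # constitutive RNase-P cleavage of the mascRNA site, 1/h
                   # [anchored: yields the reported 166-fold rescue]
  # Degradation added by n repeats of the wt1 motif, 1/h, piecewise-linear
  # through these knots.  [anchored at n=30: >300-fold ladder reduction]
  d_fast_knots:
    0: 0.0
    4: 0.3
    8: 1.1
    16: 6.0
    30: 35.0
  alpha_default: 1.0   # transcription per plasmid copy, a.u. mRNA/h/copy
  t_end: 48.0          # endpoint, h

uptake:
  # Zero-inflated lognormal plasmid uptake per complex.  [placeholder;
  # transfected fraction and dispersion are not reported]
  p_transfected: 0.6
  log_mu: 4.0        # natural-log median total copies per complex (~55)
  log_sigma: 1.2
  rho_within: 0.95   # intra-complex log-copy correlation

spectral:
  channels: [tagBFP, EYFP, mKO2, iRFP720]
  # fluorophore -> channel mixing, diagonal 1.  [placeholder]
  bleed:
    - {source: EYFP, channel: mKO2, value: 0.05}
    - {source: mKO2, channel: EYFP, value: 0.02}
    - {source: tagBFP, channel: EYFP, value: 0.01}
  autofluor_mu: {tagBFP: 3.9, EYFP: 3.7, mKO2: 3.5, iRFP720: 3.2}  # ln a.u.
  autofluor_sigma: 0.35
  cv_meas: 0.25      # multiplicative measurement noise CV

analysis:
  n_bins: 20
  n_min: 20
  positive_percentile: 99.9
  threshold_band: [0.0316227766016838, 0.316227766016838]  # 10-fold gray region
  cffl_eval_marker: 10000.0

toggle:
  # Two-node toggle: each node's enzyme carries the other's hairpin in its
  # 5' UTR and its own hairpin in its 3' ON motif (30 repeats, PEST), and a
  # co-delivered reporter carries the opposing enzyme's 5' hairpin.
  enzymes: [Csy4, Cse3]
  reporters: [EYFP, mKO2]
  markers: [tagBFP, iRFP720]
  deg_repeats: 30
  copies_median: 40     # median plasmid copies per node plasmid
  reporter_alpha: 8.0   # strong constitutive promoter on the state reporters
  marker_alpha: 1.0
  n_events: 10000
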