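# Methods

This note documents the models, parameter choices and numerical conventions
behind `grinvar`, and what the synthetic-data validation does and does not
establish about real recordings.

## Assay models

**Concentration–response (dose_response).**  Agonist activation follows the
Hill equation `R(%) = 100/(1 + (EC50/c)^N)`; inhibition follows
`R(%) = (100 − min)/(1 + (c/IC50)^N) + min` with the residual response
`min` constrained non-negative (a saturating open-channel blocker can leave
a small residual current).  Fits are parameterized in log10 potency, and the
95% CI is the normal (z-based) interval on log10 EC50/IC50,
back-transformed — so intervals are multiplicative/asymmetric, matching the
convention in which potencies are summarized.  Composite fits pool all cells
of a construct after normalizing each cell to its own fitted maximum (a free
amplitude absorbs any residual normalization error in the pooled fit, which
otherwise biases EC50 upward by a few percent).  An alternative raw-pooled
mode (`normalize=False`) is available.  Significance between constructs is
CI non-overlap, the primary rule for potency columns; ANOVA-style flags can
be supplied externally but are not re-derived.

**Deactivation kinetics (kinetics).**  The decay after agonist removal is a
sum of two exponentials; the decay segment starts one sample interval after
the end of the application window (solution-exchange dead time is not
modelled).  Numerical conventions:

- initial time scale from the 1/e crossing of the decay; components seeded
  at 0.5× and 3× that scale;
- a degenerate pair (τ values within 5%, or one amplitude below 10⁻³ of the
  total) is collapsed to a single exponential, whose τ is then reported as
  τ_w — unidentifiable amplitude splits are never reported;
- component order is canonicalized to τ_fast ≤ τ_slow after fitting;
- a response whose smoothed peak (5-sample moving average, so one noisy
  sample cannot cross the bar) is below 3 baseline SDs is reported
  `too_small` rather than fitted, mirroring how tiny currents are handled in
  practice;
- weighted τ is the amplitude-weighted mean and is by construction a convex
  combination of the two time constants.

Rise time is the linear-interpolated 10–90% interval of the onset; the
desensitization extent of prolonged applications is `1 − steady/peak` with
the steady state taken over the final 10% of the application window.

**Open probability (channel_props).**  `P_open = γ_ratio / Potentiation`
with γ_ratio = 0.67 by default (a parameter, not a constant, since the
conductance ratio is an empirical estimate for cysteine-substituted
GluN1/GluN2A receptors).  Pairs with potentiation ≤ 1 are flagged
`no_potentiation` — MTSEA failing to lock the channel open is information,
not a probability of zero.  Estimates above 1 are flagged inconsistent but
returned.  Variants adjacent to the reporter cysteine can confound this
assay; the module reports values and flags, it does not adjudicate.

**Surface expression.**  Reporter absorbance ramps are linear over the
30-minute read; slopes come from ordinary least squares over the full
window, background (mock-transfected) slopes are subtracted before
ratioing, and the construct's surface/total ratio is normalized to the
same-day wild-type ratio — making the measure invariant to plate-wide gain
and pinning the WT self-ratio at 1.

**Permeability screen (permeability).**  Reversal potentials are
interpolated linearly between the two voltage steps bracketing the
zero-current crossing (no polynomial I–V model: the step protocol is
15 mV-spaced and a local chord is adequate); multiple crossings in noisy
families use the one nearest 0 mV, flagged.  The screen threshold ±3.4 mV is
the 99% confidence half-width of the wild-type Ba²⁺ shift computed with the
normal quantile (2.576 × SEM 1.3 mV ≈ 3.35; Student's t at n = 15 would give
3.9 and is inconsistent with the stated threshold, so z is used).  The
−6 mV junction-potential shift predicted for the Ba²⁺ solution is left
uncorrected, because the threshold was derived under that same convention.

**Charge transfer and classification (classify).**  The synaptic composite
multiplies the τ_w, P_open, surface, R_GLY (3 µM glycine), R_GLU (1 mM
glutamate) and Mg-inhibition (1 mM) variant/WT ratios; the non-synaptic
composite drops τ_w and evaluates R_GLU at 0.1 µM, the ambient extracellular
glutamate regime.  R terms use each construct's fitted Hill slope; when no
slope is available (as in the tabulated panel, which prints potencies only)
N = 1 is assumed with a logged warning.  The Mg term is computed from the
fitted IC50 via percent inhibition at 1 mM when raw inhibition is absent.
Ledger display convention: agonist potencies as WT/variant EC50, all other
assays variant/WT, so fold > 1 always supports gain of function.

Confidence grading: a significant change of ≥2-fold (either direction) is
high confidence, a smaller significant change moderate.  The 2-fold cutoff
is this package's documented approximation — the upstream grading scheme's
exact cutoffs are not published in a reusable form — and is exposed in
`PipelineConfig.high_conf_fold`.

Decision order (fixed, total): (1) deactivation unmeasurable from tiny
currents with all other assays complete → `Indeterminant*`; (2) unanimous
vote direction → GoF or LoF; (3) otherwise, two suprathreshold composites
(outside [0.4, 2.5]) in opposite directions → `Indeterminant`; else a
composite > 2.5 rescues to `Possible GoF`, < 0.4 to `Possible LoF`;
(5) else `no change`.  The conflict check deliberately precedes the rescue.

**Fold-change regressions.**  Variants with EC50 ≤ 30 nM are excluded
(trace agonist contamination at tens of nanomolar distorts such potencies).
The τ_w-vs-EC50 regression uses all backgrounds by default (a
`backgrounds` filter is exposed because the inclusion set is genuinely
ambiguous).  For the glycine/glutamate relation the default orientation
regresses the glutamate fold on the glycine fold with both potencies above
the floor — the orientation under which the panel shows its reported
steeper-than-unity coupling — with the transpose behind a flag.  On the packaged panel the
defaults give slope −0.85 / r² 0.76 (τ_w vs glutamate potency; the intercept
is sensitive to which pooled WT τ reference is used and is not a validated
quantity) and slope 1.21 / r² 0.91 (glutamate vs glycine fold).

**EC50/P_open coupling.**  `ec50_po_relation` is a deliberately simple
two-state stand-in: binding (Kd) followed by a gating equilibrium E gives
EC50 = Kd/(1+E) = Kd·(1−p) with p = E/(1+E).  It encodes only the
qualitative fact that stronger gating lowers apparent EC50 and is labelled
as such; it is not a fitted kinetic scheme.

**3DMTR (mtr3d).**  Score =
`[obs_mis/(obs_mis+obs_syn)] / [exp_mis/(exp_mis+exp_syn)]` over a window of
the central residue plus its k = 30 nearest resolved residues, distances
between α-carbons (the representative atom is a package choice; any single
point per residue works).  Windows pool counts before the ratio; averaging
per-residue ratios is available behind `method="mean_ratio"`.  Ties in
distance break lexicographically by (distance, chain, index) so windows are
fully deterministic.  Chain termini with fewer than 31 resolved residues get
reduced windows, flagged.  Residue-numbering reconciliation between
structure and transcript coordinates is the caller's responsibility (counts
must be supplied on the structure's numbering); no automatic alignment is
attempted.  Obtaining and modelling population variant counts (e.g. from
gnomAD) is out of scope — counts are an input.

## Synthetic data: what it emulates and what it does not

The generator produces, per construct: 9-point half-log concentration series
spanning 0.01–100× the potency (the acquisition series is a package default;
real protocols vary); biexponential decays with a single-exponential onset
(10–90% rise 5 ms for brief 6 ms applications — onset shape is cosmetic, the
decay carries the information); paired control/MTSEA currents; linear-chord
I–V families at the −90…+30 mV step protocol with a configurable Ba²⁺
reversal shift; and linear absorbance ramps.  All noise is seeded and
mean-one: lognormal multiplicative on steady-state responses and
potentiation ratios (applied so the implied per-pair P_open is unbiased),
lognormal cell-to-cell scatter on kinetic parameters and peaks, additive
Gaussian on trace samples and I–V currents.

Noise defaults are calibrated against the tabulated wild-type uncertainties
at the tabulated cell counts:

| knob | default | calibration |
|---|---|---|
| `cr_noise_cv` | 0.06 | composite-fit EC50 sd at n = 113 equals the CI-implied sd (≈0.05 on 3.5 µM) |
| `noise_cv` | 0.20 | per-cell scatter of P_open and peaks (CV 0.18–0.3 implied by the tabulated SEMs) |
| `tau_cell_cv` | 0.25 | per-cell τ_w scatter (the tabulated SEMs imply CV 0.30 / 0.22 on the two WT backgrounds) |
| `baseline_sd` | 2 pA/pF | ~1% of the WT peak |
| `iv_noise_sd` | 0.015 nA | single-family reversal resolution ≈0.6 mV |

Two deliberate simplifications.  First, the Mg²⁺ IC50 CI of a simulated
113-cell panel is tighter than the tabulated one — day-to-day variability
between recording sessions is not modelled.  Second, the I–V noise reflects
instrumentation only; the tabulated WT shift SEM (1.3 mV at n = 15) implies
cell-level scatter at which a ±4 mV difference between 15-cell panels cannot
be detected with 95% reliability at all — with that scatter the ±3.4 mV
threshold is precisely the detection limit, which is why it exists.  A
`vrev` jitter can be added per profile to study that regime; the default
screen validation runs at instrumentation noise.

Consequently, passing tests show that the estimators are unbiased and
correctly propagate uncertainty under the stated noise model — not that the
model captures every failure mode of oocyte or HEK-cell recordings
(rundown, series-resistance error, solution-exchange artifacts, day
effects).  Wild-type presets encode the tabulated panel values exactly
(EC50 3.5/1.2 µM, IC50 19 µM, P_open 0.24, τ_w 44 ms via 0.8·30 + 0.2·100;
GluN2B: 1.2/0.39 µM, 22 µM, 0.033, 524 ms via ⅔·262 + ⅓·1048); Hill slopes
are not tabulated, so presets use N = 1.2 (agonists) and N = 1.0 (Mg²⁺),
typical for these receptors.

Validation panel sizes mirror the tabulated per-assay cell counts (113
cells for potencies, 37/26 traces, 122/84 MTSEA pairs), so tabulated-CI and
2-SEM recovery bands are properly powered; the acceptance script uses the
smaller 12- and 20-cell panels of its stated setups.

## Known limitations

- Per-variant Hill slopes are unprinted in the tabulated panel; with the
  N = 1 fallback the charge-transfer composites recomputed from potencies
  alone do not exactly reproduce the tabulated composite columns (the
  tabulated columns are therefore shipped as data, and threshold counting
  operates on them).
- Voltage dependence of Mg²⁺ block is not modelled; IC50s are per holding
  potential, carried as metadata.
- Triheteromeric receptors (one variant copy) are out of scope; all
  profiles describe two-variant-copy diheteromers.
- The classifier's confidence cutoffs are an approximation (above); the
  GoF/LoF direction logic and the decision order are exact.
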