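# Methods

## The analysis problem

Dissociated sputum is a difficult cytometry matrix: a large share of events
are debris, cell aggregates, or dead squamous epithelial cells (SECs) from
the oral cavity, and SECs are both large and strongly autofluorescent, so
they cannot be removed by scatter gating alone.  The pipeline therefore
leans on three controls rather than manual gates: a bead run fixes the
scatter window, the unstained tube fixes the viability and CD45 cutoffs,
and fluorescence-minus-one (FMO) tubes fix every antibody positivity
threshold.  Dead-cell exclusion via the viability stain is what removes
SECs; scatter is deliberately not used for that purpose.

## Gating model

**Size gate.** A rectangle on (FSC-A, SSC-A).  The FSC bounds come from the
bead run: 1st percentile of the 5 µm cluster to 99th percentile of the
30 µm cluster, bracketing intact cells of interest while cutting small
debris and large aggregates.  Bead clusters are found by deterministic 1-D
k-means on log FSC-A with quantile initialization; calibration fails if a
requested diameter's cluster is missing or clusters are not separated by at
least four within-cluster log-SDs.  The SSC upper bound excludes the
instrument's top ADC channel (2^18), where aggregates saturate.

**Singlet gate.** FSC-H/FSC-A within median ± k·MAD, k = 4, estimated on
the events inside the size gate.  Doublets carry roughly the summed area of
two cells but a pulse height near the larger one, so their ratio falls far
below the singlet band.  The MAD is floored at 1e-6 of the median so a
degenerate (constant-ratio) input retains all events.

**Thresholds.** Every positivity threshold is the q = 0.9995 quantile of the
appropriate control subset (configurable).  This stringency reproduces
background rates on the order of a few events per 10^5 — the scale of
reported FMO backgrounds — while remaining estimable from 10^4–10^5 control
events.  Viability and CD45 cutoffs come from the unstained tube's live
singles; CD206 from the CD206-FMO tube's CD45+ events; the
granulocyte/lymphocyte cocktail from the cocktail-FMO tube's CD45+ CD206−
events (macrophage FITC autofluorescence would otherwise contaminate the
background estimate); EpCAM and panCK from their FMO tubes' CD45− events.

**Macrophage subgates.** Within CD45+: gate 1 (granulocytes/lymphocytes) is
cocktail-positive and CD206-negative; gate 2 (alveolar macrophages) is
CD206-bright and above the FITC threshold (their constitutive
autofluorescence); gate 3 (interstitial macrophages) is CD206-intermediate
and FITC-negative.  The intermediate/bright boundary is the midpoint of the
two component means of a 2-component Gaussian mixture fitted to CD206+
events on the transformed scale (fixed random state, deterministic).  When
fewer than 50 CD206+ events exist, the components are closer than 0.8
transformed units, or a component weight falls below 0.1, the boundary
falls back to the FMO threshold plus 1.5 transformed units and the result
is flagged.

**Tie-breaking.** All gate bounds are half-open `[lo, hi)`, so an event on a
boundary belongs to exactly one side and exhaustive sibling partitions
conserve counts exactly.

## TCPP stratification

Live single events are split into LOW / INTERMEDIATE / HIGH porphyrin
strata on the arcsinh scale.  Both densities are Gaussian KDEs with
Silverman bandwidth, evaluated by binning onto a 512-point grid and
convolving with the kernel (equivalent to the exact KDE to well below the
grid step, at linear cost).  The LOW boundary is where the unstained
overlay's density crosses under the stained sample's, searched between the
unstained mode and the stained sample's main mode.  The HIGH boundary is
the density valley between the stained sample's main mode and its uppermost
well-separated mode (peak prominence ≥ 2% of the maximum, separation ≥ 0.8
transformed units); when no upper mode exists the 99.5th percentile of the
stained sample is used and flagged.  The main mode is defined as the
highest peak at least 0.8 units below the uppermost peak — not the global
argmax — so samples in which the TCPP-bright cluster happens to be densest
are still stratified correctly.  Degenerate overlays (stained and unstained
densities agreeing within 15% of peak height everywhere) put the LOW cut at
the common mode; a failed crossing search with separated modes falls back
to the unstained 0.9995 quantile, flagged.  `low < high` is enforced, and
strata partition live singles exactly by construction.

Strata are derived per sample and per tube from that sample's own unstained
control (the alternative — cohort-common cuts — would couple samples run on
different days).  Per-stratum metrics are reported only when the relevant
subset holds at least 25 events; below that, medians and MFIs are too
unstable and the value is NaN.  The unstained tube cannot be viability
gated (it carries no viability stain), so its TCPP reference population is
its size-gated singlets.  The TCPP-high SSC median and leukocyte-side
stratum metrics are read from the leukocyte tube, epithelial-side metrics
(quadrants, EpCAM/panCK MFI) from the epithelial tube.

## Adequacy QC

Four inclusive rules, all configurable, defaulting to: pre-stain cell count
≥ 1.5×10⁶; CD45+ events ≥ 1000 (leukocyte tube); combined alveolar +
interstitial macrophages ≥ 0.05% — five per 10,000 — of live single events;
and at least one alveolar macrophage event, since interstitial macrophages
without alveolar ones do not establish lung origin.  The macrophage
percentage's denominator is live single events (a per-analyzable-cell
reading); a CD45+ denominator is available as an option.  The
background-derived alternative (FMO mean + 2 SD) is computed but not used
as the default rule, matching practice: it lands near 0.0065%, too close to
the detection floor of the CD206 fluorochrome's linear range.  Report
percentages round half-up to one decimal.

## Cohort statistics

Per-sample metrics are compared with the two-sided Mann-Whitney U test:
exact enumeration when both groups have ≤ 20 samples and no ties, otherwise
the tie-corrected normal approximation; an all-constant metric reports
p = 1 directly.  A Welch t-test is available behind a flag.  No multiple
testing correction is applied by default (the panel is exploratory and each
row is interpreted on its own); Benjamini-Hochberg is available behind a
flag.  Group summaries report both mean and median; the row's direction is
read from medians, falling back to means on ties.  The fixed panel compares
cancer vs high-risk on the CD45+ fraction, gates 1 and 3, the three TCPP
stratum fractions, the TCPP-high SSC median, the TCPP-high CD45−
EpCAM+panCK+ fraction and that subset's EpCAM and panCK MFI; plus Stage
I/II vs III/IV EpCAM MFI within cancer and current vs former smoker
contrasts (EpCAM+panCK+ fraction, alveolar and interstitial percentages)
within high-risk.

## Synthetic data model

The generator is a mixture of eight populations — debris, SEC,
granulocytes/lymphocytes, alveolar macrophages, interstitial macrophages,
EpCAM+panCK+ epithelial cells, marker-negative epithelial cells, and a
TCPP-dim CD45− remainder — with log-normal marker intensities per
population (the standard cytometry stand-in), bivariate normal scatter, and
FSC-H = FSC-A × (0.95 + N(0, 0.02)).  Doublets (3% by default) sum the
scatter and fluorescence of two mixture draws with FSC-H set to the pair
maximum.  Dead populations (SECs) draw FVS510 around 2×10⁴ against a live
autofluorescence baseline around 60, exceeding any live-derived threshold
in ≥ 99% of events.  Alveolar macrophages are CD206-bright (~2×10⁴) and
FITC-autofluorescent (~3×10³); interstitial macrophages CD206-intermediate
(~1.5×10³) without the autofluorescence.  TCPP is bright in alveolar
macrophages and EpCAM+panCK+ cells, broad in marker-negative epithelial
cells, and near baseline in the CD45− remainder — which is what gives the
stained TCPP density its low/main/upper three-mode structure.  Every event
carries its true population code in an extra `truth_label` channel that the
analysis never reads, so gates can be scored for precision and recall.

A typical high-risk sample is 12% debris, 18% SEC, with 38.95% of live
cells CD45+ (52/37/11% gates 1/2/3) and 22% of CD45− cells EpCAM+panCK+.
The cancer composition raises CD45+ to 49.64%, gate 1 to 62% and gate 3 to
20%, raises the EpCAM+panCK+ fraction to 38% with a +0.5 log-unit EpCAM
shift, and scales the TCPP-bright populations' SSC by 0.72.  Between-sample
variation is logit-normal on all fractions (SD 0.30), normal on log
intensity locations (SD 0.12) and log-normal on the SSC scale (SD 0.06);
these dispersions are calibrated so that the configured group means are
detectable by Mann-Whitney at the study's 32-vs-132 group sizes in well
over 80% of replicate cohorts.  Current smokers in the high-risk group get
logit shifts of +0.8/+0.7/+0.8 on the alveolar, interstitial and
EpCAM+panCK+ fractions; within cancer, Stage I/II (III/IV) shifts the EpCAM
location by +0.3 (−0.3).  Smoking status is drawn at 40.6%/44.7% current
(cancer/high-risk) and cancer stage at 14:14:4 odds for I-II : III-IV :
unknown.  Pre-stain cell counts are log-uniform on [2×10⁶, 4×10⁷].

What the generator does **not** emulate: spectral spillover and
compensation, acquisition-time drift, carryover, batch effects between
instrument sessions, non-log-normal heavy tails, and any real biological
correlation structure beyond the configured group/covariate shifts.  The
synthetic TCPP-bright stratum is also far larger (~25% of live singles)
than a typical clinical sample's upper tail, which makes stratum metrics
estimable at test-scale event counts.  Passing tests therefore demonstrate
that the pipeline recovers known composition and effect directions under
idealized, well-separated populations — not that it would achieve the same
precision on real acquisitions.

## Numerical and design choices

- Fluorescence channels are arcsinh-transformed with cofactor 150 (typical
  for conventional cytometers); scatter stays linear.  Storage (FCS) is
  always raw/linear; MFIs are computed on the raw scale by inverting the
  recorded transform.  All transforms are strictly increasing, so
  quantile-derived gates are scale-invariant.
- FCS files are written as version 3.1, single data segment, list mode,
  little-endian float32; reading accepts 3.0/3.1 with float32/float64.
  No spillover compensation is applied anywhere; a panel map exists as a
  plain-text `marker=parameter` config.
- Thresholds require ≥ 1000 control events by default; the scaled test
  configurations lower this floor to 150–500 together with smaller control
  tubes, since the quantile separations in the generator are large relative
  to estimation noise at those sizes.
- Determinism: every generator takes an explicit seed (cohorts spawn
  per-sample streams from the master seed), k-means and the Gaussian
  mixture use fixed initialization, and `SampleResult` serializes with
  sorted keys, so identical inputs produce byte-identical result JSON.
- Test and acceptance problem sizes are scaled to the suite: the
  parameter-recovery check runs 32 samples at 10⁵ events/tube; replicate
  cohort simulations (type-I calibration over 200 null cohorts, direction
  recovery over 25 effect cohorts) run 20–36 samples per cohort at 2500
  events/tube, where the tested properties — rank-test calibration and
  effect directions — do not depend on event depth once per-sample metrics
  are estimable.

## Known limitations

- The CD206 bright/intermediate boundary assumes at most two CD206+ modes;
  heavily skewed or trimodal CD206 distributions would need a different
  split rule.
- The TCPP HIGH cut is one-dimensional; a 2-D polygon on TCPP × FITC could
  separate bright populations that overlap in TCPP intensity alone.
- FMO thresholds are single quantiles; no uncertainty is propagated from
  control size into downstream percentages.
- The exclusion ledger records categories; it does not itself adjudicate
  eligibility or technical failure.
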