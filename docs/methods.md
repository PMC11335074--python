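# Methods

This note documents the models, default parameters and design choices
behind `casite`, and what its synthetic-data tests do and do not
demonstrate about real data.

## 1. Contact screening of ion–carboxylate trajectories

### Data model

A `TrajectoryBundle` holds consecutive segments of nominally fixed duration
(100 ns by default), each with shared frame times on one global clock,
per-frame positions of tagged Ca²⁺ ions, and the two side-chain oxygen
positions of every Asp/Glu carboxylate group. The contact reference point
of a group is the unweighted midpoint of its two oxygens ("gravity
center"): the two oxygens have equal mass and the carbonyl carbon is not
included. Coordinates are Å, times ns; readers convert nothing silently and
assume pre-imaged coordinates (no periodic-boundary handling).

### Two-step screen

1. **Coarse pass.** Distances for every (ion, group) pair are sampled at
   `screen_interval` (default 10 ns): the frames nearest the targets
   t₀ + k·Δ for k = 1..⌊T/Δ⌋, with T the segment's nominal duration and no
   interpolation. This yields exactly 10 measurements per 100-ns segment
   and makes the record count a pure product — the bookkeeping twin
   `count_screening_distances` (2 channels × 18 ions × 183 acidic residues
   × 6 segments × 10 samples = 395 280) is kept as an exact identity.
   Pairs with at least one distance strictly below `screen_cutoff` (10 Å)
   are retained. All distance thresholds in the package are strict (<),
   matching the "smaller than"/"closer than" wording of the protocol.
2. **Refined pass.** Distances for retained pairs are recomputed at
   `refine_interval` (0.4 ns). A group passes a segment when some retained
   pair spends ≥ `min_fraction` (10 %) of that segment's refined frames
   below `candidate_cutoff` (6 Å); the frames need not be contiguous.
   Overall candidacy is a pass in **at least one** segment. The protocol's
   two descriptions differ (per 100-ns period vs whole simulated time);
   the per-segment OR is used and per-segment flags are retained in the
   report so either reading can be recovered.

### Second-passage exclusion and departures

An ion "departs" when its distance to the static centroid of its home
vestibule (mean of that vestibule's group centers at frame 0) exceeds
`departure_radius` (25 Å) continuously for ≥ `departure_dwell` (5 ns); the
event time is the start of the excursion, which may span segment
boundaries. After departure, the ion's records with groups outside its
home vestibule are excluded from refinement and metrics; home-vestibule
records are kept (the ion may return). The 25 Å / 5 ns operationalization
is a package choice — the source protocol never quantifies "left the
vestibule".

### Metrics

For each group and each matching vestibule/ion pairing (AP groups pair
with their pocket's ions, CV groups with CV ions), the per-frame distance
to the **closest** matching ion (after masking) gives: occupancy fractions
below 4 / 6 / 20 Å, and the mean distance over records ≤ `mean_cap`
(10 Å) with the used record count (`NaN` with n = 0 when nothing
qualifies — a no-contact sentinel, never a zero). One pairing is one data
point; per-group spread across pairings is reported as both s.d. and
s.e.m. because the source display does not say which it shows. Initial
site labels (inner vs outer acidic-pocket site) are assigned by the
smaller first-frame distance to configurable anchor-group centroids, ties
to inner.

## 2. Brownian-dynamics trajectory generator

Ions follow the overdamped update

x(t+Δ) = x(t) − ∇U·D·Δ + √(2DΔ)·η,  U(x) = Σ_w −d_w·exp(−|x−c_w|²/2w_w²),

with well depths d in kT (kT absorbed), widths w in Å, inside a reflective
sphere. Defaults: D = 0.5 Å²/ns, Δ = 0.1 ns, 6 segments × 100 ns,
boundary 40 Å, wells 8 kT × 2 Å — deep enough that a trapped ion's
positional spread is ≈ 1 Å r.m.s., so groups within ~2.5 Å of a well
center satisfy the occupancy criterion essentially always and groups
≥ 15 Å from every well essentially never. A 100-frame segment simulates in
milliseconds. The boundary is reflective, not periodic, because the
analysis side deliberately excludes imaging logic.

Presets (`preset_bundle`):

* `wt_like` — one acidic pocket with an inner site (anchors E219/D409,
  plus E242 nearby) and an outer site 14 Å away (E97, E238, D347, D351),
  and a central-vestibule cluster (E375, E413, E418); five non-binder
  groups ≥ 15 Å from every well; three ions start at their sites. Ground
  truth: the ten groups adjacent to wells are binders.
* `nonbinding` — same groups, no wells; ions start in bulk solvent ≥ 40 Å
  from every group inside an 80 Å sphere. Free ions placed at the
  (well-less) sites would loiter there long enough to satisfy a 10 %
  criterion early on, which is diffusion, not binding; the bulk placement
  represents the intended no-binding condition.
* `escape` — the inner-site wells switch off at 300 ns and a small
  constant drift (≈ 1.1 Å/ns) pulls the ion out of the pocket; free
  diffusion alone at D = 0.5 Å²/ns would take ~200 ns to reach the 25 Å
  departure radius, which would conflate "escape time" with slow
  diffusion. The generator records the true first sustained crossing by an
  independent direct scan of the trajectory.

Generated bundles round-trip through a flat CSV coordinate dialect and a
multi-model PDB (biotite; CAL ion residues, OD1/OD2 / OE1/OE2 oxygens;
segment/time in REMARK 250 header lines). Region and home-site metadata
travel in a JSON sidecar since neither format has a place for them.

What these tests show: the screening logic discriminates planted
attractive sites from non-sites with exact precision/recall under
known-truth dynamics. What they do not show: force-field realism,
electrostatics, hydration shells, coordination geometry or protonation
dynamics — none of which the generator models.

## 3. Electrophysiology models and fitting

Model forms (responses are magnitudes of normalized inward currents):

* activation/SSD: I = I_max / (1 + 10^(±n_H·(pH − pH₅₀))), the sign
  giving a response that grows with stimulation acidity (activation) or an
  availability that falls with conditioning acidity (SSD, midpoint
  pHD₅₀); n_H is reported positive in both cases.
* inhibition: I = NonIn + (I_max − NonIn)/(1 + (x/IC₅₀)^n_H); also used
  with fitted pH₅₀ values as the response to estimate the apparent
  affinity of the pH₅₀-vs-[Ca²⁺] relation.
* recovery from desensitization: I = I_max·(1 − e^(−t/τ)).
* SSD onset: I = NonDes + (I_max − NonDes)·e^(−t/τ).

Fits are unweighted least squares (`scipy.optimize.curve_fit`) with a
5-point multistart on the midpoint/τ parameter (linear grid over the
stimulus range for pH midpoints, log grid for IC₅₀ and τ), bounds
pH₅₀ ∈ [3, 9], n_H ∈ (0, 10], IC₅₀ ∈ (1e−4, 1e3] mM, and tolerances 1e−10.
Degenerate inputs raise typed errors: fewer than four distinct stimulus
values, constant responses (unidentifiable IC₅₀/τ), zero control
amplitudes, non-positive fitted τ.

Normalization: activation/SSD series divide by the series' maximal peak
magnitude (the normalized maximum is exactly 1; for SSD this is the series
maximum rather than the first control, a documented choice). Recovery and
onset series divide by the control response, encoded as rows with an empty
stimulus field.

Paired summaries are computed per oocyte and then averaged, matching the
paired experimental design: ΔpH₅₀ (or ΔpHD₅₀) = low-divalent midpoint −
high-divalent midpoint; τ ratios are low/high for recovery and high/low
for onset. Unpaired oocytes are dropped with a count. Group comparisons:
two-sided paired t, one-way ANOVA followed by Dunnett (each group vs a
control) or Tukey (all pairs) at α = 0.05, via `scipy.stats`.
Concentrations are mM throughout; 100 nM free divalent is stored as
1e−4 mM.

## 4. Oocyte-level peak generator and presets

For each simulated oocyte the generator draws a high-divalent-arm
midpoint ~ N(preset mean, between-oocyte s.d.), an independent per-oocyte
shift ~ N(preset Δ, Δ s.d.) added to form the low arm, a maximal current
amplitude (lognormal, mean 5 µA, CV 0.5, inward negative), evaluates the
model on the protocol grid, and applies multiplicative measurement noise
(1 + N(0, σ), σ = 0.03). Drawing the arm difference directly (rather than
two independent arm midpoints) reproduces the tight per-oocyte shift
spreads of the paired design. Kinetic τs are lognormal with CV 0.4 per
arm, echoing the large population spreads of recovery kinetics.

Stimulus grids: activation 8 pH points 7.4 → 5.0; SSD 8 conditioning
points 7.8 → 6.6; inhibition {0.1, 1, 3, 10, 30} mM at pH 5.5; recovery
intervals 0.5–180 s and onset durations 1–300 s (8-point log-spaced
ladders covering both arm τs). Hill coefficients are generator
assumptions (activation 1.5, SSD 3.0 — the steeper SSD matching the
narrower printed curves); they are not published values.

Preset registry (midpoints in pH units; τ in s):

* `wt_ca`: activation 6.50 ± 0.12 at 2 mM Ca, Δ 0.25 ± 0.09 to 100 nM;
  SSD 7.14 ± 0.04 at 2 mM, Δ 0.28 ± 0.03 to 0.1 mM; inhibition IC₅₀
  9.6 mM, n_H 1, NonIn 0 (chosen so the analytic block at 10 mM is
  10/19.6 = 51 %); pH₅₀-vs-Ca floor 6.01, ceiling 6.78, IC₅₀ 3.5 mM
  (passing ≈ 6.50 at 2 mM and ≈ 6.75 at 100 nM); recovery τ 4.0 (2 mM) /
  22.8 (0.1 mM); onset τ 63.6 (2 mM) / 3.9 (0.1 mM), NonDes 0.05.
* `wt_mg`: activation 6.59 ± 0.11 at 2 mM Mg, Δ 0.13 ± 0.07; SSD
  6.97 ± 0.07 at **10 mM** Mg, Δ 0.39 ± 0.03 to 0.1 mM (the SSD
  comparison uses 10 vs 0.1 mM because 2 vs 0.1 mM produces no
  significant Mg²⁺ shift).
* `wt_kinetics`: the WT kinetics alone.
* `asic1b`: activation 6.13 ± 0.06, Δ 0.20; SSD 7.13 ± 0.07, Δ 0.24.
* shift presets `ap_act` (Δ 0.10 ± 0.09), `d409a` (Δ 0.41 ± 0.09),
  `ap_ssd` (Δ 0.05 ± 0.11), `cv_ssd` (Δ 0.13 ± 0.03), `asic1b_cv_ssd`
  (Δ −0.14 ± 0.30). Their high-arm midpoints are plausible acidic-shifted
  placements, not published numbers.
* `nonmodulated`: identical arms, for null checks.

A caveat recorded rather than resolved: the published per-oocyte τ-ratio
means (8.3 recovery, 17.3 onset) exceed the ratios of the arm-mean τs
(5.7, 16.3) because the ratio of noisy per-oocyte τs is upward-skewed;
the oocyte-level correlation between arms needed to reproduce the ratio
means exactly is not published, so the generator draws arm τs
independently and τ-ratio means are not asserted against the printed
values.

## 5. Three-state gating simulator

States closed (C), open (O), desensitized (D), with rates
k_CO = k₁·θ_a, k_OC = k₂·(1−θ_a), k_OD = k₃, k_CD = k₄·θ_d,
k_DC = k₅·(1−θ_d), proton occupancies
θ_x = 1/(1 + 10^(n_x·(pH − pK_x,app))) and Ca²⁺ competition
pK_app = pK₀ − log₁₀(1 + [Ca]/K_Ca), K_Ca = 3.5 mM. C and O are
integrated (LSODA, rtol 1e−8, atol 1e−10) and D = 1 − C − O, so
conservation is exact by construction; current ∝ −O and peak responses
are the per-step maxima of O.

Defaults k₁ = 20, k₂ = 400, k₃ = 0.5, k₄ = 0.2, k₅ = 0.1 s⁻¹,
n_act = 1.5, n_des = 3; intrinsic pK₀s (6.696 activation, 7.336
desensitization) are back-computed so the 2 mM Ca apparent proton
midpoints sit at the WT presets (6.50 / 7.14). The rate choices keep the
resting open probability below 10⁻³ at pH 7.8 and give a clear transient
peak on stimulation; because the response depends on pH only through
θ(pH − shift), lowering [Ca] from 2 mM to 100 nM shifts the fitted
peak-response midpoint alkaline by log₁₀(1 + 2/3.5) ≈ 0.196 — the
closed-form competition limit, verified by simulation. No claim of
kinetic realism is made: the rate constants are not fitted to recorded
traces, and the fitted absolute midpoint of the peak response sits acidic
of θ_a's midpoint (by ≈ log₁₀(k₂/k₁)/n_act) by construction.

## 6. Reproduction harness and problem sizes

`scripts/acceptance.py` and `casite reproduce` regenerate each headline
quantity from scratch: cohorts of 20 oocytes (activation and SSD
midpoints, paired shifts), 10 recovery ladders, 8 Mg²⁺ SSD oocytes, 20
oocytes per concentration for the pH₅₀-vs-Ca relation — the designs of the
corresponding experiments. Stochastic quantities are averaged over 20
independent replicate cohorts (40 for the IC₅₀ target, whose
four-parameter profile over six concentrations makes a single-cohort
estimate noisy and slightly skewed; the replicate means are pooled per
concentration before the single fit). Replication changes only the
Monte-Carlo precision, not the estimand; the reported `n` is the total
number of simulated oocytes. All randomness derives from the single
`--seed` argument through fixed integer mixing.

## 7. Known limitations

* The screening engine holds all sampled distances in memory as a
  DataFrame; it is sized for desk-scale bundles (minutes of synthetic
  data), not for production MD output. Binary trajectory formats
  (XTC/DCD) are out of scope; convert externally.
* Oocyte noise is multiplicative Gaussian and between-oocyte variation is
  Gaussian/lognormal; real recordings add rundown, series-resistance and
  perfusion artefacts that the generator does not emulate, so parameter
  recovery here bounds estimator correctness, not experimental accuracy.
* The gating model is a minimal competition scheme: no open-channel block
  by Ca²⁺ (pore block is modelled only at the inhibition-curve level), no
  state-dependent Ca²⁺ affinities, no sustained-current phenotypes.
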