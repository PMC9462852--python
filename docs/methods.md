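# Methods

## Gating model behind the Popen → E_eff conversion

Within a cluster the channel is modelled as equilibrating between one shut
and one open class; the maximum open probability then determines a single
overall gating equilibrium constant E_eff = Popen/(1 − Popen). E_eff lumps
all pre-open conformational steps (flipping/priming) together with the
opening step; the package deliberately does not attempt to separate them or
to fit multi-state activation mechanisms. One E_eff value is computed per
cluster, so each cluster is the unit of observation for all inference.

Free energies use ΔG = −RT ln(E_eff,mod/E_eff,ref) with R = 1.987 cal K⁻¹
mol⁻¹ and T = 295 K; RT = 0.586 kcal/mol. R is given in calories, and the
10⁻³ conversion to kcal/mol is applied exactly once, in
`EfficacyConstants.RT_kcal`. Cycle closure (ΔG1 + ΔG2′ = ΔG2 + ΔG1′) is an
algebraic identity and is asserted, not estimated. The coupling energy is
reported with the sign convention ΔΔG_int = ΔG1 − ΔG1′; because the
literature often quotes the magnitude, |ΔΔG_int| is reported alongside.

Point estimator: the per-corner E_eff is the mean of the per-cluster E_eff
values by default (consistent with reporting a bootstrap "standard deviation
of the mean"); a median estimator is available because E_eff is strongly
convex in Popen and the mean is pulled upward by high-Popen clusters. Both
can be computed side by side; neither is privileged as "the" published
estimator, which is not identifiable from summary statistics alone.

Clusters with Popen exactly 0 or 1 have undefined (zero/infinite) E_eff. The
default policy excludes them and reports the excluded count per corner; a
continuity-correction policy ((p + ε)/(1 + 2ε)) is available. Exclusion was
chosen as the conservative, auditable default.

## Bootstrap and randomization inference

`bootstrap_cycle` resamples each corner's per-cluster E_eff list with
replacement, independently across corners, 10,000 times by default;
replicate distributions of all four edge ΔGs and of ΔΔG_int are kept and
their SDs (n − 1 denominator) reported. The randomization test uses the
absolute difference of group means (the convention of the DC-Stats tool
family; difference of medians is available), two-tailed, non-paired, with
50,000 label shuffles by default. Monte Carlo p-values use the add-one
convention p = (1 + k)/(n_iter + 1), so p can never be zero; when the number
of distinct splits C(nA+nB, nA) does not exceed n_iter the test switches to
exhaustive enumeration and the p-value is exact (no add-one). Ties at the
observed statistic are counted as extreme, with a 1e-12 absolute guard
against floating-point ties.

## Synthetic single-channel data

No generative kinetic scheme is published for these recordings, so the
simulator uses the minimal scheme that reproduces the observable the
analysis consumes: alternating open/shut dwells with exponential durations
(means 1/α open, 1/β shut, so the within-cluster Popen is β/(α+β)), each
cluster terminated after an opening with geometric probability into an
exponential desensitized gap. Defaults: α = 100 s⁻¹ (10 ms mean open time),
desens_prob = 0.01 (~100 openings per cluster, giving roughly one-second
clusters as seen at saturating agonist), mean desensitized gap 2 s,
unitary current 5 pA (no amplitude is published for these cell-attached
recordings at +100 mV; 5 pA is an arbitrary but typical value and is
configurable). `make_agonist_dataset` chooses β per agonist to hit the
target Popen, cuts clusters at the ground-truth desensitized dwells, and
applies the recording protocol's own acceptance rule (clusters ≥ 100 ms),
which also removes degenerate single-opening clusters whose Popen is
exactly 1.

What the generator emulates: the cluster/desensitization structure, the
Popen levels of the four agonists, exponential dwell-time scatter, the
recording chain (white noise entering before a Gaussian anti-alias filter).
What it does not emulate: multi-exponential shut-time distributions, modal
gating, inter-patch heterogeneity (the real per-cluster Popen SDs, e.g.
0.19 for the sulfonate agonist, exceed the binomial-style scatter this
scheme produces), open-channel noise, baseline drift, and superimposed
channels (a double-opening test fixture can be constructed directly).
Consequently the simulated bootstrap SD of ΔΔG_int (~0.03–0.04 kcal/mol at
100 clusters per corner) is smaller than the published ~0.2 kcal/mol, which
reflects real biological spread; passing recovery tests demonstrates
correctness of the estimator chain, not realism of the noise model.

Rendering: the two-level signal is sampled at fs (default 100 kHz), white
Gaussian noise of the requested SD is added, and the trace is filtered with
a Gaussian kernel specified by its −3 dB cutoff (σ_t = 0.1325/fc, truncated
at ±4σ, renormalized — the standard single-channel convention), default
10 kHz standing in for the acquisition Bessel filter. The Bessel and
Gaussian responses are not identical; the simulator exposes a single
effective cutoff and makes no equivalence claim.

## Idealization

Analysis filtering follows the published chain: an additional 3 kHz Gaussian
filter (cascaded cutoffs compose as 1/fc² addition), linear-interpolation
resampling to 33.3 kHz, then half-amplitude threshold crossing (threshold
fraction 0.5 of the unitary amplitude, configurable; the half-amplitude rule
is the field standard and makes long-event durations unbiased). No dead time
is imposed by default; a minimum-event filter exists for noisy data. First
and last dwells are censored by the observation window; clusters touching
them are flagged and excluded by default from Popen statistics. Double
openings are flagged where the current exceeds 1.5× the unitary amplitude
for longer than one filter rise time (0.3321/fc).

Two parametrizations hit a target Popen: `beta_for_popen` fixes the closing
rate (used by `make_agonist_dataset`, whose clusters are cut at ground-truth
desensitized dwells so shut-time scales are irrelevant), while the
end-to-end pipeline fixes the opening rate (mean shut 4 ms) and derives the
closing rate, emulating weak agonists with brief openings rather than long
closures. The second form keeps every corner's within-cluster shut times
far below tcrit, which the pipeline's threshold segmentation requires; with
the closing rate fixed instead, a 0.12-Popen agonist would have 73 ms mean
shut times overlapping tcrit and its clusters would be falsely split.

tcrit (default 100 ms) separates within-cluster closures from desensitized
gaps. With seconds-long desensitized gaps and millisecond closures any value
in the decade-wide gap gives the same segmentation; because the generator's
gaps are exponential, a small fraction of true gaps can fall under any fixed
tcrit, which ground-truth tests handle by fixing seeds that satisfy the
separation precondition.

## Dose-response analysis

The Hill equation is used in its three-parameter form with bottom fixed at
zero (peak currents are measured above a subtracted baseline), fitted by
unweighted least squares (`scipy.optimize.curve_fit`), with the fixed
initialization Imax = max response, EC50 = concentration nearest half-max,
nH = 1, and bounds keeping all parameters positive. Non-convergence is a
flag, not an exception. Per-cell fits are unconstrained. Rundown control:
cells whose interleaved saturating-glycine response declines by more than
30% are excluded with an audit entry. Normalization modes: by the cell's own
maximum (same-agonist curves) or by the same cell's saturating glycine
response (relative-efficacy curves, where a partial agonist's pooled maximum
is a fraction of the glycine maximum).

At 5% multiplicative noise and eight concentrations the single-fit EC50
scatter is ~7%, so recovery is assessed on the median of the replicate
estimates (a bias check, within 5% of truth over 200 replicates), matching
how the recovery oracle is defined.

## Protonation arithmetic

The zwitterion fraction of the amino group is Henderson–Hasselbalch:
f = 1/(1 + 10^(pH − pKa)), pKa 5.75 for aminomethanesulfonic acid. It is
strictly decreasing in pH and satisfies f(pKa − x) + f(pKa + x) = 1.

## Numerical and reproducibility choices

- Every stochastic function takes an explicit seed; pipeline stages derive
  seeds from one global seed by fixed offsets, and reruns are byte-identical
  (JSON written with sorted keys, CSV floats at %.17g, reads with
  round-trip float parsing).
- Medians use the midpoint convention for even n; SDs use the n − 1
  denominator throughout.
- Problem sizes in the test and acceptance runs (100 clusters per corner,
  10,000 bootstrap resamples, 1,000 × 5,000 randomization replicates, 400
  rendered events) were chosen to keep standard errors a few-fold below the
  tolerances being checked.

## Known limitations

- No missed-event (dead-time) correction and no HMM/SKM idealization; very
  brief events near the filter rise time are systematically shortened or
  lost, as with any threshold method.
- The cycle analysis treats clusters as exchangeable across patches
  (patch-level random effects are not modelled), mirroring the per-cluster
  bootstrap it implements.
- Whole-cell currents are used as supplied: no series-resistance, liquid
  junction or desensitization-peak corrections.
- Binary acquisition formats are out of scope; data enter as CSV.
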