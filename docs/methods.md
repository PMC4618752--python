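# Methods

## Model

The dynamic state has eleven core variables: three hepatocyte pools
(quiescent Q, primed P, replicating R, measured relative to the post-PHx
remnant, so Q(0)=1), the relative functional mass G of responding cells
(G(0)=1), and seven molecular levels expressed as fold-changes over a
pre-operative baseline of 1 (IL6, JAK, pSTAT3, SOCS3, immediate-early
genes IE, growth factor GF, extracellular matrix ECM). The optional
matrix-bound-factor extension adds a bound pool MBF_ECM (initially 50)
and a liberated pool MBF_free (initially 0). An auxiliary state carries
the first-order activation of the hypertrophy gate (below).

Cell-pool balance:

    dQ/dt = -k_QP s_prime Q + k_RQ [ECM] R + k_req σ_req (P + R) - k_ap σ_ap Q
    dP/dt = +k_QP s_prime Q - k_PR ([GF]-[GF]0) P - k_req σ_req P - k_ap σ_ap P
    dR/dt = +k_PR ([GF]-[GF]0) P - k_RQ [ECM] R + k_prol R - k_req σ_req R
            - k_ap σ_ap R

with priming signal s_prime = ([IE]-[IE]0)⁺ (+ MBF_free⁺ when the MBF
extension is on). Molecular balances combine first-order and
Michaelis-Menten kinetics (JAK activation saturating in IL-6; pSTAT3
production saturating in monomeric STAT3 and competitively inhibited by
SOCS3; IE and SOCS3 induction saturating in pSTAT3; GF produced in
proportion to demand per cell, taken up by ECM and degraded; ECM degraded
by an IL-6-driven MMP term plus a constitutive term). Basal production
constants k1..k7, one per molecular equation, are solved in closed form so
that the pre-operative configuration (all levels 1, demand per cell basal)
is an exact steady state; they are recomputed whenever parameters change.

**Demand normalization.** Demand per cell is D = M/((1-f)·N) with
N = Q + G(P+R) in remnant units and f the resected fraction: the
pre-operative pool (N = 1/(1-f)) carries demand M per unit mass, so basal
D = M = 20.8 for rat, jumping to M/(1-f) = 69.3 at a 70% PHx. The
alternative convention (basal D = M(1-f)) is available via
`demand_convention="remnant"`; the default is the one that reproduces the
published cascade amplitudes (pSTAT3 amplification, replicating-fraction
peak) and sigmoid operating points.

**Requiescence acting on R.** As printed, the replicating pool gains
k_prol·R (0.02/h) but can only leave through k_RQ·[ECM]·R, which is
bounded by k_RQ·k6/κ_ECM ≈ 0.0065/h because ECM cannot exceed
k6/κ_ECM ≈ 1.2; replication would never terminate. Since cycling cells
are described as returning to quiescence through "natural requiescence or
ECM buildup", the requiescence flux k_req σ_req, with
σ_req = ½(1+tanh((θ_req-[GF])/β_req)), is applied to R as well as P
(configurable). Replication then shuts down sharply once GF falls through
θ_req = 8, producing the plateau the recovery curves show.

**Apoptosis.** The sigmoid as printed,
σ_ap = ½(1+tanh((θ_ap - M/N)/β_ap)) with θ_ap = 9e-3 and M/N of order
10-70, is identically ≈ 0 and contradicts the stated behaviour (high
apoptosis under high load). We use the inverse-demand reading: the
argument compares θ_ap against the surviving cell count per unit demand,
x = (1-f)(Q+P+R)/(c_ap·M), so apoptosis is appreciable immediately after
resection and vanishes as the pool recovers. The load normalization
c_ap = 0.84 is the one genuinely free constant of this reading; it was
calibrated once, jointly with the growth activation lag below, against
the published dynamic-sensitivity timings (sign changes of the
metabolic-demand sensitivity near 53 h/43 h without/with cell growth) and
then frozen. The count-based (rather than mass-based) load measure is
deliberate: hypertrophy does not protect an under-populated liver from
overload. `apoptosis_convention="as_printed"` restores the literal form.

**Cell growth (hypertrophy).** The governing ODE for G is not given in
the source material and is reconstructed as

    dA/dt = (s(D) - A)/τ_G,   dG/dt = ln2 · (60·G_rate) · G · A · c(G)

with gate s(D) = ½(1+tanh((D - D_basal)/(0.1·D_basal))): growth runs at
the full rate G_rate (printed in mass-equivalent doublings per minute,
hence the factor 60 on the hourly time base) while demand per cell
exceeds basal, and stops as the recovering mass meets pre-operative
demand — which makes the with-growth plateau independent of M and flips
the sign of the late demand sensitivity, as reported. The activation
state A (τ_G = 10 h) encodes that functional mass accrues in response to
sustained, not instantaneous, overload; without it the with-growth
sensitivity sign change lands in the high 20s of hours for every
admissible apoptosis operating point. c(G) = (1-(G/G_cap)^8)⁺ with
G_cap = 100 is a saturation guard far above the fold-changes reached on
the nominal trajectory; it only tames non-viable regimes in which the
demand is never met.

**Matrix-bound factors.** Release is mass-action in the remaining bound
pool: u = k_MBF(1/[ECM] - [ECM]0)·MBF_ECM when positive (re-binding, when
ECM exceeds baseline, drains the free pool instead), and the bound pool
is replenished at the GF-uptake rate k_up[GF][ECM]. Under this law the
liberated signal MBF_free peaks within the first hour, carries the same
order of magnitude as the IE priming signal, and is exhausted after the
priming phase — the three qualitative properties reported for this
extension. A pool-independent release law peaks hours later (it simply
tracks the IL-6 peak) and was rejected.

**Time base.** All rates are interpreted per hour. The per-minute unit
labels attached to the transition/proliferation constants inherited from
the predecessor model are treated as labeling errors: used at face value
(x60) they place the priming peak below one hour and make replication
explode, incompatible with every published timing. G_rate is the one
parameter whose per-minute unit is taken literally (it is the model's own
addition, with the unit stated in its definition).

## Parameters

Defaults are the nominal rat values (M = 20.8, G_rate = 3.5e-4
doublings/min, k_IL6 = 1.5, ..., MBF_ECM0 = 50; see
`hepregen/data/rat_nominal.yaml`, which the `ModelParameters` defaults
reproduce exactly). phx_fraction defaults to 0.7. Reference levels IE0,
GF0, ECM0 default to 1. The model-variant flags (`include_growth`,
`include_mbf`, conventions, c_ap, τ_G, G_cap) are ordinary fields of
`ModelParameters` and participate in validation.

## Numerics

Integration uses `scipy.integrate.solve_ivp` with LSODA, rtol 1e-8,
atol 1e-10 (mode surveys use 1e-6/1e-8; halving tolerances moves the mass
fraction by < 1e-4 relative). The GF ≥ 1 floor (a numerical guard
documented for the original implementation) and the nonnegativity of
molecular levels are enforced by stiff continuous restoring terms with a
0.01 h relaxation time rather than hard derivative switches, which make
implicit integrators chatter at the boundary; substrate levels are
additionally clamped at zero inside the saturating fluxes. Demand per
cell floors the pool at 1e-3 so extinct-pool (liver-failure) regimes
saturate instead of diverging. `simulate` caps rhs evaluations (2e6) and
raises a step-size-collapse error instead of hanging; parameter-space
surveys and paired scans catch that error per sample (recorded as liver
failure / failure-floor metric). Peak reporting refines the argmax with a
local parabola through the three surrounding samples; ties break to the
earliest time and constant series are flagged flat.

## Mode classification

The classifier compares a trajectory against the nominal reference using
its plateau (mean over the trailing 10% of the horizon) and the time τ at
which 90% of the reference mass deficit is recovered. Defaults: liver
failure if final mass falls below the remnant or declines monotonically
over the trailing 20% (to below 0.9 of the reference plateau);
unresponsive if < 10% of the deficit is recovered; suppressed if the
plateau is < 0.90 of reference; enhanced if the plateau exceeds 1.05 of
reference or τ < 0.80 τ*; delayed if τ > 1.05 τ*; delayed+enhanced when
both hold; otherwise normal. The delayed threshold is set at 1.05 (not a
larger margin) so that the canonical delayed exemplar — cytokine
production reduced until the IL-6 peak falls 25% — is labelled delayed;
all thresholds are configurable. Envelope summaries use the sample
(n-1) standard deviation.

## Calibration

Fits minimize the sum of squared errors between the simulated mass
fraction (interpolated to the data times) and a fractional-recovery
series, using a log-parameterized Nelder-Mead simplex with box penalties
and seeded multistarts (5 by default). When M is free, the apoptosis
threshold θ_ap is rescaled in proportion to M (the cross-species
convention) unless disabled. The Gaussian log-likelihood of the residuals
is evaluated at their maximum-likelihood mean and variance (divide-by-n),
and nested models are compared by G² = 2(l_u - l_r) against the
chi-square upper tail. On the published log-likelihood pair (4.42, 9.64)
this gives G² = 10.44; the originally reported 10.53 reflects unrounded
inputs and is not forced. Disease scenarios free one of two documented
subsets — non-parenchymal (M, G_rate and the Kupffer/stellate
production-degradation rates; 9 parameters) or hepatocyte response
(transition, JAK-STAT and requiescence/apoptosis parameters) — or a
user-defined subset. The full subsets are not identifiable from a single
recovery series; parameter-recovery guarantees hold for the perturbed
subset itself.

The likelihood-ratio null-calibration test precomputes the model's
recovery curve on a dense (M, G) grid and fits replicates against a cubic
interpolant of that surface (interpolation error ~1e-5, far below the
2%/1% noise), which makes 200 maximum-likelihood nested fits exact and
fast; the resulting G² sample is compared to chi-square(1) by a KS test.

## Synthetic data

`make_synthetic_series` samples a simulated mass-fraction curve at sparse
time points (default 8 points over 10 days, the typical density of
published sacrifice schedules) and adds i.i.d. Gaussian noise (default
SD 0.02, the scale of inter-animal scatter in such series), clipped at a
small positive floor. It emulates the one feature calibration needs —
sparse, noisy fractional-recovery measurements of a known ground truth —
and none it does not: no inter-animal correlation, no digitization bias,
no systematic unit-conversion error. Passing recovery tests therefore
demonstrate that the optimizer identifies parameters when the model
family contains the truth, not that the model family is correct for any
real dataset.

## Known limitations

* The cell-mass ODE, the apoptosis operating point and the growth
  activation lag are reconstructions constrained by published timings,
  not transcriptions; c_ap and τ_G are calibrated constants.
* Two published effect sizes of the reduced-IL-6 experiment are not
  reproduced at the stated horizon: the priming-peak reduction comes out
  near 13% (reported ~10%), and the overall-recovery reduction at 300 h
  is ~1% because the demand-gated growth plateau is M-independent — the
  maximum reduction over the time course, ~5% near 100 h, matches the
  reported number, but the gap closes again by the horizon. The IE peak
  falls near 7.5 h rather than the reported ~3 h: the printed molecular
  rate constants give an IL-6 rise time of ~2.6 h, which bounds the IE
  peak from below. The corresponding acceptance tests fail by design
  rather than being loosened.
* With the published hypothesis overrides applied at rat demand, the
  altered-cytokine and altered-ECM/GF hypothesis sets collapse to liver
  failure under the calibrated apoptosis operating point instead of
  producing slow human-like recovery; the machinery (override application,
  day-14/day-30 readouts) is provided and tested, but those two scenarios
  should be interpreted with that caveat.
* No spatial/zonated structure, no NF-κB or ERK signaling, no
  drug-induced-injury scenarios, and strictly local (not variance-based)
  sensitivity analysis.
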