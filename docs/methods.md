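# Methods

## The circuit and its assumptions

The model is a deterministic, well-mixed mass-action description of the
Hsp70–Hsf1 feedback loop of the budding yeast heat shock response. Its
central assumption is that the response is triggered by immature newly
synthesized proteins (NSPs), not by denaturation of mature proteins:
translation supplies unfolded protein at a constant rate `k_up`
(a.u.·min⁻¹), spontaneous folding drains it at `k_dup` (min⁻¹), and
heat shock acts solely by slowing folding, so unfolded protein
accumulates. Unfolded protein and Hsf1 compete for free Hsp70
(association/dissociation pairs `k₃/k₄` and `k₁/k₂`); chaperone-bound
unfolded protein is cleared at `k₅`, returning free Hsp70. Free Hsf1
drives synthesis of Hsp70 and of an HSE-YFP reporter through one shared
Hill function `β·[Hsf]ⁿ/(K_dⁿ+[Hsf]ⁿ)`. The reporter has no loss term
(fluorescent protein maturation and dilution are not modeled), so YFP
is non-decreasing — an invariant the integrator enforces.

The co-chaperone Sis1 is not an explicit species. Its J-domain role of
substantiating Hsp70–client binding enters as a dimensionless level `s`
(basal 1) that inversely scales the Hsp70·Hsf1 dissociation rate:
`k₂_eff = k₂/s`. An off-by-default flag (`couple_k4_to_sis1`) extends
the same scaling to the Hsp70·UP dissociation rate `k₄` for exploring
Sis1's secondary role on misfolded-client binding; the default couples
only `k₂` because the depletion mapping is defined on the Hsf1 complex.
There is no Sis1 synthesis/degradation dynamics and no transcriptional
induction of Sis1 — deliberately, since the circuit reproduces response
dynamics without Sis1 feedback.

Default parameters (`KineticParameters()`): `k_up=1`, `k_dup=0.35`,
`k1=320`, `k2=0.7`, `k3=112`, `k4=0.1`, `k5=0.15`, `beta=0.1`, `n=3`,
`kd=0.0025`, all concentrations in arbitrary units and time in minutes.
`k_up` is treated as a zeroth-order source of magnitude 1 a.u.·min⁻¹.
The default initial state (`ModelState()`) — `[HSP]=12`, `[Hsf]=0`,
`[HSP·Hsf]=1250`, `[UP]=0`, `[HSP·UP]=0`, `[YFP]=1` — describes t=0 of
a heat shock at the reference temperature (39°C); no pre-equilibration
phase is simulated.

## Conservation structure

The equations force `d([Hsf]+[HSP·Hsf])/dt = 0` identically: total
Hsf1 stays at 1250 a.u. forever. Total Hsp70
(`[HSP]+[HSP·Hsf]+[HSP·UP]`) changes only through the Hill synthesis
term, so it is constant when feedback is disabled; total unfolded
protein obeys `d([UP]+[HSP·UP])/dt = k_up − k_dup[UP] − k₅[HSP·UP]`.
These identities are asserted symbolically on random states in the
property tests and numerically (to 1e-6 relative) on every integration.

## Conditions and scenarios

Experimental conditions are parameter mappings applied per protocol
segment:

- **rapamycin** — `k_up × 0.6` (TORC1 inhibition removes ~40% of NSPs);
- **temperature** — `k_dup × scale`; the shipped table maps
  35/37/39/41°C to 1.6/1.3/1.0/0.8. Only the monotone-decreasing
  direction is meaningful; the numeric entries are editable conventions,
  not fitted values.
- **sis1_depletion** — `s = 0.1` by default (10× effective `k₂`),
  run at basal temperature (no `k_dup` change). The magnitude is an
  exposed order-of-magnitude choice, not a measured one.
- **hsp70_dFBL** — the Hill term is removed from `d[HSP]/dt` only; the
  reporter keeps it (the strain retains HSE-YFP).
- **pulse_recovery** — recovery segments scale `k_dup` by 1.5
  (folding faster at permissive temperature). This protocol support is
  an extension for exploring pulse regimes, not a reproduction of a
  published simulation.

Day-to-day experimental variability is modeled by drawing one `k_up`
multiplier per replicate uniformly from [1−f, 1+f], f = 0.2 by default
(metabolic state differences feeding into basal translation). Uniform
sampling is a declared convention; only the ±20% envelope is specified
by the study conditions.

## Numerical choices

The rate constants span five orders of magnitude (`k1=320` vs
`kd=0.0025`) and the Hsp70·Hsf1 binding mode relaxes at
`≈ k₁([HSP]+[Hsf]) ≈ 4×10³ min⁻¹`, so the system is stiff.
`integrate` uses LSODA with `rtol=1e-10`, `atol=1e-12`; at these
tolerances splitting a protocol segment in two changes outputs by
< 1e-9 relative and total Hsf1 drifts by < 1e-12 relative over 240 min.
Integration restarts at every protocol boundary (conditions switch
instantaneously, concentrations are continuous). Solver undershoots
below zero are tolerated to 1e-9 and clamped; anything worse is an
error, as are NaNs, conservation drift beyond 1e-6, and decreasing YFP.

`fixed_step_reference` is an independently coded classical 4th-order
fixed-step integrator used as a numerical oracle. Its default step is
5×10⁻⁴ min: the scheme's real-axis stability interval ends near
−2.785, and with the fast binding mode at ≈ 4×10³ min⁻¹ any step above
≈ 7×10⁻⁴ min is unstable — empirically, a 10⁻³ step produces bounded
but systematically wrong trajectories (per-species errors of several
percent) rather than an overflow, which is why the function refuses
steps outside the stability region instead of returning them. At
5×10⁻⁴ the oracle converges cleanly at 4th order and agrees with the
adaptive solution to ~2×10⁻⁶ relative over 30 min.

Ties and degenerate inputs: a zero-length horizon returns the initial
state; an empty temperature sweep returns an empty list; `hill(0)=0`
exactly; the Hill function is evaluated in ratio form (choosing the
ratio ≤ 1) so it neither overflows nor loses the saturation limit at
extreme `[Hsf]/K_d`.

## The saturated-Hill regime

With the published constants, basal free Hsf1 relaxes within
milliseconds to `≈ k₂·1250/(k₁·12) ≈ 0.23 a.u.`, about 100-fold above
`K_d = 0.0025`. The Hill activation therefore runs at > 0.9999 of its
ceiling β throughout every packaged scenario: the reporter rises almost
linearly at β = 0.1 min⁻¹ and perturbations (rapamycin, Sis1 depletion,
temperature, feedback deletion) shift it in the expected *direction*
but by very small margins (relative YFP differences of order 10⁻⁵).
The equations and constants are implemented exactly as published;
`hill_regime_report` computes the occupancy along any trajectory and
flags saturation, and the scenario tests surface that flag as an
explicit warning so the regime is reported rather than silently passed
over. Conclusions about the *magnitude* of scenario separations should
not be drawn from this parameter set without rescaling `kd` or the
total Hsf1 pool.

## Derived statistics

**Translation dependence.** For each Hsf1 target gene,
`1 − fold_CHX/fold_untreated`, where each fold is heat shock over
non-heat-shock expression within its cycloheximide stratum; the
headline summary is the arithmetic cross-gene mean (median also
reported). Values are at most 1 and may be negative. Fold changes are
computed on replicate means with a pseudocount (default 0.5) guarding
zero denominators; per-replicate pairing is available.

**Library-size normalization.** `relative_expression` can scale counts
by per-sample totals (default on). One caveat the test suite makes
explicit: on a table containing *only* induced target genes, the column
total itself carries the induction, so normalizing by it cancels a
uniform induction or dependence signal exactly. Whole-transcriptome
totals (where the targets are a negligible fraction) do not have this
problem. The synthetic recovery analyses therefore generate
depth-matched libraries and compute on raw counts
(`depth_normalize=False`).

**Flow cytometry.** Per-cell fluorescence is divided by side scatter
(cell-size proxy) and summarized by the median, which is robust to the
right-skewed tail of expression.

**Ensemble spread.** Across replicate trajectories at a fixed time:
population CV and (max−min)/mean of the reporter — both invariant to
common rescaling.

**Ring-to-cell ratio.** Mean intensity in a peri-nucleolar ring mask
over mean intensity in the cell mask (ring ⊆ cell enforced); invariant
to global intensity scaling, *not* to background offsets — background
should be subtracted upstream.

## Synthetic data generators

The flow generator emulates per-cell reporter readouts along a
trajectory: `fluorescence = yfp(t) · scatter · ε`, with scatter
lognormal (mean 100, CV 0.3) and ε lognormal with **unit median** and
CV 0.25 by default — so the median scatter-normalized readout equals
`yfp(t)` by construction and the round trip through `median_reporter`
is exact at zero noise. Lognormal noise reflects the right-skew of
flow fluorescence; defaults are declared conventions, since assay noise
was not characterized quantitatively in the source data.

The RNA-seq generator emulates the NHS/HS × untreated/CHX design over
39 target genes, two biological replicates, negative-binomial counts
(`var = m + φm²`, dispersion φ = 0.05) at baseline mean 500. Per gene,
heat shock log-fold `φ_g ~ N(2.0, 0.5)` (≈ 7.4-fold typical induction)
and dependence `d_g ~ N(0.7, 0.15)` truncated at 1; the CHX+HS mean is
`baseline·e^{φ_g}·(1−d_g)`, so the programmed dependence is recovered
by the statistic in expectation. With these study conditions the
recovered cross-gene mean over 20 seeds is ≈ 0.68–0.70: each seed's
value carries sampling noise of sd ≈ 0.03 (dominated by the per-gene
heterogeneity sd 0.15 over 39 genes, plus a small downward
ratio-of-means bias), so the ±0.05 recovery band applies to the
distribution's center across seeds, not to every individual seed.

What passing these tests shows — and does not. The generators verify
that the statistics recover what they are defined to measure under the
assumed noise models. They do not validate the noise models against
real flow or sequencing data: real data carry batch structure,
gene-specific dispersions, compositional effects and instrument
artifacts the generators deliberately omit.

## Known limitations

- Deterministic ODEs only: no intrinsic (molecule-number) noise; the
  only stochasticity is between-replicate parameter variation.
- No temperature model beyond the `k_dup` multiplier table; no fitting
  of multipliers to measured temperature responses.
- No reporter maturation delay or dilution by growth; YFP is a pure
  integrator of Hsf1 activity.
- Sis1 has no dynamics of its own; depletion is instantaneous and
  sustained.
- The published parameter regime saturates the Hill function (above),
  limiting the model's dynamic range around the baseline.
- The optional GEO fetch downloads supplementary files only; parsing a
  specific series' layout into a count table is left to the user.
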