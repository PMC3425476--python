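# Methods

## Scope and structure

`pinewater` simulates the first six years of a Mongolian Scots pine planted
at 1 m × 1 m spacing on deep aeolian sand, where water is the limiting
resource.  Eight concerns map onto eight modules: weather input and
reference evapotranspiration (`weather`), the daily root-zone balance
(`soil`), topology and 3D geometry (`architecture`), the yearly source-sink
engine (`growth`), hidden-parameter estimation (`calibration`), the
precipitation experiment (`sensitivity`), synthetic inputs (`synthetic`)
and configuration/CLI (`config`, `cli`).  Only the aboveground tree is
modelled; roots enter solely through a fixed effective rooting depth.

## Daily water balance

The root zone is a single bucket.  With Z_r = 1 m, θ_F = 0.12 and
θ_W = 0.07 (sand), TAW = 50 mm; the depletable-before-stress fraction r is
not published for this system and defaults to the conventional 0.5, so
RAW = 25 mm.  The stress coefficient K_s is 1 up to RAW and falls linearly
to 0 at TAW.  Each day ET_a = K_s·K_c·ET_0 (K_c = 1 for conifers) is drawn
from the bucket and rain refills it; interception, runoff and groundwater
recharge are neglected (young trees, deep water table, bare sandy
understory).  Two clamps close the accounting: rain beyond field capacity
is discarded ("surplus") and demand the bucket cannot supply is recorded as
"overdraft"; the daily ledger keeps both so the balance
ΣET_a = ΣP − surplus + overdraft + ΔD_r closes to machine precision —
exactly, when neither clamp fires.  The season starts with a full profile
(D_r = 0), consistent with snowmelt and spring recharge, on the first day
of the first 5-day run of mean temperature ≥ 0 °C and ends with the last
such run in autumn.

ET_0 uses the standard daily reference-crop combination equation
(radiation term 0.408·Δ·R_n, aerodynamic coefficient 900/(T + 273), wind
multiplier 0.34, zero daily soil heat flux).  Stations in this network do
not measure radiation, so R_n is estimated from sunshine duration with the
Angström relation (a = 0.25, b = 0.50, both in config) at 42.717°N, plus
the usual clear-sky-scaled net-longwave correction.  Δ is the exact Tetens
derivative 17.27·237.3·e_s(T)/(T + 237.3)², not the rounded 4098 constant,
so it matches a hand derivative to 1e-9.  Pressure may come per day from
the file or as a site constant from elevation; per-day wins.

The plant's share of ET_a is the Beer-Lambert interception fraction
1 − exp(−k·LAI) with k = 0.5.  ET_a (total) drives the bucket; only the
canopy share T_a drives growth — this keeps soil evaporation in the water
budget without crediting it to the tree.

## Growth cycle

One cycle per calendar year, five stages, in this order: develop topology →
allocate last cycle's production → allometry, rings and leaf area → run the
water season with the new LAI → produce Q(i).  The LAI used for year i
therefore includes the needles flushed in spring of year i.

Production is Q(i) = WUE·T_a(i)·S_p/(1 − C_w) in grams fresh, with
WUE = 4.5 g dry per kg water, C_w = 0.60 and S_p = 1/density = 1 m².
Allocation is proportional to relative sink strengths against the demand
D(i); the ring sink p_c = 11.09 enters the demand once per tree and its
pool is then spread over all internodes (including the current flush) with
weights R_p(pa)·l·(λ·A_above + 1 − λ), where A_above is the fraction of
living needle area borne at or distal to the internode, λ = 0.03, and the
trunk uses an implicit R_p = 1 reference mirroring the needle reference
sink p_a(1) = 1.  Ring mass thickens an internode at constant length
through the cylinder relation Δarea = Δm/(ρ·l).

Organs complete primary expansion in their birth cycle.  Internode length
follows the slenderness law s = b(pa)·q^β(pa) closed with a cylinder of
fresh density ρ = 1 g cm⁻³ (not measured; configurable).  Needle entities
(all needles of a growth unit pooled) convert fresh mass to area via
dry = fresh·(1 − C_w) and specific leaf weight ε = 0.035 g cm⁻², and
function for 3 cycles (observed functioning-time class; configurable),
after which they stop contributing to LAI and to the ring weighting but —
absent an abscission term in the model — keep their biomass in the
compartment totals.

The initial supply q0 is the reserve of the planted nursery stock.  It is
not published for this system; 10 g fresh is the size class of a 2-year-old
bare-root seedling and is the package default.  Absolute trajectories are
proportional to q0 in the young, open-canopy regime, and with the published
parameter set they stay well below the measured biomass of six-year-olds —
the parameter set itself is internally tense (a WUE of 4.5 g kg⁻¹ with a
~170 mm transpiration season implies far more annual production than the
measured standing biomass).  The engine follows the production equation
literally rather than absorbing that tension into a hidden rescaling;
relative responses (the sensitivity experiment, calibration, all
conservation properties) are unaffected.

## Architecture

Physiological age equals branching order, 1 (trunk) to M = 4.  Each cycle
every terminal bud extends its axis with one growth unit of the same PA and
every unit formed the previous cycle bears laterals of PA+1.  Branch counts
per PA were observed in the field but never tabulated; the defaults
3/2/1 laterals for PA 1→2/2→3/3→4 are placeholders producing a plausible
six-year-old (261 growth units) and live in config.  Counts are
deterministic, so the census is exactly reproducible and independent of the
geometry seed; the only randomness is geometric (azimuth uniform on the
circle, insertion angle uniform in 70–90°), used for visualisation only.
Coordinates are right-handed, z up, trunk along +z; config angles in
degrees, radians internally.  Export writes an OBJ triangle mesh
(12-facet closed cylinders per internode, small triangular markers per
needle entity) plus a flat CSV of frames.

## Calibration

The 13 hidden parameters θ = (WUE, p_e1..4, p_a2..4, p_c, λ, R_p2..4) are
estimated from target records grouped by observable kind (internode
biomass/length/diameter, needle biomass at organ level for the oldest tree;
internode and needle compartment totals for younger ages).  Stage 1 is
bounded nonlinear least squares (trust-region reflective, from a
config-supplied start); stage 2 estimates each group's error variance from
the current residuals and re-fits the inverse-variance-weighted criterion;
stages iterate to a relative parameter change below 1e-6 (max 20
iterations, both in config), and non-convergence is flagged on the result
rather than raised.  Residuals are observed − simulated on the natural
scale; groups are assumed independent with common within-group variance.

Identifiability has a hard physical edge: λ multiplies ring weights by
1 − λ·(1 − A_above) and so moves any diameter by under 1% at its calibrated
value of 0.03 — consistent with the finding that needle position barely
affects ring partitioning.  Noise-free targets pin all 13 parameters to
numerical precision, but under 5% multiplicative noise λ (and to a lesser
degree the smallest sinks p_a4, R_p3, R_p4, which are drowned inside their
groups' common variances) cannot be recovered reliably; the test suite
records this limit honestly rather than hiding it.

## Synthetic data

The weather generator produces one 365-day year per call: a seasonal
sine for mean temperature (amplitude 18 °C, the regional January/July
contrast) with Gaussian jitter, jittered diurnal range for max/min,
clipped-Gaussian humidity/sunshine/wind, constant pressure from elevation,
Bernoulli wet days with exponential amounts boosted in July–August to a
prescribed summer share (default 0.45) and rescaled to hit the annual
total exactly.  Presets encode the seven reference years (e.g. 2007:
9.3 °C, 412.6 mm).  It reproduces annual statistics, not spell structure:
no wet/dry-spell persistence, no snow, no radiation extremes — so passing
tests certify the model's response to realistic annual regimes, not to any
particular observed sequence.  Target files come from forward simulation
with a chosen θ*, per-record lognormal factors exp(σZ) and configurable
replicate counts; all randomness flows from explicit seeds.

## Numerical choices and degenerate inputs

Depletion clamps are exact (no negative storage, no overdraft); K_s is
clipped to [0, 1]; ET_0 is clamped at 0; zero demand with positive supply,
zero ring weights with a positive pool, non-positive internode biomass and
out-of-range depletion all raise typed errors naming the offender.  A dead
seed (q0 = 0) is a fixed point: every ledger stays at zero.  Weather files
are written with %.17g and read with round-trip float parsing so ledgers
reproduce byte-for-byte across runs.  Allocation conserves mass to 1e-9
relative by construction (shares are computed from one common ratio).

## Problem sizes

The default study runs six cycles over six synthetic weather years
(~230-day seasons); a full simulation takes ~30 ms, the 21-point sweep
~2 s, a noise-free calibration ~2 s and the complete acceptance script
~3 s on one CPU.  Property suites use 1,000 seasons / 1,000 days / 500
censuses / 64 rule sets as stated in the tests.

## Known limitations

Single-layer soil, no root growth, no stomatal or canopy-conductance
control on transpiration, no respiration or senescence biomass loss, no
light competition (orientations are cosmetic), no source-sink feedback on
bud numbers, fixed one-year cycles without thermal-time modulation.  The
branching counts and q0 are placeholders pending field tabulation, and the
ring-repartition weight is a reconstruction kept behind a single function
(`growth.allocate_rings`) so an exact published form can replace it.
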