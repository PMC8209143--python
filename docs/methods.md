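# Methods

This note documents the model equations as implemented, the parameters that
matter, what the synthetic inputs emulate, and the numerical and design
choices made where the design was genuinely open.  Nothing here states an
empirical result that the test suite or `scripts/acceptance.py` does not
itself compute.

## Sward model

State: biomass m_x (kg DM ha⁻¹) for x ∈ {storage, root, leaf, stem}, total
plant nitrogen (kg N ha⁻¹), accumulated growing degree days and the derived
development state DVS ∈ [0, 1], and two seasonal flags (season active,
first cut done).

**Phenology.** ΔGDD accumulates max(0, T̄ − Ω_T,BASE) of the daily mean
temperature; DVS = min(ΔGDD/Ω_GDD, 1).  A separate from-January-1 GDD sum
triggers the season onset at a threshold (default 70 °C·d); at onset and at
every cut the entire storage pool is translocated into the other
compartments according to the current allocation fractions.  ΔGDD, DVS and
the first-cut flag reset at year end only — cutting does not reset
development, since the development state encodes the seasonal reproductive
progression rather than regrowth age.

**Allocation.** θ_storage = DVS·Ω_STORAGE; θ_root = (1 − θ_storage)·
Ω_ROOT·γ_cut/(Ω_ROOT·γ_cut + Ω_LEAF + Ω_STEM) with γ_cut = Ω_CUT (< 1)
before the first cut of the season and 1 afterwards.  The leaf/stem split of
the remainder is a proportional-controller step: the stem share of new
growth is clamp(2 s* − s, 0, 1) where s* = Ω_STEM/(Ω_LEAF+Ω_STEM) is the
target and s the current stem mass fraction.  This moves the standing ratio
toward the target without instantaneously re-partitioning existing mass,
whose adjustment dynamics are not otherwise constrained.

**Photosynthesis.** The canopy kernel is
GPP = a_max · a_rubisco · (1 − e^(−k·LAI)) · PAR/(PAR + I_50) · f_CO₂,
with f_CO₂ a Michaelis factor normalized to 1 at 400 ppm (K_C = 300 ppm) and
LAI = m_leaf·Ω_SLA/10⁴.  The kernel is deliberately contract-level — zero
without light/leaf area/rubisco activity, strictly increasing and saturating
in PAR, CO₂ and LAI, exactly multiplicative in a_rubisco — rather than a
full biochemical leaf model, because those are the properties the coupled
management behavior depends on.  a_rubisco = Ω_RUBISCO·f_drought·f_temp·
f_nitrogen with

* f_drought = 0 for ψ ≤ ψ_wilt, else min(1, (ψ−ψ_wilt)/(Ω_H2O·(ψ_field−ψ_wilt)));
* f_temp = clamp((T − 0.8 Ω_LIMIT)/(0.2 Ω_LIMIT), 0, 1) on hourly air
  temperature.  The ramp form is implemented as a two-sided clamp: written
  as a bare max it would be constant 1, which contradicts its stated role
  of inhibiting photosynthesis below the critical temperature; the clamp is
  continuous at Ω_LIMIT and zero below 0.8 Ω_LIMIT;
* f_nitrogen = min(1, (c_N,LEAF/Ω_NC,LEAF)^Ω_NDEF).

**Respiration and exudation.** R_g = Ω_YIELD·GPP, attributed to
compartments by θ_x.  Maintenance respiration per compartment is
R_m,x = m_x·c_DM·Ω_R,x·f_temp(T)·2^((T−Ω_T,REF)/10), averaged over the 24
hourly temperatures (c_DM = 0.45 kg C kg DM⁻¹ converts the biomass to
carbon so all fluxes share carbon units; the Ω_R,x are per-day
coefficients at the reference temperature).  Root exudation is
Ω_EXUDATE·θ_root·R_g — a fraction of the root-assigned growth respiration.

**Carbon budget and floors.** The daily net assimilate
A = GPP − R_g − ΣR_m − exudation is converted to dry matter by 1/c_DM and
allocated by θ.  When A < 0 the deficit is drained from storage first, then
proportionally from the other compartments; if the deficit would exceed the
total plant carbon, maintenance respiration is scaled down so the sward
cannot burn carbon it does not have.  The daily carbon residual is logged
and held below 10⁻⁹ relative by construction.

**Senescence.** S_x = max(f_s,drought, f_s,frost, f_s,age)·m_x, capped at
the available mass.  Air temperature drives frost senescence of leaf and
stem, topsoil temperature that of root and storage.
f_s,frost = Ω_SEN,FROST·|T| for T < 0 and 0 otherwise; f_s,age = Ω_SEN,AGE.
The drought rate declines linearly from Ω_SEN,DROUGHT as moisture rises and
is held at Ω_SEN,DROUGHT at and below wilting — a continuity correction: a
literal zero below wilting would make senescence vanish exactly where
drought stress is maximal.  Litter dry matter leaves the live pools; litter
nitrogen recycles into the slow soil organic pool.

**Nitrogen.** Demand is Σ m_x·Ω_NC,x.  Uptake = min(deficit, mineral pool,
daily cap Ω of 6 kg N ha⁻¹ d⁻¹).  Plant N is spread across compartments in
proportion to demand, so concentrations share one fill ratio and never
exceed the optima (surplus after mass loss returns to the mineral pool).

**Cutting.** Harvest removes leaf and stem above the configured residuals
(defaults 300 + 100 kg DM ha⁻¹) and exports N at current concentrations;
the first-cut flag flips γ_cut to 1 and storage is translocated.

## Soil

Water is stored per layer in mm; a tipping-bucket cascade drains everything
above field capacity to the next layer and out of the profile at the bottom.
Interception (capacity 1 mm d⁻¹) evaporates before infiltration.  PET uses a
Hargreaves-type temperature–radiation formula,
PET = 0.0135 (T̄ + 17.8) R_s[mm], because the weather generator provides no
humidity or wind for a combination equation; actual ET = min(demand, PET,
extractable water above wilting in the root zone), with demand =
PET·min(1, LAI/3) and extraction proportional to per-layer availability.
Root-zone moisture for the plant model is the thickness-weighted water
content over the top 30 cm (configurable).

Snow accumulates below 0 °C daily mean and melts at 2 mm °C⁻¹ d⁻¹; snow
cover insulates the soil (damping × 0.3).  Soil temperature relaxes
exponentially toward a running-mean air temperature with depth-dependent
damping d(z) = clamp(0.5·e^(−z/25 cm), 0.02, 1).

Mineral N is a single pool (no NO₃/NH₄ split, no leaching or gaseous losses
— only the N limitation of growth must be exercisable).  Slurry events add
the NH₄+NO₃+urea share (60 % by default) to the mineral pool and the DON
share to the slow organic pool; mineralization transfers
pool·rate·f_T(T)·f_ψ(ψ) per day, with f_T the same low-temperature ramp and
Q₁₀ shape as respiration and f_ψ a piecewise-linear optimum curve (0 at
wilting, 1 at 80 % of the plant-available range, 0.6 at field capacity).
The optimum-curve shape is this package's own choice; no canonical form was
prescribed.

## Management rules

Cut decision, once per day at end of day, on harvestable biomass
(leaf + stem − residual): cut when it reaches the target; else force the
first cut on the first evaluated day after DOY 150 and later cuts on the
first day ≥ 56 days after the previous cut; no cuts outside the season or
after DOY 305 (season end; a configurable closure the source rules imply
but do not state).  The target model is either the site-specific 75th
percentile regression (with a switch to use per-event maxima instead) or
the general per-cut fractions (default 0.30/0.25/0.20/0.15/0.10 — a
fixture shaped as a linear decrease over cut index and normalized to 1)
times the expected annual production, which the elevation regression
AGB = 159 − 0.058 h can supply.

Manure: the season-start application waits for DOY ≥ 32, bare and unfrozen
ground; each post-cut application waits for the first day with < 5 mm rain,
extending past the nominal 7-day window if every day is wet and aborting at
the next cut or season end (the all-wet case is not covered by the source
rules).  Applications after the nominal final cut index and beyond are
excluded by default, so a 5-fraction target model yields at most five
slurry events (240 kg N yr⁻¹) however many cuts occur — "no manure after
the last scheduled cut" cannot be decided online, so the nominal cut count
stands in for it.  The reduced-N policy allows only the season-start and
post-cut-1/post-cut-3 slots and scales per-event loads to keep the annual
total ≤ 170 kg N ha⁻¹.

## Weather generation and scenarios

Precipitation occurrence is a two-state first-order Markov chain per month
(wet-after-dry probability derived from the stationary wet frequency);
wet-day amounts are gamma (shape 0.75); tmax carries an AR(1) standardized
residual (ρ = 0.7) around *month-constant* means with monthly SDs, tmin
correlates with it (r = 0.8), and radiation is normal conditioned on the
wet/dry state, truncated at zero.  Month-constant means were chosen over a
fitted seasonal sinusoid so that long-run monthly means converge exactly to
the configured normals (a harmonic fit cannot honor all twelve monthly
targets); the AR(1) persistence smooths month boundaries.  The shipped
generator configuration targets a high-elevation pre-alpine site: March–
October mean near 10.8 °C and 1219 mm.

Hourly disaggregation: temperature follows a 24-h cosine with the minimum
at 04:00 and maximum at 16:00 (exact min/max and mean on integer hours);
precipitation is spread uniformly; radiation follows a half-sine over the
astronomical day length, rescaled to preserve the daily mean.  These curves
are declared substitutes — the disaggregation algorithms behind such
forcing are conventionally cited, not specified.

Scenarios hold monthly additive temperature deltas and multiplicative
precipitation factors at anchor years, linearly interpolated over the
horizon, plus a piecewise-linear CO₂ pathway (baseline fixed at 400 ppm;
the shipped moderate and strong pathways reach 538 and 936 ppm in 2100).
A linear bias-correction helper (t → a·t + b) supports transferring nearby
station records to a site.

## Orchestration and problem sizes

Daily loop order: snow partition → soil temperature → season bookkeeping →
phenology → hourly canopy fluxes (24-element vectors) → growth/allocation →
senescence → mineralization and N redistribution → water balance →
management decision → logging.  Spin-up replays the first two years of
forcing to equilibrate plant, water and N states and is excluded from all
outputs.  A 90-year run takes a few seconds; the test suite's heaviest
fixture (three 90-year realizations under three management modes on shared
weather) runs in about a minute, and the acceptance script in about two —
sizes chosen so the full evidence chain reruns comfortably on one CPU.

Determinism: every random draw flows from the user seed through
`numpy.random.default_rng`; identical configuration and seed reproduce
byte-identical outputs.

## Calibration

The species-mixture parameter vector is not identifiable from first
principles, and `scripts/calibrate_defaults.py` documents how the shipped
defaults were chosen: a small grid over canopy capacity (a_max), leaf
maintenance respiration, age senescence and the mineralization rate, scored
against (i) a present-climate decade with 4–5 cuts and ~10–11 t DM ha⁻¹
yr⁻¹ under dynamic management and (ii) qualitative late-century contrasts
(dynamic > static, dynamic > reduced-N).  Notable physical anchors that
emerged: total autotrophic respiration near half of GPP (leaf maintenance
0.015 d⁻¹), leaf age turnover of 0.6 % d⁻¹, and a soil N supply of roughly
100–200 kg N ha⁻¹ yr⁻¹ from mineralization.  The defaults are versioned
fixtures, not field measurements.

## What the synthetic data do and do not show

The generator and the deterministic synthetic years reproduce seasonality,
rain persistence, radiation–rain coupling and realistic magnitudes, but not
observed spell-length distributions, inter-annual modes, humidity/wind, or
site microclimate; passing tests therefore demonstrate internal consistency
and qualitative climate responses of the coupled model, not agreement with
any particular site record.  The phenology and cut-record fixtures are
labelled synthetic and exist to exercise readers, fits and statistics with
known ground truth.

## Known limitations

Single sward type — no species competition or functional-diversity
dynamics; no overwintering physiology beyond the seasonal reset; mineral N
is one pool without leaching or gaseous losses; the photosynthesis kernel
has no explicit temperature optimum above the low-temperature ramp, so
high-end warming responses lean on respiration and water limitation; PET
ignores humidity and wind; management magnitudes late in strong-warming
scenarios (cut counts, absolute yields) are model-specific — only the signs
and orderings of the scenario contrasts are claimed, and that is what the
acceptance checks assert.
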