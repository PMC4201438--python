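# Methods

## Overview

`mangal` couples two pieces of machinery that together estimate how long a
degraded mangrove stand needs to regain the standing biomass of a healthy
forest:

1. an individual-based, spatially explicit stand simulator in the
   field-of-neighborhood (FON) tradition of mangrove gap models, run for a
   single species (*Rhizophora apiculata*) on a 120 m × 120 m domain; and
2. the aggregation arithmetic of a Delphi expert survey (weighted Likert
   ranking, strict-majority consensus listing, plurality choice, and
   short/long-term stratification by country development level), whose
   intensity and spatial-scale scores parameterise the simulator's impact
   scenarios.

## Stand model

**State.** Each tree carries a position (m), a stem diameter at breast
height (dbh, cm), an age, and a five-year memory of relative diameter
increments. Height follows the parabolic height–diameter law
H(D) = 137 + b₂D − b₃D² with b₂, b₃ fixed so that H(0) = 137 cm and
H(d_max) = h_max = 5000 cm (50 m, the species' maximum). Above-ground
biomass is the power law B = s·D^t.

**Competition.** A stem of radius r (m) projects a FON of radius
R = a·r^b. The FON intensity is 1 over the stem cross-section, decays
exponentially to `fon_min` at R, and is 0 beyond. The competition index F
of a tree is the mean summed intensity of all *other* trees over its own
FON disc:

    F_k = (1/A_k) ∫_{FON_k} Σ_{j≠k} f_j(x, y) dA.

The integral is evaluated by midpoint quadrature on a fixed global grid
(default cell size 0.25 m; configurable). Cells outside the domain carry
zero intensity but still count toward the disc area, so border trees feel
proportionally less crowding — combined with the 10 m buffer band around
the sampled hectare this keeps edge effects out of the reported summaries.
At 0.25 m the quadrature is within 2–3 % of a 0.02 m brute-force integral
on few-tree configurations and within 1 % at 0.125 m; simulation results
are insensitive to this because F feeds a linear growth multiplier whose
parameters are themselves calibrated.

**Growth.** Annual diameter increment follows the JABOWA kernel

    ΔD = g·D·(1 − D·H/(d_max·h_max)) / (274 + 3b₂D − 4b₃D²),

multiplied by the competition factor max(0, 1 − c·F) and, inside an
impacted zone, by the scenario's growth-reduction factor. Growth is
monotone to a d_max asymptote in the absence of competition.

**Mortality.** Each year a tree whose five-year mean relative increment
falls below `suppression_threshold` dies with probability
`p_die_suppressed`. This single mechanism produces both competitive
self-thinning (suppressed subcanopy trees stagnate and die, but can be
released by a neighbour's death within their memory window) and
senescence (large trees approach the growth asymptote, their relative
increment collapses, and they die without an explicit age term). An
optional hard `max_age` cap exists for control experiments but is off by
default. Saplings are not exposed until their memory buffer holds five
years.

**Recruitment.** Seeds disperse at random: candidate positions arrive as a
Poisson process over the whole domain at 390 stems·ha⁻¹·yr⁻¹, are thinned
by the recruit factor of the zone containing them, and establish with
probability max(0, 1 − ΣFON) at their location — establishment is free on
bare ground and blocked under a closed canopy. Established saplings enter
at dbh 1 cm with an empty memory.

**Update order.** competition → growth → memory push → mortality →
recruitment → ageing, annually; each step is a pure function of the stand
and a seeded generator, so runs are bit-reproducible.

## Impact scenarios

An impact is a pair of Delphi-elicited scores on [0, 1]: intensity I and
spatial scale S. Applying it to an equilibrium stand

1. clears every tree from a strip covering fraction S of the sample
   hectare (single killing event; the strip extends through the buffer
   band at the same x-range), and
2. multiplies recruitment and growth inside the strip by a reduction
   factor during recovery.

Two readings of the reduction factor are provided. The **literal** mode
implements the scenario table's printed formula 1 − I·(1 − S). Because
that expression *weakens* the reduction as S grows (at S = 1 an impact of
any intensity leaves regrowth untouched), which sits oddly with clearing
the whole zone, a **zone_intensity** mode applying 1 − I inside the zone
is provided behind a config switch; outputs record which mode was used.
Monotonicity of recovery time in S at fixed I (and in I at fixed S) holds
in zone_intensity mode and is tested there; in literal mode it provably
fails for large S, and the default development scenario (I = 0.8, S = 0.8)
is nevertheless run in literal mode because that is the printed protocol.
A `thin` variant of the killing event (keeping each in-zone tree with
probability 1 − I(1 − S), the reduced-density reading) and a random-scatter
zone are available as options; clearing a contiguous strip is the default.

**Recovery time** is the number of annual steps until sample biomass
re-enters the 300–400 t/ha halting band, declared at the band's lower
edge (the halting rule is a band, not a point; 375 t/ha is the healthy
equilibrium within it). Runs are censored, not failed, at a configurable
horizon (default 200 yr), and censored replicates enter medians at the
bound with a flag.

## Experiment pipeline

A scenario experiment consists of: a 300-year spinup of a bare domain to
the healthy-forest state; one shared equilibrium snapshot; per-impact
replicates that re-apply the killing event with independent seeds and
simulate recovery; and the per-impact median recovery time. Sharing one
snapshot across replicates isolates impact-response variance and is
cheaper than per-replicate spinups (a config switch restores the latter).
The published protocol uses 100 replicates per scenario; the bundled
acceptance runs use 10 spinup seeds and 20 scenario replicates to fit a
single-CPU budget, which leaves the medians stable to well within the
sampling error the tests allow (disjoint 10-replicate batches agree
within 20 %).

## Calibration

The species constants that no source states (growth constant, FON scaling,
competition slope, suppression parameters, biomass allometry) form a
calibration surface anchored to the healthy-stand state: 1344 stems/ha,
31.89 m²/ha basal area, 300 t/ha initial biomass and a 375 t/ha stable
equilibrium. The biomass allometry is pinned analytically — 300 t/ha over
1344 stems gives 223 kg at the basal-area-implied mean diameter of
17.38 cm, so with t = 2.5 (typical of *Rhizophora* above-ground biomass
laws) s = 0.1772. The remaining constants were fixed by coordinate
exploration of 300-year spinups against those anchors;
`mangal.pipeline.calibrate` reproduces the procedure programmatically
(coordinate search minimising summed squared relative anchor error).

Two qualitative failure modes bracket the chosen defaults and motivated
them. With wide FONs and a steep competition slope (a = 10, c = 2) the
founding cohort locks into mutual suppression: thousands of stems sit at
zero growth, biomass plateaus an order of magnitude below the target.
Conversely, any parameterisation that holds total stem density at the
1344/ha anchor must block establishment under the closed canopy, and then
regeneration arrives only after synchronized senescence — the stand
oscillates with ±25 % biomass waves and the year-300 state depends on
wave phase. The defaults (a = 7, b = 0.5, fon_min = 0.2, c = 1.5,
threshold = 0.005 yr⁻¹, p = 0.3, g = 500, d_max = 45 cm) sit between: small
enough FONs for gap-phase, spatially decorrelated regeneration, strong
enough suppression for a stable plateau. The cost is a deliberate
compromise on the density anchor: the simulated stand holds ≈3000
stems/ha *counting every established sapling*, roughly half of them below
5 cm dbh; canopy-stem density and basal area (≈34–36 m²/ha) sit close to
the anchors. Field inventories that produced the anchor count measurable
stems, not first-year seedlings, so the tests hold the dbh ≥ 5 cm density
against the 1344/ha ± 25 % anchor and this note records the
interpretation.

Validation under the defaults (10 seeds): year-300 sample biomass 356–379
t/ha, median ≈ 365; all seeds inside the 300–400 band; a control
continuation stays inside the band for a further century; the development
scenario (I = 0.8, S = 0.8, literal) needs a median of ≈ 66 years to
re-enter the band, comfortably beyond the 40-year benchmark.

## Delphi aggregation

Likert votes (1–5) are weighted by their level and summed per option;
the percentage scale divides by the maximum attainable score (5 × votes),
so 100 % is a unanimous top rank and 20 % the floor. The published text
does not pin the normalisation; an alternative share-of-total-scores
normalisation is available behind a flag. Consensus species are those
with strictly more than 50 % yes-votes. Timeframe votes over the four
offered bins (0–10, 10–20, 20–30, > 30 yr) aggregate to short (< 20) and
long (> 20) term, stratified by the HD/LD classification of the
respondent's fieldwork country (bundled as an editable CSV seeded with
the published roster: 9 HD and 10 LD responses). Ranking ties are always
reported, never silently broken.

## Synthetic data

The raw expert responses were never deposited, so generators emulate
their structure for testing: vote tables draw each expert's level as
1 + ⌊5·σ(strength·(quality − ½) + ε)⌋ with option quality ~ U(0,1) and
logistic noise ε — exactly uniform over levels at strength 0 (the
σ(ε) probability transform is uniform) and increasingly peaked as
strength grows; impact sets draw (I, S) uniformly on the unit square with
an optional componentwise-dominant "development" impact; timeframe votes
are categorical draws; fixture stands have Poisson counts, uniform
positions and truncated-normal diameters. Generators are pure functions
of their seeds. They reproduce the *statistical shape* of the elicitation,
not the historical responses, so downstream tests demonstrate correctness
of the arithmetic and orderings, not agreement with any archived survey.

## Numerical choices and limitations

- Quadrature resolution 0.25 m (simulation), 0.125 m (oracle tests);
  trees processed in FON-radius buckets so sapling-heavy stands do not
  pay the patch size of their largest tree.
- The domain boundary is absorbing, not periodic: the killing strip and
  all summaries follow the buffered-sample design.
- Ties and degenerate inputs: empty stands summarise to zeros; an option
  with no votes has no percentage; plurality ties return no winner;
  recovery from a stand already inside the band is 0 years.
- Single species, no hydrology, salinity or climate forcing — impacts are
  abstracted entirely into (I, S) reductions, so mechanistic impact
  pathways (oil toxicity, hydrologic blockage) are out of scope.
- The year-300 biomass retains a weak founder-cohort wave (±5 % at the
  sampled phase); medians over seeds absorb it.
- Recovery times depend on the calibrated growth speed; their *ordering*
  across impacts is the robust output, the absolute years inherit the
  calibration's uncertainty.
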