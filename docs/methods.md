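# Methods

## The intactness model

The engine quantifies local terrestrial biodiversity intactness with the
mean species abundance (MSA) metric: a dimensionless value in [0, 1]
where 1 is a fully intact original species assemblage and 0 means every
original species has been extirpated. Two species groups are modelled —
vascular plants and warm-blooded vertebrates (birds & mammals) — each
responding to its own set of direct drivers:

| driver | covariate (units) | plants | vertebrates |
|---|---|---|---|
| climate change | global mean temperature increase, GMTI (°C) | ✓ | ✓ |
| nitrogen deposition | ND (kg N ha⁻¹ yr⁻¹) | ✓ | — |
| habitat loss | land-use class (categorical) | ✓ | ✓ |
| habitat fragmentation | habitat patch size PS (ha) | — | ✓ |
| habitat disturbance | distance D to nearest road/mine (m) | — | ✓ |

Every relationship is a logistic curve on a transformed covariate,
`MSA = 1 / (1 + exp(c0 + c1·f(x)))`, with `f` the identity (climate) or a
logarithm (nitrogen, patch size, distance). Habitat-loss relationships
are constants per land-use class; mines are assigned MSA = 0 exactly —
complete loss of biodiversity at the extraction site. The packaged
coefficients live in `src/msabif/data/response_curves.csv` and are taken
as given; refitting them is out of scope.

The written source of the relationships does not state the base of its
logarithms. We default to log₁₀, the convention for dose–response
covariates spanning orders of magnitude in this literature, and expose
`log_base` so natural-log users can switch; all documented worked values
assume log₁₀.

Per grid cell `i` and group `g`, the combined intactness is the product
over applicable drivers,

    MSA_g,i = ∏_x MSA_x,g,i ,

and the total loss `1 − MSA_g,i` is attributed back to drivers
proportionally to their individual deficits,

    MSA-loss_x,g,i = (1 − MSA_x,g,i) / Σ_x (1 − MSA_x,g,i) · (1 − MSA_g,i).

Subordination rules are encoded in a boolean applicability matrix that
acts *before* both the product and the attribution: nitrogen deposition
has no additional effect on plants in fertilized agricultural or urban
land; vertebrates in urban land feel only habitat loss and climate;
fragmentation applies only inside habitat (natural and plantation)
cells; disturbance applies everywhere except urban land. An excluded
driver therefore contributes neither intactness loss nor an attribution
share in that context.

## Grid conventions and numerical choices

* **Grid.** Abstract equal-area grids; cell width = √cell_area km; road
  geometry in km with the origin at the top-left, x along columns, y
  downward along rows. Water/no-data cells are not modelled.
* **Roads.** GRIP-style types 1–5; only types 1–3 (highways, primary,
  secondary) disturb wildlife. Rasterization splits each polyline at
  grid lines; a cell is a road cell iff a piece of positive length lies
  inside it, and each piece's length accrues to the country of its own
  cell, so border-crossing roads are split without double counting.
* **Patches.** Habitat = natural ∪ plantation minus road cells; barriers
  = converted land, mines and roads. Components are labelled under
  8-connectivity by default (4 available). A patch that touches no
  barrier cell — its only boundary is the domain edge — is treated as a
  window into an unbounded landscape and counts as unfragmented
  (fragmentation MSA = 1); reported patch sizes remain the literal
  member-cell areas.
* **Distances.** Centre-to-centre Euclidean distance between cells via
  an exact distance transform, not sub-cell geometry. Disturbance is
  confined to a 5 km impact zone; within overlapping zones the nearest
  feature wins, with an exact road/mine tie broken toward the mine
  (deterministic and documented; the underlying model only says
  "closest"). On-feature and near-zero distances are floored at
  `D_min` = half a cell width, because the log curve is undefined at 0.
* **Zero deposition.** ND = 0 means no impact (MSA = 1) rather than
  flooring ND into the log curve.
* **Degenerate attribution.** If no driver is active in a cell the
  attributed losses are all zero (the 0/0 share is not evaluated).
* **Zero-pressure countries.** A country without a land-use class, road
  network or deposition has a zero factor for that pressure — the
  pressure is absent, not undefined.

## Fragmentation decomposition

Fragmentation is caused jointly by land use and roads. To split it, the
engine performs the standard three runs — default; roads removed;
urban/cropland/pasture barriers removed — and splits the full-run loss
per cell proportionally to the two single-pressure losses. On a bounded
synthetic grid, however, a single-pressure run retains a residual
fragmentation signal even when its pressure is entirely absent, because
patch size is capped by the domain itself. A fourth, no-barrier baseline
run is therefore subtracted from both single-pressure losses before the
split. On a global grid the baseline vanishes (continent-sized patches)
and the procedure reduces to the plain three-run split; on synthetic
windows it guarantees that an absent pressure receives no share. If both
excesses are zero where the full-run loss is positive (possible when
mines are the only barrier), the split falls back to 50/50 with a
warning.

## Impact factors

Country-level biodiversity impact factors (BIFs) integrate attributed
losses over area (and time for emissions) per unit of pressure:

* **CO₂** (MSA-loss·km²·yr·kg⁻¹): `IAGTP_CO2 · Σ_i loss_CC,i·A_i / GMTI`,
  with IAGTP = 47.6·10⁻¹⁵ °C·yr·kg⁻¹ for the default 100-year horizon
  and GMTI required to equal the engine-run input (default 1.26 °C, the
  2020 warming level). Climate is well mixed, so the factor is global
  and replicated per country.
* **NH₃ / NOₓ** (MSA-loss·km²·yr·kg⁻¹, plants only): each receiving
  region's loss-area per kg of N deposited, weighted by the emitting
  region's source–receptor fractions and scaled by the nitrogen-ion
  conversion factor (NH₃: 14/17 ≈ 0.82; NOₓ at 90 % NO₂ / 10 % NO:
  0.90·14/46 + 0.10·14/30 ≈ 0.32). Countries inherit their region's
  value. The conversion factor is algebraically independent of the
  receiving region and is applied as a common factor.
* **Land use** (MSA-loss·km²·km⁻²): the class-caused loss anywhere in
  the country divided by the country's area of that class. Habitat-loss
  losses sit in the class's own cells; mine-disturbance losses are the
  disturbance losses of cells whose nearest feature is a mine;
  land-use-caused fragmentation losses (from the decomposition) are
  split equally among the fragmenting classes (urban, cropland,
  pasture) present in the country — the underlying model does not
  allocate fragmentation among barrier classes, so an equal split is
  the least-informative choice and is configurable in principle.
* **Roads** (MSA-loss·km²·km⁻¹): road-caused fragmentation and
  disturbance loss-area divided by the country's total type 1–3 road
  length.

Per-driver factors are emitted alongside pressure-level `all`
aggregates; combined-group factors are arithmetic means of the plant
and vertebrate factors with zero substituted for a group a driver does
not affect.

**Exact zonal aggregation.** The per-country ratios (loss-area over
pressure extent) are accumulated in exact rational arithmetic
(`fractions.Fraction`) and rounded to a double only once, at the final
division. Floating-point summation makes a ratio of constant per-cell
values depend at the ulp level on how many cells a country happens to
contain; exact accumulation guarantees that factors which are
analytically constant across countries (e.g. plant habitat loss in
cropland under uniform warming) are bit-identical in the output. Grid
sizes here (≤ ~10⁴ cells per country) make the exact path cheap.

## Footprint application

Emission and land-occupation entries multiply their factor directly
(kg × MSA-loss·km²·yr·kg⁻¹; km²·yr × MSA-loss·km²·km⁻²). Road impacts
are allocated to an actor by its share of the region's transport fuel
use, `BF = BIF_R · RL · T · FU_actor/FU_region` with the duration of
road use `T` defaulting to 1 year, or converted to per-ton-km /
per-person-km factors through the activity's fuel intensity. Greenhouse
gases other than CO₂ — or other horizons (20/500 yr) — scale the default
CO₂ factor through the packaged gas × horizon table
(`src/msabif/data/ghg_conversion.csv`, shipped as given; the underlying
warming potentials are not recomputed here). An inventory should carry
non-CO₂ gases either pre-converted to CO₂-equivalents or by name through
this table, never both, to avoid double counting.

## The synthetic-data generator

`synthetic_world` produces worlds with the structure the real inputs
have, so that every downstream stage is testable without external data:

* countries as contiguous rectangular blocks (a Voronoi option exists
  for irregular shapes); each country maps to one emission region,
  by default its own;
* land use sampled independently per cell from the spec fractions
  (defaults: 60 % natural, 15 % cropland, 10 % pasture, 10 % plantation,
  5 % urban), plus a fixed number of single-cell mines (default 4);
* roads as straight two-point polylines inside each country's bounding
  box, with per-type Poisson segment counts (defaults: 1/2/3 expected
  type-1/2/3 segments and one each of types 4–5 per country);
* deposition as a Gaussian-smoothed exponential random field rescaled
  to a target mean (default 5 kg N ha⁻¹ yr⁻¹, a mid-range terrestrial
  deposition level; correlation scale 5 cells);
* GMTI defaulting to 1.26 °C;
* row-substochastic source–receptor matrices with a prescribed
  self-deposition fraction and a random share of the remainder spread
  over other regions (the rest deposits outside modelled land).

All randomness derives from a single seed through named substreams, so
identical specs give bit-identical worlds. What the generator does *not*
emulate: spatially autocorrelated land-use mosaics, realistic road
topology (networks, curvature), latitude-dependent cell areas, water
masks, and any real-world geography. Passing tests therefore demonstrate
the correctness of the model mechanics and the factor algebra, not the
reproduction of published country values, which depend on the real
global input stack.

## Problem sizes

Default test and validation runs use 30×30 to 50×50 grids with 1–4
countries; the conservation suite covers 50 random 50×50 worlds and the
oracle suites 100 random grids up to 40×40. A full pipeline on a
100×100, 4-country world (simulate → MSA run → factor derivation →
footprint) completes in roughly a second on one CPU; the sizes were
chosen because the model's properties under test (conservation,
subordination, constancy, decomposition additivity) are scale-free.

## Known limitations

* Table-driven response curves are universal: a given pressure causes
  the same loss everywhere, so no spatial gradients in community
  composition are represented.
* Climate and nitrogen curves return MSA < 1 at zero pressure as
  printed; no renormalization to anchor MSA = 1 at zero pressure is
  applied (the raw curves are used as published).
* No uncertainty quantification on factors; no recovery dynamics after
  pressure release; direct exploitation (hunting) is excluded.
* Mine-caused disturbance uses the road disturbance curve (no
  mining-specific relationship exists) and applies in the same land-use
  contexts as road disturbance.
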