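# Methods

This note records the models implemented, the conventions and numerical
choices behind them, and what the synthetic generators do and do not
emulate.

## Trophic levels from diets

A food web is wired by the diet-composition matrix `DC`, `DC[i, j]` being
the fraction of prey *i* in the diet of predator *j* (columns sum to 1
together with any imported diet). Fractional trophic levels satisfy
`TL_i = 1 + Σ_j DC_ji·TL_j` with producers and detritus pinned at 1.
Rather than iterating this recursion we solve the consumer block
`(I − A)·TL = rhs` directly (`A` the consumer-on-consumer diet transpose),
which is exact for webs with cycles — mutual predation and cannibalism —
provided the spectral radius of `A` is below 1; a radius at or above 1
(e.g. a fully cannibalistic column) is reported as a degenerate cycle.
Conventions: detritus is a role, not a producer — it receives flows but
has no diet; imported diet is assigned TL 1 because its trophic history is
untracked.

Diet columns from several studies are pooled by a weighted mean with
renormalisation (weights default equal; sample sizes are the natural
choice). Density-based pooling methods exist in the literature but do not
reduce to a closed formula; the pooling function accepts per-study weights
as the extension point.

## Catch indicators

- **MTL** is the catch-weighted mean of species trophic levels per year.
  Species without a catalogue entry are excluded from both numerator and
  denominator — assigning them a default TL would bias the index — and a
  coverage fraction (usable catch over total catch) is reported instead.
- **FiB** uses base-10 logarithms throughout and transfer efficiency
  `TE = 0.1` (the conventional cross-ecosystem mean) unless overridden.
  Both terms are evaluated with the same log implementation so the
  reference year is exactly zero in floating point. The reference year
  defaults to the first year of the series and is configurable.
- **Region decomposition (RMTL).** After a fleet expands, the original
  region is assumed (1) still fished and (2) in trophic balance relative
  to the last pre-expansion year `n1`. Its catch follows
  `Ŷ¹_k = Y_{n1}·(1/TE)^(MTL_{n1} − MTL_k)` and its MTL the FiB = 0 line
  `MTL̂¹_k = MTL_{n1} − log10(Y_k/Y_{n1})/log10(1/TE)`; the expanded region
  takes the residual catch, and its MTL is recovered from the mass-weighted
  identity `MTL_k·Y_k = Σ_r MTL̂ʳ_k·Ŷʳ_k`. When assumption (1) fails in the
  data the residual can go negative; it is floored at zero and the year is
  flagged `assumption violated` rather than silently propagated. A zero
  residual leaves the expanded-region MTL undefined (NaN, flagged). With
  more than one breakpoint the same construction cascades, each new region
  freezing its state at its own breakpoint year as the reference. The
  default breakpoint treats 2007 as the last original-area year, i.e. an
  original area 2000–2007 and an expanded area from 2008.
- **Quadrants.** Fishing positions are gridded on a 30-arc-minute lattice
  anchored at integer degrees with half-open bands, cells indexed by the
  signed floor of `coordinate/0.5°` — reproducible and hemisphere-safe for
  the study window (~21–34° S). Cell areas use a spherical Earth at the
  cell-centre latitude (111.32 km per degree). Biomass density divides the
  summed catch by the total area of quadrants visited that year.
- **Effort** indices (days at sea, fishing days, hauls) are yearly totals
  per fleet relative to the reference year.

## Mass balance

Each non-detritus group obeys
`B_i·PB_i·EE_i − Σ_j B_j·QB_j·DC_ij − Y_i − EX_i = 0` (production used in
the system equals predation plus fishery removals and exports). Exactly
one of {B, PB, EE} may be unknown per group; each equation is linear in
its group's unknown and, through the predation term, in other groups'
unknown biomasses, so all unknowns assemble into a single linear system
solved simultaneously — groups with unknown EE reduce to one equation
each, mirroring standard practice for this model family. A group whose
balance equation is vacuous (nothing eats it, no catch, no export) is
reported as structurally unsolvable by name. Solved EE outside [0, 1]
marks the group `unbalanced`; it is returned, not hidden. A parameter
table may also supply EE as an input and leave B or PB to be solved — the
solver accepts either orientation. Detritus has no production equation of
its own; any supplied detritus P/B is ignored with a warning, since its
balance follows from inflows.

Derived attributes (per group): predation mortality
`M2_i = Σ_j B_j·QB_j·DC_ij / B_i`; gross efficiency `P/Q = PB/QB`; omnivory
index `OI_i = Σ_j DC_ji·(TL_j − (TL_i − 1))²`, the diet-weighted variance
of prey trophic levels (zero for producers and single-prey consumers; the
import fraction counts as a TL-1 item); flow to detritus
`B·PB·(1 − EE) + B·QB·u` with the unassimilated fraction `u = 0.2` by
default (the conventional value for fish; configurable); net efficiency
`PB/(QB·(1 − u))`; `F = Y/B`, `F/Z = Y/(B·PB)` and proportion natural
mortality `1 − F/Z`. Biomass accumulation is treated as a pass-through
input defaulting to 0.

**PPR.** The primary production and detritus flow required to sustain the
catches is computed by enumerating every simple diet path from each caught
group down to producers/detritus (depth-first, cycles cut at the first
repeated node, contributions below 1e−12 pruned). Two conventions are
provided because the normalisation differs between published forms: the
default scales each caught group's contribution by `Y_i/P_i` with per-link
factor `(Q_j/P_j)·EE_j·DC`, and a classic raising-factor alternative
(`convention="raising"`) uses the raw catch with per-link `(Q_j/P_j)·DC`.
Both are nonnegative and linear in the catches. No wet-weight-to-carbon
conversion is applied; PPR is reported in the flow units of the inputs.

## Mixed trophic impacts and keystones

The direct impact of *j* on *i* is `q_ij = DC_ij − FC_ji`: the fraction of
*i*'s diet supplied by *j* (bottom-up benefit) minus *j*'s share of the
total predation and removal on *i* (top-down cost), the shares computed
from the `B·QB·DC` consumption flows. Fishing fleets can optionally enter
as impacting columns through their share of removals. Total impacts
propagate over all interaction paths as the Leontief-type series
`m = q + q² + … = (I − q)⁻¹ − I`. The inverse is returned whenever
`(I − q)` is nonsingular; when the spectral radius of `q` reaches 1 the
power series formally diverges and a warning is issued (the inverse is its
analytic continuation, and is the construction used by the standard
software for this model family — a strict truncated series is available
via `method="series"`). A singular `(I − q)` raises.

Keystoneness uses the overall effect `ε_i = sqrt(Σ_{j≠i} m_ji²)` (diagonal
excluded) against biomass on log axes: x = log₁₀B, y = log₁₀ε². The plane
is split at the medians of both axes, with an intermediate band of half an
interquartile range (±IQR/4) around each split; quadrants map to keystone
(high impact, low biomass), high-impact–high-biomass,
low-impact–low-biomass and low-impact–high-biomass, and points inside a
band are intermediate. Median/IQR splits make the rule data-driven,
scale-free on the log axes and invariant under group reordering; the band
fraction and thresholds are configurable. Groups with zero biomass or zero
effect have undefined logs and are excluded with a warning.

## Life-history estimators

- `L_t = L∞·(1 − e^(−K·(t − t0)))` (lengths cm, ages yr).
- Pauly: `log10 M = 0.654·log10 K − 0.279·log10 L∞ + 0.463·log10 T`, T in
  °C. The temperature term is interpreted as base-10 log of T, the
  standard form of this regression.
- Hoenig: `Z = exp(a + b·ln Tm)`, a = 1.46, b = −1.01 for fish; a = 1.23,
  b = −0.832 for mollusks. Natural log, as in the source regression.
- Palomares–Pauly:
  `log10 Q/B = 7.964 − 0.204·log10 W∞ − 1.965·T′ + 0.083·Ar + 0.532·H + 0.398·D`
  with `T′ = 1000/(T + 273.15)`; the default temperature is 23.4 °C, the
  study-system mean, and is a parameter. The caudal-fin aspect ratio
  `Ar = h²/S` may be given directly or via fin height and surface area; a
  >1% mismatch between the two raises.
- Under equilibrium `P/B = Z = M + F`; `F = Z − M` is clamped at zero and
  flagged when a supplied M exceeds Z.

All four estimators are positive, continuous and monotone in each argument
with the signs of the printed coefficients (asserted numerically in the
test suite).

## Synthetic generators

`generate_catch_series` emulates the structure the indicators assume: an
ice fleet fishing a southern region every year over 2000–2016, and from
the 2008 expansion year a refrigerated-brine fleet (plus part of the ice
fleet) opening a northern region with a distinct species pool and
trophic-level mix. Per-record catches are lognormal (landings are positive
and right-skewed) around fleet means of 80 t (VIC) and 160 t (VRB) with
log-sd 0.6, 120 records per year in the original region and half that in
the expanded one; positions are uniform inside per-region coordinate
boxes so the quadrant gridding is exercised. The default timeline mirrors
the documented fishery (reference year 2000, expansion 2008) so outputs
read naturally; no numeric reproduction of the real series is claimed.
What it does **not** emulate: oceanographic drivers, within-year spatial
autocorrelation, vessel-level heterogeneity, misreporting. Passing tests
therefore demonstrate correctness of the index arithmetic and the
decomposition identities, not realism of any particular trajectory.

`generate_two_region_series` builds aggregate yearly (Y, MTL) series in
which the decomposition's two assumptions hold *exactly*: region 2 has a
fixed configured MTL and a slowly growing catch, and each year's totals
are resolved by fixed-point iteration (to 1e−13) so that region 1
simultaneously satisfies the balance catch relation and the FiB = 0 MTL
line. On these series the decomposition must recover the configured
region-2 MTL to numerical precision, which is the package's strongest
internal check of the RMTL algebra.

`generate_foodweb` draws TL-ordered groups (detritus, producers,
consumers), dense Dirichlet diets over lower-indexed groups (acyclic, with
optional small cannibalism), P/B and Q/B from ranges bracketing coastal
pelagic model magnitudes (producer P/B 20–120 yr⁻¹, consumer P/B 0.3–8
yr⁻¹, gross efficiency 0.1–0.35), then *back-solves biomass* from a drawn
target EE per group in reverse trophic order, giving the apex group a
small catch so its EE is positive. Every generated web is therefore
exactly balanced with all EE inside (0, 1) by construction, and the solver
round-trip (blank one parameter per group, re-solve, compare) closes to
1e−9 relative. Sizes of 5–15 groups are used in the round-trip tests —
large enough to couple many unknowns through predation, small enough that
200 webs solve in seconds.

## Numerical choices

- All linear solves go through `numpy.linalg.solve`; spectral radii via
  `numpy.linalg.eigvals` on webs of at most a few dozen groups.
- Diet-column sums are validated to 1e−6; trophic-level and balance
  residual tolerances are 1e−9 (relative to `max(1, B·PB)` for balance).
- The path-sum oracle used to validate impact propagation accumulates
  matrix powers to length 50; comparisons are made on webs with spectral
  radius ≤ 0.6, where the truncation tail (≲ ρ⁵¹/(1−ρ) ≈ 1e−11) is far
  below the 1e−9 comparison tolerance.
- Degenerate inputs are signalled, not patched: empty diets, all-unknown
  groups, zero visited area, zero usable catch and unknown fixtures all
  raise with the offending name in the message.

## Known limitations

- The mass-balance stage is static; no dynamic (time-forward) simulation
  or spatial variant is provided.
- PPR unit conventions differ across the literature; both implemented
  forms are exposed and documented, but no carbon conversion is applied.
- The keystone rule is a transparent median/band classifier, not a fitted
  classification tree; with strongly clustered clouds the intermediate
  band can absorb genuine corner points (widen or narrow via the band
  fraction).
- Diet pooling is a weighted mean; full density-based pooling with error
  ranges is out of scope.
- GAM-type trend fitting and multivariate period comparisons of model
  outputs are deliberately out of scope — they are standard statistics
  available elsewhere.
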