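# Methods

## The model

Floating catchment area (FCA) methods measure potential spatial
accessibility as a two-stage allocation of supply to demand over travel
time. Facility *i* has capacity *S*ᵢ (beds); population point *j* has
count *P*ⱼ; *d*ⱼᵢ is the (symmetric) travel time in minutes between them.
Both methods in this package run in four steps over a common search grid
*t* ∈ {*t*₀, *t*₀+Δ*t*, …, *t*_max}.

**Steps 1–2 (catchment sizes).** The enhanced-variable method (EV2SFCA)
grows each facility catchment *C*ᵢ until the unweighted
facility-to-population ratio *S*ᵢ / Σ_{d≤t} *P*ⱼ falls to the threshold
FPRT₁; the saved ratio at *C*ᵢ is FPRᵢ. Each population catchment *C*ⱼ
grows until Σ_{d≤t} FPRᵢ reaches FPRT₂. Because capacity sits in the
numerator of the stopping criterion, *C*ᵢ scales with bed count — the
method's defining feature. The variable-catchment baseline (V2SFCA)
instead grows supply catchments to a fixed base population BP (making them
capacity-invariant) and demand catchments to a target provider-to-population
ratio PPR.

**Steps 3–4 (scoring).** The discounted ratio and accessibility score are

    D_i = S_i / Σ_j P_j ω(d_ji),    A_j = Σ_i D_i ω(d_ij),

summed over *eligible* pairs. The enhanced method requires mutual
containment — *d* ≤ *C*ᵢ **and** *d* ≤ *C*ⱼ — so that a pair is scored
only when each side's catchment actually reaches the other location. The
baseline is one-sided: Step 3 uses *d* ≤ *C*ᵢ alone and Step 4 *d* ≤ *C*ⱼ
alone, which is exactly where the two methods' scores diverge.

Steps 1–2 deliberately use unweighted sums; decay weights appear only in
Steps 3–4, where the scoring formulas call for them.

## Parameters

| parameter | default | meaning |
|---|---|---|
| t₀ | 5 min | initial catchment size |
| Δt | 1 min | search increment |
| t_max | 120 min | travel-time cap; searches that never meet their threshold stop here, flagged `capped` |
| FPRT₁ | 135/50,000 = 0.0027 | facility-side stopping ratio (beds per reachable person) |
| FPRT₂ | 30/1000 = 0.03 | demand-side target (beds per person) |
| BP | 50,000 | baseline base population |
| PPR | 30/1000 | baseline demand target |
| β | 1 | Gaussian decay shape exponent |
| zone weights | (1.00, 0.42, 0.03) | stepwise decay, equal-width zones |

Smaller FPRT₁ forces facilities to gather more demand, so catchments grow;
larger FPRT₂ widens demand catchments and (in a fixed system) can only add
eligible facilities. Both directions are enforced by property tests.

## Decay

The continuous family is the catchment-normalized truncated Gaussian

    ω(d, C) = [(e^{−d²/2C²} − e^{−1/2}) / (1 − e^{−1/2})]^β,  d ≤ C,

which equals 1 at d=0 and 0 at d=C for every catchment size, so the weight
is continuous across the catchment edge and comparable between sites with
different catchments. β is a shape exponent (β>1 sharpens decay). An
un-normalized `gaussian_raw` variant e^{−d²/β} is available behind the same
interface for experimentation; it is discontinuous at the edge and its β
has units of minutes². The stepwise family splits the catchment into K
equal-width zones with fixed weights; zone intervals are half-open (lo, hi]
with the boundary assigned to the inner (higher-weight) zone. With a
45-minute catchment the default weights give 1.00 within 15 min, 0.42 from
15–30, 0.03 from 30–45.

Which catchment parametrizes ω is genuinely open in this method family:
by default Step 3 uses the facility's *C*ᵢ and Step 4 the population's
*C*ⱼ (`weight_param="own_catchment"`, the standard 2SFCA convention). A
`symmetric_min` mode uses min(*C*ᵢ, *C*ⱼ) on both sides; it is the only
choice under which the conservation identity below holds exactly for a
non-trivial decay.

## Numerical and edge-case choices

- **Inclusive comparisons everywhere.** Distance eligibility is d ≤ C
  (boundary pairs count), and threshold attainment is FPR ≤ FPRT₁ /
  Σ ≥ FPRT₂. The descriptions of these stopping rules in the literature
  are ambiguous at equality; inclusive stopping is the documented default
  and `strict_thresholds=True` switches both to strict inequalities
  (which can only delay stopping — property-tested).
- **Empty windows.** A facility with zero reachable population has
  FPR = ∞ (sentinel): the facility search continues (and caps, flagged and
  logged), and if such a facility enters a population's window its summand
  satisfies FPRT₂ immediately — a defined, testable degeneracy rather than
  a division-by-zero.
- **Caps.** A catchment that never meets its criterion is set to t_max and
  flagged, not dropped; capped facilities' FPRᵢ (possibly ∞) still enter
  Step 2, with a log warning.
- **Empty eligible sets.** D_i = 0 when nobody can reach a facility;
  A_j = 0 exactly when a population has no eligible facility.
- **Determinism.** Sites are processed in sorted-id order; OD matrices
  store one undirected time per pair; outputs print with 10 significant
  digits.

**Conservation diagnostic.** When the weight on a pair is the same number
in Step 3 and Step 4 (decay `none`, or `symmetric_min` with the same
constraint set on both steps), the double sum telescopes:
Σⱼ *P*ⱼ*A*ⱼ = Σᵢ *S*ᵢ over facilities with at least one eligible pair —
every served bed is allocated exactly once. `conservation_check` reports
this ratio (1 ± 1e-9 in tests); under `own_catchment` weights with
*C*ᵢ ≠ *C*ⱼ it drifts from 1 and is reported, not asserted.

## Travel times

OD matrices can be supplied directly (long CSV) or built from a classed
road network: per-edge minutes = length/speed with standard speeds of
60 km/h (expressway), 50 (main), 40 (secondary), 30 (other); sites snap to
the nearest network node with zero access time; pair times are Dijkstra
shortest paths truncated at t_max, symmetric because the graph is
undirected. The snapping and access-cost conventions are explicit package
choices — commercial OD tools do not document theirs — so OD files are
reproducible from the inputs.

## Synthetic city

The generator emulates a monocentric city: population counts follow
`density_scale · exp(−r / density_decay_m)` on jittered grid points inside
a disc (defaults: 200 points, 4,000 persons at the center, 8 km length
scale, 20 km radius); facilities (default 20) are placed with a
center-biased radial draw; capacities (20–800 beds) come from a
heavy-tailed log-interpolated draw **independent of location**, so any
downstream capacity–catchment correlation is attributable to the
algorithm, not the generator. A square road grid (2.5 km spacing) carries
faster classes in inner rings. Everything is driven by one mandatory seed;
identical parameters and seed give byte-identical CSVs.

On the default city (seed 1) the enhanced method reproduces the
qualitative behaviour expected of it: facility catchments rank-correlate
positively with capacity (Spearman ρ ≈ 0.80, p ≈ 2×10⁻⁵) while the
baseline's supply catchments are exactly invariant under capacity
permutations, and mean catchments are smaller in the core quartile than in
the periphery (facilities ≈ 11 vs ≈ 55 min). These are direction claims on
one synthetic configuration: the generator has no multi-centric structure,
no correlation between capacity and location, no congestion, and no
behavioural demand model, so passing tests demonstrate algorithmic
properties, not calibration to any real city.

## Problem sizes

Tests and the acceptance script run the full pipeline at desk scale — the
2×2 worked instance, 100–500 randomized instances up to 5×5, and the
200-population/20-facility default city — chosen so the whole suite
completes in seconds while still exercising every code path, including
caps, degeneracies and disconnected pairs.

## Known limitations

- Facility-side and demand-side competition beyond the FPR mechanism
  (e.g. three-step FCA adjustments, Huff choice probabilities) is out of
  scope, as are kernel-density decay variants.
- Coordinates are assumed projected planar meters; no CRS handling.
- The road model ignores one-way streets, turn penalties and congestion.
- Non-spatial access factors (fees, quality, staffing) are not modelled.
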