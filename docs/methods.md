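# Methods

## Coordinate model

The worm body is modelled as a straight cylinder of radius `r` and
centerline length `L`; every skeleton node lives on its surface in
coordinates `(s, θ)` with `s ∈ [0, L]` the axial position (0 = anterior
tip) and `θ ∈ [0, 2π)` the circumferential angle. Distances are geodesics
on the cylinder, `ds² = dS² + (r·dθ)²`, with angular differences always
taken as the shortest wrapped arc in `(−π, π]`. The reference frame is set
by the dorsal-midline angle: the lateral line carrying the soma and primary
dendrite sits a quarter turn ventral of it, and the ventral nerve cord is
antipodal to the dorsal midline. Unrolling maps `(s, θ)` to the plane as
`u = s`, `v = r·wrap(θ − θ_lateral)`; the cut seam is antipodal to the
lateral line so the arbor, which straddles that line, never wraps. The
model deliberately ignores body taper, bending, and the head/tail caps —
skeletons are assumed already projected onto the cylinder (nodes more than
2% of `r` off the surface are rejected on SWC import, which catches unit
mistakes early).

SWC interchange lays the cylinder axis along `x`. Branch orders survive a
round trip through the SWC type column (1°–4° → 3–6, axon → 2, trapped 2° →
7, AIS → 8) but only in files carrying an explicit header marker; vanilla
type codes in third-party files are treated as hints for the classifier,
never as final labels.

## Synthetic arbor generator

The generator emulates the menorah lattice: candidate 2° sites are laid out
at fixed spacing along the primary dendrite (three quarters anterior to the
soma, matching the anterior-dominant arbor), and each site decides
independently per dorsal/ventral side whether it branches
(`p_branch`), becomes a trapped 2° running along the primary axis
(`p_trapped`, conditional on failed branching), or stays bare. A branched
site sends a stem to the sublateral line and grows a 3° base
bidirectionally; facing tips of neighbouring bases meet at their midpoint
when within reach (`max_tertiary_extent_um`, default one inter-site
spacing) and the meeting resolves by self-avoidance with probability
`p_sa` — both tips retract, leaving a gap of `gap_um` — or persists with an
overlap drawn uniformly on `[0, spacing/4]` (the real overlap-length
distribution is unknown; this choice only matters for overlap rendering,
not for any counted statistic). 4° candles are placed by a Poisson process
along each base and reach toward the dorsal/ventral cord lines. A single
process from the soma to the ventral cord plays the axon, its first segment
the AIS.

Defaults (all lengths μm): 16 sites at spacing 30, `p_branch` 0.95,
`p_trapped` 0.1, `p_sa` 0.95, gap 5, sublateral offset 20, candle rate
0.15/μm, positional jitter s.d. 0.5 on site positions and candle termini.
The body is 1000 μm long with radius 25 μm, soma at 650 μm, mouth at
20 μm — typical young-adult proportions. Presets move only the three
probabilities: `wildtype_like` (0.95/0.05/0.95 for branch/trapped/sa),
`gk8_like` (0.30/0.85/0.90, branching failure with trapping),
`xr58_like` (0.95/0.05/0.25, intact branching but failed self-avoidance),
`dma1_oe_like` (0.60/0.30/0.50, both degraded). The presets are chosen to
reproduce the *direction and separability* of the phenotypes, not any
particular measured value.

Two exact laws follow from the construction and anchor the tests: with all
sites branched and `p_sa = 1`, each side carries `M−1` gaps of exactly
`gap_um` between its `M` menorahs, so TBAI = `(M−1)/M` per side; with
`p_sa = 0`, TBAI = 0. Tertiary bases are kept exactly on the sublateral
line (jitter applies to site positions and candle termini, not base arcs),
which keeps these laws exact under the default jitter as well.

Determinism: every stochastic decision draws from a substream keyed by
`(seed, side, site, purpose)`, so identical parameters and seed reproduce
identical arbors node for node, and individual site decisions are
insensitive to unrelated parameter changes.

Ground truth records the true order of every edge, every contact event with
its resolution, menorah membership, and the landmark list (2° and 4° branch
points plus retracted contact points). What the generator does *not*
emulate: growth dynamics over developmental time, tapered or bent bodies,
tracing noise beyond Gaussian jitter, missing or spurious branches from
segmentation error, and multi-neuron scenes. Passing tests therefore
validate the measurement machinery on idealised skeletons, not robustness
to tracing artifacts.

## Branch-order classification

Each edge is scored axial or circumferential from its total displacement
vector (threshold 45°: whichever component dominates); per-segment tangents
would be noisier. The maximal axial path through the soma is the primary
dendrite (at each branch point the most-axial child continues it). Orders
then alternate: a branch leaving an order-n path orthogonally gets order
n+1; a branch continuing in the same orientation keeps order n; exact ties
resolve to n+1, since the alternation is the lattice's own prior. The soma
process whose first edge is circumferential and whose subtree reaches the
ventral cord line (within `trapped_radius_um`) is the axon, first segment
AIS; an SWC type-2 hint breaks ties, and residual ambiguity is an error
rather than a guess. A 2°-rooted subtree that stays within
`trapped_radius_um` (default 5 μm) of the primary line *and* turns axial is
relabeled trapped-2° wholesale. Axial branches off the primary that are not
its continuation, and anything deeper than 4°, stay `unassigned` and are
reported, not guessed.

A menorah is one 2° stem bearing at least one 3° edge; stems without a base
are counted as secondary but not as menorahs, and abutting or overlapping
menorahs still count one per stem.

## Morphometrics

**Adjacency.** Tertiary branches form a linear array per side, so adjacency
is defined by ordering menorah bases along the sublateral line by projected
midpoint; each consecutive pair is scored once. The pair's gap is the
geodesic between the facing base endpoints when their axial intervals are
disjoint, and the (negative) interval overlap otherwise. A gap above the
visibility threshold ε (default 0.5 μm ≈ optical resolution; configurable)
counts as a visible gap, at or below ε as contact/overlap — so gaps and
overlaps exactly partition the pair set by construction.

**TBAI** = visible gaps / menorah count, sides pooled, whole arbor by
default (whether the original index pooled sides or included the posterior
arbor is not specified anywhere authoritative; both are config switches).
A windowless arbor with no menorahs raises an undefined-statistic error
rather than returning 0, so cohort tables distinguish "no data" from
"zero". Overlapped-3° counts use a 200-μm anterior window and mean gaps a
150-μm anterior window by default.

**Zones.** The menorah coverage zone measures the stretch of primary
dendrite flanked by menorahs, *not* the area of the individual branches:
menorah-owned edges are projected onto the axis, unioned with gaps up to
`zone_merge_gap_um` (default 10 μm) bridged — so the 5-μm self-avoidance
gaps of a healthy arbor do not fragment its coverage — then
trapped-2° intervals are subtracted and the result is clipped to the
200-μm anterior window. The trapped zone is the clipped union of trapped-2°
intervals. Both are averaged over the dorsal and ventral sides.

**Secondary-branching defect.** The boolean compares the pooled in-window
menorah count against the candidate-site expectation
(`2·window/site_spacing`) at a configurable fraction (default 0.5). The
0–3 severity grade bins the fraction of the window *not* covered by the
menorah zone (bin edges 0.1/0.3/0.6). Grading uncovered-plus-trapped
fraction rather than the trapped zone alone makes the degenerate
no-branching arbor grade 3 as it should, and is monotone in trapping since
trapped intervals are subtracted from the coverage.

**Receptive-field index.** Numerator: the anterior dendrite skeleton
rasterised on the unrolled plane (cell size 1 μm), dilated by the reach
radius ρ via a Euclidean distance transform that is periodic in the
circumferential direction, clipped to the strip `[mouth, soma] × [−πr, πr]`.
Denominator: the strip area `2πr·(soma − mouth)`. The operational meaning
of "innervated" is exactly this dilation; ρ (default 10 μm, about half the
inter-menorah spacing) is exposed rather than inferred, and reported RFI
values are only comparable at a fixed ρ. Strictly posterior edges do not
contribute to the numerator.

**Dendritomy regrowth** sums, over every post-injury terminal absent from
the pre-injury graph, the contour length from the cut site to that
terminal. The cut site must lie on the labeled primary dendrite; the cut
offset is an explicit argument with no claimed default.

## Fluorescence quantification

Recovery fractions are `(Fₙ − F₀)/(Fₚ − F₀)` with `F₀` the first
post-conversion sample and `Fₚ` the pre-conversion intensity (mean of
pre-conversion samples if several); fractions are not clipped, and
`Fₚ = F₀` is an error. The fraction at t = 0 is 0 by construction. Traces
are sampled every 5 s over 6 min (73 samples) by default.

The summarising fit is `R(t) = r_inf·(1 − exp(−k·t))` by constrained least
squares (`k, r_inf ≥ 0`), initialised from the tail mean and the half-rise
time; a flat zero curve fits exactly with `r_inf = 0`. The saturating
exponential is an added, clearly-labeled summary — a rate comparison needs
a rate parameter — not a claim about the underlying synthesis kinetics.

Cohorts are compared by two-way ANOVA on the raw fractions with factors
group and time. Because all samples of one curve share that curve's noisy
`F₀` and `Fₚ`, samples within a curve are correlated; the group effect is
therefore tested against the between-curve (within-group) mean square —
the repeated-measures layout — not the sample residual. Testing against
the residual is badly anti-conservative here (its null p-values pile up
near zero), which the calibration test demonstrates by construction.

**Puncta.** Per-neuron summaries are the mean punctum count per 3° branch
(maximal connected run of 3° edges) and the boolean "has any 3° punctum",
aggregated into cohort percentages. Spatial enrichment at landmarks is a
permutation test: the statistic is the fraction of puncta within the
capture radius (default 2 μm, geodesic) of any landmark; the null
repositions puncta uniformly along edges of the *same branch order*,
preserving per-order counts, so order-level abundance differences cannot
masquerade as spatial enrichment; `p = (1 + #{null ≥ obs})/(n_perm + 1)`.

## Statistics utilities

Two-proportion Z uses the pooled-variance statistic with a two-sided normal
p, erroring on a degenerate pooled proportion. Group dispatch covers
Student's t, one-way ANOVA with Tukey or Dunnett post-hoc, two-way ANOVA,
and the Z-test; means are reported ± SEM and proportions ± SEP, with no
additional multiplicity correction imposed beyond the post-hoc family.

## Numerical choices

Angles are stored in `[0, 2π)` and differenced in `(−π, π]`; SWC round
trips are exact to < 1e-9 μm at 9 printed decimals; unroll/roll is exact to
machine precision. Interval arithmetic treats zero-length intervals as
empty. RFI is grid-quantised: the analytic single-dendrite fixture is
reproduced within two grid cells of circumference. Undefined statistics
(no menorahs, no qualifying gaps) raise typed errors.

## Problem sizes

The test and acceptance studies use cohorts of 50–200 arbors per condition
(16 sites each; 5 sites for the brute-force-oracle arbors so menorah counts
stay ≤ 10), 100 traces for rate-recovery error, 10,000 simulations for
Z-test calibration, and 200 replicates at 199 permutations for
permutation-null calibration — sizes at which every Monte-Carlo check is
stable from run to run yet the whole suite completes in about a minute on
one core.

## Known limitations

Single straight cylinder only; one neuron per scene; classification assumes
the orientation-alternation lattice and arbors with at most four orders;
the generator's spacing and overlap distributions are configurable defaults,
not biological estimates; RFI depends explicitly on the chosen reach
radius; puncta are taken as given point events (no spot detection or
intensity model); photobleaching and diffusion are not modelled in the
recovery forward model.
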