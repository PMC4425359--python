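# Methods

This note documents the model implemented by `hippocirc`, the provenance of
its default parameters, and the numerical choices that are not forced by the
model definition itself.

## Model

### Architecture

The simulator is a rate network with four regions wired in the classic
hippocampal loop:

```
            EC (1,100 cells, a = 0.35, continuous)
           /  |  \
          v   |   v
  DG (12,000, a = 0.0078)   CA1 (3,900, a = 0.0896)
          \   |   ^    \
           v  v   |     v
        CA3 (2,500, a = 0.032, binary) --> CA1 --> EC
             ^__|   (recurrent collaterals)
```

Projections and fan-ins (connections per *target* cell):

| projection | fan-in | weights | learning rule |
|---|---|---|---|
| EC → DG | 400 | plastic or static | one-shot competitive |
| EC → CA3 | 400 | plastic | hetero-association |
| DG → CA3 (mossy) | 5 | static random U(0,1) | — |
| CA3 → CA3 | 1,200 | plastic | covariance |
| CA3 → CA1 (Schaffer) | 1,200 | plastic | hetero-association |
| EC → CA1 (temporoammonic) | 400 | static random U(0,1) | — |
| CA1 → EC | 400 | plastic | hetero-association |

Wiring masks are sampled uniformly: each target cell picks `fan_in` distinct
source cells; the CA3 recurrent mask excludes self-connections. Weights exist
only where the mask is 1.

### Activation

A cell's drive is the weighted sum of its inputs, `h = W p`. Population
activity is enforced by k-winner-take-all (k-WTA): with `k = max(1,
round(a·N))`, the `k` cells with the largest drive fire and all others are
silenced. Ties are broken toward the lowest cell index (a fixed, documented
convention; see "Numerical choices"). Winning cells in continuous regions
(EC, DG, CA1) keep their drive, clamped at zero from below; CA3 is binary and
winners are set to 1.

### Learning rules

With connection mask `C`, input patterns `p^(s)` and output patterns
`q^(s)`, `s = 1..M`:

- **Hetero-association** (EC→CA3, CA3→CA1, CA1→EC), written in one batch
  after all patterns are realized:
  `w_ij = c_ij Σ_s (p_j^(s) − p̄_j) q_i^(s)`, where `p̄_j` is the mean input
  rate of cell `j` over the stored set.
- **Covariance auto-association** (CA3→CA3):
  `v_ij = c_ij Σ_s (p_j^(s) − p̄_j)(p_i^(s) − p̄_i)`.
- **One-shot competitive rule** (EC→DG), applied sequentially during the
  storage pass: for each pattern, after the DG winners `q` are determined,
  every firing row is updated in place,
  `w_i ← (w_i + γ q_i p) / ‖w_i + γ q_i p‖`, with masked entries pinned at
  zero before normalization. Rows start at random U(0,1) values on the mask,
  normalized to unit length.

### Storage

For each EC input pattern: DG responds through EC→DG (updating those weights
if the DG is plastic), CA3 responds through the sparse mossy fibers only,
and CA1 responds through the static temporoammonic projection. The EC→CA3,
CA3→CA1 and CA1→EC hetero-associations and the CA3 covariance weights are
then written in one batch over the whole realized pattern set.

Three DG modes are available: `plastic` (competitive learning on),
`static` (random initialization left untouched), and `perfect_separator`
(the EC–DG–CA3 pathway is bypassed and CA3 receives an i.i.d. random binary
code — the idealized benchmark separator).

### Recall

A corrupted EC cue drives CA3 through the learned EC→CA3 weights; the
recurrent network then runs 15 clamped cycles

`h_i(t) = α Σ_j w_ij p̂_j + β Σ_j v_ij q̃_j(t−1)`, α = 1, β = 3,

with k-WTA after every cycle. The final CA3 pattern is decoded through
CA3→CA1 and CA1→EC, with k-WTA at each stage. The DG plays no role in
recall.

Variants: `no_recurrence` passes the initial CA3 response straight to CA1;
`minimal_ec_ca1_ec` stores only EC→CA1 and CA1→EC hetero-associations (CA1
driven during storage by a completely static EC→DG→CA3→CA1 chain) and
recalls through cue → CA1 → EC.

## Parameters and their provenance

**Cell counts** are rat anatomy divided by 100 (EC 110,000 → 1,100; DG
1,200,000 → 12,000; CA3 250,000 → 2,500; CA1 390,000 → 3,900) and **fan-ins**
are anatomy divided by 10 (EC→DG 4,000 → 400, mossy 46 → 5, CA3 recurrents
12,000 → 1,200, Schaffer 12,000 → 1,200, CA1→EC and EC→CA1 ~4,000 → 400).
`check_scaling` verifies these two per-quantity ratios symbolically. Note
that scaling cells by 1/100 and per-cell connections by 1/10 scales *total*
synapse counts by 1/1000.

**Sparsities** come from a two-factor estimate: the fraction of cells active
anywhere in an environment (from immediate-early-gene and electrophysiology
reports: means 2.9% DG, 22.8% CA3, 42.7% CA1) times the fraction of the
environment a single active cell covers (27% DG, 14% CA3, 21% CA1, 35% EC
grid cells). This gives a = 0.0078 (DG), 0.032 (CA3), 0.0896 (CA1), 0.35
(EC). Where a literature report is an interval we take its midpoint.

**Grid modules**: four modules with mean spacings 0.388, 0.484, 0.650,
0.984 m (SD 8 cm), mean orientations 15°, 30°, 45°, 60° (SD 3°), cell counts
in proportions 4:3:2:1 from small to large spacing. Field centers lie on a
triangular lattice spanned by basis vectors at the module orientation and
orientation + 60°; each cell has a uniform random phase inside the unit cell
and field peak rates uniform in [0.5, 1.5].

**Radial field profile**: `rate(d) = peak · exp(−(d/r)² ln 5)` for distance
`d` to the nearest field center, so the rate is exactly `0.2 · peak` at the
field border `d = r`.

**Field radius**: `r = κ · spacing`. κ is not directly observable; it was
calibrated once by bisection so that the mean fraction of a 1 m arena where a
grid cell fires above 0.2 of its lowest peak is ≈ 0.35, the coverage value
used in the EC sparsity derivation. The result, κ = 0.264, is frozen as
`KAPPA_DEFAULT` and not re-fit per run.

**LEC cells** sum 30 circular place fields with the same radial profile,
radii uniform in [5, 15] cm, centers uniform in the arena, peaks uniform in
[0.5, 1.5].

**Remapping**: each grid module receives one rotation uniform in [0°, 60°)
about the arena center and one shift uniform over its unit cell, shared by
all member cells (spacings and relative phases are preserved); LEC cells
draw entirely fresh field layouts per environment. Each cell's base lattice
covers a disc of radius `arena·√0.5 + 2·spacing` so any remapping still
tiles the whole arena.

**Protocol constants**: 400 candidate locations on a 20×20 lattice (5 cm
pitch), 252 of them stored (drawn uniformly without replacement); cue
corruption levels 0%–90% of EC cells in 10% steps, where each corrupted cell
takes the rate of another uniformly chosen cell of the same pattern; recall
uses α = 1, β = 3, 15 cycles.

## Design decisions on under-determined points

These choices are not fixed by the model description; each is a deliberate
default, and all are configurable.

- **Competitive learning rate γ = 0.1.** The one-shot rule only fixes the
  form of the update, not its magnitude. γ = 0.1 moves a unit-norm row
  noticeably in one shot without erasing its previous selectivity.
- **Static weights are U(0,1) on the mask.** Random positive weights are the
  weakest assumption for unlearned pathways; EC→DG rows are additionally
  unit-normalized because the competitive rule maintains unit rows.
- **EC→CA1 fan-in = 400**, matching the other EC efferents, since the
  temporoammonic count is not separately specified.
- **Joint k-WTA over grid + LEC cells.** The EC activity constraint is a
  single population constraint (one sparsity for EC), so mixed populations
  compete in one k-WTA rather than per-subpopulation.
- **EC output thresholding.** Recall reports use k-WTA'd EC reconstructions
  by default; `ec_output="raw"` exposes the unthresholded activations for
  decomposition analyses.
- **Multi-environment storage** splits the M stored patterns as evenly as
  possible across environments (remainder to the earliest environments).
- **Tie-breaking toward the lowest index** makes every run exactly
  reproducible; ties are measure-zero for continuous drives and only matter
  in degenerate toy cases.

## Numerical choices

- All dense algebra is NumPy float64; k-WTA uses a stable argsort of the
  negated drive, which is what guarantees the lowest-index tie rule.
- The batch learning rules are computed as single matrix products of
  mean-centered pattern matrices and verified against explicit double-sum
  oracles in the test suite (`tests/test_plasticity.py`).
- Sequential competitive updates touch only the rows of firing DG cells, in
  place; a row that becomes all-zero after masking is left unnormalized and
  logged.
- Randomness is organized as named substreams: every consumer (wiring per
  projection, static weights per pathway, cue draws, remapping, ...) derives
  its own 31-bit seed from `(master_seed, name)` via BLAKE2b, so adding a
  consumer never shifts the draws of another.
- Pearson correlations of zero-variance vectors are defined as 0 and logged;
  the separation index refuses degenerate correlation sets instead of
  silently fitting them.

## Generator realism and limitations

- Grid cells are noiseless, stationary, and share one analytic field
  profile; real grid cells show firing-rate variability across fields and
  theta modulation, none of which is modeled.
- LEC cells are a deliberately weak spatial code (a sum of random place
  fields), standing in for what is empirically a weakly spatial, highly
  heterogeneous population.
- The arena is sampled on a 5 cm lattice rather than along behavioral
  trajectories; conditional-firing statistics therefore have no occupancy
  correction.
- The network is a discrete-time rate model with global, instantaneous
  inhibition (k-WTA); no membrane dynamics, noise, or learning during
  recall.
- Cell counts and fan-ins are scaled (1/100, 1/10), so absolute capacity
  numbers are not directly comparable to the full-size system, though the
  qualitative comparisons are insensitive to a 100 → 20 change in the cell
  scaling factor.
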