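# Methods

## Reference layout

The reference structure is a straight bundle of 12 helices on the
honeycomb lattice (two rows of six columns; each helix has at most three
lattice neighbours, numbered along a serpentine Hamiltonian path so that
consecutive ids are always neighbours). Eleven *body* helices carry the
folded scaffold over the full bundle length; the twelfth lattice helix
carries the **adjuster strand**, a 504-nt scaffold segment anchored
symmetrically about the bundle midpoint and hybridised into duplex form by
twelve 42-nt strut staples (12 × 42 = 504).

Module spans (5′→3′ along the bundle axis, nt):

| L1 | seam | L2 | seam | L3 | seam | M1 | seam | M2 | seam | M3 | seam | R1 | seam | R2 | seam | R3 |
|----|------|----|------|----|------|----|------|----|------|----|------|----|------|----|------|----|
| 63 | 28 | 35 | 28 | 40 | 28 | 35 | 28 | 42 | 28 | 35 | 28 | 40 | 28 | 35 | 28 | 63 |

Total bundle length 612 nt; scaffold usage 11 × 612 + 504 = 7,236 nt ≤
7,249 nt (M13mp18). The middle spans are symmetric about M2 and all lie in
the 35–42-nt band; M2 is 42 nt so that its eleven body-helix segments are
42-nt ssDNA portions when the module is a hinge. A strictly alternating
35/42 pattern would overrun the scaffold budget, which is why two modules
are 40 nt. With eleven body helices the per-module arithmetic closes
exactly: M2 contributes 11 × 42 = 462 staple-bound bases routed as 11
staples, and the module/seam staple allocation
(15, 11, 12, 11, 11, 11, 11, 11, 15 body staples per module; 8/7
alternating per seam) gives the 180-staple census of 108 body + 60 seam +
12 strut.

**Scaffold routing.** The scaffold rakes through the 11 body helices block
by block (one block per module plus half of each flanking seam), with all
between-module crossovers inside seam regions and fold-backs at the bundle
ends. **Staple routing.** Within each module or seam region, staples are
cut from a serpentine traversal of the region's cells into the allocated
number of footprints; cuts that would fall exactly on a helix switch are
staggered by 14 nt so staples span crossovers. The exact cut positions are
free design variables — the class/module census above is the constrained,
externally meaningful surface.

## Hinges

`apply_hinge(design, module, dsNhb)` deletes every body staple inside the
module (11 for M2) and, for N > 0, adds N single-helix hinge staples that
re-duplex the N helices nearest the cross-section centroid (a symmetric
placement; the printed record underdetermines which helices stay duplex).
Seam staples and the scaffold path are never touched, so a hinge is fully
reversible (`fill_module`).

## Adjuster shortening and replacement accounting

A shortened adjuster of length ℓ = 504 − 21k keeps its scaffold anchored at
one end and parks the surplus in a reservoir at the other. Its duplex is
tiled in two parts: as many full 42-nt struts as fit on the *reference strut
grid* (these keep their reference sequences and are "shared"), plus a
**re-anchoring block** of seven short struts (18 or 21 nt) tiled from the
reservoir junction. The block is what a length change actually replaces:
its staples cannot occur in the reference pool, so every shortened
adjuster costs exactly 7 replaced staples (fewer than 7 only when
ℓ < 147 nt, where the whole adjuster is within the block). Replacement
counts therefore compose additively and emerge from the design rules, not
from bookkeeping constants: a single ds0hb hinge + shortened adjuster
replaces 7 staples (3.9 % of 180); dsNhb hinge staples add N; a second
adjuster adds another 7. Across the 24-case catalog the counts span 7–23
(3.9–12.8 %), with the maximum reached by the closed form with three ds3hb
hinges and two adjusters.

`diff_staples` compares *sequence sets*: a staple is replaced iff its
sequence is absent from the reference pool, which is the operationally
relevant definition (it is what a designer must newly order).

## Included-angle series

With anchors symmetric about the M2 hinge (252 nt of duplex arm each side,
r = 85.68 nm), a duplex adjuster of ℓ nt sets the chord
0.34 ℓ = 2r sin(θ/2). The 11-design series targets 0°–150° in 15° steps;
each design uses the nearest 21-nt multiple of 504·sin(θ/2), which lands
within 5° of every target (exactly on 60° and 90°). Consecutive 21-nt
decrements would *not* give uniform 15° steps under this chord geometry —
the 21-nt basis constrains the available lengths, the target grid picks
among them.

## Mechanics model

* **WLC**: Marko–Siggia interpolation
  F = (kT/Lp)[¼(1−x/Lc)⁻² − ¼ + x/Lc]; energy is its closed-form integral,
  so dE/dx = F identically. Defaults: Lp = 1.0 nm (ssDNA in ~20 mM Mg²⁺),
  contour 0.63 nm/nt, kT = 4.114 pN nm (298 K). All configurable.
* **Hinge**: harmonic torsional spring E = ½k(θ−θ₀)², θ₀ = 180° (the
  reference folds straight). With θ₀ = 180° the adjuster tension's moment
  arm r₁r₂ sin θ/x vanishes at the rest angle, so a slack adjuster (weak
  tension relative to k) leaves the equilibrium *exactly* at θ₀ — not just
  approximately.
* **Equilibrium**: global minimum of E_total on a 0.05° grid over (0°,180°],
  refined by bounded scalar minimisation to better than 0.01°; ties break
  towards θ₀; grid points whose chord exceeds the contour are flagged
  infeasible. Note the stiff limit θ*→θ₀ requires the chain to be able to
  reach θ₀ (contour > r₁+r₂); otherwise θ* saturates at the geometric cap
  where x = Lc.
* **Stiffness estimation**: the torque balance
  k(θ₀−θ) = F(x)·r₁r₂ sin θ/x is the stationarity condition of E_total, so
  estimation inverts prediction exactly (noise-free round trips recover k
  to numerical precision). Observations at θ = θ₀ are indeterminate
  (error); observations whose chord exceeds the contour are skipped with a
  record. Aggregation is the arithmetic mean with min/max spread.
* **PCA stiffness**: equipartition k = kT/var(θ) in radians after mean
  removal; for multivariate trajectories, k_i = kT/λ_i per principal mode.
* The ssDNA scaffold portions inside the hinge itself are *not* modelled
  as additional entropic springs; the torsional constant k absorbs them.
  This keeps the hinge description to one measurable parameter.

The stiffness values this model operates around (25.3 / 33.8 / 49.6
pN nm rad⁻¹ for ds0hb/ds2hb/ds3hb) enter only as operating points in
parameter-recovery tests: the angle-vs-length measurements that would
re-derive them are not reproducible computationally, so the tests verify
that the estimator is the exact inverse of the predictor at those points
(noise-free to <1 %, and to <10 % under 5° particle noise with 250
particles per design).

## Synthetic AFM scenes and measurement

The generator renders each monomer as two rods (6 nm wide, 2 nm tall —
the 12-helix bundle footprint; arm lengths 104 nm from the M2 hinge to the
bundle ends) meeting at the hinge vertex, applies a grey-scale dilation
with a 2-nm tip radius and additive Gaussian height noise (default
0.15 nm), and places particles on a jittered grid so scenes are
overlap-free and reproducible under a seed. Arms cannot interpenetrate:
nominal angles below the contact angle (~3.3° for these arms) render at
the contact angle, which is how folded-in-half particles actually sit.
Scenes can include malformed monomers (angle 30–90° off target) and
aggregates (two merged particles) with known ground truth.

Measurement: masks are connected components above a 1-nm height threshold
(small components removed), classified monomer/aggregate/fragment by area
relative to the expected dilated monomer footprint (0.55×/1.6× bands).
For each monomer the mask is skeletonised; the vertex is the skeleton
branch point, or for branch-free skeletons the point of maximum deviation
from the end-to-end chord; each arm's direction is the principal (SVD)
direction of its branch with pixels within 6 px of the vertex excluded,
and the included angle is the angle between the outward arm directions.
Hairpin-like particles (folded nearly shut: no branch, far end wider than
the near end) use a width-profile estimate, θ = 2 asin((W_far−W_near)/2L),
which is self-calibrating against tip dilation. Straight rods are
reported as 180° with a flag.

Yield: a trimmed Gaussian fit (iterative 3σ re-selection, robust to
off-target outliers) gives the angle mean/sd; structural yield is the
fraction of monomers inside target ± 3σ. The window criterion is a
labelled substitute for unpublished manual counting rules.

**What the synthetic scenes do and do not show.** They exercise the full
measurement chain (rendering → dilation → noise → segmentation →
skeleton/width analysis → statistics) with exact ground truth, so passing
tests demonstrate the *pipeline's* accuracy (scene-mean recovery MAE
< 5° across the 0–150° grid at 250 monomers per scene; an 80 %
well-formed scene reports 0.80 ± 0.03 yield). They do not emulate real
AFM artefacts — scanner drift and line noise, tip convolution beyond a
disk dilation, surface-interaction deformation, partially folded or
overlapping structures — so experimental yields and angle spreads are not
expected to match these numbers.

## Problem sizes

The test suite and acceptance script run at the sizes stated above by
choice: design statistics are exact and instantaneous; mechanics uses
0.05° grids; AFM recovery uses 250-monomer scenes per angle (matching the
per-case cohort size used for real images) and an 800-monomer scene for
the yield check, where the binomial sampling error (±0.014) sits
comfortably inside the ±0.03 band.

## Known limitations

* Staple break-point positions within regions are conventional, not
  optimised for melting temperature or strand length distribution.
* The caDNAno dialect carries a metadata block; files from other tools
  import only if that block is present (connectivity is still validated).
* The hinge model is quasi-static and harmonic; annealing kinetics,
  multi-well trapping of multi-hinge designs, and non-specific ssDNA
  interactions at the hinge are outside its scope.
* The 24-case catalog's case-by-case geometry is a reconstruction of the
  published groupings (single / multi-hinge / complex), not a copy of an
  authoritative table.
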