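# Methods

This note documents the models, defaults and design choices behind
`gpcrvar`, in the order the pipeline uses them.

## Segment model and distance profiling

A *segment* is a set of residues on one chain — the VFTD lobes LB1/LB2 or
a single TM helix — given as inclusive author-numbered residue ranges.
The packaged library holds the GABA_B receptor segments used throughout:
GB1 LBupper (222–235 ∪ 247–260), GB1 LBlower (347–358 ∪ 368–382), and the
TM4/TM5/TM6 helices of both subunits (GB1 711–731 / 769–789 / 805–825,
GB2 598–618 / 655–675 / 692–712). Author numbering is used because the
ranges are defined on the deposited structures; chain letters differ
between depositions, so the GB1/GB2 → chain mapping is configuration, not
code.

Per frame, the segment centre is the unweighted mean of the Cα atoms
(`CA_ONLY`, the default) or the mass-weighted mean of heavier selections.
`CA_ONLY` is the default for the TM helices as well as the lobes, for
consistency and insensitivity to side-chain noise; `HEAVY` is available.

The COM coordinate series of each segment is smoothed with a discrete
Gaussian filter along time (reflective boundary). The **filter is applied
to the coordinates before distances are taken**; smoothing the scalar
distance series instead is exposed as `filter_order="distances"` for
sensitivity checks only. The filter width `sigma_frames` defaults to 5.0
frames — the source analyses do not state a width, so this is a package
default, echoed into every output. Sigma 0 is the exact identity.

The per-frame distance is the Euclidean norm between the two (smoothed)
COMs. For a rigid trajectory filtered and raw series coincide; distances
are invariant to global rotations/translations to 1e−6 Å (tested).

### Slab slices

"Slice" extraction reduces a helix pair to the residues within
`half_width` of a plane. A plane through two points is underdetermined;
we resolve it by requiring the plane to also contain the membrane normal
(default z), i.e. plane normal = normalize(membrane_normal × (COM_B −
COM_A)), giving a vertical slab through both helices. The inclusion rule
is the explicit one — a residue is kept iff some atom lies within
`half_width = 5.0 Å` of the plane (total slab 10 Å); where a stated
"width" and the explicit ≤ 5 Å rule conflict, the explicit rule wins.
Degenerate geometry (coincident COMs, normal parallel to the axis) raises
rather than guessing.

## Interaction criteria

The per-frame interaction detector uses standard literature geometry, all
configurable and echoed into output headers (the original analysis used a
vendor script with unpublished criteria, so these are declared package
defaults):

| type | rule | default |
|---|---|---|
| SALT_BRIDGE | oppositely charged side-chain group atoms (Arg NE/NH1/NH2, Lys NZ, His ND1/NE2 vs Asp OD1/OD2, Glu OE1/OE2) within cutoff | 4.0 Å |
| HBOND | donor–acceptor heavy atoms within cutoff; donor–H–acceptor angle ≥ threshold when hydrogens are present, distance-only otherwise (flagged) | 3.5 Å, 120° |
| CONTACT | any heavy-atom pair within cutoff | 4.5 Å |

A focal–partner pair reports one record per frame with its
highest-priority type (salt bridge > H-bond > contact). Scope
`SIDE_CHAIN` (default) restricts both sides to side-chain atoms — glycine
can then only partner under scope `ANY`. Occupancy is the fraction of
frames with any record for that partner; partners are ordered by
descending occupancy, and the inter-subunit summary counts partners at or
above a 0.1 occupancy reporting threshold.

## State classification

Activation of the heterodimer moves the TM6 helices of the two subunits
together (forming the active TM6/TM6 interface) and the TM5 and TM4
helices apart, while the agonist-bound VFTD closes (LB1–LB2 distance
~41.5 Å open → ~34.5 Å closed; the cryo-EM literature values 41/33 Å are
kept for reference; the packaged defaults are midpoints of simulated
ranges).

A *shift* for a segment pair is Δ = mean(variant) − mean(WT) over the
Gaussian-filtered series after discarding the first 10% of frames
(equilibration; configurable). Significance is an effect-size rule,
|Δ| ≥ max(min_effect_A, k·pooled_sd) with defaults min_effect_A = 1.0 Å
and k = 2: MD frames are strongly autocorrelated, so frame-wise hypothesis
tests would wildly overstate confidence, and no test was reported for the
original comparisons. The rule is conservative and transparent.

The call logic:

* GAIN_OF_FUNCTION — TM6 Δ significantly negative **and** TM5 Δ
  significantly positive;
* LOSS_OF_FUNCTION — the mirror pattern;
* otherwise INDETERMINATE.

TM4 separation corroborates a gain (TM4 helices separate during
activation) but never decides a call, because its behaviour is the least
consistent across variants. VFTD evidence (shift plus closure index
(41.5 − mean)/7, unclamped) is always reported, and flagged *discordant*
when it opposes the TM call — it never overrides it: at trajectory
lengths of a few hundred nanoseconds TM distances are the more reliable
indicator of activity alterations, and the discordant-VFTD case is
exactly the situation the flag exists to surface. Swapping WT and variant
flips GAIN ↔ LOSS and negates every Δ (tested). No numeric threshold for
"reduced" vs "unchanged" was published; the defaults here are declared
package values.

The classifier report carries a fixed footer noting that conformational
bias in simulation does not by itself predict in-cell efficacy (surface
expression and adaptive changes are not modelled).

## Dose–response model

Three-parameter log-logistic with Hill slope fixed at 1:

    R(c) = basal + (top − basal) / (1 + 10^(logEC50 − log10 c))

Fitting is unweighted least squares (Levenberg–Marquardt) in
log-concentration space with a deterministic initializer (basal = min
response, top = max response, logEC50 = log10 of the concentration
nearest half-maximum). Zero-concentration wells contribute R(0) = basal
analytically, avoiding log(0). `top ≥ basal` is *not* enforced — slightly
negative constitutive activity is a real observation for
inverse-agonist-like variants. Constant responses return basal = top with
the EC50 flagged unidentifiable; non-convergence is reported on the
result, never raised. Standard errors come from the Jacobian at the
optimum. A free-slope 4-parameter option exists but is off by default.
Equivariances (response scaling scales basal/top and leaves EC50 fixed;
relabelling concentration units shifts logEC50 by the exact decade
offset) are tested to 1e−6 relative.

Normalizing raw luminescence to a reference Emax is the caller's job;
`normalize_to_reference` divides by a designated fitted top. Group
summaries report mean ± SEM per condition, excluding (and counting)
non-converged fits; hypothesis-testing machinery is deliberately out of
scope.

The 1:1 co-expression model is the pointwise mixture
R_mix(c) = w·R_wt(c) + (1−w)·R_var(c), default w = 0.5 — a receptor-pool
average that ignores any cooperative assembly effects.

## Synthetic data: what it emulates and what it does not

**Trajectories.** Segments are idealized α-helical poly-alanine traces
(2.3 Å radius, 1.5 Å rise, 100°/residue, with coarse N/C/O/CB
decoration), centred so the Cα centroid is exactly at the requested
position. Pair placements come from embedding the target distance matrix
(classical MDS per connected component of the pair graph, verified to
1e−6 and raising on triangle-violating targets); unrelated components are
spaced 400 Å apart. Per frame each segment is displaced **rigidly** by an
isotropic Gaussian offset (default sd 0.5 Å); rigid-body jitter, rather
than per-atom noise, keeps the sampling distribution of the pair
separation analytic (mean = target, sd ≈ jitter_sd·√2 for separations ≫
jitter), which is what makes the ±3-standard-error test tolerances
computable. Linear drift (separation + drift·t) is supported for
two-segment pairs. Bookkeeping records the realized per-frame separations
and is the ground truth every downstream measurement is checked against.

Packaged profiles encode the study conditions: VFTD lobe pairs at 41.5 Å
(WT inactive), 34.5 Å (active; also the variant-W inactive value) and
37.5 Å (variant-Q inactive), 250 frames, jitter 0.5 Å, seed 42; TM
profiles place the three helix pairs at WT baselines of 32/30/28 Å
(TM6/TM5/TM4 — illustrative plausible values, since only the direction of
each variant shift is reported) with ±2 Å variant effects over 100
frames.

What the generator does **not** emulate: force-field physics, solvent,
membrane, autocorrelated dynamics, conformational transitions within a
run, or per-atom flexibility. Passing tests therefore demonstrate that
the *measurement* pipeline is correct and that the classifier responds to
separations as designed — not that real trajectories of these receptors
would show these separations.

**Curves.** Replicates are the three-parameter model evaluated at 8
log-spaced GABA concentrations (0.01–100 μM) plus one zero-concentration
basal well, with i.i.d. Gaussian noise (sd 0.02 response units). The
packaged parameter sets are the reported assay values — WT-Q
(0.08, 1.02, 1.58 μM), R212Q (0.26, 0.86, 0.49 μM), WT-W
(0.06, 1.04, 1.51 μM), R212W (−0.02, 1.06, 4.18 μM); the two WT sets come
from separate experiment batches and are kept as independent profiles,
never pooled. Real assay noise is heteroscedastic and plate-correlated;
i.i.d. noise is a simplification that the recovery experiments inherit.

**Scripted interactions.** A focal arginine faces partner glutamates that
are placed with their carboxylate 3 Å from the guanidinium in "on" frames
(a salt bridge under defaults) and 25 Å away in "off" frames, so the
occurrence matrix equals the script exactly.

## Problem sizes and numerical choices

The test suite and the acceptance script use 100–250-frame trajectories
(≈100–650 atoms) and 200-replicate curve recoveries — sizes chosen so the
statistical tolerances (3 standard errors; 2% on means over 200
replicates) are meaningful while the whole analysis reruns in seconds.
Tolerances on exact arithmetic are 1e−6 to 1e−9; stochastic checks state
their error bands in terms of the generator's known sampling
distribution. Ties and degenerate inputs fail loudly (degenerate
geometry, empty selections, unidentifiable EC50) rather than returning
silent defaults.

## Known limitations

* Trajectory input is multi-model PDB/mmCIF; binary MD formats need a
  thin adapter supplying (metadata, coordinates).
* H-bond detection without hydrogens is distance-only (flagged); no
  π-stacking or cation–π detection, no interaction energies.
* The classifier encodes this receptor family's activation geometry; for
  other dimers the segment library and call rules must be re-derived.
* No PBC unwrapping: trajectories are assumed whole.
* Group summaries stop at mean ± SEM; inferential statistics are out of
  scope by design.
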