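# Methods

This note documents the models and numerical procedures implemented in
`hydrasite`, the choices made where the design was genuinely open, and what
the synthetic test bed does and does not demonstrate.

## Overview

The package addresses hydration-site analysis on protein structures in four
connected pieces:

1. a **location model** that places hydration sites (HS) on a protein
   surface in one shot, from structure alone;
2. a **thermodynamics head** that assigns each site the enthalpy and entropy
   change of moving one water from bulk solvent into the site;
3. a **trajectory analysis** that derives reference sites and their
   thermodynamics from explicit-water simulation frames (the quantities the
   models are trained to reproduce); and
4. an **evaluation and application layer**: recovery-rate metrics and
   ligand-desolvation scoring by hydration-site displacement.

Energies are kcal/mol internally; the desolvation benchmark and optional
report outputs convert to kJ/mol at the boundary. T = 300 K, gas constant
R = 1.9872 cal/(mol K), bulk water density C° = 1/29.9 Å⁻³ throughout.

## Location model

**Input features.** Protein heavy atoms carry a 92-dimensional feature
vector: a 38-slot one-hot over PDB atom-name classes (37 named classes
covering the 20 standard amino acids, frozen in `structure_io.ATOM_VOCAB`,
plus one reserved "other" slot), a 21-slot one-hot over residue types
(20 standard + other), a 32-center Gaussian radial-basis expansion of the
fractional solvent-accessible surface area (SASA) on [0, 1], and one
atom/water flag. SASA is computed by the Shrake–Rupley method with Bondi
radii, a 1.4 Å probe and a fixed 960-point deterministic (golden-spiral)
sphere, and normalized by each atom's probe-expanded sphere area so the
value is a fraction of full exposure; the 0.1 seeding threshold below is
read as fractional exposure.

**Water initialization.** One candidate water node is seeded at the
position of every heavy atom whose fractional SASA exceeds 0.1. Seeded
water nodes copy their seed atom's feature vector with the node-type flag
set to water, so the network knows what chemistry each candidate starts
from.

**Architecture.** Five equivariant attention layers of EGNN type operate on
a spatial graph rebuilt before every layer: nodes are connected when closer
than 6 Å (strict inequality), edges carry a 32-center RBF of their length
on [0, 6]. Messages are invariant functions of the two endpoint feature
vectors and the edge RBF; each edge also emits a sigmoid attention gate and
a scalar coordinate weight; a water node's position update is the
attention-gated, degree-normalized sum of relative position vectors scaled
by those weights. Protein atom positions are never updated — they pass
through every layer bit-identically. Because coordinates enter only through
distances and leave only through relative-vector combinations, the
predictions transform exactly with any rigid motion of the input and are
invariant to atom reordering; the test suite asserts both to 1e-5. A
sigmoid head maps final water-node features to a certainty weight
w ∈ [0, 1]. Hidden width (default 32) and learning-rate schedule are free
parameters; correctness is defined by the equivariance and loss contracts,
not by any particular weight values.

**Loss.** Predictions (x_j, w_j) define a Gaussian mixture p with
normalized weights w̃_j = w_j / Σw_k and isotropic σ = 0.5 Å; the reference
sites with occupancy ≥ 0.5 define a mixture q weighted by normalized
occupancy. As the divergence surrogate we use the closed-form L2 distance

    L1 = ∫(p − q)² dx = Σ_jk w̃_j w̃_k G(x_j − x_k) − 2 Σ_ji w̃_j v_i G(x_j − y_i) + Σ_ii' v_i v_i' G(y_i − y_i'),

with G the Gaussian kernel of variance 2σ². L1 is symmetric in p and q,
uniquely minimized at p = q, and differentiable in both coordinates and
weights; the tests verify the minimum property against random perturbations
and the analytic gradients against central finite differences. A
concentration penalty L2 = Σ w̃_j² (smallest when certainty is spread
uniformly) is added with weight α = 0.1 (configurable): L = L1 + α·L2.

**Training.** Adam (lr 6e-3, ×0.997/epoch decay) on the summed loss over
the training structures. The mixture width is annealed deterministically
from 2.0 Å down to the target 0.5 Å (×0.99/epoch): with σ = 0.5 Å from the
start, a reference site ~3 Å from every prediction exerts an exponentially
small pull and entire modes get dropped; the broad early mixture removes
this failure while the final phase optimizes exactly the σ = 0.5 Å loss.
Gradients flow through coordinates and weights but not through the
topology rebuilds (a discrete operation).

**Post-processing.** Predictions with w < w_c = 0.035 are discarded. The
rest are clustered by Ward agglomerative clustering (scipy linkage) with a
2 Å distance threshold on unweighted coordinates; each cluster is reduced
to its certainty-weighted centroid Σw_j x_j / Σw_j. The cluster weight is
the **sum of member raw certainties** (a "mean" option exists); clusters at
or below 0.1 are dropped. Summing raw weights (rather than normalized ones)
keeps the 0.1 gate independent of how many candidate waters a protein
seeds, which would otherwise make the gate stricter for larger proteins.
Tie-breaks are deterministic (lexicographic coordinate order).

## Thermodynamics head

A second graph is built over protein heavy atoms plus hydration sites:
8 Å cutoff, **no atom–atom edges** (atom–site and site–site only). During
training, sites with occupancy ≤ 0.3 are excluded as nodes. Three
graph-attention layers (per-edge logits from both endpoint projections and
the edge-length RBF, softmax-normalized per receiving node) update node
features; a feed-forward head maps each site node to two outputs
interpreted as ΔH and T·ΔS (both kcal/mol — predicting the T-scaled entropy
keeps the two loss terms in the same units), and ΔG = ΔH − TΔS holds
exactly by construction. The loss is MSE(ΔH) + MSE(TΔS) over sites with
occupancy ≥ 0.5.

At the small training scales this package targets, the head is strongly
overparameterized relative to the number of labelled sites and some random
inits converge to sharp minima that memorize the training structures.
Training is therefore regularized on three fronts: decoupled weight decay
(2e-2 on weight matrices), a 20 % validation split whose best-loss
parameters are snapshotted, and selection of the best of 3 independently
initialized runs — both selections use validation loss only. The default
hidden width is 16.

## Trajectory analysis (reference generation)

Water-oxygen observations are binned on a 0.25 Å grid (counts are conserved
exactly). Sites are extracted greedily: take the highest-count voxel (ties:
lexicographic voxel index), form the density-weighted centroid of all
density within 1 Å, remove that density, and repeat until the top peak
falls below 1 % of the frame count (≥ 2); a peak landing within 2 Å of an
accepted center is absorbed without emitting a new site. Occupancy is the
fraction of frames with a water inside the 1 Å site sphere.

ΔH is the mean water interaction energy inside the site minus the bulk
reference energy. Interaction energies are **inputs** (from MD
post-processing in production, from the synthetic generator in tests); a
toy Lennard-Jones + Coulomb evaluator is included only so fixtures can
carry self-consistent energies. The bulk reference energy is a
configuration input (the generator's default is −9.5 kcal/mol).

ΔS is a discretized version of −R ∫ p ln(p / p_bulk) dq over the external
(translational + rotational) modes, factorized into a translational term
against the bulk density C° = 1/29.9 Å⁻³ (3-D histogram, 0.25 Å bins) and a
rotational term against the uniform Haar distribution on SO(3) (ZYZ Euler
angles binned uniformly in (α, cos β, γ), 30° resolution, so the uniform
distribution is uniform across bins; 8π² total volume). Both terms are ≤ 0
for localized/oriented waters and 0 for bulk-like ones. For a uniform
occupation of the 1 Å site sphere with uniform orientations, the estimator
must approach R ln(V·C°) with V = (4/3)π Å³; the tests assert this with the
tolerance measured by bin halving (the histogram estimator is first-order
at a hard density boundary, so the error at bin width h/2 is bounded by the
h → h/2 successive difference) and additionally against the closed form for
Gaussian densities. At least 50 observations are required.

## Evaluation and desolvation

GTRR (fraction of reference sites with a prediction within r) and PHR
(fraction of predictions within r of a reference) use any-within-r matching;
a Hungarian one-to-one variant is available behind a flag for sensitivity
checks. Sites within 3.5 Å (inclusive) of a protein heavy atom are "first
layer". Occupancy-binned GTRR uses bins [0.5,0.6) … [0.9,1.0]; empty bins
are reported as absent, never as zero. R² is 1 − SS_res/SS_tot (not squared
Pearson correlation — the packaged benchmark is only reproduced under this
convention), alongside MSE and RMSE.

Desolvation: a site is displaced when its center is within 2.4 Å of a
ligand heavy atom; the score is **minus** the sum of displaced-site ΔG
values, so expelling water that is less favorable in the site than in bulk
(ΔG > 0) contributes favorably (negatively), matching the sign of the
packaged benchmark table. Predictions are compared with experimental
binding free energies after slope-one calibration (an intercept-only mean
shift, which any constant offset cannot affect).

## Synthetic data

The generator produces the package's entire test bed. Structures are
geometric toys: an extended self-avoiding Cα walk (3.8 Å steps, persistent
direction) with templated dummy side-chain atoms named after real PDB
atoms, and a hard guarantee that every heavy-atom pair is ≥ 2 Å apart (the
template is deliberately inflated relative to covalent geometry to make
that invariant hold). Sites are planted 2.8–3.0 Å from solvent-exposed
polar (N/O) atoms, pointing outward, pairwise > 2 Å apart. Occupancy is
uniform on a configurable range. Positional spread σ grows with local
hydrophobicity (0.15–0.30 Å), and labels follow smooth deterministic rules
of the local environment: ΔH = −0.5 − 2.5·polar_fraction − 0.08·n_close
(kcal/mol, 4 Å neighborhood) and TΔS = −1.8 + 4σ, so entropy labels
increase strictly with spread and both targets are learnable from geometry
alone. Trajectories emit, per frame and site, a water with probability
equal to occupancy, Gaussian positional noise σ, uniform (or optionally
concentrated) orientation, and energy = bulk + ΔH + N(0, 0.2²).

What passing these tests shows: the pipeline's geometric, statistical and
thermodynamic contracts hold end to end, and the models can represent and
recover planted structure–label relationships. What it does not show:
performance on real proteins — the toys have no folded cores, rotamers,
force-field energetics, water–water cooperativity, or conformational
ensembles, and the label rules are far simpler than simulated
thermodynamics.

## Problem sizes and numerical choices

Test and acceptance runs use 5–25 structures of 5–8 residues (40–50 heavy
atoms), ≤ 8 sites each, 1000-frame trajectories, hidden width 16–32, and
200–300 training epochs; these sizes were chosen so the full pipeline,
including both training loops, demonstrates its contracts in a few minutes
on one CPU. Degenerate inputs are explicit errors (no ATOM records,
malformed coordinate fields with the offending line number, unknown
elements in SASA, all-zero certainty weights, empty reference or prediction
sets, too few entropy observations); empty *results* (no seeded waters, no
site passing a gate) are valid outputs. Checkpoints are single-file JSON
with a config hash that is verified on load.

## Known limitations

- The trained toy models are demonstrations of the training machinery, not
  transferable predictors; no pretrained weights ship with the package.
- The entropy estimator's histogram bias is first-order at hard density
  boundaries (see above); bin width is a config knob and should be chosen
  with the available observation count in mind.
- The greedy density-peak site extraction guarantees ≥ 2 Å center
  separation but can merge genuinely overlapping sites closer than that.
- Desolvation sums displaced-site ΔG without occupancy weighting or
  per-site caps; alternative aggregations are easy to add at the call site.
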