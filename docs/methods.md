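# Methods

`corncloud` implements a complete desk-scale pipeline for extracting
phenotypic traits of maize seedlings from multi-plant tray point clouds:
semantic segmentation (seedling vs. background) with an attention-augmented
hierarchical point network, instance separation with adaptive-eps density
clustering, and per-plant trait measurement after ground-plane alignment and
metric scaling. Because the reconstructions such pipelines are built for are
rarely shareable, the package ships a synthetic scene generator whose ground
truth is exact by construction; every stage is validated against it.

## Synthetic tray scenes

A scene is a square tray of side 25 cm (uniformly sampled plane points with
vertical jitter) plus `n_plants` seedlings. A seedling is a vertical stem —
a thin cylinder shell of points — carrying 2–4 parabolic leaf ribbons
attached partway up the stem. Plant positions are rejection-sampled with a
minimum mutual separation (default 8 cm); the whole placement restarts on a
dead end, and a `GenerationError` is raised only when 100 restarts fail.

Two design choices make the generator a usable oracle:

* **Exact ground truth.** After sampling (and after point jitter is
  injected), each plant is affinely rescaled so that its z-extent equals the
  designed height and its horizontal bounding box equals the designed canopy
  extents. The manifest therefore records the *exact* height and canopy
  diagonal of the generated points, not an approximation.
* **Tilt after truth.** The whole-scene tilt (a Rodrigues rotation about a
  horizontal axis, up to 45°) is applied after ground truth is recorded, so
  alignment recovery can be scored against clean references.

Normals are analytic: the tray normal is +z, stem normals are radial, and
leaf normals come from the cross product of the ribbon's parametric
derivatives (rotated along with the scene and renormalized after the
anisotropic rescale). The manifest's volume/area columns are numeric
integrals of the generating solids (leaves treated as 0.05 cm-thick sheets);
they describe the solids, not what a voxel or mesh estimator measures on a
sparse sampling, and are informational rather than test oracles.

What the generator does **not** emulate: photogrammetric artifacts
(holes, ghost points, density gradients), leaf self-occlusion, soil texture,
and any biology (no growth, no stress response). Passing tests demonstrate
the pipeline's geometric and statistical correctness, not robustness to
reconstruction pathologies.

## Augmentation

Six techniques, one variant each per cloud plus the original (7× the input
count, so 106 originals yield 742 files): fake dropout removes
`round(p·N)` points with p uniform in [0.10, 0.20]; jitter adds per-coordinate
N(0, 0.01) noise hard-clipped to ±0.05 (clipping rather than resampling — at
5σ the difference is unobservable); rotation composes Rz·Ry·Rx with
independent angles uniform in ±10° per axis; scaling applies one factor
uniform in [0.67, 1.5] about the centroid; shuffling permutes the point
order; translation shifts all points by a per-axis offset uniform in ±0.1.
The train/test/validation split is per-file uniform with expected 8:1:1
proportions — a ratio, not an exact partition, so realized counts fluctuate.

## Segmentation network

The backbone is a three-level set-abstraction encoder with multi-scale
grouping and a mirrored three-level feature-propagation decoder, per-point
input features being the normalized coordinates and the normals (clouds are
centered and scaled into the unit sphere first; only labels are returned, so
the inverse transform is never needed). Each SA level runs farthest-point
sampling (started from the point farthest from the centroid, which makes the
selection — and hence the whole eval-mode forward pass — invariant to input
point order), ball-grouping at two radii with a nearest-neighbor fallback, a
shared per-point MLP, a CBAM block, and per-group max pooling.

CBAM is the sequential channel-then-spatial attention:

    Mc(F) = σ(MLP(AvgPool(F)) + MLP(MaxPool(F)))        F1 = Mc ⊗ F
    Ms(F1) = σ(conv([AvgPool(F1); MaxPool(F1)]))        F2 = Ms ⊗ F1

with pooling over the group's points for the channel branch and over
channels for the spatial branch; the channel MLP bottleneck ratio is 8
(configurable). The block sits after the final per-group MLP and before max
pooling.

The loss is the composite form

    L = L_cls + λ·L_reg,   L_cls = −(1/N) Σ [y log p + (1−y) log(1−p)],
    L_reg = Σ |t − t̄|

with probabilities clamped to [1e-7, 1−1e-7]. As printed this is binary
cross-entropy plus an L1 regression term over externally supplied pairs;
λ defaults to 0 because pure per-point segmentation provides no such pairs
(the hook is kept for box-style auxiliary targets). The stated intent of
up-weighting the hard minority class is carried by inverse-frequency class
weights normalized to mean 1, computed per batch; a one-class batch falls
back to uniform weights.

The network and its training loop are pure NumPy over a small in-repo
reverse-mode autodiff engine (gradient-checked against central differences).
Optimization is Adam (lr 5e-4, weight decay 1e-4, batch 24 or the training
set size if smaller, up to 100 epochs), fully driven by one integer seed
(initialization, batch order, resampling). Batch normalization is omitted:
plain ReLU MLPs with He initialization converge reliably at these sizes and
keep the forward pass exactly deterministic. Clouds are resampled to
`npoint` per epoch — uniform subsampling without replacement above, padding
by repetition (labels copied) below. The reference configuration uses
npoint 4096 with sample counts 1024/256/64; the `NetConfig.small()` preset
(npoint 1024, sample counts 256/64/16, narrower MLPs) is the configuration
used throughout the test suite and the acceptance script, chosen as the
package's single-CPU working size. Full-cloud inference covers every point
with random npoint chunks and combines repeated predictions by majority
vote, breaking ties with summed probabilities.

## Instance separation

The neighborhood radius is estimated from the data: eps is the mean over all
points of the distance to the 55th nearest neighbor (self excluded — "the
most distant neighbor within the k-nearest set"). DBSCAN then runs with that
eps and minpts = 3; noise is −1 and clusters are renumbered by descending
size. Degenerate inputs generalize the formula smoothly: for N ≤ 55, k drops
to N−1 with a warning; below minpts, or when all points coincide (eps = 0),
everything is noise. Distances are Euclidean in scene units with no prior
normalization — eps is estimated on exactly the coordinates it is applied
to, so the pair is scale-consistent, and eps itself is homogeneous of degree
1 in the coordinates. eps is estimated on the seedling-labeled subset that
is clustered, not the full scene. Predicted clusters are matched one-to-one
to ground-truth plants by the Hungarian algorithm on the pairwise-IoU
contingency table (maximizing summed IoU, which is invariant to cluster
renumbering); surplus clusters stay unmatched and count as false positives.

## Metrics

Semantic: Acc = (TP+TN)/total, Pre and Rec for the seedling class,
IoU_c = TP_c/(TP_c+FP_c+FN_c) per class and mIoU their mean — all percent.
Instance: per matched pair TP = shared points, FP = predicted-only,
FN = truth-only; Pre/Rec/F1 pool these counts over instances
(micro-average — robust to tiny instances; the alternative macro-average is
isolated behind one function), and iIoU is the mean IoU over ground-truth
instances with unmatched ones contributing 0. Noise points belong to no
cluster: they add to their truth instance's FN and never to any FP. A zero
denominator reports 0 with an `undefined` flag instead of NaN.

## Alignment, scaling, traits

The ground plane is found by RANSAC (1000 seeded iterations; inlier
threshold 1% of the bounding-box diagonal — it must track scene scale; plane
refit by total least squares on the consensus set), with the normal oriented
so the plants lie on its positive side. The rotation mapping the detected
normal m onto ẑ is the Rodrigues matrix about (m × ẑ)/|m × ẑ| by
θ = cos⁻¹(m·ẑ); the antiparallel case rotates 180° about x by convention.
Metric scale is k = L_real / L_virtual with L_real the 25 cm tray side and
L_virtual either supplied or measured as the largest horizontal extent of
the plane inliers after alignment.

Per plant (in the aligned frame): height = (z_max − z_min)·k, measured from
the plant's own lowest point (its soil contact), not the plane offset;
canopy width = √(L² + W²)·k from the horizontal axis-aligned bounding box;
volume = occupied-voxel count × (0.1 cm)³ on a grid anchored at the plant's
AABB minimum corner (translation-covariant with the plant; sub-voxel shifts
change the count by at most a boundary shell); surface area = Heron-formula
sum over the triangles of a ball-pivoting reconstruction at radius 0.2 cm.
The ball-pivoting implementation is in-repo: a seeded front of directed
edges is pivoted, each pivot choosing the smallest-rotation empty ball among
kNN candidates, with manifold bookkeeping (each edge bounds at most two
triangles) and re-seeding across disconnected components. Homogeneity holds
in the proper sense: height and canopy scale as k, and volume/area scale as
k³/k² when the voxel side and ball radius scale with k (they are physical
grains fixed in cm, so changing k at fixed grain is a resolution change,
not a similarity).

## Problem sizes and numerical choices

The test suite and acceptance script run, per invocation: a 106-scene
augmentation pass (reduced point densities — the 7× count rule is
density-independent), 100 clustering scenes, one 4-scene/50-epoch overfit
run at npoint 512, one 40-scene/30-epoch training run at npoint 1024 with a
32/4/4 split, 50 trait-recovery scenes, and a 20 000-point sphere
reconstruction. These are the package's reference experiment sizes for a
single CPU; all are parameters, not constants. Tolerances: probability
clamp 1e-7; eps homogeneity and Rodrigues orthonormality asserted at 1e-9;
network permutation equivariance at 1e-5 (float accumulation order);
ball-emptiness tested with a 1e-7 relative shrink so the three support
points never fail their own ball.

## Known limitations

* The network is CPU-sized; the reference 4096-point configuration trains
  slowly in pure NumPy and is intended for correctness work, not production
  throughput.
* Ball-pivoting needs sampling denser than the ball radius; the default
  600-point synthetic plants are sparser than that on leaf tips, so mesh
  areas on default scenes under-cover (the closed-form fixtures use
  adequate densities). Real reconstructions at photogrammetric density do
  not have this problem at r = 0.2 cm.
* Voxel volume measures occupied space of a surface sampling, which for
  thin organs exceeds the solid volume of the generating sheet; it is a
  consistent comparative index, not a literal solid volume.
* The adaptive eps assumes plants are denser internally than the gaps
  between them; heavily overlapping canopies would merge.
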