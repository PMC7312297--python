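# Methods

This note records the models the package implements, the conventions it
adopts where common lab practice leaves room, and what its synthetic data
do and do not establish about real measurements.

## Barrier assays

TEER is the blank-subtracted resistance–area product
`(R_raw − R_blank) · A` in Ω·cm². The default blank corresponds to a
cell-free insert reading of 95 Ω·cm² (typical cell-free polycarbonate
inserts fall in the 90–100 Ω·cm² band). Negative TEER is returned with a
warning rather than rejected: it indicates a measurement problem the
caller should see, not an invalid input.

The apparent permeability coefficient is
`Papp = Δ[C]_A · V_A / (A · [C]_D · Δt)` with mL treated as cm³ (exact)
and concentration units cancelling, so Papp comes out in cm/s. `Δ[C]_A`
is the acceptor concentration at assay end minus at start (start taken as
0 unless the caller subtracts it). Donor depletion is neglected — the sink
assumption — which is appropriate for 30–60 min assays where a ~10⁻³
fraction of tracer crosses. Negative measured `Δ[C]_A` (plate-reader
noise near blank) is clamped to 0 with a warning. Papp is computed per
insert; aggregation over replicate wells happens afterwards, so group
statistics see one value per insert.

Defaults mirror a standard 12-well Transwell geometry: V_A = 1.5 mL,
A = 1.12 cm², Δt = 1800 s.

## Impedance kinetics

Cell index is the instrument definition CI = (Rn − Rb)/15 at a single
10 kHz reading; no equivalent-circuit modelling is attempted.
Normalization divides by the CI at the **last sample at or before the
treatment time** — treatments are applied at the plateau phase, so this
anchor is the standard choice for real-time cell-analysis instruments; the
anchor sample maps to exactly 1. Optional division by a control-well
trajectory is deliberately not the default.

Viability calls use two post-treatment windows, 6–15 h (transient) and
16–24 h (terminal). A trace is *lethal* if its terminal-window mean falls
at or below the threshold (a supplied absolute value, or the terminal mean
of a detergent reference + 10%); *transient effect* if the transient
window deviates from control by more than 20% but the terminal window
recovers to within 20% of 1; otherwise *viable*. The 20%/10% margins are
explicit configuration — published calls of this kind are qualitative, so
the package makes the rule concrete and overridable.

## Confocal localization

Arrays are (z, y, x) with z = 0 at the apical top. The pipeline:

1. **Lateral smoothing** of the membrane-stain channel only: each z-slice
   is convolved with a 2-D Gaussian. "10 pixels wide" is interpreted as
   kernel support ≈ width with σ = width/4 (σ = 2.5 px by default),
   truncated at width/2 and renormalized; σ is configurable. Reflective
   padding avoids edge darkening that would bias column maxima.
2. **Contour detection** per column: the smallest z whose smoothed
   intensity is *strictly greater* than 30% of the column maximum,
   scanning from the apical top; ties break toward smaller z (first
   crossing). Columns whose maximum is below 5% of the global channel
   maximum are background — per-column thresholds are meaningless where
   there is no signal; the floor is configurable.
3. **Masks**: membrane = a 12-voxel stripe (2.4 µm at 0.2 µm axial
   spacing) starting at the contour, clipped to the grid; cytoplasm =
   everything below the stripe to the stack bottom. Columns whose
   cytoplasm clips away are recorded as degenerate, not dropped. The
   partition membrane ∪ cytoplasm ∪ above-contour ∪ background tiles the
   grid exactly — asserted in tests for every generated stack.
4. **Scoring** on the **raw** target channel (smoothing is for contour
   detection only): mean membrane intensity / mean cytoplasm intensity.
5. **Cell height** = (z_basal − z*) · axial spacing averaged over cell
   columns; the basal reference defaults to the last z index, matching
   the cytoplasm-mask convention.

Voxel spacing defaults to 0.2 µm axial (so 12 voxels = 2.4 µm) and 0.2 µm
lateral, both configurable; input bit depth is irrelevant because all
computations are on floats.

## Junction segmentation

K-means on raw pixel intensity (a 1-D feature — the segmentation is
intensity-based by design; no texture features). k = 3 by default
(background, cytoplasm, junction) since real images contain unlabeled
background; k = 2 for cropped images. Clusters are relabelled by ascending
mean so the brightest cluster is always the junctional one. k-means++
initialisation with a fixed seed and multiple restarts makes runs
deterministic; on small 1-D inputs the solution provably coincides with
the exhaustive minimum within-cluster-sum-of-squares bipartition (tested).
The readout is the mean raw intensity over the junction mask, computed per
image and then averaged across images.

## pH calibration

The ratio–pH relationship over the 6.0–8.4 nigericin calibration range is
modelled as a least-squares line `ratio = a·pH + b`; over this range the
linear model is the simplest defensible choice, and fit residuals are
reported so a user can judge adequacy (a sigmoidal dye-titration model
was considered and left out of scope — anchors in practice span the
near-linear center of the titration curve). Conversion inverts the line;
results outside the anchor span are flagged as extrapolation. Resting pH
is the baseline-window mean ratio (default: first 60 s of the trace,
sampled every 2 s) converted per ROI; group statistics are across ROIs.
Anchor sets need ≥ 2 distinct pH values; non-monotone anchors warn.

## Statistics

One-way ANOVA is computed from explicit between/within sums of squares,
which lets the degenerate zero-variance cases be defined (F = 0 with all
means equal; F = ∞ with distinct means) instead of producing NaN.

Dunnett's many-to-one comparisons use pooled-variance t statistics. The
family-wise adjustment samples the null distribution of
max_i |T_i| — correlated multivariate t induced by the shared control mean
and shared pooled-variance draw — with a seeded generator (2×10⁵ samples
by default; the critical value changes by <0.5% on doubling). This keeps
the procedure dimension-agnostic, reproducible and independently checkable
(tests cross-validate against `scipy.stats.dunnett`).

Two-way ANOVA uses an OLS fit with the classical decomposition (Type-II
sums of squares when unbalanced — the designs this package targets are
balanced, so the choice only matters for user data and is stated here).
Post-hoc cell contrasts use the pooled within-cell error and Bonferroni
multiplication, `p_adj = min(1, m·p)`. Variance homogeneity is assumed
throughout; no Welch variant is in scope.

Null simulations (10⁴ replicates) show both procedures hold family-wise
error at 0.05 ± 0.01.

## Synthetic data: what it does and does not show

The generators invert each analysis: stacks are drawn with a known surface
height field (flat, step, or band-limited smooth random field), a membrane
band of known thickness and a target channel whose membrane/cytoplasm mean
ratio equals the specified enrichment exactly before noise; permeability
records invert the Papp equation; impedance traces are
Rn = Rb + 15·CI_true with logistic growth and multiplicative per-window
treatment effects (windows act strictly after the treatment instant, so
the normalization anchor stays pre-treatment); pH traces fluctuate around
the ratio of a known linear calibration. Noise is additive Gaussian
(multiplicative-relative for plate-reader concentrations), clipped at
zero; defaults are 10 a.u. on a 100 a.u. cytoplasm baseline (stack), 5%
relative (assays), and 0.01 ratio units (pH) — magnitudes a practitioner
would call realistic for well-acquired data.

Passing round trips establish that the analysis recovers known parameters
under these conditions. They do **not** establish performance on real
microscopy: no point-spread function, axial chromatic shift, shading,
photobleaching, or cell-to-cell biological heterogeneity is simulated,
and tessellation borders are idealised junctions. Real-data quantities
(absolute TEER of a given cell line, true CFTR ratios, etc.) are
laboratory measurements outside what synthetic tests can reproduce.

Problem sizes used in the shipped checks — 256×256×40 voxels for contour
recovery, 48×48×40 stacks across the enrichment grid, 10³ assay/pH
replicates, 10⁴ null datasets for error-rate calibration — were chosen as
the smallest sizes at which the Monte-Carlo error of each check is
comfortably below its tolerance.

## Known limitations

- No instance segmentation: localization scores whole fields, as the
  masks are per-column, not per-cell.
- The contour detector assumes one apical surface per column; overlapping
  cell layers or debris above the layer will bias z*.
- The linear pH model degrades outside ~6–8.4; conversions there are
  flagged, not corrected.
- Donor depletion and unstirred water layers are ignored in Papp; both
  matter for long assays or very permeable layers.
- Dunnett adjustment is Monte-Carlo: adjusted p-values carry sampling
  error ~(p(1−p)/N)^½; raise `mc_samples` where that matters.
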