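# Methods

`ribbonquant` reimplements, as tested library code, the quantification
pipelines used to characterize ribbon-synapse maturation in zebrafish
lateral-line hair cells: automated synaptic-puncta detection and
cross-channel pairing, evoked GCaMP dF/F0 response classification,
afferent-terminal selectivity indexing, and acoustic-startle scoring.
Because no raw imaging or behavioral data are publicly deposited, every
pipeline is validated by parameter recovery on ground-truthed synthetic
data generated in-package: the generator plants a known per-group
structure, the pipeline must recover it.

## Puncta detection and pairing

The detector follows the standard confocal spot-counting recipe for
Airyscan-style acquisitions (0.043 um/px lateral sampling, 0.15 um z
steps):

1. rolling-ball background subtraction per z-slice (default radius 10 px;
   the radius is not dictated by the biology and is exposed in
   `DetectionParams`),
2. maximum-intensity projection,
3. masking to an externally supplied hair-cell region (a label image; the
   original workflow drew this mask manually, and for some preparations
   pre-segmented volumes in a 3-D viewer — both are replaced here by the
   mask input),
4. mean-based adaptive thresholding: threshold = local mean over a 51-px
   window minus `adaptive_offset`. A *negative* offset raises the
   threshold above the local mean; the default is -50 intensity units,
   chosen so that with the generator's default punctum amplitude (~150)
   the binarization cut sits near the blobs' half-maximum,
5. particle analysis with a per-channel minimum area (presets: lateral
   line CTBP 0.025 um^2, MAGUK 0.04 um^2, CaV1.3 0.025 um^2; inner ear
   CTBP/MAGUK 0.025 um^2; mouse IHC CTBP2/GluR2 0.025 um^2; RNA-FISH
   0.03 or 0.01 um^2) and a circularity window of 0.1-0.5,
6. a distance-transform watershed to break apart touching particles,
   followed by a second particle-analysis pass with the same filters,
7. area (um^2) and mean intensity measured on the background-subtracted
   projection. Whether intensities should come from the raw or the
   background-subtracted projection is ambiguous in the source workflow;
   this package measures on the background-subtracted projection.

**Circularity convention.** Circularity is `4*pi*A/P^2` with `P` the
staircase perimeter: the count of foreground pixel faces exposed to
background. Under this convention a digitized disk scores about 0.5-0.6
and elongated, lumpy spots score 0.2-0.45, which makes the published
0.1-0.5 acceptance window a meaningful filter: it passes irregular
synaptic puncta and rejects compact round blobs. Smooth-boundary
perimeter estimators (weighted pixel-pair counts, traced polygons) score
small digitized ellipses at 0.55-1.0 and would make the same window
reject nearly everything; they were measured and rejected during design.

**Watershed seeding.** Seeds are the h-maxima (depth tolerance 1 px) of a
sigma-1 Gaussian-smoothed Euclidean distance transform, with a guaranteed
seed per connected component. Naive local-maxima seeding shatters small
elongated particles (their digitized distance ridge carries many spurious
1-px maxima); the smoothing plus depth tolerance leaves single lumpy
particles whole while genuinely fused bodies — whose distance map has a
deep saddle at the neck — still receive one seed each and are split.

**Pairing.** Two puncta from opposite channels are partners when their
pixel sets overlap or lie within 2 px edge to edge (minimum distance
between member pixels). Candidates are resolved greedily by ascending
distance with (pre id, post id) tie-breaks into a one-to-one matching;
remaining puncta are reported as unpaired. On well-separated geometry the
greedy matching equals the exhaustive minimum-total-distance matching
(property-tested against a brute-force oracle). Organ summaries divide
whole-organ counts by a supplied hair-cell count (hair cells are counted
manually in this workflow) and report paired/unpaired areas and
intensities separately.

## Synthetic neuromast stacks

Hair cells are elliptical footprints on a grid, sized so the requested
number of synaptic sites fits at the required gaps. Each punctum is a
chain of four overlapping Gaussian lobes (spacing 1.8 sigma, perpendicular
jitter 0.6 sigma, per-lobe size and brightness variation). The renderer
resamples each blob until it passes the detector's own acceptance — size
floor (with a 1.3x margin over the channel minimum), circularity window,
single connectedness and watershed survival, checked at threshold
fractions 0.30-0.55 of peak to cover the adaptive threshold's plausible
landing zone. This constructive coupling is what makes the noiseless
oracle-closure property exact: with noise off, the full pipeline
reproduces planted per-cell counts identically.

Pairing structure is enforced on rendered pixel sets, not nominal radii:
pair members are placed at a 0.2 um centroid offset and re-rendered until
their half-max sets lie within 2 px edge to edge; lone puncta keep at
least 5 px (default) from every opposite-channel half-max set and 2.5 px
support-level clearance from everything, so they can never pair and
same-channel particles can never merge. An optional CaV1.3 channel plants
one punctum almost concentric with every presynapse (pairing with its
postsynapse only at complete sites). Imaging adds a constant background
(20), a planar shading gradient (amplitude 10), per-punctum z-profiles
across 3 slices, and noise with variance `read^2 + gain*intensity`
(read sd 3, gain 0.6) — a Gaussian approximation to photon noise adequate
for threshold-robustness testing; no optical PSF or detector model is
attempted. Identical spec and seed give bit-identical output.

What the generator does not emulate: diffraction/PSF blur correlations,
Airyscan reconstruction artifacts, intensity statistics of real
immunolabel (no published values exist; amplitude 150 +/- 10% is a free
default), 3-D overlap of puncta from different cells, or biologically
realistic spatial clustering of synapses. Passing recovery tests
therefore shows the *pipeline arithmetic and rules* are correct under the
stated imaging model, not that the detector is optimal on real Airyscan
data.

## Calcium movies and dF/F0 classification

Processing: per-timepoint average z-projection; translation-only
registration of every frame to the mean of the first five projected
frames by subpixel phase correlation (classical cross-correlation
normalization — the whitened variant is unstable on smooth, low-texture
frames); spatial Gaussian smoothing with a 3x3 kernel and sigma 2; removal
of the first 10 timepoints (~1 s, initial photobleaching); F0 as the mean
of the next 20 retained timepoints, which with a stimulus starting at
acquisition timepoint 31 makes the baseline window end exactly at
stimulus onset; dF/F0 = (F - F0)/F0 from square ROIs (presynaptic 18x18,
hair bundle 8x8, postsynaptic 12x12 px; an inscribed-disk mask is
available but off by default since the stated ROI sizes are squares).

Response rules, applied on windows derived from the ~100 ms per-volume
interval: presynaptic >10% dF/F0 within the 500 ms stimulus OR >20%
within 1 s of onset (the 1-s window includes the stimulus itself);
hair-bundle >15% within the stimulus AND >15% in the 500 ms after it
(that window starts strictly after the stimulus ends), with bundles
responding to both stimulus directions excluded; postsynaptic >5%
sustained continuously for at least 500 ms. Organ-level magnitude is the
maximum of the mean trace over responsive, artifact-free ROIs.

**Square-wave artifact flag.** The exclusion of movement artifacts is
qualitative in the source workflow; here it is a configurable heuristic: a
trace is flagged when its excursion jumps from below 20% to above 80% of
its own range within one frame and at least half of the post-jump samples
stay above 80% with coefficient of variation < 0.05. The CV allowance
absorbs slow photobleaching across a genuine step; physiological
transients fail the persistence condition because they decay off the
peak.

The movie generator plants a stimulus-locked transient per ROI
(saturating rise, tau 0.18 s, during the 500 ms stimulus; exponential
decay, tau 1.2 s, after — GCaMP6s-like defaults, configurable), normalized
to unit maximum on the movie's own sample grid so the planted peak dF/F0
is exact by construction. Cell bodies are flat-top super-Gaussian
footprints with jittered centers and sizes (a strictly periodic layout
would make translation registration ambiguous), over a weak static
texture (5% of baseline) that anchors registration; bleaching is a slow
exponential (tau 200 s) times a 5% fast component (tau 0.5 s) — the fast
part is what the 10-timepoint trim removes. Residual systematic bias of
the recovered peak (bleach between baseline window and response peak,
plus background dilution of the ROI mean) is about -7%, within the +/-10%
amplitude-recovery budget, and cancels in control/mutant percent
reductions because it is common to both groups.

## Selectivity, behavior, statistics

The selectivity index of an afferent terminal is 100 x (innervated hair
cells of the dominant orientation)/(all innervated hair cells); 50 = no
selectivity, 100 = perfect selectivity, and an exact tie yields 50
regardless of which orientation is called dominant, so no tie-break rule
is needed. Synapse-to-terminal assignment comes from the input contact
table (a manual 3-D inspection step upstream); no image-based assignment
is attempted.

A startle is a straight-line displacement strictly greater than 4 px
(~1.9 mm at the tracker's 0.475 mm/px scale) between any two frame
positions within two frames of stimulus onset (pairs checked: onset/+1,
onset/+2, +1/+2 — "within two frames" read as the whole window, and
displacement read as pairwise distance, not cumulative path length).
Trials with missing tracking in the window are unassessable; animals with
no assessable trial are excluded; per-animal proportions are taken over
assessable trials out of five.

The statistics layer is deliberately textbook: a D'Agostino-Pearson
normality gate (alpha 0.05, requires n >= 8 per sample) choosing between
an unpaired two-tailed t-test and a two-sided Mann-Whitney U; one- or
two-way ANOVA (interaction included when cells have replication) with
Sidak-adjusted pairwise p-values, `1 - (1-p)^m` over the reported family
(the family is a configuration choice — which pairs belong to a family is
not derivable from the figures). Zero-variance data yield F = 0, p = 1
rather than an undefined ratio.

## Problem sizes and numerical choices

Recovery cohorts follow the study conditions: 12 organs per genotype,
15 hair cells per organ for synapse counting; 12 movies per genotype
(110 timepoints presynaptic, 80 postsynaptic, onset at timepoint 31,
noise sd 1% of baseline) for calcium recovery. These sizes give
group-mean estimates whose seed-to-seed spread is well inside the +/-5
percentage-point acceptance bands. Degenerate inputs are flagged rather
than guessed at: empty masks warn and return nothing, uniform images
flag the Otsu threshold as degenerate, zero responsive ROIs yield an
explicit NaN organ maximum with an active count of 0.

## Known limitations

- The pairing is 2-D (projection-based), as in the source workflow;
  volumetric pairing is out of scope.
- The two RNA-FISH minimum-area presets (0.03 and 0.01 um^2) are both
  provided; which probe set maps to which floor is ambiguous upstream.
- The greedy matching is only guaranteed optimal on separated geometry;
  adversarial configurations where greedy and optimal matchings differ
  are possible but do not arise from the generator's placement rules.
- The square-wave flag and the registration model (translation only) are
  the package's own concrete renderings of qualitative upstream steps.
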