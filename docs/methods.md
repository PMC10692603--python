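# Methods

This note documents the models, parameters and numerical choices behind
`microswarm`, and what its synthetic scenes do and do not establish about
real bright-field movies.

## The measurement problem

A mixed suspension of three morphologically distinct telluric microbes —
*Phytophthora*-like zoospores, *Vorticella*-like ciliates and
*Enterobacter*-like bacteria — is imaged in a shallow microchamber while a
potassium gradient spreads passively from a lateral inlet. The analysis
task is to (i) detect every cell as a *spot* in every binarized frame,
(ii) assign each spot to a species purely by its size, (iii) link spots
into per-species *tracks* across consecutive frames, (iv) summarize each
track by mean speed and confinement ratio, and (v) compare those metrics
between named grid-cell *microenvironments* (near/far from the potassium
source; near/far from a sessile ciliate). Because real movies come with no
per-cell ground truth, an agent-based simulator generates scenes with
known identities, positions and speeds against which every stage is
scored.

## Synthetic scenes

### Chamber and optics

The default field of view is 1000×800 µm imaged at 1.3 µm/pixel, frame
interval 0.0735 s, 136 frames (a 10 s sequence). The chamber is 400 µm
deep; densities in cells/µl are converted to agent counts through the
imaged volume (0.32 µl at the defaults), which treats the full depth as
in focus — a simplification that makes the default scenes at least as
crowded as real focal-plane movies. The pixel size is not dictated by the
source data (only a 10× objective); 1.3 µm/pixel makes a ~2 µm bacterium
span one to two pixels and is configurable.

### Potassium gradient

The source is modeled as an instantaneous 2-D point release on the
top-edge midline: C(x, t) = M/(4πD·te)·exp(−|x−x₀|²/(4D·te)) with
te = t + 300 s, so imaging starts at the 5-minute time point of the
dispersal. Defaults: D = 1000 µm²/s (small-ion scale), M = 250 units
(0.5 µl of 500 mM KCl ≈ 250 nmol, units arbitrary since only the contour
shape matters). The kernel is singular at te = 0 and is rejected there.
Mass is conserved on the grid to <1% only when the diffusion length
√(4D·te) fits inside the field; with the default top-edge source much of
the kernel lies outside the image, which is physically correct (the inlet
feeds the whole chamber) and only the within-field contour shape is used.

### Agents

One seeded `numpy` generator drives initialization, motion and rendering
noise, so identical configurations reproduce bit-identical stacks.
Boundaries reflect (closed chamber walls). Per species:

* **Zoospores** (default 200 /µl, body radius 5–7 µm, speed 80–160 µm/s,
  rotational diffusion 1 rad²/s). Each step the heading diffuses; with
  probability 1 − exp(−χ·dt) (χ = 5 s⁻¹ by default) the cell reorients
  directly away from the local concentration gradient plus a small
  angular scatter — negative chemotaxis as biased reorientation. Where
  concentration exceeds the encystment threshold the cell switches
  permanently to an immobile encysted state. The default threshold
  (6.1×10⁻⁵ units) is the concentration at the contour enclosing roughly
  the nearest 20% of the default field at the start of imaging; no
  quantitative dose–response is available, so both χ and the threshold
  are free parameters exposed in the config.
* **Vorticellae** (default 10 /µl, radius 11–15 µm). A configurable
  fraction (default 0.4) are sessile trophonts pinned in place; the rest
  are telotrochs moving ballistically at 250–600 µm/s with a sinusoidal
  heading wobble (amplitude 0.5 rad, 1 Hz), indifferent to the gradient.
  Sessile bodies never move between frames (stalk contraction is not
  modeled).
* **Bacteria** (default 2000 /µl, radius 1.5–2.5 µm, self speed
  2–12 µm/s, rotational diffusion 2 rad²/s) perform a rotational-diffusion
  random walk and are advected by ciliate feeding vortices.

### Feeding vortices

Each sessile vorticella generates a planar vortex. The induced tangential
speed is constant at `strength/core_radius` inside a 20 µm core, decays
as `strength/r` outside it, and vanishes beyond the 450 µm influence
radius reported for a single *Vorticella*. The profile was chosen as the
simplest field that (a) yields circular passive orbits, (b) is
non-increasing with distance, and (c) has a finite reach; a solid-body
core was rejected because its induced speed grows with radius. The
default strength of 1200 µm²/s gives 60 µm/s at the core edge and
~2.7 µm/s at the influence boundary, which reproduces the reported
magnitudes: bacteria far from a trophont average below 10 µm/s, bacteria
in the adjacent grid cells above 10 µm/s. Advection is integrated as an
exact rotation about the nearest vortex center (forward Euler on a
circular flow spirals outward), so a passive tracer orbits at constant
radius by construction.

### Rendering

Bodies are drawn dark (intensity ≈ 50) on a bright background (≈ 200):
zoospores, trophonts and bacteria as disks, telotrochs as 3:1 ellipses of
equal area oriented along the heading. Edges are area-sampled
(anti-aliased); Gaussian noise (default SD 10) is added and the frame
clipped to [0, 255] and quantized to 8 bits. Overlapping bodies merge
into single blobs — deliberately, since occlusion merging is a dominant
artifact of real binary masks. Note that after thresholding, the binary
mask of an anti-aliased disk is identical to the hard rasterization of a
slightly smaller disk, so anti-aliasing improves grayscale realism but
not binary-centroid precision.

What the simulator does **not** model: 3-D motion and defocus, optical
point-spread, illumination gradients, hydrodynamic coupling beyond the
single-vortex advection, cell division/death, flagellar or ciliary
mechanics. Passing tests therefore demonstrate the correctness of the
analysis chain and the qualitative behavioral directions, not performance
on arbitrary real movies.

## Analysis chain

* **Binarization**: global threshold, default 110 within the advisory
  8-bit band [100, 118]; thresholds outside the band warn but run. Dark
  and bright polarities supported; foreground fractions outside (0, 0.5)
  warn.
* **Spot detection**: connected components, 8-connectivity by default
  (diagonal-touching pixels merge; configurable). Centroids are
  unweighted means of member-pixel centers with the convention
  x = (col + 0.5)·pixel_size. Perimeters use the multi-directional
  Crofton estimator, so tests compare perimeter-derived quantities with
  tolerances, never exactly. Circularity 4π·area/perimeter² is clipped to
  ≤ 1 (raster estimators can slightly exceed it for small disks). Quality
  is the pixel count — a monotone proxy for detection confidence — with a
  permissive default threshold of 1 pixel so single-pixel bacteria
  survive. Border-touching components are kept and flagged; no contour
  simplification is performed anywhere.
* **Partition**: thresholds on equivalent radius √(area/π), resolved to
  single boundary values (4.5 and 10 µm) from the per-replicate tuning
  ranges of the original double-filter scheme. Intervals are
  lower-exclusive/upper-inclusive, so a boundary value belongs to the
  smaller-radius class. Spots in a configured gap are reported as
  `unassigned`, never dropped silently or tracked.
* **Tracking**: per-species greedy nearest-neighbor linking under the
  per-species maximal linking distances (bacteria 2, zoospores 15,
  vorticellae 60 µm). Candidate pairs within d_max are accepted in
  ascending distance order, ties broken by the lower spot id —
  deterministic and one-to-one. No gap closing, splitting or merging.
  Greedy matching equals the exhaustive minimum-sum assignment whenever
  inter-spot spacing exceeds 2·d_max, and on seeded small scenes its
  aggregate displacement is within a fraction of a percent of optimal;
  single crowded instances can exceed the optimum by more (the classic
  greedy swap penalty), which is inherent to nearest-neighbor tracking.
* **Metrics**: mean speed = total path / elapsed time (identical to the
  mean of instantaneous speeds at uniform Δt); confinement ratio = net
  displacement / total path, defined 0 for zero-path tracks; tracks
  shorter than two spots carry no motion information and are excluded
  (counted in the log as non-motile candidates). Motility labels: a
  zoospore below 10 µm/s is non-motile (encysted/deflagellated), a
  vorticella below 20 µm/s is a sessile trophont, at or above it a
  telotroch; strict inequality on the slow side.
* **Microenvironments**: a 170 µm square grid labeled A1 (top-left)
  downward/rightward; a track belongs to a cell through its mean position
  (an any-spot rule is available), to a frame range (1-based, inclusive)
  and to one species. Comparisons use one-way ANOVA (scipy) with
  Sidak-adjusted pairwise t-tests, 1 − (1 − p)^m for the family of m
  pairs; each configured condition pair is its own family. Groups under
  two tracks are refused — ANOVA is unreliable for very small samples.
  The statistical unit is the track, with no correction for repeated
  cells across tracks; this mirrors the original analysis and is a known
  limitation.

## Validation experiments and problem sizes

The test suite regenerates all scenes programmatically; sizes were chosen
as the smallest that make each check statistically meaningful.

* *Parameter recovery*: a 150-frame default-density scene with the source
  off and vortices disabled (so configured self-propulsion speeds are the
  whole truth) rendered noise-free. Recovery compares, per species, the
  link-weighted ensemble speed (Σ path / Σ duration over motile tracks
  with ≥ 10 links) to the mean configured speed of swimming agents; an
  unweighted per-track mean would over-weight agents whose tracks
  fragment. Zoospore and telotroch speeds recover to ~1–3%; bacterial
  speeds carry a systematic +8% from binary-centroid digitization of
  ~1.5-pixel bodies at 0.0735 s — the intrinsic noise floor of
  path-length speed estimation for near-pixel-sized objects, present in
  any mask-based tracker at this resolution.
* *Link recovery*: at default densities ~3% of zoospores per frame are
  occluded inside merged blobs; of the links whose endpoints are
  detectable, ≥ 98% are recovered. Unconditional recovery (~93–94%) is
  reported alongside, since occlusion is a detection phenomenon, not a
  linking one.
* *Behavioral directions*: seeded runs reproduce qualitative directions —
  zoospore ensembles drift away from the source and their encysted forms
  concentrate near it; zoospore track speeds are bimodal about the
  10 µm/s cutoff when an encysting subpopulation exists; bacteria in grid
  cells adjacent to a trophont are significantly faster than far-field
  bacteria.
* *Statistics*: the ANOVA F agrees with a from-scratch sum-of-squares
  computation to 10⁻¹⁰, Sidak with its closed form to 10⁻¹², and the
  empirical type-I error over 1000 null simulations sits in
  [0.035, 0.065] at α = 0.05.

Degenerate inputs are handled explicitly: empty masks yield empty tables;
singular diffusion times, NaN fields, non-positive steps, duplicate spot
ids, overlapping species rules, undersized ANOVA groups and zero total
variance are all rejected with errors; zero within-group variance with
unequal means yields F = ∞, p = 0.
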