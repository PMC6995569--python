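# Methods

`nmfpick` implements an unsupervised particle picker and segmenter for
low-contrast cryo-EM micrographs, built around two ideas: multi-scale
anisotropic regularization to stabilize structure against noise, and a
rank-2 non-negative matrix factorization (NNMF) that splits the resulting
scale-space stack into a structure band and a background band. It was
designed around keyhole limpet hemocyanin (KLH)-like specimens, which
project as annuli (top views) and striated rectangles (side views).

## Phase I — scale-space stack

A micrograph `W` (m x n) is min-max normalized to [0, 1] and, by default,
contrast-inverted so that conventionally dark particles become bright
foreground. It is then resampled into `U = 16` scales with factors

    s_u = 2^((u+1)/U - 1),  u = 0..U-1,

i.e. from half size up to full size, dimensions rounded to the nearest
integer. Each scale is regularized by explicit Perona-Malik (PM)
diffusion with 4-neighbor fluxes, reflecting boundaries, time step
`dt = 0.2`, diffusivity

    g(s) = exp(-(s/K)^2),  K = 0.05,

and an iteration count growing linearly with the scale index
(`5 * (u+1)` by default), so coarser scales receive more smoothing. Two
properties of this scheme are load-bearing and tested exactly: symmetric
inter-pixel fluxes conserve total intensity, and for `dt <= 0.25` every
update is a convex combination of neighbors, so the dynamic range cannot
expand.

Each diffused scale forms one octave of 4 Gaussian images
(`sigma = 1.6 * 2^(j/4)`, kernel truncated at 4 sigma), and the
difference of each octave image to the octave's last (a
difference-of-Gaussians variant that targets extended structure rather
than interest points) yields 3 band-pass images per scale. All 48
difference images are resampled back to (m, n) bilinearly, flattened
row-major, and stacked into the feature matrix `M` (48 x mn). `M` is
shifted by its global minimum — not clipped — so the factorization sees
nonnegative data with structure preserved.

## Phase II — band separation and picking

`M ~= S H` is computed by multiplicative updates under a selectable
beta-divergence (Frobenius `beta=2` default, Kullback-Leibler `beta=1`,
Itakura-Saito `beta=0`; the IS option matters when the dynamic range is
wide, since its objective is invariant under global rescaling of `M`).
The update exponent is 1 for `beta in [1, 2]` and `1/(2-beta)` below,
the regime in which multiplicative updates provably do not increase the
objective; the per-iteration objective trace is recorded and tested for
monotonicity. Initialization is seeded uniform in (0, 1], so a run is
bit-reproducible given its seed. Iterations stop at `max_iter = 500` or
when the relative objective change falls below `1e-5`.

With rank 2, each rank-1 slice is collapsed to one image by averaging
over its 48 scale rows (`mean(S[:, j]) * H[j, :]` reshaped to m x n).
The slice with the larger share of spectral power above the radial
median frequency becomes the structure channel `W1`; the other is the
background channel `W2`. Both are Otsu-thresholded (fixed 256 uniform
bins over [0, 1]; the threshold is the exhaustive maximizer of
between-class variance) into `B1`, `B2`.

Candidates are the connected components of `B2` (8-connectivity) whose
area lies in the inclusive gate `[100, 1500]` px. For each candidate
centroid, 64 rays of length `r = 50` px sample `B1` by nearest-pixel
lookup; the border distance `d_i` of ray `i` is the step of the first
positive impulse of the profile's discrete derivative. The intensity
image `W2` is unwrapped around the centroid into a 64 x 50 polar patch.

The false-positive filter computes the cepstrum `C = log|F(patch)|`
(magnitude floored at 1e-8) and asserts that its inverse transform is
purely real — true for any real patch, and kept as a numerical sanity
constraint. The discriminative score is the fraction of non-DC spectral
power of the standardized patch carried by angular harmonics `|k| <= 2`:
a closed border is a band coherent across all rays and concentrates
power in low angular harmonics (measured on clean phantoms: annulus 1.0,
rectangle 0.66, i.i.d. noise 0.075), while this fraction was chosen over
a radial-frequency statistic, which did not separate banded from noisy
patches in our prototyping. Patches scoring at least 0.15 are accepted.

## Phase III — segmentation

For each accepted candidate, a window of the structure binary around the
centroid is reduced to a border band by erasing every pixel whose full
8-neighborhood is foreground (the morphological-interior realization of
"superposing an internal polygon"). The geodesic distance from the
centroid is propagated through the non-border domain with 8-neighbor
chamfer steps (1 and sqrt 2). Open borders are closed by the level set
`{g <= D}` with critical distance `D = 3 * median(d_i > 0)`: leakage
through a gap travels farther than the direct path, so the level set
stays inside the particle. The outer closed contour of the level set is
traced; candidates whose level set produces no closed contour, or no
border impulse on any ray, are dropped.

The contour, viewed as the complex sequence `x + iy` with its centroid
removed, is low-pass filtered by retaining ascending symmetric harmonic
pairs until they carry at least 98% of the non-DC spectral energy.
The smoothed boundary is fitted with a direct least-squares ellipse
(conic with the ellipse-specific constraint), followed by one
outlier-rejection pass that drops points with algebraic residual above
twice the median and refits when at least 5 points remain. The aspect
ratio classifies the view: `a/b < 1.5` is a top view, otherwise a side
view (the threshold value itself lands exactly on "side"); circles
report angle 0 by convention.

## Synthetic study conditions

The generator emulates the statistics that matter to the pipeline, not
electron optics:

- background: `1/f^beta` pink noise (`beta = 1` default), synthesized by
  spectral shaping of white Gaussian noise, standardized; the radially
  averaged power-spectrum slope is verified by fit (within 0.2 over 10
  seeds, mid-band frequencies to avoid finite-size artifacts);
- particles: dark annuli (outer/inner radius 18/10 px) and rotated
  rectangles (56 x 16 px) with two lighter internal striations that
  reproduce the diffuse-border failure mode of real side views;
- contrast: background level 0.65, particle depth 0.35, striation depth
  0.15 (arbitrary units, normalized away by the pipeline);
- SNR: `10 log10(P_signal / sigma_noise^2) = 10 dB` by construction,
  with `P_signal` the mean squared contrast over the particle footprint;
- layout: centers at least 45 px apart, a 2x outer-radius margin to the
  frame, rejection sampling (up to 1000 attempts per particle).

What it does not model: CTF oscillations, focal pairs, particle overlap
and aggregation, ice-thickness gradients, detector fixed-pattern noise.
Passing the synthetic acceptance conditions therefore demonstrates the
pipeline's noise robustness and geometry recovery, not performance on
any real dataset.

## Numerical choices and degenerate inputs

- Constant micrographs normalize to all zeros with a degenerate flag and
  short-circuit the pipeline; a degenerate (constant) channel aborts
  picking with a warning rather than an error.
- KL/IS divergences floor the data and reconstructions at 1e-12.
- Ray sampling is nearest-pixel; out-of-bounds samples read 0.
- Ties: exact tie in channel assignment keeps component order; equal
  pick-truth distances match the lowest pick index; an aspect ratio
  exactly at the view threshold classifies as side.
- Matching is greedy nearest-first with a 10 px cap by default (4 px in
  the acceptance experiment). For truth layouts separated well beyond
  the cap — guaranteed here by the 45 px rule — greedy matching equals
  the optimal assignment; in general it is only a lower bound, and both
  properties are tested.
- All randomness (NNMF initialization, synthesis) flows from explicit
  seeds; two runs with the same configuration produce byte-identical
  CSV output.

## Problem sizes

Unit tests run on 100x100 to 256x256 phantoms. The end-to-end acceptance
experiment uses ten 512x512 micrographs with 6 + 6 particles each
(about half a minute per micrograph on one CPU), the size at which the
default 16-scale configuration and the 50 px search radius are
well-proportioned to the 18 px particle radius.

## Known limitations

- Precision is low at the default acceptance threshold (0.15): the NNMF
  channels are smooth, so noise-blob patches also show substantial
  angular coherence, and the gate removes only the worst offenders. The
  measured false-discovery rate on synthetic data is high, echoing the
  method's known high false-positive rate; a supervised post-classifier
  is the natural remedy and is out of scope here.
- Otsu's threshold on the near-unimodal background channel is bistable
  across NNMF initializations: some seeds give a permissive split (many
  candidates), others a conservative one (few, mostly true particles).
  Top-view recall is unaffected; side-view recall dips in the
  conservative mode.
- Rectangular side views are recovered less reliably than annular top
  views — their borders are longer, thinner, and partially erased by the
  striations — which matches the qualitative behavior reported for the
  original method.
- The scale-space stack assumes particle diameters within roughly a
  factor of two of the defaults; different magnifications require
  adjusting the area gate and search radius, which are exposed in the
  configuration.
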