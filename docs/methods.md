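# Methods

## Data model

A map is a set of n points on a pixel grid, each carrying an intensity
spectrum on a shared, strictly increasing wavenumber axis (cm⁻¹). Points are
kept in canonical row-major order (sorted by y, then x) so that amplitude
vectors are comparable across runs and file round-trips. The data matrix is
assembled channels × points, **uncentered and unscaled**: this is what makes
the first left singular vector proportional to the map's average spectral
shape for non-negative data, and it is the substantive difference from PCA
(which centers and would fold the average into every component).

## Factorization and sign convention

`decompose` computes the thin SVD D = U·W·Vᵀ (LAPACK via
`numpy.linalg.svd`). The SVD leaves the joint sign of each (U_i, V_i) pair
free; we flip each pair so that the entry of U_i with the largest absolute
value is positive. For spectra with a dominant band this is stable and makes
statements like "U₂ is positive at the minor band and negative at the major
band" directly testable. Reconstruction at rank r uses the leading r triples;
its Frobenius error equals √(Σ_{i>r} W_ii²) (Eckart–Young), which the test
suite asserts.

A numerical note: for a matrix of exact rank 2 the *weights* W₃, W₄ … are
zero to machine precision, but the rows V₃, V₄ … are still unit-norm
orthonormal vectors with arbitrary (noise-like) content. Statements about a
"null" component therefore refer to the weighted contribution W_i·V_i, never
to the bare V_i values.

## Effective rank

The effective rank n_e separates signal components from noise components.
Each component i is judged on two criteria:

* **weight**: relative weight W_ii/ΣW ≥ `weight_floor` (default 1e-4);
* **structure**: the V_i-map must be spatially non-random.

"Structure" is quantified as Moran's I under 4-neighbor (rook) contiguity on
the recovered pixel grid — near 0 for spatially random maps, near 1 for
smooth structured maps, −1 for a perfect checkerboard — with a one-sided
permutation p-value (values shuffled over grid positions; default
`n_perm=499`, `alpha=0.01`, seed mandatory). The structure test dominates: a
heavy-weight component with a noise-like map is rejected. Components must
pass as a consecutive prefix, so a "gap" (component 3 passing while 2 fails)
cannot inflate n_e. With these defaults the noiseless two-component phantoms
give n_e = 2 for any weight floor ≤ 1e-4 and alpha ≥ 0.001; a signal-free
noise map gives n_e ∈ {0, 1}.

There is no universally correct rank criterion; weight-only rules and
map-structure rules can genuinely disagree on real data. The permutation-
Moran formalization is this package's choice for making "observable
structure" reproducible rather than a matter of visual judgment.

## Clustering in amplitude space

Points are embedded with their **unscaled** values on V₁ … V_{n_e}.
Scaling by W_ii would shrink the minor component's axis by ~two orders of
magnitude on the phantoms and destroy the clean group separation the
embedding exists to provide; the unscaled convention treats every retained
direction as equally informative. (A `scale`d variant is easy to build from
`SVDResult.amplitudes` if needed.)

k-means (Euclidean, Lloyd, k-means++ seeding, best of `n_init=10` restarts)
runs via scikit-learn with a mandatory seed. Labels are renumbered by
decreasing cluster size (ties by center norm) so partitions are comparable
across runs and point orderings. k is the user's choice; a warning is issued
when k < n_e, since fewer clusters than significant V-maps cannot represent
the resolved structure.

**Outlier removal** (optional, before clustering): a point is excluded when
any embedding coordinate lies more than c·MAD (default c = 10) from that
coordinate's median; coordinates with MAD = 0 are skipped, and a safety cap
raises an error instead of silently discarding more than 10% of the points.
The rule targets corrupt spectra (cosmic-ray spikes, detector glitches) on
maps whose V-value distributions are unimodal. Limitation: on maps where a
large exact-zero background dominates, the MAD collapses to 0 (rule
inactive) or, with noise, to the noise scale — in which case genuinely
structured regions can exceed the fence and trip the cap. That is the
intended failure mode: the cap converts a misapplied fence into a loud
error, and c should be raised on strongly structured maps.

**Cluster spectra** are arithmetic means of member spectra — of the original
data (default) or of the rank-n_e reconstruction. Being convex combinations,
they are mixtures of the generating component spectra whenever components
overlap spatially; only a spatially distinct component yields its pure
spectrum. The test suite asserts both directions (cosine > 0.999 to the pure
bands on the distinct phantom; < 0.999 for every cluster on the overlapping
and on-top phantoms).

## Phantoms

Defaults (all configurable on `ModelSpec`):

| parameter | default | meaning |
|---|---|---|
| grid | 101 × 101 px, origin-centered | map size |
| axis | 1400–2100 cm⁻¹, 2 cm⁻¹ step | 351 channels, covers both bands beyond 2×FWHM |
| band 1 | 1620 cm⁻¹, FWHM 60, height 100 | major component |
| band 2 | 1850 cm⁻¹, FWHM 40, height 1 | minor component (100:1 ratio at profile maxima) |
| circle radii | 30 px / 15 px | component ring centers |
| rect half-width | 3 px | all-or-nothing ring profile (distinct) |
| radial Lorentz FWHM | 6 px | smooth ring profile (overlapping, on-top) |
| arc | center 0°, half-width 20° (HWHM) | minor band's angular confinement (on-top) |

The arc profile uses the half-width-at-half-maximum convention (value 0.5 at
±20°), stated explicitly because "half-width" is ambiguous between HWHM and
FWHM; the radial Lorentzian uses its width parameter as a FWHM.

White noise is zero-mean Gaussian, i.i.d. per channel and point, with
standard deviation (percent/100) × the global maximum intensity of the
noiseless map (= the major band's peak, 100). Gaussian is the standard
choice for additive white noise; real Raman shot noise is Poisson and is
deliberately not modeled — noise-whitening transforms are out of scope, so
conclusions about noise tolerance transfer to real data only after such
preprocessing.

What the phantoms do not emulate: instrument baselines and cosmic-ray
artifacts, band-shape variation across the map, spatially correlated noise,
and more than two components. Passing tests therefore validate the pipeline's
mechanics and its separability claims, not instrument-specific robustness.

## Noise-tolerance experiment

`noise_sweep` regenerates the phantom, injects noise at each level (fresh
seeded draw per replicate, sub-seeds derived as SeedSequence(master, level
index, replicate index)), decomposes, and asks whether the minor component
is still visible in the V₂-map. Visibility is the absolute Pearson
correlation between |V₂| and the ground-truth minor-component support
(rectangular profiles: exact support; Lorentzian profiles: the HWHM region),
tested with a permutation null at p ≤ 0.01 (`n_perm=199`). Absolute values
are used because component sign is conventional. The reported
`threshold_percent` is the smallest swept level at which fewer than half the
replicates detect the component. Default sweep size: 64 × 64 grid, 20
replicates per level — chosen as the package's standard desk-scale setting.

**Known limitation — geometry sets the absolute threshold.** The level at
which V₂ loses the minor component is governed by random-matrix behavior:
the component survives roughly while its singular value W₂ ≈ ‖c₂‖·‖L₂‖
exceeds σ·(mn)^¼ (m channels, n points, σ the noise standard deviation).
With the default ring geometry this transition sits near 3% noise for the
distinct phantom and near 1% for the on-top phantom (whose arc support is
about 3× smaller in ℓ₂ norm), and no detection criterion applied to V₂ —
statistical or visual — can see the component much beyond it. Larger or
thicker minor-component supports move the threshold up in proportion to
√(support area). The 3:1 robustness ratio between the spatially separated
and the superimposed arrangement, and the monotone decay of the detection
fraction with noise, are geometry-independent and are what the acceptance
suite asserts alongside the absolute values.

## I/O and numerical conventions

Tab-separated UTF-8 with mandatory headers; wide (`x y <wavenumbers…>`) and
long (`x y wavenumber intensity`) map dialects, auto-detected from the
header; floats written with 9 significant digits (round-trip error ≤ 5e-9
relative). Spectral-window selection optionally subtracts a per-spectrum
linear baseline anchored on the means of the first and last three in-window
channels (3-channel means damp noise relative to single anchor channels).
Singular values below 1e-10·σ₁ are treated as numerically zero where a rank
statement is needed. Duplicate coordinates, ragged rows, non-shared axes and
non-finite values are rejected with file/line context rather than repaired.
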