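# Methods

This note documents the models implemented in `medcrypt`, the choices made
where the design was genuinely open, and what the synthetic-data experiments
do and do not demonstrate.

## Chaotic keystream

The cipher's pseudorandomness comes from three independent logistic maps
`x <- r·x·(1−x)` with control parameters r = 3.99, 3.98, 3.97, all in the
fully chaotic regime. The three initial values, the three parameters, the
transient length m and the quantiser scale together form the secret key
(a small JSON file). The maps are iterated `m + P·Q + 1` times for a P×Q
image: the first m values (default 1000) are discarded to decouple the
streams from the initial state, the next value of series 1 is reserved for
scramble-corner selection (`floor(v·10⁴) mod 4`), and each remaining value
u is quantised to a byte `floor(u·10¹⁰) mod 256`. The two diffusion
keystreams are XOR combinations of the quantised series, R1 = b₁⊕b₂ and
R2 = b₂⊕b₃, which mixes all three series and flattens the residual
non-uniformity of the logistic map's arcsine-shaped invariant density.
The diffusion boundary bytes (IVs) are the quantised last discarded values
of series 1 and 3, so decryption regenerates them from the key alone.

The chaotic system sits behind a one-function interface so another map
family can be slotted in; only the three-logistic system ships.

Numerical notes: iteration is plain IEEE-754 double arithmetic and
therefore bit-reproducible across runs on the same platform; a 10⁻¹⁰
perturbation of any initial value decorrelates ≥ 95 % of keystream bytes
within 10⁴ draws (Lyapunov exponent near ln 4 amplifies it within ~50
iterations, well inside the transient).

## Cipher

Lossless mode (default) operates directly on the raw 8-bit pixels:

1. **Extended zigzag confusion.** Anti-diagonal boustrophedon scan of the
   (possibly non-square) pixel matrix. The top-left traversal is the
   classic JPEG zigzag (anti-diagonals d = i+j in increasing d, direction
   alternating); the other three corners are its row/column reflections.
   The start corner is chosen by the reserved chaotic draw, which removes
   the fixed-point weakness of the plain zigzag (corner pixels that never
   move). The scan sequence is rewritten into the grid row-major.
2. **Two-pass chained XOR diffusion.** Forward pass
   `E[i] = E[i−1] ⊕ R1[i] ⊕ Q[i]` (left boundary = IV₁), then a reverse
   pass of the same form with R2 and IV₂ run right-to-left. Both chains
   telescope to prefix/suffix XOR scans, so they are computed vectorised;
   inversion uses `P[i] = C[i∓1] ⊕ C[i] ⊕ S[i]`.

**Plaintext-bound key schedule.** Chained XOR diffusion is linear over
GF(2): a one-pixel plaintext difference propagates as a *constant* XOR
difference whose double-pass image changes only ~50 % of bytes — no XOR
chain alone can reach the ~99.6 % NPCR expected of a modern image cipher.
`medcrypt` therefore binds the keystream to the plaintext: a
position-weighted pixel checksum (mod 2³¹, guaranteed to change for any
single-pixel edit in images below ~8.4 Mpixel) perturbs the first initial
value before the chaotic iteration, and travels in the ciphertext
metadata. Any one-pixel change re-keys the whole cipher, so two
ciphertexts of near-identical plaintexts are statistically independent:
NPCR converges to 100·(1−2⁻⁸) ≈ 99.61 % and UACI to
100·(256²−1)/(3·256·255) ≈ 33.46 %. The digest is not secret and leaks a
255-ary checksum of the plaintext; this is the usual cost of
plaintext-sensitive keying and is documented as a limitation.

Wrong-key decryption silently yields noise — there is no integrity or
authentication tag, by design.

**Lossy compression front end** (opt-in): the image is min-max normalised
to [0, 1] (the degenerate constant image maps to Ymin), reflect-padded and
split into m×m blocks (default 8×8), and a per-image autoencoder
(64 → ut tansig hidden → 64 logsig output, default ut = 16, compression
rate t = ui/ut = 4) is trained on the image's own blocks by full-batch
Adam (500 steps, rate 0.01, seeded). Hidden activations are quantised to
bytes to form the H×ut code image on which confusion/diffusion then run.
The decoder weights travel in cleartext metadata (securing them is out of
scope). Reconstruction is lossy; on smooth 64×64 phantoms at rate 4 it
exceeds 25 dB PSNR. Lossless mode is the default because the diagnosis
stages consume decrypted images and medical decryption must be faithful.

## Security metrics

Entropy is Shannon entropy of the 256-bin histogram (0·log 0 := 0).
Adjacent-pixel correlation samples 2000 anchor positions uniformly without
replacement (seeded) with offsets (0,1)/(1,0)/(1,1); a constant marginal
returns 0 with a warning flag instead of dividing by zero. NPCR is the
percentage of differing positions; UACI is the mean absolute difference
over 255, as a percentage — the denominator is 255, the only choice
consistent with the 33.46 % expectation for independent uniform images.
`analyze()` composes all metrics for one image/key pair;
`differential_benchmark()` is the 50-trial, 256×256, one-pixel-difference
study whose means the acceptance script reports. At 2000 sampled pairs the
correlation estimator has standard error ≈ 0.022, so individual seeded
draws on a true-zero-correlation cipher scatter within a few hundredths.

## Improved PCA

Columns are centred, the 1/n sample covariance is eigendecomposed
(`numpy.linalg.eigh`), the spectrum sorted descending, and the selected
component count is the smallest n whose cumulative contribution rate
(eigenvalue share of the trace) strictly exceeds the threshold, default
85 %. Eigenvector signs are fixed so each component's largest-magnitude
entry is positive (reproducibility); with all components retained the
transform inverts to machine precision.

## K-means segmentation

Lloyd iterations with seeded initial centres drawn from the data points:
assign to the nearest centre (Euclidean; ties to the lowest index),
recompute centres as member means, stop on unchanged assignments or
`max_iter`. An empty cluster is re-seeded from the point farthest from its
current centre. The recorded objective trace is non-increasing — the
standard Lloyd monotonicity. Image segmentation clusters raw intensities
and relabels clusters by ascending centre so label k−1 is always the
brightest tissue class (on tumour phantoms the lesion lands there).

## Fuzzy CNN

Forward pass: Gaussian fuzzification of the normalised pixel grid (two
MFs; centres initialised at the 1st/99th intensity percentiles of the
training data so the upper MF sits at bright-lesion intensity, widths half
the centre spacing), fuzzified kernels (Gaussian membership of each 3×3
kernel's weights around a trainable centre Mz), valid convolution of every
membership grid with every fuzzified kernel (sum of products by default; a
min-max composition mode replaces multiply/add with min/max), ReLU, global
max pooling, then centre-of-gravity defuzzification *across the MF axis
per kernel*: y_k = Σ_m My[m,k]·x[m,k] / Σ_m x[m,k]. Each crisp feature is
thus a soft interpolation between the low- and high-intensity
defuzzification centres, which is exactly the quantity that separates
bright-lesion images from normal ones under max pooling. A single sigmoid
unit with trainable weights and bias produces the class score; zero
weights and bias give exactly 0.5.

Training is seeded mini-batch gradient descent on mean binary
cross-entropy (natural log, scores clipped at 10⁻¹²) with separate
learning rates for Wf/bias, My, Mz and Mx. Gradients are hand-derived by
the chain rule; max-pool and ReLU pass subgradients at the arg-max, and
the centre-of-gravity layer has the closed-form Jacobians
∂y/∂My[m] = x[m]/Σx and ∂y/∂x[m] = (My[m]−y)/Σx (falling back to the
centre mean when Σx = 0). Every parameter group passes a central-difference
check at 10⁻⁴ relative error. In min-max mode the min/max compositions are
not differentiated through the kernels; Mz and Mx are frozen and only the
output layers train — a documented limitation. The output layer carries a
bias because two feature clusters that differ only by a positive shift are
not separable by a homogeneous linear functional through a sigmoid; with
zero initialisation it preserves the 0.5-at-zero-weights contract.

The published reference architecture (56×28 input, kernel-height 3/4/5
branches of width-128 strips, 55/54/53×1 pools, 2×128 defuzzification) is
recorded as a named configuration; tests and the pipeline use the reduced
desk configuration (16×16 input, eight 3×3 kernels, global pool), which
keeps the full training loop under a few seconds.

Evaluation uses a stratified 75/25 split and the standard confusion-table
metrics (specificity, sensitivity, accuracy, precision, recall,
F-measure); a zero denominator flags the metric as undefined (None) rather
than raising.

## Synthetic phantoms

A phantom is an axis-aligned ellipse ("brain", intensity 120) on a dark
background (20) with i.i.d. Gaussian noise (σ = 8) and, with configurable
probability, a brighter disk ("tumour", +80 over brain tissue, radius
drawn from a configured range, centre well inside the ellipse). The label
is 1 iff the tumour was placed and the generator also returns the exact
tumour mask. Datasets are exactly stratified and fully reproducible under
a seed. Default intensities give a lesion contrast of 10 noise standard
deviations — cleanly separable by construction, so classifier results on
phantoms demonstrate that the training machinery recovers a recoverable
signal (parameter/label recovery), not clinical performance: phantoms have
none of the texture, partial-volume effects, intensity inhomogeneity or
anatomical variability of real MRI.

Problem sizes used throughout (chosen to exercise every code path at desk
scale): 120 phantoms of 16×16 for classification, 256×256 plaintexts and
50 trials for the differential study, 512×512 for entropy, 100 random
images (1×1 up to 48×48, square and not) for the lossless round trip.

## Known limitations

- The chaotic system the original scheme names is fractional-order but
  unspecified; the three-logistic default is a documented stand-in behind
  a pluggable interface.
- The plaintext digest in the metadata leaks a checksum; metadata is not
  authenticated and decoder weights (lossy mode) travel in cleartext.
- Min-max convolution trains only the output layers.
- Multiclass output, colour images and DICOM I/O are out of scope.
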