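# Methods

This note documents the models, conventions and design choices behind
`wfc`, in the order the pipeline runs them.

## Problem setting

Screening mammography reads a large population of mostly normal images;
the prior probability of disease in the queue is a few percent at most.
`wfc` implements a *triage* (pre-sorting) classifier: it assigns each
image to a normal or suspicious output bin, with a calibrated confidence,
so that confidently normal images can be removed from (or de-prioritized
in) the human review queue.  The design objective throughout is
sensitivity first: a false negative leaves the queue and is unlikely to
be seen again, while a false positive merely costs a second read.

## Regularization

Images are resampled to a common 200 µm pixel spacing (bilinear, with
Gaussian anti-aliasing when downsampling), padded or cropped to a
1024 × 1024 canvas (zero padding; crops anchor to the tissue-bearing side
horizontally and centre on the foreground centroid vertically), and
segmented: Otsu's method on a 256-bin histogram of the full image picks
the background/tissue threshold, the largest 8-connected above-threshold
component is kept as the tissue mask, and everything outside it —
including disconnected film labels and scanner artifacts — is set to
exactly zero without touching tissue values.  Orientation is normalized
by mirroring whenever the tissue centroid falls in the right half-image,
and intensities are divided by their maximum so every image peaks at 1.

Choices the procedure leaves open, fixed here:

* **Order of operations**: resample → canvas → threshold → segment →
  orient → rescale.  Thresholding after resampling makes the histogram
  resolution-independent.
* **Idempotence**: a regularized image carries its tissue mask; running
  the pipeline again reuses that mask rather than re-estimating it, so
  re-regularization is exactly the identity.  (Re-estimating could move
  the threshold by a bin and flip boundary pixels.)
* Otsu on constant images is an error; empty foregrounds are errors.

## Wavelet decomposition

Each regularized image is decomposed with a separable 2D DWT: one level
produces an approximation map `a` (low-pass in both directions) and
horizontal/vertical/diagonal detail maps `h`, `v`, `d`, each decimated by
two; the approximation feeds the next level, eight levels deep.  Eleven
bases are supported: Haar, Daubechies 2/4/8, and the biorthogonal 1.5,
2.2, 2.8, 3.7, 4.4, 5.5 and 6.8 pairs (PyWavelets filter banks).

Conventions, fixed project-wide because feature values depend on them:

* **Filter normalization** is orthonormal (1/√2), so orthogonal bases
  conserve energy exactly.
* **Boundary handling** is half-sample symmetric extension by default;
  a periodic mode is available and is what the reconstruction and
  energy tests use (exact dyadic shapes, perfect reconstruction for all
  eleven bases).  In symmetric mode, subbands of long filters are
  slightly larger than n/2^L; the surplus is boundary coefficients.
* In symmetric mode a level whose input is smaller than the filter
  support is an error; periodic mode remains valid (and invertible)
  down to two samples per axis.

## Features

For each of the 32 subband maps and for the raw regularized image, four
moments of the in-tissue value distribution are computed: mean `M`,
population standard deviation `SD`, skewness `S` = m₃/σ³ and kurtosis
`K` = m₄/σ⁴ (non-excess; Gaussian → 3).  That yields 4 × 33 = 132
features per basis, named `basis:moment-map` (e.g. `bior2.2:M-h5`,
`haar:K-raw`).  The count includes the raw image as a 33rd map: the four
wavelet maps over eight levels alone give 128, and raw-intensity moments
are the natural companions (they are also where microcalcifications show
up most directly in the unsmoothed histogram).

The tissue mask is carried to a map's resolution by 2×2 block-OR applied
once per level — inclusive, so low-resolution cells touching tissue
count as tissue and boundary coefficients carrying lesion signal are
kept — then centre-padded with background to the subband's actual shape
when symmetric extension makes it larger than n/2^L.

Degenerate maps (zero spread, e.g. a one-coefficient level-8 map under a
small canvas) would make S and K undefined; inside batch extraction they
yield S = K = 0 with a warning, while the standalone `moments` operation
raises.  This keeps a single blank corner of one image from aborting a
cohort run.

## Classification

Class-conditional densities are independent univariate Gaussians with
empirical (divide-by-n) means and variances and empirical class priors;
per-feature class variances are floored at 1e-9 times the feature's
overall variance.  Posterior ties go to the suspicious class — in a
triage tool ambiguity must never discharge an image.  Evaluation is
leave-one-out cross-validation; the implementation downdates the
full-sample sums per fold, which is algebraically identical to refitting
n models (verified against a naive refit oracle in the tests) but lets
the exhaustive search below run in seconds.  Folds whose training split
would empty a class are predicted from the remaining data's priors.

Feature subsets are selected by exhaustive enumeration of all 1-, 2- and
3-feature combinations from a restricted pool — one wavelet basis, two
of the four moment types, the 32 wavelet maps, hence 64 candidates and
C(64,1)+C(64,2)+C(64,3) = 43,744 subsets — scored by

    s = w·NTP + (1−w)·NTN,  w = 0.995,

the weighted sum of true-positive and true-negative LOOCV counts.  Ties
break to the higher NTN, then to feature-id order (making the search
result independent of pool ordering).  Tuned classifiers redefine NTP as
correctly classified images of one lesion type and NTN as correctly
classified images of every other type.  Subset selection operates on the
LOOCV counts of the full table (selection outside the fold); the
optimistic bias this carries for generalization estimates is the price
of following the search protocol exactly, and is why the end-to-end
checks report routing sensitivity rather than claiming unbiased error.

## Networks and confidence

Hard classifiers are chained so that bin membership, not a single
verdict, carries the information:

* **Sequential chain** — each stage's normal verdict is a terminal bin;
  suspicious images pass on.  No basis repeats within a chain.  A
  truncation depth (default 5) stops the chain where late-stage normal
  bins become unreliable.
* **Four-tap branched** — two calcification-tuned stages (both normal
  outputs fall through to the mass leg, confirmed suspicious is a tap),
  then two mass-tuned stages (first normal verdict terminates; its
  suspicious verdict is re-examined, giving one mass tap and two normal
  taps).
* **Six-tap branched** — a router stage sends suspicious images to a
  two-stage calcification leg and normal ones to a two-stage mass leg;
  within each leg every normal verdict is its own terminal bin.

The published figures for the branched layouts were not available as
images; the wiring above is reconstructed from their prose description
(tap counts, the single mass-suspicious tap, the pairs of normal bins)
and reproduces the described bin structure exactly.

Network-level evaluation keeps the leave-one-out contract: when image i
is routed, every node's verdict for i comes from a model fit without i.

Bin tallies η(bin, N), η(bin, S) — actually-normal and
actually-suspicious occupants — feed the confidence calculus.  Because
development cohorts are far richer in abnormalities than a clinic,
tallies are rescaled to a target prevalence P_real(S) through

    α = P_real(N)·T_exp(S) / (P_real(S)·T_exp(N)),

with T_exp the experimental class totals.  Confidence that a normal
bin's occupant is truly normal is C(N) = 1/(1 + (1/α)·η_S/η_N), and
symmetrically C(S) = 1/(1 + α·η_N/η_S) for suspicious bins; `C_even`
uses α at 50 % prevalence.  The rescaling is monotone, so bin rankings
agree under any two positive α (property-tested over random tallies).
Pure bins give confidence 1; an empty on-class count gives 0 by
continuity; an empty bin is undefined.

## Synthetic phantoms

The phantom generator produces the structure the method relies on and
nothing more.  Its contract has two halves: the *geometry* the
regularizer assumes, and a *learnability* condition — lesions must be
conspicuous enough that a searched single-basis classifier recovers
nearly all of them (the qualitative regime the method reports on real
screening databases), since the phantoms exist to exercise the full
pipeline, not to pose an open detection problem.  The defaults below
are set to the weakest lesions that honour that condition while staying
clinically plausible.  Concretely: a zero background; one connected half-elliptical tissue
region abutting a randomly chosen lateral edge (so orientation
normalization has work to do); isotropic 1/f² power-law noise inside
tissue, linearly mapped to (0.15, 0.85] (correlated, coarse-dominated,
strictly positive — Otsu then separates tissue from background across a
wide empty gap); and optional lesions that only add intensity:

* microcalcifications: 5 clusters of 2-4 Gaussian-profile spots
  (σ ≈ 0.5-0.9 px) at +0.5 peak contrast;
* masses: one well-circumscribed dense disc — flat core with a 4-px
  soft linear margin — of 45 px (9 mm) radius at +0.3 contrast,
  i.e. an 18 mm lesion denser than any surrounding stroma, the
  configuration of mass this whole-image method is built to catch.
  (A cos²-soft, low-contrast profile was considered and rejected as the
  default: it emulates the ill-defined, near-isodense masses that the
  underlying method does not claim to detect, and it leaves the
  generator unable to satisfy the learnability contract above.)

Lesion randomness is drawn from a stream independent of the tissue
stream, so a lesioned phantom differs from its same-seed lesion-free
twin only at the lesion pixels.  Everything is bit-deterministic in the
seed.

What the phantom does **not** emulate: anatomical texture (ducts,
vessels, pectoral muscle), film-grain and scanner artifacts, breast-size
and compression variation, architectural distortions, and lesions whose
density matches surrounding stroma.  Passing the end-to-end tests
therefore demonstrates that the pipeline is implemented correctly and
recovers separable lesion signal at realistic geometry — not that the
same feature sets would reach the same operating points on clinical
databases.

## Problem sizes and defaults

The shipped study conditions: phantoms default to the full 1024 × 1024
canvas at 200 µm.  The network-level evaluation cohort is 300 phantoms
at one-third prevalence (the mid-scale separability check uses 200
phantoms at one-half prevalence on a 512 canvas); both are fixed-seed.
Every stock node — tuned and sequential alike — uses
`moments="auto"`, scanning all six moment pairs: which pair best
exposes a lesion type is an empirical question answered by the search,
not decided a priori.  (Fixing pairs mechanistically was tried and
rejected: the strongest calcification signal turns out to live in mean
and standard deviation — a cluster of very bright pixels shifts the
image maximum, and maximum-intensity normalization then dims every
other statistic — not in the skewness/kurtosis channel mechanism alone
would suggest.)

## Known limitations

* The 132-feature count interprets the four extra features as raw-image
  moments; an alternative reading (a ninth approximation-only level) is
  possible but not implemented.
* Selection-outside-the-fold optimism, as discussed above.
* Subset search beyond three features, kernel-density class densities,
  undecimated transforms and wavelet packets are out of scope.
* Lesion localization is out of scope by design: the classifier scores
  whole images and never regionalizes an abnormality.
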