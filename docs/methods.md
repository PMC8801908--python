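# Methods

## The model

`fil` implements factorisation-based image labelling: a patch-wise generative
latent-variable model for propagating anatomical labels onto brain MRI scans
that have been spatially normalised and reduced to categorical tissue maps.
The working assumption is that, after normalisation, the residual anatomical
variability within a small patch is low-dimensional and *shared* between what
the tissue image looks like and what the correct labelling is — so a latent
code inferred from the tissue channel alone can predict the labels.

Every volume is categorical: `M + 1` mutually exclusive categories stored as
`M` explicit channels with the last (reference) category implicit. For each
patch, subject `n` and voxel `i`,

    f_ni^(c) ~ Cat( softmax( W_i^(c) z_n + mu_i^(c) ) ),     c in {1, 2},

where channel set 1 is the tissue image (`M1` explicit classes), channel set
2 the anatomical labels (patch-local `M2` explicit codes), and the latent
vector `z_n` (length `K`) is shared by both channel sets — a multinomial
analogue of probabilistic PCA. The softmax has an implicit zero logit for the
reference category, so its log-partition function is
`lse(eta) = ln(1 + sum_m exp eta_m)`.

Priors: each basis column `w_ki ~ N(0, (I_M + 11'/(M+1))^-1)`; no prior on
the means; and `z_n ~ N(z0, P0^-1)` with `(z0, P0)` supplied empirically by
the patch-coupling random field described below.

## Variational EM with Böhning's bound

The posterior over latents is approximated by independent Gaussians
`q(z_n) = N(z_hat_n, V_n)`. The categorical likelihood is made conjugate by
majorising `lse` with Böhning's fixed-curvature quadratic bound, whose
Hessian `A = (I_M − 11'/(M+1))/2` dominates every true softmax Hessian in the
Loewner order; the bound touches `lse` in value and gradient at its expansion
point. All four update families are then closed-form Gaussian solves:

* **E-step**: `V = (P0 + Σ_i w_i W_i' A W_i)^-1`,
  `z_hat = V (P0 z0 + Σ_i w_i W_i' (f_i − ρ_i + A(η_i − μ_i)))`, with the
  expansion point `η = W z_prev + μ` refreshed from the previous mean at the
  start of every repeat. The sum over voxels runs over *both* channel sets
  during training and over the image set only at test time.
* **M-step for μ**: a Gauss–Newton-like step
  `μ_i ← (Ñ_i A)^-1 Σ_n u_n w_ni (f_ni − ρ_ni + A μ_i)` with effective count
  `Ñ_i = Σ_n u_n w_ni`.
* **M-step for W**: solved on `vec(W_i)` (category index fastest) with
  Hessian `H_i = Σ_n u_n w_ni (z_hat z_hat' + V) ⊗ A + I_K ⊗ (I_M + 11'/(M+1))`;
  the prior term keeps `H_i` positive definite even with no data, so empty
  patches shrink to `W = 0`. μ and W are updated sequentially, μ first.

Because every update maximises a surrogate that touches the bounded evidence
lower bound at the current estimate, the ELBO reported by `fil.vem.elbo` is
non-decreasing along the update sequence (a property the test suite checks).

Two kinds of observation weight thread through every sum: per-subject
replicate weights `u_n` (translation augmentation) and per-voxel weights
`w_ni` (Jacobian determinants of the normalising deformation; zero on
padding). With all weights equal to one the formulas reduce exactly to the
unweighted updates.

## The conditional random field over patch latents

Patches are not independent: the joint vector `x_n = [z_n; y_n]` of a patch's
latents and the concatenated latents of its up-to-six face neighbours
(fixed layout order −x, +x, −y, +y, −z, +z; boundary patches simply have
fewer neighbours) is modelled as `x_n ~ N(0, P^-1)` with a conjugate Wishart
posterior `q(P) = W(Ψ, ν)`:

    Ψ = ( Σ_n u_n E[x_n x_n'] + Ψ0^-1 )^-1,     ν = Σ_n u_n + ν0,

where the expectation uses the posterior means plus the `V` (self) and
block-diagonal `U` (neighbour) covariance blocks. Through `E[P] = νΨ` this
induces the per-subject empirical prior
`P0 = ν Ψ_zz`, `z0 = −Ψ_zz^-1 Ψ_zy y_hat_n` consumed by the E-step.

The prior scale follows `Ψ0^-1 = I ν0 v0`. Three ν0 policies are exposed:
`improper_1` (ν0 = 1, improper), `least_informative`
(ν0 = K_total + 0.01, a proper prior whose dimension tracks pruning), and a
user-supplied `scaled` value. The default is `least_informative` with
`v0 = 1.0`. Patch updates are scheduled in red-black (checkerboard) order —
patch `(px, py, pz)` is red iff `px + py + pz` is even — so a sweep updates
one colour class while conditioning only on latents held fixed within the
sweep, which keeps the mean-field factorisation valid. The Wishart
posteriors are refreshed once per outer iteration, after both sweeps.

## Training schedule and defaults

Defaults (`TrainConfig`) are the settings used for the final model fit:
4×4×4-voxel patches; up to `K = 24` latent components per patch; four outer
iterations, each holding five EM sub-iterations per patch with the E-step and
the M-step each repeated five times; translation augmentation up to a
3-voxel radius with Gaussian weights of standard deviation 2 voxels,
renormalised to sum to one (19 offsets at radius 1.5, 123 at radius 3);
pruning after every second outer iteration.

Implementation choices where the procedure was genuinely open:

* **Initialisation.** μ starts at the weighted empirical per-voxel log-odds
  clamped to ±log(1e4); W entries i.i.d. N(0, 0.01²) under the config seed;
  `z = 0`, `V = I`. The small-W start keeps the first Böhning expansion near
  the mean model. Training is bit-reproducible given the seed.
* **Taylor point.** The expansion point is refreshed at the start of every
  E-step repeat and every M-step repeat (each refresh is itself a valid
  majorise-maximise step, so monotonicity is preserved).
* **Augmentation** shifts image, labels and weight volume jointly — required
  by the shared-latent model — with out-of-field voxels entering at weight
  zero; a replicate with weight `u` contributes exactly like `u` fractional
  subjects.
* **Label-category reduction.** Each patch encodes only the global label
  codes with nonzero weighted mass in that patch, ordered ascending with the
  background code rotated last as the patch-local reference; a
  background-only patch degenerates to a single-category model.
* **Pruning (ARD).** The latent second moment is eigendecomposed; the
  rotation is applied to `z`, `V` and (inversely) both bases, which provably
  leaves every prediction unchanged, and components whose share of
  post-rotation weighted latent variance × squared basis norm falls below
  `prune_tol = 1e-6` of the patch total are dropped. The Wishart posteriors
  are rebuilt by congruently rotating Ψ block-wise and deleting the dropped
  rows/columns, keeping ν — this preserves positive definiteness and the
  information in the retained subspace.
* **Padding.** Volumes whose dimensions are not multiples of the patch size
  are zero-padded (pure reference mass) on the high side; padded voxels
  carry weight zero everywhere, so they cannot bias any fit, and μ is left
  untouched at voxels with no effective data.
* **Numerics.** All SPD solves use Cholesky with a single jitter retry
  (+1e-8·trace/K on the diagonal) before raising; `lse` is stabilised by
  shifting with `max(0, max η)` so the implicit zero logit participates;
  hard-label ties break to the lowest code. `K = 0` is a valid degenerate
  model: the E-step returns empty latents and decoding yields the weighted
  empirical label frequencies — the majority-voting baseline.

## Labelling a new image

Encoding precomputes per patch `V = (ν Ψ_zz + W'(I⊗A)W)^-1`, `B0 = −V Ψ_zy ν`,
`B1 = V W'`, `B2 = V W'(I⊗A)W` from the *image* basis only, then iterates

    z* ← B1 f* + B0 y* + B2 z* − B1 softmax(W z* + μ)

which is algebraically one bounded E-step with the CRF conditional prior
substituted in (the test suite verifies the equivalence to 1e-10, and that a
fixed point satisfies the stationarity condition of the underlying
objective). Latents start at zero; the default schedule is 10 red-black
sweeps with 5 inner iterations per patch. When a voxel-weight volume
accompanies the target, the cache is rebuilt per subject with the weights
entering exactly as in training. Decoding maps `softmax(W2 z* + μ2)` per
voxel from each patch's local label subset back to the global codes;
`synthesize_template` does the same with the image basis to produce the
subject-specific tissue template intended as the moving image for an
external registration refinement (registration itself is out of scope, as is
warping predictions back to native space). Decoding uses the posterior mean
only; sampling from `N(z*, V*)` is available behind a flag but off by
default.

## The synthetic generator

`fil.synth.generate` samples directly from the generative process above:
smooth unit-variance Gaussian fields (FWHM 4 voxels) provide per-patch means
and bases (basis entries scaled to a total latent-driven logit SD of
`basis_scale = 2` per voxel); per subject, the latent field over the patch
grid follows a separable first-order Gaussian autoregression with
face-neighbour correlation `smoothness = 0.6` (deliberately *not* the
model's own Wishart CRF, so that structure recovery is a falsifiable check
rather than a tautology); voxels are hard categorical draws. Defaults:
16³ voxels, 4³ patches, 2 explicit tissue classes, 4 explicit label codes
(background 0 as reference), `K_true = 3`, 120 subjects.

What the generator emulates: simplex-valued tissue/label pairs driven by
shared low-dimensional latents with spatially correlated patch codes, plus
categorical sampling noise. What it does not emulate: registration error,
tissue-segmentation error, partial-volume effects, MR contrast or bias
fields, anatomically realistic label topology, or inter-rater labelling
noise. Passing the recovery experiment therefore demonstrates that the
estimation machinery recovers the structure the model class expresses — not
that the model is adequate for any particular real dataset.

Because any factor model is identified only up to rotation of the latent
space, recovery is scored by predictive Dice overlap and by principal angles
between true and estimated bases, never by elementwise comparison of W.

## The recovery experiment

The end-to-end check (test suite and `scripts/acceptance.py`) generates a
16³ cohort (M1 = 2, M2 = 4, K_true = 3) with 100 training and 20 held-out
subjects, trains for four outer iterations with `K_max = 8` and no
augmentation — the synthetic volumes are in perfect register by
construction, so translation augmentation, which models registration
uncertainty, has nothing to compensate — and requires the trained model's
mean held-out hard-label Dice to strictly exceed that of the `K = 0`
majority-voting baseline trained identically. `K_max = 8` leaves ample
headroom above `K_true` while keeping the experiment small enough to run
routinely.

## Limitations

Single-resolution, CPU-only; the diffeomorphic registration and tissue
segmentation that produce the inputs are upstream and out of scope, as is
the registration-refinement loop against the synthesised template;
augmentation at radius 3 multiplies the in-memory training set 123-fold, so
large cohorts need the radius reduced or substantial memory; the Wishart
coupling is restricted to face neighbours and a Gaussian latent field;
semi-supervised training with unlabelled subjects is not supported.
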