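# Methods

## Overview

`gexmol` generates candidate small molecules conditioned on a transcriptomic
signature. It couples two models:

1. **A SMILES-to-grammar translator** that defines a continuous molecular
   latent space. A GRU encoder reads the canonical SMILES character by
   character (one-hot); its final cell state, squashed elementwise by tanh,
   is the molecule's latent vector x ∈ [−1, 1]^L. A GRU decoder maps a
   latent back to a sequence of context-free-grammar production rules,
   which deterministically expands to a SMILES string.
2. **A two-stage conditional WGAN-GP** over that latent space. Stage I
   maps (noise z ~ N(0, I), signature c) to a latent G0(z, c); stage II
   refines a latent under the same condition, G1(s0, c), through residual
   blocks x ← x + W2·act(W1·x + b1) + b2. Each stage has an unconditional
   Wasserstein critic D and a conditional network f(x, c) ∈ (0, 1) scoring
   whether a latent matches a signature.

Losses per stage:

    L_D = E[−D(x)] + E[D(G(·, c))] + λ·E[(‖∇_x̂ D(x̂)‖₂ − 1)²]
    L_G = E[−D(G(·, c)) − α·log f(G(·, c), c)]

with x̂ uniform on segments between paired real and generated latents and
λ = α = 10. The critic sees only molecules, never the condition: all
conditioning pressure on the generator comes through the α·log f term.

## Grammar and decoding

The shipped grammar (`gexmol/data/smiles_cfg.txt`) is a SMILES CFG in the
grammar-autoencoder style: organic-subset atoms, bracket atoms with charge/
H-count/isotope/class, ring bonds, branches; 79 productions including one
padding rule `Nothing -> None`. It is data, not code — alternative dialects
can be dropped in. A molecule is represented by the leftmost derivation of
its canonical SMILES (stereochemistry and isotopes are stripped first; the
grammar does not model them).

Parsing uses a memoized span parser (no reachable ε-productions, so spans
strictly shrink and left recursion terminates); an independent depth-first
enumerator serves as a test oracle. Decoding is **stack-masked**: a symbol
stack replays the derivation, and at each step every rule whose left-hand
side differs from the stack top gets probability zero before the
argmax/sample. Any decode is therefore grammatically consistent by
construction; chemical validity (toolkit sanitization) is a separate,
weaker property that is measured, not guaranteed. If the stack is not empty
after T steps the sequence carries a `truncated` flag and counts as invalid
downstream.

The translator decoder receives the previous rule's one-hot (teacher-forced
during training) concatenated with the latent at every step, and the latent
also initializes the GRU state; re-feeding the latent keeps the
conditioning signal from fading over long derivations. The elementwise tanh
on the encoder state is a deliberate reconciliation: generators end in
tanh, so real and generated latents must share [−1, 1]^L support.

## Numerical machinery

No deep-learning framework is used; `gexmol.autodiff` is a small
reverse-mode engine over numpy arrays. Vector-Jacobian products are
expressed as graph operations, so gradients are differentiable again —
`create_graph=True` is what lets the gradient penalty (a function of
∇_x̂ D) be back-propagated into critic weights. The penalty evaluates the
critic as a deterministic function (dropout off) so the input gradient is
well defined; a 1e−12 stabilizer inside the norm keeps the square root
differentiable at zero (and shifts the zero-critic penalty by ~2e−6, which
tests account for). f outputs are clamped to [1e−7, 1−1e−7] before logs.

Batch norm (generators only, as specified) uses batch statistics in
training and running averages (momentum 0.9) at inference. Dropout: 0.2 in
the translator decoder, 0.4 in critics and conditional nets. LeakyReLU
slope is 0.2 everywhere. All networks train with RMSprop (ρ = 0.9,
ε = 1e−7) at a single learning rate.

The Fréchet distance d² = ‖μg−μr‖² + Tr(Cg+Cr−2(CgCr)^{1/2}) is computed
via eigendecomposition of Cr^{1/2}·Cg·Cr^{1/2} with negative eigenvalues
clipped at zero; inputs failing PSD beyond tolerance 1e−6 raise.

## Training schedule

Full-scale defaults follow the reference protocol: 1000 epochs × 125 steps,
batch 256, learning rate 5e−5, critics (and conditional nets) updated every
step, generators every 10 steps, both stages stepped in the same loop. The
conditional networks' training is not prescribed anywhere we could find, so
they are fitted jointly with the critics by binary cross-entropy on matched
versus within-batch shuffled (latent, signature) pairs — the matching-aware
construction standard in conditional-GAN work. f0 and f1 are separate
networks of identical architecture. A single run seed fans out through
`numpy.random.SeedSequence.spawn` to independent streams for
initialization, batch sampling, noise, interpolation, dropout and
monitoring, making runs bit-reproducible on one machine.

At each epoch end one latent is generated per monitored training signature
and compared with the real latent distribution by Fréchet distance (both
stages); at desk scale the monitored set is subsampled (default 256).

## Synthetic world

Desk-scale data emulate the L1000 shape: molecules paired with z-scored
signatures, plus query signatures with no paired molecule. The biology is
replaced by a known mechanism: a molecule acts only through d = 5 structural
descriptors (heavy atoms, aromatic atoms, rings, heteroatoms, branch
points), mapped to gene space by a fixed random projection A (G × d,
entries N(0, 1/d)) plus N(0, noise_sd²) noise, then per-gene standardized
against the noiseless corpus distribution. Defaults: G = 64 genes,
noise_sd = 0.1, corpora of 200–1000 molecules enumerated from random
C/N/O trees and substituted five-membered/six-membered aromatic rings, all
grammar-parseable and toolkit-valid by construction.

Query ("knock-out-like") conditions are jittered mixtures of two corpus
descriptor profiles, rejected unless they lie ≥ 0.5 z-scored descriptor
units from every training profile — so no training molecule exactly
realizes a query, and the nearest-neighbour baseline cannot be trivially
perfect. Because conditioning is descriptor-mediated, condition fulfilment
is directly measurable: compare descriptors of generated molecules with the
query's target profile.

What this world does **not** emulate: transcriptomic covariance structure,
cell-line and dose effects, many-to-one compound–signature multiplicity,
and realistic chemical diversity. Passing tests show the machinery learns a
recoverable molecule→signature mechanism at desk scale; they say nothing
about performance on real L1000 data at full scale.

## Reference experiments and problem sizes

* **Toy translator run** — 200 molecules ("small" complexity), 50 epochs,
  L = 96, batch 32, RMSprop 5e−3. Reports teacher-forced token accuracy
  (≥ 0.9 expected) and is bit-reproducible under a fixed seed.
* **Conditional recovery** — corpus 500, G = 64, noise 0.1, 20 queries.
  The reference translator trains 80 epochs (autoregressive reconstruction
  of the library ≈ 95%). The stage-I GAN trains 500 epochs × 25 steps,
  batch 128, lr 2e−4, width-64 networks, λ = α = 10 — the schedule where
  the epoch-end Fréchet curve has plateaued and results are stable across
  seeds. For each query, 100 latents are generated and decoded (argmax);
  the mean descriptor vector of the valid molecules is compared with the
  query's target profile by Spearman correlation and by z-scored L2 error
  against the Euclidean signature nearest-neighbour baseline. Typical
  outcomes: mean ρ ≈ 0.85–0.9, generator beats the baseline on ~60–70% of
  queries, Fréchet distance drops roughly tenfold from the first epoch.
  The win fraction over 20 queries is binomially noisy (±11 points), so
  the stochastic acceptance check aggregates a majority over three seeds.

These sizes are the package's desk-scale reference conditions; full-scale
dimensions (978 genes, 256-d latents, 1000-d noise, [512, 256] branches)
remain the configuration defaults.

## Design choices where the design was open

* **Latent bounding** (tanh on encoder states): required so generated and
  real latents share support; documented as a deviation-by-necessity since
  raw GRU cell states are unbounded.
* **Decoder conditioning**: latent initializes the decoder state *and* is
  concatenated to each step's input. The pure init-state variant loses the
  signal over ~50-step derivations at desk scale.
* **f-net training**: BCE on matched vs shuffled pairs, on the critic
  schedule (see above).
* **Gradient penalty interpolation**: uniform ε per pair; penalty computed
  on the dropout-free critic.
* **Stage-II identity behaviour**: with zero residual weights and an
  identity output layer, G1 reduces to tanh(s0) — used as a structural
  test.
* **Mann–Whitney U**: exact enumeration for group sizes ≤ 8 without ties,
  otherwise normal approximation with tie and continuity correction
  (delegated to scipy, cross-checked against exhaustive enumeration).
* **Generic scaffolds**: Murcko framework with atoms→C, bonds→single, the
  toolkit's standard abstraction.
* **"Classification score"**: computed with the stage-I conditional net f0
  by default (configurable to f1) — f0 is the score the conditioned
  generation optimizes first.

## Known limitations

* The translator is trained per-corpus at desk scale; out-of-library
  molecules encode but decode less reliably.
* Conditional-mean recovery carries a small bias toward high-confidence
  regions of f (visible on a 2-d Gaussian task as deviations of order 0.05
  beyond 3 standard errors at some bins before convergence).
* Validity of decoded molecules is grammatical by construction but chemical
  only empirically (ring-closure digits and valence are not tracked by the
  grammar).
* The pure-numpy stack is single-threaded and desk-scale only; full-scale
  training (10⁶ molecules, 978 genes) is out of reach by design.
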