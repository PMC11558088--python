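# Methods

This note documents the models implemented in `duplexml`, the
assumptions behind them, the parameters that matter, and what the
synthetic data generators do and do not emulate.

## Notation

A duplex is two 5'→3' strands plus a base-pairing map.  In the string
notation, every contiguous paired run (*stack domain*) is wrapped in one
pair of parentheses and a single `.` separates the strands.  Two
conventions are not derivable from the notation alone and are fixed
here:

* **Cross-strand matching** is nested (last-opened, first-closed) at the
  domain level, as in dot-parens-plus: the *k*-th domain of strand 1
  pairs with the (*n*−*k*+1)-th domain of strand 2, antiparallel.
  Pseudoknots and complexes of more than two strands are out of scope.
* **Shorthand**: when strand 2 is exactly the complement of strand 1's
  paired region, the encoder may drop it and write the single-strand
  form (`(CGCG)`); a flag (`allow_shorthand`) controls this.

Coordinates are 0-based half-open internally; error messages and all
user-facing output are 1-based.

## Descriptors

Four term kinds decompose a string: stacking quartets (width-4 windows,
step 1, over each parenthesized domain, parentheses included — a domain
of L paired bases yields L−1 quartets and needs L ≥ 2), dangling tokens
(one per unpaired terminal nucleotide; the nucleotide adjacent to a
parenthesis absorbs it together with the first nucleotide inside, others
are starred), looping tokens (single characters between two domains) and
initiating tokens (`(X`, `X)` per domain, plus `.`).  The alphabet
census is fixed by combinatorics: 400 stacking (256 middle + 128 end +
16 double-parenthesis), 36 dangling (32 with parentheses), 4 looping,
9 initiating.  Reverse-complement canonicalization (lexicographic
minimum of a token and its opposite-strand image) reduces the middle
quartets to (4⁴+4²)/2 = 136 classes and the end terms to 128/2 = 64.

For strings containing `.`, stacking and initiating terms are extracted
from strand 1 only (the duplex is encoded once; a flag extracts both
strands), while dangling and looping nucleotides of both strands always
contribute since they are physically distinct nucleotides.

Term identifiers (the *Number* feature) are assigned kind-major in
lexicographic order — stacking 1–400, dangling 401–436, looping
437–440, initiating 441–449 — a deterministic convention chosen because
any dense assignment works as a model input.

## Energies

A stacking quartet involves six pairwise interactions (two hydrogen-bond
pairs 1·4 and 2·3; intra-strand 1·2 and 3·4; inter-strand 1·3 and 2·4);
a dangling term keeps three (one hydrogen bond, plus the dangle base's
intra- and inter-strand stacking).  Each pairwise energy is
counterpoise-corrected (Boys–Bernardi), `E_int = E_AB − E_A − E_B` with
the monomers evaluated in the dimer basis, and averaged over the
supplied structural conformations (two by default) before summation.
Double-parenthesis terms `(XY)` are defined as the mean of the other 24
members of their 25-combination family `xXYy`, x ∈ {A,C,G,T,(},
y ∈ {A,C,G,T,)}, read jointly so parentheses stay matched — the only
reading that yields 25 combinations containing `(XY)` itself.

The shipped synthetic energy table draws one value per
reverse-complement class, uniform over [−52.174, −20.615] kcal/mol for
stacking terms and [−15, −2] for parenthesis-bearing dangling terms;
starred dangling, looping and initiating terms are zero.  It preserves
the structural facts a real table would have (class sharing, the
averaging rule, the value range) but **not** sequence-specific physics:
in a real table, energies correlate with base identity (G·C-rich
quartets bind more strongly), which the uniform draw deliberately does
not encode.  Conclusions about *which* sequences are strong binders
therefore cannot be read off the synthetic pipeline; the pipeline's
mechanics (featurization, training, acquisition) are exercised fully.

## Entropy

Each unpaired nucleotide contributes (entropy coefficient) × (rotatable
bonds).  The coefficient ladder is 0.33 for the nucleotide adjacent to a
stack domain, 0.67 for the second, 1.0 beyond; stacking and initiating
terms are 0 (structurally locked).  Loop nucleotides use the distance to
the nearer flank — the symmetric reading of "decreases approaching a
stack domain".  The rotatable-bond count per unpaired nucleotide is not
fixed by the bond classes alone (glycosidic C–N, two C–O, one C–C, two
backbone P–O); the default B = 6 is the literal count of those classes
for a generic nucleotide and is configurable.  Base-specific counts and
temperature-dependent entropy are out of scope.

## Matrices and normalization

Columns follow descriptor order (stacking → dangling → looping →
initiating, string order within kind — a deterministic convention),
zero-padded on the right to the dataset-wide maximum width.  Default
scalers are fixed and data-independent wherever a natural range exists:
identifier / 449, energy magnitude / |table minimum| (sign-preserving,
so zero-energy terms and padding coincide at 0), entropy / B, and
temperature mapped from the 13–49 °C design range onto [0, 1].  A batch
min-max `MatrixScaler` with frozen training statistics is provided for
user-supplied tables whose range is unknown a priori; it excludes
padding columns (identified by a zero Number entry) from its statistics
and maps constant rows to 0.

Strand-displacement inputs are two 5-row matrices (invading strand,
product complex) sharing a constant temperature row.  The fourth row is
the per-descriptor mean of per-nucleotide equilibrium unpaired
probabilities; the built-in stub derives it from the declared secondary
structure (0 inside a stack domain, 1 outside), and a per-position
override file accepts values from any external partition-function
calculation.  Multi-descriptor terms (quartets) take the mean over the
nucleotides they cover.

## Nearest-neighbor baseline

44 parameters: 2 initiations keyed by the terminal pair type (A·T vs
G·C, applied at both ends of every stack domain), 10 canonical stack
dimers, 32 dangles keyed by (dangle base, adjacent paired base, 5'/3'
side).  Terminal-AT penalties, loop parameters and salt corrections are
excluded.  Motifs are extracted per physical strand, which makes the
prediction invariant under swapping strand labels.  Fitting is ordinary
least squares on motif counts; the design matrix must have full column
rank over the 44 motifs, otherwise a structured error lists the
unidentifiable motifs.  The shipped `illustrative_parameters()` are
round placeholder magnitudes for demos, clearly marked as such; all
quantitative work uses fitted or synthetic parameters.

## Regressor

One convolution layer whose kernel spans the full matrix height (N × 4,
stride 1, no pooling), ReLU, dropout, flatten, then a 256/128 ReLU
feed-forward head with a linear scalar output — the smallest
architecture consistent with "convolve, flatten, feed forward".  Two-
matrix displacement samples share the convolution; the flattened outputs
are concatenated before the head.  Training: Xavier initialization, MSE
loss, Adam, 8:2 train/validation split, early stopping with
best-weight restoration.  Defaults are batch 999 — effectively full
batch at these dataset sizes — learning rate 0.001 and 250 epochs;
filter count (32), dropout rate (0.2), activation (ReLU) and patience
(25) are free design choices exposed as configuration.  The implementation is plain numpy with exact
analytic gradients, fully deterministic given the seed; dropout is
disabled at prediction time, so repeated predictions agree bit-exactly.

Zero-padding interacts with the flatten contract: predictions are
stable within one dataset-wide width W, but extending W changes the
flattened dimension and requires retraining — matrices from a new
dataset must be padded to the training width.

## Active learning

Query-by-committee with 4 members differing only in their weight
initialization seed; the data split is re-drawn per iteration with an
iteration-indexed seed, and the committee retrains from scratch each
iteration (no warm start).  Disagreement is ε = max |member − committee
mean|; candidates are pool items with ε above the threshold (0.6
kcal/mol for hybridization, 0.5 log-units for displacement), acquired
largest-first up to the cap (16 / 10 per iteration) until none remain.
A hard iteration cap (default 50) guards non-termination and emits a
warning rather than raising.

## Synthetic pools and oracles

The hybridization pool holds perfect duplexes and dangled duplexes
(10 000 + 10 000 by default), stacks 5–14 nt, dangles 1–4 nt.  Ten
structural types are generated, indexed by which strand termini carry
dangles: none, the four single termini, both termini of one strand (2),
the two diagonal one-per-strand arrangements, and all four.  This
taxonomy is declared, not canonical; it is one concrete enumeration of
the possible dangle placements.  A hygiene filter (switchable) rejects
runs of ≥ 5 identical bases and self-reverse-complementary stacks —
practical sequence-design hygiene, our choice.  The displacement pool
(10 000 sets) uses toeholds 4–14 nt, poly-T spacers of 0–10 nt kept
shorter than the toehold, and 22-nt branch domains; the template carries
a same-length poly-C spacer so the two spacers are never complementary.

The free-energy oracle is the NN backbone plus Gaussian noise
(σ = 0.2 kcal/mol by default, a plausible melt-fit precision), with
backbone parameters solved from the target label window over the
designed stack-length range: initiations −0.78, dimers uniform in
[−1.05, −0.97] (mean ≈ −1.01), paren-adjacent dangles in [−0.10,
−0.02], giving pool-wide ΔG° spanning ≈ [−14.7, −5.58] kcal/mol.
The rate oracle is an openly phenomenological saturating-toehold form,
log₁₀k = a + b·min(L_toe, 7) − c·L_spacer + d·(T − 25), with a = 3.5,
b = 0.3, c = 0.18, d = 0.02 per °C and σ = 0.15 log-units, calibrated
once on the design pool so the span across 13–49 °C is ≈ 2.5 decades,
the 25 °C median log k ≈ 4.8, and warming accelerates the reaction.
Noise is keyed by (seed, item id), so oracles are pure functions.

Because both oracles are additive in motif-level features, they test
whether the pipeline can recover additive structure from descriptor
matrices — they cannot certify performance on real measurements, where
labels contain non-additive physics (secondary structure in single
strands, salt and concentration effects, melt-curve fitting artifacts).

## Desk-scale configuration

Active-learning demonstrations and the acceptance script run on a
500-item pool with a 100-item held-out set and a compact committee
network (32 filters, 128/64 hidden units, batch 32, learning rate
0.003, ≤ 300 epochs, patience 35, dropout 0.1; see
`DESK_COMMITTEE_CONFIG`), the package's chosen problem size for
single-CPU runs.  Under these conditions the loop converges to zero
candidates in ~15–25 iterations with ~200–300 labels acquired, and the
committee-mean prediction on held-out duplexes lands well inside the
2σ + 0.3 kcal/mol error budget.  Full-scale defaults remain on the
estimator and the pool specs.

## Numerical notes and limitations

* Least-squares fits use `numpy.linalg.lstsq`; noiseless NN recovery is
  exact to ~1e−12 kcal/mol.
* Candidate selection breaks ε ties by pool index; committee member
  seeds derive deterministically from (loop seed, iteration, member).
* A constant feature row min-max-scales to 0 by convention.
* Stack domains of a single base pair are representable in the notation
  but admit no stacking quartet; descriptor extraction raises a
  structured error for them.
* Adjacent stack domains with a zero-length loop merge into one domain
  at the pairing level (they are one continuous helix), though the
  displacement product string keeps toehold and branch parentheses
  distinct.
* The regressor is a small CPU network; no GPU path, no hyperparameter
  search, and no recurrent comparison model are provided.
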