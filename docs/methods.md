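# Methods

## Sequence representation

All chains live on the 149-column AHo alignment frame, so heavy (H), kappa
(K) and lambda (L) variable domains are directly comparable column by
column. The alphabet has 26 tokens: the 20 standard amino acids, the gap
symbol `-` (a first-class alignment symbol, generated like any residue), and
five structural tokens `[CLS] [PAD] [SEP] [MASK] [UNK]` used only in the
model's input/output layout.

CDR columns are fixed by a versioned constant table (`NORTH_CDR_SEGMENTS`,
version 1) that maps North-style CDR boundaries onto the AHo frame. The
table is chosen so the three segments concatenate to exactly 64 columns on
heavy chains and 67 on light chains; kappa and lambda share one light-chain
table because the light-chain CDR total is a single number. The four
framework segments FR1–FR4 are the complement, partitioned by the CDRs.
Coordinates are 0-based half-open internally; 1-based numbers appear only
in human-readable reports. Records that do not fit the 149-column frame are
rejected (not truncated): silently truncating an insertion would corrupt
column semantics, and upstream numbering tools exist to produce conforming
alignments. Raw-sequence numbering (ANARCI-style HMM alignment) is out of
scope; the library contract takes pre-aligned input.

## Forward process

Absorbing-state discrete diffusion over the token vocabulary: at step t each
V-region position independently transitions to `[MASK]` with probability
β_t, stays itself otherwise, and `[MASK]` is absorbing. Single-step and
cumulative transition matrices are row-stochastic 26×26 matrices; because
the chain is absorbing, the product Q̄_t = Q_1⋯Q_t is itself an absorbing
matrix whose diagonal is the cumulative keep probability
ᾱ_t = Π_{s≤t}(1−β_s), which is how `cumulative_transition` computes it in
closed form (the explicit product is kept as a test oracle).

The schedule kind is configurable:

- `linear-marginal` (default): β_t = 1/(T−t+1), hence ᾱ_t = (T−t)/T — the
  masked fraction grows exactly linearly and ᾱ_T = 0. Chosen as default
  because it is the standard absorbing-state schedule whose endpoints match
  the model's contract (clean at t=0, fully masked at t=T) and it makes
  every forward-marginal test analytic.
- `cosine` and `spindle`: alternatives with the same endpoints, mask
  probability concentrated late or mid-trajectory.

T defaults to 512; toy pipelines use T=16 (see "Problem sizes" below).

The CDR prefix is conditioning only: it is carried bitwise unchanged through
every forward and reverse step. Whether the V-region *copies* of the CDR
columns are themselves noised is a genuinely open design point; by default
the whole 149-column V region is noised and the prefix alone carries the
conditioning, with `freeze_cdr_columns` implementing the alternative reading
(CDR columns of the V region exempt from masking and pre-filled at
generation time). Neither behavior is claimed to be uniquely correct; the
default is the one that lets CDR-reconstruction fidelity be *measured*
(`enforce_cdrs(mode="check")`) rather than imposed.

## Posterior and ELBO

For an absorbing chain the reverse posterior q(x_{t−1}|x_t, x_0) has a
two-case closed form: a non-mask x_t is carried backwards as a point mass
(it can never have been anything else), and a masked x_t reveals x_0 with
weight a = (ᾱ_{t−1} − ᾱ_t)/(1 − ᾱ_t), staying masked otherwise. During
sampling the one-hot x_0 is replaced by the denoiser's predicted x_0
distribution. `posterior_params` implements exactly this; a brute-force
Bayes enumeration over transition matrices is kept as an independent oracle
in the tests and the acceptance script (agreement to 1e-12).

The ELBO of a sequence is the standard discrete-diffusion variational bound:
reconstruction term E_q[log p(x_0|x_1)] minus Σ_{t≥2} E_q KL(q(x_{t−1}|x_t,
x_0) ‖ p_θ(x_{t−1}|x_t)); the prior term vanishes because q(x_T|x_0) is the
deterministic all-mask state. It is estimated by Monte Carlo over uniform t
and x_t ~ q(x_t|x_0), each draw scaled by T to keep the estimator unbiased.
A perfect (oracle) denoiser gives exactly 0; the value is ≤ 0 for any
stochastic denoiser. Numerical guards: probabilities are floored at 1e-300
inside logs, and 0·log 0 is taken as 0 in the KL.

## Denoiser

Input layout `[CDR prefix][CLS][V region, 149][SEP]` (total length
prefix + 151), with one shared token-embedding table, learned absolute
position embeddings over the whole concatenation, and a two-valued segment
embedding (0 on the prefix, 1 on the V-region side including `[CLS]` and
`[SEP]`). `[CLS]` sits immediately before the V region; the placement is a
documented layout choice, not a claim about the only possible one. The
diffusion step t enters as a sinusoidal embedding passed through a learned
linear projection and added to the input of every transformer block; t may
differ per batch row (training samples t per example). Blocks are pre-norm
multi-head self-attention (softmax(qkᵀ/√d_k)v) with dropout applied to the
concatenated heads, plus a GELU feed-forward of width 4×hidden. Output
logits are read off the 149 V-region slots only.

Reference configuration: 12 layers, 16 heads, hidden 1024 (≈164 M
parameters by the closed-form count, which the tests pin against the
allocated count on small configs). All toy work uses 2 layers, 2 heads,
hidden 32. By default the softmax support for generation excludes the five
structural tokens (the gap stays: aligned sequences contain gaps).

The network runs on a small reverse-mode autodiff engine written on numpy
(`autodiff.py`): tape-based Tensors, broadcast-aware arithmetic, batched
matmul, softmax/log-softmax/GELU/layer-norm, embedding/gather, an AdamW
optimizer and global-norm gradient clipping. float64 throughout — at the
problem sizes this package targets, checkable gradients and determinism
matter more than throughput; gradient correctness is pinned against central
finite differences in the test suite.

## Training

Per example: draw t uniform on {1..T}, sample x_t by the forward process,
predict x_0, take the loss. The default objective (`ce-masked`) is the
x0-parameterized cross-entropy on masked positions — the masked-language
objective standard in this model family. The `hybrid` objective adds
λ·KL(posterior(one-hot x0) ‖ posterior(model x0)), computed per masked
position from the absorbing-chain closed form and verified against a full
categorical-KL oracle. Noise is re-seeded per (run seed, epoch, example
index), so the epoch loss does not depend on how examples are batched.
AdamW (reference learning rate 3e-5, batch 64; toy runs use larger rates,
see below) with gradient clipping at global norm 1.0. A non-finite loss
aborts with a diagnostic rather than continuing silently. The number of
epochs is a free parameter; the reference run's convergence criterion is
unknown, so toy runs fix epoch counts explicitly.

## Generation, ranking, scoring

Generation starts at t=T from all-mask and visits every step down to t=1;
at each step the denoiser's logits are divided by the temperature before
the softmax (posterior mixture weights untouched), and masked positions are
revealed or kept masked according to the posterior. Reveal decisions and
token draws consume independent uniforms from one seeded stream, so the
temperature→0 limit coincides exactly with the dedicated greedy path under
the same seed. Defaults: temperature 0.7 (H) / 0.65 (K, L), 100 variants
per call. Generated CDR columns are not overwritten by default; grafting is
opt-in and the CDR fidelity check is always reported by the CLI.

Ranking: LL = Σ_j log P_j(s_j|M) per scorer; with several scorers the
unweighted mean is used (the simplest aggregation; rank aggregation is a
configurable alternative), sorted descending with a stable id tie-break.
External pretrained protein language models are adapters behind the Scorer
contract and excluded from the test suite; the built-in model scorer is a
pseudo-log-likelihood that masks one position at a time at t=1.

Normalized ELBO: min-max against a user-supplied reference cohort, clipped
to [0,1]; a degenerate reference (all equal) maps everything to 0 with a
warning flag rather than dividing by zero. Paired (VH, VL) scores are
stratified by min(vh, vl) against a threshold (default 0.9) — the weaker
chain is assumed to set the immunogenicity level.

## Metrics

Template Overlap Ratio: the query's CDR columns are masked with `X`, the
best template is found by exhaustive framework-identity scan (ties to the
lowest id), and the ratio is identical non-gap FR residues divided by the
query's non-gap FR residue count — a denominator chosen so a verbatim
template copy scores exactly 1. The exhaustive scan is exact and serves as
the correctness oracle; a local-alignment search tool would only be an
accelerator for large databases.

Diversity: single-linkage agglomerative clustering of FR segments
(scipy.cluster.hierarchy) on 1 − identity, cut at distance ≤ 1 − threshold;
this equals connected components of the thresholded identity graph, which a
union-find oracle re-derives in the tests. Identity counts residue=residue
matches only; gap–gap columns are excluded from numerator and denominator
(two all-gap segments count as identical). Cluster counts are non-decreasing
in the threshold by construction, and that monotonicity is property-tested.

## Synthetic repertoires

The generator emulates three features of AHo-aligned human repertoire data:
near-conserved framework columns (one dominant residue per column with
probability `fr_conservation`, default 0.85 — the order of framework
conservation seen in variable-domain alignments), hypervariable CDR columns
(uniform over the 20 residues), and a fixed chain-type-specific set of
gap-dominant columns (gap probability 0.9) standing in for the AHo indel
architecture, placed mid-CDR with an extra FR1 gap column on light chains.
Columns are sampled independently — deliberately: column independence gives
closed-form expectations (multinomial errors, χ² goodness of fit, TV
distances) for every downstream distributional test. What it does *not*
model: clonal/phylogenetic structure, hypermutation hotspots, residue
covariation, or chain pairing. Passing tests therefore demonstrate that the
machinery is correct and can learn column-wise structure, not that the model
reaches production quality on real repertoires.

Precursor emulation mutates each non-gap FR residue to a uniformly random
different residue with probability `fr_mutation_rate` (default 0.30,
the order of murine-vs-human framework divergence), leaving CDRs untouched.

## Problem sizes

Full-scale settings (12×1024 model, T=512, millions of sequences) are
supported by the code but not exercised in tests. The packaged experiments
run at desk scale, chosen once as the smallest sizes at which every
qualitative property is visible: 200 training chains, a 2-layer/32-hidden
denoiser, T=16, 30 epochs at learning rate 3e-3 for the learning experiment
(loss falls from ≈3.19 to ≈1.41 nats; mean total-variation distance between
generated and training FR column marginals falls from ≈0.82 untrained to
≈0.14, under the monitored 0.2 convergence level); 64 copies × 60 epochs at
rate 1e-2 for the memorization experiment (generated FR identity to the
memorized sequence reaches 1.0, against a ≥0.95 criterion). Oracle-based
checks (posterior enumeration, 512-step collapse, endpoint masking) run at
the full T=512.

## Known limitations

- No HMM-based numbering: inputs must already be on the 149-column frame.
- The denoiser is CPU/numpy; it is a correctness-first reference, not a
  training engine for full-scale corpora.
- External pretrained scorers (ESM-family) and structure-based evaluation
  (pLDDT, scPerplexity, TMScore, Vernier RMSD) are out of scope; only the
  Scorer contract is provided.
- Skip-step samplers are not implemented; generation visits all T steps.
- The ELBO estimator is Monte Carlo; small n_samples gives noisy scores
  (use ≥ 64 draws for cohort-level comparisons).
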