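# Methods

## Model

`pepfunc` predicts, for a peptide sequence, a subset of `C` therapeutic
function classes (default vocabulary: AMP, TXP, ABP, AIP, AVP, ACP, AFP,
DDV, CPP, CCC, APP, AAP, AHTP, PBP, QSP; `C = 15`). The model is an
encoder–decoder transformer in which the decoder's input tokens are the
classes themselves ("label embedding"):

* **Sequence encoding.** Sequences are normalised to `L = 50` positions:
  shorter peptides are zero-padded at the C-terminal end; longer ones are
  spliced as first 25 + last 25 residues, preserving both termini (where
  the functional signal of short peptides concentrates). Each position
  carries 40 features: a 20-dim one-hot residue indicator (columns ordered
  alphabetically `ACDEFGHIKLMNPQRSTVWY`) and a 20-dim PSSM log-odds row.
  PSSMs are parsed from PSI-BLAST ASCII output (`-out_ascii_pssm`); when a
  profile is unavailable the block is zero-filled (default) or filled with
  BLOSUM62 substitution rows (`pssm_fallback="blosum62"`). PSSM rows are
  used as raw log-odds, unscaled.
* **Encoder.** `f_enc` projects the 40-dim rows to `d_model`, sinusoidal
  positional encodings with base constant **1000** are added
  (`PE(pos,2i) = sin(pos/1000^{2i/d'})`, `d' = d_model` by default but
  independently settable), and `n_enc` post-LN transformer layers
  (self-attention + ReLU feed-forward, residual connections) follow.
  Attention logits are scaled by `√d_model`; per-head width is
  `d_model / h` (constructor errors if indivisible). Padding positions are
  masked out of all attention over sequence keys, so padded feature values
  provably (and bit-exactly) never influence the output.
* **Decoder.** The class tokens enter as the identity matrix, projected by
  `f_dec` — i.e. one learned embedding per function. Decoder layers apply
  self-attention over classes (function–function attention), then
  cross-attention into the encoder memory (function–residue attention),
  then feed-forward; no causal mask and no positional encoding, because
  classes are an unordered set. The decoder is therefore
  permutation-equivariant over function tokens (exactly, up to one ulp of
  floating-point summation reordering). Self-attention precedes
  cross-attention, as in the standard architecture.
* **Heads.** Phase 1 uses a single shared linear+sigmoid head applied to
  every class representation row; phase 2 and inference use `C`
  independent heads `ŷᵢ = sigmoid(wᵢ·zᵢ + bᵢ)`. Labels are called at a
  strict `> 0.5` threshold (a tie at exactly 0.5 is a negative).

Defaults (desk scale): `d_model = 64`, `h = 4`, 2 encoder + 2 decoder
layers, `d_ff = 128`, dropout 0 (configurable; a seeded generator keeps
runs reproducible when enabled). Weight init is uniform fan-in, seeded.

## Training

The loss is binary cross-entropy summed over functions and averaged over a
batch, with probabilities clipped to `[1e−7, 1 − 1e−7]`. (The loss as a
*maximised* log-likelihood sum appears in some descriptions; we use the
standard negated, minimised form.) Optimisation is AdamW
(`lr 1e−3`, weight decay `1e−2`, β = (0.9, 0.999)) with a linear LR warmup
(200 steps by default) — post-LN transformers optimise poorly without it.
Batches are reshuffled each epoch under the run seed, and the final
epoch's weights are kept; model selection happens across grid-search
configurations by minimum validation loss, not across epochs.

**Phase 1** trains the sequence-embedding module, the label-embedding
module and the shared head, so all classes share one output space and the
decoder can absorb inter-class correlations. **Phase 2** copies the shared
head into all `C` specific heads (so zero phase-2 epochs reproduces
phase-1 predictions exactly) and trains them with the label-embedding
module frozen. By default the sequence module is frozen too — the
per-class boundaries are meant to adapt to a *stable* representation
geometry, and with the whole backbone fixed phase 2 reduces exactly to `C`
logistic fits on precomputed representations `Z`, which is far cheaper.
`freeze_seq_in_phase2=False` restores joint phase-2 training of the
encoder. Each configured experiment is repeated over a seed list (default
5) and metrics are averaged arithmetically with per-seed values retained.

**MCRT.** After both phases, each function's head is retrained alone as a
binary task on a bootstrap of the training set drawn with square-root
class sampling: each of `N` draws picks the positive class with
probability `p = √n_pos / (√n_pos + √(N − n_pos))` (`p_negative` is
returned as `1 − p`, which coincides with the direct formula because both
shares have the same denominator), then a uniform member of that class
with replacement. `N` defaults to the training-set size. The backbone and
all other heads are frozen — bit-exactly, because only the two arrays of
head `c` are ever passed to the optimiser — so retraining order is
irrelevant and other functions' predictions cannot change. Per-function
sub-seeds are derived deterministically from the run seed.

**Weak-label construction.** To emulate incomplete annotation, for each
function independently `round(r·n_pos)` (half-up) of its positive entries
in the training and validation splits are flipped to 0, chosen uniformly
under a per-function sub-seed; the test split is never degraded. Samples
whose label vector becomes all-zero are retained (they are legitimate
"no known function" negatives in this regime), and the original labels are
kept in a provenance record. Whether multi-positive samples should be
protected from losing all labels is an open choice; we do not protect
them.

## Evaluation

`ACC_example` is the mean per-sample Jaccard index `|L∩L̂|/|L∪L̂|`; the
convention for two empty sets is 1 (perfectly predicted absence) and its
occurrence is flagged in reports, since real data always carries at least
one label. `F1_label` is macro-F1 with all zero-division cases scored 0.
One-vs-all metrics per function use the model's per-function probabilities
directly: AUC by the rank method with half-credit ties (undefined with one
class present → reported missing), MCC/F1/precision/recall from the
0.5-threshold confusion counts. `RkCC` is Gorodkin's K-category
correlation coefficient computed from a confusion matrix; it equals MCC at
`K = 2` and returns 0 (flagged) for degenerate marginals. Shot groups bin
functions by training-set positive count (defaults: many > 1000,
few < 200, thresholds configurable since they only make sense at full
benchmark scale). Correlation matrices: Pearson between label columns
(co-occurrence) and the per-sample Pearson between representation rows
`zᵢ, zⱼ` averaged over samples; zero-variance entries are 0 and flagged.
Attention summaries average the last decoder layer's weights over samples,
heads and query positions, giving per-function and per-residue-position
*received* attention (column means of row-stochastic matrices, so the
per-function vector sums to 1). All heads of the last layer are included.

## Synthetic benchmark generator

The generator emulates the statistical structure of curated multi-label
peptide collections: (i) label sets drawn from weighted templates —
power-law-weighted singletons (`(rank+1)^−1.5`), correlated adjacent pairs
and triples and one quadruple — giving 1–4 labels per sample and a
long-tail per-function count distribution (max/min positive count ratio
> 5 at the default scale); (ii) sequences of uniform random length 15–50
over a uniform residue background; (iii) a recoverable signal: each
function owns a distinct 4-mer motif inserted at a uniform non-overlapping
position into its positives with probability 0.9. The default motif table
assigns function `i` the alternating doublet of alphabet letters `2i` and
`2i+1`, so motifs are compositionally well separated and the signal is
learnable at desk scale — a deliberate generator design requirement, fixed
a priori. Splits are a seeded random 8:1:1 with best-effort stratification
so every represented function keeps a training positive. Everything is
deterministic given the spec (including its seed).

What the generator does *not* emulate: evolutionary profiles (PSSMs are
zero at generation time), homology structure between splits, realistic
residue composition (configurable but uniform by default), and
position-dependent motif preferences. Passing tests on this fixture
therefore demonstrates that the architecture, training procedure and
retraining strategy work as designed — not that any particular accuracy
transfers to curated peptide data.

## Desk-scale study conditions

All heavy computations run on a single CPU in float32 (a global dtype
switch in the autodiff engine; float64 is the default elsewhere). Problem
sizes, chosen as the package's desk-scale defaults:

* Main benchmark: 2000 samples, `C = 8`, split 1600/200/200; phase 1
  30 epochs, phase 2 10 epochs, batch 16; 5 seeds in the test suite,
  3 in the acceptance script.
* Weak-label sweep: 800 samples, `C = 8`, ratios {0.5, 0.7, 0.9}, same
  epochs; MCRT reuses phase-2 settings (`mcrt_epochs_factor = 1`).
* Memorisation check: 10 samples, `C = 4`, batch 2, lr 1.5e−3,
  60 + 30 epochs.

Under these conditions the held-out `ACC_example` of the default benchmark
averages ≈ 0.81 and per-function AUCs are high across the tail, while
few-shot F1 at the fixed 0.5 threshold collapses — the long-tail failure
mode MCRT then mitigates (weak-label sweep: macro-F1 roughly 0.18 → 0.28
at ratio 0.5, 0.08 → 0.20 at 0.7, 0.00 → 0.04 at 0.9, 5-seed means; the
suite recomputes these).

## Numerical and design notes

* The autodiff engine is a ~300-line reverse-mode tape over NumPy with
  broadcast-aware primitives; every composite used by the model is
  gradient-checked against central finite differences in the test suite.
* Attention masking adds −1e9 to masked logits; after the softmax's
  max-shift the masked weights underflow to exactly 0, which is what makes
  padding invariance bit-exact rather than approximate.
* BCE clipping bounds gradients but freezes saturated units at the clip
  boundary; at desk scale this is never reached before convergence.
* `grid_search` trains both phases for every hyperparameter combination
  and returns the configuration with minimum final validation loss along
  with the full (setting, loss) table. The epoch budget applies to every
  candidate (a desk-scale override is available via the config).
* Degenerate inputs: empty training sets, empty template spaces,
  single-class AUC, all-mass-one-cell confusion matrices and zero-variance
  correlation rows all have explicit, tested conventions rather than NaNs.

## Known limitations

* No pretrained protein language model features; representations are
  learned from scratch per run.
* The per-head projection uses split heads (`d_k = d_model/h`); logits are
  scaled by `√d_model` rather than the conventional `√d_k` — equivalent up
  to a per-head constant absorbed by the learned projections.
* MCRT retrains heads on frozen representations; if the backbone itself
  failed to learn (e.g. extreme weak-label ratios at small n), retraining
  can only recover what the representation still separates.
* The CLI writes checkpoints as NumPy archives; they are runtime
  artifacts, not an interchange format.
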