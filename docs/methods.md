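# Methods

## The model

`molscreen` predicts the ERα activity (pIC50, a regression target) and five
binary ADMET endpoints (Caco-2 permeability, CYP3A4 metabolism, hERG
blockade, human oral bioavailability, micronucleus genotoxicity) of drug-like
compounds from two complementary views, then converts the six predictions
into a single ranked candidate list.

### Topological branch

Each SMILES is parsed (RDKit) into a heavy-atom graph. Atoms carry a
39-dimensional feature vector — seven frozen one-hot blocks (atom type 12,
heavy-atom degree 6, formal charge 5, chirality 4, bound-hydrogen count 5,
hybridization 5, aromaticity 1) plus atomic mass normalized by 200 Da and
clipped to [0, 1]. Bonds populate a symmetric adjacency matrix A with the
numeric bond order as the entry (single 1, aromatic 1.5, double 2, triple 3);
these scalars act as edge weights during aggregation — there are no
per-bond-type weight matrices.

Node states start at the atom features (the hidden width is fixed to 39 so
no input projection is needed; one is available for other widths) and are
updated for T rounds (default T = 2) of GRU-gated message passing:

    o_t = (A h_{t-1}) W_o + b_o
    z_t = σ(o_t W_z + h_{t-1} U_z + b_z)
    r_t = σ(o_t W_r + h_{t-1} U_r + b_r)
    c_t = tanh(o_t W_h + (r_t ⊙ h_{t-1}) U_h + b_h)
    h_t = c_t ⊙ z_t + h_{t-1} ⊙ (1 − z_t)

The first line deserves a note: a literal reading of the aggregation as a
product of an n×n adjacency with d×d weights does not type-check, so the
implementation aggregates neighbor states weighted by bond order and then
applies the linear map — the standard gated-graph message form and the
closest dimensionally consistent reading.

The readout gates each node vector through two single-hidden-layer
perceptrons of width d, g_w = σ(f1(h_w)) ⊙ tanh(f2(h_w)), and combines a
*shrunken mean* (divisor |V| + 1, kept as printed in the readout definition
the model follows) with an elementwise max-pool over the gated vectors.
The max-pool argument list is the gated node vectors only; no extra vector
participates. `pooling` may be set to `mean`, `max` or `fusion` (default)
to ablate the two pooling paths.

Substructures come from a SMILES-pair-encoding vocabulary: byte-pair-style
merges over atom-wise SMILES tokens, learned on the training split only
(max 300 merges, minimum pair frequency 5). Each multi-atom token of a
molecule maps back to the heavy-atom indices it spans; the vertex-induced
subgraphs (at most 8 per molecule, ordered by corpus frequency) run through
the same GGNN and readout — parameters shared with the parent graph — and
are fused with the parent vector by softmax attention
w_j ∝ exp(cᵀ tanh(W h_j + b)). A molecule with no multi-atom token keeps
its parent vector exactly. Tokens that span ring closures are resolved by
induced-subgraph semantics: every bond internal to the covered atom set is
kept, contiguous in the SMILES string or not.

### Descriptor branch

The compound table supplies 729 numeric molecular descriptors. A
gradient-boosted tree ensemble (xgboost: 200 rounds, depth 4, learning rate
0.1, λ = 1, γ = 0) trained on the configured selection target (default the
ERα label; per-task or merged mean-normalized-gain rankings are available)
ranks descriptors by total split gain, ties broken by name; the top 50 are
kept. The closed forms of the second-order boosting objective — the optimal
leaf weight −G/(H+λ) and the structure score −½ Σ G_j²/(H_j+λ) + γT — are
implemented and tested directly; the ensemble trainer is the library.

Selected descriptors are z-scored with training-split statistics (missing
values are imputed with the training-split median). Each scalar position
m_j receives a softmax attention weight with logit cᵀ tanh(w m_j + b) —
the attention operates per scalar digit, as the readout is defined — and the
reweighted vector is projected by one fully connected layer to 39
dimensions (h_m). Because the softmax shrinks each position to roughly
m_j / k, the projection's initialization variance is scaled by k so that
h_m starts at the same magnitude as the topological vector; without this
the descriptor branch begins effectively silent inside the fused model.

### Fusion, heads and training

h_final = λ·h + (1−λ)·h_m with λ = 0.6 by default; λ = 1 and λ = 0
degenerate to the single branches and are used as the branch ablations.
A linear head predicts pIC50 (mean-squared-error loss); a two-way softmax
head predicts each ADMET endpoint (cross-entropy). One model is trained
per task. Training is Adam at learning rate 0.01 with dropout 0.5 on
h_final, minibatches of 64 (24 in the desk-scale experiments), early
stopping on validation loss (patience 20), and a single seed fanned out
deterministically to every stage. Optional decoupled L2 weight decay on
the matrix weights is available (default 0). The 8:1:1
train/validation/test split is stratified for the binary tasks; repeated
resampling (10 repeats) reconciles the cross-validation and fixed-split
protocols by reporting means over re-drawn splits.

All tensor computation runs on an in-repo reverse-mode automatic
differentiation engine over numpy float64 arrays (~250 lines: broadcast
arithmetic, batched matmul, sigmoid/tanh/exp/log, axis reductions, max,
concatenation, gather). It is gradient-checked against central finite
differences at 1e-7. Graphs are padded per batch — parents and the much
smaller substructure subgraphs separately — so an epoch is a handful of
large einsum-style operations rather than a per-molecule Python loop.

### Ranking operator

Predictions become scorecard features: the predicted pIC50 plus the five
binary ADMET calls. Each feature is discretized by chi-merge — initial
bins at unique values (capped at 20 quantile bins), repeated merging of
the adjacent pair with the smallest 2×2 chi-square statistic (ties: lowest
index; a zero marginal forces the merge) until every pair exceeds the
χ²₁ critical value at significance 0.05 (3.841) or two bins remain. Bins
are encoded by weight of evidence, woe_i = ln(py_i/pn_i), with 0.5 added
to both class counts of a bin when a cell is empty (shares renormalized).
A logistic regression on the WOE-encoded features supplies coefficients
β_i and intercept a (a separable fit falls back to a ridge-penalized refit
and is flagged); per-feature points are
(woe_i·β_i + a/n)·factor + offset/n, summed over the n features. The
printed per-feature offset/n is kept; the n terms sum back to one global
offset. Defaults factor = 20/ln 2, offset = 600 (points-to-double-odds);
the ordering of compounds is invariant to both for factor > 0 and ties
break lexicographically by compound id.

The binary outcome behind β_i is not prescribed by the scoring equations,
so the package defines a trainable default: "good candidate" = predicted
pIC50 above the 70th percentile AND at least 4 of 5 ADMET calls in the
favorable direction (favorable = permeable Caco-2, CYP3A4-metabolized,
hERG-negative, orally bioavailable, micronucleus-negative). Both
thresholds are config keys and a user-supplied target column is accepted.
The predicted activity (not the ground truth) is binned for scoring.

## The synthetic data generator

The real screening table (1,974 compounds, 729 descriptors, balanced
binary endpoints) is not distributable, so the generator emulates its
*shape* while planting recoverable ground truth; its defaults are the
study conditions of every test.

Molecules are chains of 1–2 random "free" fragments from a 29-fragment
drug-like pool (each fragment is valid as a SMILES continuation, so any
concatenation parses). About half the molecules additionally receive the
signal substructure — an anilide, `C(=O)Nc1ccccc1`. Every signal-free
molecule instead receives the same atoms as two disconnected decoys, a
carbonyl `C(=O)` and an aniline `Nc1ccccc1` (the aniline never opens the
SMILES, keeping its nitrogen's degree equal to the amide nitrogen's). The
two classes are therefore composition-matched at the atom-feature level:
a readout of raw atom features cannot separate them well, while one or two
rounds of message passing resolve the carbonyl–nitrogen bond — this is
what gives the interaction-step ablation its interior optimum.

Descriptors are standard normal; ten planted columns (spread across the
729) drive the activity linearly (effect sizes 1.0…0.5, alternating sign)
plus a +1.5 bonus when the signal substructure is present and N(0, 0.5)
noise. Each ADMET latent combines the substructure indicator (weight 2.0,
centered), the molecule's signed nitrogen-minus-oxygen balance
(n_N − n_O)/n standardized (weight 0.8) — a counting quantity an averaged
readout expresses directly but a max-pool readout cannot — three of the
planted descriptor columns (unit weight) and N(0, 0.5) noise; labels
threshold the latent at the quantile realizing the requested positive
fraction (0.5). By construction the topological branch alone cannot see
the descriptor part and the descriptor branch alone cannot see the
substructure or balance parts, which is what the branch-ablation and
λ-sweep directions probe.

What the generator does not emulate: real descriptor semantics or
correlations, realistic chemistry beyond valence-correct fragments,
activity cliffs, assay noise structure, or class imbalance. Passing
recovery and direction tests therefore demonstrates that the pipeline's
machinery works and its comparisons point the right way under controlled
signal, not that the reported real-data metrics transfer.

## Experiment scales and numerical choices

Desk-scale sizes keep the full suite within minutes on one CPU: ablations
train on 300 compounds (standard 8:1:1 split for early stopping, 35
epochs, batch 24) and are scored on an independent 600-compound table from
the same generator, mean over five seeds — the external set keeps variant
comparisons from being dominated by 30-compound test splits. Branch and
λ comparisons are read on F1; the readout-architecture comparisons
(pooling variants, propagation depth) are read on the threshold-free AUC,
since at these sizes the 0.5-threshold adds noise comparable to the
effects under study. Descriptor
recovery uses n = 1000 with ten replicates; the overfit sanity check
trains 30 compounds for 500 epochs with dropout and early stopping off.

Numerical conventions: float64 throughout the neural stack; softmax logits
are max-shifted; masked softmax uses an additive −1e9 surrogate; the
max-pool routes gradient to the first argmax on ties; attention weights
sum to 1 within 1e−9; the forced-zero-gate propagation test uses a bias of
−1e6 as the −∞ surrogate. Degenerate inputs are handled explicitly: a
constant ranking target falls back to a variance ranking with a flag, a
constant binning feature yields a single bin with a warning, an empty
substructure list leaves the parent vector untouched, and an unseen
element encodes as an all-zero atom-type block with a warning.

## Known limitations

* The hidden width is tied to the 39-dimensional featurization by default;
  other widths require the optional input projection.
* Substructure GGNN parameters are shared with the parent graph (a config
  switch could untie them; unshared parameters double the cost).
* The boosted ranking uses the library's total-gain importance, which
  enumerates features in column order and accumulates in float32 —
  near-tied noise columns may swap under column permutation.
* Pooling-fusion gains over the best single pooling are small by nature —
  typically a ~1-point effect on ADMET benchmarks — and are the least
  stable of the direction experiments at desk scale.
* The scorecard's logistic target is a package convention (see above), not
  a property of the scoring equations themselves.
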