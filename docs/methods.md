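# Methods

This note documents the models, the simulator, the numerical choices and
the limitations of `denovoms`. It describes what the code computes;
every empirical statement here is produced by the test suite or by
`scripts/acceptance.py`.

## Problem setting

An MS2 scan is a set of N peaks \((\mathbf{m}, \mathbf{I})\) with
precursor m/z and charge; the neutral precursor mass follows as
\(M = z\,(m/z) - z\,m_p\) with \(m_p = 1.007276\) Da. A tryptic peptide
of residues \(r_1..r_n\) has neutral mass \(\sum_i m(r_i) + m_{H_2O}\).
Under HCD fragmentation the dominant ions are the N-terminal b series
(\(b_i = \sum_{j\le i} m(r_j) + z m_p\), charge z) and the C-terminal y
series (\(y_i = \sum_{j>n-i} m(r_j) + m_{H_2O} + z m_p\)). De novo
sequencing inverts this map: from the peak list back to the residue
sequence.

## Vocabulary and mass arithmetic

Residues are tokens with fixed 6-decimal monoisotopic masses compiled
into the package; modified residues are first-class tokens in bracket
notation. The default vocabulary holds the 19 canonical residues other
than cysteine, plus carbamidomethyl-cysteine `C[+57.02146]` (alkylation
is treated as fixed; a config switch restores bare `C`), oxidized
methionine `M[+15.99491]`, and deamidated asparagine/glutamine
`N[+0.98402]` / `Q[+0.98402]`. Note two exact isobaric pairs: I/L, and
deamidated-N vs D; these are indistinguishable by mass and the
evaluation treats them as equivalent.

## Autoregressive model

Peak i is embedded as a multi-scale sinusoidal encoding of its m/z —
sin/cos pairs over `hidden_dim/2` wavelengths geometrically spaced in
`[wavelength_min, wavelength_max]` — plus a learned linear lift of
`log1p(intensity)` (intensities are normalized to the base peak at
ingestion, so inputs are scale-free and the representation is monotone
in intensity). The peaks pass through a pre-norm transformer encoder;
the output is concatenated with a learnt latent-spectrum token and a
precursor token (sinusoidal encoding of the precursor mass summed with a
learned per-charge embedding; charges outside 1..6 map to an
unknown-charge row with a warning). Memory length is therefore always
N + 2. A config flag (`precursor_mode="sos"`) instead injects the
precursor vector through the decoder's start token; both conditioning
routes are supported because neither is expected to dominate.

The decoder embeds the partial peptide, applies causally masked
self-attention and cross-attention to the memory, and emits one logit
per vocabulary token. Decoding order is C-terminal-first ("rtl") by
default — y ions of tryptic peptides give the cleaner ladder — with
"ltr" available for ablation; predictions are reversed to N→C order on
output.

**Decoder positions.** Two positional schemes are provided
(`ModelConfig.decoder_pos`). The conventional choice, `"index"`, is the
standard transformer positional encoding. The default, `"mass"`,
encodes the cumulative residue mass of the decoded prefix with the same
multi-scale sinusoidal family used for the peaks. The rationale is
mechanistic: predicting the next residue amounts to asking which y-ion
peak sits one residue mass beyond the current suffix mass, and with
mass positions the decoder's queries already live in the same phase
space as the peak keys, so cross-attention can express that comparison
with a linear map instead of having to re-derive prefix masses from
token identities. At desk scale this matters empirically: with index
positions a toy model (2+2 layers, hidden 64) memorizes a
5,000-spectrum training set while held-out token accuracy stays at the
prior level (~0.33); with mass positions held-out accuracy climbs
steadily from the first epochs. Large models trained on millions of
spectra can learn the arithmetic internally; a desk-scale model
demonstrably does not, which is why the mass encoding is the default
here. Both variants satisfy causality (the cumulative mass depends only
on the prefix).

Training minimizes token-level cross-entropy against the ground-truth
peptide in decoding order (teacher forcing) with Adam (default lr 1e-3,
gradient clipping at norm 1, optional decoupled weight decay and label
smoothing, optional 5%-warmup cosine lr schedule) and fully seeded
shuffling: a fixed seed gives a bit-identical loss trace on one
machine.

The full-scale geometry (9 encoder + 9 decoder layers, 16 heads, hidden
768, feed-forward 1024) is constructible and its parameter count is
reported by `Module.n_parameters()`; the count depends on embedding and
output-head details that are not uniquely determined by the stated
geometry, so no particular published total is asserted. All trained
models in the tests use the toy preset (2+2 layers, 4 heads, hidden 64,
feed-forward 128).

## Knapsack-constrained beam search

All masses in the decoding constraint are residue-sum masses (precursor
neutral mass minus water); keeping water out of the table avoids the
classic off-by-one. `build_table` computes, for every mass bin (default
resolution 0.0005 Da, default ceiling 4000 Da), the minimum number of
residues in any multiset reaching that bin (255 = unreachable); plain
reachability is its boolean shadow. The build is a one-time vectorized
dynamic program (blocks of the minimum residue width only depend on
earlier blocks) and can be cached to disk keyed by (vocabulary hash,
resolution, max mass).

During beam search each candidate extension is kept only if the
remaining budget is completable within the remaining length budget:
some bin within `tol_ppm × (precursor residue mass)` of the remainder
must be reachable with at most the number of residues that may still
follow. Discretization is handled asymmetrically: when the tolerance
window spans many bins it is inset by 8 bins (0.004 Da) from each edge,
so a path flagged feasible cannot drift outside the exact tolerance by
termination time (bin-rounding drift for peptides of ≤ 30 residues is
well below that); only when the window itself is a few bins wide is it
instead widened by one bin so reachability is never falsely denied. A
sequence may terminate only when its assembled residue mass is inside
the exact ppm window, so every returned peptide satisfies the precursor
constraint by construction, and a mass-feasible composition essentially
always decodes (the acceptance suite asserts this for every one of its
held-out spectra). Terminals are ranked by the sum of
per-residue log-probabilities; the end-of-sequence token acts as a gate,
not a score, which keeps the beam exactly equivalent to exhaustive
enumeration of mass-valid sequences under the same scorer (asserted over
75 random toy instances in the tests). Ties break lexicographically on
token ids for determinism. Returning nothing is a data condition (no
vocabulary composition fits the window), not an error.

## Diffusion refinement

The refiner shares the spectrum-encoder architecture and adds a
bidirectional decoder over a fixed-length residue-class sequence; the
decoder cross-attends to the spectrum memory extended with an embedding
of the current timestep. The forward process replaces each position with
a uniform residue draw with per-step probability β_t; the closed-form
marginal keeps a position with probability
\(\bar\alpha_t + (1-\bar\alpha_t)/K\). β follows a cosine schedule
mapped to T = 20 discrete steps (satisfying \(\bar\alpha_0 = 1\),
strictly decreasing, \(\bar\alpha_T \le 0.05\)); the schedule shape was
an open choice and the cosine form is the standard stable one.

Training uses the simple x0-prediction surrogate: sample t ~ U{1..T},
corrupt, minimize per-position cross-entropy to the clean sequence. The
full variational bound was deliberately not used; the surrogate is the
common, stable choice for discrete diffusion.

Reverse decoding samples \(x_{t-1}\) from the multinomial posterior
\(q(x_{t-1}|x_t, \hat{x}_0) \propto
(\alpha_t\,\mathrm{onehot}(x_t) + (1-\alpha_t)/K)\,\odot\,
(\bar\alpha_{t-1}\,\hat{p}(x_0) + (1-\bar\alpha_{t-1})/K)\)
with the model's predicted x0 distribution plugged in. Degenerate
all-zero rows (possible only with an inconsistent x0 estimate at β → 0)
fall back to a point mass on x_t.

Sample-and-select decoding draws `n_samples` (default 5) refined
sequences per spectrum. With an initializing autoregressive prediction
the chain starts from the uncorrupted sequence injected at t = 15 (a
config switch corrupts it to q(x_t|x0) first — the injection convention
was an open choice and the uncorrupted variant is the default); without
one it starts from uniform noise at t = T, at a length drawn from the
training length distribution (length handling is otherwise fixed at the
initialization's length — the refiner cannot change peptide length).
Among mass-valid samples the highest model log-probability wins; with
none, the initializing prediction is returned as the fallback (so an
init always yields a mass-consistent output), or the best sample flagged
mass-violating when there is no init. The refiner's confidence is the
sum of per-position log-probabilities of the final sequence under the
model at t = 1; this is a lower-bound-style surrogate and is NOT
calibrated against autoregressive confidences — the two scales should
not be compared without recalibration.

## Evaluation

A predicted residue matches the aligned true residue when their masses
differ by < 0.1 Da and the aligned cumulative masses differ by ≤ 0.5 Da;
positions are tested from both termini and the union taken, crediting
correct subsequences on both sides of a local error. These constants
follow the convention of the de novo benchmark lineage; the exact
published formulation is not fully specified, so the tolerances are
config values and this matching rule is a documented substitution.
Peptide-level matches require equal length and all residues matched —
string equality is deliberately not required, so isobaric substitutions
are not errors.

Peptide recall (main metric) divides full matches by ground-truth PSMs;
precision divides by predictions made. PR curves sweep the confidence
threshold from highest to lowest; AUC is the recall-axis trapezoid
anchored at recall 0. The FDR threshold is the lowest confidence at
which the fraction of retained predictions disagreeing with the
reference is ≤ the target (default 5%). This is a surrogate FDR against
database-search-style ground truth — NOT a target-decoy FDR — and is
only as good as the reference identifications. The error taxonomy bins
wrong predictions, in order, into {1, 2, >2} residue errors at equal
length, length mismatch, and a residual precursor-mass-mismatch bucket.

## Simulator

`simulate` draws peptides uniformly over canonical residues (lengths
7–16 by default, ≤ 30 always), forces K/R termini when tryptic,
substitutes PTM variants at configured rates (oxidation 10%, deamidation
5% per eligible residue; cysteine always carbamidomethylated), samples
precursor charge from {2: 0.65, 3: 0.35}, and renders b/y ladders
(charge-2 fragments only for charge-3 precursors). Intensities are
log-normal with a ×2 y-ion boost (y ions of tryptic peptides read out
better, giving the model a learnable asymmetry); fragment m/z is
jittered uniformly within ±5 ppm by default; 5% of fragment peaks drop
out; noise peaks (Poisson, mean 10) are uniform over the scan range with
intensities from the lowest signal quartile. The precursor m/z itself is
exact. A ladder-walking oracle sequencer (depth-first search over b-ion
extensions) validates the simulator independently of any learned model:
in the noise-free limit it recovers the peptide up to isobaric
ambiguity.

What the simulator does not emulate: isotope envelopes, neutral losses,
a/c/x/z ions, co-isolation chimeras, retention-time structure, charge
state errors, and realistic intensity models (no learned fragmentation
intensities). Passing tests on synthetic data therefore demonstrate the
correctness and trainability of the machinery, not real-data
performance of a desk-scale model.

## Problem sizes and numerical choices

Test-suite trainings use the toy geometry on small corpora chosen so the
whole suite runs on one CPU: unit tests overfit 40–60 spectra; the
acceptance tests train on a few thousand clean spectra and evaluate on
500 held-out spectra of unseen peptides of seen lengths. The
acceptance script trains for one epoch on 500 simulated spectra before
decoding them — enough for the mass-constraint measurement, which holds
for any model by construction of the beam search. Knapsack resolution
0.0005 Da with ±1-bin widening keeps discretization conservative;
float32 is used for all network arithmetic and float64 for mass
arithmetic and log-probability bookkeeping.

## Known limitations

- Desk-scale models trained here are far below published full-scale de
  novo sequencing performance; no real-data benchmark numbers are
  claimed or reproduced.
- Diffusion refinement operates at fixed sequence length; it can repair
  substitutions but not insertions/deletions relative to its
  initialization.
- The surrogate FDR requires reference identifications and inherits
  their biases.
- mzML reading supports the standard dialect produced by common
  converters; vendor rawfiles and FAIMS metadata are out of scope.
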