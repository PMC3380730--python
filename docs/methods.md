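# Methods

## Problem

Heme cofactors bind proteins through a small set of contact residues.
Identifying those residues from sequence alone — no structure — is a
per-residue binary classification problem with strong class imbalance
(roughly 13–14% of residues in residue-labelled heme chains are binding
sites). This package implements a sequence-only predictor whose feature
space couples two information sources available for any chain:

* **evolutionary profiles** — the L×20 log-odds matrix produced by an
  iterative profile search (PSI-BLAST `-out_ascii_pssm`), squashed
  elementwise into (0,1) by the standard logistic `M = 1/(1+e^{-x})`;
* **physicochemical scales** — AAindex1 entries assigning one value to
  each amino-acid type, z-normalized across the 20 types with the
  *population* standard deviation (denominator 20):
  `w_j = (P_j − μ)/σ`, `μ = (1/20)Σ P_j`, `σ = sqrt((1/20)Σ(P_j−μ)²)`.

## The integrative profile (PSSMPP)

For a window of odd size *w* (default 17) centred on the target
residue, each slot *i* contributes, for every selected scale *p*, one
coupled channel

    F_ip = Σ_{j=1..20} w_pj · M_ij

— the normalized scale dotted with the logistic-scaled PSSM row — plus
one terminal-indicator bit per slot (1 when the slot falls outside the
chain, with all channels zeroed; zero is neutral in every channel
family since normalized scales have zero mean). With P selected scales
this gives (P+1)·w dimensions: 85 at w=17, P=4, against 357 for the
plain PSSM encoding ((20+1)·w) and 425 for the concatenation
((20+P+1)·w). Because Σ_j w_pj = 0, a uniform PSSM row contributes
exactly nothing — the coupled channel responds to profile *shape*, not
level.

Alternative encoders with the same window/padding scheme: `binary`
(one-hot residue identity, 21·w), `pp` (the P scale values of the
slot's residue type, (P+1)·w), and `pssm_pp_concat`. Slot channels are
ordered N→C; within a slot: PSSM columns in the canonical order
ARNDCQEGHILKMFPSTWYV, then scales in selection order, then the bit.

## Scale screening and greedy selection

Individual scales are first scored without any classifier: each
residue receives the scale's value for its amino-acid type, and the
ROC AUC of that value sequence against the labels (Mann–Whitney with
midrank ties) measures discrimination. AUCs below 0.5 are folded to
1−AUC by default — a scale separating in either direction is equally
informative — and scales are ranked descending (ties broken by
accession).

The top *k* (default 20) form a candidate pool C. The greedy loop pops
the best-ranked candidate f, evaluates the balanced 5-fold CV AUC of
the PSSMPP classifier built from S∪{f} against the S-only baseline
(chance level 0.5 for empty S), and accepts f iff the gain exceeds ε
(default 0). On acceptance, remaining candidates with |Pearson r| ≥ ρ
(default 0.8) against f — computed over per-residue assigned values,
i.e. composition-weighted — are pruned. The loop ends when C is empty.
One CV plan (fold assignment and negative draws) is drawn per run and
reused for every candidate, so accept/reject comparisons are paired
rather than re-randomized. The initial static ranking is used
throughout; ranks are not recomputed after acceptances.

ρ = 0.8 keeps genuinely complementary scales (correlations around
0.3–0.6 survive) while discarding near-duplicates; ε = 0 accepts any
strict improvement.

## Model and evaluation protocol

The classifier is an RBF-kernel SVM at library-default
hyperparameters (scikit-learn `SVC`, the libsvm implementation),
exposing its real decision value as the per-residue score. Because
positives are rare, each fold's training set is *all* positives of the
training partition plus an equal-size uniform draw of negatives
without replacement; evaluation keeps the natural imbalance — every
held-out residue is scored, and metrics are pooled over the
concatenated held-out scores at decision threshold 0 (configurable).

Folds are assigned at chain level by default so overlapping windows of
one chain never straddle a train/test split; residue-level assignment
is available. Metrics: ACC, SN, SP, PR, F1, and MCC in its standard
form with the square root over the four-factor denominator product
(the unrooted variant is not bounded in [−1,1]); a metric with a zero
denominator is reported as undefined (`NA`), never coerced to 0. AUC
is the trapezoid area over the threshold sweep, identical to the
midrank Mann–Whitney statistic.

## Synthetic benchmark

No public residue-labelled heme set ships with the package; the
`synthetic` module generates one with a planted, recoverable signal:

* per position, a latent **consensus** residue (uniform over 20 types)
  stands for the conserved identity; the observed sequence mutates
  away from it with probability 0.15;
* the PSSM row concentrates on the consensus with the shape of a
  conserved PSI-BLAST position — integer log-odds ≈ +7 at the
  consensus column, ≈ −4 elsewhere, Gaussian noise sd 1.0. With this
  shape the profile is the *cleaner* channel: the summed logistic
  noise of the 19 off-consensus entries is an order of magnitude
  smaller than the 15% mutation noise in the raw sequence, so
  profile-coupled encoders should, and do, outperform sequence-only
  ones on average;
* binding labels follow a logistic link on the sum of the informative
  scales' normalized values at the consensus type, slope δ (default
  2.0), intercept calibrated by root finding so the marginal positive
  rate is 0.135; informative scales are drawn mutually orthogonal
  (Gram–Schmidt) so each plants an independent signal.

Defaults: 60 chains of 50–100 residues (small heme-binding-domain
scale — cytochrome b5 ≈ 85 aa, cytochrome c ≈ 104 aa; ~4,500 residues
per replicate), 20 scales with 2 informative. Raw scale values are
rounded to 3 decimals and log-odds to integers at generation time, so
the AAindex1/ascii-pssm round trip is bit-exact.

What the generator does **not** emulate: spatial clustering of binding
residues along the sequence, realistic amino-acid background
frequencies, alignment-depth-dependent PSSM statistics, and any
dependence of labels on information outside the single consensus
residue (window context is therefore pure noise here). Passing tests
show the machinery is correct and the protocol unbiased — not that
real heme chains reach any particular accuracy.

## Numerical choices

* Logistic scaling is the plain unit-slope, zero-offset logistic.
* Normalization tolerance 1e-10 (mean/σ contract), encoder contract
  check at 1e-8; the integrative profile agrees with a naive
  triple-loop evaluation to 1e-12 (BLAS summation order accounts for
  ~1e-15 discrepancies).
* Non-standard residues (B, Z, X, U) take value 0 — the mean of a
  normalized scale — in scale-based encoders, and an all-zero block in
  the one-hot encoder; imputation is neutral by construction.
* Degenerate inputs fail loudly: constant scales (σ=0), single-class
  AUC/ROC, constant-input correlations, folds without positives, and
  infeasible balanced draws all raise typed errors.
* Determinism: all randomness flows through `numpy.random.default_rng`
  seeded from explicit config fields; libsvm training is deterministic
  for fixed input, so a seeded cross-validation is bit-reproducible.

## Known limitations

* The benchmark is synthetic; absolute metric values have no bearing
  on real heme datasets, only the contracts and orderings do.
* Greedy selection with ε=0 admits weakly-helpful noise scales along
  with the planted ones; it guarantees no minimal subset.
* The SVM is never tuned (library defaults throughout, matching the
  protocol's spirit of comparing feature spaces, not tuned models).
* PSI-BLAST itself is out of scope: profiles are consumed, not
  produced; label assignment from structures is likewise external.
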