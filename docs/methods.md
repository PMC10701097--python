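# Methods

## The model

`pkplace` places query reads onto a fixed, rooted reference phylogeny
without aligning them, using a precomputed *phylo-k-mer database*: a map
from k-mers to tree branches with scores approximating the probability that
the k-mer occurs in an unsampled sequence that diverged from that branch.

### Ghost nodes and posterior state probabilities

For every branch *y* of the reference tree *T* (with maximum-likelihood
branch lengths and a reversible substitution model), a *ghost node* u_y is
placed at the branch midpoint and a *ghost leaf* v_y is attached to it.
The ghost branch (u_y, v_y) has length equal to the mean path length from
u_y to the original leaves below it — the expected divergence of a query
that belongs on *y*.  Because this mean runs over the leaves *descending*
from u_y, correct rooting is a prerequisite; unrooted input is either
rejected or, on request, midpoint-rooted.

Marginal posterior state probabilities at every ghost node and alignment
site are computed internally by the standard up–down (inside–outside)
algorithm on top of Felsenstein pruning, with the stationary distribution π
as the root prior.  Gaps and ambiguity codes at leaves are treated as
missing data (all-ones partial likelihood).  Per-site scaling factors are
carried in log space, so alignments of ~10 kb (full viral genomes) do not
underflow.  The posterior at v_y is the posterior at u_y propagated through
the ghost branch transition matrix; both nodes enter the score so that the
database represents both "ancestral" and "diverged relative" sequences.
Correctness is tested against an exhaustive sum-over-assignments oracle on
small trees and by the pulley-principle invariance of the site likelihood
to the evaluation node.

Alignment columns whose gap fraction is ≥ `gap_ratio` (default 0.99, i.e.
only near-empty columns) are removed first.

### Substitution models

JC69 and GTR for DNA; Poisson and a general user-parameterized
exchangeability model for amino acids.  Rate matrices are normalized to one
expected substitution per unit branch length; P(t) = exp(Qt) is evaluated
through the eigendecomposition of the π-symmetrized rate matrix, which is
exactly symmetric for any reversible model.  Among-site rate variation is
not modelled in this version (a documented extension point); posteriors
only require *some* reversible model, and the synthetic study conditions
use JC69.

### Database construction

Assuming site independence, the probability of k-mer *w* in the window of
k consecutive columns starting at site *s*, at ghost node *g*, is
Π_i P_g[s+i, w_i].  The score is

    S_y(w) = max over windows s and g ∈ {u_y, v_y} of that product,

stored if and only if S_y(w) > ε.  The default threshold is parameterized
as ε = (ω/σ)^k with ω = 1.5 (σ the alphabet size), which keeps the
threshold commensurate across word lengths; k defaults to 10 for DNA and 6
for amino acids.  Window enumeration uses a meet-in-the-middle split: all
σ^⌈k/2⌉ half-window products are tabulated, the right halves sorted, and
qualifying pairs emitted through a thresholded cross join with a relative
slack of 1e-12 before an exact product filter, so the output equals the
brute-force set exactly.  The construction kernel is JIT-compiled and
max-accumulates into a dense per-code table (for σ^k up to 2^26; beyond
that a sort-based path is used).

### Mutual-information filtering

The informativeness of *w* is the mutual information between the branch
variable and the indicator of observing *w*, which up to a constant factor
(set to 1, natural log) is

    MI(w) = S_w ( ln|E(T)| + Σ_y (S_y(w)/S_w) ln(S_y(w)/S_w) ),
    S_w = Σ_y S_y(w),

where the sum runs over the *stored* tuples: branches whose score fell
below ε contribute nothing to S_w.  (Whether absent branches should
instead be imputed at ε is not determined by the closed form; the
stored-only convention was chosen and is the one all tests pin down.)
A k-mer confined to one branch has MI = S_w·ln|E(T)|; one spread evenly
over all branches has MI = 0.

Entries are serialized in MI-descending order (ties broken by ascending
k-mer code for determinism), so a prefix of the file is always the most
informative part.  Loading with fraction μ reads entries in order and
stops before the entry that would push the cumulative *entry* size past
μ·|D|, where |D| is the sum of serialized entry sizes (header excluded) —
hence a μ′ < μ load is a strict prefix of the μ load, and μ = 1 reproduces
the database bit-exactly.  The *random* baseline filter selects entries in
a seeded random order up to the same budget; the in-memory filter and the
partial deserializer apply identical bookkeeping and seeded selection, and
are tested to agree exactly.

### Placement

For query *q* with k-mers w_1 … w_{|q|−k+1} (windows containing gaps or
ambiguity codes are skipped), the score of branch *y* is

    ℓ_y(q) = (1/k) Σ_i max{ log_b ε, log_b S_y(w_i) },

with a branch absent from a k-mer's tuple list contributing log_b ε.  The
1/k factor compensates for each character being counted by up to k
overlapping k-mers, making ℓ an approximate per-sequence log-probability.
Branches are ranked by ℓ (ties by ascending branch id) and reported with
likelihood weight ratios LWR(q,y) = b^{ℓ_y} / Σ_x b^{ℓ_x}, normalized over
*all* branches and computed stably by subtracting the maximum before
exponentiation.  The logarithm base b is 10 throughout; the LWR is
invariant to the base only if one base is used consistently, so it is
fixed globally rather than exposed per formula.

DNA queries are scored in both orientations by default and the better
orientation is reported, since real reads are unoriented; `--no-revcomp`
(or `use_revcomp=False`) gives the single-orientation behaviour.

Output is jplace version 3.  Edge numbers come from a deterministic
post-order traversal of the original tree.  The method estimates neither a
distal nor a pendant position, so the file reports the model's own
geometry: `distal_length` = half the branch length (the u_y midpoint) and
`pendant_length` = the ghost branch length.  Unplaced queries (no
encodable k-mer) appear with an empty placement list.

## Evaluation

Pruning-based accuracy (PAC): a uniformly random subtree is removed
(draws leaving fewer than three leaves, or attached directly to the root,
are resampled), the two edges at the detachment point merge into one
branch — the *expected* placement — and 150-bp reads extracted from the
removed sequences are placed on the rebuilt reference.  The read count per
pruning is ⌈removed residues / 150⌉, capped (default 100 in the experiment
harness).  Accuracy is the *node distance*: the number of tree nodes on
the path between observed and expected edges, counted on the unrooted tree
(the degree-2 root is suppressed, which also identifies its two child
edges).  The filtering experiment rebuilds the database per pruning and
compares MI against random filtering over a μ grid with identical prunings
and reads.

## Synthetic study conditions

The generator produces Yule-topology trees (a uniformly chosen extant leaf
splits at each step) with i.i.d. exponential branch lengths of mean 0.1
substitutions/site — divergences typical of a single-marker reference
phylogeny — and evolves ungapped alignments site-independently under the
chosen model from a stationary root draw.  Reads are uniform-start
substrings with i.i.d. substitution errors.  Two standard fixtures are
used by the tests and the reproduction script: **small** (16 leaves ×
600 bp) and **medium** (64 leaves × 1500 bp), both DNA under JC69.  The
filtering experiment uses 10 prunings of the medium fixture with
μ ∈ {1, 1/2, 1/4, 1/8, 1/16}; these sizes keep a full run in minutes on
one CPU while the databases remain large enough (≈10⁶ k-mers, ≈10⁸ tuples
at k = 10) for filtering to bite.

What the generator does *not* emulate: indels (reference alignments are
ungapped; the gap filter is tested on hand-made fixtures), among-site rate
heterogeneity, compositional biases, sequencing-specific error profiles,
and paralogy/contamination.  Passing the recovery and filtering tests
therefore shows the pipeline is internally correct and that MI filtering
preserves accuracy on well-behaved data; it does not by itself predict
accuracy on real marker genes.

## Numerical choices and edge cases

- Enumeration is exact with respect to brute force; borderline products are
  decided by the product itself, never by a division.
- Zero-length branches are legal: u_y coincides with both endpoints and a
  zero-length ghost branch copies u_y's posterior to v_y exactly.
- A column with no data yields the prior π as posterior.
- Queries shorter than k, or with every window poisoned by an ambiguity
  code, are flagged unplaced rather than erroring.
- Equal placement scores are broken by ascending branch id; equal MI by
  ascending k-mer code — all output is deterministic for a fixed seed.
- Scores are stored and serialized as 64-bit floats; round-trips are
  bit-exact.

## Known limitations

Single-threaded; in-memory construction only (no external-memory build);
no Γ rate categories; no paired-read handling; jplace is the only
placement output format.  The distal/pendant jplace fields follow the
package's own midpoint/ghost-length convention, which downstream consumers
should not interpret as estimated attachment positions.
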