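# Methods

## Representation

A sequence is read as overlapping words of length K over A < C < G < T, the
D = 4^K words ordered alphabetically so that word j is the base-4 expansion
of j and the four single-base extensions of any (K−1)-base pretext occupy the
consecutive index quadruple {4h, …, 4h+3}. Three vector modes are derived
from the raw window counts: presence (0/1), frequency (raw counts) and
profile (frequencies divided by their sum). RNA input is folded to DNA
(U→T) and case is ignored. Any window containing a symbol outside
{A, C, G, T} — IUPAC ambiguity codes, gaps — is skipped rather than imputed;
skipping is the dominant convention for word-count classifiers and keeps the
counts interpretable as exact window tallies (total ≤ L − K + 1). Words are
counted on the given strand only; no reverse-complement canonicalization.

## Classifiers

All five share one decision rule: assign to the genus with the strictly
largest score; if two or more genera tie, return `unclassified`. Ties are
declared at relative tolerance 1e−12 (|z_max − z| ≤ 1e−12·max(1, |z_max|))
because exact float equality is fragile across platforms, while genuinely
distinct scores differ by far more than 1e−12 in practice. A query with zero
countable K-mers is returned `unclassified` by every method rather than
falling back to an arbitrary genus. `unclassified` outcomes count as errors
in all reported figures; treating abstention as success would understate
error.

**Presence naive Bayes (rdp).** With N training sequences of which n_j
contain word w_j, the background presence probability is
Pr(w_j) = (n_j + 0.5)/(N + 1), strictly inside (0, 1). For genus g with M_g
sequences of which m_gj contain w_j, q_gj = (m_gj + Pr(w_j))/(M_g + 1). The
score of a presence vector a is z = p + L a′ with L = log₂ Q. Flat priors
are represented by the all-zero log-prior vector: a constant shared by all
genera never changes the argmax, so the prior term is simply omitted;
abundance priors use log₂(M_g/N). Base-2 logarithms are used throughout (the
choice is argmax-invariant).

**Multinomial naive Bayes.** Here m_gj is the *summed frequency* of w_j over
the genus (not a sequence count — the two trainers deliberately consume
different vector modes). Pseudo-counted frequencies F(w_j|g) = m_gj/M_g + 1/D
are normalized by their row sum to multinomial probabilities, and a raw
frequency query vector is scored as z = p + L a′.

**Markov chain of order K−1.** From the same pseudo-counted F, the
transition probability of the last base given the (K−1)-base pretext is
obtained by normalizing each pretext's four extensions to sum to 1 — in the
alphabetical layout, each consecutive quadruple of columns. The score is
z = L a′ with no prior term. Requires K ≥ 2.

**Nearest neighbour (nn).** Each training sequence is a row of the profile
matrix; a query profile is assigned the genus of the Euclidean-nearest row.
If rows of two or more distinct genera tie for the minimum distance the
query is `unclassified`; a tie among rows of a single genus still
classifies. Degenerate training sequences (no countable K-mer) are skipped
with a warning. Batch classification uses the squared-distance expansion
‖a‖² + ‖b‖² − 2a·b with clipping at zero for numerical safety.

**PLS-preprocessed nearest neighbour (plsnn).** PLS2 is fitted by NIPALS
with X-deflation: X is the N×D training profile matrix, Y the N×G 0/1 genus
indicator matrix, both column-mean-centered (no variance scaling — profiles
already share a scale, and autoscaling 4^K mostly-zero columns would inflate
noise). Each component's weight vector maximizes covariance with Y subject
to orthogonality with earlier weights; the weights are unit-norm and
mutually orthogonal, so the projection matrix R satisfies R′R = I, and the
training scores S are the NIPALS scores (X·R ≈ S). A query is projected as
s = (a − training mean)·R and classified by the same nearest-neighbour rule
over the rows of S. Component extraction stops early, with a warning, when
the residual X variance falls below 1e−12 of its initial value, and the
NIPALS inner iteration converges on the score vector at relative tolerance
1e−12 (cap 1000 iterations). The candidate dimensions are
C = round(i·C_max/8) for i = 1..8 with C_max = min(N−1, D−1, 2000);
selection across the grid is a benchmarking loop, not something hidden
inside training — `run_cross_validation` defaults to the smallest grid
value, which is cheap and already ample when genera are separable (it
exceeds the number of genera in all the bundled study conditions).

One subtlety worth recording: with X-deflation the scores of components
beyond the first are computed from deflated X, so S is *not* exactly
X_centered·R; the identity s = a·R used at classification time is the
standard approximation (exact for C = 1). At full rank the scores span the
centered row space exactly (regressing X_centered on S reconstructs it),
while S·R′ only approximates X_centered — both facts are asserted in the
test suite, and agreement with an independent PLS2 implementation
(scikit-learn, used strictly as a cross-check) is verified per component up
to column sign.

## Evaluation protocol

Records are sorted alphabetically by genus, ties broken by sequence id for
run-to-run determinism, and dealt round-robin into ten folds: position i
(1-based) goes to fold ((i−1) mod 10) + 1. This spreads every genus over as
many folds as it has sequences; a genus of size s ≤ 10 lands in s distinct
folds. Each fold serves once as the test set.

Singleton genera (one sequence in the whole corpus) are excluded from the
error denominator: their genus is absent from training whenever they are
tested, so they are wrong by construction under every method — the test
suite asserts this rather than assuming it.

Fragment mode cuts each test sequence into n = 10 windows of 200 bases with
start offsets round((i−1)(L−200)/9): evenly spaced, first window at the
start, last window ending at the last base. This is the minimal scheme that
is both "partially overlapping" and spans the whole sequence; both n and the
fragment length are configurable. A sequence no longer than the fragment
length yields n identical copies. Each fragment is classified as an
independent query (fragments are not vote-aggregated per sequence), and
per-position error curves are computed from the recorded fragment index.

Error breakdowns: per-fold and pooled summaries (pooled error equals the
evaluation-count-weighted mean of fold errors), error by genus size
(per-genus error percentages averaged across genera of the same size, sizes
2–10), Venn sector counts of per-method error sets (with the count of
queries given the identical wrong genus by every method), and per-fragment
positional error.

## Synthetic communities

The generator emulates the two structural features of real 16S reference
corpora that drive classifier behaviour: strongly right-skewed genus sizes
(sizes drawn from a discrete power law P(s) ∝ s^(−1.8) truncated at 50,
making singletons the most common size; explicit size lists are preferred in
tests) and within-genus divergence far below between-genus divergence. One
uniform random root sequence is mutated at per-site rate d_between to give
each genus an ancestor, and each sequence mutates its ancestor at rate
d_within (substitutions only, uniform over the three alternative bases);
sequence lengths are uniform on length ± jitter, default 1500 ± 100 — the
full 16S gene. Defaults d_between = 0.25, d_within = 0.01 put within-genus
identity around 98% and between-genus identity around 70%, a deliberately
clean caricature of the real separation. Identical specs (including seed)
produce byte-identical corpora.

What the generator does *not* model: indels (kept out so fragment
coordinates stay trivial), the conserved/hypervariable region structure of
the real gene, chimeras, sequencing error, shared phylogenetic structure
between genera (the star phylogeny makes all genera equidistant), or
mislabelled reference sequences. Consequently, passing the bundled
benchmarks shows the pipeline is implemented correctly and behaves sensibly
as separability degrades — it does not predict absolute error rates on real
reference corpora, where label noise and uneven divergence dominate and
errors plateau well above zero.

## Problem sizes and numerical choices

The bundled study conditions use a reference community of 30 genera with
5–20 sequences each plus singleton genera (~380 sequences of ~1500 bases) at
word length K = 6 (D = 4096) for the end-to-end checks, and smaller corpora
for unit-level properties; these sizes exercise every code path, including
fragment mode (ten 200-base windows per test sequence), while keeping the
whole suite comfortably interactive. At these conditions all five methods
reach 0% cross-validated error on full-length sequences, singleton test
sequences are 100% wrong, and the presence/absence method collapses at K = 2
(word saturation: nearly every dimer is present in every sequence, so
presence vectors carry no signal) — the qualitative shape expected of these
methods.

Other numerics: probability matrices are stored as dense log₂ arrays;
training sums are accumulated per genus with exact integer counts before the
single division; model files are versioned NumPy archives and a newer
format version is refused rather than misread; fragment start offsets use
floor(x + 0.5) rounding for platform-stable behaviour.

## Known limitations

- Genus is the only rank; no bootstrap confidence values (a feature of the
  original RDP tool outside this comparison's scope).
- No significance testing on per-fold errors; the per-fold vectors are
  exported so any statistics package can do it.
- The NN-family methods hold the full reference matrix in memory and compute
  all pairwise distances per query; at K = 8 and corpus sizes in the tens of
  thousands this is the known cost of the approach.
- `classify` applies flat priors; abundance priors are available wherever
  training labels are in hand (library and `benchmark`).
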