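# Methods

## Scope and model

`allerscreen` implements the sequence-comparison battery used in regulatory
allergenicity assessment of novel food proteins: a full-length local
alignment scan with E-value thresholds of 10 and 1.0, the CODEX sliding
80-amino-acid window criterion (> 35 % identity), an exact 8-mer word
search, the Aalberse full-length > 50 % identity rule, and safe-homolog
context ranking with neighbor-joining trees.  The screen is a *flagging*
procedure, not a classifier: its tri-state verdict ("no significant match",
"match — context outranked by safe homologs", "match — review required")
never asserts allergenicity, because sequence similarity is only one arm of
a weight-of-evidence assessment.

## Alignment

Full-length comparisons use exact affine-gap Smith–Waterman local alignment
(Biopython's `PairwiseAligner` C engine behind the package's surface).
Defaults are BLOSUM50 with gap open −10 and gap extend −2 — the classic
FASTA protein parameters — where a gap of length *g* costs
`gap_open + (g−1)·gap_extend`.  Matrices are loadable by name or from
NCBI-format files; rows for ambiguity codes absent from the matrix
(selenocysteine U) score 0, and ambiguity codes (X, B, Z, U) **never** count
as identities anywhere in the package — a conservative rule for a safety
screen.  Among co-optimal alignments the engine's first reported path is
taken; it is deterministic for fixed inputs, which is the property the
reports rely on.  The test suite anchors the engine to two independent
oracles: a pure-Python Gotoh dynamic program (1000 random pairs) and, for
the Gotoh code itself, an explicit enumeration of every gapped local
alignment path on tiny sequences.

Percent identity over an alignment is `100·identities/aligned_columns`,
with gap columns in the denominator.  "Full-length identity" — the currency
of the Aalberse > 50 % rule, safe-homolog ranking, and tree distances — is
`100·identities/max(len_query, len_subject)`: spreading the best local
alignment's identities over the longer sequence cannot overstate
relatedness from a short, well-conserved core.

### Window scan is ungapped by design

The 80-mer scan places each window on each subject at every offset
(overhangs free) and takes the best-scoring placement; identity is counted
positionally over the full window.  This is deliberate: the > 35 %-over-80
criterion's arithmetic is positional (29/80 identities pass, 28/80 do not),
and a gapped window alignment can manufacture extra "identities" by
inserting an indel pair when the window is mismatch-dense (observed: a
52-mismatch plant realigned to 30 identities over 81 columns).  Under
ungapped placement a segment planted with *k* substitutions is recovered at
exactly `100·(80−k)/80` for every seed.  Gapped similarity is the
full-length scan's job.  Queries shorter than 80 residues are scanned as a
single full-length window (conservative inclusion); the window step is 1.

## E-value calibration

Search-engine E-value statistics are not reproducible offline, so E-values
are calibrated empirically per query: database entries
are cycled, residue-shuffled, and scored against the query (default 500
shuffles; minimum 100; 5-entry minimum database), and the null scores are
fitted by maximum likelihood to a Gumbel distribution — the asymptotic law
for optimal local alignment scores.  Then `E(S) = D · sf(S)` for a database
of D entries: E is the expected number of chance hits at or above S, linear
in database size and strictly decreasing in score wherever the fitted tail
is floating-point resolvable.  On pure decoy databases the mean number of
hits with E ≤ 1 per query is ≈ 1 (measured 0.88–1.0 over 200 replicates),
which is the calibration's honesty check.  Entry length variation within a
database is absorbed into the fit rather than modeled per entry.  For the
window scan, one calibration from a representative window (the first) is
reused across all windows of a query: a per-window fit would multiply the
cost by the window count while the binding gate of the window scan is the
identity threshold, not the loose E < 10 rule — note that for databases of
fewer than ~10 entries `E = D·sf ≤ D < 10` holds identically, so at desk
scale the E < 10 column simply counts scored entries.

## Safe-homolog context and trees

Context ranking compares the best allergen hit (at E < 10) with the best
match from a user-supplied safe set, both in full-length identity; the
verdict is *outranked* when the safe identity is strictly higher.  Distance
matrices are p-distances `1 − identity/100`; neighbor joining is the
Saitou–Nei/Studier–Keppler agglomeration with two determinism choices:
equal Q-criterion ties join the pair whose smallest leaf labels sort first,
and negative branch-length estimates are clamped to zero and flagged.  On
additive matrices NJ recovers the generating topology and path lengths
exactly (machine precision); the implementation is cross-checked against
scikit-bio's NJ on random matrices.  Model-corrected distances, multiple
alignment, likelihood trees and bootstrap are out of scope — the tree is a
grouping aid, not an inference.

## Synthetic data

The generators emulate the *structure* of a curated allergen database at
desk scale, not its content:

* **Decoys** — i.i.d. residues, uniform over the 20 standard amino acids by
  default (an empirical composition can be supplied), lengths uniform in a
  configurable range (default 100–300, spanning typical single-domain
  proteins).  Decoys are rejection-sampled (budget 200 tries) so they share
  no 8-mer with the paired queries; clean databases therefore give
  provably zero word-scan hits.
* **Planted homologs** — a query segment copied with exactly *k*
  substitutions, each drawn uniformly from the 19 non-identical residues,
  embedded in 60-residue flanks.  Flanks are decoy residues by default;
  with `mask_flanks=True` they are X padding, which makes exact-identity
  recovery a theorem (X never counts as an identity) rather than a
  high-probability event — the variant used wherever a test asserts an
  identity to the digit.
* **Tree-evolved families** — substitution positions are allocated globally
  without replacement across branches (error if the counts oversubscribe
  the sequence), so pairwise leaf differences are exactly additive along
  the tree; the measured difference table is returned for bookkeeping.

What passing tests on these fixtures do **not** show: real allergen
databases have biased composition, repeats, and homologous families, so
E-value calibration on real data is harsher and 8-mer hits are not
independent across entries; the printed identities of any particular
published screen also depend on that engine's gap parameters and statistics.
Desk-scale results here validate the machinery and its thresholds, not any
specific database's hit counts.

## Numerical and reporting choices

* Strict thresholds: window identity must exceed 35 % (35.0 % fails);
  full-length identity must exceed 50 %; E-value comparisons use `<`.
* 8-mer counts are distinct query 8-mers per entry, not occurrence pairs.
* The E < 10 count is display-capped as "20+" in the TSV (only that
  column); the JSON mirror always stores exact integers.  Empty cells mean
  "not applicable", 0 means "scanned and found nothing".
* Hit lists sort by (E-value, subject id); per-query calibration seeds are
  derived deterministically from the run seed; two runs with the same
  config and inputs are byte-identical.
* Exit codes: 0 success, 2 input error, 3 calibration failure, 4 internal
  inconsistency.
* Problem sizes in the shipped tests and acceptance script (10–15-entry
  databases, 120–200 shuffles, 200 calibration replicates, 1000 oracle
  pairs) were chosen as the smallest sizes at which each property is
  statistically meaningful.

## Known limitations

* No heuristic seeding or banding: alignment is exact DP, so very long
  proteins (>2000 residues) against large databases are slow; the package
  targets curated, keyword-filtered databases of modest size.
* The Gumbel fit ignores edge effects and length-dependence of local
  alignment score distributions (finite-size corrections); at desk scale
  the calibration check bounds the resulting error.
* Safe-homolog context uses pairwise identities only; it cannot detect
  shared epitopes between proteins of low overall identity.
* No nucleotide, six-frame, epitope-prediction, or serum-IgE modeling.
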