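# Methods

This note documents the models and procedures msaforge implements, the
defaults and why, what the synthetic-data generators do and do not emulate,
and the numerical choices made where the design was genuinely open.

## Alignment model and encoding

An MSA lives on the query's match-column coordinate system: the first row
is the gap-free query of length `L`; uppercase letters and `-` occupy match
columns, lowercase letters are insertions and carry no column index
(HH-suite A3M convention). Aligned FASTA is accepted as the
no-lowercase special case. Internally all coordinates are 0-based
half-open; user-facing text output (score matrices, distance lists) is
1-based.

Residues map onto a fixed 22-state alphabet: the 20 canonical amino acids
in alphabetical one-letter order (states 0–19), an unknown state (20) for
X and all nonstandard codes (B, Z, J, U, O, anything unrecognised), and the
gap state (21). Fixing the order makes coupling indices reproducible. The
encoding is total: every printable character maps to some state.

Species keys come from UniProt-style headers; the numeric `OX=` taxon
identifier takes precedence over the `OS=` organism name (both parseable
individually via a mode switch) because taxon ids are unambiguous where
organism names may vary in formatting. Sequences without an annotation —
typically metagenomic hits — have no species key and can never be linked
across chains. Species comparison is exact string match after whitespace
trimming; no taxonomy-tree awareness.

## Diversity statistics

Pairwise identity is computed over match columns only: identical residues
divided by mutually non-gap columns, zero when no column is shared. The
denominator choice (mutual non-gap, not full length) is symmetric and
insensitive to terminal gaps, matching standard filtering tools; insertions
never contribute. The effective-sequence count

    Neff = (1/sqrt(L)) * sum_n 1 / (1 + sum_{m!=n} I[S_mn >= 0.8])

treats the query as an ordinary row (Neff is a property of the alignment,
and the query is a row of it). The redundancy comparison is `>=` on the
0.8 threshold, which is exposed as a parameter. Coverage is the mean
aligned fraction over homologs (undefined for a query-only alignment, which
raises rather than returning a sentinel); per-site depth counts homologs
aligned per column; `mean(depth)/(N-1) == coverage` holds by construction
and is tested.

## Monomer orchestration

The orchestrator owns control flow only; each search stage is a pluggable
backend receiving its database label and verbatim parameter preset as
opaque strings. Two stage shapes exist: direct profile search, and raw-hit
retrieval followed by an enrichment step (clustering at 30% identity,
per-cluster realignment, custom profile database construction and
re-search are one pluggable `enrich` contract — their internals belong to
HH-suite-style tooling, their position in the dataflow is the design).
The orchestrator truncates raw hit lists to the 30,000 top-ranked before
enrichment; the hit backend supplies the ranking. This cap is applied to
every hit-enrichment stage.

A block halts after the first stage whose alignment has `Neff > 128`
(strict comparison; 128 exactly continues — the boundary is tested). An
early stop ends that block only. The metagenomic block runs one probe
search (the deepest available qMSA alignment; stage 3 when present) and
then up to three seeded searches using the dMSA stage-2 and qMSA stage-2/3
alignments as seeds, skipping absent seeds; it is skipped entirely when
both dMSA and qMSA Neff-stopped at stage 1. A backend failure at stage k
yields the partial result for stages < k plus a diagnostic string; an
empty stage-1 result degrades to a query-only candidate.

Ranking: each candidate MSA receives five model-confidence values from a
pluggable structure scorer; the rank score is the best of five; the
top-ranked MSA is selected, ties broken by higher Neff and then by block
(dMSA < qMSA < mMSA) and stage order, so selection is deterministic.

## Multimer pairing and linking

Stoichiometry strings (`A2B2C1`) parse into ordered (chain, copies) pairs.
The pairing depth is the largest `M` with `M^N <= 100` (`N` distinct
chains), additionally capped by the candidates actually available per
chain; enumeration is the full lexicographic product, so exactly `M^N`
combinations when supply suffices.

Linking (heteromers only): per chain, homologs are grouped by species key
and sorted within a group by identity to that chain's query, descending and
stable. A species present in two or more distinct chains contributes
rank-matched linked rows down to its smallest group size (a `link_depth`
option caps this at 1 for top-row-only linking); chains lacking the species
contribute gap blocks. Species present in a single chain are never linked.
Linked species blocks are emitted in sorted-key order and all remaining
rows are appended below, one row per homolog, gap-padded in every other
chain's columns, in within-chain identity order — so every input homolog
appears exactly once and all rows share the concatenated length
`sum_i n_i * L_i` (chain blocks are repeated per copy count, mirroring the
homomer rule). Insertions are dropped when concatenating; the paired
alignment is a pure match-column object, with per-chain column spans
recorded in a sidecar structure.

Homomers skip linking: every candidate MSA of the single chain is
concatenated with itself once per copy (row count unchanged, length
multiplied).

The M-score multiplies the paired alignment's Neff — computed on the full
concatenated MSA, linked and padded rows alike — by the copy-weighted mean
of the per-chain model confidences carried over from the monomer stage.
Heteromers keep the top 25 by M-score (ties by component choice,
lexicographic); homomers keep all self-concatenations. The complex
predictor contract returns 25 scored models per kept MSA; all models
(625 heteromer / 250 homomer under defaults) are ranked by predicted
TM-score and the top five returned with provenance. A predictor failure on
one MSA skips that MSA with a diagnostic.

## Coevolution features

Mutual information uses plug-in frequencies over all 22 states (gaps and
unknowns are ordinary states; an optional pseudocount is off by default),
natural logarithm, `0·ln 0 := 0`. Rows are unweighted — the objective is a
plain sum over sequences — and an identity-threshold reweighting is
deliberately not applied by default.

The Potts model minimises the negative log-pseudolikelihood: for each site
`i` and row `n`, the conditional probability of the observed state given
the rest of the row, a softmax over `h_i(q) + sum_{j!=i} P_ij(q, s_n^j)`,
plus L2 penalties `lambda_single*||h||^2 + lambda_pair*||P||^2` with
defaults `lambda_single = 1`, `lambda_pair = 0.2*(L-1)`. Couplings are
parameterised asymmetrically during optimisation (each directed block
free), diagonal blocks are excluded from energies, penalty and gradient,
and the fitted tensor is symmetrised post hoc as `(P_ij + P_ji^T)/2` —
standard pseudolikelihood practice. The optimiser is L-BFGS from a zero
start (deterministic), iteration cap 200 and projected-gradient tolerance
1e-4 by default; hitting the cap returns the model flagged unconverged
rather than raising. Analytic gradients are verified against central
finite differences in the test suite.

One geometric consequence of the uniform L2 choice worth knowing: a fully
conserved column's logit can be carried by the `L-1` couplings at total
penalty `0.2*c^2`, cheaper than the field's `1*c^2`, so zero-covariation
alignments show a *uniform* nonzero coupling background rather than exactly
zero couplings. The invariant that matters for contact inference — no
pair-specific signal — still holds exactly and is what the tests assert.

Contact scores are Frobenius norms of the 21×21 non-gap sub-blocks of the
symmetrised couplings (the gap state is excluded from scoring, not from
fitting). The average-product correction subtracts
`rowmean_i*rowmean_j/grandmean` with means over the full matrix including
the diagonal; this makes the correction exactly annihilate rank-one
matrices, at the cost of a small `~score/L` residual from the zero
diagonal — an acceptable trade for a closed-form-testable definition.
Top-contact listing filters to `|i-j| >= min_separation` (default 24) and
breaks ties by (i, j).

Distogram point estimates take the midpoint of the highest-probability bin
(first bin on ties); because the upstream binning is not fixed by the
pipeline, the bin scheme is caller-supplied, with a preset of 36
half-Angstrom bins over [2 Å, 20 Å] plus an open last bin whose nominal
midpoint is its lower edge plus half the previous width. The distance MAE
averages `|d_pred - d_exp|` over the top `5L` long-range pairs in the
caller-supplied confidence order (input order by default); pairs without
experimental truth are dropped with the divisor reduced, and zero eligible
pairs is an explicit undefined-value error.

## Synthetic data: what it emulates, what it does not

The generators exist so that every orchestration and inference rule is
exercised against hand-computable ground truth:

* **Mutated-query alignments** hit requested identity levels *exactly*
  (mutating `round((1-level)*L)` distinct positions; a level unreachable
  within ±0.02 is an error), so closed-form Neff values (`N/sqrt(L)`
  all-diverse, `1/sqrt(L)` all-identical) hold without tolerance. Species
  labels are assigned round-robin to a configurable annotated fraction and
  are encoded in the headers so they survive serialisation.
* **Potts alignments** are sampled from a zero-field model whose only
  couplings sit on the planted pairs — each pair gets a random-permutation
  coupling of configurable strength (default 3.0, strong enough for
  unambiguous dependence at N≈1500 while keeping marginals uniform).
  Sampling runs one independent Gibbs chain per output row for
  100 burn-in + 10 decorrelation full sweeps (recorded in the fixture);
  independence across rows is exact by construction, unlike a single
  thinned chain. The coupling-recovery checks run at L=20, N=1500 with
  three planted pairs — sizes chosen so the full fit completes in seconds
  on one CPU while leaving the recovery margin wide.
* **Complex fixtures** build per-chain candidate MSAs from an explicit
  species-membership table, so the expected number of linked rows is a
  short enumeration, not a re-implementation of the linking rule.
* **Mock scorer/predictor/backends** are deterministic: confidences are a
  saturating function `neff/(neff+5)` of alignment depth (monotone, so
  ranking tests are closed-form), and scripted search backends return
  alignments with prescribed exact Neff values (diverse rows at L=16, so
  `Neff = N/4`), which makes the 128-boundary tests exact rather than
  approximate.

None of this emulates real evolutionary structure: no phylogenetic
correlation between rows, no realistic substitution process, no alignment
errors, no gap patterns from true insertions/deletions, and species labels
are uniform rather than clade-structured. Passing tests therefore
demonstrate that the orchestration, linking, ranking and inference rules
are implemented correctly and that the estimators behave as their
definitions demand — not that any particular biological accuracy is
achieved on real proteins, which additionally depends on the external
search tools and predictors behind the contracts.

## Known limitations

* Pipeline adapters invoking real local binaries (HHblits/Jackhmmer/...)
  are out of scope; only the contracts and mock implementations ship.
* Species linking is exact-key matching; no taxonomy-tree awareness, so
  strain-level annotation differences prevent linking.
* The pseudolikelihood fit stores the dense `L^2 Q^2` coupling tensor
  (~1.5 MB at L=20, but ~24 GB at L=800); the implementation targets
  feature extraction and validation at modest L, not proteome-scale
  scans.
* Distogram binning is caller-defined; results depend on the supplied
  scheme.
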