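# msaforge

Staged multiple-sequence-alignment (MSA) construction for protein structure
prediction, at desk scale: MSA diversity statistics, orchestration of the
iterative monomer search blocks, species-aware pairing and linking of
multichain (complex) MSAs, and MSA-derived coevolution features (mutual
information and pseudolikelihood Potts couplings). External search engines
(HHblits, Jackhmmer, HMMsearch, ...) and deep-learning structure predictors
are abstracted behind pluggable contracts, so the whole pipeline is testable
on deterministic synthetic inputs without any sequence database.

It is written for people who study or build MSA-construction pipelines: the
logic that decides *which* alignments get built, capped, stopped, paired and
ranked is the subject here, not the third-party search tools behind it.

## The quantities at the core

**Effective sequences.** For an alignment of `N` rows over a query of length
`L`, with `S_mn` the pairwise identity over mutually non-gap match columns,

```
Neff = (1/√L) · Σ_n 1 / (1 + Σ_{m≠n} I[S_mn ≥ 0.8])
```

so mutually diverse rows give `Neff = N/√L`, and the rough minimum number of
diverse sequences needed to reach a diversity cutoff is
`N_min = cutoff · √L`.

**Monomer orchestration.** Three search blocks (dMSA: 3 stages, qMSA: 4,
mMSA: up to 3 seeded searches) run over pluggable backends. A block stops as
soon as a stage's alignment has `Neff > 128`; raw hits entering
cluster-based enrichment are capped at the 30,000 top-ranked; the
metagenomic block is skipped when both other blocks stopped at stage 1. The
up-to-ten candidate MSAs are each scored by a pluggable structure scorer
(five model confidences, best-of-five is the rank score) and the best MSA
wins.

**Multimer pairing.** For a complex with stoichiometry string like `A2B2C1`
(`N` distinct chains), the top `M` monomer MSAs per chain are combined,
where `M` is the largest integer with `M^N ≤ 100`. Heteromer combinations
are linked by species: same-species homologs of different chains are
concatenated rank-by-rank (sorted by identity to the query), absent chains
are gap-padded, and all unlinked rows are appended gap-padded below.
Concatenated MSAs are ranked by the M-score

```
M-score = Neff(paired) · ( Σ_i n_i · pLDDT_i ) / ( Σ_i n_i )
```

with `n_i` the copy number and `pLDDT_i` the chain's monomer-stage model
confidence. Heteromers keep the top 25; homomers keep all (≤10)
self-concatenations; 25 models per kept MSA are generated and the top five
by predicted TM-score returned.

**Coevolution features.** Column-pair mutual information (in nats) and a
22-state Potts model fitted by pseudolikelihood maximisation with L2
penalties (`λ_single = 1`, `λ_pair = 0.2·(L−1)`), reduced to contact scores
by Frobenius norms of the non-gap coupling blocks with average-product
correction. Distance-map evaluation uses the mean absolute error of the top
`5L` long-range (`|i−j| ≥ 24`) predicted distances.

## Worked example

```python
>>> from msaforge import fixtures, monomer, multimer
>>> from msaforge.msa_stats import neff, min_diverse_sequences

>>> min_diverse_sequences(2**0, 100), min_diverse_sequences(2**4, 100)
(10.0, 160.0)

# a 20-row alignment of mutually diverse sequences over 100 columns
>>> neff(fixtures.diverse_msa(20, 100, seed=1))
2.0

# full monomer orchestration on scripted mock backends (per-stage Neffs)
>>> backends = fixtures.scripted_monomer_backends([20, 40, 60], [30, 50, 70, 90])
>>> cands = monomer.generate_candidates("ACDEFGHIKLMNPQRS", backends)
>>> len(cands)
10
>>> best = monomer.rank_and_select(cands, fixtures.MockScorer())
>>> best.label, round(best.rank_score, 3)
('qMSA-4', 0.947)

# multimer bookkeeping for a two-chain heteromer
>>> st = multimer.parse_stoichiometry("A1B1")
>>> chains, _ = fixtures.make_complex_fixture(
...     st, {"9606": {"A": 2, "B": 2}, "10090": {"A": 1, "B": 1}},
...     seed=3, candidates_per_chain=10)
>>> result = multimer.run_multimer(chains, st, fixtures.MockPredictor())
>>> result.n_generated, len(result.models)
(625, 5)
```

The ten candidates are the 3 + 4 + 3 contributions of the three search
blocks (no early stop triggered); the deepest alignment wins ranking under
the depth-monotone mock scorer; and the heteromer run selects 25 paired
MSAs × 25 models = 625 models before returning the top five.

A CLI wraps the same library (`msaforge stats`, `convert`, `monomer run`,
`multimer pair`, `coevolve mi|plm`, `mae`, `simulate`); exit codes are 0 on
success, 1 for usage errors, 2 for data/format errors.

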