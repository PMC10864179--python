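"""Deterministic synthetic data for every pipeline stage.

Nothing here is downloaded: mutated-query alignments with controllable
identity levels and species annotations, Gibbs-sampled Potts alignments
with planted couplings, complex chain sets with hand-computable linked-row
counts, and scripted stand-ins for the external search tools and structure
predictors.  All generators are pure functions of their spec, seed
included: the same spec yields byte-identical output.

The mutated-query generator hits a requested identity level exactly by
mutating ``k = round((1 - level) * L)`` distinct positions, so closed-form
effective-sequence values (e.g. ``N / sqrt(L)`` for an all-diverse
alignment) can be asserted without tolerance.  The Potts generator runs
independent parallel Gibbs chains (one per output row) from random
initialisations through a burn-in plus decorrelation schedule, with
couplings placed only on the planted pairs, giving a generative ground
truth for coupling-recovery checks.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np

from .monomer import (
    CandidateMsa,
    MmsaBackend,
    MonomerBackends,
    PipelineStage,
    StageSpec,
    DMSA_STAGES,
    QMSA_STAGES,
)
from .msa_io import AA20, Msa, SeqRecord
from .msa_stats import neff as compute_neff


@dataclass(frozen=True)
class FixtureSpec:
    """Recipe for a mutated-query alignment."""

    seed: int
    L: int
    N: int
    identity_levels: tuple = (0.5,)
    species_pool: tuple = ()
    fraction_annotated: float = 0.0


def _random_query(rng: np.random.Generator, L: int) -> str:
    return "".join(rng.choice(list(AA20), size=L))


def _mutate(rng: np.random.Generator, query: str, k: int) -> str:
    """Mutate exactly k distinct positions to a different residue."""
    seq = list(query)
    positions = rng.choice(len(seq), size=k, replace=False)
    for pos in positions:
        alternatives = [a for a in AA20 if a != seq[pos]]
        seq[pos] = alternatives[int(rng.integers(len(alternatives)))]
    return "".join(seq)


def make_msa(spec: FixtureSpec) -> Msa:
    """Generate a query plus ``N - 1`` homologs at the requested identity
    levels (cycled), each level hit within +/-0.02 by point mutation.

    Species labels from the pool are assigned round-robin to the first
    ``fraction_annotated`` share of homologs; numeric pool entries become
    ``OX=`` taxon annotations, others ``OS=`` names, so annotations survive
    an A3M round trip.
    """
    if spec.L < 1 or spec.N < 1:
        raise ValueError("L and N must be positive")
    rng = np.random.default_rng(spec.seed)
    query = _random_query(rng, spec.L)
    records = [SeqRecord(id="query", aligned_seq=query, description="synthetic query")]
    n_homologs = spec.N - 1
    n_annotated = math.ceil(spec.fraction_annotated * n_homologs)
    for idx in range(n_homologs):
        level = spec.identity_levels[idx % len(spec.identity_levels)]
        if level == 1.0:
            k = 0
        else:
            k = max(1, round((1.0 - level) * spec.L))
            achieved = 1.0 - k / spec.L
            if abs(achieved - level) > 0.02:
                raise ValueError(
                    f"identity level {level} infeasible for L={spec.L} "
                    f"(closest achievable {achieved:.3f})"
                )
        seq = _mutate(rng, query, k)
        species = None
        desc = f"synthetic homolog level={level}"
        if spec.species_pool and idx < n_annotated:
            species = spec.species_pool[idx % len(spec.species_pool)]
            tag = f"OX={species}" if species.isdigit() else f"OS={species}"
            desc = f"{desc} {tag}"
        records.append(
            SeqRecord(id=f"h{idx + 1}", aligned_seq=seq, description=desc, species_key=species)
        )
    return Msa(records)


def diverse_msa(n_rows: int, L: int, seed: int) -> Msa:
    """An alignment of ``n_rows`` mutually diverse rows (all pairwise
    identities far below 0.8), so Neff equals ``n_rows / sqrt(L)``."""
    return make_msa(FixtureSpec(seed=seed, L=L, N=n_rows, identity_levels=(0.5,)))


def msa_with_neff(target_neff: float, L: int = 16, seed: int = 0) -> Msa:
    """A diverse alignment whose Neff is ``round(target * sqrt(L)) / sqrt(L)``
    (equal to ``target_neff`` whenever ``target * sqrt(L)`` is integral)."""
    n_rows = max(1, round(target_neff * math.sqrt(L)))
    return diverse_msa(n_rows, L, seed)


# ---------------------------------------------------------------------------
# planted-coupling Potts alignments
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GibbsSettings:
    burn_in: int = 100
    thinning: int = 10
    seed: int = 0
    n_states: int = 20


@dataclass
class PottsFixture:
    """Alignment sampled from a Potts model with known coupled pairs."""

    msa: Msa
    planted_pairs: list
    sampler: GibbsSettings


def make_potts_msa(
    L: int,
    N: int,
    planted_pairs: Sequence[tuple],
    strength: float = 3.0,
    seed: int = 0,
    burn_in: int = 100,
    thinning: int = 10,
) -> PottsFixture:
    """Sample ``N`` sequences from a zero-field Potts model whose only
    couplings sit on the planted pairs.

    Each planted pair (i, j) gets a permutation coupling: a random
    bijection ``pi`` over the 20 amino-acid states with energy bonus
    ``strength`` whenever ``s_j == pi(s_i)``, which makes the pair strongly
    dependent while leaving its marginals uniform.  ``N`` independent
    chains are run in parallel for ``burn_in + thinning`` full Gibbs
    sweeps; the final state of each chain becomes one alignment row.
    """
    n_states = 20
    rng = np.random.default_rng(seed)
    pairs = []
    adjacency: dict = {site: [] for site in range(L)}
    for i, j in planted_pairs:
        if not (0 <= i < j < L):
            raise ValueError(f"planted pair ({i}, {j}) out of range for L={L}")
        pi = rng.permutation(n_states)
        J = np.zeros((n_states, n_states))
        J[np.arange(n_states), pi] = strength
        pairs.append((i, j, strength))
        adjacency[i].append((j, J, "row"))
        adjacency[j].append((i, J, "col"))

    states = rng.integers(0, n_states, size=(N, L))
    for _ in range(burn_in + thinning):
        for site in range(L):
            logits = np.zeros((N, n_states))
            for other, J, orient in adjacency[site]:
                s_other = states[:, other]
                if orient == "row":
                    logits += J[:, s_other].T
                else:
                    logits += J[s_other, :]
            gumbel = rng.gumbel(size=(N, n_states))
            states[:, site] = np.argmax(logits + gumbel, axis=1)

    letters = np.array(list(AA20))
    records = []
    for n in range(N):
        seq = "".join(letters[states[n]])
        rec_id = "query" if n == 0 else f"s{n}"
        records.append(SeqRecord(id=rec_id, aligned_seq=seq, description="potts sample"))
    return PottsFixture(
        msa=Msa(records),
        planted_pairs=pairs,
        sampler=GibbsSettings(burn_in=burn_in, thinning=thinning, seed=seed, n_states=n_states),
    )


# ---------------------------------------------------------------------------
# complex chain sets
# ---------------------------------------------------------------------------

def make_complex_fixture(
    stoich,
    species_overlap: Mapping[str, Mapping[str, int]],
    seed: int = 0,
    L: int = 16,
    candidates_per_chain: int = 1,
    n_unannotated: int = 0,
):
    """Per-chain candidate MSAs with controlled species sharing.

    ``species_overlap`` maps species key -> {chain id -> member count}.
    Homolog rows of a chain carry strictly decreasing identities to the
    query (one extra mutation per successive row), making the within-group
    identity ordering deterministic.  Returns ``(chain_set, expected)``
    where ``expected`` is the linked-row count the rank-matched rule must
    produce: the sum over species present in >= 2 chains of the smallest
    member count among those chains.

    Candidate rank scores decrease with candidate index so each chain's
    list is already sorted best-first.
    """
    rng = np.random.default_rng(seed)
    chain_set: dict = {}
    for cid, _ in stoich.chains:
        query = _random_query(rng, L)
        candidates = []
        for cand_idx in range(candidates_per_chain):
            records = [SeqRecord(id=f"{cid}_query", aligned_seq=query, description="chain query")]
            k = max(2, L // 4)
            for sp in sorted(species_overlap):
                count = species_overlap[sp].get(cid, 0)
                for member in range(count):
                    seq = _mutate(rng, query, min(k, L - 1))
                    tag = f"OX={sp}" if sp.isdigit() else f"OS={sp}"
                    records.append(
                        SeqRecord(
                            id=f"{cid}_{sp}_{member + 1}",
                            aligned_seq=seq,
                            description=f"member {tag}",
                            species_key=sp,
                        )
                    )
                    k += 1
            for extra in range(n_unannotated):
                seq = _mutate(rng, query, min(k, L - 1))
                records.append(
                    SeqRecord(id=f"{cid}_meta_{extra + 1}", aligned_seq=seq,
                              description="metagenome contig")
                )
                k += 1
            msa = Msa(records)
            candidates.append(
                CandidateMsa(
                    msa=msa,
                    block="dMSA",
                    stage=1,
                    neff=compute_neff(msa),
                    rank_score=round(max(0.05, 0.9 - 0.05 * cand_idx), 6),
                )
            )
        chain_set[cid] = candidates

    expected = 0
    for sp, members in species_overlap.items():
        present = [cid for cid, _ in stoich.chains if members.get(cid, 0) > 0]
        if len(present) >= 2:
            expected += min(members[cid] for cid in present)
    return chain_set, expected


# ---------------------------------------------------------------------------
# scripted backends, scorer and predictor
# ---------------------------------------------------------------------------

def saturating_confidence(neff_value: float, scale: float = 5.0) -> float:
    """Monotone map from effective-sequence count to a [0, 1) confidence."""
    return neff_value / (neff_value + scale)


class MockScorer:
    """Deterministic structure scorer: five confidences, the best of which
    is a saturating function of the MSA's Neff."""

    def __init__(self, scale: float = 5.0):
        self.scale = scale

    def score(self, msa: Msa) -> list:
        base = saturating_confidence(compute_neff(msa), self.scale)
        return [max(0.0, base - 0.02 * k) for k in range(5)]


class MockPredictor:
    """Deterministic complex predictor: predicted TM-scores saturate in the
    paired MSA's Neff and decay slightly with model index."""

    def __init__(self, scale: float = 5.0):
        self.scale = scale

    def predict(self, paired, count: int) -> list:
        base = saturating_confidence(paired.neff, self.scale)
        return [
            (f"model_{paired.component_choice}_{k}", base * (1.0 - 0.002 * k))
            for k in range(count)
        ]


class ScriptedSearchBackend:
    """Returns a fixed alignment regardless of query/seed."""

    def __init__(self, msa: Optional[Msa]):
        self._msa = msa

    def search(self, query, seed, stage):
        return self._msa


class FailingBackend:
    """Always raises; used to exercise partial-result handling."""

    def search(self, query, seed, stage):
        raise RuntimeError("scripted backend failure")


class ScriptedHitBackend:
    """Returns a fixed ranked raw-hit list."""

    def __init__(self, hits: Sequence[str]):
        self._hits = list(hits)

    def fetch_hits(self, query, seed, stage):
        return self._hits


class RecordingEnricher:
    """Returns a fixed alignment and records how many hits it received."""

    def __init__(self, msa: Optional[Msa]):
        self._msa = msa
        self.received_hit_counts: list = []

    def enrich(self, seed, hits, stage):
        self.received_hit_counts.append(len(hits))
        return self._msa


class ScriptedMmsaBackend:
    """Derives a fixed-Neff alignment for each seed it is given."""

    def __init__(self, target_neff: float, L: int = 16, seed: int = 0):
        self.target_neff = target_neff
        self.L = L
        self.seed = seed
        self._calls = 0

    def search(self, seed_msa, probe, stage):
        self._calls += 1
        return msa_with_neff(self.target_neff, L=self.L, seed=self.seed + self._calls)


def scripted_stages(
    stage_specs: Sequence[StageSpec],
    neff_targets: Sequence[float],
    L: int = 16,
    seed: int = 0,
) -> list:
    """Build direct-search pipeline stages that return alignments with the
    requested Neff values."""
    stages = []
    for idx, (spec, target) in enumerate(zip(stage_specs, neff_targets)):
        msa = msa_with_neff(target, L=L, seed=seed + 1000 * idx)
        stages.append(PipelineStage(spec=spec, backend=ScriptedSearchBackend(msa)))
    return stages


def scripted_monomer_backends(
    dmsa_neffs: Sequence[float],
    qmsa_neffs: Sequence[float],
    mmsa_neff: float = 60.0,
    L: int = 16,
    seed: int = 0,
) -> MonomerBackends:
    """Full mock wiring for a monomer run with prescribed per-stage Neffs."""
    return MonomerBackends(
        dmsa=scripted_stages(DMSA_STAGES, dmsa_neffs, L=L, seed=seed),
        qmsa=scripted_stages(QMSA_STAGES, qmsa_neffs, L=L, seed=seed + 7),
        mmsa=ScriptedMmsaBackend(mmsa_neff, L=L, seed=seed + 17),
    )
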