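"""Species-aware construction of multichain (paired) MSAs.

A complex is described by a stoichiometry string such as ``A2B2C1`` (two
copies of chain A, two of B, one of C).  For each distinct chain the
monomer pipeline supplies up to ten ranked candidate MSAs; pairing picks
the top ``M`` per chain, where ``M`` is the largest integer with
``M**N <= 100`` (``N`` distinct chains), so that all ``M**N`` combinations
stay affordable.

For heteromers each combination is turned into one concatenated MSA by
species linking: homologs of each chain are grouped by their UniProt
species annotation and sorted within a group by identity to the query;
rank-matched members of a species present in two or more chains are
concatenated side-by-side (chains missing that species contribute a gap
block), and every remaining homolog is appended below, gap-padded in all
other chains' columns, so no input row is lost.  Rows without a species
annotation — metagenomic hits — can never be linked and always end up in
the padded section.  Homomers skip linking entirely: every monomer MSA is
concatenated with itself once per copy.

Concatenated MSAs are ranked by the M-score,

    M = Neff(paired) * (sum_i n_i * pLDDT_i) / (sum_i n_i),

the paired alignment's effective-sequence count weighted by the
copy-number-weighted mean of the per-chain model confidences from the
monomer stage.  Heteromers keep the top 25 by M-score; homomers keep all
(up to ten) self-concatenations.  A pluggable complex predictor then
produces 25 scored models per kept MSA (625 for a heteromer, 250 for a
homomer) and the five best by predicted TM-score are returned.
"""

from __future__ import annotations

import itertools
import re
from dataclasses import dataclass, field
from typing import Mapping, Optional, Protocol, Sequence

from .errors import StoichiometryError
from .msa_io import Msa, SeqRecord
from .msa_stats import neff as compute_neff
from .msa_stats import seq_identity
from .monomer import CandidateMsa

DEFAULT_PAIRING_BUDGET = 100
DEFAULT_AVAILABLE_PER_CHAIN = 10
DEFAULT_KEEP_HETEROMER = 25
DEFAULT_MODELS_PER_MSA = 25
DEFAULT_FINAL_MODELS = 5

_STOICH_TOKEN = re.compile(r"([A-Za-z])(\d+)")


@dataclass(frozen=True)
class Stoichiometry:
    """Parsed complex composition: ordered (chain id, copy count) pairs."""

    chains: tuple

    def __post_init__(self) -> None:
        ids = [c for c, _ in self.chains]
        if len(ids) != len(set(ids)):
            raise StoichiometryError("duplicate chain identifiers")
        if any(n < 1 for _, n in self.chains):
            raise StoichiometryError("copy counts must be positive")

    @property
    def N(self) -> int:
        """Number of distinct chains."""
        return len(self.chains)

    @property
    def is_homomer(self) -> bool:
        return self.N == 1 and self.chains[0][1] >= 2

    @property
    def chain_ids(self) -> tuple:
        return tuple(c for c, _ in self.chains)

    @property
    def copies(self) -> dict:
        return dict(self.chains)

    @property
    def total_chains(self) -> int:
        return sum(n for _, n in self.chains)

    def format(self) -> str:
        return "".join(f"{c}{n}" for c, n in self.chains)


def parse_stoichiometry(s: str) -> Stoichiometry:
    """Parse a stoichiometry string like ``A2B2C1``.

    Raises :class:`StoichiometryError` with the offending position on
    malformed input.
    """
    if not s:
        raise StoichiometryError("empty stoichiometry string")
    chains = []
    pos = 0
    while pos < len(s):
        m = _STOICH_TOKEN.match(s, pos)
        if not m:
            raise StoichiometryError(
                f"malformed stoichiometry {s!r} at position {pos}: "
                "expected letter followed by digits"
            )
        chains.append((m.group(1), int(m.group(2))))
        pos = m.end()
    return Stoichiometry(tuple(chains))


def pairing_depth(
    N: int,
    budget: int = DEFAULT_PAIRING_BUDGET,
    available: int = DEFAULT_AVAILABLE_PER_CHAIN,
) -> int:
    """Largest per-chain MSA count ``M`` with ``M**N <= budget``.

    Capped by the number of candidate MSAs available per chain; never
    below 1.
    """
    if N < 1:
        raise ValueError("N must be at least 1")
    m = 1
    while (m + 1) ** N <= budget:
        m += 1
    return max(1, min(m, available))


def enumerate_pairings(chain_set: Mapping[str, Sequence[CandidateMsa]], M: int) -> list:
    """All per-chain candidate index tuples, lexicographic over rank indices.

    When some chain offers fewer than ``M`` candidates, ``M`` is lowered to
    the minimum available so the enumeration stays rectangular.
    """
    if not chain_set:
        return []
    m_eff = min(M, min(len(v) for v in chain_set.values()))
    if m_eff < 1:
        raise ValueError("every chain needs at least one candidate MSA")
    return list(itertools.product(range(m_eff), repeat=len(chain_set)))


@dataclass
class PairedMsa:
    """A concatenated multichain MSA with provenance and ranking state."""

    msa: Msa
    component_choice: tuple
    linked_rows: int
    neff: float
    m_score: Optional[float] = None
    chain_spans: list = field(default_factory=list)


def _grouped_homologs(msa: Msa):
    """Group homolog rows by species, sorted within a group by identity to
    the query (descending, stable); also return unannotated rows in identity
    order."""
    scored = []
    for idx, rec in enumerate(msa.homologs):
        scored.append((-seq_identity(msa.query, rec), idx, rec))
    scored.sort()
    groups: dict = {}
    unannotated = []
    for _, _, rec in scored:
        if rec.species_key is None:
            unannotated.append(rec)
        else:
            groups.setdefault(rec.species_key, []).append(rec)
    return groups, unannotated


def _gap_block(length: int) -> str:
    return "-" * length


def link_heteromer(
    choice: Mapping[str, Msa],
    stoich: Stoichiometry,
    component_choice: tuple = (),
    link_depth: Optional[int] = None,
) -> PairedMsa:
    """Concatenate one monomer MSA per distinct chain into a paired MSA.

    Linking follows the species rule described in the module docstring;
    ``link_depth`` optionally caps how many rank-matched rows each shared
    species may contribute (``None`` links down to the smallest group).
    Chain blocks are repeated per copy count; every input homolog appears
    exactly once in the output (linked or gap-padded below), and insertions
    are dropped so all rows share the concatenated match-column system.
    """
    for cid in stoich.chain_ids:
        if cid not in choice:
            raise ValueError(f"no monomer MSA supplied for chain {cid!r}")
    lengths = {cid: choice[cid].L for cid in stoich.chain_ids}
    copies = stoich.copies

    grouped: dict = {}
    unannotated: dict = {}
    for cid in stoich.chain_ids:
        grouped[cid], unannotated[cid] = _grouped_homologs(choice[cid])

    def paste(parts: Mapping[str, str]) -> str:
        return "".join(parts[cid] * copies[cid] for cid in stoich.chain_ids)

    rows = [
        SeqRecord(
            id="query",
            aligned_seq=paste({cid: choice[cid].query.match_columns for cid in stoich.chain_ids}),
            description="concatenated query",
        )
    ]

    # species shared by >= 2 chains get rank-matched linked rows
    species_order = sorted({s for g in grouped.values() for s in g})
    consumed: dict = {cid: set() for cid in stoich.chain_ids}
    linked = 0
    for sp in species_order:
        members = [cid for cid in stoich.chain_ids if sp in grouped[cid]]
        if len(members) < 2:
            continue
        depth = min(len(grouped[cid][sp]) for cid in members)
        if link_depth is not None:
            depth = min(depth, link_depth)
        for rank in range(depth):
            parts = {}
            ids = []
            for cid in stoich.chain_ids:
                if cid in members:
                    rec = grouped[cid][sp][rank]
                    parts[cid] = rec.match_columns
                    consumed[cid].add(id(rec))
                    ids.append(rec.id)
                else:
                    parts[cid] = _gap_block(lengths[cid])
            rows.append(
                SeqRecord(
                    id="|".join(ids),
                    aligned_seq=paste(parts),
                    description=f"linked species={sp} rank={rank + 1}",
                    species_key=sp,
                )
            )
            linked += 1

    # every unconsumed homolog goes below, gap-padded in the other chains
    for cid in stoich.chain_ids:
        leftovers = []
        for sp in sorted(grouped[cid]):
            leftovers.extend(r for r in grouped[cid][sp] if id(r) not in consumed[cid])
        leftovers.extend(unannotated[cid])
        # keep identity order within the chain
        order = {id(r): i for i, (_, _, r) in enumerate(
            sorted((-seq_identity(choice[cid].query, r), i, r) for i, r in enumerate(choice[cid].homologs))
        )}
        leftovers.sort(key=lambda r: order[id(r)])
        for rec in leftovers:
            parts = {
                other: rec.match_columns if other == cid else _gap_block(lengths[other])
                for other in stoich.chain_ids
            }
            rows.append(
                SeqRecord(
                    id=rec.id,
                    aligned_seq=paste(parts),
                    description=f"unlinked chain={cid}",
                    species_key=rec.species_key,
                )
            )

    msa = Msa(rows)
    spans = []
    offset = 0
    for cid in stoich.chain_ids:
        for copy in range(copies[cid]):
            spans.append({"chain": cid, "copy": copy, "start": offset, "stop": offset + lengths[cid]})
            offset += lengths[cid]
    return PairedMsa(
        msa=msa,
        component_choice=tuple(component_choice),
        linked_rows=linked,
        neff=compute_neff(msa),
        chain_spans=spans,
    )


def concat_homomer(msa: Msa, copies: int, component_choice: tuple = ()) -> PairedMsa:
    """Self-concatenate a monomer MSA ``copies`` times side-by-side."""
    if copies < 2:
        raise ValueError("a homomer needs at least two copies")
    rows = [
        SeqRecord(
            id=rec.id,
            aligned_seq=rec.aligned_seq * copies,
            description=rec.description,
            species_key=rec.species_key,
        )
        for rec in msa.records
    ]
    paired = Msa(rows)
    spans = [
        {"chain": "A", "copy": k, "start": k * msa.L, "stop": (k + 1) * msa.L}
        for k in range(copies)
    ]
    return PairedMsa(
        msa=paired,
        component_choice=tuple(component_choice),
        linked_rows=paired.N - 1,
        neff=compute_neff(paired),
        chain_spans=spans,
    )


def m_score(paired: PairedMsa, chain_plddts: Mapping[str, float], stoich: Stoichiometry) -> float:
    """Effective-sequence count of the paired MSA times the copy-weighted
    mean per-chain model confidence."""
    num = 0.0
    den = 0
    for cid, n in stoich.chains:
        p = chain_plddts[cid]
        if not 0.0 <= p <= 1.0:
            raise ValueError(f"pLDDT for chain {cid!r} outside [0, 1]")
        num += n * p
        den += n
    return paired.neff * num / den


def select_paired(
    paired_list: Sequence[PairedMsa],
    stoich: Stoichiometry,
    k_het: int = DEFAULT_KEEP_HETEROMER,
) -> list:
    """Keep the top ``k_het`` heteromer MSAs by M-score (ties broken by
    component choice); homomer self-concatenations pass through unfiltered."""
    if stoich.is_homomer:
        return list(paired_list)
    ranked = sorted(paired_list, key=lambda p: (-(p.m_score or 0.0), p.component_choice))
    return ranked[:k_het]


class ComplexPredictor(Protocol):
    """Returns ``count`` (model, predicted-TM) pairs for a paired MSA."""

    def predict(self, paired: PairedMsa, count: int) -> Sequence[tuple]:
        ...


@dataclass(frozen=True)
class ComplexModel:
    """One predicted complex model with its provenance."""

    model: object
    predicted_tm: float
    msa_index: int
    component_choice: tuple


@dataclass
class MultimerResult:
    models: list
    n_generated: int
    paired_msas: list
    diagnostics: list = field(default_factory=list)


def build_paired_candidates(
    chain_set: Mapping[str, Sequence[CandidateMsa]],
    stoich: Stoichiometry,
    budget: int = DEFAULT_PAIRING_BUDGET,
    link_depth: Optional[int] = None,
) -> list:
    """Enumerate, link and M-score all paired MSAs for a complex.

    For homomers this is the list of self-concatenations of every candidate
    MSA of the single chain; for heteromers, the full ``M**N`` enumeration
    of linked combinations with the per-chain confidence entering the
    M-score taken from each chosen candidate's rank score.
    """
    if stoich.is_homomer:
        cid, copies = stoich.chains[0]
        out = []
        for idx, cand in enumerate(chain_set[cid]):
            paired = concat_homomer(cand.msa, copies, component_choice=(idx,))
            paired.m_score = m_score(paired, {cid: cand.rank_score or 0.0}, stoich)
            out.append(paired)
        return out
    available = min(len(chain_set[cid]) for cid in stoich.chain_ids)
    M = pairing_depth(stoich.N, budget=budget, available=available)
    out = []
    for combo in enumerate_pairings({cid: chain_set[cid] for cid in stoich.chain_ids}, M):
        choice = {
            cid: chain_set[cid][idx].msa for cid, idx in zip(stoich.chain_ids, combo)
        }
        paired = link_heteromer(choice, stoich, component_choice=combo, link_depth=link_depth)
        plddts = {
            cid: chain_set[cid][idx].rank_score or 0.0
            for cid, idx in zip(stoich.chain_ids, combo)
        }
        paired.m_score = m_score(paired, plddts, stoich)
        out.append(paired)
    return out


def run_multimer(
    chain_set: Mapping[str, Sequence[CandidateMsa]],
    stoich: Stoichiometry,
    predictor: ComplexPredictor,
    models_per_msa: int = DEFAULT_MODELS_PER_MSA,
    final_k: int = DEFAULT_FINAL_MODELS,
    k_het: int = DEFAULT_KEEP_HETEROMER,
    budget: int = DEFAULT_PAIRING_BUDGET,
) -> MultimerResult:
    """Full multimer orchestration: pair, link, select, predict, rank.

    Generates ``models_per_msa`` models per selected MSA (25 selected for a
    heteromer, all self-concatenations for a homomer), ranks everything by
    predicted TM-score and returns the ``final_k`` best with provenance.
    A predictor failure on one MSA skips that MSA with a diagnostic.
    """
    candidates = build_paired_candidates(chain_set, stoich, budget=budget)
    selected = select_paired(candidates, stoich, k_het=k_het)
    models = []
    diagnostics = []
    for msa_index, paired in enumerate(selected):
        try:
            preds = list(predictor.predict(paired, models_per_msa))
        except Exception as exc:
            diagnostics.append(f"predictor failed on MSA {msa_index}: {exc}")
            continue
        for model, tm in preds:
            models.append(
                ComplexModel(
                    model=model,
                    predicted_tm=float(tm),
                    msa_index=msa_index,
                    component_choice=paired.component_choice,
                )
            )
    models.sort(key=lambda m: (-m.predicted_tm, m.msa_index, m.component_choice))
    return MultimerResult(
        models=models[:final_k],
        n_generated=len(models),
        paired_msas=selected,
        diagnostics=diagnostics,
    )
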