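"""Staged monomer MSA search orchestration.

Three blocks of iterative homology search are coordinated here:

* **dMSA** — three stages: a profile search of a clustered genomic
  database, then two rounds in which raw hits from a broader database are
  clustered/realigned into a custom profile database that is searched again
  starting from the previous stage's alignment.
* **qMSA** — four stages over progressively larger genomic and metagenomic
  databases, with the same hit-enrichment pattern from stage 2 on.
* **mMSA** — the deepest available qMSA alignment probes a combined
  metagenomic database once; the resulting hit database is then searched
  with up to three seed alignments (dMSA stage 2, qMSA stages 2 and 3) to
  derive up to three further MSAs.

Each block stops early as soon as a stage's alignment exceeds the
effective-sequence threshold (strictly ``Neff > 128`` by default), on the
rationale that further, more expensive searches add little once the
alignment is diverse enough.  A ranking filter caps the raw hits entering
cluster-based enrichment at 30,000 (the "BLAST filter").  The mMSA block is
skipped entirely when both dMSA and qMSA early-stopped at their first
stage, i.e. genomic databases alone already produced diverse alignments.

The external tools behind each stage (HHblits, Jackhmmer, HMMsearch,
kClust, Clustal Omega, PSIBLAST) are abstracted as pluggable backend
contracts; the orchestrator owns only the control flow, the hit cap and the
stop rule.  Final selection feeds every candidate MSA to a pluggable
structure scorer returning five model-confidence values; the best of the
five becomes the MSA's rank score and the top-ranked MSA wins, with ties
broken by higher Neff and then by block/stage order.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional, Protocol, Sequence

from .errors import BackendError
from .msa_io import Msa, query_only_msa
from .msa_stats import neff as compute_neff

DEFAULT_NEFF_STOP = 128.0
DEFAULT_BLAST_KEEP = 30_000

#: Deterministic ordering of blocks for tie-breaking.
BLOCK_ORDER = {"dMSA": 0, "qMSA": 1, "mMSA": 2}

#: Fixed ordering of mMSA seed alignments.
MMSA_SEED_ORDER = ("dmsa_stage2", "qmsa_stage2", "qmsa_stage3")


@dataclass(frozen=True)
class StageSpec:
    """Declarative description of one search stage.

    ``parameter_string`` is an opaque preset passed verbatim to the backend;
    the orchestrator never interprets it.
    """

    block: str
    stage_index: int
    tool_label: str
    database_label: str
    parameter_string: str = ""

    def __post_init__(self) -> None:
        limits = {"dMSA": 3, "qMSA": 4, "mMSA": 3}
        if self.block not in limits:
            raise ValueError(f"unknown block {self.block!r}")
        if not 1 <= self.stage_index <= limits[self.block]:
            raise ValueError(
                f"stage {self.stage_index} out of range for block {self.block}"
            )


#: Verbatim stage presets for the three blocks.
DMSA_STAGES = (
    StageSpec("dMSA", 1, "hhblits2", "Uniclust30", "-diff inf -id 99 -cov 50 -n 3"),
    StageSpec("dMSA", 2, "jackhmmer", "Uniref90", "-N 3 -E 10 --incE 1e-3"),
    StageSpec("dMSA", 3, "hmmsearch", "Metaclust", "-E 10 --incE 1e-3"),
)

QMSA_STAGES = (
    StageSpec("qMSA", 1, "hhblits2", "UniRef30", "-diff inf -id 99 -cov 50 -n 3"),
    StageSpec("qMSA", 2, "jackhmmer", "Uniref90", "-N 3 -E 10 --incE 1e-3"),
    StageSpec("qMSA", 3, "hhblits3", "BFD", "-diff inf -id 99 -cov 40 -n 3 -e 1"),
    StageSpec("qMSA", 4, "hmmsearch", "Mgnify", "-E 10 --incE 1e-3"),
)

MMSA_PROBE_STAGE = StageSpec(
    "mMSA", 1, "hmmsearch", "JGIclust+TaraDB+MetaSourceDB", "-E 10 --incE 1e-3"
)


class SearchBackend(Protocol):
    """Direct profile search: query (plus optional seed MSA) to MSA."""

    def search(self, query: str, seed: Optional[Msa], stage: StageSpec) -> Optional[Msa]:
        ...


class HitBackend(Protocol):
    """Raw-hit retrieval; hits come back already ranked best-first."""

    def fetch_hits(self, query: str, seed: Optional[Msa], stage: StageSpec) -> Sequence[str]:
        ...


class Enricher(Protocol):
    """Cluster/realign raw hits into a custom profile database and search it
    starting from the seed alignment."""

    def enrich(self, seed: Optional[Msa], hits: Sequence[str], stage: StageSpec) -> Optional[Msa]:
        ...


class MmsaBackend(Protocol):
    """Build the metagenomic hit database from the probe alignment, then
    search it with a seed alignment."""

    def search(self, seed: Msa, probe: Msa, stage: StageSpec) -> Optional[Msa]:
        ...


class StructureScorer(Protocol):
    """Returns exactly five model-confidence values in [0, 1] for an MSA."""

    def score(self, msa: Msa) -> Sequence[float]:
        ...


@dataclass
class PipelineStage:
    """One executable stage: either a direct search backend, or a raw-hit
    backend paired with an enricher (the hit cap applies to the latter)."""

    spec: StageSpec
    backend: Optional[SearchBackend] = None
    hit_backend: Optional[HitBackend] = None
    enricher: Optional[Enricher] = None

    def __post_init__(self) -> None:
        direct = self.backend is not None
        enriched = self.hit_backend is not None and self.enricher is not None
        if direct == enriched:
            raise ValueError(
                "a stage needs either a direct search backend or a "
                "hit backend plus enricher"
            )


@dataclass
class CandidateMsa:
    """An MSA plus provenance and ranking state."""

    msa: Msa
    block: str
    stage: int
    neff: float
    rank_score: Optional[float] = None

    @property
    def label(self) -> str:
        return f"{self.block}-{self.stage}"

    def sort_key(self):
        return (BLOCK_ORDER[self.block], self.stage)


@dataclass
class BlockResult(Sequence):
    """Candidates produced by one block, plus bookkeeping.

    Behaves as a sequence of :class:`CandidateMsa` so callers that only care
    about the MSAs can treat it as a plain list.
    """

    block: str
    candidates: list = field(default_factory=list)
    stage_msas: dict = field(default_factory=dict)
    stopped_by_neff_at: Optional[int] = None
    diagnostics: list = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.candidates)

    def __getitem__(self, idx):
        return self.candidates[idx]


def _run_block(
    query: str,
    stages: Sequence[PipelineStage],
    block: str,
    neff_stop: float,
    blast_keep: int,
) -> BlockResult:
    result = BlockResult(block=block)
    seed: Optional[Msa] = None
    for stage in stages:
        spec = stage.spec
        try:
            if stage.backend is not None:
                msa = stage.backend.search(query, seed, spec)
            else:
                hits = list(stage.hit_backend.fetch_hits(query, seed, spec))
                # ranking filter: only the top hits reach clustering
                hits = hits[:blast_keep]
                msa = stage.enricher.enrich(seed, hits, spec)
        except Exception as exc:  # backend failure -> partial result
            result.diagnostics.append(f"{block} stage {spec.stage_index} failed: {exc}")
            break
        if msa is None or msa.N == 0:
            if spec.stage_index == 1:
                msa = query_only_msa("query", query)
            else:
                result.diagnostics.append(
                    f"{block} stage {spec.stage_index} returned no alignment"
                )
                break
        nf = compute_neff(msa)
        result.candidates.append(CandidateMsa(msa=msa, block=block, stage=spec.stage_index, neff=nf))
        result.stage_msas[spec.stage_index] = msa
        seed = msa
        if nf > neff_stop:
            result.stopped_by_neff_at = spec.stage_index
            break
    return result


def run_dmsa(
    query: str,
    stages: Sequence[PipelineStage],
    neff_stop: float = DEFAULT_NEFF_STOP,
    blast_keep: int = DEFAULT_BLAST_KEEP,
) -> BlockResult:
    """Run the three-stage dMSA block; halts after the first stage whose
    alignment exceeds ``neff_stop`` (strict comparison)."""
    if len(stages) > 3:
        raise ValueError("dMSA has at most three stages")
    return _run_block(query, stages, "dMSA", neff_stop, blast_keep)


def run_qmsa(
    query: str,
    stages: Sequence[PipelineStage],
    neff_stop: float = DEFAULT_NEFF_STOP,
    blast_keep: int = DEFAULT_BLAST_KEEP,
) -> BlockResult:
    """Run the four-stage qMSA block with the same stop rule as dMSA."""
    if len(stages) > 4:
        raise ValueError("qMSA has at most four stages")
    return _run_block(query, stages, "qMSA", neff_stop, blast_keep)


def run_mmsa(
    seeds: Mapping[str, Optional[Msa]],
    probe: Optional[Msa],
    backend: MmsaBackend,
) -> BlockResult:
    """Derive up to three metagenomic MSAs, one per available seed.

    ``seeds`` maps the fixed seed labels (``dmsa_stage2``, ``qmsa_stage2``,
    ``qmsa_stage3``) to alignments; absent seeds are skipped.  The probe
    alignment defines the hit database the seeds are searched against.
    """
    result = BlockResult(block="mMSA")
    if probe is None:
        result.diagnostics.append("mMSA skipped: no probe alignment available")
        return result
    stage_idx = 0
    for label in MMSA_SEED_ORDER:
        seed = seeds.get(label)
        if seed is None:
            continue
        stage_idx += 1
        spec = StageSpec("mMSA", stage_idx, "hhblits2", "mMSA-hitdb", "")
        try:
            msa = backend.search(seed, probe, spec)
        except Exception as exc:
            result.diagnostics.append(f"mMSA seed {label} failed: {exc}")
            continue
        if msa is None or msa.N == 0:
            result.diagnostics.append(f"mMSA seed {label} returned no alignment")
            continue
        result.candidates.append(
            CandidateMsa(msa=msa, block="mMSA", stage=stage_idx, neff=compute_neff(msa))
        )
        result.stage_msas[stage_idx] = msa
    return result


@dataclass
class MonomerBackends:
    """Backend wiring for a full monomer run."""

    dmsa: Sequence[PipelineStage]
    qmsa: Sequence[PipelineStage]
    mmsa: Optional[MmsaBackend] = None


@dataclass
class MonomerConfig:
    neff_stop: float = DEFAULT_NEFF_STOP
    blast_keep: int = DEFAULT_BLAST_KEEP


def generate_candidates(
    query: str,
    backends: MonomerBackends,
    config: MonomerConfig = MonomerConfig(),
) -> list:
    """Run dMSA, qMSA and (when warranted) mMSA; return up to ten candidates.

    mMSA is skipped when both dMSA and qMSA early-stopped at stage 1, since
    genomic databases alone then already produced diverse alignments.
    """
    d = run_dmsa(query, backends.dmsa, config.neff_stop, config.blast_keep)
    q = run_qmsa(query, backends.qmsa, config.neff_stop, config.blast_keep)
    candidates = list(d.candidates) + list(q.candidates)
    both_stopped_at_1 = d.stopped_by_neff_at == 1 and q.stopped_by_neff_at == 1
    if backends.mmsa is not None and not both_stopped_at_1:
        seeds = {
            "dmsa_stage2": d.stage_msas.get(2),
            "qmsa_stage2": q.stage_msas.get(2),
            "qmsa_stage3": q.stage_msas.get(3),
        }
        # probe: the deepest qMSA alignment available (stage 3 preferred)
        probe = q.stage_msas.get(3)
        if probe is None and q.stage_msas:
            probe = q.stage_msas[max(q.stage_msas)]
        m = run_mmsa(seeds, probe, backends.mmsa)
        candidates.extend(m.candidates)
    return candidates


def rank_and_select(candidates: Sequence[CandidateMsa], scorer: StructureScorer) -> CandidateMsa:
    """Score every candidate with five structure models and return the best.

    Each candidate's rank score is the maximum of its five model-confidence
    values; ties are broken by higher Neff, then earlier block/stage order.
    """
    if not candidates:
        raise ValueError("cannot select from an empty candidate list")
    for cand in candidates:
        scores = list(scorer.score(cand.msa))
        if len(scores) != 5:
            raise BackendError(
                f"structure scorer returned {len(scores)} values, expected 5"
            )
        if any(not 0.0 <= s <= 1.0 for s in scores):
            raise BackendError("model confidence values must lie in [0, 1]")
        cand.rank_score = max(scores)
    return min(
        candidates,
        key=lambda c: (-c.rank_score, -c.neff, BLOCK_ORDER[c.block], c.stage),
    )
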