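"""Alignment diversity and depth statistics.

The central quantity is the number of effective sequences,

    Neff = (1/sqrt(L)) * sum_n 1 / (1 + sum_{m != n} I[S_mn >= t]),

a diversity-weighted, length-normalised row count: each row is discounted
by the number of other rows at least ``t`` (default 0.8) identical to it,
and the sum is scaled by ``1/sqrt(L)``.  When all rows are mutually diverse
(every off-diagonal identity below the threshold) the value is exactly
``N / sqrt(L)``; inverting this gives the rough minimum number of diverse
sequences needed to reach a diversity cutoff, ``N_min = cutoff * sqrt(L)``.

Pairwise identity ``S_mn`` is computed over query match columns only:
matching residues divided by the number of columns where both rows are
non-gap (zero when the rows share no aligned column).  This symmetric,
terminal-gap-insensitive convention is the one standard filtering tools
use; the query row counts as an ordinary row of the MSA.

Coverage is the mean, over homologs (query excluded), of the fraction of
query columns a row aligns; per-site depth counts the homologs aligned at
each query column.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional

import numpy as np

from .errors import UndefinedStatisticError
from .msa_io import GAP_STATE, Msa, SeqRecord, to_match_matrix

DEFAULT_IDENTITY_THRESHOLD = 0.8


def _identity_from_states(a: np.ndarray, b: np.ndarray) -> float:
    both = (a != GAP_STATE) & (b != GAP_STATE)
    denom = int(both.sum())
    if denom == 0:
        return 0.0
    return float(((a == b) & both).sum()) / denom


def seq_identity(a: SeqRecord, b: SeqRecord, context: Optional[Msa] = None) -> float:
    """Sequence identity between two aligned rows over match columns.

    Identical residues divided by mutually non-gap match columns; 0.0 when
    the rows have no aligned column in common.  Symmetric by construction.
    """
    if context is not None:
        for rec in (a, b):
            if rec not in context.records:
                raise ValueError(f"record {rec.id!r} does not belong to the given MSA")
    sa, sb = a.match_columns, b.match_columns
    if len(sa) != len(sb):
        raise ValueError("records live on different coordinate systems")
    arr_a = np.frombuffer(sa.encode("latin-1"), dtype=np.uint8)
    arr_b = np.frombuffer(sb.encode("latin-1"), dtype=np.uint8)
    gap = ord("-")
    both = (arr_a != gap) & (arr_b != gap)
    denom = int(both.sum())
    if denom == 0:
        return 0.0
    return float(((arr_a == arr_b) & both).sum()) / denom


def pairwise_identity_matrix(states: np.ndarray, chunk: int = 256) -> np.ndarray:
    """All-vs-all identity matrix for an ``N x L`` state matrix.

    Processed in row chunks to bound memory on deep alignments.
    """
    n = states.shape[0]
    nongap = states != GAP_STATE
    out = np.zeros((n, n))
    for start in range(0, n, chunk):
        stop = min(start + chunk, n)
        a = states[start:stop, None, :]
        both = nongap[start:stop, None, :] & nongap[None, :, :]
        num = ((a == states[None, :, :]) & both).sum(axis=-1)
        denom = both.sum(axis=-1)
        out[start:stop] = np.where(denom > 0, num / np.maximum(denom, 1), 0.0)
    return out


def neff(msa: Msa, identity_threshold: float = DEFAULT_IDENTITY_THRESHOLD) -> float:
    """Number of effective sequences of the alignment.

    All rows, query included, participate; the redundancy test uses ``>=``
    on the identity threshold.
    """
    states = to_match_matrix(msa)
    sim = pairwise_identity_matrix(states)
    redundant = sim >= identity_threshold
    # exclude the self term m == n
    np.fill_diagonal(redundant, False)
    weights = 1.0 / (1.0 + redundant.sum(axis=1))
    return float(weights.sum() / math.sqrt(msa.L))


def min_diverse_sequences(neff_cut: float, L: int) -> float:
    """Rough minimum count of mutually diverse sequences needed to reach a
    target effective-sequence cutoff: ``neff_cut * sqrt(L)``."""
    if neff_cut < 0:
        raise ValueError("neff_cut must be nonnegative")
    if L < 1:
        raise ValueError("L must be at least 1")
    return neff_cut * math.sqrt(L)


def coverage(msa: Msa) -> float:
    """Mean fraction of query columns aligned, over homologs (query excluded)."""
    if msa.N < 2:
        raise UndefinedStatisticError("coverage needs at least one homolog")
    states = to_match_matrix(msa)[1:]
    return float((states != GAP_STATE).mean())


def per_site_depth(msa: Msa) -> np.ndarray:
    """Number of homologs (query excluded) aligned at each query column."""
    if msa.N < 2:
        return np.zeros(msa.L, dtype=np.int64)
    states = to_match_matrix(msa)[1:]
    return (states != GAP_STATE).sum(axis=0).astype(np.int64)


@dataclass(frozen=True)
class MsaStats:
    """Bundle of per-MSA summary statistics."""

    neff: float
    coverage: float
    n_sequences: int
    length: int
    per_site_depth: np.ndarray
    mean_identity: float

    def to_dict(self) -> dict:
        return {
            "neff": self.neff,
            "coverage": self.coverage,
            "n_sequences": self.n_sequences,
            "length": self.length,
            "mean_identity": self.mean_identity,
            "per_site_depth": self.per_site_depth.tolist(),
        }


def compute_stats(msa: Msa, identity_threshold: float = DEFAULT_IDENTITY_THRESHOLD) -> MsaStats:
    """Compute Neff, coverage, depth and mean identity-to-query in one pass.

    Requires at least one homolog (coverage is undefined for a query-only
    alignment).  ``mean_identity`` averages each homolog's identity to the
    query row.
    """
    if msa.N < 2:
        raise UndefinedStatisticError("statistics need at least one homolog")
    states = to_match_matrix(msa)
    sim = pairwise_identity_matrix(states)
    redundant = sim >= identity_threshold
    np.fill_diagonal(redundant, False)
    nf = float((1.0 / (1.0 + redundant.sum(axis=1))).sum() / math.sqrt(msa.L))
    nongap = states[1:] != GAP_STATE
    return MsaStats(
        neff=nf,
        coverage=float(nongap.mean()),
        n_sequences=msa.N,
        length=msa.L,
        per_site_depth=nongap.sum(axis=0).astype(np.int64),
        mean_identity=float(sim[0, 1:].mean()),
    )
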