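"""MSA-derived coevolution features: mutual information and Potts couplings.

Two complementary pair features are extracted from an alignment encoded
over the 22-state alphabet (20 amino acids, unknown, gap):

* **Mutual information.**  With plug-in column frequencies ``f_i(k)`` and
  pair frequencies ``f_ij(k,l)``,

      M_ij(k,l) = f_ij(k,l) * ln( f_ij(k,l) / (f_i(k) f_j(l)) ),

  with ``0 * ln 0 := 0`` and natural logarithms (nats).  The summed matrix
  ``sum_kl M_ij(k,l)`` is the usual column-pair MI: symmetric, nonnegative,
  and zero whenever either column is constant.

* **Pseudolikelihood-maximised Potts model.**  Fields ``h_i(q)`` and
  couplings ``P_ij(q,q')`` minimise the negative log-pseudolikelihood

      L = - sum_i sum_n ln p(s_n^i | s_n^{-i}; h, P)
          + lambda_single * ||h||_2^2 + lambda_pair * ||P||_2^2,

  where the conditional at site i is the softmax over the 22 states of
  ``h_i(q) + sum_{j != i} P_ij(q, s_n^j)``.  Defaults follow the standard
  regularisation choice ``lambda_single = 1`` and
  ``lambda_pair = 0.2 * (L - 1)``.  Rows are weighted uniformly (no
  identity-based reweighting) by default.  The couplings are fitted
  asymmetrically and symmetrised afterwards as ``(P_ij + P_ji^T) / 2``.

Scalar contact scores are the Frobenius norms of the 21x21 non-gap blocks
of the symmetrised couplings, optionally with the average-product
correction (APC) subtracting ``rowmean_i * rowmean_j / grandmean``.

Distance-map evaluation utilities round out the module: converting
distogram bin probabilities to a point estimate (midpoint of the
highest-probability bin) and the mean absolute error of the top ``5L``
long-range (sequence separation >= 24) predicted distances against an
experimental Cbeta-Cbeta distance set.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Optional, Sequence

import numpy as np
from scipy.optimize import minimize
from scipy.special import logsumexp, softmax

from .errors import UndefinedStatisticError
from .msa_io import GAP_STATE, NUM_STATES, Msa, to_match_matrix

DEFAULT_LAMBDA_SINGLE = 1.0
DEFAULT_MIN_SEPARATION = 24
DEFAULT_TOP_MULTIPLIER = 5


def default_lambda_pair(L: int) -> float:
    return 0.2 * (L - 1)


# ---------------------------------------------------------------------------
# frequencies and mutual information
# ---------------------------------------------------------------------------

def _one_hot(matrix: np.ndarray, Q: int = NUM_STATES) -> np.ndarray:
    n, L = matrix.shape
    X = np.zeros((n, L, Q))
    X[np.arange(n)[:, None], np.arange(L)[None, :], matrix] = 1.0
    return X


def frequencies(matrix: np.ndarray, pseudocount: float = 0.0):
    """Empirical single-site and pairwise state frequencies.

    Returns ``(f_i, f_ij)`` of shapes ``(L, Q)`` and ``(L, L, Q, Q)``; each
    ``f_i`` row and each ``f_ij`` block sums to one.  An optional
    pseudocount is added to every cell before normalisation.
    """
    if matrix.ndim != 2 or matrix.shape[0] == 0:
        raise ValueError("need a nonempty N x L state matrix")
    if matrix.max() >= NUM_STATES:
        raise ValueError("states must lie in 0..21")
    n, L = matrix.shape
    X = _one_hot(matrix)
    Xf = X.reshape(n, L * NUM_STATES)
    counts_i = X.sum(axis=0) + pseudocount
    f_i = counts_i / counts_i.sum(axis=1, keepdims=True)
    counts_ij = (Xf.T @ Xf).reshape(L, NUM_STATES, L, NUM_STATES).transpose(0, 2, 1, 3)
    counts_ij = counts_ij + pseudocount
    f_ij = counts_ij / counts_ij.sum(axis=(2, 3), keepdims=True)
    return f_i, f_ij


@dataclass
class MiResult:
    """Per-pair MI tensor and its state-summed L x L matrix.

    Diagonal entries of ``summed`` are the column entropies
    (self-information) and should be ignored for contact ranking.
    """

    per_pair_tensor: np.ndarray
    summed: np.ndarray


def mutual_information(msa: Msa, pseudocount: float = 0.0) -> MiResult:
    """Mutual information between all column pairs of the alignment.

    Gap and unknown states participate as ordinary states; values are in
    nats.
    """
    matrix = to_match_matrix(msa)
    f_i, f_ij = frequencies(matrix, pseudocount)
    indep = f_i[:, None, :, None] * f_i[None, :, None, :]
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where(f_ij > 0, f_ij / np.where(indep > 0, indep, 1.0), 1.0)
        tensor = np.where(f_ij > 0, f_ij * np.log(ratio), 0.0)
    return MiResult(per_pair_tensor=tensor, summed=tensor.sum(axis=(2, 3)))


# ---------------------------------------------------------------------------
# pseudolikelihood Potts model
# ---------------------------------------------------------------------------

@dataclass
class PottsModel:
    """Fields ``h`` (L x Q) and couplings ``P`` (L x L x Q x Q).

    Diagonal coupling blocks are identically zero; after fitting, ``P`` is
    symmetric under ``(i, j, q, q') <-> (j, i, q', q)`` up to numerical
    tolerance.
    """

    h: np.ndarray
    P: np.ndarray
    Q: int = NUM_STATES
    lambda_single: float = DEFAULT_LAMBDA_SINGLE
    lambda_pair: float = 0.0
    converged: bool = True

    @classmethod
    def zeros(cls, L: int, Q: int = NUM_STATES, lambda_single: float = DEFAULT_LAMBDA_SINGLE,
              lambda_pair: Optional[float] = None) -> "PottsModel":
        if lambda_pair is None:
            lambda_pair = default_lambda_pair(L)
        return cls(
            h=np.zeros((L, Q)),
            P=np.zeros((L, L, Q, Q)),
            Q=Q,
            lambda_single=lambda_single,
            lambda_pair=lambda_pair,
        )

    @property
    def L(self) -> int:
        return self.h.shape[0]

    def symmetrized(self) -> "PottsModel":
        P_sym = 0.5 * (self.P + self.P.transpose(1, 0, 3, 2))
        return PottsModel(
            h=self.h.copy(), P=P_sym, Q=self.Q,
            lambda_single=self.lambda_single, lambda_pair=self.lambda_pair,
            converged=self.converged,
        )


def _masked_P(P: np.ndarray) -> np.ndarray:
    out = P.copy()
    L = P.shape[0]
    out[np.arange(L), np.arange(L)] = 0.0
    return out


def plm_loss_grad(model: PottsModel, matrix: np.ndarray):
    """Negative log-pseudolikelihood plus L2 penalties, with gradients.

    Returns ``(loss, (grad_h, grad_P))`` where the gradients match the
    model's array shapes.  Diagonal coupling blocks are excluded from both
    the conditional energies and the penalty, so their gradient is zero.
    """
    n, L = matrix.shape
    Q = model.Q
    if model.h.shape != (L, Q) or model.P.shape != (L, L, Q, Q):
        raise ValueError("model shapes inconsistent with the data matrix")
    X = _one_hot(matrix, Q)
    Xf = X.reshape(n, L * Q)
    P = _masked_P(model.P)
    Pmat = P.transpose(0, 2, 1, 3).reshape(L * Q, L * Q)
    logits = (model.h.reshape(1, L * Q) + Xf @ Pmat.T).reshape(n, L, Q)
    lse = logsumexp(logits, axis=2)
    observed = (logits * X).sum(axis=2)
    data_loss = float((lse - observed).sum())
    reg_loss = model.lambda_single * float((model.h ** 2).sum()) + \
        model.lambda_pair * float((P ** 2).sum())

    probs = softmax(logits, axis=2)
    D = (probs - X).reshape(n, L * Q)
    grad_h = D.sum(axis=0).reshape(L, Q) + 2.0 * model.lambda_single * model.h
    grad_P = (D.T @ Xf).reshape(L, Q, L, Q).transpose(0, 2, 1, 3)
    grad_P = _masked_P(grad_P) + 2.0 * model.lambda_pair * P
    return data_loss + reg_loss, (grad_h, grad_P)


@dataclass
class PlmConfig:
    """Optimiser settings for the pseudolikelihood fit.

    Quasi-Newton (L-BFGS) from a zero initialisation, with a projected
    gradient tolerance and iteration cap; regularisation strengths default
    to ``lambda_single = 1`` and ``lambda_pair = 0.2 * (L - 1)``.
    """

    max_iter: int = 200
    grad_tol: float = 1e-4
    lambda_single: float = DEFAULT_LAMBDA_SINGLE
    lambda_pair: Optional[float] = None


def plm_fit(msa: Msa, config: PlmConfig = PlmConfig()) -> PottsModel:
    """Fit the Potts model to an alignment by pseudolikelihood maximisation.

    Deterministic for fixed input: zero initialisation and a deterministic
    quasi-Newton path.  Couplings are symmetrised after optimisation.  If
    the iteration budget is exhausted before the gradient tolerance is met
    the model is returned with ``converged=False``.
    """
    matrix = to_match_matrix(msa)
    n, L = matrix.shape
    Q = NUM_STATES
    lam_pair = config.lambda_pair if config.lambda_pair is not None else default_lambda_pair(L)
    n_h = L * Q

    def unpack(x: np.ndarray) -> PottsModel:
        return PottsModel(
            h=x[:n_h].reshape(L, Q),
            P=x[n_h:].reshape(L, L, Q, Q),
            Q=Q,
            lambda_single=config.lambda_single,
            lambda_pair=lam_pair,
        )

    def objective(x: np.ndarray):
        model = unpack(x)
        loss, (gh, gP) = plm_loss_grad(model, matrix)
        return loss, np.concatenate([gh.ravel(), gP.ravel()])

    x0 = np.zeros(n_h + L * L * Q * Q)
    res = minimize(
        objective, x0, jac=True, method="L-BFGS-B",
        options={"maxiter": config.max_iter, "gtol": config.grad_tol},
    )
    fitted = unpack(res.x)
    fitted.P = _masked_P(fitted.P)
    fitted.converged = bool(res.success)
    return fitted.symmetrized()


# ---------------------------------------------------------------------------
# contact scores
# ---------------------------------------------------------------------------

def apc(scores: np.ndarray) -> np.ndarray:
    """Average-product correction: subtract ``rowmean_i * rowmean_j / mean``.

    Means are taken over the full matrix, so an exactly rank-one input maps
    to (numerically) zero.
    """
    row = scores.mean(axis=1)
    grand = scores.mean()
    if grand == 0:
        return scores.copy()
    return scores - np.outer(row, row) / grand


def coupling_scores(model: PottsModel, use_apc: bool = True) -> np.ndarray:
    """Frobenius norms of the non-gap 21x21 coupling blocks, optionally APC
    corrected; symmetric with a zero diagonal."""
    P = model.symmetrized().P
    sub = P[:, :, :GAP_STATE, :GAP_STATE]
    norms = np.sqrt((sub ** 2).sum(axis=(2, 3)))
    np.fill_diagonal(norms, 0.0)
    if use_apc:
        norms = apc(norms)
        np.fill_diagonal(norms, 0.0)
    return norms


def top_contacts(
    scores: np.ndarray,
    count: int,
    min_separation: int = DEFAULT_MIN_SEPARATION,
) -> list:
    """The ``count`` highest-scoring residue pairs with sequence separation
    ``|i - j| >= min_separation`` (0-based indices, i < j), descending, ties
    broken by (i, j); fewer eligible pairs are returned as-is."""
    L = scores.shape[0]
    pairs = [
        (float(scores[i, j]), i, j)
        for i in range(L)
        for j in range(i + min_separation, L)
    ]
    pairs.sort(key=lambda t: (-t[0], t[1], t[2]))
    return [(i, j, s) for s, i, j in pairs[:count]]


# ---------------------------------------------------------------------------
# distance-map evaluation
# ---------------------------------------------------------------------------

@dataclass
class DistanceSet:
    """Residue-pair distances in Angstroms, 0-based indices with i < j."""

    pairs: list
    kind: str = "predicted"
    bin_scheme: Optional[list] = None

    def __post_init__(self) -> None:
        for i, j, v in self.pairs:
            if i >= j:
                raise ValueError(f"pair ({i}, {j}) must have i < j")
            if v <= 0:
                raise ValueError(f"distance for pair ({i}, {j}) must be positive")


def default_bin_scheme(n_bins: int = 36, lo: float = 2.0, hi: float = 20.0) -> list:
    """Equal-width distance bins over [lo, hi] plus an open last bin."""
    edges = np.linspace(lo, hi, n_bins + 1)
    scheme = [(float(a), float(b)) for a, b in zip(edges[:-1], edges[1:])]
    scheme.append((float(hi), math.inf))
    return scheme


def bin_midpoint_estimate(bin_probs: Sequence[float], bin_scheme: Sequence[tuple]) -> float:
    """Point distance estimate: midpoint of the highest-probability bin.

    Ties resolve to the first (shortest-distance) bin.  An open final bin
    reports its lower edge plus half the preceding bin's width.
    """
    probs = np.asarray(bin_probs, dtype=float)
    if len(probs) != len(bin_scheme):
        raise ValueError("probability vector and bin scheme disagree in length")
    if abs(probs.sum() - 1.0) > 1e-3:
        raise ValueError("bin probabilities must sum to approximately 1")
    k = int(np.argmax(probs))
    lo, hi = bin_scheme[k]
    if math.isinf(hi):
        if k == 0:
            raise ValueError("an open bin needs a preceding closed bin")
        prev_lo, prev_hi = bin_scheme[k - 1]
        return lo + 0.5 * (prev_hi - prev_lo)
    return 0.5 * (lo + hi)


def mae_top_long_range(
    pred: DistanceSet,
    exp: DistanceSet,
    length: int,
    multiplier: int = DEFAULT_TOP_MULTIPLIER,
    min_separation: int = DEFAULT_MIN_SEPARATION,
    selector: Optional[Callable] = None,
) -> float:
    """Mean absolute error of the top ``multiplier * length`` long-range
    predicted distances against the experimental set.

    ``selector`` orders the predicted pairs by the predictor's confidence;
    by default the input order of ``pred.pairs`` is taken as that ranking.
    Pairs without an experimental distance are excluded and the divisor
    reduced accordingly; zero eligible pairs raise
    :class:`UndefinedStatisticError`.
    """
    ordered = list(selector(pred.pairs)) if selector is not None else list(pred.pairs)
    eligible = [(i, j, v) for i, j, v in ordered if j - i >= min_separation]
    top = eligible[: multiplier * length]
    exp_map = {(i, j): v for i, j, v in exp.pairs}
    errors = [abs(v - exp_map[(i, j)]) for i, j, v in top if (i, j) in exp_map]
    if not errors:
        raise UndefinedStatisticError("no long-range pair with experimental distance")
    return float(np.mean(errors))
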