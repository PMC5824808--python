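"""Copy-number substitution model and tree likelihood.

Each allele at each locus evolves as a birth-death Markov chain on copy
states 0..K with per-copy event rates: gains at ``rho * lambda * c``,
losses at ``(1 - rho) * lambda * c``; state 0 is absorbing. The unaltered
ancestor sits at state 1 per allele at ``root_age`` and a stem branch
connects it to the sample MRCA. Genome doubling enters as an independent
irreversible binary character with its own rate.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import scipy.linalg

from .._tree import Node, Phylogeny
from ..profiles_io import GenomeGrid, SampleMeta, SegmentProfile, ValidationError
from ..ploidy_gd import GD_THRESHOLD, sample_ploidy

NA_STATE = -1
DEFAULT_K = 4


# ---------------------------------------------------------------------------
# data container
# ---------------------------------------------------------------------------


@dataclass
class CNMatrix:
    """Per-(sample, locus, allele) integer copy states with sampling ages."""

    sample_ids: list[str]
    ages: np.ndarray  # (n,) sampling age in years
    states: np.ndarray  # (n, n_loci, 2) in 0..K, NA_STATE for missing
    K: int = DEFAULT_K
    gd: Optional[np.ndarray] = None  # (n,) bool genome-doubling flags

    def __post_init__(self):
        self.ages = np.asarray(self.ages, dtype=float)
        self.states = np.asarray(self.states, dtype=np.int64)
        n = len(self.sample_ids)
        if self.ages.shape != (n,) or self.states.shape[0] != n:
            raise ValidationError("CNMatrix dimensions inconsistent")
        if np.any(self.ages <= 0):
            raise ValidationError("sampling ages must be positive")
        valid = (self.states == NA_STATE) | (
            (self.states >= 0) & (self.states <= self.K)
        )
        if not valid.all():
            raise ValidationError(f"copy states must lie in 0..{self.K} or NA")
        if self.gd is not None:
            self.gd = np.asarray(self.gd, dtype=bool)
            if self.gd.shape != (n,):
                raise ValidationError("gd flags shape mismatch")

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_loci(self) -> int:
        return self.states.shape[1]

    def characters(self) -> np.ndarray:
        """(n, 2 * n_loci) flattened per-allele characters."""
        return self.states.reshape(self.n_samples, -1)


def cn_matrix_from_profiles(profiles: Sequence[SegmentProfile],
                            metas: Sequence[SampleMeta], grid: GenomeGrid,
                            K: int = DEFAULT_K,
                            gd_threshold: float = GD_THRESHOLD) -> CNMatrix:
    """Build a CNMatrix on the shared grid; GD samples are flagged and their
    allele states halved (rounded to nearest) before capping at K."""
    age_by_id = {m.sample_id: m.sampling_age_years for m in metas}
    sample_ids, ages, rows, gd = [], [], [], []
    for p in sorted(profiles, key=lambda p: p.sample_id):
        if p.sample_id not in age_by_id:
            raise ValidationError(f"sample {p.sample_id}: no metadata")
        states = p.states_on_grid(grid).astype(float)
        doubled = sample_ploidy(p) > gd_threshold
        if doubled:
            covered = states >= 0
            states[covered] = np.rint(states[covered] / 2.0)
        states = np.where(states < 0, NA_STATE, np.minimum(states, K)).astype(np.int64)
        sample_ids.append(p.sample_id)
        ages.append(age_by_id[p.sample_id])
        rows.append(states)
        gd.append(doubled)
    return CNMatrix(sample_ids, np.array(ages), np.stack(rows), K=K,
                    gd=np.array(gd))


# ---------------------------------------------------------------------------
# generator and transition probabilities
# ---------------------------------------------------------------------------


def build_generator(K: int, lam: float, rho: float) -> np.ndarray:
    """Rate matrix over copy states 0..K; rows sum to zero, state 0 absorbing."""
    if K < 1:
        raise ValidationError("K must be >= 1")
    if not 0.0 <= rho <= 1.0:
        raise ValidationError("rho must lie in [0, 1]")
    if lam < 0:
        raise ValidationError("lambda must be non-negative")
    Q = np.zeros((K + 1, K + 1))
    for c in range(1, K + 1):
        if c < K:
            Q[c, c + 1] = rho * lam * c
        Q[c, c - 1] = (1.0 - rho) * lam * c
        Q[c, c] = -Q[c].sum()
    return Q


def transition_probs(generator: np.ndarray, elapsed: float) -> np.ndarray:
    """Matrix exponential of ``generator * elapsed`` (a stochastic matrix)."""
    if elapsed < 0:
        raise ValidationError("elapsed time must be non-negative")
    P = scipy.linalg.expm(generator * elapsed)
    return np.clip(P, 0.0, 1.0)


class _Propagator:
    """Eigendecomposition of the unit-rate generator, reused across branches.

    The generator factorizes as ``lambda * M(rho)``; M is tridiagonal with
    positive off-diagonals (similar to a symmetric matrix), so its
    eigenvalues are real and ``P(s) = V exp(D s) V^-1`` is numerically
    safe for the small K used here.
    """

    def __init__(self, K: int, rho: float):
        M = build_generator(K, 1.0, rho)
        w, V = scipy.linalg.eig(M)
        self.w = w.real
        self.V = V.real
        self.Vinv = scipy.linalg.inv(self.V)

    def matrices(self, s: np.ndarray) -> np.ndarray:
        """(len(s), K+1, K+1) transition matrices for substitution times s."""
        E = np.exp(np.outer(s, self.w))
        P = np.einsum("ij,bj,jk->bik", self.V, E, self.Vinv)
        return np.clip(P, 0.0, 1.0)


# ---------------------------------------------------------------------------
# clock state
# ---------------------------------------------------------------------------


@dataclass
class ClockState:
    """Parameters of the copy-number clock.

    ``rlc_indicators``/``rlc_multipliers`` align with the postorder
    sequence of non-root nodes of ``tree``; the effective rate of a branch
    is ``lam`` times the product of multipliers of active branches on the
    root-to-branch path (inclusive).
    """

    lam: float
    rho: float
    ne_tau: float
    root_age: float
    gd_rate: float = 0.0
    tree: Optional[Phylogeny] = None
    rlc_indicators: Optional[np.ndarray] = None
    rlc_multipliers: Optional[np.ndarray] = None

    def validate(self) -> None:
        if self.lam <= 0:
            raise ValidationError("lambda must be positive")
        if not 0.0 <= self.rho <= 1.0:
            raise ValidationError("rho must lie in [0, 1]")
        if self.ne_tau <= 0:
            raise ValidationError("Ne_tau must be positive")
        if self.rlc_multipliers is not None and np.any(
            np.asarray(self.rlc_multipliers) <= 0
        ):
            raise ValidationError("rate multipliers must be positive")


# ---------------------------------------------------------------------------
# pruning likelihood
# ---------------------------------------------------------------------------


def _node_ages(tree: Phylogeny, tip_ages: dict[str, float]) -> dict[Node, float]:
    """Node ages (years since patient birth) from tip ages and branch lengths."""
    ages: dict[Node, float] = {}
    for node in tree.postorder():
        if node.is_leaf:
            if node.label not in tip_ages:
                raise ValidationError(f"tip {node.label!r} not in CN matrix")
            ages[node] = tip_ages[node.label]
        else:
            candidates = [ages[c] - (c.length or 0.0) for c in node.children]
            if max(candidates) - min(candidates) > 1e-6:
                raise ValidationError("branch lengths inconsistent with tip ages")
            ages[node] = candidates[0]
    return ages


def _branch_rates(tree: Phylogeny, lam: float,
                  indicators: Optional[np.ndarray],
                  multipliers: Optional[np.ndarray]) -> dict[Node, float]:
    non_root = [n for n in tree.postorder() if n is not tree.root]
    if indicators is None:
        return {n: lam for n in non_root}
    indicators = np.asarray(indicators)
    multipliers = np.asarray(multipliers, dtype=float)
    if len(indicators) != len(non_root) or len(multipliers) != len(non_root):
        raise ValidationError("RLC vectors must have one entry per non-root branch")
    own = {
        n: multipliers[i] if indicators[i] else 1.0 for i, n in enumerate(non_root)
    }
    rates: dict[Node, float] = {}
    for node in tree.preorder():
        if node is tree.root:
            continue
        parent_rate = rates.get(node.parent, lam)
        rates[node] = parent_rate * own[node]
    return rates


def _gd_log_likelihood(tree: Phylogeny, ages: dict[Node, float],
                       gd_flags: dict[str, bool], gd_rate: float,
                       root_age: float) -> float:
    """Irreversible binary character: 0 -> 1 at gd_rate, rooted at 0."""
    partials: dict[Node, np.ndarray] = {}
    for node in tree.postorder():
        if node.is_leaf:
            state = 1 if gd_flags[node.label] else 0
            vec = np.zeros(2)
            vec[state] = 1.0
            partials[node] = vec
        else:
            acc = np.ones(2)
            for c in node.children:
                dt = ages[c] - ages[node]
                decay = np.exp(-gd_rate * dt)
                P = np.array([[decay, 1.0 - decay], [0.0, 1.0]])
                acc = acc * (P @ partials[c])
            partials[node] = acc
    stem = ages[tree.root] - root_age
    decay = np.exp(-gd_rate * stem)
    lik = decay * partials[tree.root][0] + (1.0 - decay) * partials[tree.root][1]
    return float(np.log(lik)) if lik > 0 else -np.inf


def tree_log_likelihood(tree: Phylogeny, cn: CNMatrix, state: ClockState) -> float:
    """Felsenstein pruning over loci x alleles plus the GD overlay.

    Branch lengths of ``tree`` are calendar years; the root connects to
    the unaltered ancestor (state 1 per allele) at ``state.root_age`` via
    a stem evolving at the base rate. NA tip states marginalize out.
    """
    state.validate()
    tip_ages = dict(zip(cn.sample_ids, cn.ages))
    ages = _node_ages(tree, tip_ages)
    if ages[tree.root] < state.root_age - 1e-9:
        raise ValidationError("root_age is younger than the sample MRCA")
    rates = _branch_rates(tree, state.lam, state.rlc_indicators,
                          state.rlc_multipliers)
    # expm (not the eigen fast path) keeps this reference implementation
    # accurate to ~1e-14 for oracle comparisons
    Q_unit = build_generator(cn.K, 1.0, state.rho)
    chars = cn.characters()  # (n, nchar)
    nchar = chars.shape[1]
    nstates = cn.K + 1
    row_of = {sid: i for i, sid in enumerate(cn.sample_ids)}

    partials: dict[Node, np.ndarray] = {}
    for node in tree.postorder():
        if node.is_leaf:
            obs = chars[row_of[node.label]]
            part = np.zeros((nchar, nstates))
            na = obs == NA_STATE
            part[na, :] = 1.0
            idx = np.where(~na)[0]
            part[idx, obs[idx]] = 1.0
            partials[node] = part
        else:
            acc = np.ones((nchar, nstates))
            for c in node.children:
                dt = ages[c] - ages[node]
                P = scipy.linalg.expm(Q_unit * (dt * rates[c]))
                acc = acc * (partials[c] @ P.T)
            partials[node] = acc

    stem_s = (ages[tree.root] - state.root_age) * state.lam
    P_stem = scipy.linalg.expm(Q_unit * stem_s)
    site_lik = partials[tree.root] @ P_stem[1]
    if np.any(site_lik <= 0):
        return -np.inf
    loglik = float(np.log(site_lik).sum())

    if cn.gd is not None:
        gd_flags = dict(zip(cn.sample_ids, cn.gd))
        loglik += _gd_log_likelihood(tree, ages, gd_flags, state.gd_rate,
                                     state.root_age)
    return loglik
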