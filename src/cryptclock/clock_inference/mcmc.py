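"""Metropolis-Hastings sampler for the copy-number clock.

The state is (lambda, rho, Ne_tau, root_age, gd_rate, time tree, RLC
indicators and multipliers). Scalar parameters mix through log/reflected
random walks plus occasional independent draws from their priors (the
latter make prior-only chains mix instantly and are harmless with data);
the tree mixes through uniform node-height slides and narrow exchange.
RLC dimension changes use a birth/death flip whose multiplier proposal is
the prior, so the Jacobian-free acceptance ratio is exact.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .._tree import Node, Phylogeny
from ..profiles_io import PosteriorTrace, ValidationError
from .model import NA_STATE, CNMatrix, _Propagator
from .priors import ClockConfig, coalescent_log_density, rlc_log_prior


# ---------------------------------------------------------------------------
# array-backed time tree
# ---------------------------------------------------------------------------


@dataclass
class _TimeTree:
    """Rooted binary tree over tips 0..n-1 (internal nodes n..2n-2).

    Ages are years since patient birth, increasing toward the present;
    every parent is older (smaller age) than its children.
    """

    parent: np.ndarray
    children: np.ndarray  # (2n-1, 2), -1 rows for tips
    age: np.ndarray
    n_tips: int
    root: int

    def postorder_internal(self) -> list[int]:
        order, stack = [], [self.root]
        while stack:
            v = stack.pop()
            if self.children[v, 0] >= 0:
                order.append(v)
                stack.extend(self.children[v])
        return order[::-1]

    def copy(self) -> "_TimeTree":
        return _TimeTree(self.parent.copy(), self.children.copy(),
                         self.age.copy(), self.n_tips, self.root)

    def check(self) -> bool:
        for v in range(len(self.parent)):
            p = self.parent[v]
            if p >= 0 and self.age[v] < self.age[p]:
                return False
        return True


def _initial_tree(ages: np.ndarray, depth_budget: float) -> _TimeTree:
    """Deterministic ladder tree: joins tips newest-first with small steps so
    the MRCA stays within ``depth_budget`` years of the earliest tip."""
    n = len(ages)
    total = 2 * n - 1
    parent = np.full(total, -1, dtype=np.int64)
    children = np.full((total, 2), -1, dtype=np.int64)
    age = np.zeros(total)
    age[:n] = ages
    step = depth_budget / (n + 1)
    order = sorted(range(n), key=lambda i: -ages[i])
    current = order[0]
    current_age = ages[order[0]]
    nxt = n
    for tip in order[1:]:
        current_age = min(current_age, ages[tip]) - step
        children[nxt] = (current, tip)
        parent[current] = parent[tip] = nxt
        age[nxt] = current_age
        current = nxt
        nxt += 1
    return _TimeTree(parent, children, age, n, current)


# ---------------------------------------------------------------------------
# likelihood on the array tree
# ---------------------------------------------------------------------------


class _Likelihood:
    def __init__(self, cn: CNMatrix):
        chars = cn.characters()
        self.nchar = chars.shape[1]
        self.K = cn.K
        self.nstates = cn.K + 1
        n = cn.n_samples
        self.tip_partials = np.zeros((n, self.nchar, self.nstates))
        for i in range(n):
            na = chars[i] == NA_STATE
            self.tip_partials[i, na, :] = 1.0
            idx = np.where(~na)[0]
            self.tip_partials[i, idx, chars[i, idx]] = 1.0
        self.gd = cn.gd
        self._eig_rho = None
        self._eig = None

    def _propagator(self, rho: float) -> _Propagator:
        if self._eig_rho != rho:
            self._eig = _Propagator(self.K, rho)
            self._eig_rho = rho
        return self._eig

    def branch_rates(self, tt: _TimeTree, lam: float,
                     indicators: np.ndarray | None,
                     multipliers: np.ndarray | None) -> np.ndarray:
        rates = np.full(len(tt.parent), lam)
        if indicators is None or not indicators.any():
            return rates
        for v in reversed(tt.postorder_internal()):  # preorder
            for c in tt.children[v]:
                rates[c] = rates[v] * (multipliers[c] if indicators[c] else 1.0)
        # tips hanging directly off the root are covered above via root's children
        return rates

    def __call__(self, tt: _TimeTree, lam: float, rho: float, root_age: float,
                 gd_rate: float, indicators=None, multipliers=None) -> float:
        if self.nchar == 0 and self.gd is None:
            return 0.0
        rates = self.branch_rates(tt, lam, indicators, multipliers)
        loglik = 0.0
        if self.nchar:
            prop = self._propagator(rho)
            elapsed = tt.age - tt.age[tt.parent]
            elapsed[tt.root] = tt.age[tt.root] - root_age
            s = elapsed * rates
            s[tt.root] = elapsed[tt.root] * lam  # stem runs at the base rate
            P = prop.matrices(s)
            partials = np.empty((len(tt.parent), self.nchar, self.nstates))
            partials[: tt.n_tips] = self.tip_partials
            for v in tt.postorder_internal():
                c1, c2 = tt.children[v]
                partials[v] = (partials[c1] @ P[c1].T) * (partials[c2] @ P[c2].T)
            site = partials[tt.root] @ P[tt.root][1]
            if np.any(site <= 0):
                return -np.inf
            loglik += float(np.log(site).sum())
        if self.gd is not None:
            loglik += self._gd_loglik(tt, gd_rate, root_age)
        return loglik

    def _gd_loglik(self, tt: _TimeTree, gd_rate: float, root_age: float) -> float:
        part = np.zeros((len(tt.parent), 2))
        part[: tt.n_tips, 0] = ~self.gd
        part[: tt.n_tips, 1] = self.gd
        elapsed = tt.age - tt.age[tt.parent]
        elapsed[tt.root] = tt.age[tt.root] - root_age
        decay = np.exp(-gd_rate * elapsed)
        for v in tt.postorder_internal():
            acc = 1.0
            for c in tt.children[v]:
                msg0 = decay[c] * part[c, 0] + (1 - decay[c]) * part[c, 1]
                acc = acc * np.array([msg0, part[c, 1]])
            part[v] = acc
        d = decay[tt.root]
        lik = d * part[tt.root, 0] + (1 - d) * part[tt.root, 1]
        return float(np.log(lik)) if lik > 0 else -np.inf


# ---------------------------------------------------------------------------
# the sampler
# ---------------------------------------------------------------------------


def _log_coalescent(tt: _TimeTree, ne: float) -> float:
    return coalescent_log_density(tt.age[: tt.n_tips], tt.age[tt.n_tips :], ne)


def _snapshot(tt: _TimeTree, sample_ids, rates: np.ndarray,
              indicators: np.ndarray | None, root_age: float) -> Phylogeny:
    nodes = {}
    for v in range(len(tt.parent)):
        node = Node(sample_ids[v] if v < tt.n_tips else None)
        p = tt.parent[v]
        node.length = float(tt.age[v] - tt.age[p]) if p >= 0 else float(
            tt.age[v] - root_age
        )
        node.annotations["rate"] = float(rates[v])
        if indicators is not None:
            node.annotations["shift"] = int(indicators[v])
        nodes[v] = node
    for v in range(len(tt.parent)):
        if tt.parent[v] >= 0:
            nodes[tt.parent[v]].add_child(nodes[v])
    return Phylogeny(nodes[tt.root])


def mcmc_run(cn: CNMatrix, config: ClockConfig, seed: int
             ) -> tuple[PosteriorTrace, list[Phylogeny]]:
    """Sample the clock posterior; reproducible given ``seed``.

    Returns the scalar-parameter trace (burn-in removed) and the retained
    tree samples. Per-move acceptance rates are attached to the trace as
    ``trace.acceptance_rates``.
    """
    config.validate()
    if cn.n_samples < 3:
        raise ValidationError("mcmc_run needs at least 3 samples")
    rng = np.random.default_rng(seed)
    lik = _Likelihood(cn)
    n = cn.n_samples
    nb_nodes = 2 * n - 1
    rlc = config.mode == "rlc"
    with_gd = cn.gd is not None

    min_age = float(cn.ages.min())
    ra_lo = min_age - config.root_age_window_years
    ra_hi = min_age
    llam_lo, llam_hi = (math.log(b) for b in config.lambda_bounds)
    lne_lo, lne_hi = (math.log(b) for b in config.ne_bounds)
    lgd_lo, lgd_hi = (math.log(b) for b in config.gd_rate_bounds)

    tt = _initial_tree(cn.ages, config.root_age_window_years / 2.0)
    loglam = 0.5 * (llam_lo + llam_hi)
    rho = 0.5
    logne = 0.5 * (lne_lo + lne_hi)
    loggd = 0.5 * (lgd_lo + lgd_hi)
    root_age = max(ra_lo + 1e-6, tt.age[tt.root] - 1.0)
    indicators = np.zeros(nb_nodes, dtype=bool) if rlc else None
    multipliers = np.ones(nb_nodes) if rlc else None

    def loglik_now():
        return lik(tt, math.exp(loglam), rho, root_age,
                   math.exp(loggd) if with_gd else 0.0, indicators, multipliers)

    def logrlc_now():
        if not rlc:
            return 0.0
        mask = np.ones(nb_nodes, dtype=bool)
        mask[tt.root] = False
        return rlc_log_prior(indicators[mask], multipliers[mask],
                             config.rlc_expected_changes, config.rlc_sigma)

    cur_ll = loglik_now()
    cur_coal = _log_coalescent(tt, math.exp(logne))
    cur_rlc = logrlc_now()

    moves = ["lambda", "lambda_prior", "rho", "rho_prior", "ne", "ne_prior",
             "root_age", "root_age_prior", "height", "tree_scale", "rate_tree",
             "rate_stem"]
    weights = [4, 1, 2, 1, 2, 1, 2, 1, 6, 3, 3, 3]
    if config.sample_topology and n >= 3:
        moves.append("exchange")
        weights.append(4)
    if rlc:
        moves += ["rlc_flip", "rlc_mult"]
        weights += [4, 3]
    if with_gd:
        moves += ["gd_rate"]
        weights += [1]
    weights = np.array(weights, dtype=float)
    weights /= weights.sum()
    accepted = {m: 0 for m in moves}
    proposed = {m: 0 for m in moves}

    records = []
    trees: list[Phylogeny] = []
    tree_thin = config.tree_thin or config.thin
    burnin_steps = int(config.n_steps * config.burnin_fraction)

    for step in range(config.n_steps):
        move = moves[int(rng.choice(len(moves), p=weights))]
        proposed[move] += 1
        accept = False

        if move in ("lambda", "lambda_prior"):
            new = (rng.uniform(llam_lo, llam_hi) if move == "lambda_prior"
                   else loglam + 0.8 * (rng.random() - 0.5))
            if llam_lo <= new <= llam_hi:
                old, loglam = loglam, new
                new_ll = loglik_now()
                if math.log(rng.random()) < new_ll - cur_ll:
                    cur_ll, accept = new_ll, True
                else:
                    loglam = old
        elif move in ("rho", "rho_prior"):
            if move == "rho_prior":
                new = rng.random()
            else:
                new = abs(rho + 0.2 * (rng.random() - 0.5))
                if new > 1.0:
                    new = 2.0 - new
            old, rho = rho, new
            new_ll = loglik_now()
            if math.log(rng.random()) < new_ll - cur_ll:
                cur_ll, accept = new_ll, True
            else:
                rho = old
        elif move in ("ne", "ne_prior"):
            new = (rng.uniform(lne_lo, lne_hi) if move == "ne_prior"
                   else logne + 1.2 * (rng.random() - 0.5))
            if lne_lo <= new <= lne_hi:
                new_coal = _log_coalescent(tt, math.exp(new))
                if math.log(rng.random()) < new_coal - cur_coal:
                    logne, cur_coal, accept = new, new_coal, True
        elif move in ("root_age", "root_age_prior"):
            new = (rng.uniform(ra_lo, ra_hi) if move == "root_age_prior"
                   else root_age + 8.0 * (rng.random() - 0.5))
            if ra_lo <= new <= ra_hi and new <= tt.age[tt.root]:
                old, root_age = root_age, new
                new_ll = loglik_now()
                if math.log(rng.random()) < new_ll - cur_ll:
                    cur_ll, accept = new_ll, True
                else:
                    root_age = old
        elif move == "height":
            v = int(rng.integers(n, nb_nodes))
            lower = root_age if v == tt.root else tt.age[tt.parent[v]]
            upper = tt.age[tt.children[v]].min()
            if upper > lower:
                old = tt.age[v]
                tt.age[v] = rng.uniform(lower, upper)
                new_ll = loglik_now()
                new_coal = _log_coalescent(tt, math.exp(logne))
                if math.log(rng.random()) < (new_ll - cur_ll) + (new_coal - cur_coal):
                    cur_ll, cur_coal, accept = new_ll, new_coal, True
                else:
                    tt.age[v] = old
        elif move == "rate_stem":
            # scale lambda up while shrinking the stem by the same factor:
            # walks along the shared-event ridge (Jacobians cancel exactly)
            m = math.exp(0.5 * (rng.random() - 0.5))
            new_loglam = loglam + math.log(m)
            new_ra = tt.age[tt.root] - (tt.age[tt.root] - root_age) / m
            if llam_lo <= new_loglam <= llam_hi and ra_lo <= new_ra <= ra_hi:
                old_ra, old_loglam = root_age, loglam
                root_age, loglam = new_ra, new_loglam
                new_ll = loglik_now()
                if math.log(rng.random()) < new_ll - cur_ll:
                    cur_ll, accept = new_ll, True
                else:
                    root_age, loglam = old_ra, old_loglam
        elif move in ("tree_scale", "rate_tree"):
            # scale backward times (from the latest tip) of all internal
            # nodes plus the onset age; "rate_tree" counter-scales lambda to
            # walk along the rate x time ridge
            m = math.exp(0.15 * (rng.random() - 0.5))
            ref = float(cn.ages.max())
            old_age = tt.age.copy()
            old_ra, old_loglam = root_age, loglam
            tt.age[n:] = ref - m * (ref - tt.age[n:])
            new_ra = ref - m * (ref - root_age)
            ok = ra_lo <= new_ra <= ra_hi and tt.check()
            if ok:
                root_age = new_ra
                k = (n - 1) + 1  # scaled variables
                log_hastings = k * math.log(m)
                if move == "rate_tree":
                    new_loglam = loglam - math.log(m)
                    if llam_lo <= new_loglam <= llam_hi:
                        loglam = new_loglam
                        log_hastings -= math.log(m)
                    else:
                        ok = False
            if ok:
                new_ll = loglik_now()
                new_coal = _log_coalescent(tt, math.exp(logne))
                delta = (new_ll - cur_ll) + (new_coal - cur_coal) + log_hastings
                if math.log(rng.random()) < delta:
                    cur_ll, cur_coal, accept = new_ll, new_coal, True
            if not accept:
                tt.age = old_age
                root_age, loglam = old_ra, old_loglam
        elif move == "exchange":
            eligible = [v for v in range(nb_nodes)
                        if tt.parent[v] >= 0 and tt.parent[tt.parent[v]] >= 0]
            v = int(rng.choice(eligible))
            p = tt.parent[v]
            g = tt.parent[p]
            u = tt.children[g][tt.children[g] != p][0]
            if tt.age[u] >= tt.age[p]:
                old_tt = tt.copy()
                ci = np.where(tt.children[p] == v)[0][0]
                cj = np.where(tt.children[g] == u)[0][0]
                tt.children[p, ci] = u
                tt.children[g, cj] = v
                tt.parent[u] = p
                tt.parent[v] = g
                new_ll = loglik_now()
                new_coal = _log_coalescent(tt, math.exp(logne))
                if math.log(rng.random()) < (new_ll - cur_ll) + (new_coal - cur_coal):
                    cur_ll, cur_coal, accept = new_ll, new_coal, True
                else:
                    tt = old_tt
        elif move == "rlc_flip":
            candidates = [v for v in range(nb_nodes) if v != tt.root]
            v = int(rng.choice(candidates))
            sigma = config.rlc_sigma
            if indicators[v]:
                old_mult = multipliers[v]
                indicators[v] = False
                multipliers[v] = 1.0
                logq = _lognorm_logpdf(old_mult, sigma)
                new_ll, new_rlc = loglik_now(), logrlc_now()
                delta = (new_ll - cur_ll) + (new_rlc - cur_rlc) + logq
                if math.log(rng.random()) < delta:
                    cur_ll, cur_rlc, accept = new_ll, new_rlc, True
                else:
                    indicators[v] = True
                    multipliers[v] = old_mult
            else:
                m = float(np.exp(rng.normal(0.0, sigma)))
                indicators[v] = True
                multipliers[v] = m
                logq = _lognorm_logpdf(m, sigma)
                new_ll, new_rlc = loglik_now(), logrlc_now()
                delta = (new_ll - cur_ll) + (new_rlc - cur_rlc) - logq
                if math.log(rng.random()) < delta:
                    cur_ll, cur_rlc, accept = new_ll, new_rlc, True
                else:
                    indicators[v] = False
                    multipliers[v] = 1.0
        elif move == "rlc_mult":
            active = np.where(indicators)[0]
            if len(active):
                v = int(rng.choice(active))
                old = multipliers[v]
                multipliers[v] = float(old * np.exp(0.6 * (rng.random() - 0.5)))
                new_ll, new_rlc = loglik_now(), logrlc_now()
                delta = (new_ll - cur_ll) + (new_rlc - cur_rlc)
                if math.log(rng.random()) < delta:
                    cur_ll, cur_rlc, accept = new_ll, new_rlc, True
                else:
                    multipliers[v] = old
        elif move == "gd_rate":
            new = loggd + 1.0 * (rng.random() - 0.5)
            if lgd_lo <= new <= lgd_hi:
                old, loggd = loggd, new
                new_ll = loglik_now()
                if math.log(rng.random()) < new_ll - cur_ll:
                    cur_ll, accept = new_ll, True
                else:
                    loggd = old

        if accept:
            accepted[move] += 1

        if step >= burnin_steps and (step - burnin_steps) % config.thin == 0:
            row = {
                "lambda": math.exp(loglam),
                "rho": rho,
                "ne_tau": math.exp(logne),
                "root_age": root_age,
                "t_mrca": float(tt.age[tt.root]),
                "n_rate_changes": int(indicators.sum()) if rlc else 0,
                "log_likelihood": cur_ll,
                "log_prior": cur_coal + cur_rlc,
                "log_posterior": cur_ll + cur_coal + cur_rlc,
            }
            if with_gd:
                row["gd_rate"] = math.exp(loggd)
            records.append(row)
        if step >= burnin_steps and (step - burnin_steps) % tree_thin == 0:
            rates = lik.branch_rates(tt, math.exp(loglam), indicators, multipliers)
            trees.append(_snapshot(tt, cn.sample_ids, rates, indicators, root_age))

    trace = PosteriorTrace(pd.DataFrame(records),
                           burnin_fraction=config.burnin_fraction,
                           thin=config.thin)
    trace.acceptance_rates = {
        m: accepted[m] / proposed[m] if proposed[m] else float("nan") for m in moves
    }
    return trace, trees


def _lognorm_logpdf(x: float, sigma: float) -> float:
    lx = math.log(x)
    return -0.5 * (lx / sigma) ** 2 - math.log(sigma * x) - 0.5 * math.log(2 * math.pi)
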