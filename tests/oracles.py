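"""Independent reference implementations used by unit and acceptance tests.

Everything here is deliberately naive (enumeration, closed forms, direct
Monte-Carlo) and shares no code with the package paths it checks.
"""

import itertools
import math

import numpy as np
import scipy.linalg

from cryptclock.clock_inference import build_generator


def brute_force_loglik(tree, cn, state) -> float:
    """Sum over all internal-node state assignments, per character."""
    K = cn.K
    nodes = list(tree.postorder())
    internals = [n for n in nodes if not n.is_leaf]
    tip_age = dict(zip(cn.sample_ids, cn.ages))
    ages = {}
    for n in nodes:
        if n.is_leaf:
            ages[n] = tip_age[n.label]
    for n in nodes:  # postorder: children aged before parents
        if not n.is_leaf:
            ages[n] = ages[n.children[0]] - (n.children[0].length or 0.0)
    Q = build_generator(K, state.lam, state.rho)
    P = {
        n: scipy.linalg.expm(Q * (ages[n] - ages[n.parent]))
        for n in nodes if n.parent is not None
    }
    P_stem = scipy.linalg.expm(Q * (ages[tree.root] - state.root_age))
    chars = cn.characters()
    row = {s: i for i, s in enumerate(cn.sample_ids)}
    total = 0.0
    for ch in range(chars.shape[1]):
        site = 0.0
        for assign in itertools.product(range(K + 1), repeat=len(internals)):
            st = dict(zip(internals, assign))
            for n in nodes:
                if n.is_leaf:
                    st[n] = chars[row[n.label], ch]
            p = P_stem[1, st[tree.root]]
            for n in nodes:
                if n.parent is not None:
                    p *= P[n][st[n.parent], st[n]]
            site += p
        total += math.log(site)
    return total


def gillespie_endpoint(start: int, K: int, lam: float, rho: float, t: float,
                       n_paths: int, rng: np.random.Generator) -> np.ndarray:
    """End states of n_paths birth-death chains run to time t (vectorized)."""
    states = np.full(n_paths, start, dtype=np.int64)
    clock = np.zeros(n_paths)
    active = np.ones(n_paths, dtype=bool)
    while active.any():
        s = states[active]
        gain = rho * lam * s * (s < K)
        loss = (1 - rho) * lam * s
        total = gain + loss
        stuck = total <= 0
        wait = np.full(len(s), np.inf)
        nz = ~stuck
        wait[nz] = rng.exponential(1.0 / total[nz])
        clock_a = clock[active] + wait
        done = clock_a >= t
        # events for paths still inside the window
        move = ~done
        if move.any():
            u = rng.random(int(move.sum()))
            go_up = u < (gain[move] / total[move])
            delta = np.where(go_up, 1, -1)
            s[move] += delta
        states[active] = s
        clock[active] = clock_a
        idx = np.where(active)[0]
        active[idx[done]] = False
    return states


def direct_prior_sample(n_draws, tip_ages, lambda_bounds, ne_bounds,
                        root_age_window, seed):
    """Joint prior via rejection: Ne and lambda log-uniform, rho and onset
    uniform, tree from the coalescent, accept iff onset predates the MRCA."""
    from cryptclock.synthetic_data import sample_coalescent

    rng = np.random.default_rng(seed)
    min_age = min(tip_ages)
    lo, hi = math.log(lambda_bounds[0]), math.log(lambda_bounds[1])
    nlo, nhi = math.log(ne_bounds[0]), math.log(ne_bounds[1])
    labels = [f"t{i}" for i in range(len(tip_ages))]
    out = {"lambda": [], "rho": [], "ne_tau": [], "root_age": [], "t_mrca": []}
    while len(out["lambda"]) < n_draws:
        ne = math.exp(rng.uniform(nlo, nhi))
        root_age = rng.uniform(min_age - root_age_window, min_age)
        tree, ages = sample_coalescent(labels, tip_ages, ne, rng)
        if ages[tree.root] < root_age:
            continue
        out["lambda"].append(math.exp(rng.uniform(lo, hi)))
        out["rho"].append(rng.random())
        out["ne_tau"].append(ne)
        out["root_age"].append(root_age)
        out["t_mrca"].append(ages[tree.root])
    return {k: np.asarray(v) for k, v in out.items()}
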