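"""Posterior summaries: HPD intervals, ESS, density overlap, onset age and
rate-change consensus trees."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .._tree import Node, Phylogeny
from ..profiles_io import PosteriorTrace, ValidationError


def summarize_posterior(trace: PosteriorTrace, parameter: str
                        ) -> tuple[float, tuple[float, float], float]:
    """(mean, 95% HPD interval, ESS) for one trace column.

    The HPD is the shortest interval containing 95% of the samples; ESS
    uses the autocorrelation-time estimator from arviz.
    """
    x = trace.column(parameter)
    if len(x) == 0:
        raise ValidationError("empty trace")
    return float(np.mean(x)), hpd_interval(x), effective_sample_size(x)


def hpd_interval(x: np.ndarray, mass: float = 0.95) -> tuple[float, float]:
    x = np.sort(np.asarray(x, dtype=float))
    n = len(x)
    k = max(1, int(np.ceil(mass * n)))
    if k >= n:
        return float(x[0]), float(x[-1])
    widths = x[k:] - x[: n - k]
    i = int(np.argmin(widths))
    return float(x[i]), float(x[i + k])


def effective_sample_size(x: np.ndarray) -> float:
    x = np.asarray(x, dtype=float)
    if np.allclose(x, x[0]):
        return float(len(x))
    import arviz

    return float(arviz.ess(np.asarray(x)[None, :]))


def posterior_overlap(trace_a: PosteriorTrace, trace_b: PosteriorTrace,
                      parameter: str, grid_size: int = 2048) -> float:
    """Overlapping coefficient of two posterior marginals.

    Gaussian KDEs of both samples are evaluated on a shared grid spanning
    both supports; the overlap is the integral of their pointwise minimum
    (1 for identical distributions, 0 for disjoint ones).
    """
    from scipy.stats import gaussian_kde

    a, b = trace_a.column(parameter), trace_b.column(parameter)
    lo = min(a.min(), b.min())
    hi = max(a.max(), b.max())
    span = hi - lo if hi > lo else max(abs(hi), 1.0)
    grid = np.linspace(lo - 0.1 * span, hi + 0.1 * span, grid_size)
    fa = gaussian_kde(a)(grid)
    fb = gaussian_kde(b)(grid)
    return float(np.trapezoid(np.minimum(fa, fb), grid))


def onset_age(trace: PosteriorTrace) -> tuple[float, tuple[float, float], float]:
    """Posterior summary of the unaltered-ancestor age on the patient-age axis."""
    return summarize_posterior(trace, "root_age")


# ---------------------------------------------------------------------------
# consensus of sampled trees
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class RateChange:
    clade: frozenset
    mean_multiplier_rate: float
    conditional_posterior: float  # P(shift | clade present)


def _clades(tree: Phylogeny):
    """Yield (frozenset of tip labels, node) for every node."""
    below: dict[Node, frozenset] = {}
    for node in tree.postorder():
        if node.is_leaf:
            below[node] = frozenset([node.label])
        else:
            acc = frozenset()
            for c in node.children:
                acc |= below[c]
            below[node] = acc
        yield below[node], node


def annotate_rate_changes(sampled_trees: list[Phylogeny]) -> tuple[Phylogeny, list[RateChange]]:
    """Majority-rule consensus with per-branch mean effective rates.

    Each branch of the consensus carries ``posterior`` (clade frequency)
    and ``rate`` (mean of the per-sample branch rate over trees containing
    the clade). Rate changes are clades whose branch carried an active
    shift indicator, reported with the shift posterior conditional on the
    clade being present.
    """
    if len(sampled_trees) < 100:
        raise ValidationError("need at least 100 sampled trees for a consensus")
    n_trees = len(sampled_trees)
    count: dict[frozenset, int] = {}
    rate_sum: dict[frozenset, float] = {}
    shift_sum: dict[frozenset, int] = {}
    length_sum: dict[frozenset, float] = {}
    for tree in sampled_trees:
        for clade, node in _clades(tree):
            count[clade] = count.get(clade, 0) + 1
            rate_sum[clade] = rate_sum.get(clade, 0.0) + float(
                node.annotations.get("rate", np.nan)
            )
            shift_sum[clade] = shift_sum.get(clade, 0) + int(
                node.annotations.get("shift", 0)
            )
            length_sum[clade] = length_sum.get(clade, 0.0) + (node.length or 0.0)

    all_tips = max(count, key=len)
    majority = [c for c, k in count.items() if k > n_trees / 2 or c == all_tips]
    majority.sort(key=len)

    nodes: dict[frozenset, Node] = {}
    for clade in majority:
        node = Node(next(iter(clade)) if len(clade) == 1 else None)
        node.annotations["posterior"] = count[clade] / n_trees
        node.annotations["rate"] = rate_sum[clade] / count[clade]
        node.length = length_sum[clade] / count[clade]
        nodes[clade] = node
    for clade in majority:
        if clade == all_tips:
            continue
        containers = [c for c in majority if len(c) > len(clade) and clade < c]
        parent = min(containers, key=len)
        nodes[parent].add_child(nodes[clade])
    consensus = Phylogeny(nodes[all_tips])

    changes = [
        RateChange(clade, rate_sum[clade] / count[clade],
                   shift_sum[clade] / count[clade])
        for clade in majority
        if shift_sum.get(clade, 0) > 0
    ]
    changes.sort(key=lambda rc: -rc.conditional_posterior)
    return consensus, changes
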