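"""Priors: constant-size coalescent tree density and the random-local-clock
prior, plus the configuration block that fixes prior bounds and chain
settings."""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy.special import gammaln

from .._tree import Phylogeny
from ..profiles_io import ValidationError

LN2 = math.log(2.0)


@dataclass
class ClockConfig:
    """Chain and prior settings. Priors follow the documented defaults:
    log-uniform rate and Ne, uniform gain fraction, a 60-year uniform
    window on the onset age ending at the earliest sampling age."""

    n_steps: int = 2_000_000
    burnin_fraction: float = 0.10
    thin: int = 1000
    mode: str = "strict"  # "strict" | "rlc"
    K: int = 4
    lambda_bounds: tuple[float, float] = (1e-5, 1.0)
    ne_bounds: tuple[float, float] = (0.1, 1000.0)
    gd_rate_bounds: tuple[float, float] = (1e-6, 1.0)
    root_age_window_years: float = 60.0
    rlc_expected_changes: float = LN2
    rlc_sigma: float = 1.0
    sample_topology: bool = True
    tree_thin: Optional[int] = None  # defaults to thin

    def validate(self) -> None:
        if self.mode not in ("strict", "rlc"):
            raise ValidationError(f"unknown clock mode {self.mode!r}")
        if self.n_steps <= 0 or not 0.0 <= self.burnin_fraction < 1.0:
            raise ValidationError("bad chain length or burn-in fraction")
        if self.thin <= 0:
            raise ValidationError("thin must be positive")
        for lo, hi in (self.lambda_bounds, self.ne_bounds, self.gd_rate_bounds):
            if not 0 < lo < hi:
                raise ValidationError("prior bounds must satisfy 0 < lo < hi")

    @classmethod
    def from_file(cls, path) -> "ClockConfig":
        """key=value config file; tuple values comma-separated."""
        kwargs = {}
        for line in open(path, encoding="utf-8"):
            line = line.split("#", 1)[0].strip()
            if not line:
                continue
            key, _, val = line.partition("=")
            key, val = key.strip(), val.strip()
            if key in ("lambda_bounds", "ne_bounds", "gd_rate_bounds"):
                lo, hi = val.split(",")
                kwargs[key] = (float(lo), float(hi))
            elif key in ("n_steps", "thin", "K", "tree_thin"):
                kwargs[key] = int(val)
            elif key in ("mode",):
                kwargs[key] = val
            elif key == "sample_topology":
                kwargs[key] = val.lower() in ("1", "true", "yes")
            else:
                kwargs[key] = float(val)
        config = cls(**kwargs)
        config.validate()
        return config


def coalescent_intervals(tip_times: np.ndarray, node_times: np.ndarray
                         ) -> list[tuple[float, int]]:
    """(interval length, active lineage count) walking from the latest tip
    back to the MRCA. Times increase toward the present."""
    events = sorted(
        [(t, +1) for t in tip_times] + [(t, -1) for t in node_times],
        key=lambda e: (-e[0], e[1]),
    )
    out = []
    active = 0
    prev = events[0][0]
    for time, delta in events:
        if active > 0 and prev - time > 0:
            out.append((prev - time, active))
        if delta > 0:
            active += 1
        else:
            active -= 1
        prev = time
    return out


def coalescent_log_prior(tree: Phylogeny, ne_tau: float) -> float:
    """Constant-size coalescent log density of a time tree (heterochronous
    tips allowed); branch lengths are in years, ``ne_tau`` is the
    coalescent timescale in years."""
    if ne_tau <= 0:
        raise ValidationError("Ne_tau must be positive")
    depths = tree.depths()
    maxdepth = max(depths.values())
    tip_times = np.array([maxdepth - depths[n] for n in tree.postorder() if n.is_leaf])
    node_times = np.array(
        [maxdepth - depths[n] for n in tree.postorder() if not n.is_leaf]
    )
    # times measured backward from the latest tip; flip to forward axis
    return coalescent_log_density(-tip_times, -node_times, ne_tau)


def coalescent_log_density(tip_ages: np.ndarray, node_ages: np.ndarray,
                           ne_tau: float) -> float:
    """Density on a forward time axis (ages increase toward the present)."""
    if ne_tau <= 0:
        raise ValidationError("Ne_tau must be positive")
    logp = -len(node_ages) * math.log(ne_tau)
    for dt, k in coalescent_intervals(np.asarray(tip_ages), np.asarray(node_ages)):
        logp -= k * (k - 1) / 2.0 * dt / ne_tau
    return logp


def rlc_log_prior(indicators: Sequence[int], multipliers: Sequence[float],
                  expected_changes: float = LN2, sigma: float = 1.0) -> float:
    """Poisson(expected_changes) on the number of active branches, uniform
    over placements, log-normal(0, sigma) on each active multiplier;
    inactive multipliers are pinned at 1."""
    ind = np.asarray(indicators, dtype=bool)
    mult = np.asarray(multipliers, dtype=float)
    if ind.shape != mult.shape:
        raise ValidationError("indicator/multiplier shape mismatch")
    if np.any(mult <= 0):
        raise ValidationError("rate multipliers must be positive")
    k, nb = int(ind.sum()), len(ind)
    logp = (k * math.log(expected_changes) if k else 0.0) - expected_changes
    logp -= gammaln(k + 1)
    # uniform over the C(nb, k) placements
    logp -= gammaln(nb + 1) - gammaln(k + 1) - gammaln(nb - k + 1)
    if k:
        x = np.log(mult[ind])
        logp += float(
            -0.5 * np.sum(x**2) / sigma**2
            - k * (math.log(sigma) + 0.5 * math.log(2 * math.pi))
            - np.sum(np.log(mult[ind]))
        )
    return logp
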