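"""Ground-truthed cohort simulator.

Crypt lineages follow a constant-size heterochronous coalescent; copy
states evolve along the genealogy as per-allele birth-death events placed
by Gillespie simulation at a per-branch rate of
``lambda * copies * multiplier * GEJ factor``. Founder clonal events sit
on the root stem, genome doubling doubles all states on designated
branches, biopsy epithelium profiles carry events present in at least a
fraction ``f`` of their crypts, and crypt-level noise (event dropout,
spurious single-segment events) is applied last.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np

from ._tree import Node, Phylogeny
from .profiles_io import (
    GenomeGrid,
    PatientMeta,
    SampleMeta,
    SegmentProfile,
    ValidationError,
    write_sample_sheet,
    write_segment_table,
)


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------


@dataclass
class NoiseConfig:
    p_false_negative: float = 0.0  # per-event dropout probability in crypts
    spurious_rate: float = 0.0  # expected spurious single-segment events per crypt

    def validate(self):
        if not 0.0 <= self.p_false_negative <= 1.0:
            raise ValidationError("p_false_negative must lie in [0, 1]")
        if self.spurious_rate < 0:
            raise ValidationError("spurious_rate must be non-negative")


@dataclass
class SimConfig:
    """Cohort design and generative parameters (defaults follow the
    two-arm, two-time-point sampling design: non-progressors 3+3
    endoscopic biopsies, progressors 3 endoscopic + 8 surgical, each
    biopsy yielding 8 crypts in 4 sections plus 1 epithelium sample)."""

    n_nonprogressors: int = 4
    n_progressors: int = 4
    biopsies_np: tuple[int, int] = (3, 3)  # per time point
    biopsies_p: tuple[int, int] = (3, 8)
    sections_per_biopsy: int = 4
    crypts_per_section: int = 2
    n_chromosomes: int = 4
    chrom_length_bp: int = 50_000_000
    locus_bp: int = 2_000_000
    K: int = 4
    lambda_true: float = 0.01  # events / allele copy / locus / year
    rho_true: float = 0.5
    ne_tau_true: float = 5.0
    onset_age: float = 40.0
    age_at_t1: float = 60.0
    months_between_timepoints: float = 72.0
    n_founder_events: int = 2
    rlc_shifts: list = field(default_factory=list)  # [(clade_size, multiplier)]
    gd_clades: list = field(default_factory=list)  # [clade_size, ...]
    gej_gradient_beta: float = 0.0  # rate multiplier exp(-beta * distance)
    biopsy_consensus_f: float = 0.5
    noise: NoiseConfig = field(default_factory=NoiseConfig)

    def validate(self):
        if not 0.5 <= self.biopsy_consensus_f <= 1.0:
            raise ValidationError("biopsy consensus fraction must lie in [0.5, 1]")
        if self.lambda_true < 0 or self.ne_tau_true <= 0:
            raise ValidationError("rates must be non-negative, Ne positive")
        if self.onset_age >= self.age_at_t1:
            raise ValidationError("onset must precede the first sampling age")
        if self.chrom_length_bp % self.locus_bp:
            raise ValidationError("chromosome length must be a locus multiple")
        self.noise.validate()

    def grid(self) -> GenomeGrid:
        return GenomeGrid.uniform(self.n_chromosomes, self.chrom_length_bp,
                                  self.locus_bp)

    @property
    def crypts_per_biopsy(self) -> int:
        return self.sections_per_biopsy * self.crypts_per_section

    @property
    def age_at_t2(self) -> float:
        return self.age_at_t1 + self.months_between_timepoints / 12.0


@dataclass
class SimEvent:
    event_id: int
    age: float
    locus: int
    allele: int  # 0 or 1 (truth haplotype)
    delta: int  # +1 gain, -1 loss
    kind: str = "sca"  # "sca" | "founder" | "gd"


@dataclass
class SyntheticTruth:
    tree: Phylogeny  # crypt genealogy, branch lengths in years
    onset_age: float
    events: list
    crypt_event_counts: dict
    marker_truth: dict  # sample -> sorted list of (chrom, pos, allele_index)
    event_incidence: dict  # event_id -> set of crypt sample ids
    gd_samples: set
    rlc_branches: list  # [(frozenset of tips, multiplier)]
    profiles_pre_noise: dict  # sample -> SegmentProfile
    params: dict


# ---------------------------------------------------------------------------
# coalescent genealogy
# ---------------------------------------------------------------------------


def sample_coalescent(labels: Sequence[str], ages: Sequence[float], ne_tau: float,
                      rng: np.random.Generator,
                      min_root_age: Optional[float] = None,
                      max_tries: int = 1000) -> tuple[Phylogeny, dict]:
    """Constant-size serial coalescent; returns (tree, node ages).

    If ``min_root_age`` is given, genealogies whose MRCA predates it are
    rejected and redrawn (the clone cannot be older than its onset).
    """
    for _ in range(max_tries):
        tree, node_ages = _draw_coalescent(labels, ages, ne_tau, rng)
        if min_root_age is None or node_ages[tree.root] >= min_root_age:
            return tree, node_ages
    raise ValidationError(
        "coalescent rejection sampling failed; Ne too large for the onset window"
    )


def _draw_coalescent(labels, ages, ne_tau, rng):
    max_age = max(ages)
    pending = sorted(
        [(max_age - a, Node(lbl)) for lbl, a in zip(labels, ages)],
        key=lambda x: x[0],
    )
    node_t: dict[Node, float] = {n: t for t, n in pending}
    active: list[Node] = []
    t = 0.0
    i = 0
    while True:
        while i < len(pending) and pending[i][0] <= t + 1e-12:
            active.append(pending[i][1])
            i += 1
        if len(active) == 1 and i == len(pending):
            break
        if len(active) < 2:
            t = pending[i][0]
            continue
        k = len(active)
        wait = rng.exponential(ne_tau / (k * (k - 1) / 2.0))
        if i < len(pending) and t + wait > pending[i][0]:
            t = pending[i][0]
            continue
        t += wait
        a, b = rng.choice(k, size=2, replace=False)
        left, right = active[a], active[b]
        parent = Node()
        parent.add_child(left)
        parent.add_child(right)
        node_t[parent] = t
        active = [n for j, n in enumerate(active) if j not in (a, b)]
        active.append(parent)
    root = active[0]
    node_ages = {}
    for node, bt in node_t.items():
        node_ages[node] = max_age - bt
    tree = Phylogeny(root)
    for node in tree.postorder():
        if node.parent is not None:
            node.length = node_ages[node] - node_ages[node.parent]
    return tree, node_ages


# ---------------------------------------------------------------------------
# event placement
# ---------------------------------------------------------------------------


def _gillespie_branch(states: np.ndarray, t0: float, t1: float, rate: float,
                      rho: float, K: int, rng: np.random.Generator,
                      events: list, next_id: list[int]) -> None:
    """Evolve (L, 2) states in place from age t0 to t1, logging events."""
    t = t0
    while True:
        gain = rho * states * (states < K)
        loss = (1.0 - rho) * states * (states >= 1)
        weights = (gain + loss).ravel()
        total = rate * weights.sum()
        if total <= 0:
            return
        t += rng.exponential(1.0 / total)
        if t >= t1:
            return
        cell = rng.choice(len(weights), p=weights / weights.sum())
        locus, allele = divmod(cell, 2)
        p_gain = gain[locus, allele] / (gain[locus, allele] + loss[locus, allele])
        delta = 1 if rng.random() < p_gain else -1
        states[locus, allele] += delta
        events.append(SimEvent(next_id[0], t, locus, allele, delta))
        next_id[0] += 1


def _pick_clade_branch(tree: Phylogeny, clade_size: int,
                       taken: set) -> Optional[Node]:
    """Internal branch whose clade size is closest to the request."""
    sizes = {}
    for node in tree.postorder():
        sizes[node] = 1 if node.is_leaf else sum(sizes[c] for c in node.children)
    candidates = [n for n in tree.postorder()
                  if n.parent is not None and not n.is_leaf and id(n) not in taken]
    if not candidates:
        return None
    best = min(candidates, key=lambda n: (abs(sizes[n] - clade_size), sizes[n]))
    taken.add(id(best))
    return best


def _states_to_markers(states: np.ndarray, grid: GenomeGrid
                       ) -> list[tuple[str, int, int]]:
    """Truth breakpoint boundaries straight from the locus-state matrix."""
    markers = []
    offset = 0
    for chrom in grid.chromosomes:
        nloc = grid.n_segments(chrom)
        bnds = grid.boundaries[chrom]
        for allele in (0, 1):
            col = states[offset:offset + nloc, allele]
            if col[0] != 1:
                markers.append((chrom, 0, allele))
            for j in range(nloc - 1):
                if col[j] != col[j + 1]:
                    markers.append((chrom, int(bnds[j + 1]), allele))
            if col[-1] != 1:
                markers.append((chrom, int(bnds[-1]), allele))
        offset += nloc
    return sorted(markers)


# ---------------------------------------------------------------------------
# patient simulation
# ---------------------------------------------------------------------------


def simulate_patient(config: SimConfig, seed: int, patient_id: str = "SIM-1",
                     progressor: bool = False
                     ) -> tuple[list[SegmentProfile], tuple[PatientMeta, list[SampleMeta]], SyntheticTruth]:
    """One patient: genealogy, events, crypt + biopsy profiles, metadata."""
    config.validate()
    rng = np.random.default_rng(seed)
    grid = config.grid()
    L = grid.total_segments
    K = config.K

    design = config.biopsies_p if progressor else config.biopsies_np
    biopsies = []  # (biopsy_id, time_point, gej_distance)
    for tp, count in ((1, design[0]), (2, design[1])):
        for b in range(count):
            gej = 1.0 + 2.0 * b  # deterministic axial spacing in cm
            biopsies.append((f"{patient_id}-B{tp}{b + 1}", tp, gej))

    crypt_labels, crypt_ages, crypt_biopsy = [], [], {}
    for biopsy_id, tp, gej in biopsies:
        age = config.age_at_t1 if tp == 1 else config.age_at_t2
        for section in range(1, config.sections_per_biopsy + 1):
            for slot_i in range(config.crypts_per_section):
                slot = chr(ord("a") + slot_i)
                label = f"{biopsy_id}-s{section}{slot}"
                crypt_labels.append(label)
                crypt_ages.append(age)
                crypt_biopsy[label] = (biopsy_id, tp, gej, section, slot)

    tree, node_ages = sample_coalescent(crypt_labels, crypt_ages,
                                        config.ne_tau_true, rng,
                                        min_root_age=config.onset_age)

    # clade-level rate shifts and genome doublings
    taken: set = set()
    shift_mult: dict[int, float] = {}
    rlc_branches = []
    for clade_size, mult in config.rlc_shifts:
        node = _pick_clade_branch(tree, clade_size, taken)
        if node is not None:
            shift_mult[id(node)] = float(mult)
            rlc_branches.append((frozenset(
                n.label for n in Phylogeny(node).tips()), float(mult)))
    gd_nodes: set[int] = set()
    gd_samples: set[str] = set()
    for clade_size in config.gd_clades:
        node = _pick_clade_branch(tree, clade_size, taken)
        if node is not None:
            gd_nodes.add(id(node))
            gd_samples |= {n.label for n in Phylogeny(node).tips()}

    # GEJ factor per branch: mean over destination biopsies of descendant crypts
    beta = config.gej_gradient_beta
    tip_factor = {
        lbl: math.exp(-beta * crypt_biopsy[lbl][2]) for lbl in crypt_labels
    }
    branch_factor: dict[int, float] = {}
    factor_below: dict[Node, list[float]] = {}
    for node in tree.postorder():
        if node.is_leaf:
            factor_below[node] = [tip_factor[node.label]]
        else:
            acc = []
            for c in node.children:
                acc.extend(factor_below[c])
            factor_below[node] = acc
        branch_factor[id(node)] = float(np.mean(factor_below[node]))

    # founder events on the stem
    events: list[SimEvent] = []
    next_id = [0]
    root_states = np.ones((L, 2), dtype=np.int64)
    stem_mid = 0.5 * (config.onset_age + node_ages[tree.root])
    founder_cells = rng.choice(L * 2, size=min(config.n_founder_events, L * 2),
                               replace=False)
    for cell in founder_cells:
        locus, allele = divmod(int(cell), 2)
        delta = -1 if rng.random() < 0.5 else 1
        root_states[locus, allele] = max(0, min(K, 1 + delta))
        events.append(SimEvent(next_id[0], stem_mid, locus, allele, delta,
                               kind="founder"))
        next_id[0] += 1
    _gillespie_branch(root_states, config.onset_age, node_ages[tree.root],
                      config.lambda_true, config.rho_true, K, rng, events,
                      next_id)
    stem_events = list(events)

    # walk the tree, accumulating per-branch events
    tip_states: dict[str, np.ndarray] = {}
    path_events: dict[str, list[SimEvent]] = {}
    tip_doubled: dict[str, bool] = {}

    def walk(node: Node, states: np.ndarray, inherited: list[SimEvent],
             rate_mult: float, doubled: bool) -> None:
        for child in node.children:
            s = states.copy()
            ev = list(inherited)
            mult = rate_mult * shift_mult.get(id(child), 1.0)
            child_doubled = doubled
            before = len(events)
            t0, t1 = node_ages[node], node_ages[child]
            if id(child) in gd_nodes:
                mid = 0.5 * (t0 + t1)
                _gillespie_branch(s, t0, mid, config.lambda_true * mult
                                  * branch_factor[id(child)], config.rho_true,
                                  K, rng, events, next_id)
                np.minimum(2 * s, K, out=s)
                events.append(SimEvent(next_id[0], mid, -1, -1, 0, kind="gd"))
                next_id[0] += 1
                child_doubled = True
                _gillespie_branch(s, mid, t1, config.lambda_true * mult
                                  * branch_factor[id(child)], config.rho_true,
                                  K, rng, events, next_id)
            else:
                _gillespie_branch(s, t0, t1, config.lambda_true * mult
                                  * branch_factor[id(child)], config.rho_true,
                                  K, rng, events, next_id)
            ev.extend(events[before:])
            if child.is_leaf:
                tip_states[child.label] = s
                path_events[child.label] = ev
                tip_doubled[child.label] = child_doubled
            else:
                walk(child, s, ev, mult, child_doubled)

    walk(tree.root, root_states, stem_events, 1.0, False)

    # biopsy consensus profiles from pre-noise crypt event sets
    biopsy_states: dict[str, np.ndarray] = {}
    biopsy_doubled: dict[str, bool] = {}
    for biopsy_id, tp, gej in biopsies:
        members = [lbl for lbl in crypt_labels if crypt_biopsy[lbl][0] == biopsy_id]
        threshold = config.biopsy_consensus_f * len(members)
        counts: dict[int, int] = {}
        for lbl in members:
            for ev in path_events[lbl]:
                counts[ev.event_id] = counts.get(ev.event_id, 0) + 1
        keep = {eid for eid, c in counts.items() if c >= threshold}
        ordered = sorted(
            {ev.event_id: ev for lbl in members for ev in path_events[lbl]}.values(),
            key=lambda e: (e.age, e.event_id),
        )
        s = np.ones((L, 2), dtype=np.int64)
        doubled = False
        for ev in ordered:
            if ev.event_id not in keep:
                continue
            if ev.kind == "gd":
                np.minimum(2 * s, K, out=s)
                doubled = True
            else:
                s[ev.locus, ev.allele] = max(0, min(K, s[ev.locus, ev.allele]
                                                    + ev.delta))
        biopsy_states[biopsy_id] = s
        biopsy_doubled[biopsy_id] = doubled
        if doubled:
            gd_samples.add(f"{biopsy_id}-epi")

    # assemble profiles and truth
    profiles_pre_noise: dict[str, SegmentProfile] = {}
    marker_truth: dict[str, list] = {}
    crypt_event_counts: dict[str, int] = {}
    for lbl in crypt_labels:
        profiles_pre_noise[lbl] = SegmentProfile.from_grid_states(
            lbl, grid, tip_states[lbl], phased=True)
        marker_truth[lbl] = _states_to_markers(tip_states[lbl], grid)
        crypt_event_counts[lbl] = sum(1 for e in path_events[lbl]
                                      if e.kind != "gd")
        if tip_doubled[lbl]:
            gd_samples.add(lbl)
    for biopsy_id, tp, gej in biopsies:
        sid = f"{biopsy_id}-epi"
        profiles_pre_noise[sid] = SegmentProfile.from_grid_states(
            sid, grid, biopsy_states[biopsy_id], phased=True)
        marker_truth[sid] = _states_to_markers(biopsy_states[biopsy_id], grid)

    incidence = {
        ev.event_id: {lbl for lbl in crypt_labels
                      if any(e.event_id == ev.event_id for e in path_events[lbl])}
        for ev in events if ev.kind != "gd"
    }

    truth = SyntheticTruth(
        tree=tree,
        onset_age=config.onset_age,
        events=events,
        crypt_event_counts=crypt_event_counts,
        marker_truth=marker_truth,
        event_incidence=incidence,
        gd_samples=gd_samples,
        rlc_branches=rlc_branches,
        profiles_pre_noise=profiles_pre_noise,
        params={
            "lambda_true": config.lambda_true,
            "rho_true": config.rho_true,
            "ne_tau_true": config.ne_tau_true,
            "onset_age": config.onset_age,
        },
    )

    # noise is applied to crypt profiles only, last
    profiles = [profiles_pre_noise[lbl] for lbl in sorted(profiles_pre_noise)]
    if config.noise.p_false_negative > 0 or config.noise.spurious_rate > 0:
        noisy = degrade([profiles_pre_noise[lbl] for lbl in crypt_labels],
                        truth, config.noise, seed=int(rng.integers(2**31)),
                        grid=grid, K=K)
        noisy_by_id = {p.sample_id: p for p in noisy}
        profiles = [noisy_by_id.get(p.sample_id, p) for p in profiles]

    patient = PatientMeta(patient_id, progressor, config.age_at_t1,
                          config.months_between_timepoints)
    metas = []
    for lbl in crypt_labels:
        biopsy_id, tp, gej, section, slot = crypt_biopsy[lbl]
        metas.append(SampleMeta(
            sample_id=lbl, patient_id=patient_id, role="crypt", time_point=tp,
            biopsy_id=biopsy_id, baguette_section=section, crypt_slot=slot,
            gej_distance_cm=gej, map_axial_cm=gej,
            sampling_age_years=config.age_at_t1 if tp == 1 else config.age_at_t2,
        ))
    for biopsy_id, tp, gej in biopsies:
        metas.append(SampleMeta(
            sample_id=f"{biopsy_id}-epi", patient_id=patient_id,
            role="biopsy_epithelium", time_point=tp, biopsy_id=biopsy_id,
            gej_distance_cm=gej, map_axial_cm=gej,
            sampling_age_years=config.age_at_t1 if tp == 1 else config.age_at_t2,
        ))
    return profiles, (patient, metas), truth


def degrade(profiles: Sequence[SegmentProfile], truth: SyntheticTruth,
            noise: NoiseConfig, seed: int, grid: Optional[GenomeGrid] = None,
            K: int = 4) -> list[SegmentProfile]:
    """Apply crypt measurement noise: independent event dropout plus
    Poisson-many spurious single-segment events. Biopsy profiles are not
    touched (pass crypt profiles only)."""
    noise.validate()
    rng = np.random.default_rng(seed)
    if grid is None:
        raise ValidationError("degrade needs the genome grid")
    L = grid.total_segments
    path_events: dict[str, list[SimEvent]] = {}
    by_id = {e.event_id: e for e in truth.events}
    for sid, members in truth.event_incidence.items():
        for lbl in members:
            path_events.setdefault(lbl, []).append(by_id[sid])
    gd_events = [e for e in truth.events if e.kind == "gd"]

    out = []
    for prof in profiles:
        evs = sorted(path_events.get(prof.sample_id, []),
                     key=lambda e: (e.age, e.event_id))
        kept = [e for e in evs if rng.random() >= noise.p_false_negative]
        s = np.ones((L, 2), dtype=np.int64)
        # one doubling per lineage; the earliest GD event sets its timing
        doubled_ages = sorted(e.age for e in gd_events
                              if prof.sample_id in truth.gd_samples)[:1]
        merged = sorted(
            kept + [SimEvent(-1, a, -1, -1, 0, kind="gd") for a in doubled_ages],
            key=lambda e: (e.age, e.event_id),
        )
        for ev in merged:
            if ev.kind == "gd":
                np.minimum(2 * s, K, out=s)
            else:
                s[ev.locus, ev.allele] = max(0, min(K, s[ev.locus, ev.allele]
                                                    + ev.delta))
        n_spurious = rng.poisson(noise.spurious_rate)
        for _ in range(n_spurious):
            locus = int(rng.integers(L))
            allele = int(rng.integers(2))
            delta = 1 if rng.random() < 0.5 else -1
            s[locus, allele] = max(0, min(K, s[locus, allele] + delta))
        out.append(SegmentProfile.from_grid_states(prof.sample_id, grid, s,
                                                   phased=True))
    return out


# ---------------------------------------------------------------------------
# cohort simulation
# ---------------------------------------------------------------------------


def simulate_cohort(config: SimConfig, seed: int, out_dir=None
                    ) -> tuple[list[SegmentProfile], list[PatientMeta],
                               list[SampleMeta], dict]:
    """Full two-arm cohort; optionally writes ingest files plus truth JSON."""
    config.validate()
    rng = np.random.default_rng(seed)
    profiles: list[SegmentProfile] = []
    patients: list[PatientMeta] = []
    samples: list[SampleMeta] = []
    truths: dict[str, SyntheticTruth] = {}
    arms = (
        [(f"NP{i + 1:02d}", False) for i in range(config.n_nonprogressors)]
        + [(f"P{i + 1:02d}", True) for i in range(config.n_progressors)]
    )
    for patient_id, progressor in arms:
        pseed = int(rng.integers(2**31))
        prof, (patient, metas), truth = simulate_patient(
            config, pseed, patient_id=patient_id, progressor=progressor)
        profiles.extend(prof)
        patients.append(patient)
        samples.extend(metas)
        truths[patient_id] = truth

    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        write_segment_table(profiles, out / "segments.tsv")
        write_sample_sheet(patients, samples, out / "samples.csv")
        payload = {
            "genome": {
                "n_chromosomes": config.n_chromosomes,
                "chrom_length_bp": config.chrom_length_bp,
                "locus_bp": config.locus_bp,
            },
            "params": {
                "lambda_true": config.lambda_true,
                "rho_true": config.rho_true,
                "ne_tau_true": config.ne_tau_true,
                "onset_age": config.onset_age,
            },
            "patients": {
                pid: {
                    "newick": t.tree.newick(),
                    "onset_age": t.onset_age,
                    "gd_samples": sorted(t.gd_samples),
                    "crypt_event_counts": t.crypt_event_counts,
                    "marker_counts": {s: len(m) for s, m in t.marker_truth.items()},
                }
                for pid, t in truths.items()
            },
        }
        (out / "truth.json").write_text(json.dumps(payload, indent=1),
                                        encoding="utf-8")
    return profiles, patients, samples, truths


# ---------------------------------------------------------------------------
# direct clock-model dataset (for calibration studies)
# ---------------------------------------------------------------------------


def simulate_clock_dataset(n_tips: int, n_loci: int, lam: float, rho: float,
                           ne_tau: float, onset_age: float,
                           tip_ages: Sequence[float], seed: int, K: int = 4,
                           rlc_shift: Optional[tuple[int, float]] = None):
    """Copy-state matrix evolved on a coalescent tree under the clock model.

    Returns ``(CNMatrix, truth dict)``; states are sampled from exact
    branch transition probabilities. ``rlc_shift=(clade_size, multiplier)``
    scales the rate of one clade (inherited by all its branches).
    """
    from .clock_inference.model import CNMatrix, _Propagator

    rng = np.random.default_rng(seed)
    labels = [f"t{i + 1}" for i in range(n_tips)]
    ages = np.asarray(tip_ages, dtype=float)
    tree, node_ages = sample_coalescent(labels, ages, ne_tau, rng,
                                        min_root_age=onset_age)
    shift_node = None
    mult = 1.0
    if rlc_shift is not None:
        shift_node = _pick_clade_branch(tree, rlc_shift[0], set())
        mult = float(rlc_shift[1])

    prop = _Propagator(K, rho)
    shifted_ids: set[int] = set()
    if shift_node is not None:
        for node in Phylogeny(shift_node).postorder():
            shifted_ids.add(id(node))

    def draw_states(parent_states: np.ndarray, dt: float, rate: float
                    ) -> np.ndarray:
        P = prop.matrices(np.array([dt * rate]))[0]
        P = P / P.sum(axis=1, keepdims=True)
        out = np.empty_like(parent_states)
        for state in range(K + 1):
            mask = parent_states == state
            if mask.any():
                out[mask] = rng.choice(K + 1, size=int(mask.sum()), p=P[state])
        return out

    stem_dt = node_ages[tree.root] - onset_age
    root_states = draw_states(np.ones(2 * n_loci, dtype=np.int64), stem_dt, lam)
    states_at: dict[Node, np.ndarray] = {tree.root: root_states}
    for node in tree.preorder():
        if node is tree.root:
            continue
        rate = lam * (mult if id(node) in shifted_ids else 1.0)
        dt = node_ages[node] - node_ages[node.parent]
        states_at[node] = draw_states(states_at[node.parent], dt, rate)

    data = np.stack([states_at[tip].reshape(n_loci, 2)
                     for tip in tree.tips()])
    cn = CNMatrix([t.label for t in tree.tips()],
                  np.array([node_ages[t] for t in tree.tips()]), data, K=K)
    truth = {
        "tree": tree,
        "node_ages": node_ages,
        "lambda": lam,
        "rho": rho,
        "ne_tau": ne_tau,
        "onset_age": onset_age,
        "shift_clade": (frozenset(t.label for t in Phylogeny(shift_node).tips())
                        if shift_node is not None else None),
        "shift_multiplier": mult,
    }
    return cn, truth
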