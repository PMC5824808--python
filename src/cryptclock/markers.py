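"""Allele-specific breakpoint markers and presence/absence characters.

A marker is a grid boundary at which one allele's copy number changes.
Chromosome start/end pseudo-boundaries are included so whole-arm and
whole-chromosome events are scoreable. Marker identity keys on
``(chromosome, boundary, allele)`` only — the magnitude of the change is
recorded but does not split markers, matching their use as binary
presence/absence characters.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .profiles_io import SampleMeta, Segment, SegmentProfile, ValidationError

NA = -1  # missing character state


def _chrom_key(chrom: str):
    return (0, int(chrom)) if chrom.isdigit() else (1, chrom)


@dataclass(frozen=True)
class BreakpointMarker:
    marker_id: str
    chromosome: str
    boundary_position: int
    allele_label: int  # 1 or 2, post-phasing
    transition: tuple[int, int]  # (cn_left, cn_right) across the boundary

    def __post_init__(self):
        if self.transition[0] == self.transition[1]:
            raise ValidationError(f"marker {self.marker_id}: no copy-number change")

    @property
    def key(self) -> tuple[str, int, int]:
        return (self.chromosome, self.boundary_position, self.allele_label)


def _marker_id(chrom: str, pos: int, allele: int) -> str:
    return f"{chrom}:{pos}:a{allele}"


class MarkerCatalog:
    """Deterministically ordered union of markers across a patient's samples."""

    def __init__(self, markers: Sequence[BreakpointMarker]):
        self.markers = sorted(
            markers,
            key=lambda m: (_chrom_key(m.chromosome), m.boundary_position, m.allele_label),
        )
        self._by_id = {m.marker_id: m for m in self.markers}

    def __len__(self) -> int:
        return len(self.markers)

    def __iter__(self):
        return iter(self.markers)

    def __getitem__(self, marker_id: str) -> BreakpointMarker:
        return self._by_id[marker_id]

    @property
    def marker_ids(self) -> list[str]:
        return [m.marker_id for m in self.markers]


class CharacterMatrix:
    """0/1/NA presence of each marker in each sample."""

    def __init__(self, sample_ids: Sequence[str], marker_ids: Sequence[str],
                 values: np.ndarray):
        values = np.asarray(values, dtype=np.int8)
        if values.shape != (len(sample_ids), len(marker_ids)):
            raise ValidationError("character matrix dimensions inconsistent")
        if not np.isin(values, [0, 1, NA]).all():
            raise ValidationError("character values must be 0, 1 or NA")
        if marker_ids and (values == NA).all(axis=0).any():
            raise ValidationError("character matrix has an all-NA column")
        self.sample_ids = list(sample_ids)
        self.marker_ids = list(marker_ids)
        self.values = values

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def row(self, sample_id: str) -> np.ndarray:
        return self.values[self.sample_ids.index(sample_id)]

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.sample_ids, columns=self.marker_ids)

    def subset(self, sample_ids: Sequence[str]) -> "CharacterMatrix":
        idx = [self.sample_ids.index(s) for s in sample_ids]
        return CharacterMatrix(list(sample_ids), self.marker_ids, self.values[idx])

    def to_nexus(self) -> str:
        lines = [
            "#NEXUS",
            "BEGIN DATA;",
            f"    DIMENSIONS NTAX={len(self.sample_ids)} NCHAR={len(self.marker_ids)};",
            '    FORMAT DATATYPE=STANDARD SYMBOLS="01" MISSING=?;',
            "    MATRIX",
        ]
        width = max((len(s) for s in self.sample_ids), default=0) + 2
        for sid, row in zip(self.sample_ids, self.values):
            chars = "".join("?" if v == NA else str(int(v)) for v in row)
            lines.append(f"    {sid:<{width}}{chars}")
        lines += ["    ;", "END;", ""]
        return "\n".join(lines)


@dataclass(frozen=True)
class DivergenceRecord:
    crypt_id: str
    biopsy_id: str
    n_private_to_crypt: int
    n_missing_from_crypt: int
    pct_divergent: float
    informative: bool = True


# ---------------------------------------------------------------------------
# phasing
# ---------------------------------------------------------------------------


def _alteration_count(profile: SegmentProfile) -> int:
    return sum(1 for s in profile.segments if {s.cn1, s.cn2} != {1})


def _flip_chromosome(profile: SegmentProfile, chrom: str) -> SegmentProfile:
    segs = [
        Segment(s.chrom, s.start, s.end, s.cn2, s.cn1) if s.chrom == chrom else s
        for s in profile.segments
    ]
    return SegmentProfile(profile.sample_id, segs, phased=profile.phased)


def phase_alleles(profiles: Sequence[SegmentProfile], seed: int = 0
                  ) -> list[SegmentProfile]:
    """Assign consistent allele labels across a patient's samples.

    Within-chromosome relative labels are taken as given (they come from
    upstream allele-specific segmentation); only the chromosome-wide 2-way
    flip is chosen. Greedy over samples ordered by descending alteration
    count (ties by sample_id): the orientation sharing the most breakpoint
    markers with already-labeled samples wins (ties keep the input
    orientation). Deterministic; ``seed`` is accepted for API symmetry
    with the stochastic stages.
    """
    del seed  # deterministic heuristic
    order = sorted(profiles, key=lambda p: (-_alteration_count(p), p.sample_id))
    shared: set[tuple[str, int, int]] = set()
    phased: dict[str, SegmentProfile] = {}
    for prof in order:
        cand = SegmentProfile(prof.sample_id, list(prof.segments), phased=False)
        for chrom in cand.chromosomes():
            keep = {m.key for m in extract_breakpoints(cand.with_phase(True))
                    if m.chromosome == chrom}
            flipped = _flip_chromosome(cand, chrom)
            flip = {m.key for m in extract_breakpoints(flipped.with_phase(True))
                    if m.chromosome == chrom}
            if len(flip & shared) > len(keep & shared):
                cand = flipped
        cand = cand.with_phase(True)
        shared |= {m.key for m in extract_breakpoints(cand)}
        phased[prof.sample_id] = cand
    return [phased[p.sample_id] for p in profiles]


# ---------------------------------------------------------------------------
# breakpoint extraction
# ---------------------------------------------------------------------------


def extract_breakpoints(profile: SegmentProfile) -> set[BreakpointMarker]:
    """One marker per (grid boundary, allele) where that allele's state changes.

    Terminal boundaries are compared against the implicit diploid state 1,
    so whole-chromosome events produce start/end edge markers.
    """
    if not profile.phased:
        raise ValidationError(
            f"sample {profile.sample_id}: extract_breakpoints needs a phased profile"
        )
    markers: set[BreakpointMarker] = set()
    by_chrom: dict[str, list[Segment]] = {}
    for seg in profile.segments:
        by_chrom.setdefault(seg.chrom, []).append(seg)
    for chrom, segs in by_chrom.items():
        for allele, attr in ((1, "cn1"), (2, "cn2")):
            states = [getattr(s, attr) for s in segs]
            bounded = [1] + states + [1]
            positions = [segs[0].start] + [s.end for s in segs]
            for pos, left, right in zip(positions, bounded[:-1], bounded[1:]):
                if left != right:
                    markers.add(BreakpointMarker(
                        _marker_id(chrom, pos, allele), chrom, pos, allele,
                        (left, right),
                    ))
    return markers


# ---------------------------------------------------------------------------
# character matrix
# ---------------------------------------------------------------------------


def _boundary_sets(profile: SegmentProfile) -> dict[str, tuple[int, ...]]:
    out: dict[str, list[int]] = {}
    for seg in profile.segments:
        out.setdefault(seg.chrom, [seg.start]).append(seg.end)
    return {c: tuple(v) for c, v in out.items()}


def build_character_matrix(profiles: Sequence[SegmentProfile],
                           tolerance_bp: int = 0
                           ) -> tuple[MarkerCatalog, CharacterMatrix]:
    """Union marker catalog plus per-sample presence/absence matrix.

    Samples lacking a chromosome entirely score NA for that chromosome's
    markers. Grids must agree across samples to within ``tolerance_bp``.
    """
    if not profiles:
        raise ValidationError("no profiles given")
    for p in profiles:
        if not p.phased:
            raise ValidationError(f"sample {p.sample_id}: profiles must be phased")
    reference = _boundary_sets(profiles[0])
    for p in profiles[1:]:
        bs = _boundary_sets(p)
        for chrom in set(reference) & set(bs):
            a, b = reference[chrom], bs[chrom]
            if len(a) != len(b) or any(abs(x - y) > tolerance_bp for x, y in zip(a, b)):
                raise ValidationError(
                    f"sample {p.sample_id}: grid on chromosome {chrom} differs from "
                    f"sample {profiles[0].sample_id} beyond tolerance {tolerance_bp} bp"
                )

    per_sample: dict[str, dict[tuple, BreakpointMarker]] = {}
    union: dict[tuple, BreakpointMarker] = {}
    for p in profiles:
        found = {}
        for m in extract_breakpoints(p):
            key = m.key
            if tolerance_bp:
                # snap to the first sample's boundary within tolerance
                ref = reference.get(m.chromosome, ())
                snapped = next(
                    (b for b in ref if abs(b - m.boundary_position) <= tolerance_bp),
                    m.boundary_position,
                )
                key = (m.chromosome, snapped, m.allele_label)
                m = BreakpointMarker(_marker_id(*key), m.chromosome, snapped,
                                     m.allele_label, m.transition)
            found[key] = m
            union.setdefault(key, m)
        per_sample[p.sample_id] = found

    catalog = MarkerCatalog(list(union.values()))
    sample_ids = [p.sample_id for p in profiles]
    chroms = {p.sample_id: set(p.chromosomes()) for p in profiles}
    values = np.zeros((len(profiles), len(catalog)), dtype=np.int8)
    for i, sid in enumerate(sample_ids):
        for j, m in enumerate(catalog):
            if m.chromosome not in chroms[sid]:
                values[i, j] = NA
            elif m.key in per_sample[sid]:
                values[i, j] = 1
    return catalog, CharacterMatrix(sample_ids, catalog.marker_ids, values)


def clonal_markers(matrix: CharacterMatrix) -> list[str]:
    """Markers present in every sample (NA counts as absence)."""
    if not matrix.sample_ids:
        raise ValidationError("empty character matrix")
    keep = (matrix.values == 1).all(axis=0)
    return [mid for mid, k in zip(matrix.marker_ids, keep) if k]


def crypt_biopsy_divergence(matrix: CharacterMatrix,
                            metas: Sequence[SampleMeta]) -> list[DivergenceRecord]:
    """Per crypt: markers private to the crypt / missing from it vs its biopsy.

    NA in either member of a pair removes the marker from the informative
    set. Crypts with no informative markers report 0% with a flag.
    """
    by_id = {m.sample_id: m for m in metas}
    epithelium = {
        m.biopsy_id: m.sample_id for m in metas if m.role == "biopsy_epithelium"
    }
    records = []
    for sid in matrix.sample_ids:
        meta = by_id.get(sid)
        if meta is None or meta.role != "crypt":
            continue
        parent = epithelium.get(meta.biopsy_id)
        if parent is None or parent not in matrix.sample_ids:
            raise ValidationError(
                f"crypt {sid}: no biopsy_epithelium sample for biopsy {meta.biopsy_id}"
            )
        crypt, biopsy = matrix.row(sid), matrix.row(parent)
        ok = (crypt != NA) & (biopsy != NA)
        private = int(((crypt == 1) & (biopsy == 0) & ok).sum())
        missing = int(((crypt == 0) & (biopsy == 1) & ok).sum())
        union = int((((crypt == 1) | (biopsy == 1)) & ok).sum())
        if union == 0:
            records.append(DivergenceRecord(sid, meta.biopsy_id, 0, 0, 0.0,
                                            informative=False))
        else:
            records.append(DivergenceRecord(
                sid, meta.biopsy_id, private, missing,
                100.0 * (private + missing) / union,
            ))
    return records


# ---------------------------------------------------------------------------
# window distance
# ---------------------------------------------------------------------------


def _window_states(profile: SegmentProfile, window_bp: int) -> dict[tuple[str, int], int]:
    """Majority total-CN state per fixed window, weighted by overlap length."""
    states: dict[tuple[str, int], dict[int, int]] = {}
    for seg in profile.segments:
        first = seg.start // window_bp
        last = (seg.end - 1) // window_bp
        for w in range(first, last + 1):
            lo, hi = w * window_bp, (w + 1) * window_bp
            overlap = min(seg.end, hi) - max(seg.start, lo)
            acc = states.setdefault((seg.chrom, w), {})
            acc[seg.total] = acc.get(seg.total, 0) + overlap
    return {
        key: min(k for k, v in acc.items() if v == max(acc.values()))
        for key, acc in states.items()
    }


def window_distance(profile_a: SegmentProfile, profile_b: SegmentProfile,
                    window_bp: int = 1_000_000) -> float:
    """Percent of fixed windows whose majority total-CN state differs."""
    sa = _window_states(profile_a, window_bp)
    sb = _window_states(profile_b, window_bp)
    windows = set(sa) | set(sb)
    if not windows:
        return 0.0
    differing = sum(1 for w in windows if sa.get(w, 2) != sb.get(w, 2))
    return 100.0 * differing / len(windows)
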