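"""Data model and file formats for allele-specific copy-number analyses.

Coordinates are 0-based half-open, chromosome names carry no ``chr``
prefix, and only autosomes are modeled. The diploid normal state is
``(cn1, cn2) = (1, 1)``; total copy number is ``cn1 + cn2``. All profiles
of one patient must live on one shared segment grid (joint segmentation
is upstream of this package).
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

from ._tree import Phylogeny, TreeParseError, parse_newick

__all__ = [
    "ValidationError",
    "GenomeGrid",
    "Segment",
    "SegmentProfile",
    "PatientMeta",
    "SampleMeta",
    "PosteriorTrace",
    "read_segment_table",
    "write_segment_table",
    "read_sample_sheet",
    "write_sample_sheet",
    "read_tree",
    "write_tree",
    "read_trace",
    "write_trace",
    "load_clinical_patients",
    "summarize_patients",
    "Phylogeny",
    "TreeParseError",
]

MIN_LESION_BP = 1_000_000  # smallest reliably detectable lesion

_FLOAT_FMT = "%.9g"


class ValidationError(ValueError):
    """Input violates a documented invariant; message names the culprit."""


# ---------------------------------------------------------------------------
# genome grid
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class GenomeGrid:
    """Shared per-patient segmentation grid.

    ``boundaries[chrom]`` includes 0 and the chromosome length, strictly
    increasing.
    """

    chrom_lengths: dict[str, int]
    boundaries: dict[str, tuple[int, ...]]

    def __post_init__(self):
        for chrom, length in self.chrom_lengths.items():
            bnds = self.boundaries.get(chrom)
            if bnds is None:
                raise ValidationError(f"chromosome {chrom} has no boundaries")
            arr = np.asarray(bnds)
            if arr[0] != 0 or arr[-1] != length:
                raise ValidationError(
                    f"chromosome {chrom}: boundaries must span [0, {length}]"
                )
            if not np.all(np.diff(arr) > 0):
                raise ValidationError(f"chromosome {chrom}: boundaries not increasing")

    @property
    def chromosomes(self) -> list[str]:
        return list(self.chrom_lengths)

    def n_segments(self, chrom: str) -> int:
        return len(self.boundaries[chrom]) - 1

    @property
    def total_segments(self) -> int:
        return sum(self.n_segments(c) for c in self.chromosomes)

    def segments(self) -> Iterable[tuple[str, int, int]]:
        for chrom in self.chromosomes:
            bnds = self.boundaries[chrom]
            for start, end in zip(bnds[:-1], bnds[1:]):
                yield chrom, start, end

    @staticmethod
    def uniform(n_chromosomes: int, chrom_length: int, segment_length: int) -> "GenomeGrid":
        """Toy genome with equal-length chromosomes and a regular grid."""
        lengths = {str(i + 1): chrom_length for i in range(n_chromosomes)}
        bounds = {
            c: tuple(range(0, chrom_length + 1, segment_length)) for c in lengths
        }
        return GenomeGrid(lengths, bounds)


# ---------------------------------------------------------------------------
# segment profiles
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Segment:
    chrom: str
    start: int
    end: int
    cn1: int
    cn2: int

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def total(self) -> int:
        return self.cn1 + self.cn2


@dataclass
class SegmentProfile:
    """One sample's allele-specific integer copy numbers on a grid."""

    sample_id: str
    segments: list[Segment]
    phased: bool = False

    def validate(self, grid: Optional[GenomeGrid] = None,
                 min_segment_bp: int = MIN_LESION_BP) -> None:
        by_chrom: dict[str, list[Segment]] = {}
        for seg in self.segments:
            if seg.cn1 < 0 or seg.cn2 < 0:
                raise ValidationError(
                    f"sample {self.sample_id}: segment {seg.chrom}:{seg.start}-{seg.end} "
                    f"has negative copy number ({seg.cn1},{seg.cn2})"
                )
            if seg.length < min_segment_bp:
                raise ValidationError(
                    f"sample {self.sample_id}: segment {seg.chrom}:{seg.start}-{seg.end} "
                    f"shorter than {min_segment_bp} bp"
                )
            by_chrom.setdefault(seg.chrom, []).append(seg)
        for chrom, segs in by_chrom.items():
            for a, b in zip(segs[:-1], segs[1:]):
                if b.start < a.end:
                    raise ValidationError(
                        f"sample {self.sample_id}: overlapping segments on {chrom} "
                        f"at {b.start}"
                    )
                if b.start != a.end:
                    raise ValidationError(
                        f"sample {self.sample_id}: coverage gap on {chrom} at {a.end}"
                    )
        if grid is not None:
            for chrom in by_chrom:
                if chrom not in grid.chrom_lengths:
                    raise ValidationError(
                        f"sample {self.sample_id}: unknown chromosome {chrom}"
                    )
            for chrom, length in grid.chrom_lengths.items():
                segs = by_chrom.get(chrom)
                if not segs:
                    raise ValidationError(
                        f"sample {self.sample_id}: chromosome {chrom} missing"
                    )
                if segs[0].start != 0 or segs[-1].end != length:
                    raise ValidationError(
                        f"sample {self.sample_id}: chromosome {chrom} not fully covered"
                    )
                bnds = set(grid.boundaries[chrom])
                for seg in segs:
                    if seg.start not in bnds or seg.end not in bnds:
                        raise ValidationError(
                            f"sample {self.sample_id}: segment {chrom}:{seg.start}-"
                            f"{seg.end} off the shared grid"
                        )

    def chromosomes(self) -> list[str]:
        seen: dict[str, None] = {}
        for seg in self.segments:
            seen.setdefault(seg.chrom, None)
        return list(seen)

    def states_on_grid(self, grid: GenomeGrid) -> np.ndarray:
        """(total_segments, 2) integer allele states in grid order.

        Grid cells not covered by the profile (missing chromosome) get -1.
        """
        out = np.full((grid.total_segments, 2), -1, dtype=np.int64)
        index = {
            (chrom, start): i for i, (chrom, start, _end) in enumerate(grid.segments())
        }
        for seg in self.segments:
            bnds = grid.boundaries[seg.chrom]
            lo = np.searchsorted(bnds, seg.start)
            hi = np.searchsorted(bnds, seg.end)
            for b in bnds[lo:hi]:
                i = index[(seg.chrom, int(b))]
                out[i, 0] = seg.cn1
                out[i, 1] = seg.cn2
        return out

    @staticmethod
    def from_grid_states(sample_id: str, grid: GenomeGrid, states: np.ndarray,
                         phased: bool = False) -> "SegmentProfile":
        segs = []
        for i, (chrom, start, end) in enumerate(grid.segments()):
            cn1, cn2 = int(states[i, 0]), int(states[i, 1])
            segs.append(Segment(chrom, start, end, cn1, cn2))
        return SegmentProfile(sample_id, segs, phased=phased)

    def with_phase(self, phased: bool) -> "SegmentProfile":
        return SegmentProfile(self.sample_id, list(self.segments), phased=phased)


# ---------------------------------------------------------------------------
# metadata
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class PatientMeta:
    patient_id: str
    progressor: bool
    age_at_t1: float
    months_between_timepoints: float

    def __post_init__(self):
        if self.age_at_t1 <= 0:
            raise ValidationError(f"patient {self.patient_id}: age_at_t1 must be > 0")
        if self.months_between_timepoints < 0:
            raise ValidationError(
                f"patient {self.patient_id}: months_between_timepoints must be >= 0"
            )


@dataclass(frozen=True)
class SampleMeta:
    sample_id: str
    patient_id: str
    role: str  # "crypt" | "biopsy_epithelium"
    time_point: int  # 1 | 2
    biopsy_id: str
    sampling_age_years: float
    gej_distance_cm: float = 0.0
    baguette_section: Optional[int] = None
    crypt_slot: Optional[str] = None
    map_axial_cm: Optional[float] = None
    map_circumferential: Optional[float] = None

    def __post_init__(self):
        if self.role not in ("crypt", "biopsy_epithelium"):
            raise ValidationError(f"sample {self.sample_id}: bad role {self.role!r}")
        if self.time_point not in (1, 2):
            raise ValidationError(f"sample {self.sample_id}: bad time_point")
        if self.gej_distance_cm < 0:
            raise ValidationError(f"sample {self.sample_id}: negative GEJ distance")
        if self.role == "crypt":
            if self.baguette_section not in (1, 2, 3, 4):
                raise ValidationError(
                    f"sample {self.sample_id}: crypt needs baguette_section in 1..4"
                )
            if self.crypt_slot not in ("a", "b"):
                raise ValidationError(
                    f"sample {self.sample_id}: crypt needs crypt_slot 'a' or 'b'"
                )
        else:
            if self.baguette_section is not None or self.crypt_slot is not None:
                raise ValidationError(
                    f"sample {self.sample_id}: biopsy_epithelium must not carry "
                    "crypt fields"
                )


def check_sampling_ages(patients: Sequence[PatientMeta],
                        samples: Sequence[SampleMeta],
                        tolerance_years: float = 0.05) -> None:
    by_id = {p.patient_id: p for p in patients}
    for s in samples:
        p = by_id.get(s.patient_id)
        if p is None:
            raise ValidationError(f"sample {s.sample_id}: unknown patient {s.patient_id}")
        expected = p.age_at_t1
        if s.time_point == 2:
            expected += p.months_between_timepoints / 12.0
        if abs(s.sampling_age_years - expected) > tolerance_years:
            raise ValidationError(
                f"sample {s.sample_id}: sampling_age_years {s.sampling_age_years} "
                f"inconsistent with patient record ({expected:.3f} expected)"
            )


# ---------------------------------------------------------------------------
# segment table TSV
# ---------------------------------------------------------------------------

_SEGMENT_COLUMNS = ["sample", "chrom", "start", "end", "cn1", "cn2"]


def read_segment_table(path, grid: Optional[GenomeGrid] = None,
                       min_segment_bp: int = MIN_LESION_BP) -> list[SegmentProfile]:
    """Read a segment TSV (``sample chrom start end cn1 cn2``) into profiles.

    Profiles are validated and returned sorted by ``sample_id``.
    """
    df = pd.read_csv(path, sep="\t", dtype={"sample": str, "chrom": str})
    missing = [c for c in _SEGMENT_COLUMNS if c not in df.columns]
    if missing:
        raise ValidationError(f"segment table missing columns: {missing}")
    profiles = []
    for sample_id, grp in df.groupby("sample", sort=True):
        segs = [
            Segment(r.chrom, int(r.start), int(r.end), int(r.cn1), int(r.cn2))
            for r in grp.itertuples()
        ]
        prof = SegmentProfile(str(sample_id), segs)
        prof.validate(grid, min_segment_bp=min_segment_bp)
        profiles.append(prof)
    return profiles


def write_segment_table(profiles: Sequence[SegmentProfile], path) -> None:
    rows = [
        (p.sample_id, s.chrom, s.start, s.end, s.cn1, s.cn2)
        for p in sorted(profiles, key=lambda p: p.sample_id)
        for s in p.segments
    ]
    pd.DataFrame(rows, columns=_SEGMENT_COLUMNS).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# sample sheet CSV
# ---------------------------------------------------------------------------

_PATIENT_COLUMNS = ["patient_id", "progressor", "age_at_t1", "months_between_timepoints"]
_SAMPLE_COLUMNS = [
    "sample_id", "patient_id", "role", "time_point", "biopsy_id",
    "baguette_section", "crypt_slot", "gej_distance_cm",
    "map_axial_cm", "map_circumferential", "sampling_age_years",
]


def _opt(value, cast):
    if value is None or (isinstance(value, float) and np.isnan(value)) or value == "":
        return None
    return cast(value)


def read_sample_sheet(path) -> tuple[list[PatientMeta], list[SampleMeta]]:
    """Read the combined sample sheet CSV.

    The sheet has two blocks separated by a blank line: a patient block
    (``patient_id,progressor,age_at_t1,months_between_timepoints``) and a
    sample block. Every sample must reference a declared patient.
    """
    text = Path(path).read_text(encoding="utf-8")
    blocks = [b for b in text.split("\n\n") if b.strip()]
    if len(blocks) != 2:
        raise ValidationError("sample sheet must contain patient and sample blocks")
    from io import StringIO

    pdf = pd.read_csv(StringIO(blocks[0]), dtype={"patient_id": str})
    sdf = pd.read_csv(StringIO(blocks[1]), dtype={"sample_id": str, "patient_id": str,
                                                  "biopsy_id": str, "crypt_slot": str})
    for col in _PATIENT_COLUMNS:
        if col not in pdf.columns:
            raise ValidationError(f"patient block missing column {col}")
    for col in _SAMPLE_COLUMNS:
        if col not in sdf.columns:
            raise ValidationError(f"sample block missing column {col}")
    if pdf["patient_id"].duplicated().any():
        raise ValidationError("duplicate patient_id in sheet")
    if sdf["sample_id"].duplicated().any():
        dup = sdf.loc[sdf["sample_id"].duplicated(), "sample_id"].iloc[0]
        raise ValidationError(f"duplicate sample_id {dup!r}")
    patients = [
        PatientMeta(r.patient_id, bool(r.progressor), float(r.age_at_t1),
                    float(r.months_between_timepoints))
        for r in pdf.itertuples()
    ]
    known = {p.patient_id for p in patients}
    samples = []
    for r in sdf.itertuples():
        if r.patient_id not in known:
            raise ValidationError(
                f"sample {r.sample_id}: orphan (patient {r.patient_id} not declared)"
            )
        samples.append(SampleMeta(
            sample_id=r.sample_id,
            patient_id=r.patient_id,
            role=r.role,
            time_point=int(r.time_point),
            biopsy_id=r.biopsy_id,
            baguette_section=_opt(r.baguette_section, int),
            crypt_slot=_opt(r.crypt_slot, str),
            gej_distance_cm=float(r.gej_distance_cm),
            map_axial_cm=_opt(r.map_axial_cm, float),
            map_circumferential=_opt(r.map_circumferential, float),
            sampling_age_years=float(r.sampling_age_years),
        ))
    check_sampling_ages(patients, samples)
    return patients, samples


def write_sample_sheet(patients: Sequence[PatientMeta],
                       samples: Sequence[SampleMeta], path) -> None:
    pdf = pd.DataFrame(
        [(p.patient_id, p.progressor, p.age_at_t1, p.months_between_timepoints)
         for p in patients],
        columns=_PATIENT_COLUMNS,
    )
    sdf = pd.DataFrame(
        [(s.sample_id, s.patient_id, s.role, s.time_point, s.biopsy_id,
          s.baguette_section, s.crypt_slot, s.gej_distance_cm,
          s.map_axial_cm, s.map_circumferential, s.sampling_age_years)
         for s in samples],
        columns=_SAMPLE_COLUMNS,
    )
    with open(path, "w", encoding="utf-8") as fh:
        pdf.to_csv(fh, index=False, float_format=_FLOAT_FMT)
        fh.write("\n")
        sdf.to_csv(fh, index=False, float_format=_FLOAT_FMT)


# ---------------------------------------------------------------------------
# trees
# ---------------------------------------------------------------------------


def write_tree(tree: Phylogeny, path) -> None:
    Path(path).write_text(tree.newick() + "\n", encoding="utf-8")


def read_tree(path) -> Phylogeny:
    tree = parse_newick(Path(path).read_text(encoding="utf-8"))
    if len(tree.root.children) > 2:
        raise ValidationError(
            f"tree in {path} is unrooted (root degree {len(tree.root.children)})"
        )
    return tree


# ---------------------------------------------------------------------------
# posterior traces
# ---------------------------------------------------------------------------


@dataclass
class PosteriorTrace:
    """Retained MCMC iterations, one named column per parameter."""

    samples: pd.DataFrame
    burnin_fraction: float = 0.0
    thin: int = 1

    def __post_init__(self):
        if not np.all(np.isfinite(self.samples.select_dtypes("number").to_numpy())):
            raise ValidationError("trace contains non-finite values")

    def __len__(self) -> int:
        return len(self.samples)

    @property
    def parameters(self) -> list[str]:
        return list(self.samples.columns)

    def column(self, name: str) -> np.ndarray:
        if name not in self.samples.columns:
            raise KeyError(f"trace has no parameter {name!r}")
        return self.samples[name].to_numpy()


def write_trace(trace: PosteriorTrace, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(f"# burnin_fraction={trace.burnin_fraction:.9g}\tthin={trace.thin}\n")
        trace.samples.to_csv(fh, sep="\t", index=False, float_format=_FLOAT_FMT)


def read_trace(path) -> PosteriorTrace:
    burnin, thin = 0.0, 1
    with open(path, encoding="utf-8") as fh:
        first = fh.readline()
        if first.startswith("#"):
            for item in first[1:].split():
                key, _, val = item.partition("=")
                if key == "burnin_fraction":
                    burnin = float(val)
                elif key == "thin":
                    thin = int(val)
            body = fh.read()
        else:
            body = first + fh.read()
    from io import StringIO

    lines = [ln for ln in body.splitlines() if ln.strip()]
    ncols = len(lines[0].split("\t"))
    for i, ln in enumerate(lines[1:], start=2):
        if len(ln.split("\t")) != ncols:
            raise ValidationError(f"trace row {i} is ragged")
    df = pd.read_csv(StringIO(body), sep="\t")
    return PosteriorTrace(df, burnin_fraction=burnin, thin=thin)


# ---------------------------------------------------------------------------
# bundled clinical demo table
# ---------------------------------------------------------------------------


def load_clinical_patients() -> list[PatientMeta]:
    """Eight-patient demo clinical table bundled with the package."""
    path = importlib.resources.files("cryptclock") / "data" / "clinical_patients.csv"
    df = pd.read_csv(str(path), dtype={"patient_id": str})
    return [
        PatientMeta(r.patient_id, bool(r.progressor), float(r.age_at_t1),
                    float(r.months_between_timepoints))
        for r in df.itertuples()
    ]


def summarize_patients(patients: Sequence[PatientMeta]) -> pd.DataFrame:
    """Per-arm count and mean age / inter-timepoint interval."""
    df = pd.DataFrame(
        [(p.patient_id, p.progressor, p.age_at_t1, p.months_between_timepoints)
         for p in patients],
        columns=_PATIENT_COLUMNS,
    )
    return df.groupby("progressor").agg(
        n_patients=("patient_id", "size"),
        mean_age_at_t1=("age_at_t1", "mean"),
        mean_months_between_timepoints=("months_between_timepoints", "mean"),
    )
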