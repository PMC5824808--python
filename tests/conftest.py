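import numpy as np
import pytest

from cryptclock.profiles_io import (
    GenomeGrid,
    PatientMeta,
    SampleMeta,
    Segment,
    SegmentProfile,
)


@pytest.fixture
def toy_grid() -> GenomeGrid:
    """4 chromosomes x 50 Mb on a 2 Mb grid (the simulator default)."""
    return GenomeGrid.uniform(4, 50_000_000, 2_000_000)


@pytest.fixture
def tiny_grid() -> GenomeGrid:
    """2 chromosomes x 10 Mb on a 2 Mb grid for hand-checkable cases."""
    return GenomeGrid.uniform(2, 10_000_000, 2_000_000)


def normal_profile(sample_id: str, grid: GenomeGrid, phased=True) -> SegmentProfile:
    segs = [Segment(c, s, e, 1, 1) for c, s, e in grid.segments()]
    return SegmentProfile(sample_id, segs, phased=phased)


def profile_with(sample_id, grid, overrides, phased=True) -> SegmentProfile:
    """overrides: {(chrom, start): (cn1, cn2)}"""
    segs = []
    for c, s, e in grid.segments():
        cn1, cn2 = overrides.get((c, s), (1, 1))
        segs.append(Segment(c, s, e, cn1, cn2))
    return SegmentProfile(sample_id, segs, phased=phased)


def markers_match_up_to_chromosome_flips(per_sample_found: dict,
                                         per_sample_truth: dict) -> bool:
    """Compare marker sets allowing one global allele flip per chromosome.

    Phasing identifies allele labels only up to a chromosome-wide 2-way
    flip, so closure checks must quotient that symmetry out. A flip choice
    must work for every sample simultaneously.
    """
    chroms = {c for s in per_sample_truth.values() for c, _, _ in s}

    def flipped(markers, chrom_flips):
        return {
            (c, p, (3 - a) if chrom_flips.get(c) else a)
            for c, p, a in markers
        }

    for chrom in chroms:
        for flip in (False, True):
            ok = all(
                {m for m in flipped(per_sample_truth[s], {chrom: flip})
                 if m[0] == chrom}
                == {m for m in per_sample_found[s] if m[0] == chrom}
                for s in per_sample_truth
            )
            if ok:
                break
        else:
            return False
    return True


@pytest.fixture
def crypt_meta_factory():
    def make(sample_id, biopsy_id, section=1, slot="a", patient="PX", tp=1,
             gej=2.0, age=60.0):
        return SampleMeta(
            sample_id=sample_id, patient_id=patient, role="crypt",
            time_point=tp, biopsy_id=biopsy_id, baguette_section=section,
            crypt_slot=slot, gej_distance_cm=gej, sampling_age_years=age,
        )

    return make


@pytest.fixture
def biopsy_meta_factory():
    def make(sample_id, biopsy_id, patient="PX", tp=1, gej=2.0, age=60.0):
        return SampleMeta(
            sample_id=sample_id, patient_id=patient, role="biopsy_epithelium",
            time_point=tp, biopsy_id=biopsy_id, gej_distance_cm=gej,
            sampling_age_years=age,
        )

    return make
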