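"""PCA colors and geometric layout for clonal maps.

Samples are colored by projecting their 0/1 marker rows onto the first
three principal components (mapped to R, G, B). Biopsies are drawn as
ovals split into four baguette sections, crypts as squares inside their
section, ordered along the axial (GEJ-distance) axis.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import asdict, dataclass, field
from typing import Optional, Sequence

import numpy as np

from .markers import NA, CharacterMatrix
from .profiles_io import SampleMeta, ValidationError

GRAY = 0.5  # fallback component score for rank-deficient matrices


def pca_colors(matrix: CharacterMatrix) -> dict[str, tuple[float, float, float]]:
    """Map the first three principal components to (R, G, B) in [0,1].

    NA is treated as absence. Components are min-max scaled per channel;
    missing components (rank < 3) fall back to mid-gray. The sign of each
    component is fixed by making its largest-|loading| element positive,
    so colors do not depend on sample order or SVD sign whim.
    """
    if len(matrix.sample_ids) < 3:
        raise ValidationError("pca_colors needs at least 3 samples")
    X = matrix.values.astype(float)
    X[matrix.values == NA] = 0.0
    X -= X.mean(axis=0, keepdims=True)
    u, s, vt = np.linalg.svd(X, full_matrices=False)
    scores = np.full((len(matrix.sample_ids), 3), GRAY)
    tol = max(X.shape) * np.finfo(float).eps * (s[0] if s.size else 0.0)
    for comp in range(min(3, len(s))):
        if s[comp] <= tol:
            break
        loading = vt[comp]
        # deterministic sign: first non-negligible loading element positive
        # (marker order is canonical, so this is sample-order invariant and
        # immune to |loading| ties)
        nz = np.argmax(np.abs(loading) > 1e-9)
        if loading[nz] < 0:
            col = -u[:, comp]
        else:
            col = u[:, comp]
        proj = col * s[comp]
        lo, hi = proj.min(), proj.max()
        scores[:, comp] = GRAY if hi - lo < 1e-12 else (proj - lo) / (hi - lo)
    return {
        sid: tuple(float(v) for v in scores[i])
        for i, sid in enumerate(matrix.sample_ids)
    }


@dataclass
class BiopsyGlyph:
    biopsy_id: str
    axial_cm: float
    circumferential: float
    color: Optional[tuple[float, float, float]]
    localized: bool
    crypts: list[dict] = field(default_factory=list)


@dataclass
class MapLayout:
    biopsies: list[BiopsyGlyph]

    def to_json(self) -> str:
        return json.dumps([asdict(b) for b in self.biopsies], indent=1, sort_keys=True)

    @staticmethod
    def from_json(text: str) -> "MapLayout":
        data = json.loads(text)
        glyphs = []
        for b in data:
            color = tuple(b["color"]) if b["color"] is not None else None
            glyphs.append(BiopsyGlyph(b["biopsy_id"], b["axial_cm"],
                                      b["circumferential"], color, b["localized"],
                                      b["crypts"]))
        return MapLayout(glyphs)

    def to_svg(self) -> str:
        def css(color):
            if color is None:
                return "#cccccc"
            r, g, b = (int(round(255 * c)) for c in color)
            return f"#{r:02x}{g:02x}{b:02x}"

        parts = ['<svg xmlns="http://www.w3.org/2000/svg" width="800" height="400">']
        for i, bio in enumerate(sorted(self.biopsies, key=lambda b: b.axial_cm)):
            cx, cy = 60 + i * 90, 120 + 60 * bio.circumferential
            parts.append(
                f'<ellipse cx="{cx}" cy="{cy}" rx="40" ry="20" fill="{css(bio.color)}"'
                ' stroke="black"/>'
            )
            for k in range(1, 4):  # baguette section dividers
                x = cx - 40 + k * 20
                parts.append(f'<line x1="{x}" y1="{cy-20}" x2="{x}" y2="{cy+20}"'
                             ' stroke="black" stroke-width="0.5"/>')
            for crypt in bio.crypts:
                sx = cx - 40 + (crypt["section"] - 1) * 20 + 4
                sy = cy - 12 + (0 if crypt["slot"] == "a" else 14)
                parts.append(
                    f'<rect x="{sx}" y="{sy}" width="10" height="10"'
                    f' fill="{css(tuple(crypt["color"]) if crypt["color"] else None)}"'
                    ' stroke="black" stroke-width="0.5"/>'
                )
            parts.append(
                f'<text x="{cx}" y="{cy+35}" font-size="9" text-anchor="middle">'
                f'{bio.biopsy_id}</text>'
            )
        parts.append("</svg>")
        return "\n".join(parts)


def layout_map(metas: Sequence[SampleMeta],
               colors: dict[str, tuple[float, float, float]]) -> MapLayout:
    """Deterministic clonal-map layout: one oval per biopsy, one square per crypt.

    Biopsies without positional metadata go on an 'unlocalized' rail (axial
    position after the last placed biopsy) with a warning.
    """
    by_biopsy: dict[str, list[SampleMeta]] = {}
    for m in metas:
        by_biopsy.setdefault(m.biopsy_id, []).append(m)

    glyphs = []
    max_axial = max((m.gej_distance_cm for m in metas), default=0.0)
    rail = max_axial + 2.0
    for biopsy_id in sorted(by_biopsy):
        members = by_biopsy[biopsy_id]
        epi = next((m for m in members if m.role == "biopsy_epithelium"), None)
        anchor = epi or members[0]
        axial = anchor.map_axial_cm
        if axial is None:
            axial = anchor.gej_distance_cm
        localized = axial is not None
        if axial is None:
            warnings.warn(f"biopsy {biopsy_id}: no position, placed on rail")
            axial, rail = rail, rail + 2.0
        circ = anchor.map_circumferential or 0.0
        glyph = BiopsyGlyph(
            biopsy_id, float(axial), float(circ),
            colors.get(epi.sample_id) if epi else None, localized,
        )
        for m in sorted((x for x in members if x.role == "crypt"),
                        key=lambda x: (x.baguette_section, x.crypt_slot)):
            glyph.crypts.append({
                "sample_id": m.sample_id,
                "section": m.baguette_section,
                "slot": m.crypt_slot,
                "color": list(colors[m.sample_id]) if m.sample_id in colors else None,
            })
        glyphs.append(glyph)
    placed = [m.sample_id for ms in by_biopsy.values() for m in ms]
    if len(placed) != len(set(placed)):
        raise ValidationError("a sample was placed more than once")
    return MapLayout(sorted(glyphs, key=lambda g: (g.axial_cm, g.biopsy_id)))
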