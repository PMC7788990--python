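"""Heatmap and chord-diagram construction and rendering.

Specs are plain data (testable without a canvas); :func:`render` turns them
into deterministic PNG/SVG files with matplotlib.

Coloring schemes:

* ``gradient`` — continuous short-to-long ramp (default).
* ``threshold`` — three flat bands split exactly at 8 and 12 A, highlighting
  the contact / near-contact boundaries.
* ``uniform`` — a perceptually uniform ramp, friendlier to color-blind users.

The heatmap's upper triangle carries the prediction and the lower triangle the
true map; the diagonal shows secondary-structure bands (helix red, strand
green, coil white) when an SS string is given, else a red-green-blue sequence
gradient shared with the chord-diagram arcs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import numpy as np
from matplotlib.colors import BoundaryNorm, LinearSegmentedColormap, ListedColormap, Normalize

from .formats import ContactPrediction
from .geometry import DistanceMap
from .metrics import DISTANCE_CAP, DISTANCE_FLOOR, standardize

__all__ = [
    "SCHEMES",
    "HeatmapSpec",
    "ChordSpec",
    "Chord",
    "residue_gradient_color",
    "ss_color",
    "scheme_cmap",
    "chord_width",
    "chord_alpha",
    "build_heatmap",
    "build_error_heatmap",
    "build_chord",
    "render",
]

SCHEMES = ("gradient", "threshold", "uniform")
SS_COLORS = {"H": (1.0, 0.0, 0.0), "E": (0.0, 0.5, 0.0), "C": (1.0, 1.0, 1.0)}
MAX_CHORD_WIDTH = 8.0

_SEQ_GRADIENT = LinearSegmentedColormap.from_list(
    "seq_gradient", ["red", "green", "blue"]
)


def residue_gradient_color(i: int, L: int) -> tuple:
    """Gradient color (red through green to blue) of 1-based residue ``i``."""
    frac = 0.0 if L <= 1 else (i - 1) / (L - 1)
    return _SEQ_GRADIENT(frac)[:3]


def ss_color(cls: str) -> tuple:
    """Band color of a three-class secondary-structure label (H/E/C)."""
    return SS_COLORS[cls.upper()]


def scheme_cmap(scheme: str, kind: str = "distance"):
    """Return ``(cmap, norm)`` for a coloring scheme.

    The threshold scheme places its color discontinuities exactly at 8 and
    12 A.  For confidence-valued maps the range is [0, 1].
    """
    if scheme not in SCHEMES:
        raise ValueError(f"unknown scheme {scheme!r}; choose from {SCHEMES}")
    if kind == "confidence":
        norm = Normalize(0.0, 1.0)
        cmap = plt.get_cmap("viridis" if scheme == "uniform" else "hot_r")
        return cmap, norm
    if scheme == "threshold":
        cmap = ListedColormap(["#b2182b", "#fddbc7", "#d1e5f0"])
        norm = BoundaryNorm([DISTANCE_FLOOR, 8.0, 12.0, DISTANCE_CAP], cmap.N)
        return cmap, norm
    norm = Normalize(DISTANCE_FLOOR, DISTANCE_CAP)
    cmap = plt.get_cmap("viridis" if scheme == "uniform" else "jet")
    return cmap, norm


@dataclass
class HeatmapSpec:
    """Data behind a combined predicted/true heatmap.

    ``values`` is an L x L array whose upper triangle is the prediction and
    lower triangle the true map (NaN = masked / absent); ``diagonal`` is one
    RGB color per residue.
    """

    values: np.ndarray
    upper_kind: str  # "distance" | "confidence" | "error"
    lower_kind: str | None
    diagonal: list[tuple]
    scheme: str = "gradient"
    rotated: bool = False

    @property
    def L(self) -> int:
        return self.values.shape[0]


@dataclass
class Chord:
    i: int
    j: int
    width: float
    alpha: float
    color: tuple


@dataclass
class ChordSpec:
    """Arc colors (one per residue) and the chords to draw between them."""

    arc_colors: list[tuple]
    chords: list[Chord]

    @property
    def L(self) -> int:
        return len(self.arc_colors)


def _diagonal_colors(L: int, ss: str | None) -> list[tuple]:
    if ss is None:
        return [residue_gradient_color(i, L) for i in range(1, L + 1)]
    if len(ss) != L:
        raise ValueError(f"SS string length {len(ss)} does not match L={L}")
    return [ss_color(c) for c in ss]


def _contact_matrix(pred: ContactPrediction, L: int) -> np.ndarray:
    m = np.full((L, L), np.nan)
    for i, j, c in pred.pairs:
        m[i - 1, j - 1] = c
    return m


def build_heatmap(
    pred: DistanceMap | ContactPrediction,
    true: DistanceMap | None = None,
    ss: str | None = None,
    scheme: str = "gradient",
    rotated: bool = False,
) -> HeatmapSpec:
    """Combined heatmap: prediction in the upper triangle, truth in the lower."""
    if scheme not in SCHEMES:
        raise ValueError(f"unknown scheme {scheme!r}; choose from {SCHEMES}")
    if isinstance(pred, ContactPrediction):
        L = true.L if true is not None else (pred.target_length or pred.max_index())
        upper = _contact_matrix(pred, L)
        upper_kind = "confidence"
    else:
        std = standardize(pred)
        L = std.L
        upper = np.where(std.mask, std.values, np.nan)
        upper_kind = "distance"
    values = np.full((L, L), np.nan)
    iu, ju = np.triu_indices(L, k=1)
    values[iu, ju] = upper[iu, ju]
    lower_kind = None
    if true is not None:
        if true.L != L:
            raise ValueError(f"shape mismatch: pred L={L}, true L={true.L}")
        tstd = standardize(true)
        tvals = np.where(tstd.mask, tstd.values, np.nan)
        values[ju, iu] = tvals[iu, ju]
        lower_kind = "distance"
    return HeatmapSpec(
        values, upper_kind, lower_kind, _diagonal_colors(L, ss), scheme, rotated
    )


def build_error_heatmap(pred: DistanceMap, true: DistanceMap) -> HeatmapSpec:
    """Absolute-error heatmap |pred - true|, masked where either side is."""
    if pred.L != true.L:
        raise ValueError(f"shape mismatch: pred L={pred.L}, true L={true.L}")
    p, t = standardize(pred), standardize(true)
    both = p.mask & t.mask
    err = np.where(both, np.abs(p.values - t.values), np.nan)
    return HeatmapSpec(err, "error", "error", _diagonal_colors(pred.L, None))


def chord_width(distance: float) -> float:
    """Chord width for a standardized distance: linear, max at 3.5 A, 0 at 20 A."""
    d = float(np.clip(distance, DISTANCE_FLOOR, DISTANCE_CAP))
    return MAX_CHORD_WIDTH * (DISTANCE_CAP - d) / (DISTANCE_CAP - DISTANCE_FLOOR)


def chord_alpha(distance: float) -> float:
    """Opacity for a standardized distance: transparency grows with distance."""
    d = float(np.clip(distance, DISTANCE_FLOOR, DISTANCE_CAP))
    frac = (DISTANCE_CAP - d) / (DISTANCE_CAP - DISTANCE_FLOOR)
    return 0.1 + 0.9 * frac


def build_chord(
    source: DistanceMap | ContactPrediction,
    ss: str | None = None,
    L: int | None = None,
    max_distance: float = 12.0,
    min_sep: int = 6,
) -> ChordSpec:
    """Chord diagram data for a distance map or contact prediction.

    Distance maps draw pairs with standardized distance < ``max_distance`` and
    ``|i-j| >= min_sep``; width and opacity fall linearly with distance.
    Contact predictions draw the top 2L pairs by confidence with width
    proportional to confidence.  Each chord takes the arc color of its
    lower-index residue.
    """
    if isinstance(source, DistanceMap):
        L = source.L
        arcs = _diagonal_colors(L, ss)
        chords = []
        std = standardize(source)
        for i, j, d in std.upper_pairs():
            if d >= max_distance or (j - i) < min_sep:
                continue
            w = chord_width(d)
            if w <= 0:
                continue
            chords.append(Chord(i, j, w, chord_alpha(d), arcs[i - 1]))
    else:
        if L is None:
            L = source.target_length or source.max_index()
        arcs = _diagonal_colors(L, ss)
        ranked = sorted(source.pairs, key=lambda p: (-p[2], p[0], p[1]))[: 2 * L]
        chords = []
        for i, j, conf in ranked:
            if conf <= 0:
                continue
            chords.append(
                Chord(i, j, MAX_CHORD_WIDTH * conf, 0.1 + 0.9 * conf, arcs[i - 1])
            )
    return ChordSpec(arcs, chords)


def _render_heatmap(spec: HeatmapSpec, path: Path) -> None:
    if spec.upper_kind == "error":
        cmap = plt.get_cmap("magma")
        norm = Normalize(0.0, DISTANCE_CAP - DISTANCE_FLOOR)
    else:
        cmap, norm = scheme_cmap(spec.scheme, spec.upper_kind)
    cmap = cmap.copy()
    cmap.set_bad("white")

    if spec.rotated:
        fig, ax = plt.subplots(figsize=(10.0, 7.2))
    else:
        fig, ax = plt.subplots(figsize=(8.0, 8.0))
    values = np.ma.masked_invalid(spec.values)
    if spec.rotated:
        from matplotlib.transforms import Affine2D

        tr = Affine2D().rotate_deg(-45) + ax.transData
        im = ax.imshow(values, cmap=cmap, norm=norm, interpolation="nearest")
        im.set_transform(tr)
        L = spec.L
        ax.set_xlim(-1, L * np.sqrt(2) + 1)
        ax.set_ylim(-L / np.sqrt(2) - 1, L / np.sqrt(2) + 1)
        ax.set_aspect("auto")
    else:
        ax.imshow(values, cmap=cmap, norm=norm, interpolation="nearest")
    # diagonal SS / gradient band
    for k, color in enumerate(spec.diagonal):
        if spec.rotated:
            continue  # the band is drawn by the rotated diagonal cells themselves
        ax.add_patch(
            plt.Rectangle((k - 0.5, k - 0.5), 1, 1, facecolor=color, edgecolor="none")
        )
    ax.set_xlabel("residue j")
    ax.set_ylabel("residue i")
    fig.colorbar(plt.cm.ScalarMappable(norm=norm, cmap=cmap), ax=ax, shrink=0.8)
    _save(fig, path)


def _render_chord(spec: ChordSpec, path: Path) -> None:
    from matplotlib.patches import Path as MplPath
    from matplotlib.patches import PathPatch, Wedge

    fig, ax = plt.subplots(figsize=(8.0, 8.0))
    L = max(spec.L, 1)
    angles = np.linspace(90, 90 - 360, L + 1)  # clockwise from top

    def point(idx: int) -> np.ndarray:
        a = np.deg2rad((angles[idx - 1] + angles[idx]) / 2.0)
        return np.array([np.cos(a), np.sin(a)])

    for k, color in enumerate(spec.arc_colors):
        ax.add_patch(
            Wedge(
                (0, 0), 1.05, min(angles[k], angles[k + 1]),
                max(angles[k], angles[k + 1]), width=0.05,
                facecolor=color, edgecolor="0.3", linewidth=0.2,
            )
        )
    for chord in spec.chords:
        p0, p1 = point(chord.i), point(chord.j)
        path_data = MplPath(
            [p0, (0.0, 0.0), p1],
            [MplPath.MOVETO, MplPath.CURVE3, MplPath.CURVE3],
        )
        ax.add_patch(
            PathPatch(
                path_data, fill=False, edgecolor=chord.color,
                linewidth=chord.width, alpha=chord.alpha, capstyle="round",
            )
        )
    ax.set_xlim(-1.15, 1.15)
    ax.set_ylim(-1.15, 1.15)
    ax.set_aspect("equal")
    ax.axis("off")
    _save(fig, path)


def _save(fig, path: Path) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    if path.suffix.lower() == ".svg":
        fig.savefig(path, metadata={"Date": None})
    else:
        fig.savefig(path, dpi=100)
    plt.close(fig)


def render(spec: HeatmapSpec | ChordSpec, path: str | Path) -> Path:
    """Render a spec to a PNG or SVG file; deterministic for a fixed spec."""
    path = Path(path)
    if isinstance(spec, HeatmapSpec):
        _render_heatmap(spec, path)
    elif isinstance(spec, ChordSpec):
        _render_chord(spec, path)
    else:
        raise TypeError(f"cannot render {type(spec).__name__}")
    return path
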