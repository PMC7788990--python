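"""Conversions from binned distograms to distance maps and contact rankings."""

from __future__ import annotations

import logging

import numpy as np

from .formats import ContactPrediction, Distogram
from .geometry import DistanceMap

logger = logging.getLogger(__name__)

__all__ = ["bin_midpoints", "flatten_distogram", "distogram_to_contacts"]

#: Representative distance assigned to the open final bin, in Angstroms beyond
#: its lower edge.  Anything past 20 A is masked by standardization anyway, so
#: only the beyond-cap semantics matter.
OPEN_BIN_OFFSET = 1.0


def bin_midpoints(edges: np.ndarray) -> np.ndarray:
    """Representative distance of each bin: finite-bin midpoints, plus
    ``last_edge + 1`` for the open final bin."""
    edges = np.asarray(edges, dtype=float)
    mids = np.empty(len(edges))
    mids[:-1] = (edges[:-1] + edges[1:]) / 2.0
    mids[-1] = edges[-1] + OPEN_BIN_OFFSET
    return mids


def flatten_distogram(dg: Distogram, L: int | None = None) -> DistanceMap:
    """Flatten a distogram to a distance map via the most-confident bin.

    Each pair's distance is the midpoint of its argmax-probability bin; ties
    break toward the lower-distance bin.  All-zero rows are masked with a
    warning.  ``L`` defaults to the distogram's declared target length or the
    largest residue index seen.
    """
    if L is None:
        L = dg.target_length or dg.max_index()
    if dg.max_index() > L:
        raise ValueError(
            f"distogram references residue {dg.max_index()} beyond length {L}"
        )
    mids = bin_midpoints(dg.bin_edges)
    values = np.full((L, L), np.nan)
    mask = np.zeros((L, L), dtype=bool)
    # np.argmax returns the first maximum, i.e. the lower-distance bin on ties
    best = np.argmax(dg.probs, axis=1)
    row_max = dg.probs.max(axis=1)
    n_zero = 0
    for (i, j), b, m in zip(dg.pairs, best, row_max):
        if m <= 0.0:
            n_zero += 1
            continue
        d = mids[b]
        values[i - 1, j - 1] = values[j - 1, i - 1] = d
        mask[i - 1, j - 1] = mask[j - 1, i - 1] = True
    if n_zero:
        logger.warning("masked %d all-zero distogram rows during flattening", n_zero)
    return DistanceMap(values, mask)


def distogram_to_contacts(dg: Distogram, threshold: float = 8.0) -> ContactPrediction:
    """Extract contact confidences: total probability mass below ``threshold``.

    Requires ``threshold`` to be one of the bin edges — no partial-bin
    interpolation is attempted.
    """
    edge_idx = np.flatnonzero(np.isclose(dg.bin_edges, threshold))
    if edge_idx.size == 0:
        raise ValueError(
            f"{threshold} A is not a bin boundary of edges {dg.bin_edges.tolist()}; "
            "contact extraction needs an exact edge"
        )
    k = int(edge_idx[0])  # bins 0..k-1 have upper edge <= threshold
    conf = dg.probs[:, :k].sum(axis=1)
    conf = np.clip(conf, 0.0, 1.0)
    pairs = [(i, j, float(c)) for (i, j), c in zip(dg.pairs, conf)]
    return ContactPrediction(pairs, target_length=dg.target_length)
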