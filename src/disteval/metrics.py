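"""Quantitative evaluation of predicted distances and contacts.

All metrics consult only the upper triangle (i < j) of distance maps, exclude
pairs touching masked cells from their denominators, and report an explicit
``None`` (never 0) when their pair set is empty.

Conventions baked in here:

* A *contact* is a true representative-atom distance < 8 A.
* MAE / RMSE / PCC restrict to pairs whose TRUE distance is <= 20 A.
* LDDT uses inclusion radius 15 A on true distances, tolerance thresholds
  {0.5, 1, 2, 4} A, and a global pair-averaged formulation; pairs whose
  prediction is masked count as not preserved.
* top-L/5 takes max(1, floor(L/5)) pairs; L = min(sequence length, number of
  valid residues).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

from .formats import ContactPrediction, Distogram
from .geometry import (
    DistanceMap,
    ProteinRecord,
    SeparationClass,
    effective_length,
    true_distance_map,
)

__all__ = [
    "CONTACT_THRESHOLD",
    "DISTANCE_CAP",
    "DISTANCE_FLOOR",
    "LDDT_INCLUSION_RADIUS",
    "LDDT_TOLERANCES",
    "MetricValue",
    "EvaluationReport",
    "standardize",
    "mae",
    "rmse",
    "pcc_distances",
    "lddt",
    "distances_to_contact_ranking",
    "precision_topk",
    "evaluate",
]

CONTACT_THRESHOLD = 8.0
DISTANCE_CAP = 20.0
DISTANCE_FLOOR = 3.5
LDDT_INCLUSION_RADIUS = 15.0
LDDT_TOLERANCES = (0.5, 1.0, 2.0, 4.0)

_CLASS_BOUNDS = {
    SeparationClass.LOCAL: (1, 5),
    SeparationClass.SHORT: (6, 11),
    SeparationClass.MEDIUM: (12, 23),
    SeparationClass.LONG: (24, None),
}


def standardize(dmap: DistanceMap) -> DistanceMap:
    """Clamp a distance map to the comparable [3.5, 20] A range.

    Values below 3.5 A are ceiled to 3.5; values above 20 A are masked.  The
    transform is idempotent.
    """
    values = dmap.values.copy()
    mask = dmap.mask.copy()
    with np.errstate(invalid="ignore"):
        mask &= ~(values > DISTANCE_CAP)
        values = np.where(mask & (values < DISTANCE_FLOOR), DISTANCE_FLOOR, values)
    return DistanceMap(values, mask)


def _sep_matrix(L: int) -> np.ndarray:
    idx = np.arange(L)
    return np.abs(idx[:, None] - idx[None, :])


def _class_mask(L: int, classes) -> np.ndarray:
    sep = _sep_matrix(L)
    out = np.zeros((L, L), dtype=bool)
    for cls in classes:
        lo, hi = _CLASS_BOUNDS[cls]
        m = sep >= lo
        if hi is not None:
            m &= sep <= hi
        out |= m
    return out


def _eligible_errors(pred: DistanceMap, true: DistanceMap, classes):
    """Upper-triangle (pred, true) value pairs eligible for MAE/RMSE/PCC."""
    if pred.L != true.L:
        raise ValueError(f"shape mismatch: pred L={pred.L}, true L={true.L}")
    L = true.L
    iu, ju = np.triu_indices(L, k=1)
    keep = (
        pred.mask[iu, ju]
        & true.mask[iu, ju]
        & _class_mask(L, classes)[iu, ju]
        & (true.values[iu, ju] <= DISTANCE_CAP)
    )
    return pred.values[iu, ju][keep], true.values[iu, ju][keep]


def mae(pred: DistanceMap, true: DistanceMap, classes) -> tuple[float | None, int]:
    """Mean absolute error over eligible pairs; ``(None, 0)`` if none."""
    p, t = _eligible_errors(pred, true, classes)
    if p.size == 0:
        return None, 0
    return float(np.mean(np.abs(p - t))), int(p.size)


def rmse(pred: DistanceMap, true: DistanceMap, classes) -> tuple[float | None, int]:
    """Root mean squared error over eligible pairs; ``(None, 0)`` if none."""
    p, t = _eligible_errors(pred, true, classes)
    if p.size == 0:
        return None, 0
    return float(np.sqrt(np.mean((p - t) ** 2))), int(p.size)


def pcc_distances(
    pred: DistanceMap, true: DistanceMap, classes
) -> tuple[float | None, int]:
    """Pearson correlation between predicted and true eligible distances."""
    from scipy.stats import pearsonr

    p, t = _eligible_errors(pred, true, classes)
    if p.size < 3 or np.std(p) == 0 or np.std(t) == 0:
        return None, int(p.size)
    r = pearsonr(p, t).statistic
    return float(r), int(p.size)


def lddt(
    pred: DistanceMap, true: DistanceMap, min_sep: int
) -> tuple[float | None, int]:
    """Local distance difference test on representative-atom distances.

    Reference pairs: unmasked true upper-triangle pairs with ``|i-j| >=
    min_sep`` and true distance < 15 A.  Score: fraction of reference pairs
    preserved within each tolerance in {0.5, 1, 2, 4} A, averaged over the
    four tolerances.  A masked prediction preserves nothing.
    """
    if pred.L != true.L:
        raise ValueError(f"shape mismatch: pred L={pred.L}, true L={true.L}")
    L = true.L
    iu, ju = np.triu_indices(L, k=1)
    sep = (ju - iu) >= min_sep
    ref = true.mask[iu, ju] & sep & (true.values[iu, ju] < LDDT_INCLUSION_RADIUS)
    n_ref = int(ref.sum())
    if n_ref == 0:
        return None, 0
    err = np.abs(pred.values[iu, ju][ref] - true.values[iu, ju][ref])
    pred_ok = pred.mask[iu, ju][ref]
    # integer hit counting with a single final division keeps the score exact
    hits = 0
    for tol in LDDT_TOLERANCES:
        hits += int(np.count_nonzero(pred_ok & (err < tol)))
    return hits / (len(LDDT_TOLERANCES) * n_ref), n_ref


def distances_to_contact_ranking(
    pred: DistanceMap, contact_threshold: float = CONTACT_THRESHOLD
) -> ContactPrediction:
    """Translate a distance prediction into ranked predicted contacts.

    Only pairs predicted below the contact threshold are predicted contacts
    (a 15 A prediction is not a contact call), ranked by ascending distance.
    The stored confidence is ``(20 - clamp(d, 3.5, 20)) / 16.5`` so it lands
    in [0, 1] and is monotone decreasing in distance; ranking ties break
    lexicographically on (i, j).
    """
    pairs = []
    for i, j, d in pred.upper_pairs():
        if d >= contact_threshold:
            continue
        conf = (DISTANCE_CAP - np.clip(d, DISTANCE_FLOOR, DISTANCE_CAP)) / (
            DISTANCE_CAP - DISTANCE_FLOOR
        )
        pairs.append((i, j, float(conf)))
    return ContactPrediction(pairs, target_length=pred.L)


def _ranked(pred: ContactPrediction) -> list[tuple[int, int, float]]:
    # confidence descending, ties lexicographic on (i, j)
    return sorted(pred.pairs, key=lambda p: (-p[2], p[0], p[1]))


def precision_topk(
    pred: ContactPrediction,
    true: DistanceMap,
    classes,
    k_mode: str,
    L: int,
) -> tuple[float | None, int]:
    """Precision of the top-k most confident predicted contacts.

    ``k_mode`` is ``"topL5"`` (k = max(1, floor(L/5))) or ``"topL"`` (k = L).
    Predicted pairs are filtered to the requested separation classes and to
    pairs with an evaluable (unmasked) true distance before the top k are
    taken, so unevaluable predictions consume no slot.  Precision is the
    fraction of the taken pairs with true distance < 8 A.
    """
    if k_mode == "topL5":
        k = max(1, L // 5)
    elif k_mode == "topL":
        k = L
    else:
        raise ValueError(f"unknown k_mode {k_mode!r}")

    allowed = _class_mask(true.L, classes)
    taken = []
    for i, j, conf in _ranked(pred):
        if j > true.L:
            continue
        a, b = i - 1, j - 1
        if not allowed[a, b] or not true.mask[a, b]:
            continue
        taken.append(true.values[a, b])
        if len(taken) == k:
            break
    if not taken:
        return None, 0
    hits = sum(1 for d in taken if d < CONTACT_THRESHOLD)
    return hits / len(taken), len(taken)


@dataclass
class MetricValue:
    """A metric value with the pair count it was computed over."""

    value: float | None
    n: int

    @property
    def applicable(self) -> bool:
        return self.value is not None


_NA = MetricValue(None, 0)

REPORT_FIELDS = (
    "mae_long",
    "mae_medium_long",
    "rmse_long",
    "rmse_medium_long",
    "pcc_medium_long",
    "lddt_sep6",
    "lddt_sep12",
    "lddt_sep24",
    "precision_topL5_long",
    "precision_topL_long",
    "precision_topL5_medlong",
    "precision_topL_medlong",
)


@dataclass
class EvaluationReport:
    """Named metric values plus the pair count each was computed over."""

    L: int
    metrics: dict[str, MetricValue] = field(default_factory=dict)

    def __getitem__(self, key: str) -> MetricValue:
        return self.metrics[key]

    def to_dict(self) -> dict:
        return {
            "L": self.L,
            "metrics": {
                k: {"value": v.value, "n": v.n} for k, v in self.metrics.items()
            },
        }

    def to_json(self, indent: int = 2) -> str:
        return json.dumps(self.to_dict(), indent=indent)

    def to_text(self) -> str:
        width = max(len(k) for k in self.metrics)
        lines = [f"{'L':<{width}}  {self.L}"]
        for k in REPORT_FIELDS:
            if k not in self.metrics:
                continue
            v = self.metrics[k]
            shown = "n/a" if v.value is None else f"{v.value:.4f}"
            lines.append(f"{k:<{width}}  {shown:>8}  (n={v.n})")
        return "\n".join(lines) + "\n"


def evaluate(
    pred: ContactPrediction | DistanceMap | Distogram,
    structure: ProteinRecord,
) -> EvaluationReport:
    """Compute the full metric report for any supported prediction kind.

    Distograms are both flattened (distance metrics) and reduced to contact
    confidences (precision metrics).  Distance maps are additionally ranked
    into contacts.  Contact-only inputs produce precision metrics only, with
    distance fields marked not-applicable.
    """
    from .distogram_ops import distogram_to_contacts, flatten_distogram
    from .geometry import LONG_ONLY, MEDIUM_LONG

    true = true_distance_map(structure)
    L = effective_length(len(structure), structure.n_valid)

    dist_map: DistanceMap | None = None
    contacts: ContactPrediction
    if isinstance(pred, Distogram):
        n = pred.target_length or pred.max_index()
        if n != len(structure):
            raise ValueError(
                f"length mismatch: prediction covers {n} residues, "
                f"structure has {len(structure)}"
            )
        dist_map = flatten_distogram(pred, L=len(structure))
        contacts = distogram_to_contacts(pred)
    elif isinstance(pred, DistanceMap):
        if pred.L != len(structure):
            raise ValueError(
                f"length mismatch: prediction covers {pred.L} residues, "
                f"structure has {len(structure)}"
            )
        dist_map = pred
        contacts = distances_to_contact_ranking(pred)
    elif isinstance(pred, ContactPrediction):
        if pred.max_index() > len(structure):
            raise ValueError(
                f"length mismatch: prediction references residue "
                f"{pred.max_index()}, structure has {len(structure)}"
            )
        contacts = pred
    else:
        raise TypeError(f"unsupported prediction type {type(pred).__name__}")

    report = EvaluationReport(L=L)
    m = report.metrics
    if dist_map is not None:
        m["mae_long"] = MetricValue(*mae(dist_map, true, LONG_ONLY))
        m["mae_medium_long"] = MetricValue(*mae(dist_map, true, MEDIUM_LONG))
        m["rmse_long"] = MetricValue(*rmse(dist_map, true, LONG_ONLY))
        m["rmse_medium_long"] = MetricValue(*rmse(dist_map, true, MEDIUM_LONG))
        m["pcc_medium_long"] = MetricValue(*pcc_distances(dist_map, true, MEDIUM_LONG))
        m["lddt_sep6"] = MetricValue(*lddt(dist_map, true, 6))
        m["lddt_sep12"] = MetricValue(*lddt(dist_map, true, 12))
        m["lddt_sep24"] = MetricValue(*lddt(dist_map, true, 24))
    else:
        for k in REPORT_FIELDS[:8]:
            m[k] = _NA
    m["precision_topL5_long"] = MetricValue(
        *precision_topk(contacts, true, LONG_ONLY, "topL5", L)
    )
    m["precision_topL_long"] = MetricValue(
        *precision_topk(contacts, true, LONG_ONLY, "topL", L)
    )
    m["precision_topL5_medlong"] = MetricValue(
        *precision_topk(contacts, true, MEDIUM_LONG, "topL5", L)
    )
    m["precision_topL_medlong"] = MetricValue(
        *precision_topk(contacts, true, MEDIUM_LONG, "topL", L)
    )
    return report
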