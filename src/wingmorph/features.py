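"""Dataset-level feature extraction: shared harmonic count, shape
matrix and size vector for a SpecimenTable."""

from __future__ import annotations

import numpy as np

from . import efa
from .errors import InputValidationError
from .io_contours import SpecimenTable

__all__ = ["global_harmonics", "extract_features"]


def global_harmonics(table: SpecimenTable, threshold: float = 0.9999,
                     fixed_K: int | None = None) -> int:
    """Shared harmonic count for a dataset.

    Shape vectors must have one common length, so the per-specimen
    cumulative-power choice is aggregated as the maximum over specimens,
    capped at the smallest contour's harmonic ceiling.  A ``fixed_K``
    overrides the power criterion.
    """
    if len(table) == 0:
        raise InputValidationError("empty specimen table")
    cap = min(efa.max_harmonics(r.contour) for r in table)
    if fixed_K is not None:
        if not (1 <= fixed_K <= cap):
            raise InputValidationError(
                f"fixed K={fixed_K} outside [1, {cap}] for this dataset"
            )
        return fixed_K
    K = max(efa.choose_harmonics(r.contour, threshold) for r in table)
    return min(K, cap)


def extract_features(table: SpecimenTable, K: int):
    """Per-record size (mm) and normalized shape vectors at harmonic
    count K.

    Returns ``(groups, specimen_ids, sizes, shapes)`` where ``shapes``
    is an (M, 4K-3) matrix aligned with the table's record order.
    """
    sizes = np.empty(len(table))
    shapes = np.empty((len(table), 4 * K - 3))
    groups, ids = [], []
    for i, r in enumerate(table):
        coeffs = efa.compute_efa(r.contour, K)
        ns = efa.normalize(coeffs)
        sizes[i] = ns.size_mm
        shapes[i] = ns.vector
        groups.append(r.group)
        ids.append(r.specimen_id)
    return np.array(groups), np.array(ids), sizes, shapes
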