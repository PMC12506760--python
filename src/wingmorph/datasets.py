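"""Published reference tables for the four Thai *Lutzia* species.

A published outline-based wing morphometric study of the four *Lutzia*
mosquito species occurring in Thailand (*Lt. chiangmaiensis*,
*Lt. fuscana*, *Lt. halifaxii*, *Lt. vorax*; 128 specimens) reports,
for each of the four wing elements, the per-group correct counts of the
jackknife classifications based on size and on shape, together with the
chance-corrected (adjusted) total assignment accuracies.  The counts
are inputs for the accuracy arithmetic; the raw wing contours were not
deposited.
"""

from __future__ import annotations

from .size_stats import ClassificationReport

__all__ = [
    "LUTZIA_SPECIES",
    "LUTZIA_GROUP_SIZES",
    "SIZE_CLASSIFICATION_CORRECT",
    "SHAPE_CLASSIFICATION_CORRECT",
    "PUBLISHED_ADJUSTED_PCT",
    "lutzia_classification_report",
]

LUTZIA_SPECIES = (
    "Lt_chiangmaiensis",
    "Lt_fuscana",
    "Lt_halifaxii",
    "Lt_vorax",
)

#: Specimens per species (N = 128).
LUTZIA_GROUP_SIZES = (30, 41, 35, 22)

#: Correctly reassigned specimens per species, jackknife classification
#: on global size, per wing element (species order as above).
SIZE_CLASSIFICATION_CORRECT = {
    "wing_contour": (10, 6, 19, 16),
    "second_submarginal": (17, 4, 4, 20),
    "first_posterior": (14, 5, 8, 19),
    "third_posterior": (16, 9, 6, 14),
}

#: Same, for the jackknife classification on shape (Mahalanobis rule).
SHAPE_CLASSIFICATION_CORRECT = {
    "wing_contour": (15, 29, 22, 14),
    "second_submarginal": (20, 16, 18, 14),
    "first_posterior": (8, 26, 11, 16),
    "third_posterior": (19, 36, 26, 20),
}

#: Published adjusted total assignment accuracies (percent).
PUBLISHED_ADJUSTED_PCT = {
    "size": {
        "wing_contour": 19,
        "second_submarginal": 12,
        "first_posterior": 13,
        "third_posterior": 12,
    },
    "shape": {
        "wing_contour": 49,
        "second_submarginal": 36,
        "first_posterior": 29,
        "third_posterior": 71,
    },
}


def lutzia_classification_report(kind: str, element: str) -> ClassificationReport:
    """ClassificationReport built from the published per-group correct
    counts (``kind`` is ``"size"`` or ``"shape"``)."""
    counts = {
        "size": SIZE_CLASSIFICATION_CORRECT,
        "shape": SHAPE_CLASSIFICATION_CORRECT,
    }[kind][element]
    return ClassificationReport.from_counts(
        LUTZIA_SPECIES, LUTZIA_GROUP_SIZES, counts
    )
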