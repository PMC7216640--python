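"""Seven-way homeolog expression bias categories (HEBC) in ternary space.

Each triad's composition (A%, B%, D%) is a point on the 2-simplex. It is
assigned to the nearest of seven ideal compositions by Euclidean distance on
the fraction scale:

    balanced      (1/3, 1/3, 1/3)
    A-dominant    (1, 0, 0)        B-dominant  (0, 1, 0)   D-dominant (0, 0, 1)
    A-suppressed  (0, 1/2, 1/2)    B-suppressed (1/2, 0, 1/2)
    D-suppressed  (1/2, 1/2, 0)

Distances are measured on the 3-vector of fractions rather than on the
projected ternary-plot plane; the two differ only by a fixed isometry up to
scale, so the nearest centroid is the same either way. Ties (measure zero on
real data, but reachable on grid-like synthetic compositions) are broken by
the fixed centroid order above. This is plain hard nearest-centroid
assignment, without fuzzy or expression-level refinements.
"""

from __future__ import annotations

import math

import numpy as np
import pandas as pd

#: category order is the tie-break order
CATEGORIES = (
    "balanced",
    "A-dominant",
    "B-dominant",
    "D-dominant",
    "A-suppressed",
    "B-suppressed",
    "D-suppressed",
)

SHORT_LABELS = {
    "balanced": "Bal",
    "A-dominant": "A-D",
    "B-dominant": "B-D",
    "D-dominant": "D-D",
    "A-suppressed": "A-S",
    "B-suppressed": "B-S",
    "D-suppressed": "D-S",
}

CENTROIDS = np.array(
    [
        [1 / 3, 1 / 3, 1 / 3],
        [1.0, 0.0, 0.0],
        [0.0, 1.0, 0.0],
        [0.0, 0.0, 1.0],
        [0.0, 0.5, 0.5],
        [0.5, 0.0, 0.5],
        [0.5, 0.5, 0.0],
    ]
)

_SQRT3_2 = math.sqrt(3.0) / 2.0

HEBC_COLUMNS = ["triad_id", "condition", "category", "distance", "x", "y"]


def classify_composition(fractions: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Nearest-centroid labels and distances for an (n, 3) array of fractions."""
    fractions = np.atleast_2d(np.asarray(fractions, dtype=float))
    if fractions.shape[1] != 3:
        raise ValueError("compositions must have three components (A, B, D)")
    # (n, 7) distance matrix; argmin returns the first minimum -> fixed tie-break
    d = np.linalg.norm(fractions[:, None, :] - CENTROIDS[None, :, :], axis=2)
    idx = d.argmin(axis=1)
    labels = np.array(CATEGORIES, dtype=object)[idx]
    return labels, d[np.arange(len(idx)), idx]


def classify_hebc(revs: pd.DataFrame) -> pd.DataFrame:
    """Assign every REV record to its bias category.

    Takes the output of :func:`triadbias.rev_analysis.compute_rev` and returns
    one row per triad x condition with the category, the distance to the
    chosen centroid (fraction scale) and the ternary plot coordinates.
    """
    fractions = revs[["a_pct", "b_pct", "d_pct"]].to_numpy(float) / 100.0
    labels, dist = classify_composition(fractions)
    x, y = ternary_coordinates(fractions)
    return pd.DataFrame(
        {
            "triad_id": revs["triad_id"].to_numpy(),
            "condition": revs["condition"].to_numpy(),
            "category": labels,
            "distance": dist,
            "x": x,
            "y": y,
        },
        columns=HEBC_COLUMNS,
    )


def ternary_coordinates(fractions: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Barycentric -> Cartesian map with vertices A=(0,0), B=(1,0), D=(1/2, √3/2).

    x = b + d/2, y = d·√3/2 for a composition (a, b, d) of fractions. The map
    is injective on the simplex and every image lies in the unit triangle.
    """
    fractions = np.atleast_2d(np.asarray(fractions, dtype=float))
    b = fractions[:, 1]
    d = fractions[:, 2]
    return b + d / 2.0, d * _SQRT3_2


def hebc_change(
    control: pd.DataFrame, stress: pd.DataFrame
) -> tuple[pd.DataFrame, float, int]:
    """Compare per-triad categories between conditions.

    Returns (changes table, fraction changed, number of triads present in only
    one condition and therefore excluded).
    """
    c = control.set_index("triad_id")["category"]
    s = stress.set_index("triad_id")["category"]
    shared = c.index.intersection(s.index)
    n_excluded = (len(c) - len(shared)) + (len(s) - len(shared))
    if len(shared) == 0:
        raise ValueError("no triads shared between control and stress assignments")
    changes = pd.DataFrame(
        {
            "triad_id": shared,
            "category_control": c.loc[shared].to_numpy(),
            "category_stress": s.loc[shared].to_numpy(),
        }
    )
    changes["changed"] = changes["category_control"] != changes["category_stress"]
    fraction = float(changes["changed"].mean())
    return changes.reset_index(drop=True), fraction, n_excluded


def hebc_summary(assignments: pd.DataFrame) -> pd.DataFrame:
    """Count and percentage of each of the seven categories.

    Percentages are of the rows passed in (typically one condition at a time)
    and always sum to 100.
    """
    if assignments.empty:
        raise ValueError("no assignments to summarize")
    counts = assignments["category"].value_counts()
    total = int(counts.sum())
    rows = [
        {
            "category": cat,
            "count": int(counts.get(cat, 0)),
            "percentage": 100.0 * counts.get(cat, 0) / total,
        }
        for cat in CATEGORIES
    ]
    return pd.DataFrame(rows)
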