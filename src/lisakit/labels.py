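"""Categorical cluster labels per method, and cross-method aggregation.

Per-method labels follow the usual LISA conventions: Local Moran's I splits
significant results into cluster ("high-high", "low-low") and outlier
("high-low", "low-high") quadrants by the signs of the focal z value and
its spatial lag; Local Geary's C distinguishes significant positive spatial
autocorrelation (lower tail: "high-high", "low-low", or "other-positive"
when the quadrant signs disagree) from "negative" (upper tail); the
Getis-Ord statistics yield "hot-spot" (significant upper tail) and
"cold-spot" (significant lower tail).

The aggregate assignment canonicalizes labels (hot-spot = high value
cluster, cold-spot = low value cluster) and reports a consensus category
with an agreement score, flagging genuine contradictions (one method
claiming a high cluster while another claims a low cluster).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .inference import PermutationResult

NOT_SIGNIFICANT = "not-significant"
UNDEFINED = "undefined"

LEGAL_LABELS = {
    "local_moran": {"high-high", "low-low", "high-low", "low-high", NOT_SIGNIFICANT, UNDEFINED},
    "local_geary": {"high-high", "low-low", "other-positive", "negative", NOT_SIGNIFICANT, UNDEFINED},
    "gi": {"hot-spot", "cold-spot", NOT_SIGNIFICANT, UNDEFINED},
    "gi_star": {"hot-spot", "cold-spot", NOT_SIGNIFICANT, UNDEFINED},
}

#: canonical classes used for aggregation and agreement
_CANON = {
    "high-high": "HIGH",
    "hot-spot": "HIGH",
    "low-low": "LOW",
    "cold-spot": "LOW",
    "high-low": "OUTLIER",
    "low-high": "OUTLIER",
    "other-positive": "SIMILAR",  # positive SA, direction unspecified
    "negative": "COMPATIBLE",  # negative SA, compatible with outliers
    NOT_SIGNIFICANT: "NONE",
}

#: canonical label equivalence for cross-method / cross-time agreement
EQUIVALENT = {"hot-spot": "high-high", "cold-spot": "low-low"}


def canonical_label(label: str) -> str:
    """Map hot-spot/cold-spot onto their high-high/low-low equivalents."""
    return EQUIVALENT.get(label, label)


def _sig(res: PermutationResult | None, alpha: float) -> bool:
    # degenerate nulls (sd(S) == 0, standardized undefined) are never significant
    return res is not None and res.pseudo_p <= alpha and np.isfinite(res.standardized)


def label_local_moran(
    res: PermutationResult | None, z_i: float, lag_i: float, alpha: float
) -> str:
    """Quadrant label for a Local Moran result at one location."""
    if res is None or not np.isfinite(lag_i):
        return UNDEFINED
    if not _sig(res, alpha):
        return NOT_SIGNIFICANT
    # sign of I_i == sign of z*lag; exactly-zero products count as clusters
    if z_i * lag_i >= 0.0:
        return "high-high" if z_i >= 0.0 else "low-low"
    return "high-low" if z_i > 0.0 else "low-high"


def label_local_geary(
    res: PermutationResult | None, z_i: float, lag_i: float, alpha: float
) -> str:
    """Label for a Local Geary result (lower tail = positive SA)."""
    if res is None or not np.isfinite(lag_i):
        return UNDEFINED
    if not _sig(res, alpha):
        return NOT_SIGNIFICANT
    if res.tail == "upper":
        return "negative"
    if z_i > 0.0 and lag_i > 0.0:
        return "high-high"
    if z_i < 0.0 and lag_i < 0.0:
        return "low-low"
    return "other-positive"


def label_getis(res: PermutationResult | None, alpha: float) -> str:
    """Hot/cold-spot label for a Gi or Gi* result."""
    if res is None:
        return UNDEFINED
    if not _sig(res, alpha):
        return NOT_SIGNIFICANT
    return "hot-spot" if res.tail == "upper" else "cold-spot"


def label_local(
    method: str,
    res: PermutationResult | None,
    z_i: float,
    lag_i: float,
    alpha: float,
) -> str:
    """Dispatch to the method's labeling rule."""
    if method == "local_moran":
        return label_local_moran(res, z_i, lag_i, alpha)
    if method == "local_geary":
        return label_local_geary(res, z_i, lag_i, alpha)
    if method in ("gi", "gi_star"):
        return label_getis(res, alpha)
    raise KeyError(f"unknown method {method!r}")


def label_global(method: str, res: PermutationResult | None, alpha: float) -> str:
    """Label for a global statistic (Moran's I, Geary's C, General G)."""
    if res is None:
        return UNDEFINED
    if not _sig(res, alpha):
        return NOT_SIGNIFICANT
    if method == "moran":
        return "positive" if res.tail == "upper" else "negative"
    if method == "geary":
        # small Geary's C = positive spatial autocorrelation
        return "positive" if res.tail == "lower" else "negative"
    if method == "general_g":
        return "high-clustering" if res.tail == "upper" else "low-clustering"
    raise KeyError(f"unknown global statistic {method!r}")


@dataclass(frozen=True)
class AggregateAssignment:
    """Cross-method consensus at one (area, time)."""

    category: str  # high | low | outlier | mixed | contradiction | none | undefined
    agreement: float  # in [0,1] for high/low/outlier; 0 for none; NaN otherwise
    n_methods: int  # enabled methods with a defined label


def aggregate_labels(labels) -> AggregateAssignment:
    """Aggregate one label per enabled method into a consensus category.

    Rules: HIGH and LOW evidence together -> contradiction; exactly one of
    {HIGH, LOW, OUTLIER} present -> that category with agreement =
    supporting/defined; several -> mixed; only unspecific significant labels
    ("other-positive", "negative") -> mixed; nothing significant -> none.
    """
    labels = list(labels)
    defined = [l for l in labels if l not in (UNDEFINED, "missing")]
    if not defined:
        return AggregateAssignment(UNDEFINED, float("nan"), 0)
    classes = [_CANON[l] for l in defined]
    counts = {c: classes.count(c) for c in set(classes)}
    primary = [c for c in ("HIGH", "LOW", "OUTLIER") if counts.get(c, 0) > 0]
    n = len(defined)
    if counts.get("HIGH", 0) and counts.get("LOW", 0):
        return AggregateAssignment("contradiction", float("nan"), n)
    if len(primary) == 1:
        cat = primary[0]
        return AggregateAssignment(cat.lower(), counts[cat] / n, n)
    if len(primary) > 1:
        return AggregateAssignment("mixed", float("nan"), n)
    if counts.get("SIMILAR", 0) or counts.get("COMPATIBLE", 0):
        return AggregateAssignment("mixed", float("nan"), n)
    return AggregateAssignment("none", 0.0, n)
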