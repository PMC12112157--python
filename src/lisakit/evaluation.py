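"""Inter-method and temporal evaluation of the cluster-label tensor.

Three summaries of the (area, time, method) label tensor:

* :func:`compare_methods` — for every unordered between-method comparison
  at one (area, time), classify the label pair as both-same / similar /
  other-not-significant / contrasting, and break the fractions down by
  involved label (plus the full pairwise matrix P(L, L')).
* :func:`final_time_agreement` — for each location, does the label at lag k
  before the final time match the final-time label?
* :func:`label_cooccurrence` — per method, Q(L, L') = fraction of locations
  ever assigned L that were assigned L' at some other time point.

Agreement always uses canonical label equality (hot-spot = high-high,
cold-spot = low-low).  Undefined / missing labels are dropped from all
denominators.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import pandas as pd

from .errors import ConfigError
from .labels import NOT_SIGNIFICANT, UNDEFINED, canonical_label

COMPARISON_CATEGORIES = ["both-same", "similar", "other-not-significant", "contrasting"]

_SIDE = {
    "high-high": "cluster",
    "low-low": "cluster",
    "other-positive": "cluster",
    "high-low": "outlier",
    "low-high": "outlier",
    "negative": "outlier",
}


@dataclass(frozen=True)
class LabelTensor:
    """Long (area, time, method) -> label table with fixed orders."""

    labels: pd.DataFrame  # columns: area_id, time, method, label
    methods: list[str]
    times: list[str]

    @classmethod
    def from_results(cls, local_df: pd.DataFrame, methods: list[str], times: list[str]):
        cols = ["area_id", "time", "method", "label"]
        return cls(labels=local_df[cols].copy(), methods=list(methods), times=list(times))

    def defined(self) -> pd.DataFrame:
        """Rows with an analyzable label (drops undefined / missing cells)."""
        ok = ~self.labels["label"].isin([UNDEFINED, "missing"])
        return self.labels[ok]


def classify_pair(a: str, b: str) -> str:
    """Classify one unordered between-method label pair.

    Labels are compared after canonical equivalence.  "contrasting" means a
    high cluster against a low cluster, or a cluster-type label against an
    outlier-type label; "similar" covers significant, non-identical,
    non-contradictory pairs (e.g. high-high vs other-positive, or negative
    vs low-high).
    """
    a, b = canonical_label(a), canonical_label(b)
    if a == b:
        return "both-same"
    if a == NOT_SIGNIFICANT or b == NOT_SIGNIFICANT:
        return "other-not-significant"
    if _SIDE[a] != _SIDE[b]:
        return "contrasting"
    if {a, b} == {"high-high", "low-low"}:
        return "contrasting"
    return "similar"


@dataclass(frozen=True)
class ComparisonBreakdown:
    """Fractions of comparison categories, per involved label."""

    fractions: pd.DataFrame  # index: label; columns: COMPARISON_CATEGORIES
    pairwise: pd.DataFrame  # P(L, L'): rows sum to 1
    totals: pd.Series  # comparisons involving each label

    def to_tidy(self) -> pd.DataFrame:
        rows = []
        for label in self.fractions.index:
            for cat in COMPARISON_CATEGORIES:
                rows.append(
                    {
                        "label": label,
                        "category": cat,
                        "fraction": self.fractions.loc[label, cat],
                        "n_comparisons": int(self.totals[label]),
                    }
                )
        return pd.DataFrame(rows)


def compare_methods(tensor: LabelTensor) -> ComparisonBreakdown:
    """Between-method comparison breakdown, pooled over all time points."""
    if len(tensor.methods) < 2:
        raise ConfigError("need at least 2 methods for inter-method comparison")
    df = tensor.defined()
    wide = df.pivot_table(
        index=["area_id", "time"], columns="method", values="label", aggfunc="first"
    )
    cat_counts: dict[str, dict[str, int]] = {}
    pair_counts: dict[str, dict[str, int]] = {}
    for m1, m2 in itertools.combinations(tensor.methods, 2):
        if m1 not in wide.columns or m2 not in wide.columns:
            continue
        sub = wide[[m1, m2]].dropna()
        for a, b in zip(sub[m1], sub[m2]):
            cat = classify_pair(a, b)
            ca, cb = canonical_label(a), canonical_label(b)
            pairs = [(ca, cb)] if ca == cb else [(ca, cb), (cb, ca)]
            for lab, other in pairs:
                cat_counts.setdefault(lab, {}).setdefault(cat, 0)
                cat_counts[lab][cat] += 1
                pair_counts.setdefault(lab, {}).setdefault(other, 0)
                pair_counts[lab][other] += 1
    labels = sorted(cat_counts)
    frac = pd.DataFrame(0.0, index=labels, columns=COMPARISON_CATEGORIES)
    totals = pd.Series(0, index=labels, dtype=int)
    for lab in labels:
        tot = sum(cat_counts[lab].values())
        totals[lab] = tot
        for cat, cnt in cat_counts[lab].items():
            frac.loc[lab, cat] = cnt / tot
    pw = pd.DataFrame(0.0, index=labels, columns=labels)
    for lab in labels:
        tot = sum(pair_counts[lab].values())
        for other, cnt in pair_counts[lab].items():
            pw.loc[lab, other] = cnt / tot
    return ComparisonBreakdown(fractions=frac, pairwise=pw, totals=totals)


def final_time_agreement(tensor: LabelTensor) -> pd.DataFrame:
    """Agreement between the final-time label and the label k steps earlier.

    Returns a tidy frame (label, lag, fraction, n) pooled over methods, with
    the lag-0 self-comparison anchor included (identically 1).
    """
    if len(tensor.times) < 2:
        raise ConfigError("need at least 2 time points for temporal agreement")
    df = tensor.defined().copy()
    df["label"] = df["label"].map(canonical_label)
    final = tensor.times[-1]
    wide = df.pivot_table(
        index=["area_id", "method"], columns="time", values="label", aggfunc="first"
    )
    if final not in wide.columns:
        raise ConfigError("no defined labels at the final time point")
    wide = wide[wide[final].notna()]
    rows = []
    T = len(tensor.times)
    for k in range(T):
        t = tensor.times[T - 1 - k]
        if t not in wide.columns:
            continue
        if k == 0:
            sub = wide[[final]].dropna()
            match = sub[final] == sub[final]  # lag-0 anchor: identically true
        else:
            sub = wide[[final, t]].dropna()
            match = sub[final] == sub[t]
        if len(sub) == 0:
            continue
        for label, grp in match.groupby(sub[final]):
            rows.append(
                {"label": label, "lag": k, "fraction": grp.mean(), "n": int(len(grp))}
            )
    return pd.DataFrame(rows)


def label_cooccurrence(tensor: LabelTensor) -> pd.DataFrame:
    """Per-method temporal label co-occurrence matrix Q(L, L').

    Q(L, L') = (# locations with L at >= 1 time and L' at >= 1 *other* time)
    / (# locations with L at >= 1 time).  Q(L, L) requires L at two or more
    distinct times.  Tidy frame: method, label, other_label, fraction, n.
    """
    if len(tensor.times) < 2:
        raise ConfigError("need at least 2 time points for co-occurrence")
    df = tensor.defined().copy()
    df["label"] = df["label"].map(canonical_label)
    rows = []
    for method, mdf in df.groupby("method"):
        counts = mdf.groupby(["area_id", "label"]).size()
        by_area: dict[str, dict[str, int]] = {}
        for (area, label), cnt in counts.items():
            by_area.setdefault(area, {})[label] = int(cnt)
        labels = sorted(mdf["label"].unique())
        base = {
            lab: [a for a, labs in by_area.items() if lab in labs] for lab in labels
        }
        for lab in labels:
            denom = len(base[lab])
            for other in labels:
                if denom == 0:
                    continue
                if lab == other:
                    num = sum(1 for a in base[lab] if by_area[a][lab] >= 2)
                else:
                    num = sum(1 for a in base[lab] if other in by_area[a])
                rows.append(
                    {
                        "method": method,
                        "label": lab,
                        "other_label": other,
                        "fraction": num / denom,
                        "n": denom,
                    }
                )
    return pd.DataFrame(rows)
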