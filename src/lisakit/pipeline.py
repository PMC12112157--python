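"""Full analysis pipeline: normalization, weights, statistics, inference,
labeling, aggregation and longitudinal evaluation.

Each time point is analyzed independently: areas with missing values are
excluded, the contiguity weights are subset and re-row-normalized over the
remaining areas, the slice is z-normalized, the enabled global and local
statistics are computed with permutation inference, and labels are
assigned and aggregated.  Everything is reproducible from the master seed:
per-location permutation streams are keyed by (seed, CRC32 of the time
label, area index), so results do not depend on iteration order, on the
enabled-method set, or on the order of time points in the input.
"""

from __future__ import annotations

import hashlib
import json
import logging
import zlib
from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import __about__
from .errors import ConfigError, DegenerateInputError, LisaError
from .evaluation import (
    ComparisonBreakdown,
    LabelTensor,
    compare_methods,
    final_time_agreement,
    label_cooccurrence,
)
from .geodata import MISSING_LABEL, SpatioTemporalDataset
from .inference import local_inference, permute_global
from .labels import UNDEFINED, aggregate_labels, label_global, label_local
from .stats import LOCAL_STATS, spatial_lag, znormalize
from .weights import WeightMatrix, add_self, contiguity_weights, row_normalize, subset_weights

logger = logging.getLogger(__name__)

METHOD_ORDER = ["local_moran", "local_geary", "gi", "gi_star"]
DEFAULT_METHODS = ("local_moran", "local_geary", "gi_star")

#: global statistic family computed alongside each local method
GLOBAL_FAMILY = {
    "local_moran": "moran",
    "local_geary": "geary",
    "gi": "general_g",
    "gi_star": "general_g",
}
_GLOBAL_STAT_ID = {"moran": 0, "geary": 1, "general_g": 2}


@dataclass(frozen=True)
class RunConfig:
    """Analysis configuration; the seed is mandatory (no silent nondeterminism)."""

    seed: int
    methods: tuple = DEFAULT_METHODS
    contiguity: str = "queen"
    permutations: int = 999
    alpha: float = 0.05
    strict_join: bool = True
    pool_comparisons: bool = True
    normalization: str = "per-time"  # or "pooled"

    def __post_init__(self) -> None:
        object.__setattr__(self, "methods", tuple(self.methods))
        unknown = [m for m in self.methods if m not in LOCAL_STATS]
        if unknown:
            raise ConfigError(f"unknown methods: {', '.join(unknown)}")
        if not self.methods:
            raise ConfigError("at least one method must be enabled")
        if not 0.0 < self.alpha < 0.5:
            raise ConfigError(f"alpha must be in (0, 0.5), got {self.alpha}")
        if self.permutations < 99:
            raise ConfigError("need at least 99 permutations")
        if self.contiguity not in ("queen", "rook"):
            raise ConfigError(f"contiguity must be queen or rook, got {self.contiguity!r}")
        if self.normalization not in ("per-time", "pooled"):
            raise ConfigError("normalization must be 'per-time' or 'pooled'")

    def ordered_methods(self) -> list[str]:
        return [m for m in METHOD_ORDER if m in self.methods]

    def to_dict(self) -> dict:
        return {
            "seed": self.seed,
            "methods": list(self.ordered_methods()),
            "contiguity": self.contiguity,
            "permutations": self.permutations,
            "alpha": self.alpha,
            "strict_join": self.strict_join,
            "pool_comparisons": self.pool_comparisons,
            "normalization": self.normalization,
        }


@dataclass
class RunResults:
    """Everything one analysis run produces."""

    local: pd.DataFrame  # area_id,time,method,statistic,...,label
    global_: pd.DataFrame  # time,statistic_name,statistic,...,label
    aggregate: pd.DataFrame  # area_id,time,category,agreement,n_methods
    methods: list[str]
    times: list[str]
    skipped_times: list[str]
    config: RunConfig

    def label_tensor(self) -> LabelTensor:
        return LabelTensor.from_results(self.local, self.methods, self.analyzed_times())

    def analyzed_times(self) -> list[str]:
        return [t for t in self.times if t not in self.skipped_times]

    def evaluations(self):
        """(ComparisonBreakdown | None, agreement frame | None, co-occurrence | None)."""
        tensor = self.label_tensor()
        if len(self.methods) < 2:
            comparison = None
        elif self.config.pool_comparisons or len(self.analyzed_times()) < 2:
            comparison = compare_methods(tensor)
        else:
            # restrict between-method comparisons to the most recent time point
            final = self.analyzed_times()[-1]
            comparison = compare_methods(
                LabelTensor(
                    labels=tensor.labels[tensor.labels["time"] == final],
                    methods=self.methods,
                    times=[final],
                )
            )
        if len(self.analyzed_times()) >= 2:
            agreement = final_time_agreement(tensor)
            cooccurrence = label_cooccurrence(tensor)
        else:
            agreement = cooccurrence = None
        return comparison, agreement, cooccurrence


def local_result_count(n_areas: int, n_times: int, n_methods: int) -> int:
    """Number of individual local results an analysis produces."""
    return int(n_areas) * int(n_times) * int(n_methods)


def _time_key(time: str) -> int:
    """Stable 31-bit key for a time label, for permutation sub-seeding."""
    return zlib.crc32(str(time).encode("utf8")) & 0x7FFFFFFF


_NAN_ROW = dict(
    statistic=np.nan,
    permutation_mean=np.nan,
    permutation_sd=np.nan,
    standardized=np.nan,
    pseudo_p=np.nan,
    significant=False,
)


def run_analysis(
    dataset: SpatioTemporalDataset,
    config: RunConfig,
    weights: WeightMatrix | None = None,
) -> RunResults:
    """Run the full per-time analysis and assemble the results tables.

    ``weights`` may be passed to reuse a precomputed contiguity matrix;
    otherwise it is built from the dataset geometries with the configured
    rule.
    """
    methods = config.ordered_methods()
    base = weights if weights is not None else contiguity_weights(
        dataset.areas, config.contiguity
    )
    if base.n != dataset.n:
        raise ConfigError("weight matrix does not match dataset size")

    pooled_z = None
    if config.normalization == "pooled":
        flat = dataset.values[np.isfinite(dataset.values)]
        if flat.size < 2 or flat.std(ddof=1) <= 0:
            raise DegenerateInputError("pooled normalization needs varying values")
        mu, sigma = flat.mean(), flat.std(ddof=1)
        pooled_z = (dataset.values - mu) / sigma

    local_rows: list[dict] = []
    global_rows: list[dict] = []
    agg_rows: list[dict] = []
    skipped: list[str] = []

    for ti, time in enumerate(dataset.times):
        col = dataset.values[:, ti]
        usable = np.flatnonzero(np.isfinite(col))
        if usable.size < 2:
            logger.warning("time %s skipped: fewer than 2 usable areas", time)
            skipped.append(time)
            continue
        try:
            if pooled_z is not None:
                z = pooled_z[usable, ti]
            else:
                z = znormalize(col[usable]).z
        except DegenerateInputError:
            logger.warning("time %s skipped: constant values", time)
            skipped.append(time)
            continue

        sub = subset_weights(base, usable)
        w_ns = row_normalize(sub)
        w_self = row_normalize(add_self(sub))
        tkey = _time_key(time)

        # global statistics for the enabled method families
        for fam in sorted({GLOBAL_FAMILY[m] for m in methods}, key=_GLOBAL_STAT_ID.get):
            try:
                res = permute_global(
                    fam,
                    w_ns,
                    z,
                    M=config.permutations,
                    seed=[config.seed, tkey, 3, _GLOBAL_STAT_ID[fam]],
                    alpha=config.alpha,
                )
            except LisaError as exc:
                logger.warning("time %s: global %s inference failed: %s", time, fam, exc)
                res = None
            row = {"time": time, "statistic_name": fam}
            if res is None:
                row.update(_NAN_ROW, label=UNDEFINED)
            else:
                row.update(
                    statistic=res.observed,
                    permutation_mean=res.permutation_mean,
                    permutation_sd=res.permutation_sd,
                    standardized=res.standardized,
                    pseudo_p=res.pseudo_p,
                    significant=res.significant,
                    label=label_global(fam, res, config.alpha),
                )
            global_rows.append(row)

        # local statistics with conditional randomization (shared draws)
        results = local_inference(
            methods,
            w_ns,
            z,
            M=config.permutations,
            seed=[config.seed, tkey, 2],
            alpha=config.alpha,
            W_self=w_self,
        )
        lag = spatial_lag(w_ns, z)
        pos_of = {int(orig): p for p, orig in enumerate(usable)}
        for i_area, area in enumerate(dataset.areas):
            aid = area.area_id
            if i_area not in pos_of:
                for m in methods:
                    local_rows.append(
                        {"area_id": aid, "time": time, "method": m,
                         **_NAN_ROW, "label": MISSING_LABEL}
                    )
                agg_rows.append(
                    {"area_id": aid, "time": time, "category": MISSING_LABEL,
                     "agreement": np.nan, "n_methods": 0}
                )
                continue
            p = pos_of[i_area]
            labels_here = []
            for m in methods:
                res = results[m][p]
                label = label_local(m, res, float(z[p]), float(lag[p]), config.alpha)
                labels_here.append(label)
                row = {"area_id": aid, "time": time, "method": m, "label": label}
                if res is None:
                    row.update(_NAN_ROW)
                else:
                    row.update(
                        statistic=res.observed,
                        permutation_mean=res.permutation_mean,
                        permutation_sd=res.permutation_sd,
                        standardized=res.standardized,
                        pseudo_p=res.pseudo_p,
                        significant=res.significant,
                    )
                local_rows.append(row)
            agg = aggregate_labels(labels_here)
            agg_rows.append(
                {"area_id": aid, "time": time, "category": agg.category,
                 "agreement": agg.agreement, "n_methods": agg.n_methods}
            )

    if not local_rows:
        raise LisaError("all time points were skipped; nothing to analyze")

    # stable (area, time, method) order
    local = pd.DataFrame(local_rows)
    aorder = {a: i for i, a in enumerate(dataset.area_ids)}
    torder = {t: i for i, t in enumerate(dataset.times)}
    morder = {m: i for i, m in enumerate(methods)}
    local = local.sort_values(
        by=["area_id", "time", "method"],
        key=lambda s: s.map({"area_id": aorder, "time": torder, "method": morder}[s.name]),
        kind="stable",
    ).reset_index(drop=True)
    aggregate = pd.DataFrame(agg_rows).sort_values(
        by=["area_id", "time"],
        key=lambda s: s.map({"area_id": aorder, "time": torder}[s.name]),
        kind="stable",
    ).reset_index(drop=True)
    global_ = pd.DataFrame(global_rows)

    return RunResults(
        local=local,
        global_=global_,
        aggregate=aggregate,
        methods=methods,
        times=list(dataset.times),
        skipped_times=skipped,
        config=config,
    )


# ---------------------------------------------------------------------------
# caching
# ---------------------------------------------------------------------------


def dataset_config_digest(dataset: SpatioTemporalDataset, config: RunConfig) -> str:
    """Deterministic content hash of (dataset, config) for cache keys."""
    h = hashlib.sha256()
    h.update(json.dumps(config.to_dict(), sort_keys=True).encode())
    h.update("|".join(dataset.area_ids).encode())
    h.update("|".join(dataset.times).encode())
    for a in dataset.areas:
        h.update(a.geometry.wkb)
    h.update(np.ascontiguousarray(dataset.values).tobytes())
    return h.hexdigest()


_CACHE_FILES = {"local": "local.csv", "global_": "global.csv", "aggregate": "aggregate.csv"}


def _read_cached_frame(path) -> pd.DataFrame:
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    for col in df.columns:
        if col in ("area_id", "time", "method", "label", "statistic_name", "category"):
            continue
        if col == "significant":
            df[col] = df[col].map({"True": True, "False": False})
        elif col == "n_methods":
            df[col] = df[col].astype(int)
        else:
            # exact round-trip parse: shortest-repr strings back to identical doubles
            df[col] = df[col].map(lambda s: float(s) if s != "" else np.nan)
    return df


def run_analysis_cached(
    dataset: SpatioTemporalDataset,
    config: RunConfig,
    store,
    weights: WeightMatrix | None = None,
) -> tuple[RunResults, bool]:
    """Memoized :func:`run_analysis`; returns (results, cache_hit).

    Results are keyed by a content digest of the dataset and configuration
    and stored as CSV under ``store``.  A corrupt entry is ignored with a
    warning and recomputed.
    """
    from pathlib import Path

    store = Path(store)
    key = dataset_config_digest(dataset, config)
    entry = store / key
    manifest = entry / "entry.json"
    if manifest.exists():
        try:
            meta = json.loads(manifest.read_text())
            frames = {
                attr: _read_cached_frame(entry / fname)
                for attr, fname in _CACHE_FILES.items()
            }
            need = {"area_id", "time", "method", "statistic", "pseudo_p", "label"}
            if not need <= set(frames["local"].columns) or len(frames["local"]) == 0:
                raise ValueError("cached local results table is malformed")
            results = RunResults(
                local=frames["local"],
                global_=frames["global_"],
                aggregate=frames["aggregate"],
                methods=meta["methods"],
                times=meta["times"],
                skipped_times=meta["skipped_times"],
                config=config,
            )
            return results, True
        except Exception as exc:  # corrupt entry: recompute
            logger.warning("ignoring corrupt cache entry %s: %s", key, exc)
    results = run_analysis(dataset, config, weights=weights)
    entry.mkdir(parents=True, exist_ok=True)
    results.local.to_csv(entry / _CACHE_FILES["local"], index=False, na_rep="")
    results.global_.to_csv(entry / _CACHE_FILES["global_"], index=False, na_rep="")
    results.aggregate.to_csv(entry / _CACHE_FILES["aggregate"], index=False, na_rep="")
    manifest.write_text(
        json.dumps(
            {
                "methods": results.methods,
                "times": results.times,
                "skipped_times": results.skipped_times,
                "config": config.to_dict(),
                "version": __about__.__version__,
            }
        )
    )
    return results, False
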