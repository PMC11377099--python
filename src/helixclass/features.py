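"""From trajectory bundles to the machine-learning feature matrix.

Each simulation is reduced to one row: after discarding the
equilibration window (by default the first 10% of the simulated span,
i.e. 10 ns of a 100 ns run) and the two base pairs at each terminus
(bases 3–23 of a 25-mer remain), every retained (base, parameter) cell
is aggregated over time with a single statistic (mean by default).
For a 25-mer this yields 17 × 21 = 357 features per duplex; replicates
stay as separate rows, so the reference-scale design of 12 sites ×
3 replicates × 2 adduct states gives a 72 × 357 matrix.

Feature columns are named ``<base>—<parameter>`` (em dash, ASCII hyphen
accepted on input), e.g. ``14—propeller``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .canal_io import (ParameterSeries, SampleMeta, TrajectoryBundle,
                       TrajectoryRecord, ValidationError)
from .registry import PARAMETER_ORDER, get_parameter

__all__ = [
    "WindowSpec",
    "FeatureMatrix",
    "CLASS4_LABELS",
    "trim_equilibration",
    "trim_termini",
    "aggregate_record",
    "build_feature_matrix",
    "feature_name",
    "parse_feature_name",
    "equilibration_window",
]

FEATURE_SEP = "—"  # em dash, as used in the field's feature tables
META_COLUMNS = ("gene", "site", "sequence", "methylated_positions",
                "adducted", "hotspot", "replicate", "dataset_tag", "class4")
CLASS4_LABELS = ("hotspot_adduct", "hotspot_control",
                 "nonhotspot_adduct", "nonhotspot_control")
AGGREGATORS = ("mean", "sd", "median")


@dataclass(frozen=True)
class WindowSpec:
    """Retained analysis window: start_time <= t (< end_time if closed)."""

    start_time: float
    end_time: float | None = None

    def __post_init__(self):
        if self.start_time < 0:
            raise ValueError("start_time must be >= 0")
        if self.end_time is not None and self.end_time <= self.start_time:
            raise ValueError("end_time must exceed start_time")

    def mask(self, times: np.ndarray) -> np.ndarray:
        m = times >= self.start_time
        if self.end_time is not None:
            m &= times < self.end_time
        return m


def equilibration_window(times: np.ndarray, fraction: float = 0.10
                         ) -> WindowSpec:
    """Window that drops the leading `fraction` of the simulated span."""
    t0, t1 = float(times[0]), float(times[-1])
    return WindowSpec(start_time=t0 + fraction * (t1 - t0))


def feature_name(base: int, parameter: str) -> str:
    return f"{base}{FEATURE_SEP}{parameter}"


def parse_feature_name(name: str) -> tuple[int, str]:
    """Parse ``<base>—<parameter>``; ASCII ``-`` accepted as separator."""
    for sep in (FEATURE_SEP, "-"):
        if sep in name:
            base_str, param = name.split(sep, 1)
            try:
                base = int(base_str)
            except ValueError:
                break
            return base, get_parameter(param).name
    raise ValueError(f"unparseable feature name: {name!r}")


def trim_equilibration(traj: TrajectoryRecord, window: WindowSpec
                       ) -> TrajectoryRecord:
    """Drop frames outside the analysis window, identically in all series."""
    keep = window.mask(traj.times)
    if not keep.any():
        raise ValueError("window excludes all frames")
    series = {
        name: ParameterSeries(
            parameter=s.parameter,
            times=s.times[keep],
            values=s.values[keep],
            levels=s.levels,
            defined_mask=s.defined_mask[keep],
        )
        for name, s in traj.series.items()
    }
    return TrajectoryRecord(meta=traj.meta, series=series)


def trim_termini(traj: TrajectoryRecord, n_trim: int = 2) -> TrajectoryRecord:
    """Drop `n_trim` base-pair levels at each end of the duplex.

    Terminal base pairs lack stacking partners and fray in simulation,
    so they are excluded from the learning problem.  Original 1-based
    level labels are preserved (a 25-mer keeps levels 3–23).
    """
    if n_trim < 0:
        raise ValueError("n_trim must be >= 0")
    if n_trim == 0:
        return traj
    n_levels = traj.n_levels
    if n_levels <= 2 * n_trim:
        raise ValueError(
            f"cannot trim {n_trim} levels from each end of {n_levels}")
    sl = slice(n_trim, n_levels - n_trim)
    series = {
        name: ParameterSeries(
            parameter=s.parameter,
            times=s.times,
            values=s.values[:, sl],
            levels=s.levels[sl],
            defined_mask=s.defined_mask[:, sl],
        )
        for name, s in traj.series.items()
    }
    return TrajectoryRecord(meta=traj.meta, series=series)


def _aggregate(values: np.ndarray, mask: np.ndarray, aggregator: str
               ) -> np.ndarray:
    """Column statistics over defined frames (ddof=0 for sd)."""
    work = np.where(mask, values, np.nan)
    with np.errstate(invalid="ignore"):
        if aggregator == "mean":
            return np.nanmean(work, axis=0)
        if aggregator == "sd":
            return np.nanstd(work, axis=0, ddof=0)
        if aggregator == "median":
            return np.nanmedian(work, axis=0)
    raise ValueError(f"unknown aggregator {aggregator!r}; "
                     f"choose from {AGGREGATORS}")


def aggregate_record(traj: TrajectoryRecord, aggregator: str = "mean"
                     ) -> pd.Series:
    """Collapse a (trimmed) record to one value per (base, parameter).

    Output order: ascending base index, registry parameter order within
    each base.  Frames flagged undefined are excluded from the statistic;
    a cell with no defined frame at all is an error.
    """
    names, vals = [], []
    levels = traj.series[PARAMETER_ORDER[0]].levels
    per_param = {p: _aggregate(traj.series[p].values,
                               traj.series[p].defined_mask, aggregator)
                 for p in PARAMETER_ORDER}
    counts = {p: traj.series[p].defined_mask.sum(axis=0)
              for p in PARAMETER_ORDER}
    for j, level in enumerate(levels):
        for p in PARAMETER_ORDER:
            if counts[p][j] == 0:
                raise ValueError(
                    f"no defined frames for parameter {p} at base {level}")
            names.append(feature_name(int(level), p))
            vals.append(per_param[p][j])
    return pd.Series(vals, index=names, name=str(traj.meta.key()))


@dataclass
class FeatureMatrix:
    """Samples × (base, parameter) feature table with class labels."""

    features: pd.DataFrame  # numeric, columns = feature names
    meta: pd.DataFrame      # columns = META_COLUMNS, aligned to features

    def __post_init__(self):
        if len(self.features) != len(self.meta):
            raise ValueError("features and meta must have equal row counts")
        if self.features.isna().any().any():
            raise ValueError("feature matrix contains missing values")

    @property
    def n_samples(self) -> int:
        return len(self.features)

    @property
    def feature_names(self) -> list[str]:
        return list(self.features.columns)

    def labels(self, which: str = "class4") -> pd.Series:
        if which not in ("class4", "hotspot", "adducted"):
            raise ValueError(f"unknown label {which!r}")
        if which == "class4":
            return self.meta["class4"]
        if which == "hotspot":
            return self.meta["hotspot"].map({True: "hotspot",
                                             False: "nonhotspot"})
        return self.meta["adducted"].map({True: "adduct", False: "control"})

    def to_frame(self) -> pd.DataFrame:
        meta = self.meta.copy()
        meta["adducted"] = meta["adducted"].astype(int)
        meta["hotspot"] = meta["hotspot"].astype(int)
        return pd.concat([meta.reset_index(drop=True),
                          self.features.reset_index(drop=True)], axis=1)

    def to_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path) -> "FeatureMatrix":
        df = pd.read_csv(path, sep="\t")
        meta = df[list(META_COLUMNS)].copy()
        meta["adducted"] = meta["adducted"].astype(bool)
        meta["hotspot"] = meta["hotspot"].astype(bool)
        meta["methylated_positions"] = meta["methylated_positions"].astype(str)
        feats = df.drop(columns=list(META_COLUMNS))
        return cls(features=feats, meta=meta)

    def select_rows(self, mask) -> "FeatureMatrix":
        mask = np.asarray(mask, dtype=bool)
        return FeatureMatrix(
            features=self.features.loc[mask].reset_index(drop=True),
            meta=self.meta.loc[mask].reset_index(drop=True),
        )


def _meta_row(meta: SampleMeta) -> dict:
    return {
        "gene": meta.gene,
        "site": meta.site,
        "sequence": meta.sequence,
        "methylated_positions": ",".join(
            str(p) for p in sorted(meta.methylated_positions)),
        "adducted": meta.adducted,
        "hotspot": meta.hotspot,
        "replicate": meta.replicate,
        "dataset_tag": meta.dataset_tag,
        "class4": meta.class4,
    }


def build_feature_matrix(bundle: TrajectoryBundle,
                         window: WindowSpec | None = None,
                         aggregator: str = "mean",
                         n_trim: int = 2,
                         window_fraction: float = 0.10) -> FeatureMatrix:
    """Build the full feature matrix from a bundle.

    When no explicit window is given, each record drops the leading
    `window_fraction` of its own simulated span, so bundles whose spans
    differ from the nominal 100 ns are handled consistently.  Rows follow
    bundle order; replicates are kept as separate rows.
    """
    if len(bundle) == 0:
        raise ValueError("empty bundle")
    lengths = {rec.n_levels for rec in bundle}
    if len(lengths) != 1:
        raise ValueError(f"mixed sequence lengths in bundle: {sorted(lengths)}")

    rows, metas = [], []
    for rec in bundle:
        win = window if window is not None else equilibration_window(
            rec.times, window_fraction)
        trimmed = trim_termini(trim_equilibration(rec, win), n_trim)
        rows.append(aggregate_record(trimmed, aggregator))
        metas.append(_meta_row(rec.meta))

    features = pd.DataFrame(rows).reset_index(drop=True)
    meta = pd.DataFrame(metas, columns=list(META_COLUMNS))
    return FeatureMatrix(features=features, meta=meta)
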