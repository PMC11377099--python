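"""Synthetic helical-parameter trajectory generator.

Emulates the statistical structure of Curves+/Canal output for 25-mer
duplex simulations so that every downstream stage (feature extraction,
classifier benchmark, feature scoring, GC comparison) can be exercised
without molecular-dynamics data:

* one time × level series per helical parameter, nominally 1000 frames
  spanning 0–100 ns;
* class structure {hotspot, nonhotspot} × {adducted, control}, sites
  simulated in triplicate (reference scale: 12 sites → 72 records);
* stationary AR(1) Gaussian noise per (parameter, level) around
  B-DNA-like baselines (twist 34°, rise 3.4 Å, deviatory parameters
  centred on 0), plus a per-series replicate offset;
* planted mean-shift effects on chosen (parameter, base) cells, gated
  on the (hotspot, adducted) condition;
* hotspot/nonhotspot 25-mer sequences with controlled regional GC
  content, methyl-C at position 6 and the lesion G at position 7.

The generator makes no claim of physical fidelity; it reproduces only
the moments the analysis pipeline relies on.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Sequence

import numpy as np
from scipy.signal import lfilter

from .canal_io import (ParameterSeries, SampleMeta, TrajectoryBundle,
                       TrajectoryRecord, load_site_table, series_filename,
                       write_canal_series, write_manifest)
from .registry import PARAMETER_ORDER, PARAMETERS

__all__ = [
    "PlantedEffect",
    "SyntheticConfig",
    "BASELINE_MEANS",
    "BASELINE_SDS",
    "generate_bundle",
    "write_bundle",
    "generate_sequences",
    "ar1_autocorrelation",
    "tp53_preset",
    "gene_preset",
    "DEFAULT_TP53_EFFECTS",
]

#: Canonical B-DNA-like baseline means (degrees / angstrom).
BASELINE_MEANS = {p: 0.0 for p in PARAMETER_ORDER}
BASELINE_MEANS["twist"] = 34.0
BASELINE_MEANS["rise"] = 3.4

#: Parameter-typical marginal standard deviations.
BASELINE_SDS = {
    "shear": 0.30, "stretch": 0.15, "stagger": 0.40,
    "buckle": 8.0, "propeller": 8.0, "opening": 4.0,
    "shift": 0.60, "slide": 0.60, "rise": 0.25,
    "tilt": 4.0, "roll": 5.0, "twist": 4.0,
    "xdisp": 1.0, "ydisp": 0.50, "inclination": 5.0,
    "tip": 5.0, "axisbend": 3.0,
}

#: Step-wise parameters are stored at the 3'-side base pair, leaving
#: level 1 undefined.
_LEVEL1_UNDEFINED = frozenset(
    p.name for p in PARAMETERS.values() if p.category in ("inter", "bend"))

_CONDITIONS: dict[str, Callable[[bool, bool], bool]] = {
    "all": lambda h, a: True,
    "hotspot": lambda h, a: h,
    "adducted": lambda h, a: a,
    "hotspot_adduct": lambda h, a: h and a,
}


@dataclass(frozen=True)
class PlantedEffect:
    """A mean shift (and optional variance scaling) planted at one cell.

    `condition` gates the effect on the record's (hotspot, adducted)
    state: one of ``all``, ``hotspot``, ``adducted``, ``hotspot_adduct``
    or an arbitrary predicate.
    """

    parameter: str
    base: int
    condition: str | Callable[[bool, bool], bool] = "hotspot_adduct"
    mean_shift: float = 0.0
    sd_scale: float = 1.0

    def applies(self, hotspot: bool, adducted: bool) -> bool:
        cond = self.condition
        if isinstance(cond, str):
            try:
                cond = _CONDITIONS[cond]
            except KeyError:
                raise ValueError(f"unknown condition {self.condition!r}") from None
        return bool(cond(hotspot, adducted))


@dataclass
class SyntheticConfig:
    """Study-design parameters for one synthetic gene context."""

    gene: str = "TP53"
    hotspot_sites: Sequence[str] = ("157", "158", "245", "248", "273", "282")
    nonhotspot_sites: Sequence[str] = ("170", "186", "202", "213", "267", "290")
    replicates: int = 3
    adduct_states: Sequence[bool] = (True, False)
    n_frames: int = 1000
    t_start: float = 0.0
    t_end: float = 100.0          # ns
    seq_length: int = 25
    baseline_means: dict = field(default_factory=lambda: dict(BASELINE_MEANS))
    baseline_sds: dict = field(default_factory=lambda: dict(BASELINE_SDS))
    ar1_phi: float = 0.3
    replicate_offset_scale: float = 0.2   # × marginal sd, one draw per series
    planted_effects: Sequence[PlantedEffect] = ()
    gc_high: float = 0.80         # regional GC target for hotspot sequences
    gc_low: float = 0.35          # ... for nonhotspot sequences
    dataset_tag: str = "train"
    seed: int = 0
    sequences: dict | None = None  # optional site -> sequence override

    def validate(self) -> None:
        if not self.hotspot_sites and not self.nonhotspot_sites:
            raise ValueError("need at least one site")
        if self.replicates < 1:
            raise ValueError("replicates must be >= 1")
        if not 0 <= self.ar1_phi < 1:
            raise ValueError("ar1_phi must be in [0, 1)")
        if self.n_frames < 1:
            raise ValueError("n_frames must be >= 1")
        for eff in self.planted_effects:
            if eff.parameter not in PARAMETERS:
                raise ValueError(f"unknown planted parameter {eff.parameter!r}")
            if not 1 <= eff.base <= self.seq_length:
                raise ValueError(
                    f"planted base {eff.base} outside 1..{self.seq_length}")
            if eff.sd_scale < 0:
                raise ValueError("sd_scale must be >= 0")


def generate_sequences(n: int, gc_target: float, seed_or_rng,
                       length: int = 25, region: tuple[int, int] = (2, 12)
                       ) -> list[str]:
    """Random 25-mers with C6/G7 fixed and regional GC steered to target.

    Every position other than the fixed methyl-C (6) and lesion G (7) is
    drawn G/C with probability `gc_target`, A/T otherwise, so the mean
    realized GC fraction in the control region approaches the target as
    closely as the two fixed positions allow.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if not 0.0 <= gc_target <= 1.0:
        raise ValueError(f"gc_target {gc_target} infeasible; must be in [0, 1]")
    if length < 7:
        raise ValueError("length must be >= 7 to place C6/G7")
    rng = (seed_or_rng if isinstance(seed_or_rng, np.random.Generator)
           else np.random.default_rng(seed_or_rng))
    out = []
    for _ in range(n):
        bases = []
        for pos in range(1, length + 1):
            if pos == 6:
                bases.append("C")
            elif pos == 7:
                bases.append("G")
            elif rng.random() < gc_target:
                bases.append("G" if rng.random() < 0.5 else "C")
            else:
                bases.append("A" if rng.random() < 0.5 else "T")
        out.append("".join(bases))
    return out


def _ar1_series(rng: np.random.Generator, n: int, n_levels: int,
                sd: np.ndarray, phi: float) -> np.ndarray:
    """Stationary zero-mean AR(1) columns with marginal sd per level."""
    sd = np.broadcast_to(np.asarray(sd, dtype=float), (n_levels,))
    if n == 0:
        return np.empty((0, n_levels))
    eps = rng.standard_normal((n, n_levels)) * (sd * math.sqrt(1.0 - phi ** 2))
    x0 = rng.standard_normal(n_levels) * sd
    if phi == 0.0:
        x = eps.copy()
    else:
        x = lfilter([1.0], [1.0, -phi], eps, axis=0)
        x += x0 * phi ** np.arange(1, n + 1)[:, None]
    return x


def generate_bundle(config: SyntheticConfig) -> TrajectoryBundle:
    """Generate one TrajectoryRecord per (site, adduct state, replicate).

    Fully deterministic given ``config.seed``: sequences are drawn first,
    then series in a fixed record/parameter order.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    L = config.seq_length
    times = np.linspace(config.t_start, config.t_end, config.n_frames)

    if config.sequences is not None:
        seqs = dict(config.sequences)
    else:
        hot = (generate_sequences(len(config.hotspot_sites), config.gc_high,
                                  rng, length=L)
               if config.hotspot_sites else [])
        non = (generate_sequences(len(config.nonhotspot_sites), config.gc_low,
                                  rng, length=L)
               if config.nonhotspot_sites else [])
        seqs = dict(zip(list(config.hotspot_sites) + list(config.nonhotspot_sites),
                        hot + non))

    site_states = ([(s, True) for s in config.hotspot_sites]
                   + [(s, False) for s in config.nonhotspot_sites])

    records = []
    for site, hotspot in site_states:
        for adducted in config.adduct_states:
            for rep in range(1, config.replicates + 1):
                meta = SampleMeta(
                    gene=config.gene, site=str(site), sequence=seqs[site],
                    methylated_positions=frozenset({6}),
                    adducted=bool(adducted), hotspot=hotspot,
                    replicate=rep, dataset_tag=config.dataset_tag,
                )
                series = {}
                for pname in PARAMETER_ORDER:
                    mean = np.full(L, config.baseline_means[pname])
                    sd = np.full(L, config.baseline_sds[pname])
                    for eff in config.planted_effects:
                        if (eff.parameter == pname
                                and eff.applies(hotspot, adducted)):
                            mean[eff.base - 1] += eff.mean_shift
                            sd[eff.base - 1] *= eff.sd_scale
                    noise = _ar1_series(rng, config.n_frames, L, sd,
                                        config.ar1_phi)
                    offset = rng.normal(
                        0.0, config.replicate_offset_scale
                        * config.baseline_sds[pname]) \
                        if config.replicate_offset_scale > 0 \
                        and config.baseline_sds[pname] > 0 else 0.0
                    values = mean[None, :] + offset + noise
                    mask = np.ones_like(values, dtype=bool)
                    if pname in _LEVEL1_UNDEFINED:
                        values[:, 0] = np.nan
                        mask[:, 0] = False
                    series[pname] = ParameterSeries(
                        parameter=pname, times=times.copy(), values=values,
                        levels=np.arange(1, L + 1), defined_mask=mask)
                rec = TrajectoryRecord(meta=meta, series=series)
                records.append(rec)
    bundle = TrajectoryBundle(records)
    bundle.validate()
    return bundle


def write_bundle(bundle: TrajectoryBundle, out_dir,
                 manifest_name: str = "manifest.tsv") -> Path:
    """Write a bundle as a manifest plus one series file per parameter."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    entries = []
    for rec in bundle:
        m = rec.meta
        prefix = (f"{m.gene}_{m.site}_"
                  f"{'adduct' if m.adducted else 'control'}_r{m.replicate}"
                  f"_{m.dataset_tag}")
        for pname, s in rec.series.items():
            write_canal_series(s, out_dir / series_filename(prefix, pname))
        entries.append((m, prefix))
    manifest = out_dir / manifest_name
    write_manifest(entries, manifest)
    return manifest


def ar1_autocorrelation(series: np.ndarray) -> float:
    """Lag-1 sample autocorrelation of a 1-D series."""
    x = np.asarray(series, dtype=float)
    if x.ndim != 1 or x.size < 2:
        raise ValueError("need a 1-D series of at least 2 values")
    if np.allclose(x, x[0]):
        raise ValueError("autocorrelation undefined for a constant series")
    return float(np.corrcoef(x[:-1], x[1:])[0, 1])


#: Planted effects of the reference-scale preset.  Three kinds of signal:
#: local adduct distortion (any adducted duplex), intrinsic hotspot
#: topology (bound or not), and hotspot-specific adduct response — the
#: three hotspot_adduct cells are the feature-scoring recovery targets.
DEFAULT_TP53_EFFECTS = (
    PlantedEffect("buckle", 7, "adducted", mean_shift=24.0),
    PlantedEffect("rise", 8, "adducted", mean_shift=0.75),
    PlantedEffect("shift", 6, "adducted", mean_shift=1.8),
    PlantedEffect("tip", 10, "hotspot", mean_shift=15.0),
    PlantedEffect("propeller", 14, "hotspot", mean_shift=-24.0),
    PlantedEffect("axisbend", 10, "hotspot", mean_shift=9.0),
    PlantedEffect("tip", 23, "hotspot_adduct", mean_shift=15.0),
    PlantedEffect("rise", 23, "hotspot_adduct", mean_shift=0.75),
    PlantedEffect("propeller", 13, "hotspot_adduct", mean_shift=24.0),
)


def tp53_preset(seed: int = 0, dataset_tag: str = "train",
                planted_effects: Sequence[PlantedEffect] = DEFAULT_TP53_EFFECTS,
                **overrides) -> SyntheticConfig:
    """Reference-scale TP53 context: 6 hotspot + 6 nonhotspot codons,
    triplicate, ± adduct → 72 records."""
    return SyntheticConfig(seed=seed, dataset_tag=dataset_tag,
                           planted_effects=tuple(planted_effects),
                           **overrides)


def gene_preset(gene: str, seed: int = 0, dataset_tag: str | None = None,
                planted_effects: Sequence[PlantedEffect] = DEFAULT_TP53_EFFECTS,
                **overrides) -> SyntheticConfig:
    """Preset for a bundled gene context (cII or lacZ site tables)."""
    table = load_site_table(gene)
    hot = table.loc[table["hotspot"] == "1"]
    non = table.loc[table["hotspot"] == "0"]
    seqs = dict(zip(table["site"], table["sequence"]))
    return SyntheticConfig(
        gene=gene,
        hotspot_sites=tuple(hot["site"]),
        nonhotspot_sites=tuple(non["site"]),
        sequences=seqs,
        seed=seed,
        dataset_tag=dataset_tag or gene,
        planted_effects=tuple(planted_effects),
        **overrides,
    )
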