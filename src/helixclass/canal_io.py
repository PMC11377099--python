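"""Reading and writing Canal-style helical-parameter series files.

A Canal series file holds one helical parameter for one simulation: each
data row is one trajectory snapshot, column 1 is the snapshot time in ns
and the remaining columns are base-pair levels (1-based along the
duplex).  Undefined cells (e.g. step parameters at the first level) are
written as the sentinel ``NA``.  Lines starting with ``#`` are comments.

A sample manifest (TSV) ties series files to their biological metadata:
gene context, site label, 25-mer sequence of the adducted strand,
methylation positions, adduct status, hotspot label and replicate.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd

from .registry import PARAMETER_ORDER, PARAMETERS

__all__ = [
    "CanalFormatError",
    "ValidationError",
    "ParameterSeries",
    "SampleMeta",
    "TrajectoryRecord",
    "TrajectoryBundle",
    "SENTINEL",
    "read_canal_series",
    "write_canal_series",
    "read_manifest",
    "write_manifest",
    "load_bundle",
    "load_site_table",
]

#: Token written for undefined cells.
SENTINEL = "NA"

#: Manifest column order.
MANIFEST_COLUMNS = (
    "gene", "site", "sequence", "methylated_positions", "adducted",
    "hotspot", "replicate", "dataset_tag", "series_prefix",
)


class CanalFormatError(ValueError):
    """A series file violates the Canal text dialect."""


class ValidationError(ValueError):
    """Manifest or bundle metadata violates an invariant."""

    def __init__(self, problems):
        self.problems = list(problems)
        super().__init__("; ".join(self.problems))


@dataclass
class ParameterSeries:
    """Time × level matrix for one helical parameter of one simulation."""

    parameter: str
    times: np.ndarray          # (n_frames,) snapshot times in ns
    values: np.ndarray         # (n_frames, n_levels) in parameter units
    levels: np.ndarray         # (n_levels,) 1-based base-pair indices
    defined_mask: np.ndarray   # (n_frames, n_levels) bool

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        self.levels = np.asarray(self.levels, dtype=int)
        self.defined_mask = np.asarray(self.defined_mask, dtype=bool)
        if self.parameter not in PARAMETERS:
            raise ValueError(f"unknown parameter {self.parameter!r}")
        if self.times.ndim != 1 or self.times.size < 1:
            raise ValueError("times must be a non-empty 1-D array")
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")
        if self.values.ndim != 2:
            raise ValueError("values must be 2-D (frames × levels)")
        n_frames, n_levels = self.values.shape
        if n_frames != self.times.size:
            raise ValueError("row count must match number of times")
        if n_levels < 1:
            raise ValueError("need at least one level")
        if self.levels.shape != (n_levels,):
            raise ValueError("levels must match value columns")
        if self.defined_mask.shape != self.values.shape:
            raise ValueError("defined_mask must match values shape")

    @property
    def n_frames(self) -> int:
        return self.values.shape[0]

    @property
    def n_levels(self) -> int:
        return self.values.shape[1]


@dataclass(frozen=True)
class SampleMeta:
    """Metadata for one simulated duplex."""

    gene: str
    site: str
    sequence: str
    methylated_positions: frozenset[int]
    adducted: bool
    hotspot: bool
    replicate: int
    dataset_tag: str = "train"

    def key(self) -> tuple:
        """Identity of the record within a bundle."""
        return (self.gene, self.site, self.adducted, self.replicate,
                self.dataset_tag)

    def problems(self) -> list[str]:
        """Invariant violations, as human-readable strings."""
        out = []
        tag = f"{self.gene}/{self.site}/rep{self.replicate}"
        seq = self.sequence.upper()
        if len(seq) != 25:
            out.append(f"{tag}: sequence length {len(seq)} != 25")
        else:
            if seq[6] != "G":
                out.append(f"{tag}: position 7 is {seq[6]!r}, expected G")
            if 6 not in self.methylated_positions:
                out.append(f"{tag}: position 6 not methylated")
            if seq[5] != "C":
                out.append(f"{tag}: methylated position 6 is {seq[5]!r}, "
                           "expected C")
        if any(c not in "ACGTRYSWKMBDHVN" for c in seq):
            out.append(f"{tag}: non-IUPAC character in sequence")
        if self.replicate < 1:
            out.append(f"{tag}: replicate {self.replicate} < 1")
        bad = [p for p in self.methylated_positions
               if not 1 <= p <= max(len(seq), 1)]
        if bad:
            out.append(f"{tag}: methylated positions out of range: {bad}")
        return out

    @property
    def class4(self) -> str:
        h = "hotspot" if self.hotspot else "nonhotspot"
        a = "adduct" if self.adducted else "control"
        return f"{h}_{a}"


@dataclass
class TrajectoryRecord:
    """All 17 parameter series of one simulation plus its metadata."""

    meta: SampleMeta
    series: dict[str, ParameterSeries]

    def validate(self) -> None:
        missing = [p for p in PARAMETER_ORDER if p not in self.series]
        if missing:
            raise ValidationError(
                [f"{self.meta.key()}: missing series for {m}" for m in missing])
        ref = self.series[PARAMETER_ORDER[0]].times
        for name, s in self.series.items():
            if s.times.shape != ref.shape or not np.allclose(s.times, ref):
                raise ValidationError(
                    [f"{self.meta.key()}: series {name} times differ"])

    @property
    def times(self) -> np.ndarray:
        return self.series[PARAMETER_ORDER[0]].times

    @property
    def n_levels(self) -> int:
        return self.series[PARAMETER_ORDER[0]].n_levels


@dataclass
class TrajectoryBundle:
    """Ordered collection of trajectory records."""

    records: list[TrajectoryRecord] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    def validate(self) -> None:
        problems = []
        seen = {}
        for i, rec in enumerate(self.records):
            problems.extend(rec.meta.problems())
            k = rec.meta.key()
            if k in seen:
                problems.append(f"duplicate record identity {k} "
                                f"(rows {seen[k]} and {i})")
            seen[k] = i
        if problems:
            raise ValidationError(problems)
        for rec in self.records:
            rec.validate()


def read_canal_series(path, parameter: str) -> ParameterSeries:
    """Parse one whitespace-delimited Canal series file.

    Column 1 is the snapshot time; remaining columns are base-pair
    levels.  ``NA`` marks undefined cells.  ``#`` lines are skipped.
    """
    path = Path(path)
    times, rows, mask_rows = [], [], []
    n_cols = None
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            stripped = line.strip()
            if not stripped or stripped.startswith("#"):
                continue
            tokens = stripped.split()
            if n_cols is None:
                n_cols = len(tokens)
                if n_cols < 2:
                    raise CanalFormatError(
                        f"{path}:{lineno}: need a time column plus at least "
                        "one level column")
            elif len(tokens) != n_cols:
                raise CanalFormatError(
                    f"{path}:{lineno}: ragged row has {len(tokens)} tokens, "
                    f"expected {n_cols}")
            try:
                times.append(float(tokens[0]))
            except ValueError:
                raise CanalFormatError(
                    f"{path}:{lineno}: non-numeric time {tokens[0]!r}") from None
            vals, defined = [], []
            for col, tok in enumerate(tokens[1:], start=2):
                if tok == SENTINEL:
                    vals.append(math.nan)
                    defined.append(False)
                else:
                    try:
                        vals.append(float(tok))
                    except ValueError:
                        raise CanalFormatError(
                            f"{path}:{lineno}: column {col}: non-numeric "
                            f"cell {tok!r}") from None
                    defined.append(True)
            rows.append(vals)
            mask_rows.append(defined)
    if not rows:
        raise CanalFormatError(f"{path}: no data rows")
    values = np.array(rows, dtype=float)
    return ParameterSeries(
        parameter=parameter,
        times=np.array(times),
        values=values,
        levels=np.arange(1, values.shape[1] + 1),
        defined_mask=np.array(mask_rows, dtype=bool),
    )


def write_canal_series(series: ParameterSeries, path) -> None:
    """Write a series in the dialect that :func:`read_canal_series` reads.

    Values are printed with six decimals, so a round trip preserves them
    to within 1e-6; the defined mask round-trips exactly.
    """
    path = Path(path)
    with open(path, "w") as fh:
        fh.write(f"# helixclass canal series: {series.parameter}; "
                 f"columns: time_ns then levels "
                 f"{series.levels[0]}..{series.levels[-1]}\n")
        for t, row, defined in zip(series.times, series.values,
                                   series.defined_mask):
            cells = [f"{t:.6f}"]
            for v, ok in zip(row, defined):
                cells.append(f"{v:.6f}" if ok else SENTINEL)
            fh.write(" ".join(cells) + "\n")


def _parse_bool(token: str, what: str) -> bool:
    if token in ("0", "1"):
        return token == "1"
    raise ValidationError([f"{what}: boolean must be 0 or 1, got {token!r}"])


def _parse_methylated(token: str) -> frozenset[int]:
    token = token.strip()
    if not token or token == "-":
        return frozenset()
    return frozenset(int(p) for p in token.split(","))


def read_manifest(path) -> list[tuple[SampleMeta, str]]:
    """Read a sample manifest TSV into (meta, series_prefix) pairs."""
    df = pd.read_csv(path, sep="\t", dtype=str).fillna("")
    missing = [c for c in MANIFEST_COLUMNS if c not in df.columns]
    if missing:
        raise ValidationError([f"manifest missing columns: {missing}"])
    out = []
    for _, row in df.iterrows():
        try:
            replicate = int(row["replicate"])
        except ValueError:
            raise ValidationError(
                [f"{row['gene']}/{row['site']}: replicate "
                 f"{row['replicate']!r} is not an integer"]) from None
        meta = SampleMeta(
            gene=row["gene"],
            site=row["site"],
            sequence=row["sequence"].upper(),
            methylated_positions=_parse_methylated(row["methylated_positions"]),
            adducted=_parse_bool(row["adducted"],
                                 f"{row['gene']}/{row['site']} adducted"),
            hotspot=_parse_bool(row["hotspot"],
                                f"{row['gene']}/{row['site']} hotspot"),
            replicate=replicate,
            dataset_tag=row["dataset_tag"],
        )
        out.append((meta, row["series_prefix"]))
    return out


def write_manifest(entries: Iterable[tuple[SampleMeta, str]], path) -> None:
    rows = []
    for meta, prefix in entries:
        rows.append({
            "gene": meta.gene,
            "site": meta.site,
            "sequence": meta.sequence,
            "methylated_positions": ",".join(
                str(p) for p in sorted(meta.methylated_positions)),
            "adducted": int(meta.adducted),
            "hotspot": int(meta.hotspot),
            "replicate": meta.replicate,
            "dataset_tag": meta.dataset_tag,
            "series_prefix": prefix,
        })
    pd.DataFrame(rows, columns=list(MANIFEST_COLUMNS)).to_csv(
        path, sep="\t", index=False)


def series_filename(prefix: str, parameter: str) -> str:
    return f"{prefix}_{parameter}.ser"


def load_bundle(manifest, data_dir) -> TrajectoryBundle:
    """Assemble a trajectory bundle from a manifest and its series files.

    Record order follows manifest order; all metadata and uniqueness
    invariants are enforced before any series file is read.
    """
    data_dir = Path(data_dir)
    entries = read_manifest(manifest)

    problems = []
    seen = {}
    for i, (meta, _) in enumerate(entries):
        problems.extend(meta.problems())
        k = meta.key()
        if k in seen:
            problems.append(f"duplicate record identity {k} "
                            f"(manifest rows {seen[k]} and {i})")
        seen[k] = i
    if problems:
        raise ValidationError(problems)

    records = []
    for meta, prefix in entries:
        series = {}
        for parameter in PARAMETER_ORDER:
            fpath = data_dir / series_filename(prefix, parameter)
            if not fpath.exists():
                raise FileNotFoundError(
                    f"missing series file for sample {meta.key()}, "
                    f"parameter {parameter}: {fpath}")
            series[parameter] = read_canal_series(fpath, parameter)
        rec = TrajectoryRecord(meta=meta, series=series)
        rec.validate()
        records.append(rec)
    bundle = TrajectoryBundle(records)
    bundle.validate()
    return bundle


def load_site_table(gene: str) -> pd.DataFrame:
    """Load a bundled synthetic site table for a gene context.

    The cII and lacZ tables each list seven BPDE-binding sites (five
    hotspot, two nonhotspot) with synthetic stand-in 25-mer sequences.
    """
    data_dir = Path(__file__).parent / "data"
    fpath = data_dir / f"{gene}_sites_synthetic.tsv"
    if not fpath.exists():
        known = sorted(p.name.split("_")[0] for p in data_dir.glob("*_sites_synthetic.tsv"))
        raise FileNotFoundError(
            f"no bundled site table for {gene!r}; available: {known}")
    return pd.read_csv(fpath, sep="\t", dtype=str)
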