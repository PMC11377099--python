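"""Regional G/C content around the lesion and group comparison.

Hotspot and nonhotspot 25-mers are compared over the positional window
spanning the lesion (bases 2–12 by default, 1-based inclusive; the
lesion guanine sits at position 7).  The default test is a two-sided
permutation test on the difference of group-mean GC fractions —
exhaustive whenever the number of group assignments is small enough,
Monte-Carlo otherwise — with Welch's t available as an alternative.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass

import numpy as np
from scipy.special import comb
from scipy.stats import ttest_ind

__all__ = ["GCReport", "regional_gc", "compare_gc"]

DEFAULT_REGION = (2, 12)


@dataclass
class GCReport:
    """Outcome of a hotspot vs nonhotspot regional GC comparison."""

    region: tuple[int, int]
    hotspot_gc: list[float]
    nonhotspot_gc: list[float]
    hotspot_mean: float
    nonhotspot_mean: float
    test: str           # permutation_exhaustive | permutation_mc | welch
    statistic: float    # mean difference (permutation) or t (welch)
    p_value: float
    n_permutations: int | None = None

    def as_dict(self) -> dict:
        return {
            "region": list(self.region),
            "hotspot_gc": self.hotspot_gc,
            "nonhotspot_gc": self.nonhotspot_gc,
            "hotspot_mean": self.hotspot_mean,
            "nonhotspot_mean": self.nonhotspot_mean,
            "test": self.test,
            "statistic": self.statistic,
            "p_value": self.p_value,
            "n_permutations": self.n_permutations,
        }


def regional_gc(sequence: str, start: int = 2, end: int = 12) -> float:
    """G+C fraction over 1-based inclusive positions start..end.

    Methylated cytosine counts as C.  Ambiguous IUPAC codes inside the
    region are an error because their GC contribution is undefined.
    """
    seq = sequence.upper()
    if not 1 <= start <= end <= len(seq):
        raise ValueError(f"region {start}..{end} outside sequence of length "
                         f"{len(seq)}")
    window = seq[start - 1:end]
    bad = sorted({c for c in window if c not in "ACGT"})
    if bad:
        raise ValueError(f"ambiguous bases in region: {bad}")
    return (window.count("G") + window.count("C")) / len(window)


def _mean_diff(values: np.ndarray, idx_a) -> float:
    mask = np.zeros(values.size, dtype=bool)
    mask[list(idx_a)] = True
    return float(values[mask].mean() - values[~mask].mean())


def compare_gc(hotspot_seqs: list[str], nonhotspot_seqs: list[str],
               region: tuple[int, int] = DEFAULT_REGION,
               test: str = "permutation", n_permutations: int = 10000,
               seed: int = 0, max_exhaustive: int = 20000) -> GCReport:
    """Compare regional GC fractions between the two groups.

    The permutation test permutes group assignments of the pooled GC
    fractions and computes the two-sided p-value of the observed
    difference of group means; it enumerates all C(n1+n2, n1)
    assignments when that count is at most `max_exhaustive`, otherwise
    it draws `n_permutations` Monte-Carlo assignments (the observed
    assignment is included in the null set, so p > 0).
    """
    if len(hotspot_seqs) < 2 or len(nonhotspot_seqs) < 2:
        raise ValueError("need at least 2 sequences per group")
    start, end = region
    gc_hot = [regional_gc(s, start, end) for s in hotspot_seqs]
    gc_non = [regional_gc(s, start, end) for s in nonhotspot_seqs]
    pooled = np.array(gc_hot + gc_non)
    n1, n = len(gc_hot), len(pooled)
    obs = float(np.mean(gc_hot) - np.mean(gc_non))

    if test == "welch":
        stat, p = ttest_ind(gc_hot, gc_non, equal_var=False)
        return GCReport(region=region, hotspot_gc=gc_hot, nonhotspot_gc=gc_non,
                        hotspot_mean=float(np.mean(gc_hot)),
                        nonhotspot_mean=float(np.mean(gc_non)),
                        test="welch", statistic=float(stat),
                        p_value=float(p))
    if test != "permutation":
        raise ValueError(f"unknown test {test!r}")

    tol = 1e-12
    n_assign = int(comb(n, n1, exact=True))
    if n_assign <= max_exhaustive:
        hits = sum(
            abs(_mean_diff(pooled, idx)) >= abs(obs) - tol
            for idx in itertools.combinations(range(n), n1))
        p = hits / n_assign
        label, used = "permutation_exhaustive", n_assign
    else:
        rng = np.random.default_rng(seed)
        hits = 1  # observed assignment
        for _ in range(n_permutations):
            idx = rng.choice(n, size=n1, replace=False)
            if abs(_mean_diff(pooled, idx)) >= abs(obs) - tol:
                hits += 1
        p = hits / (n_permutations + 1)
        label, used = "permutation_mc", n_permutations

    return GCReport(region=region, hotspot_gc=gc_hot, nonhotspot_gc=gc_non,
                    hotspot_mean=float(np.mean(gc_hot)),
                    nonhotspot_mean=float(np.mean(gc_non)),
                    test=label, statistic=obs, p_value=float(p),
                    n_permutations=used)
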