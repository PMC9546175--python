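"""Population-variability statistics over miRNA anatomy.

Covers the coverage rule, SNV densities (per kb and per mature site),
transition/transversion composition, the allele-frequency spectrum,
score-distribution comparisons and the high-percentile selection used to
flag potentially highly deleterious variants. Only variants passing all
quality filters are meant to enter these statistics; the filtering itself
is the caller's responsibility (see :mod:`mirlog.datasets`).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "classify_substitution",
    "tstv_report",
    "TsTvReport",
    "snv_density",
    "DensityReport",
    "compare_densities",
    "per_base_density",
    "af_spectrum",
    "AFSpectrum",
    "coverage_pass",
    "CoverageSummary",
    "compare_score_distributions",
    "correlate",
    "percentile_select",
    "PercentileSelection",
]

PURINES = {"A", "G"}
PYRIMIDINES = {"C", "T"}

#: strand-symmetric substitution categories (2 transitions, 4 transversions)
TS_CATEGORIES = ("A/T>G/C", "G/C>A/T")
TV_CATEGORIES = ("G/C>C/G", "G/C>T/A", "A/T>T/A", "A/T>C/G")

_CATEGORY = {
    ("A", "G"): "A/T>G/C",
    ("T", "C"): "A/T>G/C",
    ("G", "A"): "G/C>A/T",
    ("C", "T"): "G/C>A/T",
    ("G", "C"): "G/C>C/G",
    ("C", "G"): "G/C>C/G",
    ("G", "T"): "G/C>T/A",
    ("C", "A"): "G/C>T/A",
    ("A", "T"): "A/T>T/A",
    ("T", "A"): "A/T>T/A",
    ("A", "C"): "A/T>C/G",
    ("T", "G"): "A/T>C/G",
}


def classify_substitution(ref: str, alt: str) -> tuple[str, str]:
    """Classify a substitution as transition/transversion with its category.

    Transitions exchange bases within the purines (A<->G) or within the
    pyrimidines (C<->T); everything else is a transversion. The category is
    the strand-symmetric class, e.g. both C>G and G>C map to ``G/C>C/G``.
    """
    ref, alt = ref.upper(), alt.upper()
    for b in (ref, alt):
        if b not in PURINES | PYRIMIDINES:
            raise ValueError(f"invalid base {b!r}")
    if ref == alt:
        raise ValueError("ref and alt are identical")
    kind = (
        "transition"
        if (ref in PURINES) == (alt in PURINES)
        else "transversion"
    )
    return kind, _CATEGORY[(ref, alt)]


@dataclass
class TsTvReport:
    """Counts and fractions of the six substitution categories."""

    counts: dict[str, int]
    n_transitions: int
    n_transversions: int

    @property
    def n(self) -> int:
        return self.n_transitions + self.n_transversions

    @property
    def fractions(self) -> dict[str, float]:
        n = self.n
        return {k: (v / n if n else 0.0) for k, v in self.counts.items()}

    @property
    def ts_tv_ratio(self) -> float:
        """Transitions over transversions; +inf when no transversions."""
        if self.n_transversions == 0:
            return math.inf
        return self.n_transitions / self.n_transversions


def tstv_report(variants: Iterable[tuple[str, str]] | pd.DataFrame) -> TsTvReport:
    """Tabulate transitions/transversions over (ref, alt) pairs."""
    if isinstance(variants, pd.DataFrame):
        pairs = list(zip(variants["ref"], variants["alt"]))
    else:
        pairs = list(variants)
    counts = {c: 0 for c in TS_CATEGORIES + TV_CATEGORIES}
    ts = tv = 0
    for ref, alt in pairs:
        kind, cat = classify_substitution(ref, alt)
        counts[cat] += 1
        if kind == "transition":
            ts += 1
        else:
            tv += 1
    return TsTvReport(counts=counts, n_transitions=ts, n_transversions=tv)


@dataclass
class DensityReport:
    region: str
    n_snvs: int
    length_nt: int

    @property
    def density_per_kb(self) -> float:
        return self.n_snvs / (self.length_nt / 1000)


def snv_density(variants: int | Sequence, region_length_nt: int, region: str = "") -> DensityReport:
    """SNVs per kb of region; multi-allelic sites count once per alt allele."""
    n = variants if isinstance(variants, (int, np.integer)) else len(variants)
    if region_length_nt <= 0:
        raise ValueError("region length must be positive")
    return DensityReport(region=region, n_snvs=int(n), length_nt=int(region_length_nt))


@dataclass
class DensityComparison:
    statistic: float
    p_value: float
    small_expected_counts: bool


def compare_densities(count_a: int, len_a: int, count_b: int, len_b: int) -> DensityComparison:
    """Chi-square test of two region densities on a 2x2 site table.

    The table is (variant sites, non-variant sites) per region; no
    continuity correction is applied. A flag marks expected cells < 5.
    """
    table = np.array([[count_a, len_a - count_a], [count_b, len_b - count_b]], dtype=float)
    if (table < 0).any():
        raise ValueError("counts exceed region lengths")
    if (table.sum(axis=1) == 0).any() or (table.sum(axis=0) == 0).any():
        return DensityComparison(statistic=0.0, p_value=1.0, small_expected_counts=True)
    chi2, p, _, expected = sps.chi2_contingency(table, correction=False)
    return DensityComparison(
        statistic=float(chi2),
        p_value=float(p),
        small_expected_counts=bool((expected < 5).any()),
    )


def per_base_density(
    mature_positions: Sequence[int],
    mature_lengths: Sequence[int],
    per: int = 1000,
) -> pd.DataFrame:
    """Variant counts per mature site, scaled per ``per`` miRNAs.

    ``mature_positions`` are 1-based sites within the mature sequence
    (1 = first mature base) of each observed variant; ``mature_lengths``
    are the lengths of all mature miRNAs considered. Sites beyond the
    shortest mature use the number of matures long enough as denominator.
    """
    lengths = np.asarray(mature_lengths, dtype=int)
    if len(lengths) == 0:
        raise ValueError("no mature lengths supplied")
    max_site = int(lengths.max())
    pos = np.asarray(mature_positions, dtype=int)
    if len(pos) and (pos.min() < 1 or pos.max() > max_site):
        raise ValueError("mature-local positions outside 1..max mature length")
    counts = np.bincount(pos, minlength=max_site + 1)[1:]
    n_matures = np.array([(lengths >= s).sum() for s in range(1, max_site + 1)])
    return pd.DataFrame(
        {
            "site": np.arange(1, max_site + 1),
            "n_snvs": counts,
            "n_matures": n_matures,
            f"per_{per}": per * counts / n_matures,
        }
    )


#: default AF histogram bin edges (log-spaced; first bin is the ultra-rare class)
DEFAULT_AF_BINS = (0.0, 1e-4, 1e-3, 1e-2, 0.1, 0.5, 1.0)

ULTRA_RARE_AF = 1e-4


@dataclass
class AFSpectrum:
    bin_edges: np.ndarray
    counts: np.ndarray
    ultra_rare_fraction: float

    @property
    def n(self) -> int:
        return int(self.counts.sum())


def af_spectrum(af: Sequence[float], bins: Sequence[float] | None = None) -> AFSpectrum:
    """Allele-frequency histogram plus the ultra-rare (AF <= 0.01%) fraction."""
    a = np.asarray(af, dtype=float)
    if len(a) and (a.min() < 0 or a.max() > 1):
        raise ValueError("allele frequencies must lie in [0, 1]")
    edges = np.asarray(DEFAULT_AF_BINS if bins is None else bins, dtype=float)
    counts, _ = np.histogram(a, bins=edges)
    frac = float((a <= ULTRA_RARE_AF).mean()) if len(a) else 0.0
    return AFSpectrum(bin_edges=edges, counts=counts, ultra_rare_fraction=frac)


@dataclass
class CoverageSummary:
    """Outcome of the sequencing-coverage adequacy rule for one hairpin.

    ``fraction_bases_covered`` is the fraction of hairpin bases at which at
    least ``indiv_frac`` of individuals reach the depth threshold; the
    hairpin passes when that fraction is at least ``base_frac``. All
    comparisons are inclusive (>=).
    """

    fraction_bases_covered: float
    passes: bool


def coverage_pass(
    depth_summary,
    min_depth: int = 20,
    base_frac: float = 0.8,
    indiv_frac: float = 0.8,
) -> CoverageSummary:
    """Apply the coverage rule: >=``min_depth`` reads over >=80% of bases in
    >=80% of individuals.

    ``depth_summary`` is either a 2-D array (bases x individuals) of read
    depths, or a 1-D array of per-base fractions of individuals already at
    the depth threshold (the per-base TSV form).
    """
    arr = np.asarray(depth_summary, dtype=float)
    if arr.ndim == 2:
        per_base_frac = (arr >= min_depth).mean(axis=1)
    elif arr.ndim == 1:
        if len(arr) and (arr.min() < 0 or arr.max() > 1):
            raise ValueError("per-base fractions must lie in [0, 1]")
        per_base_frac = arr
    else:
        raise ValueError("depth_summary must be 1-D or 2-D")
    frac_bases = float((per_base_frac >= indiv_frac).mean())
    return CoverageSummary(fraction_bases_covered=frac_bases, passes=frac_bases >= base_frac)


@dataclass
class RankSumComparison:
    u_statistic: float
    p_value: float
    median_a: float
    median_b: float
    mean_a: float
    mean_b: float


def compare_score_distributions(scores_a: Sequence[float], scores_b: Sequence[float]) -> RankSumComparison:
    """Two-sided Mann-Whitney rank-sum comparison with tie correction."""
    a = np.asarray(scores_a, dtype=float)
    b = np.asarray(scores_b, dtype=float)
    res = sps.mannwhitneyu(a, b, alternative="two-sided", method="asymptotic")
    return RankSumComparison(
        u_statistic=float(res.statistic),
        p_value=float(min(res.pvalue, 1.0)),
        median_a=float(np.median(a)),
        median_b=float(np.median(b)),
        mean_a=float(a.mean()),
        mean_b=float(b.mean()),
    )


def correlate(x: Sequence[float], y: Sequence[float], method: str = "spearman") -> tuple[float, float]:
    """Rank correlation (Spearman, average ranks for ties): (rho, p)."""
    if method != "spearman":
        raise ValueError("only Spearman correlation is supported")
    rho, p = sps.spearmanr(x, y)
    return float(rho), float(p)


@dataclass
class PercentileSelection:
    threshold: float
    selected: np.ndarray = field(repr=False)  # boolean mask

    @property
    def n_selected(self) -> int:
        return int(self.selected.sum())


def percentile_select(scores: Sequence[float], q: float = 0.99) -> PercentileSelection:
    """Select scores strictly above the q-quantile of the whole table.

    The quantile uses linear interpolation between order statistics, so on
    a given score table the threshold/percentile pairing is reproducible.
    If all scores are equal nothing is strictly greater and the selection
    is empty.
    """
    s = np.asarray(scores, dtype=float)
    if not 0 <= q <= 1:
        raise ValueError("q must be in [0, 1]")
    threshold = float(np.quantile(s, q))
    return PercentileSelection(threshold=threshold, selected=s > threshold)
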