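"""Per-SNV feature matrix: score assembly, iterative imputation, PCA diagnostic.

Ten precomputed noncoding-variant scores make up the feature space. Seven are
allele-level (a value per chrom/pos/ref/alt) and three — phyloP, phastCons
and LINSIGHT — are position-level, so one value is broadcast to all three
alternate alleles of a site. An ``autosomal`` boolean flags variants off the
X/Y chromosomes, where several scoring systems have no coverage.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA
from sklearn.ensemble import ExtraTreesRegressor
from sklearn.experimental import enable_iterative_imputer  # noqa: F401
from sklearn.impute import IterativeImputer

__all__ = [
    "SCORE_COLUMNS",
    "POSITION_LEVEL_SCORES",
    "FeatureMatrix",
    "assemble",
    "impute",
    "pca_diagnostic",
]

#: fixed feature-column order: 8 deleteriousness scores then 2 conservation scores
SCORE_COLUMNS = (
    "cadd",
    "remm",
    "eigen_pc",
    "funseq",
    "ncer",
    "fathmm_xf",
    "dann",
    "linsight",
    "phylop",
    "phastcons",
)

#: scores defined per genomic position (identical for the 3 alternate alleles)
POSITION_LEVEL_SCORES = frozenset({"phylop", "phastcons", "linsight"})

KEY_COLUMNS = ["chrom", "pos", "ref", "alt"]

SEX_CHROMS = {"X", "Y", "chrX", "chrY"}


def is_autosomal(chrom: pd.Series | Sequence[str]) -> np.ndarray:
    s = pd.Series(chrom).astype(str)
    return ~s.isin(SEX_CHROMS).to_numpy()


@dataclass
class FeatureMatrix:
    """SNV-by-score table with an explicit missingness mask.

    ``frame`` holds the key columns (chrom, pos, ref, alt), the ten score
    columns (NaN where missing) and the ``autosomal`` boolean.
    """

    frame: pd.DataFrame

    def __post_init__(self) -> None:
        missing = [c for c in KEY_COLUMNS + list(SCORE_COLUMNS) + ["autosomal"] if c not in self.frame.columns]
        if missing:
            raise ValueError(f"feature frame lacks columns: {missing}")

    @property
    def keys(self) -> pd.DataFrame:
        return self.frame[KEY_COLUMNS]

    @property
    def values(self) -> np.ndarray:
        """n x 10 float array of scores (NaN = missing)."""
        return self.frame[list(SCORE_COLUMNS)].to_numpy(dtype=float)

    @property
    def autosomal(self) -> np.ndarray:
        return self.frame["autosomal"].to_numpy(dtype=bool)

    @property
    def missing_mask(self) -> np.ndarray:
        return np.isnan(self.values)

    @property
    def missingness(self) -> pd.Series:
        """Fraction missing per score column."""
        return self.frame[list(SCORE_COLUMNS)].isna().mean()

    def model_matrix(self) -> np.ndarray:
        """n x 11 array: the 10 scores followed by the autosomal flag."""
        return np.column_stack([self.values, self.autosomal.astype(float)])

    def __len__(self) -> int:
        return len(self.frame)


def _read_table(source) -> pd.DataFrame:
    if isinstance(source, pd.DataFrame):
        return source
    return pd.read_csv(source, sep="\t")


def assemble(
    score_tables: Mapping[str, pd.DataFrame | str | Path],
    snv_list: pd.DataFrame,
) -> FeatureMatrix:
    """Join the per-tool score tables onto the requested SNV list.

    ``score_tables`` maps tool name -> TSV path or DataFrame; allele-level
    tables are keyed (chrom, pos, ref, alt) and position-level ones
    (chrom, pos), in which case one entry fills all three allelic rows.
    Entries absent from a table are left NaN. Duplicate keys within a table
    are a hard error when their values conflict.
    """
    unknown = set(score_tables) - set(SCORE_COLUMNS)
    if unknown:
        raise ValueError(f"unknown score tables: {sorted(unknown)}")
    out = snv_list[KEY_COLUMNS].copy().reset_index(drop=True)
    dup = out.duplicated(subset=KEY_COLUMNS)
    if dup.any():
        raise ValueError("snv_list contains duplicate (chrom,pos,ref,alt) keys")
    for name in SCORE_COLUMNS:
        if name not in score_tables:
            out[name] = np.nan
            continue
        tab = _read_table(score_tables[name])
        key = ["chrom", "pos"] if name in POSITION_LEVEL_SCORES else KEY_COLUMNS
        tab = tab[key + ["score"]].copy()
        grouped = tab.groupby(key, sort=False)["score"]
        if (grouped.nunique() > 1).any():
            bad = grouped.nunique()
            bad = bad[bad > 1].index[0]
            raise ValueError(f"score table {name!r}: conflicting duplicate entries at key {bad}")
        tab = grouped.first().reset_index().rename(columns={"score": name})
        out = out.merge(tab, on=key, how="left")
    out["autosomal"] = is_autosomal(out["chrom"])
    return FeatureMatrix(out)


def impute(
    m: FeatureMatrix,
    n_trees: int = 126,
    repeats: int = 10,
    seed: int = 0,
    max_iter: int = 10,
) -> FeatureMatrix:
    """Fill missing scores by repeated Extra-Trees iterative imputation.

    Each incomplete column is regressed, round-robin, on the other nine with
    an extremely-randomized-trees regressor of ``n_trees`` trees. The whole
    imputation is run ``repeats`` times with distinct seeds and the imputed
    values averaged; observed cells are never altered, and the autosomal
    flag takes no part (it is never missing).
    """
    values = m.values
    mask = np.isnan(values)
    if not mask.any():
        return FeatureMatrix(m.frame.copy())
    fully_missing = mask.all(axis=0)
    if fully_missing.any():
        names = [SCORE_COLUMNS[i] for i in np.flatnonzero(fully_missing)]
        raise ValueError(f"column(s) fully missing, cannot impute: {names}")
    seeds = np.random.SeedSequence(seed).generate_state(repeats) % (2**31 - 1)
    acc = np.zeros_like(values)
    for s in seeds:
        est = ExtraTreesRegressor(n_estimators=n_trees, random_state=int(s))
        imp = IterativeImputer(estimator=est, random_state=int(s), max_iter=max_iter)
        acc += imp.fit_transform(values)
    filled = acc / repeats
    filled[~mask] = values[~mask]  # observed cells bitwise untouched
    frame = m.frame.copy()
    frame[list(SCORE_COLUMNS)] = filled
    return FeatureMatrix(frame)


@dataclass
class PCADiagnostic:
    explained_variance_ratio: np.ndarray
    components: np.ndarray  # loadings, one row per component


def pca_diagnostic(m: FeatureMatrix | np.ndarray) -> PCADiagnostic:
    """Principal-component spectrum of the (standardized) continuous scores.

    Quantifies collinearity among the ten scoring systems: strongly
    redundant scores concentrate the variance in few leading components.
    Columns are standardized first so the diagnostic reflects correlation
    structure, not tool-specific scales. The boolean flag is excluded.
    """
    X = m.values if isinstance(m, FeatureMatrix) else np.asarray(m, dtype=float)
    if X.ndim != 2 or X.shape[0] < 2:
        raise ValueError("pca_diagnostic needs a 2-D matrix with at least 2 rows")
    if np.isnan(X).any():
        raise ValueError("matrix contains missing values; impute first")
    sd = X.std(axis=0, ddof=0)
    sd[sd == 0] = 1.0
    Z = (X - X.mean(axis=0)) / sd
    pca = PCA()
    pca.fit(Z)
    return PCADiagnostic(
        explained_variance_ratio=pca.explained_variance_ratio_,
        components=pca.components_,
    )


def write_wide_tsv(m: FeatureMatrix, path: str | Path) -> None:
    """Write the assembled matrix as one wide TSV with missingness columns."""
    frame = m.frame.copy()
    for c in SCORE_COLUMNS:
        frame[f"{c}_missing"] = frame[c].isna()
    frame.to_csv(path, sep="\t", index=False, float_format="%.6g")


def read_wide_tsv(path: str | Path) -> FeatureMatrix:
    frame = pd.read_csv(path, sep="\t")
    keep = KEY_COLUMNS + list(SCORE_COLUMNS) + ["autosomal"]
    extra = [c for c in frame.columns if c not in keep and not c.endswith("_missing") and c != "label"]
    return FeatureMatrix(frame[keep + extra] if extra else frame[keep])
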