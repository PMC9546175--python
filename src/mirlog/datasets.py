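"""Dataset-construction rules, VCF/TSV readers and the dbmiR record builder.

Two labeled training sets are built from a curated deleterious list and a
population VCF:

* ``dataset1`` (stringent): deleterious = curated variants absent from the
  population cohort; neutral = population variants with AF > 10% that are
  not in the curated list.
* ``dataset2`` (relaxed): deleterious = curated variants present in the
  cohort; neutral = population variants with AF < 10% not in the curated
  list. Both AF comparisons are strict, so AF exactly 0.10 falls in
  neither neutral set; such rows appear in the audit log.

Only variants passing all quality filters are considered on the population
side. An audit log records every excluded input row with its reason.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .anatomy import MirnaHairpin, cluster_flag, enumerate_allelic_snvs
from .features import KEY_COLUMNS, SCORE_COLUMNS, FeatureMatrix, is_autosomal

__all__ = [
    "DatasetRule",
    "DATASET1",
    "DATASET2",
    "build_datasets",
    "build_dbmir",
    "read_population_vcf",
    "read_curated_tsv",
    "read_labeled_tsv",
    "write_labeled_tsv",
    "write_dbmir_tsv",
]

AF_THRESHOLD = 0.10


@dataclass(frozen=True)
class DatasetRule:
    """Filters defining one labeled dataset."""

    rule_id: str
    deleterious_in_population: bool  # must the curated SNV be observed?
    neutral_af_min: float | None  # neutral requires AF > this (strict)
    neutral_af_max: float | None  # neutral requires AF < this (strict)


DATASET1 = DatasetRule("dataset1", deleterious_in_population=False, neutral_af_min=AF_THRESHOLD, neutral_af_max=None)
DATASET2 = DatasetRule("dataset2", deleterious_in_population=True, neutral_af_min=None, neutral_af_max=AF_THRESHOLD)

_RULES = {"dataset1": DATASET1, "dataset2": DATASET2}


def _keys(df: pd.DataFrame) -> pd.Series:
    return df["chrom"].astype(str) + ":" + df["pos"].astype(str) + ":" + df["ref"] + ">" + df["alt"]


def build_datasets(
    curated: pd.DataFrame,
    population: pd.DataFrame,
    rule: DatasetRule | str,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Apply a dataset rule; returns (labeled table, audit log).

    ``curated`` needs chrom/pos/ref/alt (+ optional ``source``);
    ``population`` needs chrom/pos/ref/alt/af/pass_filters. Every input row
    ends up either in the labeled output or in the audit log with a reason,
    so audit rows + output rows == input rows.
    """
    if isinstance(rule, str):
        rule = _RULES[rule]
    curated = curated.reset_index(drop=True)
    population = population.reset_index(drop=True)
    pop_keys_pass = set(_keys(population[population["pass_filters"]]))
    curated_keys = set(_keys(curated))

    audit_rows = []
    labeled_rows = []

    ckeys = _keys(curated)
    for i, row in curated.iterrows():
        in_pop = ckeys[i] in pop_keys_pass
        if in_pop == rule.deleterious_in_population:
            labeled_rows.append(
                {**{c: row[c] for c in KEY_COLUMNS}, "label": 1, "origin": "curated"}
            )
        else:
            reason = (
                "curated variant observed in population cohort"
                if in_pop
                else "curated variant not observed in population cohort"
            )
            audit_rows.append({**{c: row[c] for c in KEY_COLUMNS}, "origin": "curated", "reason": reason})

    pkeys = _keys(population)
    for i, row in population.iterrows():
        if not row["pass_filters"]:
            audit_rows.append(
                {**{c: row[c] for c in KEY_COLUMNS}, "origin": "population", "reason": "failed quality filters"}
            )
            continue
        if pkeys[i] in curated_keys:
            audit_rows.append(
                {**{c: row[c] for c in KEY_COLUMNS}, "origin": "population", "reason": "listed in curated deleterious sources"}
            )
            continue
        af = row["af"]
        if rule.neutral_af_min is not None and not af > rule.neutral_af_min:
            audit_rows.append(
                {**{c: row[c] for c in KEY_COLUMNS}, "origin": "population",
                 "reason": f"AF {af:.4g} not > {rule.neutral_af_min}"}
            )
            continue
        if rule.neutral_af_max is not None and not af < rule.neutral_af_max:
            audit_rows.append(
                {**{c: row[c] for c in KEY_COLUMNS}, "origin": "population",
                 "reason": f"AF {af:.4g} not < {rule.neutral_af_max}"}
            )
            continue
        labeled_rows.append({**{c: row[c] for c in KEY_COLUMNS}, "label": 0, "origin": "population"})

    labeled = pd.DataFrame(labeled_rows, columns=KEY_COLUMNS + ["label", "origin"])
    audit = pd.DataFrame(audit_rows, columns=KEY_COLUMNS + ["origin", "reason"])
    return labeled, audit


def build_dbmir(
    hairpins: Sequence[MirnaHairpin],
    scores: FeatureMatrix | pd.DataFrame | None = None,
    population: pd.DataFrame | None = None,
    model=None,
    extra_annotations: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Assemble the full per-allelic-SNV annotation table (dbmiR-style).

    One row per possible allelic SNV per hairpin, in deterministic order
    (hairpin id, offset, alt): genomic key, HGVS name, subregion, cluster
    flag, population AF where observed, the ten raw scores, and the model
    score when a fitted model is given (requires imputed scores).
    ``extra_annotations`` is a generic key-join: any table keyed
    chrom/pos/ref/alt whose remaining columns are appended.
    """
    from .simulate import snvs_to_frame  # local import to avoid cycle

    rows = []
    for h in sorted(hairpins, key=lambda h: h.id):
        snvs = enumerate_allelic_snvs(h)
        frame = snvs_to_frame(snvs)
        frame["cluster"] = cluster_flag(h, hairpins)
        rows.append(frame)
    db = pd.concat(rows, ignore_index=True)
    db = db.sort_values(["hairpin", "hairpin_offset", "alt"], kind="mergesort").reset_index(drop=True)

    if population is not None:
        pop = population[population["pass_filters"]][KEY_COLUMNS + ["af"]]
        db = db.merge(pop, on=KEY_COLUMNS, how="left")
    else:
        db["af"] = np.nan

    if scores is not None:
        sframe = scores.frame if isinstance(scores, FeatureMatrix) else scores
        score_cols = [c for c in SCORE_COLUMNS if c in sframe.columns]
        merged = db.merge(sframe[KEY_COLUMNS + score_cols], on=KEY_COLUMNS, how="left")
        orphan = sframe.merge(db[KEY_COLUMNS], on=KEY_COLUMNS, how="left", indicator=True)
        n_orphan = int((orphan["_merge"] == "left_only").sum())
        if n_orphan:
            warnings.warn(f"{n_orphan} score-table entries fall outside all hairpins", stacklevel=2)
        db = merged
    else:
        for c in SCORE_COLUMNS:
            db[c] = np.nan

    if model is not None:
        X = np.column_stack(
            [db[list(SCORE_COLUMNS)].to_numpy(dtype=float), is_autosomal(db["chrom"]).astype(float)]
        )
        if np.isnan(X).any():
            raise ValueError("scores contain missing values; impute before model scoring")
        db["mirlog_score"] = model.predict_score(X)
    else:
        db["mirlog_score"] = np.nan

    if extra_annotations is not None:
        db = db.merge(extra_annotations, on=KEY_COLUMNS, how="left")
    return db


# -- readers / writers -----------------------------------------------------


def read_population_vcf(path: str | Path) -> pd.DataFrame:
    """Read a VCF into chrom/pos/ref/alt/af/pass_filters rows.

    Multi-allelic records are split into one row per alternate allele; AF
    is taken from the INFO field (per-allele when a list). FILTER must be
    PASS/'.' for ``pass_filters`` to be True.
    """
    from cyvcf2 import VCF

    rows = []
    for v in VCF(str(path)):
        af = v.INFO.get("AF")
        afs = list(af) if isinstance(af, (tuple, list)) else [af] * len(v.ALT)
        passing = v.FILTER is None  # cyvcf2: None means PASS
        for alt, a in zip(v.ALT, afs):
            rows.append(
                {
                    "chrom": v.CHROM,
                    "pos": v.POS,
                    "ref": v.REF,
                    "alt": alt,
                    "af": float(a) if a is not None else np.nan,
                    "pass_filters": passing,
                }
            )
    return pd.DataFrame(rows, columns=KEY_COLUMNS + ["af", "pass_filters"])


def read_curated_tsv(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in KEY_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"curated list lacks columns: {missing}")
    return df


def read_labeled_tsv(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    if "label" not in df.columns:
        raise ValueError("labeled dataset needs a 'label' column")
    return df


def write_labeled_tsv(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index=False, float_format="%.6g")


def write_dbmir_tsv(db: pd.DataFrame, path: str | Path) -> None:
    """Deterministic TSV export; nullable fields are empty-string encoded."""
    db.to_csv(path, sep="\t", index=False, float_format="%.6g", na_rep="")
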