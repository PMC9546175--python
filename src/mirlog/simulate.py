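"""Synthetic inputs emulating the real data the toolkit consumes.

Every generator is a pure function of its :class:`SimConfig` (and explicit
arguments), so the exact files can be regenerated from a seed. The
generators emulate: miRBase-style hairpin definitions (GFF3 + FASTA),
per-tool score tables with controlled collinearity and missingness,
labeled deleterious/neutral variant sets, and population VCFs with target
SNV density, Ts/Tv ratio and allele-frequency spectrum. Sequence content
is random — no secondary-structure realism is attempted.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .anatomy import (
    DNA_BASES,
    AllelicSNV,
    MatureArm,
    MirnaHairpin,
    enumerate_allelic_snvs,
)
from .features import KEY_COLUMNS, POSITION_LEVEL_SCORES, SCORE_COLUMNS

__all__ = [
    "SimConfig",
    "gen_hairpins",
    "gen_score_matrix",
    "gen_labeled_dataset",
    "gen_population_vcf",
    "gen_curated_deleterious",
    "write_gff3",
    "write_fasta",
    "write_vcf",
    "write_score_tables",
    "snvs_to_frame",
]

#: default allele-frequency spectrum: (weight, lower, upper) log-uniform blocks;
#: 73% of variants are ultra-rare (AF <= 1e-4)
DEFAULT_AF_SPECTRUM = ((0.73, 1e-6, 1e-4), (0.17, 1e-4, 0.1), (0.10, 0.1, 0.5))

#: per-column affine (offset, scale) giving each tool a plausible native range
_COLUMN_AFFINE = {
    "cadd": (15.0, 8.0),
    "remm": (0.5, 0.25),
    "eigen_pc": (0.0, 2.0),
    "funseq": (1.5, 1.0),
    "ncer": (50.0, 25.0),
    "fathmm_xf": (0.5, 0.25),
    "dann": (0.5, 0.25),
    "linsight": (0.2, 0.15),
    "phylop": (0.0, 2.0),
    "phastcons": (0.5, 0.3),
}


@dataclass
class SimConfig:
    """Study conditions for the synthetic inputs.

    Defaults mirror the real-data regime the toolkit targets: hairpins of
    41-180 nt averaging ~80 nt, matures of 16-28 nt, about half the
    hairpins with two annotated matures, ~11% missing score cells, SNV
    density ~72/kb, Ts/Tv 2.03 and 73% ultra-rare allele frequencies.
    """

    seed: int = 0
    n_hairpins: int = 50
    hairpin_length_band: tuple[int, int] = (41, 180)
    mature_length_band: tuple[int, int] = (16, 28)
    prob_two_matures: float = 0.5
    prob_chrx: float = 0.05
    n_latent_factors: int = 3
    factor_communality: float = 0.9  # variance share carried by the latent factors
    missing_rate: float = 0.11
    class_separation: float = 3.0  # d' shift of deleterious rows along factor 1
    target_density_per_kb: float = 72.0
    target_ts_tv: float = 2.03
    af_spectrum: tuple[tuple[float, float, float], ...] = DEFAULT_AF_SPECTRUM
    pass_fraction: float = 0.95

    def __post_init__(self) -> None:
        for rate in (self.prob_two_matures, self.prob_chrx, self.missing_rate, self.pass_fraction):
            if not 0 <= rate <= 1:
                raise ValueError("probabilities and rates must lie in [0, 1]")
        if not 0 < self.factor_communality < 1:
            raise ValueError("factor_communality must be in (0, 1)")
        if abs(sum(w for w, _, _ in self.af_spectrum) - 1) > 1e-9:
            raise ValueError("af_spectrum weights must sum to 1")


def _rng(cfg: SimConfig, stream: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence((cfg.seed, stream)))


def _loadings(cfg: SimConfig) -> np.ndarray:
    """10 x k factor loadings with fixed communality per score column."""
    rng = _rng(cfg, 101)
    raw = rng.normal(size=(len(SCORE_COLUMNS), cfg.n_latent_factors))
    unit = raw / np.linalg.norm(raw, axis=1, keepdims=True)
    return math.sqrt(cfg.factor_communality) * unit


def _hairpin_length(cfg: SimConfig, rng: np.random.Generator) -> int:
    # right-skewed within the band so the mean sits near 80 nt
    lo, hi = cfg.hairpin_length_band
    for _ in range(100):
        length = int(round(lo + rng.gamma(shape=2.2, scale=18.0)))
        if lo <= length <= hi:
            return length
    return (lo + hi) // 2


def gen_hairpins(cfg: SimConfig) -> list[MirnaHairpin]:
    """Synthetic hairpins with 1 or 2 non-overlapping matures (loop >= 2 nt)."""
    rng = _rng(cfg, 1)
    lo_m, hi_m = cfg.mature_length_band
    cursors: dict[str, int] = {}
    hairpins: list[MirnaHairpin] = []
    for i in range(cfg.n_hairpins):
        if rng.random() < cfg.prob_chrx:
            chrom = "chrX"
        else:
            chrom = f"chr{rng.integers(1, 23)}"
        length = _hairpin_length(cfg, rng)
        two = rng.random() < cfg.prob_two_matures
        for attempt in range(20):
            m_lens = [int(rng.integers(lo_m, hi_m + 1)) for _ in range(2 if two else 1)]
            slack = length - sum(m_lens) - (2 if two else 0)
            if slack >= 0:
                break
        else:
            raise RuntimeError(f"cannot place matures in a {length} nt hairpin")
        pre = int(rng.integers(0, slack + 1))
        rest = slack - pre
        name = f"syn-mir-{i + 1}"
        if two:
            loop_extra = int(rng.integers(0, rest + 1))
            o1 = 1 + pre
            o2 = o1 + m_lens[0] + 2 + loop_extra
            matures = [
                MatureArm(f"syn-miR-{i + 1}-5p", o1, m_lens[0]),
                MatureArm(f"syn-miR-{i + 1}-3p", o2, m_lens[1]),
            ]
        else:
            o1 = 1 + pre
            matures = [MatureArm(f"syn-miR-{i + 1}-5p", o1, m_lens[0])]
        seq = "".join(rng.choice(["A", "C", "G", "U"], size=length))
        gap = int(rng.integers(120, 3000))
        start = cursors.get(chrom, 10_000) + gap
        cursors[chrom] = start + length
        strand = "+" if rng.random() < 0.5 else "-"
        hairpins.append(
            MirnaHairpin(
                id=name,
                chrom=chrom,
                strand=strand,
                start=start,
                end=start + length - 1,
                sequence=seq,
                matures=matures,
            )
        )
    return hairpins


def snvs_to_frame(snvs: Sequence[AllelicSNV]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "chrom": [v.chrom for v in snvs],
            "pos": [v.pos for v in snvs],
            "ref": [v.ref for v in snvs],
            "alt": [v.alt for v in snvs],
            "hairpin": [v.hairpin_id for v in snvs],
            "hairpin_offset": [v.hairpin_offset for v in snvs],
            "subregion": [v.region.value for v in snvs],
            "hgvs": [v.hgvs for v in snvs],
        }
    )


def gen_score_matrix(snvs: pd.DataFrame | Sequence[AllelicSNV], cfg: SimConfig) -> pd.DataFrame:
    """Collinear 10-score table for the given SNVs, with MCAR holes.

    Values follow a latent-factor model: per-position factor vectors mixed
    through fixed loadings plus unique noise, then mapped to each tool's
    native range. Position-level tools (phyloP, phastCons, LINSIGHT) share
    one value across the three alternate alleles of a site. Cells are set
    missing completely at random at ``cfg.missing_rate``.
    """
    if not isinstance(snvs, pd.DataFrame):
        snvs = snvs_to_frame(snvs)
    rng = _rng(cfg, 2)
    L = _loadings(cfg)
    noise_sd = math.sqrt(1 - cfg.factor_communality)
    out = snvs[KEY_COLUMNS].copy().reset_index(drop=True)
    pos_key = out["chrom"].astype(str) + ":" + out["pos"].astype(str)
    pos_index, uniq = pd.factorize(pos_key)
    factors = rng.normal(size=(len(uniq), cfg.n_latent_factors))
    signal = factors[pos_index] @ L.T  # (n, 10)
    for j, name in enumerate(SCORE_COLUMNS):
        if name in POSITION_LEVEL_SCORES:
            eps = rng.normal(scale=noise_sd, size=len(uniq))[pos_index]
        else:
            eps = rng.normal(scale=noise_sd, size=len(out))
        offset, scale = _COLUMN_AFFINE[name]
        out[name] = offset + scale * (signal[:, j] + eps)
    mask = rng.random(size=(len(out), len(SCORE_COLUMNS))) < cfg.missing_rate
    for j, name in enumerate(SCORE_COLUMNS):
        col = out[name].to_numpy()
        col[mask[:, j]] = np.nan
        out[name] = col
    return out


def gen_labeled_dataset(
    cfg: SimConfig,
    n_deleterious: int = 24,
    n_neutral: int = 219,
    missing_rate: float = 0.0,
) -> pd.DataFrame:
    """Labeled score rows: deleterious shifted along the first latent factor.

    Neutral rows draw their latent factors from N(0, I); deleterious rows
    shift factor 1 by ``cfg.class_separation`` (d'), which propagates into
    every score through the loadings. Returns a frame with the 10 score
    columns, ``autosomal`` and ``label`` (1 = deleterious).
    """
    rng = _rng(cfg, 3)
    L = _loadings(cfg)
    noise_sd = math.sqrt(1 - cfg.factor_communality)
    n = n_deleterious + n_neutral
    labels = np.r_[np.ones(n_deleterious, dtype=int), np.zeros(n_neutral, dtype=int)]
    factors = rng.normal(size=(n, cfg.n_latent_factors))
    factors[labels == 1, 0] += cfg.class_separation
    signal = factors @ L.T
    out = pd.DataFrame()
    for j, name in enumerate(SCORE_COLUMNS):
        offset, scale = _COLUMN_AFFINE[name]
        out[name] = offset + scale * (signal[:, j] + rng.normal(scale=noise_sd, size=n))
    if missing_rate:
        mask = rng.random(size=(n, len(SCORE_COLUMNS))) < missing_rate
        vals = out.to_numpy()
        vals[mask] = np.nan
        out[:] = vals
    out["autosomal"] = rng.random(n) >= cfg.prob_chrx
    out["label"] = labels
    perm = rng.permutation(n)
    return out.iloc[perm].reset_index(drop=True)


_TRANSITION = {"A": "G", "G": "A", "C": "T", "T": "C"}
_TRANSVERSIONS = {
    "A": ("C", "T"),
    "G": ("C", "T"),
    "C": ("A", "G"),
    "T": ("A", "G"),
}


def gen_population_vcf(
    hairpins: Sequence[MirnaHairpin],
    cfg: SimConfig,
    flank_nt: int = 300,
) -> pd.DataFrame:
    """Population variants over hairpin + flanking space.

    PASS variants are placed at ``cfg.target_density_per_kb`` over the union
    of hairpins and their ``flank_nt`` flanks (positions drawn without
    replacement, so each site carries at most one alternate allele);
    additional non-PASS variants are added so PASS variants make up
    ``cfg.pass_fraction`` of the total. Alternate alleles are transitions
    with probability ts_tv / (1 + ts_tv); allele frequencies follow the
    configured spectrum.
    """
    rng = _rng(cfg, 4)
    site_chrom: list[str] = []
    site_pos: list[np.ndarray] = []
    base_lookup: dict[tuple[str, int], str] = {}
    for h in hairpins:
        start = max(1, h.start - flank_nt)
        end = h.end + flank_nt
        site_chrom.extend([h.chrom] * (end - start + 1))
        site_pos.append(np.arange(start, end + 1))
        for off in range(1, len(h) + 1):
            base_lookup[(h.chrom, h.genomic_position(off))] = h.plus_strand_base(off)
    pos_arr = np.concatenate(site_pos)
    chrom_arr = np.asarray(site_chrom)
    total = len(pos_arr)
    n_pass = int(rng.poisson(cfg.target_density_per_kb * total / 1000))
    n_fail = int(round(n_pass * (1 - cfg.pass_fraction) / cfg.pass_fraction)) if cfg.pass_fraction < 1 else 0
    n = n_pass + n_fail
    if n > total:
        raise ValueError("target density too high for the simulated region")
    idx = rng.choice(total, size=n, replace=False)
    chroms = chrom_arr[idx]
    positions = pos_arr[idx]
    refs = np.array(
        [
            base_lookup.get((c, int(p))) or DNA_BASES[rng.integers(4)]
            for c, p in zip(chroms, positions)
        ]
    )
    p_ts = cfg.target_ts_tv / (1 + cfg.target_ts_tv)
    is_ts = rng.random(n) < p_ts
    alts = np.empty(n, dtype=object)
    tv_pick = rng.integers(0, 2, size=n)
    for i in range(n):
        ref = refs[i]
        alts[i] = _TRANSITION[ref] if is_ts[i] else _TRANSVERSIONS[ref][tv_pick[i]]
    weights = np.array([w for w, _, _ in cfg.af_spectrum])
    comp = rng.choice(len(weights), size=n, p=weights)
    lows = np.array([lo for _, lo, _ in cfg.af_spectrum])[comp]
    highs = np.array([hi for _, _, hi in cfg.af_spectrum])[comp]
    af = np.exp(rng.uniform(np.log(lows), np.log(highs)))
    filters = np.array(["PASS"] * n_pass + ["lowq"] * n_fail)
    df = pd.DataFrame(
        {
            "chrom": chroms,
            "pos": positions,
            "ref": refs,
            "alt": alts.astype(str),
            "af": af,
            "pass_filters": filters == "PASS",
            "filter": filters,
        }
    )
    df = df.drop_duplicates(subset=["chrom", "pos", "alt"])
    return df.sort_values(["chrom", "pos", "alt"], kind="mergesort").reset_index(drop=True)


def gen_curated_deleterious(
    hairpins: Sequence[MirnaHairpin],
    population: pd.DataFrame,
    cfg: SimConfig,
    n_absent: int = 24,
    n_present: int = 0,
) -> pd.DataFrame:
    """Synthetic curated deleterious list (emulating disease-variant sources).

    Picks ``n_absent`` hairpin SNVs not observed in the population VCF (the
    stringent deleterious class) and ``n_present`` observed ones (the
    relaxed class). Returns chrom/pos/ref/alt plus a ``source`` tag.
    """
    rng = _rng(cfg, 5)
    pop_keys = set(zip(population["chrom"], population["pos"], population["alt"]))
    absent, present = [], []
    for h in hairpins:
        for v in enumerate_allelic_snvs(h):
            k = (v.chrom, v.pos, v.alt)
            (present if k in pop_keys else absent).append(v)
    if len(absent) < n_absent or len(present) < n_present:
        raise ValueError("not enough candidate SNVs for the curated list")
    sel = [absent[i] for i in rng.choice(len(absent), size=n_absent, replace=False)]
    if n_present:
        sel += [present[i] for i in rng.choice(len(present), size=n_present, replace=False)]
    df = snvs_to_frame(sel)[KEY_COLUMNS]
    df["source"] = "curated"
    return df.sort_values(KEY_COLUMNS, kind="mergesort").reset_index(drop=True)


# -- writers (the exact dialects the readers consume) ----------------------


def write_gff3(hairpins: Sequence[MirnaHairpin], path: str | Path) -> None:
    lines = ["##gff-version 3"]
    for i, h in enumerate(hairpins):
        hid = f"MI{i + 1:07d}"
        lines.append(
            "\t".join(
                [
                    h.chrom,
                    ".",
                    "miRNA_primary_transcript",
                    str(h.start),
                    str(h.end),
                    ".",
                    h.strand,
                    ".",
                    f"ID={hid};Name={h.id}",
                ]
            )
        )
        for j, m in enumerate(h.matures):
            if h.strand == "+":
                g_start = h.start + m.offset - 1
                g_end = g_start + m.length - 1
            else:
                g_end = h.end - m.offset + 1
                g_start = g_end - m.length + 1
            lines.append(
                "\t".join(
                    [
                        h.chrom,
                        ".",
                        "miRNA",
                        str(g_start),
                        str(g_end),
                        ".",
                        h.strand,
                        ".",
                        f"ID={hid}_{j};Name={m.name};Derives_from={hid}",
                    ]
                )
            )
    Path(path).write_text("\n".join(lines) + "\n")


def write_fasta(hairpins: Sequence[MirnaHairpin], path: str | Path) -> None:
    lines = []
    for h in hairpins:
        lines.append(f">{h.id}")
        lines.append(h.sequence)
    Path(path).write_text("\n".join(lines) + "\n")


def write_vcf(variants: pd.DataFrame, path: str | Path) -> None:
    """Write a minimal VCF v4.2 with AF in INFO and the FILTER column."""
    header = [
        "##fileformat=VCFv4.2",
        '##INFO=<ID=AF,Number=A,Type=Float,Description="Allele Frequency">',
        '##FILTER=<ID=lowq,Description="Failed quality filters">',
    ]
    header += [f"##contig=<ID={c}>" for c in sorted(variants["chrom"].astype(str).unique())]
    header.append("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO")
    lines = header[:]
    for row in variants.itertuples(index=False):
        filt = getattr(row, "filter", "PASS" if row.pass_filters else "lowq")
        lines.append(
            f"{row.chrom}\t{row.pos}\t.\t{row.ref}\t{row.alt}\t.\t{filt}\tAF={row.af:.6g}"
        )
    Path(path).write_text("\n".join(lines) + "\n")


def write_score_tables(scores: pd.DataFrame, out_dir: str | Path) -> dict[str, Path]:
    """One TSV per tool; position-level tools keyed (chrom, pos) only."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}
    for name in SCORE_COLUMNS:
        if name in POSITION_LEVEL_SCORES:
            tab = (
                scores[["chrom", "pos", name]]
                .dropna()
                .drop_duplicates(subset=["chrom", "pos"])
                .rename(columns={name: "score"})
            )
        else:
            tab = scores[KEY_COLUMNS + [name]].dropna().rename(columns={name: "score"})
        p = out_dir / f"{name}.tsv"
        tab.to_csv(p, sep="\t", index=False, float_format="%.6g")
        paths[name] = p
    return paths


def write_labeled_tsv(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index=False, float_format="%.6g")
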