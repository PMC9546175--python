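"""miRNA hairpin anatomy: parsing, subregion assignment, allelic-SNV enumeration.

The coordinate conventions used throughout this module:

* genomic coordinates are 1-based inclusive (GFF3 / VCF convention);
* hairpin-local offsets are 1-based positions into the 5'->3' hairpin
  sequence (which is the reverse complement of the genomic + strand for
  minus-strand hairpins);
* reference/alternate alleles of an :class:`AllelicSNV` are DNA bases on the
  genomic + strand, while HGVS names use RNA bases in hairpin sense.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field, replace
from enum import Enum
from typing import Iterable, Sequence

import gffutils
from Bio import SeqIO

__all__ = [
    "Subregion",
    "MatureArm",
    "MirnaHairpin",
    "AllelicSNV",
    "parse_hairpins",
    "assign_subregions",
    "enumerate_allelic_snvs",
    "hgvs_name",
    "parse_hgvs",
    "locate_variant",
    "cluster_flag",
    "flanking_regions",
]

DNA_BASES = ("A", "C", "G", "T")
_DNA_COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}

#: sanity bands from the miRBase distribution of human precursors
HAIRPIN_LENGTH_BAND = (41, 180)
MATURE_LENGTH_BAND = (16, 28)
SEED_LENGTH = 8


class Subregion(str, Enum):
    """Functional subregion of a hairpin position.

    ``seed``/``rest_of_mature`` partition each mature arm; ``loop`` and
    ``out_of_loop`` partition the non-mature sequence of two-mature hairpins;
    hairpins with at most one mature arm use ``rest_of_premirna`` for all
    non-mature positions.
    """

    SEED = "seed"
    REST_OF_MATURE = "rest_of_mature"
    LOOP = "loop"
    OUT_OF_LOOP = "out_of_loop"
    REST_OF_PREMIRNA = "rest_of_premirna"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


def dna_complement(base: str) -> str:
    return _DNA_COMPLEMENT[base]


def rna_to_dna(seq: str) -> str:
    return seq.upper().replace("U", "T")


def dna_to_rna(seq: str) -> str:
    return seq.upper().replace("T", "U")


@dataclass(frozen=True)
class MatureArm:
    """A mature miRNA within its hairpin, in hairpin-local coordinates."""

    name: str
    offset: int  # 1-based start within the hairpin sequence
    length: int

    @property
    def end(self) -> int:
        """1-based inclusive end offset within the hairpin."""
        return self.offset + self.length - 1


@dataclass
class MirnaHairpin:
    """An extended miRNA precursor (pre-miRNA) with its mature arms.

    ``sequence`` is the RNA sequence 5'->3' of the hairpin itself; for a
    minus-strand hairpin it is the reverse complement of the genomic
    + strand.
    """

    id: str
    chrom: str
    strand: str
    start: int
    end: int
    sequence: str
    matures: list[MatureArm] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.sequence = dna_to_rna(self.sequence)
        if self.strand not in {"+", "-"}:
            raise ValueError(f"{self.id}: strand must be '+' or '-', got {self.strand!r}")
        if len(self.sequence) != self.end - self.start + 1:
            raise ValueError(
                f"{self.id}: sequence length {len(self.sequence)} does not match "
                f"genomic span {self.chrom}:{self.start}-{self.end} "
                f"({self.end - self.start + 1} nt)"
            )
        if len(self.matures) > 2:
            raise ValueError(f"{self.id}: more than two mature arms")
        for m in self.matures:
            if m.offset < 1 or m.end > len(self.sequence):
                raise ValueError(f"{self.id}: mature {m.name} not contained in hairpin")
        ms = sorted(self.matures, key=lambda m: m.offset)
        for a, b in zip(ms, ms[1:]):
            if b.offset <= a.end:
                raise ValueError(f"{self.id}: mature arms {a.name} and {b.name} overlap")
        lo, hi = HAIRPIN_LENGTH_BAND
        if not lo <= len(self.sequence) <= hi:
            warnings.warn(
                f"{self.id}: hairpin length {len(self.sequence)} outside the "
                f"usual {lo}-{hi} nt band",
                stacklevel=2,
            )
        for m in self.matures:
            lo, hi = MATURE_LENGTH_BAND
            if not lo <= m.length <= hi:
                warnings.warn(
                    f"{self.id}: mature {m.name} length {m.length} outside the "
                    f"usual {lo}-{hi} nt band",
                    stacklevel=2,
                )

    def __len__(self) -> int:
        return len(self.sequence)

    def genomic_position(self, offset: int) -> int:
        """Genomic 1-based position of hairpin-local ``offset``."""
        if not 1 <= offset <= len(self):
            raise ValueError(f"offset {offset} outside hairpin {self.id}")
        if self.strand == "+":
            return self.start + offset - 1
        return self.end - offset + 1

    def local_offset(self, pos: int) -> int:
        """Hairpin-local offset of genomic position ``pos`` (must overlap)."""
        if not self.start <= pos <= self.end:
            raise ValueError(f"position {pos} outside hairpin {self.id}")
        if self.strand == "+":
            return pos - self.start + 1
        return self.end - pos + 1

    def plus_strand_base(self, offset: int) -> str:
        """Genomic + strand DNA base at hairpin-local ``offset``."""
        base = rna_to_dna(self.sequence[offset - 1])
        if self.strand == "-":
            base = dna_complement(base)
        return base


@dataclass
class AllelicSNV:
    """One possible single-nucleotide substitution at a hairpin position."""

    hairpin_id: str
    chrom: str
    pos: int  # genomic, 1-based
    hairpin_offset: int  # 1-based within hairpin
    ref: str  # genomic + strand DNA base
    alt: str  # genomic + strand DNA base
    region: Subregion
    hgvs: str
    ref_matches: bool = True

    @property
    def key(self) -> tuple[str, int, str, str]:
        return (self.chrom, self.pos, self.ref, self.alt)


def assign_subregions(h: MirnaHairpin) -> dict[int, Subregion]:
    """Map every hairpin offset to its subregion label.

    Seeds are mature positions 1-8; positions 9..end of each mature are
    ``rest_of_mature``. With exactly two matures the remaining positions
    split into ``loop`` (strictly between the arms) and ``out_of_loop``
    (outside both); with <=1 mature they are all ``rest_of_premirna``.
    """
    for m in h.matures:
        if m.length < SEED_LENGTH:
            raise ValueError(
                f"{h.id}: mature {m.name} is {m.length} nt, shorter than the "
                f"{SEED_LENGTH} nt seed"
            )
    labels: dict[int, Subregion] = {}
    matures = sorted(h.matures, key=lambda m: m.offset)
    for m in matures:
        for i in range(m.offset, m.end + 1):
            rel = i - m.offset + 1
            labels[i] = Subregion.SEED if rel <= SEED_LENGTH else Subregion.REST_OF_MATURE
    if len(matures) == 2:
        first, second = matures
        for i in range(1, len(h) + 1):
            if i in labels:
                continue
            if first.end < i < second.offset:
                labels[i] = Subregion.LOOP
            else:
                labels[i] = Subregion.OUT_OF_LOOP
    else:
        for i in range(1, len(h) + 1):
            labels.setdefault(i, Subregion.REST_OF_PREMIRNA)
    return labels


def hgvs_name(hairpin_id: str, offset: int, ref_rna: str, alt_rna: str) -> str:
    """HGVS-style name for a noncoding-RNA substitution, e.g. ``x:n.34A>G``."""
    return f"{hairpin_id}:n.{offset}{ref_rna}>{alt_rna}"


_HGVS_RE = re.compile(r"^(?P<id>[^:]+):n\.(?P<offset>\d+)(?P<ref>[ACGU])>(?P<alt>[ACGU])$")


def parse_hgvs(name: str) -> tuple[str, int, str, str]:
    """Inverse of :func:`hgvs_name`: ``(hairpin_id, offset, ref_rna, alt_rna)``."""
    m = _HGVS_RE.match(name)
    if m is None:
        raise ValueError(f"not a valid n. substitution name: {name!r}")
    return (m["id"], int(m["offset"]), m["ref"], m["alt"])


def _snv_at(h: MirnaHairpin, offset: int, alt: str, labels: dict[int, Subregion]) -> AllelicSNV:
    ref = h.plus_strand_base(offset)
    ref_rna = h.sequence[offset - 1]
    alt_local = dna_complement(alt) if h.strand == "-" else alt
    return AllelicSNV(
        hairpin_id=h.id,
        chrom=h.chrom,
        pos=h.genomic_position(offset),
        hairpin_offset=offset,
        ref=ref,
        alt=alt,
        region=labels[offset],
        hgvs=hgvs_name(h.id, offset, ref_rna, dna_to_rna(alt_local)),
    )


def enumerate_allelic_snvs(h: MirnaHairpin) -> list[AllelicSNV]:
    """All possible substitutions in ``h``: 3 per unambiguous position.

    Positions whose base is not A/C/G/U are skipped with a warning, so the
    returned count is ``3 * (len(h) - n_ambiguous)``.
    """
    labels = assign_subregions(h)
    out: list[AllelicSNV] = []
    for offset in range(1, len(h) + 1):
        base = rna_to_dna(h.sequence[offset - 1])
        if base not in DNA_BASES:
            warnings.warn(
                f"{h.id}: ambiguous base {base!r} at offset {offset}, skipped",
                stacklevel=2,
            )
            continue
        ref = h.plus_strand_base(offset)
        for alt in DNA_BASES:
            if alt != ref:
                out.append(_snv_at(h, offset, alt, labels))
    return out


def locate_variant(
    chrom: str,
    pos: int,
    ref: str,
    alt: str,
    hairpins: Iterable[MirnaHairpin],
) -> list[AllelicSNV]:
    """Place a genomic substitution into every overlapping hairpin.

    Returns one :class:`AllelicSNV` per hairpin containing ``pos`` (hairpins
    may overlap); the entry's ``ref_matches`` flag is False when the supplied
    ref allele disagrees with the hairpin sequence.
    """
    ref, alt = ref.upper(), alt.upper()
    if ref not in DNA_BASES or alt not in DNA_BASES:
        raise ValueError(f"malformed alleles {ref!r}>{alt!r}: single DNA bases required")
    if ref == alt:
        raise ValueError("ref and alt alleles are identical")
    hits: list[AllelicSNV] = []
    for h in hairpins:
        if h.chrom != chrom or not h.start <= pos <= h.end:
            continue
        offset = h.local_offset(pos)
        labels = assign_subregions(h)
        snv = _snv_at(h, offset, alt, labels)
        if snv.ref != ref:
            snv = replace(snv, ref=ref, ref_matches=False)
        hits.append(snv)
    return hits


def cluster_flag(h: MirnaHairpin, hairpins: Iterable[MirnaHairpin], window: int = 200) -> bool:
    """True when another hairpin lies within ``window`` nt of ``h`` (or overlaps)."""
    for other in hairpins:
        if other is h or (other.id == h.id and other.start == h.start and other.chrom == h.chrom):
            continue
        if other.chrom != h.chrom:
            continue
        if other.start <= h.end + window and other.end >= h.start - window:
            return True
    return False


def flanking_regions(
    h: MirnaHairpin, width: int = 100, count: int = 3
) -> list[tuple[str, int, int, str]]:
    """Non-overlapping flanking intervals adjacent to the hairpin span.

    Returns up to ``2 * count`` tuples ``(chrom, start, end, label)`` with
    labels ``upstream_1..`` / ``downstream_1..`` (1 = nearest the hairpin).
    Upstream regions truncated by the chromosome start are clipped, or
    dropped with a warning when fully off-chromosome.
    """
    regions: list[tuple[str, int, int, str]] = []
    for i in range(1, count + 1):
        start = h.start - i * width
        end = h.start - (i - 1) * width - 1
        if end < 1:
            warnings.warn(
                f"{h.id}: upstream flank {i} lies before the chromosome start, dropped",
                stacklevel=2,
            )
            continue
        if start < 1:
            warnings.warn(f"{h.id}: upstream flank {i} truncated at chromosome start", stacklevel=2)
            start = 1
        regions.append((h.chrom, start, end, f"upstream_{i}"))
    for i in range(1, count + 1):
        start = h.end + (i - 1) * width + 1
        end = h.end + i * width
        regions.append((h.chrom, start, end, f"downstream_{i}"))
    return regions


def parse_hairpins(gff3_source: str, fasta_source: str) -> list[MirnaHairpin]:
    """Read hairpin + mature definitions from a miRBase-style GFF3 and FASTA.

    The GFF3 must carry ``miRNA_primary_transcript`` features (hairpins) and
    ``miRNA`` features (matures) linked by ``Derives_from``; matures without
    that attribute are attached to the hairpin containing them. FASTA ids
    must match hairpin ``Name`` (or ``ID``) attributes; T/U are normalised.

    A mature feature contained in no hairpin is rejected with a warning; a
    FASTA/GFF3 length mismatch is a hard error naming the record.
    """
    db = gffutils.create_db(
        str(gff3_source),
        dbfn=":memory:",
        force=True,
        keep_order=True,
        merge_strategy="create_unique",
    )
    seqs = {rec.id: str(rec.seq) for rec in SeqIO.parse(str(fasta_source), "fasta")}

    hairpin_feats: dict[str, gffutils.Feature] = {}
    names: dict[str, str] = {}
    for f in db.features_of_type("miRNA_primary_transcript"):
        fid = f.attributes.get("ID", [f.id])[0]
        hairpin_feats[fid] = f
        names[fid] = f.attributes.get("Name", [fid])[0]

    matures_by_hairpin: dict[str, list[gffutils.Feature]] = {fid: [] for fid in hairpin_feats}
    for m in db.features_of_type("miRNA"):
        parent = m.attributes.get("Derives_from", [None])[0]
        if parent is None or parent not in hairpin_feats:
            parent = None
            for fid, hf in hairpin_feats.items():
                if hf.seqid == m.seqid and hf.start <= m.start and m.end <= hf.end:
                    parent = fid
                    break
        if parent is None:
            mname = m.attributes.get("Name", [m.id])[0]
            warnings.warn(f"mature {mname} not contained in any hairpin, rejected", stacklevel=2)
            continue
        matures_by_hairpin[parent].append(m)

    hairpins: list[MirnaHairpin] = []
    for fid, hf in hairpin_feats.items():
        name = names[fid]
        seq = seqs.get(name, seqs.get(fid))
        if seq is None:
            raise ValueError(f"no FASTA sequence for hairpin {name}")
        if len(seq) != hf.end - hf.start + 1:
            raise ValueError(
                f"hairpin {name}: FASTA sequence length {len(seq)} does not match "
                f"GFF3 span {hf.seqid}:{hf.start}-{hf.end}"
            )
        matures = []
        for m in matures_by_hairpin[fid]:
            mname = m.attributes.get("Name", [m.id])[0]
            if m.start < hf.start or m.end > hf.end:
                warnings.warn(
                    f"mature {mname} not contained in hairpin {name}, rejected",
                    stacklevel=2,
                )
                continue
            if hf.strand == "+":
                offset = m.start - hf.start + 1
            else:
                offset = hf.end - m.end + 1
            matures.append(MatureArm(name=mname, offset=offset, length=m.end - m.start + 1))
        hairpins.append(
            MirnaHairpin(
                id=name,
                chrom=hf.seqid,
                strand=hf.strand,
                start=hf.start,
                end=hf.end,
                sequence=seq,
                matures=sorted(matures, key=lambda a: a.offset),
            )
        )
    return hairpins


def subregion_table(hairpins: Sequence[MirnaHairpin]):
    """BED-like per-position subregion map as a pandas DataFrame."""
    import pandas as pd

    rows = []
    for h in hairpins:
        labels = assign_subregions(h)
        for offset in range(1, len(h) + 1):
            rows.append(
                {
                    "chrom": h.chrom,
                    "pos": h.genomic_position(offset),
                    "hairpin": h.id,
                    "offset": offset,
                    "subregion": labels[offset].value,
                }
            )
    return pd.DataFrame(rows)
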