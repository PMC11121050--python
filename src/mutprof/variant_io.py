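"""VCF reading/writing, hard filters, mutant-vs-wild-type subtraction.

Coordinates are 1-based (VCF native) throughout this module.  Window
arithmetic downstream (``hotspot_scan``) converts to 0-based half-open bins.
"""

from __future__ import annotations

import logging
import os
from collections import Counter
from dataclasses import dataclass, field, fields

from cyvcf2 import VCF

logger = logging.getLogger(__name__)

SBS = "SBS"
INS = "INS"
DEL = "DEL"
OTHER = "other"

_VALID_BASES = frozenset("ACGT")


@dataclass(frozen=True)
class Mutation:
    """One induced variant carried by a mutant line.

    ``indel_len`` is 0 for SBSs and ``|len(ref) - len(alt)|`` for InDels.
    """

    line_id: str
    chrom: str
    pos: int  # 1-based
    ref: str
    alt: str
    mclass: str
    zygosity: str = "unknown"
    indel_len: int = 0

    def __post_init__(self) -> None:
        if not self.ref or not self.alt or self.ref == self.alt:
            raise ValueError(f"invalid alleles {self.ref!r}>{self.alt!r}")
        if not (_VALID_BASES.issuperset(self.ref) and _VALID_BASES.issuperset(self.alt)):
            raise ValueError(f"non-ACGT alleles {self.ref!r}>{self.alt!r}")
        if self.mclass not in (SBS, INS, DEL):
            raise ValueError(f"bad mutation class {self.mclass!r}")

    @property
    def key(self) -> tuple[str, int, str, str]:
        return (self.chrom, self.pos, self.ref, self.alt)

    @property
    def is_indel(self) -> bool:
        return self.mclass in (INS, DEL)


@dataclass(frozen=True)
class FilterThresholds:
    """Hard-filter cutoffs mirrored from the GATK VariantFiltration step."""

    qd_min: float = 2.0
    fs_max: float = 60.0
    mq_min: float = 40.0
    gq_min: int = 20
    indel_len_max: int = 50

    def __post_init__(self) -> None:
        for f in fields(self):
            v = getattr(self, f.name)
            if not (v > 0 and v == v):
                raise ValueError(f"threshold {f.name} must be finite and positive, got {v}")


@dataclass(frozen=True)
class RawVariant:
    """A single-sample, single-alt VCF record as read from disk."""

    line_id: str
    chrom: str
    pos: int  # 1-based
    ref: str
    alt: str
    qd: float | None = None
    fs: float | None = None
    mq: float | None = None
    gq: int | None = None
    genotype: str = "./."

    @property
    def key(self) -> tuple[str, int, str, str]:
        return (self.chrom, self.pos, self.ref, self.alt)

    @property
    def zygosity(self) -> str:
        alleles = self.genotype.replace("|", "/").split("/")
        if alleles == ["1", "1"]:
            return "hom"
        if sorted(alleles) == ["0", "1"]:
            return "het"
        return "unknown"


@dataclass
class ExclusionLog:
    """Counts every record excluded between raw read and induced set."""

    hard_filtered: int = 0
    wt_shared: int = 0
    mnv: int = 0
    indel_too_long: int = 0
    duplicate_keys: int = 0
    stop_loss_as_nonsyn: int = 0

    def as_dict(self) -> dict[str, int]:
        return {f.name: getattr(self, f.name) for f in fields(self)}

    def total_excluded(self) -> int:
        return self.hard_filtered + self.wt_shared + self.mnv + self.indel_too_long + self.duplicate_keys

    def emit(self, prefix: str = "") -> None:
        for name, count in self.as_dict().items():
            logger.info("%sexcluded %s=%d", prefix, name, count)


def read_vcf(path: str | os.PathLike, line_id: str) -> list[RawVariant]:
    """Read a single-sample VCF into :class:`RawVariant` records.

    Multi-allelic records are split into one record per alt allele.  INFO
    fields QD/FS/MQ and the sample's GQ are carried when present, ``None``
    when absent.
    """
    path = os.fspath(path)
    if not os.path.exists(path):
        raise FileNotFoundError(path)
    vcf = VCF(path)
    try:
        if len(vcf.samples) == 0:
            raise ValueError(f"{path}: VCF has no sample column")
        records: list[RawVariant] = []
        for i, v in enumerate(vcf):
            try:
                qd = v.INFO.get("QD")
                fs = v.INFO.get("FS")
                mq = v.INFO.get("MQ")
                gq = None
                try:
                    g = v.gt_quals[0]
                    if g is not None and g >= 0:
                        gq = int(g)
                except (TypeError, IndexError):
                    gq = None
                gts = v.genotypes[0] if v.genotypes else [-1, -1, False]
                sep = "|" if (len(gts) > 2 and gts[-1]) else "/"
                gt_alleles = [str(a) if a >= 0 else "." for a in gts[:-1]]
                for alt_index, alt in enumerate(v.ALT, start=1):
                    # when splitting, alleles other than this alt map to ref
                    remapped = [
                        "." if a == "." else ("1" if int(a) == alt_index else "0")
                        for a in gt_alleles
                    ]
                    records.append(
                        RawVariant(
                            line_id=line_id,
                            chrom=v.CHROM,
                            pos=v.POS,
                            ref=v.REF,
                            alt=alt,
                            qd=float(qd) if qd is not None else None,
                            fs=float(fs) if fs is not None else None,
                            mq=float(mq) if mq is not None else None,
                            gq=gq,
                            genotype=sep.join(remapped),
                        )
                    )
            except Exception as exc:  # pragma: no cover - defensive
                raise ValueError(f"{path}: malformed VCF record #{i + 1}: {exc}") from exc
        return records
    finally:
        vcf.close()


def passes_hard_filters(record: RawVariant, thresholds: FilterThresholds) -> bool:
    """Missing annotations pass (GATK convention: filters only remove on
    an explicit threshold breach)."""
    if record.qd is not None and record.qd < thresholds.qd_min:
        return False
    if record.fs is not None and record.fs > thresholds.fs_max:
        return False
    if record.mq is not None and record.mq < thresholds.mq_min:
        return False
    if record.gq is not None and record.gq < thresholds.gq_min:
        return False
    return True


def apply_hard_filters(
    records: list[RawVariant],
    thresholds: FilterThresholds | None = None,
    log: ExclusionLog | None = None,
) -> list[RawVariant]:
    """Remove records breaching QD/FS/MQ site filters or the sample GQ
    filter; order is preserved."""
    thresholds = thresholds or FilterThresholds()
    kept = [r for r in records if passes_hard_filters(r, thresholds)]
    if log is not None:
        log.hard_filtered += len(records) - len(kept)
    return kept


def classify_mutation(ref: str, alt: str) -> tuple[str, int]:
    """Classify an allele pair into (mclass, indel_len).

    SBS when both alleles are single bases; INS/DEL by length difference of
    anchored VCF alleles; equal-length multi-base pairs are MNVs and come
    back as ``other`` (excluded from SBS/InDel tallies).
    """
    lr, la = len(ref), len(alt)
    if lr == 1 and la == 1:
        return SBS, 0
    if la > lr:
        return INS, la - lr
    if lr > la:
        return DEL, lr - la
    return OTHER, 0


def derive_induced(
    mutant_records: list[RawVariant],
    wildtype_records: list[RawVariant],
    indel_len_max: int = 50,
    log: ExclusionLog | None = None,
) -> list[Mutation]:
    """Induced mutations = mutant records whose (chrom, pos, ref, alt) key is
    absent from the wild-type set.

    MNVs and InDels longer than ``indel_len_max`` are dropped and counted in
    ``log``.  Duplicate keys within either input are deduplicated with a
    warning count.
    """
    log = log if log is not None else ExclusionLog()

    def dedup(records: list[RawVariant]) -> dict[tuple, RawVariant]:
        counts = Counter(r.key for r in records)
        n_dup = sum(c - 1 for c in counts.values())
        if n_dup:
            log.duplicate_keys += n_dup
            logger.warning("deduplicated %d duplicate record keys", n_dup)
        out: dict[tuple, RawVariant] = {}
        for r in records:
            out.setdefault(r.key, r)
        return out

    mut = dedup(mutant_records)
    wt_keys = set(dedup(wildtype_records))

    induced: list[Mutation] = []
    for key, rec in mut.items():
        if key in wt_keys:
            log.wt_shared += 1
            continue
        mclass, indel_len = classify_mutation(rec.ref, rec.alt)
        if mclass == OTHER:
            log.mnv += 1
            continue
        if indel_len > indel_len_max:
            log.indel_too_long += 1
            continue
        induced.append(
            Mutation(
                line_id=rec.line_id,
                chrom=rec.chrom,
                pos=rec.pos,
                ref=rec.ref,
                alt=rec.alt,
                mclass=mclass,
                zygosity=rec.zygosity,
                indel_len=indel_len,
            )
        )
    return induced


MUTATION_TSV_COLUMNS = ["line_id", "chrom", "pos", "ref", "alt", "mclass", "indel_len", "zygosity"]


def write_mutations_tsv(path: str | os.PathLike, mutations: list[Mutation]) -> None:
    with open(path, "w") as fh:
        fh.write("\t".join(MUTATION_TSV_COLUMNS) + "\n")
        for m in mutations:
            fh.write(
                f"{m.line_id}\t{m.chrom}\t{m.pos}\t{m.ref}\t{m.alt}\t{m.mclass}\t{m.indel_len}\t{m.zygosity}\n"
            )


def read_mutations_tsv(path: str | os.PathLike) -> list[Mutation]:
    out: list[Mutation] = []
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header != MUTATION_TSV_COLUMNS:
            raise ValueError(f"{path}: unexpected header {header}")
        for ln in fh:
            line_id, chrom, pos, ref, alt, mclass, indel_len, zyg = ln.rstrip("\n").split("\t")
            out.append(
                Mutation(line_id, chrom, int(pos), ref, alt, mclass, zyg, int(indel_len))
            )
    return out


def write_vcf(
    path: str | os.PathLike,
    contig_lengths: dict[str, int],
    rows: list[tuple],
    sample: str,
) -> None:
    """Write a minimal single-sample VCF 4.2.

    ``rows`` are (chrom, pos, ref, alt, qd, fs, mq, gt, gq) tuples, sorted by
    the caller.  Plain text keeps fixtures diffable and deterministic.
    """
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        for chrom, length in contig_lengths.items():
            fh.write(f"##contig=<ID={chrom},length={length}>\n")
        fh.write('##INFO=<ID=QD,Number=1,Type=Float,Description="Quality by depth">\n')
        fh.write('##INFO=<ID=FS,Number=1,Type=Float,Description="Fisher strand bias">\n')
        fh.write('##INFO=<ID=MQ,Number=1,Type=Float,Description="RMS mapping quality">\n')
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write('##FORMAT=<ID=GQ,Number=1,Type=Integer,Description="Genotype quality">\n')
        fh.write(f"#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t{sample}\n")
        for chrom, pos, ref, alt, qd, fs, mq, gt, gq in rows:
            info = f"QD={qd:g};FS={fs:g};MQ={mq:g}"
            fh.write(f"{chrom}\t{pos}\t.\t{ref}\t{alt}\t.\t.\t{info}\tGT:GQ\t{gt}:{gq}\n")
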