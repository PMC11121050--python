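"""Synthetic genomes, gene models, and planted mutation sets.

Generates toy fixtures with the statistical structure the downstream
analysis assumes — a configurable SBS/InDel mix, directional substitution
weights, InDel length distribution, and planted hotspot regions — together
with a truth table, so every stage is testable without external data.

All randomness flows through one ``numpy.random.Generator`` per fixture.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, field

import numpy as np
from Bio.Seq import Seq

from . import feature_effects, variant_io
from .feature_effects import GenomeAnnotation, TranscriptModel
from .mutation_spectrum import SUB_TYPES, TRANSITIONS

_BASES = ("A", "C", "G", "T")
_STOP_CODONS = ("TAA", "TAG", "TGA")
_NONSTOP_CODONS = tuple(
    a + b + c
    for a in _BASES
    for b in _BASES
    for c in _BASES
    if a + b + c not in _STOP_CODONS
)

INDEL_LEN_MAX = 50

#: synthetic annotation defaults; chosen to pass the default hard filters
DEFAULT_QD = 20.0
DEFAULT_FS = 1.0
DEFAULT_MQ = 60.0
DEFAULT_GQ = 99


@dataclass(frozen=True)
class SpectrumParams:
    """Planted mutation-spectrum parameters.

    ``sub_weights`` are 12 nonnegative directional weights whose transition
    share must equal ``ti_fraction``; ``indel_len_dist`` is a probability
    vector over lengths 1..50.
    """

    ti_fraction: float
    sub_weights: dict[str, float]
    indel_fraction: float
    indel_len_dist: tuple[float, ...]
    ins_del_balance: float = 0.5

    def __post_init__(self) -> None:
        for name in ("ti_fraction", "indel_fraction", "ins_del_balance"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0,1], got {v}")
        if set(self.sub_weights) != set(SUB_TYPES):
            raise ValueError("sub_weights must cover exactly the 12 directional types")
        if any(w < 0 for w in self.sub_weights.values()):
            raise ValueError("sub_weights must be nonnegative")
        total = sum(self.sub_weights.values())
        if total <= 0:
            raise ValueError("sub_weights must not all be zero")
        ti_share = sum(w for t, w in self.sub_weights.items() if t in TRANSITIONS) / total
        if abs(ti_share - self.ti_fraction) > 1e-9:
            raise ValueError(
                f"sub_weights transition share {ti_share} inconsistent with ti_fraction {self.ti_fraction}"
            )
        if len(self.indel_len_dist) != INDEL_LEN_MAX:
            raise ValueError(f"indel_len_dist must have {INDEL_LEN_MAX} entries")
        if abs(sum(self.indel_len_dist) - 1.0) > 1e-9:
            raise ValueError("indel_len_dist must sum to 1")

    @classmethod
    def default(
        cls,
        ti_fraction: float = 0.565,
        indel_fraction: float = 0.12,
        ins_del_balance: float = 0.5,
        short_indel_fraction: float = 0.65,
    ) -> "SpectrumParams":
        """Defaults emulating a heavy-ion mutagenesis spectrum: SBS-dominated
        (~88%), Ti/Tv ~1.3, InDel lengths geometric with ~65% at 1-2 bp."""
        weights = {
            t: (ti_fraction / 4 if t in TRANSITIONS else (1 - ti_fraction) / 8)
            for t in SUB_TYPES
        }
        # geometric length distribution with P(len<=2) = short_indel_fraction
        p = 1.0 - np.sqrt(1.0 - short_indel_fraction)
        lens = np.arange(1, INDEL_LEN_MAX + 1)
        dist = p * (1 - p) ** (lens - 1)
        dist = dist / dist.sum()
        return cls(
            ti_fraction=ti_fraction,
            sub_weights=weights,
            indel_fraction=indel_fraction,
            indel_len_dist=tuple(dist),
            ins_del_balance=ins_del_balance,
        )


@dataclass(frozen=True)
class HotspotRegion:
    chrom: str
    start: int  # 0-based half-open
    end: int
    fold: float

    def __post_init__(self) -> None:
        if self.fold < 1:
            raise ValueError("hotspot fold must be >= 1")
        if self.end <= self.start or self.start < 0:
            raise ValueError("invalid hotspot interval")

    def contains(self, pos: int) -> bool:
        """pos is 1-based."""
        return self.start < pos <= self.end


@dataclass(frozen=True)
class HotspotSpec:
    """Planted per-bp rate multipliers relative to background."""

    regions: tuple[HotspotRegion, ...] = ()

    def validate(self, contig_lengths: dict[str, int]) -> None:
        by_chrom: dict[str, list[HotspotRegion]] = {}
        for r in self.regions:
            if r.chrom not in contig_lengths:
                raise ValueError(f"hotspot on unknown chromosome {r.chrom!r}")
            if r.end > contig_lengths[r.chrom]:
                raise ValueError(f"hotspot {r.chrom}:{r.start}-{r.end} beyond contig bounds")
            by_chrom.setdefault(r.chrom, []).append(r)
        for regions in by_chrom.values():
            regions.sort(key=lambda r: r.start)
            for a, b in zip(regions, regions[1:]):
                if b.start < a.end:
                    raise ValueError(f"overlapping hotspot regions on {a.chrom}")

    def contains(self, chrom: str, pos: int) -> bool:
        return any(r.chrom == chrom and r.contains(pos) for r in self.regions)

    @classmethod
    def parse(cls, specs: list[str]) -> "HotspotSpec":
        """Parse "chrom:start-end:fold" strings (0-based half-open)."""
        regions = []
        for s in specs:
            chrom, span, fold = s.rsplit(":", 2)
            start, end = span.split("-")
            regions.append(HotspotRegion(chrom, int(start), int(end), float(fold)))
        return cls(tuple(regions))


@dataclass(frozen=True)
class TruthRecord:
    """One planted mutation with its oracle annotations."""

    line_id: str
    chrom: str
    pos: int
    ref: str
    alt: str
    mclass: str
    sub_type: str  # "" for InDels
    indel_len: int
    in_hotspot: bool
    oracle_effect: str  # "" for noncoding mutations

    @property
    def key(self) -> tuple[str, int, str, str]:
        return (self.chrom, self.pos, self.ref, self.alt)


# ---------------------------------------------------------------------------
# genome generation


def _random_sequence(rng: np.random.Generator, length: int, gc_fraction: float) -> np.ndarray:
    p_gc = gc_fraction / 2
    p_at = (1 - gc_fraction) / 2
    return rng.choice(np.array(list("ACGT")), size=length, p=[p_at, p_gc, p_gc, p_at])


def _make_gene(rng: np.random.Generator) -> list[tuple[str, str]]:
    """Transcript-order pieces (type, sequence); types: utr5/cds/intron/utr3."""
    n_codons = int(rng.integers(40, 200))  # internal codons
    cds = "ATG" + "".join(rng.choice(_NONSTOP_CODONS) for _ in range(n_codons))
    cds += str(rng.choice(_STOP_CODONS))
    utr5 = "".join(rng.choice(_BASES, size=int(rng.integers(30, 100))))
    utr3 = "".join(rng.choice(_BASES, size=int(rng.integers(30, 100))))
    pieces: list[tuple[str, str]] = [("utr5", utr5)]
    if rng.random() < 0.6:  # single intron splitting the CDS
        cut = int(rng.integers(1, len(cds)))
        intron = "".join(rng.choice(_BASES, size=int(rng.integers(60, 300))))
        pieces += [("cds", cds[:cut]), ("intron", intron), ("cds", cds[cut:])]
    else:
        pieces.append(("cds", cds))
    pieces.append(("utr3", utr3))
    return pieces


def _place_gene(
    pieces: list[tuple[str, str]], start: int, strand: str
) -> tuple[str, TranscriptModel]:
    """Lay transcript pieces onto the genome at 0-based ``start``; returns the
    genomic sequence of the span and the transcript model."""
    if strand == "-":
        genomic_pieces = [
            (kind, str(Seq(seq).reverse_complement())) for kind, seq in reversed(pieces)
        ]
    else:
        genomic_pieces = pieces
    seq = "".join(s for _, s in genomic_pieces)
    intervals: dict[str, list[tuple[int, int]]] = {"utr5": [], "cds": [], "intron": [], "utr3": []}
    cursor = start
    for kind, piece in genomic_pieces:
        intervals[kind].append((cursor + 1, cursor + len(piece)))  # 1-based inclusive
        cursor += len(piece)
    non_intron = sorted(intervals["utr5"] + intervals["cds"] + intervals["utr3"])
    exons: list[tuple[int, int]] = []
    for s, e in non_intron:
        if exons and s == exons[-1][1] + 1:
            exons[-1] = (exons[-1][0], e)
        else:
            exons.append((s, e))
    model = TranscriptModel(
        transcript_id="PLACEHOLDER",
        chrom="PLACEHOLDER",
        strand=strand,
        exons=tuple(exons),
        cds=tuple(intervals["cds"]),
        utr5=tuple(intervals["utr5"]),
        utr3=tuple(intervals["utr3"]),
    )
    return seq, model


def _generate_genome(
    rng: np.random.Generator,
    n_chromosomes: int,
    chrom_length: int,
    gene_count: int,
    gc_fraction: float,
) -> tuple[dict[str, str], GenomeAnnotation]:
    if chrom_length < 10_000:
        raise ValueError("chrom_length must be >= 10,000")
    if gene_count < 0:
        raise ValueError("gene_count must be >= 0")
    contigs = {f"chr{i + 1}": chrom_length for i in range(n_chromosomes)}
    genome: dict[str, str] = {}
    transcripts: list[TranscriptModel] = []
    per_chrom = [gene_count // n_chromosomes + (1 if i < gene_count % n_chromosomes else 0)
                 for i in range(n_chromosomes)]
    tx_counter = 0
    min_gap = 1500
    for ci, (chrom, k) in enumerate(zip(contigs, per_chrom)):
        background = _random_sequence(rng, chrom_length, gc_fraction)
        genes = [(_make_gene(rng), "+" if rng.random() < 0.5 else "-") for _ in range(k)]
        spans = [sum(len(s) for _, s in pieces) for pieces, _ in genes]
        free = chrom_length - sum(spans) - (k + 1) * min_gap
        if k and free < 0:
            raise ValueError(
                f"infeasible packing: {k} genes (total {sum(spans)} bp + gaps) "
                f"do not fit in {chrom_length} bp"
            )
        if k:
            gaps = rng.multinomial(free, [1.0 / (k + 1)] * (k + 1)) + min_gap
            cursor = 0
            for gi, ((pieces, strand), span) in enumerate(zip(genes, spans)):
                cursor += int(gaps[gi])
                seq, model = _place_gene(pieces, cursor, strand)
                background[cursor : cursor + span] = list(seq)
                tx_counter += 1
                transcripts.append(
                    TranscriptModel(
                        transcript_id=f"tx{tx_counter:04d}",
                        chrom=chrom,
                        strand=model.strand,
                        exons=model.exons,
                        cds=model.cds,
                        utr5=model.utr5,
                        utr3=model.utr3,
                    )
                )
                cursor += span
        genome[chrom] = "".join(background)
    return genome, GenomeAnnotation(contig_lengths=contigs, transcripts=transcripts)


def generate_genome(
    n_chromosomes: int,
    chrom_length: int,
    gene_count: int,
    seed: int,
    gc_fraction: float = 0.5,
) -> tuple[dict[str, str], GenomeAnnotation]:
    """Random genome with non-overlapping strand-assigned gene models.

    Every CDS starts with ATG, ends with a stop codon, has no internal stop,
    and its length is a multiple of 3.  Deterministic given ``seed``.
    """
    rng = np.random.default_rng(seed)
    return _generate_genome(rng, n_chromosomes, chrom_length, gene_count, gc_fraction)


# ---------------------------------------------------------------------------
# oracle effects (full-CDS retranslation; independent of feature_effects'
# single-codon path)


def retranslation_effect_sbs(
    genome: dict[str, str], transcript: TranscriptModel, pos: int, ref: str, alt: str
) -> str:
    """Effect category from translating the whole spliced CDS before and
    after the substitution."""
    chrom_seq = genome[transcript.chrom]
    assert chrom_seq[pos - 1] == ref
    mutated = {transcript.chrom: chrom_seq[: pos - 1] + alt + chrom_seq[pos:]}
    prot_ref = str(Seq(transcript.coding_sequence(genome)).translate())
    prot_alt = str(Seq(transcript.coding_sequence(mutated)).translate())
    if prot_ref == prot_alt:
        return "synonymous"
    diffs = [i for i, (a, b) in enumerate(zip(prot_ref, prot_alt)) if a != b]
    i = diffs[0]
    if prot_alt[i] == "*":
        return "nonsense"
    return "nonsynonymous"  # includes stop-loss


def _oracle_effect(
    genome: dict[str, str],
    annotation: GenomeAnnotation,
    chrom: str,
    pos: int,
    ref: str,
    alt: str,
    mclass: str,
    indel_len: int,
) -> str:
    for t in annotation.transcripts_on(chrom):
        if not t.cds:
            continue
        if mclass == "SBS":
            if t.contains(pos, t.cds):
                return retranslation_effect_sbs(genome, t, pos, ref, alt)
        elif mclass == "INS":
            if t.contains(pos, t.cds):
                return "frameshift" if indel_len % 3 else "inframe_indel"
        else:  # DEL
            overlap = t.cds_overlap_length(pos + 1, pos + indel_len)
            if overlap > 0:
                return "frameshift" if overlap % 3 else "inframe_indel"
    return ""


# ---------------------------------------------------------------------------
# mutation planting


class _PositionSampler:
    """Samples distinct 1-based positions with per-bp weight ``fold`` inside
    hotspot regions and 1 elsewhere."""

    def __init__(self, contig_lengths: dict[str, int], hotspots: HotspotSpec):
        hotspots.validate(contig_lengths)
        self.segments: list[tuple[str, int, int, float]] = []  # chrom, start0, end0, fold
        for chrom, length in contig_lengths.items():
            regions = sorted(
                (r for r in hotspots.regions if r.chrom == chrom), key=lambda r: r.start
            )
            cursor = 0
            for r in regions:
                if r.start > cursor:
                    self.segments.append((chrom, cursor, r.start, 1.0))
                self.segments.append((chrom, r.start, r.end, r.fold))
                cursor = r.end
            if cursor < length:
                self.segments.append((chrom, cursor, length, 1.0))
        self.weights = np.array([(e - s) * f for _, s, e, f in self.segments])
        self.weights /= self.weights.sum()
        self.total_positions = sum(contig_lengths.values())

    def sample(self, rng: np.random.Generator, used: set[tuple[str, int]]) -> tuple[str, int]:
        for _ in range(10_000):
            si = rng.choice(len(self.segments), p=self.weights)
            chrom, s, e, _ = self.segments[si]
            pos = int(rng.integers(s, e)) + 1  # 1-based
            if (chrom, pos) not in used:
                used.add((chrom, pos))
                return chrom, pos
        raise RuntimeError("position sampling saturated; too many mutations for the genome")


def _plant(
    rng: np.random.Generator,
    genome: dict[str, str],
    annotation: GenomeAnnotation,
    params: SpectrumParams,
    hotspots: HotspotSpec,
    n_mutations: int,
    line_id: str,
    used: set[tuple[str, int]],
) -> tuple[list[TruthRecord], list[tuple]]:
    if n_mutations < 1:
        raise ValueError("n_mutations must be >= 1")
    sampler = _PositionSampler(annotation.contig_lengths, hotspots)
    if len(used) + n_mutations > sampler.total_positions:
        raise ValueError(
            f"n_mutations={n_mutations} exceeds available positions "
            f"({sampler.total_positions - len(used)} left)"
        )
    sub_by_ref = {
        ref: (
            [f"{ref}>{alt}" for alt in _BASES if alt != ref],
            np.array([params.sub_weights[f"{ref}>{alt}"] for alt in _BASES if alt != ref]),
        )
        for ref in _BASES
    }
    len_choices = np.arange(1, INDEL_LEN_MAX + 1)
    truth: list[TruthRecord] = []
    rows: list[tuple] = []
    for _ in range(n_mutations):
        while True:
            chrom, pos = sampler.sample(rng, used)
            seq = genome[chrom]
            if rng.random() < params.indel_fraction:
                length = int(rng.choice(len_choices, p=params.indel_len_dist))
                if rng.random() < params.ins_del_balance:
                    ref = seq[pos - 1]
                    alt = ref + "".join(rng.choice(_BASES, size=length))
                    mclass, sub_type = "INS", ""
                else:
                    if pos + length > len(seq):
                        used.discard((chrom, pos))
                        continue  # deletion would run off the chromosome
                    ref = seq[pos - 1 : pos + length]
                    alt = ref[0]
                    mclass, sub_type = "DEL", ""
                indel_len = length
            else:
                ref = seq[pos - 1]
                labels, weights = sub_by_ref[ref]
                sub_type = str(rng.choice(labels, p=weights / weights.sum()))
                alt = sub_type[-1]
                mclass, indel_len = "SBS", 0
            break
        oracle = _oracle_effect(genome, annotation, chrom, pos, ref, alt, mclass, indel_len)
        truth.append(
            TruthRecord(
                line_id=line_id,
                chrom=chrom,
                pos=pos,
                ref=ref,
                alt=alt,
                mclass=mclass,
                sub_type=sub_type,
                indel_len=indel_len,
                in_hotspot=hotspots.contains(chrom, pos),
                oracle_effect=oracle,
            )
        )
        gt = "1/1" if rng.random() < 0.8 else "0/1"
        rows.append((chrom, pos, ref, alt, DEFAULT_QD, DEFAULT_FS, DEFAULT_MQ, gt, DEFAULT_GQ))
    return truth, rows


def plant_mutations(
    genome: dict[str, str],
    annotation: GenomeAnnotation,
    params: SpectrumParams,
    hotspots: HotspotSpec,
    n_mutations: int,
    seed: int,
    line_id: str = "mut1",
) -> tuple[list[TruthRecord], list[tuple]]:
    """Plant ``n_mutations`` at distinct positions for one line.

    Returns the truth records and the matching VCF row tuples (all passing
    the default hard filters).
    """
    rng = np.random.default_rng(seed)
    return _plant(rng, genome, annotation, params, hotspots, n_mutations, line_id, set())


# ---------------------------------------------------------------------------
# full fixtures


@dataclass
class SimulatedFixture:
    genome: dict[str, str]
    annotation: GenomeAnnotation
    ponds: dict[str, tuple[str, ...]]  # wild-type id -> member line ids
    truth: list[TruthRecord]
    vcf_rows: dict[str, list[tuple]]  # per sample (wild-types included)
    seed: int
    n_filter_fail: int = 0

    @property
    def line_ids(self) -> list[str]:
        return [l for members in self.ponds.values() for l in members]


def simulate_fixture(
    seed: int,
    n_chromosomes: int = 2,
    chrom_length: int = 100_000,
    gene_count: int = 10,
    ponds: dict[str, tuple[str, ...]] | None = None,
    n_mutations_per_line: int = 1000,
    n_background: int = 500,
    n_filter_fail: int = 0,
    params: SpectrumParams | None = None,
    hotspots: HotspotSpec = HotspotSpec(),
    gc_fraction: float = 0.5,
) -> SimulatedFixture:
    """End-to-end fixture: genome + annotation, shared wild-type background
    variants, planted per-line mutations, and optional filter-failing decoys.

    Wild-type VCFs carry only the shared background variants; each mutant
    VCF carries its pond's background plus its own planted set, so induced
    derivation by subtraction is exercised.
    """
    if ponds is None:
        ponds = {"WT1": ("mut1", "mut2")}
    params = params or SpectrumParams.default()
    rng = np.random.default_rng(seed)
    genome, annotation = _generate_genome(rng, n_chromosomes, chrom_length, gene_count, gc_fraction)
    hotspots.validate(annotation.contig_lengths)

    used: set[tuple[str, int]] = set()
    no_hotspots = HotspotSpec()
    background_params = SpectrumParams.default(indel_fraction=0.1)
    truth: list[TruthRecord] = []
    vcf_rows: dict[str, list[tuple]] = {}
    for wt_id, members in ponds.items():
        bg_rows: list[tuple] = []
        if n_background:
            _, bg_rows = _plant(
                rng, genome, annotation, background_params, no_hotspots,
                n_background, wt_id, used,
            )
        vcf_rows[wt_id] = sorted(bg_rows)
        for line_id in members:
            line_truth, line_rows = _plant(
                rng, genome, annotation, params, hotspots,
                n_mutations_per_line, line_id, used,
            )
            truth.extend(line_truth)
            decoys: list[tuple] = []
            if n_filter_fail:
                _, decoy_rows = _plant(
                    rng, genome, annotation, background_params, no_hotspots,
                    n_filter_fail, line_id, used,
                )
                # failing annotations: rotate through the four filters
                for i, (chrom, pos, ref, alt, _, _, _, gt, _) in enumerate(decoy_rows):
                    bad = [(1.0, DEFAULT_FS, DEFAULT_MQ, DEFAULT_GQ),
                           (DEFAULT_QD, 80.0, DEFAULT_MQ, DEFAULT_GQ),
                           (DEFAULT_QD, DEFAULT_FS, 30.0, DEFAULT_GQ),
                           (DEFAULT_QD, DEFAULT_FS, DEFAULT_MQ, 5)][i % 4]
                    decoys.append((chrom, pos, ref, alt, bad[0], bad[1], bad[2], gt, bad[3]))
            vcf_rows[line_id] = sorted(bg_rows + line_rows + decoys)
    return SimulatedFixture(
        genome=genome,
        annotation=annotation,
        ponds={k: tuple(v) for k, v in ponds.items()},
        truth=truth,
        vcf_rows=vcf_rows,
        seed=seed,
        n_filter_fail=n_filter_fail,
    )


# ---------------------------------------------------------------------------
# writing


TRUTH_COLUMNS = [
    "line_id", "chrom", "pos", "ref", "alt", "class", "sub_type",
    "indel_len", "in_hotspot", "oracle_effect",
]


def write_truth_tsv(path: str | os.PathLike, truth: list[TruthRecord]) -> None:
    with open(path, "w") as fh:
        fh.write("\t".join(TRUTH_COLUMNS) + "\n")
        for t in truth:
            fh.write(
                f"{t.line_id}\t{t.chrom}\t{t.pos}\t{t.ref}\t{t.alt}\t{t.mclass}\t"
                f"{t.sub_type}\t{t.indel_len}\t{int(t.in_hotspot)}\t{t.oracle_effect}\n"
            )


def read_truth_tsv(path: str | os.PathLike) -> list[TruthRecord]:
    out: list[TruthRecord] = []
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header != TRUTH_COLUMNS:
            raise ValueError(f"{path}: unexpected truth header {header}")
        for ln in fh:
            (line_id, chrom, pos, ref, alt, mclass, sub_type,
             indel_len, in_hotspot, oracle_effect) = ln.rstrip("\n").split("\t")
            out.append(
                TruthRecord(
                    line_id, chrom, int(pos), ref, alt, mclass, sub_type,
                    int(indel_len), bool(int(in_hotspot)), oracle_effect,
                )
            )
    return out


def write_fasta(path: str | os.PathLike, genome: dict[str, str], width: int = 60) -> None:
    with open(path, "w") as fh:
        for chrom, seq in genome.items():
            fh.write(f">{chrom}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def read_fasta(path: str | os.PathLike) -> dict[str, str]:
    from Bio import SeqIO

    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(os.fspath(path), "fasta")}


def write_fixture(outdir: str | os.PathLike, fixture: SimulatedFixture) -> dict[str, str]:
    """Write FASTA, GFF3, per-sample VCFs, truth TSV, and metadata.

    Returns a name -> path map.  Files round-trip losslessly through
    ``variant_io`` / ``feature_effects`` readers.
    """
    outdir = os.fspath(outdir)
    os.makedirs(outdir, exist_ok=True)
    paths: dict[str, str] = {}
    paths["fasta"] = os.path.join(outdir, "genome.fasta")
    write_fasta(paths["fasta"], fixture.genome)
    paths["gff3"] = os.path.join(outdir, "annotation.gff3")
    feature_effects.write_gff3(paths["gff3"], fixture.annotation)
    for sample, rows in fixture.vcf_rows.items():
        p = os.path.join(outdir, f"{sample}.vcf")
        variant_io.write_vcf(p, fixture.annotation.contig_lengths, rows, sample)
        paths[f"vcf:{sample}"] = p
    paths["truth"] = os.path.join(outdir, "truth.tsv")
    write_truth_tsv(paths["truth"], fixture.truth)
    meta = {
        "seed": fixture.seed,
        "ponds": {k: list(v) for k, v in fixture.ponds.items()},
        "n_truth": len(fixture.truth),
        "n_filter_fail": fixture.n_filter_fail,
        "contigs": fixture.annotation.contig_lengths,
    }
    paths["metadata"] = os.path.join(outdir, "metadata.json")
    with open(paths["metadata"], "w") as fh:
        json.dump(meta, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return paths
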