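"""Genomic-context classification and coding-effect annotation.

Each mutation gets exactly one location category (precedence
exonic > UTR5 > UTR3 > intron > upstream > downstream > intergenic) and, when
it touches a CDS, a coding effect from a strand-aware codon translation of
the spliced coding sequence.
"""

from __future__ import annotations

import logging
import os
from dataclasses import dataclass, field

import gffutils
from Bio.Seq import Seq

from .variant_io import DEL, INS, SBS, ExclusionLog, Mutation

logger = logging.getLogger(__name__)

LOCATION_CATEGORIES = ("exonic", "UTR5", "UTR3", "intron", "upstream", "downstream", "intergenic")

EFFECT_CATEGORIES = ("synonymous", "nonsynonymous", "nonsense", "frameshift", "inframe_indel")

#: highest impact first; used to pick one call among overlapping transcripts
_IMPACT_ORDER = {"frameshift": 0, "nonsense": 1, "nonsynonymous": 2, "inframe_indel": 3, "synonymous": 4}

_COMPLEMENT = str.maketrans("ACGT", "TGCA")


def _revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class TranscriptModel:
    """Strand-aware transcript: 1-based inclusive genomic intervals."""

    transcript_id: str
    chrom: str
    strand: str
    exons: tuple[tuple[int, int], ...]
    cds: tuple[tuple[int, int], ...]
    utr5: tuple[tuple[int, int], ...] = ()
    utr3: tuple[tuple[int, int], ...] = ()

    def __post_init__(self) -> None:
        if self.strand not in "+-":
            raise ValueError(f"{self.transcript_id}: strand must be + or -")
        for name in ("exons", "cds", "utr5", "utr3"):
            ivs = getattr(self, name)
            object.__setattr__(self, name, tuple(sorted(tuple(iv) for iv in ivs)))
            ivs = getattr(self, name)
            for (s1, e1), (s2, e2) in zip(ivs, ivs[1:]):
                if s2 <= e1:
                    raise ValueError(f"{self.transcript_id}: overlapping {name} intervals")
        if not self.exons:
            raise ValueError(f"{self.transcript_id}: no exons")
        if self.cds and self.cds_length % 3 != 0:
            logger.warning("%s: CDS length %d not a multiple of 3", self.transcript_id, self.cds_length)

    @property
    def start(self) -> int:
        return self.exons[0][0]

    @property
    def end(self) -> int:
        return self.exons[-1][1]

    @property
    def cds_length(self) -> int:
        return sum(e - s + 1 for s, e in self.cds)

    def contains(self, pos: int, intervals: tuple[tuple[int, int], ...]) -> bool:
        return any(s <= pos <= e for s, e in intervals)

    def cds_offset(self, pos: int) -> int:
        """0-based offset of a genomic position within the spliced CDS on the
        coding strand."""
        if not self.contains(pos, self.cds):
            raise ValueError(f"{self.transcript_id}: position {pos} not in CDS")
        offset = 0
        if self.strand == "+":
            for s, e in self.cds:
                if pos > e:
                    offset += e - s + 1
                else:
                    return offset + (pos - s)
        else:
            for s, e in reversed(self.cds):
                if pos < s:
                    offset += e - s + 1
                else:
                    return offset + (e - pos)
        raise AssertionError("unreachable")

    def coding_sequence(self, genome: dict[str, str]) -> str:
        """Spliced CDS on the coding strand."""
        seq = genome[self.chrom]
        spliced = "".join(seq[s - 1 : e] for s, e in self.cds)
        return spliced if self.strand == "+" else _revcomp(spliced)

    def cds_overlap_length(self, start: int, end: int) -> int:
        """Coding bases within the 1-based inclusive genomic span [start, end]."""
        return sum(max(0, min(e, end) - max(s, start) + 1) for s, e in self.cds)


@dataclass
class GenomeAnnotation:
    """Contig lengths plus transcript models, indexed by chromosome."""

    contig_lengths: dict[str, int]
    transcripts: list[TranscriptModel]
    _by_chrom: dict[str, list[TranscriptModel]] = field(default=None, repr=False)

    def __post_init__(self) -> None:
        by_chrom: dict[str, list[TranscriptModel]] = {c: [] for c in self.contig_lengths}
        for t in self.transcripts:
            by_chrom.setdefault(t.chrom, []).append(t)
        for lst in by_chrom.values():
            lst.sort(key=lambda t: (t.start, t.transcript_id))
        self._by_chrom = by_chrom

    def transcripts_on(self, chrom: str) -> list[TranscriptModel]:
        if chrom not in self.contig_lengths:
            raise KeyError(f"unknown chromosome {chrom!r}")
        return self._by_chrom.get(chrom, [])

    @property
    def genome_length(self) -> int:
        return sum(self.contig_lengths.values())


@dataclass(frozen=True)
class EffectCall:
    """Coding-effect call for one mutation against one transcript."""

    line_id: str
    chrom: str
    pos: int
    ref: str
    alt: str
    category: str
    transcript_id: str
    codon_change: str = ""
    aa_change: str = ""


def _transcript_category(t: TranscriptModel, pos: int, upstream_bp: int, downstream_bp: int) -> str | None:
    if t.contains(pos, t.cds):
        return "exonic"
    if t.contains(pos, t.utr5):
        return "UTR5"
    if t.contains(pos, t.utr3):
        return "UTR3"
    if t.start <= pos <= t.end:
        return "intron"
    if t.strand == "+":
        if t.start - upstream_bp <= pos < t.start:
            return "upstream"
        if t.end < pos <= t.end + downstream_bp:
            return "downstream"
    else:
        if t.end < pos <= t.end + upstream_bp:
            return "upstream"
        if t.start - downstream_bp <= pos < t.start:
            return "downstream"
    return None


def locate(
    mutation: Mutation,
    annotation: GenomeAnnotation,
    upstream_bp: int = 1000,
    downstream_bp: int = 1000,
) -> str:
    """Single location category for a mutation, by fixed precedence over all
    overlapping transcripts."""
    chrom_len = annotation.contig_lengths.get(mutation.chrom)
    if chrom_len is None:
        raise KeyError(f"unknown chromosome {mutation.chrom!r}")
    best = len(LOCATION_CATEGORIES) - 1  # intergenic
    for t in annotation.transcripts_on(mutation.chrom):
        cat = _transcript_category(t, mutation.pos, upstream_bp, downstream_bp)
        if cat is not None:
            best = min(best, LOCATION_CATEGORIES.index(cat))
    return LOCATION_CATEGORIES[best]


def location_table(mutations, annotation, upstream_bp: int = 1000, downstream_bp: int = 1000):
    """Per-line counts over the seven location categories."""
    table: dict[str, dict[str, int]] = {}
    for m in mutations:
        row = table.setdefault(m.line_id, dict.fromkeys(LOCATION_CATEGORIES, 0))
        row[locate(m, annotation, upstream_bp, downstream_bp)] += 1
    return table


def coding_effect_sbs(
    mutation: Mutation,
    transcript: TranscriptModel,
    genome: dict[str, str],
    log: ExclusionLog | None = None,
) -> EffectCall:
    """Effect of a single-base substitution inside a CDS interval.

    The affected codon is rebuilt on the coding strand (reverse-complementing
    for minus-strand transcripts) and translated with the standard nuclear
    codon table.
    """
    genome_base = genome[mutation.chrom][mutation.pos - 1]
    if genome_base != mutation.ref:
        raise ValueError(
            f"ref mismatch at {mutation.chrom}:{mutation.pos}: genome has "
            f"{genome_base!r}, mutation says {mutation.ref!r}"
        )
    offset = transcript.cds_offset(mutation.pos)
    coding = transcript.coding_sequence(genome)
    codon_idx, within = divmod(offset, 3)
    ref_codon = coding[codon_idx * 3 : codon_idx * 3 + 3]
    if transcript.strand == "+":
        ref_c, alt_c = mutation.ref, mutation.alt
    else:
        ref_c = mutation.ref.translate(_COMPLEMENT)
        alt_c = mutation.alt.translate(_COMPLEMENT)
    if ref_codon[within] != ref_c:
        raise ValueError(f"{transcript.transcript_id}: codon/ref inconsistency at offset {offset}")
    alt_codon = ref_codon[:within] + alt_c + ref_codon[within + 1 :]
    aa_ref = str(Seq(ref_codon).translate())
    aa_alt = str(Seq(alt_codon).translate())
    if aa_ref == aa_alt:
        category = "synonymous"
    elif aa_alt == "*":
        category = "nonsense"
    elif aa_ref == "*":
        # stop-loss folded into nonsynonymous (no separate class in the
        # four-way scheme); counted distinctly in the log
        category = "nonsynonymous"
        if log is not None:
            log.stop_loss_as_nonsyn += 1
    else:
        category = "nonsynonymous"
    return EffectCall(
        line_id=mutation.line_id,
        chrom=mutation.chrom,
        pos=mutation.pos,
        ref=mutation.ref,
        alt=mutation.alt,
        category=category,
        transcript_id=transcript.transcript_id,
        codon_change=f"{ref_codon}>{alt_codon}",
        aa_change=f"{aa_ref}>{aa_alt}",
    )


def coding_effect_indel(mutation: Mutation, transcript: TranscriptModel) -> EffectCall:
    """Frameshift iff the number of coding bases inserted/removed is not a
    multiple of 3.

    For deletions spanning a CDS boundary only the coding overlap counts:
    frame is affected only by coding-length change.
    """
    if mutation.mclass == INS:
        if not transcript.contains(mutation.pos, transcript.cds):
            raise ValueError(f"{transcript.transcript_id}: insertion anchor not in CDS")
        coding_change = mutation.indel_len
    elif mutation.mclass == DEL:
        coding_change = transcript.cds_overlap_length(mutation.pos + 1, mutation.pos + mutation.indel_len)
        if coding_change == 0:
            raise ValueError(f"{transcript.transcript_id}: deletion does not touch CDS")
    else:
        raise ValueError(f"not an InDel: {mutation.mclass}")
    category = "frameshift" if coding_change % 3 != 0 else "inframe_indel"
    return EffectCall(
        line_id=mutation.line_id,
        chrom=mutation.chrom,
        pos=mutation.pos,
        ref=mutation.ref,
        alt=mutation.alt,
        category=category,
        transcript_id=transcript.transcript_id,
    )


def _coding_transcripts(mutation: Mutation, annotation: GenomeAnnotation) -> list[TranscriptModel]:
    out = []
    for t in annotation.transcripts_on(mutation.chrom):
        if not t.cds:
            continue
        if mutation.mclass == SBS or mutation.mclass == INS:
            if t.contains(mutation.pos, t.cds):
                out.append(t)
        else:  # DEL: deleted span is pos+1 .. pos+len
            if t.cds_overlap_length(mutation.pos + 1, mutation.pos + mutation.indel_len) > 0:
                out.append(t)
    return out


def classify_effect(
    mutation: Mutation,
    annotation: GenomeAnnotation,
    genome: dict[str, str],
    log: ExclusionLog | None = None,
) -> EffectCall | None:
    """One coding-effect call per mutation, or None when no CDS is touched.

    Among overlapping transcripts the highest-impact call wins; ties resolve
    by lexicographic transcript id (deterministic).
    """
    calls = []
    for t in _coding_transcripts(mutation, annotation):
        if mutation.mclass == SBS:
            calls.append(coding_effect_sbs(mutation, t, genome, log=log))
        else:
            calls.append(coding_effect_indel(mutation, t))
    if not calls:
        return None
    calls.sort(key=lambda c: (_IMPACT_ORDER[c.category], c.transcript_id))
    return calls[0]


EFFECT_TABLE_COLUMNS = ("synonymous", "nonsynonymous", "nonsense", "frameshift")


def effect_table(mutations, annotation: GenomeAnnotation, genome: dict[str, str]):
    """Per-line counts of the four coding-effect categories.

    In-frame InDels are coding but fall outside the four-way scheme; they are
    reported in a separate column and not in the high-impact total.
    Returns (per_line table, per-mutation EffectCall list).
    """
    table: dict[str, dict[str, int]] = {}
    calls: list[EffectCall] = []
    for m in mutations:
        row = table.setdefault(m.line_id, dict.fromkeys(EFFECT_TABLE_COLUMNS + ("inframe_indel",), 0))
        call = classify_effect(m, annotation, genome)
        if call is None:
            continue
        calls.append(call)
        row[call.category] += 1
    return table, calls


def aggregate_effect_counts(per_line: dict[str, dict[str, int]]):
    """Totals row, per-line average row, and the high-impact summary
    (nonsense + frameshift total and its per-line average)."""
    if not per_line:
        raise ValueError("empty effect table")
    n_lines = len(per_line)
    cols = EFFECT_TABLE_COLUMNS
    totals = {c: sum(row.get(c, 0) for row in per_line.values()) for c in cols}
    average = {c: totals[c] / n_lines for c in cols}
    high_impact_total = totals["nonsense"] + totals["frameshift"]
    high_impact_avg = high_impact_total / n_lines
    return totals, average, high_impact_total, high_impact_avg


# ---------------------------------------------------------------------------
# GFF3 / FASTA interfaces


def read_gff3(path: str | os.PathLike, contig_lengths: dict[str, int] | None = None) -> GenomeAnnotation:
    """Load transcript models from GFF3 (gene/mRNA/exon/CDS/UTR features).

    Contig lengths come from ``##sequence-region`` directives unless given
    explicitly.
    """
    db = gffutils.create_db(
        os.fspath(path), dbfn=":memory:", force=True, keep_order=True,
        merge_strategy="create_unique",
    )
    if contig_lengths is None:
        contig_lengths = {}
        for d in db.directives:
            if d.startswith("sequence-region"):
                _, chrom, _start, end = d.split()
                contig_lengths[chrom] = int(end)
        if not contig_lengths:
            raise ValueError(f"{path}: no ##sequence-region directives and no contig lengths given")
    transcripts = []
    for mrna in db.features_of_type("mRNA"):
        kids = {"exon": [], "CDS": [], "five_prime_UTR": [], "three_prime_UTR": []}
        for child in db.children(mrna):
            if child.featuretype in kids:
                kids[child.featuretype].append((child.start, child.end))
        transcripts.append(
            TranscriptModel(
                transcript_id=mrna.id,
                chrom=mrna.seqid,
                strand=mrna.strand,
                exons=tuple(kids["exon"]),
                cds=tuple(kids["CDS"]),
                utr5=tuple(kids["five_prime_UTR"]),
                utr3=tuple(kids["three_prime_UTR"]),
            )
        )
    transcripts.sort(key=lambda t: (t.chrom, t.start, t.transcript_id))
    return GenomeAnnotation(contig_lengths=contig_lengths, transcripts=transcripts)


def write_gff3(path: str | os.PathLike, annotation: GenomeAnnotation) -> None:
    """Write annotation as GFF3 (1-based inclusive, 9 tab-separated columns)."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for chrom, length in annotation.contig_lengths.items():
            fh.write(f"##sequence-region {chrom} 1 {length}\n")
        for t in sorted(annotation.transcripts, key=lambda t: (t.chrom, t.start, t.transcript_id)):
            gene_id = f"{t.transcript_id}.gene"
            base = f"{t.chrom}\tmutprof\t"
            tail = f"\t.\t{t.strand}\t"
            fh.write(f"{base}gene\t{t.start}\t{t.end}{tail}.\tID={gene_id}\n")
            fh.write(f"{base}mRNA\t{t.start}\t{t.end}{tail}.\tID={t.transcript_id};Parent={gene_id}\n")
            for i, (s, e) in enumerate(t.exons, 1):
                fh.write(f"{base}exon\t{s}\t{e}{tail}.\tID={t.transcript_id}.exon{i};Parent={t.transcript_id}\n")
            # CDS phase: bases to trim to reach the next codon start
            acc = 0
            phases = []
            cds_tx_order = t.cds if t.strand == "+" else tuple(reversed(t.cds))
            for s, e in cds_tx_order:
                phases.append((3 - acc % 3) % 3)
                acc += e - s + 1
            if t.strand == "-":
                phases = list(reversed(phases))
            for i, ((s, e), ph) in enumerate(zip(t.cds, phases), 1):
                fh.write(f"{base}CDS\t{s}\t{e}\t.\t{t.strand}\t{ph}\tID={t.transcript_id}.cds{i};Parent={t.transcript_id}\n")
            for i, (s, e) in enumerate(t.utr5, 1):
                fh.write(f"{base}five_prime_UTR\t{s}\t{e}{tail}.\tID={t.transcript_id}.utr5.{i};Parent={t.transcript_id}\n")
            for i, (s, e) in enumerate(t.utr3, 1):
                fh.write(f"{base}three_prime_UTR\t{s}\t{e}{tail}.\tID={t.transcript_id}.utr3.{i};Parent={t.transcript_id}\n")


def write_effect_tsv(path: str | os.PathLike, per_line: dict[str, dict[str, int]]) -> None:
    """Effect table with Totals and Average rows."""
    with open(path, "w") as fh:
        fh.write("line\t" + "\t".join(EFFECT_TABLE_COLUMNS) + "\thigh_impact\n")
        for line_id in sorted(per_line):
            row = per_line[line_id]
            hi = row.get("nonsense", 0) + row.get("frameshift", 0)
            fh.write(line_id + "\t" + "\t".join(str(row.get(c, 0)) for c in EFFECT_TABLE_COLUMNS) + f"\t{hi}\n")
        if per_line:
            totals, average, hi_total, hi_avg = aggregate_effect_counts(per_line)
            fh.write("Total\t" + "\t".join(str(totals[c]) for c in EFFECT_TABLE_COLUMNS) + f"\t{hi_total}\n")
            fh.write("Average\t" + "\t".join(f"{average[c]:.1f}" for c in EFFECT_TABLE_COLUMNS) + f"\t{hi_avg:.1f}\n")


def write_effect_calls_tsv(path: str | os.PathLike, calls: list[EffectCall]) -> None:
    with open(path, "w") as fh:
        fh.write("line_id\tchrom\tpos\tref\talt\tcategory\ttranscript_id\tcodon_change\taa_change\n")
        for c in sorted(calls, key=lambda c: (c.line_id, c.chrom, c.pos, c.alt)):
            fh.write(f"{c.line_id}\t{c.chrom}\t{c.pos}\t{c.ref}\t{c.alt}\t{c.category}\t{c.transcript_id}\t{c.codon_change}\t{c.aa_change}\n")
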