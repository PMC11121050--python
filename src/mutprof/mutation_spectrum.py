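"""Substitution and InDel spectrum summaries per line and per pond.

Substitutions are kept directional (12 types, no pyrimidine-strand
collapsing); a collapsed 6-type view is available as an option.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

SUB_TYPES = (
    "A>C", "A>G", "A>T",
    "C>A", "C>G", "C>T",
    "G>A", "G>C", "G>T",
    "T>A", "T>C", "T>G",
)

TRANSITIONS = frozenset({"A>G", "G>A", "C>T", "T>C"})

#: collapsed 6-type scheme keyed by the pyrimidine-strand representative
COLLAPSED_6 = {
    "A>C": "T>G", "A>G": "T>C", "A>T": "T>A",
    "G>A": "C>T", "G>C": "C>G", "G>T": "C>A",
    "C>A": "C>A", "C>G": "C>G", "C>T": "C>T",
    "T>A": "T>A", "T>C": "T>C", "T>G": "T>G",
}

INDEL_LEN_MAX = 50

_BASES = frozenset("ACGT")


def _check_bases(ref: str, alt: str) -> None:
    if ref not in _BASES or alt not in _BASES:
        raise ValueError(f"non-ACGT base in substitution {ref!r}>{alt!r}")
    if ref == alt:
        raise ValueError(f"ref equals alt ({ref!r})")


def is_transition(ref: str, alt: str) -> bool:
    """True iff the substitution is purine<->purine or pyrimidine<->pyrimidine."""
    _check_bases(ref, alt)
    return {ref, alt} in ({"A", "G"}, {"C", "T"})


def substitution_type(ref: str, alt: str) -> str:
    """Ordered directional label ``"ref>alt"`` (one of the 12 types)."""
    _check_bases(ref, alt)
    return f"{ref}>{alt}"


def collapse_substitution(sub_type: str) -> str:
    """Collapse a directional type to its pyrimidine-strand 6-type label."""
    return COLLAPSED_6[sub_type]


@dataclass(frozen=True)
class MutationPond:
    """A wild-type background's group of derived mutant lines."""

    pond_id: str
    wildtype_id: str
    member_line_ids: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(self.member_line_ids) < 1:
            raise ValueError(f"pond {self.pond_id} has no members")


@dataclass
class SpectrumSummary:
    """Counts describing a line's (or pond's) mutation spectrum.

    Marginal-only summaries (built from published per-line totals, where the
    12-type and length breakdowns were not printed) leave the detail fields
    ``None``; aggregation propagates ``None``.
    """

    scope: str
    n_total: int = 0
    n_sbs: int = 0
    n_ins: int | None = 0
    n_del: int | None = 0
    n_indel: int = 0
    ti: int | None = 0
    tv: int | None = 0
    sub_counts: dict[str, int] | None = field(default_factory=lambda: dict.fromkeys(SUB_TYPES, 0))
    indel_hist_ins: dict[int, int] | None = field(
        default_factory=lambda: dict.fromkeys(range(1, INDEL_LEN_MAX + 1), 0)
    )
    indel_hist_del: dict[int, int] | None = field(
        default_factory=lambda: dict.fromkeys(range(1, INDEL_LEN_MAX + 1), 0)
    )

    @classmethod
    def from_marginals(cls, scope: str, n_total: int, n_sbs: int, n_indel: int) -> "SpectrumSummary":
        if n_sbs + n_indel != n_total:
            raise ValueError(f"{scope}: {n_sbs} SBSs + {n_indel} InDels != total {n_total}")
        return cls(
            scope=scope, n_total=n_total, n_sbs=n_sbs, n_indel=n_indel,
            n_ins=None, n_del=None, ti=None, tv=None,
            sub_counts=None, indel_hist_ins=None, indel_hist_del=None,
        )

    @property
    def ti_tv_ratio(self) -> float | None:
        """ti/tv rounded to 2 decimals; None when undefined."""
        if self.ti is None or self.tv is None or self.tv == 0:
            return None
        return round(self.ti / self.tv, 2)

    def _short_fraction(self, hist: dict[int, int] | None) -> float | None:
        if hist is None:
            return None
        total = sum(hist.values())
        if total == 0:
            return None
        return (hist.get(1, 0) + hist.get(2, 0)) / total

    @property
    def short_indel_fraction_ins(self) -> float | None:
        return self._short_fraction(self.indel_hist_ins)

    @property
    def short_indel_fraction_del(self) -> float | None:
        return self._short_fraction(self.indel_hist_del)

    def validate(self) -> None:
        """Check count-consistency invariants on every populated field."""
        if self.n_total != self.n_sbs + self.n_indel:
            raise AssertionError(f"{self.scope}: total != SBS + InDel")
        if self.n_ins is not None and self.n_del is not None:
            if self.n_ins + self.n_del != self.n_indel:
                raise AssertionError(f"{self.scope}: INS + DEL != InDel total")
        if self.ti is not None and self.tv is not None and self.ti + self.tv != self.n_sbs:
            raise AssertionError(f"{self.scope}: Ti + Tv != SBS total")
        if self.sub_counts is not None and sum(self.sub_counts.values()) != self.n_sbs:
            raise AssertionError(f"{self.scope}: substitution counts do not sum to SBS total")
        if self.indel_hist_ins is not None and self.indel_hist_del is not None:
            if sum(self.indel_hist_ins.values()) + sum(self.indel_hist_del.values()) != self.n_indel:
                raise AssertionError(f"{self.scope}: InDel histogram does not sum to InDel total")


def summarize(mutations, scope: str) -> SpectrumSummary:
    """Tally a full spectrum summary for the mutations of one scope."""
    s = SpectrumSummary(scope=scope)
    for m in mutations:
        s.n_total += 1
        if m.mclass == "SBS":
            s.n_sbs += 1
            t = substitution_type(m.ref, m.alt)
            s.sub_counts[t] += 1
            if t in TRANSITIONS:
                s.ti += 1
            else:
                s.tv += 1
        elif m.mclass == "INS":
            s.n_ins += 1
            s.n_indel += 1
            s.indel_hist_ins[m.indel_len] += 1
        elif m.mclass == "DEL":
            s.n_del += 1
            s.n_indel += 1
            s.indel_hist_del[m.indel_len] += 1
        else:
            raise ValueError(f"unexpected mutation class {m.mclass!r} in spectrum input")
    s.validate()
    return s


def _sum_maybe(values):
    out = 0
    for v in values:
        if v is None:
            return None
        out += v
    return out


def pond_aggregate(line_summaries: dict[str, SpectrumSummary], pond: MutationPond) -> SpectrumSummary:
    """Field-wise sum of member-line summaries; the Ti/Tv ratio is recomputed
    from the summed counts."""
    missing = [m for m in pond.member_line_ids if m not in line_summaries]
    if missing:
        raise KeyError(f"pond {pond.pond_id}: missing member summaries {missing}")
    members = [line_summaries[m] for m in pond.member_line_ids]

    def sum_dicts(key):
        dicts = [getattr(s, key) for s in members]
        if any(d is None for d in dicts):
            return None
        out = dict.fromkeys(dicts[0], 0)
        for d in dicts:
            for k, v in d.items():
                out[k] += v
        return out

    agg = SpectrumSummary(
        scope=pond.pond_id,
        n_total=sum(s.n_total for s in members),
        n_sbs=sum(s.n_sbs for s in members),
        n_indel=sum(s.n_indel for s in members),
        n_ins=_sum_maybe(s.n_ins for s in members),
        n_del=_sum_maybe(s.n_del for s in members),
        ti=_sum_maybe(s.ti for s in members),
        tv=_sum_maybe(s.tv for s in members),
        sub_counts=sum_dicts("sub_counts"),
        indel_hist_ins=sum_dicts("indel_hist_ins"),
        indel_hist_del=sum_dicts("indel_hist_del"),
    )
    agg.validate()
    return agg


def sbs_share(n_sbs: int, n_total: int) -> float:
    """Percentage of SBSs among all mutations, to 1 decimal."""
    if n_total <= 0:
        raise ValueError("n_total must be positive")
    return round(100.0 * n_sbs / n_total, 1)


def sbs_share_headline(n_sbs: int, n_total: int) -> int:
    """Headline figure: nearest-integer percentage."""
    if n_total <= 0:
        raise ValueError("n_total must be positive")
    return round(100.0 * n_sbs / n_total)


def write_summary_tsv(path: str | os.PathLike, summaries: list[SpectrumSummary]) -> None:
    with open(path, "w") as fh:
        fh.write("scope\ttotal\tsbs\tindels\tti\ttv\tti_tv\n")
        for s in summaries:
            ratio = "" if s.ti_tv_ratio is None else f"{s.ti_tv_ratio:.2f}"
            ti = "" if s.ti is None else s.ti
            tv = "" if s.tv is None else s.tv
            fh.write(f"{s.scope}\t{s.n_total}\t{s.n_sbs}\t{s.n_indel}\t{ti}\t{tv}\t{ratio}\n")


def write_spectrum_tsv(path: str | os.PathLike, summary: SpectrumSummary) -> None:
    if summary.sub_counts is None:
        raise ValueError("summary has no substitution detail")
    with open(path, "w") as fh:
        fh.write("sub_type\tcount\n")
        for t in SUB_TYPES:
            fh.write(f"{t}\t{summary.sub_counts[t]}\n")


def write_indel_hist_tsv(path: str | os.PathLike, summary: SpectrumSummary) -> None:
    if summary.indel_hist_ins is None or summary.indel_hist_del is None:
        raise ValueError("summary has no InDel length detail")
    with open(path, "w") as fh:
        fh.write("length\tins_count\tdel_count\n")
        for ln in range(1, INDEL_LEN_MAX + 1):
            fh.write(f"{ln}\t{summary.indel_hist_ins[ln]}\t{summary.indel_hist_del[ln]}\n")
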