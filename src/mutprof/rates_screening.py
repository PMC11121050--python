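"""Mendelian back-projection of Mn mutation counts to M1, per-pond mutation
rates, and the trait screening statistic.

A heterozygous M1 mutation propagated by selfing is homozygous in generation
Mn with probability (1 - 2^-(n-1))/2.  Back-projection divides the Mn count
by this retention probability.  ``mode="table"`` uses the asymptotic factor
1/2 (every estimate is exactly 2 x Nn); ``mode="exact"`` uses the
generation-specific probability; ``mode="inclusive"`` additionally counts
mutations still segregating as heterozygotes.
"""

from __future__ import annotations

import os
from dataclasses import dataclass

import numpy as np

MODES = ("table", "exact", "inclusive")


def retention_probability(n: int, mode: str = "table") -> float:
    """Probability that an M1 heterozygous mutation is detected in Mn."""
    if n < 2:
        raise ValueError(f"generation index must be >= 2, got {n}")
    if mode == "table":
        return 0.5
    if mode == "exact":
        return (1.0 - 2.0 ** -(n - 1)) / 2.0
    if mode == "inclusive":
        return (1.0 - 2.0 ** -(n - 1)) / 2.0 + 2.0 ** -(n - 1)
    raise ValueError(f"unknown mode {mode!r}; expected one of {MODES}")


@dataclass(frozen=True)
class BackProjection:
    n: int
    Nn: int
    mode: str
    p_detect: float
    N1: int


def back_project(Nn: int, n: int = 6, mode: str = "table") -> int:
    """Estimated M1 mutation count from the Mn count."""
    if Nn < 0:
        raise ValueError("mutation count must be >= 0")
    p = retention_probability(n, mode)
    return round(Nn / p)


def back_projection(Nn: int, n: int = 6, mode: str = "table") -> BackProjection:
    p = retention_probability(n, mode)
    return BackProjection(n=n, Nn=Nn, mode=mode, p_detect=p, N1=back_project(Nn, n, mode))


@dataclass(frozen=True)
class PondSummary:
    """Back-projection summary of one wild-type background's mutant group."""

    pond_id: str
    member_line_ids: tuple[str, ...]
    m6_counts: tuple[int, ...]
    n1_counts: tuple[int, ...]
    genome_length: int

    @property
    def n_lines(self) -> int:
        return len(self.member_line_ids)

    @property
    def n1_sum(self) -> int:
        return sum(self.n1_counts)

    @property
    def rate(self) -> float:
        """Per-bp M1 mutation frequency averaged over member lines."""
        return self.n1_sum / (self.n_lines * self.genome_length)


def pond_rate(n1_values, n_lines: int, genome_length: int) -> float:
    """sum(N1) / (n_lines x genome_length)."""
    if n_lines < 1:
        raise ValueError("n_lines must be >= 1")
    if genome_length <= 0:
        raise ValueError("genome_length must be positive")
    return sum(n1_values) / (n_lines * genome_length)


def format_rate(rate: float) -> str:
    """Display convention: 1 decimal in units of 1e-5 per bp."""
    return f"{rate * 1e5:.1f} x 10^-5"


def summarize_pond(
    pond_id: str,
    member_counts: dict[str, int],
    genome_length: int,
    n: int = 6,
    mode: str = "table",
) -> PondSummary:
    lines = tuple(member_counts)
    m6 = tuple(member_counts[l] for l in lines)
    n1 = tuple(back_project(c, n, mode) for c in m6)
    return PondSummary(pond_id, lines, m6, n1, genome_length)


def simulate_selfing(n_mutations: int, n: int = 6, seed: int = 0) -> float:
    """Monte-Carlo selfing of heterozygous M1 mutations; returns the fraction
    homozygous for the mutant allele at generation Mn.

    Independent oracle for ``retention_probability(n, "exact")``.
    """
    if n < 2:
        raise ValueError("generation index must be >= 2")
    rng = np.random.default_rng(seed)
    # states: 0 = het, 1 = hom alt, 2 = hom ref (absorbing)
    state = np.zeros(n_mutations, dtype=np.int8)
    for _ in range(n - 1):
        het = state == 0
        draws = rng.random(int(het.sum()))
        new = np.zeros(len(draws), dtype=np.int8)
        new[draws < 0.25] = 1
        new[draws >= 0.75] = 2
        state[het] = new
    return float(np.mean(state == 1))


@dataclass(frozen=True)
class TraitScreen:
    """Deviation of a mutant's trait value from the wild-type distribution."""

    trait: str
    statistic: float
    passed: bool


def screen_trait(wt_values, mutant_value: float, trait: str = "trait") -> TraitScreen:
    """|mutant - mean(wt)| / sd(wt) with sample sd (n-1); passes at >= 3."""
    wt = np.asarray(list(wt_values), dtype=float)
    if len(wt) < 2:
        raise ValueError("need >= 2 wild-type values")
    sd = float(np.std(wt, ddof=1))
    if sd == 0:
        raise ValueError("wild-type values have zero spread")
    stat = abs(mutant_value - float(np.mean(wt))) / sd
    return TraitScreen(trait=trait, statistic=stat, passed=stat >= 3.0)


def write_rates_tsv(
    path: str | os.PathLike,
    ponds: list[PondSummary],
    line_totals: dict[str, tuple[int, int, int]],
) -> None:
    """Per-line totals with back-projections and per-pond rates.

    ``line_totals`` maps line id -> (total, sbs, indel).  The genome length
    used as denominator is echoed in a trailing comment line.
    """
    with open(path, "w") as fh:
        fh.write("pond\tline\ttotal\tsbs\tindels\testimated_m1\tpond_rate_per_bp\n")
        for p in ponds:
            rate = format_rate(p.rate)
            for i, line_id in enumerate(p.member_line_ids):
                total, sbs, indel = line_totals[line_id]
                rate_cell = rate if i == 0 else ""
                fh.write(f"{p.pond_id}\t{line_id}\t{total}\t{sbs}\t{indel}\t{p.n1_counts[i]}\t{rate_cell}\n")
        if ponds:
            fh.write(f"# genome_length={ponds[0].genome_length}\n")


def write_screen_tsv(path: str | os.PathLike, screens: list[TraitScreen]) -> None:
    with open(path, "w") as fh:
        fh.write("trait\tstatistic\tpass\n")
        for s in screens:
            fh.write(f"{s.trait}\t{s.statistic:.3f}\t{'yes' if s.passed else 'no'}\n")
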