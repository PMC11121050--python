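"""Bundled summary counts from a published eight-line carbon-ion-beam rice
mutagenesis study: per-line M6 mutation totals (three wild-type backgrounds)
and per-line coding-effect counts.  Used as desk-scale worked examples for
the aggregation and back-projection stages.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

#: assembly span (bp) of the rice reference used as the per-pond rate
#: denominator in worked examples
RICE_GENOME_LENGTH = 373_245_519


def _load(name: str) -> pd.DataFrame:
    with resources.files("mutprof.data").joinpath(name).open() as fh:
        return pd.read_csv(fh, sep="\t")


def load_line_counts() -> pd.DataFrame:
    """Per-line M6 counts: wildtype, line, total, sbs, indels."""
    return _load("line_counts.tsv")


def load_effect_counts() -> pd.DataFrame:
    """Per-line coding-effect counts: line, synonymous, nonsynonymous,
    nonsense, frameshift."""
    return _load("effect_counts.tsv")


def line_count_ponds() -> dict[str, tuple[str, ...]]:
    """Wild-type -> member lines mapping of the bundled dataset."""
    df = load_line_counts()
    return {wt: tuple(g["line"]) for wt, g in df.groupby("wildtype", sort=False)}
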