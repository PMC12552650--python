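"""Expression-based hit prioritization.

Screen hits are triaged by whether the miRNA is constitutively expressed
across a panel of cell lines (>= ``min_reads`` reads in at least
``min_fraction`` of the lines) and by membership in a curated
common-essential list, so that follow-up focuses on hits plausibly active in
the models at hand.
"""

from __future__ import annotations

import io
import math
from typing import Iterable, Mapping, Sequence

import pandas as pd


def read_expression_panel(text: str) -> pd.DataFrame:
    """Panel TSV: mirna_id column then one integer column per cell line."""
    df = pd.read_csv(io.StringIO(text), sep="\t", index_col=0)
    if df.shape[1] < 2:
        raise ValueError("expression panel needs >= 2 cell lines")
    if (df.to_numpy() < 0).any():
        raise ValueError("expression counts must be nonnegative")
    return df


def constitutive_expression_filter(
    panel: pd.DataFrame, min_reads: int = 5, min_fraction: float = 0.8
) -> set[str]:
    """miRNAs with >= min_reads in at least min_fraction of the panel.

    "At least 80%" of n lines is read inclusively as ceil(min_fraction * n)
    lines.
    """
    n_lines = panel.shape[1]
    need = math.ceil(min_fraction * n_lines)
    ok = (panel >= min_reads).sum(axis=1) >= need
    return set(panel.index[ok])


def prioritize_hits_by_expression(
    hits: Iterable[str], expressed_set: set[str]
) -> tuple[pd.DataFrame, tuple[int, int]]:
    """Flag each hit as expressed or not; summary = (n_expressed, n_hits)."""
    hits = sorted(set(hits))
    table = pd.DataFrame(
        {"hit": hits, "expressed": [h in expressed_set for h in hits]}
    ).set_index("hit")
    return table, (int(table["expressed"].sum()), len(hits))


def common_essential_overlap(
    hit_sets: Mapping[str, Iterable[str]], curated_common: Iterable[str]
) -> tuple[set[str], pd.DataFrame]:
    """Genes present in every hit set and the curated common-essential list.

    Returns the intersection plus a per-gene membership table over the union
    of all inputs.
    """
    if len(hit_sets) < 2:
        raise ValueError("need at least two hit sets")
    named = {name: set(s) for name, s in hit_sets.items()}
    named["curated_common"] = set(curated_common)
    universe = sorted(set().union(*named.values()))
    table = pd.DataFrame(
        {name: [g in s for g in universe] for name, s in named.items()},
        index=pd.Index(universe, name="gene"),
    )
    common = set(universe)
    for s in named.values():
        common &= s
    return common, table
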