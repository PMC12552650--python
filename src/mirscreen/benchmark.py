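"""Library-quality benchmarking: on-target score profiles and cumulative
off-target exceedance counts, comparable across gRNA libraries."""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .design import LibraryManifest, OffTargetSite


@dataclass(frozen=True)
class ScoreProfile:
    """Distribution summary of a library's on-target scores."""

    library_name: str
    n_guides: int
    quartile1: float
    median: float
    quartile3: float
    fraction_below_default: float
    default_threshold: float

    def __post_init__(self) -> None:
        if not (self.quartile1 <= self.median <= self.quartile3):
            raise ValueError("quartiles out of order")


@dataclass(frozen=True)
class OffTargetExceedance:
    library_name: str
    threshold: float
    cumulative_count: int


def _scores_from(manifest_or_scores) -> np.ndarray:
    if isinstance(manifest_or_scores, LibraryManifest):
        s = manifest_or_scores.entries["on_target"]
        return s.dropna().to_numpy(dtype=float)
    return np.asarray(
        [s for s in manifest_or_scores if s is not None and not np.isnan(s)],
        dtype=float,
    )


def summarize_on_target_profile(
    manifest_or_scores,
    threshold: float = 0.2,
    library_name: str = "library",
) -> ScoreProfile:
    """Quartiles (linear interpolation) + fraction strictly below threshold."""
    scores = _scores_from(manifest_or_scores)
    if scores.size == 0:
        raise ValueError("no scored guides to profile")
    q1, med, q3 = np.percentile(scores, [25, 50, 75], method="linear")
    return ScoreProfile(
        library_name=library_name,
        n_guides=int(scores.size),
        quartile1=float(q1),
        median=float(med),
        quartile3=float(q3),
        fraction_below_default=float(np.mean(scores < threshold)),
        default_threshold=threshold,
    )


def fraction_below(manifest_or_scores, threshold: float) -> float:
    scores = _scores_from(manifest_or_scores)
    if scores.size == 0:
        raise ValueError("no scored guides")
    return float(np.mean(scores < threshold))


def cumulative_offtarget_exceedance(
    site_lists: Iterable[Sequence[OffTargetSite]],
    threshold: float = 0.2,
    protein_coding_only: bool = True,
    library_name: str = "library",
) -> OffTargetExceedance:
    """Count off-target loci with CFD strictly above threshold, summed over
    guides (restricted to protein-coding loci when flagged)."""
    count = 0
    for sites in site_lists:
        for s in sites:
            if s.cfd > threshold and (s.in_protein_coding or not protein_coding_only):
                count += 1
    return OffTargetExceedance(
        library_name=library_name, threshold=threshold, cumulative_count=count
    )


def benchmark_report(profiles: Sequence[ScoreProfile],
                     exceedances: Sequence[OffTargetExceedance]) -> pd.DataFrame:
    """Long-format table suitable for plotting library comparisons."""
    rows = []
    for p in profiles:
        rows += [
            {"library": p.library_name, "metric": m, "value": v}
            for m, v in [
                ("n_guides", p.n_guides), ("q1", p.quartile1),
                ("median", p.median), ("q3", p.quartile3),
                (f"fraction_below_{p.default_threshold}", p.fraction_below_default),
            ]
        ]
    for e in exceedances:
        rows.append(
            {"library": e.library_name,
             "metric": f"offtarget_loci_cfd_gt_{e.threshold}",
             "value": e.cumulative_count}
        )
    return pd.DataFrame(rows, columns=["library", "metric", "value"])
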