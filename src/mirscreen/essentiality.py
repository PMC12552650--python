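"""Pooled dropout-screen essentiality analysis.

The analysis follows the BAGEL family of supervised Bayes-factor methods:
read counts are depth-normalised and converted to log2 fold changes against
the pre-selection (T0) sample; per gene, the evidence that its guides' fold
changes were drawn from the distribution of core-essential reference guides
rather than non-essential reference guides is summarised as a Bayes factor

    BF(gene) = sum over (guide, replicate) of log2 p(fc | essential) / p(fc | non-essential)

with the two class densities estimated by Gaussian kernel density fits to
bootstrap-resampled reference-gene training sets, averaged over iterations
(default 1000) in which the gene was held out of the training draw.  The
per-gene false-discovery rate comes from a precision-recall walk down the
BF ranking over the reference genes; the hit rule is BF > 0 and FDR < 0.1.
"""

from __future__ import annotations

import io
import re
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy.stats import gaussian_kde
from sklearn.metrics import average_precision_score

DENSITY_FLOOR = 2.0 ** -30


@dataclass
class ScreenCounts:
    """gRNA x sample integer counts plus guide and sample metadata.

    ``counts``: DataFrame indexed by guide_id, one column per sample label.
    ``guides``: DataFrame indexed by guide_id with target_id and category.
    ``samples``: DataFrame indexed by sample label with timepoint (numeric),
    replicate (int, 0 for T0) and is_t0 (bool).
    """

    counts: pd.DataFrame
    guides: pd.DataFrame
    samples: pd.DataFrame

    def __post_init__(self) -> None:
        if (self.counts.to_numpy() < 0).any():
            raise ValueError("counts must be nonnegative")
        if not self.counts.index.is_unique:
            raise ValueError("guide ids must be unique")
        if not self.samples["is_t0"].any():
            raise ValueError("a designated T0 sample is required")
        if not self.counts.index.equals(self.guides.index):
            raise ValueError("counts and guide metadata indexes differ")
        if list(self.counts.columns) != list(self.samples.index):
            raise ValueError("counts columns and sample metadata differ")

    def to_tsv(self) -> str:
        df = self.guides[["target_id", "category"]].join(self.counts)
        df.index.name = "guide_id"
        return df.to_csv(sep="\t")

    @classmethod
    def from_tsv(cls, text: str) -> "ScreenCounts":
        df = pd.read_csv(io.StringIO(text), sep="\t", index_col="guide_id")
        guides = df[["target_id", "category"]]
        counts = df.drop(columns=["target_id", "category"])
        return cls(counts=counts, guides=guides, samples=parse_sample_labels(counts.columns))


def parse_sample_labels(labels: Sequence[str]) -> pd.DataFrame:
    """Interpret sample labels of the form ``T0`` or ``T<d>_R<r>``."""
    rows = []
    for lab in labels:
        m = re.fullmatch(r"T(\d+)(?:_R(\d+))?", lab)
        if m is None:
            raise ValueError(f"cannot parse sample label {lab!r}; expected T<d>[_R<r>]")
        t = int(m.group(1))
        rows.append(
            {"sample": lab, "timepoint": t,
             "replicate": int(m.group(2) or 0), "is_t0": t == 0}
        )
    return pd.DataFrame(rows).set_index("sample")


@dataclass
class FoldChangeTable:
    """Per-(guide, sample) log2 fold changes vs T0, with metadata."""

    fc: pd.DataFrame  # guide x non-T0 sample
    guides: pd.DataFrame
    samples: pd.DataFrame  # metadata for the fc columns
    pseudocount: float
    scale: float

    def terminal_samples(self) -> list[str]:
        tmax = self.samples["timepoint"].max()
        return list(self.samples.index[self.samples["timepoint"] == tmax])


@dataclass(frozen=True)
class ReferenceSets:
    """Core-essential and non-essential reference gene ids."""

    essential: frozenset
    nonessential: frozenset

    def __post_init__(self) -> None:
        if not self.essential or not self.nonessential:
            raise ValueError("both reference sets must be nonempty")
        if self.essential & self.nonessential:
            raise ValueError("reference sets must be disjoint")


def normalize_and_fold_change(
    sc: ScreenCounts, pseudocount: float = 5.0, scale: float = 1e7
) -> FoldChangeTable:
    """Scale each sample to ``scale`` total reads; log2 FC vs normalised T0.

    fc(g, s) = log2((norm_s(g) + pseudocount) / (norm_T0(g) + pseudocount)).
    With several designated T0 samples their normalised counts are averaged.
    """
    totals = sc.counts.sum(axis=0)
    zero = totals[totals == 0]
    if len(zero):
        raise ValueError(f"sample(s) with zero total reads: {list(zero.index)}")
    norm = sc.counts / totals * scale
    t0_cols = list(sc.samples.index[sc.samples["is_t0"]])
    t0 = norm[t0_cols].mean(axis=1)
    other = [c for c in norm.columns if c not in t0_cols]
    fc = np.log2(
        (norm[other] + pseudocount).div(t0 + pseudocount, axis=0)
    )
    return FoldChangeTable(
        fc=fc, guides=sc.guides, samples=sc.samples.loc[other],
        pseudocount=pseudocount, scale=scale,
    )


def compute_bayes_factors(
    fct: FoldChangeTable,
    refs: ReferenceSets,
    n_iterations: int = 1000,
    seed: int = 0,
    samples: Optional[Sequence[str]] = None,
    grid_size: int = 512,
    density_floor: float = DENSITY_FLOOR,
) -> pd.DataFrame:
    """Supervised iterative Bayes factors from terminal fold changes.

    Per iteration, the essential and non-essential reference gene lists are
    bootstrap-resampled (with replacement, same size); Gaussian KDEs of the
    drawn genes' guide fold changes (all requested samples pooled) form the
    two class densities, evaluated on a fixed grid and interpolated,
    floored at ``density_floor``.  Every gene absent from the iteration's
    training draw receives BF_iter = sum of per-observation log2 density
    ratios; the final BF is the mean over iterations in which the gene was
    scored.  Returns a gene-indexed frame with BF, category, n_guides and
    n_iterations_scored.
    """
    ess = sorted(refs.essential & set(fct.guides["target_id"]))
    non = sorted(refs.nonessential & set(fct.guides["target_id"]))
    if len(ess) < 2 or len(non) < 2:
        raise ValueError(
            f"need >= 2 scored reference genes per class, got {len(ess)} essential "
            f"and {len(non)} non-essential"
        )
    cols = list(samples) if samples is not None else fct.terminal_samples()
    long = fct.fc[cols].to_numpy(dtype=float).ravel()  # guide-major order
    n_samples = len(cols)
    gene_of_guide = fct.guides["target_id"].to_numpy()
    genes = pd.unique(gene_of_guide)
    gene_idx = {g: i for i, g in enumerate(genes)}
    obs_gene = np.repeat(
        np.array([gene_idx[g] for g in gene_of_guide]), n_samples
    )
    # per-class observation pools, grouped by reference gene for resampling
    def _class_obs(gene_list):
        return [
            fct.fc.loc[fct.guides["target_id"] == g, cols].to_numpy().ravel()
            for g in gene_list
        ]

    ess_obs = _class_obs(ess)
    non_obs = _class_obs(non)
    grid = np.linspace(long.min() - 1.0, long.max() + 1.0, grid_size)
    rng = np.random.default_rng(seed)
    n_genes = len(genes)
    bf_sum = np.zeros(n_genes)
    bf_n = np.zeros(n_genes, dtype=int)
    ess_arr = np.array([gene_idx[g] for g in ess])
    non_arr = np.array([gene_idx[g] for g in non])
    for _ in range(n_iterations):
        ei = rng.integers(0, len(ess), size=len(ess))
        ni = rng.integers(0, len(non), size=len(non))
        train_e = np.concatenate([ess_obs[i] for i in ei])
        train_n = np.concatenate([non_obs[i] for i in ni])
        log_e = np.log2(np.maximum(gaussian_kde(train_e)(grid), density_floor))
        log_n = np.log2(np.maximum(gaussian_kde(train_n)(grid), density_floor))
        logratio = np.interp(long, grid, log_e - log_n)
        bf_iter = np.bincount(obs_gene, weights=logratio, minlength=n_genes)
        scored = np.ones(n_genes, dtype=bool)
        scored[ess_arr[np.unique(ei)]] = False
        scored[non_arr[np.unique(ni)]] = False
        bf_sum[scored] += bf_iter[scored]
        bf_n[scored] += 1
    with np.errstate(invalid="ignore"):
        bf = np.where(bf_n > 0, bf_sum / np.maximum(bf_n, 1), np.nan)
    cat = fct.guides.groupby("target_id")["category"].first()
    n_guides = fct.guides.groupby("target_id").size()
    out = pd.DataFrame(
        {
            "BF": bf,
            "category": cat.reindex(genes).to_numpy(),
            "n_guides": n_guides.reindex(genes).to_numpy(),
            "n_iterations_scored": bf_n,
        },
        index=pd.Index(genes, name="gene"),
    )
    return out.sort_values(["BF", "gene"], ascending=[False, True], kind="mergesort")


def fdr_from_precision_recall(
    bf: pd.Series, refs: ReferenceSets
) -> tuple[pd.Series, pd.DataFrame, float]:
    """Per-gene FDR from the precision-recall walk down the BF ranking.

    At each rank, precision = essential references seen / all references
    seen; FDR = 1 - precision, monotonized (cumulative max) downward so FDR
    never decreases as BF decreases.  Genes with tied BF share the
    precision evaluated at the end of their tie block (threshold
    semantics).  Also returns the PR curve over reference genes and its
    PR-AUC (average precision).
    """
    vals = bf.fillna(-np.inf)
    order = sorted(vals.index, key=lambda g: (-vals[g], str(g)))
    ordered_bf = vals.reindex(order).to_numpy()
    is_ess = np.array([g in refs.essential for g in order])
    is_non = np.array([g in refs.nonessential for g in order])
    if not (is_ess.any() or is_non.any()):
        raise ValueError("no reference genes present in the BF table")
    cum_ess = np.cumsum(is_ess)
    cum_ref = cum_ess + np.cumsum(is_non)
    # index of the last gene in each tie block of equal BF
    n = len(order)
    block_end = np.empty(n, dtype=int)
    i = 0
    while i < n:
        j = i
        while j + 1 < n and ordered_bf[j + 1] == ordered_bf[i]:
            j += 1
        block_end[i : j + 1] = j
        i = j + 1
    cum_ess_b = cum_ess[block_end]
    cum_ref_b = cum_ref[block_end]
    with np.errstate(invalid="ignore", divide="ignore"):
        precision = np.where(cum_ref_b > 0, cum_ess_b / np.maximum(cum_ref_b, 1), 1.0)
    fdr = np.maximum.accumulate(1.0 - precision)
    fdr_series = pd.Series(fdr, index=pd.Index(order, name="gene"), name="FDR")
    ref_mask = is_ess | is_non
    curve = pd.DataFrame(
        {
            "rank": np.arange(1, len(order) + 1)[ref_mask],
            "recall": cum_ess[ref_mask] / max(int(is_ess.sum()), 1),
            "precision": precision[ref_mask],
        }
    )
    labels = is_ess[ref_mask].astype(int)
    scores = bf.reindex(np.array(order)[ref_mask]).to_numpy()
    pr_auc = float(average_precision_score(labels, scores)) if labels.any() else float("nan")
    return fdr_series, curve, pr_auc


def call_hits(
    table: pd.DataFrame,
    bf_min: float = 0.0,
    fdr_max: float = 0.1,
    restrict_to_category: Optional[str] = "mirna",
) -> list[str]:
    """Hit rule: BF strictly above ``bf_min`` and FDR strictly below
    ``fdr_max``, optionally restricted to one guide category."""
    mask = (table["BF"] > bf_min) & (table["FDR"] < fdr_max)
    if restrict_to_category is not None:
        mask &= table["category"] == restrict_to_category
    return sorted(table.index[mask])


@dataclass(frozen=True)
class OverlapResult:
    common: frozenset
    union: frozenset

    @property
    def counts(self) -> dict:
        return {"common": len(self.common), "union": len(self.union)}


def overlap_hits(hits_a, hits_b) -> OverlapResult:
    a, b = frozenset(hits_a), frozenset(hits_b)
    return OverlapResult(common=a & b, union=a | b)


def analyze_screen(
    sc: ScreenCounts,
    refs: ReferenceSets,
    n_iterations: int = 1000,
    seed: int = 0,
    pseudocount: float = 5.0,
    scale: float = 1e7,
    bf_min: float = 0.0,
    fdr_max: float = 0.1,
    restrict_to_category: Optional[str] = "mirna",
) -> dict:
    """End-to-end screen analysis: normalise, BF, FDR, hit calls.

    Returns a dict with the per-gene results table (BF, FDR, hit), the PR
    curve over reference genes, PR-AUC and the hit list.
    """
    fct = normalize_and_fold_change(sc, pseudocount=pseudocount, scale=scale)
    bf_table = compute_bayes_factors(fct, refs, n_iterations=n_iterations, seed=seed)
    fdr, curve, pr_auc = fdr_from_precision_recall(bf_table["BF"], refs)
    table = bf_table.join(fdr)
    hits = call_hits(
        table, bf_min=bf_min, fdr_max=fdr_max,
        restrict_to_category=restrict_to_category,
    )
    table["hit"] = table.index.isin(hits)
    return {"table": table, "pr_curve": curve, "pr_auc": pr_auc, "hits": hits}
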