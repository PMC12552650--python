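"""gRNA enumeration, scoring filters, selection and library assembly.

The design pipeline mirrors standard pooled-knockout practice for SpCas9:
every 20-nt protospacer adjacent to an NGG PAM on either strand is a
candidate; candidates are filtered on a consumed on-target efficiency score
(Rule Set 2 style, external input; guides below 0.2 excluded) and on the
count of high-CFD off-target loci ("bin I", guides with more than 3
excluded); for each pre-miRNA hairpin up to four survivors are selected with
non-loop (stem-cutting) guides strictly prioritised and a minimum of three
required.  Control arms (core-essential / non-essential genes chosen by
reference Bayes factors) and a ~1% non-targeting padding complete the
library.

The CFD (Cutting Frequency Determination) score of a guide against an
off-target locus is the product over the 20 protospacer positions of
empirical position- and base-pair-specific mismatch penalties, times a PAM
penalty; a perfect match with canonical PAM scores 1.0.
"""

from __future__ import annotations

import csv
import io
import json
import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .annotation import (
    GenomicInterval,
    HairpinRecord,
    RegionMap,
    LOOP,
    reverse_complement,
)

CATEGORIES = ("mirna", "essential_ctrl", "noness_ctrl", "non_targeting")

_IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT",
}


def _pattern_match(seq: str, pattern: str) -> bool:
    return len(seq) == len(pattern) and all(
        b in _IUPAC.get(p, "") for b, p in zip(seq, pattern)
    )


class CfdTableError(KeyError):
    """A penalty lookup key is missing from the CFD table."""


@dataclass(frozen=True)
class OffTargetSite:
    locus: GenomicInterval
    mismatch_count: int
    cfd: float
    in_protein_coding: bool = False


@dataclass(frozen=True)
class GuideCandidate:
    """A 20-nt protospacer + PAM with cut site and scoring annotations.

    ``cut_site`` is the genomic boundary coordinate between protospacer
    positions 17 and 18 (the blunt SpCas9 cut, 3 nt 5' of the PAM).
    """

    protospacer: str
    pam: str
    chrom: str
    cut_site: int
    strand: str
    target_id: str = ""
    region_class: str = "n/a"
    on_target_score: Optional[float] = None
    off_target_sites: tuple[OffTargetSite, ...] = ()
    guide_id: str = ""

    def __post_init__(self) -> None:
        if len(self.protospacer) != 20:
            raise ValueError(f"protospacer must be 20 nt, got {len(self.protospacer)}")
        if not self.guide_id:
            object.__setattr__(
                self, "guide_id", f"{self.chrom}:{self.cut_site}:{self.strand}"
            )

    def bin1_count(self, cfd_threshold: float = 1.0) -> int:
        """Number of off-target loci at or above the bin-I CFD threshold."""
        return sum(1 for s in self.off_target_sites if s.cfd >= cfd_threshold)


@dataclass
class CfdPenaltyTable:
    """Mismatch penalties keyed by (position 1-20, guide base, site base).

    ``mismatch[(pos, g, o)]`` is the penalty for guide base ``g`` opposite
    off-target base ``o`` at protospacer position ``pos`` (1 = PAM-distal);
    matched bases score 1.0 by definition.  ``pam[pam_seq]`` is the PAM
    penalty (canonical NGG variants 1.0).
    """

    mismatch: dict[tuple[int, str, str], float]
    pam: dict[str, float]

    def mismatch_penalty(self, pos: int, guide_base: str, site_base: str) -> float:
        if guide_base == site_base:
            return 1.0
        key = (pos, guide_base, site_base)
        try:
            return self.mismatch[key]
        except KeyError:
            raise CfdTableError(
                f"no CFD mismatch penalty for position={pos} "
                f"guide_base={guide_base} site_base={site_base}"
            ) from None

    def pam_penalty(self, pam: str) -> float:
        try:
            return self.pam[pam]
        except KeyError:
            raise CfdTableError(f"no CFD PAM penalty for PAM={pam}") from None

    def to_csv(self) -> str:
        buf = io.StringIO()
        w = csv.writer(buf)
        w.writerow(["kind", "position", "guide_base", "site_base", "penalty"])
        for (pos, g, o), p in sorted(self.mismatch.items()):
            w.writerow(["mismatch", pos, g, o, p])
        for pam, p in sorted(self.pam.items()):
            w.writerow(["pam", "", pam, "", p])
        return buf.getvalue()

    @classmethod
    def from_csv(cls, text: str) -> "CfdPenaltyTable":
        mismatch: dict[tuple[int, str, str], float] = {}
        pam: dict[str, float] = {}
        for row in csv.DictReader(io.StringIO(text)):
            p = float(row["penalty"])
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"penalty out of [0,1]: {row}")
            if row["kind"] == "mismatch":
                mismatch[(int(row["position"]), row["guide_base"], row["site_base"])] = p
            elif row["kind"] == "pam":
                pam[row["guide_base"]] = p
            else:
                raise ValueError(f"unknown CFD table row kind {row['kind']!r}")
        return cls(mismatch=mismatch, pam=pam)


def enumerate_candidates(
    sequence: str,
    window: GenomicInterval,
    pam_pattern: str = "NGG",
) -> list[GuideCandidate]:
    """Enumerate every PAM-adjacent 20-mer on both strands of a window.

    ``sequence`` is the forward-strand genomic sequence of ``window``.
    Candidates containing non-ACGT bases in the protospacer or PAM are
    skipped.  Cut sites are genomic boundary coordinates 3 nt 5' of the PAM.
    """
    seq = sequence.upper()
    if len(seq) != len(window):
        raise ValueError("sequence length must equal window length")
    plen = len(pam_pattern)
    out: list[GuideCandidate] = []
    rc = reverse_complement(seq)
    n = len(seq)
    for strand, s in (("+", seq), ("-", rc)):
        for i in range(0, len(s) - 20 - plen + 1):
            proto = s[i : i + 20]
            pam = s[i + 20 : i + 20 + plen]
            if not _pattern_match(pam, pam_pattern):
                continue
            if any(b not in "ACGT" for b in proto + pam):
                continue
            if strand == "+":
                cut = window.start + i + 17
            else:
                cut = window.end - (i + 17)
            out.append(
                GuideCandidate(
                    protospacer=proto, pam=pam, chrom=window.chrom,
                    cut_site=cut, strand=strand,
                )
            )
    out.sort(key=lambda c: (c.cut_site, c.strand, c.protospacer))
    return out


def cfd_score(guide: str, site: str, pam: str, table: CfdPenaltyTable) -> float:
    """CFD score of a guide against a (site, PAM): product of penalties."""
    guide = guide.upper()
    site = site.upper()
    if len(guide) != len(site):
        raise ValueError("guide and site must be equal length")
    score = table.pam_penalty(pam.upper())
    for pos, (g, o) in enumerate(zip(guide, site), start=1):
        score *= table.mismatch_penalty(pos, g, o)
    return score


def _hamming(a: str, b: str) -> int:
    return sum(x != y for x, y in zip(a, b))


def enumerate_off_targets(
    guide: GuideCandidate,
    genome: Mapping[str, str],
    max_mismatches: int,
    table: CfdPenaltyTable,
    coding_intervals: Sequence[GenomicInterval] = (),
    pam_pattern: str = "NGG",
) -> list[OffTargetSite]:
    """Exhaustively scan a (fixture-scale) genome for off-target loci.

    Returns every PAM-adjacent locus within ``max_mismatches`` of the
    protospacer, excluding the guide's own cut locus, with its CFD score and
    protein-coding overlap flag.
    """
    plen = len(pam_pattern)
    sites: list[OffTargetSite] = []
    for chrom, seq in genome.items():
        seq = seq.upper()
        rc = reverse_complement(seq)
        n = len(seq)
        for strand, s in (("+", seq), ("-", rc)):
            for i in range(0, len(s) - 20 - plen + 1):
                proto = s[i : i + 20]
                pam = s[i + 20 : i + 20 + plen]
                if not _pattern_match(pam, pam_pattern):
                    continue
                if any(b not in "ACGT" for b in proto + pam):
                    continue
                mm = _hamming(guide.protospacer, proto)
                if mm > max_mismatches:
                    continue
                if strand == "+":
                    start, end = i, i + 20
                    cut = i + 17
                else:
                    start, end = n - (i + 20), n - i
                    cut = n - (i + 17)
                if (
                    chrom == guide.chrom
                    and strand == guide.strand
                    and cut == guide.cut_site
                ):
                    continue  # the on-target locus itself
                locus = GenomicInterval(chrom, start, end, strand)
                sites.append(
                    OffTargetSite(
                        locus=locus,
                        mismatch_count=mm,
                        cfd=cfd_score(guide.protospacer, proto, pam, table),
                        in_protein_coding=any(locus.overlaps(c) for c in coding_intervals),
                    )
                )
    return sites


@dataclass(frozen=True)
class ExclusionRecord:
    candidate: GuideCandidate
    reason: str  # 'unscored' | 'on_target' | 'off_target'


def apply_design_filters(
    candidates: Sequence[GuideCandidate],
    on_target_min: float = 0.2,
    bin1_max: int = 3,
    bin1_cfd_threshold: float = 1.0,
) -> tuple[list[GuideCandidate], list[ExclusionRecord]]:
    """Score filters: drop guides with on-target < 0.2 or bin-I count > 3.

    Thresholds are exclusive exactly as stated (boundary values are kept).
    Unscored candidates are excluded with reason ``unscored``, never silently
    kept.  Each exclusion carries exactly one primary reason, checked in the
    order unscored > on_target > off_target.
    """
    kept: list[GuideCandidate] = []
    excluded: list[ExclusionRecord] = []
    for c in candidates:
        if c.on_target_score is None:
            excluded.append(ExclusionRecord(c, "unscored"))
        elif c.on_target_score < on_target_min:
            excluded.append(ExclusionRecord(c, "on_target"))
        elif c.bin1_count(bin1_cfd_threshold) > bin1_max:
            excluded.append(ExclusionRecord(c, "off_target"))
        else:
            kept.append(c)
    return kept, excluded


def classify_candidates(
    candidates: Sequence[GuideCandidate],
    hairpin: HairpinRecord,
    region_map: RegionMap,
) -> list[GuideCandidate]:
    """Attach stem/loop region classes by cut-site position.

    The indel forms at the cut, so the cut boundary position (clamped into
    the hairpin) determines the region class; guides cutting outside the
    hairpin keep class 'n/a'.
    """
    out = []
    n = len(hairpin.sequence)
    for c in candidates:
        if hairpin.locus.strand == "+":
            local = c.cut_site - hairpin.locus.start
        else:
            local = hairpin.locus.end - c.cut_site
        if 0 <= local <= n:
            cls = region_map.label_at(min(max(local, 0), n - 1))
        else:
            cls = "n/a"
        out.append(replace(c, region_class=cls, target_id=hairpin.hairpin_id))
    return out


def _selection_key(c: GuideCandidate) -> tuple:
    score = c.on_target_score if c.on_target_score is not None else -1.0
    return (-score, c.bin1_count(), c.protospacer)


@dataclass
class HairpinSelection:
    hairpin_id: str
    guides: list[GuideCandidate]
    excluded: bool = False
    reason: str = ""


def select_guides_for_hairpin(
    kept_candidates: Sequence[GuideCandidate],
    region_map: RegionMap,
    n_target: int = 4,
    n_min: int = 3,
) -> HairpinSelection:
    """Select up to ``n_target`` guides, stem (non-loop) cuts strictly first.

    Within a stratum the order is (higher on-target score, fewer bin-I
    off-targets, lexicographic protospacer) — fully deterministic.  Hairpins
    with fewer than ``n_min`` kept candidates are returned as excluded.
    """
    hid = region_map.hairpin_id
    if len(kept_candidates) < n_min:
        return HairpinSelection(
            hairpin_id=hid, guides=[], excluded=True,
            reason=f"only {len(kept_candidates)} kept candidates (< {n_min})",
        )
    non_loop = sorted(
        (c for c in kept_candidates if c.region_class != LOOP), key=_selection_key
    )
    loop = sorted(
        (c for c in kept_candidates if c.region_class == LOOP), key=_selection_key
    )
    chosen = (non_loop + loop)[:n_target]
    return HairpinSelection(hairpin_id=hid, guides=chosen)


@dataclass(frozen=True)
class ControlGeneSet:
    essential_genes: tuple[str, ...]
    nonessential_genes: tuple[str, ...]
    source_bf: Mapping[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if set(self.essential_genes) & set(self.nonessential_genes):
            raise ValueError("essential and non-essential control sets overlap")


def choose_control_genes(
    reference_bf_tables: Sequence[Mapping[str, float]],
    n_ess: int = 100,
    n_noness: int = 100,
) -> ControlGeneSet:
    """Pick control genes by mean reference Bayes factor across screens.

    Genes must be scored in every table; the top ``n_ess`` by mean BF become
    essential controls, the bottom ``n_noness`` non-essential controls, ties
    broken lexicographically.
    """
    if not reference_bf_tables:
        raise ValueError("at least one reference BF table required")
    common = set(reference_bf_tables[0])
    for t in reference_bf_tables[1:]:
        common &= set(t)
    if len(common) < n_ess + n_noness:
        raise ValueError(
            f"only {len(common)} genes scored in all tables; "
            f"need {n_ess + n_noness}"
        )
    mean_bf = {
        g: float(np.mean([t[g] for t in reference_bf_tables])) for g in common
    }
    ranked = sorted(mean_bf, key=lambda g: (-mean_bf[g], g))
    essential = tuple(ranked[:n_ess])
    ranked_low = sorted(mean_bf, key=lambda g: (mean_bf[g], g))
    noness = tuple(g for g in ranked_low if g not in set(essential))[:n_noness]
    return ControlGeneSet(essential, noness, mean_bf)


def pad_non_targeting(
    n_other_guides: int,
    fraction: float = 0.01,
    pool: Sequence[str] = (),
    seed: int = 0,
) -> list[str]:
    """Sample non-targeting protospacers to make up ``fraction`` of the library.

    k solves k = fraction * (n_other + k), i.e. k = f*n/(1-f), rounded
    half-away-from-zero; sampling is without replacement from ``pool`` with
    the given seed.
    """
    if not 0 <= fraction < 1:
        raise ValueError("fraction must be in [0, 1)")
    k = math.floor(fraction * n_other_guides / (1.0 - fraction) + 0.5)
    if k == 0:
        return []
    if len(pool) < k:
        raise ValueError(f"non-targeting pool has {len(pool)} entries; need {k}")
    rng = np.random.default_rng(seed)
    idx = rng.choice(len(pool), size=k, replace=False)
    return [pool[i] for i in idx]


@dataclass(frozen=True)
class DkoPair:
    """Two guides flanking a locus for complete excision (dual knockout)."""

    left_guide: GuideCandidate
    right_guide: GuideCandidate
    excised_interval: GenomicInterval
    cassette_layout: tuple[str, ...] = ("gRNA", "tracrRNA", "U6", "gRNA")

    def __post_init__(self) -> None:
        if not (
            self.excised_interval.start == self.left_guide.cut_site
            and self.excised_interval.end == self.right_guide.cut_site
        ):
            raise ValueError("excised interval must span the two cut sites")


def design_dko_pair(
    target: GenomicInterval, candidates: Sequence[GuideCandidate]
) -> DkoPair:
    """Choose the innermost flanking guide pair that excises ``target``.

    Minimises excised length subject to both cuts strictly flanking the
    target; ties broken lexicographically on protospacers.
    """
    lefts = [c for c in candidates if c.chrom == target.chrom and c.cut_site < target.start]
    rights = [c for c in candidates if c.chrom == target.chrom and c.cut_site > target.end]
    if not lefts:
        raise ValueError("no kept candidate cuts left of the target")
    if not rights:
        raise ValueError("no kept candidate cuts right of the target")
    best = min(
        ((l, r) for l in lefts for r in rights),
        key=lambda p: (p[1].cut_site - p[0].cut_site, p[0].protospacer, p[1].protospacer),
    )
    left, right = best
    return DkoPair(
        left_guide=left,
        right_guide=right,
        excised_interval=GenomicInterval(
            target.chrom, left.cut_site, right.cut_site, target.strand
        ),
    )


MANIFEST_COLUMNS = [
    "guide_id", "protospacer", "pam", "category", "target_id",
    "region_class", "on_target", "bin1_count",
]


@dataclass
class LibraryManifest:
    """The assembled gRNA library with per-category composition totals."""

    entries: pd.DataFrame
    composition: dict
    report: dict

    def to_tsv(self) -> str:
        return self.entries.to_csv(sep="\t", index=False)

    def to_summary_json(self) -> str:
        return json.dumps(
            {"composition": self.composition, "report": self.report},
            indent=2, sort_keys=True,
        )

    @classmethod
    def from_tsv(cls, text: str) -> "LibraryManifest":
        entries = pd.read_csv(io.StringIO(text), sep="\t", dtype={"target_id": str})
        comp, report = composition_report(entries)
        return cls(entries=entries, composition=comp, report=report)


def composition_report(entries: pd.DataFrame) -> tuple[dict, dict]:
    """Per-category totals and the guides-per-target consistency breakdown."""
    comp = {cat: int((entries["category"] == cat).sum()) for cat in CATEGORIES}
    comp["total"] = int(len(entries))
    mirna = entries[entries["category"] == "mirna"]
    per_target = mirna.groupby("target_id").size() if len(mirna) else pd.Series(dtype=int)
    hist = per_target.value_counts().to_dict()
    report = {
        "n_mirna_targets": int(per_target.shape[0]),
        "guides_per_target": {int(k): int(v) for k, v in sorted(hist.items())},
        "three_guide_targets": int(hist.get(3, 0)),
        "four_guide_targets": int(hist.get(4, 0)),
        "zero_mirna_targets": bool(per_target.shape[0] == 0),
    }
    return comp, report


def assemble_library(
    selections: Sequence[HairpinSelection],
    control_set: ControlGeneSet,
    control_guides: Mapping[str, Sequence[GuideCandidate]],
    padding: Sequence[str],
    seed: int = 0,
) -> LibraryManifest:
    """Assemble the final manifest from selections, controls and padding.

    Raises on duplicate protospacers across categories (collisions listed).
    Entry order and guide ids are fully deterministic so identical inputs and
    seed produce a byte-identical manifest.
    """
    rows: list[dict] = []
    for sel in sorted(selections, key=lambda s: s.hairpin_id):
        if sel.excluded:
            continue
        for c in sel.guides:
            rows.append(
                {
                    "protospacer": c.protospacer, "pam": c.pam, "category": "mirna",
                    "target_id": sel.hairpin_id, "region_class": c.region_class,
                    "on_target": c.on_target_score, "bin1_count": c.bin1_count(),
                }
            )
    for gene in control_set.essential_genes + control_set.nonessential_genes:
        cat = (
            "essential_ctrl" if gene in control_set.essential_genes else "noness_ctrl"
        )
        for c in control_guides.get(gene, []):
            rows.append(
                {
                    "protospacer": c.protospacer, "pam": c.pam, "category": cat,
                    "target_id": gene, "region_class": "n/a",
                    "on_target": c.on_target_score, "bin1_count": c.bin1_count(),
                }
            )
    for proto in padding:
        rows.append(
            {
                "protospacer": proto, "pam": "", "category": "non_targeting",
                "target_id": "none", "region_class": "n/a",
                "on_target": None, "bin1_count": 0,
            }
        )
    entries = pd.DataFrame(rows, columns=[c for c in MANIFEST_COLUMNS if c != "guide_id"])
    dup = entries["protospacer"][entries["protospacer"].duplicated(keep=False)]
    if len(dup):
        raise ValueError(
            "duplicate protospacers across library entries: "
            + ", ".join(sorted(dup.unique()))
        )
    order = {cat: i for i, cat in enumerate(CATEGORIES)}
    entries = entries.sort_values(
        by=["category", "target_id", "protospacer"],
        key=lambda col: col.map(order) if col.name == "category" else col,
        kind="mergesort",
    ).reset_index(drop=True)
    entries.insert(
        0,
        "guide_id",
        [
            f"{row.category}_{row.target_id}_{i:05d}"
            for i, row in enumerate(entries.itertuples(), start=1)
        ],
    )
    comp, report = composition_report(entries)
    report["seed"] = seed
    report["excluded_hairpins"] = sorted(
        s.hairpin_id for s in selections if s.excluded
    )
    return LibraryManifest(entries=entries, composition=comp, report=report)
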