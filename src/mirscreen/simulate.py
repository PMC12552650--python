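"""Synthetic fixtures for end-to-end testing of the design and analysis stack.

Three generators cover the toolchain's inputs:

* a toy miRNome — a small genome with planted plus-strand hairpins (both
  mature arms annotated), guaranteed stem-cutting PAM sites, optional planted
  off-target decoys, a surrogate on-target score table and a full CFD penalty
  fixture;
* pooled-screen count matrices under the study conditions (1000x culture
  representation, 500x sequencing depth, three replicates, log2 depletion of
  planted essential genes by the terminal timepoint), using a log-normal
  abundance / multinomial sequencing model with a gamma dispersion knob;
* two-agent dose-response surfaces built as the Bliss combination of two
  Hill curves with a tunable additive interaction term.

Every generator is deterministic given its seed.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .annotation import GenomicInterval, HairpinRecord, write_mirna_annotations
from .design import (
    CfdPenaltyTable,
    GuideCandidate,
    LibraryManifest,
    assemble_library,
    composition_report,
    enumerate_candidates,
)
from .essentiality import ScreenCounts, parse_sample_labels
from .pharmacology import DoseResponseSurface, four_pl

_BASES = np.array(list("ACGT"))

HAIRPIN_LEN = 80
ARM5P = (6, 28)
ARM3P = (52, 74)
# plus-strand PAM start positions (hairpin-local); cuts land 3 nt left, in stem
_PLANTED_PAM_STARTS = (15, 20, 25, 63, 68, 73)


def surrogate_on_target_score(protospacer: str, seed: int = 0) -> float:
    """Deterministic hash-based stand-in for an external on-target score."""
    h = hashlib.sha256(f"{protospacer}/{seed}".encode()).digest()
    return int.from_bytes(h[:4], "big") / 2**32


def make_cfd_table(seed: int = 0) -> CfdPenaltyTable:
    """A complete CFD penalty fixture: PAM-proximal mismatches penalised
    hardest, pair-specific factors drawn deterministically from the seed."""
    rng = np.random.default_rng(seed)
    mismatch: dict[tuple[int, str, str], float] = {}
    for pos in range(1, 21):
        profile = max(1.0 - pos / 22.0, 0.05)
        for g in "ACGT":
            for o in "ACGT":
                if g == o:
                    continue
                pair = float(rng.uniform(0.6, 1.0))
                mismatch[(pos, g, o)] = round(min(profile * pair, 1.0), 4)
    pam: dict[str, float] = {}
    for a in "ACGT":
        for b in "ACGT":
            for c in "ACGT":
                p = a + b + c
                if p.endswith("GG"):
                    pam[p] = 1.0
                elif p.endswith("AG"):
                    pam[p] = 0.26
                elif p.endswith("GA"):
                    pam[p] = 0.07
                else:
                    pam[p] = 0.0
    return CfdPenaltyTable(mismatch=mismatch, pam=pam)


@dataclass
class MirnomeFixture:
    """A self-consistent toy miRNome: genome, annotations, scores, CFD table."""

    genome: dict[str, str]
    hairpins: list[HairpinRecord]
    gff_text: str
    hairpin_fasta: str
    scores: pd.DataFrame  # columns protospacer, score
    cfd_table: CfdPenaltyTable
    planted_offtargets: list[GenomicInterval]

    def score_lookup(self) -> dict[str, float]:
        return dict(zip(self.scores["protospacer"], self.scores["score"]))


def simulate_mirnome_fixture(
    n_hairpins: int = 3,
    genome_length: int = 3000,
    n_planted_offtargets: int = 0,
    seed: int = 0,
    chrom: str = "chrS",
) -> MirnomeFixture:
    """Build a toy genome hosting ``n_hairpins`` hairpins plus decoys.

    Each hairpin carries planted GG dinucleotides so that at least six
    PAM-adjacent candidates cut within stem regions.  Planted off-target
    decoys are exact protospacer+PAM copies pasted into the intergenic tail,
    at recorded loci.
    """
    rng = np.random.default_rng(seed)
    tail = 150 + 30 * max(n_planted_offtargets, 1)
    spacing = 60
    need = 100 + n_hairpins * (HAIRPIN_LEN + spacing) + tail
    if genome_length < need:
        raise ValueError(
            f"genome_length {genome_length} too small to pack {n_hairpins} "
            f"hairpins (need >= {need})"
        )
    genome = rng.choice(_BASES, size=genome_length)
    hairpins: list[HairpinRecord] = []
    for i in range(n_hairpins):
        start = 100 + i * (HAIRPIN_LEN + spacing)
        for pam_start in _PLANTED_PAM_STARTS:
            genome[start + pam_start + 1] = "G"
            genome[start + pam_start + 2] = "G"
        locus = GenomicInterval(chrom, start, start + HAIRPIN_LEN, "+")
        seq = "".join(genome[start : start + HAIRPIN_LEN])
        hairpins.append(
            HairpinRecord(
                hairpin_id=f"SYN-MI{i + 1:04d}",
                name=f"syn-mir-{i + 1}",
                sequence=seq,
                locus=locus,
                arm5p=ARM5P,
                arm3p=ARM3P,
            )
        )
    # plant exact-duplicate off-target decoys in the tail
    planted: list[GenomicInterval] = []
    tail_cursor = genome_length - tail + 20
    for k in range(n_planted_offtargets):
        src = hairpins[k % n_hairpins].locus.start + _PLANTED_PAM_STARTS[0]
        dup = genome[src - 20 : src + 3].copy()
        genome[tail_cursor : tail_cursor + 23] = dup
        planted.append(GenomicInterval(chrom, tail_cursor, tail_cursor + 23, "+"))
        tail_cursor += 30
    genome_str = "".join(genome)
    gff_text, hairpin_fasta = write_mirna_annotations(hairpins)
    # surrogate scores for every candidate around each hairpin
    protos: list[str] = []
    for h in hairpins:
        win = GenomicInterval(
            chrom, h.locus.start - 25, h.locus.end + 25, "+"
        )
        for c in enumerate_candidates(genome_str[win.start : win.end], win):
            protos.append(c.protospacer)
    protos = sorted(set(protos))
    scores = pd.DataFrame(
        {
            "protospacer": protos,
            "score": [surrogate_on_target_score(p, seed) for p in protos],
        }
    )
    return MirnomeFixture(
        genome={chrom: genome_str},
        hairpins=hairpins,
        gff_text=gff_text,
        hairpin_fasta=hairpin_fasta,
        scores=scores,
        cfd_table=make_cfd_table(seed),
        planted_offtargets=planted,
    )


@dataclass(frozen=True)
class ScreenSimParams:
    """Generative settings for a pooled dropout screen.

    Defaults mirror the screen's study conditions: 1000x cells per guide
    maintained in culture, 500x reads per guide at sequencing, three
    technical replicates per timepoint, and a terminal-timepoint log2
    depletion of -4 for essential guides.
    """

    representation: int = 1000
    seq_depth: int = 500
    timepoints: tuple[int, ...] = (9, 18, 27)
    replicates: int = 3
    dropout_effect: float = -4.0
    guide_effect_rel_sd: float = 0.15
    abundance_sigma: float = 0.5
    noise_dispersion: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.representation, self.seq_depth, self.replicates) <= 0:
            raise ValueError("representation, seq_depth, replicates must be positive")
        if self.dropout_effect > 0:
            raise ValueError("dropout_effect must be <= 0 for depletion")


@dataclass(frozen=True)
class SyntheticTruth:
    """Ground truth of a simulated screen for recovery testing."""

    essential_targets: frozenset
    guide_effects: Mapping[str, float]
    planted_offtargets: tuple = ()


def random_protospacers(n: int, rng: np.random.Generator) -> list[str]:
    """``n`` unique random 20-mers."""
    out: set[str] = set()
    while len(out) < n:
        block = rng.choice(_BASES, size=(n - len(out) + 8, 20))
        out.update("".join(row) for row in block)
    return sorted(out)[:n]


def synthetic_manifest(
    n_hairpins: int = 1649,
    n_three_guide: int = 64,
    guides_per_target: int = 4,
    n_ess_ctrl: int = 100,
    n_noness_ctrl: int = 100,
    ctrl_guides_per_gene: int = 4,
    non_targeting_fraction: float = 0.01,
    seed: int = 0,
) -> LibraryManifest:
    """A manifest-shaped library built directly (no genome), at any scale.

    Defaults reproduce the study's composition: 1649 hairpin targets with 3
    or 4 guides each (64 at 3), 100+100 control genes at 4 guides, and ~1%
    non-targeting padding.
    """
    import math

    rng = np.random.default_rng(seed)
    n_three_guide = min(n_three_guide, n_hairpins)
    n_mirna = n_hairpins * guides_per_target - n_three_guide
    n_ctrl = (n_ess_ctrl + n_noness_ctrl) * ctrl_guides_per_gene
    n_other = n_mirna + n_ctrl
    k_pad = math.floor(
        non_targeting_fraction * n_other / (1.0 - non_targeting_fraction) + 0.5
    )
    protos = random_protospacers(n_other + k_pad, rng)
    rows = []
    it = iter(protos)
    for i in range(n_hairpins):
        n_g = guides_per_target - (1 if i < n_three_guide else 0)
        for _ in range(n_g):
            rows.append(
                {"category": "mirna", "target_id": f"SYN-MI{i + 1:04d}",
                 "protospacer": next(it), "region_class": "stem5p"}
            )
    for j in range(n_ess_ctrl):
        for _ in range(ctrl_guides_per_gene):
            rows.append(
                {"category": "essential_ctrl", "target_id": f"ESS{j + 1:03d}",
                 "protospacer": next(it), "region_class": "n/a"}
            )
    for j in range(n_noness_ctrl):
        for _ in range(ctrl_guides_per_gene):
            rows.append(
                {"category": "noness_ctrl", "target_id": f"NON{j + 1:03d}",
                 "protospacer": next(it), "region_class": "n/a"}
            )
    for _ in range(k_pad):
        rows.append(
            {"category": "non_targeting", "target_id": "none",
             "protospacer": next(it), "region_class": "n/a"}
        )
    entries = pd.DataFrame(rows)
    entries["pam"] = "AGG"
    entries["on_target"] = [
        round(0.2 + 0.8 * surrogate_on_target_score(p, seed), 4)
        for p in entries["protospacer"]
    ]
    entries["bin1_count"] = 0
    entries.insert(
        0, "guide_id",
        [f"{r.category}_{r.target_id}_{i:05d}"
         for i, r in enumerate(entries.itertuples(), start=1)],
    )
    comp, report = composition_report(entries)
    report["seed"] = seed
    return LibraryManifest(entries=entries, composition=comp, report=report)


def plant_essentials(
    manifest: LibraryManifest,
    n_essential_mirna: int,
    params: ScreenSimParams,
) -> SyntheticTruth:
    """Pick planted essential miRNA targets and assign per-guide depletion.

    Guides of planted miRNA targets and of all essential-control genes
    deplete by ``dropout_effect`` log2 units at the terminal timepoint.
    Guide-to-guide efficiency variation scales the effect multiplicatively
    (normal with mean 1, sd ``guide_effect_rel_sd``), so a zero effect gives
    a true null; all other guides are neutral.
    """
    rng = np.random.default_rng(params.seed + 1)
    entries = manifest.entries
    mirna_targets = sorted(entries.loc[entries["category"] == "mirna", "target_id"].unique())
    if n_essential_mirna > len(mirna_targets):
        raise ValueError("more planted essentials requested than miRNA targets")
    chosen = sorted(
        rng.choice(mirna_targets, size=n_essential_mirna, replace=False)
    )
    essential = set(chosen)
    effects: dict[str, float] = {}
    for row in entries.itertuples():
        if row.target_id in essential or row.category == "essential_ctrl":
            effects[row.guide_id] = params.dropout_effect * float(
                rng.normal(1.0, params.guide_effect_rel_sd)
            )
        else:
            effects[row.guide_id] = 0.0
    return SyntheticTruth(essential_targets=frozenset(essential), guide_effects=effects)


def simulate_screen_counts(
    manifest: LibraryManifest,
    truth: SyntheticTruth,
    params: ScreenSimParams,
) -> ScreenCounts:
    """Simulate gRNA read counts for T0 and every timepoint x replicate.

    T0 abundances are log-normal around the culture representation; a guide
    with true depletion rate e loses 2^(e * t / t_terminal) of its abundance
    by timepoint t; sequencing draws ``seq_depth x n_guides`` reads per
    sample from the (gamma-perturbed) abundance simplex.
    """
    rng = np.random.default_rng(params.seed)
    entries = manifest.entries
    guide_ids = list(entries["guide_id"])
    n = len(guide_ids)
    effects = np.array([truth.guide_effects.get(g, 0.0) for g in guide_ids])
    a0 = rng.lognormal(mean=np.log(params.representation), sigma=params.abundance_sigma, size=n)
    reads_per_sample = params.seq_depth * n
    t_max = max(params.timepoints)

    def _draw(abundance: np.ndarray) -> np.ndarray:
        if params.noise_dispersion > 0:
            shape = 1.0 / params.noise_dispersion
            abundance = abundance * rng.gamma(shape, 1.0 / shape, size=n)
        p = abundance / abundance.sum()
        return rng.multinomial(reads_per_sample, p)

    data: dict[str, np.ndarray] = {"T0": _draw(a0)}
    for t in params.timepoints:
        decayed = a0 * np.exp2(effects * t / t_max)
        for r in range(1, params.replicates + 1):
            data[f"T{t}_R{r}"] = _draw(decayed)
    counts = pd.DataFrame(data, index=pd.Index(guide_ids, name="guide_id"))
    guides = entries.set_index("guide_id")[["target_id", "category"]]
    return ScreenCounts(
        counts=counts, guides=guides, samples=parse_sample_labels(counts.columns)
    )


@dataclass(frozen=True)
class HillParams:
    """Monotherapy Hill curve (viability %): response falls from top to
    bottom with midpoint ec50 and slope hill."""

    ec50: float
    hill: float = 1.0
    top: float = 100.0
    bottom: float = 0.0

    def __post_init__(self) -> None:
        if self.ec50 <= 0:
            raise ValueError("ec50 must be positive")

    def viability(self, dose) -> np.ndarray:
        return four_pl(np.asarray(dose, dtype=float),
                       self.top, self.bottom, self.ec50, self.hill)

    def inhibition(self, dose) -> np.ndarray:
        return 1.0 - self.viability(dose) / 100.0


def simulate_dose_response_surface(
    hill_a: HillParams,
    hill_b: HillParams,
    doses_a: Sequence[float],
    doses_b: Sequence[float],
    interaction_delta: float = 0.0,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> DoseResponseSurface:
    """Bliss combination of two Hill curves plus a planted interaction.

    ``interaction_delta`` (percent-inhibition units) is added to every
    combination well (both doses > 0); Gaussian noise of ``noise_sd``
    (viability % units) is added everywhere.
    """
    rng = np.random.default_rng(seed)
    da = np.asarray(doses_a, dtype=float)
    db = np.asarray(doses_b, dtype=float)
    ya = hill_a.inhibition(da)
    yb = hill_b.inhibition(db)
    y = ya[:, None] + yb[None, :] - ya[:, None] * yb[None, :]
    combo = (da[:, None] > 0) & (db[None, :] > 0)
    y = y + np.where(combo, interaction_delta / 100.0, 0.0)
    viability = 100.0 * (1.0 - y)
    if noise_sd > 0:
        viability = viability + rng.normal(0.0, noise_sd, size=viability.shape)
    return DoseResponseSurface(doses_a=da, doses_b=db, response=viability)
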