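"""Pre-miRNA hairpin annotation, stem/loop geometry and seed-site utilities.

A pre-miRNA hairpin folds into two base-paired arms (the stem) closed by an
unpaired apical loop.  The mature 5p and 3p miRNA strands are excised from the
arms, so the annotated mature intervals define the stem geometry directly:
positions inside either mature arm (and their flanks) are stem, positions
strictly between the two arms are loop.  Guide selection downstream
prioritises stem cuts, which disrupt hairpin processing more reliably than
loop cuts.

All internal coordinates are 0-based half-open; GFF3's 1-based inclusive
convention is converted at the parsing boundary.  RNA sequences are mapped to
the DNA alphabet (U -> T) on ingestion so a single alphabet serves matching.
"""

from __future__ import annotations

import io
import logging
from dataclasses import dataclass, field, replace
from typing import Iterator, Optional, Sequence

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from gffutils.feature import feature_from_line

logger = logging.getLogger(__name__)

STEM5P = "stem5p"
LOOP = "loop"
STEM3P = "stem3p"

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

#: seed site classes ordered weakest -> strongest
SITE_TYPES = ("6mer", "7mer-A1", "7mer-m8", "8mer")


class GffParseError(ValueError):
    """A GFF3 line could not be parsed; carries the 1-based line number."""


class AnnotationConsistencyError(ValueError):
    """Mature/hairpin records are mutually inconsistent."""


class NoArmAnnotationError(ValueError):
    """Hairpin has no annotated mature arm; caller should exclude it."""


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def as_dna(seq: str) -> str:
    """Uppercase and map RNA to the DNA alphabet (U -> T)."""
    return seq.upper().replace("U", "T")


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """0-based half-open genomic interval."""

    chrom: str
    start: int
    end: int
    strand: str = "+"

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(f"require 0 <= start < end, got [{self.start}, {self.end})")
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    def contains(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start <= other.start
            and other.end <= self.end
        )

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )


@dataclass(frozen=True)
class HairpinRecord:
    """A pre-miRNA locus with sequence and mature-arm sub-intervals.

    Arm intervals are in hairpin-local coordinates (0-based, half-open,
    relative to the 5' end of the hairpin transcript, i.e. already
    orientation-corrected for minus-strand loci).
    """

    hairpin_id: str
    name: str
    sequence: str
    locus: GenomicInterval
    arm5p: Optional[tuple[int, int]] = None
    arm3p: Optional[tuple[int, int]] = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "sequence", as_dna(self.sequence))
        n = len(self.sequence)
        if n != len(self.locus):
            raise AnnotationConsistencyError(
                f"{self.hairpin_id}: sequence length {n} != locus length {len(self.locus)}"
            )
        for label, arm in (("arm5p", self.arm5p), ("arm3p", self.arm3p)):
            if arm is not None:
                s, e = arm
                if not (0 <= s < e <= n):
                    raise AnnotationConsistencyError(
                        f"{self.hairpin_id}: {label} {arm} outside [0, {n})"
                    )
        if self.arm5p is not None and self.arm3p is not None:
            if self.arm5p[1] > self.arm3p[0]:
                raise AnnotationConsistencyError(
                    f"{self.hairpin_id}: arm5p {self.arm5p} must precede arm3p {self.arm3p}"
                )

    def genomic_to_local(self, pos: int) -> int:
        """Map a genomic coordinate onto the hairpin transcript (5'->3')."""
        if self.locus.strand == "+":
            return pos - self.locus.start
        return self.locus.end - 1 - pos


@dataclass(frozen=True)
class RegionMap:
    """Per-position stem/loop labels over one hairpin."""

    hairpin_id: str
    labels: tuple[str, ...]

    def __post_init__(self) -> None:
        bad = set(self.labels) - {STEM5P, LOOP, STEM3P}
        if bad:
            raise ValueError(f"unknown region labels: {sorted(bad)}")

    def __len__(self) -> int:
        return len(self.labels)

    def label_at(self, local_pos: int) -> str:
        return self.labels[local_pos]

    def segments(self) -> list[tuple[int, int, str]]:
        """Maximal runs of identical labels as (start, end, label)."""
        out: list[tuple[int, int, str]] = []
        start = 0
        for i in range(1, len(self.labels) + 1):
            if i == len(self.labels) or self.labels[i] != self.labels[start]:
                out.append((start, i, self.labels[start]))
                start = i
        return out


@dataclass(frozen=True)
class SeedMatch:
    """A canonical miRNA seed-complementary site in a 3'UTR."""

    site_type: str
    utr_position: int
    matched_sequence: str

    def __post_init__(self) -> None:
        if self.site_type not in SITE_TYPES:
            raise ValueError(f"unknown site_type {self.site_type!r}")


@dataclass
class ParseResult:
    """Parsed hairpins plus the number of unmatched FASTA entries skipped."""

    records: list[HairpinRecord]
    n_skipped: int = 0

    def __iter__(self) -> Iterator[HairpinRecord]:
        return iter(self.records)

    def __len__(self) -> int:
        return len(self.records)


def _parse_gff_features(gff_text: str):
    features = []
    for lineno, raw in enumerate(gff_text.splitlines(), start=1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        fields = line.split("\t")
        if len(fields) != 9 or not (fields[3].isdigit() and fields[4].isdigit()):
            raise GffParseError(
                f"malformed GFF line {lineno}: expected 9 tab-separated fields "
                f"with integer coordinates"
            )
        try:
            features.append((lineno, feature_from_line(line)))
        except Exception as exc:  # gffutils raises assorted exception types
            raise GffParseError(f"malformed GFF line {lineno}: {exc}") from exc
    return features


def parse_mirna_annotations(gff_text: str, hairpin_fasta: str) -> ParseResult:
    """Parse miRBase-dialect GFF3 + hairpin FASTA into :class:`HairpinRecord`.

    The GFF carries ``miRNA_primary_transcript`` features (the hairpins) and
    ``miRNA`` features (mature strands) linked by ``Derives_from``.  FASTA ids
    must resolve to a hairpin's ``ID`` or ``Name``; entries that do not are
    skipped with a warning and counted in the result.  Hairpins without a
    sequence are rejected (dropped) as unusable for guide design.
    """
    primaries: dict[str, GenomicInterval] = {}
    names: dict[str, str] = {}
    matures: dict[str, list[GenomicInterval]] = {}
    alias: dict[str, str] = {}

    for lineno, feat in _parse_gff_features(gff_text):
        attrs = {k: v[0] for k, v in feat.attributes.items() if v}
        if feat.featuretype == "miRNA_primary_transcript":
            fid = attrs.get("ID")
            if fid is None:
                raise GffParseError(f"malformed GFF line {lineno}: missing ID attribute")
            iv = GenomicInterval(feat.seqid, feat.start - 1, feat.end, feat.strand)
            primaries[fid] = iv
            names[fid] = attrs.get("Name", fid)
            alias[fid] = fid
            alias[names[fid]] = fid
        elif feat.featuretype == "miRNA":
            parent = attrs.get("Derives_from") or attrs.get("Parent")
            if parent is None:
                raise GffParseError(
                    f"malformed GFF line {lineno}: mature miRNA lacks Derives_from"
                )
            iv = GenomicInterval(feat.seqid, feat.start - 1, feat.end, feat.strand)
            matures.setdefault(parent, []).append(iv)

    sequences: dict[str, str] = {}
    n_skipped = 0
    for rec in SeqIO.parse(io.StringIO(hairpin_fasta), "fasta"):
        fid = alias.get(rec.id)
        if fid is None:
            logger.warning("FASTA entry %s has no matching GFF record; skipped", rec.id)
            n_skipped += 1
            continue
        sequences[fid] = as_dna(str(rec.seq))

    records: list[HairpinRecord] = []
    for fid, locus in primaries.items():
        seq = sequences.get(fid)
        if seq is None:
            logger.warning("hairpin %s has no sequence; rejected", fid)
            continue
        arms: list[tuple[int, int]] = []
        for miv in matures.get(fid, []):
            if not locus.contains(miv) or miv.strand != locus.strand:
                raise AnnotationConsistencyError(
                    f"mature record {miv} outside hairpin {fid} at {locus}"
                )
            if locus.strand == "+":
                arms.append((miv.start - locus.start, miv.end - locus.start))
            else:
                arms.append((locus.end - miv.end, locus.end - miv.start))
        arms.sort()
        arm5p = arm3p = None
        if len(arms) == 1:
            # single annotated arm: assign by which half of the hairpin it sits in
            mid = len(locus) / 2
            center = (arms[0][0] + arms[0][1]) / 2
            if center <= mid:
                arm5p = arms[0]
            else:
                arm3p = arms[0]
        elif len(arms) >= 2:
            if len(arms) > 2:
                raise AnnotationConsistencyError(
                    f"hairpin {fid} has {len(arms)} mature records; expected <= 2"
                )
            arm5p, arm3p = arms
        records.append(
            HairpinRecord(
                hairpin_id=fid,
                name=names[fid],
                sequence=seq,
                locus=locus,
                arm5p=arm5p,
                arm3p=arm3p,
            )
        )
    return ParseResult(records=records, n_skipped=n_skipped)


def write_mirna_annotations(records: Sequence[HairpinRecord]) -> tuple[str, str]:
    """Serialise records back to (GFF3 text, FASTA text); inverse of parsing."""
    gff_lines = ["##gff-version 3"]
    fasta = io.StringIO()
    for rec in records:
        loc = rec.locus
        gff_lines.append(
            "\t".join(
                [
                    loc.chrom,
                    "mirscreen",
                    "miRNA_primary_transcript",
                    str(loc.start + 1),
                    str(loc.end),
                    ".",
                    loc.strand,
                    ".",
                    f"ID={rec.hairpin_id};Name={rec.name}",
                ]
            )
        )
        for suffix, arm in (("5p", rec.arm5p), ("3p", rec.arm3p)):
            if arm is None:
                continue
            s, e = arm
            if loc.strand == "+":
                gs, ge = loc.start + s, loc.start + e
            else:
                gs, ge = loc.end - e, loc.end - s
            gff_lines.append(
                "\t".join(
                    [
                        loc.chrom,
                        "mirscreen",
                        "miRNA",
                        str(gs + 1),
                        str(ge),
                        ".",
                        loc.strand,
                        ".",
                        f"ID={rec.hairpin_id}-{suffix};Name={rec.name}-{suffix};"
                        f"Derives_from={rec.hairpin_id}",
                    ]
                )
            )
        fasta.write(f">{rec.hairpin_id}\n{rec.sequence}\n")
    return "\n".join(gff_lines) + "\n", fasta.getvalue()


def classify_hairpin_regions(h: HairpinRecord) -> RegionMap:
    """Label every hairpin position as stem5p, loop or stem3p.

    With both arms annotated, loop = positions strictly between the arms and
    flanking positions adopt the nearest arm's stem label.  With a single
    annotated arm the missing arm is taken as the mirror image of the
    annotated one about the sequence midpoint, and the loop is the interval
    strictly between the arm and its mirror (empty if they touch or cross).
    """
    n = len(h.sequence)
    if h.arm5p is None and h.arm3p is None:
        raise NoArmAnnotationError(
            f"hairpin {h.hairpin_id} has no annotated mature arm; exclude it"
        )
    if h.arm5p is not None and h.arm3p is not None:
        loop_start, loop_end = h.arm5p[1], h.arm3p[0]
    elif h.arm5p is not None:
        s, e = h.arm5p
        loop_start, loop_end = e, max(e, n - e)  # mirror of the arm end
    else:
        s, e = h.arm3p  # type: ignore[misc]
        loop_start, loop_end = min(s, n - s), s  # mirror of the arm start
        if loop_start > loop_end:
            loop_start = loop_end
    labels = [STEM5P] * loop_start + [LOOP] * (loop_end - loop_start) + [STEM3P] * (
        n - loop_end
    )
    return RegionMap(hairpin_id=h.hairpin_id, labels=tuple(labels))


def find_seed_matches(utr: str, mirna: str) -> list[SeedMatch]:
    """Scan a 3'UTR for canonical seed-complementary sites.

    The seed is miRNA positions 2-7 (position 1 = 5' nucleotide).  Site
    classes: 6mer = Watson-Crick complement of the seed; 7mer-m8 extends
    pairing to position 8; 7mer-A1 adds an adenosine opposite position 1
    (3' of the seed match on the UTR); 8mer has both.  Each seed-match locus
    is reported once, at its strongest class.  Positions containing N never
    match.
    """
    utr = utr.upper()
    m = as_dna(mirna)
    if len(m) < 8:
        raise ValueError(f"miRNA must be >= 8 nt, got {len(m)}")
    core = reverse_complement(m[1:7])  # pairs seed positions 2-7
    m8_base = reverse_complement(m[7])  # UTR base pairing miRNA position 8
    if "N" in core:
        return []
    out: list[SeedMatch] = []
    for i in range(len(utr) - 5):
        if utr[i : i + 6] != core:
            continue
        has_m8 = i > 0 and "N" not in m8_base and utr[i - 1] == m8_base
        has_a1 = i + 6 < len(utr) and utr[i + 6] == "A"
        if has_m8 and has_a1:
            out.append(SeedMatch("8mer", i - 1, utr[i - 1 : i + 7]))
        elif has_m8:
            out.append(SeedMatch("7mer-m8", i - 1, utr[i - 1 : i + 6]))
        elif has_a1:
            out.append(SeedMatch("7mer-A1", i, utr[i : i + 7]))
        else:
            out.append(SeedMatch("6mer", i, utr[i : i + 6]))
    return out


def seed_pairing_interval(site: SeedMatch) -> tuple[int, int]:
    """UTR interval whose bases pair miRNA seed positions 3-7 for this site."""
    start = site.utr_position + (1 if site.site_type in ("7mer-m8", "8mer") else 0)
    return start, start + 5


def mutate_seed_site(utr: str, site: SeedMatch, replacement: str) -> str:
    """Substitute the UTR bases pairing miRNA seed positions 3-7.

    ``replacement`` is given on the UTR strand (5'->3') and must have the
    same length as the replaced pentamer.  Everything outside the replaced
    interval is returned byte-identical.
    """
    start, end = seed_pairing_interval(site)
    if len(replacement) != end - start:
        raise ValueError(
            f"replacement length {len(replacement)} != replaced length {end - start}"
        )
    if end > len(utr) or start < 0:
        raise ValueError(f"replacement interval [{start}, {end}) runs past the UTR")
    return utr[:start] + as_dna(replacement) + utr[end:]


def region_maps_to_tsv(maps: Sequence[RegionMap]) -> str:
    """Long-format TSV of region segments: hairpin_id, start, end, label."""
    rows = [
        {"hairpin_id": rm.hairpin_id, "start": s, "end": e, "label": lab}
        for rm in maps
        for s, e, lab in rm.segments()
    ]
    return pd.DataFrame(rows, columns=["hairpin_id", "start", "end", "label"]).to_csv(
        sep="\t", index=False
    )


def seed_matches_to_tsv(utr_id: str, matches: Sequence[SeedMatch]) -> str:
    rows = [
        {
            "utr_id": utr_id,
            "offset": sm.utr_position,
            "site_type": sm.site_type,
            "matched_sequence": sm.matched_sequence,
        }
        for sm in matches
    ]
    return pd.DataFrame(
        rows, columns=["utr_id", "offset", "site_type", "matched_sequence"]
    ).to_csv(sep="\t", index=False)
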