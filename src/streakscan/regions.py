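"""Variant and sequence domain model.

This module holds the coordinate-carrying value types used throughout the
package (variants, variant streaks, sequence windows) together with the
readers and elementary operations that feed the screening pipeline:
loading variants from VCF, minor-allele-frequency filtering, flank
extraction around a SNP, allele substitution into a window, and grouping
of nearby SNPs into streaks.

Conventions
-----------
All genomic coordinates are 1-based and inclusive (the VCF convention);
``SequenceWindow.origin`` records the genomic position of the window's
first base so window offsets can always be mapped back. BED input, which
is 0-based half-open, is converted on read. Sequences are uppercased on
read; ``N`` bases are tolerated in genomes but windows containing ``N``
are excluded from scoring by the pipeline.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

from Bio import SeqIO

from .errors import BoundsError, ConsistencyError, OrderingError, ParseError

logger = logging.getLogger(__name__)

DNA_BASES = frozenset("ACGT")


@dataclass(frozen=True)
class GenomicRegion:
    """A closed 1-based genomic interval."""

    chrom: str
    start: int
    end: int
    assembly: str = ""

    def __post_init__(self) -> None:
        if self.start < 1:
            raise ValueError(f"start must be >= 1, got {self.start}")
        if self.end < self.start:
            raise ValueError(f"end ({self.end}) < start ({self.start})")

    def __len__(self) -> int:
        return self.end - self.start + 1


@dataclass(frozen=True)
class Variant:
    """One biallelic single-nucleotide substitution.

    ``maf`` is the minor allele frequency, folded into [0, 0.5]; the alt
    allele need not be the minor one.
    """

    id: str
    chrom: str
    pos: int
    ref: str
    alt: str
    maf: float

    def __post_init__(self) -> None:
        if self.ref not in DNA_BASES or self.alt not in DNA_BASES:
            raise ValueError(f"ref/alt must be single A/C/G/T bases, got {self.ref}/{self.alt}")
        if self.ref == self.alt:
            raise ValueError(f"ref and alt must differ at {self.chrom}:{self.pos}")
        if not 0.0 <= self.maf <= 0.5:
            raise ValueError(f"maf must lie in [0, 0.5], got {self.maf}")


@dataclass(frozen=True)
class SequenceWindow:
    """A DNA window with its genomic anchor.

    ``origin`` is the 1-based genomic position of ``sequence[0]``;
    ``allele_label`` records which allele the window carries at any
    substituted sites ("ref", "alt", or "other" for raw genome slices).
    """

    sequence: str
    origin: int
    allele_label: str = "other"

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError("window sequence must be nonempty")
        if self.sequence != self.sequence.upper():
            raise ValueError("window sequence must be uppercase")
        if self.allele_label not in ("ref", "alt", "other"):
            raise ValueError(f"bad allele_label {self.allele_label!r}")

    def __len__(self) -> int:
        return len(self.sequence)

    @property
    def end(self) -> int:
        return self.origin + len(self.sequence) - 1


@dataclass(frozen=True)
class VariantStreak:
    """A maximal run of nearby variants treated as one composite allele.

    ``wt_allele``/``mt_allele`` are the full reference-span strings with,
    respectively, all member reference or alternate bases installed; they
    differ exactly at the member offsets. Either may be ``None`` when no
    reference sequence was available to fill the gaps.
    """

    variants: tuple[Variant, ...]
    span: GenomicRegion
    wt_allele: str | None = None
    mt_allele: str | None = None

    def __post_init__(self) -> None:
        if not self.variants:
            raise ValueError("streak needs at least one member variant")
        positions = [v.pos for v in self.variants]
        if positions != sorted(set(positions)):
            raise ValueError("streak variants must have strictly increasing positions")
        if len({v.chrom for v in self.variants}) != 1:
            raise ValueError("streak variants must share a chromosome")
        if self.wt_allele is not None:
            n = len(self.span)
            if len(self.wt_allele) != n or len(self.mt_allele or "") != n:
                raise ValueError("allele strings must match the span length")
            diff = [i for i, (a, b) in enumerate(zip(self.wt_allele, self.mt_allele)) if a != b]
            member = [v.pos - self.span.start for v in self.variants]
            if diff != member:
                raise ValueError("wt/mt alleles must differ exactly at member offsets")

    def __len__(self) -> int:
        return len(self.variants)

    @property
    def member_offsets(self) -> list[int]:
        """0-based offsets of member variants within the span."""
        return [v.pos - self.span.start for v in self.variants]


# ---------------------------------------------------------------------------
# readers
# ---------------------------------------------------------------------------

def load_fasta(path: str | Path, name: str | None = None) -> str:
    """Read one sequence from a (multi-)FASTA file, uppercased.

    The first record is used unless ``name`` selects another by id.
    """
    path = Path(path)
    if not path.exists():
        raise IOError(f"FASTA file not found: {path}")
    for record in SeqIO.parse(str(path), "fasta"):
        if name is None or record.id == name:
            return str(record.seq).upper()
    if name is not None:
        raise ParseError(f"no record named {name!r} in {path}")
    raise ParseError(f"no FASTA records in {path}")


def load_variants(path: str | Path, af_key: str = "AF") -> list[Variant]:
    """Load biallelic SNPs from a VCF (v4.x, plain or bgzipped).

    The minor allele frequency is folded from the INFO ``af_key`` field:
    ``maf = min(AF, 1 - AF)``. Multi-allelic and indel records are skipped
    with a logged count.
    """
    from cyvcf2 import VCF

    path = Path(path)
    if not path.exists():
        raise IOError(f"VCF file not found: {path}")
    variants: list[Variant] = []
    n_skipped = 0
    for rec in VCF(str(path)):
        if rec.POS is None:
            raise ParseError(f"VCF record without position in {path}")
        alts = rec.ALT
        if len(alts) != 1 or len(rec.REF) != 1 or len(alts[0]) != 1:
            n_skipped += 1
            continue
        ref, alt = rec.REF.upper(), alts[0].upper()
        if ref not in DNA_BASES or alt not in DNA_BASES:
            n_skipped += 1
            continue
        af = rec.INFO.get(af_key)
        if af is None:
            raise ParseError(
                f"record {rec.CHROM}:{rec.POS} lacks INFO field {af_key!r}"
            )
        af = float(af)
        variants.append(
            Variant(
                id=rec.ID or f"{rec.CHROM}:{rec.POS}",
                chrom=rec.CHROM,
                pos=rec.POS,
                ref=ref,
                alt=alt,
                maf=min(af, 1.0 - af),
            )
        )
    if n_skipped:
        logger.info("skipped %d multi-allelic/indel records in %s", n_skipped, path)
    variants.sort(key=lambda v: (v.chrom, v.pos))
    return variants


def load_bed_regions(path: str | Path) -> list[GenomicRegion]:
    """Read BED intervals (0-based half-open) as 1-based inclusive regions."""
    regions = []
    for i, line in enumerate(Path(path).read_text().splitlines(), start=1):
        line = line.strip()
        if not line or line.startswith(("#", "track", "browser")):
            continue
        parts = line.split("\t")
        if len(parts) < 3:
            raise ParseError(f"BED line {i} has fewer than 3 columns")
        chrom, start0, end0 = parts[0], int(parts[1]), int(parts[2])
        regions.append(GenomicRegion(chrom=chrom, start=start0 + 1, end=end0))
    return regions


# ---------------------------------------------------------------------------
# operations
# ---------------------------------------------------------------------------

def filter_common(variants: Iterable[Variant], maf_min: float) -> list[Variant]:
    """Keep variants with MAF strictly greater than ``maf_min`` (order kept)."""
    if not 0.0 <= maf_min <= 0.5:
        raise ValueError(f"maf_min must lie in [0, 0.5], got {maf_min}")
    return [v for v in variants if v.maf > maf_min]


def extract_window(genome: str, pos: int, flank: int) -> SequenceWindow:
    """Extract the window of ``flank`` bases either side of ``pos``.

    The window is ``[max(1, pos - flank), min(L, pos + flank)]`` in 1-based
    coordinates — 2*flank + 1 bases long unless truncated at an edge.
    """
    L = len(genome)
    if not 1 <= pos <= L:
        raise BoundsError(f"position {pos} outside sequence of length {L}")
    if flank < 0:
        raise ValueError("flank must be nonnegative")
    start = max(1, pos - flank)
    end = min(L, pos + flank)
    return SequenceWindow(sequence=genome[start - 1 : end], origin=start)


def substitute_alleles(
    window: SequenceWindow,
    variants: Sequence[Variant],
    choice: str,
) -> SequenceWindow:
    """Return a copy of ``window`` with the chosen allele at each variant.

    When installing alt alleles into a reference-derived window, the
    current base at each variant offset must equal the variant's declared
    reference base; a mismatch raises :class:`ConsistencyError` naming the
    position.
    """
    if choice not in ("ref", "alt"):
        raise ValueError(f"choice must be 'ref' or 'alt', got {choice!r}")
    seq = list(window.sequence)
    for v in variants:
        off = v.pos - window.origin
        if not 0 <= off < len(seq):
            raise BoundsError(
                f"variant {v.id} at {v.pos} outside window "
                f"[{window.origin}, {window.end}]"
            )
        current = seq[off]
        if current not in (v.ref, v.alt):
            raise ConsistencyError(
                f"window base {current!r} at position {v.pos} matches neither "
                f"ref {v.ref!r} nor alt {v.alt!r} of {v.id}"
            )
        seq[off] = v.ref if choice == "ref" else v.alt
    return SequenceWindow(
        sequence="".join(seq), origin=window.origin, allele_label=choice
    )


def group_streaks(
    variants: Sequence[Variant],
    max_gap: int,
    genome: str | None = None,
) -> list[VariantStreak]:
    """Partition position-sorted variants into maximal streaks.

    Consecutive variants whose positions differ by at most ``max_gap``
    fall in the same streak. When ``genome`` (the full reference, 1-based)
    is supplied, each streak carries composite wild-type and mutant allele
    strings over its span; otherwise the allele strings are ``None``.
    """
    if max_gap < 0:
        raise ValueError("max_gap must be nonnegative")
    vs = list(variants)
    if not vs:
        return []
    for a, b in zip(vs, vs[1:]):
        if a.chrom != b.chrom:
            raise OrderingError("streak grouping requires a single chromosome")
        if b.pos <= a.pos:
            raise OrderingError(
                f"variants not sorted by position: {a.pos} then {b.pos}"
            )
    runs: list[list[Variant]] = [[vs[0]]]
    for v in vs[1:]:
        if v.pos - runs[-1][-1].pos <= max_gap:
            runs[-1].append(v)
        else:
            runs.append([v])
    streaks = []
    for run in runs:
        span = GenomicRegion(chrom=run[0].chrom, start=run[0].pos, end=run[-1].pos)
        wt = mt = None
        if genome is not None:
            if span.end > len(genome):
                raise BoundsError(
                    f"streak span end {span.end} beyond genome length {len(genome)}"
                )
            segment = genome[span.start - 1 : span.end]
            wt_l, mt_l = list(segment), list(segment)
            for v in run:
                off = v.pos - span.start
                if segment[off] != v.ref:
                    raise ConsistencyError(
                        f"reference base {segment[off]!r} at {v.pos} does not "
                        f"match declared ref {v.ref!r} of {v.id}"
                    )
                wt_l[off] = v.ref
                mt_l[off] = v.alt
            wt, mt = "".join(wt_l), "".join(mt_l)
        streaks.append(
            VariantStreak(variants=tuple(run), span=span, wt_allele=wt, mt_allele=mt)
        )
    return streaks
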