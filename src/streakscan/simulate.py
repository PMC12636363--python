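"""Synthetic inputs with the statistical structure the screen assumes.

The generators emulate the study geometry end to end: a ~5 kb promoter
segment carrying a planted wild-type streak string (a tandem-motif
repeat), a panel of ~27 common biallelic SNPs (MAF ~ 0.27) of which five
are the C->A members of the streak, Hardy–Weinberg case-control genotype
counts at a chosen allelic odds ratio, and dosage vectors for a pair of
markers at a chosen LD level. Every generator is deterministic per seed
and records its ground truth in a :class:`SyntheticTruth` sidecar.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from .association import GenotypeCounts
from .regions import Variant

logger = logging.getLogger(__name__)

#: the wild-type (5C) streak allele: four AAC repeats, an A6 tract, AAC, AA
WT_STREAK = "AACAACAACAACAAAAAAACAACAA"
#: the mutant (5A) streak allele: every variable C replaced by A
MT_STREAK = "AAAAAAAAAAAAAAAAAAAAAACAA"
#: 0-based offsets of the five C->A SNPs within the streak string
STREAK_SNP_OFFSETS = tuple(
    i for i, (a, b) in enumerate(zip(WT_STREAK, MT_STREAK)) if a != b
)

DEFAULT_REGION_LENGTH = 5196
DEFAULT_N_SNPS = 27
DEFAULT_MAF = 0.273
DEFAULT_CHROM = "chr10"


@dataclass(frozen=True)
class SyntheticTruth:
    """Ground truth recorded alongside every generated dataset."""

    seed: int
    kind: str
    streak_position: int | None = None
    streak_member_positions: tuple[int, ...] = ()
    planted_motif_id: str | None = None
    true_odds_ratio: float | None = None
    true_ctrl_alt_freq: float | None = None
    true_case_alt_freq: float | None = None
    true_r2: float | None = None
    extra: dict = field(default_factory=dict)

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(
            json.dumps(dataclasses.asdict(self), indent=2, default=list) + "\n"
        )


def write_fasta(path: str | Path, seq: str, name: str = DEFAULT_CHROM) -> None:
    with open(path, "w") as fh:
        fh.write(f">{name}\n")
        for i in range(0, len(seq), 70):
            fh.write(seq[i : i + 70] + "\n")


def write_vcf(
    path: str | Path,
    variants: Sequence[Variant],
    contig: str = DEFAULT_CHROM,
    contig_length: int | None = None,
) -> None:
    """Write biallelic SNPs as a minimal VCF v4.2 with AF INFO fields."""
    lines = [
        "##fileformat=VCFv4.2",
        '##INFO=<ID=AF,Number=A,Type=Float,Description="Allele Frequency">',
    ]
    if contig_length is not None:
        lines.append(f"##contig=<ID={contig},length={contig_length}>")
    else:
        lines.append(f"##contig=<ID={contig}>")
    lines.append("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO")
    for v in sorted(variants, key=lambda x: x.pos):
        lines.append(
            f"{v.chrom}\t{v.pos}\t{v.id}\t{v.ref}\t{v.alt}\t.\t.\tAF={v.maf:.6g}"
        )
    Path(path).write_text("\n".join(lines) + "\n")


def make_reference(
    length: int = DEFAULT_REGION_LENGTH,
    seed: int = 0,
    streak_position: int | None = None,
    streak_wt: str = WT_STREAK,
    base_probs: Sequence[float] = (0.25, 0.25, 0.25, 0.25),
) -> tuple[str, SyntheticTruth]:
    """An i.i.d. background sequence with the wild-type streak planted.

    ``streak_position`` is the 1-based position of the streak's first
    base; ``None`` plants it ~600 bp before the region end (emulating a
    promoter-proximal block), and a negative value omits it entirely.
    """
    rng = np.random.default_rng(seed)
    probs = np.asarray(base_probs, dtype=float)
    probs = probs / probs.sum()
    seq = rng.choice(list("ACGT"), size=length, p=probs)
    if streak_position is None:
        streak_position = length - 600 - len(streak_wt) + 1
    member_positions: tuple[int, ...] = ()
    if streak_position >= 1:
        if streak_position + len(streak_wt) - 1 > length:
            raise ValueError("streak does not fit inside the reference")
        seq[streak_position - 1 : streak_position - 1 + len(streak_wt)] = list(
            streak_wt
        )
        member_positions = tuple(
            streak_position + off for off in STREAK_SNP_OFFSETS
        )
    truth = SyntheticTruth(
        seed=seed,
        kind="reference",
        streak_position=streak_position if streak_position >= 1 else None,
        streak_member_positions=member_positions,
    )
    return "".join(seq), truth


def make_panel(
    reference: str,
    seed: int = 0,
    n_snps: int = DEFAULT_N_SNPS,
    maf: float | Sequence[float] = DEFAULT_MAF,
    streak_member_positions: Sequence[int] = (),
    chrom: str = DEFAULT_CHROM,
    min_spacing: int = 50,
) -> tuple[list[Variant], SyntheticTruth]:
    """A biallelic SNP panel over ``reference``.

    The streak member positions become C->A SNPs (their reference bases
    must be C); the remaining ``n_snps - len(members)`` background SNPs
    fall at random positions with a random non-reference alt, kept at
    least ``min_spacing`` bases from every other SNP so the planted
    streak is the panel's only tightly clustered run. ``maf`` may be a
    scalar (all SNPs) or one value per SNP.
    """
    rng = np.random.default_rng(seed)
    members = sorted(int(p) for p in streak_member_positions)
    if len(members) > n_snps:
        raise ValueError("more streak members than total SNPs requested")
    mafs = (
        list(np.broadcast_to(np.asarray(maf, dtype=float), (n_snps,)))
        if np.ndim(maf) == 0
        else [float(x) for x in maf]
    )
    if len(mafs) != n_snps:
        raise ValueError(f"need {n_snps} MAF values, got {len(mafs)}")

    variants: list[Variant] = []
    taken = set(members)
    for i, pos in enumerate(members):
        ref = reference[pos - 1]
        if ref != "C":
            raise ValueError(f"streak member at {pos} has reference {ref!r}, not C")
        variants.append(
            Variant(id=f"streak_snp_{i + 1}", chrom=chrom, pos=pos, ref="C",
                    alt="A", maf=mafs[i])
        )
    n_background = n_snps - len(members)
    i_bg = 0
    attempts = 0
    while i_bg < n_background:
        attempts += 1
        if attempts > 10_000 * n_snps:
            raise ValueError("cannot place background SNPs with the requested spacing")
        pos = int(rng.integers(1, len(reference) + 1))
        if taken and min(abs(pos - t) for t in taken) < min_spacing:
            continue
        ref = reference[pos - 1]
        if ref not in "ACGT":
            continue
        alt = str(rng.choice([b for b in "ACGT" if b != ref]))
        taken.add(pos)
        variants.append(
            Variant(id=f"bg_snp_{i_bg + 1}", chrom=chrom, pos=pos, ref=ref,
                    alt=alt, maf=mafs[len(members) + i_bg])
        )
        i_bg += 1
    variants.sort(key=lambda v: v.pos)
    truth = SyntheticTruth(
        seed=seed,
        kind="panel",
        streak_member_positions=tuple(members),
        extra={"n_snps": n_snps},
    )
    return variants, truth


def planted_screen_inputs(
    seed: int,
    n_decoys: int = 2,
    length: int = DEFAULT_REGION_LENGTH,
    n_snps: int = DEFAULT_N_SNPS,
    consensus: str = "AA/CAACAAA/C",
) -> tuple[str, list[Variant], list, SyntheticTruth]:
    """Reference + panel + motif library for one end-to-end screen trial.

    The library holds one PFM derived from the planted consensus and
    ``n_decoys`` random PFMs of the same width; the returned truth names
    the planted motif and the streak member positions.
    """
    from .motifs import MotifModel, consensus_to_pfm, parse_consensus

    reference, ref_truth = make_reference(length=length, seed=seed)
    variants, _ = make_panel(
        reference, seed=seed, n_snps=n_snps,
        streak_member_positions=ref_truth.streak_member_positions,
    )
    pattern = parse_consensus(consensus)
    planted = MotifModel(id="planted_consensus", pfm=consensus_to_pfm(pattern))
    rng = np.random.default_rng(np.random.SeedSequence((seed, 104729)))
    library = [planted] + [
        MotifModel(
            id=f"decoy_{i}",
            pfm=rng.integers(1, 30, size=(pattern.width, 4)).astype(float),
        )
        for i in range(n_decoys)
    ]
    truth = SyntheticTruth(
        seed=seed,
        kind="planted_screen",
        streak_position=ref_truth.streak_position,
        streak_member_positions=ref_truth.streak_member_positions,
        planted_motif_id="planted_consensus",
    )
    return reference, variants, library, truth


def simulate_case_control(
    n_cases: int,
    n_controls: int,
    ctrl_alt_freq: float,
    odds_ratio: float,
    seed: int = 0,
) -> tuple[GenotypeCounts, GenotypeCounts, SyntheticTruth]:
    """Hardy–Weinberg genotypes in two groups at a chosen allelic OR.

    The case allele frequency solves
    ``odds(q_case) = OR * odds(ctrl_alt_freq)``; genotypes are binomial
    draws of two allele copies per individual within each group.
    """
    if not 0.0 < ctrl_alt_freq < 1.0:
        raise ValueError("ctrl_alt_freq must lie in (0, 1)")
    if odds_ratio <= 0:
        raise ValueError("odds_ratio must be positive")
    odds_case = odds_ratio * ctrl_alt_freq / (1.0 - ctrl_alt_freq)
    q_case = odds_case / (1.0 + odds_case)
    rng = np.random.default_rng(seed)

    def _draw(n: int, q: float, label: str) -> GenotypeCounts:
        dosages = rng.binomial(2, q, size=n)
        return GenotypeCounts(
            hom_ref=int((dosages == 0).sum()),
            het=int((dosages == 1).sum()),
            hom_alt=int((dosages == 2).sum()),
            group_label=label,
        )

    cases = _draw(n_cases, q_case, "cases")
    controls = _draw(n_controls, ctrl_alt_freq, "controls")
    truth = SyntheticTruth(
        seed=seed,
        kind="case_control",
        true_odds_ratio=odds_ratio,
        true_ctrl_alt_freq=ctrl_alt_freq,
        true_case_alt_freq=q_case,
    )
    return cases, controls, truth


def simulate_ld_genotypes(
    n: int,
    maf: float,
    concordance: float,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray, SyntheticTruth]:
    """Dosage vectors for two markers at haplotype concordance ``c``.

    Each individual carries two haplotypes; marker B's allele copies
    marker A's with probability ``c`` and is otherwise redrawn at ``maf``,
    giving expected dosage correlation ``c`` and r^2 = c^2.
    """
    if not 0.0 <= concordance <= 1.0:
        raise ValueError("concordance must lie in [0, 1]")
    if not 0.0 < maf < 1.0:
        raise ValueError("maf must lie in (0, 1)")
    rng = np.random.default_rng(seed)
    hap_a = rng.random((n, 2)) < maf
    copy = rng.random((n, 2)) < concordance
    fresh = rng.random((n, 2)) < maf
    hap_b = np.where(copy, hap_a, fresh)
    truth = SyntheticTruth(
        seed=seed,
        kind="ld_pair",
        true_r2=concordance**2,
        extra={"maf": maf, "concordance": concordance},
    )
    return hap_a.sum(axis=1).astype(int), hap_b.sum(axis=1).astype(int), truth
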