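"""Case-control association statistics and in-silico genotyping.

Implements the allele-level 2x2 analysis used for candidate regulatory
haplotypes: allele tabulation from genotype counts, the allelic odds
ratio with its Woolf (log-normal) 95% confidence interval, the Pearson
chi-square test, and composite linkage-disequilibrium r^2 from genotype
dosages. Also provides the two genotyping utilities the wet-lab designs
rely on: restriction-digest fragment prediction (RFLP) and streak-allele
calling from bidirectional Sanger-style reads with IUPAC ambiguity codes.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .errors import AmbiguityError, LocateError, UndefinedStatisticError
from .motifs import IUPAC_CODES, reverse_complement
from .regions import VariantStreak

logger = logging.getLogger(__name__)

Z_95 = 1.959963984540054  # two-sided 95% normal quantile


@dataclass(frozen=True)
class GenotypeCounts:
    """Genotype tallies for one group (e.g. controls or one case arm)."""

    hom_ref: int
    het: int
    hom_alt: int
    group_label: str = ""

    def __post_init__(self) -> None:
        if min(self.hom_ref, self.het, self.hom_alt) < 0:
            raise ValueError("genotype counts must be nonnegative")

    @property
    def n(self) -> int:
        return self.hom_ref + self.het + self.hom_alt


@dataclass(frozen=True)
class Allele2x2:
    """Allele-count contingency table, cases vs controls."""

    case_alt: int
    case_ref: int
    ctrl_alt: int
    ctrl_ref: int

    def __post_init__(self) -> None:
        if min(self.case_alt, self.case_ref, self.ctrl_alt, self.ctrl_ref) < 0:
            raise ValueError("allele counts must be nonnegative")

    @property
    def cells(self) -> tuple[int, int, int, int]:
        return (self.case_alt, self.case_ref, self.ctrl_alt, self.ctrl_ref)


@dataclass(frozen=True)
class AssociationResult:
    odds_ratio: float
    ci_low: float
    ci_high: float
    chi2_stat: float | None = None
    pvalue: float | None = None
    corrected: bool = False  # Haldane–Anscombe 0.5 applied

    def __post_init__(self) -> None:
        if not self.ci_low <= self.odds_ratio <= self.ci_high:
            raise ValueError("CI must bracket the odds ratio")


def tabulate_alleles(g: GenotypeCounts) -> tuple[int, int]:
    """Fold genotype counts to (ref, alt) allele counts.

    Each homozygote contributes two copies of its allele and each
    heterozygote one of each, so ref + alt = 2 * sample size.
    """
    ref = 2 * g.hom_ref + g.het
    alt = 2 * g.hom_alt + g.het
    return ref, alt


def allelic_or(t: Allele2x2) -> AssociationResult:
    """Allelic odds ratio with Woolf 95% CI.

    ``OR = (case_alt * ctrl_ref) / (case_ref * ctrl_alt)``;
    ``CI = exp(ln OR +- 1.96 * sqrt(sum 1/cell))``. A zero cell triggers
    the Haldane–Anscombe 0.5 correction on all four cells, recorded in
    ``corrected``.
    """
    a, b, c, d = (float(x) for x in t.cells)
    corrected = False
    if min(a, b, c, d) == 0:
        a, b, c, d = a + 0.5, b + 0.5, c + 0.5, d + 0.5
        corrected = True
        logger.info("zero cell in 2x2 table: Haldane–Anscombe 0.5 applied")
    or_ = (a * d) / (b * c)
    se = math.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
    log_or = math.log(or_)
    return AssociationResult(
        odds_ratio=or_,
        ci_low=math.exp(log_or - Z_95 * se),
        ci_high=math.exp(log_or + Z_95 * se),
        corrected=corrected,
    )


def allelic_chi2(t: Allele2x2, correction: bool = False) -> tuple[float, float]:
    """Pearson chi-square (1 df) on the allele table; continuity
    correction off by default."""
    table = np.array([[t.case_alt, t.case_ref], [t.ctrl_alt, t.ctrl_ref]], dtype=float)
    if (table.sum(axis=0) == 0).any() or (table.sum(axis=1) == 0).any():
        raise UndefinedStatisticError("chi-square undefined: zero margin")
    res = stats.chi2_contingency(table, correction=correction)
    return float(res.statistic), float(res.pvalue)


def fisher_exact_pvalue(t: Allele2x2) -> float:
    """Two-sided Fisher exact p-value on the allele table."""
    table = [[t.case_alt, t.case_ref], [t.ctrl_alt, t.ctrl_ref]]
    return float(stats.fisher_exact(table).pvalue)


def associate(t: Allele2x2, fisher: bool = False) -> AssociationResult:
    """Odds ratio, Woolf CI and test p-value in one result."""
    base = allelic_or(t)
    if fisher:
        p = fisher_exact_pvalue(t)
        stat = math.nan
    else:
        stat, p = allelic_chi2(t)
    return AssociationResult(
        odds_ratio=base.odds_ratio,
        ci_low=base.ci_low,
        ci_high=base.ci_high,
        chi2_stat=stat,
        pvalue=p,
        corrected=base.corrected,
    )


def ld_r2(dosages_a, dosages_b) -> float:
    """Composite LD r^2: squared Pearson correlation of genotype dosages.

    Appropriate for unphased data; equals haplotype r^2 under random
    mating. Both vectors must be nonconstant and of equal length >= 2.
    """
    a = np.asarray(dosages_a, dtype=float)
    b = np.asarray(dosages_b, dtype=float)
    if a.shape != b.shape or a.ndim != 1 or len(a) < 2:
        raise ValueError("dosage vectors must be 1-D, equal length >= 2")
    if np.ptp(a) == 0 or np.ptp(b) == 0:
        raise UndefinedStatisticError("LD undefined for a constant dosage vector")
    r = np.corrcoef(a, b)[0, 1]
    return float(r * r)


# ---------------------------------------------------------------------------
# in-silico genotyping
# ---------------------------------------------------------------------------

def restriction_digest(seq: str, site: str, cut_offset: int) -> list[int]:
    """Fragment lengths after cutting every occurrence of ``site``.

    The cut falls after ``cut_offset`` bases of the recognition site
    (e.g. CAG^CTG is ``cut_offset=3``). Overlapping site occurrences make
    the cut order ambiguous and raise :class:`AmbiguityError`. A
    site-free sequence returns one fragment, the whole length.
    """
    seq, site = seq.upper(), site.upper()
    if not 0 <= cut_offset <= len(site):
        raise ValueError("cut_offset must lie within the recognition site")
    starts = []
    i = seq.find(site)
    while i != -1:
        starts.append(i)
        i = seq.find(site, i + 1)
    for s1, s2 in zip(starts, starts[1:]):
        if s2 - s1 < len(site):
            raise AmbiguityError(
                f"overlapping {site} occurrences at {s1 + 1} and {s2 + 1}"
            )
    cuts = [s + cut_offset for s in starts]
    bounds = [0, *cuts, len(seq)]
    return [b - a for a, b in zip(bounds, bounds[1:]) if b > a]


def _iupac_compatible(read_base: str, allowed: frozenset[str]) -> bool:
    read_set = IUPAC_CODES.get(read_base)
    return read_set is not None and read_set <= allowed


def _locate_span(read: str, streak: VariantStreak) -> int:
    """0-based offset of the unique streak-span alignment in a read.

    Non-member positions must match the wild-type base exactly; member
    positions may carry either allele or their two-allele IUPAC code.
    """
    wt, mt = streak.wt_allele, streak.mt_allele
    member = set(streak.member_offsets)
    allowed = [
        frozenset({wt[i], mt[i]}) if i in member else frozenset({wt[i]})
        for i in range(len(wt))
    ]
    matches = [
        start
        for start in range(len(read) - len(wt) + 1)
        if all(_iupac_compatible(read[start + i], allowed[i]) for i in range(len(wt)))
    ]
    if len(matches) != 1:
        raise LocateError(
            f"streak span aligned {len(matches)} times in read (need exactly 1)"
        )
    return matches[0]


def _call_one_read(read: str, streak: VariantStreak) -> str:
    start = _locate_span(read.upper(), streak)
    wt, mt = streak.wt_allele, streak.mt_allele
    calls = []
    for off in streak.member_offsets:
        base = read.upper()[start + off]
        het_code = next(
            (c for c, s in IUPAC_CODES.items() if s == frozenset({wt[off], mt[off]})),
        )
        if base == wt[off]:
            calls.append("wt")
        elif base == mt[off]:
            calls.append("mt")
        elif base == het_code:
            calls.append("het")
        else:
            calls.append("?")
    if all(c == "wt" for c in calls):
        return "hom_wt"
    if all(c == "mt" for c in calls):
        return "hom_mt"
    if all(c == "het" for c in calls):
        return "het"
    return "no_call"


def call_streak_genotype(
    fwd_read: str, rev_read: str, streak: VariantStreak
) -> str:
    """Genotype a streak from bidirectional reads.

    Each read must contain exactly one alignment of the streak span (the
    reverse read is reverse-complemented first); heterozygotes show the
    two-allele IUPAC code (M for C/A) at every member position. The two
    reads must agree, otherwise ``no_call``.
    """
    if streak.wt_allele is None or streak.mt_allele is None:
        raise ValueError("streak must carry wt/mt allele strings")
    fwd_call = _call_one_read(fwd_read, streak)
    rev_call = _call_one_read(reverse_complement(rev_read.upper()), streak)
    if fwd_call == rev_call and fwd_call != "no_call":
        return fwd_call
    return "no_call"
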