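"""The allele-specific binding-disruption screen.

For each common SNP the pipeline extracts a flanking window from the
reference, scans it against the motif library with exact-p-value PWM
matching, Benjamini–Hochberg-adjusts the match p-values within the
configured family, computes biophysical (TRAP-style) affinities of the
reference and alternate windows, and flags motifs whose binding is both
present (match + affinity significance) and allele-dependent. Motifs are
then ranked by recurrence — the number of screened SNPs at which they are
flagged.

SNPs grouped into a streak (consecutive positions within ``streak_max_gap``)
are treated as one composite allele: the alternate window of a streak
member carries the alternate bases of *all* members that fall inside the
window, mirroring how a tightly linked haplotype block segregates.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd

from .motifs import (
    ConsensusPattern,
    MotifModel,
    bh_adjust,
    pfm_to_pwm,
    scan_consensus,
    scan_pwm,
    sequence_background,
)
from .regions import (
    SequenceWindow,
    Variant,
    extract_window,
    filter_common,
    group_streaks,
    substitute_alleles,
)
from .trap import (
    DifferentialConfig,
    TrapParams,
    decide_differential,
    pfm_to_energy,
    sample_background_affinities,
    sequence_affinity,
)

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ScreenConfig:
    """Tunable thresholds and policies of the screen.

    Defaults follow the screening design: common variants are MAF > 0.1,
    windows are 30 bp per side of the SNP, motif matches must survive a
    BH-adjusted p <= 1e-3, and affinities must beat an empirical
    background p < 1e-4.
    """

    maf_min: float = 0.1
    flank: int = 30
    match_adj_p: float = 1e-3
    affinity_p: float = 1e-4
    bh_family: str = "per_snp"  # or "global"
    consensus_strands: str = "forward"
    pwm_strands: str = "both"
    trap: TrapParams = field(default_factory=TrapParams)
    pwm_pseudocount: float = 0.8
    energy_pseudocount: float = 1.0
    granularity: float = 1e-3
    background_floor: float = 0.01
    n_null: int = 20_000
    log2_ratio_min: float = 1.0
    streak_max_gap: int = 10
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("match_adj_p", "affinity_p"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {v}")
        if self.bh_family not in ("per_snp", "global"):
            raise ValueError(f"bh_family must be per_snp or global, got {self.bh_family!r}")

    def config_hash(self) -> str:
        payload = {k: (asdict(v) if hasattr(v, "__dataclass_fields__") else v)
                   for k, v in asdict(self).items()}
        return hashlib.sha256(
            json.dumps(payload, sort_keys=True, default=str).encode()
        ).hexdigest()[:12]


@dataclass(frozen=True)
class CandidateRecord:
    """One SNP x motif screen result (the full grid is emitted, with the
    per-criterion outcomes as columns, not only the survivors)."""

    snp_id: str
    motif_id: str
    match_p: float
    match_adj_p: float
    affinity_ref: float
    affinity_alt: float
    affinity_p_ref: float
    affinity_p_alt: float
    log2_ratio: float
    match_ok: bool
    differential_ok: bool
    flagged: bool


@dataclass(frozen=True)
class MotifRanking:
    motif_id: str
    recurrence: int
    mean_abs_log2_ratio: float


@dataclass(frozen=True)
class ClusterReport:
    """Tandem-motif content of one window."""

    span_start: int
    span_end: int
    hit_count: int
    hit_starts: tuple[int, ...]
    is_cluster: bool


def run_screen(
    genome: str,
    variants: Sequence[Variant],
    motif_library: Sequence[MotifModel],
    cfg: ScreenConfig | None = None,
) -> list[CandidateRecord]:
    """Screen every common SNP against every motif.

    Returns one :class:`CandidateRecord` per (SNP, motif) pair — flagged
    or not — deterministic for a fixed ``cfg`` (including ``cfg.seed``).
    """
    cfg = cfg or ScreenConfig()
    common = filter_common(variants, cfg.maf_min)
    if not common:
        logger.info("no variants pass the MAF > %s filter; empty screen", cfg.maf_min)
        return []
    widths = [m.width for m in motif_library]
    if widths and cfg.flank < max(widths):
        logger.warning(
            "flank %d smaller than the widest motif (%d); hits may be missed",
            cfg.flank, max(widths),
        )

    streaks = group_streaks(common, cfg.streak_max_gap, genome)
    joint_members: dict[str, tuple[Variant, ...]] = {}
    for st in streaks:
        for v in st.variants:
            joint_members[v.id] = st.variants

    records: list[CandidateRecord] = []
    raw_match_p: list[float] = []  # parallel to records, for BH
    for i_snp, snp in enumerate(common):
        ref_win = extract_window(genome, snp.pos, cfg.flank)
        if "N" in ref_win.sequence:
            logger.warning("window at %s contains N; skipped", snp.id)
            continue
        members = [
            v for v in joint_members.get(snp.id, (snp,))
            if ref_win.origin <= v.pos <= ref_win.end
        ]
        ref_win = substitute_alleles(ref_win, members, "ref")
        alt_win = substitute_alleles(ref_win, members, "alt")
        bg = sequence_background(ref_win.sequence, floor=cfg.background_floor)

        for i_motif, motif in enumerate(motif_library):
            pwm = pfm_to_pwm(motif, background=bg, pseudocount=cfg.pwm_pseudocount)
            hits = scan_pwm(
                ref_win.sequence, pwm, p_threshold=1.0,
                strands=cfg.pwm_strands, granularity=cfg.granularity,
            )
            match_p = min((h.pvalue for h in hits), default=1.0)

            e = pfm_to_energy(motif, cfg.trap, pseudocount=cfg.energy_pseudocount)
            a_ref = sequence_affinity(e, ref_win.sequence).affinity
            a_alt = sequence_affinity(e, alt_win.sequence).affinity
            child = np.random.SeedSequence(
                entropy=(cfg.seed, i_snp, i_motif)
            )
            null = sample_background_affinities(
                e, bg, len(ref_win), cfg.n_null, np.random.default_rng(child)
            )
            p_ref = float((1 + (null >= a_ref).sum()) / (cfg.n_null + 1))
            p_alt = float((1 + (null >= a_alt).sum()) / (cfg.n_null + 1))
            log2_ratio = float(np.log2((a_alt + 1e-9) / (a_ref + 1e-9)))
            diff_ok = decide_differential(
                p_ref, p_alt, log2_ratio,
                DifferentialConfig(
                    affinity_p=cfg.affinity_p, log2_ratio_min=cfg.log2_ratio_min
                ),
            )
            records.append(
                CandidateRecord(
                    snp_id=snp.id,
                    motif_id=motif.id,
                    match_p=match_p,
                    match_adj_p=1.0,  # filled after BH
                    affinity_ref=a_ref,
                    affinity_alt=a_alt,
                    affinity_p_ref=p_ref,
                    affinity_p_alt=p_alt,
                    log2_ratio=log2_ratio,
                    match_ok=False,
                    differential_ok=diff_ok,
                    flagged=False,
                )
            )
            raw_match_p.append(match_p)

    return _apply_bh(records, raw_match_p, cfg)


def _apply_bh(
    records: list[CandidateRecord], raw_p: list[float], cfg: ScreenConfig
) -> list[CandidateRecord]:
    """Fill BH-adjusted match p-values and the final flags."""
    if not records:
        return records
    if cfg.bh_family == "global":
        groups = {None: list(range(len(records)))}
    else:
        groups = {}
        for i, r in enumerate(records):
            groups.setdefault(r.snp_id, []).append(i)
    adjusted = [1.0] * len(records)
    for idx in groups.values():
        adj = bh_adjust([raw_p[i] for i in idx])
        for i, p in zip(idx, adj):
            adjusted[i] = p
    out = []
    for r, adj in zip(records, adjusted):
        match_ok = adj <= cfg.match_adj_p
        out.append(
            replace(
                r,
                match_adj_p=adj,
                match_ok=match_ok,
                flagged=match_ok and r.differential_ok,
            )
        )
    return out


def rank_motifs(records: Sequence[CandidateRecord]) -> list[MotifRanking]:
    """Rank motifs by recurrence (number of SNPs flagged), then mean
    |log2 ratio| over their records, then id."""
    by_motif: dict[str, list[CandidateRecord]] = {}
    for r in records:
        by_motif.setdefault(r.motif_id, []).append(r)
    rankings = []
    for motif_id, recs in by_motif.items():
        recurrence = len({r.snp_id for r in recs if r.flagged})
        ratios = [abs(r.log2_ratio) for r in recs]
        rankings.append(
            MotifRanking(
                motif_id=motif_id,
                recurrence=recurrence,
                mean_abs_log2_ratio=float(np.mean(ratios)) if ratios else 0.0,
            )
        )
    rankings.sort(key=lambda m: (-m.recurrence, -m.mean_abs_log2_ratio, m.motif_id))
    return rankings


def detect_cluster(
    window: SequenceWindow,
    pattern: ConsensusPattern,
    min_count: int,
    strands: str = "forward",
) -> ClusterReport:
    """Count (overlapping) consensus occurrences in a window and decide
    whether they form a tandem cluster (``count >= min_count``)."""
    if min_count < 1:
        raise ValueError("min_count must be >= 1")
    hits = scan_consensus(window.sequence, pattern, strands=strands)
    starts = tuple(h.start for h in hits)
    return ClusterReport(
        span_start=window.origin,
        span_end=window.end,
        hit_count=len(starts),
        hit_starts=starts,
        is_cluster=len(starts) >= min_count,
    )


def records_to_frame(records: Sequence[CandidateRecord]) -> pd.DataFrame:
    """Tabulate screen records (one row per SNP x motif)."""
    return pd.DataFrame([asdict(r) for r in records])


def write_records_tsv(
    records: Sequence[CandidateRecord], path, cfg: ScreenConfig
) -> None:
    """Write the screen grid as TSV with a provenance header line."""
    from . import __version__

    with open(path, "w") as fh:
        fh.write(
            f"# streakscan {__version__} config={cfg.config_hash()} seed={cfg.seed}\n"
        )
        records_to_frame(records).to_csv(fh, sep="\t", index=False)
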