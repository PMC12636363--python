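"""Motif representations and scanning.

Two motif dialects are supported: IUPAC consensus patterns (including the
slash-degenerate notation used in the literature, e.g. ``AA/CAACAAA/C``)
and JASPAR-format position frequency matrices. PFMs convert to log-odds
position weight matrices, and PWM window scores get *exact* p-values from
the full score distribution under an i.i.d. background, computed by
dynamic programming on a discretized score grid.

The base order everywhere is A, C, G, T (columns 0..3).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
from Bio import motifs as bio_motifs
from statsmodels.stats.multitest import multipletests

from .errors import DegenerateMatrixError, ParseError

logger = logging.getLogger(__name__)

BASES = "ACGT"
BASE_INDEX = {b: i for i, b in enumerate(BASES)}

#: IUPAC nucleotide codes -> the set of bases each matches.
IUPAC_CODES: dict[str, frozenset[str]] = {
    "A": frozenset("A"), "C": frozenset("C"), "G": frozenset("G"), "T": frozenset("T"),
    "R": frozenset("AG"), "Y": frozenset("CT"), "S": frozenset("CG"),
    "W": frozenset("AT"), "K": frozenset("GT"), "M": frozenset("AC"),
    "B": frozenset("CGT"), "D": frozenset("AGT"), "H": frozenset("ACT"),
    "V": frozenset("ACG"), "N": frozenset("ACGT"),
}
_SET_TO_CODE = {v: k for k, v in IUPAC_CODES.items()}

_COMPLEMENT = str.maketrans("ACGTRYSWKMBDHVN", "TGCAYRSWMKVHDBN")


def reverse_complement(seq: str) -> str:
    """Reverse complement, IUPAC-aware."""
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class ConsensusPattern:
    """A degenerate consensus motif over the IUPAC alphabet."""

    iupac: str

    def __post_init__(self) -> None:
        if not self.iupac:
            raise ValueError("consensus pattern must be nonempty")
        bad = [c for c in self.iupac if c not in IUPAC_CODES]
        if bad:
            raise ValueError(f"invalid IUPAC characters {bad!r} in pattern")

    @property
    def width(self) -> int:
        return len(self.iupac)


@dataclass(frozen=True)
class MotifModel:
    """A position frequency matrix with provenance.

    ``pfm`` is width x 4 nonnegative counts in A,C,G,T column order.
    """

    id: str
    pfm: np.ndarray
    source: str = ""

    def __post_init__(self) -> None:
        pfm = np.asarray(self.pfm, dtype=float)
        if pfm.ndim != 2 or pfm.shape[1] != 4 or pfm.shape[0] < 1:
            raise ValueError("pfm must be a width x 4 matrix with width >= 1")
        if (pfm < 0).any():
            raise ValueError("pfm counts must be nonnegative")
        if (pfm.sum(axis=1) <= 0).any():
            raise ValueError("every pfm position needs a positive column sum")
        object.__setattr__(self, "pfm", pfm)

    @property
    def width(self) -> int:
        return self.pfm.shape[0]


@dataclass(frozen=True)
class PWM:
    """Log2-odds position weight matrix with its background model."""

    logodds: np.ndarray
    background: np.ndarray
    pseudocount: float

    def __post_init__(self) -> None:
        bg = np.asarray(self.background, dtype=float)
        if bg.shape != (4,) or (bg <= 0).any() or abs(bg.sum() - 1.0) > 1e-9:
            raise ValueError("background must be 4 positive probabilities summing to 1")
        if self.pseudocount < 0:
            raise ValueError("pseudocount must be nonnegative")
        object.__setattr__(self, "logodds", np.asarray(self.logodds, dtype=float))
        object.__setattr__(self, "background", bg)

    @property
    def width(self) -> int:
        return self.logodds.shape[0]

    @property
    def max_score(self) -> float:
        return float(self.logodds.max(axis=1).sum())


@dataclass(frozen=True)
class MotifHit:
    """One motif occurrence in a scanned sequence (1-based start)."""

    start: int
    strand: str
    score: float
    pvalue: float | None = None

    def __post_init__(self) -> None:
        if self.start < 1:
            raise ValueError("hit start must be >= 1")
        if self.strand not in "+-":
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")
        if self.pvalue is not None and not 0.0 <= self.pvalue <= 1.0:
            raise ValueError(f"pvalue {self.pvalue} outside [0, 1]")


# ---------------------------------------------------------------------------
# consensus patterns
# ---------------------------------------------------------------------------

def parse_consensus(text: str) -> ConsensusPattern:
    """Parse a slash-degenerate consensus string into IUPAC.

    Each ``B1/B2`` token (two alternatives at one position) collapses to
    the IUPAC code for the pair, so ``AA/CAACAAA/C`` becomes ``AMAACAAM``.
    Optional 5'-/-3' decorations and whitespace are stripped.
    """
    s = text.strip().upper()
    for deco in ("5'-", "5'", "-3'", "3'"):
        s = s.removeprefix(deco).removesuffix(deco)
    s = s.replace("′", "'").strip("-' ")
    out = []
    i = 0
    while i < len(s):
        c = s[i]
        if c == "/":
            raise ParseError(f"misplaced '/' at position {i + 1} in {text!r}")
        if c not in IUPAC_CODES:
            raise ParseError(f"unknown character {c!r} in consensus {text!r}")
        if i + 2 <= len(s) - 1 and s[i + 1] == "/":
            d = s[i + 2]
            if d not in IUPAC_CODES:
                raise ParseError(f"unknown character {d!r} in consensus {text!r}")
            combined = IUPAC_CODES[c] | IUPAC_CODES[d]
            out.append(_SET_TO_CODE[frozenset(combined)])
            i += 3
        else:
            out.append(c)
            i += 1
    return ConsensusPattern(iupac="".join(out))


def scan_consensus(
    seq: str, pattern: ConsensusPattern, strands: str = "forward"
) -> list[MotifHit]:
    """Find every (overlapping) occurrence of an IUPAC pattern.

    Reverse-strand hits (``strands="both"``) are matched against the
    reverse complement and reported on the forward coordinate system with
    ``strand="-"``; the start is the leftmost base of the occupied window.
    """
    if strands not in ("forward", "both"):
        raise ValueError(f"strands must be 'forward' or 'both', got {strands!r}")
    seq = seq.upper()
    w = pattern.width
    allowed = [IUPAC_CODES[c] for c in pattern.iupac]
    hits = []

    def _forward_hits(s: str) -> list[int]:
        found = []
        for start in range(len(s) - w + 1):
            if all(s[start + j] in allowed[j] for j in range(w)):
                found.append(start)
        return found

    for start in _forward_hits(seq):
        hits.append(MotifHit(start=start + 1, strand="+", score=float(w)))
    if strands == "both":
        rc = reverse_complement(seq)
        for start in _forward_hits(rc):
            # map back: rc offset start covers forward bases
            # [len - start - w, len - start - 1] (0-based)
            fwd_start = len(seq) - start - w
            hits.append(MotifHit(start=fwd_start + 1, strand="-", score=float(w)))
    hits.sort(key=lambda h: (h.start, h.strand))
    return hits


# ---------------------------------------------------------------------------
# motif library input
# ---------------------------------------------------------------------------

def load_jaspar(path: str | Path) -> list[MotifModel]:
    """Read a JASPAR-format PFM file (">ID name" + 4 labelled count rows)."""
    path = Path(path)
    models = []
    with open(path) as fh:
        for m in bio_motifs.parse(fh, "jaspar"):
            pfm = np.array([[m.counts[b][i] for b in BASES] for i in range(m.length)])
            label = m.matrix_id or m.name
            models.append(MotifModel(id=label, pfm=pfm, source=str(path)))
    if not models:
        raise ParseError(f"no JASPAR motifs found in {path}")
    return models


def load_consensus_list(path: str | Path) -> list[ConsensusPattern]:
    """Read a plain text file with one consensus pattern per line.

    Slash-degenerate notation is accepted, so a motif can be supplied
    exactly as printed in the literature. Blank lines and ``#`` comments
    are skipped.
    """
    patterns = []
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        patterns.append(parse_consensus(line))
    if not patterns:
        raise ParseError(f"no consensus patterns found in {path}")
    return patterns


def consensus_to_pfm(
    pattern: ConsensusPattern, match_count: float = 10.0, mismatch_count: float = 1.0
) -> np.ndarray:
    """Build a PFM from a consensus: allowed bases get ``match_count``
    pseudo-observations per position, others ``mismatch_count``."""
    pfm = np.full((pattern.width, 4), float(mismatch_count))
    for i, code in enumerate(pattern.iupac):
        for b in IUPAC_CODES[code]:
            pfm[i, BASE_INDEX[b]] = match_count
    return pfm


# ---------------------------------------------------------------------------
# PWMs and exact score p-values
# ---------------------------------------------------------------------------

def uniform_background() -> np.ndarray:
    return np.full(4, 0.25)


def sequence_background(seq: str, floor: float = 0.01) -> np.ndarray:
    """Mononucleotide composition of ``seq`` with a per-base floor."""
    counts = np.array([seq.count(b) for b in BASES], dtype=float)
    total = counts.sum()
    freqs = counts / total if total > 0 else uniform_background()
    freqs = np.maximum(freqs, floor)
    return freqs / freqs.sum()


def pfm_to_pwm(
    m: MotifModel,
    background: np.ndarray | None = None,
    pseudocount: float = 0.8,
) -> PWM:
    """Convert counts to a log2-odds PWM.

    ``logodds[i, b] = log2(((c[i, b] + p * bg[b]) / (colsum_i + p)) / bg[b])``
    — the total pseudocount ``p`` is split across bases in proportion to
    the background, the standard construction.
    """
    bg = uniform_background() if background is None else np.asarray(background, float)
    if pseudocount < 0:
        raise ValueError("pseudocount must be nonnegative")
    colsum = m.pfm.sum(axis=1, keepdims=True)
    if pseudocount == 0 and (colsum == 0).any():
        raise DegenerateMatrixError(f"motif {m.id}: zero column with zero pseudocount")
    with np.errstate(divide="ignore"):
        probs = (m.pfm + pseudocount * bg[None, :]) / (colsum + pseudocount)
        logodds = np.log2(probs / bg[None, :])
    return PWM(logodds=logodds, background=bg, pseudocount=pseudocount)


class ScoreDistribution:
    """Exact PWM score distribution under an i.i.d. background.

    Scores are rounded to an integer grid of step ``granularity`` (in
    log2-odds units) and the distribution of the motif-width word score is
    built position by position by discrete convolution. ``-inf`` entries
    (possible with zero pseudocount) are carried as a separate probability
    mass that only counts toward ``P(S >= s)`` at ``s = -inf``.
    """

    def __init__(self, pwm: PWM, granularity: float = 1e-3) -> None:
        if granularity <= 0:
            raise ValueError("granularity must be positive")
        self.granularity = granularity
        lo = pwm.logodds
        finite = np.isfinite(lo)
        iscores = np.zeros(lo.shape, dtype=np.int64)
        iscores[finite] = np.round(lo[finite] / granularity).astype(np.int64)

        # running distribution over the integer grid [offset, offset + len)
        dist = np.array([1.0])
        offset = 0
        neginf_mass = 0.0
        for i in range(pwm.width):
            cols = [
                (iscores[i, b], pwm.background[b])
                for b in range(4)
                if finite[i, b]
            ]
            p_inf = float(sum(pwm.background[b] for b in range(4) if not finite[i, b]))
            neginf_mass = neginf_mass + (1.0 - neginf_mass) * p_inf
            if not cols:
                dist = np.array([1.0])
                offset = 0
                continue
            smin = min(s for s, _ in cols)
            smax = max(s for s, _ in cols)
            new = np.zeros(len(dist) + (smax - smin), dtype=float)
            for s, p in cols:
                new[s - smin : s - smin + len(dist)] += p * dist
            dist = new
            offset += smin
        total_finite = dist.sum()
        # renormalize the finite part against accumulated -inf mass
        if neginf_mass > 0 and total_finite > 0:
            dist = dist * ((1.0 - neginf_mass) / total_finite)
        self._dist = dist
        self._offset = offset
        self._neginf_mass = neginf_mass
        # survival[k] = P(S >= offset + k) over the finite grid
        self._survival = np.concatenate([np.cumsum(dist[::-1])[::-1], [0.0]])

    def pvalue(self, score: float) -> float:
        """P(word score >= score) for a random background word."""
        if score == -math.inf:
            return 1.0
        k = int(round(score / self.granularity))
        idx = k - self._offset
        if idx >= len(self._survival):
            return 0.0
        # words scoring -inf never reach a finite threshold, so only the
        # finite mass counts even below the finite minimum
        return float(min(1.0, self._survival[max(idx, 0)]))


def pwm_score_pvalue(pwm: PWM, score: float, granularity: float = 1e-3) -> float:
    """Exact background p-value of a PWM score (see ScoreDistribution)."""
    return ScoreDistribution(pwm, granularity).pvalue(score)


def _encode(seq: str) -> np.ndarray:
    """Map A,C,G,T -> 0..3; any other character -> -1."""
    lut = np.full(256, -1, dtype=np.int8)
    for b, i in BASE_INDEX.items():
        lut[ord(b)] = i
    return lut[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


def score_windows(seq: str, pwm: PWM) -> np.ndarray:
    """Log2-odds score of every window of ``seq`` (forward strand)."""
    codes = _encode(seq.upper())
    w = pwm.width
    n = len(codes) - w + 1
    if n <= 0:
        return np.zeros(0)
    windows = np.lib.stride_tricks.sliding_window_view(codes, w)
    valid = (windows >= 0).all(axis=1)
    scores = np.full(n, -np.inf)
    if valid.any():
        idx = np.arange(w)
        scores[valid] = pwm.logodds[idx[None, :], windows[valid]].sum(axis=1)
    return scores


def scan_pwm(
    seq: str,
    pwm: PWM,
    p_threshold: float,
    strands: str = "both",
    granularity: float = 1e-3,
) -> list[MotifHit]:
    """Report windows whose exact score p-value is <= ``p_threshold``."""
    if not 0.0 <= p_threshold <= 1.0:
        raise ValueError("p_threshold must lie in [0, 1]")
    if strands not in ("forward", "both"):
        raise ValueError(f"strands must be 'forward' or 'both', got {strands!r}")
    seq = seq.upper()
    if len(seq) < pwm.width:
        logger.warning(
            "sequence length %d shorter than motif width %d", len(seq), pwm.width
        )
        return []
    dist = ScoreDistribution(pwm, granularity)
    hits = []
    fwd = score_windows(seq, pwm)
    for start0, score in enumerate(fwd):
        if np.isfinite(score):
            p = dist.pvalue(float(score))
            if p <= p_threshold:
                hits.append(MotifHit(start=start0 + 1, strand="+",
                                     score=float(score), pvalue=p))
    if strands == "both":
        rc = reverse_complement(seq)
        rev = score_windows(rc, pwm)
        for start0, score in enumerate(rev):
            if np.isfinite(score):
                p = dist.pvalue(float(score))
                if p <= p_threshold:
                    fwd_start0 = len(seq) - start0 - pwm.width
                    hits.append(MotifHit(start=fwd_start0 + 1, strand="-",
                                         score=float(score), pvalue=p))
    hits.sort(key=lambda h: (h.start, h.strand))
    return hits


def bh_adjust(pvalues: Sequence[float]) -> list[float]:
    """Benjamini–Hochberg step-up adjusted p-values, in the input order."""
    ps = np.asarray(list(pvalues), dtype=float)
    if ps.size == 0:
        return []
    if ((ps < 0) | (ps > 1)).any() or np.isnan(ps).any():
        raise ValueError("p-values must lie in [0, 1]")
    _, adjusted, _, _ = multipletests(ps, method="fdr_bh")
    return [float(p) for p in adjusted]
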