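"""Biophysical transcription-factor occupancy (TRAP-style affinity).

A position frequency matrix is converted to per-position *mismatch
energies*: the consensus base at each position costs zero and every other
base costs ``(1/lambda) * ln((c_max + p) / (c_b + p))``, so rarer bases in
the alignment are energetically penalized. A window of motif width then
binds with probability ``R0 * exp(-E) / (1 + R0 * exp(-E))`` where ``E``
is the summed mismatch energy, and the *affinity* of a sequence is the
expected number of bound positions — the sum of window occupancies over
all offsets (both strands by default).

Affinity p-values are empirical: the observed affinity is compared with
affinities of i.i.d. background sequences of the same length, with the
add-one rule ``p = (1 + #{A_bg >= A}) / (n + 1)``.

Defaults follow the published TRAP parameterization: ``lambda = 0.7`` and
``ln R0 = 0.584 * width - 5.66``, both overridable.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, replace

import numpy as np

from .errors import DegenerateMatrixError
from .motifs import BASE_INDEX, MotifModel, _encode
from .regions import SequenceWindow

logger = logging.getLogger(__name__)

#: published defaults for the width-dependent binding-strength intercept
_R0_SLOPE = 0.584
_R0_INTERCEPT = -5.66


@dataclass(frozen=True)
class TrapParams:
    """Energy-scale and strength parameters of the occupancy model.

    ``r0 = None`` means "derive from motif width" via
    ``ln R0 = 0.584 * width - 5.66`` when the energy matrix is built.
    """

    lambda_: float = 0.7
    r0: float | None = None
    both_strands: bool = True

    def __post_init__(self) -> None:
        if self.lambda_ <= 0:
            raise ValueError("lambda_ must be positive")
        if self.r0 is not None and self.r0 <= 0:
            raise ValueError("r0 must be positive")


def default_r0(width: int) -> float:
    return math.exp(_R0_SLOPE * width + _R0_INTERCEPT)


@dataclass(frozen=True)
class EnergyMatrix:
    """Per-position mismatch energies (width x 4, A/C/G/T columns).

    Invariant: each row's minimum is exactly zero (the consensus base).
    """

    eps: np.ndarray
    params: TrapParams
    motif_id: str = ""

    def __post_init__(self) -> None:
        eps = np.asarray(self.eps, dtype=float)
        if eps.ndim != 2 or eps.shape[1] != 4:
            raise ValueError("eps must be a width x 4 matrix")
        if (eps < 0).any():
            raise ValueError("mismatch energies must be nonnegative")
        if not np.allclose(eps.min(axis=1), 0.0):
            raise ValueError("each position must have a zero-energy consensus base")
        if self.params.r0 is None:
            raise ValueError("EnergyMatrix requires a resolved r0")
        object.__setattr__(self, "eps", eps)

    @property
    def width(self) -> int:
        return self.eps.shape[0]


@dataclass(frozen=True)
class AffinityResult:
    """Expected number of bound positions on one window."""

    affinity: float
    pvalue: float | None = None
    window_label: str = "other"

    def __post_init__(self) -> None:
        if self.affinity < 0:
            raise ValueError("affinity must be nonnegative")
        if self.pvalue is not None and not 0.0 <= self.pvalue <= 1.0:
            raise ValueError("pvalue outside [0, 1]")


@dataclass(frozen=True)
class DifferentialConfig:
    """Decision rule for calling an allele-dependent affinity change.

    A record is flagged when the better allele's affinity p-value beats
    ``affinity_p`` AND either the affinity shifts by at least
    ``log2_ratio_min`` in magnitude or exactly one allele clears the
    p-value threshold (binding created or destroyed).
    """

    affinity_p: float = 1e-4
    log2_ratio_min: float = 1.0
    n_samples: int = 20_000
    seed: int = 0
    epsilon: float = 1e-9


@dataclass(frozen=True)
class DifferentialResult:
    """Alt-vs-ref affinity comparison for one variant x motif pair."""

    log2_ratio: float
    null_pvalue: float | None
    flagged: bool
    affinity_ref: float = 0.0
    affinity_alt: float = 0.0
    pvalue_ref: float | None = None
    pvalue_alt: float | None = None


# ---------------------------------------------------------------------------
# construction
# ---------------------------------------------------------------------------

def pfm_to_energy(
    m: MotifModel,
    params: TrapParams | None = None,
    pseudocount: float = 1.0,
) -> EnergyMatrix:
    """Convert counts to mismatch energies.

    ``eps[i, b] = (1/lambda) * ln((max_b' c[i, b'] + p) / (c[i, b] + p))``;
    the per-position maximum-count base gets energy exactly zero.
    """
    params = params or TrapParams()
    if pseudocount < 0:
        raise ValueError("pseudocount must be nonnegative")
    if pseudocount == 0 and (m.pfm == 0).any():
        raise DegenerateMatrixError(
            f"motif {m.id}: zero count with zero pseudocount gives infinite energy"
        )
    cmax = m.pfm.max(axis=1, keepdims=True)
    eps = np.log((cmax + pseudocount) / (m.pfm + pseudocount)) / params.lambda_
    eps[np.isclose(eps, 0.0)] = 0.0
    if params.r0 is None:
        params = replace(params, r0=default_r0(m.width))
    return EnergyMatrix(eps=eps, params=params, motif_id=m.id)


# ---------------------------------------------------------------------------
# occupancy and affinity
# ---------------------------------------------------------------------------

def window_occupancy(e: EnergyMatrix, word: str) -> float:
    """Binding probability of one motif-width word.

    ``occ = R0 exp(-E) / (1 + R0 exp(-E))`` with ``E`` the summed mismatch
    energy of the word — 0.5 for the consensus word at ``R0 = 1``.
    """
    word = word.upper()
    if len(word) != e.width:
        raise ValueError(f"word length {len(word)} != motif width {e.width}")
    try:
        energy = sum(e.eps[i, BASE_INDEX[b]] for i, b in enumerate(word))
    except KeyError as exc:
        raise ValueError(f"invalid base {exc} in word {word!r}") from None
    z = e.params.r0 * math.exp(-energy)
    return z / (1.0 + z)


def _reverse_energy(e: EnergyMatrix) -> np.ndarray:
    """Energy matrix that scores the reverse-complement strand of a
    forward window: reversed positions, complemented columns."""
    return e.eps[::-1, ::-1]


def _window_energies(codes: np.ndarray, eps: np.ndarray) -> np.ndarray:
    """Summed energies of all width-w windows of encoded sequence(s).

    ``codes`` is (..., L) int in 0..3; returns (..., L - w + 1).
    """
    w = eps.shape[0]
    windows = np.lib.stride_tricks.sliding_window_view(codes, w, axis=-1)
    idx = np.arange(w)
    return eps[idx, windows].sum(axis=-1)


def _occupancy_sum(codes: np.ndarray, e: EnergyMatrix) -> np.ndarray:
    """Total occupancy (affinity) per encoded sequence, vectorized over
    leading axes; includes the reverse strand when configured."""
    r0 = e.params.r0
    energy = _window_energies(codes, e.eps)
    z = r0 * np.exp(-energy)
    total = (z / (1.0 + z)).sum(axis=-1)
    if e.params.both_strands:
        energy_rc = _window_energies(codes, _reverse_energy(e))
        z = r0 * np.exp(-energy_rc)
        total = total + (z / (1.0 + z)).sum(axis=-1)
    return total


def sequence_affinity(e: EnergyMatrix, seq: str) -> AffinityResult:
    """Affinity of a sequence: sum of window occupancies over all offsets
    (and both strands when ``e.params.both_strands``)."""
    seq = seq.upper()
    if len(seq) < e.width:
        logger.warning(
            "sequence length %d shorter than motif width %d; affinity 0",
            len(seq), e.width,
        )
        return AffinityResult(affinity=0.0)
    codes = _encode(seq)
    if (codes < 0).any():
        raise ValueError("sequence contains non-ACGT characters")
    return AffinityResult(affinity=float(_occupancy_sum(codes, e)))


def sample_background_affinities(
    e: EnergyMatrix,
    bg: np.ndarray,
    seq_len: int,
    n_samples: int,
    rng: np.random.Generator,
    batch: int = 5_000,
) -> np.ndarray:
    """Affinities of ``n_samples`` i.i.d. background sequences."""
    bg = np.asarray(bg, dtype=float)
    bg = bg / bg.sum()
    out = np.empty(n_samples)
    done = 0
    while done < n_samples:
        n = min(batch, n_samples - done)
        codes = rng.choice(4, size=(n, seq_len), p=bg).astype(np.int8)
        out[done : done + n] = _occupancy_sum(codes, e)
        done += n
    return out


def affinity_pvalue(
    a: float,
    e: EnergyMatrix,
    bg: np.ndarray,
    seq_len: int,
    n_samples: int = 20_000,
    seed: int = 0,
    null_affinities: np.ndarray | None = None,
) -> float:
    """Empirical background p-value of an affinity.

    ``p = (1 + #{background affinity >= a}) / (n_samples + 1)``; a
    precomputed ``null_affinities`` array can be passed to share one null
    sample across several queries.
    """
    if null_affinities is None:
        if n_samples < 1:
            raise ValueError("n_samples must be >= 1")
        rng = np.random.default_rng(seed)
        null_affinities = sample_background_affinities(e, bg, seq_len, n_samples, rng)
    n = len(null_affinities)
    return float((1 + int((null_affinities >= a).sum())) / (n + 1))


def differential_affinity(
    ref_win: SequenceWindow,
    alt_win: SequenceWindow,
    e: EnergyMatrix,
    cfg: DifferentialConfig | None = None,
    compute_null: bool = True,
) -> DifferentialResult:
    """Compare motif affinity between the two alleles of a window.

    ``log2_ratio = log2((A_alt + eps) / (A_ref + eps))``. The null p-value
    is paired: background sequences of the window's composition receive
    the ref and the alt bases at the differing offsets, and the observed
    |log2 ratio| is ranked against the null |log2 ratio| distribution.
    """
    cfg = cfg or DifferentialConfig()
    if len(ref_win) != len(alt_win):
        raise ValueError("ref and alt windows must have equal length")
    a_ref = sequence_affinity(e, ref_win.sequence).affinity
    a_alt = sequence_affinity(e, alt_win.sequence).affinity
    log2_ratio = math.log2((a_alt + cfg.epsilon) / (a_ref + cfg.epsilon))

    diff_offsets = [
        i for i, (a, b) in enumerate(zip(ref_win.sequence, alt_win.sequence)) if a != b
    ]
    null_p = p_ref = p_alt = None
    if compute_null:
        from .motifs import sequence_background

        rng = np.random.default_rng(cfg.seed)
        bg = sequence_background(ref_win.sequence)
        L = len(ref_win)
        codes = rng.choice(4, size=(cfg.n_samples, L), p=bg).astype(np.int8)
        null_raw = _occupancy_sum(codes, e)
        p_ref = float((1 + (null_raw >= a_ref).sum()) / (cfg.n_samples + 1))
        p_alt = float((1 + (null_raw >= a_alt).sum()) / (cfg.n_samples + 1))
        if diff_offsets:
            ref_codes = _encode(ref_win.sequence)
            alt_codes = _encode(alt_win.sequence)
            paired_ref = codes.copy()
            paired_alt = codes.copy()
            for i in diff_offsets:
                paired_ref[:, i] = ref_codes[i]
                paired_alt[:, i] = alt_codes[i]
            a1 = _occupancy_sum(paired_ref, e)
            a2 = _occupancy_sum(paired_alt, e)
            null_lr = np.abs(np.log2((a2 + cfg.epsilon) / (a1 + cfg.epsilon)))
            null_p = float(
                (1 + (null_lr >= abs(log2_ratio)).sum()) / (cfg.n_samples + 1)
            )
        else:
            null_p = 1.0

    flagged = decide_differential(p_ref, p_alt, log2_ratio, cfg)
    return DifferentialResult(
        log2_ratio=log2_ratio,
        null_pvalue=null_p,
        flagged=flagged,
        affinity_ref=a_ref,
        affinity_alt=a_alt,
        pvalue_ref=p_ref,
        pvalue_alt=p_alt,
    )


def decide_differential(
    p_ref: float | None,
    p_alt: float | None,
    log2_ratio: float,
    cfg: DifferentialConfig,
) -> bool:
    """The allele-dependent-change rule shared by the standalone operation
    and the screening pipeline."""
    if p_ref is None or p_alt is None:
        return False
    below_ref = p_ref < cfg.affinity_p
    below_alt = p_alt < cfg.affinity_p
    if not (below_ref or below_alt):
        return False
    return abs(log2_ratio) >= cfg.log2_ratio_min or (below_ref != below_alt)
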