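"""Banded affine-gap extension of seeds, scoring, E-values and hit filtering.

Each representative seed is extended outward from its two edges by banded
dynamic programming: one extension runs rightward from the seed end, one runs
leftward from the seed start (on reversed flanks), and both are confined to
cells within ``half_width`` diagonals of the seed diagonal.  The seed
interior is never realigned; it contributes ``k * match`` and k matched
columns.

Two termination modes are supported:

* **global (glocal)** — the default for taxonomic assignment.  Each
  extension must consume its query flank to the end; the reference endpoint
  floats freely within the band, so the full query is covered while the
  reference is matched only locally.
* **local** — each extension stops at its maximum-scoring cell, so poor
  flanks are trimmed; useful for motif-style partial matches.

Scores follow the usual affine convention where a gap of length g costs
``gap_open + g * gap_extend``.  E-values use the Karlin-Altschul form
``E = K m n exp(-lambda S)`` with user-configurable lambda and K.

The inner DP is a numba-compiled kernel over a band stored in offset
coordinates ``d = j - i + half_width``; traceback is done inside the kernel
and only the alignment statistics (matches, mismatches, gap opens, columns,
endpoints) cross back into Python.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from numba import njit

from .errors import InputError, ParameterError
from .seeding import FORWARD, Seed

NEG = -(10**15)  # effectively -infinity for int64 scores


@dataclass(frozen=True)
class ScoringScheme:
    """Match/mismatch/affine-gap scores plus Karlin-Altschul lambda and K.

    Defaults are megablast-style: +1/-3 with gap open -5 and extend -2, and
    the ungapped lambda=1.28, K=0.46 appropriate for that match/mismatch
    ratio.  All values are user-configurable.
    """

    match: int = 1
    mismatch: int = -3
    gap_open: int = -5
    gap_extend: int = -2
    lam: float = 1.28
    K: float = 0.46

    def __post_init__(self) -> None:
        if self.match <= 0 or self.mismatch >= 0:
            raise ParameterError("need match > 0 and mismatch < 0")
        if self.gap_open > 0 or self.gap_extend >= 0:
            raise ParameterError("need gap_open <= 0 and gap_extend < 0")
        if not (math.isfinite(self.lam) and self.lam > 0 and math.isfinite(self.K) and self.K > 0):
            raise ParameterError("lambda and K must be finite and positive")


@dataclass(frozen=True)
class BandSpec:
    """Band half-width: maximum deviation, in diagonals, from the seed diagonal."""

    half_width: int = 32

    def __post_init__(self) -> None:
        if self.half_width < 0:
            raise ParameterError("half_width must be >= 0")


@dataclass
class Hit:
    """One extended alignment.

    Query coordinates are 0-based half-open on the forward query strand;
    reference coordinates are 0-based half-open on the (parent) reference.
    ``identity`` is matched columns / alignment columns (gaps included).
    """

    query_id: str
    ref_parent_id: str
    strand: int
    q_start: int
    q_end: int
    r_start: int
    r_end: int
    score: int
    identity: float
    aln_length: int
    mismatches: int
    gap_opens: int
    evalue: float
    bitscore: float


@njit(cache=False)
def _extend_kernel(q, r, hw, match, mismatch, gap_open, gap_extend, glocal):  # pragma: no cover
    """Banded affine extension anchored at (0, 0).

    Returns (score, end_i, end_j, matches, mismatches, gap_opens, gap_cols).
    In glocal mode the path must reach i == n (full query flank); if the band
    never reaches row n the score comes back as NEG.  In local mode the best
    cell over the whole band is taken (the empty extension scores 0).
    """
    n = q.shape[0]
    m = r.shape[0]
    W = 2 * hw + 1
    H = np.full((n + 1, W), NEG, dtype=np.int64)
    E = np.full((n + 1, W), NEG, dtype=np.int64)
    F = np.full((n + 1, W), NEG, dtype=np.int64)
    # ptrH: 0 none, 1 diag, 2 from E, 3 from F; ptrE/ptrF: 1 open, 2 extend
    ptrH = np.zeros((n + 1, W), dtype=np.int8)
    ptrE = np.zeros((n + 1, W), dtype=np.int8)
    ptrF = np.zeros((n + 1, W), dtype=np.int8)

    H[0, hw] = 0
    for d in range(hw + 1, W):
        j = d - hw
        if j > m:
            break
        open_cand = H[0, d - 1] + gap_open + gap_extend
        ext_cand = E[0, d - 1] + gap_extend
        if open_cand >= ext_cand:
            E[0, d] = open_cand
            ptrE[0, d] = 1
        else:
            E[0, d] = ext_cand
            ptrE[0, d] = 2
        H[0, d] = E[0, d]
        ptrH[0, d] = 2

    for i in range(1, n + 1):
        qc = q[i - 1]
        for d in range(W):
            j = i + d - hw
            if j < 0 or j > m:
                continue
            best = NEG
            ptr = 0
            if j >= 1 and H[i - 1, d] > NEG:
                s = match if qc == r[j - 1] else mismatch
                cand = H[i - 1, d] + s
                if cand > best:
                    best = cand
                    ptr = 1
            if d + 1 < W:
                open_cand = H[i - 1, d + 1] + gap_open + gap_extend
                ext_cand = F[i - 1, d + 1] + gap_extend
                if open_cand >= ext_cand:
                    F[i, d] = open_cand
                    ptrF[i, d] = 1
                else:
                    F[i, d] = ext_cand
                    ptrF[i, d] = 2
                if F[i, d] > best:
                    best = F[i, d]
                    ptr = 3
            if d >= 1 and j >= 1:
                open_cand = H[i, d - 1] + gap_open + gap_extend
                ext_cand = E[i, d - 1] + gap_extend
                if open_cand >= ext_cand:
                    E[i, d] = open_cand
                    ptrE[i, d] = 1
                else:
                    E[i, d] = ext_cand
                    ptrE[i, d] = 2
                if E[i, d] > best:
                    best = E[i, d]
                    ptr = 2
            if ptr != 0:
                H[i, d] = best
                ptrH[i, d] = ptr

    # pick the end cell
    bi = 0
    bd = hw
    best = NEG
    if glocal:
        for d in range(W):
            j = n + d - hw
            if 0 <= j <= m and H[n, d] > best:
                best = H[n, d]
                bi = n
                bd = d
        if best <= NEG // 2:
            return NEG, 0, 0, 0, 0, 0, 0
    else:
        best = 0  # empty extension at the origin
        for i in range(n + 1):
            for d in range(W):
                j = i + d - hw
                if 0 <= j <= m and H[i, d] > best:
                    best = H[i, d]
                    bi = i
                    bd = d

    # traceback
    n_match = 0
    n_mismatch = 0
    n_gap_open = 0
    n_gap_cols = 0
    i = bi
    d = bd
    state = 0  # 0=H, 1=E, 2=F
    while not (state == 0 and i == 0 and d == hw):
        if state == 0:
            ptr = ptrH[i, d]
            if ptr == 1:
                j = i + d - hw
                if q[i - 1] == r[j - 1]:
                    n_match += 1
                else:
                    n_mismatch += 1
                i -= 1
            elif ptr == 2:
                state = 1
            elif ptr == 3:
                state = 2
            else:
                break  # unreachable if the DP is consistent
        elif state == 1:
            was_open = ptrE[i, d] == 1
            n_gap_cols += 1
            d -= 1
            if was_open:
                n_gap_open += 1
                state = 0
        else:
            was_open = ptrF[i, d] == 1
            n_gap_cols += 1
            i -= 1
            d += 1
            if was_open:
                n_gap_open += 1
                state = 0

    end_j = bi + bd - hw
    return best, bi, end_j, n_match, n_mismatch, n_gap_open, n_gap_cols


def _as_bytes(s: str) -> np.ndarray:
    return np.frombuffer(s.upper().encode("ascii"), dtype=np.uint8)


def compute_evalue(
    score: int, query_length: int, database_length: int, scoring: ScoringScheme
) -> tuple[float, float]:
    """Karlin-Altschul E-value and bit score.

    ``bitscore = (lambda * S - ln K) / ln 2``;
    ``evalue = m * n * 2**(-bitscore) = K m n exp(-lambda S)``.
    ``database_length`` is the total residue count over all reference records
    in the run.
    """
    if query_length < 1 or database_length < 1:
        raise ParameterError("query_length and database_length must be >= 1")
    bitscore = (scoring.lam * score - math.log(scoring.K)) / math.log(2.0)
    # exp form avoids underflow to 0 bit-shifting for high scores; deeply
    # negative scores (possible in glocal mode) saturate to infinity
    exponent = -scoring.lam * score
    if exponent > 700.0:
        return math.inf, bitscore
    evalue = scoring.K * query_length * database_length * math.exp(exponent)
    return evalue, bitscore


def banded_extend(
    query: str,
    ref: str,
    seed: Seed,
    k: int,
    mode: str = "global",
    band: BandSpec = BandSpec(),
    scoring: ScoringScheme = ScoringScheme(),
    query_id: str = "",
    ref_id: str = "",
    database_length: int | None = None,
) -> Hit | None:
    """Extend one seed into a full hit, or return None.

    ``query`` is the searched strand (already reverse-complemented for
    reverse-strand seeds) and ``ref`` the reference fragment; ``seed`` holds
    their anchoring offsets and ``k`` the anchor length.  Coordinates in the
    returned hit are relative to the given strings; the pipeline lifts them
    to parent/forward frames.

    Returns None when (local mode) the total score is not positive, or when
    (global mode) the band cannot accommodate the full query flank on either
    side — e.g. the query overhangs the reference by more than the band
    half-width.
    """
    if mode not in ("global", "local"):
        raise ParameterError(f"unknown mode {mode!r}")
    qs, rs = seed.query_offset, seed.ref_offset
    if query[qs : qs + k].upper() != ref[rs : rs + k].upper():
        raise InputError("seed windows do not match; seed/extension inputs are inconsistent")
    hw = band.half_width
    glocal = mode == "global"

    # Right extension: suffixes after the seed.
    q_right = query[qs + k :]
    cap_r = min(len(ref) - (rs + k), len(q_right) + hw)
    r_right = ref[rs + k : rs + k + cap_r]
    # Left extension: reversed prefixes before the seed.
    q_left = query[:qs][::-1]
    cap_l = min(rs, len(q_left) + hw)
    r_left = ref[max(0, rs - cap_l) : rs][::-1]

    results = []
    for q_flank, r_flank in ((q_left, r_left), (q_right, r_right)):
        res = _extend_kernel(
            _as_bytes(q_flank),
            _as_bytes(r_flank),
            hw,
            scoring.match,
            scoring.mismatch,
            scoring.gap_open,
            scoring.gap_extend,
            glocal,
        )
        if res[0] <= NEG // 2:
            return None
        results.append(res)
    (sL, iL, jL, mL, xL, goL, gcL), (sR, iR, jR, mR, xR, goR, gcR) = results

    score = int(sL + k * scoring.match + sR)
    if mode == "local" and score <= 0:
        return None
    matches = mL + k + mR
    mismatches = xL + xR
    gap_opens = goL + goR
    aln_length = matches + mismatches + gcL + gcR
    identity = matches / aln_length
    q_start = qs - iL
    q_end = qs + k + iR
    r_start = rs - jL
    r_end = rs + k + jR
    dblen = database_length if database_length is not None else max(1, len(ref))
    evalue, bitscore = compute_evalue(score, max(1, len(query)), dblen, scoring)
    return Hit(
        query_id=query_id,
        ref_parent_id=ref_id,
        strand=seed.strand if seed.strand is not None else FORWARD,
        q_start=q_start,
        q_end=q_end,
        r_start=r_start,
        r_end=r_end,
        score=score,
        identity=identity,
        aln_length=aln_length,
        mismatches=mismatches,
        gap_opens=gap_opens,
        evalue=evalue,
        bitscore=bitscore,
    )


def filter_hits(hits: list[Hit], evalue_threshold: float, min_aln_length: int) -> list[Hit]:
    """Keep hits with evalue <= threshold (inclusive) and aln_length >= minimum."""
    return [h for h in hits if h.evalue <= evalue_threshold and h.aln_length >= min_aln_length]
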