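"""Independent reference implementations used to check the package.

Everything here is deliberately written the slow, obvious way — full
unbanded DP matrices, dictionary lookups, quadratic scans — and shares no
code with the package internals it checks.
"""

from __future__ import annotations

NEG = float("-inf")


def extend_score_oracle(
    q: str,
    r: str,
    match: int,
    mismatch: int,
    gap_open: int,
    gap_extend: int,
    glocal: bool,
) -> float:
    """Unbanded affine-gap extension score, anchored at (0, 0).

    A gap of length g costs gap_open + g * gap_extend.  In glocal mode the
    whole of ``q`` must be consumed and the best reference endpoint is taken;
    otherwise the best cell anywhere (including the empty extension, score 0)
    is taken.
    """
    n, m = len(q), len(r)
    H = [[NEG] * (m + 1) for _ in range(n + 1)]
    E = [[NEG] * (m + 1) for _ in range(n + 1)]  # gap in query: consumes ref
    F = [[NEG] * (m + 1) for _ in range(n + 1)]  # gap in ref: consumes query
    H[0][0] = 0.0
    for j in range(1, m + 1):
        E[0][j] = max(H[0][j - 1] + gap_open + gap_extend, E[0][j - 1] + gap_extend)
        H[0][j] = E[0][j]
    for i in range(1, n + 1):
        F[i][0] = max(H[i - 1][0] + gap_open + gap_extend, F[i - 1][0] + gap_extend)
        H[i][0] = F[i][0]
        qc = q[i - 1]
        row_h, prev_h = H[i], H[i - 1]
        row_e, row_f, prev_f = E[i], F[i], F[i - 1]
        for j in range(1, m + 1):
            row_e[j] = max(row_h[j - 1] + gap_open + gap_extend, row_e[j - 1] + gap_extend)
            row_f[j] = max(prev_h[j] + gap_open + gap_extend, prev_f[j] + gap_extend)
            s = match if qc == r[j - 1] else mismatch
            row_h[j] = max(prev_h[j - 1] + s, row_e[j], row_f[j])
    if glocal:
        return max(H[n])
    best = 0.0
    for row in H:
        m_ = max(row)
        if m_ > best:
            best = m_
    return best


def seeded_pair_score_oracle(q, r, qs, rs, k, scoring, glocal) -> float:
    """Score of extending a (qs, rs, k) seed without any band restriction."""
    assert q[qs : qs + k] == r[rs : rs + k]
    left = extend_score_oracle(
        q[:qs][::-1], r[:rs][::-1],
        scoring.match, scoring.mismatch, scoring.gap_open, scoring.gap_extend, glocal,
    )
    right = extend_score_oracle(
        q[qs + k :], r[rs + k :],
        scoring.match, scoring.mismatch, scoring.gap_open, scoring.gap_extend, glocal,
    )
    return left + k * scoring.match + right


def brute_force_seed_set(query: str, ref: str, k: int, p: int = 1) -> set[tuple[int, int]]:
    """All (query_offset, ref_offset) exact k-mer correspondences, ref offsets
    restricted to multiples of p; windows with non-ACGT letters excluded."""
    acgt = set("ACGT")
    out = set()
    for qo in range(len(query) - k + 1):
        w = query[qo : qo + k]
        if set(w) - acgt:
            continue
        for ro in range(0, len(ref) - k + 1, p):
            if ref[ro : ro + k] == w and not set(ref[ro : ro + k]) - acgt:
                out.add((qo, ro))
    return out


def hash_map_index_oracle(keys, values, repeat_threshold) -> dict:
    """key -> list of values, emptied for keys exceeding the repeat threshold.

    Insertion order within a key equals the stable-sort order of the index.
    """
    table: dict = {}
    for key, value in zip(keys, values):
        table.setdefault(int(key), []).append(value)
    return {
        k: (vs if len(vs) <= repeat_threshold else [])
        for k, vs in table.items()
    }


def _in_area(a, b, z, w) -> bool:
    if (a.query_ordinal, a.ref_ordinal, a.strand) != (b.query_ordinal, b.ref_ordinal, b.strand):
        return False
    if abs(b.diagonal - a.diagonal) > z:
        return False
    return 0 < b.ref_offset - a.ref_offset <= w


def two_pass_reduction_oracle(sorted_seeds: list, z: int, w: int) -> list:
    """Literal restaging of the two passes on plain Python lists."""
    def survivors(seeds, keep_if_next_in_area):
        out = []
        for i, s in enumerate(seeds):
            next_in = i + 1 < len(seeds) and _in_area(s, seeds[i + 1], z, w)
            if next_in == keep_if_next_in_area:
                out.append(s)
        return out

    after_pass1 = survivors(sorted_seeds, keep_if_next_in_area=True)
    return survivors(after_pass1, keep_if_next_in_area=False)


def chain_runs(sorted_seeds: list, z: int, w: int) -> list[list]:
    """Maximal runs of consecutive seeds linked by the in-area relation."""
    runs: list[list] = []
    current: list = []
    for i, s in enumerate(sorted_seeds):
        current.append(s)
        linked = i + 1 < len(sorted_seeds) and _in_area(s, sorted_seeds[i + 1], z, w)
        if not linked:
            runs.append(current)
            current = []
    return runs
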