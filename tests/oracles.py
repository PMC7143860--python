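"""Independent brute-force oracles used only by tests.

These deliberately re-derive results by enumeration or path counting,
taking no shortcuts shared with the implementations they check.
"""

from __future__ import annotations

import numpy as np


def brute_force_roh(calls, positions, params):
    """All maximal (start, end) SNP windows satisfying the ROH constraints.

    Enumerates every window, marks it valid if all calls are homozygous
    and all internal gaps are within the limit, keeps windows that
    cannot be extended in either direction, then applies the minimum
    SNP-count and length thresholds.  Returns (start_bp, end_bp, n_snps)
    tuples for one sample on one chromosome.
    """
    calls = np.asarray(calls)
    positions = np.asarray(positions)
    n = len(calls)
    hom = (calls == 0) | (calls == 2)
    gap_ok = np.diff(positions) <= params.max_gap_bp if n > 1 else np.empty(0, bool)

    def window_valid(i, j):
        return hom[i : j + 1].all() and (j == i or gap_ok[i:j].all())

    out = []
    for i in range(n):
        for j in range(i, n):
            if not window_valid(i, j):
                continue
            left_ext = i > 0 and window_valid(i - 1, j)
            right_ext = j < n - 1 and window_valid(i, j + 1)
            if left_ext or right_ext:
                continue
            n_snps = j - i + 1
            length = positions[j] - positions[i] + 1
            if n_snps >= params.min_snps and length >= params.min_length_bp:
                out.append((int(positions[i]), int(positions[j]), n_snps))
    return sorted(out)


def wright_path_f(parents, individual):
    """Wright's path-counting inbreeding coefficient.

    F = sum over common ancestors A and non-overlapping path pairs of
    (1/2)^(n_sire + n_dam + 1) * (1 + F_A), evaluated recursively.
    ``parents`` maps id -> (sire or None, dam or None).
    """
    sire, dam = parents.get(individual, (None, None))
    if sire is None or dam is None:
        return 0.0

    def paths_up(ind, path):
        # all ancestor paths (ancestor, tuple of intermediate ids incl. ind)
        yield ind, path
        s, d = parents.get(ind, (None, None))
        for p in (s, d):
            if p is not None:
                yield from paths_up(p, path + (ind,))

    total = 0.0
    for anc1, p1 in paths_up(sire, ()):
        for anc2, p2 in paths_up(dam, ()):
            if anc1 != anc2:
                continue
            # paths must not share any individual besides the ancestor
            if set(p1) & set(p2):
                continue
            n_links = len(p1) + len(p2) + 1
            total += 0.5**n_links * (1.0 + wright_path_f(parents, anc1))
    return total


def point_in_segments(position, chromosome, segments):
    """Sample ids with at least one segment covering the position."""
    return {
        s.sample_id
        for s in segments
        if s.chromosome == chromosome and s.start_bp <= position <= s.end_bp
    }
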