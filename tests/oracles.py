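"""Independent reference implementations used as test oracles.

These deliberately share no code with the package: the aligner oracle is an
exhaustive Hamming-distance scan over raw ASCII bytes, and the BH oracle is
a textbook step-up written directly from the procedure's definition.
"""

from __future__ import annotations

import numpy as np

_COMP = str.maketrans("ACGTN", "TGCAN")


def revcomp(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


def oracle_align(read: str, ref_entries: dict[str, str], cap: int):
    """Exhaustive scan over every offset of every unigene and both strands.

    Returns (min_mismatches, best_placements) where best_placements is the
    set of (unigene_id, start, strand) achieving the minimum, restricted to
    placements with at most ``cap`` mismatches; (None, empty set) when the
    read is unmappable. N anywhere counts as a mismatch.
    """
    L = len(read)
    best = cap + 1
    hits: list[tuple[int, str, int, str]] = []
    for strand, oriented in (("+", read), ("-", revcomp(read))):
        r = np.frombuffer(oriented.encode(), dtype=np.uint8)
        for uid, seq in ref_entries.items():
            if len(seq) < L:
                continue
            s = np.frombuffer(seq.encode(), dtype=np.uint8)
            windows = np.lib.stride_tricks.sliding_window_view(s, L)
            mm = (
                (windows != r[None, :])
                | (windows == ord("N"))
                | (r[None, :] == ord("N"))
            ).sum(axis=1)
            for start in np.nonzero(mm <= cap)[0]:
                hits.append((int(mm[start]), uid, int(start), strand))
    if not hits:
        return None, set()
    best = min(h[0] for h in hits)
    return best, {(uid, start, strand) for m, uid, start, strand in hits if m == best}


def oracle_bh(p_values) -> np.ndarray:
    """Textbook Benjamini–Hochberg step-up adjusted p-values."""
    p = np.asarray(p_values, dtype=float)
    m = p.size
    order = np.argsort(p, kind="mergesort")
    adj = np.empty(m)
    running = 1.0
    for rank in range(m, 0, -1):
        i = order[rank - 1]
        running = min(running, p[i] * m / rank)
        adj[i] = running
    return adj
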