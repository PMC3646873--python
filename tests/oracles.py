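"""Independent brute-force reference implementations.

These work on plain HSP attribute access with naive double loops and
never share code with the package's logic module; tests compare the two
routes on randomized sessions.
"""

from collections import Counter


def brute_visible(hsps, ranges):
    """ranges: {param: (lo, hi)}; inclusive bounds, conjunction."""
    out = []
    for h in hsps:
        ok = True
        for name, (lo, hi) in ranges.items():
            v = getattr(h, name)
            if lo is not None and v < lo:
                ok = False
            if hi is not None and v > hi:
                ok = False
        if ok:
            out.append(h)
    return out


def subjects_of(hsps, qid):
    return {h.subject_id for h in hsps if h.query_id == qid}


def brute_common(hsps, selected):
    """Subjects hit by every selected query."""
    shared = None
    for qid in selected:
        s = subjects_of(hsps, qid)
        shared = s if shared is None else shared & s
    return shared or set()


def brute_cross(hsps_ab, hsps_ba, self_mode=False):
    """Unordered (a, b) pairs with hits in both directions."""
    pairs = set()
    for h in hsps_ab:
        for g in hsps_ba:
            if h.subject_id == g.query_id and h.query_id == g.subject_id:
                if self_mode:
                    if h.query_id == h.subject_id:
                        continue
                    pairs.add(tuple(sorted((h.query_id, h.subject_id))))
                else:
                    pairs.add((h.query_id, h.subject_id))
    return pairs


def brute_best_subject(hsps, qid):
    """Top-ranked subject of one query: lowest e-value, then highest
    bitscore, then highest coverage, then smallest subject id."""
    best = None
    best_key = None
    for h in hsps:
        if h.query_id != qid:
            continue
        key = (h.evalue, -h.bitscore, -h.coverage, h.subject_id)
        if best_key is None or key < best_key:
            best_key = key
            best = h.subject_id
    return best


def brute_rbh(hsps_ab, hsps_ba, self_mode=False):
    pairs = set()
    if self_mode:
        # the trivial (x, x) match is excluded from the ranking domain
        dom = [h for h in hsps_ab if h.query_id != h.subject_id]
        for a, b in brute_cross(hsps_ab, hsps_ba, self_mode=True):
            if brute_best_subject(dom, a) == b and brute_best_subject(dom, b) == a:
                pairs.add(tuple(sorted((a, b))))
        return pairs
    for a, b in brute_cross(hsps_ab, hsps_ba):
        if brute_best_subject(hsps_ab, a) == b and brute_best_subject(hsps_ba, b) == a:
            pairs.add((a, b))
    return pairs


def brute_multiple(hsps):
    """{(query, subject): hsp count} restricted to counts >= 2."""
    counts = Counter((h.query_id, h.subject_id) for h in hsps)
    return {pair: n for pair, n in counts.items() if n >= 2}
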