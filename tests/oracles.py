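"""Independent brute-force reference implementations used as test oracles.

These are deliberately written with naive data structures (per-position
sets, exhaustive enumeration) and share no code with the package.
"""

from __future__ import annotations

from itertools import combinations


def n50_bruteforce(lengths):
    """Largest L such that sequences of length >= L sum to >= half the total."""
    total = sum(lengths)
    best = 0
    for cand in sorted(set(lengths), reverse=True):
        if sum(l for l in lengths if l >= cand) * 2 >= total:
            best = cand
            break
    return best


def lis_length_bruteforce(values):
    """Length of the longest strictly increasing subsequence by enumeration."""
    n = len(values)
    for size in range(n, 0, -1):
        for idxs in combinations(range(n), size):
            seq = [values[i] for i in idxs]
            if all(a < b for a, b in zip(seq, seq[1:])):
                return size
    return 0


def single_coverage_bruteforce(alignments, min_keep_len):
    """Greedy single-coverage filter on per-position sets.

    Mirrors the stated rule: candidates in descending score order (ties:
    longer combined span, then lexicographic ids/coords); each candidate is
    trimmed to its largest accepted-free sub-interval per axis (ties toward
    the lower coordinate) with proportional integer-floor trimming of the
    paired axis; remnants shorter than ``min_keep_len`` on either axis drop.
    Returns tuples (query_id, q_start, q_end, ref_id, r_start, r_end, strand).
    """
    items = [
        {
            "qid": a.query_id, "qs": a.q_start, "qe": a.q_end,
            "rid": a.ref_id, "rs": a.r_start, "re": a.r_end,
            "strand": a.strand, "score": a.score,
        }
        for a in alignments
    ]
    items.sort(
        key=lambda d: (
            -d["score"], -((d["qe"] - d["qs"]) + (d["re"] - d["rs"])),
            d["qid"], d["rid"], d["qs"], d["rs"],
        )
    )
    covered_ref: dict[str, set[int]] = {}
    covered_query: dict[str, set[int]] = {}
    kept = []

    def largest_free_run(start, end, covered):
        runs = []
        run_start = None
        for x in range(start, end + 1):
            free = x < end and x not in covered
            if free and run_start is None:
                run_start = x
            elif not free and run_start is not None:
                runs.append((run_start, x))
                run_start = None
        if not runs:
            return None
        return max(runs, key=lambda r: (r[1] - r[0], -r[0]))

    for d in items:
        cur = dict(d)
        while True:
            rset = covered_ref.setdefault(cur["rid"], set())
            qset = covered_query.setdefault(cur["qid"], set())
            free_r = largest_free_run(cur["rs"], cur["re"], rset)
            if free_r is None:
                cur = None
                break
            if free_r != (cur["rs"], cur["re"]):
                rs2, re2 = free_r
                rspan = cur["re"] - cur["rs"]
                qspan = cur["qe"] - cur["qs"]
                dlow = (rs2 - cur["rs"]) * qspan // rspan
                dhigh = (cur["re"] - re2) * qspan // rspan
                if cur["strand"] == "+":
                    qs2, qe2 = cur["qs"] + dlow, cur["qe"] - dhigh
                else:
                    qs2, qe2 = cur["qs"] + dhigh, cur["qe"] - dlow
                if qe2 <= qs2:
                    cur = None
                    break
                cur.update(rs=rs2, re=re2, qs=qs2, qe=qe2)
                continue
            free_q = largest_free_run(cur["qs"], cur["qe"], qset)
            if free_q is None:
                cur = None
                break
            if free_q != (cur["qs"], cur["qe"]):
                qs2, qe2 = free_q
                rspan = cur["re"] - cur["rs"]
                qspan = cur["qe"] - cur["qs"]
                dlow = (qs2 - cur["qs"]) * rspan // qspan
                dhigh = (cur["qe"] - qe2) * rspan // qspan
                if cur["strand"] == "+":
                    rs2, re2 = cur["rs"] + dlow, cur["re"] - dhigh
                else:
                    rs2, re2 = cur["rs"] + dhigh, cur["re"] - dlow
                if re2 <= rs2:
                    cur = None
                    break
                cur.update(rs=rs2, re=re2, qs=qs2, qe=qe2)
                continue
            break
        if cur is None:
            continue
        if min(cur["qe"] - cur["qs"], cur["re"] - cur["rs"]) < min_keep_len:
            continue
        kept.append(cur)
        covered_ref[cur["rid"]].update(range(cur["rs"], cur["re"]))
        covered_query[cur["qid"]].update(range(cur["qs"], cur["qe"]))
    return sorted(
        (d["qid"], d["qs"], d["qe"], d["rid"], d["rs"], d["re"], d["strand"])
        for d in kept
    )
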