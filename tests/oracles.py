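"""Independent reference implementations used to cross-check the package.

Everything here is deliberately written from first principles — exhaustive
enumeration and direct pair-table walks — and stays independent of the code
paths it validates.
"""

from __future__ import annotations

import re

PAIR_W = {("G", "C"): 3, ("C", "G"): 3, ("A", "T"): 2, ("T", "A"): 2,
          ("G", "T"): 1, ("T", "G"): 1}


# --- folding: exhaustive enumeration of all non-crossing structures -------

def enumerate_structures(seq: str, min_loop: int = 3):
    """Yield every valid pseudoknot-free pair set as a frozenset of pairs."""
    s = seq.upper().replace("U", "T")

    def rec(i, j):
        if i > j:
            yield frozenset()
            return
        yield from rec(i + 1, j)
        for k in range(i + min_loop + 1, j + 1):
            if (s[i], s[k]) in PAIR_W:
                for left in rec(i + 1, k - 1):
                    for right in rec(k + 1, j):
                        yield left | right | {(i, k)}

    yield from rec(0, len(s) - 1)


def best_score_by_enumeration(seq: str, min_loop: int = 3) -> int:
    s = seq.upper().replace("U", "T")
    best = 0
    for pairs in enumerate_structures(s, min_loop):
        score = sum(PAIR_W[(s[i], s[k])] for i, k in pairs)
        if score > best:
            best = score
    return best


# --- hairpin criteria: direct pair-table duplex walk ----------------------

def duplex_annotate(structure, mature_interval, max_mismatch=4, max_bulge_nt=2,
                    mature_len=(19, 25)):
    """Re-derive the hairpin-criteria verdict straight from the pair table.

    Returns a dict with the component verdicts plus the overall 'passed'.
    """
    db = structure.dotbracket
    pt = structure.pair_table
    m_s, m_e = mature_interval
    n_stems = len(re.findall(r"\(\.*\)", db))

    n_mismatch = sum(1 for i in range(m_s, m_e) if pt[i] is None)
    paired = [i for i in range(m_s, m_e) if pt[i] is not None]
    asym = 0
    for a, b in zip(paired, paired[1:]):
        asym += abs((b - a - 1) - (abs(pt[a] - pt[b]) - 1))

    in_one_arm = False
    if "(" in db and n_stems == 1:
        first = min(i for i, p in enumerate(pt) if p is not None)
        last = max(i for i, p in enumerate(pt) if p is not None)
        loop_match = re.search(r"\(\.*\)", db)
        loop_lo = loop_match.start() + 1
        loop_hi = loop_match.end() - 1
        in_one_arm = (first <= m_s and m_e <= loop_lo) or \
                     (loop_hi <= m_s and m_e <= last + 1)

    duplex_partners = [pt[i] for i in range(m_s, max(m_s, m_e - 2))
                       if pt[i] is not None]
    overhang_ok = False
    star = None
    if duplex_partners:
        lo = min(duplex_partners)
        hi = min(len(db), max(duplex_partners) + 3)
        star = (lo, hi)
        overhang_ok = (all(t < m_s or t >= m_e for t in duplex_partners)
                       and (hi <= m_s or lo >= m_e))

    length_ok = mature_len[0] <= (m_e - m_s) <= mature_len[1]
    passed = (n_stems == 1 and in_one_arm and overhang_ok and length_ok
              and n_mismatch <= max_mismatch and asym <= max_bulge_nt)
    return {"n_stems": n_stems, "n_mismatch": n_mismatch, "asym": asym,
            "in_one_arm": in_one_arm, "overhang_ok": overhang_ok,
            "star": star, "passed": passed}


# --- adapter trimming: brute scan over offsets and mismatch counts --------

def trim_by_scan(read, adapter, min_overlap=6):
    read = read.upper()
    adapter = adapter.upper()
    for start in range(len(read)):
        k = min(len(adapter), len(read) - start)
        if k < min_overlap:
            break
        mismatches = sum(1 for a, b in zip(read[start:start + k], adapter[:k])
                         if a != b)
        if mismatches <= 1:
            return read[:start]
    return None


# --- target expectation: exhaustive alignment enumeration -----------------

_RC = str.maketrans("ACGT", "TGCA")


def _rc(s):
    return s.upper().replace("U", "T").translate(_RC)[::-1]


def _col_cost(m, c, pos):
    if m == "-" or c == "-":
        pen = 2.0
    elif m == c:
        pen = 0.0
    elif (m == "G" and c == "A") or (m == "T" and c == "C"):
        pen = 0.5
    else:
        pen = 1.0
    if pen and 2 <= pos <= 13:
        pen *= 2
    return pen


def _alignment_cost(m_aln, c_aln):
    total, consumed = 0.0, 0
    for mc, cc in zip(m_aln, c_aln):
        if mc != "-":
            consumed += 1
        total += _col_cost(mc, cc, max(consumed, 1))
    return total


def best_expectation_by_enumeration(mirna, site, max_gaps=1):
    """Minimum expectation over all alignments of the miRNA against one
    site, enumerating every placement of at most ``max_gaps`` gaps."""
    m = mirna.upper().replace("U", "T")
    c = _rc(site)
    M, L = len(m), len(c)
    candidates = []
    if L == M:
        candidates.append((m, c))
    if max_gaps >= 1:
        if L == M - 1:  # one gap in the target strand
            for g in range(M):
                candidates.append((m, c[:g] + "-" + c[g:]))
        if L == M + 1:  # one gap in the miRNA strand
            for g in range(M + 1):
                candidates.append((m[:g] + "-" + m[g:], c))
    if not candidates:
        return float("inf")
    return min(_alignment_cost(a, b) for a, b in candidates)


def scan_transcript_by_enumeration(mirna, transcript, max_gaps=1):
    """Per-start best expectation over window lengths M-1, M, M+1."""
    m = mirna.upper().replace("U", "T")
    t = transcript.upper().replace("U", "T")
    M = len(m)
    out = {}
    for s in range(len(t)):
        best = float("inf")
        for L in (M - 1, M, M + 1):
            if L < 1 or s + L > len(t) or abs(L - M) > max_gaps:
                continue
            best = min(best, best_expectation_by_enumeration(
                m, t[s:s + L], max_gaps))
        out[s] = best
    return out
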