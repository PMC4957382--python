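"""miRNA target prediction by position-weighted complementarity scoring.

The expectation score follows the scheme popularized by psRNATarget /
Allen et al.: per aligned position, a mismatch costs 1.0, a G:U wobble 0.5
and a gap 2.0; penalties are doubled when the miRNA position (counted from
its 5' end) falls in the seed/core region, positions 2-13.  A perfect
Watson-Crick duplex scores 0.  Sites up to a configurable maximum
expectation (default 3.0) are reported; a penalized column at miRNA
positions 9-11 calls the site translational inhibition, otherwise cleavage.

Alignments are represented as two equal-length strings: the miRNA 5'->3'
and the reverse complement of the target site, so a Watson-Crick match is
character equality and G:U wobbles are (miRNA G vs rc A) or (miRNA U vs
rc C).  A gap column is assigned the position of the most recent miRNA base
consumed (minimum 1).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numba import njit

from .seqs import revcomp, u_to_t

MISMATCH = 1.0
WOBBLE = 0.5
GAP = 2.0
CORE = (2, 13)           # 1-based miRNA positions with doubled penalties
CENTRAL = (9, 11)        # mismatch here -> translational inhibition
DEFAULT_MAX_EXPECTATION = 3.0
DEFAULT_MAX_GAPS = 1

_CODE = {"A": 0, "C": 1, "G": 2, "T": 3, "U": 3}
_COMP = np.array([3, 2, 1, 0], dtype=np.int64)  # A<->T, C<->G

# half-penalty units so the DP stays integral: match 0, wobble 1,
# mismatch 2, gap 4
_PEN2 = np.full((4, 4), 2, dtype=np.int64)
for _i in range(4):
    _PEN2[_i, _i] = 0
_PEN2[2, 0] = 1   # miRNA G vs rc A  (site U)
_PEN2[3, 1] = 1   # miRNA U vs rc C  (site G)


@dataclass
class TargetHit:
    mirna_name: str
    transcript_id: str
    site_interval: tuple          # 0-based half-open on the transcript
    alignment: tuple              # (miRNA 5'->3', rc(site)) with '-' gaps
    expectation: float
    inhibition_mode: str          # 'cleavage' | 'translation'
    reference_set: str = ""


def _column_penalty(m_char: str, c_char: str, position: int) -> float:
    if m_char == "-" or c_char == "-":
        pen = GAP
    elif m_char == c_char:
        pen = 0.0
    elif (m_char == "G" and c_char == "A") or (m_char == "T" and c_char == "C"):
        pen = WOBBLE
    else:
        pen = MISMATCH
    if pen and CORE[0] <= position <= CORE[1]:
        pen *= 2
    return pen


def score_site(mirna_aligned: str, site_rc_aligned: str) -> float:
    """Expectation of one alignment (miRNA 5'->3' vs rc of the site).

    Additive over columns; raises ``ValueError`` on unequal lengths.
    """
    if len(mirna_aligned) != len(site_rc_aligned):
        raise ValueError("alignment strings of unequal length")
    m = u_to_t(mirna_aligned).replace("U", "T")
    c = u_to_t(site_rc_aligned)
    total = 0.0
    consumed = 0
    for mc, cc in zip(m, c):
        if mc != "-":
            consumed += 1
        total += _column_penalty(mc, cc, max(consumed, 1))
    return total


@njit(cache=True)
def _scan(mcodes, tcodes, comp, pen2, max_gaps, core_lo, core_hi):  # pragma: no cover
    M = mcodes.size
    n = tcodes.size
    INF = np.int64(1 << 30)
    best = np.full(n, INF, dtype=np.int64)
    bestL = np.zeros(n, dtype=np.int64)
    G = max_gaps
    dp = np.empty((M + 1, M + G + 1, G + 1), dtype=np.int64)
    for s in range(n):
        for dL in range(-G, G + 1):
            L = M + dL
            if L < 1 or s + L > n:
                continue
            for i in range(M + 1):
                for j in range(L + 1):
                    for g in range(G + 1):
                        dp[i, j, g] = INF
            dp[0, 0, 0] = 0
            for i in range(M + 1):
                for j in range(L + 1):
                    for g in range(G + 1):
                        cur = dp[i, j, g]
                        if cur >= INF:
                            continue
                        if i < M and j < L:
                            cc = comp[tcodes[s + L - 1 - j]]
                            p = pen2[mcodes[i], cc]
                            pos = i + 1
                            if p > 0 and core_lo <= pos <= core_hi:
                                p *= 2
                            if cur + p < dp[i + 1, j + 1, g]:
                                dp[i + 1, j + 1, g] = cur + p
                        if g < G:
                            if i < M:  # gap in target, consume miRNA base
                                pos = i + 1
                                p = 4
                                if core_lo <= pos <= core_hi:
                                    p *= 2
                                if cur + p < dp[i + 1, j, g + 1]:
                                    dp[i + 1, j, g + 1] = cur + p
                            if j < L:  # gap in miRNA, consume site base
                                pos = i if i > 0 else 1
                                p = 4
                                if core_lo <= pos <= core_hi:
                                    p *= 2
                                if cur + p < dp[i, j + 1, g + 1]:
                                    dp[i, j + 1, g + 1] = cur + p
            final = INF
            for g in range(G + 1):
                if dp[M, L, g] < final:
                    final = dp[M, L, g]
            if final < best[s] or (final == best[s] and L < bestL[s]):
                best[s] = final
                bestL[s] = L
    return best, bestL


def _align_traceback(mirna: str, site: str, max_gaps: int):
    """Best-scoring alignment strings for one (miRNA, site) pair.

    Small python DP mirroring the scan kernel, used only to annotate
    reported hits.
    """
    m = u_to_t(mirna)
    c = revcomp(site)
    M, L = len(m), len(c)
    INF = float("inf")
    dp = {(0, 0, 0): (0.0, None)}
    order = [(i, j, g) for i in range(M + 1) for j in range(L + 1)
             for g in range(max_gaps + 1)]
    for i, j, g in order:
        if (i, j, g) not in dp:
            continue
        cur, _ = dp[(i, j, g)]
        if i < M and j < L:
            p = _column_penalty(m[i], c[j], i + 1)
            _relax(dp, (i + 1, j + 1, g), cur + p, (i, j, g, "M"))
        if g < max_gaps:
            if i < M:
                _relax(dp, (i + 1, j, g + 1),
                       cur + _column_penalty(m[i], "-", i + 1), (i, j, g, "D"))
            if j < L:
                _relax(dp, (i, j + 1, g + 1),
                       cur + _column_penalty("-", c[j], max(i, 1)),
                       (i, j, g, "I"))
    finals = [(dp[(M, L, g)][0], g) for g in range(max_gaps + 1)
              if (M, L, g) in dp]
    if not finals:
        return None, None, INF
    cost, g = min(finals)
    state = (M, L, g)
    m_aln, c_aln = [], []
    while state != (0, 0, 0):
        _, back = dp[state]
        i, j, g, op = back
        if op == "M":
            m_aln.append(m[i])
            c_aln.append(c[j])
        elif op == "D":
            m_aln.append(m[i])
            c_aln.append("-")
        else:
            m_aln.append("-")
            c_aln.append(c[j])
        state = (i, j, g)
    return "".join(reversed(m_aln)), "".join(reversed(c_aln)), cost


def _relax(dp, state, cost, back):
    if state not in dp or cost < dp[state][0]:
        dp[state] = (cost, back)


def _inhibition_mode(m_aln: str, c_aln: str) -> str:
    consumed = 0
    for mc, cc in zip(m_aln, c_aln):
        if mc != "-":
            consumed += 1
        pos = max(consumed, 1)
        if CENTRAL[0] <= pos <= CENTRAL[1]:
            if _column_penalty(mc, cc, pos) > 0:
                return "translation"
    return "cleavage"


def site_expectations(mirna: str, transcript: str,
                      max_gaps: int = DEFAULT_MAX_GAPS):
    """Best expectation (and site length) for every start position.

    Low-level view of the scan :func:`find_targets` builds on; useful for
    diagnostics and cross-checks.
    """
    mseq = u_to_t(mirna)
    t = u_to_t(transcript)
    mcodes = np.array([_CODE[ch] for ch in mseq], dtype=np.int64)
    tcodes = np.array([_CODE[ch] for ch in t], dtype=np.int64)
    best, bestL = _scan(mcodes, tcodes, _COMP, _PEN2, max_gaps,
                        CORE[0], CORE[1])
    return best / 2.0, bestL


def find_targets(mirna_name: str, mirna: str, transcripts,
                 max_expectation: float = DEFAULT_MAX_EXPECTATION,
                 max_gaps: int = DEFAULT_MAX_GAPS,
                 reference_set: str = ""):
    """All target sites of one miRNA across ``transcripts``.

    ``transcripts`` is an ordered list of ``(id, sequence)``.  Every start
    position is evaluated by a semi-global alignment of the miRNA against
    the reverse complement of the site with at most ``max_gaps`` gaps;
    overlapping reportable sites are reduced greedily (lowest expectation,
    then leftmost).  Output order is (transcript, position).
    """
    mseq = u_to_t(mirna)
    mcodes = np.array([_CODE[ch] for ch in mseq], dtype=np.int64)
    hits = []
    for tid, tseq in transcripts:
        t = u_to_t(tseq)
        if len(t) < len(mseq) - max_gaps:
            continue
        tcodes = np.array([_CODE[ch] for ch in t], dtype=np.int64)
        best, bestL = _scan(mcodes, tcodes, _COMP, _PEN2, max_gaps,
                            CORE[0], CORE[1])
        candidates = [(best[s] / 2.0, int(s), int(bestL[s]))
                      for s in range(len(t))
                      if best[s] / 2.0 <= max_expectation + 1e-12]
        candidates.sort(key=lambda x: (x[0], x[1], x[2]))
        chosen = []
        for exp, s, L in candidates:
            if all(s + L <= cs or s >= cs + cL for _, cs, cL in chosen):
                chosen.append((exp, s, L))
        chosen.sort(key=lambda x: x[1])
        for exp, s, L in chosen:
            m_aln, c_aln, cost = _align_traceback(mseq, t[s:s + L], max_gaps)
            hits.append(TargetHit(
                mirna_name=mirna_name, transcript_id=tid,
                site_interval=(s, s + L), alignment=(m_aln, c_aln),
                expectation=cost, inhibition_mode=_inhibition_mode(m_aln, c_aln),
                reference_set=reference_set))
    return hits


def search_multi_reference(mirnas, reference_sets,
                           max_expectation: float = DEFAULT_MAX_EXPECTATION,
                           max_gaps: int = DEFAULT_MAX_GAPS):
    """Search several transcript sets in priority order.

    ``mirnas`` is a list of ``(name, sequence)``; ``reference_sets`` an
    ordered list of ``(set_name, transcripts)``.  Returns ``(full, summary)``
    where ``full`` holds every hit from every set and ``summary`` keeps, per
    miRNA, only hits from the highest-priority set that yielded any (miRNAs
    with no hit anywhere appear in the summary with ``n_hits`` 0).
    """
    if not reference_sets:
        raise ValueError("at least one reference set is required")
    full = []
    summary = []
    n_hits = {}
    for name, seq in mirnas:
        chosen = None
        for set_name, transcripts in reference_sets:
            hits = find_targets(name, seq, transcripts,
                                max_expectation=max_expectation,
                                max_gaps=max_gaps, reference_set=set_name)
            full.extend(hits)
            if hits and chosen is None:
                chosen = hits
        summary.extend(chosen or [])
        n_hits[name] = len(chosen or [])
    return full, summary, n_hits


def hits_table(hits):
    import pandas as pd

    rows = [{
        "mirna": h.mirna_name, "reference_set": h.reference_set,
        "transcript": h.transcript_id, "start": h.site_interval[0],
        "end": h.site_interval[1], "expectation": h.expectation,
        "inhibition": h.inhibition_mode,
        "mirna_aligned": h.alignment[0], "site_rc_aligned": h.alignment[1],
    } for h in hits]
    return pd.DataFrame(rows)
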