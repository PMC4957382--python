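"""Novel miRNA discovery by precursor folding and hairpin-criteria evaluation.

Unannotated tags are mapped by exact substring search (sense and antisense)
to transcript/EST and rRNA references; candidate precursor windows around
each hit are folded and scored against plant miRNA annotation criteria
(single stem-loop, mature contained in one arm, limited unpaired mature
bases, limited asymmetric-bulge nucleotides, star placement by the 2-nt 3'
overhang rule).  The best passing window per tag becomes its precursor;
tags accepted on opposite arms of the same precursor are cross-linked as
mature/star partners, and precursors located in rRNA references are flagged
as rRNA-derived.
"""

from __future__ import annotations

from dataclasses import dataclass

from .seqs import revcomp, u_to_t
from .structure import (DEFAULT_MIN_LOOP, FoldedRegion, SecondaryStructure,
                        decompose_hairpin)


@dataclass(frozen=True)
class Criteria:
    """Hairpin annotation thresholds (plant miRNA community criteria)."""

    max_mismatch: int = 4          # unpaired mature bases in the duplex
    max_bulge_nt: int = 2          # total asymmetric-bulge nucleotides
    mature_len: tuple = (19, 25)   # acceptable mature length range
    min_loop: int = DEFAULT_MIN_LOOP


@dataclass(frozen=True)
class WindowScheme:
    """Candidate precursor window enumeration around a mapped tag.

    Window starts are the boundary placements (mature at the 5' edge,
    centered, at the 3' edge) plus every grid-aligned start (absolute source
    coordinates, step ``grid``) whose window still contains the mature hit,
    all restricted to ``hit +/- flank`` and clipped at the source ends.
    Absolute grid alignment means nearby tags (e.g. a mature and its star)
    enumerate identical windows, which makes arm-partner linking by shared
    precursor window well-defined.
    """

    flank: int = 150
    lengths: tuple = (80, 120, 160, 200, 250, 300)
    grid: int = 10


@dataclass(frozen=True)
class Hit:
    tag_sequence: str
    source_id: str
    position: int
    strand: str  # '+' or '-'


@dataclass
class PrecursorCandidate:
    source_id: str
    window: tuple                 # (start, end) on the source, 0-based half-open
    strand: str
    sequence: str                 # window sequence, revcomped for '-' hits
    structure: SecondaryStructure
    mature_positions: list        # [(tag_sequence, (start, end) on window)]
    source_class: str             # 'transcript' | 'rRNA'


@dataclass
class HairpinEvaluation:
    mature_interval: tuple
    star_interval: tuple          # or None when no duplex partner exists
    n_mismatch: int
    n_asym_bulge_nt: int
    overhang_ok: bool
    single_stem: bool
    mature_in_one_arm: bool
    mature_len_ok: bool
    arm: str                      # '5p' | '3p' | ''
    passed: bool


@dataclass
class NovelMiRNA:
    name: str
    mature_tag: object
    precursor: PrecursorCandidate
    evaluation: HairpinEvaluation
    arm: str
    partner_name: str = None


def map_to_references(tags, references):
    """All exact occurrences of each tag (sense and antisense) in order.

    ``references`` is an ordered list of ``(name, sequence)``.  Hits are
    returned sorted by (reference order, position, strand) with '+' before
    '-'; tags with no occurrence are simply absent.
    """
    prepared = [(name, u_to_t(seq)) for name, seq in references]
    hits = []
    for tag in tags:
        seq = tag.sequence
        rc = revcomp(seq)
        for ref_index, (name, ref_seq) in enumerate(prepared):
            per_ref = []
            for query, strand in ((seq, "+"), (rc, "-")):
                pos = ref_seq.find(query)
                while pos != -1:
                    per_ref.append((ref_index, pos, strand))
                    pos = ref_seq.find(query, pos + 1)
            per_ref.sort()
            for ref_index_, pos, strand in per_ref:
                hits.append((tag, Hit(tag_sequence=seq, source_id=name,
                                      position=pos, strand=strand)))
    return hits


def extract_window_coords(hit: Hit, tag_len: int, source_len: int,
                          scheme: WindowScheme = WindowScheme()):
    """Candidate (start, end) windows on the source containing the hit."""
    p = hit.position
    q = p + tag_len
    out = set()
    for L in scheme.lengths:
        if L >= source_len:
            out.add((0, source_len))
            continue
        lo = max(0, q - L, p - scheme.flank)
        hi = min(p, source_len - L, q + scheme.flank - L)
        if lo > hi:
            continue
        starts = {lo, hi, min(hi, max(lo, p - (L - tag_len) // 2))}
        g = (lo + scheme.grid - 1) // scheme.grid * scheme.grid
        while g <= hi:
            starts.add(g)
            g += scheme.grid
        for s in starts:
            out.add((s, s + L))
    return sorted(out, key=lambda w: (w[1] - w[0], w[0]))


def evaluate_hairpin(structure: SecondaryStructure, mature_interval,
                     criteria: Criteria = Criteria()) -> HairpinEvaluation:
    """Score one mature placement on a folded precursor window.

    Definitions (walked on the pair table):

    * ``n_mismatch`` — mature positions without a partner in the structure;
    * ``n_asym_bulge_nt`` — over consecutive paired mature positions p < q
      with partners t_p, t_q: ``|(q-p-1) - (|t_p-t_q|-1)|`` summed;
    * star — partners of the mature minus its 2-nt 3' overhang, extended by
      2 nt at the high-index end (the star's own 3' overhang), clipped;
    * ``overhang_ok`` — a star interval exists, lies outside the mature and
      all duplex partners fall on the opposite arm.
    """
    m_s, m_e = mature_interval
    n = len(structure)
    if not (0 <= m_s < m_e <= n):
        raise ValueError("mature interval outside the precursor window")
    pt = structure.pair_table
    mature_len = m_e - m_s
    lo_len, hi_len = criteria.mature_len
    mature_len_ok = lo_len <= mature_len <= hi_len

    single_stem = False
    mature_in_one_arm = False
    arm = ""
    try:
        dec = decompose_hairpin(structure)
        single_stem = dec.n_stems == 1
        if dec.stem5[0] <= m_s and m_e <= dec.stem5[1]:
            mature_in_one_arm = True
            arm = "5p"
        elif dec.stem3[0] <= m_s and m_e <= dec.stem3[1]:
            mature_in_one_arm = True
            arm = "3p"
    except ValueError:
        pass  # no pairs at all: every flag stays false

    n_mismatch = sum(1 for i in range(m_s, m_e) if pt[i] is None)

    paired = [i for i in range(m_s, m_e) if pt[i] is not None]
    n_asym = 0
    for p, q in zip(paired, paired[1:]):
        u_mature = q - p - 1
        u_opposite = abs(pt[p] - pt[q]) - 1
        n_asym += abs(u_mature - u_opposite)

    duplex_partners = [pt[i] for i in range(m_s, max(m_s, m_e - 2))
                       if pt[i] is not None]
    star_interval = None
    overhang_ok = False
    if duplex_partners:
        star_lo = min(duplex_partners)
        star_hi = min(n, max(duplex_partners) + 1 + 2)
        star_interval = (star_lo, star_hi)
        outside = all(t < m_s or t >= m_e for t in duplex_partners)
        disjoint = star_hi <= m_s or star_lo >= m_e
        overhang_ok = outside and disjoint

    passed = (single_stem and mature_in_one_arm and overhang_ok
              and mature_len_ok
              and n_mismatch <= criteria.max_mismatch
              and n_asym <= criteria.max_bulge_nt)
    return HairpinEvaluation(
        mature_interval=(m_s, m_e), star_interval=star_interval,
        n_mismatch=n_mismatch, n_asym_bulge_nt=n_asym,
        overhang_ok=overhang_ok, single_stem=single_stem,
        mature_in_one_arm=mature_in_one_arm, mature_len_ok=mature_len_ok,
        arm=arm, passed=passed)


def evaluate_candidate(candidate: PrecursorCandidate,
                       criteria: Criteria = Criteria()) -> HairpinEvaluation:
    """Evaluate a candidate carrying exactly one mature position."""
    if len(candidate.mature_positions) != 1:
        raise ValueError("exactly one mature position must be under evaluation")
    _, interval = candidate.mature_positions[0]
    return evaluate_hairpin(candidate.structure, interval, criteria)


class _RegionCache:
    """Per-(source, strand, region) fold matrices shared across windows."""

    def __init__(self, min_loop):
        self.min_loop = min_loop
        self._cache = {}

    def get(self, source_id, strand, source_seq, region):
        key = (source_id, strand, region)
        if key not in self._cache:
            rs, re_ = region
            seq = source_seq[rs:re_]
            if strand == "-":
                seq = revcomp(seq)
            self._cache[key] = FoldedRegion(seq, min_loop=self.min_loop)
        return self._cache[key]


def _window_structure(cache, source_id, strand, source_seq, region, window):
    """Structure of a source-coordinate window, read from the region fold."""
    rs, re_ = region
    s, e = window
    folded = cache.get(source_id, strand, source_seq, region)
    if strand == "+":
        return folded.subfold(s - rs, e - rs)
    return folded.subfold(re_ - e, re_ - s)


def _mature_on_window(hit_pos, tag_len, window, strand):
    s, e = window
    if strand == "+":
        return (hit_pos - s, hit_pos + tag_len - s)
    return (e - (hit_pos + tag_len), e - hit_pos)


def discover(tags, transcript_reference, rrna_reference,
             criteria: Criteria = Criteria(),
             scheme: WindowScheme = WindowScheme(),
             min_count: int = 5,
             require_star_tag: bool = False,
             name_prefix: str = "novel"):
    """Accept novel miRNAs from unannotated tags.

    For each tag with a per-library count of at least ``min_count`` in some
    library, every exact hit on the transcript and rRNA references is
    expanded into candidate windows; the best passing window (highest fold
    score, ties broken by shortest window then leftmost start) becomes the
    tag's precursor.  Tags accepted on opposite arms of one precursor are
    re-anchored to the best window in which both pass and cross-linked as
    partners.  ``require_star_tag=True`` is a strict mode keeping only
    miRNAs whose star sequence is itself present among the input tags.

    Names are assigned deterministically: ``<prefix>-1..n`` by descending
    summed count, ties by sequence.
    """
    references = list(transcript_reference) + list(rrna_reference)
    rrna_names = {name for name, _ in rrna_reference}
    source_seqs = {name: u_to_t(seq) for name, seq in references}
    source_index = {name: i for i, (name, _) in enumerate(references)}

    eligible = [t for t in tags if t.max_count() >= min_count]
    cache = _RegionCache(criteria.min_loop)
    hits = map_to_references(eligible, references)

    # per tag: all passing candidates, for best selection and re-linking
    passing: dict = {}
    for tag, hit in hits:
        src = source_seqs[hit.source_id]
        tag_len = len(hit.tag_sequence)
        rs = max(0, hit.position - scheme.flank)
        re_ = min(len(src), hit.position + tag_len + scheme.flank)
        region = (rs, re_)
        for window in extract_window_coords(hit, tag_len, len(src), scheme):
            structure = _window_structure(cache, hit.source_id, hit.strand,
                                          src, region, window)
            interval = _mature_on_window(hit.position, tag_len, window,
                                         hit.strand)
            ev = evaluate_hairpin(structure, interval, criteria)
            if ev.passed:
                cand = PrecursorCandidate(
                    source_id=hit.source_id, window=window, strand=hit.strand,
                    sequence=structure.sequence, structure=structure,
                    mature_positions=[(hit.tag_sequence, interval)],
                    source_class="rRNA" if hit.source_id in rrna_names
                    else "transcript")
                passing.setdefault(id(tag), (tag, []))[1].append((cand, ev))

    def cand_key(item):
        cand, _ = item
        s, e = cand.window
        return (-cand.structure.score, e - s, s, source_index[cand.source_id],
                0 if cand.strand == "+" else 1)

    records = []
    for tag, cands in passing.values():
        cands.sort(key=cand_key)
        cand, ev = cands[0]
        records.append(NovelMiRNA(name="", mature_tag=tag, precursor=cand,
                                  evaluation=ev, arm=ev.arm))

    _link_arm_partners(records, passing)

    if require_star_tag:
        tag_seqs = {t.sequence for t in eligible}
        records = [r for r in records if _star_sequence(r) in tag_seqs]

    records.sort(key=lambda r: (-sum(r.mature_tag.counts.values()),
                                r.mature_tag.sequence))
    for i, r in enumerate(records, start=1):
        r.name = f"{name_prefix}-{i}"
    name_of = {id(r.mature_tag): r.name for r in records}
    for r in records:
        if r.partner_name is not None:
            r.partner_name = name_of.get(r.partner_name)
    return records


def _star_sequence(record: NovelMiRNA):
    ev = record.evaluation
    if ev.star_interval is None:
        return None
    s, e = ev.star_interval
    return record.precursor.sequence[s:e]


def _link_arm_partners(records, passing):
    """Re-anchor overlapping opposite-arm records onto a common best window
    (one in which both matures pass) and cross-link them as partners."""
    for i in range(len(records)):
        for j in range(i + 1, len(records)):
            a, b = records[i], records[j]
            if a.partner_name is not None or b.partner_name is not None:
                continue
            pa, pb = a.precursor, b.precursor
            if (pa.source_id != pb.source_id or pa.strand != pb.strand):
                continue
            if pa.window[1] <= pb.window[0] or pb.window[1] <= pa.window[0]:
                continue
            shared = _common_windows(a, b, passing)
            if not shared:
                continue
            (cand_a, ev_a), (cand_b, ev_b) = shared[0]
            if {ev_a.arm, ev_b.arm} != {"5p", "3p"}:
                continue
            a.precursor, a.evaluation, a.arm = cand_a, ev_a, ev_a.arm
            b.precursor, b.evaluation, b.arm = cand_b, ev_b, ev_b.arm
            a.partner_name = id(b.mature_tag)
            b.partner_name = id(a.mature_tag)


def _common_windows(a, b, passing):
    """Windows in which both records' matures pass, best first."""
    _, cands_a = passing[id(a.mature_tag)]
    _, cands_b = passing[id(b.mature_tag)]
    by_window_b = {(c.source_id, c.strand, c.window): (c, e)
                   for c, e in cands_b}
    shared = []
    for c, e in cands_a:
        key = (c.source_id, c.strand, c.window)
        if key in by_window_b:
            shared.append(((c, e), by_window_b[key]))
    shared.sort(key=lambda pair: (-pair[0][0].structure.score,
                                  pair[0][0].window[1] - pair[0][0].window[0],
                                  pair[0][0].window[0]))
    return shared


def novel_table(records):
    """Tabular report of accepted novel miRNAs (one row per miRNA)."""
    import pandas as pd

    rows = []
    for r in records:
        tag = r.mature_tag
        rows.append({
            "name": r.name,
            "sequence": tag.sequence,
            **{f"count_{lib}": n for lib, n in sorted(tag.counts.items())},
            **{f"tpm_{lib}": round(v, 4) for lib, v in sorted(tag.tpm.items())},
            "source_id": r.precursor.source_id,
            "window_start": r.precursor.window[0],
            "window_end": r.precursor.window[1],
            "strand": r.precursor.strand,
            "arm": r.arm,
            "partner": r.partner_name or "",
            "source_class": r.precursor.source_class,
            "n_mismatch": r.evaluation.n_mismatch,
            "n_asym_bulge_nt": r.evaluation.n_asym_bulge_nt,
            "structure_score": r.precursor.structure.score,
        })
    return pd.DataFrame(rows)


def precursor_gff3(records):
    """GFF3 lines (1-based inclusive) for accepted precursor loci."""
    lines = ["##gff-version 3"]
    for r in records:
        s, e = r.precursor.window
        attrs = f"ID={r.name};arm={r.arm};source_class={r.precursor.source_class}"
        if r.partner_name:
            attrs += f";partner={r.partner_name}"
        lines.append("\t".join([
            r.precursor.source_id, "mirnaome", "miRNA_primary_transcript",
            str(s + 1), str(e), f"{r.precursor.structure.score:g}",
            r.precursor.strand, ".", attrs,
        ]))
    return "\n".join(lines) + "\n"
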