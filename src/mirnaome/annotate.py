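"""ncRNA filtering and conserved-miRNA annotation.

Tags matching structural ncRNAs (rRNA, tRNA, snoRNA, snRNA) are removed
before annotation; a tag is annotated as a conserved miRNA when it equals a
known mature miRNA sequence exactly (full length, U/T-insensitive) and
reaches the count threshold (>= ``min_count`` in at least one library).
Family labels are derived from miRBase-style names by extracting the
``miR<number>`` stem.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass

import pandas as pd

from .seqs import revcomp, u_to_t

logger = logging.getLogger(__name__)

DEFAULT_MIN_COUNT = 5

_FAMILY_RE = re.compile(r"(?:^|[-_])miR(\d+)", re.IGNORECASE)


@dataclass
class NcrnaFilterResult:
    retained: list
    discarded: list
    matched_reference: dict  # tag sequence -> name of the matching ncRNA


@dataclass
class ConservedAnnotation:
    tag: object
    mirna_ids: list
    family: str
    passes_count_threshold: bool


def filter_ncrna(tags, ncrna_reference) -> NcrnaFilterResult:
    """Partition tags into (retained, discarded) against an ncRNA reference.

    A tag is discarded iff its sequence is an exact substring of any
    reference sequence or of its reverse complement.  ``matched_reference``
    records, per discarded tag, the first matching reference name (reference
    order, sense before antisense) so callers can route rRNA-matching tags
    into rRNA-derived miRNA discovery.
    """
    if not ncrna_reference:
        logger.warning("empty ncRNA reference: all tags retained")
        return NcrnaFilterResult(retained=list(tags), discarded=[],
                                 matched_reference={})
    prepared = [(name, u_to_t(seq), revcomp(seq)) for name, seq in ncrna_reference]
    retained, discarded, matched = [], [], {}
    for tag in tags:
        seq = tag.sequence
        hit = None
        for name, fwd, rev in prepared:
            if seq in fwd or seq in rev:
                hit = name
                break
        if hit is None:
            retained.append(tag)
        else:
            discarded.append(tag)
            matched[seq] = hit
    return NcrnaFilterResult(retained=retained, discarded=discarded,
                             matched_reference=matched)


def assign_family(mirna_name: str) -> str:
    """Extract the family stem: ``osa-miR156a`` -> ``miR156``;
    names without a parsable stem map to ``unassigned``."""
    m = _FAMILY_RE.search(mirna_name)
    return f"miR{m.group(1)}" if m else "unassigned"


def _family_for(ids) -> str:
    stems = {assign_family(i) for i in ids}
    stems.discard("unassigned")
    if not stems:
        return "unassigned"
    if len(stems) > 1:
        return "ambiguous"
    return stems.pop()


def match_conserved(tags, mature_reference, min_count: int = DEFAULT_MIN_COUNT,
                    substring: bool = False):
    """Annotate tags that perfectly match a mature-miRNA reference.

    ``mature_reference`` is a list of ``(name, sequence)`` pairs (RNA or DNA
    alphabet; U->T conversion is applied).  By default a match means
    full-length equality; ``substring=True`` additionally accepts tags that
    are exact substrings of a mature sequence.  Only annotations passing the
    count threshold (max per-library count >= ``min_count``) are reported as
    conserved miRNAs, but all matches are returned with the flag set.
    """
    names = [name for name, _ in mature_reference]
    if len(names) != len(set(names)):
        dupes = sorted({n for n in names if names.count(n) > 1})
        raise ValueError(f"duplicate reference names: {dupes}")
    by_seq: dict = {}
    for name, seq in mature_reference:
        by_seq.setdefault(u_to_t(seq), []).append(name)
    annotations = []
    for tag in tags:
        ids = list(by_seq.get(tag.sequence, []))
        if not ids and substring:
            for seq, ns in by_seq.items():
                if tag.sequence in seq:
                    ids.extend(ns)
        if ids:
            annotations.append(ConservedAnnotation(
                tag=tag, mirna_ids=ids, family=_family_for(ids),
                passes_count_threshold=tag.max_count() >= min_count))
    return annotations


def conserved_mirnas(annotations):
    """The annotations reported as conserved miRNAs (count threshold met)."""
    return [a for a in annotations if a.passes_count_threshold]


def summarize_families(annotations):
    """Family membership table plus the unassigned/ambiguous count.

    Returns ``(DataFrame[family, n_members], n_unassigned)``; counts
    partition the annotated set.
    """
    fam_counts: dict = {}
    unassigned = 0
    for a in annotations:
        if a.family in ("unassigned", "ambiguous"):
            unassigned += 1
        else:
            fam_counts[a.family] = fam_counts.get(a.family, 0) + 1
    table = pd.DataFrame(
        sorted(fam_counts.items(), key=lambda kv: (-kv[1], kv[0])),
        columns=["family", "n_members"],
    )
    return table, unassigned
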