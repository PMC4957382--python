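"""Raw small-RNA reads -> length-filtered, collapsed, TPM-normalized tags.

Stages mirror standard small RNA-seq practice: 3' adapter trimming (prefix
match with >= ``min_overlap`` nt overlap and at most one mismatch), dropping
reads with ambiguous base calls, collapsing identical inserts into unique
tags with counts, retaining 19-30 nt tags, and normalizing counts to tags
per million (TPM) of the library's clean-read total.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field

from Bio import SeqIO

from .seqs import DNA_ALPHABET

DEFAULT_MIN_LEN = 19
DEFAULT_MAX_LEN = 30
DEFAULT_MIN_OVERLAP = 6


@dataclass
class SequenceTag:
    """A unique small-RNA sequence with per-library counts and TPM."""

    sequence: str
    counts: dict = field(default_factory=dict)
    tpm: dict = field(default_factory=dict)

    def count(self, library_id=None) -> int:
        if library_id is None:
            return sum(self.counts.values())
        return self.counts.get(library_id, 0)

    def max_count(self) -> int:
        return max(self.counts.values()) if self.counts else 0


@dataclass
class LibraryStats:
    library_id: str
    raw_reads: int = 0
    clean_reads: int = 0
    discarded_ncrna: int = 0
    unique_tags: int = 0


def trim_adapter(read: str, adapter: str, min_overlap: int = DEFAULT_MIN_OVERLAP):
    """Return the insert before the leftmost adapter occurrence, or ``None``.

    A match is a prefix of the adapter of length >= ``min_overlap`` (clipped
    at the read end) aligned with at most one mismatch.  Absence of the
    adapter is a value, not an error.
    """
    if min_overlap < 6:
        raise ValueError("min_overlap must be >= 6")
    read = read.upper()
    adapter = adapter.upper()
    for start in range(0, len(read) - min_overlap + 1):
        k = min(len(adapter), len(read) - start)
        mismatches = 0
        for a, b in zip(read[start:start + k], adapter[:k]):
            if a != b:
                mismatches += 1
                if mismatches > 1:
                    break
        if mismatches <= 1:
            return read[:start]
    return None


def collapse(reads, library_id: str):
    """Collapse trimmed reads into unique tags for one library.

    Output is sorted by descending count then lexicographic sequence, and
    count totals are conserved.
    """
    counter = Counter(reads)
    tags = [SequenceTag(sequence=seq, counts={library_id: n})
            for seq, n in counter.items()]
    tags.sort(key=lambda t: (-t.counts[library_id], t.sequence))
    return tags


def length_filter(tags, min_len: int = DEFAULT_MIN_LEN,
                  max_len: int = DEFAULT_MAX_LEN):
    """Retain tags with ``min_len <= length <= max_len`` (inclusive)."""
    if min_len <= 0 or min_len > max_len:
        raise ValueError("invalid length bounds")
    return [t for t in tags if min_len <= len(t.sequence) <= max_len]


def normalize_tpm(tags, library_clean_total: int, library_id: str):
    """Set ``tpm = count / library_clean_total * 1e6`` for one library."""
    if library_clean_total <= 0:
        raise ValueError("library_clean_total must be positive")
    for t in tags:
        t.tpm[library_id] = t.counts.get(library_id, 0) / library_clean_total * 1e6
    return tags


def merge_libraries(per_library_tags: dict):
    """Merge per-library tag lists into tags carrying counts per library."""
    merged = {}
    for lib, tags in per_library_tags.items():
        for t in tags:
            m = merged.setdefault(t.sequence, SequenceTag(sequence=t.sequence))
            for k, v in t.counts.items():
                m.counts[k] = m.counts.get(k, 0) + v
            m.tpm.update(t.tpm)
    out = list(merged.values())
    out.sort(key=lambda t: (-sum(t.counts.values()), t.sequence))
    return out


def _valid_insert(seq: str) -> bool:
    return bool(seq) and not (set(seq) - DNA_ALPHABET)


def process_reads(reads, library_id: str, adapter: str,
                  min_overlap: int = DEFAULT_MIN_OVERLAP,
                  min_len: int = DEFAULT_MIN_LEN,
                  max_len: int = DEFAULT_MAX_LEN):
    """Full preprocessing of one library's raw read sequences.

    Reads without a recognizable adapter, with an empty insert, or containing
    ambiguous base calls ('N') are dropped as low quality.  Returns
    ``(tags, stats)`` where TPM is normalized to the clean-read total (reads
    surviving trimming and the length filter).
    """
    stats = LibraryStats(library_id=library_id, raw_reads=len(reads))
    inserts = []
    for r in reads:
        insert = trim_adapter(r, adapter, min_overlap=min_overlap)
        if insert is None or not _valid_insert(insert):
            continue
        if min_len <= len(insert) <= max_len:
            inserts.append(insert)
    stats.clean_reads = len(inserts)
    tags = collapse(inserts, library_id)
    tags = length_filter(tags, min_len=min_len, max_len=max_len)
    if stats.clean_reads:
        normalize_tpm(tags, stats.clean_reads, library_id)
    stats.unique_tags = len(tags)
    return tags, stats


def read_fastq(path):
    """Read sequences from a FASTQ file (Phred+33)."""
    return [str(rec.seq) for rec in SeqIO.parse(str(path), "fastq")]
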