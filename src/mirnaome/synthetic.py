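"""Synthetic two-library small-RNA study with machine-readable ground truth.

The generator emulates the shape of a pooled-tissue durum-wheat style
small RNA-seq experiment: two adapter-ligated libraries whose reads are
drawn from (i) conserved mature miRNAs spiked from a miRBase-style
reference, (ii) designed novel stem-loop precursors embedded in EST-like
transcripts, (iii) hairpins embedded inside rRNA backbones (rRNA-derived
miRNAs), and (iv) degradation fragments of the transcript/ncRNA backbones.
Designed hairpins are validated against the same hairpin-annotation
criteria the discovery stage applies (including recovery through the
sliding-window search), so every planted element is recoverable by
construction and recorded in a truth manifest with 0-based half-open
coordinates.

A companion qPCR simulator produces Ct tables under the comparative-Ct
model: Ct = base_ct - log2(quantity) + N(0, sd), with designed fold
changes per assay and tissue.

One integer seed drives every random draw; identical configurations give
byte-identical FASTA/FASTQ/TSV/JSON outputs.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .discovery import Criteria, WindowScheme, Hit, extract_window_coords, \
    evaluate_hairpin
from .preprocess import trim_adapter
from .qpcr import CT_COLUMNS, GROUP_EARLY, GROUP_MATURE
from .seqs import revcomp
from .structure import FoldedRegion

_BASES = np.array(list("ACGT"))

#: TruSeq small-RNA 3' adapter
DEFAULT_ADAPTER = "TGGAATTCTCGGGTGCCAAGG"


class DesignError(RuntimeError):
    """Raised when a planted element cannot be designed within the retry
    budget; the message names the offending element."""


@dataclass
class QpcrDesign:
    """Assays with designed per-tissue fold changes plus candidate
    reference assays with per-assay Ct noise SDs."""

    assays: dict = field(default_factory=lambda: {
        "miR399b": {"leaf": 0.038, "root": 0.072},
        "miR167h": {"leaf": 3.325, "root": 3.482},
        "miR444d": {"leaf": 1.0, "root": 4.982},
        "miR156n": {"leaf": 1.0, "root": 3.031},
        "miR393a": {"leaf": 2.639, "root": 1.0},
        "novel-48": {"leaf": 0.256, "root": 0.100},
    })
    reference_assay: str = "miR159"
    candidate_references: dict = field(default_factory=lambda: {
        "miR159": 0.05, "miR319": 0.5, "miR164": 0.5, "miR156": 0.5,
        "miR444": 0.5, "miR167": 0.5, "miR171": 0.5, "miR160": 0.5,
    })
    tissues: tuple = ("leaf", "root")
    n_biological: int = 3
    n_technical: int = 3
    noise_sd: float = 0.2
    base_ct: float = 25.0


@dataclass
class SimulationConfig:
    n_conserved_spikes: int = 50
    n_novel_hairpins: int = 18       # transcript-embedded
    n_rrna_hairpins: int = 2         # rRNA-embedded
    n_armpaired: int = 1             # of the transcript hairpins, both arms planted
    n_degradation_fragments: int = 120
    n_mature_reference: int = 120
    n_background_transcripts: int = 10
    reads_per_library: int = 100_000
    read_length: int = 40
    adapter: str = DEFAULT_ADAPTER
    error_rate: float = 0.01
    seed: int = 0
    library_ids: tuple = ("libA", "libB")
    mature_length: int = 21
    abundance_sigma: float = 1.0     # log-normal spread of element abundances
    degradation_fraction: float = 0.30
    min_reads_per_element: int = 10  # floor for planted miRNA elements
    qpcr: QpcrDesign = field(default_factory=QpcrDesign)

    def validate(self):
        counts = (self.n_conserved_spikes, self.n_novel_hairpins,
                  self.n_rrna_hairpins, self.n_degradation_fragments,
                  self.reads_per_library)
        if any(c < 0 for c in counts):
            raise ValueError("counts must be non-negative")
        for p in (self.error_rate, self.degradation_fraction):
            if not 0.0 <= p <= 1.0:
                raise ValueError("probabilities must lie in [0, 1]")
        if self.n_armpaired > self.n_novel_hairpins:
            raise ValueError("n_armpaired exceeds n_novel_hairpins")
        if self.qpcr.n_biological < 2:
            raise ValueError("qPCR needs >= 2 biological replicates")


@dataclass
class ReferenceBundle:
    mature_reference: list      # (name, sequence)
    ncrna_reference: list
    transcript_reference: list
    manifest: dict


def _rand_seq(rng, n, alphabet="ACGT") -> str:
    letters = np.array(list(alphabet))
    return "".join(letters[rng.integers(0, len(letters), n)])


def _trims_cleanly(seq: str, adapter: str) -> bool:
    """Planted elements must not contain chance adapter-like stretches, or
    trimming would truncate them; designs failing this are redrawn."""
    return trim_adapter(seq + adapter, adapter) == seq


def _design_stem_loop(rng, config, criteria):
    """One hairpin: mature + extension + loop + rc(extension) + rc(mature).

    The mature sits at the outer end of the 5' arm (its star at the outer
    end of the 3' arm), keeping it away from opportunistic loop-adjacent
    pairings; the loop uses only A/C so it cannot pair internally.  Each
    draw is checked against :func:`evaluate_hairpin` for both arms and
    redrawn on failure.
    """
    mlen = config.mature_length
    for _ in range(100):
        mature = _rand_seq(rng, mlen)
        ext = _rand_seq(rng, 14)
        loop = _rand_seq(rng, int(rng.integers(8, 12)), alphabet="AC")
        if not (_trims_cleanly(mature, config.adapter)
                and _trims_cleanly(revcomp(mature), config.adapter)):
            continue
        precursor = mature + ext + loop + revcomp(ext) + revcomp(mature)
        structure = FoldedRegion(precursor, criteria.min_loop).subfold(
            0, len(precursor))
        m_iv = (0, mlen)
        s_iv = (len(precursor) - mlen, len(precursor))
        ev_m = evaluate_hairpin(structure, m_iv, criteria)
        ev_s = evaluate_hairpin(structure, s_iv, criteria)
        if ev_m.passed and ev_m.arm == "5p" and ev_s.passed and ev_s.arm == "3p":
            return precursor, m_iv, s_iv
    raise DesignError("stem-loop design failed after bounded retries")


def _recoverable(source_seq, intervals, criteria, scheme):
    """True when each mature interval has a passing window, and (for two
    intervals) a window exists in which both pass — the discovery stage's
    own acceptance path."""
    per_interval = []
    region_cache = {}
    for (m_s, m_e) in intervals:
        hit = Hit(tag_sequence=source_seq[m_s:m_e], source_id="x",
                  position=m_s, strand="+")
        rs = max(0, m_s - scheme.flank)
        re_ = min(len(source_seq), m_e + scheme.flank)
        if (rs, re_) not in region_cache:
            region_cache[(rs, re_)] = FoldedRegion(source_seq[rs:re_],
                                                   criteria.min_loop)
        folded = region_cache[(rs, re_)]
        good = set()
        for (s, e) in extract_window_coords(hit, m_e - m_s, len(source_seq),
                                            scheme):
            if s < rs or e > re_:
                continue
            structure = folded.subfold(s - rs, e - rs)
            ev = evaluate_hairpin(structure, (m_s - s, m_e - s), criteria)
            if ev.passed:
                good.add((s, e))
        if not good:
            return False
        per_interval.append(good)
    if len(per_interval) == 2 and not (per_interval[0] & per_interval[1]):
        return False
    return True


def _embed(rng, precursor, flank_lo=100, flank_hi=300):
    left = _rand_seq(rng, int(rng.integers(flank_lo, flank_hi)))
    right = _rand_seq(rng, int(rng.integers(flank_lo, flank_hi)))
    return left + precursor + right, len(left)


def build_references(config: SimulationConfig,
                     criteria: Criteria = Criteria(),
                     scheme: WindowScheme = WindowScheme()) -> ReferenceBundle:
    """Design all references plus the truth manifest (read counts are
    filled in later by :func:`simulate_reads`)."""
    config.validate()
    rng = np.random.default_rng(config.seed + 1)

    mature_reference = _make_mature_reference(rng, config)
    mature_seqs = {seq for _, seq in mature_reference}

    spike_names = []
    if config.n_conserved_spikes:
        if config.n_conserved_spikes > len(mature_reference):
            raise ValueError("more spikes requested than reference entries")
        idx = rng.choice(len(mature_reference), size=config.n_conserved_spikes,
                         replace=False)
        spike_names = [mature_reference[i][0] for i in sorted(idx)]
    spikes = [{"name": n, "sequence": dict(mature_reference)[n]}
              for n in spike_names]

    transcripts = []
    ncrna = _make_ncrna_backbones(rng, config)
    novel = []

    def plant(kind, index, container_name=None):
        """Design, embed and validate one hairpin; returns manifest rows."""
        label = f"hairpin-{len(novel) + 1}"
        for _ in range(30):
            precursor, m_iv, s_iv = _design_stem_loop(rng, config, criteria)
            mature = precursor[m_iv[0]:m_iv[1]]
            star = precursor[s_iv[0]:s_iv[1]]
            if mature in mature_seqs or star in mature_seqs:
                continue
            source, offset = _embed(rng, precursor)
            intervals = [(offset + m_iv[0], offset + m_iv[1])]
            both_arms = kind == "armpaired"
            if both_arms:
                intervals.append((offset + s_iv[0], offset + s_iv[1]))
            if not _recoverable(source, intervals, criteria, scheme):
                continue
            if kind == "rrna":
                name = f"rRNA_{['18S', '28S', '5.8S', '25S'][index % 4]}-{index + 1}"
                source_class = "rRNA"
            else:
                name = f"transcript-{index + 1}"
                source_class = "transcript"
            rows = []
            arms = ["5p", "3p"]
            for a, (ms, me) in enumerate(intervals):
                rows.append({
                    "name": f"{label}-{arms[a]}" if both_arms else label,
                    "mature_sequence": source[ms:me],
                    "source_id": name,
                    "source_class": source_class,
                    "strand": "+",
                    "precursor_interval": [offset, offset + len(precursor)],
                    "mature_interval": [ms, me],
                    "arm": arms[a],
                    "partner": (f"{label}-{arms[1 - a]}" if both_arms else None),
                })
            return name, source, rows
        raise DesignError(f"could not design a recoverable hairpin for {label}")

    for i in range(config.n_novel_hairpins):
        kind = "armpaired" if i < config.n_armpaired else "transcript"
        name, source, rows = plant(kind, i)
        transcripts.append((name, source))
        novel.extend(rows)
    for i in range(config.n_rrna_hairpins):
        name, source, rows = plant("rrna", i)
        ncrna.insert(i, (name, source))
        novel.extend(rows)

    for i in range(config.n_background_transcripts):
        transcripts.append((f"transcript-bg-{i + 1}",
                            _rand_seq(rng, int(rng.integers(500, 1200)))))

    degradation = _make_degradation(rng, config, transcripts, ncrna, novel,
                                    mature_seqs)

    manifest = {
        "config": _config_dict(config),
        "conserved": spikes,
        "novel": novel,
        "degradation": degradation,
        "read_counts": {},
        "qpcr": {
            "fold_changes": config.qpcr.assays,
            "reference_assay": config.qpcr.reference_assay,
            "noise_sd": config.qpcr.noise_sd,
        },
    }
    return ReferenceBundle(mature_reference=mature_reference,
                           ncrna_reference=ncrna,
                           transcript_reference=transcripts,
                           manifest=manifest)


_SPECIES = ("osa", "ath", "tae", "zma", "hvu", "bdi")
_FAMILIES = (156, 159, 160, 164, 166, 167, 169, 171, 172, 319, 390, 393,
             396, 399, 408, 444, 528, 827, 1130, 2916)


def _make_mature_reference(rng, config):
    entries = []
    seen_names, seen_seqs = set(), set()
    letters = "abcdefgh"
    attempts = 0
    while len(entries) < config.n_mature_reference and attempts < 10000:
        attempts += 1
        fam = int(rng.choice(_FAMILIES))
        sp = str(rng.choice(_SPECIES))
        letter = letters[int(rng.integers(0, len(letters)))]
        arm = ["", "-5p", "-3p"][int(rng.integers(0, 3))]
        name = f"{sp}-miR{fam}{letter}{arm}"
        seq = _rand_seq(rng, int(rng.integers(20, 23)))
        if name in seen_names or seq in seen_seqs:
            continue
        if not _trims_cleanly(seq, config.adapter):
            continue
        seen_names.add(name)
        seen_seqs.add(seq)
        entries.append((name, seq))
    if len(entries) < config.n_mature_reference:
        raise DesignError("mature reference generation exhausted its retries")
    return entries


def _make_ncrna_backbones(rng, config):
    out = [("rRNA_18S", _rand_seq(rng, 600)),
           ("rRNA_28S", _rand_seq(rng, 800))]
    for i in range(3):
        out.append((f"tRNA-{i + 1}", _rand_seq(rng, 75)))
    for i in range(2):
        out.append((f"snoRNA-{i + 1}", _rand_seq(rng, 110)))
    for i in range(2):
        out.append((f"snRNA-{i + 1}", _rand_seq(rng, 150)))
    return out


def _make_degradation(rng, config, transcripts, ncrna, novel, mature_seqs):
    """Uniform random 15-30 nt substrings of the backbones, avoiding the
    planted hairpin windows and any mature sequence."""
    sources = list(transcripts) + list(ncrna)
    forbidden = {}
    for row in novel:
        forbidden.setdefault(row["source_id"], []).append(
            tuple(row["precursor_interval"]))
    out = []
    seen = set(mature_seqs)
    attempts = 0
    while len(out) < config.n_degradation_fragments and attempts < 20000:
        attempts += 1
        sid, sseq = sources[int(rng.integers(0, len(sources)))]
        frag_len = int(rng.integers(15, 31))
        if len(sseq) <= frag_len:
            continue
        start = int(rng.integers(0, len(sseq) - frag_len))
        if any(start < e and start + frag_len > s
               for s, e in forbidden.get(sid, [])):
            continue
        frag = sseq[start:start + frag_len]
        if frag in seen or not _trims_cleanly(frag, config.adapter):
            continue
        seen.add(frag)
        out.append({"sequence": frag, "source_id": sid,
                    "interval": [start, start + frag_len]})
    if len(out) < config.n_degradation_fragments:
        raise DesignError("degradation fragment sampling exhausted its retries")
    return out


def _config_dict(config):
    d = dataclasses.asdict(config)
    d["library_ids"] = list(config.library_ids)
    d["qpcr"]["tissues"] = list(config.qpcr.tissues)
    return d


def _planted_elements(bundle):
    """(element_id, sequence, kind) for every read-generating element."""
    elements = []
    for row in bundle.manifest["conserved"]:
        elements.append((row["name"], row["sequence"], "conserved"))
    for row in bundle.manifest["novel"]:
        elements.append((row["name"], row["mature_sequence"], "novel"))
    for i, row in enumerate(bundle.manifest["degradation"]):
        elements.append((f"degradation-{i + 1}", row["sequence"],
                         "degradation"))
    return elements


def simulate_reads(bundle: ReferenceBundle, config: SimulationConfig):
    """Two FASTQ-ready read libraries drawn from the planted elements.

    Each read is (element sequence + 3' adapter) truncated to the read
    length, with per-base substitution errors at ``error_rate``.  Per-element
    per-library read counts are drawn log-normally, floored for planted
    miRNA elements, and recorded in the bundle manifest (they sum exactly to
    ``reads_per_library``).
    """
    if len(config.adapter) < 6:
        raise ValueError("adapter shorter than 6 nt: trimming ambiguous")
    elements = _planted_elements(bundle)
    libraries = {}
    for lib_index, lib in enumerate(config.library_ids):
        rng = np.random.default_rng(config.seed + 100 + lib_index)
        counts = _draw_counts(rng, config, elements)
        reads = []
        for (eid, seq, _), c in zip(elements, counts):
            if c == 0:
                continue
            template = (seq + config.adapter)[:config.read_length]
            reads.extend(_mutate(rng, template, c, config.error_rate))
        order = rng.permutation(len(reads))
        libraries[lib] = [(f"{lib}:read{i + 1}", reads[j])
                          for i, j in enumerate(order)]
        bundle.manifest["read_counts"][lib] = {
            eid: int(c) for (eid, _, _), c in zip(elements, counts) if c > 0}
        bundle.manifest.setdefault("read_totals", {})[lib] = int(counts.sum())
    return libraries


def _draw_counts(rng, config, elements):
    n = len(elements)
    if n == 0 or config.reads_per_library == 0:
        return np.zeros(n, dtype=np.int64)
    kinds = np.array([k for _, _, k in elements])
    w = rng.lognormal(mean=0.0, sigma=config.abundance_sigma, size=n)
    planted = kinds != "degradation"
    if planted.any() and (~planted).any():
        target = config.degradation_fraction / (1 - config.degradation_fraction)
        w[~planted] *= target * w[planted].sum() / w[~planted].sum()
    counts = rng.multinomial(config.reads_per_library, w / w.sum())
    counts = counts.astype(np.int64)
    floor = min(config.min_reads_per_element,
                config.reads_per_library // max(1, n))
    for i in np.flatnonzero(planted):
        while counts[i] < floor:
            donor = int(np.argmax(counts))
            if donor == i or counts[donor] <= floor:
                break
            move = min(floor - counts[i], counts[donor] - floor)
            counts[donor] -= move
            counts[i] += move
    return counts


def _mutate(rng, template, n_copies, error_rate):
    if error_rate == 0.0:
        return [template] * n_copies
    codes = np.array([{"A": 0, "C": 1, "G": 2, "T": 3}[c] for c in template],
                     dtype=np.int64)
    L = codes.size
    hitmask = rng.random((n_copies, L)) < error_rate
    shifts = rng.integers(1, 4, size=(n_copies, L))
    out = []
    for r in range(n_copies):
        if not hitmask[r].any():
            out.append(template)
            continue
        mutated = codes.copy()
        idx = np.flatnonzero(hitmask[r])
        mutated[idx] = (mutated[idx] + shifts[r, idx]) % 4
        out.append("".join(_BASES[mutated]))
    return out


def simulate_qpcr(config: SimulationConfig):
    """Ct table plus designed-truth fold changes.

    Quantities: 1 in the early group; the designed fold change in the
    mature group (candidate reference assays stay at 1 in both).  Ct =
    base_ct - log2(quantity) + N(0, sd) per technical measurement, with the
    per-assay SD for candidate references and the global noise SD otherwise.
    """
    design = config.qpcr
    if design.n_biological < 2:
        raise ValueError("need >= 2 biological replicates for the t-test")
    rng = np.random.default_rng(config.seed + 500)
    assay_names = list(design.assays)
    for cand in design.candidate_references:
        if cand not in assay_names:
            assay_names.append(cand)
    rows = []
    for tissue in design.tissues:
        for assay in assay_names:
            sd = design.candidate_references.get(assay, design.noise_sd)
            for group in (GROUP_EARLY, GROUP_MATURE):
                q = 1.0
                if group == GROUP_MATURE and assay in design.assays:
                    q = float(design.assays[assay].get(tissue, 1.0))
                base = design.base_ct - np.log2(q)
                for bio in range(1, design.n_biological + 1):
                    for tech in range(1, design.n_technical + 1):
                        noise = rng.normal(0.0, sd) if sd > 0 else 0.0
                        rows.append((assay, tissue, group, bio, tech,
                                     base + noise))
    ct = pd.DataFrame(rows, columns=CT_COLUMNS)
    truth = {"fold_changes": {a: dict(v) for a, v in design.assays.items()},
             "reference_assay": design.reference_assay}
    return ct, truth


# ---------------------------------------------------------------------------
# writers


def write_fasta(records, path):
    from Bio.Seq import Seq
    from Bio.SeqIO import write as seqio_write
    from Bio.SeqRecord import SeqRecord

    recs = [SeqRecord(Seq(seq), id=name, description="") for name, seq in records]
    seqio_write(recs, str(path), "fasta")


def write_fastq(reads, path):
    """Phred+33 FASTQ with constant quality 'I' (Q40)."""
    with open(path, "w") as fh:
        for read_id, seq in reads:
            fh.write(f"@{read_id}\n{seq}\n+\n{'I' * len(seq)}\n")


def write_manifest(manifest, path):
    with open(path, "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
        fh.write("\n")


def write_ct_table(ct: pd.DataFrame, path):
    ct.to_csv(path, sep="\t", index=False, float_format="%.6f")


def simulate_study(config: SimulationConfig, outdir=None):
    """End-to-end generation; optionally writes all artefacts to ``outdir``."""
    bundle = build_references(config)
    libraries = simulate_reads(bundle, config)
    ct, _ = simulate_qpcr(config)
    if outdir is not None:
        from pathlib import Path

        out = Path(outdir)
        out.mkdir(parents=True, exist_ok=True)
        write_fasta(bundle.mature_reference, out / "mature_reference.fasta")
        write_fasta(bundle.ncrna_reference, out / "ncrna_reference.fasta")
        write_fasta(bundle.transcript_reference, out / "transcripts.fasta")
        for lib, reads in libraries.items():
            write_fastq(reads, out / f"{lib}.fastq")
        write_ct_table(ct, out / "ct_table.tsv")
        write_manifest(bundle.manifest, out / "truth_manifest.json")
    return bundle, libraries, ct
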