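"""End-to-end orchestration: simulate -> preprocess -> annotate -> discover
-> predict targets -> qPCR, with a JSON run manifest.

All stage parameters live in :class:`RunConfig` (loadable from YAML; unknown
keys are rejected).  A run is fully determined by its configuration and
seed: rerunning with the same config produces byte-identical tables and
manifest.  Stage timings go to the log only, never into output files.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from . import annotate as ann
from . import discovery as disc
from . import preprocess as prep
from . import qpcr as qp
from . import synthetic as syn
from . import targets as tgt
from .structure import write_vienna

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    seed: int = 0
    simulation: syn.SimulationConfig = field(default_factory=syn.SimulationConfig)
    min_overlap: int = prep.DEFAULT_MIN_OVERLAP
    min_len: int = prep.DEFAULT_MIN_LEN
    max_len: int = prep.DEFAULT_MAX_LEN
    min_count: int = ann.DEFAULT_MIN_COUNT
    ncrna_filter: bool = True
    criteria: disc.Criteria = field(default_factory=disc.Criteria)
    windows: disc.WindowScheme = field(default_factory=disc.WindowScheme)
    require_star_tag: bool = False
    max_expectation: float = tgt.DEFAULT_MAX_EXPECTATION
    max_gaps: int = tgt.DEFAULT_MAX_GAPS
    predict_targets: bool = True
    fc_threshold: float = 2.0
    alpha: float = 0.05

    @classmethod
    def from_yaml(cls, path):
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls.from_dict(data)

    @classmethod
    def from_dict(cls, data: dict):
        def build(dc_type, payload):
            names = {f.name: f for f in dataclasses.fields(dc_type)}
            unknown = set(payload) - set(names)
            if unknown:
                raise ValueError(f"unknown config keys for "
                                 f"{dc_type.__name__}: {sorted(unknown)}")
            kwargs = {}
            for key, value in payload.items():
                ftype = names[key].type
                nested = {"SimulationConfig": syn.SimulationConfig,
                          "Criteria": disc.Criteria,
                          "WindowScheme": disc.WindowScheme,
                          "QpcrDesign": syn.QpcrDesign,
                          "syn.SimulationConfig": syn.SimulationConfig,
                          "disc.Criteria": disc.Criteria,
                          "disc.WindowScheme": disc.WindowScheme,
                          "syn.QpcrDesign": syn.QpcrDesign}.get(ftype)
                if nested is not None and isinstance(value, dict):
                    kwargs[key] = build(nested, value)
                elif key in ("library_ids", "lengths", "mature_len", "tissues") \
                        and isinstance(value, list):
                    kwargs[key] = tuple(value)
                else:
                    kwargs[key] = value
            return dc_type(**kwargs)

        return build(cls, data)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def run_all(config: RunConfig, outdir) -> dict:
    """Execute every stage into ``outdir`` and return the run manifest."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = {"parameters": _params_dict(config), "counts": {},
                "inputs": {}, "outputs": {}}
    timings = {}

    def stage(name):
        class _Timer:
            def __enter__(self_):
                self_.t0 = time.perf_counter()
                logger.info("stage %s started", name)
                return self_

            def __exit__(self_, exc_type, exc, tb):
                timings[name] = time.perf_counter() - self_.t0
                if exc_type is not None:
                    logger.error("stage %s failed: %s", name, exc)
                else:
                    logger.info("stage %s done in %.2fs", name, timings[name])
                return False

        return _Timer()

    sim = dataclasses.replace(config.simulation, seed=config.seed)

    with stage("simulate"):
        bundle, libraries, ct = syn.simulate_study(sim, outdir=out / "inputs")
    for p in sorted((out / "inputs").iterdir()):
        manifest["inputs"][p.name] = _sha256(p)

    with stage("preprocess"):
        per_lib_tags = {}
        stats = {}
        for lib, reads in libraries.items():
            seqs = [seq for _, seq in reads]
            tags, st = prep.process_reads(
                seqs, lib, sim.adapter, min_overlap=config.min_overlap,
                min_len=config.min_len, max_len=config.max_len)
            per_lib_tags[lib] = tags
            stats[lib] = st
        tags = prep.merge_libraries(per_lib_tags)
    manifest["counts"]["raw_reads"] = {k: v.raw_reads for k, v in stats.items()}
    manifest["counts"]["clean_reads"] = {k: v.clean_reads for k, v in stats.items()}
    manifest["counts"]["unique_tags"] = len(tags)

    with stage("annotate"):
        if config.ncrna_filter:
            ncres = ann.filter_ncrna(tags, bundle.ncrna_reference)
        else:
            ncres = ann.NcrnaFilterResult(retained=list(tags), discarded=[],
                                          matched_reference={})
        annotations = ann.match_conserved(ncres.retained,
                                          bundle.mature_reference,
                                          min_count=config.min_count)
        conserved = ann.conserved_mirnas(annotations)
        families, unassigned = ann.summarize_families(conserved)
    manifest["counts"]["ncrna_discarded_tags"] = len(ncres.discarded)
    manifest["counts"]["ncrna_retained_tags"] = len(ncres.retained)
    manifest["counts"]["conserved_mirnas"] = len(conserved)
    manifest["counts"]["conserved_families"] = int(len(families))
    manifest["counts"]["conserved_unassigned"] = unassigned

    with stage("discover"):
        annotated_seqs = {a.tag.sequence for a in annotations}
        unannotated = [t for t in ncres.retained
                       if t.sequence not in annotated_seqs]
        # rRNA-matching tags re-enter discovery: rRNA is searched for
        # rRNA-derived precursors even though it is filtered before
        # conserved annotation
        rrna_tags = [t for t in ncres.discarded
                     if ncres.matched_reference[t.sequence].startswith("rRNA")]
        rrna_refs = [(n, s) for n, s in bundle.ncrna_reference
                     if n.startswith("rRNA")]
        novel = disc.discover(unannotated + rrna_tags,
                              bundle.transcript_reference, rrna_refs,
                              criteria=config.criteria, scheme=config.windows,
                              min_count=config.min_count,
                              require_star_tag=config.require_star_tag)
    manifest["counts"]["novel_mirnas"] = len(novel)
    manifest["counts"]["novel_rrna_derived"] = sum(
        1 for r in novel if r.precursor.source_class == "rRNA")

    with stage("predict_targets"):
        queries = [(f"conserved:{a.mirna_ids[0]}", a.tag.sequence)
                   for a in conserved]
        queries += [(r.name, r.mature_tag.sequence) for r in novel]
        if config.predict_targets and queries:
            full, summary, n_hits = tgt.search_multi_reference(
                queries, [("transcripts", bundle.transcript_reference)],
                max_expectation=config.max_expectation,
                max_gaps=config.max_gaps)
        else:
            full, summary, n_hits = [], [], {}
    manifest["counts"]["target_hits"] = len(full)

    with stage("qpcr"):
        design = sim.qpcr
        qmat = qp.quantities_from_ct(ct, assays=design.candidate_references)
        m_values, trace = qp.genorm_stability(qmat)
        groups = [c.split(":")[1] for c in qmat.columns]
        nf = qp.normfinder_stability(qmat, groups)
        results = []
        for tissue in design.tissues:
            for assay in design.assays:
                results.append(qp.ddct_fold_change(
                    ct, assay, design.reference_assay, tissue))
        results = qp.call_differential(results, fc_threshold=config.fc_threshold,
                                       alpha=config.alpha)
    manifest["counts"]["qpcr_assays_tested"] = len(results)
    manifest["counts"]["qpcr_significant"] = sum(r.significant for r in results)

    _write_reports(out, tags, stats, annotations, conserved, families,
                   unassigned, novel, full, summary, m_values, nf, results)
    for p in sorted((out / "reports").iterdir()):
        manifest["outputs"][p.name] = _sha256(p)

    with open(out / "run_manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
        fh.write("\n")
    logger.info("timings: %s", {k: round(v, 2) for k, v in timings.items()})
    return manifest


def _params_dict(config: RunConfig):
    d = dataclasses.asdict(config)
    d["simulation"] = syn._config_dict(config.simulation)
    d["windows"]["lengths"] = list(config.windows.lengths)
    d["criteria"]["mature_len"] = list(config.criteria.mature_len)
    return d


def _write_reports(out, tags, stats, annotations, conserved, families,
                   unassigned, novel, full_hits, summary_hits, m_values, nf,
                   results):
    import pandas as pd

    rep = out / "reports"
    rep.mkdir(parents=True, exist_ok=True)

    libs = sorted(stats)
    tag_rows = [{"sequence": t.sequence,
                 **{f"count_{lib}": t.counts.get(lib, 0) for lib in libs},
                 **{f"tpm_{lib}": round(t.tpm.get(lib, 0.0), 4) for lib in libs}}
                for t in tags]
    pd.DataFrame(tag_rows).to_csv(rep / "tags.tsv", sep="\t", index=False)

    cons_rows = [{"sequence": a.tag.sequence,
                  "mirna_ids": ";".join(a.mirna_ids),
                  "family": a.family,
                  **{f"count_{lib}": a.tag.counts.get(lib, 0) for lib in libs}}
                 for a in conserved]
    pd.DataFrame(cons_rows).to_csv(rep / "conserved.tsv", sep="\t", index=False)
    families.to_csv(rep / "families.tsv", sep="\t", index=False)

    disc.novel_table(novel).to_csv(rep / "novel.tsv", sep="\t", index=False)
    (rep / "novel_precursors.gff3").write_text(disc.precursor_gff3(novel))
    write_vienna([(r.name, r.precursor.structure) for r in novel],
                 rep / "novel_precursors.vienna")

    tgt.hits_table(full_hits).to_csv(rep / "targets_full.tsv", sep="\t",
                                     index=False, float_format="%.4f")
    tgt.hits_table(summary_hits).to_csv(rep / "targets_priority.tsv", sep="\t",
                                        index=False, float_format="%.4f")

    m_values.rename("genorm_M").to_frame().assign(
        normfinder=nf).to_csv(rep / "stability.tsv", sep="\t",
                              float_format="%.6f")
    res_rows = [dataclasses.asdict(r) for r in results]
    pd.DataFrame(res_rows).to_csv(rep / "fold_changes.tsv", sep="\t",
                                  index=False, float_format="%.6f")
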