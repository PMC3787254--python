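"""Configurable multi-stage pipeline orchestration.

Stages are drawn from {initial-process, derep, chimera-hook,
community-error, cluster, rep-seqs, diversity} and declared in a flat
INI-style config.  Each stage writes its own subdirectory; a JSON
manifest records versions, parameters, seeds, and per-stage read counts.
Expensive per-sequence stages (community-error) are automatically
dereplicated before and re-replicated ("exploded") after.

Example config::

    [pipeline]
    stages = initial-process, derep, community-error, cluster, diversity

    [input]
    seqs = reads.fastq
    tags = tags.tsv

    [initial-process]
    fwd_primers = GGYTGGATHACNGCHATGTA
    rev_primers = GCRTAVGTYTCNGGRTTRTA
    max_fwd_diff = 2

    [community-error]
    refs = references.fasta

    [cluster]
    aln = aligned.fasta
    method = complete
    cutoff = 0.5
    step = 0.01
"""

from __future__ import annotations

import configparser
import json
import shlex
import subprocess
import tarfile
from pathlib import Path

from . import __version__
from .cluster import cluster_alignment, representative_sequences
from .community_error import run_error_analysis, write_outputs
from .dereplicate import dereplicate, explode
from .diversity import alpha_diversity_report, beta_diversity_report
from .initial_process import FilterConfig, PrimerSet, process_run
from .seqio import (
    Read,
    load_masked_alignment,
    load_reads,
    parse_tag_table,
    read_clust,
    write_clust,
    write_fasta,
    write_id_mapping,
    write_sample_mapping,
)

__all__ = ["PipelineError", "load_config", "run_pipeline"]

KNOWN_STAGES = (
    "initial-process",
    "derep",
    "chimera-hook",
    "community-error",
    "cluster",
    "rep-seqs",
    "diversity",
)


class PipelineError(RuntimeError):
    pass


def load_config(path: str | Path) -> configparser.ConfigParser:
    cfg = configparser.ConfigParser()
    with open(path) as fh:
        cfg.read_file(fh)
    return cfg


def _validate(cfg: configparser.ConfigParser, stages: list[str]) -> None:
    for stage in stages:
        if stage not in KNOWN_STAGES:
            raise PipelineError(f"unknown stage {stage!r}")
    if "input" not in cfg or not cfg.get("input", "seqs", fallback="").strip():
        raise PipelineError("config must name input sequence files ([input] seqs)")
    if "initial-process" in stages and not cfg.get(
        "initial-process", "fwd_primers", fallback=""
    ):
        raise PipelineError("initial-process stage requires fwd_primers")
    if "community-error" in stages and not cfg.get(
        "community-error", "refs", fallback=""
    ):
        raise PipelineError("community-error stage requires a reference FASTA")
    if "cluster" in stages and not cfg.get("cluster", "aln", fallback=""):
        raise PipelineError(
            "cluster stage requires an alignment file ([cluster] aln); "
            "alignments are produced by an external profile aligner"
        )
    for dependent in ("rep-seqs", "diversity"):
        if dependent in stages and "cluster" not in stages and not cfg.get(
            dependent, "clust", fallback=""
        ):
            raise PipelineError(f"{dependent} stage requires the cluster stage")


def run_pipeline(
    config: str | Path | configparser.ConfigParser,
    out_dir: str | Path,
    archive: bool = False,
) -> dict:
    """Run the configured stages; returns the manifest dictionary."""
    cfg = config if isinstance(config, configparser.ConfigParser) else load_config(config)
    stages = [
        s.strip()
        for s in cfg.get("pipeline", "stages", fallback="").replace(",", " ").split()
    ]
    if not stages:
        raise PipelineError("no stages configured ([pipeline] stages)")
    _validate(cfg, stages)

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seed = cfg.getint("pipeline", "seed", fallback=0)
    manifest: dict = {
        "version": __version__,
        "seed": seed,
        "stages": stages,
        "parameters": {s: dict(cfg[s]) for s in cfg.sections()},
        "counts": {},
    }

    seq_files = [Path(p) for p in cfg.get("input", "seqs").split()]
    qual_files = [Path(p) for p in cfg.get("input", "quals", fallback="").split()] or None
    tag_path = cfg.get("input", "tags", fallback="").strip()
    tags = parse_tag_table(tag_path) if tag_path else None

    # current working read set flows between stages
    reads: list[Read] = []
    for sf in seq_files:
        qp = None
        if qual_files:
            qp = qual_files[seq_files.index(sf)]
        reads.extend(load_reads(sf, qual_path=qp, sample=sf.stem))
    manifest["counts"]["input"] = len(reads)

    clust_path: Path | None = None
    aln_path: str | None = cfg.get("cluster", "aln", fallback="") or None

    for stage in stages:
        sdir = out / stage.replace("-", "_")
        sdir.mkdir(exist_ok=True)
        if stage == "initial-process":
            sec = cfg["initial-process"]
            primers = PrimerSet(
                forward=sec.get("fwd_primers").split(),
                reverse=sec.get("rev_primers", fallback="").split(),
            )
            fc = FilterConfig(
                max_fwd_diff=sec.getint("max_fwd_diff", fallback=2),
                max_rev_diff=sec.getint("max_rev_diff", fallback=1),
                max_n=sec.getint("max_ns", fallback=0),
                min_length=sec.getint("min_length", fallback=150),
                min_rq=sec.getfloat("min_rq", fallback=20.0),
                keep_primer=sec.getboolean("keep_primer", fallback=False),
            )
            report = process_run(seq_files, tags, primers, fc, sdir, qual_files)
            passed = [
                oc.trimmed for oc in report.outcomes if oc.passed and oc.trimmed
            ]
            reads = passed
            manifest["counts"][stage] = len(reads)
        elif stage == "derep":
            uniques, idmap, samplemap = dereplicate(reads)
            fdir = sdir / "filtered_sequences"
            mdir = sdir / "filtered_mapping"
            fdir.mkdir(exist_ok=True)
            mdir.mkdir(exist_ok=True)
            write_fasta(uniques, fdir / "unique.fasta")
            write_id_mapping(idmap, mdir / "ids.map")
            write_sample_mapping(samplemap, mdir / "samples.map")
            manifest["counts"][stage] = len(uniques)
        elif stage == "chimera-hook":
            command = cfg.get("chimera-hook", "command", fallback="").strip()
            if not command:
                manifest["counts"][stage] = len(reads)
                continue
            in_fa = sdir / "input.fasta"
            out_fa = sdir / "non_chimeric.fasta"
            write_fasta(reads, in_fa)
            cmd = [
                part.format(input=in_fa, output=out_fa)
                for part in shlex.split(command)
            ]
            proc = subprocess.run(cmd, capture_output=True, text=True)
            if proc.returncode != 0:
                raise PipelineError(
                    f"chimera hook failed ({proc.returncode}): {proc.stderr[:500]}"
                )
            kept = load_reads(out_fa)
            kept_ids = {r.id for r in kept}
            unknown = kept_ids - {r.id for r in reads}
            if unknown:
                raise PipelineError(
                    "chimera hook emitted unknown ids: "
                    + ", ".join(sorted(unknown)[:5])
                )
            reads = [r for r in reads if r.id in kept_ids]
            manifest["counts"][stage] = len(reads)
        elif stage == "community-error":
            refs = load_reads(cfg.get("community-error", "refs"))
            # dereplicate before the expensive per-sequence analysis,
            # then re-replicate the per-read results
            uniques, idmap, samplemap = dereplicate(reads)
            alignments, subs, indels, profiles = run_error_analysis(uniques, refs)
            exploded = explode(
                {r.id: r for r in uniques}, idmap, samplemap
            )
            write_outputs(sdir, alignments, subs, indels, profiles)
            manifest["counts"][stage] = sum(len(v) for v in exploded.values())
        elif stage == "cluster":
            sec = cfg["cluster"]
            aln = load_masked_alignment(sec.get("aln"))
            sample_map = {r.id: (r.sample or "sample") for r in reads}
            for rid in aln.ids:
                sample_map.setdefault(rid, "sample")
            cs = cluster_alignment(
                aln,
                method=sec.get("method", fallback="complete"),
                max_cutoff=sec.getfloat("cutoff", fallback=0.5),
                step=sec.getfloat("step", fallback=0.01),
                sample_map=sample_map,
            )
            clust_path = sdir / "output.clust"
            write_clust(cs, clust_path)
            manifest["counts"][stage] = len(aln.ids)
        elif stage == "rep-seqs":
            sec = cfg["rep-seqs"] if "rep-seqs" in cfg else {}
            cp = cfg.get("rep-seqs", "clust", fallback="") or clust_path
            if cp is None:
                raise PipelineError("rep-seqs: no cluster file available")
            cs = read_clust(cp)
            aln = load_masked_alignment(cfg.get("rep-seqs", "aln", fallback="") or aln_path)
            cutoff = cfg.getfloat("rep-seqs", "cutoff", fallback=0.03)
            reps = representative_sequences(cs, aln, cutoff)
            with open(sdir / "representatives.fasta", "w") as fh:
                for cid, rid, seq in reps:
                    fh.write(f">{rid} cluster={cid}\n{seq}\n")
            manifest["counts"][stage] = len(reps)
        elif stage == "diversity":
            cp = cfg.get("diversity", "clust", fallback="") or clust_path
            if cp is None:
                raise PipelineError("diversity: no cluster file available")
            cs = read_clust(cp)
            rows = alpha_diversity_report(cs)
            with open(sdir / "alpha.tsv", "w") as fh:
                fh.write("cutoff\tsample\tn_seqs\ts_obs\tshannon\tchao1\n")
                for r in rows:
                    fh.write(
                        f"{r['cutoff']:g}\t{r['sample']}\t{r['n_seqs']}\t"
                        f"{r['s_obs']}\t{r['shannon']:.6f}\t{r['chao1']:.6f}\n"
                    )
            if len(cs.samples) >= 2:
                beta_diversity_report(cs, sdir / "beta")
            manifest["counts"][stage] = len(rows)

    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
    if archive:
        with tarfile.open(out.with_suffix(".tar.gz"), "w:gz") as tf:
            tf.add(out, arcname=out.name)
    return manifest
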