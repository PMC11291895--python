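"""End-to-end orchestration: configuration, stage ordering, manifest.

The pipeline mirrors the study workflow: curate/validate a replicon
(skew + read support + SNP tiers + chimera flags -> completeness
verdict), quantify in-situ activity (ANI/MAPQ filtering -> per-gene
counts -> RPKM -> category sums, plus genome relative abundance), and
summarize features (tRNA introns, homology-hit filter).  A JSON
manifest records versions, parameters, input checksums, and every
output path, so a re-run with the same config and seeds reproduces
byte-identical tables.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import os
import platform
import sys
from dataclasses import dataclass, field
from typing import Dict, List, Optional

import pandas as pd

from . import __version__
from .core import ParameterError
from . import curation, features, io as mio, quant, skew as skewmod

logger = logging.getLogger("magqc")


@dataclass
class RunConfig:
    """Flat pipeline configuration; every field's default is the
    documented stage default, and CLI flags override file values."""

    # inputs
    fasta: Optional[str] = None
    dna_alignments: Optional[str] = None
    rna_alignments: Optional[str] = None
    genes: Optional[str] = None
    gene_categories: Optional[str] = None
    trna_table: Optional[str] = None
    hit_table: Optional[str] = None
    out_dir: str = "magqc_out"
    # stage toggles
    run_skew: bool = True
    run_validate: bool = True
    run_quantify: bool = True
    run_summarize: bool = True
    # skew stage
    skew_window: int = 1000
    skew_step: int = 10
    skew_circular: bool = True
    ori_at: str = "min"
    null_shuffles: int = 200
    null_quantile: float = 0.99
    # validation stage
    min_identity: float = 0.95
    strict_snp: float = 0.0
    relaxed_snp: float = 0.03
    snp_min_depth: int = 5
    min_depth: int = 1
    gc_window: int = 1000
    gc_z_min: float = 5.0
    join_dist: int = 1000
    waive_replication: bool = False
    # quantification stage
    quant_min_mapq: int = 10
    quant_min_ani: float = 0.97
    count_mode: str = "midpoint"
    abundance_min_identity: float = 0.95
    # misc
    seed: int = 0

    def to_file(self, path: str) -> None:
        with open(path, "w") as fh:
            for f in dataclasses.fields(self):
                value = getattr(self, f.name)
                fh.write(f"{f.name} = {'' if value is None else value}\n")

    @classmethod
    def from_file(cls, path: str, **overrides) -> "RunConfig":
        known = {f.name: f for f in dataclasses.fields(cls)}
        values: Dict[str, object] = {}
        with open(path) as fh:
            for lineno, raw in enumerate(fh, start=1):
                line = raw.strip()
                if not line or line.startswith("#"):
                    continue
                if "=" not in line:
                    raise ParameterError(f"{path}:{lineno}: expected 'key = value'")
                key, _, val = (p.strip() for p in line.partition("="))
                if key not in known:
                    raise ParameterError(f"{path}:{lineno}: unknown config key '{key}'")
                values[key] = _coerce(val, known[key].type)
        values.update({k: v for k, v in overrides.items() if v is not None})
        return cls(**values)


def _coerce(val: str, annot) -> object:
    if val == "":
        return None
    text = str(annot)
    if "bool" in text:
        return val.lower() in ("1", "true", "yes", "on")
    if "int" in text:
        return int(val)
    if "float" in text:
        return float(val)
    return val


def _sha256(path: str) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def run_pipeline(config: RunConfig) -> Dict:
    """Execute the configured stages in dependency order.

    Returns the manifest dict (also written to ``manifest.json``); a
    stage failure aborts the stages depending on it and is recorded in
    the manifest.
    """
    os.makedirs(config.out_dir, exist_ok=True)
    manifest: Dict = {
        "tool": "magqc",
        "version": __version__,
        "python": platform.python_version(),
        "parameters": dataclasses.asdict(config),
        "inputs": {},
        "stages": {},
        "outputs": [],
    }
    for name in ("fasta", "dna_alignments", "rna_alignments", "genes",
                 "gene_categories", "trna_table", "hit_table"):
        path = getattr(config, name)
        if path:
            if not os.path.exists(path):
                raise ParameterError(f"input '{name}' not found: {path}")
            manifest["inputs"][name] = {"path": path, "sha256": _sha256(path)}

    def out(name: str) -> str:
        path = os.path.join(config.out_dir, name)
        manifest["outputs"].append(path)
        return path

    sequences = mio.read_fasta(config.fasta) if config.fasta else {}
    oriter_by_rep: Dict[str, skewmod.OriTerCall] = {}

    # ---- skew stage -------------------------------------------------
    if config.run_skew and sequences:
        try:
            rows = []
            for rep_id, seq in sequences.items():
                profile = skewmod.compute_gc_skew(
                    seq, config.skew_window, config.skew_step,
                    circular=config.skew_circular, replicon_id=rep_id,
                )
                mio.write_skew_profile(out(f"skew_{rep_id}.tsv"), profile)
                if config.skew_circular and profile.n_windows >= 20:
                    amp_min = skewmod.null_amplitude_threshold(
                        seq, config.skew_window, config.skew_step,
                        n_shuffles=config.null_shuffles,
                        quantile=config.null_quantile, seed=config.seed,
                    )
                    call = skewmod.predict_ori_ter(profile, amp_min, config.ori_at)
                    oriter_by_rep[rep_id] = call
                    mio.write_oriter_call(out(f"oriter_{rep_id}.json"), call, rep_id)
                    rows.append({"replicon": rep_id, **dataclasses.asdict(call)})
            manifest["stages"]["skew"] = {"status": "ok", "replicons": len(sequences)}
        except Exception as exc:  # noqa: BLE001 - recorded, then re-raised
            manifest["stages"]["skew"] = {"status": "failed", "error": str(exc)}
            _write_manifest(config, manifest)
            raise

    # ---- validation stage -------------------------------------------
    verdicts: Dict[str, curation.CompletenessVerdict] = {}
    if config.run_validate and config.dna_alignments and sequences:
        if "skew" in manifest["stages"] and manifest["stages"]["skew"]["status"] != "ok":
            manifest["stages"]["validate"] = {"status": "skipped", "reason": "skew failed"}
        else:
            try:
                alns = mio.read_alignments(config.dna_alignments)
                for rep_id, seq in sequences.items():
                    rep_alns = [a for a in alns if a.ref_id == rep_id]
                    profile = curation.build_support_profile(
                        rep_alns, len(seq), min_identity=config.min_identity, ref_id=rep_id
                    )
                    mio.write_support_profile(out(f"support_{rep_id}.tsv"), profile)
                    gaps = curation.find_unsupported_regions(
                        profile, min_depth=config.min_depth, circular=config.skew_circular
                    )
                    snps = curation.snp_scan(
                        rep_alns, seq, min_depth=config.snp_min_depth,
                        strict_max=config.strict_snp, relaxed_max=config.relaxed_snp,
                    )
                    mio.write_variant_calls(out(f"variants_{rep_id}.tsv"), snps)
                    gc = curation.detect_gc_anomalies(
                        seq, window=config.gc_window, z_min=config.gc_z_min
                    )
                    flags = curation.flag_chimeras(
                        gc.anomalies, gaps, join_dist=config.join_dist,
                        length=len(seq), support=profile,
                    )
                    pd.DataFrame(
                        [
                            {
                                "start": f.interval[0],
                                "end": f.interval[1],
                                "evidence": ",".join(sorted(f.evidence)),
                                "gc_z": round(f.gc_z, 3),
                                "min_support": f.min_support,
                            }
                            for f in flags
                        ],
                        columns=["start", "end", "evidence", "gc_z", "min_support"],
                    ).to_csv(out(f"chimera_flags_{rep_id}.tsv"), sep="\t", index=False)
                    verdict = curation.completeness_verdict(
                        gaps, snps, oriter_by_rep.get(rep_id),
                        waive_replication=config.waive_replication,
                    )
                    verdicts[rep_id] = verdict
                    with open(out(f"verdict_{rep_id}.json"), "w") as fh:
                        json.dump(dataclasses.asdict(verdict), fh, indent=2)
                        fh.write("\n")
                manifest["stages"]["validate"] = {
                    "status": "ok",
                    "verdicts": {k: v.status for k, v in verdicts.items()},
                }
            except Exception as exc:  # noqa: BLE001
                manifest["stages"]["validate"] = {"status": "failed", "error": str(exc)}
                _write_manifest(config, manifest)
                raise

    # ---- quantification stage ---------------------------------------
    if config.run_quantify and config.rna_alignments and config.genes:
        try:
            genes = (
                mio.read_gff3(config.genes)
                if config.genes.endswith((".gff", ".gff3"))
                else mio.read_bed(config.genes)
            )
            alns = mio.read_alignments(config.rna_alignments)
            retained, summary = quant.filter_alignments(
                alns, min_mapq=config.quant_min_mapq, min_ani=config.quant_min_ani
            )
            gc_counts = quant.count_per_gene(retained, genes, count_mode=config.count_mode)
            table = quant.rpkm(gc_counts.counts, genes, gc_counts.n_fragments)
            table.counts.to_csv(out("counts.tsv"), sep="\t", index_label="gene_id")
            table.rpkm.to_csv(out("rpkm.tsv"), sep="\t", index_label="gene_id",
                              float_format="%.6g")
            if config.gene_categories:
                cats = mio.read_gene_categories(config.gene_categories)
                quant.category_matrix(table, cats).to_csv(
                    out("category_rpkm.tsv"), sep="\t", index_label="category",
                    float_format="%.6g",
                )
            ref_to_genome = {g.ref_id: g.ref_id for g in genes}
            abundance = quant.relative_abundance(
                alns, ref_to_genome, min_identity=config.abundance_min_identity,
                seed=config.seed,
            )
            abundance.to_frame().to_csv(out("abundance.tsv"), sep="\t",
                                        index_label="genome", float_format="%.6g")
            manifest["stages"]["quantify"] = {
                "status": "ok",
                "n_input": summary.n_input,
                "n_retained": summary.n_retained,
                "intergenic": gc_counts.intergenic,
            }
        except Exception as exc:  # noqa: BLE001
            manifest["stages"]["quantify"] = {"status": "failed", "error": str(exc)}
            _write_manifest(config, manifest)
            raise

    # ---- feature summaries ------------------------------------------
    if config.run_summarize and (config.trna_table or config.hit_table):
        try:
            if config.trna_table:
                with open(config.trna_table) as fh:
                    trnas = features.parse_trna_table(fh.read())
                features.intron_stats(trnas, per_genome=True).to_csv(
                    out("trna_summary.tsv"), sep="\t", index_label="genome",
                    float_format="%.6g",
                )
            if config.hit_table:
                with open(config.hit_table) as fh:
                    hits = features.parse_hit_table(fh.read())
                kept = features.filter_homology_hits(hits)
                pd.DataFrame(
                    [dataclasses.asdict(h) for h in kept]
                ).to_csv(out("esp_kept.tsv"), sep="\t", index=False)
                if any(h.category for h in kept):
                    features.category_percentages(kept).to_csv(
                        out("esp_categories.tsv"), sep="\t", index_label="category",
                        float_format="%.6g",
                    )
            manifest["stages"]["summarize"] = {"status": "ok"}
        except Exception as exc:  # noqa: BLE001
            manifest["stages"]["summarize"] = {"status": "failed", "error": str(exc)}
            _write_manifest(config, manifest)
            raise

    _write_manifest(config, manifest)
    return manifest


def _write_manifest(config: RunConfig, manifest: Dict) -> None:
    path = os.path.join(config.out_dir, "manifest.json")
    if path not in manifest["outputs"]:
        manifest["outputs"].append(path)
    with open(path, "w") as fh:
        json.dump(manifest, fh, indent=2, default=str)
        fh.write("\n")


def setup_logging(verbosity: int = 1, log_file: Optional[str] = None) -> None:
    level = logging.WARNING if verbosity == 0 else logging.INFO if verbosity == 1 else logging.DEBUG
    handlers: List[logging.Handler] = [logging.StreamHandler(sys.stderr)]
    if log_file:
        handlers.append(logging.FileHandler(log_file))
    logging.basicConfig(
        level=level,
        handlers=handlers,
        format="%(asctime)s %(name)s %(levelname)s %(message)s",
        force=True,
    )
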