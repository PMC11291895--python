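"""Readers and writers for the standard formats the pipeline touches.

FASTA goes through Biopython, SAM/BAM through pysam (the NM tag is
mandatory on ingest — alignments without it cannot pass the identity
filter and are a hard error naming the record), genes through BED
(0-based half-open) or GFF3, and all tabular outputs through pandas as
plain TSV.  Truth tables for the synthetic generator round-trip through
the same path.
"""

from __future__ import annotations

import json
import os
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple

import pandas as pd
import pysam
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .core import GeneModel, ParameterError, ReadAlignment
from .curation import SnpScanResult, SupportProfile
from .simulate import ChimeraTruth, DnaTruth, RepliconTruth
from .skew import OriTerCall, SkewProfile


# ---------------------------------------------------------------- FASTA

def read_fasta(path: str) -> Dict[str, str]:
    """Sequences keyed by the first whitespace-delimited token of the header."""
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(path, "fasta")}


def write_fasta(path: str, sequences: Mapping[str, str]) -> None:
    records = [SeqRecord(Seq(seq), id=name, description="") for name, seq in sequences.items()]
    SeqIO.write(records, path, "fasta")


# ------------------------------------------------------------- SAM/BAM

def write_sam(
    path: str,
    alns: Sequence[ReadAlignment],
    ref_lengths: Mapping[str, int],
) -> None:
    """Serialize alignment records to SAM with NM tags set."""
    header = {
        "HD": {"VN": "1.6", "SO": "unsorted"},
        "SQ": [{"SN": name, "LN": int(length)} for name, length in ref_lengths.items()],
    }
    ref_index = {name: i for i, name in enumerate(ref_lengths)}
    mode = "wb" if path.endswith(".bam") else "w"
    with pysam.AlignmentFile(path, mode, header=header) as out:
        for a in alns:
            seg = pysam.AlignedSegment(out.header)
            seg.query_name = a.read_id
            seg.reference_id = ref_index[a.ref_id]
            seg.reference_start = a.start
            length = a.end - a.start
            seg.cigarstring = f"{length}M"
            seg.query_sequence = a.seq if a.seq is not None else "N" * length
            seg.query_qualities = pysam.qualitystring_to_array("I" * length)
            seg.mapping_quality = a.mapq
            flag = 0
            if a.strand == "-":
                flag |= 0x10
            if a.proper_pair:
                flag |= 0x1 | 0x2
                if a.read_id.endswith("/2"):
                    flag |= 0x80
                else:
                    flag |= 0x40
            seg.flag = flag
            if a.mate_ref is not None and a.mate_start is not None:
                seg.next_reference_id = ref_index[a.mate_ref]
                seg.next_reference_start = a.mate_start
            seg.set_tag("NM", a.edit_distance)
            out.write(seg)


def read_alignments(path: str) -> List[ReadAlignment]:
    """Read SAM/BAM into alignment records.

    Secondary and supplementary alignments are skipped (MAPQ-based
    filtering presupposes primary placements).  A mapped record lacking
    the NM tag is a hard error naming the record.
    """
    alns: List[ReadAlignment] = []
    with pysam.AlignmentFile(path, check_sq=False) as fh:
        for seg in fh:
            if seg.is_unmapped or seg.is_secondary or seg.is_supplementary:
                continue
            if not seg.has_tag("NM"):
                raise ParameterError(
                    f"alignment record {seg.query_name} at "
                    f"{seg.reference_name}:{seg.reference_start} lacks the NM tag"
                )
            aligned_len = seg.reference_end - seg.reference_start
            alns.append(
                ReadAlignment(
                    read_id=seg.query_name,
                    ref_id=seg.reference_name,
                    start=seg.reference_start,
                    end=seg.reference_end,
                    strand="-" if seg.is_reverse else "+",
                    mapq=seg.mapping_quality,
                    edit_distance=int(seg.get_tag("NM")),
                    aligned_len=aligned_len,
                    seq=seg.query_sequence,
                    mate_ref=seg.next_reference_name if seg.is_paired else None,
                    mate_start=seg.next_reference_start if seg.is_paired else None,
                    proper_pair=bool(seg.is_proper_pair),
                )
            )
    return alns


# ----------------------------------------------------------- BED / GFF3

def read_bed(path: str) -> List[GeneModel]:
    genes: List[GeneModel] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            cols = line.split("\t")
            if len(cols) < 4:
                raise ParameterError(f"{path}:{lineno}: BED needs >= 4 columns (name required)")
            strand = cols[5] if len(cols) > 5 else "+"
            genes.append(GeneModel(cols[3], cols[0], int(cols[1]), int(cols[2]), strand))
    return genes


def write_bed(path: str, genes: Sequence[GeneModel]) -> None:
    with open(path, "w") as fh:
        for g in genes:
            fh.write(f"{g.ref_id}\t{g.start}\t{g.end}\t{g.gene_id}\t0\t{g.strand}\n")


def read_gff3(path: str, feature_types: Tuple[str, ...] = ("gene", "CDS")) -> List[GeneModel]:
    """Minimal GFF3 gene ingest: keeps the requested feature types,
    naming genes by ID= (or locus_tag=) in the attributes column."""
    genes: List[GeneModel] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            cols = line.split("\t")
            if len(cols) != 9:
                raise ParameterError(f"{path}:{lineno}: GFF3 needs 9 columns")
            if cols[2] not in feature_types:
                continue
            attrs = dict(
                kv.split("=", 1) for kv in cols[8].split(";") if "=" in kv
            )
            name = attrs.get("ID") or attrs.get("locus_tag")
            if not name:
                raise ParameterError(f"{path}:{lineno}: feature lacks ID/locus_tag")
            genes.append(GeneModel(name, cols[0], int(cols[3]) - 1, int(cols[4]), cols[6]))
    return genes


def read_gene_categories(path: str) -> Dict[str, str]:
    """Two-column gene -> category TSV."""
    df = pd.read_csv(path, sep="\t", header=None, names=["gene_id", "category"], dtype=str)
    return dict(zip(df["gene_id"], df["category"]))


# -------------------------------------------------------- truth tables

def write_replicon_truth(path: str, truths: Sequence[RepliconTruth]) -> None:
    pd.DataFrame(
        [
            {
                "replicon_id": t.replicon_id,
                "length": t.length,
                "ori_pos": t.ori_pos,
                "ter_pos": t.ter_pos,
                "skew_strength": t.skew_strength,
                "gc_content": t.gc_content,
                "seed": t.seed,
            }
            for t in truths
        ]
    ).to_csv(path, sep="\t", index=False)


def read_replicon_truth(path: str) -> List[RepliconTruth]:
    df = pd.read_csv(path, sep="\t")
    return [
        RepliconTruth(
            length=int(r.length),
            ori_pos=int(r.ori_pos),
            ter_pos=int(r.ter_pos),
            skew_strength=float(r.skew_strength),
            gc_content=float(r.gc_content),
            seed=int(r.seed),
            replicon_id=str(r.replicon_id),
        )
        for r in df.itertuples()
    ]


def write_variant_truth(path: str, truth: DnaTruth) -> None:
    pd.DataFrame(
        [
            {
                "pos": v.pos,
                "ref_base": v.ref_base,
                "alt_base": v.alt_base,
                "alt_count": v.alt_count,
                "depth": v.depth,
            }
            for v in truth.variants.values()
        ]
    ).to_csv(path, sep="\t", index=False)


def write_chimera_truth(path: str, truths: Sequence[ChimeraTruth]) -> None:
    pd.DataFrame(
        [
            {"junction_pos": t.junction_pos, "donor_a": t.donor_ids[0], "donor_b": t.donor_ids[1]}
            for t in truths
        ]
    ).to_csv(path, sep="\t", index=False)


def read_chimera_truth(path: str) -> List[ChimeraTruth]:
    df = pd.read_csv(path, sep="\t")
    return [
        ChimeraTruth(junction_pos=int(r.junction_pos), donor_ids=(str(r.donor_a), str(r.donor_b)))
        for r in df.itertuples()
    ]


# ------------------------------------------------------- stage outputs

def write_skew_profile(path: str, profile: SkewProfile) -> None:
    pd.DataFrame(
        {
            "replicon": profile.replicon_id,
            "center": profile.centers,
            "skew": profile.skew,
            "cumulative": profile.cumulative,
        }
    ).to_csv(path, sep="\t", index=False, float_format="%.6g")


def write_oriter_call(path: str, call: OriTerCall, replicon_id: str) -> None:
    with open(path, "w") as fh:
        json.dump(
            {
                "replicon": replicon_id,
                "ori_pos": call.ori_pos,
                "ter_pos": call.ter_pos,
                "amplitude": call.amplitude,
                "arm_balance": call.arm_balance,
                "classification": call.classification,
                "amplitude_min": call.amplitude_min,
            },
            fh,
            indent=2,
        )
        fh.write("\n")


def write_support_profile(path: str, profile: SupportProfile) -> None:
    pd.DataFrame({"ref_id": profile.ref_id, "pos": range(profile.length), "depth": profile.depth}).to_csv(
        path, sep="\t", index=False
    )


def write_variant_calls(path: str, result: SnpScanResult) -> None:
    pd.DataFrame(
        [
            {
                "pos": c.pos,
                "ref_base": c.ref_base,
                "alt_base": c.alt_base,
                "depth": c.depth,
                "alt_fraction": round(c.alt_fraction, 6),
                "tier": c.tier,
            }
            for c in result.calls
        ],
        columns=["pos", "ref_base", "alt_base", "depth", "alt_fraction", "tier"],
    ).to_csv(path, sep="\t", index=False)
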