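"""ANI/MAPQ-filtered per-gene counting, RPKM, and relative abundance.

Reimplements the read-counting stage of in-situ activity profiling: RNA
alignments are retained when MAPQ >= 10 and per-read identity >= 0.97
(both inclusive), fragments (read pairs, or single reads when unpaired)
are assigned to genes by the midpoint of their aligned span, counts are
normalised to RPKM = count / ((gene length / 1e3) x (mapped fragments /
1e6)), and genome-level relative abundance is computed from fragments
passing a 95% identity cutoff, with the unmapped remainder in the
denominator.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from intervaltree import IntervalTree

from .core import GeneModel, ParameterError, ReadAlignment

DEFAULT_MIN_MAPQ = 10
DEFAULT_MIN_ANI = 0.97
DEFAULT_ABUNDANCE_MIN_IDENTITY = 0.95


@dataclass
class FilterSummary:
    n_input: int
    n_retained: int
    n_fail_mapq: int
    n_fail_identity: int


def filter_alignments(
    alns: Sequence[ReadAlignment],
    min_mapq: int = DEFAULT_MIN_MAPQ,
    min_ani: float = DEFAULT_MIN_ANI,
) -> Tuple[List[ReadAlignment], FilterSummary]:
    """Retain alignments with MAPQ >= min_mapq AND identity >= min_ani.

    Both thresholds are inclusive, so MAPQ 10 and a 3-mismatch/100 bp
    read (identity exactly 0.97) are kept at the defaults.  The summary
    counts each rejection criterion independently (an alignment failing
    both is counted under both).
    """
    retained: List[ReadAlignment] = []
    fail_mapq = fail_identity = 0
    for a in alns:
        ok = True
        if a.mapq < min_mapq:
            fail_mapq += 1
            ok = False
        if a.identity() < min_ani:
            fail_identity += 1
            ok = False
        if ok:
            retained.append(a)
    return retained, FilterSummary(len(alns), len(retained), fail_mapq, fail_identity)


@dataclass
class Fragment:
    """The aligned span of one sequenced fragment (pair or single)."""

    read_id: str
    ref_id: str
    start: int
    end: int
    min_identity: float

    @property
    def midpoint(self) -> int:
        return (self.start + self.end) // 2


def fragments_from_alignments(alns: Sequence[ReadAlignment]) -> List[Fragment]:
    """Group alignment segments into fragments by (read id, reference).

    Read-pair suffixes (/1, /2) are stripped so mates collapse into one
    fragment whose span runs from the leftmost to the rightmost aligned
    base; the fragment's identity is the minimum over its segments.
    """
    grouped: Dict[Tuple[str, str], List[ReadAlignment]] = {}
    order: List[Tuple[str, str]] = []
    for a in alns:
        base_id = a.read_id.rsplit("/", 1)[0]
        key = (base_id, a.ref_id)
        if key not in grouped:
            grouped[key] = []
            order.append(key)
        grouped[key].append(a)
    fragments = []
    for key in order:
        segs = grouped[key]
        fragments.append(
            Fragment(
                read_id=key[0],
                ref_id=key[1],
                start=min(s.start for s in segs),
                end=max(s.end for s in segs),
                min_identity=min(s.identity() for s in segs),
            )
        )
    return fragments


@dataclass
class GeneCounts:
    counts: Dict[str, int]
    intergenic: int
    n_fragments: int


def count_per_gene(
    retained: Sequence[ReadAlignment],
    genes: Sequence[GeneModel],
    count_mode: str = "midpoint",
) -> GeneCounts:
    """Tally retained fragments per gene.

    In the default midpoint mode a fragment is assigned to the gene
    containing the midpoint of its aligned span (ties between
    overlapping genes broken by gene start, then gene id), so each
    fragment is counted at most once; fragments hitting no gene are
    counted as intergenic.  ``count_mode='overlap'`` instead credits a
    fragment to every gene it overlaps (fragments may then count more
    than once; intended for comparison only).
    """
    if count_mode not in ("midpoint", "overlap"):
        raise ParameterError("count_mode must be 'midpoint' or 'overlap'")
    seen = set()
    for g in genes:
        if g.gene_id in seen:
            raise ParameterError(f"duplicate gene_id {g.gene_id}")
        seen.add(g.gene_id)
    trees: Dict[str, IntervalTree] = {}
    for g in genes:
        trees.setdefault(g.ref_id, IntervalTree()).addi(g.start, g.end, g)
    counts = {g.gene_id: 0 for g in genes}
    intergenic = 0
    fragments = fragments_from_alignments(retained)
    for frag in fragments:
        tree = trees.get(frag.ref_id)
        if count_mode == "midpoint":
            hits = sorted(
                (iv.data for iv in tree.at(frag.midpoint)) if tree else [],
                key=lambda g: (g.start, g.gene_id),
            )
            if hits:
                counts[hits[0].gene_id] += 1
            else:
                intergenic += 1
        else:
            hits = [iv.data for iv in tree.overlap(frag.start, frag.end)] if tree else []
            if hits:
                for g in hits:
                    counts[g.gene_id] += 1
            else:
                intergenic += 1
    return GeneCounts(counts=counts, intergenic=intergenic, n_fragments=len(fragments))


def rpkm_value(count: int, gene_length: int, total_mapped: int) -> float:
    """RPKM = (count / (gene length in kb)) / (total mapped in millions)."""
    if total_mapped <= 0:
        raise ParameterError("total_mapped must be > 0")
    return count / ((gene_length / 1000.0) * (total_mapped / 1.0e6))


@dataclass
class ExpressionTable:
    """Per-gene fragment counts and RPKM across samples.

    ``counts`` and ``rpkm`` are genes x samples DataFrames;
    ``total_mapped`` the per-sample retained fragment totals used as the
    RPKM denominator.
    """

    counts: pd.DataFrame
    rpkm: pd.DataFrame
    total_mapped: pd.Series
    gene_lengths: pd.Series
    categories: Optional[pd.Series] = None

    def __post_init__(self) -> None:
        if (self.counts.values < 0).any():
            raise ParameterError("negative counts")
        if (self.rpkm.values < 0).any():
            raise ParameterError("negative RPKM")

    @classmethod
    def from_counts(
        cls,
        genes: Sequence[GeneModel],
        sample_counts: Mapping[str, Mapping[str, int]],
        total_mapped: Mapping[str, int],
    ) -> "ExpressionTable":
        gene_ids = [g.gene_id for g in genes]
        lengths = pd.Series({g.gene_id: g.length for g in genes}, name="length")
        counts = pd.DataFrame(
            {s: [int(sample_counts[s].get(g, 0)) for g in gene_ids] for s in sample_counts},
            index=gene_ids,
        )
        rpkm = pd.DataFrame(index=gene_ids)
        for s in counts.columns:
            total = int(total_mapped[s])
            rpkm[s] = [
                rpkm_value(c, lengths[g], total) for g, c in zip(gene_ids, counts[s])
            ]
        cats = pd.Series({g.gene_id: g.category for g in genes})
        return cls(
            counts=counts,
            rpkm=rpkm,
            total_mapped=pd.Series({s: int(total_mapped[s]) for s in sample_counts}),
            gene_lengths=lengths,
            categories=cats if cats.notna().any() else None,
        )


def rpkm(
    counts: Mapping[str, int],
    genes: Sequence[GeneModel],
    total_mapped: int,
    sample: str = "sample",
) -> ExpressionTable:
    """Single-sample convenience wrapper around ExpressionTable."""
    return ExpressionTable.from_counts(genes, {sample: counts}, {sample: total_mapped})


def relative_abundance(
    alns: Sequence[ReadAlignment],
    ref_to_genome: Mapping[str, str],
    n_unmapped: int = 0,
    min_identity: float = DEFAULT_ABUNDANCE_MIN_IDENTITY,
    seed: int = 0,
) -> pd.Series:
    """Percent of library fragments assigned to each genome.

    Fragments below the identity cutoff join the unmapped pool;
    ``n_unmapped`` adds library fragments that never aligned.  Fragments
    whose segments hit references from more than one genome are resolved
    uniformly at random with a fixed seed (ambiguous = random).
    Percentages, including "unmapped", sum to 100.
    """
    rng = np.random.default_rng(seed)
    per_genome: Dict[str, int] = {g: 0 for g in dict.fromkeys(ref_to_genome.values())}
    unmapped = int(n_unmapped)
    grouped: Dict[str, List[ReadAlignment]] = {}
    for a in alns:
        grouped.setdefault(a.read_id.rsplit("/", 1)[0], []).append(a)
    for read_id, segs in grouped.items():
        passing = [s for s in segs if s.identity() >= min_identity]
        if not passing:
            unmapped += 1
            continue
        genomes = sorted({ref_to_genome.get(s.ref_id) for s in passing} - {None})
        if not genomes:
            raise ParameterError(f"fragment {read_id}: reference not assigned to any genome")
        choice = genomes[0] if len(genomes) == 1 else genomes[int(rng.integers(len(genomes)))]
        per_genome[choice] += 1
    total = sum(per_genome.values()) + unmapped
    if total == 0:
        raise ParameterError("no fragments to profile")
    out = {g: 100.0 * n / total for g, n in per_genome.items()}
    out["unmapped"] = 100.0 * unmapped / total
    return pd.Series(out, name="relative_abundance_percent")


def category_matrix(table: ExpressionTable, gene_to_category: Mapping[str, str]) -> pd.DataFrame:
    """Sum gene RPKM into a category x sample matrix.

    Genes without a category are pooled under "unassigned"; rows are
    ordered by category code with "unassigned" last.
    """
    cats = pd.Series(
        {g: gene_to_category.get(g, "unassigned") for g in table.rpkm.index}, name="category"
    )
    mat = table.rpkm.groupby(cats).sum()
    order = sorted(c for c in mat.index if c != "unassigned")
    if "unassigned" in mat.index:
        order.append("unassigned")
    return mat.loc[order]
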