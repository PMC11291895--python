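"""tRNA intron architecture summaries and homology-hit filtering.

Archaeal tRNA genes carry introns canonically inserted between
positions 37 and 38, immediately 3' of the anticodon; some lineages
instead show pervasive introns at non-canonical positions, and genes
with multiple introns.  This module parses tRNA scanner tabular output
(tRNAscan-SE v2 dialect), censuses intron counts and positions, and
applies the eukaryotic-signature-protein (ESP) hit filter: a homology
hit survives only when the absolute subject/query length difference is
below 75% of the query length, after which hits are dereplicated to the
best hit per query.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import pandas as pd

from .core import HomologyHit, ParameterError


@dataclass
class TRNAGene:
    """One tRNA gene with its introns, 0-based half-open internally.

    The scanner's native coordinates are 1-based inclusive with begin >
    end on the minus strand; ingest normalizes to genomic start < end
    plus a strand flag, and intron intervals likewise.
    ``anticodon_start``/``anticodon_end`` (0-based half-open genomic)
    are present only when the table carries the extended anticodon
    columns.
    """

    trna_id: str
    replicon: str
    start: int
    end: int
    strand: str
    isotype: str
    anticodon: str
    introns: List[Tuple[int, int]] = field(default_factory=list)
    score: float = 0.0
    anticodon_start: Optional[int] = None
    anticodon_end: Optional[int] = None
    note: str = ""

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ParameterError(f"tRNA {self.trna_id}: end must exceed start")
        ivs = sorted(self.introns)
        for (s, e) in ivs:
            if not (self.start <= s < e <= self.end):
                raise ParameterError(f"tRNA {self.trna_id}: intron [{s},{e}) outside gene")
        for (s1, e1), (s2, e2) in zip(ivs, ivs[1:]):
            if s2 < e1:
                raise ParameterError(f"tRNA {self.trna_id}: overlapping introns")

    @property
    def n_introns(self) -> int:
        return len(self.introns)


def _native_to_interval(begin: int, end: int) -> Tuple[int, int, str]:
    """1-based inclusive native pair -> (start, end, strand) 0-based half-open."""
    if begin <= end:
        return begin - 1, end, "+"
    return end - 1, begin, "-"


def parse_trna_table(text: str) -> List[TRNAGene]:
    """Parse tRNA scanner tabular output (tRNAscan-SE v2 dialect).

    Header lines (the three-line banner) are tolerated.  Columns:
    sequence name, tRNA number, begin, end, isotype, anticodon, intron
    begin(s), intron end(s), score, and optionally a note; multi-intron
    genes carry comma-separated values in the intron columns and "0" in
    both marks no intron.  Tables with two extra integer columns after
    the score are read as carrying the anticodon begin/end.
    """
    genes: List[TRNAGene] = []
    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.rstrip("\n")
        if not line.strip():
            continue
        stripped = line.strip()
        if stripped.startswith(("Sequence", "Name", "---")) or stripped.split("\t")[0].endswith(
            ("Name", "#")
        ):
            continue
        cols = [c.strip() for c in line.split("\t")]
        if len(cols) < 9:
            raise ParameterError(f"line {lineno}: expected >= 9 tab-separated columns")
        try:
            begin, end = int(cols[2]), int(cols[3])
            intron_begins = [int(x) for x in cols[6].split(",")]
            intron_ends = [int(x) for x in cols[7].split(",")]
            score = float(cols[8])
        except ValueError as exc:
            raise ParameterError(f"line {lineno}: malformed numeric field ({exc})") from exc
        if len(intron_begins) != len(intron_ends):
            raise ParameterError(f"line {lineno}: unequal intron begin/end lists")
        start, gend, strand = _native_to_interval(begin, end)
        introns = []
        for ib, ie in zip(intron_begins, intron_ends):
            if ib == 0 and ie == 0:
                continue
            s, e, _ = _native_to_interval(ib, ie)
            introns.append((s, e))
        ac_start = ac_end = None
        note = ""
        rest = cols[9:]
        if len(rest) >= 2:
            try:
                ab, ae = int(rest[0]), int(rest[1])
            except ValueError:
                note = " ".join(rest)
            else:
                if ab != 0 or ae != 0:
                    ac_start, ac_end, _ = _native_to_interval(ab, ae)
                note = " ".join(rest[2:])
        elif rest:
            note = rest[0]
        genes.append(
            TRNAGene(
                trna_id=f"{cols[0]}.trna{cols[1]}",
                replicon=cols[0],
                start=start,
                end=gend,
                strand=strand,
                isotype=cols[4],
                anticodon=cols[5],
                introns=sorted(introns),
                score=score,
                anticodon_start=ac_start,
                anticodon_end=ac_end,
                note=note,
            )
        )
    return genes


def write_trna_table(genes: Sequence[TRNAGene]) -> str:
    """Serialize genes back to the scanner tabular dialect (with the
    extended anticodon columns); re-parsing round-trips the records."""
    out = io.StringIO()
    out.write("Sequence\ttRNA #\tBegin\tEnd\tType\tCodon\tIntron Begin\tIntron End\t"
              "Score\tAc Begin\tAc End\tNote\n")
    for g in genes:
        num = g.trna_id.rsplit(".trna", 1)[-1]

        def native(s: int, e: int) -> Tuple[int, int]:
            return (s + 1, e) if g.strand == "+" else (e, s + 1)

        begin, end = native(g.start, g.end)
        if g.introns:
            ivs = g.introns if g.strand == "+" else list(reversed(g.introns))
            pairs = [native(s, e) for s, e in ivs]
            ib = ",".join(str(p[0]) for p in pairs)
            ie = ",".join(str(p[1]) for p in pairs)
        else:
            ib = ie = "0"
        if g.anticodon_start is not None:
            ab, ae = native(g.anticodon_start, g.anticodon_end)
        else:
            ab = ae = 0
        out.write(
            f"{g.replicon}\t{num}\t{begin}\t{end}\t{g.isotype}\t{g.anticodon}\t"
            f"{ib}\t{ie}\t{g.score:g}\t{ab}\t{ae}\t{g.note}\n"
        )
    return out.getvalue()


CANONICAL = "canonical_37_38"
NONCANONICAL = "noncanonical"
UNKNOWN = "unknown"


def classify_intron_position(
    gene: TRNAGene, intron: Tuple[int, int], tolerance: int = 1
) -> Tuple[str, str]:
    """Classify an intron as canonical (immediately 3' of the anticodon,
    i.e. between tRNA positions 37 and 38) or non-canonical.

    Canonical means the intron's 5' boundary lies within ``tolerance``
    nucleotides of the position immediately 3' of the anticodon (the
    scanner coordinate conventions can differ by one).  Returns the
    class and a short record of the basis for the call; genes without
    anticodon coordinates classify as "unknown".
    """
    if gene.anticodon_start is None or gene.anticodon_end is None:
        return UNKNOWN, "no anticodon coordinates in scanner record"
    s, e = intron
    if gene.strand == "+":
        expected = gene.anticodon_end  # first position 3' of the anticodon
        dist = abs(s - expected)
    else:
        expected = gene.anticodon_start  # 3' side is the lower genomic coordinate
        dist = abs(e - expected)
    basis = f"intron 5' boundary {dist} nt from anticodon 3' edge (tolerance {tolerance})"
    return (CANONICAL if dist <= tolerance else NONCANONICAL), basis


def intron_stats(genes: Sequence[TRNAGene], per_genome: bool = False) -> pd.DataFrame:
    """Census of tRNA intron architecture.

    Reports, overall or per replicon: gene and intron totals, the number
    and percentage of genes with at least one intron and with two or
    more, and the intron position-class counts.
    """
    if not genes:
        raise ParameterError("no tRNA genes to summarize")

    def summarize(subset: Sequence[TRNAGene]) -> Dict[str, float]:
        n = len(subset)
        with_intron = sum(1 for g in subset if g.n_introns >= 1)
        multi = sum(1 for g in subset if g.n_introns >= 2)
        classes = {CANONICAL: 0, NONCANONICAL: 0, UNKNOWN: 0}
        for g in subset:
            for iv in g.introns:
                cls, _ = classify_intron_position(g, iv)
                classes[cls] += 1
        return {
            "n_genes": n,
            "total_introns": sum(g.n_introns for g in subset),
            "genes_with_intron": with_intron,
            "pct_with_intron": 100.0 * with_intron / n,
            "genes_multi_intron": multi,
            "pct_multi_intron": 100.0 * multi / n,
            "introns_canonical": classes[CANONICAL],
            "introns_noncanonical": classes[NONCANONICAL],
            "introns_unknown_position": classes[UNKNOWN],
        }

    if per_genome:
        rows = {}
        for rep in dict.fromkeys(g.replicon for g in genes):
            rows[rep] = summarize([g for g in genes if g.replicon == rep])
        rows["all"] = summarize(genes)
        return pd.DataFrame.from_dict(rows, orient="index")
    return pd.DataFrame.from_dict({"all": summarize(genes)}, orient="index")


# BLAST outfmt-6-like parsing: the length filter needs full sequence
# lengths, so qlen/slen columns are required.
DEFAULT_HIT_COLUMNS = (
    "qseqid sseqid pident length mismatch gapopen qstart qend sstart send "
    "evalue bitscore qlen slen"
).split()


def parse_hit_table(text: str, columns: Sequence[str] = DEFAULT_HIT_COLUMNS) -> List[HomologyHit]:
    """Parse a tabular homology-hit file (outfmt-6 style).

    ``columns`` names the fields in order; qseqid, sseqid, bitscore,
    evalue, qlen and slen are required, and a ``category`` column is
    honoured when present.
    """
    required = {"qseqid", "sseqid", "bitscore", "evalue", "qlen", "slen"}
    missing = required - set(columns)
    if missing:
        raise ParameterError(f"hit table columns missing: {sorted(missing)}")
    idx = {name: i for i, name in enumerate(columns)}
    hits: List[HomologyHit] = []
    for lineno, raw in enumerate(text.splitlines(), start=1):
        if not raw.strip() or raw.startswith("#"):
            continue
        cols = raw.rstrip("\n").split("\t")
        if len(cols) < len(columns):
            raise ParameterError(f"line {lineno}: expected {len(columns)} columns")
        try:
            hits.append(
                HomologyHit(
                    query_id=cols[idx["qseqid"]],
                    subject_id=cols[idx["sseqid"]],
                    query_len=int(cols[idx["qlen"]]),
                    subject_len=int(cols[idx["slen"]]),
                    bitscore=float(cols[idx["bitscore"]]),
                    evalue=float(cols[idx["evalue"]]),
                    category=cols[idx["category"]] if "category" in idx else None,
                )
            )
        except ValueError as exc:
            raise ParameterError(f"line {lineno}: malformed field ({exc})") from exc
    return hits


def filter_homology_hits(
    hits: Sequence[HomologyHit],
    max_len_diff_frac: float = 0.75,
    use_aligned_length: bool = False,
) -> List[HomologyHit]:
    """Length-difference filter plus best-hit-per-query dereplication.

    A hit is kept iff |subject length - query length| is strictly less
    than ``max_len_diff_frac`` x query length (the boundary case is
    rejected).  Kept hits are then dereplicated to one per query:
    highest bitscore, ties broken by lowest e-value, remaining ties by
    input order.  ``use_aligned_length`` switches the comparison to the
    aligned-region lengths where those are recorded.
    """
    best: Dict[str, Tuple[float, float, int, HomologyHit]] = {}
    order: List[str] = []
    for i, h in enumerate(hits):
        if use_aligned_length:
            qlen = h.aligned_query_len or h.query_len
            slen = h.aligned_subject_len or h.subject_len
        else:
            qlen, slen = h.query_len, h.subject_len
        if not abs(slen - qlen) < max_len_diff_frac * qlen:
            continue
        key = (-h.bitscore, h.evalue, i)
        if h.query_id not in best:
            best[h.query_id] = (*key, h)
            order.append(h.query_id)
        elif key < best[h.query_id][:3]:
            best[h.query_id] = (*key, h)
    return [best[q][3] for q in order]


def category_percentages(hits: Sequence[HomologyHit]) -> pd.DataFrame:
    """Counts and percentages of kept hits per functional category."""
    if not hits:
        raise ParameterError("no hits to summarize")
    labels = [h.category if h.category is not None else "unassigned" for h in hits]
    counts = pd.Series(labels).value_counts().sort_index()
    df = pd.DataFrame({"count": counts})
    df["percent"] = 100.0 * df["count"] / df["count"].sum()
    return df
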