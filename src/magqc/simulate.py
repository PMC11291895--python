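"""Synthetic replicons, read alignments, and chimeras with known truth.

Every input the curation/quantification pipeline consumes can be
generated here with a ground-truth record, so each detector is testable
without external data:

* circular replicons whose two replichore arms carry opposite GC-skew
  bias (the signature of bidirectional replication);
* paired short-read alignments with controlled coverage, per-read edit
  distance, mapping quality, planted strain variants at a chosen
  minor-allele fraction, and optional masked (zero-coverage) intervals;
* chimeric contigs joining two donors, with donor-only read simulation
  that leaves the junction without spanning fragments;
* RNA alignments with controlled per-gene abundance and identity/MAPQ
  spectra.

The error model is uniform substitutions only (no indels); read
alignments are synthesized directly as alignment records rather than by
running an aligner, so edit distance and MAPQ are exactly controllable.
Unique placements get MAPQ 60; fragments drawn as ambiguous get MAPQ 0.
All operations are deterministic given their seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np

from .core import GeneModel, ParameterError, ReadAlignment

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)

DEFAULT_MAPQ_UNIQUE = 60
DEFAULT_MAPQ_AMBIGUOUS = 0


@dataclass
class RepliconTruth:
    """Ground truth for one synthetic circular replicon."""

    length: int
    ori_pos: int
    ter_pos: int
    skew_strength: float
    gc_content: float
    seed: int
    replicon_id: str = "replicon"

    def __post_init__(self) -> None:
        if not (0 <= self.ori_pos < self.length and 0 <= self.ter_pos < self.length):
            raise ParameterError("ori_pos and ter_pos must lie in [0, length)")
        if self.ori_pos == self.ter_pos:
            raise ParameterError("ori_pos and ter_pos must differ")
        if not 0.0 <= self.skew_strength <= 1.0:
            raise ParameterError("skew_strength must be in [0, 1]")
        if not 0.0 < self.gc_content < 1.0:
            raise ParameterError("gc_content must be in (0, 1)")


@dataclass
class PlantedVariant:
    """A strain variant planted at ``pos`` with minor-allele fraction
    ``fraction``; ``alt_base`` is chosen off the reference if None."""

    pos: int
    fraction: float
    alt_base: Optional[str] = None

    def __post_init__(self) -> None:
        if not 0.0 <= self.fraction <= 0.5:
            raise ParameterError("minor-allele fraction must be in [0, 0.5]")


@dataclass
class VariantTruth:
    pos: int
    ref_base: str
    alt_base: str
    alt_count: int
    depth: int


@dataclass
class DnaTruth:
    """What the DNA read simulator actually drew."""

    n_fragments: int
    variants: Dict[int, VariantTruth] = field(default_factory=dict)


@dataclass
class ChimeraTruth:
    junction_pos: int
    donor_ids: Tuple[str, str]


def generate_replicon(truth: RepliconTruth) -> Tuple[str, RepliconTruth]:
    """Generate a circular replicon with two oppositely skew-biased arms.

    Each position is GC with probability ``gc_content``; among GC
    positions, G is chosen with probability (1 + s)/2 on the clockwise
    arc ori -> ter and (1 - s)/2 on the complementary arc, so the
    expected windowed skew is +s on the leading arm and -s on the
    lagging arm.  A/T placement is unbiased.
    """
    rng = np.random.default_rng(truth.seed)
    L = truth.length
    idx = np.arange(L)
    on_leading = ((idx - truth.ori_pos) % L) < ((truth.ter_pos - truth.ori_pos) % L)
    p_g = np.where(on_leading, (1 + truth.skew_strength) / 2, (1 - truth.skew_strength) / 2)
    is_gc = rng.random(L) < truth.gc_content
    u = rng.random(L)
    bases = np.where(
        is_gc,
        np.where(u < p_g, ord("G"), ord("C")),
        np.where(u < 0.5, ord("A"), ord("T")),
    ).astype(np.uint8)
    return bases.tobytes().decode("ascii"), truth


def _substitute(rng: np.random.Generator, base: int) -> int:
    """A uniform substitution to one of the three other bases."""
    alt = _BASES[_BASES != base]
    return int(alt[rng.integers(0, 3)])


def expected_fragment_count(coverage: float, length: int, read_len: int) -> int:
    return int(round(coverage * length / (2 * read_len)))


def simulate_dna_alignments(
    sequence: str,
    coverage: float,
    read_len: int = 100,
    insert: int = 300,
    error_rate: float = 0.0,
    variants: Optional[Sequence[PlantedVariant]] = None,
    seed: int = 0,
    circular: bool = True,
    exclude: Optional[Sequence[Tuple[int, int]]] = None,
    regions: Optional[Sequence[Tuple[int, int]]] = None,
    ambiguous_fraction: float = 0.0,
    ref_id: str = "replicon",
) -> Tuple[List[ReadAlignment], DnaTruth]:
    """Simulate a paired-end DNA library as alignment records.

    ``exclude`` intervals (0-based half-open) receive no coverage:
    reads overlapping them are dropped, planting a support gap.
    ``regions`` restricts fragments to lie entirely within one of the
    given intervals (used for donor-only chimera libraries); regions
    imply a linear layout.  Reads crossing the origin of a circular
    replicon are emitted as two alignment segments sharing a read id.
    """
    if coverage <= 0:
        raise ParameterError("coverage must be > 0")
    if not 0.0 <= error_rate <= 0.1:
        raise ParameterError("error_rate must be in [0, 0.1]")
    if insert < read_len:
        raise ParameterError(f"insert ({insert}) must be >= read_len ({read_len})")
    arr = np.frombuffer(sequence.upper().encode("ascii"), dtype=np.uint8)
    L = len(arr)
    if insert > L:
        raise ParameterError("insert exceeds replicon length")
    variants = list(variants or [])
    for v in variants:
        if not 0 <= v.pos < L:
            raise ParameterError(f"variant position {v.pos} outside replicon")

    rng = np.random.default_rng(seed)
    n_frag = expected_fragment_count(coverage, L, read_len)

    # Fragment start positions.
    if regions is not None:
        usable = [(s, e) for s, e in regions if e - s >= insert]
        if not usable:
            raise ParameterError("no region can hold a fragment of the given insert size")
        weights = np.array([e - s - insert + 1 for s, e in usable], dtype=float)
        which = rng.choice(len(usable), size=n_frag, p=weights / weights.sum())
        starts = np.array(
            [usable[w][0] + rng.integers(0, usable[w][1] - usable[w][0] - insert + 1) for w in which]
        )
    elif circular:
        starts = rng.integers(0, L, size=n_frag)
    else:
        starts = rng.integers(0, L - insert + 1, size=n_frag)

    def read_masked(s: int) -> bool:
        """True when the read [s, s + read_len) touches a masked interval."""
        if not exclude:
            return False
        spans = [(s, min(s + read_len, L))]
        if circular and s + read_len > L:
            spans.append((0, s + read_len - L))
        return any(fs < me and ms < fe for fs, fe in spans for ms, me in exclude)

    # Resolve variant alt bases once.
    var_truth: Dict[int, VariantTruth] = {}
    for v in variants:
        ref_base = chr(arr[v.pos])
        if v.alt_base is None:
            alt = chr(_substitute(rng, arr[v.pos]))
        else:
            alt = v.alt_base.upper()
            if alt == ref_base:
                raise ParameterError(f"variant at {v.pos}: alt equals reference base")
        var_truth[v.pos] = VariantTruth(v.pos, ref_base, alt, 0, 0)
    var_fraction = {v.pos: v.fraction for v in variants}

    template = np.arange(read_len)
    alignments: List[ReadAlignment] = []

    def emit_read(frag_id: str, which: str, s: int, strand: str, mapq: int, mate_start: int) -> None:
        if read_masked(s):
            return
        pos = (template + s) % L if circular else template + s
        ref_bases = arr[pos]
        read = ref_bases.copy()
        # Planted variants: each covering read carries the alt with prob fraction.
        for p, frac in var_fraction.items():
            off = (p - s) % L if circular else p - s
            if 0 <= off < read_len:
                if rng.random() < frac:
                    read[off] = ord(var_truth[p].alt_base)
        # Uniform substitution errors.
        if error_rate > 0:
            k = rng.binomial(read_len, error_rate)
            if k:
                err_pos = rng.choice(read_len, size=k, replace=False)
                for ep in err_pos:
                    read[ep] = _substitute(rng, read[ep])
        # Truth pileup bookkeeping from the final read bases.
        for p in var_truth:
            off = (p - s) % L if circular else p - s
            if 0 <= off < read_len:
                var_truth[p].depth += 1
                if read[off] == ord(var_truth[p].alt_base):
                    var_truth[p].alt_count += 1
        read_str = read.tobytes().decode("ascii")
        rid = f"{frag_id}/{which}"
        end = s + read_len
        if circular and end > L:  # split the wrapped read into two segments
            cut = L - s
            for seg_start, seg_end, seg_seq, seg_ref in (
                (s, L, read_str[:cut], ref_bases[:cut]),
                (0, end - L, read_str[cut:], ref_bases[cut:]),
            ):
                nm = int(np.count_nonzero(np.frombuffer(seg_seq.encode(), dtype=np.uint8) != seg_ref))
                alignments.append(
                    ReadAlignment(
                        read_id=rid,
                        ref_id=ref_id,
                        start=int(seg_start),
                        end=int(seg_end),
                        strand=strand,
                        mapq=mapq,
                        edit_distance=nm,
                        aligned_len=seg_end - seg_start,
                        seq=seg_seq,
                        mate_ref=ref_id,
                        mate_start=int(mate_start),
                        proper_pair=True,
                    )
                )
        else:
            nm = int(np.count_nonzero(read != ref_bases))
            alignments.append(
                ReadAlignment(
                    read_id=rid,
                    ref_id=ref_id,
                    start=int(s),
                    end=int(end),
                    strand=strand,
                    mapq=mapq,
                    edit_distance=nm,
                    aligned_len=read_len,
                    seq=read_str,
                    mate_ref=ref_id,
                    mate_start=int(mate_start),
                    proper_pair=True,
                )
            )

    for i, s in enumerate(starts):
        s = int(s)
        mapq = (
            DEFAULT_MAPQ_AMBIGUOUS
            if ambiguous_fraction > 0 and rng.random() < ambiguous_fraction
            else DEFAULT_MAPQ_UNIQUE
        )
        s2 = s + insert - read_len
        if circular:
            s2 %= L
        frag_id = f"frag{i:06d}"
        emit_read(frag_id, "1", s, "+", mapq, s2)
        emit_read(frag_id, "2", s2, "-", mapq, s)

    return alignments, DnaTruth(n_fragments=len(starts), variants=var_truth)


def make_chimera(
    seq_a: str,
    seq_b: str,
    junction_pos: int,
    id_a: str = "donorA",
    id_b: str = "donorB",
) -> Tuple[str, ChimeraTruth]:
    """Join a prefix of ``seq_a`` to a suffix of ``seq_b`` at
    ``junction_pos``, recording the junction as truth."""
    if not (0 < junction_pos <= len(seq_a)):
        raise ParameterError("junction_pos outside donor A's usable range")
    if not (0 < junction_pos < len(seq_b)):
        raise ParameterError("junction_pos outside donor B's usable range")
    contig = seq_a[:junction_pos] + seq_b[junction_pos:]
    return contig, ChimeraTruth(junction_pos=junction_pos, donor_ids=(id_a, id_b))


def simulate_chimera_alignments(
    contig: str,
    truth: ChimeraTruth,
    coverage: float,
    read_len: int = 100,
    insert: int = 300,
    error_rate: float = 0.0,
    seed: int = 0,
    ref_id: str = "chimera",
) -> Tuple[List[ReadAlignment], DnaTruth]:
    """Simulate reads as if drawn from the two donors independently:
    fragments lie entirely on one side of the junction, so no fragment
    spans it — the support-gap signature of a chimeric join."""
    j = truth.junction_pos
    return simulate_dna_alignments(
        contig,
        coverage=coverage,
        read_len=read_len,
        insert=insert,
        error_rate=error_rate,
        seed=seed,
        circular=False,
        regions=[(0, j), (j, len(contig))],
        ref_id=ref_id,
    )


def _draw_from_spectrum(rng: np.random.Generator, spectrum: Mapping[float, float], n: int) -> np.ndarray:
    values = np.array(list(spectrum.keys()), dtype=float)
    probs = np.array(list(spectrum.values()), dtype=float)
    if abs(probs.sum() - 1.0) > 1e-9:
        raise ParameterError("spectrum probabilities must sum to 1")
    return values[rng.choice(len(values), size=n, p=probs)]


def simulate_rna_alignments(
    genes: Sequence[GeneModel],
    per_gene_abundance: Mapping[str, int],
    total_library: int,
    ref_length: int,
    identity_spectrum: Mapping[float, float] = None,
    mapq_spectrum: Mapping[int, float] = None,
    seed: int = 0,
    read_len: int = 100,
) -> Tuple[List[ReadAlignment], Dict[str, int]]:
    """Single-end RNA alignments with exact planted per-gene counts.

    Each gene receives exactly ``per_gene_abundance[gene_id]`` fragments
    whose midpoints fall inside the gene; the remainder of the library
    (up to ``total_library``) lands in intergenic space.  Identity and
    MAPQ are drawn per fragment from discrete spectra, so the expected
    post-filter count per gene is abundance x P(identity >= cutoff) x
    P(MAPQ >= cutoff).
    """
    identity_spectrum = identity_spectrum or {1.0: 1.0}
    mapq_spectrum = mapq_spectrum or {DEFAULT_MAPQ_UNIQUE: 1.0}
    planted = {g.gene_id: int(per_gene_abundance.get(g.gene_id, 0)) for g in genes}
    n_genic = sum(planted.values())
    if n_genic > total_library:
        raise ParameterError("sum of per-gene abundances exceeds total_library")
    for g in genes:
        if g.start < 0 or g.end > ref_length:
            raise ParameterError(f"gene {g.gene_id} outside reference [0, {ref_length})")
    if total_library == 0:
        return [], planted

    rng = np.random.default_rng(seed)
    half = read_len // 2
    alignments: List[ReadAlignment] = []
    counter = 0

    def mid_range(lo: int, hi: int) -> Tuple[int, int]:
        """Valid midpoint range inside [lo, hi) keeping the read on-reference."""
        return max(lo, half), min(hi, ref_length - read_len + half + 1)

    def emit(ref_id: str, mid: int, identity: float, mapq: int) -> None:
        nonlocal counter
        start = mid - half
        nm = int(round((1.0 - identity) * read_len))
        alignments.append(
            ReadAlignment(
                read_id=f"rna{counter:07d}",
                ref_id=ref_id,
                start=start,
                end=start + read_len,
                strand="+" if rng.random() < 0.5 else "-",
                mapq=int(mapq),
                edit_distance=nm,
                aligned_len=read_len,
                proper_pair=False,
            )
        )
        counter += 1

    for g in genes:
        n = planted[g.gene_id]
        if n == 0:
            continue
        lo, hi = mid_range(g.start, g.end)
        if lo >= hi:
            raise ParameterError(f"gene {g.gene_id} too close to the reference edge for read_len")
        mids = rng.integers(lo, hi, size=n)
        idents = _draw_from_spectrum(rng, identity_spectrum, n)
        mapqs = _draw_from_spectrum(rng, {float(k): v for k, v in mapq_spectrum.items()}, n)
        for m, ident, q in zip(mids, idents, mapqs):
            emit(g.ref_id, int(m), float(ident), int(q))

    leftover = total_library - n_genic
    if leftover > 0:
        # Intergenic gaps on the (single) reference of the first gene.
        ref_id = genes[0].ref_id if genes else "replicon"
        occupied = sorted((g.start, g.end) for g in genes if g.ref_id == ref_id)
        gaps, cursor = [], 0
        for s, e in occupied:
            if s > cursor:
                gaps.append((cursor, s))
            cursor = max(cursor, e)
        if cursor < ref_length:
            gaps.append((cursor, ref_length))
        gaps = [mid_range(s, e) for s, e in gaps]
        gaps = [(lo, hi) for lo, hi in gaps if hi > lo]
        if not gaps:
            raise ParameterError("no intergenic space to place background fragments")
        weights = np.array([hi - lo for lo, hi in gaps], dtype=float)
        which = rng.choice(len(gaps), size=leftover, p=weights / weights.sum())
        idents = _draw_from_spectrum(rng, identity_spectrum, leftover)
        mapqs = _draw_from_spectrum(rng, {float(k): v for k, v in mapq_spectrum.items()}, leftover)
        for w, ident, q in zip(which, idents, mapqs):
            lo, hi = gaps[w]
            emit(ref_id, int(rng.integers(lo, hi)), float(ident), int(q))

    return alignments, planted
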