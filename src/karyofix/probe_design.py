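"""Single-copy oligo probe candidates along a target scaffold.

Candidates are tiled at a fixed step (3 nt) along the unmasked target,
with length chosen per start from a small window (43–45 nt) to pull the
melting temperature toward a target — narrowing the thermodynamic range
of the set.  Regions homologous to the background genome (from a
pre-computed BLAST of the target against it) are masked out, and a
canonical k-mer uniqueness screen over the hybrid genome flags oligos
that could hybridize away from their target.  The k-mer + Tm screen is a
documented heuristic, not a thermodynamic duplex model.
"""

from __future__ import annotations

import statistics
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

from .locus_mapping import BlastHit

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class ProbeParams:
    step: int = 3
    len_min: int = 43
    len_max: int = 45
    tm_target: float | None = None    # None: median Tm of 44-mer windows
    k_unique: int = 21
    homology_word: int = 21
    homology_evalue: float = 1e-50

    def __post_init__(self) -> None:
        if self.len_min > self.len_max:
            raise ValueError("len_min must be <= len_max")
        if self.step < 1:
            raise ValueError("step must be >= 1")
        if self.k_unique > self.len_min:
            raise ValueError("k_unique must be <= len_min")


@dataclass(frozen=True)
class MaskInterval:
    scaffold: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if not self.start < self.end:
            raise ValueError("mask interval start >= end")


@dataclass(frozen=True)
class Oligo:
    scaffold: str
    start: int
    length: int
    sequence: str
    tm: float
    unique: bool | None = None


def oligo_tm(seq: str) -> float:
    """GC-content melting temperature: 64.9 + 41 * (#GC - 16.4) / length.

    A long-oligo approximation adequate for ranking candidate lengths at a
    start; not a nearest-neighbor duplex model.
    """
    if not seq:
        raise ValueError("empty sequence")
    seq = seq.upper()
    bad = set(seq) - set("ACGT")
    if bad:
        raise ValueError(f"non-ACGT characters: {sorted(bad)}")
    gc = seq.count("G") + seq.count("C")
    return 64.9 + 41.0 * (gc - 16.4) / len(seq)


def mask_from_hits(hits: Iterable[BlastHit], scaffold: str | None = None) -> list[MaskInterval]:
    """Union of hit query spans as sorted, non-overlapping mask intervals.

    Book-ended (half-open adjacent) intervals merge — adjacency implies no
    gap base.  Hits are assumed already filtered to the homology e-value.
    """
    spans: dict[str, list[tuple[int, int]]] = {}
    for h in hits:
        lo, hi = sorted((h.qstart, h.qend))
        spans.setdefault(h.query_id, []).append((lo - 1, hi))
    out: list[MaskInterval] = []
    for scaf in sorted(spans):
        if scaffold is not None and scaf != scaffold:
            continue
        ivs = sorted(spans[scaf])
        cur_s, cur_e = ivs[0]
        for s, e in ivs[1:]:
            if s > cur_e:          # strict gap; book-ended intervals merge
                out.append(MaskInterval(scaf, cur_s, cur_e))
                cur_s, cur_e = s, e
            else:
                cur_e = max(cur_e, e)
        out.append(MaskInterval(scaf, cur_s, cur_e))
    return out


def default_tm_target(seq: str, mask: Sequence[MaskInterval] = (), probe_len: int = 44) -> float:
    """Median Tm over all fixed-length windows of the unmasked, N-free target."""
    seq = seq.upper()
    masked = [(m.start, m.end) for m in mask]
    tms = []
    for start in range(0, len(seq) - probe_len + 1):
        end = start + probe_len
        if any(start < me and ms < end for ms, me in masked):
            continue
        window = seq[start:end]
        if "N" in window:
            continue
        tms.append(oligo_tm(window))
    if not tms:
        raise ValueError("no unmasked N-free windows to set a Tm target")
    return float(statistics.median(tms))


def tile_candidates(
    seq: str,
    mask: Sequence[MaskInterval] = (),
    params: ProbeParams = ProbeParams(),
    scaffold: str = "",
) -> list[Oligo]:
    """Fixed-step tiling with Tm-guided length selection.

    Starts at 0, step, 2*step, ...; at each start the length in
    [len_min, len_max] fitting within the sequence that minimizes
    |Tm - tm_target| is chosen (ties -> shortest).  Candidates that
    overlap any mask interval or contain N are dropped.
    """
    seq = seq.upper()
    if len(seq) < params.len_min:
        return []
    masked = [(m.start, m.end) for m in mask]
    tm_target = params.tm_target
    if tm_target is None:
        try:
            tm_target = default_tm_target(seq, mask)
        except ValueError:
            return []
    out: list[Oligo] = []
    for start in range(0, len(seq) - params.len_min + 1, params.step):
        best: tuple[float, int, float] | None = None  # (|dTm|, length, tm)
        for length in range(params.len_min, params.len_max + 1):
            end = start + length
            if end > len(seq):
                break
            window = seq[start:end]
            if "N" in window:
                continue
            if any(start < me and ms < end for ms, me in masked):
                continue
            tm = oligo_tm(window)
            key = (abs(tm - tm_target), length, tm)
            if best is None or key < best:
                best = key
        if best is not None:
            _, length, tm = best
            out.append(Oligo(scaffold, start, length, seq[start:start + length], tm))
    for o in out:
        assert o.sequence == seq[o.start:o.start + o.length]
    return out


def canonical_kmers(seq: str, k: int) -> Iterable[str]:
    """Canonical (lexicographic min of strand pair) k-mers, skipping N."""
    seq = seq.upper()
    for i in range(len(seq) - k + 1):
        kmer = seq[i:i + k]
        if "N" in kmer:
            continue
        yield min(kmer, revcomp(kmer))


def uniqueness_screen(
    oligos: Sequence[Oligo],
    genome: Mapping[str, str],
    k: int = 21,
) -> list[Oligo]:
    """Flag each oligo unique iff all its canonical k-mers occur exactly
    once among the canonical k-mers of the genome (both strands collapsed)."""
    if oligos and k > min(o.length for o in oligos):
        raise ValueError("k exceeds the shortest oligo length")
    counts: dict[str, int] = {}
    for seq in genome.values():
        for kmer in canonical_kmers(seq, k):
            counts[kmer] = counts.get(kmer, 0) + 1
    out = []
    for o in oligos:
        unique = all(counts.get(kmer, 0) == 1 for kmer in canonical_kmers(o.sequence, k))
        out.append(Oligo(o.scaffold, o.start, o.length, o.sequence, o.tm, unique))
    return out


def write_oligos_tsv(oligos: Sequence[Oligo], sink) -> None:
    own = isinstance(sink, str)
    handle = open(sink, "w") if own else sink
    try:
        handle.write("scaffold\tstart\tlength\ttm\tunique\tsequence\n")
        for o in oligos:
            uq = "" if o.unique is None else str(o.unique).lower()
            handle.write(f"{o.scaffold}\t{o.start}\t{o.length}\t{o.tm:.3f}\t{uq}\t{o.sequence}\n")
    finally:
        if own:
            handle.close()


def write_oligos_fasta(oligos: Sequence[Oligo], sink) -> None:
    own = isinstance(sink, str)
    handle = open(sink, "w") if own else sink
    try:
        for o in oligos:
            handle.write(f">{o.scaffold}:{o.start}-{o.start + o.length}\n{o.sequence}\n")
    finally:
        if own:
            handle.close()
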