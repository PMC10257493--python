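"""Assign SNP tags to genome scaffolds from similarity hits; synteny-block filters.

Tag placement consumes finished BLAST tabular output (outfmt 6, 12 columns)
rather than running an aligner: a hit survives a base-composition screen on
the query tag, an e-value ceiling, an identity floor and a query-overlap
floor, and the single best surviving hit per locus becomes its assignment.
Whole-genome alignment blocks (nucmer show-coords style) are reduced to
one-to-one synteny blocks longer than a minimum length and summarized.

All internal coordinates are 0-based half-open; 1-based inclusive appears
only at format boundaries.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from .genotype_io import Locus


@dataclass(frozen=True)
class BlastHit:
    """One line of 12-column BLAST tabular output (coordinates as printed)."""

    query_id: str
    subject_id: str
    pident: float
    aln_length: int
    mismatches: int
    gap_opens: int
    qstart: int
    qend: int
    sstart: int
    send: int
    evalue: float
    bitscore: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.pident <= 100.0:
            raise ValueError(f"pident {self.pident} outside [0, 100]")
        if self.aln_length < 1:
            raise ValueError(f"aln_length {self.aln_length} < 1")
        if self.evalue < 0:
            raise ValueError(f"evalue {self.evalue} < 0")

    @property
    def strand(self) -> str:
        return "-" if self.send < self.sstart else "+"

    def subject_interval(self) -> tuple[int, int]:
        """Subject span as 0-based half-open regardless of strand."""
        lo, hi = sorted((self.sstart, self.send))
        return lo - 1, hi


@dataclass(frozen=True)
class HitFilterConfig:
    """Post-hoc thresholds applied to BLAST hits.

    Defaults mirror the published run: e-value 5e-7, 70% identity, 70%
    query overlap, one hit kept per tag, and a 3%/60% per-base composition
    window on the tag itself (a low-complexity screen).  The aligner-side
    culling limit has no post-hoc analogue and is only recorded in run
    manifests.
    """

    evalue_max: float = 5e-7
    min_identity: float = 70.0
    min_overlap: float = 0.70
    max_hits_per_query: int = 1
    base_freq_min: float = 0.03
    base_freq_max: float = 0.60
    check_base_composition: bool = True

    def __post_init__(self) -> None:
        if not 0.0 <= self.base_freq_min < self.base_freq_max <= 1.0:
            raise ValueError("require 0 <= base_freq_min < base_freq_max <= 1")


@dataclass(frozen=True)
class LocusAssignment:
    """Best-hit placement of a SNP tag on a scaffold (0-based half-open)."""

    locus_id: str
    scaffold: str
    start: int
    end: int
    strand: str

    def __post_init__(self) -> None:
        if not self.start < self.end:
            raise ValueError(f"assignment {self.locus_id!r}: start >= end")
        if self.strand not in ("+", "-"):
            raise ValueError(f"assignment {self.locus_id!r}: bad strand {self.strand!r}")


@dataclass(frozen=True)
class SyntenyBlock:
    ref_scaffold: str
    query_scaffold: str
    ref_start: int
    ref_end: int
    query_start: int
    query_end: int
    identity: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.identity <= 100.0:
            raise ValueError(f"identity {self.identity} outside [0, 100]")
        if self.length < 1:
            raise ValueError("block length < 1")

    @property
    def length(self) -> int:
        return self.ref_end - self.ref_start


@dataclass(frozen=True)
class SyntenyStats:
    n_query_scaffolds: int
    total_query_span: int
    identity_mean: float
    identity_sd: float
    identity_min: float
    identity_max: float


# ---------------------------------------------------------------------------
# Base composition screen
# ---------------------------------------------------------------------------

def base_composition_ok(seq: str, cfg: HitFilterConfig) -> bool:
    """True iff each of A, C, G, T has frequency within the configured window.

    N bases are excluded from the denominator.  A frequency of exactly the
    boundary passes (closed interval).
    """
    if not seq:
        raise ValueError("empty sequence")
    seq = seq.upper()
    counts = Counter(seq)
    bad = set(counts) - {"A", "C", "G", "T", "N"}
    if bad:
        raise ValueError(f"non-ACGTN characters in sequence: {sorted(bad)}")
    denom = len(seq) - counts.get("N", 0)
    if denom == 0:
        return False
    for base in "ACGT":
        freq = counts.get(base, 0) / denom
        if not cfg.base_freq_min <= freq <= cfg.base_freq_max:
            return False
    return True


# ---------------------------------------------------------------------------
# BLAST tabular parsing
# ---------------------------------------------------------------------------

def parse_blast_tab(stream) -> list[BlastHit]:
    """Parse 12-column BLAST tabular (outfmt 6) text.

    Blank lines and '#' comment lines are skipped; a malformed line raises
    with its line number.
    """
    if isinstance(stream, str):
        lines = stream.splitlines()
    else:
        lines = [line.rstrip("\n") for line in stream]
    hits: list[BlastHit] = []
    for lineno, line in enumerate(lines, start=1):
        stripped = line.strip()
        if not stripped or stripped.startswith("#"):
            continue
        fields = stripped.split("\t") if "\t" in stripped else stripped.split()
        if len(fields) != 12:
            raise ValueError(f"line {lineno}: expected 12 columns, got {len(fields)}")
        try:
            hits.append(
                BlastHit(
                    query_id=fields[0],
                    subject_id=fields[1],
                    pident=float(fields[2]),
                    aln_length=int(fields[3]),
                    mismatches=int(fields[4]),
                    gap_opens=int(fields[5]),
                    qstart=int(fields[6]),
                    qend=int(fields[7]),
                    sstart=int(fields[8]),
                    send=int(fields[9]),
                    evalue=float(fields[10]),
                    bitscore=float(fields[11]),
                )
            )
        except ValueError as exc:
            raise ValueError(f"line {lineno}: {exc}") from exc
    return hits


# ---------------------------------------------------------------------------
# Assignment selection
# ---------------------------------------------------------------------------

def hit_passes(hit: BlastHit, tag: str | None, tag_length: int, cfg: HitFilterConfig) -> bool:
    """Apply the per-hit thresholds (composition, e-value, identity, overlap)."""
    if cfg.check_base_composition and tag is not None and not base_composition_ok(tag, cfg):
        return False
    if hit.evalue > cfg.evalue_max:
        return False
    if hit.pident < cfg.min_identity:
        return False
    if tag_length <= 0 or hit.aln_length / tag_length < cfg.min_overlap:
        return False
    return True


def select_assignments(
    hits: Sequence[BlastHit],
    loci: Sequence[Locus],
    cfg: HitFilterConfig = HitFilterConfig(),
) -> list[LocusAssignment]:
    """Filter hits and keep the single best per locus as its assignment.

    Best = highest bitscore; ties broken by lowest e-value, then
    lexicographically smallest subject id, then smallest subject start.
    The overlap denominator is the full tag length, not the aligned span.
    Output order follows the locus list; at most one assignment per locus.
    """
    by_id: dict[str, Locus] = {}
    for loc in loci:
        by_id[loc.id] = loc
    survivors: dict[str, list[BlastHit]] = {}
    for hit in hits:
        loc = by_id.get(hit.query_id)
        if loc is None:
            raise KeyError(f"hit references unknown locus {hit.query_id!r}")
        if loc.tag_sequence is None:
            raise ValueError(f"locus {loc.id!r} has no tag sequence (length unknown)")
        if hit_passes(hit, loc.tag_sequence, len(loc.tag_sequence), cfg):
            survivors.setdefault(loc.id, []).append(hit)

    assignments: list[LocusAssignment] = []
    for loc in loci:
        cands = survivors.get(loc.id)
        if not cands:
            continue
        best = min(
            cands,
            key=lambda h: (-h.bitscore, h.evalue, h.subject_id, min(h.sstart, h.send)),
        )
        start, end = best.subject_interval()
        assignments.append(
            LocusAssignment(loc.id, best.subject_id, start, end, best.strand)
        )
    assert len({a.locus_id for a in assignments}) == len(assignments)
    return assignments


def restrict_to_scaffolds(
    assignments: Sequence[LocusAssignment], scaffolds: Iterable[str]
) -> list[LocusAssignment]:
    """Keep assignments landing on the given scaffolds, order preserved."""
    wanted = set(scaffolds)
    return [a for a in assignments if a.scaffold in wanted]


# ---------------------------------------------------------------------------
# Synteny blocks
# ---------------------------------------------------------------------------

def parse_coords_tab(stream) -> list[SyntenyBlock]:
    """Parse `show-coords -rclT`-style tabular alignment blocks.

    Expected data columns: ref_start ref_end query_start query_end
    ref_aln_len query_aln_len identity ... ref_id query_id, 1-based
    inclusive on both genomes.  Header/separator lines are skipped.
    """
    if isinstance(stream, str):
        lines = stream.splitlines()
    else:
        lines = [line.rstrip("\n") for line in stream]
    blocks: list[SyntenyBlock] = []
    for line in lines:
        stripped = line.strip()
        if not stripped or stripped.startswith(("#", "=", "/", "NUCMER")):
            continue
        fields = stripped.split("\t") if "\t" in stripped else stripped.split()
        if len(fields) < 9 or not fields[0].lstrip("-").isdigit():
            continue  # header row such as "[S1] [E1] ..."
        rs, re_, qs, qe = (int(fields[i]) for i in range(4))
        identity = float(fields[6])
        ref_id, query_id = fields[-2], fields[-1]
        q_lo, q_hi = sorted((qs, qe))
        blocks.append(
            SyntenyBlock(
                ref_scaffold=ref_id,
                query_scaffold=query_id,
                ref_start=rs - 1,
                ref_end=re_,
                query_start=q_lo - 1,
                query_end=q_hi,
                identity=identity,
            )
        )
    return blocks


def _overlaps(a: tuple[str, int, int], b: tuple[str, int, int]) -> bool:
    return a[0] == b[0] and a[1] < b[2] and b[1] < a[2]


def filter_synteny_blocks(
    blocks: Sequence[SyntenyBlock], min_len: int = 500
) -> list[SyntenyBlock]:
    """Retain one-to-one blocks strictly longer than ``min_len``.

    One-to-one is resolved greedily: blocks are visited by descending
    length (ties by (ref_scaffold, ref_start)) and a block is kept only if
    it overlaps no already-kept block on either genome.  The filter is
    idempotent and its output is pairwise non-overlapping on both genomes.
    """
    long_enough = [b for b in blocks if b.length > min_len]
    ordered = sorted(long_enough, key=lambda b: (-b.length, b.ref_scaffold, b.ref_start))
    kept: list[SyntenyBlock] = []
    for blk in ordered:
        r = (blk.ref_scaffold, blk.ref_start, blk.ref_end)
        q = (blk.query_scaffold, blk.query_start, blk.query_end)
        clash = any(
            _overlaps(r, (k.ref_scaffold, k.ref_start, k.ref_end))
            or _overlaps(q, (k.query_scaffold, k.query_start, k.query_end))
            for k in kept
        )
        if not clash:
            kept.append(blk)
    kept.sort(key=lambda b: (b.ref_scaffold, b.ref_start))
    return kept


def summarize_synteny(
    blocks: Sequence[SyntenyBlock], length_weighted: bool = False
) -> SyntenyStats:
    """Distinct query scaffolds, total covered query span and identity stats.

    Identity statistics are unweighted per block (sample sd) by default;
    the length-weighted variant is available because the averaging basis of
    published per-scaffold identities is ambiguous.
    """
    if not blocks:
        raise ValueError("no synteny blocks")
    idents = np.array([b.identity for b in blocks], dtype=float)
    if length_weighted:
        w = np.array([b.length for b in blocks], dtype=float)
        mean = float(np.average(idents, weights=w))
        var = float(np.average((idents - mean) ** 2, weights=w))
        sd = float(np.sqrt(var))
    else:
        mean = float(idents.mean())
        sd = float(idents.std(ddof=1)) if len(idents) > 1 else 0.0
    # union span per query scaffold
    per_scaf: dict[str, list[tuple[int, int]]] = {}
    for b in blocks:
        per_scaf.setdefault(b.query_scaffold, []).append((b.query_start, b.query_end))
    total = 0
    for ivs in per_scaf.values():
        ivs.sort()
        cur_s, cur_e = ivs[0]
        for s, e in ivs[1:]:
            if s > cur_e:
                total += cur_e - cur_s
                cur_s, cur_e = s, e
            else:
                cur_e = max(cur_e, e)
        total += cur_e - cur_s
    return SyntenyStats(
        n_query_scaffolds=len(per_scaf),
        total_query_span=total,
        identity_mean=mean,
        identity_sd=sd,
        identity_min=float(idents.min()),
        identity_max=float(idents.max()),
    )


# ---------------------------------------------------------------------------
# Writers
# ---------------------------------------------------------------------------

def write_assignments_bed(assignments: Sequence[LocusAssignment], sink) -> None:
    """BED6 with the locus id in the name column."""
    own = isinstance(sink, str)
    handle = open(sink, "w") if own else sink
    try:
        for a in assignments:
            handle.write(f"{a.scaffold}\t{a.start}\t{a.end}\t{a.locus_id}\t0\t{a.strand}\n")
    finally:
        if own:
            handle.close()


def read_assignments_bed(source) -> list[LocusAssignment]:
    own = isinstance(source, str)
    handle = open(source) if own else source
    try:
        out = []
        for line in handle:
            line = line.strip()
            if not line or line.startswith(("#", "track")):
                continue
            f = line.split("\t")
            out.append(LocusAssignment(f[3], f[0], int(f[1]), int(f[2]),
                                       f[5] if len(f) > 5 else "+"))
        return out
    finally:
        if own:
            handle.close()
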