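"""Read, validate, write and subset karyotype-labelled diploid genotype matrices.

The in-memory model follows the DArT convention for scored SNP tags: each
locus is a short Illumina tag carrying one SNP, and each individual receives
a call in {0, 1, 2} — 0 and 2 the two opposite homozygotes, 1 the
heterozygote — or a missing sentinel.  Which homozygote is "reference" is
locus-local and only meaningful together with the locus' ref/alt alleles.

Karyotype labels (AA / MA / MM for the two homozygous chromosome
arrangements and the heterokaryotype) are carried in a separate metadata
table joined on individual id, never encoded in the ids themselves.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field, replace
from enum import Enum
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

#: Integer sentinel for a missing genotype call in the calls array.
MISSING = -1

#: Tokens accepted as "missing" when reading; "-" is written canonically.
MISSING_TOKENS = {"-", "NA", ""}


class KaryotypeLabel(str, Enum):
    """Chromosome-arrangement class of the polymorphic pair.

    AA: both homologs acrocentric; MM: both submetacentric;
    MA: heterokaryotype (one of each); UNKNOWN: not scored.
    """

    AA = "AA"
    MA = "MA"
    MM = "MM"
    UNKNOWN = "UNKNOWN"

    @classmethod
    def parse(cls, token: str) -> "KaryotypeLabel":
        token = str(token).strip().upper()
        if token in ("AA", "MA", "MM"):
            return cls(token)
        return cls.UNKNOWN


@dataclass(frozen=True)
class Individual:
    id: str
    population: str
    karyotype: KaryotypeLabel = KaryotypeLabel.UNKNOWN

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("individual id must be non-empty")
        if not self.population:
            raise ValueError(f"individual {self.id!r}: population must be non-empty")


@dataclass(frozen=True)
class Locus:
    """A scored SNP tag.

    tag_sequence, snp_offset and ref/alt alleles are optional: plain count
    matrices carry none of them, while tag FASTA + SNP metadata populate all.
    """

    id: str
    tag_sequence: str | None = None
    snp_offset: int | None = None
    ref_allele: str | None = None
    alt_allele: str | None = None

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("locus id must be non-empty")
        if self.tag_sequence is not None and self.snp_offset is not None:
            if not (0 <= self.snp_offset < len(self.tag_sequence)):
                raise ValueError(
                    f"locus {self.id!r}: snp_offset {self.snp_offset} outside tag "
                    f"of length {len(self.tag_sequence)}"
                )
        if self.ref_allele is not None and self.alt_allele is not None:
            if self.ref_allele == self.alt_allele:
                raise ValueError(f"locus {self.id!r}: ref and alt alleles are equal")


class GenotypeMatrix:
    """Loci x individuals grid of diploid calls with karyotype metadata.

    ``calls`` is an int8 array of shape (n_loci, n_individuals) with values
    in {0, 1, 2, MISSING}.  Row order follows ``loci``, column order follows
    ``individuals``; both orders are preserved from input.
    """

    def __init__(
        self,
        loci: Sequence[Locus],
        individuals: Sequence[Individual],
        calls: np.ndarray,
    ) -> None:
        self.loci = list(loci)
        self.individuals = list(individuals)
        calls = np.asarray(calls, dtype=np.int8)
        if calls.shape != (len(self.loci), len(self.individuals)):
            raise ValueError(
                f"calls shape {calls.shape} does not match "
                f"{len(self.loci)} loci x {len(self.individuals)} individuals"
            )
        bad = ~np.isin(calls, (0, 1, 2, MISSING))
        if bad.any():
            li, ii = np.argwhere(bad)[0]
            raise ValueError(
                f"call {calls[li, ii]} outside {{0,1,2,missing}} at locus "
                f"{self.loci[li].id!r}, individual {self.individuals[ii].id!r}"
            )
        seen: set[str] = set()
        for loc in self.loci:
            if loc.id in seen:
                raise ValueError(f"duplicate locus id {loc.id!r}")
            seen.add(loc.id)
        seen = set()
        for ind in self.individuals:
            if ind.id in seen:
                raise ValueError(f"duplicate individual id {ind.id!r}")
            seen.add(ind.id)
        self.calls = calls

    # -- basic accessors -------------------------------------------------

    @property
    def n_loci(self) -> int:
        return len(self.loci)

    @property
    def n_individuals(self) -> int:
        return len(self.individuals)

    def locus_ids(self) -> list[str]:
        return [loc.id for loc in self.loci]

    def individual_ids(self) -> list[str]:
        return [ind.id for ind in self.individuals]

    def call_rates(self) -> np.ndarray:
        """Per-locus fraction of non-missing calls (1.0 when no individuals)."""
        if self.n_individuals == 0:
            return np.ones(self.n_loci)
        return (self.calls != MISSING).sum(axis=1) / self.n_individuals

    def karyotype_groups(self) -> dict[KaryotypeLabel, list[int]]:
        """Column indices grouped by karyotype label."""
        groups: dict[KaryotypeLabel, list[int]] = {}
        for j, ind in enumerate(self.individuals):
            groups.setdefault(ind.karyotype, []).append(j)
        return groups

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, GenotypeMatrix):
            return NotImplemented
        return (
            self.loci == other.loci
            and self.individuals == other.individuals
            and np.array_equal(self.calls, other.calls)
        )

    def __repr__(self) -> str:
        return f"GenotypeMatrix({self.n_loci} loci x {self.n_individuals} individuals)"


# ---------------------------------------------------------------------------
# Reading and writing
# ---------------------------------------------------------------------------

def read_metadata(source) -> dict[str, Individual]:
    """Read the individual metadata CSV (columns id, population, karyotype).

    Unknown karyotype tokens map to :attr:`KaryotypeLabel.UNKNOWN`.
    """
    meta = pd.read_csv(source, dtype=str)
    required = {"id", "population", "karyotype"}
    if not required.issubset(meta.columns):
        raise ValueError(f"metadata must have columns {sorted(required)}")
    out: dict[str, Individual] = {}
    for row in meta.itertuples(index=False):
        ind = Individual(str(row.id), str(row.population), KaryotypeLabel.parse(row.karyotype))
        if ind.id in out:
            raise ValueError(f"duplicate individual id {ind.id!r} in metadata")
        out[ind.id] = ind
    return out


def _parse_call(token, locus_id: str, individual_id: str) -> int:
    token = "" if token is None or (isinstance(token, float) and np.isnan(token)) else str(token).strip()
    if token in MISSING_TOKENS:
        return MISSING
    if token in ("0", "1", "2"):
        return int(token)
    # allow "0.0" style floats from spreadsheet round-trips
    try:
        val = float(token)
    except ValueError:
        val = None
    if val is not None and val in (0.0, 1.0, 2.0):
        return int(val)
    raise ValueError(
        f"call {token!r} outside {{0,1,2,missing}} at locus {locus_id!r}, "
        f"individual {individual_id!r}"
    )


def read_genotypes(source, dialect: str, metadata) -> GenotypeMatrix:
    """Read a genotype matrix from CSV.

    dialect "wide": loci as rows (first column the locus id), individuals as
    columns.  dialect "long": columns locus,individual,call, one triple per
    row.  ``metadata`` is the id/population/karyotype CSV and must cover every
    individual present in ``source``.
    """
    if dialect not in ("wide", "long"):
        raise ValueError(f"unknown dialect {dialect!r}")
    meta = metadata if isinstance(metadata, dict) else read_metadata(metadata)

    if dialect == "wide":
        table = pd.read_csv(source, dtype=str, keep_default_na=False)
        locus_col = table.columns[0]
        ind_ids = [str(c) for c in table.columns[1:]]
        locus_ids = [str(v) for v in table[locus_col]]
        calls = np.full((len(locus_ids), len(ind_ids)), MISSING, dtype=np.int8)
        for j, ind_id in enumerate(ind_ids):
            col = table.iloc[:, j + 1]
            for i, tok in enumerate(col):
                calls[i, j] = _parse_call(tok, locus_ids[i], ind_id)
    else:
        table = pd.read_csv(source, dtype=str, keep_default_na=False)
        required = {"locus", "individual", "call"}
        if not required.issubset(table.columns):
            raise ValueError(f"long dialect requires columns {sorted(required)}")
        locus_ids = list(dict.fromkeys(str(v) for v in table["locus"]))
        ind_ids = list(dict.fromkeys(str(v) for v in table["individual"]))
        li = {lid: i for i, lid in enumerate(locus_ids)}
        ii = {iid: j for j, iid in enumerate(ind_ids)}
        calls = np.full((len(locus_ids), len(ind_ids)), MISSING, dtype=np.int8)
        for row in table.itertuples(index=False):
            calls[li[str(row.locus)], ii[str(row.individual)]] = _parse_call(
                row.call, str(row.locus), str(row.individual)
            )

    missing_meta = [iid for iid in ind_ids if iid not in meta]
    if missing_meta:
        raise ValueError(f"individuals missing from metadata: {missing_meta}")
    individuals = [meta[iid] for iid in ind_ids]
    loci = [Locus(lid) for lid in locus_ids]
    return GenotypeMatrix(loci, individuals, calls)


def write_genotypes(matrix: GenotypeMatrix, sink, dialect: str = "wide") -> None:
    """Write a matrix as CSV; missing calls are written as "-"."""
    if dialect not in ("wide", "long"):
        raise ValueError(f"unknown dialect {dialect!r}")

    def fmt(v: int) -> str:
        return "-" if v == MISSING else str(int(v))

    own = isinstance(sink, (str,))
    handle = open(sink, "w", newline="") if own else sink
    try:
        if dialect == "wide":
            handle.write(",".join(["locus"] + matrix.individual_ids()) + "\n")
            for i, loc in enumerate(matrix.loci):
                handle.write(
                    ",".join([loc.id] + [fmt(v) for v in matrix.calls[i]]) + "\n"
                )
        else:
            handle.write("locus,individual,call\n")
            for i, loc in enumerate(matrix.loci):
                for j, ind in enumerate(matrix.individuals):
                    handle.write(f"{loc.id},{ind.id},{fmt(matrix.calls[i, j])}\n")
    finally:
        if own:
            handle.close()


def write_metadata(matrix: GenotypeMatrix, sink) -> None:
    own = isinstance(sink, str)
    handle = open(sink, "w", newline="") if own else sink
    try:
        handle.write("id,population,karyotype\n")
        for ind in matrix.individuals:
            kar = ind.karyotype.value
            handle.write(f"{ind.id},{ind.population},{kar}\n")
    finally:
        if own:
            handle.close()


def read_tag_fasta(source) -> dict[str, str]:
    """Read SNP tag sequences keyed by locus id from FASTA."""
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(source, "fasta")}


def write_tag_fasta(tags: dict[str, str], sink) -> None:
    records = [SeqRecord(Seq(seq), id=lid, description="") for lid, seq in tags.items()]
    SeqIO.write(records, sink, "fasta")


def attach_tags(matrix: GenotypeMatrix, tags: dict[str, str],
                snp_meta: dict[str, tuple[int, str, str]] | None = None) -> GenotypeMatrix:
    """Return a matrix whose loci carry tag sequences (and SNP offset/alleles)."""
    loci = []
    for loc in matrix.loci:
        tag = tags.get(loc.id, loc.tag_sequence)
        if snp_meta and loc.id in snp_meta:
            off, ref, alt = snp_meta[loc.id]
            loci.append(replace(loc, tag_sequence=tag, snp_offset=off,
                                ref_allele=ref, alt_allele=alt))
        else:
            loci.append(replace(loc, tag_sequence=tag))
    return GenotypeMatrix(loci, matrix.individuals, matrix.calls)


# ---------------------------------------------------------------------------
# Filtering and subsetting
# ---------------------------------------------------------------------------

def filter_call_rate(matrix: GenotypeMatrix, min_rate: float) -> GenotypeMatrix:
    """Retain loci whose fraction of non-missing calls is >= ``min_rate``.

    The published analysis used min_rate = 1 ("call rate of 1") to remove
    every locus with any missing call before the diversity summaries.
    """
    if not 0.0 <= min_rate <= 1.0:
        raise ValueError(f"min_rate must be in [0, 1], got {min_rate}")
    keep = matrix.call_rates() >= min_rate
    loci = [loc for loc, k in zip(matrix.loci, keep) if k]
    return GenotypeMatrix(loci, matrix.individuals, matrix.calls[keep])


def subset(
    matrix: GenotypeMatrix,
    keep_individuals: Iterable[str] | None = None,
    keep_loci: Iterable[str] | None = None,
) -> GenotypeMatrix:
    """Project onto the requested individuals and/or loci, preserving order.

    Ids not present in the matrix raise; no call values are altered.
    """
    loci = matrix.loci
    individuals = matrix.individuals
    calls = matrix.calls

    if keep_loci is not None:
        wanted = set(keep_loci)
        unknown = wanted - set(matrix.locus_ids())
        if unknown:
            raise KeyError(f"unknown locus ids: {sorted(unknown)}")
        mask = np.array([loc.id in wanted for loc in loci], dtype=bool)
        loci = [loc for loc, k in zip(loci, mask) if k]
        calls = calls[mask]

    if keep_individuals is not None:
        wanted = set(keep_individuals)
        unknown = wanted - set(matrix.individual_ids())
        if unknown:
            raise KeyError(f"unknown individual ids: {sorted(unknown)}")
        mask = np.array([ind.id in wanted for ind in individuals], dtype=bool)
        individuals = [ind for ind, k in zip(individuals, mask) if k]
        calls = calls[:, mask]

    return GenotypeMatrix(loci, individuals, calls)
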