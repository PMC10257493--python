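"""Cohort, genome and hit-table simulator for inversion-polymorphism analyses.

The simulator encodes the recombination-suppression model the analysis
assumes: each individual carries two arrangement haplotypes of the
polymorphic chromosome (AA: a/a, MA: m/a, MM: m/m).  Inside a planted
rearranged region, rearrangement-linked loci are deterministic per
haplotype — the derived arrangement m carries the alt allele as a single
frozen haplotype, the ancestral a carries ref — so noiseless calls are
AA -> 0, MA -> 1, MM -> 2.  All other loci are karyotype-independent:
an alt-allele frequency is drawn per locus and genotypes follow
Hardy–Weinberg proportions.  Symmetric genotyping error (a call is
replaced by one of the other two states uniformly, probability e per
call) and independent missingness are applied last.

Default cohort sizes mirror the four-population, 34-individual design of
the study system (three karyotypes present in one western reference
population); scaffold counts and relative sizes mirror its seven
candidate scaffolds, scaled down so a full simulation runs in seconds.
"""

from __future__ import annotations

import json
import zlib
from dataclasses import dataclass, field, asdict
from typing import Mapping, Sequence

import numpy as np

from .genotype_io import (
    MISSING,
    GenotypeMatrix,
    Individual,
    KaryotypeLabel,
    Locus,
)
from .locus_mapping import LocusAssignment

#: DArT tags are short restriction fragments; 69 bp is the standard read core.
TAG_LENGTH = 69

#: (n_AA, n_MA, n_MM) per population — one population carries all three
#: karyotypes and serves as the natural reference cohort.
DEFAULT_COHORT: dict[str, tuple[int, int, int]] = {
    "south": (0, 3, 5),
    "west": (5, 3, 5),
    "east": (0, 0, 5),
    "north": (5, 3, 0),
}

#: Seven scaffolds with relative sizes matching the candidate set
#: (46.3 / 2.2 / 20.1 / 3.1 / 5.2 / 3.1 / 3.4), scaled to ~10 kb per unit.
DEFAULT_SCAFFOLDS: tuple[tuple[str, int], ...] = (
    ("scaf_1", 463_000),
    ("scaf_2", 22_000),
    ("scaf_3", 201_000),
    ("scaf_4", 31_000),
    ("scaf_5", 52_000),
    ("scaf_6", 31_000),
    ("scaf_7", 34_000),
)


@dataclass(frozen=True)
class SimConfig:
    n_per_karyotype: Mapping[str, tuple[int, int, int]] = field(
        default_factory=lambda: dict(DEFAULT_COHORT)
    )
    scaffolds: tuple[tuple[str, int], ...] = DEFAULT_SCAFFOLDS
    n_loci: int = 2000
    planted_region: tuple[str, int, int] = ("scaf_3", 50_000, 150_000)
    linked_fraction_in_region: float = 0.8
    maf_range: tuple[float, float] = (0.05, 0.5)
    genotyping_error: float = 0.01
    missing_rate: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        lengths = dict(self.scaffolds)
        scaf, lo, hi = self.planted_region
        if scaf not in lengths:
            raise ValueError(f"planted region scaffold {scaf!r} not in scaffold list")
        if not (0 <= lo < hi <= lengths[scaf]):
            raise ValueError("planted region outside its scaffold")
        for p in (self.linked_fraction_in_region, self.genotyping_error, self.missing_rate):
            if not 0.0 <= p <= 1.0:
                raise ValueError("probabilities must be in [0, 1]")
        lo_f, hi_f = self.maf_range
        if not 0.0 < lo_f <= hi_f < 1.0:
            raise ValueError("maf_range must lie strictly inside (0, 1)")
        n_aa = sum(v[0] for v in self.n_per_karyotype.values())
        n_mm = sum(v[2] for v in self.n_per_karyotype.values())
        if n_aa < 1 or n_mm < 1:
            raise ValueError("need at least one AA and one MM individual")


@dataclass
class SimTruth:
    linked_locus_ids: set[str]
    locus_scaffold: dict[str, str]
    locus_position: dict[str, int]       # tag start, 0-based
    karyotypes: dict[str, str]           # individual id -> label token
    config: SimConfig

    def to_json(self) -> str:
        payload = {
            "linked_locus_ids": sorted(self.linked_locus_ids),
            "locus_scaffold": self.locus_scaffold,
            "locus_position": self.locus_position,
            "karyotypes": self.karyotypes,
            "config": {
                **asdict(self.config),
                "n_per_karyotype": {k: list(v) for k, v in self.config.n_per_karyotype.items()},
                "scaffolds": [list(s) for s in self.config.scaffolds],
                "planted_region": list(self.config.planted_region),
                "maf_range": list(self.config.maf_range),
            },
        }
        return json.dumps(payload, indent=2, sort_keys=True)


def _rng(config: SimConfig, stage: str) -> np.random.Generator:
    # independent substream per stage so stages reproduce in isolation
    return np.random.default_rng([config.seed, zlib.crc32(stage.encode())])


def expected_false_fixed_rate(n_AA: int, n_MM: int, p: float) -> float:
    """Probability an unlinked HWE locus shows the fixed-opposite pattern.

    With alt frequency p and q = 1 - p, all AA homozygous-ref while all MM
    homozygous-alt (or the mirror image):
    (q^2)^n_AA (p^2)^n_MM + (p^2)^n_AA (q^2)^n_MM.  The MA-heterozygosity
    constraint is excluded, so this upper-bounds the strict-policy rate.
    """
    if n_AA < 1 or n_MM < 1:
        raise ValueError("both groups must be non-empty")
    if not 0.0 <= p <= 1.0:
        raise ValueError("p must be in [0, 1]")
    q = 1.0 - p
    return (p * p) ** n_AA * (q * q) ** n_MM + (q * q) ** n_AA * (p * p) ** n_MM


def simulate_cohort(
    config: SimConfig = SimConfig(),
) -> tuple[GenotypeMatrix, list[LocusAssignment], dict[str, str], SimTruth]:
    """Simulate genotypes, true locus placements, genome and ground truth.

    Returns (matrix, assignments, genome, truth) where ``genome`` maps
    scaffold name to sequence.  Deterministic given the config (seeded
    substreams per stage).  Tag sequences are slices of the simulated
    genome, so downstream hit tables and probe tiling operate on
    internally consistent coordinates.
    """
    # individuals
    individuals: list[Individual] = []
    counter = 1
    for pop in config.n_per_karyotype:
        n_aa, n_ma, n_mm = config.n_per_karyotype[pop]
        for label, count in ((KaryotypeLabel.AA, n_aa), (KaryotypeLabel.MA, n_ma),
                             (KaryotypeLabel.MM, n_mm)):
            for _ in range(count):
                individuals.append(Individual(f"ind{counter:03d}", pop, label))
                counter += 1

    # genome
    rng_g = _rng(config, "genome")
    bases = np.frombuffer(b"ACGT", dtype="S1")
    genome = {
        name: b"".join(rng_g.choice(bases, size=length)).decode()
        for name, length in config.scaffolds
    }

    # loci: scaffold weighted by length, tag position uniform
    rng_l = _rng(config, "loci")
    names = [n for n, _ in config.scaffolds]
    lengths = np.array([l for _, l in config.scaffolds], dtype=float)
    probs = lengths / lengths.sum()
    scaf_idx = rng_l.choice(len(names), size=config.n_loci, p=probs)
    region_scaf, region_lo, region_hi = config.planted_region

    loci: list[Locus] = []
    assignments: list[LocusAssignment] = []
    linked_ids: set[str] = set()
    locus_scaffold: dict[str, str] = {}
    locus_position: dict[str, int] = {}
    for k in range(config.n_loci):
        lid = f"L{k:05d}"
        scaf = names[scaf_idx[k]]
        max_start = int(lengths[scaf_idx[k]]) - TAG_LENGTH
        pos = int(rng_l.integers(0, max_start + 1))
        tag = genome[scaf][pos:pos + TAG_LENGTH]
        offset = int(rng_l.integers(0, TAG_LENGTH))
        ref = tag[offset]
        alt = rng_l.choice([b for b in "ACGT" if b != ref])
        loci.append(Locus(lid, tag, offset, ref, str(alt)))
        assignments.append(LocusAssignment(lid, scaf, pos, pos + TAG_LENGTH, "+"))
        locus_scaffold[lid] = scaf
        locus_position[lid] = pos
        in_region = scaf == region_scaf and region_lo <= pos < region_hi
        if in_region and rng_l.random() < config.linked_fraction_in_region:
            linked_ids.add(lid)

    # genotypes
    rng_c = _rng(config, "calls")
    n_ind = len(individuals)
    calls = np.zeros((config.n_loci, n_ind), dtype=np.int8)
    kar_calls = {KaryotypeLabel.AA: 0, KaryotypeLabel.MA: 1, KaryotypeLabel.MM: 2}
    kar_vec = np.array([kar_calls[ind.karyotype] for ind in individuals], dtype=np.int8)
    for k, loc in enumerate(loci):
        if loc.id in linked_ids:
            calls[k] = kar_vec
        else:
            p = rng_c.uniform(*config.maf_range)
            calls[k] = rng_c.binomial(2, p, size=n_ind).astype(np.int8)

    # symmetric genotyping error: replace with one of the other two states
    if config.genotyping_error > 0:
        rng_e = _rng(config, "error")
        flip = rng_e.random(calls.shape) < config.genotyping_error
        shift = rng_e.integers(1, 3, size=calls.shape)  # +1 or +2 mod 3
        calls = np.where(flip, (calls + shift) % 3, calls).astype(np.int8)

    # missingness
    if config.missing_rate > 0:
        rng_m = _rng(config, "missing")
        drop = rng_m.random(calls.shape) < config.missing_rate
        calls = np.where(drop, np.int8(MISSING), calls)

    matrix = GenotypeMatrix(loci, individuals, calls)
    truth = SimTruth(
        linked_locus_ids=linked_ids,
        locus_scaffold=locus_scaffold,
        locus_position=locus_position,
        karyotypes={ind.id: ind.karyotype.value for ind in individuals},
        config=config,
    )
    return matrix, assignments, genome, truth


def simulate_hit_table(
    truth: SimTruth,
    off_target_rate: float = 0.0,
    identity_jitter: float = 0.0,
) -> str:
    """BLAST-tabular (outfmt 6) text with one on-target hit per locus.

    On-target hits carry pident >= 95 (reduced by up to ``identity_jitter``
    percentage points, capped at 95) and e-value 1e-30.  With probability
    ``off_target_rate`` a locus also receives a decoy hit on another
    scaffold with sub-threshold identity (~50%) and e-value (1e-3), which
    the standard filters must reject.  Deterministic under the truth's seed.
    """
    config = truth.config
    rng = _rng(config, "hits")
    names = [n for n, _ in config.scaffolds]
    lengths = dict(config.scaffolds)
    lines = []
    for lid in sorted(truth.locus_scaffold):
        scaf = truth.locus_scaffold[lid]
        pos = truth.locus_position[lid]
        pident = 100.0 - (rng.random() * identity_jitter if identity_jitter else 0.0)
        pident = max(95.0, pident)
        mism = int(round(TAG_LENGTH * (100.0 - pident) / 100.0))
        lines.append(
            f"{lid}\t{scaf}\t{pident:.2f}\t{TAG_LENGTH}\t{mism}\t0\t1\t{TAG_LENGTH}\t"
            f"{pos + 1}\t{pos + TAG_LENGTH}\t1e-30\t{120.0:.1f}"
        )
        if off_target_rate and rng.random() < off_target_rate:
            other = names[int(rng.integers(0, len(names)))]
            dpos = int(rng.integers(0, max(1, lengths[other] - TAG_LENGTH)))
            dident = 40.0 + rng.random() * 25.0      # below the 70% floor
            lines.append(
                f"{lid}\t{other}\t{dident:.2f}\t{TAG_LENGTH // 2}\t20\t2\t1\t{TAG_LENGTH // 2}\t"
                f"{dpos + 1}\t{dpos + TAG_LENGTH // 2}\t1e-3\t{30.0:.1f}"
            )
    return "\n".join(lines) + "\n"
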