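"""Fixed-allele-difference classification between karyotype groups.

A locus is a *fixed allele difference* between the two homozygous
karyotype groups when every AA individual carries one homozygous call
h in {0, 2}, every MM individual carries the opposite homozygote 2 - h,
and (under the strict policy) every heterokaryotypic MA individual is
heterozygous (call 1).  Such loci witness a complete absence of allele
sharing between the two chromosome arrangements — the population-genetic
signature of recombination suppression across a rearranged region.

The module classifies loci, tabulates per-scaffold pre-/post-sorting
counts, builds the individual-level Euclidean distance matrix over
candidate loci with agglomerative clustering for heat-map ordering, and
summarizes per-karyotype diversity (observed heterozygosity, minor-call
frequency).
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum
from typing import Iterable, Sequence

import numpy as np

from .genotype_io import MISSING, GenotypeMatrix, KaryotypeLabel
from .locus_mapping import LocusAssignment


class FixedStatus(str, Enum):
    FIXED = "FIXED"
    NOT_FIXED = "NOT_FIXED"
    INELIGIBLE = "INELIGIBLE"


class Orientation(str, Enum):
    AA_IS_0 = "AA_is_0"
    AA_IS_2 = "AA_is_2"
    NA = "NA"


@dataclass(frozen=True)
class FixedDiffPolicy:
    """Strictness knobs for the fixed-difference filter.

    require_het_in_MA: insist every heterokaryotype is called 1 (the strict
    reading); when false, MA calls never veto and only ma_consistency is
    reported.  allow_missing=False renders a locus INELIGIBLE if any group
    member is missing, mirroring a call-rate-1 stance; True evaluates the
    non-missing calls only.
    """

    require_het_in_MA: bool = True
    min_group_size: int = 2
    allow_missing: bool = False

    def __post_init__(self) -> None:
        if self.min_group_size < 1:
            raise ValueError("min_group_size must be >= 1")


@dataclass(frozen=True)
class LocusVerdict:
    locus_id: str
    status: FixedStatus
    orientation: Orientation
    ma_consistency: float | None
    reason: str = ""

    def __post_init__(self) -> None:
        if (self.status == FixedStatus.FIXED) != (self.orientation != Orientation.NA):
            raise ValueError("orientation must be set iff status is FIXED")


@dataclass(frozen=True)
class ScaffoldCountRow:
    scaffold: str
    n_loci_mapped: int
    n_fixed: int
    scaffold_span: int | None = None

    def __post_init__(self) -> None:
        if self.n_fixed > self.n_loci_mapped:
            raise ValueError("n_fixed cannot exceed n_loci_mapped")


@dataclass
class PairwiseMatrix:
    individuals: list[str]
    values: np.ndarray
    metric_tag: str

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        n = len(self.individuals)
        if v.shape != (n, n):
            raise ValueError("pairwise matrix shape mismatch")
        if not np.allclose(v, v.T, atol=1e-12):
            raise ValueError("pairwise matrix not symmetric")
        if not np.allclose(np.diag(v), 0.0, atol=1e-12):
            raise ValueError("pairwise matrix diagonal not zero")
        if (v < -1e-12).any():
            raise ValueError("pairwise matrix has negative entries")
        self.values = v


@dataclass(frozen=True)
class DiversitySummary:
    """Per-karyotype-group diversity over a set of loci."""

    group: KaryotypeLabel
    het_obs: tuple[float, ...]      # per-locus observed heterozygosity (nan = no data)
    minor_call_freq: tuple[float, ...]  # per-locus minor homozygote frequency
    mean_het: float


# ---------------------------------------------------------------------------
# Locus classification
# ---------------------------------------------------------------------------

def classify_locus(
    calls_AA: Sequence[int],
    calls_MM: Sequence[int],
    calls_MA: Sequence[int] = (),
    policy: FixedDiffPolicy = FixedDiffPolicy(),
) -> LocusVerdict:
    """Classify one locus as FIXED / NOT_FIXED / INELIGIBLE.

    FIXED iff every AA call equals some h in {0, 2}, every MM call equals
    2 - h, and — when require_het_in_MA and MA is non-empty — every MA
    call equals 1.  A group smaller than min_group_size makes the locus
    INELIGIBLE (reported, not raised), as does any missing call when
    allow_missing is false; with allow_missing the non-missing calls are
    evaluated instead.  ma_consistency (fraction of non-missing MA calls
    equal to 1) is reported whenever MA individuals exist.
    """
    aa = np.asarray(calls_AA, dtype=int)
    mm = np.asarray(calls_MM, dtype=int)
    ma = np.asarray(calls_MA, dtype=int)

    ma_cons: float | None = None
    if ma.size:
        ma_nm = ma[ma != MISSING]
        ma_cons = float((ma_nm == 1).mean()) if ma_nm.size else None

    def ineligible(reason: str, locus_id: str = "") -> LocusVerdict:
        return LocusVerdict(locus_id, FixedStatus.INELIGIBLE, Orientation.NA, ma_cons, reason)

    if len(aa) < policy.min_group_size or len(mm) < policy.min_group_size:
        return ineligible("group below min_group_size")

    if not policy.allow_missing:
        if (aa == MISSING).any() or (mm == MISSING).any() or (ma == MISSING).any():
            return ineligible("missing call under allow_missing=false")
        aa_e, mm_e, ma_e = aa, mm, ma
    else:
        aa_e = aa[aa != MISSING]
        mm_e = mm[mm != MISSING]
        ma_e = ma[ma != MISSING]
        if len(aa_e) < policy.min_group_size or len(mm_e) < policy.min_group_size:
            return ineligible("non-missing group below min_group_size")

    for h in (0, 2):
        if (aa_e == h).all() and (mm_e == 2 - h).all():
            if policy.require_het_in_MA and ma_e.size and not (ma_e == 1).all():
                break
            orientation = Orientation.AA_IS_0 if h == 0 else Orientation.AA_IS_2
            return LocusVerdict("", FixedStatus.FIXED, orientation, ma_cons)
    return LocusVerdict("", FixedStatus.NOT_FIXED, Orientation.NA, ma_cons)


def scan_fixed_differences(
    matrix: GenotypeMatrix,
    assignments: Sequence[LocusAssignment],
    policy: FixedDiffPolicy = FixedDiffPolicy(),
    reference_individuals: Iterable[str] | None = None,
) -> tuple[list[LocusVerdict], list[ScaffoldCountRow]]:
    """Classify every assigned locus and tabulate per-scaffold counts.

    ``reference_individuals`` restricts which individuals' calls define the
    karyotype groups (the published analysis used the single western
    population holding all three karyotypes); None uses every individual.
    Returns the verdicts (one per assignment, in assignment order) and the
    per-scaffold count table sorted by scaffold name with a totals row
    ("TOTAL") appended.
    """
    if reference_individuals is not None:
        ref = list(reference_individuals)
        if not ref:
            raise ValueError("empty reference individual set")
        unknown = set(ref) - set(matrix.individual_ids())
        if unknown:
            raise KeyError(f"unknown reference individuals: {sorted(unknown)}")
        use = [j for j, ind in enumerate(matrix.individuals) if ind.id in set(ref)]
    else:
        use = list(range(matrix.n_individuals))

    cols = {lab: [j for j in use if matrix.individuals[j].karyotype == lab]
            for lab in (KaryotypeLabel.AA, KaryotypeLabel.MM, KaryotypeLabel.MA)}
    row_of = {loc.id: i for i, loc in enumerate(matrix.loci)}

    verdicts: list[LocusVerdict] = []
    mapped: dict[str, int] = {}
    fixed: dict[str, int] = {}
    for a in assignments:
        if a.locus_id not in row_of:
            raise KeyError(f"assignment references unknown locus {a.locus_id!r}")
        row = matrix.calls[row_of[a.locus_id]]
        v = classify_locus(
            row[cols[KaryotypeLabel.AA]],
            row[cols[KaryotypeLabel.MM]],
            row[cols[KaryotypeLabel.MA]],
            policy,
        )
        v = LocusVerdict(a.locus_id, v.status, v.orientation, v.ma_consistency, v.reason)
        verdicts.append(v)
        mapped[a.scaffold] = mapped.get(a.scaffold, 0) + 1
        if v.status == FixedStatus.FIXED:
            fixed[a.scaffold] = fixed.get(a.scaffold, 0) + 1

    rows = [
        ScaffoldCountRow(s, mapped[s], fixed.get(s, 0)) for s in sorted(mapped)
    ]
    if rows:
        rows.append(
            ScaffoldCountRow(
                "TOTAL",
                sum(r.n_loci_mapped for r in rows),
                sum(r.n_fixed for r in rows),
            )
        )
    return verdicts, rows


def aggregate_counts(rows: Sequence[ScaffoldCountRow]) -> tuple[int, int]:
    """Column sums (total mapped, total fixed), ignoring any TOTAL row."""
    body = [r for r in rows if r.scaffold != "TOTAL"]
    return (sum(r.n_loci_mapped for r in body), sum(r.n_fixed for r in body))


# ---------------------------------------------------------------------------
# Pairwise distances and clustering
# ---------------------------------------------------------------------------

def pairwise_call_distance(
    matrix: GenotypeMatrix,
    candidate_loci: Iterable[str],
    pairwise_complete_scaling: bool = True,
) -> PairwiseMatrix:
    """Euclidean distance between individuals over candidate loci.

    Per pair, only loci where both calls are non-missing contribute; the
    norm is rescaled by sqrt(L / L_complete) so missingness does not
    deflate distances (switchable off).  A pair with zero jointly
    non-missing loci raises.
    """
    wanted = list(dict.fromkeys(candidate_loci))
    if not wanted:
        raise ValueError("candidate locus set is empty")
    row_of = {loc.id: i for i, loc in enumerate(matrix.loci)}
    unknown = [lid for lid in wanted if lid not in row_of]
    if unknown:
        raise KeyError(f"unknown candidate loci: {unknown}")
    sub = matrix.calls[[row_of[lid] for lid in wanted]].astype(float)
    sub[sub == MISSING] = np.nan
    L = sub.shape[0]
    n = matrix.n_individuals
    out = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            both = ~np.isnan(sub[:, i]) & ~np.isnan(sub[:, j])
            lc = int(both.sum())
            if lc == 0:
                raise ValueError(
                    f"individuals {matrix.individuals[i].id!r} and "
                    f"{matrix.individuals[j].id!r} share no non-missing loci"
                )
            d = float(np.sqrt(((sub[both, i] - sub[both, j]) ** 2).sum()))
            if pairwise_complete_scaling:
                d *= np.sqrt(L / lc)
            out[i, j] = out[j, i] = d
    tag = "euclidean_pairwise_complete" if pairwise_complete_scaling else "euclidean"
    return PairwiseMatrix(matrix.individual_ids(), out, tag)


@dataclass(frozen=True)
class DendrogramNode:
    """Binary merge-tree node; leaves carry a label, internal nodes a height."""

    height: float
    label: str | None = None
    children: tuple["DendrogramNode", ...] = ()

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def leaves(self) -> list[str]:
        if self.is_leaf:
            return [self.label]  # type: ignore[list-item]
        return [leaf for child in self.children for leaf in child.leaves()]

    def to_newick(self) -> str:
        def rec(node: DendrogramNode, parent_height: float) -> str:
            bl = max(parent_height - node.height, 0.0)
            if node.is_leaf:
                return f"{node.label}:{bl:.6g}"
            inner = ",".join(rec(c, node.height) for c in node.children)
            return f"({inner}):{bl:.6g}"

        if self.is_leaf:
            return f"{self.label};"
        inner = ",".join(rec(c, self.height) for c in self.children)
        return f"({inner});"


def hierarchical_cluster(matrix: PairwiseMatrix, linkage: str = "average") -> DendrogramNode:
    """Agglomerative clustering with single/complete/average linkage.

    Lance–Williams updates; among equal-distance pairs the one whose
    (sorted) smallest-leaf labels are lexicographically smallest merges
    first, making leaf order deterministic.  Merge heights are
    non-decreasing for these linkages on a metric input.
    """
    if linkage not in ("single", "complete", "average"):
        raise ValueError(f"unknown linkage {linkage!r}")
    n = len(matrix.individuals)
    if n < 2:
        raise ValueError("need at least 2 individuals to cluster")

    dist: dict[tuple[int, int], float] = {}
    for i in range(n):
        for j in range(i + 1, n):
            dist[(i, j)] = float(matrix.values[i, j])
    nodes: dict[int, DendrogramNode] = {
        i: DendrogramNode(0.0, matrix.individuals[i]) for i in range(n)
    }
    sizes: dict[int, int] = {i: 1 for i in range(n)}
    keyname: dict[int, str] = {i: matrix.individuals[i] for i in range(n)}
    next_id = n

    def d(a: int, b: int) -> float:
        return dist[(a, b) if a < b else (b, a)]

    active = set(range(n))
    while len(active) > 1:
        best = None
        for a in sorted(active):
            for b in sorted(active):
                if a >= b:
                    continue
                key = (d(a, b), tuple(sorted((keyname[a], keyname[b]))))
                if best is None or key < best[0]:
                    best = (key, a, b)
        (h, _), a, b = best  # type: ignore[misc]
        merged = DendrogramNode(h, None, (nodes[a], nodes[b]))
        nodes[next_id] = merged
        sizes[next_id] = sizes[a] + sizes[b]
        keyname[next_id] = min(keyname[a], keyname[b])
        for c in active:
            if c in (a, b):
                continue
            if linkage == "single":
                nd = min(d(a, c), d(b, c))
            elif linkage == "complete":
                nd = max(d(a, c), d(b, c))
            else:
                nd = (sizes[a] * d(a, c) + sizes[b] * d(b, c)) / (sizes[a] + sizes[b])
            dist[(min(c, next_id), max(c, next_id))] = nd
        active.discard(a)
        active.discard(b)
        active.add(next_id)
        next_id += 1
    return nodes[next_id - 1]


# ---------------------------------------------------------------------------
# Diversity summaries
# ---------------------------------------------------------------------------

def group_diversity(
    matrix: GenotypeMatrix,
    groups: dict[KaryotypeLabel, Sequence[str]] | None = None,
) -> list[DiversitySummary]:
    """Observed heterozygosity and minor-call frequency per karyotype group.

    Per locus per group: het_obs = fraction of non-missing calls equal
    to 1; minor_call_freq = the rarer of the 0/2 homozygote counts over
    their total (0 when no homozygotes).  Loci with no non-missing calls
    in a group are excluded from that group's mean (reported as nan).
    Default grouping: all karyotype labels present except UNKNOWN.
    """
    if groups is None:
        groups = {}
        for ind in matrix.individuals:
            if ind.karyotype != KaryotypeLabel.UNKNOWN:
                groups.setdefault(ind.karyotype, []).append(ind.id)  # type: ignore[arg-type]
    col_of = {ind.id: j for j, ind in enumerate(matrix.individuals)}
    out: list[DiversitySummary] = []
    for label, ids in groups.items():
        if not len(ids):
            raise ValueError(f"group {label} is empty")
        cols = [col_of[i] for i in ids]
        sub = matrix.calls[:, cols]
        het = np.full(matrix.n_loci, np.nan)
        minor = np.full(matrix.n_loci, np.nan)
        for i in range(matrix.n_loci):
            row = sub[i]
            nm = row[row != MISSING]
            if nm.size == 0:
                continue
            het[i] = float((nm == 1).mean())
            n0 = int((nm == 0).sum())
            n2 = int((nm == 2).sum())
            minor[i] = min(n0, n2) / (n0 + n2) if (n0 + n2) else 0.0
        mean_het = float(np.nanmean(het)) if np.isfinite(het).any() else float("nan")
        out.append(DiversitySummary(label, tuple(het), tuple(minor), mean_het))
    return out


# ---------------------------------------------------------------------------
# Exports
# ---------------------------------------------------------------------------

def write_verdicts_tsv(verdicts: Sequence[LocusVerdict], sink) -> None:
    own = isinstance(sink, str)
    handle = open(sink, "w") if own else sink
    try:
        handle.write("locus_id\tstatus\torientation\tma_consistency\treason\n")
        for v in verdicts:
            mc = "" if v.ma_consistency is None else f"{v.ma_consistency:.6g}"
            handle.write(
                f"{v.locus_id}\t{v.status.value}\t{v.orientation.value}\t{mc}\t{v.reason}\n"
            )
    finally:
        if own:
            handle.close()


def write_count_table_tsv(rows: Sequence[ScaffoldCountRow], sink) -> None:
    own = isinstance(sink, str)
    handle = open(sink, "w") if own else sink
    try:
        handle.write("scaffold\tn_loci_mapped\tn_fixed\n")
        for r in rows:
            handle.write(f"{r.scaffold}\t{r.n_loci_mapped}\t{r.n_fixed}\n")
    finally:
        if own:
            handle.close()


def write_pairwise_tsv(matrix: PairwiseMatrix, sink) -> None:
    own = isinstance(sink, str)
    handle = open(sink, "w") if own else sink
    try:
        handle.write("\t" + "\t".join(matrix.individuals) + "\n")
        for i, iid in enumerate(matrix.individuals):
            handle.write(iid + "\t" + "\t".join(f"{v:.6g}" for v in matrix.values[i]) + "\n")
    finally:
        if own:
            handle.close()


def render_heatmap(
    matrix: GenotypeMatrix,
    candidate_loci: Sequence[str],
    dendrogram: DendrogramNode,
    path: str,
) -> None:
    """Calls heat map over candidate loci, columns ordered by the dendrogram."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    order = dendrogram.leaves()
    col_of = {ind.id: j for j, ind in enumerate(matrix.individuals)}
    row_of = {loc.id: i for i, loc in enumerate(matrix.loci)}
    grid = np.array(
        [[matrix.calls[row_of[lid], col_of[iid]] for iid in order] for lid in candidate_loci],
        dtype=float,
    )
    grid[grid == MISSING] = np.nan
    fig, ax = plt.subplots(figsize=(max(4, len(order) * 0.4), max(3, len(candidate_loci) * 0.12)))
    im = ax.imshow(grid, aspect="auto", cmap="coolwarm", vmin=0, vmax=2)
    labels = []
    for iid in order:
        ind = matrix.individuals[col_of[iid]]
        labels.append(f"{ind.karyotype.value} {iid} ({ind.population})")
    ax.set_xticks(range(len(order)), labels, rotation=90, fontsize=6)
    ax.set_yticks([])
    fig.colorbar(im, ax=ax, label="call")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
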