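"""Windowed repeat densities, GC/CpG summaries, and rank-sum scaffold contrasts.

Repeat annotations come from RepeatMasker ``.out`` tables (parsed, never
recomputed).  Densities are reduced to fixed windows (100 kb by default)
as covered fraction per repeat class, with each scaffold's profile
normalized so its maximal window equals 1.  Two scaffolds are contrasted
class-by-class with a Wilcoxon rank-sum test, windows as observations:
exact two-sided p by enumeration for small tie-free samples, otherwise a
tie-corrected normal approximation with continuity correction.
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.stats import norm

#: Sentinel for a window with no informative (non-N) bases.
UNDEFINED = float("nan")


@dataclass(frozen=True)
class RepeatFeature:
    """One annotated repeat interval (0-based half-open)."""

    scaffold: str
    start: int
    end: int
    repeat_class: str
    family: str = ""

    def __post_init__(self) -> None:
        if not self.start < self.end:
            raise ValueError(
                f"repeat on {self.scaffold}: start {self.start} >= end {self.end}"
            )


@dataclass(frozen=True)
class WindowProfile:
    scaffold: str
    window_start: int
    window_end: int
    covered_fraction: dict[str, float]
    normalized_density: dict[str, float]
    gc_fraction: float = UNDEFINED


@dataclass(frozen=True)
class RankSumResult:
    n1: int
    n2: int
    statistic: float        # rank-sum of sample 1
    p_two_sided: float
    method: str             # "exact" or "normal_tie_corrected"


# ---------------------------------------------------------------------------
# RepeatMasker .out parsing
# ---------------------------------------------------------------------------

def parse_repeatmasker_out(stream) -> list[RepeatFeature]:
    """Parse RepeatMasker ``.out`` text into repeat features.

    The two header lines and blank lines are skipped.  The class/family
    column (11th) is split on '/' into class and family; coordinates
    (1-based inclusive in the file) become 0-based half-open.
    """
    if isinstance(stream, str):
        lines = stream.splitlines()
    else:
        lines = [line.rstrip("\n") for line in stream]
    feats: list[RepeatFeature] = []
    for lineno, line in enumerate(lines, start=1):
        stripped = line.strip()
        if not stripped:
            continue
        fields = stripped.split()
        if fields[0] in ("SW", "score"):  # header rows
            continue
        if len(fields) < 11:
            raise ValueError(f"line {lineno}: expected >= 11 columns, got {len(fields)}")
        try:
            scaffold = fields[4]
            start = int(fields[5]) - 1
            end = int(fields[6])
            cls_fam = fields[10]
        except ValueError as exc:
            raise ValueError(f"line {lineno}: {exc}") from exc
        if end <= start:
            raise ValueError(f"line {lineno}: end <= start")
        cls, _, family = cls_fam.partition("/")
        feats.append(RepeatFeature(scaffold, start, end, cls, family))
    return feats


# ---------------------------------------------------------------------------
# Window profiles
# ---------------------------------------------------------------------------

def _union(intervals: list[tuple[int, int]]) -> list[tuple[int, int]]:
    if not intervals:
        return []
    intervals.sort()
    merged = [list(intervals[0])]
    for s, e in intervals[1:]:
        if s > merged[-1][1]:
            merged.append([s, e])
        else:
            merged[-1][1] = max(merged[-1][1], e)
    return [(s, e) for s, e in merged]


def window_densities(
    features: Sequence[RepeatFeature],
    scaffold_length: int,
    window: int = 100_000,
    classes: Sequence[str] | None = None,
) -> list[WindowProfile]:
    """Per-window covered fraction and max-normalized density per repeat class.

    Windows tile [0, scaffold_length); the last window may be short and its
    fraction uses its true width.  Overlapping features of a class are
    unioned first so fractions never exceed 1.  The synthetic class
    "total" is always included (union over all classes).  An all-zero
    class yields all-zero normalized densities (no division).
    """
    if scaffold_length < 1:
        raise ValueError("scaffold_length must be >= 1")
    if window <= 0:
        raise ValueError("window must be positive")
    class_names = sorted({f.repeat_class for f in features}) if classes is None else list(classes)
    per_class = {c: [(f.start, f.end) for f in features if f.repeat_class == c]
                 for c in class_names}
    per_class["total"] = [(f.start, f.end) for f in features]
    unions = {c: _union(list(ivs)) for c, ivs in per_class.items()}

    starts = list(range(0, scaffold_length, window))
    covered: dict[str, list[float]] = {c: [] for c in unions}
    for ws in starts:
        we = min(ws + window, scaffold_length)
        width = we - ws
        for c, ivs in unions.items():
            ov = sum(max(0, min(e, we) - max(s, ws)) for s, e in ivs)
            covered[c].append(ov / width)
    normalized: dict[str, list[float]] = {}
    for c, vals in covered.items():
        mx = max(vals) if vals else 0.0
        normalized[c] = [v / mx for v in vals] if mx > 0 else [0.0] * len(vals)

    return [
        WindowProfile(
            scaffold=features[0].scaffold if features else "",
            window_start=ws,
            window_end=min(ws + window, scaffold_length),
            covered_fraction={c: covered[c][k] for c in covered},
            normalized_density={c: normalized[c][k] for c in covered},
        )
        for k, ws in enumerate(starts)
    ]


def gc_windows(seq: str, window: int) -> list[float]:
    """G+C fraction over non-N bases per window; all-N windows are NaN."""
    if not seq:
        raise ValueError("empty sequence")
    if window <= 0:
        raise ValueError("window must be positive")
    seq = seq.upper()
    out = []
    for ws in range(0, len(seq), window):
        chunk = seq[ws:ws + window]
        counts = Counter(chunk)
        denom = len(chunk) - counts.get("N", 0)
        if denom == 0:
            out.append(UNDEFINED)
        else:
            out.append((counts.get("G", 0) + counts.get("C", 0)) / denom)
    return out


def cpg_obs_exp(seq: str, window: int) -> list[float]:
    """Observed/expected CpG ratio per window.

    obs/exp = count(CG) * window_length / (count(C) * count(G)); 0 when
    the window lacks C or G.  CG dinucleotides are counted within windows
    (the boundary-straddling dinucleotide is attributed to neither).
    """
    if not seq:
        raise ValueError("empty sequence")
    if window <= 0:
        raise ValueError("window must be positive")
    seq = seq.upper()
    out = []
    for ws in range(0, len(seq), window):
        chunk = seq[ws:ws + window]
        c = chunk.count("C")
        g = chunk.count("G")
        if c == 0 or g == 0:
            out.append(0.0)
        else:
            out.append(chunk.count("CG") * len(chunk) / (c * g))
    return out


def call_cpg_islands(
    seq: str,
    min_obs_exp: float = 0.6,
    min_gc: float = 0.5,
    min_length: int = 200,
    window: int = 200,
) -> list[tuple[int, int]]:
    """Classic CpG-island rule: windows with obs/exp >= 0.6 and GC >= 0.5,
    merged, reported when the merged run is >= min_length."""
    gc = gc_windows(seq, window)
    oe = cpg_obs_exp(seq, window)
    hits = [
        (i * window, min((i + 1) * window, len(seq)))
        for i in range(len(gc))
        if not math.isnan(gc[i]) and gc[i] >= min_gc and oe[i] >= min_obs_exp
    ]
    return [(s, e) for s, e in _union(hits) if e - s >= min_length]


# ---------------------------------------------------------------------------
# Wilcoxon rank-sum test
# ---------------------------------------------------------------------------

def _midranks(pooled: np.ndarray) -> np.ndarray:
    order = np.argsort(pooled, kind="mergesort")
    ranks = np.empty(len(pooled))
    sorted_vals = pooled[order]
    i = 0
    while i < len(pooled):
        j = i
        while j + 1 < len(pooled) and sorted_vals[j + 1] == sorted_vals[i]:
            j += 1
        ranks[order[i:j + 1]] = (i + j) / 2 + 1  # average of 1-based ranks
        i = j + 1
    return ranks


def _exact_ranksum_counts(n1: int, n2: int) -> np.ndarray:
    """counts[w] = number of n1-subsets of ranks 1..n1+n2 summing to w
    (dynamic programming over rank inclusion)."""
    N = n1 + n2
    max_sum = n1 * N
    table = np.zeros((n1 + 1, max_sum + 1), dtype=float)
    table[0, 0] = 1.0
    for r in range(1, N + 1):
        for k in range(min(r, n1), 0, -1):
            table[k, r:] += table[k - 1, :-r] if r else table[k - 1, :]
    return table[n1]


def rank_sum_test(
    x: Sequence[float], y: Sequence[float], exact_max_n: int = 25
) -> RankSumResult:
    """Two-sample Wilcoxon rank-sum test; statistic = rank-sum of ``x``.

    Exact two-sided p by enumeration of all rank assignments when
    n1 + n2 <= exact_max_n and the pooled data are tie-free (two-sided p =
    2 * min tail, capped at 1); otherwise the tie-corrected normal
    approximation with a 0.5 continuity correction.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be non-empty")
    n1, n2 = len(x), len(y)
    pooled = np.concatenate([x, y])
    ranks = _midranks(pooled)
    w = float(ranks[:n1].sum())
    has_ties = len(np.unique(pooled)) < len(pooled)

    if n1 + n2 <= exact_max_n and not has_ties:
        counts = _exact_ranksum_counts(n1, n2)
        total = counts.sum()
        wi = int(round(w))
        lower = counts[: wi + 1].sum() / total
        upper = counts[wi:].sum() / total
        p = min(1.0, 2.0 * min(lower, upper))
        return RankSumResult(n1, n2, w, float(p), "exact")

    N = n1 + n2
    mean = n1 * (N + 1) / 2.0
    tie_counts = np.array(list(Counter(pooled.tolist()).values()), dtype=float)
    tie_term = ((tie_counts ** 3 - tie_counts).sum()) / ((N * (N - 1)) or 1)
    var = n1 * n2 / 12.0 * ((N + 1) - tie_term)
    if var <= 0:
        return RankSumResult(n1, n2, w, 1.0, "normal_tie_corrected")
    diff = w - mean
    cc = 0.5 if abs(diff) > 0.5 else abs(diff)
    z = (abs(diff) - cc) / math.sqrt(var)
    p = min(1.0, 2.0 * float(norm.sf(z)))
    return RankSumResult(n1, n2, w, p, "normal_tie_corrected")


def contrast_scaffolds(
    profiles_a: Sequence[WindowProfile],
    profiles_b: Sequence[WindowProfile],
    repeat_class: str,
    exact_max_n: int = 25,
) -> RankSumResult:
    """Rank-sum contrast of one repeat class between two scaffolds,
    windowed covered fractions as the observations."""
    xa = [p.covered_fraction.get(repeat_class, 0.0) for p in profiles_a]
    xb = [p.covered_fraction.get(repeat_class, 0.0) for p in profiles_b]
    return rank_sum_test(xa, xb, exact_max_n=exact_max_n)
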