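"""End-to-end orchestration: map -> fixedscan -> repeatstats -> tree -> probes.

A single run configuration drives all stages; every stage that drops
records reports in/out counts in the run manifest, artifacts are written
under one output directory, and the run is deterministic given inputs
and seed.
"""

from __future__ import annotations

import hashlib
import json
import logging
import sys
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import yaml

from . import __version__
from .concat_phylo import concat_sequences, export_alignment, midpoint_root, nj, p_distance
from .fixed_allele_core import (
    FixedDiffPolicy,
    FixedStatus,
    hierarchical_cluster,
    pairwise_call_distance,
    render_heatmap,
    scan_fixed_differences,
    write_count_table_tsv,
    write_pairwise_tsv,
    write_verdicts_tsv,
)
from .genotype_io import read_genotypes, read_metadata, read_tag_fasta, attach_tags
from .locus_mapping import (
    HitFilterConfig,
    parse_blast_tab,
    restrict_to_scaffolds,
    select_assignments,
    write_assignments_bed,
)
from .probe_design import (
    ProbeParams,
    mask_from_hits,
    tile_candidates,
    uniqueness_screen,
    write_oligos_fasta,
    write_oligos_tsv,
)
from .repeat_stats import contrast_scaffolds, parse_repeatmasker_out, window_densities

logger = logging.getLogger("karyofix")


class ConfigError(ValueError):
    """Raised before any stage runs when the configuration is invalid."""


class StageError(RuntimeError):
    def __init__(self, stage: str, message: str) -> None:
        super().__init__(f"stage {stage}: {message}")
        self.stage = stage


@dataclass
class RunConfig:
    genotypes: Path
    metadata: Path
    hits: Path
    out_dir: Path
    tags: Path | None = None
    genome: Path | None = None
    repeats: Path | None = None
    homology_hits: Path | None = None   # target scaffold vs background genome
    dialect: str = "wide"
    hit_filter: HitFilterConfig = field(default_factory=HitFilterConfig)
    policy: FixedDiffPolicy = field(default_factory=FixedDiffPolicy)
    reference_population: str | None = None
    restrict_scaffolds: tuple[str, ...] | None = None
    tree_scaffold: str | None = None       # default: scaffold with most fixed loci
    probe_scaffold: str | None = None
    window: int = 100_000
    contrast: tuple[str, str] | None = None
    probe_params: ProbeParams = field(default_factory=ProbeParams)
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        kwargs: dict[str, Any] = {}
        for key in ("genotypes", "metadata", "hits", "out_dir", "tags", "genome",
                    "repeats", "homology_hits"):
            if raw.get(key) is not None:
                kwargs[key] = Path(raw[key])
        for key in ("dialect", "reference_population", "tree_scaffold",
                    "probe_scaffold", "window", "seed"):
            if key in raw:
                kwargs[key] = raw[key]
        if "restrict_scaffolds" in raw and raw["restrict_scaffolds"]:
            kwargs["restrict_scaffolds"] = tuple(raw["restrict_scaffolds"])
        if "contrast" in raw and raw["contrast"]:
            kwargs["contrast"] = tuple(raw["contrast"])
        if "hit_filter" in raw:
            kwargs["hit_filter"] = HitFilterConfig(**raw["hit_filter"])
        if "policy" in raw:
            kwargs["policy"] = FixedDiffPolicy(**raw["policy"])
        if "probe_params" in raw:
            kwargs["probe_params"] = ProbeParams(**raw["probe_params"])
        missing = {k for k in ("genotypes", "metadata", "hits", "out_dir") if k not in kwargs}
        if missing:
            raise ConfigError(f"missing required config keys: {sorted(missing)}")
        return cls(**kwargs)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def run_pipeline(config: RunConfig) -> dict:
    """Execute the pipeline; returns (and writes) the run manifest.

    Validates all input paths before any stage runs (ConfigError), then
    aborts on the first stage failure naming the stage (StageError).
    """
    required = {"genotypes": config.genotypes, "metadata": config.metadata,
                "hits": config.hits}
    optional = {"tags": config.tags, "genome": config.genome,
                "repeats": config.repeats, "homology_hits": config.homology_hits}
    for name, path in {**required, **{k: v for k, v in optional.items() if v}}.items():
        if not Path(path).exists():
            raise ConfigError(f"{name} file not found: {path}")
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    manifest: dict[str, Any] = {
        "tool_version": __version__,
        "seed": config.seed,
        "timestamp": time.strftime("%Y-%m-%dT%H:%M:%S"),
        "inputs": {name: {"path": str(p), "sha256": _sha256(Path(p))}
                   for name, p in {**required, **optional}.items() if p},
        "config": {
            "dialect": config.dialect,
            "hit_filter": vars(config.hit_filter).copy(),
            "policy": vars(config.policy).copy(),
            "reference_population": config.reference_population,
            "restrict_scaffolds": list(config.restrict_scaffolds or []),
            "window": config.window,
            "probe_params": vars(config.probe_params).copy(),
            "note": "aligner-side culling limit has no post-hoc analogue",
        },
        "stages": {},
    }

    def stage(name: str, records_in: int, records_out: int, **extra) -> None:
        dropped = records_in - records_out
        manifest["stages"][name] = {"in": records_in, "out": records_out,
                                    "dropped": dropped, **extra}
        logger.info("stage %s: %d -> %d (%d dropped)", name, records_in, records_out, dropped)

    # ---- load ----
    try:
        matrix = read_genotypes(str(config.genotypes), config.dialect, str(config.metadata))
        if config.tags:
            matrix = attach_tags(matrix, read_tag_fasta(str(config.tags)))
        with open(config.hits) as fh:
            hits = parse_blast_tab(fh)
    except Exception as exc:
        raise StageError("load", str(exc)) from exc
    stage("load", len(hits), len(hits), n_loci=matrix.n_loci,
          n_individuals=matrix.n_individuals)

    # ---- map ----
    try:
        assignments = select_assignments(hits, matrix.loci, config.hit_filter)
        n_before_restrict = len(assignments)
        if config.restrict_scaffolds:
            assignments = restrict_to_scaffolds(assignments, config.restrict_scaffolds)
    except Exception as exc:
        raise StageError("map", str(exc)) from exc
    stage("map", len(hits), len(assignments), assigned_loci=n_before_restrict)
    write_assignments_bed(assignments, str(out / "assignments.bed"))

    # ---- fixedscan ----
    try:
        ref_ids = None
        if config.reference_population:
            ref_ids = [ind.id for ind in matrix.individuals
                       if ind.population == config.reference_population]
            if not ref_ids:
                raise ValueError(
                    f"no individuals in population {config.reference_population!r}"
                )
        verdicts, count_rows = scan_fixed_differences(
            matrix, assignments, config.policy, ref_ids
        )
    except Exception as exc:
        raise StageError("fixedscan", str(exc)) from exc
    fixed_ids = [v.locus_id for v in verdicts if v.status == FixedStatus.FIXED]
    stage("fixedscan", len(assignments), len(fixed_ids))
    write_verdicts_tsv(verdicts, str(out / "verdicts.tsv"))
    write_count_table_tsv(count_rows, str(out / "scaffold_counts.tsv"))

    # ---- heat map / clustering over fixed loci ----
    if len(fixed_ids) >= 1 and matrix.n_individuals >= 2:
        try:
            pw = pairwise_call_distance(matrix, fixed_ids)
            dendro = hierarchical_cluster(pw, "average")
            write_pairwise_tsv(pw, str(out / "fixed_distance_matrix.tsv"))
            (out / "dendrogram.nwk").write_text(dendro.to_newick() + "\n")
            render_heatmap(matrix, fixed_ids, dendro, str(out / "heatmap.png"))
        except Exception as exc:
            raise StageError("heatmap", str(exc)) from exc

    # ---- repeatstats (optional) ----
    if config.repeats and config.genome and config.contrast:
        try:
            with open(config.repeats) as fh:
                feats = parse_repeatmasker_out(fh)
            genome = read_tag_fasta(str(config.genome))
            results = {}
            for cls in sorted({f.repeat_class for f in feats} | {"total"}):
                profs = {}
                for scaf in config.contrast:
                    sub = [f for f in feats if f.scaffold == scaf]
                    profs[scaf] = window_densities(sub, len(genome[scaf]), config.window)
                res = contrast_scaffolds(profs[config.contrast[0]],
                                         profs[config.contrast[1]], cls)
                results[cls] = {"statistic": res.statistic, "p": res.p_two_sided,
                                "method": res.method}
            (out / "repeat_contrasts.json").write_text(json.dumps(results, indent=2))
            stage("repeatstats", len(feats), len(results))
        except Exception as exc:
            raise StageError("repeatstats", str(exc)) from exc

    # ---- tree ----
    by_scaffold: dict[str, int] = {}
    for v, a in zip(verdicts, assignments):
        if v.status == FixedStatus.FIXED:
            by_scaffold[a.scaffold] = by_scaffold.get(a.scaffold, 0) + 1
    tree_scaffold = config.tree_scaffold or (
        max(sorted(by_scaffold), key=lambda s: by_scaffold[s]) if by_scaffold else None
    )
    if tree_scaffold is not None:
        try:
            aln = concat_sequences(matrix, assignments, tree_scaffold)
            if len(aln.individuals) >= 3:
                tree = midpoint_root(nj(p_distance(aln)))
                (out / "tree.nwk").write_text(tree.to_newick() + "\n")
            (out / "alignment.fasta").write_text(export_alignment(aln, "fasta"))
            (out / "alignment.nex").write_text(export_alignment(aln, "nexus"))
            stage("tree", matrix.n_individuals, len(aln.locus_order),
                  scaffold=tree_scaffold)
        except Exception as exc:
            raise StageError("tree", str(exc)) from exc

    # ---- probes ----
    probe_scaffold = config.probe_scaffold or tree_scaffold
    if config.genome and probe_scaffold:
        try:
            genome = read_tag_fasta(str(config.genome))
            if probe_scaffold not in genome:
                raise ValueError(f"scaffold {probe_scaffold!r} not in genome FASTA")
            target = genome[probe_scaffold]
            mask = []
            if config.homology_hits:
                with open(config.homology_hits) as fh:
                    hom = parse_blast_tab(fh)
                mask = mask_from_hits(
                    [h for h in hom if h.evalue <= config.probe_params.homology_evalue
                     and h.query_id == probe_scaffold]
                )
            oligos = tile_candidates(target, mask, config.probe_params, probe_scaffold)
            oligos = uniqueness_screen(oligos, genome, config.probe_params.k_unique)
            kept = [o for o in oligos if o.unique]
            write_oligos_tsv(oligos, str(out / "probes.tsv"))
            write_oligos_fasta(kept, str(out / "probes.fasta"))
            stage("probes", len(oligos), len(kept), scaffold=probe_scaffold)
        except Exception as exc:
            raise StageError("probes", str(exc)) from exc

    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest


# ---------------------------------------------------------------------------
# Full published-data reproduction (accession scale)
# ---------------------------------------------------------------------------

def reproduce_full_study(data_dir: str | Path) -> dict:
    """Recompute the accession-scale summary numbers from deposited data.

    Expects ``data_dir`` to hold the deposited genotype matrix
    (genotypes.csv wide + metadata.csv), tag FASTA (tags.fasta), a BLAST
    tabular file of tags vs the reference assembly (hits.tsv), and a
    nucmer show-coords table of the two genome alignments (coords.tsv) —
    inputs produced by external downloads and aligner runs, hours of
    compute not bundled here.  Returns per-scaffold pre-/post-sorting
    counts, synteny summary statistics and the total locus count.
    """
    from .locus_mapping import filter_synteny_blocks, parse_coords_tab, summarize_synteny

    data_dir = Path(data_dir)
    for name in ("genotypes.csv", "metadata.csv", "tags.fasta", "hits.tsv", "coords.tsv"):
        if not (data_dir / name).exists():
            raise FileNotFoundError(
                f"full-study input {name} not found under {data_dir} "
                "(requires externally downloaded accession data)"
            )
    matrix = read_genotypes(str(data_dir / "genotypes.csv"), "wide",
                            str(data_dir / "metadata.csv"))
    matrix = attach_tags(matrix, read_tag_fasta(str(data_dir / "tags.fasta")))
    with open(data_dir / "hits.tsv") as fh:
        hits = parse_blast_tab(fh)
    assignments = select_assignments(hits, matrix.loci)
    with open(data_dir / "coords.tsv") as fh:
        blocks = filter_synteny_blocks(parse_coords_tab(fh))
    stats = summarize_synteny(blocks)
    ref_ids = [ind.id for ind in matrix.individuals if ind.population == "bh"]
    verdicts, rows = scan_fixed_differences(
        matrix, assignments, FixedDiffPolicy(), ref_ids or None
    )
    return {
        "total_loci": matrix.n_loci,
        "per_scaffold": {r.scaffold: {"mapped": r.n_loci_mapped, "fixed": r.n_fixed}
                         for r in rows},
        "n_query_scaffolds": stats.n_query_scaffolds,
        "identity_mean": stats.identity_mean,
        "identity_sd": stats.identity_sd,
    }
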