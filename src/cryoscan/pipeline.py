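"""End-to-end orchestration and report aggregation.

A single config drives every stage in dependency order — ORF calling,
domain annotation, family assembly, similarity clustering, parameter
profiling, group statistics, and per-column flexibility deviation — and
writes a report bundle shaped like the study's summary tables: per-family
candidate counts by dataset, per-strain candidate counts, comparison
records with pairwise counts, and per-column deviation tables, plus a
manifest recording seeds and parameters.

The default mode consumes precomputed external-tool outputs (or synthetic
fixtures); stages whose inputs are supplied are skipped.
"""

from __future__ import annotations

import json
import os
from dataclasses import asdict, dataclass, field
from importlib import resources

import numpy as np
import pandas as pd

from . import comparative_stats as cs
from . import domain_annotation as da
from . import flexibility_deviation as fd
from . import orf_caller as oc
from . import protein_parameters as pp
from . import similarity_clustering as sc
from . import synthetic_data as sd


@dataclass
class PipelineConfig:
    """All stage parameters plus the synthetic family specs to run on."""

    out_dir: str
    seed: int = 0
    families: list[dict] = field(default_factory=list)
    min_orf_nt: int = 150
    max_evalue: float = 1e-5
    cap: int = 5000
    min_fraction: float = 0.66
    d_max: float = 10.0
    mad_k: float = 6.0
    window: int = 9
    alpha: float = 0.05
    trend_alpha: float = 0.05
    min_group_n: int = 2
    intergenic_length: int = 120

    def validate(self) -> None:
        if not self.families:
            raise ValueError("config lists no families to process")
        for i, fam in enumerate(self.families):
            if "family" not in fam:
                raise ValueError(f"family entry {i} missing 'family' name")


def load_config(path) -> PipelineConfig:
    import yaml

    with open(path) as fh:
        raw = yaml.safe_load(fh)
    return PipelineConfig(**raw)


def aggregate_counts(candidates: pd.DataFrame) -> dict[str, pd.DataFrame]:
    """Per-strain, per-family candidate counts with group totals.

    Expects columns strain, group, pfam (one row per candidate).  Returns
    the pivot table plus per-group totals and the number of strains per
    group with at least one candidate.
    """
    if candidates.empty:
        return {
            "counts": pd.DataFrame(),
            "totals": pd.DataFrame(columns=["group", "total", "strains_with_candidates"]),
        }
    pivot = (
        candidates.groupby(["group", "strain", "pfam"]).size().unstack(fill_value=0)
    )
    per_strain = pivot.sum(axis=1)
    totals = (
        per_strain.groupby("group")
        .agg(total="sum", strains_with_candidates=lambda s: int((s > 0).sum()))
        .reset_index()
    )
    return {"counts": pivot, "totals": totals}


def load_published_counts() -> pd.DataFrame:
    """The shipped per-strain candidate count table (printed study values)."""
    with resources.files("cryoscan.data").joinpath("table2_counts.tsv").open() as fh:
        return pd.read_csv(fh, sep="\t")


# cluster columns of the published count table grouped by pfam family
PUBLISHED_FAMILY_COLUMNS = {
    "Bac_luciferase": ["LadA"],
    "Pyr_redox_3": ["AlmA"],
    "FA_desaturase": ["AlkB", "AlkB_like"],
    "p450": ["p450_bacterial", "p450_eukaryotic"],
}


def published_count_summary(table: pd.DataFrame | None = None) -> dict:
    """Totals and pairing-rule comparison counts from the published table."""
    if table is None:
        table = load_published_counts()
    cluster_cols = [c for cols in PUBLISHED_FAMILY_COLUMNS.values() for c in cols]
    per_strain = table[cluster_cols].sum(axis=1)
    out: dict = {}
    for group in ("psychrophile", "mesophile"):
        mask = table["group"] == group
        out[f"{group}_total"] = int(per_strain[mask].sum())
        out[f"{group}_genomes_with_candidates"] = int((per_strain[mask] > 0).sum())
    for family, cols in PUBLISHED_FAMILY_COLUMNS.items():
        fam_counts = table[cols].sum(axis=1)
        pair_counts: dict[str, tuple[int, int]] = {}
        for pair in sorted(table["pair"].unique()):
            psy = int(fam_counts[(table["pair"] == pair) & (table["group"] == "psychrophile")].sum())
            meso = int(fam_counts[(table["pair"] == pair) & (table["group"] == "mesophile")].sum())
            pair_counts[pair] = (psy, meso)
        out[f"{family}_pairwise_comparisons"] = cs.n_pairwise_comparisons(pair_counts)
    return out


def _family_stage(fam_cfg: dict, cfg: PipelineConfig, fam_seed: int, fam_dir: str) -> dict:
    """Run every stage for one synthetic family; returns report fragments."""
    spec = sd.FamilySpec(seed=fam_seed, **{k: v for k, v in fam_cfg.items() if k != "seed"})
    alignment, truth = sd.generate_family(spec)
    fixtures = sd.write_fixture_outputs(alignment, fam_dir, seed=fam_seed)

    # genome stage: plant a handful of group proteins, recover ORFs
    planted = {
        r.protein_id: r.sequence.replace("-", "")
        for r in alignment.rows[: 3]
    }
    genome, genome_truth = sd.generate_genome(
        planted, intergenic_length=cfg.intergenic_length, seed=fam_seed
    )
    orfs = oc.find_orfs(genome, min_orf_nt=cfg.min_orf_nt)
    called = {(o.start, o.end, o.strand) for o in orfs}
    recovered = sum(
        (s, e, strand) in called for _, s, e, strand in genome_truth.orf_coordinates
    )
    orf_recall = recovered / len(genome_truth.orf_coordinates)

    # domain annotation from the fixture domtblout
    hits = da.filter_hits(da.parse_domtblout(fixtures["domtblout"]), cfg.max_evalue)
    group_labels = {
        r.protein_id: (r.source_group, "A", r.protein_id) for r in alignment.rows
    }
    catalog = da.PfamCatalog(diagnostic={"p450"}, excluded={})
    candidates = da.extract_candidates(hits, catalog, group_labels)

    # clustering
    dm = sc.distance_matrix(alignment, d_max=cfg.d_max)
    emb = sc.nmds(dm, k=3, seed=fam_seed, groups={r.protein_id: r.source_group for r in alignment.rows})
    kept, culled = sc.cull_outliers(emb, mad_k=cfg.mad_k)
    xy = emb.coords_2d()
    box = (
        (float(xy[:, 0].min()) - 1.0, float(xy[:, 0].max()) + 1.0),
        (float(xy[:, 1].min()) - 1.0, float(xy[:, 1].max()) + 1.0),
    )
    selections = sc.select_clusters(emb, {f"{spec.family}_cluster0": box})

    # parameter profiles and deviation statistics
    profiles = {
        r.protein_id: pp.flexibility_profile(r.sequence.replace("-", ""), w=cfg.window, protein_id=r.protein_id)
        for r in alignment.rows
    }
    matrix = fd.project_profiles(profiles, alignment)
    sites = fd.column_stats(matrix, min_group_n=cfg.min_group_n)
    summary = fd.summarize(sites)

    # stratified group comparisons from the fixture ss2 files
    records: list[cs.ComparisonRecord] = []
    pools: dict[str, dict[str, list[float]]] = {
        "psychrophile": {r: [] for r in cs.REGIONS},
        "mesophile": {r: [] for r in cs.REGIONS},
    }
    for row in alignment.rows:
        if row.source_group not in pools:
            continue
        ss = cs.parse_ss2(fixtures["ss2"][row.protein_id])
        strata = cs.stratify(profiles[row.protein_id], ss)
        for region, vals in strata.items():
            pools[row.source_group][region].extend(vals)
    records = cs.classify(
        cs.compare_groups(spec.family, pools["psychrophile"], pools["mesophile"], "flexibility"),
        alpha=cfg.alpha,
        trend_alpha=cfg.trend_alpha,
    )

    return {
        "family": spec.family,
        "orf_recall": orf_recall,
        "n_orfs_called": len(orfs),
        "n_candidates": len(candidates),
        "nmds_stress": emb.stress,
        "n_culled": len(culled),
        "cluster_sizes": {s.cluster_id: len(s.member_ids) for s in selections},
        "n_deviation_sites": len(sites),
        "n_flagged": summary.n_flagged,
        "sum_delta_all": summary.sum_delta_all,
        "sum_delta_flagged": summary.sum_delta_flagged,
        "sites_frame": fd.sites_to_frame(sites),
        "comparison_records": records,
        "candidates_frame": da.candidates_to_frame(candidates),
    }


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute all stages for every configured family and write the bundle."""
    config.validate()
    os.makedirs(config.out_dir, exist_ok=True)
    root_rng = np.random.default_rng(config.seed)
    results = []
    for fam_cfg in config.families:
        fam_seed = int(root_rng.integers(2**31))
        fam_dir = os.path.join(config.out_dir, "fixtures", fam_cfg["family"])
        results.append(_family_stage(fam_cfg, config, fam_seed, fam_dir))

    # report: per-family summary
    summary_rows = []
    for res in results:
        summary_rows.append(
            {
                "family": res["family"],
                "orf_recall": res["orf_recall"],
                "n_candidates": res["n_candidates"],
                "nmds_stress": round(res["nmds_stress"], 6),
                "n_deviation_sites": res["n_deviation_sites"],
                "n_flagged": res["n_flagged"],
                "sum_delta_all": round(res["sum_delta_all"], 6),
                "sum_delta_flagged": round(res["sum_delta_flagged"], 6),
            }
        )
    summary = pd.DataFrame(summary_rows)
    summary.to_csv(os.path.join(config.out_dir, "family_summary.tsv"), sep="\t", index=False)

    all_candidates = pd.concat(
        [r["candidates_frame"] for r in results], ignore_index=True
    )
    counts = aggregate_counts(all_candidates)
    counts["totals"].to_csv(
        os.path.join(config.out_dir, "candidate_totals.tsv"), sep="\t", index=False
    )
    if not counts["counts"].empty:
        counts["counts"].to_csv(os.path.join(config.out_dir, "candidate_counts.tsv"), sep="\t")

    comp_rows = [
        {
            "family": rec.family,
            "region": rec.region,
            "parameter": rec.parameter,
            "u_statistic": rec.u_statistic,
            "raw_p": rec.raw_p,
            "adjusted_p": rec.adjusted_p,
            "significant": rec.significant,
            "trending": rec.trending,
            "direction": rec.direction,
        }
        for res in results
        for rec in res["comparison_records"]
    ]
    pd.DataFrame(comp_rows).to_csv(
        os.path.join(config.out_dir, "comparisons.tsv"), sep="\t", index=False
    )

    for res in results:
        res["sites_frame"].to_csv(
            os.path.join(config.out_dir, f"deviation_{res['family']}.tsv"),
            sep="\t",
            index=False,
        )

    manifest = {
        "seed": config.seed,
        "parameters": {
            k: v for k, v in asdict(config).items() if k not in ("families", "out_dir")
        },
        "families": [r["family"] for r in results],
    }
    with open(os.path.join(config.out_dir, "manifest.json"), "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)

    return {"summary": summary, "results": results, "manifest": manifest}
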