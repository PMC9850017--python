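"""End-to-end orchestration with a plain-text config and report bundle.

``run_all`` executes: input loading -> filtering cascade -> site-effect
classification -> per-gene diversity -> coalescent nulls -> selection
classification -> outlier scans -> structure analysis, and writes
table-style reports (cluster summary, gene x cluster x class grid with sign
markers, D-band fractions, outlier tables). Every stochastic stage logs its
seed; a rerun with the same config and seed reproduces outputs bit-exactly.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import diversity, neutral_null, outliers, selection_scan, structure, variant_io
from .datatypes import FilterReport, UndefinedStatistic

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    vcf: str = ""
    annotation: str = ""
    clusters: str = ""
    microsats: str = ""
    out_dir: str = "invadiv_out"
    seed: int = 0
    # filtering
    site_gq: float = 80.0
    site_dp: float = 10.0
    max_missing: float = 0.15
    mac_min: int = 3            # outlier profile; diversity profile uses 0
    het_max: float = 0.9
    min_len: int = 150
    min_snps: int = 3
    # diversity / nulls / classification
    l_class_method: str = "nei_gojobori"
    n_summary: str = "median"
    theta_source: str = "watterson"
    null_reps: int = 9999
    alpha: float = 0.05
    d_cut: float = 1.5
    q_low: float = 0.05
    q_high: float = 0.95
    # outliers
    flk_reps: int = 1_000_000
    flk_quantile: float = 0.995
    pca_K: int | None = None
    # structure
    k_max: int = 8
    n_pca_max: int = 80
    xval_reps: int = 100
    training_fraction: float = 0.8

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=True)


@dataclass
class RunResult:
    config: RunConfig
    filter_report: pd.DataFrame
    diversity_records: pd.DataFrame
    cluster_summary: pd.DataFrame
    signs: pd.DataFrame
    balancing: list
    directional: list
    flk: pd.DataFrame | None
    pca: object | None
    structure_k: int
    structure_assignments: pd.Series
    out_paths: dict = field(default_factory=dict)


def _validate_inputs(cfg: RunConfig) -> None:
    for name in ("vcf", "annotation", "clusters"):
        p = getattr(cfg, name)
        if not p or not Path(p).exists():
            raise FileNotFoundError(f"required input {name!r} missing: {p!r}")


def load_filtered(cfg: RunConfig, profile: str = "diversity"):
    """Filtering cascade for one profile: mask -> missingness -> (MAC) ->
    duplicates -> informativeness. The diversity profile skips the MAC
    filter; the outlier profile applies it."""
    report = FilterReport()
    gm = variant_io.read_vcf(cfg.vcf)
    frags = variant_io.read_fragments(cfg.annotation)
    cm = variant_io.read_cluster_map(cfg.clusters)
    cm.validate_against(gm)
    gm = variant_io.mask_and_filter_sites(
        gm, gq_min=cfg.site_gq, dp_min=cfg.site_dp, max_missing=cfg.max_missing,
        report=report,
    )
    if profile == "outlier":
        gm = variant_io.filter_mac(gm, mac_min=cfg.mac_min, report=report)
    gm, frags = variant_io.drop_duplicate_fragments(gm, frags, het_max=cfg.het_max,
                                                    report=report)
    gm, frags = variant_io.select_informative_fragments(
        gm, frags, min_len=cfg.min_len, min_snps=cfg.min_snps, report=report,
    )
    return gm, frags, cm, report


def run_all(cfg: RunConfig) -> RunResult:
    _validate_inputs(cfg)
    out_dir = Path(cfg.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    cfg.to_yaml(out_dir / "effective_config.yaml")

    gm, frags, cm, report = load_filtered(cfg, profile="diversity")
    eff = variant_io.classify_site_effects(frags, gm)
    effects = variant_io.effect_table(eff, gm)
    records = diversity.diversity_table(
        gm, frags, eff, cm, l_class_method=cfg.l_class_method,
        n_summary=cfg.n_summary,
    )
    summary = diversity.summarize_clusters(records)
    comparisons = _pairwise_cluster_tests(records, cm)
    cache = neutral_null.NullCache(reps=cfg.null_reps, seed=cfg.seed,
                                   theta_source=cfg.theta_source)
    signs = selection_scan.build_signs(records, cache, d_cut=cfg.d_cut,
                                       alpha=cfg.alpha)
    balancing = selection_scan.classify_balancing(signs)
    directional = selection_scan.classify_directional(signs)

    gm_out, _, _, _ = load_filtered(cfg, profile="outlier")
    flk = None
    if cfg.microsats and Path(cfg.microsats).exists():
        ms = outliers.read_microsat_table(cfg.microsats)
        flk = outliers.flk_scan(gm_out, ms, cm, reps=cfg.flk_reps,
                                seed=cfg.seed, quantile=cfg.flk_quantile)
    pca = outliers.pca_outlier_scan(gm_out, K=cfg.pca_K, alpha=cfg.alpha)
    bic, assignments = structure.find_clusters(gm_out, k_max=cfg.k_max,
                                               seed=cfg.seed)
    coords = structure.dapc_project(gm_out, cm, n_pcs=min(30, gm_out.n_samples - 2),
                                    seed=cfg.seed)

    bal_genes = {c.gene for c in balancing if c.verdict == "balancing"}
    sel_vs_rest = None
    if bal_genes and len(bal_genes) < records["gene"].nunique():
        try:
            sel_vs_rest = selection_scan.compare_selected_vs_rest(records, bal_genes)
        except UndefinedStatistic:
            pass

    paths = _write_reports(out_dir, report, records, summary, signs, balancing,
                           directional, flk, pca, bic, assignments, coords,
                           effects, comparisons, sel_vs_rest)
    return RunResult(
        config=cfg, filter_report=report.to_frame(),
        diversity_records=records, cluster_summary=summary, signs=signs,
        balancing=balancing, directional=directional, flk=flk, pca=pca,
        structure_k=int(bic.idxmin()), structure_assignments=assignments,
        out_paths=paths,
    )


def _pairwise_cluster_tests(records: pd.DataFrame, cm) -> pd.DataFrame:
    """Wilcoxon matched-pair comparisons of per-gene pi and D between every
    cluster pair, per site class."""
    rows = []
    clusters = cm.clusters
    for sc, sub in records.groupby("site_class"):
        for i, a in enumerate(clusters):
            for b in clusters[i + 1 :]:
                ra = sub[sub["cluster"] == a]
                rb = sub[sub["cluster"] == b]
                for value in ("pi", "d"):
                    try:
                        w, p = diversity.paired_cluster_test(ra, rb, value=value)
                    except UndefinedStatistic:
                        w, p = float("nan"), float("nan")
                    rows.append({"site_class": sc, "cluster_a": a, "cluster_b": b,
                                 "value": value, "W": w, "p": p})
    return pd.DataFrame(rows)


def _write_reports(out_dir, report, records, summary, signs, balancing,
                   directional, flk, pca, bic, assignments, coords,
                   effects, comparisons, sel_vs_rest) -> dict:
    from . import plots

    paths = {}

    def emit(name, frame):
        p = out_dir / name
        frame.to_csv(p, sep="\t", index=False, float_format="%.6g")
        paths[name] = p

    emit("filter_report.tsv", report.to_frame())
    emit("site_effects.tsv", effects)
    emit("diversity_records.tsv", records)
    emit("cluster_summary.tsv", summary)      # Table-1-style
    emit("cluster_comparisons.tsv", comparisons)
    if sel_vs_rest is not None:
        emit("selected_vs_rest.tsv", sel_vs_rest)
    emit("signs.tsv", signs)

    grid = signs.pivot_table(index="gene", columns=["site_class", "cluster"],
                             values="d").round(3)
    grid.columns = [f"D_{sc}_{cl}" for sc, cl in grid.columns]
    emit("gene_grid.tsv", grid.reset_index())  # Table-2-style

    verdicts = pd.DataFrame(
        [{"gene": c.gene, "verdict": c.verdict, "anchor": c.anchor_cluster,
          "supporting": ";".join(c.supporting_clusters),
          "classes": ";".join(c.carrying_classes)}
         for c in balancing + directional if c.verdict != "none"]
    )
    emit("verdicts.tsv", verdicts if not verdicts.empty
         else pd.DataFrame(columns=["gene", "verdict", "anchor", "supporting",
                                    "classes"]))
    flags = {
        "balancing": [c.gene for c in balancing if c.verdict == "balancing"],
        "directional": [c.gene for c in directional if c.verdict == "directional"],
    }
    p = out_dir / "flags.json"
    with open(p, "w") as fh:
        json.dump(flags, fh, indent=1, sort_keys=True)
    paths["flags.json"] = p

    bands = summary[["cluster", "site_class", "frac_d_gt1", "frac_d_lt_m1",
                     "frac_d_mid"]]
    emit("d_bands.tsv", bands)                 # Figure-3-style fractions

    if flk is not None:
        emit("flk_scan.tsv", flk)
        emit("flk_outliers.tsv", outliers.flk_outlier_summary(flk))
    emit("pca_scan.tsv", pca.table)
    emit("structure_bic.tsv", bic.rename_axis("k").reset_index())
    emit("structure_assignments.tsv",
         assignments.rename_axis("sample").reset_index())
    emit("dapc_coords.tsv", coords.rename_axis("sample").reset_index())

    plots.plot_d_density(records, out_dir / "d_density.png")
    plots.plot_d_bands(summary, out_dir / "d_bands.png")
    plots.plot_pca_scan(pca.table, out_dir / "pca_scan.png")
    plots.plot_dapc(coords, out_dir / "dapc_scatter.png")
    if flk is not None:
        plots.plot_flk(flk, out_dir / "flk_ht.png")
    for name in ("d_density.png", "d_bands.png", "pca_scan.png",
                 "dapc_scatter.png", "flk_ht.png"):
        p = out_dir / name
        if p.exists():
            paths[name] = p
    return paths
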