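"""End-to-end orchestration of the multiregional ITH analysis.

Stages: simulate (or load) -> normalize -> ITH scoring -> subtype
classification -> concordance -> expression clustering with bootstrap
support -> ssGSEA pathway heterogeneity -> protein panels.  Thresholds
default to the analysis' canonical values (high-ITH SD > 0.5, expression
filter log2(CPM) > 1, stroma/CNA panel scores > 0.5, AU >= 95, NPX
detection >= 75 %, enrichment-map similarity >= 0.375, top 5000 varying
gene sets).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field, replace
from pathlib import Path


import pandas as pd

from crcith import cluster as cl
from crcith import cohort as co
from crcith import concordance as conc
from crcith import ith as ith_mod
from crcith import normalize as norm
from crcith import protein as prot
from crcith import ssgsea as ss
from crcith.classify import KTSPSubtyper, NearestCentroidSubtyper, calls_to_frame

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    cohort: co.CohortConfig = field(default_factory=co.CohortConfig)
    training_tumors: int = 100
    training_biopsies: int = 2
    ith_threshold: float = 0.5
    stroma_threshold: float = 0.5
    cna_threshold: float = 0.5
    filter_threshold: float = 1.0
    au_threshold: float = 95.0
    detection_threshold: float = 0.75
    similarity_threshold: float = 0.375
    top_n_sets: int = 5000
    nboot: int = 100
    protein_clusters: int = 2
    n_gene_sets: int = 150
    outdir: str | None = None

    def validate(self) -> None:
        self.cohort.validate()
        if not (0 <= self.detection_threshold <= 1):
            raise ValueError("detection_threshold must be in [0, 1]")
        if not (0 <= self.au_threshold <= 100):
            raise ValueError("au_threshold must be in [0, 100]")
        if self.nboot and self.nboot < 50:
            raise ValueError("nboot must be 0 (off) or >= 50")


def _stage(name):
    """Abort with the stage name on failure."""

    def deco(fn):
        def wrapped(*a, **kw):
            try:
                return fn(*a, **kw)
            except Exception as e:
                raise RuntimeError(f"pipeline stage {name!r} failed: {e}") from e

        return wrapped

    return deco


def intrinsic_gene_mask(gene_meta: pd.DataFrame) -> pd.Series:
    """Cancer-cell-intrinsic genes: not stromal, not immune-program.

    The rank-pair (kTSP) classifier family is trained on this space,
    mirroring cancer-cell-intrinsic subtype systems that exclude
    microenvironment transcripts by design.
    """
    stroma = gene_meta.get("stroma_score", pd.Series(0.0, index=gene_meta.index))
    mask = stroma.fillna(0.0) <= 0.5
    if "role" in gene_meta.columns:
        mask &= gene_meta["role"] != "immune"
    return mask


def train_classifiers(config: PipelineConfig):
    """Train both classifier families on an independent labeled cohort.

    The training cohort shares the gene universe of the analysis cohort
    (same master seed) but uses an independent tumor substream block.  The
    centroid SSP trains on the full coding space; the kTSP family trains on
    the cancer-cell-intrinsic subset.
    """
    cfg = replace(
        config.cohort,
        n_tumors=config.training_tumors,
        biopsies_per_tumor=config.training_biopsies,
        replicate=config.cohort.replicate + 1,
        gene_seed=config.cohort.gene_seed
        if config.cohort.gene_seed is not None
        else config.cohort.seed,
        mixed_subtype_tumors=(),
        stromal_ith_proximal=None,
        subclonal_cna_distal=False,
    )
    train = co.simulate_cohort(cfg)
    factors = norm.tmm_factors(train.counts)
    expr = norm.log2_cpm(train.counts, factors)
    expr = norm.filter_expressed(
        expr, config.filter_threshold, train.gene_meta["coding"]
    )
    labels = pd.Series(train.truth.subtype)
    ssp = NearestCentroidSubtyper(classifier_id="SSP").fit(expr.T, labels[expr.columns])
    intrinsic = expr.index[intrinsic_gene_mask(train.gene_meta).reindex(expr.index)]
    expr_i = expr.loc[intrinsic]
    ktsp = KTSPSubtyper(classifier_id="kTSP").fit(expr_i.T, labels[expr_i.columns])
    return ssp, ktsp


def run_pipeline(config: PipelineConfig | None = None) -> dict:
    """Run every stage on a simulated cohort; return the summary bundle.

    The returned dict holds the machine-readable summary plus the stage
    tables; with ``config.outdir`` set, all tables, the summary JSON and a
    run manifest are written there.
    """
    config = config or PipelineConfig()
    config.validate()
    cohort = _stage("simulate")(co.simulate_cohort)(config.cohort)
    meta = cohort.sample_meta
    tumor_of = meta["tumor_id"]

    @_stage("normalize")
    def _normalize():
        factors = norm.tmm_factors(cohort.counts)
        expr = norm.log2_cpm(cohort.counts, factors)
        return factors, norm.filter_expressed(
            expr, config.filter_threshold, cohort.gene_meta["coding"]
        )

    factors, expr = _normalize()

    @_stage("ith")
    def _ith():
        table = ith_mod.gene_ith_scores(expr, tumor_of)
        ith_mod.quartile_bins(table)
        counts = ith_mod.high_ith_counts(table, config.ith_threshold)
        cna = ith_mod.compute_cna_score(cohort.copy_number, config.cna_threshold)
        panels = ith_mod.make_gene_panels(
            cohort.gene_meta.loc[expr.index],
            cna.reindex(expr.index),
            config.stroma_threshold,
            config.cna_threshold,
        )
        dists = {
            name: ith_mod.panel_quartile_distribution(table, genes)
            for name, genes in panels.items()
            if len(set(genes) & set(table.gene_ids))
        }
        return table, counts, cna, panels, dists

    ith_table, high_counts, cna_score, gene_panels, panel_dists = _ith()

    ssp, ktsp = _stage("classify_train")(train_classifiers)(config)

    @_stage("classify")
    def _classify():
        calls = ssp.predict_calls(expr.T, mode="predicted")
        calls += ssp.predict_calls(expr.T, mode="nearest")
        calls += ktsp.predict_calls(expr.T)
        return calls

    all_calls = _classify()
    predicted_calls = [
        c for c in all_calls if not (c.classifier_id == "SSP" and c.mode == "nearest")
    ]

    @_stage("concordance")
    def _concordance():
        records = conc.tumor_concordance(predicted_calls, tumor_of)
        by_loc = conc.discordance_by_location(records, meta.reset_index())
        intra_r = conc.intra_tumor_correlation(expr, tumor_of)
        rec_df = conc.records_to_frame(records)
        disc_tumors = rec_df.groupby("tumor_id")["discordant"].sum()
        per_biopsy = tumor_of.map(disc_tumors).astype(int)
        test = None
        if (per_biopsy == 0).any() and (per_biopsy >= 1).any():
            u, p = conc.correlation_vs_discordance_test(intra_r, per_biopsy)
            test = {"U": u, "p": p}
        return records, by_loc, intra_r, test

    records, by_location, intra_r, corr_test = _concordance()

    @_stage("cluster_rna")
    def _cluster_rna():
        z = norm.zscore_rows(expr)
        dist = cl.correlation_distance(z)
        tree = cl.ward_cluster(dist)
        if config.nboot:
            cl.multiscale_bootstrap(z, tree, nboot=config.nboot,
                                    seed=config.cohort.seed)
        pure = cl.tumor_pure_clades(tree, tumor_of)
        return tree, pure, dist

    rna_tree, pure_clades, rna_dist = _cluster_rna()

    @_stage("ssgsea")
    def _ssgsea():
        sets = co.simulate_gene_sets(
            cohort.gene_meta, config.n_gene_sets, seed=config.cohort.seed
        )
        scores = ss.ssgsea_scores(expr, sets)
        top = ss.top_varying_sets(scores, tumor_of, config.top_n_sets)
        deltas = ss.median_normalize_scores(scores, tumor_of)
        edges = ss.enrichment_map_edges(sets, config.similarity_threshold)
        return scores, top, deltas, edges

    ss_scores, ss_top, ss_deltas, ss_edges = _ssgsea()

    @_stage("protein")
    def _protein():
        npx = prot.NPXData(
            values=cohort.npx,
            detected=cohort.npx_detected,
            flagged=meta["flagged"],
        )
        npx = prot.qc_filter_npx(npx, config.detection_threshold)
        means = {
            name: prot.panel_mean(npx.values, members)
            for name, members in cohort.panels.items()
        }
        tam = means["TAM_inflammation"]
        tests = prot.subtype_panel_test(tam, predicted_calls, co.IMMUNE_SUBTYPES)
        z = norm.zscore_rows(npx.values.T)
        dist = cl.correlation_distance(z)
        tree = cl.ward_cluster(dist)
        assignment = cl.majority_cluster_assignment(
            tree, config.protein_clusters, tumor_of, dist
        )
        msi = meta.groupby("tumor_id")["msi_status"].first()
        enrich = prot.cluster_enrichment(assignment, msi)
        prot_pure = cl.tumor_pure_clades(tree, tumor_of)
        return npx, means, tests, tree, assignment, enrich, prot_pure

    npx, panel_means, panel_tests, prot_tree, prot_assign, enrich, prot_pure = _protein()

    summary = {
        "n_tumors": int(config.cohort.n_tumors),
        "n_biopsies": int(cohort.counts.shape[1]),
        "n_genes_total": int(cohort.counts.shape[0]),
        "n_genes_expressed": int(expr.shape[0]),
        "n_proteins_retained": int(npx.values.shape[1]),
        "high_ith_counts": {k: int(v) for k, v in high_counts.items()},
        "pure_clade_tumors_rna": int(pure_clades.sum()),
        "pure_clade_tumors_protein": int(prot_pure.sum()),
        "discordance_by_location": by_location.to_dict(orient="records"),
        "correlation_vs_discordance": corr_test,
        "protein_cluster_enrichment": {
            "odds_ratio": enrich["odds_ratio"],
            "p": enrich["p"],
            "composition": enrich["composition"],
        },
        "panel_tests": panel_tests.to_dict(orient="records"),
        "significant_rna_clades": (
            int(rna_tree.significant_nodes(config.au_threshold).sum())
            if rna_tree.au is not None
            else None
        ),
    }

    bundle = {
        "summary": summary,
        "cohort": cohort,
        "expr": expr,
        "factors": factors,
        "ith_table": ith_table,
        "high_ith_counts": high_counts,
        "cna_score": cna_score,
        "gene_panels": gene_panels,
        "panel_quartiles": panel_dists,
        "calls": all_calls,
        "concordance": records,
        "discordance_by_location": by_location,
        "intra_tumor_r": intra_r,
        "rna_tree": rna_tree,
        "pure_clades": pure_clades,
        "ssgsea_scores": ss_scores,
        "ssgsea_top_sets": ss_top,
        "ssgsea_deltas": ss_deltas,
        "enrichment_edges": ss_edges,
        "npx": npx,
        "panel_means": panel_means,
        "panel_tests": panel_tests,
        "protein_tree": prot_tree,
        "protein_assignment": prot_assign,
    }
    if config.outdir:
        write_outputs(bundle, config)
    return bundle


def _config_hash(config: PipelineConfig) -> str:
    blob = json.dumps(dataclasses.asdict(config), sort_keys=True, default=str)
    return hashlib.sha256(blob.encode()).hexdigest()[:16]


def write_outputs(bundle: dict, config: PipelineConfig) -> None:
    """Write stage TSVs, the JSON summary, and the run manifest."""
    import crcith

    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    co.write_cohort(bundle["cohort"], out / "cohort")
    bundle["expr"].to_csv(out / "expr_log2cpm.tsv", sep="\t")
    bundle["ith_table"].full().to_csv(out / "ith_scores.tsv", sep="\t")
    bundle["high_ith_counts"].to_csv(out / "high_ith_counts.tsv", sep="\t")
    calls_to_frame(bundle["calls"]).to_csv(out / "subtype_calls.tsv", sep="\t",
                                           index=False)
    conc.records_to_frame(bundle["concordance"]).to_csv(
        out / "concordance.tsv", sep="\t", index=False
    )
    bundle["discordance_by_location"].to_csv(
        out / "discordance_by_location.tsv", sep="\t", index=False
    )
    bundle["intra_tumor_r"].to_csv(out / "intra_tumor_correlation.tsv", sep="\t")
    (out / "rna_tree.nwk").write_text(bundle["rna_tree"].to_newick())
    tree = bundle["rna_tree"]
    if tree.au is not None:
        pd.DataFrame({"AU": tree.au, "BP": tree.bp}).to_csv(
            out / "rna_tree_support.tsv", sep="\t"
        )
    bundle["pure_clades"].to_csv(out / "pure_clades.tsv", sep="\t")
    bundle["ssgsea_scores"].to_csv(out / "ssgsea_scores.tsv", sep="\t")
    bundle["ssgsea_deltas"].to_csv(out / "ssgsea_median_deltas.tsv", sep="\t")
    bundle["enrichment_edges"].to_csv(out / "enrichment_edges.tsv", sep="\t",
                                      index=False)
    for name, s in bundle["panel_means"].items():
        s.to_csv(out / f"panel_mean_{name}.tsv", sep="\t")
    bundle["panel_tests"].to_csv(out / "panel_tests.tsv", sep="\t", index=False)
    bundle["protein_assignment"].to_csv(out / "protein_clusters.tsv", sep="\t")
    (out / "summary.json").write_text(json.dumps(bundle["summary"], indent=1))
    manifest = {
        "package_version": crcith.__version__,
        "config_hash": _config_hash(config),
        "seed": config.cohort.seed,
        "config": dataclasses.asdict(config),
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1, default=str))


def write_report(bundle: dict, path: str | Path) -> str:
    """Markdown report mirroring the summary tables."""
    s = bundle["summary"]
    lines = [
        "# Multiregional ITH analysis report",
        "",
        f"Cohort: {s['n_tumors']} tumors, {s['n_biopsies']} biopsies, "
        f"{s['n_genes_expressed']}/{s['n_genes_total']} genes past the "
        "expression filter.",
        "",
        "## Subtype concordance by location",
        "",
        "| stratum | classifier | discordant / n | fraction |",
        "|---|---|---|---|",
    ]
    for r in s["discordance_by_location"]:
        lines.append(
            f"| {r['stratum']} | {r['classifier_id']} | "
            f"{r['n_discordant']}/{r['n_tumors']} | "
            f"{r['discordant_fraction']:.2f} |"
        )
    lines += [
        "",
        "## High-ITH gene counts (SD > 0.5)",
        "",
        "| tumor | genes |",
        "|---|---|",
    ]
    for t, n in sorted(s["high_ith_counts"].items()):
        lines.append(f"| {t} | {n} |")
    lines += [
        "",
        "## Clustering",
        "",
        f"Tumor-pure RNA clades: {s['pure_clade_tumors_rna']}/{s['n_tumors']}; "
        f"protein level: {s['pure_clade_tumors_protein']}/{s['n_tumors']}.",
        "",
        "## Protein cluster enrichment",
        "",
        f"Fisher p = {s['protein_cluster_enrichment']['p']:.3g}, "
        f"odds ratio = {s['protein_cluster_enrichment']['odds_ratio']:.3g}.",
        "",
        "## Panel tests",
        "",
    ]
    if s["panel_tests"]:
        lines += ["| classifier | comparison | p | stars |", "|---|---|---|---|"]
        for r in s["panel_tests"]:
            lines.append(
                f"| {r['classifier_id']} | {r['group_a']} vs {r['group_b']} | "
                f"{r['p']:.3g} | {r['stars']} |"
            )
    else:
        lines.append("skipped")
    text = "\n".join(lines) + "\n"
    Path(path).write_text(text)
    return text


__all__ = ["PipelineConfig", "run_pipeline", "write_outputs", "write_report",
           "train_classifiers"]
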