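"""Synthetic multiregional biopsy cohorts.

Generates RNA counts, copy numbers, protein NPX values and metadata with the
statistical structure the downstream ITH analyses assume:

* tumor-level expression baselines whose spread (``inter_tumor_sd``) exceeds
  the within-tumor biopsy spread (``intra_tumor_sd``);
* a stromal expression program whose per-biopsy contribution is driven by a
  Beta-distributed stromal admixture fraction, so stromal genes acquire high
  within-tumor ITH-scores;
* contiguous copy-number segments with log2 dosage effects, concentrated in
  distal/MSS tumors and optionally subclonal (varying between biopsies);
* an immune program tied to MSI status, proximal location and an
  immune-related molecular subtype, which also drives correlated
  inflammation-protein panels on the NPX scale;
* four molecular subtypes (immune, metabolic, CNA/chromosomal, stromal) with
  disjoint signature-gene blocks anchored to the corresponding programs.

Counts are negative-binomial draws with a shared dispersion around
exp2(tumor baseline + biopsy deviation + program effects), scaled to
per-sample library sizes.  Each tumor consumes an independent random
substream derived from the master seed by a counter scheme, so adding tumors
never perturbs existing ones.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
import pandas as pd

SUBTYPES = ("IMM", "MET", "CIN", "STR")
#: subtypes treated as immune-related when grouping for protein tests
IMMUNE_SUBTYPES = ("IMM", "STR")

PROXIMAL_SEGMENTS = (1, 2, 3, 4)  # cecum .. transverse colon
DISTAL_SEGMENTS = (5, 6, 7, 8)  # splenic flexure .. rectum


def call_msi(marker_positives: int) -> str:
    """MSI call from a pentaplex PCR marker panel: MSI iff >3 of 5 positive."""
    if not (0 <= marker_positives <= 5):
        raise ValueError(f"marker count must be in [0, 5], got {marker_positives}")
    return "MSI" if marker_positives > 3 else "MSS"


@dataclass(frozen=True)
class CohortConfig:
    """Parameters of the simulated multiregional cohort.

    All SDs are in log2 expression units unless noted.  Defaults describe a
    cohort of 14 tumors with 3 spatially distinct biopsies each, matching the
    scale of a multiregional biopsy study.
    """

    n_tumors: int = 14
    biopsies_per_tumor: int = 3
    n_genes: int = 2000
    fraction_coding: float = 0.85
    location_labels: tuple[int, ...] = tuple(range(1, 9))
    msi_fraction_proximal: float = 0.5
    msi_fraction_distal: float = 0.05
    inter_tumor_sd: float = 2.0
    intra_tumor_sd: float = 0.3
    stromal_admixture_sd: float = 0.10
    cna_segment_count: int = 10
    cna_segment_size: int = 20
    cna_copy_states: tuple[int, ...] = (1, 3, 4)  # arm-level loss / gains
    cna_effect_log2: float = 1.0
    immune_effect_log2: float = 1.0
    immune_ith_sd: float = 0.1
    library_size_mean: int = 1_000_000
    dispersion: float = 0.05
    seed: int = 0
    # program sizes
    n_stromal_genes: int = 300
    n_housekeeping_genes: int = 400
    n_immune_genes: int = 200
    signature_genes_per_subtype: int = 50
    subtype_effect_log2: float = 2.0
    housekeeping_stability: float = 0.15
    stromal_fraction_mean: float = 0.3
    # scenario switches
    mixed_subtype_tumors: tuple[int, ...] = ()
    stromal_ith_proximal: float | None = None
    subclonal_cna_distal: bool = False
    subclonal_segment_fraction: float = 0.6
    # protein panel
    n_proteins: int = 96
    n_low_detection_proteins: int = 28
    npx_noise_sd: float = 0.5
    npx_immune_effect: float = 1.0
    # substream block: replicate r uses tumor streams [seed, r*100000 + t]
    replicate: int = 0
    # seed of the fixed gene/protein universe (baselines, program roles,
    # panel structure).  None -> follow `seed`.  Cohorts that must be
    # comparable (e.g. classifier training vs application) share it.
    gene_seed: int | None = None

    def validate(self) -> None:
        if self.n_tumors < 1:
            raise ValueError("n_tumors must be positive")
        if self.biopsies_per_tumor < 2:
            raise ValueError(
                "biopsies_per_tumor must be >= 2 (ITH-score undefined otherwise)"
            )
        for name in (
            "inter_tumor_sd",
            "intra_tumor_sd",
            "stromal_admixture_sd",
            "npx_noise_sd",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        for name in ("fraction_coding", "msi_fraction_proximal", "msi_fraction_distal"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must be in [0, 1]")
        if self.dispersion <= 0:
            raise ValueError("dispersion must be positive")
        if self.cna_segment_count < 0:
            raise ValueError("cna_segment_count must be >= 0")
        n_program = (
            self.n_stromal_genes
            + self.n_housekeeping_genes
            + self.n_immune_genes
            + len(SUBTYPES) * self.signature_genes_per_subtype
        )
        if self.n_genes < n_program + self.cna_segment_count * self.cna_segment_size:
            raise ValueError(
                f"n_genes={self.n_genes} smaller than planted program genes "
                f"({n_program} + CNA region "
                f"{self.cna_segment_count * self.cna_segment_size})"
            )


@dataclass
class PlantedTruth:
    """Ground truth of the generative model, for parameter-recovery tests."""

    subtype: dict[str, str]  # sample_id -> subtype label
    tumor_subtype: dict[str, str]  # tumor_id -> dominant label
    stromal_fraction: pd.Series  # per biopsy
    stromal_effect: pd.Series  # per gene, log2 shift per unit fraction
    immune_level: pd.Series  # per biopsy
    copy_number: pd.DataFrame  # gene x sample integer copies (diploid = 2)
    expected_log2_expr: pd.DataFrame  # gene x sample mean of the count model
    signature_genes: dict[str, list[str]]  # subtype -> gene ids
    program_genes: dict[str, list[str]]  # stromal / housekeeping / immune / cna


@dataclass
class SimulatedCohort:
    counts: pd.DataFrame  # genes x samples
    sample_meta: pd.DataFrame  # one row per sample
    gene_meta: pd.DataFrame  # one row per gene
    copy_number: pd.DataFrame  # genes x samples
    npx: pd.DataFrame  # samples x proteins (wide, Olink-style)
    npx_detected: pd.DataFrame  # samples x proteins boolean
    panels: dict[str, list[str]]  # protein panel definitions
    truth: PlantedTruth


def _gene_structure(cfg: CohortConfig, rng: np.random.Generator):
    """Assign disjoint program roles to gene index blocks and draw annotation."""
    g = cfg.n_genes
    ids = np.array([f"G{i:05d}" for i in range(g)])
    roles = np.full(g, "other", dtype=object)
    pos = 0

    def take(n):
        nonlocal pos
        sl = slice(pos, pos + n)
        pos += n
        return sl

    stromal = take(cfg.n_stromal_genes)
    housekeeping = take(cfg.n_housekeeping_genes)
    immune = take(cfg.n_immune_genes)
    roles[stromal] = "stromal"
    roles[housekeeping] = "housekeeping"
    roles[immune] = "immune"

    signature: dict[str, list[str]] = {}
    half = cfg.signature_genes_per_subtype // 2
    for st in SUBTYPES:
        if st == "STR":
            # half the stromal-subtype signature lies inside the stromal
            # program (admixture-sensitive), half is cancer-cell intrinsic
            sl = take(cfg.signature_genes_per_subtype - half)
            idx = np.concatenate(
                [np.arange(stromal.start, stromal.start + half),
                 np.arange(sl.start, sl.stop)]
            )
        else:
            # fully cancer-cell-intrinsic signature (the immune subtype is
            # additionally marked by the whole immune program through its
            # high infiltration level, not through its signature genes)
            sl = take(cfg.signature_genes_per_subtype)
            idx = np.arange(sl.start, sl.stop)
        signature[st] = list(ids[idx])

    cna_region = take(cfg.cna_segment_count * cfg.cna_segment_size)
    cna_gene_idx = np.arange(cna_region.start, cna_region.stop)
    # the "CIN" signature lies inside the CNA region: canonical/CIN-type
    # signatures sit on recurrently amplified segments, so subclonal dosage
    # changes move exactly the genes this subtype is recognized by
    if cfg.cna_segment_count * cfg.cna_segment_size >= cfg.signature_genes_per_subtype:
        signature["CIN"] = list(ids[cna_gene_idx[: cfg.signature_genes_per_subtype]])

    segments = [
        cna_gene_idx[i * cfg.cna_segment_size : (i + 1) * cfg.cna_segment_size]
        for i in range(cfg.cna_segment_count)
    ]

    base = rng.normal(4.0, 1.5, size=g)
    length = rng.integers(300, 20000, size=g)
    stroma_score = np.clip(rng.normal(0.05, 0.1, size=g), 0, None)
    stroma_score[stromal] = rng.uniform(0.6, 1.0, size=cfg.n_stromal_genes)
    coding = rng.random(g) < cfg.fraction_coding
    coding[stromal] = True
    coding[housekeeping] = True
    coding[immune] = True

    variability = np.ones(g)
    variability[housekeeping] = cfg.housekeeping_stability
    # program genes co-vary with their latent (admixture / immune level);
    # their gene-autonomous between-tumor drift is correspondingly smaller
    variability[stromal] = 0.5
    variability[immune] = 0.5
    # subtype signature genes are subtype-driven by definition: most of
    # their between-tumor variance is the class label, not autonomous drift
    for st in SUBTYPES:
        sig_pos = [int(gid[1:]) for gid in signature[st]]
        variability[sig_pos] = 0.35

    gene_meta = pd.DataFrame(
        {
            "gene_id": ids,
            "length_bp": length,
            "coding": coding,
            "stroma_score": stroma_score,
            "cna_score": 0.0,  # recomputed downstream from copy numbers
            "housekeeping": roles == "housekeeping",
            "role": roles,
        }
    ).set_index("gene_id")

    program_genes = {
        "stromal": list(ids[stromal]),
        "housekeeping": list(ids[housekeeping]),
        "immune": list(ids[immune]),
        "cna": list(ids[cna_gene_idx]),
    }
    stromal_effect = np.zeros(g)
    stromal_effect[stromal] = 3.0 * stroma_score[stromal]
    return (
        ids,
        base,
        variability,
        gene_meta,
        signature,
        segments,
        program_genes,
        pd.Series(stromal_effect, index=ids, name="stromal_effect"),
    )


def contrast_scenario_config(seed: int = 0, **overrides) -> CohortConfig:
    """Planted location-contrast scenario.

    Proximal tumors carry strong stromal-admixture ITH (microenvironment
    mechanism); distal MSS tumors carry subclonal copy-number ITH
    (cancer-cell mechanism).  Background admixture spread and immune
    within-tumor jitter are switched off so the two planted mechanisms are
    the only within-tumor call-moving forces.
    """
    base = dict(
        seed=seed,
        stromal_ith_proximal=0.4,
        stromal_admixture_sd=0.05,
        subclonal_cna_distal=True,
        subclonal_segment_fraction=1.0,
        # focal high-level events: the planted cancer-cell ITH mechanism
        cna_copy_states=(0, 1, 4, 8),
        immune_ith_sd=0.0,
    )
    base.update(overrides)
    return CohortConfig(**base)


def _beta_params(mean: float, sd: float) -> tuple[float, float]:
    """Beta(a, b) with the requested mean and (capped) SD."""
    sd = min(sd, 0.95 * np.sqrt(mean * (1 - mean)))
    if sd <= 0:
        return np.inf, np.inf  # degenerate: handled by caller
    nu = mean * (1 - mean) / sd**2 - 1
    return mean * nu, (1 - mean) * nu


def simulate_cohort(config: CohortConfig) -> SimulatedCohort:
    """Draw one cohort under the configured generative model.

    Deterministic: identical (config, seed) give bit-identical output.
    """
    cfg = config
    cfg.validate()
    gene_seed = cfg.seed if cfg.gene_seed is None else cfg.gene_seed
    rng_global = np.random.default_rng([gene_seed, 0])
    (
        ids,
        base,
        variability,
        gene_meta,
        signature,
        segments,
        program_genes,
        stromal_effect,
    ) = _gene_structure(cfg, rng_global)

    immune_idx = gene_meta["role"].to_numpy() == "immune"
    sig_idx = {st: gene_meta.index.get_indexer(genes) for st, genes in signature.items()}

    samples, metas = [], []
    mu_cols, count_cols, cn_cols = [], [], []
    truth_subtype: dict[str, str] = {}
    tumor_subtype: dict[str, str] = {}
    stromal_frac: dict[str, float] = {}
    immune_level: dict[str, float] = {}

    for t in range(cfg.n_tumors):
        rng = np.random.default_rng([cfg.seed, cfg.replicate * 100_000 + t + 1])
        tumor_id = f"T{t + 1:02d}"
        segment = int(rng.choice(cfg.location_labels))
        side = "proximal" if segment in PROXIMAL_SEGMENTS else "distal"
        p_msi = cfg.msi_fraction_proximal if side == "proximal" else cfg.msi_fraction_distal
        is_msi = rng.random() < p_msi
        marker_positives = int(rng.integers(4, 6) if is_msi else rng.integers(0, 4))
        msi_status = call_msi(marker_positives)

        # dominant subtype; MSI tumors are predominantly immune-subtype,
        # and a minority of MSS tumors are immune-subtype too
        u = rng.random()
        if (msi_status == "MSI" and u < 0.8) or (msi_status == "MSS" and u < 0.1):
            dom = "IMM"
        else:
            dom = str(rng.choice([s for s in SUBTYPES if s != "IMM"]))
        tumor_subtype[tumor_id] = dom

        tumor_dev = rng.normal(0.0, cfg.inter_tumor_sd, size=cfg.n_genes) * variability

        # per-tumor CNA profile; distal/MSS tumors carry the full burden.
        # The leading segments host the canonical CIN-signature amplicons:
        # near-diploid (light) tumors aberrate only non-signature segments.
        heavy = side == "distal" and msi_status == "MSS"
        n_sig_segments = -(-cfg.signature_genes_per_subtype // max(cfg.cna_segment_size, 1))
        seg_copies = np.full(cfg.cna_segment_count, 2)
        if heavy:
            pool = np.arange(cfg.cna_segment_count)
        else:
            pool = np.arange(min(n_sig_segments, cfg.cna_segment_count),
                             cfg.cna_segment_count)
        n_aberrant = min(
            len(pool),
            cfg.cna_segment_count if heavy else cfg.cna_segment_count // 3,
        )
        aberrant = rng.choice(pool, size=n_aberrant, replace=False) if n_aberrant else []
        for si in aberrant:
            seg_copies[si] = int(rng.choice(cfg.cna_copy_states))
        # coherent spatial subclones: a subset of the aberrant segments is
        # carried only by biopsies belonging to the derived subclone
        subclonal = cfg.subclonal_cna_distal and heavy
        subclonal_segments = (
            {
                int(si)
                for si in aberrant
                if rng.random() < cfg.subclonal_segment_fraction
            }
            if subclonal
            else set()
        )
        if subclonal:
            membership = rng.random(cfg.biopsies_per_tumor) < 0.5
            if membership.all() or not membership.any():
                membership[-1] = not membership[-1]  # both subclones sampled
        else:
            membership = np.ones(cfg.biopsies_per_tumor, dtype=bool)

        adm_sd = cfg.stromal_admixture_sd
        if cfg.stromal_ith_proximal is not None and side == "proximal":
            adm_sd = cfg.stromal_ith_proximal
        a, b = _beta_params(cfg.stromal_fraction_mean, adm_sd)

        immune_base = (
            (1.0 if msi_status == "MSI" else 0.0)
            + (0.5 if side == "proximal" else 0.0)
            + (1.5 if dom == "IMM" else 0.0)
        )

        for i in range(cfg.biopsies_per_tumor):
            sid = f"{tumor_id}B{i + 1}"
            label = dom
            if t in cfg.mixed_subtype_tumors and i == cfg.biopsies_per_tumor - 1:
                label = str(
                    rng.choice([s for s in SUBTYPES if s != dom])
                )
            truth_subtype[sid] = label

            frac = (
                cfg.stromal_fraction_mean
                if not np.isfinite(a)
                else float(rng.beta(a, b))
            )
            if label == "STR":  # stromal subtype: stroma-rich biopsy
                frac = frac + 0.3
            frac = min(frac, 0.9)  # a biopsy always retains tumor content
            stromal_frac[sid] = frac

            lvl = immune_base + rng.normal(0.0, cfg.immune_ith_sd)
            if label == "IMM" and dom != "IMM":
                lvl += 1.5
            immune_level[sid] = lvl

            in_subclone = bool(membership[i])
            copies = np.full(cfg.n_genes, 2)
            for si, seg in enumerate(segments):
                c = seg_copies[si]
                if si in subclonal_segments and not in_subclone:
                    c = 2  # ancestral biopsy: did not acquire the event
                copies[seg] = c

            mu = (
                base
                + tumor_dev
                + rng.normal(0.0, cfg.intra_tumor_sd, size=cfg.n_genes) * variability
                + stromal_effect.to_numpy() * frac
                # physical dosage response: log2 of the copy ratio, with a
                # floor so homozygous loss stays finite
                + cfg.cna_effect_log2 * np.log2(np.maximum(copies, 0.25) / 2.0)
                + cfg.immune_effect_log2 * lvl * immune_idx
            )
            mu = mu + 0.0
            mu[sig_idx[label]] += cfg.subtype_effect_log2

            lib = float(
                cfg.library_size_mean * np.exp(rng.normal(0.0, 0.1))
            )
            w = np.exp2(mu)
            mean_counts = w / w.sum() * lib
            if cfg.dispersion < 1e-8:
                counts = rng.poisson(mean_counts)
            else:
                r = 1.0 / cfg.dispersion
                counts = rng.negative_binomial(r, r / (r + mean_counts))

            samples.append(sid)
            metas.append(
                {
                    "sample_id": sid,
                    "tumor_id": tumor_id,
                    "location_segment": segment,
                    "side": side,
                    "msi_status": msi_status,
                    "flagged": False,
                }
            )
            mu_cols.append(mu)
            count_cols.append(counts)
            cn_cols.append(copies)

    counts = pd.DataFrame(
        np.column_stack(count_cols), index=ids, columns=samples
    )
    copy_number = pd.DataFrame(
        np.column_stack(cn_cols), index=ids, columns=samples
    )
    expected = pd.DataFrame(np.column_stack(mu_cols), index=ids, columns=samples)
    sample_meta = pd.DataFrame(metas).set_index("sample_id")

    npx, detected, panels = _simulate_npx(
        cfg,
        samples,
        pd.Series(immune_level),
        universe_rng=rng_global,
        cohort_rng=np.random.default_rng([cfg.seed, cfg.replicate * 100_000 + 99_999]),
    )

    truth = PlantedTruth(
        subtype=truth_subtype,
        tumor_subtype=tumor_subtype,
        stromal_fraction=pd.Series(stromal_frac, name="stromal_fraction"),
        stromal_effect=stromal_effect,
        immune_level=pd.Series(immune_level, name="immune_level"),
        copy_number=copy_number,
        expected_log2_expr=expected,
        signature_genes=signature,
        program_genes=program_genes,
    )
    return SimulatedCohort(
        counts=counts,
        sample_meta=sample_meta,
        gene_meta=gene_meta,
        copy_number=copy_number,
        npx=npx,
        npx_detected=detected,
        panels=panels,
        truth=truth,
    )


def _simulate_npx(cfg, samples, immune_level, universe_rng, cohort_rng):
    """Olink-style NPX panel: proteins Gaussian around shared latent levels.

    Protein baselines, panel loadings and the low-detection set belong to
    the fixed universe; measurement noise and detection draws are
    cohort-specific.
    """
    prot = np.array([f"P{i:03d}" for i in range(cfg.n_proteins)])
    n_tam, n_tcyt = 12, 8
    panels = {
        "TAM_inflammation": list(prot[:n_tam]),
        "Tcyt_response": list(prot[n_tam : n_tam + n_tcyt]),
    }
    baseline = universe_rng.normal(5.0, 1.0, size=cfg.n_proteins)
    loading = np.zeros(cfg.n_proteins)
    loading[: n_tam + n_tcyt] = cfg.npx_immune_effect * universe_rng.uniform(
        0.7, 1.3, size=n_tam + n_tcyt
    )
    lvl = immune_level.reindex(samples).to_numpy()
    vals = (
        baseline[None, :]
        + loading[None, :] * lvl[:, None]
        + cohort_rng.normal(0.0, cfg.npx_noise_sd, size=(len(samples), cfg.n_proteins))
    )
    npx = pd.DataFrame(vals, index=samples, columns=prot)
    # planted low-detection proteins (never panel members) fail the 75% QC rule
    detect_p = np.full(cfg.n_proteins, 0.995)
    lowdet = prot[n_tam + n_tcyt : n_tam + n_tcyt + cfg.n_low_detection_proteins]
    detect_p[n_tam + n_tcyt : n_tam + n_tcyt + cfg.n_low_detection_proteins] = 0.4
    detected = pd.DataFrame(
        cohort_rng.random((len(samples), cfg.n_proteins)) < detect_p[None, :],
        index=samples,
        columns=prot,
    )
    npx.attrs["low_detection_proteins"] = list(lowdet)
    return npx, detected, panels


def simulate_subtype_samples(
    n_samples: int,
    n_genes: int = 500,
    n_classes: int = 4,
    shift: float = 2.0,
    noise_sd: float = 0.3,
    seed: int = 0,
    genes_per_class: int = 50,
    gene_seed: int = 0,
) -> tuple[pd.DataFrame, pd.Series]:
    """Simple labeled expression set for classifier training/evaluation.

    Each class up-shifts its own disjoint signature block by ``shift`` log2
    units on top of shared gene baselines plus N(0, noise_sd) noise.  The
    baselines form a fixed universe (``gene_seed``) so draws with different
    ``seed`` values are comparable.  Returns (expr genes x samples in log2
    units, labels per sample).
    """
    if n_genes < n_classes * genes_per_class:
        raise ValueError("n_genes too small for the signature blocks")
    base = np.random.default_rng([gene_seed, 9999]).normal(4.0, 1.5, size=n_genes)
    rng = np.random.default_rng([seed, 10_000])
    labels = np.array([f"C{i % n_classes + 1}" for i in range(n_samples)])
    x = base[:, None] + rng.normal(0.0, noise_sd, size=(n_genes, n_samples))
    for c in range(n_classes):
        block = slice(c * genes_per_class, (c + 1) * genes_per_class)
        x[block, labels == f"C{c + 1}"] += shift
    ids = [f"G{i:05d}" for i in range(n_genes)]
    cols = [f"S{i:04d}" for i in range(n_samples)]
    return (
        pd.DataFrame(x, index=ids, columns=cols),
        pd.Series(labels, index=cols, name="label"),
    )


def simulate_gene_sets(
    gene_meta: pd.DataFrame,
    n_random_sets: int = 150,
    set_size: tuple[int, int] = (10, 60),
    seed: int = 0,
) -> dict[str, list[str]]:
    """Gene-set collection over simulated genes: program sets + random sets."""
    rng = np.random.default_rng([seed, 777])
    sets: dict[str, list[str]] = {}
    for role in ("stromal", "housekeeping", "immune"):
        members = list(gene_meta.index[gene_meta["role"] == role])
        if members:
            sets[f"PROGRAM_{role.upper()}"] = members[:80]
    genes = np.array(gene_meta.index)
    for i in range(n_random_sets):
        size = int(rng.integers(set_size[0], set_size[1] + 1))
        sets[f"RANDOM_SET_{i:04d}"] = list(rng.choice(genes, size=size, replace=False))
    return sets


def write_cohort(cohort: SimulatedCohort, outdir: str | Path) -> None:
    """Write the fixture bundle as plain-text files."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    cohort.counts.to_csv(out / "counts.tsv", sep="\t")
    cohort.sample_meta.to_csv(out / "sample_meta.tsv", sep="\t")
    cohort.gene_meta.to_csv(out / "gene_meta.tsv", sep="\t")
    cohort.copy_number.to_csv(out / "copy_number.tsv", sep="\t")
    cohort.npx.to_csv(out / "npx.csv")
    cohort.npx_detected.to_csv(out / "npx_detected.csv")
    truth = {
        "subtype": cohort.truth.subtype,
        "tumor_subtype": cohort.truth.tumor_subtype,
        "stromal_fraction": cohort.truth.stromal_fraction.to_dict(),
        "immune_level": cohort.truth.immune_level.to_dict(),
        "signature_genes": cohort.truth.signature_genes,
        "program_genes": cohort.truth.program_genes,
    }
    (out / "truth.json").write_text(json.dumps(truth, indent=1))
    pd.Series(
        {k: ";".join(v) for k, v in cohort.panels.items()}, name="members"
    ).to_csv(out / "panels.tsv", sep="\t")


__all__ = [
    "CohortConfig",
    "PlantedTruth",
    "SimulatedCohort",
    "SUBTYPES",
    "IMMUNE_SUBTYPES",
    "call_msi",
    "simulate_cohort",
    "simulate_subtype_samples",
    "simulate_gene_sets",
    "write_cohort",
    "replace",
]
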