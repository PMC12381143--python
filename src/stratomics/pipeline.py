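"""End-to-end orchestration: simulate (or load) -> normalize -> differential
enrichment -> contaminant filtering and synaptic DE -> PLS-DA -> integration
-> overrepresentation analysis, with all products written as a TSV bundle
plus a JSON summary and manifest.

Every stage is a pure function of (inputs, config, seed); reruns with the
same configuration and seed produce byte-identical bundles.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import io
from .containers import ConfigError, GeneSetCollection, OmicsMatrix, ReferenceTables
from .differential import (
    call_enrichment,
    moderated_lm_de,
    moderated_lm_fraction_de,
    nb_wald_de,
    nb_wald_fraction_de,
)
from .integrate import (
    co_enrichment_map,
    compartment_means,
    halflife_group_test,
    population_correlation,
    profile_correlation_classify,
    zscore_fold_changes,
)
from .normalize import ibaq_transform, log2_normalized_counts, peptide_count_table, rlr_normalize
from .ora import ora_hypergeometric
from .plsda import cross_validate_plsda, fit_plsda, vip_scores
from .simulate import (
    SimConfig,
    simulate_reference_tables,
    simulate_sorting_experiment,
    simulate_spatial_omics,
)
from .synapto import apply_contaminant_filter, build_contaminant_list

log = logging.getLogger("stratomics")

#: stand-ins for methods of the source toolchain, reported in every summary
DIVERGENCES = [
    "effect-size shrinkage with sign-error s-values replaced by unshrunk "
    "Wald log2 fold changes with BH q-values at the same thresholds",
    "peptide-level robust/empirical-error protein DE replaced by a "
    "protein-level empirical-Bayes moderated linear model",
    "GO-term redundancy simplification omitted; full ORA tables reported",
]


@dataclass
class RunConfig:
    """Full-pipeline configuration.

    Thresholds default to the tissue/synaptosome conventions: enrichment at
    q < 0.01 for tissue and q < 0.05 for synaptosomes, |log2FC| >= 0.1,
    profile-correlation classes at r >= 0.9 / r <= -0.9, ORA FDR 0.05, and
    3-fold PLS-DA cross-validation with 15 repetitions.
    """

    sim: SimConfig = field(default_factory=SimConfig)
    scheme_tissue: str = "one_vs_rest"
    scheme_synapto: str = "one_vs_rest"
    alpha_tissue: float = 0.01
    alpha_synapto: float = 0.05
    lfc_min: float = 0.1
    r_pos: float = 0.9
    r_neg: float = -0.9
    fdr_cutoff: float = 0.05
    plsda_k: int = 3
    plsda_repeats: int = 15
    plsda_a_max: int = 6
    seed: int = 0

    def validate(self) -> None:
        self.sim.validate()
        for name, v, lo, hi in [("alpha_tissue", self.alpha_tissue, 0, 1),
                                ("alpha_synapto", self.alpha_synapto, 0, 1),
                                ("fdr_cutoff", self.fdr_cutoff, 0, 1),
                                ("r_pos", self.r_pos, -1, 1),
                                ("r_neg", self.r_neg, -1, 1)]:
            if not (lo <= v <= hi):
                raise ConfigError(f"{name}={v} outside [{lo}, {hi}]")
        if self.r_neg >= self.r_pos:
            raise ConfigError("r_neg must lie below r_pos")
        if self.plsda_k < 2 or self.plsda_repeats < 1 or self.plsda_a_max < 1:
            raise ConfigError("invalid PLS-DA settings")

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        sim_d = d.pop("sim", {})
        known_sim = {f.name for f in dataclasses.fields(SimConfig)}
        bad = set(sim_d) - known_sim
        if bad:
            raise ConfigError(f"unknown sim config fields: {sorted(bad)}")
        known = {f.name for f in dataclasses.fields(cls)} - {"sim"}
        bad = set(d) - known
        if bad:
            raise ConfigError(f"unknown config fields: {sorted(bad)}")
        if "compartments" in sim_d:
            sim_d["compartments"] = tuple(sim_d["compartments"])
        cfg = cls(sim=SimConfig(**sim_d), **d)
        cfg.validate()
        return cfg

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["sim"]["compartments"] = list(d["sim"]["compartments"])
        return d


def run_pipeline(config: RunConfig, outdir: str | Path | None = None) -> dict:
    """Execute the full analysis on a simulated bundle; return all products.

    Stages: simulate tissue + sorting bundles and reference tables ->
    normalize (size factors, rlr, iBAQ) -> tissue DE and enrichment calls
    (RNA and protein) -> contaminant list from P3-vs-P2, filter, synaptic DE
    -> PLS-DA with VIP on complete-case synaptic proteins -> integration
    (population and profile correlations, half-life rank test, co-enrichment
    with translatome proportions, z-scored fold changes) -> ORA of
    correlation classes. Writes the TSV bundle and summary when ``outdir``
    is given.
    """
    config.validate()
    seed = config.seed
    results: dict = {}
    log.info("stage: simulate")
    rna, protein, truth = simulate_spatial_omics(config.sim, seed=seed)
    prot_sort, rna_sort, truth_sort = simulate_sorting_experiment(
        config.sim, seed=seed + 1)
    reference, gene_sets = simulate_reference_tables(config.sim, truth,
                                                     seed=seed + 2)
    results.update(truth=truth, truth_sort=truth_sort, reference=reference,
                   gene_sets=gene_sets, rna=rna, protein=protein,
                   rna_sort=rna_sort, prot_sort=prot_sort)

    log.info("stage: normalize")
    size_factors, rna_log2 = log2_normalized_counts(rna)
    prot_norm = rlr_normalize(protein)
    pep_counts = peptide_count_table(reference.sequences)
    prot_ibaq = ibaq_transform(prot_norm, pep_counts)
    results.update(size_factors=size_factors, rna_log2=rna_log2,
                   prot_norm=prot_norm, prot_ibaq=prot_ibaq)

    log.info("stage: tissue differential enrichment")
    de_rna = nb_wald_de(rna, scheme=config.scheme_tissue,
                        size_factors=size_factors)
    de_prot = moderated_lm_de(prot_norm, scheme=config.scheme_tissue)
    call_scheme = ("pairwise_intersection" if config.scheme_tissue == "pairwise"
                   else "one_vs_rest")
    calls_rna = call_enrichment(de_rna, call_scheme, "mrna",
                                lfc_min=config.lfc_min, alpha=config.alpha_tissue)
    calls_prot = call_enrichment(de_prot, call_scheme, "protein",
                                 lfc_min=config.lfc_min,
                                 alpha=config.alpha_tissue)
    results.update(de_rna=de_rna, de_prot=de_prot, calls_rna=calls_rna,
                   calls_prot=calls_prot)

    log.info("stage: contaminant filtering and synaptic DE")
    de_p3p2_prot = moderated_lm_fraction_de(prot_sort)
    de_p3p2_rna = nb_wald_fraction_de(rna_sort)
    contam_prot = build_contaminant_list(de_p3p2_prot, "protein",
                                         alpha=config.alpha_synapto,
                                         lfc_min=config.lfc_min)
    contam_rna = build_contaminant_list(de_p3p2_rna, "rna",
                                        alpha=config.alpha_synapto,
                                        lfc_min=config.lfc_min)
    prot_syn = apply_contaminant_filter(
        prot_sort.subset_samples(prot_sort.samples_where(fraction="P3")),
        contam_prot)
    rna_syn = apply_contaminant_filter(
        rna_sort.subset_samples(rna_sort.samples_where(fraction="P3")),
        contam_rna)
    de_syn_prot = moderated_lm_de(prot_syn, scheme=config.scheme_synapto)
    calls_syn_prot = call_enrichment(
        de_syn_prot,
        "pairwise_intersection" if config.scheme_synapto == "pairwise"
        else "one_vs_rest",
        "protein", lfc_min=config.lfc_min, alpha=config.alpha_synapto)
    results.update(de_p3p2_prot=de_p3p2_prot, de_p3p2_rna=de_p3p2_rna,
                   contam_prot=contam_prot, contam_rna=contam_rna,
                   prot_syn=prot_syn, rna_syn=rna_syn,
                   de_syn_prot=de_syn_prot, calls_syn_prot=calls_syn_prot)

    log.info("stage: PLS-DA")
    complete = prot_syn.values.dropna(axis=0)
    X = complete.to_numpy().T
    labels = prot_syn.meta["compartment"].to_numpy()
    a_max = min(config.plsda_a_max, X.shape[0] - int(np.ceil(X.shape[0] / config.plsda_k)) - 1)
    cv = cross_validate_plsda(X, labels, k=config.plsda_k,
                              repeats=config.plsda_repeats,
                              A_grid=list(range(1, a_max + 1)), seed=seed + 3)
    model = fit_plsda(X, labels, cv.chosen_A)
    vip = vip_scores(model)
    vip["feature"] = complete.index[model.kept]
    results.update(plsda_cv=cv, plsda_model=model, vip=vip,
                   plsda_features=list(complete.index))

    log.info("stage: integration")
    ibaq_vals = prot_ibaq.values
    pop_corr = population_correlation(rna_log2, ibaq_vals, rna.meta)
    comps = rna.compartments
    rna_means = compartment_means(rna_log2, rna.meta, comps)
    prot_means = compartment_means(ibaq_vals, prot_ibaq.meta, comps)
    corr_records = profile_correlation_classify(rna_means, prot_means,
                                                r_pos=config.r_pos,
                                                r_neg=config.r_neg)
    halflife_test = halflife_group_test(corr_records, reference)
    co_table = co_enrichment_map(calls_rna, calls_prot, reference.translatome)
    lfc_wide = de_rna.pivot(index="feature", columns="contrast", values="log2fc")
    zscores, z_long = zscore_fold_changes(lfc_wide, gene_sets)
    results.update(pop_corr=pop_corr, corr_records=corr_records,
                   halflife_test=halflife_test, co_enrichment=co_table,
                   zscores=zscores, zscore_sets=z_long)

    log.info("stage: overrepresentation analysis")
    background = list(rna.feature_ids)
    ora_tables = {}
    for cls in ("positive", "negative"):
        query = corr_records.loc[corr_records["class"] == cls, "gene"]
        if len(query):
            ora_tables[cls] = ora_hypergeometric(query, background, gene_sets,
                                                 fdr_cutoff=config.fdr_cutoff)
    results["ora"] = ora_tables

    summary = summarize(results, config)
    results["summary"] = summary
    if outdir is not None:
        write_bundle(results, config, Path(outdir))
    return results


def summarize(results: dict, config: RunConfig) -> dict:
    """Compact JSON summary: counts per class, test statistics, model sizes."""
    calls_rna = results["calls_rna"]
    calls_prot = results["calls_prot"]
    corr = results["corr_records"]
    ht = results["halflife_test"]
    cv = results["plsda_cv"]
    summary = {
        "n_genes": len(results["rna"].feature_ids),
        "enriched_mrna_per_compartment": calls_rna[
            calls_rna["direction"] == "enriched"].groupby(
            "compartment").size().to_dict(),
        "enriched_protein_per_compartment": calls_prot[
            calls_prot["direction"] == "enriched"].groupby(
            "compartment").size().to_dict(),
        "contaminants_removed": {"protein": len(results["contam_prot"]),
                                 "rna": len(results["contam_rna"])},
        "correlation_classes": corr["class"].value_counts().to_dict(),
        "population_correlation": results["pop_corr"].set_index(
            "scope")["r"].to_dict(),
        "halflife_test": {"H": ht.H, "df": ht.df, "pvalue": ht.pvalue,
                          "n_joined": ht.n_joined},
        "plsda": {"chosen_A": cv.chosen_A, "best_A": cv.best_A,
                  "cv_accuracy_best": float(cv.mean_accuracy.max()),
                  "n_complete_features": len(results["plsda_features"])},
        "divergences_from_source_study": DIVERGENCES,
    }
    return summary


def write_bundle(results: dict, config: RunConfig, outdir: Path) -> None:
    tables: dict[str, pd.DataFrame] = {}
    for key in ("de_rna", "de_prot", "de_p3p2_prot", "de_p3p2_rna",
                "de_syn_prot", "calls_rna", "calls_prot", "calls_syn_prot",
                "corr_records", "pop_corr"):
        tables[key] = results[key]
    tables["contaminants_protein"] = results["contam_prot"].provenance
    tables["contaminants_rna"] = results["contam_rna"].provenance
    tables["halflife_test"] = results["halflife_test"].to_frame()
    tables["co_enrichment"] = results["co_enrichment"].cells
    tables["zscores"] = results["zscores"].reset_index(names="feature")
    if results["zscore_sets"] is not None:
        tables["zscore_sets"] = results["zscore_sets"]
    tables["vip"] = results["vip"]
    tables["plsda_cv"] = results["plsda_cv"].accuracy
    for cls, tab in results["ora"].items():
        tables[f"ora_{cls}"] = tab
    for name, frame in results["truth"].to_frames().items():
        tables[name] = frame
    for name, frame in results["truth_sort"].to_frames().items():
        tables[f"sorting_{name}"] = frame
    io.write_results_bundle(tables, outdir, config=config.to_dict(),
                            seed=config.seed, summary=results["summary"])
    io.write_abundance_table(results["rna"], outdir / "rna_counts.tsv",
                             outdir / "rna_meta.tsv")
    io.write_abundance_table(results["protein"], outdir / "protein_log2.tsv")


# ---------------------------------------------------------------------------
# evaluation against planted truth
# ---------------------------------------------------------------------------

def evaluate_against_truth(results: dict) -> dict:
    """Recovery metrics of each stage against the planted ground truth."""
    truth = results["truth"].genes
    out: dict = {}

    planted = set(zip(truth.index[truth["mrna_compartment"] != ""],
                      truth.loc[truth["mrna_compartment"] != "",
                                "mrna_compartment"]))
    up = results["calls_rna"]
    up = up[up["direction"] == "enriched"]
    called = set(zip(up["feature"], up["compartment"]))
    tp = len(called & planted)
    out["mrna_enrichment"] = {
        "sensitivity": tp / len(planted) if planted else np.nan,
        "fdr": 1 - tp / len(called) if called else 0.0,
        "n_planted": len(planted), "n_called": len(called)}

    pos = truth.index[truth["protein_sign"] > 0]
    planted_p = set(zip(pos, truth.loc[pos, "protein_compartment"]))
    upp = results["calls_prot"]
    upp = upp[upp["direction"] == "enriched"]
    called_p = set(zip(upp["feature"], upp["compartment"]))
    tpp = len(called_p & planted_p)
    out["protein_enrichment"] = {
        "sensitivity": tpp / len(planted_p) if planted_p else np.nan,
        "n_planted": len(planted_p), "n_called": len(called_p)}

    rec = results["corr_records"].set_index("gene")
    shared = rec.index.intersection(truth.index)
    cls_truth = truth.loc[shared, "coupling_class"]
    cls_est = rec.loc[shared, "class"]
    for cls in ("positive", "negative"):
        idx = cls_truth == cls
        out[f"coupling_{cls}_sensitivity"] = float(
            (cls_est[idx] == cls).mean()) if idx.any() else np.nan
    nul = cls_truth == "null"
    out["coupling_null_misclass"] = float(
        (cls_est[nul] != "neither").mean()) if nul.any() else np.nan

    tc = results["truth_sort"].contaminants
    true_set = set(tc.index[tc["is_contaminant"]])
    for mol, key in (("protein", "contam_prot"), ("rna", "contam_rna")):
        listed = results[key].features
        out[f"contaminant_{mol}"] = {
            "recall": len(listed & true_set) / len(true_set) if true_set else np.nan,
            "false_listing": len(listed - true_set) / len(listed) if listed else 0.0,
            "n_listed": len(listed), "n_true": len(true_set)}

    cv = results["plsda_cv"]
    out["plsda_cv_accuracy"] = float(cv.mean_accuracy.loc[cv.chosen_A])
    return out
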