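"""Integrative statistics joining the transcriptome and proteome tracks.

Covers population-level Pearson correlation of mean mRNA and protein
abundances, per-gene profile-correlation classification across strata,
row-wise z-scoring of fold changes for gene-set distribution summaries,
Kruskal-Wallis / Dunn rank tests of protein half-lives across correlation
classes, and the co-enrichment cross-tabulation with translatome
proportions.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .containers import DesignError, OmicsMatrix, ReferenceTables, compartment_scheme

log = logging.getLogger("stratomics")


# ---------------------------------------------------------------------------
# abundance correlations
# ---------------------------------------------------------------------------

def compartment_means(mat: pd.DataFrame, meta: pd.DataFrame,
                      compartments: list[str]) -> pd.DataFrame:
    """Per-gene mean abundance per compartment (replicate means, NaN-aware)."""
    out = {}
    for c in compartments:
        cols = meta.index[meta["compartment"] == c]
        out[c] = mat[list(cols)].mean(axis=1)
    return pd.DataFrame(out)


def population_correlation(rna_abund: pd.DataFrame, prot_abund: pd.DataFrame,
                           meta: pd.DataFrame) -> pd.DataFrame:
    """Pearson r of mean mRNA vs protein abundance, per stratum and pooled.

    ``rna_abund`` holds log2 normalized counts, ``prot_abund`` log2 iBAQ
    values, both genes x samples. Only complete pairs (gene present in both
    tables with non-missing means) enter each correlation; pair counts are
    reported. Fewer than 3 complete pairs yields NaN with a flag.
    """
    comps = [c for c in compartment_scheme(meta["compartment"])
             if c in set(meta["compartment"])]
    shared = rna_abund.index.intersection(prot_abund.index)
    rna_means = compartment_means(rna_abund.loc[shared], meta, comps)
    prot_means = compartment_means(prot_abund.loc[shared], meta, comps)
    rows = []
    for scope in comps + ["pooled"]:
        if scope == "pooled":
            x = rna_means.mean(axis=1)
            y = prot_means.mean(axis=1)
        else:
            x, y = rna_means[scope], prot_means[scope]
        ok = x.notna() & y.notna()
        n_pairs = int(ok.sum())
        if n_pairs < 3 or x[ok].std() == 0 or y[ok].std() == 0:
            rows.append((scope, np.nan, n_pairs, False))
            continue
        r = float(np.corrcoef(x[ok], y[ok])[0, 1])
        rows.append((scope, r, n_pairs, True))
    return pd.DataFrame(rows, columns=["scope", "r", "n_pairs", "defined"])


def profile_correlation_classify(rna_means: pd.DataFrame,
                                 prot_means: pd.DataFrame,
                                 r_pos: float = 0.9, r_neg: float = -0.9
                                 ) -> pd.DataFrame:
    """Per-gene Pearson correlation of mRNA vs protein compartment profiles.

    Both inputs are genes x compartments mean-abundance tables on matching
    log2 scales. Genes absent from either table are skipped (counted in the
    log); zero-variance profiles on either side yield class ``neither`` with
    an undefined r (flagged). Classes: ``positive`` iff ``r >= r_pos``,
    ``negative`` iff ``r <= r_neg``, else ``neither``.
    """
    if r_neg >= r_pos:
        raise DesignError("r_neg must be below r_pos")
    shared = rna_means.index.intersection(prot_means.index)
    skipped = (len(rna_means) - len(shared), len(prot_means) - len(shared))
    if any(skipped):
        log.info("profile correlation: skipped %d RNA-only and %d protein-only "
                 "genes", *skipped)
    X = rna_means.loc[shared].to_numpy(dtype=float)
    Y = prot_means.loc[shared].to_numpy(dtype=float)
    n_points = X.shape[1]
    rows = []
    for gene, x, y in zip(shared, X, Y):
        if np.isnan(x).any() or np.isnan(y).any():
            rows.append((gene, np.nan, n_points, "neither", False))
            continue
        sx, sy = x.std(ddof=1), y.std(ddof=1)
        if sx == 0 or sy == 0:
            rows.append((gene, np.nan, n_points, "neither", False))
            continue
        r = float(np.corrcoef(x, y)[0, 1])
        cls = "positive" if r >= r_pos else "negative" if r <= r_neg else "neither"
        rows.append((gene, r, n_points, cls, True))
    df = pd.DataFrame(rows, columns=["gene", "r", "n_profile_points", "class",
                                     "defined"])
    counts = df["class"].value_counts().to_dict()
    log.info("profile correlation classes: %s", counts)
    return df


# ---------------------------------------------------------------------------
# z-scored fold changes
# ---------------------------------------------------------------------------

def zscore_fold_changes(lfc: pd.DataFrame, gene_sets=None
                        ) -> tuple[pd.DataFrame, pd.DataFrame | None]:
    """Row-wise z-scores of a gene x strata fold-change matrix.

    Each row is centered on its mean across strata and divided by its sample
    standard deviation (ddof=1). Constant rows become all-zero and are
    flagged. When ``gene_sets`` (a GeneSetCollection) is given, a long-format
    per-set distribution table is returned alongside.
    """
    if lfc.shape[1] < 2:
        raise ValueError("need at least 2 strata columns")
    vals = lfc.to_numpy(dtype=float)
    mean = np.nanmean(vals, axis=1, keepdims=True)
    sd = np.nanstd(vals, axis=1, ddof=1, keepdims=True)
    flat = (sd == 0) | ~np.isfinite(sd)
    safe_sd = np.where(flat, 1.0, sd)
    z = (vals - mean) / safe_sd
    z[flat[:, 0]] = 0.0
    zdf = pd.DataFrame(z, index=lfc.index, columns=lfc.columns)
    zdf["flat_profile"] = flat[:, 0]
    long = None
    if gene_sets is not None:
        records = []
        for name, (_desc, genes) in gene_sets.items():
            members = zdf.index.intersection(list(genes))
            sub = zdf.loc[members, lfc.columns]
            melted = sub.reset_index(names="gene").melt(
                id_vars="gene", var_name="stratum", value_name="z")
            melted.insert(0, "set", name)
            records.append(melted)
        long = (pd.concat(records, ignore_index=True) if records
                else pd.DataFrame(columns=["set", "gene", "stratum", "z"]))
    return zdf, long


# ---------------------------------------------------------------------------
# Kruskal-Wallis / Dunn half-life tests
# ---------------------------------------------------------------------------

@dataclass
class RankTestResult:
    """Tie-corrected Kruskal-Wallis H with post hoc Dunn comparisons."""

    H: float
    df: int
    pvalue: float
    group_sizes: dict[str, int]
    dunn: pd.DataFrame  # group_a, group_b, Z, pvalue, p_adjusted (Bonferroni)
    n_joined: int = 0

    def to_frame(self) -> pd.DataFrame:
        d = self.dunn.copy()
        d.insert(0, "H", self.H)
        d.insert(1, "H_df", self.df)
        d.insert(2, "H_pvalue", self.pvalue)
        return d


def kruskal_dunn(groups: dict[str, np.ndarray]) -> RankTestResult:
    """Tie-corrected Kruskal-Wallis test with Dunn's z post hoc comparisons.

    ``H = [12/(N(N+1)) * sum n_i (rbar_i - (N+1)/2)^2] / [1 - sum(t^3 - t) /
    (N^3 - N)]`` with chi-square reference on k-1 df. Dunn's
    ``Z_ij = (rbar_i - rbar_j) / sqrt((N(N+1)/12 - sum(t^3 - t)/(12(N-1))) *
    (1/n_i + 1/n_j))``, two-sided normal p, Bonferroni over all pairs.
    """
    names = list(groups)
    sizes = {g: len(np.asarray(groups[g], dtype=float)) for g in names}
    if any(n < 2 for n in sizes.values()):
        raise ValueError(f"every group needs n >= 2, got {sizes}")
    values = np.concatenate([np.asarray(groups[g], dtype=float) for g in names])
    labels = np.concatenate([np.full(sizes[g], gi) for gi, g in enumerate(names)])
    N = values.size
    ranks = stats.rankdata(values)
    _, tie_counts = np.unique(values, return_counts=True)
    tie_term = float(np.sum(tie_counts ** 3 - tie_counts))

    rbar = np.array([ranks[labels == gi].mean() for gi in range(len(names))])
    n_i = np.array([sizes[g] for g in names], dtype=float)
    H_raw = 12.0 / (N * (N + 1)) * np.sum(n_i * (rbar - (N + 1) / 2.0) ** 2)
    correction = 1.0 - tie_term / (N ** 3 - N)
    if correction <= 0:
        raise ValueError("all values tied; rank test undefined")
    H = float(H_raw / correction)
    df = len(names) - 1
    p = float(stats.chi2.sf(H, df))

    var_term = N * (N + 1) / 12.0 - tie_term / (12.0 * (N - 1))
    pairs = list(itertools.combinations(range(len(names)), 2))
    rows = []
    for i, j in pairs:
        z = (rbar[i] - rbar[j]) / np.sqrt(var_term * (1 / n_i[i] + 1 / n_i[j]))
        pz = 2.0 * stats.norm.sf(abs(z))
        rows.append((names[i], names[j], float(z), float(pz),
                     float(min(1.0, pz * len(pairs)))))
    dunn = pd.DataFrame(rows, columns=["group_a", "group_b", "Z", "pvalue",
                                       "p_adjusted"])
    return RankTestResult(H=H, df=df, pvalue=p, group_sizes=sizes, dunn=dunn)


def halflife_group_test(records: pd.DataFrame, reference: ReferenceTables,
                        groups: tuple[str, ...] = ("all", "positive", "negative")
                        ) -> RankTestResult:
    """Compare protein half-lives across profile-correlation classes.

    ``records`` is the output of :func:`profile_correlation_classify`. Genes
    are joined to the half-life table by symbol; the ``all`` group contains
    every joined gene (overlapping with the class groups, mirroring a
    three-box comparison where the pooled group is shown alongside the
    classes — the groups are therefore not independent).
    """
    hl = reference.half_life.rename("half_life")
    hl.index.name = "gene"
    joined = records.merge(hl.reset_index(), on="gene")
    n_joined = len(joined)
    log.info("half-life join: %d of %d genes mapped", n_joined, len(records))
    data: dict[str, np.ndarray] = {}
    for g in groups:
        sub = joined if g == "all" else joined[joined["class"] == g]
        data[g] = sub["half_life"].to_numpy(dtype=float)
    result = kruskal_dunn(data)
    result.n_joined = n_joined
    return result


# ---------------------------------------------------------------------------
# co-enrichment / translatome mapping
# ---------------------------------------------------------------------------

@dataclass
class CoEnrichmentTable:
    """Cross-tab of mRNA vs protein enrichment compartments.

    ``counts``: rows = mRNA compartment, columns = protein compartment.
    ``cells``: long-format per-cell gene lists and translatome proportions
    over labeled genes (proportions sum to 1 per cell); unlabeled genes are
    counted separately.
    """

    counts: pd.DataFrame
    cells: pd.DataFrame


def co_enrichment_map(mrna_calls: pd.DataFrame, prot_calls: pd.DataFrame,
                      translatome: pd.Series | None = None) -> CoEnrichmentTable:
    """Cross-tabulate enriched-direction calls of mRNAs and their proteins.

    A gene enriched at both molecule levels contributes to every applicable
    (mRNA compartment, protein compartment) cell, so multi-compartment
    enrichment fans out over several cells. Per cell, the proportions of
    translatome labels are computed over the genes carrying a label.
    """
    m_up = mrna_calls[mrna_calls["direction"] == "enriched"]
    p_up = prot_calls[prot_calls["direction"] == "enriched"]
    m_comps = set(m_up["compartment"]) | set(p_up["compartment"])
    scheme = [c for c in compartment_scheme(m_comps)] if m_comps else []
    merged = m_up[["feature", "compartment"]].rename(
        columns={"compartment": "mrna_compartment"}).merge(
        p_up[["feature", "compartment"]].rename(
            columns={"compartment": "protein_compartment"}), on="feature")

    comps = [c for c in scheme]
    counts = pd.DataFrame(0, index=pd.Index(comps, name="mrna_compartment"),
                          columns=pd.Index(comps, name="protein_compartment"))
    rows = []
    for (mc, pc), sub in merged.groupby(["mrna_compartment", "protein_compartment"]):
        genes = sorted(sub["feature"].unique())
        counts.loc[mc, pc] = len(genes)
        props = {"soma": np.nan, "neuropil": np.nan, "unbiased": np.nan}
        n_labeled = 0
        n_unlabeled = len(genes)
        if translatome is not None:
            labels = translatome.reindex(genes).dropna()
            n_labeled = len(labels)
            n_unlabeled = len(genes) - n_labeled
            if n_labeled:
                vc = labels.value_counts()
                for lab in props:
                    props[lab] = float(vc.get(lab, 0)) / n_labeled
        rows.append((mc, pc, len(genes), ";".join(genes), n_labeled, n_unlabeled,
                     props["soma"], props["neuropil"], props["unbiased"]))
    cells = pd.DataFrame(rows, columns=[
        "mrna_compartment", "protein_compartment", "n_genes", "genes",
        "n_labeled", "n_unlabeled", "prop_soma", "prop_neuropil",
        "prop_unbiased"])
    return CoEnrichmentTable(counts=counts, cells=cells)
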