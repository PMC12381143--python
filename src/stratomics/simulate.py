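"""Synthetic paired transcriptome/proteome bundles with planted ground truth.

The generator emulates the statistical structure the analysis assumes:

* RNA counts ``K_gj ~ NegBin(mean = s_j * b_g * 2**beta_{g,c(j)}, dispersion
  alpha_g)`` with log-normal per-sample size factors ``s_j`` (geometric mean
  1) and per-gene log-fold enrichments ``beta`` planted in one compartment.
* Protein log2 intensities ``y_gj = c_g + gamma_{g,c(j)} + eps`` with
  ``eps ~ Normal(0, protein_noise_sd)``. The compartment profile ``gamma_g``
  is ``amplitude * (rho_g * standardized(beta_g) + sqrt(1 - rho_g^2) * z_g)``
  with ``z_g`` an independent standardized profile, so the expected
  mRNA-protein profile correlation equals ``rho_g``. Coupling classes
  (rho = +1 / -1 / 0) are planted among genes with a non-flat mRNA profile;
  genes with flat profiles get rho applied to a random unit profile.
* Missing protein values are intensity-dependent (lowest-intensity tercile
  twice as likely as the upper two), mimicking abundance-linked DIA
  missingness.
* A sorted-synaptosome experiment with paired P2 (unsorted control) and P3
  (sorted) fractions per compartment, where planted contaminant features are
  shifted up in P2.
* Reference tables: protein half-lives log-linearly anti-correlated with the
  coupling coefficient (positively coupled genes turn over faster),
  translatome labels with the neuropil probability raised for genes whose
  mRNA and protein are both planted in the most distal compartment, gene
  sets for each planted enrichment group plus random decoys, and random
  protein sequences.

Everything is deterministic given (config, seed), and the truth record is a
separate artifact that never leaks into the data files.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .containers import (
    ConfigError,
    GeneSetCollection,
    OmicsMatrix,
    ReferenceTables,
    STRATA,
)

AA20 = np.array(list("ACDEFGHIKLMNPQRSTVWY"))


@dataclass
class SimConfig:
    """Parameters of the synthetic study.

    Defaults describe a deep paired tissue design: 4 CA1 strata with 7
    biological replicates, ~2000 genes, log2 enrichment effects of 1.0
    planted in 10% of genes per compartment, negative-binomial dispersion
    around 0.02 (deep bulk RNA-seq of pooled tissue), protein measurement
    noise of 0.5 log2 units (typical DIA replicate CV), and 5% missing
    protein values.
    """

    n_genes: int = 2000
    compartments: tuple[str, ...] = STRATA
    n_replicates: int = 7
    enriched_fraction: float = 0.1          # per compartment
    effect_lfc: float = 1.0                 # planted log2 enrichment
    base_log2_mean: float = 7.0             # log2 mean count of an average gene
    base_log2_sd: float = 1.5
    nb_dispersion_log_mean: float = float(np.log(0.02))
    nb_dispersion_log_sd: float = 0.3
    size_factor_log_sd: float = 0.15
    coupling_fractions: tuple[float, float, float] = (0.2, 0.15, 0.65)
    coupling_amplitude: float = 1.0         # log2 SD of the protein profile
    protein_base_log2_mean: float = 20.0
    protein_base_log2_sd: float = 2.0
    population_coupling: float = 0.35   # cross-gene mRNA-protein abundance r
    protein_noise_sd: float = 0.5           # log2
    missing_rate: float = 0.05
    halflife_base_hours: float = 96.0
    halflife_coupling_slope: float = 0.4    # log-hours per unit rho
    halflife_log_sd: float = 0.5
    contaminant_fraction: float = 0.1
    contaminant_lfc: float = 2.0            # P2 - P3 shift, log2
    translatome_neuropil_prob: float = 0.2
    translatome_soma_prob: float = 0.4
    translatome_distal_neuropil_prob: float = 0.7
    n_decoy_sets: int = 10
    decoy_set_size: int = 25
    seed: int = 0

    def validate(self) -> None:
        if self.n_genes < 1:
            raise ConfigError("n_genes must be >= 1")
        if len(self.compartments) < 2:
            raise ConfigError("need at least 2 compartments")
        if self.n_replicates < 2:
            raise ConfigError("n_replicates must be >= 2")
        fr = [self.enriched_fraction, self.missing_rate,
              self.contaminant_fraction, *self.coupling_fractions,
              self.translatome_neuropil_prob, self.translatome_soma_prob]
        if any(not (0.0 <= f <= 1.0) for f in fr):
            raise ConfigError("fractions must lie in [0, 1]")
        if sum(self.coupling_fractions) > 1.0 + 1e-12:
            raise ConfigError("coupling fractions must sum to <= 1")
        if not np.isfinite([self.effect_lfc, self.contaminant_lfc]).all():
            raise ConfigError("effect sizes must be finite")
        if self.enriched_fraction * len(self.compartments) > 1.0 + 1e-12:
            raise ConfigError("enriched_fraction * n_compartments exceeds 1")

    def validate_coupling(self) -> None:
        """Coupled genes are planted among genes with a non-flat profile."""
        f_pos, f_neg, _ = self.coupling_fractions
        n_coupled = (int(round(f_pos * self.n_genes))
                     + int(round(f_neg * self.n_genes)))
        n_enriched = (len(self.compartments)
                      * int(round(self.enriched_fraction * self.n_genes)))
        if n_coupled > n_enriched:
            raise ConfigError(
                "coupling fractions require more coupled genes than there are "
                "genes with a planted (non-flat) mRNA profile; raise "
                "enriched_fraction or lower coupling fractions")


@dataclass
class SimTruth:
    """Planted ground truth, one artifact per simulated bundle.

    ``genes`` has one row per gene: planted mRNA enrichment compartment and
    sign, planted protein enrichment compartment and sign, coupling class and
    coefficient rho, half-life (hours) and translatome label (filled in by
    :func:`simulate_reference_tables`). ``contaminants`` flags features of
    the sorting experiment. ``size_factors`` holds the true per-sample
    factors of the tissue counts.
    """

    genes: pd.DataFrame
    size_factors: pd.Series = field(default_factory=lambda: pd.Series(dtype=float))
    contaminants: pd.DataFrame = field(default_factory=pd.DataFrame)

    def to_frames(self) -> dict[str, pd.DataFrame]:
        out = {"truth_genes": self.genes.reset_index()}
        if len(self.size_factors):
            sf = self.size_factors.rename("size_factor")
            sf.index.name = "sample_id"
            out["truth_size_factors"] = sf.reset_index()
        if len(self.contaminants):
            out["truth_contaminants"] = self.contaminants.reset_index()
        return out


def _gene_ids(n: int) -> list[str]:
    return [f"g{i:05d}" for i in range(n)]


def _sample_meta(compartments, n_reps, fraction="tissue") -> pd.DataFrame:
    rows = []
    for c in compartments:
        for r in range(1, n_reps + 1):
            suffix = "" if fraction == "tissue" else f"_{fraction}"
            rows.append((f"{c}_r{r}{suffix}", c, r, fraction))
    return pd.DataFrame(rows, columns=["sample_id", "compartment", "replicate",
                                       "fraction"]).set_index("sample_id")


def _standardize_profile(profile: np.ndarray) -> np.ndarray:
    """Zero-mean unit-population-SD version of a compartment profile."""
    mu = profile.mean()
    sd = profile.std()
    return (profile - mu) / sd


def _plant_enrichment(rng, n_genes, compartments, frac, effect):
    """Assign each gene to at most one enriched compartment.

    A random permutation of genes is cut into one block of
    ``round(frac * n_genes)`` genes per compartment (the remainder stays
    flat), so realized enrichment counts match the configured fraction
    exactly while membership stays random.

    Returns (beta matrix genes x compartments, compartment label per gene,
    "" for flat genes)."""
    k = len(compartments)
    per_comp = int(round(frac * n_genes))
    order = rng.permutation(n_genes)
    beta = np.zeros((n_genes, k))
    labels = np.full(n_genes, "", dtype=object)
    for ci, comp in enumerate(compartments):
        idx = order[ci * per_comp:(ci + 1) * per_comp]
        beta[idx, ci] = effect
        labels[idx] = comp
    return beta, labels


def simulate_spatial_omics(config: SimConfig, seed: int | None = None
                           ) -> tuple[OmicsMatrix, OmicsMatrix, SimTruth]:
    """Generate the paired tissue bundle: RNA counts, protein log2, truth."""
    config.validate()
    config.validate_coupling()
    rng = np.random.default_rng(config.seed if seed is None else seed)
    n = config.n_genes
    comps = list(config.compartments)
    k = len(comps)
    genes = _gene_ids(n)
    meta = _sample_meta(comps, config.n_replicates)
    samples = list(meta.index)
    comp_idx = np.array([comps.index(c) for c in meta["compartment"]])

    # --- planted mRNA structure ------------------------------------------
    beta, mrna_comp = _plant_enrichment(rng, n, comps, config.enriched_fraction,
                                        config.effect_lfc)
    base = 2.0 ** rng.normal(config.base_log2_mean, config.base_log2_sd, size=n)
    alpha = np.exp(rng.normal(config.nb_dispersion_log_mean,
                              config.nb_dispersion_log_sd, size=n))
    log_s = rng.normal(0.0, config.size_factor_log_sd, size=len(samples))
    log_s -= log_s.mean()
    s = np.exp(log_s)

    mean = base[:, None] * (2.0 ** beta[:, comp_idx]) * s[None, :]
    # NB with mean m, dispersion a: gamma-poisson mixture
    shape = 1.0 / alpha
    lam = rng.gamma(shape[:, None], (mean * alpha[:, None]))
    counts = rng.poisson(lam)
    rna = OmicsMatrix(pd.DataFrame(counts, index=genes, columns=samples),
                      "rna_counts", meta.copy())

    # --- coupling classes -------------------------------------------------
    f_pos, f_neg, _f_null = config.coupling_fractions
    n_pos = int(round(f_pos * n))
    n_neg = int(round(f_neg * n))
    enriched_idx = np.flatnonzero(mrna_comp != "")
    chosen = rng.permutation(enriched_idx)
    rho = np.zeros(n)
    rho[chosen[:n_pos]] = 1.0
    rho[chosen[n_pos:n_pos + n_neg]] = -1.0
    coupling_class = np.where(rho > 0, "positive",
                              np.where(rho < 0, "negative", "null"))

    # --- protein profiles -------------------------------------------------
    gamma = np.zeros((n, k))
    prot_comp = np.full(n, "", dtype=object)
    prot_sign = np.zeros(n, dtype=int)
    indep = np.array([_standardize_profile(rng.normal(size=k)) for _ in range(n)])
    for gi in range(n):
        if rho[gi] != 0.0:
            if mrna_comp[gi] != "":
                prof = _standardize_profile(beta[gi])
            else:  # flat mRNA profile: rho applied to a random unit profile
                prof = indep[gi]
            gamma[gi] = config.coupling_amplitude * rho[gi] * prof
            if mrna_comp[gi] != "":
                prot_comp[gi] = mrna_comp[gi]
                prot_sign[gi] = int(np.sign(rho[gi]))
        else:
            gamma[gi] = config.coupling_amplitude * indep[gi]
    # base protein abundance modestly coupled to base mRNA abundance across
    # genes (population-level correlation), independent of profile coupling
    log2_base = np.log2(base)
    zb = (log2_base - log2_base.mean()) / log2_base.std()
    rho_pop = config.population_coupling
    c_g = (config.protein_base_log2_mean + config.protein_base_log2_sd
           * (rho_pop * zb + np.sqrt(1.0 - rho_pop ** 2) * rng.normal(size=n)))
    eps = rng.normal(0.0, config.protein_noise_sd, size=(n, len(samples)))
    y = c_g[:, None] + gamma[:, comp_idx] + eps

    # --- intensity-dependent missingness ---------------------------------
    y = _inject_missing(rng, y, config.missing_rate)
    protein = OmicsMatrix(pd.DataFrame(y, index=genes, columns=samples),
                          "protein_log2", meta.copy())

    truth_genes = pd.DataFrame({
        "mrna_compartment": mrna_comp,
        "protein_compartment": prot_comp,
        "protein_sign": prot_sign,
        "coupling_class": coupling_class,
        "rho": rho,
        "dispersion": alpha,
    }, index=pd.Index(genes, name="gene"))
    truth = SimTruth(genes=truth_genes,
                     size_factors=pd.Series(s, index=samples))
    return rna, protein, truth


def _inject_missing(rng, y: np.ndarray, rate: float) -> np.ndarray:
    """MNAR-lite missingness: lowest-intensity tercile twice as likely.

    Per-cell rates (2a, a, a) across ascending terciles with overall mean
    equal to ``rate``.
    """
    if rate <= 0:
        return y
    a = 0.75 * rate
    flat = y.flatten()
    qs = np.quantile(flat, [1 / 3, 2 / 3])
    p = np.where(y <= qs[0], 2 * a, a)
    drop = rng.random(y.shape) < p
    out = y.copy()
    out[drop] = np.nan
    return out


def simulate_sorting_experiment(config: SimConfig, seed: int | None = None
                                ) -> tuple[OmicsMatrix, OmicsMatrix, SimTruth]:
    """Paired P2 (unsorted) / P3 (sorted) fractions with planted contaminants.

    Returns (protein matrix, RNA count matrix, truth). Contaminant features
    have their mean shifted ``+contaminant_lfc`` (log2) in P2 relative to P3
    in both molecule types; non-contaminants differ only by symmetric noise.
    P3 samples additionally carry the planted per-compartment synaptic
    enrichment so downstream synaptic DE has signal to recover.
    """
    config.validate()
    rng = np.random.default_rng(config.seed + 1 if seed is None else seed)
    n = config.n_genes
    comps = list(config.compartments)
    k = len(comps)
    genes = _gene_ids(n)
    meta = pd.concat([_sample_meta(comps, config.n_replicates, "P2"),
                      _sample_meta(comps, config.n_replicates, "P3")])
    samples = list(meta.index)
    comp_idx = np.array([comps.index(c) for c in meta["compartment"]])
    is_p2 = (meta["fraction"] == "P2").to_numpy()

    contaminant = rng.random(n) < config.contaminant_fraction
    beta, syn_comp = _plant_enrichment(rng, n, comps, config.enriched_fraction,
                                       config.effect_lfc)

    # protein intensities
    c_g = rng.normal(config.protein_base_log2_mean, config.protein_base_log2_sd,
                     size=n)
    shift = np.where(contaminant[:, None] & is_p2[None, :],
                     config.contaminant_lfc, 0.0)
    y = (c_g[:, None] + beta[:, comp_idx] * (~is_p2)[None, :] + shift
         + rng.normal(0.0, config.protein_noise_sd, size=(n, len(samples))))
    y = _inject_missing(rng, y, config.missing_rate)
    protein = OmicsMatrix(pd.DataFrame(y, index=genes, columns=samples),
                          "protein_log2", meta.copy())

    # RNA counts
    base = 2.0 ** rng.normal(config.base_log2_mean, config.base_log2_sd, size=n)
    alpha = np.exp(rng.normal(config.nb_dispersion_log_mean,
                              config.nb_dispersion_log_sd, size=n))
    log_s = rng.normal(0.0, config.size_factor_log_sd, size=len(samples))
    log_s -= log_s.mean()
    s = np.exp(log_s)
    lfc = beta[:, comp_idx] * (~is_p2)[None, :] + np.where(
        contaminant[:, None] & is_p2[None, :], config.contaminant_lfc, 0.0)
    mean = base[:, None] * (2.0 ** lfc) * s[None, :]
    lam = rng.gamma((1.0 / alpha)[:, None], mean * alpha[:, None])
    counts = rng.poisson(lam)
    rna = OmicsMatrix(pd.DataFrame(counts, index=genes, columns=samples),
                      "rna_counts", meta.copy())

    truth_genes = pd.DataFrame({
        "synaptic_compartment": syn_comp,
    }, index=pd.Index(genes, name="gene"))
    contam = pd.DataFrame({"is_contaminant": contaminant},
                          index=pd.Index(genes, name="feature"))
    truth = SimTruth(genes=truth_genes, contaminants=contam,
                     size_factors=pd.Series(s, index=samples))
    return protein, rna, truth


def simulate_reference_tables(config: SimConfig, truth: SimTruth,
                              seed: int | None = None
                              ) -> tuple[ReferenceTables, GeneSetCollection]:
    """Half-lives, translatome labels, gene sets and protein sequences.

    Half-life: ``exp(log(base) - slope * rho + Normal(0, sd))`` hours, so
    positively coupled genes turn over stochastically faster. Translatome:
    neuropil probability raised for genes whose mRNA and protein are both
    planted in the most distal compartment. Gene sets: one set per planted
    enrichment group plus random decoy sets. Sequences: random 100-600 aa.
    """
    config.validate()
    rng = np.random.default_rng(config.seed + 2 if seed is None else seed)
    genes = truth.genes.index.to_numpy()
    n = genes.size
    rho = truth.genes.get("rho", pd.Series(0.0, index=truth.genes.index)).to_numpy()

    half_life = np.exp(np.log(config.halflife_base_hours)
                       - config.halflife_coupling_slope * rho
                       + rng.normal(0.0, config.halflife_log_sd, size=n))

    distal = config.compartments[-1]
    mrna_c = truth.genes.get("mrna_compartment",
                             pd.Series("", index=truth.genes.index)).to_numpy()
    prot_c = truth.genes.get("protein_compartment",
                             pd.Series("", index=truth.genes.index)).to_numpy()
    co_distal = (mrna_c == distal) & (prot_c == distal)
    p_neu = np.where(co_distal, config.translatome_distal_neuropil_prob,
                     config.translatome_neuropil_prob)
    p_soma = np.minimum(config.translatome_soma_prob, 1.0 - p_neu)
    u = rng.random(n)
    labels = np.where(u < p_neu, "neuropil",
                      np.where(u < p_neu + p_soma, "soma", "unbiased"))

    lengths = rng.integers(100, 601, size=n)
    seqs = {g: "".join(rng.choice(AA20, size=L)) for g, L in zip(genes, lengths)}

    sets = GeneSetCollection()
    for comp in config.compartments:
        members = genes[mrna_c == comp]
        if members.size:
            sets.add(f"planted_{comp}", f"genes with planted mRNA enrichment in {comp}",
                     members.tolist())
    for i in range(config.n_decoy_sets):
        size = min(config.decoy_set_size, n)
        members = rng.choice(genes, size=size, replace=False)
        sets.add(f"decoy_{i:02d}", "random decoy set", members.tolist())

    ref = ReferenceTables(
        half_life=pd.Series(half_life, index=pd.Index(genes, name="gene")),
        translatome=pd.Series(labels, index=pd.Index(genes, name="gene")),
        sequences=seqs,
    )
    truth.genes["half_life_hours"] = half_life
    truth.genes["translatome"] = labels
    return ref, sets
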