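"""Differential enrichment testing for counts and log intensities.

RNA counts are tested with a negative-binomial generalized linear model and a
two-sided Wald test. Per-gene dispersions are estimated by method of moments
on size-factor-normalized counts (pooled within groups), a mean-dispersion
trend ``alpha(mu) = a1/mu + a0`` is fitted robustly across genes, and the
final dispersion is the geometric mean of the gene-wise and trend values
(trend-only when the gene-wise estimate collapses to the floor).

Protein log2 intensities are tested with an ordinary least-squares linear
model per protein and empirical-Bayes variance moderation: a scaled
inverse-chi-square prior (d0, s0^2) is fitted to the observed residual
variances by matching the first two moments of log s^2 (digamma/trigamma
inversion), and moderated t statistics use the shrunken variance with
d0 + d_g degrees of freedom.

Both tracks share Benjamini-Hochberg adjustment and threshold-based
enrichment calling (q below alpha and |log2 fold change| at least lfc_min).
Compartment contrasts come in two schemes — every compartment against each
other one separately, or each against the pooled rest — and a
fraction contrast (sorted P3 vs unsorted P2 within each compartment) feeds
the contaminant filter.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import special, stats

from .containers import DesignError, OmicsMatrix

log = logging.getLogger("stratomics")

LN2 = np.log(2.0)
DISPERSION_FLOOR = 1e-8


# ---------------------------------------------------------------------------
# multiple testing
# ---------------------------------------------------------------------------

def bh_adjust(p) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (NaN propagated)."""
    p = np.asarray(p, dtype=float)
    q = np.full(p.shape, np.nan)
    ok = ~np.isnan(p)
    pv = p[ok]
    if ((pv < 0) | (pv > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    m = pv.size
    if m == 0:
        return q
    order = np.argsort(pv, kind="mergesort")
    ranked = pv[order] * m / np.arange(1, m + 1)
    ranked = np.minimum.accumulate(ranked[::-1])[::-1]
    qs = np.empty(m)
    qs[order] = np.minimum(ranked, 1.0)
    q[ok] = qs
    return q


# ---------------------------------------------------------------------------
# valid-value filtering
# ---------------------------------------------------------------------------

def filter_valid_values(mat: OmicsMatrix, groups: dict[str, list[str]],
                        min_quant: int = 1, by_contrast: bool = True
                        ) -> OmicsMatrix:
    """Keep features with at least ``min_quant`` non-missing values per group.

    ``groups`` maps group label -> sample ids of the contrast. With
    ``by_contrast=False`` the requirement is over the union of all groups
    instead of each group separately.
    """
    for name, samples in groups.items():
        if len(samples) == 0:
            raise DesignError(f"empty group {name!r}")
    present = mat.values.notna()
    if by_contrast:
        keep = pd.Series(True, index=mat.values.index)
        for name, samples in groups.items():
            keep &= present[list(samples)].sum(axis=1) >= min_quant
    else:
        all_samples = list(itertools.chain.from_iterable(groups.values()))
        keep = present[all_samples].sum(axis=1) >= min_quant
    return mat.subset_features(mat.values.index[keep])


# ---------------------------------------------------------------------------
# contrast enumeration and design matrices
# ---------------------------------------------------------------------------

def contrast_pairs(compartments, scheme: str) -> list[tuple[str, tuple]]:
    """Enumerate (label, (target, baseline compartments)) for a scheme.

    ``pairwise``: every ordered pair ``C_vs_D``. ``one_vs_rest``:
    ``C_vs_rest`` with all remaining compartments pooled.
    """
    comps = list(compartments)
    if len(comps) < 2:
        raise DesignError("need at least 2 compartments")
    out = []
    if scheme == "pairwise":
        for c, d in itertools.permutations(comps, 2):
            out.append((f"{c}_vs_{d}", (c, (d,))))
    elif scheme == "one_vs_rest":
        for c in comps:
            rest = tuple(d for d in comps if d != c)
            out.append((f"{c}_vs_rest", (c, rest)))
    else:
        raise DesignError(f"unknown contrast scheme {scheme!r}")
    return out


def _design(meta: pd.DataFrame, samples: list[str], indicator: np.ndarray,
            include_replicate: bool) -> np.ndarray:
    """[intercept, target indicator, replicate dummies] design matrix."""
    sub = meta.loc[samples]
    cols = [np.ones(len(samples)), indicator.astype(float)]
    if include_replicate:
        reps = sorted(sub["replicate"].unique())
        for r in reps[1:]:
            cols.append((sub["replicate"] == r).to_numpy(dtype=float))
    return np.column_stack(cols)


def _compartment_contrast_samples(mat: OmicsMatrix, target: str, baseline
                                  ) -> tuple[list[str], np.ndarray]:
    samples = mat.samples_where(compartment=(target, *baseline))
    sub = mat.meta.loc[samples]
    if (sub.groupby("compartment").size() < 2).any():
        raise DesignError(f"{target} vs {baseline}: fewer than 2 replicates "
                          "in a group")
    return samples, (sub["compartment"] == target).to_numpy()


def _fraction_contrasts(mat: OmicsMatrix, target: str = "P3",
                        baseline: str = "P2"):
    """Per-compartment (label, samples, indicator) for a fraction contrast."""
    fracs = set(mat.meta["fraction"])
    if not {target, baseline} <= fracs:
        raise DesignError(f"matrix lacks fraction labels {target}/{baseline}")
    for comp in mat.compartments:
        samples = mat.samples_where(compartment=comp, fraction=(target, baseline))
        sub = mat.meta.loc[samples]
        if (sub.groupby("fraction").size() < 2).any():
            raise DesignError(f"{comp}: fewer than 2 replicates in a fraction")
        yield (f"{comp}_{target}_vs_{baseline}", samples,
               (sub["fraction"] == target).to_numpy())


# ---------------------------------------------------------------------------
# NB dispersion estimation
# ---------------------------------------------------------------------------

@dataclass
class DispersionFit:
    """Per-gene dispersions with the fitted mean-dispersion trend."""

    alpha: pd.Series            # final per-gene dispersion
    alpha_genewise: pd.Series   # method-of-moments estimate (floored)
    trend_coef: tuple[float, float]  # (a0, a1) of alpha = a0 + a1/mu
    base_mean: pd.Series


def estimate_dispersions(norm_counts: pd.DataFrame, group_labels: pd.Series
                         ) -> DispersionFit:
    """Method-of-moments dispersions with robust trend shrinkage.

    Within-group means and variances of normalized counts are pooled across
    groups; ``alpha_hat = max(pooled (v - mu) / pooled mu^2, floor)``. The
    trend ``a0 + a1/mu`` is fitted by iteratively reweighted Huber regression
    over genes with informative gene-wise estimates, and the final dispersion
    is ``exp((log alpha_hat + log trend)/2)`` (trend-only at the floor).
    """
    M = norm_counts.to_numpy(dtype=float)
    groups = pd.Series(group_labels).loc[norm_counts.columns]
    num = np.zeros(M.shape[0])
    den = np.zeros(M.shape[0])
    for g in groups.unique():
        idx = (groups == g).to_numpy()
        n = int(idx.sum())
        if n < 2:
            continue
        sub = M[:, idx]
        mu = sub.mean(axis=1)
        v = sub.var(axis=1, ddof=1)
        num += (n - 1) * (v - mu)
        den += (n - 1) * mu ** 2
    base_mean = M.mean(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        alpha_hat = np.where(den > 0, num / den, np.nan)
    alpha_hat = np.where(np.isfinite(alpha_hat), alpha_hat, DISPERSION_FLOOR)
    at_floor = alpha_hat <= DISPERSION_FLOOR
    alpha_hat = np.maximum(alpha_hat, DISPERSION_FLOOR)

    inform = (~at_floor) & (base_mean > 0)
    if inform.sum() >= 10:
        a0, a1 = _fit_dispersion_trend(base_mean[inform], alpha_hat[inform])
    else:  # too few informative genes: flat trend at the median
        a0 = float(np.median(alpha_hat[~at_floor])) if (~at_floor).any() else DISPERSION_FLOOR
        a1 = 0.0
    with np.errstate(divide="ignore"):
        trend = np.maximum(a0 + a1 / np.maximum(base_mean, 1e-12), DISPERSION_FLOOR)
    final = np.where(at_floor, trend,
                     np.exp(0.5 * (np.log(alpha_hat) + np.log(trend))))
    idx = norm_counts.index
    return DispersionFit(
        alpha=pd.Series(final, index=idx, name="dispersion"),
        alpha_genewise=pd.Series(alpha_hat, index=idx),
        trend_coef=(float(a0), float(a1)),
        base_mean=pd.Series(base_mean, index=idx, name="base_mean"),
    )


def _fit_dispersion_trend(mu, alpha, iters: int = 10) -> tuple[float, float]:
    """Huber-weighted least squares of alpha on [1, 1/mu], coefficients >= 0."""
    X = np.column_stack([np.ones_like(mu), 1.0 / mu])
    w = np.ones_like(alpha)
    coef = np.array([np.median(alpha), 0.0])
    for _ in range(iters):
        WX = X * w[:, None]
        coef_new, *_ = np.linalg.lstsq(WX.T @ X, WX.T @ alpha, rcond=None)
        coef_new = np.maximum(coef_new, 0.0)
        resid = alpha - X @ coef_new
        scale = np.median(np.abs(resid)) / 0.6745 + 1e-12
        u = np.abs(resid) / (1.345 * scale)
        w = np.where(u <= 1.0, 1.0, 1.0 / u)
        if np.allclose(coef_new, coef, rtol=1e-6, atol=1e-12):
            coef = coef_new
            break
        coef = coef_new
    if coef[0] <= 0 and coef[1] <= 0:
        coef[0] = max(float(np.median(alpha)), DISPERSION_FLOOR)
    return float(coef[0]), float(coef[1])


# ---------------------------------------------------------------------------
# NB GLM with Wald test
# ---------------------------------------------------------------------------

def _nb_glm_wald(y: np.ndarray, X: np.ndarray, offset: np.ndarray, alpha: float,
                 maxiter: int = 100, tol: float = 1e-8):
    """Fit an NB GLM (log link, fixed dispersion) by IRLS; Wald on column 1.

    Returns (beta_group, se_group, converged).
    """
    n, p = X.shape
    beta, *_ = np.linalg.lstsq(X, np.log(y + 0.5) - offset, rcond=None)
    converged = False
    for _ in range(maxiter):
        eta = np.clip(X @ beta + offset, -30, 30)
        mu = np.exp(eta)
        W = mu / (1.0 + alpha * mu)
        z = (eta - offset) + (y - mu) / mu
        XtW = X.T * W
        A = XtW @ X + np.eye(p) * 1e-10
        beta_new = np.linalg.solve(A, XtW @ z)
        if np.max(np.abs(beta_new - beta)) < tol:
            beta = beta_new
            converged = True
            break
        beta = beta_new
    eta = np.clip(X @ beta + offset, -30, 30)
    mu = np.exp(eta)
    W = mu / (1.0 + alpha * mu)
    A = (X.T * W) @ X + np.eye(p) * 1e-10
    cov = np.linalg.inv(A)
    return float(beta[1]), float(np.sqrt(cov[1, 1])), converged


def _nb_contrast_frame(counts: OmicsMatrix, label: str, samples: list[str],
                       indicator: np.ndarray, size_factors: pd.Series,
                       norm: pd.DataFrame, dispersions: DispersionFit,
                       include_replicate: bool) -> pd.DataFrame:
    X = _design(counts.meta, samples, indicator, include_replicate)
    offset = np.log(size_factors.loc[samples].to_numpy())
    Y = counts.values[samples].to_numpy(dtype=float)
    rows = []
    for gi, gene in enumerate(counts.feature_ids):
        y = Y[gi]
        alpha = float(dispersions.alpha.iloc[gi])
        if y.sum() == 0:
            rows.append((gene, label, 0.0, np.nan, np.nan, np.nan, np.nan,
                         alpha, False))
            continue
        beta, se, conv = _nb_glm_wald(y, X, offset, alpha)
        if not conv:
            log.debug("gene %s contrast %s: IRLS not converged", gene, label)
        stat = beta / se if se > 0 else np.nan
        pval = 2.0 * stats.norm.sf(abs(stat)) if np.isfinite(stat) else np.nan
        rows.append((gene, label, float(norm.loc[gene, samples].mean()),
                     beta / LN2, se / LN2, stat, pval, alpha, conv))
    df = pd.DataFrame(rows, columns=["feature", "contrast", "base_mean",
                                     "log2fc", "se", "stat", "pvalue",
                                     "dispersion", "tested"])
    df["padj"] = bh_adjust(df["pvalue"])
    return df


def _nb_prepare(counts: OmicsMatrix, size_factors, group_labels):
    from .normalize import median_ratio_size_factors

    if size_factors is None:
        size_factors, norm = median_ratio_size_factors(counts)
    else:
        norm = counts.values.astype(float).div(size_factors, axis=1)
    dispersions = estimate_dispersions(norm, group_labels)
    return size_factors, norm, dispersions


def nb_wald_de(counts: OmicsMatrix, scheme: str = "one_vs_rest",
               size_factors: pd.Series | None = None,
               include_replicate: bool = True,
               dispersions: DispersionFit | None = None) -> pd.DataFrame:
    """Negative-binomial Wald differential expression over compartments.

    Returns a long-format DataFrame with one row per (feature, contrast):
    ``log2fc``, ``se`` (log2 scale), Wald ``stat``, two-sided normal
    ``pvalue``, BH ``padj`` within contrast, ``base_mean`` (mean normalized
    count), ``dispersion`` and a ``tested`` flag (all-zero genes are kept but
    flagged untestable).
    """
    sf, norm, disp = _nb_prepare(counts, size_factors,
                                 counts.meta["compartment"])
    if dispersions is not None:
        disp = dispersions
    frames = []
    for label, (target, baseline) in contrast_pairs(counts.compartments, scheme):
        samples, indicator = _compartment_contrast_samples(counts, target, baseline)
        frames.append(_nb_contrast_frame(counts, label, samples, indicator,
                                         sf, norm, disp, include_replicate))
    return pd.concat(frames, ignore_index=True)


def nb_wald_fraction_de(counts: OmicsMatrix, target: str = "P3",
                        baseline: str = "P2", include_replicate: bool = True
                        ) -> pd.DataFrame:
    """Per-compartment sorted-vs-unsorted (P3 vs P2) NB Wald DE on counts."""
    groups = (counts.meta["compartment"].astype(str) + "/"
              + counts.meta["fraction"].astype(str))
    sf, norm, disp = _nb_prepare(counts, None, groups)
    frames = []
    for label, samples, indicator in _fraction_contrasts(counts, target, baseline):
        frames.append(_nb_contrast_frame(counts, label, samples, indicator,
                                         sf, norm, disp, include_replicate))
    return pd.concat(frames, ignore_index=True)


# ---------------------------------------------------------------------------
# moderated linear model for intensities
# ---------------------------------------------------------------------------

def trigamma_inverse(x: float, iters: int = 50) -> float:
    """Solve trigamma(y) = x for y > 0 by Newton iteration."""
    if x <= 0:
        return np.inf
    if x > 1e7:
        return 1.0 / np.sqrt(x)
    if x < 1e-6:
        return 1.0 / x
    y = 0.5 + 1.0 / x
    for _ in range(iters):
        tri = special.polygamma(1, y)
        dif = tri * (1.0 - tri / x) / special.polygamma(2, y)
        y += dif
        if abs(dif) < 1e-10 * y:
            break
    return float(y)


def fit_variance_prior(s2: np.ndarray, df: np.ndarray) -> tuple[float, float]:
    """Fit a scaled inverse-chi-square prior (d0, s0^2) to residual variances.

    Matches the first two moments of ``log s^2`` using digamma/trigamma
    identities for the log of a scaled F variate. Returns ``d0 = inf`` when
    the observed spread is no larger than expected from the residual
    degrees of freedom alone.
    """
    ok = (df > 0) & np.isfinite(s2) & (s2 > 0)
    if ok.sum() < 2:
        raise ValueError("need at least 2 positive variances with df > 0")
    s2 = s2[ok]
    df = df[ok].astype(float)
    z = np.log(s2)
    e = z - special.digamma(df / 2.0) + np.log(df / 2.0)
    e_mean = e.mean()
    n = e.size
    e_var = np.sum((e - e_mean) ** 2) / (n - 1)
    excess = e_var * (n - 1) / n - np.mean(special.polygamma(1, df / 2.0))
    if excess <= 0:
        d0 = np.inf
        s0_2 = float(np.exp(e_mean))
    else:
        d0 = 2.0 * trigamma_inverse(excess)
        s0_2 = float(np.exp(e_mean + special.digamma(d0 / 2.0) - np.log(d0 / 2.0)))
    return float(d0), s0_2


def _moderated_contrast_frame(logmat: OmicsMatrix, label: str,
                              samples: list[str], indicator: np.ndarray,
                              include_replicate: bool, min_quant: int
                              ) -> pd.DataFrame:
    groups = {"target": [s for s, ind in zip(samples, indicator) if ind],
              "baseline": [s for s, ind in zip(samples, indicator) if not ind]}
    sub = filter_valid_values(logmat.subset_samples(samples), groups,
                              min_quant=min_quant)
    X_full = _design(sub.meta, samples, indicator, include_replicate)
    Y = sub.values[samples].to_numpy(dtype=float)

    n_feat = Y.shape[0]
    betas = np.full(n_feat, np.nan)
    varc = np.full(n_feat, np.nan)
    s2 = np.full(n_feat, np.nan)
    dfs = np.zeros(n_feat)
    means = np.full(n_feat, np.nan)
    for gi in range(n_feat):
        y = Y[gi]
        ok = ~np.isnan(y)
        Xg = X_full[ok]
        keep_cols = [0, 1] + [c for c in range(2, Xg.shape[1])
                              if Xg[:, c].any() and not Xg[:, c].all()]
        Xg = Xg[:, keep_cols]
        yv = y[ok]
        rank = np.linalg.matrix_rank(Xg)
        if rank < 2 or not (0 < Xg[:, 1].sum() < Xg.shape[0]):
            continue  # group effect not estimable
        XtX_inv = np.linalg.pinv(Xg.T @ Xg)
        beta = XtX_inv @ Xg.T @ yv
        resid = yv - Xg @ beta
        d = yv.size - rank
        betas[gi] = beta[1]
        varc[gi] = XtX_inv[1, 1]
        dfs[gi] = d
        s2[gi] = resid @ resid / d if d > 0 else np.nan
        means[gi] = yv.mean()

    estim = np.isfinite(betas)
    if (dfs[estim] > 0).sum() < 2:
        raise ValueError(f"contrast {label}: fewer than 2 proteins with "
                         "positive residual df; cannot moderate")
    d0, s0_2 = fit_variance_prior(s2[estim], dfs[estim])
    s2_filled = np.where(dfs > 0, np.nan_to_num(s2, nan=s0_2), s0_2)
    if np.isinf(d0):
        s2_mod = np.full_like(s2_filled, s0_2)
        df_total = np.full_like(dfs, np.inf)
    else:
        s2_mod = (d0 * s0_2 + dfs * s2_filled) / (d0 + dfs)
        df_total = d0 + dfs
    prior_only = estim & (dfs == 0)
    if prior_only.any():
        log.warning("contrast %s: %d proteins with zero residual df use the "
                    "prior variance only", label, int(prior_only.sum()))
    with np.errstate(invalid="ignore"):
        t = betas / np.sqrt(s2_mod * varc)
    pvals = 2.0 * stats.t.sf(np.abs(t), df_total)
    frame = pd.DataFrame({
        "feature": sub.feature_ids,
        "contrast": label,
        "base_mean": means,
        "log2fc": betas,
        "se": np.sqrt(s2_mod * varc),
        "stat": t,
        "pvalue": np.where(np.isfinite(t), pvals, np.nan),
        "df_resid": dfs,
        "prior_df": d0,
        "prior_var": s0_2,
        "tested": estim,
    })
    frame["padj"] = bh_adjust(frame["pvalue"])
    return frame


def moderated_lm_de(logmat: OmicsMatrix, scheme: str = "one_vs_rest",
                    include_replicate: bool = True, min_quant: int = 1
                    ) -> pd.DataFrame:
    """Empirical-Bayes moderated linear-model DE over compartments.

    Per contrast, proteins passing the valid-value filter are fitted by OLS
    on their non-missing values (compartment indicator plus replicate
    blocking); residual variances are shrunk toward the moments-fitted prior
    and moderated t statistics use ``d0 + d_g`` degrees of freedom. Output
    format matches :func:`nb_wald_de`, with diagnostics columns ``df_resid``,
    ``prior_df`` and ``prior_var``.
    """
    frames = []
    for label, (target, baseline) in contrast_pairs(logmat.compartments, scheme):
        samples, indicator = _compartment_contrast_samples(logmat, target, baseline)
        frames.append(_moderated_contrast_frame(logmat, label, samples,
                                                indicator, include_replicate,
                                                min_quant))
    return pd.concat(frames, ignore_index=True)


def moderated_lm_fraction_de(logmat: OmicsMatrix, target: str = "P3",
                             baseline: str = "P2",
                             include_replicate: bool = True, min_quant: int = 1
                             ) -> pd.DataFrame:
    """Per-compartment sorted-vs-unsorted moderated-t DE on log2 intensities."""
    frames = []
    for label, samples, indicator in _fraction_contrasts(logmat, target, baseline):
        frames.append(_moderated_contrast_frame(logmat, label, samples,
                                                indicator, include_replicate,
                                                min_quant))
    return pd.concat(frames, ignore_index=True)


# ---------------------------------------------------------------------------
# enrichment calling
# ---------------------------------------------------------------------------

def call_enrichment(de: pd.DataFrame, scheme: str, molecule: str,
                    lfc_min: float = 0.1, alpha: float = 0.05) -> pd.DataFrame:
    """Threshold DE results into per-compartment enrichment calls.

    ``pairwise_intersection``: a feature is enriched in compartment C iff
    every ``C_vs_D`` contrast has ``padj < alpha`` and ``log2fc >= lfc_min``
    (depleted analogously with ``log2fc <= -lfc_min``). ``one_vs_rest``: the
    single ``C_vs_rest`` contrast decides. Returns columns feature, molecule,
    compartment, direction, contrasts.
    """
    if scheme not in ("pairwise_intersection", "one_vs_rest"):
        raise DesignError(f"unknown enrichment scheme {scheme!r}")
    labels = de["contrast"].unique()
    per_comp: dict[str, list[str]] = {}
    for lab in labels:
        comp = lab.split("_vs_")[0]
        per_comp.setdefault(comp, []).append(lab)
    if scheme == "pairwise_intersection":
        for comp, labs in per_comp.items():
            if len(labs) != len(per_comp) - 1:
                raise DesignError(
                    f"compartment {comp}: expected {len(per_comp) - 1} pairwise "
                    f"contrasts, found {len(labs)}")
    else:
        for comp, labs in per_comp.items():
            if labs != [f"{comp}_vs_rest"]:
                raise DesignError(f"compartment {comp}: expected single "
                                  f"one-vs-rest contrast, found {labs}")
    rows = []
    for comp, labs in per_comp.items():
        sub = de[de["contrast"].isin(labs)]
        piv_q = sub.pivot(index="feature", columns="contrast", values="padj")
        piv_fc = sub.pivot(index="feature", columns="contrast", values="log2fc")
        sig = piv_q.notna() & (piv_q < alpha)
        complete = piv_q.notna().all(axis=1)
        up = (sig & (piv_fc >= lfc_min)).all(axis=1) & complete
        down = (sig & (piv_fc <= -lfc_min)).all(axis=1) & complete
        for feat in piv_q.index[up]:
            rows.append((feat, molecule, comp, "enriched", ";".join(sorted(labs))))
        for feat in piv_q.index[down]:
            rows.append((feat, molecule, comp, "depleted", ";".join(sorted(labs))))
    calls = pd.DataFrame(rows, columns=["feature", "molecule", "compartment",
                                        "direction", "contrasts"])
    return calls.sort_values(["compartment", "direction", "feature"],
                             ignore_index=True)
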