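"""Abundance normalization: median-of-ratios size factors for counts,
robust-linear-regression (rlr) normalization for log2 intensities, and the
iBAQ transform with its in-silico Trypsin/P digest.

Size factors follow the median-of-ratios estimator used for RNA-seq count
libraries: each sample's factor is the median, over genes detected in every
sample, of the ratio of its count to the gene's geometric-mean count. The
overall scale is fixed by a unit-geometric-mean convention.

rlr normalization fits each sample's log2 intensities against the per-feature
median reference profile by Huber M-estimation and inverts the fitted affine
map, removing per-sample shift and scale effects while leaving missing cells
missing.
"""

from __future__ import annotations

import itertools
import logging

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .containers import NormalizationError, OmicsMatrix, check_protein_sequence

log = logging.getLogger("stratomics")


# ---------------------------------------------------------------------------
# median-of-ratios size factors
# ---------------------------------------------------------------------------

def median_ratio_size_factors(counts: OmicsMatrix) -> tuple[pd.Series, pd.DataFrame]:
    """Median-of-ratios size factors and the normalized count matrix.

    Returns
    -------
    (size_factors, normalized)
        ``size_factors`` is a Series over samples with geometric mean 1;
        ``normalized`` holds counts divided by their sample's factor.
    """
    K = counts.values.to_numpy(dtype=float)
    all_pos = (K > 0).all(axis=1)
    if not all_pos.any():
        raise NormalizationError("no gene with positive counts in every sample")
    logK = np.log(K[all_pos])
    log_ref = logK.mean(axis=1)  # log geometric mean per reference gene
    log_ratios = logK - log_ref[:, None]
    log_s = np.median(log_ratios, axis=0)
    log_s = log_s - log_s.mean()  # unit geometric mean convention
    s = pd.Series(np.exp(log_s), index=counts.sample_ids, name="size_factor")
    normalized = counts.values.astype(float).div(s, axis=1)
    return s, normalized


def log2_normalized_counts(counts: OmicsMatrix, pseudocount: float = 1.0
                           ) -> tuple[pd.Series, pd.DataFrame]:
    """Size factors plus log2(normalized count + pseudocount)."""
    s, norm = median_ratio_size_factors(counts)
    return s, np.log2(norm + pseudocount)


# ---------------------------------------------------------------------------
# rlr normalization of log2 intensities
# ---------------------------------------------------------------------------

def rlr_normalize(logmat: OmicsMatrix, maxiter: int = 50, tol: float = 1e-8
                  ) -> OmicsMatrix:
    """Robust-linear-regression normalization of a log2 intensity matrix.

    The reference is the per-feature median across samples
    (pairwise-complete). For each sample ``j`` the model
    ``x_gj = a_j + b_j * r_g`` is fitted by Huber M-estimation (tuning
    constant 1.345); the output is ``(x_gj - a_j) / b_j``. Missing cells stay
    missing.
    """
    X = logmat.values
    ref = X.median(axis=1, skipna=True)
    out = X.copy()
    for sample in X.columns:
        x = X[sample]
        ok = x.notna() & ref.notna()
        if ok.sum() < 3:
            raise NormalizationError(
                f"sample {sample!r}: fewer than 3 non-missing features")
        design = sm.add_constant(ref[ok].to_numpy())
        rlm = sm.RLM(x[ok].to_numpy(), design, M=sm.robust.norms.HuberT(t=1.345))
        try:
            fit = rlm.fit(maxiter=maxiter, tol=tol)
        except Exception as exc:  # pragma: no cover - statsmodels failure path
            raise NormalizationError(f"sample {sample!r}: rlr fit failed: {exc}")
        a, b = fit.params
        if not np.isfinite(b) or b <= 0:
            raise NormalizationError(
                f"sample {sample!r}: non-positive rlr slope {b!r}")
        out[sample] = (x - a) / b
    return logmat.with_values(out)


# ---------------------------------------------------------------------------
# in-silico tryptic digest and iBAQ
# ---------------------------------------------------------------------------

def count_tryptic_peptides(seq: str, min_len: int = 7, max_len: int = 35,
                           missed_cleavages: int = 0) -> int:
    """Count distinct theoretical tryptic peptides within a length window.

    Cleavage follows the Trypsin/P rule: after every K or R, including when
    the next residue is proline. With ``missed_cleavages = m``, fragments
    spanning up to ``m`` internal cleavage sites are also enumerated. Distinct
    fragment sequences with length in ``[min_len, max_len]`` are counted.
    """
    s = check_protein_sequence(seq)
    pieces: list[str] = []
    start = 0
    for i, aa in enumerate(s):
        if aa in "KR":
            pieces.append(s[start:i + 1])
            start = i + 1
    if start < len(s):
        pieces.append(s[start:])
    fragments: set[str] = set()
    for i in range(len(pieces)):
        for m in range(missed_cleavages + 1):
            if i + m >= len(pieces):
                break
            frag = "".join(pieces[i:i + m + 1])
            if min_len <= len(frag) <= max_len:
                fragments.add(frag)
    return len(fragments)


def peptide_count_table(sequences: dict[str, str], min_len: int = 7,
                        max_len: int = 35, missed_cleavages: int = 0) -> pd.Series:
    """Theoretical peptide counts for every protein in ``sequences``."""
    return pd.Series(
        {pid: count_tryptic_peptides(seq, min_len, max_len, missed_cleavages)
         for pid, seq in sequences.items()},
        name="n_peptides", dtype=int)


def ibaq_transform(intensity: OmicsMatrix, counts: pd.Series,
                   input_log2: bool = True) -> OmicsMatrix:
    """iBAQ: divide each protein's linear-scale intensity by its theoretical
    peptide count; input/output stay on the log2 scale when ``input_log2``.

    Proteins with a zero peptide count become missing (warned); proteins
    absent from ``counts`` raise a mapping error.
    """
    missing = [p for p in intensity.feature_ids if p not in counts.index]
    if missing:
        raise KeyError(f"no peptide count for proteins: {missing[:5]}")
    n = counts.loc[intensity.feature_ids].astype(float)
    zero = n == 0
    if zero.any():
        log.warning("iBAQ: %d proteins have 0 theoretical peptides; set missing",
                    int(zero.sum()))
    n = n.where(~zero)
    if input_log2:
        linear = np.power(2.0, intensity.values)
        ibaq = np.log2(linear.div(n, axis=0))
    else:
        ibaq = intensity.values.div(n, axis=0)
    return intensity.with_values(ibaq, kind="protein_ibaq")
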