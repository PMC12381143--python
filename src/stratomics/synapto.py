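"""Sorted-synaptosome contaminant filtering.

Features significantly enriched in the unsorted control fraction (P2) of any
compartment, in the sorted-vs-unsorted (P3 vs P2) differential comparison,
are compiled into a contaminant list (union over compartments, one list per
molecule type) and removed from the synaptosome matrices before any
synaptic comparison.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import pandas as pd

from .containers import OmicsMatrix

log = logging.getLogger("stratomics")


@dataclass
class ContaminantList:
    """Flagged features with the (compartment, contrast) evidence per feature."""

    molecule: str
    provenance: pd.DataFrame  # feature, contrast, log2fc, padj

    @property
    def features(self) -> frozenset[str]:
        return frozenset(self.provenance["feature"])

    def __len__(self) -> int:
        return len(self.features)


def build_contaminant_list(p3_vs_p2_de: pd.DataFrame, molecule: str,
                           alpha: float = 0.05, lfc_min: float = 0.1,
                           union_adjust: bool = True) -> ContaminantList:
    """Union over compartments of features enriched in the unsorted fraction.

    ``p3_vs_p2_de`` is a long DE table (one contrast per compartment) with
    log2 fold changes of P3 over P2; a feature is flagged when
    ``padj < alpha`` and ``log2fc <= -lfc_min`` in any compartment.

    Because the compiled list is a union of one FDR-controlled screening per
    compartment, thresholding each screening at ``alpha`` lets the
    false-listing rate of the union grow with the number of compartments.
    With ``union_adjust`` (default) each screening is thresholded at
    ``alpha / n_compartments`` instead, so ``alpha`` bounds the error of the
    compiled list rather than of each screening.
    """
    de = p3_vs_p2_de
    n_contrasts = max(de["contrast"].nunique(), 1) if len(de) else 1
    level = alpha / n_contrasts if union_adjust else alpha
    hit = de["padj"].notna() & (de["padj"] < level) & (de["log2fc"] <= -lfc_min)
    prov = de.loc[hit, ["feature", "contrast", "log2fc", "padj"]].copy()
    prov = prov.sort_values(["feature", "contrast"], ignore_index=True)
    log.info("contaminant list (%s): %d features from %d evidence records",
             molecule, prov["feature"].nunique(), len(prov))
    return ContaminantList(molecule=molecule, provenance=prov)


def apply_contaminant_filter(mat: OmicsMatrix, contaminants: ContaminantList
                             ) -> OmicsMatrix:
    """Remove listed features from all compartments, preserving order."""
    listed = contaminants.features
    keep = [f for f in mat.feature_ids if f not in listed]
    removed = len(mat.feature_ids) - len(keep)
    log.info("contaminant filter (%s): removed %d of %d features",
             contaminants.molecule, removed, len(mat.feature_ids))
    return mat.subset_features(keep)
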