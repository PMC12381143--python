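"""Core in-memory containers for abundance matrices, gene sets and reference tables.

The central object is :class:`OmicsMatrix`, a feature-by-sample abundance table
(RNA counts or log2 protein intensities) carrying per-sample metadata
(compartment, replicate, fraction). Downstream modules accept and return these
containers; plain :class:`pandas.DataFrame` objects back the numeric payloads.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

#: hippocampal subregion compartment scheme
SUBREGIONS = ("CA1", "CA23", "DG")
#: CA1 strata compartment scheme (basal dendrites, somata, proximal/distal apical)
STRATA = ("SO", "SP", "SR", "SLM")

FRACTIONS = ("tissue", "P2", "P3")

KINDS = ("rna_counts", "protein_log2", "protein_ibaq")

AA_ALPHABET = frozenset("ACDEFGHIKLMNPQRSTVWY")


class StratomicsError(Exception):
    """Base class for all package errors."""


class FormatError(StratomicsError):
    """Malformed input file."""


class ConsistencyError(StratomicsError):
    """Inputs are individually valid but mutually inconsistent."""


class DesignError(StratomicsError):
    """Invalid experimental-design specification (groups, contrasts)."""


class NormalizationError(StratomicsError):
    """Normalization could not be computed (degenerate input, non-convergence)."""


class ConfigError(StratomicsError):
    """Invalid configuration value."""


def _check_unique(ids, what: str) -> None:
    seen = pd.Index(ids)
    if seen.has_duplicates:
        dups = seen[seen.duplicated()].unique().tolist()
        raise FormatError(f"duplicate {what}: {dups[:5]}")


def compartment_scheme(compartments) -> tuple[str, ...]:
    """Return the scheme (SUBREGIONS or STRATA) the given labels belong to.

    Raises :class:`ConsistencyError` if labels mix schemes or are unknown.
    """
    comps = set(compartments)
    if comps <= set(SUBREGIONS):
        return SUBREGIONS
    if comps <= set(STRATA):
        return STRATA
    raise ConsistencyError(
        f"compartments {sorted(comps)} are not all from one scheme "
        f"({SUBREGIONS} or {STRATA})"
    )


@dataclass
class OmicsMatrix:
    """Feature x sample abundance matrix with per-sample metadata.

    Parameters
    ----------
    values
        DataFrame indexed by feature id (gene symbol), columns are sample ids.
        For ``kind='rna_counts'`` all values must be nonnegative integers with
        no missing cells; intensity kinds allow NaN (missing) cells.
    kind
        One of ``rna_counts``, ``protein_log2``, ``protein_ibaq``.
    meta
        DataFrame indexed by sample id with columns ``compartment``,
        ``replicate`` and ``fraction``; every sample column of ``values`` must
        have exactly one row.
    """

    values: pd.DataFrame
    kind: str
    meta: pd.DataFrame

    def __post_init__(self) -> None:
        if self.kind not in KINDS:
            raise ConfigError(f"unknown matrix kind {self.kind!r}")
        _check_unique(self.values.index, "feature ids")
        _check_unique(self.values.columns, "sample ids")
        missing_meta = [s for s in self.values.columns if s not in self.meta.index]
        if missing_meta:
            raise ConsistencyError(f"samples absent from metadata: {missing_meta[:5]}")
        for col in ("compartment", "replicate", "fraction"):
            if col not in self.meta.columns:
                raise FormatError(f"metadata lacks required column {col!r}")
        self.meta = self.meta.loc[list(self.values.columns)]
        compartment_scheme(self.meta["compartment"])
        bad_frac = set(self.meta["fraction"]) - set(FRACTIONS)
        if bad_frac:
            raise ConsistencyError(f"unknown fraction labels: {sorted(bad_frac)}")
        vals = self.values.to_numpy()
        if self.kind == "rna_counts":
            if np.isnan(vals.astype(float)).any():
                raise FormatError("count matrix contains missing values")
            fvals = vals.astype(float)
            if (fvals < 0).any():
                raise FormatError("count matrix contains negative values")
            if not np.allclose(fvals, np.round(fvals)):
                raise FormatError("count matrix contains non-integer values")
            self.values = self.values.astype(np.int64)
        else:
            self.values = self.values.astype(float)

    # -- convenience -------------------------------------------------------
    @property
    def feature_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def compartments(self) -> list[str]:
        """Compartment labels in scheme order, restricted to those present."""
        scheme = compartment_scheme(self.meta["compartment"])
        present = set(self.meta["compartment"])
        return [c for c in scheme if c in present]

    def samples_where(self, **conditions) -> list[str]:
        """Sample ids whose metadata matches all keyword conditions.

        Values may be scalars or collections, e.g.
        ``samples_where(compartment="SO", fraction=("P2", "P3"))``.
        """
        mask = pd.Series(True, index=self.meta.index)
        for col, val in conditions.items():
            if isinstance(val, (list, tuple, set, frozenset)):
                mask &= self.meta[col].isin(list(val))
            else:
                mask &= self.meta[col] == val
        return [s for s in self.sample_ids if mask.loc[s]]

    def subset_samples(self, sample_ids) -> "OmicsMatrix":
        ids = list(sample_ids)
        return OmicsMatrix(self.values[ids].copy(), self.kind, self.meta.loc[ids].copy())

    def subset_features(self, feature_ids) -> "OmicsMatrix":
        ids = list(feature_ids)
        return OmicsMatrix(self.values.loc[ids].copy(), self.kind, self.meta.copy())

    def with_values(self, values: pd.DataFrame, kind: str | None = None) -> "OmicsMatrix":
        """New matrix sharing this metadata with replaced numeric payload."""
        return OmicsMatrix(values, kind or self.kind, self.meta.loc[list(values.columns)].copy())

    def equals(self, other: "OmicsMatrix") -> bool:
        return (
            self.kind == other.kind
            and self.values.equals(other.values)
            and self.meta.equals(other.meta)
        )


@dataclass
class GeneSetCollection:
    """Named gene sets with free-text descriptions (GMT semantics)."""

    sets: dict[str, tuple[str, frozenset[str]]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name, (_desc, genes) in self.sets.items():
            if not genes:
                raise FormatError(f"gene set {name!r} is empty")

    def add(self, name: str, description: str, genes) -> None:
        if name in self.sets:
            raise FormatError(f"duplicate gene-set name {name!r}")
        genes = frozenset(genes)
        if not genes:
            raise FormatError(f"gene set {name!r} is empty")
        self.sets[name] = (description, genes)

    def __len__(self) -> int:
        return len(self.sets)

    def __contains__(self, name: str) -> bool:
        return name in self.sets

    def genes(self, name: str) -> frozenset[str]:
        return self.sets[name][1]

    def items(self):
        return self.sets.items()


@dataclass
class ReferenceTables:
    """External per-gene annotations used by the integration stage.

    ``half_life``: gene -> protein half-life in hours (strictly positive).
    ``translatome``: gene -> preferential translation site
    (``soma`` | ``neuropil`` | ``unbiased``).
    ``sequences``: protein id (gene symbol) -> amino-acid sequence.
    """

    half_life: pd.Series = field(default_factory=lambda: pd.Series(dtype=float))
    translatome: pd.Series = field(default_factory=lambda: pd.Series(dtype=object))
    sequences: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        hl = self.half_life.astype(float)
        if ((~np.isfinite(hl)) | (hl <= 0)).any():
            raise FormatError("half-lives must be finite and > 0")
        self.half_life = hl
        bad = set(self.translatome) - {"soma", "neuropil", "unbiased"}
        if bad:
            raise FormatError(f"unknown translatome labels: {sorted(bad)}")
        for pid, seq in self.sequences.items():
            check_protein_sequence(seq, pid)


def check_protein_sequence(seq: str, pid: str = "") -> str:
    """Validate and canonicalize an amino-acid sequence (uppercase, no '*')."""
    s = seq.upper().rstrip("*")
    bad = set(s) - AA_ALPHABET
    if bad:
        raise FormatError(f"sequence {pid!r} has non amino-acid characters: {sorted(bad)}")
    if not s:
        raise FormatError(f"sequence {pid!r} is empty")
    return s
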