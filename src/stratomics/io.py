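"""Readers and writers for the package's plain-text interchange formats.

All tables are tab-separated UTF-8 with '.' decimal separator; missing cells
are empty or "NA" on read and "NA" on write. Protein sequences travel as
FASTA, gene sets as GMT. A results bundle is a directory of TSVs plus a JSON
manifest recording configuration, seed and software version.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd
from Bio import SeqIO

from . import __version__
from .containers import (
    ConsistencyError,
    FormatError,
    GeneSetCollection,
    OmicsMatrix,
    ReferenceTables,
    check_protein_sequence,
)

log = logging.getLogger("stratomics")

NA_VALUES = ["", "NA"]
FLOAT_FMT = "%.12g"  # round-trips to 12 significant digits


def setup_logging(level: str = "INFO", logfile: str | Path | None = None) -> None:
    handlers: list[logging.Handler] = [logging.StreamHandler()]
    if logfile is not None:
        handlers.append(logging.FileHandler(logfile))
    logging.basicConfig(
        level=getattr(logging, level.upper()),
        format="%(asctime)s %(name)s %(levelname)s %(message)s",
        handlers=handlers,
        force=True,
    )


# ---------------------------------------------------------------------------
# abundance tables + sample metadata
# ---------------------------------------------------------------------------

def read_sample_meta(path: str | Path) -> pd.DataFrame:
    meta = pd.read_csv(path, sep="\t", dtype={"sample_id": str, "compartment": str,
                                              "fraction": str})
    required = {"sample_id", "compartment", "replicate", "fraction"}
    missing = required - set(meta.columns)
    if missing:
        raise FormatError(f"metadata {path} lacks columns {sorted(missing)}")
    if meta["sample_id"].duplicated().any():
        raise FormatError(f"duplicate sample_id rows in {path}")
    meta = meta.set_index("sample_id")
    meta["replicate"] = meta["replicate"].astype(int)
    if (meta["replicate"] < 1).any():
        raise FormatError("replicate numbers must be positive")
    return meta


def read_abundance_table(path: str | Path, kind: str, meta_path: str | Path) -> OmicsMatrix:
    """Read a feature x sample TSV plus its sample-metadata TSV.

    First column holds feature ids, header row holds sample ids. Empty and
    "NA" cells become missing values (rejected for ``kind='rna_counts'``).
    """
    df = pd.read_csv(path, sep="\t", index_col=0, na_values=NA_VALUES,
                     keep_default_na=False)
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    meta = read_sample_meta(meta_path)
    absent = [s for s in df.columns if s not in meta.index]
    if absent:
        raise ConsistencyError(f"samples in {path} absent from {meta_path}: {absent[:5]}")
    return OmicsMatrix(df, kind, meta)


def write_abundance_table(mat: OmicsMatrix, path: str | Path,
                          meta_path: str | Path | None = None) -> None:
    mat.values.to_csv(path, sep="\t", na_rep="NA", float_format=FLOAT_FMT,
                      index_label="feature_id")
    if meta_path is not None:
        write_sample_meta(mat.meta, meta_path)


def write_sample_meta(meta: pd.DataFrame, path: str | Path) -> None:
    meta.to_csv(path, sep="\t", index_label="sample_id")


# ---------------------------------------------------------------------------
# gene sets (GMT)
# ---------------------------------------------------------------------------

def read_gene_sets_gmt(path: str | Path) -> GeneSetCollection:
    """Read a GMT file: ``name TAB description TAB gene1 TAB gene2 ...``.

    Duplicate genes within one line are deduplicated; a line with fewer than
    three fields is a format error.
    """
    coll = GeneSetCollection()
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise FormatError(f"{path}:{lineno}: GMT line has < 3 fields")
            name, desc = fields[0], fields[1]
            genes = [g for g in fields[2:] if g]
            coll.add(name, desc, genes)
    return coll


def write_gene_sets_gmt(coll: GeneSetCollection, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for name, (desc, genes) in coll.items():
            fh.write("\t".join([name, desc, *sorted(genes)]) + "\n")


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

def read_fasta(path: str | Path) -> dict[str, str]:
    """Read protein FASTA into ``{id: sequence}``.

    The id is the first whitespace-delimited header token; wrapped lines are
    joined and uppercased; a trailing '*' terminator is stripped. Characters
    outside the 20-letter amino-acid alphabet or duplicate ids raise errors.
    """
    seqs: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seqs:
            raise FormatError(f"duplicate FASTA id {rec.id!r} in {path}")
        seqs[rec.id] = check_protein_sequence(str(rec.seq), rec.id)
    return seqs


def write_fasta(seqs: dict[str, str], path: str | Path, width: int = 60) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for pid, seq in seqs.items():
            fh.write(f">{pid}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i:i + width] + "\n")


# ---------------------------------------------------------------------------
# reference tables
# ---------------------------------------------------------------------------

def read_half_life_table(path: str | Path) -> pd.Series:
    df = pd.read_csv(path, sep="\t", na_values=NA_VALUES, keep_default_na=False)
    if not {"gene", "half_life_hours"} <= set(df.columns):
        raise FormatError(f"{path} needs columns gene, half_life_hours")
    if df["gene"].duplicated().any():
        raise FormatError(f"duplicate genes in half-life table {path}")
    return df.set_index("gene")["half_life_hours"].astype(float)


def read_translatome_table(path: str | Path) -> pd.Series:
    df = pd.read_csv(path, sep="\t", na_values=NA_VALUES, keep_default_na=False)
    if not {"gene", "translation_site"} <= set(df.columns):
        raise FormatError(f"{path} needs columns gene, translation_site")
    if df["gene"].duplicated().any():
        raise FormatError(f"duplicate genes in translatome table {path}")
    return df.set_index("gene")["translation_site"].astype(str)


def write_reference_tables(ref: ReferenceTables, outdir: str | Path) -> None:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    hl = ref.half_life.rename("half_life_hours")
    hl.to_csv(outdir / "half_life.tsv", sep="\t", index_label="gene",
              float_format=FLOAT_FMT)
    tr = ref.translatome.rename("translation_site")
    tr.to_csv(outdir / "translatome.tsv", sep="\t", index_label="gene")
    if ref.sequences:
        write_fasta(ref.sequences, outdir / "proteins.fasta")


def read_reference_tables(indir: str | Path) -> ReferenceTables:
    indir = Path(indir)
    hl = read_half_life_table(indir / "half_life.tsv")
    tr = read_translatome_table(indir / "translatome.tsv")
    fasta = indir / "proteins.fasta"
    seqs = read_fasta(fasta) if fasta.exists() else {}
    return ReferenceTables(half_life=hl, translatome=tr, sequences=seqs)


# ---------------------------------------------------------------------------
# results bundle
# ---------------------------------------------------------------------------

def write_results_bundle(results: dict[str, pd.DataFrame], outdir: str | Path,
                         config: dict | None = None, seed: int | None = None,
                         summary: dict | None = None) -> None:
    """Write one TSV per result table plus a machine-readable run manifest.

    The manifest records the configuration, the seed and the package version;
    it deliberately excludes wall-clock information so identical runs produce
    byte-identical bundles.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written = []
    for name, df in results.items():
        path = outdir / f"{name}.tsv"
        df.to_csv(path, sep="\t", na_rep="NA", float_format=FLOAT_FMT, index=False)
        written.append(path.name)
        log.info("wrote %s (%d rows)", path, len(df))
    manifest = {
        "package": "stratomics",
        "version": __version__,
        "seed": seed,
        "config": config,
        "tables": sorted(written),
    }
    if summary is not None:
        with open(outdir / "summary.json", "w", encoding="utf-8") as fh:
            json.dump(_jsonable(summary), fh, indent=2, sort_keys=True)
    with open(outdir / "manifest.json", "w", encoding="utf-8") as fh:
        json.dump(_jsonable(manifest), fh, indent=2, sort_keys=True)


def _jsonable(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return [_jsonable(v) for v in obj.tolist()]
    return obj
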