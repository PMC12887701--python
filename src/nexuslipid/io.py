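"""Plain-text readers and writers for the pipeline's interchange formats.

Formats:
    summary stats   TSV ``snp chr pos ea oa eaf beta se pval n`` (pos 1-based)
    LD matrix       square TSV of r^2 values, SNP ids as header/index
    expression      genes x samples TSV; labels as two-column sample/label TSV
    chem edges      TSV ``chemical_name chemical_id gene_symbol action``
    gene annotation BED4 ``chr start end gene`` (0-based half-open)
    gene sets       GMT ``name<TAB>description<TAB>gene...``
    truth           JSON
"""

from __future__ import annotations

import json
import logging
import warnings
from pathlib import Path

import pandas as pd

log = logging.getLogger(__name__)

SUMSTAT_COLUMNS = ["snp", "chr", "pos", "ea", "oa", "eaf", "beta", "se", "pval", "n"]


def write_sumstats(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index=False, columns=SUMSTAT_COLUMNS)


def read_sumstats(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"chr": str})
    missing = [c for c in SUMSTAT_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"summary-statistics file {path} lacks columns: {missing}")
    return df


def write_ld(ld: pd.DataFrame, path: str | Path) -> None:
    ld.to_csv(path, sep="\t", index=True, index_label="snp")


def read_ld(path: str | Path) -> pd.DataFrame:
    ld = pd.read_csv(path, sep="\t", index_col=0)
    ld.index.name = "snp"
    return ld


def write_expression(matrix: pd.DataFrame, labels: pd.Series, prefix: str | Path) -> None:
    """Write ``<prefix>.expr.tsv`` (genes x samples) and ``<prefix>.labels.tsv``."""
    prefix = Path(prefix)
    matrix.to_csv(prefix.with_suffix(".expr.tsv"), sep="\t", index_label="gene")
    labels.rename("label").to_frame().to_csv(
        prefix.with_suffix(".labels.tsv"), sep="\t", index_label="sample"
    )


def read_expression(prefix: str | Path) -> tuple[pd.DataFrame, pd.Series]:
    prefix = Path(prefix)
    matrix = pd.read_csv(prefix.with_suffix(".expr.tsv"), sep="\t", index_col=0)
    labels = pd.read_csv(prefix.with_suffix(".labels.tsv"), sep="\t", index_col=0)["label"]
    return matrix, labels


def write_chem_edges(edges: pd.DataFrame, path: str | Path) -> None:
    edges.to_csv(path, sep="\t", index=False,
                 columns=["chemical_name", "chemical_id", "gene_symbol", "action"])


def read_chem_edges(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    # tolerate raw CTD-style export headers
    renames = {"ChemicalName": "chemical_name", "ChemicalID": "chemical_id",
               "GeneSymbol": "gene_symbol", "InteractionActions": "action"}
    df = df.rename(columns=renames)
    required = ["chemical_name", "chemical_id", "gene_symbol", "action"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"chemical-gene edge file {path} lacks columns: {missing}")
    return df


def read_bed(path: str | Path) -> pd.DataFrame:
    """Read BED4 annotation (chr, start, end, gene), 0-based half-open."""
    df = pd.read_csv(path, sep="\t", header=None,
                     names=["chr", "start", "end", "gene"], dtype={"chr": str})
    bad = df[df["start"] >= df["end"]]
    if len(bad):
        raise ValueError(f"BED rows with start >= end in {path}: {bad['gene'].tolist()}")
    return df


def write_bed(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index=False, header=False,
              columns=["chr", "start", "end", "gene"])


def load_gmt(path: str | Path) -> list["GeneSet"]:
    """Parse a GMT gene-set file into GeneSet records.

    Duplicate genes within a line are deduplicated with a warning; a
    malformed line (fewer than three fields) raises with its line number.
    """
    from .enrichment import GeneSet

    sets: list[GeneSet] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"{path}:{lineno}: malformed GMT line "
                                 f"(expected name, description, >=1 gene)")
            name, description = fields[0], fields[1]
            genes = [g for g in fields[2:] if g]
            unique = list(dict.fromkeys(genes))
            if len(unique) < len(genes):
                warnings.warn(f"{path}:{lineno}: duplicate genes in set {name!r} deduplicated")
            sets.append(GeneSet(name=name, domain=description, members=frozenset(unique)))
    if not sets:
        warnings.warn(f"{path}: empty GMT file")
    return sets


def write_gmt(sets, path: str | Path) -> None:
    with open(path, "w") as fh:
        for s in sets:
            fh.write("\t".join([s.name, s.domain] + sorted(s.members)) + "\n")


def write_json(obj, path: str | Path) -> None:
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True)
        fh.write("\n")


def read_json(path: str | Path):
    with open(path) as fh:
        return json.load(fh)
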