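"""Tabular input/output and gene-level annotation joins.

The pipeline's universal input is a genes x samples FPKM matrix with a
sample design (group labels) attached.  Everything is plain TSV so that
each stage's output can be reloaded by the next stage or inspected by
hand.  Gene identity is by plain symbol, case-sensitive exact match; no
synonym or ortholog mapping is attempted.
"""

from __future__ import annotations

import importlib.resources
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: Controlled vocabulary of behavior/neurological-phenotype terms.
BEHAVIOR_TERMS = (
    "abnormal aggression-related behavior",
    "increased aggression",
    "abnormal anxiety-related response",
    "abnormal fear-related response",
    "abnormal response to social novelty",
    "learning or memory",
    "abnormal learning/memory/conditioning",
)


class PlsrankError(Exception):
    """Base class for errors raised by this package."""


class FormatError(PlsrankError):
    """A file does not conform to the expected tabular dialect."""


class DesignError(PlsrankError):
    """Sample design is inconsistent with the expression matrix."""


class ConfigurationError(PlsrankError):
    """Invalid configuration values."""


@dataclass
class ExpressionMatrix:
    """Genes x samples FPKM values with the sample design attached.

    Parameters
    ----------
    values : pandas.DataFrame
        Non-negative FPKM values, index = gene symbols, columns = sample
        IDs.  Both must be unique.
    design : pandas.Series
        Maps sample ID -> group label for every sample in ``values``.
    """

    values: pd.DataFrame
    design: pd.Series

    def __post_init__(self) -> None:
        dup_genes = self.values.index[self.values.index.duplicated()].unique()
        if len(dup_genes):
            raise FormatError(f"duplicate gene IDs: {', '.join(map(str, dup_genes))}")
        dup_samples = self.values.columns[self.values.columns.duplicated()].unique()
        if len(dup_samples):
            raise FormatError(
                f"duplicate sample IDs: {', '.join(map(str, dup_samples))}"
            )
        missing = [s for s in self.values.columns if s not in self.design.index]
        if missing:
            raise DesignError(
                f"samples missing from design: {', '.join(map(str, missing))}"
            )
        if (self.values.to_numpy() < 0).any():
            raise FormatError("FPKM values must be non-negative")
        # keep design restricted to and ordered like the matrix columns
        self.design = self.design.loc[self.values.columns]

    @property
    def gene_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def groups(self) -> list[str]:
        """Group labels in order of first appearance in the design."""
        return list(dict.fromkeys(self.design))

    def samples_in(self, *groups: str) -> list[str]:
        """Sample IDs belonging to the given groups, matrix order."""
        for g in groups:
            if g not in set(self.design):
                raise DesignError(f"group {g!r} not present in design")
        return [s for s in self.sample_ids if self.design[s] in groups]

    def subset(self, *groups: str) -> "ExpressionMatrix":
        cols = self.samples_in(*groups)
        return ExpressionMatrix(self.values[cols], self.design.loc[cols])


@dataclass
class GeneSetCollection:
    """Named, non-empty sets of gene symbols with optional descriptions."""

    sets: dict[str, set[str]]
    descriptions: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name, members in self.sets.items():
            if not members:
                raise FormatError(f"gene set {name!r} is empty")

    def __len__(self) -> int:
        return len(self.sets)

    def __getitem__(self, name: str) -> set[str]:
        return self.sets[name]


def read_expression(matrix_path, design_path) -> ExpressionMatrix:
    """Read a TSV expression matrix plus its design table.

    The matrix has a header row of sample IDs and the gene symbol in the
    first column; the design file has columns ``sample_id`` and ``group``.
    """
    values = pd.read_csv(matrix_path, sep="\t", index_col=0)
    values.index = values.index.astype(str)
    design_df = pd.read_csv(design_path, sep="\t", dtype=str)
    if not {"sample_id", "group"}.issubset(design_df.columns):
        raise FormatError(
            f"{design_path}: design file needs 'sample_id' and 'group' columns"
        )
    dup = design_df["sample_id"][design_df["sample_id"].duplicated()].unique()
    if len(dup):
        raise FormatError(f"duplicate sample IDs in design: {', '.join(dup)}")
    design = design_df.set_index("sample_id")["group"]
    return ExpressionMatrix(values, design)


def write_expression(matrix: ExpressionMatrix, matrix_path, design_path) -> None:
    df = matrix.values.copy()
    df.index.name = "gene_id"
    df.to_csv(matrix_path, sep="\t")
    design = matrix.design.rename("group")
    design.index.name = "sample_id"
    design.to_frame().to_csv(design_path, sep="\t")


def load_gene_sets(gmt_path) -> GeneSetCollection:
    """Load a GMT file: per line, name TAB description TAB members..."""
    sets: dict[str, set[str]] = {}
    descriptions: dict[str, str] = {}
    with open(gmt_path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise FormatError(
                    f"{gmt_path}:{lineno}: expected name, description and at "
                    f"least one member, got {len(fields)} field(s)"
                )
            name, description = fields[0], fields[1]
            if name in sets:
                raise FormatError(f"{gmt_path}:{lineno}: duplicate set name {name!r}")
            members = {g for g in fields[2:] if g}
            if not members:
                raise FormatError(f"{gmt_path}:{lineno}: set {name!r} has no members")
            sets[name] = members
            descriptions[name] = description
    return GeneSetCollection(sets, descriptions)


def write_gene_sets(collection: GeneSetCollection, gmt_path) -> None:
    with open(gmt_path, "w") as fh:
        for name, members in collection.sets.items():
            desc = collection.descriptions.get(name, "")
            fh.write("\t".join([name, desc, *sorted(members)]) + "\n")


def read_annotation(path) -> pd.DataFrame:
    """Read a gene annotation table.

    Columns: ``gene_id``, ``is_neurogenesis``, ``is_tf``,
    ``behavior_terms`` (pipe-delimited, possibly empty).  Term labels are
    validated against the controlled vocabulary.
    """
    df = pd.read_csv(path, sep="\t", dtype=str, na_filter=False)
    required = {"gene_id", "is_neurogenesis", "is_tf", "behavior_terms"}
    if not required.issubset(df.columns):
        raise FormatError(f"{path}: annotation needs columns {sorted(required)}")
    dup = df["gene_id"][df["gene_id"].duplicated()].unique()
    if len(dup):
        raise FormatError(f"duplicate gene IDs in annotation: {', '.join(dup)}")
    out = pd.DataFrame(
        {
            "gene_id": df["gene_id"],
            "is_neurogenesis": df["is_neurogenesis"].astype(int).astype(bool),
            "is_tf": df["is_tf"].astype(int).astype(bool),
            "behavior_terms": [
                frozenset(t for t in terms.split("|") if t)
                for terms in df["behavior_terms"]
            ],
        }
    ).set_index("gene_id")
    bad = sorted(set().union(*out["behavior_terms"]) - set(BEHAVIOR_TERMS))
    if bad:
        raise FormatError(f"{path}: unknown behavior terms: {', '.join(bad)}")
    return out


def write_annotation(annotation: pd.DataFrame, path) -> None:
    df = pd.DataFrame(
        {
            "gene_id": annotation.index,
            "is_neurogenesis": annotation["is_neurogenesis"].astype(int).to_numpy(),
            "is_tf": annotation["is_tf"].astype(int).to_numpy(),
            "behavior_terms": [
                "|".join(sorted(t)) for t in annotation["behavior_terms"]
            ],
        }
    )
    df.to_csv(path, sep="\t", index=False)


def load_curated_annotation() -> pd.DataFrame:
    """Packaged annotation of key mouse hippocampal genes.

    A small curated table of neurogenesis membership, transcription-factor
    status and behavior/neurological-phenotype terms for the genes this
    pipeline treats as worked examples (Nr1d1, Fmr1, Pten, ...).  Live
    database retrieval (MANGO, Rat Genome Database, TF atlas) is out of
    scope; this is a static snapshot restricted to those genes.
    """
    ref = importlib.resources.files("plsrank.data") / "curated_annotation.tsv"
    with importlib.resources.as_file(ref) as path:
        return read_annotation(path)


def annotate(genes, annotation: pd.DataFrame) -> pd.DataFrame:
    """Total left join of an annotation table onto a gene list.

    Genes absent from the annotation get all-false flags and an empty
    term set; the output has exactly one row per input gene, in input
    order.
    """
    genes = list(genes)
    out = pd.DataFrame(
        {
            "is_neurogenesis": False,
            "is_tf": False,
            "behavior_terms": [frozenset()] * len(genes),
        },
        index=pd.Index(genes, name="gene_id"),
    )
    present = [g for g in genes if g in annotation.index]
    if present:
        out.loc[present, ["is_neurogenesis", "is_tf"]] = annotation.loc[
            present, ["is_neurogenesis", "is_tf"]
        ]
        out.loc[present, "behavior_terms"] = annotation.loc[present, "behavior_terms"]
    return out
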