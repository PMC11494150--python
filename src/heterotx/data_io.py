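"""Readers, writers and design validation for trio expression experiments.

On-disk formats
---------------
* counts: wide TSV, first column ``gene_id``, remaining columns one per
  sample (integer read counts, HTSeq-count style); one file may hold any
  number of trios, distinguished only through the sample sheet;
* sample sheet: TSV with columns ``sample_id, trio_id, role, condition,
  replicate`` (extra columns such as ``genotype_id`` are carried through);
* gene lengths: GTF (1-based closed intervals; union-exon length per gene);
* phenotypes: long TSV with ``trait, genotype_id, condition, replicate,
  value``;
* annotations: GMT (term id, description, then tab-separated gene ids);
* gene sets: two-column TSV ``set_name, gene_id`` with an optional JSON
  sidecar carrying direction and provenance.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .response_sets import GeneSet, ResponseSets

__all__ = [
    "CONDITIONS",
    "ROLES",
    "SampleSheet",
    "TrioExpressionSet",
    "AnnotationMap",
    "read_sample_sheet",
    "read_counts",
    "read_phenotypes",
    "write_phenotypes",
    "gene_lengths_from_gtf",
    "read_gmt",
    "write_gmt",
    "write_gene_sets",
    "read_gene_sets",
]

CONDITIONS = ("WW", "WD", "RW")
ROLES = ("hybrid", "parent1", "parent2")
SHEET_COLUMNS = ["sample_id", "trio_id", "role", "condition", "replicate"]


class DesignError(ValueError):
    """Raised when data and sample sheet disagree or the design is invalid."""


@dataclass
class SampleSheet:
    """Experimental design: one row per RNA-seq library.

    Each trio comprises one hybrid (F1) and two parental inbred lines
    grown under up to three watering conditions (WW = well-watered,
    WD = water deficit, RW = re-watered) with replicated libraries.
    """

    df: pd.DataFrame

    def __post_init__(self):
        df = self.df
        missing = [c for c in SHEET_COLUMNS if c not in df.columns]
        if missing:
            raise DesignError(f"sample sheet missing columns: {missing}")
        if df["sample_id"].duplicated().any():
            dupes = df.loc[df["sample_id"].duplicated(), "sample_id"].tolist()
            raise DesignError(f"duplicate sample_ids: {dupes}")
        bad_role = set(df["role"]) - set(ROLES)
        if bad_role:
            raise DesignError(f"unknown roles: {sorted(bad_role)}")
        bad_cond = set(df["condition"]) - set(CONDITIONS)
        if bad_cond:
            raise DesignError(f"unknown conditions: {sorted(bad_cond)}")
        reps = pd.to_numeric(df["replicate"], errors="coerce")
        if reps.isna().any() or (reps < 1).any() or (reps % 1 != 0).any():
            raise DesignError("replicate must be a positive integer")
        self.df = df.reset_index(drop=True)
        for trio, sub in self.df.groupby("trio_id"):
            if set(sub["role"]) != set(ROLES):
                raise DesignError(
                    f"trio {trio!r} must have exactly one hybrid and two "
                    f"parent roles, found {sorted(set(sub['role']))}")

    @property
    def sample_ids(self) -> list:
        return self.df["sample_id"].tolist()

    def trios(self) -> list:
        return sorted(self.df["trio_id"].unique())

    def conditions(self) -> list:
        return [c for c in CONDITIONS if c in set(self.df["condition"])]

    def samples(self, trio_id: str, role: str, condition: str) -> list:
        """Sample ids of one design cell, in replicate order."""
        sub = self.df[(self.df["trio_id"] == trio_id)
                      & (self.df["role"] == role)
                      & (self.df["condition"] == condition)]
        return sub.sort_values("replicate")["sample_id"].tolist()

    def label(self, trio_id: str, role: str) -> str:
        """Human-readable genotype label for a (trio, role) cell."""
        sub = self.df[(self.df["trio_id"] == trio_id) & (self.df["role"] == role)]
        if "genotype_id" in sub.columns and sub["genotype_id"].nunique() == 1:
            return str(sub["genotype_id"].iloc[0])
        return f"{trio_id}.{role}"


@dataclass
class TrioExpressionSet:
    """Count (and optionally FPKM) matrix bound to a validated design.

    ``counts`` is genes x samples with columns in sample-sheet order;
    ``fpkm`` (same shape) is present only when ``gene_lengths`` was
    supplied.
    """

    counts: pd.DataFrame
    sheet: SampleSheet
    fpkm: pd.DataFrame | None = None
    gene_lengths: pd.Series | None = None

    def __post_init__(self):
        if self.counts.index.duplicated().any():
            dupes = self.counts.index[self.counts.index.duplicated()]
            raise DesignError(f"duplicate gene_ids: {list(dupes)[:5]}")
        values = self.counts.to_numpy()
        if not np.issubdtype(values.dtype, np.number):
            raise DesignError("counts must be numeric")
        if np.any(values < 0) or np.any(np.mod(values, 1) != 0):
            raise DesignError("counts must be non-negative integers")
        sheet_ids = self.sheet.sample_ids
        if list(self.counts.columns) != sheet_ids:
            missing = set(sheet_ids) - set(self.counts.columns)
            if missing:
                raise DesignError(
                    f"sheet names samples absent from matrix: {sorted(missing)}")
            # silent reordering is forbidden: align explicitly to sheet order
            self.counts = self.counts.loc[:, sheet_ids]
        if self.fpkm is not None and self.gene_lengths is None:
            raise DesignError("fpkm requires gene_lengths")
        if self.fpkm is not None and self.fpkm.shape != self.counts.shape:
            raise DesignError("fpkm shape must match counts")

    @property
    def gene_ids(self) -> pd.Index:
        return self.counts.index

    @property
    def n_genes(self) -> int:
        return self.counts.shape[0]

    def cell_counts(self, trio_id: str, role: str, condition: str) -> pd.DataFrame:
        """Raw counts of one design cell (genes x replicates)."""
        return self.counts[self.sheet.samples(trio_id, role, condition)]


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------

def read_sample_sheet(path) -> SampleSheet:
    return SampleSheet(pd.read_csv(path, sep="\t", dtype={"sample_id": str}))


def read_counts(path, sheet_path) -> TrioExpressionSet:
    """Load a counts TSV plus sample sheet into a validated expression set.

    Raises :class:`DesignError` on non-integer counts, duplicate gene ids,
    samples named in the sheet but absent from the matrix, or a trio with a
    missing role.  Matrix columns not named in the sheet are dropped.
    """
    sheet = read_sample_sheet(sheet_path)
    mat = pd.read_csv(path, sep="\t", index_col=0)
    extra = [c for c in mat.columns if c not in set(sheet.sample_ids)]
    if extra:
        mat = mat.drop(columns=extra)
    return TrioExpressionSet(counts=mat, sheet=sheet)


def write_counts(eset: TrioExpressionSet, counts_path, sheet_path) -> None:
    eset.counts.rename_axis("gene_id").to_csv(counts_path, sep="\t")
    eset.sheet.df.to_csv(sheet_path, sep="\t", index=False)


PHENO_COLUMNS = ["trait", "genotype_id", "condition", "replicate", "value"]


def read_phenotypes(path) -> pd.DataFrame:
    """Long-format phenotype table; values must be positive reals.

    Missing replicate values are rejected rather than imputed — the
    downstream heterosis t-tests require real replication.
    """
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in PHENO_COLUMNS if c not in df.columns]
    if missing:
        raise DesignError(f"phenotype table missing columns: {missing}")
    if df["value"].isna().any():
        raise DesignError("phenotype table contains missing values")
    if (df["value"] <= 0).any():
        raise DesignError("phenotype values must be > 0")
    return df[PHENO_COLUMNS + [c for c in df.columns if c not in PHENO_COLUMNS]]


def write_phenotypes(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# GTF union-exon gene lengths
# ---------------------------------------------------------------------------

_GENE_ID_RE = re.compile(r'gene_id\s+"([^"]+)"')


def gene_lengths_from_gtf(path) -> pd.Series:
    """Per-gene union-exon length (bp) from a GTF file.

    GTF intervals are 1-based closed; they are converted to 0-based
    half-open before the interval-union sweep, so overlapping and abutting
    exons are merged and each base is counted once.
    """
    exons: dict = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 9:
                raise ValueError(f"malformed GTF line {lineno}: "
                                 f"expected 9 tab-separated fields")
            if fields[2] != "exon":
                continue
            try:
                start, end = int(fields[3]), int(fields[4])
            except ValueError as exc:
                raise ValueError(f"malformed GTF line {lineno}: "
                                 f"non-integer coordinates") from exc
            if end < start:
                raise ValueError(f"malformed GTF line {lineno}: end < start")
            m = _GENE_ID_RE.search(fields[8])
            if m is None:
                raise ValueError(f"malformed GTF line {lineno}: no gene_id")
            # key on (gene, chrom, strand); 0-based half-open
            exons.setdefault((m.group(1), fields[0], fields[6]), []).append(
                (start - 1, end))
    if not exons:
        raise ValueError("GTF contains no exon features")
    lengths: dict = {}
    for (gene, _chrom, _strand), ivals in exons.items():
        ivals.sort()
        total, cur_start, cur_end = 0, *ivals[0]
        for s, e in ivals[1:]:
            if s <= cur_end:
                cur_end = max(cur_end, e)
            else:
                total += cur_end - cur_start
                cur_start, cur_end = s, e
        total += cur_end - cur_start
        lengths[gene] = lengths.get(gene, 0) + total
    return pd.Series(lengths, name="length").astype(int)


# ---------------------------------------------------------------------------
# annotations (GMT) and gene sets
# ---------------------------------------------------------------------------

@dataclass
class AnnotationMap:
    """term_id -> (term_name, gene set); no term may be empty."""

    terms: dict = field(default_factory=dict)

    def __post_init__(self):
        for tid, (_name, genes) in self.terms.items():
            if not genes:
                raise ValueError(f"term {tid!r} has an empty gene set")

    def add(self, term_id: str, term_name: str, genes) -> None:
        genes = frozenset(genes)
        if not genes:
            raise ValueError(f"term {term_id!r} has an empty gene set")
        self.terms[term_id] = (term_name, genes)

    def __len__(self) -> int:
        return len(self.terms)

    def items(self):
        return self.terms.items()


def read_gmt(path) -> AnnotationMap:
    amap = AnnotationMap()
    with open(path) as fh:
        for line in fh:
            if not line.strip():
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 3:
                raise ValueError(f"GMT line with no genes: {parts[0]!r}")
            amap.add(parts[0], parts[1], parts[2:])
    return amap


def write_gmt(amap: AnnotationMap, path) -> None:
    with open(path, "w") as fh:
        for tid, (name, genes) in amap.items():
            fh.write("\t".join([tid, name, *sorted(genes)]) + "\n")


def write_gene_sets(rs: ResponseSets, path, meta_path=None) -> None:
    """Write sets as two-column TSV; an optional JSON sidecar records
    direction and provenance (and preserves empty sets)."""
    rows = [(name, gene) for name, gs in rs.sets.items()
            for gene in sorted(gs.genes)]
    pd.DataFrame(rows, columns=["set_name", "gene_id"]).to_csv(
        path, sep="\t", index=False)
    if meta_path is not None:
        meta = {name: {"direction": gs.direction,
                       "provenance": list(gs.provenance)}
                for name, gs in rs.sets.items()}
        Path(meta_path).write_text(json.dumps(meta, indent=1))


def read_gene_sets(path, meta_path=None) -> ResponseSets:
    df = pd.read_csv(path, sep="\t", dtype=str)
    if list(df.columns) != ["set_name", "gene_id"]:
        raise ValueError("gene-set TSV must have columns set_name, gene_id")
    members: dict = {name: frozenset(sub["gene_id"])
                     for name, sub in df.groupby("set_name")}
    rs = ResponseSets()
    if meta_path is None:
        for name in sorted(members):
            rs.add(GeneSet(name, "both", members[name], ("leaf", "file")))
        return rs
    meta = json.loads(Path(meta_path).read_text())
    unknown = set(members) - set(meta)
    if unknown:
        raise ValueError(f"sets absent from sidecar schema: {sorted(unknown)}")
    for name, info in meta.items():
        rs.add(GeneSet(name, info["direction"],
                       members.get(name, frozenset()),
                       tuple(info["provenance"])))
    return rs
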