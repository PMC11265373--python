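"""Readers, writers, and the shared data model.

All genomic coordinates are converted once, on load, to 0-based half-open
intervals; writers restore each format's native convention (GFF3 is 1-based
inclusive).  Loaders reject structural violations outright — every error
names the file, the line where known, and the offending identifier — rather
than silently repairing input.

Tabular dialects
----------------
BGC table (TSV, one row per gene, gene order = row order within a bgc_id):
    bgc_id  genome_id  contig_id  start  end  bgc_class  gene_id
    function_label  is_backbone  protein_sequence
Orthology summary (two TSVs):
    totals: genome_id  total_proteins
    pairs:  genome_i  genome_j  shared_i  shared_j
        shared_i = number of genome_i proteins in orthogroups shared with j.
Presence/absence matrix: strains as rows, families as columns, cells in {0,1}.
Strain metadata: strain_id  genus  agriculture.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .tree import Phylogeny

__all__ = [
    "Assembly",
    "GeneRecord",
    "GeneAnnotation",
    "BgcGene",
    "BgcRecord",
    "OrthologySummary",
    "StrainMetadata",
    "read_fasta",
    "write_fasta",
    "read_gff3",
    "write_gff3",
    "read_newick",
    "write_newick",
    "read_bgc_table",
    "write_bgc_table",
    "read_orthology",
    "write_orthology",
    "read_metadata",
    "read_presence_absence",
    "write_presence_absence",
    "DEFAULT_CLASS_MAP",
    "BGC_CLASSES",
]

DNA_ALPHABET = set("ACGTN")

BGC_CLASSES = ("NRPS", "PKS", "terpene", "hybrid", "betalactone", "other")

#: antiSMASH-style product labels mapped onto the six-way class vocabulary.
DEFAULT_CLASS_MAP = {
    "nrps": "NRPS",
    "nrps-like": "NRPS",
    "pks": "PKS",
    "t1pks": "PKS",
    "t2pks": "PKS",
    "t3pks": "PKS",
    "hglks": "PKS",
    "pks-like": "PKS",
    "terpene": "terpene",
    "terpenoid": "terpene",
    "hybrid": "hybrid",
    "nrps-t1pks": "hybrid",
    "t1pks-nrps": "hybrid",
    "indole": "other",
    "betalactone": "betalactone",
    "ripp": "other",
    "siderophore": "other",
    "other": "other",
}


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass
class Assembly:
    """A genome assembly: ordered contigs of uppercase DNA over {A,C,G,T,N}."""

    genome_id: str
    contigs: dict[str, str]  # insertion-ordered

    def __post_init__(self) -> None:
        for cid, seq in self.contigs.items():
            if not seq:
                raise ValueError(f"assembly {self.genome_id}: contig {cid} is empty")

    @property
    def total_length(self) -> int:
        return sum(len(s) for s in self.contigs.values())


@dataclass(frozen=True)
class GeneRecord:
    contig_id: str
    start: int  # 0-based half-open
    end: int
    strand: str
    gene_id: str
    product_label: str = ""


@dataclass
class GeneAnnotation:
    genome_id: str
    records: list[GeneRecord]

    def by_contig(self) -> dict[str, list[GeneRecord]]:
        out: dict[str, list[GeneRecord]] = {}
        for rec in self.records:
            out.setdefault(rec.contig_id, []).append(rec)
        return out


@dataclass(frozen=True)
class BgcGene:
    gene_id: str
    function_label: str
    is_backbone: bool
    protein_sequence: str = ""


@dataclass
class BgcRecord:
    """One biosynthetic gene cluster region; genes ordered by genomic position."""

    bgc_id: str
    genome_id: str
    contig_id: str
    start: int  # 0-based half-open
    end: int
    bgc_class: str
    genes: list[BgcGene]
    has_proteins: bool = True

    def __post_init__(self) -> None:
        if not self.genes:
            raise ValueError(f"BGC {self.bgc_id}: zero genes")
        if self.bgc_class not in BGC_CLASSES:
            raise ValueError(f"BGC {self.bgc_id}: unknown class {self.bgc_class!r}")
        self.has_proteins = all(g.protein_sequence for g in self.genes)

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def function_labels(self) -> frozenset[str]:
        return frozenset(g.function_label for g in self.genes)

    @property
    def adjacency_pairs(self) -> frozenset[frozenset[str]]:
        """Orientation-insensitive adjacent function-label pairs."""
        return frozenset(
            frozenset((a.function_label, b.function_label))
            for a, b in zip(self.genes, self.genes[1:])
        )


@dataclass
class OrthologySummary:
    """Per-genome protein totals plus directional shared counts per pair.

    ``shared[(i, j)]`` is the number of genome-i proteins assigned to
    orthogroups that contain both genome i and genome j.
    """

    genome_ids: list[str]
    totals: dict[str, int]
    shared: dict[tuple[str, str], int]

    def __post_init__(self) -> None:
        for g in self.genome_ids:
            if g not in self.totals:
                raise ValueError(f"orthology summary: no total for genome {g}")
            if self.totals[g] <= 0:
                raise ValueError(f"orthology summary: non-positive total for {g}")
        for i in self.genome_ids:
            for j in self.genome_ids:
                if i == j:
                    continue
                if (i, j) not in self.shared:
                    raise ValueError(f"orthology summary: missing pair ({i}, {j})")
                c = self.shared[(i, j)]
                if c < 0 or c > self.totals[i]:
                    raise ValueError(
                        f"orthology summary: shared count {c} for ({i}, {j}) "
                        f"outside [0, {self.totals[i]}]"
                    )


@dataclass
class StrainMetadata:
    """strain_id -> (genus_label, agriculture_label)."""

    table: pd.DataFrame  # index strain_id, columns genus, agriculture

    def __post_init__(self) -> None:
        missing = {"genus", "agriculture"} - set(self.table.columns)
        if missing:
            raise ValueError(f"metadata missing columns: {sorted(missing)}")
        if self.table.index.duplicated().any():
            raise ValueError("metadata: duplicate strain ids")

    def genus(self, strain: str) -> str:
        return str(self.table.loc[strain, "genus"])

    def agriculture(self, strain: str) -> str:
        return str(self.table.loc[strain, "agriculture"])


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

def read_fasta(path: str | Path, genome_id: str | None = None) -> Assembly:
    """Load a DNA FASTA; sequences are uppercased and validated over {A,C,G,T,N}."""
    path = Path(path)
    contigs: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in contigs:
            raise ValueError(f"{path}: duplicate contig id {rec.id!r}")
        seq = str(rec.seq).upper()
        bad = set(seq) - DNA_ALPHABET
        if bad:
            raise ValueError(
                f"{path}: contig {rec.id!r} has non-DNA characters {sorted(bad)}"
            )
        contigs[rec.id] = seq
    if not contigs:
        raise ValueError(f"{path}: no FASTA records")
    return Assembly(genome_id=genome_id or path.stem, contigs=contigs)


def write_fasta(assembly: Assembly, path: str | Path, width: int = 60) -> None:
    records = [
        SeqRecord(Seq(seq), id=cid, description="")
        for cid, seq in assembly.contigs.items()
    ]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width)
        writer.write_file(records)


# ---------------------------------------------------------------------------
# GFF3
# ---------------------------------------------------------------------------

def _gff_attr(attrs: str, key: str) -> str | None:
    for part in attrs.strip().split(";"):
        if "=" in part:
            k, v = part.split("=", 1)
            if k.strip() == key:
                return v.strip()
    return None


def read_gff3(
    path: str | Path,
    genome_id: str | None = None,
    feature_type: str = "gene",
) -> GeneAnnotation:
    """Load gene (or, via ``feature_type``, mRNA) features from a GFF3 file.

    Coordinates are converted from GFF3's 1-based inclusive convention to
    0-based half-open on load.
    """
    path = Path(path)
    records: list[GeneRecord] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            cols = line.split("\t")
            if len(cols) != 9:
                raise ValueError(
                    f"{path}:{lineno}: expected 9 tab-separated columns, got {len(cols)}"
                )
            contig, _src, ftype, start, end, _score, strand, _phase, attrs = cols
            if ftype != feature_type:
                continue
            try:
                s1, e1 = int(start), int(end)
            except ValueError:
                raise ValueError(f"{path}:{lineno}: non-integer coordinates") from None
            if s1 > e1:
                raise ValueError(f"{path}:{lineno}: start {s1} > end {e1}")
            if strand not in {"+", "-"}:
                raise ValueError(f"{path}:{lineno}: unknown strand {strand!r}")
            gid = _gff_attr(attrs, "ID") or f"{contig}:{s1}-{e1}"
            records.append(
                GeneRecord(
                    contig_id=contig,
                    start=s1 - 1,
                    end=e1,
                    strand=strand,
                    gene_id=gid,
                    product_label=_gff_attr(attrs, "product") or "",
                )
            )
    return GeneAnnotation(genome_id=genome_id or path.stem, records=records)


def write_gff3(annotation: GeneAnnotation, path: str | Path, feature_type: str = "gene") -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for rec in annotation.records:
            attrs = f"ID={rec.gene_id}"
            if rec.product_label:
                attrs += f";product={rec.product_label}"
            fh.write(
                "\t".join(
                    [
                        rec.contig_id,
                        "symbiomet",
                        feature_type,
                        str(rec.start + 1),
                        str(rec.end),
                        ".",
                        rec.strand,
                        ".",
                        attrs,
                    ]
                )
                + "\n"
            )


# ---------------------------------------------------------------------------
# Newick
# ---------------------------------------------------------------------------

def read_newick(path: str | Path, default_length: float = 1.0) -> Phylogeny:
    text = Path(path).read_text()
    return Phylogeny.from_newick(text, default_length=default_length)


def write_newick(tree: Phylogeny, path: str | Path) -> None:
    Path(path).write_text(tree.to_newick() + "\n")


# ---------------------------------------------------------------------------
# BGC table
# ---------------------------------------------------------------------------

_BGC_COLUMNS = [
    "bgc_id", "genome_id", "contig_id", "start", "end", "bgc_class",
    "gene_id", "function_label", "is_backbone", "protein_sequence",
]


def normalise_bgc_class(raw: str, class_map: dict[str, str] | None = None) -> str:
    """Map free-text region products onto the six-way class vocabulary."""
    mapping = DEFAULT_CLASS_MAP if class_map is None else class_map
    key = raw.strip().lower()
    if key in mapping:
        return mapping[key]
    # multi-product regions (e.g. "NRPS.T1PKS") are hybrids
    if any(sep in key for sep in (".", "+", "/")):
        return "hybrid"
    raise ValueError(f"unknown BGC class {raw!r} with no mapping")


def read_bgc_table(
    path: str | Path,
    class_map: dict[str, str] | None = None,
) -> list[BgcRecord]:
    """Load the tabular BGC dialect (one row per gene, 1-based inclusive coords)."""
    path = Path(path)
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing = set(_BGC_COLUMNS[:-1]) - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    has_protein_col = "protein_sequence" in df.columns
    if not has_protein_col:
        warnings.warn(
            f"{path}: no protein_sequence column; pathway grouping rule (iii) "
            "will be unavailable",
            stacklevel=2,
        )
    records: list[BgcRecord] = []
    for bgc_id, grp in df.groupby("bgc_id", sort=False):
        first = grp.iloc[0]
        genes = [
            BgcGene(
                gene_id=row["gene_id"],
                function_label=row["function_label"],
                is_backbone=str(row["is_backbone"]).strip().lower() in {"1", "true", "yes"},
                protein_sequence=row["protein_sequence"] if has_protein_col else "",
            )
            for _, row in grp.iterrows()
        ]
        records.append(
            BgcRecord(
                bgc_id=str(bgc_id),
                genome_id=first["genome_id"],
                contig_id=first["contig_id"],
                start=int(first["start"]) - 1,
                end=int(first["end"]),
                bgc_class=normalise_bgc_class(first["bgc_class"], class_map),
                genes=genes,
            )
        )
    if not records:
        raise ValueError(f"{path}: no BGC rows")
    return records


def write_bgc_table(bgcs: list[BgcRecord], path: str | Path) -> None:
    rows = []
    for bgc in bgcs:
        for g in bgc.genes:
            rows.append(
                {
                    "bgc_id": bgc.bgc_id,
                    "genome_id": bgc.genome_id,
                    "contig_id": bgc.contig_id,
                    "start": bgc.start + 1,
                    "end": bgc.end,
                    "bgc_class": bgc.bgc_class,
                    "gene_id": g.gene_id,
                    "function_label": g.function_label,
                    "is_backbone": int(g.is_backbone),
                    "protein_sequence": g.protein_sequence,
                }
            )
    pd.DataFrame(rows, columns=_BGC_COLUMNS).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# orthology summary
# ---------------------------------------------------------------------------

def read_orthology(totals_path: str | Path, pairs_path: str | Path) -> OrthologySummary:
    totals_df = pd.read_csv(totals_path, sep="\t", dtype={"genome_id": str})
    pairs_df = pd.read_csv(pairs_path, sep="\t", dtype={"genome_i": str, "genome_j": str})
    totals = dict(zip(totals_df["genome_id"], totals_df["total_proteins"].astype(int)))
    shared: dict[tuple[str, str], int] = {}
    for _, row in pairs_df.iterrows():
        i, j = row["genome_i"], row["genome_j"]
        shared[(i, j)] = int(row["shared_i"])
        shared[(j, i)] = int(row["shared_j"])
    return OrthologySummary(genome_ids=sorted(totals), totals=totals, shared=shared)


def write_orthology(
    summary: OrthologySummary, totals_path: str | Path, pairs_path: str | Path
) -> None:
    pd.DataFrame(
        {"genome_id": list(summary.totals), "total_proteins": list(summary.totals.values())}
    ).to_csv(totals_path, sep="\t", index=False)
    rows = []
    ids = summary.genome_ids
    for a, i in enumerate(ids):
        for j in ids[a + 1:]:
            rows.append(
                {
                    "genome_i": i,
                    "genome_j": j,
                    "shared_i": summary.shared[(i, j)],
                    "shared_j": summary.shared[(j, i)],
                }
            )
    pd.DataFrame(rows, columns=["genome_i", "genome_j", "shared_i", "shared_j"]).to_csv(
        pairs_path, sep="\t", index=False
    )


# ---------------------------------------------------------------------------
# metadata / presence-absence
# ---------------------------------------------------------------------------

def read_metadata(path: str | Path) -> StrainMetadata:
    df = pd.read_csv(path, sep="\t", dtype=str).set_index("strain_id")
    return StrainMetadata(table=df)


def read_presence_absence(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", index_col=0)
    bad = ~df.isin([0, 1]).all(axis=None)
    if bad:
        raise ValueError(f"{path}: presence/absence cells must be 0 or 1")
    return df.astype("int8")


def write_presence_absence(matrix: pd.DataFrame, path: str | Path) -> None:
    matrix.astype(int).to_csv(path, sep="\t")
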