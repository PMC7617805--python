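"""Readers, writers and canonical in-memory types for annotated genomes.

Genomic start/end coordinates are 1-based inclusive (GFF3 convention);
protein spans elsewhere in the package are 0-based half-open. Gene order
indices are assigned from genomic position regardless of strand, and are
dense 0..n-1 within every contig after ingestion.
"""
from __future__ import annotations

import os
from dataclasses import dataclass, field

import pandas as pd

from .errors import ParseError, ValidationError

STRANDS = ("+", "-")

CATALOG_COLUMNS = [
    "assembly_id",
    "contig_id",
    "mksf_gene",
    "mkse_gene",
    "mksb_gene",
    "mksg_gene",
    "mksf_index",
    "mkse_index",
    "mksb_index",
    "mksg_index",
    "strand",
    "order_signature",
    "first_index",
    "accepted",
    "reasons",
]


@dataclass
class GeneRecord:
    """One protein-coding gene on a contig."""

    gene_id: str
    contig_id: str
    order_index: int
    strand: str
    protein: str

    def __post_init__(self) -> None:
        if self.strand not in STRANDS:
            raise ValidationError(
                f"gene {self.gene_id}: strand must be '+' or '-', got {self.strand!r}"
            )
        if self.order_index < 0:
            raise ValidationError(f"gene {self.gene_id}: negative order_index")
        self.protein = self.protein.upper()

    @property
    def length(self) -> int:
        return len(self.protein)


@dataclass
class ContigAnnotation:
    """Genes of one contig, sorted by order_index (dense, 0-based)."""

    contig_id: str
    genes: list[GeneRecord] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.genes = sorted(self.genes, key=lambda g: g.order_index)
        idx = [g.order_index for g in self.genes]
        if idx != list(range(len(idx))):
            raise ValidationError(
                f"contig {self.contig_id}: order indices must be exactly 0..n-1"
            )

    @property
    def n_genes(self) -> int:
        return len(self.genes)


@dataclass
class GenomeSet:
    """A set of annotated contigs belonging to one assembly."""

    assembly_id: str
    contigs: list[ContigAnnotation] = field(default_factory=list)
    domain_label: str | None = None

    def __post_init__(self) -> None:
        ids = [c.contig_id for c in self.contigs]
        if len(set(ids)) != len(ids):
            raise ValidationError(f"assembly {self.assembly_id}: duplicate contig ids")

    def gene_lookup(self) -> dict[str, GeneRecord]:
        out: dict[str, GeneRecord] = {}
        for contig in self.contigs:
            for gene in contig.genes:
                out[gene.gene_id] = gene
        return out


@dataclass
class Alignment:
    """Equal-length gapped rows over the protein alphabet plus '-'."""

    names: list[str]
    rows: list[str]

    def __post_init__(self) -> None:
        if len(self.names) != len(self.rows):
            raise ValidationError("alignment: names and rows differ in count")
        if len(set(self.names)) != len(self.names):
            raise ValidationError("alignment: duplicate row names")
        if self.rows:
            w = len(self.rows[0])
            if any(len(r) != w for r in self.rows):
                raise ValidationError("alignment: rows have unequal lengths")
        self.rows = [r.upper() for r in self.rows]

    @property
    def n_cols(self) -> int:
        return len(self.rows[0]) if self.rows else 0

    @property
    def n_rows(self) -> int:
        return len(self.rows)

    def degapped(self, i: int) -> str:
        return self.rows[i].replace("-", "")


def read_fasta(path: str) -> list[tuple[str, str]]:
    """Strict FASTA reader: uppercased sequences, gaps preserved, order kept.

    Raises ParseError (with the offending line number) on sequence data
    before the first header, and on duplicate record names.
    """
    records: list[tuple[str, str]] = []
    seen: set[str] = set()
    name: str | None = None
    chunks: list[str] = []

    def flush(line_no: int) -> None:
        if name is None:
            return
        seq = "".join(chunks).upper()
        if not seq:
            raise ParseError(f"{path}: record {name!r} has an empty sequence")
        records.append((name, seq))

    with open(path) as fh:
        for line_no, raw in enumerate(fh, 1):
            line = raw.strip()
            if not line:
                continue
            if line.startswith(">"):
                flush(line_no)
                name = line[1:].split()[0] if line[1:].split() else ""
                if not name:
                    raise ParseError(f"{path}:{line_no}: empty FASTA header")
                if name in seen:
                    raise ParseError(f"{path}:{line_no}: duplicate record name {name!r}")
                seen.add(name)
                chunks = []
            else:
                if name is None:
                    raise ParseError(
                        f"{path}:{line_no}: sequence data before any '>' header"
                    )
                chunks.append(line)
    flush(-1)
    return records


def write_fasta(records, path: str, width: int = 60) -> None:
    with open(path, "w") as fh:
        for name, seq in records:
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")
            if not seq:
                fh.write("\n")


def read_alignment(path: str) -> Alignment:
    recs = read_fasta(path)
    return Alignment(names=[n for n, _ in recs], rows=[s for _, s in recs])


def write_alignment(aln: Alignment, path: str, width: int = 60) -> None:
    write_fasta(zip(aln.names, aln.rows), path, width=width)


def _parse_gff3_attributes(attrs: str) -> dict[str, str]:
    out: dict[str, str] = {}
    for part in attrs.strip().split(";"):
        if not part:
            continue
        if "=" not in part:
            continue
        k, v = part.split("=", 1)
        out[k.strip()] = v.strip()
    return out


def _rows_from_tsv(path: str) -> list[dict]:
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = {"contig_id", "gene_id", "start", "end", "strand"}
    missing = required - set(df.columns)
    if missing:
        raise ParseError(f"{path}: missing columns {sorted(missing)}")
    rows = []
    for _, r in df.iterrows():
        rows.append(
            {
                "contig_id": r["contig_id"],
                "gene_id": r["gene_id"],
                "start": int(r["start"]),
                "end": int(r["end"]),
                "strand": r["strand"],
            }
        )
    return rows


def _rows_from_gff3(path: str) -> list[dict]:
    rows = []
    with open(path) as fh:
        for line_no, raw in enumerate(fh, 1):
            line = raw.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 9:
                raise ParseError(f"{path}:{line_no}: expected 9 tab-separated columns")
            seqid, _src, ftype, start, end, _score, strand, _phase, attrs = parts
            if ftype != "CDS":
                continue
            attributes = _parse_gff3_attributes(attrs)
            if "ID" not in attributes:
                raise ParseError(f"{path}:{line_no}: CDS feature lacks an ID attribute")
            rows.append(
                {
                    "contig_id": seqid,
                    "gene_id": attributes["ID"],
                    "start": int(start),
                    "end": int(end),
                    "strand": strand,
                }
            )
    return rows


def read_gene_table(
    path: str,
    dialect: str,
    protein_fasta: str,
    assembly_id: str | None = None,
    domain_label: str | None = None,
) -> GenomeSet:
    """Ingest a gene table (TSV or GFF3) plus its companion protein FASTA.

    Genes are sorted per contig by start coordinate (ties broken by
    gene_id) and given dense 0-based order indices.
    """
    if dialect == "tsv":
        rows = _rows_from_tsv(path)
    elif dialect == "gff3":
        rows = _rows_from_gff3(path)
    else:
        raise ValidationError(f"unknown gene-table dialect {dialect!r}")

    for r in rows:
        if r["strand"] not in STRANDS:
            raise ParseError(
                f"{path}: gene {r['gene_id']}: strand must be '+' or '-', got {r['strand']!r}"
            )

    proteins = dict(read_fasta(protein_fasta))
    missing = sorted({r["gene_id"] for r in rows} - set(proteins))
    if missing:
        raise ValidationError(
            f"{path}: gene ids absent from {protein_fasta}: {missing}"
        )

    by_contig: dict[str, list[dict]] = {}
    for r in rows:
        by_contig.setdefault(r["contig_id"], []).append(r)

    contigs = []
    for contig_id in sorted(by_contig):
        genes = sorted(by_contig[contig_id], key=lambda r: (r["start"], r["gene_id"]))
        records = [
            GeneRecord(
                gene_id=r["gene_id"],
                contig_id=contig_id,
                order_index=i,
                strand=r["strand"],
                protein=proteins[r["gene_id"]],
            )
            for i, r in enumerate(genes)
        ]
        contigs.append(ContigAnnotation(contig_id=contig_id, genes=records))

    if assembly_id is None:
        assembly_id = os.path.splitext(os.path.basename(path))[0]
    return GenomeSet(assembly_id=assembly_id, contigs=contigs, domain_label=domain_label)


def write_gene_table(genomes: GenomeSet, path: str, gene_spacing: int = 2000) -> None:
    """Write the TSV dialect of the gene table (synthetic coordinates)."""
    rows = []
    for contig in genomes.contigs:
        for gene in contig.genes:
            start = 1 + gene.order_index * gene_spacing
            rows.append(
                {
                    "contig_id": contig.contig_id,
                    "gene_id": gene.gene_id,
                    "start": start,
                    "end": start + 3 * gene.length - 1,
                    "strand": gene.strand,
                }
            )
    pd.DataFrame(rows, columns=["contig_id", "gene_id", "start", "end", "strand"]).to_csv(
        path, sep="\t", index=False
    )


def write_operon_catalog(calls, path: str) -> None:
    """Write OperonCalls as a TSV catalog, one row per call.

    Rows are ordered by (assembly, contig, first member index); rejected
    calls carry their comma-joined reason codes.
    """
    rows = []
    for call in calls:
        fam_gene = dict(call.core_gene_ids)
        rows.append(
            {
                "assembly_id": call.assembly_id,
                "contig_id": call.contig_id,
                "mksf_gene": fam_gene.get("MksF", ""),
                "mkse_gene": fam_gene.get("MksE", ""),
                "mksb_gene": fam_gene.get("MksB", ""),
                "mksg_gene": call.mksg_gene_id or "",
                "mksf_index": call.core["MksF"],
                "mkse_index": call.core["MksE"],
                "mksb_index": call.core["MksB"],
                "mksg_index": -1 if call.mksg is None else call.mksg,
                "strand": call.strand,
                "order_signature": call.order_signature,
                "first_index": call.first_index,
                "accepted": int(call.accepted),
                "reasons": ",".join(call.reasons),
            }
        )
    rows.sort(key=lambda r: (r["assembly_id"], r["contig_id"], r["first_index"]))
    pd.DataFrame(rows, columns=CATALOG_COLUMNS).to_csv(path, sep="\t", index=False)


def read_operon_catalog(path: str):
    """Read a catalog TSV back into OperonCall objects."""
    from .operon_inference import OperonCall

    df = pd.read_csv(path, sep="\t", dtype={"reasons": str}, keep_default_na=False)
    calls = []
    for _, r in df.iterrows():
        mksg = None if int(r["mksg_index"]) < 0 else int(r["mksg_index"])
        calls.append(
            OperonCall(
                assembly_id=str(r["assembly_id"]),
                contig_id=str(r["contig_id"]),
                core={
                    "MksF": int(r["mksf_index"]),
                    "MksE": int(r["mkse_index"]),
                    "MksB": int(r["mksb_index"]),
                },
                mksg=mksg,
                strand=str(r["strand"]),
                order_signature=str(r["order_signature"]),
                accepted=bool(int(r["accepted"])),
                reasons=tuple(c for c in str(r["reasons"]).split(",") if c),
                core_gene_ids=(
                    ("MksF", str(r["mksf_gene"])),
                    ("MksE", str(r["mkse_gene"])),
                    ("MksB", str(r["mksb_gene"])),
                ),
                mksg_gene_id=str(r["mksg_gene"]) or None,
            )
        )
    return calls
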