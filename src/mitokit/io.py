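"""Readers and writers: FASTA, GFF3, the TSV feature dialect, alignments, Newick.

The TSV feature dialect mirrors published mitogenome gene tables:
``name  type  start  end  strand  n_exons`` with two optional columns,
``exons`` ("s1-e1;s2-e2;...") and ``nested_in`` (host gene of an
intron-encoded ORF). Coordinates are 1-based inclusive in both dialects.
"""

from __future__ import annotations

import csv
from pathlib import Path
from typing import Iterable, Optional, Sequence

from Bio import SeqIO

from .model import (
    FeatureTable,
    GeneFeature,
    Mitogenome,
    MitokitError,
    StrainAlignment,
)

_TSV_COLUMNS = ["name", "type", "start", "end", "strand", "n_exons"]


# ---------------------------------------------------------------- FASTA

def read_fasta(path: str | Path, circular: bool = True) -> list[Mitogenome]:
    """Load genomes from a (multi-)FASTA file.

    DNA only: sequences are uppercased and must be over {A,C,G,T,N}.
    Duplicate record ids are an error.
    """
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise MitokitError(f"{path}: empty or not FASTA")
    genomes = []
    seen: set[str] = set()
    for rec in records:
        if rec.id in seen:
            raise MitokitError(f"{path}: duplicate record id {rec.id!r}")
        seen.add(rec.id)
        genomes.append(Mitogenome(id=rec.id, sequence=str(rec.seq), circular=circular))
    return genomes


def write_fasta(genomes: Sequence[Mitogenome], path: str | Path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for g in genomes:
            fh.write(f">{g.id}\n")
            for i in range(0, len(g.sequence), width):
                fh.write(g.sequence[i:i + width] + "\n")


# ---------------------------------------------------------------- features

def _parse_exons(text: str) -> Optional[list[tuple[int, int]]]:
    text = text.strip()
    if not text:
        return None
    out = []
    for part in text.split(";"):
        s, e = part.split("-")
        out.append((int(s), int(e)))
    return out


def _format_exons(exons: Optional[list[tuple[int, int]]]) -> str:
    if not exons:
        return ""
    return ";".join(f"{s}-{e}" for (s, e) in exons)


_STRAND_IN = {"forward": "forward", "reverse": "reverse", "+": "forward", "-": "reverse"}


def read_feature_table(
    path: str | Path, dialect: str = "auto", genome_id: str | None = None
) -> FeatureTable:
    """Read a feature table from GFF3 or the TSV dialect.

    ``dialect``: "gff3", "tsv", or "auto" (by extension; .gff/.gff3 -> GFF3).
    """
    path = Path(path)
    if dialect == "auto":
        dialect = "gff3" if path.suffix.lower() in (".gff", ".gff3") else "tsv"
    if dialect == "gff3":
        return _read_gff3(path, genome_id)
    if dialect == "tsv":
        return _read_feature_tsv(path, genome_id)
    raise MitokitError(f"unknown feature dialect {dialect!r}")


def _read_feature_tsv(path: Path, genome_id: str | None) -> FeatureTable:
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        if reader.fieldnames is None or not set(_TSV_COLUMNS) <= set(reader.fieldnames):
            raise MitokitError(
                f"{path}: TSV feature dialect requires columns {_TSV_COLUMNS}"
            )
        features = []
        for row in reader:
            strand = _STRAND_IN.get(row["strand"].strip().lower())
            if strand is None:
                raise MitokitError(f"{path}: malformed strand {row['strand']!r}")
            features.append(
                GeneFeature(
                    name=row["name"].strip(),
                    feature_type=row["type"].strip(),
                    start=int(row["start"]),
                    end=int(row["end"]),
                    strand=strand,
                    n_exons=int(row["n_exons"]),
                    exons=_parse_exons(row.get("exons") or ""),
                    nested_in_intron_of=(row.get("nested_in") or "").strip() or None,
                )
            )
    return FeatureTable(genome_id=genome_id or path.stem, features=features)


def write_feature_table(
    table: FeatureTable, path: str | Path, dialect: str = "auto"
) -> None:
    path = Path(path)
    if dialect == "auto":
        dialect = "gff3" if path.suffix.lower() in (".gff", ".gff3") else "tsv"
    if dialect == "tsv":
        _write_feature_tsv(table, path)
    elif dialect == "gff3":
        _write_gff3(table, path)
    else:
        raise MitokitError(f"unknown feature dialect {dialect!r}")


def _write_feature_tsv(table: FeatureTable, path: Path) -> None:
    cols = _TSV_COLUMNS + ["exons", "nested_in"]
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(cols)
        for f in table:
            writer.writerow(
                [
                    f.name, f.feature_type, f.start, f.end, f.strand,
                    f.n_exons, _format_exons(f.exons), f.nested_in_intron_of or "",
                ]
            )


_GFF_STRAND = {"forward": "+", "reverse": "-"}


def _gff3_attrs(text: str) -> dict[str, str]:
    out = {}
    for item in text.strip().split(";"):
        if not item or "=" not in item:
            continue
        k, v = item.split("=", 1)
        out[k.strip()] = v.strip()
    return out


def _read_gff3(path: Path, genome_id: str | None) -> FeatureTable:
    features: list[GeneFeature] = []
    exons_by_parent: dict[str, list[tuple[int, int]]] = {}
    pending: list[dict] = []
    seqid = None
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            cols = line.split("\t")
            if len(cols) != 9:
                raise MitokitError(f"{path}: malformed GFF3 line: {line!r}")
            seqid = seqid or cols[0]
            ftype = cols[2]
            start, end = int(cols[3]), int(cols[4])
            if end < start:
                raise MitokitError(f"{path}: end < start on line: {line!r}")
            strand = _STRAND_IN.get(cols[6])
            if strand is None:
                raise MitokitError(f"{path}: malformed strand {cols[6]!r}")
            attrs = _gff3_attrs(cols[8])
            if ftype == "exon":
                parent = attrs.get("Parent", "")
                exons_by_parent.setdefault(parent, []).append((start, end))
            elif ftype in ("CDS", "tRNA", "rRNA"):
                pending.append(
                    dict(
                        name=attrs.get("Name", attrs.get("ID", f"feature_{len(pending)+1}")),
                        id=attrs.get("ID", ""),
                        feature_type=ftype,
                        start=start,
                        end=end,
                        strand=strand,
                        n_exons=int(attrs.get("n_exons", 0)) or None,
                        nested_in=attrs.get("nested_in") or None,
                    )
                )
            # other feature types (region, gene wrappers) are ignored
    for p in pending:
        exons = exons_by_parent.get(p["id"]) or None
        n_exons = p["n_exons"] or (len(exons) if exons else 1)
        features.append(
            GeneFeature(
                name=p["name"],
                feature_type=p["feature_type"],
                start=p["start"],
                end=p["end"],
                strand=p["strand"],
                n_exons=n_exons,
                exons=exons,
                nested_in_intron_of=p["nested_in"],
            )
        )
    if not features:
        raise MitokitError(f"{path}: no CDS/tRNA/rRNA features found")
    return FeatureTable(genome_id=genome_id or seqid or path.stem, features=features)


def _write_gff3(table: FeatureTable, path: Path) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for i, f in enumerate(table, 1):
            fid = f"f{i:04d}"
            attrs = [f"ID={fid}", f"Name={f.name}", f"n_exons={f.n_exons}"]
            if f.nested_in_intron_of:
                attrs.append(f"nested_in={f.nested_in_intron_of}")
            fh.write(
                "\t".join(
                    [
                        table.genome_id, "mitokit", f.feature_type,
                        str(f.start), str(f.end), ".",
                        _GFF_STRAND[f.strand], ".", ";".join(attrs),
                    ]
                )
                + "\n"
            )
            for (s, e) in f.exons or []:
                fh.write(
                    "\t".join(
                        [
                            table.genome_id, "mitokit", "exon",
                            str(s), str(e), ".",
                            _GFF_STRAND[f.strand], ".", f"Parent={fid}",
                        ]
                    )
                    + "\n"
                )


# ---------------------------------------------------------------- alignments

def read_alignment(path: str | Path) -> StrainAlignment:
    """Read an aligned multi-FASTA into a StrainAlignment."""
    records = list(SeqIO.parse(str(path), "fasta"))
    if len(records) < 2:
        raise MitokitError(f"{path}: an alignment needs >= 2 sequences")
    return StrainAlignment(
        strain_ids=[r.id for r in records],
        rows=[str(r.seq).upper() for r in records],
    )


def write_alignment(aln: StrainAlignment, path: str | Path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for sid, row in zip(aln.strain_ids, aln.rows):
            fh.write(f">{sid}\n")
            for i in range(0, len(row), width):
                fh.write(row[i:i + width] + "\n")


# ---------------------------------------------------------------- tables, trees

def write_tsv(rows: Iterable[Sequence], path: str | Path, header: Sequence[str]) -> None:
    """Write a report table as tab-separated UTF-8 with Unix newlines."""
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(header)
        for row in rows:
            writer.writerow(row)


def write_newick(tree, path: str | Path) -> None:
    """Write a PhyloTree (or dendropy Tree) to a Newick file."""
    newick = tree.as_newick() if hasattr(tree, "as_newick") else tree.as_string(schema="newick")
    with open(path, "w") as fh:
        fh.write(newick.strip() + "\n")
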