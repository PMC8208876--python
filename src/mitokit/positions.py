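"""Classify genomic intervals against a gene annotation.

Four positional classes, in precedence order: genic (overlaps >= 1 exon
base of a top-level feature), intronic ORF (overlaps a CDS nested inside
another gene's intron — typically a LAGLIDADG homing endonuclease),
intronic (lies only within intron bases), and intergenic. Overlap is
any-overlap: a single shared base attributes the interval to the gene.

When the annotation carries no exon sub-intervals the classifier degrades
to a two-class genic/intergenic mode (gene spans act as exonic) and flags
results as approximate.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .model import (
    FeatureTable,
    GeneFeature,
    MitokitError,
    PositionClass,
    SSRCatalog,
    interval_overlap,
)


def _nested_features(table: FeatureTable) -> set[str]:
    """Names of CDS features nested inside another feature's intron.

    The explicit ``nested_in_intron_of`` field takes precedence; otherwise a
    CDS whose span lies within another feature's span but outside that
    feature's exons is treated as nested. Without exon detail on the host,
    span containment alone is not enough to call nesting, so nothing is
    inferred.
    """
    nested: set[str] = set()
    for f in table:
        if f.nested_in_intron_of is not None:
            nested.add(f.name)
            continue
        if f.feature_type != "CDS":
            continue
        for host in table:
            if host.name == f.name or host.exons is None:
                continue
            if host.start <= f.start and f.end <= host.end:
                inside_exon = any(
                    interval_overlap(f.start, f.end, s, e)
                    for (s, e) in host.exons
                )
                if not inside_exon:
                    nested.add(f.name)
                    break
    return nested


def classify_interval(
    start: int, end: int, table: FeatureTable, genome_length: int | None = None
) -> PositionClass:
    """Positional class of a 1-based inclusive interval."""
    if start < 1 or start > end:
        raise MitokitError(f"invalid interval {start}..{end}")
    if genome_length is not None and end > genome_length:
        raise MitokitError(
            f"interval {start}..{end} outside genome of length {genome_length}"
        )
    has_exon_detail = any(f.exons is not None for f in table)
    nested = _nested_features(table)

    genic_hits: list[str] = []
    nested_hits: list[str] = []
    intron_hits: list[str] = []
    for f in table:
        if not interval_overlap(start, end, f.start, f.end):
            continue
        if f.name in nested:
            nested_hits.append(f.name)
            continue
        exon_overlap = any(
            interval_overlap(start, end, s, e) for (s, e) in f.exon_intervals()
        )
        if exon_overlap:
            genic_hits.append(f.name)
        else:
            intron_hits.append(f.name)

    approximate = not has_exon_detail and len(table) > 0
    if genic_hits:
        return PositionClass("genic", genic_hits, approximate=approximate)
    if nested_hits:
        genes = nested_hits + [f"(Intron){h}" for h in intron_hits]
        return PositionClass("intronic_orf", genes, approximate=approximate)
    if intron_hits:
        return PositionClass(
            "intronic", [f"(Intron){h}" for h in intron_hits], approximate=approximate
        )
    return PositionClass("intergenic", [], approximate=approximate)


def annotate_catalog(
    catalog: SSRCatalog, table: FeatureTable, genome_length: int | None = None
) -> tuple[SSRCatalog, pd.DataFrame, pd.DataFrame]:
    """Fill each record's positional class; return per-class and per-gene counts.

    Returns ``(catalog, class_counts, gene_counts)`` where ``class_counts``
    has one row per positional class and ``gene_counts`` one row per gene
    (an SSR overlapping several genes counts once for each).
    """
    if table.genome_id != catalog.genome_id:
        raise MitokitError(
            f"genome id mismatch: catalog {catalog.genome_id!r} vs "
            f"features {table.genome_id!r}"
        )
    class_counts = {"genic": 0, "intronic_orf": 0, "intronic": 0, "intergenic": 0}
    gene_counts: dict[str, int] = {}
    for rec in catalog:
        pc = classify_interval(rec.start, rec.end, table, genome_length)
        rec.position_class = pc
        class_counts[pc.klass] += 1
        for g in pc.genes:
            name = g.removeprefix("(Intron)")
            gene_counts[name] = gene_counts.get(name, 0) + 1
    class_df = pd.DataFrame(
        {"position": list(class_counts), "n_ssrs": list(class_counts.values())}
    )
    gene_df = pd.DataFrame(
        sorted(gene_counts.items(), key=lambda kv: (-kv[1], kv[0])),
        columns=["gene", "n_ssrs"],
    )
    return catalog, class_df, gene_df
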