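"""Bundled reference tables for the WBPH fungal endosymbiont mitogenome.

These are the published gene annotation and SSR catalog of the KR isolate
(GenBank MW115131) and the intraspecific variation counts of the four
Ophiocordycipitaceae species used as comparators. The genome sequences
themselves are not bundled (they live in GenBank: MW115131, MW373710,
MW373711, MW376862, BK059186).
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

from .io import read_feature_table
from .model import FeatureTable

KR_ACCESSION = "MW115131"
KR_GENOME_LENGTH = 55_393
KR_GC_PERCENT = 30.7


def _data_path(name: str):
    return resources.files("mitokit.data").joinpath(name)


def load_kr_annotation() -> FeatureTable:
    """The 42-gene annotation of the KR mitogenome (28 CDS, 12 tRNA, 2 rRNA).

    Spans are 1-based inclusive; exon sub-intervals were not published, so
    positional classification against this table runs in the approximate
    two-class (genic/intergenic) mode. Intron-encoded ORFs carry explicit
    nesting metadata.
    """
    with resources.as_file(_data_path("mw115131_features.tsv")) as p:
        return read_feature_table(p, dialect="tsv", genome_id=KR_ACCESSION)


def load_kr_ssr_catalog() -> pd.DataFrame:
    """The published SSR catalog of the KR mitogenome (169 records).

    Columns: no, name, category, ssr_type, start, end, unit, repeat_number,
    genes. A few printed unit sequences are truncated relative to the span;
    the span identity (end - start + 1 = unit length x copies) is the
    authoritative description of those records.
    """
    with resources.as_file(_data_path("mw115131_ssr_catalog.tsv")) as p:
        return pd.read_csv(p, sep="\t", keep_default_na=False)


def load_variation_counts() -> pd.DataFrame:
    """Published intraspecific variation counts for four Ophiocordycipitaceae
    species: aligned length, SNP count, and gap-column (INDEL) count per
    conspecific mitogenome panel."""
    with resources.as_file(_data_path("ophiocordycipitaceae_variation_counts.tsv")) as p:
        return pd.read_csv(p, sep="\t")
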