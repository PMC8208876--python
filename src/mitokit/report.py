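"""Report writers mirroring the published table layouts, plus run logging.

All reports are TSV (UTF-8, Unix newlines). Values are kept at full
precision internally and rounded only here, at the report boundary.
"""

from __future__ import annotations

import hashlib
import json
import platform
from datetime import datetime, timezone
from pathlib import Path
from typing import Optional, Sequence

from . import __version__
from .io import write_tsv
from .model import SSRCatalog, VariantEvent, VariationSummary

SSR_TYPE_LABEL = {
    "mono": "MonoSSR", "di": "DiSSR", "tri": "TriSSR", "tetra": "TetraSSR",
    "penta": "PentaSSR", "hexa": "HexaSSR", "hepta": "HeptaSSR",
    "octa": "OctaSSR", "nona": "NonaSSR", "deca": "DecaSSR",
}
CATEGORY_LABEL = {
    "normal": "Normal SSR", "extended": "Extended SSR", "potential": "Potential SSR",
}

SSR_HEADER = [
    "No.", "Name", "SSR type", "Type", "Start", "End",
    "Unit sequence", "Repeat number", "Genes",
]
VARIANT_HEADER = [
    "No.", "Type", "Coordination of multiple sequence alignments",
    "Strains", "Base changes", "Position",
]
SUMMARY_HEADER = [
    "No. of genomes", "Aligned length (bp)", "No. of SNPs", "SNP coverage (%)",
    "No. of INDELs", "INDEL coverage (%)",
]


def ssr_catalog_rows(catalog: SSRCatalog) -> list[list]:
    rows = []
    for i, rec in enumerate(catalog, 1):
        genes = ", ".join(rec.position_class.genes) if rec.position_class else ""
        rows.append(
            [
                i, rec.ssr_id, CATEGORY_LABEL[rec.category],
                SSR_TYPE_LABEL[rec.ssr_type], rec.start, rec.end,
                rec.unit, rec.copy_number, genes,
            ]
        )
    return rows


def write_ssr_catalog(catalog: SSRCatalog, path: str | Path) -> None:
    write_tsv(ssr_catalog_rows(catalog), path, SSR_HEADER)


def variant_rows(events: Sequence[VariantEvent]) -> list[list]:
    rows = []
    for i, ev in enumerate(events, 1):
        coord = (
            str(ev.msa_start) if ev.msa_start == ev.msa_end
            else f"{ev.msa_start}-{ev.msa_end}"
        )
        rows.append(
            [
                i, ev.vtype.capitalize() if ev.vtype != "SNP" else "SNP",
                coord, ", ".join(sorted(ev.carriers)),
                ev.base_change, ev.position_note,
            ]
        )
    return rows


def write_variant_table(events: Sequence[VariantEvent], path: str | Path) -> None:
    write_tsv(variant_rows(events), path, VARIANT_HEADER)


def write_variation_summary(
    summary: VariationSummary, path: str | Path, snp_decimals: int = 3,
    indel_decimals: int = 2,
) -> None:
    row = [
        summary.n_genomes, summary.aligned_length, summary.n_snps,
        f"{summary.snp_coverage_pct:.{snp_decimals}f}",
        summary.n_indels, f"{summary.indel_coverage_pct:.{indel_decimals}f}",
    ]
    write_tsv([row], path, SUMMARY_HEADER)


def write_run_log(
    out_path: str | Path,
    subcommand: str,
    params: dict,
    inputs: Optional[Sequence[str]] = None,
    seed: Optional[int] = None,
) -> Path:
    """Machine-readable provenance record accompanying every report."""
    out_path = Path(out_path)
    payload = {
        "tool": "mitokit",
        "version": __version__,
        "subcommand": subcommand,
        "timestamp": datetime.now(timezone.utc).isoformat(),
        "python": platform.python_version(),
        "inputs": list(inputs or []),
        "seed": seed,
        "parameters": params,
    }
    payload["parameter_hash"] = hashlib.sha256(
        json.dumps(params, sort_keys=True, default=str).encode()
    ).hexdigest()[:16]
    log_path = out_path.with_suffix(out_path.suffix + ".log.json")
    with open(log_path, "w") as fh:
        json.dump(payload, fh, indent=2, default=str)
    return log_path
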