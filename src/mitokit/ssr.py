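"""Perfect tandem-repeat (SSR) mining and three-tier classification.

The classification scheme is the one used across organelle-genome SSR
surveys: units of 1-6 bp whose perfect run totals at least 10 bp are
*normal* SSRs, units of 7-10 bp at >= 2 copies are *extended* SSRs, and
penta/hexanucleotide units at exactly 2 copies are *potential* SSRs.
Implied minimum copy numbers for normal SSRs: mono >= 10, di >= 5,
tri >= 4, tetra >= 3, penta >= 3, hexa >= 3 (penta/hexa at 2 copies fall
into the potential tier instead).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import NamedTuple, Optional

from .model import (
    Mitogenome,
    MitokitError,
    SSRCatalog,
    SSRRecord,
    SSR_ID_PREFIX,
    SSR_TYPE_BY_UNIT_LEN,
)

NORMAL = "normal"
EXTENDED = "extended"
POTENTIAL = "potential"
REJECTED = "rejected"


@dataclass
class SSRConfig:
    """Scanner / classifier thresholds.

    ``min_total_length_normal`` is compared with >= : published catalogs
    contain 10-bp records (T x 10, five-copy dinucleotides), so 10 bp
    repeats are accepted.
    """

    min_total_length_normal: int = 10
    normal_unit_range: tuple[int, int] = (1, 6)
    extended_unit_range: tuple[int, int] = (7, 10)
    potential_unit_lengths: frozenset[int] = frozenset({5, 6})
    potential_copy_number: int = 2
    require_primitive_unit: bool = True
    scan_wraps_origin: bool = False

    def __post_init__(self) -> None:
        if self.min_total_length_normal < 2:
            raise MitokitError("min_total_length_normal must be >= 2")
        if self.normal_unit_range[1] >= self.extended_unit_range[0]:
            raise MitokitError("unit-length ranges must be ordered and disjoint")
        if self.scan_wraps_origin:
            raise MitokitError("origin-wrapping scans are not supported")

    @property
    def max_unit_length(self) -> int:
        return self.extended_unit_range[1]


class TandemRepeat(NamedTuple):
    """A maximal perfect tandem repeat candidate (1-based inclusive span).

    The span covers full copies only; ``trailing_partial_length`` records
    how many bases of an incomplete further copy follow the span.
    """

    unit: str
    copy_number: int
    start: int
    end: int
    trailing_partial_length: int


def is_primitive(unit: str) -> bool:
    """True unless the unit is a whole repetition of a shorter string."""
    n = len(unit)
    for d in range(1, n):
        if n % d == 0 and unit == unit[:d] * (n // d):
            return False
    return True


def find_tandem_repeats(sequence: str, config: SSRConfig | None = None) -> list[TandemRepeat]:
    """Enumerate maximal perfect tandem repeats with unit lengths 1..10.

    Every candidate is perfect (exact copies), maximal (extendable by no
    further unit on either side), left-anchored (start is the first base of
    the first full copy) and primitive-united (a unit that is itself a
    repetition of a shorter unit is reported at the shorter unit length
    only). N never participates in a repeat. Candidates have >= 2 copies
    (for mono units: run length >= 2).
    """
    config = config or SSRConfig()
    seq = sequence.upper()
    n = len(seq)
    if n == 0:
        raise MitokitError("cannot scan an empty sequence")
    out: list[TandemRepeat] = []
    for u in range(1, config.max_unit_length + 1):
        # match[j] == True when seq[j] equals seq[j+u] and neither is N.
        j = 0
        limit = n - u
        while j < limit:
            if seq[j] != seq[j + u] or seq[j] == "N":
                j += 1
                continue
            run_start = j
            while j < limit and seq[j] == seq[j + u] and seq[j] != "N":
                j += 1
            m = j - run_start            # matched positions
            region_len = m + u           # total perfect region length
            copies = region_len // u
            if copies < 2:
                continue
            unit = seq[run_start:run_start + u]
            if config.require_primitive_unit and not is_primitive(unit):
                continue
            out.append(
                TandemRepeat(
                    unit=unit,
                    copy_number=copies,
                    start=run_start + 1,
                    end=run_start + copies * u,
                    trailing_partial_length=region_len % u,
                )
            )
    out.sort(key=lambda r: (r.start, len(r.unit)))
    return out


def classify_ssr(candidate: TandemRepeat, config: SSRConfig | None = None) -> str:
    """Assign the three-tier category to a candidate, or reject it."""
    config = config or SSRConfig()
    u = len(candidate.unit)
    total = u * candidate.copy_number
    lo_n, hi_n = config.normal_unit_range
    lo_e, hi_e = config.extended_unit_range
    if lo_e <= u <= hi_e and candidate.copy_number >= 2:
        return EXTENDED
    if lo_n <= u <= hi_n:
        if (
            u in config.potential_unit_lengths
            and candidate.copy_number == config.potential_copy_number
        ):
            return POTENTIAL
        if total >= config.min_total_length_normal:
            return NORMAL
    return REJECTED


def _resolve_overlaps(records: list[SSRRecord]) -> list[SSRRecord]:
    """Suppress contained records; resolve remaining conflicts greedily.

    Priority: longer total length, then smaller unit length, then leftmost
    start. The survivors are mutually non-overlapping.
    """
    order = sorted(
        records, key=lambda r: (-(r.length), len(r.unit), r.start, r.unit)
    )
    kept: list[SSRRecord] = []
    for rec in order:
        if any(rec.start <= k.end and k.start <= rec.end for k in kept):
            continue
        kept.append(rec)
    kept.sort(key=lambda r: (r.start, r.end))
    return kept


def find_ssrs(
    genome: Mitogenome | str,
    config: SSRConfig | None = None,
    genome_id: str | None = None,
) -> SSRCatalog:
    """Scan a genome and return its catalog of accepted, id-assigned SSRs."""
    config = config or SSRConfig()
    if isinstance(genome, Mitogenome):
        seq, gid = genome.sequence, genome.id
    else:
        seq, gid = genome.upper(), genome_id or "seq"
    accepted: list[SSRRecord] = []
    for cand in find_tandem_repeats(seq, config):
        category = classify_ssr(cand, config)
        if category == REJECTED:
            continue
        accepted.append(
            SSRRecord(
                ssr_id="",
                category=category,
                ssr_type=SSR_TYPE_BY_UNIT_LEN[len(cand.unit)],
                unit=cand.unit,
                copy_number=cand.copy_number,
                start=cand.start,
                end=cand.end,
                genome_id=gid,
            )
        )
    accepted = _resolve_overlaps(accepted)
    counters: dict[str, int] = {}
    for rec in accepted:
        prefix = SSR_ID_PREFIX[len(rec.unit)]
        counters[prefix] = counters.get(prefix, 0) + 1
        rec.ssr_id = f"{prefix}{counters[prefix]:07d}"
    return SSRCatalog(genome_id=gid, records=accepted)


_TYPE_ORDER = ["mono", "di", "tri", "tetra", "penta", "hexa", "hepta", "octa", "nona", "deca"]


def count_by_type(catalog: SSRCatalog) -> dict[str, dict[str, int]]:
    """Per-type counts split into normal+extended vs potential, with subtotals."""
    main = {t: 0 for t in _TYPE_ORDER}
    potential = {t: 0 for t in _TYPE_ORDER}
    for rec in catalog:
        if rec.category == POTENTIAL:
            potential[rec.ssr_type] += 1
        else:
            main[rec.ssr_type] += 1
    return {
        "normal_extended": main,
        "normal_extended_subtotal": sum(main.values()),
        "potential": {t: potential[t] for t in ("penta", "hexa")},
        "potential_subtotal": sum(potential.values()),
    }


def max_ssr_length(catalog: SSRCatalog, include_potential: bool = False) -> int:
    """Maximum SSR span in bp over normal + extended records."""
    lengths = [
        r.length
        for r in catalog
        if include_potential or r.category in (NORMAL, EXTENDED)
    ]
    if not lengths:
        raise MitokitError("max_ssr_length of an empty catalog")
    return max(lengths)
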