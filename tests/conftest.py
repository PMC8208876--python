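import pytest

from mitokit.datasets import (
    KR_GENOME_LENGTH,
    load_kr_annotation,
    load_kr_ssr_catalog,
    load_variation_counts,
)


@pytest.fixture(scope="session")
def kr_features():
    return load_kr_annotation()


@pytest.fixture(scope="session")
def kr_ssr_catalog():
    return load_kr_ssr_catalog()


@pytest.fixture(scope="session")
def variation_counts():
    return load_variation_counts()


@pytest.fixture(scope="session")
def kr_length():
    return KR_GENOME_LENGTH


def brute_force_repeats(seq: str, max_unit: int = 10) -> set[tuple[str, int, int, int]]:
    """Independent tandem-repeat enumerator: direct string-slice checking.

    Returns {(unit, copies, start, end)} (1-based inclusive, full copies
    only) for every maximal, left-anchored, primitive-united perfect repeat
    with >= 2 copies. O(n * u * copies); used as the oracle for the scanner.
    """

    def primitive(u: str) -> bool:
        return all(
            not (len(u) % d == 0 and u == u[:d] * (len(u) // d))
            for d in range(1, len(u))
        )

    seq = seq.upper()
    n = len(seq)
    found = set()
    for u in range(1, max_unit + 1):
        for i in range(n - 2 * u + 1):
            unit = seq[i:i + u]
            if "N" in unit or not primitive(unit):
                continue
            if i > 0 and seq[i - 1] == unit[-1]:
                continue  # the matched region extends left: not the anchor
            k = 1
            while seq[i + k * u:i + (k + 1) * u] == unit:
                k += 1
            if k >= 2:
                found.add((unit, k, i + 1, i + k * u))
    return found
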