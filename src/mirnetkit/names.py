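"""Canonicalization of miRNA names and gene symbols.

Interaction databases disagree on letter case and stray whitespace
("MIR-34A-5P", " miR-34a-5p "). Matching is exact after canonicalization:
no fuzzy matching of accession variants (miR-34a and miR-34a-5p stay
distinct, since collapsing them would invent interactions).
"""

from __future__ import annotations

import re

_MIR_PREFIX = re.compile(r"^((?:[a-z]{3}-)?)mir")


def normalize_mirna(name: str) -> str:
    """Return the canonical form of a miRNA name.

    Trims, removes internal whitespace, lower-cases, then restores the
    conventional ``miR`` casing of the mature-miRNA prefix (an optional
    three-letter species prefix such as ``hsa-`` is preserved).
    """
    s = "".join(str(name).split()).lower()
    return _MIR_PREFIX.sub(lambda m: m.group(1) + "miR", s)


def normalize_gene(symbol: str) -> str:
    """Return the canonical gene symbol: trimmed, upper-cased."""
    return "".join(str(symbol).split()).upper()
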