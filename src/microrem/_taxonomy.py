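"""Taxonomy lineage parsing.

Lineages are semicolon-separated rank strings covering phylum, class,
order, family and genus (the five ranks carried by the cladogram-ready
output). Both Greengenes-style prefixed names ("p__Firmicutes") and bare
names are accepted; empty or missing ranks become "unclassified_<parent>".
"""

from __future__ import annotations

from dataclasses import dataclass

RANKS = ("phylum", "class", "order", "family", "genus")
_PREFIXES = {"p": "phylum", "c": "class", "o": "order", "f": "family", "g": "genus"}


@dataclass(frozen=True)
class Lineage:
    """A parsed five-rank lineage. ``missing`` flags ranks that were absent."""

    phylum: str
    class_: str
    order: str
    family: str
    genus: str
    missing: tuple[str, ...] = ()

    def rank(self, name: str) -> str:
        return getattr(self, "class_" if name == "class" else name)

    @property
    def levels(self) -> tuple[str, ...]:
        return tuple(self.rank(r) for r in RANKS)

    def __str__(self) -> str:  # Greengenes-style round-trip form
        return ";".join(
            f"{p}__{v}" for p, v in zip("pcofg", self.levels)
        )


def _strip_prefix(token: str) -> tuple[str | None, str]:
    token = token.strip()
    if len(token) >= 3 and token[1:3] == "__" and token[0].lower() in _PREFIXES:
        return _PREFIXES[token[0].lower()], token[3:].strip()
    return None, token


def parse_lineage(text: str) -> Lineage:
    """Parse a lineage string into five ranks.

    Prefixed tokens are placed at their declared rank; bare tokens fill
    ranks in order. Unfilled ranks are named ``unclassified_<parent>`` and
    recorded in ``missing``.
    """
    tokens = [t for t in (tok.strip() for tok in text.split(";")) if t != ""]
    # drop an explicit kingdom/domain token (k__/d__ prefix, or a leading
    # seventh bare token in a full 6-rank lineage)
    if tokens and len(tokens[0]) >= 3 and tokens[0][1:3] == "__" and tokens[0][0].lower() in "kd":
        tokens = tokens[1:]
    elif len(tokens) == len(RANKS) + 1 and _strip_prefix(tokens[0])[0] is None:
        tokens = tokens[1:]

    values: dict[str, str] = {}
    cursor = 0
    for token in tokens:
        rank, name = _strip_prefix(token)
        if rank is None:
            if cursor >= len(RANKS):
                continue
            rank = RANKS[cursor]
        cursor = RANKS.index(rank) + 1
        if name:
            values[rank] = name
    missing = []
    parent = "root"
    out: dict[str, str] = {}
    for r in RANKS:
        if r in values:
            out[r] = values[r]
            parent = values[r]
        else:
            out[r] = f"unclassified_{parent}"
            missing.append(r)
    return Lineage(
        phylum=out["phylum"],
        class_=out["class"],
        order=out["order"],
        family=out["family"],
        genus=out["genus"],
        missing=tuple(missing),
    )


def genus_of(text: str) -> str:
    """Convenience: the genus-rank name of a lineage string."""
    return parse_lineage(text).genus
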