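"""Gene-set algebra and overlap statistics for screen hit lists.

Overlap significance uses the hypergeometric upper tail: for two sets of
sizes |a| and |b| drawn from a universe of N genes, the probability of
sharing at least the observed number of members by chance. Overlap size
is also reported as a percentage of the union, the convention used when
comparing per-condition hit lists.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable

from scipy.stats import hypergeom

from .errors import InvalidParameterError, InvalidUniverseError

DEFAULT_UNIVERSE = 4308  # scored strains in a genome-wide deletion screen


@dataclass(frozen=True)
class GeneSet:
    """A labelled set of unique, case-insensitive gene identifiers."""

    label: str
    members: frozenset

    def __init__(self, label: str, members: Iterable[str]):
        if not label:
            raise InvalidParameterError("gene set label must be non-empty")
        object.__setattr__(self, "label", label)
        object.__setattr__(
            self, "members", frozenset(str(m).upper() for m in members)
        )

    def __len__(self) -> int:
        return len(self.members)


def read_gene_set(path, label: str | None = None) -> GeneSet:
    """Read one identifier per line; '#' starts a comment; blank lines skipped."""
    path = Path(path)
    members = []
    for line in path.read_text().splitlines():
        token = line.split("#", 1)[0].strip()
        if token:
            members.append(token)
    return GeneSet(label or path.stem, members)


def write_gene_set(gene_set: GeneSet, path) -> None:
    Path(path).write_text("\n".join(sorted(gene_set.members)) + "\n")


@dataclass
class OverlapResult:
    label_a: str
    label_b: str
    n_a: int
    n_b: int
    n_intersection: int
    n_union: int
    pct_overlap: int  # 100 * intersection / union, nearest integer
    universe_N: int
    p_upper: float  # P(X >= n_intersection), hypergeometric

    def as_dict(self) -> dict:
        return dict(self.__dict__)


def overlap(a: GeneSet, b: GeneSet, universe_N: int = DEFAULT_UNIVERSE) -> OverlapResult:
    """Two-set overlap counts, union percentage, and hypergeometric p.

    p_upper = P(X >= k) for X ~ Hypergeom(universe_N, |a|, |b|) where k is
    the observed intersection; exact tail evaluated in a numerically
    stable way. Raises if the universe is smaller than the union.
    """
    inter = a.members & b.members
    union = a.members | b.members
    if universe_N < len(union):
        raise InvalidUniverseError(
            f"universe {universe_N} smaller than union {len(union)}"
        )
    k = len(inter)
    pct = int(math.floor(100.0 * k / len(union) + 0.5)) if union else 0
    p_upper = float(hypergeom.sf(k - 1, universe_N, len(a), len(b)))
    return OverlapResult(
        label_a=a.label,
        label_b=b.label,
        n_a=len(a),
        n_b=len(b),
        n_intersection=k,
        n_union=len(union),
        pct_overlap=pct,
        universe_N=universe_N,
        p_upper=min(max(p_upper, 0.0), 1.0),
    )


def venn3(a: GeneSet, b: GeneSet, c: GeneSet) -> dict:
    """Counts of the 7 disjoint regions of a three-set Venn diagram.

    Keys name membership: 'a_only', 'b_only', 'c_only', 'ab', 'ac', 'bc',
    'abc'. The counts sum to |a or b or c|.
    """
    A, B, C = a.members, b.members, c.members
    return {
        "a_only": len(A - B - C),
        "b_only": len(B - A - C),
        "c_only": len(C - A - B),
        "ab": len((A & B) - C),
        "ac": len((A & C) - B),
        "bc": len((B & C) - A),
        "abc": len(A & B & C),
    }


def lpi_fold(lpi: float) -> float:
    """Fold change in doubling time for an LPI value: 2^LPI.

    An LPI of 2.5 corresponds to a ~5.6-fold longer relative doubling time.
    """
    if not math.isfinite(lpi):
        raise InvalidParameterError("LPI must be finite")
    return 2.0 ** lpi


def format_fold(fold: float, decimals: int = 1) -> str:
    """Report formatting for fold changes: truncated, not rounded."""
    scale = 10 ** decimals
    return f"{math.floor(fold * scale) / scale:.{decimals}f}"
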