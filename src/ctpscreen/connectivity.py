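"""Rank-based Kolmogorov–Smirnov enrichment of a gene set in a compound profile.

A compound's predicted effect on the transcriptome (its change in
transcriptional profile, CTP) is represented as a *rank list*: a bijection
from a fixed gene universe of size ``n`` onto the integers ``1..n``, with
rank 1 the gene the compound upregulates most strongly.  Whether a query
gene set of size ``t`` concentrates near the top or the bottom of that list
is measured with the classical two-sided rank-KS statistic used in
connectivity-map screening.

With ``V(1) <= V(2) <= ... <= V(t)`` the ascending sorted ranks of the set's
members, the two directional deviations are

    a = max_{j=1..t} ( j/t - V(j)/n )        (excess toward the top)
    b = max_{j=1..t} ( V(j)/n - (j-1)/t )    (excess toward the bottom)

and the signed enrichment score is ``ES = a`` if ``a > b``, ``ES = -b`` if
``b > a`` and 0 on a tie.  ``ES`` lies in ``[-1, 1]``; a set packed into the
very top of the list approaches +1, a set packed into the bottom approaches
-1, and a uniformly spread set scores near 0.

The statistic is unweighted: only ranks enter, never the magnitude of the
predicted expression change.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from functools import cached_property
from typing import Iterable, Mapping, Sequence

import numpy as np

from .errors import ConfigurationError, DisjointSetError

logger = logging.getLogger(__name__)

__all__ = [
    "RankedProfile",
    "GeneSet",
    "EnrichmentResult",
    "rank_transform",
    "enrichment_score",
]


@dataclass(frozen=True)
class RankedProfile:
    """One compound's CTP as a permutation of ranks over a gene universe.

    Parameters
    ----------
    gene_ids
        The gene universe, one identifier per gene.
    ranks
        Integer ranks aligned with ``gene_ids``; must be a permutation of
        ``1..n``.  Rank 1 is the most upregulated gene.
    compound_id
        Identifier of the compound the profile belongs to.
    """

    gene_ids: tuple[str, ...]
    ranks: np.ndarray
    compound_id: str = ""

    def __post_init__(self):
        ranks = np.asarray(self.ranks, dtype=np.int64)
        object.__setattr__(self, "ranks", ranks)
        n = len(self.gene_ids)
        if n < 2:
            raise ConfigurationError("profile universe must contain >= 2 genes")
        if ranks.shape != (n,):
            raise ConfigurationError(
                f"ranks length {ranks.shape} does not match universe size {n}"
            )
        if len(set(self.gene_ids)) != n:
            raise ConfigurationError("duplicate gene identifiers in universe")
        sorted_ranks = np.sort(ranks)
        if not np.array_equal(sorted_ranks, np.arange(1, n + 1)):
            raise ConfigurationError(
                f"ranks of profile {self.compound_id!r} are not a permutation of 1..{n}"
            )

    @property
    def n(self) -> int:
        return len(self.gene_ids)

    @cached_property
    def rank_map(self) -> Mapping[str, int]:
        """Gene identifier -> rank lookup."""
        return dict(zip(self.gene_ids, self.ranks.tolist()))


@dataclass(frozen=True)
class GeneSet:
    """A named query gene set (members unique, order irrelevant)."""

    name: str
    members: tuple[str, ...]

    def __post_init__(self):
        members = tuple(self.members)
        if len(set(members)) != len(members):
            seen: set[str] = set()
            deduped = []
            for m in members:
                if m not in seen:
                    seen.add(m)
                    deduped.append(m)
            logger.warning(
                "gene set %r: %d duplicate member(s) collapsed",
                self.name,
                len(members) - len(deduped),
            )
            members = tuple(deduped)
        object.__setattr__(self, "members", members)

    def __len__(self) -> int:
        return len(self.members)


@dataclass(frozen=True)
class EnrichmentResult:
    """Directional deviations and signed enrichment score for one set/profile pair.

    ``a_dev`` and ``b_dev`` are the top- and bottom-side maxima of the rank-KS
    running deviation; ``es`` is their signed resolution.  ``t`` is the member
    count after intersection with the universe, ``n`` the universe size, and
    ``dropped`` lists any query members absent from the universe.
    """

    a_dev: float
    b_dev: float
    es: float
    t: int
    n: int
    dropped: tuple[str, ...] = field(default_factory=tuple)


def rank_transform(
    gene_ids: Sequence[str],
    values: Sequence[float] | np.ndarray,
    compound_id: str = "",
) -> RankedProfile:
    """Convert per-gene real change scores into a rank profile.

    The largest score receives rank 1 (most upregulated).  Ties are broken
    by ascending gene identifier so the output is deterministic.

    Raises
    ------
    ConfigurationError
        If any score is non-finite; the message names the offending gene.
    """
    ids = tuple(gene_ids)
    vals = np.asarray(values, dtype=float)
    if vals.shape != (len(ids),):
        raise ConfigurationError("one value per universe gene is required")
    bad = ~np.isfinite(vals)
    if bad.any():
        offenders = [ids[i] for i in np.flatnonzero(bad)[:5]]
        raise ConfigurationError(f"non-finite change score for gene(s): {offenders}")
    # primary key: descending value; secondary: ascending identifier.
    order = np.lexsort((np.asarray(ids), -vals))
    ranks = np.empty(len(ids), dtype=np.int64)
    ranks[order] = np.arange(1, len(ids) + 1)
    return RankedProfile(gene_ids=ids, ranks=ranks, compound_id=compound_id)


def directional_deviations(member_ranks: np.ndarray, n: int) -> tuple[float, float]:
    """Compute (a, b) from ascending-sorted member ranks ``V`` and universe size ``n``.

    ``a = max_j (j/t - V(j)/n)`` and ``b = max_j (V(j)/n - (j-1)/t)``.
    """
    v = np.asarray(member_ranks, dtype=float)
    t = v.size
    j = np.arange(1, t + 1, dtype=float)
    a = float(np.max(j / t - v / n))
    b = float(np.max(v / n - (j - 1) / t))
    return a, b


def enrichment_score(gene_set: GeneSet, profile: RankedProfile) -> EnrichmentResult:
    """Score one query gene set against one rank profile.

    Members absent from the profile universe are dropped (with a warning) and
    reported in the result; ``t`` is the post-intersection count.  A fully
    disjoint set is an error rather than a silent zero.
    """
    rank_map = profile.rank_map
    present = [m for m in gene_set.members if m in rank_map]
    dropped = tuple(m for m in gene_set.members if m not in rank_map)
    if dropped:
        logger.warning(
            "gene set %r: %d member(s) absent from the profile universe",
            gene_set.name,
            len(dropped),
        )
    if not present:
        raise DisjointSetError(
            f"query set {gene_set.name!r} is disjoint from the profile universe"
        )
    v = np.sort(np.array([rank_map[m] for m in present], dtype=np.int64))
    a, b = directional_deviations(v, profile.n)
    if a > b:
        es = a
    elif b > a:
        es = -b
    else:
        es = 0.0
    return EnrichmentResult(
        a_dev=a, b_dev=b, es=es, t=len(present), n=profile.n, dropped=dropped
    )


def enrichment_scores_matrix(
    member_ranks: np.ndarray, n: int
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Vectorised (a, b, es) over many profiles sharing one universe.

    ``member_ranks`` is a ``t x m`` integer array: the ranks of the same ``t``
    query genes in each of ``m`` profiles over a universe of size ``n``.
    Returns three ``(m,)`` arrays.  Semantics per column are identical to
    :func:`enrichment_score`; the scalar path is kept as an independent check.
    """
    vn = np.sort(np.asarray(member_ranks, dtype=float), axis=0) / n
    t = vn.shape[0]
    j = np.arange(1, t + 1, dtype=float)[:, None]
    a = np.max(j / t - vn, axis=0)
    b = np.max(vn - (j - 1) / t, axis=0)
    es = np.where(a > b, a, np.where(b > a, -b, 0.0))
    return a, b, es
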