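"""Synthetic expression matrices and CTP libraries with planted signal.

Two generators make every downstream stage testable without external data:

* :func:`simulate_expression` emulates a small two-group bulk RNA-seq design
  (three replicates per condition by default, matching the young-vs-adult
  femur comparison the pipeline targets).  Baseline expression is drawn per
  gene on the log2 scale, a chosen subset of genes receives a planted linear
  fold change (factor ``effect_fc`` for up genes, ``1/effect_fc`` for down
  genes, applied to the non-reference group), observation noise is added on
  the log2 scale, and values are exponentiated back — so planted fold
  changes are exact in expectation and all values stay positive.

* :func:`simulate_ctp_library` emulates a compound library of rank profiles
  over a shared gene universe.  Null compounds are independent uniformly
  random permutations.  A planted *reverser* forces a ``strength`` fraction
  of the query's up-set genes to the top-most ranks and of its down-set
  genes to the bottom-most ranks (remaining genes permuted over the
  remaining ranks); a *mimicker* is the mirror image.  Forced genes are
  placed by displacement, so every profile stays a valid permutation.

Both generators are pure functions of their configuration, including the
seed: the same config yields bit-identical output.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ConfigurationError, UndefinedMetricError, UniverseError
from .signature import ExpressionMatrix, SignaturePair

__all__ = [
    "ExpressionSimConfig",
    "LibrarySimConfig",
    "GroundTruth",
    "CTPLibrary",
    "gene_universe",
    "simulate_expression",
    "simulate_ctp_library",
    "recovery_rate",
]


def gene_universe(n_genes: int) -> list[str]:
    """Canonical synthetic gene identifiers, shared by both generators.

    Fixed-width naming (``g000001`` ...) keeps identifiers consistent across
    universes of different sizes, so a signature extracted from a small
    expression simulation is a subset of any larger library universe.
    """
    return [f"g{i:06d}" for i in range(1, n_genes + 1)]


@dataclass(frozen=True)
class ExpressionSimConfig:
    """Parameters of the two-group expression simulation.

    ``effect_fc`` is the planted *linear* fold change (> 1); ``noise_sd`` is
    the per-observation noise standard deviation on the log2 scale;
    baseline log2 expression is drawn per gene from
    ``Normal(baseline_log2_mean, baseline_log2_sd)``.
    """

    n_genes: int = 1000
    n_deg_up: int = 50
    n_deg_down: int = 50
    n_per_group: int = 3
    effect_fc: float = 4.0
    noise_sd: float = 0.25
    baseline_log2_mean: float = 6.0
    baseline_log2_sd: float = 2.0
    seed: int = 0

    def __post_init__(self):
        if self.n_genes < 1:
            raise ConfigurationError("n_genes must be >= 1")
        if self.n_deg_up < 0 or self.n_deg_down < 0:
            raise ConfigurationError("planted DEG counts must be >= 0")
        if self.n_deg_up + self.n_deg_down > self.n_genes:
            raise ConfigurationError(
                f"n_deg_up + n_deg_down = {self.n_deg_up + self.n_deg_down} "
                f"exceeds n_genes = {self.n_genes}"
            )
        if self.n_per_group < 2:
            raise ConfigurationError("n_per_group must be >= 2 (t-test undefined below)")
        if self.effect_fc <= 1:
            raise ConfigurationError(f"effect_fc must exceed 1, got {self.effect_fc}")
        if self.noise_sd < 0:
            raise ConfigurationError("noise_sd must be >= 0")


@dataclass(frozen=True)
class LibrarySimConfig:
    """Parameters of the compound rank-profile library simulation.

    Defaults mirror a realistic screening setting (a ~12k-gene universe and
    a ~1000-compound approved-drug library); tests use scaled-down sizes.
    ``strength`` is the fraction of each signature set forced to extreme
    ranks in a planted compound.
    """

    n_genes: int = 12328
    n_compounds: int = 961
    n_reversers: int = 0
    n_mimickers: int = 0
    strength: float = 1.0
    seed: int = 0

    def __post_init__(self):
        if self.n_genes < 2:
            raise ConfigurationError("n_genes must be >= 2")
        if self.n_compounds < 1:
            raise ConfigurationError("n_compounds must be >= 1")
        if self.n_reversers < 0 or self.n_mimickers < 0:
            raise ConfigurationError("planted compound counts must be >= 0")
        if self.n_reversers + self.n_mimickers > self.n_compounds:
            raise ConfigurationError(
                "n_reversers + n_mimickers exceeds n_compounds"
            )
        if not 0.0 <= self.strength <= 1.0:
            raise ConfigurationError(f"strength must lie in [0, 1], got {self.strength}")


@dataclass(frozen=True)
class GroundTruth:
    """Identifiers of planted signal, for evaluating downstream recovery."""

    deg_up_ids: tuple[str, ...] = ()
    deg_down_ids: tuple[str, ...] = ()
    reverser_ids: tuple[str, ...] = ()
    mimicker_ids: tuple[str, ...] = ()

    def __post_init__(self):
        if set(self.deg_up_ids) & set(self.deg_down_ids):
            raise ConfigurationError("a gene cannot be planted both up and down")
        if set(self.reverser_ids) & set(self.mimicker_ids):
            raise ConfigurationError("a compound cannot be both reverser and mimicker")


@dataclass(frozen=True)
class CTPLibrary:
    """A compound library of rank profiles over one shared gene universe.

    ``ranks`` is a genes x compounds DataFrame; each column is a permutation
    of ``1..n_genes`` (rank 1 = most upregulated by that compound).
    """

    ranks: pd.DataFrame

    def __post_init__(self):
        n = len(self.ranks.index)
        expected = np.arange(1, n + 1)
        arr = self.ranks.to_numpy(dtype=np.int64)
        sorted_cols = np.sort(arr, axis=0)
        bad = np.flatnonzero(~(sorted_cols == expected[:, None]).all(axis=0))
        if bad.size:
            raise ConfigurationError(
                f"column(s) {list(self.ranks.columns[bad[:5]])} are not "
                f"permutations of 1..{n}"
            )

    @property
    def n_genes(self) -> int:
        return len(self.ranks.index)

    @property
    def compound_ids(self) -> list[str]:
        return list(self.ranks.columns)

    def profile(self, compound_id: str):
        from .connectivity import RankedProfile

        return RankedProfile(
            gene_ids=tuple(self.ranks.index),
            ranks=self.ranks[compound_id].to_numpy(),
            compound_id=compound_id,
        )


def simulate_expression(
    cfg: ExpressionSimConfig,
) -> tuple[ExpressionMatrix, GroundTruth]:
    """Generate a two-group expression matrix with planted DEGs.

    Group ``A`` is the reference; planted up genes have a group-B linear
    mean of ``effect_fc`` times their group-A mean (before noise), planted
    down genes the reciprocal factor.
    """
    rng = np.random.default_rng(cfg.seed)
    genes = gene_universe(cfg.n_genes)
    n_planted = cfg.n_deg_up + cfg.n_deg_down
    planted_idx = rng.choice(cfg.n_genes, size=n_planted, replace=False)
    up_idx = planted_idx[: cfg.n_deg_up]
    down_idx = planted_idx[cfg.n_deg_up :]

    baseline = rng.normal(cfg.baseline_log2_mean, cfg.baseline_log2_sd, cfg.n_genes)
    shift = np.zeros(cfg.n_genes)
    shift[up_idx] = math.log2(cfg.effect_fc)
    shift[down_idx] = -math.log2(cfg.effect_fc)

    k = cfg.n_per_group
    log2_means = np.column_stack(
        [np.tile(baseline, (k, 1)).T, np.tile(baseline + shift, (k, 1)).T]
    )
    noise = rng.normal(0.0, cfg.noise_sd, size=log2_means.shape)
    values = np.exp2(log2_means + noise)

    samples = [f"A{i}" for i in range(1, k + 1)] + [f"B{i}" for i in range(1, k + 1)]
    condition = pd.Series(["A"] * k + ["B"] * k, index=samples, name="group")
    matrix = ExpressionMatrix(
        values=pd.DataFrame(values, index=genes, columns=samples),
        condition=condition,
        reference="A",
    )
    truth = GroundTruth(
        deg_up_ids=tuple(sorted(genes[i] for i in up_idx)),
        deg_down_ids=tuple(sorted(genes[i] for i in down_idx)),
    )
    return matrix, truth


def _planted_profile(
    rng: np.random.Generator,
    universe: np.ndarray,
    index_of: dict[str, int],
    up_members: tuple[str, ...],
    down_members: tuple[str, ...],
    strength: float,
    mirror: bool,
) -> np.ndarray:
    """Rank vector for one planted compound (reverser, or mimicker if mirror)."""
    n = universe.size
    s_up = math.ceil(strength * len(up_members))
    s_down = math.ceil(strength * len(down_members))
    chosen_up = rng.choice(np.array(up_members), size=s_up, replace=False)
    chosen_down = rng.choice(np.array(down_members), size=s_down, replace=False)
    if mirror:
        top_genes, bottom_genes = chosen_down, chosen_up
    else:
        top_genes, bottom_genes = chosen_up, chosen_down

    ranks = np.empty(n, dtype=np.int64)
    forced = np.zeros(n, dtype=bool)
    top_idx = np.array([index_of[g] for g in top_genes], dtype=np.int64)
    bottom_idx = np.array([index_of[g] for g in bottom_genes], dtype=np.int64)
    ranks[top_idx] = rng.permutation(len(top_idx)) + 1
    ranks[bottom_idx] = n - rng.permutation(len(bottom_idx))
    forced[top_idx] = True
    forced[bottom_idx] = True
    free = np.flatnonzero(~forced)
    free_ranks = np.arange(len(top_idx) + 1, n - len(bottom_idx) + 1)
    ranks[free] = rng.permutation(free_ranks)
    return ranks


def simulate_ctp_library(
    cfg: LibrarySimConfig,
    signature: SignaturePair,
    gene_ids: list[str] | None = None,
) -> tuple[CTPLibrary, GroundTruth]:
    """Generate a CTP library with planted signature-reversers and mimickers.

    Parameters
    ----------
    cfg
        Library dimensions, planted counts, strength and seed.
    signature
        The query signature whose reversal is planted; every member must
        exist in the universe.
    gene_ids
        The gene universe; defaults to :func:`gene_universe(cfg.n_genes)`.

    Planted compounds are assigned to randomly chosen library positions;
    their identifiers are reported in the returned :class:`GroundTruth`.
    """
    universe = np.array(gene_ids if gene_ids is not None else gene_universe(cfg.n_genes))
    if universe.size != cfg.n_genes:
        raise ConfigurationError(
            f"gene_ids length {universe.size} does not match cfg.n_genes {cfg.n_genes}"
        )
    index_of = {g: i for i, g in enumerate(universe)}
    missing = [m for m in (*signature.up.members, *signature.down.members)
               if m not in index_of]
    if missing:
        raise UniverseError(
            f"signature gene(s) absent from the library universe: {missing[:10]}"
        )

    rng = np.random.default_rng(cfg.seed)
    width = len(str(cfg.n_compounds))
    compounds = [f"c{i:0{width}d}" for i in range(1, cfg.n_compounds + 1)]
    n_planted = cfg.n_reversers + cfg.n_mimickers
    planted_pos = rng.choice(cfg.n_compounds, size=n_planted, replace=False)
    reverser_pos = set(planted_pos[: cfg.n_reversers].tolist())
    mimicker_pos = set(planted_pos[cfg.n_reversers :].tolist())

    ranks = np.empty((cfg.n_genes, cfg.n_compounds), dtype=np.int64)
    base = np.arange(1, cfg.n_genes + 1)
    for j in range(cfg.n_compounds):
        if j in reverser_pos or j in mimicker_pos:
            ranks[:, j] = _planted_profile(
                rng, universe, index_of,
                signature.up.members, signature.down.members,
                cfg.strength, mirror=j in mimicker_pos,
            )
        else:
            ranks[:, j] = rng.permutation(base)

    library = CTPLibrary(pd.DataFrame(ranks, index=universe, columns=compounds))
    truth = GroundTruth(
        reverser_ids=tuple(sorted(compounds[j] for j in reverser_pos)),
        mimicker_ids=tuple(sorted(compounds[j] for j in mimicker_pos)),
    )
    return library, truth


def recovery_rate(
    ranking: list[str], truth: GroundTruth, k: int
) -> float:
    """Fraction of planted reversers recovered in the top-``k`` of a ranking."""
    if not truth.reverser_ids:
        raise UndefinedMetricError(
            "recovery rate undefined: no reversers planted in the ground truth"
        )
    if k < 1 or k > len(ranking):
        raise ConfigurationError(
            f"k must lie in 1..{len(ranking)}, got {k}"
        )
    top = set(ranking[:k])
    hits = sum(1 for r in truth.reverser_ids if r in top)
    return hits / len(truth.reverser_ids)
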