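"""Differential-expression signature extraction from a two-condition matrix.

Given linear-scale expression values for two groups of replicates, each gene
gets a fold change (ratio of non-reference to reference group mean on the
linear scale) and a two-sided pooled-variance Student's t-test P value.
Genes pass as *up* when ``fold_change > fc_threshold`` and
``p < p_threshold`` (strict inequalities), as *down* when
``fold_change < 1/fc_threshold`` and ``p < p_threshold``, otherwise *none*.
Defaults are fold change > 2 and P < 0.05 with no multiple-testing
correction; Benjamini–Hochberg adjustment is available as an opt-in.

Degenerate variance (all replicates identical in both groups) is resolved
explicitly: equal means give P = 1, unequal means give the smallest positive
float with a logged warning, so noiseless simulated inputs never crash.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .connectivity import GeneSet
from .errors import ConfigurationError

logger = logging.getLogger(__name__)

__all__ = [
    "ExpressionMatrix",
    "SignaturePair",
    "compute_deg",
    "extract_signature",
]


@dataclass
class ExpressionMatrix:
    """Genes x samples linear-scale expression with a two-level condition.

    Attributes
    ----------
    values
        DataFrame, index = unique gene identifiers, columns = sample
        identifiers, non-negative linear-scale values.
    condition
        Series mapping every sample to one of exactly two group labels.
    reference
        The reference (denominator) condition level.
    """

    values: pd.DataFrame
    condition: pd.Series
    reference: str

    def __post_init__(self):
        if self.values.index.has_duplicates:
            dups = self.values.index[self.values.index.duplicated()].unique().tolist()
            raise ConfigurationError(f"duplicate gene identifiers: {dups[:5]}")
        if (np.asarray(self.values, dtype=float) < 0).any():
            raise ConfigurationError("expression values must be non-negative")
        missing = set(self.values.columns) - set(self.condition.index)
        if missing:
            raise ConfigurationError(f"samples without a condition label: {sorted(missing)}")
        self.condition = self.condition.loc[self.values.columns]
        levels = sorted(self.condition.unique())
        if len(levels) != 2:
            raise ConfigurationError(f"expected exactly two condition levels, got {levels}")
        if self.reference not in levels:
            raise ConfigurationError(
                f"reference level {self.reference!r} not among condition levels {levels}"
            )
        counts = self.condition.value_counts()
        if (counts < 2).any():
            raise ConfigurationError(
                "each condition level needs >= 2 samples for the t-test; "
                f"got {counts.to_dict()}"
            )

    @property
    def other(self) -> str:
        """The non-reference condition level."""
        return next(l for l in self.condition.unique() if l != self.reference)

    def group_values(self, level: str) -> np.ndarray:
        cols = self.condition.index[self.condition == level]
        return self.values[cols].to_numpy(dtype=float)


@dataclass(frozen=True)
class SignaturePair:
    """An (up-set, down-set) differential-expression query signature."""

    up: GeneSet
    down: GeneSet
    provenance: str = ""

    def __post_init__(self):
        overlap = set(self.up.members) & set(self.down.members)
        if overlap:
            raise ConfigurationError(
                f"up and down sets overlap: {sorted(overlap)[:5]}"
            )

    def flipped(self) -> "SignaturePair":
        """Swap the roles of the up and down sets (orientation flip)."""
        return SignaturePair(
            up=GeneSet(self.down.name, self.down.members),
            down=GeneSet(self.up.name, self.up.members),
            provenance=self.provenance + " [orientation flipped]",
        )


def _pooled_t_pvalues(b: np.ndarray, a: np.ndarray) -> np.ndarray:
    """Two-sided pooled (equal-variance) two-sample t-test P values per row.

    Rows where the pooled variance vanishes are handled by the degenerate
    rule: equal means -> P = 1; unequal means -> smallest positive float.
    """
    na, nb = a.shape[1], b.shape[1]
    mean_a, mean_b = a.mean(axis=1), b.mean(axis=1)
    var_a = a.var(axis=1, ddof=1)
    var_b = b.var(axis=1, ddof=1)
    df = na + nb - 2
    pooled = ((na - 1) * var_a + (nb - 1) * var_b) / df
    se = np.sqrt(pooled * (1.0 / na + 1.0 / nb))
    with np.errstate(divide="ignore", invalid="ignore"):
        tstat = (mean_b - mean_a) / se
    p = np.empty(len(mean_a))
    ok = se > 0
    p[ok] = 2.0 * stats.t.sf(np.abs(tstat[ok]), df)
    degenerate = ~ok
    if degenerate.any():
        equal = degenerate & np.isclose(mean_a, mean_b, rtol=0, atol=0)
        p[equal] = 1.0
        hard = degenerate & ~equal
        if hard.any():
            logger.warning(
                "%d gene(s) with zero pooled variance but unequal means; "
                "P set to the smallest positive float",
                int(hard.sum()),
            )
            p[hard] = np.finfo(float).tiny
    return p


def compute_deg(
    expr: ExpressionMatrix,
    fc_threshold: float = 2.0,
    p_threshold: float = 0.05,
    fdr: bool = False,
) -> pd.DataFrame:
    """Call differentially expressed genes between the two conditions.

    Parameters
    ----------
    expr
        The expression matrix with its condition labels.
    fc_threshold
        Linear fold-change cutoff (> 1); a gene is a candidate *up* gene when
        its fold change strictly exceeds this value, *down* when it falls
        strictly below its reciprocal.
    p_threshold
        Raw (or BH-adjusted, see ``fdr``) P-value cutoff, strict.
    fdr
        When True, apply Benjamini–Hochberg adjustment before thresholding
        and report the adjusted values in an extra ``p_adjusted`` column.

    Returns
    -------
    DataFrame indexed by gene with columns ``fold_change``, ``log2_fc``,
    ``p_value``, ``direction`` (and ``p_adjusted`` when ``fdr``).
    """
    if fc_threshold <= 1:
        raise ConfigurationError(f"fc_threshold must exceed 1, got {fc_threshold}")
    if not 0 < p_threshold <= 1:
        raise ConfigurationError(f"p_threshold must lie in (0, 1], got {p_threshold}")

    a = expr.group_values(expr.reference)
    b = expr.group_values(expr.other)
    mean_a, mean_b = a.mean(axis=1), b.mean(axis=1)

    with np.errstate(divide="ignore", invalid="ignore"):
        fc = mean_b / mean_a
    both_zero = (mean_a == 0) & (mean_b == 0)
    fc[both_zero] = 1.0  # identically silent gene: no change by convention
    with np.errstate(divide="ignore"):
        log2_fc = np.log2(fc)

    p = _pooled_t_pvalues(b, a)
    p_effective = p
    table = pd.DataFrame(
        {"fold_change": fc, "log2_fc": log2_fc, "p_value": p},
        index=expr.values.index,
    )
    if fdr:
        from statsmodels.stats.multitest import multipletests

        p_effective = multipletests(p, method="fdr_bh")[1]
        table["p_adjusted"] = p_effective

    up = (fc > fc_threshold) & (p_effective < p_threshold)
    down = (fc < 1.0 / fc_threshold) & (p_effective < p_threshold)
    direction = np.where(up, "up", np.where(down, "down", "none"))
    table["direction"] = direction
    return table


def extract_signature(deg: pd.DataFrame, provenance: str = "") -> SignaturePair:
    """Build the (up, down) query signature from a DEG table.

    Membership is exactly the genes called ``up`` / ``down``; each set is
    ordered by ascending gene identifier so the output is deterministic.
    Empty sets are permitted here and rejected only at scoring time.
    """
    up_genes = tuple(sorted(deg.index[deg["direction"] == "up"]))
    down_genes = tuple(sorted(deg.index[deg["direction"] == "down"]))
    return SignaturePair(
        up=GeneSet("up", up_genes),
        down=GeneSet("down", down_genes),
        provenance=provenance,
    )
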