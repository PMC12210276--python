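"""Gene-set overlap, rescue, and redundancy-pruning statistics.

Overlap between two gene lists over a common universe is summarized by the
cross-product odds ratio of the 2x2 contingency table with a two-sided Fisher
exact p-value. "Rescue" classifies stress-induced differential genes whose
change reverses under an intervention contrast. Redundant gene sets in a
collection are removed by iterative Jaccard pruning (threshold 0.5,
preferentially keeping the bigger set).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .datamodel import GeneSetCollection, ValidationError

__all__ = [
    "OverlapResult",
    "RescueReport",
    "overlap_odds_ratio",
    "rescue_fraction",
    "jaccard_prune",
    "jaccard",
]


@dataclass
class OverlapResult:
    a: int  # |A and B|
    b: int  # |A minus B|
    c: int  # |B minus A|
    d: int  # |universe minus (A or B)|
    odds_ratio: float
    p_value: float


def overlap_odds_ratio(set_a, set_b, universe) -> OverlapResult:
    """Cross-product odds ratio ad/bc of the overlap 2x2 table with two-sided
    Fisher exact p (hypergeometric tail summation); OR is inf when bc = 0 and
    ad > 0, and 0 when ad = 0 with bc > 0."""
    universe = set(universe)
    if not universe:
        raise ValidationError("empty universe")
    A, B = set(set_a), set(set_b)
    if not A <= universe or not B <= universe:
        raise ValidationError("sets must be subsets of the universe")
    a = len(A & B)
    b = len(A - B)
    c = len(B - A)
    d = len(universe) - a - b - c
    ad, bc = a * d, b * c
    if bc == 0:
        odds = float("inf") if ad > 0 else 0.0
    else:
        odds = ad / bc
    p = float(stats.fisher_exact([[a, b], [c, d]], alternative="two-sided")[1])
    return OverlapResult(a=a, b=b, c=c, d=d, odds_ratio=odds, p_value=p)


@dataclass
class RescueReport:
    n_stress_degs: int
    n_rescued: int
    fraction_rescued: float
    by_direction: pd.DataFrame  # index up/down -> n_degs, n_rescued, fraction


def rescue_fraction(
    stress_de: pd.DataFrame,
    rescue_de: pd.DataFrame,
    fdr: float = 0.1,
    require_significance: bool = True,
) -> RescueReport:
    """Fraction of stress DEGs reversed by the intervention contrast.

    Both tables need ``log2_effect`` and ``q_value`` columns indexed by gene.
    A stress DEG (q < fdr) counts as rescued when the rescue contrast shows an
    opposite-sign effect that is itself significant at the same FDR; with
    ``require_significance=False`` sign reversal alone suffices. Fractions are
    reported overall and stratified by the stress direction.
    """
    shared = stress_de.index.intersection(rescue_de.index)
    if shared.empty:
        raise ValidationError("no shared gene identifiers")
    s = stress_de.loc[shared]
    r = rescue_de.loc[shared]
    is_deg = s["q_value"] < fdr
    opposite = np.sign(s["log2_effect"]) * np.sign(r["log2_effect"]) < 0
    rescued = is_deg & opposite
    if require_significance:
        rescued &= r["q_value"] < fdr

    rows = []
    for direction, mask in (
        ("up", s["log2_effect"] > 0),
        ("down", s["log2_effect"] < 0),
    ):
        n_degs = int((is_deg & mask).sum())
        n_resc = int((rescued & mask).sum())
        rows.append(
            {
                "direction": direction,
                "n_degs": n_degs,
                "n_rescued": n_resc,
                "fraction": n_resc / n_degs if n_degs else float("nan"),
            }
        )
    n_degs = int(is_deg.sum())
    n_resc = int(rescued.sum())
    return RescueReport(
        n_stress_degs=n_degs,
        n_rescued=n_resc,
        fraction_rescued=n_resc / n_degs if n_degs else float("nan"),
        by_direction=pd.DataFrame(rows).set_index("direction"),
    )


def jaccard(a: set, b: set) -> float:
    union = len(a | b)
    return len(a & b) / union if union else 0.0


def jaccard_prune(
    collection: GeneSetCollection, threshold: float = 0.5
) -> GeneSetCollection:
    """Iteratively drop the smaller member of the most similar pair until every
    pairwise Jaccard index is below the threshold.

    At each step the pair with maximal Jaccard >= threshold is found and its
    smaller set removed (ties on size remove the lexicographically later
    name; ties on Jaccard resolve to the lexicographically first pair), so the
    result is deterministic and idempotent.
    """
    if not 0 < threshold <= 1:
        raise ValidationError("threshold must be in (0, 1]")
    sets = {name: set(genes) for name, genes in collection.sets.items()}
    while True:
        names = sorted(sets)
        best = None  # (jaccard, name_i, name_j)
        for i in range(len(names)):
            for j in range(i + 1, len(names)):
                jac = jaccard(sets[names[i]], sets[names[j]])
                if jac >= threshold and (best is None or jac > best[0]):
                    best = (jac, names[i], names[j])
        if best is None:
            break
        _, ni, nj = best
        if len(sets[ni]) > len(sets[nj]):
            drop = nj
        elif len(sets[ni]) < len(sets[nj]):
            drop = ni
        else:
            drop = max(ni, nj)
        del sets[drop]
    return GeneSetCollection(universe=set(collection.universe), sets=sets)
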