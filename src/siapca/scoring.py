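"""Nucleobase-preference scores from PCA projections.

The per-pool score is the distance between the free spectrum and one bound
spectrum along a chosen principal component, computed as

    score(base) = |projection_free| − |projection_bound(base)|

on that component. The second component is the default: across ensembles the
first is dominated by overall intensity (the bound samples are diluted), and
the second is the one whose projections track chemical-shift changes.
Rankings use |score| — component signs are an arbitrary convention, so
magnitude of separation is the robust ordering — while the signed value is
kept for reporting.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Tuple

import numpy as np
import pandas as pd

from .nipals import PCAResult, pca_ensemble, variance_table
from .spectra import BASES, EnsembleStack

__all__ = [
    "PreferenceTable",
    "ReliabilityFlag",
    "pca_pool_score",
    "rank_bases",
    "reliability_check",
    "pca_preference_table",
]


def pca_pool_score(result: PCAResult, component: int = 2) -> Dict[str, float]:
    """Per-base separation from the free spectrum on one component.

    ``component`` is 1-based. The result's plane labels must follow the
    canonical [free, A, C, G, U] order.
    """
    proj = result.projections(component)  # raises if out of range
    labels = list(result.plane_labels)
    free = abs(proj[labels.index("free")])
    return {base: free - abs(proj[labels.index(base)]) for base in BASES}


def rank_bases(scores: Mapping[str, float]) -> Tuple[List[str], bool]:
    """Bases by decreasing |score|; ties broken alphabetically and flagged.

    Larger separation from the free spectrum means larger average shifts,
    hence greater average affinity of that pool.
    """
    missing = [b for b in BASES if b not in scores]
    if missing:
        raise ValueError(f"scores missing base(s) {missing}")
    order = sorted(BASES, key=lambda b: (-abs(scores[b]), b))
    mags = sorted((abs(scores[b]) for b in BASES), reverse=True)
    tied = any(np.isclose(a, b, rtol=0.0, atol=1e-12) for a, b in zip(mags, mags[1:]))
    return order, tied


@dataclass
class ReliabilityFlag:
    reliable: bool
    message: str


def reliability_check(result: PCAResult, ratio_threshold: float = 3.0) -> ReliabilityFlag:
    """Heuristic guard against ensembles where PC2 carries no signal.

    When few peaks respond to binding (small domains) the variance spreads
    evenly over the components and the shift-tracking role of the second
    component is lost. The ensemble is flagged unreliable when
    ``var(PC2) < ratio_threshold × var(PC3)``. The default threshold of 3
    is a heuristic calibrated to the anchored-basis variance structure,
    where even a signal-free ensemble gives PC2 roughly twice PC3's
    variance (the four bound planes share a residual direction); healthy
    ensembles sit well above it.
    """
    fractions = result.variance_fractions()
    if len(fractions) < 3:
        raise ValueError("reliability_check needs at least 3 components")
    v2, v3 = float(fractions[1]), float(fractions[2])
    if v2 < ratio_threshold * v3:
        return ReliabilityFlag(
            reliable=False,
            message=(
                f"variance is evenly spread: PC2 {100 * v2:.2f}% < "
                f"{ratio_threshold} x PC3 {100 * v3:.2f}% — few shifting peaks; "
                "prefer manual shift scoring"
            ),
        )
    return ReliabilityFlag(
        reliable=True,
        message=f"PC2 {100 * v2:.2f}% >= {ratio_threshold} x PC3 {100 * v3:.2f}%",
    )


@dataclass
class PreferenceTable:
    """Position × base preference scores with derived rankings.

    ``method`` is ``"pca"`` or ``"sia_manual"``. ``diagnostics`` carries,
    per position, the variance table, tie/reliability flags and (for PCA)
    the |free − bound| projection distances on every component — the raw
    material for cross-method correlation.
    """

    method: str
    scores: Dict[Tuple[int, str], float]
    component_used: Optional[int] = None
    diagnostics: Dict[int, dict] = field(default_factory=dict)

    def positions(self) -> List[int]:
        return sorted({pos for pos, _ in self.scores})

    def scores_at(self, position: int) -> Dict[str, float]:
        out = {b: self.scores[(position, b)] for b in BASES if (position, b) in self.scores}
        if len(out) != 4:
            raise ValueError(f"position {position} lacks scores for all four bases")
        return out

    def ranking(self, position: int) -> List[str]:
        order, _ = rank_bases(self.scores_at(position))
        return order

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for pos in self.positions():
            order, tied = rank_bases(self.scores_at(pos))
            flags = self.diagnostics.get(pos, {})
            reliable = flags.get("reliability")
            for base in BASES:
                rows.append(
                    {
                        "position": pos,
                        "base": base,
                        "score": self.scores[(pos, base)],
                        "abs_score": abs(self.scores[(pos, base)]),
                        "rank": order.index(base) + 1,
                        "tied": tied,
                        "reliable": "" if reliable is None else reliable.reliable,
                    }
                )
        return pd.DataFrame(rows)


def pca_preference_table(
    stacks: Mapping[int, EnsembleStack],
    component: int = 2,
    centering: str = "none",
    ratio_threshold: float = 3.0,
    tol: float = 1e-11,
    max_iter: int = 50_000,
) -> Tuple[PreferenceTable, Dict[int, PCAResult]]:
    """Run PCA independently per position and collect scores + diagnostics."""
    scores: Dict[Tuple[int, str], float] = {}
    diagnostics: Dict[int, dict] = {}
    results: Dict[int, PCAResult] = {}
    for position, stack in sorted(stacks.items()):
        result = pca_ensemble(stack, centering=centering, tol=tol, max_iter=max_iter)
        results[position] = result
        pool_scores = pca_pool_score(result, component=component)
        for base, s in pool_scores.items():
            scores[(position, base)] = s
        labels = list(result.plane_labels)
        component_distances = {
            k: {
                base: abs(
                    abs(result.projections(k)[labels.index("free")])
                    - abs(result.projections(k)[labels.index(base)])
                )
                for base in BASES
            }
            for k in range(1, len(result) + 1)
        }
        _, tied = rank_bases(pool_scores)
        diagnostics[position] = {
            "variance_table": variance_table(result),
            "reliability": reliability_check(result, ratio_threshold=ratio_threshold),
            "tied": tied,
            "component_distances": component_distances,
            "warnings": list(result.warnings),
        }
    return (
        PreferenceTable(
            method="pca",
            scores=scores,
            component_used=component,
            diagnostics=diagnostics,
        ),
        results,
    )
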