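"""Manual SIA scoring from tracked peak lists, and the PCA cross-check.

The manual procedure works on a handful of well-resolved amide peaks whose
positions can be measured accurately in all five spectra. For each selected
peak the combined (weighted) chemical-shift perturbation

    Δδ = sqrt(ΔδH² + (α · ΔδN)²),   α = 0.2 by default

is computed against each of the four pool complexes; the four values are
normalised by the peak's largest Δδ, and the normalised values are averaged
across peaks to give each pool a score in [0, 1]. The α factor rescales the
¹⁵N ppm range onto the ¹H one (community-standard amide weighting).

``compare_methods`` reproduces the cross-validation between this manual
score and the PCA score: rank agreement per position (Kendall τ) and, per
principal component, the correlation between projection distance and the
mean weighted shift — the diagnostic that singles out the second component
as the shift-tracking one.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Mapping, Sequence, Tuple

import numpy as np
from scipy import stats

from .errors import PairingError
from .scoring import PreferenceTable
from .spectra import BASES, PeakEntry, PeakList

__all__ = [
    "ShiftRecord",
    "ComparisonReport",
    "weighted_delta",
    "sia_scores",
    "sia_preference_table",
    "subset_sensitivity",
    "compare_methods",
]

DEFAULT_ALPHA = 0.2


def weighted_delta(free: PeakEntry, bound: PeakEntry, alpha: float = DEFAULT_ALPHA) -> float:
    """Weighted chemical-shift perturbation between one peak's free and
    bound positions, sqrt(ΔδH² + (α·ΔδN)²), in ¹H-equivalent ppm."""
    if free.assignment_id != bound.assignment_id:
        raise PairingError(
            f"assignment mismatch: {free.assignment_id!r} vs {bound.assignment_id!r}"
        )
    dh = bound.delta_h - free.delta_h
    dn = bound.delta_n - free.delta_n
    return float(np.hypot(dh, alpha * dn))


@dataclass
class ShiftRecord:
    """Per-peak perturbations against the four pools, raw and normalised."""

    assignment_id: str
    delta: Dict[str, float]  # base -> weighted Δδ (ppm)
    normalized: Dict[str, float]  # base -> Δδ / max over the four pools
    excluded: bool = False  # True when all four Δδ are zero


def _paired_entry(peaks: PeakList, pid: str, base: str) -> PeakEntry:
    try:
        return peaks.get(pid)
    except KeyError:
        raise PairingError(f"peak {pid!r} absent from the {base!r} pool list") from None


def sia_scores(
    free: PeakList,
    bound_by_base: Mapping[str, PeakList],
    selected_ids: Sequence[str],
    alpha: float = DEFAULT_ALPHA,
) -> Tuple[Dict[str, float], List[ShiftRecord]]:
    """Manual SIA scores for one position.

    Per selected peak, the four pool Δδ values are normalised by the peak's
    maximum; per base, the score is the mean of the normalised values over
    the selected peaks. Peaks whose Δδ is zero against every pool carry no
    ranking information and are excluded from the means (and flagged on
    their record).
    """
    if not selected_ids:
        raise ValueError("selected_ids must contain at least one peak")
    missing_pools = [b for b in BASES if b not in bound_by_base]
    if missing_pools:
        raise PairingError(f"missing bound peak lists for base(s) {missing_pools}")
    records: List[ShiftRecord] = []
    for pid in selected_ids:
        free_entry = _paired_entry(free, pid, "free")
        delta = {
            base: weighted_delta(free_entry, _paired_entry(bound_by_base[base], pid, base), alpha)
            for base in BASES
        }
        peak_max = max(delta.values())
        if peak_max == 0.0:
            records.append(
                ShiftRecord(pid, delta, {b: 0.0 for b in BASES}, excluded=True)
            )
        else:
            records.append(
                ShiftRecord(pid, delta, {b: d / peak_max for b, d in delta.items()})
            )
    used = [r for r in records if not r.excluded]
    if not used:
        scores = {b: 0.0 for b in BASES}
    else:
        scores = {b: float(np.mean([r.normalized[b] for r in used])) for b in BASES}
    return scores, records


def sia_preference_table(
    free_by_position: Mapping[int, PeakList],
    bound_by_position: Mapping[int, Mapping[str, PeakList]],
    selected_ids: Sequence[str],
    alpha: float = DEFAULT_ALPHA,
) -> PreferenceTable:
    """Manual SIA scores for every position, as a PreferenceTable.

    Diagnostics store, per position, the mean weighted Δδ per pool (over the
    selected peaks) and the per-peak shift records.
    """
    scores: Dict[Tuple[int, str], float] = {}
    diagnostics: Dict[int, dict] = {}
    for position in sorted(free_by_position):
        pos_scores, records = sia_scores(
            free_by_position[position], bound_by_position[position], selected_ids, alpha
        )
        for base, s in pos_scores.items():
            scores[(position, base)] = s
        used = [r for r in records if not r.excluded]
        mean_delta = {
            base: float(np.mean([r.delta[base] for r in used])) if used else 0.0
            for base in BASES
        }
        diagnostics[position] = {
            "mean_delta": mean_delta,
            "records": records,
            "excluded_ids": [r.assignment_id for r in records if r.excluded],
        }
    return PreferenceTable(method="sia_manual", scores=scores, diagnostics=diagnostics)


def subset_sensitivity(
    free: PeakList,
    bound_by_base: Mapping[str, PeakList],
    id_subsets: Sequence[Sequence[str]],
    alpha: float = DEFAULT_ALPHA,
) -> Dict[str, float]:
    """How much the manual score depends on which peaks were picked.

    Computes the scores for each id subset and reports, per base, the
    maximum absolute pairwise difference — the peak-selection bias that a
    whole-spectrum analysis avoids.
    """
    if len(id_subsets) < 2:
        raise ValueError("need at least two id subsets to compare")
    per_subset = [sia_scores(free, bound_by_base, ids, alpha)[0] for ids in id_subsets]
    out: Dict[str, float] = {}
    for base in BASES:
        vals = [s[base] for s in per_subset]
        out[base] = float(max(vals) - min(vals))
    return out


def _ranking_to_ranks(order: Sequence[str]) -> List[int]:
    return [order.index(b) for b in BASES]


@dataclass
class ComparisonReport:
    """Agreement between the PCA-based and manual preference tables."""

    kendall_tau: Dict[int, float]  # position -> tau between base rankings
    exact_match: Dict[int, bool]
    component_correlation: Dict[int, float]  # component -> pooled Pearson r
    per_position_correlation: Dict[int, Dict[int, float]]  # pos -> comp -> r

    def best_component(self) -> int:
        return max(self.component_correlation, key=lambda k: self.component_correlation[k])

    def to_dict(self) -> dict:
        return {
            "kendall_tau": {str(k): v for k, v in self.kendall_tau.items()},
            "exact_match": {str(k): v for k, v in self.exact_match.items()},
            "component_correlation": {
                str(k): v for k, v in self.component_correlation.items()
            },
            "per_position_correlation": {
                str(p): {str(c): r for c, r in comps.items()}
                for p, comps in self.per_position_correlation.items()
            },
            "best_component": self.best_component(),
        }


def compare_methods(
    pca_table: PreferenceTable, sia_table: PreferenceTable
) -> ComparisonReport:
    """Cross-validate the PCA scores against the manual SIA scores.

    Per position: Kendall τ between the two base rankings (and an
    exact-match flag). Per principal component: Pearson correlation between
    the |free − bound| projection distance and the mean weighted Δδ of each
    pool, pooled over all positions × pools; also reported per position.
    Requires the PCA table's ``component_distances`` and the SIA table's
    ``mean_delta`` diagnostics.
    """
    pos_pca = pca_table.positions()
    if pos_pca != sia_table.positions():
        raise ValueError(
            f"position mismatch: pca={pos_pca} vs sia={sia_table.positions()}"
        )
    tau: Dict[int, float] = {}
    exact: Dict[int, bool] = {}
    for pos in pos_pca:
        r1 = _ranking_to_ranks(pca_table.ranking(pos))
        r2 = _ranking_to_ranks(sia_table.ranking(pos))
        tau[pos] = float(stats.kendalltau(r1, r2).statistic)
        exact[pos] = r1 == r2
    # correlation of per-pool PCA distance vs mean weighted shift, per component
    comp_indices = sorted(
        pca_table.diagnostics[pos_pca[0]]["component_distances"]
    )
    pooled: Dict[int, float] = {}
    per_position: Dict[int, Dict[int, float]] = {p: {} for p in pos_pca}
    for k in comp_indices:
        xs: List[float] = []
        ys: List[float] = []
        for pos in pos_pca:
            dist = pca_table.diagnostics[pos]["component_distances"][k]
            mean_delta = sia_table.diagnostics[pos]["mean_delta"]
            x = [dist[b] for b in BASES]
            y = [mean_delta[b] for b in BASES]
            xs.extend(x)
            ys.extend(y)
            per_position[pos][k] = _safe_pearson(x, y)
        pooled[k] = _safe_pearson(xs, ys)
    return ComparisonReport(
        kendall_tau=tau,
        exact_match=exact,
        component_correlation=pooled,
        per_position_correlation=per_position,
    )


def _safe_pearson(x: Sequence[float], y: Sequence[float]) -> float:
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if np.std(x) == 0.0 or np.std(y) == 0.0:
        return float("nan")
    return float(stats.pearsonr(x, y).statistic)
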