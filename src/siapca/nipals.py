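"""NIPALS principal component analysis of five-spectrum ensembles.

Each ensemble (free protein + four pool complexes) is flattened into a
5 × (n1·n2) data matrix, one spectrum per row, and decomposed sequentially:
for component *k*, alternate

    p ← Xᵀt / tᵀt,  p ← p / ‖p‖,  t ← Xp

until the per-spectrum projection vector ``t`` stabilises, then deflate
``X ← X − t pᵀ`` and continue. The per-spectrum projections are what the
field calls the spectra's "loadings" on a component; with spectra as rows
they are conventionally *scores*, so this package calls them projections
throughout and keeps the eigen-spectra (the length-n1·n2 unit vectors) as
the components' spatial patterns.

By default no mean is subtracted, and the first basis vector is *anchored*
to the free-protein spectrum: component 1 is the unit vector along the
reference row (so it carries the shared overall intensity, including the
dilution of the bound samples), and NIPALS extracts the remaining
components from the residual after projecting the reference direction out.
Anchoring puts the free spectrum at exactly zero on every later component,
which is what makes the |free| − |bound| separation on component 2 a
monotone readout of how far each pool drags the spectrum: without it the
second-component coordinates of a one-parameter family of spectra straddle
their own mean and the separation score loses monotonicity. Five input
spectra still yield five components. Plain (unanchored) NIPALS and mean-
or reference-centering of the data matrix remain available.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Optional, Tuple

import numpy as np
import pandas as pd

from .errors import DegenerateInputError
from .spectra import PLANE_ORDER, EnsembleStack

__all__ = [
    "PCAComponent",
    "PCAResult",
    "build_data_matrix",
    "nipals_pca",
    "pca_ensemble",
    "variance_table",
]

CENTERING_MODES = ("none", "mean", "reference")


@dataclass
class PCAComponent:
    """One principal component of a spectral ensemble."""

    eigen_spectrum: np.ndarray  # unit-norm, length n1·n2
    projections: np.ndarray  # one value per input spectrum
    variance_fraction: float


@dataclass
class PCAResult:
    """Ordered components plus the bookkeeping needed to interpret them."""

    components: List[PCAComponent]
    centering: str
    n_input_spectra: int
    plane_labels: Tuple[str, ...] = PLANE_ORDER
    anchored: bool = False  # component 1 fixed to the reference direction
    warnings: List[str] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.components)

    def projections(self, component: int) -> np.ndarray:
        """Per-spectrum projections on a 1-based component index."""
        if not 1 <= component <= len(self.components):
            raise IndexError(
                f"component {component} out of range 1..{len(self.components)}"
            )
        return self.components[component - 1].projections

    def variance_fractions(self) -> np.ndarray:
        return np.array([c.variance_fraction for c in self.components])

    def to_frame(self) -> pd.DataFrame:
        """Tabular export: one row per component."""
        rows = []
        for k, comp in enumerate(self.components, start=1):
            row = {"component": k, "variance_pct": 100.0 * comp.variance_fraction}
            for label, proj in zip(self.plane_labels, comp.projections):
                row[f"proj_{label}"] = proj
            rows.append(row)
        return pd.DataFrame(rows)


def build_data_matrix(
    stack: EnsembleStack, centering: str = "none"
) -> Tuple[np.ndarray, str]:
    """Flatten an ensemble into the PCA data matrix.

    Rows are the planes in order [free, A, C, G, U], each flattened
    row-major. ``centering`` is ``none`` (rows untouched), ``mean``
    (subtract the across-spectra mean vector) or ``reference`` (subtract
    the free-protein row from every row).
    """
    if centering not in CENTERING_MODES:
        raise ValueError(f"centering must be one of {CENTERING_MODES}, got {centering!r}")
    rows = [plane.intensities.ravel(order="C") for plane in stack.planes()]
    matrix = np.vstack(rows).astype(float)
    if centering == "mean":
        matrix = matrix - matrix.mean(axis=0, keepdims=True)
    elif centering == "reference":
        matrix = matrix - matrix[0:1, :]
    return matrix, centering


def _orthonormal_filler(
    previous: List[np.ndarray], n_cols: int, rng_index: int
) -> np.ndarray:
    """Unit vector orthogonal to all ``previous`` eigen-spectra.

    Used for components beyond the matrix rank, where the deflated residual
    is numerically zero and NIPALS has no direction to find: Gram–Schmidt
    on canonical basis vectors keeps the returned set orthonormal.
    """
    for j in range(rng_index, n_cols):
        v = np.zeros(n_cols)
        v[j] = 1.0
        for p in previous:
            v -= (p @ v) * p
        norm = np.linalg.norm(v)
        if norm > 1e-8:
            return v / norm
    raise DegenerateInputError("cannot extend eigen-spectra to an orthonormal set")


def nipals_pca(
    matrix: np.ndarray,
    n_components: Optional[int] = None,
    tol: float = 1e-11,
    max_iter: int = 50_000,
    centering: str = "none",
    anchor_first_row: bool = False,
) -> PCAResult:
    """Sequential NIPALS decomposition of a spectra-as-rows matrix.

    Parameters
    ----------
    matrix
        Real matrix, one spectrum per row (already centered as desired).
    n_components
        Number of components to extract; defaults to ``min(rows, cols)``.
    tol
        Relative convergence tolerance on the projection vector.
    max_iter
        Iteration cap per component; hitting it records a warning on the
        result rather than raising.
    centering
        Recorded on the result for provenance only.
    anchor_first_row
        When True, component 1 is fixed to the unit vector along the first
        (reference) row rather than found iteratively; NIPALS then runs on
        the residual. Requires a nonzero first row.

    The sign of each component is fixed so the first spectrum's projection
    is ≥ 0 (falling back to the first projection clearly above rounding
    noise when the first is zero). Variance fractions are sums of squared
    projections over the total sum of squares of the input matrix, so they
    sum to ≤ 1 and are comparable with "% variance" tables.
    """
    X = np.asarray(matrix, dtype=float)
    if X.ndim != 2:
        raise ValueError("nipals_pca expects a 2D matrix")
    n_rows, n_cols = X.shape
    max_rank = min(n_rows, n_cols)
    if n_components is None:
        n_components = max_rank
    if not 1 <= n_components <= max_rank:
        raise ValueError(
            f"n_components must lie in 1..{max_rank}, got {n_components}"
        )
    if tol <= 0:
        raise ValueError("tol must be > 0")
    total_ss = float(np.sum(X * X))
    if total_ss == 0.0:
        raise DegenerateInputError("input matrix is identically zero")

    R = X.copy()
    components: List[PCAComponent] = []
    eigen: List[np.ndarray] = []
    warnings: List[str] = []
    start = 0
    if anchor_first_row:
        ref_norm = np.linalg.norm(X[0])
        if ref_norm <= 1e-12 * np.sqrt(total_ss):
            raise DegenerateInputError(
                "cannot anchor the basis to a (numerically) zero reference row"
            )
        p = X[0] / ref_norm
        t = R @ p
        if t[0] < 0:  # sign convention: reference projection >= 0
            t, p = -t, -p
        R = R - np.outer(t, p)
        eigen.append(p)
        components.append(
            PCAComponent(
                eigen_spectrum=p,
                projections=t,
                variance_fraction=float(t @ t) / total_ss,
            )
        )
        start = 1
    for k in range(start, n_components):
        resid_ss = float(np.sum(R * R))
        if resid_ss <= 1e-24 * total_ss:
            p = _orthonormal_filler(eigen, n_cols, rng_index=0)
            t = R @ p
        else:
            t = R[:, int(np.argmax(np.sum(R * R, axis=0)))].copy()
            # The NIPALS update t <- R Rᵀ t / tᵀt only ever touches the row
            # space, so iterate on the precomputed Gram matrix: identical
            # iterates to the textbook p/t alternation, at O(rows²) per step
            # instead of O(rows x cols), which lets near-degenerate
            # components run to convergence.
            G = R @ R.T
            converged = False
            for _ in range(max_iter):
                # t <- R p with p = normalize(R' t / t't); in the row space
                # this is exactly G t / sqrt(t' G t)
                Gt = G @ t
                t_new = Gt / max(np.sqrt(float(t @ Gt)), 1e-300)
                if np.linalg.norm(t_new - t) <= tol * max(np.linalg.norm(t_new), 1e-300):
                    t = t_new
                    converged = True
                    break
                t = t_new
            if not converged:
                warnings.append(
                    f"component {k + 1}: NIPALS did not converge in {max_iter} iterations"
                )
            p = R.T @ t / float(t @ t)
            # re-orthogonalise against earlier components: keeps the
            # returned eigen-spectra orthonormal to tight tolerance
            for q in eigen:
                p -= (q @ p) * q
            norm = np.linalg.norm(p)
            if norm == 0.0:
                p = _orthonormal_filler(eigen, n_cols, rng_index=0)
            else:
                p /= norm
            t = R @ p
        # deterministic sign: reference (first) projection >= 0
        scale = float(np.max(np.abs(t))) if np.any(t) else 0.0
        pivot = 0
        if scale > 0 and abs(t[0]) <= 1e-12 * scale:
            nz = np.nonzero(np.abs(t) > 1e-12 * scale)[0]
            if nz.size:
                pivot = int(nz[0])
        if t[pivot] < 0:
            t = -t
            p = -p
        R = R - np.outer(t, p)
        eigen.append(p)
        components.append(
            PCAComponent(
                eigen_spectrum=p,
                projections=t,
                variance_fraction=float(t @ t) / total_ss,
            )
        )
    return PCAResult(
        components=components,
        centering=centering,
        n_input_spectra=n_rows,
        anchored=anchor_first_row,
        warnings=warnings,
    )


def pca_ensemble(
    stack: EnsembleStack,
    centering: str = "none",
    n_components: Optional[int] = None,
    tol: float = 1e-11,
    max_iter: int = 50_000,
    anchor_reference: bool = True,
) -> PCAResult:
    """Decompose a five-plane ensemble: flatten, (optionally) center, NIPALS.

    The default — no centering, first component anchored to the free
    spectrum — is the configuration under which the second component's
    projections track binding-induced shift magnitude. ``anchor_reference``
    is ignored (forced off) under reference centering, whose first row is
    identically zero.
    """
    matrix, mode = build_data_matrix(stack, centering=centering)
    anchor = anchor_reference and mode != "reference"
    result = nipals_pca(
        matrix,
        n_components=n_components,
        tol=tol,
        max_iter=max_iter,
        centering=mode,
        anchor_first_row=anchor,
    )
    result.plane_labels = stack.plane_labels
    return result


def variance_table(result: PCAResult) -> List[Tuple[int, float]]:
    """Per-component explained variance as ``(1-based index, percent)`` pairs."""
    return [
        (k, 100.0 * comp.variance_fraction)
        for k, comp in enumerate(result.components, start=1)
    ]
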