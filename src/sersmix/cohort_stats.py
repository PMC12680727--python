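"""Cohort-level band attribution: Spearman correlation against anchor
bands and centered (unscaled) principal component analysis.

Two bands whose intensities rise and fall together across donors very
likely belong to the same molecular species; rank (Spearman)
correlation against an anchor band (638 cm^-1 for uric acid,
725 cm^-1 for hypoxanthine) with a membership threshold of rho > 0.6
groups bands by their parent biomolecule.  PCA of the preprocessed
spectra shows how much inter-donor spectral variability each direction
explains; matching loadings against reference components (and signed
component differences) attributes that variability to metabolites.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.decomposition import PCA

from .core_io import SpectrumSet, WavenumberAxis
from .decompose import ComponentLibrary

__all__ = [
    "BandIntensityMatrix",
    "CorrelationReport",
    "PCAResult",
    "band_intensity_matrix",
    "spearman_with_anchor",
    "run_pca",
    "match_loadings",
]

DEFAULT_BAND_TOL = 3.0  # cm^-1 search window around a nominal band position
DEFAULT_RHO_THRESHOLD = 0.6


@dataclass
class BandIntensityMatrix:
    """Donor x band intensity table (preprocessed intensities)."""

    table: pd.DataFrame  # index: donor ids, columns: band positions (float)
    tol: float

    @property
    def positions(self) -> np.ndarray:
        return np.asarray(self.table.columns, dtype=float)

    def column(self, position: float) -> np.ndarray:
        return self.table[position].to_numpy()


def band_intensity_matrix(
    sset: SpectrumSet,
    positions,
    tol: float = DEFAULT_BAND_TOL,
) -> BandIntensityMatrix:
    """Extract per-donor band intensities.

    Each entry is the maximum intensity within +-tol cm^-1 of the
    nominal position (tol = 0 reads the exact grid point), absorbing
    small instrument-to-instrument shifts.
    """
    positions = np.sort(np.asarray(positions, dtype=float))
    axis = sset.common_axis
    for p in positions:
        if p < axis.lo or p > axis.hi:
            raise ValueError(f"band position {p} outside axis [{axis.lo}, {axis.hi}]")
    matrix = sset.to_matrix()
    cols = {}
    for p in positions:
        mask = np.abs(axis.values - p) <= tol
        if not mask.any():
            mask = np.zeros(len(axis), dtype=bool)
            mask[axis.nearest_index(p)] = True
        cols[float(p)] = matrix[:, mask].max(axis=1)
    table = pd.DataFrame(cols, index=sset.ids())
    return BandIntensityMatrix(table, tol)


@dataclass
class CorrelationReport:
    """Spearman correlation of every band against an anchor band."""

    anchor: float
    table: pd.DataFrame  # columns: band, rho, member, valid
    threshold: float

    def rho(self, band: float) -> float:
        return float(self.table.set_index("band").loc[band, "rho"])

    def members(self) -> np.ndarray:
        t = self.table
        return t.loc[t["member"], "band"].to_numpy()


def spearman_with_anchor(
    matrix: BandIntensityMatrix,
    anchor: float,
    threshold: float = DEFAULT_RHO_THRESHOLD,
) -> CorrelationReport:
    """Rank-correlate each band column against the anchor band.

    Bands with rho > threshold are flagged as members of the anchor's
    group.  Constant columns have undefined rho; they are flagged
    invalid and excluded from membership.
    """
    if matrix.table.shape[0] < 3:
        raise ValueError("need at least 3 donors for rank correlation")
    positions = matrix.positions
    if float(anchor) not in set(positions.tolist()):
        raise ValueError(f"anchor {anchor} is not a column of the matrix")
    a = matrix.column(float(anchor))
    rows = []
    for p in positions:
        col = matrix.column(float(p))
        if np.all(col == col[0]) or np.all(a == a[0]):
            rows.append({"band": p, "rho": np.nan, "member": False, "valid": False})
            continue
        rho = stats.spearmanr(a, col).statistic
        rows.append(
            {"band": p, "rho": float(rho), "member": bool(rho > threshold), "valid": True}
        )
    return CorrelationReport(float(anchor), pd.DataFrame(rows), threshold)


@dataclass
class PCAResult:
    explained_variance_ratio: np.ndarray
    loadings: np.ndarray  # (n_pc, n_points), rows orthonormal
    scores: np.ndarray  # (n_donors, n_pc)
    axis: WavenumberAxis

    @property
    def cumulative(self) -> np.ndarray:
        return np.cumsum(self.explained_variance_ratio)


def run_pca(sset: SpectrumSet, n_components: int) -> PCAResult:
    """Centered, unscaled PCA of a cohort's intensity matrix.

    Sign convention: the largest-magnitude element of each loading is
    made positive (scores flipped accordingly).  A cohort with zero
    total variance is degenerate and raises.
    """
    n = len(sset)
    if n < 2:
        raise ValueError("need at least 2 donors for PCA")
    x = sset.to_matrix()
    p = x.shape[1]
    if n_components > min(n - 1, p):
        raise ValueError(
            f"n_components={n_components} exceeds min(n-1, p) = {min(n - 1, p)}"
        )
    centered = x - x.mean(axis=0)
    # a cohort of identical spectra has zero variance up to the rounding
    # of the mean; treat that as degenerate
    if float(np.sum(centered**2)) <= 1e-18 * max(float(np.sum(x**2)), 1e-300):
        raise ValueError("degenerate cohort: zero total variance")
    pca = PCA(n_components=n_components, svd_solver="full")
    scores = pca.fit_transform(x)
    loadings = pca.components_.copy()
    for i in range(loadings.shape[0]):
        j = int(np.argmax(np.abs(loadings[i])))
        if loadings[i, j] < 0:
            loadings[i] *= -1.0
            scores[:, i] *= -1.0
    return PCAResult(
        explained_variance_ratio=pca.explained_variance_ratio_.copy(),
        loadings=loadings,
        scores=scores,
        axis=sset.common_axis,
    )


def _cosine(u: np.ndarray, v: np.ndarray) -> float:
    nu, nv = np.linalg.norm(u), np.linalg.norm(v)
    if nu == 0 or nv == 0:
        return 0.0
    return float(u @ v / (nu * nv))


def match_loadings(pca: PCAResult, library: ComponentLibrary) -> pd.DataFrame:
    """Cosine similarity of each PC loading to each component and to all
    signed pairwise component differences.

    Rows are PCs; columns are component names plus ``"a-b"`` contrast
    columns holding cos(loading, comp_a - comp_b).
    """
    if len(pca.axis) != len(library.axis):
        raise ValueError("PCA and library must share one axis")
    rows = []
    names = library.names
    for i in range(pca.loadings.shape[0]):
        load = pca.loadings[i]
        row: dict = {"pc": i + 1}
        for n in names:
            row[n] = _cosine(load, library.component(n))
        for a in names:
            for b_ in names:
                if a != b_:
                    row[f"{a}-{b_}"] = _cosine(
                        load, library.component(a) - library.component(b_)
                    )
        rows.append(row)
    return pd.DataFrame(rows).set_index("pc")
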