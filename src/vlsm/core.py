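"""Mass-univariate lesion-symptom mapping with permutation thresholds.

At every voxel of the template grid the binary lesion indicator across
subjects is regressed, by ordinary least squares, on a symptom design
matrix whose first column is the ordinal seizure-frequency score and
whose remaining columns are the sex, age and tumor-volume nuisance
covariates plus an intercept (a linear-probability model per voxel).
The t-statistic of the frequency coefficient measures how strongly
lesion status at that voxel tracks seizure frequency once the nuisance
covariates are regressed out.

Voxels are screened by a statistical power map (two-sample normal
approximation at an assumed standardized effect size), thresholded
voxel-wise against an empirical permutation null of the frequency score
(the 95th-percentile permuted t per voxel at alpha = 0.05), and the
surviving voxels are grouped into connected clusters whose peak voxel
defines per-subject tumor involvement.

The per-voxel fits use the Frisch-Waugh-Lovell identity: residualizing
both the lesion indicator and the score against the nuisance block gives
the same frequency coefficient and t as the full normal equations, and
lets a thousand score permutations be evaluated as a single matrix
product.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from skimage import measure

from .clinical import ClinicalRecord, RankTestResult, mann_whitney
from .imaging import GridMismatchError, LesionVolume, OverlapMap, TemplateGrid

__all__ = [
    "SymptomDesign",
    "StatMap",
    "PermutationNull",
    "PowerMap",
    "Cluster",
    "ClusterResult",
    "T_CAP",
    "build_design",
    "voxelwise_glm",
    "power_map",
    "eligible_mask",
    "permutation_null",
    "apply_threshold",
    "extract_clusters",
    "label_involvement",
    "involvement_vs_frequency",
]

#: Finite stand-in for the t-statistic of an exact (zero-residual) fit.
T_CAP = 1e12

#: Relative tolerance below which a residual sum of squares counts as zero.
_SSR_TOL = 1e-10

_CONNECTIVITY = {6: 1, 18: 2, 26: 3}  # neighbour count -> skimage rank


# ---------------------------------------------------------------------------
# Design matrix
# ---------------------------------------------------------------------------

@dataclass
class SymptomDesign:
    """Per-subject regression design: [frequency_score, nuisance..., intercept]."""

    X: np.ndarray
    columns: list[str]
    subject_ids: list[str]

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=np.float64)
        if self.X.ndim != 2 or self.X.shape[0] != len(self.subject_ids):
            raise ValueError("design matrix rows must match subjects")
        if len(self.columns) != self.X.shape[1]:
            raise ValueError("column labels must match design width")
        if np.linalg.matrix_rank(self.X) < self.X.shape[1]:
            raise ValueError("design matrix is rank deficient")

    @property
    def n_subjects(self) -> int:
        return self.X.shape[0]

    @property
    def n_columns(self) -> int:
        return self.X.shape[1]

    @property
    def score_index(self) -> int:
        return self.columns.index("frequency_score")

    @property
    def df_residual(self) -> int:
        return self.n_subjects - self.n_columns


def build_design(records: Sequence[ClinicalRecord]) -> SymptomDesign:
    """Assemble the symptom matrix from clinical records.

    Column 1 is the ordinal frequency score (0-4); sex, age and tumor
    volume follow as mean-centered nuisance columns; an intercept is
    appended.  Centering leaves the frequency t-statistic unchanged but
    keeps the coefficient interpretable.  A nuisance column that is
    constant across the cohort (e.g. a single-sex cohort) is dropped with
    a warning; keeping it would make the design rank deficient.
    """
    if not records:
        raise ValueError("no clinical records supplied")
    for r in records:
        for name in ("age", "sex", "tumor_volume", "frequency_category"):
            v = getattr(r, name)
            if v is None or (isinstance(v, float) and not np.isfinite(v)):
                raise ValueError(f"subject {r.subject_id}: missing covariate {name}")
    score = np.array([float(r.frequency_score) for r in records])
    cols: list[tuple[str, np.ndarray]] = [("frequency_score", score)]
    for name, vals in (
        ("sex", np.array([float(r.sex) for r in records])),
        ("age", np.array([float(r.age) for r in records])),
        ("tumor_volume", np.array([float(r.tumor_volume) for r in records])),
    ):
        if np.ptp(vals) == 0:
            warnings.warn(
                f"nuisance column {name!r} is constant across the cohort; dropped",
                UserWarning,
                stacklevel=2,
            )
            continue
        cols.append((name, vals - vals.mean()))
    cols.append(("intercept", np.ones(len(records))))
    X = np.column_stack([c[1] for c in cols])
    return SymptomDesign(X, [c[0] for c in cols], [r.subject_id for r in records])


# ---------------------------------------------------------------------------
# Per-voxel GLM
# ---------------------------------------------------------------------------

@dataclass
class StatMap:
    """Per-voxel frequency coefficient and t-statistic volumes."""

    beta: np.ndarray
    t: np.ndarray
    eligible: np.ndarray
    n_subjects: int
    df_residual: int
    grid: TemplateGrid
    deterministic: np.ndarray | None = None  # exact-fit voxels (t capped)


class _FwlSolver:
    """Residualize score and response against the nuisance block once.

    After projecting out the nuisance columns Z (with intercept), the
    frequency coefficient at a voxel is (s~' y~)/(s~' s~) and its classical
    OLS standard error uses the full-model residual degrees of freedom.
    """

    def __init__(self, design: SymptomDesign):
        j = design.score_index
        self.design = design
        self.Z = np.delete(design.X, j, axis=1)
        self.Zplus = np.linalg.pinv(self.Z)
        self.s = design.X[:, j]
        self.s_til = self._residualize(self.s[:, None])[:, 0]
        self.ss = float(self.s_til @ self.s_til)
        if self.ss <= 1e-12 * max(1.0, float(self.s @ self.s)):
            raise ValueError("frequency score is collinear with nuisance columns")
        self.df = design.df_residual
        if self.df <= 0:
            raise ValueError("need more subjects than design columns")

    def _residualize(self, M: np.ndarray) -> np.ndarray:
        return M - self.Z @ (self.Zplus @ M)

    def prepare_response(self, Y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Return (Y~, per-column ||Y~||^2) for an (n, V) response block."""
        Ytil = self._residualize(Y)
        return Ytil, np.einsum("ij,ij->j", Ytil, Ytil)

    def score_stats(
        self, s_til: np.ndarray, Ytil: np.ndarray, y2: np.ndarray
    ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """beta, t and the exact-fit flag for one (already residualized) score."""
        ss = float(s_til @ s_til)
        num = s_til @ Ytil
        beta = num / ss
        ssr = np.maximum(y2 - beta**2 * ss, 0.0)
        exact = ssr <= _SSR_TOL * np.maximum(y2, 1.0)
        with np.errstate(divide="ignore", invalid="ignore"):
            se = np.sqrt(ssr / self.df / ss)
            t = beta / se
        t = np.where(exact, np.sign(beta) * T_CAP, t)
        t = np.where(np.isnan(t), 0.0, t)  # beta == 0 with zero residual
        return beta, t, exact


def _stack_lesions(masks: Sequence[LesionVolume]) -> tuple[np.ndarray, TemplateGrid]:
    if not masks:
        raise ValueError("no lesion masks supplied")
    grid = masks[0].grid
    for m in masks:
        if m.grid != grid:
            raise GridMismatchError(f"mask {m.subject_id} is on a different grid")
    return np.stack([m.data for m in masks]).astype(np.float64), grid


def voxelwise_glm(
    masks: Sequence[LesionVolume],
    design: SymptomDesign,
    eligible: np.ndarray | None = None,
) -> StatMap:
    """OLS of lesion status on the symptom design at every eligible voxel.

    Voxels where the lesion indicator is constant across subjects carry no
    information and are marked ineligible.  Voxels fitted exactly (zero
    residual) report t = +/-T_CAP and are flagged in ``deterministic``.
    """
    L, grid = _stack_lesions(masks)
    n = L.shape[0]
    if n != design.n_subjects:
        raise ValueError("design rows do not match number of masks")
    solver = _FwlSolver(design)

    flat = L.reshape(n, -1)
    nonconstant = (flat.min(axis=0) != flat.max(axis=0)).reshape(grid.dims)
    elig = nonconstant if eligible is None else (np.asarray(eligible, bool) & nonconstant)

    beta_map = np.full(grid.dims, np.nan)
    t_map = np.full(grid.dims, np.nan)
    det_map = np.zeros(grid.dims, dtype=bool)
    idx = np.flatnonzero(elig.ravel())
    if idx.size:
        Y = flat[:, idx]
        Ytil, y2 = solver.prepare_response(Y)
        beta, t, exact = solver.score_stats(solver.s_til, Ytil, y2)
        beta_map.ravel()[idx] = beta
        t_map.ravel()[idx] = t
        det_map.ravel()[idx] = exact
    return StatMap(
        beta=beta_map, t=t_map, eligible=elig,
        n_subjects=n, df_residual=solver.df, grid=grid,
        deterministic=det_map,
    )


# ---------------------------------------------------------------------------
# Power map and eligibility screen
# ---------------------------------------------------------------------------

@dataclass
class PowerMap:
    power: np.ndarray
    assumed_effect_size: float
    alpha: float
    grid: TemplateGrid


def power_map(overlap: OverlapMap, effect_size: float = 1.0, alpha: float = 0.05) -> PowerMap:
    """Two-sample power at each voxel's lesioned/intact split.

    With k of n subjects lesioned at a voxel, the power to detect a
    standardized mean difference d between the two groups (two-sided
    level-alpha z-test, normal approximation) is
    ``Phi(d * sqrt(k (n-k) / n) - z_{1-alpha/2})``; voxels lesioned in
    none or all subjects have no contrast and get power 0.
    """
    if not 0 < alpha < 1:
        raise ValueError("alpha must be in (0, 1)")
    if effect_size <= 0:
        raise ValueError("effect size must be positive")
    k = overlap.counts.astype(np.float64)
    n = overlap.n_subjects
    z = stats.norm.ppf(1 - alpha / 2)
    with np.errstate(invalid="ignore"):
        pw = stats.norm.cdf(effect_size * np.sqrt(k * (n - k) / n) - z)
    pw = np.where((overlap.counts == 0) | (overlap.counts == n), 0.0, pw)
    return PowerMap(power=pw, assumed_effect_size=effect_size, alpha=alpha, grid=overlap.grid)


def eligible_mask(power: PowerMap, threshold: float = 0.8) -> np.ndarray:
    """Voxels with power strictly above ``threshold``."""
    if not 0 < threshold < 1:
        raise ValueError("threshold must be in (0, 1)")
    return power.power > threshold


# ---------------------------------------------------------------------------
# Permutation null
# ---------------------------------------------------------------------------

@dataclass
class PermutationNull:
    """Empirical per-voxel t thresholds from symptom-score permutations."""

    threshold: np.ndarray
    eligible: np.ndarray
    n_permutations: int
    alpha: float
    seed: int
    scheme: str
    mode: str
    grid: TemplateGrid


def permutation_null(
    masks: Sequence[LesionVolume],
    design: SymptomDesign,
    eligible: np.ndarray,
    n_permutations: int = 1000,
    alpha: float = 0.05,
    seed: int | None = None,
    scheme: str = "score",
    mode: str = "voxelwise",
    batch_size: int = 200,
) -> PermutationNull:
    """Build the permutation null of the frequency t-statistic.

    Each permutation shuffles the frequency-score column across subjects
    while the nuisance covariates stay attached to their subject's lesion
    (scheme='score', the default); scheme='freedman_lane' instead permutes
    the reduced-model residuals of the lesion data.  The per-voxel
    threshold is the ceil((1-alpha) * n_permutations)-th order statistic
    of the permuted t at that voxel; mode='max_stat' replaces it with the
    familywise threshold from the permutation distribution of the maximum
    t over eligible voxels.
    """
    if seed is None:
        raise ValueError("an explicit seed is required for permutation testing")
    if n_permutations < 1:
        raise ValueError("n_permutations must be >= 1")
    if n_permutations < 1 / alpha:
        warnings.warn(
            f"n_permutations={n_permutations} cannot resolve alpha={alpha}; "
            "the threshold is the sample maximum",
            UserWarning,
            stacklevel=2,
        )
    if scheme not in ("score", "freedman_lane"):
        raise ValueError(f"unknown permutation scheme: {scheme!r}")
    if mode not in ("voxelwise", "max_stat"):
        raise ValueError(f"unknown threshold mode: {mode!r}")

    L, grid = _stack_lesions(masks)
    n = L.shape[0]
    solver = _FwlSolver(design)
    elig = np.asarray(eligible, bool)
    flat = L.reshape(n, -1)
    nonconstant = flat.min(axis=0) != flat.max(axis=0)
    idx = np.flatnonzero(elig.ravel() & nonconstant)
    rng = np.random.default_rng(seed)
    perms = np.stack([rng.permutation(n) for _ in range(n_permutations)])

    threshold_map = np.full(grid.dims, np.nan)
    elig_final = np.zeros(grid.dims, dtype=bool)
    elig_final.ravel()[idx] = True
    k = int(np.ceil((1 - alpha) * n_permutations))

    if idx.size:
        Y = flat[:, idx]
        Ytil, y2 = solver.prepare_response(Y)
        t_all = np.empty((n_permutations, idx.size))
        for start in range(0, n_permutations, batch_size):
            block = perms[start:start + batch_size]
            for off, perm in enumerate(block):
                if scheme == "score":
                    s_perm = solver.s[perm]
                    s_til = s_perm - solver.Z @ (solver.Zplus @ s_perm)
                    _, t, _ = solver.score_stats(s_til, Ytil, y2)
                else:  # freedman_lane: permute reduced-model residuals
                    Ystar = Ytil[perm]
                    Ystar_til = Ystar - solver.Z @ (solver.Zplus @ Ystar)
                    y2star = np.einsum("ij,ij->j", Ystar_til, Ystar_til)
                    _, t, _ = solver.score_stats(solver.s_til, Ystar_til, y2star)
                t_all[start + off] = t
        if mode == "voxelwise":
            thr = np.partition(t_all, k - 1, axis=0)[k - 1]
        else:
            tmax = t_all.max(axis=1)
            thr = np.full(idx.size, np.partition(tmax, k - 1)[k - 1])
        threshold_map.ravel()[idx] = thr

    return PermutationNull(
        threshold=threshold_map, eligible=elig_final,
        n_permutations=n_permutations, alpha=alpha, seed=seed,
        scheme=scheme, mode=mode, grid=grid,
    )


def apply_threshold(stat: StatMap, null: PermutationNull) -> np.ndarray:
    """Voxels whose observed t strictly exceeds its permutation threshold.

    One-sided: only positive associations (lesion more likely with higher
    frequency) can survive, because the threshold is the upper tail of the
    permuted t.
    """
    if stat.grid != null.grid:
        raise GridMismatchError("statistic and null are on different grids")
    both = stat.eligible & null.eligible
    with np.errstate(invalid="ignore"):
        retained = both & (stat.t > null.threshold)
    return retained


# ---------------------------------------------------------------------------
# Clusters, peaks, involvement
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Cluster:
    label: int
    size: int
    peak: tuple[int, int, int]
    peak_t: float


@dataclass
class ClusterResult:
    labels: np.ndarray
    clusters: list[Cluster]
    connectivity: int

    def to_table(self) -> pd.DataFrame:
        """Cluster table with 0-based and 1-based peak coordinates."""
        rows = []
        for c in self.clusters:
            x, y, z = c.peak
            rows.append({
                "cluster": c.label, "size_voxels": c.size,
                "peak_x": x, "peak_y": y, "peak_z": z,
                "peak_x_1based": x + 1, "peak_y_1based": y + 1, "peak_z_1based": z + 1,
                "peak_t": c.peak_t,
            })
        return pd.DataFrame(rows, columns=[
            "cluster", "size_voxels", "peak_x", "peak_y", "peak_z",
            "peak_x_1based", "peak_y_1based", "peak_z_1based", "peak_t",
        ])


def extract_clusters(
    retained: np.ndarray, t: np.ndarray, connectivity: int = 26
) -> ClusterResult:
    """Connected components of the retained mask with their t peaks.

    Clusters are sorted by peak t descending; ties break on the smallest
    lexicographic peak coordinate.  An empty retained mask yields an empty
    result.
    """
    if connectivity not in _CONNECTIVITY:
        raise ValueError(f"connectivity must be one of {sorted(_CONNECTIVITY)}")
    retained = np.asarray(retained, bool)
    raw = measure.label(retained, connectivity=_CONNECTIVITY[connectivity])
    clusters = []
    for lab in range(1, raw.max() + 1):
        where = raw == lab
        coords = np.argwhere(where)
        tvals = t[where]
        # argwhere/boolean indexing iterate in C order, so argmax on the
        # flat values lands on the lexicographically smallest tied peak
        best = int(np.nanargmax(tvals))
        peak = tuple(int(v) for v in coords[best])
        clusters.append((float(tvals[best]), peak, int(where.sum()), lab))
    clusters.sort(key=lambda c: (-c[0], c[1]))
    out_labels = np.zeros_like(raw)
    result = []
    for new_lab, (peak_t, peak, size, old_lab) in enumerate(clusters, start=1):
        out_labels[raw == old_lab] = new_lab
        result.append(Cluster(label=new_lab, size=size, peak=peak, peak_t=peak_t))
    return ClusterResult(labels=out_labels, clusters=result, connectivity=connectivity)


def label_involvement(
    masks: Sequence[LesionVolume], peak: tuple[int, int, int]
) -> np.ndarray:
    """Per-subject flag: does the tumor mask contain the peak voxel?"""
    if not masks:
        raise ValueError("no masks supplied")
    grid = masks[0].grid
    if not grid.contains(peak):
        raise ValueError(f"peak {peak} lies outside the grid {grid.dims}")
    px, py, pz = (int(v) for v in peak)
    return np.array([m.data[px, py, pz] == 1 for m in masks])


def involvement_vs_frequency(
    involvement: np.ndarray,
    scores: Sequence[int],
    restrict: np.ndarray | None = None,
) -> RankTestResult:
    """Mann-Whitney comparison of frequency scores by peak involvement.

    ``restrict`` optionally limits the comparison to a subset of subjects
    (e.g. one hemisphere), mirroring how involved tumors are compared with
    same-hemisphere tumors located elsewhere.
    """
    inv = np.asarray(involvement, bool)
    sc = np.asarray(scores, dtype=float)
    if inv.shape != sc.shape:
        raise ValueError("involvement and scores must align")
    keep = np.ones_like(inv) if restrict is None else np.asarray(restrict, bool)
    a = sc[inv & keep]
    b = sc[~inv & keep]
    if a.size == 0 or b.size == 0:
        raise ValueError("both involvement groups must be non-empty")
    return mann_whitney(a, b)
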