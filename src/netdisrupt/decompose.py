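"""Group sparse dictionary learning, dual regression, and group ICA.

Two decomposition routes produce per-subject spatial activation maps from a
temporally concatenated group dataset:

* **sDL + dual regression** — the group fit alternately minimizes, over a
  unit-norm dictionary D of temporal atoms and sparse spatial codes alpha,

      (1/n_vox) sum_j [ 1/2 ||s_j - D alpha_j||_2^2 + lambda ||alpha_j||_1 ]

  (per-voxel LASSO coding, block least-squares atom updates on each atom's
  active voxel set).  Dual regression then maps the group spatial maps onto
  each subject: stage 1 solves s_i = D_i alpha_g by ordinary least squares
  for the subject dictionary D_i; stage 2 sparse-codes s_i against D_i.

* **group ICA + back-reconstruction** — PCA reduces the time dimension of
  the concatenated data, spatial ICA unmixes the reduced data into
  independent spatial maps, and each subject's maps are recovered by
  projecting the subject's partition through the stored reduction and the
  inverse unmixing.

Every component is sign-flipped so its maximum-absolute-weight voxel is
positive; thresholding downstream keeps the positive tail.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import linalg
from sklearn.decomposition import FastICA, sparse_encode
from sklearn.exceptions import ConvergenceWarning

__all__ = [
    "TimeDictionary",
    "SpatialMapSet",
    "SdlConfig",
    "GroupIcaModel",
    "sparse_code",
    "sdl_fit",
    "dual_regression",
    "group_ica",
    "back_reconstruct",
    "sdl_objective",
]


@dataclass
class TimeDictionary:
    """T x n matrix of temporal atoms with unit-norm columns."""

    atoms: np.ndarray
    source: str = "group"  # "group" | "subject"
    dead: np.ndarray | None = None  # flags for all-zero (dead) atoms

    def __post_init__(self) -> None:
        self.atoms = np.asarray(self.atoms, dtype=np.float64)
        if self.atoms.ndim != 2:
            raise ValueError("atoms must be a T x n matrix")
        norms = np.linalg.norm(self.atoms, axis=0)
        if self.dead is None:
            self.dead = norms == 0
        live = ~self.dead
        if live.any() and not np.allclose(norms[live], 1.0, atol=1e-6):
            raise ValueError("live atoms must have unit Euclidean norm")

    @property
    def n_atoms(self) -> int:
        return int(self.atoms.shape[1])

    @property
    def n_timepoints(self) -> int:
        return int(self.atoms.shape[0])


@dataclass
class SpatialMapSet:
    """Component x voxel spatial maps with normalization/threshold state."""

    maps: np.ndarray  # n_components x n_voxels
    method: str  # "sdl" | "ica"
    state: str = "raw"  # raw | normalized | thresholded
    subject_id: str | None = None  # None => group maps
    component_ids: list[int] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.maps = np.asarray(self.maps, dtype=np.float64)
        if self.maps.ndim != 2:
            raise ValueError("maps must be n_components x n_voxels")
        if not self.component_ids:
            self.component_ids = list(range(self.maps.shape[0]))

    @property
    def n_components(self) -> int:
        return int(self.maps.shape[0])


@dataclass
class SdlConfig:
    n_atoms: int = 300
    lam: float = 0.15
    max_outer_iters: int = 15
    code_tolerance: float = 1e-6
    seed: int = 0

    def __post_init__(self) -> None:
        if self.lam < 0:
            raise ValueError("lam must be >= 0")
        if self.n_atoms < 1:
            raise ValueError("n_atoms must be >= 1")


def _fix_signs(maps: np.ndarray, atoms: np.ndarray | None = None
               ) -> tuple[np.ndarray, np.ndarray | None]:
    """Flip component signs so the max-|weight| voxel of each map is positive.

    Flipping a map row together with its atom/time-course column leaves the
    reconstruction invariant.
    """
    if maps.shape[1] == 0:
        return maps, atoms
    peak = np.take_along_axis(maps, np.abs(maps).argmax(axis=1)[:, None], axis=1)
    signs = np.where(peak[:, 0] < 0, -1.0, 1.0)
    maps = maps * signs[:, None]
    if atoms is not None:
        atoms = atoms * signs[None, :]
    return maps, atoms


def sdl_objective(matrix: np.ndarray, atoms: np.ndarray, codes: np.ndarray,
                  lam: float) -> float:
    """Mean per-voxel value of 1/2||s - D a||^2 + lam ||a||_1."""
    resid = matrix - codes.T @ atoms.T
    n_vox = matrix.shape[0]
    return float((0.5 * np.sum(resid ** 2) + lam * np.abs(codes).sum()) / n_vox)


def sparse_code(matrix: np.ndarray, dictionary: TimeDictionary,
                lam: float, max_iter: int = 1000) -> SpatialMapSet:
    """Solve the per-voxel LASSO min_a 1/2||s_j - D a||^2 + lam||a||_1.

    ``matrix`` is voxel x time.  Returns raw spatial maps (n_atoms x voxel);
    the attained objective is stored on the result as ``objective``.
    """
    matrix = np.asarray(matrix, dtype=np.float64)
    if not np.isfinite(matrix).all():
        raise ValueError("matrix contains non-finite values")
    D = dictionary.atoms
    if D.shape[0] != matrix.shape[1]:
        raise ValueError("dictionary time length must equal matrix time length")
    if lam < 0:
        raise ValueError("lam must be >= 0")
    if lam == 0:
        codes, *_ = np.linalg.lstsq(D, matrix.T, rcond=None)  # n x voxel
    else:
        codes = sparse_encode(matrix, D.T, algorithm="lasso_cd", alpha=lam,
                              max_iter=max_iter).T
    out = SpatialMapSet(maps=codes, method="sdl", state="raw")
    out.objective = sdl_objective(matrix, D, codes, lam)
    return out


def _init_dictionary(matrix: np.ndarray, n_atoms: int,
                     rng: np.random.Generator) -> np.ndarray:
    """Initial atoms: dominant temporal singular vectors of the data.

    Energy-ordered SVD initialization makes the fit start from the
    directions that explain the most variance (the shared network courses in
    group data) regardless of how few voxels a structure occupies; atoms
    beyond the data rank are filled with random voxel time courses.
    """
    n_vox, T = matrix.shape
    r = min(n_atoms, n_vox, T)
    _U, s, Wt = np.linalg.svd(matrix, full_matrices=False)
    D = np.zeros((T, n_atoms))
    rank = int((s > 1e-12 * s[0]).sum()) if s.size else 0
    k = min(r, rank)
    D[:, :k] = Wt[:k].T  # unit-norm right singular vectors
    if n_atoms > k:
        idx = rng.choice(n_vox, size=n_atoms - k, replace=n_atoms - k > n_vox)
        extra = matrix[idx].T.astype(np.float64).copy()
        norms = np.linalg.norm(extra, axis=0)
        bad = norms < 1e-12
        if bad.any():
            extra[:, bad] = rng.standard_normal((T, int(bad.sum())))
            norms = np.linalg.norm(extra, axis=0)
        D[:, k:] = extra / norms
    return D


def sdl_fit(group, config: SdlConfig) -> tuple[TimeDictionary, SpatialMapSet]:
    """Group sparse dictionary learning by alternating minimization.

    Coding step: :func:`sparse_code` with the dictionary fixed.  Dictionary
    step: for each atom, unit-norm-constrained least squares against the
    residual restricted to the atom's active voxels; dead atoms (all-zero
    codes) are re-seeded from the worst-reconstructed voxel's residual.  The
    objective trajectory is recorded on the returned map set
    (``objective_path``); a convergence warning (not an error) is emitted if
    the objective failed to decrease within ``max_outer_iters``.
    """
    X = np.asarray(group.matrix if hasattr(group, "matrix") else group,
                   dtype=np.float64)
    rng = np.random.default_rng(config.seed)
    D = _init_dictionary(X, config.n_atoms, rng)

    objective_path: list[float] = []
    codes = None
    for _ in range(config.max_outer_iters):
        mapset = sparse_code(X, TimeDictionary(D), config.lam)
        codes = mapset.maps  # n_atoms x voxel
        objective_path.append(mapset.objective)

        recon = codes.T @ D.T  # voxel x time
        for k in range(config.n_atoms):
            a = codes[k]
            active = np.flatnonzero(a)
            if active.size == 0:
                # dead atom: re-seed from the currently worst-coded voxel
                resid_norms = np.sum((X - recon) ** 2, axis=1)
                j = int(resid_norms.argmax())
                d_new = X[j] - (recon[j] - 0.0)
                nrm = np.linalg.norm(d_new)
                D[:, k] = d_new / nrm if nrm > 1e-12 else \
                    _init_dictionary(X, 1, rng)[:, 0]
                continue
            # residual with atom k removed, on its active voxel set
            E = X[active] - recon[active] + np.outer(a[active], D[:, k])
            d = E.T @ a[active]
            nrm = np.linalg.norm(d)
            if nrm <= 1e-12:
                continue
            d /= nrm
            recon[active] += np.outer(a[active], d - D[:, k])
            D[:, k] = d
        if len(objective_path) >= 2:
            prev, cur = objective_path[-2], objective_path[-1]
            if prev - cur <= config.code_tolerance * max(abs(prev), 1.0):
                break

    final = sparse_code(X, TimeDictionary(D), config.lam)
    objective_path.append(final.objective)
    if len(objective_path) >= 2 and objective_path[-1] > objective_path[0] + \
            config.code_tolerance * max(abs(objective_path[0]), 1.0):
        warnings.warn("sdl_fit objective did not decrease within "
                      f"{config.max_outer_iters} outer iterations",
                      ConvergenceWarning)
    maps, D = _fix_signs(final.maps, D)
    dictionary = TimeDictionary(D, source="group")
    out = SpatialMapSet(maps=maps, method="sdl", state="raw")
    out.objective = final.objective
    out.objective_path = objective_path
    return dictionary, out


def dual_regression(subject_matrix: np.ndarray, group_maps: SpatialMapSet,
                    lam: float) -> tuple[TimeDictionary, SpatialMapSet]:
    """Two-stage dual regression of a subject against group spatial maps.

    Stage 1 solves ``s_i = D_i alpha_g`` for the subject dictionary by
    ordinary least squares (ridge jitter 1e-8 with a warning if the group
    map Gram matrix is rank deficient), then renormalizes its columns to
    unit norm.  Stage 2 sparse-codes the subject data against D_i.
    """
    S = np.asarray(subject_matrix, dtype=np.float64)  # voxel x time
    A = group_maps.maps  # n x voxel
    if A.shape[1] != S.shape[0]:
        raise ValueError("group maps do not share the subject voxel raster")
    gram = A @ A.T
    rhs = A @ S  # n x time
    try:
        cf = linalg.cho_factor(gram)
        Di_T = linalg.cho_solve(cf, rhs)  # n x time
    except linalg.LinAlgError:
        warnings.warn("rank-deficient group maps in dual regression; "
                      "using ridge jitter 1e-8")
        jitter = 1e-8 * np.trace(gram) / max(gram.shape[0], 1)
        Di_T = linalg.solve(gram + jitter * np.eye(gram.shape[0]), rhs,
                            assume_a="pos")
    D_i = Di_T.T  # time x n
    norms = np.linalg.norm(D_i, axis=0)
    dead = norms < 1e-12
    live = ~dead
    D_i[:, live] = D_i[:, live] / norms[live]
    D_i[:, dead] = 0.0
    dictionary = TimeDictionary(D_i, source="subject", dead=dead)
    alpha_i = sparse_code(S, dictionary, lam)
    alpha_i.maps[dead] = 0.0
    alpha_i.subject_id = getattr(group_maps, "subject_id", None)
    return dictionary, alpha_i


@dataclass
class GroupIcaModel:
    """Stored group ICA fit: PCA basis, ICA mixing, spans, group maps."""

    basis: np.ndarray          # total_time x k (PCA reduction, Yc ~ basis @ F)
    mixing: np.ndarray         # k x k ICA mixing (F = mixing @ sources)
    group_maps: SpatialMapSet  # k x voxel independent spatial maps
    subject_spans: list[tuple[str, int, int]]
    row_means: np.ndarray | None = None  # per-time-point spatial mean of Y
    n_iter: int = 0

    @property
    def time_courses(self) -> np.ndarray:
        """total_time x k component time courses."""
        return self.basis @ self.mixing


def group_ica(group, n_components: int, seed: int = 0,
              tol: float = 1e-6, max_iter: int = 1000) -> GroupIcaModel:
    """Group spatial ICA: PCA time reduction then FastICA on voxels.

    The voxel x time group matrix is transposed to time x voxel, reduced to
    ``n_components`` by SVD, and the whitened spatial signals are unmixed
    into independent spatial maps.  Deterministic given ``seed``; emits a
    convergence warning (results still returned) if FastICA hits
    ``max_iter``.
    """
    X = np.asarray(group.matrix, dtype=np.float64)
    spans = list(group.subject_spans)
    n_vox, total_t = X.shape
    if n_components > min(n_vox, total_t):
        raise ValueError("n_components exceeds min(voxels, time)")
    Y = X.T  # time x voxel
    row_means = Y.mean(axis=1, keepdims=True)  # spatial mean per time point
    Y = Y - row_means
    U, s, Vt = np.linalg.svd(Y, full_matrices=False)
    k = n_components
    # whitened spatial signals: rows have unit variance across voxels
    F = Vt[:k] * np.sqrt(n_vox)
    basis = U[:, :k] * (s[:k] / np.sqrt(n_vox))  # Y ~ basis @ F

    # F is already reduced to k whitened rows, so no further reduction here
    ica = FastICA(whiten=False, fun="logcosh", tol=tol,
                  max_iter=max_iter, random_state=np.random.RandomState(seed))
    with warnings.catch_warnings():
        warnings.simplefilter("always", ConvergenceWarning)
        sources = ica.fit_transform(F.T).T  # k x voxel
    W = ica.components_  # k x k unmixing: sources = W @ F
    mixing = np.linalg.inv(W)  # F = mixing @ sources

    # flipping source row k together with mixing *column* k keeps F invariant
    sources, mixing = _fix_signs(sources, mixing)
    maps = SpatialMapSet(maps=sources, method="ica", state="raw")
    return GroupIcaModel(basis=basis, mixing=mixing, group_maps=maps,
                         subject_spans=spans, row_means=row_means,
                         n_iter=getattr(ica, "n_iter_", 0))


def back_reconstruct(group, model: GroupIcaModel,
                     subject_id: str) -> SpatialMapSet:
    """Per-subject maps from a group ICA fit via the stored PCA partition.

    The subject's rows of the PCA basis (G_i) and the ICA mixing A give the
    subject maps ``alpha_i = A^{-1} pinv(G_i) Y_i``; for a single-subject
    group this reproduces the group maps exactly.
    """
    for sid, start, end in model.subject_spans:
        if sid == subject_id:
            break
    else:
        raise KeyError(f"subject {subject_id!r} not in the fitted group")
    X = np.asarray(group.matrix, dtype=np.float64)
    Y_i = X[:, start:end].T  # T_i x voxel
    if model.row_means is not None:
        Y_i = Y_i - model.row_means[start:end]
    G_i = model.basis[start:end]  # T_i x k
    F_i, *_ = np.linalg.lstsq(G_i, Y_i, rcond=None)  # k x voxel
    alpha = np.linalg.solve(model.mixing, F_i)
    alpha, _ = _fix_signs(alpha)
    return SpatialMapSet(maps=alpha, method="ica", state="raw",
                         subject_id=subject_id)
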