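"""Nonnegative PARAFAC decomposition of EEM collections with split-half validation.

Fits the trilinear model

    X[i, j, k] = sum_f  A[i, f] * B[j, f] * C[k, f]  + E[i, j, k]

to a stack of corrected EEMs (i samples, j emission wavelengths, k
excitation wavelengths) by alternating least squares with nonnegativity on
all three modes. Missing cells (NaN, e.g. excised scatter regions) are
excluded from the least-squares objective: each sweep refills them with
the current reconstruction, so they contribute zero residual and never
constrain the factors (an expectation-maximisation scheme whose observed-
cell loss is monotone non-increasing).

Loading columns are normalized to unit maximum with the magnitude absorbed
into the sample scores, so a score *is* the component's Fmax in that
sample. Model validity is assessed by split-half analysis: the sample set
is halved, each half fitted independently, components matched one-to-one
by maximal Tucker congruence, and the model accepted when every matched
component's combined (excitation x emission) congruence exceeds the
threshold (0.95 by default).
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.linalg import cho_factor, cho_solve, solve_triangular
from scipy.optimize import nnls

from .spectra import EEM

__all__ = [
    "ParafacModel",
    "SplitHalfResult",
    "fit_parafac",
    "tucker_congruence",
    "match_components",
    "split_half_validate",
    "component_fmax",
    "percent_contribution",
    "detect_outliers",
    "export_openfluor",
    "model_to_json",
    "model_from_json",
    "model_congruence",
]


# ---------------------------------------------------------------------------
# Model container
# ---------------------------------------------------------------------------

@dataclass
class ParafacModel:
    """A fitted PARAFAC model of an EEM collection.

    ``scores`` (n_samples x F) carry the component magnitudes; the
    emission/excitation loadings have unit-max columns, so scores equal
    Fmax in the intensity units of the input EEMs (Raman units for a
    corrected collection).
    """

    scores: np.ndarray
    em_loadings: np.ndarray
    ex_loadings: np.ndarray
    em: np.ndarray
    ex: np.ndarray
    n_components: int
    explained_variance: float
    converged: bool
    iterations: int
    loss_history: np.ndarray = field(default_factory=lambda: np.empty(0))
    seed: int | None = None

    @property
    def fmax(self) -> np.ndarray:
        return component_fmax(self)

    @property
    def percent_contribution(self) -> np.ndarray:
        return percent_contribution(self)

    def reconstruct(self) -> np.ndarray:
        return np.einsum("if,jf,kf->ijk", self.scores, self.em_loadings,
                         self.ex_loadings)


@dataclass
class SplitHalfResult:
    """Outcome of a split-half validation run."""

    assignment: list[tuple[int, int]]        # (component in half A, in half B)
    congruence_em: np.ndarray                # per matched component
    congruence_ex: np.ndarray
    congruence_combined: np.ndarray          # em * ex product
    threshold: float
    passed: bool
    halves: tuple[np.ndarray, np.ndarray]    # sample indices per half
    models: tuple[ParafacModel, ParafacModel]


# ---------------------------------------------------------------------------
# Core ALS machinery
# ---------------------------------------------------------------------------

def _stack_cube(eems: Sequence[EEM] | np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    if isinstance(eems, np.ndarray):
        if eems.ndim != 3:
            raise ValueError("EEM cube must be 3-dimensional (sample, em, ex)")
        cube = np.asarray(eems, dtype=float)
        em = np.arange(cube.shape[1], dtype=float)
        ex = np.arange(cube.shape[2], dtype=float)
        return cube, em, ex
    eems = list(eems)
    if not eems:
        raise ValueError("empty EEM collection")
    first = eems[0]
    for e in eems[1:]:
        if not first.same_grids(e):
            raise ValueError("EEMs in the collection are on inconsistent grids")
    cube = np.stack([e.intensity for e in eems]).astype(float)
    return cube, first.em.copy(), first.ex.copy()


def _nnls_rows(gram: np.ndarray, mttkrp: np.ndarray) -> np.ndarray:
    """Row-wise nonnegative LS: argmin_{a>=0} ||Z a - x|| via the compact system.

    ``gram`` = Z'Z (F x F), ``mttkrp`` rows are Z'x_i. With the Cholesky
    factor L L' = gram, each row solves nnls(L', L^-1 m_i).
    """
    F = gram.shape[0]
    G = gram + 1e-12 * np.trace(gram) / F * np.eye(F)
    L = np.linalg.cholesky(G)
    Y = solve_triangular(L, mttkrp.T, lower=True)   # (F, n_rows)
    out = np.empty_like(mttkrp)
    Lt = L.T
    for i in range(mttkrp.shape[0]):
        out[i], _ = nnls(Lt, Y[:, i])
    return out


def _ls_rows(gram: np.ndarray, mttkrp: np.ndarray) -> np.ndarray:
    F = gram.shape[0]
    G = gram + 1e-12 * np.trace(gram) / F * np.eye(F)
    return cho_solve(cho_factor(G), mttkrp.T).T


def _normalize_factors(A, B, C, rng):
    """Unit-max loading columns, scale absorbed into scores; revive dead columns."""
    for M in (B, C):
        peaks = M.max(axis=0)
        dead = peaks <= 0
        if dead.any():
            M[:, dead] = rng.uniform(0.1, 1.0, size=(M.shape[0], int(dead.sum())))
            peaks = M.max(axis=0)
        A *= peaks
        M /= peaks
    return A, B, C


def _als_once(cube_filled: np.ndarray, observed: np.ndarray,
              x_obs: np.ndarray, sst: float,
              n_components: int, max_iter: int, tol: float,
              nonneg: bool, rng: np.random.Generator):
    """One random-start ALS run; returns factors, loss history, converged flag.

    Plain ALS creeps through 'swamps' when components are collinear, so
    each iteration also tries a line-search extrapolation along the last
    step (accepted only when it lowers the loss, keeping the loss history
    monotone).
    """
    n, J, K = cube_filled.shape
    F = n_components
    solve = _nnls_rows if nonneg else _ls_rows
    B = rng.uniform(0.1, 1.0, size=(J, F))
    C = rng.uniform(0.1, 1.0, size=(K, F))
    A = np.ones((n, F))
    X = cube_filled.copy()

    def obs_loss(model):
        return float(np.sum((x_obs - model[observed]) ** 2))

    losses = []
    prev = np.inf
    converged = False
    it = 0
    A_old = B_old = C_old = None
    accel_fail = 0
    for it in range(1, max_iter + 1):
        A = solve((B.T @ B) * (C.T @ C), np.einsum("ijk,jf,kf->if", X, B, C))
        B = solve((A.T @ A) * (C.T @ C), np.einsum("ijk,if,kf->jf", X, A, C))
        C = solve((A.T @ A) * (B.T @ B), np.einsum("ijk,if,jf->kf", X, A, B))
        A, B, C = _normalize_factors(A, B, C, rng)
        model = np.einsum("if,jf,kf->ijk", A, B, C)
        loss = obs_loss(model)
        if A_old is not None and it > 3:
            # extrapolate along the last step (Bro-style line search);
            # the step length grows while acceleration keeps succeeding
            step = min(it, 2.0 + (it - accel_fail) ** (1 / 3.0))
            A2 = A + step * (A - A_old)
            B2 = B + step * (B - B_old)
            C2 = C + step * (C - C_old)
            if nonneg:
                np.maximum(A2, 0.0, out=A2)
                np.maximum(B2, 0.0, out=B2)
                np.maximum(C2, 0.0, out=C2)
            A2, B2, C2 = _normalize_factors(A2, B2, C2, rng)
            model2 = np.einsum("if,jf,kf->ijk", A2, B2, C2)
            loss2 = obs_loss(model2)
            if loss2 < loss:
                A, B, C, model, loss = A2, B2, C2, model2, loss2
            else:
                accel_fail = it
        A_old, B_old, C_old = A.copy(), B.copy(), C.copy()
        losses.append(loss)
        # EM refill of missing cells with the current reconstruction
        X[~observed] = model[~observed]
        # converged when the loss decrease is negligible against the data's
        # total sum of squares (robust even when the loss reaches zero)
        if np.isfinite(prev) and prev - loss <= tol * max(sst, 1e-30):
            converged = True
            break
        prev = loss
    return A, B, C, np.asarray(losses), converged, it


def fit_parafac(eems: Sequence[EEM] | np.ndarray,
                n_components: int,
                n_starts: int = 10,
                max_iter: int = 500,
                tol: float = 1e-8,
                nonneg: bool = True,
                seed: int | None = None) -> ParafacModel:
    """Fit a nonnegative PARAFAC model by best-of-``n_starts`` ALS.

    Parameters
    ----------
    eems
        Corrected EEM collection on a shared grid (or a raw (n, em, ex)
        cube). NaN cells are treated as missing and excluded from the
        objective.
    n_components
        Number of trilinear components F (>= 1); at least ``2 F`` samples
        are required.
    n_starts, max_iter, tol
        Random restarts, iteration cap per start, and relative-loss
        convergence tolerance.
    nonneg
        Enforce nonnegativity on all three modes (default) via NNLS
        subproblems.
    seed
        Seed for the restart initialisations; fixing it makes the fit
        deterministic.
    """
    if n_components < 1:
        raise ValueError("n_components must be >= 1")
    cube, em, ex = _stack_cube(eems)
    n = cube.shape[0]
    if n < 2 * n_components:
        raise ValueError(
            f"need at least {2 * n_components} samples to fit {n_components} "
            f"components; got {n}"
        )
    observed = np.isfinite(cube)
    bad = ~observed.reshape(n, -1).any(axis=1)
    if bad.any():
        raise ValueError(f"samples with all cells missing: {np.where(bad)[0].tolist()}")
    x_obs = cube[observed]
    sst = float(np.sum((x_obs - x_obs.mean()) ** 2))
    filled = cube.copy()
    filled[~observed] = x_obs.mean()

    rng = np.random.default_rng(seed)
    best = None
    for _ in range(max(1, n_starts)):
        A, B, C, losses, conv, iters = _als_once(
            filled, observed, x_obs, sst, n_components, max_iter, tol, nonneg, rng
        )
        if best is None or losses[-1] < best[3][-1]:
            best = (A, B, C, losses, conv, iters)
    A, B, C, losses, conv, iters = best
    ssr = losses[-1]
    ev = 1.0 - ssr / sst if sst > 0 else float("nan")
    return ParafacModel(
        scores=A, em_loadings=B, ex_loadings=C, em=em, ex=ex,
        n_components=n_components, explained_variance=ev,
        converged=conv, iterations=iters, loss_history=losses, seed=seed,
    )


# ---------------------------------------------------------------------------
# Congruence, matching, split-half validation
# ---------------------------------------------------------------------------

def tucker_congruence(u: np.ndarray, v: np.ndarray) -> float:
    """Tucker congruence (cosine similarity) between two loading vectors."""
    u = np.asarray(u, float).ravel()
    v = np.asarray(v, float).ravel()
    if u.shape != v.shape:
        raise ValueError("vectors must have equal length")
    nu, nv = np.linalg.norm(u), np.linalg.norm(v)
    if nu == 0 or nv == 0:
        raise ValueError("congruence undefined for a zero vector")
    return float(u @ v / (nu * nv))


def match_components(model_a: ParafacModel, model_b: ParafacModel
                     ) -> tuple[list[tuple[int, int]], np.ndarray, np.ndarray]:
    """Greedy one-to-one component matching by combined (em*ex) congruence.

    Returns the assignment [(f_a, f_b), ...] ordered by model_a component
    index, plus the per-pair emission and excitation congruences.
    """
    Fa, Fb = model_a.n_components, model_b.n_components
    cem = np.empty((Fa, Fb))
    cex = np.empty((Fa, Fb))
    for i in range(Fa):
        for j in range(Fb):
            cem[i, j] = tucker_congruence(model_a.em_loadings[:, i],
                                          model_b.em_loadings[:, j])
            cex[i, j] = tucker_congruence(model_a.ex_loadings[:, i],
                                          model_b.ex_loadings[:, j])
    combined = cem * cex
    pairs: list[tuple[int, int]] = []
    free_a, free_b = set(range(Fa)), set(range(Fb))
    work = combined.copy()
    while free_a and free_b:
        # highest remaining congruence; ties break toward lower indices
        i, j = max(((i, j) for i in sorted(free_a) for j in sorted(free_b)),
                   key=lambda p: (work[p], -p[0], -p[1]))
        pairs.append((i, j))
        free_a.remove(i)
        free_b.remove(j)
    pairs.sort()
    em_c = np.array([cem[i, j] for i, j in pairs])
    ex_c = np.array([cex[i, j] for i, j in pairs])
    return pairs, em_c, ex_c


def split_half_validate(eems: Sequence[EEM] | np.ndarray,
                        n_components: int,
                        threshold: float = 0.95,
                        scheme: tuple[Sequence[int], Sequence[int]] | None = None,
                        seed: int | None = None,
                        **fit_kwargs) -> SplitHalfResult:
    """Split-half validation of a PARAFAC model.

    The sample set is partitioned into two halves (default: shuffled with
    ``seed`` then assigned alternately; a custom ``scheme`` of index
    sequences may be given), a model is fitted independently on each,
    components are matched greedily by congruence, and the validation
    passes when every matched component's combined em*ex congruence
    exceeds ``threshold``.
    """
    cube, em, ex = _stack_cube(eems)
    n = cube.shape[0]
    if n < 4:
        raise ValueError("split-half validation needs at least 4 samples")
    if scheme is None:
        order = np.random.default_rng(seed).permutation(n)
        half_a, half_b = order[0::2], order[1::2]
    else:
        half_a = np.asarray(scheme[0], dtype=int)
        half_b = np.asarray(scheme[1], dtype=int)
    for h in (half_a, half_b):
        if h.size < n_components * 2:
            raise ValueError(
                f"a half with {h.size} samples cannot support {n_components} components"
            )
    sub_a = [EEM(ex=ex, em=em, intensity=cube[i]) for i in half_a]
    sub_b = [EEM(ex=ex, em=em, intensity=cube[i]) for i in half_b]
    # same seed for both halves: the data differ, and a duplicated dataset
    # split into identical halves then yields exactly identical models
    model_a = fit_parafac(sub_a, n_components, seed=seed, **fit_kwargs)
    model_b = fit_parafac(sub_b, n_components, seed=seed, **fit_kwargs)
    pairs, em_c, ex_c = match_components(model_a, model_b)
    combined = em_c * ex_c
    return SplitHalfResult(
        assignment=pairs, congruence_em=em_c, congruence_ex=ex_c,
        congruence_combined=combined, threshold=threshold,
        passed=bool(np.min(combined) > threshold),
        halves=(half_a, half_b), models=(model_a, model_b),
    )


# ---------------------------------------------------------------------------
# Derived quantities
# ---------------------------------------------------------------------------

def component_fmax(model: ParafacModel) -> np.ndarray:
    """Per-sample, per-component maximum fluorescence (Fmax).

    Fmax[i, f] = score * max(em loading) * max(ex loading); with unit-max
    loadings this is the score itself.
    """
    return (model.scores
            * model.em_loadings.max(axis=0)[None, :]
            * model.ex_loadings.max(axis=0)[None, :])


def percent_contribution(model: ParafacModel) -> np.ndarray:
    """Percent contribution of each component to a sample's summed Fmax.

    Rows sum to 100; samples whose components are all zero get NaN rows
    (flagged with a warning).
    """
    fmax = component_fmax(model)
    totals = fmax.sum(axis=1)
    out = np.full_like(fmax, np.nan)
    ok = totals > 0
    if not ok.all():
        warnings.warn(
            f"{int((~ok).sum())} sample(s) have zero total Fmax; "
            "percent contribution undefined there"
        )
    out[ok] = 100.0 * fmax[ok] / totals[ok, None]
    return out


def detect_outliers(model: ParafacModel,
                    cutoff: float | None = None,
                    cutoff_factor: float = 3.0) -> tuple[np.ndarray, np.ndarray]:
    """Sample leverage from the score matrix, with high-leverage flags.

    Leverage h_i = diag(A (A'A)^-1 A'). The mean leverage is always F/n;
    samples above ``cutoff`` (default ``cutoff_factor`` times the mean)
    are flagged for inspection. Removal is left to the user — flagged
    samples are never dropped automatically.
    """
    A = model.scores
    n, F = A.shape
    gram = A.T @ A
    try:
        ginv = np.linalg.inv(gram)
    except np.linalg.LinAlgError:
        warnings.warn("singular score Gram matrix; using pseudo-inverse")
        ginv = np.linalg.pinv(gram)
    leverage = np.einsum("if,fg,ig->i", A, ginv, A)
    if cutoff is None:
        cutoff = cutoff_factor * F / n
    flags = np.where(leverage > cutoff)[0]
    return leverage, flags


# ---------------------------------------------------------------------------
# Import/export
# ---------------------------------------------------------------------------

def export_openfluor(model: ParafacModel, path, name: str = "model",
                     extra_header: dict | None = None) -> None:
    """Write loadings as an OpenFluor-compatible text block.

    One ``Ex``/``Em`` line per wavelength per component:
    ``Ex<TAB>wavelength<TAB>load1<TAB>load2...``.
    """
    lines = ["#", f"# name\t{name}", f"# components\t{model.n_components}"]
    for k, v in (extra_header or {}).items():
        lines.append(f"# {k}\t{v}")
    lines.append("#")
    for mode, grid, load in (("Ex", model.ex, model.ex_loadings),
                             ("Em", model.em, model.em_loadings)):
        for w, row in zip(grid, load):
            vals = "\t".join(f"{v:.6f}" for v in row)
            lines.append(f"{mode}\t{w:g}\t{vals}")
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")


def model_to_json(model: ParafacModel, path) -> None:
    """Serialise a fitted model (scores, loadings, grids, diagnostics) to JSON."""
    payload = {
        "n_components": model.n_components,
        "explained_variance": model.explained_variance,
        "converged": bool(model.converged),
        "iterations": int(model.iterations),
        "seed": model.seed,
        "em": model.em.tolist(),
        "ex": model.ex.tolist(),
        "scores": model.scores.tolist(),
        "em_loadings": model.em_loadings.tolist(),
        "ex_loadings": model.ex_loadings.tolist(),
    }
    with open(path, "w") as fh:
        json.dump(payload, fh)


def model_from_json(path) -> ParafacModel:
    """Load a reference model written by :func:`model_to_json`."""
    with open(path) as fh:
        d = json.load(fh)
    return ParafacModel(
        scores=np.asarray(d["scores"], float),
        em_loadings=np.asarray(d["em_loadings"], float),
        ex_loadings=np.asarray(d["ex_loadings"], float),
        em=np.asarray(d["em"], float),
        ex=np.asarray(d["ex"], float),
        n_components=int(d["n_components"]),
        explained_variance=float(d["explained_variance"]),
        converged=bool(d["converged"]),
        iterations=int(d["iterations"]),
        seed=d.get("seed"),
    )


def model_congruence(model: ParafacModel, reference: ParafacModel):
    """Match a model against a reference and report per-pair congruences."""
    pairs, em_c, ex_c = match_components(model, reference)
    return pairs, em_c, ex_c, em_c * ex_c
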