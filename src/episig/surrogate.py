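"""Surrogate-variable estimation from model residuals.

Surrogate variables (SVs) absorb latent structure — in blood methylation,
chiefly cell-composition differences — that the known design does not
capture.  The number of SVs is chosen by parallel analysis: the observed
residual variance fractions are compared with the 95th percentile of the
same fractions after independently permuting each probe's residual row
(and re-projecting onto the residual space of the design, which keeps the
permutation null on the same footing as the observed matrix).  SVs
themselves are the leading right singular vectors of the residual matrix.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import AnalysisConfig, ConfigError, DesignError, MValueMatrix


@dataclass
class SurrogateSet:
    sample_ids: pd.Index
    k: int
    sv: pd.DataFrame  # samples x k, orthonormal columns
    variance_explained: np.ndarray

    def __post_init__(self) -> None:
        if self.k < 0:
            raise ConfigError("k must be nonnegative")
        if self.k and self.sv.shape != (len(self.sample_ids), self.k):
            raise ConfigError("SV matrix shape disagrees with (n_samples, k)")


def _as_design_array(design) -> np.ndarray:
    X = np.asarray(getattr(design, "values", design), dtype=float)
    if X.ndim != 2:
        raise DesignError("design must be a 2-D samples-by-covariates matrix")
    return X


def _design_column_names(design) -> list[str]:
    cols = getattr(design, "columns", None)
    if cols is None:
        cols = getattr(getattr(design, "values", None), "columns", None)
    return list(cols) if cols is not None else []


def _check_full_rank(X: np.ndarray, design) -> None:
    if np.linalg.matrix_rank(X) < X.shape[1]:
        names = _design_column_names(design) or [f"col{i}" for i in range(X.shape[1])]
        # name columns whose removal restores full rank
        bad = [
            names[j]
            for j in range(X.shape[1])
            if np.linalg.matrix_rank(np.delete(X, j, axis=1)) == np.linalg.matrix_rank(X)
        ]
        raise DesignError(f"design matrix is rank deficient; collinear columns: {bad}")


def _residuals(m: MValueMatrix, X: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Residual matrix over probes with no missingness, and the residual projector."""
    Y = m.m.to_numpy()
    complete = ~np.isnan(Y).any(axis=1)
    Y = Y[complete]
    if Y.shape[0] == 0:
        raise ConfigError("no probes without missing values; cannot form residuals")
    proj = X @ np.linalg.pinv(X)  # hat matrix, n x n
    resid_proj = np.eye(X.shape[0]) - proj
    return Y @ resid_proj, resid_proj


def _variance_fractions(R: np.ndarray) -> np.ndarray:
    ev = np.linalg.eigvalsh(R.T @ R)[::-1]
    ev = np.clip(ev, 0.0, None)
    total = ev.sum()
    return ev / total if total > 0 else ev


def estimate_n_sv(m: MValueMatrix, design, cfg: AnalysisConfig) -> int:
    """Estimate the number of significant surrogate variables by permutation."""
    X = _as_design_array(design)
    n = X.shape[0]
    if m.m.shape[1] != n:
        raise DesignError("design rows do not match number of samples")
    if n < X.shape[1] + 2:
        raise DesignError(
            f"need at least {X.shape[1] + 2} samples for {X.shape[1]} design columns"
        )
    _check_full_rank(X, design)

    R, resid_proj = _residuals(m, X)
    obs = _variance_fractions(R)
    rank = int(round(np.trace(resid_proj)))  # residual rank = n - rank(X)

    rng = np.random.default_rng(cfg.rng_seed)
    perm_fracs = np.empty((cfg.sva_permutations, n))
    for b in range(cfg.sva_permutations):
        idx = rng.random(R.shape).argsort(axis=1)
        Rp = np.take_along_axis(R, idx, axis=1) @ resid_proj
        perm_fracs[b] = _variance_fractions(Rp)
    # 'higher' makes the cut an order statistic: conservative for few permutations
    thresh = np.percentile(perm_fracs, 95, axis=0, method="higher")

    k = 0
    for i in range(max(rank, 0)):
        if obs[i] > thresh[i]:
            k += 1
        else:
            break
    return k


def _right_singular_vectors(Y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    ev, vec = np.linalg.eigh(Y.T @ Y)
    order = np.argsort(ev)[::-1]
    return np.clip(ev[order], 0.0, None), vec[:, order]


def construct_svs(m: MValueMatrix, design, k: int) -> SurrogateSet:
    """Two-step surrogate construction, sign-fixed and orthonormalized.

    Step one finds the leading right singular vectors (eigengenes) of the
    residual matrix.  Step two rebuilds each surrogate from the *raw*
    data: probes associated with the eigengene are selected (BH q < 0.1
    on the per-probe correlation, falling back to the strongest 100) and
    the right singular vector of their row-centered raw data most
    correlated with the eigengene becomes the surrogate.  Rebuilding from
    raw data matters: a bare residual eigenvector is orthogonal to the
    design, so any share of the latent factor that is collinear with the
    main effect would stay aliased with it and confound the fit.
    """
    X = _as_design_array(design)
    n = X.shape[0]
    if k < 0:
        raise ConfigError("k must be nonnegative")
    sample_ids = m.sample_ids
    if k == 0:
        return SurrogateSet(sample_ids, 0, pd.DataFrame(index=sample_ids), np.array([]))
    if k >= n - X.shape[1]:
        raise ConfigError(
            f"k = {k} is too large for {n} samples and {X.shape[1]} design columns"
        )
    R, _ = _residuals(m, X)
    ev, eigenvec = _right_singular_vectors(R)
    Y = m.m.to_numpy()
    Yc = Y[~np.isnan(Y).any(axis=1)]
    Yc = Yc - Yc.mean(axis=1, keepdims=True)
    row_norm = np.linalg.norm(Yc, axis=1)
    row_norm[row_norm == 0] = np.inf

    from scipy import stats as _st

    vs = []
    for j in range(k):
        e = eigenvec[:, j]
        r = (Yc @ e) / row_norm  # e has unit norm
        r = np.clip(r, -1 + 1e-12, 1 - 1e-12)
        tstat = r * np.sqrt((n - 2) / (1 - r**2))
        p = 2.0 * _st.t.sf(np.abs(tstat), n - 2)
        order = np.argsort(p, kind="mergesort")
        qv = np.minimum.accumulate((p[order] * len(p) / np.arange(1, len(p) + 1))[::-1])[::-1]
        sel = np.zeros(len(p), bool)
        sel[order] = qv < 0.1
        if sel.sum() < 25:
            sel = np.zeros(len(p), bool)
            sel[np.argsort(-np.abs(r))[: min(100, len(p))]] = True
        _, subvec = _right_singular_vectors(Yc[sel])
        cors = subvec.T @ e
        best = int(np.abs(cors).argmax())
        v = subvec[:, best] * np.sign(cors[best])
        vs.append(v)

    # Gram-Schmidt in order; keeps the invariant of mutually orthonormal scores
    V = np.empty((n, k))
    for j, v in enumerate(vs):
        for i in range(j):
            v = v - (v @ V[:, i]) * V[:, i]
        nrm = np.linalg.norm(v)
        V[:, j] = v / nrm if nrm > 0 else eigenvec[:, j]
    flips = np.sign(V[np.abs(V).argmax(axis=0), np.arange(k)])
    flips[flips == 0] = 1.0
    V = V * flips
    frac = ev[:k] / ev.sum() if ev.sum() > 0 else ev[:k]
    sv = pd.DataFrame(V, index=sample_ids, columns=[f"SV{i + 1}" for i in range(k)])
    return SurrogateSet(sample_ids, k, sv, frac)


def canonical_correlations(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Canonical correlations between two column spaces (for recovery checks)."""
    qa, _ = np.linalg.qr(a - a.mean(axis=0))
    qb, _ = np.linalg.qr(b - b.mean(axis=0))
    s = np.linalg.svd(qa.T @ qb, compute_uv=False)
    return np.clip(s, 0.0, 1.0)
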