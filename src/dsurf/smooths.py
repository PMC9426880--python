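"""Low-rank thin-plate regression splines with null-space shrinkage.

A smooth of 1 or 2 covariates is built from radial basis functions at a
deterministic knot subset plus the polynomial null space (order m = 2).  The
null-space block of the wiggliness penalty is replaced by a small multiple of
the smallest positive penalty eigenvalue so the whole term can shrink to
zero ("shrinkage" smooths).  Columns are centred (sum-to-zero over the
training rows) for identifiability next to a free intercept.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

#: null-space penalty = SHRINK_FRAC * smallest positive penalty eigenvalue
SHRINK_FRAC = 0.1


def _eta(r: np.ndarray, d: int) -> np.ndarray:
    """Thin-plate radial basis function (m=2): r^3 for d=1, r^2 log r for d=2."""
    if d == 1:
        return r**3
    with np.errstate(divide="ignore", invalid="ignore"):
        out = r**2 * np.log(r)
    return np.where(r > 0, out, 0.0)


def _select_knots(values: np.ndarray, k: int) -> np.ndarray:
    """Deterministic knot subset: unique rows in lexicographic order, thinned
    to k by even spacing.  Order-invariant w.r.t. input row order."""
    uniq = np.unique(values, axis=0)
    if uniq.shape[0] <= k:
        return uniq
    idx = np.unique(np.round(np.linspace(0, uniq.shape[0] - 1, k)).astype(int))
    return uniq[idx]


@dataclass
class ThinPlateSmooth:
    """One fitted-basis smooth term (data-dependent construction)."""

    name: str
    covariates: list[str]
    k: int
    knots: np.ndarray = field(repr=False)          # (k_knots, d) scaled space
    shift: np.ndarray = field(repr=False)          # covariate centering
    scale: np.ndarray = field(repr=False)          # covariate scaling
    Z: np.ndarray = field(repr=False)              # null-space absorber
    col_center: np.ndarray = field(repr=False)     # training column means
    S: np.ndarray = field(repr=False)              # penalty (with shrinkage)
    n_cols: int = 0

    def _scaled(self, rows) -> np.ndarray:
        V = np.column_stack([np.asarray(rows[c], float) for c in self.covariates])
        return (V - self.shift) / self.scale

    def basis(self, rows, center: bool = True) -> np.ndarray:
        """Evaluate the (centred) design columns of this smooth at new rows."""
        P = self._scaled(rows)
        d = P.shape[1]
        r = np.sqrt(((P[:, None, :] - self.knots[None, :, :]) ** 2).sum(axis=2))
        X = np.column_stack([_eta(r, d) @ self.Z, P])
        if center:
            X = X - self.col_center
        return X


def build_smooth(name: str, covariates: list[str], rows, k: int) -> ThinPlateSmooth:
    """Construct a shrinkage TPRS basis from training rows.

    ``k`` is the requested basis dimension (columns = k - 1 after the
    identifiability constraint); it is reduced with a warning when the data
    support fewer unique knot locations.
    """
    V = np.column_stack([np.asarray(rows[c], float) for c in covariates])
    if not np.all(np.isfinite(V)):
        raise ValueError(f"non-finite values in smooth covariates {covariates}")
    d = V.shape[1]
    if d not in (1, 2):
        raise ValueError("smooths support 1 or 2 covariates")
    shift = V.mean(axis=0)
    scale = V.std(axis=0)
    scale[scale == 0] = 1.0
    P = (V - shift) / scale

    M = d + 1  # polynomial null-space dimension for m=2
    n_unique = np.unique(P, axis=0).shape[0]
    if k > n_unique:
        import warnings

        warnings.warn(
            f"smooth {name!r}: basis dimension {k} exceeds {n_unique} unique "
            f"covariate rows; reduced", stacklevel=2,
        )
        k = max(M + 2, n_unique)
    knots = _select_knots(P, k)
    kk = knots.shape[0]

    r = np.sqrt(((knots[:, None, :] - knots[None, :, :]) ** 2).sum(axis=2))
    E = _eta(r, d)
    T = np.column_stack([np.ones(kk), knots])
    Q, _ = np.linalg.qr(T, mode="complete")
    Z = Q[:, M:]

    S_rad = Z.T @ E @ Z
    S_rad = 0.5 * (S_rad + S_rad.T)
    vals, vecs = np.linalg.eigh(S_rad)
    vals = np.clip(vals, 0.0, None)
    S_rad = vecs @ np.diag(vals) @ vecs.T

    q_rad = S_rad.shape[0]
    q_poly = M - 1  # intercept handled globally
    S = np.zeros((q_rad + q_poly, q_rad + q_poly))
    S[:q_rad, :q_rad] = S_rad
    pos = vals[vals > 1e-10 * vals.max()] if vals.max() > 0 else np.array([1.0])
    eps = SHRINK_FRAC * float(pos.min())
    # shrinkage: penalize the (polynomial) null space slightly so the whole
    # term can be shrunk out of the model
    S[q_rad:, q_rad:] = eps * np.eye(q_poly)
    S /= np.abs(S).max()

    sm = ThinPlateSmooth(
        name=name, covariates=list(covariates), k=k, knots=knots,
        shift=shift, scale=scale, Z=Z,
        col_center=np.zeros(q_rad + q_poly), S=S, n_cols=q_rad + q_poly,
    )
    sm.col_center = sm.basis(rows, center=False).mean(axis=0)
    return sm
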