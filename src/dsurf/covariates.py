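"""Standardization and correlation-matrix PCA of landscape covariates.

Loadings are reported correlation-scaled (eigenvector * sqrt(eigenvalue)),
so per-component percent contributions are 100 * loading^2 / eigenvalue.
Components are retained by the latent-root criterion (eigenvalue >= 1) and
interpreted against |loading| thresholds of 0.40 (moderate) and 0.60
(strong).
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np
import pandas as pd


@dataclass
class PcaModel:
    covariates: list[str]
    means: np.ndarray
    sds: np.ndarray
    eigenvalues: np.ndarray          # non-increasing
    eigenvectors: np.ndarray         # covariate x component, unit columns
    n_retained: int

    @property
    def loadings(self) -> np.ndarray:
        """Correlation-scaled loadings: eigenvector * sqrt(eigenvalue)."""
        return self.eigenvectors * np.sqrt(self.eigenvalues)[None, :]

    @property
    def pct_variance(self) -> np.ndarray:
        return 100.0 * self.eigenvalues / self.eigenvalues.sum()

    def to_json(self) -> str:
        return json.dumps(
            {
                "covariates": self.covariates,
                "means": self.means.tolist(),
                "sds": self.sds.tolist(),
                "eigenvalues": self.eigenvalues.tolist(),
                "eigenvectors": self.eigenvectors.tolist(),
                "n_retained": self.n_retained,
            }
        )

    @classmethod
    def from_json(cls, text: str) -> "PcaModel":
        d = json.loads(text)
        return cls(
            covariates=d["covariates"],
            means=np.asarray(d["means"]),
            sds=np.asarray(d["sds"]),
            eigenvalues=np.asarray(d["eigenvalues"]),
            eigenvectors=np.asarray(d["eigenvectors"]),
            n_retained=int(d["n_retained"]),
        )


def fit_pca(table: pd.DataFrame, covariates: list[str] | None = None) -> PcaModel:
    """Correlation-matrix PCA of the covariate columns of ``table``.

    Components are ordered by eigenvalue; each eigenvector's sign is
    canonicalized so the covariate with the largest |loading| loads positive.
    """
    if covariates is None:
        covariates = [c for c in table.columns]
    if len(covariates) < 2:
        raise ValueError("need at least 2 covariates")
    X = table[covariates].to_numpy(float)
    if X.shape[0] < 3:
        raise ValueError("need at least 3 rows")
    if not np.all(np.isfinite(X)):
        raise ValueError("missing or non-finite covariate values")
    means = X.mean(axis=0)
    sds = X.std(axis=0, ddof=1)
    zero = [covariates[i] for i in np.nonzero(sds == 0)[0]]
    if zero:
        raise ValueError(f"zero-variance covariate(s): {zero}")
    Z = (X - means) / sds
    corr = np.corrcoef(Z, rowvar=False)
    vals, vecs = np.linalg.eigh(corr)
    order = np.argsort(vals)[::-1]
    vals = np.clip(vals[order], 0.0, None)
    vecs = vecs[:, order]
    for j in range(vecs.shape[1]):  # deterministic sign convention
        i = int(np.argmax(np.abs(vecs[:, j])))
        if vecs[i, j] < 0:
            vecs[:, j] = -vecs[:, j]
    model = PcaModel(
        covariates=list(covariates), means=means, sds=sds,
        eigenvalues=vals, eigenvectors=vecs, n_retained=0,
    )
    model.n_retained = retain_components(model)
    return model


def retain_components(model: PcaModel) -> int:
    """Latent-root criterion: number of eigenvalues >= 1."""
    return int(np.sum(model.eigenvalues >= 1.0))


def contributions(model: PcaModel) -> pd.DataFrame:
    """Percent contribution table: 100 * loading^2 / eigenvalue per component.

    Columns sum to 100 for every component with a positive eigenvalue.
    """
    lam = model.eigenvalues
    with np.errstate(invalid="ignore", divide="ignore"):
        contrib = 100.0 * model.loadings**2 / lam[None, :]
    cols = [f"PC{j + 1}" for j in range(len(lam))]
    return pd.DataFrame(contrib, index=model.covariates, columns=cols)


def score(model: PcaModel, rows: pd.DataFrame, n_components: int | None = None) -> pd.DataFrame:
    """Project rows onto the principal axes using training means/sds.

    Training-set scores have mean ~0 and variance ~eigenvalue per component.
    """
    missing = [c for c in model.covariates if c not in rows.columns]
    if missing:
        raise ValueError(f"rows lack training covariates: {missing}")
    k = n_components or model.n_retained or len(model.covariates)
    Z = (rows[model.covariates].to_numpy(float) - model.means) / model.sds
    S = Z @ model.eigenvectors[:, :k]
    return pd.DataFrame(S, index=rows.index, columns=[f"PC{j + 1}" for j in range(k)])


def interpret_loadings(
    model: PcaModel, strong: float = 0.60, moderate: float = 0.40
) -> pd.DataFrame:
    """Flag covariates per component as strong / moderate / none by |loading|."""
    L = np.abs(model.loadings)
    labels = np.where(L >= strong, "strong", np.where(L >= moderate, "moderate", "none"))
    cols = [f"PC{j + 1}" for j in range(L.shape[1])]
    return pd.DataFrame(labels, index=model.covariates, columns=cols)
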