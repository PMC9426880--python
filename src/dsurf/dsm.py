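"""Stage-2 density surface model.

A Tweedie GAM (log link) of Horvitz-Thompson-corrected segment abundances on
a bivariate thin-plate smooth of planar coordinates and univariate smooths
of principal-component scores, with a log effort-area offset.  Smoothing
parameters are chosen by a (quasi-)REML criterion, the Tweedie power is
profiled on a deterministic grid, shrinkage penalties allow terms to leave
the model, and detection-function uncertainty is propagated into the
coefficient covariance by refitting with an auxiliary random-effect term.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from itertools import combinations
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats
from statsmodels.genmod.families import Tweedie

from .smooths import ThinPlateSmooth, build_smooth

TERM_POOL = ("xy", "PC1", "PC2", "PC3")
DEFAULT_POWER_GRID = (1.2, 1.35, 1.5, 1.65, 1.8)


class DsmError(RuntimeError):
    pass


@dataclass(frozen=True)
class DsmSpec:
    """Model specification: smooth terms, basis dimensions, Tweedie power."""

    terms: tuple[str, ...] = ("xy", "PC1")
    k_xy: int = 25
    k_pc: int = 10
    tweedie_power: float | None = None  # None -> profile over power_grid
    power_grid: tuple[float, ...] = DEFAULT_POWER_GRID

    def __post_init__(self):
        unknown = [t for t in self.terms if t not in TERM_POOL]
        if unknown:
            raise ValueError(f"unknown DSM terms {unknown}; pool is {TERM_POOL}")
        if self.k_xy < 10:
            raise ValueError("k_xy must be >= 10")


def tweedie_deviance(y: np.ndarray, mu: np.ndarray, p: float) -> float:
    """Tweedie unit deviance summed over observations (1 < p < 2)."""
    y = np.asarray(y, float)
    mu = np.asarray(mu, float)
    a, b = 1.0 - p, 2.0 - p
    yp = np.where(y > 0, y, 1.0)
    d = 2.0 * (
        np.where(y > 0, y * (yp**a - mu**a) / a, 0.0)
        - (np.where(y > 0, y**b, 0.0) - mu**b) / b
    )
    return float(np.sum(d))


def _pirls(
    X: np.ndarray,
    y: np.ndarray,
    offset: np.ndarray,
    S: np.ndarray,
    power: float,
    beta0: np.ndarray | None = None,
    max_iter: int = 200,
    tol: float = 1e-9,
):
    """Penalized IRLS for a Tweedie log-link model.

    Returns (beta, mu, W diagonal, penalized deviance, deviance).
    """
    n, q = X.shape
    if beta0 is None:
        mu = y + 0.1 * max(float(np.mean(y)), 1e-3)
        eta = np.log(mu)
        beta = np.linalg.lstsq(X, eta - offset, rcond=None)[0]
    else:
        beta = beta0.copy()
    eta = X @ beta + offset
    eta = np.clip(eta, -30, 30)
    mu = np.exp(eta)
    pdev = tweedie_deviance(y, mu, power) + float(beta @ S @ beta)
    for _ in range(max_iter):
        w = mu ** (2.0 - power)
        z = (eta - offset) + (y - mu) / mu
        XW = X * w[:, None]
        A = XW.T @ X + S
        rhs = XW.T @ z
        try:
            beta_new = np.linalg.solve(A, rhs)
        except np.linalg.LinAlgError:
            beta_new = np.linalg.solve(A + 1e-8 * np.eye(q) * np.trace(A) / q, rhs)
        # step halving if the penalized deviance worsens
        step = 1.0
        for _half in range(30):
            cand = beta + step * (beta_new - beta)
            eta_c = np.clip(X @ cand + offset, -30, 30)
            mu_c = np.exp(eta_c)
            pdev_c = tweedie_deviance(y, mu_c, power) + float(cand @ S @ cand)
            if np.isfinite(pdev_c) and pdev_c <= pdev + 1e-12 * (1 + abs(pdev)):
                break
            step *= 0.5
        else:
            raise DsmError("PIRLS diverged: step halving failed")
        delta = abs(pdev - pdev_c)
        beta, eta, mu, pdev = cand, eta_c, mu_c, pdev_c
        if delta < tol * (0.1 + abs(pdev)):
            break
    dev = tweedie_deviance(y, mu, power)
    w = mu ** (2.0 - power)
    return beta, mu, w, pdev, dev


def _assemble_penalty(q: int, blocks: list[tuple[slice, np.ndarray]], lam: np.ndarray) -> np.ndarray:
    S = np.zeros((q, q))
    for (sl, Sm), lm in zip(blocks, lam):
        S[sl, sl] += lm * Sm
    return S


def _reml_score(
    X, y, offset, blocks, log_lam, power, beta_warm=None
) -> tuple[float, np.ndarray]:
    """Quasi-REML score (smaller is better) at the given log smoothing
    parameters, with the scale profiled out."""
    lam = np.exp(np.clip(log_lam, -25, 25))
    q = X.shape[1]
    S = _assemble_penalty(q, blocks, lam)
    try:
        beta, mu, w, pdev, _dev = _pirls(X, y, offset, S, power, beta0=beta_warm)
    except DsmError:
        return 1e12, beta_warm if beta_warm is not None else np.zeros(q)
    n = len(y)
    M = q - sum(Sm.shape[0] for _sl, Sm in blocks)  # unpenalized coefficients
    phi = pdev / max(n - M, 1)
    phi = max(phi, 1e-12)
    XWX = (X * w[:, None]).T @ X
    sign, logdet_A = np.linalg.slogdet(XWX + S)
    if sign <= 0:
        return 1e12, beta
    logdet_S = 0.0
    for (sl, Sm), lm in zip(blocks, lam):
        s2, ld = np.linalg.slogdet(lm * Sm)
        if s2 <= 0:
            return 1e12, beta
        logdet_S += ld
    score = (
        pdev / (2.0 * phi)
        + 0.5 * (logdet_A - logdet_S)
        + 0.5 * ((n - M) * np.log(2.0 * np.pi * phi) - M * np.log(phi))
    )
    return float(score), beta


def tweedie_loglik(y: np.ndarray, mu: np.ndarray, phi: float, power: float) -> float:
    """Exact Tweedie log-likelihood (series evaluation)."""
    fam = Tweedie(var_power=power, eql=False)
    return float(np.sum(fam.loglike_obs(np.asarray(y, float), np.asarray(mu, float), scale=phi)))


@dataclass
class DsmFit:
    """Fitted density surface model."""

    spec: DsmSpec
    smooths: dict[str, ThinPlateSmooth]
    term_slices: dict[str, slice]
    beta: np.ndarray
    lambdas: dict[str, float]
    power: float
    phi: float
    V_base: np.ndarray
    V_prop: np.ndarray | None = None
    cv_det_rel: float = 0.0     # relative detection CV of the HT total (delta fallback)
    edf_by_term: dict[str, float] = field(default_factory=dict)
    edf_total: float = np.nan
    loglik: float = np.nan
    aic: float = np.nan
    deviance: float = np.nan
    n_obs: int = 0
    reml_score: float = np.nan
    # training state retained for variance propagation
    X: np.ndarray | None = field(default=None, repr=False)
    y: np.ndarray | None = field(default=None, repr=False)
    offset: np.ndarray | None = field(default=None, repr=False)
    w_irls: np.ndarray | None = field(default=None, repr=False)
    S_lambda: np.ndarray | None = field(default=None, repr=False)
    segment_ids: np.ndarray | None = field(default=None, repr=False)

    @property
    def V(self) -> np.ndarray:
        """Coefficient covariance for downstream uncertainty (propagated when
        available)."""
        return self.V_base if self.V_prop is None else self.V_prop

    def design(self, rows: pd.DataFrame) -> np.ndarray:
        """Model matrix for new rows (intercept + smooth columns)."""
        cols = [np.ones(len(rows))]
        for term in self.spec.terms:
            cols.append(self.smooths[term].basis(rows))
        return np.column_stack(cols)

    def predict_eta(self, rows: pd.DataFrame) -> np.ndarray:
        """Link-scale prediction per unit area (no offset)."""
        return self.design(rows) @ self.beta

    def fitted(self) -> np.ndarray:
        return np.exp(self.X @ self.beta + self.offset)


def build_smooths(spec: DsmSpec, rows: pd.DataFrame) -> dict[str, ThinPlateSmooth]:
    """Construct the shrinkage TPRS bases declared by ``spec`` from training
    rows (coordinates in km, PC scores present as columns)."""
    smooths: dict[str, ThinPlateSmooth] = {}
    for term in spec.terms:
        if term == "xy":
            smooths[term] = build_smooth("xy", ["x", "y"], rows, spec.k_xy)
        else:
            smooths[term] = build_smooth(term, [term], rows, spec.k_pc)
    return smooths


def fit_dsm(
    segments: pd.DataFrame,
    spec: DsmSpec,
    response: str = "n_hat",
    effort_col: str = "effort_area",
    min_segments: int = 30,
) -> DsmFit:
    """Fit the Tweedie GAM of HT-corrected segment abundance.

    ``segments`` carries the response, coordinates (km), PC-score columns for
    any PC terms, and a positive effort area whose log is the offset.
    """
    if len(segments) < min_segments:
        raise DsmError(f"need >= {min_segments} segments, got {len(segments)}")
    y = segments[response].to_numpy(float)
    if np.all(y == 0):
        raise DsmError("all-zero response: degenerate fit")
    eff = segments[effort_col].to_numpy(float)
    if np.any(eff <= 0):
        raise DsmError("offsets (effort areas) must be > 0")
    offset = np.log(eff)

    smooths = build_smooths(spec, segments)
    cols = [np.ones(len(segments))]
    slices: dict[str, slice] = {}
    blocks: list[tuple[slice, np.ndarray]] = []
    pos = 1
    for term in spec.terms:
        B = smooths[term].basis(segments)
        sl = slice(pos, pos + B.shape[1])
        slices[term] = sl
        blocks.append((sl, smooths[term].S))
        cols.append(B)
        pos += B.shape[1]
    X = np.column_stack(cols)
    n, q = X.shape

    powers = [spec.tweedie_power] if spec.tweedie_power is not None else list(spec.power_grid)
    best = None
    log_lam0 = None
    for ip, power in enumerate(powers):
        if blocks:
            if log_lam0 is None:
                # start lambdas so penalty and information are comparable
                start = []
                for sl, Sm in blocks:
                    xb = X[:, sl]
                    start.append(np.log(max(np.trace(xb.T @ xb), 1e-8) / max(np.trace(Sm), 1e-8)))
                log_lam0 = np.array(start)
            warm = {"beta": None}

            def obj(ll):
                s, b = _reml_score(X, y, offset, blocks, ll, power, beta_warm=warm["beta"])
                if np.isfinite(s) and s < 1e11:
                    warm["beta"] = b
                return s

            res = optimize.minimize(
                obj, log_lam0, method="Nelder-Mead",
                options={"maxfev": 400 if ip == 0 else 150, "xatol": 1e-3, "fatol": 1e-4},
            )
            log_lam = res.x
            reml = float(res.fun)
            log_lam0 = log_lam  # warm start across powers
        else:
            log_lam, reml = np.array([]), np.nan

        lam = np.exp(np.clip(log_lam, -25, 25))
        S = _assemble_penalty(q, blocks, lam)
        beta, mu, w, pdev, dev = _pirls(X, y, offset, S, power)
        XWX = (X * w[:, None]).T @ X
        A = XWX + S
        Ainv = np.linalg.inv(A)
        F = Ainv @ XWX
        edf_cols = np.diag(F)
        edf_total = float(np.sum(edf_cols))
        phi = float(np.sum((y - mu) ** 2 / mu**power) / max(n - edf_total, 1.0))
        ll = tweedie_loglik(y, mu, phi, power)
        cand = {
            "power": power, "log_lam": log_lam, "beta": beta, "mu": mu, "w": w,
            "S": S, "Ainv": Ainv, "edf_cols": edf_cols, "edf_total": edf_total,
            "phi": phi, "loglik": ll, "dev": dev, "reml": reml,
        }
        if best is None or ll > best["loglik"]:
            best = cand

    edf_by_term = {
        t: float(np.sum(best["edf_cols"][slices[t]])) for t in spec.terms
    }
    # +2: scale and power estimated alongside the smooth coefficients
    aic = -2.0 * best["loglik"] + 2.0 * (best["edf_total"] + 2.0)
    fit = DsmFit(
        spec=replace(spec, tweedie_power=best["power"]),
        smooths=smooths,
        term_slices=slices,
        beta=best["beta"],
        lambdas={t: float(np.exp(l)) for t, l in zip(spec.terms, best["log_lam"])},
        power=best["power"],
        phi=best["phi"],
        V_base=best["phi"] * best["Ainv"],
        edf_by_term=edf_by_term,
        edf_total=best["edf_total"],
        loglik=best["loglik"],
        aic=aic,
        deviance=best["dev"],
        n_obs=n,
        reml_score=best["reml"],
        X=X,
        y=y,
        offset=offset,
        w_irls=best["w"],
        S_lambda=best["S"],
        segment_ids=segments["segment_id"].to_numpy() if "segment_id" in segments else None,
    )
    return fit


def all_subsets_select(
    segments: pd.DataFrame,
    pool: Sequence[str] = TERM_POOL,
    spec: DsmSpec | None = None,
    delta_aic: float = 2.0,
    **fit_kwargs,
) -> tuple[pd.DataFrame, dict[tuple[str, ...], DsmFit], DsmFit]:
    """Fit every subset of ``pool`` (incl. the null model), rank by AIC, and
    apply the parsimony rule (fewest terms within ``delta_aic`` of the best,
    ties by lower AIC)."""
    if not pool:
        raise ValueError("term pool must be non-empty")
    base = spec or DsmSpec(terms=tuple(pool))
    fits: dict[tuple[str, ...], DsmFit] = {}
    errors = {}
    for r in range(len(pool) + 1):
        for terms in combinations(pool, r):
            try:
                fits[terms] = fit_dsm(segments, replace(base, terms=terms), **fit_kwargs)
            except (DsmError, np.linalg.LinAlgError) as exc:  # pragma: no cover
                errors[terms] = str(exc)
    if not fits:
        raise DsmError(f"all candidate fits failed: {errors}")
    rows = []
    best_aic = min(f.aic for f in fits.values())
    for terms, f in fits.items():
        rows.append(
            {
                "model": "+".join(terms) if terms else "null",
                "n_terms": len(terms),
                "edf": f.edf_total,
                "power": f.power,
                "AIC": f.aic,
                "dAIC": f.aic - best_aic,
            }
        )
    table = pd.DataFrame(rows).sort_values(["dAIC", "n_terms"], kind="stable").reset_index(drop=True)
    window = [t for t, f in fits.items() if f.aic - best_aic <= delta_aic]
    selected_terms = min(window, key=lambda t: (len(t), fits[t].aic, "+".join(t)))
    return table, fits, fits[selected_terms]


def propagate_detection_variance(fit: DsmFit, det_fit, obs: pd.DataFrame) -> DsmFit:
    """Propagate detection-parameter uncertainty into the GAM covariance.

    Refits the working penalized model augmented with per-segment columns of
    d log(HT response)/d theta treated as a random effect with prior
    covariance equal to the detection-parameter covariance.  Falls back to a
    delta-method CV combination when the detection covariance is singular.
    The propagated covariance never shrinks predicted-abundance uncertainty
    below the base fit (enforced downstream via ``cv_det_rel``).
    """
    if fit.X is None:
        raise DsmError("fit does not retain training state")
    theta = det_fit.theta
    V_det = det_fit.vcov
    q = fit.X.shape[1]

    # d log(sum s_i/p_i)/d theta per segment, finite differences
    from .detection import average_p

    design = det_fit.design_for(obs)
    sizes = obs["group_size"].to_numpy(float)
    seg_of_obs = obs["segment_id"].to_numpy()
    seg_ids = fit.segment_ids
    seg_index = {s: i for i, s in enumerate(seg_ids)}

    def log_ht_by_segment(t):
        if det_fit.log_b is not None:
            beta, b = t[:-1], float(np.exp(t[-1]))
        else:
            beta, b = t, None
        p = average_p(np.exp(design @ beta), det_fit.model.truncation, key=det_fit.model.key, b=b)
        ht = np.zeros(len(seg_ids))
        np.add.at(ht, [seg_index[s] for s in seg_of_obs], sizes / p)
        with np.errstate(divide="ignore"):
            return np.where(ht > 0, np.log(np.where(ht > 0, ht, 1.0)), 0.0), ht

    D = np.zeros((len(seg_ids), theta.size))
    for k in range(theta.size):
        step = 1e-5 * max(1.0, abs(theta[k]))
        tp = theta.copy(); tp[k] += step
        tm = theta.copy(); tm[k] -= step
        lp, _ = log_ht_by_segment(tp)
        lm, _ = log_ht_by_segment(tm)
        D[:, k] = (lp - lm) / (2 * step)

    _l0, ht0 = log_ht_by_segment(theta)
    total = ht0.sum()
    gbar = (ht0 @ D) / total if total > 0 else np.zeros(theta.size)

    if V_det is None or not np.all(np.isfinite(V_det)):
        import warnings

        warnings.warn("singular detection covariance: delta-method fallback only")
        fit.V_prop = fit.V_base.copy()
        fit.cv_det_rel = np.nan
        return fit
    fit.cv_det_rel = float(np.sqrt(max(gbar @ V_det @ gbar, 0.0)))

    try:
        P_delta = fit.phi * np.linalg.inv(V_det)
    except np.linalg.LinAlgError:
        import warnings

        warnings.warn("singular detection covariance: delta-method fallback only")
        fit.V_prop = fit.V_base.copy()
        return fit

    X_aug = np.hstack([fit.X, D])
    S_aug = np.zeros((q + theta.size, q + theta.size))
    S_aug[:q, :q] = fit.S_lambda
    S_aug[q:, q:] = 0.5 * (P_delta + P_delta.T)
    beta0 = np.concatenate([fit.beta, np.zeros(theta.size)])
    beta_a, mu_a, w_a, _pdev, _dev = _pirls(X_aug, fit.y, fit.offset, S_aug, fit.power, beta0=beta0)
    A = (X_aug * w_a[:, None]).T @ X_aug + S_aug
    V_aug = fit.phi * np.linalg.inv(A)
    fit.V_prop = V_aug[:q, :q]
    return fit


def term_significance(fit: DsmFit) -> pd.DataFrame:
    """Wald-type per-term tests using the propagated covariance.

    Returns edf, reference df (basis columns), an F statistic on
    ~round(edf) effective directions, and its p-value.
    """
    rows = []
    n = fit.n_obs
    V = fit.V
    for term, sl in fit.term_slices.items():
        b = fit.beta[sl]
        Vt = V[sl, sl]
        edf = fit.edf_by_term[term]
        r = max(1, int(round(edf)))
        vals, vecs = np.linalg.eigh(0.5 * (Vt + Vt.T))
        order = np.argsort(vals)[::-1]
        vals, vecs = vals[order], vecs[:, order]
        keep = vals[:r] > max(vals[0], 0) * 1e-10
        U = vecs[:, :r][:, keep]
        lv = vals[:r][keep]
        if lv.size == 0:
            stat, p = 0.0, 1.0
        else:
            proj = U.T @ b
            stat = float(np.sum(proj**2 / lv)) / lv.size
            p = float(stats.f.sf(stat, lv.size, max(n - fit.edf_total, 1.0)))
        rows.append(
            {"term": term, "edf": edf, "ref_df": b.size, "F": stat, "p_value": p}
        )
    return pd.DataFrame(rows)
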