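"""Cell-state proportion estimation by linear-kernel nu-SVR.

The bulk profile is modeled as a nonnegative weighted sum of the signature
columns.  Following the CIBERSORT recipe, signature and mixture are
standardized, a linear nu-SVR is fit for each nu in a small grid, negative
coefficients are truncated and the vector renormalized to the simplex, and
the grid point with the lowest reconstruction RMSE wins.  A nonnegative
least squares solver is provided as an independent oracle.
"""

from __future__ import annotations

from dataclasses import dataclass

import warnings

import numpy as np
import pandas as pd
from scipy.optimize import nnls
from sklearn.exceptions import ConvergenceWarning
from sklearn.svm import NuSVR

from .containers import BulkMethylome
from .signature import SignatureMatrix, build_mixture_matrix

DEFAULT_NU_GRID = (0.25, 0.5, 0.75)
DEFAULT_SVR_C = 1.0
# libsvm stopping tolerance: the default 1e-3 leaves ~1e-3 weight error,
# which matters only when the mixture is an (almost) exact combination of
# signature columns; such fits are polished at the tight tolerance
SVR_TOL = 1e-3
SVR_POLISH_TOL = 1e-6
SVR_POLISH_RMSE = 1e-3  # centered reconstruction RMSE of a noiseless fit
SVR_POLISH_MAX_ITER = 20_000


@dataclass
class CellProportionTable:
    """Per-sample nonnegative cell-state fractions summing to one."""

    proportions: pd.DataFrame  # sample x class
    diagnostics: pd.DataFrame  # sample x (rmse, pearson_r, nu, degenerate)

    @property
    def sample_ids(self) -> pd.Index:
        return self.proportions.index

    @property
    def class_labels(self) -> list[str]:
        return list(self.proportions.columns)


def _standardize(x: np.ndarray) -> tuple[np.ndarray, float, float]:
    mu = float(x.mean())
    sd = float(x.std())
    if sd == 0:
        raise ValueError("zero variance; cannot standardize")
    return (x - mu) / sd, mu, sd


def deconvolve_sample(
    mixture_column: np.ndarray,
    signature: SignatureMatrix | np.ndarray,
    nu_grid: tuple[float, ...] = DEFAULT_NU_GRID,
    C: float = DEFAULT_SVR_C,
    standardize: bool = True,
) -> tuple[np.ndarray, dict]:
    """Estimate one sample's proportions from its signature-CpG betas.

    Returns (proportions, diagnostics).  If every SVR coefficient is
    nonpositive for every nu, the uniform vector is returned with
    ``degenerate=True`` so cohort runs complete.
    """
    S = signature.values.to_numpy() if isinstance(signature, SignatureMatrix) else np.asarray(signature, float)
    m = np.asarray(mixture_column, dtype=float)
    if m.shape[0] != S.shape[0]:
        raise ValueError("mixture not aligned to signature rows")
    if np.isnan(m).any() or np.isnan(S).any():
        raise ValueError("missing values; impute upstream")
    col_sd = S.std(axis=0)
    if np.any(col_sd == 0):
        labels = (
            signature.class_labels
            if isinstance(signature, SignatureMatrix)
            else [str(i) for i in range(S.shape[1])]
        )
        bad = [labels[i] for i in np.flatnonzero(col_sd == 0)]
        raise ValueError(f"zero-variance signature column(s): {bad}")

    if standardize:
        # signature and mixture each z-scored over the signature CpGs; the
        # per-sample mixture scaling makes the normalized output exactly
        # invariant to positive rescaling of the input
        Ss, _, _ = _standardize(S)
        ms, _, _ = _standardize(m)
    else:
        Ss, ms = S, m

    def _fit(nu: float, tol: float, max_iter: int = -1) -> tuple[float, np.ndarray]:
        with warnings.catch_warnings():
            # the capped polish refinement may stop at max_iter by design
            warnings.simplefilter("ignore", ConvergenceWarning)
            fit = NuSVR(kernel="linear", nu=nu, C=C, tol=tol, max_iter=max_iter).fit(Ss, ms)
        w = fit.coef_.ravel().copy()
        w[w < 0] = 0.0
        recon = Ss @ w
        # the fitted intercept absorbs the offset between the mixture and
        # reconstruction means; compare the centered profiles
        recon = recon - recon.mean() + ms.mean()
        rmse = float(np.sqrt(np.mean((recon - ms) ** 2)))
        return rmse, w

    best: tuple[float, np.ndarray, float] | None = None
    for nu in nu_grid:
        rmse, w = _fit(nu, SVR_TOL)
        if best is None or rmse < best[0]:
            best = (rmse, w, nu)

    rmse, w, nu = best
    if rmse < SVR_POLISH_RMSE:
        # near-exact mixture: redo the grid at the tight tolerance
        best = None
        for g in nu_grid:
            r, wg = _fit(g, SVR_POLISH_TOL, max_iter=SVR_POLISH_MAX_ITER)
            if best is None or r < best[0]:
                best = (r, wg, g)
        rmse, w, nu = best
    total = w.sum()
    if total <= 0:
        k = S.shape[1]
        props = np.full(k, 1.0 / k)
        return props, {"rmse": rmse, "pearson_r": np.nan, "nu": nu, "degenerate": True}
    props = w / total
    recon = Ss @ w
    r = float(np.corrcoef(recon, ms)[0, 1]) if np.std(recon) > 0 else np.nan
    return props, {"rmse": rmse, "pearson_r": r, "nu": nu, "degenerate": False}


def nnls_oracle(
    mixture_column: np.ndarray, signature: SignatureMatrix | np.ndarray
) -> np.ndarray:
    """Constrained least-squares verification oracle.

    Solves min ||S w - m||^2 subject to w >= 0 on the raw (unstandardized)
    matrices and renormalizes to the simplex.  A rank-deficient signature
    yields one of the valid solutions (non-unique).
    """
    S = signature.values.to_numpy() if isinstance(signature, SignatureMatrix) else np.asarray(signature, float)
    m = np.asarray(mixture_column, dtype=float)
    w, _ = nnls(S, m)
    total = w.sum()
    if total <= 0:
        return np.full(S.shape[1], 1.0 / S.shape[1])
    return w / total


def deconvolve_cohort(
    bulk: BulkMethylome,
    signature: SignatureMatrix,
    nu_grid: tuple[float, ...] = DEFAULT_NU_GRID,
    C: float = DEFAULT_SVR_C,
    standardize: bool = True,
    mixture: pd.DataFrame | None = None,
) -> CellProportionTable:
    """Apply :func:`deconvolve_sample` to every bulk sample.

    Builds the mixture matrix via :func:`build_mixture_matrix` unless one
    is supplied already aligned to the signature rows.
    """
    if mixture is None:
        mixture, signature = build_mixture_matrix(bulk, signature)
    labels = signature.class_labels
    props = np.zeros((mixture.shape[1], len(labels)))
    diags = []
    for j, sample in enumerate(mixture.columns):
        try:
            props[j], d = deconvolve_sample(
                mixture.iloc[:, j].to_numpy(), signature, nu_grid=nu_grid, C=C,
                standardize=standardize,
            )
        except ValueError as exc:
            raise ValueError(f"sample {sample!r}: {exc}") from exc
        diags.append(d)
    return CellProportionTable(
        proportions=pd.DataFrame(props, index=mixture.columns, columns=labels),
        diagnostics=pd.DataFrame(diags, index=mixture.columns),
    )
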