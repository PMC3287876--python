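"""Covariate adjustment by ordinary least squares.

The trait is regressed on an intercept plus the covariates and the residuals
become the quantitative response for screening.  This two-stage scheme keeps
every downstream variant model free of nuisance terms: both the response and
the centred genotype columns have mean zero, so no intercept is needed there.
Genotype x covariate interactions are deliberately not adjusted for.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


@dataclass
class ResidualTrait:
    """Trait with covariate effects removed.

    Attributes
    ----------
    values : ndarray of shape (n,)
        OLS residuals; mean zero and orthogonal to every covariate column.
    r_squared_covariates : float
        Fraction of trait variance explained by the covariate regression.
    """

    values: np.ndarray
    r_squared_covariates: float


def residualize(trait: np.ndarray, covariates: np.ndarray | None = None) -> ResidualTrait:
    """Remove covariate effects from ``trait`` by least squares.

    Parameters
    ----------
    trait : array-like of shape (n,)
    covariates : array-like of shape (n, c) or None
        Covariate columns; an intercept is always appended internally, so
        ``covariates=None`` (or zero columns) simply mean-centres the trait.

    Raises
    ------
    ValueError
        If the design (intercept + covariates) is rank deficient; the message
        names the first collinear column.
    """
    y = np.asarray(trait, dtype=float).ravel()
    n = y.shape[0]
    if covariates is None:
        Z = np.empty((n, 0))
    else:
        Z = np.asarray(covariates, dtype=float)
        if Z.ndim == 1:
            Z = Z[:, None]
    c = Z.shape[1]
    if n <= c + 1:
        raise ValueError(f"need n > c + 1 individuals (n={n}, c={c})")
    design = np.column_stack([np.ones(n), Z])
    # rank check with a pivoted QR so the offending column can be named
    from scipy.linalg import qr

    _, R, piv = qr(design, mode="economic", pivoting=True)
    diag = np.abs(np.diag(R))
    tol = diag.max() * max(design.shape) * np.finfo(float).eps
    deficient = np.where(diag < tol)[0]
    if deficient.size:
        col = piv[deficient[0]]
        name = "intercept" if col == 0 else f"covariate {col - 1}"
        raise ValueError(f"covariate design is rank deficient ({name} is collinear)")
    beta, *_ = np.linalg.lstsq(design, y, rcond=None)
    resid = y - design @ beta
    tss = float(np.sum((y - y.mean()) ** 2))
    r2 = 0.0 if tss == 0 else 1.0 - float(resid @ resid) / tss
    return ResidualTrait(values=resid, r_squared_covariates=max(0.0, min(1.0, r2)))
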