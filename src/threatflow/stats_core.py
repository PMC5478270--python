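"""Shared statistics for paired safe/threat designs.

All routines use the sample (``ddof=1``) standard deviation, consistent with
the t distributions they reference, and return plain floats so results
serialize directly to JSON/TSV.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as sps

__all__ = [
    "PairedSample",
    "fisher_z",
    "paired_t",
    "pearson_r",
    "ancova_on_differences",
    "within_subject_sem",
]

#: correlations are clipped to this magnitude before atanh so maps stay finite
R_CLIP = 1.0 - 1e-7


@dataclass(frozen=True)
class PairedSample:
    """Per-subject (safe, threat) values with an optional per-subject covariate."""

    safe: np.ndarray
    threat: np.ndarray
    covariate: np.ndarray | None = None

    def __post_init__(self):
        safe = np.asarray(self.safe, float)
        threat = np.asarray(self.threat, float)
        if safe.shape != threat.shape or safe.ndim != 1:
            raise ValueError("safe and threat must be 1-D arrays of equal length")
        if not (np.isfinite(safe).all() and np.isfinite(threat).all()):
            raise ValueError("missing or non-finite pairs are not allowed")
        object.__setattr__(self, "safe", safe)
        object.__setattr__(self, "threat", threat)
        if self.covariate is not None:
            cov = np.asarray(self.covariate, float)
            if cov.shape != safe.shape:
                raise ValueError("covariate must align with the subject axis")
            object.__setattr__(self, "covariate", cov)

    @property
    def differences(self) -> np.ndarray:
        """Threat minus safe, one value per subject."""
        return self.threat - self.safe


def fisher_z(r, clip: bool = False):
    """Variance-stabilizing atanh transform of correlation coefficients.

    Parameters
    ----------
    r : array_like
        Correlation value(s) in [-1, 1].
    clip : bool
        If True, clip ``|r|`` to ``1 - 1e-7`` first (used when perfect
        correlations, e.g. a seed with itself, must stay finite).
    """
    r = np.asarray(r, float)
    if np.any(np.abs(r) > 1 + 1e-12):
        raise ValueError("correlation magnitude exceeds 1")
    if clip:
        r = np.clip(r, -R_CLIP, R_CLIP)
    elif np.any(np.abs(r) > R_CLIP):
        raise ValueError("|r| above clip bound; pass clip=True to saturate")
    out = np.arctanh(r)
    return float(out) if out.ndim == 0 else out


def paired_t(sample: PairedSample) -> tuple[float, int, float]:
    """Two-sided paired t test. Returns ``(t, df, p)``."""
    d = sample.differences
    n = d.size
    if n < 2:
        raise ValueError("paired t needs at least 2 subjects")
    sd = d.std(ddof=1)
    if sd == 0:
        raise ValueError("zero variance in paired differences")
    t = d.mean() / (sd / np.sqrt(n))
    df = n - 1
    p = 2.0 * sps.t.sf(abs(t), df)
    return float(t), df, float(p)


def pearson_r(x, y) -> tuple[float, int, float]:
    """Sample Pearson correlation with df = n - 2 and its two-sided p."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D and aligned")
    n = x.size
    if n < 3:
        raise ValueError("need at least 3 pairs")
    if x.std(ddof=1) == 0 or y.std(ddof=1) == 0:
        raise ValueError("zero variance input")
    r, p = sps.pearsonr(x, y)
    return float(r), n - 2, float(p)


def ancova_on_differences(d, covariate) -> tuple[float, int, int, float]:
    """Condition effect on difference scores, adjusted for a covariate.

    OLS of the per-subject differences on ``[intercept, centered covariate]``;
    the F statistic tests intercept = 0 (the covariate-adjusted condition
    effect) on (1, n - 2) degrees of freedom.

    Returns ``(F, df1, df2, p)``.
    """
    d = np.asarray(d, float)
    cov = np.asarray(covariate, float)
    if d.shape != cov.shape or d.ndim != 1:
        raise ValueError("differences and covariate must be 1-D and aligned")
    n = d.size
    if n < 3:
        raise ValueError("need at least 3 subjects")
    cov_c = cov - cov.mean()
    if np.allclose(cov_c, 0):
        raise ValueError("constant covariate is collinear with the intercept")
    X = np.column_stack([np.ones(n), cov_c])
    beta, _, _, _ = np.linalg.lstsq(X, d, rcond=None)
    resid = d - X @ beta
    df2 = n - 2
    mse = resid @ resid / df2
    # centered covariate makes X'X diagonal: var(beta0) = mse / n
    se0 = np.sqrt(mse / n)
    F = (beta[0] / se0) ** 2
    p = float(sps.f.sf(F, 1, df2))
    return float(F), 1, df2, p


def within_subject_sem(values: np.ndarray, morey: bool = True) -> np.ndarray:
    """Repeated-measures SEM per condition (Cousineau normalization).

    Subject means are removed and the grand mean restored before computing
    each condition's SEM; with ``morey=True`` the result is inflated by
    ``sqrt(C / (C - 1))`` for C conditions.

    Parameters
    ----------
    values : ndarray, shape (n_subjects, n_conditions)
        Complete subject-by-condition matrix.
    """
    x = np.asarray(values, float)
    if x.ndim != 2:
        raise ValueError("expected a subjects x conditions matrix")
    n, c = x.shape
    if c < 2:
        raise ValueError("within-subject SEM needs >= 2 conditions")
    if not np.isfinite(x).all():
        raise ValueError("matrix must be complete")
    norm = x - x.mean(axis=1, keepdims=True) + x.mean()
    sem = norm.std(axis=0, ddof=1) / np.sqrt(n)
    if morey:
        sem = sem * np.sqrt(c / (c - 1))
    return sem
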