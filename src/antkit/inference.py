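"""Inferential statistics for ANT score analyses.

Covers the tests used to characterise the scores: one-sample and paired
t-tests, Pearson correlation, and two-factor repeated-measures ANOVA on a
complete balanced subject × A × B grid, with a subject-by-effect error term
per effect, partial eta squared, and the Greenhouse–Geisser sphericity
correction.

The Greenhouse–Geisser epsilon for an effect with d numerator degrees of
freedom is computed from the sample covariance S of the subjects' cell
scores through an orthonormal contrast matrix C spanning the effect
(a Helmert basis; for the interaction, the Kronecker product of the two
main-effect bases):

    M = C S C',   epsilon = tr(M)^2 / (d * tr(M M))

which lies in [1/d, 1] and equals 1 exactly when d = 1 (two-level factors).
Corrected p-values use F with both degrees of freedom multiplied by epsilon.
Both the uncorrected and corrected p-values are always reported; selecting
between them (e.g. only on sphericity violation) is left to the caller.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats


class DegenerateSampleError(ValueError):
    """The sample cannot support the requested test (zero variance, n too small)."""


@dataclass(frozen=True)
class TestResult:
    """Result of a t-test or of one rm-ANOVA effect."""

    statistic: float                 # t or F
    df: tuple[float, ...]            # (df,) for t; (df1, df2) for F
    p_value: float                   # two-tailed, uncorrected
    effect_size: float | None = None  # partial eta squared (ANOVA only)
    epsilon: float | None = None      # Greenhouse–Geisser epsilon (ANOVA only)
    p_gg: float | None = None         # epsilon-corrected p (ANOVA only)


def one_sample_t(values, mu0: float = 0.0) -> TestResult:
    """Two-tailed one-sample t-test of mean(values) against ``mu0``."""
    x = np.asarray(values, dtype=float)
    if x.ndim != 1 or x.size < 2:
        raise DegenerateSampleError("one_sample_t needs a 1-d sample with n >= 2")
    if np.ptp(x) == 0:
        raise DegenerateSampleError("sample has zero variance")
    t, p = stats.ttest_1samp(x, popmean=mu0)
    return TestResult(statistic=float(t), df=(float(x.size - 1),), p_value=float(p))


def paired_t(a, b) -> TestResult:
    """Paired-samples t-test; identical to ``one_sample_t(a - b, 0)``."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise DegenerateSampleError(
            f"paired samples differ in length: {a.shape} vs {b.shape}"
        )
    return one_sample_t(a - b, 0.0)


def pearson_r(a, b) -> tuple[float, float]:
    """Pearson correlation with its two-tailed p-value."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or a.ndim != 1 or a.size < 3:
        raise DegenerateSampleError("pearson_r needs two equal-length samples, n >= 3")
    if np.ptp(a) == 0 or np.ptp(b) == 0:
        raise DegenerateSampleError("correlation undefined for a constant input")
    r, p = stats.pearsonr(a, b)
    return float(r), float(p)


def _helmert_contrasts(k: int) -> np.ndarray:
    """Orthonormal contrast basis of a k-level within factor, shape (k-1, k)."""
    c = np.zeros((k - 1, k))
    for i in range(1, k):
        c[i - 1, :i] = 1.0
        c[i - 1, i] = -float(i)
        c[i - 1] /= np.linalg.norm(c[i - 1])
    return c


def _gg_epsilon(cells: np.ndarray, contrasts: np.ndarray) -> float:
    """Greenhouse–Geisser epsilon of one effect from subjects' cell scores."""
    d = contrasts.shape[0]
    if d == 1:
        return 1.0
    s = np.cov(cells, rowvar=False, ddof=1)
    m = contrasts @ s @ contrasts.T
    denom = d * float(np.sum(m * m))
    if denom <= 0:
        return 1.0
    eps = float(np.trace(m)) ** 2 / denom
    return float(min(1.0, max(eps, 1.0 / d)))


def rm_anova(
    cells: np.ndarray, factor_names: tuple[str, str] = ("A", "B")
) -> dict[str, TestResult]:
    """Two-factor repeated-measures ANOVA on a complete balanced grid.

    Parameters
    ----------
    cells
        Array of shape ``(n_subjects, a, b)``: every subject contributes a
        score in every A × B cell.  NaN cells are a balanced-design error.
    factor_names
        Labels for the two within-subject factors.

    Returns a dict mapping each effect (the two factor names and
    ``"A*B"``-style interaction) to its :class:`TestResult`.
    """
    y = np.asarray(cells, dtype=float)
    if y.ndim != 3:
        raise ValueError("cells must have shape (n_subjects, a_levels, b_levels)")
    if np.isnan(y).any():
        raise ValueError("balanced design required: grid contains missing cells")
    n, a, b = y.shape
    if n < 2 or a < 2 or b < 2:
        raise DegenerateSampleError("need n >= 2 subjects and >= 2 levels per factor")

    gm = y.mean()
    m_s = y.mean(axis=(1, 2))
    m_a = y.mean(axis=(0, 2))
    m_b = y.mean(axis=(0, 1))
    m_ab = y.mean(axis=0)
    m_sa = y.mean(axis=2)
    m_sb = y.mean(axis=1)

    ss_a = n * b * float(np.sum((m_a - gm) ** 2))
    ss_as = b * float(np.sum((m_sa - m_s[:, None] - m_a[None, :] + gm) ** 2))
    ss_b = n * a * float(np.sum((m_b - gm) ** 2))
    ss_bs = a * float(np.sum((m_sb - m_s[:, None] - m_b[None, :] + gm) ** 2))
    ss_ab = n * float(np.sum((m_ab - m_a[:, None] - m_b[None, :] + gm) ** 2))
    resid = (
        y
        - m_sa[:, :, None]
        - m_sb[:, None, :]
        - m_ab[None, :, :]
        + m_s[:, None, None]
        + m_a[None, :, None]
        + m_b[None, None, :]
        - gm
    )
    ss_abs = float(np.sum(resid ** 2))

    c_a = _helmert_contrasts(a)
    c_b = _helmert_contrasts(b)
    effects = {
        factor_names[0]: (ss_a, ss_as, a - 1, (a - 1) * (n - 1), m_sa, c_a),
        factor_names[1]: (ss_b, ss_bs, b - 1, (b - 1) * (n - 1), m_sb, c_b),
        f"{factor_names[0]}*{factor_names[1]}": (
            ss_ab,
            ss_abs,
            (a - 1) * (b - 1),
            (a - 1) * (b - 1) * (n - 1),
            y.reshape(n, a * b),
            np.kron(c_a, c_b),
        ),
    }

    out: dict[str, TestResult] = {}
    for name, (ss_eff, ss_err, df1, df2, scores, contrasts) in effects.items():
        if ss_eff == 0.0:
            # an exactly null effect is reported as F = 0 even when its error
            # term also vanishes (e.g. duplicated factor levels)
            f, np2 = 0.0, 0.0
        elif ss_err <= 0:
            raise DegenerateSampleError(f"zero error variance for effect {name!r}")
        else:
            f = (ss_eff / df1) / (ss_err / df2)
            np2 = ss_eff / (ss_eff + ss_err)
        eps = _gg_epsilon(scores, contrasts)
        out[name] = TestResult(
            statistic=float(f),
            df=(float(df1), float(df2)),
            p_value=float(stats.f.sf(f, df1, df2)),
            effect_size=np2,
            epsilon=eps,
            p_gg=float(stats.f.sf(f, df1 * eps, df2 * eps)),
        )
    return out
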