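"""Discrete entropies, mutual information, and prediction-error bounds.

For a label X and an observation Y with joint distribution P(X, Y), any
predictor of X from Y has error at least the (weakened) Fano bound

    Pe >= (H(X|Y) - 1) / log |chi|,

while the maximum-likelihood (MAP) predictor has error at most the
Hellman-Raviv bound Pe <= H(X|Y) / 2.  Along a Markov chain
X -> Y -> Y', the data processing inequality I(X;Y) >= I(X;Y') says
deterministic or stochastic post-processing of Y cannot add information
about X — the theoretical reason a reconstructed spectrum cannot beat
the raw signal it was computed from.

All quantities are plug-in Shannon measures in bits by default; a
single ``base`` parameter keeps the entropy and the log|chi| in the
Fano denominator in the same base.  Estimators here are for discrete
(or discretized) variables only.
"""

from __future__ import annotations

import dataclasses
from typing import NamedTuple

import numpy as np
from scipy.special import xlogy

__all__ = [
    "EntropyTerms",
    "BoundsReport",
    "DPIAudit",
    "entropy_terms",
    "fano_lower",
    "hellman_raviv_upper",
    "bayes_error",
    "bounds_report",
    "dpi_audit",
    "joint_from_counts",
]


def _validate_joint(joint) -> np.ndarray:
    P = np.asarray(joint, dtype=float)
    if P.ndim != 2 or P.size == 0:
        raise ValueError("joint must be a non-empty 2-D table")
    if np.any(P < 0) or not np.all(np.isfinite(P)):
        raise ValueError("joint probabilities must be finite and >= 0")
    total = P.sum()
    if total == 0:
        raise ValueError("joint table is all zero")
    if abs(total - 1.0) > 1e-12:
        raise ValueError("joint probabilities must sum to 1 within 1e-12")
    return P


def joint_from_counts(counts) -> np.ndarray:
    """Empirical joint from a non-negative integer co-occurrence table."""
    C = np.asarray(counts, dtype=float)
    if np.any(C < 0) or np.any(C != np.round(C)):
        raise ValueError("counts must be non-negative integers")
    if C.sum() == 0:
        raise ValueError("counts table is all zero")
    return C / C.sum()


class EntropyTerms(NamedTuple):
    h_x: float
    h_x_given_y: float
    mutual_information: float


def entropy_terms(joint, base: float = 2.0) -> EntropyTerms:
    """Plug-in H(X), H(X|Y) and I(X;Y) from an exact joint table.

    Rows index X, columns index Y; 0 log 0 := 0.  I = H(X) - H(X|Y) is
    clipped of negative rounding noise.
    """
    P = _validate_joint(joint)
    if base <= 1:
        raise ValueError("log base must be > 1")
    log_b = np.log(base)
    px = P.sum(axis=1)
    py = P.sum(axis=0)
    h_x = float(-xlogy(px, px).sum() / log_b)
    h_y = float(-xlogy(py, py).sum() / log_b)
    h_xy = float(-xlogy(P, P).sum() / log_b)
    h_x_given_y = max(h_xy - h_y, 0.0)
    mi = max(h_x - h_x_given_y, 0.0)
    return EntropyTerms(h_x, h_x_given_y, mi)


def fano_lower(h_x_given_y: float, support_size: int, base: float = 2.0) -> float:
    """Weakened Fano lower bound (H(X|Y) - 1) / log|chi| on prediction
    error.  May be negative (vacuous); callers clamp at 0 for display.
    The log uses the same base as the entropy."""
    if support_size < 2:
        raise ValueError("support size must be >= 2")
    if h_x_given_y < 0:
        raise ValueError("conditional entropy must be >= 0")
    return (h_x_given_y - 1.0) / (np.log(support_size) / np.log(base))


def hellman_raviv_upper(h_x_given_y: float) -> float:
    """Hellman-Raviv upper bound H(X|Y)/2 on the ML predictor's error."""
    if h_x_given_y < 0:
        raise ValueError("conditional entropy must be >= 0")
    return 0.5 * h_x_given_y


def bayes_error(joint) -> float:
    """Exact MAP error 1 - sum_y max_x P(x, y) for a known joint.

    For empirical data use a holdout error estimate instead; this
    routine requires the exact table."""
    P = _validate_joint(joint)
    return float(1.0 - P.max(axis=0).sum())


@dataclasses.dataclass(frozen=True)
class BoundsReport:
    """Entropies, information and the error-bound sandwich for one joint."""

    h_x: float
    h_x_given_y: float
    mutual_information: float
    fano_lower: float
    fano_lower_clamped: float
    hellman_raviv_upper: float
    bayes_error: float


def bounds_report(joint, base: float = 2.0) -> BoundsReport:
    """Assemble the full sandwich fano <= Pe(MAP) <= Hellman-Raviv for
    an exact joint table."""
    terms = entropy_terms(joint, base=base)
    support = np.asarray(joint).shape[0]
    lo = fano_lower(terms.h_x_given_y, support, base=base)
    return BoundsReport(
        h_x=terms.h_x,
        h_x_given_y=terms.h_x_given_y,
        mutual_information=terms.mutual_information,
        fano_lower=lo,
        fano_lower_clamped=max(lo, 0.0),
        hellman_raviv_upper=hellman_raviv_upper(terms.h_x_given_y),
        bayes_error=bayes_error(joint),
    )


class DPIAudit(NamedTuple):
    i_xy: float
    i_xyprime: float
    margin: float


def _validate_stochastic(mat, n_rows: int, name: str) -> np.ndarray:
    M = np.asarray(mat, dtype=float)
    if M.ndim != 2 or M.shape[0] != n_rows:
        raise ValueError(f"{name} must be 2-D with {n_rows} rows")
    if np.any(M < 0):
        raise ValueError(f"{name} must be non-negative")
    if np.any(np.abs(M.sum(axis=1) - 1.0) > 1e-10):
        raise ValueError(f"{name} rows must sum to 1")
    return M


def dpi_audit(p_x, channel_xy, channel_yyprime, base: float = 2.0) -> DPIAudit:
    """Exact I(X;Y), I(X;Y') and margin for a chain X -> Y -> Y'.

    ``p_x`` is the prior; the channels are row-stochastic matrices.
    The margin I(X;Y) - I(X;Y') is mathematically >= 0; a violation
    beyond -1e-10 (impossible up to rounding) raises."""
    px = np.asarray(p_x, dtype=float).ravel()
    if np.any(px < 0) or abs(px.sum() - 1.0) > 1e-10:
        raise ValueError("p_x must be a probability vector")
    ch_xy = _validate_stochastic(channel_xy, px.size, "channel X->Y")
    ch_yyp = _validate_stochastic(channel_yyprime, ch_xy.shape[1], "channel Y->Y'")
    joint_xy = px[:, None] * ch_xy
    joint_xyp = px[:, None] * (ch_xy @ ch_yyp)
    i_xy = entropy_terms(joint_xy, base=base).mutual_information
    i_xyp = entropy_terms(joint_xyp, base=base).mutual_information
    margin = i_xy - i_xyp
    if margin < -1e-10:
        raise RuntimeError(
            f"data processing inequality violated: margin={margin:.3e}"
        )
    return DPIAudit(i_xy, i_xyp, margin)
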