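"""Information-theoretic primitives.

Entropy H(X) = -sum_c p_c log2 p_c over the distinct non-missing values;
information content IC(X) = -sum_i log2 p(x_i) over the non-missing elements
(equal to n*H for discrete data); mutual information content
MIC(X, Y) = MI(X, Y) * n_complete; symmetric uncertainty
SU(X, Y) = 2 (H(X) + H(Y) - H(X,Y)) / (H(X) + H(Y)).

All measures use base-2 logarithms (bits) and are complete-case: the missing
marker never forms a probability mass.  Continuous variables get an adaptive
(Abramson-style) Gaussian kernel density estimate for IC and equal-frequency
discretisation for mutual information; both are declared estimator choices.
"""

from __future__ import annotations

import math
from collections import Counter

import numpy as np
import pandas as pd

from .core import MISSING, as_number, is_missing

__all__ = [
    "entropy",
    "information_content_discrete",
    "information_content_continuous",
    "mutual_information",
    "mutual_information_content",
    "symmetric_uncertainty",
    "joint_entropy",
    "min_max_normalise",
]

#: Densities are floored at this value before taking logs.
DENSITY_FLOOR = 1e-12


def _nonmissing(x) -> list:
    return [v for v in x if not is_missing(v)]


def _complete_pairs(x, y) -> list[tuple]:
    x = list(x)
    y = list(y)
    if len(x) != len(y):
        raise ValueError(f"length mismatch: {len(x)} vs {len(y)}")
    return [(a, b) for a, b in zip(x, y)
            if not is_missing(a) and not is_missing(b)]


def entropy(x) -> float:
    """Shannon entropy in bits of the non-missing values of *x*.

    Empty or all-missing input has entropy 0; the result is 0 iff at most one
    distinct non-missing value is present.
    """
    values = _nonmissing(x)
    n = len(values)
    if n == 0:
        return 0.0
    counts = Counter(values)
    return -sum((c / n) * math.log2(c / n) for c in counts.values())


def information_content_discrete(x) -> float:
    """Discrete information content in bits: -sum_i log2 p(x_i).

    The sum runs over non-missing *elements* (not distinct values), so the
    identity IC(X) = n * H(X) holds exactly.
    """
    values = _nonmissing(x)
    n = len(values)
    if n == 0:
        return 0.0
    counts = Counter(values)
    return -sum(c * math.log2(c / n) for c in counts.values())


def _adaptive_kde_density(values: np.ndarray, alpha: float = 0.5) -> np.ndarray:
    """Leave-none-out adaptive Gaussian KDE evaluated at the sample points.

    A Silverman-rule pilot estimate seeds Abramson local bandwidths
    lambda_j = (p_pilot(x_j) / g)^(-alpha) with g the geometric mean pilot
    density.
    """
    n = values.size
    sd = values.std(ddof=1)
    iqr = np.subtract(*np.percentile(values, [75, 25]))
    spread = min(sd, iqr / 1.349) if iqr > 0 else sd
    if spread <= 0:
        raise ValueError("degenerate (constant) sample: density undefined")
    h = 0.9 * spread * n ** (-1 / 5)  # Silverman's rule of thumb

    diffs = values[:, None] - values[None, :]
    pilot = np.exp(-0.5 * (diffs / h) ** 2).sum(axis=1) / (n * h * math.sqrt(2 * math.pi))
    pilot = np.maximum(pilot, DENSITY_FLOOR)
    g = np.exp(np.mean(np.log(pilot)))
    lam = (pilot / g) ** (-alpha)

    hj = h * lam  # per-point bandwidths, attached to the kernel centres
    dens = (np.exp(-0.5 * (diffs / hj[None, :]) ** 2) / hj[None, :]).sum(axis=1)
    dens /= n * math.sqrt(2 * math.pi)
    return np.maximum(dens, DENSITY_FLOOR)


def information_content_continuous(x, bandwidth_mode: str = "adaptive") -> float:
    """Continuous information content in bits via kernel density estimation.

    The density at each observation comes from a Gaussian KDE with adaptive
    per-point (Abramson) bandwidths seeded by a Silverman pilot
    (``bandwidth_mode="adaptive"``) or from the fixed Silverman pilot itself
    (``"silverman"``); the result is -sum_i log2 p_hat(x_i).  Requires at
    least 5 non-missing numeric values and a non-degenerate spread.
    """
    if bandwidth_mode not in ("adaptive", "silverman"):
        raise ValueError(f"unknown bandwidth_mode {bandwidth_mode!r}")
    numbers = [as_number(v) for v in x if not is_missing(v)]
    if any(v is None for v in numbers):
        raise ValueError("continuous IC requires numeric values")
    values = np.asarray(numbers, dtype=float)
    if values.size < 5:
        raise ValueError(
            f"continuous IC needs >=5 non-missing values, got {values.size}; "
            "use information_content_discrete for small categorical vectors"
        )
    if np.ptp(values) == 0:
        raise ValueError("degenerate (constant) sample: density undefined")
    if bandwidth_mode == "adaptive":
        dens = _adaptive_kde_density(values)
    else:
        dens = _adaptive_kde_density(values, alpha=0.0)
    return float(-np.log2(dens).sum())


def _looks_continuous(values: list, max_bins: int) -> bool:
    """A side counts as continuous when it is all-numeric with more distinct
    values than the bin budget; discrete numeric codes pass through."""
    numbers = [as_number(v) for v in values]
    if any(v is None for v in numbers):
        return False
    return len(set(numbers)) > max_bins


def _discretise_pairs(pairs: list[tuple], max_bins: int = 10) -> list[tuple]:
    """Equal-frequency binning of any continuous-looking side of the pairs."""
    n = len(pairs)
    n_bins = min(max_bins, max(2, int(math.isqrt(n))))
    xs = [a for a, _ in pairs]
    ys = [b for _, b in pairs]

    def maybe_bin(side: list) -> list:
        if not _looks_continuous(side, max_bins):
            return side
        codes = pd.qcut(
            np.asarray([as_number(v) for v in side], dtype=float),
            q=n_bins, labels=False, duplicates="drop",
        )
        return [int(c) for c in codes]

    return list(zip(maybe_bin(xs), maybe_bin(ys)))


def mutual_information(x, y, max_bins: int = 10) -> float:
    """Plug-in mutual information in bits, on complete cases.

    Discrete inputs use the joint contingency table directly; a
    continuous-looking input (all-numeric with more distinct values than
    bins) is first discretised into equal-frequency bins
    (min(*max_bins*, sqrt(n))).
    """
    pairs = _complete_pairs(x, y)
    n = len(pairs)
    if n == 0:
        raise ValueError("no complete cases shared by x and y")
    pairs = _discretise_pairs(pairs, max_bins=max_bins)
    joint = Counter(pairs)
    mx = Counter(a for a, _ in pairs)
    my = Counter(b for _, b in pairs)
    mi = 0.0
    for (a, b), c in joint.items():
        p_ab = c / n
        mi += p_ab * math.log2(p_ab / ((mx[a] / n) * (my[b] / n)))
    return max(mi, 0.0)


def mutual_information_content(x, y, max_bins: int = 10) -> float:
    """MIC(X, Y) = MI(X, Y) * number of complete cases, in bits."""
    n = len(_complete_pairs(x, y))
    if n == 0:
        raise ValueError("no complete cases shared by x and y")
    return mutual_information(x, y, max_bins=max_bins) * n


def joint_entropy(x, y) -> float:
    """Entropy in bits of the paired value vector, on complete cases."""
    return entropy(_complete_pairs(x, y))


def symmetric_uncertainty(x, y, max_bins: int = 10) -> float:
    """Symmetric uncertainty in [0, 1] on complete cases.

    SU = 2 (H(X) + H(Y) - H(X,Y)) / (H(X) + H(Y)); returns 0 when both
    marginal entropies are zero (declared convention: a constant shares no
    information).
    """
    pairs = _complete_pairs(x, y)
    if not pairs:
        return 0.0
    pairs = _discretise_pairs(pairs, max_bins=max_bins)
    hx = entropy([a for a, _ in pairs])
    hy = entropy([b for _, b in pairs])
    denom = hx + hy
    if denom == 0:
        return 0.0
    hxy = entropy(pairs)
    su = 2 * (hx + hy - hxy) / denom
    return min(max(su, 0.0), 1.0)


def min_max_normalise(x, name: str = "variable"):
    """Min-max normalisation to [0, 1]; missing values preserved in place.

    Raises on a constant vector (max == min), naming the variable so the
    caller may choose to skip normalisation.
    """
    values = list(x)
    numbers = [as_number(v) for v in values]
    for v, n in zip(values, numbers):
        if not is_missing(v) and n is None:
            raise ValueError(f"{name}: non-numeric value {v!r} cannot be normalised")
    present = [n for n in numbers if n is not None]
    if not present:
        return [MISSING for _ in values]
    lo, hi = min(present), max(present)
    if hi == lo:
        raise ValueError(f"{name}: constant variable (min == max), cannot normalise")
    return [MISSING if n is None else (n - lo) / (hi - lo) for n in numbers]
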