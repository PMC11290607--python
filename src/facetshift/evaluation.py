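"""Presence-background model evaluation: AUC, continuous Boyce index,
and the max(sensitivity + specificity) binarisation threshold."""

from __future__ import annotations

import numpy as np
from scipy.stats import rankdata, spearmanr

__all__ = ["auc", "boyce_index", "select_threshold"]


def auc(scores, labels) -> float:
    """Rank-based AUC: probability that a random presence outscores a random
    background point, ties counting one half.

    Parameters
    ----------
    scores : array-like
        Predicted suitabilities.
    labels : array-like of {0, 1}
        1 = presence, 0 = background.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(bool)
    n1 = int(labels.sum())
    n0 = labels.size - n1
    if n1 == 0 or n0 == 0:
        raise ValueError("AUC undefined: both classes must be present")
    ranks = rankdata(scores)  # average ranks handle ties as 1/2
    u = ranks[labels].sum() - n1 * (n1 + 1) / 2.0
    return float(u / (n1 * n0))


def boyce_index(
    presence_suit,
    background_suit,
    n_windows: int = 101,
    window_width: float | None = None,
    window_fraction: float | None = None,
) -> float:
    """Continuous Boyce index.

    Moving windows slide across the pooled suitability range (default 101
    window centres, width one fiftieth of the range).  Per window, P is the
    fraction of presence suitabilities inside and E the fraction of background
    suitabilities inside; windows with E = 0 are dropped.  The index is the
    Spearman rank correlation between P/E and the window centre: +1 means the
    predicted-to-expected ratio rises monotonically with suitability, values
    near 0 mean no better than random, negative values mean predictions
    contradict the data.

    The default window width is deliberately narrow (range/50 rather than the
    also-common range/10): wide windows overlap so heavily that neighbouring
    P/E values are strongly correlated, which inflates the rank correlation's
    null variance and makes near-random models score far from 0.  Both the
    width and the number of centres are configurable: ``window_width`` is an
    absolute width, ``window_fraction`` a fraction of the pooled range (the
    classic smoothing is ``window_fraction=0.1``).
    """
    pres = np.asarray(presence_suit, dtype=float)
    bg = np.asarray(background_suit, dtype=float)
    if pres.size == 0 or bg.size == 0:
        raise ValueError("boyce_index needs non-empty presence and background vectors")
    lo = min(pres.min(), bg.min())
    hi = max(pres.max(), bg.max())
    rng = hi - lo
    if rng == 0:
        raise ValueError("boyce_index undefined: all suitabilities identical")
    if window_width is not None:
        width = window_width
    elif window_fraction is not None:
        width = rng * window_fraction
    else:
        width = rng / 50.0
    centers = np.linspace(lo + width / 2.0, hi - width / 2.0, n_windows)

    lo_edges = centers - width / 2.0
    hi_edges = centers + width / 2.0
    # fraction inside each closed window
    p = ((pres[None, :] >= lo_edges[:, None]) & (pres[None, :] <= hi_edges[:, None])).mean(axis=1)
    e = ((bg[None, :] >= lo_edges[:, None]) & (bg[None, :] <= hi_edges[:, None])).mean(axis=1)

    use = e > 0
    if use.sum() < 3:
        raise ValueError("boyce_index undefined: fewer than 3 windows contain background points")
    f = p[use] / e[use]
    if np.ptp(f) == 0:
        return 0.0  # flat P/E profile carries no rank information
    rho = spearmanr(f, centers[use]).statistic
    return float(rho)


def select_threshold(presence_scores, background_scores) -> float:
    """Threshold maximising sensitivity + specificity.

    Candidates are the observed scores themselves (exact optimum).  A cell is
    classified suitable when its score is >= the threshold, so
    ``sensitivity(t) = P(presence >= t)`` and
    ``specificity(t) = P(background < t)``.  Ties in the objective are broken
    by the smallest such threshold.
    """
    pres = np.sort(np.asarray(presence_scores, dtype=float))
    bg = np.sort(np.asarray(background_scores, dtype=float))
    if pres.size == 0 or bg.size == 0:
        raise ValueError("select_threshold needs both presence and background scores")
    cand = np.unique(np.concatenate([pres, bg]))
    # exact integer arithmetic so ties are true rational ties:
    # sens + spec = (n_p - a)/n_p + b/n_b, compared via cross-multiplication
    a = np.searchsorted(pres, cand, side="left")  # presences below threshold
    b = np.searchsorted(bg, cand, side="left")    # background below threshold
    score = (pres.size - a) * bg.size + b * pres.size
    best = np.argmax(score)  # argmax returns the first (= smallest) maximiser
    return float(cand[best])
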