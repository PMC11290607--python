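"""Bioclimatic predictors and collinearity filtering.

Derives the subset of the classical bioclim variables the analysis needs from
monthly minimum/maximum temperature and precipitation, plus Emberger's
pluviometric quotient (an aridity index), and reduces a predictor stack to a
non-collinear set via correlation clustering followed by iterative VIF
pruning.

Conventions
-----------
* "Quarters" are the 12 wrap-around 3-month windows, indexed by their *centre*
  month; ties between equally wet/warm quarters go to the lowest centre month.
* Emberger temperatures are taken in kelvin (the envirem convention):
  ``Q = 2000 P / ((Tmax + Tmin)(Tmax - Tmin))``.
* bio15 uses the ``1 + bio12/12`` denominator so arid cells stay defined.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .grids import PredictorStack, RasterGrid

logger = logging.getLogger(__name__)

__all__ = ["bioclim", "emberger_q", "filter_collinear", "CollinearityReport", "vif"]

_K0 = 273.15  # degC -> K


def _check_monthly(arr: np.ndarray, what: str) -> np.ndarray:
    arr = np.asarray(arr, dtype=float)
    if arr.ndim != 3 or arr.shape[0] != 12:
        raise ValueError(f"{what} must have shape (12, rows, cols); got {arr.shape}")
    return arr


def bioclim(tmin: np.ndarray, tmax: np.ndarray, prec: np.ndarray) -> dict[str, np.ndarray]:
    """Bioclim variables from monthly climate.

    Parameters
    ----------
    tmin, tmax : ndarray (12, rows, cols)
        Monthly minimum / maximum temperature, degC.
    prec : ndarray (12, rows, cols)
        Monthly precipitation, mm.

    Returns
    -------
    dict of 2-D arrays with keys
    ``bio1`` (annual mean temperature), ``bio4`` (temperature seasonality,
    100*sd of monthly means), ``bio5`` (max monthly tmax), ``bio6`` (min
    monthly tmin), ``bio7`` (annual range, bio5-bio6), ``bio8`` (mean
    temperature of the wettest quarter), ``bio10`` (mean temperature of the
    warmest quarter), ``bio12`` (annual precipitation) and ``bio15``
    (precipitation seasonality, CV).
    """
    tmin = _check_monthly(tmin, "tmin")
    tmax = _check_monthly(tmax, "tmax")
    prec = _check_monthly(prec, "prec")
    if tmin.shape != tmax.shape or tmin.shape != prec.shape:
        raise ValueError("monthly inputs must share shape")
    if np.any(tmax < tmin):
        raise ValueError("tmax < tmin somewhere: inputs are inconsistent")

    tavg = (tmin + tmax) / 2.0

    # quarter windows centred on each month m: (m-1, m, m+1), wrap-around
    q_prec = np.empty_like(prec)
    q_tavg = np.empty_like(tavg)
    for m in range(12):
        idx = [(m - 1) % 12, m, (m + 1) % 12]
        q_prec[m] = prec[idx].sum(axis=0)
        q_tavg[m] = tavg[idx].mean(axis=0)

    wettest = np.argmax(q_prec, axis=0)  # first max -> lowest centre month
    warmest = np.argmax(q_tavg, axis=0)
    rows, cols = np.indices(wettest.shape)

    out: dict[str, np.ndarray] = {}
    out["bio1"] = tavg.mean(axis=0)
    out["bio4"] = tavg.std(axis=0, ddof=1) * 100.0
    out["bio5"] = tmax.max(axis=0)
    out["bio6"] = tmin.min(axis=0)
    out["bio7"] = out["bio5"] - out["bio6"]
    out["bio8"] = q_tavg[wettest, rows, cols]
    out["bio10"] = q_tavg[warmest, rows, cols]
    out["bio12"] = prec.sum(axis=0)
    out["bio15"] = 100.0 * prec.std(axis=0, ddof=1) / (1.0 + out["bio12"] / 12.0)
    return out


def emberger_q(bio5: RasterGrid, bio6: RasterGrid, bio12: RasterGrid) -> RasterGrid:
    """Emberger's pluviometric quotient.

    ``Q = 2000 P / ((Tmax + Tmin)(Tmax - Tmin))`` with P the annual
    precipitation (mm) and Tmax/Tmin the extreme monthly temperatures in
    kelvin.  Cells with ``Tmax == Tmin`` (zero denominator) are masked.
    """
    for layer in (bio6, bio12):
        if not layer.same_grid(bio5):
            raise ValueError("emberger_q inputs are not aligned")
    tmax_k = bio5.values + _K0
    tmin_k = bio6.values + _K0
    denom = (tmax_k + tmin_k) * (tmax_k - tmin_k)
    bad = denom == 0
    with np.errstate(divide="ignore", invalid="ignore"):
        q = 2000.0 * bio12.values / denom
    q[bad] = np.nan
    if bad.any():
        logger.warning("emberger_q: %d cells with Tmax == Tmin masked", int(bad.sum()))
    return bio5.like(q, name="embergerQ", mask=bad if bad.any() else None)


def vif(sample: np.ndarray) -> np.ndarray:
    """Variance inflation factors of the columns of ``sample``.

    VIF_j = 1 / (1 - R^2_j) of each column regressed (with intercept) on the
    others; computed as the diagonal of the inverse correlation matrix.
    """
    x = np.asarray(sample, dtype=float)
    r = np.corrcoef(x, rowvar=False)
    r = np.atleast_2d(r)
    return np.diag(np.linalg.pinv(r))


@dataclass
class CollinearityReport:
    """Decision log of :func:`filter_collinear`."""

    kept: list[str] = field(default_factory=list)
    dropped: list[tuple[str, str]] = field(default_factory=list)  # (name, reason)
    clusters: list[list[str]] = field(default_factory=list)
    final_vif: dict[str, float] = field(default_factory=dict)

    def drop(self, name: str, reason: str) -> None:
        self.dropped.append((name, reason))


def filter_collinear(
    stack: PredictorStack,
    sample,
    r_max: float = 0.5,
    vif_max: float = 3.0,
    keep: list[str] | None = None,
) -> tuple[PredictorStack, CollinearityReport]:
    """Reduce a predictor stack to a non-collinear subset.

    Step 1: hierarchical clustering (average linkage) of variables on the
    distance ``1 - |Pearson r|``, cut at height ``1 - r_max``; one variable
    kept per cluster — by default the member with the lowest mean |r| against
    all other variables, overridable by naming it in ``keep``.  A post-hoc
    pass enforces the pairwise guarantee: if two retained representatives
    still correlate at |r| >= r_max (possible under average linkage), the one
    with the higher mean |r| is dropped.

    Step 2: iteratively drop the variable with the highest variance inflation
    factor until all VIF <= ``vif_max``.  Variables named in ``keep`` are
    never dropped.

    Parameters
    ----------
    sample : DataFrame
        Cell sample of the stack's layers (columns = layer names), e.g. from
        :meth:`PredictorStack.sample_frame`; no missing values.

    Returns
    -------
    (filtered stack, CollinearityReport)
    """
    from scipy.cluster.hierarchy import fcluster, linkage
    from scipy.spatial.distance import squareform

    keep = list(keep or [])
    names = [n for n in stack.names if n in sample.columns]
    if len(names) < 2:
        raise ValueError("need at least two layers to filter")
    report = CollinearityReport()

    x = sample[names].to_numpy(dtype=float)
    if np.isnan(x).any():
        raise ValueError("sample matrix contains missing values")

    # constant layers have undefined correlation
    keep_cols = []
    for j, name in enumerate(names):
        if np.ptp(x[:, j]) == 0:
            report.drop(name, "constant layer (undefined correlation)")
            logger.warning("filter_collinear: dropping constant layer %r", name)
        else:
            keep_cols.append(j)
    names = [names[j] for j in keep_cols]
    x = x[:, keep_cols]

    r = np.corrcoef(x, rowvar=False)
    abs_r = np.abs(r)
    mean_abs_r = (abs_r.sum(axis=0) - 1.0) / max(len(names) - 1, 1)

    dist = 1.0 - abs_r
    np.fill_diagonal(dist, 0.0)
    dist = (dist + dist.T) / 2.0  # symmetrise away float noise
    z = linkage(squareform(dist, checks=False), method="average")
    labels = fcluster(z, t=1.0 - r_max, criterion="distance")

    chosen: list[str] = []
    for lab in np.unique(labels):
        members = [names[i] for i in range(len(names)) if labels[i] == lab]
        report.clusters.append(members)
        forced = [m for m in members if m in keep]
        reps = forced or [min(members, key=lambda m: mean_abs_r[names.index(m)])]
        chosen.extend(reps)
        for m in members:
            if m not in reps:
                report.drop(m, f"clustered with {reps[0]} at |r| >= {r_max}")

    # post-hoc pairwise guarantee
    changed = True
    while changed and len(chosen) > 1:
        changed = False
        idx = [names.index(n) for n in chosen]
        sub = abs_r[np.ix_(idx, idx)]
        np.fill_diagonal(sub, 0.0)
        i, j = np.unravel_index(np.argmax(sub), sub.shape)
        if sub[i, j] >= r_max:
            a, b = chosen[i], chosen[j]
            if a in keep and b in keep:
                break  # user forced both; honour the override
            if b in keep or (a not in keep and mean_abs_r[names.index(a)] >= mean_abs_r[names.index(b)]):
                victim = a
            else:
                victim = b
            chosen.remove(victim)
            report.drop(victim, f"post-hoc pairwise |r| >= {r_max}")
            changed = True

    # step 2: VIF pruning
    while len(chosen) > 1:
        v = vif(sample[chosen].to_numpy(dtype=float))
        order = np.argsort(v)[::-1]
        victim_idx = None
        for k in order:
            if v[k] <= vif_max:
                break
            if chosen[k] not in keep:
                victim_idx = k
                break
        if victim_idx is None:
            break
        victim = chosen[victim_idx]
        report.drop(victim, f"VIF {v[victim_idx]:.2f} > {vif_max}")
        chosen.remove(victim)

    report.kept = list(chosen)
    if len(chosen) > 1:
        report.final_vif = dict(zip(chosen, vif(sample[chosen].to_numpy(dtype=float))))
    else:
        report.final_vif = {chosen[0]: 1.0}
    return stack.subset(chosen), report
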