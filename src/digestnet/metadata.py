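"""Physicochemical metadata preparation.

Aligns parameter series to biological sampling dates by natural cubic
spline interpolation, correlates individual ASV traces with parameters,
and searches for the environmental-variable subset whose distance
structure best matches community structure (the classic "bioenv"
maximum-rank-correlation procedure).
"""

from __future__ import annotations

import datetime as _dt
import itertools
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.interpolate import CubicSpline
from scipy.spatial.distance import pdist
from scipy.stats import pearsonr, spearmanr

from .community import DistanceMatrix
from .datatypes import ParameterSeries, ValidationError

__all__ = [
    "InterpolatedSeries",
    "BioenvResult",
    "interpolate_parameters",
    "asv_parameter_correlation",
    "bioenv_best_subset",
]

MEASURED = "measured"
INTERPOLATED = "interpolated"


@dataclass
class InterpolatedSeries:
    """Parameter values at query dates, with provenance flags.

    ``values``: query-date-by-parameter frame; ``flags`` marks each entry
    as measured (copied verbatim from the raw series) or interpolated;
    ``suspect`` lists (date, parameter) pairs where an interpolated value
    strays beyond 1.5x the measured range — the automated stand-in for
    eyeballing the interpolation.
    """

    values: pd.DataFrame
    flags: pd.DataFrame
    suspect: list

    def to_frame(self) -> pd.DataFrame:
        """Long-format export with a flag column."""
        rows = []
        for date in self.values.index:
            for param in self.values.columns:
                rows.append(
                    {"date": date.isoformat(), "parameter": param,
                     "value": self.values.loc[date, param],
                     "flag": self.flags.loc[date, param]}
                )
        return pd.DataFrame(rows)


@dataclass
class BioenvResult:
    best_subset: tuple[str, ...]
    rho: float
    ranking: pd.DataFrame  # all evaluated subsets, sorted by rho desc
    degenerate: bool = False  # community distances constant; rho undefined


def _as_dates(dates) -> list[_dt.date]:
    out = []
    for d in dates:
        if isinstance(d, _dt.datetime):
            out.append(d.date())
        elif isinstance(d, _dt.date):
            out.append(d)
        else:
            out.append(_dt.date.fromisoformat(str(d)))
    return out


def interpolate_parameters(series: ParameterSeries, query_dates) -> InterpolatedSeries:
    """Natural cubic spline through each parameter's measurements.

    Measured query dates return the raw measurement bit-exactly (flag
    ``measured``); other query dates are spline-interpolated.  Queries
    outside the measured range are refused (no extrapolation); each
    parameter needs at least two measurements.
    """
    query = _as_dates(query_dates)
    qx = np.array([d.toordinal() for d in query], dtype=float)
    values = pd.DataFrame(index=pd.Index(query), columns=series.parameters, dtype=float)
    flags = pd.DataFrame(index=pd.Index(query), columns=series.parameters, dtype=object)
    suspect: list[tuple[_dt.date, str]] = []
    for param in series.parameters:
        measured = series.measured(param)
        if len(measured) < 2:
            raise ValidationError(
                f"parameter {param!r}: need >= 2 measurements to interpolate"
            )
        mx = np.array([d.toordinal() for d in measured.index], dtype=float)
        my = measured.to_numpy()
        if qx.min() < mx.min() or qx.max() > mx.max():
            bad = [q for q, x in zip(query, qx) if x < mx.min() or x > mx.max()]
            raise ValidationError(
                f"parameter {param!r}: query dates {bad} outside measured range "
                "(extrapolation refused)"
            )
        if len(mx) == 2:
            # two points define a line; a cubic spline degenerates to it
            interp = my[0] + (my[1] - my[0]) * (qx - mx[0]) / (mx[1] - mx[0])
        else:
            interp = CubicSpline(mx, my, bc_type="natural")(qx)
        measured_map = {d: v for d, v in measured.items()}
        lo, hi = my.min(), my.max()
        span = hi - lo
        for i, date in enumerate(query):
            if date in measured_map:
                values.loc[date, param] = measured_map[date]
                flags.loc[date, param] = MEASURED
            else:
                v = float(interp[i])
                values.loc[date, param] = v
                flags.loc[date, param] = INTERPOLATED
                # flag values outside the measured range widened to 1.5x its span
                if span > 0 and (v > hi + 0.25 * span or v < lo - 0.25 * span):
                    suspect.append((date, param))
    return InterpolatedSeries(values, flags, suspect)


def asv_parameter_correlation(
    rel_abundance: pd.DataFrame,
    params: InterpolatedSeries,
    method: str = "pearson",
) -> pd.DataFrame:
    """Correlate each ASV trace with each interpolated parameter.

    ``rel_abundance``: ASV-by-sample matrix whose columns align, in order,
    with the rows (query dates) of ``params``.  Constant vectors yield NaN
    (flagged missing).
    """
    if method not in ("pearson", "spearman"):
        raise ValueError(f"unknown method {method!r}")
    if rel_abundance.shape[1] != len(params.values.index):
        raise ValidationError(
            "sample axis does not align with interpolated query dates"
        )
    if rel_abundance.shape[1] == 0:
        raise ValidationError("no overlapping dates")
    corr = pd.DataFrame(index=rel_abundance.index, columns=params.values.columns,
                        dtype=float)
    func = pearsonr if method == "pearson" else spearmanr
    for param in params.values.columns:
        y = params.values[param].to_numpy(dtype=float)
        if np.ptp(y) == 0:
            corr[param] = np.nan
            continue
        for asv in rel_abundance.index:
            x = rel_abundance.loc[asv].to_numpy(dtype=float)
            if np.ptp(x) == 0:
                corr.loc[asv, param] = np.nan
            else:
                corr.loc[asv, param] = func(x, y)[0]
    return corr


def _spearman_condensed(a: np.ndarray, b: np.ndarray) -> float:
    rho = spearmanr(a, b)[0]
    return float(rho)


def bioenv_best_subset(
    community_dist: DistanceMatrix,
    params: pd.DataFrame,
    max_size: int | None = None,
) -> BioenvResult:
    """Exhaustive environmental-subset search (bioenv / BEST).

    Parameters are z-standardized; for every non-empty subset up to
    ``max_size``, Euclidean distances among the standardized parameter
    vectors are rank-correlated (Spearman) with the community distances
    over corresponding off-diagonal entries.  Returns the argmax subset and
    the full ranking.  Constant community distances make rho undefined;
    the result is flagged degenerate with rho 0 for every subset.
    """
    names = list(params.columns)
    if max_size is None:
        max_size = len(names)
    if max_size > len(names):
        raise ValidationError("max_size exceeds the number of parameters")
    n_subsets = sum(math.comb(len(names), k) for k in range(1, max_size + 1))
    if n_subsets > 2**20:
        raise ValidationError(
            f"{n_subsets} subsets exceed the 2^20 guard; lower max_size"
        )
    if list(params.index) != list(community_dist.ids):
        params = params.loc[community_dist.ids]
    z = (params - params.mean()) / params.std(ddof=1)
    comm = community_dist.condensed()
    degenerate = np.ptp(comm) == 0
    rows = []
    for k in range(1, max_size + 1):
        for subset in itertools.combinations(names, k):
            env = pdist(z[list(subset)].to_numpy(), metric="euclidean")
            rho = 0.0 if degenerate else _spearman_condensed(comm, env)
            if np.isnan(rho):
                rho = 0.0
            rows.append({"subset": subset, "size": k, "rho": rho})
    ranking = pd.DataFrame(rows).sort_values(
        ["rho", "size"], ascending=[False, True], kind="mergesort"
    ).reset_index(drop=True)
    best = ranking.iloc[0]
    return BioenvResult(tuple(best["subset"]), float(best["rho"]), ranking,
                        degenerate=bool(degenerate))
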