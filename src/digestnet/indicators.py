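"""Indicator species analysis (group-equalized IndVal with permutation test).

For ASV *i* and configuration *k* the group-equalized indicator value is

    A_ik = mean abundance of i in k / sum over groups j of mean abundance in j
    B_ik = fraction of group-k samples where i is present
    IndVal_ik = sqrt(A_ik * B_ik)

A (specificity) asks "when I see this ASV, am I in configuration k?" after
equalizing group sizes; B (fidelity) asks "when I am in k, do I see it?".
Significance of each ASV's best group is assessed by permuting the
sample-to-configuration labels.  Abundances are taken as relative
abundances so the statistic is insensitive to sequencing depth.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .community import relative_abundance
from .datatypes import AbundanceTable, ValidationError
from .network import bh_adjust

__all__ = ["IndicatorResult", "indval", "indicator_test"]


@dataclass
class IndicatorResult:
    asv_id: str
    group: str
    a: float
    b: float
    stat: float
    p: float
    q: float
    n_perm: int
    seed: int

    @property
    def significant(self) -> bool:
        return bool(self.q < 0.05)


def _group_matrix(labels: np.ndarray, groups: np.ndarray) -> np.ndarray:
    """Samples-by-groups 0/1 membership matrix."""
    return (labels[:, None] == groups[None, :]).astype(float)


def _indval_components(rel: np.ndarray, member: np.ndarray):
    """A, B, and stat matrices (ASV x group) from relative abundances.

    ``rel``: ASV x sample; ``member``: sample x group membership.
    """
    n_per_group = member.sum(axis=0)
    group_mean = (rel @ member) / n_per_group  # asv x group
    total = group_mean.sum(axis=1, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        a = np.where(total > 0, group_mean / np.where(total > 0, total, 1.0), np.nan)
    b = ((rel > 0).astype(float) @ member) / n_per_group
    return a, b, np.sqrt(a * b)


def indval(table: AbundanceTable, groups=None) -> pd.DataFrame:
    """Group-equalized IndVal components for every ASV and group.

    Returns a tidy DataFrame with one row per (asv, group): columns
    ``A``, ``B``, ``stat``, and ``best`` (True on the ASV's argmax group).
    ASVs absent from every sample are excluded (flagged in ``attrs``).
    """
    labels = np.asarray(
        list(table.configuration) if groups is None
        else ([groups[s] for s in table.sample_ids]
              if isinstance(groups, (dict, pd.Series)) else list(groups))
    )
    uniq = np.unique(labels)
    if len(uniq) < 2:
        raise ValidationError("IndVal needs at least two groups")
    rel = relative_abundance(table.counts).to_numpy()
    member = _group_matrix(labels, uniq)
    a, b, stat = _indval_components(rel, member)
    absent = np.isnan(stat).all(axis=1)
    rows = []
    for i, asv in enumerate(table.asv_ids):
        if absent[i]:
            continue
        best = int(np.nanargmax(stat[i]))
        for g, grp in enumerate(uniq):
            rows.append(
                {"asv_id": asv, "group": grp, "A": a[i, g], "B": b[i, g],
                 "stat": stat[i, g], "best": g == best}
            )
    out = pd.DataFrame(rows)
    out.attrs["excluded_absent"] = [
        asv for i, asv in enumerate(table.asv_ids) if absent[i]
    ]
    return out


def indicator_test(
    table: AbundanceTable,
    groups=None,
    n_perm: int = 999,
    seed: int = 0,
    alpha: float = 0.05,
) -> list[IndicatorResult]:
    """Permutation test of each ASV's best-group IndVal.

    The null distribution permutes sample-to-group labels (group sizes
    preserved); ``p = (1 + #{permuted max-stat >= observed}) / (1 + n_perm)``
    per ASV, BH-adjusted across ASVs.  Results are sorted by q then asv_id;
    the significant set is ``q < alpha`` (see ``IndicatorResult``).
    """
    if n_perm < 99:
        raise ValidationError("use at least 99 permutations")
    labels = np.asarray(
        list(table.configuration) if groups is None
        else ([groups[s] for s in table.sample_ids]
              if isinstance(groups, (dict, pd.Series)) else list(groups))
    )
    uniq = np.unique(labels)
    if len(uniq) < 2:
        raise ValidationError("need at least two groups")
    rel = relative_abundance(table.counts).to_numpy()
    member = _group_matrix(labels, uniq)
    a, b, stat = _indval_components(rel, member)
    keep = ~np.isnan(stat).all(axis=1)
    stat_obs = np.nanmax(np.where(np.isnan(stat), -np.inf, stat), axis=1)

    rng = np.random.default_rng(seed)
    exceed = np.zeros(len(stat_obs))
    for _ in range(n_perm):
        perm = rng.permutation(labels)
        _, _, s = _indval_components(rel, _group_matrix(perm, uniq))
        s_max = np.nanmax(np.where(np.isnan(s), -np.inf, s), axis=1)
        exceed += s_max >= stat_obs
    p = (1 + exceed) / (1 + n_perm)

    idx = np.where(keep)[0]
    q = bh_adjust(p[idx])
    results = []
    for rank, i in enumerate(idx):
        g = int(np.nanargmax(stat[i]))
        results.append(
            IndicatorResult(
                asv_id=table.asv_ids[i], group=str(uniq[g]),
                a=float(a[i, g]), b=float(b[i, g]), stat=float(stat[i, g]),
                p=float(p[i]), q=float(q[rank]), n_perm=n_perm, seed=seed,
            )
        )
    results.sort(key=lambda r: (r.q, r.asv_id))
    return results
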