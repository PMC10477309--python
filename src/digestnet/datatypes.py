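"""Shared data containers for the digester time-series analysis.

The backbone of the pipeline is an ASV-by-sample count table with dated,
configuration-labelled samples, a table of physicochemical parameter series
measured on (possibly different) dates, and a collection of genome bins
(MAGs) carrying taxonomy, quality metrics, 16S sequences, and gene
annotations.  Networks are plain :class:`networkx.Graph` objects with a
documented attribute schema (see :data:`NODE_ATTRS` / :data:`EDGE_ATTRS`).
"""

from __future__ import annotations

import datetime as _dt
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "RANKS",
    "GUILDS",
    "NODE_ATTRS",
    "EDGE_ATTRS",
    "ValidationError",
    "AbundanceTable",
    "TaxonomyTable",
    "ParameterSeries",
    "Gene",
    "MagRecord",
    "ExpressionTable",
    "validate_network",
]

#: taxonomic ranks, shallowest to deepest
RANKS = ("domain", "phylum", "class", "order", "family", "genus", "species")

#: functional guild labels carried on network nodes
GUILDS = (
    "hydrogenotrophic_methanogen",
    "acetoclastic_methanogen",
    "syntroph",
    "other",
)

#: node attributes of a co-occurrence network
NODE_ATTRS = ("mean_rel_abundance", "guild", "indicator", "mag_id", "expression")
#: edge attributes of a co-occurrence network
EDGE_ATTRS = ("weight", "qvalue")


class ValidationError(ValueError):
    """Raised when an input violates a container invariant."""


def _parse_date(value) -> _dt.date:
    if isinstance(value, _dt.datetime):
        return value.date()
    if isinstance(value, _dt.date):
        return value
    return _dt.date.fromisoformat(str(value))


@dataclass
class AbundanceTable:
    """ASV-by-sample count matrix with per-sample date and configuration.

    Parameters
    ----------
    counts
        Non-negative integer DataFrame, rows indexed by ASV id, columns by
        sample id.
    sample_dates
        Mapping sample id -> :class:`datetime.date` (ISO strings accepted).
    configuration
        Mapping sample id -> process-configuration label (e.g. SOI, CEPT,
        SOII, SER).
    """

    counts: pd.DataFrame
    sample_dates: pd.Series
    configuration: pd.Series

    def __post_init__(self):
        self.counts = self.counts.copy()
        self.sample_dates = pd.Series(
            {s: _parse_date(d) for s, d in pd.Series(self.sample_dates).items()}
        )
        self.configuration = pd.Series(self.configuration).astype(str)
        self.validate()

    # -- invariants ------------------------------------------------------
    def validate(self) -> None:
        if self.counts.index.duplicated().any():
            dupes = self.counts.index[self.counts.index.duplicated()].tolist()
            raise ValidationError(f"duplicate ASV ids: {dupes}")
        if self.counts.columns.duplicated().any():
            dupes = self.counts.columns[self.counts.columns.duplicated()].tolist()
            raise ValidationError(f"duplicate sample ids: {dupes}")
        values = self.counts.to_numpy()
        if not np.issubdtype(values.dtype, np.number):
            raise ValidationError("counts must be numeric")
        if (values < 0).any():
            i, j = np.argwhere(values < 0)[0]
            raise ValidationError(
                f"negative count at ASV {self.counts.index[i]!r}, "
                f"sample {self.counts.columns[j]!r}"
            )
        if np.any(values != np.round(values)):
            i, j = np.argwhere(values != np.round(values))[0]
            raise ValidationError(
                f"non-integer count at ASV {self.counts.index[i]!r}, "
                f"sample {self.counts.columns[j]!r}"
            )
        for name, series in (
            ("date", self.sample_dates),
            ("configuration", self.configuration),
        ):
            missing = [s for s in self.counts.columns if s not in series.index]
            if missing:
                raise ValidationError(f"samples missing a {name}: {missing}")
        self.sample_dates = self.sample_dates.loc[self.counts.columns]
        self.configuration = self.configuration.loc[self.counts.columns]

    # -- convenience -----------------------------------------------------
    @property
    def asv_ids(self) -> list[str]:
        return list(self.counts.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.counts.columns)

    @property
    def n_samples(self) -> int:
        return self.counts.shape[1]

    def days_since_start(self) -> pd.Series:
        """Sample dates as integer days since the earliest sample."""
        start = min(self.sample_dates)
        return pd.Series(
            [(d - start).days for d in self.sample_dates],
            index=self.sample_dates.index,
            dtype=int,
        )

    def subset_asvs(self, asv_ids) -> "AbundanceTable":
        return AbundanceTable(
            self.counts.loc[list(asv_ids)], self.sample_dates, self.configuration
        )

    def __eq__(self, other) -> bool:
        if not isinstance(other, AbundanceTable):
            return NotImplemented
        return (
            self.counts.equals(other.counts)
            and self.sample_dates.equals(other.sample_dates)
            and self.configuration.equals(other.configuration)
        )


class TaxonomyTable:
    """Ranked lineages for ASV or MAG ids.

    Stored as a DataFrame with columns :data:`RANKS`; missing ranks are
    ``None`` and must form a suffix (once a rank is unannotated, all deeper
    ranks are unannotated too).
    """

    def __init__(self, frame: pd.DataFrame):
        frame = frame.reindex(columns=list(RANKS)).astype(object)
        frame = frame.where(pd.notna(frame) & (frame != ""), None)
        for rid, row in frame.iterrows():
            vals = [row[r] for r in RANKS]
            seen_missing = False
            for rank, v in zip(RANKS, vals):
                if v is None:
                    seen_missing = True
                elif seen_missing:
                    raise ValidationError(
                        f"{rid!r}: rank {rank!r} annotated below a missing rank"
                    )
        if frame.index.duplicated().any():
            raise ValidationError("duplicate ids in taxonomy table")
        self.frame = frame

    def lineage(self, record_id: str) -> list[str]:
        """Annotated ranks of ``record_id``, shallowest first, no gaps."""
        row = self.frame.loc[record_id]
        return [row[r] for r in RANKS if row[r] is not None]

    def rank(self, record_id: str, rank: str):
        return self.frame.loc[record_id, rank]

    @property
    def ids(self) -> list[str]:
        return list(self.frame.index)

    def __len__(self) -> int:
        return len(self.frame)


class ParameterSeries:
    """Dated physicochemical measurements (parameters in columns).

    Missing entries are NaN; dates (the index) must be strictly increasing.
    """

    def __init__(self, values: pd.DataFrame):
        values = values.copy()
        values.index = [_parse_date(d) for d in values.index]
        diffs = np.diff([d.toordinal() for d in values.index])
        if len(diffs) and (diffs <= 0).any():
            raise ValidationError("measurement dates must be strictly increasing")
        self.values = values.astype(float)

    @property
    def parameters(self) -> list[str]:
        return list(self.values.columns)

    @property
    def dates(self) -> list[_dt.date]:
        return list(self.values.index)

    def measured(self, parameter: str) -> pd.Series:
        """Non-missing measurements of one parameter."""
        return self.values[parameter].dropna()


@dataclass(frozen=True)
class Gene:
    gene_id: str
    length: int  # bp
    labels: tuple[str, ...] = ()  # gene symbols / ortholog ids

    def __post_init__(self):
        if self.length <= 0:
            raise ValidationError(f"gene {self.gene_id!r}: length must be > 0")


@dataclass
class MagRecord:
    """One metagenome-assembled genome bin."""

    mag_id: str
    taxonomy: list[str] = field(default_factory=list)  # annotated ranks, no gaps
    completeness: float = 0.0  # percent
    contamination: float = 0.0  # percent
    rrna_counts: dict = field(default_factory=dict)  # {"5S": n, "16S": n, "23S": n}
    ssu_sequences: list[str] = field(default_factory=list)
    genes: list[Gene] = field(default_factory=list)

    def __post_init__(self):
        if not 0.0 <= self.completeness <= 100.0:
            raise ValidationError(
                f"MAG {self.mag_id!r}: completeness outside [0, 100]"
            )
        if self.contamination < 0.0:
            raise ValidationError(f"MAG {self.mag_id!r}: negative contamination")
        self.rrna_counts = {k: int(v) for k, v in self.rrna_counts.items()}

    @property
    def quality_tier(self) -> str:
        from .linking import mag_quality_tier

        return mag_quality_tier(self.completeness, self.contamination, self.rrna_counts)


class ExpressionTable:
    """Per-gene read counts with lengths, MAG assignment, and TPM.

    ``gene_info`` is a DataFrame indexed by gene id with columns ``mag_id``
    (the string ``"unbinned"`` for unassigned genes) and ``length``;
    ``counts`` is gene-by-sample.  TPM is computed on construction and sums
    to 1e6 per sample whenever the sample has any mapped read.
    """

    UNBINNED = "unbinned"

    def __init__(self, gene_info: pd.DataFrame, counts: pd.DataFrame):
        if not gene_info.index.equals(counts.index):
            gene_info = gene_info.loc[counts.index]
        if (gene_info["length"] <= 0).any():
            raise ValidationError("gene lengths must be > 0")
        if (counts.to_numpy() < 0).any():
            raise ValidationError("negative read count")
        self.gene_info = gene_info
        self.counts = counts.astype(float)
        from .linking import tpm

        self.tpm = pd.DataFrame(
            {s: tpm(self.counts[s].to_numpy(), gene_info["length"].to_numpy())
             for s in counts.columns},
            index=counts.index,
        )

    @property
    def gene_ids(self) -> list[str]:
        return list(self.counts.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.counts.columns)


def validate_network(net) -> None:
    """Check co-occurrence network invariants.

    No self-edges; stored edges carry a positive ``weight`` and a ``qvalue``.
    """
    for u, v, data in net.edges(data=True):
        if u == v:
            raise ValidationError(f"self-edge at node {u!r}")
        if "weight" not in data:
            raise ValidationError(f"edge ({u!r}, {v!r}) lacks a weight")
        if data["weight"] <= 0:
            raise ValidationError(
                f"edge ({u!r}, {v!r}) has non-positive weight {data['weight']}"
            )
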