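"""Link genome bins (MAGs) to ASV network nodes and overlay expression.

A MAG is paired with an ASV when the V4 region of one of its 16S rRNA
genes — located between the 515F/806R primer sites — matches the ASV
sequence at >99.5% identity end-to-end (0-1 mismatches over a ~273 bp
fragment) and the two taxonomies agree at their shared deepest annotated
rank (lowest-common-ancestor concordance).  Expression is carried as TPM
per gene, aggregated per MAG, and compared between matched metagenome and
metatranscriptome libraries.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .datatypes import ExpressionTable, MagRecord, ValidationError

__all__ = [
    "FWD_PRIMER",
    "REV_PRIMER",
    "AsvMagPair",
    "PathwayMarkerReport",
    "MARKER_SETS",
    "GUILD_TABLE",
    "extract_v4",
    "pair_asv_mag",
    "lca_concordant",
    "mag_quality_tier",
    "tpm",
    "aggregate_mag_expression",
    "mg_mt_correlation",
    "pathway_markers",
    "assign_guilds",
]

#: Earth Microbiome Project V4 primers (515F / 806R)
FWD_PRIMER = "GTGYCAGCMGCCGCGGTAA"
REV_PRIMER = "GGACTACNVGGGTWTCTAAT"

IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT",
}
_COMPLEMENT = str.maketrans("ACGTRYSWKMBDHVN", "TGCAYRSWMKVHDBN")


def reverse_complement(seq: str) -> str:
    return seq.upper().translate(_COMPLEMENT)[::-1]


def _iupac_regex(primer: str) -> re.Pattern:
    return re.compile("".join(
        c if len(IUPAC[c]) == 1 else f"[{IUPAC[c]}]" for c in primer.upper()
    ))


class PrimerNotFoundError(ValidationError):
    pass


def extract_v4(seq: str, fwd: str = FWD_PRIMER, rev: str = REV_PRIMER) -> str:
    """Cut the V4 region out of a 16S sequence.

    Matches the forward primer (IUPAC-degenerate, no mismatches) and the
    reverse complement of the reverse primer downstream of it; returns the
    sequence between the forward primer's 3' end and the reverse site.
    With multiple hits the leftmost forward match and the nearest
    downstream reverse site are used (a warning is emitted).
    """
    seq = seq.upper()
    if len(seq) < len(fwd) + len(rev):
        raise PrimerNotFoundError("sequence shorter than the two primers")
    fwd_re = _iupac_regex(fwd)
    rev_re = _iupac_regex(reverse_complement(rev))
    fwd_hits = list(fwd_re.finditer(seq))
    if not fwd_hits:
        raise PrimerNotFoundError("forward primer site not found")
    start = fwd_hits[0].end()
    rev_hits = list(rev_re.finditer(seq, start))
    if not rev_hits:
        raise PrimerNotFoundError("reverse primer site not found downstream")
    if len(fwd_hits) > 1 or len(rev_hits) > 1:
        warnings.warn(
            "multiple primer sites; using leftmost forward and nearest "
            "downstream reverse", stacklevel=2,
        )
    return seq[start:rev_hits[0].start()]


@dataclass
class AsvMagPair:
    asv_id: str
    mag_id: str
    identity: float
    mismatches: int
    alignment_length: int
    lca_concordant: bool | None = None  # None when no taxonomy was supplied
    accepted: bool = False


def _best_ungapped(query: str, region: str) -> tuple[int, int] | None:
    """Minimum-mismatch ungapped placement of ``query`` within ``region``.

    Returns (mismatches, offset) or None when the region is shorter than
    the query.  The leftmost placement wins ties, which makes the result
    independent of input file order.
    """
    lq, lr = len(query), len(region)
    if lr < lq:
        return None
    q = np.frombuffer(query.encode(), dtype=np.uint8)
    r = np.frombuffer(region.encode(), dtype=np.uint8)
    best = None
    for off in range(lr - lq + 1):
        mm = int((q != r[off:off + lq]).sum())
        if best is None or mm < best[0]:
            best = (mm, off)
            if mm == 0:
                break
    return best


def pair_asv_mag(
    asv_seqs: dict[str, str],
    mags: list[MagRecord],
    min_identity: float = 0.995,
    asv_taxonomy: dict[str, list[str]] | None = None,
) -> list[AsvMagPair]:
    """Pair each ASV with its best-matching MAG 16S V4 region.

    Identity is ``1 - mismatches / query length`` over an end-to-end
    ungapped placement of the ASV in the MAG's extracted V4 region (full
    16S used as a fallback when primers are absent).  A pair is accepted
    when identity exceeds ``min_identity``, the best MAG is unique under
    the tie-break (higher identity, then quality score
    ``completeness - 5*contamination``, then mag_id), and — if taxonomy is
    supplied — the lineages are LCA-concordant.
    """
    results: list[AsvMagPair] = []
    mag_regions: list[tuple[MagRecord, str]] = []
    for mag in mags:
        for ssu in mag.ssu_sequences:
            try:
                region = extract_v4(ssu)
            except PrimerNotFoundError:
                region = ssu.upper()  # full-16S fallback
            mag_regions.append((mag, region))

    for asv_id, asv_seq in asv_seqs.items():
        asv_seq = asv_seq.upper()
        candidates = []
        for mag, region in mag_regions:
            hit = _best_ungapped(asv_seq, region)
            if hit is None:
                continue
            mm, _ = hit
            identity = 1.0 - mm / len(asv_seq)
            quality = mag.completeness - 5.0 * mag.contamination
            candidates.append((identity, quality, mag.mag_id, mm, mag))
        if not candidates:
            continue
        candidates.sort(key=lambda c: (-c[0], -c[1], c[2]))
        identity, _, _, mm, mag = candidates[0]
        pair = AsvMagPair(
            asv_id=asv_id, mag_id=mag.mag_id, identity=identity,
            mismatches=mm, alignment_length=len(asv_seq),
        )
        pair.accepted = identity > min_identity
        if asv_taxonomy is not None:
            pair.lca_concordant = lca_concordant(
                asv_taxonomy.get(asv_id, []), mag.taxonomy
            )
            pair.accepted = pair.accepted and bool(pair.lca_concordant)
        results.append(pair)
    return results


_RANK_PREFIX = re.compile(r"^[a-z]__")


def _norm_rank(name: str) -> str:
    return _RANK_PREFIX.sub("", str(name)).strip().lower()


def lca_concordant(lineage_a: list[str], lineage_b: list[str]) -> bool:
    """Do two lineages agree down to their shared deepest annotated rank?

    Both lineages are truncated to the shallower annotation depth and
    compared rank by rank after stripping ``x__`` prefixes and case.
    """
    a = [_norm_rank(r) for r in lineage_a if r]
    b = [_norm_rank(r) for r in lineage_b if r]
    if not a or not b:
        return False
    depth = min(len(a), len(b))
    return a[:depth] == b[:depth]


def mag_quality_tier(completeness: float, contamination: float, rrna_counts) -> str:
    """MIMAG-style tiering.

    HQ: >90% complete, <5% contamination, >=1 each of 5S/16S/23S.
    MQ: >50% complete, <10% contamination, >=1 of any rRNA subunit.
    Otherwise fail.
    """
    counts = dict(rrna_counts or {})
    all_three = all(counts.get(k, 0) >= 1 for k in ("5S", "16S", "23S"))
    any_one = any(v >= 1 for v in counts.values())
    if completeness > 90 and contamination < 5 and all_three:
        return "HQ"
    if completeness > 50 and contamination < 10 and any_one:
        return "MQ"
    return "fail"


def tpm(counts, lengths) -> np.ndarray:
    """Transcripts per million: ``(c/l) / sum(c/l) * 1e6``.

    All-zero counts return all-zero TPM (flagged by the caller's sum
    check rather than raising).
    """
    c = np.asarray(counts, dtype=float)
    l = np.asarray(lengths, dtype=float)
    if (l <= 0).any():
        raise ValidationError("gene lengths must be > 0")
    if (c < 0).any():
        raise ValidationError("read counts must be >= 0")
    rate = c / l
    total = rate.sum()
    if total == 0:
        return np.zeros_like(rate)
    return rate / total * 1e6


def aggregate_mag_expression(expr: ExpressionTable, mags: list[MagRecord]) -> pd.DataFrame:
    """Sum gene TPM per MAG; rows are mag_ids, plus attrs recording the
    unbinned TPM fraction per sample."""
    known = {m.mag_id for m in mags}
    assigned = expr.gene_info["mag_id"]
    unknown = set(assigned.unique()) - known - {ExpressionTable.UNBINNED}
    if unknown:
        raise ValidationError(f"genes mapped to unknown MAGs: {sorted(unknown)}")
    out = pd.DataFrame(0.0, index=sorted(known), columns=expr.sample_ids)
    grouped = expr.tpm.groupby(assigned).sum()
    for mag_id in grouped.index:
        if mag_id in known:
            out.loc[mag_id] = grouped.loc[mag_id]
    unbinned = (
        grouped.loc[ExpressionTable.UNBINNED] / 1e6
        if ExpressionTable.UNBINNED in grouped.index
        else pd.Series(0.0, index=expr.sample_ids)
    )
    out.attrs["unbinned_fraction"] = unbinned
    return out


def mg_mt_correlation(
    mg_tpm: pd.DataFrame,
    mt_tpm: pd.DataFrame,
    exclude: set[str] | None = None,
    method: str = "spearman",
):
    """Correlate MAG abundance between metagenome and metatranscriptome.

    Observations are all (MAG, sample) cells shared by the two matrices,
    optionally excluding a guild (by mag_id set — typically the
    methanogens, whose transcription decouples from genome abundance).
    Returns a CorrelationResult with rho, t, and df = n - 2.
    """
    from .network import CorrelationResult

    keep = [m for m in mg_tpm.index if m in set(mt_tpm.index)
            and (exclude is None or m not in exclude)]
    samples = [s for s in mg_tpm.columns if s in set(mt_tpm.columns)]
    x = mg_tpm.loc[keep, samples].to_numpy().ravel()
    y = mt_tpm.loc[keep, samples].to_numpy().ravel()
    if len(x) < 3:
        raise ValidationError("need at least 3 paired observations")
    if method == "spearman":
        r = stats.spearmanr(x, y)[0]
    elif method == "pearson":
        r = stats.pearsonr(x, y)[0]
    else:
        raise ValueError(f"unknown method {method!r}")
    from .network import correlation_test

    result = correlation_test(float(r), len(x))
    return result


# -- guilds and pathway markers -----------------------------------------

#: taxonomy name -> functional guild; editable/overridable at call sites
GUILD_TABLE = {
    "methanoregulaceae": "hydrogenotrophic_methanogen",
    "methanospirillaceae": "hydrogenotrophic_methanogen",
    "methanomicrobiaceae": "hydrogenotrophic_methanogen",
    "methanobacteriaceae": "hydrogenotrophic_methanogen",
    "methanolinea": "hydrogenotrophic_methanogen",
    "methanobacterium": "hydrogenotrophic_methanogen",
    "methanoculleus": "hydrogenotrophic_methanogen",
    "methanospirillum": "hydrogenotrophic_methanogen",
    "methanosaetaceae": "acetoclastic_methanogen",
    "methanothrix": "acetoclastic_methanogen",
    "methanosaeta": "acetoclastic_methanogen",
    "syntrophaceae": "syntroph",
    "syntrophorhabdus": "syntroph",
    "syntrophorhabdaceae": "syntroph",
    "syntrophomonas": "syntroph",
    "syntrophomonadaceae": "syntroph",
    "smithella": "syntroph",
    "synergistaceae": "syntroph",
}


def assign_guilds(taxonomy, guild_table: dict[str, str] | None = None) -> dict[str, str]:
    """Map each id to a guild by scanning its lineage against the table.

    ``taxonomy``: TaxonomyTable or {id: lineage list}.  Deeper ranks take
    precedence; ids with no hit get ``other``.
    """
    table = guild_table or GUILD_TABLE
    if hasattr(taxonomy, "lineage"):
        lineages = {i: taxonomy.lineage(i) for i in taxonomy.ids}
    else:
        lineages = taxonomy
    out = {}
    for rid, lineage in lineages.items():
        guild = "other"
        for name in lineage:  # shallow -> deep; deepest hit wins
            hit = table.get(_norm_rank(name))
            if hit:
                guild = hit
        out[rid] = guild
    return out


#: marker gene sets for methanogenesis and candidate syntrophy routes
MARKER_SETS = {
    "hydrogenotrophic_methanogenesis": (
        "mcrA", "mcrB", "mcrC", "mcrD", "mcrG",
        "mtrA", "mtrB", "mtrC", "mtrD", "mtrE", "mtrF", "mtrH",
    ),
    "acetoclastic_methanogenesis": ("ack", "pta"),
    "wood_ljungdahl_methyl_branch": ("fdh", "fhs", "fol", "met"),
    "glycine_cleavage_system": ("gcvH", "gcvP", "gcvT"),
}


@dataclass
class PathwayMarkerReport:
    mag_id: str
    marker_set: str
    encoded: dict[str, bool]
    expressed: dict[str, bool]

    @property
    def fully_encoded(self) -> bool:
        return all(self.encoded.values())

    @property
    def fully_expressed(self) -> bool:
        return all(self.expressed.values())


def pathway_markers(
    mag: MagRecord,
    expr: ExpressionTable | None,
    marker_sets: dict[str, tuple[str, ...]] | None = None,
) -> list[PathwayMarkerReport]:
    """Presence and expression of marker genes in one MAG.

    A marker is encoded when any of the MAG's genes carries a matching
    label (case-insensitive); it is expressed when encoded and the summed
    TPM of those genes is > 0 in any sample.
    """
    sets = MARKER_SETS if marker_sets is None else marker_sets
    if not sets:
        raise ValidationError("empty marker set")
    label_to_genes: dict[str, list[str]] = {}
    for gene in mag.genes:
        for label in gene.labels:
            label_to_genes.setdefault(label.lower(), []).append(gene.gene_id)
    reports = []
    for set_name, markers in sets.items():
        encoded, expressed = {}, {}
        for marker in markers:
            genes = label_to_genes.get(marker.lower(), [])
            encoded[marker] = bool(genes)
            if genes and expr is not None:
                present = [g for g in genes if g in expr.tpm.index]
                expressed[marker] = bool(present) and bool(
                    (expr.tpm.loc[present].to_numpy() > 0).any()
                )
            else:
                expressed[marker] = False
        reports.append(PathwayMarkerReport(mag.mag_id, set_name, encoded, expressed))
    return reports
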