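"""Genome linking: V4 primer extraction with IUPAC degeneracy, ASV-MAG
pairing at the 99.5 % identity rule, LCA taxonomy concordance, MIMAG-style
quality tiers, TPM, MAG expression aggregation, and pathway markers."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

from digestnet.datatypes import ExpressionTable, Gene, MagRecord, ValidationError
from digestnet.linking import (
    FWD_PRIMER,
    REV_PRIMER,
    MARKER_SETS,
    PrimerNotFoundError,
    aggregate_mag_expression,
    assign_guilds,
    extract_v4,
    lca_concordant,
    mag_quality_tier,
    mg_mt_correlation,
    pair_asv_mag,
    pathway_markers,
    reverse_complement,
    tpm,
)

FWD_SITE = "GTGTCAGCAGCCGCGGTAA"   # concrete realization of 515F
REV_SITE = "GGACTACAAGGGTATCTAAT"  # concrete realization of 806R


def _sixteen_s(v4: str, left="ACGT" * 10, right="TGCA" * 10) -> str:
    return left + FWD_SITE + v4 + reverse_complement(REV_SITE) + right


class TestExtractV4:
    def test_recovers_inserted_region(self):
        v4 = "ATGCATGCAT" * 5
        assert extract_v4(_sixteen_s(v4)) == v4

    def test_iupac_degeneracy_accepts_y_as_ct_only(self):
        v4 = "AAAACCCCGGGGTTTT"
        # 4th base of 515F is Y = {C, T}
        for base, ok in [("C", True), ("T", True), ("G", False), ("A", False)]:
            site = FWD_SITE[:3] + base + FWD_SITE[4:]
            seq = "AC" * 8 + site + v4 + reverse_complement(REV_SITE) + "GT" * 8
            if ok:
                assert extract_v4(seq) == v4
            else:
                with pytest.raises(PrimerNotFoundError):
                    extract_v4(seq)

    def test_missing_primer_raises(self):
        with pytest.raises(PrimerNotFoundError):
            extract_v4("ACGT" * 50)

    def test_multiple_hits_use_leftmost_with_warning(self):
        v4a, v4b = "A" * 30, "C" * 30
        seq = _sixteen_s(v4a) + _sixteen_s(v4b)
        with pytest.warns(UserWarning, match="multiple primer"):
            assert extract_v4(seq) == v4a


class TestPairAsvMag:
    def _mag(self, mag_id, v4, completeness=95.0, contamination=1.0,
             taxonomy=()):
        return MagRecord(
            mag_id=mag_id, taxonomy=list(taxonomy),
            completeness=completeness, contamination=contamination,
            rrna_counts={"5S": 1, "16S": 1, "23S": 1},
            ssu_sequences=[_sixteen_s(v4)],
            genes=[Gene(f"{mag_id}_g0", 900)],
        )

    def _asv(self, rng, length=273):
        return "".join("ACGT"[i] for i in rng.integers(0, 4, length))

    def test_identity_rule_0_1_2_mismatches_over_273(self, rng):
        asv = self._asv(rng)
        def mutate(seq, k):
            out = list(seq)
            for pos in range(k):
                out[pos * 3] = {"A": "C", "C": "G", "G": "T", "T": "A"}[out[pos * 3]]
            return "".join(out)

        mags = [self._mag("M0", asv), self._mag("M1", mutate(asv, 1)),
                self._mag("M2", mutate(asv, 2))]
        for mag, expected_identity, accepted in [
            (mags[0], 1.0, True),
            (mags[1], 272 / 273, True),    # 0.99634 > 0.995
            (mags[2], 271 / 273, False),   # 0.99267 < 0.995
        ]:
            pairs = pair_asv_mag({"asv": asv}, [mag])
            assert pairs[0].identity == pytest.approx(expected_identity)
            assert pairs[0].accepted is accepted

    def test_best_mag_wins_and_order_invariance(self, rng):
        asv = self._asv(rng)
        one_mm = list(asv)
        one_mm[5] = {"A": "C", "C": "G", "G": "T", "T": "A"}[one_mm[5]]
        mags = [self._mag("M_worse", "".join(one_mm)), self._mag("M_exact", asv)]
        for ordering in (mags, mags[::-1]):
            pairs = pair_asv_mag({"asv": asv}, ordering)
            assert pairs[0].mag_id == "M_exact"
            assert pairs[0].mismatches == 0

    def test_exact_tie_broken_by_quality_then_id(self, rng):
        asv = self._asv(rng)
        low = self._mag("A_mag", asv, completeness=60.0, contamination=5.0)
        high = self._mag("B_mag", asv, completeness=99.0, contamination=0.0)
        for ordering in ([low, high], [high, low]):
            pairs = pair_asv_mag({"asv": asv}, ordering)
            assert pairs[0].mag_id == "B_mag"  # higher completeness-5*contam

    def test_taxonomy_gate(self, rng):
        asv = self._asv(rng)
        mag = self._mag("M0", asv, taxonomy=["Bacteria", "Firmicutes"])
        pairs = pair_asv_mag(
            {"asv": asv}, [mag],
            asv_taxonomy={"asv": ["Bacteria", "Proteobacteria"]},
        )
        assert pairs[0].lca_concordant is False
        assert not pairs[0].accepted

    def test_asv_longer_than_region_rejected(self, rng):
        asv = self._asv(rng, length=273)
        mag = self._mag("M0", "A" * 50)  # short V4 region
        assert pair_asv_mag({"asv": asv}, [mag]) == []


class TestLcaConcordant:
    def test_order_vs_family_worked_example(self):
        asv = ["Bacteria", "Proteobacteria", "Deltaproteobacteria", "o__X"]
        mag = ["Bacteria", "Proteobacteria", "Deltaproteobacteria", "o__X",
               "f__Y"]
        assert lca_concordant(asv, mag)

    def test_phylum_mismatch(self):
        assert not lca_concordant(
            ["Bacteria", "Firmicutes"], ["Bacteria", "Bacteroidota"]
        )

    def test_domain_only_equal(self):
        assert lca_concordant(["Archaea"], ["Archaea"])

    def test_prefix_and_case_normalized(self):
        assert lca_concordant(["d__Bacteria", "p__Firmicutes"],
                              ["bacteria", "FIRMICUTES", "Clostridia"])

    def test_empty_lineage_not_concordant(self):
        assert not lca_concordant([], ["Bacteria"])


class TestMagQualityTier:
    FULL = {"5S": 1, "16S": 1, "23S": 1}

    @pytest.mark.parametrize(
        "completeness,contamination,rrna,tier",
        [
            (99.0, 0.0, FULL, "HQ"),
            (93.3, 1.4, FULL, "HQ"),
            (78.3, 0.4, {"16S": 1}, "MQ"),
            (95.0, 6.0, FULL, "MQ"),       # fails HQ on contamination
            (95.0, 1.0, {"16S": 1}, "MQ"),  # fails HQ on rRNA operon
            (40.0, 1.0, FULL, "fail"),
            (60.0, 1.0, {}, "fail"),
        ],
    )
    def test_tiers(self, completeness, contamination, rrna, tier):
        assert mag_quality_tier(completeness, contamination, rrna) == tier

    @given(
        c1=st.floats(0, 100), c2=st.floats(0, 100),
        contam=st.floats(0, 20),
    )
    def test_monotone_in_completeness(self, c1, c2, contam):
        lo, hi = sorted((c1, c2))
        order = {"fail": 0, "MQ": 1, "HQ": 2}
        assert order[mag_quality_tier(hi, contam, self.FULL)] >= order[
            mag_quality_tier(lo, contam, self.FULL)
        ]


class TestTpm:
    def test_equal_counts_equal_lengths(self):
        np.testing.assert_allclose(tpm([10, 10], [500, 500]),
                                   [500_000.0, 500_000.0])

    def test_length_normalization_hand_case(self):
        out = tpm([10, 10], [100, 200])
        np.testing.assert_allclose(out, [2e6 / 3, 1e6 / 3], rtol=1e-9)

    def test_sums_to_one_million(self, rng):
        out = tpm(rng.poisson(20.0, 50), rng.integers(100, 5000, 50))
        assert out.sum() == pytest.approx(1e6, abs=1e-3)

    def test_all_zero_counts_give_zero(self):
        np.testing.assert_array_equal(tpm([0, 0], [100, 200]), [0.0, 0.0])

    def test_depth_invariance(self, rng):
        c = rng.poisson(20.0, 30).astype(float)
        l = rng.integers(100, 5000, 30)
        np.testing.assert_allclose(tpm(c, l), tpm(c * 3, l))


class TestAggregateAndCorrelate:
    def _expr(self, gene_mags, counts):
        info = pd.DataFrame(
            {"mag_id": gene_mags, "length": [1000] * len(gene_mags)},
            index=[f"g{i}" for i in range(len(gene_mags))],
        )
        frame = pd.DataFrame(
            counts, index=info.index,
            columns=[f"s{j}" for j in range(np.shape(counts)[1])],
        )
        return ExpressionTable(info, frame)

    def _mag(self, mag_id):
        return MagRecord(mag_id=mag_id, completeness=90, contamination=1,
                         rrna_counts={"16S": 1}, genes=[Gene(f"{mag_id}_g", 500)])

    def test_single_mag_sums(self):
        expr = self._expr(["M0", "M0"], [[10, 0], [30, 5]])
        out = aggregate_mag_expression(expr, [self._mag("M0")])
        np.testing.assert_allclose(out.loc["M0"], expr.tpm.sum(axis=0))

    def test_two_mags_split_and_empty_mag_zero(self):
        expr = self._expr(["M0", "M1", "M1"], [[10, 10], [10, 0], [20, 10]])
        out = aggregate_mag_expression(
            expr, [self._mag("M0"), self._mag("M1"), self._mag("M2")]
        )
        np.testing.assert_allclose(
            out.loc["M1"], expr.tpm.iloc[1:].sum(axis=0)
        )
        assert (out.loc["M2"] == 0).all()

    def test_unbinned_reported_not_aggregated(self):
        expr = self._expr(["M0", "unbinned"], [[10, 10], [30, 10]])
        out = aggregate_mag_expression(expr, [self._mag("M0")])
        assert "unbinned" not in out.index
        frac = out.attrs["unbinned_fraction"]
        assert frac["s0"] == pytest.approx(0.75)

    def test_unknown_mag_rejected(self):
        expr = self._expr(["MX"], [[1, 1]])
        with pytest.raises(ValidationError, match="unknown MAG"):
            aggregate_mag_expression(expr, [self._mag("M0")])

    def test_identical_tables_give_rho_one_and_df(self, rng):
        m = pd.DataFrame(rng.lognormal(size=(10, 4)),
                         index=[f"M{i}" for i in range(10)])
        res = mg_mt_correlation(m, m)
        assert res.r == pytest.approx(1.0)
        assert res.df == 40 - 2

    def test_exclusion_drops_guild(self, rng):
        m = pd.DataFrame(rng.lognormal(size=(6, 5)),
                         index=[f"M{i}" for i in range(6)])
        res = mg_mt_correlation(m, m, exclude={"M0", "M1"})
        assert res.df == 4 * 5 - 2


class TestPathwayMarkers:
    def _methanogen_mag(self):
        genes = [Gene(f"g_{sym}", 1200, (sym,)) for sym in
                 MARKER_SETS["hydrogenotrophic_methanogenesis"]]
        genes.append(Gene("g_house", 800, ("housekeeping",)))
        return MagRecord(
            mag_id="MAG_meth", taxonomy=["Archaea"], completeness=99.0,
            contamination=0.0, rrna_counts={"5S": 1, "16S": 1, "23S": 1},
            genes=genes,
        )

    def _expr_for(self, mag, tpm_value=5.0):
        info = pd.DataFrame(
            {"mag_id": [mag.mag_id] * len(mag.genes),
             "length": [g.length for g in mag.genes]},
            index=[g.gene_id for g in mag.genes],
        )
        counts = pd.DataFrame(
            tpm_value, index=info.index, columns=["s0", "s1"]
        )
        return ExpressionTable(info, counts)

    def test_hydrogenotrophic_set_fully_encoded_and_expressed(self):
        mag = self._methanogen_mag()
        reports = {r.marker_set: r
                   for r in pathway_markers(mag, self._expr_for(mag))}
        hydro = reports["hydrogenotrophic_methanogenesis"]
        assert hydro.fully_encoded and hydro.fully_expressed

    def test_missing_ack_pta_reported_absent(self):
        mag = self._methanogen_mag()  # no ack/pta genes
        reports = {r.marker_set: r
                   for r in pathway_markers(mag, self._expr_for(mag))}
        aceto = reports["acetoclastic_methanogenesis"]
        assert not aceto.encoded["ack"]
        assert not aceto.encoded["pta"]

    def test_encoded_but_not_expressed_when_tpm_zero(self):
        mag = self._methanogen_mag()
        reports = {r.marker_set: r
                   for r in pathway_markers(mag, self._expr_for(mag, 0.0))}
        hydro = reports["hydrogenotrophic_methanogenesis"]
        assert hydro.fully_encoded and not any(hydro.expressed.values())

    def test_expressed_implies_encoded(self):
        mag = self._methanogen_mag()
        for report in pathway_markers(mag, self._expr_for(mag)):
            for marker, expressed in report.expressed.items():
                assert not expressed or report.encoded[marker]

    def test_empty_marker_set_rejected(self):
        with pytest.raises(ValidationError):
            pathway_markers(self._methanogen_mag(), None, {})


class TestGuilds:
    def test_taxonomy_to_guild_mapping(self):
        lineages = {
            "a": ["Archaea", "Halobacterota", "Methanomicrobia",
                  "Methanomicrobiales", "Methanoregulaceae"],
            "b": ["Archaea", "Halobacterota", "Methanosarcinia",
                  "Methanotrichales", "Methanosaetaceae", "Methanothrix"],
            "c": ["Bacteria", "Desulfobacterota", "Syntrophia",
                  "Syntrophales", "Syntrophaceae", "Smithella"],
            "d": ["Bacteria", "Cloacimonadota"],
        }
        guilds = assign_guilds(lineages)
        assert guilds["a"] == "hydrogenotrophic_methanogen"
        assert guilds["b"] == "acetoclastic_methanogen"
        assert guilds["c"] == "syntroph"
        assert guilds["d"] == "other"
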