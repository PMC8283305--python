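"""Signature validation, protein mapping, motif census and tallies."""
import numpy as np
import pandas as pd
import pytest

from glycodag.glycosite_caller import (
    EvidenceRecord,
    ProteinIndex,
    call_glycosites,
    map_to_protein,
    motif_census,
    read_evidence,
    tally_identifications,
    validate_signature,
    write_evidence,
)
from glycodag.proteome_model import (
    DEAMIDATION_18O_SHIFT_DA as SHIFT,
    MassTable,
    ProteinRecord,
    peptide_mass,
)


def _ev(rows):
    df = pd.DataFrame(
        rows,
        columns=[
            "peptide_sequence",
            "deamidated_positions",
            "mass_delta_da",
            "genotype",
            "treatment",
            "replicate",
            "intensity",
        ],
    )
    return df


class TestEvidenceRecord:
    def test_positions_must_index_asn(self):
        with pytest.raises(ValueError, match="not Asn"):
            EvidenceRecord("AVK", (1,), SHIFT, "WT", "control", 1, 1.0)
        with pytest.raises(ValueError, match="outside"):
            EvidenceRecord("NVK", (9,), SHIFT, "WT", "control", 1, 1.0)

    def test_roundtrip_tsv(self, tmp_path):
        df = _ev([("NVSK", (1,), SHIFT, "WT", "control", 1, 1e6),
                  ("ANNTK", (2, 3), 2 * SHIFT, "WT", "NaCl", 2, 2e6)])
        path = tmp_path / "ev.tsv"
        write_evidence(df, path)
        back = read_evidence(path)
        assert list(back["deamidated_positions"]) == [(1,), (2, 3)]
        assert back["intensity"].tolist() == [1e6, 2e6]


class TestValidateSignature:
    def test_single_deamidation_exact_shift_accepted(self):
        res = validate_signature("NVDFSNNNLSGR", (6,), 2.9890)
        assert res.accepted and res.k == 1

    def test_double_deamidation_additive_shift_accepted(self):
        res = validate_signature("ANNTK", (2, 3), 5.9780)
        assert res.accepted and res.k == 2

    def test_light_oxygen_deamidation_rejected(self):
        # spontaneous (H2^16O) deamidation: +0.9840 Da, ~2 Da off signature
        res = validate_signature("NVDFSNNNLSGR", (6,), 0.9840)
        assert not res.accepted

    def test_no_deamidation_rejected_with_reason(self):
        res = validate_signature("AVK", (), 2.9890)
        assert not res.accepted and res.reason == "no deamidation annotated"

    def test_tolerance_scales_with_peptide_mass(self):
        pep = "NVDFSNNNLSGR"
        theo = peptide_mass(pep, 0)
        just_in = SHIFT + 9e-6 * theo
        just_out = SHIFT + 11e-6 * theo
        assert validate_signature(pep, (6,), just_in, tol_ppm=10).accepted
        assert not validate_signature(pep, (6,), just_out, tol_ppm=10).accepted

    def test_acceptance_monotone_in_tolerance(self):
        pep = "NVSK"
        rng = np.random.default_rng(3)
        for _ in range(200):
            delta = SHIFT + rng.normal(0, 5e-5)
            tols = (1.0, 5.0, 10.0, 50.0)
            accepted = [
                validate_signature(pep, (1,), delta, tol_ppm=t).accepted
                for t in tols
            ]
            # once accepted at a tolerance, accepted at every larger one
            assert accepted == sorted(accepted)


class TestMapToProtein:
    def test_position_arithmetic(self, toy_proteins):
        index = ProteinIndex(toy_proteins)
        # LLLNATR starts at position 9 of P3; peptide Asn at 4 -> protein 12
        calls = map_to_protein("LLLNATR", (4,), index)
        assert [(c.protein_id, c.protein_position) for c in calls] == [("P3", 12)]
        assert calls[0].canonical and calls[0].unique

    def test_sequon_split_across_tryptic_boundary_is_canonical(self, toy_proteins):
        # P1 peptide VSLLNK ends ...NK; the protein continues TR, giving N-K-T
        index = ProteinIndex(toy_proteins)
        calls = map_to_protein("VSLLNK", (5,), index)
        (call,) = calls
        assert call.protein_id == "P1" and call.protein_position == 13
        assert call.canonical  # completed by the next tryptic peptide

    def test_shared_peptide_flagged_non_unique(self, toy_proteins):
        index = ProteinIndex(toy_proteins)
        calls = map_to_protein("AAGNVTK", (4,), index)
        assert {c.protein_id for c in calls} == {"P1", "P2"}
        assert all(not c.unique for c in calls)

    def test_unknown_peptide_maps_nowhere(self, toy_proteins):
        index = ProteinIndex(toy_proteins)
        assert map_to_protein("WWWWNCSWWW", (5,), index) == []


class TestCallGlycosites:
    def test_rejected_and_unmapped_are_audited(self, toy_proteins):
        ev = _ev(
            [
                ("LLLNATR", (4,), SHIFT, "WT", "control", 1, 1e6),
                ("LLLNATR", (4,), 0.984, "WT", "control", 2, 1e6),  # light decoy
                ("NCSWWWW", (1,), SHIFT, "WT", "control", 1, 1e6),  # unmapped
            ]
        )
        calls, audit = call_glycosites(ev, ProteinIndex(toy_proteins))
        assert audit == {
            "n_evidence_rows": 3,
            "n_accepted": 2,
            "n_rejected": 1,
            "n_unmapped": 1,
        }
        assert len(calls) == 1

    def test_row_order_and_duplication_invariance(self, toy_proteins):
        rows = [
            ("LLLNATR", (4,), SHIFT, "WT", "control", 1, 1e6),
            ("VSLLNK", (5,), SHIFT, "WT", "control", 1, 2e6),
        ]
        index = ProteinIndex(toy_proteins)
        base, _ = call_glycosites(_ev(rows), index)
        shuffled, _ = call_glycosites(_ev(rows[::-1] + rows), index)
        key = ["protein_id", "protein_position"]
        assert set(map(tuple, base[key].values)) == set(
            map(tuple, shuffled[key].values)
        )


class TestMotifCensus:
    def test_single_site_context(self):
        prot = ProteinRecord("P", "AAANVSAAA")
        calls = pd.DataFrame(
            [
                dict(
                    protein_id="P",
                    protein_position=4,
                    peptide_sequence="AAANVSAAA",
                    deamidated_positions=(4,),
                    canonical=True,
                    n_deamidations=1,
                    unique=True,
                    genotype="WT",
                    treatment="control",
                    replicate=1,
                    intensity=1.0,
                    mass_delta_da=SHIFT,
                )
            ]
        )
        m = motif_census(calls, {"P": prot}, flank=2)
        assert m.frequencies.loc[2, "S"] == 1.0
        assert m.frequencies.loc[0, "N"] == 1.0
        assert (m.n_canonical, m.n_noncanonical) == (1, 0)

    def test_frequencies_sum_to_one_and_truncate_at_termini(self):
        prot = ProteinRecord("P", "NVSAAAAANVT")  # site 1 has no -1/-2 context
        rows = []
        for pos in (1, 9):
            rows.append(
                dict(
                    protein_id="P", protein_position=pos,
                    peptide_sequence=prot.sequence, deamidated_positions=(pos,),
                    canonical=True, n_deamidations=1, unique=True,
                    genotype="WT", treatment="control", replicate=1,
                    intensity=1.0, mass_delta_da=SHIFT,
                )
            )
        m = motif_census(pd.DataFrame(rows), {"P": prot}, flank=2)
        sums = m.frequencies.sum(axis=1)
        assert np.allclose(sums.loc[[0, 1, 2]], 1.0)
        # offset -1 exists only for the internal site
        assert np.isclose(sums.loc[-1], 1.0)
        assert m.frequencies.loc[2, "S"] == 0.5
        assert m.frequencies.loc[2, "T"] == 0.5

    def test_empty_call_set(self):
        m = motif_census(pd.DataFrame(), {}, flank=2)
        assert m.n_total == 0
        assert (m.frequencies.to_numpy() == 0).all()


class TestTallies:
    def _calls(self, toy_proteins, rows):
        return call_glycosites(_ev(rows), ProteinIndex(toy_proteins))[0]

    def test_multisite_peptide_counts_sites_once_each(self, toy_proteins):
        prot = [ProteinRecord("Q", "AANGTNWSAAK")]
        rows = [("AANGTNWSAAK", (3, 6), 2 * SHIFT, "WT", "control", 1, 1e6)]
        calls = call_glycosites(_ev(rows), ProteinIndex(prot))[0]
        tally = tally_identifications(calls)
        total = tally[tally["genotype"] == "all"].iloc[0]
        assert (
            total["n_glycosites"],
            total["n_glycopeptides"],
            total["n_glycoproteins"],
        ) == (2, 1, 1)

    def test_replicates_counted_once_per_group(self, toy_proteins):
        rows = [
            ("LLLNATR", (4,), SHIFT, "WT", "control", r, 1e6) for r in (1, 2, 3)
        ]
        calls = self._calls(toy_proteins, rows)
        tally = tally_identifications(calls)
        wt = tally[(tally["genotype"] == "WT") & (tally["treatment"] == "control")]
        assert wt.iloc[0]["n_glycopeptides"] == 1

    def test_disjoint_peptides_same_site_counted_once(self):
        # two peptides (0-missed and 1-missed) covering the same Asn
        prot = [ProteinRecord("Q", "AAKNGTKLLLR")]
        rows = [
            ("NGTK", (1,), SHIFT, "WT", "control", 1, 1e6),
            ("NGTKLLLR", (1,), SHIFT, "WT", "control", 1, 1e6),
        ]
        calls = call_glycosites(_ev(rows), ProteinIndex(prot))[0]
        tally = tally_identifications(calls)
        total = tally[tally["genotype"] == "all"].iloc[0]
        assert total["n_glycosites"] == 1
        assert total["n_glycopeptides"] == 2

    def test_canonical_flag_agrees_with_sequon_scan(self, small_bundle, small_result):
        from glycodag.proteome_model import canonical_sequon_positions

        proteins = {p.id: p for p in small_bundle["proteins"]}
        for row in small_result.calls.drop_duplicates(
            ["protein_id", "protein_position"]
        ).itertuples(index=False):
            expected = row.protein_position in canonical_sequon_positions(
                proteins[row.protein_id]
            )
            assert row.canonical == expected
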