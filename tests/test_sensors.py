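"""Luciferase sensor sites and tandem-site insert assembly."""

import pytest

from starmir.errors import BoundsError, ConfigError
from starmir.oligos import verify_duplex
from starmir.reference import MATURE_MIRNAS, PRINTED_OLIGOS
from starmir.sensors import (
    assemble_sensor_insert,
    make_bulged_site,
    make_perfect_site,
    make_seed_mutant_site,
    seed_complementarity,
)
from starmir.sequences import (
    MatureMiRNA,
    dna,
    reverse_complement,
    rna,
    transcribe,
    watson_crick_pair,
)


def opposing_mirna_base(mirna, site_pos):
    """Site position p lies opposite miRNA position L - p + 1."""
    return mirna.sequence.base(len(mirna) - site_pos + 1)


@pytest.mark.parametrize(
    "mirna,expected",
    [
        ("hsa-miR-146b-3p", "CCAGAACTGAGTCCACAGGGCA"),
        ("hsa-miR-146b-5p", "AGCCTATGGAATTCAGTTCTCA"),
    ],
)
def test_perfect_site_is_the_dna_reverse_complement(mirna, expected):
    site = make_perfect_site(MATURE_MIRNAS[mirna])
    assert site.sequence == expected
    assert site.edits == ()
    back = transcribe(reverse_complement(dna(site.sequence)))
    assert back.residues == MATURE_MIRNAS[mirna].sequence.residues


class TestBulgedSite:
    def test_validated_146b_bulged_site(self, mir146b_3p):
        site = make_bulged_site(mir146b_3p)
        assert site.sequence == "CCAGAACTGACAGCACAGGGCA"
        assert site.edits == (
            (11, "G", "C"),
            (12, "T", "A"),
            (13, "C", "G"),
        )

    def test_edited_positions_cannot_pair_with_the_mirna(self, mir146b_3p):
        site = make_bulged_site(mir146b_3p)
        for pos, _old, new in site.edits:
            opposite = opposing_mirna_base(mir146b_3p, pos)
            assert not watson_crick_pair(opposite, new.replace("T", "U"))

    def test_bulge_must_not_touch_the_seed(self, mir146b_3p):
        with pytest.raises(ConfigError, match="seed"):
            make_bulged_site(mir146b_3p, (6, 7, 8))
        with pytest.raises(BoundsError):
            make_bulged_site(mir146b_3p, (23,))

    def test_generic_mirna_bulge_follows_the_same_rule(self):
        mirna = MatureMiRNA(rna("UAGCUUAUCAGACUGAUGUUGA", "toy"))
        site = make_bulged_site(mirna)
        assert len(site.edits) == 3
        for pos, _old, new in site.edits:
            assert new == opposing_mirna_base(mirna, pos).replace("U", "T")


class TestSeedMutantSite:
    def test_validated_146b_mut_site(self, mir146b_3p):
        parent = make_bulged_site(mir146b_3p)
        site = make_seed_mutant_site(parent, mir146b_3p)
        assert site.sequence == "CCAGAACTGACAGCAGACGGGA"
        assert site.edits == (
            (16, "C", "G"),
            (18, "G", "C"),
            (21, "C", "G"),
        )

    def test_seed_pairing_is_abolished(self, mir146b_3p):
        parent = make_bulged_site(mir146b_3p)
        site = make_seed_mutant_site(parent, mir146b_3p)
        assert seed_complementarity(parent, mir146b_3p, (2, 7)) == 6
        assert seed_complementarity(site, mir146b_3p, (2, 7)) < 4

    def test_parent_must_be_bulged(self, mir146b_3p):
        perfect = make_perfect_site(mir146b_3p)
        with pytest.raises(ConfigError, match="bulged parent"):
            make_seed_mutant_site(perfect, mir146b_3p)


class TestAssembledInserts:
    @pytest.mark.parametrize(
        "mirna,kind,vector,construct",
        [
            ("hsa-miR-146b-3p", "perfect", "psicheck", "psicheck-hs-146b-3p"),
            ("hsa-miR-146b-5p", "perfect", "psicheck", "psicheck-hs-146b-5p"),
            ("hsa-miR-146b-3p", "bulged", "pmir", "pMIR-hs-146b-3p"),
            ("hsa-miR-146b-3p", "seed_mutant", "pmir", "pMIR-hs-146b-3p-mut"),
        ],
    )
    def test_all_validated_sensor_pairs_reproduce(
        self, mirna, kind, vector, construct
    ):
        m = MATURE_MIRNAS[mirna]
        if kind == "perfect":
            site = make_perfect_site(m)
        elif kind == "bulged":
            site = make_bulged_site(m)
        else:
            site = make_seed_mutant_site(make_bulged_site(m), m)
        insert = assemble_sensor_insert(site, vector)
        assert (insert.oligos.top, insert.oligos.bottom) == PRINTED_OLIGOS[
            construct
        ]
        report = verify_duplex(insert.oligos, insert.profile)
        assert report.ok and report.n_mismatches == 0

    def test_insert_contains_exactly_two_site_copies(self, mir146b_3p):
        site = make_perfect_site(mir146b_3p)
        insert = assemble_sensor_insert(site, "psicheck")
        assert insert.oligos.top.count(site.sequence) == 2
        assert insert.body.count(site.sequence) == 2

    def test_hairpin_profile_rejected_for_sensors(self, mir146b_3p):
        site = make_perfect_site(mir146b_3p)
        with pytest.raises(ConfigError, match="not a sensor"):
            assemble_sensor_insert(site, "plvx-shRNA2")

    def test_bottom_core_is_exact_reverse_complement_of_top_core(
        self, mir146b_3p
    ):
        site = make_bulged_site(mir146b_3p)
        insert = assemble_sensor_insert(site, "pmir")
        comp = {"A": "T", "T": "A", "C": "G", "G": "C"}
        pair = insert.oligos
        assert pair.bottom_core == "".join(
            comp[b] for b in reversed(pair.top_core)
        )
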