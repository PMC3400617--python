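"""Hairpin design: passenger construction, seed collisions, mutations."""

import pytest

from starmir.errors import ConfigError
from starmir.hairpin import (
    DEFAULT_LOOP,
    PAPER_POLICY,
    HairpinDesign,
    MutationSpec,
    apply_mutations,
    assemble_hairpin,
    build_passenger,
    design_hairpin,
    destabilize_passenger_3prime,
    detect_seed_collision,
    propose_seed_mutations,
)
from starmir.sequences import MatureMiRNA, reverse_complement, rna
from starmir.synthetic import generate_fixtures
from starmir.thermo import duplex_end_stability


@pytest.mark.parametrize(
    "mirna,expected",
    [
        ("hsa-miR-127-3p", "AGCCAAGCUCAGACGGAUCCGA"),
        ("hsa-miR-142-3p", "UCCAUAAAGUAGGAAACACUACA"),
        ("hsa-miR-146b-3p", "CCAGAACUGAGUCCACAGGGCA"),
    ],
)
def test_build_passenger_is_exact_reverse_complement(mirna, expected):
    from starmir.reference import MATURE_MIRNAS

    guide = MATURE_MIRNAS[mirna]
    passenger = build_passenger(guide)
    assert passenger.residues == expected
    # base-by-base complement oracle
    comp = {"A": "U", "U": "A", "C": "G", "G": "C"}
    assert passenger.residues == "".join(
        comp[b] for b in reversed(guide.sequence.residues)
    )


class TestSeedCollision:
    def test_unmutated_anti_146b_collides_with_counterpart(self, mir146b_5p):
        report = detect_seed_collision(
            rna("CCAGAACUGAGUCCACAGGGCA"), mir146b_5p
        )
        assert report.window == (3, 8)
        assert report.identical_count == 6
        assert report.collision
        assert report.passenger_window_bases == "AGAACU"
        assert report.counterpart_window_bases == "AGAACU"

    def test_mutated_passenger_no_longer_collides(self, mir146b_5p):
        report = detect_seed_collision(
            rna("CCAGGAUUGAGUCCACAGGGCA"), mir146b_5p
        )
        assert report.identical_count == 4  # AGGAUU vs AGAACU
        assert not report.collision

    def test_disjoint_window_bases_count_zero(self):
        counterpart = MatureMiRNA(rna("GGGGGGGGGGGGGGGGGGGGGG"))
        report = detect_seed_collision(
            rna("AAAAAAAAAAAAAAAAAAAAAA"), counterpart
        )
        assert report.identical_count == 0
        assert not report.collision

    def test_missing_counterpart_is_a_configuration_error(self):
        with pytest.raises(ConfigError, match="no-counterpart"):
            detect_seed_collision(rna("CCAGAACUGAGUCCACAGGGCA"), None)


class TestProposeSeedMutations:
    def test_prototype_case_reproduces_sites_5_and_7(self, mir146b_5p):
        passenger = rna("CCAGAACUGAGUCCACAGGGCA")
        mutations = propose_seed_mutations(passenger, mir146b_5p)
        assert [(m.position, m.from_base, m.to_base) for m in mutations] == [
            (5, "A", "G"),
            (7, "C", "U"),
        ]

    def test_no_collision_returns_empty_list(self, mir127_3p, mir146b_5p):
        passenger = build_passenger(mir127_3p)
        assert propose_seed_mutations(passenger, mir146b_5p) == []

    def test_mutations_always_destroy_the_collision(self):
        import re

        def runs(seq):
            return [
                m.span() for m in re.finditer(r"U{4,}", "CCC" + seq + "UUCAAGAGA")
            ]

        pairs = generate_fixtures(seed=11, n=120, seed_overlap=6)
        for pair in pairs:
            passenger = build_passenger(pair.guide)
            mutations = propose_seed_mutations(passenger, pair.counterpart)
            assert len(mutations) >= 2
            mutated = apply_mutations(passenger, mutations)
            report = detect_seed_collision(mutated, pair.counterpart)
            assert not report.collision
            # no terminator run introduced that the unmutated insert lacked:
            # post-mutation runs all lie inside pre-existing runs
            before = runs(passenger.residues)
            for start, end in runs(mutated.residues):
                assert any(s <= start and end <= e for s, e in before)

    def test_selection_is_deterministic(self):
        (pair,) = generate_fixtures(seed=5, n=1, seed_overlap=6)
        passenger = build_passenger(pair.guide)
        first = propose_seed_mutations(passenger, pair.counterpart)
        second = propose_seed_mutations(passenger, pair.counterpart)
        assert first == second

    def test_reference_seed_set_forces_a_novel_window(self, mir146b_5p):
        passenger = rna("CCAGAACUGAGUCCACAGGGCA")
        baseline = propose_seed_mutations(passenger, mir146b_5p)
        mutated = apply_mutations(passenger, baseline)
        taken = mutated.window(*PAPER_POLICY.window)
        shifted = propose_seed_mutations(
            passenger, mir146b_5p, reference_seeds=[taken]
        )
        final = apply_mutations(passenger, shifted)
        assert final.window(*PAPER_POLICY.window) != taken


class TestAssembleHairpin:
    def test_prototype_precursor_layout_and_length(self, prototype_design):
        d = prototype_design
        assert d.precursor.residues == (
            "CCAGGAUUGAGUCCACAGGGCA" "UUCAAGAGA" "UGCCCUGUGGACUCAGUUCUGG"
        )
        assert len(d.precursor) == 22 + 9 + 22 == 53
        assert len(d.loop) == 9

    def test_unmutated_design_passenger_equals_revcomp(self, mir127_3p):
        design = assemble_hairpin(mir127_3p)
        assert design.mutations == ()
        assert (
            design.passenger.residues
            == reverse_complement(mir127_3p.sequence).residues
        )

    def test_reverting_mutations_restores_the_complement(
        self, prototype_design
    ):
        d = prototype_design
        reverted = list(d.passenger.residues)
        for m in d.mutations:
            reverted[m.position - 1] = m.from_base
        assert "".join(reverted) == d.unmutated_passenger.residues

    def test_short_loop_is_rejected(self, mir127_3p):
        with pytest.raises(ConfigError, match="cannot close"):
            assemble_hairpin(mir127_3p, loop=rna("UUC"))

    def test_inconsistent_mutation_record_is_rejected(self, mir146b_3p):
        # from_base must match the unmutated passenger at that position
        with pytest.raises(ValueError):
            HairpinDesign(
                guide=mir146b_3p,
                passenger=rna("CCAGGAUUGAGUCCACAGGGCA"),
                loop=DEFAULT_LOOP,
                mutations=(MutationSpec(5, "C", "G"), MutationSpec(7, "C", "U")),
            )


class TestDestabilizePassenger3Prime:
    def test_single_pass_places_one_mutation_in_terminal_window(
        self, prototype_design
    ):
        improved = destabilize_passenger_3prime(prototype_design, 1)
        new = set(improved.mutations) - set(prototype_design.mutations)
        assert len(new) == 1
        (spec,) = new
        assert 19 <= spec.position <= 22
        # exhaustive oracle: no single substitution does strictly better
        best = duplex_end_stability(
            improved.guide.sequence, improved.passenger
        ).asymmetry
        for pos in range(19, 23):
            base = prototype_design.passenger.base(pos)
            for alt in "ACGU":
                if alt == base:
                    continue
                candidate = apply_mutations(
                    prototype_design.passenger,
                    [MutationSpec(pos, base, alt)],
                )
                score = duplex_end_stability(
                    prototype_design.guide.sequence, candidate
                ).asymmetry
                assert score <= best + 1e-12

    def test_asymmetry_never_decreases(self):
        pairs = generate_fixtures(seed=3, n=25, seed_overlap=0)
        for pair in pairs:
            design = assemble_hairpin(pair.guide)
            before = duplex_end_stability(
                design.guide.sequence, design.passenger
            ).asymmetry
            import warnings as w

            with w.catch_warnings():
                w.simplefilter("ignore")
                after_design = destabilize_passenger_3prime(design, 2)
            after = duplex_end_stability(
                after_design.guide.sequence, after_design.passenger
            ).asymmetry
            assert after >= before - 1e-12

    def test_saturated_design_returned_unchanged_with_warning(
        self, mir146b_3p
    ):
        passenger = build_passenger(mir146b_3p)
        # pre-mutate the whole 3'-terminal window so nothing is left to try
        specs = tuple(
            MutationSpec(p, passenger.base(p), "A" if passenger.base(p) != "A" else "G")
            for p in range(19, 23)
        )
        design = assemble_hairpin(
            mir146b_3p, apply_mutations(passenger, specs), mutations=specs
        )
        with pytest.warns(UserWarning, match="unchanged"):
            result = destabilize_passenger_3prime(design, 1)
        assert result == design


def test_design_hairpin_without_counterpart_warns_and_emits_complement(
    mir127_3p,
):
    result = design_hairpin(mir127_3p)
    assert result.collision_pre is None
    assert result.design.mutations == ()
    assert any("counterpart" in note for note in result.warnings)
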