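"""Tokenizer, parser, validator and serializer behavior."""

import string

import pytest
from hypothesis import given, settings, strategies as st

from spices import (
    SpicesSyntaxError,
    StructureError,
    TokenKind,
    UnknownParticleError,
    parse,
    random_molecule,
    read_particle_catalog,
    serialize,
    tokenize,
    validate,
)
from conftest import molecules_isomorphic


class TestTokenize:
    def test_simple_chain(self):
        kinds = [(t.kind, t.value, t.pos) for t in tokenize("Et-Et")]
        assert kinds == [(TokenKind.NAME, "Et", 0),
                         (TokenKind.BOND, "-", 2),
                         (TokenKind.NAME, "Et", 3)]

    def test_backbone_label_offset(self):
        toks = tokenize("Me'12'")
        assert (toks[0].kind, toks[0].value) == (TokenKind.NAME, "Me")
        assert (toks[1].kind, toks[1].value, toks[1].pos) == \
            (TokenKind.LABEL, "12", 2)

    def test_illegal_character_yields_error_token(self):
        toks = tokenize("A(&")
        assert toks[2].kind is TokenKind.ERROR
        assert toks[2].pos == 2

    @pytest.mark.parametrize("text,kind,value", [
        ("[START]", TokenKind.TAG, "START"),
        ("[END]", TokenKind.TAG, "END"),
        ("[7]", TokenKind.RING, 7),
        ("12", TokenKind.COUNT, 12),
        (".", TokenKind.DOT, "."),
    ])
    def test_token_kinds(self, text, kind, value):
        tok = tokenize(text)[0]
        assert (tok.kind, tok.value) == (kind, value)

    def test_never_raises_on_junk(self):
        for junk in ["", "'''", "[", "[x]", "ä", " \t", "@#%"]:
            tokenize(junk)  # must not raise


class TestParse:
    def test_single_particle(self):
        mol = parse("Et")
        assert len(mol.nodes) == 1 and not mol.bonds and mol.parts == 1

    def test_chain_and_branch_connectivity(self):
        mol = parse("A-B(-C)-D")
        assert {tuple(b) for b in mol.bonds} == {(0, 1), (1, 2), (1, 3)}

    def test_ring_closure_bonds_two_occurrences(self):
        mol = parse("A-B[1]-C-D[1]")
        assert len(mol.nodes) == 4
        assert len(mol.bonds) == 4
        assert (1, 3) in mol.bonds  # the labeled pair B..D

    def test_four_cycle(self):
        mol = parse("A[1]-B-C-D[1]")
        assert mol.bonds == frozenset({(0, 1), (1, 2), (2, 3), (0, 3)})

    def test_repeat_prefix_chains_linearly(self):
        mol = parse("A-3B-C")
        assert [n.name for n in mol.nodes] == ["A", "B", "B", "B", "C"]
        assert mol.bonds == frozenset({(0, 1), (1, 2), (2, 3), (3, 4)})

    def test_parts_split_and_tags_attach(self):
        mol = parse("A[START]-B[END].C'x'")
        assert mol.parts == 2
        assert mol.nodes[0].tags == {"START"}
        assert mol.nodes[1].tags == {"END"}
        assert mol.nodes[2].part_index == 1
        assert mol.nodes[2].backbone_label == "x"

    def test_branch_after_branch_reattaches_to_root(self):
        mol = parse("A(-B)(-C)-D")
        assert mol.bonds == frozenset({(0, 1), (0, 2), (0, 3)})

    def test_invalid_raises_with_report(self):
        with pytest.raises(SpicesSyntaxError) as exc:
            parse("A(-B")
        assert exc.value.report.errors[0].message == "unclosed branch"

    def test_catalog_enforced(self):
        parse("Et-MeAc", catalog={"Et", "MeAc"})
        with pytest.raises(UnknownParticleError) as exc:
            parse("Et-Qx", catalog={"Et", "MeAc"})
        assert exc.value.name == "Qx"

    def test_catalog_soundness_matches_uncatalogued_parse(self):
        # parse with catalog C succeeds iff plain parse succeeds and names ⊆ C
        for seed in range(30):
            text = random_molecule(8, branch_prob=0.4, ring_prob=0.2, seed=seed)
            mol = parse(text)
            names = {n.name for n in mol.nodes}
            assert len(parse(text, catalog=names).nodes) == len(mol.nodes)
            with pytest.raises(UnknownParticleError):
                parse(text, catalog=names - {sorted(names)[0]})


class TestValidate:
    @pytest.mark.parametrize("text", [
        "Et", "Et-Et", "Et[START]-Et[END]", "A(-B)-C", "A(B)-C",
        "A[1]-B-C-D[1]", "Me'12'-Me'15'", "A.B.C", "6Et", "A-2B(-C)-D",
    ])
    def test_valid_strings(self, text):
        report = validate(text)
        assert report.valid and not report.errors

    @pytest.mark.parametrize("text,message", [
        ("A(-B", "unclosed branch"),
        ("A-B[1]", "unmatched ring closure label 1"),
        ("A-", "dangling bond separator"),
        ("-A", "dangling bond separator"),
        ("A()", "empty branch"),
        ("A B", "whitespace is not allowed"),
        ("", "empty part"),
        ("A..B", "empty part"),
        ("A[START]-B[START]", "duplicate [START] tag in part"),
        ("'x'A", "backbone label must directly follow a particle name"),
        ("A[1][1]", "ring closure bonds a particle to itself"),
        ("0Et", "repeat count must be positive"),
        ("2Et'9'", "backbone label must directly follow a particle name"),
        ("(A)", "branch must follow a particle"),
        ("A)B", "unmatched ')'"),
    ])
    def test_errors_reported_with_message(self, text, message):
        report = validate(text)
        assert not report.valid
        assert message in [e.message for e in report.errors]

    def test_unclosed_branch_position(self):
        report = validate("A(-B")
        err = report.errors[0]
        assert (err.position, err.message) == (1, "unclosed branch")

    def test_multiple_errors_in_one_pass(self):
        report = validate("A(-B.C-")
        messages = [e.message for e in report.errors]
        assert "unclosed branch" in messages
        assert "dangling bond separator" in messages

    def test_error_positions_inside_input(self):
        for text in ["A(-B", "ä-", "[", "A''B", "99999999999Et", "(('"]:
            for err in validate(text).errors:
                assert 0 <= err.position <= len(text)
                assert err.position + err.length <= len(text) + 1

    @settings(max_examples=300, deadline=None, derandomize=True)
    @given(st.text(alphabet=string.printable, max_size=40))
    def test_validate_total_on_arbitrary_text(self, text):
        report = validate(text)
        assert report.valid == (not report.errors)

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(st.text(max_size=30))
    def test_validate_total_on_unicode(self, text):
        validate(text)  # must never raise


class TestSerialize:
    def test_single_node(self):
        assert serialize(parse("Et")) == "Et"

    def test_dmpc_round_trip_isomorphic(self, dmpc):
        again = parse(serialize(dmpc))
        assert len(again.nodes) == 16
        assert molecules_isomorphic(dmpc, again)

    def test_multi_part_round_trip(self):
        mol = parse("A[START]-B(-C'7')-D[END].2Et")
        again = parse(serialize(mol))
        assert again.parts == 2
        assert molecules_isomorphic(mol, again)

    @pytest.mark.parametrize("seed", range(0, 500, 25))
    def test_random_round_trips_sampled(self, seed):
        text = random_molecule(1 + seed % 14, branch_prob=0.4,
                               ring_prob=0.15, seed=seed)
        mol = parse(text)
        assert molecules_isomorphic(mol, parse(serialize(mol)))

    def test_rejects_invariant_violations(self):
        from spices import ParticleNode, SpicesMolecule
        bad = SpicesMolecule(
            nodes=(ParticleNode(0, 0, "A"), ParticleNode(1, 0, "B")),
            bonds=frozenset({(0, 5)}), parts=1)
        with pytest.raises(StructureError):
            serialize(bad)
        disconnected = SpicesMolecule(
            nodes=(ParticleNode(0, 0, "A"), ParticleNode(1, 0, "B")),
            bonds=frozenset(), parts=1)
        with pytest.raises(StructureError):
            serialize(disconnected)


class TestExternalInterfaces:
    def test_batch_file_skips_comments(self, tmp_path):
        from spices import iter_spices_file
        path = tmp_path / "batch.spices"
        path.write_text("# header\nEt-Et\n\nA-B\n")
        assert [(ln, s) for ln, s in iter_spices_file(path)] == \
            [(2, "Et-Et"), (4, "A-B")]

    def test_particle_catalog_round_trip(self, tmp_path):
        path = tmp_path / "catalog.tsv"
        path.write_text("Et\tethylene fragment\nMeAc\tester fragment\n")
        catalog = read_particle_catalog(path)
        assert catalog == {"Et": "ethylene fragment", "MeAc": "ester fragment"}

    def test_particle_catalog_rejects_bad_names(self, tmp_path):
        bad = tmp_path / "bad.tsv"
        bad.write_text("9x\tdigit-initial name\n")
        with pytest.raises(StructureError):
            read_particle_catalog(bad)
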