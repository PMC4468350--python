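import numpy as np
import pytest

from liemarkov import (MODEL_STRUCTURES, MODELTEST_EXTRA,
                       SYMMETRIC_STRUCTURES, Pairing, build_model,
                       catalogue, distinct_pairing_structures,
                       ebf_degrees_of_freedom, get_model, is_nested,
                       is_time_reversible, list_models, list_structures,
                       nesting_graph_dot, spans_equal, verify_lie_closure)

# expected equilibrium-frequency degrees of freedom per structure,
# grouped by which frequency-moving generators (D; E1/E2) are present
_EBF_EXPECTED = {
    0: ["1.1", "2.2b", "3.3a", "3.3b", "3.3c", "5.6a", "5.7b", "5.7c",
        "5.11b", "5.11c", "9.20b"],
    1: ["3.4", "4.4b", "4.5a", "4.5b", "5.16", "6.6", "6.8b", "6.17a",
        "6.17b", "8.10b"],
    2: ["5.7a", "5.11a", "9.20a"],
    3: ["4.4a", "5.6b", "6.7a", "6.7b", "6.8a", "8.8", "8.10a", "8.16",
        "8.17", "8.18", "10.12", "10.34", "12.12"],
}

_REVERSIBLE_STRUCTURES = {"1.1", "2.2b", "3.3a", "3.3c", "3.4",
                          "4.4a", "4.4b"}


def test_structure_count():
    assert len(list_structures()) == 37


def test_variant_count_99():
    assert len(list_models()) == 99


def test_variant_names_unique():
    names = list_models(include_modeltest=True)
    assert len(names) == len(set(names)) == 108


def test_panel_count_108():
    assert len(list_models(include_modeltest=True)) == 108
    assert len(MODELTEST_EXTRA) == 9


def test_six_fully_symmetric():
    assert set(SYMMETRIC_STRUCTURES) == {"1.1", "3.3a", "4.4a", "6.7a",
                                         "9.20b", "12.12"}


def test_distinct_pairing_structures_31():
    distinct = distinct_pairing_structures()
    assert len(distinct) == 31
    assert set(distinct) == set(MODEL_STRUCTURES) - set(SYMMETRIC_STRUCTURES)


def test_dimension_matches_name_and_basis():
    for name, basis in MODEL_STRUCTURES.items():
        m = get_model(name if name in SYMMETRIC_STRUCTURES else f"RY{name}")
        assert m.dimension == int(name.split(".")[0]) == len(basis)
        assert np.linalg.matrix_rank(
            np.array([b.ravel() for b in m.basis_matrices()])) == m.dimension


def test_hidden_2_2a_rejected_with_explanation():
    with pytest.raises(KeyError, match="transversions"):
        build_model("2.2a")
    hidden = build_model("2.2a", allow_hidden=True)
    assert hidden.basis_names == ("A1", "D1")
    assert hidden.hidden


def test_symmetric_structures_ignore_pairing():
    for s in SYMMETRIC_STRUCTURES:
        assert build_model(s, Pairing.WS).pairing is Pairing.FULLY_SYMMETRIC


def test_get_model_parsing_and_aliases():
    assert get_model("RY5.6b").name == "RY5.6b"
    assert get_model("WS6.6").alias == "SSM"
    assert get_model("5.6b").pairing is Pairing.RY  # RY is the default
    assert get_model("JC").structure_name == "1.1"
    assert get_model("K2ST").name == "RY2.2b"
    assert get_model("K3ST").structure_name == "3.3a"
    assert get_model("TrNef").name == "RY3.3c"
    assert get_model("F81").structure_name == "4.4a"
    assert get_model("GM").structure_name == "12.12"
    assert get_model("DS").structure_name == "9.20b"
    with pytest.raises(KeyError):
        get_model("XY5.6b")
    with pytest.raises(KeyError):
        get_model("5.6z")


def test_spans_equal_and_pairing_difference():
    assert spans_equal(get_model("3.3a"), get_model("3.3a"))
    assert not spans_equal(get_model("RY2.2b"), get_model("WS2.2b"))
    # fully symmetric: explicit pairing copies have identical spans
    for s in SYMMETRIC_STRUCTURES:
        ry = build_model(s, Pairing.RY) if s not in SYMMETRIC_STRUCTURES \
            else get_model(s)
        assert spans_equal(ry, get_model(s))


def test_ebf_degrees_of_freedom_full_classification():
    seen = {}
    for df, names in _EBF_EXPECTED.items():
        for s in names:
            seen[s] = df
    assert set(seen) == set(MODEL_STRUCTURES)
    for s, df in seen.items():
        m = get_model(s if s in SYMMETRIC_STRUCTURES else f"RY{s}")
        assert ebf_degrees_of_freedom(m) == df, s


def test_ebf_spot_targets():
    assert ebf_degrees_of_freedom(get_model("4.4a")) == 3
    for s in ("RY5.7a", "RY5.11a", "RY9.20a"):
        assert ebf_degrees_of_freedom(get_model(s)) == 2


def test_reversibility_flags():
    for s in MODEL_STRUCTURES:
        m = get_model(s if s in SYMMETRIC_STRUCTURES else f"RY{s}")
        assert is_time_reversible(m) == (s in _REVERSIBLE_STRUCTURES), s


def test_lie_closure_spot_checks():
    for name in ("RY5.6b", "WS8.10a", "MK10.34", "12.12", "9.20b"):
        rep = verify_lie_closure(get_model(name))
        assert rep["closed"], rep


def test_nesting():
    assert is_nested(get_model("1.1"), get_model("RY2.2b"))
    assert is_nested(get_model("4.4a"), get_model("RY5.6b"))
    assert is_nested(get_model("RY2.2b"), get_model("3.3a"))
    assert is_nested(get_model("WS2.2b"), get_model("3.3a"))
    assert is_nested(get_model("RY5.6b"), get_model("RY8.8"))
    for name in ("RY8.8", "WS6.6", "9.20b"):
        assert is_nested(get_model(name), get_model("12.12"))
    assert not is_nested(get_model("RY2.2b"), get_model("WS3.3c"))
    assert not is_nested(get_model("RY5.6b"), get_model("4.4a"))


def test_catalogue_dataframe():
    df = catalogue()
    assert len(df) == 99
    assert set(df.columns) >= {"name", "dimension", "rays", "ebf_df",
                               "reversible", "alias"}
    assert (df[df.name == "RY5.6b"].rays == 6).all()
    assert df[df.name == "WS6.6"].alias.iloc[0] == "SSM"


def test_nesting_graph_dot():
    dot = nesting_graph_dot(Pairing.RY)
    assert dot.startswith("digraph")
    assert '"1.1" -> "RY2.2b"' in dot
    assert '"12.12"' in dot
    # covering edges only: the transitive 1.1 -> 12.12 edge must be absent
    assert '"1.1" -> "12.12"' not in dot
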