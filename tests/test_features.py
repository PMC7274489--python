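"""Feature encoders: dimension contracts, worked examples, brute-force
oracle equivalence and order-sensitivity properties.

Each oracle below is an independent pure-Python re-derivation of the
descriptor definition (explicit loops over positions, slices and
lookup tables), kept deliberately free of the vectorized implementation
paths it checks.
"""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from plantloc import features as ft
from plantloc.features import (
    EncodingError,
    encode,
    encode_aac,
    encode_ctdc,
    encode_ctdt,
    encode_dipep,
    encode_hybrid,
    encode_many,
    encode_ncc,
    encode_physchem,
    encode_pseaac,
    encode_qso,
    make_recipe,
)
from plantloc.seqio import ProteinRecord
from plantloc.tables import AA_INDEX, STANDARD_AA

from oracles import (
    oracle_aac,
    oracle_ctdc,
    oracle_ctdt,
    oracle_dipep,
    oracle_ncc,
    oracle_physchem,
    oracle_pseaac,
    oracle_qso,
)

# ---------------------------------------------------------------------------
# dimension contracts

@pytest.mark.parametrize(
    "name,kwargs,dim",
    [
        ("AAC", {}, 20),
        ("DIPEP", {}, 400),
        ("PseAAC", {"lam": 20}, 40),
        ("PseAAC", {"lam": 5}, 25),
        ("NCC", {}, 60),
        ("PHYSCHEM", {}, 26),
        ("CTDC", {}, 21),
        ("CTDT", {}, 21),
        ("QSO", {"maxlag": 30}, 50),
        ("QSO", {"maxlag": 12}, 32),
        ("PseAAC-NCC-DIPEP", {"lam": 20}, 500),
        ("NCC-DIPEP", {}, 460),
        ("NCC-DIPEP-CTDC-CTDT-QSO", {"maxlag": 30}, 552),
    ],
)
def test_dimension_contract(name, kwargs, dim, random_sequence):
    recipe = make_recipe(name, **kwargs)
    assert recipe.dimension == dim
    vec = encode(random_sequence(120), recipe)
    assert len(vec.values) == dim
    assert np.all(np.isfinite(vec.values))


# ---------------------------------------------------------------------------
# worked examples

def test_aac_examples():
    v = encode_aac("AAA").values
    assert v[AA_INDEX["A"]] == 1.0 and v.sum() == 1.0
    assert np.allclose(encode_aac(STANDARD_AA).values, 0.05)


def test_dipep_examples():
    v = encode_dipep("AAA").values
    assert v[0] == 1.0 and v.sum() == 1.0
    v = encode_dipep("ACAC").values
    assert v[AA_INDEX["A"] * 20 + AA_INDEX["C"]] == pytest.approx(2 / 3)
    assert v[AA_INDEX["C"] * 20 + AA_INDEX["A"]] == pytest.approx(1 / 3)
    assert v.sum() == pytest.approx(1.0)


def test_pseaac_lambda_zero_reduces_to_aac(random_sequence):
    seq = random_sequence(90)
    assert np.allclose(encode_pseaac(seq, lam=0).values, encode_aac(seq).values)


def test_pseaac_homopolymer_thetas_zero():
    v = encode_pseaac("A" * 10, lam=3).values
    assert np.allclose(v[20:], 0)
    assert np.allclose(v[:20], encode_aac("A" * 10).values)


def test_ncc_examples():
    v = encode_ncc("K" * 60, terminal_length=25).values
    for block in range(3):
        b = v[20 * block : 20 * (block + 1)]
        assert b[AA_INDEX["K"]] == 1.0 and b.sum() == 1.0


def test_ncc_blocks_each_sum_to_one(random_sequence):
    v = encode_ncc(random_sequence(75)).values
    for block in range(3):
        assert v[20 * block : 20 * (block + 1)].sum() == pytest.approx(1.0)


def test_physchem_homopolymer_lysine(table):
    v = encode_physchem("K" * 30).values
    names = [n for n, _ in table.physchem_groups]
    assert v[names.index("basic")] == 1.0
    assert v[names.index("acidic")] == 0.0
    assert len(v) == 26


def test_ctdc_hydrophobicity_group1_sequence():
    # all six residues lie in hydrophobicity group 1 (polar)
    v = encode_ctdc("RKEDQN").values
    assert tuple(v[:3]) == (1.0, 0.0, 0.0)


def test_ctdc_attribute_blocks_sum_to_one(random_sequence):
    v = encode_ctdc(random_sequence(100)).values
    for k in range(7):
        assert v[3 * k : 3 * k + 3].sum() == pytest.approx(1.0)


def test_ctdt_homopolymer_is_zero():
    assert np.allclose(encode_ctdt("W" * 40).values, 0)


def test_ctdt_single_transition():
    # R is hydrophobicity class 1, C class 3: one (1,3) transition over
    # one adjacent pair
    v = encode_ctdt("RC").values
    assert v[1] == 1.0  # hydrophobicity pair (1,3)
    assert v[0] == 0.0 and v[2] == 0.0


def test_qso_weight_zero_limit(random_sequence):
    seq = random_sequence(100)
    with pytest.raises(EncodingError):
        encode_qso(seq, maxlag=100)
    # w = 0: composition part equals normalized AAC, lag part vanishes
    v = encode_qso(seq, maxlag=10, w_qso=0.0).values
    assert np.allclose(v[:20], encode_aac(seq).values, atol=1e-12)
    assert np.all(v[20:] == 0)


def test_qso_sums_to_one(random_sequence):
    for _ in range(5):
        v = encode_qso(random_sequence(), maxlag=30, w_qso=0.1).values
        assert v.sum() == pytest.approx(1.0, abs=1e-9)


def test_hybrid_prefix_identity(random_sequence):
    seq = random_sequence(130)
    v = encode_hybrid(seq, ["NCC", "DIPEP"])
    assert len(v.values) == 460
    assert np.array_equal(v.values[:60], encode_ncc(seq).values)
    assert np.array_equal(v.values[60:], encode_dipep(seq).values)
    assert v.recipe.feature_names[0] == "NCC:N.A"


def test_hybrid_error_names_failing_part():
    with pytest.raises(EncodingError, match="NCC"):
        encode_hybrid("A" * 40, ["AAC", "NCC"])


# ---------------------------------------------------------------------------
# oracle equivalence on random sequences

N_ORACLE = 100


@pytest.mark.parametrize(
    "name",
    ["AAC", "DIPEP", "PseAAC", "NCC", "PHYSCHEM", "CTDC", "CTDT", "QSO"],
)
def test_oracle_equivalence(name, table, rng):
    """Every encoder matches its independent brute-force oracle on 100
    random sequences of length 51-500, to 1e-9."""
    recipe = make_recipe(name, lam=5, maxlag=15)
    oracles = {
        "AAC": lambda s: oracle_aac(s),
        "DIPEP": lambda s: oracle_dipep(s),
        "PseAAC": lambda s: oracle_pseaac(s, 5, 0.05, table),
        "NCC": lambda s: oracle_ncc(s, 25),
        "PHYSCHEM": lambda s: oracle_physchem(s, table),
        "CTDC": lambda s: oracle_ctdc(s, table),
        "CTDT": lambda s: oracle_ctdt(s, table),
        "QSO": lambda s: oracle_qso(s, 15, 0.1, table),
    }
    for _ in range(N_ORACLE):
        length = int(rng.integers(51, 501))
        seq = "".join(rng.choice(list(STANDARD_AA), size=length))
        got = encode(seq, recipe).values
        want = oracles[name](seq)
        assert np.max(np.abs(got - want)) < 1e-9


def test_hybrid_matches_partwise_oracle(table, rng):
    recipe = make_recipe("NCC-DIPEP-CTDC-CTDT-QSO", maxlag=30)
    assert recipe.dimension == 552
    for _ in range(5):
        seq = "".join(rng.choice(list(STANDARD_AA), size=int(rng.integers(60, 300))))
        want = np.concatenate(
            [
                oracle_ncc(seq, 25),
                oracle_dipep(seq),
                oracle_ctdc(seq, table),
                oracle_ctdt(seq, table),
                oracle_qso(seq, 30, 0.1, table),
            ]
        )
        assert np.max(np.abs(encode(seq, recipe).values - want)) < 1e-9


def test_pseaac_dense_oracle(table, rng):
    for _ in range(10):
        seq = "".join(rng.choice(list(STANDARD_AA), size=80))
        got = encode_pseaac(seq, lam=5, w_pse=0.05).values
        assert np.max(np.abs(got - oracle_pseaac(seq, 5, 0.05, table))) < 1e-10


# ---------------------------------------------------------------------------
# properties

@settings(deadline=None, max_examples=50, derandomize=True)
@given(st.text(alphabet=STANDARD_AA, min_size=1, max_size=200))
def test_aac_nonnegative_sums_to_one(seq):
    v = encode_aac(seq).values
    assert np.all(v >= 0)
    assert v.sum() == pytest.approx(1.0, abs=1e-9)


@settings(deadline=None, max_examples=30, derandomize=True)
@given(st.text(alphabet=STANDARD_AA, min_size=2, max_size=200))
def test_dipep_normalized(seq):
    v = encode_dipep(seq).values
    assert np.all(v >= 0) and v.sum() == pytest.approx(1.0, abs=1e-9)


def test_permutation_invariance_and_sensitivity(rng):
    """Reversal preserves composition-type features but changes
    order-sensitive ones (on a sequence built to guarantee a change)."""
    seq = "ACDEF" * 10 + "WYWYW" * 10  # asymmetric block structure
    rev = seq[::-1]
    assert np.allclose(encode_aac(seq).values, encode_aac(rev).values)
    assert np.allclose(encode_physchem(seq).values, encode_physchem(rev).values)
    assert np.allclose(encode_ctdc(seq).values, encode_ctdc(rev).values)
    # NCC sees different termini; QSO/PseAAC/DIPEP see different order
    shuffled = "".join(rng.permutation(list(seq)))
    assert not np.allclose(encode_dipep(seq).values, encode_dipep(shuffled).values)
    assert not np.allclose(
        encode_qso(seq, maxlag=5).values, encode_qso(shuffled, maxlag=5).values
    )
    assert not np.allclose(
        encode_pseaac(seq, lam=5).values, encode_pseaac(shuffled, lam=5).values
    )
    assert not np.allclose(encode_ncc(seq).values, encode_ncc(seq[::-1]).values)


def test_encoders_are_pure(random_sequence):
    seq = random_sequence(150)
    recipe = make_recipe("PseAAC-NCC-DIPEP")
    a = encode(seq, recipe).values
    b = encode(seq, recipe).values
    assert np.array_equal(a, b)


def test_domain_errors():
    with pytest.raises(EncodingError):
        encode_aac("")
    with pytest.raises(EncodingError):
        encode_dipep("A")
    with pytest.raises(EncodingError):
        encode_pseaac("ACDEF", lam=5)
    with pytest.raises(EncodingError, match="length"):
        encode_ncc("A" * 50, terminal_length=25)
    with pytest.raises(EncodingError):
        encode_aac("MKXV")
    with pytest.raises(ValueError, match="unknown encoder"):
        make_recipe("AAC-NOPE")


def test_encode_many_stacks_rows(random_sequence):
    recs = [ProteinRecord(f"p{i}", random_sequence(100)) for i in range(4)]
    recipe = make_recipe("AAC")
    m = encode_many(recs, recipe)
    assert m.values.shape == (4, 20)
    assert m.record_ids == ("p0", "p1", "p2", "p3")
    assert np.allclose(m.values[2], encode_aac(recs[2].sequence).values)
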