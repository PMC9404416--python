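import numpy as np
import pandas as pd
import pytest

from herdfert.pedigree import Pedigree, PedigreeError, UNKNOWN
from herdfert.studies import _random_pedigree


def test_trio_relationships_and_inverse(trio):
    A = trio.relationship_matrix()
    i = {a: k for k, a in enumerate(trio.ids)}
    assert A[i["O"], i["S"]] == 0.5 and A[i["O"], i["D"]] == 0.5
    assert A[i["O"], i["O"]] == 1.0 and A[i["S"], i["D"]] == 0.0
    Ai = trio.a_inverse().toarray()
    # Henderson's rules by hand for a non-inbred trio
    assert Ai[i["S"], i["S"]] == pytest.approx(1.5)
    assert Ai[i["D"], i["D"]] == pytest.approx(1.5)
    assert Ai[i["O"], i["O"]] == pytest.approx(2.0)
    assert Ai[i["O"], i["S"]] == pytest.approx(-1.0)
    assert Ai[i["S"], i["D"]] == pytest.approx(0.5)
    assert np.abs(A @ Ai - np.eye(3)).max() < 1e-12


def test_founders_only_identity():
    ped = Pedigree.from_frame(
        pd.DataFrame({"animal": ["A", "B"], "sire": [None, None], "dam": [None, None]})
    )
    assert np.array_equal(ped.relationship_matrix(), np.eye(2))
    assert np.array_equal(ped.a_inverse().toarray(), np.eye(2))


def test_fullsib_pair_relationship():
    ped = Pedigree.from_frame(
        pd.DataFrame(
            {
                "animal": ["P1", "P2", "S1", "S2"],
                "sire": [None, None, "P1", "P1"],
                "dam": [None, None, "P2", "P2"],
            }
        )
    )
    A = ped.relationship_matrix()
    i = ped.index
    assert A[i["S1"], i["S2"]] == pytest.approx(0.5)


@pytest.mark.parametrize(
    "builder, expected_F",
    [
        ("fullsib_mating", 0.25),
        ("parent_offspring", 0.25),
    ],
)
def test_inbreeding_hand_cases(builder, expected_F, fullsib_mating):
    if builder == "fullsib_mating":
        ped = fullsib_mating
        target = "O"
    else:
        ped = Pedigree.from_frame(
            pd.DataFrame(
                {
                    "animal": ["P", "M", "C", "X"],
                    "sire": [None, None, "P", "P"],
                    "dam": [None, None, "M", "C"],
                }
            )
        )
        target = "X"
    F = ped.inbreeding()
    assert F[ped.index[target]] == pytest.approx(expected_F)
    A = ped.relationship_matrix()
    assert np.allclose(np.diag(A) - 1.0, F)


def test_offspring_of_unrelated_parents_not_inbred(trio):
    assert trio.inbreeding()[trio.index["O"]] == 0.0


def test_toposort_reorders_offspring_first_listing():
    ped = Pedigree.from_frame(
        pd.DataFrame({"animal": ["O", "S", "D"], "sire": ["S", None, None], "dam": ["D", None, None]})
    )
    i = ped.index
    assert i["S"] < i["O"] and i["D"] < i["O"]


def test_self_parent_and_cycle_raise():
    with pytest.raises(PedigreeError):
        Pedigree.from_frame(
            pd.DataFrame({"animal": ["A"], "sire": ["A"], "dam": [None]})
        )
    with pytest.raises(PedigreeError, match="cycle"):
        Pedigree.from_frame(
            pd.DataFrame({"animal": ["A", "B"], "sire": ["B", "A"], "dam": [None, None]})
        )


def test_duplicate_animal_raises():
    with pytest.raises(PedigreeError, match="duplicate"):
        Pedigree.from_frame(
            pd.DataFrame({"animal": ["A", "A"], "sire": [None, None], "dam": [None, None]})
        )


def test_prune_is_ancestor_closure():
    rng = np.random.default_rng(7)
    ped = _random_pedigree(rng, 200)
    keep = [str(ped.ids[k]) for k in rng.integers(100, 200, size=10)]
    sub = ped.prune(keep, drop_unknown_birth=False)
    # brute-force closure oracle
    closure = set()
    stack = [ped.index[a] for a in keep]
    while stack:
        i = stack.pop()
        if i in closure:
            continue
        closure.add(i)
        for p in (ped.sire[i], ped.dam[i]):
            if p != UNKNOWN:
                stack.append(p)
    assert set(sub.ids) == {ped.ids[i] for i in closure}
    # pruned pedigree is still valid and parents are retained
    sub.relationship_matrix()


def test_prune_empty_and_missing_ids(trio):
    assert trio.prune([], drop_unknown_birth=False).n == 0
    sub = trio.prune(["O", "ZZ"], drop_unknown_birth=False)
    assert sub.n == 3
    assert any("ZZ" in w for w in sub.warnings)


def test_random_pedigrees_algebra_properties():
    rng = np.random.default_rng(11)
    for _ in range(5):
        ped = _random_pedigree(rng, int(rng.integers(50, 200)))
        A = ped.relationship_matrix()
        Ai = ped.a_inverse()
        assert np.abs(A @ Ai.toarray() - np.eye(ped.n)).max() < 1e-8
        assert np.linalg.eigvalsh(A)[0] >= -1e-10
        assert np.allclose(np.diag(A) - 1.0, ped.inbreeding())
        assert Ai.nnz <= 9 * ped.n


def test_noninbred_toggle_matches_when_no_inbreeding(trio):
    a = trio.a_inverse().toarray()
    b = trio.a_inverse(assume_noninbred=True).toarray()
    assert np.allclose(a, b)


def test_dense_limit_guides_to_sparse_path():
    rng = np.random.default_rng(3)
    ped = _random_pedigree(rng, 60)
    with pytest.raises(ValueError, match="a_inverse"):
        ped.relationship_matrix(max_dense=50)
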