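"""Salt-bridge detection and interface burial analysis."""

import itertools

import numpy as np
import pytest

from yrb.classify import (
    AtomClass,
    NEGATIVE_ATOMS,
    POSITIVE_ATOMS,
    classify_structure,
)
from yrb.fixtures import (
    PlantedContact,
    PlantedDimerSpec,
    build_planted_dimer,
)
from yrb.interface import (
    UNDEFINED,
    find_salt_bridges,
    interface_atoms,
    interface_class_profile,
    salt_bridges_tsv,
)
from yrb.model import StructureModel


def brute_force_bridges(model, group_a, group_b, cutoff=4.0):
    """All-pairs O(n^2) oracle: residue-level pairs at minimal atom distance."""
    charged = []
    for chain, residue, atom in model.iter_atoms():
        if (residue.name, atom.name) in POSITIVE_ATOMS:
            charged.append(("+", chain.chain_id, residue.seq_id, atom))
        elif (residue.name, atom.name) in NEGATIVE_ATOMS:
            charged.append(("-", chain.chain_id, residue.seq_id, atom))
    pairs = {}
    for (s1, c1, r1, a1), (s2, c2, r2, a2) in itertools.combinations(charged, 2):
        if {s1, s2} != {"+", "-"}:
            continue
        in_a1, in_b1 = c1 in group_a, c1 in group_b
        in_a2, in_b2 = c2 in group_a, c2 in group_b
        if not ((in_a1 and in_b2) or (in_b1 and in_a2)):
            continue
        d = a1.distance_to(a2)
        if d > cutoff:
            continue
        cat = (c1, r1) if s1 == "+" else (c2, r2)
        an = (c1, r1) if s1 == "-" else (c2, r2)
        key = (cat, an)
        pairs[key] = min(pairs.get(key, np.inf), d)
    return pairs


def _as_pairs(bridges):
    return {
        ((b.cation_chain, b.cation_seq), (b.anion_chain, b.anion_seq)): b.distance
        for b in bridges
    }


def test_planted_bridge_found_exactly(bridge_dimer):
    bridges = find_salt_bridges(bridge_dimer, {"A"}, {"B"})
    assert len(bridges) == 1
    b = bridges[0]
    assert (b.cation_resname, b.cation_atom) == ("LYS", "NZ")
    assert (b.anion_resname, b.anion_atom) == ("ASP", "OD1")
    assert b.distance == pytest.approx(3.5, abs=0.051)


def test_planted_far_contact_not_a_bridge(far_dimer):
    assert find_salt_bridges(far_dimer, {"A"}, {"B"}) == []


def test_empty_model_gives_no_bridges():
    model = StructureModel("e", [])
    with pytest.raises(ValueError):
        # no chains at all: groups cannot reference anything
        find_salt_bridges(model, {"A"}, {"B"})


def test_group_validation(bridge_dimer):
    with pytest.raises(ValueError, match="overlap"):
        find_salt_bridges(bridge_dimer, {"A"}, {"A"})
    with pytest.raises(ValueError, match="unknown chain"):
        find_salt_bridges(bridge_dimer, {"A"}, {"Z"})
    with pytest.raises(ValueError, match="non-empty"):
        find_salt_bridges(bridge_dimer, set(), {"B"})
    with pytest.raises(ValueError, match="positive"):
        find_salt_bridges(bridge_dimer, {"A"}, {"B"}, cutoff=0)


@pytest.fixture(scope="module")
def multi_bridge_dimer():
    """Two planted bridges plus decoy charged residues out of range."""
    spec = PlantedDimerSpec(
        sequence_a=("LYS", "GLY", "ARG", "GLY", "GLU"),
        sequence_b=("ASP", "GLY", "GLU", "GLY", "LYS"),
        contacts=(
            PlantedContact(1, "NZ", 1, "OD1", 3.2),
            PlantedContact(3, "NH1", 3, "OE1", 3.8),
        ),
        seed=11,
    )
    return build_planted_dimer(spec)


def test_neighbor_search_equals_brute_force(multi_bridge_dimer, bridge_dimer, far_dimer):
    for model in (multi_bridge_dimer, bridge_dimer, far_dimer):
        for cutoff in (3.0, 4.0, 5.0, 8.0):
            fast = _as_pairs(find_salt_bridges(model, {"A"}, {"B"}, cutoff=cutoff))
            slow = brute_force_bridges(model, {"A"}, {"B"}, cutoff=cutoff)
            assert set(fast) == set(slow)
            for key in fast:
                assert fast[key] == pytest.approx(slow[key], abs=1e-9)


def test_symmetry_in_group_order(multi_bridge_dimer):
    ab = _as_pairs(find_salt_bridges(multi_bridge_dimer, {"A"}, {"B"}))
    ba = _as_pairs(find_salt_bridges(multi_bridge_dimer, {"B"}, {"A"}))
    assert ab == ba


def test_monotone_in_cutoff(multi_bridge_dimer):
    found = [
        set(_as_pairs(find_salt_bridges(multi_bridge_dimer, {"A"}, {"B"}, cutoff=c)))
        for c in (2.5, 3.0, 3.5, 4.0, 5.0, 6.0, 10.0)
    ]
    for smaller, larger in zip(found, found[1:]):
        assert smaller <= larger


def test_residue_pair_not_double_counted(multi_bridge_dimer):
    # ARG NH1/NH2 (and GLU OE1/OE2) may both be in range; only one bridge
    # per residue pair is reported, at the minimal atom-atom distance
    bridges = find_salt_bridges(multi_bridge_dimer, {"A"}, {"B"}, cutoff=8.0)
    pairs = [b.residue_pair for b in bridges]
    assert len(pairs) == len(set(pairs))


def test_distant_chains_have_no_interface():
    spec = PlantedDimerSpec(
        sequence_a=("GLY", "ALA", "GLY"),
        sequence_b=("GLY", "ALA", "GLY"),
        contacts=(PlantedContact(2, "CB", 2, "CB", 100.0),),
        seed=2,
    )
    model = build_planted_dimer(spec)
    report = interface_atoms(model, {"A"}, {"B"}, n_points=240)
    assert report.interface_atoms_a == [] and report.interface_atoms_b == []
    assert report.buried_area_a == 0.0 and report.buried_area_b == 0.0


def test_distance_method_finds_contacting_residues(bridge_dimer):
    report = interface_atoms(
        bridge_dimer, {"A"}, {"B"}, method="distance", distance_cutoff=5.0,
        n_points=240,
    )
    residues_a = {k[1] for k in report.interface_atoms_a}
    residues_b = {k[1] for k in report.interface_atoms_b}
    assert 2 in residues_a and 2 in residues_b  # the planted LYS and ASP
    # the contacting side-chain tips are interfacial
    assert any(k[3] == "NZ" for k in report.interface_atoms_a)
    assert any(k[3] == "OD1" for k in report.interface_atoms_b)


def test_buried_area_roughly_symmetric(leucine_dimer):
    report = interface_atoms(leucine_dimer, {"A"}, {"B"}, n_points=480)
    a, b = report.buried_area_a, report.buried_area_b
    assert a > 0 and b > 0
    assert abs(a - b) / max(a, b) < 0.25


def test_buried_area_partition(leucine_dimer):
    report = interface_atoms(leucine_dimer, {"A"}, {"B"}, n_points=240)
    classified = classify_structure(leucine_dimer)
    profile = interface_class_profile(classified, report)
    for side, total in (("a", report.buried_area_a), ("b", report.buried_area_b)):
        class_sum = sum(entry["area"] for entry in profile[side].values())
        assert class_sum == pytest.approx(total, abs=1e-9)
        fr_sum = sum(
            entry["fraction"] for entry in profile[side].values()
            if not isinstance(entry["fraction"], str)
        )
        assert fr_sum == pytest.approx(1.0, abs=1e-9)


def test_hydrophobic_interface_profile(leucine_dimer):
    report = interface_atoms(leucine_dimer, {"A"}, {"B"}, n_points=480)
    profile = interface_class_profile(classify_structure(leucine_dimer), report)
    for side in ("a", "b"):
        assert profile[side][str(AtomClass.HYDROPHOBIC)]["fraction"] > 0.5


def test_zero_contact_fractions_undefined():
    spec = PlantedDimerSpec(
        sequence_a=("GLY",), sequence_b=("GLY",),
        contacts=(PlantedContact(1, "CA", 1, "CA", 80.0),), seed=4,
    )
    model = build_planted_dimer(spec)
    report = interface_atoms(model, {"A"}, {"B"}, n_points=240)
    profile = interface_class_profile(classify_structure(model), report)
    assert profile["a"][str(AtomClass.NEUTRAL)]["fraction"] == UNDEFINED


def test_salt_bridge_tsv_row_count(bridge_dimer):
    bridges = find_salt_bridges(bridge_dimer, {"A"}, {"B"})
    text = salt_bridges_tsv(bridges)
    lines = text.strip().splitlines()
    assert len(lines) == 2  # header + one bridge
    assert "K2(A)-D2(B)" in lines[1]
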