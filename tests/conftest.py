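import pytest

from yrb.classify import build_standard_table, classify_structure
from yrb.fixtures import (
    PlantedContact,
    PlantedDimerSpec,
    build_all_residue_peptide,
    build_planted_dimer,
    simple_salt_bridge_dimer,
)
from yrb.model import StructureModel


@pytest.fixture(scope="session")
def table():
    return build_standard_table()


@pytest.fixture(scope="session")
def twenty_mer():
    """One chain containing each standard residue exactly once."""
    return StructureModel("all-residues", [build_all_residue_peptide()])


@pytest.fixture(scope="session")
def twenty_mer_classified(twenty_mer):
    return classify_structure(twenty_mer)


@pytest.fixture(scope="session")
def bridge_dimer():
    """LYS/ASP dimer with one NZ-OD1 contact planted at 3.5 A."""
    return simple_salt_bridge_dimer(3.5, seed=0)


@pytest.fixture(scope="session")
def far_dimer():
    """Same chains, contact planted at 6.0 A: no bridge at the default cutoff."""
    spec = PlantedDimerSpec(
        sequence_a=("GLY", "LYS", "GLY"),
        sequence_b=("GLY", "ASP", "GLY"),
        contacts=(PlantedContact(2, "NZ", 2, "OD1", 6.0),),
        seed=3,
        identifier="far-dimer",
    )
    return build_planted_dimer(spec)


@pytest.fixture(scope="session")
def leucine_dimer():
    """Hydrophobic interface: leucine isopropyl groups planted face to face."""
    spec = PlantedDimerSpec(
        sequence_a=("GLY", "LEU", "GLY"),
        sequence_b=("GLY", "LEU", "GLY"),
        contacts=(
            PlantedContact(2, "CD1", 2, "CD1", 4.0),
            PlantedContact(2, "CD2", 2, "CD2", 4.0),
            PlantedContact(2, "CG", 2, "CG", 4.6),
        ),
        seed=5,
        identifier="leu-dimer",
    )
    return build_planted_dimer(spec)
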