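"""Shared fixtures: toy structures and a synthetic mutation dataset."""

import warnings

import pytest

from rinsev import aa_index, ml_framework, structure_io, synthetic_data

warnings.filterwarnings("ignore", category=FutureWarning)


@pytest.fixture(scope="session")
def helix_model():
    return structure_io.read_structure(
        structure_io.generate_toy_structure("helix", 12, seed=1))


@pytest.fixture(scope="session")
def strand_model():
    return structure_io.read_structure(
        structure_io.generate_toy_structure("strand", 8, seed=7))


@pytest.fixture(scope="session")
def globule_bundle():
    """60-residue compact toy structure with props, RIN and centralities."""
    return synthetic_data.synthetic_structure_bundle(n_residues=60, seed=7)


@pytest.fixture(scope="session")
def synthetic_aa_dist():
    return aa_index.build_distance_index(
        synthetic_data.generate_property_matrix(seed=7))


@pytest.fixture(scope="session")
def planted_dataset(globule_bundle, synthetic_aa_dist):
    """Default-condition mutation set (n=400, seed 7) with feature matrix."""
    cfg = synthetic_data.GeneratorConfig(n_mutations=400, seed=7)
    muts, truth = synthetic_data.generate_mutation_dataset(
        cfg, globule_bundle["position_features"], synthetic_aa_dist)
    assembler = ml_framework.FeatureAssembler(
        globule_bundle["position_features"], synthetic_aa_dist)
    X, y, dropped = assembler.fit(muts)
    return {"muts": muts, "truth": truth, "assembler": assembler,
            "X": X, "y": y, "dropped": dropped}
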