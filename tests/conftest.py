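"""Shared fixtures: synthetic complexes and a trained model.

The expensive end-to-end model is trained once per session on 20 seeded
synthetic complexes (the study conditions of the recovery experiments) and
shared between the pipeline and acceptance tests.
"""

from __future__ import annotations

import warnings

import pytest

from betop.pipeline import EpitopePredictor
from betop.structure_io import ComplexRecord, parse_structure
from betop.synthetic import SyntheticSpec, generate_complex

warnings.filterwarnings("ignore", category=FutureWarning)
warnings.filterwarnings("ignore", category=UserWarning)

TRAIN_SEEDS = range(100, 120)


def make_complex(seed: int, n_patches: int = 1, **kwargs) -> tuple[ComplexRecord, list[set]]:
    """Parse one synthetic complex; returns (record, planted patch residue sets)."""
    pdb_text, truth = generate_complex(
        SyntheticSpec(seed=seed, n_patches=n_patches, **kwargs))
    record = parse_structure(pdb_text, truth["antigen_chains"],
                             truth["antibody_chains"], name=f"synth{seed}")
    patches = [{(c, int(n), i) for c, n, i in patch} for patch in truth["epitopes"]]
    return record, patches


def make_antigen(seed: int, n_patches: int = 1, **kwargs) -> tuple[ComplexRecord, list[set]]:
    """Same structure but with the antibody chain left out (prediction input)."""
    pdb_text, truth = generate_complex(
        SyntheticSpec(seed=seed, n_patches=n_patches, **kwargs))
    record = parse_structure(pdb_text, truth["antigen_chains"], [],
                             name=f"antigen{seed}")
    patches = [{(c, int(n), i) for c, n, i in patch} for patch in truth["epitopes"]]
    return record, patches


@pytest.fixture(scope="session")
def training_complexes() -> list[ComplexRecord]:
    return [make_complex(seed)[0] for seed in TRAIN_SEEDS]


@pytest.fixture(scope="session")
def trained_model(training_complexes) -> EpitopePredictor:
    return EpitopePredictor(random_state=0).fit(training_complexes)
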