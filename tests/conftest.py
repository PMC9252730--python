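"""Shared fixtures: synthetic structures and template stores, generated once
per session (everything is seeded, nothing is read from outside the repo)."""

from __future__ import annotations

import numpy as np
import pytest

from resbind import features as feat
from resbind import model as mdl
from resbind import synth
from resbind.structure import parse_pdb

MAIN_STORE_SEED = 11
QUERY_SEED = 424242


@pytest.fixture(scope="session")
def helix_bundle():
    """A 60-residue bound helical fixture: (pdb text, manifest, structure)."""
    spec = synth.FixtureSpec(n_residues=60, seed=7, structure_id="helix60")
    text, manifest = synth.generate_structure(spec)
    return text, manifest, parse_pdb(text, structure_id="helix60")


@pytest.fixture(scope="session")
def unbound_bundle():
    """A 50-residue ligand-free fixture for oracle-equivalence checks."""
    spec = synth.FixtureSpec(
        n_residues=50, seed=19, ligand="none", structure_id="apo50"
    )
    text, manifest = synth.generate_structure(spec)
    return text, manifest, parse_pdb(text, structure_id="apo50")


@pytest.fixture(scope="session")
def main_store_dir(tmp_path_factory):
    """On-disk 20-template store (default study conditions)."""
    out = tmp_path_factory.mktemp("store") / "templates"
    return synth.generate_template_store(20, out, seed=MAIN_STORE_SEED)


@pytest.fixture(scope="session")
def main_records(main_store_dir):
    return mdl.load_template_store(main_store_dir)


@pytest.fixture(scope="session")
def query_bundle():
    """Held-out bound query with its ground truth: (text, manifest, structure)."""
    spec = synth.FixtureSpec(
        n_residues=60, seed=QUERY_SEED, structure_id="query"
    )
    text, manifest = synth.generate_structure(spec)
    return text, manifest, parse_pdb(text, structure_id="query")


@pytest.fixture(scope="session")
def end_to_end(main_records, query_bundle):
    """Predictions of the held-out query from the 20-template store."""
    text, manifest, structure = query_bundle
    predictions, model, frame = mdl.predict_structure(
        structure, main_records, seed=5
    )
    keys = feat.residue_keys_from_frame(frame)
    truth = dict(zip(keys, manifest["labels"]))
    return {
        "structure": structure,
        "manifest": manifest,
        "predictions": predictions,
        "model": model,
        "frame": frame,
        "truth": truth,
    }


@pytest.fixture(scope="session")
def cli_store_dir(tmp_path_factory):
    """A smaller store for CLI smoke tests (6 templates of 40 residues)."""
    out = tmp_path_factory.mktemp("clistore") / "templates"
    base = synth.FixtureSpec(n_residues=40)
    return synth.generate_template_store(6, out, base_spec=base, seed=23)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
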