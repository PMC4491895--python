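import warnings

import numpy as np
import pytest

from jrpnet import embedding, pipeline, recurrence, synth


@pytest.fixture(autouse=True)
def _quiet_flag_warnings():
    # fallback delay/dimension warnings are expected on stochastic data
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", UserWarning)
        yield


@pytest.fixture
def sine_series():
    """Noiseless sine, 1200 frames.

    The period (40.618 frames, golden-ratio fractional part) is
    incommensurate with the sampling grid so the orbit fills its ellipse
    densely instead of revisiting a handful of exact values."""
    t = np.arange(1200)
    return np.sin(2 * np.pi * t / 40.618)


@pytest.fixture
def noisy_sine():
    """Period-40 sine with light measurement noise (SNR ~ 35 dB), which
    breaks the bin-degeneracy plateaus of the histogram MI curve."""
    rng = np.random.default_rng(8)
    t = np.arange(1200)
    return np.sin(2 * np.pi * t / 40) + 0.02 * rng.normal(size=1200)


@pytest.fixture
def small_run(tmp_path):
    """Synthetic inputs for a small end-to-end run (12 residues, 400 frames)."""
    system = synth.SyntheticSystem(
        n_residues=12, n_frames=400,
        coupling_pairs=frozenset({(2, 5)}), coupling_strength=0.8, seed=7,
    )
    series_path = tmp_path / "series.tsv"
    pdb_path = tmp_path / "reference.pdb"
    synth.write_series_tsv(series_path, synth.generate_series(system), system.residue_ids)
    synth.write_ca_pdb(pdb_path, synth.generate_reference_coordinates(system),
                       system.residue_ids)
    return system, series_path, pdb_path


def recurrence_matrices_for(system, target_rate=0.03):
    """Default-parameter recurrence matrices of a synthetic system."""
    mat = synth.generate_series(system)
    params = pipeline.compute_embedding_params(mat, system.residue_ids)
    matrices, rates = pipeline.compute_recurrence_matrices(
        mat, system.residue_ids, params, target_rate
    )
    return matrices, rates
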